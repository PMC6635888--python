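# Methods

`speechmaps` simulates early speech acquisition (babbling and imitation)
with two growing self-organizing maps (GSOMs) bound by a Hebbian
association: a **semantic map (S-MAP)** whose nodes come to represent words,
and a **phonetic map (P-MAP)** whose nodes come to represent syllable
realizations.  The scientific question the simulation addresses is whether
adding somatosensory (tactile/proprioceptive) input to auditory input
accelerates the emergence of consonantal feature ordering — in particular
place of articulation — on the phonetic map.

## The model language

The corpus is a synthetic 70-word monosyllabic lexicon: 5 V syllables
(/i e a o u/), 45 CV syllables (consonants /b d g p t k m n l/ × 5 vowels)
and 20 CCV syllables (onset clusters /bl gl pl kl/ × 5 vowels).  Each word
is realized three times with phonetic jitter (timing ±10 % per segment,
articulatory targets ±0.05), giving 210 stimulus items.

**Semantics.**  Each word carries a sparse binary semantic feature vector
from a hierarchical category scheme: 1 shared feature, 10 categories × 8
category features, and 4 idiosyncratic features per word — 361 distinct
features in total at the defaults.  The pairing of meaning slots to phonetic
forms is a seeded random bijection, so meaning is arbitrary with respect to
form.

**Articulation.**  A motor plan is a list of tier/target/timing actions on
four articulator tiers (lip aperture, tongue-tip distance, tongue-dorsum
distance, jaw height; values are normalized distances, 0 = contact).
Consonants contribute a contact action (target exactly 0) on their
place-matched tier plus a manner-dependent jaw posture (plosive 0.15, nasal
0.35, lateral 0.45 — a tight seal needs a high jaw, the lateral channel a
low one); the lateral additionally holds a mid tongue-dorsum posture
(lowered tongue sides).  Closure durations encode the one laryngeal trace
visible to articulator tracking: voiced plosives 55 ms, voiceless 95 ms
(the closure/VOT asymmetry), nasals 100 ms (murmur), lateral 60 ms.
Trajectories are rendered with cosine ramps (50 ms attack) at a 10 ms hop
and clipped to [0, 1].  The somatosensory representation is
`activation = 1 − distance` per tier per frame.

**Audition.**  The auditory representation is a 24-band bark spectrogram
(10 ms frames) synthesized directly in the bark domain: vowels carry
Gaussian formant peaks (standard F1–F3 reference values) with
place-dependent initial transitions from consonantal loci; plosive closures
are silent (voiced: low-frequency voice bar) and released with a
place-dependent burst (labial diffuse-low, alveolar high, velar compact
mid); nasals carry a low murmur; the lateral is vowel-like with attenuated
mid bands.  A `bark_filterbank` front end (10 ms frames, Zwicker bands,
log-compressed) is provided for externally supplied waveforms but is not
used by the synthetic path.

What the generator does **not** emulate: natural within-speaker variability
beyond parametric jitter, coarticulatory detail beyond CV transitions,
prosody, voicing continua, or waveform-accurate acoustics.  Passing tests
therefore show that the *mechanism* (map ordering, association learning,
the modality contrast) works on representationally faithful input geometry
— not that it would survive raw natural recordings.

## Map inputs

Each representation is time-normalized to 30 frames by linear interpolation
and flattened (auditory 720, somatosensory 120, combined 840 dimensions).
In combined mode the two blocks are scaled to equal corpus-mean squared
norm so neither modality dominates by sheer energy.  Each mode's assembled
vectors are then globally rescaled so the corpus **total variance** equals
`0.1 × dim`.  This variance convention is what makes the dimension-
proportional GSOM growth threshold (below) behave identically across modes:
somatosensory vectors are far more correlated than auditory ones, and
without the rescale their pairwise distances never accumulate past the
growth threshold.  Semantic vectors follow the same convention.

## Growing self-organizing maps

Both maps are rectangular 4-neighborhood lattices starting as 2×2 seeds.
Training is online: winner-takes-all best-matching-unit (BMU) search
(Euclidean; ties to the lowest node id), neighborhood adaptation
`w += lr · exp(−d²/2σ²) · (x − w)` over lattice-Manhattan distance `d ≤
radius`, and quantization-error accumulation `err(bmu) += ‖x − w‖²`.

Growth follows the spread-factor rule `GT = −D · ln(SF)` with `SF = 0.05`:
a boundary node whose accumulated error exceeds GT inserts new nodes into
its free lattice neighbor positions (weights linearly extrapolated from the
opposite neighbor, else copy+noise) and resets its error; an interior node
pushes half its error outward to its neighbors instead, so insertion only
ever extends the map edge and the lattice stays connected and hole-free.

Three stabilizers keep growth in the regime where node counts rise quickly
and then saturate (the behavior the simulation is meant to reproduce)
rather than avalanche:

* **error forgetting** — accumulated errors decay ×0.9 at each cycle end,
  so only *sustained* quantization error drives growth.  0.9 is the largest
  retention at which the manner-of-articulation contrast between training
  modes stays null (stronger retention over-fragments the combined map);
* **growth budget** — at most `max(8, 1.0 × N)` insertions per map per
  cycle (128 in the establishment cycle), bounding the transient when every
  node is simultaneously over threshold;
* **dissipative redistribution** — interior nodes shed only half their
  excess, so redistribution chains decay geometrically.

The S-MAP uses a fixed neighborhood radius of 1: word vectors are
near-orthogonal discrete clusters, and a wide neighborhood only drags
other words' nodes off their targets (measured as runaway growth).  The
P-MAP uses the 3 → 1 radius schedule, which is what produces its
topographic feature ordering.

Key defaults: learning rate 0.35 → 0.05 (linear per cycle), radius 3 → 1,
establishment-cycle learning rate 0.6.  All constants are config keys.

## Association and working modes

The S-MAP×P-MAP link matrix holds weights in [0, 1].  On each co-activation
of winners (s, p): `w[s,p] += lr·(1 − w[s,p])` while every other weight in
row s and column p decays by `(1 − lr·decay_ratio)` (bounded Hebbian rule
with competitive normalization; lr 0.2, decay ratio 0.5).  The matrix gains
zero rows/columns whenever either map grows.

*Production*: word → semantic winner → argmax over its association row →
P-MAP node → the stored exemplar nearest that node's weights.  *Perception*:
auditory form → P-MAP winner → argmax over its association column → word of
that semantic node.  For combined-mode models the perception winner is
found on the auditory sub-distance (the somatosensory block is masked): an
external speaker provides no somatosensory signal, and experiments with
imputing the corpus-mean block showed it systematically displaces the
winner toward somatosensorily average nodes, depressing perception accuracy.
Somatosensory-only models cannot perceive external audio at all and raise
`ModeError`; their internal round-trip checks use the mode-consistent
training vectors.

## Training regimen

Cycle 0 presents every item once at high learning rate to establish both
maps and seed the link weights.  Cycles 1–50 present each of the 210 items
7 times in seeded shuffled order (1470 base steps and association updates
per cycle).  After every step a GSOM check runs: if the presented item's
P-MAP node also hosts items of a different word, the conflicting items are
scheduled for 2 extra presentations within the cycle (total extras capped
at 20 % of base steps).  Cycles 1–10 are the babbling phase; from cycle 11
an interconnection check at each cycle end verifies every word's
produce/perceive round trip and re-presents failing words at an elevated
association learning rate (0.5), plus the conflicting items where the
failure involves an unclear node.  All corrective actions are logged.

Experiments run 10 seeds per input mode (auditory, somatosensory,
combined) over the *same* corpus with the *same* seed list, so per-run
differences between modes are attributable to modality alone.

## Measurements

Per cycle: the number of **unclear nodes** (≥2 items of different words),
**clear non-separated nodes** (≥2 items, one word; the inverse of
overlearning), **occupied nodes**; **feature-region counts** (place,
manner) — occupied nodes take the majority label of their items, unoccupied
nodes the label of the nearest occupied node in lattice graph distance, and
regions are 4-connected uniform-label components counted over the completed
map; **round-trip accuracies**.  Mode contrasts are tested with a two-sided
Wilcoxon rank-sum: exact by full enumeration of rank assignments (midranks,
so ties are handled) for combined n ≤ 20, normal approximation with tie
correction otherwise.

## Problem sizes and determinism

The default experiment (3 modes × 10 runs × 51 cycles on 210 items) takes
roughly 8–10 minutes on one CPU; the test suite trains the same experiment
once and shares it across checks.  All randomness flows from integer seeds
through `numpy` SeedSequences: corpus generation, map initialization,
presentation order, and growth noise are all reproducible bit-for-bit from
(config, seed).

## Known limitations

* The somatosensory representation is 4-tier articulator-distance coding;
  manner and voicing contrasts are carried only by closure durations and
  jaw posture, so somatosensory-only training separates words much more
  slowly than the other modes (and place far better than manner) — this
  asymmetry is the designed basis of the modality effect, not an artifact.
* Region counts depend on final map size; comparisons are meaningful
  between modes trained with identical schedules, not against maps of a
  different size.
* The phonemic level (syllable-structure awareness, phoneme inventory
  extraction) is outside the model: the maps order phonetic realizations,
  and the association to meanings is what renders phonetic differences
  contrastive.
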