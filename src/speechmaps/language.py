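"""Synthetic model language: lexicon, semantics, articulation and sensory codes.

The training corpus emulated here is a 70-word monosyllabic "model language":
5 V syllables (/i e a o u/), 45 CV syllables (9 consonants x 5 vowels) and
20 CCV syllables (4 onset clusters /bl gl pl kl/ x 5 vowels), each word
realized three times with phonetic jitter, giving 210 stimulus items.

Every item carries
  * a motor plan (articulator-tier target/timing actions),
  * rendered articulator trajectories (normalized distances, 10 ms hop),
  * a somatosensory neural representation (activation = 1 - distance),
  * a bark-scale auditory neural representation (24 bands x 10 ms frames),
and every word carries a sparse binary semantic feature vector drawn from a
hierarchical category scheme (361 distinct features at the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Segment",
    "Word",
    "MotorPlan",
    "TrajectorySet",
    "AuditoryRep",
    "SomatoRep",
    "StimulusItem",
    "TrainingVector",
    "CorpusConfig",
    "Corpus",
    "ConfigurationError",
    "build_lexicon",
    "synthesize_motor_plan",
    "render_trajectories",
    "somatosensory_rep",
    "synthesize_auditory",
    "bark_filterbank",
    "vectorize",
    "build_corpus",
    "hz_to_bark",
    "TIERS",
    "MODES",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent corpus configurations."""


# ---------------------------------------------------------------------------
# segment inventory

TIERS = ("lip", "tongue_tip", "tongue_dorsum", "jaw")
MODES = ("auditory", "somatosensory", "combined")

FRAME_HOP_MS = 10.0


@dataclass(frozen=True)
class Segment:
    symbol: str
    kind: str                      # "vowel" | "consonant"
    place: str = "none"            # labial | alveolar | velar | none
    manner: str = "none"           # plosive | nasal | lateral | none
    voiced: bool = True
    vowel_height: str = "none"     # high | mid | low | none
    vowel_backness: str = "none"   # front | central | back | none

    def __post_init__(self):
        if self.kind == "vowel":
            assert self.place == "none" and self.manner == "none"
            assert self.vowel_height != "none" and self.vowel_backness != "none"
        else:
            assert self.place != "none" and self.manner != "none"
            assert self.vowel_height == "none" and self.vowel_backness == "none"


def _v(sym, height, backness):
    return Segment(sym, "vowel", vowel_height=height, vowel_backness=backness)


def _c(sym, place, manner, voiced):
    return Segment(sym, "consonant", place=place, manner=manner, voiced=voiced)


SEGMENT_INVENTORY: dict[str, Segment] = {
    s.symbol: s
    for s in [
        _v("i", "high", "front"),
        _v("e", "mid", "front"),
        _v("a", "low", "central"),
        _v("o", "mid", "back"),
        _v("u", "high", "back"),
        _c("b", "labial", "plosive", True),
        _c("d", "alveolar", "plosive", True),
        _c("g", "velar", "plosive", True),
        _c("p", "labial", "plosive", False),
        _c("t", "alveolar", "plosive", False),
        _c("k", "velar", "plosive", False),
        _c("m", "labial", "nasal", True),
        _c("n", "alveolar", "nasal", True),
        _c("l", "alveolar", "lateral", True),
    ]
}


# ---------------------------------------------------------------------------
# domain records


@dataclass
class Word:
    word_id: int
    syllable_structure: str            # "V" | "CV" | "CCV"
    segments: tuple[Segment, ...]
    semantic_vector: np.ndarray        # binary, len = global feature count

    @property
    def symbols(self) -> str:
        return "".join(s.symbol for s in self.segments)

    @property
    def vowel(self) -> Segment:
        return next(s for s in self.segments if s.kind == "vowel")

    @property
    def onset(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "consonant")


@dataclass
class MotorPlan:
    # actions: (tier name, target value in [0,1], onset ms, offset ms)
    actions: list[tuple[str, float, float, float]]
    total_duration: float
    # segment timeline kept for the auditory front-end: (symbol, onset, offset)
    segment_times: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self):
        for _, _, on, off in self.actions:
            if not (0.0 <= on <= off <= self.total_duration + 1e-9):
                raise ValueError("action outside plan duration")


@dataclass
class TrajectorySet:
    tiers: dict[str, np.ndarray]       # tier name -> samples in [0,1]
    hop_ms: float = FRAME_HOP_MS

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.tiers.values())))

    def as_array(self) -> np.ndarray:
        return np.stack([self.tiers[t] for t in TIERS])


@dataclass
class AuditoryRep:
    activation: np.ndarray             # 24 x T in [0,1]
    frame_hop: float = FRAME_HOP_MS

    def __post_init__(self):
        if self.activation.shape[0] != 24:
            raise ValueError("auditory representation must have 24 bark rows")


@dataclass
class SomatoRep:
    activation: np.ndarray             # 4 x T in [0,1]
    frame_hop: float = FRAME_HOP_MS


@dataclass
class StimulusItem:
    word_id: int
    realization_index: int
    motor_plan: MotorPlan
    trajectories: TrajectorySet
    auditory: AuditoryRep
    somato: SomatoRep


@dataclass
class TrainingVector:
    values: np.ndarray
    modality_mask: np.ndarray          # per entry: 0 = auditory, 1 = somato

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class CorpusConfig:
    vowels: tuple[str, ...] = ("i", "e", "a", "o", "u")
    consonants: tuple[str, ...] = ("b", "d", "g", "p", "t", "k", "m", "n", "l")
    clusters: tuple[str, ...] = ("bl", "gl", "pl", "kl")
    realizations_per_word: int = 3
    seed: int = 0
    frames: int = 30                   # fixed frame count after time normalization
    timing_jitter: float = 0.10        # relative duration jitter per segment
    target_jitter: float = 0.05        # absolute articulatory target jitter
    amplitude: float = 1.0             # auditory output gain (0 -> silence)
    # map-input scale: per mode, vectors are globally rescaled so the corpus
    # total variance equals rep_variance * dim.  This keeps the ratio between
    # typical pairwise distances and the dimension-proportional GSOM growth
    # threshold identical across modes (somatosensory vectors are far more
    # correlated than auditory ones), so growth is driven by accumulated
    # error everywhere rather than by one-shot presentations.
    rep_variance: float = 0.1
    # hierarchical semantic generator: total distinct features =
    # shared + categories*category_features + n_words*word_features
    semantic_categories: int = 10
    category_features: int = 8
    word_features: int = 4
    shared_features: int = 1

    def validate(self) -> None:
        for sym in self.vowels + self.consonants:
            if sym not in SEGMENT_INVENTORY:
                raise ConfigurationError(f"unknown segment {sym!r}")
        for cl in self.clusters:
            for sym in cl:
                if sym not in self.consonants:
                    raise ConfigurationError(
                        f"cluster {cl!r} uses consonant {sym!r} absent from inventory"
                    )

    def n_words(self) -> int:
        return (
            len(self.vowels)
            + len(self.consonants) * len(self.vowels)
            + len(self.clusters) * len(self.vowels)
        )

    def n_semantic_features(self) -> int:
        cats = min(self.semantic_categories, self.n_words())
        return (
            self.shared_features
            + cats * self.category_features
            + self.n_words() * self.word_features
        )


# ---------------------------------------------------------------------------
# lexicon and semantics


def _semantic_vectors(config: CorpusConfig, n_words: int) -> np.ndarray:
    """Binary word-by-feature matrix from a hierarchical category scheme.

    Every word activates the shared feature block, its semantic category's
    block and its own idiosyncratic block.  The pairing of meaning slots to
    phonetic forms is a seeded random bijection, so meaning is arbitrary with
    respect to form.
    """
    n_feat = config.n_semantic_features()
    cats = min(config.semantic_categories, n_words)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5E17]))
    meaning_slot = rng.permutation(n_words)

    vectors = np.zeros((n_words, n_feat), dtype=np.float64)
    cat_block = config.shared_features
    word_block = cat_block + cats * config.category_features
    for word_id in range(n_words):
        slot = meaning_slot[word_id]
        vec = vectors[word_id]
        vec[: config.shared_features] = 1.0
        cat = slot % cats if cats else 0
        if cats:
            start = cat_block + cat * config.category_features
            vec[start : start + config.category_features] = 1.0
        start = word_block + slot * config.word_features
        vec[start : start + config.word_features] = 1.0
    return vectors


def build_lexicon(config: CorpusConfig | None = None) -> list[Word]:
    """Enumerate the V / CV / CCV cross-product and attach semantic vectors."""
    config = config or CorpusConfig()
    config.validate()

    forms: list[tuple[str, tuple[Segment, ...]]] = []
    for v in config.vowels:
        forms.append(("V", (SEGMENT_INVENTORY[v],)))
    for c in config.consonants:
        for v in config.vowels:
            forms.append(("CV", (SEGMENT_INVENTORY[c], SEGMENT_INVENTORY[v])))
    for cl in config.clusters:
        for v in config.vowels:
            segs = tuple(SEGMENT_INVENTORY[s] for s in cl) + (SEGMENT_INVENTORY[v],)
            forms.append(("CCV", segs))

    semantics = _semantic_vectors(config, len(forms))
    return [
        Word(word_id=i, syllable_structure=st, segments=segs, semantic_vector=semantics[i])
        for i, (st, segs) in enumerate(forms)
    ]


# ---------------------------------------------------------------------------
# articulation: motor plans and trajectories

# neutral articulator-distance posture (schwa-like half-open vocal tract)
NEUTRAL = {"lip": 0.55, "tongue_tip": 0.6, "tongue_dorsum": 0.6, "jaw": 0.5}

# vowel articulatory targets: normalized distances (0 = contact/high position)
VOWEL_ARTICULATION = {
    "i": {"lip": 0.45, "tongue_tip": 0.50, "tongue_dorsum": 0.30, "jaw": 0.30},
    "e": {"lip": 0.55, "tongue_tip": 0.60, "tongue_dorsum": 0.45, "jaw": 0.45},
    "a": {"lip": 0.90, "tongue_tip": 0.80, "tongue_dorsum": 0.85, "jaw": 0.85},
    "o": {"lip": 0.35, "tongue_tip": 0.75, "tongue_dorsum": 0.40, "jaw": 0.55},
    "u": {"lip": 0.25, "tongue_tip": 0.70, "tongue_dorsum": 0.25, "jaw": 0.40},
}

PLACE_TIER = {"labial": "lip", "alveolar": "tongue_tip", "velar": "tongue_dorsum"}

LEAD_IN_MS = 50.0
TAIL_MS = 40.0
GESTURE_GAP_MS = 30.0
VOWEL_MS = {"V": 250.0, "CV": 180.0, "CCV": 180.0}

# closure durations; voiceless plosive closures are longer than voiced ones
# (the standard closure-duration/VOT asymmetry), which is the only laryngeal
# trace visible to the 4 somatosensory tiers
def _closure_ms(seg: Segment) -> float:
    if seg.manner == "plosive":
        return 55.0 if seg.voiced else 95.0
    if seg.manner == "nasal":
        return 100.0   # nasal murmur: long quasi-steady closure
    return 60.0  # lateral


# manner-dependent consonant posture: plosives need a tight seal (high jaw),
# nasals a moderate one, and the lateral channel keeps the jaw low; the
# lateral also holds a mid tongue-dorsum position (lowered tongue sides)
CONSONANT_JAW = {"plosive": 0.15, "nasal": 0.35, "lateral": 0.45}
LATERAL_DORSUM = 0.5


def synthesize_motor_plan(
    word: Word,
    realization_rng: np.random.Generator,
    timing_jitter: float = 0.10,
    target_jitter: float = 0.05,
) -> MotorPlan:
    """Emit tier target/timing actions for one jittered realization of a word.

    Consonants contribute a contact action (target 0) on their place-matched
    tier plus jaw support; the vowel contributes targets on all four tiers.
    Timing jitter scales each segment duration; target jitter perturbs
    non-contact targets (contact targets stay exactly 0).
    """
    rng = realization_rng
    actions: list[tuple[str, float, float, float]] = []
    segment_times: list[tuple[str, float, float]] = []

    def jit_dur(base: float) -> float:
        return base * (1.0 + timing_jitter * rng.uniform(-1.0, 1.0))

    def jit_target(base: float) -> float:
        return float(np.clip(base + rng.uniform(-target_jitter, target_jitter), 0.0, 1.0))

    t = LEAD_IN_MS
    for seg in word.onset:
        dur = jit_dur(_closure_ms(seg))
        tier = PLACE_TIER[seg.place]
        actions.append((tier, 0.0, t, t + dur))  # contact: target exactly 0
        actions.append(("jaw", jit_target(CONSONANT_JAW[seg.manner]), t, t + dur))
        if seg.manner == "lateral" and tier != "tongue_dorsum":
            actions.append(("tongue_dorsum", jit_target(LATERAL_DORSUM), t, t + dur))
        segment_times.append((seg.symbol, t, t + dur))
        t += dur + GESTURE_GAP_MS

    vowel = word.vowel
    vdur = jit_dur(VOWEL_MS[word.syllable_structure])
    targets = VOWEL_ARTICULATION[vowel.symbol]
    for tier in TIERS:
        actions.append((tier, jit_target(targets[tier]), t, t + vdur))
    segment_times.append((vowel.symbol, t, t + vdur))
    t += vdur

    return MotorPlan(actions=actions, total_duration=t + TAIL_MS, segment_times=segment_times)


RAMP_MS = 50.0
RELEASE_MS = 80.0


def render_trajectories(plan: MotorPlan, hop_ms: float = FRAME_HOP_MS) -> TrajectorySet:
    """Sample per-tier trajectories with cosine-ramp transitions between targets."""
    n = int(round(plan.total_duration / hop_ms))
    times = np.arange(n) * hop_ms
    tiers: dict[str, np.ndarray] = {}

    for tier in TIERS:
        acts = sorted(
            [a for a in plan.actions if a[0] == tier], key=lambda a: a[2]
        )
        for prev, nxt in zip(acts, acts[1:]):
            if nxt[2] < prev[3] - 1e-9:
                if abs(nxt[1] - prev[1]) > 1e-12:
                    raise ValueError(
                        f"overlapping contradictory actions on tier {tier!r}"
                    )
        knots_t = [0.0]
        knots_v = [NEUTRAL[tier]]
        for _, target, on, off in acts:
            ramp_start = max(on - RAMP_MS, knots_t[-1])
            if ramp_start > knots_t[-1] + 1e-9:
                knots_t.append(ramp_start)
                knots_v.append(knots_v[-1])
            knots_t.append(max(on, knots_t[-1] + 1e-6))
            knots_v.append(target)
            knots_t.append(max(off, knots_t[-1] + 1e-6))
            knots_v.append(target)
        back = min(knots_t[-1] + RELEASE_MS, plan.total_duration)
        if back > knots_t[-1] + 1e-9:
            knots_t.append(back)
            knots_v.append(NEUTRAL[tier])
        kt = np.asarray(knots_t)
        kv = np.asarray(knots_v)
        idx = np.searchsorted(kt, times, side="right") - 1
        idx = np.clip(idx, 0, len(kt) - 2)
        span = kt[idx + 1] - kt[idx]
        u = np.where(span > 0, (times - kt[idx]) / np.maximum(span, 1e-9), 0.0)
        u = np.clip(u, 0.0, 1.0)
        ease = 0.5 * (1.0 - np.cos(np.pi * u))
        vals = kv[idx] + (kv[idx + 1] - kv[idx]) * ease
        vals = np.where(times >= kt[-1], kv[-1], vals)
        tiers[tier] = np.clip(vals, 0.0, 1.0)

    return TrajectorySet(tiers=tiers, hop_ms=hop_ms)


def somatosensory_rep(trajectories: TrajectorySet) -> SomatoRep:
    """Tactile/proprioceptive code: activation = 1 - normalized distance."""
    dist = trajectories.as_array()
    if dist.min() < -1e-9 or dist.max() > 1.0 + 1e-9:
        raise ValueError("trajectory distances must lie in [0, 1]")
    return SomatoRep(activation=1.0 - np.clip(dist, 0.0, 1.0), frame_hop=trajectories.hop_ms)


# ---------------------------------------------------------------------------
# auditory synthesis (parametric bark-domain front end)


def hz_to_bark(f):
    """Zwicker critical-band rate (bark) for frequency in Hz."""
    f = np.asarray(f, dtype=np.float64)
    return 13.0 * np.arctan(0.00076 * f) + 3.5 * np.arctan((f / 7500.0) ** 2)


_BAND_CENTERS_BARK = np.arange(24) + 0.5

# vowel formant targets (Hz), standard reference values
VOWEL_FORMANTS = {
    "i": (280.0, 2250.0, 2890.0),
    "e": (400.0, 2100.0, 2700.0),
    "a": (700.0, 1220.0, 2600.0),
    "o": (450.0, 800.0, 2550.0),
    "u": (310.0, 700.0, 2350.0),
}

# consonant-place formant loci shaping the CV transition (Hz)
PLACE_LOCI = {
    "labial": (250.0, 900.0, 2400.0),
    "alveolar": (350.0, 1800.0, 2700.0),
    "velar": (300.0, 2300.0, 2400.0),  # velar pinch: F2 locus near F3
}

# burst spectra: (centroid Hz, width in bark, amplitude)
BURST_SPECTRA = {
    "labial": (800.0, 3.0, 0.55),      # diffuse-falling
    "alveolar": (3800.0, 2.0, 0.80),   # diffuse-rising, high centroid
    "velar": (1900.0, 1.3, 0.80),      # compact mid
}

NEUTRAL_LOCI = (500.0, 1500.0, 2500.0)
FORMANT_AMPS = (1.0, 0.8, 0.5)
FORMANT_BW_BARK = 0.7
TRANSITION_MS = 40.0
VOICE_BAR_AMP = 0.30
_LOW_BANDS = hz_to_bark(300.0)  # voice-bar region


def _formant_frame(freqs, amps=FORMANT_AMPS) -> np.ndarray:
    out = np.zeros(24)
    for f, a in zip(freqs, amps):
        zf = hz_to_bark(f)
        out += a * np.exp(-0.5 * ((_BAND_CENTERS_BARK - zf) / FORMANT_BW_BARK) ** 2)
    return out


def synthesize_auditory(
    word: Word, plan: MotorPlan, realization_rng: np.random.Generator,
    amplitude: float = 1.0,
) -> AuditoryRep:
    """Parametric bark-domain synthesis of the word from its motor-plan timing.

    Vowel intervals carry formant energy with place-dependent initial
    transitions; plosive closures are silent (voiced: low voice bar) and are
    released with a place-dependent burst; nasals carry a low murmur; the
    lateral is vowel-like with attenuated mid bands.
    """
    rng = realization_rng
    n = int(round(plan.total_duration / FRAME_HOP_MS))
    act = np.zeros((24, n))
    t_frames = (np.arange(n) + 0.5) * FRAME_HOP_MS

    seg_by_sym = {s.symbol: s for s in word.segments}
    prev_place: str | None = None

    def fjit(freqs):
        return tuple(f * (1.0 + 0.03 * rng.uniform(-1, 1)) for f in freqs)

    for k, (sym, on, off) in enumerate(plan.segment_times):
        seg = seg_by_sym[sym]
        in_seg = (t_frames >= on) & (t_frames < off)
        if seg.kind == "vowel":
            loci = PLACE_LOCI[prev_place] if prev_place else NEUTRAL_LOCI
            targets = fjit(VOWEL_FORMANTS[sym])
            for i in np.nonzero(in_seg)[0]:
                frac = min(1.0, (t_frames[i] - on) / TRANSITION_MS)
                freqs = [lo + (tg - lo) * frac for lo, tg in zip(loci, targets)]
                env = min(1.0, (t_frames[i] - on + 5.0) / 20.0)
                env *= min(1.0, (off - t_frames[i] + 5.0) / 20.0)
                act[:, i] += env * _formant_frame(freqs)
            act[np.ix_(_BAND_CENTERS_BARK < _LOW_BANDS, in_seg)] += VOICE_BAR_AMP
        elif seg.manner == "plosive":
            if seg.voiced:
                act[np.ix_(_BAND_CENTERS_BARK < _LOW_BANDS, in_seg)] += VOICE_BAR_AMP
            # release burst (+ aspiration for voiceless)
            burst_ms = 20.0 if seg.voiced else 45.0
            c, w, a = BURST_SPECTRA[seg.place]
            zf = hz_to_bark(c * (1.0 + 0.03 * rng.uniform(-1, 1)))
            profile = a * np.exp(-0.5 * ((_BAND_CENTERS_BARK - zf) / w) ** 2) + 0.06
            in_burst = (t_frames >= off) & (t_frames < off + burst_ms)
            act[:, in_burst] += profile[:, None]
            prev_place = seg.place
        elif seg.manner == "nasal":
            # low-dominant murmur with the nasal anti-resonance notch
            murmur = _formant_frame((250.0, 2500.0), amps=(0.65, 0.10))
            notch = (_BAND_CENTERS_BARK > hz_to_bark(600.0)) & (
                _BAND_CENTERS_BARK < hz_to_bark(2000.0)
            )
            murmur[notch] *= 0.3
            act[:, in_seg] += murmur[:, None]
            act[np.ix_(_BAND_CENTERS_BARK < _LOW_BANDS, in_seg)] += VOICE_BAR_AMP
            prev_place = seg.place
        else:  # lateral
            lat = _formant_frame(fjit((360.0, 1300.0, 2700.0)), amps=(0.75, 0.45, 0.35))
            mid = (_BAND_CENTERS_BARK > hz_to_bark(1500.0)) & (
                _BAND_CENTERS_BARK < hz_to_bark(2600.0)
            )
            lat[mid] *= 0.35
            act[:, in_seg] += lat[:, None]
            prev_place = seg.place

    # per-realization band-amplitude jitter
    act *= 1.0 + 0.05 * rng.standard_normal(act.shape)
    act = np.clip(act, 0.0, None) * amplitude
    peak = act.max()
    if peak > 0:
        act = act / peak * min(1.0, amplitude) if amplitude > 0 else act
        act = np.clip(act, 0.0, 1.0)
    return AuditoryRep(activation=act)


# ---------------------------------------------------------------------------
# optional waveform front end


def bark_filterbank(signal: np.ndarray, sample_rate: float) -> AuditoryRep:
    """24 critical-band energies per 10 ms frame from a mono waveform.

    Energies are summed per Zwicker band, log-compressed and normalized to
    [0, 1].  This path is only used for externally supplied audio; the
    synthetic corpus is generated directly in the bark domain.
    """
    signal = np.asarray(signal, dtype=np.float64).ravel()
    if signal.size == 0:
        raise ValueError("empty signal")
    if sample_rate < 16000:
        raise ValueError("sample_rate must be >= 16 kHz")
    hop = int(round(sample_rate * FRAME_HOP_MS / 1000.0))
    win = 2 * hop
    n_frames = signal.size // hop
    window = np.hanning(win)
    freqs = np.fft.rfftfreq(win, d=1.0 / sample_rate)
    band = np.clip(np.floor(hz_to_bark(freqs)).astype(int), 0, 23)
    energies = np.zeros((24, n_frames))
    padded = np.concatenate([signal, np.zeros(win)])
    for k in range(n_frames):
        frame = padded[k * hop : k * hop + win] * window
        power = np.abs(np.fft.rfft(frame)) ** 2
        energies[:, k] = np.bincount(band, weights=power, minlength=24)
    out = np.log1p(energies)
    peak = out.max()
    if peak > 0:
        out /= peak
    return AuditoryRep(activation=out)


# ---------------------------------------------------------------------------
# vectorization


def _time_normalize(block: np.ndarray, frames: int) -> np.ndarray:
    """Linear interpolation of a (rows x T) block to a fixed frame count."""
    rows, T = block.shape
    if T == 0:
        raise ValueError("empty representation")
    if T == 1:
        return np.repeat(block, frames, axis=1)
    src = np.arange(T, dtype=np.float64)
    dst = np.linspace(0.0, T - 1.0, frames)
    lo = np.clip(np.floor(dst).astype(int), 0, T - 2)
    w = dst - lo
    return block[:, lo] * (1.0 - w) + block[:, lo + 1] * w


def vectorize(
    item: StimulusItem,
    mode: str,
    frames: int = 30,
    block_scales: tuple[float, float] | None = None,
) -> TrainingVector:
    """Fixed-length map input for one item under a modality configuration.

    Each included modality is time-normalized to `frames` frames, flattened
    and concatenated.  `block_scales` (auditory, somato) are corpus-level
    factors equalizing the expected squared-norm contribution of the two
    blocks; pass the factors fitted by :meth:`Corpus.training_matrix` for
    corpus-consistent vectors (the default applies no scaling).
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    sa, ss = block_scales if block_scales is not None else (1.0, 1.0)
    parts = []
    masks = []
    if mode in ("auditory", "combined"):
        a = _time_normalize(item.auditory.activation, frames).ravel() * sa
        parts.append(a)
        masks.append(np.zeros(a.size, dtype=np.int8))
    if mode in ("somatosensory", "combined"):
        s = _time_normalize(item.somato.activation, frames).ravel() * ss
        parts.append(s)
        masks.append(np.ones(s.size, dtype=np.int8))
    return TrainingVector(
        values=np.concatenate(parts), modality_mask=np.concatenate(masks)
    )


# ---------------------------------------------------------------------------
# corpus


@dataclass
class Corpus:
    config: CorpusConfig
    lexicon: list[Word]
    items: list[StimulusItem]
    _cache: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, i) -> StimulusItem:
        return self.items[i]

    def __iter__(self):
        return iter(self.items)

    @property
    def word_of_item(self) -> np.ndarray:
        return np.array([it.word_id for it in self.items])

    def raw_blocks(self, frames: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Unscaled time-normalized (auditory, somato) block matrices."""
        frames = frames or self.config.frames
        key = ("raw", frames)
        if key not in self._cache:
            A = np.stack(
                [_time_normalize(it.auditory.activation, frames).ravel() for it in self.items]
            )
            S = np.stack(
                [_time_normalize(it.somato.activation, frames).ravel() for it in self.items]
            )
            self._cache[key] = (A, S)
        return self._cache[key]

    def block_scales(self, mode: str, frames: int | None = None) -> tuple[float, float]:
        """Per-modality factors for map inputs.

        Included blocks are first equalized so each contributes the same
        corpus-mean squared norm, then the whole vector is rescaled so the
        corpus total variance equals rep_variance * total_dim (uniform
        distance-to-growth-threshold ratio across modes)."""
        frames = frames or self.config.frames
        A, S = self.raw_blocks(frames)
        n_blocks = 2 if mode == "combined" else 1
        total = {"auditory": A.shape[1], "somatosensory": S.shape[1],
                 "combined": A.shape[1] + S.shape[1]}[mode]
        target = total / n_blocks
        sa = float(np.sqrt(target / max((A ** 2).sum(1).mean(), 1e-12)))
        ss = float(np.sqrt(target / max((S ** 2).sum(1).mean(), 1e-12)))

        def _var(M, s):
            Ms = M * s
            return float((Ms ** 2).sum(1).mean() - (Ms.mean(0) ** 2).sum())

        variance = 0.0
        if mode in ("auditory", "combined"):
            variance += _var(A, sa)
        if mode in ("somatosensory", "combined"):
            variance += _var(S, ss)
        g = float(np.sqrt(self.config.rep_variance * total / max(variance, 1e-12)))
        sa *= g
        ss *= g
        if mode == "auditory":
            ss = 0.0
        elif mode == "somatosensory":
            sa = 0.0
        return sa, ss

    def training_matrix(self, mode: str, frames: int | None = None) -> np.ndarray:
        """Items-by-dimension matrix of scaled training vectors for a mode."""
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        frames = frames or self.config.frames
        key = ("mat", mode, frames)
        if key not in self._cache:
            A, S = self.raw_blocks(frames)
            sa, ss = self.block_scales(mode, frames)
            if mode == "auditory":
                M = A * sa
            elif mode == "somatosensory":
                M = S * ss
            else:
                M = np.hstack([A * sa, S * ss])
            self._cache[key] = np.ascontiguousarray(M)
        return self._cache[key]

    def semantic_matrix(self, scaled: bool = True) -> np.ndarray:
        """Word-by-feature matrix; scaled so the corpus total variance equals
        rep_variance * n_features, the same convention as sensory vectors."""
        key = ("sem", scaled)
        if key not in self._cache:
            M = np.stack([w.semantic_vector for w in self.lexicon]).astype(np.float64)
            if scaled:
                var = (M ** 2).sum(1).mean() - (M.mean(0) ** 2).sum()
                target = self.config.rep_variance * M.shape[1]
                M = M * np.sqrt(target / max(var, 1e-12))
            self._cache[key] = M
        return self._cache[key]

    def query_matrix(self, mode: str, frames: int | None = None) -> np.ndarray:
        """Perception queries: auditory block plus (in combined mode) the
        corpus-mean somatosensory block, since an external speaker provides
        no somatosensory signal."""
        frames = frames or self.config.frames
        M = self.training_matrix(mode, frames)
        if mode != "combined":
            return M
        A, S = self.raw_blocks(frames)
        sa, ss = self.block_scales(mode, frames)
        mean_s = (S * ss).mean(axis=0)
        return np.hstack([A * sa, np.tile(mean_s, (len(self.items), 1))])


def build_corpus(config: CorpusConfig | None = None) -> Corpus:
    """Generate the full stimulus set: every word x every jittered realization."""
    config = config or CorpusConfig()
    lexicon = build_lexicon(config)
    items: list[StimulusItem] = []
    for word in lexicon:
        for r in range(config.realizations_per_word):
            rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, 0xAC0, word.word_id, r])
            )
            plan = synthesize_motor_plan(
                word, rng,
                timing_jitter=config.timing_jitter,
                target_jitter=config.target_jitter,
            )
            traj = render_trajectories(plan)
            som = somatosensory_rep(traj)
            aud = synthesize_auditory(word, plan, rng, amplitude=config.amplitude)
            items.append(
                StimulusItem(
                    word_id=word.word_id,
                    realization_index=r,
                    motor_plan=plan,
                    trajectories=traj,
                    auditory=aud,
                    somato=som,
                )
            )
    return Corpus(config=config, lexicon=lexicon, items=items)
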