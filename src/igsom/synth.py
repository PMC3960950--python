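"""Synthetic acoustic-semantic pair corpora.

The generator emulates the statistical structure of the study data set
without its (unavailable) recordings and hand-built feature list: syllable
templates are 24-band x T activation matrices with formant-like Gaussian
bands, vowel-dependent band heights, consonant-class onset patterns, a
linear formant transition and duration-contrastive V < CV < CCV active
spans; realizations add Gaussian noise and a +-1-frame time jitter; words
carry binary feature vectors with category-shared blocks, word-specific
bits and sparse cross-category bits, then pass through the singleton-
pruning rule; syllables are paired bijectively with words, all realizations
of a syllable sharing the pair.  Everything is reproducible from the
config seed.

An optional waveform mode synthesizes crude band-limited audio (sums of
sinusoids at the formant-analog band centres plus onset noise) so the
preprocessing pipeline can be exercised end to end; it makes no claim to
articulatory realism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preproc import BARK_EDGES_HZ, SpeechRecord
from .training import TrainingToken

_VOWELS = "ieaou"
_CONSONANTS = "bpdtgkmnl"
_CONSONANT_CLASS = {
    "b": "plosive", "p": "plosive", "d": "plosive",
    "t": "plosive", "g": "plosive", "k": "plosive",
    "m": "nasal", "n": "nasal", "l": "lateral",
}
#: (F1-analog band row, F2-analog band row), low rows = low frequencies
_VOWEL_ROWS = {"i": (2, 18), "e": (4, 16), "a": (7, 11), "o": (5, 7), "u": (3, 5)}
_CLASS_ROWS = {"plosive": (6, 12, 17), "nasal": (1, 9), "lateral": (3, 14)}
#: place-of-articulation analog: shifts the class bands so consonants within a
#: class stay distinguishable (burst/murmur spectra vary with place), plus a
#: voicing-bar row for voiced plosives.
_CONSONANT_SHIFT = {"b": 0, "p": 0, "d": 2, "t": 2, "g": 4, "k": 4, "m": 0, "n": 3, "l": 0}
_VOICED = set("bdgmnl")
#: active-duration fraction of the template width per syllable type
_DURATION_FRACTION = {"V": 0.45, "CV": 0.62, "CCV": 0.80}


@dataclass
class SyntheticConfig:
    """Corpus shape and noise settings; defaults match the study data set
    (70 syllables x 3 realizations paired with 70 words in 9 categories,
    24 x 57 activations)."""

    n_vowels: int = 5
    n_consonants: int = 9
    n_syllables: int = 70
    n_realizations: int = 3
    n_words: int = 70
    n_semantic_categories: int = 9
    features_per_category: int = 20
    features_per_word: int = 4
    cross_feature_rate: float = 0.05
    noise_sd: float = 0.02
    time_jitter: int = 1
    time_frames: int = 57
    prune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words != self.n_syllables:
            raise ValueError("n_words must equal n_syllables (bijective pairing)")
        if not 1 <= self.n_vowels <= len(_VOWELS):
            raise ValueError(f"n_vowels must lie in 1..{len(_VOWELS)}")
        if not 1 <= self.n_consonants <= len(_CONSONANTS):
            raise ValueError(f"n_consonants must lie in 1..{len(_CONSONANTS)}")
        if self.time_frames < 8:
            raise ValueError("time_frames too small to host formant transitions (< 8)")
        if self.n_semantic_categories < 1 or self.n_semantic_categories > self.n_words:
            raise ValueError("n_semantic_categories must lie in 1..n_words")
        if self.features_per_category < 1 or self.features_per_word < 1:
            raise ValueError("feature block sizes must be positive")
        if self.noise_sd < 0 or self.time_jitter < 0:
            raise ValueError("noise_sd and time_jitter must be non-negative")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be positive")


@dataclass
class SyntheticCorpus:
    tokens: list[TrainingToken]
    pairing: dict[str, str]  # syllable_id -> word_id
    category_of: dict[str, str]  # word_id -> category label
    templates: dict[str, np.ndarray]  # noise-free 24 x T activations
    semantic_matrix: np.ndarray  # words x kept features, 0/1
    word_ids: list[str]

    @property
    def audio_dimension(self) -> int:
        return next(iter(self.templates.values())).size

    @property
    def semantic_dimension(self) -> int:
        return self.semantic_matrix.shape[1]


# -- syllable inventory and templates --------------------------------------


def syllable_inventory(config: SyntheticConfig) -> list[str]:
    """The first ``n_syllables`` syllables, mixing V, CV and CCV types in
    roughly the study's 5:45:20 proportion."""
    vowels = _VOWELS[: config.n_vowels]
    consonants = _CONSONANTS[: config.n_consonants]
    v_pool = list(vowels)
    cv_pool = [c + v for c in consonants for v in vowels]
    plosives = [c for c in consonants if _CONSONANT_CLASS[c] == "plosive"]
    sonorants = [c for c in consonants if _CONSONANT_CLASS[c] != "plosive"] or plosives
    ccv_pool = [c1 + c2 + v for c1 in plosives for c2 in sonorants for v in vowels]
    if not ccv_pool:
        ccv_pool = [c1 + c2 + v for c1 in consonants for c2 in consonants for v in vowels]
    n = config.n_syllables
    n_v = min(len(v_pool), max(1, round(n * 5 / 70)))
    n_cv = min(len(cv_pool), max(1, round(n * 45 / 70)))
    n_ccv = n - n_v - n_cv
    if n_ccv > len(ccv_pool) or n_ccv < 0:
        raise ValueError(f"cannot build {n} syllables from the configured phoneme inventory")
    return v_pool[:n_v] + cv_pool[:n_cv] + ccv_pool[:n_ccv]


def _syllable_type(syllable: str) -> str:
    return {1: "V", 2: "CV", 3: "CCV"}[len(syllable)]


def _add_band(column: np.ndarray, center: float, amplitude: float) -> None:
    rows = np.arange(24)
    column += amplitude * np.exp(-((rows - center) ** 2) / 2.0)


def gen_syllable_templates(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Noise-free 24 x time_frames activation templates, one per syllable."""
    t_total = config.time_frames
    templates: dict[str, np.ndarray] = {}
    for syllable in syllable_inventory(config):
        kind = _syllable_type(syllable)
        duration = max(6, round(t_total * _DURATION_FRACTION[kind]))
        mat = np.zeros((24, t_total))
        vowel = syllable[-1]
        v_rows = _VOWEL_ROWS[vowel]
        onsets: list[tuple[float, ...]] = []
        for c in syllable[:-1]:
            rows = [min(22.0, r + _CONSONANT_SHIFT[c]) for r in _CLASS_ROWS[_CONSONANT_CLASS[c]]]
            if c in _VOICED:
                rows.append(0.0)  # voicing-bar analog
            onsets.append(tuple(rows))
        seg = max(2, duration // (2 + 2 * len(onsets)))
        transition = 3
        t = 0
        for rows in onsets:
            for _ in range(seg):
                for r in rows:
                    _add_band(mat[:, t], r, 0.7)
                t += 1
        if onsets:
            start_rows = onsets[-1][:2]
            for k in range(transition):
                frac = (k + 1) / (transition + 1)
                for r0, r1 in zip(start_rows, v_rows):
                    _add_band(mat[:, t], r0 + frac * (r1 - r0), 0.85)
                t += 1
        while t < duration:
            for r in v_rows:
                _add_band(mat[:, t], r, 1.0)
            t += 1
        templates[syllable] = np.clip(mat, 0.0, 1.0)
    return templates


def gen_audio_tokens(
    templates: dict[str, np.ndarray], config: SyntheticConfig, rng: np.random.Generator
) -> dict[tuple[str, int], np.ndarray]:
    """Noisy, time-jittered realizations of each template, clipped to [0, 1].

    Keys are (syllable_id, realization_index); values are 24 x T matrices.
    """
    out: dict[tuple[str, int], np.ndarray] = {}
    for syllable in templates:
        template = templates[syllable]
        for k in range(config.n_realizations):
            mat = template
            if config.time_jitter > 0:
                shift = int(rng.integers(-config.time_jitter, config.time_jitter + 1))
                if shift:
                    mat = np.roll(mat, shift, axis=1)
                    if shift > 0:
                        mat[:, :shift] = 0.0
                    else:
                        mat[:, shift:] = 0.0
            if config.noise_sd > 0:
                mat = mat + rng.normal(0.0, config.noise_sd, mat.shape)
            out[(syllable, k)] = np.clip(mat, 0.0, 1.0)
    return out


# -- semantic vectors ------------------------------------------------------


def gen_semantic_vectors(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[str], dict[str, str]]:
    """Binary word x feature matrix with hierarchical category structure.

    Each word activates its category's shared feature block, its own
    word-specific bits (which guarantee pairwise-distinct vectors), and a
    sparse sample of other categories' shared features.
    Returns (matrix, word ids, word -> category label).
    """
    n_cat = config.n_semantic_categories
    n_shared = n_cat * config.features_per_category
    n_features = n_shared + config.n_words * config.features_per_word
    matrix = np.zeros((config.n_words, n_features), dtype=int)
    word_ids: list[str] = []
    category_of: dict[str, str] = {}
    for w in range(config.n_words):
        cat = w % n_cat
        word = f"word{w:03d}"
        word_ids.append(word)
        category_of[word] = f"cat{cat}"
        lo = cat * config.features_per_category
        matrix[w, lo: lo + config.features_per_category] = 1
        lo = n_shared + w * config.features_per_word
        matrix[w, lo: lo + config.features_per_word] = 1
        if config.cross_feature_rate > 0:
            cross = rng.random(n_shared) < config.cross_feature_rate
            matrix[w, :n_shared] |= cross.astype(int)
    return matrix, word_ids, category_of


def prune_features(matrix: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Drop singleton features unless the drop would merge two word vectors.

    Features (columns) are visited in order; a feature occurring in exactly
    one word on the input matrix is removed unless removing it would leave
    two rows identical over the currently kept columns.  Returns the pruned
    matrix and the kept column indices.
    """
    matrix = np.asarray(matrix)
    if matrix.size == 0:
        raise ValueError("feature matrix must be non-empty")
    if len({row.tobytes() for row in matrix}) < matrix.shape[0]:
        raise ValueError("input matrix has duplicate word vectors")
    singleton = matrix.sum(axis=0) == 1
    kept = list(range(matrix.shape[1]))
    for j in range(matrix.shape[1]):
        if not singleton[j]:
            continue
        trial = [c for c in kept if c != j]
        rows = {row.tobytes() for row in matrix[:, trial]}
        if len(rows) == matrix.shape[0]:
            kept = trial
    return matrix[:, kept], kept


# -- assembly --------------------------------------------------------------


def build_pairs(
    audio: dict[tuple[str, int], np.ndarray],
    semantic_matrix: np.ndarray,
    word_ids: list[str],
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[list[TrainingToken], dict[str, str]]:
    """Seeded random bijection syllable -> word; every realization of a
    syllable shares the pair.  Tokens come out syllable-major,
    realization-minor."""
    syllables = sorted({s for s, _ in audio})
    if len(syllables) != len(word_ids):
        raise ValueError("syllable and word counts must match")
    order = rng.permutation(len(word_ids))
    pairing = {s: word_ids[order[i]] for i, s in enumerate(syllables)}
    word_row = {w: i for i, w in enumerate(word_ids)}
    tokens = [
        TrainingToken(
            audio_vector=audio[(s, k)].ravel(),
            semantic_vector=semantic_matrix[word_row[pairing[s]]].astype(float),
            syllable_id=s,
            word_id=pairing[s],
            realization_index=k,
        )
        for s in syllables
        for k in range(config.n_realizations)
    ]
    return tokens, pairing


def generate_corpus(config: SyntheticConfig) -> SyntheticCorpus:
    """Full corpus generation, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    templates = gen_syllable_templates(config)
    audio = gen_audio_tokens(templates, config, rng)
    matrix, word_ids, category_of = gen_semantic_vectors(config, rng)
    if config.prune:
        matrix, _ = prune_features(matrix)
    tokens, pairing = build_pairs(audio, matrix, word_ids, config, rng)
    return SyntheticCorpus(
        tokens=tokens,
        pairing=pairing,
        category_of=category_of,
        templates=templates,
        semantic_matrix=matrix,
        word_ids=word_ids,
    )


# -- waveform mode ---------------------------------------------------------

_BAND_CENTERS_HZ = [
    (BARK_EDGES_HZ[b] + BARK_EDGES_HZ[b + 1]) / 2.0 for b in range(len(BARK_EDGES_HZ) - 1)
]


def gen_waveform_records(
    config: SyntheticConfig, sample_rate: float = 44100.0, vowel_duration: float = 0.12
) -> list[SpeechRecord]:
    """Crude waveform realizations of the syllable inventory.

    Vowels are sums of sinusoids at the formant-analog Bark-band centres;
    consonant onsets are noise bursts (plosive analog) or low-frequency
    murmurs (nasal/lateral analogs).  The release index marks the onset end.
    """
    rng = np.random.default_rng(config.seed + 1)
    records = []
    for syllable in syllable_inventory(config):
        v_rows = _VOWEL_ROWS[syllable[-1]]
        freqs = [_BAND_CENTERS_HZ[r] for r in v_rows]
        n_vowel = int(vowel_duration * sample_rate)
        t = np.arange(n_vowel) / sample_rate
        vowel_wave = sum(np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) for f in freqs)
        vowel_wave *= np.hanning(n_vowel)
        for k in range(config.n_realizations):
            onset = np.empty(0)
            for c in syllable[:-1]:
                n_c = int(0.04 * sample_rate)
                if _CONSONANT_CLASS[c] == "plosive":
                    seg = rng.normal(0.0, 0.3, n_c) * np.hanning(n_c)
                else:
                    tc = np.arange(n_c) / sample_rate
                    f = _BAND_CENTERS_HZ[_CLASS_ROWS[_CONSONANT_CLASS[c]][0]]
                    seg = 0.6 * np.sin(2 * np.pi * f * tc) * np.hanning(n_c)
                onset = np.concatenate([onset, seg])
            noise = rng.normal(0.0, 0.01, len(onset) + n_vowel)
            samples = np.concatenate([onset, vowel_wave]) + noise
            records.append(
                SpeechRecord(
                    samples=samples,
                    sample_rate=sample_rate,
                    release_index=max(0, len(onset) - 1) if len(onset) else 0,
                    syllable_id=syllable,
                    realization_index=k,
                )
            )
    return records
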