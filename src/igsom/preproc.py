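"""Audio preprocessing: annotated syllable waveforms to 24-Bark neural activations.

The pipeline: first-order derivative (a 6 dB/oct high-pass suppressing F0),
release-aligned zero-padding to corpus-maximal pre/post durations, per-signal
amplitude normalization, short-time magnitude spectra (256-sample Hamming
frames every 45 samples, zero-padded to a 2048-point FFT), conversion to dB
re 2e-5 clipped into [60, 100], pooling into Zwicker's 24 critical bands and
time groups of 10 frames, and a final local [0, 1] normalization.  At
44.1 kHz the analysis window spans ~5.8 ms and the hop ~1 ms; the paper
corpus yields 24 x 57 activation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

FFT_SIZE = 2048
WINDOW_SIZE = 256
HOP = 45
TIME_POOL = 10
DB_REFERENCE = 2e-5
DB_FLOOR = 60.0
DB_CEIL = 100.0

#: Zwicker critical-band edges in Hz (24 bands, 0 .. 15.5 kHz).
BARK_EDGES_HZ: tuple[float, ...] = (
    0, 100, 200, 300, 400, 510, 630, 770, 920, 1080, 1270, 1480, 1720,
    2000, 2320, 2700, 3150, 3700, 4400, 5300, 6400, 7700, 9500, 12000, 15500,
)
N_BARK = len(BARK_EDGES_HZ) - 1


@dataclass
class SpeechRecord:
    """A mono waveform with its release-of-obstruction annotation."""

    samples: np.ndarray
    sample_rate: float
    release_index: int
    syllable_id: str = ""
    realization_index: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a mono (1-d) sequence")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not 0 <= self.release_index < len(self.samples):
            raise ValueError("release_index must fall inside the signal")


def derivative_filter(record: SpeechRecord) -> SpeechRecord:
    """First difference of the waveform: s[i] - s[i-1].

    Acts as a 6 dB/oct high-pass that attenuates the fundamental relative to
    the formant region.  The signal shortens by one sample and the release
    index shifts back by one (floored at 0).
    """
    if len(record.samples) < 2:
        raise ValueError("signal must have at least 2 samples")
    return replace(
        record,
        samples=np.diff(record.samples),
        release_index=max(0, record.release_index - 1),
    )


def align_and_pad(records: list[SpeechRecord]) -> list[SpeechRecord]:
    """Zero-pad all records to shared pre/post-release spans.

    Every output has length max(pre) + max(post) and the identical release
    index max(pre), so a given column of the later spectrogram carries the
    same articulatory landmark for every record.
    """
    if not records:
        raise ValueError("record list must be non-empty")
    pre = [r.release_index for r in records]
    post = [len(r.samples) - r.release_index for r in records]
    max_pre, max_post = max(pre), max(post)
    out = []
    for r, p, q in zip(records, pre, post):
        padded = np.pad(r.samples, (max_pre - p, max_post - q))
        out.append(replace(r, samples=padded, release_index=max_pre))
    return out


def spectrogram(record: SpeechRecord) -> np.ndarray:
    """Short-time magnitude spectrum matrix, frequency bins x frames.

    256-sample Hamming-windowed frames are taken every 45 samples and
    zero-padded to a 2048-point FFT; the DC bin and the 1024 positive
    frequency bins are kept.  Frame count: floor((len - 256)/45) + 1.
    """
    s = record.samples
    if len(s) < WINDOW_SIZE:
        raise ValueError(f"signal shorter than one window ({WINDOW_SIZE} samples)")
    n_frames = (len(s) - WINDOW_SIZE) // HOP + 1
    window = np.hamming(WINDOW_SIZE)
    starts = np.arange(n_frames) * HOP
    frames = s[starts[:, None] + np.arange(WINDOW_SIZE)] * window
    return np.abs(np.fft.rfft(frames, n=FFT_SIZE, axis=1)).T


def to_db(magnitudes: np.ndarray) -> np.ndarray:
    """20*log10(|amplitude| / 2e-5), clipped into [60, 100] dB.

    Zero amplitude maps to the lower clip.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    if (magnitudes < 0).any():
        raise ValueError("magnitudes must be non-negative")
    with np.errstate(divide="ignore"):
        db = 20.0 * np.log10(magnitudes / DB_REFERENCE)
    return np.clip(db, DB_FLOOR, DB_CEIL)


def bark_time_pool(db_matrix: np.ndarray, sample_rate: float) -> np.ndarray:
    """Pool a (frequency bins x frames) dB matrix into 24 Bark bands and
    time groups of 10 frames.

    Each band's value is the mean over the FFT bins whose frequency lies in
    [edge_b, edge_{b+1}); bins at or above 15.5 kHz are discarded.  The final
    partial time group is averaged over its actual size.
    """
    db_matrix = np.asarray(db_matrix, dtype=float)
    freqs = np.fft.rfftfreq(FFT_SIZE, d=1.0 / sample_rate)
    if len(freqs) != db_matrix.shape[0]:
        raise ValueError(
            f"expected {len(freqs)} frequency rows for a {FFT_SIZE}-point FFT "
            f"at {sample_rate} Hz, got {db_matrix.shape[0]}"
        )
    bands = np.empty((N_BARK, db_matrix.shape[1]))
    for b in range(N_BARK):
        mask = (freqs >= BARK_EDGES_HZ[b]) & (freqs < BARK_EDGES_HZ[b + 1])
        if not mask.any():  # cannot happen for 2048-pt FFT at 44.1 kHz
            raise AssertionError(f"empty Bark band {b} at sample rate {sample_rate}")
        bands[b] = db_matrix[mask].mean(axis=0)
    n_frames = bands.shape[1]
    n_groups = -(-n_frames // TIME_POOL)
    pooled = np.empty((N_BARK, n_groups))
    for g in range(n_groups):
        pooled[:, g] = bands[:, g * TIME_POOL: (g + 1) * TIME_POOL].mean(axis=1)
    return pooled


def normalize_local(matrix: np.ndarray) -> np.ndarray:
    """Affine rescale of one signal's values into [0, 1]; a constant input
    maps to all zeros (silence semantics)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size == 0:
        raise ValueError("matrix must be non-empty")
    lo, hi = matrix.min(), matrix.max()
    if hi == lo:
        return np.zeros_like(matrix)
    return (matrix - lo) / (hi - lo)


def preprocess_corpus(records: list[SpeechRecord]) -> list[np.ndarray]:
    """Run the full pipeline for a corpus; padding maxima are corpus-global.

    Returns one 24 x T unit-interval activation matrix per record, in input
    order; T is determined by the corpus' maximal padded duration.
    """
    filtered = [derivative_filter(r) for r in records]
    aligned = align_and_pad(filtered)
    out = []
    for rec in aligned:
        rec = replace(rec, samples=normalize_local(rec.samples))
        mags = spectrogram(rec)
        db = normalize_local(to_db(mags))
        neural = normalize_local(bark_time_pool(db, rec.sample_rate))
        out.append(neural)
    return out


def wav_to_neural_representation(
    record: SpeechRecord, alignment_context: list[SpeechRecord]
) -> np.ndarray:
    """Neural representation of one record, padded against its corpus context."""
    for i, r in enumerate(alignment_context):
        if r is record:
            return preprocess_corpus(alignment_context)[i]
    raise ValueError("record must be a member of its alignment context")
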