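"""Raw-signal to model-input conversion.

Beat tasks: resample to 125 Hz, split into 10-s windows, min-max normalize
each window, detect R peaks as high local maxima, window each beat over
[peak, peak + 1.2*median RR), and truncate/zero-pad to 187 samples.

Rhythm task: a linear-phase FIR filter bank turns the single-lead signal
into four band-limited channels, which are then cut into fixed-length
sliding windows (length 3000 at 300 Hz); the window step is chosen per
class (small step for the rare AF class, large step for non-AF) so that
segment counts come out roughly balanced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .synthetic import BeatDataset, SyntheticRecording

__all__ = [
    "SegmentDataset",
    "DEFAULT_LABEL_MAP",
    "DEFAULT_BANDS",
    "extract_beats",
    "map_labels",
    "fir_four_channel",
    "sliding_segments",
    "build_segment_dataset",
]

logger = logging.getLogger("ecgkit")

DEFAULT_BANDS = ((0.5, 5.0), (5.0, 15.0), (15.0, 40.0), (40.0, 100.0))
SEGMENT_LEN = 3000
STEP_AF = 50
STEP_NON_AF = 500


@dataclass
class SegmentDataset:
    """Fixed-length multichannel windows with a binary label per window."""

    segments: np.ndarray  # (m, window, 4)
    labels: np.ndarray
    source_id: np.ndarray  # recording identifier per segment

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=int)
        self.source_id = np.asarray(self.source_id)
        if self.segments.ndim != 3:
            raise ValueError("segments must be (m, window, channels)")
        if len(self.labels) != len(self.segments) or \
                len(self.source_id) != len(self.segments):
            raise ValueError("one label and one source id per segment required")

    def __len__(self):
        return len(self.segments)


# ---------------------------------------------------------------------------
# beat extraction
# ---------------------------------------------------------------------------

def _resample(x: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    if fs == target_fs:
        return x
    frac = Fraction(target_fs / fs).limit_denominator(1000)
    return sps.resample_poly(x, frac.numerator, frac.denominator)


def extract_beats(recording, fs: float | None = None, target_fs: float = 125.0,
                  beat_len: int = 187, window_s: float = 10.0,
                  peak_threshold: float = 0.9, refractory_s: float = 0.2,
                  rr_factor: float = 1.2):
    """Segment a raw signal into fixed-length beats.

    ``recording`` is a :class:`SyntheticRecording` or a plain 1-D array (then
    ``fs`` is required). Returns ``(BeatDataset, peak_indices)`` where the
    peaks are sample indices at ``target_fs``; the dataset is unlabeled.

    Windows with fewer than two detected peaks are skipped with a warning;
    an empty result is allowed.
    """
    if isinstance(recording, SyntheticRecording):
        x, fs = recording.samples, recording.fs
    else:
        x = np.asarray(recording, dtype=np.float64)
        if fs is None:
            raise ValueError("fs is required for a raw-array recording")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if x.size < 2 * fs:
        raise ValueError("recording must be at least 2 s long")
    x = _resample(x, fs, target_fs)
    win = int(round(window_s * target_fs))
    refractory = max(1, int(round(refractory_s * target_fs)))
    edge = refractory  # extra context so peaks at window borders are seen
    beats, all_peaks = [], []
    for start in range(0, x.size, win):
        lo, hi = max(0, start - edge), min(x.size, start + win + edge)
        seg = x[lo:hi]
        rng_amp = seg.max() - seg.min()
        if rng_amp < 1e-12:
            continue  # flat window: nothing to detect
        norm = (seg - seg.min()) / rng_amp
        pk, _ = sps.find_peaks(norm, height=peak_threshold, distance=refractory)
        # keep peaks belonging to this window's core range
        pk_global = pk + lo
        core = (pk_global >= start) & (pk_global < start + win)
        pk, pk_global = pk[core], pk_global[core]
        if pk.size < 2:
            logger.warning("window at %d: %d peak(s) detected, skipped",
                           start, pk.size)
            continue
        rr = int(round(np.median(np.diff(pk_global))))
        span = int(round(rr_factor * rr))
        for g, p_loc in zip(pk_global, pk):
            all_peaks.append(int(g))
            end = min(p_loc + span, norm.size)
            b = norm[p_loc:end]
            if b.size >= beat_len:
                b = b[:beat_len]
            else:
                b = np.concatenate([b, np.zeros(beat_len - b.size)])
            beats.append(b)
    beats = np.asarray(beats).reshape(len(beats), beat_len) if beats else \
        np.empty((0, beat_len))
    ds = BeatDataset(beats=np.clip(beats, 0.0, 1.0), labels=None)
    return ds, np.asarray(sorted(set(all_peaks)), dtype=int)


# ---------------------------------------------------------------------------
# annotation mapping (AAMI EC57 five-category grouping)
# ---------------------------------------------------------------------------

_AAMI_ROWS = {
    "N": ["Normal", "Left bundle branch block", "Right bundle branch block",
          "Atrial escape", "Nodal escape",
          # standard MIT-BIH annotation symbols
          "N", "L", "R", "e", "j", "."],
    "S": ["Atrial premature", "Aberrant atrial premature", "Nodal premature",
          "Supra-ventricular premature", "A", "a", "J", "S"],
    "V": ["Premature ventricular contraction", "Ventricular escape", "V", "E"],
    "F": ["Fusion of ventricular and normal", "F"],
    "Q": ["Paced", "Fusion of paced and normal", "Unclassifiable",
          "/", "f", "Q"],
}
CATEGORY_ORDER = ("N", "S", "V", "F", "Q")
DEFAULT_LABEL_MAP = {sym: cat for cat, syms in _AAMI_ROWS.items() for sym in syms}


def map_labels(annotations, label_map: dict | None = None) -> np.ndarray:
    """Map annotation symbols to class ids N=0, S=1, V=2, F=3, Q=4.

    Symbols missing from the map fall back to Q (unclassifiable) with a
    logged warning.
    """
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    idx = {c: i for i, c in enumerate(CATEGORY_ORDER)}
    out = []
    for sym in annotations:
        cat = label_map.get(sym)
        if cat is None:
            logger.warning("unknown annotation %r mapped to Q", sym)
            cat = "Q"
        if cat not in idx:
            raise ValueError(f"label map produced unknown category {cat!r}")
        out.append(idx[cat])
    return np.asarray(out, dtype=int)


# ---------------------------------------------------------------------------
# FIR filter bank and sliding segmentation (rhythm task)
# ---------------------------------------------------------------------------

def fir_four_channel(x, fs: float, bands=DEFAULT_BANDS,
                     numtaps: int = 101) -> np.ndarray:
    """Zero-phase FIR band-pass decomposition into four channels.

    Each channel is the input filtered over one (low, high) band with a
    Hamming-window FIR applied forward and backward; output length equals
    input length.
    """
    x = np.asarray(x, dtype=np.float64)
    if len(bands) != 4:
        raise ValueError("exactly 4 bands required")
    for low, high in bands:
        if not 0 < low < high < fs / 2:
            raise ValueError(f"invalid band ({low}, {high}) at fs={fs}")
    out = np.empty((x.size, 4))
    for k, (low, high) in enumerate(bands):
        taps = sps.firwin(numtaps, [low, high], pass_zero=False, fs=fs,
                          window="hamming")
        out[:, k] = sps.filtfilt(taps, [1.0], x)
    return out


def sliding_segments(multichannel, label: int, window: int = SEGMENT_LEN,
                     step: int = 50, source_id="") -> SegmentDataset:
    """Cut an (n, 4) array into windows at offsets 0, step, 2*step, ...

    Segment count is ``floor((n - window)/step) + 1``; every segment inherits
    the recording label. Recordings shorter than the window yield zero
    segments (dropped, logged).
    """
    x = np.asarray(multichannel, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("expected an (n, channels) matrix")
    if step < 1:
        raise ValueError("step must be >= 1")
    n = x.shape[0]
    if n < window:
        logger.warning("recording %r shorter than window (%d < %d): dropped",
                       source_id, n, window)
        segs = np.empty((0, window, x.shape[1]))
    else:
        count = (n - window) // step + 1
        segs = np.stack([x[i * step : i * step + window] for i in range(count)])
    m = len(segs)
    return SegmentDataset(
        segments=segs,
        labels=np.full(m, int(label), dtype=int),
        source_id=np.full(m, source_id, dtype=object),
    )


def build_segment_dataset(recordings, labels, fs: float = 300.0,
                          bands=DEFAULT_BANDS, window: int = SEGMENT_LEN,
                          step_af: int = STEP_AF,
                          step_non_af: int = STEP_NON_AF) -> SegmentDataset:
    """Filter-bank transform + per-class sliding segmentation of recordings.

    AF recordings use the small step (many overlapping windows), non-AF the
    large step, rebalancing the segment counts between the two classes.
    """
    parts = []
    for i, (rec, lab) in enumerate(zip(recordings, labels)):
        x = rec.samples if isinstance(rec, SyntheticRecording) else np.asarray(rec)
        mc = fir_four_channel(x, fs=fs, bands=bands)
        step = step_af if lab else step_non_af
        parts.append(sliding_segments(mc, lab, window=window, step=step,
                                      source_id=str(i)))
    if not parts:
        return SegmentDataset(np.empty((0, window, 4)), np.empty(0, dtype=int),
                              np.empty(0, dtype=object))
    return SegmentDataset(
        segments=np.concatenate([p.segments for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        source_id=np.concatenate([p.source_id for p in parts]),
    )
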