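"""Synthetic ECG generation with known ground truth.

Beats are modeled as a sum of five Gaussian bumps (P, Q, R, S, T), the
standard phantom-ECG construction: analytically checkable, and distinct
enough per class that downstream classifiers are testable without real
recordings. Class-distinguishing template perturbations are fixed constants:

* N — textbook morphology (P wave, narrow QRS, T wave);
* S — supraventricular ectopic: early P wave, shortened pre-R interval;
* V — ventricular ectopic: widened QRS, absent P, inverted-T tendency;
* F — fusion: midpoint blend of the N and V templates;
* Q — paced/unclassifiable: flattened, widened morphology.

Recordings are beat trains with configurable RR mean and jitter; rhythm
strips emulate atrial fibrillation (AF) by highly variable RR intervals
with suppressed P waves versus regular RR with P waves for non-AF.

Not goals: physiologically faithful simulation (no dynamical heart model),
noise beyond additive white Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "BeatTemplate",
    "SyntheticRecording",
    "BeatDataset",
    "CLASS_TEMPLATES",
    "BINARY_TEMPLATES",
    "FIVE_CLASS_NAMES",
    "make_beat",
    "make_beat_dataset",
    "make_recording",
    "make_rhythm_strip",
]

BEAT_LEN = 187  # model input convention
BEAT_FS = 125.0  # Hz, target beat sampling rate

FIVE_CLASS_NAMES = ("N", "S", "V", "F", "Q")


@dataclass(frozen=True)
class BeatTemplate:
    """Five-Gaussian beat morphology.

    Centers and widths are fractions of the beat length; the R amplitude must
    dominate so that R-peak detection is well posed.
    """

    wave_centers: tuple  # P, Q, R, S, T offsets, fractions of beat length
    wave_amplitudes: tuple
    wave_widths: tuple
    label: int = 0

    def __post_init__(self):
        if len(self.wave_centers) != 5 or len(self.wave_amplitudes) != 5 \
                or len(self.wave_widths) != 5:
            raise ValueError("templates need exactly 5 waves (P,Q,R,S,T)")
        if any(w <= 0 for w in self.wave_widths):
            raise ValueError("wave widths must be positive")
        if any(b <= a for a, b in zip(self.wave_centers, self.wave_centers[1:])):
            raise ValueError("wave centers must be strictly increasing")
        if abs(self.wave_amplitudes[2]) < max(abs(a) for a in self.wave_amplitudes):
            raise ValueError("R amplitude must dominate the template")


# fixed per-class constants; tuned for separability, not clinical realism
_N = BeatTemplate(
    wave_centers=(0.10, 0.30, 0.35, 0.40, 0.62),
    wave_amplitudes=(0.15, -0.10, 1.00, -0.22, 0.30),
    wave_widths=(0.035, 0.012, 0.014, 0.013, 0.055),
    label=0,
)
_S = replace(_N, wave_centers=(0.05, 0.22, 0.27, 0.32, 0.55), label=1)
_V = BeatTemplate(
    wave_centers=(0.10, 0.26, 0.35, 0.46, 0.66),
    wave_amplitudes=(0.00, -0.18, 1.00, -0.45, -0.25),
    wave_widths=(0.035, 0.040, 0.050, 0.045, 0.060),
    label=2,
)
_F = BeatTemplate(
    wave_centers=tuple((a + b) / 2 for a, b in zip(_N.wave_centers, _V.wave_centers)),
    wave_amplitudes=tuple((a + b) / 2 for a, b in
                          zip(_N.wave_amplitudes, _V.wave_amplitudes)),
    wave_widths=tuple((a + b) / 2 for a, b in zip(_N.wave_widths, _V.wave_widths)),
    label=3,
)
_Q = BeatTemplate(
    wave_centers=(0.12, 0.28, 0.38, 0.50, 0.70),
    wave_amplitudes=(0.05, -0.05, 0.45, -0.10, 0.10),
    wave_widths=(0.060, 0.050, 0.080, 0.060, 0.090),
    label=4,
)

CLASS_TEMPLATES = {"N": _N, "S": _S, "V": _V, "F": _F, "Q": _Q}

# binary (diagnostic) task: normal vs abnormal; the abnormal template carries
# a widened QRS and depressed T, loosely evoking infarction-related changes
BINARY_TEMPLATES = {
    "normal": replace(_N, label=0),
    "abnormal": BeatTemplate(
        wave_centers=(0.10, 0.28, 0.35, 0.44, 0.64),
        wave_amplitudes=(0.12, -0.15, 1.00, -0.40, -0.20),
        wave_widths=(0.035, 0.030, 0.040, 0.035, 0.070),
        label=1,
    ),
}


@dataclass
class SyntheticRecording:
    """A continuous signal plus ground-truth R-peak indices and labels."""

    samples: np.ndarray
    fs: float
    r_peak_indices: np.ndarray
    beat_labels: np.ndarray
    rr_intervals_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    af: bool | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.r_peak_indices = np.asarray(self.r_peak_indices, dtype=int)
        self.beat_labels = np.asarray(self.beat_labels, dtype=int)
        if np.any(np.diff(self.r_peak_indices) <= 0):
            raise ValueError("r_peak_indices must be strictly increasing")
        if self.r_peak_indices.size and self.r_peak_indices[-1] >= self.samples.size:
            raise ValueError("r_peak_indices must lie inside the signal")
        if self.beat_labels.size != self.r_peak_indices.size:
            raise ValueError("one label per peak required")


@dataclass
class BeatDataset:
    """Fixed-length normalized beats with integer labels.

    Rows are 187-sample vectors in [0, 1]; ``labels`` is None for beats that
    came out of peak detection rather than annotation.
    """

    beats: np.ndarray
    labels: np.ndarray | None = None
    task: str = "five_class"

    def __post_init__(self):
        self.beats = np.asarray(self.beats, dtype=np.float64)
        if self.beats.ndim != 2:
            raise ValueError("beats must be a 2-D matrix")
        if self.beats.size and (self.beats.min() < -1e-9 or self.beats.max() > 1 + 1e-9):
            raise ValueError("beat values must lie in [0, 1]")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.beats):
                raise ValueError("one label per beat required")
            n_cls = 5 if self.task == "five_class" else 2
            if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= n_cls):
                raise ValueError(f"labels outside the {self.task} class set")

    def __len__(self):
        return len(self.beats)


def _gauss_sum(t: np.ndarray, template: BeatTemplate, length: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=np.float64)
    for c, a, w in zip(template.wave_centers, template.wave_amplitudes,
                       template.wave_widths):
        out += a * np.exp(-0.5 * ((t - c * length) / (w * length)) ** 2)
    return out


def make_beat(template: BeatTemplate, length: int = BEAT_LEN,
              noise_sd: float = 0.0, seed: int = 0) -> np.ndarray:
    """One beat: the template's Gaussian sum plus white noise, min-max
    rescaled to [0, 1]. Deterministic given the seed."""
    if length < 32:
        raise ValueError(f"length must be >= 32, got {length}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(length, dtype=np.float64)
    y = _gauss_sum(t, template, length)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=length)
    lo, hi = y.min(), y.max()
    if hi - lo < 1e-12:  # degenerate flat beat
        return np.zeros(length)
    return (y - lo) / (hi - lo)


def make_beat_dataset(n_per_class: dict, task: str = "five_class",
                      noise_sd: float = 0.05, seed: int = 0) -> BeatDataset:
    """Labeled beat dataset with exact per-class counts.

    ``n_per_class`` keys are class names ('N','S','V','F','Q' or
    'normal'/'abnormal'); beats have 187 samples in [0, 1].
    """
    if task == "five_class":
        templates = CLASS_TEMPLATES
    elif task == "binary":
        templates = BINARY_TEMPLATES
    else:
        raise ValueError(f"unknown task {task!r}")
    unknown = set(n_per_class) - set(templates)
    if unknown:
        raise ValueError(f"unknown class names {sorted(unknown)} for task {task!r}")
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("class counts must be >= 0")
    rng = np.random.default_rng(seed)
    beats, labels = [], []
    for name in templates:  # fixed iteration order keeps output deterministic
        tpl = templates[name]
        for _ in range(n_per_class.get(name, 0)):
            # small per-beat morphology jitter so beats within a class differ
            jitter = rng.normal(1.0, 0.03, size=5)
            tpl_i = BeatTemplate(
                wave_centers=tpl.wave_centers,
                wave_amplitudes=tuple(a * j for a, j in
                                      zip(tpl.wave_amplitudes, jitter)),
                wave_widths=tpl.wave_widths,
                label=tpl.label,
            )
            beats.append(make_beat(tpl_i, BEAT_LEN, noise_sd,
                                   seed=int(rng.integers(2**31))))
            labels.append(tpl.label)
    n = len(beats)
    order = rng.permutation(n) if n else np.empty(0, dtype=int)
    beats = np.asarray(beats).reshape(n, BEAT_LEN)[order] if n else \
        np.empty((0, BEAT_LEN))
    labels = np.asarray(labels, dtype=int)[order] if n else np.empty(0, dtype=int)
    return BeatDataset(beats=beats, labels=labels, task=task)


def _render_train(rr_s: np.ndarray, fs: float, templates, rng,
                  noise_sd: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Lay beats along a time axis; returns (signal, r_peak_indices)."""
    n_beats = len(rr_s)
    lead_s = 0.5 * rr_s[0]
    peak_times = lead_s + np.concatenate([[0.0], np.cumsum(rr_s[1:])]) \
        if n_beats > 1 else np.array([lead_s])
    total_s = peak_times[-1] + rr_s[-1]
    n = int(np.ceil(total_s * fs))
    t = np.arange(n, dtype=np.float64)
    sig = np.zeros(n)
    peaks = np.rint(peak_times * fs).astype(int)
    for i, pk in enumerate(peaks):
        tpl = templates[i]
        span = rr_s[i] * fs  # beat occupies ~one RR interval
        # shift template so its R center lands on the peak index
        offset = pk - tpl.wave_centers[2] * span
        sig += _gauss_sum(t - offset, tpl, span)
    if noise_sd > 0:
        sig += rng.normal(0.0, noise_sd, size=n)
    return sig, peaks


def make_recording(n_beats: int, fs: float = BEAT_FS, rr_mean_s: float = 0.8,
                   rr_jitter_s: float = 0.0, seed: int = 0) -> SyntheticRecording:
    """Beat train with exactly ``n_beats`` R peaks.

    Successive peak spacing is ``rr_mean_s`` plus uniform jitter in
    ``[-rr_jitter_s, +rr_jitter_s]``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 <= rr_jitter_s < rr_mean_s:
        raise ValueError("need 0 <= rr_jitter_s < rr_mean_s")
    rng = np.random.default_rng(seed)
    rr = rr_mean_s + rng.uniform(-rr_jitter_s, rr_jitter_s, size=n_beats)
    if rr_jitter_s == 0:
        rr = np.full(n_beats, rr_mean_s)
    templates = [_N] * n_beats
    sig, peaks = _render_train(rr, fs, templates, rng)
    return SyntheticRecording(
        samples=sig, fs=fs, r_peak_indices=peaks,
        beat_labels=np.zeros(n_beats, dtype=int), rr_intervals_s=rr,
    )


_AF_TARGET_CV = 0.25  # coefficient of variation imposed on AF RR intervals
_NONAF_CV = 0.01


def make_rhythm_strip(duration_s: float, fs: float = 300.0, af: bool = False,
                      seed: int = 0) -> SyntheticRecording:
    """Rhythm strip of ``duration_s * fs`` samples.

    Non-AF: near-regular RR (coefficient of variation ~0.01) with P waves.
    AF: RR deviations rescaled to a coefficient of variation of 0.25 and
    P waves suppressed.
    """
    if not 9.0 <= duration_s <= 61.0:
        raise ValueError(f"duration_s must be in [9, 61], got {duration_s}")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    rr_mean = 0.8
    n_beats = int(np.ceil(duration_s / rr_mean)) + 4
    if af:
        rr = rng.uniform(0.45, 1.15, size=n_beats)
        # impose the target RR variability exactly; sample CV of a finite
        # draw fluctuates too much at strip length to leave to chance
        dev = rr - rr.mean()
        sd = dev.std()
        rr = rr_mean + dev * (_AF_TARGET_CV * rr_mean / sd)
        rr = np.clip(rr, 0.3, 1.6)
        tpl = replace(_N, wave_amplitudes=(0.0,) + _N.wave_amplitudes[1:])
    else:
        rr = rr_mean * (1.0 + rng.normal(0.0, _NONAF_CV, size=n_beats))
        tpl = _N
    sig, peaks = _render_train(rr, fs, [tpl] * n_beats, rng, noise_sd=0.02)
    n = int(round(duration_s * fs))
    if sig.size < n:  # extend with noise floor if the train came up short
        sig = np.concatenate([sig, rng.normal(0.0, 0.02, size=n - sig.size)])
    sig = sig[:n]
    peaks = peaks[peaks < n]
    # rr_intervals_s keeps the full generated RR list of the underlying beat
    # train, so its variability statistics are exact regardless of truncation
    return SyntheticRecording(
        samples=sig, fs=fs, r_peak_indices=peaks,
        beat_labels=np.full(len(peaks), int(af), dtype=int),
        rr_intervals_s=rr, af=bool(af),
    )
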