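"""Dataset readers/writers and run manifests.

Beat tables use the common pre-split CSV convention: 187 comma-separated
sample values followed by one integer label column, no header. Rhythm
strips round-trip through one-sample-per-row CSV. Segment caches go to
``.npz``. A :class:`RunManifest` (config snapshot, seed, dataset content
hashes, output paths) is written before every artifact-producing run so a
run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import BeatDataset, SyntheticRecording
from .preprocessing import SegmentDataset

__all__ = [
    "RunManifest",
    "read_beat_csv",
    "write_beat_csv",
    "read_signal_csv",
    "write_signal_csv",
    "write_segments",
    "read_segments",
    "read_wfdb_record",
]

logger = logging.getLogger("ecgkit")

N_BEAT_COLS = 188  # 187 sample values + 1 label


class FormatError(ValueError):
    pass


def write_beat_csv(dataset: BeatDataset, path, header: bool = False) -> None:
    if dataset.labels is None:
        raise ValueError("cannot write an unlabeled beat dataset")
    df = pd.DataFrame(dataset.beats)
    df[N_BEAT_COLS - 1] = dataset.labels
    cols = [f"s{i}" for i in range(N_BEAT_COLS - 1)] + ["label"] if header else None
    df.to_csv(path, index=False, header=cols if header else False,
              float_format="%.9g")


def read_beat_csv(path, task: str = "five_class", header: bool = False) -> BeatDataset:
    """Read a 188-column beat table; malformed rows are rejected with line
    numbers, out-of-range labels dropped with a warning."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"beat table not found: {path}")
    try:
        df = pd.read_csv(path, header=0 if header else None)
    except pd.errors.EmptyDataError:
        logger.warning("empty beat table: %s", path)
        return BeatDataset(beats=np.empty((0, N_BEAT_COLS - 1)),
                           labels=np.empty(0, dtype=int), task=task)
    if df.shape[1] != N_BEAT_COLS:
        raise FormatError(
            f"{path}: expected {N_BEAT_COLS} columns (187 samples + label), "
            f"got {df.shape[1]}")
    vals = df.to_numpy(dtype=np.float64)
    beats, labels = vals[:, :-1], vals[:, -1]
    bad_rows = np.flatnonzero(
        ~np.isfinite(vals).all(axis=1)
        | (beats.min(axis=1) < -1e-9) | (beats.max(axis=1) > 1 + 1e-9)
        | (labels != np.rint(labels))
    )
    n_cls = 5 if task == "five_class" else 2
    bad_label = np.flatnonzero((labels < 0) | (labels >= n_cls))
    bad = np.union1d(bad_rows, bad_label)
    if bad.size:
        for r in bad[:20]:
            logger.warning("%s: rejected row %d (line %d)", path, r,
                           r + (2 if header else 1))
        keep = np.setdiff1d(np.arange(len(beats)), bad)
        beats, labels = beats[keep], labels[keep]
    return BeatDataset(beats=beats, labels=labels.astype(int), task=task)


def write_signal_csv(recording: SyntheticRecording, path) -> None:
    """One sample per row; fs and ground truth stored in a sidecar JSON."""
    np.savetxt(path, recording.samples, fmt="%.9g")
    meta = {
        "fs": recording.fs,
        "r_peak_indices": recording.r_peak_indices.tolist(),
        "beat_labels": recording.beat_labels.tolist(),
        "af": recording.af,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_signal_csv(path, fs: float | None = None):
    """Read a one-sample-per-row signal CSV; returns (samples, fs).

    ``fs`` comes from the sidecar JSON when present, else must be given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"signal file not found: {path}")
    x = np.loadtxt(path, dtype=np.float64)
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        fs = json.loads(sidecar.read_text())["fs"]
    if fs is None:
        raise ValueError(f"{path}: sampling rate unknown; pass fs")
    return x, float(fs)


def write_segments(dataset: SegmentDataset, path) -> None:
    np.savez_compressed(path, segments=dataset.segments, labels=dataset.labels,
                        source_id=dataset.source_id.astype(str))


def read_segments(path) -> SegmentDataset:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"segment cache not found: {path}")
    with np.load(path, allow_pickle=False) as z:
        return SegmentDataset(segments=z["segments"], labels=z["labels"],
                              source_id=z["source_id"].astype(object))


def read_wfdb_record(path, lead: str = "MLII"):
    """Read a PhysioNet waveform-database record (optional feature).

    Returns ``(signal, fs, annotations)`` with the requested lead (channel 0
    fallback, logged) and annotation symbols/samples when the annotation
    file is present (else ``None`` with a warning). Requires the ``wfdb``
    package, which is an optional dependency.
    """
    path = Path(path)
    if not path.with_suffix(".hea").exists():
        raise FileNotFoundError(f"record header not found: {path}.hea")
    try:
        import wfdb
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading waveform-database records requires the optional 'wfdb' "
            "package (pip install ecgkit[wfdb])") from exc
    rec = wfdb.rdrecord(str(path))
    names = list(rec.sig_name)
    if lead in names:
        ch = names.index(lead)
    else:
        ch = 0
        logger.warning("lead %r not in %s; using channel 0 (%r)", lead, names,
                       names[0])
    signal = rec.p_signal[:, ch]
    ann = None
    try:
        a = wfdb.rdann(str(path), "atr")
        ann = {"symbols": list(a.symbol), "samples": a.sample.tolist()}
    except FileNotFoundError:
        logger.warning("no annotation file for %s: beats-only mode", path)
    return signal, float(rec.fs), ann


@dataclass
class RunManifest:
    """Reproducibility record written before a run starts."""

    config: dict
    seed: int
    version: str
    dataset_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    @staticmethod
    def hash_array(x: np.ndarray) -> str:
        return hashlib.sha256(np.ascontiguousarray(x).tobytes()).hexdigest()[:16]

    @staticmethod
    def hash_file(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
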