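"""Containers and file I/O for recordings, state labels, feature sets and reports.

A :class:`Recording` holds a multichannel time series (channels x samples)
with its sampling rate.  Recordings are stored in self-describing HDF5
containers (dataset ``data``, attributes ``fs`` and ``channel_ids``); plain
CSV (one column per channel) is accepted for toy inputs when the sampling
rate is supplied by the caller.  State labels (awake / anesthetized
intervals, in seconds) live in a human-editable JSON sidecar, and feature
sets round-trip through CSV with a JSON header sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AWAKE = "awake"
ANESTHETIZED = "anesthetized"
STATE_LABELS = (AWAKE, ANESTHETIZED)

FEATURE_SOURCES = ("ds", "fft")
SURROGATE_TAGS = ("none", "phase", "stagger", "global_stagger")


class FormatError(ValueError):
    """A container is missing required structure or metadata."""


class DataError(ValueError):
    """The numeric payload violates a basic invariant (e.g. NaN samples)."""


class InfeasibleError(ValueError):
    """A requested segmentation does not fit in the available interval."""


@dataclass
class Recording:
    """Multichannel time series with sampling metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal values; arbitrary voltage units.
    fs : float
        Sampling frequency in Hz.
    channel_ids : list of str, optional
        One identifier per channel; defaults to ``ch000 ...``.
    meta : dict
        Free-form provenance.
    """

    data: np.ndarray
    fs: float
    channel_ids: list[str] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise DataError(f"data must be 2-D (channels x samples), got ndim={self.data.ndim}")
        n, t = self.data.shape
        if n < 1 or t < 2:
            raise DataError(f"need >= 1 channel and >= 2 samples, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise DataError("recording contains non-finite samples")
        if not (self.fs > 0):
            raise FormatError(f"sampling frequency must be positive, got {self.fs}")
        if self.channel_ids is None:
            self.channel_ids = [f"ch{i:03d}" for i in range(n)]
        if len(self.channel_ids) != n:
            raise FormatError("channel_ids length does not match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        """Sample period in seconds (``1/fs``)."""
        return 1.0 / self.fs

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def segment(self, start_s: float, dur_s: float) -> np.ndarray:
        """Return the samples covering ``[start_s, start_s + dur_s)``.

        Sample ``k`` covers time ``k * dt`` (0-based, half-open intervals).
        """
        i0 = int(round(start_s * self.fs))
        n = int(round(dur_s * self.fs))
        if i0 < 0 or i0 + n > self.n_samples:
            raise InfeasibleError(
                f"segment [{start_s}, {start_s + dur_s}) s outside recording "
                f"of {self.duration_s} s"
            )
        return self.data[:, i0 : i0 + n]


@dataclass
class StateInterval:
    """A labeled behavioral-state interval, in seconds from recording start.

    ``trim_s`` is the safety margin removed at each end before any vector is
    drawn (guards against mislabeling near state transitions).
    """

    label: str
    start_s: float
    end_s: float
    trim_s: float = 30.0

    def __post_init__(self) -> None:
        if self.label not in STATE_LABELS:
            raise FormatError(f"label must be one of {STATE_LABELS}, got {self.label!r}")
        if self.trim_s < 0:
            raise FormatError("trim_s must be nonnegative")
        if not self.start_s + self.trim_s < self.end_s - self.trim_s:
            raise FormatError(
                f"interval [{self.start_s}, {self.end_s}) empty after trimming {self.trim_s} s"
            )

    @property
    def trimmed(self) -> tuple[float, float]:
        """(start, end) after removing the trim margin at both ends."""
        return (self.start_s + self.trim_s, self.end_s - self.trim_s)


def extract_segment_starts(
    interval: StateInterval, window_s: float, n: int
) -> np.ndarray:
    """``n`` equally spaced segment start times inside the trimmed interval.

    The first segment begins at the trimmed start and the last ends at the
    trimmed end; for large ``n`` or long windows adjacent segments overlap.
    """
    if n < 1:
        raise InfeasibleError("n must be >= 1")
    t0, t1 = interval.trimmed
    if t1 - t0 < window_s - 1e-12:
        raise InfeasibleError(
            f"trimmed interval [{t0}, {t1}) shorter than window {window_s} s"
        )
    if n == 1:
        return np.array([t0])
    return np.linspace(t0, t1 - window_s, n)


@dataclass
class FeatureSet:
    """Fixed-length feature vectors with per-vector state labels.

    ``source`` records whether vectors came from dynamical-stability binning
    (``ds``) or log-spectra (``fft``); ``surrogate`` which surrogate (if any)
    was applied to the raw segments before featurization.
    """

    vectors: np.ndarray
    labels: np.ndarray
    window_s: float
    source: str = "ds"
    surrogate: str = "none"
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.vectors.ndim != 2 or self.vectors.shape[0] == 0:
            raise DataError("vectors must be a nonempty 2-D array")
        if self.labels.shape[0] != self.vectors.shape[0]:
            raise DataError("one label per vector required")
        bad = set(self.labels) - set(STATE_LABELS)
        if bad:
            raise FormatError(f"unknown labels {bad}")
        if self.source not in FEATURE_SOURCES:
            raise FormatError(f"source must be one of {FEATURE_SOURCES}")
        if self.surrogate not in SURROGATE_TAGS:
            raise FormatError(f"surrogate must be one of {SURROGATE_TAGS}")

    @property
    def n_vectors(self) -> int:
        return self.vectors.shape[0]

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def subset(self, idx) -> "FeatureSet":
        idx = np.asarray(idx)
        return FeatureSet(
            self.vectors[idx],
            self.labels[idx],
            self.window_s,
            self.source,
            self.surrogate,
            self.seed,
            dict(self.meta),
        )


# ---------------------------------------------------------------------------
# recordings

def write_recording(rec: Recording, path: str | Path) -> None:
    """Write a recording to HDF5 (``.h5``/``.hdf5``) or CSV (``.csv``)."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as h:
            h.create_dataset("data", data=rec.data)
            h.attrs["fs"] = rec.fs
            h.attrs["channel_ids"] = [str(c) for c in rec.channel_ids]
            for k, v in rec.meta.items():
                try:
                    h.attrs[f"meta_{k}"] = v
                except TypeError:
                    h.attrs[f"meta_{k}"] = json.dumps(v)
    elif path.suffix.lower() == ".csv":
        import pandas as pd

        pd.DataFrame(rec.data.T, columns=rec.channel_ids).to_csv(
            path, index=False, float_format="%.17g"
        )
    else:
        raise FormatError(f"unsupported recording container {path.suffix!r}")


def read_recording(path: str | Path, fs: float | None = None) -> Recording:
    """Read a recording written by :func:`write_recording`.

    HDF5 containers are self-describing; CSV requires ``fs`` to be passed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as h:
            if "data" not in h:
                raise FormatError(f"{path}: missing 'data' dataset")
            data = np.asarray(h["data"], dtype=float)
            if "fs" not in h.attrs:
                raise FormatError(f"{path}: missing 'fs' attribute")
            file_fs = float(h.attrs["fs"])
            ids = h.attrs.get("channel_ids")
            channel_ids = [str(c) for c in ids] if ids is not None else None
            meta = {
                k[5:]: v for k, v in h.attrs.items() if k.startswith("meta_")
            }
        return Recording(data, file_fs, channel_ids, meta)
    if path.suffix.lower() == ".csv":
        import pandas as pd

        if fs is None:
            raise FormatError(f"{path}: CSV container carries no sampling rate; pass fs=")
        df = pd.read_csv(path, float_precision="round_trip")
        return Recording(df.to_numpy().T, fs, [str(c) for c in df.columns])
    raise FormatError(f"unsupported recording container {path.suffix!r}")


# ---------------------------------------------------------------------------
# state-interval labels (JSON sidecar)

def write_intervals(intervals: list[StateInterval], path: str | Path) -> None:
    payload = [
        {"label": iv.label, "start_s": iv.start_s, "end_s": iv.end_s, "trim_s": iv.trim_s}
        for iv in intervals
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_intervals(path: str | Path) -> list[StateInterval]:
    payload = json.loads(Path(path).read_text())
    return [
        StateInterval(d["label"], d["start_s"], d["end_s"], d.get("trim_s", 30.0))
        for d in payload
    ]


# ---------------------------------------------------------------------------
# feature sets (CSV + JSON header sidecar)

def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_feature_set(fset: FeatureSet, path: str | Path) -> None:
    """CSV with one row per vector, trailing label column; JSON sidecar."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(fset.vectors)
    df.columns = [f"x{i}" for i in range(fset.dim)]
    df["label"] = fset.labels
    df.to_csv(path, index=False, float_format="%.17g")
    header = {
        "window_s": fset.window_s,
        "source": fset.source,
        "surrogate": fset.surrogate,
        "seed": fset.seed,
        "dim": fset.dim,
        "meta": fset.meta,
    }
    _sidecar(path).write_text(json.dumps(header, indent=2))


def read_feature_set(path: str | Path) -> FeatureSet:
    import pandas as pd

    path = Path(path)
    sc = _sidecar(path)
    if not sc.exists():
        raise FormatError(f"missing feature-set sidecar {sc}")
    header = json.loads(sc.read_text())
    df = pd.read_csv(path, float_precision="round_trip")
    labels = df.pop("label").to_numpy()
    return FeatureSet(
        df.to_numpy(),
        labels,
        header["window_s"],
        header["source"],
        header["surrogate"],
        header.get("seed", 0),
        header.get("meta", {}),
    )
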