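"""EEG preprocessing: epoching, seizure labelling, time-domain features.

Recordings are segmented into 2-s epochs whose consecutive windows share
0.5 s (stride 1.5 s). An epoch is labelled seizure when at least half of
its time span lies inside an annotated seizure interval. From every channel
of every epoch thirteen time-domain features are extracted, in this order:

    mean, std, peak-to-peak, variance, min, max, argmin, argmax,
    mean-square, RMS, sum of absolute first differences, skewness,
    excess kurtosis.

Conventions: std/var use population normalization (divide by n); skewness
and kurtosis are the biased standardized third moment and excess kurtosis
m4/m2^2 - 3, with a zero-variance channel defined to have skew = kurt = 0;
argmin/argmax are 0-based sample indices, first occurrence on ties.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DimensionError, FormatError, ValidationError

FEATURE_NAMES = [
    "mean",
    "std",
    "p2p",
    "var",
    "min",
    "max",
    "argmin",
    "argmax",
    "mean_square",
    "rms",
    "sum_abs_diff",
    "skew",
    "kurt",
]
N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)

DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP_S = 0.5


@dataclass
class Recording:
    """A multichannel recording in microvolts with seizure annotations."""

    samples: np.ndarray  # (n_channels, n_samples)
    fs: float
    channel_names: list[str]
    annotations: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValidationError(f"sampling rate must be > 0, got {self.fs}")
        if len(self.channel_names) != self.samples.shape[0]:
            raise ValidationError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[0]} channels"
            )
        dur = self.duration_s
        for start, end in self.annotations:
            if not (0.0 <= start < end <= dur):
                raise ValidationError(
                    f"annotation ({start}, {end}) outside [0, {dur}] or start >= end"
                )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class EpochDataset:
    """Fixed-length windows cut from a recording, with optional labels."""

    epochs: np.ndarray  # (n_epochs, n_channels, n_samples)
    start_times: np.ndarray  # (n_epochs,) seconds
    fs: float
    window_s: float = DEFAULT_WINDOW_S
    overlap_s: float = DEFAULT_OVERLAP_S
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = int(round(self.window_s * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValidationError(
                f"epoch sample count {self.epochs.shape[2]} != "
                f"round(window_s * fs) = {expected}"
            )
        if self.labels is not None and len(self.labels) != len(self.epochs):
            raise ValidationError("labels length must equal epoch count")


@dataclass
class FeatureTable:
    """Per-epoch feature matrix with one column per channel/feature pair."""

    features: np.ndarray  # (n_epochs, 13 * n_channels)
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length must match column count")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError("labels length must equal row count")
        if not np.isfinite(self.features).all():
            raise ValidationError("feature table contains non-finite entries")

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.features, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise FormatError(f"{path}: feature CSV must contain a 'label' column")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), list(df.columns), labels)


# ---------------------------------------------------------------------------
# I/O


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    """Write samples as CSV (channels as columns) plus a JSON sidecar with fs."""
    path = Path(path)
    pd.DataFrame(rec.samples.T, columns=rec.channel_names).to_csv(path, index=False)
    sidecar = {"fs": rec.fs, "channel_names": rec.channel_names}
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_annotations(path: str | Path) -> list[tuple[float, float]]:
    """Read seizure intervals from a CSV with columns start_s, end_s."""
    df = pd.read_csv(path)
    for col in ("start_s", "end_s"):
        if col not in df.columns:
            raise FormatError(f"{path}: annotations CSV must have a {col!r} column")
    return [(float(a), float(b)) for a, b in zip(df["start_s"], df["end_s"])]


def write_annotations(intervals, path: str | Path) -> None:
    pd.DataFrame(intervals, columns=["start_s", "end_s"]).to_csv(path, index=False)


def read_recording(
    path: str | Path,
    format: str = "csv",
    fs: float | None = None,
    annotations: str | Path | list | None = None,
) -> Recording:
    """Read a multichannel recording from CSV or EDF.

    CSV requires a header row of channel names and the sampling rate either
    as the ``fs`` argument or in a ``<path>.json`` sidecar. EDF carries its
    own rate. ``annotations`` may be a list of (start_s, end_s) pairs or a
    path to an annotations CSV.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if isinstance(annotations, (str, Path)):
        ann = read_annotations(annotations)
    else:
        ann = list(annotations) if annotations else []

    if format == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"could not parse {path} as CSV: {exc}") from exc
        if df.empty or df.shape[1] == 0:
            raise FormatError(f"{path}: empty CSV")
        if df.isna().any().any():
            raise ValidationError(
                f"{path}: ragged channel lengths (missing values); all channels "
                "must have a consistent channel count and equal length"
            )
        if fs is None:
            sidecar = Path(str(path) + ".json")
            if not sidecar.exists():
                raise FormatError(
                    f"{path}: sampling rate required (fs argument or {sidecar})"
                )
            fs = float(json.loads(sidecar.read_text())["fs"])
        return Recording(df.to_numpy(dtype=float).T, fs, list(df.columns), ann)
    if format == "edf":
        from .edf import read_edf

        rec = read_edf(path)
        rec.annotations = ann
        # re-run invariant checks against the annotations
        return Recording(rec.samples, rec.fs, rec.channel_names, ann)
    raise FormatError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# Epoching and labelling


def segment_epochs(
    rec: Recording,
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
) -> EpochDataset:
    """Cut the recording into overlapping full windows.

    Windows start at 0 and advance by the stride window_s - overlap_s
    (1.5 s for the defaults); partial windows at the end are dropped.
    """
    if overlap_s >= window_s:
        raise ValidationError("overlap must be smaller than the window")
    n_win = int(round(window_s * rec.fs))
    stride = int(round((window_s - overlap_s) * rec.fs))
    total = rec.samples.shape[1]
    if total < n_win:
        raise ValidationError(
            f"recording of {rec.duration_s:.3f} s is shorter than the "
            f"{window_s} s window; no epochs can be formed"
        )
    starts = np.arange(0, total - n_win + 1, stride)
    epochs = np.stack([rec.samples[:, s : s + n_win] for s in starts])
    return EpochDataset(
        epochs=epochs,
        start_times=starts / rec.fs,
        fs=rec.fs,
        window_s=window_s,
        overlap_s=overlap_s,
        labels=None,
    )


def label_epochs(
    ds: EpochDataset,
    annotations: list[tuple[float, float]],
    min_overlap_fraction: float = 0.5,
) -> EpochDataset:
    """Label an epoch 1 iff >= ``min_overlap_fraction`` of it is inside a seizure."""
    window = ds.window_s
    labels = np.zeros(len(ds.epochs), dtype=int)
    for idx, t0 in enumerate(ds.start_times):
        t1 = t0 + window
        covered = sum(
            max(0.0, min(t1, end) - max(t0, start)) for start, end in annotations
        )
        if covered >= min_overlap_fraction * window:
            labels[idx] = 1
    return EpochDataset(ds.epochs, ds.start_times, ds.fs, ds.window_s, ds.overlap_s, labels)


# ---------------------------------------------------------------------------
# Feature extraction


def _channel_features(x: np.ndarray) -> np.ndarray:
    m = x.mean()
    d = x - m
    m2 = np.mean(d * d)
    if m2 > 0:
        skew = np.mean(d**3) / m2**1.5
        kurt = np.mean(d**4) / m2**2 - 3.0
    else:
        skew = 0.0
        kurt = 0.0
    mean_sq = np.mean(x * x)
    return np.array(
        [
            m,
            np.sqrt(m2),
            x.max() - x.min(),
            m2,
            x.min(),
            x.max(),
            float(np.argmin(x)),
            float(np.argmax(x)),
            mean_sq,
            np.sqrt(mean_sq),
            np.abs(np.diff(x)).sum(),
            skew,
            kurt,
        ]
    )


def extract_features(epoch: np.ndarray) -> np.ndarray:
    """Thirteen time-domain features per channel, concatenated channel-major."""
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[1] < 2:
        raise ValidationError("each channel needs at least 2 samples")
    if not np.isfinite(epoch).all():
        raise ValidationError("epoch contains non-finite samples")
    return np.concatenate([_channel_features(ch) for ch in epoch])


def feature_names_for(channel_names: list[str]) -> list[str]:
    return [f"{ch}_{feat}" for ch in channel_names for feat in FEATURE_NAMES]


def make_dataset(
    recordings: list[Recording],
    window_s: float = DEFAULT_WINDOW_S,
    overlap_s: float = DEFAULT_OVERLAP_S,
    min_overlap_fraction: float = 0.5,
) -> FeatureTable:
    """Segment, label and featurize a list of recordings into one table.

    Rows concatenate in input order. Standardization is deliberately NOT
    applied here: z-scoring statistics belong to the training folds of the
    downstream cross-validation (see :class:`~saegbls.classifier.Standardizer`)
    so no test-fold information leaks into them.
    """
    if not recordings:
        raise ValidationError("no recordings given")
    n_ch = recordings[0].n_channels
    names = recordings[0].channel_names
    blocks, labels = [], []
    for rec in recordings:
        if rec.n_channels != n_ch:
            raise ValidationError(
                "recordings must have a consistent channel count "
                f"(got {rec.n_channels}, expected {n_ch})"
            )
        ds = label_epochs(
            segment_epochs(rec, window_s, overlap_s),
            rec.annotations,
            min_overlap_fraction,
        )
        blocks.append(np.stack([extract_features(ep) for ep in ds.epochs]))
        labels.append(ds.labels)
    return FeatureTable(
        np.vstack(blocks), feature_names_for(names), np.concatenate(labels)
    )
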