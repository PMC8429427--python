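"""From parcel time series to denoised connectivity matrices.

Steps, in pipeline order:

1. **Motion scrubbing** — frames whose framewise displacement (FD) exceeds
   a threshold (default 0.5 mm) are censored together with the one frame
   before and the two frames after each spike.
2. **Retention QC** — subjects keeping less than 40% of their frames are
   discarded (exactly 40% passes).
3. **Correlation + Fisher z** — pairwise Pearson correlation over retained
   frames, then z = atanh(r) with |r| clipped just below 1 so degenerate
   inputs stay finite.
4. **Mean-regression (MR) denoising** — for every edge, an ordinary
   least-squares fit of the edge value on the subject-mean connectivity is
   estimated across *training* subjects only; the per-edge residual
   (observed minus fitted) replaces the edge everywhere.  This removes the
   global, motion-associated component of connectivity without refitting
   on held-out data: the model is frozen after `fit_mean_regression`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ParcelTimeSeries",
    "ConnectivityMatrix",
    "MeanRegressionModel",
    "scrub_frames",
    "qc_retention",
    "correlation_fisher",
    "subject_mean_connectivity",
    "fit_mean_regression",
    "apply_mean_regression",
    "load_timeseries",
]

FD_THRESHOLD_MM = 0.5
QC_MIN_FRACTION = 0.40
_R_CLIP = 1.0 - 1e-7


@dataclass
class ParcelTimeSeries:
    subject_id: str
    data: np.ndarray  # (frames, regions)
    region_labels: list[str]
    fd: np.ndarray  # (frames,) mm
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be frames x regions")
        if len(self.fd) != self.data.shape[0]:
            raise ValueError("FD trace length must equal number of frames")
        if len(set(self.region_labels)) != len(self.region_labels):
            raise ValueError("region labels must be unique")
        if len(self.region_labels) != self.data.shape[1]:
            raise ValueError("one region label per column required")


@dataclass
class ConnectivityMatrix:
    subject_id: str
    z: np.ndarray  # (regions, regions), symmetric, zero diagonal
    region_labels: list[str]
    n_frames_used: int
    mr_residualized: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if not np.allclose(self.z, self.z.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("connectivity matrix must be finite")


def scrub_frames(fd: np.ndarray, threshold_mm: float = FD_THRESHOLD_MM) -> np.ndarray:
    """Boolean retention mask: True = frame kept.

    A frame with FD > threshold is removed together with 1 frame before and
    2 frames after (clipped at the boundaries); removal windows from
    multiple spikes are unioned.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValueError("empty FD trace")
    if np.any(fd < 0):
        raise ValueError("FD must be non-negative")
    n = fd.size
    keep = np.ones(n, dtype=bool)
    for i in np.flatnonzero(fd > threshold_mm):
        keep[max(i - 1, 0) : min(i + 3, n)] = False
    return keep


def qc_retention(mask: np.ndarray, min_fraction: float = QC_MIN_FRACTION) -> bool:
    """True iff the retained fraction is at least ``min_fraction``.

    The discard rule is "less than 40% retained", so exactly 40% passes.
    """
    mask = np.asarray(mask, dtype=bool)
    return bool(mask.mean() >= min_fraction)


def correlation_fisher(ts: ParcelTimeSeries, mask: np.ndarray | None = None) -> ConnectivityMatrix:
    """Pearson correlation over retained frames, Fisher z-transformed.

    The diagonal is stored as 0 by convention; consumers ignore it.
    """
    if mask is None:
        mask = np.ones(ts.data.shape[0], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    sub = ts.data[mask]
    if sub.shape[0] < 10:
        raise ValueError(
            f"{ts.subject_id}: only {sub.shape[0]} retained frames (< 10)"
        )
    sd = sub.std(axis=0)
    if np.any(sd == 0):
        bad = [ts.region_labels[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"{ts.subject_id}: zero-variance region(s) {bad}")
    r = np.corrcoef(sub, rowvar=False)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(
        subject_id=ts.subject_id,
        z=z,
        region_labels=list(ts.region_labels),
        n_frames_used=int(sub.shape[0]),
    )


def _upper(z: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(z.shape[0], k=1)
    return z[iu]


def subject_mean_connectivity(cm: ConnectivityMatrix) -> float:
    """Mean of the strict upper triangle of the Fisher-z matrix."""
    if cm.mr_residualized:
        raise ValueError("subject mean is defined on the pre-MR matrix")
    return float(_upper(cm.z).mean())


@dataclass
class MeanRegressionModel:
    """Frozen per-edge linear model: edge ~ intercept + slope * subject_mean.

    Fit on training subjects only; ``apply_mean_regression`` never updates
    the coefficients.
    """

    region_labels: list[str]
    slope: np.ndarray  # (n_edges,) upper-triangle order
    intercept: np.ndarray  # (n_edges,)
    n_training_subjects: int

    def coefficient_checksum(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.slope).tobytes())
        h.update(np.ascontiguousarray(self.intercept).tobytes())
        return h.hexdigest()

    def to_frame(self) -> pd.DataFrame:
        n = len(self.region_labels)
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "edge_i": [self.region_labels[i] for i in iu[0]],
                "edge_j": [self.region_labels[j] for j in iu[1]],
                "slope": self.slope,
                "intercept": self.intercept,
            }
        )


def fit_mean_regression(training_cms: list[ConnectivityMatrix]) -> MeanRegressionModel:
    """Per-edge OLS of edge value on subject-mean connectivity.

    Residuals across the training subjects sum to zero for every edge (an
    ordinary-least-squares identity used as a self-check downstream).
    """
    if len(training_cms) < 3:
        raise ValueError("need at least 3 training subjects")
    labels = training_cms[0].region_labels
    for cm in training_cms:
        if cm.region_labels != labels:
            raise ValueError("all training matrices must share region labels")
        if cm.mr_residualized:
            raise ValueError("training matrices must be pre-MR")
    edges = np.stack([_upper(cm.z) for cm in training_cms])  # (S, E)
    means = np.array([subject_mean_connectivity(cm) for cm in training_cms])
    mc = means - means.mean()
    denom = float(mc @ mc)
    if denom == 0.0:
        raise ValueError("degenerate predictor: all subject means identical")
    slope = (mc @ (edges - edges.mean(axis=0))) / denom
    intercept = edges.mean(axis=0) - slope * means.mean()
    return MeanRegressionModel(
        region_labels=list(labels),
        slope=slope,
        intercept=intercept,
        n_training_subjects=len(training_cms),
    )


def apply_mean_regression(
    model: MeanRegressionModel, cm: ConnectivityMatrix
) -> ConnectivityMatrix:
    """Replace each edge with its residual from the frozen MR model."""
    if cm.mr_residualized:
        raise ValueError("matrix is already MR-residualized")
    if cm.region_labels != model.region_labels:
        raise ValueError("region labels do not match the MR model")
    m = subject_mean_connectivity(cm)
    resid = _upper(cm.z) - (model.intercept + model.slope * m)
    n = len(model.region_labels)
    z = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    z[iu] = resid
    z = z + z.T
    return ConnectivityMatrix(
        subject_id=cm.subject_id,
        z=z,
        region_labels=list(cm.region_labels),
        n_frames_used=cm.n_frames_used,
        mr_residualized=True,
    )


def load_timeseries(dataset_dir: str | Path, subject_id: str, tr_seconds: float = 2.0) -> ParcelTimeSeries:
    """Read ``<id>_timeseries.tsv`` + ``<id>_fd.tsv`` from a dataset directory."""
    d = Path(dataset_dir)
    ts = pd.read_csv(d / f"{subject_id}_timeseries.tsv", sep="\t")
    fd = pd.read_csv(d / f"{subject_id}_fd.tsv", sep="\t")["fd_mm"].to_numpy()
    return ParcelTimeSeries(
        subject_id=subject_id,
        data=ts.to_numpy(),
        region_labels=list(ts.columns),
        fd=fd,
        tr_seconds=tr_seconds,
    )
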