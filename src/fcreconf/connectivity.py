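"""Functional connectivity (FC) and its rest-to-task reconfiguration.

FC between two ROIs is the Pearson correlation of their BOLD time series,
variance-stabilized by the Fisher transform z' = arctanh(r).  A subject's
task FC is the element-wise mean of the two task runs *on the z' scale*.
The reconfiguration statistic is the edge-wise absolute difference
|z'_rest - z'_task|, read as the amount of network change needed to move
from intrinsic to task-engaged organization.

Edges are the R(R-1)/2 unordered ROI pairs, enumerated row-major over the
upper triangle: (0,1), (0,2), ..., (0,R-1), (1,2), ...  Every downstream
table uses this ordering; with the default 16 ROIs there are 120 edges.

Optional temporal filtering (zero-phase Butterworth; 0.008-0.08 Hz band for
rest, >0.01 Hz high-pass for task) is provided for time series that arrive
unfiltered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort_io import default_roi_labels
from .exceptions import (
    ConsistencyError,
    DegenerateInputError,
    PairingError,
    ShapeError,
)

#: correlations are clipped to |r| <= 1 - CLIP before arctanh so z' stays finite
CLIP = 1e-7
_SYM_TOL = 1e-10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FCMatrix:
    """Symmetric R x R Fisher-z connectivity for one subject in one state.

    The diagonal (self-connectivity) is excluded and stored as NaN.
    """

    values: np.ndarray
    subject_id: str = ""
    state: str = ""
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).copy()
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError("FC matrix must be square")
        off = ~np.eye(v.shape[0], dtype=bool)
        if not np.all(np.isfinite(v[off])):
            raise ValueError("FC matrix has non-finite off-diagonal entries")
        if np.abs(v[off] - v.T[off]).max(initial=0.0) > _SYM_TOL:
            raise ConsistencyError("FC matrix is asymmetric beyond tolerance")
        np.fill_diagonal(v, np.nan)
        self.values = v
        if not self.roi_labels:
            self.roi_labels = default_roi_labels(v.shape[0])

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_edges(self) -> int:
        r = self.n_rois
        return r * (r - 1) // 2

    def edges(self) -> np.ndarray:
        """Upper-triangle edge vector (canonical ordering)."""
        return vectorize_upper(self)


@dataclass
class ReconfigurationVector:
    """Edge-wise |z'_rest - z'_task| for one subject; all entries >= 0."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ShapeError("reconfiguration vector must be 1-D")
        if not np.all(np.isfinite(v)) or (v < 0).any():
            raise ValueError("reconfiguration entries must be finite and non-negative")
        self.values = v


# ---------------------------------------------------------------------------
# temporal filtering
# ---------------------------------------------------------------------------


def _check_filter_args(ts: np.ndarray, tr: float, order: int) -> np.ndarray:
    ts = np.atleast_2d(np.asarray(ts, dtype=float))
    if tr <= 0:
        raise ValueError("tr must be positive")
    if order < 1:
        raise ValueError("filter order must be >= 1")
    if ts.shape[0] <= 3 * order:
        raise ValueError(
            f"need more than {3 * order} timepoints for an order-{order} filter"
        )
    return ts


def bandpass_filter(
    ts: np.ndarray, low: float, high: float, tr: float, order: int = 4
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth band-pass, column-wise.

    ``low``/``high`` are in Hz and must satisfy 0 < low < high < Nyquist
    = 1/(2 tr).  Zero-phase filtering avoids introducing lags that would
    bias the inter-regional correlations.
    """
    ts = _check_filter_args(ts, tr, order)
    nyq = 0.5 / tr
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz must be below Nyquist {nyq:g} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


def highpass_filter(ts: np.ndarray, cutoff: float, tr: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth high-pass (removes drift and DC), column-wise."""
    ts = _check_filter_args(ts, tr, order)
    nyq = 0.5 / tr
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq:g}) Hz, got {cutoff}")
    sos = signal.butter(order, cutoff, btype="highpass", fs=1.0 / tr, output="sos")
    return signal.sosfiltfilt(sos, ts, axis=0)


# ---------------------------------------------------------------------------
# Fisher transform
# ---------------------------------------------------------------------------


def fisher_z(r):
    """Fisher z-transform z' = arctanh(r), with clipping at |r| = 1 - 1e-7.

    The clip keeps perfectly (anti)correlated inputs finite and
    deterministic.  Values beyond |r| = 1 (plus a small numerical
    tolerance) are rejected.
    """
    arr = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("correlations must be finite")
    if np.any(np.abs(arr) > 1 + 1e-8):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -1 + CLIP, 1 - CLIP))
    return out if out.ndim else float(out)


def inverse_fisher_z(z):
    """Inverse transform r = tanh(z')."""
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# FC estimation and reconfiguration
# ---------------------------------------------------------------------------


def fc_from_timeseries(
    ts: np.ndarray,
    subject_id: str = "",
    state: str = "",
    roi_labels: list[str] | None = None,
) -> FCMatrix:
    """Fisher-z Pearson correlation matrix of a T x R time-series table."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ShapeError("time series must be 2-D (timepoints x ROIs)")
    t, r = ts.shape
    if t < 4:
        raise ShapeError(f"need at least 4 timepoints, got {t}")
    if r < 2:
        raise ShapeError(f"need at least 2 ROIs, got {r}")
    labels = roi_labels or default_roi_labels(r)
    sd = ts.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = ", ".join(labels[i] for i in dead)
        raise DegenerateInputError(f"zero-variance time series for ROI(s): {names}")
    corr = np.corrcoef(ts, rowvar=False)
    z = np.arctanh(np.clip(corr, -1 + CLIP, 1 - CLIP))
    return FCMatrix(values=z, subject_id=subject_id, state=state, roi_labels=labels)


def average_fc(runs: list[FCMatrix]) -> FCMatrix:
    """Element-wise mean of 1-2 runs on the Fisher-z scale.

    Averaging is done on z', not on back-transformed r: the two are not
    interchangeable, and the z'-scale mean is the one used throughout.
    """
    if not 1 <= len(runs) <= 2:
        raise ValueError("expected 1 or 2 runs")
    first = runs[0]
    for m in runs[1:]:
        if m.n_rois != first.n_rois:
            raise ShapeError("runs have different numbers of ROIs")
        if m.subject_id != first.subject_id:
            raise PairingError(
                f"runs belong to different subjects: {first.subject_id!r} vs {m.subject_id!r}"
            )
    mean = np.mean([m.values for m in runs], axis=0)
    return FCMatrix(
        values=mean,
        subject_id=first.subject_id,
        state="task",
        roi_labels=first.roi_labels,
    )


def reconfiguration(rest: FCMatrix, task: FCMatrix) -> ReconfigurationVector:
    """Edge-wise |z'_rest - z'_task|; symmetric in its arguments."""
    if rest.subject_id != task.subject_id:
        raise PairingError(
            f"rest and task matrices belong to different subjects: "
            f"{rest.subject_id!r} vs {task.subject_id!r}"
        )
    if rest.n_rois != task.n_rois:
        raise ShapeError("rest and task matrices have different sizes")
    diff = np.abs(vectorize_upper(rest) - vectorize_upper(task))
    return ReconfigurationVector(values=diff, subject_id=rest.subject_id)


# ---------------------------------------------------------------------------
# edge vectorization
# ---------------------------------------------------------------------------


def vectorize_upper(m: FCMatrix | np.ndarray) -> np.ndarray:
    """Row-major upper-triangle edge vector of a symmetric matrix."""
    values = m.values if isinstance(m, FCMatrix) else np.asarray(m, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ShapeError("expected a square matrix")
    off = ~np.eye(values.shape[0], dtype=bool)
    asym = np.abs(values[off] - values.T[off])
    if np.all(np.isfinite(asym)) and asym.max(initial=0.0) > _SYM_TOL:
        raise ConsistencyError("matrix asymmetric beyond 1e-10")
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu].copy()


def devectorize(edges: np.ndarray, diagonal: float = np.nan) -> np.ndarray:
    """Inverse of :func:`vectorize_upper`; fills the diagonal with ``diagonal``."""
    edges = np.asarray(edges, dtype=float)
    e = edges.size
    r = int(round((1 + np.sqrt(1 + 8 * e)) / 2))
    if r * (r - 1) // 2 != e:
        raise ShapeError(f"{e} is not a valid edge count R(R-1)/2")
    out = np.full((r, r), float(diagonal))
    iu = np.triu_indices(r, k=1)
    out[iu] = edges
    out[(iu[1], iu[0])] = edges
    return out


def n_edges(n_rois: int) -> int:
    return n_rois * (n_rois - 1) // 2


def edge_pair_labels(roi_labels: list[str]) -> list[str]:
    """Human-readable edge names ("ROI01-ROI02", ...) in canonical order."""
    r = len(roi_labels)
    iu = np.triu_indices(r, k=1)
    return [f"{roi_labels[i]}-{roi_labels[j]}" for i, j in zip(*iu)]
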