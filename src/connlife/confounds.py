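"""Temporal preprocessing: motion quantification, screening, nuisance
regression, and band-pass filtering.

The pipeline applies, in order: framewise-displacement screening of
subjects, least-squares removal of a 24-parameter motion design plus CSF,
white-matter and global signals (and their derivatives), then a zero-phase
0.01–0.1 Hz band-pass.  Filtering follows regression; the two do not
commute and the order is fixed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ParameterError, ValidationError

#: Rotation-to-millimetre conversion radius (mm), the usual FD convention.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Screening defaults: exclude if mean FD >= 0.2 mm or >20% of volumes
#: have FD > 0.2 mm.
DEFAULT_MEAN_FD_MM = 0.2
DEFAULT_FD_SPIKE_MM = 0.2
DEFAULT_SPIKE_FRACTION = 0.20


@dataclass(frozen=True)
class MotionTrace:
    """Six rigid-body motion parameters per volume.

    ``params`` is T x 6: x, y, z translations in mm, then roll, pitch, yaw
    rotations in radians.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.params, dtype=float)
        if p.ndim != 2 or p.shape[1] != 6:
            raise ValidationError(f"motion trace must be T x 6, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValidationError("motion trace contains non-finite values")
        object.__setattr__(self, "params", p)

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]


@dataclass(frozen=True)
class NodeTimeSeries:
    """T x N matrix of node signals sampled every ``tr_seconds``."""

    values: np.ndarray
    tr_seconds: float = 2.5

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2 or v.shape[0] < 2:
            raise ValidationError(f"time series must be T x N with T >= 2, got {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValidationError("time series contains non-finite values")
        if not (self.tr_seconds > 0):
            raise ParameterError("tr_seconds must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConfoundDesign:
    """T x P confound design matrix with labelled columns."""

    columns: np.ndarray
    column_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.columns, dtype=float)
        if c.ndim != 2 or c.shape[1] != len(self.column_labels):
            raise ValidationError("design shape does not match labels")
        object.__setattr__(self, "columns", c)

    @property
    def n_motion_columns(self) -> int:
        return sum(1 for lab in self.column_labels if lab.startswith("motion_"))


@dataclass(frozen=True)
class ScreeningDecision:
    include: bool
    mean_fd: float
    spike_fraction: float
    reasons: tuple[str, ...]


def framewise_displacement(
    trace: MotionTrace, head_radius: float = DEFAULT_HEAD_RADIUS_MM
) -> np.ndarray:
    """Per-volume framewise displacement in mm (Power convention).

    FD_t = sum of absolute backward differences of the three translations
    plus the three rotation differences converted to arc length on a sphere
    of ``head_radius`` mm.  The first volume has FD = 0 by definition.
    """
    if not np.isfinite(head_radius) or head_radius <= 0:
        raise ParameterError("head_radius must be a positive finite value in mm")
    if trace.n_volumes < 2:
        raise ValidationError("framewise displacement needs at least 2 volumes")
    d = np.abs(np.diff(trace.params, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def screen_subject(
    fd: np.ndarray,
    mean_thr: float = DEFAULT_MEAN_FD_MM,
    frac_thr: float = DEFAULT_SPIKE_FRACTION,
    spike_thr: float = DEFAULT_FD_SPIKE_MM,
) -> ScreeningDecision:
    """Two-criterion motion screen.

    A subject is excluded when mean FD >= ``mean_thr`` (default 0.2 mm) OR
    the fraction of volumes with FD > ``spike_thr`` exceeds ``frac_thr``
    (defaults 0.2 mm, 20%).  The decision records which criterion fired.
    """
    fd = np.asarray(fd, dtype=float)
    if fd.size == 0:
        raise ValidationError("empty FD sequence")
    mean_fd = float(fd.mean())
    frac = float(np.mean(fd > spike_thr))
    reasons = []
    if mean_fd >= mean_thr:
        reasons.append(f"mean FD {mean_fd:.4f} >= {mean_thr} mm")
    if frac > frac_thr:
        reasons.append(f"{100 * frac:.1f}% of volumes with FD > {spike_thr} mm")
    return ScreeningDecision(
        include=not reasons, mean_fd=mean_fd, spike_fraction=frac, reasons=tuple(reasons)
    )


def build_confound_design(
    trace: MotionTrace, nuisance: np.ndarray | None = None
) -> ConfoundDesign:
    """Assemble the full confound design.

    Columns: the 24 motion regressors {R_t, R_t^2, R_{t-1}, R_{t-1}^2}
    (6 parameters x 4), the three nuisance signals (CSF, WM, global),
    their first differences, and an intercept — 31 in the default build.
    Lag-1 columns have their first row set to 0 so T is preserved.
    """
    R = trace.params
    T = R.shape[0]
    lag = np.vstack([np.zeros((1, 6)), R[:-1]])
    names6 = ("x", "y", "z", "roll", "pitch", "yaw")
    blocks = [R, R**2, lag, lag**2]
    labels: list[str] = []
    for tag in ("R", "R2", "Rlag", "Rlag2"):
        labels.extend(f"motion_{tag}_{n}" for n in names6)
    cols = [np.hstack(blocks)]
    if nuisance is not None:
        nui = np.asarray(nuisance, dtype=float)
        if nui.ndim == 1:
            nui = nui[:, None]
        if nui.shape[0] != T:
            raise ValidationError(
                f"nuisance length {nui.shape[0]} != motion length {T}"
            )
        d_nui = np.vstack([np.zeros((1, nui.shape[1])), np.diff(nui, axis=0)])
        cols += [nui, d_nui]
        nui_names = ("csf", "wm", "global")[: nui.shape[1]] + tuple(
            f"nuisance_{j}" for j in range(3, nui.shape[1])
        )
        labels.extend(nui_names)
        labels.extend(f"d_{n}" for n in nui_names)
    cols.append(np.ones((T, 1)))
    labels.append("intercept")
    return ConfoundDesign(np.hstack(cols), tuple(labels))


class ConfoundRegressor(BaseEstimator, TransformerMixin):
    """Least-squares removal of a confound design from node time series.

    fit(X) learns the projection for a T x P design; transform(Y) returns
    the residuals of each column of the T x N data on that design.  Residuals
    are orthogonal to every design column.  Rank-deficient designs fall back
    to the pseudoinverse with a warning.
    """

    def fit(self, X, y=None):
        X = X.columns if isinstance(X, ConfoundDesign) else np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValidationError("design must be 2-D (T x P)")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            warnings.warn(
                f"confound design is rank deficient ({rank} < {X.shape[1]}); "
                "using pseudoinverse",
                stacklevel=2,
            )
        self.design_ = X
        self.pinv_ = np.linalg.pinv(X)
        self.rank_ = int(rank)
        return self

    def transform(self, Y):
        ts = Y if isinstance(Y, NodeTimeSeries) else None
        V = ts.values if ts is not None else np.asarray(Y, dtype=float)
        if V.shape[0] != self.design_.shape[0]:
            raise ValidationError(
                f"data has {V.shape[0]} volumes, design has {self.design_.shape[0]}"
            )
        resid = V - self.design_ @ (self.pinv_ @ V)
        if ts is not None:
            return NodeTimeSeries(resid, ts.tr_seconds)
        return resid


def regress_confounds(ts: NodeTimeSeries, design: ConfoundDesign) -> NodeTimeSeries:
    """Residualize ``ts`` on ``design`` (thin wrapper over ConfoundRegressor)."""
    return ConfoundRegressor().fit(design).transform(ts)


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth band-pass (default 0.01–0.1 Hz, order 2).

    Applied forward-backward (filtfilt), so the effective magnitude response
    is the square of the single-pass response and no phase shift is
    introduced — phase shifts would bias connectivity estimates.
    """

    def __init__(self, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 2):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.order = order

    def fit(self, X=None, y=None):
        return self

    def transform(self, Y):
        ts = Y if isinstance(Y, NodeTimeSeries) else None
        if ts is None:
            raise ValidationError("BandpassFilter.transform expects a NodeTimeSeries")
        fs = 1.0 / ts.tr_seconds
        nyq = fs / 2.0
        if not (0 <= self.low_hz < self.high_hz < nyq):
            raise ParameterError(
                f"band ({self.low_hz}, {self.high_hz}) Hz must satisfy "
                f"0 <= low < high < Nyquist ({nyq:g} Hz)"
            )
        if self.low_hz == 0:
            sos = signal.butter(self.order, self.high_hz, btype="low", fs=fs, output="sos")
        else:
            sos = signal.butter(
                self.order, [self.low_hz, self.high_hz], btype="band", fs=fs, output="sos"
            )
        out = signal.sosfiltfilt(sos, ts.values, axis=0)
        return NodeTimeSeries(out, ts.tr_seconds)


def bandpass(
    ts: NodeTimeSeries, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 2
) -> NodeTimeSeries:
    """Band-pass filter a node time series (wrapper over BandpassFilter)."""
    return BandpassFilter(low_hz, high_hz, order).transform(ts)


def preprocess(
    ts: NodeTimeSeries,
    trace: MotionTrace,
    nuisance: np.ndarray | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.1,
) -> NodeTimeSeries:
    """Confound regression followed by band-pass, in the pipeline's order."""
    design = build_confound_design(trace, nuisance)
    return bandpass(regress_confounds(ts, design), low_hz, high_hz)
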