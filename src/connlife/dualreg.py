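"""Dual regression: subject-specific spatial maps from group RSN templates.

Stage 1 regresses each fMRI volume (one time point) jointly on all K group
templates, yielding K subject time courses.  Stage 2 regresses each voxel's
time series jointly on those K courses, yielding K subject-specific spatial
maps.  Both stages are multivariate (joint) least squares — regressing on
one template at a time gives different, biased answers when templates are
correlated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import ValidationError


@dataclass(frozen=True)
class SpatialMap:
    """A 3-D voxel map of connectivity values for one RSN."""

    grid: np.ndarray
    rsn_label: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        object.__setattr__(self, "grid", g)
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != g.shape:
                raise ValidationError("mask shape does not match grid shape")
            object.__setattr__(self, "mask", m)
        vals = g[self.mask] if self.mask is not None else g
        if not np.all(np.isfinite(vals)):
            raise ValidationError("spatial map contains non-finite values in mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.grid.shape

    def flat(self) -> np.ndarray:
        """Masked voxel values as a 1-D array."""
        return self.grid[self.mask] if self.mask is not None else self.grid.ravel()


@dataclass(frozen=True)
class TemplateSet:
    """K group spatial maps with distinct RSN labels on one voxel grid."""

    maps: tuple[SpatialMap, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.maps) < 1:
            raise ValidationError("template set needs at least one map")
        if len(self.labels) != len(self.maps):
            raise ValidationError("labels/maps length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValidationError("template labels must be pairwise distinct")
        shapes = {m.shape for m in self.maps}
        if len(shapes) != 1:
            raise ValidationError(f"templates must share one grid shape, got {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.maps[0].shape

    @property
    def n_components(self) -> int:
        return len(self.maps)

    def as_matrix(self) -> np.ndarray:
        """Voxels x K template matrix (flattened grids)."""
        return np.column_stack([m.grid.ravel() for m in self.maps])

    def __getitem__(self, label: str) -> SpatialMap:
        return self.maps[self.labels.index(label)]


def _design_lstsq(A: np.ndarray, B: np.ndarray, what: str) -> np.ndarray:
    """Least-squares solve A x = B, warning (not failing) on collinearity."""
    coef, _, rank, _ = np.linalg.lstsq(A, B, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"collinear {what} (rank {rank} < {A.shape[1]}); minimum-norm "
            "pseudoinverse solution returned",
            stacklevel=3,
        )
    return coef


class DualRegression(BaseEstimator, TransformerMixin):
    """Two-stage dual regression against a fixed template set.

    Parameters
    ----------
    variance_normalize : bool, default True
        Scale each stage-1 time course to unit variance before stage 2
        (the usual design-normalization convention), so stage-2 map units
        are comparable across components.

    After ``fit(templates)`` the estimator exposes ``templates_`` (voxels x K)
    and ``labels_``; ``transform(data)`` returns the K subject maps as a
    K x voxels array, and ``dual_regress(data)`` additionally returns the
    stage-1 time courses.
    """

    def __init__(self, variance_normalize: bool = True):
        self.variance_normalize = variance_normalize

    def fit(self, X, y=None):
        if isinstance(X, TemplateSet):
            self.templates_ = X.as_matrix()
            self.labels_ = X.labels
            self.grid_shape_ = X.shape
        else:
            self.templates_ = np.asarray(X, dtype=float)
            if self.templates_.ndim != 2:
                raise ValidationError("templates must be voxels x K")
            self.labels_ = tuple(f"ic{k}" for k in range(self.templates_.shape[1]))
            self.grid_shape_ = None
        return self

    def stage1(self, data: np.ndarray) -> np.ndarray:
        """Spatial regression: fit each volume on all templates jointly.

        ``data`` is voxels x T; returns the K x T coefficient time courses.
        """
        data = np.asarray(data, dtype=float)
        if data.shape[0] != self.templates_.shape[0]:
            raise ValidationError(
                f"data has {data.shape[0]} voxels, templates have "
                f"{self.templates_.shape[0]}"
            )
        return _design_lstsq(self.templates_, data, "templates")

    def stage2(self, data: np.ndarray, timecourses: np.ndarray) -> np.ndarray:
        """Temporal regression: fit each voxel's series on all K courses.

        Returns K x voxels subject-specific maps.
        """
        data = np.asarray(data, dtype=float)
        tc = np.asarray(timecourses, dtype=float)
        if data.shape[1] != tc.shape[1]:
            raise ValidationError(
                f"data has {data.shape[1]} time points, courses have {tc.shape[1]}"
            )
        if self.variance_normalize:
            sd = tc.std(axis=1, ddof=1, keepdims=True)
            sd[sd == 0] = 1.0
            tc = tc / sd
        return _design_lstsq(tc.T, data.T, "time courses")

    def dual_regress(self, data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Run both stages; returns (maps K x voxels, time courses K x T)."""
        tc = self.stage1(data)
        return self.stage2(data, tc), tc

    def transform(self, data: np.ndarray) -> np.ndarray:
        maps, _ = self.dual_regress(data)
        return maps

    def subject_maps(self, data: np.ndarray, mask: np.ndarray | None = None):
        """As ``transform`` but returning labelled :class:`SpatialMap` objects."""
        maps = self.transform(data)
        if self.grid_shape_ is None:
            raise ValidationError("fit with a TemplateSet to get gridded maps")
        return {
            lab: SpatialMap(maps[k].reshape(self.grid_shape_), lab, mask)
            for k, lab in enumerate(self.labels_)
        }


def stage1_spatial_regression(data: np.ndarray, templates: TemplateSet) -> np.ndarray:
    """K x T time courses from voxels x T data (wrapper over DualRegression)."""
    return DualRegression().fit(templates).stage1(data)


def stage2_temporal_regression(
    data: np.ndarray, timecourses: np.ndarray, variance_normalize: bool = True
) -> np.ndarray:
    """K x voxels subject maps from voxels x T data and K x T courses."""
    dr = DualRegression(variance_normalize=variance_normalize)
    dr.templates_ = np.empty((data.shape[0], timecourses.shape[0]))
    dr.labels_ = tuple(f"ic{k}" for k in range(timecourses.shape[0]))
    dr.grid_shape_ = None
    return dr.stage2(data, timecourses)
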