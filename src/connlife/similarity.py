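"""The eta-squared (η²) spatial-similarity statistic and young-adult
reference construction.

η² quantifies how similar two connectivity maps a and b are::

    η² = 1 - Σ_i [(a_i - m_i)² + (b_i - m_i)²] / Σ_i [(a_i - M̄)² + (b_i - M̄)²]

where m_i is the voxelwise mean of the two maps, M̄ the grand mean of m,
and the sum runs over the V voxels compared.  η² is 1 iff the maps are
identical and 0 in the degenerate anti-similar case m ≡ M̄.  Unlike a
correlation it is sensitive to scale: η²(a, 2a) < 1.

Network integrity of a subject-specific RSN is measured as η² against a
reference map — the voxelwise mean of the subject maps of a young-adult
subgroup (age <= 30 years by default; 40 gives much the same ordering).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .dualreg import SpatialMap
from .exceptions import ConfigurationError, UndefinedStatisticError, ValidationError

DEFAULT_REFERENCE_CUTOFF_AGE = 30.0


def _paired_values(a, b, mask=None) -> tuple[np.ndarray, np.ndarray]:
    amap = a if isinstance(a, SpatialMap) else None
    bmap = b if isinstance(b, SpatialMap) else None
    av = np.asarray(amap.grid if amap else a, dtype=float)
    bv = np.asarray(bmap.grid if bmap else b, dtype=float)
    if av.shape != bv.shape:
        raise ValidationError(f"map shapes differ: {av.shape} vs {bv.shape}")
    if mask is None and amap is not None and amap.mask is not None:
        mask = amap.mask
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != av.shape:
            raise ValidationError("mask shape does not match maps")
        av, bv = av[mask], bv[mask]
    return av.ravel(), bv.ravel()


def eta_squared(a, b, mask: np.ndarray | None = None) -> float:
    """η² similarity of two maps over a shared (optional) mask.

    Raises :class:`UndefinedStatisticError` when both maps are constant and
    equal (zero denominator).
    """
    av, bv = _paired_values(a, b, mask)
    m = 0.5 * (av + bv)
    M_bar = m.mean()
    num = np.sum((av - m) ** 2 + (bv - m) ** 2)
    den = np.sum((av - M_bar) ** 2 + (bv - M_bar) ** 2)
    if den <= 0:
        raise UndefinedStatisticError(
            "eta_squared undefined: both maps constant and equal (zero denominator)"
        )
    return float(1.0 - num / den)


@dataclass(frozen=True)
class ReferenceSet:
    """Per-RSN reference maps built from a young-adult subgroup."""

    maps: Mapping[str, SpatialMap]
    cutoff_age: float
    n_reference_subjects: int

    def __getitem__(self, label: str) -> SpatialMap:
        return self.maps[label]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.maps)


def build_reference(
    subject_maps: Mapping[str, Mapping[str, SpatialMap]],
    ages: Mapping[str, float],
    cutoff_age: float = DEFAULT_REFERENCE_CUTOFF_AGE,
) -> ReferenceSet:
    """Voxelwise mean of subject-specific RSN maps for subjects with
    age <= ``cutoff_age``.

    ``subject_maps`` maps subject_id -> {rsn_label -> SpatialMap}; ``ages``
    maps subject_id -> age in years.
    """
    young = [sid for sid in subject_maps if ages[sid] <= cutoff_age]
    if not young:
        raise ConfigurationError(
            f"no subject with age <= {cutoff_age} to build the reference"
        )
    labels: list[str] = []
    for sid in young:
        labels.extend(lab for lab in subject_maps[sid] if lab not in labels)
    refs: dict[str, SpatialMap] = {}
    for lab in labels:
        have = [sid for sid in young if lab in subject_maps[sid]]
        stack = np.stack([subject_maps[sid][lab].grid for sid in have])
        mask = subject_maps[have[0]][lab].mask
        refs[lab] = SpatialMap(stack.mean(axis=0), lab, mask)
    return ReferenceSet(refs, cutoff_age, len(young))


def similarity_table(
    subject_maps: Mapping[str, Mapping[str, SpatialMap]],
    reference: ReferenceSet,
    mask: np.ndarray | None = None,
    subjects: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Long-format per-subject per-RSN η² table.

    Subjects missing a map for some RSN get a NaN cell (excluded pairwise
    downstream) rather than failing the whole table.
    """
    rows = []
    for sid in subjects if subjects is not None else subject_maps:
        maps = subject_maps[sid]
        for lab in reference.labels:
            if lab in maps:
                val = eta_squared(maps[lab], reference[lab], mask)
            else:
                val = np.nan
            rows.append((sid, lab, val))
    return pd.DataFrame(rows, columns=["subject_id", "rsn_label", "eta_sq"])
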