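"""Whole-brain parcellation bookkeeping.

The analyses operate on a 499-ROI functional parcellation in which 142 nodes
belong to 14 canonical resting-state networks (RSNs) and the remaining 357
cover the rest of cortex and subcortical areas.  This module holds the
parcellation container, the default node-count fixture, TSV round-trip, and
a count-validation report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

#: Node counts of the 14 canonical RSNs in the default 499-ROI parcellation.
RSN_NODE_COUNTS: dict[str, int] = {
    "auditory": 4,
    "basal_ganglia": 7,
    "dorsal_dmn": 21,
    "ventral_dmn": 13,
    "high_visual": 4,
    "language": 9,
    "lecn": 10,
    "recn": 14,
    "sensorimotor": 12,
    "posterior_salience": 13,
    "precuneus": 6,
    "primary_visual": 2,
    "anterior_salience": 12,
    "visuospatial": 15,
}

RSN_NAMES: tuple[str, ...] = tuple(RSN_NODE_COUNTS)
OTHER_LABEL = "other"
N_RSN_NODES = sum(RSN_NODE_COUNTS.values())  # 142
N_TOTAL_NODES = 499
N_OTHER_NODES = N_TOTAL_NODES - N_RSN_NODES  # 357


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI list with network assignments.

    Parameters
    ----------
    rois : list of (roi_id, network_label)
        One entry per node, in matrix order.  ``roi_id`` values must be
        unique; ``network_label`` is one of the RSN names or ``"other"``.
    """

    rois: tuple[tuple[str, str], ...]
    _index: dict[str, np.ndarray] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.rois) == 0:
            raise ValidationError("parcellation is empty")
        ids = [r[0] for r in self.rois]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate roi_id(s): {dupes}")
        index: dict[str, list[int]] = {}
        for i, (_, net) in enumerate(self.rois):
            index.setdefault(net, []).append(i)
        object.__setattr__(
            self, "_index", {k: np.asarray(v, dtype=int) for k, v in index.items()}
        )

    @property
    def n_nodes(self) -> int:
        return len(self.rois)

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, RSNs first in canonical order, then extras."""
        present = set(self._index)
        ordered = [n for n in RSN_NAMES if n in present]
        ordered += sorted(present - set(RSN_NAMES))
        return tuple(ordered)

    @property
    def rsn_networks(self) -> tuple[str, ...]:
        return tuple(n for n in RSN_NAMES if n in self._index)

    def network_nodes(self, network: str) -> np.ndarray:
        """Indices (matrix order) of the nodes assigned to ``network``."""
        try:
            return self._index[network]
        except KeyError:
            raise KeyError(f"unknown network {network!r}") from None

    def rsn_node_indices(self) -> np.ndarray:
        """Indices of all RSN-assigned nodes (excludes 'other')."""
        idx = [self._index[n] for n in self.rsn_networks]
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    def network_counts(self) -> dict[str, int]:
        return {n: len(self._index[n]) for n in self.networks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rois, columns=["roi_id", "network"])


def default_parcellation() -> Parcellation:
    """The default 499-node fixture: printed per-RSN counts plus 357 'other'.

    ROI ids are synthetic (``<network>_<k>``); real analyses substitute a
    table of labelled ROIs with the same structure.
    """
    rois: list[tuple[str, str]] = []
    for net, count in RSN_NODE_COUNTS.items():
        rois.extend((f"{net}_{k:02d}", net) for k in range(count))
    rois.extend((f"other_{k:03d}", OTHER_LABEL) for k in range(N_OTHER_NODES))
    return Parcellation(tuple(rois))


def make_parcellation(counts: dict[str, int], n_other: int = 0) -> Parcellation:
    """Build a reduced parcellation (used for fast simulations and tests)."""
    rois: list[tuple[str, str]] = []
    for net, count in counts.items():
        rois.extend((f"{net}_{k:02d}", net) for k in range(count))
    rois.extend((f"other_{k:03d}", OTHER_LABEL) for k in range(n_other))
    return Parcellation(tuple(rois))


def load_parcellation(path) -> Parcellation:
    """Read a two-column TSV (roi_id, network)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"roi_id", "network"} - set(df.columns)
    if missing:
        raise ValidationError(f"parcellation TSV missing columns: {sorted(missing)}")
    return Parcellation(tuple(zip(df["roi_id"], df["network"])))


def save_parcellation(parc: Parcellation, path) -> None:
    parc.to_frame().to_csv(path, sep="\t", index=False)


def validate_parcellation(parc: Parcellation) -> dict:
    """Per-network count report against the printed default counts.

    Returns a dict with observed counts, expected counts for the 14 RSNs,
    RSN-assigned and remainder totals, and a ``matches_default`` flag.
    """
    observed = parc.network_counts()
    rsn_total = int(sum(observed.get(n, 0) for n in RSN_NAMES))
    remainder = parc.n_nodes - rsn_total
    matches = all(observed.get(n, 0) == c for n, c in RSN_NODE_COUNTS.items()) and (
        parc.n_nodes == N_TOTAL_NODES
    )
    return {
        "observed_counts": observed,
        "expected_rsn_counts": dict(RSN_NODE_COUNTS),
        "rsn_total": rsn_total,
        "remainder": remainder,
        "n_total": parc.n_nodes,
        "matches_default": bool(matches),
    }
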