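"""Network-level connectivity: Fisher transform, WNFC and BNFC.

Connectivity at this level is summarized over the 142 RSN-assigned nodes:
correlations are Fisher-transformed to z, then within-network functional
connectivity (WNFC) is the mean z over all node pairs inside one RSN
(k(k-1)/2 values for a k-node network), and between-network functional
connectivity (BNFC) is the mean z over all node pairs straddling two RSNs
(k*l values).  Averaging happens in the z domain.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd

from .exceptions import UndefinedMetricError
from .graphnet import ConnectivityMatrix
from .parcellation import Parcellation

_CLIP = 1.0 - 1e-7


def fisher_z(r):
    """Fisher transform z = atanh(r); |r| >= 1 is clipped with a warning."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlation magnitude >= 1 clipped to 1 - 1e-7 before atanh",
            stacklevel=2,
        )
        r = np.clip(r, -_CLIP, _CLIP)
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def wnfc(conn: ConnectivityMatrix, parc: Parcellation, network: str) -> float:
    """Mean z over the node pairs within one network (diagonal excluded)."""
    idx = parc.network_nodes(network)
    k = idx.size
    if k < 2:
        raise UndefinedMetricError(
            f"WNFC undefined for network {network!r} with {k} node(s)"
        )
    block = conn.z_values[np.ix_(idx, idx)]
    iu = np.triu_indices(k, 1)
    return float(block[iu].mean())


def bnfc(conn: ConnectivityMatrix, parc: Parcellation, net1: str, net2: str) -> float:
    """Mean z over all node pairs with one node in each of two networks."""
    if net1 == net2:
        raise UndefinedMetricError("BNFC needs two distinct networks")
    i = parc.network_nodes(net1)
    j = parc.network_nodes(net2)
    return float(conn.z_values[np.ix_(i, j)].mean())


def network_fc_table(
    conn: ConnectivityMatrix,
    parc: Parcellation,
    subject_id: str | None = None,
    networks: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """All WNFC cells and all unordered BNFC cells for one subject.

    Columns: subject_id, cell (``net`` or ``net1|net2``), kind, value,
    n_pairs.  With the default 14-RSN parcellation the n_pairs column sums
    to 142*141/2 across all cells.
    """
    nets = networks if networks is not None else parc.rsn_networks
    rows = []
    for net in nets:
        k = parc.network_nodes(net).size
        rows.append((subject_id, net, "wnfc", wnfc(conn, parc, net), k * (k - 1) // 2))
    for n1, n2 in combinations(nets, 2):
        npairs = parc.network_nodes(n1).size * parc.network_nodes(n2).size
        rows.append(
            (subject_id, f"{n1}|{n2}", "bnfc", bnfc(conn, parc, n1, n2), npairs)
        )
    return pd.DataFrame(
        rows, columns=["subject_id", "cell", "kind", "value", "n_pairs"]
    )


def cohort_network_fc(
    conns: dict[str, ConnectivityMatrix], parc: Parcellation
) -> pd.DataFrame:
    """Wide cohort table: one row per subject, one column per WNFC/BNFC cell."""
    frames = []
    for sid, conn in conns.items():
        t = network_fc_table(conn, parc, subject_id=sid)
        frames.append(t.set_index("cell")["value"].rename(sid))
    return pd.DataFrame(frames).rename_axis("subject_id")


def edge_list(
    cells: pd.Series, pvals: pd.Series | None = None, significant=None
) -> pd.DataFrame:
    """Simple exportable edge list of BNFC cells with sign and strength."""
    rows = []
    for cell, value in cells.items():
        if "|" not in cell:
            continue
        n1, n2 = cell.split("|")
        rows.append(
            {
                "source": n1,
                "target": n2,
                "value": value,
                "sign": int(np.sign(value)),
                "p": None if pvals is None else pvals.get(cell),
                "significant": None if significant is None else bool(significant.get(cell)),
            }
        )
    return pd.DataFrame(rows)
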