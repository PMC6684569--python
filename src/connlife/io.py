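"""File I/O: NIfTI spatial maps, TSV tables, motion traces, provenance."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .confounds import MotionTrace
from .dualreg import SpatialMap, TemplateSet
from .exceptions import ValidationError


def save_map(m: SpatialMap, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(m.grid, dtype=np.float32),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_map(path, rsn_label: str = "", mask: np.ndarray | None = None) -> SpatialMap:
    img = nib.load(str(path))
    return SpatialMap(np.asarray(img.get_fdata(), dtype=float), rsn_label, mask)


def save_template_set(ts: TemplateSet, directory) -> None:
    """One NIfTI per template plus a labels sidecar TSV fixing the order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for k, (m, lab) in enumerate(zip(ts.maps, ts.labels)):
        fname = f"template_{k:02d}.nii.gz"
        save_map(m, directory / fname)
        rows.append((k, lab, fname))
    pd.DataFrame(rows, columns=["order", "rsn_label", "filename"]).to_csv(
        directory / "labels.tsv", sep="\t", index=False
    )


def load_template_set(directory) -> TemplateSet:
    directory = Path(directory)
    labels = pd.read_csv(directory / "labels.tsv", sep="\t").sort_values("order")
    maps = tuple(
        load_map(directory / row.filename, row.rsn_label)
        for row in labels.itertuples()
    )
    return TemplateSet(maps, tuple(labels["rsn_label"]))


def load_motion(path) -> MotionTrace:
    """Six-column whitespace/TSV motion file (SPM realignment style)."""
    arr = np.loadtxt(str(path))
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValidationError(f"motion file must have 6 columns, got {arr.shape}")
    return MotionTrace(arr)


def save_motion(trace: MotionTrace, path) -> None:
    np.savetxt(str(path), trace.params, fmt="%.8f", delimiter="\t")


def save_table(df: pd.DataFrame, path) -> str:
    """Write a TSV and return its sha256 checksum (provenance)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return sha256_file(path)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def save_provenance(meta: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(meta), sort_keys=False))


def _plain(obj):
    """Recursively convert to YAML-safe builtins."""
    if isinstance(obj, dict):
        return {str(_plain(k)): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
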