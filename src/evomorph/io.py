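"""Readers and writers for trees, landmark data, labels, and hypotheses.

Flat files use the landmark-major coordinate convention (x1, y1, z1, x2, ...).
Supported dialects: Newick trees; TPS landmark files (LM=/LM3= blocks with
ID= keys); wide CSV (one specimen per row, columns x1,y1[,z1],...); group
label CSV (species,label); module hypothesis CSV (landmark,module).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GroupLabels, LandmarkDataset, ModuleHypothesis, Phylogeny

__all__ = [
    "read_tree",
    "read_landmarks",
    "write_landmarks",
    "read_group_labels",
    "write_group_labels",
    "read_module_hypothesis",
    "write_module_hypothesis",
    "prune_and_match",
]

logger = logging.getLogger("evomorph")

_TPS_KEY = re.compile(r"^(LM3?|ID|IMAGE|SCALE)\s*=\s*(.*)$", re.IGNORECASE)


def read_tree(path) -> Phylogeny:
    """Read a rooted Newick tree; every non-root branch must have a length."""
    text = Path(path).read_text()
    return Phylogeny.from_newick(text)


def _read_tps(path) -> LandmarkDataset:
    records = []
    cur_pts: list[list[float]] | None = None
    cur_k = 0
    cur_d = 0
    cur_id = None
    lineno_of_block = 0

    def flush():
        nonlocal cur_pts, cur_id
        if cur_pts is None:
            return
        if len(cur_pts) != cur_k:
            raise ValueError(
                f"TPS block starting at line {lineno_of_block} declares "
                f"{cur_k} landmarks but has {len(cur_pts)}"
                + (f" (specimen {cur_id!r})" if cur_id else "")
            )
        records.append((cur_id, np.array(cur_pts)))
        cur_pts = None
        cur_id = None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            m = _TPS_KEY.match(line)
            if m:
                key = m.group(1).upper()
                val = m.group(2).strip()
                if key in ("LM", "LM3"):
                    flush()
                    cur_k = int(val)
                    cur_d = 3 if key == "LM3" else 2
                    cur_pts = []
                    lineno_of_block = lineno
                elif key == "ID":
                    cur_id = val
                continue
            if cur_pts is None:
                raise ValueError(f"coordinate line outside LM block at line {lineno}")
            parts = line.split()
            if len(parts) != cur_d:
                raise ValueError(
                    f"line {lineno}: expected {cur_d} coordinates, got {len(parts)}"
                )
            cur_pts.append([float(x) for x in parts])
    flush()
    if not records:
        raise ValueError(f"no TPS records in {path}")
    shapes = [r[1].shape for r in records]
    if len(set(shapes)) > 1:
        bad = [r[0] or f"record {i}" for i, r in enumerate(records)]
        raise ValueError(f"ragged configurations across TPS records: {bad}")
    ids = [r[0] if r[0] is not None else f"spec{i + 1}" for i, r in enumerate(records)]
    coords = np.stack([r[1] for r in records])
    return LandmarkDataset(specimen_ids=ids, species_ids=list(ids), coords=coords)


def _read_wide_csv(path) -> LandmarkDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = [c for c in df.columns if c.lower() in ("specimen", "species")]
    spec_col = next((c for c in meta_cols if c.lower() == "specimen"), None)
    sp_col = next((c for c in meta_cols if c.lower() == "species"), None)
    num = df.drop(columns=meta_cols)
    axes = []
    for c in num.columns:
        m = re.match(r"^([xyz])(\d+)$", c.lower())
        if not m:
            raise ValueError(f"unrecognized coordinate column {c!r} (expected x1,y1,...)")
        axes.append(m.group(1))
    d = len(set(axes))
    if num.shape[1] % d != 0:
        raise ValueError(
            f"ragged wide CSV: {num.shape[1]} coordinate columns is not a "
            f"multiple of dimension {d}"
        )
    k = num.shape[1] // d
    coords = num.to_numpy(dtype=float).reshape(len(df), k, d)
    ids = df[spec_col].astype(str).tolist() if spec_col else [f"spec{i + 1}" for i in range(len(df))]
    species = df[sp_col].astype(str).tolist() if sp_col else list(ids)
    return LandmarkDataset(specimen_ids=ids, species_ids=species, coords=coords)


def read_landmarks(path, dialect: str = "auto") -> LandmarkDataset:
    """Read landmark configurations; dialect ∈ {tps, wide_csv, auto}."""
    if dialect == "auto":
        dialect = "tps" if str(path).lower().endswith(".tps") else "wide_csv"
    if dialect == "tps":
        return _read_tps(path)
    if dialect == "wide_csv":
        return _read_wide_csv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_landmarks(dataset: LandmarkDataset, path, dialect: str = "auto") -> None:
    if dialect == "auto":
        dialect = "tps" if str(path).lower().endswith(".tps") else "wide_csv"
    if dialect == "tps":
        key = "LM3" if dataset.d == 3 else "LM"
        with open(path, "w") as fh:
            for i in range(dataset.n_specimens):
                fh.write(f"{key}={dataset.k}\n")
                for pt in dataset.coords[i]:
                    fh.write(" ".join(f"{v:.12f}" for v in pt) + "\n")
                fh.write(f"ID={dataset.specimen_ids[i]}\n")
        return
    if dialect == "wide_csv":
        axes = "xyz"[: dataset.d]
        cols = [f"{a}{i + 1}" for i in range(dataset.k) for a in axes]
        df = pd.DataFrame(
            dataset.coords.reshape(dataset.n_specimens, -1), columns=cols
        )
        df.insert(0, "species", dataset.species_ids)
        df.insert(0, "specimen", dataset.specimen_ids)
        df.to_csv(path, index=False)
        return
    raise ValueError(f"unknown dialect {dialect!r}")


def read_group_labels(path) -> GroupLabels:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "species" not in cols or "label" not in cols:
        raise ValueError("group label CSV needs columns species,label")
    return GroupLabels(dict(zip(df[cols["species"]].astype(str), df[cols["label"]].astype(str))))


def write_group_labels(labels: GroupLabels, path) -> None:
    pd.DataFrame(
        {"species": list(labels.mapping), "label": list(labels.mapping.values())}
    ).to_csv(path, index=False)


def read_module_hypothesis(path, name: str | None = None) -> ModuleHypothesis:
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "landmark" not in cols or "module" not in cols:
        raise ValueError("hypothesis CSV needs columns landmark,module")
    df = df.sort_values(cols["landmark"])
    return ModuleHypothesis(
        name=name or Path(path).stem,
        assignment=df[cols["module"]].to_numpy(dtype=int),
    )


def write_module_hypothesis(hyp: ModuleHypothesis, path) -> None:
    pd.DataFrame(
        {"landmark": np.arange(1, hyp.k + 1), "module": hyp.assignment}
    ).to_csv(path, index=False)


def prune_and_match(tree: Phylogeny, shapes, labels: GroupLabels | None = None):
    """Restrict tree, species-indexed shape data, and labels to common species.

    ``shapes`` is anything with an ``ids`` list and a ``subset(ids)`` method
    (e.g. :class:`AlignedShapes`). Returns (tree, shapes, labels) agreeing
    exactly in species set and order (the pruned tree's tip order). Dropped
    species are reported to the package logger. Idempotent.
    """
    tree_set = set(tree.tip_labels)
    shape_set = set(shapes.ids)
    common = tree_set & shape_set
    if labels is not None:
        common &= set(labels.mapping)
    if not common:
        raise ValueError("no species shared between tree, shapes and labels")
    dropped = (tree_set | shape_set) - common
    if dropped:
        logger.info("prune_and_match dropped %d species: %s", len(dropped), sorted(dropped))
    new_tree = tree.prune_to(common) if common != tree_set else tree
    order = new_tree.tip_labels
    new_shapes = shapes.subset(order)
    new_labels = labels.subset(order) if labels is not None else None
    return new_tree, new_shapes, new_labels
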