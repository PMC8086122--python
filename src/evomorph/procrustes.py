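"""Generalized Procrustes superimposition and species averaging.

Full Procrustes: each configuration is translated to the origin, scaled to
unit centroid size (the original centroid size is recorded as the size
variable), and rotated — reflections disallowed — to minimize summed squared
distances to an iteratively updated consensus. After convergence the whole
set is rotated into a canonical principal-axes frame so that the output does
not depend on the arbitrary orientation of the input data.
"""

from __future__ import annotations

import numpy as np

from .datatypes import AlignedShapes, LandmarkDataset

__all__ = ["centroid_size", "gpa", "species_means"]


def centroid_size(config: np.ndarray) -> float:
    """√(Σᵢ ‖xᵢ − x̄‖²): root summed squared landmark distances to the centroid."""
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def _optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation Q (det +1) minimizing ‖A Q − B‖²_F (Kabsch)."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.ones(A.shape[1])
    D[-1] = d
    return (U * D) @ Vt


def _canonical_frame(aligned: np.ndarray, consensus: np.ndarray):
    """Rotate all configurations so the consensus lies on its principal axes.

    Axis signs are fixed by making the largest-magnitude consensus coordinate
    on each of the first d−1 axes positive; the last axis sign is then chosen
    to keep the rotation proper (no reflection).
    """
    d = consensus.shape[1]
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    Q = Vt.T  # columns: principal axes
    proj = consensus @ Q
    signs = np.ones(d)
    for j in range(d - 1):
        col = proj[:, j]
        s = np.sign(col[np.argmax(np.abs(col))])
        signs[j] = s if s != 0 else 1.0
    # last axis sign chosen to keep the frame a proper rotation
    signs[d - 1] = np.sign(np.linalg.det(Q)) * np.prod(signs[: d - 1])
    Qp = Q * signs[None, :]
    return aligned @ Qp, consensus @ Qp


def gpa(dataset: LandmarkDataset, tol: float = 1e-10, max_iter: int = 100) -> AlignedShapes:
    """Generalized Procrustes alignment of all configurations in a dataset.

    Iterates rotation-to-consensus / consensus update until the consensus
    moves by less than ``tol`` (RMS) or ``max_iter`` is reached.
    """
    coords = dataset.coords
    n, k, d = coords.shape
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    if k < 3:
        raise ValueError("GPA needs at least 3 landmarks")

    sizes = np.empty(n)
    shapes = np.empty_like(coords)
    for i in range(n):
        centered = coords[i] - coords[i].mean(axis=0)
        cs = float(np.sqrt(np.sum(centered**2)))
        if cs <= 0:
            raise ValueError(
                f"degenerate configuration (zero centroid size) for specimen "
                f"{dataset.specimen_ids[i]!r}"
            )
        sizes[i] = cs
        shapes[i] = centered / cs

    consensus = shapes[0].copy()
    for _ in range(max_iter):
        for i in range(n):
            shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
        new_consensus = shapes.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        ncs = np.sqrt(np.sum(new_consensus**2))
        if ncs > 0:
            new_consensus /= ncs
        delta = np.sqrt(np.mean((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            break

    # final pass against the converged consensus, then canonical orientation
    for i in range(n):
        shapes[i] = shapes[i] @ _optimal_rotation(shapes[i], consensus)
    shapes, _ = _canonical_frame(shapes, consensus)
    consensus = shapes.mean(axis=0)

    return AlignedShapes(
        ids=list(dataset.specimen_ids),
        coords=shapes,
        centroid_sizes=sizes,
        consensus=consensus,
        landmark_names=list(dataset.landmark_names),
    )


def species_means(aligned: AlignedShapes, species_map: dict[str, str]) -> AlignedShapes:
    """Average aligned configurations (and sizes, on the original scale) by species.

    Species appear in order of first occurrence; single-specimen species pass
    through unchanged.
    """
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, spec in enumerate(aligned.ids):
        sp = species_map.get(spec, spec)
        if sp not in groups:
            groups[sp] = []
            order.append(sp)
        groups[sp].append(i)

    coords = np.stack([aligned.coords[groups[sp]].mean(axis=0) for sp in order])
    sizes = np.array([aligned.centroid_sizes[groups[sp]].mean() for sp in order])
    return AlignedShapes(
        ids=order,
        coords=coords,
        centroid_sizes=sizes,
        consensus=coords.mean(axis=0),
        landmark_names=aligned.landmark_names,
    )
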