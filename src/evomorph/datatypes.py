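"""Core containers shared across the pipeline.

The landmark-major coordinate convention used throughout: a configuration of
``k`` landmarks in ``d`` dimensions flattens to a length ``k*d`` vector
``(x1, y1, z1, x2, y2, z2, ...)``; coordinate ``c`` of landmark ``i`` sits at
flat index ``i*d + c``.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np


class Phylogeny:
    """A rooted tree with branch lengths, wrapping a :class:`dendropy.Tree`.

    Every non-root edge must carry a non-negative branch length; tip labels
    must be unique. Polytomies are accepted as-is.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal node>"
                raise ValueError(f"branch length missing above node {name!r}")
            if node.parent_node is not None and node.edge.length < 0:
                name = node.taxon.label if node.taxon else "<internal node>"
                raise ValueError(f"negative branch length above node {name!r}")
            if node.is_leaf():
                if node.taxon is None or not node.taxon.label:
                    raise ValueError("unlabeled tip in tree")
                if node.taxon.label in seen:
                    raise ValueError(f"duplicate tip label {node.taxon.label!r}")
                seen.add(node.taxon.label)
        if not seen:
            raise ValueError("tree has no tips")

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick")
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def prune_to(self, labels) -> "Phylogeny":
        """Return a new tree retaining only the given tips (original order kept)."""
        keep = set(labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        tree = self._tree.clone(depth=1)
        taxa = [lf.taxon for lf in tree.leaf_node_iter() if lf.taxon.label in keep]
        tree.retain_taxa(taxa)
        return Phylogeny(tree)

    def tip_depths(self) -> np.ndarray:
        """Root-to-tip path lengths, in ``tip_labels`` order."""
        depths = {}
        for node in self._tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[parent] + node.edge.length
        return np.array([depths[lf] for lf in self._tree.leaf_node_iter()])


@dataclass
class LandmarkDataset:
    """Raw (unaligned) landmark configurations, one per specimen."""

    specimen_ids: list[str]
    species_ids: list[str]
    coords: np.ndarray  # n_specimens × k × d
    landmark_names: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3:
            raise ValueError("coords must be n_specimens × k × d")
        n, k, d = self.coords.shape
        if d not in (2, 3):
            raise ValueError(f"dimension d must be 2 or 3, got {d}")
        if len(self.specimen_ids) != n or len(self.species_ids) != n:
            raise ValueError("specimen/species id lists must match coords")
        if len(set(self.specimen_ids)) != n:
            dupes = sorted({s for s in self.specimen_ids if self.specimen_ids.count(s) > 1})
            raise ValueError(f"duplicate specimen ids: {dupes}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates in landmark data")
        if self.landmark_names is None:
            self.landmark_names = [f"L{i + 1}" for i in range(k)]
        elif len(self.landmark_names) != k:
            raise ValueError("landmark_names length must equal k")

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]


@dataclass
class GroupLabels:
    """Species → categorical label (e.g. echolocation mode)."""

    mapping: dict[str, str]

    def labels_for(self, species: list[str]) -> list[str]:
        missing = [s for s in species if s not in self.mapping]
        if missing:
            raise KeyError(f"species without group label: {missing}")
        return [self.mapping[s] for s in species]

    def subset(self, species) -> "GroupLabels":
        return GroupLabels({s: self.mapping[s] for s in species if s in self.mapping})

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.mapping.values()))


@dataclass
class ModuleHypothesis:
    """Assignment of each landmark to one of ``m`` contiguous module ids (1..m)."""

    name: str
    assignment: np.ndarray  # length k, integer module ids 1..m

    def __post_init__(self):
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1 or self.assignment.size == 0:
            raise ValueError("assignment must be a non-empty 1-D integer array")
        ids = np.unique(self.assignment)
        if ids[0] != 1 or not np.array_equal(ids, np.arange(1, ids.size + 1)):
            raise ValueError("module ids must be contiguous integers 1..m")

    @property
    def k(self) -> int:
        return self.assignment.size

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module_id)


@dataclass
class AlignedShapes:
    """Procrustes-aligned configurations plus centroid sizes.

    Each aligned configuration has its centroid at the origin and unit centroid
    size; ``consensus`` is the arithmetic mean of the aligned configurations.
    ``centroid_sizes`` are recorded in the original units, before scaling.
    """

    ids: list[str]
    coords: np.ndarray  # N × k × d, aligned
    centroid_sizes: np.ndarray  # N, positive
    consensus: np.ndarray  # k × d
    landmark_names: list[str] | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.centroid_sizes = np.asarray(self.centroid_sizes, dtype=float)
        if self.landmark_names is None:
            self.landmark_names = [f"L{i + 1}" for i in range(self.coords.shape[1])]

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    @property
    def d(self) -> int:
        return self.coords.shape[2]

    def flat(self) -> np.ndarray:
        """N × (k·d) matrix in landmark-major order (x1, y1, z1, x2, ...)."""
        return self.coords.reshape(self.n, self.k * self.d)

    def subset(self, ids: list[str]) -> "AlignedShapes":
        index = {s: i for i, s in enumerate(self.ids)}
        rows = [index[s] for s in ids]
        return AlignedShapes(
            ids=list(ids),
            coords=self.coords[rows],
            centroid_sizes=self.centroid_sizes[rows],
            consensus=self.coords[rows].mean(axis=0),
            landmark_names=self.landmark_names,
        )
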