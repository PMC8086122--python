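"""Synthetic phylogenies and module-structured landmark data with known truth.

The generative model mirrors what the downstream estimators assume: species
shape deviations are matrix-normal with row covariance C (the tree) and
column covariance Σ = Λ^{1/2} (Ψ ⊗ I_d) Λ^{1/2}, where Ψ is a block
landmark correlation matrix (within-module ρ_w, between ρ_b) and Λ holds
per-coordinate variances σ²_m/d so each landmark's multivariate BM rate is
exactly σ²_m. Log centroid size evolves as univariate BM on the same tree,
and an allometric component β·(logCS − mean)·cac is added along a fixed unit
direction in shape space, making β and the direction sharply identifiable.

The mean (root) configuration places each module's landmarks around a
separate center, so true modules are spatially contiguous — the situation
the geometric clustering constraint assumes, as in real anatomy.

Finally each species configuration is scaled to its centroid size and given
a random rigid motion, producing raw coordinates that exercise the
Procrustes alignment stage.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .datatypes import GroupLabels, LandmarkDataset, ModuleHypothesis, Phylogeny
from .phylo import phylo_cov

__all__ = ["SimulationConfig", "SyntheticDataset", "simulate_tree", "simulate_shapes", "assign_groups"]


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one synthetic dataset.

    Defaults describe the reference study system emulated throughout: a
    ~200-tip clade, 3D landmarks in two spatially contiguous modules with
    strong within- and weak between-module evolutionary correlation, and an
    optional allometric shape component along a single direction.
    """

    n_tips: int = 200
    birth_rate: float = 1.0
    k: int = 12
    d: int = 3
    module_sizes: tuple[int, ...] = (6, 6)
    rho_within: float = 0.7
    rho_between: float = 0.1
    sigma2_modules: tuple[float, ...] = (1.0, 1.0)
    beta: float = 0.0
    size_rate: float = 1.0  # BM rate of log centroid size
    log_size_root: float = 3.0  # root log centroid size (original units ≈ e³)
    module_spread: float = 0.35  # landmark jitter around module centers
    n_groups: int = 3
    seed: int = 0

    def __post_init__(self):
        if len(self.sigma2_modules) != len(self.module_sizes):
            raise ValueError("one σ² per module required")
        if sum(self.module_sizes) != self.k:
            raise ValueError("module sizes must sum to k")
        if not (self.rho_between < self.rho_within < 1):
            raise ValueError("require ρ_b < ρ_w < 1")
        if any(s <= 0 for s in self.sigma2_modules):
            raise ValueError("module rates must be positive")
        vals = np.linalg.eigvalsh(self.landmark_correlation())
        if vals.min() <= 1e-10:
            raise ValueError("implied landmark correlation matrix is not positive definite")

    @property
    def hypothesis(self) -> ModuleHypothesis:
        assignment = np.concatenate(
            [np.full(sz, i + 1) for i, sz in enumerate(self.module_sizes)]
        )
        return ModuleHypothesis("truth", assignment)

    def landmark_correlation(self) -> np.ndarray:
        a = self.hypothesis.assignment
        psi = np.where(a[:, None] == a[None, :], self.rho_within, self.rho_between)
        np.fill_diagonal(psi, 1.0)
        return psi

    def coordinate_covariance(self) -> np.ndarray:
        """Σ = Λ^{1/2} (Ψ ⊗ I_d) Λ^{1/2}, landmark-major order."""
        psi = self.landmark_correlation()
        sig2 = np.concatenate(
            [np.full(sz, s2) for sz, s2 in zip(self.module_sizes, self.sigma2_modules)]
        )
        lam = np.repeat(sig2 / self.d, self.d)  # per-coordinate variances
        big = np.kron(psi, np.eye(self.d))
        scale = np.sqrt(lam)
        return big * np.outer(scale, scale)


@dataclass
class SyntheticDataset:
    tree: Phylogeny
    landmarks: LandmarkDataset  # raw coordinates (rigid motion + scale applied)
    shapes: np.ndarray  # N × k × d shape-space configurations (ground truth)
    log_sizes: np.ndarray  # N, true log centroid sizes
    labels: GroupLabels
    truth: dict = field(default_factory=dict)


def simulate_tree(n_tips: int, birth_rate: float = 1.0, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree with tips relabeled s1..sN; deterministic per seed."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = random.Random(seed)
    tree = dendropy.model.birthdeath.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving two
    # zero-length tip branches; extend all tips by the waiting time to the
    # next event so the tree is observed between speciations
    extra = rng.expovariate(n_tips * birth_rate)
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"s{i + 1}"
        leaf.edge.length += extra
    return Phylogeny(tree)


def _mean_configuration(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Module centers spread apart, landmarks jittered around them; unit centroid size."""
    m = len(config.module_sizes)
    centers = rng.standard_normal((m, config.d))
    centers /= np.linalg.norm(centers, axis=1, keepdims=True)
    pts = []
    for i, sz in enumerate(config.module_sizes):
        pts.append(centers[i] + config.module_spread * rng.standard_normal((sz, config.d)))
    G = np.vstack(pts)
    G -= G.mean(axis=0)
    G /= np.sqrt(np.sum(G**2))
    return G


def _random_rotation(d: int, rng: np.random.Generator) -> np.ndarray:
    Q, _ = np.linalg.qr(rng.standard_normal((d, d)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] *= -1
    return Q


def simulate_shapes(tree: Phylogeny, config: SimulationConfig, seed: int | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset on a tree; bit-identical given (config, seed)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    C = phylo_cov(tree)
    n = C.n
    LC = C.chol
    Sigma = config.coordinate_covariance()
    LS = np.linalg.cholesky(Sigma)
    p = config.k * config.d

    G0 = _mean_configuration(config, rng)
    cac_true = rng.standard_normal(p)
    cac_true /= np.linalg.norm(cac_true)

    dev = LC @ rng.standard_normal((n, p)) @ LS.T
    log_sizes = config.log_size_root + np.sqrt(config.size_rate) * (
        LC @ rng.standard_normal(n)
    )
    flat = G0.reshape(1, p) + dev
    flat = flat + config.beta * (log_sizes - log_sizes.mean())[:, None] * cac_true[None, :]
    shapes = flat.reshape(n, config.k, config.d)

    # raw coordinates: unit-centroid-size shape → scale to CS, rigid motion
    raw = np.empty_like(shapes)
    for i in range(n):
        cfg = shapes[i] - shapes[i].mean(axis=0)
        cs = np.sqrt(np.sum(cfg**2))
        cfg = cfg / cs * np.exp(log_sizes[i])
        Q = _random_rotation(config.d, rng)
        t = rng.standard_normal(config.d) * np.exp(config.log_size_root)
        raw[i] = cfg @ Q + t

    species = C.species
    dataset = LandmarkDataset(
        specimen_ids=list(species),
        species_ids=list(species),
        coords=raw,
    )
    labels = assign_groups(tree, config.n_groups, seed=seed)
    truth = {
        "hypothesis": config.hypothesis,
        "sigma2_modules": tuple(config.sigma2_modules),
        "rho_within": config.rho_within,
        "rho_between": config.rho_between,
        "beta": config.beta,
        "cac": cac_true,
        "mean_configuration": G0,
        "seed": seed,
    }
    return SyntheticDataset(
        tree=tree,
        landmarks=dataset,
        shapes=shapes,
        log_sizes=log_sizes,
        labels=labels,
        truth=truth,
    )


def assign_groups(tree: Phylogeny, n_groups: int, seed: int = 0) -> GroupLabels:
    """Label tips by ~balanced contiguous clades in tree traversal order.

    Contiguous blocks of the leaf ordering correspond to clade-like groups
    (exactly monophyletic when block boundaries fall on clade boundaries).
    Boundaries are jittered by the seed within ±20% of the even split, so
    group sizes stay within a factor 2 of each other.
    """
    tips = tree.tip_labels
    n = len(tips)
    if n_groups < 1:
        raise ValueError("n_groups must be ≥ 1")
    if n_groups > n:
        raise ValueError("more groups than tips")
    if n_groups == 1:
        return GroupLabels({t: "g1" for t in tips})
    rng = np.random.default_rng(seed)
    base = n / n_groups
    bounds = []
    for g in range(1, n_groups):
        jitter = rng.uniform(-0.2, 0.2) * base
        bounds.append(int(round(g * base + jitter)))
    bounds = sorted(set(np.clip(bounds, 1, n - 1).tolist()))
    while len(bounds) < n_groups - 1:  # degenerate collisions at tiny n
        for cand in range(1, n):
            if cand not in bounds:
                bounds.append(cand)
                break
        bounds.sort()
    mapping = {}
    g = 0
    for i, t in enumerate(tips):
        if g < len(bounds) and i >= bounds[g]:
            g += 1
        mapping[t] = f"g{g + 1}"
    return GroupLabels(mapping)
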