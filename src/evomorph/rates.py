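"""Brownian-motion rate heterogeneity across landmarks.

The landmark-level rate matrix treats each d-dimensional landmark as one
trait: its (i, j) entry sums the GLS-centered quadratic forms
(X_D − E(X_D))ᵗ C⁻¹ (X_D − E(X_D)) over the coordinate dimensions D, divided
by N. Diagonals are per-landmark multivariate BM rates σ²; off-diagonals are
inter-landmark evolutionary covariances.

The BM log-likelihood for a candidate landmark rate matrix R uses the
Kronecker structure R ⊗ C without ever materializing the Nk×Nk covariance:
per dimension the quadratic form is tr(C⁻¹ (X_D − E) R⁻¹ (X_D − E)ᵗ) and
log|R ⊗ C| = N·log|R| + k·log|C|. Candidate models constrain the diagonal
(one shared rate, one rate per module, or all rates free) while preserving
the observed inter-landmark correlations, and are ranked by AIC with the
number of distinct diagonal values as the parameter count.

The Q-mode test compares the fastest and slowest per-module (or
per-landmark) rates to a null built by simulating constant-rate BM with the
observed inter-landmark correlation structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, helmert, solve_triangular

from .datatypes import ModuleHypothesis
from .phylo import PhyloCovariance, phylo_mean

__all__ = [
    "RateModelFit",
    "QmodeResult",
    "landmark_rate_matrix",
    "bm_loglik",
    "fit_rate_models",
    "qmode_rate_test",
]


@dataclass
class RateModelFit:
    model: str
    diagonal: np.ndarray
    loglik: float
    n_params: int
    aic: float
    delta_aic: float = np.nan


@dataclass
class QmodeResult:
    unit: str  # "module" or "landmark"
    rates: np.ndarray
    ratio: float
    null_ratios: np.ndarray
    p_value: float


def _as_nkd(shapes) -> np.ndarray:
    X = shapes.coords if hasattr(shapes, "coords") else np.asarray(shapes, dtype=float)
    if X.ndim != 3:
        raise ValueError("shapes must be N × k × d")
    return np.asarray(X, dtype=float)


def _gls_centered(X: np.ndarray, C: PhyloCovariance) -> np.ndarray:
    """Subtract the per-column GLS root state, dimension by dimension."""
    n, k, d = X.shape
    out = np.empty_like(X)
    for dim in range(d):
        a = phylo_mean(X[:, :, dim], C)
        out[:, :, dim] = X[:, :, dim] - a[None, :]
    return out


def landmark_rate_matrix(shapes, C: PhyloCovariance) -> np.ndarray:
    """k×k landmark rate/covariance matrix, divisor 1/N."""
    X = _as_nkd(shapes)
    n, k, d = X.shape
    if n != C.n:
        raise ValueError("species count mismatch with C")
    Xc = _gls_centered(X, C)
    R = np.zeros((k, k))
    for dim in range(d):
        W = C.whiten(Xc[:, :, dim])
        R += W.T @ W
    R /= n
    return (R + R.T) / 2


def _repaired_chol(R: np.ndarray, floor_rel: float = 1e-10) -> tuple[np.ndarray, float]:
    """Lower Cholesky of R with eigenvalue-floor repair; returns (L, logdet)."""
    try:
        L = cholesky(R, lower=True)
    except (np.linalg.LinAlgError, ValueError):
        vals, vecs = np.linalg.eigh(R)
        floor = floor_rel * vals.max()
        warnings.warn("rate matrix not positive definite; flooring eigenvalues")
        vals = np.clip(vals, floor, None)
        R = (vecs * vals) @ vecs.T
        L = cholesky((R + R.T) / 2, lower=True)
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def _is_centroid_free(Xc: np.ndarray, tol: float = 1e-8) -> bool:
    """True when every configuration's landmarks sum to ~zero per dimension,
    as after Procrustes translation removal."""
    norms = np.sqrt((Xc**2).sum(axis=1))  # n × d
    sums = np.abs(Xc.sum(axis=1))
    return bool(np.all(sums <= tol * np.maximum(norms, 1e-300)))


def bm_loglik(
    shapes, C: PhyloCovariance, R_landmark: np.ndarray, centered: bool | str = "auto"
) -> float:
    """Multivariate BM log-likelihood with trait covariance R ⊗ C.

    Root states are the GLS estimates from the data (identical for every
    candidate R, so they drop out of model comparisons).

    Procrustes-aligned configurations are centered (landmark coordinates sum
    to zero per dimension), which makes the centroid direction an exact null
    space of the landmark rate matrix and the full k-dimensional Gaussian
    degenerate. When ``centered`` is True (or "auto" and the data are
    detected as centroid-free), the likelihood is evaluated as the proper
    degenerate-Gaussian density on the (k−1)-dimensional centroid-free
    subspace (Helmert basis), applied identically to every candidate R so
    model comparisons remain valid. Uncentered data use the full space.
    """
    X = _as_nkd(shapes)
    n, k, d = X.shape
    R_landmark = np.asarray(R_landmark, dtype=float)
    if R_landmark.shape != (k, k):
        raise ValueError("R_landmark must be k × k")
    Xc = _gls_centered(X, C)
    if centered == "auto":
        centered = _is_centroid_free(Xc)
    if centered:
        U = helmert(k).T  # k × (k−1), orthonormal, ⟂ 1
        Xc = np.einsum("nkd,km->nmd", Xc, U)
        R_landmark = U.T @ R_landmark @ U
        k_eff = k - 1
    else:
        k_eff = k
    LR, logdet_R = _repaired_chol(R_landmark)
    logdet_C = C.logdet()
    quad = 0.0
    for dim in range(d):
        W = C.whiten(Xc[:, :, dim])  # L_C⁻¹ (X_D − E)
        V = solve_triangular(LR, W.T, lower=True)  # L_R⁻¹ (·)ᵀ
        quad += float(np.sum(V**2))
    logdet = d * (n * logdet_R + k_eff * logdet_C)
    const = d * n * k_eff * np.log(2 * np.pi)
    return -0.5 * (quad + logdet + const)


def _constrained_R(R_obs: np.ndarray, diag: np.ndarray) -> np.ndarray:
    """Rescale covariances to a candidate diagonal, preserving correlations."""
    s_obs = np.sqrt(np.diag(R_obs))
    corr = R_obs / np.outer(s_obs, s_obs)
    s_new = np.sqrt(diag)
    return corr * np.outer(s_new, s_new)


def fit_rate_models(
    shapes,
    C: PhyloCovariance,
    hyp: ModuleHypothesis | None = None,
) -> list[RateModelFit]:
    """AIC comparison of one-rate, per-module, and all-rates-free BM models.

    Candidate diagonals: (i) all entries equal to the mean observed rate;
    (ii) per-module mean rates (requires a hypothesis); (iii) the observed
    per-landmark rates. Off-diagonals are rescaled to preserve the observed
    correlations under each diagonal. AIC = −2·logL + 2·q with q = number of
    distinct diagonal values.
    """
    X = _as_nkd(shapes)
    k = X.shape[1]
    R_obs = landmark_rate_matrix(X, C)
    diag_obs = np.diag(R_obs).copy()

    candidates: list[tuple[str, np.ndarray, int]] = [
        ("one_rate", np.full(k, diag_obs.mean()), 1)
    ]
    if hyp is not None:
        if hyp.k != k:
            raise ValueError("hypothesis landmark count mismatch")
        diag_mod = np.empty(k)
        for mod in range(1, hyp.n_modules + 1):
            members = hyp.members(mod)
            diag_mod[members] = diag_obs[members].mean()
        candidates.append((f"per_module_{hyp.n_modules}", diag_mod, hyp.n_modules))
    candidates.append(("all_rates", diag_obs, k))

    fits = []
    for name, diag, q in candidates:
        Rc = _constrained_R(R_obs, diag)
        ll = bm_loglik(X, C, Rc)
        fits.append(
            RateModelFit(model=name, diagonal=diag, loglik=ll, n_params=q, aic=-2 * ll + 2 * q)
        )
    best = min(f.aic for f in fits)
    for f in fits:
        f.delta_aic = f.aic - best
    return fits


def _module_rates(R_L: np.ndarray, hyp: ModuleHypothesis | None) -> np.ndarray:
    diag = np.diag(R_L)
    if hyp is None:
        return diag.copy()
    return np.array([diag[hyp.members(mod)].mean() for mod in range(1, hyp.n_modules + 1)])


def qmode_rate_test(
    shapes,
    C: PhyloCovariance,
    hyp: ModuleHypothesis | None = None,
    n_sim: int = 999,
    seed: int | None = None,
) -> QmodeResult:
    """Simulation test of rate heterogeneity across modules (or landmarks).

    Statistic: ratio of the fastest to the slowest per-unit rate. Null draws
    simulate BM with a common rate (the grand mean of observed per-landmark
    rates) and the observed inter-landmark correlation structure, then
    recompute the statistic; p = (1 + #{ratio* ≥ ratio}) / (n_sim + 1).
    """
    X = _as_nkd(shapes)
    n, k, d = X.shape
    if hyp is not None and hyp.n_modules < 2:
        raise ValueError("Q-mode test needs at least 2 modules (or hyp=None)")
    if hyp is None and k < 2:
        raise ValueError("Q-mode test needs at least 2 landmarks")
    R_obs = landmark_rate_matrix(X, C)
    rates = _module_rates(R_obs, hyp)
    ratio = float(rates.max() / rates.min())

    # null landmark matrix: constant diagonal, observed correlations;
    # coordinate covariance kron(R0, I_d)/d gives per-landmark rate R0_ii
    R0 = _constrained_R(R_obs, np.full(k, np.diag(R_obs).mean()))
    L0, _ = _repaired_chol(R0 / d)
    LC = C.chol
    rng = np.random.default_rng(seed)
    null_ratios = np.empty(n_sim)
    for s in range(n_sim):
        Z = rng.standard_normal((n, k, d))
        # per-dimension BM draws with row cov C and landmark cov R0/d
        Xs = np.einsum("ij,jkd->ikd", LC, np.einsum("kl,jld->jkd", L0, Z))
        r_sim = _module_rates(landmark_rate_matrix(Xs, C), hyp)
        null_ratios[s] = r_sim.max() / r_sim.min()
    p = float((1 + np.sum(null_ratios >= ratio)) / (n_sim + 1))
    return QmodeResult(
        unit="module" if hyp is not None else "landmark",
        rates=rates,
        ratio=ratio,
        null_ratios=null_ratios,
        p_value=p,
    )
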