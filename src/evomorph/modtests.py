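"""Confirmatory tests of module hypotheses.

Two complementary routes:

* a covariance-ratio (CR) permutation test on the phylogenetically corrected
  coordinate covariance — CR < 1 means between-module covariation is weak
  relative to within-module covariation, i.e. modularity; significance comes
  from random reassignment of whole landmarks to modules (left tail);
* a likelihood comparison of pooled-correlation models on the congruence
  matrix (EMMLi-style): each model assigns one correlation parameter ρ per
  cell (within module, between modules, per pair, ...), scores the cell's
  coefficients under a Fisher-z normal density, and models are ranked by
  AICc and Akaike weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .congruence import CongruenceMatrix
from .datatypes import ModuleHypothesis

__all__ = ["CRResult", "EMMLiResult", "phylo_cr", "holm_bonferroni", "emmli_fit"]


@dataclass
class CRResult:
    hypothesis: str
    cr: float
    n_perm: int
    p_value: float
    adjusted_p: float | None = None


@dataclass
class EMMLiResult:
    """Model comparison table plus fitted ρ per cell for each model."""

    table: pd.DataFrame  # model, n_params, loglik, aicc, weight
    rho: dict[str, dict[str, float]]  # model → cell → fitted ρ

    @property
    def best_model(self) -> str:
        return str(self.table.sort_values("aicc").iloc[0]["model"])


def _block_square_sums(R: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """S[i,j] = ‖d×d block (i,j) of R‖²_F, and the squared diagonal of each (i,i) block."""
    p = R.shape[0]
    k = p // d
    R4 = R.reshape(k, d, k, d)
    S = np.einsum("acbd,acbd->ab", R4, R4)
    diag_sq = np.einsum("add->a", R4[np.arange(k), :, np.arange(k), :] ** 2)
    return S, diag_sq


def _cr_stat(S: np.ndarray, diag_sq: np.ndarray, assignment: np.ndarray) -> float:
    """Mean pairwise covariance ratio for a landmark→module assignment."""
    m = assignment.max()
    M = np.zeros((assignment.size, m))
    M[np.arange(assignment.size), assignment - 1] = 1.0
    B = M.T @ S @ M  # module-pair block square sums
    within = np.diag(B) - M.T @ diag_sq  # within-module, diagonals zeroed
    crs = []
    for a in range(m):
        for b in range(a + 1, m):
            denom = np.sqrt(within[a] * within[b])
            crs.append(np.sqrt(B[a, b] / denom))
    return float(np.mean(crs))


def phylo_cr(
    R: np.ndarray,
    hyp: ModuleHypothesis,
    d: int,
    n_perm: int = 999,
    seed: int | None = None,
) -> CRResult:
    """Covariance-ratio permutation test on the evolutionary rate matrix R.

    The permutation unit is the whole landmark (its d coordinates move
    together); module sizes are preserved. p = (1 + #{CR* ≤ CR}) / (n_perm+1).
    """
    if hyp.n_modules < 2:
        raise ValueError("hypothesis must have at least 2 modules")
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    counts = np.bincount(hyp.assignment)[1:]
    if counts.min() < 2:
        raise ValueError("every module needs at least 2 landmarks")
    R = np.asarray(R, dtype=float)
    if R.shape[0] != hyp.k * d:
        raise ValueError("R size does not match hypothesis landmark count")
    S, diag_sq = _block_square_sums(R, d)
    obs = _cr_stat(S, diag_sq, hyp.assignment)
    rng = np.random.default_rng(seed)
    count_le = 0
    for _ in range(n_perm):
        perm = rng.permutation(hyp.k)
        if _cr_stat(S, diag_sq, hyp.assignment[perm]) <= obs:
            count_le += 1
    p = (1 + count_le) / (n_perm + 1)
    return CRResult(hypothesis=hyp.name, cr=obs, n_perm=n_perm, p_value=p)


def holm_bonferroni(pvals) -> np.ndarray:
    """Holm step-down adjusted p-values, input order preserved."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    return multipletests(pvals, method="holm")[1]


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(r)


def _cells_for_model(
    hyp: ModuleHypothesis, variant: str
) -> dict[str, tuple[np.ndarray, np.ndarray]] | None:
    """Cell name → (rows, cols index arrays of landmark pairs) per model variant."""
    k = hyp.k
    iu, ju = np.triu_indices(k, 1)
    same = hyp.assignment[iu] == hyp.assignment[ju]
    cells: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if variant == "single_rho":
        cells["all"] = (iu, ju)
        return cells
    if variant == "within_plus_between":
        cells["within"] = (iu[same], ju[same])
        cells["between"] = (iu[~same], ju[~same])
        return cells
    if variant == "within_only":
        for mod in range(1, hyp.n_modules + 1):
            sel = same & (hyp.assignment[iu] == mod)
            cells[f"within_{mod}"] = (iu[sel], ju[sel])
        cells["between"] = (iu[~same], ju[~same])
        return cells
    if variant == "separate_between":
        for mod in range(1, hyp.n_modules + 1):
            sel = same & (hyp.assignment[iu] == mod)
            cells[f"within_{mod}"] = (iu[sel], ju[sel])
        lo = np.minimum(hyp.assignment[iu], hyp.assignment[ju])
        hi = np.maximum(hyp.assignment[iu], hyp.assignment[ju])
        for a in range(1, hyp.n_modules + 1):
            for b in range(a + 1, hyp.n_modules + 1):
                sel = (lo == a) & (hi == b)
                cells[f"between_{a}_{b}"] = (iu[sel], ju[sel])
        return cells
    raise ValueError(f"unknown variant {variant!r}")


def emmli_fit(
    cm: CongruenceMatrix,
    hyps: list[ModuleHypothesis],
    n_eff: int,
    variants: tuple[str, ...] = ("within_plus_between", "within_only", "separate_between"),
    fold_abs: bool = True,
) -> EMMLiResult:
    """Likelihood comparison of pooled-correlation module models.

    For each cell, ρ̂ maximizes the sum over the cell's unique off-diagonal
    coefficients of log N(z(r); z(ρ), 1/(n_eff−3)) — i.e. the back-transformed
    mean of z(r), floored at 0. Model log-likelihood sums over cells; AICc
    uses the number of distinct ρ cells as the parameter count and the number
    of unique coefficients as the sample size. A no-module single-ρ baseline
    is always included.
    """
    if n_eff < 4:
        raise ValueError("n_eff must be ≥ 4 for the Fisher-z likelihood")
    vals = cm.values.copy()
    if fold_abs:
        vals = np.abs(vals)
    near_one = np.isfinite(vals) & (np.abs(vals) >= 1.0)
    near_one &= ~np.eye(cm.k, dtype=bool)
    if near_one.any():
        warnings.warn("|r| = 1 coefficients clipped to 1 - 1e-6 for the z-transform")
        vals = np.where(near_one, np.sign(vals) * (1 - 1e-6), vals)

    sd = 1.0 / np.sqrt(n_eff - 3)
    n_corr = cm.k * (cm.k - 1) // 2

    def fit_model(name: str, cells) -> tuple[dict, dict[str, float]]:
        loglik = 0.0
        rhos: dict[str, float] = {}
        q = 0
        for cell, (rows, cols) in cells.items():
            r = vals[rows, cols]
            r = r[np.isfinite(r)]
            if r.size == 0:
                continue
            q += 1
            z = _fisher_z(r)
            zhat = max(z.mean(), 0.0)
            rhos[cell] = float(np.tanh(zhat))
            loglik += float(
                -0.5 * np.sum(((z - zhat) / sd) ** 2)
                - r.size * (np.log(sd) + 0.5 * np.log(2 * np.pi))
            )
        aicc = -2 * loglik + 2 * q
        if n_corr - q - 1 > 0:
            aicc += 2 * q * (q + 1) / (n_corr - q - 1)
        return {"model": name, "n_params": q, "loglik": loglik, "aicc": aicc}, rhos

    baseline_hyp = ModuleHypothesis("no_modules", np.ones(cm.k, dtype=int))
    records = []
    rho_all: dict[str, dict[str, float]] = {}
    rec, rhos = fit_model("no_modules", _cells_for_model(baseline_hyp, "single_rho"))
    records.append(rec)
    rho_all["no_modules"] = rhos
    for hyp in hyps:
        if hyp.k != cm.k:
            raise ValueError(f"hypothesis {hyp.name!r} landmark count mismatch")
        if hyp.n_modules < 2:
            continue
        for variant in variants:
            name = f"{hyp.name}:{variant}"
            rec, rhos = fit_model(name, _cells_for_model(hyp, variant))
            records.append(rec)
            rho_all[name] = rhos

    table = pd.DataFrame(records)
    delta = table["aicc"] - table["aicc"].min()
    w = np.exp(-0.5 * delta)
    table["weight"] = w / w.sum()
    return EMMLiResult(table=table, rho=rho_all)
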