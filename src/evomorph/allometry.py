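"""Evolutionary allometry: shape regressed on log centroid size.

Procrustes ANOVA uses sequential (Type I) sums of squares over the ordered
terms size → group → size×group, with significance from residual
randomization (RRPP): for each term, residuals of the reduced model are
permuted, the term's F recomputed, and p = (1 + #{F* ≥ F}) / (n_perm + 1).
The phylogenetic variant premultiplies response and design by the inverse
Cholesky factor of the tip covariance C (PGLS); with C = I it reduces
exactly to the ordinary fit.

The common allometric component (CAC) is the pooled within-group regression
vector of shape on log size, normalized to unit length; its per-species
scores summarize allometric shape, and predicted configurations at the size
extremes visualize the trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AlignedShapes, GroupLabels
from .phylo import PhyloCovariance

__all__ = [
    "AllometryFit",
    "CACResult",
    "procrustes_anova",
    "pgls_allometry",
    "homogeneity_of_slopes",
    "cac_scores",
]


@dataclass
class AllometryFit:
    anova: pd.DataFrame  # term, df, ss, r2, f, p (plus residual/total rows)
    coefficients: pd.DataFrame  # predictors × shape coordinates
    n_perm: int
    phylogenetic: bool


@dataclass
class CACResult:
    vector: np.ndarray  # unit-norm p-vector
    scores: np.ndarray  # N
    predicted_min: np.ndarray  # k × d at the smallest log size
    predicted_max: np.ndarray  # k × d at the largest log size


def _as_flat(shapes) -> np.ndarray:
    if isinstance(shapes, AlignedShapes):
        return shapes.flat()
    return np.asarray(shapes, dtype=float)


def _group_dummies(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies (first level dropped), levels sorted."""
    levels = sorted(set(labels))
    cols = []
    names = []
    for lv in levels[1:]:
        cols.append(np.array([1.0 if la == lv else 0.0 for la in labels]))
        names.append(f"group[{lv}]")
    if not cols:
        return np.empty((len(labels), 0)), []
    return np.column_stack(cols), names


def _build_terms(
    x: np.ndarray, labels: list[str] | None
) -> list[tuple[str, np.ndarray, list[str]]]:
    terms = [("log_size", x[:, None], ["log_size"])]
    if labels is not None:
        G, gnames = _group_dummies(labels)
        if G.shape[1] == 0:
            raise ValueError("group term requested but only one group present")
        counts = pd.Series(labels).value_counts()
        if counts.min() < 2:
            raise ValueError(f"groups with a single species: {list(counts[counts < 2].index)}")
        terms.append(("group", G, gnames))
        inter = x[:, None] * G
        terms.append(("size_x_group", inter, [f"log_size:{g}" for g in gnames]))
    return terms


def _sequential_anova(
    Y: np.ndarray,
    terms: list[tuple[str, np.ndarray, list[str]]],
    n_perm: int,
    rng: np.random.Generator,
    transform=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Type I decomposition with RRPP p-values.

    ``transform`` (for PGLS) maps any N×· matrix to the whitened scale; it is
    applied to the response and to every design matrix, including the
    intercept column.
    """
    n = Y.shape[0]
    intercept = np.ones((n, 1))
    designs = [intercept]
    for _, block, _ in terms:
        designs.append(np.hstack([designs[-1], block]))
    if transform is not None:
        Yt = transform(Y)
        designs_t = [transform(X) for X in designs]
    else:
        Yt = Y
        designs_t = designs

    Qs = [np.linalg.qr(X)[0] for X in designs_t]
    ranks = [X.shape[1] for X in designs_t]

    def rss(Q, Yv):
        resid = Yv - Q @ (Q.T @ Yv)
        return float(np.sum(resid**2)), resid

    rss_models = []
    resid_models = []
    for Q in Qs:
        v, r = rss(Q, Yt)
        rss_models.append(v)
        resid_models.append(r)
    # total SS about the (possibly GLS) mean
    ss_total = rss_models[0]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValueError("more model columns than observations")
    ms_res = rss_models[-1] / df_res

    rows = []
    for t, (name, block, _) in enumerate(terms, start=1):
        df_t = ranks[t] - ranks[t - 1]
        ss_t = rss_models[t - 1] - rss_models[t]
        f_t = (ss_t / df_t) / ms_res
        # RRPP: permute reduced-model residuals
        fitted_prev = Yt - resid_models[t - 1]
        count_ge = 0
        for _ in range(n_perm):
            Ystar = fitted_prev + resid_models[t - 1][rng.permutation(n)]
            r_prev, _ = rss(Qs[t - 1], Ystar)
            r_curr, _ = rss(Qs[t], Ystar)
            r_full, _ = rss(Qs[-1], Ystar)
            f_star = ((r_prev - r_curr) / df_t) / (r_full / df_res)
            if f_star >= f_t:
                count_ge += 1
        p_t = (1 + count_ge) / (n_perm + 1)
        rows.append(
            {"term": name, "df": df_t, "ss": ss_t, "r2": ss_t / ss_total, "f": f_t, "p": p_t}
        )
    rows.append(
        {
            "term": "residual",
            "df": df_res,
            "ss": rss_models[-1],
            "r2": rss_models[-1] / ss_total,
            "f": np.nan,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "total", "df": n - 1, "ss": ss_total, "r2": 1.0, "f": np.nan, "p": np.nan}
    )
    anova = pd.DataFrame(rows)

    Xfull = designs_t[-1]
    beta, *_ = np.linalg.lstsq(Xfull, Yt, rcond=None)
    pred_names = ["intercept"] + [nm for _, _, nms in terms for nm in nms]
    coef = pd.DataFrame(beta, index=pred_names)
    return anova, coef


def _check_inputs(Y, log_cs, groups):
    log_cs = np.asarray(log_cs, dtype=float)
    if np.ptp(log_cs) == 0:
        raise ValueError("log centroid size is constant")
    if Y.shape[0] != log_cs.size:
        raise ValueError("shape rows and size vector must match")
    return log_cs


def procrustes_anova(
    shapes,
    log_cs,
    groups: GroupLabels | list[str] | None = None,
    ids: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AllometryFit:
    """Non-phylogenetic Procrustes ANOVA of shape on log size (and group)."""
    Y = _as_flat(shapes)
    log_cs = _check_inputs(Y, log_cs, groups)
    labels = _resolve_labels(shapes, groups, ids)
    terms = _build_terms(log_cs, labels)
    rng = np.random.default_rng(seed)
    anova, coef = _sequential_anova(Y, terms, n_perm, rng)
    return AllometryFit(anova=anova, coefficients=coef, n_perm=n_perm, phylogenetic=False)


def pgls_allometry(
    shapes,
    log_cs,
    C: PhyloCovariance,
    groups: GroupLabels | list[str] | None = None,
    ids: list[str] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AllometryFit:
    """Phylogenetic (PGLS) Procrustes ANOVA: fit on the whitened scale."""
    Y = _as_flat(shapes)
    log_cs = _check_inputs(Y, log_cs, groups)
    labels = _resolve_labels(shapes, groups, ids)
    terms = _build_terms(log_cs, labels)
    rng = np.random.default_rng(seed)
    anova, coef = _sequential_anova(Y, terms, n_perm, rng, transform=C.whiten)
    return AllometryFit(anova=anova, coefficients=coef, n_perm=n_perm, phylogenetic=True)


def _resolve_labels(shapes, groups, ids) -> list[str] | None:
    if groups is None:
        return None
    if isinstance(groups, GroupLabels):
        if ids is None:
            if isinstance(shapes, AlignedShapes):
                ids = shapes.ids
            else:
                raise ValueError("ids required to match GroupLabels to rows")
        return groups.labels_for(ids)
    return list(groups)


def homogeneity_of_slopes(
    shapes,
    log_cs,
    groups,
    ids: list[str] | None = None,
    C: PhyloCovariance | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, int, float]:
    """Test common-slope vs unique-slopes models; returns (F, residual df, p).

    The statistic is the size×group interaction F from the sequential fit,
    with RRPP permutation of the common-slope (reduced) model residuals.
    """
    labels = _resolve_labels(shapes, groups, ids)
    if labels is None or len(set(labels)) < 2:
        raise ValueError("homogeneity of slopes needs at least 2 groups")
    fit = (
        pgls_allometry(shapes, log_cs, C, groups, ids, n_perm=n_perm, seed=seed)
        if C is not None
        else procrustes_anova(shapes, log_cs, groups, ids, n_perm=n_perm, seed=seed)
    )
    row = fit.anova[fit.anova["term"] == "size_x_group"].iloc[0]
    df_res = int(fit.anova[fit.anova["term"] == "residual"].iloc[0]["df"])
    return float(row["f"]), df_res, float(row["p"])


def cac_scores(
    shapes: AlignedShapes,
    log_cs,
    groups: GroupLabels | list[str] | None = None,
) -> CACResult:
    """Common allometric component, per-species scores, and size-extreme shapes.

    CAC = pooled within-group regression vector of centered shape on centered
    log size, unit-normalized. Scores project grand-mean-centered shape onto
    the CAC. Predicted configurations evaluate the full linear model
    (group terms at their grand-mean coding) at the observed min/max log size.
    """
    Y = shapes.flat()
    log_cs = np.asarray(log_cs, dtype=float)
    labels = _resolve_labels(shapes, groups, None)
    n = Y.shape[0]
    if labels is None:
        labels = ["all"] * n
    Yc = Y.copy()
    xc = log_cs.astype(float).copy()
    for lv in set(labels):
        idx = [i for i, la in enumerate(labels) if la == lv]
        Yc[idx] -= Y[idx].mean(axis=0)
        xc[idx] -= log_cs[idx].mean()
    denom = float(xc @ xc)
    if denom == 0:
        raise ValueError("log centroid size constant within every group")
    b = (Yc.T @ xc) / denom
    norm = np.linalg.norm(b)
    if norm == 0:
        raise ValueError("no allometric signal: zero regression vector")
    cac = b / norm
    scores = (Y - Y.mean(axis=0)) @ cac

    # full model for predicted shapes
    x = log_cs
    terms = _build_terms(x, labels if len(set(labels)) > 1 else None)
    X = np.ones((n, 1))
    for _, block, _ in terms:
        X = np.hstack([X, block])
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)

    def predict(at_x: float) -> np.ndarray:
        row = [1.0, at_x]
        if len(set(labels)) > 1:
            G, _ = _group_dummies(labels)
            gmean = G.mean(axis=0)
            row.extend(gmean)
            row.extend(at_x * gmean)
        yhat = np.asarray(row) @ beta
        return yhat.reshape(shapes.k, shapes.d)

    return CACResult(
        vector=cac,
        scores=scores,
        predicted_min=predict(float(log_cs.min())),
        predicted_max=predict(float(log_cs.max())),
    )
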