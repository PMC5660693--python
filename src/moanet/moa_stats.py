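"""Per-gene MOA ANOVA gate, BH FDR, RM-vs-NRM differential expression, and
sample-level PCA / clustering diagnostics.

The gate fits, per gene, the fixed-effects model

    Y = mu + MOA + vehicle + route + date(vehicle x route) + error

on the log2 ratio observations and tests the MOA term by extra sum of
squares. With one study date per chemical the date term can alias the MOA
term, so columns are added in the order mu, MOA, vehicle, route, date and
aliased columns are dropped greedily (sequential, MOA-first extra sum of
squares); the F denominator is the residual mean square of the full
rank-reduced model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .preprocess import _as_frame

__all__ = [
    "fit_moa_anova",
    "bh_adjust",
    "class_differential",
    "sample_pca",
    "sample_cluster",
    "AnovaResult",
]

log = logging.getLogger(__name__)


def _dummies(values, prefix: str) -> pd.DataFrame:
    """Full (non-reduced) indicator coding; rank reduction happens later."""
    return pd.get_dummies(pd.Series(values, dtype="object"), prefix=prefix, dtype=float)


def _independent_columns(X: np.ndarray, tol: float = 1e-9) -> list:
    """Greedy left-to-right selection of linearly independent columns."""
    n = X.shape[0]
    basis = np.empty((n, 0))
    keep = []
    for j in range(X.shape[1]):
        col = X[:, j]
        if basis.shape[1]:
            resid = col - basis @ (basis.T @ col)
        else:
            resid = col.copy()
        norm = np.linalg.norm(resid)
        if norm > tol * max(1.0, np.linalg.norm(col)):
            basis = np.hstack([basis, (resid / norm)[:, None]])
            keep.append(j)
    return keep


def _rss(Q: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of each column of Y after projection on Q."""
    total = (Y**2).sum(axis=0)
    proj = Q.T @ Y
    return total - (proj**2).sum(axis=0)


@dataclass
class AnovaResult:
    """Per-gene MOA F-test table plus the aliasing report of the design."""

    table: pd.DataFrame          # gene, F, p, q, significant
    df_moa: int
    df_resid: int
    dropped_columns: list        # aliased design columns removed

    def significant_genes(self) -> list:
        return list(self.table.loc[self.table["significant"], "gene"])


def fit_moa_anova(
    ratios,
    annot: pd.DataFrame,
    fdr_threshold: float = 0.01,
) -> AnovaResult:
    """Fit the MOA ANOVA to every gene and gate at BH FDR < ``fdr_threshold``.

    ``ratios`` is a :class:`~moanet.preprocess.RatioMatrix` or DataFrame of
    log2 ratios (genes x treated samples); ``annot`` must annotate every
    column with moa, vehicle, route and date. Zero-variance genes get p = 1
    (logged).
    """
    Y_df = _as_frame(ratios)
    annot = annot.loc[Y_df.columns]
    if annot["moa"].nunique() < 2:
        raise ValueError("need at least 2 MOA levels")
    for col in ("moa", "vehicle", "route", "date"):
        if annot[col].isna().any():
            raise ValueError(f"missing {col} annotation")

    n = Y_df.shape[1]
    mu = pd.DataFrame({"mu": np.ones(n)}, index=Y_df.columns)
    M = _dummies(annot["moa"].to_numpy(), "moa").set_index(Y_df.columns)
    V = _dummies(annot["vehicle"].to_numpy(), "veh").set_index(Y_df.columns)
    R = _dummies(annot["route"].to_numpy(), "route").set_index(Y_df.columns)
    vrd = (
        annot["vehicle"].astype(str)
        + ":" + annot["route"].astype(str)
        + ":" + annot["date"].astype(str)
    )
    D = _dummies(vrd.to_numpy(), "date").set_index(Y_df.columns)

    X_full_df = pd.concat([mu, M, V, R, D], axis=1)
    X_all = X_full_df.to_numpy(dtype=float)
    keep = _independent_columns(X_all)
    dropped = [c for j, c in enumerate(X_full_df.columns) if j not in keep]
    if dropped:
        log.info("aliased design columns dropped: %s", dropped)
    X_full = X_all[:, keep]

    n_mu_moa = 1 + M.shape[1]
    keep_moa = [j for j in keep if j < n_mu_moa]
    X_moa = X_all[:, keep_moa]

    rank_full = len(keep)
    rank_moa = len(keep_moa)
    df_moa = rank_moa - 1
    df_resid = n - rank_full
    if df_resid <= 0:
        raise ValueError(
            "zero residual degrees of freedom; reduce the design (fewer factor levels)"
        )
    if df_moa <= 0:
        raise ValueError("MOA term fully aliased; cannot test")

    Q1, _ = np.linalg.qr(np.ones((n, 1)))
    Q2, _ = np.linalg.qr(X_moa)
    Qf, _ = np.linalg.qr(X_full)
    Y = Y_df.to_numpy(dtype=float).T  # samples x genes
    rss1 = _rss(Q1, Y)
    rss2 = _rss(Q2, Y)
    rssf = _rss(Qf, Y)

    mse = rssf / df_resid
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.where(mse > 0, (rss1 - rss2) / df_moa / np.where(mse > 0, mse, 1.0), np.nan)
    p = np.where(np.isfinite(F), stats.f.sf(F, df_moa, df_resid), 1.0)

    zero_var = Y_df.std(axis=1).to_numpy() == 0
    if zero_var.any():
        log.warning("%d zero-variance genes reported with p = 1", int(zero_var.sum()))
        p = np.where(zero_var, 1.0, p)
        F = np.where(zero_var, np.nan, F)
    p = np.clip(p, 0.0, 1.0)

    q = bh_adjust(p)
    table = pd.DataFrame(
        {
            "gene": Y_df.index,
            "F": F,
            "p": p,
            "q": q,
            "significant": q < fdr_threshold,
        }
    ).reset_index(drop=True)
    return AnovaResult(table=table, df_moa=df_moa, df_resid=df_resid, dropped_columns=dropped)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def class_differential(
    chem_avg: pd.DataFrame,
    class_of,
    p_cut: float = 0.05,
    fc_cut: float = 1.30,
) -> pd.DataFrame:
    """Welch two-sample t-test of RM vs NRM chemical-level averages per gene.

    Fold change uses the toxicogenomics sign convention
    sign(delta) * 2^|delta|, delta = mean(RM) - mean(NRM) on the log2 scale,
    so |fold change| >= 1 by construction and negative means down in RM
    relative to NRM. Genes passing both cuts are returned sorted by
    |fold change| descending.
    """
    class_of = pd.Series(class_of)
    classes = class_of.loc[[c for c in chem_avg.columns]]
    rm_cols = chem_avg.columns[(classes == "RM").to_numpy()]
    nrm_cols = chem_avg.columns[(classes == "NRM").to_numpy()]
    if len(rm_cols) < 2 or len(nrm_cols) < 2:
        raise ValueError("each class needs at least 2 chemicals")
    rm = chem_avg[rm_cols].to_numpy()
    nrm = chem_avg[nrm_cols].to_numpy()
    t, p = stats.ttest_ind(rm, nrm, axis=1, equal_var=False)
    delta = rm.mean(axis=1) - nrm.mean(axis=1)
    fc = np.sign(delta) * 2.0 ** np.abs(delta)
    fc[delta == 0] = 1.0
    out = pd.DataFrame(
        {"gene": chem_avg.index, "p_value": p, "delta_log2": delta, "fold_change": fc}
    )
    hit = (out["p_value"] < p_cut) & (np.abs(out["fold_change"]) >= fc_cut)
    return (
        out.loc[hit]
        .sort_values("fold_change", key=np.abs, ascending=False)
        .reset_index(drop=True)
    )


def sample_pca(data):
    """PCA of samples on gene-centered data.

    Returns ``(scores, variance_fractions)``: per-sample scores for all
    components (columns PC1, PC2, ...) and each component's fraction of the
    total variance.
    """
    X = _as_frame(data)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    tot = (s**2).sum()
    frac = s**2 / tot if tot > 0 else np.zeros_like(s)
    scores = pd.DataFrame(
        (Vt * s[:, None]).T,
        index=X.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return scores, frac


def sample_cluster(data):
    """Agglomerative clustering of samples: distance 1 - Spearman, Ward.

    Returns ``(linkage_matrix, sample_labels)``. Constant samples have their
    correlations defined as 0 (logged).
    """
    X = _as_frame(data)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    C = X.corr(method="spearman").to_numpy()
    const = X.std(axis=0).to_numpy() == 0
    if const.any():
        log.warning("%d constant samples; correlations set to 0", int(const.sum()))
        C[const, :] = 0.0
        C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform((D + D.T) / 2.0, checks=False), method="ward")
    return Z, list(X.columns)
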