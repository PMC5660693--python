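"""Weighted gene co-expression network construction and module detection.

For one sample class: Pearson similarity S, soft-power adjacency
a_ij = |s_ij|^beta, the (weighted) topological overlap matrix

    w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    l_ij = sum_{u != i,j} a_iu a_uj,   k_i = sum_{u != i} a_iu,

dissimilarity d_ij = 1 - w_ij, average-linkage clustering of d, a static
dendrogram cut into modules, and module eigengenes (first principal
components). On a binary (0/1) adjacency the weighted TOM reduces exactly to
the set-cardinality form: shared neighbors over the smaller neighborhood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, fcluster
from scipy.spatial.distance import squareform

__all__ = [
    "similarity",
    "soft_adjacency",
    "tom",
    "detect_modules",
    "module_eigengene",
    "build_network",
    "NetworkModel",
    "ModuleAssignment",
    "Eigengene",
    "MODULE_COLORS",
    "module_color",
]

log = logging.getLogger(__name__)

#: standard module color sequence, assigned to modules by decreasing size;
#: label 0 ("grey") is reserved for unassigned genes.
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
]


def module_color(label: int) -> str:
    if label == 0:
        return "grey"
    if label <= len(MODULE_COLORS):
        return MODULE_COLORS[label - 1]
    return f"module{label}"


def similarity(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of gene rows across samples."""
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = list(expr.index[sd == 0][:5])
        raise ValueError(f"zero-variance genes must be removed first: {bad}")
    S = np.corrcoef(X)
    np.fill_diagonal(S, 1.0)
    return pd.DataFrame(S, index=expr.index, columns=expr.index)


def soft_adjacency(S, beta: float = 10.0):
    """Soft-power adjacency a_ij = |s_ij|^beta with unit diagonal."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    S_arr = np.asarray(_values(S), dtype=float)
    A = np.abs(S_arr) ** beta
    np.fill_diagonal(A, 1.0)
    return _like(S, A)


def tom(A):
    """Topological overlap matrix W and dissimilarity D = 1 - W.

    Disconnected convention: if the denominator vanishes (no direct link, no
    neighbors), w_ij = 0. Diagonal of W is 1.
    """
    A_arr = np.asarray(_values(A), dtype=float)
    if A_arr.shape[0] != A_arr.shape[1] or not np.allclose(A_arr, A_arr.T):
        raise ValueError("adjacency must be square and symmetric")
    if A_arr.min() < 0 or A_arr.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A0 = A_arr.copy()
    np.fill_diagonal(A0, 0.0)
    k = A0.sum(axis=1)
    L = A0 @ A0  # off-diagonal entries are exactly sum_{u != i,j} a_iu a_uj
    kmin = np.minimum.outer(k, k)
    denom = kmin + 1.0 - A0
    num = L + A0
    with np.errstate(invalid="ignore", divide="ignore"):
        W = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(W, 1.0)
    W = np.clip(W, 0.0, 1.0)
    D = 1.0 - W
    return _like(A, W), _like(A, D)


@dataclass
class ModuleAssignment:
    """Gene -> module labels; 0 marks unassigned (grey) genes.

    Nonzero labels are 1..K by decreasing module size, with the conventional
    color names attached.
    """

    labels: pd.Series
    linkage: np.ndarray
    cut_height: float
    min_module_size: int

    @property
    def colors(self) -> pd.Series:
        return self.labels.map(module_color)

    @property
    def modules(self) -> list:
        return sorted(set(self.labels) - {0})

    def genes_in(self, label: int) -> list:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict:
        return {m: int((self.labels == m).sum()) for m in self.modules}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"module_index": self.labels, "module_color": self.colors}
        ).rename_axis("gene")


def detect_modules(
    D,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
    method: str = "average",
) -> ModuleAssignment:
    """Cut the average-linkage dendrogram of a TOM dissimilarity into modules.

    The static cut height is ``cut_height_fraction`` of the way from the first
    to the last merge height, i.e. ``h_min + f * (h_max - h_min)``; branches
    below the cut that are smaller than ``min_module_size`` are left
    unassigned (label 0). With a soft power of 10, absolute TOM dissimilarity
    values crowd toward 1, so the cut is placed on the observed height range
    rather than on the absolute scale.
    """
    D_df = D if isinstance(D, pd.DataFrame) else None
    D_arr = np.asarray(_values(D), dtype=float)
    genes = list(D_df.index) if D_df is not None else list(range(D_arr.shape[0]))
    Dsym = (D_arr + D_arr.T) / 2.0
    np.fill_diagonal(Dsym, 0.0)
    Z = linkage(squareform(Dsym, checks=False), method=method)
    heights = Z[:, 2]
    h_min, h_max = float(heights.min()), float(heights.max())
    cut = h_min + cut_height_fraction * (h_max - h_min)
    raw = fcluster(Z, t=cut, criterion="distance")

    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size].index
    # order surviving branches by decreasing size, ties by first raw label
    ordered = sorted(big, key=lambda b: (-sizes[b], b))
    relabel = {b: i + 1 for i, b in enumerate(ordered)}
    labels = pd.Series([relabel.get(r, 0) for r in raw], index=genes, name="module")
    if not ordered:
        log.warning("no branch reached min_module_size=%d; all genes unassigned", min_module_size)
    return ModuleAssignment(labels=labels, linkage=Z, cut_height=cut, min_module_size=min_module_size)


@dataclass
class Eigengene:
    """First principal component of a module's standardized expression."""

    module: int
    scores: pd.Series          # per-sample eigengene values (unit-norm loading)
    variance_fraction: float
    flagged_singleton: bool = False


def module_eigengene(expr: pd.DataFrame, labels: pd.Series, module: int) -> Eigengene:
    """Module eigengene: first right singular vector of the gene-standardized
    module submatrix, sign-aligned to correlate positively with the module's
    mean expression profile."""
    genes = labels.index[labels == module]
    sub = expr.loc[genes].to_numpy(dtype=float)
    if sub.shape[0] == 0:
        raise ValueError(f"module {module} has no genes")
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - mean) / sd
    if sub.shape[0] == 1:
        scores = pd.Series(Z[0], index=expr.columns)
        log.warning("module %s has a single gene; returning its standardized profile", module)
        return Eigengene(module, scores, 1.0, flagged_singleton=True)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    v = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(v, mean_profile) < 0:
        v = -v
    varfrac = float(s[0] ** 2 / (s**2).sum())
    return Eigengene(module, pd.Series(v, index=expr.columns), varfrac)


@dataclass
class NetworkModel:
    """All stages of one class's network, from similarity to eigengenes."""

    genes: list
    similarity: pd.DataFrame
    adjacency: pd.DataFrame
    beta: float
    tom: pd.DataFrame
    dissimilarity: pd.DataFrame
    connectivity: pd.Series
    assignment: ModuleAssignment | None = None
    eigengenes: dict = field(default_factory=dict)


def build_network(
    expr: pd.DataFrame,
    beta: float = 10.0,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
    detect: bool = True,
) -> NetworkModel:
    """Run the full chain similarity -> adjacency -> TOM -> modules."""
    S = similarity(expr)
    A = soft_adjacency(S, beta)
    W, D = tom(A)
    A0 = A.to_numpy().copy()
    np.fill_diagonal(A0, 0.0)
    k = pd.Series(A0.sum(axis=1), index=expr.index, name="connectivity")
    model = NetworkModel(
        genes=list(expr.index),
        similarity=S,
        adjacency=A,
        beta=beta,
        tom=W,
        dissimilarity=D,
        connectivity=k,
    )
    if detect:
        model.assignment = detect_modules(
            D, min_module_size=min_module_size, cut_height_fraction=cut_height_fraction
        )
        for m in model.assignment.modules:
            model.eigengenes[m] = module_eigengene(expr, model.assignment.labels, m)
    return model


def _values(x):
    return x.to_numpy() if isinstance(x, pd.DataFrame) else np.asarray(x, dtype=float)


def _like(template, arr):
    if isinstance(template, pd.DataFrame):
        return pd.DataFrame(arr, index=template.index, columns=template.columns)
    return arr
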