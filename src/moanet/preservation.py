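"""Permutation-based module preservation between two sample classes.

Given modules defined in a reference class (here usually the receptor-mediated
chemicals), quantify how strongly each module's structure recurs in a test
class via a composite permutation Z statistic:

* density family (computed in the test network): mean within-module
  adjacency, variance fraction explained by the test-class module eigengene,
  and mean |gene-eigengene correlation|;
* connectivity family (reference vs test agreement): correlation of
  intramodular connectivity vectors, and correlation of the vectorized
  within-module correlation matrices.

For each statistic, Z = (observed - permutation mean) / permutation sd under
size-preserving random relabelings of genes in the test dataset (reference
modules held fixed). Z_density and Z_connectivity are the medians of their
family and Z_summary is their mean; Z_summary > 10 is read as strong
preservation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

__all__ = [
    "PermutationScheme",
    "PreservationReport",
    "observed_statistics",
    "zsummary",
    "classify_preserved",
    "reports_to_frame",
    "reports_to_json",
]

log = logging.getLogger(__name__)

DENSITY_STATS = ("mean_adjacency", "eigengene_varfrac", "mean_kme")
CONNECTIVITY_STATS = ("cor_kim", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


@dataclass
class PermutationScheme:
    """Size-preserving random relabeling of genes in the test dataset."""

    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class PreservationReport:
    """Preservation of one reference module in the test class."""

    module: object
    size: int
    observed: dict
    perm_mean: dict
    perm_sd: dict
    z: dict
    z_density: float
    z_connectivity: float
    z_summary: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return asdict(self)


def _safe_cor(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (X - mean) / sd


def _module_stats(ref_rows: np.ndarray, test_rows: np.ndarray, beta: float) -> dict:
    """The five preservation statistics for one (ref genes, test genes) pair.

    ``ref_rows``/``test_rows`` are (m x n_samples) expression blocks; pairing
    of rows across the two blocks is positional.
    """
    m = test_rows.shape[0]
    C_t = np.corrcoef(test_rows)
    C_r = np.corrcoef(ref_rows)
    A_t = np.abs(C_t) ** beta
    A_r = np.abs(C_r) ** beta
    off = ~np.eye(m, dtype=bool)

    Zt = _standardize_rows(test_rows)
    U, s, Vt = np.linalg.svd(Zt, full_matrices=False)
    eig = Vt[0]
    if np.dot(eig, Zt.mean(axis=0)) < 0:
        eig = -eig
    varfrac = float(s[0] ** 2 / (s**2).sum())
    eig_z = (eig - eig.mean()) / (eig.std() or 1.0)
    kme = np.abs(Zt @ eig_z / test_rows.shape[1])

    kim_t = np.where(off, A_t, 0.0).sum(axis=1)
    kim_r = np.where(off, A_r, 0.0).sum(axis=1)
    iu = np.triu_indices(m, k=1)

    return {
        "mean_adjacency": float(A_t[off].mean()),
        "eigengene_varfrac": varfrac,
        "mean_kme": float(kme.mean()),
        "cor_kim": _safe_cor(kim_r, kim_t),
        "cor_cor": _safe_cor(C_r[iu], C_t[iu]),
    }


def observed_statistics(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    labels: pd.Series,
    beta: float = 10.0,
) -> dict:
    """Observed preservation statistics per module (size >= 3).

    ``labels`` assigns genes to modules (0 = unassigned, skipped). Both
    expression matrices must share the gene universe.
    """
    if not ref_expr.index.equals(test_expr.index):
        raise ValueError("reference and test matrices must share the same gene index")
    out = {}
    for mod in sorted(set(labels) - {0}):
        genes = labels.index[labels == mod]
        if len(genes) < 3:
            log.warning("module %s has size %d < 3; skipped", mod, len(genes))
            continue
        out[mod] = _module_stats(
            ref_expr.loc[genes].to_numpy(dtype=float),
            test_expr.loc[genes].to_numpy(dtype=float),
            beta,
        )
    return out


def zsummary(
    ref_expr: pd.DataFrame,
    test_expr: pd.DataFrame,
    labels: pd.Series,
    scheme: PermutationScheme | None = None,
    beta: float = 10.0,
) -> list:
    """Composite permutation Z statistics for every reference module.

    Permutations relabel genes in the test dataset only: each permutation
    draws a random gene set of matching size for the test-side block while the
    reference-side block keeps the original module genes. Deterministic for a
    fixed scheme seed.
    """
    scheme = scheme or PermutationScheme()
    if not ref_expr.index.equals(test_expr.index):
        raise ValueError("reference and test matrices must share the same gene index")
    rng = np.random.default_rng(scheme.seed)
    observed = observed_statistics(ref_expr, test_expr, labels, beta=beta)

    gene_pos = {g: i for i, g in enumerate(test_expr.index)}
    ref_arr = ref_expr.to_numpy(dtype=float)
    test_arr = test_expr.to_numpy(dtype=float)
    n_genes = test_arr.shape[0]

    module_rows = {
        mod: np.array([gene_pos[g] for g in labels.index[labels == mod]])
        for mod in observed
    }
    perm_vals = {mod: {s: [] for s in ALL_STATS} for mod in observed}
    for _ in range(scheme.n_permutations):
        perm = rng.permutation(n_genes)
        for mod, rows in module_rows.items():
            stats = _module_stats(ref_arr[rows], test_arr[perm[rows]], beta)
            for s in ALL_STATS:
                perm_vals[mod][s].append(stats[s])

    reports = []
    for mod, obs in observed.items():
        pm, psd, z = {}, {}, {}
        for s in ALL_STATS:
            vals = np.asarray(perm_vals[mod][s])
            pm[s] = float(vals.mean())
            psd[s] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if psd[s] > 0:
                z[s] = float((obs[s] - pm[s]) / psd[s])
            else:
                z[s] = float("inf") if obs[s] > pm[s] else 0.0
                log.warning("module %s statistic %s has zero permutation sd", mod, s)
        z_density = float(np.median([z[s] for s in DENSITY_STATS]))
        z_connectivity = float(np.median([z[s] for s in CONNECTIVITY_STATS]))
        reports.append(
            PreservationReport(
                module=mod,
                size=int(len(module_rows[mod])),
                observed=obs,
                perm_mean=pm,
                perm_sd=psd,
                z=z,
                z_density=z_density,
                z_connectivity=z_connectivity,
                z_summary=(z_density + z_connectivity) / 2.0,
                n_permutations=scheme.n_permutations,
                seed=scheme.seed,
            )
        )
    return reports


def classify_preserved(reports: list, threshold: float = 10.0) -> list:
    """Modules with Z_summary above threshold, strongest first."""
    kept = [r for r in reports if r.z_summary > threshold]
    return sorted(kept, key=lambda r: -r.z_summary)


def reports_to_frame(reports: list) -> pd.DataFrame:
    """Tabular report: module, size, Z summary plus component columns."""
    rows = []
    for r in reports:
        row = {"module": r.module, "module_size": r.size, "z_summary": r.z_summary,
               "z_density": r.z_density, "z_connectivity": r.z_connectivity}
        row.update({f"z_{s}": r.z[s] for s in ALL_STATS})
        row.update({f"obs_{s}": r.observed[s] for s in ALL_STATS})
        rows.append(row)
    return pd.DataFrame(rows)


def reports_to_json(reports: list, path) -> None:
    with open(path, "w") as fh:
        json.dump([r.to_dict() for r in reports], fh, indent=1, default=str)
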