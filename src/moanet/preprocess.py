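"""Expression preprocessing: batch mean-centering, PCA probe-set consistency
filtering, log2 ratios to matched vehicle controls, and chemical averaging.

The pipeline assumes an already-normalized log2 expression matrix (genes or
probes x samples). Stages follow the order: mean-center per route batch,
filter probe sets by probe consistency, form log2 ratios treated-minus-matched
controls, then average replicates per chemical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "control_group_key",
    "mean_center_by_batch",
    "pvac_filter",
    "to_log_ratios",
    "average_by_chemical",
    "RatioMatrix",
    "AnnotationError",
]

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Sample annotation does not support the requested operation."""


#: vehicles carrying caloric content; everything else is non-nutritional
NUTRITIONAL_VEHICLES = frozenset({"corn_oil"})

#: routes collapsed to a single injection batch for control matching
INJECTION_ROUTES = frozenset({"injection", "intraperitoneal", "intravenous", "subcutaneous"})


def control_group_key(vehicle: str, route: str) -> str:
    """Control-matching key: nutritional status of the vehicle x route class.

    Yields the three groups of the reference design: ``nutritional-oral``,
    ``non-nutritional-oral`` and ``non-nutritional-injection``.
    """
    nutrition = "nutritional" if vehicle in NUTRITIONAL_VEHICLES else "non-nutritional"
    route_class = "injection" if route in INJECTION_ROUTES else "oral"
    return f"{nutrition}-{route_class}"


@dataclass
class RatioMatrix:
    """Log2 ratio matrix (genes x treated samples) plus the control matching
    used to form it (treated sample id -> control group key)."""

    data: pd.DataFrame
    control_matching: dict

    @property
    def genes(self):
        return self.data.index

    @property
    def samples(self):
        return self.data.columns


def _as_frame(x) -> pd.DataFrame:
    return x.data if isinstance(x, RatioMatrix) else x


def mean_center_by_batch(expr: pd.DataFrame, batch) -> pd.DataFrame:
    """Subtract, per gene, the mean over each batch's samples.

    ``batch`` maps sample id -> batch label (mapping or Series). After
    centering, every (gene, batch) mean is exactly zero; the operation is
    idempotent and order-preserving within batch.
    """
    batch = pd.Series(batch)
    missing = [s for s in expr.columns if s not in batch.index or pd.isna(batch[s])]
    if missing:
        raise AnnotationError(f"samples without batch label: {missing[:5]}")
    out = expr.copy()
    labels = batch.loc[expr.columns]
    for lab in labels.unique():
        cols = expr.columns[(labels == lab).to_numpy()]
        block = out.loc[:, cols]
        out.loc[:, cols] = block.sub(block.mean(axis=1), axis=0)
    return out


def pvac_filter(
    probe_expr: pd.DataFrame,
    probe_map,
    threshold: float = 0.5,
):
    """Probe-consistency filter: keep probe sets whose first principal
    component captures at least ``threshold`` of the probe-level variance.

    The score of a probe set is lambda_1 / sum(lambda) of the probe x probe
    covariance eigenvalues computed across samples (probes centered first, so
    constant affinity offsets do not contribute). Kept sets are summarized to
    one row as the mean across probes of the probe-centered values. Sets with
    zero total variance score 0 and are dropped with a warning.

    Returns ``(scores, filtered)``: a DataFrame with columns
    probe_set_id/score/kept, and the summarized expression matrix of kept sets
    (original probe-set order).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    probe_map = pd.Series(probe_map)
    missing = probe_expr.index.difference(probe_map.index)
    if len(missing):
        raise AnnotationError(f"probes without probe-set mapping: {list(missing[:5])}")

    sets = probe_map.loc[probe_expr.index]
    records = []
    kept_rows = {}
    for set_id in sets.unique():
        probes = probe_expr.index[(sets == set_id).to_numpy()]
        if len(probes) < 2:
            raise ValueError(f"probe set {set_id!r} has fewer than 2 probes")
        X = probe_expr.loc[probes].to_numpy()
        Xc = X - X.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(Xc, compute_uv=False)
        total = float((sv**2).sum())
        if total <= 0.0:
            log.warning("probe set %s has zero variance; score set to 0 and dropped", set_id)
            score = 0.0
        else:
            score = float(sv[0] ** 2 / total)
        kept = bool(total > 0.0 and score >= threshold)
        records.append(dict(probe_set_id=set_id, score=score, kept=kept))
        if kept:
            kept_rows[set_id] = Xc.mean(axis=0)
    scores = pd.DataFrame(records)
    filtered = pd.DataFrame(
        np.array([kept_rows[s] for s in scores.loc[scores["kept"], "probe_set_id"]])
        if kept_rows
        else np.empty((0, probe_expr.shape[1])),
        index=list(scores.loc[scores["kept"], "probe_set_id"]),
        columns=probe_expr.columns,
    )
    return scores, filtered


def to_log_ratios(expr: pd.DataFrame, annot: pd.DataFrame) -> RatioMatrix:
    """Convert log2 expression to log2 ratios against matched controls.

    Each treated sample column becomes its values minus the per-gene mean of
    the control samples in its matching group (nutritional status of the
    vehicle x route class); control columns are dropped.
    """
    annot = annot.loc[expr.columns]
    keys = {
        s: control_group_key(annot.at[s, "vehicle"], annot.at[s, "route"])
        for s in expr.columns
    }
    control_cols: dict = {}
    for s in expr.columns:
        if annot.at[s, "role"] == "control":
            control_cols.setdefault(keys[s], []).append(s)

    treated = [s for s in expr.columns if annot.at[s, "role"] == "treated"]
    matching = {}
    out = {}
    for s in treated:
        group = keys[s]
        ctl = control_cols.get(group, [])
        if not ctl:
            raise AnnotationError(
                f"treated sample {s!r} has no matched controls in group {group!r}"
            )
        out[s] = expr[s] - expr[ctl].mean(axis=1)
        matching[s] = group
    return RatioMatrix(pd.DataFrame(out, index=expr.index), matching)


def average_by_chemical(ratios, annot: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns per chemical (genes x chemicals).

    Column order follows the chemicals' order of first appearance in the
    annotation.
    """
    data = _as_frame(ratios)
    annot = annot.loc[data.columns]
    chems = list(dict.fromkeys(annot["chemical"]))
    out = {}
    for chem in chems:
        cols = data.columns[(annot["chemical"] == chem).to_numpy()]
        out[chem] = data[cols].mean(axis=1)
    return pd.DataFrame(out, index=data.index)
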