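"""Over-representation analysis of module gene lists against GMT gene sets.

One-sided hypergeometric test per (module, set) with fold enrichment defined
as observed / expected overlap and BH FDR across sets within each module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .moa_stats import bh_adjust

__all__ = ["GeneSetCollection", "ora", "read_gmt", "write_gmt"]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets as parsed from a GMT file."""

    sets: dict = field(default_factory=dict)          # set id -> list of gene ids
    descriptions: dict = field(default_factory=dict)  # set id -> free text

    def __len__(self):
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def members(self, set_id: str) -> list:
        return self.sets[set_id]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, member genes per tab-separated
    line). Duplicate members within a set are dropped with a warning."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno} has {len(fields)} fields (<3): {line[:60]!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            uniq = list(dict.fromkeys(m for m in members if m))
            if len(uniq) < len([m for m in members if m]):
                log.warning("GMT line %d (%s): duplicate members deduplicated", lineno, name)
            coll.sets[name] = uniq
            coll.descriptions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            fh.write("\t".join([name, coll.descriptions.get(name, "")] + list(members)) + "\n")


def ora(module_genes, universe, sets: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in each set.

    ``module_genes`` must be a subset of ``universe``; every set is
    intersected with the universe before testing. Returns one row per set
    with columns set_id, set_name, count, expected, fold_enrichment, p_value,
    fdr, sorted by p ascending. p is the one-sided upper tail
    P(overlap >= observed).
    """
    universe = list(dict.fromkeys(universe))
    module = set(module_genes)
    if not universe:
        raise ValueError("empty universe")
    if not module:
        raise ValueError("empty module gene list")
    uni = set(universe)
    stray = module - uni
    if stray:
        raise ValueError(f"module genes outside the universe: {sorted(stray)[:5]}")

    N = len(uni)
    n = len(module)
    rows = []
    for set_id in sets:
        members = uni.intersection(sets.members(set_id))
        K = len(members)
        k = len(module & members)
        expected = n * K / N
        fold = k / expected if expected > 0 else np.nan
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K > 0 else 1.0
        rows.append(
            dict(
                set_id=set_id,
                set_name=sets.descriptions.get(set_id, ""),
                count=k,
                expected=expected,
                fold_enrichment=fold,
                p_value=min(1.0, p),
            )
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p_value"].to_numpy())
        out = out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return out
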