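"""Plain-text input/output: TSV matrices and annotation, Newick dendrograms."""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "linkage_to_newick",
]


def read_expression(path) -> pd.DataFrame:
    """Read a genes x samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(float)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t", float_format="%.10g")


def read_annotation(path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"replicate": "Int64"})
    return annot.set_index("sample_id", drop=False)


def write_annotation(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def linkage_to_newick(Z: np.ndarray, labels) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    from skbio.tree import TreeNode

    tree = TreeNode.from_linkage_matrix(np.asarray(Z, dtype=float), list(labels))
    buf = _io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()
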