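"""Plain-text readers and writers for the formats the pipeline exchanges.

Expression travels as TSV with genes in rows and a header of sample ids;
gene roles and sample metadata as sidecar TSVs; alteration and variant
tables as TSV with MAF-like columns.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .synthetic import ExpressionMatrix

__all__ = [
    "write_expression",
    "read_expression",
    "write_table",
    "read_alteration_table",
    "read_variant_table",
]


def write_expression(expr: ExpressionMatrix, prefix) -> None:
    """Write <prefix>.expr.tsv, <prefix>.genes.tsv and <prefix>.samples.tsv."""
    prefix = Path(prefix)
    expr.values.to_csv(prefix.with_suffix(".expr.tsv"), sep="\t", index_label="gene")
    expr.gene_roles.rename("role").to_csv(
        prefix.with_suffix(".genes.tsv"), sep="\t", index_label="gene"
    )
    expr.sample_meta.to_csv(prefix.with_suffix(".samples.tsv"), sep="\t", index_label="sample")


def read_expression(expr_path, genes_path=None, samples_path=None) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    if genes_path is not None:
        roles = pd.read_csv(genes_path, sep="\t", index_col=0)["role"]
    else:
        roles = pd.Series("unknown", index=values.index, name="role")
    if samples_path is not None:
        meta = pd.read_csv(samples_path, sep="\t", index_col=0)
    else:
        meta = pd.DataFrame(
            {"latent_coordinate": float("nan"), "subtype": "unknown"},
            index=values.columns,
        )
    return ExpressionMatrix(values=values, gene_roles=roles, sample_meta=meta)


def write_table(table: pd.DataFrame, path, index: bool = True) -> None:
    table.to_csv(path, sep="\t", index=index)


def read_alteration_table(path) -> pd.DataFrame:
    alt = pd.read_csv(path, sep="\t", index_col=0)
    bad = [c for c in alt.columns if not set(alt[c].unique()) <= {0, 1}]
    if bad:
        raise ValueError(f"non-binary alteration columns: {bad}")
    return alt


def read_variant_table(path) -> pd.DataFrame:
    """MAF-like TSV with columns variant, vaf, depth, purity, cn, multiplicity."""
    tab = pd.read_csv(path, sep="\t")
    required = {"variant", "vaf", "purity", "cn", "multiplicity"}
    missing = required - set(tab.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return tab
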