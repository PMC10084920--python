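"""Two-component adeno/squamous deconvolution of bulk expression.

With exactly two reference profiles the simplex-constrained least-squares
problem min ||y - M f||^2 s.t. f >= 0, sum f = 1 is one-dimensional and has
a closed-form solution on the segment f_adeno in [0, 1]:

    f_adeno = <y - m_S, m_A - m_S> / ||m_A - m_S||^2, clipped to [0, 1].

Deconvolution is done in log2 expression space by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .scoring import EnrichmentScores, GeneSet
from .synthetic import ExpressionMatrix

__all__ = [
    "SignatureMatrix",
    "DeconvResult",
    "build_signature_matrix",
    "estimate_fractions",
    "correlate_fractions",
]


@dataclass
class SignatureMatrix:
    """Genes x 2 reference centroids (adeno, squam), log2 scale."""

    profiles: pd.DataFrame  # columns: adeno, squam

    def __post_init__(self) -> None:
        if list(self.profiles.columns) != ["adeno", "squam"]:
            raise ValueError("signature matrix must have columns [adeno, squam]")
        if self.profiles.shape[0] < 2:
            raise ValueError("signature matrix needs at least 2 genes")
        if np.allclose(self.profiles["adeno"], self.profiles["squam"]):
            raise ValueError("adeno and squam reference profiles are identical")


@dataclass
class DeconvResult:
    """Per-sample lineage fractions on the 1-simplex, plus residual norms."""

    fractions: pd.DataFrame  # columns: f_adeno, f_squam, residual

    def __post_init__(self) -> None:
        f = self.fractions
        if not np.allclose(f["f_adeno"] + f["f_squam"], 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1")


def build_signature_matrix(
    expr: ExpressionMatrix,
    labels: pd.Series | None = None,
    gene_sets: tuple[GeneSet, GeneSet] | None = None,
) -> SignatureMatrix:
    """Reference centroids from labeled samples or from gene sets.

    With ``labels`` (sample -> {adeno, squam}), each centroid is the per-gene
    mean over that lineage's reference samples. With ``gene_sets``
    (adeno set, squam set), indicator profiles are used instead.
    """
    if (labels is None) == (gene_sets is None):
        raise ValueError("provide exactly one of labels or gene_sets")
    if labels is not None:
        for lineage in ("adeno", "squam"):
            if not (labels == lineage).any():
                raise ValueError(f"no reference samples labeled {lineage!r}")
        adeno = expr.values[labels.index[labels == "adeno"]].mean(axis=1)
        squam = expr.values[labels.index[labels == "squam"]].mean(axis=1)
        prof = pd.DataFrame({"adeno": adeno, "squam": squam})
    else:
        a_set, s_set = gene_sets
        prof = pd.DataFrame(
            {
                "adeno": [1.0 if g in a_set.members else 0.0 for g in expr.genes],
                "squam": [1.0 if g in s_set.members else 0.0 for g in expr.genes],
            },
            index=expr.genes,
        )
    return SignatureMatrix(profiles=prof)


def estimate_fractions(expr: ExpressionMatrix, sig: SignatureMatrix) -> DeconvResult:
    """Exact simplex-constrained least squares, sample by sample."""
    shared = expr.genes.intersection(sig.profiles.index)
    if len(shared) < 2:
        raise ValueError("fewer than 2 genes shared between matrix and signatures")
    Y = expr.values.loc[shared].to_numpy()
    mA = sig.profiles.loc[shared, "adeno"].to_numpy()
    mS = sig.profiles.loc[shared, "squam"].to_numpy()
    diff = mA - mS
    denom = float(diff @ diff)
    f = np.clip(((Y - mS[:, None]).T @ diff) / denom, 0.0, 1.0)
    fitted = np.outer(mS, np.ones_like(f)) + np.outer(diff, f)
    resid = np.linalg.norm(Y - fitted, axis=0)
    return DeconvResult(
        fractions=pd.DataFrame(
            {"f_adeno": f, "f_squam": 1.0 - f, "residual": resid},
            index=expr.samples,
        )
    )


def correlate_fractions(
    result: DeconvResult,
    scores: EnrichmentScores,
    immune_sets: list[str],
) -> pd.DataFrame:
    """Pearson correlation of f_adeno with each immune score, BH-corrected.

    Zero-variance inputs yield NaN r (reported, excluded from the BH family).
    """
    f = result.fractions["f_adeno"]
    if len(f) < 3:
        raise ValueError("need at least 3 samples to correlate")
    rows = []
    for name in immune_sets:
        s = scores.for_set(name).reindex(f.index)
        if np.std(s.to_numpy()) == 0 or np.std(f.to_numpy()) == 0:
            rows.append({"gene_set": name, "r": np.nan, "p": np.nan})
            continue
        r, p = stats.pearsonr(f.to_numpy(), s.to_numpy())
        rows.append({"gene_set": name, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["q"] = np.nan
    valid = table["p"].notna()
    if valid.any():
        table.loc[valid, "q"] = multipletests(table.loc[valid, "p"], method="fdr_bh")[1]
    return table
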