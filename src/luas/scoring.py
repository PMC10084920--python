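"""Single-sample lineage enrichment scoring, ranking and subtype assignment.

The score is the single-sample weighted running-sum statistic (ssGSEA style):
for each sample, genes are ranked by expression and the score is the summed
difference between the weighted in-set empirical CDF (weights = ascending
rank raised to a weight exponent, so higher-expressed genes weigh more) and
the uniform out-of-set CDF. Being purely rank-based, the score is invariant
under any strictly monotone transform of a sample's expression values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .synthetic import ExpressionMatrix

__all__ = [
    "GeneSet",
    "EnrichmentScores",
    "RankedCohort",
    "read_gmt",
    "ssgsea_score",
    "score_gene_sets",
    "rank_samples",
    "assign_subtype",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: frozenset[str]
    lineage: str = "other"  # adeno | squamous | immune | other

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class EnrichmentScores:
    """Sample x gene-set score table with the method parameters used."""

    scores: pd.DataFrame  # index = samples, columns = gene set names
    method: str = "ssgsea"
    weight_exponent: float = 0.25

    def for_set(self, gs_name: str) -> pd.Series:
        if gs_name not in self.scores.columns:
            raise KeyError(
                f"gene set {gs_name!r} was not scored; have {list(self.scores.columns)}"
            )
        return self.scores[gs_name]


@dataclass
class RankedCohort:
    """Sample order along the adeno->squamous axis (ascending score)."""

    order: list[str]
    scores: pd.Series
    gs_name: str

    def __post_init__(self) -> None:
        if sorted(self.order) != sorted(self.scores.index):
            raise ValueError("ranking is not a permutation of the sample ids")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...)."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            lineage = parts[1] if parts[1] in ("adeno", "squamous", "immune") else "other"
            sets.append(
                GeneSet(name=parts[0], members=frozenset(p for p in parts[2:] if p), lineage=lineage)
            )
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.lineage, *sorted(gs.members)]) + "\n")


def _single_sample_score(
    expr: np.ndarray, gene_ids: np.ndarray, in_set: np.ndarray, tau: float
) -> float:
    """Weighted running-sum statistic for one sample.

    ``expr`` values are converted to average ranks (ascending, so the
    highest-expressed gene gets the largest rank); the walk is over genes in
    descending expression order with ties broken by gene id for determinism.
    """
    n = expr.size
    n_in = int(in_set.sum())
    if n_in == n:
        # out-of-set ECDF undefined; degenerate case pinned to 0
        return 0.0
    ranks = rankdata(expr, method="average")  # 1 = lowest expression
    # descending-expression walk order, gene id as deterministic tiebreak
    order = np.lexsort((gene_ids, -expr))
    weights = np.where(in_set, ranks**tau, 0.0)[order]
    w_total = weights.sum()
    in_sorted = in_set[order]
    p_in = np.cumsum(weights) / w_total if w_total > 0 else np.cumsum(in_sorted) / n_in
    p_out = np.cumsum(~in_sorted) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_score(
    expr: ExpressionMatrix, gs: GeneSet, weight_exponent: float = 0.25
) -> EnrichmentScores:
    """Score one gene set across all samples."""
    if weight_exponent < 0:
        raise ValueError("weight_exponent must be >= 0")
    if expr.values.shape[0] < 2:
        raise ValueError("need at least 2 genes to score")
    present = np.asarray([g in gs.members for g in expr.genes])
    if not present.any():
        raise ValueError(f"gene set {gs.name!r} shares no genes with the matrix")
    gene_ids = expr.genes.to_numpy(dtype=object)
    vals = expr.values.to_numpy()
    scores = [
        _single_sample_score(vals[:, j], gene_ids, present, weight_exponent)
        for j in range(vals.shape[1])
    ]
    return EnrichmentScores(
        scores=pd.DataFrame({gs.name: scores}, index=expr.samples),
        method="ssgsea",
        weight_exponent=weight_exponent,
    )


def score_gene_sets(
    expr: ExpressionMatrix, sets: list[GeneSet], weight_exponent: float = 0.25
) -> EnrichmentScores:
    """Score several gene sets into one table."""
    frames = [ssgsea_score(expr, gs, weight_exponent).scores for gs in sets]
    return EnrichmentScores(
        scores=pd.concat(frames, axis=1),
        method="ssgsea",
        weight_exponent=weight_exponent,
    )


def rank_samples(scores: EnrichmentScores, gs_name: str) -> RankedCohort:
    """Stable ascending sort by score; ties broken by sample id."""
    s = scores.for_set(gs_name)
    order_df = pd.DataFrame({"score": s, "sample": s.index})
    order = order_df.sort_values(["score", "sample"], kind="mergesort")["sample"]
    return RankedCohort(order=list(order), scores=s, gs_name=gs_name)


def assign_subtype(
    scores: EnrichmentScores,
    adeno_set: str,
    squam_set: str,
    immune_set: str,
    immune_threshold: float | None = None,
) -> pd.Series:
    """Score-threshold subtype assignment.

    A sample is ``inflammatory`` iff its immune score exceeds the threshold
    (default: upper tercile of the cohort immune scores); otherwise it is
    ``TRU-like`` when adeno score >= squam score, else ``basal-like``.
    """
    adeno = scores.for_set(adeno_set)
    squam = scores.for_set(squam_set)
    immune = scores.for_set(immune_set)
    if immune_threshold is None:
        immune_threshold = float(np.quantile(immune.to_numpy(), 2.0 / 3.0))
    labels = np.where(
        immune > immune_threshold,
        "inflammatory",
        np.where(adeno >= squam, "TRU-like", "basal-like"),
    )
    return pd.Series(labels, index=scores.scores.index, name="subtype")
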