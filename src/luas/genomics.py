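"""Cohort genomics: co-occurrence/exclusivity, printed-count percentages,
mutational-signature NMF, and CCF-based clonality and origin analysis.

Fisher's exact test is two-sided under the minimum-likelihood convention
(sum of all hypergeometric tables no more probable than the observed one).
Signature extraction is multiplicative-update NMF under generalized
Kullback-Leibler divergence, restarted from several random initializations.
Cancer cell fraction uses the standard purity/copy-number adjustment
CCF = VAF * (p*CN + (1-p)*2) / (p*m).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment
from statsmodels.stats.multitest import multipletests

from .synthetic import CONTEXTS_96, PairedComponents

__all__ = [
    "fisher_cooccurrence",
    "contingency_percent",
    "SignatureSet",
    "extract_signatures_nmf",
    "compute_ccf",
    "ccf_table",
    "classify_origin",
    "OriginCall",
]


# ---------------------------------------------------------------- Fisher ----

def fisher_cooccurrence(
    alt: pd.DataFrame,
    pairs: list[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise co-occurrence / mutual-exclusivity testing on a binary table.

    Returns one row per tested pair with the Haldane-corrected odds ratio
    (0.5 added to every cell when any cell is zero), the two-sided Fisher
    exact p, BH-FDR q, the relation call (co_occurrent if OR > 1 else
    exclusive) and a significance flag at q < alpha. Constant columns are
    skipped with a warning.
    """
    if alt.shape[1] < 2:
        raise ValueError("need at least 2 event columns")
    events = list(alt.columns)
    constant = [e for e in events if alt[e].nunique() <= 1]
    if constant:
        import warnings

        warnings.warn(f"skipping constant event columns: {constant}", stacklevel=2)
    usable = [e for e in events if e not in constant]
    if pairs is None:
        pairs = list(itertools.combinations(usable, 2))
    rows = []
    for a, b in pairs:
        if a in constant or b in constant:
            continue
        va, vb = alt[a].to_numpy(), alt[b].to_numpy()
        n11 = int(((va == 1) & (vb == 1)).sum())
        n10 = int(((va == 1) & (vb == 0)).sum())
        n01 = int(((va == 0) & (vb == 1)).sum())
        n00 = int(((va == 0) & (vb == 0)).sum())
        table = np.array([[n11, n10], [n01, n00]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if (table == 0).any():
            oddsr = (n11 + 0.5) * (n00 + 0.5) / ((n10 + 0.5) * (n01 + 0.5))
        else:
            oddsr = n11 * n00 / (n10 * n01)
        rows.append(
            {
                "event_a": a,
                "event_b": b,
                "n11": n11,
                "n10": n10,
                "n01": n01,
                "n00": n00,
                "odds_ratio": float(oddsr),
                "p": float(p),
                "relation": "co_occurrent" if oddsr > 1 else "exclusive",
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["q"] < alpha
    return out


def contingency_percent(fixture, numerator_key: str, denominator_key: str, decimals: int = 1) -> float:
    """100 * num / den, rounded half-away-from-zero to ``decimals``."""
    table = fixture.table
    for key in (numerator_key, denominator_key):
        if key not in table:
            raise KeyError(f"key {key!r} not in fixture {fixture.name!r}")
    den = table[denominator_key]
    if den == 0:
        raise ZeroDivisionError(f"denominator {denominator_key!r} is zero")
    pct = 100.0 * table[numerator_key] / den
    scale = 10**decimals
    return math.floor(abs(pct) * scale + 0.5) / scale * (1 if pct >= 0 else -1)


# ------------------------------------------------------------------- NMF ----

def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    return float(np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum())


def _nmf_kl(
    V: np.ndarray, k: int, max_iter: int, rng: np.random.Generator, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Multiplicative updates for generalized KL; returns (W, H, obj, trace)."""
    n, m = V.shape
    eps = 1e-12
    W = rng.uniform(0.1, 1.0, (n, k))
    H = rng.uniform(0.1, 1.0, (k, m))
    trace = []
    prev = np.inf
    for _ in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        obj = _kl_divergence(V, W @ H + eps)
        trace.append(obj)
        if prev - obj < tol * max(abs(prev), 1.0):
            break
        prev = obj
    return W, H, trace[-1], trace


@dataclass
class SignatureSet:
    """Extracted mutational signatures (k x 96) and per-sample exposures."""

    signatures: pd.DataFrame  # index = signature names, columns = contexts
    exposures: pd.DataFrame  # index = samples, columns = signature names
    objective: float
    objective_trace: list[float]
    cosine_match: pd.DataFrame | None = None  # vs reference set, if given

    def __post_init__(self) -> None:
        sig_sums = self.signatures.sum(axis=1).to_numpy()
        exp_sums = self.exposures.sum(axis=1).to_numpy()
        if not np.allclose(sig_sums, 1.0, atol=1e-9):
            raise ValueError("signature rows must sum to 1")
        if not np.allclose(exp_sums, 1.0, atol=1e-9):
            raise ValueError("exposure rows must sum to 1")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def extract_signatures_nmf(
    catalog: pd.DataFrame,
    k: int,
    n_restarts: int = 20,
    max_iter: int = 500,
    seed: int = 0,
    reference: pd.DataFrame | None = None,
) -> SignatureSet:
    """De novo signature extraction from a samples x 96 catalog.

    Best of ``n_restarts`` KL-NMF runs by final objective. Signatures are
    L1-normalized to probability vectors, exposures renormalized per sample,
    and signatures ordered by descending total exposure. If ``reference``
    (profiles x 96) is given, each extracted signature is assigned to its
    max-cosine reference by optimal one-to-one matching.
    """
    if list(catalog.columns) != list(CONTEXTS_96):
        if catalog.shape[1] != 96:
            raise ValueError("catalog must have exactly 96 context columns")
    V = catalog.to_numpy(dtype=float).T  # 96 x samples
    if k > min(catalog.shape[0], 96):
        raise ValueError(f"k={k} exceeds min(n_samples, 96)")
    if V.sum() <= 0:
        raise ValueError("catalog has no mutations")
    ss = np.random.SeedSequence(seed)
    best: tuple | None = None
    for child in ss.spawn(n_restarts):
        rng = np.random.default_rng(child)
        W, H, obj, trace = _nmf_kl(V, k, max_iter, rng)
        # multiplicative updates guarantee a monotone objective
        if any(trace[i + 1] > trace[i] + 1e-6 * max(abs(trace[i]), 1.0) for i in range(len(trace) - 1)):
            raise RuntimeError("KL objective increased during multiplicative updates")
        if best is None or obj < best[2]:
            best = (W, H, obj, trace)
    W, H, obj, trace = best

    col_sums = W.sum(axis=0)
    W = W / col_sums
    H = H * col_sums[:, None]
    exp_total = H.sum(axis=1)
    order = np.argsort(-exp_total)
    W, H = W[:, order], H[order]
    H_norm = H / np.maximum(H.sum(axis=0), 1e-300)

    names = [f"signature_{chr(ord('A') + i)}" for i in range(k)]
    signatures = pd.DataFrame(W.T, index=names, columns=list(catalog.columns))
    exposures = pd.DataFrame(H_norm.T, index=catalog.index, columns=names)

    match = None
    if reference is not None:
        cos = np.array(
            [
                [cosine_similarity(W[:, i], reference.loc[r].to_numpy()) for r in reference.index]
                for i in range(k)
            ]
        )
        ri, ci = linear_sum_assignment(-cos)
        match = pd.DataFrame(
            {
                "signature": [names[i] for i in ri],
                "reference": [reference.index[j] for j in ci],
                "cosine": [cos[i, j] for i, j in zip(ri, ci)],
            }
        )
    return SignatureSet(
        signatures=signatures,
        exposures=exposures,
        objective=obj,
        objective_trace=trace,
        cosine_match=match,
    )


# ------------------------------------------------------------------- CCF ----

def _wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """Two-sided 95% Wilson score interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("depth must be positive")
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return max(center - half, 0.0), min(center + half, 1.0)


def compute_ccf(
    vaf: float,
    purity: float,
    cn: float = 2.0,
    multiplicity: float = 1.0,
    depth: int | None = None,
    clonal_ccf: float = 0.9,
) -> dict:
    """Cancer cell fraction of one variant.

    CCF_raw = VAF * (p*CN + (1-p)*2) / (p*m); CCF = min(CCF_raw, 1) with the
    raw value retained. When ``depth`` is given, a Wilson 95% CI on the VAF
    is propagated linearly to the CCF scale; the variant is flagged clonal
    when the CI reaches the clonal region (upper bound >= ``clonal_ccf``).
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must lie in (0, 1]")
    if cn < 1:
        raise ValueError("copy number must be >= 1")
    if not 1 <= multiplicity <= cn:
        raise ValueError("multiplicity must lie in [1, CN]")
    if not 0 <= vaf <= 1:
        raise ValueError("VAF must lie in [0, 1]")
    factor = (purity * cn + (1.0 - purity) * 2.0) / (purity * multiplicity)
    raw = vaf * factor
    out = {"ccf": min(raw, 1.0), "ccf_raw": raw, "ccf_low": np.nan, "ccf_high": np.nan, "clonal": np.nan}
    if depth is not None:
        k = int(round(vaf * depth))
        lo, hi = _wilson_interval(k, depth)
        out["ccf_low"] = lo * factor
        out["ccf_high"] = hi * factor
        out["clonal"] = bool(out["ccf_high"] >= clonal_ccf)
    return out


def ccf_table(variants: pd.DataFrame, clonal_ccf: float = 0.9) -> pd.DataFrame:
    """Apply :func:`compute_ccf` to a variant table.

    Expects columns vaf, purity, cn, multiplicity and (optionally) depth.
    """
    rows = []
    has_depth = "depth" in variants.columns
    for _, v in variants.iterrows():
        rows.append(
            compute_ccf(
                vaf=float(v["vaf"]),
                purity=float(v["purity"]),
                cn=float(v["cn"]),
                multiplicity=float(v["multiplicity"]),
                depth=int(v["depth"]) if has_depth else None,
                clonal_ccf=clonal_ccf,
            )
        )
    return pd.concat([variants.reset_index(drop=True), pd.DataFrame(rows)], axis=1)


@dataclass(frozen=True)
class OriginCall:
    origin: str  # monoclonal | independent
    directionality: str  # adeno_first | squam_first | undetermined
    shared_fraction: float
    frac_clonal_s_subclonal_a: float
    frac_clonal_a_subclonal_s: float


def classify_origin(
    pc: PairedComponents,
    tau_share: float = 0.1,
    delta: float = 0.2,
    clonal_ccf: float = 0.9,
) -> OriginCall:
    """Monoclonal-vs-collision call plus lineage directionality.

    The tumor is monoclonal when the shared-variant fraction (shared/union)
    is >= ``tau_share``. Among shared variants, if the fraction that is
    clonal in the squamous component but subclonal in the adenomatous one
    exceeds the converse by ``delta``, the squamous lesion is inferred to
    arise from an adenomatous subclone (``adeno_first``); symmetrically for
    ``squam_first``; otherwise ``undetermined``.
    """
    if len(pc.adeno) == 0 or len(pc.squam) == 0:
        raise ValueError("both components must contain at least one variant")
    a = ccf_table(pc.adeno, clonal_ccf).set_index("variant")
    s = ccf_table(pc.squam, clonal_ccf).set_index("variant")
    shared = a.index.intersection(s.index)
    union = a.index.union(s.index)
    shared_frac = len(shared) / len(union)
    if shared_frac < tau_share:
        return OriginCall("independent", "undetermined", shared_frac, 0.0, 0.0)
    clon_a = a.loc[shared, "clonal"].astype(bool)
    clon_s = s.loc[shared, "clonal"].astype(bool)
    f_as = float((clon_s & ~clon_a).mean())  # clonal in S, subclonal in A
    f_sa = float((clon_a & ~clon_s).mean())
    if f_as - f_sa > delta:
        direction = "adeno_first"
    elif f_sa - f_as > delta:
        direction = "squam_first"
    else:
        direction = "undetermined"
    return OriginCall("monoclonal", direction, shared_frac, f_as, f_sa)
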