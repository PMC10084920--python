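"""Synthetic LUAS-like cohort generation.

Everything the analysis pipeline consumes can be generated here: expression
cohorts spanning a latent adeno->squamous coordinate with a planted
correlation/variance burst (the DNB structure), binary alteration tables with
planted co-occurrence or mutual exclusivity, 96-context mutation catalogs
drawn from signature mixtures, and paired adenomatous/squamous variant sets
with a shared trunk. All generators are pure functions of (config, seed).

The latent coordinate t is equally spaced on [0, 1] so that window indices in
downstream sliding-window analyses are deterministic. Adeno markers follow a
decreasing logistic profile in t, squamous markers an increasing one, immune
genes a wide Gaussian bump at the tipping position, and the DNB gene module
gets an extra shared-factor variance burst in a +/- half-window band around
the tipping position (single-factor model: corr = lambda^2 / total variance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "ExpressionMatrix",
    "PairedComponents",
    "CONTEXTS_96",
    "gen_expression_cohort",
    "gen_alteration_table",
    "gen_mutation_catalog",
    "gen_paired_components",
]

ROLES = ("adeno_marker", "squam_marker", "immune", "dnb", "background")

#: pyrimidine-centered trinucleotide contexts, lexicographic within each
#: substitution class: C>A ACA ... T>G TTT
CONTEXTS_96: tuple[str, ...] = tuple(
    f"{left}[{sub}]{right}"
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
    for left in "ACGT"
    for right in "ACGT"
)

# fixed profile shape constants (log2-expression units)
_BASE_LEVEL = 5.0
_MARKER_AMPLITUDE = 4.0
_MARKER_STEEPNESS = 10.0
_IMMUNE_AMPLITUDE = 1.5
_IMMUNE_WIDTH = 0.1
_HALF_WINDOW_SAMPLES = 5  # ties the burst band to the default sliding window


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic transition cohort."""

    n_samples: int = 93
    n_genes_per_role: dict[str, int] = field(
        default_factory=lambda: {
            "adeno_marker": 15,
            "squam_marker": 15,
            "immune": 10,
            "dnb": 25,
            "background": 100,
        }
    )
    tipping_position: float = 0.6
    noise_sd: float = 0.5
    dnb_burst_sd: float = 1.0
    dnb_burst_corr: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        unknown = set(self.n_genes_per_role) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown roles in n_genes_per_role: {sorted(unknown)}")
        for role in ("adeno_marker", "squam_marker", "dnb"):
            if self.n_genes_per_role.get(role, 0) < 1:
                raise ValueError(f"n_genes_per_role[{role!r}] must be >= 1")
        if any(v < 0 for v in self.n_genes_per_role.values()):
            raise ValueError("gene counts must be nonnegative")
        if not 0.0 < self.tipping_position < 1.0:
            raise ValueError("tipping_position must lie in (0, 1)")
        if self.noise_sd < 0 or self.dnb_burst_sd < 0:
            raise ValueError("noise parameters must be nonnegative")
        if not 0.0 <= self.dnb_burst_corr < 1.0:
            raise ValueError("dnb_burst_corr must lie in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)


@dataclass
class ExpressionMatrix:
    """Genes x samples log2 expression with per-sample metadata.

    ``values``: DataFrame indexed by gene id, columns = sample ids.
    ``gene_roles``: Series mapping gene id -> role.
    ``sample_meta``: DataFrame indexed by sample id with columns
    ``latent_coordinate`` (t in [0,1], NaN for real data) and ``subtype``.
    """

    values: pd.DataFrame
    gene_roles: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene ids must be unique")
        if self.values.columns.duplicated().any():
            raise ValueError("sample ids must be unique")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not self.sample_meta.index.equals(self.values.columns):
            raise ValueError("sample metadata does not match sample ids")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def genes_with_role(self, role: str) -> list[str]:
        return list(self.gene_roles.index[self.gene_roles == role])


def _role_means(role: str, t: np.ndarray, tipping: float) -> np.ndarray:
    """Noise-free mean profile of one gene of the given role along t."""
    if role == "adeno_marker":
        return _BASE_LEVEL + _MARKER_AMPLITUDE / (
            1.0 + np.exp(_MARKER_STEEPNESS * (t - 0.5))
        )
    if role == "squam_marker":
        return _BASE_LEVEL + _MARKER_AMPLITUDE / (
            1.0 + np.exp(-_MARKER_STEEPNESS * (t - 0.5))
        )
    if role == "immune":
        return _BASE_LEVEL + _IMMUNE_AMPLITUDE * np.exp(
            -((t - tipping) ** 2) / (2.0 * _IMMUNE_WIDTH**2)
        )
    # dnb and background genes are flat on average
    return np.full_like(t, _BASE_LEVEL)


def burst_half_width(n_samples: int) -> float:
    """Half-width (in t units) of the planted DNB burst band."""
    return _HALF_WINDOW_SAMPLES / max(n_samples - 1, 1)


def gen_expression_cohort(config: CohortConfig) -> ExpressionMatrix:
    """Generate a synthetic transition cohort.

    Samples sit at equally spaced latent coordinates t in [0, 1]. DNB genes
    receive, inside |t - tipping| <= half-window, a shared latent factor that
    inflates their SD by ``dnb_burst_sd`` (in quadrature with ``noise_sd``)
    and sets their pairwise correlation to ``dnb_burst_corr``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.linspace(0.0, 1.0, n) if n > 1 else np.array([0.5])
    tip = config.tipping_position
    w = burst_half_width(n)

    gene_ids: list[str] = []
    roles: list[str] = []
    rows: list[np.ndarray] = []

    burst = np.abs(t - tip) <= w
    total_burst_var = config.noise_sd**2 + config.dnb_burst_sd**2
    lam2 = config.dnb_burst_corr * total_burst_var
    lam = np.sqrt(lam2)
    # residual per-gene burst noise; clamp if the target correlation cannot
    # be reached on top of the baseline noise
    extra_var = max(config.dnb_burst_sd**2 - lam2, 0.0)
    # two-state (+/-1) unit-variance factor: near the tipping point each
    # sample sits in one of two transient regimes. Constant magnitude keeps
    # the burst correlation signal localized — a heavy-tailed factor draw
    # would dominate the correlation estimates of partially overlapping
    # windows and delocalize the composite-index peak
    shared_factor = rng.choice(np.array([-1.0, 1.0]), n)

    prefix = {
        "adeno_marker": "ADENO",
        "squam_marker": "SQUAM",
        "immune": "IMMUNE",
        "dnb": "DNB",
        "background": "BG",
    }
    for role in ROLES:
        count = config.n_genes_per_role.get(role, 0)
        mean = _role_means(role, t, tip)
        for g in range(count):
            x = mean + config.noise_sd * rng.standard_normal(n)
            if role == "dnb":
                x = x + np.where(burst, lam * shared_factor, 0.0)
                if extra_var > 0:
                    x = x + np.where(
                        burst, np.sqrt(extra_var) * rng.standard_normal(n), 0.0
                    )
            gene_ids.append(f"{prefix[role]}_{g:03d}")
            roles.append(role)
            rows.append(x)

    sample_ids = [f"S{i:03d}" for i in range(n)]
    values = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=sample_ids)

    subtype = np.where(
        np.abs(t - tip) <= w, "inflammatory", np.where(t < tip, "TRU-like", "basal-like")
    )
    meta = pd.DataFrame(
        {"latent_coordinate": t, "subtype": subtype}, index=pd.Index(sample_ids)
    )
    return ExpressionMatrix(
        values=values,
        gene_roles=pd.Series(roles, index=pd.Index(gene_ids), name="role"),
        sample_meta=meta,
    )


def gen_alteration_table(
    n_samples: int,
    planted_pairs: list[tuple[str, str, str, float]],
    base_rates: dict[str, float],
    seed: int = 0,
) -> pd.DataFrame:
    """Binary sample x gene alteration table with planted pair structure.

    ``planted_pairs`` entries are (geneA, geneB, relation, strength) with
    relation in {"co_occurrent", "exclusive"} and strength in [0, 1].
    Exclusive pairs: events drawn independently, then a double-positive sample
    is resolved to a single event with probability ``strength``. Co-occurrent
    pairs: both genes share a latent Bernoulli driver of rate
    strength * min(rates); marginal rates are preserved.
    """
    for g, r in base_rates.items():
        if not 0.0 <= r < 1.0:
            raise ValueError(f"base rate for {g!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    genes = list(base_rates)
    data = {
        g: (rng.random(n_samples) < base_rates[g]).astype(int) for g in genes
    }

    for a, b, relation, strength in planted_pairs:
        if a not in base_rates or b not in base_rates:
            raise ValueError(f"planted pair ({a}, {b}) missing from base_rates")
        if not 0.0 <= strength <= 1.0:
            raise ValueError("pair strength must be in [0, 1]")
        if relation == "exclusive":
            both = (data[a] == 1) & (data[b] == 1)
            resolve = both & (rng.random(n_samples) < strength)
            drop_a = rng.random(n_samples) < 0.5
            data[a] = np.where(resolve & drop_a, 0, data[a])
            data[b] = np.where(resolve & ~drop_a, 0, data[b])
        elif relation == "co_occurrent":
            ra, rb = base_rates[a], base_rates[b]
            p_shared = strength * min(ra, rb)
            z = rng.random(n_samples) < p_shared
            # top-up rates keep the marginals at ra, rb
            top_a = (ra - p_shared) / (1.0 - p_shared) if p_shared < 1 else 0.0
            top_b = (rb - p_shared) / (1.0 - p_shared) if p_shared < 1 else 0.0
            data[a] = (z | (rng.random(n_samples) < top_a)).astype(int)
            data[b] = (z | (rng.random(n_samples) < top_b)).astype(int)
        else:
            raise ValueError(f"unknown pair relation {relation!r}")

    return pd.DataFrame(
        data, index=pd.Index([f"S{i:03d}" for i in range(n_samples)])
    )


def gen_mutation_catalog(
    signature_profiles: np.ndarray | pd.DataFrame,
    exposures: np.ndarray | pd.DataFrame,
    n_mut_per_sample: int | np.ndarray,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw per-sample 96-context mutation counts from a signature mixture.

    Each row of ``signature_profiles`` (k x 96) and of ``exposures``
    (samples x k) must sum to 1.
    """
    P = np.asarray(signature_profiles, dtype=float)
    E = np.asarray(exposures, dtype=float)
    if P.ndim != 2 or P.shape[1] != 96:
        raise ValueError("signature_profiles must be k x 96")
    if not np.allclose(P.sum(axis=1), 1.0, atol=1e-8) or (P < 0).any():
        raise ValueError("each signature profile must be a probability vector")
    if E.ndim != 2 or E.shape[1] != P.shape[0]:
        raise ValueError("exposures must be samples x k")
    if not np.allclose(E.sum(axis=1), 1.0, atol=1e-8) or (E < 0).any():
        raise ValueError("each exposure row must sum to 1")
    n_samples = E.shape[0]
    n_mut = np.broadcast_to(np.asarray(n_mut_per_sample, dtype=int), (n_samples,))
    rng = np.random.default_rng(seed)
    mixture = E @ P  # samples x 96
    mixture = mixture / mixture.sum(axis=1, keepdims=True)
    counts = np.vstack(
        [rng.multinomial(int(n_mut[i]), mixture[i]) for i in range(n_samples)]
    )
    return pd.DataFrame(
        counts,
        index=pd.Index([f"S{i:03d}" for i in range(n_samples)]),
        columns=list(CONTEXTS_96),
    )


def expected_vaf(ccf: float, purity: float, cn: float, multiplicity: float) -> float:
    """VAF implied by CCF under the standard purity/copy-number model."""
    return multiplicity * ccf * purity / (purity * cn + (1.0 - purity) * 2.0)


@dataclass
class PairedComponents:
    """Matched adenomatous and squamous variant tables from one tumor.

    Each table has columns: variant, vaf, depth, purity, cn, multiplicity,
    true_ccf. In monoclonal mode the trunk is shared between components and
    is clonal in the squamous component (CCF = 1) but subclonal in the
    adenomatous component (CCF drawn < 1).
    """

    adeno: pd.DataFrame
    squam: pd.DataFrame
    mode: Literal["monoclonal", "collision"]

    @property
    def shared_variants(self) -> set[str]:
        return set(self.adeno["variant"]) & set(self.squam["variant"])


def _component_table(
    rng: np.random.Generator,
    variants: list[str],
    ccf: np.ndarray,
    purity: float,
    depth: int,
) -> pd.DataFrame:
    cn, mult = 2.0, 1.0
    vaf_true = np.array([expected_vaf(c, purity, cn, mult) for c in ccf])
    if depth <= 0:
        raise ValueError("depth must be positive")
    alt = rng.binomial(depth, vaf_true)
    return pd.DataFrame(
        {
            "variant": variants,
            "vaf": alt / depth,
            "depth": depth,
            "purity": purity,
            "cn": cn,
            "multiplicity": mult,
            "true_ccf": ccf,
        }
    )


def gen_paired_components(
    n_trunk: int = 100,
    n_private_A: int = 40,
    n_private_S: int = 40,
    purity_A: float = 0.9,
    purity_S: float = 0.9,
    mode: Literal["monoclonal", "collision"] = "monoclonal",
    depth: int = 100,
    seed: int = 0,
) -> PairedComponents:
    """Simulate paired adenomatous/squamous variant sets.

    Monoclonal mode plants ``n_trunk`` shared variants, clonal in the
    squamous component and subclonal (CCF ~ U(0.3, 0.7)) in the adenomatous
    one, mimicking squamous lesions arising from an adenomatous subclone.
    Collision mode emits disjoint variant sets. Read counts are binomial at
    the given depth with CN=2, multiplicity=1.
    """
    if min(n_trunk, n_private_A, n_private_S) < 0:
        raise ValueError("variant counts must be nonnegative")
    if not (0 < purity_A <= 1 and 0 < purity_S <= 1):
        raise ValueError("purities must lie in (0, 1]")
    if mode not in ("monoclonal", "collision"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "monoclonal" and n_trunk == 0:
        warnings.warn(
            "monoclonal mode with n_trunk=0 is degenerate: indistinguishable "
            "from a collision of independent tumors",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)

    trunk_ids = [f"trunk_{i:04d}" for i in range(n_trunk)]
    priv_a_ids = [f"privA_{i:04d}" for i in range(n_private_A)]
    priv_s_ids = [f"privS_{i:04d}" for i in range(n_private_S)]

    priv_a_ccf = rng.uniform(0.2, 1.0, n_private_A)
    priv_s_ccf = rng.uniform(0.2, 1.0, n_private_S)
    if mode == "monoclonal":
        trunk_ccf_a = rng.uniform(0.3, 0.7, n_trunk)
        trunk_ccf_s = np.ones(n_trunk)
        adeno = _component_table(
            rng,
            trunk_ids + priv_a_ids,
            np.concatenate([trunk_ccf_a, priv_a_ccf]),
            purity_A,
            depth,
        )
        squam = _component_table(
            rng,
            trunk_ids + priv_s_ids,
            np.concatenate([trunk_ccf_s, priv_s_ccf]),
            purity_S,
            depth,
        )
    else:
        extra_a = [f"collA_{i:04d}" for i in range(n_trunk)]
        extra_s = [f"collS_{i:04d}" for i in range(n_trunk)]
        adeno = _component_table(
            rng,
            extra_a + priv_a_ids,
            np.concatenate([rng.uniform(0.5, 1.0, n_trunk), priv_a_ccf]),
            purity_A,
            depth,
        )
        squam = _component_table(
            rng,
            extra_s + priv_s_ids,
            np.concatenate([rng.uniform(0.5, 1.0, n_trunk), priv_s_ccf]),
            purity_S,
            depth,
        )
    return PairedComponents(adeno=adeno, squam=squam, mode=mode)
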