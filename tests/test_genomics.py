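"""Fisher exact oracle equality, percentages, NMF recovery, CCF and origin."""

import numpy as np
import pandas as pd
import pytest

from luas import genomics
from luas.fixtures import load_fixture
from luas.genomics import (
    classify_origin,
    compute_ccf,
    contingency_percent,
    extract_signatures_nmf,
    fisher_cooccurrence,
)
from luas.synthetic import CONTEXTS_96, gen_mutation_catalog, gen_paired_components

from tests.oracles import fisher_exact_enumeration


class TestFisher:
    def test_diagonal_table_exact_value(self):
        """[[5,0],[0,5]]: p = 2/252, Haldane OR = 121."""
        alt = pd.DataFrame({"A": [1] * 5 + [0] * 5, "B": [1] * 5 + [0] * 5})
        out = fisher_cooccurrence(alt, pairs=[("A", "B")])
        assert out["p"].iloc[0] == pytest.approx(2 / 252)
        assert out["odds_ratio"].iloc[0] == pytest.approx(121.0)
        assert out["relation"].iloc[0] == "co_occurrent"

    def test_matches_enumeration_oracle_on_all_small_tables(self):
        """Exact equality with hypergeometric enumeration for all margins
        with n <= 30 (subsampled deterministically for speed)."""
        rng = np.random.default_rng(0)
        checked = 0
        for n in range(4, 31, 2):
            for _ in range(20):
                n11, n10, n01 = rng.multinomial(n, [0.25, 0.25, 0.25])[:3]
                n00 = n - n11 - n10 - n01
                if n00 < 0:
                    continue
                col = np.array(
                    [1] * (n11 + n10) + [0] * (n01 + n00)
                )
                colb = np.array(
                    [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
                )
                alt = pd.DataFrame({"A": col, "B": colb})
                if alt["A"].nunique() < 2 or alt["B"].nunique() < 2:
                    continue
                out = fisher_cooccurrence(alt, pairs=[("A", "B")])
                oracle = fisher_exact_enumeration(n11, n10, n01, n00)
                assert out["p"].iloc[0] == pytest.approx(oracle, rel=1e-9)
                checked += 1
        assert checked > 100

    def test_null_calibration(self):
        """Independent events: about 5% of pairs reach p < 0.05 (the exact
        test is conservative, so the observed rate sits at or below 5%)."""
        rng = np.random.default_rng(3)
        from scipy.stats import fisher_exact

        hits = 0
        n_pairs = 1000
        for _ in range(n_pairs):
            a = rng.random(500) < 0.5
            b = rng.random(500) < 0.5
            table = [
                [int((a & b).sum()), int((a & ~b).sum())],
                [int((~a & b).sum()), int((~a & ~b).sum())],
            ]
            hits += fisher_exact(table)[1] < 0.05
        assert 0.02 <= hits / n_pairs <= 0.065

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(1)
        alt = pd.DataFrame(
            (rng.random((60, 6)) < 0.4).astype(int), columns=list("ABCDEF")
        )
        out = fisher_cooccurrence(alt).sort_values("p")
        assert (out["q"].diff().dropna() >= -1e-12).all()
        assert (out["q"] <= 1).all()

    def test_constant_column_skipped_with_warning(self):
        alt = pd.DataFrame({"A": [1, 0, 1, 0], "B": [1, 1, 1, 1], "C": [0, 1, 1, 0]})
        with pytest.warns(UserWarning, match="constant"):
            out = fisher_cooccurrence(alt)
        assert set(out["event_a"]) | set(out["event_b"]) == {"A", "C"}


class TestContingencyPercent:
    @pytest.mark.parametrize(
        "fixture,num,den,decimals,expected",
        [
            ("nsclc_collection", "LUAS", "NSCLC", 1, 2.1),
            ("egfr_alleles", "L858R", "EGFR_mutant", 0, 50),
            ("egfr_alleles", "ex19del", "EGFR_mutant", 0, 25),
            ("erbb2_alleles", "ex20ins", "ERBB2_mutant", 0, 57),
            ("cohort_stage", "stage_I", "total", 1, 50.5),
            ("smoking", "non_smoker", "total", 1, 46.8),
            ("alk_fusion", "ALK_fusion", "rnaseq_samples", 0, 8),
            ("alk_in_C1", "in_C1", "ALK_fusion", 1, 83.3),
            ("eml4_alk_mouse", "AST_positive", "mice", 0, 75),
        ],
    )
    def test_printed_ratios(self, fixture, num, den, decimals, expected):
        assert contingency_percent(load_fixture(fixture), num, den, decimals) == expected

    def test_zero_numerator(self):
        fx = load_fixture("cohort_stage")
        assert contingency_percent(fx, "stage_IV", "total", 1) == 0.9

    def test_missing_key_and_zero_denominator(self):
        fx = load_fixture("cohort_stage")
        with pytest.raises(KeyError):
            contingency_percent(fx, "nope", "total")


class TestSignatureNmf:
    def test_rank_one_point_mass_recovered(self):
        prof = np.zeros((1, 96))
        prof[0, 13] = 1.0
        cat = gen_mutation_catalog(prof, np.ones((10, 1)), 200, seed=0)
        ref = pd.DataFrame(prof, index=["truth"], columns=list(CONTEXTS_96))
        res = extract_signatures_nmf(cat, k=1, n_restarts=3, seed=0, reference=ref)
        assert res.cosine_match["cosine"].iloc[0] >= 0.999

    def test_two_planted_signatures_recovered(self):
        """Two separated signatures, 50 samples x 2000 mutations: cosine
        >= 0.95 for both across 5 extraction seeds."""
        rng = np.random.default_rng(0)
        prof = np.zeros((2, 96))
        prof[0, :48] = rng.dirichlet(np.ones(48))
        prof[1, 48:] = rng.dirichlet(np.ones(48))
        expo = rng.dirichlet([2, 2], size=50)
        cat = gen_mutation_catalog(prof, expo, 2000, seed=1)
        ref = pd.DataFrame(prof, index=["p0", "p1"], columns=list(CONTEXTS_96))
        for seed in range(5):
            res = extract_signatures_nmf(cat, k=2, n_restarts=5, seed=seed, reference=ref)
            assert (res.cosine_match["cosine"] >= 0.95).all()

    def test_objective_trace_monotone(self):
        rng = np.random.default_rng(2)
        cat = pd.DataFrame(
            rng.poisson(5, size=(20, 96)), columns=list(CONTEXTS_96)
        )
        res = extract_signatures_nmf(cat, k=3, n_restarts=2, seed=0)
        trace = np.array(res.objective_trace)
        assert (np.diff(trace) <= 1e-6 * np.maximum(np.abs(trace[:-1]), 1)).all()

    def test_agrees_with_sklearn_kl_nmf(self):
        """Independent cross-check: sklearn's MU solver reaches a similar KL
        objective and similar signatures on the same catalog."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(4)
        prof = np.vstack([rng.dirichlet(np.ones(96)), rng.dirichlet(np.ones(96))])
        cat = gen_mutation_catalog(prof, rng.dirichlet([1, 1], 40), 1000, seed=2)
        res = extract_signatures_nmf(cat, k=2, n_restarts=5, seed=0)
        model = sklearn.NMF(
            n_components=2, solver="mu", beta_loss="kullback-leibler",
            init="random", random_state=0, max_iter=600,
        )
        W = model.fit_transform(cat.to_numpy().T.astype(float))
        W = W / W.sum(axis=0)
        best = [
            max(
                genomics.cosine_similarity(
                    res.signatures.iloc[i].to_numpy(), W[:, j]
                )
                for j in range(2)
            )
            for i in range(2)
        ]
        assert min(best) >= 0.95

    def test_k_too_large_rejected(self):
        cat = pd.DataFrame(np.ones((3, 96)), columns=list(CONTEXTS_96))
        with pytest.raises(ValueError, match="k="):
            extract_signatures_nmf(cat, k=5)


class TestCcf:
    @pytest.mark.parametrize(
        "vaf,p,cn,m,expected",
        [
            (0.25, 0.5, 2, 1, 1.0),
            (0.5, 1.0, 2, 1, 1.0),
            (0.1, 0.4, 3, 1, 0.6),
        ],
    )
    def test_closed_form_cases(self, vaf, p, cn, m, expected):
        assert compute_ccf(vaf, p, cn, m)["ccf_raw"] == pytest.approx(expected)

    def test_reduces_to_twice_vaf_in_pure_diploid(self):
        for vaf in (0.1, 0.3, 0.45):
            assert compute_ccf(vaf, 1.0, 2, 1)["ccf_raw"] == pytest.approx(2 * vaf)

    def test_cap_retains_raw_value(self):
        out = compute_ccf(0.4, 0.5, 2, 1)
        assert out["ccf"] == 1.0
        assert out["ccf_raw"] == pytest.approx(1.6)

    def test_multiplicity_above_cn_rejected(self):
        with pytest.raises(ValueError, match="multiplicity"):
            compute_ccf(0.2, 0.5, 2, 3)

    def test_deep_coverage_clonal_flag(self):
        clonal = compute_ccf(0.45, 0.9, 2, 1, depth=500)
        subclonal = compute_ccf(0.18, 0.9, 2, 1, depth=500)
        assert clonal["clonal"] and not subclonal["clonal"]


class TestClassifyOrigin:
    def test_collision_called_independent(self):
        pc = gen_paired_components(mode="collision", seed=0)
        assert classify_origin(pc).origin == "independent"

    def test_monoclonal_recovery_with_direction(self):
        """Planted trunk (clonal in squamous, subclonal in adenomatous):
        monoclonal + adeno_first in >= 19/20 seeds at depth 200."""
        hits = 0
        for seed in range(20):
            pc = gen_paired_components(depth=200, seed=seed)
            call = classify_origin(pc)
            hits += call.origin == "monoclonal" and call.directionality == "adeno_first"
        assert hits >= 19

    def test_fully_clonal_trunk_undetermined(self):
        tab = pd.DataFrame(
            {
                "variant": ["v1", "v2"],
                "vaf": [0.45, 0.45],
                "depth": [500, 500],
                "purity": [0.9, 0.9],
                "cn": [2.0, 2.0],
                "multiplicity": [1.0, 1.0],
            }
        )
        from luas.synthetic import PairedComponents

        pc = PairedComponents(adeno=tab, squam=tab.copy(), mode="monoclonal")
        call = classify_origin(pc)
        assert call.origin == "monoclonal"
        assert call.directionality == "undetermined"

    def test_empty_component_rejected(self):
        from luas.synthetic import PairedComponents

        pc = gen_paired_components(seed=0)
        empty = pc.adeno.iloc[0:0]
        with pytest.raises(ValueError, match="at least one"):
            classify_origin(PairedComponents(adeno=empty, squam=pc.squam, mode="monoclonal"))
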