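"""Generator contracts: monotone profiles, planted structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from luas import fixtures
from luas.synthetic import (
    CONTEXTS_96,
    CohortConfig,
    burst_half_width,
    expected_vaf,
    gen_alteration_table,
    gen_expression_cohort,
    gen_mutation_catalog,
    gen_paired_components,
)


class TestCohortConfig:
    def test_roundtrip(self):
        cfg = CohortConfig(seed=3, tipping_position=0.4)
        assert CohortConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_samples": 0},
            {"tipping_position": 1.5},
            {"dnb_burst_corr": 1.0},
            {"noise_sd": -1.0},
            {"n_genes_per_role": {"adeno_marker": 0, "squam_marker": 1, "dnb": 1}},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)


class TestExpressionCohort:
    def test_zero_noise_marker_monotonicity(self, noiseless_cohort):
        ex = noiseless_cohort
        vals = ex.values
        for g in ex.genes_with_role("adeno_marker"):
            assert (np.diff(vals.loc[g].to_numpy()) <= 0).all()
        for g in ex.genes_with_role("squam_marker"):
            assert (np.diff(vals.loc[g].to_numpy()) >= 0).all()

    def test_immune_peak_at_tipping(self, noiseless_cohort):
        ex = noiseless_cohort
        t = ex.sample_meta["latent_coordinate"].to_numpy()
        for g in ex.genes_with_role("immune"):
            peak_t = t[np.argmax(ex.values.loc[g].to_numpy())]
            assert abs(peak_t - 0.6) < 0.05

    def test_deterministic_under_seed(self):
        a = gen_expression_cohort(CohortConfig(seed=1))
        b = gen_expression_cohort(CohortConfig(seed=1))
        pd.testing.assert_frame_equal(a.values, b.values)
        c = gen_expression_cohort(CohortConfig(seed=2))
        assert not a.values.equals(c.values)

    def test_burst_window_correlation_exceeds_baseline(self):
        """Direct Pearson computation: the planted DNB window has higher
        within-module |r| than the first (far-from-tipping) window."""
        cfg = CohortConfig(n_samples=93, dnb_burst_corr=0.8, seed=5)
        ex = gen_expression_cohort(cfg)
        t = ex.sample_meta["latent_coordinate"].to_numpy()
        dnb_genes = ex.genes_with_role("dnb")
        center = int(np.argmin(np.abs(t - cfg.tipping_position)))
        tip_cols = ex.samples[center - 5 : center + 5]
        first_cols = ex.samples[:10]

        def mean_abs_r(cols):
            m = ex.values.loc[dnb_genes, cols].to_numpy()
            r = np.corrcoef(m)
            return np.abs(r[np.triu_indices_from(r, k=1)]).mean()

        assert mean_abs_r(tip_cols) > mean_abs_r(first_cols) + 0.3

    def test_burst_window_sd_exceeds_distant_windows(self):
        """Planted burst inflates within-module SD relative to any window
        at least 3 half-widths away, averaged over seeds."""
        deltas = []
        for seed in range(10):
            cfg = CohortConfig(seed=seed)
            ex = gen_expression_cohort(cfg)
            t = ex.sample_meta["latent_coordinate"].to_numpy()
            dnb = ex.values.loc[ex.genes_with_role("dnb")].to_numpy()
            w = burst_half_width(cfg.n_samples)
            tip_mask = np.abs(t - cfg.tipping_position) <= w
            far_mask = np.abs(t - cfg.tipping_position) >= 3 * w
            deltas.append(
                dnb[:, tip_mask].std(axis=1, ddof=1).mean()
                - dnb[:, far_mask].std(axis=1, ddof=1).mean()
            )
        assert min(deltas) > 0

    def test_subtype_labels_partition_cohort(self, default_cohort):
        labels = set(default_cohort.sample_meta["subtype"])
        assert labels == {"TRU-like", "inflammatory", "basal-like"}


class TestAlterationTable:
    def test_strength_one_exclusive_pair_never_cooccurs(self):
        alt = gen_alteration_table(
            500, [("A", "B", "exclusive", 1.0)], {"A": 0.5, "B": 0.5}, seed=0
        )
        assert int(((alt["A"] == 1) & (alt["B"] == 1)).sum()) == 0

    def test_zero_base_rate_gives_empty_column(self):
        alt = gen_alteration_table(100, [], {"A": 0.0, "B": 0.3}, seed=0)
        assert alt["A"].sum() == 0

    def test_exclusive_pair_detected_by_exact_test(self):
        """Planted exclusivity shows OR < 1 with p < 0.05 (exact
        hypergeometric oracle) in >= 18/20 seeds."""
        from tests.oracles import fisher_exact_enumeration

        hits = 0
        for seed in range(20):
            alt = gen_alteration_table(
                200, [("A", "B", "exclusive", 0.9)], {"A": 0.4, "B": 0.4}, seed=seed
            )
            a, b = alt["A"].to_numpy(), alt["B"].to_numpy()
            n11 = int(((a == 1) & (b == 1)).sum())
            n10 = int(((a == 1) & (b == 0)).sum())
            n01 = int(((a == 0) & (b == 1)).sum())
            n00 = int(((a == 0) & (b == 0)).sum())
            p = fisher_exact_enumeration(n11, n10, n01, n00)
            odds = (n11 + 0.5) * (n00 + 0.5) / ((n10 + 0.5) * (n01 + 0.5))
            hits += (odds < 1) and (p < 0.05)
        assert hits >= 18

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError, match="relation"):
            gen_alteration_table(10, [("A", "B", "anti", 0.5)], {"A": 0.1, "B": 0.1})


class TestMutationCatalog:
    def test_point_mass_signature_concentrates_counts(self):
        prof = np.zeros((1, 96))
        prof[0, 7] = 1.0
        cat = gen_mutation_catalog(prof, np.ones((5, 1)), 100, seed=0)
        assert (cat.iloc[:, 7] == 100).all()
        assert cat.drop(columns=cat.columns[7]).to_numpy().sum() == 0

    def test_large_n_recovers_profile(self):
        """Law of large numbers: empirical frequencies approach the profile."""
        rng = np.random.default_rng(0)
        # sparse profiles, as real substitution signatures are
        prof = rng.dirichlet(np.full(96, 0.05), size=2)
        cat = gen_mutation_catalog(prof, np.eye(2), 10000, seed=1)
        freq = cat.to_numpy() / 10000
        assert np.abs(freq - prof).sum(axis=1).max() < 0.05

    def test_unnormalized_profile_rejected(self):
        prof = np.full((1, 96), 0.5)
        with pytest.raises(ValueError, match="probability"):
            gen_mutation_catalog(prof, np.ones((2, 1)), 10)

    def test_context_order(self):
        assert CONTEXTS_96[0] == "A[C>A]A"
        assert CONTEXTS_96[-1] == "T[T>G]T"
        assert len(set(CONTEXTS_96)) == 96


class TestPairedComponents:
    def test_collision_mode_shares_nothing(self):
        pc = gen_paired_components(mode="collision", seed=0)
        assert pc.shared_variants == set()

    def test_trunk_vaf_closed_form(self):
        # CCF=1, purity=1, CN=2, m=1 -> VAF exactly 0.5
        assert expected_vaf(1.0, 1.0, 2.0, 1.0) == pytest.approx(0.5)
        pc = gen_paired_components(
            n_trunk=5, n_private_A=0, n_private_S=0, purity_A=1.0, purity_S=1.0,
            depth=100000, seed=0,
        )
        trunk = pc.squam[pc.squam["variant"].str.startswith("trunk")]
        assert np.allclose(trunk["vaf"], 0.5, atol=0.02)

    def test_monoclonal_trunk_direction(self):
        pc = gen_paired_components(seed=1)
        trunk_a = pc.adeno[pc.adeno["variant"].str.startswith("trunk")]
        trunk_s = pc.squam[pc.squam["variant"].str.startswith("trunk")]
        assert (trunk_s["true_ccf"] == 1.0).all()
        assert (trunk_a["true_ccf"] < 1.0).all()

    def test_degenerate_monoclonal_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            gen_paired_components(n_trunk=0, seed=0)


class TestFixtures:
    @pytest.mark.parametrize(
        "name,key,value",
        [
            ("egfr_alleles", "L858R", 20),
            ("egfr_alleles", "EGFR_mutant", 40),
            ("nsclc_collection", "LUAS", 120),
            ("nsclc_collection", "NSCLC", 5676),
            ("cohort_stage", "stage_I", 55),
            ("alk_fusion", "EML4_ALK", 6),
        ],
    )
    def test_registered_counts(self, name, key, value):
        assert fixtures.load_fixture(name).table[key] == value

    def test_unknown_fixture_lists_available(self):
        with pytest.raises(KeyError, match="egfr_alleles"):
            fixtures.load_fixture("no_such")

    def test_derived_counts_flagged(self):
        assert fixtures.load_fixture("smoking").derived_count
        assert fixtures.load_fixture("eml4_alk_mouse").derived_count
        assert not fixtures.load_fixture("egfr_alleles").derived_count
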