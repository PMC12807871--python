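"""Significance tests, two-stage FDR, QC correlations, OddsPath, hydropathy."""

import numpy as np
import pandas as pd
import pytest

from mutscan import stats as st


def bh_reject(p, q):
    """Step-up Benjamini–Hochberg at level q (brute-force reference)."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    below = p[order] <= q * np.arange(1, m + 1) / m
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    rej = np.zeros(m, bool)
    rej[order[:k]] = True
    return rej


def bky_reference(p, Q):
    """Two-stage step-up procedure, coded independently for cross-checking."""
    m = len(p)
    q1 = Q / (1 + Q)
    r1 = int(bh_reject(p, q1).sum())
    if r1 == 0:
        return np.zeros(m, bool)
    if r1 == m:
        return np.ones(m, bool)
    return bh_reject(p, q1 * m / (m - r1))


class TestLogTTest:
    def test_variant_indistinguishable_from_control(self):
        rng = np.random.default_rng(0)
        pool = np.exp(rng.normal(0, 0.3, size=40))
        gm = float(np.exp(np.mean(np.log(pool))))
        variant = np.array([gm, gm, gm, gm])
        res = st.log_t_test(variant, pool)
        assert res["p"] > 0.9

    def test_e_fold_shift_detected(self):
        rng = np.random.default_rng(1)
        pool = np.exp(rng.normal(0, 0.1, size=40))
        variant = np.exp(1.0 + rng.normal(0, 0.01, size=4))
        res = st.log_t_test(variant, pool)
        assert res["p"] < 0.01
        assert res["t"] > 0

    def test_scale_invariance(self):
        # a common multiplicative factor shifts both log means equally
        rng = np.random.default_rng(2)
        pool = np.exp(rng.normal(0, 0.3, size=30))
        variant = np.exp(rng.normal(0.5, 0.2, size=4))
        r1 = st.log_t_test(variant, pool)
        r2 = st.log_t_test(variant * 7.3, pool * 7.3)
        assert r1["t"] == pytest.approx(r2["t"])
        assert r1["p"] == pytest.approx(r2["p"])

    def test_input_validation(self):
        pool = np.ones(12)
        with pytest.raises(ValueError, match="2 variant replicates"):
            st.log_t_test([1.0], pool)
        with pytest.raises(ValueError, match=">= 10"):
            st.log_t_test([1.0, 2.0], np.ones(5))
        with pytest.raises(ValueError, match="> 0"):
            st.log_t_test([0.0, 1.0], pool)


class TestBkyFdr:
    def test_all_ones_no_discoveries(self):
        q, disc = st.bky_fdr(np.ones(100), Q=0.01)
        assert disc.sum() == 0

    def test_all_tiny_all_discovered(self):
        q, disc = st.bky_fdr(np.full(50, 1e-9), Q=0.01)
        assert disc.sum() == 50

    def test_empty_input(self):
        q, disc = st.bky_fdr(np.array([]), Q=0.01)
        assert len(q) == 0 and len(disc) == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            st.bky_fdr(np.array([0.5, 1.5]))

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=300)
        q, _ = st.bky_fdr(p, Q=0.05)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_reference(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(50):
            m = int(rng.integers(5, 400))
            p = rng.uniform(size=m)
            if rng.random() < 0.5:
                p[: m // 4] = rng.uniform(0, 0.005, size=m // 4)
            Q = float(rng.choice([0.01, 0.05, 0.1]))
            _, disc = st.bky_fdr(p, Q=Q)
            assert np.array_equal(disc, bky_reference(p, Q))


class TestReplicateCorrelation:
    def test_duplicated_replicate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        df = pd.DataFrame({"r1": x, "r2": x})
        out = st.replicate_correlation(df)
        assert out["pearson"].iloc[0] == pytest.approx(1.0)

    def test_independent_noise(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(5000, 2)), columns=["r1", "r2"])
        out = st.replicate_correlation(df)
        assert abs(out["pearson"].iloc[0]) < 0.05

    def test_shared_signal_band(self):
        # effect SD 1 and noise SD 0.5 -> expected r = 1/(1+0.25) = 0.8
        rng = np.random.default_rng(6)
        effect = rng.normal(0, 1.0, size=2000)
        df = pd.DataFrame(
            {f"r{i}": effect + rng.normal(0, 0.5, size=2000) for i in range(3)}
        )
        out = st.replicate_correlation(df)
        assert ((out["pearson"] > 0.75) & (out["pearson"] < 0.85)).all()

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"r1": [1.0, 1.0, 1.0, 1.0], "r2": [1.0, 2.0, 3.0, 4.0]})
        out = st.replicate_correlation(df)
        assert np.isnan(out["pearson"].iloc[0])


class TestCodonConsistency:
    def test_identical_scores_perfect_correlation(self, design_frame):
        rng = np.random.default_rng(7)
        aa_effect = pd.Series(
            rng.lognormal(0, 1, size=design_frame["aa_change"].nunique()),
            index=design_frame["aa_change"].unique(),
        )
        medians = design_frame["aa_change"].map(aa_effect)
        out = st.codon_consistency(medians, design_frame)
        assert out["pearson"] == pytest.approx(1.0)
        assert out["n_pairs"] > 0

    def test_shuffled_scores_uncorrelated(self, design_frame):
        rng = np.random.default_rng(8)
        medians = pd.Series(rng.lognormal(0, 1, size=len(design_frame)),
                            index=design_frame.index)
        out = st.codon_consistency(medians, design_frame)
        assert abs(out["pearson"]) < 0.25

    def test_aa_effect_plus_noise_positive(self, design_frame):
        rng = np.random.default_rng(9)
        aa_effect = pd.Series(
            rng.lognormal(0, 1, size=design_frame["aa_change"].nunique()),
            index=design_frame["aa_change"].unique(),
        )
        medians = design_frame["aa_change"].map(aa_effect) * rng.lognormal(
            0, 0.2, size=len(design_frame)
        )
        out = st.codon_consistency(medians, design_frame)
        assert 0.5 < out["spearman"] <= 1.0

    def test_no_multi_encoded_changes(self):
        design = pd.DataFrame(
            {"aa_change": ["a", "b"], "cds_pos": [1, 2], "alt_nt": ["A", "C"]},
            index=["v1", "v2"],
        )
        medians = pd.Series([1.0, 2.0], index=["v1", "v2"])
        out = st.codon_consistency(medians, design)
        assert out["n_pairs"] == 0 and np.isnan(out["pearson"])


class TestOddsPath:
    def _series(self, n_path_abn, n_path_norm, n_ben_abn, n_ben_norm):
        labels, calls = {}, {}
        i = 0
        for n, label, call in [
            (n_path_abn, "pathogenic", "functionally_abnormal"),
            (n_path_norm, "pathogenic", "functionally_normal"),
            (n_ben_abn, "benign", "functionally_abnormal"),
            (n_ben_norm, "benign", "functionally_normal"),
        ]:
            for _ in range(n):
                labels[f"v{i}"] = label
                calls[f"v{i}"] = call
                i += 1
        return pd.Series(calls), pd.Series(labels)

    def test_formula_oracle(self):
        # P1 = 0.5, P2 = 0.9 -> OddsPath = (0.9 * 0.5) / (0.1 * 0.5) = 9
        calls, labels = self._series(9, 1, 1, 9)
        res = st.odds_path(calls, labels)
        assert res["P1"] == pytest.approx(0.5)
        assert res["P2_path"] == pytest.approx(0.9)
        assert res["odds_path_pathogenic"] == pytest.approx(9.0)

    def test_uninformative_assay(self):
        calls, labels = self._series(5, 5, 5, 5)
        res = st.odds_path(calls, labels)
        assert res["odds_path_pathogenic"] == pytest.approx(1.0)
        assert res["odds_path_benign"] == pytest.approx(1.0)

    def test_tier_thresholds(self):
        th = st.OddsPathThresholds()
        assert th.pathogenic_tier(45.4) == "strong"
        assert th.pathogenic_tier(52.0) == "strong"
        assert th.pathogenic_tier(400.0) == "very strong"
        assert th.pathogenic_tier(1.0) == "indeterminate"
        assert th.benign_tier(0.010) == "strong"
        assert th.benign_tier(0.015) == "strong"
        assert th.benign_tier(0.3) == "supporting"

    def test_invariant_to_duplicating_controls(self):
        calls, labels = self._series(8, 2, 3, 7)
        res1 = st.odds_path(calls, labels)
        calls2 = pd.concat([calls, calls.rename(lambda s: s + "_dup")])
        labels2 = pd.concat([labels, labels.rename(lambda s: s + "_dup")])
        res2 = st.odds_path(calls2, labels2)
        assert res1["odds_path_pathogenic"] == pytest.approx(
            res2["odds_path_pathogenic"]
        )

    def test_degenerate_p2_continuity_corrected(self):
        calls, labels = self._series(5, 0, 0, 5)  # perfect separation
        res = st.odds_path(calls, labels)
        assert res["continuity_corrected"]
        assert np.isfinite(res["odds_path_pathogenic"])

    def test_missing_label_class_rejected(self):
        calls, labels = self._series(5, 5, 0, 0)
        with pytest.raises(ValueError, match="both"):
            st.odds_path(calls, labels)


class TestHydropathy:
    def test_scale_difference(self):
        # Ile -> Asp on the Kyte–Doolittle scale: -3.5 - 4.5 = -8.0
        assert st.KYTE_DOOLITTLE["D"] - st.KYTE_DOOLITTLE["I"] == pytest.approx(-8.0)

    def test_exact_rank_sum_enumeration(self):
        # fully separated 3-vs-3: one-sided p = 1 / C(6,3) = 1/20
        p = st.exact_rank_sum_p([2, 3, 4], [-1, 0, 1], alternative="greater")
        assert p == pytest.approx(1 / 20)

    def test_association_detected(self, design_frame):
        rng = np.random.default_rng(10)
        missense = design_frame[design_frame["consequence"] == "missense"]
        dh = missense["alt_aa"].map(st.KYTE_DOOLITTLE) - missense["ref_aa"].map(
            st.KYTE_DOOLITTLE
        )
        # construct calls where hydrophobicity-increasing changes are hits
        calls = pd.DataFrame(index=design_frame.index)
        calls["assayed"] = True
        calls["hit"] = False
        calls["lof"] = False
        hits = dh[dh > 2].index
        calls.loc[hits, "hit"] = True
        out = st.hydropathy_association(calls, design_frame)
        assert out["gof_median_dh"] > out["neutral_median_dh"]
        assert out["gof_vs_neutral_p"] < 1e-6
        assert out["fisher_2x2_p"] < 1e-6


class TestPredictionScoreCorrelation:
    def test_scores_equal_enrichment(self):
        rng = np.random.default_rng(11)
        m = pd.Series(rng.lognormal(0, 1, size=200),
                      index=[f"v{i}" for i in range(200)])
        out = st.prediction_score_correlation(m, m)
        assert out["rho_enriched"] == pytest.approx(1.0)
        assert out["rho_depleted"] == pytest.approx(1.0)

    def test_abs_log_scores_reproduce_piecewise_pattern(self):
        rng = np.random.default_rng(12)
        m = pd.Series(rng.lognormal(0, 1, size=500),
                      index=[f"v{i}" for i in range(500)])
        scores = np.abs(np.log(m))
        out = st.prediction_score_correlation(m, scores)
        assert out["rho_enriched"] == pytest.approx(1.0)
        assert out["rho_depleted"] == pytest.approx(-1.0)

    def test_permuted_scores_uncorrelated(self):
        rng = np.random.default_rng(13)
        m = pd.Series(rng.lognormal(0, 1, size=2000),
                      index=[f"v{i}" for i in range(2000)])
        scores = pd.Series(rng.permutation(m.to_numpy()), index=m.index)
        out = st.prediction_score_correlation(m, scores)
        assert abs(out["rho_enriched"]) < 0.1
        assert abs(out["rho_depleted"]) < 0.1

    def test_small_stratum_missing(self):
        m = pd.Series([2.0] * 12 + [0.5] * 3, index=[f"v{i}" for i in range(15)])
        out = st.prediction_score_correlation(m, m)
        assert np.isnan(out["rho_depleted"])
        assert out["n_depleted"] == 3


class TestTestTable:
    def test_null_discovery_rate_bounded(self, design_frame):
        from mutscan import scoring
        from mutscan import simulate as sim

        config = sim.SimConfig(seed=30, depth=300, class_fractions={})
        truth = sim.make_true_effects(design_frame, config)
        counts = sim.simulate_counts(design_frame, truth, config)
        layout = sim.sample_layout(config)
        table = scoring.score_screen(counts, design_frame, layout["plasmid"],
                                     layout["activation"])
        enr = table[scoring.enrichment_columns(table)]
        res = st.test_table(enr, design_frame["consequence"] == "synonymous",
                            table["assayed"], Q=0.01)
        assert res["discovery"].mean() <= 0.02

    def test_programmed_effects_discovered(self, design_frame):
        from mutscan import scoring
        from mutscan import simulate as sim

        config = sim.SimConfig(seed=31, depth=300)
        truth = sim.make_true_effects(design_frame, config)
        counts = sim.simulate_counts(design_frame, truth, config)
        layout = sim.sample_layout(config)
        table = scoring.score_screen(counts, design_frame, layout["plasmid"],
                                     layout["activation"])
        enr = table[scoring.enrichment_columns(table)]
        res = st.test_table(enr, design_frame["consequence"] == "synonymous",
                            table["assayed"], Q=0.01)
        strong = truth.index[truth["effect_activation"] >= 5]
        found = res.loc[res.index.intersection(strong), "discovery"]
        assert found.mean() >= 0.95
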