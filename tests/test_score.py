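"""PHS derivation: prescreen, stepwise selection, bootstrap averaging,
scoring, and the population reference distribution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyhazard.datasets import load_ad_weights
from polyhazard.score import (PolygenicHazardModel, bootstrap_betas, compute_phs,
                              empirical_distribution, percentile_of, prescreen,
                              reference_distribution, stepwise_select)
from polyhazard.simulate import GenotypeMatrix

from conftest import BASE_COVARIATES, make_cohort


class TestPrescreen:
    def test_threshold_filter(self):
        stats = pd.DataFrame(
            {"snp": ["a", "b", "c", "d"], "p": [1e-7, 1e-6, 1e-4, 0.5],
             "beta": [0.1, -0.2, 0.3, 0.1]}
        )
        assert prescreen(stats) == ["a", "b"]

    def test_threshold_one_keeps_all(self):
        stats = pd.DataFrame({"snp": list("abc"), "p": [0.2, 0.9, 1.0],
                              "beta": [1, 1, 1]})
        assert prescreen(stats, p_threshold=1.0) == ["a", "b"]  # p=1 is not < 1

    def test_direction_filter(self):
        stats = pd.DataFrame(
            {"snp": ["a", "b"], "p": [1e-8, 1e-8], "beta": [0.2, -0.2]}
        )
        assert prescreen(stats, direction_filter=True) == ["a"]
        assert prescreen(stats, direction_filter=False) == ["a", "b"]

    def test_empty_input_gives_empty_list(self):
        assert prescreen(pd.DataFrame(columns=["snp", "p"])) == []

    def test_invalid_p_values_raise(self):
        stats = pd.DataFrame({"snp": ["a"], "p": [0.0]})
        with pytest.raises(ValueError):
            prescreen(stats)


class TestStepwise:
    def test_causal_snp_chosen_first_and_criterion_decreases(self):
        cohort, _, _ = make_cohort(
            n=6000, betas=(0.6,) + (0.0,) * 9, freqs=(0.3,) * 10,
            design="case_control", n_cases=700, n_controls=1300, seed=21,
        )
        trace, selected = stepwise_select(
            [f"snp{j}" for j in range(10)], cohort, BASE_COVARIATES
        )
        assert selected[0] == "snp0"
        path = [s["criterion_before"] for s in trace.steps] + [
            trace.steps[-1]["criterion_after"]
        ]
        assert all(a > b for a, b in zip(path, path[1:]))

    def test_null_candidates_select_few(self):
        picked = []
        for rep in range(5):
            cohort, _, _ = make_cohort(
                n=2500, betas=(0.0,) * 8, freqs=(0.3,) * 8,
                design="case_control", n_cases=350, n_controls=650, seed=100 + rep,
            )
            _, selected = stepwise_select(
                [f"snp{j}" for j in range(8)], cohort, BASE_COVARIATES
            )
            picked.append(len(selected))
        assert np.mean([k <= 2 for k in picked]) >= 0.8

    def test_empty_candidate_list(self):
        cohort, _, _ = make_cohort(n=500, seed=2)
        trace, selected = stepwise_select([], cohort, BASE_COVARIATES)
        assert selected == []
        assert trace.halted_because == "empty candidate pool"

    def test_missing_base_covariate_raises(self):
        cohort, _, _ = make_cohort(n=500, seed=2)
        with pytest.raises(ValueError, match="absent"):
            stepwise_select(["snp0"], cohort, ["nonexistent"])


class TestBootstrap:
    def test_degenerate_single_identity_resample_equals_full_fit(self):
        cohort, _, _ = make_cohort(n=800, betas=(0.5,), seed=13)
        # find a seed whose single resample is close to the identity is fragile;
        # instead check B=1 returns that one resample's fit, se = 0 convention
        table = bootstrap_betas(["snp0"], cohort, BASE_COVARIATES, B=1, seed=0)
        assert np.all(table["se"] == 0.0)
        assert set(table["variant"]) == {"apoe_e2", "apoe_e4", "snp0"}

    def test_bootstrap_consistency_against_analytic_se(self):
        cohort, _, _ = make_cohort(
            n=5000, betas=(0.4,), freqs=(0.3,),
            design="case_control", n_cases=900, n_controls=1600, seed=31,
        )
        table = bootstrap_betas(["snp0"], cohort, BASE_COVARIATES, B=200, seed=5)
        row = table.set_index("variant").loc["snp0"]
        assert abs(row.beta - 0.4) < 3 * row.se
        import polyhazard as ph

        full = ph.fit_cox(cohort, BASE_COVARIATES + ["snp0"])
        assert abs(row.se - full.se["snp0"]) < 0.3 * full.se["snp0"]

    def test_seed_stability(self):
        cohort, _, _ = make_cohort(
            n=2000, betas=(0.4,), design="case_control", n_cases=250,
            n_controls=750, seed=17,
        )
        t1 = bootstrap_betas(["snp0"], cohort, BASE_COVARIATES, B=150, seed=1)
        t2 = bootstrap_betas(["snp0"], cohort, BASE_COVARIATES, B=150, seed=2)
        mc_se = t1.set_index("variant").se / np.sqrt(150)
        diff = (t1.set_index("variant").beta - t2.set_index("variant").beta).abs()
        assert (diff < 4 * mc_se).all()

    def test_invalid_B_raises(self):
        cohort, _, _ = make_cohort(n=300, seed=1)
        with pytest.raises(ValueError):
            bootstrap_betas(["snp0"], cohort, BASE_COVARIATES, B=0)


class TestComputePHS:
    def test_zero_genotype_zero_score(self):
        w = load_ad_weights()
        snps = [v for v in w.variant if v.startswith("rs")]
        geno = pd.DataFrame(0.0, index=["i1"], columns=snps)
        apoe = pd.DataFrame({"apoe_e2": [0.0], "apoe_e4": [0.0]}, index=["i1"])
        assert compute_phs(w, geno, apoe)["i1"] == 0.0

    def test_single_e4_allele_scores_published_weight(self):
        w = load_ad_weights()
        snps = [v for v in w.variant if v.startswith("rs")]
        geno = pd.DataFrame(0.0, index=["i1"], columns=snps)
        apoe = pd.DataFrame({"apoe_e2": [0.0], "apoe_e4": [1.0]}, index=["i1"])
        assert compute_phs(w, geno, apoe)["i1"] == pytest.approx(1.03)

    def test_hand_summed_published_weights(self):
        # 2 copies at rs6733839 (-0.15), 1 at rs115124923 (0.17), one e4 (1.03)
        w = load_ad_weights()
        snps = [v for v in w.variant if v.startswith("rs")]
        geno = pd.DataFrame(0.0, index=["i1"], columns=snps)
        geno.loc["i1", "rs6733839"] = 2.0
        geno.loc["i1", "rs115124923"] = 1.0
        apoe = pd.DataFrame({"apoe_e2": [0.0], "apoe_e4": [1.0]}, index=["i1"])
        s = compute_phs(w, geno, apoe)["i1"]
        assert s == pytest.approx(2 * (-0.15) + 0.17 + 1.03, abs=1e-12)
        assert s == pytest.approx(0.90, abs=1e-12)

    def test_allele_flip_and_mismatch(self):
        w = pd.DataFrame({"variant": ["v1"], "beta": [1.0], "effect_allele": ["A"]})
        gm = GenotypeMatrix(["i1"], ["v1"], ["G"], ["A"], np.array([[2.0]]))
        # genotype counts G but weights are for A -> dosage flips to 0
        assert compute_phs(w, gm)["i1"] == 0.0
        bad = GenotypeMatrix(["i1"], ["v1"], ["G"], ["T"], np.array([[2.0]]))
        with pytest.raises(ValueError, match="v1"):
            compute_phs(w, bad)

    def test_missing_dosage_mean_imputed(self):
        w = pd.DataFrame({"variant": ["v1", "v2"], "beta": [1.0, 2.0]})
        geno = pd.DataFrame({"v1": [np.nan], "v2": [1.0]}, index=["i1"])
        s = compute_phs(w, geno, freqs={"v1": 0.25})
        assert s["i1"] == pytest.approx(1.0 * 0.5 + 2.0)
        with pytest.raises(KeyError):
            compute_phs(w, geno)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_in_genotypes(self, seed):
        rng = np.random.default_rng(seed)
        w = pd.DataFrame({"variant": ["a", "b", "c"], "beta": rng.normal(size=3)})
        g1 = pd.DataFrame(rng.uniform(0, 1, (2, 3)), columns=["a", "b", "c"])
        g2 = pd.DataFrame(rng.uniform(0, 1, (2, 3)), columns=["a", "b", "c"])
        lhs = compute_phs(w, g1 + g2)
        rhs = compute_phs(w, g1) + compute_phs(w, g2)
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestReferenceDistribution:
    def test_single_snp_enumeration(self):
        w = pd.DataFrame({"variant": ["v"], "beta": [np.log(2)]})
        dist = reference_distribution(w, {"v": 0.5}, method="exact")
        c = np.log(2)  # population mean 2 * 0.5 * ln2
        assert np.allclose(np.sort(dist.support), [-c, np.log(2) - c, 2 * np.log(2) - c])
        assert np.allclose(dist.weights[np.argsort(dist.support)], [0.25, 0.5, 0.25])
        assert dist.mean == pytest.approx(0.0, abs=1e-12)

    def test_uncentered_mean_is_linear_in_frequencies(self):
        w = load_ad_weights()
        freqs = {v: 0.3 for v in w.variant if v.startswith("rs")}
        dist = reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=10_000, seed=1
        )
        snp = w[w.variant.str.startswith("rs")]
        expect = float((2 * 0.3 * snp.beta).sum()) + 2 * 0.08 * -0.47 + 2 * 0.14 * 1.03
        assert dist.mean_shift == pytest.approx(expect, abs=1e-9)

    def test_monte_carlo_matches_exact_within_dkw_bound(self):
        rng = np.random.default_rng(3)
        w = pd.DataFrame(
            {"variant": [f"v{j}" for j in range(8)], "beta": rng.normal(0, 0.2, 8)}
        )
        freqs = {f"v{j}": f for j, f in enumerate(rng.uniform(0.05, 0.95, 8))}
        exact = reference_distribution(w, freqs, method="exact")
        n_mc = 200_000
        mc = reference_distribution(w, freqs, method="monte_carlo", n_mc=n_mc, seed=9)
        grid = np.linspace(exact.support.min(), exact.support.max(), 300)
        gap = np.abs(mc.cdf(grid) - exact.cdf(grid)).max()
        assert gap < 3.0 / np.sqrt(n_mc)

    def test_exact_with_too_many_variants_raises(self):
        w = pd.DataFrame(
            {"variant": [f"v{j}" for j in range(13)], "beta": np.zeros(13)}
        )
        with pytest.raises(ValueError, match="monte_carlo"):
            reference_distribution(w, {f"v{j}": 0.5 for j in range(13)}, method="exact")

    def test_e4_conditioning_shifts_distribution_upward(self):
        w = load_ad_weights()
        freqs = {v: 0.3 for v in w.variant if v.startswith("rs")}
        dist = reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=50_000, seed=4
        )
        carrier = dist.condition_e4(True)
        non = dist.condition_e4(False)
        assert carrier.mean > non.mean + 0.5  # e4 log HR is 1.03


class TestPercentiles:
    def test_median_maps_to_fifty(self):
        dist = empirical_distribution(np.random.default_rng(0).normal(size=10_001))
        med = dist.quantile(0.5)
        assert percentile_of(med, dist) == pytest.approx(50.0, abs=0.5)

    def test_quantile_cdf_inverse_consistency(self):
        dist = empirical_distribution(np.random.default_rng(1).normal(size=100_000))
        q99 = dist.quantile(0.99)
        assert percentile_of(q99, dist) == pytest.approx(99.0, abs=0.2)

    def test_probability_integral_transform_uniform(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        w = load_ad_weights()
        freqs = {v: 0.3 for v in w.variant if v.startswith("rs")}
        dist = reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=200_000, seed=6
        )
        # an independent draw from the same population
        fresh = reference_distribution(
            w, freqs, apoe_freqs=(0.08, 0.78, 0.14), n_mc=5_000, seed=7
        ).support
        pct = percentile_of(fresh, dist)
        assert stats.kstest(pct / 100.0, "uniform").pvalue > 0.01


class TestEstimatorAPI:
    def test_sklearn_params_roundtrip_and_fit_attributes(self):
        model = PolygenicHazardModel(B=25, seed=3)
        assert model.get_params()["B"] == 25
        model.set_params(tol=1e-3)
        cohort, _, _ = make_cohort(
            n=2500, betas=(0.6, 0.0), freqs=(0.3, 0.3),
            design="case_control", n_cases=300, n_controls=800, seed=8,
        )
        stats = pd.DataFrame(
            {"snp": ["snp0", "snp1", "snpX"], "p": [1e-9, 1e-7, 0.9],
             "beta": [0.5, 0.1, 0.0]}
        )
        model.fit(cohort, summary_stats=stats)
        assert model.candidates_ == ["snp0", "snp1"]  # snpX fails the prescreen
        assert "snp0" in model.selected_
        scores = model.transform(
            cohort[model.selected_], apoe=cohort[["apoe_e2", "apoe_e4"]]
        )
        assert len(scores) == len(cohort)
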