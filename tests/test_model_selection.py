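"""NB GLM fitting, information criteria, Akaike weights, model averaging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import statsmodels.api as sm

from rodentcam.model_selection import (
    ModelSpec,
    NBFit,
    aic,
    aicc,
    akaike_weights,
    candidate_sets,
    fit_nb_glm,
    ic_table,
    model_average,
    parse_model_name,
    selection_uncertain,
)

# printed detection-model comparison used as worked-example input:
# (-2 logLik, K) per model for two species
DETECTION_ROWS = {
    ("black rat", "psi(.)p(night)"): (2577.08, 12),
    ("black rat", "psi(.)p(.)"): (2627.84, 2),
    ("house mouse", "psi(.)p(night)"): (2191.64, 12),
    ("house mouse", "psi(.)p(.)"): (2239.78, 2),
}


def nb_data(seed=0, n=200, beta=(1.0, 0.5), theta=2.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    mu = np.exp(beta[0] + beta[1] * x)
    y = rng.negative_binomial(theta, theta / (theta + mu))
    cov = pd.DataFrame({"x": x})
    return y, cov


class TestModelSpec:
    def test_parse_main_effects_and_interaction(self):
        spec = parse_model_name("C_gt1m+BD+C_gt1m*BD")
        assert spec.terms == ("C_gt1m", "BD")
        assert spec.interactions == (("C_gt1m", "BD"),)
        assert spec.columns == ["C_gt1m", "BD", "C_gt1m*BD"]

    def test_constant_model_has_no_terms(self):
        assert parse_model_name("Constant").columns == []

    def test_interaction_without_mains_rejected(self):
        with pytest.raises(ValueError, match="requires both main effects"):
            ModelSpec("bad", terms=("A",), interactions=(("A", "B"),))


class TestCandidateSets:
    def test_black_rat_set(self):
        specs = candidate_sets("black_rat")
        assert len(specs) == 12
        assert specs[0].name == "C_gt1m"
        assert "RR" not in {t for s in specs for t in s.terms}

    def test_house_mouse_set_adds_rat_activity(self):
        specs = candidate_sets("house_mouse")
        assert len(specs) == 13
        assert any(s.name == "RR" for s in specs)

    def test_every_interaction_spec_contains_its_mains(self):
        for species in ("black_rat", "house_mouse"):
            for spec in candidate_sets(species):
                for a, b in spec.interactions:
                    assert a in spec.terms and b in spec.terms

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            candidate_sets("brown rat")


class TestFitNBGLM:
    def test_intercept_only_closed_form(self):
        # constant counts c with equal offsets: intercept = log(c / nights)
        y = np.full(20, 6)
        cov = pd.DataFrame(index=range(20))
        offset = np.log(np.full(20, 8.0))
        fit = fit_nb_glm("Constant", y, cov, offset=offset)
        assert fit.params["Intercept"] == pytest.approx(np.log(6 / 8), abs=1e-6)

    def test_non_integer_response_rejected(self):
        cov = pd.DataFrame({"x": np.zeros(5)})
        with pytest.raises(ValueError, match="integer"):
            fit_nb_glm(ModelSpec("m", ("x",)), [1.5, 2, 3, 4, 5], cov)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="not found"):
            fit_nb_glm(ModelSpec("m", ("zz",)), [1, 2], pd.DataFrame({"x": [0, 1]}))

    def test_recovers_generating_parameters(self):
        y, cov = nb_data(seed=1, n=2000, beta=(1.0, 0.5), theta=2.0)
        fit = fit_nb_glm(ModelSpec("m", ("x",)), y, cov)
        assert fit.params["Intercept"] == pytest.approx(1.0, abs=0.1)
        assert fit.params["x"] == pytest.approx(0.5, abs=0.1)
        assert fit.theta == pytest.approx(2.0, rel=0.25)
        assert fit.k == 3 and fit.converged

    def test_poisson_limit_matches_poisson_fit(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        mu = np.exp(0.8 + 0.4 * x)
        y = rng.poisson(mu)
        cov = pd.DataFrame({"x": x})
        X = sm.add_constant(cov["x"])
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        # dispersion held at the Poisson limit: coefficients coincide
        fit = fit_nb_glm(ModelSpec("m", ("x",)), y, cov, fixed_theta=1e8)
        assert fit.params["Intercept"] == pytest.approx(pois.params["const"],
                                                        abs=1e-4)
        assert fit.params["x"] == pytest.approx(pois.params["x"], abs=1e-4)
        # profiled dispersion on Poisson data is large, coefficients close
        prof = fit_nb_glm(ModelSpec("m", ("x",)), y, cov)
        assert prof.theta > 50
        assert prof.params["x"] == pytest.approx(pois.params["x"], abs=1e-3)

    def test_wald_ci_coverage_near_nominal(self):
        hits = 0
        reps = 200
        for rep in range(reps):
            y, cov = nb_data(seed=10_000 + rep, n=276, beta=(1.0, 0.5),
                             theta=2.0)
            fit = fit_nb_glm(ModelSpec("m", ("x",)), y, cov)
            lo = fit.params["x"] - 1.96 * fit.bse["x"]
            hi = fit.params["x"] + 1.96 * fit.bse["x"]
            hits += lo <= 0.5 <= hi
        assert 0.90 <= hits / reps <= 0.99

    def test_nesting_never_decreases_loglik(self):
        y, cov = nb_data(seed=5, n=300)
        cov["z"] = np.random.default_rng(6).normal(size=300)
        small = fit_nb_glm(ModelSpec("s", ("x",)), y, cov)
        big = fit_nb_glm(ModelSpec("b", ("x", "z")), y, cov)
        assert big.loglik >= small.loglik - 1e-6


class TestInformationCriteria:
    @pytest.mark.parametrize(
        "minus2ll,k,expected",
        [(2577.08, 12, 2601.08), (2239.78, 2, 2243.78),
         (2627.84, 2, 2631.84), (2191.64, 12, 2215.64)],
    )
    def test_criterion_arithmetic_on_printed_rows(self, minus2ll, k, expected):
        assert aic(-minus2ll / 2.0, k) == pytest.approx(expected, abs=1e-9)

    def test_aic_of_zero_loglik_no_parameters(self):
        assert aic(0.0, 0) == 0.0

    def test_aicc_small_sample_correction(self):
        assert aicc(-10.0, 3, 20) == pytest.approx(20 + 6 + 24 / 16)

    def test_aicc_requires_enough_samples(self):
        with pytest.raises(ValueError, match="n > K"):
            aicc(-10.0, 5, 6)

    def test_aicc_converges_to_aic(self):
        assert abs(aicc(-100.0, 5, 10**8) - aic(-100.0, 5)) < 1e-6


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([0.0]) == pytest.approx([1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            akaike_weights([])

    def test_two_model_gap_of_thirty(self):
        w = akaike_weights([0.0, 30.76])
        assert round(w[0], 2) == 1.00 and round(w[1], 2) == 0.00

    @given(st.lists(st.floats(min_value=0, max_value=50), min_size=1,
                    max_size=15),
           st.floats(min_value=-100, max_value=100))
    def test_sum_to_one_and_shift_invariant(self, deltas, shift):
        w = akaike_weights(deltas)
        assert np.sum(w) == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(w, akaike_weights(np.array(deltas) + shift))


def make_fit(name, loglik, k, params=None, bse=None, n=100):
    spec = parse_model_name(name)
    cols = ["Intercept"] + spec.columns
    params = pd.Series(params if params is not None else np.zeros(len(cols)),
                       index=cols)
    bse = pd.Series(bse if bse is not None else np.ones(len(cols)), index=cols)
    return NBFit(spec=spec, params=params, bse=bse, theta=1.0, loglik=loglik,
                 k=k, n=n, converged=True)


class TestICTable:
    def test_equal_fits_split_weight(self):
        fits = [make_fit("A", -100.0, 3), make_fit("B", -100.0, 3)]
        tab = ic_table(fits, n=100)
        assert np.allclose(tab["weight"], 0.5)

    def test_duplicate_names_rejected(self):
        fits = [make_fit("A", -100.0, 3), make_fit("A", -90.0, 3)]
        with pytest.raises(ValueError, match="duplicate"):
            ic_table(fits, n=100)

    def test_sorted_by_criterion_with_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        fits = [make_fit(f"M{i}", -float(rng.uniform(80, 120)),
                         int(rng.integers(2, 7))) for i in range(10)]
        tab = ic_table(fits, n=60, criterion="aicc")
        oracle = sorted(aicc(f.loglik, f.k, 60) for f in fits)
        assert np.allclose(tab["AICc"], oracle)
        assert tab["delta"].iloc[0] == 0.0
        assert tab["weight"].sum() == pytest.approx(1.0, abs=1e-12)

    def test_emits_both_criteria_and_records_choice(self):
        tab = ic_table([make_fit("A", -100.0, 3)], n=50, criterion="aic")
        assert {"AIC", "AICc"} <= set(tab.columns)
        assert tab.attrs["criterion"] == "aic"


class TestModelAverage:
    def test_term_in_all_models_with_identical_beta_unchanged(self):
        fits = [
            make_fit("x", -100.0, 3, params=[0.0, 2.5], bse=[1.0, 0.3]),
            make_fit("x+y", -100.0, 4, params=[0.0, 2.5, 1.0],
                     bse=[1.0, 0.3, 0.5]),
        ]
        tab = ic_table(fits, n=100)
        avg = model_average(tab, fits).set_index("term")
        assert avg.loc["x", "estimate"] == pytest.approx(2.5)
        assert avg.loc["x", "se"] == pytest.approx(0.3)
        assert avg.loc["x", "importance"] == pytest.approx(1.0)

    def test_term_only_in_weightless_model_shrinks_to_zero(self):
        fits = [
            make_fit("x", -10.0, 3, params=[0.0, 1.0], bse=[1.0, 0.1]),
            make_fit("y", -500.0, 3, params=[0.0, 9.9], bse=[1.0, 0.1]),
        ]
        tab = ic_table(fits, n=100)
        avg = model_average(tab, fits).set_index("term")
        assert avg.loc["y", "estimate"] == pytest.approx(0.0, abs=1e-12)
        assert avg.loc["y", "importance"] == pytest.approx(0.0, abs=1e-12)

    def test_three_model_hand_computed_average(self):
        # weights: deltas (0, 2, 4) -> w = (0.7040, 0.2590, 0.0953)
        fits = [
            make_fit("x", -50.0, 3, params=[0.0, 1.0], bse=[1.0, 0.2]),
            make_fit("x+y", -50.0, 4, params=[0.0, 2.0, 0.5],
                     bse=[1.0, 0.4, 0.1], n=0),
            make_fit("y", -50.0, 5, params=[0.0, 0.8], bse=[1.0, 0.3]),
        ]
        # force the deltas by giving identical logLik but different K
        tab = ic_table(fits, n=10**9, criterion="aic")
        w = np.exp(np.array([0.0, -1.0, -2.0]))
        w = w / w.sum()
        beta_bar = w[0] * 1.0 + w[1] * 2.0 + w[2] * 0.0
        se_bar = (
            w[0] * np.sqrt(0.2**2 + (1.0 - beta_bar) ** 2)
            + w[1] * np.sqrt(0.4**2 + (2.0 - beta_bar) ** 2)
            + w[2] * np.sqrt(0.0 + beta_bar**2)
        )
        avg = model_average(tab, fits).set_index("term")
        assert avg.loc["x", "estimate"] == pytest.approx(beta_bar, abs=1e-12)
        assert avg.loc["x", "se"] == pytest.approx(se_bar, abs=1e-12)
        assert avg.loc["x", "importance"] == pytest.approx(w[0] + w[1])

    def test_ci_contains_estimate(self):
        fits = [make_fit("x", -10.0, 3, params=[0.0, 1.2], bse=[1.0, 0.4])]
        avg = model_average(ic_table(fits, n=100), fits).set_index("term")
        assert avg.loc["x", "lower"] < avg.loc["x", "estimate"] < avg.loc["x", "upper"]

    def test_selection_uncertainty_trigger(self):
        certain = ic_table([make_fit("A", -10.0, 2),
                            make_fit("B", -40.0, 2)], n=100)
        uncertain = ic_table([make_fit("A", -10.0, 2),
                              make_fit("B", -10.5, 2)], n=100)
        assert not selection_uncertain(certain)
        assert selection_uncertain(uncertain)


class TestSelectionConsistency:
    def test_true_model_wins_most_replicates(self):
        # strong C_gt1m effect; true model should top the set usually
        rng = np.random.default_rng(42)
        wins = 0
        reps = 30
        for _ in range(reps):
            n = 150
            cov = pd.DataFrame({
                "C_gt1m": rng.uniform(0, 100, n),
                "C10_40": rng.uniform(0, 20, n),
                "BD": rng.uniform(0, 300, n),
                "Atden": rng.uniform(0, 150, n),
                "Emden": rng.uniform(0, 150, n),
                "Poa": rng.uniform(0, 50, n),
                "Tetra": rng.uniform(0, 30, n),
                "Rhag": rng.uniform(0, 20, n),
            })
            mu = np.exp(0.5 + 0.02 * cov["C_gt1m"])
            theta = 2.0
            y = rng.negative_binomial(theta, theta / (theta + mu))
            fits = [fit_nb_glm(s, y, cov) for s in candidate_sets("black_rat")]
            tab = ic_table(fits, n=n)
            wins += tab["Model"].iloc[0] == "C_gt1m"
        assert wins / reps >= 0.8
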