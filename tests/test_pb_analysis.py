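"""Transformation rule, effect estimation, significance limits, equations."""

import math

import numpy as np
import pytest

from _oracles import normal_equations, t_quantile
from lycoscreen.errors import AnalysisError, DataError, SaturationError
from lycoscreen.pb_analysis import (
    Transformation,
    choose_transformation,
    coded_equation,
    estimate_effects,
    format_coefficient,
    pareto_data,
    significance_limits,
)
from lycoscreen.pb_design import Factor, assign_factors, pb_matrix

# term sets of the printed reduced models (letters absent from the published
# coded equations are pooled into error)
T1_BIOMASS_TERMS = list("ABCDEGHJKLMNOQRSTUVWX")
T1_LYCOPENE_TERMS = list("ABCDEGHJKLMNOPQRTUVWX")
T4_LYCOPENE_TERMS = list("ABDEFGJKLMNPQRSTUVWX")


def small_design(n=12, k=11, seed=3):
    factors = [Factor(chr(65 + i), low_level=0.0, high_level=1.0)
               for i in range(k)]
    return assign_factors(pb_matrix(n), factors, seed=seed)


class TestChooseTransformation:
    def test_moderate_ratio_keeps_identity(self, table4):
        t = choose_transformation(table4.response("Biomass"))
        assert t.kind == "identity"  # max/min 3.91

    def test_zeros_with_wide_ratio_forces_sqrt(self, table1):
        t = choose_transformation(table1.response("Lycopene"))
        assert t.kind == "sqrt"

    def test_wide_positive_ratio_selects_log10(self, table4):
        t = choose_transformation(table4.response("Lycopene"))
        assert t.kind == "log10"  # max/min 23.29, all positive

    def test_override_is_validated(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert choose_transformation(y, "sqrt").kind == "sqrt"
        with pytest.raises(DataError):
            choose_transformation(y, "log10")  # zeros are never offset

    def test_negative_responses_rejected(self):
        with pytest.raises(DataError):
            choose_transformation(np.array([1.0, -0.5]))


class TestEstimateEffects:
    def test_table1_biomass_reproduces_printed_equation(self, table1):
        a = estimate_effects(table1, "Biomass", Transformation("sqrt"))
        assert a.intercept == pytest.approx(2.24, abs=0.005)
        assert a.coefficients["A"] == pytest.approx(-0.38, abs=0.005)
        assert a.coefficients["O"] == pytest.approx(0.37, abs=0.005)
        assert a.effects["A"] == pytest.approx(2 * a.coefficients["A"])

    def test_table1_lycopene_intercept(self, table1):
        a = estimate_effects(table1, "Lycopene", Transformation("sqrt"))
        assert a.intercept == pytest.approx(0.75, abs=0.005)
        assert a.coefficients["A"] == pytest.approx(-0.52, abs=0.005)

    def test_table4_lycopene_grand_mean(self, table4):
        a = estimate_effects(table4, "Lycopene", Transformation("log10"))
        assert a.intercept == pytest.approx(1.10, abs=0.005)

    def test_constant_response_gives_zero_effects(self):
        d = small_design()
        d.responses["const"] = np.full(12, 9.0)
        a = estimate_effects(d, "const", Transformation("identity"))
        assert a.intercept == pytest.approx(9.0)
        assert all(e == pytest.approx(0.0) for e in a.effects.values())

    @pytest.mark.parametrize("response", ["Biomass", "Lycopene"])
    def test_contrasts_equal_least_squares_oracle(self, table1, response):
        """Half-effects equal normal-equation coefficients of [1 | X]."""
        t = Transformation("sqrt")
        a = estimate_effects(table1, response, t)
        y = t.apply(table1.response(response))
        x = np.column_stack([np.ones(24), table1.coded_matrix.astype(float)])
        beta = normal_equations(x, y)
        assert a.intercept == pytest.approx(beta[0], abs=1e-10)
        for j, label in enumerate(table1.factor_labels):
            assert a.coefficients[label] == pytest.approx(beta[j + 1], abs=1e-10)

    def test_run_order_permutation_invariance(self, table1):
        rng = np.random.default_rng(5)
        perm = rng.permutation(24)
        shuffled = small_design(24, 23, seed=0)
        shuffled.coded_matrix = table1.coded_matrix[perm]
        shuffled.factors = table1.factors
        shuffled.responses = {"Biomass": table1.response("Biomass")[perm]}
        a = estimate_effects(table1, "Biomass", Transformation("sqrt"))
        b = estimate_effects(shuffled, "Biomass", Transformation("sqrt"))
        for label in a.coefficients:
            assert a.coefficients[label] == pytest.approx(
                b.coefficients[label], abs=1e-12
            )

    def test_linearity_at_all_plus_corner(self):
        d = small_design()
        rng = np.random.default_rng(11)
        d.responses["y"] = rng.uniform(1, 5, size=12)
        a = estimate_effects(d, "y", Transformation("identity"))
        # prediction at the all-+1 corner is intercept + sum of coefficients
        pred = a.intercept + sum(a.coefficients.values())
        x = np.column_stack([np.ones(12), d.coded_matrix.astype(float)])
        beta = normal_equations(x, d.responses["y"])
        assert pred == pytest.approx(beta.sum(), abs=1e-9)


class TestSignificanceLimits:
    def test_limits_match_integrated_t_quantiles(self, table4):
        a = estimate_effects(table4, "Lycopene", Transformation("log10"))
        a = significance_limits(a, table4, selected_terms=T4_LYCOPENE_TERMS)
        assert a.residual_df == 3
        m = 23
        assert a.t_limit == pytest.approx(t_quantile(0.025, 3), abs=1e-4)
        assert a.bonferroni_limit == pytest.approx(
            t_quantile(0.025 / m, 3), abs=1e-3
        )
        assert a.bonferroni_limit >= a.t_limit

    def test_df5_m20_quantiles(self):
        d = small_design(24, 20, seed=9)
        rng = np.random.default_rng(2)
        d.responses["y"] = rng.uniform(1, 3, 24)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=list("ABCDEFGHJKLMNOPQRS"))
        assert a.residual_df == 5
        assert a.t_limit == pytest.approx(t_quantile(0.025, 5), abs=1e-4)
        assert a.bonferroni_limit == pytest.approx(
            t_quantile(0.025 / 20, 5), abs=1e-3
        )

    def test_single_candidate_bonferroni_equals_t_limit(self):
        d = small_design(8, 1, seed=0)
        rng = np.random.default_rng(3)
        d.responses["y"] = rng.uniform(1, 2, 8)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=["A"])
        assert a.bonferroni_limit == pytest.approx(a.t_limit)

    def test_noise_free_response_classified_certain(self):
        d = small_design()
        x_a = d.column("A").astype(float)
        d.responses["y"] = 5.0 + 2.0 * x_a  # exactly spanned by {1, A}
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=["A"])
        assert a.t_values["A"] == math.inf
        assert a.classification["A"] == "certain"
        assert a.t_values["B"] == 0.0

    def test_saturated_selection_raises(self, table1):
        a = estimate_effects(table1, "Biomass", Transformation("sqrt"))
        with pytest.raises(SaturationError):
            significance_limits(a, table1, selected_terms=table1.factor_labels)

    def test_auto_k_pools_smallest_effects(self, table1):
        a = estimate_effects(table1, "Biomass", Transformation("sqrt"))
        a = significance_limits(a, table1, auto_k=2)
        # F and P have the smallest |effects| in this response
        assert set(table1.factor_labels) - set(a.selected_terms) == {"F", "P"}
        assert a.residual_df == 2

    def test_classification_never_contradicts_limits(self, table1):
        a = estimate_effects(table1, "Lycopene", Transformation("sqrt"))
        a = significance_limits(a, table1, selected_terms=T1_LYCOPENE_TERMS)
        for label, t in a.t_values.items():
            cls = a.classification[label]
            if cls == "certain":
                assert t >= a.bonferroni_limit
            elif cls == "possible":
                assert a.t_limit <= t < a.bonferroni_limit
            else:
                assert t < a.t_limit


class TestEquationAndPareto:
    def test_table1_biomass_equation_prefix(self, table1):
        a = estimate_effects(table1, "Biomass", Transformation("sqrt"))
        a = significance_limits(a, table1, selected_terms=T1_BIOMASS_TERMS)
        eq = coded_equation(a)
        assert eq.startswith("Sqrt(Biomass) = 2.24 - 0.38 × A")
        assert "× F" not in eq and "× P" not in eq  # pooled terms absent

    def test_intercept_only_model(self):
        d = small_design()
        d.responses["y"] = np.full(12, 4.0)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=[])
        assert coded_equation(a) == "y = 4.00"

    def test_small_coefficients_rendered_scientific(self):
        assert format_coefficient(5.397e-4) == "5.397e-004"
        assert format_coefficient(0.055) == "0.06"
        assert format_coefficient(-0.38) == "0.38"

    def test_pareto_ranked_by_t_with_design_order_ties(self):
        d = small_design()
        x_a, x_b = d.column("A").astype(float), d.column("B").astype(float)
        rng = np.random.default_rng(8)
        d.responses["y"] = 10 - 4 * x_a + 2 * x_b + rng.normal(0, 0.5, 12)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=["A", "B"])
        ranked = pareto_data(a)
        assert ranked[0][0] == "A" and ranked[1][0] == "B"

    def test_planted_effect_ranks_first_and_certain(self):
        """One large planted effect dominates an otherwise-noise design."""
        d = small_design()
        x_c = d.column("C").astype(float)
        rng = np.random.default_rng(21)
        d.responses["y"] = 3.0 + 1.0 * x_c + rng.normal(0, 0.01, 12)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, selected_terms=["C"])
        ranked = pareto_data(a)
        assert ranked[0][0] == "C"
        assert a.classification["C"] == "certain"

    def test_all_zero_effects_all_insignificant(self):
        d = small_design()
        rng = np.random.default_rng(13)
        d.responses["y"] = 5.0 + rng.normal(0, 1.0, 12)
        a = estimate_effects(d, "y", Transformation("identity"))
        a = significance_limits(a, d, auto_k=6)
        assert pareto_data(a)  # stable, defined order
        # with pure noise nothing should clear the Bonferroni limit
        assert all(c != "certain" for c in a.classification.values())


class TestParameterRecovery:
    def test_mean_absolute_coefficient_error_within_clt_bound(self):
        """Over 200 replicates the mean |coef error| stays under 3*sigma/sqrt(n)."""
        d = small_design()
        sigma = 0.5
        beta = {"A": 1.0, "B": -0.7, "C": 0.3}
        x = d.coded_matrix.astype(float)
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(200):
            y = 2.0 + sum(b * d.column(l) for l, b in beta.items())
            y = y + rng.normal(0, sigma, 12)
            d.responses["y"] = y
            a = estimate_effects(d, "y", Transformation("identity"))
            errs.extend(
                abs(a.coefficients[l] - beta.get(l, 0.0))
                for l in d.factor_labels
            )
        assert np.mean(errs) <= 3 * sigma / math.sqrt(12)
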