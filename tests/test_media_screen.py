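"""Growth-pinned target optimization, supplement scanning and the C/N filter."""

import math

import numpy as np
import pytest

from _oracles import brute_force_lp
from lycoscreen.errors import DataError, MappingError, StateError
from lycoscreen.gsmn import fba, set_exchange_bound
from lycoscreen.media_screen import (
    MediumComponent,
    ScreenSettings,
    cn_filter,
    max_growth,
    medium_cn_ratio,
    negative_flux_exchanges,
    supplement_scan,
    target_flux_at_growth,
)

MINIMAL_MEDIUM = [
    MediumComponent("glucose", "EX_substrate", 20.0, formula="C6H12O6",
                    category="carbon_source"),
    MediumComponent("ammonium sulfate", "", 3.0, formula="(NH4)2SO4",
                    category="nitrogen_source"),
    MediumComponent("KH2PO4", "", 2.0, formula="KH2PO4", category="salt"),
]


class TestGrowthAndTarget:
    def test_max_growth_closed_form(self, toy_model):
        model, guarantees = toy_model
        assert max_growth(model) == pytest.approx(guarantees.max_growth, abs=1e-8)

    def test_growth_pinned_to_zero_gives_unconstrained_target(self, toy_model):
        model, guarantees = toy_model
        sol = target_flux_at_growth(model, ScreenSettings(), growth_rate=0.0)
        assert sol.objective_value == pytest.approx(
            guarantees.target_at_fraction(0.0), abs=1e-8
        )

    def test_target_at_fraction_matches_hand_lp(self, toy_model):
        """Closed form and vertex enumeration agree with the pinned-growth LP."""
        model, guarantees = toy_model
        sol = target_flux_at_growth(model, ScreenSettings(growth_fraction=0.9))
        assert sol.fluxes["GROWTH"] == pytest.approx(0.9 * guarantees.max_growth)
        assert sol.objective_value == pytest.approx(
            guarantees.target_at_fraction(0.9), abs=1e-8
        )
        pinned = model.copy()
        g = pinned.reaction("GROWTH")
        g.lower_bound = g.upper_bound = 0.9 * guarantees.max_growth
        s, _, rxn_ids = pinned.stoichiometric_matrix()
        lb = np.array([r.lower_bound for r in pinned.reactions])
        ub = np.array([r.upper_bound for r in pinned.reactions])
        c = np.zeros(len(rxn_ids)); c[rxn_ids.index("FPP_SYNTH")] = 1.0
        assert brute_force_lp(s, lb, ub, c) == pytest.approx(
            sol.objective_value, abs=1e-7
        )

    def test_full_growth_leaves_no_more_target_than_slack_growth(self, toy_model):
        model, _ = toy_model
        tight = target_flux_at_growth(model, ScreenSettings(growth_fraction=1.0))
        slack = target_flux_at_growth(model, ScreenSettings(growth_fraction=0.9))
        assert tight.objective_value <= slack.objective_value + 1e-9


class TestNegativeFluxExchanges:
    def test_definition_ordering(self, toy_model):
        model, _ = toy_model
        sol = fba(model, "GROWTH")
        sol.fluxes = dict(sol.fluxes)
        sol.fluxes.update({"EX_substrate": -1.8, "EX_o2": -3.0, "EX_fpp": 2.0})
        out = negative_flux_exchanges(sol, model, ScreenSettings())
        ids = [rid for rid, _ in out]
        assert ids.index("EX_o2") < ids.index("EX_substrate")
        assert "EX_fpp" not in ids

    def test_rounding_noise_treated_as_zero(self, toy_model):
        """Magnitudes like -8.05e-35 are LP rounding errors, not uptake."""
        model, _ = toy_model
        sol = fba(model, "GROWTH")
        sol.fluxes = {r.id: 0.0 for r in model.reactions}
        sol.fluxes["EX_o2"] = -8.05e-35
        sol.fluxes["EX_l_isoleucine"] = -1.46e-13
        assert negative_flux_exchanges(sol, model, ScreenSettings()) == []

    def test_all_zero_fluxes(self, toy_model):
        model, _ = toy_model
        sol = fba(model, "GROWTH")
        sol.fluxes = {r.id: 0.0 for r in model.reactions}
        assert negative_flux_exchanges(sol, model, ScreenSettings()) == []

    def test_requires_optimal_solution(self, toy_model):
        model, _ = toy_model
        sol = fba(model, "GROWTH")
        sol.status = "infeasible"
        with pytest.raises(StateError):
            negative_flux_exchanges(sol, model, ScreenSettings())


class TestSupplementScan:
    def test_deltas_equal_planted_gains(self, toy_model, toy_cands):
        model, guarantees = toy_model
        results = supplement_scan(model, toy_cands, ScreenSettings())
        by_id = {r.exchange_reaction_id: r for r in results}
        for name in guarantees.boosts:
            rid = "EX_" + name.replace("-", "_")
            assert by_id[rid].delta == pytest.approx(
                guarantees.boost_delta(name), abs=1e-8
            )
            assert by_id[rid].supplement_flux == pytest.approx(
                guarantees.boosts[name][0], abs=1e-8
            )

    def test_ranking_matches_per_candidate_hand_lp(self, toy_model, toy_cands):
        model, guarantees = toy_model
        results = supplement_scan(model, toy_cands, ScreenSettings())
        expected_order = sorted(
            guarantees.boosts, key=lambda n: -guarantees.boost_delta(n)
        )
        got_order = [
            r.exchange_reaction_id.removeprefix("EX_").replace("_", "-")
            for r in results
        ]
        assert got_order == expected_order

    def test_relaxation_monotonicity_invariant(self, toy_model, toy_cands):
        model, _ = toy_model
        for r in supplement_scan(model, toy_cands, ScreenSettings()):
            assert r.relaxed_target_flux >= r.baseline_target_flux - 1e-6
            assert r.delta == pytest.approx(
                r.relaxed_target_flux - r.baseline_target_flux
            )

    def test_already_open_bound_is_noop(self, toy_model, toy_cands):
        model, _ = toy_model
        opened = set_exchange_bound(model, "EX_l_isoleucine", -5.0)
        results = supplement_scan(opened, toy_cands, ScreenSettings())
        ile = next(r for r in results
                   if r.exchange_reaction_id == "EX_l_isoleucine")
        assert ile.bound_used == -5.0  # never tightened back to -2
        assert ile.delta == pytest.approx(0.0, abs=1e-9)

    def test_empty_and_duplicated_candidates(self, toy_model, toy_cands):
        model, _ = toy_model
        assert supplement_scan(model, [], ScreenSettings()) == []
        doubled = supplement_scan(model, toy_cands + toy_cands, ScreenSettings())
        single = supplement_scan(model, toy_cands, ScreenSettings())
        assert len(doubled) == 2 * len(single)
        assert doubled[0].delta == doubled[1].delta  # statelessness

    def test_unmapped_candidate_listed_in_error(self, toy_model):
        model, _ = toy_model
        ghost = MediumComponent("serine", "EX_no_such", category="amino_acid")
        with pytest.raises(MappingError, match="serine"):
            supplement_scan(model, [ghost], ScreenSettings())


class TestCNRatio:
    def test_minimal_medium_hand_arithmetic(self):
        # 20/180.16*6 mol C vs 3/132.14*2 mol N
        expected = (20 / 180.156 * 6) / (3 / 132.134 * 2)
        assert medium_cn_ratio(MINIMAL_MEDIUM) == pytest.approx(expected, rel=1e-3)
        assert medium_cn_ratio(MINIMAL_MEDIUM) == pytest.approx(14.7, abs=0.1)

    def test_salts_only_is_infinite(self):
        salts = [MediumComponent("KH2PO4", "", 2.0, formula="KH2PO4",
                                 category="salt")]
        assert medium_cn_ratio(salts) == math.inf

    def test_glycine_forced_ratio(self):
        gly = [MediumComponent("glycine", "", 7.5, formula="C2H5NO2",
                               category="amino_acid")]
        assert medium_cn_ratio(gly) == pytest.approx(2.0, abs=1e-12)

    def test_missing_molar_mass_raises(self):
        bad = MediumComponent("mystery", "", 1.0, category="other")
        bad.formula = {"C": 1, "N": 1}  # formula present, mass never derived
        bad.molar_mass = None
        with pytest.raises(DataError, match="mystery"):
            medium_cn_ratio([bad])


class TestCNFilter:
    def test_zero_uptake_flag_equals_base_medium_test(self, toy_model, toy_cands):
        model, _ = toy_model
        results = supplement_scan(model, toy_cands, ScreenSettings())
        for r in results:
            r.supplement_flux = 0.0
        flagged = cn_filter(results, MINIMAL_MEDIUM, toy_cands, ScreenSettings())
        base_ok = medium_cn_ratio(MINIMAL_MEDIUM) > 10
        assert all(r.passes_cn_filter == base_ok for r in flagged)

    def test_nitrogen_free_candidate_always_passes(self, toy_model, toy_cands):
        model, _ = toy_model
        cands = [MediumComponent("succinate", "EX_l_valine", 0.0,
                                 formula="C4H6O4", category="cofactor")]
        results = supplement_scan(model, cands, ScreenSettings())
        flagged = cn_filter(results, MINIMAL_MEDIUM, cands, ScreenSettings())
        assert all(r.passes_cn_filter for r in flagged)

    def test_high_nitrogen_dose_fails(self, toy_model, toy_cands):
        """A nitrogen-rich supplement at a large dose drags C/N below 10."""
        model, _ = toy_model
        results = supplement_scan(model, toy_cands, ScreenSettings())
        # hand arithmetic: forcing a huge dose via override must sink the ratio
        overrides = {c.name: 50.0 for c in toy_cands}  # 50 g/L of amino acid
        flagged = cn_filter(results, MINIMAL_MEDIUM, toy_cands, ScreenSettings(),
                            dose_overrides=overrides)
        aug = MINIMAL_MEDIUM + [MediumComponent(
            "l-isoleucine", "x", 50.0, formula="C6H13NO2", category="amino_acid")]
        assert medium_cn_ratio(aug) < 10
        ile = next(r for r in flagged
                   if r.exchange_reaction_id == "EX_l_isoleucine")
        assert not ile.passes_cn_filter

    def test_small_scan_doses_keep_base_verdict(self, toy_model, toy_cands):
        model, _ = toy_model
        results = supplement_scan(model, toy_cands, ScreenSettings())
        flagged = cn_filter(results, MINIMAL_MEDIUM, toy_cands, ScreenSettings())
        # mmol-scale uptake doses barely move a 14.7 baseline ratio
        assert all(r.passes_cn_filter for r in flagged)
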