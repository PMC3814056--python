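"""FBA, FVA, linear MOMA, gene deletion, and flux-span classification."""

import numpy as np
import pandas as pd
import pytest

from tisnet.flux_analysis import (
    FvaResult,
    InfeasibleProblemError,
    LpData,
    fba,
    flux_span_ratio,
    fva,
    linear_moma,
    single_gene_deletion,
)
from tisnet.model_core import apply_knockout, toy9

from .conftest import random_model


class TestFba:
    def test_uptake_limited_optimum(self, toy):
        result = fba(toy)
        assert result.status == "optimal"
        assert result.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_lethal_knockout(self, toy):
        result = fba(apply_knockout(toy, {"g1"}))
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_forced_uptake_without_consumer_is_infeasible(self, toy):
        ex = toy.reaction("EX_A")
        ex.lower_bound = ex.upper_bound = -5.0
        result = fba(apply_knockout(toy, {"g1"}))
        assert result.status == "infeasible"
        assert result.fluxes is None

    def test_solution_satisfies_constraints(self):
        """Optimal fluxes respect S v = 0 (1e-6) and bounds (1e-9)."""
        for seed in range(15):
            model = random_model(seed)
            lp = LpData(model)
            result = fba(model, lp=lp)
            assert result.ok
            v = np.array([result.fluxes[r] for r in lp.reaction_ids])
            assert np.abs(lp.S @ v).max() < 1e-6
            assert (v >= lp.lb - 1e-9).all() and (v <= lp.ub + 1e-9).all()


class TestFva:
    def test_unconstrained_intervals(self, toy):
        result = fva(toy, fraction=0.0)
        assert result.intervals["R3"] == pytest.approx((0.0, 10.0))
        assert result.intervals["EX_D"] == pytest.approx((0.0, 10.0))
        assert result.intervals["BIOMASS"] == pytest.approx((0.0, 10.0))

    def test_optimum_forces_all_carbon_to_biomass(self, toy):
        result = fva(toy, fraction=1.0)
        assert result.intervals["R3"] == pytest.approx((0.0, 0.0), abs=1e-7)
        assert result.intervals["R1"] == pytest.approx((10.0, 10.0), abs=1e-7)
        assert result.intervals["EX_A"] == pytest.approx((-10.0, -10.0), abs=1e-7)

    def test_knocked_reaction_pinned_to_zero(self, toy):
        result = fva(apply_knockout(toy, {"g4"}), fraction=0.0)
        assert result.intervals["R3"] == (0.0, 0.0)

    def test_intervals_respect_bounds_and_contain_optimum(self, toy):
        opt = fba(toy).objective_value
        for fraction in (0.0, 0.5, 1.0):
            result = fva(toy, fraction=fraction)
            for rid, (lo, hi) in result.intervals.items():
                rxn = toy.reaction(rid)
                assert rxn.lower_bound - 1e-9 <= lo <= hi <= rxn.upper_bound + 1e-9
        lo0, hi0 = fva(toy, fraction=0.0).intervals["BIOMASS"]
        assert lo0 - 1e-7 <= opt <= hi0 + 1e-7
        lo1, _ = fva(toy, fraction=1.0).intervals["BIOMASS"]
        assert lo1 == pytest.approx(opt, abs=1e-7)

    def test_reaction_subset_and_bad_fraction(self, toy):
        result = fva(toy, reactions=["R1"])
        assert set(result.intervals) == {"R1"}
        with pytest.raises(ValueError):
            fva(toy, fraction=1.5)

    def test_infeasible_base_problem_raises(self, toy):
        ex = toy.reaction("EX_A")
        ex.lower_bound = ex.upper_bound = -5.0
        with pytest.raises(InfeasibleProblemError):
            fva(apply_knockout(toy, {"g1"}), fraction=0.0)


class TestMoma:
    def test_blocked_chain_distance(self, toy, toy_wt_flux):
        result = linear_moma(apply_knockout(toy, {"g2", "g3"}), toy_wt_flux)
        assert result.ok
        assert result.distance == pytest.approx(40.0, abs=1e-7)
        assert result.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_wild_type_still_feasible(self, toy, toy_wt_flux):
        result = linear_moma(apply_knockout(toy, {"g6"}), toy_wt_flux)
        assert result.distance == pytest.approx(0.0, abs=1e-9)
        assert result.objective_value == pytest.approx(10.0, abs=1e-7)

    def test_zero_flux_reaction_knockout(self, toy, toy_wt_flux):
        result = linear_moma(apply_knockout(toy, {"g4"}), toy_wt_flux)
        assert result.distance == pytest.approx(0.0, abs=1e-9)

    def test_growth_bounded_by_fba(self, toy, toy_wt_flux):
        """MOMA growth never exceeds the knockout model's FBA optimum, and
        distance is zero iff the wild-type flux stays feasible."""
        for genes in ({"g2"}, {"g2", "g3"}, {"g4"}, {"g6"}, {"g1"}):
            ko = apply_knockout(toy, genes)
            moma = linear_moma(ko, toy_wt_flux)
            assert moma.objective_value <= fba(ko).objective_value + 1e-7
            disabled = {r.id for r in ko.reactions if r.upper_bound == 0.0 == r.lower_bound}
            wt_feasible = all(toy_wt_flux[r] == 0.0 for r in disabled)
            assert (moma.distance < 1e-7) == wt_feasible

    def test_missing_reactions_rejected(self, toy):
        with pytest.raises(ValueError):
            linear_moma(toy, {"R1": 1.0})


class TestDeletion:
    @pytest.mark.parametrize("method", ["FBA", "MOMA"])
    def test_toy_verdicts(self, toy, method):
        table = single_gene_deletion(toy, ["g1", "g2", "g4", "g6"], method=method)
        verdicts = dict(zip(table["gene"], table["verdict"]))
        assert verdicts == {"g1": "lethal", "g2": "nonlethal", "g4": "nonlethal",
                            "g6": "nonlethal"}
        ratios = dict(zip(table["gene"], table["ratio"]))
        assert ratios["g1"] == pytest.approx(0.0, abs=1e-9)
        assert ratios["g2"] == pytest.approx(1.0, abs=1e-7)

    def test_empty_gene_list(self, toy):
        table = single_gene_deletion(toy, [])
        assert table.empty

    def test_absent_gene_reported_nonlethal(self, toy):
        table = single_gene_deletion(toy, ["not_a_gene"])
        assert table["ratio"].item() == 1.0
        assert table["verdict"].item() == "nonlethal"

    def test_knockout_monotonicity_random_networks(self):
        """Knocking out a superset of genes never raises the FBA optimum."""
        rng = np.random.default_rng(11)
        checked = 0
        for seed in range(80):
            model = random_model(seed, with_gprs=True)
            genes = sorted(model.genes)
            if len(genes) < 3:
                continue
            g = set(rng.choice(genes, size=1))
            h = g | set(rng.choice(genes, size=2, replace=False))
            opt_g = fba(apply_knockout(model, g)).objective_value
            opt_h = fba(apply_knockout(model, h)).objective_value
            assert opt_h <= opt_g + 1e-7
            checked += 1
            if checked >= 50:
                break
        assert checked >= 50


class TestFluxSpans:
    def test_span_collapse_is_type_three(self):
        frame = flux_span_ratio(
            FvaResult({"R": (0.0, 10.0)}), FvaResult({"R": (0.0, 0.0)})
        )
        row = frame.iloc[0]
        assert (row.f_wt, row.f_ko, row.ratio) == (10.0, 0.0, 0.0)
        assert row.alteration_class == "type_III"

    def test_identity_is_unchanged(self):
        frame = flux_span_ratio(
            FvaResult({"R": (0.0, 10.0)}), FvaResult({"R": (0.0, 10.0)})
        )
        assert frame.iloc[0].ratio == 1.0
        assert frame.iloc[0].alteration_class == "unchanged"

    def test_widened_span_is_type_one(self):
        frame = flux_span_ratio(
            FvaResult({"R": (0.0, 2.0)}), FvaResult({"R": (-3.0, 2.0)})
        )
        row = frame.iloc[0]
        assert (row.f_wt, row.f_ko, row.ratio) == (2.0, 5.0, 2.5)
        assert row.alteration_class == "type_I"

    @pytest.mark.parametrize(
        "wt, ko, expected",
        [
            ((0.0, 10.0), (0.0, 4.0), "type_II"),     # 0 < r < 0.5
            ((0.0, 10.0), (0.0, 5.0), "unchanged"),   # r = 0.5 boundary
            ((0.0, 10.0), (0.0, 20.0), "unchanged"),  # r = 2 boundary
            ((0.0, 10.0), (0.0, 21.0), "type_I"),
            ((0.0, 0.0), (0.0, 3.0), "novel"),
            ((0.0, 0.0), (0.0, 0.0), "unchanged"),
        ],
    )
    def test_class_boundaries(self, wt, ko, expected):
        frame = flux_span_ratio(FvaResult({"R": wt}), FvaResult({"R": ko}))
        assert frame.iloc[0].alteration_class == expected

    def test_novel_ratio_is_missing(self):
        frame = flux_span_ratio(FvaResult({"R": (0.0, 0.0)}), FvaResult({"R": (0.0, 3.0)}))
        assert pd.isna(frame.iloc[0].ratio)

    def test_swapping_conditions_inverts_ratio(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            a = tuple(sorted(rng.uniform(-5, 5, 2)))
            b = tuple(sorted(rng.uniform(-5, 5, 2)))
            fwd = flux_span_ratio(FvaResult({"R": a}), FvaResult({"R": b})).iloc[0]
            rev = flux_span_ratio(FvaResult({"R": b}), FvaResult({"R": a})).iloc[0]
            if fwd.f_wt > 0 and fwd.f_ko > 0:
                assert rev.ratio == pytest.approx(1.0 / fwd.ratio)

    def test_mismatched_reactions_rejected(self):
        with pytest.raises(ValueError):
            flux_span_ratio(FvaResult({"R": (0, 1)}), FvaResult({"Q": (0, 1)}))
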