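"""PDG, degree statistics, enrichment, DEG profiling, and target ranking."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tisnet.comparison import (
    bh_adjust,
    deg_perturbation_profile,
    degree_distribution,
    degree_histogram_slope,
    enrich,
    hypergeometric_tail,
    pair_different_genes,
    similar_flux_targets,
)
from tisnet.model_core import GprRule, toy9


def annotation_frame(pairs):
    return pd.DataFrame(
        [(g, t, f"name {t}") for g, t in pairs], columns=["gene", "term", "term_name"]
    )


def deg_frame(genes):
    return pd.DataFrame(
        [(g, 2.0, 2.0) for g in genes], columns=["gene", "fc_glomeruli", "fc_tubuli"]
    )


class TestPdg:
    def test_set_difference(self, toy):
        other = toy.copy()
        other.reaction("R1").gpr = GprRule("g9")
        a_only, b_only = pair_different_genes(toy, other)
        assert (a_only, b_only) == ({"g1"}, {"g9"})

    def test_identity_and_disjoint(self, toy):
        assert pair_different_genes(toy, toy.copy()) == (set(), set())


class TestDegrees:
    def test_toy_histogram(self, toy):
        result = degree_distribution(toy)
        assert result["histogram"] == {1: 6}
        assert all(d == 1 for d in result["degrees"].values())
        assert math.isnan(result["slope"])  # single degree: slope undefined

    def test_shared_gene_counts_all_reactions(self, toy):
        model = toy.copy()
        model.reaction("R3").gpr = GprRule("g1")
        model.reaction("R5").gpr = GprRule("g1")
        result = degree_distribution(model)
        assert result["degrees"]["g1"] == 3

    def test_geometric_series_slope_is_minus_one(self):
        assert degree_histogram_slope({1: 8, 2: 4, 4: 2}) == pytest.approx(-1.0)

    def test_no_gprs(self, toy):
        for rxn in toy.reactions:
            rxn.gpr = GprRule("")
        result = degree_distribution(toy)
        assert result["histogram"] == {}
        assert math.isnan(result["slope"])


def exact_tail(N, K, n, k):
    """Exact-rational upper-tail hypergeometric by direct enumeration."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        total += Fraction(math.comb(K, i) * math.comb(N - K, n - i), math.comb(N, n))
    return total


class TestHypergeometric:
    def test_documented_value(self):
        assert hypergeometric_tail(10, 4, 5, 3) == pytest.approx(66 / 252, abs=1e-12)

    def test_matches_exact_enumeration_small_populations(self):
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        expected = float(exact_tail(N, K, n, k))
                        assert hypergeometric_tail(N, K, n, k) == pytest.approx(
                            expected, abs=1e-10
                        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            hypergeometric_tail(5, 6, 2, 1)


class TestBh:
    @staticmethod
    def reference_bh(p):
        """Hand-rolled step-up BH: q_(i) = min over j>=i of p_(j)*m/j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            idx = order[rank - 1]
            running = min(running, p[idx] * m / rank)
            q[idx] = running
        return q

    def test_documented_example(self):
        assert bh_adjust([0.001, 0.004, 0.03]) == pytest.approx([0.003, 0.006, 0.03])

    def test_matches_reference_on_random_vectors(self):
        rng = np.random.default_rng(13)
        for _ in range(200):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            assert bh_adjust(p) == pytest.approx(self.reference_bh(p), abs=1e-12)

    def test_q_dominates_p_and_is_monotone(self):
        rng = np.random.default_rng(14)
        for _ in range(50):
            p = rng.uniform(0, 1, 20)
            q = bh_adjust(p)
            assert (q >= p - 1e-12).all()
            order = np.argsort(p, kind="stable")
            assert (np.diff(q[order]) >= -1e-12).all()
            assert (q < 0.01).sum() <= (p < 0.01).sum()


class TestEnrich:
    def test_single_term(self):
        ann = annotation_frame([("a", "T1"), ("b", "T1"), ("c", "T1"), ("d", "T1")])
        universe = set("abcdefgh") | {"x", "y"}
        result = enrich({"a", "b", "c", "x", "y"}, ann, universe)
        row = result.iloc[0]
        assert (row.k, row.K, row.n, row.N) == (3, 4, 5, 10)
        assert row.p == pytest.approx(66 / 252)

    def test_empty_query_nothing_enriched(self):
        ann = annotation_frame([("a", "T1")])
        result = enrich(set(), ann, {"a", "b"})
        assert not result["enriched"].any()

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich(set(), annotation_frame([("a", "T1")]), set())

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            enrich({"z"}, annotation_frame([("a", "T1")]), {"a"})

    def test_null_annotation_rarely_enriched(self):
        """Shuffled labels keep the any-term false-enrichment rate at
        alpha=0.01 below 2% (smoke-scale version of the stochastic bound)."""
        rng = np.random.default_rng(99)
        universe = [f"g{i}" for i in range(60)]
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            ann = annotation_frame(
                [(g, f"T{t}") for t in range(15)
                 for g in rng.choice(universe, size=8, replace=False)]
            )
            query = set(rng.choice(universe, size=12, replace=False))
            result = enrich(query, ann, set(universe), alpha=0.01)
            hits += int(result["enriched"].any())
        assert hits / n_sim <= 0.02


class TestDegProfiles:
    def test_and_pair_gene_collapses_drain_branch(self, toy):
        result = deg_perturbation_profile(toy, deg_frame(["g4"]))
        summary = result["summary"].iloc[0]
        assert (summary.n_type_I, summary.n_type_II, summary.n_type_III) == (0, 0, 2)
        profile = result["profiles"]["g4"]
        type3 = set(profile.loc[profile["alteration_class"] == "type_III", "reaction"])
        assert type3 == {"R3", "EX_D"}

    def test_side_branch_gene(self, toy):
        result = deg_perturbation_profile(toy, deg_frame(["g6"]))
        profile = result["profiles"]["g6"].set_index("reaction")
        assert set(profile.index[profile["alteration_class"] == "type_III"]) == {"R5", "EX_E"}
        others = profile.drop(["R5", "EX_E"])
        assert (others["ratio"] == 1.0).all()

    def test_unmapped_deg_reported(self, toy):
        result = deg_perturbation_profile(toy, deg_frame(["g4", "zzz"]))
        assert result["unmapped"] == ["zzz"]
        assert set(result["profiles"]) == {"g4"}

    def test_zero_fold_change_rejected(self, toy):
        degs = pd.DataFrame([("g4", 0.0, 1.0)], columns=["gene", "fc_glomeruli", "fc_tubuli"])
        with pytest.raises(ValueError):
            deg_perturbation_profile(toy, degs)


class TestTargets:
    def test_and_partner_is_perfect_match(self, toy):
        ranking = similar_flux_targets(toy, "g4")
        top = ranking.iloc[0]
        assert (top["gene"], top["similarity"], top["rank"]) == ("g5", 1.0, 1)

    def test_lethal_reference_has_no_perfect_match(self, toy):
        ranking = similar_flux_targets(toy, "g1")
        assert (ranking["similarity"] < 1.0).all()

    def test_similarity_symmetric(self, toy):
        genes = sorted(toy.genes)
        for a in genes:
            for b in genes:
                if a >= b:
                    continue
                sim_ab = similar_flux_targets(toy, a).set_index("gene").loc[b, "similarity"]
                sim_ba = similar_flux_targets(toy, b).set_index("gene").loc[a, "similarity"]
                assert sim_ab == pytest.approx(sim_ba)

    def test_unknown_reference_rejected(self, toy):
        with pytest.raises(KeyError):
            similar_flux_targets(toy, "gX")
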