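from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from methstage.linmod import INTERSTAGE_PAIRS, STAGE_ORDER
from methstage.salience import (
    StageSalientCall,
    TierCriteria,
    consensus,
    direction,
    fisher_enrichment,
    stage_agnostic,
    tier1_dmgs,
    tier2_salience,
    topk_rank,
)


def make_contrasts(rows):
    """rows: gene -> (lfc per stage, adj_p). Returns stage->table."""
    out = {}
    for stage in STAGE_ORDER:
        data = {
            "lfc": {g: v[0][stage] for g, v in rows.items()},
            "adj_p": {g: v[1] for g, v in rows.items()},
            "p": {g: v[1] for g, v in rows.items()},
        }
        out[stage] = pd.DataFrame(data)
    return out


class TestTier1:
    def test_strong_gene_in_all_four_sets(self):
        lfcs = {"I": 2.28, "II": 2.19, "III": 2.16, "IV": 2.32}
        contrasts = make_contrasts({"gA": (lfcs, 1e-82)})
        sets = tier1_dmgs(contrasts)
        for stage in STAGE_ORDER:
            assert "gA" in sets[stage].index
            assert sets[stage].loc["gA", "direction"] == "Hyper"

    def test_lfc_below_threshold_excluded(self):
        contrasts = make_contrasts({"g": ({s: 1.9 for s in STAGE_ORDER}, 1e-10)})
        sets = tier1_dmgs(contrasts)
        assert all("g" not in sets[s].index for s in STAGE_ORDER)

    def test_p_above_threshold_excluded(self):
        contrasts = make_contrasts({"g": ({s: 2.5 for s in STAGE_ORDER}, 0.005)})
        sets = tier1_dmgs(contrasts)
        assert all("g" not in sets[s].index for s in STAGE_ORDER)

    def test_missing_contrast_rejected(self):
        contrasts = make_contrasts({"g": ({s: 2.5 for s in STAGE_ORDER}, 1e-5)})
        del contrasts["III"]
        with pytest.raises(ValueError, match="III"):
            tier1_dmgs(contrasts)


def make_interstage(pvals):
    """pvals: (a, b) -> p for gene 'g'."""
    return {
        pair: pd.DataFrame({"p": {"g": pvals.get(pair, 0.5)}}) for pair in INTERSTAGE_PAIRS
    }


class TestTier2:
    def test_all_three_contrasts_significant(self):
        inter = make_interstage({("I", "II"): 0.01, ("II", "III"): 0.03, ("II", "IV"): 0.001})
        assert tier2_salience("g", "II", inter)

    def test_one_nonsignificant_contrast_fails(self):
        inter = make_interstage({("I", "II"): 0.01, ("II", "III"): 0.2, ("II", "IV"): 0.001})
        assert not tier2_salience("g", "II", inter)

    def test_boundary_p_is_not_salient(self):
        inter = make_interstage({("I", "II"): 0.05, ("II", "III"): 0.01, ("II", "IV"): 0.01})
        assert not tier2_salience("g", "II", inter)

    def test_unknown_gene_fails_closed(self):
        inter = make_interstage({})
        assert not tier2_salience("absent", "II", inter)


class TestTopkRank:
    def test_truncates_to_k(self, rng):
        tab = pd.DataFrame(
            {"lfc": rng.normal(size=150), "adj_p": rng.uniform(size=150)},
            index=[f"g{i}" for i in range(150)],
        )
        assert len(topk_rank(tab, k=100)) == 100

    def test_tie_broken_by_abs_lfc(self):
        tab = pd.DataFrame(
            {"lfc": [2.5, 3.1], "adj_p": [0.001, 0.001]}, index=["small", "big"]
        )
        assert list(topk_rank(tab, k=2).index) == ["big", "small"]

    def test_matches_brute_force_sort(self, rng):
        n = 60
        tab = pd.DataFrame(
            {
                "lfc": rng.normal(size=n),
                "adj_p": rng.choice([1e-5, 1e-4, 1e-3], size=n),
            },
            index=[f"g{i}" for i in range(n)],
        )
        got = list(topk_rank(tab, k=20).index)
        expected = sorted(
            tab.index, key=lambda g: (tab.loc[g, "adj_p"], -abs(tab.loc[g, "lfc"]), g)
        )[:20]
        assert got == expected

    def test_probe_collapse_keeps_best_probe(self):
        tab = pd.DataFrame(
            {"lfc": [2.0, 3.0, 2.5], "adj_p": [1e-3, 1e-6, 1e-4]},
            index=["p1", "p2", "p3"],
        )
        gene_of = pd.Series({"p1": "gA", "p2": "gA", "p3": "gB"})
        out = topk_rank(tab, k=10, gene_of=gene_of)
        assert list(out.index) == ["gA", "gB"]
        assert out.loc["gA", "adj_p"] == 1e-6


class TestDirection:
    @pytest.mark.parametrize("lfc,label", [(-3.63, "Hypo"), (3.15, "Hyper"), (0.001, "Hyper")])
    def test_sign_convention(self, lfc, label):
        assert direction(lfc) == label

    def test_zero_lfc_undefined(self):
        with pytest.raises(ValueError):
            direction(0.0)


class TestStageAgnostic:
    def _tier1(self, membership):
        out = {}
        for stage in STAGE_ORDER:
            genes = membership.get(stage, [])
            out[stage] = pd.DataFrame(
                {
                    "lfc": [3.0] * len(genes),
                    "adj_p": [1e-9] * len(genes),
                    "direction": ["Hyper"] * len(genes),
                },
                index=genes,
            )
        return out

    def test_gene_in_all_four_sets_concordant(self):
        tier1 = self._tier1({s: ["g1"] for s in STAGE_ORDER})
        out = stage_agnostic(tier1)
        assert list(out.index) == ["g1"]
        assert bool(out.loc["g1", "concordant"])

    def test_gene_in_three_sets_excluded(self):
        tier1 = self._tier1({s: ["g1"] for s in ("I", "II", "III")})
        assert "g1" not in stage_agnostic(tier1).index

    def test_discordant_direction_flagged(self):
        tier1 = self._tier1({s: ["g1"] for s in STAGE_ORDER})
        tier1["IV"].loc["g1", "direction"] = "Hypo"
        out = stage_agnostic(tier1)
        assert not bool(out.loc["g1", "concordant"])


class TestConsensus:
    def _inputs(self, votes, margins_ok=True, tier2_ok=True):
        """votes: method -> stages gene 'g' appears in."""
        stub = pd.DataFrame({"adj_p": [1e-9]}, index=["g"])
        method_lists = {
            m: {s: (stub if s in stages else stub.iloc[:0]) for s in STAGE_ORDER}
            for m, stages in votes.items()
        }
        lfc_iv = 3.0
        others = 0.5 if margins_ok else 2.9
        stage_lfc = pd.DataFrame(
            {"I": [others], "II": [others], "III": [others], "IV": [lfc_iv]}, index=["g"]
        )
        p = 0.01 if tier2_ok else 0.5
        inter = {
            pair: pd.DataFrame({"p": {"g": p}}) for pair in INTERSTAGE_PAIRS
        }
        return method_lists, inter, stage_lfc

    def test_four_of_six_methods_yield_call(self):
        votes = {f"m{i}": ["IV"] for i in range(4)}
        votes.update({"m4": [], "m5": []})
        lists, inter, lfc = self._inputs(votes)
        calls = consensus(lists, inter, lfc)
        assert len(calls) == 1
        assert calls[0].gene == "g" and calls[0].stage == "IV"
        assert calls[0].direction == "Hyper"
        assert set(calls[0].methods) == {"m0", "m1", "m2", "m3"}

    def test_two_methods_insufficient(self):
        votes = {"m0": ["IV"], "m1": ["IV"], "m2": [], "m3": []}
        lists, inter, lfc = self._inputs(votes)
        assert consensus(lists, inter, lfc) == []

    def test_small_margin_blocks_call(self):
        votes = {f"m{i}": ["IV"] for i in range(4)}
        lists, inter, lfc = self._inputs(votes, margins_ok=False)
        assert consensus(lists, inter, lfc) == []

    def test_tier2_gate_blocks_call(self):
        votes = {f"m{i}": ["IV"] for i in range(4)}
        lists, inter, lfc = self._inputs(votes, tier2_ok=False)
        assert consensus(lists, inter, lfc) == []

    def test_method_order_invariance(self):
        votes = {f"m{i}": ["IV"] for i in range(5)}
        lists, inter, lfc = self._inputs(votes)
        calls_a = consensus(lists, inter, lfc)
        reordered = dict(reversed(list(lists.items())))
        calls_b = consensus(reordered, inter, lfc)
        assert [(c.gene, c.stage, c.methods) for c in calls_a] == [
            (c.gene, c.stage, c.methods) for c in calls_b
        ]

    def test_conflicting_two_stage_gene_rejected(self):
        stub = pd.DataFrame({"adj_p": [1e-9]}, index=["g"])
        lists = {
            f"m{i}": {s: (stub if s in ("III", "IV") else stub.iloc[:0]) for s in STAGE_ORDER}
            for i in range(4)
        }
        stage_lfc = pd.DataFrame({"I": [0.0], "II": [0.0], "III": [3.0], "IV": [6.0]}, index=["g"])
        inter = {pair: pd.DataFrame({"p": {"g": 0.001}}) for pair in INTERSTAGE_PAIRS}
        assert consensus(lists, inter, stage_lfc) == []

    def test_raising_thresholds_never_adds_calls(self):
        votes = {f"m{i}": ["IV"] for i in range(4)}
        votes.update({"m4": [], "m5": []})
        lists, inter, lfc = self._inputs(votes)
        base = len(consensus(lists, inter, lfc, TierCriteria()))
        for stricter in [
            TierCriteria(min_methods=5),
            TierCriteria(salience_margin=5.0),
            TierCriteria(tier1_lfc_min=4.0),
        ]:
            assert len(consensus(lists, inter, lfc, stricter)) <= base

    def test_too_few_methods_supplied(self):
        lists, inter, lfc = self._inputs({"m0": ["IV"], "m1": ["IV"]})
        with pytest.raises(ValueError):
            consensus(lists, inter, lfc, TierCriteria(min_methods=3))


class TestFisherEnrichment:
    def test_hand_computed_hypergeometric_tail(self):
        # N=20, K=5, n=5, k=4: P(X>=4) = [C(5,4)C(15,1)+C(5,5)] / C(20,5)
        universe = [f"u{i}" for i in range(20)]
        gene_set = universe[:5]
        gene_list = universe[:4] + [universe[10]]
        out = fisher_enrichment(gene_list, {"S": gene_set}, universe)
        expected = Fraction(comb(5, 4) * comb(15, 1) + comb(5, 5), comb(20, 5))
        assert float(expected) == pytest.approx(76 / 15504)
        assert out.loc["S", "p"] == pytest.approx(float(expected), rel=1e-12)
        assert out.loc["S", "k"] == 4

    def test_zero_overlap_gives_p_one(self):
        universe = [f"u{i}" for i in range(10)]
        out = fisher_enrichment(universe[5:], {"S": universe[:3]}, universe)
        assert out.loc["S", "k"] == 0
        assert out.loc["S", "p"] == pytest.approx(1.0)  # P(X >= 0) is certain

    def test_list_equals_universe_degenerate(self):
        universe = [f"u{i}" for i in range(8)]
        out = fisher_enrichment(universe, {"S": universe[:4]}, universe)
        assert out.loc["S", "k"] == 4
        assert out.loc["S", "p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            fisher_enrichment(["g"], {"S": ["g"]}, [])
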