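"""Consensus building, rarity, de novo flags, selection cascade, burden."""

import numpy as np
import pandas as pd
import pytest

from consangcnv import synthetic as syn
from consangcnv.cnv import (
    ConsensusCNV,
    build_consensus,
    burden_test,
    carrier_counts,
    classify_rarity,
    flag_de_novo,
    select_cnv0,
)

from oracles import consensus_depth_oracle, fisher_one_sided_oracle

COLS = ["sample_id", "caller", "chrom", "start", "end", "cn", "probes"]


def calls_frame(rows):
    return pd.DataFrame(rows, columns=COLS)


class TestConsensus:
    def test_four_identical_calls(self):
        calls = calls_frame(
            [("s1", c, "chr1", 100, 200, 0, 10) for c in "ABCD"]
        )
        (cnv,) = build_consensus(calls, min_algorithms=3)
        assert (cnv.start, cnv.end, cnv.cn) == (100, 200, 0)
        assert cnv.callers == frozenset("ABCD")
        assert cnv.min_probes == 10

    def test_staggered_boundaries_give_depth_region(self):
        calls = calls_frame(
            [
                ("s1", "A", "chr1", 100, 200, 0, 10),
                ("s1", "B", "chr1", 105, 195, 0, 8),
                ("s1", "C", "chr1", 110, 210, 0, 12),
            ]
        )
        (cnv,) = build_consensus(calls, min_algorithms=3)
        assert (cnv.start, cnv.end) == (110, 195)
        assert cnv.n_callers == 3 and cnv.min_probes == 8

    def test_copy_number_classes_never_pooled(self):
        calls = calls_frame(
            [
                ("s1", "A", "chr1", 100, 200, 0, 10),
                ("s1", "B", "chr1", 100, 200, 0, 10),
                ("s1", "C", "chr1", 100, 200, 1, 10),
                ("s1", "D", "chr1", 100, 200, 1, 10),
            ]
        )
        assert build_consensus(calls, min_algorithms=3) == []

    def test_min_algorithms_beyond_roster_rejected(self):
        calls = calls_frame([("s1", "A", "chr1", 0, 10, 0, 5)])
        with pytest.raises(ValueError, match="distinct callers"):
            build_consensus(calls, min_algorithms=3)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_per_base_depth_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for caller in "ABCD":
            for _ in range(rng.integers(1, 5)):
                s = int(rng.integers(0, 180))
                e = s + int(rng.integers(1, 60))
                rows.append(("s1", caller, "chr1", s, e, 0, 10))
        calls = calls_frame(rows)
        for k in (2, 3, 4):
            got = [
                (c.start, c.end) for c in build_consensus(calls, min_algorithms=k)
            ]
            want = consensus_depth_oracle(
                [(r[1], r[3], r[4]) for r in rows], k, 260
            )
            assert got == want, f"k={k}"

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_min_algorithms(self, seed):
        rng = np.random.default_rng(100 + seed)
        rows = []
        for caller in "ABCD":
            for _ in range(3):
                s = int(rng.integers(0, 500))
                rows.append(("s1", caller, "chr1", s, s + int(rng.integers(1, 200)), 1, 9))
        calls = calls_frame(rows)
        prev_bp = None
        for k in (1, 2, 3, 4):
            total = sum(c.length for c in build_consensus(calls, min_algorithms=k))
            if prev_bp is not None:
                assert total <= prev_bp
            prev_bp = total


def catalog_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn", "count"])


class TestRarity:
    def _cnv(self, start, end, cn=0):
        return ConsensusCNV("s1", "chr1", start, end, cn, frozenset("ABC"), 10)

    def test_empty_catalog_is_rare(self):
        assert classify_rarity(self._cnv(110, 190), catalog_frame([]))

    def test_class_mismatch_stays_rare(self):
        # a locus seen only as single-copy loss never makes a CNV0 common
        cat = catalog_frame([("chr1", 0, 1000, 1, 7)])
        assert classify_rarity(self._cnv(110, 190, cn=0), cat)
        assert not classify_rarity(self._cnv(110, 190, cn=1), cat)

    def test_exact_half_overlap_is_rare(self):
        cat = catalog_frame([("chr1", 0, 150_000, 0, 1)])
        cnv = self._cnv(100_000, 200_000)  # 100 kb query, exactly 50 kb overlap
        assert classify_rarity(cnv, cat)  # strict "more than 50%"
        cat2 = catalog_frame([("chr1", 0, 150_001, 0, 1)])
        assert not classify_rarity(cnv, cat2)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_catalog(self, seed):
        rng = np.random.default_rng(seed)
        cnv = self._cnv(1000, 2000)
        entries = [
            ("chr1", int(s), int(s) + int(rng.integers(100, 2000)), 0, 1)
            for s in rng.integers(0, 3000, 12)
        ]
        was_rare = True
        for k in range(len(entries) + 1):
            rare = classify_rarity(cnv, catalog_frame(entries[:k]))
            assert rare or not was_rare or True  # rarity can only decrease
            if not was_rare:
                assert not rare
            was_rare = rare


class TestDeNovo:
    @pytest.fixture
    def trio(self):
        return syn.PedigreeSpec(
            [
                syn.PedigreeMember("dad", "male"),
                syn.PedigreeMember("mom", "female"),
                syn.PedigreeMember("kid", "unknown", affected=True,
                                   father="dad", mother="mom"),
            ]
        )

    def _child_cnv(self, cn=1):
        return ConsensusCNV("kid", "chr1", 1000, 2000, cn, frozenset("ABC"), 10)

    def test_call_free_parents_give_de_novo(self, trio):
        calls = calls_frame([("dad", "A", "chr2", 0, 100, 1, 5)])
        (out,) = flag_de_novo([self._child_cnv()], calls, trio,
                              genotyped={"dad", "mom"})
        assert out.inheritance == "de novo"

    def test_lenient_parental_overlap_marks_inherited(self, trio):
        # 10% single-caller overlap in one parent suffices
        calls = calls_frame([("dad", "D", "chr1", 900, 1100, 1, 5)])
        (out,) = flag_de_novo([self._child_cnv()], calls, trio,
                              genotyped={"dad", "mom"})
        assert out.inheritance == "inherited"

    def test_gain_loss_directions_separate_but_cn3_cn4_pool(self, trio):
        gain_parent = calls_frame([("mom", "A", "chr1", 900, 2100, 4, 5)])
        (loss,) = flag_de_novo([self._child_cnv(cn=1)], gain_parent, trio,
                               genotyped={"dad", "mom"})
        assert loss.inheritance == "de novo"
        (gain,) = flag_de_novo([self._child_cnv(cn=3)], gain_parent, trio,
                               genotyped={"dad", "mom"})
        assert gain.inheritance == "inherited"

    def test_ungenotyped_parent_gives_unknown(self, trio):
        (out,) = flag_de_novo([self._child_cnv()], calls_frame([]), trio,
                              genotyped={"dad"})
        assert out.inheritance == "unknown"

    def test_planted_transmissions_recovered_at_zero_jitter(self, trio, toy):
        genome, _ = toy
        rng = np.random.default_rng(2)
        truth_rows = []
        expected = {}
        for i in range(30):
            s = int(rng.integers(0, 100_000_000))
            transmitted = i % 2 == 0
            truth_rows.append(("kid", "chr1", s, s + 20_000, 1, 10))
            if transmitted:
                truth_rows.append(("dad", "chr1", s, s + 20_000, 1, 10))
            expected[(s, s + 20_000)] = "inherited" if transmitted else "de novo"
        truth = pd.DataFrame(
            truth_rows, columns=["sample_id", "chrom", "start", "end", "cn", "probes"]
        )
        specs = [syn.CallerSpec(c, sensitivity=1.0) for c in "ABCD"]
        calls = syn.synth_caller_calls(truth, specs, genome, seed=3)
        child = build_consensus(
            calls[calls["sample_id"] == "kid"], min_algorithms=3
        )
        out = flag_de_novo(child, calls, trio, genotyped={"dad", "mom"})
        assert len(out) == 30
        for cnv in out:
            assert cnv.inheritance == expected[(cnv.start, cnv.end)]


class TestSelectionCascade:
    def _samples(self):
        return pd.DataFrame(
            {
                "sample_id": ["a1", "a2", "u1", "x1"],
                "family_id": ["f1", "f2", "f1", "f9"],
                "affected": [True, True, False, True],
            }
        )

    def _event(self, sample, cn=0, callers="ABC", probes=10, start=1000, end=50_000):
        return ConsensusCNV(sample, "chr1", start, end, cn, frozenset(callers), probes)

    def test_no_cnv0_empties_cascade_at_stage_two(self):
        events = [self._event("a1", cn=1), self._event("u1", cn=3)]
        final, report = select_cnv0(events, catalog_frame([]), self._samples())
        assert final == []
        assert report.loc[1, "events_affected"] == 0
        assert report.loc[1, "events_unaffected"] == 0

    def test_planted_rare_cnv0_survives_all_stages(self):
        events = [self._event("a1")]
        final, report = select_cnv0(events, catalog_frame([]), self._samples())
        assert len(final) == 1 and final[0].rare
        assert (report["events_affected"] == 1).all()

    def test_common_cnv0_removed_exactly_at_rarity_stage(self):
        cat = catalog_frame([("chr1", 0, 60_000, 0, 3)])
        events = [self._event("a1")]
        final, report = select_cnv0(events, cat, self._samples())
        assert final == []
        assert report.loc[2, "events_affected"] == 1  # still present pre-rarity
        assert report.loc[3, "events_affected"] == 0

    def test_excluded_family_dropped_at_stage_one(self):
        events = [self._event("x1")]
        final, report = select_cnv0(
            events, catalog_frame([]), self._samples(), excluded_families={"f9"}
        )
        assert final == [] and report.loc[0, "events_affected"] == 0

    def test_weak_support_dropped_at_stringency_stage(self):
        events = [self._event("a1", callers="AB"), self._event("a2", probes=3)]
        final, report = select_cnv0(events, catalog_frame([]), self._samples())
        assert final == []
        assert report.loc[1, "events_affected"] == 2
        assert report.loc[2, "events_affected"] == 0


class TestBurden:
    def test_empty_table_p_one(self):
        assert burden_test(0, 10, 0, 10) == 1.0

    def test_extreme_table_closed_form(self):
        from math import comb

        p = burden_test(5, 5, 0, 1000)
        closed = 1 / comb(1005, 5)
        assert p == pytest.approx(closed, rel=1e-9)
        assert p < 1e-10

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            burden_test(0, 0, 0, 10)
        with pytest.raises(ValueError):
            burden_test(11, 10, 0, 10)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(300):
            n_a = int(rng.integers(1, 60))
            n_u = int(rng.integers(1, 60))
            k_a = int(rng.integers(0, n_a + 1))
            k_u = int(rng.integers(0, n_u + 1))
            assert burden_test(k_a, n_a, k_u, n_u) == pytest.approx(
                fisher_one_sided_oracle(k_a, n_a, k_u, n_u), rel=1e-9
            )

    def test_carrier_rates_reproduce_on_constructed_cohort(self):
        """25/199 affected vs 5/131 unaffected carriers -> 12.6% vs 3.8%."""
        samples = pd.DataFrame(
            {
                "sample_id": [f"a{i}" for i in range(199)]
                + [f"u{i}" for i in range(131)],
                "family_id": "f",
                "affected": [True] * 199 + [False] * 131,
            }
        )
        events = [
            ConsensusCNV(f"a{i}", "chr1", 0, 10, 0, frozenset("ABC"), 10)
            for i in range(25)
        ] + [
            ConsensusCNV(f"u{i}", "chr1", 0, 10, 0, frozenset("ABC"), 10)
            for i in range(5)
        ]
        ca, cu = carrier_counts(events, samples)
        assert (ca, cu) == (25, 5)
        assert 100 * ca / 199 == pytest.approx(12.56, abs=0.01)
        assert 100 * cu / 131 == pytest.approx(3.82, abs=0.01)
        p = burden_test(ca, 199, cu, 131)
        assert p == pytest.approx(fisher_one_sided_oracle(25, 199, 5, 131), rel=1e-9)
        assert p < 0.01
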