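"""Generators: gene dropping, founder IBD, genotypes, callers, tracks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from consangcnv import synthetic as syn
from consangcnv.cnv import build_consensus
from consangcnv.enrichment import call_peaks
from consangcnv.genome import Interval, IntervalSet
from consangcnv.panel import HET, MISSING

from oracles import overlap_probability


class TestPedigreeSpec:
    def test_single_parent_rejected(self):
        with pytest.raises(ValueError, match="two parents"):
            syn.PedigreeSpec([
                syn.PedigreeMember("a"),
                syn.PedigreeMember("b", father="a", mother=None),
            ])

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            syn.PedigreeSpec([
                syn.PedigreeMember("a", father="b", mother="c"),
                syn.PedigreeMember("b", father="a", mother="c"),
                syn.PedigreeMember("c"),
            ])

    def test_offspring_ids_are_leaves(self):
        ped = syn.first_cousin_pedigree()
        assert ped.offspring_ids() == ["child"]


class TestGeneDrop:
    def test_outbred_offspring_never_autozygous(self, toy):
        genome, gmap = toy
        ped = syn.outbred_pedigree()
        for rep in syn.gene_drop(ped, gmap, genome, n_replicates=25, seed=0):
            assert rep["child"].segments == []

    def test_first_cousin_mean_autozygosity_matches_inbreeding_coefficient(
        self, full_genome
    ):
        genome, gmap = full_genome
        ped = syn.first_cousin_pedigree()
        reps = syn.gene_drop(ped, gmap, genome, n_replicates=600, seed=11)
        total = gmap.total_length_cm(genome.autosomes)
        fr = np.array([r["child"].total_cm() / total for r in reps])
        se = fr.std(ddof=1) / np.sqrt(len(fr))
        assert abs(fr.mean() - 1 / 16) < 3 * se

    def test_second_cousin_mean_autozygosity(self, full_genome):
        genome, gmap = full_genome
        ped = syn.second_cousin_pedigree()
        reps = syn.gene_drop(ped, gmap, genome, n_replicates=600, seed=12)
        total = gmap.total_length_cm(genome.autosomes)
        fr = np.array([r["child"].total_cm() / total for r in reps])
        se = fr.std(ddof=1) / np.sqrt(len(fr))
        assert abs(fr.mean() - 1 / 64) < 3 * se

    def test_segments_non_overlapping_and_consistent(self, toy):
        genome, gmap = toy
        ped = syn.first_cousin_pedigree()
        for rep in syn.gene_drop(ped, gmap, genome, n_replicates=40, seed=3):
            by_chrom = {}
            for s in rep["child"].segments:
                assert s.end > s.start and s.cm_length > 0
                by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
            for ivs in by_chrom.values():
                ivs.sort()
                for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                    assert e1 <= s2

    def test_bit_reproducible(self, toy):
        genome, gmap = toy
        ped = syn.first_cousin_pedigree()
        a = syn.gene_drop(ped, gmap, genome, n_replicates=5, seed=42)
        b = syn.gene_drop(ped, gmap, genome, n_replicates=5, seed=42)
        assert [r["child"].segments for r in a] == [r["child"].segments for r in b]


class TestFounderIBD:
    # distribution checks use one long chromosome: interior segments on
    # short chromosomes are length-biased low by end censoring
    def test_mean_segment_length_is_100_over_loop_meioses(self):
        genome, gmap = syn.toy_genome(1, 3000.0)
        df = syn.simulate_founder_ibd(4, gmap, genome, n=150, seed=7)
        interior = df.loc[df["interior"], "length_cm"].to_numpy()
        assert interior.mean() == pytest.approx(100 / 8, rel=0.05)

    def test_interior_lengths_exponential(self):
        genome, gmap = syn.toy_genome(1, 3000.0)
        df = syn.simulate_founder_ibd(8, gmap, genome, n=40, seed=8)
        interior = df.loc[df["interior"], "length_cm"].to_numpy()
        sub = np.random.default_rng(0).choice(interior, 1500, replace=False)
        ks = stats.kstest(sub, "expon", args=(0, 100 / 16))
        assert ks.pvalue > 1e-3

    def test_invalid_arguments(self, toy):
        genome, gmap = toy
        with pytest.raises(ValueError):
            syn.simulate_founder_ibd(0, gmap, genome, n=1)
        with pytest.raises(ValueError):
            syn.simulate_founder_ibd(2, gmap, genome, n=0)


@pytest.fixture(scope="module")
def child_ancestry(toy):
    genome, gmap = toy
    ped = syn.first_cousin_pedigree()
    for seed in range(30):  # find a replicate with a big autozygous block
        anc = syn.gene_drop_ancestry(ped, gmap, genome, seed=seed)
        markers = syn.make_marker_table(genome, gmap, 4000, seed=seed)
        sg = syn.genotypes_from_ancestry(
            {"child": anc["child"]}, markers, gmap, genome, seed=seed
        )
        if any(s.cm_length >= 10 for s in sg.truth["child"].segments):
            return anc, markers, sg
    raise AssertionError("no replicate with a long autozygous segment")


class TestGenotypesFromAncestry:
    def test_error_free_autozygous_region_fully_homozygous(self, child_ancestry, toy):
        genome, gmap = toy
        _, markers, sg = child_ancestry
        g = sg.panel.genotypes[0]
        seg = max(sg.truth["child"].segments, key=lambda s: s.cm_length)
        inside = (
            (markers["chrom"] == seg.chrom)
            & (markers["bp"] >= seg.start)
            & (markers["bp"] < seg.end)
        ).to_numpy()
        assert inside.sum() > 50
        assert not (g[inside] == HET).any()
        assert not (g[inside] == MISSING).any()

    def test_error_rate_produces_hets_in_autozygous_regions(self, child_ancestry, toy):
        genome, gmap = toy
        anc, markers, sg = child_ancestry
        noisy = syn.genotypes_from_ancestry(
            {"child": anc["child"]}, markers, gmap, genome,
            error_rate=0.01, seed=99,
        )
        g = noisy.panel.genotypes[0]
        seg = max(sg.truth["child"].segments, key=lambda s: s.cm_length)
        inside = (
            (markers["chrom"] == seg.chrom)
            & (markers["bp"] >= seg.start)
            & (markers["bp"] < seg.end)
        ).to_numpy()
        het_rate = (g[inside] == HET).mean()
        # binomial 3-sigma band around the configured rate
        sigma = np.sqrt(0.01 * 0.99 / inside.sum())
        assert abs(het_rate - 0.01) < 3 * sigma + 1e-9

    def test_all_missing_kills_downstream_runs(self, child_ancestry, toy):
        genome, gmap = toy
        anc, markers, _ = child_ancestry
        sg = syn.genotypes_from_ancestry(
            {"child": anc["child"]}, markers, gmap, genome,
            missing_rate=1.0, seed=1,
        )
        assert (sg.panel.genotypes == MISSING).all()
        from consangcnv.homozygosity import call_homozygous_runs

        assert call_homozygous_runs(sg.panel, gmap) == []

    def test_marker_outside_map_rejected(self, toy):
        genome, gmap = toy
        ped = syn.outbred_pedigree()
        anc = syn.gene_drop_ancestry(ped, gmap, genome, seed=0)
        markers = pd.DataFrame(
            {"chrom": ["chr9"], "marker_id": ["m"], "cm": [0.0], "bp": [100]}
        )
        with pytest.raises(ValueError, match="chr9"):
            syn.genotypes_from_ancestry(anc, markers, gmap, genome)


class TestCallerEmulation:
    @pytest.fixture
    def true_cnvs(self):
        rows = []
        rng = np.random.default_rng(5)
        for i in range(40):
            start = int(rng.integers(0, 140_000_000))
            rows.append((f"s{i}", "chr1", start, start + 50_000, 0, 12))
        return pd.DataFrame(
            rows, columns=["sample_id", "chrom", "start", "end", "cn", "probes"]
        )

    def _specs(self, sens, jitter=0.0, fp=0.0):
        return [
            syn.CallerSpec(c, sensitivity=s, jitter_sd_bp=jitter, fp_rate=fp)
            for c, s in zip("ABCD", sens)
        ]

    def test_perfect_callers_reproduce_truth_and_consensus(self, toy, true_cnvs):
        genome, _ = toy
        calls = syn.synth_caller_calls(
            true_cnvs, self._specs([1, 1, 1, 1]), genome, seed=0
        )
        assert len(calls) == 4 * len(true_cnvs)
        consensus = build_consensus(calls, min_algorithms=3)
        got = {(c.sample_id, c.start, c.end) for c in consensus}
        want = {(r.sample_id, r.start, r.end) for r in true_cnvs.itertuples()}
        assert got == want

    def test_two_dead_callers_kill_consensus(self, toy, true_cnvs):
        genome, _ = toy
        calls = syn.synth_caller_calls(
            true_cnvs, self._specs([1, 1, 0, 0]), genome, seed=0
        )
        assert build_consensus(calls, min_algorithms=3, callers=list("ABCD")) == []

    def test_three_of_four_detection_rate_matches_binomial_tail(self, toy):
        genome, _ = toy
        rng = np.random.default_rng(21)
        rows = [
            (f"s{i}", "chr1", s, s + 40_000, 0, 10)
            for i, s in enumerate(rng.integers(0, 140_000_000, 900))
        ]
        truth = pd.DataFrame(
            rows, columns=["sample_id", "chrom", "start", "end", "cn", "probes"]
        )
        calls = syn.synth_caller_calls(
            truth, self._specs([0.9] * 4), genome, seed=3
        )
        n_support = calls.groupby("sample_id").size()
        frac = (n_support >= 3).sum() / len(truth)
        expect = 0.9**4 + 4 * 0.9**3 * 0.1
        sigma = np.sqrt(expect * (1 - expect) / len(truth))
        assert abs(frac - expect) < 3.5 * sigma

    def test_reproducible(self, toy, true_cnvs):
        genome, _ = toy
        a = syn.synth_caller_calls(true_cnvs, self._specs([0.7] * 4, 500, 1), genome, seed=9)
        b = syn.synth_caller_calls(true_cnvs, self._specs([0.7] * 4, 500, 1), genome, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestTracks:
    def test_realized_coverage_near_target(self):
        genome, _ = syn.toy_genome(1, 10.0)  # 10 Mb
        st_ = syn.synth_tracks(genome, coverage_fraction=0.07, seed=4)
        assert st_.realized_coverage == pytest.approx(0.07, rel=0.10)

    def test_subthreshold_peaks_invisible_to_peak_caller(self):
        genome, _ = syn.toy_genome(1, 5.0)
        st_ = syn.synth_tracks(
            genome, coverage_fraction=0.05, peak_score=10.0,
            background_score=1.0, seed=4,
        )
        assert len(call_peaks(st_.track, threshold=20)) == 0
        # at a permissive threshold, the called peaks are exactly the planted ones
        assert call_peaks(st_.track, threshold=10) == st_.peaks

    def test_state_variant_marks_same_intervals(self):
        genome, _ = syn.toy_genome(1, 5.0)
        st_ = syn.synth_state_track(genome, coverage_fraction=0.05, seed=4)
        assert st_.track.state_intervals(["7_Enh"]) == st_.peaks
        quies = st_.track.state_intervals(["15_Quies"])
        assert quies.total_length + st_.peaks.total_length >= genome.lengths["chr1"]

    def test_unreachable_coverage_rejected(self):
        genome, _ = syn.toy_genome(1, 1.0)
        with pytest.raises(ValueError):
            syn.synth_tracks(genome, coverage_fraction=0.5, mean_peak_bp=2e6)


class TestCaseControlCNVs:
    @pytest.fixture
    def setup(self):
        genome, _ = syn.toy_genome(1, 10.0)
        track = syn.synth_tracks(genome, coverage_fraction=0.10, seed=1)
        mappable = IntervalSet([Interval("chr1", 0, genome.lengths["chr1"])])
        return track.peaks, mappable

    def test_full_bias_always_overlaps(self, setup):
        peaks, mappable = setup
        aff, _ = syn.synth_case_control_cnvs(
            [20_000] * 28, [], 1.0, peaks, mappable, seed=2
        )
        assert all(peaks.intersects_interval(iv) for iv in aff)
        assert len(aff) == 28

    def test_half_bias_matches_linearity_of_expectation(self):
        # tiny genome so the brute-force placement oracle stays cheap
        genome, _ = syn.toy_genome(1, 0.2)  # 200 kb
        track = syn.synth_tracks(
            genome, coverage_fraction=0.10, mean_peak_bp=2_000.0, seed=1
        )
        peaks = track.peaks
        mappable = IntervalSet([Interval("chr1", 0, genome.lengths["chr1"])])
        length = 5_000
        p0 = float(
            overlap_probability(
                [(iv.start, iv.end) for iv in mappable],
                [(iv.start, iv.end) for iv in peaks],
                length,
            )
        )
        n = 400
        aff, _ = syn.synth_case_control_cnvs(
            [length] * n, [], 0.5, peaks, mappable, seed=6
        )
        hits = sum(peaks.intersects_interval(iv) for iv in aff)
        expect = n / 2 + (n / 2) * p0
        sigma = np.sqrt((n / 2) * p0 * (1 - p0))
        assert abs(hits - expect) < 4 * sigma

    def test_unbiased_placement_on_mappable_only(self, setup):
        peaks, _ = setup
        mappable = IntervalSet([Interval("chr1", 1_000_000, 2_000_000)])
        aff, un = syn.synth_case_control_cnvs(
            [5_000] * 10, [5_000] * 5, 0.0, peaks, mappable, seed=3
        )
        for iv in aff + un:
            assert iv.start >= 1_000_000 and iv.end <= 2_000_000
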