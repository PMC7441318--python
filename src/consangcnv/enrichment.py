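"""Mappable genome, peak calling, and Monte-Carlo coincidence testing.

The null model re-places the observed CNV sets on the mappable autosomal
genome with lengths preserved: a placement picks a mappable interval with
probability proportional to its number of valid start positions for that
length, then a uniform valid start, so every feasible placement (the CNV
wholly inside one mappable interval) is equally likely. Per replicate both
phenotype groups are re-placed independently and their coincidence counts
with the annotation peaks recorded; enrichment/depletion/joint p-values use
the add-one estimator (1 + #more-extreme) / (n + 1), which can never return
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import (
    GenomeLayout,
    IntensityTrack,
    Interval,
    IntervalSet,
    StateTrack,
)

__all__ = [
    "MappableGenome",
    "build_mappable",
    "call_peaks",
    "count_coincidences",
    "PlacementSampler",
    "MonteCarloResult",
    "monte_carlo_joint",
    "chromhmm_overlap",
    "sweep_peak_thresholds",
]


@dataclass
class MappableGenome:
    """Autosomal regions dense enough in markers for reliable CNV calling."""

    intervals: IntervalSet
    provenance: Dict[str, object] = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        return self.intervals.total_length


def build_mappable(marker_bp: Mapping[str, Sequence[int]], genome: GenomeLayout,
                   max_gap_bp: int = 100_000,
                   exclusions: IntervalSet | None = None) -> MappableGenome:
    """Marker-span mappable genome: drop inter-marker gaps > ``max_gap_bp``.

    Per autosome, the mappable region is the union of intervals between
    consecutive markers no farther apart than ``max_gap_bp``, minus any
    exclusion regions. Chromosomes with fewer than two markers are excluded
    with a warning.
    """
    pieces: List[Interval] = []
    for chrom in genome.autosomes:
        bp = np.sort(np.asarray(marker_bp.get(chrom, []), dtype=np.int64))
        if bp.size < 2:
            warnings.warn(f"{chrom}: < 2 markers, excluded from mappable genome",
                          stacklevel=2)
            continue
        gaps = np.diff(bp)
        ok = gaps <= max_gap_bp
        for s, e in zip(bp[:-1][ok], bp[1:][ok]):
            pieces.append(Interval(chrom, int(s), int(e)))
    mappable = IntervalSet(pieces)
    if exclusions is not None:
        mappable = mappable.subtract(exclusions)
    return MappableGenome(
        mappable,
        provenance={
            "max_gap_bp": max_gap_bp,
            "n_chromosomes": len(mappable.chromosomes),
            "total_bp": mappable.total_length,
        },
    )


def call_peaks(track: IntensityTrack, threshold: float = 20.0) -> IntervalSet:
    """Maximal runs of bins scoring >= ``threshold``, as bp intervals."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out: List[Interval] = []
    for chrom, vec in track.scores.items():
        mask = vec >= threshold
        if not mask.any():
            continue
        edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
        for b0, b1 in zip(edges[::2], edges[1::2]):
            out.append(
                Interval(
                    chrom,
                    int(b0) * track.bin_bp,
                    min(int(b1) * track.bin_bp, track.genome.lengths[chrom]),
                )
            )
    return IntervalSet(out)


def count_coincidences(cnvs: Sequence[Interval],
                       collections: Mapping[str, IntervalSet]) -> pd.DataFrame:
    """Per CNV and track collection: does it intersect any peak by >= 1 bp?

    Each collection is typically already the union over a set of profiles
    (e.g. all cell lines of one mark, or all epigenomes of one tissue).
    """
    data = {
        name: [peaks.intersects_interval(iv) for iv in cnvs]
        for name, peaks in collections.items()
    }
    df = pd.DataFrame(data)
    df.insert(0, "chrom", [iv.chrom for iv in cnvs])
    df.insert(1, "start", [iv.start for iv in cnvs])
    df.insert(2, "end", [iv.end for iv in cnvs])
    return df


class PlacementSampler:
    """Uniform placement of fixed-length intervals on the mappable genome.

    A placement always lies wholly within one mappable interval, so the
    placed length on the mappable genome is preserved exactly.
    """

    def __init__(self, mappable: IntervalSet):
        if mappable.total_length == 0:
            raise ValueError("mappable genome is empty")
        ivs = list(mappable)
        self.chroms = [iv.chrom for iv in ivs]
        self.starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        self.lengths = np.array([iv.length for iv in ivs], dtype=np.int64)
        # virtual concatenated axis for vectorized peak lookups
        uniq = list(dict.fromkeys(self.chroms))
        span = {c: 0 for c in uniq}
        for iv in ivs:
            span[iv.chrom] = max(span[iv.chrom], iv.end)
        self._chrom_offset: Dict[str, int] = {}
        off = 0
        for c in uniq:
            self._chrom_offset[c] = off
            off += span[c] + 1
        self._global_start = np.array(
            [self._chrom_offset[c] for c in self.chroms], dtype=np.int64
        ) + self.starts

    def valid_starts(self, length: int) -> np.ndarray:
        return np.maximum(0, self.lengths - length + 1)

    def n_feasible(self, length: int) -> int:
        return int(self.valid_starts(length).sum())

    def place(self, length: int, rng: np.random.Generator) -> Interval:
        idx, off = self._draw(length, 1, rng)
        s = int(self.starts[idx[0]] + off[0])
        return Interval(self.chroms[idx[0]], s, s + int(length))

    def _draw(self, length: int, n: int, rng: np.random.Generator
              ) -> Tuple[np.ndarray, np.ndarray]:
        vs = self.valid_starts(length)
        total = vs.sum()
        if total == 0:
            raise ValueError(
                f"CNV of length {length} bp does not fit in any mappable interval"
            )
        idx = rng.choice(len(vs), size=n, p=vs / total)
        off = (rng.random(n) * vs[idx]).astype(np.int64)
        return idx, off

    def global_peaks(self, peaks: IntervalSet) -> Tuple[np.ndarray, np.ndarray]:
        """Peak (start, end) arrays on the virtual concatenated axis."""
        gs, ge = [], []
        for iv in peaks:
            off = self._chrom_offset.get(iv.chrom)
            if off is None:
                continue
            gs.append(off + iv.start)
            ge.append(off + iv.end)
        order = np.argsort(gs) if gs else []
        return (
            np.asarray(gs, dtype=np.int64)[order],
            np.asarray(ge, dtype=np.int64)[order],
        )

    def coincidence_counts(self, lengths: Sequence[int], peaks: IntervalSet,
                           n: int, rng: np.random.Generator) -> np.ndarray:
        """Replicate coincidence counts for a CNV set re-placed ``n`` times."""
        pk_s, pk_e = self.global_peaks(peaks)
        counts = np.zeros(n, dtype=np.int32)
        for length in lengths:
            idx, off = self._draw(int(length), n, rng)
            g0 = self._global_start[idx] + off
            g1 = g0 + int(length)
            if pk_s.size:
                j = np.searchsorted(pk_s, g1, side="left") - 1
                hit = (j >= 0) & (pk_e[np.clip(j, 0, None)] > g0)
                counts += hit.astype(np.int32)
        return counts


@dataclass
class MonteCarloResult:
    """Observed vs randomized coincidence counts and their p-values."""

    n_replicates: int
    observed_affected: int
    observed_unaffected: int
    expected_affected: float
    expected_unaffected: float
    p_enrichment: float  # affected coincidences >= observed
    p_depletion: float  # unaffected coincidences <= observed
    p_joint: float
    seed: int | None
    diagnostics: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_replicates": self.n_replicates,
            "observed_affected": self.observed_affected,
            "observed_unaffected": self.observed_unaffected,
            "expected_affected": self.expected_affected,
            "expected_unaffected": self.expected_unaffected,
            "p_enrichment": self.p_enrichment,
            "p_depletion": self.p_depletion,
            "p_joint": self.p_joint,
            "seed": self.seed,
            **self.diagnostics,
        }


def monte_carlo_joint(affected: Sequence[Interval], unaffected: Sequence[Interval],
                      peaks: IntervalSet, mappable: IntervalSet | MappableGenome,
                      n: int = 100_000,
                      seed: int | np.random.Generator | None = 0
                      ) -> MonteCarloResult:
    """Joint enrichment/depletion test by interval randomization.

    Both CNV sets are independently re-placed in every replicate (lengths
    preserved, uniform over feasible placements). With A_i/U_i the replicate
    coincidence counts and A/U the observed ones:

    * enrichment p  = (1 + #{A_i >= A}) / (n + 1)
    * depletion p   = (1 + #{U_i <= U}) / (n + 1)
    * joint p       = (1 + #{A_i >= A and U_i <= U}) / (n + 1)
    """
    if isinstance(mappable, MappableGenome):
        mappable = mappable.intervals
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = seed if isinstance(seed, int) else None
    sampler = PlacementSampler(mappable)
    for group, cnvs in (("affected", affected), ("unaffected", unaffected)):
        for iv in cnvs:
            if sampler.n_feasible(iv.length) == 0:
                raise ValueError(
                    f"{group} CNV {iv.chrom}:{iv.start}-{iv.end} "
                    f"({iv.length} bp) exceeds every mappable interval"
                )
    obs_a = sum(peaks.intersects_interval(iv) for iv in affected)
    obs_u = sum(peaks.intersects_interval(iv) for iv in unaffected)
    a_counts = sampler.coincidence_counts([iv.length for iv in affected], peaks, n, rng)
    u_counts = sampler.coincidence_counts([iv.length for iv in unaffected], peaks, n, rng)
    p_enr = (1 + int((a_counts >= obs_a).sum())) / (n + 1)
    p_dep = (1 + int((u_counts <= obs_u).sum())) / (n + 1)
    p_joint = (1 + int(((a_counts >= obs_a) & (u_counts <= obs_u)).sum())) / (n + 1)
    return MonteCarloResult(
        n_replicates=n,
        observed_affected=int(obs_a),
        observed_unaffected=int(obs_u),
        expected_affected=float(a_counts.mean()),
        expected_unaffected=float(u_counts.mean()),
        p_enrichment=p_enr,
        p_depletion=p_dep,
        p_joint=p_joint,
        seed=seed_val,
        diagnostics={
            "mappable_bp": mappable.total_length,
            "n_affected_cnvs": len(affected),
            "n_unaffected_cnvs": len(unaffected),
        },
    )


def chromhmm_overlap(affected: Sequence[Interval], unaffected: Sequence[Interval],
                     state_tracks: Mapping[str, StateTrack],
                     state_subset: Sequence[str],
                     mappable: IntervalSet | MappableGenome,
                     gene_models: Sequence | None = None,
                     noncoding_only: bool = False,
                     tissue_map: Mapping[str, Sequence[str]] | None = None,
                     n: int = 100_000, seed: int = 0
                     ) -> Dict[str, MonteCarloResult]:
    """Per-epigenome Monte-Carlo tests on chromatin-state bins.

    Coincidence means intersecting >= 1 bin whose state is in
    ``state_subset``. With ``noncoding_only`` (requires ``gene_models``),
    CNVs intersecting any coding exon of a coding gene are excluded from
    the tested sets first. ``tissue_map`` adds tests on the union of
    selected-state bins across each tissue's epigenomes. No multiple-testing
    correction is applied — tissues overlap and are highly correlated, so
    all marginal and joint p-values are reported as-is.
    """
    grids = {t.bin_bp for t in state_tracks.values()}
    if len(grids) > 1:
        raise ValueError(f"state tracks on mismatched bin grids: {sorted(grids)}")
    if noncoding_only:
        if gene_models is None:
            raise ValueError("noncoding_only requires gene_models")
        from .genes import annotate_exonic

        affected = [iv for iv in affected if not annotate_exonic(iv, gene_models)[0]]
        unaffected = [iv for iv in unaffected if not annotate_exonic(iv, gene_models)[0]]

    ss = np.random.SeedSequence(seed)
    names = list(state_tracks)
    tissues = list(tissue_map) if tissue_map else []
    children = ss.spawn(len(names) + len(tissues))
    results: Dict[str, MonteCarloResult] = {}
    selected = {
        name: track.state_intervals(state_subset)
        for name, track in state_tracks.items()
    }
    for name, child in zip(names, children):
        results[name] = monte_carlo_joint(
            affected, unaffected, selected[name], mappable, n=n,
            seed=np.random.default_rng(child),
        )
    for tissue, child in zip(tissues, children[len(names):]):
        union = IntervalSet()
        for epi in tissue_map[tissue]:
            union = union.union(selected[epi])
        results[f"tissue:{tissue}"] = monte_carlo_joint(
            affected, unaffected, union, mappable, n=n,
            seed=np.random.default_rng(child),
        )
    return results


def sweep_peak_thresholds(affected: Sequence[Interval],
                          unaffected: Sequence[Interval],
                          track: IntensityTrack,
                          mappable: IntervalSet | MappableGenome,
                          thresholds: Sequence[float] = (20, 25, 30, 35, 40),
                          n: int = 10_000, seed: int = 0) -> pd.DataFrame:
    """Robustness of the joint test to the peak-calling threshold."""
    rows = []
    for t, child in zip(thresholds, np.random.SeedSequence(seed).spawn(len(thresholds))):
        peaks = call_peaks(track, threshold=t)
        res = monte_carlo_joint(
            affected, unaffected, peaks, mappable, n=n,
            seed=np.random.default_rng(child),
        )
        rows.append((t, res.observed_affected, res.expected_affected,
                     res.observed_unaffected, res.expected_unaffected,
                     res.p_enrichment, res.p_depletion, res.p_joint))
    return pd.DataFrame(
        rows, columns=["threshold", "observed_affected", "expected_affected",
                       "observed_unaffected", "expected_unaffected",
                       "p_enrichment", "p_depletion", "p_joint"],
    )
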