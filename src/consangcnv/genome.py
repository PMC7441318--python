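"""Genome model, genetic map, and interval algebra.

All internal coordinates are 0-based half-open ``[start, end)``. One-based
inclusive coordinates appear only in human-readable report writers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "Interval",
    "IntervalSet",
    "GenomeLayout",
    "GeneticMap",
    "IntensityTrack",
    "StateTrack",
    "GeneModel",
]


@dataclass(frozen=True, order=True)
class Interval:
    """A half-open genomic interval ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Overlap in bp with another interval (0 if different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def intersects(self, other: "Interval") -> bool:
        return self.overlap(other) > 0


class IntervalSet:
    """A normalized (sorted, merged) collection of intervals.

    Normalization merges overlapping and book-ended intervals, so the set is
    a canonical disjoint representation; total length is then simply the sum
    of interval lengths.
    """

    def __init__(self, intervals: Iterable[Interval] = ()):  # noqa: D107
        per_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for iv in intervals:
            per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._data: Dict[str, np.ndarray] = {}
        for chrom, pairs in per_chrom.items():
            arr = np.array(sorted(pairs), dtype=np.int64)
            merged: List[Tuple[int, int]] = []
            cur_s, cur_e = arr[0]
            for s, e in arr[1:]:
                if s <= cur_e:  # overlapping or adjacent: merge
                    cur_e = max(cur_e, e)
                else:
                    merged.append((cur_s, cur_e))
                    cur_s, cur_e = s, e
            merged.append((cur_s, cur_e))
            self._data[chrom] = np.array(merged, dtype=np.int64)

    # -- construction helpers -------------------------------------------------
    @classmethod
    def from_arrays(
        cls, chroms: Sequence[str], starts: Sequence[int], ends: Sequence[int]
    ) -> "IntervalSet":
        return cls(Interval(c, int(s), int(e)) for c, s, e in zip(chroms, starts, ends))

    # -- basic protocol -------------------------------------------------------
    def __iter__(self) -> Iterator[Interval]:
        for chrom in sorted(self._data):
            for s, e in self._data[chrom]:
                yield Interval(chrom, int(s), int(e))

    def __len__(self) -> int:
        return sum(arr.shape[0] for arr in self._data.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            return False
        return all(np.array_equal(self._data[c], other._data[c]) for c in self._data)

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals, {self.total_length} bp)"

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) arrays for one chromosome (empty if absent)."""
        arr = self._data.get(chrom)
        if arr is None:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return arr[:, 0], arr[:, 1]

    @property
    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._data.values())
        )

    # -- set algebra ----------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: List[Interval] = []
        for chrom in self._data:
            s1, e1 = self.arrays(chrom)
            s2, e2 = other.arrays(chrom)
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    out.append(Interval(chrom, int(lo), int(hi)))
                if e1[i] < e2[j]:
                    i += 1
                else:
                    j += 1
        return IntervalSet(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: List[Interval] = []
        for chrom in self._data:
            s1, e1 = self.arrays(chrom)
            s2, e2 = other.arrays(chrom)
            for s, e in zip(s1, e1):
                cur = int(s)
                mask = (s2 < e) & (e2 > s)
                for ms, me in zip(s2[mask], e2[mask]):
                    if ms > cur:
                        out.append(Interval(chrom, cur, int(min(ms, e))))
                    cur = max(cur, int(me))
                    if cur >= e:
                        break
                if cur < e:
                    out.append(Interval(chrom, cur, int(e)))
        return IntervalSet(out)

    def intersects_interval(self, iv: Interval) -> bool:
        """True if any member overlaps ``iv`` by >= 1 bp."""
        starts, ends = self.arrays(iv.chrom)
        if starts.size == 0:
            return False
        idx = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return idx >= 0 and ends[idx] > iv.start

    def overlap_bp(self, iv: Interval) -> int:
        """Total bp of overlap between ``iv`` and the set."""
        starts, ends = self.arrays(iv.chrom)
        if starts.size == 0:
            return 0
        lo = np.maximum(starts, iv.start)
        hi = np.minimum(ends, iv.end)
        return int(np.clip(hi - lo, 0, None).sum())


@dataclass
class GenomeLayout:
    """Chromosome names, lengths, excluded regions and the autosome set."""

    lengths: Dict[str, int]
    exclusions: IntervalSet = field(default_factory=IntervalSet)
    autosomes: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.lengths)) != len(self.lengths):
            raise ValueError("duplicate chromosome names")
        for chrom, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom} has non-positive length")
        for iv in self.exclusions:
            if iv.chrom not in self.lengths:
                raise ValueError(f"exclusion on unknown chromosome {iv.chrom}")
            if iv.end > self.lengths[iv.chrom]:
                raise ValueError(f"exclusion {iv} beyond chromosome end")
        if not self.autosomes:
            self.autosomes = tuple(
                c for c in self.lengths if c not in ("chrX", "chrY", "X", "Y")
            )

    @property
    def chromosomes(self) -> List[str]:
        return list(self.lengths)

    def autosome_layout(self) -> "GenomeLayout":
        return GenomeLayout(
            lengths={c: self.lengths[c] for c in self.autosomes},
            exclusions=IntervalSet(
                iv for iv in self.exclusions if iv.chrom in self.autosomes
            ),
            autosomes=self.autosomes,
        )


class GeneticMap:
    """Piecewise-linear genetic map: per chromosome, (bp, cM) anchor points.

    Queries interpolate linearly between anchors; queries beyond the anchor
    range clamp to the terminal cM values (no extrapolation, so lengths can
    never go negative on sparse maps).
    """

    def __init__(self, anchors: Mapping[str, Sequence[Tuple[float, float]]]):
        self._bp: Dict[str, np.ndarray] = {}
        self._cm: Dict[str, np.ndarray] = {}
        for chrom, pts in anchors.items():
            pts = sorted(pts)
            bp = np.array([p[0] for p in pts], dtype=float)
            cm = np.array([p[1] for p in pts], dtype=float)
            if bp.size < 2:
                raise ValueError(f"chromosome {chrom}: need >= 2 map anchors")
            if np.any(np.diff(bp) <= 0):
                raise ValueError(f"chromosome {chrom}: bp anchors not strictly increasing")
            if np.any(np.diff(cm) < 0):
                raise ValueError(f"chromosome {chrom}: cM anchors decreasing")
            self._bp[chrom] = bp
            self._cm[chrom] = cm

    @property
    def chromosomes(self) -> List[str]:
        return list(self._bp)

    def interpolate_cm(self, chrom: str, bp) -> np.ndarray | float:
        """Genetic position (cM) at physical position(s) ``bp``."""
        if chrom not in self._bp:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        out = np.interp(bp, self._bp[chrom], self._cm[chrom])
        return float(out) if np.isscalar(bp) else out

    def interpolate_bp(self, chrom: str, cm) -> np.ndarray | float:
        """Inverse query: physical position at genetic position(s) ``cm``.

        On flat map regions (zero recombination) the left edge is returned.
        """
        if chrom not in self._bp:
            raise KeyError(f"chromosome {chrom} not in genetic map")
        out = np.interp(cm, self._cm[chrom], self._bp[chrom])
        return float(out) if np.isscalar(cm) else out

    def chrom_length_cm(self, chrom: str) -> float:
        return float(self._cm[chrom][-1] - self._cm[chrom][0])

    def total_length_cm(self, chromosomes: Iterable[str] | None = None) -> float:
        chroms = list(chromosomes) if chromosomes is not None else self.chromosomes
        return float(sum(self.chrom_length_cm(c) for c in chroms))


class IntensityTrack:
    """Dense per-bin enrichment scores on a fixed bp grid (default 25 bp)."""

    def __init__(self, genome: GenomeLayout, bin_bp: int = 25,
                 scores: Dict[str, np.ndarray] | None = None):
        if bin_bp <= 0:
            raise ValueError("bin width must be positive")
        self.genome = genome
        self.bin_bp = int(bin_bp)
        self.scores: Dict[str, np.ndarray] = {}
        for chrom, length in genome.lengths.items():
            n_bins = -(-length // self.bin_bp)  # ceil
            if scores is not None and chrom in scores:
                vec = np.asarray(scores[chrom], dtype=float)
                if vec.shape[0] != n_bins:
                    raise ValueError(
                        f"{chrom}: expected {n_bins} bins, got {vec.shape[0]}"
                    )
                if np.any(vec < 0):
                    raise ValueError(f"{chrom}: negative scores")
                self.scores[chrom] = vec
            else:
                self.scores[chrom] = np.zeros(n_bins)

    def n_bins(self, chrom: str) -> int:
        return self.scores[chrom].shape[0]


class StateTrack:
    """Per-bin categorical chromatin-state labels on a fixed grid (200 bp)."""

    def __init__(self, genome: GenomeLayout, alphabet: Sequence[str],
                 bin_bp: int = 200,
                 states: Dict[str, np.ndarray] | None = None,
                 fill: str | None = None):
        if bin_bp <= 0:
            raise ValueError("bin width must be positive")
        self.genome = genome
        self.bin_bp = int(bin_bp)
        self.alphabet = tuple(alphabet)
        self._index = {s: i for i, s in enumerate(self.alphabet)}
        fill_idx = 0 if fill is None else self._index[fill]
        self.states: Dict[str, np.ndarray] = {}
        for chrom, length in genome.lengths.items():
            n_bins = -(-length // self.bin_bp)
            if states is not None and chrom in states:
                vec = np.asarray(states[chrom])
                if vec.dtype.kind in "iu":
                    idx = vec.astype(np.int32)
                    if idx.min(initial=0) < 0 or idx.max(initial=0) >= len(self.alphabet):
                        raise ValueError(f"{chrom}: state index outside alphabet")
                else:
                    try:
                        idx = np.array([self._index[s] for s in vec], dtype=np.int32)
                    except KeyError as exc:
                        raise ValueError(f"{chrom}: unknown state {exc}") from exc
                if idx.shape[0] != n_bins:
                    raise ValueError(f"{chrom}: expected {n_bins} bins, got {idx.shape[0]}")
                self.states[chrom] = idx
            else:
                self.states[chrom] = np.full(n_bins, fill_idx, dtype=np.int32)

    def state_intervals(self, subset: Sequence[str]) -> IntervalSet:
        """bp intervals covered by bins whose state is in ``subset``."""
        wanted = {self._index[s] for s in subset}
        out: List[Interval] = []
        for chrom, idx in self.states.items():
            mask = np.isin(idx, list(wanted))
            if not mask.any():
                continue
            edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
            for s_bin, e_bin in zip(edges[::2], edges[1::2]):
                out.append(
                    Interval(
                        chrom,
                        int(s_bin) * self.bin_bp,
                        min(int(e_bin) * self.bin_bp, self.genome.lengths[chrom]),
                    )
                )
        return IntervalSet(out)


@dataclass(frozen=True)
class GeneModel:
    """A gene with transcript/coding spans and coding-exon blocks."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    coding_exons: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"gene {self.name}: coding span outside transcript span")
        for s, e in self.coding_exons:
            if not (self.cds_start <= s < e <= self.cds_end):
                raise ValueError(f"gene {self.name}: coding exon outside coding span")
        if not self.is_coding and self.coding_exons:
            raise ValueError(f"gene {self.name}: noncoding gene with coding exons")

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start
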