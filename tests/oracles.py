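"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit enumeration, exact integer
arithmetic) and shares no code with the package internals it checks.
"""

from fractions import Fraction
from math import comb
from typing import Dict, List, Sequence, Tuple


def roh_runs_oracle(genotypes: Sequence[int], window: int,
                    min_hom_frac: Fraction) -> List[Tuple[int, int]]:
    """Enumerate every window, mark supported markers, merge stretches.

    Genotype codes: 0/2 homozygous, 1 het, -1 missing. Returns (first, last)
    marker-index pairs of maximal supported stretches (no length filter).
    """
    n = len(genotypes)
    supported = [False] * n
    for w0 in range(0, n - window + 1):
        win = genotypes[w0 : w0 + window]
        nonmiss = sum(1 for g in win if g != -1)
        hom = sum(1 for g in win if g in (0, 2))
        if nonmiss > 0 and Fraction(hom, nonmiss) >= min_hom_frac:
            for i in range(w0, w0 + window):
                supported[i] = True
    runs: List[Tuple[int, int]] = []
    i = 0
    while i < n:
        if supported[i]:
            j = i
            while j + 1 < n and supported[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def consensus_depth_oracle(calls: List[Tuple[str, int, int]], min_algorithms: int,
                           max_pos: int) -> List[Tuple[int, int]]:
    """Per-base caller depth by scanning every bp position.

    ``calls`` are (caller, start, end) for one sample/chromosome/class.
    Returns maximal [start, end) regions where the number of DISTINCT
    callers covering the base is >= min_algorithms.
    """
    covered = [set() for _ in range(max_pos)]
    for caller, s, e in calls:
        for pos in range(s, min(e, max_pos)):
            covered[pos].add(caller)
    regions: List[Tuple[int, int]] = []
    start = None
    for pos in range(max_pos):
        ok = len(covered[pos]) >= min_algorithms
        if ok and start is None:
            start = pos
        elif not ok and start is not None:
            regions.append((start, pos))
            start = None
    if start is not None:
        regions.append((start, max_pos))
    return regions


def fisher_one_sided_oracle(k_aff: int, n_aff: int, k_un: int, n_un: int) -> float:
    """Exact one-sided Fisher p by explicit hypergeometric enumeration."""
    total = n_aff + n_un
    k_total = k_aff + k_un
    denom = comb(total, n_aff)
    num = 0
    for x in range(k_aff, min(k_total, n_aff) + 1):
        if k_total - x > n_un:
            continue
        num += comb(k_total, x) * comb(total - k_total, n_aff - x)
    return num / denom


def enumerate_placements(mappable: List[Tuple[int, int]], length: int
                         ) -> List[int]:
    """All feasible start positions (single chromosome) for a CNV length."""
    starts: List[int] = []
    for s, e in mappable:
        for pos in range(s, e - length + 2):
            if pos + length <= e:
                starts.append(pos)
    return starts


def overlap_probability(mappable: List[Tuple[int, int]],
                        peaks: List[Tuple[int, int]], length: int) -> Fraction:
    """Exact per-CNV peak-overlap probability under uniform placement."""
    starts = enumerate_placements(mappable, length)
    hits = sum(
        1
        for pos in starts
        if any(pos < pe and pos + length > ps for ps, pe in peaks)
    )
    return Fraction(hits, len(starts))


def exonic_overlap_oracle(cnv: Tuple[str, int, int],
                          coding_exons: Dict[str, List[Tuple[str, int, int]]]
                          ) -> List[str]:
    """All-pairs interval intersection of a CNV against coding exons."""
    chrom, s, e = cnv
    hit = []
    for gene, exons in coding_exons.items():
        for (c, es, ee) in exons:
            if c == chrom and es < e and ee > s:
                hit.append(gene)
                break
    return hit
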