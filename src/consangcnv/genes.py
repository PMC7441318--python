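"""Gene-context annotation of CNVs: exonic disruption, neighbors, TADs.

Neighbor selection follows a genomic-distance rule anchored on coding
spans: the nearest coding gene, plus any coding gene whose coding span lies
within 150 kb of the nearest gene's coding region, with a hard cap of 1 Mb
+ 150 kb between CNV and gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .genome import GeneModel, Interval

__all__ = [
    "annotate_exonic",
    "NeighborReport",
    "neighbor_genes",
    "TADDisruption",
    "tad_disruption",
]


def annotate_exonic(cnv: Interval, gene_models: Sequence[GeneModel]
                    ) -> Tuple[bool, List[str]]:
    """Exonic iff the CNV intersects a coding exon of a coding gene.

    A CNV touching only noncoding transcripts (or only UTRs/introns) is
    noncoding under this rule; such genes still appear in neighbor reports.
    """
    hit: List[str] = []
    for gene in gene_models:
        if gene.chrom != cnv.chrom or not gene.is_coding:
            continue
        if any(s < cnv.end and e > cnv.start for s, e in gene.coding_exons):
            hit.append(gene.name)
    return bool(hit), hit


def _gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """bp gap between two intervals; 0 if they overlap or abut."""
    return max(0, max(a_start, b_start) - min(a_end, b_end))


@dataclass
class NeighborReport:
    """Coding genes in the neighborhood of one CNV."""

    cnv: Interval
    exonic: bool
    disrupted_genes: List[str]
    nearest: List[str]  # all tied nearest coding genes
    nearest_distance: int | None
    neighbors: List[str]  # additional genes within the window of the nearest
    table: pd.DataFrame  # gene, distance, signed_distance, position

    @property
    def genes(self) -> List[str]:
        return self.nearest + self.neighbors


def neighbor_genes(cnv: Interval, gene_models: Sequence[GeneModel],
                   window_kb: float = 150.0, cap_kb: float = 1150.0
                   ) -> NeighborReport:
    """Nearest coding gene plus window neighbors, under the distance cap.

    Distances are gaps between the CNV and the gene's CODING span (0 when
    overlapping); the window for additional neighbors is measured between
    coding spans (nearest gene to candidate, gene-to-gene). Genes farther
    than ``cap_kb`` from the CNV are never reported. Signed distance is
    negative for genes entirely to the left of the CNV, positive to the
    right, zero when overlapping.
    """
    window_bp = int(window_kb * 1000)
    cap_bp = int(cap_kb * 1000)
    exonic, disrupted = annotate_exonic(cnv, gene_models)
    coding = [
        g for g in gene_models if g.is_coding and g.chrom == cnv.chrom
    ]
    dist = {
        g.name: _gap(cnv.start, cnv.end, g.cds_start, g.cds_end) for g in coding
    }
    in_cap = [g for g in coding if dist[g.name] <= cap_bp]
    empty = pd.DataFrame(columns=["gene", "distance", "signed_distance", "position"])
    if not in_cap:
        return NeighborReport(cnv, exonic, disrupted, [], None, [], empty)
    d_min = min(dist[g.name] for g in in_cap)
    nearest = [g for g in in_cap if dist[g.name] == d_min]
    neighbors: List[GeneModel] = []
    for g in in_cap:
        if g in nearest:
            continue
        gene_gap = min(
            _gap(ng.cds_start, ng.cds_end, g.cds_start, g.cds_end) for ng in nearest
        )
        if gene_gap <= window_bp:
            neighbors.append(g)
    reported = nearest + neighbors

    def signed(g: GeneModel) -> int:
        d = dist[g.name]
        if d == 0:
            return 0
        return -d if g.cds_end <= cnv.start else d

    def position(g: GeneModel) -> str:
        d = dist[g.name]
        if d == 0:
            return "exonic" if g.name in disrupted else "intronic"
        return "left" if g.cds_end <= cnv.start else "right"

    table = pd.DataFrame(
        {
            "gene": [g.name for g in reported],
            "distance": [dist[g.name] for g in reported],
            "signed_distance": [signed(g) for g in reported],
            "position": [position(g) for g in reported],
        }
    ).sort_values("distance", kind="stable", ignore_index=True)
    return NeighborReport(
        cnv, exonic, disrupted, [g.name for g in nearest], int(d_min),
        [g.name for g in neighbors], table,
    )


@dataclass
class TADDisruption:
    """Boundary-disruption flags for one CNV across TAD profiles.

    strict: an entire inter-TAD boundary region is contained in the
    deletion; permissive: the deletion removes a TAD start or end site
    (strict always implies permissive).
    """

    cnv: Interval
    strict: Dict[str, bool] = field(default_factory=dict)
    permissive: Dict[str, bool] = field(default_factory=dict)

    def any_strict(self) -> bool:
        return any(self.strict.values())

    def any_permissive(self) -> bool:
        return any(self.permissive.values())


def tad_disruption(cnv: Interval,
                   tad_profiles: Mapping[str, Sequence[Interval]]) -> TADDisruption:
    """Strict and permissive TAD boundary disruption per profile.

    Profiles are plain interval sequences (not merged IntervalSets, which
    would fuse abutting TADs). Boundary regions are the gaps between
    consecutive TADs on a chromosome; abutting TADs contribute a 1-bp point
    boundary at the junction so strict containment stays decidable.
    Overlapping TADs within a profile raise.
    """
    import numpy as np

    result = TADDisruption(cnv)
    for name, tads in tad_profiles.items():
        strict = False
        permissive = False
        per_chrom: Dict[str, List[Interval]] = {}
        for iv in tads:
            per_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in per_chrom.items():
            ivs = sorted(ivs, key=lambda v: v.start)
            starts = np.array([v.start for v in ivs])
            ends = np.array([v.end for v in ivs])
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"profile {name}: overlapping TADs on {chrom}")
            if chrom != cnv.chrom:
                continue
            # site removal: last base of a TAD (end-1) or first base (start)
            for s, e in zip(starts, ends):
                if cnv.start <= e - 1 < cnv.end or cnv.start <= s < cnv.end:
                    permissive = True
            for e_prev, s_next in zip(ends[:-1], starts[1:]):
                b0, b1 = int(e_prev), int(s_next)
                if b1 == b0:
                    b1 = b0 + 1  # point boundary between abutting TADs
                if cnv.start <= b0 and b1 <= cnv.end:
                    strict = True
        permissive = permissive or strict
        result.strict[name] = strict
        result.permissive[name] = permissive
    return result
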