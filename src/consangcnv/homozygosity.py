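"""Runs of homozygosity by a sliding-window rule, in genetic distance.

A window of ``window_snps`` consecutive markers (step 1) qualifies when the
homozygous fraction among its non-missing calls is at least ``min_hom_frac``
(98% by default, so one or two scattered heterozygotes do not break a run).
A marker is run-supporting when at least one qualifying window covers it;
maximal stretches of run-supporting markers become runs, and only runs
spanning at least ``min_cm`` (default 5 cM) of the genetic map are retained
— the length filter enriches for recent shared ancestry over residual
population homozygosity. Family classification calls a family highly
homozygous when any child carries 2.5% or more of the autosomal genetic map
in retained runs. All threshold comparisons are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence
import warnings

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GeneticMap
from .panel import HET, MISSING, GenotypePanel

__all__ = [
    "HomozygosityRun",
    "FamilyHomozygosityClass",
    "call_homozygous_runs",
    "total_autozygosity",
    "classify_families",
    "runs_to_frame",
]

_EPS = 1e-9  # guards the inclusive >= against float representation of the fraction


@dataclass(frozen=True)
class HomozygosityRun:
    sample_id: str
    chrom: str
    start: int  # bp of first supporting marker (half-open end = last + 1)
    end: int
    first_marker: int  # index within the chromosome's marker vector
    last_marker: int
    n_markers: int
    n_het: int
    n_missing: int
    cm_length: float


def call_homozygous_runs(panel: GenotypePanel, gmap: GeneticMap,
                         window_snps: int = 100, min_hom_frac: float = 0.98,
                         min_cm: float = 5.0,
                         chromosomes: Sequence[str] | None = None
                         ) -> List[HomozygosityRun]:
    """Call retained homozygosity runs for every sample in the panel.

    Missing genotypes are excluded from both numerator and denominator of
    the window homozygosity fraction; a window with no non-missing calls
    never qualifies. Chromosomes with fewer markers than the window are
    skipped with a warning.
    """
    if window_snps < 1:
        raise ValueError("window_snps must be >= 1")
    runs: List[HomozygosityRun] = []
    chroms = (
        list(chromosomes)
        if chromosomes is not None
        else list(dict.fromkeys(panel.markers["chrom"]))
    )
    for chrom in chroms:
        cmask = (panel.markers["chrom"] == chrom).to_numpy()
        n = int(cmask.sum())
        if n < window_snps:
            warnings.warn(
                f"{chrom}: {n} markers < window of {window_snps}, skipped",
                stacklevel=2,
            )
            continue
        cm = panel.markers.loc[cmask, "cm"].to_numpy(dtype=float)
        bp = panel.markers.loc[cmask, "bp"].to_numpy(dtype=np.int64)
        geno = panel.genotypes[:, cmask]
        for si, sample in enumerate(panel.samples):
            g = geno[si]
            supported = _supported_markers(g, window_snps, min_hom_frac)
            for first, last in _stretches(supported):
                cm_len = float(cm[last] - cm[first])
                if cm_len + _EPS < min_cm:
                    continue
                seg = g[first : last + 1]
                runs.append(
                    HomozygosityRun(
                        sample_id=sample,
                        chrom=chrom,
                        start=int(bp[first]),
                        end=int(bp[last]) + 1,
                        first_marker=int(first),
                        last_marker=int(last),
                        n_markers=int(last - first + 1),
                        n_het=int((seg == HET).sum()),
                        n_missing=int((seg == MISSING).sum()),
                        cm_length=cm_len,
                    )
                )
    return runs


def _supported_markers(g: np.ndarray, window: int, min_hom_frac: float) -> np.ndarray:
    """Boolean mask: marker covered by >= 1 qualifying window."""
    nonmiss = (g != MISSING).astype(np.int32)
    het = (g == HET).astype(np.int32)
    kernel = np.ones(window, dtype=np.int32)
    win_nm = np.convolve(nonmiss, kernel, mode="valid")
    win_het = np.convolve(het, kernel, mode="valid")
    win_hom = win_nm - win_het
    ok = (win_nm > 0) & (win_hom + _EPS >= min_hom_frac * win_nm)
    # marker i is covered by windows starting in [i - window + 1, i]
    return np.convolve(ok.astype(np.int32), kernel, mode="full")[: g.shape[0]] > 0


def _stretches(mask: np.ndarray) -> Iterable[tuple[int, int]]:
    """(first, last) index pairs of maximal True stretches."""
    edges = np.flatnonzero(np.diff(np.r_[0, mask.view(np.int8), 0]))
    for s, e in zip(edges[::2], edges[1::2]):
        yield int(s), int(e) - 1


def total_autozygosity(runs: Iterable[HomozygosityRun], gmap: GeneticMap,
                       genome: GenomeLayout) -> Dict[str, float]:
    """Percent of the autosomal genetic map in retained runs, per sample.

    Input runs are assumed already length-filtered (``call_homozygous_runs``
    applies the 5 cM rule); sex-chromosome runs are ignored.
    """
    total_cm = gmap.total_length_cm(genome.autosomes)
    out: Dict[str, float] = {}
    autosomes = set(genome.autosomes)
    for run in runs:
        if run.chrom not in autosomes:
            continue
        out[run.sample_id] = out.get(run.sample_id, 0.0) + run.cm_length
    return {s: 100.0 * v / total_cm for s, v in out.items()}


@dataclass(frozen=True)
class FamilyHomozygosityClass:
    family_id: str
    child_fractions: Mapping[str, float]  # percent of autosomal map, per child
    high: bool

    @property
    def label(self) -> str:
        return "high" if self.high else "low"


def classify_families(family_children: Mapping[str, Sequence[str]],
                      fractions: Mapping[str, float],
                      threshold: float = 2.5) -> List[FamilyHomozygosityClass]:
    """High/low homozygosity per family: high iff any child >= threshold (%).

    ``fractions`` maps child id -> percent autozygosity; children absent
    from it count as 0%.
    """
    out: List[FamilyHomozygosityClass] = []
    for fam, children in family_children.items():
        if not children:
            raise ValueError(f"family {fam} has no children")
        fr = {c: float(fractions.get(c, 0.0)) for c in children}
        out.append(
            FamilyHomozygosityClass(fam, fr, max(fr.values()) >= threshold)
        )
    return out


def runs_to_frame(runs: Iterable[HomozygosityRun]) -> pd.DataFrame:
    """Runs as a BED+extras table (0-based half-open coordinates)."""
    return pd.DataFrame(
        [
            (r.chrom, r.start, r.end, r.sample_id, r.n_markers, r.n_het,
             r.n_missing, r.cm_length)
            for r in runs
        ],
        columns=["chrom", "start", "end", "sample_id", "n_markers", "n_het",
                 "n_missing", "cm_length"],
    )
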