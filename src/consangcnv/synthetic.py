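"""Synthetic cohorts with known ground truth.

Every analysis stage in this package can be exercised without restricted
genotype data: this module generates consanguineous pedigrees and drops
founder haplotypes through them with recombination, reads genotypes off the
resulting ancestry mosaics, emulates multi-caller CNV call sets with
boundary jitter and false calls, and lays down annotation tracks with
controllable genome coverage.

Crossover model
---------------
Meioses place crossovers as a Poisson process with rate 1 per Morgan on the
genetic map, without interference and without sex-specific maps; chromosomes
assort independently (phase re-randomized at every chromosome start). This
is the standard gene-dropping assumption. Autozygosity is read off directly
as the regions where an individual's two haplotypes carry the same founder
haplotype label, so the simulated truth is exact, not inferred.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import GenomeLayout, GeneticMap, Interval, IntervalSet
from .panel import HET, HOM_ALT, HOM_REF, MISSING, GenotypePanel

__all__ = [
    "PedigreeSpec",
    "PedigreeMember",
    "AutozygousSegment",
    "TrueAutozygosity",
    "synthetic_genome",
    "toy_genome",
    "first_cousin_pedigree",
    "second_cousin_pedigree",
    "outbred_pedigree",
    "cousin_pedigree",
    "gene_drop",
    "gene_drop_ancestry",
    "autozygous_fraction",
    "simulate_founder_ibd",
    "make_marker_table",
    "genotypes_from_ancestry",
    "synth_sex_panel",
    "CallerSpec",
    "synth_caller_calls",
    "synth_tracks",
    "synth_state_track",
    "synth_case_control_cnvs",
    "CHROMHMM_STATES",
    "ENHANCER_STATES",
]


# ---------------------------------------------------------------------------
# Default synthetic genome: 22 autosomes, ~3,500 cM total, 1 cM ~ 1 Mb.
# ---------------------------------------------------------------------------

_CHROM_CM = np.array(
    [284.0, 269.3, 223.3, 214.6, 204.1, 192.0, 187.2, 168.0, 166.4, 181.0,
     158.2, 174.7, 125.9, 119.5, 141.4, 134.0, 128.5, 117.5, 107.0, 107.9,
     62.8, 70.8]
)


def synthetic_genome(n_chrom: int = 22) -> Tuple[GenomeLayout, GeneticMap]:
    """Autosomal genome of ``n_chrom`` chromosomes (~3,500 cM at 22).

    Physical scale is 1 Mb per cM with a linear map per chromosome.
    """
    if not 1 <= n_chrom <= 22:
        raise ValueError("n_chrom must be in 1..22")
    lengths = {f"chr{i + 1}": int(_CHROM_CM[i] * 1e6) for i in range(n_chrom)}
    genome = GenomeLayout(lengths=lengths)
    gmap = GeneticMap(
        {c: [(0.0, 0.0), (float(L), L / 1e6)] for c, L in lengths.items()}
    )
    return genome, gmap


def toy_genome(n_chrom: int = 2, cm_per_chrom: float = 150.0) -> Tuple[GenomeLayout, GeneticMap]:
    """Small genome for fast tests: equal chromosomes, 1 Mb per cM."""
    lengths = {f"chr{i + 1}": int(cm_per_chrom * 1e6) for i in range(n_chrom)}
    genome = GenomeLayout(lengths=lengths)
    gmap = GeneticMap(
        {c: [(0.0, 0.0), (float(L), L / 1e6)] for c, L in lengths.items()}
    )
    return genome, gmap


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    sex: str = "unknown"  # "male" / "female" / "unknown"
    affected: bool = False
    father: str | None = None
    mother: str | None = None

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class PedigreeSpec:
    """A pedigree: founders have no parents, everyone else exactly two."""

    members: List[PedigreeMember]
    family_id: str = "FAM1"

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate individual ids")
        known = set(ids)
        for m in self.members:
            has = (m.father is not None, m.mother is not None)
            if has[0] != has[1]:
                raise ValueError(f"{m.individual_id}: needs two parents or none")
            for p in (m.father, m.mother):
                if p is not None and p not in known:
                    raise ValueError(f"{m.individual_id}: unknown parent {p}")
        self.topological_order()  # raises on cycles

    def __getitem__(self, individual_id: str) -> PedigreeMember:
        for m in self.members:
            if m.individual_id == individual_id:
                return m
        raise KeyError(individual_id)

    @property
    def founders(self) -> List[str]:
        return [m.individual_id for m in self.members if m.is_founder]

    def topological_order(self) -> List[str]:
        """Parents-before-children ordering; raises on parent-link cycles."""
        order: List[str] = []
        placed: set = set()
        remaining = list(self.members)
        while remaining:
            progress = False
            still: List[PedigreeMember] = []
            for m in remaining:
                if m.is_founder or (m.father in placed and m.mother in placed):
                    order.append(m.individual_id)
                    placed.add(m.individual_id)
                    progress = True
                else:
                    still.append(m)
            if not progress:
                raise ValueError("pedigree contains a parent-link cycle")
            remaining = still
        return order

    def offspring_ids(self) -> List[str]:
        """Non-founders that are nobody's parent (the bottom generation)."""
        parents = {m.father for m in self.members} | {m.mother for m in self.members}
        return [
            m.individual_id
            for m in self.members
            if not m.is_founder and m.individual_id not in parents
        ]


def cousin_pedigree(degree: int = 1, child_id: str = "child",
                    affected: bool = True) -> PedigreeSpec:
    """Offspring of ``degree``-th cousins sharing one ancestral couple.

    First cousins (degree 1) give an inbreeding coefficient of 1/16 and an
    autozygosity loop of 6 meioses per shared ancestor; second cousins
    (degree 2) give 1/64 and an 8-meiosis loop.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    members = [
        PedigreeMember("anc_f", "male"),
        PedigreeMember("anc_m", "female"),
        PedigreeMember("lineA_0", "male", father="anc_f", mother="anc_m"),
        PedigreeMember("lineB_0", "female", father="anc_f", mother="anc_m"),
    ]
    last = {"A": "lineA_0", "B": "lineB_0"}
    for g in range(1, degree + 1):
        for line in ("A", "B"):
            spouse = f"spouse{line}_{g}"
            sex = "male" if line == "A" else "female"
            spouse_sex = "female" if sex == "male" else "male"
            members.append(PedigreeMember(spouse, spouse_sex))
            parent = last[line]
            father, mother = (parent, spouse) if sex == "female" else (spouse, parent)
            # keep sexes alternating so father/mother slots are well-formed
            child = f"line{line}_{g}"
            members.append(PedigreeMember(child, sex, father=father, mother=mother))
            last[line] = child
    members.append(
        PedigreeMember(child_id, "unknown", affected=affected,
                       father=last["A"], mother=last["B"])
    )
    return PedigreeSpec(members)


def first_cousin_pedigree(child_id: str = "child") -> PedigreeSpec:
    return cousin_pedigree(1, child_id=child_id)


def second_cousin_pedigree(child_id: str = "child") -> PedigreeSpec:
    return cousin_pedigree(2, child_id=child_id)


def outbred_pedigree(child_id: str = "child") -> PedigreeSpec:
    return PedigreeSpec(
        [
            PedigreeMember("father", "male"),
            PedigreeMember("mother", "female"),
            PedigreeMember(child_id, "unknown", affected=True,
                           father="father", mother="mother"),
        ]
    )


# ---------------------------------------------------------------------------
# Gene dropping on a concatenated genetic-map axis
# ---------------------------------------------------------------------------


class _GenomeAxis:
    """Autosomes laid end to end on a single cM axis.

    Independent assortment is realized by re-randomizing meiotic phase at
    every chromosome start, so one Poisson crossover draw covers the genome.
    """

    def __init__(self, gmap: GeneticMap, genome: GenomeLayout):
        self.chroms = list(genome.autosomes)
        missing = [c for c in self.chroms if c not in gmap.chromosomes]
        if missing:
            raise ValueError(f"genetic map missing chromosomes: {missing}")
        self.len_cm = np.array([gmap.chrom_length_cm(c) for c in self.chroms])
        self.offsets = np.concatenate([[0.0], np.cumsum(self.len_cm)])
        self.starts = self.offsets[:-1]
        self.total = float(self.offsets[-1])
        self.cm0 = np.array([gmap._cm[c][0] for c in self.chroms])
        self._gmap = gmap

    def to_bp(self, chrom_idx: int, global_cm: float) -> int:
        chrom = self.chroms[chrom_idx]
        local = global_cm - self.offsets[chrom_idx] + self.cm0[chrom_idx]
        return int(round(self._gmap.interpolate_bp(chrom, local)))


@dataclass
class _Haplotype:
    """Piecewise-constant founder-label mosaic on the global cM axis."""

    breaks: np.ndarray  # segment start positions, breaks[0] == 0
    labels: np.ndarray  # founder-haplotype label per segment

    def labels_at(self, pos: np.ndarray) -> np.ndarray:
        return self.labels[np.searchsorted(self.breaks, pos, side="right") - 1]

    def compressed(self) -> "_Haplotype":
        keep = np.r_[True, self.labels[1:] != self.labels[:-1]]
        return _Haplotype(self.breaks[keep], self.labels[keep])


def _meiosis(hap_a: _Haplotype, hap_b: _Haplotype, axis: _GenomeAxis,
             rng: np.random.Generator) -> _Haplotype:
    """One meiosis: recombine the two parental haplotypes into a gamete."""
    n_x = rng.poisson(axis.total / 100.0)
    xs = np.sort(rng.uniform(0.0, axis.total, n_x))
    phases = rng.integers(0, 2, len(axis.chroms))

    def source_at(pos: np.ndarray) -> np.ndarray:
        c = np.searchsorted(axis.starts, pos, side="right") - 1
        k = (
            np.searchsorted(xs, pos, side="right")
            - np.searchsorted(xs, axis.starts[c], side="right")
        )
        return (phases[c] + k) % 2

    seg_starts = np.unique(np.concatenate([axis.starts, xs]))
    seg_src = source_at(seg_starts)

    def kept_breaks(hap: _Haplotype, want_src: int) -> np.ndarray:
        src = seg_src[np.searchsorted(seg_starts, hap.breaks, side="right") - 1]
        return hap.breaks[src == want_src]

    breaks = np.unique(
        np.concatenate([seg_starts, kept_breaks(hap_a, 0), kept_breaks(hap_b, 1)])
    )
    src = seg_src[np.searchsorted(seg_starts, breaks, side="right") - 1]
    labels = np.where(src == 0, hap_a.labels_at(breaks), hap_b.labels_at(breaks))
    return _Haplotype(breaks, labels).compressed()


def _drop_once(pedigree: PedigreeSpec, axis: _GenomeAxis,
               rng: np.random.Generator) -> Dict[str, Tuple[_Haplotype, _Haplotype]]:
    haps: Dict[str, Tuple[_Haplotype, _Haplotype]] = {}
    label = 0
    root = np.array([0.0])
    for ind_id in pedigree.topological_order():
        member = pedigree[ind_id]
        if member.is_founder:
            haps[ind_id] = (
                _Haplotype(root, np.array([label])),
                _Haplotype(root, np.array([label + 1])),
            )
            label += 2
        else:
            haps[ind_id] = (
                _meiosis(*haps[member.father], axis, rng),
                _meiosis(*haps[member.mother], axis, rng),
            )
    return haps


@dataclass(frozen=True)
class AutozygousSegment:
    chrom: str
    start: int  # bp, half-open
    end: int
    cm_length: float


@dataclass
class TrueAutozygosity:
    """Ground-truth autozygous segments for one individual."""

    individual_id: str
    segments: List[AutozygousSegment] = field(default_factory=list)

    def total_cm(self, min_cm: float = 0.0) -> float:
        return float(sum(s.cm_length for s in self.segments if s.cm_length >= min_cm))


def _autozygosity(ind_id: str, h1: _Haplotype, h2: _Haplotype,
                  axis: _GenomeAxis) -> TrueAutozygosity:
    breaks = np.unique(
        np.concatenate([h1.breaks, h2.breaks, axis.starts, [axis.total]])
    )
    starts = breaks[:-1]
    eq = h1.labels_at(starts) == h2.labels_at(starts)
    chrom_idx = np.searchsorted(axis.starts, starts, side="right") - 1
    # group contiguous equal-label stretches within a chromosome
    new_run = np.r_[True, (eq[1:] != eq[:-1]) | (chrom_idx[1:] != chrom_idx[:-1])]
    run_id = np.cumsum(new_run) - 1
    segments: List[AutozygousSegment] = []
    for rid in np.unique(run_id):
        sel = run_id == rid
        if not eq[sel][0]:
            continue
        g0 = float(starts[sel][0])
        last = np.flatnonzero(sel)[-1]
        g1 = float(breaks[last + 1])
        ci = int(chrom_idx[sel][0])
        bp0 = axis.to_bp(ci, g0)
        bp1 = axis.to_bp(ci, g1)
        if bp1 <= bp0:
            continue  # degenerate under a flat map region
        segments.append(
            AutozygousSegment(axis.chroms[ci], bp0, bp1, g1 - g0)
        )
    return TrueAutozygosity(ind_id, segments)


def gene_drop_ancestry(pedigree: PedigreeSpec, gmap: GeneticMap,
                       genome: GenomeLayout, seed: int | np.random.Generator = 0
                       ) -> Dict[str, Tuple[_Haplotype, _Haplotype]]:
    """One gene-drop replicate, returning full ancestry mosaics."""
    axis = _GenomeAxis(gmap, genome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _drop_once(pedigree, axis, rng)


def gene_drop(pedigree: PedigreeSpec, gmap: GeneticMap, genome: GenomeLayout,
              n_replicates: int = 1, seed: int | np.random.Generator = 0,
              individuals: Sequence[str] | None = None
              ) -> List[Dict[str, TrueAutozygosity]]:
    """Drop founder haplotypes through the pedigree ``n_replicates`` times.

    Returns, per replicate, the true autozygosity of each requested
    individual (default: the pedigree's bottom-generation offspring).
    """
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    axis = _GenomeAxis(gmap, genome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    who = list(individuals) if individuals is not None else pedigree.offspring_ids()
    out: List[Dict[str, TrueAutozygosity]] = []
    for _ in range(n_replicates):
        haps = _drop_once(pedigree, axis, rng)
        out.append(
            {ind: _autozygosity(ind, *haps[ind], axis) for ind in who}
        )
    return out


def autozygous_fraction(truth: TrueAutozygosity, gmap: GeneticMap,
                        genome: GenomeLayout, min_cm: float = 5.0) -> float:
    """Percent of the autosomal genetic map in segments >= ``min_cm``."""
    total = gmap.total_length_cm(genome.autosomes)
    return 100.0 * truth.total_cm(min_cm=min_cm) / total


# ---------------------------------------------------------------------------
# Founder-IBD segment lengths
# ---------------------------------------------------------------------------


def simulate_founder_ibd(meioses_per_side: int, gmap: GeneticMap,
                         genome: GenomeLayout, n: int = 1000,
                         seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Length distribution of autozygous segments through a deep loop.

    Two independent descent lines of ``meioses_per_side`` meioses each
    connect an individual's two alleles to a single founder haplotype
    (total loop = 2 x meioses_per_side meioses). Conditional on a region
    being autozygous through the loop, its segment boundaries are set by the
    nearest crossover in *any* of the loop's meioses, i.e. by a Poisson
    process at ``k/100`` per cM with ``k`` the loop size, truncated at
    chromosome ends. Interior segment lengths are therefore exponential with
    mean ``100/k`` cM; this is the standard IBD segment-length model and the
    quantity the 5 cM retention/rejection calibrations are about.

    Returns a table with columns replicate, chrom, length_cm, interior
    (False for segments abutting a chromosome end).
    """
    if meioses_per_side < 1:
        raise ValueError("meioses_per_side must be >= 1")
    if n <= 0:
        raise ValueError("n must be positive")
    axis = _GenomeAxis(gmap, genome)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = 2 * meioses_per_side
    rate = k / 100.0  # crossovers per cM over the whole loop
    reps, chrom_codes, seg_len, seg_int = [], [], [], []
    for rep in range(n):
        n_x = rng.poisson(axis.total * rate)
        xs = np.sort(rng.uniform(0.0, axis.total, n_x))
        bounds = np.unique(np.concatenate([axis.offsets, xs]))
        lengths = np.diff(bounds)
        chrom_idx = np.searchsorted(axis.starts, bounds[:-1], side="right") - 1
        interior = ~(
            np.isin(bounds[:-1], axis.offsets) | np.isin(bounds[1:], axis.offsets)
        )
        keep = lengths > 0
        reps.append(np.full(int(keep.sum()), rep, dtype=np.int32))
        chrom_codes.append(chrom_idx[keep].astype(np.int16))
        seg_len.append(lengths[keep])
        seg_int.append(interior[keep])
    codes = np.concatenate(chrom_codes)
    return pd.DataFrame(
        {
            "replicate": np.concatenate(reps),
            "chrom": pd.Categorical.from_codes(codes, categories=axis.chroms),
            "length_cm": np.concatenate(seg_len),
            "interior": np.concatenate(seg_int),
        }
    )


# ---------------------------------------------------------------------------
# Genotypes from ancestry
# ---------------------------------------------------------------------------


def make_marker_table(genome: GenomeLayout, gmap: GeneticMap, n_markers: int,
                      seed: int | np.random.Generator = 0,
                      chromosomes: Sequence[str] | None = None) -> pd.DataFrame:
    """Random marker positions, count per chromosome proportional to length."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chroms = list(chromosomes) if chromosomes is not None else list(genome.autosomes)
    lengths = np.array([genome.lengths[c] for c in chroms], dtype=float)
    per = np.maximum(1, np.round(n_markers * lengths / lengths.sum()).astype(int))
    rows = []
    for chrom, m in zip(chroms, per):
        bp = np.sort(rng.choice(genome.lengths[chrom], size=m, replace=False))
        cm = gmap.interpolate_cm(chrom, bp)
        for j, (b, c) in enumerate(zip(bp, cm)):
            rows.append((chrom, f"{chrom}_m{j}", float(c), int(b)))
    return pd.DataFrame(rows, columns=["chrom", "marker_id", "cm", "bp"])


@dataclass
class SyntheticGenotypes:
    panel: GenotypePanel
    truth: Dict[str, TrueAutozygosity]
    allele_freqs: np.ndarray


def genotypes_from_ancestry(ancestry: Mapping[str, Tuple[_Haplotype, _Haplotype]],
                            markers: pd.DataFrame, gmap: GeneticMap,
                            genome: GenomeLayout,
                            missing_rate: float = 0.0, error_rate: float = 0.0,
                            seed: int | np.random.Generator = 0,
                            allele_freqs: np.ndarray | None = None
                            ) -> SyntheticGenotypes:
    """Read genotypes off ancestry mosaics under an allele-frequency model.

    Founder haplotypes carry alleles drawn per marker from ``allele_freqs``
    (default Uniform(0.1, 0.9) frequencies); genotype error flips one allele
    with probability ``error_rate`` (so a truly homozygous site is mis-read
    as heterozygous at ~``error_rate``); missingness is applied last.
    """
    if not 0 <= missing_rate <= 1 or not 0 <= error_rate <= 1:
        raise ValueError("rates must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    axis = _GenomeAxis(gmap, genome)
    chrom_pos = {c: i for i, c in enumerate(axis.chroms)}
    unknown = set(markers["chrom"]) - set(chrom_pos)
    if unknown:
        raise ValueError(f"markers on chromosomes outside the map: {sorted(unknown)}")
    global_cm = (
        np.array([axis.offsets[chrom_pos[c]] for c in markers["chrom"]])
        + np.array(
            [gmap.interpolate_cm(c, b) for c, b in zip(markers["chrom"], markers["bp"])]
        )
        - np.array([axis.cm0[chrom_pos[c]] for c in markers["chrom"]])
    )
    n_markers = len(markers)
    max_label = max(int(h.labels.max()) for pair in ancestry.values() for h in pair)
    if allele_freqs is None:
        allele_freqs = rng.uniform(0.1, 0.9, n_markers)
    founder_alleles = (
        rng.uniform(size=(max_label + 1, n_markers)) < allele_freqs
    ).astype(np.int8)

    samples = list(ancestry)
    geno = np.empty((len(samples), n_markers), dtype=np.int8)
    truth: Dict[str, TrueAutozygosity] = {}
    for i, sid in enumerate(samples):
        h1, h2 = ancestry[sid]
        a1 = founder_alleles[h1.labels_at(global_cm), np.arange(n_markers)]
        a2 = founder_alleles[h2.labels_at(global_cm), np.arange(n_markers)]
        g = (a1 + a2).astype(np.int8)
        if error_rate > 0:
            flip = rng.uniform(size=n_markers) < error_rate
            which = rng.integers(0, 2, n_markers)  # which allele to flip
            g_f = g.copy()
            g_f[flip & (g == HOM_REF)] = HET
            g_f[flip & (g == HOM_ALT)] = HET
            het_flip = flip & (g == HET)
            g_f[het_flip] = np.where(which[het_flip] == 0, HOM_REF, HOM_ALT)
            g = g_f
        if missing_rate > 0:
            g[rng.uniform(size=n_markers) < missing_rate] = MISSING
        geno[i] = g
        truth[sid] = _autozygosity(sid, h1, h2, axis)
    panel = GenotypePanel(samples, markers.reset_index(drop=True), geno)
    return SyntheticGenotypes(panel, truth, allele_freqs)


def synth_sex_panel(sexes: Mapping[str, str], n_x: int = 200, n_y: int = 50,
                    seed: int | np.random.Generator = 0) -> GenotypePanel:
    """X/Y-marker panel consistent with declared sexes, for sex inference.

    Males: hemizygous X (no true hets) and present Y calls; females:
    ordinary diploid X heterozygosity and missing Y.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = [("chrX", f"x_m{j}", 0.0, 1000 * (j + 1)) for j in range(n_x)]
    rows += [("chrY", f"y_m{j}", 0.0, 1000 * (j + 1)) for j in range(n_y)]
    markers = pd.DataFrame(rows, columns=["chrom", "marker_id", "cm", "bp"])
    samples = list(sexes)
    geno = np.zeros((len(samples), n_x + n_y), dtype=np.int8)
    for i, sid in enumerate(samples):
        male = sexes[sid] == "male"
        freq = rng.uniform(0.1, 0.9, n_x)
        if male:
            geno[i, :n_x] = np.where(rng.uniform(size=n_x) < freq, HOM_ALT, HOM_REF)
            geno[i, n_x:] = np.where(
                rng.uniform(size=n_y) < 0.5, HOM_ALT, HOM_REF
            )
        else:
            a1 = rng.uniform(size=n_x) < freq
            a2 = rng.uniform(size=n_x) < freq
            geno[i, :n_x] = (a1.astype(np.int8) + a2.astype(np.int8))
            geno[i, n_x:] = MISSING
    return GenotypePanel(samples, markers, geno)


# ---------------------------------------------------------------------------
# Multi-caller CNV call emulation
# ---------------------------------------------------------------------------


@dataclass
class CallerSpec:
    """Detection behaviour of one emulated CNV caller."""

    caller: str
    sensitivity: float = 1.0
    jitter_sd_bp: float = 0.0
    fp_rate: float = 0.0  # mean false calls per sample
    fp_length_bp: float = 50_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if self.jitter_sd_bp < 0 or self.fp_rate < 0 or self.fp_length_bp <= 0:
            raise ValueError("invalid caller spec")


def synth_caller_calls(true_cnvs: pd.DataFrame, caller_specs: Sequence[CallerSpec],
                       genome: GenomeLayout,
                       seed: int | np.random.Generator = 0,
                       fp_cn_weights: Mapping[int, float] | None = None
                       ) -> pd.DataFrame:
    """Emulate per-caller call tables from a table of true CNVs.

    ``true_cnvs`` columns: sample_id, chrom, start, end, cn, probes. Each
    caller detects each true CNV independently with its sensitivity, jitters
    boundaries with Gaussian noise (clipped to positive length), and emits a
    Poisson number of uniformly placed false calls per sample.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if fp_cn_weights is None:
        fp_cn_weights = {1: 0.55, 3: 0.30, 0: 0.05, 4: 0.10}
    cn_classes = np.array(list(fp_cn_weights))
    cn_p = np.array(list(fp_cn_weights.values()), dtype=float)
    cn_p = cn_p / cn_p.sum()
    chroms = list(genome.autosomes)
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=float)
    chrom_p = chrom_len / chrom_len.sum()
    samples = sorted(set(true_cnvs["sample_id"])) if len(true_cnvs) else []

    rows = []
    for spec in caller_specs:
        for row in true_cnvs.itertuples(index=False):
            if rng.uniform() >= spec.sensitivity:
                continue
            s, e = int(row.start), int(row.end)
            if spec.jitter_sd_bp > 0:
                s = int(round(s + rng.normal(0, spec.jitter_sd_bp)))
                e = int(round(e + rng.normal(0, spec.jitter_sd_bp)))
                s = max(0, min(s, genome.lengths[row.chrom] - 1))
                e = max(s + 1, min(e, genome.lengths[row.chrom]))
            rows.append((row.sample_id, spec.caller, row.chrom, s, e,
                         int(row.cn), int(row.probes)))
        for sid in samples:
            for _ in range(rng.poisson(spec.fp_rate)):
                ci = rng.choice(len(chroms), p=chrom_p)
                length = max(1, int(rng.exponential(spec.fp_length_bp)))
                length = min(length, genome.lengths[chroms[ci]] - 1)
                start = int(rng.integers(0, genome.lengths[chroms[ci]] - length))
                rows.append((sid, spec.caller, chroms[ci], start, start + length,
                             int(rng.choice(cn_classes, p=cn_p)),
                             int(rng.integers(5, 50))))
    return pd.DataFrame(
        rows, columns=["sample_id", "caller", "chrom", "start", "end", "cn", "probes"]
    )


# ---------------------------------------------------------------------------
# Annotation tracks
# ---------------------------------------------------------------------------

CHROMHMM_STATES: Tuple[str, ...] = (
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv", "13_ReprPC",
    "14_ReprPCWk", "15_Quies",
)
ENHANCER_STATES: Tuple[str, ...] = ("6_EnhG", "7_Enh")


@dataclass
class SyntheticTrack:
    track: "object"  # IntensityTrack or StateTrack
    peaks: IntervalSet
    realized_coverage: float


def _place_peaks(genome: GenomeLayout, coverage_fraction: float,
                 mean_peak_bp: float, bin_bp: int,
                 rng: np.random.Generator) -> IntervalSet:
    if not 0 < coverage_fraction < 1:
        raise ValueError("coverage_fraction must be in (0, 1)")
    chroms = list(genome.autosomes)
    chrom_len = np.array([genome.lengths[c] for c in chroms], dtype=float)
    if mean_peak_bp >= chrom_len.min():
        raise ValueError("mean peak length exceeds a chromosome length")
    total = chrom_len.sum()
    target = coverage_fraction * total
    chrom_p = chrom_len / total
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    covered = 0.0
    attempts = 0
    while covered < target:
        attempts += 1
        if attempts > 200_000:
            raise RuntimeError("could not reach requested peak coverage")
        ci = rng.choice(len(chroms), p=chrom_p)
        chrom = chroms[ci]
        length = max(bin_bp, int(round(rng.exponential(mean_peak_bp) / bin_bp)) * bin_bp)
        if length >= genome.lengths[chrom]:
            continue
        start = int(rng.integers(0, (genome.lengths[chrom] - length) // bin_bp)) * bin_bp
        end = start + length
        if any(s < end and e > start for s, e in placed[chrom]):
            continue
        placed[chrom].append((start, end))
        covered += length
    return IntervalSet(
        Interval(c, s, e) for c, ivs in placed.items() for s, e in ivs
    )


def synth_tracks(genome: GenomeLayout, coverage_fraction: float = 0.07,
                 mean_peak_bp: float = 2_000.0, peak_score: float = 40.0,
                 background_score: float = 5.0, bin_bp: int = 25,
                 seed: int | np.random.Generator = 0) -> SyntheticTrack:
    """Intensity track with non-overlapping peaks at a target coverage.

    Peak lengths are exponential around ``mean_peak_bp`` (snapped to the bin
    grid); peak bins carry ``peak_score``, the rest ``background_score``.
    """
    from .genome import IntensityTrack

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peaks = _place_peaks(genome, coverage_fraction, mean_peak_bp, bin_bp, rng)
    track = IntensityTrack(genome, bin_bp=bin_bp)
    for chrom in track.scores:
        track.scores[chrom][:] = background_score
    for iv in peaks:
        vec = track.scores[iv.chrom]
        vec[iv.start // bin_bp : -(-iv.end // bin_bp)] = peak_score
    total = float(sum(genome.lengths[c] for c in genome.autosomes))
    return SyntheticTrack(track, peaks, peaks.total_length / total)


def synth_state_track(genome: GenomeLayout, coverage_fraction: float = 0.07,
                      mean_peak_bp: float = 2_000.0, bin_bp: int = 200,
                      state: str = "7_Enh", background: str = "15_Quies",
                      seed: int | np.random.Generator = 0) -> SyntheticTrack:
    """Categorical variant: ``state`` bins over the peaks, quiescent elsewhere."""
    from .genome import StateTrack

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    peaks = _place_peaks(genome, coverage_fraction, mean_peak_bp, bin_bp, rng)
    track = StateTrack(genome, CHROMHMM_STATES, bin_bp=bin_bp, fill=background)
    idx = track._index[state]
    for iv in peaks:
        vec = track.states[iv.chrom]
        vec[iv.start // bin_bp : -(-iv.end // bin_bp)] = idx
    total = float(sum(genome.lengths[c] for c in genome.autosomes))
    return SyntheticTrack(track, peaks, peaks.total_length / total)


# ---------------------------------------------------------------------------
# Case/control CNV sets for the Monte-Carlo harness
# ---------------------------------------------------------------------------


def sample_cnv_lengths(n: int, rng: np.random.Generator,
                       median_bp: float = 20_000.0, sigma: float = 1.0,
                       min_bp: int = 2_000, max_bp: int = 900_000) -> np.ndarray:
    """Deletion lengths: lognormal with a ~20 kb median and a long right
    tail, clipped to the 2 kb - 900 kb range observed for validated
    biallelic deletions."""
    ln = rng.lognormal(np.log(median_bp), sigma, n)
    return np.clip(ln, min_bp, max_bp).astype(np.int64)


def synth_case_control_cnvs(affected_lengths: Sequence[int],
                            unaffected_lengths: Sequence[int],
                            overlap_bias: float, peaks: IntervalSet,
                            mappable: IntervalSet,
                            seed: int | np.random.Generator = 0
                            ) -> Tuple[List[Interval], List[Interval]]:
    """Place case/control CNVs on the mappable genome with optional bias.

    Unbiased CNVs use the same uniform placement contract as the Monte-Carlo
    null sampler; a fraction ``overlap_bias`` of the affected CNVs is placed
    uniformly among the peak-overlapping placements (rejection sampling).
    """
    from .enrichment import PlacementSampler

    if not 0 <= overlap_bias <= 1:
        raise ValueError("overlap_bias must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sampler = PlacementSampler(mappable)

    def place(length: int, force_overlap: bool) -> Interval:
        for _ in range(100_000):
            iv = sampler.place(length, rng)
            if not force_overlap or peaks.intersects_interval(iv):
                return iv
        raise RuntimeError(f"no peak-overlapping placement found for length {length}")

    n_forced = int(round(overlap_bias * len(affected_lengths)))
    affected = [
        place(int(ln), i < n_forced) for i, ln in enumerate(affected_lengths)
    ]
    unaffected = [place(int(ln), False) for ln in unaffected_lengths]
    return affected, unaffected
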