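"""Readers and writers for the text formats the pipeline touches.

BED and bedGraph-like inputs are 0-based half-open. The parsers are thin
wrappers over :func:`pandas.read_csv` with the coordinate/invariant checks
the domain types require.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

from .genome import (
    GeneModel,
    GenomeLayout,
    GeneticMap,
    IntensityTrack,
    Interval,
    IntervalSet,
    StateTrack,
)
from .panel import GenotypePanel

__all__ = [
    "read_intervals",
    "write_bed",
    "read_intensity_track",
    "read_state_track",
    "read_genetic_map",
    "read_gene_models",
    "read_caller_calls",
    "read_genotype_panel",
    "write_genotype_panel",
    "normalize_chrom",
]


class ParseError(ValueError):
    """Malformed input record, with file and line context."""


def normalize_chrom(name: str, strip_prefix: bool = False) -> str:
    """Exact-match chromosome naming, optionally dropping a 'chr' prefix."""
    name = str(name)
    if strip_prefix and name.startswith("chr"):
        return name[3:]
    return name


def _read_table(path, n_min_cols: int, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < n_min_cols:
        raise ParseError(f"{path}: {what} needs >= {n_min_cols} tab-separated columns")
    return df


def read_intervals(
    path, genome: GenomeLayout | None = None, on_unknown_chrom: str = "error"
) -> IntervalSet:
    """Read a BED file into a normalized :class:`IntervalSet`.

    ``on_unknown_chrom``: "error" rejects records on chromosomes absent from
    ``genome``; "skip" drops them silently.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        return IntervalSet()
    df = _read_table(path, 3, "BED")
    intervals: List[Interval] = []
    for lineno, (chrom, start, end) in enumerate(
        zip(df[0], df[1], df[2]), start=1
    ):
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if s >= e:
            raise ParseError(f"{path}:{lineno}: start {s} >= end {e}")
        if genome is not None and chrom not in genome.lengths:
            if on_unknown_chrom == "skip":
                continue
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
        intervals.append(Interval(chrom, s, e))
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path, extra: Sequence[Sequence] | None = None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if extra is not None:
                cols.extend(str(x) for x in extra[i])
            fh.write("\t".join(cols) + "\n")


def read_intensity_track(path, genome: GenomeLayout, bin_bp: int = 25) -> IntensityTrack:
    """Read a 4-column bedGraph-like score file into a dense bin track.

    Records not aligned to the bin grid are resampled by per-bin maximum;
    uncovered bins score 0. Negative scores are rejected.
    """
    track = IntensityTrack(genome, bin_bp=bin_bp)
    path = Path(path)
    if path.stat().st_size == 0:
        return track
    df = _read_table(path, 4, "bedGraph")
    for lineno, (chrom, start, end, score) in enumerate(
        zip(df[0], df[1], df[2], df[3]), start=1
    ):
        try:
            s, e, v = int(start), int(end), float(score)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: malformed record") from exc
        if s >= e:
            raise ParseError(f"{path}:{lineno}: start {s} >= end {e}")
        if v < 0:
            raise ParseError(f"{path}:{lineno}: negative score {v}")
        if chrom not in track.scores:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
        vec = track.scores[chrom]
        b0 = s // bin_bp
        b1 = -(-e // bin_bp)  # ceil: last bin touched, exclusive
        b1 = min(b1, vec.shape[0])
        np.maximum(vec[b0:b1], v, out=vec[b0:b1])
    return track


def write_intensity_track(track: IntensityTrack, path) -> None:
    """Write non-zero bins as bedGraph records, one per bin."""
    with open(path, "w") as fh:
        for chrom, vec in track.scores.items():
            nz = np.flatnonzero(vec)
            for b in nz:
                s = int(b) * track.bin_bp
                e = min(s + track.bin_bp, track.genome.lengths[chrom])
                fh.write(f"{chrom}\t{s}\t{e}\t{vec[b]:g}\n")


def read_state_track(
    path, genome: GenomeLayout, alphabet: Sequence[str], bin_bp: int = 200,
    fill: str | None = None,
) -> StateTrack:
    """Read a 4-column BED segmentation (label in column 4) into a StateTrack.

    Segment boundaries must align to the bin grid.
    """
    track = StateTrack(genome, alphabet, bin_bp=bin_bp, fill=fill)
    df = _read_table(path, 4, "state BED")
    index = {s: i for i, s in enumerate(track.alphabet)}
    for lineno, (chrom, start, end, label) in enumerate(
        zip(df[0], df[1], df[2], df[3]), start=1
    ):
        s, e = int(start), int(end)
        if s >= e:
            raise ParseError(f"{path}:{lineno}: start {s} >= end {e}")
        if s % bin_bp != 0:
            raise ParseError(f"{path}:{lineno}: segment not aligned to {bin_bp} bp grid")
        if label not in index:
            raise ParseError(f"{path}:{lineno}: state {label!r} outside alphabet")
        if chrom not in track.states:
            raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom}")
        vec = track.states[chrom]
        vec[s // bin_bp : min(-(-e // bin_bp), vec.shape[0])] = index[label]
    return track


def read_genetic_map(path) -> GeneticMap:
    """Read a PLINK-style .map file (chrom, id, cM, bp) into a GeneticMap."""
    df = _read_table(path, 4, ".map")
    anchors: Dict[str, List] = {}
    for chrom, _mid, cm, bp in zip(df[0], df[1], df[2], df[3]):
        anchors.setdefault(chrom, []).append((int(bp), float(cm)))
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for chrom in gmap.chromosomes:
            bp = gmap._bp[chrom]
            cm = gmap._cm[chrom]
            for i, (b, c) in enumerate(zip(bp, cm)):
                fh.write(f"{chrom}\tanchor_{chrom}_{i}\t{c:g}\t{int(b)}\n")


def read_gene_models(path) -> List[GeneModel]:
    """Read a refFlat-like TSV of gene models.

    Columns: geneName, chrom, strand, txStart, txEnd, cdsStart, cdsEnd,
    exonCount, exonStarts (comma list), exonEnds (comma list). Noncoding
    transcripts have cdsStart == cdsEnd.
    """
    df = _read_table(path, 10, "refFlat")
    genes: List[GeneModel] = []
    for row in df.itertuples(index=False):
        name, chrom, strand = row[0], row[1], row[2]
        tx_s, tx_e = int(row[3]), int(row[4])
        cds_s, cds_e = int(row[5]), int(row[6])
        exon_starts = [int(x) for x in str(row[8]).rstrip(",").split(",") if x]
        exon_ends = [int(x) for x in str(row[9]).rstrip(",").split(",") if x]
        coding_exons = []
        if cds_e > cds_s:
            for es, ee in zip(exon_starts, exon_ends):
                lo, hi = max(es, cds_s), min(ee, cds_e)
                if lo < hi:
                    coding_exons.append((lo, hi))
        genes.append(
            GeneModel(name, chrom, strand, tx_s, tx_e, cds_s, cds_e,
                      tuple(coding_exons))
        )
    return genes


CALLER_COLUMNS = ["sample_id", "caller", "chrom", "start", "end", "cn", "probes"]


def read_caller_calls(path) -> pd.DataFrame:
    """Read a per-caller CNV call table (TSV with a header row)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CALLER_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    df = df.astype({"start": np.int64, "end": np.int64, "cn": int, "probes": int})
    if (df["start"] >= df["end"]).any():
        raise ParseError(f"{path}: record with start >= end")
    if (df["probes"] < 1).any():
        raise ParseError(f"{path}: probe count < 1")
    return df


def read_genotype_panel(genotype_path, map_path) -> GenotypePanel:
    """Read a marker-major genotype TSV plus a PLINK-style .map.

    The genotype table has columns marker_id then one column per sample with
    codes 0/1/2 and NA for missing; marker order must match the .map file.
    """
    geno = pd.read_csv(genotype_path, sep="\t")
    mp = _read_table(map_path, 4, ".map")
    markers = pd.DataFrame(
        {
            "chrom": mp[0].to_numpy(),
            "marker_id": mp[1].to_numpy(),
            "cm": mp[2].astype(float).to_numpy(),
            "bp": mp[3].astype(np.int64).to_numpy(),
        }
    )
    if not (markers["marker_id"].to_numpy() == geno["marker_id"].to_numpy()).all():
        raise ParseError("marker order mismatch between genotype table and map")
    samples = [c for c in geno.columns if c != "marker_id"]
    mat = geno[samples].to_numpy(dtype=float).T
    mat = np.where(np.isnan(mat), -1, mat).astype(np.int8)
    return GenotypePanel(samples, markers, mat)


def write_genotype_panel(panel: GenotypePanel, genotype_path, map_path) -> None:
    out = pd.DataFrame({"marker_id": panel.markers["marker_id"]})
    for i, s in enumerate(panel.samples):
        col = panel.genotypes[i].astype(object)
        col[panel.genotypes[i] < 0] = np.nan
        out[s] = col
    out.to_csv(genotype_path, sep="\t", index=False, na_rep="NA")
    with open(map_path, "w") as fh:
        for row in panel.markers.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.marker_id}\t{row.cm:g}\t{int(row.bp)}\n")
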