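"""Sample- and family-level quality control.

Three independent gates: per-platform chip metrics (call rate, CNV-call
count), genotype-based sex inference against declared sex, and pedigree
relationship verification by genotype/allele sharing counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .panel import HET, HOM_ALT, HOM_REF, MISSING, GenotypePanel
from .synthetic import PedigreeSpec

__all__ = [
    "PlatformThresholds",
    "DEFAULT_PLATFORMS",
    "qc_filter",
    "infer_sex",
    "RelationshipStats",
    "verify_relationships",
]


@dataclass(frozen=True)
class PlatformThresholds:
    """QC gates for one array platform.

    ``min_call_rate`` is a fraction; samples fail when call rate is below
    it, or when the CNV-call count reaches ``max_cnv_calls``.
    """

    min_call_rate: float
    max_cnv_calls: int


# High-density arrays get the stricter call-rate gate (97%) and the higher
# CNV-count cap (200); lower-density platforms use 95% / 125.
DEFAULT_PLATFORMS: Dict[str, PlatformThresholds] = {
    "affy6": PlatformThresholds(0.97, 200),
    "affy5": PlatformThresholds(0.95, 125),
    "affy500k": PlatformThresholds(0.95, 125),
}


def qc_filter(metrics: pd.DataFrame,
              platforms: Mapping[str, PlatformThresholds] | None = None
              ) -> pd.DataFrame:
    """Pass/fail each sample with enumerated reasons.

    ``metrics`` columns: sample_id, platform, call_rate (fraction),
    n_cnv_calls. Unknown platforms raise.
    """
    platforms = dict(DEFAULT_PLATFORMS if platforms is None else platforms)
    rows = []
    for row in metrics.itertuples(index=False):
        if row.platform not in platforms:
            raise KeyError(f"no thresholds configured for platform {row.platform!r}")
        thr = platforms[row.platform]
        reasons: List[str] = []
        if row.call_rate < thr.min_call_rate:
            reasons.append(
                f"call rate {row.call_rate:.3f} < {thr.min_call_rate:.2f}"
            )
        if row.n_cnv_calls >= thr.max_cnv_calls:
            reasons.append(f"CNV count >= {thr.max_cnv_calls}")
        rows.append((row.sample_id, not reasons, ";".join(reasons)))
    return pd.DataFrame(rows, columns=["sample_id", "passed", "reasons"])


def infer_sex(panel: GenotypePanel, declared: Mapping[str, str] | None = None,
              max_male_x_het: float = 0.05, min_y_call_rate: float = 0.5,
              x_chrom: str = "chrX", y_chrom: str = "chrY") -> pd.DataFrame:
    """Call sex from X heterozygosity and Y call rate.

    Male iff the X heterozygosity rate (hets / non-missing X calls) is below
    ``max_male_x_het`` and the Y call rate is above ``min_y_call_rate``;
    female otherwise. With no sex-chromosome markers the call is
    "undetermined". Samples conflicting with a declared sex are flagged.
    """
    xmask = panel.marker_mask([x_chrom])
    ymask = panel.marker_mask([y_chrom])
    rows = []
    for i, sid in enumerate(panel.samples):
        gx = panel.genotypes[i, xmask]
        gy = panel.genotypes[i, ymask]
        x_nm = int((gx != MISSING).sum())
        x_het = float((gx == HET).sum() / x_nm) if x_nm else np.nan
        y_rate = float((gy != MISSING).sum() / gy.shape[0]) if gy.shape[0] else np.nan
        if x_nm == 0 and gy.shape[0] == 0:
            call = "undetermined"
        elif x_nm and x_het < max_male_x_het and (
            np.isnan(y_rate) or y_rate > min_y_call_rate
        ):
            call = "male"
        else:
            call = "female"
        mismatch = (
            declared is not None
            and sid in declared
            and call != "undetermined"
            and declared[sid] in ("male", "female")
            and call != declared[sid]
        )
        rows.append((sid, x_het, y_rate, call, bool(mismatch)))
    return pd.DataFrame(
        rows, columns=["sample_id", "x_het_rate", "y_call_rate", "inferred_sex",
                       "sex_mismatch"]
    )


@dataclass(frozen=True)
class RelationshipStats:
    """Sharing statistics for one declared sample pair."""

    pair: Tuple[str, str]
    declared: str  # "parent-child" | "siblings"
    n_markers: int  # markers non-missing in both
    identical_fraction: float
    share_allele_fraction: float
    opposite_hom_fraction: float
    action: str  # keep | drop | duplicate | insufficient


def _pair_stats(g1: np.ndarray, g2: np.ndarray) -> Tuple[int, float, float, float]:
    both = (g1 != MISSING) & (g2 != MISSING)
    n = int(both.sum())
    if n == 0:
        return 0, np.nan, np.nan, np.nan
    a, b = g1[both], g2[both]
    identical = float((a == b).sum() / n)
    opp_hom = float(
        (((a == HOM_REF) & (b == HOM_ALT)) | ((a == HOM_ALT) & (b == HOM_REF))).sum()
        / n
    )
    # genotypes share >= 1 allele unless they are opposite homozygotes
    share = 1.0 - opp_hom
    return n, identical, share, opp_hom


def verify_relationships(panel: GenotypePanel, pedigree: PedigreeSpec,
                         max_parent_child_opp_hom: float = 0.01,
                         sib_identical_window: Tuple[float, float] = (0.45, 0.9),
                         duplicate_identical: float = 0.95,
                         min_markers: int = 100) -> List[RelationshipStats]:
    """Check declared parent-child and full-sib pairs against genotypes.

    Parent-child pairs share an allele at every marker, so their
    opposite-homozygote fraction should only reflect genotype error; full
    sibs share genotypes at an intermediate rate. Near-total genotype
    identity marks a duplicate/MZ pair.
    """
    in_panel = set(panel.samples)
    pairs: List[Tuple[str, str, str]] = []
    by_parents: Dict[Tuple[str, str], List[str]] = {}
    for m in pedigree.members:
        if m.is_founder:
            continue
        for p in (m.father, m.mother):
            if p in in_panel and m.individual_id in in_panel:
                pairs.append((p, m.individual_id, "parent-child"))
        by_parents.setdefault((m.father, m.mother), []).append(m.individual_id)
    for sibs in by_parents.values():
        for i in range(len(sibs)):
            for j in range(i + 1, len(sibs)):
                if sibs[i] in in_panel and sibs[j] in in_panel:
                    pairs.append((sibs[i], sibs[j], "siblings"))

    out: List[RelationshipStats] = []
    for a, b, declared in pairs:
        n, ident, share, opp = _pair_stats(
            panel.sample_genotypes(a), panel.sample_genotypes(b)
        )
        if n < min_markers:
            action = "insufficient"
        elif ident >= duplicate_identical:
            action = "duplicate"
        elif declared == "parent-child":
            action = "keep" if opp <= max_parent_child_opp_hom else "drop"
        else:
            lo, hi = sib_identical_window
            action = "keep" if lo <= ident <= hi else "drop"
        out.append(RelationshipStats((a, b), declared, n, ident, share, opp, action))
    return out
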