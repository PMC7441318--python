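"""Consensus CNV building, rarity classification, and burden testing.

Consensus across callers is geometric: per sample and copy-number class,
the per-base depth of distinct supporting callers is computed and maximal
regions with depth >= ``min_algorithms`` become consensus events. Classes
are never pooled — a locus called CNV0 by two callers and CNV1 by two
others has no 3-caller consensus in either class. Rarity is matched against
a control catalog of the SAME copy-number class (a locus seen only as a
single-copy loss in controls does not make a biallelic deletion common).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Interval
from .synthetic import PedigreeSpec

__all__ = [
    "ConsensusCNV",
    "build_consensus",
    "classify_rarity",
    "flag_de_novo",
    "select_cnv0",
    "burden_test",
    "carrier_counts",
    "consensus_to_frame",
]

CN_CLASSES = (0, 1, 3, 4)


@dataclass(frozen=True)
class ConsensusCNV:
    """A caller-supported CNV for one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cn: int
    callers: FrozenSet[str]
    min_probes: int
    rare: bool | None = None
    inheritance: str | None = None  # "de novo" | "inherited" | "unknown"
    validated: bool | None = None

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_callers(self) -> int:
        return len(self.callers)


def _merge_caller_intervals(group: pd.DataFrame) -> Dict[str, np.ndarray]:
    """Per caller, union of its call intervals (sorted, merged)."""
    out: Dict[str, np.ndarray] = {}
    for caller, sub in group.groupby("caller"):
        arr = np.sort(sub[["start", "end"]].to_numpy(dtype=np.int64), axis=0)
        merged: List[List[int]] = []
        for s, e in sorted(map(tuple, sub[["start", "end"]].to_numpy())):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[caller] = np.array(merged, dtype=np.int64)
    return out


def build_consensus(calls: pd.DataFrame, min_algorithms: int = 3,
                    min_probes: int = 1,
                    callers: Sequence[str] | None = None) -> List[ConsensusCNV]:
    """Consensus CNVs from a multi-caller call table.

    ``calls`` columns: sample_id, caller, chrom, start, end, cn, probes.
    The consensus probe count is the minimum probe count among the calls of
    supporting callers overlapping the consensus region; events below
    ``min_probes`` are dropped. ``callers`` declares the full caller roster
    (a caller that produced no calls still counts as run); by default the
    roster is inferred from the table.
    """
    n_callers = len(callers) if callers is not None else calls["caller"].nunique()
    if min_algorithms > n_callers:
        raise ValueError(
            f"min_algorithms={min_algorithms} exceeds the {n_callers} distinct "
            "callers present"
        )
    out: List[ConsensusCNV] = []
    for (sample, chrom, cn), group in calls.groupby(
        ["sample_id", "chrom", "cn"], sort=True
    ):
        per_caller = _merge_caller_intervals(group)
        deltas: Dict[int, int] = {}  # net caller-depth change per position
        for arr in per_caller.values():
            for s, e in arr:
                deltas[int(s)] = deltas.get(int(s), 0) + 1
                deltas[int(e)] = deltas.get(int(e), 0) - 1
        depth = 0
        region_start = None
        regions: List[Tuple[int, int]] = []
        for pos in sorted(deltas):
            new_depth = depth + deltas[pos]
            if depth < min_algorithms <= new_depth:
                region_start = pos
            elif new_depth < min_algorithms <= depth:
                regions.append((region_start, pos))
                region_start = None
            depth = new_depth
        for rs, re_ in regions:
            supporters = set()
            probe_min = None
            for caller, arr in per_caller.items():
                overl = (arr[:, 0] < re_) & (arr[:, 1] > rs)
                if overl.any():
                    supporters.add(caller)
            probes = group.loc[
                (group["start"] < re_) & (group["end"] > rs), "probes"
            ]
            probe_min = int(probes.min())
            if probe_min < min_probes:
                continue
            out.append(
                ConsensusCNV(sample, chrom, rs, re_, int(cn),
                             frozenset(supporters), probe_min)
            )
    return out


def classify_rarity(cnv: ConsensusCNV, catalog: pd.DataFrame) -> bool:
    """True (rare) unless >50% of the query overlaps one same-class entry.

    ``catalog`` columns: chrom, start, end, cn (plus optional count). The
    overlap fraction uses the query length as denominator and the strict
    inequality, so exactly half-overlap stays rare.
    """
    if len(catalog) == 0:
        return True
    same = catalog[(catalog["cn"] == cnv.cn) & (catalog["chrom"] == cnv.chrom)]
    if len(same) == 0:
        return True
    ov = (
        np.minimum(same["end"].to_numpy(), cnv.end)
        - np.maximum(same["start"].to_numpy(), cnv.start)
    )
    return not bool((ov > 0.5 * cnv.length).any())


def _direction(cn: int) -> str:
    return "loss" if cn < 2 else "gain"


def flag_de_novo(cnvs: Iterable[ConsensusCNV], caller_calls: pd.DataFrame,
                 pedigree: PedigreeSpec,
                 genotyped: Set[str] | None = None) -> List[ConsensusCNV]:
    """Label each child CNV de novo / inherited / unknown.

    Parental evidence is deliberately lenient: ANY single-caller parental
    call of the same gain/loss direction overlapping the child CNV by >= 1
    bp marks it inherited (guards against caller boundary jitter producing
    false de novos). Both parents must be genotyped for a call either way.
    """
    if genotyped is None:
        genotyped = set(caller_calls["sample_id"])
    out: List[ConsensusCNV] = []
    for cnv in cnvs:
        try:
            member = pedigree[cnv.sample_id]
        except KeyError:
            member = None
        if (
            member is None
            or member.is_founder
            or member.father not in genotyped
            or member.mother not in genotyped
        ):
            out.append(replace(cnv, inheritance="unknown"))
            continue
        want = _direction(cnv.cn)
        parental = caller_calls[
            caller_calls["sample_id"].isin([member.father, member.mother])
            & (caller_calls["chrom"] == cnv.chrom)
            & (caller_calls["start"] < cnv.end)
            & (caller_calls["end"] > cnv.start)
        ]
        hit = any(_direction(int(cn)) == want for cn in parental["cn"])
        out.append(replace(cnv, inheritance="inherited" if hit else "de novo"))
    return out


def carrier_counts(cnvs: Iterable[ConsensusCNV], samples: pd.DataFrame
                   ) -> Tuple[int, int]:
    """(affected carriers, unaffected carriers): individuals with >= 1 event."""
    carriers = {c.sample_id for c in cnvs}
    aff = samples["affected"].astype(bool)
    in_set = samples["sample_id"].isin(carriers)
    return int((in_set & aff).sum()), int((in_set & ~aff).sum())


def select_cnv0(consensus: Sequence[ConsensusCNV], catalog: pd.DataFrame,
                samples: pd.DataFrame,
                excluded_families: Set[str] | None = None,
                min_algorithms: int = 3, min_probes: int = 5
                ) -> Tuple[List[ConsensusCNV], pd.DataFrame]:
    """Increasingly stringent selection cascade for biallelic deletions.

    Stages: drop excluded (known-cause) families -> keep copy-number 0 ->
    keep >= ``min_algorithms`` callers and >= ``min_probes`` probes -> keep
    rare against the control catalog. Returns the surviving events and a
    per-stage report of event and carrier counts in both phenotype groups.

    ``samples`` columns: sample_id, family_id, affected (bool).
    """
    excluded_families = excluded_families or set()
    fam = dict(zip(samples["sample_id"], samples["family_id"]))
    kept_samples = samples[~samples["family_id"].isin(excluded_families)]
    n_aff = int(kept_samples["affected"].astype(bool).sum())
    n_un = int((~kept_samples["affected"].astype(bool)).sum())

    stages: List[Tuple[str, List[ConsensusCNV]]] = []
    cur = [c for c in consensus if fam.get(c.sample_id) not in excluded_families]
    stages.append(("exclude known-cause families", cur))
    cur = [c for c in cur if c.cn == 0]
    stages.append(("copy number 0", cur))
    cur = [c for c in cur
           if c.n_callers >= min_algorithms and c.min_probes >= min_probes]
    stages.append((f">= {min_algorithms} algorithms & >= {min_probes} probes", cur))
    cur = [replace(c, rare=classify_rarity(c, catalog)) for c in cur]
    cur = [c for c in cur if c.rare]
    stages.append(("rare vs control catalog", cur))

    aff_ids = set(kept_samples.loc[kept_samples["affected"].astype(bool), "sample_id"])
    rows = []
    for name, events in stages:
        ev_aff = sum(1 for c in events if c.sample_id in aff_ids)
        ev_un = len(events) - ev_aff
        ca, cu = carrier_counts(events, kept_samples)
        p = burden_test(ca, n_aff, cu, n_un) if n_aff and n_un else np.nan
        rows.append((name, ev_aff, ev_un, ca, cu, n_aff, n_un, p))
    report = pd.DataFrame(
        rows,
        columns=["stage", "events_affected", "events_unaffected",
                 "carriers_affected", "carriers_unaffected",
                 "n_affected", "n_unaffected", "fisher_p"],
    )
    return cur, report


def burden_test(n_affected_carriers: int, n_affected: int,
                n_unaffected_carriers: int, n_unaffected: int) -> float:
    """One-sided Fisher exact p for carrier excess in affected individuals.

    Exact hypergeometric upper tail with both margins fixed:
    P(X >= observed affected carriers).
    """
    if n_affected <= 0 or n_unaffected <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= n_affected_carriers <= n_affected
            and 0 <= n_unaffected_carriers <= n_unaffected):
        raise ValueError("carrier counts exceed group sizes")
    total = n_affected + n_unaffected
    k_total = n_affected_carriers + n_unaffected_carriers
    return float(
        stats.hypergeom.sf(n_affected_carriers - 1, total, k_total, n_affected)
    )


def consensus_to_frame(cnvs: Iterable[ConsensusCNV]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.sample_id, c.chrom, c.start, c.end, c.cn, ",".join(sorted(c.callers)),
             c.n_callers, c.min_probes, c.rare, c.inheritance, c.validated,
             c.length / 1000.0)
            for c in cnvs
        ],
        columns=["sample_id", "chrom", "start", "end", "cn", "callers",
                 "n_callers", "min_probes", "rare", "inheritance", "validated",
                 "size_kb"],
    )
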