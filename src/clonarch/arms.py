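"""Arm-level somatic copy-number alteration (SCNA) events.

Per-segment total copy numbers are compared against the sample's rounded
ploidy to classify amplification vs deletion.  Within each chromosome arm
the altered segment lengths are accumulated per clonality state: an arm is
called clonal (or subclonal) when the cumulative length of clonal (or
subclonal) altered segments exceeds 50% of the arm, and the arm-level CCF is
the median CCF of the contributing segments.  Segment clonality uses the
same CCF >= 0.95 definition as SNVs, applied as a point threshold on the
annotated per-segment CCF.

When both arms of a chromosome carry the same-direction event in a sample,
the pair is reported as a single whole-chromosome event (e.g. ``del(9)``);
otherwise the arm label is used (e.g. ``del(14q)``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ccf import CLONAL_CCF_THRESHOLD
from .io import ArmDefinition, SamplePurity, SegmentRecord

__all__ = [
    "ArmEvent",
    "classify_segment_direction",
    "segment_clonality",
    "aggregate_arm",
    "arm_ccf",
    "build_arm_events",
    "merge_chromosome_events",
    "frequency_filter",
]


@dataclass
class ArmEvent:
    sample_id: str
    arm_id: str
    direction: str  # "amp" | "del"
    clonality: str  # "clonal" | "subclonal" | "none"
    ccf: float | None
    clonal_length_fraction: float
    subclonal_length_fraction: float

    @property
    def event_id(self) -> str:
        return f"{self.direction}({self.arm_id})"


def classify_segment_direction(segment: SegmentRecord, sample_ploidy: float) -> str:
    """amp / del / neutral relative to the rounded sample ploidy."""
    base = round(sample_ploidy)
    if segment.total_copy_number > base:
        return "amp"
    if segment.total_copy_number < base:
        return "del"
    return "neutral"


def segment_clonality(segment: SegmentRecord) -> str | None:
    """Clonal iff the annotated segment CCF >= 0.95 (point threshold).

    Returns None when the segment has no CCF annotation (such segments do
    not contribute to arm aggregation).
    """
    if segment.segment_ccf is None:
        return None
    return "clonal" if segment.segment_ccf >= CLONAL_CCF_THRESHOLD else "subclonal"


def arm_ccf(ccfs) -> float:
    """Median CCF of the contributing segments (midpoint for even counts)."""
    ccfs = [c for c in ccfs if c is not None]
    if not ccfs:
        raise ValueError("no contributing segment CCFs")
    return float(np.median(ccfs))


def _overlap(seg: SegmentRecord, arm: ArmDefinition) -> int:
    lo = max(seg.start, arm.start)
    hi = min(seg.end, arm.end)
    return max(0, hi - lo + 1)


def aggregate_arm(
    segments,
    arm: ArmDefinition,
    direction: str,
    sample_ploidy: float,
) -> ArmEvent | None:
    """Aggregate one sample's altered segments of one direction over one arm.

    Returns None when no altered segment of that direction overlaps the arm.
    """
    clonal_len = 0
    subclonal_len = 0
    clonal_ccfs: list[float] = []
    subclonal_ccfs: list[float] = []
    sample_id = None
    for seg in segments:
        if seg.chromosome != arm.chromosome:
            continue
        if classify_segment_direction(seg, sample_ploidy) != direction:
            continue
        ov = _overlap(seg, arm)
        if ov == 0:
            continue
        state = segment_clonality(seg)
        if state is None:
            continue
        sample_id = seg.sample_id
        if state == "clonal":
            clonal_len += ov
            clonal_ccfs.append(seg.segment_ccf)
        else:
            subclonal_len += ov
            subclonal_ccfs.append(seg.segment_ccf)
    if sample_id is None:
        return None
    cf = clonal_len / arm.length
    sf = subclonal_len / arm.length
    if cf > 0.5:
        clonality, ccfs = "clonal", clonal_ccfs
    elif sf > 0.5:
        clonality, ccfs = "subclonal", subclonal_ccfs
    else:
        clonality, ccfs = "none", clonal_ccfs + subclonal_ccfs
    return ArmEvent(
        sample_id=sample_id,
        arm_id=arm.arm_id,
        direction=direction,
        clonality=clonality,
        ccf=arm_ccf(ccfs) if ccfs else None,
        clonal_length_fraction=cf,
        subclonal_length_fraction=sf,
    )


def build_arm_events(
    segments: list[SegmentRecord],
    purities: list[SamplePurity],
    arms: list[ArmDefinition],
) -> list[ArmEvent]:
    """Arm-level events for every sample and arm.

    Amp and del on the same arm are tracked as two candidates; the one with
    the larger altered length fraction is reported.
    """
    ploidy = {p.sample_id: p.ploidy for p in purities}
    by_sample: dict[str, list[SegmentRecord]] = {}
    for s in segments:
        by_sample.setdefault(s.sample_id, []).append(s)
    events: list[ArmEvent] = []
    for sample_id, segs in sorted(by_sample.items()):
        if sample_id not in ploidy:
            raise ValueError(f"no purity/ploidy entry for sample {sample_id}")
        for arm in arms:
            cands = []
            for direction in ("amp", "del"):
                ev = aggregate_arm(segs, arm, direction, ploidy[sample_id])
                if ev is not None:
                    cands.append(ev)
            if not cands:
                continue
            cands.sort(
                key=lambda e: e.clonal_length_fraction + e.subclonal_length_fraction,
                reverse=True,
            )
            events.append(cands[0])
    return events


def merge_chromosome_events(events: list[ArmEvent], arms: list[ArmDefinition]) -> pd.DataFrame:
    """Event table with whole-chromosome labels where both arms agree.

    If a sample carries the same-direction event on both arms of a
    chromosome, the two rows merge into one labelled ``dir(chrom)`` with
    length fractions re-weighted over the whole chromosome and CCF the
    median of the two arm CCFs; otherwise rows keep their arm labels.
    Returns columns: sample_id, event_id, direction, clonality, ccf.
    """
    arm_by_id = {a.arm_id: a for a in arms}
    chrom_len: dict[str, int] = {}
    for a in arms:
        chrom_len[a.chromosome] = chrom_len.get(a.chromosome, 0) + a.length
    rows = []
    by_key: dict[tuple[str, str, str], list[ArmEvent]] = {}
    for e in events:
        chrom = arm_by_id[e.arm_id].chromosome
        by_key.setdefault((e.sample_id, chrom, e.direction), []).append(e)
    for (sample_id, chrom, direction), evs in by_key.items():
        arms_on_chrom = [a for a in arm_by_id.values() if a.chromosome == chrom]
        if len(evs) == 2 and len(arms_on_chrom) == 2:
            l1 = arm_by_id[evs[0].arm_id].length
            l2 = arm_by_id[evs[1].arm_id].length
            total = chrom_len[chrom]
            cf = (evs[0].clonal_length_fraction * l1 + evs[1].clonal_length_fraction * l2) / total
            sf = (
                evs[0].subclonal_length_fraction * l1 + evs[1].subclonal_length_fraction * l2
            ) / total
            if cf > 0.5:
                clonality = "clonal"
            elif sf > 0.5:
                clonality = "subclonal"
            else:
                clonality = "none"
            ccfs = [e.ccf for e in evs if e.ccf is not None]
            rows.append(
                (
                    sample_id,
                    f"{direction}({chrom})",
                    direction,
                    clonality,
                    float(np.median(ccfs)) if ccfs else np.nan,
                )
            )
        else:
            for e in evs:
                rows.append(
                    (sample_id, e.event_id, direction, e.clonality, e.ccf if e.ccf is not None else np.nan)
                )
    return pd.DataFrame(rows, columns=["sample_id", "event_id", "direction", "clonality", "ccf"])


def frequency_filter(
    arm_event_table: pd.DataFrame,
    gene_calls: pd.DataFrame,
    n_samples: int,
    min_gene_freq: float = 0.03,
    min_arm_freq: float = 0.10,
) -> tuple[list[str], list[str]]:
    """Background-noise filter on event frequency across the cohort.

    Genes are kept when non-silently mutated in >= 3% of samples; arm-level
    events (label incl. direction) when altered with a clonal or subclonal
    call in >= 10% of samples.
    """
    if n_samples == 0:
        raise ValueError("n_samples must be positive")
    genes: list[str] = []
    if len(gene_calls):
        gcounts = gene_calls.groupby("event_id")["sample_id"].nunique()
        genes = sorted(g for g, c in gcounts.items() if c / n_samples >= min_gene_freq)
    arms_kept: list[str] = []
    if len(arm_event_table):
        called = arm_event_table[arm_event_table["clonality"].isin(["clonal", "subclonal"])]
        acounts = called.groupby("event_id")["sample_id"].nunique()
        arms_kept = sorted(a for a, c in acounts.items() if c / n_samples >= min_arm_freq)
    return genes, arms_kept
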