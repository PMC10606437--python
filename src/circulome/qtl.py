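"""Overlap of mapped eccDNAs and their coding sequences with
herbicide-resistance QTL intervals.

QTLs come from prior genetic mapping and are inputs here. An eccDNA (or a
CDS predicted on one) matches a QTL by any >= 1 bp overlap. Each QTL is
classified by the phenotype of the coding sequences it contains: HR-only,
HS-only, both, or none.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .io import AnnotationFeature, MappedInterval
from .windows import WindowCount


@dataclass
class QtlReport:
    qtl_id: str
    n_hr_ecc: int
    n_hs_ecc: int
    cds_class: str  # HR-only | HS-only | both | none


@dataclass
class QtlSummary:
    n_qtl: int
    n_with_cds: int
    n_hs_only: int
    n_hr_only: int
    n_hr_ecc_total: int  # unique HR eccDNAs overlapping any QTL
    n_hs_ecc_total: int


def overlap_qtl(
    ecc_intervals: list[MappedInterval],
    cds_intervals: list[MappedInterval],
    qtls: list[AnnotationFeature],
    group_map: dict[str, str],
    dedupe: bool = True,
) -> tuple[list[QtlReport], QtlSummary]:
    """Per-QTL eccDNA counts by phenotype plus CDS-content classification.

    ``dedupe`` counts unique eccDNA ids per phenotype in the totals (an
    eccDNA overlapping several QTLs counts once); without it the per-QTL
    counts are summed. Overlapping QTLs are allowed and an eccDNA may count
    toward several.
    """

    def build(intervals: list[MappedInterval]) -> dict[str, IntervalTree]:
        trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            if iv.sample not in group_map:
                raise ValueError(f"sample {iv.sample!r} missing from group map")
            trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        return trees

    ecc_trees = build(ecc_intervals)
    cds_trees = build(cds_intervals)
    reports = []
    hr_ids: set[str] = set()
    hs_ids: set[str] = set()
    n_hr_sum = n_hs_sum = 0
    for q in sorted(qtls, key=lambda f: f.id):
        ecc_hits = [
            h.data for h in ecc_trees.get(q.chrom, IntervalTree()).overlap(q.start, q.end)
        ]
        cds_hits = [
            h.data for h in cds_trees.get(q.chrom, IntervalTree()).overlap(q.start, q.end)
        ]
        hr_here = {h.ecc_id for h in ecc_hits if group_map[h.sample] == "HR"}
        hs_here = {h.ecc_id for h in ecc_hits if group_map[h.sample] == "HS"}
        hr_ids |= hr_here
        hs_ids |= hs_here
        n_hr_sum += len(hr_here)
        n_hs_sum += len(hs_here)
        has_hr_cds = any(group_map[h.sample] == "HR" for h in cds_hits)
        has_hs_cds = any(group_map[h.sample] == "HS" for h in cds_hits)
        cds_class = (
            "both" if has_hr_cds and has_hs_cds
            else "HR-only" if has_hr_cds
            else "HS-only" if has_hs_cds
            else "none"
        )
        reports.append(
            QtlReport(qtl_id=q.id, n_hr_ecc=len(hr_here), n_hs_ecc=len(hs_here), cds_class=cds_class)
        )
    summary = QtlSummary(
        n_qtl=len(reports),
        n_with_cds=sum(r.cds_class != "none" for r in reports),
        n_hs_only=sum(r.cds_class == "HS-only" for r in reports),
        n_hr_only=sum(r.cds_class == "HR-only" for r in reports),
        n_hr_ecc_total=len(hr_ids) if dedupe else n_hr_sum,
        n_hs_ecc_total=len(hs_ids) if dedupe else n_hs_sum,
    )
    return reports, summary


def hr_exclusive_windows(
    window_counts: list[WindowCount],
    qtls: list[AnnotationFeature],
    group_map: dict[str, str],
    min_samples: int = 3,
) -> list[WindowCount]:
    """Windows overlapping a QTL that carry eccDNAs from at least
    ``min_samples`` distinct HR samples and none from any HS sample."""
    qtl_trees: dict[str, IntervalTree] = {}
    for q in qtls:
        qtl_trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end, q.id)
    out = []
    for w in sorted(window_counts, key=lambda w: (w.chrom, w.start)):
        t = qtl_trees.get(w.chrom)
        if t is None or not t.overlap(w.start, w.end):
            continue
        for s in w.per_sample:
            if s not in group_map:
                raise ValueError(f"sample {s!r} missing from group map")
        n_hr_samples = sum(
            1 for s, c in w.per_sample.items() if c > 0 and group_map[s] == "HR"
        )
        n_hs = sum(c for s, c in w.per_sample.items() if group_map[s] == "HS")
        if n_hr_samples >= min_samples and n_hs == 0:
            out.append(w)
    return out
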