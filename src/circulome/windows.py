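"""Genome-window density mapping of eccDNA origins and hotspot calling.

The genome is tiled with non-overlapping windows of fixed width (default
500 kb; the terminal window of each chromosome may be short). A mapped
eccDNA increments every window it overlaps by >= 1 bp (BEDtools-intersect
semantics); a midpoint-assignment mode is available behind a flag. Window
counts are aggregated per sample and per phenotype (herbicide-resistant HR
vs -sensitive HS), and hotspot windows are called as those whose grand count
exceeds the genome-wide mean by at least k standard deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import AnnotationFeature, MappedInterval

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 500_000


@dataclass
class WindowCount:
    chrom: str
    start: int
    end: int
    per_sample: dict[str, int] = field(default_factory=dict)
    hr_total: int | None = None
    hs_total: int | None = None

    @property
    def grand(self) -> int:
        if self.hr_total is not None and self.hs_total is not None:
            return self.hr_total + self.hs_total
        return sum(self.per_sample.values())


@dataclass
class MappingStats:
    """Placement bookkeeping: how many alignments landed on anchored
    chromosomes vs unanchored/unknown sequences, and (when the total circle
    inventory is supplied) the overall mapping rate."""

    n_intervals: int
    n_anchored: int
    n_unplaced: int
    n_total_ecc: int | None = None

    @property
    def unplaced_fraction(self) -> float:
        return self.n_unplaced / self.n_intervals if self.n_intervals else 0.0

    @property
    def mapped_fraction(self) -> float | None:
        if self.n_total_ecc is None:
            return None
        mapped_ids = self.n_anchored + self.n_unplaced
        return mapped_ids / self.n_total_ecc if self.n_total_ecc else 0.0


@dataclass
class HotspotCall:
    window: WindowCount
    score: float
    passed: bool


def make_windows(genome_index: dict[str, int], window_size: int = DEFAULT_WINDOW) -> list[WindowCount]:
    """Tile each chromosome exactly; the last window may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    out = []
    for chrom, length in genome_index.items():
        for start in range(0, length, window_size):
            out.append(WindowCount(chrom=chrom, start=start, end=min(start + window_size, length)))
    return out


def count_windows(
    intervals: list[MappedInterval],
    genome_index: dict[str, int],
    window_size: int = DEFAULT_WINDOW,
    group_map: dict[str, str] | None = None,
    midpoint: bool = False,
    n_total_ecc: int | None = None,
) -> tuple[list[WindowCount], MappingStats]:
    """Count mapped eccDNAs per window.

    Default counting increments every window an interval overlaps, so a
    boundary-spanning eccDNA contributes to both neighbours; ``midpoint``
    assigns each interval to the single window holding its midpoint.
    Intervals on chromosomes absent from ``genome_index`` go to an
    "unplaced" bucket (with a warning) and are excluded from the grid.
    """
    windows = make_windows(genome_index, window_size)
    index: dict[tuple[str, int], WindowCount] = {}
    for w in windows:
        index[(w.chrom, w.start // window_size)] = w
    n_unplaced = 0
    for iv in intervals:
        if iv.chrom not in genome_index:
            n_unplaced += 1
            continue
        clip_end = min(iv.end, genome_index[iv.chrom])
        if midpoint:
            mid = (iv.start + clip_end) // 2
            wins = [mid // window_size]
        else:
            wins = range(iv.start // window_size, (clip_end - 1) // window_size + 1)
        for wi in wins:
            w = index.get((iv.chrom, wi))
            if w is not None:
                w.per_sample[iv.sample] = w.per_sample.get(iv.sample, 0) + 1
    if n_unplaced:
        logger.warning("%d interval(s) on chromosomes outside the genome index (unplaced)", n_unplaced)
    if group_map is not None:
        for w in windows:
            for s in w.per_sample:
                if s not in group_map:
                    raise ValueError(f"sample {s!r} missing from group map")
            w.hr_total = sum(c for s, c in w.per_sample.items() if group_map[s] == "HR")
            w.hs_total = sum(c for s, c in w.per_sample.items() if group_map[s] == "HS")
    stats = MappingStats(
        n_intervals=len(intervals),
        n_anchored=len(intervals) - n_unplaced,
        n_unplaced=n_unplaced,
        n_total_ecc=n_total_ecc,
    )
    return windows, stats


def phenotype_totals(window: WindowCount) -> tuple[int, int, int]:
    """(HR total, HS total, grand) for one window."""
    if window.hr_total is None or window.hs_total is None:
        raise ValueError("window has no phenotype totals; count with a group map")
    return window.hr_total, window.hs_total, window.hr_total + window.hs_total


def call_hotspots(windows: list[WindowCount], k: float = 3.0) -> list[HotspotCall]:
    """Score each window as standard deviations above the genome-wide mean.

    Note that with N windows the population z-score is bounded by
    sqrt(N - 1): a single extreme window among few can never reach a large
    k, so hotspot calling needs a reasonably fine grid.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows to call hotspots")
    counts = np.array([w.grand for w in windows], dtype=float)
    sd = counts.std()
    mean = counts.mean()
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    if sd == 0:
        logger.warning("zero variance across windows; no hotspots callable")
        return [HotspotCall(window=w, score=0.0, passed=False) for w in ordered]
    return [
        HotspotCall(window=w, score=(w.grand - mean) / sd, passed=(w.grand - mean) / sd >= k)
        for w in ordered
    ]


def call_hotspots_quantile(windows: list[WindowCount], q: float = 0.99) -> list[HotspotCall]:
    """Alternative rule: windows at or above the q-quantile of grand counts."""
    counts = np.array([w.grand for w in windows], dtype=float)
    cut = float(np.quantile(counts, q))
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    return [HotspotCall(window=w, score=float(w.grand), passed=w.grand >= cut) for w in ordered]


def export_tracks(
    windows: list[WindowCount],
    genes: list[AnnotationFeature],
    tes: list[AnnotationFeature],
    outdir,
    genome_index: dict[str, int],
    window_size: int = DEFAULT_WINDOW,
) -> dict[str, str]:
    """Write circos-style per-window track TSVs (chrom, start, end, value):
    eccDNA counts per phenotype plus gene and TE densities on the same grid."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ordered = sorted(windows, key=lambda w: (w.chrom, w.start))
    paths = {}

    def _write(name: str, values: list[int]) -> None:
        p = outdir / f"track_{name}.tsv"
        with open(p, "w") as fh:
            fh.write("chrom\tstart\tend\tvalue\n")
            for w, v in zip(ordered, values):
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{v}\n")
        paths[name] = str(p)

    if ordered and ordered[0].hr_total is not None:
        _write("ecc_hr", [w.hr_total for w in ordered])
        _write("ecc_hs", [w.hs_total for w in ordered])
    else:
        _write("ecc", [w.grand for w in ordered])
    for name, feats in (("genes", genes), ("tes", tes)):
        as_iv = [
            MappedInterval(ecc_id=f.id, sample=name, chrom=f.chrom, start=f.start, end=f.end)
            for f in feats
        ]
        fw, _ = count_windows(as_iv, genome_index, window_size)
        fw_sorted = sorted(fw, key=lambda w: (w.chrom, w.start))
        _write(name, [w.grand for w in fw_sorted])
    return paths
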