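"""Flank-density profiles and the label-permutation enrichment test.

For each unit (an annotated gene, or a fixed genome window) the number of
genes and transposable elements falling in its +/-200 kb flanks is counted,
and the unit is labelled eccDNA-present when its own interval overlaps at
least one mapped eccDNA. The test statistic is the difference of mean flank
counts between present and absent units; its null distribution is built by
permuting the present/absent labels with group sizes held fixed. Small
instances are enumerated exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np
from intervaltree import IntervalTree

from .io import AnnotationFeature, MappedInterval

DEFAULT_FLANK = 200_000
EXACT_ENUMERATION_LIMIT = 20_000


@dataclass
class FlankProfile:
    unit_id: str
    flank_gene_count: int
    flank_te_count: int
    ecc_present: bool


@dataclass
class PermutationResult:
    feature: str  # gene | TE
    obs_diff: float  # mean(present) - mean(absent)
    n_perm: int
    p_value: float
    sidedness: str  # two | greater
    seed: int | None
    exact: bool = False


def _tree(features: list[AnnotationFeature]) -> IntervalTree:
    t = IntervalTree()
    for f in features:
        t.addi(f.start, f.end, f)
    return t


def build_flank_profiles(
    units: list[AnnotationFeature],
    genes: list[AnnotationFeature],
    tes: list[AnnotationFeature],
    ecc_intervals: list[MappedInterval],
    flank: int = DEFAULT_FLANK,
    genome_index: dict[str, int] | None = None,
) -> list[FlankProfile]:
    """Profile every unit: flank gene/TE counts and eccDNA presence.

    The flank is [start - flank, end + flank) minus the unit interval
    itself, clipped to the chromosome; a feature counts when it overlaps
    either flank arm by >= 1 bp. When the unit is itself an annotated gene,
    it is excluded from its own flank count (matched by feature id).
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not units:
        raise ValueError("no units to profile")
    by_chrom_genes: dict[str, IntervalTree] = {}
    by_chrom_tes: dict[str, IntervalTree] = {}
    by_chrom_ecc: dict[str, IntervalTree] = {}
    for f in genes:
        by_chrom_genes.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.id)
    for f in tes:
        by_chrom_tes.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f.id)
    for iv in ecc_intervals:
        by_chrom_ecc.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.ecc_id)

    profiles = []
    for u in units:
        chrom_len = genome_index.get(u.chrom) if genome_index else None
        left = (max(0, u.start - flank), u.start)
        right = (u.end, u.end + flank if chrom_len is None else min(u.end + flank, chrom_len))

        def _count(trees: dict[str, IntervalTree]) -> int:
            t = trees.get(u.chrom)
            if t is None:
                return 0
            hits = set()
            for a, b in (left, right):
                if a < b:
                    hits |= {iv.data for iv in t.overlap(a, b)}
            hits.discard(u.id)
            return len(hits)

        te = by_chrom_ecc.get(u.chrom)
        present = bool(te.overlap(u.start, u.end)) if te is not None else False
        profiles.append(
            FlankProfile(
                unit_id=u.id,
                flank_gene_count=_count(by_chrom_genes),
                flank_te_count=_count(by_chrom_tes),
                ecc_present=present,
            )
        )
    return profiles


def windows_as_units(genome_index: dict[str, int], window_size: int) -> list[AnnotationFeature]:
    """The window grid expressed as profiling units."""
    from .windows import make_windows

    return [
        AnnotationFeature(chrom=w.chrom, start=w.start, end=w.end, kind="window",
                          id=f"{w.chrom}:{w.start}-{w.end}")
        for w in make_windows(genome_index, window_size)
    ]


def permutation_test(
    profiles: list[FlankProfile],
    feature: str = "gene",
    n_perm: int = 10_000,
    sidedness: str = "two",
    seed: int | None = None,
    exact_limit: int = EXACT_ENUMERATION_LIMIT,
) -> PermutationResult:
    """Difference-of-means permutation test between present and absent units.

    When the number of distinct labelings C(n, n_present) is at most
    ``exact_limit``, the null is enumerated exactly and the p-value is the
    fraction of labelings at least as extreme as the observed one (the
    identity labeling is always counted, so p > 0). Otherwise ``n_perm``
    labelings are sampled and the add-one estimator
    p = (1 + #extreme) / (1 + n_perm) is used; sampling requires a seed.
    """
    if feature not in ("gene", "TE"):
        raise ValueError(f"feature must be 'gene' or 'TE', got {feature!r}")
    if sidedness not in ("two", "greater"):
        raise ValueError(f"sidedness must be 'two' or 'greater', got {sidedness!r}")
    attr = "flank_gene_count" if feature == "gene" else "flank_te_count"
    values = np.array([getattr(p, attr) for p in profiles], dtype=float)
    labels = np.array([p.ecc_present for p in profiles], dtype=bool)
    n = len(values)
    n1 = int(labels.sum())
    n0 = n - n1
    if n1 == 0:
        raise ValueError("the eccDNA-present group is empty")
    if n0 == 0:
        raise ValueError("the eccDNA-absent group is empty")
    total = values.sum()

    def diff_from_present_sum(s: float) -> float:
        return s / n1 - (total - s) / n0

    obs = diff_from_present_sum(values[labels].sum())

    def extreme(stat: float) -> bool:
        if sidedness == "greater":
            return stat >= obs
        return abs(stat) >= abs(obs)

    n_label = comb(n, n1)
    if n_label <= exact_limit:
        hits = sum(
            extreme(diff_from_present_sum(values[list(idx)].sum()))
            for idx in itertools.combinations(range(n), n1)
        )
        return PermutationResult(
            feature=feature, obs_diff=obs, n_perm=n_label,
            p_value=hits / n_label, sidedness=sidedness, seed=seed, exact=True,
        )
    if seed is None:
        raise ValueError("a seed is required when the permutation null is sampled")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        s = values[rng.choice(n, size=n1, replace=False)].sum()
        if extreme(diff_from_present_sum(s)):
            hits += 1
    return PermutationResult(
        feature=feature, obs_diff=obs, n_perm=n_perm,
        p_value=(1 + hits) / (1 + n_perm), sidedness=sidedness, seed=seed, exact=False,
    )
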