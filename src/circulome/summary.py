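"""Per-sample circulome summary tables and length distributions."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .io import EccDNARecord


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal half-up rounding (2.5 -> 3), matching printed report tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class SampleSummary:
    sample: str
    n_ecc: int
    mean_length: float
    min_length: int
    max_length: int
    n_with_gene: int
    n_with_trna: int
    pct_with_cds: float  # percent, 2 decimals, half-up
    genes_per_ecc_min: int = 0
    genes_per_ecc_max: int = 0
    genes_per_ecc_mean: float = 0.0


def pct_with_cds(n_ecc: int, n_with_gene: int) -> float:
    """Percent of circles carrying a predicted coding sequence, 2 decimals."""
    return round_half_up(100.0 * n_with_gene / n_ecc, 2)


def summarize(
    records: list[EccDNARecord],
    gene_counts: dict[str, int] | None = None,
    sample: str | None = None,
) -> SampleSummary:
    """Summarize one sample's circulome (the per-sample inventory row).

    ``gene_counts`` maps ecc id -> number of predicted genes; circles absent
    from the map carry no genes. When omitted, the records' ``has_cds`` flags
    are used and per-circle gene statistics are reported as zero.
    """
    if not records:
        raise ValueError(f"cannot summarize an empty record list (sample {sample!r})")
    samples = {r.sample for r in records}
    if len(samples) > 1:
        raise ValueError(f"records from more than one sample: {sorted(samples)}")
    sample = records[0].sample
    lengths = np.array([r.length for r in records])
    if gene_counts is not None:
        per_ecc = [gene_counts.get(r.id, 0) for r in records]
        n_with_gene = sum(1 for c in per_ecc if c > 0)
        positive = [c for c in per_ecc if c > 0]
    else:
        n_with_gene = sum(r.has_cds for r in records)
        positive = []
    n_ecc = len(records)
    return SampleSummary(
        sample=sample,
        n_ecc=n_ecc,
        mean_length=float(lengths.mean()),
        min_length=int(lengths.min()),
        max_length=int(lengths.max()),
        n_with_gene=n_with_gene,
        n_with_trna=sum(r.has_trna for r in records),
        pct_with_cds=pct_with_cds(n_ecc, n_with_gene),
        genes_per_ecc_min=min(positive) if positive else 0,
        genes_per_ecc_max=max(positive) if positive else 0,
        genes_per_ecc_mean=float(np.mean(positive)) if positive else 0.0,
    )


def aggregate(summaries: list[SampleSummary]) -> dict[str, int]:
    """Cross-sample cohort means (rounded half-up to the nearest integer)."""
    if not summaries:
        raise ValueError("no summaries to aggregate")
    mean_n_ecc = np.mean([s.n_ecc for s in summaries])
    mean_n_gene = np.mean([s.n_with_gene for s in summaries])
    return {
        "mean_n_ecc": int(round_half_up(float(mean_n_ecc))),
        "mean_n_with_gene": int(round_half_up(float(mean_n_gene))),
    }


def length_histogram(
    records: list[EccDNARecord], bin_width: int = 1000
) -> dict[int, int]:
    """Counts of circle lengths in half-open bins [k*w, (k+1)*w)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    out: dict[int, int] = {}
    for r in records:
        b = r.length // bin_width
        out[b] = out.get(b, 0) + 1
    return dict(sorted(out.items()))


def summary_table_rows(summaries: list[SampleSummary]) -> list[dict]:
    """Rows in the published inventory's column order; mean length printed
    to 0 decimals as in the source table."""
    return [
        {
            "sample": s.sample,
            "n_ecc": s.n_ecc,
            "mean_length": int(round_half_up(s.mean_length)),
            "length_range": f"{s.min_length}-{s.max_length}",
            "n_with_gene": s.n_with_gene,
            "n_with_trna": s.n_with_trna,
            "pct_with_cds": s.pct_with_cds,
        }
        for s in summaries
    ]
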