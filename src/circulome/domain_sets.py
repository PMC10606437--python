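"""Set algebra over per-sample PFAM domain catalogs.

Each sample's catalog is the set of PFAM accessions annotated on its
eccDNA-encoded genes, with per-accession eccDNA counts. The partition of
interest compares the herbicide-resistant (HR) core (accessions present in
every HR sample) with the herbicide-sensitive (HS) core: their intersection
is the all-sample core, and each group's remainder is its group-specific
core. Per-sample unique accessions and pairwise sharing are reported
alongside, plus a plain hypergeometric term-enrichment utility
(Benjamini-Hochberg corrected) standing in for length-bias-aware GO
enrichment, as a deliberate simplification.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .io import DomainRecord

logger = logging.getLogger(__name__)


@dataclass
class DomainCatalog:
    sample: str
    counts: dict[str, int] = field(default_factory=dict)  # accession -> n eccDNA

    @property
    def accessions(self) -> set[str]:
        return set(self.counts)


def catalogs_from_records(records: list[DomainRecord]) -> dict[str, DomainCatalog]:
    """Collapse domain annotation rows into per-sample catalogs; the count of
    an accession is the number of distinct eccDNAs carrying it."""
    ecc_sets: dict[str, dict[str, set[str]]] = {}
    for r in records:
        ecc_sets.setdefault(r.sample, {}).setdefault(r.pfam, set()).add(r.ecc_id)
    return {
        sample: DomainCatalog(
            sample=sample, counts={acc: len(eccs) for acc, eccs in accs.items()}
        )
        for sample, accs in ecc_sets.items()
    }


@dataclass
class SetPartition:
    core_all: set[str]
    hr_core: set[str]
    hs_core: set[str]
    hr_core_specific: set[str]
    hs_core_specific: set[str]
    per_sample_unique: dict[str, set[str]]
    pairwise_shared: dict[tuple[str, str], set[str]]


def partition(
    catalogs: dict[str, DomainCatalog],
    group_map: dict[str, str],
    pairwise_exclusive: bool = False,
    unique_in_group_only: bool = False,
) -> SetPartition:
    """Shared-core / group-specific / unique decomposition of the catalogs.

    * HR core = intersection over HR samples; HS core likewise.
    * all-sample core = HR core intersect HS core; group-specific cores are
      the set differences, so |HR core| = |core| + |HR-specific| always.
    * unique = present in exactly one sample (across both groups by
      default; ``unique_in_group_only`` restricts the comparison to the
      sample's own group).
    * pairwise_shared maps same-group sample pairs to the accessions both
      carry; with ``pairwise_exclusive`` accessions carried by any other
      sample of that group are removed.
    """
    if not catalogs:
        raise ValueError("no catalogs supplied")
    for s, cat in catalogs.items():
        if not cat.counts:
            raise ValueError(f"catalog for sample {s!r} is empty")
        if s not in group_map:
            raise ValueError(f"sample {s!r} missing from group map")
    hr = sorted(s for s in catalogs if group_map[s] == "HR")
    hs = sorted(s for s in catalogs if group_map[s] == "HS")
    if not hr or not hs:
        raise ValueError("need at least one sample in each of HR and HS")
    hr_core = set.intersection(*(catalogs[s].accessions for s in hr))
    hs_core = set.intersection(*(catalogs[s].accessions for s in hs))
    core_all = hr_core & hs_core

    unique: dict[str, set[str]] = {}
    for s in catalogs:
        others = [
            o for o in catalogs
            if o != s and (not unique_in_group_only or group_map[o] == group_map[s])
        ]
        other_union = set().union(*(catalogs[o].accessions for o in others)) if others else set()
        unique[s] = catalogs[s].accessions - other_union

    pairwise: dict[tuple[str, str], set[str]] = {}
    for group_samples in (hr, hs):
        for a, b in itertools.combinations(group_samples, 2):
            shared = catalogs[a].accessions & catalogs[b].accessions
            if pairwise_exclusive:
                rest = [s for s in group_samples if s not in (a, b)]
                if rest:
                    shared = shared - set().union(*(catalogs[s].accessions for s in rest))
            pairwise[(a, b)] = shared

    return SetPartition(
        core_all=core_all,
        hr_core=hr_core,
        hs_core=hs_core,
        hr_core_specific=hr_core - hs_core,
        hs_core_specific=hs_core - hr_core,
        per_sample_unique=unique,
        pairwise_shared=pairwise,
    )


def rank_abundance(
    catalogs: dict[str, DomainCatalog],
    subset: set[str] | None = None,
    top_n: int | None = None,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Total eccDNA count per accession over the chosen samples, descending
    (ties broken by accession string)."""
    use = samples if samples is not None else sorted(catalogs)
    totals: dict[str, int] = {}
    for s in use:
        for acc, c in catalogs[s].counts.items():
            if subset is not None and acc not in subset:
                continue
            totals[acc] = totals.get(acc, 0) + c
    rows = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(rows, columns=["pfam", "n_ecc"])


def detox_flags(
    catalogs: dict[str, DomainCatalog], watchlist: dict[str, set[str]]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Presence matrix (sample x watchlist entry) for named accession groups
    such as cytochrome P450s, ABC transporters and glutathione transferases,
    plus the 'exclusively detected in' sample list per entry (empty when the
    entry is present in every sample)."""
    samples = sorted(catalogs)
    all_accs = set().union(*(c.accessions for c in catalogs.values()))
    data = {}
    for name, accs in watchlist.items():
        if not (accs & all_accs):
            logger.warning("watchlist entry %r: no accession observed in any sample", name)
        data[name] = [bool(accs & catalogs[s].accessions) for s in samples]
    matrix = pd.DataFrame(data, index=samples)
    exclusive = {}
    for name in watchlist:
        present = [s for s in samples if matrix.loc[s, name]]
        exclusive[name] = present if 0 < len(present) < len(samples) else []
    return matrix, exclusive


def term_enrichment(
    target_set: set[str],
    background_set: set[str],
    term_map: dict[str, set[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of terms in the target set.

    Upper-tail hypergeometric p per term, Benjamini-Hochberg adjusted q,
    flagged enriched at q < fdr. Terms with no member in the background are
    dropped.
    """
    if not target_set:
        raise ValueError("empty target set")
    if not target_set <= background_set:
        raise ValueError("target set must be a subset of the background set")
    if not term_map:
        raise ValueError("empty term map")
    M = len(background_set)
    N = len(target_set)
    rows = []
    for term, members in sorted(term_map.items()):
        K = len(members & background_set)
        if K == 0:
            continue
        k = len(members & target_set)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append({"term": term, "k": k, "K": K, "N": N, "M": M, "p": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(q=[], enriched=[])
    df["q"] = multipletests(df["p"].values, method="fdr_bh")[1]
    df["enriched"] = df["q"] < fdr
    return df.sort_values(["p", "term"]).reset_index(drop=True)
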