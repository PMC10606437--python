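from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from circulome.domain_sets import (
    DomainCatalog,
    catalogs_from_records,
    detox_flags,
    partition,
    rank_abundance,
    term_enrichment,
)
from circulome.io import DomainRecord


def cat(sample, accs):
    return DomainCatalog(sample=sample, counts={a: 1 for a in accs})


GM = {"A": "HR", "B": "HR", "X": "HS", "Y": "HS"}


def test_planted_core_structure_recovered(default_sim):
    """The generator plants 69 all-sample, 11 HR-specific and 22 HS-specific
    core domains; the partition recovers them exactly."""
    catalogs = catalogs_from_records(default_sim.domains)
    part = partition(catalogs, default_sim.truth.group_map)
    assert len(part.core_all) == 69
    assert len(part.hr_core_specific) == 11
    assert len(part.hs_core_specific) == 22
    assert len(part.hr_core) == 80 and len(part.hs_core) == 91
    # per-sample unique vocabularies recovered too
    for s, voc in default_sim.truth.vocab.items():
        expected_unique = {a for a in voc if a.startswith("PF4")}
        assert part.per_sample_unique[s] == expected_unique


def test_identical_catalogs_make_everything_core():
    accs = {"PF00001", "PF00002"}
    catalogs = {s: cat(s, accs) for s in GM}
    part = partition(catalogs, GM)
    assert part.core_all == accs
    assert not part.hr_core_specific and not part.hs_core_specific
    assert all(not u for u in part.per_sample_unique.values())


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.lists(st.sets(st.integers(0, 30), min_size=1), min_size=4, max_size=4))
def test_partition_identities_on_random_catalogs(vocabs):
    catalogs = {
        s: cat(s, {f"PF{v:05d}" for v in voc})
        for s, voc in zip(sorted(GM), vocabs)
    }
    part = partition(catalogs, GM)
    assert part.hr_core_specific == part.hr_core - part.core_all
    assert part.core_all == part.hr_core & part.hs_core
    assert len(part.hr_core) == len(part.core_all) + len(part.hr_core_specific)
    assert len(part.hs_core) == len(part.core_all) + len(part.hs_core_specific)
    assert part.core_all <= part.hr_core <= set.union(*(c.accessions for c in catalogs.values()))


def test_partition_ignores_counts_and_sample_order():
    c1 = {"A": cat("A", {"PF00001"}), "B": cat("B", {"PF00001"}),
          "X": cat("X", {"PF00001"}), "Y": cat("Y", {"PF00001", "PF00002"})}
    c2 = {k: DomainCatalog(k, {a: 99 for a in v.counts}) for k, v in reversed(list(c1.items()))}
    p1, p2 = partition(c1, GM), partition(c2, GM)
    assert p1 == p2


def test_partition_validation_errors():
    with pytest.raises(ValueError):
        partition({}, GM)
    with pytest.raises(ValueError, match="empty"):
        partition({"A": DomainCatalog("A", {}), "X": cat("X", {"PF00001"})},
                  {"A": "HR", "X": "HS"})


def test_catalogs_count_distinct_circles():
    recs = [
        DomainRecord("s", "e1", "g1", "PF00001"),
        DomainRecord("s", "e1", "g2", "PF00001"),  # same circle, counted once
        DomainRecord("s", "e2", "g3", "PF00001"),
    ]
    catalogs = catalogs_from_records(recs)
    assert catalogs["s"].counts == {"PF00001": 2}


def test_rank_abundance_totals_and_order():
    catalogs = {"a": DomainCatalog("a", {"PF00001": 3, "PF00002": 7}),
                "b": DomainCatalog("b", {"PF00001": 3})}
    table = rank_abundance(catalogs)
    assert list(table.itertuples(index=False, name=None)) == [("PF00002", 7), ("PF00001", 6)]
    top = rank_abundance(catalogs, top_n=1)
    assert len(top) == 1 and top.iloc[0]["pfam"] == "PF00002"


def test_planted_dominant_domain_ranks_first(default_sim):
    catalogs = catalogs_from_records(default_sim.domains)
    table = rank_abundance(catalogs)
    assert table.iloc[0]["pfam"] == "PF04195"


def test_detox_flags_matrix_and_exclusivity():
    catalogs = {"A": cat("A", {"PF00001"}), "B": cat("B", {"PF00001"}),
                "X": cat("X", {"PF00001", "PF00002"}), "Y": cat("Y", {"PF00003"})}
    watch = {"P450": {"PF00001"}, "GST": {"PF00002"}, "ABC": {"PF99999"}}
    matrix, exclusive = detox_flags(catalogs, watch)
    assert list(matrix["P450"]) == [True, True, True, False]
    assert exclusive["P450"] == ["A", "B", "X"]
    assert exclusive["GST"] == ["X"]
    assert not matrix["ABC"].any() and exclusive["ABC"] == []
    # entry present everywhere -> empty exclusivity list
    matrix2, excl2 = detox_flags(catalogs, {"all": {"PF00001", "PF00003"}})
    assert excl2["all"] == []


def test_term_enrichment_closed_forms():
    background = {f"x{i}" for i in range(50)}
    target = {f"x{i}" for i in range(5)}
    term_map = {"hit": set(target), "everything": set(background)}
    df = term_enrichment(target, background, term_map).set_index("term")
    assert df.loc["hit", "p"] == pytest.approx(1 / comb(50, 5))
    assert df.loc["everything", "p"] == pytest.approx(1.0)


def test_benjamini_hochberg_matches_hand_rule():
    """The enriched flags equal the hand-computed BH step-up rule: reject
    the k smallest p-values where k is the largest index with
    p(k) <= k * fdr / m."""
    background = {f"x{i}" for i in range(60)}
    target = {f"x{i}" for i in range(12)}
    terms = {"t1": {f"x{i}" for i in range(8)},
             "t2": {f"x{i}" for i in range(4)} | {"x55", "x56"},
             "t3": {f"x{i}" for i in range(3)} | {"x50", "x51", "x52"},
             "t4": {"x40", "x41", "x42", "x43"}}
    fdr = 0.05
    df = term_enrichment(target, background, terms, fdr=fdr)
    ps = sorted(df["p"])
    m = len(ps)
    k_max = max((k + 1 for k, p in enumerate(ps) if p <= (k + 1) * fdr / m), default=0)
    cut = ps[k_max - 1] if k_max else -1.0
    expected = {row.term: row.p <= cut for row in df.itertuples()}
    assert {row.term: bool(row.enriched) for row in df.itertuples()} == expected
    assert df.loc[df["term"] == "t1", "enriched"].item()  # strong signal passes


def test_term_enrichment_validation():
    with pytest.raises(ValueError):
        term_enrichment(set(), {"a"}, {"t": {"a"}})
    with pytest.raises(ValueError, match="subset"):
        term_enrichment({"b"}, {"a"}, {"t": {"a"}})
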