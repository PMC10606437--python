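import numpy as np
import pytest

from circulome.io import AnnotationFeature, MappedInterval
from circulome.simulate import SimConfig, simulate
from circulome.windows import (
    WindowCount,
    call_hotspots,
    count_windows,
    export_tracks,
    make_windows,
    phenotype_totals,
)

GI = {"chr1": 2_000_000, "chr2": 1_500_000}


def iv(chrom, start, end, sample="HR1", eid=None):
    return MappedInterval(eid or f"{sample}_{start}", sample, chrom, start, end)


def test_window_grid_tiles_exactly():
    wins = make_windows(GI, 500_000)
    assert len(wins) == 4 + 3
    last_chr2 = [w for w in wins if w.chrom == "chr2"][-1]
    assert (last_chr2.start, last_chr2.end) == (1_000_000, 1_500_000)


def test_boundary_spanning_interval_counts_in_both_windows():
    wins, _ = count_windows([iv("chr1", 499_900, 500_100)], GI, 500_000)
    by_idx = {(w.chrom, w.start): w.grand for w in wins}
    assert by_idx[("chr1", 0)] == 1 and by_idx[("chr1", 500_000)] == 1
    assert sum(by_idx.values()) == 2


def test_midpoint_mode_assigns_single_window():
    wins, _ = count_windows([iv("chr1", 499_900, 500_100)], GI, 500_000, midpoint=True)
    assert sum(w.grand for w in wins) == 1


def test_no_intervals_all_zero():
    wins, stats = count_windows([], GI, 500_000)
    assert all(w.grand == 0 for w in wins)
    assert stats.n_intervals == 0


def test_window_counts_match_quadratic_oracle(rng):
    intervals = []
    for i in range(500):
        chrom = "chr1" if rng.random() < 0.6 else "chr2"
        start = int(rng.integers(0, GI[chrom] - 1))
        length = int(rng.integers(1, 40_000))
        end = min(start + length, GI[chrom])
        intervals.append(iv(chrom, start, end, sample=f"S{rng.integers(3)}"))
    W = 500_000
    wins, _ = count_windows(intervals, GI, W)
    for w in wins:
        expect = sum(
            1 for v in intervals if v.chrom == w.chrom and v.start < w.end and v.end > w.start
        )
        assert w.grand == expect


def test_conservation_bound(rng):
    intervals = [iv("chr1", s, s + 1000) for s in rng.integers(0, 1_900_000, 200)]
    wins, _ = count_windows(intervals, GI, 500_000)
    spanners = sum(1 for v in intervals if v.start // 500_000 != (v.end - 1) // 500_000)
    assert sum(w.grand for w in wins) == len(intervals) + spanners


def test_unknown_chromosome_goes_unplaced():
    wins, stats = count_windows([iv("contig9", 0, 100)], GI, 500_000)
    assert stats.n_unplaced == 1 and stats.n_anchored == 0
    assert all(w.grand == 0 for w in wins)


def test_phenotype_totals_printed_window_counts():
    w1 = WindowCount("chr5", 8_500_000, 9_000_000, hr_total=133, hs_total=104)
    w2 = WindowCount("chr5", 45_000_000, 45_500_000, hr_total=82, hs_total=55)
    assert phenotype_totals(w1) == (133, 104, 237)
    assert phenotype_totals(w2) == (82, 55, 137)
    assert phenotype_totals(WindowCount("c", 0, 1, hr_total=0, hs_total=0)) == (0, 0, 0)


def test_phenotype_totals_require_group_map():
    with pytest.raises(ValueError):
        phenotype_totals(WindowCount("c", 0, 1))
    with pytest.raises(ValueError, match="missing"):
        count_windows([iv("chr1", 0, 10, sample="mystery")], GI, 500_000,
                      group_map={"HR1": "HR"})


def test_uniform_counts_give_no_hotspots():
    wins = [WindowCount("c", i, i + 1, per_sample={"s": 5}) for i in range(10)]
    calls = call_hotspots(wins)
    assert not any(c.passed for c in calls)


def test_hotspot_threshold_semantics_k0():
    counts = [1, 1, 1, 1, 10]
    wins = [WindowCount("c", i, i + 1, per_sample={"s": c}) for i, c in enumerate(counts)]
    calls = call_hotspots(wins, k=0)
    passed = [c.window.start for c in calls if c.passed]
    assert passed == [4]  # only the window above the mean


def test_planted_hotspot_dominates_every_sample():
    cfg = SimConfig(window_size=200_000, hotspot_windows=(("chr1", 3, 50.0),),
                    gene_density_beta=0.0, qtl_plan=None, duplicate_fraction=0.0,
                    emit_sequences=False, seed=21)
    res = simulate(cfg)
    anchored = [v for v in res.alignments if v.chrom in res.genome_index]
    wins, _ = count_windows(anchored, res.genome_index, cfg.window_size)
    for sample in cfg.samples():
        per = [(w.per_sample.get(sample, 0), w.chrom, w.start) for w in wins]
        top = max(per)
        assert (top[1], top[2] // cfg.window_size) == ("chr1", 3)


def test_mapping_rate_emulates_unanchored_fraction(default_sim):
    res = default_sim
    n_total = sum(len(v) for v in res.records.values())
    _, stats = count_windows(res.alignments, res.genome_index, 500_000, n_total_ecc=n_total)
    # 8.5% of circles planted on unanchored contigs, within binomial error
    n = stats.n_intervals
    se = np.sqrt(0.085 * 0.915 / n)
    assert abs(stats.unplaced_fraction - 0.085) < 4 * se
    assert stats.mapped_fraction > 0.9


def test_export_tracks_consistent_with_feature_counts(tmp_path):
    genes = [AnnotationFeature("chr1", 100, 600, "gene", "g1"),
             AnnotationFeature("chr1", 600_000, 601_000, "gene", "g2")]
    wins, _ = count_windows([iv("chr1", 0, 1000, "HR1")], GI, 500_000,
                            group_map={"HR1": "HR"})
    paths = export_tracks(wins, genes, [], tmp_path, GI, 500_000)
    gene_track = [l.split("\t") for l in open(paths["genes"]).read().splitlines()[1:]]
    vals = {(r[0], int(r[1])): int(r[3]) for r in gene_track}
    assert vals[("chr1", 0)] == 1 and vals[("chr1", 500_000)] == 1
    te_track = open(paths["tes"]).read().splitlines()[1:]
    assert all(l.split("\t")[3] == "0" for l in te_track)
    assert set(paths) == {"ecc_hr", "ecc_hs", "genes", "tes"}
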