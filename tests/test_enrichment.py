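import numpy as np
import pytest

from circulome.enrichment import (
    FlankProfile,
    build_flank_profiles,
    permutation_test,
    windows_as_units,
)
from circulome.io import AnnotationFeature, MappedInterval

GI = {"chr1": 3_000_000}


def gene(i, start, end, chrom="chr1"):
    return AnnotationFeature(chrom, start, end, "gene", f"g{i}")


def te(i, start, end, chrom="chr1"):
    return AnnotationFeature(chrom, start, end, "TE", f"t{i}")


def ecc(start, end, chrom="chr1", sample="HR1"):
    return MappedInterval(f"e{start}", sample, chrom, start, end)


def test_flank_counts_nearby_gene_but_not_unit_itself():
    g1 = gene(1, 1_000_000, 1_001_000)
    g2 = gene(2, 1_151_000, 1_152_000)  # 150 kb away
    profs = build_flank_profiles([g1], [g1, g2], [], [], flank=200_000, genome_index=GI)
    assert profs[0].flank_gene_count == 1


def test_flank_clipped_at_chromosome_start():
    g1 = gene(1, 0, 1_000)
    g2 = gene(2, 50_000, 51_000)
    profs = build_flank_profiles([g1], [g1, g2], [], [], flank=200_000, genome_index=GI)
    assert profs[0].flank_gene_count == 1


def test_gene_spanning_both_flanks_counts_once():
    unit = gene(1, 1_000_000, 1_001_000)
    big = gene(2, 900_000, 1_100_000)  # overlaps left and right arms
    profs = build_flank_profiles([unit], [unit, big], [], [], flank=200_000, genome_index=GI)
    assert profs[0].flank_gene_count == 1


def test_presence_requires_overlap_with_unit_interval():
    unit = gene(1, 1_000_000, 1_001_000)
    profs = build_flank_profiles([unit], [unit], [], [ecc(1_000_500, 1_002_000)],
                                 flank=200_000, genome_index=GI)
    assert profs[0].ecc_present
    profs = build_flank_profiles([unit], [unit], [], [ecc(1_100_000, 1_101_000)],
                                 flank=200_000, genome_index=GI)
    assert not profs[0].ecc_present


def test_profiles_match_quadratic_oracle(rng):
    genes_ = [gene(i, s := int(rng.integers(0, 2_900_000)), s + int(rng.integers(500, 5000)))
              for i in range(50)]
    tes_ = [te(i, s := int(rng.integers(0, 2_900_000)), s + int(rng.integers(200, 3000)))
            for i in range(50)]
    eccs = [ecc(s := int(rng.integers(0, 2_900_000)), s + int(rng.integers(100, 30_000)))
            for i in range(40)]
    flank = 200_000
    profs = build_flank_profiles(genes_, genes_, tes_, eccs, flank=flank, genome_index=GI)
    for u, p in zip(genes_, profs):
        left = (max(0, u.start - flank), u.start)
        right = (u.end, min(u.end + flank, GI["chr1"]))

        def overlaps(f, a, b):
            return f.start < b and f.end > a

        exp_g = sum(
            1 for f in genes_
            if f.id != u.id and (overlaps(f, *left) or overlaps(f, *right))
        )
        exp_t = sum(1 for f in tes_ if overlaps(f, *left) or overlaps(f, *right))
        exp_p = any(v.start < u.end and v.end > u.start for v in eccs)
        assert (p.flank_gene_count, p.flank_te_count, p.ecc_present) == (exp_g, exp_t, exp_p)


def test_window_units_cover_grid():
    units = windows_as_units({"chr1": 1_200_000}, 500_000)
    assert [u.end - u.start for u in units] == [500_000, 500_000, 200_000]


def test_empty_units_rejected():
    with pytest.raises(ValueError):
        build_flank_profiles([], [], [], [])


def prof(vals_present, vals_absent):
    out = [FlankProfile(f"p{i}", v, v, True) for i, v in enumerate(vals_present)]
    out += [FlankProfile(f"a{i}", v, v, False) for i, v in enumerate(vals_absent)]
    return out


def test_identical_groups_give_p_one():
    r = permutation_test(prof([1, 1, 1], [1, 1, 1]))
    assert r.obs_diff == 0 and r.p_value == 1


def test_exact_enumeration_toy():
    r = permutation_test(prof([2, 2, 2], [0, 0, 0]), sidedness="greater")
    assert r.exact and r.n_perm == 20
    assert r.obs_diff == 2
    assert r.p_value == pytest.approx(1 / 20)


def test_sampled_p_converges_to_exact():
    profiles = prof([2, 2, 2], [0, 0, 0])
    exact = permutation_test(profiles, sidedness="greater").p_value
    sampled = permutation_test(profiles, sidedness="greater", seed=13,
                               exact_limit=0, n_perm=10_000).p_value
    se = np.sqrt(exact * (1 - exact) / 10_000)
    assert abs(sampled - exact) < 3 * se


def test_p_monotone_in_observed_difference():
    """With the permutation null held fixed, a larger observed shift can
    only make the one-sided p smaller."""
    base_absent = [0, 1, 2, 0, 1]
    ps = []
    for shift in (0, 1, 2, 4):
        profiles = prof([v + shift for v in (1, 2, 1)], base_absent)
        ps.append(permutation_test(profiles, sidedness="greater").p_value)
    assert all(a >= b for a, b in zip(ps, ps[1:]))


def test_one_empty_group_is_error():
    with pytest.raises(ValueError, match="absent"):
        permutation_test(prof([1, 2], []))
    with pytest.raises(ValueError, match="present"):
        permutation_test(prof([], [1, 2]))


def test_sampling_without_seed_is_error():
    profiles = prof(list(range(12)), list(range(12)))
    with pytest.raises(ValueError, match="seed"):
        permutation_test(profiles, exact_limit=0, seed=None)
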