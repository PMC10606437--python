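import hashlib
from pathlib import Path

import numpy as np
import pytest
from scipy.stats import chisquare

from circulome.simulate import (
    QtlPlan,
    SimConfig,
    simulate,
    solve_length_mu,
    write_dataset,
    _truncated_lognormal_mean,
)


def dir_hash(d: Path) -> dict[str, str]:
    return {
        str(p.relative_to(d)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.rglob("*")) if p.is_file()
    }


def test_same_seed_gives_byte_identical_datasets(tmp_path):
    cfg = SimConfig(genome_length=400_000, circles_per_sample=30, length_mean=600,
                    length_max=3_000, n_genes=50, n_tes=30, qtl_plan=None,
                    hotspot_windows=(), window_size=50_000, seed=5)
    write_dataset(simulate(cfg), tmp_path / "a")
    write_dataset(simulate(cfg), tmp_path / "b")
    assert dir_hash(tmp_path / "a") == dir_hash(tmp_path / "b")


def test_different_seed_changes_dataset(tmp_path):
    base = dict(genome_length=400_000, circles_per_sample=30, length_mean=600,
                length_max=3_000, n_genes=50, n_tes=30, qtl_plan=None,
                hotspot_windows=(), window_size=50_000)
    write_dataset(simulate(SimConfig(**base, seed=5)), tmp_path / "a")
    write_dataset(simulate(SimConfig(**base, seed=6)), tmp_path / "b")
    assert dir_hash(tmp_path / "a") != dir_hash(tmp_path / "b")


def test_circle_sequences_match_genome_truth(small_seq_sim):
    res = small_seq_sim
    checked = 0
    for recs in res.records.values():
        for r in recs:
            if r.id in res.truth.duplicate_of or r.id not in res.truth.origins:
                continue
            chrom, a, b = res.truth.origins[r.id]
            assert r.sequence == res.genome[chrom][a:b]
            checked += 1
    assert checked > 100


def test_truth_intervals_lie_within_genome(small_seq_sim):
    res = small_seq_sim
    sizes = {c: len(s) for c, s in res.genome.items()}
    for chrom, a, b in res.truth.origins.values():
        assert 0 <= a < b <= sizes[chrom]


def test_mean_length_within_5pct_at_study_scale(default_sim):
    lengths = [
        r.length
        for recs in default_sim.records.values()
        for r in recs
        if r.id not in default_sim.truth.duplicate_of
    ]
    assert len(lengths) >= 3_500
    assert abs(np.mean(lengths) - 6_900) / 6_900 < 0.05
    assert min(lengths) >= 31 and max(lengths) <= 29_081


def test_uniform_origins_under_null_config():
    cfg = SimConfig(gene_density_beta=0.0, hotspot_windows=(), qtl_plan=None,
                    duplicate_fraction=0.0, emit_sequences=False, seed=3)
    res = simulate(cfg)
    W = cfg.window_size
    counts = {}
    for chrom, a, _b in res.truth.origins.values():
        if chrom in res.genome_index:
            counts[(chrom, a // W)] = counts.get((chrom, a // W), 0) + 1
    n_windows = sum(size // W for size in res.genome_index.values())
    observed = [counts.get(k, 0) for k in
                [(c, i) for c in res.genome_index for i in range(res.genome_index[c] // W)]]
    assert len(observed) == n_windows
    stat, p = chisquare(observed)
    assert p > 0.01


def test_hotspot_window_has_max_count_in_every_sample():
    cfg = SimConfig(window_size=200_000, hotspot_windows=(("chr2", 5, 50.0),),
                    gene_density_beta=0.0, qtl_plan=None, duplicate_fraction=0.0,
                    emit_sequences=False, seed=9)
    res = simulate(cfg)
    W = cfg.window_size
    for sample, recs in res.records.items():
        counts = {}
        for r in recs:
            o = res.truth.origins.get(r.id)
            if o and o[0] in res.genome_index:
                counts[(o[0], o[1] // W)] = counts.get((o[0], o[1] // W), 0) + 1
        assert max(counts, key=counts.get) == ("chr2", 5)


def test_domain_vocabularies_follow_group_structure(default_sim):
    res = default_sim
    gm = res.truth.group_map
    seen = {}
    for d in res.domains:
        seen.setdefault(d.sample, set()).add(d.pfam)
    for sample, accs in seen.items():
        assert accs == res.truth.vocab[sample]
        hr_specific = {a for a in accs if a.startswith("PF2")}
        hs_specific = {a for a in accs if a.startswith("PF3")}
        if gm[sample] == "HR":
            assert len(hr_specific) == 11 and not hs_specific
        else:
            assert len(hs_specific) == 22 and not hr_specific


def test_infeasible_length_law_is_hard_error():
    with pytest.raises(ValueError, match="infeasible"):
        solve_length_mu(50_000, 1.0, 31, 29_081)
    with pytest.raises(ValueError, match="infeasible"):
        SimConfig(length_mean=10.0) and simulate(SimConfig(length_mean=10.0))


def test_length_law_solver_hits_target_mean():
    mu = solve_length_mu(6_900, 1.0, 31, 29_081)
    assert _truncated_lognormal_mean(mu, 1.0, 31, 29_081) == pytest.approx(6_900, rel=1e-6)


def test_adding_samples_does_not_perturb_existing_ones():
    base = dict(circles_per_sample=40, emit_sequences=False, qtl_plan=None, seed=13)
    a = simulate(SimConfig(n_samples_hr=2, n_samples_hs=1, **base))
    b = simulate(SimConfig(n_samples_hr=2, n_samples_hs=2, **base))
    ids_a = [(r.id, r.length) for r in a.records["HR1"]]
    ids_b = [(r.id, r.length) for r in b.records["HR1"]]
    assert ids_a == ids_b
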