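"""Clustering: identity scoring against an independent dynamic-programming
oracle, rotation awareness, greedy semantics, and prefilter safety."""

import numpy as np
import pytest

from circulome.cluster import Cluster, cluster_greedy, identity, representatives
from circulome.io import EccDNARecord
from conftest import random_dna


def gotoh_local(a: str, b: str, match=1, mismatch=-1, open_=2, extend=1):
    """Independent affine-gap local aligner (first gap position costs
    -open_, each further -extend). Returns (best score, identities of one
    best-scoring alignment)."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = np.full((n + 1, m + 1), 0.0)
    X = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG, dtype=float)  # gap in a (consume b)
    id_m = np.zeros((n + 1, m + 1), dtype=int)
    id_x = np.zeros((n + 1, m + 1), dtype=int)
    id_y = np.zeros((n + 1, m + 1), dtype=int)
    best, best_id = 0.0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            # gap states
            cands = (X[i - 1][j] - extend, M[i - 1][j] - open_)
            ids = (id_x[i - 1][j], id_m[i - 1][j])
            k = int(np.argmax(cands))
            X[i][j], id_x[i][j] = cands[k], ids[k]
            cands = (Y[i][j - 1] - extend, M[i][j - 1] - open_)
            ids = (id_y[i][j - 1], id_m[i][j - 1])
            k = int(np.argmax(cands))
            Y[i][j], id_y[i][j] = cands[k], ids[k]
            # match state (local: can restart at 0)
            cands = (M[i - 1][j - 1] + s, X[i - 1][j - 1] + s, Y[i - 1][j - 1] + s, 0.0)
            ids = (
                id_m[i - 1][j - 1] + (s > 0),
                id_x[i - 1][j - 1] + (s > 0),
                id_y[i - 1][j - 1] + (s > 0),
                0,
            )
            k = int(np.argmax(cands))
            M[i][j], id_m[i][j] = cands[k], ids[k]
            if M[i][j] > best:
                best, best_id = M[i][j], id_m[i][j]
    return best, best_id


def rec(i, seq, sample="s"):
    return EccDNARecord(id=f"e{i:03d}", sample=sample, sequence=seq)


def test_identity_matches_dp_oracle_on_mutated_pairs(rng):
    """Scores must equal the independent DP oracle exactly; identities may
    differ only by co-optimal tie-breaking (bounded slack)."""
    from circulome.cluster import _aligner

    for _ in range(5):
        a = random_dna(rng, 120)
        arr = list(a)
        for p in rng.choice(120, 12, replace=False):
            arr[p] = "ACGT"[rng.integers(0, 4)]
        b = "".join(arr)
        score, n_ident = gotoh_local(b, a)
        assert _aligner().score(b, a) == score
        assert identity(a, b, circular=False) == pytest.approx(n_ident / 120, abs=3 / 120)


def test_identical_sequences_form_one_cluster(rng):
    s = random_dna(rng, 1000)
    clusters = cluster_greedy([rec(1, s), rec(2, s)], threshold=0.9)
    assert len(clusters) == 1
    assert clusters[0].identity_to_rep == [1.0, 1.0]


def test_rotation_clusters_only_in_circular_mode(rng):
    s = random_dna(rng, 1000)
    rot = s[300:] + s[:300]
    # check the premise: the rotation destroys linear identity below 0.9
    assert identity(s, rot, circular=False) < 0.9
    assert identity(s, rot, circular=True) == pytest.approx(1.0)
    recs = [rec(1, s), rec(2, rot)]
    assert len(cluster_greedy(recs, circular=True)) == 1
    assert len(cluster_greedy(recs, circular=False)) == 2


def test_random_sequences_stay_singletons_vs_brute_force(rng):
    recs = [rec(i, random_dna(rng, 500)) for i in range(20)]
    # brute-force premise with the same scorer: all pairs below threshold
    for i in range(20):
        for j in range(i + 1, 20):
            assert identity(recs[i].sequence, recs[j].sequence) < 0.9
    assert len(cluster_greedy(recs, threshold=0.9)) == 20


def test_prefilter_equals_no_prefilter_oracle(rng):
    """Greedy clustering with the k-mer/edit-distance prefilter must agree
    exactly with the exhaustive no-prefilter run, including rotations."""
    recs = []
    for i in range(15):
        s = random_dna(rng, int(rng.integers(200, 600)))
        recs.append(rec(2 * i, s))
        if i % 3 == 0:  # rotated, lightly mutated copy
            k = int(rng.integers(0, len(s)))
            arr = list(s[k:] + s[:k])
            for p in rng.choice(len(arr), max(1, len(arr) // 50), replace=False):
                arr[p] = "ACGT"[rng.integers(0, 4)]
            recs.append(rec(2 * i + 1, "".join(arr)))
    with_f = cluster_greedy(recs, prefilter=True)
    without_f = cluster_greedy(recs, prefilter=False)
    as_sets = lambda cs: {frozenset(m.id for m in c.members) for c in cs}
    assert as_sets(with_f) == as_sets(without_f)


def test_idempotence_on_representatives(rng):
    recs = [rec(i, random_dna(rng, 300)) for i in range(10)]
    s = recs[0].sequence
    recs.append(rec(99, s[:290]))  # contained fragment joins e000
    reps = representatives(cluster_greedy(recs))
    again = cluster_greedy(reps)
    assert all(len(c.members) == 1 for c in again)
    assert len(again) == len(reps)


def test_input_order_does_not_change_representatives(rng):
    recs = [rec(i, random_dna(rng, int(rng.integers(100, 400)))) for i in range(12)]
    recs.append(rec(50, recs[0].sequence))
    reps1 = {r.sequence for r in representatives(cluster_greedy(recs))}
    shuffled = [recs[i] for i in rng.permutation(len(recs))]
    reps2 = {r.sequence for r in representatives(cluster_greedy(shuffled))}
    assert reps1 == reps2


def test_representative_is_longest_member(rng):
    s = random_dna(rng, 400)
    frag = s[50:350]
    clusters = cluster_greedy([rec(1, frag), rec(2, s)])
    assert len(clusters) == 1
    assert clusters[0].representative.id == "e002"


def test_empty_and_threshold_validation(rng):
    assert representatives([]) == []
    with pytest.raises(ValueError):
        cluster_greedy([rec(1, "ACGT" * 20)], threshold=1.5)
    with pytest.raises(ValueError):
        cluster_greedy([rec(1, "ACGT" * 20)], threshold=0.0)


def test_synthetic_duplicates_are_absorbed(small_seq_sim):
    """Planted rotated/mutated copies never found their own clusters."""
    recs = small_seq_sim.records["HR1"]
    dup_ids = {r.id for r in recs if r.id in small_seq_sim.truth.duplicate_of}
    assert dup_ids  # premise: the sample has planted duplicates
    clusters = cluster_greedy(recs, threshold=0.9, circular=True)
    rep_ids = {c.representative.id for c in clusters}
    assert not (dup_ids & rep_ids)
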