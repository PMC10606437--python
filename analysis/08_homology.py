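"""Screen eccDNA-encoded proteins against herbicide-resistance candidate
genes (GSTF1-style planting): an exact copy planted in one
herbicide-resistant sample, a truncated (61%-length) copy, and unrelated
decoys. Writes results/08_homology.tsv.
"""

import numpy as np

from _common import RESULTS, SEED

from circulome.homology import screen

AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rng = np.random.default_rng(SEED)
    gstf1 = "".join(AA[rng.integers(0, 20, 220)])
    opr1 = "".join(AA[rng.integers(0, 20, 250)])
    queries = {
        "HR1_p1": gstf1,                    # exact planted copy
        "HR2_p1": gstf1[: int(220 * 0.61)],  # truncated copy
        "HS1_p1": "".join(AA[rng.integers(0, 20, 200)]),  # decoy
        "HS2_p1": "".join(AA[rng.integers(0, 20, 180)]),  # decoy
    }
    gm = {"HR1": "HR", "HR2": "HR", "HS1": "HS", "HS2": "HS"}
    hits = screen(queries, {"GSTF1": gstf1, "OPR1": opr1}, max_e=1e-10,
                  sample_of={q: q.split("_")[0] for q in queries}, group_map=gm)
    with open(RESULTS / "08_homology.tsv", "w") as fh:
        fh.write("query_id\tsubject_id\tidentity_pct\te_value\tbit_score\taln_length\texclusivity\n")
        for h in hits:
            fh.write(f"{h.query_id}\t{h.subject_id}\t{h.pct_identity}\t"
                     f"{h.e_value:.3g}\t{h.bit_score}\t{h.aln_length}\t{h.exclusivity}\n")
            print(f"{h.query_id} vs {h.subject_id}: identity {h.pct_identity}%, "
                  f"E = {h.e_value:.3g}, bits = {h.bit_score} ({h.exclusivity})")
    assert any(h.query_id == "HR1_p1" and h.pct_identity == 100.0 for h in hits)


if __name__ == "__main__":
    main()
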