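"""Set algebra over the per-sample PFAM catalogs: the shared core across
all samples, group-specific cores, per-sample unique domains, pairwise
sharing, abundance ranking, and a detoxification-family watchlist. Writes
results/06_partition.tsv, 06_abundance.tsv and 06_detox.tsv.
"""

from _common import RESULTS, study_scale_config

from circulome.domain_sets import (
    catalogs_from_records,
    detox_flags,
    partition,
    rank_abundance,
)
from circulome.simulate import simulate

# gypsy-type transposon and (synthetic) detox-family accessions
WATCHLIST = {
    "gypsy_transposon": {"PF04195"},
    "hr_marker_1": {"PF20001"},
    "hs_marker_1": {"PF30001"},
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    res = simulate(study_scale_config())
    catalogs = catalogs_from_records(res.domains)
    part = partition(catalogs, res.truth.group_map)
    with open(RESULTS / "06_partition.tsv", "w") as fh:
        fh.write("set\tsize\n")
        for name, accs in (("core_all", part.core_all), ("hr_core", part.hr_core),
                           ("hs_core", part.hs_core),
                           ("hr_core_specific", part.hr_core_specific),
                           ("hs_core_specific", part.hs_core_specific)):
            fh.write(f"{name}\t{len(accs)}\n")
        for s in sorted(part.per_sample_unique):
            fh.write(f"unique:{s}\t{len(part.per_sample_unique[s])}\n")
        for (a, b), accs in sorted(part.pairwise_shared.items()):
            fh.write(f"pair:{a}-{b}\t{len(accs)}\n")
    print(f"domains shared by all samples: {len(part.core_all)}; "
          f"HR-specific core: {len(part.hr_core_specific)}; "
          f"HS-specific core: {len(part.hs_core_specific)} "
          f"(HR core {len(part.hr_core)} = {len(part.core_all)} + "
          f"{len(part.hr_core_specific)}; HS core {len(part.hs_core)})")

    table = rank_abundance(catalogs, top_n=20)
    table.to_csv(RESULTS / "06_abundance.tsv", sep="\t", index=False)
    print(f"most abundant domain: {table.iloc[0]['pfam']} "
          f"({table.iloc[0]['n_ecc']} circles)")

    matrix, exclusive = detox_flags(catalogs, WATCHLIST)
    matrix.to_csv(RESULTS / "06_detox.tsv", sep="\t")
    for name, samples in exclusive.items():
        if samples:
            print(f"{name}: exclusively detected in {', '.join(samples)}")


if __name__ == "__main__":
    main()
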