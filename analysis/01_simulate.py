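"""Generate the synthetic seven-sample eccDNA dataset with planted truth.

Emulates the study conditions: 4 herbicide-resistant + 3 herbicide-sensitive
samples, log-normal circle lengths (mean ~6.9 kb on [31, 29081]), ~8.5% of
circles on unanchored contigs, planted hotspot windows, a 69/11/22
shared/HR-specific/HS-specific domain vocabulary, and QTL intervals with
known CDS-content classes. Writes the pipeline input files to scratch/ and
the per-sample inventory to results/01_inventory.tsv.
"""

from _common import RESULTS, SCRATCH, sequence_config

from circulome.simulate import simulate, write_dataset


def main() -> None:
    cfg = sequence_config()
    res = simulate(cfg)
    outdir = SCRATCH / "dataset"
    write_dataset(res, outdir)
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "01_inventory.tsv", "w") as fh:
        fh.write("sample\tgroup\tn_circles\tn_duplicates\tn_unmapped\tn_with_cds\n")
        for s in cfg.samples():
            recs = res.records[s]
            ndup = sum(1 for r in recs if r.id in res.truth.duplicate_of)
            nunm = sum(1 for r in recs if r.id in res.truth.unmapped_ids)
            ncds = sum(1 for r in recs if r.has_cds)
            fh.write(f"{s}\t{res.truth.group_map[s]}\t{len(recs)}\t{ndup}\t{nunm}\t{ncds}\n")
            print(f"{s}: {len(recs)} circles ({ndup} planted duplicates, "
                  f"{nunm} unmapped, {ncds} with CDS)")
    print(f"dataset written to {outdir}")


if __name__ == "__main__":
    main()
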