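"""Full-pipeline orchestration from a single YAML configuration.

Stage order: cluster -> summarize -> windows/hotspots -> permutation
enrichment -> domain set algebra -> QTL overlap -> candidate homology.
Every stage writes TSVs into the report directory and the run closes with a
machine-readable manifest (package version, config hash, seed, output
hashes); identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import cluster_greedy, membership_table, representatives
from .domain_sets import catalogs_from_records, partition, rank_abundance
from .enrichment import build_flank_profiles, permutation_test
from .homology import screen
from .io import (
    read_alignments,
    read_domains,
    read_fasta,
    read_features,
    read_protein_fasta,
    write_fasta,
)
from .qtl import hr_exclusive_windows, overlap_qtl
from .summary import length_histogram, summarize, summary_table_rows
from .windows import call_hotspots, count_windows, export_tracks, phenotype_totals

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    samples: dict[str, dict[str, str]]  # sample -> {fasta, alignments}
    group_map: dict[str, str]
    genome_index: str  # TSV chrom<TAB>length
    genes: str
    tes: str
    qtls: str | None = None
    domains: str | None = None
    gene_counts: str | None = None
    cds: str | None = None
    ecc_proteins: str | None = None
    candidates: str | None = None
    threshold: float = 0.9
    window_size: int = 500_000
    flank: int = 200_000
    n_perm: int = 10_000
    hotspot_k: float = 3.0
    fdr: float = 0.05
    max_e: float = 1e-10
    sidedness: str = "two"
    unit_mode: str = "gene"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()

    def validate(self) -> None:
        missing = []
        for sample, paths in self.samples.items():
            for key in ("fasta", "alignments"):
                if key in paths and not Path(paths[key]).exists():
                    missing.append(f"{sample}.{key}: {paths[key]}")
            if sample not in self.group_map:
                raise ValueError(f"sample {sample!r} missing from group_map")
        for key in ("genome_index", "genes", "tes", "qtls", "domains",
                    "gene_counts", "cds", "ecc_proteins", "candidates"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                missing.append(f"{key}: {p}")
        if missing:
            raise FileNotFoundError("missing input file(s): " + "; ".join(missing))
        if self.seed is None and self.n_perm > 0:
            raise ValueError("a seed is required for the sampled permutation test")


def _read_genome_index(path: str | Path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            chrom, size = line.split("\t")
            out[chrom] = int(size)
    return out


def _read_gene_counts(path: str | Path) -> tuple[dict[str, int], dict[str, bool]]:
    counts, trna = {}, {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            sample, eid, n, has_trna = line.rstrip("\n").split("\t")
            counts[eid] = int(n)
            trna[eid] = bool(int(has_trna))
    return counts, trna


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the report directory."""
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        genome_index = _read_genome_index(config.genome_index)
        genes = read_features(config.genes, kind="gene")
        tes = read_features(config.tes, kind="TE")
        gene_counts, trna_flags = (
            _read_gene_counts(config.gene_counts) if config.gene_counts else ({}, {})
        )

        # --- cluster -------------------------------------------------------
        stage = "cluster"
        reps_by_sample = {}
        with open(out / "clusters.tsv", "w") as fh:
            fh.write("sample\tcluster_id\tmember_id\tidentity\n")
            for sample in sorted(config.samples):
                recs = read_fasta(config.samples[sample]["fasta"], sample=sample)
                clusters = cluster_greedy(recs, threshold=config.threshold, circular=True)
                for cid, mid, ident in membership_table(clusters):
                    fh.write(f"{sample}\t{cid}\t{mid}\t{ident}\n")
                reps = representatives(clusters)
                for r in reps:
                    r.has_cds = gene_counts.get(r.id, 0) > 0
                    r.has_trna = trna_flags.get(r.id, False)
                reps_by_sample[sample] = reps
                write_fasta(reps, out / f"{sample}.nr.fasta")

        # --- summarize -----------------------------------------------------
        stage = "summary"
        summaries = [
            summarize(reps_by_sample[s], gene_counts if config.gene_counts else None, sample=s)
            for s in sorted(reps_by_sample)
        ]
        rows = summary_table_rows(summaries)
        with open(out / "summary.tsv", "w") as fh:
            fh.write("sample\tn_ecc\tmean_length\tlength_range\tn_with_gene\tn_with_trna\tpct_with_cds\n")
            for r in rows:
                fh.write("\t".join(str(r[k]) for k in (
                    "sample", "n_ecc", "mean_length", "length_range",
                    "n_with_gene", "n_with_trna", "pct_with_cds")) + "\n")
        with open(out / "length_histograms.tsv", "w") as fh:
            fh.write("sample\tbin_start\tcount\n")
            for s in sorted(reps_by_sample):
                for b, c in length_histogram(reps_by_sample[s]).items():
                    fh.write(f"{s}\t{b * 1000}\t{c}\n")

        # --- windows -------------------------------------------------------
        stage = "windows"
        rep_ids = {r.id for reps in reps_by_sample.values() for r in reps}
        intervals = []
        n_total = sum(len(v) for v in reps_by_sample.values())
        for sample in sorted(config.samples):
            ivs = read_alignments(config.samples[sample]["alignments"], sample=sample)
            intervals.extend(iv for iv in ivs if iv.ecc_id in rep_ids)
        windows, stats = count_windows(
            intervals, genome_index, config.window_size,
            group_map=config.group_map, n_total_ecc=n_total,
        )
        with open(out / "windows.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\thr_total\ths_total\tgrand\n")
            for w in sorted(windows, key=lambda w: (w.chrom, w.start)):
                hr, hs, g = phenotype_totals(w)
                fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{hr}\t{hs}\t{g}\n")
        calls = call_hotspots(windows, k=config.hotspot_k)
        with open(out / "hotspots.tsv", "w") as fh:
            fh.write("chrom\tstart\tend\tgrand\tscore\tpassed\n")
            for c in calls:
                fh.write(
                    f"{c.window.chrom}\t{c.window.start}\t{c.window.end}\t"
                    f"{c.window.grand}\t{c.score:.4f}\t{int(c.passed)}\n"
                )
        export_tracks(windows, genes, tes, out / "tracks", genome_index, config.window_size)
        with open(out / "mapping_stats.tsv", "w") as fh:
            fh.write("n_intervals\tn_anchored\tn_unplaced\tunplaced_fraction\tmapped_fraction\n")
            mf = stats.mapped_fraction
            fh.write(
                f"{stats.n_intervals}\t{stats.n_anchored}\t{stats.n_unplaced}\t"
                f"{stats.unplaced_fraction:.4f}\t{'' if mf is None else f'{mf:.4f}'}\n"
            )

        # --- permutation enrichment ---------------------------------------
        stage = "permtest"
        with open(out / "permutation.tsv", "w") as fh:
            fh.write("group\tfeature\tobs_diff\tn_perm\tp_value\tsidedness\tseed\texact\n")
            for gi, group in enumerate(("HR", "HS")):
                ecc = [iv for iv in intervals
                       if config.group_map[iv.sample] == group and iv.chrom in genome_index]
                profiles = build_flank_profiles(
                    units=genes, genes=genes, tes=tes, ecc_intervals=ecc,
                    flank=config.flank, genome_index=genome_index,
                )
                for fi, feature in enumerate(("gene", "TE")):
                    r = permutation_test(
                        profiles, feature=feature, n_perm=config.n_perm,
                        sidedness=config.sidedness, seed=config.seed + 10 * gi + fi,
                    )
                    fh.write(
                        f"{group}\t{feature}\t{r.obs_diff:.6f}\t{r.n_perm}\t"
                        f"{r.p_value:.6g}\t{r.sidedness}\t{r.seed}\t{int(r.exact)}\n"
                    )

        # --- domain set algebra -------------------------------------------
        stage = "domains"
        if config.domains:
            catalogs = catalogs_from_records(read_domains(config.domains))
            part = partition(catalogs, config.group_map)
            with open(out / "domain_partition.tsv", "w") as fh:
                fh.write("set\tsize\taccessions\n")
                for name, accs in (
                    ("core_all", part.core_all), ("hr_core", part.hr_core),
                    ("hs_core", part.hs_core), ("hr_core_specific", part.hr_core_specific),
                    ("hs_core_specific", part.hs_core_specific),
                ):
                    fh.write(f"{name}\t{len(accs)}\t{','.join(sorted(accs))}\n")
                for s in sorted(part.per_sample_unique):
                    accs = part.per_sample_unique[s]
                    fh.write(f"unique:{s}\t{len(accs)}\t{','.join(sorted(accs))}\n")
                for (a, b), accs in sorted(part.pairwise_shared.items()):
                    fh.write(f"pair:{a}-{b}\t{len(accs)}\t{','.join(sorted(accs))}\n")
            rank_abundance(catalogs).to_csv(out / "domain_abundance.tsv", sep="\t", index=False)
            with open(out / "venn_membership.tsv", "w") as fh:
                fh.write("pfam\t" + "\t".join(sorted(catalogs)) + "\n")
                all_accs = sorted(set().union(*(c.accessions for c in catalogs.values())))
                for acc in all_accs:
                    row = [str(int(acc in catalogs[s].accessions)) for s in sorted(catalogs)]
                    fh.write(acc + "\t" + "\t".join(row) + "\n")

        # --- QTL overlap ---------------------------------------------------
        stage = "qtl"
        if config.qtls:
            qtls = read_features(config.qtls, kind="QTL")
            cds = read_alignments(config.cds, format="bed") if config.cds else []
            # the BED name column carries the ecc id; sample is its prefix
            cds = [
                type(iv)(ecc_id=iv.ecc_id, sample=iv.ecc_id.split("_")[0],
                         chrom=iv.chrom, start=iv.start, end=iv.end, strand=iv.strand)
                for iv in cds
            ]
            reports, qsummary = overlap_qtl(intervals, cds, qtls, config.group_map)
            with open(out / "qtl_report.tsv", "w") as fh:
                fh.write("qtl_id\tn_hr_ecc\tn_hs_ecc\tcds_class\n")
                for r in reports:
                    fh.write(f"{r.qtl_id}\t{r.n_hr_ecc}\t{r.n_hs_ecc}\t{r.cds_class}\n")
                fh.write(
                    f"#summary\tn_qtl={qsummary.n_qtl}\tn_with_cds={qsummary.n_with_cds}\t"
                    f"n_hs_only={qsummary.n_hs_only}\tn_hr_only={qsummary.n_hr_only}\t"
                    f"hr_ecc={qsummary.n_hr_ecc_total}\ths_ecc={qsummary.n_hs_ecc_total}\n"
                )
            hrx = hr_exclusive_windows(windows, qtls, config.group_map)
            with open(out / "qtl_hr_exclusive_windows.tsv", "w") as fh:
                fh.write("chrom\tstart\tend\n")
                for w in hrx:
                    fh.write(f"{w.chrom}\t{w.start}\t{w.end}\n")

        # --- candidate homology --------------------------------------------
        stage = "homology"
        if config.ecc_proteins and config.candidates:
            queries = read_protein_fasta(config.ecc_proteins)
            cands = read_protein_fasta(config.candidates)
            sample_of = {q: q.split("_")[0] for q in queries}
            hits = screen(
                queries, cands, max_e=config.max_e,
                sample_of=sample_of, group_map=config.group_map,
            )
            with open(out / "homology.tsv", "w") as fh:
                fh.write("query_id\tsubject_id\tidentity_pct\te_value\tbit_score\taln_length\texclusivity\n")
                for h in hits:
                    fh.write(
                        f"{h.query_id}\t{h.subject_id}\t{h.pct_identity}\t{h.e_value:.3g}\t"
                        f"{h.bit_score}\t{h.aln_length}\t{h.exclusivity or ''}\n"
                    )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "package": "circulome",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
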