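"""Synthetic eccDNA-excision datasets with known ground truth.

The generator emulates the study conditions of a seven-sample blackgrass
circulome experiment (4 herbicide-resistant, 3 herbicide-sensitive
populations): a toy two-chromosome genome plus unanchored contigs, gene and
TE annotations, per-sample circle inventories with a truncated log-normal
length law (target mean 6,900 bp on [31, 29,081]), excision origins whose
density can be concentrated in planted hotspot windows and coupled to local
gene density, redundant (mutated, rotated) circle copies to exercise
clustering, per-sample PFAM domain vocabularies with a planted
shared-core / HR-specific / HS-specific structure (69/11/22 by default),
and QTL intervals planted so their CDS content classes are known.

Every emitted circle's sequence is copied verbatim from the genome at its
truth interval (before duplicate mutation), and a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .io import (
    AnnotationFeature,
    DomainRecord,
    EccDNARecord,
    MappedInterval,
    write_bed,
    write_domains,
    write_fasta,
    write_gff3,
    write_paf,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
ORIGIN_BIN = 1_000  # origin-sampling resolution, bp


@dataclass
class QtlPlan:
    """How many QTL intervals to plant per CDS-content class, plus how many
    full windows to reserve as HR-exclusive (eccDNA from >= 3 HR samples,
    none from HS)."""

    n_both: int = 7
    n_hs_only: int = 4
    n_hr_only: int = 1
    n_none: int = 3
    segment_length: int = 20_000
    hr_exclusive_windows: int = 2


@dataclass
class SimConfig:
    genome_length: int = 5_000_000
    n_chromosomes: int = 2
    n_unanchored: int = 3
    unanchored_length: int = 50_000
    n_samples_hr: int = 4
    n_samples_hs: int = 3
    circles_per_sample: int = 500
    length_mean: float = 6_900.0
    length_sigma: float = 1.0
    length_min: int = 31
    length_max: int = 29_081
    window_size: int = 500_000
    hotspot_windows: tuple = (("chr1", 2, 6.0), ("chr2", 4, 4.0))
    gene_density_beta: float = 0.02
    coupling_flank: int = 200_000
    n_genes: int = 400
    n_tes: int = 300
    # minimum gap enforced between annotated genes (0 = free placement);
    # with a gap larger than the circle length cap, no circle can span two
    # genes, which makes presence labels independent across gene units
    min_gene_gap: int = 0
    domain_core: int = 69
    domain_hr_only: int = 11
    domain_hs_only: int = 22
    domain_unique_per_sample: int = 12
    cds_fraction: float = 0.22
    trna_fraction: float = 0.012
    duplicate_fraction: float = 0.10
    mutation_rate: float = 0.02
    frac_unanchored: float = 0.085
    frac_unmapped: float = 0.015
    qtl_plan: QtlPlan | None = field(default_factory=QtlPlan)
    emit_sequences: bool = True
    seed: int = 0

    def hr_samples(self) -> list[str]:
        return [f"HR{i + 1}" for i in range(self.n_samples_hr)]

    def hs_samples(self) -> list[str]:
        return [f"HS{i + 1}" for i in range(self.n_samples_hs)]

    def samples(self) -> list[str]:
        return self.hr_samples() + self.hs_samples()

    def group_map(self) -> dict[str, str]:
        gm = {s: "HR" for s in self.hr_samples()}
        gm.update({s: "HS" for s in self.hs_samples()})
        return gm


@dataclass
class SimTruth:
    origins: dict[str, tuple[str, int, int]]
    hotspot_windows: list[tuple[str, int]]
    vocab: dict[str, set[str]]
    group_map: dict[str, str]
    duplicate_of: dict[str, str]
    qtl_classes: dict[str, str]
    hr_exclusive_windows: list[tuple[str, int]]
    unmapped_ids: set[str]


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]  # empty strings when emit_sequences=False
    genome_index: dict[str, int]  # anchored chromosomes only
    records: dict[str, list[EccDNARecord]]
    alignments: list[MappedInterval]
    cds_intervals: list[MappedInterval]
    genes: list[AnnotationFeature]
    tes: list[AnnotationFeature]
    qtls: list[AnnotationFeature]
    domains: list[DomainRecord]
    gene_counts: dict[str, int]
    truth: SimTruth


# ---------------------------------------------------------------------------
# truncated log-normal length law


def _truncated_lognormal_mean(mu: float, sigma: float, lo: float, hi: float) -> float:
    a = (np.log(lo) - mu) / sigma
    b = (np.log(hi) - mu) / sigma
    z = norm.cdf(b) - norm.cdf(a)
    if z < 1e-300:  # numerically fully truncated: mean pinned to a bound
        return lo if mu < np.log(lo) else hi
    num = norm.cdf(b - sigma) - norm.cdf(a - sigma)
    return float(np.exp(mu + sigma**2 / 2) * num / z)


def solve_length_mu(target_mean: float, sigma: float, lo: float, hi: float) -> float:
    """Location parameter of a log-normal truncated to [lo, hi] whose
    truncated mean equals the target; hard error when infeasible."""
    if not lo < target_mean < hi:
        raise ValueError(
            f"infeasible truncated length law: mean {target_mean} outside ({lo}, {hi})"
        )
    f = lambda mu: _truncated_lognormal_mean(mu, sigma, lo, hi) - target_mean
    return brentq(f, np.log(lo) - 10 * sigma, np.log(hi) + 10 * sigma, xtol=1e-8)


def sample_lengths(rng: np.random.Generator, n: int, cfg: SimConfig, mu: float) -> np.ndarray:
    """Rejection sampling from the truncated law; integer bp."""
    out = np.empty(0, dtype=np.int64)
    while out.size < n:
        draw = rng.lognormal(mean=mu, sigma=cfg.length_sigma, size=max(2 * (n - out.size), 16))
        draw = draw[(draw >= cfg.length_min) & (draw <= cfg.length_max)]
        out = np.concatenate([out, draw.astype(np.int64)])
    return out[:n]


# ---------------------------------------------------------------------------
# helpers


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _mutate_rotate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """A redundant detection of the same circle: rotated start, point
    substitutions at the given rate (identity stays well above 0.9)."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    k = int(rng.integers(0, len(arr)))
    arr = np.concatenate([arr[k:], arr[:k]])
    n_mut = rng.binomial(len(arr), rate)
    if n_mut:
        pos = rng.choice(len(arr), size=n_mut, replace=False)
        arr[pos] = BASES[rng.integers(0, 4, size=n_mut)]
    return arr.tobytes().decode()


def _chrom_sizes(cfg: SimConfig) -> dict[str, int]:
    per = cfg.genome_length // cfg.n_chromosomes
    return {f"chr{i + 1}": per for i in range(cfg.n_chromosomes)}


# ---------------------------------------------------------------------------
# main generator


def simulate(config: SimConfig) -> SimResult:
    cfg = config
    chrom_sizes = _chrom_sizes(cfg)
    contig_sizes = {f"contig{i + 1}": cfg.unanchored_length for i in range(cfg.n_unanchored)}
    mu = solve_length_mu(cfg.length_mean, cfg.length_sigma, cfg.length_min, cfg.length_max)

    rng_genome = np.random.default_rng([cfg.seed, 0])
    rng_annot = np.random.default_rng([cfg.seed, 1])
    rng_qtl = np.random.default_rng([cfg.seed, 2])

    genome: dict[str, str] = {}
    for chrom, size in {**chrom_sizes, **contig_sizes}.items():
        genome[chrom] = _random_seq(rng_genome, size) if cfg.emit_sequences else ""

    # --- annotations -------------------------------------------------------
    genes: list[AnnotationFeature] = []
    tes: list[AnnotationFeature] = []
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    for kind, n, lo, hi, gap, store in (
        ("gene", cfg.n_genes, 500, 5_000, cfg.min_gene_gap, genes),
        ("TE", cfg.n_tes, 200, 3_000, 0, tes),
    ):
        which = rng_annot.choice(len(chroms), size=n, p=sizes / sizes.sum())
        lengths = rng_annot.integers(lo, hi, size=n)
        if gap > 0:
            # non-overlapping placement with a minimum inter-gene gap:
            # spread the free space uniformly between the packed features
            starts = np.empty(n, dtype=np.int64)
            for ci, chrom in enumerate(chroms):
                idxs = np.flatnonzero(which == ci)
                occupied = int((lengths[idxs] + gap).sum())
                free = chrom_sizes[chrom] - occupied
                if free <= 0:
                    raise ValueError(
                        f"cannot place {len(idxs)} spaced features on {chrom}"
                    )
                points = np.sort(rng_annot.integers(0, free, size=len(idxs)))
                offsets = np.concatenate(
                    [[0], np.cumsum(lengths[idxs][:-1] + gap)]
                )
                starts[idxs] = points + offsets
        else:
            starts = (rng_annot.random(n) * (sizes[which] - lengths)).astype(np.int64)
        order = np.lexsort((starts, which))
        for j, idx in enumerate(order):
            c = chroms[which[idx]]
            store.append(
                AnnotationFeature(
                    chrom=c, start=int(starts[idx]), end=int(starts[idx] + lengths[idx]),
                    kind=kind, id=f"{'g' if kind == 'gene' else 't'}{j + 1:06d}",
                )
            )

    # --- planted QTL layout and origin exclusion masks ---------------------
    margin = cfg.length_max  # a circle starting this close could reach in
    qtls: list[AnnotationFeature] = []
    qtl_classes: dict[str, str] = {}
    hrx_windows: list[tuple[str, int]] = []
    blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}  # no random circles
    hs_blocked: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    forced_specs: list[tuple[str, str, int, bool]] = []  # (sample, chrom, start_bp, with_cds)

    if cfg.qtl_plan is not None:
        plan = cfg.qtl_plan
        hr_s, hs_s = cfg.hr_samples(), cfg.hs_samples()
        hotspot_spans = [
            (c, wi * cfg.window_size, (wi + 1) * cfg.window_size)
            for c, wi, _ in cfg.hotspot_windows
        ]

        def _free(chrom: str, a: int, b: int) -> bool:
            for (x, y) in blocked[chrom]:
                if a < y + margin and x < b + margin:
                    return False
            for (c, x, y) in hotspot_spans:
                if c == chrom and a < y and x < b:
                    return False
            return True

        def _place_segment(length: int) -> tuple[str, int]:
            for _ in range(10_000):
                chrom = chroms[int(rng_qtl.integers(0, len(chroms)))]
                hi = chrom_sizes[chrom] - length - margin
                start = int(rng_qtl.integers(margin, hi))
                if _free(chrom, start, start + length):
                    return chrom, start
            raise RuntimeError("could not place QTL segments; genome too small for the plan")

        qi = 0
        # HR-exclusive full windows first (they need the largest free spans),
        # reserved from all random sampling
        for _ in range(plan.hr_exclusive_windows):
            for _try in range(10_000):
                chrom = chroms[int(rng_qtl.integers(0, len(chroms)))]
                n_win = chrom_sizes[chrom] // cfg.window_size
                wi = int(rng_qtl.integers(1, max(n_win - 1, 2)))
                a, b = wi * cfg.window_size, (wi + 1) * cfg.window_size
                if _free(chrom, a, b) and (chrom, wi) not in hrx_windows:
                    break
            else:
                raise RuntimeError("could not place HR-exclusive windows")
            hrx_windows.append((chrom, wi))
            blocked[chrom].append((a, b))
            qi += 1
            qid = f"qtl-{qi:02d}"
            qtls.append(AnnotationFeature(chrom=chrom, start=a, end=b, kind="QTL", id=qid))
            qtl_classes[qid] = "none"
            for s in cfg.hr_samples()[:3]:
                forced_specs.append((s, chrom, a + int(rng_qtl.integers(0, cfg.window_size // 2)), False))

        spec = (
            [("both", plan.n_both), ("HS-only", plan.n_hs_only),
             ("HR-only", plan.n_hr_only), ("none", plan.n_none)]
        )
        hr_cycle = hs_cycle = 0
        for cls, count in spec:
            for _ in range(count):
                chrom, start = _place_segment(plan.segment_length)
                end = start + plan.segment_length
                qi += 1
                qid = f"qtl-{qi:02d}"
                qtls.append(AnnotationFeature(chrom=chrom, start=start, end=end, kind="QTL", id=qid))
                qtl_classes[qid] = cls
                blocked[chrom].append((start, end))
                jitter = plan.segment_length // 4
                if cls in ("both", "HR-only"):
                    s = hr_s[hr_cycle % len(hr_s)]; hr_cycle += 1
                    forced_specs.append((s, chrom, start + int(rng_qtl.integers(0, jitter)), True))
                if cls in ("both", "HS-only"):
                    s = hs_s[hs_cycle % len(hs_s)]; hs_cycle += 1
                    forced_specs.append((s, chrom, start + int(rng_qtl.integers(0, jitter)), True))

    # --- origin-sampling weights per phenotype -----------------------------
    gene_starts = {c: np.sort([g.start for g in genes if g.chrom == c]) for c in chroms}
    weights: dict[str, dict[str, np.ndarray]] = {"HR": {}, "HS": {}}
    for chrom in chroms:
        n_bins = chrom_sizes[chrom] // ORIGIN_BIN
        centers = (np.arange(n_bins) + 0.5) * ORIGIN_BIN
        gs = gene_starts[chrom]
        gcount = np.searchsorted(gs, centers + cfg.coupling_flank) - np.searchsorted(
            gs, centers - cfg.coupling_flank
        )
        w = np.exp(cfg.gene_density_beta * gcount.astype(float))
        for c, wi, mult in cfg.hotspot_windows:
            if c == chrom:
                a = wi * cfg.window_size // ORIGIN_BIN
                b = min((wi + 1) * cfg.window_size // ORIGIN_BIN, n_bins)
                w[a:b] *= mult
        for group in ("HR", "HS"):
            wg = w.copy()
            spans = blocked[chrom] + (hs_blocked[chrom] if group == "HS" else [])
            for (x, y) in spans:
                a = max((x - margin) // ORIGIN_BIN, 0)
                b = min((y + ORIGIN_BIN - 1) // ORIGIN_BIN, n_bins)
                wg[a:b] = 0.0
            weights[group][chrom] = wg

    # --- per-sample circle inventories -------------------------------------
    group_map = cfg.group_map()
    records: dict[str, list[EccDNARecord]] = {}
    alignments: list[MappedInterval] = []
    cds_intervals: list[MappedInterval] = []
    gene_counts: dict[str, int] = {}
    origins: dict[str, tuple[str, int, int]] = {}
    duplicate_of: dict[str, str] = {}
    unmapped_ids: set[str] = set()

    contigs = list(contig_sizes)
    for si, sample in enumerate(cfg.samples()):
        rng = np.random.default_rng([cfg.seed, 100 + si])
        group = group_map[sample]
        chrom_w = np.array([weights[group][c].sum() for c in chroms])
        recs: list[EccDNARecord] = []

        forced_here = [f for f in forced_specs if f[0] == sample]
        n_random = cfg.circles_per_sample
        lengths = sample_lengths(rng, n_random + len(forced_here), cfg, mu)
        destiny = rng.choice(
            3, size=n_random,
            p=[cfg.frac_unmapped, cfg.frac_unanchored, 1 - cfg.frac_unmapped - cfg.frac_unanchored],
        )

        def _emit(i: int, chrom: str | None, start: int, length: int, mapped: bool,
                  force_cds: bool | None = None) -> EccDNARecord:
            eid = f"{sample}_ecc{i:05d}"
            if mapped:
                seq = (
                    genome[chrom][start : start + length]
                    if cfg.emit_sequences
                    else "N"  # placeholder; sequence-free mode
                )
                origins[eid] = (chrom, start, start + length)
            else:
                seq = _random_seq(rng, length) if cfg.emit_sequences else "N"
                unmapped_ids.add(eid)
            has_cds = force_cds if force_cds is not None else bool(rng.random() < cfg.cds_fraction)
            rec = EccDNARecord(
                id=eid, sample=sample, sequence=seq,
                has_cds=has_cds, has_trna=bool(rng.random() < cfg.trna_fraction),
            )
            rec.length = length  # authoritative in sequence-free mode
            if has_cds:
                gene_counts[eid] = 1 + min(int(rng.poisson(1.0)), 14)
                if mapped:
                    cds_len = int(min(length, rng.integers(300, 2_001)))
                    off = int(rng.integers(0, max(length - cds_len, 0) + 1)) if not force_cds else 0
                    cds_intervals.append(
                        MappedInterval(ecc_id=eid, sample=sample, chrom=chrom,
                                       start=start + off, end=start + off + cds_len)
                    )
            else:
                gene_counts[eid] = 0
            if mapped:
                alignments.append(
                    MappedInterval(ecc_id=eid, sample=sample, chrom=chrom,
                                   start=start, end=start + length, strand="+")
                )
            return rec

        for i in range(n_random):
            length = int(lengths[i])
            if destiny[i] == 0:  # unmapped
                recs.append(_emit(i, None, 0, length, mapped=False))
                continue
            if destiny[i] == 1:  # unanchored contig
                contig = contigs[int(rng.integers(0, len(contigs)))]
                length = min(length, contig_sizes[contig] - 1)
                start = int(rng.integers(0, contig_sizes[contig] - length))
                recs.append(_emit(i, contig, start, length, mapped=True))
                continue
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w / chrom_w.sum()))]
            w = weights[group][chrom]
            b = int(rng.choice(w.size, p=w / w.sum()))
            start = b * ORIGIN_BIN + int(rng.integers(0, ORIGIN_BIN))
            start = min(start, chrom_sizes[chrom] - length)
            start = max(start, 0)
            recs.append(_emit(i, chrom, start, length, mapped=True))

        for j, (_, chrom, start, with_cds) in enumerate(forced_here):
            length = int(lengths[n_random + j])
            start = min(start, chrom_sizes[chrom] - length)
            recs.append(_emit(n_random + j, chrom, start, length, mapped=True, force_cds=with_cds))

        # redundant detections: rotated, lightly mutated copies
        if cfg.emit_sequences and cfg.duplicate_fraction > 0:
            dup_mask = rng.random(len(recs)) < cfg.duplicate_fraction
            for rec, is_dup in zip(list(recs), dup_mask):
                if not is_dup:
                    continue
                dup = EccDNARecord(
                    id=rec.id + "d", sample=sample,
                    sequence=_mutate_rotate(rng, rec.sequence, cfg.mutation_rate),
                    has_cds=rec.has_cds, has_trna=rec.has_trna,
                )
                gene_counts[dup.id] = gene_counts[rec.id]
                duplicate_of[dup.id] = rec.id
                recs.append(dup)
        records[sample] = recs

    # --- domain catalogs ----------------------------------------------------
    core = ["PF04195"] + [f"PF{10000 + i:05d}" for i in range(1, cfg.domain_core)]
    hr_only = [f"PF{20000 + i:05d}" for i in range(cfg.domain_hr_only)]
    hs_only = [f"PF{30000 + i:05d}" for i in range(cfg.domain_hs_only)]
    vocab: dict[str, set[str]] = {}
    domains: list[DomainRecord] = []
    for si, sample in enumerate(cfg.samples()):
        rng = np.random.default_rng([cfg.seed, 500 + si])
        group = group_map[sample]
        uniq = [
            f"PF{40000 + 200 * si + j:05d}" for j in range(cfg.domain_unique_per_sample)
        ]
        voc = core + (hr_only if group == "HR" else hs_only) + uniq
        vocab[sample] = set(voc)
        cds_circles = [
            r.id for r in records[sample] if r.has_cds and r.id not in duplicate_of
        ]
        if not cds_circles:
            raise RuntimeError(f"sample {sample}: no coding circles to carry domains")
        wts = np.ones(len(voc))
        wts[0] = 30.0  # the gypsy-type transposon domain dominates abundance
        probs = wts / wts.sum()
        assigned: dict[str, set[str]] = {}
        for eid in cds_circles:
            k = 1 + min(int(rng.poisson(0.6)), 2)
            for acc_i in rng.choice(len(voc), size=k, replace=False, p=probs):
                assigned.setdefault(voc[acc_i], set()).add(eid)
        for acc in voc:  # guarantee full vocabulary coverage
            if acc not in assigned:
                assigned[acc] = {cds_circles[int(rng.integers(0, len(cds_circles)))]}
        gi = 0
        for acc in sorted(assigned):
            for eid in sorted(assigned[acc]):
                gi += 1
                domains.append(
                    DomainRecord(sample=sample, ecc_id=eid, gene_id=f"{eid}_g{gi}", pfam=acc)
                )

    truth = SimTruth(
        origins=origins,
        hotspot_windows=[(c, wi) for c, wi, _ in cfg.hotspot_windows],
        vocab=vocab,
        group_map=group_map,
        duplicate_of=duplicate_of,
        qtl_classes=qtl_classes,
        hr_exclusive_windows=hrx_windows,
        unmapped_ids=unmapped_ids,
    )
    return SimResult(
        config=cfg,
        genome=genome,
        genome_index=chrom_sizes,
        records=records,
        alignments=alignments,
        cds_intervals=cds_intervals,
        genes=genes,
        tes=tes,
        qtls=qtls,
        domains=domains,
        gene_counts=gene_counts,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# dataset writer


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, str]:
    """Write the simulated dataset in the pipeline's input formats, plus a
    truth/ directory. Deterministic: same SimResult -> identical bytes."""
    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    cfg = result.config
    paths: dict[str, str] = {}

    all_sizes = {**result.genome_index,
                 **{f"contig{i + 1}": cfg.unanchored_length for i in range(cfg.n_unanchored)}}
    with open(out / "genome_index.tsv", "w") as fh:
        for chrom, size in result.genome_index.items():
            fh.write(f"{chrom}\t{size}\n")
    paths["genome_index"] = str(out / "genome_index.tsv")

    qlens = {}
    for sample, recs in result.records.items():
        if cfg.emit_sequences:
            write_fasta(recs, out / f"{sample}.fasta")
            paths[f"fasta:{sample}"] = str(out / f"{sample}.fasta")
        for r in recs:
            qlens[r.id] = r.length
        ivs = [iv for iv in result.alignments if iv.sample == sample]
        write_paf(ivs, out / f"{sample}.paf", qlens, all_sizes)
        paths[f"paf:{sample}"] = str(out / f"{sample}.paf")

    write_gff3(result.genes, out / "genes.gff3", result.genome_index)
    write_bed(result.tes, out / "tes.bed")
    write_bed(result.qtls, out / "qtl.bed")
    write_bed(result.cds_intervals, out / "cds.bed")
    write_domains(result.domains, out / "domains.tsv")
    paths.update(
        genes=str(out / "genes.gff3"), tes=str(out / "tes.bed"),
        qtls=str(out / "qtl.bed"), cds=str(out / "cds.bed"),
        domains=str(out / "domains.tsv"),
    )

    with open(out / "gene_counts.tsv", "w") as fh:
        fh.write("sample\tecc_id\tn_genes\thas_trna\n")
        for sample in cfg.samples():
            for r in result.records[sample]:
                fh.write(f"{sample}\t{r.id}\t{result.gene_counts[r.id]}\t{int(r.has_trna)}\n")
    paths["gene_counts"] = str(out / "gene_counts.tsv")

    with open(out / "group_map.tsv", "w") as fh:
        for s in cfg.samples():
            fh.write(f"{s}\t{result.truth.group_map[s]}\n")
    paths["group_map"] = str(out / "group_map.tsv")

    t = result.truth
    with open(out / "truth" / "origins.tsv", "w") as fh:
        fh.write("ecc_id\tchrom\tstart\tend\n")
        for eid in sorted(t.origins):
            c, a, b = t.origins[eid]
            fh.write(f"{eid}\t{c}\t{a}\t{b}\n")
    with open(out / "truth" / "vocab.tsv", "w") as fh:
        fh.write("sample\tpfam\n")
        for s in sorted(t.vocab):
            for acc in sorted(t.vocab[s]):
                fh.write(f"{s}\t{acc}\n")
    with open(out / "truth" / "hotspots.tsv", "w") as fh:
        fh.write("chrom\twindow_index\n")
        for c, wi in t.hotspot_windows:
            fh.write(f"{c}\t{wi}\n")
    with open(out / "truth" / "qtl_classes.tsv", "w") as fh:
        fh.write("qtl_id\tcds_class\n")
        for q in sorted(t.qtl_classes):
            fh.write(f"{q}\t{t.qtl_classes[q]}\n")
    with open(out / "truth" / "duplicates.tsv", "w") as fh:
        fh.write("duplicate_id\toriginal_id\n")
        for d in sorted(t.duplicate_of):
            fh.write(f"{d}\t{t.duplicate_of[d]}\n")
    with open(out / "truth" / "hr_exclusive_windows.tsv", "w") as fh:
        fh.write("chrom\twindow_index\n")
        for c, wi in t.hr_exclusive_windows:
            fh.write(f"{c}\t{wi}\n")
    return paths
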