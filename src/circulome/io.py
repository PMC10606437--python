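"""Readers and writers for the external formats the pipeline touches.

All coordinates held in memory are 0-based half-open (BED convention).
GFF3 (1-based closed) and any other off-convention format is converted at
this boundary and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

PFAM_RE = __import__("re").compile(r"^PF\d{5}$")


@dataclass
class EccDNARecord:
    """One circular DNA molecule with its sample of origin.

    ``has_cds``/``has_trna`` are annotation flags (predicted protein-coding
    gene / tRNA content); they default to False until an annotation table is
    attached.
    """

    id: str
    sample: str
    sequence: str
    length: int = 0
    has_cds: bool = False
    has_trna: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"eccDNA record {self.id!r}: empty sequence")
        self.sequence = self.sequence.upper()
        self.length = len(self.sequence)


@dataclass(frozen=True)
class MappedInterval:
    """A genomic placement of an eccDNA (0-based half-open)."""

    ecc_id: str
    sample: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} for {self.ecc_id}"
            )


@dataclass(frozen=True)
class AnnotationFeature:
    """A genome annotation interval: a gene, a transposable element, or a QTL."""

    chrom: str
    start: int
    end: int
    kind: str  # gene | TE | QTL
    id: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature {self.id} {self.chrom}:{self.start}-{self.end}")


@dataclass(frozen=True)
class DomainRecord:
    """One PFAM domain annotation on a gene predicted on an eccDNA."""

    sample: str
    ecc_id: str
    gene_id: str
    pfam: str

    def __post_init__(self) -> None:
        if not PFAM_RE.match(self.pfam):
            raise ValueError(f"malformed PFAM accession {self.pfam!r} (expected PFxxxxx)")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, sample: str | None = None) -> list[EccDNARecord]:
    """Read eccDNA sequences from FASTA.

    ``sample`` defaults to the file stem. Duplicate headers are a hard error:
    ids must be unique within a sample.
    """
    path = Path(path)
    if sample is None:
        sample = path.stem.split(".")[0]
    records: list[EccDNARecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate eccDNA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(EccDNARecord(id=rec.id, sample=sample, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[EccDNARecord], path: str | Path) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(recs, str(path), "fasta")


def read_protein_fasta(path: str | Path) -> dict[str, str]:
    """Protein FASTA as an id -> sequence map (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


# ---------------------------------------------------------------------------
# Alignments (PAF / BED)


def read_alignments(
    path: str | Path,
    format: str | None = None,
    sample: str | None = None,
    primary_only: bool = True,
) -> list[MappedInterval]:
    """Read eccDNA-to-genome alignments from PAF or BED.

    PAF target start/end are already 0-based half-open and are copied as-is.
    When the minimap2 ``tp:A`` tag is present, ``primary_only`` keeps only
    primary alignments (``tp:A:P``). Lines with start >= end are skipped with
    a warning; the total skipped is logged once at the end.
    """
    path = Path(path)
    if format is None:
        format = "paf" if path.suffix.lower() == ".paf" else "bed"
    if sample is None:
        sample = path.stem.split(".")[0]
    out: list[MappedInterval] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format == "paf":
                if len(f) < 9:
                    raise ValueError(f"PAF line with <9 columns in {path}: {line[:80]!r}")
                ecc_id, strand, chrom = f[0], f[4], f[5]
                start, end = int(f[7]), int(f[8])
                if primary_only:
                    tags = {t[:4]: t for t in f[12:] if t.startswith("tp:A")}
                    if "tp:A" in tags and tags["tp:A"] != "tp:A:P":
                        continue
            else:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                ecc_id = f[3] if len(f) > 3 else f"{chrom}:{start}-{end}"
                strand = f[5] if len(f) > 5 and f[5] in "+-" else "unknown"
            if start >= end:
                skipped += 1
                logger.warning("skipping alignment with start >= end: %s", line[:80])
                continue
            out.append(
                MappedInterval(
                    ecc_id=ecc_id,
                    sample=sample,
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand if strand in "+-" else "unknown",
                )
            )
    if skipped:
        logger.warning("%s: skipped %d malformed alignment line(s)", path, skipped)
    return out


def write_paf(
    intervals: Iterable[MappedInterval],
    path: str | Path,
    query_lengths: dict[str, int],
    target_lengths: dict[str, int],
) -> None:
    """Write minimal 12-column PAF (+ tp:A:P tag) for each mapped interval."""
    with open(path, "w") as fh:
        for iv in intervals:
            qlen = query_lengths[iv.ecc_id]
            alen = iv.end - iv.start
            strand = iv.strand if iv.strand in "+-" else "+"
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        iv.ecc_id, qlen, 0, min(qlen, alen), strand,
                        iv.chrom, target_lengths[iv.chrom], iv.start, iv.end,
                        alen, alen, 60, "tp:A:P",
                    )
                )
                + "\n"
            )


def write_bed(
    features: Iterable[AnnotationFeature | MappedInterval], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for f in features:
            name = f.id if isinstance(f, AnnotationFeature) else f.ecc_id
            fh.write(f"{f.chrom}\t{f.start}\t{f.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Annotation features (GFF3 / BED)


def read_features(path: str | Path, kind: str, format: str | None = None) -> list[AnnotationFeature]:
    """Read annotation intervals of one kind from GFF3 or BED.

    GFF3 is 1-based closed and is converted to 0-based half-open here; only
    ``gene``-type lines are used when kind == "gene". BED is native.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in {".gff", ".gff3"} else "bed"
    out: list[AnnotationFeature] = []
    skipped = 0
    n_anon = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if format == "gff3":
                if len(f) < 9:
                    continue
                if kind == "gene" and f[2] != "gene":
                    continue
                chrom = f[0]
                start, end = int(f[3]) - 1, int(f[4])  # 1-based closed -> half-open
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                fid = attrs.get("ID", attrs.get("Name", ""))
            else:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                fid = f[3] if len(f) > 3 else ""
            if not fid:
                n_anon += 1
                fid = f"{kind}_{n_anon:06d}"
            if start >= end:
                skipped += 1
                logger.warning("skipping feature with start >= end: %s", line[:80])
                continue
            out.append(AnnotationFeature(chrom=chrom, start=start, end=end, kind=kind, id=fid))
    if skipped:
        logger.warning("%s: skipped %d malformed feature line(s)", path, skipped)
    return out


def write_gff3(
    genes: Iterable[AnnotationFeature], path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##sequence-region {chrom} 1 {length}\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\tcirculome\tgene\t{g.start + 1}\t{g.end}\t.\t+\t.\tID={g.id}\n"
            )


# ---------------------------------------------------------------------------
# Domain annotations (TSV with header: sample, ecc_id, gene_id, pfam)

DOMAIN_COLUMNS = ("sample", "ecc_id", "gene_id", "pfam")


def read_domains(path: str | Path) -> list[DomainRecord]:
    out: list[DomainRecord] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != DOMAIN_COLUMNS:
            raise ValueError(
                f"{path}: expected header {DOMAIN_COLUMNS}, got {tuple(header)}"
            )
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample, ecc_id, gene_id, pfam = line.split("\t")
            out.append(DomainRecord(sample=sample, ecc_id=ecc_id, gene_id=gene_id, pfam=pfam))
    return out


def write_domains(records: Iterable[DomainRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(DOMAIN_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.sample}\t{r.ecc_id}\t{r.gene_id}\t{r.pfam}\n")
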