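"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  Rendered outputs
restore each standard's own convention (VCF 1-based, BED 0-based).  Chromosome
names are normalized to carry a ``chr`` prefix.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Transcript",
    "GeneModel",
    "ExpressionMatrix",
    "ClinicalRecord",
    "VariantObservation",
    "normalize_chrom",
    "read_variant_records",
    "write_variant_records",
    "read_gene_models",
    "read_fasta",
    "read_gmt",
    "read_expression_matrix",
    "read_clinical_table",
    "read_sample_table",
    "read_mutation_table",
    "read_snp_positions",
    "write_bed6",
]


def normalize_chrom(name: str) -> str:
    """Add a ``chr`` prefix if absent (UCSC-style naming)."""
    name = str(name)
    return name if name.startswith("chr") else "chr" + name


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval: ``start`` 0-based inclusive, ``end`` exclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "?"  # "+", "-" or "?" (unknown)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class Transcript:
    transcript_id: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)
    cds: list[tuple[GenomicInterval, int]] = field(default_factory=list)  # (interval, frame)
    utr5: list[GenomicInterval] = field(default_factory=list)
    utr3: list[GenomicInterval] = field(default_factory=list)
    complete: bool = True

    @property
    def span(self) -> GenomicInterval:
        ex = self.exons
        return GenomicInterval(ex[0].chrom, min(e.start for e in ex),
                               max(e.end for e in ex), self.strand)

    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons (genomic order)."""
        ex = sorted(self.exons, key=lambda e: e.start)
        out = []
        for a, b in zip(ex, ex[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(a.chrom, a.end, b.start, self.strand))
        return out

    def cds_length(self) -> int:
        return sum(len(iv) for iv, _ in self.cds)


@dataclass
class GeneModel:
    gene_id: str
    gene_name: str
    gene_type: str  # protein_coding | lncRNA | other
    chrom: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        starts = [t.span.start for t in self.transcripts]
        ends = [t.span.end for t in self.transcripts]
        return GenomicInterval(self.chrom, min(starts), max(ends), self.strand)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample raw counts with sample role labels."""

    counts: pd.DataFrame  # genes x samples, non-negative integers
    roles: pd.Series  # sample -> "tumor" | "normal"

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("expression counts must be non-negative")


@dataclass
class ClinicalRecord:
    sample_id: str
    time: float  # overall survival, days
    event: int  # 1 = death
    gender: str
    age: float
    bmi: float
    grade: int  # 1..4
    stage: int  # 1..4
    hbv_hcv: bool = False
    alcohol: bool = False
    nafld: bool = False

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"survival time must be > 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


@dataclass(frozen=True)
class VariantObservation:
    """One candidate variant in one sample (0-based position)."""

    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    fs: float | None = None  # Fisher Strand; None = absent in the call
    qd: float | None = None  # Quality by Depth


OBS_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads", "fs", "qd"]


def observations_to_frame(observations) -> pd.DataFrame:
    """Tabular view of observations (fs/qd NaN when absent)."""
    rows = [
        (o.sample, o.chrom, o.pos, o.ref, o.alt, o.ref_reads, o.alt_reads,
         np.nan if o.fs is None else o.fs, np.nan if o.qd is None else o.qd)
        for o in observations
    ]
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_variant_records(path, sample: str | None = None) -> list[VariantObservation]:
    """Read a single-sample VCF into VariantObservation records.

    Positions are shifted to 0-based; multi-allelic records are split into one
    observation per alternate allele, with the matching AD entry.  FS/QD absent
    from INFO are recorded as ``None``, never as zero.
    """
    path = str(path)
    obs: list[VariantObservation] = []
    with pysam.VariantFile(path) as vf:
        vcf_samples = list(vf.header.samples)
        if sample is None:
            if len(vcf_samples) != 1:
                raise ValueError(f"{path}: expected single-sample VCF, found {vcf_samples}")
            sample = vcf_samples[0]
        for i, rec in enumerate(vf):
            try:
                chrom = normalize_chrom(rec.chrom)
                fs = rec.info.get("FS")
                qd = rec.info.get("QD")
                ad = rec.samples[sample].get("AD")
                if ad is None:
                    raise ValueError("missing AD")
                alts = rec.alts or ()
                for k, alt in enumerate(alts):
                    obs.append(VariantObservation(
                        sample=sample, chrom=chrom, pos=rec.pos - 1,
                        ref=rec.ref, alt=alt,
                        ref_reads=int(ad[0]), alt_reads=int(ad[k + 1]),
                        fs=None if fs is None else float(fs),
                        qd=None if qd is None else float(qd)))
            except Exception as exc:  # noqa: BLE001 - re-raise with location
                raise ValueError(f"{path}: malformed VCF record #{i + 1} "
                                 f"at {rec.chrom}:{rec.pos}: {exc}") from exc
    return obs


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled p-value using Fisher's exact test to detect strand bias">
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant Confidence/Quality by Depth">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_variant_records(path, observations, contigs: dict[str, int],
                          sample: str | None = None) -> None:
    """Write observations as a single-sample VCF v4.2 (1-based positions)."""
    obs = sorted(observations, key=lambda o: (o.chrom, o.pos, o.alt))
    if sample is None:
        samples = {o.sample for o in obs}
        if len(samples) != 1:
            raise ValueError("observations span multiple samples; pass sample=")
        sample = samples.pop()
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
        for o in obs:
            info = []
            if o.fs is not None:
                info.append(f"FS={o.fs:g}")
            if o.qd is not None:
                info.append(f"QD={o.qd:g}")
            dp = o.ref_reads + o.alt_reads
            fh.write(f"{o.chrom}\t{o.pos + 1}\t.\t{o.ref}\t{o.alt}\t.\t.\t"
                     f"{';'.join(info) or '.'}\tGT:AD:DP\t"
                     f"0/1:{o.ref_reads},{o.alt_reads}:{dp}\n")


def read_snp_positions(path) -> set[tuple[str, int]]:
    """Known-SNP positions from a (sites-only or genotyped) VCF, as 0-based keys."""
    out: set[tuple[str, int]] = set()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            out.add((normalize_chrom(rec.chrom), rec.pos - 1))
    return out


# ---------------------------------------------------------------------------
# GTF gene models
# ---------------------------------------------------------------------------

def _iv(feature, strand) -> GenomicInterval:
    # gffutils keeps GTF 1-based inclusive coordinates
    return GenomicInterval(normalize_chrom(feature.seqid), feature.start - 1,
                           feature.end, strand)


def read_gene_models(path, warn=None) -> list[GeneModel]:
    """Parse a GTF into GeneModel records (one per gene).

    Transcripts are assembled from exon/CDS/UTR features; intron intervals are
    derived as exon complements.  A CDS feature without a valid frame marks its
    transcript incomplete (its coding consequences will report "unknown").
    UTR features may be given as five_prime_utr/three_prime_utr or as generic
    UTR lines, which are sided relative to the CDS.
    """
    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True, disable_infer_genes=True,
                            disable_infer_transcripts=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        biotype = (g.attributes.get("gene_biotype") or g.attributes.get("gene_type")
                   or ["other"])[0]
        if biotype not in ("protein_coding", "lncRNA"):
            biotype = "other"
        gene = GeneModel(
            gene_id=g.attributes["gene_id"][0],
            gene_name=(g.attributes.get("gene_name") or g.attributes["gene_id"])[0],
            gene_type=biotype,
            chrom=normalize_chrom(g.seqid),
            strand=g.strand if g.strand in "+-" else "?",
        )
        for t in db.children(g, featuretype="transcript", order_by="start"):
            tx = Transcript(transcript_id=t.attributes["transcript_id"][0],
                            strand=gene.strand)
            generic_utrs = []
            for child in db.children(t, order_by="start"):
                if child.featuretype == "exon":
                    tx.exons.append(_iv(child, gene.strand))
                elif child.featuretype == "CDS":
                    frame = child.frame
                    if frame not in ("0", "1", "2"):
                        if warn is not None:
                            warn(f"CDS without frame in {tx.transcript_id}; "
                                 f"transcript marked incomplete")
                        tx.complete = False
                        frame = "0"
                    tx.cds.append((_iv(child, gene.strand), int(frame)))
                elif child.featuretype == "five_prime_utr":
                    tx.utr5.append(_iv(child, gene.strand))
                elif child.featuretype == "three_prime_utr":
                    tx.utr3.append(_iv(child, gene.strand))
                elif child.featuretype == "UTR":
                    generic_utrs.append(_iv(child, gene.strand))
            if generic_utrs and tx.cds:
                cds_start = min(iv.start for iv, _ in tx.cds)
                cds_end = max(iv.end for iv, _ in tx.cds)
                for u in generic_utrs:
                    before = u.end <= cds_start
                    five = before if gene.strand != "-" else not before
                    (tx.utr5 if five else tx.utr3).append(u)
            if tx.cds and tx.cds_length() % 3 != 0:
                tx.complete = False
            if tx.exons:
                gene.transcripts.append(tx)
        if gene.transcripts:
            genes.append(gene)
    return genes


# ---------------------------------------------------------------------------
# FASTA / GMT / tables
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    """Name -> uppercased sequence; U converted to T (original alphabet is
    recorded in the companion :func:`read_fasta_alphabets`)."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence name {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper().replace("U", "T")
    return seqs


def read_fasta_alphabets(path) -> dict[str, str]:
    """Name -> "RNA" if the record contained U, else "DNA"."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = "RNA" if "U" in str(rec.seq).upper() else "DNA"
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """MSigDB-style GMT: one gene set per line (name, description, members...)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene-set name {name!r} in {path}")
            sets[name] = {g for g in parts[2:] if g}
    return sets


def read_expression_matrix(path, roles: pd.Series) -> ExpressionMatrix:
    """Gene-by-sample TSV of raw counts (first column = gene id)."""
    counts = pd.read_csv(path, sep="\t", index_col=0)
    if not np.issubdtype(counts.to_numpy().dtype, np.number):
        raise ValueError(f"{path}: non-numeric entries in expression matrix")
    return ExpressionMatrix(counts=counts, roles=roles.reindex(counts.columns))


def read_clinical_table(path) -> list[ClinicalRecord]:
    df = pd.read_csv(path, sep="\t")
    recs = []
    for row in df.itertuples(index=False):
        recs.append(ClinicalRecord(
            sample_id=row.sample, time=float(row.time), event=int(row.event),
            gender=str(row.gender), age=float(row.age), bmi=float(row.bmi),
            grade=int(row.grade), stage=int(row.stage),
            hbv_hcv=bool(row.hbv_hcv), alcohol=bool(row.alcohol),
            nafld=bool(row.nafld)))
    return recs


def read_sample_table(path) -> pd.DataFrame:
    """Sample sheet: sample, role (tumor|normal), patient, pair id (or empty)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "role": str})
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    return df


def read_mutation_table(path) -> pd.DataFrame:
    """Per-sample somatic mutations, TSV with 1-based positions on disk."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    df["chrom"] = df["chrom"].map(normalize_chrom)
    df["pos"] = df["pos"].astype(int) - 1  # -> 0-based
    return df


def write_bed6(path, rows) -> None:
    """Rows of (chrom, start0, end0, name, score, strand) to BED6."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in rows:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score}\t{strand}\n")


_SITE_ID_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<pos>\d+):(?P<ref>[ACGT]+)>(?P<alt>[ACGT]+)$")


def site_id(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical site key, 0-based position."""
    return f"{chrom}:{pos}:{ref}>{alt}"


def parse_site_id(sid: str) -> tuple[str, int, str, str]:
    m = _SITE_ID_RE.match(sid)
    if m is None:
        raise ValueError(f"bad site id {sid!r}")
    return m["chrom"], int(m["pos"]), m["ref"], m["alt"]
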