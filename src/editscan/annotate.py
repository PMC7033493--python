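"""Site annotation: variant type, host gene, genomic feature, coding consequence.

A-to-I editing appears as A>G on the transcribed strand, i.e. A>G on the
reference strand for a + gene and T>C for a − gene.  When one site maps to
several features across isoforms the fixed precedence CDS > 3'UTR > 5'UTR >
intron resolves it; intergenic sites carry no strand and can never be flagged
A-to-I (there is nothing to orient them against).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from Bio.Seq import Seq

from .formats import GeneModel, Transcript

log = logging.getLogger(__name__)

__all__ = [
    "SiteAnnotation",
    "revcomp",
    "spliced_sequence",
    "transcript_coord",
    "classify_variant_type",
    "assign_feature",
    "coding_consequence",
    "annotate_sites",
    "SPLICE_WINDOW",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: intronic bases adjacent to an exon boundary treated as splice-affecting
#: (the canonical donor/acceptor dinucleotides)
SPLICE_WINDOW = 2

# precedence for isoform conflicts; lower rank wins
_FEATURE_RANK = {"CDS": 0, "3UTR": 1, "5UTR": 2, "noncoding_exon": 3, "intron": 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SiteAnnotation:
    variant_type: str  # reference-strand label, e.g. "A-to-G"
    is_a_to_i: bool
    gene_id: str | None  # None = intergenic
    gene_name: str | None
    gene_type: str | None
    feature: str  # CDS | 3UTR | 5UTR | intron | noncoding_exon | intergenic
    strand: str  # gene strand, "?" for intergenic
    coding_consequence: str  # synonymous | non-synonymous | stop_gain | stop_loss
    #                          | splicing | unknown | not_applicable
    aa_change: str | None = None  # e.g. "S367G"


def classify_variant_type(ref: str, alt: str, strand: str) -> tuple[str, bool]:
    """Reference-strand variant label plus the strand-aware A-to-I flag."""
    label = f"{ref}-to-{alt}"
    a_to_i = (ref == "A" and alt == "G" and strand == "+") or (
        ref == "T" and alt == "C" and strand == "-")
    return label, a_to_i


# ---------------------------------------------------------------------------
# Transcript coordinate machinery
# ---------------------------------------------------------------------------

def spliced_sequence(tx: Transcript, genome: dict[str, str]) -> str:
    """Spliced transcript sequence in sense (5'->3') orientation."""
    exons = sorted(tx.exons, key=lambda e: e.start)
    seq = "".join(genome[e.chrom][e.start:e.end] for e in exons)
    return revcomp(seq) if tx.strand == "-" else seq


def transcript_coord(tx: Transcript, pos: int) -> int | None:
    """Map a genomic position to its 0-based spliced-transcript coordinate."""
    exons = sorted(tx.exons, key=lambda e: e.start)
    offset = 0
    hit = None
    for e in exons:
        if e.contains(pos):
            hit = offset + (pos - e.start)
            break
        offset += len(e)
    if hit is None:
        return None
    if tx.strand == "-":
        total = sum(len(e) for e in exons)
        return total - 1 - hit
    return hit


def _transcript_feature(tx: Transcript, pos: int) -> str | None:
    """Feature of ``pos`` within one transcript, or None if outside its span."""
    for iv, _ in tx.cds:
        if iv.contains(pos):
            return "CDS"
    for iv in tx.utr3:
        if iv.contains(pos):
            return "3UTR"
    for iv in tx.utr5:
        if iv.contains(pos):
            return "5UTR"
    if any(e.contains(pos) for e in tx.exons):
        return "noncoding_exon"
    span = tx.span
    if span.contains(pos):
        return "intron"
    return None


def assign_feature(chrom: str, pos: int, genes: list[GeneModel],
                   ) -> tuple[GeneModel | None, str]:
    """Best (gene, feature) for a site under the CDS > 3'UTR > 5'UTR > intron
    precedence; ties broken by gene id.  No overlapping gene -> intergenic."""
    best: tuple[int, str, str, GeneModel] | None = None
    for gene in genes:
        if gene.chrom != chrom or not gene.span.contains(pos):
            continue
        for tx in gene.transcripts:
            feat = _transcript_feature(tx, pos)
            if feat is None:
                continue
            key = (_FEATURE_RANK[feat], gene.gene_id)
            if best is None or key < (best[0], best[1]):
                best = (_FEATURE_RANK[feat], gene.gene_id, feat, gene)
    if best is None:
        return None, "intergenic"
    return best[3], best[2]


def _in_splice_window(tx: Transcript, pos: int) -> bool:
    for intron in tx.introns():
        if intron.contains(pos) and (
                pos - intron.start < SPLICE_WINDOW or intron.end - pos <= SPLICE_WINDOW):
            return True
    return False


def _cds_sequence(tx: Transcript, genome: dict[str, str]) -> str:
    ivs = sorted((iv for iv, _ in tx.cds), key=lambda iv: iv.start)
    seq = "".join(genome[iv.chrom][iv.start:iv.end] for iv in ivs)
    return revcomp(seq) if tx.strand == "-" else seq


def _cds_index(tx: Transcript, pos: int) -> int | None:
    """0-based coding position of a genomic site inside the CDS."""
    ivs = sorted((iv for iv, _ in tx.cds), key=lambda iv: iv.start)
    offset = 0
    hit = None
    for iv in ivs:
        if iv.contains(pos):
            hit = offset + (pos - iv.start)
            break
        offset += len(iv)
    if hit is None:
        return None
    if tx.strand == "-":
        total = sum(len(iv) for iv in ivs)
        return total - 1 - hit
    return hit


def coding_consequence(chrom: str, pos: int, ref: str, alt: str,
                       tx: Transcript, genome: dict[str, str],
                       ) -> tuple[str, str | None]:
    """Consequence of a single-base edit on one transcript.

    Sites inside a CDS are translated codon-wise with the standard code;
    intronic sites within ``SPLICE_WINDOW`` bp of an exon boundary are called
    splicing.  Incomplete transcripts (missing frame, CDS length not divisible
    by 3) report "unknown" rather than a guess.
    """
    if _in_splice_window(tx, pos):
        return "splicing", None
    idx = _cds_index(tx, pos)
    if idx is None:
        return "not_applicable", None
    if not tx.complete or tx.cds_length() % 3 != 0:
        return "unknown", None
    # translation-order first CDS segment must start in frame 0
    ivs = sorted(tx.cds, key=lambda c: c[0].start, reverse=tx.strand == "-")
    if ivs[0][1] != 0:
        return "unknown", None
    cds_seq = _cds_sequence(tx, genome)
    sense_ref = ref if tx.strand != "-" else revcomp(ref)
    sense_alt = alt if tx.strand != "-" else revcomp(alt)
    if cds_seq[idx] != sense_ref:
        log.warning("reference mismatch at %s:%d (CDS has %s, expected %s)",
                    chrom, pos, cds_seq[idx], sense_ref)
        return "unknown", None
    codon_i, codon_p = divmod(idx, 3)
    ref_codon = cds_seq[codon_i * 3:codon_i * 3 + 3]
    alt_codon = ref_codon[:codon_p] + sense_alt + ref_codon[codon_p + 1:]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    aa_change = f"{ref_aa}{codon_i + 1}{alt_aa}"
    if ref_aa == alt_aa:
        return "synonymous", aa_change
    if alt_aa == "*":
        return "stop_gain", aa_change
    if ref_aa == "*":
        return "stop_loss", aa_change
    return "non-synonymous", aa_change


def _consequence_transcript(gene: GeneModel, pos: int) -> Transcript | None:
    """Transcript used for consequence calling: first complete transcript whose
    CDS (or splice window) contains the site, else the first matching one."""
    matching = [tx for tx in gene.transcripts
                if _cds_index(tx, pos) is not None or _in_splice_window(tx, pos)]
    for tx in matching:
        if tx.complete:
            return tx
    return matching[0] if matching else None


def annotate_site(chrom: str, pos: int, ref: str, alt: str,
                  genes: list[GeneModel], genome: dict[str, str] | None = None,
                  ) -> SiteAnnotation:
    gene, feature = assign_feature(chrom, pos, genes)
    strand = gene.strand if gene is not None else "?"
    variant_type, a_to_i = classify_variant_type(ref, alt, strand)
    consequence, aa = "not_applicable", None
    if gene is not None and genome is not None:
        tx = _consequence_transcript(gene, pos)
        if tx is not None:
            consequence, aa = coding_consequence(chrom, pos, ref, alt, tx, genome)
    return SiteAnnotation(
        variant_type=variant_type, is_a_to_i=a_to_i,
        gene_id=gene.gene_id if gene else None,
        gene_name=gene.gene_name if gene else None,
        gene_type=gene.gene_type if gene else None,
        feature=feature, strand=strand,
        coding_consequence=consequence, aa_change=aa)


def annotate_sites(sites, genes: list[GeneModel], genome: dict[str, str] | None = None):
    """Annotate a site table (columns chrom, pos, ref, alt; index = site id)."""
    import pandas as pd

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    rows = []
    for sid, row in sites.iterrows():
        ann = annotate_site(row["chrom"], int(row["pos"]), row["ref"], row["alt"],
                            by_chrom.get(row["chrom"], []), genome)
        rows.append((sid, ann.variant_type, ann.is_a_to_i, ann.gene_id,
                     ann.gene_name, ann.gene_type, ann.feature, ann.strand,
                     ann.coding_consequence, ann.aa_change))
    return pd.DataFrame(
        rows, columns=["site_id", "variant_type", "is_a_to_i", "gene_id",
                       "gene_name", "gene_type", "feature", "strand",
                       "consequence", "aa_change"]).set_index("site_id")
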