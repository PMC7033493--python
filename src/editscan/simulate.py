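"""Synthetic tumor/normal cohort generator with recorded ground truth.

Emits everything the pipeline reads — genome FASTA, GTF gene models, per-sample
variant VCFs, somatic-mutation table, known-SNP VCF, mature-miRNA FASTA, raw
expression counts, clinical table, gene-set GMT — plus ground-truth tables
sufficient to score recall and precision of every downstream stage.

The default configuration is a desk-scale stand-in for a 373-tumor/50-normal
cohort: 80 tumor / 30 normal (20 paired) samples, 2 chromosomes x 100 kb,
60 genes, 2,000 candidate sites with 50 gain + 50 loss + 20 dys-edited sites
planted, plus artifact and confounder sites at known positions that exercise
every filter in the cascade.  Per site and sample, coverage is negative
binomial and edited reads binomial in the true editing degree; expression is
log-normal/Poisson with a configurable monotone link to editing degree at
linked sites; survival is exponential with hazard proportional to
exp(beta x linear predictor) built from the planted risk sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import revcomp
from .formats import (GeneModel, GenomicInterval, Transcript, VariantObservation,
                      site_id, write_variant_records)

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "null_config", "simulate_filter_stress", "simulate_expression_link",
           "simulate_survival_groups"]

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    # cohort
    n_tumor: int = 80
    n_normal: int = 30
    n_paired: int = 20
    # genome / annotation
    n_chrom: int = 2
    chrom_length: int = 100_000
    n_genes: int = 60
    # candidate sites and planted classes
    n_sites: int = 2000
    n_gain: int = 50
    n_loss: int = 50
    n_dys: int = 20
    n_expression_linked: int = 20
    n_survival_linked: int = 10
    # degrees and coverage
    background_beta: tuple[float, float] = (2.0, 5.0)
    background_prevalence: tuple[float, float] = (0.15, 0.50)
    planted_degree_beta: tuple[float, float] = (8.0, 6.0)
    coverage_nb_mean: float = 50.0
    coverage_nb_k: float = 8.0
    # effect sizes
    gain_tumor_frac: float = 0.40
    gain_normal_frac: float = 0.00
    loss_normal_frac: float = 0.70
    loss_tumor_frac: float = 0.03
    dys_shift: float = 0.30
    expression_target_r: float = -0.60
    expression_noise_sigma: float = 0.30
    expression_prevalence: float = 0.60
    log_hazard_per_unit: float = 1.5
    baseline_hazard: float = math.log(2) / 1500.0  # per day
    censor_range: tuple[float, float] = (100.0, 3000.0)
    # confounders / artifacts
    n_snp_overlap: int = 50
    n_snp_extra: int = 100
    n_mutation_overlap: int = 50
    n_extra_mutations_per_sample: int = 5
    n_artifact_100pct: int = 30
    n_artifact_lowcov: int = 30
    n_artifact_quality: int = 20
    n_artifact_lowspread: int = 20
    n_dual_strand: int = 20
    n_noncanonical: int = 20
    n_indel: int = 10
    quality_violation_frac: float = 0.03
    absent_fs_qd_frac: float = 0.02
    # variant-type mixture
    a_to_i_fraction: float = 0.60
    # miRNA catalog
    n_mirna: int = 30
    n_mirna_gain: int = 3
    n_mirna_loss: int = 2
    mirna_length: int = 22

    def __post_init__(self) -> None:
        counts = [self.n_tumor, self.n_normal, self.n_paired, self.n_sites,
                  self.n_gain, self.n_loss, self.n_dys, self.n_expression_linked,
                  self.n_survival_linked]
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_tumor == 0 or self.n_normal == 0:
            raise ValueError("tumor and normal groups must both be non-empty")
        if self.n_paired > min(self.n_tumor, self.n_normal):
            raise ValueError("n_paired exceeds group size")
        planted = (self.n_gain + self.n_loss + self.n_dys + self.n_expression_linked
                   + self.n_artifact_100pct + self.n_artifact_lowcov
                   + self.n_artifact_quality + self.n_artifact_lowspread
                   + self.n_snp_overlap + self.n_mutation_overlap
                   + self.n_dual_strand + self.n_noncanonical + self.n_indel)
        if planted > self.n_sites:
            raise ValueError("planted site counts exceed n_sites")
        if self.n_survival_linked + self.n_mirna_gain + self.n_mirna_loss > self.n_gain:
            raise ValueError("survival/miRNA-planted sites must fit inside n_gain")
        a, b = self.background_beta
        if a <= 0 or b <= 0:
            raise ValueError("Beta parameters must be positive")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Zero-planted-effect configuration (confounders and artifacts kept)."""
    return replace(SimulationConfig(seed=seed), n_gain=0, n_loss=0, n_dys=0,
                   n_expression_linked=0, n_survival_linked=0,
                   n_mirna_gain=0, n_mirna_loss=0, **overrides)


@dataclass
class SyntheticCohort:
    out_dir: Path
    config: SimulationConfig
    paths: dict[str, Path]
    gene_models: list[GeneModel]
    truth_sites: pd.DataFrame
    truth_observations: pd.DataFrame
    truth_removed_mutations: pd.DataFrame
    truth_patients: pd.DataFrame
    truth_mirna: pd.DataFrame


# ---------------------------------------------------------------------------
# Gene construction (fixed 3-exon architecture)
# ---------------------------------------------------------------------------

_GENE_SPAN = 2400
_GENE_STRIDE = 3000
_GENE_OFFSET = 2000


def _build_gene(gene_idx: int, chrom: str, start: int, strand: str) -> GeneModel:
    gid = f"G{gene_idx:03d}"
    g = start
    tx = Transcript(transcript_id=f"{gid}.t1", strand=strand)
    if strand == "+":
        tx.exons = [GenomicInterval(chrom, g, g + 300, strand),
                    GenomicInterval(chrom, g + 700, g + 1000, strand),
                    GenomicInterval(chrom, g + 1400, g + 2400, strand)]
        tx.utr5 = [GenomicInterval(chrom, g, g + 150, strand)]
        cds = [GenomicInterval(chrom, g + 150, g + 300, strand),
               GenomicInterval(chrom, g + 700, g + 1000, strand),
               GenomicInterval(chrom, g + 1400, g + 1550, strand)]
        tx.utr3 = [GenomicInterval(chrom, g + 1550, g + 2400, strand)]
        order = cds
    else:
        tx.exons = [GenomicInterval(chrom, g, g + 1000, strand),
                    GenomicInterval(chrom, g + 1400, g + 1700, strand),
                    GenomicInterval(chrom, g + 2100, g + 2400, strand)]
        tx.utr3 = [GenomicInterval(chrom, g, g + 850, strand)]
        cds = [GenomicInterval(chrom, g + 850, g + 1000, strand),
               GenomicInterval(chrom, g + 1400, g + 1700, strand),
               GenomicInterval(chrom, g + 2100, g + 2250, strand)]
        tx.utr5 = [GenomicInterval(chrom, g + 2250, g + 2400, strand)]
        order = cds[::-1]  # translation order for - strand
    cum = 0
    frames = {}
    for iv in order:
        frames[(iv.start, iv.end)] = (3 - cum % 3) % 3
        cum += len(iv)
    tx.cds = [(iv, frames[(iv.start, iv.end)]) for iv in cds]
    return GeneModel(gene_id=gid, gene_name=f"GENE{gene_idx:03d}",
                     gene_type="protein_coding", chrom=chrom, strand=strand,
                     transcripts=[tx])


def _write_gtf(path: Path, genes: list[GeneModel]) -> None:
    def attrs(gene, tx=None):
        a = (f'gene_id "{gene.gene_id}"; gene_name "{gene.gene_name}"; '
             f'gene_biotype "{gene.gene_type}";')
        if tx is not None:
            a += f' transcript_id "{tx.transcript_id}";'
        return a

    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span
            fh.write(f"{gene.chrom}\tsim\tgene\t{span.start + 1}\t{span.end}\t.\t"
                     f"{gene.strand}\t.\t{attrs(gene)}\n")
            for tx in gene.transcripts:
                ts = tx.span
                fh.write(f"{gene.chrom}\tsim\ttranscript\t{ts.start + 1}\t{ts.end}"
                         f"\t.\t{gene.strand}\t.\t{attrs(gene, tx)}\n")
                feats = ([("exon", iv, ".") for iv in tx.exons]
                         + [("CDS", iv, str(fr)) for iv, fr in tx.cds]
                         + [("five_prime_utr", iv, ".") for iv in tx.utr5]
                         + [("three_prime_utr", iv, ".") for iv in tx.utr3])
                for feat, iv, frame in sorted(feats, key=lambda f: (f[1].start, f[0])):
                    fh.write(f"{gene.chrom}\tsim\t{feat}\t{iv.start + 1}\t{iv.end}"
                             f"\t.\t{gene.strand}\t{frame}\t{attrs(gene, tx)}\n")


def _write_fasta(path: Path, seqs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _coverage(rng, cfg, size, minimum=1):
    k = cfg.coverage_nb_k
    p = k / (k + cfg.coverage_nb_mean)
    return np.maximum(rng.negative_binomial(k, p, size=size), minimum)


def _variant_alleles(rng, strand: str, a_to_i_fraction: float) -> tuple[str, str]:
    """Genomic (ref, alt) with an A-to-I majority oriented by gene strand."""
    if strand in "+-" and rng.random() < a_to_i_fraction:
        return ("A", "G") if strand == "+" else ("T", "C")
    pairs = [("T", "C"), ("G", "A"), ("C", "T"), ("A", "C"), ("A", "T"),
             ("C", "A"), ("C", "G"), ("G", "C"), ("G", "T"), ("T", "A"),
             ("T", "G"), ("A", "G")]
    weights = np.array([0.24, 0.20, 0.16] + [0.05] * 8 + [0.0])
    if strand not in "+-":  # unoriented: A>G is just another type
        weights[-1] = 0.15
    weights = weights / weights.sum()
    return pairs[rng.choice(len(pairs), p=weights)]


class _SitePlanner:
    """Allocates non-colliding site positions from per-feature pools."""

    def __init__(self, rng, genes: list[GeneModel], chrom_names, chrom_length,
                 overlap_region):
        self.rng = rng
        self.used: set[tuple[str, int]] = set()
        self.excluded: set[tuple[str, int]] = set()
        self.pools: dict[str, list[tuple[str, int, int]]] = {}
        genic = {c: np.zeros(chrom_length, dtype=bool) for c in chrom_names}
        pools = {"utr3": [], "utr5": [], "cds": [], "intron": []}
        for gi, gene in enumerate(genes):
            span = gene.span
            genic[gene.chrom][max(span.start - 50, 0):span.end + 50] = True
            tx = gene.transcripts[0]
            for key, ivs in (("utr3", tx.utr3), ("utr5", tx.utr5),
                             ("cds", [iv for iv, _ in tx.cds]),
                             ("intron", tx.introns())):
                for iv in ivs:
                    pools[key].extend((gene.chrom, p, gi)
                                      for p in range(iv.start, iv.end))
        if overlap_region is not None:
            c, a, b = overlap_region
            genic[c][max(a - 50, 0):b + 50] = True
        inter = []
        for c in chrom_names:
            free = np.where(~genic[c])[0]
            free = free[(free > 500) & (free < chrom_length - 500)]
            inter.extend((c, int(p), -1) for p in free)
        pools["intergenic"] = inter
        for key, pool in pools.items():
            order = self.rng.permutation(len(pool))
            self.pools[key] = [pool[i] for i in order]

    def exclude_around(self, chrom, pos, radius=60):
        for p in range(pos - radius, pos + radius + 1):
            self.excluded.add((chrom, p))

    def draw(self, feature: str, count: int, distinct_genes: set | None = None,
             utr3_margin: int = 0, genes: list[GeneModel] | None = None):
        out = []
        pool = self.pools[feature]
        while len(out) < count:
            if not pool:
                raise ValueError(f"position pool exhausted for {feature!r}")
            chrom, pos, gi = pool.pop()
            if (chrom, pos) in self.used or (chrom, pos) in self.excluded:
                continue
            if distinct_genes is not None and gi in distinct_genes:
                continue
            if utr3_margin and gi >= 0:
                iv = genes[gi].transcripts[0].utr3[0]
                if pos < iv.start + utr3_margin or pos >= iv.end - utr3_margin:
                    continue
            self.used.add((chrom, pos))
            if distinct_genes is not None:
                distinct_genes.add(gi)
            out.append((chrom, pos, gi))
        return out

    def draw_mix(self, count: int, weights=None):
        """Background-style feature mixture."""
        feats = ["utr3", "intron", "cds", "utr5", "intergenic"]
        w = np.array(weights or [0.55, 0.25, 0.05, 0.05, 0.10])
        picks = self.rng.choice(len(feats), size=count, p=w / w.sum())
        return [self.draw(feats[i], 1)[0] for i in picks]


def simulate_cohort(config: SimulationConfig, out_dir) -> SyntheticCohort:
    """Generate the full cohort; deterministic given ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    out_dir = Path(out_dir)
    (out_dir / "vcf").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(exist_ok=True)

    # --- samples ----------------------------------------------------------
    tumors = [f"T{i + 1:03d}" for i in range(cfg.n_tumor)]
    normals = [f"N{i + 1:03d}" for i in range(cfg.n_normal)]
    samples = tumors + normals
    n_all = len(samples)
    pair_of = {}
    sample_rows = []
    for i, s in enumerate(tumors):
        pair = f"P{i + 1:02d}" if i < cfg.n_paired else ""
        sample_rows.append((s, "tumor", f"PT{i + 1:03d}", pair))
        if pair:
            pair_of[pair] = [s]
    for i, s in enumerate(normals):
        pair = f"P{i + 1:02d}" if i < cfg.n_paired else ""
        patient = f"PT{i + 1:03d}" if pair else f"PN{i + 1:03d}"
        sample_rows.append((s, "normal", patient, pair))
        if pair:
            pair_of[pair].append(s)
    samples_df = pd.DataFrame(sample_rows, columns=["sample", "role", "patient", "pair"])

    # --- genome and genes -------------------------------------------------
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chrom)]
    genome = {c: rng.choice(_BASES, size=cfg.chrom_length) for c in chrom_names}
    genes: list[GeneModel] = []
    per_chrom = math.ceil(cfg.n_genes / cfg.n_chrom)
    for gi in range(cfg.n_genes):
        chrom = chrom_names[gi // per_chrom]
        slot = gi % per_chrom
        start = _GENE_OFFSET + slot * _GENE_STRIDE
        if start + _GENE_SPAN > cfg.chrom_length - 500:
            raise ValueError("chromosome too short for requested gene count")
        genes.append(_build_gene(gi, chrom, start, "+" if gi % 2 == 0 else "-"))
    # overlapping +/- gene pair for the dual-strand filter
    overlap_region = None
    if cfg.n_dual_strand > 0:
        base = cfg.chrom_length - 7000
        ga = _build_gene(cfg.n_genes, chrom_names[0], base, "+")
        gb = _build_gene(cfg.n_genes + 1, chrom_names[0], base + 200, "-")
        genes.extend([ga, gb])
        overlap_region = (chrom_names[0], base + 200, base + _GENE_SPAN)

    planner = _SitePlanner(rng, genes[:cfg.n_genes], chrom_names,
                           cfg.chrom_length, overlap_region)

    # --- site allocation --------------------------------------------------
    sites: list[dict] = []

    def add_site(chrom, pos, gi, klass, **kw):
        gene = genes[gi] if gi >= 0 else None
        strand = gene.strand if gene else "?"
        rec = dict(chrom=chrom, pos=pos, gene_idx=gi, klass=klass, strand=strand,
                   is_gain=False, is_loss=False, is_dys=False,
                   is_expression_linked=False, is_survival_linked=False,
                   rewire_kind="", feature=kw.pop("feature", ""),
                   ref="", alt="")
        rec.update(kw)
        sites.append(rec)
        return rec

    linked_genes: set[int] = set()
    mirna_records = []  # (mirna_name, sequence RNA, site index, expected kind)

    # miRNA-rewiring plants (inside the gain class), segment written into genome
    def plant_rewire(kind: str, count: int, tag: str):
        for k in range(count):
            chrom, pos, gi = planner.draw("utr3", 1, distinct_genes=linked_genes,
                                          utr3_margin=25, genes=genes)[0]
            planner.exclude_around(chrom, pos)
            gene = genes[gi]
            # 18-nt GC-leaning target segment; the edited base sits at miRNA
            # seed position 5, so the off-target window fails the score gate
            seg = rng.choice(_BASES, size=18, p=[0.2, 0.3, 0.3, 0.2])
            tx_ref, tx_alt = ("A", "G") if kind == "gain" else ("G", "A")
            seg[13] = tx_ref
            for j in range(18):
                delta = j - 13  # transcript offset relative to the site
                if gene.strand == "+":
                    genome[chrom][pos + delta] = seg[j]
                else:
                    genome[chrom][pos - delta] = _COMP[seg[j]]
            edited_seg = seg.copy()
            edited_seg[13] = tx_alt
            target = edited_seg if kind == "gain" else seg
            mirna_seq = revcomp("".join(target)).replace("T", "U")
            if gene.strand == "+":
                ref, alt = tx_ref, tx_alt
            else:
                ref, alt = _COMP[tx_ref], _COMP[tx_alt]
            rec = add_site(chrom, pos, gi, "gain", is_gain=True, feature="3UTR",
                           ref=ref, alt=alt, rewire_kind=f"{kind}_plant")
            name = f"mir-plant-{tag}-{k + 1}"
            expected = "edited_gain" if kind == "gain" else "edited_loss"
            mirna_records.append((name, mirna_seq, len(sites) - 1, expected))

    plant_rewire("gain", cfg.n_mirna_gain, "gain")
    plant_rewire("loss", cfg.n_mirna_loss, "loss")

    # survival-linked sites: CDS gain sites at a codon start with a forced
    # AAA -> GAA (Lys -> Glu) A-to-I edit, so the functional consequence is a
    # guaranteed non-synonymous coding change
    avail_genes = [gi for gi in range(cfg.n_genes) if gi not in linked_genes]
    if cfg.n_survival_linked > len(avail_genes):
        raise ValueError("not enough genes for survival-linked sites")
    for k in range(cfg.n_survival_linked):
        gi = avail_genes[k]
        gene = genes[gi]
        tx = gene.transcripts[0]
        codon_i = 10 + 2 * k  # stays inside the first 150-bp coding segment
        if gene.strand == "+":
            first = min((iv for iv, _ in tx.cds), key=lambda iv: iv.start)
            pos = first.start + 3 * codon_i
            codon_span = range(pos, pos + 3)
            genome[gene.chrom][pos:pos + 3] = list("AAA")
            ref, alt = "A", "G"
        else:
            first = max((iv for iv, _ in tx.cds), key=lambda iv: iv.end)
            pos = first.end - 1 - 3 * codon_i
            codon_span = range(pos - 2, pos + 1)
            genome[gene.chrom][pos - 2:pos + 1] = list("TTT")
            ref, alt = "T", "C"
        for p in codon_span:
            planner.used.add((gene.chrom, p))
            planner.excluded.add((gene.chrom, p))
        linked_genes.add(gi)
        add_site(gene.chrom, pos, gi, "gain", is_gain=True,
                 is_survival_linked=True, feature="CDS", ref=ref, alt=alt)
    for chrom, pos, gi in planner.draw("utr3", cfg.n_expression_linked,
                                       distinct_genes=linked_genes,
                                       utr3_margin=5, genes=genes):
        add_site(chrom, pos, gi, "expression", is_expression_linked=True,
                 feature="3UTR")

    n_gain_rest = cfg.n_gain - cfg.n_mirna_gain - cfg.n_mirna_loss - cfg.n_survival_linked
    n_gain_cds = min(n_gain_rest // 4, len(planner.pools["cds"]))
    for chrom, pos, gi in planner.draw("utr3", n_gain_rest - n_gain_cds):
        add_site(chrom, pos, gi, "gain", is_gain=True, feature="3UTR")
    for chrom, pos, gi in planner.draw("cds", n_gain_cds):
        add_site(chrom, pos, gi, "gain", is_gain=True, feature="CDS")
    n_loss_cds = cfg.n_loss // 5
    for chrom, pos, gi in planner.draw("utr3", cfg.n_loss - n_loss_cds):
        add_site(chrom, pos, gi, "loss", is_loss=True, feature="3UTR")
    for chrom, pos, gi in planner.draw("cds", n_loss_cds):
        add_site(chrom, pos, gi, "loss", is_loss=True, feature="CDS")
    for chrom, pos, gi in planner.draw("utr3", cfg.n_dys):
        add_site(chrom, pos, gi, "dys", is_dys=True, feature="3UTR")

    for klass, n in (("artifact_100pct", cfg.n_artifact_100pct),
                     ("artifact_lowcov", cfg.n_artifact_lowcov),
                     ("artifact_quality", cfg.n_artifact_quality),
                     ("artifact_lowspread", cfg.n_artifact_lowspread),
                     ("snp_overlap", cfg.n_snp_overlap),
                     ("mutation_overlap", cfg.n_mutation_overlap)):
        for chrom, pos, gi in planner.draw_mix(n):
            add_site(chrom, pos, gi, klass)
    if overlap_region is not None:
        c, a, b = overlap_region
        ds_pos = rng.choice(np.arange(a + 10, b - 10), size=cfg.n_dual_strand,
                            replace=False)
        for pos in sorted(int(p) for p in ds_pos):
            add_site(c, pos, -1, "dual_strand", strand="?")
    for k in range(cfg.n_noncanonical):
        add_site("chrUn_test1", 1000 + 97 * k, -1, "noncanonical", strand="?")
    for chrom, pos, gi in planner.draw_mix(cfg.n_indel):
        add_site(chrom, pos, gi, "indel")
    n_background = cfg.n_sites - len(sites)
    for chrom, pos, gi in planner.draw_mix(n_background):
        add_site(chrom, pos, gi, "background")

    # alleles: set genome reference base at every canonical-chromosome site
    for rec in sites:
        if rec["klass"] == "indel":
            ref = str(genome[rec["chrom"]][rec["pos"]])
            rec["ref"], rec["alt"] = ref, ref + "G"
            continue
        if not rec["ref"]:
            rec["ref"], rec["alt"] = _variant_alleles(rng, rec["strand"],
                                                      cfg.a_to_i_fraction)
        if rec["chrom"] in genome:
            genome[rec["chrom"]][rec["pos"]] = rec["ref"]

    # --- per-site degrees and read counts --------------------------------
    tumor_idx = np.arange(cfg.n_tumor)
    normal_idx = np.arange(cfg.n_tumor, n_all)
    paired_t = tumor_idx[:cfg.n_paired]
    paired_n = normal_idx[:cfg.n_paired]
    a_bg, b_bg = cfg.background_beta
    a_pl, b_pl = cfg.planted_degree_beta

    # fraction edited for dys sites outside the pairs, matched across groups
    f_dys = min(0.95, max(0.70, cfg.n_paired / cfg.n_normal + 0.05,
                          cfg.n_paired / cfg.n_tumor + 0.05))

    def _other_p(n_group, n_paired_group):
        rest = n_group - n_paired_group
        if rest <= 0:
            return 0.0
        return float(np.clip((f_dys * n_group - n_paired_group) / rest, 0.0, 1.0))

    obs_sample: list[np.ndarray] = []
    obs_cov: list[np.ndarray] = []
    obs_k: list[np.ndarray] = []
    removed_mut_rows = []
    mutation_rows = []
    violation_mode = []  # per site: "all" for quality artifacts, else ""

    for rec in sites:
        klass = rec["klass"]
        edited = np.zeros(n_all, dtype=bool)
        degree = np.zeros(n_all)
        forced_cov = None
        if klass in ("background", "snp_overlap", "mutation_overlap",
                     "artifact_quality", "dual_strand", "noncanonical"):
            prev = rng.uniform(*cfg.background_prevalence)
            edited = rng.random(n_all) < prev
            degree[edited] = np.clip(rng.beta(a_bg, b_bg, edited.sum()), 0.02, 0.95)
        elif klass == "indel":
            edited = rng.random(n_all) < 0.15
            degree[edited] = np.clip(rng.beta(a_bg, b_bg, edited.sum()), 0.02, 0.95)
        elif klass == "gain":
            et = rng.random(cfg.n_tumor) < cfg.gain_tumor_frac
            en = rng.random(cfg.n_normal) < cfg.gain_normal_frac
            edited[tumor_idx] = et
            edited[normal_idx] = en
            if rec["is_survival_linked"]:
                degree[edited] = rng.uniform(0.10, 0.90, edited.sum())
            else:
                degree[edited] = np.clip(rng.beta(a_pl, b_pl, edited.sum()),
                                         0.05, 0.90)
        elif klass == "loss":
            et = rng.random(cfg.n_tumor) < cfg.loss_tumor_frac
            en = rng.random(cfg.n_normal) < cfg.loss_normal_frac
            edited[tumor_idx] = et
            edited[normal_idx] = en
            degree[edited] = np.clip(rng.beta(a_pl, b_pl, edited.sum()), 0.05, 0.90)
        elif klass == "expression":
            edited = rng.random(n_all) < cfg.expression_prevalence
            degree[edited] = rng.uniform(0.10, 0.90, edited.sum())
        elif klass == "dys":
            hyper = bool(rng.random() < 0.5)
            rec["dys_direction"] = "hyper" if hyper else "hypo"
            pair_eff = rng.normal(0.0, 0.05, cfg.n_paired)
            if hyper:
                base = np.clip(rng.uniform(0.15, 0.30) + pair_eff, 0.05, 0.60)
                t_deg, n_deg = base + cfg.dys_shift, base
            else:
                base = np.clip(rng.uniform(0.40, 0.55) + pair_eff, 0.35, 0.60)
                t_deg, n_deg = base - cfg.dys_shift, base
            edited[paired_t] = True
            edited[paired_n] = True
            degree[paired_t] = np.clip(t_deg, 0.02, 0.95)
            degree[paired_n] = np.clip(n_deg, 0.02, 0.95)
            ot = rng.random(cfg.n_tumor - cfg.n_paired) < _other_p(cfg.n_tumor,
                                                                   cfg.n_paired)
            on = rng.random(cfg.n_normal - cfg.n_paired) < _other_p(cfg.n_normal,
                                                                    cfg.n_paired)
            edited[tumor_idx[cfg.n_paired:]] = ot
            edited[normal_idx[cfg.n_paired:]] = on
            extra = edited.copy()
            extra[paired_t] = extra[paired_n] = False
            degree[extra] = np.clip(rng.uniform(0.15, 0.45, extra.sum()), 0.02, 0.95)
        elif klass == "artifact_100pct":
            edited = rng.random(n_all) < 0.20
            degree[edited] = 1.0
        elif klass == "artifact_lowcov":
            edited = rng.random(n_all) < 0.30
            degree[edited] = np.clip(rng.beta(a_bg, b_bg, edited.sum()), 0.3, 0.9)
            forced_cov = rng.integers(4, 10, size=n_all)
        elif klass == "artifact_lowspread":
            edited = np.ones(n_all, dtype=bool)
            degree[:] = 0.30
            forced_cov = _coverage(rng, cfg, n_all, minimum=20)
        else:  # pragma: no cover
            raise AssertionError(klass)

        idx = np.where(edited)[0]
        if forced_cov is not None:
            cov = forced_cov[idx]
        else:
            cov = _coverage(rng, cfg, len(idx))
        if klass == "artifact_100pct":
            k = cov.copy()
        elif klass == "artifact_lowcov":
            k = np.minimum(np.maximum(rng.binomial(cov, degree[idx]), 2), cov - 1)
        elif klass == "artifact_lowspread":
            k = np.clip(np.round(0.30 * cov).astype(int), 2, cov - 1)
        else:
            k = rng.binomial(cov, degree[idx])
            nz = k > 0
            idx, cov, k = idx[nz], cov[nz], k[nz]
        obs_sample.append(idx)
        obs_cov.append(cov)
        obs_k.append(k)
        violation_mode.append("all" if klass == "artifact_quality" else "")

        if klass == "mutation_overlap" and len(idx):
            n_mut = max(1, len(idx) // 2)
            hit = rng.choice(idx, size=n_mut, replace=False)
            for si in sorted(int(h) for h in hit):
                mutation_rows.append((samples[si], rec["chrom"], rec["pos"],
                                      rec["ref"], rec["alt"]))
                removed_mut_rows.append((site_id(rec["chrom"], rec["pos"],
                                                 rec["ref"], rec["alt"]),
                                         samples[si]))

    # realized degrees (what the emitted VCFs actually contain)
    truth_obs_rows = []
    per_sample_obs: dict[str, list[VariantObservation]] = {s: [] for s in samples}
    for si, rec in enumerate(sites):
        sid = site_id(rec["chrom"], rec["pos"], rec["ref"], rec["alt"])
        rec["site_id"] = sid
        for j, cov, k in zip(obs_sample[si], obs_cov[si], obs_k[si]):
            s = samples[j]
            cov_i, k_i = int(cov), int(k)
            if violation_mode[si] == "all" or rng.random() < cfg.quality_violation_frac:
                if rng.random() < 0.5:
                    fs, qd = round(rng.uniform(20.5, 40.0), 3), round(rng.uniform(2.5, 30.0), 3)
                else:
                    fs, qd = round(rng.uniform(0.0, 15.0), 3), round(rng.uniform(0.2, 1.8), 3)
            else:
                fs = round(min(rng.exponential(3.0), 19.5), 3)
                qd = round(rng.uniform(2.5, 30.0), 3)
            if rng.random() < cfg.absent_fs_qd_frac:
                fs = qd = None
            per_sample_obs[s].append(VariantObservation(
                sample=s, chrom=rec["chrom"], pos=rec["pos"], ref=rec["ref"],
                alt=rec["alt"], ref_reads=cov_i - k_i, alt_reads=k_i, fs=fs, qd=qd))
            truth_obs_rows.append((sid, s, cov_i, k_i, k_i / cov_i))

    # --- extra (non-overlapping) somatic mutations ------------------------
    inter_pool = planner.pools["intergenic"]
    for s in samples_df[samples_df["role"] == "tumor"]["sample"]:
        for _ in range(cfg.n_extra_mutations_per_sample):
            while True:
                if not inter_pool:
                    break
                chrom, pos, _gi = inter_pool.pop()
                if (chrom, pos) not in planner.used:
                    break
            planner.used.add((chrom, pos))
            ref = str(genome[chrom][pos])
            alt = rng.choice([b for b in "ACGT" if b != ref])
            mutation_rows.append((s, chrom, pos, ref, str(alt)))

    # --- SNP catalog -------------------------------------------------------
    snp_rows = [(r["chrom"], r["pos"], r["ref"], r["alt"])
                for r in sites if r["klass"] == "snp_overlap"]
    for _ in range(cfg.n_snp_extra):
        while inter_pool:
            chrom, pos, _gi = inter_pool.pop()
            if (chrom, pos) not in planner.used:
                break
        planner.used.add((chrom, pos))
        ref = str(genome[chrom][pos])
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        snp_rows.append((chrom, pos, ref, alt))
    snp_rows.sort()

    # --- expression --------------------------------------------------------
    gene_names = [g.gene_id for g in genes]
    base = rng.lognormal(math.log(300.0), 0.7, size=len(genes))
    size_factor = rng.lognormal(0.0, 0.15, size=n_all)
    sd_deg = 0.8 / math.sqrt(12.0)  # degrees at linked sites ~ U(0.1, 0.9)
    r = abs(cfg.expression_target_r)
    slope = r * cfg.expression_noise_sigma / (sd_deg * math.sqrt(max(1e-9, 1 - r * r)))
    link = np.zeros((len(genes), n_all))
    truth_site_ids = [rec["site_id"] for rec in sites]
    realized_degree = np.zeros((len(sites), n_all))
    for si in range(len(sites)):
        realized_degree[si, obs_sample[si]] = obs_k[si] / obs_cov[si]
    for si, rec in enumerate(sites):
        if rec["is_expression_linked"] and rec["gene_idx"] >= 0:
            sgn = -1.0 if cfg.expression_target_r < 0 else 1.0
            link[rec["gene_idx"]] += sgn * slope * (realized_degree[si] - 0.5)
    sigma = cfg.expression_noise_sigma
    noise = rng.normal(0.0, sigma, size=(len(genes), n_all))
    mean = base[:, None] * size_factor[None, :] * np.exp(link + noise - sigma ** 2 / 2)
    counts = rng.poisson(mean)
    expr = pd.DataFrame(counts, index=gene_names, columns=samples)

    # --- clinical / survival ----------------------------------------------
    # the true linear predictor IS the risk-score form: sum over risk sites of
    # (size-factor-normalized expression) x (editing degree), standardized, so
    # log_hazard_per_unit is the log hazard per SD of the true risk score
    surv_idx = [si for si, rec in enumerate(sites) if rec["is_survival_linked"]]
    norm_counts = counts / size_factor[None, :]
    raw_score = np.zeros(cfg.n_tumor)
    for si in surv_idx:
        gi = sites[si]["gene_idx"]
        raw_score += norm_counts[gi, :cfg.n_tumor] * realized_degree[si, :cfg.n_tumor]
    sd = raw_score.std()
    lp = (raw_score - raw_score.mean()) / sd if sd > 0 else np.zeros(cfg.n_tumor)
    lp_c = lp
    rate = cfg.baseline_hazard * np.exp(cfg.log_hazard_per_unit * lp_c)
    t_event = rng.exponential(1.0 / rate)
    censor = rng.uniform(*cfg.censor_range, size=cfg.n_tumor)
    time = np.maximum(np.minimum(t_event, censor), 1.0).round(1)
    event = (t_event <= censor).astype(int)
    p_grade = np.clip(0.35 + 0.12 * lp_c, 0.05, 0.92)
    grade = 1 + rng.binomial(3, p_grade)
    stage = 1 + rng.binomial(3, np.clip(0.35 + 0.10 * lp_c, 0.05, 0.92))
    clinical = pd.DataFrame({
        "sample": tumors, "time": time, "event": event,
        "gender": rng.choice(["male", "female"], size=cfg.n_tumor, p=[0.7, 0.3]),
        "age": np.clip(rng.normal(60, 10, cfg.n_tumor), 25, 90).round(1),
        "bmi": np.clip(rng.normal(26, 4, cfg.n_tumor), 16, 45).round(1),
        "grade": grade, "stage": stage,
        "hbv_hcv": (rng.random(cfg.n_tumor) < 0.45).astype(int),
        "alcohol": (rng.random(cfg.n_tumor) < 0.30).astype(int),
        "nafld": (rng.random(cfg.n_tumor) < 0.25).astype(int),
    })

    # --- miRNA catalog ------------------------------------------------------
    mirnas: dict[str, str] = {}
    for i in range(cfg.n_mirna):
        seq = "".join(rng.choice(_BASES, size=cfg.mirna_length))
        mirnas[f"mir-{i + 1:04d}"] = seq.replace("T", "U")
    truth_mirna_rows = []
    for name, seq, si, expected in mirna_records:
        mirnas[name] = seq
        truth_mirna_rows.append((sites[si]["site_id"], name, expected))

    # --- gene sets ----------------------------------------------------------
    gain_hosts = sorted({genes[r["gene_idx"]].gene_name for r in sites
                         if r["is_gain"] and r["gene_idx"] >= 0})
    loss_hosts = sorted({genes[r["gene_idx"]].gene_name for r in sites
                         if r["is_loss"] and r["gene_idx"] >= 0})
    all_names = [g.gene_name for g in genes]
    gmt_lines = []
    if gain_hosts:
        gmt_lines.append(("GAIN_HOST_GENES", gain_hosts))
    if loss_hosts:
        gmt_lines.append(("LOSS_HOST_GENES", loss_hosts))
    for i in range(18):
        hi = min(26, len(all_names) + 1)
        size = int(rng.integers(min(10, hi - 1), hi))
        members = sorted(rng.choice(all_names, size=size, replace=False))
        gmt_lines.append((f"RANDOM_SET_{i + 1:02d}", members))

    # --- write everything ---------------------------------------------------
    paths = {
        "genome": out_dir / "genome.fa", "gtf": out_dir / "genes.gtf",
        "mirna": out_dir / "mirnas.fa", "snps": out_dir / "snps.vcf",
        "mutations": out_dir / "mutations.tsv",
        "expression": out_dir / "expression.tsv",
        "clinical": out_dir / "clinical.tsv", "samples": out_dir / "samples.tsv",
        "gmt": out_dir / "gene_sets.gmt", "vcf_dir": out_dir / "vcf",
    }
    genome_str = {c: "".join(genome[c]) for c in chrom_names}
    _write_fasta(paths["genome"], genome_str)
    _write_gtf(paths["gtf"], genes)
    _write_fasta(paths["mirna"], mirnas)
    contigs = {c: cfg.chrom_length for c in chrom_names}
    contigs["chrUn_test1"] = 50_000
    with open(paths["snps"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in contigs.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in snp_rows:
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\n")
    mut_df = pd.DataFrame(mutation_rows,
                          columns=["sample", "chrom", "pos", "ref", "alt"])
    mut_df = mut_df.sort_values(["sample", "chrom", "pos"], kind="stable")
    mut_out = mut_df.copy()
    mut_out["pos"] = mut_out["pos"] + 1  # 1-based on disk
    mut_out.to_csv(paths["mutations"], sep="\t", index=False)
    expr.to_csv(paths["expression"], sep="\t", index_label="gene")
    clinical.to_csv(paths["clinical"], sep="\t", index=False)
    samples_df.to_csv(paths["samples"], sep="\t", index=False)
    with open(paths["gmt"], "w") as fh:
        for name, members in gmt_lines:
            fh.write("\t".join([name, "synthetic"] + list(members)) + "\n")
    for s in samples:
        write_variant_records(paths["vcf_dir"] / f"{s}.vcf", per_sample_obs[s],
                              contigs, sample=s)

    truth_sites = pd.DataFrame([{k: v for k, v in rec.items() if k != "gene_idx"}
                                | {"gene_id": genes[rec["gene_idx"]].gene_id
                                   if rec["gene_idx"] >= 0 else ""}
                                for rec in sites]).set_index("site_id")
    truth_obs = pd.DataFrame(truth_obs_rows,
                             columns=["site_id", "sample", "coverage",
                                      "alt_reads", "degree"])
    truth_removed = pd.DataFrame(removed_mut_rows, columns=["site_id", "sample"])
    truth_patients = pd.DataFrame({"sample": tumors, "lp": lp,
                                   "event_time": t_event.round(2)})
    truth_mirna = pd.DataFrame(truth_mirna_rows,
                               columns=["site_id", "mirna", "expected_kind"])
    truth_sites.to_csv(out_dir / "truth" / "sites.tsv", sep="\t")
    truth_obs.to_csv(out_dir / "truth" / "observations.tsv", sep="\t", index=False)
    truth_removed.to_csv(out_dir / "truth" / "removed_mutations.tsv", sep="\t",
                         index=False)
    truth_patients.to_csv(out_dir / "truth" / "patients.tsv", sep="\t", index=False)
    truth_mirna.to_csv(out_dir / "truth" / "mirna.tsv", sep="\t", index=False)

    return SyntheticCohort(out_dir=out_dir, config=cfg, paths=paths,
                           gene_models=genes, truth_sites=truth_sites,
                           truth_observations=truth_obs,
                           truth_removed_mutations=truth_removed,
                           truth_patients=truth_patients,
                           truth_mirna=truth_mirna)


# ---------------------------------------------------------------------------
# Small targeted simulators used by the validation suite
# ---------------------------------------------------------------------------

def simulate_filter_stress(n_obs: int, seed: int, n_samples: int = 12):
    """Random variant observations with injected violations of every cascade
    rule: FS/QD, support, coverage, 100% degree, indels, SNP overlap,
    per-sample mutations, low-spread and low-recurrence sites.

    Returns (observations frame, mutations frame, snp positions, roles).
    """
    rng = np.random.default_rng(seed)
    samples = [f"S{i:02d}" for i in range(n_samples)]
    n_sites = max(n_obs // (n_samples // 2), 1)
    rows = []
    positions = rng.choice(np.arange(1000, 1000 + 10 * n_sites, 10), size=n_sites,
                           replace=False)
    for pos in positions:
        chrom = "chr1" if rng.random() < 0.9 else "chrUn_x"
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        constant = rng.random() < 0.05  # low-spread candidate
        rare = rng.random() < 0.05  # low-recurrence candidate
        n_edit = 1 if rare else int(rng.integers(2, n_samples + 1))
        members = rng.choice(n_samples, size=n_edit, replace=False)
        for m in members:
            cov = int(rng.integers(5, 80))
            deg = 0.3 if constant else float(rng.uniform(0.05, 1.0))
            k = int(np.clip(round(deg * cov), 1, cov))
            fs = float(rng.uniform(0, 35)) if rng.random() < 0.8 else None
            qd = float(rng.uniform(0.5, 25)) if rng.random() < 0.8 else None
            if rng.random() < 0.03:  # indel
                alt_a = alt + "T"
            else:
                alt_a = alt
            rows.append((samples[m], chrom, int(pos), ref, alt_a, cov - k, k,
                         np.nan if fs is None else fs,
                         np.nan if qd is None else qd))
    obs = pd.DataFrame(rows, columns=["sample", "chrom", "pos", "ref", "alt",
                                      "ref_reads", "alt_reads", "fs", "qd"])
    obs = obs.head(n_obs).reset_index(drop=True)
    # SNP overlap for ~5% of positions; per-sample mutations for ~5% of rows
    upos = obs[["chrom", "pos"]].drop_duplicates()
    snp_take = upos.sample(frac=0.05, random_state=int(rng.integers(2 ** 31)))
    snps = set(zip(snp_take["chrom"], snp_take["pos"]))
    mut_take = obs.sample(frac=0.05, random_state=int(rng.integers(2 ** 31)))
    mutations = mut_take[["sample", "chrom", "pos"]].reset_index(drop=True)
    roles = pd.Series(["tumor"] * (n_samples // 2) + ["normal"] * (n_samples - n_samples // 2),
                      index=samples)
    return obs, mutations, snps, roles


def simulate_expression_link(n_samples: int, target_r: float, seed: int,
                             n_null_sites: int = 20,
                             noise_sigma: float = 0.30):
    """Editing degrees plus normalized expression with one planted monotone
    link and ``n_null_sites`` independent sites.  Returns (degrees DataFrame
    site x sample, expression DataFrame site x sample, planted site id)."""
    rng = np.random.default_rng(seed)
    sd_deg = 0.8 / math.sqrt(12.0)
    r = abs(target_r)
    slope = r * noise_sigma / (sd_deg * math.sqrt(1 - r * r))
    sgn = -1.0 if target_r < 0 else 1.0
    deg_rows, expr_rows, ids = [], [], []
    for i in range(n_null_sites + 1):
        d = rng.uniform(0.1, 0.9, size=n_samples)
        base = 8.0
        if i == 0:
            y = np.exp(base + sgn * slope * (d - 0.5)
                       + rng.normal(0, noise_sigma, n_samples))
        else:
            y = np.exp(base + rng.normal(0, noise_sigma, n_samples))
        ids.append("planted" if i == 0 else f"null{i:02d}")
        deg_rows.append(d)
        expr_rows.append(y)
    cols = [f"S{j:03d}" for j in range(n_samples)]
    return (pd.DataFrame(deg_rows, index=ids, columns=cols),
            pd.DataFrame(expr_rows, index=ids, columns=cols), "planted")


def simulate_survival_groups(n: int, hazard_ratio: float, seed: int,
                             baseline: float = 1.0 / 1000.0,
                             censor_at: float = 3000.0):
    """Two equal groups with a true hazard ratio; returns a survival frame
    with columns time, event, group (1 = high risk)."""
    rng = np.random.default_rng(seed)
    group = np.repeat([0, 1], n // 2)
    rate = baseline * np.power(hazard_ratio, group)
    t = rng.exponential(1.0 / rate)
    c = rng.uniform(0, censor_at, size=len(group))
    return pd.DataFrame({"time": np.minimum(t, c).clip(min=1e-3),
                         "event": (t <= c).astype(int), "group": group})
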