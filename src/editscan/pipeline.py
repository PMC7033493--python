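"""End-to-end orchestration: load a cohort directory, run every stage of the
analysis, and write per-stage result tables.

Stage order: call (filter cascade) -> annotate -> diffedit (+ enrichment) ->
rewire -> expresslink -> prognosis.  Each stage function is also usable on
its own; :func:`run_pipeline` wires them together and asserts the inter-stage
invariants (degrees in (0,1), recurrence bound, dys calls inside the catalog).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate as _annotate
from . import diffedit as _diffedit
from . import expresslink as _expresslink
from . import prognosis as _prognosis
from . import rewire as _rewire
from .editcall import FilterThresholds, SiteCatalog, run_cascade
from .formats import (GeneModel, observations_to_frame, read_expression_matrix,
                      read_fasta, read_gene_models, read_gmt,
                      read_mutation_table, read_sample_table,
                      read_snp_positions, read_variant_records, write_bed6)

log = logging.getLogger(__name__)

__all__ = ["CohortInputs", "PipelineResult", "load_cohort", "run_pipeline",
           "CONSEQUENCE_CDS"]

#: CDS/splicing consequence categories counted as functional
CONSEQUENCE_CDS = {"non-synonymous", "stop_gain", "stop_loss", "splicing", "unknown"}


@dataclass
class CohortInputs:
    observations: pd.DataFrame
    mutations: pd.DataFrame
    snp_positions: set
    genes: list[GeneModel]
    genome: dict[str, str]
    mirnas: dict[str, str]
    expression: pd.DataFrame  # raw counts, gene x sample
    clinical: pd.DataFrame  # indexed by (tumor) sample
    samples: pd.DataFrame  # sample sheet
    gene_sets: dict[str, set[str]] = field(default_factory=dict)

    @property
    def roles(self) -> pd.Series:
        return self.samples.set_index("sample")["role"]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        out = []
        paired = self.samples[self.samples["pair"].astype(str).str.len() > 0]
        for pair, grp in paired.groupby("pair"):
            t = grp[grp["role"] == "tumor"]["sample"]
            n = grp[grp["role"] == "normal"]["sample"]
            if len(t) == 1 and len(n) == 1:
                out.append((t.iloc[0], n.iloc[0]))
        return sorted(out)


def load_cohort(cohort_dir) -> CohortInputs:
    """Read every input the generator (or an equivalent preparation) emits."""
    d = Path(cohort_dir)
    samples = read_sample_table(d / "samples.tsv")
    obs = []
    for s in samples["sample"]:
        obs.extend(read_variant_records(d / "vcf" / f"{s}.vcf", sample=s))
    clinical = pd.read_csv(d / "clinical.tsv", sep="\t").set_index("sample")
    roles = samples.set_index("sample")["role"]
    gmt_path = d / "gene_sets.gmt"
    return CohortInputs(
        observations=observations_to_frame(obs),
        mutations=read_mutation_table(d / "mutations.tsv"),
        snp_positions=read_snp_positions(d / "snps.vcf"),
        genes=read_gene_models(d / "genes.gtf"),
        genome=read_fasta(d / "genome.fa"),
        mirnas=read_fasta(d / "mirnas.fa"),
        expression=read_expression_matrix(d / "expression.tsv", roles).counts,
        clinical=clinical,
        samples=samples,
        gene_sets=read_gmt(gmt_path) if gmt_path.exists() else {},
    )


@dataclass
class PipelineResult:
    catalog: SiteCatalog
    annotations: pd.DataFrame
    differential: pd.DataFrame
    enrichment: pd.DataFrame | None
    rewiring: pd.DataFrame
    mirna_consequence: pd.DataFrame
    expression_link: pd.DataFrame
    consequence: pd.Series  # site -> bool
    risk_model: _prognosis.RiskModel | None
    risk_scores: pd.Series | None
    association: pd.DataFrame | None
    survival: _prognosis.SurvivalComparison | None
    multivariate: pd.DataFrame | None

    def hcc_related_sites(self) -> pd.Index:
        return self.differential.index[self.differential["hcc_related"]]


def _check_invariants(catalog: SiteCatalog, differential: pd.DataFrame,
                      n_samples: int) -> None:
    d = catalog.degrees.to_numpy()
    finite = d[~np.isnan(d)]
    assert ((finite > 0) & (finite < 1)).all(), "degrees must lie in (0,1)"
    edited = (catalog.degrees.fillna(0.0) > 0).sum(axis=1)
    assert (edited >= math.ceil(0.01 * n_samples)).all(), "recurrence violated"
    assert differential.index.equals(catalog.sites.index), \
        "differential table must cover the catalog"


def run_pipeline(inputs: CohortInputs, out_dir=None,
                 thresholds: FilterThresholds = FilterThresholds(),
                 duplex_params: _rewire.DuplexParams = _rewire.DuplexParams(),
                 run_rewire: bool = True) -> PipelineResult:
    roles = inputs.roles
    canonical = set(inputs.genome)
    catalog = run_cascade(inputs.observations, inputs.mutations,
                          inputs.snp_positions, inputs.genes, canonical, roles,
                          thresholds)
    ann = _annotate.annotate_sites(catalog.sites, inputs.genes, inputs.genome)
    diff = _diffedit.classify_differential(catalog, inputs.pairs)
    _check_invariants(catalog, diff, len(roles))

    enrichment = None
    if inputs.gene_sets:
        # gene sets are keyed by symbol (MSigDB convention)
        universe = set(ann["gene_name"].dropna()) - {""}
        query = set(ann.loc[diff.index[diff["hcc_related"]], "gene_name"].dropna()) - {""}
        if universe:
            enrichment = _diffedit.enrich_gene_sets(query, inputs.gene_sets, universe)

    if run_rewire and inputs.mirnas:
        rewiring, mirna_cons = _rewire.rewire_sites(
            catalog.sites, ann, inputs.genes, inputs.genome, inputs.mirnas,
            duplex_params)
    else:
        rewiring = pd.DataFrame(columns=["site_id", "mirna", "kind", "ddg"])
        mirna_cons = pd.DataFrame(columns=["n_changes", "mirna_consequence"])

    try:
        factors = _expresslink.size_factors(inputs.expression)
    except ValueError as exc:
        log.warning("size factors: %s; using pseudo-reference fallback", exc)
        factors = _expresslink.size_factors(inputs.expression,
                                            allow_pseudo_reference=True)
    norm_expr = inputs.expression / factors
    site_gene = ann["gene_id"].fillna("")
    link = _expresslink.correlate_editing_expression(catalog.degrees, norm_expr,
                                                     site_gene)

    # functional-consequence pool: CDS/splicing change, miRNA-target
    # regulation change, or expression-correlated editing
    cds_cons = ann["consequence"].isin(CONSEQUENCE_CDS)
    mir_cons = pd.Series(False, index=ann.index)
    if len(mirna_cons):
        hit = mirna_cons.index[mirna_cons["mirna_consequence"].astype(bool)]
        mir_cons.loc[mir_cons.index.intersection(hit)] = True
    expr_cons = pd.Series(False, index=ann.index)
    if len(link):
        hit = link.index[link["significant"].astype(bool)]
        expr_cons.loc[expr_cons.index.intersection(hit)] = True
    consequence = cds_cons | mir_cons | expr_cons
    consequence.name = "consequence"

    # --- prognosis ---------------------------------------------------------
    risk_model = risk_scores = association = survival = multivariate = None
    patients = [p for p in inputs.clinical.index if p in catalog.degrees.columns]
    survival_df = inputs.clinical.loc[patients, ["time", "event"]]
    eligible = [sid for sid in catalog.sites.index
                if diff.loc[sid, "hcc_related"] and consequence.loc[sid]
                and site_gene.loc[sid]]
    if eligible and len(patients) >= 20:
        risk_model = _prognosis.build_risk_model(eligible, site_gene,
                                                 catalog.degrees[patients],
                                                 survival_df)
        if len(risk_model.table):
            risk_scores = _prognosis.risk_score(risk_model, norm_expr,
                                                catalog.degrees, patients)
            clin = inputs.clinical.loc[patients]
            association = _prognosis.grade_stage_association(risk_scores, clin)
            survival = _prognosis.km_logrank(risk_scores, survival_df)
            multivariate = _prognosis.multivariate_adjustment(risk_scores, clin)
    else:
        log.info("prognosis skipped: %d eligible sites, %d patients",
                 len(eligible), len(patients))

    result = PipelineResult(catalog=catalog, annotations=ann, differential=diff,
                            enrichment=enrichment, rewiring=rewiring,
                            mirna_consequence=mirna_cons, expression_link=link,
                            consequence=consequence, risk_model=risk_model,
                            risk_scores=risk_scores, association=association,
                            survival=survival, multivariate=multivariate)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat = result.catalog
    cat.sites.join(cat.edited_counts()).to_csv(out / "sites.tsv", sep="\t")
    cat.degrees.to_csv(out / "degrees.tsv", sep="\t")
    cat.coverage.to_csv(out / "coverage.tsv", sep="\t")
    write_bed6(out / "sites.bed",
               ((r["chrom"], r["pos"], r["pos"] + 1, sid, 0, r["strand"])
                for sid, r in cat.sites.iterrows()))
    result.annotations.to_csv(out / "annotations.tsv", sep="\t")
    result.differential.to_csv(out / "differential.tsv", sep="\t")
    if result.enrichment is not None:
        result.enrichment.to_csv(out / "enrichment.tsv", sep="\t")
    result.rewiring.to_csv(out / "rewiring.tsv", sep="\t", index=False)
    result.mirna_consequence.to_csv(out / "mirna_consequence.tsv", sep="\t")
    result.expression_link.to_csv(out / "expression_link.tsv", sep="\t")
    result.consequence.to_frame().to_csv(out / "consequence.tsv", sep="\t")
    if result.risk_model is not None:
        result.risk_model.table.to_csv(out / "risk_model.tsv", sep="\t")
    if result.risk_scores is not None:
        result.risk_scores.to_frame().to_csv(out / "risk_scores.tsv", sep="\t")
    if result.association is not None:
        result.association.to_csv(out / "association.tsv", sep="\t", index=False)
    if result.survival is not None:
        km = pd.concat(result.survival.km_curves.values(), axis=1)
        km.to_csv(out / "km.tsv", sep="\t")
        pd.DataFrame({"logrank_stat": [result.survival.logrank_stat],
                      "logrank_p": [result.survival.logrank_p]}
                     ).to_csv(out / "logrank.tsv", sep="\t", index=False)
    if result.multivariate is not None:
        result.multivariate.to_csv(out / "multivariate.tsv", sep="\t")
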