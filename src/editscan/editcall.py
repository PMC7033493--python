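"""The multi-stage filter cascade that turns candidate variant observations
into an editing-site catalog with per-sample editing degrees.

Steps, applied to the pooled observations of a tumor/normal cohort:

(i)    drop an observation when that same sample carries a DNA mutation at the
       position (other samples' observations survive);
(ii)   drop all observations at known-SNP positions (cohort-wide, position
       based) and all non-SNV observations (indels);
(iii)  quality filter: FS > 20, QD < 2, edited reads < 2 or coverage < 10
       removes the observation (strict comparisons as printed; absent FS/QD
       pass and are counted);
(iv)   observations with editing degree exactly 1.0 are removed (100% editing
       is treated as an artifact; per-observation by default, with a
       site-level mode);
(v)    site-level: the Q90 - Q10 editing-degree spread across the full cohort
       (zeros for unedited samples) must be >= 0.10, and the site must be
       edited in at least ceil(1% of the cohort) samples.

Finally sites outside the canonical chromosome set and sites covered by
annotated genes on both strands are removed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .formats import GeneModel, site_id

log = logging.getLogger(__name__)

__all__ = [
    "FilterThresholds",
    "EditingSite",
    "SiteCatalog",
    "editing_degree",
    "remove_sample_mutations",
    "remove_known_snps_and_indels",
    "quality_filter",
    "remove_full_degree",
    "quantile_spread_keep",
    "recurrence_keep",
    "site_filters",
    "finalize_sites",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterThresholds:
    """Cascade thresholds.  All comparisons are strict as printed: FS must
    exceed ``max_fs`` to be removed, coverage exactly ``min_coverage``
    survives, etc."""

    max_fs: float = 20.0
    min_qd: float = 2.0
    min_alt_reads: int = 2
    min_coverage: int = 10
    min_quantile_spread: float = 0.10
    recurrence_fraction: float = 0.01
    hundred_percent_mode: str = "observation"  # or "site"


def editing_degree(alt_reads: int, total_reads: int) -> float:
    """Fraction of edited reads among all mapped reads at the site."""
    if total_reads <= 0:
        raise ValueError("editing degree undefined for zero coverage")
    if alt_reads > total_reads:
        raise ValueError("edited reads exceed total reads")
    return alt_reads / total_reads


# ---------------------------------------------------------------------------
# Per-observation filters (steps i-iv). Observations travel as a DataFrame
# with columns sample, chrom, pos, ref, alt, ref_reads, alt_reads, fs, qd.
# ---------------------------------------------------------------------------

def remove_sample_mutations(obs: pd.DataFrame, mutations: pd.DataFrame) -> pd.DataFrame:
    """Drop observations whose own sample has a DNA mutation at the position."""
    if mutations.empty or obs.empty:
        return obs
    mut_keys = set(zip(mutations["sample"], mutations["chrom"], mutations["pos"]))
    mask = [(s, c, p) not in mut_keys
            for s, c, p in zip(obs["sample"], obs["chrom"], obs["pos"])]
    return obs[np.asarray(mask, dtype=bool)]


def remove_known_snps_and_indels(obs: pd.DataFrame,
                                 snp_positions: set[tuple[str, int]]) -> pd.DataFrame:
    """Drop all observations at known-SNP positions and all non-SNV records."""
    if obs.empty:
        return obs
    snv = (obs["ref"].str.len() == 1) & (obs["alt"].str.len() == 1)
    not_snp = np.asarray([(c, p) not in snp_positions
                          for c, p in zip(obs["chrom"], obs["pos"])], dtype=bool)
    return obs[snv.to_numpy() & not_snp]


def quality_filter(obs: pd.DataFrame,
                   thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """GATK-annotation quality filter; absent FS/QD pass (counted, not dropped)."""
    if obs.empty:
        return obs
    fs = obs["fs"].to_numpy(dtype=float)
    qd = obs["qd"].to_numpy(dtype=float)
    alt = obs["alt_reads"].to_numpy()
    cov = alt + obs["ref_reads"].to_numpy()
    n_absent = int(np.isnan(fs).sum() + np.isnan(qd).sum())
    if n_absent:
        log.info("quality_filter: %d absent FS/QD annotations treated as passing",
                 n_absent)
    bad = (np.nan_to_num(fs, nan=-np.inf) > thresholds.max_fs) \
        | (np.nan_to_num(qd, nan=np.inf) < thresholds.min_qd) \
        | (alt < thresholds.min_alt_reads) | (cov < thresholds.min_coverage)
    return obs[~bad]


def remove_full_degree(obs: pd.DataFrame, mode: str = "observation") -> pd.DataFrame:
    """Remove 100%-editing-degree artifacts.

    ``observation`` (default): only the offending sample's observation is
    dropped.  ``site``: any 100%-degree observation removes the whole site.
    """
    if obs.empty:
        return obs
    full = obs["ref_reads"].to_numpy() == 0
    if mode == "observation":
        return obs[~full]
    if mode == "site":
        bad_sites = set(zip(obs.loc[full, "chrom"], obs.loc[full, "pos"],
                            obs.loc[full, "ref"], obs.loc[full, "alt"]))
        keep = [(c, p, r, a) not in bad_sites for c, p, r, a in
                zip(obs["chrom"], obs["pos"], obs["ref"], obs["alt"])]
        return obs[np.asarray(keep, dtype=bool)]
    raise ValueError(f"unknown 100%-degree mode {mode!r}")


# ---------------------------------------------------------------------------
# Site-level filters (step v)
# ---------------------------------------------------------------------------

def quantile_spread_keep(degrees: np.ndarray, n_samples: int,
                         min_spread: float = 0.10) -> bool:
    """Keep iff Q90 - Q10 of the full-cohort degree vector >= ``min_spread``.

    ``degrees`` holds the degrees of edited samples; unedited samples enter
    as zeros.  Quantiles use linear interpolation on the sorted vector.
    """
    v = np.zeros(n_samples)
    v[:len(degrees)] = degrees
    q10, q90 = np.quantile(v, [0.10, 0.90])
    return bool(q90 - q10 >= min_spread)


def recurrence_keep(n_edited: int, n_samples: int, fraction: float = 0.01) -> bool:
    """Keep iff edited in at least ceil(fraction x cohort) samples."""
    return n_edited >= math.ceil(fraction * n_samples)


def site_filters(obs: pd.DataFrame, n_samples: int,
                 thresholds: FilterThresholds = FilterThresholds()) -> pd.DataFrame:
    """Apply the spread and recurrence rules site by site."""
    if obs.empty:
        return obs
    deg = obs["alt_reads"].to_numpy() / (obs["alt_reads"] + obs["ref_reads"]).to_numpy()
    obs = obs.assign(_degree=deg)
    keep_sites = []
    for key, grp in obs.groupby(["chrom", "pos", "ref", "alt"], sort=False):
        degrees = grp["_degree"].to_numpy()
        if not quantile_spread_keep(degrees, n_samples, thresholds.min_quantile_spread):
            continue
        n_edited = int((degrees > 0).sum())
        if not recurrence_keep(n_edited, n_samples, thresholds.recurrence_fraction):
            continue
        keep_sites.append(key)
    keep = set(keep_sites)
    mask = [(c, p, r, a) in keep for c, p, r, a in
            zip(obs["chrom"], obs["pos"], obs["ref"], obs["alt"])]
    return obs[np.asarray(mask, dtype=bool)].drop(columns="_degree")


# ---------------------------------------------------------------------------
# Finalization
# ---------------------------------------------------------------------------

@dataclass
class EditingSite:
    """A site surviving all filters, with per-sample degrees."""

    chrom: str
    pos: int
    ref: str
    alt: str
    strand: str
    degrees: dict[str, float] = field(default_factory=dict)  # sample -> degree
    coverage: dict[str, int] = field(default_factory=dict)

    @property
    def site_id(self) -> str:
        return site_id(self.chrom, self.pos, self.ref, self.alt)

    def edited_count(self, samples) -> int:
        return sum(1 for s in samples if self.degrees.get(s, 0.0) > 0)


@dataclass
class SiteCatalog:
    """Catalog frames: ``sites`` (index site_id; chrom/pos/ref/alt/strand),
    ``degrees`` and ``coverage`` (site x sample, NaN = not observed)."""

    sites: pd.DataFrame
    degrees: pd.DataFrame
    coverage: pd.DataFrame
    roles: pd.Series  # sample -> tumor | normal

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.roles[self.roles == "tumor"].index)

    @property
    def normal_samples(self) -> list[str]:
        return list(self.roles[self.roles == "normal"].index)

    def edited_counts(self) -> pd.DataFrame:
        d = self.degrees.fillna(0.0)
        return pd.DataFrame({
            "tumor_edited": (d[self.tumor_samples] > 0).sum(axis=1),
            "normal_edited": (d[self.normal_samples] > 0).sum(axis=1),
        })


def _dual_strand_positions(chrom: str, pos: int, genes: list[GeneModel]) -> bool:
    strands = {g.strand for g in genes
               if g.chrom == chrom and g.span.contains(pos) and g.strand in "+-"}
    return strands >= {"+", "-"}


def finalize_sites(obs: pd.DataFrame, genes: list[GeneModel],
                   canonical_chroms: set[str], roles: pd.Series) -> SiteCatalog:
    """Restrict to canonical chromosomes, drop dual-strand sites, group the
    surviving observations into the catalog."""
    if not obs.empty:
        canon = obs["chrom"].isin(canonical_chroms).to_numpy()
        obs = obs[canon]
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    site_rows, deg_rows, cov_rows = [], {}, {}
    for (c, p, r, a), grp in obs.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        overlapping = [g for g in by_chrom.get(c, []) if g.span.contains(p)]
        strands = {g.strand for g in overlapping if g.strand in "+-"}
        if strands >= {"+", "-"}:
            continue
        strand = strands.pop() if len(strands) == 1 else "?"
        sid = site_id(c, p, r, a)
        alt_n = grp["alt_reads"].to_numpy()
        cov_n = alt_n + grp["ref_reads"].to_numpy()
        site_rows.append((sid, c, p, r, a, strand))
        deg_rows[sid] = dict(zip(grp["sample"], alt_n / cov_n))
        cov_rows[sid] = dict(zip(grp["sample"], cov_n))
    sites = pd.DataFrame(site_rows, columns=["site_id", "chrom", "pos", "ref",
                                             "alt", "strand"]).set_index("site_id")
    samples = list(roles.index)
    degrees = pd.DataFrame.from_dict(deg_rows, orient="index").reindex(
        index=sites.index, columns=samples)
    coverage = pd.DataFrame.from_dict(cov_rows, orient="index").reindex(
        index=sites.index, columns=samples)
    return SiteCatalog(sites=sites, degrees=degrees, coverage=coverage, roles=roles)


def run_cascade(obs: pd.DataFrame, mutations: pd.DataFrame,
                snp_positions: set[tuple[str, int]], genes: list[GeneModel],
                canonical_chroms: set[str], roles: pd.Series,
                thresholds: FilterThresholds = FilterThresholds()) -> SiteCatalog:
    """Run steps (i)-(v) plus finalization and return the site catalog."""
    n_samples = len(roles)
    if n_samples == 0:
        raise ValueError("empty cohort")
    n0 = len(obs)
    obs = remove_sample_mutations(obs, mutations)
    n1 = len(obs)
    obs = remove_known_snps_and_indels(obs, snp_positions)
    n2 = len(obs)
    obs = quality_filter(obs, thresholds)
    n3 = len(obs)
    obs = remove_full_degree(obs, thresholds.hundred_percent_mode)
    n4 = len(obs)
    obs = site_filters(obs, n_samples, thresholds)
    n5 = len(obs)
    catalog = finalize_sites(obs, genes, canonical_chroms, roles)
    log.info("cascade: %d obs -> mutations %d -> snps/indels %d -> quality %d "
             "-> 100%% %d -> site rules %d -> %d sites",
             n0, n1, n2, n3, n4, n5, len(catalog.sites))
    return catalog
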