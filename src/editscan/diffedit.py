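"""Differential-editing classification (gain / loss / dys-edited) and gene-set
enrichment of the implicated genes.

A site is a *gain* site when it is edited significantly more often in tumors
(two-sided Fisher exact test on the edited/unedited x tumor/normal table,
Benjamini-Hochberg adjusted p < 0.05) while being edited in at most 5% of
normal samples; *loss* is the mirror image.  *Dys-edited* sites are tested on
the paired tumor/normal subcohort with a paired t test on per-pair degree
differences (absent = 0): called when BH-adjusted p < 0.2 AND raw p < 0.01 AND
at least two pairs shift by more than 0.25 in the direction of the mean
difference.  "Edited" means a degree is present and > 0 after all filters.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .editcall import SiteCatalog

log = logging.getLogger(__name__)

__all__ = ["fisher_gain_loss", "paired_dys_edit", "classify_differential",
           "enrich_gene_sets", "FRACTION_RESTRICTION"]

#: maximum edited-sample fraction allowed in the complementary group
FRACTION_RESTRICTION = 0.05


def fisher_gain_loss(catalog: SiteCatalog, alpha: float = 0.05,
                     max_other_fraction: float = FRACTION_RESTRICTION) -> pd.DataFrame:
    """Per-site Fisher screen over the whole catalog (BH across all sites).

    Returns a frame indexed by site id with the 2x2 counts, raw and adjusted
    p, edited fractions, and the gain/loss class.
    """
    tumors, normals = catalog.tumor_samples, catalog.normal_samples
    n_t, n_n = len(tumors), len(normals)
    if n_t == 0 or n_n == 0:
        raise ValueError("both tumor and normal samples are required")
    d = catalog.degrees.fillna(0.0)
    t_edit = (d[tumors] > 0).sum(axis=1).to_numpy()
    n_edit = (d[normals] > 0).sum(axis=1).to_numpy()
    pvals = np.ones(len(d))
    cache: dict[tuple[int, int], float] = {}
    for i, (a, b) in enumerate(zip(t_edit, n_edit)):
        key = (int(a), int(b))
        if key not in cache:
            if a + b == 0 or (n_t - a) + (n_n - b) == 0:
                cache[key] = 1.0  # zero-margin table carries no information
            else:
                table = [[a, n_t - a], [b, n_n - b]]
                cache[key] = stats.fisher_exact(table, alternative="two-sided")[1]
        pvals[i] = cache[key]
    adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    t_frac = t_edit / n_t
    n_frac = n_edit / n_n
    cls = np.full(len(d), "none", dtype=object)
    gain = (adj < alpha) & (n_frac <= max_other_fraction) & (t_frac > n_frac)
    loss = (adj < alpha) & (t_frac <= max_other_fraction) & (n_frac > t_frac)
    cls[gain] = "gain"
    cls[loss] = "loss"
    return pd.DataFrame({
        "tumor_edited": t_edit, "normal_edited": n_edit,
        "tumor_fraction": t_frac, "normal_fraction": n_frac,
        "fisher_p": pvals, "fisher_p_adj": adj, "cls": cls,
    }, index=catalog.degrees.index)


def paired_dys_edit(catalog: SiteCatalog, pairs: list[tuple[str, str]],
                    adj_alpha: float = 0.2, raw_alpha: float = 0.01,
                    min_shift: float = 0.25, min_shifted_pairs: int = 2,
                    require_raw: bool = True) -> pd.DataFrame:
    """Paired dys-edit screen over sites edited in the paired subcohort.

    ``pairs`` holds (tumor sample, normal sample) tuples.  ``require_raw``
    keeps the dual-threshold AND reading (BH-adjusted < ``adj_alpha`` AND raw
    < ``raw_alpha``); switching it off keeps the BH gate only.  Zero-variance
    difference vectors are degenerate (the t statistic is undefined) and are
    excluded with a log message.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 tumor/normal pairs")
    t_cols = [t for t, _ in pairs]
    n_cols = [n for _, n in pairs]
    d = catalog.degrees.fillna(0.0)
    diffs = d[t_cols].to_numpy() - d[n_cols].to_numpy()
    present = ((d[t_cols] > 0) | (d[n_cols].to_numpy() > 0)).sum(axis=1) > 0
    rows = []
    for i, sid in enumerate(d.index):
        if not present.iloc[i]:
            continue
        x = diffs[i]
        if np.allclose(x, x[0]):
            log.info("dys screen: %s excluded (zero-variance pair differences)", sid)
            continue
        t_stat, p = stats.ttest_rel(d[t_cols].iloc[i], d[n_cols].iloc[i])
        mean_diff = float(x.mean())
        direction = "hyper" if mean_diff > 0 else "hypo"
        sign = 1.0 if mean_diff > 0 else -1.0
        n_shift = int(((np.abs(x) > min_shift) & (np.sign(x) == sign)).sum())
        rows.append((sid, float(t_stat), float(p), mean_diff, direction, n_shift))
    out = pd.DataFrame(rows, columns=["site_id", "t_stat", "t_p", "mean_diff",
                                      "direction", "n_shifted_pairs"]
                       ).set_index("site_id")
    if len(out):
        out["t_p_adj"] = multipletests(out["t_p"], method="fdr_bh")[1]
    else:
        out["t_p_adj"] = pd.Series(dtype=float)
    called = (out["t_p_adj"] < adj_alpha) & (out["n_shifted_pairs"] >= min_shifted_pairs)
    if require_raw:
        called &= out["t_p"] < raw_alpha
    out["is_dys"] = called
    return out


def classify_differential(catalog: SiteCatalog, pairs: list[tuple[str, str]] | None,
                          **kwargs) -> pd.DataFrame:
    """Combined differential call table (one row per catalog site).

    The Fisher screen covers the whole cohort; the dys screen runs on the
    paired subcohort when pairs exist.  A site called by both keeps the
    Fisher label and the dys columns (the classes describe different
    contrasts and the paper counts them separately).
    """
    fisher = fisher_gain_loss(catalog)
    out = fisher.copy()
    out["dys"] = False
    out["dys_direction"] = ""
    out["dys_p"] = np.nan
    out["dys_p_adj"] = np.nan
    if pairs:
        dys = paired_dys_edit(catalog, pairs, **kwargs)
        idx = dys.index.intersection(out.index)
        out.loc[idx, "dys"] = dys.loc[idx, "is_dys"]
        out.loc[idx, "dys_direction"] = dys.loc[idx, "direction"]
        out.loc[idx, "dys_p"] = dys.loc[idx, "t_p"]
        out.loc[idx, "dys_p_adj"] = dys.loc[idx, "t_p_adj"]
    out["hcc_related"] = (out["cls"] != "none") | out["dys"]
    # disjoint accounting: gain/loss keep their Fisher label; dys only counts
    # sites not already called by the cohort-wide screen
    hcc_class = out["cls"].copy()
    hcc_class[(hcc_class == "none") & out["dys"]] = "dys"
    out["hcc_class"] = hcc_class
    return out


def enrich_gene_sets(query_genes: set[str], collections: dict[str, set[str]],
                     universe: set[str], alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each gene set.

    The universe is the set of genes carrying any surviving editing site; gene
    sets are clipped to it.  Upper-tail p-values are BH-corrected across the
    collection; ``significant`` marks adjusted p < ``alpha``.
    """
    if not universe:
        raise ValueError("empty gene universe")
    query = query_genes & universe
    rows = []
    for name, members in collections.items():
        term = members & universe
        if not term:
            continue
        overlap = len(query & term)
        # P(X >= overlap), X ~ Hypergeom(|universe|, |term|, |query|)
        p = stats.hypergeom.sf(overlap - 1, len(universe), len(term), len(query))
        rows.append((name, len(term), overlap, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"]
                       ).set_index("term")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
        out = out.sort_values("p")
    return out
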