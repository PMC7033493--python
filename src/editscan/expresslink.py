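"""Expression normalization and editing-degree/expression correlation.

Raw counts are normalized with median-of-ratios size factors: for each sample,
the factor is the median over genes (non-zero in every sample) of that
sample's count divided by the gene's geometric mean across samples.  Each
editing site is then tested for a Pearson correlation between its editing
degree and the normalized expression of its host gene, over the samples where
the site is actually edited (degree > 0) and expression is measured; p-values
come from the t transform and are BH-corrected across all tested sites.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = ["size_factors", "normalize_counts", "correlate_editing_expression"]


def size_factors(counts: pd.DataFrame, allow_pseudo_reference: bool = False,
                 ) -> pd.Series:
    """Median-of-ratios size factors (one per sample, all > 0).

    Genes with a zero count in any sample are excluded from the reference.
    With none left, the default is a hard error; ``allow_pseudo_reference``
    instead falls back to per-sample medians over that sample's non-zero
    genes.
    """
    x = counts.to_numpy(dtype=float)
    nonzero = (x > 0).all(axis=1)
    if not nonzero.any():
        if not allow_pseudo_reference:
            raise ValueError(
                "no gene has non-zero counts in every sample; re-run with "
                "allow_pseudo_reference=True to use a per-sample fallback")
        logx = np.full(x.shape, np.nan)
        np.log(x, out=logx, where=x > 0)
        ref = np.nanmean(logx, axis=1)
        ratios = logx - ref[:, None]
        factors = np.exp(np.nanmedian(ratios, axis=0))
    else:
        xr = x[nonzero]
        log_geomean = np.log(xr).mean(axis=1)
        ratios = np.log(xr) - log_geomean[:, None]
        factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(counts: pd.DataFrame, factors: pd.Series | None = None,
                     log2: bool = False, **kwargs) -> pd.DataFrame:
    """Counts divided by their size factors (optionally log2(x+1))."""
    if factors is None:
        factors = size_factors(counts, **kwargs)
    out = counts / factors
    return np.log2(out + 1.0) if log2 else out


def correlate_editing_expression(degrees: pd.DataFrame, expression: pd.DataFrame,
                                 site_gene: pd.Series, min_samples: int = 3,
                                 alpha: float = 0.05) -> pd.DataFrame:
    """Per-site Pearson correlation between editing degree and the normalized
    expression of the site's gene.

    ``degrees`` is site x sample (NaN/0 = unedited), ``expression`` is
    gene x sample (already normalized), ``site_gene`` maps site id -> gene id.
    Sites with fewer than ``min_samples`` edited samples, an unannotated or
    unmeasured gene, or a constant vector (undefined r) are skipped with a
    log message.
    """
    rows = []
    d = degrees.fillna(0.0)
    for sid, gene in site_gene.items():
        if not gene or gene not in expression.index or sid not in d.index:
            continue
        deg = d.loc[sid]
        expr = expression.loc[gene].reindex(deg.index)
        mask = (deg > 0) & expr.notna()
        n = int(mask.sum())
        if n < min_samples:
            continue
        x = deg[mask].to_numpy(dtype=float)
        y = expr[mask].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            log.info("correlation skipped at %s: constant degree or expression", sid)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((sid, gene, n, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["site_id", "gene_id", "n", "r", "p"]
                       ).set_index("site_id")
    if len(out):
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = out["p_adj"] < alpha
    else:
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
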