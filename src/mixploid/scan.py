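"""Diversity-versus-differentiation selection scan.

Genes that are more differentiated between a diploid and a tetraploid
lineage than their within-population diversity predicts are candidates for
positive selection in the tetraploid (e.g. introgressed meiosis alleles
sweeping after whole-genome duplication).  The scan regresses per-gene dxy
on per-gene pi (ordinary least squares with intercept) and flags genes whose
residual exceeds an upper empirical quantile.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from mixploid import popgen
from mixploid.io import GenotypeMatrix, to_halfopen

logger = logging.getLogger("mixploid")


def per_gene_stats(gm: GenotypeMatrix, focal_samples, contrast_samples,
                   genes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene pi (within the focal population) and dxy (focal vs contrast).

    ``genes``: gene_id, chrom, start, end in GFF coordinates (1-based
    closed).  Genes with no usable site keep an NA row.
    """
    windows = genes[["gene_id", "chrom", "start", "end"]].copy()
    half = [to_halfopen(s, e) for s, e in zip(windows["start"], windows["end"])]
    windows["start"] = [h[0] for h in half]
    windows["end"] = [h[1] for h in half]
    pi_df = popgen.pi(gm, focal_samples, windows)
    dxy_df = popgen.dxy(gm, focal_samples, contrast_samples, windows)
    return pd.DataFrame({"gene_id": genes["gene_id"].to_numpy(),
                         "pi": pi_df["value"].to_numpy(),
                         "dxy": dxy_df["value"].to_numpy(),
                         "n_sites_pi": pi_df["n_sites_used"].to_numpy(),
                         "n_sites_dxy": dxy_df["n_sites_used"].to_numpy()})


def residual_outliers(gene_table: pd.DataFrame, quantile: float = 0.99) -> pd.DataFrame:
    """OLS fit dxy ~ pi over genes with both statistics defined; flag genes
    whose residual exceeds the empirical ``quantile`` of residuals.

    Returns the table with ``residual`` and ``outlier`` columns; NA genes
    keep NaN residuals and are never flagged.  Fewer than 10 usable genes is
    an error; zero pi variance degrades to an intercept-only fit (warning).
    """
    table = gene_table.copy()
    ok = table["pi"].notna() & table["dxy"].notna()
    if int(ok.sum()) < 10:
        raise ValueError(f"only {int(ok.sum())} genes with defined pi and dxy; "
                         "need >= 10")
    x = table.loc[ok, "pi"].to_numpy(float)
    y = table.loc[ok, "dxy"].to_numpy(float)
    if np.ptp(x) == 0.0:
        warnings.warn("zero variance in pi; intercept-only fit", stacklevel=2)
        fitted = np.full_like(y, y.mean())
    else:
        slope, intercept = np.polyfit(x, y, 1)
        fitted = intercept + slope * x
    resid = y - fitted
    cutoff = float(np.quantile(resid, quantile))
    table["residual"] = np.nan
    table.loc[ok, "residual"] = resid
    table["outlier"] = False
    table.loc[ok, "outlier"] = resid > cutoff
    return table


def overlap_report(gene_table: pd.DataFrame, introgression_genes) -> dict:
    """Overlap between residual outliers and introgression-window genes.

    Returns counts, the identities in each cell of the 2x2 table, and a
    one-sided hypergeometric enrichment p-value (an interpretability
    extra — the raw overlap is the primary output).
    """
    universe = list(gene_table["gene_id"])
    outliers = set(gene_table.loc[gene_table.get("outlier", False) == True,  # noqa: E712
                                  "gene_id"])
    intro = set(introgression_genes) & set(universe)
    both = sorted(outliers & intro)
    m_total, k_out, k_in, k_both = len(universe), len(outliers), len(intro), len(both)
    # P(X >= k_both) for X ~ Hypergeom(M=m_total, n=k_out, N=k_in)
    pval = float(stats.hypergeom.sf(k_both - 1, m_total, k_out, k_in)) \
        if k_out and k_in else 1.0
    return {"n_genes": m_total,
            "n_outliers": k_out,
            "n_introgressed": k_in,
            "n_both": k_both,
            "both": both,
            "outlier_only": sorted(outliers - intro),
            "introgressed_only": sorted(intro - outliers),
            "hypergeom_p": pval}
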