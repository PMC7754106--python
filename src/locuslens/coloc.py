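"""GWAS-eQTL locus-compare tables and P-value correlation.

For each gene x eQTL dataset the GWAS and eQTL associations inside a locus
window are joined on variant id and both P values are put on the -log10
scale (the scale of a locus-compare scatter). A table is *eligible* — i.e.
would have been plotted — only if it contains the locus risk variant or a
good proxy (r2 > 0.7) for it. The Pearson correlation of the two -log10 P
columns, computed when enough shared variants are present, feeds the
QTL-correl evidence bit (|r| > 0.3 by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PAIR_COLUMNS = ["variant_id", "pos", "neglog10p_gwas", "neglog10p_qtl"]


@dataclass(frozen=True)
class ColocResult:
    """Locus-compare summary for one gene x dataset.

    ``pearson_r`` is None when the table is ineligible, too small, or has a
    zero-variance column.
    """

    gene: str
    dataset: str
    n_shared: int
    eligible: bool
    pearson_r: float | None


def locuscompare_table(gwas_region: pd.DataFrame, eqtl: pd.DataFrame) -> pd.DataFrame:
    """Pair GWAS and eQTL -log10 P values over shared variants.

    ``gwas_region`` carries ``variant_id``, ``pos``, ``p``; ``eqtl`` carries
    ``variant_id``, ``p`` for a single gene x dataset. Duplicate eQTL rows
    for one variant (e.g. several isoforms) collapse to the smallest P with
    a warning. Output is ordered by position.
    """
    if len(eqtl) and eqtl["variant_id"].duplicated().any():
        n_dup = int(eqtl["variant_id"].duplicated().sum())
        logger.warning("collapsing %d duplicate eQTL row(s) to the minimum P per variant", n_dup)
        eqtl = eqtl.sort_values("p", kind="mergesort").drop_duplicates(subset="variant_id")
    merged = gwas_region.merge(
        eqtl[["variant_id", "p"]].rename(columns={"p": "p_qtl"}), on="variant_id", how="inner"
    )
    out = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "pos": merged["pos"],
            "neglog10p_gwas": -np.log10(merged["p"]),
            "neglog10p_qtl": -np.log10(merged["p_qtl"]),
        }
    )
    return out.sort_values("pos", kind="mergesort").reset_index(drop=True)


def plot_eligible(pairs: pd.DataFrame, risk_variant: str, proxies) -> bool:
    """Would this locus-compare table have been plotted?

    True iff the paired table contains the locus risk variant or at least
    one of its proxies; tables with neither are omitted.
    """
    present = set(pairs["variant_id"]) if len(pairs) else set()
    if risk_variant in present:
        return True
    return any(p in present for p in proxies)


def gwas_qtl_correlation(
    pairs: pd.DataFrame, min_variants: int = 10, scale: str = "neglog10"
) -> float | None:
    """Pearson correlation of GWAS vs eQTL significance over shared variants.

    Computed on the -log10 P scale by default (the plotted axes); ``scale=
    "raw"`` correlates raw P values instead. Returns None when fewer than
    ``min_variants`` shared variants exist or either column has zero
    variance.
    """
    if min_variants < 3:
        raise ValueError("min_variants must be at least 3")
    if len(pairs) < min_variants:
        return None
    if scale == "neglog10":
        x = pairs["neglog10p_gwas"].to_numpy(dtype=float)
        y = pairs["neglog10p_qtl"].to_numpy(dtype=float)
    elif scale == "raw":
        x = np.power(10.0, -pairs["neglog10p_gwas"].to_numpy(dtype=float))
        y = np.power(10.0, -pairs["neglog10p_qtl"].to_numpy(dtype=float))
    else:
        raise ValueError(f"unknown correlation scale {scale!r}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero variance in a locus-compare column; correlation undefined")
        return None
    r = float(stats.pearsonr(x, y).statistic)
    return r


def compute_coloc(
    gene: str,
    dataset: str,
    gwas_region: pd.DataFrame,
    eqtl: pd.DataFrame,
    risk_variant: str,
    proxies,
    min_variants: int = 10,
    scale: str = "neglog10",
) -> ColocResult:
    """Full locus-compare evaluation for one gene x dataset.

    The correlation is only computed for eligible tables, so ``pearson_r``
    present implies eligibility and a sufficient shared-variant count.
    """
    pairs = locuscompare_table(gwas_region, eqtl)
    eligible = plot_eligible(pairs, risk_variant, proxies)
    r = gwas_qtl_correlation(pairs, min_variants=min_variants, scale=scale) if eligible else None
    return ColocResult(
        gene=gene, dataset=dataset, n_shared=len(pairs), eligible=eligible, pearson_r=r
    )


def plot_locuscompare(pairs: pd.DataFrame, path, title: str = "") -> None:
    """Render a locus-compare scatter to PNG/SVG (convenience only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(pairs["neglog10p_qtl"], pairs["neglog10p_gwas"], s=12, alpha=0.7)
    ax.set_xlabel(r"eQTL $-\log_{10} P$")
    ax.set_ylabel(r"GWAS $-\log_{10} P$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
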