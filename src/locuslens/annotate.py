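"""Risk-variant annotation: coding variants in LD and phenotype overlaps.

Coding-variant deleteriousness (CADD) and allele frequencies are passthrough
input columns; this module adds the LD of each annotated variant with the
locus risk variant and filters GWAS-catalog associations to those in strong
LD (r2 > 0.8 and D' > 0.9 by default, both strict).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .ld import GenotypePanel, LDUndefinedError, em_haplotypes

logger = logging.getLogger(__name__)


def _ld_vs_risk(risk: str, variant_ids, panel: GenotypePanel):
    """r2/D' of each variant against the risk variant; NaN when unavailable."""
    ga = panel.dosage(risk)
    r2 = np.full(len(variant_ids), np.nan)
    dprime = np.full(len(variant_ids), np.nan)
    for i, vid in enumerate(variant_ids):
        if vid not in panel:
            logger.warning("variant %s absent from panel; LD left blank", vid)
            continue
        try:
            stats = em_haplotypes(ga, panel.dosage(vid))
        except LDUndefinedError as exc:
            logger.warning("LD undefined for %s vs %s: %s", vid, risk, exc)
            continue
        r2[i] = stats.r2
        dprime[i] = stats.d_prime
    return r2, dprime


def annotate_coding(
    risk: str,
    coding: pd.DataFrame,
    panel: GenotypePanel,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Attach LD-with-risk to coding variants in the locus window.

    ``coding`` columns: variant_id, gene, hgvs, cadd, af. Variants absent
    from the panel keep their row with blank LD and a logged warning. Rows
    are sorted by descending r2 (blank LD last), then variant id.
    """
    idx = panel.index_of(risk)
    chrom, pos = str(panel.chrom[idx]), int(panel.pos[idx])
    lo, hi = max(1, pos - window), pos + window
    in_window = []
    for vid in coding["variant_id"]:
        if vid in panel:
            j = panel.index_of(vid)
            in_window.append(str(panel.chrom[j]) == chrom and lo <= int(panel.pos[j]) <= hi)
        else:
            in_window.append(True)  # cannot place it; keep and flag below
    out = coding[np.asarray(in_window, dtype=bool)].copy().reset_index(drop=True)
    r2, dprime = _ld_vs_risk(risk, list(out["variant_id"]), panel)
    out["r2"] = r2
    out["d_prime"] = dprime
    out = out.sort_values(
        ["r2", "variant_id"], ascending=[False, True], kind="mergesort", na_position="last"
    ).reset_index(drop=True)
    return out


def catalog_overlap(
    risk: str,
    catalog: pd.DataFrame,
    panel: GenotypePanel,
    r2_min: float = 0.8,
    dprime_min: float = 0.9,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """GWAS-catalog associations tagging the same signal as the risk variant.

    Returns one row per (variant, trait) for catalog variants in the locus
    window with r2 strictly above ``r2_min`` and D' strictly above
    ``dprime_min`` against the risk variant.
    """
    idx = panel.index_of(risk)
    chrom, pos = str(panel.chrom[idx]), int(panel.pos[idx])
    lo, hi = max(1, pos - window), pos + window
    unique = catalog.drop_duplicates(subset=["variant_id", "trait"]).reset_index(drop=True)
    keep_rows = []
    cache: dict[str, tuple[float, float]] = {}
    for _, row in unique.iterrows():
        vid = row["variant_id"]
        if vid not in cache:
            if vid not in panel:
                cache[vid] = (np.nan, np.nan)
            else:
                j = panel.index_of(vid)
                if str(panel.chrom[j]) != chrom or not (lo <= int(panel.pos[j]) <= hi):
                    cache[vid] = (np.nan, np.nan)
                else:
                    try:
                        stats = em_haplotypes(panel.dosage(risk), panel.dosage(vid))
                        cache[vid] = (stats.r2, stats.d_prime)
                    except LDUndefinedError:
                        cache[vid] = (np.nan, np.nan)
        r2, dp = cache[vid]
        if not np.isnan(r2) and r2 > r2_min and dp > dprime_min:
            keep_rows.append(
                {"trait": row["trait"], "variant_id": vid, "r2": r2, "d_prime": dp}
            )
    out = pd.DataFrame(keep_rows, columns=["trait", "variant_id", "r2", "d_prime"])
    return out.sort_values(["variant_id", "trait"], kind="mergesort").reset_index(drop=True)
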