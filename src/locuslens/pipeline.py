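"""End-to-end orchestration: loci -> windows -> coloc -> evidence -> ranking.

This is the library face of the ``score`` subcommand: given loaded input
tables it walks every locus, restricts GWAS and eQTL data to the locus
window, finds proxies of each lead in the reference panel (when one is
supplied), derives the evidence bits and ranks genes by conclusion score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .coloc import ColocResult, compute_coloc
from .evidence import EvidenceInputs, Thresholds, assemble_evidence
from .io_formats import EQTL_DATASETS, GeneFlagSets
from .ld import GenotypePanel, find_proxies
from .partition import Locus, genes_in_window
from .scoring import WeightConfig, rank_genes

logger = logging.getLogger(__name__)


@dataclass
class ScoreBundle:
    """All loaded inputs the scoring stage needs."""

    sumstats: pd.DataFrame
    genes: pd.DataFrame
    eqtl: dict[str, pd.DataFrame]  # dataset -> table
    expression: pd.DataFrame
    constraint: pd.DataFrame
    burden: pd.DataFrame
    flags: GeneFlagSets
    literature: pd.DataFrame
    panel: GenotypePanel | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    weights: WeightConfig = field(default_factory=WeightConfig)
    min_variants: int = 10
    proxy_r2: float = 0.7


def locus_proxies(locus: Locus, panel: GenotypePanel | None, r2_min: float = 0.7) -> list[str]:
    """Union of proxy variant ids over the locus leads (empty without panel)."""
    if panel is None:
        return []
    out: list[str] = []
    for lead in locus.lead_variants:
        if lead.variant_id not in panel:
            logger.warning("lead %s absent from panel; no proxies for it", lead.variant_id)
            continue
        for vid, _ in find_proxies(lead.variant_id, panel, r2_min=r2_min):
            if vid not in out:
                out.append(vid)
    return out


def score_locus(locus: Locus, bundle: ScoreBundle) -> pd.DataFrame:
    """Ranked evidence table for one locus."""
    genes = genes_in_window(locus.lead_variants, bundle.genes)
    known = set(bundle.genes["symbol"])
    gwas_region = bundle.sumstats[
        (bundle.sumstats["chrom"].astype(str) == str(locus.chrom))
        & (bundle.sumstats["pos"] >= locus.start)
        & (bundle.sumstats["pos"] <= locus.end)
    ]
    risk = locus.lead_variants[0].variant_id
    proxies = locus_proxies(locus, bundle.panel, bundle.proxy_r2)

    coloc: dict[str, list[ColocResult]] = {}
    region_ids = set(gwas_region["variant_id"])
    for dataset in EQTL_DATASETS:
        table = bundle.eqtl.get(dataset)
        if table is None or len(table) == 0:
            continue
        in_region = table[table["variant_id"].isin(region_ids)]
        for gene_symbol in genes["symbol"]:
            sub = in_region[in_region["gene"] == gene_symbol]
            if len(sub) == 0:
                continue
            coloc.setdefault(gene_symbol, []).append(
                compute_coloc(
                    gene_symbol,
                    dataset,
                    gwas_region,
                    sub,
                    risk_variant=risk,
                    proxies=proxies,
                    min_variants=bundle.min_variants,
                )
            )

    for table in (bundle.expression, bundle.constraint, bundle.burden, bundle.literature):
        stray = set(table["gene"]) - known if "gene" in table.columns else set()
        if stray:
            logger.warning("%d gene symbol(s) in an input table missing from the annotation", len(stray))

    inputs = EvidenceInputs(
        expression=bundle.expression,
        coloc=coloc,
        literature=bundle.literature,
        constraint=bundle.constraint,
        burden=bundle.burden,
        flags=bundle.flags,
    )
    table = assemble_evidence(locus, genes, inputs, bundle.thresholds, bundle.weights)
    return rank_genes(table, bundle.weights)


def score_loci(loci: list[Locus], bundle: ScoreBundle) -> dict[int, pd.DataFrame]:
    """Ranked evidence tables keyed by locus id."""
    out = {}
    for locus in loci:
        table = score_locus(locus, bundle)
        table["locus_id"] = locus.locus_id
        out[locus.locus_id] = table
    return out
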