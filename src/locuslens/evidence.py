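"""Per-gene evidence bits.

Each data source is reduced to a 0/1 flag per gene (NA where the source has
no data for the gene at all):

=================== ========================================================
brain/nigra/dan     mean TPM strictly above the cutoff (default 5) in GTEx
                    brain, substantia nigra, or SN dopaminergic neurons;
                    all three NA when the gene has no expression data
qtl_brain/qtl_blood an eligible locus-compare table exists for a brain
                    (eQTL or isoQTL) / blood dataset
qtl_correl          some eligible table has |Pearson r| strictly above the
                    cutoff (default 0.3); NA when no eligible table exists
literature          at least 5 PubMed hits for "GENE AND Parkinson's"
variant_intolerant  gnomAD 90% CI upper bound of any o/e ratio strictly
                    below 0.35; NA when the gene has no constraint record
burden              minimum burden P below alpha / n_genes (Bonferroni,
                    exome or imputed family); NA without burden data
nominated/pd/disease gene-set membership flags (0/1, never NA)
=================== ========================================================
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coloc import ColocResult
from .io_formats import EVIDENCE_COLUMNS, GeneFlagSets

NA_ALLOWED_COLUMNS = frozenset(
    {"brain_expr", "nigra_expr", "dan_expr", "qtl_correl", "variant_intolerant", "burden"}
)

_BRAIN_DATASETS = ("brain_eqtl", "brain_isoqtl")

#: query templates used for the literature counts (emitted for reproducibility)
PD_QUERY_TEMPLATE = "{gene}[Title/Abstract] AND Parkinson's[Title/Abstract]"
GENE_QUERY_TEMPLATE = "{gene}[Title/Abstract]"


@dataclass(frozen=True)
class Thresholds:
    """Evidence cutoffs with the browser defaults."""

    tpm_cutoff: float = 5.0
    correl_cutoff: float = 0.3
    lit_min_hits: int = 5
    oe_upper_max: float = 0.35
    alpha: float = 0.05

    def __post_init__(self):
        for name in ("tpm_cutoff", "correl_cutoff", "lit_min_hits", "oe_upper_max", "alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.correl_cutoff >= 1:
            raise ValueError("correl_cutoff must be below 1")


def expression_bits(gene: str, expr: pd.DataFrame, t: Thresholds | None = None):
    """(brain, nigra, dan) expression bits for one gene.

    1 iff mean TPM strictly exceeds the cutoff in that context. A gene with
    no expression records at all is NA in all three columns; a gene with
    records but no value for one of the scored contexts is NA in that
    context only.
    """
    t = t or Thresholds()
    rows = expr[expr["gene"] == gene]
    if len(rows) == 0:
        return (None, None, None)
    by_context = dict(zip(rows["context"], rows["mean_tpm"]))
    out = []
    for ctx in ("brain", "nigra", "dan"):
        if ctx in by_context:
            out.append(int(by_context[ctx] > t.tpm_cutoff))
        else:
            out.append(None)
    return tuple(out)


def qtl_bits(coloc: list[ColocResult], t: Thresholds | None = None):
    """(qtl_brain, qtl_blood, qtl_correl) from a gene's locus-compare results.

    qtl_brain is 1 iff any brain eQTL or isoQTL table is eligible; qtl_blood
    likewise for blood. qtl_correl is NA when neither flag is set, else 1 iff
    any eligible table has |r| strictly above the cutoff.
    """
    t = t or Thresholds()
    qtl_brain = int(any(c.eligible for c in coloc if c.dataset in _BRAIN_DATASETS))
    qtl_blood = int(any(c.eligible for c in coloc if c.dataset == "blood_eqtl"))
    if qtl_brain == 0 and qtl_blood == 0:
        return (0, 0, None)
    hit = any(
        c.eligible and c.pearson_r is not None and abs(c.pearson_r) > t.correl_cutoff
        for c in coloc
    )
    return (qtl_brain, qtl_blood, int(hit))


def literature_bit(n_hits: int, t: Thresholds | None = None) -> int:
    """1 iff the PD literature search returned at least ``lit_min_hits``."""
    t = t or Thresholds()
    if n_hits < 0 or (isinstance(n_hits, float) and math.isnan(n_hits)):
        raise ValueError("literature hit count must be a non-negative integer")
    return int(n_hits >= t.lit_min_hits)


def build_queries(gene: str) -> tuple[str, str]:
    """The exact PubMed query strings behind the literature counts."""
    return (PD_QUERY_TEMPLATE.format(gene=gene), GENE_QUERY_TEMPLATE.format(gene=gene))


def constraint_bit(rec, t: Thresholds | None = None):
    """1 iff the 90% CI upper bound of any o/e class is strictly below 0.35.

    ``rec`` is a mapping/Series with ``ci90_upper_syn/mis/lof`` (NaN allowed),
    or None when the gene has no constraint record (-> NA).
    """
    t = t or Thresholds()
    if rec is None:
        return None
    uppers = [rec.get(k) for k in ("ci90_upper_syn", "ci90_upper_mis", "ci90_upper_lof")]
    uppers = [u for u in uppers if u is not None and not pd.isna(u)]
    if not uppers:
        return None
    return int(min(uppers) < t.oe_upper_max)


def burden_bit(rec, n_exome_genes: int, n_imputed_genes: int, t: Thresholds | None = None):
    """Bonferroni-significant rare-variant burden in either test family.

    1 iff min exome P < alpha / n_exome_genes or min imputed P < alpha /
    n_imputed_genes; NA when the gene has no burden record (or both minima
    are missing — absent gene and absent value are treated identically).
    """
    t = t or Thresholds()
    if n_exome_genes < 1 or n_imputed_genes < 1:
        raise ValueError("burden gene counts must be at least 1")
    if rec is None:
        return None
    p_ex = rec.get("min_p_exome")
    p_im = rec.get("min_p_imputed")
    p_ex = None if p_ex is None or pd.isna(p_ex) else float(p_ex)
    p_im = None if p_im is None or pd.isna(p_im) else float(p_im)
    if p_ex is None and p_im is None:
        return None
    hit = (p_ex is not None and p_ex < t.alpha / n_exome_genes) or (
        p_im is not None and p_im < t.alpha / n_imputed_genes
    )
    return int(hit)


def flag_bits(gene: str, flags: GeneFlagSets):
    """(nominated_meta5, pd_gene, disease_gene) membership flags."""
    g = gene.strip().upper()
    return (
        int(g in flags.nominated_meta5),
        int(g in flags.pd_genes),
        int(g in flags.disease_genes),
    )


@dataclass
class EvidenceInputs:
    """All per-gene data sources needed to assemble an evidence table."""

    expression: pd.DataFrame
    coloc: dict[str, list[ColocResult]]  # gene -> results across datasets
    literature: pd.DataFrame
    constraint: pd.DataFrame
    burden: pd.DataFrame
    flags: GeneFlagSets
    n_exome_genes: int | None = None
    n_imputed_genes: int | None = None

    def burden_denominators(self) -> tuple[int, int]:
        """Bonferroni denominators: explicit metadata or genes-with-data."""
        n_ex = self.n_exome_genes
        n_im = self.n_imputed_genes
        if n_ex is None:
            n_ex = max(1, int(self.burden["min_p_exome"].notna().sum()))
        if n_im is None:
            n_im = max(1, int(self.burden["min_p_imputed"].notna().sum()))
        return n_ex, n_im


def _row_lookup(df: pd.DataFrame, gene: str):
    rows = df[df["gene"] == gene]
    return None if len(rows) == 0 else rows.iloc[0]


def assemble_evidence(
    locus,
    genes: pd.DataFrame,
    inputs: EvidenceInputs,
    t: Thresholds | None = None,
    weights=None,
) -> pd.DataFrame:
    """One evidence row per gene in the locus window, with conclusion score.

    ``genes`` is the (already windowed) gene table for the locus; duplicated
    symbols are an error. Bits are nullable integers (pandas ``Int64``); the
    conclusion column is the weighted sum with NA contributing 0.
    """
    from .scoring import WeightConfig, conclusion_score

    t = t or Thresholds()
    weights = weights or WeightConfig()
    symbols = list(genes["symbol"]) if len(genes) else []
    if len(set(symbols)) != len(symbols):
        dupes = sorted({s for s in symbols if symbols.count(s) > 1})
        raise ValueError(f"duplicated gene symbol(s) within locus: {dupes}")
    n_ex, n_im = inputs.burden_denominators()
    rows = []
    for gene in symbols:
        brain, nigra, dan = expression_bits(gene, inputs.expression, t)
        qb, ql, qc = qtl_bits(inputs.coloc.get(gene, []), t)
        lit_row = _row_lookup(inputs.literature, gene)
        lit = literature_bit(int(lit_row["n_hits_pd"]), t) if lit_row is not None else 0
        vi = constraint_bit(_row_lookup(inputs.constraint, gene), t)
        bur = burden_bit(_row_lookup(inputs.burden, gene), n_ex, n_im, t)
        nom, pdg, dis = flag_bits(gene, inputs.flags)
        bits = {
            "brain_expr": brain,
            "nigra_expr": nigra,
            "dan_expr": dan,
            "qtl_brain": qb,
            "qtl_blood": ql,
            "qtl_correl": qc,
            "literature": lit,
            "variant_intolerant": vi,
            "burden": bur,
            "nominated_meta5": nom,
            "pd_gene": pdg,
            "disease_gene": dis,
        }
        rows.append({"gene": gene, **bits, "conclusion": conclusion_score(bits, weights)})
    df = pd.DataFrame(rows, columns=["gene", *EVIDENCE_COLUMNS, "conclusion"])
    if len(df) == 0:
        df = pd.DataFrame(columns=["gene", *EVIDENCE_COLUMNS, "conclusion"])
    for col in EVIDENCE_COLUMNS:
        df[col] = pd.array(df[col] if len(df) else [], dtype="Int64")
    if getattr(locus, "locus_id", None) is not None:
        df["locus_id"] = locus.locus_id
    return df
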