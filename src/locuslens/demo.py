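"""Synthetic reconstructions of the browser's two published worked examples.

The PD GWAS locus browser's results include two use cases: *P2RY12* at locus
16 (risk variant rs11707416; OR 0.94, SE 0.0097, P = 1.13e-10) and *DYRK1A*
at locus 78 (rs2248244; OR 1.074, SE 0.0107, P = 2.74e-11). The consortium
tables behind those loci are not redistributable, so this module builds
small synthetic input bundles that encode exactly the facts stated for each
use case — which expression contexts clear the 5-TPM cutoff, which
locus-compare tables exist and correlate, the gene-set memberships, the
constraint and burden outcomes — and lets the real pipeline derive every
evidence bit and the conclusion score from them.

The regional association profiles are synthetic (seeded LD-decay shapes
around the printed risk-variant P value); the derived bits and scores are
computed, not asserted.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coloc import compute_coloc
from .evidence import EvidenceInputs, Thresholds, assemble_evidence
from .io_formats import GeneFlagSets
from .partition import PartitionConfig, partition_loci
from .scoring import WeightConfig, rank_genes

#: Bonferroni denominators of the browser's burden tables (genes with data).
N_EXOME_GENES = 1480
N_IMPUTED_GENES = 1026


def _regional_profile(
    rng: np.random.Generator,
    chrom: str,
    risk_id: str,
    risk_pos: int,
    risk_p: float,
    risk_beta: float,
    risk_se: float,
    n_variants: int = 60,
    halfwidth: int = 400_000,
) -> pd.DataFrame:
    """A GWAS signal around a risk variant with the printed statistics.

    The -log10 P profile peaks at the risk variant and decays with distance
    (an LD-decay stand-in) plus seeded noise; the risk variant itself keeps
    its published P exactly.
    """
    offsets = np.sort(rng.choice(np.arange(-halfwidth, halfwidth), n_variants - 1, replace=False))
    peak = -np.log10(risk_p)
    decay = peak * np.exp(-np.abs(offsets) / 150_000.0)
    noise = np.abs(rng.normal(0.0, 0.4, size=n_variants - 1))
    neglog = np.clip(decay + noise, 0.05, peak - 0.1)
    pos = np.concatenate([[risk_pos], risk_pos + offsets])
    nlp = np.concatenate([[peak], neglog])
    ids = [risk_id] + [f"{risk_id}_prox{i}" for i in range(n_variants - 1)]
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": chrom,
            "pos": pos.astype(np.int64),
            "allele_effect": "A",
            "allele_other": "G",
            "beta": risk_beta,
            "se": risk_se,
            "p": 10.0 ** (-nlp),
        }
    )
    return df.sort_values("pos", kind="mergesort").reset_index(drop=True)


def _correlated_eqtl(
    rng: np.random.Generator, gwas: pd.DataFrame, gene: str, dataset: str, rho: float = 0.9
) -> pd.DataFrame:
    """An eQTL table whose -log10 P profile tracks the GWAS profile."""
    x = -np.log10(gwas["p"].to_numpy())
    sd = x.std()
    noise = rng.normal(0.0, sd * np.sqrt(1.0 / rho**2 - 1.0), size=len(x))
    y = np.clip(0.8 * (x + noise), 0.02, None)
    return pd.DataFrame(
        {"gene": gene, "variant_id": gwas["variant_id"], "p": 10.0 ** (-y), "dataset": dataset}
    )


def _run_use_case(
    seed: int,
    gene: str,
    risk_id: str,
    chrom: str,
    risk_pos: int,
    risk_p: float,
    risk_beta: float,
    risk_se: float,
    expression_tpm: dict[str, float],
    eqtl_datasets: tuple[str, ...],
    n_hits_pd: int,
    constraint_row: dict | None,
    burden_row: dict | None,
    flags: GeneFlagSets,
    weights: WeightConfig | None = None,
):
    rng = np.random.default_rng(seed)
    sumstats = _regional_profile(rng, chrom, risk_id, risk_pos, risk_p, risk_beta, risk_se)
    loci = partition_loci(sumstats, PartitionConfig())
    if len(loci) != 1 or loci[0].lead_variants[0].variant_id != risk_id:
        raise RuntimeError("use-case region did not partition into one locus led by the risk variant")
    locus = loci[0]
    gwas_region = sumstats[(sumstats["pos"] >= locus.start) & (sumstats["pos"] <= locus.end)]

    coloc = []
    for dataset in eqtl_datasets:
        eqtl = _correlated_eqtl(rng, gwas_region, gene, dataset)
        coloc.append(
            compute_coloc(
                gene, dataset, gwas_region, eqtl, risk_variant=risk_id, proxies=[]
            )
        )

    genes = pd.DataFrame(
        {
            "symbol": [gene],
            "chrom": [chrom],
            "start": [risk_pos - 20_000],
            "end": [risk_pos + 30_000],
            "strand": ["+"],
        }
    )
    expression = pd.DataFrame(
        [(gene, ctx, tpm) for ctx, tpm in expression_tpm.items()],
        columns=["gene", "context", "mean_tpm"],
    )
    literature = pd.DataFrame({"gene": [gene], "n_hits_pd": [n_hits_pd], "n_hits_gene": [100]})
    constraint = (
        pd.DataFrame([{"gene": gene, **constraint_row}])
        if constraint_row is not None
        else pd.DataFrame(columns=["gene", "ci90_upper_syn", "ci90_upper_mis", "ci90_upper_lof"])
    )
    burden = (
        pd.DataFrame([{"gene": gene, **burden_row}])
        if burden_row is not None
        else pd.DataFrame(columns=["gene", "min_p_exome", "min_p_imputed"])
    )
    inputs = EvidenceInputs(
        expression=expression,
        coloc={gene: coloc},
        literature=literature,
        constraint=constraint,
        burden=burden,
        flags=flags,
        n_exome_genes=N_EXOME_GENES,
        n_imputed_genes=N_IMPUTED_GENES,
    )
    table = assemble_evidence(locus, genes, inputs, Thresholds(), weights)
    return rank_genes(table, weights), locus


def use_case_p2ry12(seed: int = 0, weights: WeightConfig | None = None):
    """Evidence row for P2RY12 at locus 16 (risk variant rs11707416).

    Facts encoded: expression above 5 TPM in brain, nigra and dopaminergic
    neurons (with the microglia/astrocyte enrichment the expression panel
    shows); eligible, correlated locus-compare tables in brain and blood
    eQTL; a Mendelian disease link (platelet-type bleeding disorder 8) but
    no PD-gene, META5, constraint or burden evidence; PD literature hits
    below 5. Returns (ranked evidence table, locus).
    """
    return _run_use_case(
        seed=seed,
        gene="P2RY12",
        risk_id="rs11707416",
        chrom="3",
        risk_pos=151_090_000,
        risk_p=1.13e-10,
        risk_beta=float(np.log(0.94)),
        risk_se=0.0097,
        expression_tpm={
            "brain": 12.0,
            "nigra": 18.0,
            "dan": 7.5,
            "microglia": 160.0,
            "astrocyte": 95.0,
        },
        eqtl_datasets=("brain_eqtl", "blood_eqtl"),
        n_hits_pd=0,
        constraint_row={
            "ci90_upper_syn": 1.25,
            "ci90_upper_mis": 1.05,
            "ci90_upper_lof": 0.97,
        },
        burden_row={"min_p_exome": 0.21, "min_p_imputed": 0.35},
        flags=GeneFlagSets.from_iterables(disease_genes=["P2RY12"]),
        weights=weights,
    )


def use_case_dyrk1a(seed: int = 0, weights: WeightConfig | None = None):
    """Evidence row for DYRK1A at locus 78 (risk variant rs2248244).

    Facts encoded: expression above 5 TPM in all three scored contexts;
    eligible, correlated locus-compare tables for brain eQTL, blood eQTL and
    brain isoQTL; strong loss-of-function constraint (pLI 1, low o/e upper
    bound); burden minima not Bonferroni-significant (1480 exome / 1026
    imputed genes); META5-nominated; MRD7 disease gene; at least 5 PD
    literature hits; not a monogenic PD gene. Returns (ranked evidence
    table, locus).
    """
    return _run_use_case(
        seed=seed,
        gene="DYRK1A",
        risk_id="rs2248244",
        chrom="21",
        risk_pos=38_852_000,
        risk_p=2.74e-11,
        risk_beta=float(np.log(1.074)),
        risk_se=0.0107,
        expression_tpm={"brain": 21.0, "nigra": 19.0, "dan": 16.0},
        eqtl_datasets=("brain_eqtl", "blood_eqtl", "brain_isoqtl"),
        n_hits_pd=23,
        constraint_row={
            "pli": 1.0,
            "ci90_upper_syn": 1.1,
            "ci90_upper_mis": 0.8,
            "ci90_upper_lof": 0.13,
        },
        burden_row={"min_p_exome": 0.004, "min_p_imputed": 0.02},
        flags=GeneFlagSets.from_iterables(
            nominated_meta5=["DYRK1A"], disease_genes=["DYRK1A"]
        ),
        weights=weights,
    )
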