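"""Seeded synthetic inputs with known ground truth.

The generator produces a complete, internally consistent input bundle at
desk scale so that every pipeline stage is testable without consortium
downloads:

* a diploid genotype panel whose haplotypes are drawn block-wise — within a
  block each variant copies the previous variant's allele with a fixed
  probability, planting analytically checkable LD (copy probability 1 forces
  r2 = 1 within a block; 0 gives independence);
* GWAS summary statistics simulated directly on the z-score scale:
  z(v) = r(v, causal) * effect_z + N(0, 1), with P from the two-sided normal
  tail, so the planted causal reaches genome-wide significance whenever
  effect_z is large enough;
* eQTL tables in which *colocalized* genes share the GWAS causal variant
  (their z profile is the GWAS profile plus noise) while *non-colocalized*
  genes get an independent causal variant in a different haplotype block.

All randomness flows from one integer seed through a single numpy
Generator, so identical seeds give identical bundles end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .io_formats import EXPRESSION_CONTEXTS
from .ld import GenotypePanel


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-study parameters (defaults are the standing conditions)."""

    seed: int = 0
    n_samples: int = 400
    n_variants: int = 100
    n_loci: int = 1
    block_size: int = 10
    copy_prob: float = 0.95
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_z: float = 8.0
    eqtl_noise: float = 1.0
    coloc_genes: int = 3
    non_coloc_genes: int = 3
    chrom: str = "1"
    locus_spacing: int = 10_000_000
    region_halfwidth: int = 900_000

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        for name in ("n_variants", "n_loci", "block_size", "coloc_genes", "non_coloc_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")
        if not (0.0 <= self.copy_prob <= 1.0):
            raise ValueError("copy_prob must be in [0, 1]")

    def locus_center(self, k: int) -> int:
        return (k + 1) * self.locus_spacing

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _variant_positions(cfg: SimConfig, rng: np.random.Generator, k: int) -> np.ndarray:
    center = cfg.locus_center(k)
    lo, hi = center - cfg.region_halfwidth, center + cfg.region_halfwidth
    pos = rng.choice(np.arange(lo, hi + 1), size=cfg.n_variants, replace=False)
    return np.sort(pos)


def simulate_panel(cfg: SimConfig) -> GenotypePanel:
    """Diploid panel with block-structured planted LD.

    Haplotypes (2 per sample) are drawn block by block: the first variant of
    a block is Bernoulli(maf), each later variant copies its left neighbour
    with probability ``copy_prob`` and is otherwise redrawn at its own MAF.
    Diploids pair consecutive haplotypes. The raw haplotype matrix is kept
    on the panel as ``haplotypes`` so tests can count ground-truth haplotype
    frequencies.
    """
    rng = cfg.rng()
    n_hap = 2 * cfg.n_samples
    all_ids: list[str] = []
    all_chrom: list[str] = []
    all_pos: list[int] = []
    hap_cols: list[np.ndarray] = []
    for k in range(cfg.n_loci):
        pos = _variant_positions(cfg, rng, k)
        mafs = rng.uniform(*cfg.maf_range, size=cfg.n_variants)
        H = np.empty((n_hap, cfg.n_variants), dtype=np.int8)
        for j in range(cfg.n_variants):
            fresh = rng.random(n_hap) < mafs[j]
            if j % cfg.block_size == 0:
                H[:, j] = fresh
            else:
                copy = rng.random(n_hap) < cfg.copy_prob
                H[:, j] = np.where(copy, H[:, j - 1], fresh)
        hap_cols.append(H)
        all_ids.extend(f"rs{k}_{j}" for j in range(cfg.n_variants))
        all_chrom.extend([cfg.chrom] * cfg.n_variants)
        all_pos.extend(int(p) for p in pos)
    H = np.hstack(hap_cols)
    dosages = (H[0::2] + H[1::2]).astype(float)
    panel = GenotypePanel(
        variant_ids=all_ids,
        chrom=np.array(all_chrom, dtype=object),
        pos=np.array(all_pos, dtype=np.int64),
        dosages=dosages,
        samples=[f"S{i}" for i in range(cfg.n_samples)],
    )
    panel.haplotypes = H  # ground truth for tests
    return panel


def _causal_index(cfg: SimConfig, k: int) -> int:
    """GWAS causal variant of locus k: middle of a central block."""
    block = (cfg.n_variants // cfg.block_size) // 2
    return k * cfg.n_variants + block * cfg.block_size + cfg.block_size // 2


def _eqtl_causal_index(cfg: SimConfig, k: int) -> int:
    """Independent causal for non-colocalized genes: a different block."""
    n_blocks = max(1, cfg.n_variants // cfg.block_size)
    gwas_block = n_blocks // 2
    other_block = 0 if gwas_block != 0 else n_blocks - 1
    return k * cfg.n_variants + other_block * cfg.block_size + cfg.block_size // 2


def _dosage_correlations(panel: GenotypePanel, causal_idx: int, cols: np.ndarray) -> np.ndarray:
    """Pearson r between each dosage column and the causal column."""
    X = panel.dosages[:, cols]
    c = panel.dosages[:, causal_idx]
    c = c - c.mean()
    Xc = X - X.mean(axis=0)
    denom = np.sqrt((Xc**2).sum(axis=0) * (c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ c) / denom
    return np.nan_to_num(r, nan=0.0)


def _z_to_p(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_sumstats(cfg: SimConfig, panel: GenotypePanel) -> pd.DataFrame:
    """GWAS summary statistics over the panel's variants.

    Uses a derived stream (seed + 1) so the panel and the association noise
    are independent but jointly reproducible.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    z = np.empty(panel.n_variants)
    for k in range(cfg.n_loci):
        cols = np.arange(k * cfg.n_variants, (k + 1) * cfg.n_variants)
        r = _dosage_correlations(panel, _causal_index(cfg, k), cols)
        z[cols] = r * cfg.effect_z + rng.standard_normal(cfg.n_variants)
    p = _z_to_p(z)
    se = np.full(panel.n_variants, 0.01)
    df = pd.DataFrame(
        {
            "variant_id": panel.variant_ids,
            "chrom": [str(c) for c in panel.chrom],
            "pos": panel.pos,
            "allele_effect": "A",
            "allele_other": "G",
            "beta": z * se,
            "se": se,
            "p": p,
        }
    )
    return df


def simulate_eqtl(
    cfg: SimConfig, panel: GenotypePanel, sumstats: pd.DataFrame
) -> tuple[dict[str, pd.DataFrame], dict[str, str]]:
    """Per-dataset eQTL tables plus ground-truth colocalization labels.

    Every gene is measured at every locus variant in all three datasets.
    Colocalized genes reuse the GWAS z profile plus N(0, eqtl_noise) noise;
    non-colocalized genes get a fresh signal at an independent causal.
    Returns ({dataset: table}, {gene: "coloc" | "non_coloc"}).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    gwas_z = stats.norm.isf(sumstats["p"].to_numpy() / 2.0)  # |z| is all the profile needs
    datasets = {"brain_eqtl": [], "blood_eqtl": [], "brain_isoqtl": []}
    truth: dict[str, str] = {}
    for k in range(cfg.n_loci):
        cols = np.arange(k * cfg.n_variants, (k + 1) * cfg.n_variants)
        vids = [panel.variant_ids[i] for i in cols]
        r_indep = _dosage_correlations(panel, _eqtl_causal_index(cfg, k), cols)
        for g in range(cfg.coloc_genes + cfg.non_coloc_genes):
            is_coloc = g < cfg.coloc_genes
            gene = f"{'COLOC' if is_coloc else 'NONC'}{k}_{g if is_coloc else g - cfg.coloc_genes}"
            truth[gene] = "coloc" if is_coloc else "non_coloc"
            for dataset, rows in datasets.items():
                if is_coloc:
                    z = gwas_z[cols] + cfg.eqtl_noise * rng.standard_normal(cfg.n_variants)
                else:
                    z = r_indep * cfg.effect_z + (1.0 + cfg.eqtl_noise) * rng.standard_normal(
                        cfg.n_variants
                    )
                rows.append(
                    pd.DataFrame(
                        {"gene": gene, "variant_id": vids, "p": _z_to_p(z), "dataset": dataset}
                    )
                )
    tables = {
        name: pd.concat(rows, ignore_index=True)
        for name, rows in datasets.items()
    }
    return tables, truth


def simulate_genes(cfg: SimConfig, truth: dict[str, str]) -> pd.DataFrame:
    """Place each simulated gene inside its locus window (50 kb bodies)."""
    rows = []
    by_locus: dict[int, list[str]] = {}
    for gene in truth:
        k = int(gene.split("_")[0].lstrip("COLOCN"))
        by_locus.setdefault(k, []).append(gene)
    for k, genes in sorted(by_locus.items()):
        center = cfg.locus_center(k)
        step = 120_000
        start0 = center - step * (len(genes) // 2)
        for i, gene in enumerate(sorted(genes)):
            start = max(1, start0 + i * step)
            rows.append((gene, cfg.chrom, start, start + 50_000, "+"))
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"])


def simulate_side_tables(cfg: SimConfig, truth: dict[str, str]):
    """Expression / constraint / burden / literature / flags for the bundle.

    Values are arbitrary but seeded and within-range; colocalized genes are
    given brain-expressed profiles so the demo bundle produces non-trivial
    evidence rows.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes = sorted(truth)
    expr_rows = []
    for gene in genes:
        expressed = truth[gene] == "coloc"
        for ctx in EXPRESSION_CONTEXTS:
            base = 20.0 if expressed and ctx in ("brain", "nigra", "dan") else 1.0
            expr_rows.append((gene, ctx, float(base * rng.lognormal(0.0, 0.5))))
    expression = pd.DataFrame(expr_rows, columns=["gene", "context", "mean_tpm"])

    constraint = pd.DataFrame(
        {
            "gene": genes,
            "syn_z": rng.normal(0, 1, len(genes)).round(3),
            "mis_z": rng.normal(0, 1, len(genes)).round(3),
            "pli": rng.uniform(0, 1, len(genes)).round(3),
            "oe_syn": rng.uniform(0.5, 1.0, len(genes)).round(3),
            "oe_mis": rng.uniform(0.5, 1.0, len(genes)).round(3),
            "oe_lof": rng.uniform(0.1, 0.8, len(genes)).round(3),
        }
    )
    constraint["ci90_upper_syn"] = (constraint["oe_syn"] + 0.2).round(3)
    constraint["ci90_upper_mis"] = (constraint["oe_mis"] + 0.2).round(3)
    constraint["ci90_upper_lof"] = (constraint["oe_lof"] + 0.2).round(3)

    burden = pd.DataFrame(
        {
            "gene": genes,
            "min_p_exome": rng.uniform(0.001, 1.0, len(genes)).round(5),
            "min_p_imputed": rng.uniform(0.001, 1.0, len(genes)).round(5),
        }
    )
    literature = pd.DataFrame(
        {
            "gene": genes,
            "n_hits_pd": rng.integers(0, 12, len(genes)),
            "n_hits_gene": rng.integers(5, 400, len(genes)),
        }
    )
    flags = {
        "nominated_meta5": [g for g in genes if truth[g] == "coloc"][:1],
        "pd_genes": [],
        "disease_genes": genes[:1],
    }
    return expression, constraint, burden, literature, flags


def write_panel_vcf(panel: GenotypePanel, path) -> None:
    """Write the panel as a plain diploid VCF 4.2 (unphased GTs)."""
    order = np.argsort(panel.pos, kind="stable")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = []
        for c in panel.chrom:
            if str(c) not in chroms:
                chroms.append(str(c))
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(panel.samples) + "\n")
        for j in order:
            gts = [
                gt_map.get(panel.dosages[i, j], "./.") for i in range(panel.n_samples)
            ]
            fh.write(
                f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.variant_ids[j]}"
                f"\tG\tA\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def write_bundle(cfg: SimConfig, outdir) -> dict[str, str]:
    """Write a complete seeded input bundle; returns {name: path}.

    Files: sumstats.tsv, genes.bed, panel.vcf, eqtl_{brain,blood,isoqtl}.tsv,
    expression.tsv, constraint.tsv, burden.tsv, flags.yaml, literature.tsv,
    catalog.tsv, truth.json.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = simulate_panel(cfg)
    sumstats = simulate_sumstats(cfg, panel)
    eqtl, truth = simulate_eqtl(cfg, panel, sumstats)
    genes = simulate_genes(cfg, truth)
    expression, constraint, burden, literature, flags = simulate_side_tables(cfg, truth)

    paths: dict[str, str] = {}

    def save(name, fn):
        p = outdir / name
        fn(p)
        paths[name] = str(p)

    save(
        "sumstats.tsv",
        lambda p: sumstats.rename(
            columns={
                "variant_id": "SNP",
                "chrom": "CHR",
                "pos": "BP",
                "allele_effect": "A1",
                "allele_other": "A2",
                "beta": "BETA",
                "se": "SE",
                "p": "P",
            }
        ).to_csv(p, sep="\t", index=False),
    )
    save(
        "genes.bed",
        lambda p: genes.assign(
            start0=genes["start"] - 1, score=0
        )[["chrom", "start0", "end", "symbol", "score", "strand"]].to_csv(
            p, sep="\t", index=False, header=False
        ),
    )
    save("panel.vcf", lambda p: write_panel_vcf(panel, p))
    save("eqtl_brain.tsv", lambda p: eqtl["brain_eqtl"].to_csv(p, sep="\t", index=False))
    save("eqtl_blood.tsv", lambda p: eqtl["blood_eqtl"].to_csv(p, sep="\t", index=False))
    save("eqtl_isoqtl.tsv", lambda p: eqtl["brain_isoqtl"].to_csv(p, sep="\t", index=False))
    save("expression.tsv", lambda p: expression.to_csv(p, sep="\t", index=False))
    save("constraint.tsv", lambda p: constraint.to_csv(p, sep="\t", index=False))
    save("burden.tsv", lambda p: burden.to_csv(p, sep="\t", index=False))
    save("literature.tsv", lambda p: literature.to_csv(p, sep="\t", index=False))
    save("flags.yaml", lambda p: p.write_text(yaml.safe_dump(flags)))
    catalog = pd.DataFrame(
        {
            "SNPS": [panel.variant_ids[_causal_index(cfg, k)] for k in range(cfg.n_loci)],
            "MAPPED_TRAIT": ["synthetic trait"] * cfg.n_loci,
            "PUBMEDID": ["00000000"] * cfg.n_loci,
        }
    )
    save("catalog.tsv", lambda p: catalog.to_csv(p, sep="\t", index=False))
    truth_obj = {
        "genes": truth,
        "gwas_causal": {
            str(k): panel.variant_ids[_causal_index(cfg, k)] for k in range(cfg.n_loci)
        },
        "eqtl_causal": {
            str(k): panel.variant_ids[_eqtl_causal_index(cfg, k)] for k in range(cfg.n_loci)
        },
        "seed": cfg.seed,
    }
    save("truth.json", lambda p: p.write_text(json.dumps(truth_obj, indent=1) + "\n"))
    return paths


def random_sumstats_table(
    seed: int,
    n_variants: int = 150,
    n_chrom: int = 2,
    frac_significant: float = 0.15,
    span: int = 12_000_000,
) -> pd.DataFrame:
    """Random summary-statistics table for exercising locus partitioning.

    Positions are uniform over ``span``; a seeded fraction of variants gets
    a genome-wide-significant P (log-uniform 1e-30..5e-8), the rest
    log-uniform up to 1.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in range(1, n_chrom + 1):
        m = n_variants // n_chrom
        pos = np.sort(rng.choice(np.arange(1, span), size=m, replace=False))
        sig = rng.random(m) < frac_significant
        logp = np.where(
            sig,
            rng.uniform(-30, np.log10(5e-8), size=m),
            rng.uniform(np.log10(5e-8), 0, size=m),
        )
        for j in range(m):
            rows.append((f"rs{c}_{j}", str(c), int(pos[j]), 10.0 ** logp[j]))
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])
    df["beta"] = 0.0
    df["se"] = 0.01
    return df
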