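"""Readers and writers for the tables the pipeline consumes and emits.

All genomic coordinates are held 1-based inclusive internally; BED input is
converted at the boundary. Chromosome labels are normalised by stripping a
leading ``chr``. Effect sizes are held on the log-odds (beta) scale; odds
ratios are log-transformed on read when the dialect declares an ``OR``
column.

Readers log a warning for every rejected row and record rejection counts in
``DataFrame.attrs`` so that accepted + rejected always reconciles with the
number of input data rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .ld import GenotypePanel

logger = logging.getLogger(__name__)

EXPRESSION_CONTEXTS = (
    "brain",
    "nigra",
    "dan",
    "astrocyte",
    "endothelial",
    "gaba",
    "microglia",
    "odc",
    "opc",
)

EVIDENCE_COLUMNS = (
    "brain_expr",
    "nigra_expr",
    "dan_expr",
    "qtl_brain",
    "qtl_blood",
    "qtl_correl",
    "literature",
    "variant_intolerant",
    "burden",
    "nominated_meta5",
    "pd_gene",
    "disease_gene",
)

#: canonical summary-statistics column names; a dialect maps these to the
#: actual headers in a file.
SUMSTAT_CANONICAL = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "P")

EQTL_DATASETS = ("brain_eqtl", "blood_eqtl", "brain_isoqtl")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class GeneFlagSets:
    """Symbol sets behind the three membership evidence flags."""

    nominated_meta5: frozenset[str] = frozenset()
    pd_genes: frozenset[str] = frozenset()
    disease_genes: frozenset[str] = frozenset()

    @staticmethod
    def _clean(symbols) -> frozenset[str]:
        out = frozenset(str(s).strip().upper() for s in symbols if str(s).strip())
        return out

    @classmethod
    def from_iterables(cls, nominated_meta5=(), pd_genes=(), disease_genes=()):
        return cls(
            nominated_meta5=cls._clean(nominated_meta5),
            pd_genes=cls._clean(pd_genes),
            disease_genes=cls._clean(disease_genes),
        )


def normalize_chrom(label) -> str:
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    return s


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, dialect: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics TSV.

    Parameters
    ----------
    path:
        Tab-separated file with one row per variant association.
    dialect:
        Maps canonical names (``SNP``, ``CHR``, ``BP``, ``A1``, ``A2``,
        ``BETA`` or ``OR``, ``SE``, ``P``) to the file's actual headers.
        Defaults to the identity mapping. Declaring ``OR`` instead of
        ``BETA`` log-transforms the effect on read.

    Returns
    -------
    DataFrame with columns ``variant_id, chrom, pos, allele_effect,
    allele_other, beta, se, p``; ``attrs["n_rejected"]`` holds the count of
    dropped rows (bad P/SE, multi-allelic positions).
    """
    dialect = dict(dialect or {})
    effect_col = "OR" if "OR" in dialect else "BETA"
    wanted = {
        "SNP": dialect.get("SNP", "SNP"),
        "CHR": dialect.get("CHR", "CHR"),
        "BP": dialect.get("BP", "BP"),
        "A1": dialect.get("A1", "A1"),
        "A2": dialect.get("A2", "A2"),
        effect_col: dialect.get(effect_col, effect_col),
        "SE": dialect.get("SE", "SE"),
        "P": dialect.get("P", "P"),
    }
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for canon, actual in wanted.items():
        if actual not in raw.columns:
            raise FormatError(f"summary statistics missing required column {actual!r} ({canon})")
    n_input = len(raw)
    df = pd.DataFrame(
        {
            "variant_id": raw[wanted["SNP"]].astype(str),
            "chrom": raw[wanted["CHR"]].map(normalize_chrom),
            "pos": pd.to_numeric(raw[wanted["BP"]], errors="coerce"),
            "allele_effect": raw[wanted["A1"]].astype(str),
            "allele_other": raw[wanted["A2"]].astype(str),
            "effect": pd.to_numeric(raw[wanted[effect_col]], errors="coerce"),
            "se": pd.to_numeric(raw[wanted["SE"]], errors="coerce"),
            "p": pd.to_numeric(raw[wanted["P"]], errors="coerce"),
        }
    )

    bad = (
        df["p"].isna()
        | (df["p"] <= 0)
        | (df["p"] > 1)
        | df["se"].isna()
        | (df["se"] <= 0)
        | df["pos"].isna()
        | (df["pos"] < 1)
        | df["effect"].isna()
    )
    if effect_col == "OR":
        bad |= df["effect"] <= 0
    for _, row in df[bad].iterrows():
        logger.warning("rejecting sumstat row %s: unparseable or out-of-range value", row["variant_id"])
    df = df[~bad].copy()

    # multi-allelic: >2 distinct alleles observed at one chrom:pos
    allele_sets = {}
    for chrom, pos, a1, a2 in zip(df["chrom"], df["pos"], df["allele_effect"], df["allele_other"]):
        allele_sets.setdefault((chrom, pos), set()).update((a1, a2))
    multi = {key for key, alleles in allele_sets.items() if len(alleles) > 2}
    if multi:
        is_multi = [
            (c, p) in multi for c, p in zip(df["chrom"], df["pos"])
        ]
        n_multi = int(np.sum(is_multi))
        logger.warning("dropping %d rows at %d multi-allelic position(s)", n_multi, len(multi))
        df = df[~np.asarray(is_multi)].copy()

    dup = df.duplicated(subset=["variant_id", "chrom", "pos"], keep="first")
    if dup.any():
        logger.warning("dropping %d duplicate (variant, chrom, pos) rows", int(dup.sum()))
        df = df[~dup].copy()

    df["pos"] = df["pos"].astype(np.int64)
    df["beta"] = np.log(df["effect"]) if effect_col == "OR" else df["effect"]
    df = df.drop(columns="effect").reset_index(drop=True)
    df = df[["variant_id", "chrom", "pos", "allele_effect", "allele_other", "beta", "se", "p"]]
    df.attrs["n_rejected"] = n_input - len(df)
    return df


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

def read_genes(path, format: str = "bed") -> pd.DataFrame:
    """Read gene intervals from BED4+ or GFF3 into 1-based inclusive records.

    BED intervals are 0-based half-open and are converted; zero-length BED
    intervals are rejected with a warning. GFF3 is filtered to ``gene``
    features; the symbol comes from ``Name=``, ``gene_name=`` or ``ID=``.
    """
    if format == "bed":
        return _read_genes_bed(path)
    if format == "gff3":
        return _read_genes_gff3(path)
    raise FormatError(f"unknown gene annotation format {format!r}")


def _empty_genes() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "symbol": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "start": pd.Series(dtype=np.int64),
            "end": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
        }
    )


def _read_genes_bed(path) -> pd.DataFrame:
    rows = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"BED line has fewer than 4 fields: {line!r}")
            chrom, start0, end0, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if end0 <= start0:
                logger.warning("rejecting zero/negative-length BED interval for %s", name)
                n_rejected += 1
                continue
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else "+"
            rows.append((name, normalize_chrom(chrom), start0 + 1, end0, strand))
    df = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"]) if rows else _empty_genes()
    df.attrs["n_rejected"] = n_rejected
    return df


def _gff3_attributes(field: str) -> dict[str, str]:
    out = {}
    for item in field.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_genes_gff3(path) -> pd.DataFrame:
    rows = []
    n_rejected = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(f"GFF3 line has fewer than 9 fields: {line!r}")
            if parts[2] != "gene":
                continue
            start, end = int(parts[3]), int(parts[4])
            if end < start:
                logger.warning("rejecting GFF3 gene with end < start at %s:%s", parts[0], parts[3])
                n_rejected += 1
                continue
            attrs = _gff3_attributes(parts[8])
            symbol = attrs.get("Name") or attrs.get("gene_name") or attrs.get("ID")
            if not symbol:
                logger.warning("rejecting GFF3 gene without Name/gene_name/ID at %s:%s", parts[0], parts[3])
                n_rejected += 1
                continue
            strand = parts[6] if parts[6] in ("+", "-") else "+"
            rows.append((symbol, normalize_chrom(parts[0]), start, end, strand))
    df = pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end", "strand"]) if rows else _empty_genes()
    df.attrs["n_rejected"] = n_rejected
    return df


# ---------------------------------------------------------------------------
# Reference panel (VCF)
# ---------------------------------------------------------------------------

def read_panel(path) -> GenotypePanel:
    """Load a diploid genotype reference panel from a VCF (plain or bgzip).

    Non-biallelic sites are skipped (count logged). Missing genotypes become
    NA dosages. A VCF without samples, or a haploid GT, is an error.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    if not samples:
        raise FormatError("VCF has no sample columns; a genotype panel is required")
    ids, chroms, poss, dosage_cols = [], [], [], []
    n_skipped = 0
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1 or rec.alts[0] is None:
            n_skipped += 1
            continue
        col = np.empty(len(samples))
        for i, sample in enumerate(samples):
            gt = rec.samples[sample].get("GT")
            if gt is None or len(gt) == 0:
                col[i] = np.nan
                continue
            if len(gt) == 1:
                raise FormatError(f"haploid genotype for sample {sample!r} at {rec.chrom}:{rec.pos}")
            if any(a is None for a in gt):
                col[i] = np.nan
            else:
                col[i] = float(sum(1 for a in gt if a == 1))
        vid = rec.id if rec.id not in (None, ".") else f"{normalize_chrom(rec.chrom)}:{rec.pos}"
        ids.append(vid)
        chroms.append(normalize_chrom(rec.chrom))
        poss.append(rec.pos)
        dosage_cols.append(col)
    vcf.close()
    if n_skipped:
        logger.warning("skipped %d non-biallelic site(s) in panel VCF", n_skipped)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    return GenotypePanel(
        variant_ids=ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosages=dosages,
        samples=samples,
    )


# ---------------------------------------------------------------------------
# Expression / eQTL / constraint / burden / flags / literature / catalog
# ---------------------------------------------------------------------------

def read_expression(path) -> pd.DataFrame:
    """Long-format mean-expression table: gene, context, mean_tpm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "context": str})
    for col in ("gene", "context", "mean_tpm"):
        if col not in df.columns:
            raise FormatError(f"expression table missing column {col!r}")
    unknown = set(df["context"]) - set(EXPRESSION_CONTEXTS)
    if unknown:
        raise FormatError(f"unknown expression context(s): {sorted(unknown)}")
    if (df["mean_tpm"] < 0).any():
        raise FormatError("negative mean TPM")
    if df.duplicated(subset=["gene", "context"]).any():
        raise FormatError("duplicate (gene, context) expression records")
    return df


def read_eqtl(path, dataset: str) -> pd.DataFrame:
    """Per-dataset eQTL association table: gene, variant_id, p."""
    if dataset not in EQTL_DATASETS:
        raise FormatError(f"unknown eQTL dataset {dataset!r}; expected one of {EQTL_DATASETS}")
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "variant_id": str})
    for col in ("gene", "variant_id", "p"):
        if col not in df.columns:
            raise FormatError(f"eQTL table missing column {col!r}")
    n_input = len(df)
    bad = df["p"].isna() | (df["p"] <= 0) | (df["p"] > 1)
    if bad.any():
        logger.warning("rejecting %d eQTL row(s) with P outside (0, 1]", int(bad.sum()))
    df = df[~bad].copy().reset_index(drop=True)
    df["dataset"] = dataset
    df.attrs["n_rejected"] = n_input - len(df)
    return df


_CONSTRAINT_ALIASES = {
    "gene": "gene",
    "syn_z": "syn_z",
    "mis_z": "mis_z",
    "pLI": "pli",
    "pli": "pli",
    "oe_syn": "oe_syn",
    "oe_mis": "oe_mis",
    "oe_lof": "oe_lof",
    "oe_syn_upper": "ci90_upper_syn",
    "oe_mis_upper": "ci90_upper_mis",
    "oe_lof_upper": "ci90_upper_lof",
    "ci90_upper_syn": "ci90_upper_syn",
    "ci90_upper_mis": "ci90_upper_mis",
    "ci90_upper_lof": "ci90_upper_lof",
}


def read_constraint(path) -> pd.DataFrame:
    """gnomAD-style per-gene constraint table.

    Accepts both gnomAD headers (``pLI``, ``oe_lof_upper``, ...) and the
    internal names; returns internal names.
    """
    df = pd.read_csv(path, sep="\t")
    df = df.rename(columns={c: _CONSTRAINT_ALIASES[c] for c in df.columns if c in _CONSTRAINT_ALIASES})
    required = ["gene", "ci90_upper_syn", "ci90_upper_mis", "ci90_upper_lof"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"constraint table missing column {col!r}")
    if "pli" in df.columns:
        out_of_range = df["pli"].dropna()
        if ((out_of_range < 0) | (out_of_range > 1)).any():
            raise FormatError("pLI outside [0, 1]")
    for oe, upper in (("oe_syn", "ci90_upper_syn"), ("oe_mis", "ci90_upper_mis"), ("oe_lof", "ci90_upper_lof")):
        if oe in df.columns:
            both = df[[oe, upper]].dropna()
            if (both[oe] > both[upper]).any():
                raise FormatError(f"{oe} exceeds its 90% CI upper bound")
    df["gene"] = df["gene"].astype(str)
    return df


def read_burden(path) -> pd.DataFrame:
    """Per-gene minimum burden-test P values (exome and imputed, NA allowed)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "min_p_exome", "min_p_imputed"):
        if col not in df.columns:
            raise FormatError(f"burden table missing column {col!r}")
    for col in ("min_p_exome", "min_p_imputed"):
        vals = df[col].dropna()
        if ((vals <= 0) | (vals > 1)).any():
            raise FormatError(f"burden {col} outside (0, 1]")
    return df


def read_flags(path) -> GeneFlagSets:
    """YAML gene flag lists: nominated_meta5, pd_genes, disease_genes."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return GeneFlagSets.from_iterables(
        nominated_meta5=data.get("nominated_meta5", []),
        pd_genes=data.get("pd_genes", []),
        disease_genes=data.get("disease_genes", []),
    )


def read_literature(path) -> pd.DataFrame:
    """Per-gene PubMed hit counts: gene, n_hits_pd, n_hits_gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for col in ("gene", "n_hits_pd"):
        if col not in df.columns:
            raise FormatError(f"literature table missing column {col!r}")
    if (df["n_hits_pd"] < 0).any():
        raise FormatError("negative literature hit count")
    return df


def read_catalog(path) -> pd.DataFrame:
    """GWAS-catalog associations: SNPS, MAPPED_TRAIT, PUBMEDID columns."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("SNPS", "MAPPED_TRAIT", "PUBMEDID"):
        if col not in df.columns:
            raise FormatError(f"GWAS catalog table missing column {col!r}")
    out = pd.DataFrame(
        {
            "variant_id": df["SNPS"].astype(str),
            "trait": df["MAPPED_TRAIT"].astype(str),
            "study_ref": df["PUBMEDID"].astype(str),
        }
    )
    if (out["variant_id"].str.len() == 0).any():
        raise FormatError("empty variant id in GWAS catalog table")
    return out


def read_coding_variants(path) -> pd.DataFrame:
    """Coding-variant annotations: SNP, GENE, HGVS, CADD_PHRED, AF columns."""
    df = pd.read_csv(path, sep="\t", dtype={"SNP": str, "GENE": str, "HGVS": str})
    for col in ("SNP", "GENE", "HGVS", "CADD_PHRED", "AF"):
        if col not in df.columns:
            raise FormatError(f"coding-variant table missing column {col!r}")
    af = df["AF"].astype(float)
    if ((af < 0) | (af > 1)).any():
        raise FormatError("allele frequency outside [0, 1]")
    return pd.DataFrame(
        {
            "variant_id": df["SNP"].astype(str),
            "gene": df["GENE"].astype(str),
            "hgvs": df["HGVS"].astype(str),
            "cadd": df["CADD_PHRED"].astype(float),
            "af": af,
        }
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _evidence_out_columns(df: pd.DataFrame) -> list[str]:
    cols = ["gene"] + list(EVIDENCE_COLUMNS) + ["conclusion"]
    for extra in ("rank", "locus_id"):
        if extra in df.columns:
            cols.append(extra)
    return cols


def write_evidence(df: pd.DataFrame, path, format: str = "tsv") -> None:
    """Write an evidence table with deterministic column order.

    NA bits are serialised as the literal string ``NA`` in TSV and ``null``
    in JSON; :func:`read_evidence` round-trips both losslessly.
    """
    cols = _evidence_out_columns(df)
    out = df.reindex(columns=cols)
    if format == "tsv":
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        records = []
        for _, row in out.iterrows():
            rec = {}
            for col in cols:
                v = row[col]
                rec[col] = None if pd.isna(v) else (v if col == "gene" else (int(v) if float(v).is_integer() else float(v)))
            records.append(rec)
        with open(path, "w") as fh:
            json.dump(records, fh, indent=1)
            fh.write("\n")
    else:
        raise FormatError(f"unknown evidence format {format!r}")


def read_evidence(path, format: str = "tsv") -> pd.DataFrame:
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False, dtype={"gene": str})
    elif format == "json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
        if df.empty:
            df = pd.DataFrame(columns=_evidence_out_columns(pd.DataFrame()))
    else:
        raise FormatError(f"unknown evidence format {format!r}")
    for col in EVIDENCE_COLUMNS:
        if col in df.columns:
            df[col] = pd.array(df[col], dtype="Int64")
    return df


def write_loci(loci, path) -> None:
    """Loci TSV: locus_id, chrom, start, end, n_leads, lead_rsids, min_p."""
    rows = [
        {
            "locus_id": loc.locus_id,
            "chrom": loc.chrom,
            "start": loc.start,
            "end": loc.end,
            "n_leads": len(loc.lead_variants),
            "lead_rsids": ",".join(v.variant_id for v in loc.lead_variants),
            "min_p": min(v.p for v in loc.lead_variants),
        }
        for loc in loci
    ]
    cols = ["locus_id", "chrom", "start", "end", "n_leads", "lead_rsids", "min_p"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_locuscompare(pairs: pd.DataFrame, path) -> None:
    """Locus-compare TSV: variant_id, pos, neglog10p_gwas, neglog10p_qtl."""
    cols = ["variant_id", "pos", "neglog10p_gwas", "neglog10p_qtl"]
    pairs.reindex(columns=cols).to_csv(path, sep="\t", index=False)
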