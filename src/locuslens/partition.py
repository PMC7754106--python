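"""Partition GWAS summary statistics into risk loci.

Per chromosome, the variant with the smallest P value below the genome-wide
threshold is taken as a lead; it and every variant within one window of it
are extracted from the pool, and the region lead +/- window is recorded.
This repeats until no genome-wide-significant variant remains. Regions
whose edges fall within the merge gap are then merged transitively until a
fixpoint. Every significant variant ends up inside exactly one locus, and
distinct loci on a chromosome are separated by more than the merge gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Lead:
    """A lead variant: the smallest-P variant of one extraction round."""

    variant_id: str
    chrom: str
    pos: int
    p: float
    beta: float = float("nan")
    se: float = float("nan")


@dataclass
class Locus:
    """A merged risk region with its extraction-ordered lead variants."""

    locus_id: int
    chrom: str
    start: int
    end: int
    lead_variants: list[Lead] = field(default_factory=list)
    n_merged: int = 1

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"locus start {self.start} > end {self.end}")
        if not self.lead_variants:
            raise ValueError("locus must have at least one lead variant")

    @property
    def min_p(self) -> float:
        return min(v.p for v in self.lead_variants)


@dataclass(frozen=True)
class PartitionConfig:
    """Locus-partition parameters.

    p_threshold : genome-wide significance cutoff (strict <), default 5e-8.
    window      : extraction half-width around each lead in bp, default 1 Mb.
    merge_gap   : maximum edge gap for merging regions in bp, default 100 kb.
    """

    p_threshold: float = 5e-8
    window: int = 1_000_000
    merge_gap: int = 100_000

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must be in (0, 1)")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.merge_gap <= 0:
            raise ValueError("merge_gap must be positive")


def _sort_for_extraction(sub: pd.DataFrame) -> pd.DataFrame:
    # smallest P first; ties broken by (chrom, pos) for determinism
    return sub.sort_values(["p", "chrom", "pos"], kind="mergesort")


def _extract_leads(sub: pd.DataFrame, cfg: PartitionConfig) -> list[Lead]:
    """Iterative min-P extraction for one chromosome; returns leads in order."""
    sub = _sort_for_extraction(sub)
    pos = sub["pos"].to_numpy(dtype=np.int64)
    remaining = np.ones(len(sub), dtype=bool)
    leads: list[Lead] = []
    while True:
        rem = np.nonzero(remaining)[0]
        if rem.size == 0:
            break
        # rows are P-sorted, so the first remaining row has the smallest P
        idx = int(rem[0])
        if not sub["p"].iat[idx] < cfg.p_threshold:
            break
        row = sub.iloc[idx]
        leads.append(
            Lead(
                variant_id=str(row["variant_id"]),
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                p=float(row["p"]),
                beta=float(row.get("beta", float("nan"))),
                se=float(row.get("se", float("nan"))),
            )
        )
        remaining &= np.abs(pos - int(row["pos"])) > cfg.window
    return leads


def _merge_intervals(
    intervals: list[tuple[int, int, list[Lead]]], merge_gap: int
) -> list[tuple[int, int, list[Lead], int]]:
    """Transitive merge of (start, end, leads) with edge gap <= merge_gap."""
    ordered = sorted(intervals, key=lambda t: (t[0], t[1]))
    merged: list[list] = []
    for start, end, leads in ordered:
        if merged and start - merged[-1][1] <= merge_gap:
            merged[-1][1] = max(merged[-1][1], end)
            merged[-1][2] = merged[-1][2] + leads
            merged[-1][3] += 1
        else:
            merged.append([start, end, list(leads), 1])
    return [(s, e, l, n) for s, e, l, n in merged]


def partition_loci(sumstats: pd.DataFrame, cfg: PartitionConfig | None = None) -> list[Locus]:
    """Partition a summary-statistics table into risk loci.

    Parameters
    ----------
    sumstats:
        Table with at least ``variant_id``, ``chrom``, ``pos``, ``p`` columns
        (as produced by :func:`locuslens.io_formats.read_sumstats`).
    cfg:
        Partition parameters; defaults to genome-wide 5e-8 / 1 Mb / 100 kb.

    Returns
    -------
    Loci numbered 1..k by (chrom, start); within a merged locus the lead
    variants keep their extraction order.
    """
    cfg = cfg or PartitionConfig()
    if sumstats is None or len(sumstats) == 0:
        return []

    per_chrom_regions: list[tuple[str, int, int, list[Lead], int]] = []
    for chrom, sub in sumstats.groupby("chrom", sort=False):
        leads = _extract_leads(sub, cfg)
        if not leads:
            continue
        intervals = [
            (max(1, lead.pos - cfg.window), lead.pos + cfg.window, [lead]) for lead in leads
        ]
        for start, end, region_leads, n_merged in _merge_intervals(intervals, cfg.merge_gap):
            per_chrom_regions.append((str(chrom), start, end, region_leads, n_merged))

    def chrom_key(c: str):
        return (0, int(c)) if c.isdigit() else (1, c)

    per_chrom_regions.sort(key=lambda t: (chrom_key(t[0]), t[1]))
    return [
        Locus(locus_id=i, chrom=c, start=s, end=e, lead_variants=leads, n_merged=n)
        for i, (c, s, e, leads, n) in enumerate(per_chrom_regions, start=1)
    ]


def genes_in_window(
    leads, genes: pd.DataFrame, flank: int = 1_000_000
) -> pd.DataFrame:
    """Genes overlapping lead +/- flank by at least 1 bp.

    ``leads`` may be a single lead variant or a list (a locus with several
    leads takes the union over leads, deduplicated by symbol). Gene intervals
    are 1-based inclusive.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if not isinstance(leads, (list, tuple)):
        leads = [leads]
    if len(genes) == 0:
        return genes.copy()
    keep = np.zeros(len(genes), dtype=bool)
    for lead in leads:
        lo, hi = max(1, lead.pos - flank), lead.pos + flank
        keep |= (
            (genes["chrom"].astype(str) == str(lead.chrom)).to_numpy()
            & (genes["start"].to_numpy() <= hi)
            & (genes["end"].to_numpy() >= lo)
        )
    out = genes[keep].drop_duplicates(subset="symbol").reset_index(drop=True)
    return out
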