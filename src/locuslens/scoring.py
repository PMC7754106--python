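"""Weighted conclusion score and within-locus gene ranking.

The conclusion score is the weighted sum of a gene's evidence bits: each of
the 12 columns carries an integer weight in 0..4 (default 1), NA bits
contribute nothing, and the maximum attainable score is 4 x 12. Genes are
ranked within a locus by descending score, ties broken alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import yaml

from .io_formats import EVIDENCE_COLUMNS

WEIGHT_MIN, WEIGHT_MAX = 0, 4


@dataclass(frozen=True)
class WeightConfig:
    """Integer weight (0-4) per evidence column; default all 1."""

    weights: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        merged = {col: 1 for col in EVIDENCE_COLUMNS}
        for col, w in self.weights.items():
            if col not in EVIDENCE_COLUMNS:
                raise ValueError(f"unknown evidence column {col!r}")
            if not isinstance(w, int) or isinstance(w, bool) or not (WEIGHT_MIN <= w <= WEIGHT_MAX):
                raise ValueError(f"weight for {col!r} must be an integer in 0..4, got {w!r}")
            merged[col] = w
        object.__setattr__(self, "weights", merged)

    def __getitem__(self, col: str) -> int:
        return self.weights[col]

    @classmethod
    def from_yaml(cls, path) -> "WeightConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(weights={str(k): v for k, v in data.items()})

    def with_overrides(self, overrides: dict[str, int]) -> "WeightConfig":
        merged = dict(self.weights)
        merged.update(overrides)
        return WeightConfig(weights=merged)


def conclusion_score(bits, w: WeightConfig | None = None) -> int:
    """Weighted sum of evidence bits; NA contributes 0.

    ``bits`` maps evidence column names to 0, 1, or NA (None/pd.NA). Columns
    missing from the mapping count as NA.
    """
    w = w or WeightConfig()
    total = 0
    for col in EVIDENCE_COLUMNS:
        bit = bits.get(col)
        if bit is None or pd.isna(bit):
            continue
        bit = int(bit)
        if bit not in (0, 1):
            raise ValueError(f"evidence bit {col}={bit!r} is not 0/1/NA")
        total += w[col] * bit
    return total


def rank_genes(rows: pd.DataFrame, w: WeightConfig | None = None) -> pd.DataFrame:
    """Rank one locus's evidence rows by conclusion score.

    Recomputes the conclusion under ``w``, sorts descending with ties broken
    by gene symbol ascending, and adds a 1-based ``rank`` column.
    """
    w = w or WeightConfig()
    df = rows.copy()
    if len(df):
        df["conclusion"] = [
            conclusion_score({col: row[col] for col in EVIDENCE_COLUMNS}, w)
            for _, row in df.iterrows()
        ]
    df = df.sort_values(["conclusion", "gene"], ascending=[False, True], kind="mergesort")
    df = df.reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return df
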