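"""Locus partitioning: geometry examples, invariants, brute-force oracle."""

import numpy as np
import pytest

from locuslens.partition import Lead, PartitionConfig, genes_in_window, partition_loci
from locuslens.simulate import random_sumstats_table

from conftest import make_sumstats

MB = 1_000_000


def brute_force_partition(df, p_threshold=5e-8, window=MB, merge_gap=100_000):
    """Literal restaging of the partition rules, merging by pairwise rescans.

    Independent of the production path: extraction rescans the full pool
    each round, and merging repeatedly scans all region pairs until no pair
    is within the gap (connected components by exhaustion).
    """
    out = []
    for chrom in sorted(set(df["chrom"]), key=str):
        sub = df[df["chrom"] == chrom]
        pool = list(zip(sub["variant_id"], sub["pos"].astype(int), sub["p"]))
        leads = []
        while True:
            cands = [t for t in pool if t[2] < p_threshold]
            if not cands:
                break
            lead = min(cands, key=lambda t: (t[2], t[1]))
            leads.append(lead)
            pool = [t for t in pool if abs(t[1] - lead[1]) > window]
        regions = [[max(1, p - window), p + window, {v}] for v, p, _ in leads]
        changed = True
        while changed:
            changed = False
            for i in range(len(regions)):
                for j in range(i + 1, len(regions)):
                    a, b = regions[i], regions[j]
                    gap = max(b[0] - a[1], a[0] - b[1])
                    if gap <= merge_gap:
                        regions[i] = [min(a[0], b[0]), max(a[1], b[1]), a[2] | b[2]]
                        del regions[j]
                        changed = True
                        break
                if changed:
                    break
        out.extend((str(chrom), s, e, frozenset(v)) for s, e, v in regions)
    return sorted(out, key=lambda t: ((0, int(t[0])) if t[0].isdigit() else (1, t[0]), t[1]))


def as_tuples(loci):
    return [
        (l.chrom, l.start, l.end, frozenset(v.variant_id for v in l.lead_variants)) for l in loci
    ]


class TestExamples:
    def test_single_peak_geometry(self):
        ss = make_sumstats([("rs1", "1", 5 * MB, 1e-10)])
        (locus,) = partition_loci(ss)
        assert (locus.start, locus.end) == (4 * MB, 6 * MB)
        assert [v.variant_id for v in locus.lead_variants] == ["rs1"]

    def test_no_significant_variant_gives_no_locus(self):
        ss = make_sumstats([("rs1", "1", 5 * MB, 6e-8), ("rs2", "1", 6 * MB, 0.5)])
        assert partition_loci(ss) == []

    def test_peaks_2050kb_apart_merge(self):
        # edges (p1 + 1 Mb) and (p2 - 1 Mb) are 50 kb apart -> merged
        ss = make_sumstats([("rs1", "1", 5 * MB, 1e-10), ("rs2", "1", 5 * MB + 2_050_000, 1e-9)])
        (locus,) = partition_loci(ss)
        assert (locus.start, locus.end) == (4 * MB, 5 * MB + 2_050_000 + MB)
        assert len(locus.lead_variants) == 2
        assert locus.n_merged == 2

    def test_peaks_2200kb_apart_stay_separate(self):
        ss = make_sumstats([("rs1", "1", 5 * MB, 1e-10), ("rs2", "1", 5 * MB + 2_200_000, 1e-9)])
        loci = partition_loci(ss)
        assert len(loci) == 2

    def test_extraction_order_recorded(self):
        # weaker peak extracted second even though it sits left of the stronger
        ss = make_sumstats(
            [("weak", "1", 2 * MB, 1e-9), ("strong", "1", 7 * MB, 1e-20)]
        )
        loci = partition_loci(ss)
        leads = {l.lead_variants[0].variant_id: l for l in loci}
        assert set(leads) == {"weak", "strong"}

    def test_window_clipped_at_one(self):
        ss = make_sumstats([("rs1", "1", 500_000, 1e-10)])
        (locus,) = partition_loci(ss)
        assert locus.start == 1

    def test_empty_input(self):
        import pandas as pd

        assert partition_loci(pd.DataFrame()) == []

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PartitionConfig(window=-5)
        with pytest.raises(ValueError):
            PartitionConfig(p_threshold=1.5)


class TestInvariants:
    def test_coverage_and_separation(self):
        cfg = PartitionConfig()
        for seed in range(10):
            ss = random_sumstats_table(seed)
            loci = partition_loci(ss, cfg)
            sig = ss[ss["p"] < cfg.p_threshold]
            for _, v in sig.iterrows():
                hits = [
                    l
                    for l in loci
                    if l.chrom == v["chrom"] and l.start <= v["pos"] <= l.end
                ]
                assert len(hits) == 1, f"variant {v['variant_id']} in {len(hits)} loci"
            by_chrom = {}
            for l in loci:
                by_chrom.setdefault(l.chrom, []).append(l)
            for group in by_chrom.values():
                group.sort(key=lambda l: l.start)
                for a, b in zip(group, group[1:]):
                    assert b.start - a.end > cfg.merge_gap

    def test_row_order_invariance(self):
        ss = random_sumstats_table(3)
        shuffled = ss.sample(frac=1.0, random_state=11).reset_index(drop=True)
        assert as_tuples(partition_loci(ss)) == as_tuples(partition_loci(shuffled))

    def test_p_ties_broken_by_position(self):
        ss = make_sumstats([("right", "1", 9 * MB, 1e-10), ("left", "1", 2 * MB, 1e-10)])
        loci = partition_loci(ss)
        # both significant, 7 Mb apart -> two loci; tie on P means the
        # left-most variant is extracted first but numbering is positional
        assert [l.lead_variants[0].variant_id for l in loci] == ["left", "right"]

    def test_oracle_equivalence_quick(self):
        for seed in range(25):
            ss = random_sumstats_table(seed, n_variants=120)
            assert as_tuples(partition_loci(ss)) == brute_force_partition(ss)

    def test_locus_ids_sorted_by_chrom_then_start(self):
        ss = make_sumstats(
            [("a", "2", 5 * MB, 1e-10), ("b", "1", 9 * MB, 1e-10), ("c", "1", 2 * MB, 1e-9)]
        )
        loci = partition_loci(ss)
        assert [l.locus_id for l in loci] == [1, 2, 3]
        assert [(l.chrom, l.lead_variants[0].variant_id) for l in loci] == [
            ("1", "c"),
            ("1", "b"),
            ("2", "a"),
        ]


class TestGenesInWindow:
    def _lead(self, pos=10 * MB):
        return Lead(variant_id="rs1", chrom="1", pos=pos, p=1e-10)

    def test_partial_overlap_included(self):
        import pandas as pd

        pos = 10 * MB
        genes = pd.DataFrame(
            {
                "symbol": ["EDGE", "FAR"],
                "chrom": ["1", "1"],
                "start": [pos + 999_000, pos + 1_500_000],
                "end": [pos + 1_050_000, pos + 1_600_000],
                "strand": ["+", "+"],
            }
        )
        out = genes_in_window(self._lead(pos), genes)
        assert list(out["symbol"]) == ["EDGE"]

    def test_union_over_leads_deduplicated(self):
        import pandas as pd

        genes = pd.DataFrame(
            {
                "symbol": ["G"],
                "chrom": ["1"],
                "start": [10 * MB],
                "end": [10 * MB + 1000],
                "strand": ["+"],
            }
        )
        leads = [self._lead(10 * MB), self._lead(10 * MB + 500)]
        assert list(genes_in_window(leads, genes)["symbol"]) == ["G"]

    def test_empty_gene_table(self):
        import pandas as pd

        genes = pd.DataFrame(columns=["symbol", "chrom", "start", "end", "strand"])
        assert len(genes_in_window(self._lead(), genes)) == 0

    def test_flank_validation(self):
        import pandas as pd

        with pytest.raises(ValueError):
            genes_in_window(self._lead(), pd.DataFrame({"symbol": [], "chrom": [], "start": [], "end": []}), flank=0)
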