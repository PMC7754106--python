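"""Evidence bits: boundary rules, NA semantics, assembly."""

import numpy as np
import pandas as pd
import pytest

from locuslens.coloc import ColocResult
from locuslens.evidence import (
    EvidenceInputs,
    Thresholds,
    assemble_evidence,
    build_queries,
    burden_bit,
    constraint_bit,
    expression_bits,
    flag_bits,
    literature_bit,
    qtl_bits,
)
from locuslens.io_formats import EVIDENCE_COLUMNS, GeneFlagSets
from locuslens.partition import Lead, Locus


def coloc(dataset, eligible=True, r=None):
    return ColocResult(gene="G", dataset=dataset, n_shared=20, eligible=eligible, pearson_r=r)


class TestExpressionBits:
    def test_cutoff_is_strict(self, tiny_expression):
        # G2 sits exactly at 5 TPM in brain -> 0, not 1
        assert expression_bits("G2", tiny_expression) == (0, None, None)

    def test_mixed_contexts(self, tiny_expression):
        assert expression_bits("G1", tiny_expression) == (1, 0, 1)

    def test_absent_gene_all_na(self, tiny_expression):
        assert expression_bits("NOPE", tiny_expression) == (None, None, None)

    def test_raising_cutoff_never_creates_ones(self, tiny_expression):
        low = expression_bits("G1", tiny_expression, Thresholds(tpm_cutoff=5.0))
        high = expression_bits("G1", tiny_expression, Thresholds(tpm_cutoff=8.0))
        for a, b in zip(low, high):
            if a == 0:
                assert b == 0


class TestQtlBits:
    def test_eligible_brain_above_cutoff(self):
        bits = qtl_bits([coloc("brain_eqtl", r=0.35)])
        assert bits == (1, 0, 1)

    def test_blood_only_weak_correlation(self):
        assert qtl_bits([coloc("blood_eqtl", r=0.1)]) == (0, 1, 0)

    def test_no_eligible_plots_is_na(self):
        bits = qtl_bits([coloc("brain_eqtl", eligible=False), coloc("blood_eqtl", eligible=False)])
        assert bits == (0, 0, None)

    def test_isoqtl_counts_as_brain(self):
        assert qtl_bits([coloc("brain_isoqtl", r=-0.5)]) == (1, 0, 1)

    def test_negative_correlation_magnitude(self):
        assert qtl_bits([coloc("blood_eqtl", r=-0.31)]) == (0, 1, 1)

    def test_cutoff_strict(self):
        assert qtl_bits([coloc("blood_eqtl", r=0.3)]) == (0, 1, 0)


class TestLiteratureBit:
    def test_boundary_inclusive_at_five(self):
        assert literature_bit(5) == 1

    def test_four_hits_insufficient(self):
        assert literature_bit(4) == 0

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            literature_bit(-1)

    def test_query_strings(self):
        q_pd, q_gene = build_queries("P2RY12")
        assert q_pd == "P2RY12[Title/Abstract] AND Parkinson's[Title/Abstract]"
        assert q_gene == "P2RY12[Title/Abstract]"


class TestConstraintBit:
    def test_any_class_below_cutoff(self):
        rec = {"ci90_upper_syn": 1.4, "ci90_upper_mis": 1.2, "ci90_upper_lof": 0.30}
        assert constraint_bit(rec) == 1

    def test_boundary_strict(self):
        rec = {"ci90_upper_syn": 0.35, "ci90_upper_mis": 0.35, "ci90_upper_lof": 0.35}
        assert constraint_bit(rec) == 0

    def test_absent_record_na(self):
        assert constraint_bit(None) is None

    def test_all_uppers_missing_na(self):
        assert constraint_bit({"ci90_upper_syn": np.nan, "ci90_upper_mis": np.nan, "ci90_upper_lof": np.nan}) is None


class TestBurdenBit:
    def test_exome_significant(self):
        assert burden_bit({"min_p_exome": 1e-6, "min_p_imputed": np.nan}, 1480, 1026) == 1

    def test_both_nonsignificant(self):
        # 1e-4 > 0.05/1480 ~ 3.4e-5 and 1e-3 > 0.05/1026 ~ 4.9e-5
        assert burden_bit({"min_p_exome": 1e-4, "min_p_imputed": 1e-3}, 1480, 1026) == 0

    def test_absent_record_na(self):
        assert burden_bit(None, 1480, 1026) is None

    def test_absent_values_same_as_absent_gene(self):
        assert burden_bit({"min_p_exome": np.nan, "min_p_imputed": np.nan}, 1480, 1026) is None

    def test_gene_count_validation(self):
        with pytest.raises(ValueError):
            burden_bit({"min_p_exome": 0.5, "min_p_imputed": 0.5}, 0, 1026)


class TestFlagBits:
    FLAGS = GeneFlagSets.from_iterables(
        nominated_meta5=["A", "C"], pd_genes=["B", "C"], disease_genes=["C"]
    )

    @pytest.mark.parametrize(
        "gene,expected",
        [("B", (0, 1, 0)), ("C", (1, 1, 1)), ("Z", (0, 0, 0)), ("c", (1, 1, 1))],
    )
    def test_membership(self, gene, expected):
        assert flag_bits(gene, self.FLAGS) == expected


class TestAssemble:
    def locus(self):
        return Locus(1, "1", 1, 10_000_000, [Lead("rs1", "1", 5_000_000, 1e-10)])

    def genes(self, symbols):
        return pd.DataFrame(
            {
                "symbol": symbols,
                "chrom": "1",
                "start": [5_000_000 + i for i in range(len(symbols))],
                "end": [5_050_000 + i for i in range(len(symbols))],
                "strand": "+",
            }
        )

    def inputs(self, **kw):
        defaults = dict(
            expression=pd.DataFrame(columns=["gene", "context", "mean_tpm"]),
            coloc={},
            literature=pd.DataFrame(columns=["gene", "n_hits_pd"]),
            constraint=pd.DataFrame(columns=["gene", "ci90_upper_syn", "ci90_upper_mis", "ci90_upper_lof"]),
            burden=pd.DataFrame(columns=["gene", "min_p_exome", "min_p_imputed"]),
            flags=GeneFlagSets(),
            n_exome_genes=1480,
            n_imputed_genes=1026,
        )
        defaults.update(kw)
        return EvidenceInputs(**defaults)

    def test_empty_locus_empty_table(self):
        out = assemble_evidence(self.locus(), self.genes([]), self.inputs())
        assert len(out) == 0

    def test_all_ones_gene_scores_twelve_under_unit_weights(self):
        gene = "FULL"
        expr = pd.DataFrame(
            {"gene": gene, "context": ["brain", "nigra", "dan"], "mean_tpm": [9.0, 9.0, 9.0]}
        )
        col = {
            gene: [
                ColocResult(gene, "brain_eqtl", 30, True, 0.9),
                ColocResult(gene, "blood_eqtl", 30, True, 0.8),
            ]
        }
        out = assemble_evidence(
            self.locus(),
            self.genes([gene]),
            self.inputs(
                expression=expr,
                coloc=col,
                literature=pd.DataFrame({"gene": [gene], "n_hits_pd": [10]}),
                constraint=pd.DataFrame([{"gene": gene, "ci90_upper_syn": 2.0, "ci90_upper_mis": 2.0, "ci90_upper_lof": 0.1}]),
                burden=pd.DataFrame([{"gene": gene, "min_p_exome": 1e-9, "min_p_imputed": 0.9}]),
                flags=GeneFlagSets.from_iterables([gene], [gene], [gene]),
            ),
        )
        assert int(out["conclusion"].iloc[0]) == 12
        assert all(int(out[c].iloc[0]) == 1 for c in EVIDENCE_COLUMNS)

    def test_flag_only_gene_gets_na_pattern(self):
        out = assemble_evidence(
            self.locus(),
            self.genes(["G"]),
            self.inputs(flags=GeneFlagSets.from_iterables(pd_genes=["G"])),
        )
        row = out.iloc[0]
        for col in ("brain_expr", "nigra_expr", "dan_expr", "variant_intolerant", "burden", "qtl_correl"):
            assert pd.isna(row[col])
        assert (row["qtl_brain"], row["qtl_blood"]) == (0, 0)
        assert int(row["conclusion"]) == 1  # pd_gene only

    def test_duplicate_symbols_error(self):
        with pytest.raises(ValueError, match="duplicated"):
            assemble_evidence(self.locus(), self.genes(["G", "G"]), self.inputs())

    def test_na_confined_to_allowed_columns(self):
        out = assemble_evidence(self.locus(), self.genes(["G", "H"]), self.inputs())
        never_na = set(EVIDENCE_COLUMNS) - {
            "brain_expr", "nigra_expr", "dan_expr", "qtl_correl", "variant_intolerant", "burden",
        }
        for col in never_na:
            assert out[col].notna().all(), col

    def test_order_independence(self):
        gene_tables = self.genes(["A", "B", "C"])
        ins = self.inputs(flags=GeneFlagSets.from_iterables(pd_genes=["B"]))
        a = assemble_evidence(self.locus(), gene_tables, ins)
        b = assemble_evidence(self.locus(), gene_tables.iloc[::-1].reset_index(drop=True), ins)
        a_sorted = a.sort_values("gene").reset_index(drop=True)
        b_sorted = b.sort_values("gene").reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted)
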