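# Methods

## Locus partitioning

Summary statistics are partitioned per chromosome by iterative extraction:
the smallest-P variant with P < `p_threshold` (default 5 × 10⁻⁸, strict)
becomes a lead; it and all variants within `window` (default 1 Mb) of it are
removed from the pool, and the interval lead ± window (clipped at position 1)
is recorded. Extraction repeats until no significant variant remains. Regions
whose edge gap is ≤ `merge_gap` (default 100 kb, inclusive) are then merged
transitively until a fixpoint; a merged locus keeps all its leads in
extraction order.

Design choices where the procedure is underdetermined:

- **Region span** is lead ± window (union over merged leads), not the
  min/max of extracted variant positions. The extraction rule is phrased in
  terms of the window, and the two definitions coincide when variants are
  dense; the window definition is also what makes the coverage invariant
  (every significant variant inside exactly one locus) provable.
- **Merging is a fixpoint** (transitive closure): edges are compared on the
  current merged regions, repeatedly, until no pair is within the gap.
- **P ties** are broken by (chromosome, position) ascending, making the
  output invariant to input row order.
- Windows are clipped at position 1 only; chromosome lengths are unknown to
  the tool and not clipped against.

The test oracle restages these rules literally (full pool rescans, pairwise
region merging by exhaustion) and is kept independent of the production
sorted-interval implementation. Note that building ±window intervals around
*all* significant variants — rather than around extraction leads only — is a
different and non-equivalent procedure: a significant variant swallowed by a
stronger lead's window contributes no interval of its own, so its window
must not be allowed to chain two otherwise-separate regions together.

## LD estimation

LD between two biallelic variants is estimated from unphased diploid
genotypes by EM on the 3 × 3 genotype table. Every cell except the double
heterozygote resolves to a unique haplotype pair; the double-heterozygote
count is split between coupling (AB/ab) and repulsion (Ab/aB) phase in the
E-step according to the current haplotype frequencies. The M-step renormalises
expected haplotype counts. Iteration starts at linkage equilibrium and stops
when the largest frequency change is below `tol` (10⁻⁸) or after `max_iter`
(1000) iterations; the genotype log-likelihood is non-decreasing along the
trajectory (asserted in tests). When the data contain no double
heterozygote, the EM fixed point equals direct haplotype counting, which the
tests exploit as an independent oracle.

Conventions and numerics:

- Haplotype frequencies and D are reported on the **counted (ALT) allele**
  coding, so recoding dosages g → 2 − g at one variant flips the sign of D
  and leaves r² and D′ unchanged (minor-allele frequencies are available as
  accessors). D_max is min(p_A p_b, p_a p_B) for D > 0 and
  min(p_A p_B, p_a p_b) otherwise.
- Samples missing either dosage are dropped pairwise (complete-case LD); the
  complete-case count n is always reported and no sample-size floor is
  enforced beyond n ≥ 2.
- A monomorphic variant raises a distinct undefined-LD error rather than
  returning 0 — absence of polymorphism is not absence of association.
- Frequencies are clamped at 10⁻¹² before any division, and r²/D′ are capped
  at 1 to absorb rounding overshoot at the boundaries.
- Proxy search returns variants with r² **strictly** above the cutoff
  (default 0.7) within ± 1 Mb of the target, sorted by descending r² then
  position, excluding the target; pairs with undefined LD are skipped.

## Colocalization by P-value correlation

Locus-compare tables inner-join GWAS and eQTL associations on variant id
within the locus window; duplicate eQTL rows per variant (e.g. isoform-level
records) collapse to the smallest P with a warning. Eligibility — the
criterion for a table to have been plotted at all — requires the risk
variant or at least one r² > 0.7 proxy among the shared variants. The
QTL-correl statistic is the Pearson correlation of the two **−log₁₀ P**
columns: that is the scale of the plotted axes that the 0.3 cutoff was
chosen on, although a raw-P mode is available behind the `scale` argument.
Correlation is computed only for eligible tables with at least
`min_variants` shared variants (default 10, configurable down to 3 — the
floor guards against spurious perfect correlations on tiny joins) and is
undefined when either column has zero variance.

## Evidence bits

All cutoffs sit in one `Thresholds` object: `tpm_cutoff` = 5 TPM,
`correl_cutoff` = 0.3, `lit_min_hits` = 5, `oe_upper_max` = 0.35,
`alpha` = 0.05. Boundary semantics are deliberate and tested: expression and
constraint are **strict** (5.0 TPM → 0; CI upper 0.35 → 0), literature is
**inclusive** (5 hits → 1), QTL correlation is strict in |r|, and both LD
thresholds are strict.

- Expression: a gene absent from the expression table is NA in all three
  scored contexts; a gene present but missing one scored context is NA in
  that context only (data absence, not evidence of absence).
- QTL: brain eQTL and brain isoQTL both set the brain flag; qtl_correl is NA
  exactly when neither the brain nor the blood flag is set.
- Burden: Bonferroni denominators default to the number of genes with data
  in the supplied table per family (exome / imputed); the packaged
  worked-example bundles use the published 1480/1026 counts as metadata. A
  gene with a record but both minima missing is treated the same as an
  absent gene (NA) — the two encodings are not distinguishable upstream.
- Literature counts arrive as a table; the exact PubMed query strings
  (`GENE[Title/Abstract] AND Parkinson's[Title/Abstract]`) are emitted by
  `build_queries` for reproducibility, but no live querying is performed.
- Gene-set flags match symbols upper-cased and exactly; no alias resolution
  is attempted (gene-name ambiguity such as *SHE*/*MAL* is a known hazard of
  automated matching and is out of scope).

NA can occur only in the six columns where a source can be missing
(expression × 3, qtl_correl, variant_intolerant, burden); the QTL
eligibility flags, literature and membership flags are always 0/1.

## Scoring

The conclusion score is Σ w_c · bit_c with integer weights 0–4 per column
(default all 1) and NA contributing 0; NA is preserved in the output table,
never coerced to 0 in the data itself. Fractional weights are rejected.
Ranking is by descending score with alphabetical tie-break, so output is
deterministic. The score is a transparent heuristic sum — no probabilistic
calibration is implied, which is why the weights are user-facing.

## Synthetic data

The generator plants known structure at desk scale; its defaults are the
standing study conditions for all seeded tests:

| parameter | default | rationale |
|---|---|---|
| n_samples | 400 diploids | stable EM LD estimates at desk scale |
| n_variants / locus | 100 | enough for windows, joins and proxies |
| block_size | 10 | haplotype blocks small relative to the locus |
| copy_prob | 0.95 | within-block r² high enough to yield proxies |
| maf_range | 0.1–0.5 | common variants, away from monomorphic edges |
| effect_z | 8 | causal P ≈ 10⁻¹⁵, comfortably genome-wide significant |
| eqtl_noise | 1.0 | colocalized profiles correlate ≈ 0.9, not perfectly |
| coloc / non-coloc genes | 3 / 3 | balanced recovery measurement |

Haplotypes follow a block-copying model (each variant copies its left
neighbour within the block with probability `copy_prob`, else redraws at its
own MAF), which gives planted, analytically checkable LD — not a coalescent
model. Summary statistics are simulated directly on the z-score scale
(z = r(v, causal) · effect_z + N(0,1)) rather than via individual-level
phenotype regression: the downstream statistical structure is the same and
generation is instantaneous. Colocalized genes reuse the GWAS z profile plus
noise; non-colocalized genes get an independent causal in a different block.
The block-to-locus ratio (10/100) matters: with disjoint 10-variant signal
blocks, the mechanical anti-correlation between a GWAS-high/eQTL-low block
pattern stays near |r| ≈ 0.1, well under the 0.3 cutoff, so specificity does
not depend on noise alone.

What the generator does **not** emulate: human allele-frequency spectra,
recombination-map heterogeneity, population structure, imputation
uncertainty, winner's-curse effect-size inflation, or trans-QTLs. Passing
recovery tests therefore demonstrates the pipeline's correctness and
discrimination under clean planted structure, not expected performance on
consortium data.

## Worked-example reconstructions

The two published use cases (P2RY12 at locus 16, DYRK1A at locus 78) are
rebuilt by `locuslens.demo` from the facts stated for them: the risk
variant's printed OR/SE/P, which expression contexts clear 5 TPM, which
locus-compare tables exist and correlate, the constraint/burden outcomes and
gene-set memberships. The regional association profiles around each risk
variant are synthetic (seeded exponential LD-decay shapes peaking at the
printed P value) because the underlying consortium tables are not
redistributable; every evidence bit and the conclusion score are then
*derived* by the ordinary pipeline code, and the demo asserts nothing about
their values. `scripts/acceptance.py` reports these two recomputed scores.

## Problem sizes

The default test suite runs in well under a minute: the partition oracle
covers 100 seeded tables of ≤ 200 variants, the LD oracle enumerates all
phase-unambiguous 4-sample genotype tables plus 1000 random flip/symmetry
fixtures, and colocalization recovery uses 20 seeded replicates of the
default generator (6 genes × 3 datasets each). These sizes were chosen as
the smallest at which the checked properties are non-trivial.

## Known limitations

- LD is panel-based; no reference panels ship with the package, and panel
  ancestry mismatch is the user's responsibility.
- The locus-compare correlation is a screening statistic, not a formal
  colocalization posterior; no Bayesian coloc is computed.
- No genome-build liftover or rsID reannotation; inputs must share one build.
- Multi-allelic variants are excluded rather than decomposed, both in
  summary statistics and in the panel, because the LD and proxy machinery
  assumes biallelic sites.
- CADD scores and allele frequencies on coding variants are passthrough
  columns; computing them requires external annotation databases.
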