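"""Partition GWAS summary statistics into risk loci.

Two genome-wide-significant peaks 2.05 Mb apart leave an edge gap of 50 kb
between their 1-Mb windows, so they merge into one locus; a third peak on
another chromosome stands alone.
"""

import pandas as pd

from locuslens import PartitionConfig, partition_loci

MB = 1_000_000

sumstats = pd.DataFrame(
    {
        "variant_id": ["rs_a", "rs_b", "rs_c", "rs_null"],
        "chrom": ["1", "1", "2", "2"],
        "pos": [5 * MB, 5 * MB + 2_050_000, 30 * MB, 31 * MB],
        "p": [1e-10, 1e-9, 4e-8, 0.2],
        "beta": [0.05, 0.04, -0.06, 0.0],
        "se": [0.01, 0.01, 0.012, 0.01],
    }
)

for locus in partition_loci(sumstats, PartitionConfig()):
    leads = ",".join(v.variant_id for v in locus.lead_variants)
    print(
        f"locus {locus.locus_id}: chr{locus.chrom}:{locus.start:,}-{locus.end:,}"
        f"  leads=[{leads}]  min P={locus.min_p:.2e}"
    )

# locus 1 spans both chr1 peaks (edge gap 50 kb <= 100 kb merges them);
# locus 2 is the lone chr2 peak; rs_null (P = 0.2) founds no locus.
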