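import numpy as np
import pandas as pd
import pytest

from locuslens.ld import GenotypePanel


def make_sumstats(rows):
    """rows: (variant_id, chrom, pos, p) tuples -> minimal sumstats frame."""
    df = pd.DataFrame(rows, columns=["variant_id", "chrom", "pos", "p"])
    df["beta"] = 0.0
    df["se"] = 0.01
    df["allele_effect"] = "A"
    df["allele_other"] = "G"
    return df


def panel_from_dosages(dosages, pos=None, chrom="1", ids=None):
    """samples x variants dosage array -> GenotypePanel."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"v{j}" for j in range(m)]
    pos = pos if pos is not None else [1000 * (j + 1) for j in range(m)]
    return GenotypePanel(
        variant_ids=ids,
        chrom=np.array([chrom] * m, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        dosages=dosages,
        samples=[f"S{i}" for i in range(n)],
    )


@pytest.fixture
def tiny_expression():
    return pd.DataFrame(
        {
            "gene": ["G1", "G1", "G1", "G2"],
            "context": ["brain", "nigra", "dan", "brain"],
            "mean_tpm": [6.0, 2.0, 7.0, 5.0],
        }
    )
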