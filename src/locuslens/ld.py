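"""Pairwise linkage disequilibrium from an unphased diploid panel.

Haplotype frequencies for a pair of biallelic variants are estimated by
expectation-maximisation over the 3x3 genotype table: every genotype pair
except the double heterozygote resolves to a unique pair of haplotypes, and
the double heterozygote is split between the coupling (AB/ab) and repulsion
(Ab/aB) phases according to the current frequency estimates. From the
converged haplotype frequencies the usual summaries follow:

    D   = f_AB - p_A * p_B
    D'  = |D| / D_max
    r^2 = D^2 / (p_A * p_a * p_B * p_b)

where allele ``A``/``B`` denotes the dosage-counted (ALT) allele at each
variant and ``a``/``b`` its complement. Frequencies are reported on that
ALT coding, so recoding dosages g -> 2 - g at one variant flips the sign of
D and leaves D' and r^2 unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

_FREQ_FLOOR = 1e-12  # clamp before division at monomorphic boundaries


class LDUndefinedError(ValueError):
    """LD is not defined for this pair of dosage vectors."""


class MonomorphicVariantError(LDUndefinedError):
    """A variant carries only one allele among the complete-case samples."""


class InsufficientDataError(LDUndefinedError):
    """Fewer than two samples have non-missing dosages at both variants."""


@dataclass(frozen=True)
class LDStats:
    """EM haplotype-frequency estimate and derived LD summaries.

    ``p_a`` / ``p_b`` are the counted (ALT) allele frequencies; ``hap_freqs``
    is (f_AB, f_Ab, f_aB, f_ab) on the same coding and sums to one.
    """

    p_a: float
    p_b: float
    hap_freqs: tuple[float, float, float, float]
    d: float
    d_prime: float
    r2: float
    n: int
    converged: bool
    n_iter: int
    log_likelihood: float = field(default=float("nan"), compare=False)

    @property
    def maf_a(self) -> float:
        return min(self.p_a, 1.0 - self.p_a)

    @property
    def maf_b(self) -> float:
        return min(self.p_b, 1.0 - self.p_b)


class GenotypePanel:
    """Dosage matrix (samples x variants) with variant metadata.

    Dosages count ALT alleles: 0, 1, 2, or NaN for missing. Only biallelic
    variants belong in a panel; the VCF reader enforces this.
    """

    def __init__(
        self,
        variant_ids: list[str],
        chrom: np.ndarray,
        pos: np.ndarray,
        dosages: np.ndarray,
        samples: list[str],
    ):
        dosages = np.asarray(dosages, dtype=float)
        if dosages.shape != (len(samples), len(variant_ids)):
            raise ValueError(
                f"dosage matrix {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variant_ids)} variants"
            )
        if len(set(variant_ids)) != len(variant_ids):
            raise ValueError("duplicate variant ids in panel")
        self.variant_ids = list(variant_ids)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.dosages = dosages
        self.samples = list(samples)
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variant_ids)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not in panel") from None

    def dosage(self, variant_id: str) -> np.ndarray:
        return self.dosages[:, self.index_of(variant_id)]

    def variants_in_region(self, chrom: str, start: int, end: int) -> list[str]:
        """Variant ids on ``chrom`` with start <= pos <= end, position order."""
        mask = (self.chrom == str(chrom)) & (self.pos >= start) & (self.pos <= end)
        idx = np.nonzero(mask)[0]
        return [self.variant_ids[i] for i in idx[np.argsort(self.pos[idx], kind="stable")]]

    @classmethod
    def from_dosage_frame(cls, df) -> "GenotypePanel":
        """Build a panel from a fixture table.

        Expects columns ``variant_id``, ``chrom``, ``pos`` followed by one
        column per sample holding dosages (NA allowed).
        """
        meta = ["variant_id", "chrom", "pos"]
        sample_cols = [c for c in df.columns if c not in meta]
        dosages = df[sample_cols].to_numpy(dtype=float).T
        return cls(
            variant_ids=[str(v) for v in df["variant_id"]],
            chrom=np.array([str(c) for c in df["chrom"]], dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            dosages=dosages,
            samples=[str(c) for c in sample_cols],
        )


def _genotype_counts(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """3x3 table n[i, j] of samples with dosage i at A and j at B."""
    counts = np.zeros((3, 3), dtype=float)
    for i in range(3):
        for j in range(3):
            counts[i, j] = np.sum((ga == i) & (gb == j))
    return counts


def _loglik(counts: np.ndarray, f: np.ndarray) -> float:
    """Multinomial log-likelihood of the genotype table under hap freqs f.

    f = (f_AB, f_Ab, f_aB, f_ab); genotype probabilities follow from random
    union of haplotypes (Hardy-Weinberg at the haplotype level).
    """
    fab, fAb, faB, fxx = f[0], f[1], f[2], f[3]  # AB, Ab, aB, ab
    prob = np.empty((3, 3))
    prob[2, 2] = fab * fab
    prob[2, 1] = 2 * fab * fAb
    prob[2, 0] = fAb * fAb
    prob[1, 2] = 2 * fab * faB
    prob[1, 1] = 2 * fab * fxx + 2 * fAb * faB
    prob[1, 0] = 2 * fAb * fxx
    prob[0, 2] = faB * faB
    prob[0, 1] = 2 * faB * fxx
    prob[0, 0] = fxx * fxx
    with np.errstate(divide="ignore"):
        logp = np.log(np.maximum(prob, _FREQ_FLOOR))
    return float(np.sum(counts * logp))


def em_haplotypes(
    ga: np.ndarray,
    gb: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> LDStats:
    """Estimate two-locus haplotype frequencies and LD from unphased dosages.

    Samples missing either dosage are dropped (complete-case). When the data
    contain no double heterozygote the phase is unambiguous and the EM fixed
    point equals direct haplotype counting.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 complete-case samples.
    MonomorphicVariantError
        Either variant monomorphic among complete cases: LD undefined,
        deliberately distinct from a numeric 0.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    if ga.shape != gb.shape:
        raise ValueError("dosage vectors differ in length")
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep], gb[keep]
    n = int(ga.size)
    if n < 2:
        raise InsufficientDataError(f"only {n} complete-case sample(s)")
    if not (np.all(np.isin(ga, (0, 1, 2))) and np.all(np.isin(gb, (0, 1, 2)))):
        raise ValueError("dosages must be 0, 1, 2 or NA")
    p_a = float(np.mean(ga)) / 2.0
    p_b = float(np.mean(gb)) / 2.0
    if p_a <= 0.0 or p_a >= 1.0:
        raise MonomorphicVariantError("first variant is monomorphic in complete cases")
    if p_b <= 0.0 or p_b >= 1.0:
        raise MonomorphicVariantError("second variant is monomorphic in complete cases")

    counts = _genotype_counts(ga, gb)
    n_dh = counts[1, 1]  # double heterozygotes: the only ambiguous cell

    # Haplotype counts fixed by unambiguous genotype cells. Order: AB, Ab, aB, ab.
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],
        ],
        dtype=float,
    )

    # Linkage-equilibrium start.
    f = np.array(
        [p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)]
    )
    total = 2.0 * n
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = max(f[0] * f[3] + f[1] * f[2], _FREQ_FLOOR)
        pi = f[0] * f[3] / denom  # P(coupling phase | double het)
        new = base + n_dh * np.array([pi, 1 - pi, 1 - pi, pi])
        new /= total
        delta = float(np.max(np.abs(new - f)))
        f = new
        if delta < tol:
            converged = True
            break

    f = np.maximum(f, 0.0)
    f /= f.sum()
    p_a_hat = f[0] + f[1]
    p_b_hat = f[0] + f[2]
    d = float(f[0] - p_a_hat * p_b_hat)
    q_a, q_b = 1.0 - p_a_hat, 1.0 - p_b_hat
    if d > 0:
        d_max = min(p_a_hat * q_b, q_a * p_b_hat)
    else:
        d_max = min(p_a_hat * p_b_hat, q_a * q_b)
    d_prime = abs(d) / max(d_max, _FREQ_FLOOR) if d != 0.0 else 0.0
    denom_r2 = max(p_a_hat * q_a * p_b_hat * q_b, _FREQ_FLOOR)
    r2 = d * d / denom_r2
    # EM estimates can overshoot the open boundary by rounding only.
    d_prime = float(min(d_prime, 1.0))
    r2 = float(min(r2, 1.0))

    return LDStats(
        p_a=float(p_a_hat),
        p_b=float(p_b_hat),
        hap_freqs=tuple(float(x) for x in f),
        d=d,
        d_prime=d_prime,
        r2=r2,
        n=n,
        converged=converged,
        n_iter=it,
        log_likelihood=_loglik(counts, f),
    )


def em_trajectory_loglik(ga: np.ndarray, gb: np.ndarray, max_iter: int = 1000) -> list[float]:
    """Log-likelihood after each EM iteration; monotone non-decreasing.

    Exposed for testing the EM itself; mirrors :func:`em_haplotypes` exactly.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep], gb[keep]
    n = ga.size
    p_a = float(np.mean(ga)) / 2.0
    p_b = float(np.mean(gb)) / 2.0
    counts = _genotype_counts(ga, gb)
    n_dh = counts[1, 1]
    base = np.array(
        [
            2 * counts[2, 2] + counts[2, 1] + counts[1, 2],
            2 * counts[2, 0] + counts[2, 1] + counts[1, 0],
            2 * counts[0, 2] + counts[0, 1] + counts[1, 2],
            2 * counts[0, 0] + counts[0, 1] + counts[1, 0],
        ],
        dtype=float,
    )
    f = np.array([p_a * p_b, p_a * (1 - p_b), (1 - p_a) * p_b, (1 - p_a) * (1 - p_b)])
    out = [_loglik(counts, f)]
    for _ in range(max_iter):
        denom = max(f[0] * f[3] + f[1] * f[2], _FREQ_FLOOR)
        pi = f[0] * f[3] / denom
        new = (base + n_dh * np.array([pi, 1 - pi, 1 - pi, pi])) / (2.0 * n)
        if float(np.max(np.abs(new - f))) < 1e-8:
            f = new
            out.append(_loglik(counts, f))
            break
        f = new
        out.append(_loglik(counts, f))
    return out


def ld_pair_report(a: str, b: str, panel: GenotypePanel, **kwargs) -> LDStats:
    """LD between two panel variants; symmetric in r2 and D'."""
    return em_haplotypes(panel.dosage(a), panel.dosage(b), **kwargs)


def find_proxies(
    target: str,
    panel: GenotypePanel,
    region: tuple[int, int] | None = None,
    r2_min: float = 0.7,
) -> list[tuple[str, LDStats]]:
    """Variants in LD with ``target`` at r2 strictly above ``r2_min``.

    ``region`` is a (start, end) bp interval on the target's chromosome;
    defaults to +/- 1 Mb around the target. The target itself is excluded.
    Pairs with undefined LD (monomorphic partner) are skipped. Results are
    sorted by descending r2, then position.
    """
    idx = panel.index_of(target)
    chrom = panel.chrom[idx]
    pos = int(panel.pos[idx])
    if region is None:
        region = (max(1, pos - 1_000_000), pos + 1_000_000)
    ga = panel.dosage(target)
    out: list[tuple[str, LDStats, int]] = []
    for vid in panel.variants_in_region(str(chrom), region[0], region[1]):
        if vid == target:
            continue
        try:
            stats = em_haplotypes(ga, panel.dosage(vid))
        except LDUndefinedError:
            continue
        if stats.r2 > r2_min:
            out.append((vid, stats, int(panel.pos[panel.index_of(vid)])))
    out.sort(key=lambda t: (-t[1].r2, t[2]))
    return [(vid, stats) for vid, stats, _ in out]


def counting_haplotypes(ga: np.ndarray, gb: np.ndarray) -> LDStats:
    """Direct-counting LD for phase-unambiguous data (no double heterozygote).

    Independent of the EM path; used as its oracle in tests.
    """
    ga = np.asarray(ga, dtype=float)
    gb = np.asarray(gb, dtype=float)
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga, gb = ga[keep], gb[keep]
    n = int(ga.size)
    if n < 2:
        raise InsufficientDataError(f"only {n} complete-case sample(s)")
    if np.any((ga == 1) & (gb == 1)):
        raise ValueError("double heterozygote present: phase ambiguous")
    counts = {"AB": 0.0, "Ab": 0.0, "aB": 0.0, "ab": 0.0}
    for x, y in zip(ga, gb):
        # each diploid contributes two haplotypes with known phase
        a_alleles = ["A"] * int(x) + ["a"] * (2 - int(x))
        b_alleles = ["B"] * int(y) + ["b"] * (2 - int(y))
        if int(x) == 1:  # het at A, hom at B: pairing irrelevant
            counts["A" + b_alleles[0]] += 1
            counts["a" + b_alleles[1]] += 1
        elif int(y) == 1:
            counts[a_alleles[0] + "B"] += 1
            counts[a_alleles[1] + "b"] += 1
        else:
            counts[a_alleles[0] + b_alleles[0]] += 1
            counts[a_alleles[1] + b_alleles[1]] += 1
    total = 2.0 * n
    f = np.array([counts["AB"], counts["Ab"], counts["aB"], counts["ab"]]) / total
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    if p_a <= 0 or p_a >= 1 or p_b <= 0 or p_b >= 1:
        raise MonomorphicVariantError("monomorphic variant")
    d = float(f[0] - p_a * p_b)
    q_a, q_b = 1 - p_a, 1 - p_b
    d_max = min(p_a * q_b, q_a * p_b) if d > 0 else min(p_a * p_b, q_a * q_b)
    d_prime = abs(d) / max(d_max, _FREQ_FLOOR) if d != 0.0 else 0.0
    r2 = d * d / max(p_a * q_a * p_b * q_b, _FREQ_FLOOR)
    table = _genotype_counts(ga, gb)
    return LDStats(
        p_a=float(p_a),
        p_b=float(p_b),
        hap_freqs=tuple(float(x) for x in f),
        d=d,
        d_prime=float(min(d_prime, 1.0)),
        r2=float(min(r2, 1.0)),
        n=n,
        converged=True,
        n_iter=0,
        log_likelihood=_loglik(table, f),
    )
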