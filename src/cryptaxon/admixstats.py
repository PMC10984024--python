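"""Three- and four-population admixture statistics with block-jackknife errors.

All estimators are ratio-of-sums over per-site numerator/denominator terms;
standard errors come from a delete-one block jackknife over contiguous SNP
blocks (default block size 100,000 SNPs), which is robust to linkage.

Sign conventions (fixed, to remove ambiguity):

* f3(X; A, B) negative with |Z| > 5 is evidence that X is admixed between
  A-related and B-related sources. The estimator subtracts the target's
  sampling-heterozygosity correction and (optionally) normalises by the
  target's unbiased heterozygosity.
* Patterson's D uses ABBA = (1-p1) p2 p3 (1-p4) and BABA = p1 (1-p2) p3 (1-p4)
  with alt-allele frequencies; D = sum(ABBA-BABA)/sum(ABBA+BABA). Gene flow
  between P3 and P2 drives D positive, between P3 and P1 negative; |Z| > 5
  is reported as significant.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AlleleCounts


@dataclass
class BlockStat:
    """A ratio statistic with delete-one-block jackknife SE and Z-score."""

    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    block_num: np.ndarray
    block_den: np.ndarray


def block_jackknife(block_num: np.ndarray, block_den: np.ndarray, n_sites: int = 0) -> BlockStat:
    """Delete-one-block jackknife for a ratio-of-sums statistic.

    The point estimate is the all-blocks ratio; SE^2 is
    ``(m-1)/m * sum_j (R_-j - mean(R_-.))^2``. Z is NaN when SE is zero.
    """
    num = np.asarray(block_num, dtype=np.float64)
    den = np.asarray(block_den, dtype=np.float64)
    m = len(num)
    if m < 2:
        raise ValueError("need >= 2 blocks for a jackknife SE")
    tot_n, tot_d = num.sum(), den.sum()
    if tot_d == 0:
        return BlockStat(np.nan, np.nan, np.nan, m, n_sites, num, den)
    est = tot_n / tot_d
    with np.errstate(invalid="ignore", divide="ignore"):
        loo = (tot_n - num) / (tot_d - den)
    se = float(np.sqrt((m - 1) / m * np.sum((loo - loo.mean()) ** 2)))
    z = est / se if se > 0 else np.nan
    return BlockStat(float(est), se, float(z), m, n_sites, num, den)


def _freqs(ac: AlleleCounts):
    n = ac.n_called.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, ac.counts[:, 1] / n, np.nan)
    return p, n

def _block_sums(num: np.ndarray, den: np.ndarray, use: np.ndarray, block_size: int):
    """Group included sites into contiguous blocks of block_size SNPs."""
    idx = np.flatnonzero(use)
    bid = np.arange(len(idx)) // block_size
    bn = np.bincount(bid, weights=num[idx])
    bd = np.bincount(bid, weights=den[idx])
    return bn, bd, len(idx)


def f3(
    ac_target: AlleleCounts,
    ac_a: AlleleCounts,
    ac_b: AlleleCounts,
    block_size_snps: int = 100_000,
    normalized: bool = True,
) -> BlockStat:
    """Admixture f3(target; A, B) with jackknife Z.

    Per site, numerator ``(x-a)(x-b) - x(1-x)/(n_x-1)`` with x, a, b the
    sample alt frequencies and n_x the target's called-allele count; the
    (optional) denominator ``2 x (1-x) n_x/(n_x-1)`` is the target's unbiased
    heterozygosity. Sites need >= 2 called alleles in every cohort.
    """
    x, nx = _freqs(ac_target)
    a, na = _freqs(ac_a)
    b, nb = _freqs(ac_b)
    use = (nx >= 2) & (na >= 2) & (nb >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (x - a) * (x - b) - x * (1 - x) / (nx - 1)
        den = 2.0 * x * (1 - x) * nx / (nx - 1) if normalized else np.ones_like(x)
    if normalized:
        use &= den > 0
    bn, bd, ns = _block_sums(num, den, use, block_size_snps)
    if len(bn) < 2:  # tiny inputs: still report the point estimate
        est = float(bn.sum() / bd.sum()) if bd.sum() != 0 else np.nan
        return BlockStat(est, np.nan, np.nan, len(bn), ns, bn, bd)
    return block_jackknife(bn, bd, ns)


def outgroup_f3(
    ac_test: AlleleCounts,
    ac_ref: AlleleCounts,
    ac_outgroup: AlleleCounts,
    block_size_snps: int = 100_000,
) -> BlockStat:
    """Outgroup-f3(test, ref; outgroup): shared drift of test and ref since
    the outgroup. Same estimator with the outgroup as target; larger values
    mean a closer relationship."""
    return f3(ac_outgroup, ac_test, ac_ref, block_size_snps=block_size_snps)


def patterson_d(
    ac1: AlleleCounts,
    ac2: AlleleCounts,
    ac3: AlleleCounts,
    ac4_outgroup: AlleleCounts,
    block_size_snps: int = 100_000,
) -> BlockStat:
    """Patterson's D (ABBA-BABA) for (((P1,P2),P3),O) with jackknife Z.

    Sites require at least one called allele in each cohort; a polymorphic
    outgroup is retained (frequency-based formulation).
    """
    p1, n1 = _freqs(ac1)
    p2, n2 = _freqs(ac2)
    p3, n3 = _freqs(ac3)
    p4, n4 = _freqs(ac4_outgroup)
    use = (n1 >= 1) & (n2 >= 1) & (n3 >= 1) & (n4 >= 1)
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    bn, bd, ns = _block_sums(abba - baba, abba + baba, use, block_size_snps)
    if len(bn) < 2:
        tot = bd.sum()
        est = float(bn.sum() / tot) if tot != 0 else np.nan
        return BlockStat(est, np.nan, np.nan, len(bn), ns, bn, bd)
    return block_jackknife(bn, bd, ns)
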