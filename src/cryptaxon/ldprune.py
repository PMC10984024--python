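"""Linkage-disequilibrium pruning of genotype dosages in moving SNP windows.

The r statistic is the Pearson correlation of alt-allele dosage vectors over
pairwise-complete samples (missing dosages excluded pair by pair).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PruneParams:
    window_size_snps: int = 500
    step_snps: int = 250
    r2_threshold: float = 0.01
    n_iterations: int = 1

    def __post_init__(self) -> None:
        if self.step_snps > self.window_size_snps:
            raise ValueError("step must be <= window size")
        if not 0.0 < self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def rogers_huff_r(dosages: np.ndarray) -> np.ndarray:
    """Pairwise dosage correlation matrix over pairwise-complete samples.

    ``dosages`` is (variants, samples), values 0..2 with NaN for missing.
    Zero-variance pairs and pairs with fewer than two complete observations
    return NaN.
    """
    x = np.asarray(dosages, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (variants >= 2, samples) dosage matrix")
    valid = ~np.isnan(x)
    xz = np.where(valid, x, 0.0)
    v = valid.astype(np.float64)
    n = v @ v.T
    sx = xz @ v.T          # sum of x over pairwise-complete samples
    sxx = (xz * xz) @ v.T
    sxy = xz @ xz.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = np.sqrt(varx * varx.T)
        r = np.where((n >= 2) & (denom > 0), cov / denom, np.nan)
    return r


def locate_unlinked(dosages: np.ndarray, params: PruneParams | None = None) -> np.ndarray:
    """Greedy forward LD prune; returns a boolean keep-mask over variants.

    Within each moving window (advancing by ``step_snps``), for every retained
    pair with r^2 above threshold the *later* variant is dropped. Pairs with
    undefined r are treated as unlinked. Deterministic for a fixed input
    order; iterate ``n_iterations`` times (one pass by default).
    """
    if params is None:
        params = PruneParams()
    x = np.asarray(dosages, dtype=np.float64)
    n_var = x.shape[0]
    keep = np.ones(n_var, dtype=bool)
    for _ in range(params.n_iterations):
        changed = False
        kept_idx = np.flatnonzero(keep)
        # windows slide over the currently retained variants, so convergence
        # (a pass removing nothing) makes the result a fixed point
        for start in range(0, len(kept_idx), params.step_snps):
            idx = kept_idx[start: start + params.window_size_snps]
            idx = idx[keep[idx]]
            if len(idx) < 2:
                continue
            r = rogers_huff_r(x[idx])
            with np.errstate(invalid="ignore"):
                linked = (r**2 > params.r2_threshold)
            linked &= ~np.isnan(r)
            local_keep = np.ones(len(idx), dtype=bool)
            for i in range(len(idx)):
                if not local_keep[i]:
                    continue
                drop = linked[i] & local_keep
                drop[: i + 1] = False
                if drop.any():
                    local_keep[drop] = False
                    changed = True
            keep[idx[~local_keep]] = False
            if start + params.window_size_snps >= len(kept_idx):
                break
        if not changed:
            break
    return keep
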