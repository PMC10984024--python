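"""Windowed diversity and divergence statistics over allele counts.

Per-base statistics use windows of a fixed number of *accessible* bases
(default 100 kb) produced by :func:`cryptaxon.core.accessible_windows`;
the accessible-base count is the denominator, so windows are comparable
even where the genome is patchily callable.

Estimators
----------
pi        mean pairwise difference per site, ``2 c_ref c_alt / (n (n-1))``,
          summed over sites in a window and divided by accessible bases.
theta_w   Watterson's estimator ``S / a1`` per accessible base.
Tajima_D  ``(pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1))`` with the standard
          constants; the sample size entering the constants is the median
          per-site called-allele count within the window (sites may differ
          in missingness). Undefined (NaN) when S = 0 or n < 4.
FST       Hudson's estimator in the Bhatia et al. formulation: per site
          N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
          D = p1(1-p2) + p2(1-p1), combined as a ratio of sums (never a
          mean of per-site ratios). Reported unclipped.
Dxy       per site p1(1-p2) + p2(1-p1), summed and divided by accessible
          bases (absolute divergence).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import AlleleCounts, assign_windows


def _window_sum(values: np.ndarray, wi: np.ndarray, n_windows: int) -> np.ndarray:
    ok = wi >= 0
    return np.bincount(wi[ok], weights=values[ok], minlength=n_windows)


def site_pi(ac: AlleleCounts) -> np.ndarray:
    """Per-site mean pairwise difference; 0 where fewer than 2 called alleles."""
    n = ac.n_called.astype(np.float64)
    c0, c1 = ac.counts[:, 0].astype(np.float64), ac.counts[:, 1].astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * c0 * c1 / (n * (n - 1.0)), 0.0)
    return pi


def pi_window(ac: AlleleCounts, pos: np.ndarray, windows: pd.DataFrame) -> pd.DataFrame:
    """Nucleotide diversity per accessible base, per window."""
    wi = assign_windows(pos, windows)
    out = windows.copy()
    pi_sum = _window_sum(site_pi(ac), wi, len(windows))
    nv = np.bincount(wi[wi >= 0], minlength=len(windows))
    na = out["n_accessible"].to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pi_per_base"] = np.where(na > 0, pi_sum / na, np.nan)
    out["n_variants_used"] = nv
    return out


def _harmonics(n: int) -> tuple[float, float]:
    i = np.arange(1, n)
    return float((1.0 / i).sum()), float((1.0 / i**2).sum())


def tajima_d_constants(n: int) -> dict[str, float]:
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return {"a1": a1, "a2": a2, "e1": c1 / a1, "e2": c2 / (a1**2 + a2)}


def diversity_window(ac: AlleleCounts, pos: np.ndarray, windows: pd.DataFrame) -> pd.DataFrame:
    """pi, Watterson's theta and Tajima's D per window.

    The per-window sample size for the Tajima constants is the median
    called-allele count over segregating sites in the window (rounded).
    """
    wi = assign_windows(pos, windows)
    seg = ac.is_segregating()
    pi_site = site_pi(ac)
    out = pi_window(ac, pos, windows)
    n_called = ac.n_called

    theta, tajd = np.full(len(windows), np.nan), np.full(len(windows), np.nan)
    na = out["n_accessible"].to_numpy(dtype=np.float64)
    for w in range(len(windows)):
        in_w = (wi == w) & seg
        s = int(in_w.sum())
        if s == 0:
            theta[w] = 0.0 if na[w] > 0 else np.nan
            continue
        n = int(round(float(np.median(n_called[in_w]))))
        if n < 2:
            continue
        const = tajima_d_constants(n)
        theta[w] = s / const["a1"] / na[w] if na[w] > 0 else np.nan
        if n < 4 or s < 1:
            continue
        var = const["e1"] * s + const["e2"] * s * (s - 1)
        if var <= 0:
            continue
        tajd[w] = (pi_site[in_w].sum() - s / const["a1"]) / np.sqrt(var)
    out["theta_w_per_base"] = theta
    out["tajima_d"] = tajd
    return out


def hudson_fst_sites(ac1: AlleleCounts, ac2: AlleleCounts) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Bhatia numerator and denominator; NaN where a cohort has n < 2."""
    n1 = ac1.n_called.astype(np.float64)
    n2 = ac2.n_called.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, ac1.counts[:, 1] / n1, np.nan)
        p2 = np.where(n2 > 0, ac2.counts[:, 1] / n2, np.nan)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    bad = (n1 < 2) | (n2 < 2)
    num[bad] = np.nan
    den[bad] = np.nan
    return num, den


def hudson_fst(
    ac1: AlleleCounts,
    ac2: AlleleCounts,
    pos: np.ndarray | None = None,
    windows: pd.DataFrame | None = None,
):
    """Hudson/Bhatia FST as a ratio of sums.

    Without windows, returns the genome-wide scalar. With ``pos`` and
    ``windows``, returns the window table with an ``fst`` column plus the
    genome-wide value.
    """
    num, den = hudson_fst_sites(ac1, ac2)
    ok = ~np.isnan(num)
    total = float(np.sum(num[ok]) / np.sum(den[ok])) if den[ok].sum() != 0 else np.nan
    if windows is None:
        return total
    wi = assign_windows(np.asarray(pos), windows)
    out = windows.copy()
    nsum = _window_sum(np.where(ok, num, 0.0), wi, len(windows))
    dsum = _window_sum(np.where(ok, den, 0.0), wi, len(windows))
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fst"] = np.where(dsum != 0, nsum / dsum, np.nan)
    out["n_variants_used"] = np.bincount(wi[(wi >= 0) & ok], minlength=len(windows))
    return out, total


def dxy(
    ac1: AlleleCounts,
    ac2: AlleleCounts,
    pos: np.ndarray,
    windows: pd.DataFrame,
) -> pd.DataFrame:
    """Absolute divergence per accessible base, per window."""
    n1 = ac1.n_called.astype(np.float64)
    n2 = ac2.n_called.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, ac1.counts[:, 1] / n1, np.nan)
        p2 = np.where(n2 > 0, ac2.counts[:, 1] / n2, np.nan)
    site = p1 * (1 - p2) + p2 * (1 - p1)
    site = np.where((n1 >= 2) & (n2 >= 2), site, 0.0)
    wi = assign_windows(pos, windows)
    out = windows.copy()
    na = out["n_accessible"].to_numpy(dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["dxy_per_base"] = np.where(na > 0, _window_sum(site, wi, len(windows)) / na, np.nan)
    return out


def folded_sfs(ac: AlleleCounts, drop_incomplete: bool = True) -> np.ndarray:
    """Folded site-frequency spectrum over minor-allele counts 1..n//2.

    Requires a fixed cohort size across sites; with ``drop_incomplete``
    (default) sites with any missing call are excluded and the modal full
    call count defines n. Monomorphic sites are excluded. Returns an array
    of length n//2 + 1 indexed by minor-allele count (entry 0 is zero).
    """
    n_called = ac.n_called
    n = int(n_called.max()) if len(n_called) else 0
    if n == 0:
        return np.zeros(1, dtype=np.int64)
    use = (n_called == n) if drop_incomplete else (n_called > 0)
    minor = ac.counts[use].min(axis=1)
    minor = minor[minor > 0]
    return np.bincount(minor, minlength=n // 2 + 1)[: n // 2 + 1]


def rank_top_windows(
    windows: pd.DataFrame,
    value_col: str,
    genes: pd.DataFrame,
    k: int = 5,
) -> pd.DataFrame:
    """Top-k windows by a statistic, annotated with overlapping gene IDs.

    Overlap is inclusive on both ends (a gene touching a window boundary is
    listed). ``genes`` columns: contig, start, end, gene_id.
    """
    ranked = windows.dropna(subset=[value_col]).sort_values(
        value_col, ascending=False, kind="mergesort"
    ).head(k).copy()
    ann = []
    for row in ranked.itertuples(index=False):
        g = genes[
            (genes["contig"] == row.contig)
            & (genes["start"] <= row.end)
            & (genes["end"] >= row.start)
        ]
        ann.append(",".join(g["gene_id"].tolist()))
    ranked["gene_ids"] = ann
    return ranked.reset_index(drop=True)
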