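"""Population structure: Patterson-scaled PCA and AIM-fraction assignment.

The PCA follows the Patterson, Price & Reich normalisation: each variant's
dosage row is centred by twice its mean allele frequency and scaled by
``sqrt(p(1-p))`` with ``p`` the mean-frequency estimate, then decomposed by
SVD. The AIM (ancestry-informative marker) fraction summarises, per
individual, the proportion of taxon-A diagnostic alleles carried over called
panel sites; cohorts are assigned taxon-A when the mean fraction exceeds
0.95, taxon-B below 0.05, and "intermediate" otherwise (strict inequalities;
the boundary values assign to the nearest taxon).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, VariantTable


@dataclass
class PcaResult:
    coordinates: np.ndarray        # (samples, components)
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray           # (variants_used, components)
    variant_indices: np.ndarray    # rows used after zero-variance drop


def pca_patterson(dosages: np.ndarray, n_components: int = 10) -> PcaResult:
    """PCA of a (variants, samples) dosage matrix with the Patterson scaler.

    Missing dosages are mean-imputed per variant; zero-variance variants are
    dropped. Components are sign-fixed so each one's largest-magnitude
    variant loading is positive.
    """
    x = np.asarray(dosages, dtype=np.float64)
    n_var, n_samples = x.shape
    if n_components > n_samples:
        warnings.warn(
            f"n_components reduced from {n_components} to {n_samples} (sample count)"
        )
        n_components = n_samples
    if n_var < n_components:
        raise ValueError("fewer variants than requested components")
    mean = np.nanmean(x, axis=1)
    x = np.where(np.isnan(x), mean[:, None], x)
    p = mean / 2.0
    scale = np.sqrt(p * (1 - p))
    used = np.flatnonzero(scale > 0)
    xs = (x[used] - mean[used, None]) / scale[used, None]
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    k = n_components
    coords = vt[:k].T * s[:k]
    load = u[:, :k]
    # sign convention: largest-|loading| entry positive per component
    for j in range(k):
        if load[np.argmax(np.abs(load[:, j])), j] < 0:
            load[:, j] = -load[:, j]
            coords[:, j] = -coords[:, j]
    evr = s[:k] ** 2 / (s**2).sum()
    return PcaResult(coords, evr, load, used)


@dataclass
class AimReport:
    per_sample: pd.DataFrame   # sample_id, aim_fraction, n_called_sites
    per_cohort: pd.DataFrame   # cohort, mean_fraction, assignment


def _diag_allele_codes(vt: VariantTable, panel: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Match panel rows to variants; return (variant idx, code of A allele 0/1)."""
    key = {(c, int(p)): i for i, (c, p) in enumerate(zip(vt.contig, vt.pos))}
    vidx, acode = [], []
    for row in panel.itertuples(index=False):
        i = key.get((row.contig, int(row.pos)))
        if i is None:
            continue
        if row.allele_a == vt.ref_allele[i]:
            acode.append(0)
        elif row.allele_a == vt.alt_allele[i]:
            acode.append(1)
        else:
            continue  # panel allele not present at this site
        vidx.append(i)
    return np.asarray(vidx, dtype=np.intp), np.asarray(acode, dtype=np.int8)


def aim_fraction(
    gm: GenotypeMatrix,
    vt: VariantTable,
    panel: pd.DataFrame,
    cohorts: pd.Series | None = None,
    hi: float = 0.95,
    lo: float = 0.05,
) -> AimReport:
    """Per-sample fraction of taxon-A diagnostic alleles over called panel sites.

    ``panel`` columns: contig, pos, allele_a, allele_b. ``cohorts`` maps
    sample_id -> cohort label for the per-cohort summary.
    """
    if len(panel) == 0:
        raise ValueError("empty AIM panel")
    vidx, acode = _diag_allele_codes(vt, panel)
    if len(vidx) == 0:
        raise ValueError("no panel site matches the variant table")
    calls = gm.calls[vidx]                      # (P, S, 2)
    called = (calls != MISSING).all(axis=2)
    n_a = ((calls == acode[:, None, None]) & called[:, :, None]).sum(axis=(0, 2))
    n_sites = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_sites > 0, n_a / (2.0 * n_sites), np.nan)
    if (n_sites == 0).any():
        warnings.warn("samples with zero called panel sites excluded from cohort means")
    per_sample = pd.DataFrame(
        {"sample_id": gm.sample_ids, "aim_fraction": frac, "n_called_sites": n_sites}
    )
    if cohorts is None:
        cohorts = pd.Series("all", index=gm.sample_ids)
    per_sample["cohort"] = per_sample["sample_id"].map(cohorts)
    grp = per_sample.dropna(subset=["aim_fraction"]).groupby("cohort")["aim_fraction"].mean()
    # intermediate band is open: exactly hi/lo assigns to the nearest taxon
    assign = grp.map(lambda v: "taxon_a" if v >= hi else ("taxon_b" if v <= lo else "intermediate"))
    per_cohort = pd.DataFrame(
        {"cohort": grp.index, "mean_fraction": grp.values, "assignment": assign.values}
    )
    return AimReport(per_sample=per_sample, per_cohort=per_cohort)
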