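"""Core data model for SNP-based population-genomic analyses.

Conventions
-----------
* Coordinates are 1-based inclusive throughout the data model and VCF I/O.
  BED input is 0-based half-open and converted on read (see :mod:`cryptaxon.io`).
* Genotype calls are stored as a ``(variants, samples, 2)`` integer array with
  allele codes ``0`` (ref), ``1`` (alt) and :data:`MISSING` (``-1``).
  Half-called genotypes (one called allele, one missing) are normalised to
  fully missing on construction: a half call contributes an odd number of
  alleles and would bias allele counts.
* Allele counts are per-variant ``(ref, alt)`` totals over the called alleles
  of one cohort; every frequency-based statistic downstream consumes these.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel for a missing allele call.
MISSING = -1

SAMPLE_FRAME_COLUMNS = ["sample_id", "cohort", "country", "site", "sex", "year"]


@dataclass
class VariantTable:
    """Per-variant metadata for a biallelic SNP set.

    Positions are 1-based and strictly increasing within each contig.
    ``pass_site_filter`` carries an externally supplied site-quality mask
    (e.g. the Ag1000G "gamb_colu" filter); it is consumed, never recomputed.
    """

    contig: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    pass_site_filter: np.ndarray

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref_allele = np.asarray(self.ref_allele, dtype=object)
        self.alt_allele = np.asarray(self.alt_allele, dtype=object)
        self.pass_site_filter = np.asarray(self.pass_site_filter, dtype=bool)
        n = len(self.pos)
        for name in ("contig", "ref_allele", "alt_allele", "pass_site_filter"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"VariantTable field {name!r} length mismatch")
        for ctg in pd.unique(self.contig):
            sel = self.contig == ctg
            p = self.pos[sel]
            if len(p) > 1 and not np.all(np.diff(p) >= 0):
                raise ValueError(f"positions not sorted on {ctg}")
            # equal positions only for split multiallelics (distinct alts)
            if len(p) > 1:
                dup = np.flatnonzero(np.diff(p) == 0)
                alts = self.alt_allele[sel]
                if any(alts[i] == alts[i + 1] for i in dup):
                    raise ValueError(f"duplicate variant record on {ctg}")

    @property
    def n_variants(self) -> int:
        return len(self.pos)

    def take(self, indices) -> "VariantTable":
        idx = np.asarray(indices)
        return VariantTable(
            self.contig[idx], self.pos[idx], self.ref_allele[idx],
            self.alt_allele[idx], self.pass_site_filter[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig": self.contig,
                "pos": self.pos,
                "ref_allele": self.ref_allele,
                "alt_allele": self.alt_allele,
                "pass_site_filter": self.pass_site_filter,
            }
        )


@dataclass
class GenotypeMatrix:
    """Diploid genotype calls: ``(variants, samples, 2)`` with -1 missing."""

    calls: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (variants, samples, 2)")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.calls.shape[1] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match calls")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        # half calls -> fully missing
        half = (self.calls == MISSING).any(axis=2) & (self.calls != MISSING).any(axis=2)
        if half.any():
            self.calls[half] = MISSING

    @property
    def n_variants(self) -> int:
        return self.calls.shape[0]

    @property
    def n_samples(self) -> int:
        return self.calls.shape[1]

    def sample_indices(self, sample_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        except KeyError as exc:
            raise KeyError(f"unknown sample id: {exc.args[0]!r}") from None

    def take_variants(self, indices) -> "GenotypeMatrix":
        return GenotypeMatrix(self.calls[np.asarray(indices)], list(self.sample_ids))

    def take_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(sample_ids)
        return GenotypeMatrix(self.calls[:, idx], [self.sample_ids[i] for i in idx])

    def called_mask(self) -> np.ndarray:
        """(variants, samples) boolean: genotype fully called."""
        return (self.calls != MISSING).all(axis=2)

    def dosages(self) -> np.ndarray:
        """Alt-allele dosage per genotype (0/1/2), NaN where missing."""
        d = self.calls.sum(axis=2).astype(np.float64)
        d[~self.called_mask()] = np.nan
        return d


@dataclass
class AlleleCounts:
    """Per-variant (ref, alt) called-allele counts for one cohort."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must have shape (variants, 2)")
        if (self.counts < 0).any():
            raise ValueError("negative allele counts")

    @property
    def n_variants(self) -> int:
        return self.counts.shape[0]

    @property
    def n_called(self) -> np.ndarray:
        """Total called alleles per variant."""
        return self.counts.sum(axis=1)

    def alt_freq(self) -> np.ndarray:
        """Alt-allele frequency; NaN where no alleles were called."""
        n = self.n_called.astype(np.float64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.counts[:, 1] / n, np.nan)

    def is_segregating(self) -> np.ndarray:
        return (self.counts > 0).all(axis=1)

    def take(self, indices) -> "AlleleCounts":
        return AlleleCounts(self.counts[np.asarray(indices)])


class AccessibilityMask:
    """Per-contig boolean accessibility over positions.

    Internally stored as 0-based arrays; ``self[contig][pos - 1]`` answers
    whether 1-based position ``pos`` is accessible.
    """

    def __init__(self, masks: Mapping[str, np.ndarray]):
        self.masks = {str(c): np.asarray(m, dtype=bool) for c, m in masks.items()}

    def __contains__(self, contig: str) -> bool:
        return contig in self.masks

    def __getitem__(self, contig: str) -> np.ndarray:
        if contig not in self.masks:
            raise KeyError(f"contig {contig!r} absent from accessibility mask")
        return self.masks[contig]

    def contigs(self) -> list[str]:
        return list(self.masks)

    def n_accessible(self, contig: str) -> int:
        return int(self[contig].sum())


def validate_sample_frame(df: pd.DataFrame, gm: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Check required metadata columns and (optionally) genotype consistency."""
    missing = [c for c in SAMPLE_FRAME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample frame missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample frame")
    bad_sex = set(df["sex"].unique()) - {"F", "M", "unknown"}
    if bad_sex:
        raise ValueError(f"invalid sex values: {sorted(bad_sex)}")
    if gm is not None:
        known = set(df["sample_id"])
        orphans = [s for s in gm.sample_ids if s not in known]
        if orphans:
            raise ValueError(f"genotype samples without metadata: {orphans[:5]}")
    return df


def allele_counts(gm: GenotypeMatrix, sample_subset: Sequence[str] | None = None) -> AlleleCounts:
    """Count called ref/alt alleles per variant over a sample subset.

    Missing alleles are excluded; a variant where every genotype in the
    subset is missing gets counts (0, 0).
    """
    if sample_subset is not None:
        if len(sample_subset) == 0:
            raise ValueError("sample subset is empty")
        idx = gm.sample_indices(sample_subset)
        calls = gm.calls[:, idx]
    else:
        calls = gm.calls
    flat = calls.reshape(calls.shape[0], -1)
    ref = (flat == 0).sum(axis=1)
    alt = (flat == 1).sum(axis=1)
    return AlleleCounts(np.stack([ref, alt], axis=1))


def filter_sites(
    gm: GenotypeMatrix,
    vt: VariantTable,
    maf_min: float = 0.01,
    require_biallelic: bool = True,
) -> np.ndarray:
    """Indices of variants passing site filter, biallelic and MAF >= maf_min.

    MAF is computed globally over all non-missing alleles of all samples.
    Monomorphic variants are always removed. The threshold is inclusive.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    ac = allele_counts(gm)
    n = ac.n_called.astype(np.float64)
    minor = ac.counts.min(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(n > 0, minor / n, 0.0)
    keep = vt.pass_site_filter & (minor > 0) & (maf >= maf_min)
    if require_biallelic:
        keep &= np.array(
            [r != a and len(str(r)) == 1 and len(str(a)) == 1
             for r, a in zip(vt.ref_allele, vt.alt_allele)]
        )
    idx = np.flatnonzero(keep)
    if len(idx) == 0:
        warnings.warn("filter_sites removed every variant", stacklevel=2)
    return idx


def downsample_variants(indices, n: int, seed: int) -> np.ndarray:
    """Randomly retain at most ``n`` of the given variant indices, sorted."""
    if n < 1:
        raise ValueError("n must be >= 1")
    idx = np.asarray(indices)
    if len(idx) <= n:
        return np.sort(idx)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(idx, size=n, replace=False))


def accessible_windows(
    mask: AccessibilityMask, contig: str, window_accessible_bases: int = 100_000
) -> pd.DataFrame:
    """Tile a contig into windows containing a fixed number of accessible bases.

    Each window holds exactly ``window_accessible_bases`` accessible positions
    except possibly the terminal one. Window bounds are 1-based inclusive:
    the start is the first accessible base after the previous window, the end
    is the last accessible base counted into the window.
    """
    m = mask[contig]
    w = int(window_accessible_bases)
    if w < 1:
        raise ValueError("window_accessible_bases must be >= 1")
    cum = np.cumsum(m)
    total = int(cum[-1]) if len(cum) else 0
    rows = []
    if total > 0:
        n_windows = -(-total // w)
        for k in range(n_windows):
            first = k * w + 1
            last = min((k + 1) * w, total)
            start = int(np.searchsorted(cum, first, side="left")) + 1
            end = int(np.searchsorted(cum, last, side="left")) + 1
            rows.append((contig, start, end, last - first + 1))
    return pd.DataFrame(rows, columns=["contig", "start", "end", "n_accessible"])


def assign_windows(pos: np.ndarray, windows: pd.DataFrame) -> np.ndarray:
    """Map 1-based positions to window row indices (-1 if outside any window).

    Windows must be the non-overlapping, ordered output of
    :func:`accessible_windows` for a single contig.
    """
    pos = np.asarray(pos, dtype=np.int64)
    if len(windows) == 0:
        return np.full(len(pos), -1, dtype=np.intp)
    starts = windows["start"].to_numpy()
    ends = windows["end"].to_numpy()
    wi = np.searchsorted(starts, pos, side="right") - 1
    out = np.where((wi >= 0) & (pos <= ends[np.clip(wi, 0, None)]), wi, -1)
    return out.astype(np.intp)
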