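"""Synthetic genotype, haplotype and coverage data with known ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* Allele-frequency divergence between taxa follows the Balding–Nichols model:
  given an ancestral frequency ``p`` and a drift parameter ``F`` (an FST-like
  quantity in [0, 1)), a taxon's frequency is drawn from
  ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean ``p`` and variance
  ``F p (1-p)``. Expected Hudson FST between two taxa with drifts F1, F2 is
  approximately ``(F1 + F2) / 2``.
* Divergence is allowed to be heterogeneous along the genome: a taxon's
  ``drift`` may be a per-variant vector, so a minority of "divergence island"
  loci can drift much faster than the genomic background — the situation that
  makes near-fixed diagnostic markers discoverable between otherwise weakly
  differentiated taxa.
* An admixed population's frequencies are the alpha-weighted mixture of its
  two source taxa's realised frequencies.
* Haplotypes are independent sites at given frequencies (no background LD);
  a selective sweep is implanted by making a fraction of haplotypes copy one
  or more founder sequences across a flank around the sweep centre.
* Coverage is negative-binomial read counts per 300-bp window around a
  per-sample mean depth, multiplied by a unimodal GC-bias curve and by
  (copy number / 2) inside implanted CNV intervals.

All operations are reproducible bit-for-bit given a seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import MISSING, AccessibilityMask, GenotypeMatrix, VariantTable


@dataclass
class TaxonModel:
    """One simulated taxon: name, Balding–Nichols drift, cohort size (diploids)."""

    name: str
    drift: float | np.ndarray
    cohort_size: int

    def __post_init__(self) -> None:
        d = np.asarray(self.drift, dtype=np.float64)
        if (d < 0).any() or (d >= 1).any():
            raise ValueError("drift must be in [0, 1)")
        if self.cohort_size < 1:
            raise ValueError("cohort_size must be >= 1")


@dataclass
class AdmixtureSpec:
    source_a: str
    source_b: str
    alpha: float

    def __post_init__(self) -> None:
        if self.source_a == self.source_b:
            raise ValueError("admixture sources must be distinct")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass
class SweepConfig:
    """A (hard or soft) sweep: founder haplotypes at combined frequency."""

    contig: str
    center: int
    frequency: float
    flank: int
    n_founders: int = 1

    def __post_init__(self) -> None:
        if not 0.0 < self.frequency <= 1.0:
            raise ValueError("sweep frequency must be in (0, 1]")
        if self.n_founders < 1:
            raise ValueError("n_founders must be >= 1")


@dataclass
class CnvTruth:
    """Implanted copy-number segment over window indices [start_idx, end_idx]."""

    sample_id: str
    contig: str
    start_idx: int
    end_idx: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.end_idx < self.start_idx:
            raise ValueError("end_idx < start_idx")
        if self.copy_number < 0:
            raise ValueError("copy_number must be >= 0")


def simulate_frequencies(
    n_variants: int,
    taxa: Sequence[TaxonModel],
    seed: int,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
    ancestral: np.ndarray | None = None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Draw ancestral and per-taxon allele frequencies under Balding–Nichols.

    Returns ``(ancestral, {taxon name: frequencies})``. The ancestral support
    excludes the extremes by default to avoid monomorphic inflation; an
    explicit ``ancestral`` vector overrides the uniform draw.
    """
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    rng = np.random.default_rng(seed)
    if ancestral is not None:
        p = np.asarray(ancestral, dtype=np.float64)
        if len(p) != n_variants:
            raise ValueError("ancestral length mismatch")
    else:
        p = rng.uniform(*ancestral_range, size=n_variants)
    out: dict[str, np.ndarray] = {}
    for taxon in taxa:
        f = np.broadcast_to(np.asarray(taxon.drift, dtype=np.float64), (n_variants,))
        q = p.copy()
        drifted = f > 0
        if drifted.any():
            fd, pd_ = f[drifted], p[drifted]
            q[drifted] = rng.beta(pd_ * (1 - fd) / fd, (1 - pd_) * (1 - fd) / fd)
        out[taxon.name] = q
    return p, out


def simulate_tree_frequencies(
    n_variants: int,
    tree: dict,
    seed: int,
    ancestral_range: tuple[float, float] = (0.05, 0.95),
) -> dict[str, np.ndarray]:
    """Allele frequencies under nested Balding–Nichols drift along a tree.

    ``tree`` maps a leaf name to its branch drift, or an internal-node name
    to ``(branch_drift, subtree_dict)``; drift accumulates down the tree, so
    sister taxa share the drift of their common branch (which a star
    phylogeny cannot produce, and which topology tests such as outgroup-f3
    ordering and the D statistic rely on). Example::

        {"P3": 0.1, "OUT": 0.25, "anc12": (0.02, {"P1": 0.01, "P2": 0.01})}
    """
    rng = np.random.default_rng(seed)
    p_root = rng.uniform(*ancestral_range, size=n_variants)

    def drift_from(p: np.ndarray, f: float) -> np.ndarray:
        if f < 0 or f >= 1:
            raise ValueError("drift must be in [0, 1)")
        if f == 0:
            return p.copy()
        q = np.clip(p, 1e-9, 1 - 1e-9)
        return rng.beta(q * (1 - f) / f, (1 - q) * (1 - f) / f)

    out: dict[str, np.ndarray] = {}

    def walk(p: np.ndarray, subtree: dict) -> None:
        for name, spec_ in subtree.items():
            if isinstance(spec_, tuple):
                f, children = spec_
                walk(drift_from(p, f), children)
            else:
                out[name] = drift_from(p, float(spec_))

    walk(p_root, tree)
    return out


def simulate_admixed(freq_a: np.ndarray, freq_b: np.ndarray, spec: AdmixtureSpec) -> np.ndarray:
    """Mixture frequencies alpha * p_a + (1 - alpha) * p_b."""
    freq_a = np.asarray(freq_a, dtype=np.float64)
    freq_b = np.asarray(freq_b, dtype=np.float64)
    if freq_a.shape != freq_b.shape:
        raise ValueError("source frequency vectors differ in length")
    return spec.alpha * freq_a + (1 - spec.alpha) * freq_b


def simulate_genotypes(
    freqs: np.ndarray,
    cohort_size: int,
    seed: int,
    missing_rate: float = 0.0,
    sample_prefix: str = "S",
) -> GenotypeMatrix:
    """Diploid genotypes: two independent Bernoulli(p) alleles per sample."""
    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=np.float64)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    calls = (rng.random((len(p), cohort_size, 2)) < p[:, None, None]).astype(np.int8)
    if missing_rate > 0:
        miss = rng.random((len(p), cohort_size)) < missing_rate
        calls[miss] = MISSING
    ids = [f"{sample_prefix}{i:04d}" for i in range(cohort_size)]
    return GenotypeMatrix(calls, ids)


def simulate_allele_counts(freqs: np.ndarray, cohort_size: int, seed: int):
    """Cohort allele counts drawn binomially (2N trials per site)."""
    from .core import AlleleCounts

    rng = np.random.default_rng(seed)
    p = np.asarray(freqs, dtype=np.float64)
    alt = rng.binomial(2 * cohort_size, p)
    return AlleleCounts(np.stack([2 * cohort_size - alt, alt], axis=1))


def simulate_haplotypes(
    n_variants: int,
    n_haplotypes: int,
    seed: int,
    freqs: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    sweep: SweepConfig | None = None,
    spacing: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary haplotypes (variants x haplotypes) with an optional sweep.

    Neutral background sites are independent Bernoulli draws at per-site
    frequencies (default Uniform(0.1, 0.9)). Under a sweep, a fraction
    ``frequency`` of haplotypes (split evenly over ``n_founders`` founder
    sequences) share the founder's alleles at every variant within ``flank``
    of ``center``. Returns ``(haplotypes, positions)``.
    """
    if n_haplotypes % 2 != 0:
        raise ValueError("n_haplotypes must be even (diploid phasing contract)")
    rng = np.random.default_rng(seed)
    if positions is None:
        positions = np.arange(1, n_variants + 1, dtype=np.int64) * spacing
    positions = np.asarray(positions, dtype=np.int64)
    if freqs is None:
        freqs = rng.uniform(0.1, 0.9, size=n_variants)
    haps = (rng.random((n_variants, n_haplotypes)) < np.asarray(freqs)[:, None]).astype(np.int8)
    if sweep is not None:
        lo, hi = sweep.center - sweep.flank, sweep.center + sweep.flank
        if lo < positions[0] or hi > positions[-1]:
            warnings.warn("sweep flank exceeds simulated contig; clipped")
        region = (positions >= lo) & (positions <= hi)
        n_swept = int(round(sweep.frequency * n_haplotypes))
        carriers = rng.choice(n_haplotypes, size=n_swept, replace=False)
        groups = np.array_split(carriers, sweep.n_founders)
        for g in groups:
            if len(g) == 0:
                continue
            founder = (rng.random(int(region.sum())) < np.asarray(freqs)[region]).astype(np.int8)
            haps[np.ix_(region, g)] = founder[:, None]
    return haps, positions


def default_gc_bias(gc: np.ndarray, strength: float = 1.2) -> np.ndarray:
    """Unimodal quadratic GC-bias multiplier peaking at GC = 0.45."""
    b = 1.0 - strength * (np.asarray(gc) - 0.45) ** 2
    return np.clip(b, 0.05, None)


def simulate_coverage(
    n_windows: int,
    sample_ids: Sequence[str],
    gc: np.ndarray,
    truth: Sequence[CnvTruth],
    seed: int,
    mean_count: float = 60.0,
    nb_dispersion: float = 500.0,
    gc_bias_strength: float = 1.2,
    contig: str = "sim",
) -> np.ndarray:
    """Read counts per (window, sample) with GC bias and implanted CNVs.

    Counts are negative-binomial with mean ``mean_count * bias(gc) * cn/2``
    and size parameter ``nb_dispersion`` (variance m + m^2/size). A 300-bp
    window at ~30x with 150-bp reads carries ~60 reads, the default.
    """
    gc = np.asarray(gc, dtype=np.float64)
    if ((gc < 0) | (gc > 1)).any():
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sample_index = {s: j for j, s in enumerate(sample_ids)}
    cn = np.full((n_windows, len(sample_ids)), 2.0)
    seen: dict[str, list[tuple[int, int]]] = {}
    for t in truth:
        if t.contig != contig:
            continue
        for lo, hi in seen.get(t.sample_id, []):
            if t.start_idx <= hi and t.end_idx >= lo:
                raise ValueError(f"overlapping CNV truth intervals for {t.sample_id}")
        seen.setdefault(t.sample_id, []).append((t.start_idx, t.end_idx))
        cn[t.start_idx: t.end_idx + 1, sample_index[t.sample_id]] = t.copy_number
    bias = default_gc_bias(gc, gc_bias_strength)
    mu = mean_count * bias[:, None] * cn / 2.0
    # negative binomial via gamma-poisson mixture; mu=0 -> zero counts
    lam = np.where(mu > 0, rng.gamma(nb_dispersion, 1.0, mu.shape) * mu / nb_dispersion, 0.0)
    return rng.poisson(lam).astype(np.int64)


# ---------------------------------------------------------------------------
# Scenario builders

@dataclass
class ThreeTaxaScenario:
    """Genotypes for three diverged taxa plus optional admixed cohort."""

    vt: VariantTable
    gm: GenotypeMatrix
    samples: pd.DataFrame
    ancestral: np.ndarray
    freqs: dict[str, np.ndarray]
    mask: AccessibilityMask
    contig_lengths: dict[str, int]


def three_taxa_scenario(
    seed: int,
    n_variants: int = 50_000,
    cohort_size: int = 60,
    drift: float = 0.03,
    n_island_loci: int = 300,
    n_island_loci_co: int = 300,
    island_bis_freq: tuple[float, float] = (0.90, 1.0),
    island_ancestral_freq: tuple[float, float] = (0.02, 0.10),
    admixed: AdmixtureSpec | None = None,
    admixed_size: int = 40,
    missing_rate: float = 0.0,
    outgroup_drift: float | None = 0.25,
    contig: str = "3R",
    spacing: int = 100,
) -> ThreeTaxaScenario:
    """The standard study-condition fixture: CO-like, GA-like and BIS-like taxa.

    All taxa drift at ``drift`` from a shared ancestor (pairwise FST on the
    ``drift`` scale). Divergence is heterogeneous, as in real speciation
    landscapes: the BIS-like focal taxon carries ``n_island_loci`` randomly
    placed divergence-island loci — ancestrally rare variants (frequency in
    ``island_ancestral_freq``) driven to near-fixation in BIS only
    (``island_bis_freq``), emulating completed taxon-specific sweeps, the
    localized near-fixed differentiation from which diagnostic markers are
    discovered — and the CO-like taxon carries its own disjoint island set
    (``n_island_loci_co``), from which CO/GA ancestry-informative markers
    arise (BIS then scores GA-like on those, and an admixed BIS x CO cohort
    scores intermediate). Optionally adds an admixed cohort mixing two
    taxa's frequencies.
    """
    rng = np.random.default_rng(seed)
    anc_override = rng.uniform(0.05, 0.95, size=n_variants)
    n_isl = n_island_loci + n_island_loci_co
    islands = np.array([], dtype=np.intp)
    islands_co = np.array([], dtype=np.intp)
    if n_isl > 0:
        both = rng.choice(n_variants, size=n_isl, replace=False)
        islands, islands_co = both[:n_island_loci], both[n_island_loci:]
        anc_override[both] = rng.uniform(*island_ancestral_freq, size=n_isl)
    taxa = [
        TaxonModel("CO", drift, cohort_size),
        TaxonModel("GA", drift, cohort_size),
        TaxonModel("BIS", drift, cohort_size),
    ]
    if outgroup_drift is not None:
        taxa.append(TaxonModel("OUT", outgroup_drift, cohort_size))
    anc, freqs = simulate_frequencies(
        n_variants, taxa, seed=int(rng.integers(2**31)), ancestral=anc_override
    )
    if len(islands):
        freqs["BIS"][islands] = rng.uniform(*island_bis_freq, size=len(islands))
    if len(islands_co):
        freqs["CO"][islands_co] = rng.uniform(*island_bis_freq, size=len(islands_co))
    if admixed is not None:
        freqs[f"ADM_{admixed.source_a}_{admixed.source_b}"] = simulate_admixed(
            freqs[admixed.source_a], freqs[admixed.source_b], admixed
        )

    gms, rows = [], []
    for name, f in freqs.items():
        size = admixed_size if name.startswith("ADM") else cohort_size
        g = simulate_genotypes(
            f, size, seed=rng.integers(2**31), missing_rate=missing_rate,
            sample_prefix=f"{name}_",
        )
        gms.append(g)
        for s in g.sample_ids:
            rows.append((s, name, "synthetic", "synthetic", "F", 2020))
    calls = np.concatenate([g.calls for g in gms], axis=1)
    sample_ids = [s for g in gms for s in g.sample_ids]
    gm = GenotypeMatrix(calls, sample_ids)
    samples = pd.DataFrame(
        rows, columns=["sample_id", "cohort", "country", "site", "sex", "year"]
    )

    pos = np.arange(1, n_variants + 1, dtype=np.int64) * spacing
    vt = VariantTable(
        np.full(n_variants, contig, dtype=object), pos,
        np.full(n_variants, "A", dtype=object), np.full(n_variants, "T", dtype=object),
        np.ones(n_variants, dtype=bool),
    )
    length = int(pos[-1]) + spacing
    mask = AccessibilityMask({contig: np.ones(length, dtype=bool)})
    return ThreeTaxaScenario(
        vt=vt, gm=gm, samples=samples, ancestral=anc, freqs=freqs,
        mask=mask, contig_lengths={contig: length},
    )


def write_scenario(scn: ThreeTaxaScenario, out_dir) -> dict[str, Path]:
    """Emit a scenario as VCF + metadata TSV + BED mask (exercises real readers)."""
    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": out / "genotypes.vcf",
        "meta": out / "samples.tsv",
        "bed": out / "accessible.bed",
    }
    io.write_vcf(scn.vt, scn.gm, paths["vcf"], contig_lengths=scn.contig_lengths)
    io.write_sample_frame(scn.samples, paths["meta"])
    io.write_bed_mask(scn.mask, paths["bed"])
    return paths
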