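"""Config-driven end-to-end run over the synthetic study scenario.

Stages: simulate -> site filter/down-sample -> LD prune -> PCA + AIM
fractions -> windowed diversity/divergence -> F3 / Patterson's D ->
diagnostic-marker panel + classification -> H12 calibration and scan ->
coverage CNV calling -> amino-acid substitution report. Each stage writes
its TSV outputs before the next begins; a manifest records the config hash
and the per-stage seeds so a re-run with the same config and seed is
byte-identical.

The global seed is fanned out per stage by stable hashing of the stage name,
so adding a stage never perturbs another stage's random stream.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .core import accessible_windows, allele_counts, downsample_variants, filter_sites
from .synthetic import (
    AdmixtureSpec,
    CnvTruth,
    SweepConfig,
    simulate_coverage,
    simulate_haplotypes,
    three_taxa_scenario,
)


class ScenarioConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_variants: int = 20_000
    cohort_size: int = 40
    drift: float = 0.03
    n_island_loci: int = 120
    n_island_loci_co: int = 120
    admix_alpha: float = 0.5
    admixed_size: int = 30
    missing_rate: float = 0.0


class PruneConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    window_size_snps: int = 500
    step_snps: int = 250
    r2_threshold: float = Field(0.01, gt=0.0, le=1.0)


class RunConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    out_dir: str = "cryptaxon_run"
    scenario: ScenarioConfig = ScenarioConfig()
    maf_min: float = Field(0.01, ge=0.0, le=0.5)
    downsample_snps: int = 100_000
    prune: PruneConfig = PruneConfig()
    pca_components: int = 10
    window_accessible_bases: int = 100_000
    block_size_snps: int = 1_000
    panel_tier: str = "ge85"
    hi_cutoff: float = 80.0
    lo_cutoff: float = 20.0
    h12_candidates: list[int] = [10, 20, 50, 100, 200]
    h12_haplotypes: int = 200
    h12_variants: int = 4000
    sweep_frequency: float = 0.6
    cnv_samples: int = 30
    cnv_windows: int = 3000
    min_run: int = 5


def stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.blake2s(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on the synthetic scenario; returns the manifest."""
    from . import admixstats, classifier, cnv, divstats, ldprune, resistance, selection, structure

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(config.model_dump(), sort_keys=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "stages": {},
        "outputs": [],
    }

    def done(stage: str, **info) -> None:
        manifest["stages"][stage] = {"seed": stage_seed(config.seed, stage), **info}

    # -- simulate ----------------------------------------------------------
    sc = config.scenario
    scn = three_taxa_scenario(
        seed=stage_seed(config.seed, "simulate"),
        n_variants=sc.n_variants,
        cohort_size=sc.cohort_size,
        drift=sc.drift,
        n_island_loci=sc.n_island_loci,
        n_island_loci_co=sc.n_island_loci_co,
        admixed=AdmixtureSpec("BIS", "CO", sc.admix_alpha),
        admixed_size=sc.admixed_size,
        missing_rate=sc.missing_rate,
    )
    cohorts = scn.samples.set_index("sample_id")["cohort"]
    by_cohort = {
        name: grp["sample_id"].tolist() for name, grp in scn.samples.groupby("cohort")
    }
    adm_name = next(n for n in by_cohort if n.startswith("ADM"))
    done("simulate", n_variants=scn.vt.n_variants, n_samples=scn.gm.n_samples)

    # -- prepare: site filter + down-sample --------------------------------
    kept = filter_sites(scn.gm, scn.vt, maf_min=config.maf_min)
    kept = downsample_variants(kept, config.downsample_snps, stage_seed(config.seed, "downsample"))
    vt, gm = scn.vt.take(kept), scn.gm.take_variants(kept)
    done("prepare", n_kept=len(kept))

    # -- LD prune ----------------------------------------------------------
    params = ldprune.PruneParams(
        window_size_snps=config.prune.window_size_snps,
        step_snps=config.prune.step_snps,
        r2_threshold=config.prune.r2_threshold,
    )
    keep_mask = ldprune.locate_unlinked(gm.dosages(), params)
    vt_p, gm_p = vt.take(np.flatnonzero(keep_mask)), gm.take_variants(np.flatnonzero(keep_mask))
    done("prune", n_kept=int(keep_mask.sum()))

    # -- structure: PCA + AIM fractions ------------------------------------
    pca = structure.pca_patterson(gm_p.dosages(), n_components=config.pca_components)
    pca_df = pd.DataFrame(
        pca.coordinates, columns=[f"PC{i+1}" for i in range(pca.coordinates.shape[1])]
    )
    pca_df.insert(0, "sample_id", gm_p.sample_ids)
    pca_df.insert(1, "cohort", pca_df["sample_id"].map(cohorts))
    _write(pca_df, out / "pca.tsv")
    evr = pd.DataFrame(
        {"component": np.arange(1, len(pca.explained_variance_ratio) + 1),
         "explained_variance_ratio": pca.explained_variance_ratio}
    )
    _write(evr, out / "pca_explained_variance.tsv")

    # AIM panel: fixed CO-vs-GA differences on the filtered set
    daf_aims = classifier.compute_daf(gm, vt, by_cohort["CO"], by_cohort["GA"])
    aim_sel = daf_aims[daf_aims["daf"] > 0.85]
    aims_df = pd.DataFrame(
        {
            "contig": aim_sel["contig"],
            "pos": aim_sel["pos"],
            "allele_a": np.where(aim_sel["a_allele"] == 1, vt.alt_allele[aim_sel["variant_idx"]], vt.ref_allele[aim_sel["variant_idx"]]),
            "allele_b": np.where(aim_sel["a_allele"] == 1, vt.ref_allele[aim_sel["variant_idx"]], vt.alt_allele[aim_sel["variant_idx"]]),
        }
    )
    if len(aims_df):
        report = structure.aim_fraction(gm, vt, aims_df, cohorts=cohorts)
        _write(report.per_sample, out / "aim_per_sample.tsv")
        _write(report.per_cohort, out / "aim_per_cohort.tsv")
    done("structure", n_aims=len(aims_df))

    # -- divstats ----------------------------------------------------------
    contig = scn.vt.contig[0]
    windows = accessible_windows(scn.mask, contig, config.window_accessible_bases)
    acs = {name: allele_counts(gm, ids) for name, ids in by_cohort.items()}
    for name in ("CO", "GA", "BIS"):
        div = divstats.diversity_window(acs[name], vt.pos, windows)
        _write(div, out / f"diversity_{name}.tsv")
    fst_summary = []
    for a, b in (("BIS", "CO"), ("BIS", "GA"), ("CO", "GA")):
        wtab, total = divstats.hudson_fst(acs[a], acs[b], vt.pos, windows)
        wtab = divstats.dxy(acs[a], acs[b], vt.pos, windows).merge(
            wtab, on=["contig", "start", "end", "n_accessible"]
        )
        _write(wtab, out / f"divergence_{a}_{b}.tsv")
        fst_summary.append((a, b, total))
    _write(
        pd.DataFrame(fst_summary, columns=["cohort_a", "cohort_b", "fst_genomewide"]),
        out / "fst_summary.tsv",
    )
    sfs = divstats.folded_sfs(acs["BIS"])
    _write(
        pd.DataFrame({"minor_allele_count": np.arange(len(sfs)), "n_sites": sfs}),
        out / "sfs_BIS.tsv",
    )
    done("divstats", n_windows=len(windows))

    # -- admixstats --------------------------------------------------------
    block = config.block_size_snps
    rows = []
    f3_adm = admixstats.f3(acs[adm_name], acs["BIS"], acs["CO"], block)
    rows.append(("f3_admixed_target", adm_name, f3_adm.estimate, f3_adm.se, f3_adm.z, f3_adm.n_sites))
    f3_bis = admixstats.f3(acs["BIS"], acs["CO"], acs["GA"], block)
    rows.append(("f3_clean_target", "BIS", f3_bis.estimate, f3_bis.se, f3_bis.z, f3_bis.n_sites))
    og = admixstats.outgroup_f3(acs["BIS"], acs["GA"], acs["OUT"], block)
    rows.append(("outgroup_f3_BIS_GA", "OUT", og.estimate, og.se, og.z, og.n_sites))
    _write(
        pd.DataFrame(rows, columns=["test", "target", "estimate", "se", "z", "n_sites"]),
        out / "f3.tsv",
    )
    # D for (((GA, admixed), CO), OUT): the admixed cohort's CO ancestry
    # drives an ABBA excess (D > 0)
    d = admixstats.patterson_d(acs["GA"], acs[adm_name], acs["CO"], acs["OUT"], block)
    _write(
        pd.DataFrame(
            [("GA", adm_name, "CO", "OUT", d.estimate, d.se, d.z, d.n_sites)],
            columns=["p1", "p2", "p3", "outgroup", "estimate", "se", "z", "n_sites"],
        ),
        out / "dstat.tsv",
    )
    done("admixstats")

    # -- classifier --------------------------------------------------------
    daf = classifier.compute_daf(gm, vt, by_cohort["BIS"], by_cohort["GA"])
    panel = classifier.build_panel(daf, tier=config.panel_tier)
    _write(panel.table, out / "daf_panel.tsv")
    if len(panel):
        pct = classifier.allelic_percentage(gm, panel)
        truth = cohorts.map({"BIS": "taxon_a", "GA": "taxon_b"}).dropna()
        report = classifier.classify(pct, config.hi_cutoff, config.lo_cutoff, truth=truth)
        report["cohort"] = report["sample_id"].map(cohorts)
        _write(report, out / "classification.tsv")
        done("classifier", n_markers=len(panel), accuracy=report.attrs.get("accuracy"))
    else:
        done("classifier", n_markers=0)

    # -- selection scan ----------------------------------------------------
    hseed = stage_seed(config.seed, "selection")
    haps, hpos = simulate_haplotypes(
        config.h12_variants, config.h12_haplotypes, seed=hseed,
        sweep=SweepConfig(
            contig="sim", center=(config.h12_variants // 2) * 100,
            frequency=config.sweep_frequency, flank=config.h12_variants * 100 // 10,
        ),
    )
    cal = selection.calibrate_window_size(haps, hpos, config.h12_candidates)
    _write(cal.table, out / "h12_calibration.tsv")
    scan = selection.scan_h12(haps, hpos, cal.chosen_size)
    _write(scan, out / "h12_scan.tsv")
    peaks = selection.find_peaks(scan, threshold=0.1)
    _write(peaks, out / "h12_peaks.tsv")
    done("selection", chosen_window=cal.chosen_size, n_peaks=len(peaks))

    # -- CNV ---------------------------------------------------------------
    cseed = stage_seed(config.seed, "cnv")
    rng = np.random.default_rng(cseed)
    n_w, n_s = config.cnv_windows, config.cnv_samples
    cnv_samples = [f"CNV{i:03d}" for i in range(n_s)]
    gc = rng.uniform(0.3, 0.6, size=n_w)
    truth = []
    for i in range(max(5, n_s // 3)):
        sid = cnv_samples[int(rng.integers(n_s))]
        start = int(rng.integers(0, n_w - 20))
        truth.append(CnvTruth(sid, "2R", start, start + int(rng.integers(7, 15)), int(rng.integers(3, 7))))
    try:
        counts = simulate_coverage(n_w, cnv_samples, gc, truth, seed=cseed, contig="2R")
    except ValueError:  # overlapping random truth; retry with spaced intervals
        truth = [
            CnvTruth(cnv_samples[i % n_s], "2R", 100 + 40 * i, 100 + 40 * i + 10, 4)
            for i in range(max(5, n_s // 3))
        ]
        counts = simulate_coverage(n_w, cnv_samples, gc, truth, seed=cseed, contig="2R")
    cov = cnv.CoverageMatrix(
        contig=np.full(n_w, "2R", dtype=object),
        start=np.arange(n_w, dtype=np.int64) * 300 + 1,
        counts=counts, gc=gc, sample_ids=cnv_samples,
    )
    cnv_meta = pd.DataFrame(
        {"sample_id": cnv_samples, "cohort": "BIS", "country": "synthetic",
         "site": "synthetic", "sex": "F", "year": 2020}
    )
    calls, qc = cnv.call_all(cov, cnv_meta, min_run=config.min_run)
    _write(calls, out / "cnv_calls.tsv")
    _write(qc, out / "cnv_qc.tsv")
    regions = pd.DataFrame(
        [("locus_a", "2R", 1, n_w * 300)], columns=["name", "contig", "start", "end"]
    )
    freq = cnv.cohort_cnv_frequency(calls, regions, cnv_meta, qc, valid_contigs=["2R"])
    _write(freq, out / "cnv_frequency.tsv")
    done("cnv", n_calls=len(calls))

    # -- resistance (tiny synthetic transcript) ----------------------------
    tm, ref_seq, vt_res, gm_res = _resistance_fixture(stage_seed(config.seed, "resistance"))
    ann = resistance.annotate_aa_changes(vt_res, tm, {"2L": ref_seq})
    freqs = resistance.cohort_substitution_frequencies(
        ann, gm_res, {"BIS": gm_res.sample_ids[:10], "GA": gm_res.sample_ids[10:]}
    )
    _write(freqs, out / "aa_frequencies.tsv")
    done("resistance", n_substitutions=freqs["substitution"].nunique() if len(freqs) else 0)

    manifest["outputs"] = sorted(p.name for p in out.glob("*.tsv"))
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _resistance_fixture(seed: int):
    """A 20-codon plus-strand transcript with a handful of coding SNPs."""
    from .core import GenotypeMatrix, VariantTable
    from .synthetic import simulate_genotypes

    rng = np.random.default_rng(seed)
    codons = ["ATG"] + ["TTA", "GGC", "AAA", "GAT", "TGC"] * 3 + ["CTG", "CCA", "TGG", "TAA"]
    cds = "".join(codons)
    ref_seq = "ACGT" * 5 + cds + "TTTT" * 5
    cds_start = 21
    from .resistance import TranscriptModel

    tm = TranscriptModel("TX1", "2L", "+", [(cds_start, cds_start + len(cds) - 1)])
    # SNPs: one nonsynonymous (TTA->TTT L->F), one synonymous (TTA->TTG), one noncoding
    snp_pos = [cds_start + 5, cds_start + 8, 3]
    refs = [ref_seq[p - 1] for p in snp_pos]
    alts = ["T", "G", "C"]
    order = np.argsort(snp_pos)
    vt = VariantTable(
        ["2L"] * 3, [snp_pos[i] for i in order], [refs[i] for i in order],
        [alts[i] for i in order], [True] * 3,
    )
    freqs = np.array([0.3, 0.2, 0.1])[order]
    gm = simulate_genotypes(freqs, 20, seed=seed, sample_prefix="RES_")
    return tm, ref_seq, vt, gm


def load_config(path) -> RunConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig(**data)
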