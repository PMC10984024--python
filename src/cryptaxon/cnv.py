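"""Coverage-based copy-number calling.

Pipeline per sample: GC-bin normalisation of windowed read counts to a
copy-number scale -> Gaussian HMM over integer copy-number states 0..12 ->
run-length CNV calls with a sex-aware ploidy threshold -> QC and cohort
frequencies over gene regions.

Normalisation divides each 300-bp window's count by the sample's mean count
over unfiltered autosomal windows in the same GC bin (1-percentage-point
bins; bins with fewer than 100 windows merged with neighbours) and
multiplies by two, so a diploid-neutral window sits near 2.0 regardless of
GC composition.

The HMM has fixed structure: state k emits Normal(k * baseline/ploidy,
sigma) with a shared sigma estimated robustly (1.4826 x MAD) from the
sample's track, stay-probability 1 - t and uniform switching t/12
(default t = 1e-5). Decoding is by the most likely path (Viterbi);
per-window state posteriors come from forward-backward and gate call
quality (mean posterior >= 0.9 over a called run by default).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

N_STATES = 13  # copy numbers 0..12


@dataclass
class CoverageMatrix:
    """Windowed read counts with per-window GC and mappability annotations."""

    contig: np.ndarray          # per window
    start: np.ndarray           # 1-based window start
    counts: np.ndarray          # (windows, samples)
    gc: np.ndarray
    sample_ids: list[str]
    mappability: np.ndarray | None = None
    window_size: int = 300
    x_contigs: tuple[str, ...] = ("X",)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.gc = np.asarray(self.gc, dtype=np.float64)
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if ((self.gc < 0) | (self.gc > 1)).any():
            raise ValueError("GC fraction outside [0, 1]")
        if self.mappability is None:
            self.mappability = np.ones(len(self.gc))

    @property
    def n_windows(self) -> int:
        return self.counts.shape[0]

    def is_autosome(self) -> np.ndarray:
        return ~np.isin(np.asarray(self.contig, dtype=object), self.x_contigs)


def filter_windows(
    cov: CoverageMatrix,
    gc_band: tuple[float, float] = (0.15, 0.85),
    min_mappability: float = 0.9,
) -> np.ndarray:
    """Keep-mask over windows: GC within band and mappability above threshold."""
    lo, hi = gc_band
    return (cov.gc >= lo) & (cov.gc <= hi) & (cov.mappability >= min_mappability)


def _gc_bin_groups(gc: np.ndarray, baseline: np.ndarray, min_bin: int = 100) -> np.ndarray:
    """Merge 1-pp GC bins (over baseline windows) until each group >= min_bin.

    Returns a group id per window (grouping applies to all windows; group
    occupancy is counted over the baseline windows only).
    """
    bins = np.clip(np.round(gc * 100).astype(int), 0, 100)
    occupied = np.unique(bins[baseline])
    counts = {b: int(np.sum(bins[baseline] == b)) for b in occupied}
    group_of_bin: dict[int, int] = {}
    gid, acc = 0, 0
    for b in occupied:
        group_of_bin[b] = gid
        acc += counts[b]
        if acc >= min_bin:
            gid, acc = gid + 1, 0
    if acc > 0 and gid > 0:  # trailing underfull group -> merge into previous
        for b, g in group_of_bin.items():
            if g == gid:
                group_of_bin[b] = gid - 1
    # bins never seen in the baseline windows map to the nearest occupied bin
    out = np.empty(len(bins), dtype=np.intp)
    for i, b in enumerate(bins):
        if b not in group_of_bin:
            b = occupied[np.argmin(np.abs(occupied - b))]
        out[i] = group_of_bin[b]
    return out


def gc_normalize(
    cov: CoverageMatrix,
    keep_mask: np.ndarray | None = None,
    min_bin_windows: int = 100,
) -> np.ndarray:
    """Normalised copy-number tracks, (windows, samples).

    Per sample: CN = 2 * count / mean(count over unfiltered autosomal windows
    in the window's GC bin). Samples with zero autosomal coverage raise.
    """
    if keep_mask is None:
        keep_mask = np.ones(cov.n_windows, dtype=bool)
    baseline = keep_mask & cov.is_autosome()
    if not baseline.any():
        raise ValueError("no unfiltered autosomal windows for GC baseline")
    groups = _gc_bin_groups(cov.gc, baseline, min_bin=min_bin_windows)
    n_groups = groups.max() + 1
    norm = np.empty_like(cov.counts)
    for j in range(cov.counts.shape[1]):
        c = cov.counts[:, j]
        if c[baseline].sum() == 0:
            raise ValueError(f"sample {cov.sample_ids[j]!r} has zero autosomal coverage")
        gsum = np.bincount(groups[baseline], weights=c[baseline], minlength=n_groups)
        gn = np.bincount(groups[baseline], minlength=n_groups)
        with np.errstate(invalid="ignore", divide="ignore"):
            gmean = np.where(gn > 0, gsum / gn, np.nan)
        # empty groups (can only arise off-baseline) fall back to overall mean
        gmean = np.where(np.isnan(gmean) | (gmean == 0), c[baseline].mean(), gmean)
        norm[:, j] = 2.0 * c / gmean[groups]
    return norm


def sample_qc(
    norm: np.ndarray,
    autosomal_keep: np.ndarray,
    variance_threshold: float = 0.2,
) -> np.ndarray:
    """Pass-flag per sample: variance of normalised CN over unfiltered
    autosomal windows at or below the threshold."""
    v = np.var(norm[autosomal_keep], axis=0)
    return v <= variance_threshold


# ---------------------------------------------------------------------------
# Gaussian HMM over copy-number states

def _log_emissions(tracks: np.ndarray, means: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """(T, B, K) Gaussian log-densities for B tracks with per-track means/sigma."""
    z = (tracks[:, :, None] - means[None, :, :]) / sigma[None, :, None]
    return -0.5 * z**2 - np.log(sigma * np.sqrt(2 * np.pi))[None, :, None]


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))


def viterbi_decode(log_emit: np.ndarray, stay: float) -> np.ndarray:
    """Most likely state path(s) for uniform-switch transitions (log space).

    ``log_emit`` is (T, K) for one track or (T, B, K) batched; returns (T,)
    or (T, B) integer states.
    """
    squeeze = log_emit.ndim == 2
    le = log_emit[:, None, :] if squeeze else log_emit
    t, b, k = le.shape
    log_stay = np.log(stay)
    log_switch = np.log((1 - stay) / (k - 1))
    idx = np.arange(k)[None, :]
    rows = np.arange(b)
    delta = le[0] - np.log(k)
    back = np.zeros((t, b, k), dtype=np.int8)
    back[0] = idx
    for i in range(1, t):
        # best predecessor is the same state (stay) or the best *other* state
        # (switch); track the top two to exclude self from the switch max
        top2 = np.argpartition(delta, k - 2, axis=1)[:, -2:]
        v = delta[rows[:, None], top2]
        first = np.argmax(v, axis=1)
        j1 = top2[rows, first]
        j2 = top2[rows, 1 - first]
        v1, v2 = delta[rows, j1], delta[rows, j2]
        self_best = idx == j1[:, None]
        best_other = np.where(self_best, v2[:, None], v1[:, None])
        arg_other = np.where(self_best, j2[:, None], j1[:, None])
        stay_score = delta + log_stay
        switch_score = best_other + log_switch
        take_stay = stay_score >= switch_score
        back[i] = np.where(take_stay, idx, arg_other)
        delta = np.where(take_stay, stay_score, switch_score) + le[i]
    path = np.empty((t, b), dtype=np.intp)
    path[-1] = np.argmax(delta, axis=1)
    for i in range(t - 2, -1, -1):
        path[i] = back[i + 1][rows, path[i + 1]]
    return path[:, 0] if squeeze else path


def forward_backward(log_emit: np.ndarray, stay: float) -> np.ndarray:
    """Per-window state posteriors under uniform-switch transitions.

    ``log_emit`` is (T, K) or (T, B, K); returns matching shape.
    """
    squeeze = log_emit.ndim == 2
    le = log_emit[:, None, :] if squeeze else log_emit
    t, b, k = le.shape
    switch = (1 - stay) / (k - 1)
    log_stay_excess = np.log(stay - switch)
    log_switch = np.log(switch)
    alpha = np.empty((t, b, k))
    alpha[0] = le[0] - np.log(k)
    for i in range(1, t):
        prev = alpha[i - 1]
        tot = _lse(prev, axis=1)
        alpha[i] = le[i] + np.logaddexp(prev + log_stay_excess, tot + log_switch)
    post = np.empty((t, b, k))
    beta = np.zeros((b, k))
    post[-1] = alpha[-1]
    for i in range(t - 2, -1, -1):
        nxt = beta + le[i + 1]
        tot = _lse(nxt, axis=1)
        beta = np.logaddexp(nxt + log_stay_excess, tot + log_switch)
        post[i] = alpha[i] + beta
    post -= _lse(post, axis=2)
    out = np.exp(post)
    return out[:, 0, :] if squeeze else out


@dataclass
class CnState:
    states: np.ndarray      # most-likely copy-number per window
    posterior: np.ndarray   # posterior of that state per window
    baseline: float
    sigma: float


def fit_hmm(
    track: np.ndarray,
    ploidy: int = 2,
    transition_t: float = 1e-5,
    n_states: int = N_STATES,
    sigma: float | None = None,
    min_sigma: float = 0.05,
) -> CnState:
    """Decode a normalised CN track into integer copy-number states.

    State k emits Normal(k * baseline/ploidy, sigma); baseline is the
    sample's median CN on the contig class (so ~2 on autosomes, ~1 on a male
    X after normalisation to the diploid scale... the track is always on the
    2 = diploid-neutral scale, hence ploidy enters through the threshold at
    call time and baseline/ploidy spaces states one CN apart). Shared sigma
    defaults to 1.4826 x median absolute deviation of the track.
    """
    states, posts, baselines, sigmas = fit_hmm_batch(
        np.asarray(track, dtype=np.float64)[:, None],
        ploidies=np.array([ploidy]),
        transition_t=transition_t,
        n_states=n_states,
        sigma=None if sigma is None else np.array([sigma]),
        min_sigma=min_sigma,
    )
    return CnState(
        states=states[:, 0],
        posterior=posts[:, 0],
        baseline=float(baselines[0]),
        sigma=float(sigmas[0]),
    )


def fit_hmm_batch(
    tracks: np.ndarray,
    ploidies: np.ndarray,
    transition_t: float = 1e-5,
    n_states: int = N_STATES,
    sigma: np.ndarray | None = None,
    min_sigma: float = 0.05,
):
    """Decode several tracks at once; ``tracks`` is (windows, tracks).

    Returns (states, posteriors, baselines, sigmas) with states and
    posteriors shaped like ``tracks``.
    """
    tracks = np.asarray(tracks, dtype=np.float64)
    t, b = tracks.shape
    if t < 5:
        raise ValueError("need >= 5 windows to decode")
    baselines = np.median(tracks, axis=0)
    if (baselines <= 0).any():
        bad = int(np.argmax(baselines <= 0))
        raise ValueError(f"degenerate baseline (median CN <= 0) in track {bad}")
    if sigma is None:
        mad = np.median(np.abs(tracks - baselines[None, :]), axis=0)
        sigma = np.maximum(1.4826 * mad, min_sigma)
    sigma = np.asarray(sigma, dtype=np.float64)
    if (sigma <= 0).any():
        bad = int(np.argmax(sigma <= 0))
        raise ValueError(f"degenerate emission variance in track {bad}")
    means = np.arange(n_states)[None, :] * (baselines / ploidies)[:, None]
    log_emit = _log_emissions(tracks, means, sigma)
    stay = 1.0 - transition_t
    states = viterbi_decode(log_emit, stay)
    post = forward_backward(log_emit, stay)
    wi = np.arange(t)[:, None]
    return states, post[wi, np.arange(b)[None, :], states], baselines, sigma


# ---------------------------------------------------------------------------
# Calling

def call_cnvs(
    cn: CnState,
    sample_id: str,
    contig: str,
    ploidy: int = 2,
    min_run: int = 5,
    min_posterior: float = 0.9,
    window_starts: np.ndarray | None = None,
    window_size: int = 300,
) -> pd.DataFrame:
    """Run-length CNV calls from a decoded state track.

    Amplifications are maximal runs of state > ploidy, deletions of state <
    ploidy, each at least ``min_run`` windows. Runs whose mean state
    posterior falls below ``min_posterior`` are flagged (qc_pass False) and
    excluded from cohort frequencies.
    """
    states = cn.states
    rows = []
    for kind, in_run in (("amp", states > ploidy), ("del", states < ploidy)):
        i = 0
        while i < len(states):
            if not in_run[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(states) and in_run[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                seg = states[i: j + 1]
                vals, cnts = np.unique(seg, return_counts=True)
                mean_post = float(cn.posterior[i: j + 1].mean())
                if window_starts is not None:
                    start_pos = int(window_starts[i])
                    end_pos = int(window_starts[j]) + window_size - 1
                else:
                    start_pos, end_pos = i, j
                rows.append(
                    (sample_id, contig, i, j, start_pos, end_pos, kind,
                     int(vals[np.argmax(cnts)]), mean_post,
                     mean_post >= min_posterior)
                )
            i = j + 1
    return pd.DataFrame(
        rows,
        columns=["sample_id", "contig", "start_idx", "end_idx", "start", "end",
                 "kind", "modal_state", "mean_posterior", "qc_pass"],
    )


def call_sample(
    cov: CoverageMatrix,
    norm: np.ndarray,
    sample_idx: int,
    sex: str,
    keep_mask: np.ndarray,
    contig: str,
    min_run: int = 5,
    min_posterior: float = 0.9,
    transition_t: float = 1e-5,
) -> pd.DataFrame:
    """Decode and call one sample on one contig (sex-aware X ploidy)."""
    on_contig = np.asarray(cov.contig, dtype=object) == contig
    use = on_contig & keep_mask
    if use.sum() < 5:
        return call_cnvs(CnState(np.empty(0, int), np.empty(0), 2.0, 0.1), "", contig)
    is_x = contig in cov.x_contigs
    ploidy = 1 if (is_x and sex == "M") else 2
    track = norm[use, sample_idx]
    if ploidy == 1:
        # male X tracks sit near 1.0 on the diploid scale; decode on that scale
        cn = fit_hmm(track, ploidy=1, transition_t=transition_t)
    else:
        cn = fit_hmm(track, ploidy=2, transition_t=transition_t)
    starts = cov.start[use]
    return call_cnvs(
        cn, cov.sample_ids[sample_idx], contig, ploidy=ploidy, min_run=min_run,
        min_posterior=min_posterior, window_starts=starts, window_size=cov.window_size,
    )


def call_all(
    cov: CoverageMatrix,
    samples: pd.DataFrame,
    gc_band: tuple[float, float] = (0.15, 0.85),
    min_mappability: float = 0.9,
    variance_threshold: float = 0.2,
    min_run: int = 5,
    min_posterior: float = 0.9,
    transition_t: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full calling over all samples and contigs.

    Returns (calls, per-sample QC table). QC-failing samples are excluded
    from calling altogether.
    """
    keep = filter_windows(cov, gc_band, min_mappability)
    norm = gc_normalize(cov, keep)
    qc_pass = sample_qc(norm, keep & cov.is_autosome(), variance_threshold)
    sex = samples.set_index("sample_id")["sex"] if "sex" in samples.columns else None
    all_calls = []
    passing = np.flatnonzero(qc_pass)
    for contig in pd.unique(np.asarray(cov.contig, dtype=object)):
        use = (np.asarray(cov.contig, dtype=object) == contig) & keep
        if use.sum() < 5:
            continue
        is_x = contig in cov.x_contigs
        starts = cov.start[use]
        for chunk in np.array_split(passing, max(1, len(passing) // 16)):
            if len(chunk) == 0:
                continue
            ploidies = np.array(
                [
                    1 if (is_x and sex is not None and sex.get(cov.sample_ids[j]) == "M") else 2
                    for j in chunk
                ]
            )
            states, posts, _, _ = fit_hmm_batch(
                norm[np.ix_(use, chunk)], ploidies, transition_t=transition_t
            )
            for c, j in enumerate(chunk):
                calls = call_cnvs(
                    CnState(states[:, c], posts[:, c], 2.0, 0.1),
                    cov.sample_ids[j], contig, ploidy=int(ploidies[c]),
                    min_run=min_run, min_posterior=min_posterior,
                    window_starts=starts, window_size=cov.window_size,
                )
                if len(calls):
                    all_calls.append(calls)
    calls = (
        pd.concat(all_calls, ignore_index=True)
        if all_calls
        else call_cnvs(CnState(np.empty(0, int), np.empty(0), 2.0, 0.1), "", "")
    )
    qc = pd.DataFrame({"sample_id": cov.sample_ids, "qc_pass": qc_pass})
    return calls, qc


def cohort_cnv_frequency(
    calls: pd.DataFrame,
    regions: pd.DataFrame,
    samples: pd.DataFrame,
    qc: pd.DataFrame,
    valid_contigs: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fraction of QC-passing cohort members with >= 1 call overlapping a region.

    ``regions`` columns: name, contig, start, end (1-based inclusive).
    Presence/absence only: an individual with several overlapping calls
    counts once. Amplifications and deletions tabulated separately.
    ``valid_contigs`` (when given) guards against regions on contigs the
    coverage data never saw.
    """
    ok = calls[calls["qc_pass"]] if len(calls) else calls
    passing = set(qc.loc[qc["qc_pass"], "sample_id"])
    members = samples[samples["sample_id"].isin(passing)]
    rows = []
    for region in regions.itertuples(index=False):
        if valid_contigs is not None and region.contig not in set(valid_contigs):
            raise ValueError(f"region {region.name!r} on unknown contig {region.contig!r}")
        hit = ok[
            (ok["contig"] == region.contig)
            & (ok["start"] <= region.end)
            & (ok["end"] >= region.start)
        ]
        for kind in ("amp", "del"):
            carriers = set(hit.loc[hit["kind"] == kind, "sample_id"])
            for cohort, grp in members.groupby("cohort"):
                n = len(grp)
                f = len(set(grp["sample_id"]) & carriers) / n if n else np.nan
                rows.append((region.name, region.contig, kind, cohort, n, f))
    return pd.DataFrame(
        rows, columns=["region", "contig", "kind", "cohort", "n_samples", "frequency"]
    )
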