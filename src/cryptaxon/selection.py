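"""Garud H-statistics over haplotype windows, window-size calibration and
peak flagging for selective-sweep scans.

H1 is the haplotype homozygosity ``sum f_i^2`` over the frequencies of
distinct haplotypes within a window; H12 pools the two most frequent
haplotypes, ``(f1+f2)^2 + sum_{i>=3} f_i^2``, gaining sensitivity to soft
sweeps where the swept material rides on two backgrounds; H123 pools three.
H2/H1 (``(H1 - f1^2)/H1``) helps distinguish hard from soft sweeps.

Window size is in SNPs. The calibration rule scans candidate sizes and
chooses the smallest whose genome-wide H12 distribution has its 95th
percentile at or below 0.1, so that the neutral background rarely exceeds
the peak-flagging threshold.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def haplotype_frequencies(window_haps: np.ndarray) -> np.ndarray:
    """Descending frequencies of distinct haplotype sequences in a window."""
    h = np.ascontiguousarray(np.asarray(window_haps, dtype=np.int8).T)
    if h.shape[0] < 2:
        raise ValueError("need >= 2 haplotypes")
    if h.shape[1] == 0:
        raise ValueError("zero-width window")
    _, counts = np.unique(h.view([("", h.dtype)] * h.shape[1]), return_counts=True)
    f = np.sort(counts)[::-1] / h.shape[0]
    return f


def h_statistics(window_haps: np.ndarray) -> dict[str, float]:
    """H1, H12, H123 and H2/H1 for one window of (variants, haplotypes)."""
    f = haplotype_frequencies(window_haps)
    f2 = f**2
    h1 = float(f2.sum())
    h12 = float((f[:2].sum()) ** 2 + f2[2:].sum())
    h123 = float((f[:3].sum()) ** 2 + f2[3:].sum())
    h2h1 = float((h1 - f2[0]) / h1)
    return {"H1": h1, "H12": h12, "H123": h123, "H2H1": h2h1}


def scan_h12(
    haps: np.ndarray,
    positions: np.ndarray,
    window_snps: int,
    step_snps: int | None = None,
) -> pd.DataFrame:
    """Windowed H-statistics along a contig.

    Windows of ``window_snps`` SNPs advance by ``step_snps`` (default
    window/2). Genomic spans are taken from the first/last SNP positions.
    Returns an empty frame when the contig holds fewer SNPs than one window.
    """
    if window_snps < 2:
        raise ValueError("window must span >= 2 SNPs")
    if step_snps is None:
        step_snps = max(1, window_snps // 2)
    positions = np.asarray(positions)
    n = haps.shape[0]
    rows = []
    for start in range(0, n - window_snps + 1, step_snps):
        stop = start + window_snps
        st = h_statistics(haps[start:stop])
        rows.append(
            (start, stop - 1, int(positions[start]), int(positions[stop - 1]),
             st["H1"], st["H12"], st["H123"], st["H2H1"])
        )
    return pd.DataFrame(
        rows,
        columns=["start_idx", "end_idx", "span_start", "span_end",
                 "H1", "H12", "H123", "H2H1"],
    )


@dataclass
class WindowCalibration:
    chosen_size: int
    table: pd.DataFrame      # window_snps, p95, n_windows
    satisfied: bool          # False -> no candidate met the rule (largest used)


def calibrate_window_size(
    haps: np.ndarray,
    positions: np.ndarray,
    candidate_sizes: list[int],
    percentile: float = 95.0,
    target: float = 0.1,
    step_snps: int | None = None,
) -> WindowCalibration:
    """Smallest candidate window whose H12 95th percentile is <= target.

    When no candidate satisfies the rule the largest candidate is returned
    with ``satisfied=False`` (a warning flag, not an error: very unswept-poor
    or tiny datasets may never reach the target).
    """
    if len(candidate_sizes) < 1:
        raise ValueError("need at least one candidate window size")
    rows = []
    for w in sorted(candidate_sizes):
        scan = scan_h12(haps, positions, w, step_snps)
        p95 = float(np.percentile(scan["H12"], percentile)) if len(scan) else np.nan
        rows.append((w, p95, len(scan)))
    table = pd.DataFrame(rows, columns=["window_snps", "p95", "n_windows"])
    ok = table[table["p95"] <= target]
    if len(ok):
        return WindowCalibration(int(ok["window_snps"].iloc[0]), table, True)
    return WindowCalibration(int(table["window_snps"].iloc[-1]), table, False)


def find_peaks(scan: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Maximal runs of contiguous scan windows with H12 above threshold.

    Each peak reports its window-index span, genomic span and the window of
    maximum H12.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    above = (scan["H12"] > threshold).to_numpy()
    rows = []
    i = 0
    while i < len(above):
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < len(above) and above[j + 1]:
            j += 1
        block = scan.iloc[i: j + 1]
        top = block.loc[block["H12"].idxmax()]
        rows.append(
            (int(block["start_idx"].iloc[0]), int(block["end_idx"].iloc[-1]),
             int(block["span_start"].iloc[0]), int(block["span_end"].iloc[-1]),
             float(top["H12"]), int(top["span_start"]), int(top["span_end"]))
        )
        i = j + 1
    return pd.DataFrame(
        rows,
        columns=["start_idx", "end_idx", "span_start", "span_end",
                 "max_h12", "max_window_start", "max_window_end"],
    )
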