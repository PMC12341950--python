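"""Trans-eQTL density profiles and permutation-calibrated hotspot calling.

eQTL consensus positions are counted in half-open sliding windows
[s, s + w) advanced by a fixed step along each chromosome (default 10 cM
windows, 1 cM step), plus a final window ending exactly at the chromosome
end when the regular grid falls short. The significance threshold is
global: each permutation redraws the same number of positions uniformly
over the genetic map (chromosome chosen proportionally to its length) and
the stated percentile (default 95th) of the pooled window counts across all
permutations becomes the count threshold. Maximal runs of windows whose
count exceeds the threshold are merged into hotspot intervals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import GeneticMap


@dataclass
class HotspotProfile:
    """Window counts, threshold, and called intervals for one phenotype."""

    windows: pd.DataFrame   # chromosome, start, end, count
    threshold: float
    intervals: pd.DataFrame  # chromosome, start, end, peak_cM, peak_count


def _window_starts(length: float, window: float, step: float) -> np.ndarray:
    n_regular = int(np.floor((length - window) / step + 1e-9)) + 1
    if n_regular < 1:
        return np.array([max(length - window, 0.0)])
    starts = np.arange(n_regular) * step
    if starts[-1] + window < length - 1e-9:
        starts = np.append(starts, length - window)
    return starts


def sliding_window_counts(positions: pd.DataFrame, gmap: GeneticMap,
                          window: float = 10.0, step: float = 1.0) -> pd.DataFrame:
    """Count positions per half-open sliding window on every chromosome.

    ``positions`` has columns chromosome, position_cM; a position outside
    its chromosome's [0, end] raises ``ValueError``.
    """
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be > 0")
    rows = []
    for chrom in gmap.chromosomes:
        length = gmap.chrom_ends[chrom]
        pos = positions.loc[positions["chromosome"] == chrom,
                            "position_cM"].to_numpy(float)
        if pos.size and (pos.min() < 0 or pos.max() > length + 1e-9):
            bad = pos[(pos < 0) | (pos > length + 1e-9)][0]
            raise ValueError(
                f"position {bad} outside chromosome {chrom!r} bounds [0, {length}]"
            )
        starts = _window_starts(length, window, step)
        pos_sorted = np.sort(pos)
        lo = np.searchsorted(pos_sorted, starts, side="left")
        hi = np.searchsorted(pos_sorted, starts + window, side="left")
        for s, c in zip(starts, hi - lo):
            rows.append({"chromosome": chrom, "start": float(s),
                         "end": float(s + window), "count": int(c)})
    return pd.DataFrame(rows)


def permutation_threshold(n_eqtl: int, gmap: GeneticMap, window: float,
                          step: float, n_permutations: int,
                          percentile: float, seed: int,
                          marker_weighted: bool = False) -> float:
    """Global window-count threshold from uniform-position permutations.

    Each permutation redraws ``n_eqtl`` positions uniformly over the map
    (or at markers, weighted by marker frequency, when ``marker_weighted``)
    and recomputes every window count; the threshold is the requested
    percentile of the pooled counts over all permutations and windows.
    """
    if n_eqtl == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    chroms = gmap.chromosomes
    lengths = np.array([gmap.chrom_ends[c] for c in chroms])
    probs = lengths / lengths.sum()
    marker_pos = {c: gmap.positions(c) for c in chroms}

    starts = {c: _window_starts(gmap.chrom_ends[c], window, step) for c in chroms}
    pooled = []
    for _ in range(n_permutations):
        which = rng.choice(len(chroms), size=n_eqtl, p=probs)
        for ci, chrom in enumerate(chroms):
            n_here = int(np.sum(which == ci))
            if marker_weighted:
                pos = rng.choice(marker_pos[chrom], size=n_here)
            else:
                pos = rng.uniform(0, lengths[ci], size=n_here)
            pos.sort()
            s = starts[chrom]
            counts = (np.searchsorted(pos, s + window, side="left")
                      - np.searchsorted(pos, s, side="left"))
            pooled.append(counts)
    pooled_arr = np.concatenate(pooled)
    return float(np.percentile(pooled_arr, percentile))


def call_hotspots(windows: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Merge maximal runs of windows with count > threshold into intervals.

    Interval extent is [first window start, last window end); the peak is
    the window with the maximum count (ties -> smallest start).
    """
    rows = []
    for chrom, sub in windows.groupby("chromosome", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        above = sub["count"].to_numpy() > threshold
        i = 0
        while i < len(sub):
            if not above[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(sub) and above[j + 1]:
                j += 1
            run = sub.iloc[i:j + 1]
            peak = run.loc[run["count"].idxmax()]
            rows.append({"chromosome": chrom,
                         "start": float(run["start"].iloc[0]),
                         "end": float(run["end"].iloc[-1]),
                         "peak_cM": float(peak["start"] + (peak["end"] - peak["start"]) / 2),
                         "peak_count": int(peak["count"])})
            i = j + 1
    return pd.DataFrame(rows, columns=["chromosome", "start", "end",
                                       "peak_cM", "peak_count"])


def hotspot_profile(positions: pd.DataFrame, gmap: GeneticMap,
                    window: float = 10.0, step: float = 1.0,
                    n_permutations: int = 1000, percentile: float = 95.0,
                    seed: int = 0, marker_weighted: bool = False) -> HotspotProfile:
    """Full hotspot analysis for one phenotype's trans-eQTL positions."""
    counts = sliding_window_counts(positions, gmap, window, step)
    threshold = permutation_threshold(len(positions), gmap, window, step,
                                      n_permutations, percentile, seed,
                                      marker_weighted)
    intervals = call_hotspots(counts, threshold)
    counts = counts.assign(threshold=threshold,
                           is_hotspot=counts["count"] > threshold)
    return HotspotProfile(counts, threshold, intervals)
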