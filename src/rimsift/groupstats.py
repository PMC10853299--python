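"""Voxel-wise group histogram analysis and the lesion-wise rank contrast.

Group histograms are expressed in percent of the group's voxels rather
than raw frequency, so the severely imbalanced PRL and nPR-WML samples
can be overlaid on one axis. Mode detection runs on a moving-average
smoothed histogram and keeps the two most topographically prominent local
maxima separated by a span of at least five bins. A candidate only counts
as a mode when its prominence is at least half its own height (and at
least 5% of the tallest bin): sampling bumps riding on the flank of a
dominant mode have near-zero prominence and are rejected, while a genuine
second mode — however small, like the deep-hypointense PRL mode — stands
on its full height. Between two detected modes the lowest
smoothed bin marks the inter-mode minimum, the natural cutoff below which
voxels count as deeply hypointense.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import norm, rankdata

__all__ = [
    "GroupHistogram",
    "BimodalSummary",
    "group_histogram",
    "detect_modes",
    "deep_fraction",
    "summarize_group",
    "wilcoxon_rank_sum",
]

DEFAULT_BIN_WIDTH = 0.1
DEFAULT_SMOOTH_WINDOW = 5
DEFAULT_DEEP_CUTOFF = 25.0
_MIN_MODE_SPAN_BINS = 5  # inclusive span: mode bin indices differ by >= span-1
_PROMINENCE_FRAC = 0.05  # absolute floor, relative to the tallest smoothed bin
_OWN_HEIGHT_FRAC = 0.5   # a mode's prominence must be >= half its own height


@dataclass
class GroupHistogram:
    """Uniform-bin histogram with heights in percent of group voxels."""

    bin_edges: np.ndarray
    heights_percent: np.ndarray
    group: str = ""

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.heights_percent = np.asarray(self.heights_percent, dtype=float)
        if self.bin_edges.size != self.heights_percent.size + 1:
            raise ValueError("need len(bin_edges) == len(heights) + 1")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(self.heights_percent < 0):
            raise ValueError("heights must be non-negative")
        if abs(self.heights_percent.sum() - 100.0) > 1e-9:
            raise ValueError("heights must sum to 100 percent")

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers,
                             "percent": self.heights_percent})

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class BimodalSummary:
    """Modes, inter-mode minimum and the deep-voxel fraction of one group."""

    mode_locations: tuple
    intermode_minimum: float | None = None
    deep_cutoff: float | None = None
    deep_fraction: float | None = None

    @property
    def is_bimodal(self) -> bool:
        return len(self.mode_locations) == 2


def group_histogram(values, bin_width: float = DEFAULT_BIN_WIDTH,
                    group: str = "") -> GroupHistogram:
    """Percent histogram with uniform bins covering [floor(min), ceil(max)]."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot histogram an empty sample")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = np.floor(values.min())
    # right-open bins [lo+k*w, lo+(k+1)*w): a value on the top edge opens
    # one more bin, so {1,1,2} at width 1 gives heights 2/3 and 1/3
    n_bins = int(np.floor((values.max() - lo) / bin_width)) + 1
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    return GroupHistogram(edges, counts / values.size * 100.0, group)


def detect_modes(hist: GroupHistogram,
                 smooth_window: int = DEFAULT_SMOOTH_WINDOW) -> BimodalSummary:
    """Locate up to two modes of a smoothed histogram.

    Candidate modes are prominent local maxima of the moving-average
    smoothed heights; the two most prominent (ties broken toward the
    taller, then the lower intensity) spanning at least five bins are
    kept. The inter-mode minimum is the
    bin center of the lowest smoothed height strictly between them.
    """
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be odd and >= 1")
    h = hist.heights_percent
    if h.size < 3:
        raise ValueError("need at least 3 bins for mode detection")
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(h, kernel, mode="same")
    centers = hist.bin_centers

    peaks, props = find_peaks(smoothed, prominence=_PROMINENCE_FRAC * smoothed.max())
    # a genuine mode stands mostly on its own height; a sampling bump on
    # the flank of a taller mode has near-zero prominence and is dropped
    keep = props["prominences"] >= _OWN_HEIGHT_FRAC * smoothed[peaks]
    peaks = peaks[keep]
    if peaks.size == 0:  # plateau-shaped histogram: fall back to the argmax
        peaks = np.array([int(np.argmax(smoothed))])
        props = {"prominences": smoothed[peaks]}
    else:
        props = {"prominences": props["prominences"][keep]}
    # most prominent first; ties toward the taller then the lower intensity
    prom = {int(i): float(p) for i, p in zip(peaks, props["prominences"])}
    order = sorted(peaks, key=lambda i: (-prom[int(i)], -smoothed[i], centers[i]))
    chosen: list[int] = []
    for i in order:
        if all(abs(i - j) >= _MIN_MODE_SPAN_BINS - 1 for j in chosen):
            chosen.append(int(i))
        if len(chosen) == 2:
            break
    chosen.sort()
    modes = tuple(float(centers[i]) for i in chosen)

    intermode = None
    if len(chosen) == 2:
        lo, hi = chosen
        between = np.arange(lo + 1, hi)
        k = between[np.argmin(smoothed[between])]
        intermode = float(centers[k])
    return BimodalSummary(mode_locations=modes, intermode_minimum=intermode)


def deep_fraction(values, cutoff: float) -> float:
    """Fraction of values strictly below the cutoff."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("deep_fraction of an empty sample is undefined")
    return float((values < cutoff).mean())


def summarize_group(values, bin_width: float = DEFAULT_BIN_WIDTH,
                    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
                    deep_cutoff: float = DEFAULT_DEEP_CUTOFF,
                    group: str = "") -> BimodalSummary:
    """Histogram + mode detection + deep-voxel fraction in one call."""
    hist = group_histogram(values, bin_width, group)
    summary = detect_modes(hist, smooth_window)
    summary.deep_cutoff = float(deep_cutoff)
    summary.deep_fraction = deep_fraction(values, deep_cutoff)
    return summary


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum statistic, p).

    The statistic is the sum of midranks of ``x`` in the pooled sample.
    The null distribution is enumerated exactly when m+n <= 20 and there
    are no ties; otherwise a tie-corrected normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(ranks[:m].sum())
    has_ties = np.unique(pooled).size < pooled.size

    if m + n <= 20 and not has_ties:
        # exact: enumerate rank-sum distribution via the standard
        # polynomial recursion over which ranks belong to x
        N = m + n
        # counts[s] = number of m-subsets of {1..N} with sum s
        maxsum = m * N
        counts = np.zeros((m + 1, maxsum + 1), dtype=object)
        counts[0, 0] = 1
        for r in range(1, N + 1):
            for k in range(min(m, r), 0, -1):
                counts[k, r:maxsum + 1] += counts[k - 1, 0:maxsum + 1 - r]
        dist = counts[m]
        total = int(dist.sum())
        mean = m * (N + 1) / 2.0
        # two-sided: double the smaller tail (standard exact convention)
        s = int(round(w))
        lower = int(dist[: s + 1].sum())
        upper = int(dist[s:].sum())
        p = min(1.0, 2.0 * min(lower, upper) / total)
        return w, p

    N = m + n
    mean = m * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (N * (N - 1))
    var = m * n / 12.0 * ((N + 1) - tie_term)
    if var == 0:
        return w, 1.0
    z = (abs(w - mean) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * norm.sf(z)))
    return w, p
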