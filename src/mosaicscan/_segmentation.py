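"""Interval-scan changepoint machinery and density helpers.

Mosaic events are contiguous bumps in an otherwise flat per-probe series,
so detection uses a multi-scale scan statistic: for window length w and
start s, score(s, w) = sum(x[s:s+w]) / (sigma sqrt(w)), the mean shift in
null standard errors.  Windows on a geometric scale grid seed candidate
intervals; each seed's boundaries are then refined by exact
coordinate-wise search, and non-overlapping intervals exceeding the score
threshold are accepted greedily from the best down.  Plain binary
segmentation (recursive single-changepoint CUSUM) is much weaker here: a
short interior bump splits a long sequence into halves whose means barely
differ.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.signal import find_peaks
from sklearn.neighbors import KernelDensity

_SCALE_RATIO = 1.4
_SEED_FRACTION = 0.7  # keep seeds within this fraction of threshold for refinement


def _window_scores(
    cs: np.ndarray, sigma: float, w: int, n: int, two_sided: bool
) -> tuple[np.ndarray, np.ndarray]:
    step = max(1, w // 4)
    starts = np.arange(0, n - w + 1, step)
    scores = (cs[starts + w] - cs[starts]) / (sigma * math.sqrt(w))
    if two_sided:
        scores = np.abs(scores)
    return starts, scores


def _refine(
    x: np.ndarray, cs: np.ndarray, sigma: float, s: int, e: int,
    min_size: int, two_sided: bool,
) -> tuple[int, int, float]:
    """Coordinate-wise exact boundary optimization of one seed interval."""
    n = x.size

    def score(i: int, j: int) -> float:
        sc = (cs[j] - cs[i]) / (sigma * math.sqrt(j - i))
        return abs(sc) if two_sided else sc

    for _ in range(4):
        w = e - s
        lo, hi = max(0, s - w), min(n, e + w)
        ss = np.arange(lo, e - min_size + 1)
        sc = (cs[e] - cs[ss]) / (sigma * np.sqrt(e - ss))
        if two_sided:
            sc = np.abs(sc)
        s_new = int(ss[np.argmax(sc)])
        ee = np.arange(s_new + min_size, hi + 1)
        sc = (cs[ee] - cs[s_new]) / (sigma * np.sqrt(ee - s_new))
        if two_sided:
            sc = np.abs(sc)
        e_new = int(ee[np.argmax(sc)])
        if (s_new, e_new) == (s, e):
            break
        s, e = s_new, e_new
    return s, e, score(s, e)


def scan_intervals(
    x: np.ndarray,
    sigma: float,
    threshold: float,
    min_size: int,
    two_sided: bool = True,
) -> list[tuple[int, int, float]]:
    """Non-overlapping intervals whose scan score exceeds ``threshold``.

    Returns ``(start, end, score)`` tuples with half-open index ranges,
    sorted by position.  ``two_sided=False`` accepts only positive mean
    shifts (the folded-deviation signal can only increase under an event).
    """
    n = x.size
    if n < min_size or not np.isfinite(sigma) or sigma <= 0:
        return []
    cs = np.concatenate([[0.0], np.cumsum(x)])
    cands: list[tuple[float, int, int]] = []
    w = min_size
    while True:
        starts, scores = _window_scores(cs, sigma, w, n, two_sided)
        keep = scores >= _SEED_FRACTION * threshold
        cands.extend(
            (float(sc), int(s), int(s) + w) for s, sc in zip(starts[keep], scores[keep])
        )
        if w >= n:
            break
        w = min(n, int(math.ceil(w * _SCALE_RATIO)))
    cands.sort(reverse=True)
    taken = np.zeros(n, dtype=bool)
    accepted: list[tuple[int, int, float]] = []
    for _, s, e in cands:
        if taken[s:e].any():
            continue
        s2, e2, sc2 = _refine(x, cs, sigma, s, e, min_size, two_sided)
        if sc2 >= threshold and not taken[s2:e2].any():
            accepted.append((s2, e2, sc2))
            taken[s2:e2] = True
    accepted.sort()
    return accepted


def robust_sigma(x: np.ndarray) -> float:
    """Normal-consistent scale from the median absolute deviation.

    Robust to a minority of event probes contaminating the null.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return float("nan")
    med = np.median(x)
    return float(1.4826 * np.median(np.abs(x - med)))


def kde_peaks(
    values: np.ndarray,
    bandwidth: float = 0.02,
    lo: float = 0.0,
    hi: float = 1.0,
    grid_step: float = 0.002,
    rel_prominence: float = 0.05,
) -> np.ndarray:
    """Positions of kernel-density modes of ``values`` on [lo, hi].

    Gaussian KDE with an absolute bandwidth; modes are local maxima of the
    density with prominence at least ``rel_prominence`` of the global
    maximum.  The density is zero-padded so boundary modes are counted.
    """
    values = np.asarray(values, dtype=float)
    values = values[(values >= lo) & (values <= hi)]
    if values.size < 3:
        return np.array([])
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    kde = KernelDensity(kernel="gaussian", bandwidth=bandwidth)
    kde.fit(values[:, None])
    dens = np.exp(kde.score_samples(grid[:, None]))
    padded = np.concatenate(([0.0], dens, [0.0]))
    idx, _ = find_peaks(padded, prominence=rel_prominence * dens.max())
    return grid[idx - 1]
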