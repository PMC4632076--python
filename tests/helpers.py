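"""Shared test utilities: independent oracles and signal generators."""

from __future__ import annotations

from itertools import combinations

import numpy as np

MIN_SEG = 2


def _rss(x: np.ndarray, bounds: list[int]) -> float:
    return sum(float(((x[a:b] - x[a:b].mean()) ** 2).sum())
               for a, b in zip(bounds[:-1], bounds[1:]))


def exhaustive_breakpoints(x: np.ndarray, k: int) -> list[int]:
    """Best k-changepoint segmentation by exhaustive RSS minimization.

    Independent of the production segmentation path: enumerates every
    admissible split (segments of at least MIN_SEG points) and picks the
    one with the smallest residual sum of squares.
    """
    n = len(x)
    if k == 0:
        return []
    best, best_rss = None, np.inf
    candidates = range(MIN_SEG, n - MIN_SEG + 1)
    for combo in combinations(candidates, k):
        bounds = [0, *combo, n]
        if any(b - a < MIN_SEG for a, b in zip(bounds[:-1], bounds[1:])):
            continue
        rss = _rss(x, bounds)
        if rss < best_rss:
            best, best_rss = list(combo), rss
    return best or []


def random_step_signal(rng: np.random.Generator, n: int, k: int,
                       noise_sd: float = 0.3, min_shift: float = 2.0,
                       edge: int = 5, gap: int = 8):
    """Piecewise-constant signal with ``k`` well-separated changepoints.

    Returns ``(x, breakpoints)`` with shifts of magnitude >= ``min_shift``
    alternating in direction so consecutive segments always differ.
    ``min_shift`` defaults well above sd_coefficient x noise (the
    segmentation undo threshold), so a realized level difference cannot
    legitimately be merged away.
    """
    while True:
        bps = sorted(rng.choice(np.arange(edge, n - edge), size=k, replace=False))
        if all(b - a >= gap for a, b in zip(bps[:-1], bps[1:])):
            break
    levels = [0.0]
    for i in range(k):
        step = rng.uniform(min_shift, min_shift + 1.5)
        levels.append(levels[-1] + step * (1 if i % 2 == 0 else -1))
    x = np.empty(n)
    bounds = [0, *bps, n]
    for lvl, (a, b) in zip(levels, zip(bounds[:-1], bounds[1:])):
        x[a:b] = lvl + rng.normal(0, noise_sd, b - a)
    return x, list(map(int, bps))


def deming_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Orthogonal (equal-error-variance Deming) regression slope.

    Used instead of OLS when both coordinates carry comparable measurement
    noise, which attenuates an OLS slope toward zero.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxx = np.var(x, ddof=1)
    syy = np.var(y, ddof=1)
    sxy = np.cov(x, y, ddof=1)[0, 1]
    d = syy - sxx
    return float((d + np.sqrt(d * d + 4 * sxy * sxy)) / (2 * sxy))
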