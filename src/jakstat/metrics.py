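"""Empirical CDFs and the two-sample Kolmogorov distance.

The Kolmogorov distance D_KS = sup_x |F_a(x) - F_b(x)| is used throughout the
package as a plain distance between empirical distributions (snapshot fits,
extrinsic-noise response conservation, parameter robustness scoring); no
p-values are attached.  The supremum is evaluated exactly over the merged
sample points with multiplicity-weighted steps, not on a grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ECDFRep", "ecdf", "ks_distance", "dip_statistic", "dip_test"]


@dataclass(frozen=True)
class ECDFRep:
    """Right-continuous empirical CDF: F(x) = #{samples <= x} / n."""

    values: np.ndarray  # sorted unique sample values
    probabilities: np.ndarray  # cumulative probabilities, ending at 1.0
    n: int

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.values, np.asarray(x, dtype=float), side="right")
        out = np.concatenate([[0.0], self.probabilities])[idx]
        return float(out) if np.isscalar(x) or np.asarray(x).ndim == 0 else out

    def to_csv(self, path: str | Path) -> None:
        arr = np.column_stack([self.values, self.probabilities])
        header = "value,cumulative_probability"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


def _clean(samples, name: str) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError(f"{name}: at least one sample required")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{name}: samples must be finite")
    return x


def ecdf(samples) -> ECDFRep:
    """Empirical CDF of a finite sample (ties merged by multiplicity)."""
    x = np.sort(_clean(samples, "ecdf"))
    vals, counts = np.unique(x, return_counts=True)
    probs = np.cumsum(counts) / x.size
    probs[-1] = 1.0
    return ECDFRep(vals, probs, x.size)


def ks_distance(a, b) -> float:
    """Exact two-sample Kolmogorov distance, sup over merged sample points.

    Symmetric, lies in [0, 1], and is 0 iff the two empirical distributions
    coincide.
    """
    xa = np.sort(_clean(a, "ks_distance(a)"))
    xb = np.sort(_clean(b, "ks_distance(b)"))
    grid = np.concatenate([xa, xb])
    fa = np.searchsorted(xa, grid, side="right") / xa.size
    fb = np.searchsorted(xb, grid, side="right") / xb.size
    return float(np.abs(fa - fb).max())


# --------------------------------------------------------------------------
# unimodality (Hartigan-style dip)
# --------------------------------------------------------------------------


def _hull_deviation_lower(x: np.ndarray, f: np.ndarray) -> float:
    """Max deviation of the points (x, f) above their greatest convex
    minorant (Andrew's monotone chain lower hull)."""
    hull = [0]
    for i in range(1, len(x)):
        while len(hull) >= 2:
            i1, i2 = hull[-2], hull[-1]
            cross = (x[i2] - x[i1]) * (f[i] - f[i1]) - (f[i2] - f[i1]) * (x[i] - x[i1])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    dev = 0.0
    h = np.array(hull)
    for k in range(len(h) - 1):
        i1, i2 = h[k], h[k + 1]
        if x[i2] == x[i1]:
            continue
        sl = (f[i2] - f[i1]) / (x[i2] - x[i1])
        seg = slice(i1, i2 + 1)
        d = np.max(f[seg] - (f[i1] + sl * (x[seg] - x[i1])))
        if d > dev:
            dev = d
    return dev


def dip_statistic(samples, n_modes: int = 50) -> float:
    """Distance of the ECDF to the closest unimodal CDF (Hartigan-style).

    For each candidate mode (restricted to ``n_modes`` sample quantiles) the
    closest unimodal CDF is convex left of the mode and concave right of it;
    the statistic is the smallest, over modes, of the largest one-sided
    deviation of the ECDF from that shape, halved.  Restricting the mode set
    makes the statistic a slightly conservative lower bound of the exact dip;
    :func:`dip_test` calibrates the null with the same statistic, so the
    Monte Carlo test remains valid.
    """
    x = np.sort(_clean(samples, "dip_statistic"))
    n = x.size
    if n < 4 or x[0] == x[-1]:
        return 0.0
    f = np.arange(1, n + 1) / n
    qs = np.unique(
        np.clip((np.linspace(0, 1, n_modes) * (n - 1)).astype(int), 0, n - 1)
    )
    best = np.inf
    for m in qs:
        # convex (GCM) on [0, m]: ECDF must not bulge above the minorant
        left = _hull_deviation_lower(x[: m + 1], f[: m + 1]) if m >= 1 else 0.0
        # concave (LCM) on [m, n): mirror the hull computation
        right = (
            _hull_deviation_lower(-x[m:][::-1], 1.0 - f[m:][::-1] + 1.0 / n)
            if m < n - 1
            else 0.0
        )
        d = max(left, right)
        if d < best:
            best = d
    return float(best / 2.0)


_DIP_NULL_CACHE: dict = {}


def dip_test(samples, alpha: float = 0.05, n_null: int = 200, seed: int = 0) -> dict:
    """Monte Carlo dip test of unimodality against the uniform null.

    Returns the statistic, the null critical value at ``alpha`` for the same
    sample size, and whether unimodality is rejected.  Null quantiles are
    cached per (sample size, n_null, seed).
    """
    x = np.asarray(samples, dtype=float).ravel()
    d = dip_statistic(x)
    key = (x.size, n_null, seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        _DIP_NULL_CACHE[key] = np.sort(
            [dip_statistic(rng.random(x.size)) for _ in range(n_null)]
        )
    null = _DIP_NULL_CACHE[key]
    crit = float(np.quantile(null, 1.0 - alpha))
    return {"dip": d, "critical": crit, "reject": bool(d > crit)}
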