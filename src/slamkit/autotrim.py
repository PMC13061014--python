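"""Variance-based detection of artifact-prone read ends.

Chemically damaged read ends show elevated T>C conversion rates that do not
correlate with Phred quality. The detector partitions reads into chunks,
computes the standard deviation of per-position conversion rates across
chunks, smooths it, and fits a continuous piecewise-linear curve (2-4
segments, chosen by BIC) whose breakpoints bound the reliable region. A
segment at either end whose level is elevated over the central segment by
more than ``elevation_factor`` is trimmed.

The piecewise fit is parameterized by node values at the knots (linear
interpolation between knots), so for fixed integer breakpoints the optimal
node values solve a small tridiagonal least-squares system whose entries
come from prefix sums; all candidate breakpoint placements are scored
exactly and in a single vectorized pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np


class AutotrimError(ValueError):
    pass


@dataclass
class VarianceCurve:
    rate_by_chunk: np.ndarray  # (C, L), NaN where a chunk has no T coverage
    sd: np.ndarray  # (L,) sample SD across chunks, NaN where < 2 chunks
    smoothed_sd: np.ndarray  # (L,) centered moving average, truncated edges

    @property
    def length(self) -> int:
        return self.sd.shape[0]


@dataclass
class PiecewiseFit:
    knots: list[int]  # positions incl. both endpoints
    values: list[float]  # fitted node values
    rss: float
    n_segments: int
    bic: dict[int, float] = field(default_factory=dict)

    @property
    def breakpoints(self) -> list[int]:
        return self.knots[1:-1]


@dataclass
class TrimSpec:
    trim5: int = 0
    trim3: int = 0
    breakpoints: list[int] = field(default_factory=list)
    n_segments: int = 0
    bic: dict[int, float] = field(default_factory=dict)
    scope: str = "first"
    warning: str = ""


def compute_variance_curve(profile, window: int = 5) -> VarianceCurve:
    """Per-position conversion-rate SD across read chunks, then smoothed.

    Chunks with zero T coverage at a position are missing values there; a
    position needs at least two covered chunks for a defined SD.
    """
    if profile.n_chunks < 2:
        raise AutotrimError(
            "need at least 2 read chunks for the variance curve; "
            "lower the chunk size or supply more reads"
        )
    cov = profile.t_cov.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(cov > 0, profile.tc / cov, np.nan)
    valid = np.isfinite(rates)
    n_valid = valid.sum(axis=0)
    mean = np.nanmean(np.where(valid, rates, np.nan), axis=0)
    dev = np.where(valid, rates - mean, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var = (dev**2).sum(axis=0) / np.maximum(n_valid - 1, 1)
    sd = np.where(n_valid >= 2, np.sqrt(var), np.nan)
    smoothed = _moving_average(sd, window)
    return VarianceCurve(rate_by_chunk=rates, sd=sd, smoothed_sd=smoothed)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """NaN-aware centered moving average; edge windows are truncated."""
    half = window // 2
    L = len(y)
    out = np.full(L, np.nan)
    finite = np.isfinite(y)
    for p in range(L):
        lo, hi = max(0, p - half), min(L, p + half + 1)
        w = finite[lo:hi]
        if w.any():
            out[p] = y[lo:hi][w].mean()
    return out


def _candidate_knots(n: int, m: int, min_seg: int) -> np.ndarray:
    """Interior knot index tuples (shape (N, m-1)) with min segment length."""
    idx = range(min_seg, n - min_seg + 1)
    combos = [
        c
        for c in combinations(idx, m - 1)
        if all(b - a >= min_seg for a, b in zip(c, c[1:]))
    ]
    return np.asarray(combos, dtype=np.int64).reshape(len(combos), m - 1)


def _batched_rss(x: np.ndarray, y: np.ndarray, knot_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact least-squares RSS for every candidate interior-knot placement.

    Returns (rss (N,), node values (N, m+1)). Points are assigned to the
    segment left of their knot; the optimum over node values v solves the
    tridiagonal normal equations M v = b assembled from prefix sums.
    """
    n = len(x)
    N, m_int = knot_idx.shape
    m = m_int + 1  # segments
    P0 = np.concatenate([[0.0], np.cumsum(np.ones(n))])
    Px = np.concatenate([[0.0], np.cumsum(x)])
    Px2 = np.concatenate([[0.0], np.cumsum(x * x)])
    Py = np.concatenate([[0.0], np.cumsum(y)])
    Pxy = np.concatenate([[0.0], np.cumsum(x * y)])
    Syy = float((y * y).sum())

    bounds = np.concatenate(
        [np.zeros((N, 1), dtype=np.int64), knot_idx, np.full((N, 1), n, dtype=np.int64)],
        axis=1,
    )  # (N, m+1) index boundaries of segments
    knots_x = np.concatenate(
        [np.full((N, 1), x[0]), x[knot_idx], np.full((N, 1), x[-1])], axis=1
    )  # (N, m+1) knot positions

    M = np.zeros((N, m + 1, m + 1))
    bvec = np.zeros((N, m + 1))
    for j in range(m):
        a, b = bounds[:, j], bounds[:, j + 1]
        kj, kj1 = knots_x[:, j], knots_x[:, j + 1]
        d = kj1 - kj
        s0 = P0[b] - P0[a]
        sx = Px[b] - Px[a]
        sx2 = Px2[b] - Px2[a]
        sy = Py[b] - Py[a]
        sxy = Pxy[b] - Pxy[a]
        su = (sx - kj * s0) / d
        su2 = (sx2 - 2 * kj * sx + kj * kj * s0) / (d * d)
        syu = (sxy - kj * sy) / d
        M[:, j, j] += s0 - 2 * su + su2
        M[:, j + 1, j + 1] += su2
        off = su - su2
        M[:, j, j + 1] += off
        M[:, j + 1, j] += off
        bvec[:, j] += sy - syu
        bvec[:, j + 1] += syu
    M += np.eye(m + 1) * 1e-12
    v = np.linalg.solve(M, bvec[..., None])[..., 0]
    rss = Syy - (v * bvec).sum(axis=1)
    return np.maximum(rss, 0.0), v


def fit_piecewise(
    curve: VarianceCurve,
    segment_counts: tuple[int, ...] = (2, 3, 4),
    min_seg: int = 2,
) -> PiecewiseFit:
    """BIC-selected continuous piecewise-linear fit to the smoothed SD curve.

    BIC_m = n ln(RSS/n) + 2m ln(n) with 2m parameters (m+1 node values and
    m-1 free breakpoints); the breakpoint search is exhaustive over integer
    positions with a minimum segment length.
    """
    finite = np.isfinite(curve.smoothed_sd)
    x = np.nonzero(finite)[0].astype(float)
    y = curve.smoothed_sd[finite]
    n = len(x)
    if n < 10:
        raise AutotrimError("variance curve shorter than 10 defined positions")
    best: PiecewiseFit | None = None
    bics: dict[int, float] = {}
    for m in segment_counts:
        cand = _candidate_knots(n, m, min_seg)
        if len(cand) == 0:
            continue
        rss, values = _batched_rss(x, y, cand)
        i = int(np.argmin(rss))
        rss_m = float(rss[i])
        bic = n * np.log(max(rss_m, 1e-20) / n) + 2 * m * np.log(n)
        bics[m] = float(bic)
        if best is None or bic < bics[best.n_segments]:
            knots = [int(x[0])] + [int(x[j]) for j in cand[i]] + [int(x[-1])]
            best = PiecewiseFit(
                knots=knots, values=[float(u) for u in values[i]], rss=rss_m, n_segments=m
            )
    assert best is not None
    best.bic = bics
    return best


def derive_trim(
    fit: PiecewiseFit,
    curve: VarianceCurve,
    elevation_factor: float = 1.5,
    scope: str = "first",
) -> TrimSpec:
    """Turn the piecewise fit into (trim5, trim3).

    The central reference level is the mean smoothed SD over the fitted
    segment containing the curve midpoint. An end is trimmed up to the point
    where the fitted curve falls back below ``elevation_factor`` times the
    central level: smoothing spreads a sharp artifact boundary into a ramp,
    and the fitted ramp's crossing of the elevation threshold sits close to
    the true boundary, where the breakpoints themselves land more loosely.
    The combined trim is capped at half the read length (zero trim plus a
    warning beyond that).
    """
    y = curve.smoothed_sd
    finite = np.isfinite(y)
    pos = np.nonzero(finite)[0]
    first, last = int(pos[0]), int(pos[-1])
    L = curve.length
    mid = (first + last) / 2.0

    def region_mean(lo: int, hi: int) -> float:
        seg = y[lo : hi + 1]
        seg = seg[np.isfinite(seg)]
        return float(seg.mean()) if len(seg) else np.nan

    knots = fit.knots
    central_lo, central_hi = knots[0], knots[-1]
    for a, b in zip(knots, knots[1:]):
        if a <= mid <= b:
            central_lo, central_hi = a, b
            break
    central = region_mean(central_lo, central_hi)
    threshold = elevation_factor * central
    grid = np.arange(first, last + 1)
    fitted = np.interp(grid, fit.knots, fit.values)

    trim5 = 0
    if fitted[0] > threshold:
        p = 0
        while p < len(grid) and grid[p] <= mid and fitted[p] > threshold:
            p += 1
        trim5 = int(grid[p - 1]) + 1
    trim3 = 0
    if fitted[-1] > threshold:
        p = len(grid) - 1
        while p >= 0 and grid[p] > mid and fitted[p] > threshold:
            p -= 1
        trim3 = L - int(grid[p + 1])
    spec = TrimSpec(
        trim5=trim5,
        trim3=trim3,
        breakpoints=list(fit.breakpoints),
        n_segments=fit.n_segments,
        bic=fit.bic,
        scope=scope,
    )
    if spec.trim5 + spec.trim3 > L / 2:
        return TrimSpec(
            0, 0, list(fit.breakpoints), fit.n_segments, fit.bic, scope,
            warning=f"combined trim {spec.trim5}+{spec.trim3} exceeds half the read length; trimming disabled",
        )
    return spec


def auto_trim(profile, window: int = 5, elevation_factor: float = 1.5, scope: str = "first") -> TrimSpec:
    """Full auto-trim: variance curve, BIC piecewise fit, trim derivation.

    Degenerate inputs (short curve) yield zero trim with a warning rather
    than an error.
    """
    curve = compute_variance_curve(profile, window=window)
    try:
        fit = fit_piecewise(curve)
    except AutotrimError as exc:
        return TrimSpec(warning=str(exc), scope=scope)
    return derive_trim(fit, curve, elevation_factor=elevation_factor, scope=scope)
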