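"""Photobleaching step counting and binomial stoichiometry inference.

The subunit-counting logic: a GFP trace is modelled as a piecewise-constant
staircase — one upward binding jump, then downward photobleaching steps of
one fluorophore each.  Step counts across many molecules follow a binomial
``X ~ B(n, p)`` when the population is a homogeneous n-mer and each GFP is
fluorescent with probability ``p`` (the complement of the dark fraction).
Because an all-dark complex produces no binding jump and is never localized,
observed counts are zero-truncated, and by protocol ``n`` is fixed to the
maximum number of observed bleaching steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import binom as _binom

from .trace import IntensityTrace, noise_sd

__all__ = [
    "StepFit",
    "StepHistogram",
    "BinomialFit",
    "fit_steps",
    "detect_binding",
    "build_histogram",
    "binomial_pmf",
    "truncated_binomial_pmf",
    "fit_binomial",
    "compare_n",
]

_MIN_TRACE_LEN = 10


@dataclass
class StepFit:
    """Piecewise-constant model of one trace.

    ``change_points[i]`` is the first frame of the (i+1)-th plateau;
    ``levels`` has one entry more than ``change_points``.  ``bind_frame``
    is the first upward transition (None if the trace never jumps up) and
    ``n_bleach_steps`` counts the downward transitions after it.
    """

    change_points: list[int]
    levels: list[float]
    bind_frame: int | None
    n_bleach_steps: int
    noise_sd: float

    def __post_init__(self) -> None:
        if list(self.change_points) != sorted(set(self.change_points)):
            raise ValueError("change_points must be strictly increasing")
        if len(self.levels) != len(self.change_points) + 1:
            raise ValueError("levels must have len(change_points)+1 entries")


def _best_split(y: np.ndarray, s: int, e: int, min_len: int = 1):
    """Best single change point of y[s:e] by least squares.

    Returns (k, sse_reduction, amplitude) for the split y[s:k] | y[k:e],
    or None if the segment cannot be split with both sides >= min_len.
    """
    seg = y[s:e]
    n = seg.size
    if n < 2 * min_len:
        return None
    c = np.cumsum(seg)
    tot = c[-1]
    left_n = np.arange(min_len, n - min_len + 1, dtype=np.float64)
    left_sum = c[min_len - 1:n - min_len]
    right_n = n - left_n
    right_sum = tot - left_sum
    # SSE reduction of splitting vs single mean: n_l*n_r/n * (mu_l - mu_r)^2
    diff = left_sum / left_n - right_sum / right_n
    red = left_n * right_n / n * diff**2
    i = int(np.argmax(red))
    return s + min_len + i, float(red[i]), float(abs(diff[i]))


#: window half-widths (frames) of the multi-scale local step scan
_SCAN_SCALES = (1, 2, 3, 5, 8, 10)


def _scan_segment(y: np.ndarray, s: int, e: int, sigma: float,
                  scales=_SCAN_SCALES):
    """Most significant local step within y[s:e].

    For each window half-width w, compares the mean of the w frames before
    each candidate split with the mean of the w frames after it,
    standardized by sigma * sqrt(2/w) — the local two-sample z statistic
    (equivalently, the square root of the local SSE reduction over the
    2w-frame window, in noise units).  Local windows, rather than the
    global sub-segment means, keep a short bright plateau detectable inside
    a long background stretch.  Returns (z, k, amplitude) or None.
    """
    n = e - s
    best = None
    c = np.concatenate([[0.0], np.cumsum(y[s:e])])
    for w1 in scales:
        for w2 in scales:
            # asymmetric pairs matter: a one-frame plateau pinned between
            # two steps is only testable with w=1 on the plateau side, and
            # a long window on the other side recovers most of the power
            if n < w1 + w2:
                continue
            ks = np.arange(w1, n - w2 + 1)
            ml = (c[ks] - c[ks - w1]) / w1
            mr = (c[ks + w2] - c[ks]) / w2
            amp = np.abs(mr - ml)
            i = int(np.argmax(amp))
            z = amp[i] / (sigma * math.sqrt(1.0 / w1 + 1.0 / w2))
            if best is None or z > best[0]:
                best = (float(z), s + int(ks[i]), float(amp[i]))
    return best


def _prune(y: np.ndarray, cps: list[int], sigma: float, min_step: float,
           min_significance: float, atol: float) -> list[int]:
    """Bottom-up removal of change points that fail the acceptance gates.

    Greedy placement can leave a stale point when a later, better-localized
    one lands a frame or two away; re-testing every point against the
    final plateau levels (amplitude and length-aware significance) and
    repeatedly dropping the weakest offender removes them.
    """
    cps = sorted(cps)
    while cps:
        bounds = [0, *cps, y.size]
        levels = np.array([y[s:e].mean()
                           for s, e in zip(bounds[:-1], bounds[1:])])
        amps = np.abs(np.diff(levels))
        lens = np.diff(bounds)
        worst = None  # (score, index)
        for i, amp in enumerate(amps):
            ok = amp >= max(min_step * sigma, atol)
            if ok and sigma > 0:
                z = amp / (sigma * math.sqrt(1.0 / lens[i]
                                             + 1.0 / lens[i + 1]))
                ok = z >= min_significance
            if not ok and (worst is None or amp < worst[0]):
                worst = (amp, i)
        if worst is None:
            break
        cps.pop(worst[1])
    return cps


def fit_steps(
    trace: IntensityTrace | np.ndarray,
    min_step: float = 2.5,
    min_significance: float = 5.5,
    max_steps: int = 32,
) -> StepFit:
    """Fit a piecewise-constant staircase by greedy change-point placement.

    Change points are placed one at a time, most prominent first, while
    the proposed step passes both acceptance gates: (a) its amplitude is
    at least ``min_step * sigma`` and (b) its local two-sample z statistic
    (see :func:`_scan_segment`) is at least ``min_significance``.  The
    noise scale sigma is estimated robustly from first differences
    (:func:`smcount.trace.noise_sd`).

    Gate (b) is what keeps a lone noisy frame at a plateau edge from being
    split off as a spurious step: an amplitude test alone is blind to how
    few frames support the amplitude estimate, and a single spurious step
    in a large dataset corrupts the maximum observed step count that the
    binomial trial number is fixed to.  The significance default trades a
    small miss rate on one-frame plateaus for a negligible false-step rate.

    On noiseless traces sigma = 0 and candidate steps are instead placed
    by exact least squares and accepted while their amplitude is nonzero,
    so the fit matches an exhaustive change-point search.

    Bleaching steps are the downward transitions after the binding jump
    (the first upward transition).  Traces shorter than 10 frames raise.
    """
    y = trace.values if isinstance(trace, IntensityTrace) else \
        np.asarray(trace, dtype=np.float64)
    if y.size < _MIN_TRACE_LEN:
        raise ValueError(f"trace must have >= {_MIN_TRACE_LEN} frames")
    sigma = noise_sd(y)
    # absolute floor so that exact plateaus in noiseless data terminate
    atol = max(1e-9 * max(1.0, float(np.ptp(y))), 1e-12)

    cps: list[int] = []
    while len(cps) < max_steps:
        bounds = [0, *cps, y.size]
        best = None
        for s, e in zip(bounds[:-1], bounds[1:]):
            if sigma > 0:
                cand = _scan_segment(y, s, e, sigma)
            else:
                cand = _best_split(y, s, e)
                if cand is not None:
                    # rank exact splits by SSE reduction; amplitude last
                    cand = (cand[1], cand[0], cand[2])
            if cand is not None and (best is None or cand[0] > best[0]):
                best = cand
        if best is None:
            break
        score, k, amp = best
        if amp < max(min_step * sigma, atol):
            break
        if sigma > 0 and score < min_significance:
            break
        if sigma > 0:
            # localize by exact least squares in a tight window around the
            # hit; the scan's max-amplitude position can be off by a frame,
            # and a misplaced point leaves a one-frame residual pseudo-step.
            # The window is kept narrow so it cannot span a second step.
            s = max(b for b in bounds if b < k) if k > 0 else 0
            e = min(b for b in bounds if b > k)
            ref = _best_split(y, max(s, k - 3), min(e, k + 3))
            if ref is not None:
                k = ref[0]
        if k in cps or k <= 0 or k >= y.size:
            break
        cps = sorted(cps + [k])

    cps = _prune(y, cps, sigma, min_step, min_significance, atol)

    bounds = [0, *cps, y.size]
    levels = [float(y[s:e].mean()) for s, e in zip(bounds[:-1], bounds[1:])]
    deltas = np.diff(levels)
    bind_frame = None
    n_bleach = 0
    for cp, d in zip(cps, deltas):
        if bind_frame is None:
            if d > 0:
                bind_frame = cp
        elif d < 0:
            n_bleach += 1
    return StepFit(cps, levels, bind_frame, n_bleach, sigma)


def detect_binding(
    trace: IntensityTrace | np.ndarray,
    min_jump: float = 3.0,
    **fit_kwargs,
) -> int | None:
    """Frame of the (single) binding event, or None.

    The binding event is the first upward level change of amplitude at
    least ``min_jump`` times the trace noise sd; at most one binding is
    reported.
    """
    y = trace.values if isinstance(trace, IntensityTrace) else \
        np.asarray(trace, dtype=np.float64)
    sf = fit_steps(y, **fit_kwargs)
    sigma = sf.noise_sd
    atol = max(1e-9 * max(1.0, float(np.ptp(y))), 1e-12)
    for cp, lo, hi in zip(sf.change_points, sf.levels[:-1], sf.levels[1:]):
        if hi - lo >= max(min_jump * sigma, atol):
            return cp
    return None


@dataclass
class StepHistogram:
    """Normalized distribution of observed bleaching-step counts (k >= 1).

    ``counts`` maps step count to molecule count; fractional weights are
    accepted (e.g., exact model frequencies for fitter self-tests), but
    :func:`build_histogram` — the data path — only produces integers.
    """

    counts: dict[int, float]
    n_max: int = field(init=False)
    freqs: dict[int, float] = field(init=False)
    n_molecules: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.counts:
            raise ValueError("empty step-count histogram")
        if any(k < 1 or k != int(k) for k in self.counts):
            raise ValueError("step counts must be positive integers "
                             "(k=0 molecules are unobservable)")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("molecule counts must be non-negative")
        self.counts = {int(k): v for k, v in sorted(self.counts.items())
                       if v > 0}
        self.n_max = max(self.counts)
        self.n_molecules = sum(self.counts.values())
        self.freqs = {k: v / self.n_molecules
                      for k, v in self.counts.items()}


def build_histogram(step_counts) -> StepHistogram:
    """Histogram a list of per-molecule bleaching-step counts.

    Molecules with zero steps are invisible (no GFP jump) and must be
    excluded upstream; a zero or negative count here raises.  ``n_max`` is
    the maximum observed count — the value the binomial trial number is
    fixed to by the counting protocol.
    """
    step_counts = list(step_counts)
    if not step_counts:
        raise ValueError("no step counts to histogram")
    counts: dict[int, int] = {}
    for k in step_counts:
        if k != int(k) or int(k) < 1:
            raise ValueError(f"invalid step count {k!r}")
        counts[int(k)] = counts.get(int(k), 0) + 1
    return StepHistogram(counts)


# ---------------------------------------------------------------------------
# binomial model
# ---------------------------------------------------------------------------

def binomial_pmf(k: int, n: int, p: float) -> float:
    """P(X = k) for X ~ B(n, p); raises if k is outside 0..n."""
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside 0..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    return float(_binom.pmf(k, n, p))


def truncated_binomial_pmf(k: int, n: int, p: float) -> float:
    """Zero-truncated binomial pmf, P(X = k | X >= 1) for X ~ B(n, p).

    The limit p -> 0 concentrates all mass at k = 1.
    """
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    denom = 1.0 - (1.0 - p) ** n
    if denom <= 0.0:
        return 1.0 if k == 1 else 0.0
    return float(_binom.pmf(k, n, p)) / denom


@dataclass
class BinomialFit:
    """Least-squares binomial fit of a step-count histogram.

    ``chi_sq`` is the minimized sum of squared residuals on normalized
    frequencies; ``chi_sq_reduced`` divides by (bins - 1).
    """

    n: int
    p_hat: float
    chi_sq: float
    residuals: dict[int, float]
    truncated: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_hat <= 1.0:
            raise ValueError("p_hat must be in [0, 1]")
        if self.chi_sq < 0:
            raise ValueError("chi_sq must be >= 0")

    @property
    def chi_sq_reduced(self) -> float:
        dof = max(len(self.residuals) - 1, 1)
        return self.chi_sq / dof

    def model_freqs(self) -> dict[int, float]:
        ks = sorted(self.residuals)
        if self.truncated:
            return {k: truncated_binomial_pmf(k, self.n, self.p_hat)
                    for k in ks}
        return {k: binomial_pmf(k, self.n, self.p_hat) for k in ks}


def _model_vector(ks: np.ndarray, n: int, p: float,
                  truncated: bool) -> np.ndarray:
    pmf = _binom.pmf(ks, n, p)
    if not truncated:
        return pmf
    denom = 1.0 - (1.0 - p) ** n
    if denom <= 0.0:
        return (ks == 1).astype(float)
    return pmf / denom


def fit_binomial(
    hist: StepHistogram,
    n_fixed: int | None = None,
    truncated: bool = True,
    grid_step: float = 1e-3,
    refine_tol: float = 1e-9,
) -> BinomialFit:
    """Fit p of ``B(n_fixed, p)`` to a step histogram by least squares.

    ``n_fixed`` defaults to (and must be at least) the histogram's
    ``n_max``.  With ``truncated=True`` (the default — all-dark complexes
    are never observed) frequencies over k = 1..n are compared with the
    zero-truncated pmf; the full fit compares bins k = 0..n with an
    observed frequency of 0 at k = 0.

    p_hat minimizes the sum of squared residuals, located by a grid search
    (step ``grid_step``) followed by bounded scalar minimization around the
    best grid point; the reported chi_sq is the smaller of the grid and the
    refined minimum, so tightening the refinement never increases it.  The
    optimizer is deterministic.
    """
    if n_fixed is None:
        n_fixed = hist.n_max
    if n_fixed < hist.n_max:
        raise ValueError(f"n_fixed={n_fixed} < n_max={hist.n_max}")

    if truncated:
        ks = np.arange(1, n_fixed + 1)
    else:
        ks = np.arange(0, n_fixed + 1)
    freqs = np.array([hist.freqs.get(int(k), 0.0) for k in ks])

    def sse(p: float) -> float:
        return float(np.sum((freqs - _model_vector(ks, n_fixed, p,
                                                   truncated)) ** 2))

    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    grid_sse = np.array([sse(p) for p in grid])
    i = int(np.argmin(grid_sse))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    res = minimize_scalar(sse, bounds=(lo, hi), method="bounded",
                          options={"xatol": refine_tol})
    if res.fun <= grid_sse[i]:
        p_hat, chi = float(res.x), float(res.fun)
    else:
        p_hat, chi = float(grid[i]), float(grid_sse[i])

    model = _model_vector(ks, n_fixed, p_hat, truncated)
    residuals = {int(k): float(f - m) for k, f, m in zip(ks, freqs, model)}
    return BinomialFit(n_fixed, p_hat, chi, residuals, truncated)


def compare_n(
    hist: StepHistogram,
    n_candidates,
    truncated: bool = True,
) -> pd.DataFrame:
    """One binomial fit per candidate trial number; no model selection.

    A homogeneous n-mer population should fit well at its true n; a poor
    chi_sq across all candidates flags a heterogeneous mixture of oligomeric
    states.  The table reports, it does not choose (a larger n always nests
    more freedom).
    """
    rows = []
    for n in n_candidates:
        fit = fit_binomial(hist, n_fixed=int(n), truncated=truncated)
        rows.append({"n": int(n), "p_hat": fit.p_hat, "chi_sq": fit.chi_sq,
                     "chi_sq_reduced": fit.chi_sq_reduced})
    return pd.DataFrame(rows, columns=["n", "p_hat", "chi_sq",
                                       "chi_sq_reduced"])
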