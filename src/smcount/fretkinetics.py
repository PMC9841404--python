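"""FRET efficiency, activity classification and dwell-time kinetics.

Two activity signatures are recognized on the two DNA substrates:

* repetitive unwinding (forked DNA): E drops gradually as base pairs open
  and snaps back to its starting value when the fork rewinds — a sawtooth.
* fork regression (model replication fork): E jumps and stays high when the
  three-armed fork is regressed into a four-way junction; completion is the
  simultaneous loss of donor and acceptor as the daughter duplex leaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trace import IntensityTrace, noise_sd

__all__ = [
    "FretRecord",
    "ActivitySummary",
    "DwellFit",
    "fret_efficiency",
    "classify_unwinding",
    "classify_regression",
    "activity_summary",
    "dwell_time_fit",
]

#: defaults of the hysteresis classifier; the operational definition of an
#: "active" molecule (configurable and logged by the pipeline).
LO_THRESHOLD = 0.4
HI_THRESHOLD = 0.7
MIN_CYCLES = 2
SUSTAIN_FRAMES = 3


@dataclass
class FretRecord:
    """Per-molecule FRET classification result."""

    E: np.ndarray
    events: list[tuple[str, int]]
    active: bool
    substrate: str = ""
    molecule_id: int | None = None


@dataclass
class ActivitySummary:
    n_active: int
    n_total: int
    percent: float = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.n_active <= self.n_total:
            raise ValueError("need 0 <= n_active <= n_total")
        self.percent = round(100.0 * self.n_active / self.n_total, 1)


def _values(t) -> np.ndarray:
    return t.values if isinstance(t, IntensityTrace) else \
        np.asarray(t, dtype=np.float64)


def fret_efficiency(
    donor, acceptor, dark_floor: float | None = None,
) -> np.ndarray:
    """Proximity-ratio FRET efficiency, ``E = A / (A + D)``, clipped to [0,1].

    No gamma or leakage correction is applied (raw trace behavior).  Frames
    whose total intensity falls below ``dark_floor`` are flagged dark and
    set to NaN; the default floor is 3x the pooled per-channel noise sd —
    at that level E is dominated by noise and carries no distance
    information.  Traces must be background-subtracted and equal length.
    """
    d = _values(donor)
    a = _values(acceptor)
    if d.size != a.size:
        raise ValueError("donor and acceptor traces differ in length")
    if dark_floor is None:
        dark_floor = 3.0 * max(noise_sd(d), noise_sd(a))
    total = d + a
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.clip(a / total, 0.0, 1.0)
    e[~np.isfinite(e)] = np.nan
    e[total < dark_floor] = np.nan
    return e


def _smooth(e: np.ndarray, width: int) -> np.ndarray:
    """Median filter that is transparent to NaN (dark) frames."""
    if width <= 1:
        return e
    out = e.copy()
    valid = np.isfinite(e)
    if valid.any():
        filled = np.where(valid, e, np.interp(
            np.arange(e.size), np.flatnonzero(valid), e[valid]))
        sm = ndimage.median_filter(filled, size=width, mode="nearest")
        out[valid] = sm[valid]
    return out


def classify_unwinding(
    e: np.ndarray,
    lo: float = LO_THRESHOLD,
    hi: float = HI_THRESHOLD,
    min_cycles: int = MIN_CYCLES,
    smooth: int = 3,
) -> tuple[list[tuple[str, int]], bool]:
    """Detect repetitive-unwinding cycles in an efficiency series.

    A cycle is an excursion of (median-filtered) E below ``lo`` followed by
    recovery above ``hi``; the hysteresis gap makes single threshold
    crossings by noise inconsequential, and the short median filter removes
    isolated outlier frames.  A molecule is active when it completes at
    least ``min_cycles`` cycles — unwinding must be repetitive.

    Returns ``(events, active)`` with ``unwind_start`` / ``rewind`` events.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    em = _smooth(np.asarray(e, dtype=np.float64), smooth)
    events: list[tuple[str, int]] = []
    state_low = False
    for t, v in enumerate(em):
        if not np.isfinite(v):
            continue
        if not state_low and v < lo:
            events.append(("unwind_start", t))
            state_low = True
        elif state_low and v > hi:
            events.append(("rewind", t))
            state_low = False
    n_cycles = sum(k == "rewind" for k, _ in events)
    return events, n_cycles >= min_cycles


def _channel_floor(x: np.ndarray) -> float:
    """Dark floor of one background-subtracted channel: 3x its noise sd,
    with a tiny absolute fallback so exactly-zero noiseless tails count as
    dark."""
    return max(3.0 * noise_sd(x), 1e-6 * max(1.0, float(np.ptp(x))))


def classify_regression(
    donor,
    acceptor,
    e: np.ndarray | None = None,
    lo: float = LO_THRESHOLD,
    hi: float = HI_THRESHOLD,
    sustain: int = SUSTAIN_FRAMES,
    simultaneity_window: int = 1,
    smooth: int = 3,
) -> tuple[list[tuple[str, int]], bool]:
    """Detect fork-regression events in a donor/acceptor trace pair.

    ``hj_formation``: starting from the low-FRET fork state (E below
    ``lo``), E rises above ``hi`` and stays there for at least ``sustain``
    frames (the four-way junction is a sustained state, not a spike).
    The detector re-arms when E returns below ``lo``, so repetitive
    regression on a heterologous-end substrate yields one event per cycle.

    ``dissociation``: after a junction has formed, both dyes leave with the
    daughter duplex in a single frame — the experiment's 0.4-s time
    resolution.  Operationally the loss frame is the acceptor's final
    downward step into its dark floor (in the high-FRET junction state the
    acceptor carries nearly all the signal); the donor must be dark
    afterwards and must not show a loss transition of its own a frame or
    more away (``simultaneity_window``), which would indicate sequential
    photobleaching rather than completion.

    A molecule is active iff it shows at least one ``hj_formation``.
    """
    from .stepcount import fit_steps  # local import avoids cycle at import time

    d = _values(donor)
    a = _values(acceptor)
    if d.size != a.size:
        raise ValueError("donor and acceptor traces differ in length")
    floor_d = _channel_floor(d)
    floor_a = _channel_floor(a)
    if e is None:
        e = fret_efficiency(d, a, dark_floor=max(floor_d, floor_a))
    em = _smooth(np.asarray(e, dtype=np.float64), smooth)

    events: list[tuple[str, int]] = []
    armed = True  # start in the fork (low-FRET) state
    n = em.size
    for t in range(n):
        v = em[t]
        if not np.isfinite(v):
            continue
        if armed and v > hi:
            window = em[t:t + sustain]
            window = window[np.isfinite(window)]
            if window.size >= min(sustain, n - t) and np.all(window > hi):
                events.append(("hj_formation", t))
                armed = False
        elif not armed and v < lo:
            armed = True

    hj_frames = [f for k, f in events if k == "hj_formation"]
    if hj_frames and n >= 10:
        first_hj = hj_frames[0]
        sf_a = fit_steps(a)
        loss = None
        for cp, before, after in zip(sf_a.change_points, sf_a.levels[:-1],
                                     sf_a.levels[1:]):
            if cp > first_hj and after < before and after < floor_a \
                    and before > floor_a:
                loss = cp  # keep the last qualifying transition
        if loss is not None:
            post_d = d[loss:loss + max(sustain, 1)]
            donor_dark = float(np.mean(post_d)) < floor_d
            sf_d = fit_steps(d)
            conflicting = any(
                1 <= abs(cp - loss) <= simultaneity_window
                and hi_l > lo_l
                for cp, hi_l, lo_l in zip(sf_d.change_points,
                                          sf_d.levels[:-1], sf_d.levels[1:])
            )
            if donor_dark and not conflicting:
                events.append(("dissociation", loss))

    events.sort(key=lambda kf: kf[1])
    active = bool(hj_frames)
    return events, active


def activity_summary(records) -> ActivitySummary:
    """Fraction of molecules showing activity, e.g. 224/725 -> 30.9%.

    Accepts FretRecord-like objects (anything with an ``active`` attribute)
    or plain booleans; order of records is irrelevant.
    """
    records = list(records)
    if not records:
        raise ValueError("no records to summarize")
    flags = [bool(getattr(r, "active", r)) for r in records]
    return ActivitySummary(n_active=sum(flags), n_total=len(flags))


@dataclass
class DwellFit:
    """Exponential fit of a dwell-time sample."""

    dwell_times: np.ndarray
    rate: float
    ci: tuple[float, float]
    n_censored: int = 0

    def __post_init__(self) -> None:
        if self.dwell_times.size >= 2 and not self.rate > 0:
            raise ValueError("rate must be > 0")


def dwell_time_fit(
    durations,
    censored=None,
    n_boot: int = 1000,
    seed: int = 0,
) -> DwellFit:
    """Exponential MLE of a dwell-time distribution with bootstrap CI.

    ``rate = n_events / total_observed_time``; for a fully observed sample
    this is 1/mean.  Dwells flagged in ``censored`` (end-truncated by the
    end of the movie) contribute observation time but no event.  The 95%
    CI is a seeded percentile bootstrap over dwells.
    """
    t = np.asarray(list(durations), dtype=np.float64)
    if t.size < 2:
        raise ValueError("need at least 2 dwell times")
    if np.any(t <= 0):
        raise ValueError("dwell times must be positive")
    if censored is None:
        cen = np.zeros(t.size, dtype=bool)
    else:
        cen = np.asarray(list(censored), dtype=bool)
        if cen.size != t.size:
            raise ValueError("censored mask length mismatch")
    n_events = int((~cen).sum())
    if n_events == 0:
        raise ValueError("all dwells censored; rate not identifiable")
    rate = n_events / float(t.sum())

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, t.size, size=(n_boot, t.size))
    ev = (~cen)[idx].sum(axis=1)
    tot = t[idx].sum(axis=1)
    ok = ev > 0
    boots = ev[ok] / tot[ok]
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return DwellFit(t, float(rate), ci, n_censored=int(cen.sum()))
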