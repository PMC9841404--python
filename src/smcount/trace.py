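"""Core time-trace container shared by all modules."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class IntensityTrace:
    """One molecule's per-frame intensity in one channel.

    Parameters
    ----------
    values : ndarray
        Per-frame intensity in arbitrary units (float64).
    frame_interval : float
        Seconds per frame; 0.4 s is the time resolution of the experiments
        this package targets.
    channel : str
        Free-form channel label, e.g. ``"gfp"``, ``"donor"``, ``"acceptor"``.
    """

    values: np.ndarray
    frame_interval: float = 0.4
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("trace values must be one-dimensional")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n_frames(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds (frame 0 at t = 0)."""
        return np.arange(self.values.size) * self.frame_interval


def noise_sd(values: np.ndarray) -> float:
    """Robust per-frame noise estimate for a piecewise-constant trace.

    Uses the median absolute first difference scaled for Gaussian noise,
    ``median(|x[t+1] - x[t]|) / (sqrt(2) * 0.6745)``.  Steps are sparse in
    the first-difference sequence, so the median ignores them.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        return 0.0
    return float(np.median(np.abs(np.diff(values))) / (np.sqrt(2.0) * 0.6745))
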