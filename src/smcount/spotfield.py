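"""Spot detection, two-channel colocalization and ROI trace extraction.

Coordinates are 0-based pixel indices in (row, col) order; spot positions
are continuous (sub-pixel).  Molecules are localized on a temporal average
of the first frames, matched across channels, and their intensity read out
from an 11x11 region of interest that must contain exactly one molecule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

from .trace import IntensityTrace

__all__ = [
    "Spot",
    "MoleculeRecord",
    "detect_spots",
    "colocalize",
    "extract_trace",
    "extract_molecule_records",
]

ROI_HALF = 5  # 11x11 single-molecule window
N_AVG_FRAMES = 10


@dataclass
class Spot:
    """A localized fluorescent spot (sub-pixel, 0-based row/col)."""

    row: float
    col: float
    channel: str = ""
    peak_intensity: float = 0.0

    @property
    def position(self) -> np.ndarray:
        return np.array([self.row, self.col])


@dataclass
class MoleculeRecord:
    """Per-molecule traces extracted from a colocalized ROI."""

    molecule_id: int
    roi_center: tuple[int, int]
    donor_trace: IntensityTrace | None = None
    acceptor_trace: IntensityTrace | None = None
    gfp_trace: IntensityTrace | None = None
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        lengths = {len(t) for t in (self.donor_trace, self.acceptor_trace,
                                    self.gfp_trace) if t is not None}
        if len(lengths) > 1:
            raise ValueError("channel traces differ in frame count")


def _background_stats(image: np.ndarray) -> tuple[float, float]:
    """Median background and robust (MAD-based) sd of an image."""
    med = float(np.median(image))
    mad = float(np.median(np.abs(image - med)))
    return med, mad * 1.4826


def detect_spots(
    image: np.ndarray,
    threshold: float = 5.0,
    channel: str = "",
    merge_radius: float = 2.0,
) -> list[Spot]:
    """Find diffraction-limited spots in a single frame or temporal average.

    Local maxima brighter than ``background + threshold * background_sd``
    (robust median/MAD estimates) are refined to sub-pixel positions by the
    intensity centroid of the background-subtracted 5x5 window around the
    peak; refined positions closer than ``merge_radius`` pixels are merged,
    keeping the brighter peak.  A flat or empty image yields an empty list.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("detect_spots expects a single 2-D frame")
    bg, sd = _background_stats(image)
    if sd == 0.0 and np.ptp(image) == 0.0:
        return []
    abs_thresh = bg + threshold * sd if sd > 0 else bg + 0.5 * np.ptp(image)
    peaks = peak_local_max(image, min_distance=2, threshold_abs=abs_thresh,
                           exclude_border=1)

    spots: list[Spot] = []
    h, w = image.shape
    for r, c in peaks:
        r0, r1 = max(r - 2, 0), min(r + 3, h)
        c0, c1 = max(c - 2, 0), min(c + 3, w)
        win = image[r0:r1, c0:c1] - bg
        win = np.clip(win, 0.0, None)
        tot = win.sum()
        if tot <= 0:
            continue
        rows, cols = np.mgrid[r0:r1, c0:c1]
        spots.append(Spot(float((rows * win).sum() / tot),
                          float((cols * win).sum() / tot),
                          channel=channel,
                          peak_intensity=float(image[r, c])))

    spots.sort(key=lambda s: -s.peak_intensity)
    kept: list[Spot] = []
    for s in spots:
        if all(np.hypot(s.row - k.row, s.col - k.col) >= merge_radius
               for k in kept):
            kept.append(s)
    return kept


def colocalize(
    spots_a: list[Spot],
    spots_b: list[Spot],
    channel_map=None,
    tol: float = 2.0,
) -> list[tuple[int, int, float]]:
    """Greedy nearest-neighbor matching of spots across two channels.

    ``channel_map`` maps channel-A coordinates into channel B — either a
    callable ``(N,2) -> (N,2)`` or a 2x3 affine matrix; the default is the
    identity (registered synthetic channels).  Pairs are matched in order
    of increasing distance, each spot at most once, rejecting distances
    above ``tol`` pixels.  Returns ``(index_a, index_b, distance)`` tuples.
    """
    if not spots_a or not spots_b:
        return []
    pa = np.array([[s.row, s.col] for s in spots_a])
    pb = np.array([[s.row, s.col] for s in spots_b])
    if channel_map is not None:
        if callable(channel_map):
            pa = np.asarray(channel_map(pa), dtype=np.float64)
        else:
            m = np.asarray(channel_map, dtype=np.float64)
            pa = pa @ m[:, :2].T + m[:, 2]
    dist = np.hypot(pa[:, None, 0] - pb[None, :, 0],
                    pa[:, None, 1] - pb[None, :, 1])
    order = np.dstack(np.unravel_index(np.argsort(dist, axis=None),
                                       dist.shape))[0]
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for i, j in order:
        d = dist[i, j]
        if d > tol:
            break
        if i in used_a or j in used_b:
            continue
        matches.append((int(i), int(j), float(d)))
        used_a.add(int(i))
        used_b.add(int(j))
    return matches


def extract_trace(
    stack: np.ndarray,
    center: tuple[float, float],
    roi_half: int = ROI_HALF,
    frame_interval: float = 0.4,
    channel: str = "",
) -> IntensityTrace:
    """Background-subtracted intensity trace of one ROI.

    Per frame, the intensity is the sum over the (2*roi_half+1)-square ROI
    minus the median of the ROI's one-pixel border ring times the ROI pixel
    count — a local, per-frame background estimate.  The ROI must fit
    entirely inside the image.
    """
    stack = np.asarray(stack, dtype=np.float64)
    if stack.ndim != 3:
        raise ValueError("expected a (frames, H, W) stack")
    r = int(round(center[0]))
    c = int(round(center[1]))
    h, w = stack.shape[1:]
    if (r - roi_half < 0 or r + roi_half >= h
            or c - roi_half < 0 or c + roi_half >= w):
        raise ValueError(f"ROI at ({r},{c}) exceeds the {h}x{w} image")
    roi = stack[:, r - roi_half:r + roi_half + 1,
                c - roi_half:c + roi_half + 1]
    ring = np.ones(roi.shape[1:], dtype=bool)
    ring[1:-1, 1:-1] = False
    n_pix = roi.shape[1] * roi.shape[2]
    bg = np.median(roi[:, ring], axis=1)
    values = roi.sum(axis=(1, 2)) - bg * n_pix
    return IntensityTrace(values, frame_interval, channel=channel)


def extract_molecule_records(
    donor_stack: np.ndarray,
    acceptor_stack: np.ndarray,
    gfp_stack: np.ndarray | None = None,
    threshold: float = 5.0,
    tol: float = 2.0,
    channel_map=None,
    roi_half: int = ROI_HALF,
    n_avg: int = N_AVG_FRAMES,
    frame_interval: float = 0.4,
) -> list[MoleculeRecord]:
    """Localize, colocalize and extract traces for a two-channel movie.

    Detection runs on the temporal average of the first ``n_avg`` frames of
    each channel.  Matched molecules get donor/acceptor (and optionally
    GFP) traces from the donor-channel ROI center.  QC flags set:

    - ``multi_molecule``: a second detected spot falls inside the 11x11 ROI
      (the single-molecule criterion fails);
    - ``edge``: the ROI does not fit in the image (no traces extracted).
    """
    davg = np.asarray(donor_stack, dtype=np.float64)[:n_avg].mean(axis=0)
    aavg = np.asarray(acceptor_stack, dtype=np.float64)[:n_avg].mean(axis=0)
    spots_d = detect_spots(davg, threshold, channel="donor")
    spots_a = detect_spots(aavg, threshold, channel="acceptor")
    matches = colocalize(spots_d, spots_a, channel_map=channel_map, tol=tol)

    all_positions = np.array([[s.row, s.col] for s in spots_d]) \
        if spots_d else np.empty((0, 2))
    records: list[MoleculeRecord] = []
    for mol_id, (i, _j, _d) in enumerate(matches):
        center = (int(round(spots_d[i].row)), int(round(spots_d[i].col)))
        flags: set[str] = set()
        inside = np.max(np.abs(all_positions - np.array(center)), axis=1) \
            <= roi_half
        if inside.sum() > 1:
            flags.add("multi_molecule")
        try:
            dt = extract_trace(donor_stack, center, roi_half,
                               frame_interval, "donor")
            at = extract_trace(acceptor_stack, center, roi_half,
                               frame_interval, "acceptor")
            gt = (extract_trace(gfp_stack, center, roi_half,
                                frame_interval, "gfp")
                  if gfp_stack is not None else None)
        except ValueError:
            records.append(MoleculeRecord(mol_id, center,
                                          qc_flags=flags | {"edge"}))
            continue
        records.append(MoleculeRecord(mol_id, center, dt, at, gt, flags))
    return records
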