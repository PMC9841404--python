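"""Synthetic single-molecule data with ground truth.

Every simulator in this module emits, next to the trace or movie itself, a
truth object recording what was simulated (subunit counts, bleach frames,
kinetic events, true coordinates), so downstream detection and classification
can be scored against a known answer.  All randomness flows through a
``numpy.random.Generator`` seeded explicitly; the same seed reproduces the
same output bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .trace import IntensityTrace

__all__ = [
    "SimConfig",
    "ComplexTruth",
    "FretTruth",
    "UnwindKinetics",
    "simulate_photobleaching_trace",
    "simulate_unwinding_fret",
    "simulate_regression_fret",
    "simulate_field_movie",
    "simulate_experiment",
]


@dataclass
class SimConfig:
    """Shared simulation parameters.

    frame_interval : seconds per frame (0.4 s, the experimental resolution)
    n_frames       : trace length in frames
    unit_step      : intensity of one fluorophore, a.u.
    noise_sigma    : additive Gaussian noise per frame, a.u.
                     (default 0.15 x unit_step)
    background     : constant offset, a.u.
    """

    frame_interval: float = 0.4
    n_frames: int = 600
    unit_step: float = 1.0
    noise_sigma: float = 0.15
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.unit_step <= 0:
            raise ValueError("unit_step must be > 0")


@dataclass
class ComplexTruth:
    """Ground truth for one simulated protein complex.

    ``fluorescent_count`` may be smaller than ``m_subunits`` because each
    GFP tag is fluorescent only with probability ``p_fluor`` (the dark
    fraction); all-dark complexes are invisible to the binding-jump
    localization and are flagged via :attr:`visible`.
    """

    m_subunits: int
    fluorescent_count: int
    bind_frame: int
    bleach_frames: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fluorescent_count != len(self.bleach_frames):
            raise ValueError("fluorescent_count must equal len(bleach_frames)")
        if any(b <= self.bind_frame for b in self.bleach_frames):
            raise ValueError("all bleach_frames must be after bind_frame")
        self.bleach_frames = sorted(self.bleach_frames)

    @property
    def visible(self) -> bool:
        return self.fluorescent_count > 0


@dataclass
class FretTruth:
    """Ground-truth event list for one simulated FRET trace pair.

    Events are ``(kind, frame)`` with kind in ``{"unwind_start", "rewind",
    "hj_formation", "dissociation"}``, time-ordered; a dissociation, if
    present, is last.
    """

    events: list[tuple[str, int]] = field(default_factory=list)
    active: bool = False

    def __post_init__(self) -> None:
        frames = [f for _, f in self.events]
        if frames != sorted(frames):
            raise ValueError("events must be time-ordered")
        kinds = [k for k, _ in self.events]
        if "dissociation" in kinds and kinds[-1] != "dissociation":
            raise ValueError("dissociation must be the last event")

    def frames_of(self, kind: str) -> list[int]:
        return [f for k, f in self.events if k == kind]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# photobleaching staircases
# ---------------------------------------------------------------------------

def simulate_photobleaching_trace(
    m: int,
    p_fluor: float,
    bleach_rate: float = 0.02,
    cfg: SimConfig | None = None,
    seed=None,
) -> tuple[IntensityTrace, ComplexTruth]:
    """Simulate the GFP trace of one m-mer complex binding and photobleaching.

    Each of the ``m`` subunits carries a GFP that is fluorescent with
    probability ``p_fluor``.  The complex binds at a uniform-random frame in
    the first third of the trace (one upward jump of ``fluorescent_count``
    units); each fluorophore then survives a geometric number of frames with
    per-frame bleaching hazard ``bleach_rate`` (default mean lifetime 50
    frames) and drops the trace by one unit when it bleaches.  Gaussian
    noise of ``cfg.noise_sigma`` is added to every frame.

    All-dark complexes (``fluorescent_count == 0``) produce a flat
    background trace with no binding jump and are flagged invisible in the
    truth.

    Returns the noisy trace and the :class:`ComplexTruth`.
    """
    if not 0.0 <= p_fluor <= 1.0:
        raise ValueError("p_fluor must be in [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    if bleach_rate <= 0:
        raise ValueError("bleach_rate must be > 0")
    cfg = cfg or SimConfig()
    rng = _rng(seed)

    n = cfg.n_frames
    fluorescent = int(np.sum(rng.random(m) < p_fluor))
    bind_frame = int(rng.integers(1, max(2, n // 3)))

    signal = np.full(n, cfg.background, dtype=np.float64)
    bleach_frames: list[int] = []
    if fluorescent > 0:
        lifetimes = rng.geometric(bleach_rate, size=fluorescent)
        bleach_frames = sorted(int(bind_frame + l) for l in lifetimes)
        t = np.arange(n)
        surviving = np.zeros(n, dtype=np.float64)
        for b in bleach_frames:
            surviving += (t >= bind_frame) & (t < b)
        signal += cfg.unit_step * surviving
    if cfg.noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sigma, size=n)

    trace = IntensityTrace(signal, cfg.frame_interval, channel="gfp")
    truth = ComplexTruth(m, fluorescent, bind_frame, bleach_frames)
    return trace, truth


# ---------------------------------------------------------------------------
# smFRET traces
# ---------------------------------------------------------------------------

@dataclass
class UnwindKinetics:
    """Kinetic parameters of the repetitive-unwinding simulator.

    unwind_rate : 1/s, hazard of completing the gradual unwinding phase
                  (mean phase duration = 1/unwind_rate seconds)
    idle_rate   : 1/s, hazard of leaving the fully rewound high-FRET state
    mean_extra_cycles : Poisson mean of cycles beyond the minimum of two
                  (an active molecule unwinds repetitively)
    e_high, e_low : FRET efficiency of the rewound and maximally unwound
                  states; rewinding is abrupt (single-frame return to e_high)
    """

    unwind_rate: float = 0.15
    idle_rate: float = 0.25
    mean_extra_cycles: float = 3.0
    e_high: float = 0.85
    e_low: float = 0.25
    #: shortest simulated phases, frames.  Observed unwinding cycles last
    #: seconds; a dip shorter than a few 0.4-s frames would be unresolvable
    #: at the experiment's sampling rate, so phase durations are drawn from
    #: shifted exponentials rather than allowed to collapse to one frame.
    min_unwind_frames: int = 10
    min_idle_frames: int = 3

    def __post_init__(self) -> None:
        if self.unwind_rate <= 0 or self.idle_rate <= 0:
            raise ValueError("rates must be > 0")
        if not 0 <= self.e_low < self.e_high <= 1:
            raise ValueError("need 0 <= e_low < e_high <= 1")
        if self.min_unwind_frames < 1 or self.min_idle_frames < 1:
            raise ValueError("minimum phase durations must be >= 1 frame")


def _fret_pair(
    e: np.ndarray, cfg: SimConfig, rng: np.random.Generator,
    total: np.ndarray | None = None,
) -> tuple[IntensityTrace, IntensityTrace]:
    """Render donor/acceptor traces from an efficiency series at constant
    total intensity ``cfg.unit_step`` (anti-correlated channels)."""
    if total is None:
        total = np.full(e.size, cfg.unit_step)
    donor = cfg.background + total * (1.0 - e)
    acceptor = cfg.background + total * e
    if cfg.noise_sigma > 0:
        donor = donor + rng.normal(0.0, cfg.noise_sigma, e.size)
        acceptor = acceptor + rng.normal(0.0, cfg.noise_sigma, e.size)
    return (
        IntensityTrace(donor, cfg.frame_interval, channel="donor"),
        IntensityTrace(acceptor, cfg.frame_interval, channel="acceptor"),
    )


def simulate_unwinding_fret(
    cfg: SimConfig | None = None,
    kinetics: UnwindKinetics | None = None,
    active: bool = True,
    seed=None,
) -> tuple[IntensityTrace, IntensityTrace, FretTruth]:
    """Simulate a forked-DNA smFRET trace pair (repetitive unwinding).

    Active molecules cycle: a high-FRET dwell, a gradual linear decrease of
    E to ``e_low`` over an exponential-duration unwinding phase, then an
    abrupt single-frame recovery to ``e_high`` (rewinding by sliding back).
    Only cycles that complete within the trace are emitted, so every
    ``unwind_start`` has a later ``rewind``.  Inactive molecules are static
    at ``e_high``.  Donor and acceptor are anti-correlated with constant
    total intensity.
    """
    cfg = cfg or SimConfig()
    kin = kinetics or UnwindKinetics()
    rng = _rng(seed)
    n = cfg.n_frames
    e = np.full(n, kin.e_high, dtype=np.float64)
    events: list[tuple[str, int]] = []

    if active:
        n_cycles = 2 + int(rng.poisson(kin.mean_extra_cycles))
        frame = 0
        for _ in range(n_cycles):
            idle = kin.min_idle_frames + int(round(
                rng.exponential(1.0 / kin.idle_rate) / cfg.frame_interval))
            dur = kin.min_unwind_frames + int(round(
                rng.exponential(1.0 / kin.unwind_rate) / cfg.frame_interval))
            start = frame + idle
            end = start + dur  # rewind frame
            if end >= n - 1:
                break
            ramp = np.linspace(kin.e_high, kin.e_low, dur + 1)[1:]
            e[start:end] = ramp
            events.append(("unwind_start", start))
            events.append(("rewind", end))
            frame = end

    donor, acceptor = _fret_pair(e, cfg, rng)
    truth = FretTruth(events, active=active and
                      sum(k == "rewind" for k, _ in events) >= 2)
    return donor, acceptor, truth


def simulate_regression_fret(
    cfg: SimConfig | None = None,
    repetitive: bool = False,
    active: bool = True,
    seed=None,
    e_low: float = 0.15,
    e_high: float = 0.85,
) -> tuple[IntensityTrace, IntensityTrace, FretTruth]:
    """Simulate a model-replication-fork smFRET trace pair (fork regression).

    The fork state is low-FRET.  Regression into a four-way (Holliday)
    junction raises E in one frame and the high state is sustained.  On a
    homologous-armed substrate (``repetitive=False``) regression runs to
    completion: the daughter duplex dissociates and both channels drop to
    background in the same frame.  On a heterologous-end substrate
    (``repetitive=True``) the junction cannot resolve, so E cycles between
    low and high at least twice with no dissociation.  ``active=False``
    gives a static low-FRET trace (no events).
    """
    cfg = cfg or SimConfig()
    rng = _rng(seed)
    n = cfg.n_frames
    e = np.full(n, e_low, dtype=np.float64)
    total = np.full(n, cfg.unit_step)
    events: list[tuple[str, int]] = []

    if active:
        if repetitive:
            n_cycles = 2 + int(rng.poisson(2.0))
            seg = max(4, n // (2 * n_cycles + 1))
            frame = int(rng.integers(2, seg))
            made = 0
            while made < n_cycles and frame < n - 2 * seg:
                events.append(("hj_formation", frame))
                high_end = frame + max(3, int(rng.integers(seg // 2, seg + 1)))
                e[frame:high_end] = e_high
                frame = high_end + max(2, int(rng.integers(seg // 2, seg + 1)))
                made += 1
            if made < 2:  # guarantee the repetitive contract on short traces
                raise ValueError("n_frames too short for a repetitive trace")
        else:
            hj = int(rng.integers(max(2, n // 6), max(3, n // 3)))
            diss = int(hj + max(5, rng.integers(n // 6, n // 3)))
            diss = min(diss, n - 3)
            e[hj:] = e_high
            total[diss:] = 0.0  # both dyes leave with the daughter duplex
            e[diss:] = 0.0
            events.append(("hj_formation", hj))
            events.append(("dissociation", diss))

    donor, acceptor = _fret_pair(e, cfg, rng, total=total)
    truth = FretTruth(events, active=bool(events))
    return donor, acceptor, truth


# ---------------------------------------------------------------------------
# two-channel spot-field movies
# ---------------------------------------------------------------------------

def simulate_field_movie(
    n_spots: int,
    psf_sigma: float = 1.2,
    cfg: SimConfig | None = None,
    seed=None,
    shape: tuple[int, int] = (64, 64),
    flux: float = 2000.0,
    background: float = 20.0,
    min_separation: float | None = None,
    channel_shift: tuple[float, float] = (0.0, 0.0),
    positions: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Render a two-channel diffraction-limited spot field.

    Spots are 2-D Gaussians of width ``psf_sigma`` (pixels) and total flux
    ``flux`` (photons/frame) on a Poisson background of mean ``background``
    plus Gaussian read noise ``cfg.noise_sigma``.  Positions are drawn
    uniformly with pairwise separation >= ``min_separation`` (default
    4 * psf_sigma); pass ``positions`` (N x 2, row/col) to place spots
    explicitly, e.g. to create deliberate collisions.  The same molecule
    appears in both channels, shifted by ``channel_shift`` in channel B.

    Returns ``({"a": stack, "b": stack}, positions)`` with stacks of shape
    ``(n_frames, H, W)``.
    """
    cfg = cfg or SimConfig(n_frames=10)
    rng = _rng(seed)
    h, w = shape
    margin = 3.0 * psf_sigma
    if min_separation is None:
        min_separation = 4.0 * psf_sigma

    if positions is None:
        if n_spots > 0 and (h - 2 * margin <= 0 or w - 2 * margin <= 0):
            raise ValueError("field too small for the requested PSF")
        pts: list[np.ndarray] = []
        attempts = 0
        while len(pts) < n_spots:
            cand = np.array([rng.uniform(margin, h - margin),
                             rng.uniform(margin, w - margin)])
            if all(np.hypot(*(cand - p)) >= min_separation for p in pts):
                pts.append(cand)
            attempts += 1
            if attempts > 1000 * max(1, n_spots):
                raise ValueError(
                    f"cannot place {n_spots} spots with separation "
                    f"{min_separation:.1f}px in a {h}x{w} field")
        positions = (np.array(pts).reshape(-1, 2) if pts
                     else np.empty((0, 2)))
    else:
        positions = np.asarray(positions, dtype=np.float64).reshape(-1, 2)

    yy, xx = np.mgrid[0:h, 0:w]

    def render(pos: np.ndarray) -> np.ndarray:
        img = np.zeros((h, w))
        amp = flux / (2.0 * np.pi * psf_sigma**2)
        for r, c in pos:
            img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2)
                                / (2.0 * psf_sigma**2))
        return img

    shifted = positions + np.asarray(channel_shift)
    clean = {"a": render(positions), "b": render(shifted)}
    stacks = {}
    for ch, img in clean.items():
        lam = np.broadcast_to(img + background, (cfg.n_frames, h, w))
        stack = rng.poisson(lam).astype(np.float64)
        if cfg.noise_sigma > 0:
            stack = stack + rng.normal(0.0, cfg.noise_sigma, stack.shape)
        stacks[ch] = stack
    return stacks, positions


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------

SUBSTRATES = (
    "forked",            # repetitive unwinding (Cy3/Cy5 forked duplex)
    "replication_fork",  # single regression then daughter-duplex dissociation
    "replication_fork_het",  # heterologous ends: repetitive regression
    "static",            # no activity (e.g. 3'-RNA-overhang hybrid fork)
)


def simulate_experiment(spec: dict) -> dict:
    """Generate a full synthetic dataset (traces + truths + manifest).

    ``spec`` keys:

    - ``substrate``: one of :data:`SUBSTRATES`
    - ``n_molecules``: complexes to simulate
    - ``oligomer_mix``: {m: fraction} of protomer counts (fractions sum to 1)
    - ``p_fluor``: per-subunit fluorescence probability
    - ``active_fraction``: probability a molecule shows activity
    - ``seed``: integer (mandatory — datasets must be reproducible)
    - optional ``config``: dict of :class:`SimConfig` overrides
    - optional ``bleach_rate``: per-frame hazard (default 0.02)

    Returns ``{"molecules": [...], "manifest": {...}}`` where each molecule
    dict has ``id``, ``gfp``, ``donor``, ``acceptor`` traces and the truth
    objects.  Use :func:`smcount.io.write_bundle` to serialize.
    """
    spec = dict(spec)
    substrate = spec.get("substrate")
    if substrate not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; "
                         f"expected one of {SUBSTRATES}")
    if "seed" not in spec:
        raise ValueError("dataset spec must name a seed")
    n_mol = int(spec.get("n_molecules", 100))
    mix = {int(k): float(v) for k, v in
           dict(spec.get("oligomer_mix", {2: 1.0})).items()}
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ValueError("oligomer_mix fractions must sum to 1")
    p_fluor = float(spec.get("p_fluor", 1.0))
    active_fraction = float(spec.get("active_fraction", 1.0))
    bleach_rate = float(spec.get("bleach_rate", 0.02))
    cfg = SimConfig(**spec.get("config", {}))

    root = np.random.SeedSequence(int(spec["seed"]))
    ms = sorted(mix)
    probs = np.array([mix[m] for m in ms])

    molecules = []
    for i, child in enumerate(root.spawn(n_mol)):
        rng = np.random.default_rng(child)
        m = int(rng.choice(ms, p=probs))
        active = bool(rng.random() < active_fraction)
        gfp, ctruth = simulate_photobleaching_trace(
            m, p_fluor, bleach_rate, cfg, seed=rng)
        if substrate == "forked":
            d, a, ftruth = simulate_unwinding_fret(cfg, active=active,
                                                   seed=rng)
        elif substrate == "replication_fork":
            d, a, ftruth = simulate_regression_fret(cfg, repetitive=False,
                                                    active=active, seed=rng)
        elif substrate == "replication_fork_het":
            d, a, ftruth = simulate_regression_fret(cfg, repetitive=True,
                                                    active=active, seed=rng)
        else:  # static
            d, a, ftruth = simulate_unwinding_fret(cfg, active=False,
                                                   seed=rng)
        molecules.append({
            "id": i, "gfp": gfp, "donor": d, "acceptor": a,
            "complex_truth": ctruth, "fret_truth": ftruth,
        })

    manifest = {
        "substrate": substrate, "n_molecules": n_mol,
        "oligomer_mix": {str(k): v for k, v in mix.items()},
        "p_fluor": p_fluor, "active_fraction": active_fraction,
        "bleach_rate": bleach_rate, "seed": int(spec["seed"]),
        "config": dataclasses.asdict(cfg),
    }
    return {"molecules": molecules, "manifest": manifest}
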