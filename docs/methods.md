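# Methods

## Scope and model

`smcount` implements the analysis chain of a combined single-molecule
subunit-counting / smFRET activity experiment on surface-tethered DNA:
molecule localization and trace extraction from two-channel TIRF movies,
photobleaching step counting on GFP traces, binomial inference of the
oligomeric state, and classification of Cy3/Cy5 FRET traces as repetitive
unwinding or replication-fork regression.  All components are exercised on
synthetic data with ground truth; the simulators are first-class, tested
code, not fixtures.

The statistical core is the dark-fraction model of subunit counting: each
of the *n* subunits of a bound complex carries a GFP that is fluorescent
with probability *p*, independently, so the number of observable
photobleaching steps is *X* ∼ *B*(*n*, *p*).  A complex with *X* = 0 emits
no binding jump and is never localized; the histogram of observed counts is
therefore fitted with the zero-truncated pmf
P(*X* = *k*)/(1 − (1 − *p*)ⁿ) over *k* ≥ 1 (an untruncated fit, with an
observed frequency of zero at *k* = 0, remains available as a
configuration switch).  Following the counting protocol, *n* is fixed to
the maximum step count observed in the dataset, which makes the false-step
rate of the step detector a first-order design concern (below).  The fit
minimizes the sum of squared residuals on normalized frequencies over
*p* ∈ [0, 1] by a deterministic grid search (step 10⁻³) plus bounded scalar
refinement; the reported `chi_sq` is this minimized SSR, with `SSR/(bins−1)`
reported alongside as a reduced value.  SSR on normalized frequencies is
used because it is the convention under which fit-quality values of order
10⁻²–10⁻¹ arise for histograms like these; it is not a calibrated
goodness-of-fit statistic, and `compare_n` therefore judges homogeneity by
comparison across candidate *n* (or by parametric bootstrap in the tests),
never by an absolute threshold.

## Step detection

The step-fitting algorithm is greedy change-point placement on the
piecewise-constant trace model, with the per-frame noise scale estimated
robustly as median(|Δy|)/(√2 · 0.6745).  Each iteration proposes the most
prominent new step; a proposal must pass two gates:

1. **Amplitude**: |Δ| ≥ `min_step` · σ̂ (default 2.5 σ̂).
2. **Significance**: |Δ| / (σ̂ √(1/w₁ + 1/w₂)) ≥ `min_significance`
   (default 5.5), where w₁, w₂ are the numbers of frames supporting the
   level estimates on either side.

Candidates are located by a multi-scale local scan: for window pairs
(w₁, w₂) with w ∈ {1, 2, 3, 5, 8, 10}, the difference of the w₁-frame mean
before and the w₂-frame mean after each position is standardized and the
most significant position proposed.  Local windows rather than global
segment means are essential for short bright pulses (a complex that binds
and bleaches quickly) whose amplitude is diluted to invisibility in
whole-segment averages; asymmetric pairs are what make a one-frame plateau
pinned between two steps testable at all (w = 1 on the plateau side, a
long window on the other).  Accepted positions are re-localized by exact
least squares within ±3 frames — the scan's argmax can be off by a frame,
and a misplaced point leaves a one-frame residual pseudo-step.  After
placement, a bottom-up pruning pass re-tests every change point against
both gates on the final plateau levels and repeatedly drops the weakest
offender.

The significance default (5.5) is a family-wise false-positive control:
each trace is scanned at ~600 positions × ~36 window pairs, and datasets
contain thousands of traces, while the protocol of fixing *n* to the
maximum observed step count means a *single* spurious step anywhere in the
dataset corrupts the fit.  At 5.5 the measured false-step rate is below
1/11,000 traces at the default noise level, at the cost of missing roughly
one in five one-frame plateaus.  The net effect on recovered *p* is a
small negative bias (≈ −0.02), dominated by genuinely unresolvable events:
two fluorophores bleaching in the same frame are one step in the data
itself.

On noiseless traces σ̂ = 0; candidates are then placed by exact
least-squares search and accepted while their amplitude is nonzero, which
makes the fit identical to an exhaustive change-point search (verified
against a brute-force oracle for traces ≤ 30 frames, ≤ 3 steps).

Binding is the first upward level change of amplitude ≥ 3 σ̂ (at most one
binding event is reported per trace); bleaching steps are the downward
transitions after it.

## FRET classification

Efficiency is the uncorrected proximity ratio E = A/(A + D), clipped to
[0, 1]; no gamma or leakage correction is applied, matching the raw-trace
readout the analysis targets.  Frames whose total intensity falls below a
dark floor (3× the pooled channel noise) carry no distance information and
are masked.

*Repetitive unwinding*: E is median-filtered (width 3, transparent to
masked frames) and passed through a hysteresis detector — a cycle is an
excursion below `lo` = 0.4 followed by recovery above `hi` = 0.7.  A
molecule is active when it completes ≥ 2 cycles ("repetitive").  The
filter-plus-hysteresis combination is what drives the false-positive rate
to zero at the standard noise level: an isolated noise frame cannot cross
the 0.3-wide hysteresis gap after median filtering.  The thresholds and
cycle minimum are declared operational definitions, configurable and
logged; they are not inferred from data.

*Fork regression*: junction formation is a rise of E from below `lo` to
above `hi` sustained for ≥ 3 frames (the four-way junction is a state, not
a spike), re-armed when E returns below `lo`, so a heterologous-end
substrate yields one event per regression cycle.  Dissociation — the
completion signature — must be simultaneous within one frame, the
experiment's 0.4-s resolution.  Operationally the loss frame is the
acceptor's final step into its dark floor (in the high-FRET junction state
the acceptor carries nearly all signal, so the donor's own drop can be
statistically invisible); the donor must be dark afterwards and must show
no loss transition of its own one or more frames away, which rejects
sequential photobleaching.  A corollary, documented rather than hidden:
donor photobleaching in the high-FRET state also silences the acceptor in
the same frame and is indistinguishable from dissociation in these two
channels alone — as in the experiment itself.

Dwell times are fitted as exponential by maximum likelihood
(rate = events / total observed time, censoring-aware) with a seeded
percentile-bootstrap 95% CI.

## Localization and extraction

Spots are local maxima above background + 5 robust SDs (median/MAD) on the
temporal average of the first 10 frames, refined to sub-pixel positions by
the background-subtracted 5×5 intensity centroid, with duplicates within
2 px merged.  Channels are matched by greedy nearest-neighbor assignment
under a 2-px tolerance after an optional affine channel map (identity for
synthetic data).  Traces are per-frame sums over the 11×11 ROI minus the
border-ring median × pixel count; an ROI containing a second detected spot
is flagged `multi_molecule` (single-molecule criterion), and ROIs off the
image edge are rejected.  Coordinates are 0-based (row, col) pixel indices.

## Synthetic data: what it emulates, and what it does not

The simulators reproduce the statistical structure the analysis assumes,
at the experiment's stated frame interval of 0.4 s:

- **Photobleaching traces**: one binding jump at a uniform-random frame in
  the first third of the trace ("binding occurs once"), per-subunit
  Bernoulli(p) fluorescence, geometric per-frame bleaching (mean lifetime
  50 frames = 20 s), additive Gaussian noise with σ = 0.15 × unit step,
  default 600 frames.  The noise level and bleach lifetime are
  conventional choices — the source experiments show but do not quantify
  them — and are configurable.
- **Unwinding FRET**: anti-correlated donor/acceptor at constant total;
  E ramps linearly from 0.85 to 0.25 over an unwinding phase of
  10 + Exp(mean ≈ 17) frames and recovers in a single frame (abrupt
  rewinding); idle high-FRET dwells of 3 + Exp(mean ≈ 10) frames; cycle
  count 2 + Poisson(3) for active molecules, truncated to cycles that
  complete within the trace.  The shifted-exponential durations encode
  that observed cycles last seconds — a dip shorter than a few 0.4-s
  frames would be unresolvable at the sampling rate, and such events exist
  in the data only as invisible. Inactive molecules are static at E = 0.85.
- **Regression FRET**: low-E fork state (0.15), single-frame jump to a
  sustained 0.85 junction state; completion zeroes both channels in the
  same frame; heterologous-end substrates cycle ≥ 2 times without
  dissociation.
- **Spot fields**: 2-D Gaussian PSFs on Poisson + Gaussian background,
  pairwise separation ≥ 4 σ_psf unless explicit positions request
  collisions; the same molecule appears in both channels through the
  channel map.

Not emulated: EM-CCD gain statistics, stage drift, chromatic aberration
beyond a linear map, dye blinking, and any exonuclease or strand-annealing
chemistry.  Passing recovery tests on this generator therefore shows that
the analysis is correct under its own model assumptions (binomial dark
fraction, single binding event, Gaussian noise, resolvable kinetics) — not
that it is robust to optical artifacts absent from the model.

## Numerical and reproducibility choices

- All simulators draw from `numpy.random.Generator`; the same seed gives
  bit-identical output, and the pipeline embeds the seed and a SHA-256
  config hash in every report.  Dataset generators derive one independent
  child stream per molecule, so results do not depend on iteration order.
- The binomial fitter is fully deterministic (grid + bounded refinement);
  the reported minimum never increases when the refinement tolerance
  tightens.
- Degenerate inputs are defined, not special-cased silently: a flat image
  yields zero spots; a constant trace has no change points; the truncated
  pmf's p → 0 limit concentrates at k = 1; a single-bin histogram with
  n = 1 fits p = 1 exactly under the full model while the truncated model
  fits any p (documented degenerate case).
- Study sizes in the shipped tests and acceptance script (5,000 complexes
  per recovery condition, 698 specificity traces, 10,000-draw
  distributional checks) keep each study around a minute on one CPU while
  holding Monte-Carlo scatter on recovered p near 0.01.

## Known limitations

- Step counting undercounts when two fluorophores bleach within the same
  frame (irreducible) or when a one-frame plateau fails the significance
  gate (~20% of such plateaus); the resulting bias on p̂ is ≈ −0.02 at
  default conditions, well inside the recovery tolerance but systematic.
- The greedy fitter is not an exact segmenter on noisy data; it trades a
  small miss rate for the near-zero false-step rate that the
  n-fixed-to-maximum protocol demands.
- The unwinding classifier misses ~2% of cycles whose below-threshold dip
  is marginal under noise; errors are one-sided (missed cycles, never
  spurious ones).
- Heterogeneous oligomer populations are flagged by poor fits across
  candidate n; no mixture deconvolution is attempted.
- E is treated as a state indicator only; no base-pair calibration of
  unwinding extent is implied.
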