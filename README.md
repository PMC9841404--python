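# smcount

Single-molecule subunit counting and smFRET activity classification for
DNA-bound helicase oligomers.

## The problem

How many protein subunits make up the complex that actually performs a
reaction on DNA?  In single-molecule TIRF experiments this is answered by
tagging each subunit with GFP and counting discrete photobleaching steps:
a surface-tethered DNA molecule is localized via its Cy3/Cy5 labels, the
GFP intensity trace of the bound complex is extracted from an 11×11-pixel
region of interest, and every downward step after the single upward binding
jump marks one fluorophore bleaching.  Because a fraction of GFP tags is
non-fluorescent (immature or misfolded chromophores), the observed step
count *k* of a homogeneous *n*-mer population is binomially distributed,

&nbsp;&nbsp;&nbsp;&nbsp;*X* ∼ *B*(*n*, *p*),&nbsp;&nbsp;
P(*X* = *k*) = C(*n*, *k*) *p*ᵏ (1 − *p*)ⁿ⁻ᵏ,

where *p* is the per-subunit fluorescence probability and 1 − *p* the dark
fraction.  Complexes with *k* = 0 produce no binding jump and are never
observed, so the package fits the zero-truncated binomial
P(*X* = *k* | *X* ≥ 1) to the normalized step-count histogram by least
squares, with *n* fixed to the maximum observed step count.  A poor fit at
every candidate *n* flags a heterogeneous mixture of oligomeric states.

In the same experiment the complex's catalytic activity is read out by
Cy3→Cy5 FRET on the DNA substrate: repetitive unwinding of a forked duplex
appears as a sawtooth in the efficiency *E* = *A*/(*A* + *D*) (gradual
decrease, abrupt single-frame recovery), and regression of a model
replication fork into a four-way (Holliday) junction appears as a sustained
*E* jump, terminated — on a substrate that allows completion — by the
simultaneous single-frame loss of both dye signals when the daughter duplex
dissociates.  `smcount` classifies traces into these event types so step
counting can be conditioned on the molecules that are actually active.

The package is exercised end-to-end on synthetic data: every simulator
emits ground truth (subunit counts, bleach frames, kinetic events), so
detection, classification and parameter recovery are tested against known
answers.

## Modules

- `smcount.synthgen` — simulators for photobleaching staircases, smFRET
  unwinding/regression trace pairs, two-channel spot-field movies and full
  datasets, each with a ground-truth record.
- `smcount.spotfield` — spot detection, two-channel colocalization,
  single-molecule ROI QC and trace extraction from TIFF stacks.
- `smcount.stepcount` — binding-jump and photobleaching-step detection
  (greedy change-point fitting with a multi-scale significance gate),
  step-count histograms, (truncated) binomial fits, model comparison.
- `smcount.fretkinetics` — FRET efficiency, repetitive-unwinding and
  fork-regression classifiers, activity summaries, exponential dwell-time
  fits.
- `smcount.io` / `smcount.pipeline` / `smcount.cli` — CSV/HDF5 trace
  bundles, validated JSON configuration, the end-to-end driver and the
  `smcount` command-line tool.

## Worked example

Simulate 1,000 dimeric complexes whose GFP tags are fluorescent with
probability 0.63, count photobleaching steps on every trace, and fit the
zero-truncated binomial with *n* fixed to the maximum observed step count:

```python
from smcount.pipeline import counting_study

res = counting_study(m=2, p_fluor=0.63, n_complexes=1000, seed=1)
print("histogram:", res["histogram"])
print(f"n_max={res['n_max']}  p_hat={res['p_hat']:.3f}  "
      f"chi_sq={res['chi_sq']:.4f}  n_counted={res['n_counted']}")
```

prints

```
histogram: {1: 478, 2: 385}
n_max=2  p_hat=0.617  chi_sq=0.0000  n_counted=863
```

863 of 1,000 complexes showed a binding jump and at least one bleaching
step (the rest are all-dark, as expected from (1 − 0.63)² ≈ 14%), the
maximum observed step count is 2, and the fitted per-subunit fluorescence
probability 0.617 recovers the generating value 0.63 to within sampling
error.  `chi_sq` is the minimized sum of squared residuals on the
normalized frequencies.

The same study from the shell:

```sh
smcount simulate --spec recipe.json --seed 1 --out dataset/
smcount count    --traces dataset/traces.h5 --out steps.csv
smcount fitbinom --steps steps.csv --truncated --out fit.json
smcount classify --traces dataset/traces.h5 --mode unwinding --out events.tsv
smcount run      --config pipeline.json --out results/
```

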