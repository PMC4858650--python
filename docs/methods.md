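# Methods

## Kinetic model

The generator tracks fractions of the injected dose through a whole-body
compartment model. Blood activity clears biexponentially,

    B(t) = f_fast · e^(−k_fast t) + (1 − f_fast) · e^(−k_slow t),

with B(0) = 1. The liver is a single linear tissue compartment driven by
the blood input and scaled by relative receptor density R (control
mean = 1):

    dL/dt = k_up · R · B(t) − k_off · L,   L(0) = 0.

Everything cleared from blood and not resident in the liver is routed to
the excreta, split between intestine and bladder by `excretion_split`;
the heart ROI sees a fixed share (`heart_blood_share`, default 0.10) of
the circulating blood pool and the body label carries the remainder. By
construction the pre-decay compartment fractions sum to one at every
time point, and L is exactly linear in k_up·R — the property that makes
the liver signal a receptor readout.

All compartment curves are finite sums of exponentials, so the solution
is closed-form and frame integrals (including the Tc-99m physical decay
factor, half-life fixed at 6.0067 h) are evaluated analytically rather
than by quadrature. The closed form is cross-checked against a
high-accuracy ODE solve (1e-6 relative) in the tests. Rate collisions
(k_off equal to a blood rate, within 1e-9) raise instead of switching to
the confluent limit form; perturbing a rate by one part in 10⁶ is the
documented workaround and changes nothing at the precision of interest.

### Default rates

Control defaults (per minute): f_fast = 0.6, k_fast = 0.35,
k_slow = 0.04, k_off = 0.012. These were chosen so the model reproduces
three qualitative anchors of receptor-avid tracers in healthy mice: rapid
early blood clearance, a liver time–activity curve peaking between 35 and
50 min post-injection (the shipped defaults peak at ≈ 38.8 min, which is
why the static scan sits at 40 min), and clinically familiar index
magnitudes (HH15 ≈ 0.37, LHL15 ≈ 0.90 in controls; LHL15 ≈ 0.83 in
severe fibrosis).

Each group's uptake constant `k_up` is a calibration constant stored in
`src/hepaspect/config/reference.yaml`, not in code. Because L is linear
in k_up·R, each constant is a one-line linear solve (see
`scripts/recalibrate.py`) such that, at zero covariate noise and the
nominal 1.0 mL liver, the decay-corrected static-scan LUV of each group
lands exactly on its target: 25.5 (control), 19.0 (Ishak 2–3), 14.3
(Ishak 4–5), 21.0 (Tan IIA arm). The three staging targets are the
published group means this pipeline is designed to emulate; the severe
group's receptor density mean is 0.5 of control (the reported ≈ 50%
ASGP-R down-regulation), and the residual difference between the LUV
ratio (14.3/25.5 ≈ 0.56) and the receptor ratio (0.50) is absorbed by the
group k_up, reflecting that receptor loss need not map one-to-one onto
uptake.

A deliberate non-feature: the published dynamic curves show *higher*
early (0–15 min) liver uptake in fibrotic animals even though the 40-min
LUV is lower, with no mechanism offered. The defaults follow the static
LUV behaviour only — all groups share the blood and washout rates, so
early-time group differences carry the same sign as the static ones. The
per-group kinetics in the config accept stage-specific `k_fast`/`k_up`
overrides for anyone wanting to explore kinetic explanations of that
anomaly.

## Cohort generator

Five groups, n = 6 each by default (the study's design): vehicle control
(Ishak 0), CCl₄ at 4 weeks (Ishak 2–3), 8 and 12 weeks (Ishak 4–5), and
a CCl₄ + Tan IIA treatment arm (Ishak 2–3, reflecting the reported
≈ 2-point improvement). Ishak scores are drawn uniformly from each
group's admissible set. Covariates are sampled lognormally
(moment-matched to the configured mean/SD, so SD = 0 reproduces the mean
exactly and support stays positive):

| covariate | control | 4 wk | 8 wk | 12 wk | Tan IIA | units |
| --- | --- | --- | --- | --- | --- | --- |
| ASGP-R (rel.) | 1.0 | 0.75 | 0.50 | 0.50 | 0.80 | control = 1 |
| hydroxyproline | 150 | 300 | 450 | 520 | 280 | µg/g liver |
| Sirius Red | 0.3 | 1.8 | 3.0 | 3.7 | 1.5 | % area |
| MMP-9 (rel.) | 1.0 | 2.5 | 4.0 | 4.5 | 2.0 | control = 1 |

Severe-group anchors (ASGP-R 0.5, Sirius Red 3.7%) are the published
values; the remaining means are plausible interpolations chosen once for
realism (mouse hydroxyproline in the 100–600 µg/g range, MMP-9 rising
several-fold with stage). Liver volume is 1.0 ± 0.07 mL and injected
dose 18 ± 1.5 MBq for every group (the study injected 18 MBq). The
kinetic receptor density of each animal equals its sampled ASGP-R value,
which is what couples imaging to histology and produces the correlation
structure downstream.

## Acquisition simulation

Protocols: a dynamic scan of 30 s frames spanning 0–15 min (30 frames)
and a 30 s static frame centred at 40 min. Expected organ counts per
frame are calibration × injected dose × the analytic integral of the
decaying organ fraction; Poisson noise is applied per organ (ROI mode,
default) or per voxel after spreading the organ expectation uniformly
over its label (voxel mode). Calibration defaults to 50 counts/(MBq·s),
giving a few thousand liver counts per frame — counting noise is then a
1–2% effect, deliberately small against the biological covariate spread.
No projection, reconstruction, attenuation, scatter or partial-volume
modelling: the simulation operates at the activity-map level, which is
the level at which ROI quantification consumes real reconstructed data.

The phantom is a labelled ellipsoid geometry (body, liver scaled to a
requested volume, spherical heart blood pool, tubular intestine,
spherical bladder) voxelised at 0.5 mm by default. It plays the role of
the CT-side segmentation; in voxel mode the LUV denominator is the
label-map liver volume (voxel count × voxel volume), in ROI mode the
cohort-table volume. Voxel mode exists for end-to-end NIfTI validation
on small grids; ROI mode is the default for speed.

## Quantification conventions

- ROI activity = counts / (calibration × frame duration): a
  frame-averaged MBq value. Decay correction multiplies by
  2^(+t_mid/T½).
- LUV is computed from the decay-corrected static frame by default
  (the render/quantify pair is then an exact round trip, verified to
  1e-9 relative without noise). LUV is invariant to rescaling counts and
  injected dose together.
- HH15 and LHL15 use raw (non-decay-corrected) activities, the clinical
  scintigraphy convention; over 15 min the decay effect on HH15 is
  ≈ 2.3%. Both are configurable.
- Nominal 3- and 15-min lookups take the frame whose midpoint is nearest,
  ties to the earlier frame; on the 30 s schedule they land at 2.75 and
  14.75 min.

## Statistics

- One-way fixed-effects ANOVA with a Newman–Keuls stepwise post hoc:
  pairs compared on q = |mᵢ − mⱼ|/√(MSE/n_h) (n_h the pair harmonic
  mean) at span-dependent studentized-range critical values, widest span
  first, with non-rejection blocking. The procedure runs unconditionally
  (not gated on the omnibus F), so under the complete null its
  family-wise error equals the level of the widest-span range test —
  the property the 10,000-replicate Monte Carlo test checks (rate within
  [0.04, 0.06] at α = 0.05). Studentized-range probabilities come from
  scipy's numerical quadrature of the standard double-integral form;
  critical values are cached per (α, span, df).
- Pearson correlation with the two-tailed t test on n − 2 df. No
  multiple-testing correction is applied across the correlation table
  (matching the analysis this mirrors); the report says so explicitly.
- Empirical ROC with midrank tie handling; the trapezoidal area of the
  stored curve equals the Mann–Whitney AUC exactly (tested against
  brute-force pair counting). Each index declares its disease direction —
  LUV and LHL15 fall, and under the shipped defaults HH15 also falls,
  with severity — and the orientation is recorded in the result.
- Paired AUC differences use DeLong's placement-value covariance
  estimate with a two-tailed normal reference; its type-I error at
  n = 20 + 20 is Monte-Carlo-verified in [0.04, 0.06].

Severe fibrosis is defined as Ishak ≥ 4. The treatment arm is excluded
from the staging analyses and reported as a separate treated-vs-untreated
contrast.

## Determinism and sizes

One integer seeds everything: the cohort draw and a per-animal
`SeedSequence`-spawned stream for each acquisition. Identical
(config, seed) runs produce byte-identical reports, and a report
regenerated from the saved CSV intermediates is byte-identical too (CSV
floats are written and re-read in round-trip mode). Default problem
sizes — 5 × 6 animals, 31 frames, ROI mode — run the full pipeline in
about a second; the parameter-recovery check uses 50 animals per group,
and the type-I simulations use 10,000 replicates each.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis
assumes: stage-ordered receptor loss and collagen accumulation,
receptor-proportional liver uptake, Poisson counting noise, and lognormal
biological spread. It does not emulate reconstruction artefacts,
anatomical variation beyond liver volume, intra-organ heterogeneity,
tracer-specific plasma protein binding, or the unexplained early-uptake
inversion noted above. Green tests therefore validate the quantification
and inference machinery, and the recoverability of effects of the
configured size — not the biological fidelity of any particular rate
constant. HH15 in particular carries no group signal under the shipped
defaults (blood kinetics are stage-independent), so its ROC AUC hovers
near 0.5 rather than the published 0.81; recovering that value would
require the stage-specific blood kinetics the config permits but does
not assume.

## Known limitations

- Newman–Keuls controls family-wise error only under the complete null;
  this is a property of the procedure itself, kept for fidelity.
- The confluent (equal-rate) liver solution is not implemented; rates
  must differ.
- The phantom legend is fixed at six labels; user-supplied label maps
  must follow it.
- `quantify` on external CSVs supports ROI-mode tables only; voxel-mode
  inputs go through the Python API with per-animal phantoms.
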