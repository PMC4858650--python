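# hepaspect

SPECT/CT liver-uptake quantification for staging hepatic fibrosis, built
around a synthetic digital-mouse cohort.

## The problem

Asialoglycoprotein receptors (ASGP-R) sit on hepatocyte membranes and are
progressively lost as the liver fibroses, which makes receptor-targeted
SPECT tracers quantitative markers of functional liver. In a
CCl₄-induced mouse model, three indices are read off the scans:

- **LUV** (liver uptake value, %ID/mL) from a single static scan at
  40 min post-injection:

  `LUV = (liver ROI activity / injected activity) × 100 / liver volume`

- **HH15** (blood-clearance index) from a 0–15 min dynamic scan:
  heart ROI activity at 15 min / heart ROI activity at 3 min.

- **LHL15** (receptor index): liver / (liver + heart) ROI activity at
  15 min.

LUV falls with disease stage (Ishak score), tracks hepatic collagen
(hydroxyproline, Sirius Red area) and receptor loss, and discriminates
severe fibrosis (Ishak ≥ 4) in ROC analysis. Because no per-animal raw
data exist for studies of this kind, `hepaspect` ships a seeded synthetic
cohort generator — stage-dependent covariates, biexponential blood
clearance driving a one-tissue receptor compartment, Poisson counting
noise on framed acquisitions — so the whole quantification and statistics
chain is exercisable and testable end to end. It is aimed at people
prototyping preclinical SPECT quantification pipelines or teaching
ROI-based tracer kinetics.

## What is in the box

| module | contents |
| --- | --- |
| `hepaspect.kinetics` | biexponential blood input, closed-form liver compartment, Tc-99m decay |
| `hepaspect.phantom` | labelled digital-mouse phantom (body / liver / heart / intestine / bladder) |
| `hepaspect.cohort` | seeded cohort sampling: Ishak stage, histology covariates, kinetics |
| `hepaspect.acquisition` | framed ROI- or voxel-mode count rendering with Poisson noise |
| `hepaspect.quantify` | ROI activities, time–activity curves, LUV / HH15 / LHL15 |
| `hepaspect.stats` | ANOVA + Newman–Keuls, Pearson, ROC (midrank), DeLong AUC comparison |
| `hepaspect.pipeline` | YAML-config-driven simulate → quantify → analyze orchestration |
| `hepaspect.io`, `hepaspect.plots` | NIfTI / CSV / YAML I/O, ROC figures |

## Worked example

```sh
hepaspect run --out demo_run --seed 1
```

prints (reference configuration: n = 6 per group, Poisson noise on):

```
LUV[control] = 27.76 +/- 1.48 (n=6)
LUV[mild] = 17.16 +/- 1.33 (n=6)
LUV[severe] = 13.86 +/- 0.54 (n=12)
report: demo_run/report.json
```

These are mean ± SEM liver uptake values by fibrosis stage class
(control = Ishak 0, mild = Ishak 2–3, severe = Ishak 4–5, the two
long-duration CCl₄ arms pooled). The written `report.json` also contains,
for this seed:

- one-way ANOVA of LUV across stage classes: F = 52.2, p ≈ 7e-9, with
  Newman–Keuls post hoc q and p per pair;
- Pearson correlations of LUV with hydroxyproline (r = −0.76), Sirius
  Red area (r = −0.87), ASGP-R expression (r = +0.97) and MMP-9
  (r = −0.77), each with a two-tailed p;
- ROC AUCs for predicting severe fibrosis: LUV 0.90, LHL15 0.90,
  HH15 0.61 (indices oriented so lower values indicate disease), and
  paired DeLong comparisons (LUV vs HH15 p = 0.019; LUV vs LHL15
  p = 0.87);
- the Tan IIA treatment contrast: treated mean LUV 19.7 vs untreated
  13.5 (+46%).

The same run can be driven stage by stage (`simulate`, `quantify`,
`analyze`, `report`) on the saved CSV tables; `--help` on any verb lists
the options. Library use mirrors the CLI:

```python
from hepaspect.pipeline import reference_config, run_study
report = run_study(reference_config(), seed=1)
```

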