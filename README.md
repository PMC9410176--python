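# repolab

ECG repolarization morphology analysis for case–control studies: an
SVD-based vectorcardiographic pipeline computing **TCRT** (total cosine
R-to-T) and **TMD** (T-wave morphology dispersion), tangent-method interval
measurement (QT, Bazett QTc, Tp-e and ratios) from lead V5, and the
accompanying nonparametric case–control statistics — together with a
synthetic 12-lead dipole-model cohort generator so every stage can be
verified against analytic ground truth without patient data.

It is aimed at cardiac-electrophysiology researchers who want a fully
reproducible, open reimplementation of these markers (no commercial software
computes them) and a way to validate any such implementation.

## The markers

A 12-lead ECG carries only eight independent leads (I, II, V1–V6; the limb
leads III, aVR, aVL, aVF are fixed linear combinations).  For each analysed
beat the 8×N lead matrix *X* is factorised by singular value decomposition,

&nbsp;&nbsp;&nbsp;&nbsp;*X = U S Vᵀ*,&nbsp;&nbsp; *s₃(t) = (s₁, s₂, s₃)(t)* = top-3 components scaled by their singular values,

which in practice captures ≥99% of the signal energy.  The per-sample energy
*E₃d(t) = s₁² + s₂² + s₃²* locates the QRS and T-wave landmarks (QRS
onset/peak/offset at the maximal up/down slope, T start/peak/end by a
thresholded bump search).  Then:

- **TCRT** = mean over high-energy QRS samples *t* of
  cos ∠(*s₃(t)*, *s₃(t_Tpeak)*) ∈ [−1, 1].  It measures the spatial angle
  between ventricular depolarization and repolarization; negative values
  mean the two loops point in very different directions.
- **TMD** = mean angle (degrees) over all 28 unordered lead pairs between
  per-lead 2-D "reconstruction vectors" (each lead's loadings on the first
  two components of an SVD of the T-wave window).  It quantifies how
  differently the T wave is shaped across leads.  **TMDpre**/**TMDpost**
  restrict the window to before/after the T peak.
- Markers are computed in two modes: a **randomly selected beat** and the
  **averaged beat** (sample-wise mean of all usable beats aligned on R).
- From lead V5, the T-wave end is the intersection of the isoelectric line
  with the tangent at the steepest T downslope; QT, QTc = QT/√RR (Bazett),
  Tp-e, Tp-e/QT and Tp-e/QTc follow.

The synthetic generator drives a rank-3 Gaussian-wave dipole whose QRS-loop
and T-wave directions subtend a programmable angle θ, projected onto the
leads through a fixed orthonormalised Dower-style matrix — so the pipeline's
TCRT can be checked against cos θ exactly, and a two-group cohort can be
simulated in which only the θ distribution differs between groups.

## Worked example

Simulate and analyse a two-group cohort (74 controls, 50 cases with a wider
QRS-T angle; all other generator settings identical):

```python
from repolab import RunConfig, run_cohort

art = run_cohort(RunConfig(seed=1, out_dir="demo"))
print(art["summary"].set_index("variable")
      .loc[["tcrt_averaged", "tmd_averaged"], ["control", "case", "p_rendered"]])
```

prints (values your machine reproduces exactly from seed 1):

```
                    control          case p_rendered
variable
tcrt_averaged   0.41 ± 0.03   0.06 ± 0.05      <0.01
tmd_averaged   82.48 ± 1.96  71.82 ± 4.21         NS
```

The cases' averaged-beat TCRT (mean ± SEM) is far lower than the controls'
— the programmed 85° vs 64° mean QRS-T angle, recovered as cos θ — while
TMD does not separate the groups, because each subject's dipole frame is
randomised so T-shape dispersion carries no group information.  The
confounder model (OLS of averaged TCRT on group, demographics and
treatments) finds only the group term significant:

```
          coef      se  p_value
group  -0.3288  0.0670   0.0000
age    -0.0004  0.0028   0.8963
statin  0.0019  0.0625   0.9754
```

The same run writes `results.csv` (per-subject markers and intervals),
`summary.csv`/`summary.json` (the group-comparison table), `model.json`,
`exclusions.csv`, `manifest.json` and `run.log` under `demo/`.

A command-line interface wraps the same pipeline:

```bash
repolab simulate --n-control 74 --n-case 50 --seed 1 --out-dir data/
repolab analyze --input data/ --seed 1 --out results/
repolab compare --results results/results.csv --cohort data/cohort.csv
```

## Cohort CSV schema

One row per subject: `subject_id`, `group` (`control` | `DM/IFG`), `age`
(years), `sex` (`M`/`F`), `height` (m), `weight` (kg), `bmi` (kg/m²), `sbp`,
`dbp` (mmHg), and 0/1 columns `dyslipidemia`, `hypertension`, `fhx_ihd`,
`aspirin`, `acei_arb`, `ccb`, `beta_blocker`, `statin`, `thiazide`,
`current_smoker`, `past_smoker`.  Unknown columns are preserved.  ECG
recordings are lead-per-column CSV (with a JSON sidecar declaring `fs` and
units) or WFDB format-16 records.

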