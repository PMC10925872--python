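# cvrasl

Agreement between steady-state perfusion imaging (multi-delay arterial spin
labeling, ASL) and dynamic vascular imaging (hypercapnic BOLD) — implemented
as a fully tested pipeline that runs end-to-end on synthetic 4D phantoms
with known ground truth.

## The problem

Two MRI techniques probe complementary sides of cerebral hemodynamics:

* **Multi-PLD pCASL** magnetically labels arterial blood and samples its
  inflow at several post-labeling delays, yielding quantitative **CBF**
  (cerebral blood flow, ml/100 ml/min) and **AAT** (arterial arrival
  time, s).
* **BOLD during a hypercapnic breathing challenge** measures
  **CVR** (cerebrovascular reactivity, %BOLD/mmHg PetCO2 — the vasodilatory
  reserve) and the **hemodynamic lag** (s) of each voxel's response to the
  CO2 stimulus. Voxels whose signal *falls* under vasodilation have
  exhausted their reserve: **vascular steal**, operationalized as CVR < 0.

In tissue with intact autoregulation these modalities agree (high CBF goes
with high CVR and short lags); in steal territory the CBF–CVR coupling
inverts. `cvrasl` implements the whole comparison chain — phantom
generation, BOLD conditioning, CVR/lag mapping, kinetic-model inversion of
the ASL signal, and the three comparative statistical analyses (tissue-ROI
group tests, 5%-bin repeated-measures correlation, voxelwise correlation)
— with every stage verified against known ground truth or an independent
oracle.

## The models

**CVR** is the ordinary-least-squares slope of the percent-normalized BOLD
signal on the aligned end-tidal CO2 trace. **Lag** is the shift that
maximizes the normalized correlation between the voxel series and the
regressor on a 0.2625 s grid (the acquisition TR of 1.05 s interpolated
×4). **CBF and AAT** come from per-voxel least squares on the
single-compartment pCASL kinetic curve with a Look-Locker-shortened
apparent T1,

    dM(t) = 2 M0b (f/6000) α T1app · exp(−Δa/T1b) · s(t),      1/T1app = 1/T1b − ln(cos θ)/ΔTI

with `s(t)` the inflow/plateau shape (zero before arrival Δa, saturating
rise during the τ = 1.65 s label bolus, T1app decay after). The fit uses
variable projection: flow is linear in the model, leaving a 1D arrival-time
search. **Repeated-measures correlation** (r_rm) estimates the common
within-subject slope between binned map values with subject-specific
intercepts, `r_rm = sign(b)·sqrt(SSx/(SSx+SSerr))`, df = N − k − 1.

## Worked example

```python
import numpy as np
from cvrasl.config import RunConfig
from cvrasl.pipeline import run_pipeline

report = run_pipeline(RunConfig(outdir="demo_out", seed=1, n_subjects=14))
for row in report["binned_rmcorr"]:
    print(f"{row['pair']:>8s} {row['steal_status']:>9s}  "
          f"r_rm = {row['r_rm']:+.3f}  (p = {row['p']:.2e})")
```

prints (seed 1):

```
 lag-AAT non_steal  r_rm = +0.855  (p = 1.40e-77)
 CVR-AAT non_steal  r_rm = -0.839  (p = 3.95e-72)
 lag-CBF non_steal  r_rm = -0.851  (p = 3.12e-76)
 CVR-CBF non_steal  r_rm = +0.873  (p = 1.52e-84)
 lag-AAT     steal  r_rm = +0.199  (p = 1.06e-03)
 CVR-AAT     steal  r_rm = +0.170  (p = 5.37e-03)
 lag-CBF     steal  r_rm = -0.151  (p = 1.32e-02)
 CVR-CBF     steal  r_rm = -0.189  (p = 1.88e-03)
```

The synthetic cohort was generated with positive CBF–CVR and AAT–lag
coupling in non-steal tissue and an *inverted* CBF–CVR coupling inside the
steal territory; the pipeline recovers exactly that structure: strong
positive CVR–CBF and lag–AAT correlations and a strong negative lag–CBF
correlation in non-steal tissue, and a weak *negative* CVR–CBF correlation
in steal tissue — more negative reactivity where baseline flow is higher,
the signature of exhausted autoregulation. `demo_out/` additionally holds
the per-subject CVR/lag/CBF/AAT maps (NIfTI), the tidy ROI/bin tables
(CSV) and `report.json` with all test statistics.

The same stages are scriptable individually (`cvrasl simulate`,
`cvrasl run`, `cvrasl report`, `cvrasl check-trace` on the command line).

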