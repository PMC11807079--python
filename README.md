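# brainecf

Bottom-up prediction of rat brain-extracellular-fluid (brainECF)
pharmacokinetics for passively diffusing drugs and P-glycoprotein (P-gp)
substrates.

Unbound drug concentration in the brainECF — the microdialysis-accessible
compartment where most CNS drug targets sit — is hard to predict from
plasma alone, because the blood–brain barrier (BBB) combines passive
diffusion with active P-gp efflux. `brainecf` scales widely available in
vitro transwell transport parameters to in vivo BBB clearances, drives
them through a compartmental ODE model forced by an empirical plasma PK
model, and scores the predictions with a symmetrized prediction-error
framework. It is aimed at pharmacometricians and DMPK scientists who
want to test whether literature transwell data are a reliable input for
CNS physiologically based PK (PBPK) predictions.

## Model

In vitro → in vivo scaling (permeabilities in 10⁻⁶ cm/s):

```
CL_passive = P_app,A:B[I] · SA_BBB · 60                      [mL/min]
CL_Pgp     = (ER_c − 1) · 2 · P_app,A:B[I] · SA_BBB,trans · REF · 60
REF        = P-gp expression in vivo / P-gp expression in vitro
```

where `P_app,A:B[I]` is the apical→basolateral apparent permeability
with P-gp inhibited (or in the parental cell line), `ER_c = ER / ER[I]`
is the corrected efflux ratio isolating P-gp, `SA_BBB = 155 cm²`
(`SA_BBB,trans = 0.998 · SA_BBB = 154.69 cm²`), and the REF assumes
efflux activity proportional to proteomic P-gp abundance (19.4 fmol/µg
total protein in rat brain microvessels in vivo).

The brainECF mass balance of the ODE system is

```
V_ECF dC_ECF/dt = CL_passive·fup·C_MV − (CL_Pgp + CL_passive)·C_ECF
                  − Q_ECF·C_ECF − CL_BC,in·PHF_ECF·C_ECF + CL_BC,out·C_BC
```

with C_MV the brain microvascular concentration (exchanging with plasma
at cerebral blood flow Q_CBF), Q_ECF the brainECF bulk flow (terminal
sink), and CL_BC,in/out the brain-cell-membrane partitioning clearances
gated by the unionized fraction PHF_ECF. At steady state the unbound
partition coefficient is `Kp_uu = CL_passive / (CL_passive + CL_Pgp + Q_ECF)`.

Prediction accuracy uses `PE = (Y_pred − Y_obs) / ((Y_pred + Y_obs)/2)`,
bounded in (−2, 2); a k-fold error corresponds to |PE| = 2(k−1)/(k+1),
so the twofold acceptance band is |median PE| ≤ 0.67.

The packaged fixtures transcribe the published tables: 34 transwell
measurement sets for acetaminophen, raclopride, morphine, paliperidone,
quinidine, risperidone and verapamil; per-cell-line P-gp expression
extremes; plasma PK parameters; and the dosing regimens of the in vivo
validation studies.

## Worked example

Predict quinidine brainECF PK after a 20 mg/kg, 10-min IV infusion,
using the MDCKII-MDR1 transport data of Feng et al. and the average
in vitro P-gp expression:

```python
import numpy as np
import brainecf as b

bundle = b.load_bundle()
spec = b.build_spec(bundle, "quinidine", "short",
                    cell_line="MDCKII-MDR1", source="Feng2008",
                    expression_level="average")
cl = spec.clearances
print(f"CL_passive = {cl.cl_passive:.4f} mL/min")
print(f"REF        = {cl.ref:.3f}")
print(f"CL_Pgp     = {cl.cl_pgp:.3f} mL/min")
kpuu = b.steady_state_kpuu(cl.cl_passive, cl.cl_pgp, bundle.physiology.q_ecf)
print(f"Kp_uu,ss   = {kpuu:.4f}")
res = b.simulate_brain_ecf(spec, np.linspace(0, 240, 241))
print(f"AUC_ECF    = {res.auc_ecf:.0f} ng*min/mL")
```

prints

```
CL_passive = 0.0744 mL/min
REF        = 3.079
CL_Pgp     = 2.927 mL/min
Kp_uu,ss   = 0.0248
AUC_ECF    = 124 ng*min/mL
```

The passive clearance comes from P_app[I] = 8.0 × 10⁻⁶ cm/s over the
BBB surface; the REF of 3.08 scales the in vitro efflux (ER_c = 7.4) up
to the in vivo expression level, and the resulting CL_Pgp dominates the
barrier: only ~2.5 % of the unbound plasma concentration is predicted to
reach the brainECF at steady state.

The same scenarios are available from the shell, e.g.

```
brainecf simulate --drug quinidine --cell-line MDCKII-MDR1 \
    --source Feng2008 --expression-level average --out sim.csv
brainecf band --drug quinidine --cell-line MDCKII-MDR1 \
    --source Feng2008 --out band.csv
brainecf lit-summary --drug morphine --out summary.csv
```

Every command writes a JSON run manifest next to its output with the
resolved clearances, REF and seed, sufficient to reproduce the run.

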