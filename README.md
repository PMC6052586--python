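# iolmc — IOL manufacturing tolerance and refractive prediction error

After cataract surgery, the refractive outcome depends on how well the
intraocular lens (IOL) power calculation predicted the eye's
postoperative refraction — and on how close the implanted lens's true
power is to its label. Lenses sold on a 0.50 D grid carry an ISO-style
labeling tolerance of ±0.40 D over the 15.5–25.0 D range, while a
0.25 D-grid lens is specified at ±0.11 D. `iolmc` quantifies how much of
the postoperative refractive prediction error that manufacturing
tolerance alone can produce, for clinicians and researchers studying
refractive outcome accuracy.

The package provides:

* **Vergence engines** for the SRK/T and Haigis formulas: predicted
  spectacle-plane spherical equivalent $R(P)$ for an eye (keratometry
  $K$, anterior chamber depth $ACD$, axial length $AL$) and IOL power
  $P$, and the numeric inverse $P = R^{-1}(\text{target})$. Haigis
  places the lens at $d = a_0 + a_1\,ACD + a_2\,AL$; SRK/T derives its
  effective lens position from the corneal height and the A-constant.
* **Lens-constant optimization** to the standard zero-mean-error
  criterion: the SRK/T A-constant by bracketed root search, the Haigis
  triple by back-solving each eye's effective lens position from its
  observed refraction and regressing it on $(ACD, AL)$.
* **A Monte Carlo tolerance study**: for each eye the *zero-error
  power* $P_0$ (the continuous power at which the predicted refraction
  equals the observed postoperative spherical equivalent) is
  back-solved, then perturbed as $P \sim \mathcal N(P_0, \sigma^2)$
  with $\sigma$ the lens's tolerance SD, and the induced error
  $R(P) - R(P_0)$ is summarized over 10 replicates (MedAE, MAE, and the
  share of eyes within ±0.25/±0.50/±0.75 D).
* **A synthetic paired-eye cohort generator** emulating a 40-patient
  bilateral-cataract study (one 0.25 D-interval and one 0.50 D-interval
  lens per patient), with published biometry marginals and interocular
  correlations ($R^2$ = 0.926 for K, 0.893 for ACD, 0.934 for AL).
* **Outcome statistics**: MedAE/MAE summaries, Mann–Whitney U,
  2×2 chi-square, Student's t, Pearson $R^2$.

## Worked example

```python
from iolmc import (AKREOS_AO, CohortSpec, FormulaName, SimulationConfig,
                   generate)
from iolmc.monte_carlo import run_study

cohort = generate(CohortSpec(seed=7))          # 40 patients, 80 eyes
eyes = cohort.eyes("Akreos AO")                # the 0.50 D-interval group
cfg = SimulationConfig(formula=FormulaName.HAIGIS, tolerance_sd=0.40,
                       n_replicates=10, seed=101)
res = run_study(eyes, cfg, AKREOS_AO)
print(res.aggregate["medae"])
print(res.aggregate["pct_within"][0.25])
```

prints

```
{'min': 0.1364133296218899, 'max': 0.26260999068451363, 'grand_median': 0.19158430213285968}
{'min': 45.0, 'max': 75.0, 'grand_median': 63.75, 'pooled': 62.75}
```

i.e. with a ±0.40 D power SD, the per-replicate median absolute
refractive error runs about 0.14–0.26 D and only ~60% of simulated eyes
stay within ±0.25 D of the prediction — whereas the same study at
SD 0.11 D (the 0.25 D-interval lens) keeps ≥97.5% of eyes within
±0.25 D with MedAE near 0.05 D. At the spectacle plane, a lens power
error maps to roughly 0.55–0.75 of its magnitude, so these numbers are
the direct refractive footprint of the manufacturing tolerance.

The numbered drivers under `analysis/` run the full study end to end
(cohort → constant optimization → clinical-analog report → Monte Carlo
tables), writing their tables under `results/`. The same steps are
available as a CLI: `iolmc synth | optimize-constants | clinical |
simulate`.

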