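# Methods

## The question and the model

A labeled IOL power is allowed to deviate from the lens's true power.
For 0.50 D-interval lenses the accepted tolerance over 15.5–25.0 D is
±0.40 D; a 0.25 D-interval product in the same range is specified at
±0.11 D. The analysis here isolates how much refractive prediction
error that deviation alone produces at the spectacle plane, holding
every other error source (biometry measurement, effective-lens-position
estimation, formula bias) at zero by construction. Both ±figures are
treated as standard deviations of a Gaussian power error, matching the
study design this package emulates; a uniform-within-limits mode
(`SimulationConfig.uniform_within_limits`) is available as a sensitivity
switch for reading them as hard ISO limits, and is off by default.

## Vergence engines

**SRK/T.** The published theoretic formula with its errata, transcribed
exactly: corneal radius r = 337.5/K (mm); corrected axial length
LCOR = AL for AL ≤ 24.2 mm, else −3.446 + 1.716·AL − 0.0237·AL²
(the published coefficients leave a ~0.0015 mm step at the cutoff,
which we keep); corneal width Cw = −5.41 + 0.58412·LCOR + 0.098·K;
corneal height H = r − √max(r² − Cw²/4, 0) (the clamp is the errata
behavior for very steep, small corneas); ELP = H + 0.62467·A − 68.747 −
3.336; optical axial length LOPT = AL + 0.65696 − 0.02029·AL. The
refraction form uses aqueous index 1.336 and corneal index 1.333.

**Haigis.** ELP d = a₀ + a₁·ACD + a₂·AL (mm); corneal power from the
corneal index 1.3315 applied to r = 337.5/K, per the original
publication (the 1.3375 keratometric variant is exposed via the
`corneal_index` argument, since biometer firmware differs and the
convention used in any given clinic is rarely documented); thin-lens
vergence chain retina → IOL → cornea → spectacle plane in aqueous index
1.336.

Shared numerical choices: vertex distance fixed at 12 mm for both
formulas; all powers and refractions carried at full precision
internally, with rounding only at grid selection and report formatting
(2 decimals for diopters, 1 for percentages); singular vergence
denominators raise a domain error rather than clamping. Inversion
(power for a target refraction, ELP from an observed refraction) uses
Brent's bracketed root search — refraction is strictly monotone in both
variables over the physical range — on [−10, 40] D and (0.5, 9.0) mm
respectively, tolerance 1e-10, with bracket failures reported with the
eye identifier. Grid rounding snaps to the nearest labeled power with
exact half-interval ties going to the *lower* power (the
myopia-favoring surgical convention; the tie rule matters only on exact
ties) and clamps to the lens's power range.

## Constant optimization

Both procedures enforce the standard criterion: zero mean signed
prediction error over the fitting cohort.

* SRK/T A-constant: the cohort mean error is strictly monotone in A, so
  the unique root in [100, 130] is found by bracketed search
  (tolerance 1e-8).
* Haigis: for each eye the ELP reproducing its observed postoperative
  refraction at the implanted power is back-solved; ordinary least
  squares of ELP on (ACD, AL) gives a₁, a₂ (slopes) and the raw
  intercept. Because least squares on ELP is not identical to zero mean
  *dioptric* error, the intercept is then shifted so the cohort mean
  error is exactly zero (within 1e-6 D); both the raw intercept and the
  shift are reported. This two-step reading matches the stated
  criterion most directly among the plausible variants.

## Monte Carlo tolerance propagation

For each eye the zero-error power P₀ solves R(P₀) = observed
postoperative SE, so before perturbation every prediction error is
identically zero — the construction that removes all non-manufacturing
error sources. Each replicate draws one power per eye,
P ~ N(P₀, σ²), and records the induced spectacle-plane error

    error = R(P) − R(P₀),

which equals "postoperative SE minus predicted refraction" with the
drawn power in the role of the implanted lens. The exact arithmetic of
the error under perturbation is a documented convention here (the
emulated design states the inputs and the outcome measure but not the
subtraction order); this definition preserves the sign convention
(overpowered lens → myopic, negative error). Drawn powers are *not*
re-rounded to the labeling grid — manufacturing error is continuous by
definition. Ten replicates per formula per lens group; one root seed
per study with per-replicate substreams spawned deterministically, so
replicate r is reproducible regardless of how many replicates run, and
permuting replicate order permutes outputs without changing aggregates.
Per-replicate summaries (MedAE with IQR, MAE, threshold counts) feed
min/max/grand-median aggregates plus a pooled within-threshold share
over all replicate×eye errors.

Because R is locally linear in P (sensitivity |dR/dP| ≈ 0.55–0.75 for
cohort-typical eyes — the "about half the SD" rule of thumb), MedAE
scales linearly with σ, and the MedAE ratio between the two tolerance
groups tracks 0.40/0.11 ≈ 3.64.

## Synthetic cohort

The generator emulates the paired-eye study: 40 patients, one
0.25 D-interval lens and one 0.50 D-interval lens per patient, the
first-eye lens randomized per patient.

* Biometry: per measure, value = mean + patient latent + eye deviation,
  Gaussian, with Var(latent) = r·sd² and r = √R², which makes the
  population interocular Pearson correlation r and hence the
  interocular R² hit its target. Pooled bilateral targets (eyes are
  exchangeable by design): K 44.4 (1.36) D, ACD 3.15 (0.36) mm,
  AL 23.43 (0.70) mm; R² targets 0.926/0.893/0.934. Measures are
  mutually independent — no joint K–AL structure is published for this
  cohort.
* Surgery: continuous power for the planned refraction (−0.25 D) via
  the selection formula (Haigis by default), rounded to the lens's
  grid; patients with a continuous power outside 15.5–25.0 D are
  rejected and redrawn (cap 1000 attempts), preserving Gaussian shape
  within range. This inclusion rule truncates the biometry tails, so
  the *realized* SDs sit below the latent targets (axial length most,
  ≈0.57 vs 0.70 mm) — exactly as a real enrolled cohort's spread
  reflects its inclusion criteria; the `validate` guardbands account
  for this.
* Outcome: postoperative SE = formula prediction at the implanted grid
  power + Gaussian noise, SD 0.45 D with between-eye correlation 0.6.
  Both are emulation choices, not published values: 0.45 D puts the
  clinical-analog MedAE in the published 0.2–0.5 D band, and 0.6 sits
  in the "moderate to strong" interocular range the study reports
  qualitatively.
* `manufacturing_error=True` (off by default) additionally perturbs the
  true implanted power by the lens's tolerance SD before computing the
  outcome — a sensitivity mode that builds the tolerance difference
  into the clinical analog itself.

What the generator does **not** emulate: age/sex structure, corneal
astigmatism, axial-length–keratometry correlation, surgeon- or
IOL-design-specific ELP behavior, measurement-device bias. Passing
tests therefore show that the *pipeline and the tolerance-propagation
arithmetic* behave correctly under the study's stated statistical
structure — not that the generator reproduces any real clinic's case
mix.

## Problem sizes and determinism

The shipped study runs at the emulated trial's own scale: 40 patients
(80 eyes), 10 replicates per formula per group. Distributional checks
(interocular correlations, calibration guardbands, parameter-recovery
simulations) use 200–400 patients, where the targets are tight.
Everything is seeded: cohort generation from `CohortSpec.seed`,
simulations from `SimulationConfig.seed` via spawned substreams, and
`scripts/acceptance.py` derives all of these from its single `--seed`.

## Known limitations

* Only SRK/T and Haigis are implemented; no toric/multifocal optics, no
  post-refractive-surgery eyes, no other formulas (Hoffer Q, Holladay,
  Barrett).
* The clinical two-group gap observed in the emulated study rests on
  its real patients' data; the synthetic clinical analog reproduces the
  error scale (MedAE band), not the published group difference, which
  at n = 40 is within noise of the tolerance-only effect unless
  `manufacturing_error` is enabled.
* The 2×2 chi-square is reported uncorrected by default, with Yates
  alongside; quartiles use linear interpolation (the emulated study's
  IQR convention is unstated).
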