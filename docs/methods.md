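# Methods

This note documents the models implemented in `rbekit`, the statistical
choices behind the fitting and error propagation, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Survival model and fitting

Clonogenic survival follows the linear-quadratic (LQ) model
S(D) = exp(−αD − βD²), with α in Gy⁻¹ (initial slope, single-track
damage) and β in Gy⁻² (curvature, track-interaction damage). The ratio
(α/β) in Gy characterises fractionation sensitivity; values below ~5 Gy
mark radioresistant, late-responding phenotypes.

**Plating-efficiency normalization.** Within one cell line and beam
condition, the plating efficiency (PE) of each irradiation session is the
mean colonies/cells-seeded of that session's unirradiated control wells.
Each well's surviving fraction is its own colony ratio divided by the
session PE; per-dose means and standard deviations aggregate over all
wells of all sessions (≥18 values at the default design). The 0 Gy rows
define the normalization and are not refitted as data points.

**Weighted minimum chi-square.** The fit minimises
χ² = Σᵢ [(SFᵢ − exp(−αDᵢ − βDᵢ²)) / σᵢ]² over α, β ≥ 0, where σᵢ is the
per-dose standard deviation of the surviving fraction (the survival-curve
error bars). σᵢ = 0 entries are floored at the smallest nonzero σ of the
curve (itself ≥ 1e−4) so no point receives infinite weight. The fit runs
in linear SF space (the literal reading of a 1/σ-weighted chi-square on
surviving fractions), uses `scipy.optimize.least_squares` with bounds,
and multi-starts from the fixed grid α ∈ {0.05, 0.2, 0.5} ×
β ∈ {0.005, 0.03, 0.08}, keeping the lowest-χ² solution — deterministic
without a tie to any particular initialiser. Point estimates are
invariant to the overall scale of the σᵢ, so the SD-versus-SE convention
of the error bars does not change (α̂, β̂).

**Parameter covariance.** Two error sources dominate a clonogenic fit:
per-well counting noise, and the error of the estimated session PE, which
is *shared* by every well of the session and therefore acts as a common
multiplicative factor on the whole curve. The default covariance is a
sandwich built at the optimum from the Gauss-Newton curvature and the
residual covariance

    Cov(SF̄ᵢ, SF̄ⱼ) = δᵢⱼ · sdᵢ²/nᵢ + mᵢ·mⱼ·√(vᵢ·vⱼ),

where mᵢ is the fitted model value and vᵢ the relative variance of the
shared normalization (computed from the control wells and carried on each
`SurvivalPoint` as `norm_rel_var`). A plain reduced-χ² rescaling of the
inverse curvature was rejected: with only 3 residual degrees of freedom
the scale estimate is so noisy that simulated 95% CIs covered the truth
only ~65% of the time, while the sandwich form is empirically calibrated
(~94% coverage over simulated assays at the default design).
`absolute_sigma=True` switches to the textbook inverse-curvature
covariance for users whose σᵢ are true standard errors.

**Derived ratios.** α/β and its standard error use the delta method,
Var(α/β) = (1/β)²Var(α) + (α/β²)²Var(β) − 2(α/β³)Cov(α, β). Being a
first-order expansion it is accurate while the relative errors of α and β
stay below ~10–15%; the test-suite's Monte-Carlo oracle checks 5%
agreement in that regime.

## Experimental RBE

RBE is the ratio of reference (200 kV x-ray) to proton dose producing
equal survival. At a survival level S the doses solve βD² + αD + ln S = 0
(computed via the numerically stable root form, exact as β → 0). At a
fixed proton dose Dp the ratio has the closed form

    RBE(Dp) = [√(α_x² + 4β_x·Dp·(α_p + β_p·Dp)) − α_x] / (2·β_x·Dp),

which the tests verify to be identical (to 1e−9) to the equal-effect dose
ratio at the matched survival level. When β_x = 0 the limit
(α_p + β_p·Dp)/α_x is used. RBE_90 means S = 0.90 (the low-dose region)
and RBE_10 means S = 0.10.

Standard errors propagate by the delta method over (α_x, β_x, α_p, β_p),
using each fit's internal 2×2 covariance and treating the x-ray and
proton experiments as independent; gradients are central differences.
RBE_90 values amplify input uncertainty strongly (the defining doses sit
on the flat low-dose part of both curves), which is why their printed
reference values are treated as a looser band than RBE_10 in the tests.

## Phenomenological models

All three models share the dose response

    RBE(Dp) = [√((α/β)_x² + 4Dp(α/β)_x·RBE_max + 4Dp²·RBE_min²) − (α/β)_x] / (2Dp),

where RBE_max is the vanishing-dose limit (α_p/α_x) and RBE_min the
high-dose limit (√(β_p/β_x)). When RBE_max = RBE_min the discriminant is
a perfect square and the response is the exact constant RBE_min (the
implementation special-cases this, so the unity identity is exact).
Coefficients live in `src/rbekit/data/model_coefficients.yaml`, versioned
and hashed into every pipeline manifest.

* **MCN** (McNamara): RBE_max = 0.99064 + 0.35605·LET_d/(α/β)_x,
  RBE_min = 1.1012 − 0.0038703·√((α/β)_x)·LET_d — the published proton
  coefficients. Note that at high (α/β)_x and low LET_d the model has
  RBE_min > RBE_max, i.e. RBE rising with dose; this is a genuine feature
  of the published fit, consistent with sub-unity low-dose RBE
  observations in high-(α/β)_x tissues.
* **RØR** (Rørvik, unweighted variant): RBE_max = 1 + 0.645·LET_d/(α/β)_x
  with RBE_min ≡ 1, so the model is exactly the identity at LET_d = 0.
* **JON** (Jones-type): RBE_max = 1 + 0.1035·(LET_d − 0.193)/√α_x,
  RBE_min = 1 − 0.0077·(LET_d − 0.193)/√β_x. The tissue dependence uses
  α_x and β_x separately, not only their ratio. **These three constants
  are a synthetic reconstruction**: the original Jones coefficient set
  was not available in numeric form, so a parameterization with the
  Jones model's qualitative structure was calibrated by least squares
  against the published 2 Gy prediction table (four tissues × six LET_d
  values); it reproduces all 24 published cells within ±0.01 after
  rounding. Extrapolation outside (α/β)_x ∈ [3, 15] Gy or LET_d ∈
  [1.9, 4.5] keV/µm is not validated.

No reference-quality correction is applied by default (the MCN and RØR
source data are normalized to MV photons while a 200 kV reference is
~10–15% more effective); an optional multiplicative
`reference_quality_factor` is accepted in the pipeline config for users
who want it.

## Mechanistic (RMF) conversion

The repair-misrepair-fixation model, approximated in LQ form for doses up
to ~(α/β)_x, converts photon parameters to proton parameters through the
double-strand-break induction RBE:

    α_p = α_x·RBE_DSB·(1 + 2·z̄_F·RBE_DSB/(α/β)_x),   β_p = β_x·RBE_DSB².

RBE_DSB is a **required external input** per beam condition (typically
from a Monte-Carlo damage simulation); the package never computes it, and
the pipeline skips the RMF column with a warning rather than invent one.
z̄_F, the frequency-mean specific energy per event, uses a site model of
the nucleus: z̄_F = 0.1602·LET_d/(ρ·πd²/4) Gy with diameter d in µm
(default 5 µm) and density ρ = 1 g/cm³; it can be overridden directly
when a microdosimetric value is available. The survival RBE then follows
from the fixed-dose closed form above.

## LET_d association

Per cell line and endpoint, mean RBE values are regressed on LET_d by
ordinary least squares (statsmodels), and the zero-slope null is tested
with the F-statistic on (1, n−2) degrees of freedom — numerically
identical to the squared slope t-statistic. Unweighted OLS on the mean
values is the default (the simplest reading of "linear regression" on
per-condition means); an inverse-variance weighted variant is available
via `weighted=True`. An exactly constant response returns F = 0, p = 1.
At the study design (six LET_d values between 1.9 and 4.5 keV/µm) the
exact noncentral-F power for a slope of 0.08 RBE per keV/µm at residual
noise σ = 0.05 is 0.816 at the 5% level, which the simulation-based
acceptance check reproduces.

## Synthetic generator

`simulate_assay` emulates the study design: dose grid
{0, 0.5, 1, 2, 4, 6} Gy; seeding 250 cells/well at 0 and 0.5 Gy, 500 at
1 and 2 Gy, 1000 at 4 Gy, 2000 at 6 Gy; 6-well plates; ≥3 independent
sessions. Colony counts are Poisson with mean
cells·PE_session·exp(−αD−βD²), truncated at the seeded count, with
PE_session = PE·exp(N(0, σ_session)). Defaults: PE = 0.3 (a typical
mid-range plating efficiency for adherent carcinoma lines) and
σ_session = 0.1 (a realistic ~10% between-session variability; the
session factor cancels in the surviving-fraction normalization, so it
stresses the normalization path rather than biasing the fit). The
built-in archetypes carry the published LQ parameters of the four study
cell lines as ground truth, and the six proton conditions use the
published LET_d values (1.9–4.5 keV/µm at the two SOBP setups).

Not emulated: the >50-cell colony criterion (counts are assumed already
thresholded), cell-cycle and dose-rate effects, oxygen effects, spatial
plate effects, counting error by eye, and any dosimetric uncertainty.
Passing recovery tests therefore demonstrates correctness of the
statistical chain under the canonical Poisson assay model — not
robustness to every systematic a real laboratory would face.

## Numerical choices and degenerate inputs

* Equal-survival doses via the stable quadratic root (no cancellation as
  β → 0); α = β = 0 raises a no-effect error.
* All σᵢ = 0 triggers an unweighted fall-back fit with a warning.
* Fit determinism: fixed multi-start grid, no RNG anywhere in fitting.
* Problem sizes in the statistical acceptance checks: 200 simulated
  assays per archetype for recovery/coverage, 10⁴ replicate series for
  F-test size, 2000 for power — enough that Monte-Carlo error is small
  against the asserted margins.
* The parameters-only pipeline entry accepts a printed-table style CSV of
  LQ parameters, so published summary tables can be re-analysed without
  raw counts. Values printed to two decimals limit reproduction accuracy:
  iso-survival RBEs recomputed from rounded inputs can differ from values
  computed on unrounded fits by several 0.01 (up to ~0.06 at RBE_10,
  more at RBE_90).

## Limitations

* Proton LET is a scalar (dose-averaged) quantity; no LET spectra, no
  microdosimetric-kinetic or local-effect models.
* The Jones-type coefficients are calibrated, not transcribed (above);
  treat JON outputs as a faithful reproduction of the reference
  predictions rather than the canonical published model.
* Delta-method errors are first-order and degrade for relative parameter
  errors beyond ~15%, notably for α/β of shallow curves and for RBE_90.
* The regression treats per-condition RBE means as independent
  observations; they share the same x-ray reference fit, which induces a
  small positive correlation the F-test ignores.
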