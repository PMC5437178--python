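# Methods

## Model

The package treats the CSF space as a river-like start–end system fed by
barrier-restricted diffusion from blood, whose protein concentration is
constant (blood volume and circulation dwarf the diffusional loss). Every
position along the neuraxis is a steady state between diffusional influx
across the barrier and removal by bulk flow. Summing the consecutive
steady states along the flow path yields the saturation law

    Q(t) = 1 − exp(−ℵ·k·t/L),    F(t) = exp(−ℵ·k·t/L),

with `ℵ = D·B` the exchange coefficient, `k` a proportionality constant
(1/m), `L` the barrier thickness and `t` the CSF flow time. `Q` and `F`
are exact complements. The discrete cascade — segment `i+1` receives the
influx reduced by what segment `i` already accumulated,
`Q_{i+1} = Q_i + (ℵ·k·Δt/L)(1 − Q_i)` — is implemented as an independent
numerical oracle (`cascade_q`): it reproduces the first two steady states
of the conceptual derivation verbatim and converges to the closed form as
the forward-Euler discretization of `dQ/dτ = (ℵk/L)(1 − Q)`; the tests
require relative agreement below 1e-3 at 10⁴ segments.

Exponent grouping: the dimensionally consistent reading of the rate is
`ℵ·k·t/L` (ℵ in m²/s, k in 1/m, L in m), and that is what the code
computes. Two explicit operating modes exist: `fitted` (ℵ dimensionless,
`k/L = 1`, `t` in arbitrary flow-time units — the convention of all curve
fits) and `physical` (SI units); the mode is a field of the parameter
object, never inferred.

## Assumptions and what they exclude

- Radial symmetry and planar steady-state diffusion across the barrier
  (`F = D(C1−C2)/L`).
- Intra-CSF diffusional fluxes are neglected: with the default geometry
  (flow path 50 cm, CSF volume 100 ml, production 0.3 ml/min, protein
  `D = 1e-6 cm²/s`) the bulk-flow velocity is 0.15 cm/min = 0.0025 cm/s
  and the Péclet number `v·L/D = 1.25e5 ≫ 1`. (Some sources print the
  intermediate velocity as 0.015 cm/min; that figure is inconsistent with
  both the stated arithmetic and the Péclet value, so the package uses
  0.15 cm/min = 0.0025 cm/s throughout.)
- The barrier acts as a single multiplicative factor `0 < B < 1` on free
  diffusion; different barrier sites and varying flow velocities along the
  path are absorbed into one individual mean ℵ and one total flow time.
- Blood-side concentration constant; no intrathecal synthesis in the base
  model (synthesis appears only as a classification outcome and as a
  synthetic spike in the cohort generator).
- Globular hydrophilic serum proteins only; the Stokes–Einstein/barrier
  algebra is not expected to transfer to lipophilic substances.

## Parameters

| Parameter | Default | Unit | Role |
|---|---|---|---|
| ℵ_Alb anchor | 2 | – | arbitrary anchor of the fitted mode; only ratios are identified |
| k/L anchor | 1 | – | arbitrary composite rate of the fitted mode |
| Q_Alb window | [2e-3, 0.15] | – | calibrated range of the hyperbolic curves |
| T | 310.15 | K | Stokes–Einstein temperature (body temperature) |
| η | 6.9e-4 | Pa·s | water viscosity at 37 °C |
| R_H | 3.51/5.29/6.50/12.65 | nm | measured radii: albumin/IgG/IgA (monomer)/IgM |
| ℵ fitted | 2/1.23/0.86/0.55 | – | packaged fitted exchange coefficients |

Hyperbolic curve parameters (a/b, b², c) for the IgG/IgA/IgM upper, mean
and lower discrimination curves ship in `data/reibergram_params.json`
with their printed scales (b²·10⁻⁶, c·10⁻³) applied on load. All
quotients are held internally as absolute fractions; the ×10⁻³ display
convention exists only at the I/O boundary behind an explicit flag.
Ratio fits of the fitted mode are invariant to joint rescaling of the
anchors (tested); only `ℵ_IgX/ℵ_Alb` is meaningful.

IgA is modelled with the monomeric radius; a dimeric variant can be
registered as a separate `MoleculeSpec`.

## Fitting

The empirical target is the mean hyperbolic curve re-parameterised by flow
time: `Q_Alb(t) = 1 − exp(−2t)` on a 200-point log-spaced `t` grid whose
image spans the calibrated window, with `Q_IgX` from the hyperbolic
closed form.

- Steady-state fit: scalar least squares of
  `Q_IgX(t) = 1 − exp(−2·t·r)` for `r = ℵ_IgX/ℵ_Alb`, unweighted on the
  quotient scale (the curves are compared on linear quotient axes).
  Over the default window this lands on ℵ 1.24/0.86/0.52 for IgG/IgA/IgM
  (quotients 1.61/2.32/3.85). The IgM value is the most
  window-sensitive — its quotient moves by several percent with the upper
  window bound, which is expected when a least-squares surrogate replaces
  a visual fit of a strongly curved relation; the window used and the
  per-point residuals are part of every `FitResult`.
- Half-erfc comparison fit: both curves are inverted through
  `Q = ½·erfc(z)` and the argument scaling `a` in `z_IgX = a·z_Alb` is the
  exact linear least-squares solution; the reported diffusion ratio is
  `a²`. Residuals are taken on the argument scale rather than the
  quotient scale: the argument relation is exactly linear in the model,
  every point of the window contributes evenly, and the fitted ratio then
  reflects the whole physiological range (1.22/1.39/1.78 for IgG/IgA/IgM
  over Q_Alb ∈ [2e-3, 0.1]). Quotient-scale residuals are dominated by
  the few points at the top of the window and drag the ratio far from the
  curves' behaviour below Q_Alb ≈ 0.02; they are reported as a diagnostic
  (`q_residuals`) instead.
- Residual profile: the steady-state fit is tight over the window
  relative to curve magnitude but degrades toward the low-Q_Alb end,
  where the hyperbolic form and the saturation law disagree most; a test
  pins this profile.

Convergence failures raise a dedicated error carrying the residual trace
(CLI exit code 3).

## Synthetic cohorts

The generator draws what the model says varies between individuals: a CSF
flow time `t_i` (lognormal; median 2.5e-3 in fitted-mode units, placing
the median Q_Alb at ~5e-3, the middle of the physiological 2–8 ×10⁻³
range; geometric CV 0.5 spans that range) and per-patient, per-analyte
barrier modifiers (lognormal, mean-centred on 1, CV 0.15) applied to the
packaged mean exchange coefficients, plus multiplicative measurement
noise (CV 0.08, consistent with assay imprecision below 10%). Barrier
modifiers and flow time are drawn independently — an explicit
simplification, since barrier permeability and size specificity are only
partly coupled in reality. Intrathecal synthesis is a multiplicative
spike on the affected analyte's quotient, present solely so classifiers
have positive cases. Each patient has an RNG stream spawned by counter
from one global seed, so cohorts are bit-reproducible.

What passing tests show — and do not show: noise-free cohorts sit exactly
on the model curve and the fitted ratios are recovered to <1e-4, and
under the default noise the recovery bias on `ℵ_IgG/ℵ_Alb` stays below 5%
at n=500. The generator emulates the model's own variance structure; it
does not emulate age structure, analyte-specific assay bias, truncation
by clinical referral, or a population calibrated to the printed 99%
bands, so recovery results certify the fitting machinery, not field
performance on real cohorts.

## Numerical choices

- `expm1`/`log1p` throughout the saturation law and its inverse, so
  quotients of order 1e-3 lose no precision.
- Half-erfc inversion via the complementary error function inverse
  (round-trips to 1e-10 over (0, 0.5]).
- Scalar fits use bounded least squares (`x ≥ 1e-9`, xtol/ftol 1e-14);
  the erfc-argument fit is closed-form.
- Lower-limit hyperbolic curves may be negative at tiny Q_Alb; values are
  reported as-is and clamped only when rendering diagrams.
- Classification outside the calibrated Q_Alb window proceeds but warns
  and flags the result; a missing analyte quotient yields an explicit
  missing-data band.
- Generated quotients reaching 1 (possible only under extreme synthetic
  settings) are clipped just below 1 and counted.
- The discrimination-curve ordering (upper > mean > lower) is validated
  on a 32-point probe grid at family construction.

## Known limitations

- The half-erfc fit is a reconstruction anchored only to the published
  comparison ratios; the original appendix derivation is not public.
- The IgM steady-state fit is window-sensitive (see Fitting); users
  comparing against the conventional manual value 0.55 should inspect the
  reported window and residuals.
- The variation-coefficient grid reproduces the printed population table
  only to its printed precision; at Q_Alb = 3.5e-3 the IgG value
  recomputes to 0.87 against a printed 0.89 — attributable to rounding of
  the printed curve parameters, and deliberately not "corrected".
- No intrathecal synthesis fraction formulas, oligoclonal-band logic or
  age-adjusted reference limits; no spatial PDE of the CSF space;
  pulsatile flow is outside the model.
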