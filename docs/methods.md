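# Methods

## Scope and model

`sfrmodel` computes the absorption-free reflectance `R0` of a single optical
fiber in contact with a semi-infinite turbid medium, where the same fiber is
source and detector.  At these geometries the source–detector separation is
below the transport mean free path `1/μs′`, so the signal is *subdiffuse*:
part diffuse, part "semiballistic" (photons that experienced exactly one
backscattering event, polar angle > 90°, plus any number of forward
scatterings).  The model is

    R0 = (1 + X) · ηc · R_dif(μs′d),     X = a2 · [psb/(μs′d)²]^a3,

and the package also implements everything used to derive and validate such
a model: phase-function machinery, a Monte Carlo transport code for the
overlapping-fiber geometry, the integration-angle optimization that defines
`psb`, constants calibration, and the spectral inversion.  Absorption is out
of scope throughout (the pathlength model needed to add it is future work).

## Phase functions

Four families (HG, MHG, TTHG, Gegenbauer/RMC), all normalized as densities
per steradian over the sphere.  Conventions:

* MHG: `p = α·p_HG(g) + (1−α)·(3/4π)cos²θ`, so `g1 = α·g`,
  `g2 = α·g² + 0.4(1−α)`.
* TTHG: `p = α·p_HG(gf) + (1−α)·p_HG(gb)` with `gf ∈ (0,1)`, `gb ∈ (−1,0)`;
  moments are the convex combinations `α·gf^n + (1−α)·gb^n`.
* Gegenbauer kernel: `p = K(1+g²−2g·cosθ)^−(α+1)` with the closed-form
  normalizer `K = αg(1−g²)^{2α} / (π[(1+g)^{2α} − (1−g)^{2α}])`; `α = 1/2`
  recovers HG exactly.

Moments use closed forms where they exist and otherwise fixed-order
Gauss–Legendre quadrature in `cosθ` (order 2048; the normalization `g0 = 1`
is recomputed as a convergence check and must hold to 1e-6).  Partial cone
integrals (`p_f(θ)`, `p_b(θ)`) are closed-form for every family — the HG
antiderivative for the HG-based families and the power-law antiderivative
for the Gegenbauer kernel — which is what makes the exhaustive
integration-angle scans cheap.

Sampling uses a tabulated inverse CDF on a uniform `cosθ` grid of 2^14+1
points (trapezoid CDF, linear inversion).  This is generic across families;
the sampled-moment bias is below 1e-4, checked against quadrature moments in
the tests.

### The plausible-tissue ensemble

`build_tissue_grid()` enumerates the standard parameter grids (10 equally
spaced values per range, endpoints included; TTHG uses 3+5 α values, 10 gf,
5 gb; the Gegenbauer gR upper bound shrinks with α as `0.95 − 0.2α`) and
keeps models with `g1 ≥ 0.5` and `g2 < 0.9`.  This yields 193 models:
15 MHG, 132 TTHG, 46 RMC.  The MHG and RMC counts pin down the step
conventions and the Gegenbauer parameterization; the TTHG count is then
fully determined by the standard two-term mixture above.  The ensemble's
`g1` spans 0.5–0.94.

## Subdiffuse parameters

`γ = (1−g2)/(1−g1)`, `δ = (1−g3)/(1−g1)`, and the alternating series
`σ = Σ_{i≥2} (−1/2)^{i−2}(1−g_i)/(1−g1)` (summed until a term falls below
1e-10; with a 64-moment budget the geometric tail bound guarantees this for
the whole ensemble).  `Rp(θb,θf) = p_b(θb)/(1−p_f(θf))`; `RpNA` evaluates it
at the probe acceptance angle `θacc = arcsin(NA/n_sample)` in both
directions; `psb` fixes the angles at 1° backward / 23° forward.  Those two
angles are constants of the model (chosen once by dispersion minimization
for NA 0.22), not probe-derived: a probe with a different NA changes `RpNA`
but not `psb`.  Angles are degrees at every interface and converted
internally, to keep the 1°/23° constants legible.

## Diffuse component

The pencil-beam solution with an extrapolated boundary,

    R(ρ) = (1/4π)·{ μs′²/[1+(μs′ρ)²]^{3/2}
                    + (1+4A/3)·μs′²/[(1+4A/3)²+(μs′ρ)²]^{3/2} },

is averaged over the exact density of distances between two uniform random
points on the fiber face (vanishes at 0 and d, mean `64d/45π`), giving
`R_dif(μs′d) = (πd²/4)∫R·p dρ` — a function of the product `μs′d` alone that
rises as `(μs′d)²` and saturates at 1.  Quadrature is adaptive Gauss–Kronrod
with relative tolerance 1e-8; iterative fits use a cubic-spline interpolant
of `log R_dif` vs `log μs′d` (600 knots over 1e-3..1e4, relative error
< 1e-6, exact quadrature outside the table).

The internal-reflection parameter `A` comes from the effective reflection
coefficient built from Fresnel hemispheric integrals of the fluence and flux
moments (`A = (1+R_eff)/(1−R_eff)`), evaluated for the *tissue–fiber*
relative index: the diffuse photons the model tracks reach the probed
surface under the fiber.  For 1.35/1.45 this gives A = 1.0268; `ProbeConfig`
computes it by default and accepts an override.  Collection efficiency is
`ηc = a1·sin²θacc`: the Lambertian value `sin²θacc = (NA/n_sample)²` (2.66%
at NA 0.22) scaled by `a1 ≈ 1.11`, reflecting an angular profile between
Lambertian (2.7%) and flat (3.8%).

## Monte Carlo

Single-threaded numba kernel; tissue at `z > 0`, fiber face centered at the
origin; distances in cm; unit photon weights, no absorption, no roulette.

* **Launch** — position uniform over the fiber face; polar angle uniform on
  `[0, θacc]` (literal reading of "uniform angular distribution within the
  acceptance angle"); a uniform-solid-angle option is provided.
* **Steps** — exponential, mean `1/μs`; scattering angles drawn from the
  family's inverse-CDF table via a uniform-u index (O(1) per draw), azimuth
  by rejection sampling.
* **Surface** — inside the fiber footprint the photon meets the
  tissue→fiber interface (1.35→1.45), outside it tissue→air (1.35→1.00).
  Unpolarized Fresnel reflection/transmission is sampled at both;
  transmitted photons inside the footprint are detected iff the incidence
  angle (in tissue) is within `θacc`, all other transmitted photons are
  lost; reflected photons continue.  The diffusion-limit check (below) is
  the arbiter for this convention and passes.
* **Termination** — a photon dies when its distance from the fiber-face
  center exceeds the termination distance.  The a-posteriori criterion is
  that 99.9% of detected photons stayed within 75% of it; auto mode starts
  at `max(50/μs′, 10d)` and doubles until the check passes.  Protocol runs
  in the tests and the acceptance script pass explicit, pre-validated
  distances (1 cm at μs′d = 0.1 with a 100-µm fiber, 2.5 cm for the
  300/600-µm phantom spectra) because the auto starting point is an order
  of magnitude more conservative than the criterion requires at these
  operating points.  Note the 99.9% quantile of detected excursions is
  effectively a sample maximum until thousands of photons are detected, so
  the check is conservative and noisy at small budgets.
* **Tallies** — per detected photon: scattering-event count, backscatter
  count (`cosθ < 0`), pathlength, maximum excursion; plus the angular
  histogram of all scattering events of detected photons (0.25° resolution,
  rebinnable) — the *effective phase function*.  A detected photon with
  exactly one backscatter is semiballistic.  Energy bookkeeping
  (detected + lost + terminated = launched) is exact and tested.
* **Reproducibility** — the kernel seeds numpy's RNG once per run and is
  bit-reproducible; replicates derive distinct seeds from the base seed.

Observed behaviour at `μs′d = 0.1`, NA 0.22 (the subdiffuse operating
point): ~98% of detected weight is semiballistic, and the effective phase
function rises sharply near `180° − 2θacc ≈ 161°`, as expected when both
launch and detection are confined to the acceptance cone.

## Experiments

* **Dispersion metric** — for a target reflectance, the spread (max−min) of
  `log10` of a parameter among simulations within ±10% of the target,
  divided by the full-ensemble spread; bounded in [0,1], invariant under
  rescaling.  Target reflectances are spaced equally in `log10` between the
  5th and 95th ensemble percentiles (configurable; the derivation used five
  targets).
* **Angle scan** — exhaustive scan of `Rp(θb,θf)` over 1°-step angle pairs,
  minimizing the mean relative dispersion.  On the full ensemble with
  precise reflectances the optimum is (1°, 22°), flat in `θb` up to ~20°
  and sharp in `θf`.  A caveat established during development: the argmin
  is *not stable on small subsets*.  With ~20 models a reflectance band
  holds only ~2 models, and among ~8000 angle pairs some pair makes those
  two models' `Rp` curves cross, sending the dispersion to ~0 at an
  arbitrary angle pair.  The scan is therefore meaningful only with a dense
  ensemble (≳100 models) and reflectance noise below a few percent.
* **Calibration** — least squares on `log10 R0` (errors are relative and
  span decades): stage 1 fits `(a1,a2,a3)` per NA; stage 2 fixes the shared
  `a1` (by default the stage-1 mean rounded to two decimals) and refits
  `(a2,a3)`.  95% CIs from the SVD covariance of the final Jacobian.
  Points below the validity limit `μs′d < 0.1` are excluded.
* **Error statistics** — median/std/max of `100·|R0_model − R0_MC|/R0_MC`
  with the same validity filter.

A physical caveat from this package's own ensemble: two-term HG members
with a *narrow, strong* backward lobe (gb = −0.95 and ≥ 5% backward weight)
have `psb ≳ 7e-4` and violate the single power law `X ∝ psb^a3` by factors
of 2–3 — the detected single-backscatter probability saturates once the
backward lobe concentrates inside the acceptance cone.  The calibrated
power law should be trusted for `psb ≲ 3e-4`, which covers the
moderate-backscatter shapes measured in tissue.

## Spectra

`synthesize_spectra` builds two-diameter (300/600 µm) reflectance spectra
on 400–900 nm in 5-nm steps from `μs′(λ) = a(λ/λ0)^−b` (λ0 = 600 nm) and a
smooth psb curve (packaged default: log-linear from 1e-4 to 1e-3 across the
band — a synthetic stand-in, since tissue psb dispersion is uncharacterized),
optionally with seeded multiplicative Gaussian noise.  The generator flags
any wavelength where `μs′d` falls below the 0.1 validity limit.

`MDSFRModel.fit()` runs trust-region least squares on relative residuals
over `(a, b, psb_1..psb_n)` — 2n data points, n+2 parameters; a single
diameter is rejected as underdetermined.  The Jacobian sparsity (each psb
touches two residuals) is declared to the optimizer; psb starting values
come from inverting the semiballistic ratio on the larger-diameter
spectrum; psb is positivity-bounded with no smoothness prior (none is
claimed by the model; a penalty can be added by the user post hoc).
The objective has a nearly flat ridge: because each
wavelength's psb can re-adjust, sizeable shifts in `a` can be compensated
to sub-0.1% misfit, so a coarse profile grid search over (a, b) picks the
starting basin and up to six distinct starts are polished, keeping the best
(multi-start is skipped when an explicit initial guess is given).  The same
ridge bounds identifiability: at 2% measurement noise the fitted `a`
carries a ~5% standard error even though the noiseless round trip is exact
to optimizer tolerance.  Recovered psb has ~10% median error at that noise
level.

What the synthetic phantom does *not* emulate: absorption features,
instrument response, wavelength-dependent phase-function shape, and inter-
fiber calibration errors.  Passing round-trip tests therefore demonstrates
the inversion machinery, not field performance on real spectra.

## Problem sizes and tolerances in the test suite

Scaled for a single CPU: the subdiffuse ensemble fixture runs 10 stratified
models × 2e5 photons (μs′d = 0.1); the μs′d-series fixture 8 models ×
{0.1, 1, 5, 9} × 4e4 photons; the diffusion-limit check one run at
μs′d = 100 × 3e4 photons (asserted within 3 standard errors); the MC
phantom spectra 5 wavelengths × 2 diameters × 2.5e5 photons.  Stochastic
assertions use tolerances derived from the binomial standard errors at
these budgets.  The acceptance script's Monte Carlo uses 10 models × 4e5
photons, which puts ≳10³ detected photons behind the reported semiballistic
fraction.

## Known limitations

* No absorption; no layered media; no polarization or time resolution.
* Calibration constants exist for NAs 0.10/0.22/0.50 only and are never
  interpolated; other apertures require user-supplied constants.
* The `X(psb)` power law degrades for extreme narrow-backward-lobe phase
  functions (above).
* The model is documented as unreliable for `μs′d < 0.1`; predictions there
  carry a flag and a warning rather than an exception.
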