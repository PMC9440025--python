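# Methods

This note documents the models behind `oholidar`: the forward simulator and
its assumptions, the retrieval and correction algorithms, the synthetic-scene
generator, the numerical choices, and the known limitations.  Everything here
is implemented and exercised by the test suite; no number below is asserted
that the code does not itself compute.

## Water-column model

A column is described by depth profiles of absorption `a(z)`, total
scattering `b(z)` and total backscattering `b_b(z)` at 532 nm on a uniform
grid (default spacing 0.28 m, the in-water range bin of a 400 MHz digitiser,
`c/(2·n·f_s)` with n = 1.33).  Depth is zero at the identified water surface
and positive downward.  Pure-seawater constants default to conventional
literature values and are exposed in `SeawaterConstants`:

| constant | default | units | meaning |
|---|---|---|---|
| `n` | 1.34 | — | seawater refractive index (Snell refraction, range factor) |
| `K_dw` | 0.0452 | m⁻¹ | diffuse attenuation of pure seawater |
| `beta_B_pi` | 2.0·10⁻⁴ | m⁻¹ sr⁻¹ | Brillouin 180° volume scattering function |
| `chi` | 1.0 | — | `b_bp = 2π·χ·β_p^π` conversion factor |
| `b_bw` | 9.0·10⁻⁴ | m⁻¹ | pure-seawater backscattering (b_bp → b_b) |

The reference ("truth") diffuse attenuation of a column is the empirical
relation of Lee et al., `K_d = a + 4.18·b_b·(1 − 0.52·e^(−10.8·a))`, which is
also the relation embedded in the multiple-scattering correction.  It is
monotone in both arguments and reduces to `a` when `b_b = 0`.

The particulate phase function is Fournier–Forand, indexed by its
backscatter fraction `B = b_bp/b_p` (default 0.02, a typical coastal value)
with the two FF parameters collapsed onto the standard hinge line
`n_p = 1.01 + 0.1542(μ − 3)`.  The tabulated cumulative distribution (log-
spaced angle grid down to 1 µrad) is shared by the analytic model and the
Monte-Carlo oracle, so their comparison isolates the transport
approximation, not the phase function.  Only the simulator consumes the
phase function; retrievals never do.

## Forward model (quasi-single small-angle approximation)

Geometry: platform height `H` (default 5 m), incidence `θ_i` (60° underway,
40° at a fixed station), full receiver FOV 0.2 rad, refraction angle `θ_r`
from Snell's law.  The range factor is `G(z) = nH/cosθ_i + z/cosθ_r`, the
in-water slant path `s = z/cosθ_r`, and the receiver footprint radius at
depth z is `ρ(z) = G(z)·fov/2`.  The air–sea interface is refraction only;
Fresnel transmission is a constant factor that cancels in every retrieval.

Transport assumptions: photons travel along the refracted axis; absorption
(rate `a`) and backscattering (rate `b_b`) remove them; forward scattering
(rate `b_f = b − b_b`) deflects them by an angle drawn from the FF forward
lobe (0–90°, renormalised).  A photon still contributes to the return from
depth z if its accumulated lateral displacement is inside `ρ(z)`.  Treating
each kick's own displacement independently (the quasi-single assumption),
the one-way FOV-limited transmission is

    T(z) = exp(−[(a + b_b)·s + ∫₀ˢ b_f(s′)·(1 − P_fwd(ρ(z)/(s − s′))) ds′])

with `P_fwd` the forward-lobe cumulative distribution, and, with a flat
molecular backward phase function and up/down reciprocity,

    B_M(z) = β_B^π · G(z)⁻² · T(z)².

Limiting behaviour (all enforced by tests): at `fov → 0` every kick is lost
and the slope of the range-corrected signal is the beam attenuation
`c = a + b`; at the surface every kick is retained and the effective
attenuation is `a + b_b`; in between `k_lidar` grows monotonically with
depth and stays inside `[a + b_b, c]` — small near the surface and
increasing with depth, the pattern the correction is built around.

The combined channel adds the particulate 180° return, which in this
approximation shares the molecular two-way transmission:
`B_C = (gain/T_B)·B_M·(1 + β_p^π/β_B^π)` with
`β_p^π = (b_b − b_bw)/(2πχ)`, so the channel-ratio inversion is exact on
noiseless scenes by construction (round-trip contract).  `T_B` is the
Brillouin transmittance of the iodine-cell channel; the particulate and
Rayleigh leakages `T_p`, `T_R` are accepted in the calibration object but
assumed negligible by the simplified inversion (a warning fires if
`T_p/T_B > 0.05`).

### Monte-Carlo oracle

`mc_oracle` simulates the same microphysical world without the quasi-single
shortcut: forward-scattering events are placed by an inhomogeneous Poisson
process with rate `b_f(s)`, kick angles are drawn from the same tabulated FF
forward lobe with uniform azimuth, and the exact accumulated lateral
displacement is tracked at every depth bin.  Absorption and backscatter
losses are applied analytically (a semianalytic, per-photon-weight variance
reduction), the FOV cut is the footprint indicator, and reciprocity squares
the estimated one-way transmission, as in the analytic model.  A
standard-error profile accompanies the estimate (it scales as expected with
the photon budget).  With 10⁵ photons the analytic and MC signals agree to
~1–2 % RMSRD over the first three optical depths across the tested IOP
range; the residual is the quasi-single neglect of kick accumulation and
footprint re-entry, which partially cancel.

## Preprocessing

Raw shot blocks pass through: (1) foam rejection — shots whose near-surface
integral has a modified z-score above 5 (median/MAD, with a mean-absolute-
deviation fallback when the MAD degenerates) are dropped; (2) surface
identification — global maximum of the boxcar-smoothed trace, refined to the
raw-trace argmax within the smoothing window, and the depth grid re-zeroed
there; (3) background subtraction — median of the deepest 10 % of bins
(requires a background-dominated tail, so it is skipped for noiseless
synthetic scenes); (4) a 0–3 m surface cut (bubbles, spray); and (5) a
dynamic-range cut masking bins more than D decades (default 3, configurable
3–3.5) below the sub-surface maximum, together with everything deeper.  The
chain is idempotent within the shot-noise floor.

## Retrievals

* `retrieve_beta_p_pi` / `retrieve_bbp` — the channel-ratio inversion above;
  negative values (clear water and noise) are clipped to zero and flagged;
  bins with non-positive molecular signal are masked, never raised.
* `retrieve_klidar` — sliding-window least-squares slope of
  `ln[B_M·G²]` against the slant path; window 11 bins (~3 m at 0.28 m
  sampling) as a noise/resolution compromise, one-sided at the profile ends.
  Invariant to any positive rescaling of the signal.
* `lidar_ratio` — `(K_d − K_dw)/β_p^π`, masked below a 10⁻⁷ m⁻¹ sr⁻¹
  backscatter floor.

## Multiple-scattering correction

Trained per geometry on homogeneous columns (default grid
a ∈ {0.05, 0.1, 0.2, 0.35, 0.5} m⁻¹ × b_b ∈ {0.001, 0.002, 0.004, 0.007,
0.01} m⁻¹, spanning coastal-to-open-water product ranges; b = b_b/0.02).
Each condition is simulated, `k_lidar` derived, and
`k = m₁e^(−m₂z) + m₃ + a` fitted with `a` held at its known value.  Because
the simulated attenuation *increases* with depth toward a plateau, the
amplitude `m₁` is negative; it is therefore left unbounded in the fit
(`m₂ > 0`, `m₃ ≥ 0`), initialised at `k(0) − k(z_max)`, with fallback starts
before declaring non-convergence.  A per-condition fit RMSRD above 10 %
aborts training with diagnostics.

Each m-parameter is then regressed on `b_b` over a small candidate family
{power law, linear, quadratic}, selected by R².  In this simulator the
multiple-scattering excess is exactly proportional to `b_f` at fixed
geometry, so `m₁` and `m₃` come out essentially linear in `b_b` and `m₂`
nearly constant; real water (and richer transport) would bend these, which
is why the family selection and the training grid are configurable.  The
trained model carries a geometry tag and refuses application to another
geometry unless forced (models trained at 40° and 60° differ measurably).

Application evaluates the m-parameters at the *local* `b_b(z)`
(`b_b = b_bp + b_bw` from the HSRL product) — a deliberate extrapolation of
homogeneous training to stratified columns, switchable to a scalar.  Bins
where the absorption-like residual `A(z)` goes negative are masked and
flagged.  Self-validation on a held-out grid of intermediate IOPs gives
pooled modelled-vs-simulated `k_lidar` RMSRD well under 1 % and R² > 0.999
(`scripts/acceptance.py` recomputes both).

## Elastic baselines

* Slope: least-squares log-slope, homogeneous assumption, ≥ 10 bins.
* Fernald: canonical two-component backward solution with molecular
  component (`β_B^π`, `K_dw`) and an assumed particulate lidar ratio;
  boundary at the deepest valid bin with a clear-water
  `b_bp = 10⁻⁴ m⁻¹` unless configured.  On single-scattering scenes with
  matched ratio and exact boundary it inverts to ≤ 1 %.  Its attenuation
  responds monotonically to the assumed ratio; the *direction* of that bias
  depends on the boundary value relative to the true water, so only
  monotonicity is asserted.
* Perturbation: constant attenuation from the slope (its only K_d output,
  by construction), first-order backscatter perturbation around the column
  mean, converted to `β_p^π` via a Case-1-style closure
  `K − K_dw = R_case1·β_p^π` with `R_case1 = 100 sr` (configurable — the
  closure constant is a convention, not a truth).

## Synthetic scenes and what they do not show

`generate_scene` produces time–depth curtains: homogeneous columns, Gaussian
thin layers (defaults ~1 m σ, Δb_b ≈ 0.003 m⁻¹ at layer centre), and a
"diel" template whose layer centres follow a per-column schedule (deepening,
shoaling and merging layers, emulating a day at a fixed station).  IOP
defaults sit mid-range of coastal products (a = 0.08 m⁻¹, b_b = 0.004 m⁻¹,
K_d ≈ 0.09 m⁻¹); noise is an additive depth-independent background (day vs
night is only its level) plus Poisson shot noise on scaled counts (default
10¹² counts per signal unit, giving realistic three-decade dynamic range),
all seeded.  Truth products come from the generating IOPs, with `K_d` *by
definition* the Lee relation of (a, b_b).

Consequences for interpretation: passing tests demonstrate internal
consistency of the retrieval chain and the correction under this transport
model — they do not validate the QSSA against real ocean radiative transfer,
real phase functions, sea-surface waves, depolarisation, fluorescence or
detector artefacts (PMT tailing is only handled by the dynamic-range cut).
Because the truth `K_d` is the same empirical relation the MSC embeds, the
end-to-end `K_d` checks test the removal of the multiple-scattering excess,
not the Lee relation itself.

## Numerical choices

* FF cumulative tabulated on 1500 angles (log-spaced below 0.1 rad); the
  numerical normalisation lands within 0.05 % of unity and is renormalised.
* QSSA path integrals: trapezoid on the signal grid; the O(N²) loss matrix
  is vectorised (N ≈ 90 bins for a 25 m column).
* MC oracle: photons in batches of 4000, events padded to the batch maximum;
  10⁵ photons on one CPU take a few seconds per condition.
* Curve fits use `scipy.optimize.curve_fit`; m-regression covariance
  warnings on degenerate (near-constant) parameters are suppressed — only
  point estimates are used.
* Metrics: RMSRD excludes zero-reference bins (warning); R² against a
  numerically constant reference is reported as 1 (exact match) or NaN
  (undefined), and the comparison report stores NaN as null.
* Comparison reports pool bins across profiles before computing metrics
  (rather than averaging per-profile values); the convention is recorded in
  the report itself.

## Known limitations

* Single wavelength (532 nm); no temperature/salinity dependence of `n`.
* The simplified HSRL inversion ignores `T_p`/`T_R` cross-talk.
* No polarisation, Raman or fluorescence channels; no wave-slope statistics
  at the interface; no motion compensation (timestamps/coordinates are
  carried through as attributes only).
* The MSC corrects the attenuation product only; the combined-channel
  backscatter is left uncorrected.
* Stratified columns are handled by local evaluation of homogeneously
  trained m-parameters — adequate for the gentle layers generated here,
  unvalidated for strong gradients.
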