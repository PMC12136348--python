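# Methods

## Model

All signals live on a square retinocentric grid of cell centers spanning
±`half_extent` dva with spacing `step`; x is rightward, y upward, the fovea
at the origin. Two geometries are built in: the publication-scale field
(±48 dva, 0.05 dva; ~1921² cells) and the default working grid
(±24 dva, 0.25 dva; 193² cells). Results depend on the grid only through
discretization and boundary truncation (below), and every fitted or
simulated result records the grid it used.

The input response to a target is an isotropic Gaussian normalized to unit
mass over the grid, with width one third of target eccentricity
(σ = |P|/3); the post-saccadic input additionally enforces σ ≥ 0.5 dva so
that near-foveal targets keep a well-defined response. Readouts are
population vectors without mass normalization, V = Σ r(p)·p. This literal
sum is the load-bearing choice: multiplicative gain fields change response
mass and thereby readout length, which is how flat gain constants produce
the pre-adaptation undershoot and how local gain changes produce
adaptation.

Spatial updating (prediction and postdiction) is a uniform coordinate shift
of a map by ±CDV, implemented by bilinear interpolation with zero fill
outside the field. Bilinear weights reproduce linear functions exactly, so
a shift changes the population vector by exactly mass·shift for maps away
from the boundary; the only interpolation effect on readouts is boundary
truncation. The shift scheme is an implementation choice — any
interpolation that preserves low-order moments would behave identically.

### Learning

The postdictive motor error E = V̂₁ − M is converted to a signed amplitude
error δE: magnitude |E|, sign taken from the horizontal error component
relative to the target hemifield (vertical component for targets on the
vertical meridian), negative for inward errors. If the sign-determining
product is exactly zero while |E| > 0, δE is defined as 0 — the unique
choice continuous at E = 0.

The learning distributions α_x are piecewise Gaussians evaluated
analytically in coordinates rotated to the target direction (amplitude axis
u toward the target, orthogonal axis w), with foveal width σ_F for u < 0,
peripheral width σ_P for u ≥ 0, orthogonal width σ_O, and **peak value
φ_x at the target**. The peak-rate convention makes the dynamics
independent of grid resolution — each position carries a per-position
learning rate rather than a share of a fixed total — and matches the
interpretation of φ as "the highest peak rate … at the adaptation target
location". Foveal widths are constrained to σ_F ≤ |P₁|/3 (learning may not
extend past the fovea); violations raise at construction rather than being
clipped, so fitted bounds stay explicit. Analytic rotation makes the
construction exactly rotation-equivariant up to grid sampling.

Gain fields update additively, ω ← ω + α·δE, once per trial with the
same-trial error; the gain fields are the only trial-to-trial state. A
consequence of the model's geometry is that realistic adaptation magnitudes
drive the motor gain at the target through zero: the learning dip is much
narrower than the σ = |P₁|/3 population response, so moving the
mass-weighted readout by ~2 dva requires a dip of order 1. The dynamics
remain well-defined (readouts are polynomials in the gains), but because a
non-positive rate map loses its physiological reading, the event is flagged
with a `NegativeGainWarning` (optionally an error), never silently passed.

The adaptation drop κ ∈ [0, 1] moves every gain cell back toward its
pre-adaptation value, ω_post = ω_end + κ(ω_pre − ω_end), modeling the decay
between the end of the adaptation block and the post-adaptation
measurement. Because readouts are quadratic/cubic in the cumulative error,
the induced adaptation-field scaling is only approximately linear in κ; at
50 trials the deviation from proportional scaling is < 0.05 dva, growing
with accumulated learning.

## Fast simulation path

Since updates are additive with fixed rate maps, every gain field remains
of the form ω_x = ω_xC + α_x·S with the single scalar state
S(n) = Σ_{k<n} δE(k). Pre-saccadic readouts are then polynomials in S of
degree ≤ 3 whose coefficients are grid moments of the probe response
against products of the rate maps, computed once per parameter vector; the
shift readouts use the exact identities V̂₂ = V₁ − m₁·CDV and
V̂₁ = V₂ + m₂·CDV. The fitter uses this path (~16 ms per 200-trial
protocol on the working grid); the test suite verifies it against the
reference grid engine to 1e-9 on every objective channel, with the only
documented difference (boundary truncation of the interpolated forward
shift) confined to V̂₂, which the objective does not use. Parameter vectors
in unstable regions (runaway positive feedback pushing the post-saccadic
target off the field) raise a divergence error that the fitter scores as a
failed start.

## Synthetic behavioral data

The generator emulates the reference protocol: pre- and post-adaptation
phases with 5 repetitions per probe of pre-saccadic localization trials
(response ~ V1), post-saccadic localization trials (primary saccade ~ M,
localization re fixation constructed as V2f = V1 − CDV + M so that the
behavioral identity CDV = V1 − V2f + M inverts the construction exactly),
plain saccade trials at the adaptation target, and 200 adaptation-phase
saccade trials following the simulated time course. All responses receive
iid Gaussian noise; the default SDs (saccade 0.5 dva, localizations
1.0 dva) are free choices at the scale of typical saccadic endpoint scatter
and mouse localization of a brief flash, since no measured values exist for
them. Latencies and fixation deviations are drawn inside the acceptance
windows except for a configurable fraction of injected violations that
exercise the offline filters (latency 100–400 ms, landing within ±5 dva per
axis of the trial's target, fixation held within ±2 dva, post-saccadic
localizations dropped without a valid primary saccade).

What passing tests on these data do show: the estimator inverts the model's
own forward map — filters, medians, CDV derivation, counts, weights and the
two-stage optimization are internally consistent, and the objective's
optimum sits at the generating parameters. What they do not show: anything
about model misspecification on real eyes. The generator has no corrective
saccades, no latency- or fatigue-dependent structure, no spatially
correlated localization biases, and a single synthetic observer; medians
and filters are therefore much sharper here than on real sessions.

## Fitting

Per-probe medians are taken per session and averaged across sessions (the
even-count median uses the midpoint convention); in the pre/post phases the
per-probe saccade vectors come from the post-saccadic localization trials,
whose primary saccades target the probes (plain saccade trials always go to
the adaptation target). The fitting surfaces are: V1 ↔ pre-saccadic
localizations, M ↔ saccade vectors, and the post-saccadic localization
channel entered as the behaviorally derived CDV (V1 − V2f + M) compared
against the model's CDV readout. The CDV-space comparison is an exact
linear recombination of the same medians; it is preferred over comparing
raw localizations re saccade landing against the prediction-map readout
because the latter carries the visual response mass m₁ as a factor
(V̂₂ = V₁ − m₁·CDV), which conflates localization shifts with response-mass
changes and, with self-generated data, would displace the objective's
optimum away from the generating parameters.

The objective is the balanced weighted SSE with
η_pre,post = ((q_adapt+q_pre,post)/q_pre,post)·0.6 and
η_adapt = ((q_adapt+q_pre,post)/q_adapt)·0.4, where the q's count scalar
residuals (2 coordinates per entry; the reference design gives
q_pre,post = 132 and q_adapt = 400, hence weights 2.42 and 0.53). Missing
cells are excluded from residuals and counts alike. Residual standard
errors are √(SSE/(q−1)) per surface.

Estimation is two-stage, with motor noise fixed at zero:

1. **Gain constants.** At the pre-adaptation state the model is linear in
   the per-probe readout scale, so ω_vC, ω_mC·ω_vC and their CDV product
   are closed-form least-squares scales of the pre-phase data on the
   numerically computed unit-gain readouts, followed by a Nelder–Mead
   polish of the pre-phase SSE.
2. **Learning parameters and κ.** The twelve distribution parameters plus κ
   are estimated by bound-constrained trust-region least squares (TRF) on
   the √η-scaled residual vector, from 8 starting points (one heuristic
   mid-scale start plus seeded Latin-hypercube draws over the box); the
   lowest weighted SSE wins. Bounds: |φ| ≤ 0.05, σ ∈ [0.1, 10] dva subject
   to the foveal constraint, κ ∈ [0, 1], constants ∈ [0.5, 1.5]. On
   noiseless self-generated data the estimator reproduces the generating
   parameters to machine precision; with several starts the multi-start
   spread (recorded in the diagnostics) exposes local minima, which do
   occur for short adaptation blocks or very coarse grids.

## Numerical choices and limitations

- **Grid truncation.** On the ±24 dva working grid, responses centered
  beyond ~13 dva eccentricity (σ > 4.3) lose tail mass at the field edge,
  biasing their readouts inward — up to ~1.3 dva for the outermost
  (17.2 dva) probes. Closed-form readout identities are therefore asserted
  only where the support retains ≳3σ of margin; the ±48 dva field removes
  the effect.
- **Post-saccadic evaluation window.** The fast path evaluates the
  post-saccadic response on a subwindow of ±8σ around its center
  (truncation ~1e-14 of mass).
- **Degenerate inputs.** A foveal target has no defined amplitude axis or
  response width: the pre-saccadic response and the learning distributions
  reject it; the post-saccadic response relies on the 0.5 dva floor and
  needs no special-casing.
- The model adapts amplitude only; direction-step adaptation, corrective
  saccades, retention/forgetting beyond the single κ, and head- or
  world-centered frames are out of scope. Multiple designs can share gain
  state (sequential blocks) through the experiment runner's
  `initial_gains`/returned-gains interface.
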