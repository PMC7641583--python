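# Methods

`morphosense` computes fundamental limits to the precision with which target
cells can read a morphogen gradient, for two canonical gradient-formation
mechanisms, and the comparison statistic that predicts which mechanism is more
precise at a given profile lengthscale.  This note records the models, the
numerical choices, and what the synthetic-data oracles do and do not show.

## Geometry and the readout quantity

A single source cell sits at `x = 0`; `N` target cells of radius `a` extend on
each side, cell `j` occupying `[2ja - a, 2ja + a]`.  Each cell integrates its
molecule count over a time `T`, and the readout precision at cell `j` is

    P_j^2 = (m_j T / 2 tau) (Delta m_j / m_j)^2,

with `m_j` the stationary mean count, `Delta m_j = m_j - m_{j+1}` the
adjacent-cell difference (the positional signal), and `tau` the correlation
time of the count, so that `T / tau` counts effectively independent
measurements.  The formula assumes `T >> tau`; constructors warn when
`T nu < 10`.  `P_j^2` is defined for `j = 1..N-1` (the outermost cell has no
neighbour below it); a zero mean yields `P_j^2 = 0` with a warning.

## Direct transport (DT)

Molecules are produced at rate `beta`, enter cytonemes, and run
forward/backward (velocities `v±`, switching rates `zeta±`) until absorbed by
the target (far end) or returned to the source (near end); inside targets they
degrade at `nu`.  Only the mean run lengths `d± = v±/zeta±` survive in the
steady state, through `phi = log(d-/d+)` and `kappa = 1/d+ - 1/d-`:

    Gamma_j = e^{-2 j kappa a} (1 - e^{-phi}) / (1 - e^{-phi - 2 j kappa a}),
    m_j = beta Gamma_j / (2 nu sum_k Gamma_k).

`Gamma_j` is evaluated in the log domain (`log1p`/`expm1` forms), so any
`|phi|` and any `j kappa a` are safe.  `phi << -1` gives a flat profile,
`phi >> 1` a pure exponential, `|phi| << 1` a power law.

Because molecules can leave a target only by degradation and act
independently, the arrival process into cell `j` is Poisson with rate
`beta pi_j` regardless of the transport-delay distribution, making the count a
birth-death process: `tau_DT = 1/nu` and `sigma_j^2 = 2 m_j / (T/tau)`.  The
generalized-DT oracle verifies this delay-law irrelevance directly with
deterministic, exponential, and telegraph-first-passage delays.

**Lengthscale.**  The profile lengthscale in units of `a` is the product form

    lambda_hat = (e^{|phi|} - 1)(|phi| - log(e^{|phi|} - 1)) / |kappa a|,

which we verified equals `2 * int_0^N Gamma(j) dj / (Gamma(0) - Gamma(N))` to
machine precision (the factor 2 converts index units to units of `a`, cells
being `2a` apart).  The literal integer sum
`2 (sum_{j=1..N} Gamma_j - Gamma_N)/(Gamma_1 - Gamma_N)` is also exposed
(`lengthscale_dt_discrete`); it is biased upward by `O(1/lambda_hat)` — about
+20% at `lambda_hat = 5`, +2% at 50 for steep shapes — because an integer sum
cannot see the decay inside the first cell.  All internal inversions
(`solve_kappa`) use the product form; `|phi| - log(e^{|phi|}-1)` is computed as
`-log(1 - e^{-|phi|})` to avoid catastrophic cancellation at large `|phi|`.

**Power-law branch.**  Below `|phi| < 1e-3` the exponential parametrisation
degenerates; the profile is represented as `Gamma_j = (1 + 2 j a/d+)^{-1}`
with `d+/a` solved (bisection to 1e-8) so the quadrature lengthscale over
`[0, N]` equals the requested `lambda_hat`.  This branch is necessarily
`N`-dependent (a pure power law has no intrinsic lengthscale; the observation
window provides the cutoff), and it is *not* numerically identical to the
closed form just above the threshold at large `j`, where the closed form's
exponential cutoff differs from the `N`-cutoff.  The threshold is a
parametrisation boundary, not a physical statement.

**Shape optimum.**  `optimize_phi` scans 400 log-spaced points on
`[1e-3, 30]` and refines interior maxima by golden section (ties toward
smaller `phi`).  For the centre cell of `N = 100` the maximum is interior for
`lambda_hat <~ 30`; beyond that `P^2(phi)` saturates monotonically toward the
pure-exponential-profile limit (verified out to `phi = 700`), so the
window-boundary argmax is returned with a warning — the saturated value is
correct to ~1e-10 for ratio purposes.  The window and grid density are
package choices; doubling the grid moves `phi*` by < 1%.

## Synthesis-diffusion-clearance (SDC)

Production at rate `beta` at `x = 0`, free diffusion with coefficient `D`,
uniform degradation `nu`; `lambda = sqrt(D/nu)`.  The steady concentration is
`c(x) = beta e^{-|x|/lambda} / (2 nu lambda)` and a permeable cell counts the
molecules in its volume, giving

    m_j = (beta/nu) sinh(1/lambda_hat) e^{-2j/lambda_hat}

(evaluated in log space; short profiles never overflow `sinh`).  The Langevin
noise terms (diffusion `2D grad grad' c delta`, degradation `nu c delta`,
production `beta delta`) are linear with Poissonian statistics, so molecules
are statistically independent and the count autocovariance factorises as

    C(t) = m e^{-nu t} K(t),

where `K(t)` is the probability that a molecule drawn from the steady profile
inside the cell is inside it again at time `t` under free diffusion.  The
time-averaged variance is the zero-frequency spectrum per unit window,
`sigma^2 = S_m(0)/T = 2 m tau / T` with `tau = int_0^inf C(t)/C(0) dt`.
Carrying out the integral in 1D reproduces exactly the closed form

    tau_SDC = (1/nu) [1 - ((2/lh) + sinh(2/lh)) / (4 sinh(1/lh) e^{1/lh})]

(`bracket_factor`; agreement to 1e-6 over `lambda_hat` in 0.5..10, checked in
the test suite).  The bracket is always below one — diffusion refreshes the
cell's molecules faster than degradation alone — decreasing in `lambda_hat`,
with limits `3/4` as `lambda_hat -> 0` and `1/lambda_hat` as
`lambda_hat -> inf`.  The small-`lambda_hat` limit 3/4 is a prediction of this
reconstruction; the lattice oracle confirms it (the `lambda_hat = 0.5` case of
the acceptance suite).  The fast-diffusion limit matches the hopping model's
`(4 nu h)^{-1/2}` with `h = D/(2a)^2` within 2% for `lambda_hat >= 50`.

The bracket is evaluated through `e^{-2/lambda_hat}` so neither limit
overflows.  Receptor kinetics are not modelled (volume counting is equivalent
up to an order-unity factor); the `one_sided` flag doubles the mean for
Bicoid-like one-sided geometries but its slightly-greater-than-2 variance
correction is deliberately not implemented.

**2D/3D.**  For a line of source cells feeding a sheet (2D) or a sheet
feeding a volume (3D), each source cell supplies its own perpendicular column,
so the perpendicular mean profile is unchanged; only `tau` shrinks, because
molecules also refresh by transverse diffusion:

    tau_d = int_0^inf e^{-nu t} K_perp(t) K_tr(t)^{d-1} dt,

with `K_perp` the profile-weighted survival kernel of the cell's perpendicular
extent (48-point Gauss-Legendre in space, adaptive quadrature in time,
relative tolerance 1e-9 with convergence check) and `K_tr` the closed-form
uniform-interval kernel of the transverse half-width (default `a`).  This
propagator route is mathematically identical to the low-frequency
power-spectrum quadrature of the Langevin system and avoids the
non-wavevector-diagonal integrals caused by the nonuniform profile.  As the
transverse half-width grows, `K_tr -> 1` and the 1D closed form is recovered
(the dimensional-reduction check); a vanishing transverse cell instead
decorrelates instantly and does not reduce to 1D.  A 2D lattice simulation
confirms `sigma^2 = 2 m tau_2 / T` within statistical error.

## Hopping model

Replacing diffusion by hopping at rate `h` to each neighbour gives
`C_j(t) = m_j I0(2ht) e^{-(2h+nu)t}` (the exact return probability of an
unbiased continuous-time walk times survival) and
`tau = [nu(4h+nu)]^{-1/2}`.  Evaluated via the exponentially scaled Bessel
function; valid on an effectively infinite chain, which the simulation oracle
enforces by requiring at least `25 max(1, sqrt(h/nu))` cells per side.

## Comparison and classification

`rho_j = P^2_DT(phi*(j, lambda_hat)) / P^2_SDC` with `beta`, `T`, `nu`
equated (they cancel; invariance is tested on the underlying models).  Short
profiles favour DT (larger amplitude: a power-law `1/j` tail beats an
exponential), long profiles favour SDC (faster refresh); for a power-law DT
shape the product (amplitude ratio) x (steepness ratio)^2 scales as
`e^{2j/lambda_hat} / j^3`, which the suite verifies up to a j-independent
constant.  `fraction_sdc_better` counts cells with `rho_j <= 1` over
`j = 1..N-1` (ties assigned to SDC; the edge cell is excluded since it has no
`Delta m`).  `lambda50(N)` is the smallest lengthscale at which at least half
the cells favour SDC, found by bracketing on a log grid over `[0.1, 1000]`
and log-bisection to relative tolerance 1e-3; the smallest crossing is used
should the fraction ever be non-monotone (it is monotone on all tested
grids).  For `N = 100` cells per side, `lambda50 ≈ 10.7` cell radii.

Classification annotates each morphogen record (`lambda_um`, `a_um`, `N`,
evidence class) with `lambda_hat / lambda50(N)` and predicts SDC when more
than half of its cells favour SDC.  The shipped example table
(`examples/morphogens_synthetic.csv`) contains synthetic placeholder values
flagged `unverified`; the classifier propagates that flag and the CLI warns
that concordance with experimental evidence is only meaningful once measured
values are supplied.  1D is the default geometry for classification; 2D/3D
shift `rho` but preserve the crossover.

## Stochastic oracles: what they emulate

All simulators are exact (direct-method Gillespie or exact independent-
molecule sampling — no tau-leaping), seeded, and reproducible bit for bit.
They emulate the models' own idealisations: point production, memoryless
degradation, non-interacting molecules, static cytonemes.  Passing tests
therefore validate the formulas *under the models' assumptions*; they say
nothing about crowded-medium subdiffusion, cytoneme growth/retraction,
receptor kinetics, or regulated degradation in real tissues.

* Birth-death and arrival-counting use a molecule-list Gillespie kernel
  (O(1) per event).  The arrival/concentration comparison reports a
  leave-one-replicate-out jackknife standard error.
* The SDC lattice splits each cell of width `2a` into subcells (hop rate
  `D/width^2`), injects production at the two central source subcells
  (alternating keeps an even split symmetric), and requires reflecting
  boundaries at least `5 lambda` beyond any probed cell.  Eight subcells per
  cell suffice except at `lambda_hat = 0.5`, where the subcell width is half
  the profile lengthscale and sixteen are used to keep discretisation bias
  below the statistical resolution.
* The cytoneme integrator is a finite-volume scheme (minmod-limited MUSCL
  fluxes, Heun stepping, CFL 0.4) marched until the per-unit-time relative
  change drops below 1e-10; at 400 cells per cytoneme it matches the closed
  form to ~1e-5 and halving the grid changes means by < 0.1%.
* Simulation sizes in the test suite (windows of 50-10^4 time units, 24-1600
  replicate windows, chains of ~100 cells) were chosen so that 3-standard-
  error comparisons resolve the predicted effects on a single CPU.

## Known limitations

* The power-law branch is `N`-dependent and discontinuous (in profile shape,
  not in the exposed lengthscale) against the closed form at the `1e-3`
  threshold for cells near the exponential cutoff.
* `lambda50` assumes the fraction crosses 0.5 within `[0.1, 1000]` cell
  radii; systems outside that range raise with the fraction profile attached.
* The 2D/3D extension fixes cubic cells and a transverse half-width equal to
  `a`; other cell aspect ratios are available through the
  `transverse_half_width` argument but untested against simulation.
* One-sided (Bicoid-like) geometry corrects the mean only, not the variance.
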