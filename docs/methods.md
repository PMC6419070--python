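# Methods

`wlctube` models a semiflexible (wormlike) polymer chain that is confined
in a rectangular nanochannel or slit and simultaneously stretched along
the channel axis.  This note records the models, the numerical choices,
and the reasoning behind the defaults, in enough detail to re-derive or
challenge any of them.

## The deflection picture and the modified deflection length

A wormlike chain with persistence length `Lp` inside a channel whose
sides `Hh, Hw` are well below `Lp` cannot form hairpins; it propagates
along the axis, bouncing off the walls every deflection length
`λ ~ Lp^(1/3) H^(2/3)`.  The chain then behaves as `L/λ` nearly
independent segments, which fixes the confinement free energy
`F ≈ kBT L/λ` and the mean axial extension `R∥`.

Two classical calibrations of `λ` coexist and disagree: the free-energy
form

    λ_fe = (1/A) Lp^(1/3) (Hh^{-2/3} + Hw^{-2/3})^{-1},      A = 1.1032,

and the extension form

    λ_ext = 2α Lp^(1/3) (Hh^{2/3} + Hw^{2/3}),               α = 0.09143.

Their prefactors differ by an order of magnitude, and `λ_ext` diverges in
the slit limit `Hw → ∞` instead of approaching the slit scaling law.
The package's central object is the modified deflection length

    λ_m/Lp = -(1/θ) ln[1 - (θ/A)(Ĥh^{-2/3} + Ĥw^{-2/3})^{-1}],
    θ = 8 A α ≈ 0.80692,   Ĥ = H/Lp,

obtained by requiring a single `λ` to satisfy the free-energy relation,
the known extension statistics of a free wormlike segment, and the
rectangular-channel free-energy law simultaneously.  It reduces to
`λ_fe` as the channel narrows (Taylor expansion of the logarithm) and
remains finite and slit-consistent for wide channels.  Derived closed
forms implemented in `theory`:

* free energy `F/kBT = L/λ_m` (exact identity by construction; the
  classical `L/λ_fe` is always an upper bound because `-ln(1-x) ≥ x`);
* zero-force extension deficit `1 - R∥/L = 1 - ε/(-ln(1-ε))` with
  `ε = (θ/A)(Ĥh^{-2/3}+Ĥw^{-2/3})^{-1}`;
* force–confinement–extension relation

      1 - R∥/L = ½ [ f̂ + f̂_c ]^{-1/2},   f̂_c = {-ln(1-ε)}^{-2},

  where `f̂ = fs Lp/kBT` is the reduced tension.  Confinement acts as an
  additive effective tension `f̂_c`.

The effective force is implemented exactly in this printed form, i.e.
`f̂_c = (Lp/(θ λ_m))²` and *not* `(Lp/λ_m)²`: only the former reduces to
the zero-force deficit above at `f̂ = 0`.  The classical comparison
curves use `f̂_c = Lp²/λ²` with `λ_fe` or `λ_ext`, which is how those
lengths are conventionally inserted into the additive relation.

Validity.  The logarithm exists only while
`Ĥh^{-2/3} + Ĥw^{-2/3} > θ/A`; beyond that the deflection picture has no
meaning and every modified-theory function raises a typed
`ValidityError` rather than returning NaN.  `validity_check` reports the
margin.

The aspect-ratio factor `φ(β) = ¼(β^{1/3}+β^{-1/3})²`, `β = Hh/Hw`,
measures how far the classical zero-force deficit exceeds the modified
one for non-square rectangles; it is 1 exactly at `β = 1` and diverges
for ribbon-like cross-sections.

Slits are represented as very wide rectangles (`Ĥw = 1000` by default),
matching how the simulations treat them; a true `Hw = ∞` is never used.
The classical extension form is meaningful only for tubes, and a slit
*without tension* has no preferred axis in the slit plane at all — the
chain performs a two-dimensional random walk and `R∥/L` is not close
to 1 regardless of theory.  Slit extension comparisons therefore always
carry a finite tension.

## Fokker–Planck ground state (free-energy verification)

The orientation-resolved propagator `q(r, u, s)` of a wormlike chain in
a hard-wall slit obeys a contour-evolution equation combining transport
`-u·∇r`, rotational diffusion `(1/2Lp)∇u²`, and the wall potential.  For
`L ≫ H` the partition function is dominated by the slowest-decaying
eigenmode, `q ~ exp(-μ0 L/(2Lp)) Ψ0`, giving

    F/kBT = L μ0/(2Lp),       λ = 2Lp/μ0.

Slit symmetry reduces the state to `(y, c)` with `c = cos θ` measured
against the slit normal.  Discretisation (`fokker_planck`):

* transverse: uniform grid including the wall nodes, second-order central
  differences (one-sided at the walls); the transport block is exactly
  skew-symmetric on interior nodes;
* orientation: Gauss–Legendre collocation with `l_max+1` nodes; the
  rotational diffusion operator is `-l(l+1)/2` diagonal in the Legendre
  basis and mapped to node values by exact quadrature;
* hard walls: the distribution vanishes at a wall for orientations
  pointing from the wall into the channel (no chain enters from inside a
  wall), imposed as half-range constraints on the two boundary rows.
  This is the standard realisation of the `V = ∞` exterior.

The dominant eigenpair comes from a power iteration with the
implicit-Euler resolvent `(I - ds·A)^{-1}`.  Because any rational
function of `A` shares eigenvectors with `A`, the decay rate is read off
with a Rayleigh quotient against `A` itself each sweep; the contour step
`ds` (default 0.05 Lp) therefore affects only the convergence *rate*,
never the converged value, and no step-size extrapolation is needed.
Iteration stops when successive estimates agree to `tol` (default 1e-4,
the tolerance used for the reference eigenvalue computations this solver
reproduces).  A dense direct diagonalisation over the unconstrained
subspace is provided as an independent cross-check and agrees with the
iteration to 1e-10 on small bases.

Resolution floors scale as `H^{-1/3}` (the orientation boundary layer
narrows as the slit tightens); clearly under-resolved configurations are
rejected with a `ConfigurationError`.  At the production resolution
(`n_y = 200`, `l_max = 40`) the eigenvalue is mesh-converged to better
than 1e-4 relative.

Extrapolating `(μ0/2) Ĥ^{2/3}` affinely in `Ĥ^{2/3}` from
`Ĥ ∈ {0.05, 0.1, 0.2}` to zero height recovers the Odijk prefactor; the
affine term is the leading finite-channel correction (the modified
theory predicts slope `≈ -θ/2`).  The solver yields `A ≈ 1.105`, 0.2%
from the reference 1.1032.  Rectangular-tube free energies use slit
additivity; no four-dimensional eigenproblem is solved.

## Generalized bead-rod Brownian dynamics (extension verification)

The discrete chain has `N` bead centres joined by `N-1` rigid rods of
length `b`, with the discrete wormlike-chain bending energy
`E = kBT (Lp/b) Σ(1 - cos θ_j)`; for `b ≪ Lp` this reproduces the
persistence length (the exact discrete tangent correlation per joint is
`coth(Lp/b) - b/Lp`, used by the tests rather than the continuum
exponential).  One step composes the wall penalty displacement, the
drift `(Δt/kBT) D F`, and Gaussian noise with covariance `2 D Δt`, then
projects back onto the constraint manifold.

Numerical choices:

* **Constraint projection**: Newton iteration on the rod-length
  constraints; each iteration solves the tridiagonal Lagrange-multiplier
  system (equal bead weighting) with the Thomas algorithm and displaces
  beads along the current bonds.  Quadratic convergence brings the worst
  rod-length error below 1e-10 `b` in a few iterations; this tolerance is
  enforced on *every* accepted step.
* **Walls**: beads are points; a bead centre outside the channel is
  returned to the nearest wall plane per coordinate (the channel
  dimension is the accessible span for centres).  Clamping and rod
  projection are alternated until both tolerances hold (wall residual
  ≤ 1e-9 nm); the alternation converges quadratically because each
  clamp-induced rod correction is second order in the clamp distance.
* **Tension**: `±fs ẑ` applied to the two end beads — symmetric loading,
  no net force.
* **Hydrodynamics**: free-draining Stokes mobility by default; a pairwise
  far-field Rotne–Prager–Yamakawa mobility (with the overlap-regularised
  near-field branch) drives the correlated-noise variant through a
  Cholesky factor.  Equilibrium averages are mobility-independent — the
  tests verify this — so the fast free-draining path is used for all
  production ensembles.
* **Units and defaults**: nm / ps / pN·nm with `Lp = 50` nm, `T = 293` K
  and solvent viscosity 1.005725e-4 Pa·s.  That viscosity is one order
  below real water; it rescales time only (equilibrium averages are
  unaffected) and shortens relaxation times, and is kept as the default
  for continuity with the simulation conditions it reproduces.  Both
  `viscosity` and `temperature` are plain parameters.

Averaging protocol (`analysis`): within a trajectory, time-average after
an equilibration window; across trajectories, ensemble mean with the
standard error from inter-trajectory scatter.  Trajectories are the
independent unit because extension series are strongly autocorrelated.
The equilibration detector compares forward means from block boundaries
against the final-half mean, with error bands inflated by the integrated
autocorrelation time and a 3-sigma multiplier (a 1-sigma band would
reject equilibrated-but-noisy series almost surely); a series whose
final half still drifts is flagged unequilibrated and excluded with a
warning.  A 10% burn-in floor applies even when the detector reports
earlier stabilisation.  A deliberate limitation: a slow monotone drift
with strong autocorrelation is indistinguishable from a long-period
fluctuation and can pass the detector; run-length choices must still be
physically informed.

### Study conditions for the simulation-vs-theory grid

The comparison grid runs square tubes and slits at `Ĥ = 0.3` with
reduced tensions `{0, 5, 20}` (tube) and `{5, 20}` (slit; zero force is
excluded for slits for the in-plane random-walk reason above).  Three
discretisation biases had to be controlled to make a ~5% comparison
meaningful, and set the defaults:

* **Free ends**: each end contributes an extra deficit ≈ `1/(2 f̂_eff L̂)`
  (the zero-wavenumber tilt mode of a finite chain).  Contour lengths of
  4.8–6 `Lp` (240/300 nm) keep this below ~0.003 absolute — the same
  reasoning that leads the full-scale reference simulations to use 12
  `Lp` chains for their wider channels.
* **Rod length**: `b = 3` nm (`Lp/b ≈ 17`) keeps the discrete-chain
  persistence-length renormalisation at the percent level.
* **Time step**: `Δt = 5` ps with bead radius 1.85 nm keeps the
  Euler-scheme inflation of joint-angle variance (`≈ Δt/2τ_joint`) near
  1%, and the `√(2DΔt)` wall-boundary layer near 1% of the channel.

Each cell integrates 12 independent straight-start trajectories of
5×10^5 steps (2.5 µs) and discards at least the detected burn-in.  These
are reduced-scale conditions: the reference protocol uses 120
trajectories and 60–150 µs.  The reduced ensemble widens error bars
(~±0.002 on deficits) but does not move means.

The free-chain and stretched-chain oracles avoid slow equilibration
entirely by starting from *exact* Boltzmann draws (`fixtures`):

* free chains: sequential joint sampling from the exact density
  `∝ exp((Lp/b) cos θ)` (inverse-CDF), uniform azimuth;
* chains under tension: backward transfer-operator messages in `cos θ`
  (exact by azimuthal symmetry) followed by forward sampling with
  von Mises–Fisher proposals — plus a transfer-matrix quadrature for the
  exact finite-chain force-extension deficit, used as an independent
  oracle (at `f̂ = 25`, `L = 16 Lp`, the exact deficit is 0.1017 against
  the asymptotic 0.1).

Started at equilibrium, the Brownian dynamics must merely *preserve* the
distribution, which is exactly the property under test; drift would
expose integrator bias within a short run.

### What the synthetic conditions do and do not show

The generator reproduces ideal wormlike chains: no excluded volume, no
bead–bead collisions, no charge, and walls act on bead centres.  Passing
tests therefore validate the deflection-regime statistical mechanics of
an ideal semiflexible chain, not the full physics of, say, DNA in a
nanofluidic device (electrostatics, ionic strength, self-avoidance in
wider channels).  In the Odijk regime self-avoidance is largely
irrelevant (segments rarely back-fold), which is why the ideal-chain
comparison is the meaningful one.

## Known limitations

* The eigenvalue solver covers slits only; rectangular free energies use
  additivity of the two slit contributions rather than a 4D eigensolve.
* The extension prefactor α is only spot-checked through the scaling
  collapse of tube deficits; a precision recovery needs hours-long
  ensembles in tight slits (e.g. `Ĥ = 0.1`, `L ≳ 10 Lp`), runnable
  through the CLI but not part of the default suite.
* `Trajectory` frames are stored in memory; very long frame-recording
  runs should use `frame_every` sparingly.
* The equilibration detector's drift blindness noted above.
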