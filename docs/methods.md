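# Methods

## Model

The package analyses the synthesis–diffusion–depletion (SDD) picture of
morphogen gradient formation. A 1D array of cells of length `lcell` and
volume `vcell` spans `0 <= x <= L`; morphogen enters at the left boundary
with flux `jin` (concentration × length / time), diffuses with diffusivity
`D`, and is removed everywhere at first order with rate `kd`. In the
continuum limit (`L/lcell >> 1`)

    dρ/dt = D ρ'' − kd ρ,   −D ρ'(0) = jin,   ρ'(L) = 0,

with steady state `ρ_ss(x) = (jin/√(D kd)) cosh((L−x)/λ)/sinh(L/λ)` and
decay length `λ = √(D/kd)`. Two derived numbers parameterize everything:
`λ` and the amplitude `nm = vcell·jin/(lcell·kd)`, the number of molecules
produced per degradation time. All headline results are ratios, so any
consistent unit system works; `lcell = kd = 1` is the internal convention
of the examples and fixtures, and the public constructors accept physical
units directly.

Positions are continuous coordinates; cell discreteness enters only
through the `lcell` and `vcell` factors in the noise model (the continuum
reading of a cellular array).

## Cost, precision and the trade-off

**Point measurement.** The local accumulation time
`τ(x) = f(x;λ)/kd`, `f = ½[1 + (L/λ)coth(L/λ) − ((L−x)/λ)tanh((L−x)/λ)]`,
is the time integral of the relaxation deficit
`R(x,t) = (ρ_ss − ρ(x,t))/ρ_ss` from an empty system. The cost of reaching
steady state locally is `C(x) = α_o · nm · f(x;λ)` with `α_o` the ATP
price of synthesizing and degrading one molecule (≈ 494 aa × 4 ATP ≈ 2×10³
for Bicoid). Because every reaction is of zeroth or first order, the
stationary copy-number law is product-form Poisson, so a single
instantaneous readout has squared relative positional error

    ε²(x) = (λ³/(x² lcell)) nm⁻¹ sinh(L/λ) cosh((L−x)/λ)/sinh²((L−x)/λ).

The product `π_o = C·ε²` cancels `nm` exactly. At fixed `x_b` it is
unimodal in `λ`; in the large-L limit stationarity of `(1+s)s⁻³e^s`
(`s = x_b/λ`) gives `s² − s − 3 = 0`, i.e. `λ_min = 2x_b/(1+√13) ≈ 0.4343 x_b`,
which also places the boundary at `e^{−x_b/λ_min} ≈ 0.10` of the source
concentration. The finite-L optimizer reproduces this to 1e−5.

**Space–time averaging.** A sensor of half-width `a` integrating the count
over `(x−a, x+a)` for `T` (semi-infinite domain, `jin` in molecules/time)
has mean `⟨m⟩ = 2(jin/kd)e^{−x/λ}sinh(a/λ)` and, for `T >> 1/kd`,

    ε_T²(x) = (λ/x)² e^{x/λ} g(a/λ) / (jin T),
    g(u) = (e^{−u} + 3e^{3u} − 4(1+u)e^{u}) / (2(e^{2u}−1)²),

with `g(0)=1`. The count variance is reported in the equivalent form
`σ_m² = 4 jin e^{−x/λ} sinh²(u) g(u)/(T kd²)` (identically
`⟨m⟩²(x/λ)²ε_T²`); it is validated against the particle simulation rather
than re-derived. The cost is all molecules made during the measurement,
`C_T = α_o jin T`, so `π_T = C_T·ε_T²` again cancels production. Its
minimizer satisfies `(x_b−a)/2 ≤ λ_min ≤ x_b/2`, approaching `x_b/2` as
`a → 0`. No finite-L version of these formulas is invented; small systems
should use the point model. Durations below `10/kd` are rejected
(`ValidityError`) and below `50/kd` produce a warning.

The solved worked example: at `x_b = 60a`, `λ = 30a`, a 10% positional
error requires `jin·T = 180.66` (ceiling 181) molecules; at the exact
optimum `λ_min = 29.66a` the requirement is 180.63. Counts are reported as
the real solution plus its integer ceiling, since no rounding convention
is canonical.

## Numerical conventions

Hyperbolic ratios are evaluated in factored-exponential form, e.g.
`sinh(A)cosh(B)/sinh²(B) = e^{x/λ}(1−e^{−2A})(1+e^{−2B})/(1−e^{−2B})⁻²`
with `A = L/λ`, `B = (L−x)/λ`, which is finite for arbitrarily large
`L/λ` without a branch switch; optimizers work on `log π`. The sensor
factor `g(u)` switches to its series `1 − 2u/3 + u²/6` below `u = 10⁻³`,
where the exact expression loses precision to the `8u²/8u²` cancellation.
λ-optimization is bounded scalar minimization on `log(λ/x_b)` over
`[1/50, 10]` with `xatol = 10⁻¹²`; parametrizing by the dimensionless
ratio makes the optimum exactly unit-system invariant (the argmin itself
is determined only to ~√ε_machine by function values — an intrinsic limit,
not a solver setting). `ε²` is rejected at its poles `x = 0` and `x = L`
rather than regularized.

## Stochastic simulator (synthetic data)

The generator emulates exactly the statistical structure the analysis
assumes: molecules are injected into cell 0 at `vcell·jin/lcell` per time,
hop symmetrically at `D/lcell²` per molecule with reflecting walls, and
decay at `kd` — the master equation whose mean field is the SDD equation
and whose stationary law is Poisson cell by cell. The SSA is an exact
event-driven implementation (numba kernels; numpy's MT19937 stream seeded
per run, so results are bit-reproducible from `(config, seed)`; ensemble
seeds are spawned with `numpy.random.SeedSequence`). A Poisson tau-leap
variant retries a step at halved `dt` when a draw would go negative (10
halvings → error). Runs whose expected event count exceeds a configurable
budget are refused with a pointer to tau-leaping.

The deterministic "PDE oracle" integrates the method-of-lines
discretization (conservative finite volumes, optional sub-cell refinement)
with Crank–Nicolson stepping plus two initial backward-Euler steps
(Rannacher startup — plain trapezoidal stepping barely damps the stiff
content of the empty initial state and would pollute the long-time limit).
Accuracy: the long-time profile matches the closed form to < 1e−6 at 100
sub-cells per cell for `λ = 5 lcell`, and quadrature of the deficit
reproduces the accumulation-time formula to ~1e−5.

The standard validation fixture is 50 cells, `λ = 5 lcell`
(`hop = 25 kd`), `nm = 10³`, seed 20210817. Validation sample sizes were
sized from variance estimates: 4000 snapshots spaced `2/kd` give per-cell
Fano factors to ±0.02 (1 s.e., ~√(2/n) regardless of the mean), 600
zero-start replicates give the empirical accumulation time to ~1%
(bootstrap s.e. over runs), and 500 independent window averages give the
variance to ~6% (χ² s.e.), against a 3-s.e. acceptance band.

What the generator does *not* emulate: 2D/3D geometry, advective or
ballistic transport, receptor binding, nuclear import, or any decoding
step — passing tests show the formulas are exact for the model's own
assumptions, not that real gradients obey them. One discretization caveat
matters when comparing simulation to continuum formulas: the lattice decay
rate is `acosh(1 + kd/2h)` per cell, not `1/λ`, so mean profiles carry an
`O((lcell/λ)²)` bias (~20% over 5λ at `lcell = λ`). Continuum-formula
comparisons therefore use `λ = 5 lcell` lattices, where the bias (~2%) is
well inside the statistical bands; the window-variance check keeps a
coarser `λ = 2 lcell` lattice because its ~6% sampling error dominates.

## Reversible kinetics and entropy production

To give the cost a thermodynamic definition, every elementary step gets a
reverse: synthesis into cell 0 (`ks`, zeroth order) with first-order
removal `ks_rev`; degradation `kd` with zeroth-order creation `kd_rev` in
every cell; hop rates `hop_f`/`hop_r`. Keeping the reverse steps zeroth/
first order keeps the network linear, so the stationary law stays
product-form Poisson and the mean field is a banded linear system. The
entropy production rate is the Schnakenberg sum
`Ṡ_tot = Σ_edges (J⁺−J⁻)ln(J⁺/J⁻)` over the synthesis edge, per-cell
degradation edges and hop edges, with one-way fluxes at the stationary
means — exact here because particles are independent. It is nonnegative,
zero exactly at detailed balance (symmetric hops and
`ks/ks_rev = kd_rev/kd`), and estimated consistently by the pathwise SSA
tally of `ln(a_fwd/a_rev)` per event. Strictly irreversible edges are
reported as a flagged divergence, not a silent infinity, since the
irreversible model is the limit of main interest.

The relaxation time uses the resolvent: from an empty system the deficit
is `e^{At}n_ss`, so `∫₀^∞ R dt = (−A⁻¹n_ss)_x / n_ss(x)` — exact in time,
cross-checked against an independent ODE integration to 1e−6. The
three-way product `π_rev = Ṡ_tot·τ_rev·ε²_rev` uses the Poisson positional
error with a central-difference slope. At detailed balance the profile is
flat and dissipation zero; the product is reported as 0 with a
`degenerate` flag (the bound is attained trivially but no information is
transferred). The product's lower bound over the hop rate (the
decay-length dial) is computed numerically — no closed form is assumed —
and increases monotonically with the boundary position. Entropy is in
`k_B` units; conversion to ATP equivalents requires a user-supplied
affinity per synthesis–degradation cycle and is deliberately not defaulted.

## Other geometries

*Distributed 1D source*: the steady state is the Green's-function
superposition `G(x,x') = λcosh(x_</λ)cosh((L−x_>)/λ)/(D sinh(L/λ))`,
integrated in closed form for boxcars and by quadrature for tabulated
sources. *Sphere*: conservative second-order finite volumes in the polar
angle; the metric factor `sinθ` vanishes at both poles, enforcing
regularity naturally; `kd = 0` with net production is rejected (no steady
state). The generalized trade-off defines cost as
`α_o × (total production rate) × τ(boundary)` with `τ` from the resolvent
of the discrete operator (the exact time integral of the method-of-lines
deficit), and precision as Poisson noise in a local sensing volume (a
`vcell` cell in 1D; a ring of arc width `lcell` on the sphere — the
azimuthally symmetric reading of "a cell at that latitude") over the
squared slope and squared distance. On the sphere, distance means arc
length from the source-cap edge, which makes `x_b` comparable to the 1D
coordinate; the decay-length optimizer brackets around that distance (for
wide sources the distance from the source edge, not from the origin, sets
the scale). With a point-like source these definitions collapse to the 1D
point model (verified to 1e−4); for `λ ≪ R` the sphere matches a matched
1D distributed-source system (λ_min to 1%).

## Atlas

Built-in records carry only printed biology: decay lengths 100/6/8/20 µm
for Bcd/Wg/Hh/Dpp; Bcd's boundary at 0.4 L, `L/lcell ≈ 50` and measured
`ε² ≈ 7×10⁻⁴` (its `L = 500 µm` is the value implied by λ sitting at
0.2 L); Dpp's boundary range 0.4–0.5 L and `ε² ≈ 1.5×10⁻²`. Scoring a
system needs its geometry; missing fields raise a named error rather than
being guessed. `examples/atlas_example.toml` supplies an explicitly
synthetic, illustrative wing-disc geometry (patterned lengths ~30–85 µm,
2.5 µm cells) so the pipeline can be exercised end to end; with it, all
four systems fall within a factor 2 of `λ_min` under both measurement
models. Boundary ranges are evaluated at the midpoint with both endpoints
attached. The Bicoid cost estimate divides the trade-off product by the
measured precision: ≈ 4×10⁴ molecules' worth, ~8×10⁷ ATP — orders of
magnitude below the ~5×10⁸ molecules actually synthesized, because the 1D
nuclear-profile model prices only the information-bearing margin, not the
full 3D cytoplasmic pool.

## Known limitations

* All precision formulas assume Poisson (uncorrelated, linear-kinetics)
  noise; feedback, receptor saturation or bursting would break them.
* The space–time model is semi-infinite and long-time only; its variance
  formula degrades below `T ≈ 50/kd`.
* The reversible scheme is one linear choice among possible
  reversibilizations; nonlinear reverse steps would destroy the Poisson
  stationary law the precision formula relies on.
* Sphere scoring fixes an azimuthally symmetric source and ring-shaped
  sensing volumes; asymmetric caps are out of scope.
* Decoding (morphogen → target-gene expression) is not modelled anywhere;
  boundaries are defined directly by threshold crossings of the profile.
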