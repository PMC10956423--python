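# Methods

## Model

The package reduces the NOS tyrosine gate to a single reaction coordinate
x (Å): the monitored donor–acceptor distance along the down→up rotation.
All physics lives in a one-dimensional potential U(x) in kcal/mol.

**Double-well form.** `make_double_well(x_down, x_up, barrier, asymmetry,
domain)` builds U from quintic smoothstep segments joined at the midpoint
x_b = (x_down + x_up)/2, with quartic confining walls outside the wells.
The constructor parameters are *exact* properties of the surface, not
fits: U(x_down) = 0, U(x_up) = asymmetry, the single interior maximum
equals `barrier` at x_b, and the gradient vanishes at both minima. The
quintic blend makes U C² everywhere with a flat-topped barrier and
flat-bottomed wells (zero curvature at the stationary points); this keeps
closed-form test values exact and makes the stiff-spring smearing
correction nearly cancel between landscapes that differ only in barrier
scale. The trade-off is that well widths scale weakly (∝ barrier^(−1/3))
with the barrier, so the two-state population formula 1/(1+e^(−Δ/kT)) is
exact only in the limit of identical wells; the quadrature oracle
`boltzmann_population` is always the reference.

**Isoform presets.** Both presets place the wells at 2.8 Å (a
donor–acceptor hydrogen-bond distance) and 9.8 Å (the ~7 Å displaced up
state) on the domain [0.8, 11.8] Å. The nNOS-like gate has an opening
barrier of 8 kcal/mol and an up-state offset of +4 kcal/mol; the eNOS-like
gate is 5 kcal/mol harder to open (barrier 13, the midpoint of the
reported 4–6 kcal/mol excess) with offset +6. The offsets put the up state
several kT above down so that equilibrium occupancy is governed by the
down basin — the only regime an overdamped run can actually sample, since
down↔up hopping over an 8–13 kcal/mol barrier (β·ΔU ≈ 13–22 at 300 K) has
a mean first-passage time far beyond even 200 ns-equivalents. For the same
reason the synthetic runs cannot reproduce occupancy values near the
published all-atom contrast (74.6% vs 33.1%): in the stand-in, occupancy
contrast comes from down-well stiffness (both presets sit above 99% at the
4.0 Å cutoff, with the stiffer gate consistently higher), not from
barrier-crossing statistics. Passing tests therefore demonstrate estimator
correctness and qualitative isoform ordering, not quantitative agreement
with all-atom MD.

**Units.** Å, ps, kcal/mol, Kelvin throughout;
k_B = 0.0019872041 kcal mol⁻¹ K⁻¹. The simulation temperature defaults to
300 K (kT ≈ 0.5962 kcal/mol) — a package default recorded in every output,
chosen because the source protocol does not state one.

## Synthetic dynamics

The simulator propagates overdamped Euler–Maruyama,
x ← x + (D/kT)·F(x)·dt + √(2·D·dt)·η, with default diffusion
D = 0.1 Å²/ps (a side-chain-scale coordinate in solvent) and dt = 0.01 ps.
No inertia, no solvent degrees of freedom: this reproduces the *sampling
design* of the study (durations, snapshot spacing, replica structure), not
its microscopic dynamics. Stability and accuracy margins at the defaults:
the stiffest relaxation time (restraint k = 10) is γ/k ≈ 0.6 ps ≈ 60·dt,
and halving dt changes the mean final pull work by ≪ 2% (verified on
matched Brownian paths). Equilibrium runs discard a burn-in of 10% of the
production length. Every trajectory is a pure function of (landscape,
protocol, start, ids, master seed): per-replica Generators are spawned
from SeedSequence entropy (seed, stage label, replicate id, site id), with
string ids hashed stably. Trajectories that leave the landscape domain
abort with the step and position named.

**Steered pulls.** The restraint center moves as z_c(t) = z₀ + v·t.
When pulls are launched from harvested equilibrium snapshots, all replicas
share the schedule origin z₀ (the down-well position); the snapshot
supplies only the initial coordinate, and the system first relaxes for
`pre_equilibration` (default 50 ps ≈ 80 relaxation times) with the
restraint fixed at z₀. This makes the t = 0 ensemble the *restrained*
equilibrium that the Jarzynski identity requires, so the estimator is
directly comparable to the exact restrained profile
F(z) = −kT ln ∫ exp(−[U(x) + (k/2)(x−z)²]/kT) dx. Snapshot harvesting
takes n evenly index-spaced frames from the final window of a production
run, starting at the window's first snapshot (ties toward earlier frames).

## Estimators

Work is accumulated per pull by trapezoidal quadrature of
k·v·(z_c − x) on the recorded stride (default: every step) and linearly
interpolated onto a shared grid of center positions (0.1 Å spacing, 71
points across the 7 Å pull — fine enough to resolve the barrier region
while keeping work matrices small). Estimators: `jarzynski` (log-sum-exp
stabilized exponential average; naive exponentiation overflows for
dissipative traces), `cumulant2` (⟨W⟩ − Var(W)/2kT, unbiased sample
variance), `mean_work` (upper bound). All are gauged to ΔF = 0 at the
first grid point. Percentile bootstrap bands (default 1000 resamples,
2.5/97.5) resample *replicas* stratified by site — replicas are the
independent units — and the band is widened, when necessary, to bracket
the point estimate so profile invariants hold for any resample geometry.

The scalar "PMF to complete the movement" is deliberately ambiguous in the
source material, so both definitions are computed: `endpoint` (default;
ΔF at the final center position ≈ the up/down offset) and `profile_max`
(the profile maximum ≈ the opening barrier). The between-preset comparison
targets 5 kcal/mol under `profile_max` (the presets' barrier difference;
the exact-quadrature restrained maxima differ by 4.96 at spring 10) and
2 kcal/mol under `endpoint` (their offset difference). Difference CIs pair
bootstrap draws across the two independent ensembles and average per-site
differences per draw.

At the default protocol (v = 7 Å/ns, D = 0.1 Å²/ps) the pulls are nearly
quasi-static: mean dissipation γ·v·L ≈ 0.3 kcal/mol < 1 kcal/mol, so the
N = 100 Jarzynski bias is small and the recovered profile tracks the exact
restrained profile to ≲ 0.2 kcal/mol (the acceptance suite enforces
≤ 1.0 kcal/mol).

## Occupancy statistics

`occupancy_fraction` counts frames with distance ≤ cutoff inclusively
(default 4.0 Å), as exact integer arithmetic; pooling across runs/sites is
frame-weighted counting, identical to counting the concatenated series.
For arginine endpoints read from PDB trajectories the acceptor is the
guanidinium atom set {NE, NH1, NH2} with minimum-distance aggregation (the
specific Arg atom is a package decision); frames are MODEL blocks,
uniformly weighted, with altloc entries other than blank/'A' skipped with
a warning. Simulated gate coordinates are used directly as the monitored
distance, the down well being the hydrogen-bonded (sub-cutoff) state.

Uncertainty uses a circular block bootstrap within each series (groups
resampled independently, then pooled). The default block length is
2× the integrated autocorrelation time of the occupancy indicator,
estimated by Geyer's initial-positive-sequence rule with a floor of one
frame. Degenerate inputs behave sensibly: constant series give zero IACT
variance (block length 1, CI of zero width), and block lengths exceeding
the series length are rejected.

## Problem sizes and numerical tolerances

Quadrature oracles integrate piecewise between analytic breakpoints with
`scipy.integrate.quad` at 1e-12 tolerances after subtracting the scanned
potential minimum (stable to ~1e-8 kcal/mol absolute); restrained-profile
integrands add breakpoints at z ± σ and z ± 10σ so stiff springs are never
missed. Tabulated landscapes use not-a-knot cubic splines. The
demonstration workflow defaults to scaled-down equivalents (20 ns
monitoring per run, 20 ns pre-pull production, 100 pulls per site,
200 bootstrap resamples) with `--full` restoring 200 ns-equivalent
monitoring; the statistical validation suite uses 10 ns runs with ~100
seeded repetitions for coverage checks and a 12-seed family for the
convergence-with-run-length check. Comparisons of equal-content systems
are exactly zero by construction: workflow RNG streams are keyed by the
system's content (preset name or landscape parameters), not its slot.

## Known limitations

- One coordinate, overdamped: no inertial or multidimensional effects,
  no explicit solvent, no force-field energetics.
- Barrier-crossing observables (up-state population at several-kcal/mol
  barriers) are out of reach of the stand-in, as discussed above.
- No bidirectional (Crooks/BAR) or umbrella-sampling (WHAM) estimators;
  the exact restrained profile plays the reference role instead.
- PDB input is limited to fixed-column multi-model files; other trajectory
  formats should be converted upstream.
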