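# tyrgate

Steered-pulling work analysis and hydrogen-bond occupancy statistics for a
one-dimensional model of the nitric oxide synthase (NOS) active-site
tyrosine gate.

## The problem

NOS isoforms carry a conserved active-site tyrosine that either
hydrogen-bonds to a heme propionate (the "down" state) or rotates away
("up"), opening the propionate to inhibitors. Along the monitored
Tyr–Asn/Tyr–Arg distance the two states sit about 7 Å apart, and how easily
the gate opens differs between isoforms — a mobility difference that helps
explain isoform-selective inhibitor binding. Two computational observables
quantify that difference:

1. **Equilibrium occupancy** — the fraction of trajectory frames in which
   the Tyr–Arg distance stays ≤ 4.0 Å (the hydrogen bond persists), with a
   circular block-bootstrap confidence interval that respects the
   autocorrelation of 20-ps-spaced snapshots.
2. **Potential of mean force (PMF)** — a moving harmonic restraint
   (spring k = 10 kcal mol⁻¹ Å⁻², velocity v = 7 Å/ns, 1.0 ns per pull)
   drags the gate coordinate 7 Å from down to up; the external work
   W(t) = ∫ k·v·(z_c − x) dt′ of 100 replicas per active site is combined
   through the Jarzynski equality

   exp(−ΔF(z)/kT) = ⟨exp(−W(z)/kT)⟩

   (evaluated with log-sum-exp stabilization) into the free-energy profile
   of the restrained system, with a replica bootstrap for uncertainty and a
   second-cumulant companion estimator ΔF ≈ ⟨W⟩ − Var(W)/2kT.

`tyrgate` implements this full pipeline as a reusable library plus CLI.
Because all-atom MD is out of reach at desk scale, the package ships its own
seeded overdamped-Langevin simulator over analytic free-energy landscapes:
a double well with exact constructor parameters (well positions, barrier,
up/down offset) stands in for the gate, and two presets ("nNOS-like",
"eNOS-like", opening barriers differing by 5 kcal/mol) stand in for the
contrasted isoforms. Exact quadrature oracles (region free energies,
restrained profiles, Boltzmann populations) validate every estimator.
Distance series can also be read from delimited text tables or multi-model
PDB trajectories, so the occupancy statistics apply to real data exported
in those forms.

## Worked example

```sh
tyrgate demo --seed 1 --out demo_out
```

runs the scaled-down (20 ns-equivalent monitoring) two-preset comparison
and prints:

```
report written to demo_out/report.json
system_a: occupancy(≤4 Å) = 99.2% of 4000 frames [98.9, 99.5]%
system_b: occupancy(≤4 Å) = 100.0% of 4000 frames [99.9, 100.0]%
PMF mean difference (B−A, endpoint): 2.09 kcal/mol [1.93, 2.21]
```

`system_a` is the mobile nNOS-like gate, `system_b` the stiffer eNOS-like
gate. The stiffer gate holds its hydrogen bond more often (higher
sub-4 Å occupancy) and costs more free energy to open: 2.09 kcal/mol more
at the pull endpoint (the up/down offset difference of the presets), or
~5 kcal/mol more at the profile maximum (`definition_of_total =
"profile_max"`, the barrier difference). Per-site PMF profiles, work sets,
equilibrium traces and occupancy tables are written next to `report.json`;
`--full` switches to 200 ns-equivalent monitoring, and `--plots` adds
summary figures. Every number in the report is reproducible from the
config and master seed alone.

The same stages are available as `simulate-eq`, `simulate-pull`, `pmf`,
`occupancy` and `compare` verbs, and as plain library calls
(`tyrgate.simulate_pull`, `tyrgate.jarzynski_pmf`, …).

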