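"""Overdamped-Langevin stand-in for the MD engine.

Two sampling modes mirror the study design around the tyrosine gate:

* *equilibrium monitoring*: long unbiased runs (default 200 ns with
  snapshots every 20 ps → 10,000 snapshots/run), duplicated with
  independent noise streams and repeated over the dimer's two active
  sites (2 × 2 × 10,000 = 40,000 observations);
* *steered pulls*: a harmonic restraint (default 10 kcal mol⁻¹ Å⁻²)
  whose center moves at 7.0 Å/ns for 1.0 ns drags the coordinate 7 Å
  from the down to the up state, 100 replicas per site, each started
  from a snapshot harvested off the tail of an equilibrium production
  run.

The propagator is Euler–Maruyama on the overdamped equation
``x ← x + (D/kT)·F(x)·dt + sqrt(2·D·dt)·η`` — no inertia, one slow
coordinate.  All noise is drawn from numpy Generators seeded from
``(master seed, replicate/run id, site id)``, so every trace is a pure
function of its inputs.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

from .landscapes import (
    DEFAULT_TEMPERATURE,
    KB,
    LandscapeDomainError,
    ModelLandscape,
    ParameterError,
)

__all__ = [
    "EquilibriumProtocol",
    "PullProtocol",
    "EquilibriumTrace",
    "PullTrace",
    "SimulationEscapeError",
    "simulate_equilibrium",
    "simulate_pull",
    "harvest_starting_points",
    "planned_frame_count",
    "write_equilibrium_tsv",
    "write_pull_tsv",
    "rng_stream",
]


class SimulationEscapeError(RuntimeError):
    """The trajectory left the landscape's domain."""


# ---------------------------------------------------------------------
# Protocols
# ---------------------------------------------------------------------

def _positive(name: str, value: float) -> None:
    if not (np.isfinite(value) and value > 0):
        raise ParameterError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class EquilibriumProtocol:
    """Sampling design of a conventional (unbiased) monitoring run."""

    duration: float = 200.0          # ns
    snapshot_interval: float = 20.0  # ps
    n_runs: int = 2
    n_sites: int = 2
    temperature: float = DEFAULT_TEMPERATURE  # K
    diffusion: float = 0.1           # Å²/ps
    timestep: float = 0.01           # ps
    seed: int = 0

    def __post_init__(self):
        for name in ("duration", "snapshot_interval", "temperature",
                     "diffusion", "timestep"):
            v = getattr(self, name)
            if name == "diffusion":
                if not (np.isfinite(v) and v >= 0):
                    raise ParameterError(f"diffusion must be >= 0, got {v!r}")
            else:
                _positive(name, v)
        if self.n_runs < 1 or self.n_sites < 1:
            raise ParameterError("n_runs and n_sites must be >= 1")
        n = self.duration * 1000.0 / self.snapshot_interval
        if abs(n - round(n)) > 1e-9:
            raise ParameterError(
                f"duration ({self.duration} ns) must be an integer number of "
                f"snapshot intervals ({self.snapshot_interval} ps)"
            )
        m = self.snapshot_interval / self.timestep
        if abs(m - round(m)) > 1e-9:
            raise ParameterError(
                "snapshot_interval must be an integer multiple of the timestep"
            )

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def snapshots_per_run(self) -> int:
        return round(self.duration * 1000.0 / self.snapshot_interval)


@dataclass(frozen=True)
class PullProtocol:
    """Steered-pull design: moving harmonic restraint at constant velocity."""

    velocity: float = 7.0    # Å/ns
    duration: float = 1.0    # ns
    spring: float = 10.0     # kcal/mol/Å²
    n_traces: int = 100
    harvest_window: float = 10.0  # ns, tail of the production run
    temperature: float = DEFAULT_TEMPERATURE
    diffusion: float = 0.1   # Å²/ps
    timestep: float = 0.01   # ps
    record_stride: int = 1   # record every `stride` timesteps
    pre_equilibration: float = 50.0  # ps with the restraint fixed at its origin
    seed: int = 0

    def __post_init__(self):
        for name in ("velocity", "duration", "spring", "harvest_window",
                     "temperature", "timestep"):
            _positive(name, getattr(self, name))
        if not (np.isfinite(self.diffusion) and self.diffusion >= 0):
            raise ParameterError(f"diffusion must be >= 0, got {self.diffusion!r}")
        if self.n_traces < 1:
            raise ParameterError("n_traces must be >= 1")
        if self.record_stride < 1:
            raise ParameterError("record_stride must be >= 1")
        if not (np.isfinite(self.pre_equilibration) and self.pre_equilibration >= 0):
            raise ParameterError("pre_equilibration must be >= 0")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    @property
    def displacement(self) -> float:
        """Total pull distance, Å (velocity × duration)."""
        return self.velocity * self.duration

    @property
    def n_steps(self) -> int:
        return round(self.duration * 1000.0 / self.timestep)


# ---------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class EquilibriumTrace:
    times: np.ndarray      # ps, snapshot times
    positions: np.ndarray  # Å
    run_id: object
    site_id: object
    protocol: EquilibriumProtocol
    seed_used: int


@dataclass(frozen=True)
class PullTrace:
    times: np.ndarray            # ps
    positions: np.ndarray        # Å
    center: np.ndarray           # Å, restraint center z_c(t) = start + v t
    restraint_force: np.ndarray  # kcal/mol/Å, spring*(z_c - x)
    protocol: PullProtocol
    replicate_id: object
    site_id: object
    seed_used: int

    @property
    def start(self) -> float:
        return float(self.center[0])


# ---------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------

def _token_int(token) -> int:
    """Stable 32-bit token from an id (int or string label)."""
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFF
    h = hashlib.sha256(str(token).encode()).digest()
    return int.from_bytes(h[:4], "little")


def rng_stream(seed: int, *tokens) -> np.random.Generator:
    """Independent, reproducible Generator for (seed, *tokens)."""
    entropy = [int(seed) & 0xFFFFFFFF] + [_token_int(t) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence(entropy))


# ---------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------

@njit(cache=True)
def _grad_kernel(x, kind, p, knots, coeffs):
    """dU/dx for the packed landscape (see ModelLandscape.kernel_args)."""
    if kind == 0:  # flat
        return 0.0
    if kind == 1:  # harmonic: p = [center, kappa]
        return p[1] * (x - p[0])
    if kind == 2:  # double well
        xd, xu, xb, w1, w2, b, a, cl, cr = (
            p[0], p[1], p[2], p[3], p[4], p[5], p[6], p[7], p[8]
        )
        if x < xd:
            d = xd - x
            return -4.0 * cl * d * d * d
        if x <= xb:
            s = (x - xd) / w1
            return b * 30.0 * s * s * (1.0 - s) * (1.0 - s) / w1
        if x <= xu:
            s = (xu - x) / w2
            return -(b - a) * 30.0 * s * s * (1.0 - s) * (1.0 - s) / w2
        d = x - xu
        return 4.0 * cr * d * d * d
    # tabulated cubic spline: coeffs shape (4, n-1), scipy layout
    n = knots.shape[0]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if x >= knots[mid]:
            lo = mid
        else:
            hi = mid
    t = x - knots[lo]
    return 3.0 * coeffs[0, lo] * t * t + 2.0 * coeffs[1, lo] * t + coeffs[2, lo]


@njit(cache=True)
def _propagate(
    x0, n_steps, dt, mobility, noise_scale,
    kind, p, knots, coeffs, lo, hi,
    spring, z0, vel_ps, t0,
    noise, rec_stride, out,
):
    """Advance n_steps; record x after every rec_stride-th step into out.

    Returns (final x, escape step or -1, number of records written).
    A zero `spring` gives unbiased equilibrium dynamics.
    """
    x = x0
    k = 0
    for i in range(n_steps):
        f = -_grad_kernel(x, kind, p, knots, coeffs)
        if spring > 0.0:
            zc = z0 + vel_ps * (t0 + i * dt)
            f += spring * (zc - x)
        x = x + mobility * f * dt + noise_scale * noise[i]
        if x < lo or x > hi:
            return x, i + 1, k
        if (i + 1) % rec_stride == 0:
            out[k] = x
            k += 1
    return x, -1, k


_NOISE_CHUNK = 2_000_000


def _run_chunked(
    rng: np.random.Generator,
    landscape: ModelLandscape,
    x0: float,
    n_steps: int,
    dt: float,
    diffusion: float,
    kT: float,
    rec_stride: int,
    spring: float = 0.0,
    z0: float = 0.0,
    vel_ps: float = 0.0,
    t_start: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Drive the kernel in noise chunks; return (final x, recorded positions)."""
    kind, p, knots, coeffs = landscape.kernel_args()
    lo, hi = landscape.domain
    mobility = diffusion / kT
    noise_scale = math.sqrt(2.0 * diffusion * dt)
    n_rec = n_steps // rec_stride
    out = np.empty(n_rec, dtype=np.float64)
    chunk = max(rec_stride, (_NOISE_CHUNK // rec_stride) * rec_stride)
    x = float(x0)
    done = 0
    written = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        noise = rng.standard_normal(m)
        x, esc, k = _propagate(
            x, m, dt, mobility, noise_scale,
            kind, p, knots, coeffs, lo, hi,
            spring, z0, vel_ps, t_start + done * dt,
            noise, rec_stride, out[written:],
        )
        if esc >= 0:
            step = done + esc
            raise SimulationEscapeError(
                f"trajectory escaped domain [{lo:g}, {hi:g}] at step {step} "
                f"(t = {t_start + step * dt:g} ps, x = {x:g} Å)"
            )
        done += m
        written += k
    return x, out


# ---------------------------------------------------------------------
# Simulators
# ---------------------------------------------------------------------

#: Fraction of an equilibrium run prepended as burn-in and discarded.
BURN_IN_FRACTION = 0.10


def simulate_equilibrium(
    landscape: ModelLandscape,
    protocol: EquilibriumProtocol,
    start: float,
    run_id=0,
    site_id=0,
) -> EquilibriumTrace:
    """Unbiased overdamped run recording a snapshot every snapshot_interval.

    A burn-in of 10% of the production length is simulated first and
    discarded.  Deterministic for a fixed (seed, run_id, site_id).
    """
    lo, hi = landscape.domain
    if not (lo <= start <= hi):
        raise LandscapeDomainError(f"start {start} outside domain [{lo}, {hi}]")
    rng = rng_stream(protocol.seed, "equilibrium", run_id, site_id)
    dt = protocol.timestep
    stride = round(protocol.snapshot_interval / dt)
    n_prod = protocol.snapshots_per_run * stride
    n_burn = round(BURN_IN_FRACTION * n_prod)
    x = start
    if n_burn:
        x, _ = _run_chunked(
            rng, landscape, x, n_burn, dt, protocol.diffusion, protocol.kT,
            rec_stride=n_burn,
        )
    _, positions = _run_chunked(
        rng, landscape, x, n_prod, dt, protocol.diffusion, protocol.kT,
        rec_stride=stride,
    )
    times = protocol.snapshot_interval * np.arange(1, protocol.snapshots_per_run + 1)
    return EquilibriumTrace(
        times=times, positions=positions, run_id=run_id, site_id=site_id,
        protocol=protocol, seed_used=protocol.seed,
    )


def simulate_pull(
    landscape: ModelLandscape,
    protocol: PullProtocol,
    start: float,
    replicate_id=0,
    site_id=0,
    z_start: float | None = None,
) -> PullTrace:
    """One steered pull: restraint center moves from ``z_start`` at constant v.

    The restraint center is initialized at ``start`` unless ``z_start``
    pins the schedule to a common origin (the setup used when pulls are
    launched from harvested snapshots: every replica then shares the
    same schedule z_c(t), as the Jarzynski average requires).  Before
    recording, the system relaxes for ``protocol.pre_equilibration`` ps
    with the restraint fixed at the origin, so the t=0 state is drawn
    from the *restrained* equilibrium the stiff-spring reference profile
    assumes.  Positions are recorded every ``record_stride`` timesteps
    (default: every step), including the initial point, so the external
    work can be accumulated by trapezoidal quadrature downstream.
    """
    lo, hi = landscape.domain
    if not (lo <= start <= hi):
        raise LandscapeDomainError(f"start {start} outside domain [{lo}, {hi}]")
    z0 = start if z_start is None else float(z_start)
    if not (lo <= z0 <= hi):
        raise LandscapeDomainError(f"z_start {z0} outside domain [{lo}, {hi}]")
    rng = rng_stream(protocol.seed, "pull", replicate_id, site_id)
    dt = protocol.timestep
    vel_ps = protocol.velocity / 1000.0  # Å/ps
    n_steps = protocol.n_steps
    if n_steps % protocol.record_stride != 0:
        raise ParameterError("record_stride must divide the number of steps")
    x0 = float(start)
    n_pre = round(protocol.pre_equilibration / dt)
    if n_pre:
        x0, _ = _run_chunked(
            rng, landscape, x0, n_pre, dt, protocol.diffusion, protocol.kT,
            rec_stride=n_pre, spring=protocol.spring, z0=z0, vel_ps=0.0,
        )
    _, rec = _run_chunked(
        rng, landscape, x0, n_steps, dt, protocol.diffusion, protocol.kT,
        rec_stride=protocol.record_stride,
        spring=protocol.spring, z0=z0, vel_ps=vel_ps,
    )
    positions = np.concatenate(([x0], rec))
    times = dt * protocol.record_stride * np.arange(positions.size)
    center = z0 + vel_ps * times
    force = protocol.spring * (center - positions)
    return PullTrace(
        times=times, positions=positions, center=center, restraint_force=force,
        protocol=protocol, replicate_id=replicate_id, site_id=site_id,
        seed_used=protocol.seed,
    )


def harvest_starting_points(
    trace: EquilibriumTrace, n: int, window: float
) -> np.ndarray:
    """Evenly spaced (by index) positions from the final `window` ns.

    Mirrors harvesting pull starts from the tail of a production run.
    Indices start at the window's first snapshot; ties break toward
    earlier snapshots.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    window_ps = window * 1000.0
    total_ps = trace.protocol.duration * 1000.0
    if window_ps > total_ps + 1e-9:
        raise ParameterError(
            f"window ({window} ns) exceeds trace duration ({trace.protocol.duration} ns)"
        )
    m = round(window_ps / trace.protocol.snapshot_interval)
    n_snap = trace.positions.size
    if m > n_snap or n > m:
        raise ParameterError(
            f"window holds {m} snapshots; cannot harvest {n} from trace of {n_snap}"
        )
    first = n_snap - m
    idx = first + (np.arange(n) * m) // n
    return trace.positions[idx].copy()


def planned_frame_count(protocol: EquilibriumProtocol) -> int:
    """Total distance observations the monitoring design yields."""
    return protocol.n_runs * protocol.n_sites * protocol.snapshots_per_run


# ---------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------

def _meta_lines(protocol) -> list[str]:
    return [
        f"# protocol: {type(protocol).__name__}",
        f"# seed: {protocol.seed}",
        f"# temperature_K: {protocol.temperature:g}",
        f"# diffusion_A2_per_ps: {protocol.diffusion:g}",
        f"# timestep_ps: {protocol.timestep:g}",
    ]


def write_equilibrium_tsv(traces: list[EquilibriumTrace], path) -> None:
    """Write equilibrium traces as TSV (t_ps, x_A, run, site)."""
    lines = _meta_lines(traces[0].protocol)
    lines.append("t_ps\tx_A\trun\tsite")
    for tr in traces:
        for t, x in zip(tr.times, tr.positions):
            lines.append(f"{t:.6g}\t{x:.8g}\t{tr.run_id}\t{tr.site_id}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_pull_tsv(traces: list[PullTrace], path) -> None:
    """Write pull traces as TSV (t_ps, x_A, zc_A, f_kcal_mol_A, replicate, site)."""
    lines = _meta_lines(traces[0].protocol)
    lines.append("t_ps\tx_A\tzc_A\tf_kcal_mol_A\treplicate\tsite")
    for tr in traces:
        for t, x, zc, f in zip(tr.times, tr.positions, tr.center, tr.restraint_force):
            lines.append(
                f"{t:.6g}\t{x:.8g}\t{zc:.8g}\t{f:.8g}\t{tr.replicate_id}\t{tr.site_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")
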