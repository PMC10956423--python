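"""Model free-energy landscapes for the tyrosine down/up gate.

The conserved active-site tyrosine of nitric oxide synthase either
hydrogen-bonds to a heme propionate ("down") or rotates away ("up");
along the monitored Tyr--Asn/Tyr--Arg distance the two states sit
roughly 7 Å apart.  This module represents that gate as an explicit
one-dimensional potential U(x) in kcal/mol over x in Å, together with
exact (quadrature / closed-form) oracles:

* free-energy differences between coordinate regions,
* the harmonically restrained profile F(z) that a stiff-spring pulling
  estimator should recover,
* Boltzmann populations of regions (the equilibrium analogue of the
  distance-occupancy statistic).

Every stochastic estimator elsewhere in the package is validated
against these oracles, which are deterministic integrals evaluated to
an absolute tolerance of ~1e-8 kcal/mol.

Units are fixed package-wide: Å, ps, kcal/mol, Kelvin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import CubicSpline

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "thermal_energy",
    "ParameterError",
    "LandscapeDomainError",
    "ModelLandscape",
    "IsoformPreset",
    "make_double_well",
    "make_harmonic",
    "make_flat",
    "make_tabulated",
    "evaluate_landscape",
    "exact_free_energy_difference",
    "exact_restrained_profile",
    "boltzmann_population",
    "isoform_presets",
    "read_tabulated_tsv",
    "write_tabulated_tsv",
]

#: Boltzmann constant, kcal mol^-1 K^-1.
KB = 0.0019872041

#: Default simulation temperature (K).  kT at 300 K is ~0.5962 kcal/mol.
DEFAULT_TEMPERATURE = 300.0


def thermal_energy(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kT in kcal/mol at the given temperature."""
    return KB * temperature


class ParameterError(ValueError):
    """A landscape or protocol parameter violates its contract."""


class LandscapeDomainError(ValueError):
    """A position lies outside the landscape's domain of definition."""


# integer codes shared with the numba kernels in pullsim
KIND_CODES = {"flat": 0, "harmonic": 1, "double_well": 2, "tabulated": 3}


def _quintic_smoothstep(s: np.ndarray) -> np.ndarray:
    # g(0)=0, g(1)=1, g'(0)=g'(1)=g''(0)=g''(1)=0
    return s * s * s * (10.0 + s * (-15.0 + 6.0 * s))


def _quintic_smoothstep_deriv(s: np.ndarray) -> np.ndarray:
    return 30.0 * s * s * (1.0 - s) * (1.0 - s)


@dataclass(frozen=True)
class ModelLandscape:
    """A one-dimensional free-energy surface U(x).

    Parameters are exact constructor inputs, not fits: for
    ``kind="double_well"`` the minima sit exactly at ``x_down`` /
    ``x_up`` with U(x_down)=0, U(x_up)=asymmetry, and the single
    interior maximum equals ``barrier`` at the midpoint between the
    wells.  Outside the wells the potential rises as a quartic wall, so
    the surface is confining and C² everywhere.
    """

    kind: str
    domain: tuple[float, float]
    x_down: float | None = None
    x_up: float | None = None
    barrier: float | None = None
    asymmetry: float | None = None
    kappa: float | None = None
    center: float | None = None
    table: tuple[tuple[float, float], ...] | None = None
    _spline: CubicSpline | None = field(default=None, repr=False, compare=False)

    # -- evaluation ---------------------------------------------------

    def _check_domain(self, x: np.ndarray) -> None:
        lo, hi = self.domain
        bad = (x < lo) | (x > hi) | ~np.isfinite(x)
        if np.any(bad):
            xb = np.atleast_1d(x)[np.atleast_1d(bad)][0]
            raise LandscapeDomainError(
                f"position {xb:g} outside landscape domain [{lo:g}, {hi:g}]"
            )

    def energy(self, x):
        """Potential energy U(x) in kcal/mol (vectorized)."""
        xa = np.asarray(x, dtype=float)
        self._check_domain(xa)
        if self.kind == "flat":
            out = np.zeros_like(xa)
        elif self.kind == "harmonic":
            out = 0.5 * self.kappa * (xa - self.center) ** 2
        elif self.kind == "double_well":
            out = self._dw_energy(xa)
        elif self.kind == "tabulated":
            out = self._spline(xa)
        else:  # pragma: no cover - constructors forbid this
            raise ParameterError(f"unknown landscape kind {self.kind!r}")
        return out if out.shape else float(out)

    def gradient(self, x):
        """Exact derivative dU/dx in kcal/mol/Å (vectorized)."""
        xa = np.asarray(x, dtype=float)
        self._check_domain(xa)
        if self.kind == "flat":
            out = np.zeros_like(xa)
        elif self.kind == "harmonic":
            out = self.kappa * (xa - self.center)
        elif self.kind == "double_well":
            out = self._dw_gradient(xa)
        elif self.kind == "tabulated":
            out = self._spline(xa, 1)
        else:  # pragma: no cover
            raise ParameterError(f"unknown landscape kind {self.kind!r}")
        return out if out.shape else float(out)

    @property
    def x_barrier(self) -> float:
        """Dividing point (interior maximum) of a double well."""
        if self.kind != "double_well":
            raise ParameterError("x_barrier is defined only for double wells")
        return 0.5 * (self.x_down + self.x_up)

    def _dw_pieces(self):
        xb = self.x_barrier
        w1 = xb - self.x_down
        w2 = self.x_up - xb
        c_left = self.barrier  # quartic wall, kcal/mol/Å^4
        c_right = self.barrier - self.asymmetry
        return xb, w1, w2, c_left, c_right

    def _dw_energy(self, x: np.ndarray) -> np.ndarray:
        xb, w1, w2, cl, cr = self._dw_pieces()
        xd, xu, b, a = self.x_down, self.x_up, self.barrier, self.asymmetry
        shape = x.shape
        x = np.atleast_1d(x)
        out = np.empty_like(x)
        m = x < xd
        out[m] = cl * (xd - x[m]) ** 4
        m = (x >= xd) & (x <= xb)
        out[m] = b * _quintic_smoothstep((x[m] - xd) / w1)
        m = (x > xb) & (x <= xu)
        out[m] = a + (b - a) * _quintic_smoothstep((xu - x[m]) / w2)
        m = x > xu
        out[m] = a + cr * (x[m] - xu) ** 4
        return out.reshape(shape)

    def _dw_gradient(self, x: np.ndarray) -> np.ndarray:
        xb, w1, w2, cl, cr = self._dw_pieces()
        xd, xu, b, a = self.x_down, self.x_up, self.barrier, self.asymmetry
        shape = x.shape
        x = np.atleast_1d(x)
        out = np.empty_like(x)
        m = x < xd
        out[m] = -4.0 * cl * (xd - x[m]) ** 3
        m = (x >= xd) & (x <= xb)
        out[m] = b * _quintic_smoothstep_deriv((x[m] - xd) / w1) / w1
        m = (x > xb) & (x <= xu)
        out[m] = -(b - a) * _quintic_smoothstep_deriv((xu - x[m]) / w2) / w2
        m = x > xu
        out[m] = 4.0 * cr * (x[m] - xu) ** 3
        return out.reshape(shape)

    # -- plumbing for the fast simulation kernels ----------------------

    def kernel_args(self):
        """Pack the landscape for the numba Langevin kernels.

        Returns ``(kind_code, params, knots, coeffs)`` with empty spline
        arrays for analytic kinds.
        """
        empty = np.empty(0, dtype=np.float64)
        empty2 = np.empty((4, 0), dtype=np.float64)
        code = KIND_CODES[self.kind]
        if self.kind == "flat":
            return code, empty, empty, empty2
        if self.kind == "harmonic":
            return code, np.array([self.center, self.kappa]), empty, empty2
        if self.kind == "double_well":
            xb, w1, w2, cl, cr = self._dw_pieces()
            p = np.array(
                [self.x_down, self.x_up, xb, w1, w2,
                 self.barrier, self.asymmetry, cl, cr]
            )
            return code, p, empty, empty2
        sp = self._spline
        return code, empty, np.asarray(sp.x, dtype=np.float64), np.asarray(
            sp.c, dtype=np.float64
        )

    def quad_breakpoints(self) -> list[float]:
        """Interior points where the potential changes analytic piece."""
        if self.kind == "double_well":
            return [self.x_down, self.x_barrier, self.x_up]
        if self.kind == "tabulated":
            return list(self._spline.x[1:-1:max(1, len(self._spline.x) // 40)])
        return []


@dataclass(frozen=True)
class IsoformPreset:
    """A named landscape standing in for one NOS isoform's Tyr gate."""

    name: str
    landscape: ModelLandscape
    notes: str = ""


def _require_finite(**kwargs) -> None:
    for k, v in kwargs.items():
        if not np.isfinite(v):
            raise ParameterError(f"{k} must be finite, got {v!r}")


def make_double_well(
    x_down: float,
    x_up: float,
    barrier: float,
    asymmetry: float = 0.0,
    domain: tuple[float, float] | None = None,
) -> ModelLandscape:
    """Construct a smooth double well with exact well/barrier parameters.

    ``U(x_down) = 0``, ``U(x_up) = asymmetry`` and the single interior
    maximum equals ``barrier`` (above the down well) at the midpoint.
    The inter-well shape is a quintic smoothstep blend (C² everywhere,
    flat-top barrier), with confining quartic walls outside the wells.
    """
    _require_finite(x_down=x_down, x_up=x_up, barrier=barrier, asymmetry=asymmetry)
    if not x_down < x_up:
        raise ParameterError(f"x_down ({x_down}) must be < x_up ({x_up})")
    if barrier <= 0:
        raise ParameterError(f"barrier must be positive, got {barrier}")
    if barrier + asymmetry <= 0 or barrier <= asymmetry:
        raise ParameterError(
            "up well must lie below the barrier top: require "
            f"-barrier < asymmetry < barrier (barrier={barrier}, asymmetry={asymmetry})"
        )
    if domain is None:
        domain = (x_down - 2.0, x_up + 2.0)
    lo, hi = domain
    if not (lo <= x_down - 2.0 + 1e-9 and hi >= x_up + 2.0 - 1e-9):
        raise ParameterError(
            f"domain {domain} must contain both wells with >= 2 Å margin"
        )
    return ModelLandscape(
        kind="double_well",
        domain=(float(lo), float(hi)),
        x_down=float(x_down),
        x_up=float(x_up),
        barrier=float(barrier),
        asymmetry=float(asymmetry),
    )


def make_harmonic(
    kappa: float, center: float = 0.0, domain: tuple[float, float] = (-10.0, 10.0)
) -> ModelLandscape:
    """Harmonic well U(x) = (kappa/2)(x - center)^2."""
    _require_finite(kappa=kappa, center=center)
    if kappa <= 0:
        raise ParameterError(f"kappa must be positive, got {kappa}")
    return ModelLandscape(
        kind="harmonic", domain=tuple(map(float, domain)), kappa=float(kappa),
        center=float(center),
    )


def make_flat(domain: tuple[float, float] = (-10.0, 10.0)) -> ModelLandscape:
    """Flat landscape U(x) = 0."""
    return ModelLandscape(kind="flat", domain=tuple(map(float, domain)))


def make_tabulated(points: Sequence[tuple[float, float]]) -> ModelLandscape:
    """Landscape interpolated through (position Å, energy kcal/mol) pairs.

    Cubic-spline (not-a-knot) interpolation; the domain is the tabulated
    range.
    """
    pts = sorted((float(x), float(u)) for x, u in points)
    if len(pts) < 4:
        raise ParameterError("tabulated landscape needs >= 4 points")
    xs = np.array([p[0] for p in pts])
    us = np.array([p[1] for p in pts])
    if not np.all(np.isfinite(xs)) or not np.all(np.isfinite(us)):
        raise ParameterError("tabulated points must be finite")
    if np.any(np.diff(xs) <= 0):
        raise ParameterError("tabulated positions must be strictly increasing")
    spline = CubicSpline(xs, us)
    return ModelLandscape(
        kind="tabulated",
        domain=(float(xs[0]), float(xs[-1])),
        table=tuple(pts),
        _spline=spline,
    )


def evaluate_landscape(landscape: ModelLandscape, x):
    """Return ``(energy, gradient)`` at x (scalar or array)."""
    return landscape.energy(x), landscape.gradient(x)


# ---------------------------------------------------------------------
# Exact quadrature oracles
# ---------------------------------------------------------------------

_QUAD_OPTS = dict(epsabs=1e-12, epsrel=1e-12, limit=200)


def _log_boltzmann_weight(
    landscape: ModelLandscape, lo: float, hi: float, kT: float,
    extra_potential=None, extra_breaks: Sequence[float] = (),
) -> float:
    """ln ∫_lo^hi exp(-(U(x)+extra(x))/kT) dx, computed stably.

    The minimum of the total potential on a scan grid is subtracted
    before exponentiation; integration runs piecewise between analytic
    breakpoints so the adaptive rule never misses a narrow feature.
    """
    if not (np.isfinite(lo) and np.isfinite(hi)) or lo >= hi:
        raise ParameterError(f"invalid integration interval [{lo}, {hi}]")
    dlo, dhi = landscape.domain
    if lo < dlo or hi > dhi:
        raise ParameterError(
            f"interval [{lo}, {hi}] not inside domain [{dlo}, {dhi}]"
        )

    def total(x):
        u = landscape.energy(x)
        if extra_potential is not None:
            u = u + extra_potential(x)
        return u

    breaks = sorted(
        {lo, hi}
        | {b for b in landscape.quad_breakpoints() if lo < b < hi}
        | {b for b in extra_breaks if lo < b < hi}
    )
    scan = np.unique(np.concatenate(
        [np.linspace(lo, hi, 1201)] +
        [np.linspace(max(lo, b - 0.05), min(hi, b + 0.05), 21) for b in breaks]
    ))
    shift = float(np.min(total(scan)))

    def integrand(x):
        return math.exp(-(float(total(x)) - shift) / kT)

    acc = 0.0
    for a, b in zip(breaks[:-1], breaks[1:]):
        val, _ = quad(integrand, a, b, **_QUAD_OPTS)
        acc += val
    if acc <= 0.0:  # pragma: no cover - confining potentials keep this positive
        raise ParameterError("Boltzmann weight underflowed to zero")
    return math.log(acc) - shift / kT


def exact_free_energy_difference(
    landscape: ModelLandscape,
    region_a: tuple[float, float],
    region_b: tuple[float, float],
    kT: float = thermal_energy(),
) -> float:
    """Exact ΔF = F(b) − F(a) = −kT ln(Z_b/Z_a) between two regions."""
    if kT <= 0:
        raise ParameterError(f"kT must be positive, got {kT}")
    log_za = _log_boltzmann_weight(landscape, *region_a, kT)
    log_zb = _log_boltzmann_weight(landscape, *region_b, kT)
    return -kT * (log_zb - log_za)


def exact_restrained_profile(
    landscape: ModelLandscape,
    z_grid: Sequence[float],
    k_spring: float,
    kT: float = thermal_energy(),
) -> np.ndarray:
    """Free energy F(z) of the harmonically restrained system.

    F(z) = −kT ln ∫ exp(−[U(x) + (k/2)(x−z)²]/kT) dx, gauged so that
    F(z_grid[0]) = 0.  This is the quantity a stiff-spring pulling
    estimator (Jarzynski average of restraint work) recovers, and it
    converges to U(z) − U(z₀) as k_spring → ∞.
    """
    if k_spring <= 0:
        raise ParameterError(f"k_spring must be positive, got {k_spring}")
    if kT <= 0:
        raise ParameterError(f"kT must be positive, got {kT}")
    z_grid = np.asarray(z_grid, dtype=float)
    lo, hi = landscape.domain
    sigma = math.sqrt(kT / k_spring)
    out = np.empty_like(z_grid)
    for i, z in enumerate(z_grid):
        if z < lo or z > hi:
            raise ParameterError(f"z={z:g} outside domain [{lo:g}, {hi:g}]")
        spring = lambda x, z=z: 0.5 * k_spring * (np.asarray(x) - z) ** 2
        breaks = [z - 10 * sigma, z - sigma, z, z + sigma, z + 10 * sigma]
        out[i] = -kT * _log_boltzmann_weight(
            landscape, lo, hi, kT, extra_potential=spring, extra_breaks=breaks
        )
    return out - out[0]


def boltzmann_population(
    landscape: ModelLandscape,
    region: tuple[float, float],
    kT: float = thermal_energy(),
) -> float:
    """Equilibrium probability of finding the coordinate in ``region``."""
    if kT <= 0:
        raise ParameterError(f"kT must be positive, got {kT}")
    log_zr = _log_boltzmann_weight(landscape, *region, kT)
    log_z = _log_boltzmann_weight(landscape, *landscape.domain, kT)
    return math.exp(log_zr - log_z)


# ---------------------------------------------------------------------
# Isoform presets
# ---------------------------------------------------------------------

#: Down-well position (Å): a donor--acceptor hydrogen-bond distance.
PRESET_X_DOWN = 2.8
#: Up-well position: the down position plus the ~7 Å gate displacement.
PRESET_X_UP = 9.8
PRESET_DOMAIN = (0.8, 11.8)
#: Barrier of the more mobile ("nNOS-like") gate, kcal/mol.
PRESET_BASE_BARRIER = 8.0
#: Default extra barrier of the stiffer ("eNOS-like") gate, kcal/mol.
PRESET_BARRIER_DELTA = 5.0


def isoform_presets(barrier_delta: float = PRESET_BARRIER_DELTA) -> dict[str, IsoformPreset]:
    """The two standard gate presets contrasted throughout the package.

    The eNOS-like gate is ``barrier_delta`` kcal/mol harder to open than
    the nNOS-like one (default 5.0, the midpoint of the reported 4–6
    kcal/mol excess), and holds its down state more firmly (larger
    up-state offset).  Both place the up state several kT above the
    down state so that equilibrium occupancy is dominated by the down
    basin, the regime an overdamped run can actually sample.
    """
    nnos = make_double_well(
        PRESET_X_DOWN, PRESET_X_UP,
        barrier=PRESET_BASE_BARRIER, asymmetry=4.0, domain=PRESET_DOMAIN,
    )
    enos = make_double_well(
        PRESET_X_DOWN, PRESET_X_UP,
        barrier=PRESET_BASE_BARRIER + barrier_delta, asymmetry=6.0,
        domain=PRESET_DOMAIN,
    )
    return {
        "nNOS-like": IsoformPreset(
            "nNOS-like", nnos,
            notes="mobile gate: lower rotation barrier, shallower down well",
        ),
        "eNOS-like": IsoformPreset(
            "eNOS-like", enos,
            notes="rigid gate: second-shell packing encoded as +{:g} kcal/mol "
                  "barrier and a deeper down well".format(barrier_delta),
        ),
    }


# ---------------------------------------------------------------------
# Tabulated-landscape I/O
# ---------------------------------------------------------------------

_TAB_HEADER = "position_A\tenergy_kcal_mol"


def write_tabulated_tsv(landscape: ModelLandscape, path) -> None:
    """Write a tabulated landscape as 2-column TSV with header."""
    if landscape.kind != "tabulated":
        raise ParameterError("only tabulated landscapes have a table to write")
    lines = [_TAB_HEADER]
    lines += [f"{x:.10g}\t{u:.10g}" for x, u in landscape.table]
    Path(path).write_text("\n".join(lines) + "\n")


def read_tabulated_tsv(path) -> ModelLandscape:
    """Read a tabulated landscape written by :func:`write_tabulated_tsv`."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != _TAB_HEADER.split("\t"):
        raise ParameterError(f"{path}: missing header line {_TAB_HEADER!r}")
    pts = []
    for ln_no, ln in enumerate(lines[1:], start=2):
        if not ln.strip():
            continue
        cells = ln.split("\t")
        try:
            pts.append((float(cells[0]), float(cells[1])))
        except (ValueError, IndexError) as exc:
            raise ParameterError(f"{path}: bad table row at line {ln_no}: {ln!r}") from exc
    return make_tabulated(pts)
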