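"""Jarzynski work analysis: pull traces → work curves → PMF profiles.

The external work done by a moving harmonic restraint is
``W(t) = ∫₀ᵗ k·v·(z_c(t') − x(t')) dt'``; accumulated along each pull
and resampled onto a shared grid of restraint-center positions it forms
a :class:`WorkSet`.  The Jarzynski equality
``exp(−ΔF/kT) = ⟨exp(−W/kT)⟩`` turns the nonequilibrium work ensemble
into the free energy of the restrained system ("stiff-spring" PMF),
estimated here with a log-sum-exp stabilized sample average.  A
second-cumulant companion (exact for Gaussian work) and the plain mean
work are available under the same interface, with percentile bootstrap
bands obtained by resampling replicas within each active site.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.special import logsumexp

from .landscapes import ParameterError
from .pullsim import PullTrace, rng_stream

__all__ = [
    "DEFAULT_Z_SPACING",
    "WorkSet",
    "PMFProfile",
    "PMFComparison",
    "default_z_grid",
    "accumulate_work",
    "build_workset",
    "jarzynski_pmf",
    "cumulant2_pmf",
    "mean_work_pmf",
    "bootstrap_pmf_ci",
    "compare_total_pmf",
    "write_workset_tsv",
    "read_workset_tsv",
    "write_profile_tsv",
    "read_profile_tsv",
]

#: Shared work/PMF grid spacing, Å (71 points across the 7 Å pull).
DEFAULT_Z_SPACING = 0.1

_ESTIMATORS = ("jarzynski", "cumulant2", "mean_work")
_TOTAL_DEFINITIONS = ("endpoint", "profile_max")


@dataclass(frozen=True)
class WorkSet:
    """Per-replica accumulated-work curves W_i(z_j) on a shared grid."""

    z_grid: np.ndarray                 # Å, ascending, z_grid[0] = pull start
    works: np.ndarray                  # (n_replicas, n_grid) kcal/mol
    labels: tuple[tuple, ...]          # per-row (replicate_id, site_id, run_id)
    kT: float

    def __post_init__(self):
        z = np.asarray(self.z_grid, float)
        w = np.asarray(self.works, float)
        if w.ndim != 2 or w.shape[1] != z.size:
            raise ParameterError("works must be (n_replicas, len(z_grid))")
        if np.any(np.diff(z) <= 0):
            raise ParameterError("z_grid must be strictly increasing")
        if self.kT <= 0:
            raise ParameterError("kT must be positive")
        if not np.all(np.isfinite(w)):
            bad = int(np.where(~np.all(np.isfinite(w), axis=1))[0][0])
            raise ParameterError(f"non-finite work in replica row {bad} "
                                 f"(label {self.labels[bad]})")
        if np.any(np.abs(w[:, 0]) > 1e-9):
            raise ParameterError("W(z_grid[0]) must be 0 for every replica")
        if len(self.labels) != w.shape[0]:
            raise ParameterError("one label per work row required")

    @property
    def n_traces(self) -> int:
        return self.works.shape[0]

    @property
    def sites(self) -> tuple:
        return tuple(dict.fromkeys(lbl[1] for lbl in self.labels))


@dataclass(frozen=True)
class PMFProfile:
    """Estimated ΔF(z), gauged to 0 at the first grid point."""

    z_grid: np.ndarray
    delta_f: np.ndarray               # kcal/mol
    estimator: str
    n_traces: int
    kT: float
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    boot_totals: dict[str, np.ndarray] | None = None  # bootstrap scalar totals

    def total(self, definition: str = "endpoint") -> float:
        """Scalar 'PMF to complete the movement' under the chosen definition."""
        if definition == "endpoint":
            return float(self.delta_f[-1])
        if definition == "profile_max":
            return float(np.max(self.delta_f))
        raise ParameterError(f"unknown definition_of_total {definition!r}")


@dataclass(frozen=True)
class PMFComparison:
    """Per-site totals of two systems and their (B − A) differences."""

    totals_a: dict
    totals_b: dict
    differences: dict
    mean_difference: float
    definition_of_total: str
    ci_low: float | None = None
    ci_high: float | None = None


# ---------------------------------------------------------------------
# Work accumulation
# ---------------------------------------------------------------------

def default_z_grid(start: float, displacement: float,
                   spacing: float = DEFAULT_Z_SPACING) -> np.ndarray:
    """Shared grid of restraint-center positions from start to start+L."""
    n = round(displacement / spacing)
    if abs(n * spacing - displacement) > 1e-9:
        raise ParameterError("displacement must be a multiple of the grid spacing")
    return start + spacing * np.arange(n + 1)


def accumulate_work(trace: PullTrace, z_grid: np.ndarray | None = None) -> np.ndarray:
    """External restraint work W(z) along one pull, trapezoid-accumulated.

    ``Ẇ = k·v·(z_c − x)`` is integrated over the recorded (uniform)
    time grid and resampled by linear interpolation onto ``z_grid``
    (default: the trace's own 0.1 Å grid).  W at the pull start is 0.
    """
    dts = np.diff(trace.times)
    if dts.size == 0:
        raise ParameterError("pull trace must hold more than one sample")
    if np.any(np.abs(dts - dts[0]) > 1e-9 * max(1.0, abs(dts[0]))):
        raise ParameterError("pull trace has non-uniform time spacing")
    vel_ps = trace.protocol.velocity / 1000.0
    power = trace.protocol.spring * vel_ps * (trace.center - trace.positions)
    w_t = cumulative_trapezoid(power, trace.times, initial=0.0)
    if z_grid is None:
        z_grid = default_z_grid(trace.start, trace.protocol.displacement)
    z_grid = np.asarray(z_grid, float)
    z_lo, z_hi = trace.center[0], trace.center[-1]
    if z_grid[0] < z_lo - 1e-9 or z_grid[-1] > z_hi + 1e-9:
        raise ParameterError(
            f"requested grid [{z_grid[0]:g}, {z_grid[-1]:g}] outside the pulled "
            f"range [{z_lo:g}, {z_hi:g}]"
        )
    return np.interp(z_grid, trace.center, w_t)


def build_workset(traces: Sequence[PullTrace],
                  z_grid: np.ndarray | None = None) -> WorkSet:
    """Stack pull traces into a WorkSet on a common grid."""
    if not traces:
        raise ParameterError("no pull traces supplied")
    t0 = traces[0]
    if z_grid is None:
        z_grid = default_z_grid(t0.start, t0.protocol.displacement)
    works = np.vstack([accumulate_work(tr, z_grid) for tr in traces])
    labels = tuple(
        (tr.replicate_id, tr.site_id, getattr(tr, "run_id", None)) for tr in traces
    )
    return WorkSet(z_grid=np.asarray(z_grid, float), works=works,
                   labels=labels, kT=t0.protocol.kT)


# ---------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------

def _estimate(works: np.ndarray, kT: float, estimator: str) -> np.ndarray:
    n = works.shape[0]
    if estimator == "jarzynski":
        # -kT ln (1/N) sum exp(-W/kT), stabilized: logsumexp subtracts the
        # column-wise minimum work internally.
        return -kT * (logsumexp(-works / kT, axis=0) - np.log(n))
    if estimator == "cumulant2":
        if n < 2:
            raise ParameterError("cumulant2 needs >= 2 replicas")
        return works.mean(axis=0) - works.var(axis=0, ddof=1) / (2.0 * kT)
    if estimator == "mean_work":
        return works.mean(axis=0)
    raise ParameterError(f"unknown estimator {estimator!r}")


def jarzynski_pmf(workset: WorkSet) -> PMFProfile:
    """PMF from the Jarzynski average over the work ensemble."""
    if workset.n_traces < 1:
        raise ParameterError("empty workset")
    df = _estimate(workset.works, workset.kT, "jarzynski")
    return PMFProfile(workset.z_grid, df, "jarzynski", workset.n_traces, workset.kT)


def cumulant2_pmf(workset: WorkSet) -> PMFProfile:
    """Second-cumulant PMF, ⟨W⟩ − Var(W)/(2kT) (exact for Gaussian work)."""
    df = _estimate(workset.works, workset.kT, "cumulant2")
    return PMFProfile(workset.z_grid, df, "cumulant2", workset.n_traces, workset.kT)


def mean_work_pmf(workset: WorkSet) -> PMFProfile:
    """Mean work profile (an upper bound on the free energy)."""
    df = _estimate(workset.works, workset.kT, "mean_work")
    return PMFProfile(workset.z_grid, df, "mean_work", workset.n_traces, workset.kT)


def bootstrap_pmf_ci(
    workset: WorkSet,
    estimator: str = "jarzynski",
    n_boot: int = 1000,
    seed: int = 0,
) -> PMFProfile:
    """Percentile bootstrap band, resampling replicas within each site.

    Replicas (not time points) are the independent units; resampling is
    stratified by site label.  Also records the bootstrap distribution
    of both scalar totals for downstream comparison CIs.
    """
    if estimator not in _ESTIMATORS:
        raise ParameterError(f"unknown estimator {estimator!r}")
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    rng = rng_stream(seed, "bootstrap_pmf", estimator)
    site_rows = {}
    for i, lbl in enumerate(workset.labels):
        site_rows.setdefault(lbl[1], []).append(i)
    groups = [np.array(rows) for rows in site_rows.values()]
    point = _estimate(workset.works, workset.kT, estimator)
    curves = np.empty((n_boot, workset.z_grid.size))
    for b in range(n_boot):
        rows = np.concatenate(
            [g[rng.integers(0, g.size, g.size)] for g in groups]
        )
        curves[b] = _estimate(workset.works[rows], workset.kT, estimator)
    lo = np.percentile(curves, 2.5, axis=0)
    hi = np.percentile(curves, 97.5, axis=0)
    # the percentile band is widened, if needed, to bracket the point estimate
    lo = np.minimum(lo, point)
    hi = np.maximum(hi, point)
    boot_totals = {
        "endpoint": curves[:, -1].copy(),
        "profile_max": curves.max(axis=1),
    }
    return PMFProfile(
        workset.z_grid, point, estimator, workset.n_traces, workset.kT,
        ci_low=lo, ci_high=hi, boot_totals=boot_totals,
    )


def compare_total_pmf(
    profiles_a: dict,
    profiles_b: dict,
    definition_of_total: str = "endpoint",
) -> PMFComparison:
    """Per-site scalar PMF totals of system B minus system A.

    ``profiles_a`` / ``profiles_b`` map matching site labels to
    :class:`PMFProfile`.  When both sides carry bootstrap totals of
    equal length, a percentile CI of the mean difference is propagated
    by pairing bootstrap draws across the independent ensembles.
    """
    if definition_of_total not in _TOTAL_DEFINITIONS:
        raise ParameterError(f"unknown definition_of_total {definition_of_total!r}")
    if set(profiles_a) != set(profiles_b):
        raise ParameterError(
            f"site labels differ: {sorted(map(str, profiles_a))} vs "
            f"{sorted(map(str, profiles_b))}"
        )
    sites = list(profiles_a)
    totals_a = {s: profiles_a[s].total(definition_of_total) for s in sites}
    totals_b = {s: profiles_b[s].total(definition_of_total) for s in sites}
    diffs = {s: totals_b[s] - totals_a[s] for s in sites}
    mean_diff = float(np.mean(list(diffs.values())))
    ci_low = ci_high = None
    have_boot = all(
        p.boot_totals is not None for p in (*profiles_a.values(), *profiles_b.values())
    )
    if have_boot:
        lengths = {
            p.boot_totals[definition_of_total].size
            for p in (*profiles_a.values(), *profiles_b.values())
        }
        if len(lengths) == 1:
            stack = np.mean(
                [
                    profiles_b[s].boot_totals[definition_of_total]
                    - profiles_a[s].boot_totals[definition_of_total]
                    for s in sites
                ],
                axis=0,
            )
            ci_low = float(np.percentile(stack, 2.5))
            ci_high = float(np.percentile(stack, 97.5))
    return PMFComparison(
        totals_a=totals_a, totals_b=totals_b, differences=diffs,
        mean_difference=mean_diff, definition_of_total=definition_of_total,
        ci_low=ci_low, ci_high=ci_high,
    )


# ---------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------

def write_workset_tsv(workset: WorkSet, path) -> None:
    """WorkSet as TSV: z_A then one column per replica (rep<k>_site<s>)."""
    cols = [f"rep{lbl[0]}_site{lbl[1]}" for lbl in workset.labels]
    lines = [f"# kT_kcal_mol: {workset.kT:.10g}", "z_A\t" + "\t".join(cols)]
    for j, z in enumerate(workset.z_grid):
        row = "\t".join(f"{w:.8g}" for w in workset.works[:, j])
        lines.append(f"{z:.6g}\t{row}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_workset_tsv(path) -> WorkSet:
    """Read a WorkSet written by :func:`write_workset_tsv`."""
    lines = Path(path).read_text().splitlines()
    kT = None
    body = []
    for ln in lines:
        if ln.startswith("# kT_kcal_mol:"):
            kT = float(ln.split(":", 1)[1])
        elif ln.strip() and not ln.startswith("#"):
            body.append(ln)
    if kT is None or not body:
        raise ParameterError(f"{path}: not a WorkSet TSV")
    header = body[0].split("\t")
    labels = []
    for col in header[1:]:
        rep, site = col.split("_site")
        labels.append((rep.removeprefix("rep"), site, None))
    data = np.array([[float(c) for c in ln.split("\t")] for ln in body[1:]])
    return WorkSet(z_grid=data[:, 0], works=data[:, 1:].T,
                   labels=tuple(labels), kT=kT)


def write_profile_tsv(profile: PMFProfile, path) -> None:
    """PMFProfile as TSV: z_A, dF_kcal_mol, ci_low, ci_high."""
    lines = [
        f"# estimator: {profile.estimator}",
        f"# n_traces: {profile.n_traces}",
        f"# kT_kcal_mol: {profile.kT:.10g}",
        "z_A\tdF_kcal_mol\tci_low\tci_high",
    ]
    lo = profile.ci_low if profile.ci_low is not None else [float("nan")] * len(profile.z_grid)
    hi = profile.ci_high if profile.ci_high is not None else [float("nan")] * len(profile.z_grid)
    for z, f, a, b in zip(profile.z_grid, profile.delta_f, lo, hi):
        lines.append(f"{z:.6g}\t{f:.8g}\t{a:.8g}\t{b:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile_tsv(path) -> PMFProfile:
    """Read a PMFProfile written by :func:`write_profile_tsv`."""
    lines = Path(path).read_text().splitlines()
    meta = {}
    body = []
    for ln in lines:
        if ln.startswith("# "):
            k, v = ln[2:].split(":", 1)
            meta[k.strip()] = v.strip()
        elif ln.strip():
            body.append(ln)
    data = np.array([[float(c) for c in ln.split("\t")] for ln in body[1:]])
    lo, hi = data[:, 2], data[:, 3]
    has_ci = not np.all(np.isnan(lo))
    return PMFProfile(
        z_grid=data[:, 0], delta_f=data[:, 1],
        estimator=meta.get("estimator", "jarzynski"),
        n_traces=int(meta.get("n_traces", 0)),
        kT=float(meta.get("kT_kcal_mol", 0.5961612))
        , ci_low=lo if has_ci else None, ci_high=hi if has_ci else None,
    )
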