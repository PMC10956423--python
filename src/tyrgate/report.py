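"""End-to-end two-system comparison workflow, configuration and reports.

``run_demo_workflow`` mirrors the study design on synthetic data: for
each of two gate presets and each active site it (1) runs equilibrium
monitoring and computes the sub-cutoff distance occupancy with a block
bootstrap CI, (2) runs a production trajectory, harvests pull starts
off its tail, performs the steered-pull ensemble, and estimates the
Jarzynski PMF with a replica bootstrap, then (3) pools occupancies per
system and compares per-site PMF totals between the systems.  The whole
workflow is a pure function of its TOML-serializable configuration
(including the master seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import tomllib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from . import __version__
from .landscapes import (
    ModelLandscape,
    ParameterError,
    isoform_presets,
    make_double_well,
    thermal_energy,
)
from .pullsim import (
    EquilibriumProtocol,
    PullProtocol,
    harvest_starting_points,
    planned_frame_count,
    simulate_equilibrium,
    simulate_pull,
    write_equilibrium_tsv,
)
from .freenergy import (
    bootstrap_pmf_ci,
    build_workset,
    compare_total_pmf,
    default_z_grid,
    write_profile_tsv,
    write_workset_tsv,
)
from .occupancy import (
    DEFAULT_CUTOFF,
    block_bootstrap_occupancy_ci,
    occupancy_fraction,
    series_from_equilibrium_trace,
    write_occupancy_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationError",
    "SystemSpec",
    "AnalysisOptions",
    "RunConfig",
    "ComparisonReport",
    "parse_config",
    "default_config",
    "run_demo_workflow",
    "write_report",
    "validate_report",
]


class ConfigurationError(ValueError):
    """A configuration file violates the schema or an invariant."""


@dataclass(frozen=True)
class SystemSpec:
    """One compared system: a named preset or an explicit double well."""

    name: str
    preset: str | None = "nNOS-like"
    landscape: dict | None = None

    def build(self) -> ModelLandscape:
        if self.landscape is not None:
            kw = dict(self.landscape)
            if "domain" in kw:
                kw["domain"] = tuple(kw["domain"])
            return make_double_well(**kw)
        presets = isoform_presets()
        if self.preset not in presets:
            raise ConfigurationError(
                f"unknown preset {self.preset!r}; choose from {sorted(presets)}"
            )
        return presets[self.preset].landscape


@dataclass(frozen=True)
class AnalysisOptions:
    cutoff: float = DEFAULT_CUTOFF
    estimator: str = "jarzynski"
    definition_of_total: str = "endpoint"
    n_boot: int = 200
    block_length: int | None = None
    production_ns: float = 20.0   # pre-pull NVT-like production run

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConfigurationError("analysis.cutoff must be positive")
        if self.n_boot < 100:
            raise ConfigurationError("analysis.n_boot must be >= 100")
        if self.production_ns <= 0:
            raise ConfigurationError("analysis.production_ns must be positive")


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one comparison run."""

    system_a: SystemSpec = field(default_factory=lambda: SystemSpec("nNOS-like"))
    system_b: SystemSpec = field(
        default_factory=lambda: SystemSpec("eNOS-like", preset="eNOS-like")
    )
    equilibrium: EquilibriumProtocol = field(default_factory=EquilibriumProtocol)
    pull: PullProtocol = field(default_factory=PullProtocol)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    master_seed: int = 0
    outdir: str = "tyrgate_out"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# TOML schema: section -> (target, field renames)
_EQ_KEYS = {
    "duration_ns": "duration", "snapshot_interval_ps": "snapshot_interval",
    "n_runs": "n_runs", "n_sites": "n_sites", "temperature_K": "temperature",
    "diffusion_A2_per_ps": "diffusion", "timestep_ps": "timestep",
}
_PULL_KEYS = {
    "velocity_A_per_ns": "velocity", "duration_ns": "duration",
    "spring_kcal_mol_A2": "spring", "n_traces": "n_traces",
    "harvest_window_ns": "harvest_window", "temperature_K": "temperature",
    "diffusion_A2_per_ps": "diffusion", "timestep_ps": "timestep",
    "record_stride": "record_stride",
}
_ANALYSIS_KEYS = {
    "cutoff_A": "cutoff", "estimator": "estimator",
    "definition_of_total": "definition_of_total", "n_boot": "n_boot",
    "block_length": "block_length", "production_ns": "production_ns",
}
_SYSTEM_KEYS = {"preset": "preset", "landscape": "landscape"}
_TOP_KEYS = {"master_seed", "outdir", "system_a", "system_b",
             "equilibrium", "pull", "analysis"}


def _build_section(section: str, data: dict, keymap: dict) -> dict:
    out = {}
    for key, value in data.items():
        if key not in keymap:
            raise ConfigurationError(f"unknown key {section}.{key}")
        out[keymap[key]] = value
    return out


def _parse_system(name: str, data: dict) -> SystemSpec:
    kw = _build_section(name, data, _SYSTEM_KEYS)
    if "landscape" in kw and "preset" in kw:
        raise ConfigurationError(f"{name}: give either preset or landscape, not both")
    if "landscape" in kw:
        return SystemSpec(name=name, preset=None, landscape=kw["landscape"])
    return SystemSpec(name=name, preset=kw.get("preset", name.removeprefix("system_")))


def default_config(master_seed: int = 0) -> RunConfig:
    """Study-protocol defaults: 7 Å/ns, 10 kcal/mol/Å², 100 traces,
    200 ns monitoring at 20 ps snapshots over 2 runs × 2 sites, 4.0 Å cutoff."""
    return RunConfig(
        system_a=SystemSpec("system_a", preset="nNOS-like"),
        system_b=SystemSpec("system_b", preset="eNOS-like"),
        master_seed=master_seed,
    )


def parse_config(path) -> RunConfig:
    """Parse a TOML configuration, applying protocol defaults.

    Unknown keys are rejected with their dotted path; every nested
    protocol's invariants are validated at construction time.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown key {sorted(unknown)[0]}")
    seed = raw.get("master_seed", 0)
    if not isinstance(seed, int):
        raise ConfigurationError("master_seed must be an integer")
    try:
        eq = EquilibriumProtocol(
            seed=seed, **_build_section("equilibrium", raw.get("equilibrium", {}), _EQ_KEYS)
        )
    except ParameterError as exc:
        raise ConfigurationError(f"protocol.equilibrium: {exc}") from exc
    try:
        pull = PullProtocol(
            seed=seed, **_build_section("pull", raw.get("pull", {}), _PULL_KEYS)
        )
    except ParameterError as exc:
        key = "spring" if "spring" in str(exc) else "pull"
        raise ConfigurationError(f"protocol.pull.{key}: {exc}") from exc
    analysis = AnalysisOptions(
        **_build_section("analysis", raw.get("analysis", {}), _ANALYSIS_KEYS)
    )
    return RunConfig(
        system_a=_parse_system("system_a", raw.get("system_a", {"preset": "nNOS-like"})),
        system_b=_parse_system("system_b", raw.get("system_b", {"preset": "eNOS-like"})),
        equilibrium=eq,
        pull=pull,
        analysis=analysis,
        master_seed=seed,
        outdir=raw.get("outdir", "tyrgate_out"),
    )


def scale_down(config: RunConfig, monitoring_ns: float = 20.0) -> RunConfig:
    """Desk-scale variant of a config: shorter equilibrium monitoring."""
    eq = dataclasses.replace(config.equilibrium, duration=monitoring_ns)
    return dataclasses.replace(config, equilibrium=eq)


@dataclass(frozen=True)
class ComparisonReport:
    """All quantities of one two-system comparison plus provenance."""

    occupancy: dict            # system -> {per_group: [...], pooled: {...}}
    pmf: dict                  # system -> {site: {total_*, profile artifact}}
    comparison: dict           # PMFComparison as plain dict
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "occupancy": self.occupancy,
            "pmf": self.pmf,
            "comparison": self.comparison,
            "provenance": self.provenance,
        }


def _occupancy_dict(r) -> dict:
    return {
        "fraction": r.fraction,
        "n_frames": r.n_frames,
        "n_occupied": r.n_occupied,
        "cutoff_A": r.cutoff,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "groups": [[str(g[0]), str(g[1])] for g in r.groups],
    }


def run_demo_workflow(config: RunConfig, write_artifacts: bool = True) -> ComparisonReport:
    """Execute the full two-system comparison described by ``config``."""
    outdir = Path(config.outdir)
    if write_artifacts:
        outdir.mkdir(parents=True, exist_ok=True)
    systems = {"system_a": config.system_a, "system_b": config.system_b}
    sites = [chr(ord("A") + i) for i in range(config.equilibrium.n_sites)]
    seed = config.master_seed
    occupancy_block: dict = {}
    pmf_block: dict = {}
    profiles: dict[str, dict] = {}
    artifacts: dict[str, str] = {}
    t_start = time.perf_counter()

    for sys_name, spec in systems.items():
        landscape = spec.build()
        # streams are keyed by the system's *content*, so two slots holding
        # the identical preset see identical noise and differ by exactly 0.
        sys_token = _system_token(spec)
        eqp = dataclasses.replace(
            config.equilibrium, seed=_derive_seed(seed, sys_token, "equilibrium")
        )
        # --- equilibrium monitoring & occupancy -----------------------
        t0 = time.perf_counter()
        series = []
        eq_traces = []
        per_group = []
        for site in sites:
            for run in range(1, eqp.n_runs + 1):
                tr = simulate_equilibrium(
                    landscape, eqp, start=landscape.x_down, run_id=run, site_id=site
                )
                s = series_from_equilibrium_trace(tr)
                eq_traces.append(tr)
                series.append(s)
                per_group.append(occupancy_fraction(s, config.analysis.cutoff))
        pooled = block_bootstrap_occupancy_ci(
            series,
            cutoff=config.analysis.cutoff,
            block_length=config.analysis.block_length,
            n_boot=config.analysis.n_boot,
            seed=_derive_seed(seed, sys_token, "occupancy_boot"),
        )
        if write_artifacts:
            eq_path = outdir / f"{sys_name}_equilibrium.tsv"
            write_equilibrium_tsv(eq_traces, eq_path)
            artifacts[f"{sys_name}_equilibrium"] = eq_path.name
        if write_artifacts:
            occ_path = outdir / f"{sys_name}_occupancy.tsv"
            write_occupancy_tsv([*per_group, pooled], occ_path)
            artifacts[f"{sys_name}_occupancy"] = occ_path.name
        occupancy_block[sys_name] = {
            "per_group": [_occupancy_dict(r) for r in per_group],
            "pooled": _occupancy_dict(pooled),
        }
        logger.info("%s occupancy done in %.1f s", sys_name, time.perf_counter() - t0)

        # --- production, harvest, pulls, PMF --------------------------
        t0 = time.perf_counter()
        profiles[sys_name] = {}
        pmf_block[sys_name] = {}
        for site in sites:
            prod_protocol = EquilibriumProtocol(
                duration=config.analysis.production_ns,
                snapshot_interval=config.equilibrium.snapshot_interval,
                n_runs=1,
                n_sites=1,
                temperature=config.pull.temperature,
                diffusion=config.pull.diffusion,
                timestep=config.pull.timestep,
                seed=_derive_seed(seed, sys_token, "production", site),
            )
            prod = simulate_equilibrium(
                landscape, prod_protocol, start=landscape.x_down,
                run_id="production", site_id=site,
            )
            starts = harvest_starting_points(
                prod, config.pull.n_traces, config.pull.harvest_window
            )
            pullp = dataclasses.replace(
                config.pull, seed=_derive_seed(seed, sys_token, "pull", site)
            )
            z_grid = default_z_grid(landscape.x_down, pullp.displacement)
            # all replicas share the schedule anchored at the down well;
            # each harvested snapshot supplies only the initial coordinate.
            traces = [
                simulate_pull(landscape, pullp, start=x0, replicate_id=k,
                              site_id=site, z_start=landscape.x_down)
                for k, x0 in enumerate(starts)
            ]
            ws = build_workset(traces, z_grid)
            profile = bootstrap_pmf_ci(
                ws,
                estimator=config.analysis.estimator,
                n_boot=max(100, config.analysis.n_boot),
                seed=_derive_seed(seed, sys_token, "pmf_boot", site),
            )
            profiles[sys_name][site] = profile
            if write_artifacts:
                ws_path = outdir / f"{sys_name}_site{site}_workset.tsv"
                write_workset_tsv(ws, ws_path)
                pr_path = outdir / f"{sys_name}_site{site}_pmf.tsv"
                write_profile_tsv(profile, pr_path)
                artifacts[f"{sys_name}_site{site}_workset"] = ws_path.name
                artifacts[f"{sys_name}_site{site}_pmf"] = pr_path.name
            pmf_block[sys_name][site] = {
                "total_endpoint_kcal_mol": profile.total("endpoint"),
                "total_profile_max_kcal_mol": profile.total("profile_max"),
                "n_traces": profile.n_traces,
            }
        logger.info("%s PMF done in %.1f s", sys_name, time.perf_counter() - t0)

    comparison = compare_total_pmf(
        profiles["system_a"], profiles["system_b"],
        definition_of_total=config.analysis.definition_of_total,
    )
    comp_dict = {
        "definition_of_total": comparison.definition_of_total,
        "totals_a": {str(k): v for k, v in comparison.totals_a.items()},
        "totals_b": {str(k): v for k, v in comparison.totals_b.items()},
        "differences": {str(k): v for k, v in comparison.differences.items()},
        "mean_difference_kcal_mol": comparison.mean_difference,
        "ci_low": comparison.ci_low,
        "ci_high": comparison.ci_high,
    }
    provenance = {
        "package": "tyrgate",
        "version": __version__,
        "master_seed": seed,
        "temperature_K": config.equilibrium.temperature,
        "kT_kcal_mol": thermal_energy(config.equilibrium.temperature),
        "planned_monitoring_frames": planned_frame_count(config.equilibrium),
        "config": config.to_dict(),
        "artifacts": artifacts,
        "elapsed_s": round(time.perf_counter() - t_start, 3),
    }
    return ComparisonReport(
        occupancy=occupancy_block, pmf=pmf_block, comparison=comp_dict,
        provenance=provenance,
    )


def _system_token(spec: SystemSpec) -> str:
    """Content-based identity of a system for seed derivation."""
    if spec.landscape is not None:
        return "landscape:" + repr(sorted(spec.landscape.items()))
    return "preset:" + str(spec.preset)


def _derive_seed(master: int, *tokens) -> int:
    """Stable 31-bit sub-seed for one workflow stage."""
    from .pullsim import _token_int

    h = master & 0x7FFFFFFF
    for t in tokens:
        h = (h * 1000003 + _token_int(t)) & 0x7FFFFFFF
    return h


def _common_grid(z_grid: np.ndarray, traces) -> np.ndarray:
    lo = max(tr.center[0] for tr in traces)
    hi = min(tr.center[-1] for tr in traces)
    keep = (z_grid >= lo - 1e-9) & (z_grid <= hi + 1e-9)
    if not np.any(keep):
        raise ParameterError("pull ensembles share no common center range")
    return z_grid[keep]


# ---------------------------------------------------------------------
# Report output & validation
# ---------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, tuple):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_report(report: ComparisonReport, outdir, plots: bool = False) -> Path:
    """Write report.json (and optional plots); returns the JSON path.

    The payload excludes wall-clock timing so regeneration from the same
    config is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = report.to_json_dict()
    payload["provenance"] = {
        k: v for k, v in payload["provenance"].items() if k != "elapsed_s"
    }
    validate_report(payload)
    path = outdir / "report.json"
    path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    if plots:
        _write_plots(report, outdir)
    return path


def _write_plots(report: ComparisonReport, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    for sys_name, block in report.pmf.items():
        for site, vals in block.items():
            ax1.plot(
                [], [], label=f"{sys_name} site {site}: "
                f"{vals['total_endpoint_kcal_mol']:.2f} kcal/mol"
            )
    ax1.set_title("PMF totals (endpoint)")
    ax1.legend(fontsize=7)
    names, fracs = [], []
    for sys_name, block in report.occupancy.items():
        names.append(sys_name)
        fracs.append(block["pooled"]["fraction"])
    ax2.bar(names, fracs)
    ax2.set_ylabel("fraction of frames ≤ cutoff")
    ax2.set_title("Sub-cutoff occupancy")
    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=100)
    plt.close(fig)


def _load_schema() -> dict:
    with resources.files("tyrgate.data").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def validate_report(payload: dict, schema: dict | None = None, path: str = "$") -> None:
    """Structural validation against the packaged report schema.

    Minimal checker: required keys must be present and of the declared
    type ("object", "number", "string", "integer", "number_or_null").
    """
    if schema is None:
        schema = _load_schema()
    for key, spec in schema.get("required", {}).items():
        if key not in payload:
            raise ConfigurationError(f"report invalid: missing {path}.{key}")
        value = payload[key]
        kind = spec["type"] if isinstance(spec, dict) else spec
        ok = {
            "object": lambda v: isinstance(v, dict),
            "string": lambda v: isinstance(v, str),
            "integer": lambda v: isinstance(v, int) and not isinstance(v, bool),
            "number": lambda v: isinstance(v, (int, float)) and not isinstance(v, bool),
            "number_or_null": lambda v: v is None
            or (isinstance(v, (int, float)) and not isinstance(v, bool)),
        }[kind](value)
        if not ok:
            raise ConfigurationError(
                f"report invalid: {path}.{key} should be {kind}, got {type(value).__name__}"
            )
        if isinstance(spec, dict) and "required" in spec:
            validate_report(value, spec, f"{path}.{key}")
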