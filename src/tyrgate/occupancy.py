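"""Distance-occupancy statistics for hydrogen-bond persistence.

The headline equilibrium observable is the fraction of trajectory
frames in which a monitored donor–acceptor distance stays at or below a
cutoff (default 4.0 Å, inclusive) — a geometric proxy for how often the
gate tyrosine keeps its hydrogen bond.  Distance series may come from
the package's own Langevin runs (the gate coordinate is read directly
as the monitored distance), from delimited text tables, or from
multi-model PDB trajectory files.  Uncertainty uses a circular block
bootstrap whose default block length tracks the series' integrated
autocorrelation time, because snapshots 20 ps apart are correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .landscapes import ParameterError
from .pullsim import EquilibriumTrace, rng_stream

logger = logging.getLogger(__name__)

__all__ = [
    "AtomPairSpec",
    "DistanceSeries",
    "OccupancyResult",
    "DEFAULT_CUTOFF",
    "ARG_GUANIDINIUM_ATOMS",
    "read_distance_table",
    "distances_from_multimodel_pdb",
    "series_from_equilibrium_trace",
    "occupancy_fraction",
    "pool_occupancy",
    "block_bootstrap_occupancy_ci",
    "integrated_autocorrelation_time",
    "write_occupancy_tsv",
]

#: Hydrogen-bond distance cutoff, Å (inclusive comparison).
DEFAULT_CUTOFF = 4.0

#: Default acceptor set for an arginine endpoint: the distance to the
#: guanidinium group is the minimum over these atoms.
ARG_GUANIDINIUM_ATOMS = ("NE", "NH1", "NH2")


@dataclass(frozen=True)
class AtomPairSpec:
    """A monitored atom pair, e.g. Tyr OH to the Arg guanidinium group.

    ``endpoint_1`` is a single (residue name, residue number, atom name)
    triple; ``endpoint_2`` may be a triple or a set of triples, in which
    case the recorded distance is the minimum over the set.
    """

    label: str
    endpoint_1: tuple[str, int, str]
    endpoint_2: tuple[str, int, str] | tuple[tuple[str, int, str], ...]

    def __post_init__(self):
        if self.endpoint_2 == self.endpoint_1:
            raise ParameterError("endpoints must differ")

    @property
    def endpoint_2_set(self) -> tuple[tuple[str, int, str], ...]:
        e2 = self.endpoint_2
        if e2 and isinstance(e2[0], tuple):
            return tuple(e2)
        return (e2,)


@dataclass(frozen=True)
class DistanceSeries:
    """One monitored distance time series with its provenance."""

    times: np.ndarray      # ps (frame index when no time metadata exists)
    distances: np.ndarray  # Å
    pair: str = "distance"
    run_id: object = None
    site_id: object = None
    source: str = "simulated"   # {"simulated", "table", "pdb_models"}

    def __post_init__(self):
        t = np.asarray(self.times, float)
        d = np.asarray(self.distances, float)
        if t.size != d.size:
            raise ParameterError("times and distances must be equal length")
        if np.any(np.diff(t) < 0):
            raise ParameterError("times must be non-decreasing")
        if np.any(d < 0):
            raise ParameterError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.distances)


@dataclass(frozen=True)
class OccupancyResult:
    """Fraction of frames with distance ≤ cutoff, with exact counts."""

    fraction: float
    n_frames: int
    n_occupied: int
    cutoff: float
    ci_low: float | None = None
    ci_high: float | None = None
    groups: tuple = ()

    def __post_init__(self):
        if self.n_frames < 1:
            raise ParameterError("n_frames must be >= 1")
        if self.n_occupied != round(self.fraction * self.n_frames):
            raise ParameterError("fraction must equal n_occupied / n_frames")


# ---------------------------------------------------------------------
# Input routes
# ---------------------------------------------------------------------

def read_distance_table(path, columns: dict | None = None) -> list[DistanceSeries]:
    """Read distance series from a delimited text table.

    Required columns ``time`` and ``distance`` (Å); optional ``run`` and
    ``site`` split the file into one series per (run, site) group, rows
    kept in file order.  ``columns`` may remap names, e.g.
    ``{"time": "t_ps", "distance": "distance_A"}``.
    """
    colmap = {"time": "t_ps", "distance": "distance_A", "run": "run", "site": "site"}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    for key in ("time", "distance"):
        if colmap[key] not in df.columns:
            raise ParameterError(
                f"{path}: missing required column {colmap[key]!r} "
                f"(have {list(df.columns)})"
            )
    for key in ("time", "distance"):
        col = colmap[key]
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(coerced.index[coerced.isna()][0]) + 2  # 1-based + header
            raise ParameterError(f"{path}: non-numeric {col!r} cell at line {row}")
        df[col] = coerced
    neg = df.index[df[colmap["distance"]] < 0]
    if len(neg):
        raise ParameterError(
            f"{path}: negative distance at line {int(neg[0]) + 2}"
        )
    group_cols = [colmap[k] for k in ("run", "site") if colmap[k] in df.columns]
    out = []
    groups = df.groupby(group_cols, sort=True) if group_cols else [((), df)]
    for key, sub in groups:
        key = key if isinstance(key, tuple) else (key,)
        ids = dict(zip(group_cols, key))
        t = sub[colmap["time"]].to_numpy(float)
        if np.any(np.diff(t) < 0):
            bad = int(sub.index[1:][np.diff(t) < 0][0]) + 2
            raise ParameterError(f"{path}: decreasing time at line {bad}")
        out.append(
            DistanceSeries(
                times=t,
                distances=sub[colmap["distance"]].to_numpy(float),
                run_id=ids.get(colmap["run"]),
                site_id=ids.get(colmap["site"]),
                source="table",
            )
        )
    return out


def _find_atom(model, spec: tuple[str, int, str], model_idx: int):
    resname, resnum, atomname = spec
    for chain in model:
        for residue in chain:
            if residue.id[1] == resnum and residue.get_resname().strip() == resname:
                for atom in residue:
                    if atom.get_name() == atomname:
                        alt = atom.get_altloc()
                        if alt not in (" ", "", "A"):
                            logger.warning(
                                "ignoring altloc %r for %s in model %d",
                                alt, atomname, model_idx,
                            )
                            continue
                        return atom
    raise ParameterError(
        f"atom {atomname!r} of {resname}{resnum} not found in model {model_idx}"
    )


def distances_from_multimodel_pdb(path, pair: AtomPairSpec) -> DistanceSeries:
    """Atom-pair distances per MODEL of a fixed-column PDB trajectory.

    A single-model file counts as one frame; residue numbers are the
    author numbering as written.  The frame index serves as the time
    axis.  If ``endpoint_2`` is an atom set the minimum distance over
    the set is recorded.
    """
    from Bio.PDB import PDBParser

    structure = PDBParser(QUIET=True).get_structure("trajectory", str(path))
    distances = []
    for idx, model in enumerate(structure, start=1):
        a1 = _find_atom(model, pair.endpoint_1, idx)
        d = min(
            float(np.linalg.norm(a1.get_coord() - _find_atom(model, e2, idx).get_coord()))
            for e2 in pair.endpoint_2_set
        )
        distances.append(d)
    if not distances:
        raise ParameterError(f"{path}: no MODEL frames found")
    return DistanceSeries(
        times=np.arange(len(distances), dtype=float),
        distances=np.array(distances),
        pair=pair.label,
        source="pdb_models",
    )


def series_from_equilibrium_trace(trace: EquilibriumTrace,
                                  pair: str = "gate coordinate") -> DistanceSeries:
    """Treat the simulated gate coordinate directly as the monitored distance.

    The down well corresponds to the hydrogen-bonded (sub-cutoff) state.
    """
    return DistanceSeries(
        times=trace.times, distances=trace.positions, pair=pair,
        run_id=trace.run_id, site_id=trace.site_id, source="simulated",
    )


# ---------------------------------------------------------------------
# Occupancy statistics
# ---------------------------------------------------------------------

def occupancy_fraction(series: DistanceSeries, cutoff: float = DEFAULT_CUTOFF) -> OccupancyResult:
    """Exact fraction of frames with distance ≤ cutoff (inclusive)."""
    if len(series) == 0:
        raise ParameterError("empty distance series")
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    n = len(series)
    occ = int(np.count_nonzero(series.distances <= cutoff))
    return OccupancyResult(
        fraction=occ / n, n_frames=n, n_occupied=occ, cutoff=cutoff,
        groups=((series.run_id, series.site_id),),
    )


def pool_occupancy(results: Sequence[OccupancyResult],
                   cutoff: float | None = None) -> OccupancyResult:
    """Frame-weighted pooling of disjoint occupancy results."""
    if not results:
        raise ParameterError("nothing to pool")
    cut = cutoff if cutoff is not None else results[0].cutoff
    if any(r.cutoff != cut for r in results):
        raise ParameterError("pooled results must share a cutoff")
    n = sum(r.n_frames for r in results)
    occ = sum(r.n_occupied for r in results)
    groups = tuple(g for r in results for g in r.groups)
    return OccupancyResult(
        fraction=occ / n, n_frames=n, n_occupied=occ, cutoff=cut, groups=groups,
    )


def integrated_autocorrelation_time(x: np.ndarray) -> float:
    """IACT by Geyer's initial-positive-sequence rule (floor 1.0).

    ``tau = -1 + 2 * sum of the leading positive pair sums`` of the
    normalized autocorrelation; constant series return 1.0.
    """
    x = np.asarray(x, float)
    n = x.size
    if n < 2:
        return 1.0
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0.0:
        return 1.0
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n] / n
    rho = acov / acov[0]
    tau = -1.0
    m = 0
    while 2 * m + 1 < n:
        gamma = rho[2 * m] + rho[2 * m + 1]
        if gamma <= 0.0:
            break
        tau += 2.0 * gamma
        m += 1
    return max(1.0, tau)


def default_block_length(indicator: np.ndarray) -> int:
    """2 × IACT of the occupancy indicator, floored at one frame."""
    return max(1, round(2.0 * integrated_autocorrelation_time(indicator)))


def block_bootstrap_occupancy_ci(
    series: DistanceSeries | Sequence[DistanceSeries],
    cutoff: float = DEFAULT_CUTOFF,
    block_length: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> OccupancyResult:
    """Pooled occupancy with a circular block-bootstrap percentile CI.

    Each series is resampled independently in contiguous circular blocks
    (respecting its own autocorrelation), the resampled groups are
    pooled frame-weighted, and the 2.5/97.5 percentiles of the pooled
    fraction form the CI.  Deterministic for a fixed seed.
    """
    if n_boot < 100:
        raise ParameterError("n_boot must be >= 100")
    group = [series] if isinstance(series, DistanceSeries) else list(series)
    indicators = [np.asarray(s.distances <= cutoff, dtype=float) for s in group]
    lengths = []
    for ind in indicators:
        L = block_length if block_length is not None else default_block_length(ind)
        if L < 1:
            raise ParameterError("block_length must be >= 1")
        if L > ind.size:
            raise ParameterError(
                f"block_length {L} exceeds series length {ind.size}"
            )
        lengths.append(L)
    point = pool_occupancy([occupancy_fraction(s, cutoff) for s in group], cutoff)
    rng = rng_stream(seed, "block_bootstrap", len(group))
    total = sum(ind.size for ind in indicators)
    fractions = np.empty(n_boot)
    for b in range(n_boot):
        occ = 0.0
        for ind, L in zip(indicators, lengths):
            n = ind.size
            n_blocks = -(-n // L)  # ceil
            starts = rng.integers(0, n, n_blocks)
            idx = (starts[:, None] + np.arange(L)[None, :]).ravel()[:n] % n
            occ += ind[idx].sum()
        fractions[b] = occ / total
    lo = float(np.percentile(fractions, 2.5))
    hi = float(np.percentile(fractions, 97.5))
    return OccupancyResult(
        fraction=point.fraction, n_frames=point.n_frames,
        n_occupied=point.n_occupied, cutoff=cutoff,
        ci_low=min(lo, point.fraction), ci_high=max(hi, point.fraction),
        groups=point.groups,
    )


def write_occupancy_tsv(results: Sequence[OccupancyResult], path) -> None:
    """Occupancy table: group, n_frames, fraction, ci_low, ci_high, cutoff_A."""
    from pathlib import Path

    lines = ["group\tn_frames\tfraction\tci_low\tci_high\tcutoff_A"]
    for r in results:
        group = ";".join(f"{g[0]}/{g[1]}" for g in r.groups) or "all"
        lo = f"{r.ci_low:.6g}" if r.ci_low is not None else "nan"
        hi = f"{r.ci_high:.6g}" if r.ci_high is not None else "nan"
        lines.append(
            f"{group}\t{r.n_frames}\t{r.fraction:.8g}\t{lo}\t{hi}\t{r.cutoff:g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
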