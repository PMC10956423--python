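"""Work accumulation and the Jarzynski / cumulant PMF estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import tyrgate as tg
from tyrgate.landscapes import ParameterError
from tyrgate.freenergy import (
    WorkSet,
    accumulate_work,
    bootstrap_pmf_ci,
    build_workset,
    compare_total_pmf,
    cumulant2_pmf,
    default_z_grid,
    jarzynski_pmf,
    mean_work_pmf,
    read_profile_tsv,
    read_workset_tsv,
    write_profile_tsv,
    write_workset_tsv,
)
from tyrgate.pullsim import PullProtocol, PullTrace, simulate_pull

KT = tg.thermal_energy()


def _manual_trace(positions, protocol, start=0.0):
    positions = np.asarray(positions, float)
    times = protocol.timestep * protocol.record_stride * np.arange(positions.size)
    center = start + protocol.velocity / 1000.0 * times
    return PullTrace(
        times=times, positions=positions, center=center,
        restraint_force=protocol.spring * (center - positions),
        protocol=protocol, replicate_id=0, site_id="A", seed_used=0,
    )


def _workset_at_point(work_values, kT=KT):
    """WorkSet with a leading gauge column of zeros and one active column."""
    w = np.asarray(work_values, float)
    works = np.column_stack([np.zeros_like(w), w])
    labels = tuple((i, "A", None) for i in range(w.size))
    return WorkSet(z_grid=np.array([0.0, 1.0]), works=works, labels=labels, kT=kT)


# ---------------------------------------------------------------------
# work accumulation
# ---------------------------------------------------------------------

def test_perfect_tracking_accumulates_zero_work():
    p = PullProtocol(duration=0.1, record_stride=10)
    n = p.n_steps // 10 + 1
    times = p.timestep * 10 * np.arange(n)
    positions = 0.0 + p.velocity / 1000.0 * times  # x ≡ z_c
    tr = _manual_trace(positions, p)
    w = accumulate_work(tr, tr.center)
    np.testing.assert_allclose(w, 0.0, atol=1e-12)


def test_constant_lag_closed_form():
    """Lag Δ behind the center gives W(final) = k·Δ·(v·T) = 10·0.1·7 = 7."""
    p = PullProtocol(record_stride=100)
    n = p.n_steps // 100 + 1
    times = p.timestep * 100 * np.arange(n)
    center = 0.0 + p.velocity / 1000.0 * times
    tr = _manual_trace(center - 0.1, p)
    w = accumulate_work(tr, center)
    assert w[-1] == pytest.approx(7.0, rel=1e-9)


def test_frozen_particle_work_closed_form():
    """D=0 on a flat landscape: the particle never moves and the total
    external work is (k/2)(vT)² = 245 kcal/mol under protocol defaults."""
    flat = tg.make_flat((-20.0, 20.0))
    p = PullProtocol(diffusion=0.0)
    tr = simulate_pull(flat, p, 0.0)
    np.testing.assert_array_equal(tr.positions, 0.0)
    w = accumulate_work(tr)
    assert w[-1] == pytest.approx(245.0, rel=1e-6)


def test_non_uniform_time_spacing_rejected():
    p = PullProtocol(duration=0.1)
    tr = _manual_trace(np.zeros(11), p)
    broken = PullTrace(
        times=tr.times**1.1, positions=tr.positions, center=tr.center,
        restraint_force=tr.restraint_force, protocol=p,
        replicate_id=0, site_id="A", seed_used=0,
    )
    with pytest.raises(ParameterError, match="spacing"):
        accumulate_work(broken)


def test_grid_outside_pulled_range_rejected():
    p = PullProtocol(duration=0.1, record_stride=10)
    tr = _manual_trace(np.zeros(p.n_steps // 10 + 1), p)
    with pytest.raises(ParameterError, match="range"):
        accumulate_work(tr, np.array([-1.0, 0.0]))


# ---------------------------------------------------------------------
# estimators: exact examples
# ---------------------------------------------------------------------

def test_jarzynski_of_zero_and_constant_ensembles():
    z = np.linspace(0.0, 7.0, 8)
    zeros = WorkSet(z, np.zeros((5, 8)), tuple((i, "A", None) for i in range(5)), KT)
    np.testing.assert_array_equal(jarzynski_pmf(zeros).delta_f, 0.0)
    curve = np.concatenate(([0.0], np.linspace(0.5, 4.0, 7)))
    common = WorkSet(z, np.tile(curve, (4, 1)),
                     tuple((i, "A", None) for i in range(4)), KT)
    np.testing.assert_allclose(jarzynski_pmf(common).delta_f, curve, atol=1e-12)
    np.testing.assert_allclose(cumulant2_pmf(common).delta_f, curve, atol=1e-10)


def test_jarzynski_two_point_high_precision_oracle():
    """ΔF for works {0, 1} kcal/mol against an arbitrary-precision
    evaluation of −kT·ln((1+e^(−1/kT))/2)."""
    mpmath = pytest.importorskip("mpmath")
    mpmath.mp.dps = 50
    kT = mpmath.mpf("0.0019872041") * 300
    expected = float(-kT * mpmath.log((1 + mpmath.e ** (-1 / kT)) / 2))
    ws = _workset_at_point([0.0, 1.0])
    prof = jarzynski_pmf(ws)
    assert prof.delta_f[1] == pytest.approx(expected, abs=1e-12)
    assert prof.delta_f[0] == 0.0


def test_cumulant2_two_sample_hand_computation():
    """Works {0, 2W̄}: mean W̄, unbiased variance 2W̄², so
    ΔF = W̄ − W̄²/kT."""
    wbar = 1.5
    ws = _workset_at_point([0.0, 2 * wbar])
    prof = cumulant2_pmf(ws)
    assert prof.delta_f[1] == pytest.approx(wbar - wbar**2 / KT, rel=1e-12)


def test_gaussian_works_cumulant_matches_jarzynski():
    """For Gaussian work the second cumulant is exact; at N=10⁵ both
    estimators agree within 0.05 kcal/mol."""
    rng = np.random.default_rng(42)
    w = rng.normal(5.0, 1.0, 100_000)
    ws = _workset_at_point(w)
    j = jarzynski_pmf(ws).delta_f[1]
    c = cumulant2_pmf(ws).delta_f[1]
    assert abs(j - c) < 0.05


def test_single_replica_jarzynski_is_the_work_curve():
    z = np.linspace(0.0, 7.0, 15)
    w = np.concatenate(([0.0], np.cumsum(np.abs(np.sin(np.arange(14))))))
    ws = WorkSet(z, w[None, :], ((0, "A", None),), KT)
    np.testing.assert_allclose(jarzynski_pmf(ws).delta_f, w, atol=1e-12)


def test_cumulant2_requires_two_replicas():
    z = np.array([0.0, 1.0])
    ws = WorkSet(z, np.zeros((1, 2)), ((0, "A", None),), KT)
    with pytest.raises(ParameterError):
        cumulant2_pmf(ws)


def test_non_finite_work_names_the_replica():
    z = np.array([0.0, 1.0])
    works = np.array([[0.0, 1.0], [0.0, np.nan]])
    with pytest.raises(ParameterError, match="row 1"):
        WorkSet(z, works, ((0, "A", None), (1, "B", None)), KT)


# ---------------------------------------------------------------------
# estimator properties
# ---------------------------------------------------------------------

work_matrices = arrays(
    float, shape=st.tuples(st.integers(2, 8), st.integers(2, 6)),
    elements=st.floats(-30.0, 120.0),
).map(lambda w: np.column_stack([np.zeros(w.shape[0]), w]))


@given(work_matrices)
@settings(deadline=None, max_examples=60)
def test_jarzynski_jensen_bounds_and_gauge(works):
    """min W ≤ ΔF_jarzynski ≤ ⟨W⟩ at every grid point; gauge at 0."""
    z = np.arange(works.shape[1], dtype=float)
    ws = WorkSet(z, works, tuple((i, "A", None) for i in range(works.shape[0])), KT)
    dfj = jarzynski_pmf(ws).delta_f
    assert dfj[0] == 0.0
    assert np.all(works.min(axis=0) <= dfj + 1e-9)
    assert np.all(dfj <= works.mean(axis=0) + 1e-9)
    assert np.all(dfj <= mean_work_pmf(ws).delta_f + 1e-9)


@given(work_matrices, st.floats(-10.0, 10.0))
@settings(deadline=None, max_examples=40)
def test_shift_equivariance(works, c):
    """Adding a constant c to all works at a grid point shifts every
    estimator's ΔF there by exactly c."""
    z = np.arange(works.shape[1], dtype=float)
    labels = tuple((i, "A", None) for i in range(works.shape[0]))
    ws = WorkSet(z, works, labels, KT)
    shifted = works.copy()
    shifted[:, -1] += c
    ws2 = WorkSet(z, shifted, labels, KT)
    for est in (jarzynski_pmf, cumulant2_pmf, mean_work_pmf):
        a, b = est(ws).delta_f, est(ws2).delta_f
        np.testing.assert_allclose(b[-1] - a[-1], c, atol=1e-8)
        np.testing.assert_allclose(b[:-1], a[:-1], atol=1e-10)


def test_recovery_ensemble_respects_bounds(recovery_workset):
    """The simulated 200-pull ensemble obeys the Jensen/Jarzynski bounds."""
    ws = recovery_workset
    dfj = jarzynski_pmf(ws).delta_f
    assert np.all(ws.works.min(axis=0) <= dfj + 1e-9)
    assert np.all(dfj <= ws.works.mean(axis=0) + 1e-9)


# ---------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------

def test_bootstrap_identical_rows_zero_width():
    z = np.array([0.0, 1.0, 2.0])
    curve = np.array([0.0, 1.0, 3.0])
    ws = WorkSet(z, np.tile(curve, (6, 1)),
                 tuple((i, "A", None) for i in range(6)), KT)
    prof = bootstrap_pmf_ci(ws, n_boot=200, seed=1)
    np.testing.assert_allclose(prof.ci_high - prof.ci_low, 0.0, atol=1e-12)


def test_bootstrap_is_deterministic(recovery_workset):
    a = bootstrap_pmf_ci(recovery_workset, n_boot=100, seed=7)
    b = bootstrap_pmf_ci(recovery_workset, n_boot=100, seed=7)
    np.testing.assert_array_equal(a.ci_low, b.ci_low)
    np.testing.assert_array_equal(a.ci_high, b.ci_high)


def test_bootstrap_two_point_matches_binomial_quantiles():
    """With works taking two values the bootstrap mean-work statistic is a
    rescaled Binomial; the percentile band must match the exact binomial
    quantiles within the spacing of adjacent statistic values."""
    from scipy.stats import binom

    n, p_hat = 100, 0.4
    values = np.array([1.0] * int(n * p_hat) + [0.0] * (n - int(n * p_hat)))
    ws = _workset_at_point(values)
    prof = bootstrap_pmf_ci(ws, estimator="mean_work", n_boot=4000, seed=3)
    exact_lo = binom.ppf(0.025, n, p_hat) / n
    exact_hi = binom.ppf(0.975, n, p_hat) / n
    assert prof.ci_low[1] == pytest.approx(exact_lo, abs=0.02)
    assert prof.ci_high[1] == pytest.approx(exact_hi, abs=0.02)


# ---------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------

def _profile(z, df, **kw):
    from tyrgate.freenergy import PMFProfile

    return PMFProfile(z_grid=z, delta_f=df, estimator="jarzynski",
                      n_traces=10, kT=KT, **kw)


def test_compare_identical_profiles_is_zero():
    z = np.linspace(0.0, 7.0, 8)
    df = np.concatenate(([0.0], np.linspace(1, 5, 7)))
    pa = {"A": _profile(z, df), "B": _profile(z, df)}
    comp = compare_total_pmf(pa, dict(pa), "endpoint")
    assert comp.mean_difference == 0.0
    assert all(v == 0.0 for v in comp.differences.values())


@pytest.mark.parametrize("definition", ["endpoint", "profile_max"])
def test_compare_constant_offset(definition):
    z = np.linspace(0.0, 7.0, 8)
    df = np.concatenate(([0.0], np.linspace(1, 5, 7)))
    shifted = df + np.concatenate(([0.0], np.full(7, 5.0)))
    pa = {"A": _profile(z, df), "B": _profile(z, df)}
    pb = {"A": _profile(z, shifted), "B": _profile(z, shifted)}
    comp = compare_total_pmf(pa, pb, definition)
    assert comp.mean_difference == pytest.approx(5.0)


def test_compare_rejects_mismatched_sites():
    z = np.linspace(0.0, 7.0, 8)
    df = np.zeros(8)
    with pytest.raises(ParameterError, match="site"):
        compare_total_pmf({"A": _profile(z, df)}, {"B": _profile(z, df)})


# ---------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------

def test_workset_tsv_roundtrip(tmp_path, recovery_workset):
    path = tmp_path / "works.tsv"
    write_workset_tsv(recovery_workset, path)
    back = read_workset_tsv(path)
    assert back.kT == pytest.approx(recovery_workset.kT)
    np.testing.assert_allclose(back.z_grid, recovery_workset.z_grid, atol=1e-6)
    np.testing.assert_allclose(back.works, recovery_workset.works,
                               rtol=1e-6, atol=1e-6)


def test_profile_tsv_roundtrip(tmp_path, recovery_workset):
    prof = bootstrap_pmf_ci(recovery_workset, n_boot=100, seed=5)
    path = tmp_path / "pmf.tsv"
    write_profile_tsv(prof, path)
    back = read_profile_tsv(path)
    assert back.estimator == "jarzynski"
    np.testing.assert_allclose(back.delta_f, prof.delta_f, rtol=1e-6, atol=1e-6)
    np.testing.assert_allclose(back.ci_low, prof.ci_low, rtol=1e-6, atol=1e-6)
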