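"""Permeation counting, current estimators, Poisson/bootstrap
uncertainty, I-V fitting and selectivity."""

import math

import numpy as np
import pytest

from conftest import make_walk_traces, oracle_count
from piezokit import (
    IonTrace,
    IVPoint,
    PoreRegion,
    bootstrap_sd,
    count_permeations,
    current_from_counts,
    fit_conductance,
    poisson_ci,
    selectivity_ratio,
    zdisp_current,
)

REGION = PoreRegion(z_lo=56.0, z_hi=66.0, radial_cutoff=35.0)


def straight_trace(z_from, z_to, n=41, r=0.0, ion_id=0, charge=1.0, species="K+"):
    z = np.linspace(z_from, z_to, n)
    return IonTrace(
        ion_id=ion_id, species=species, charge=charge,
        times=np.arange(n) * 0.1,
        positions=np.column_stack([np.full(n, r), np.zeros(n), z]),
    )


class TestCountPermeations:
    def test_single_upward_transit(self):
        ev, counts, net = count_permeations([straight_trace(50, 70)], REGION)
        assert len(ev) == 1
        assert ev[0].direction == "+z"
        assert ev[0].t_entry < ev[0].t_exit
        assert counts == {("K+", "+z"): 1}
        assert net == 1.0

    def test_entry_and_return_counts_nothing(self):
        z = np.concatenate([np.linspace(50, 60, 20), np.linspace(60, 50, 20)])
        tr = IonTrace(0, "K+", 1.0, np.arange(40) * 0.1,
                      np.column_stack([np.zeros(40), np.zeros(40), z]))
        ev, counts, net = count_permeations([tr], REGION)
        assert ev == [] and net == 0.0

    def test_radial_excursion_voids_transit(self):
        n = 41
        z = np.linspace(50, 70, n)
        x = np.zeros(n)
        x[n // 2] = 40.0  # outside the 35 A cylinder mid-slab
        tr = IonTrace(0, "K+", 1.0, np.arange(n) * 0.1,
                      np.column_stack([x, np.zeros(n), z]))
        ev, _, net = count_permeations([tr], REGION)
        assert ev == [] and net == 0.0

    def test_anion_downward_gives_positive_charge(self):
        tr = straight_trace(70, 50, charge=-1.0, species="Cl-")
        _, counts, net = count_permeations([tr], REGION)
        assert counts == {("Cl-", "-z"): 1}
        assert net == 1.0  # -z crossing of -1e transports +1e

    def test_interpolated_crossing_times(self):
        # z moves 50->70 over 40 steps of 0.5 A: crosses 56 at sample 12
        tr = straight_trace(50, 70, n=41)
        ev, _, _ = count_permeations([tr], REGION)
        assert ev[0].t_entry == pytest.approx(1.2, abs=1e-9)
        assert ev[0].t_exit == pytest.approx(3.2, abs=1e-9)

    def test_pbc_unwrap(self):
        # ion drifts up through the slab in a box of height 100, wrapped
        z_true = np.linspace(50, 70, 81)
        z_wrapped = ((z_true + 50) % 100) - 50 + 50  # wrap into [50, 150)? keep simple
        z_wrapped = np.where(z_true > 60, z_true - 100, z_true)
        tr = IonTrace(0, "K+", 1.0, np.arange(81) * 0.1,
                      np.column_stack([np.zeros(81), np.zeros(81), z_wrapped]))
        ev, _, net = count_permeations([tr], REGION, box_z=100.0)
        assert net == 1.0

    def test_random_walks_match_independent_oracle(self, rng):
        traces = make_walk_traces(2000, 80, rng)
        ev, counts, net = count_permeations(traces, REGION)
        oc, onet = oracle_count(traces, 56.0, 66.0, 35.0)
        assert counts == oc
        assert net == pytest.approx(onet)

    def test_nan_rejected_with_context(self):
        pos = np.zeros((5, 3))
        pos[3, 2] = np.nan
        tr = IonTrace(7, "K+", 1.0, np.arange(5) * 0.1, pos)
        with pytest.raises(ValueError, match="ion 7"):
            count_permeations([tr], REGION)

    def test_nonuniform_dt_rejected(self):
        tr = IonTrace(0, "K+", 1.0, np.array([0.0, 0.1, 0.3]), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="non-uniform"):
            count_permeations([tr], REGION)


class TestCurrentFromCounts:
    def test_zero(self):
        assert current_from_counts(0.0, 100.0) == 0.0

    def test_nine_events_100ns(self):
        # independent unit-conversion oracle: 9 * e / 100 ns in pA
        expected = 9 * 1.602177e-19 / (100e-9) * 1e12
        assert current_from_counts(9.0, 100.0) == pytest.approx(expected, rel=1e-12)
        assert current_from_counts(9.0, 100.0) == pytest.approx(14.42, abs=5e-3)

    def test_cancellation(self):
        assert current_from_counts(9.0 - 9.0, 100.0) == 0.0

    def test_bad_tau(self):
        with pytest.raises(ValueError):
            current_from_counts(1.0, 0.0)


def poisson_tail_upper(lam, n):
    """P(X >= n) by direct summation of the complement."""
    s, term = 0.0, math.exp(-lam)
    for k in range(n):
        s += term
        term *= lam / (k + 1)
    return 1.0 - s


class TestPoissonCI:
    def test_zero_count_lower_bound(self):
        lo, hi = poisson_ci(0, 0.85)
        assert lo == 0.0 and hi > 0

    def test_garwood_bounds_against_tail_oracle(self):
        lo, hi = poisson_ci(9, 0.85)
        assert lo < 9 < hi
        # at lam=lo the upper tail P(X>=9) equals 0.075; at lam=hi the
        # lower tail P(X<=9) equals 0.075
        assert poisson_tail_upper(lo, 9) == pytest.approx(0.075, abs=1e-9)
        assert 1 - poisson_tail_upper(hi, 10) == pytest.approx(0.075, abs=1e-9)

    def test_coverage_at_lambda_10(self):
        rng = np.random.default_rng(123)
        draws = rng.poisson(10.0, size=10000)
        covered = 0
        cache = {}
        for n in draws:
            if n not in cache:
                cache[n] = poisson_ci(int(n), 0.85)
            lo, hi = cache[n]
            covered += lo <= 10.0 <= hi
        assert 0.83 <= covered / 10000 <= 0.90

    def test_widening_with_level(self):
        l1 = poisson_ci(9, 0.5)
        l2 = poisson_ci(9, 0.85)
        l3 = poisson_ci(9, 0.99)
        assert l3[0] < l2[0] < l1[0] < 9 < l1[1] < l2[1] < l3[1]

    def test_invalid_level(self):
        with pytest.raises(ValueError):
            poisson_ci(5, 1.5)


class TestZdispCurrent:
    def test_full_transit_transports_one_charge(self):
        _, I, cum = zdisp_current([straight_trace(50, 70)], REGION)
        assert cum == pytest.approx(1.0, abs=1e-12)

    def test_oscillation_cancels(self):
        z = np.concatenate([np.linspace(50, 64, 30), np.linspace(64, 50, 30)])
        tr = IonTrace(0, "K+", 1.0, np.arange(60) * 0.1,
                      np.column_stack([np.zeros(60), np.zeros(60), z]))
        _, _, cum = zdisp_current([tr], REGION)
        assert cum == pytest.approx(0.0, abs=1e-12)

    def test_estimator_equivalence_bound(self, rng):
        traces = make_walk_traces(400, 120, rng, radial_spread=0.8)
        _, counts, net = count_permeations(traces, REGION)
        _, _, cum = zdisp_current(traces, REGION)
        inside = sum(
            1
            for tr in traces
            for k in (0, -1)
            if REGION.z_lo <= tr.positions[k, 2] <= REGION.z_hi
        )
        assert abs(cum - net) <= inside + 1e-9

    def test_current_units(self):
        # one +1e charge crossing 10 A slab in 4 ns -> mean I = 0.25 e/ns
        tr = straight_trace(56, 66, n=41)
        t, I, cum = zdisp_current([tr], REGION)
        e_per_ns_pa = 1.602177e-19 / 1e-9 * 1e12
        assert I.sum() * 0.1 / e_per_ns_pa == pytest.approx(1.0, abs=1e-9)


class TestFitConductance:
    def test_two_point_exact_line(self):
        iv = [IVPoint(-500.0, 100.0, {"K+": 10}, -20.0),
              IVPoint(500.0, 100.0, {"K+": 10}, 20.0)]
        fit = fit_conductance(iv, method="z_displacement")
        assert fit.G == pytest.approx(40.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_single_point(self):
        fit = fit_conductance([IVPoint(500.0, 100.0, {}, 20.0)], method="z_displacement")
        assert fit.G == pytest.approx(40.0)

    def test_random_sets_vs_normal_equation(self, rng):
        for _ in range(20):
            V = rng.uniform(-600, 600, 6)
            I = rng.normal(0, 30, 6)
            iv = [IVPoint(v, 1.0, {}, i) for v, i in zip(V, I)]
            fit = fit_conductance(iv, method="z_displacement")
            assert fit.G == pytest.approx(float(I @ V / (V @ V)) * 1000, abs=1e-10)

    def test_counts_ci_brackets_estimate(self):
        iv = [IVPoint(-500.0, 100.0, {"K+": 9}, -14.42),
              IVPoint(500.0, 100.0, {"K+": 12}, 19.2)]
        fit = fit_conductance(iv, method="counts", seed=5)
        assert fit.ci is not None
        assert fit.ci[0] < fit.G < fit.ci[1]

    def test_all_zero_voltage_rejected(self):
        with pytest.raises(ValueError):
            fit_conductance([IVPoint(0.0, 1.0, {}, 1.0)], method="z_displacement")


class TestBootstrapSD:
    def test_constant_series_zero_sd(self):
        sd = bootstrap_sd({500.0: np.full(200, 20.0)}, n_resamples=200, block=5, seed=1)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_iid_gaussian_matches_analytic_se(self):
        # G = mean(I)/V * 1000; SE_G = sigma/sqrt(n)/|V| * 1000
        n, sigma, V = 400, 5.0, 500.0
        expected = sigma / math.sqrt(n) / V * 1000
        sds = []
        for seed in range(20):
            s = np.random.default_rng(seed).normal(20.0, sigma, n)
            sds.append(bootstrap_sd({V: s}, n_resamples=400, block=1, seed=seed))
        assert abs(np.mean(sds) - expected) / expected < 0.1

    def test_deterministic_under_seed(self, rng):
        s = rng.normal(0, 1, 300)
        a = bootstrap_sd({250.0: s}, n_resamples=150, block=10, seed=42)
        b = bootstrap_sd({250.0: s}, n_resamples=150, block=10, seed=42)
        assert a == b

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_sd({500.0: np.ones(5)}, n_resamples=100, block=10, seed=1)


class TestSelectivity:
    def test_simple_ratio(self):
        r = selectivity_ratio({"K+": 18, "Cl-": 6}, "K+", "Cl-")
        assert r.ratio == pytest.approx(3.0)
        assert not r.one_sided

    def test_zero_denominator_one_sided_bound(self):
        r = selectivity_ratio({"K+": 9, "Cl-": 0}, "K+", "Cl-")
        assert r.ratio == pytest.approx(9.0)
        assert r.one_sided

    def test_randomized_vs_hand(self, rng):
        for _ in range(20):
            a, b = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            r = selectivity_ratio({"K+": a, "Cl-": b}, "K+", "Cl-")
            assert r.ratio == pytest.approx(a / b)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            selectivity_ratio({"K+": 0, "Cl-": 0}, "K+", "Cl-")
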