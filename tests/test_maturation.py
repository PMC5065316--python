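"""Delay-equation maturation model: integrator accuracy and model structure."""

import numpy as np
import pytest

from npckinetics.config import RunConfig
from npckinetics.growth import GrowthParams, PRINTED_GROWTH, area_at
from npckinetics.maturation import (
    DelayDistribution,
    MaturationParams,
    MultiStepParams,
    densities_from_samples,
    maturation_time,
    objective,
    simulate,
    simulate_distributed,
    simulate_multistep,
)

CONST_AREA = GrowthParams(a0=500.0, a1=0.0, kg1=1.0, kg2=0.0)

BURST = MaturationParams(
    variant="burst", kM=1.357, tauM=43.03, kd=0.00042, tauS=10.0, v0=0.015,
    i0_by_region={"default": 4.5}, m0_by_region={"default": 4.6},
)


def euler_delay_oracle(p: MaturationParams, growth, t_end, h=0.005, region="default"):
    """Brute-force explicit Euler with a discrete delay-history buffer.

    Independent of the production implementation: evaluates V directly from
    the variant definition.  tauM is rounded to a multiple of h.
    """
    n = int(round(t_end / h))
    lag = int(round(p.tauM / h))
    t = np.arange(n + 1) * h
    A = area_at(t + p.tauS, growth)
    if p.variant == "constant_rate":
        V = p.v * A
    elif p.variant == "decaying_rate":
        V = (p.v1 * np.exp(-p.kv * t) + p.v0) * A
    else:
        V = p.v0 * A
    I = np.zeros(n + 1)
    Im = np.zeros(n + 1)
    M = np.zeros(n + 1)
    I[0] = p.i0(region) * A[0]
    M[0] = p.m0(region) * A[0]
    for k in range(n):
        I_del = I[k - lag] if k >= lag else 0.0
        I[k + 1] = I[k] + h * (V[k] - p.kM * I[k])
        Im[k + 1] = Im[k] + h * p.kM * (I[k] - I_del)
        M[k + 1] = M[k] + h * (p.kM * I_del - p.kd * M[k])
    return t, I, Im, M, A


class TestSimulate:
    def test_all_zero_without_production_or_initial(self):
        p = MaturationParams(variant="burst", kM=1.0, tauM=30.0, v0=0.0)
        sim = simulate(p, PRINTED_GROWTH, np.linspace(0, 100, 11))
        for field in ("I", "Im", "IT", "M", "iT", "m"):
            np.testing.assert_allclose(getattr(sim, field), 0.0)

    def test_constant_area_steady_state(self):
        """Closed form: iT* = v (1/kM + tauM), m* = v/kd."""
        p = MaturationParams(variant="constant_rate", v=0.0015, kM=0.5,
                             tauM=30.0, kd=0.00042, tauS=10.0)
        sim = simulate(p, CONST_AREA, np.linspace(0.0, 40000.0, 50), step=0.5)
        assert sim.m[-1] == pytest.approx(0.0015 / 0.00042, rel=1e-4)
        assert sim.iT[-1] == pytest.approx(0.0015 * (1 / 0.5 + 30.0), rel=1e-4)

    def test_agrees_with_euler_history_buffer_oracle(self):
        t_o, I_o, Im_o, M_o, A_o = euler_delay_oracle(BURST, PRINTED_GROWTH, 110.0)
        t_grid = np.arange(5.0, 111.0, 5.0)
        sim = simulate(BURST, PRINTED_GROWTH, t_grid)
        for mine, oracle in ((sim.M, M_o), (sim.IT, I_o + Im_o)):
            ref = np.interp(t_grid, t_o, oracle)
            rel = np.abs(mine - ref) / np.abs(ref).max()
            assert rel.max() < 1e-3

    @pytest.mark.parametrize("variant,kw", [
        ("constant_rate", dict(v=0.02)),
        ("decaying_rate", dict(v1=0.3, kv=0.06, v0=0.015)),
    ])
    def test_oracle_agreement_other_variants(self, variant, kw):
        p = MaturationParams(variant=variant, kM=0.3, tauM=25.0, kd=0.00042,
                             tauS=10.0, m0_by_region={"default": 3.0}, **kw)
        t_o, I_o, Im_o, M_o, _ = euler_delay_oracle(p, PRINTED_GROWTH, 110.0)
        t_grid = np.arange(5.0, 111.0, 5.0)
        sim = simulate(p, PRINTED_GROWTH, t_grid)
        for mine, oracle in ((sim.M, M_o), (sim.IT, I_o + Im_o)):
            ref = np.interp(t_grid, t_o, oracle)
            assert (np.abs(mine - ref) / np.abs(ref).max()).max() < 1e-3

    def test_conservation_without_degradation(self):
        """With kd = 0, I + Im + M tracks the cumulative production."""
        p = MaturationParams(variant="constant_rate", v=0.001, kM=0.3,
                             tauM=25.0, kd=0.0, tauS=10.0)
        t = np.linspace(0.0, 200.0, 401)
        sim = simulate(p, PRINTED_GROWTH, t, step=0.1)
        V = 0.001 * area_at(t + 10.0, PRINTED_GROWTH)
        cumV = np.concatenate([[0.0], np.cumsum((V[1:] + V[:-1]) / 2 * np.diff(t))])
        total = sim.I + sim.Im + sim.M
        assert np.abs(total - cumV).max() / cumV.max() < 1e-6

    def test_total_intermediates_is_sum(self):
        t = np.linspace(0, 100, 21)
        sim = simulate(BURST, PRINTED_GROWTH, t)
        np.testing.assert_allclose(sim.IT, sim.I + sim.Im, rtol=1e-12)

    def test_mature_growth_monotone_while_influx_dominates(self):
        t = np.linspace(0.0, 120.0, 481)
        sim = simulate(BURST, PRINTED_GROWTH, t)
        I_del = np.interp(t - BURST.tauM, t, sim.I, left=0.0)
        influx_dominates = BURST.kd * sim.M[:-1] < BURST.kM * I_del[:-1]
        dM = np.diff(sim.M)
        assert np.all(dM[influx_dominates] > -1e-8)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            simulate(BURST, PRINTED_GROWTH, np.array([5.0, 4.0]))
        with pytest.raises(ValueError):
            simulate(BURST, PRINTED_GROWTH, np.array([-5.0, 4.0]))


class TestMultiStep:
    def test_two_steps_equal_zero_delay_model(self):
        p2 = MultiStepParams(n_steps=2, kM=0.8, kd=0.00042, tauS=10.0, v0=0.015,
                             i0_by_region={"default": 4.0},
                             m0_by_region={"default": 3.0})
        pd = MaturationParams(variant="burst", kM=0.8, tauM=0.0, kd=0.00042,
                              tauS=10.0, v0=0.015,
                              i0_by_region={"default": 4.0},
                              m0_by_region={"default": 3.0})
        t = np.linspace(0, 120, 40)
        s2 = simulate_multistep(p2, PRINTED_GROWTH, t)
        sd = simulate(pd, PRINTED_GROWTH, t)
        np.testing.assert_allclose(s2.m, sd.m, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(s2.iT, sd.iT, rtol=1e-9, atol=1e-12)

    def test_erlang_chain_converges_to_fixed_delay(self):
        """(N-1)/kM held at 43 min: the chain approaches the sharp delay."""
        t = np.linspace(0.0, 150.0, 76)
        target = simulate(
            MaturationParams(variant="burst", kM=1e6, tauM=43.0, kd=0.00042,
                             tauS=10.0, v0=0.015,
                             i0_by_region={"default": 4.0}), PRINTED_GROWTH, t)
        errs = []
        for N in (5, 15, 50):
            p = MultiStepParams(n_steps=N, kM=(N - 1) / 43.0, kd=0.00042,
                                tauS=10.0, v0=0.015,
                                i0_by_region={"default": 4.0})
            s = simulate_multistep(p, PRINTED_GROWTH, t)
            errs.append(np.abs(s.m - target.m).max())
        assert errs[0] > errs[1] > errs[2]

    def test_n_steps_validation(self):
        with pytest.raises(ValueError):
            MultiStepParams(n_steps=1, kM=1.0)

    def test_maturation_time_chain(self):
        assert maturation_time(MultiStepParams(n_steps=3, kM=0.05)) == pytest.approx(40.0)


class TestDistributed:
    def test_zero_width_equals_fixed_delay(self):
        t = np.linspace(0, 120, 40)
        sw = simulate_distributed(BURST, DelayDistribution(43.03, 0.0),
                                  PRINTED_GROWTH, t)
        sf = simulate(BURST, PRINTED_GROWTH, t)
        np.testing.assert_allclose(sw.m, sf.m, rtol=1e-9)

    def test_small_width_close_to_fixed_delay(self):
        t = np.linspace(0, 120, 40)
        sf = simulate(BURST, PRINTED_GROWTH, t)
        prev = np.inf
        for w in (10.0, 5.0, 1.0):
            sw = simulate_distributed(BURST, DelayDistribution(43.03, w),
                                      PRINTED_GROWTH, t)
            err = np.abs(sw.m - sf.m).max()
            assert err < prev
            prev = err

    def test_mean_arrival_time_matches_center(self):
        """Symmetric spread: the half-rise of M stays at the tauM half-rise."""
        p = MaturationParams(variant="burst", kM=10.0, tauM=40.0, kd=0.0,
                             tauS=10.0, v0=0.0, i0_by_region={"default": 4.0})
        t = np.linspace(0.0, 100.0, 2001)
        sf = simulate(p, CONST_AREA, t)
        sw = simulate_distributed(p, DelayDistribution(40.0, 8.0), CONST_AREA, t)
        half = 0.5 * sf.M[-1]
        t_fixed = t[np.searchsorted(sf.M, half)]
        t_dist = t[np.searchsorted(sw.M, half)]
        assert t_dist == pytest.approx(t_fixed, abs=0.5)

    def test_unsupported_form_rejected(self):
        with pytest.raises(ValueError):
            DelayDistribution(40.0, 5.0, form="gaussian")

    def test_width_bounded_by_center(self):
        with pytest.raises(ValueError):
            DelayDistribution(10.0, 11.0)


class TestObjective:
    def _self_data(self, config):
        t_ao = np.array([19.2, 42.0, 82.9, 116.0])
        data = {}
        for region, i0, m0 in (("inner_core", 4.5, 4.6), ("outer_core", 3.4, 8.8)):
            p = MaturationParams(variant="burst", kM=1.357, tauM=43.03,
                                 kd=config.kd, tauS=config.sealing_time, v0=config.v0,
                                 i0_by_region={region: i0},
                                 m0_by_region={region: m0})
            sim = simulate(p, PRINTED_GROWTH, t_ao - config.sealing_time,
                           region=region)
            data[region] = (t_ao, sim.iT, sim.m)
        params = MaturationParams(
            variant="burst", kM=1.357, tauM=43.03, kd=config.kd,
            tauS=config.sealing_time, v0=config.v0,
            i0_by_region={"inner_core": 4.5, "outer_core": 3.4},
            m0_by_region={"inner_core": 4.6, "outer_core": 8.8})
        return params, data

    def test_zero_at_generating_parameters(self, config):
        params, data = self._self_data(config)
        assert objective(params, data, PRINTED_GROWTH, config) < 1e-12

    def test_quadratic_in_perturbation(self, config):
        params, data = self._self_data(config)
        delta = 0.37
        t_ao, d_int, d_mat = data["inner_core"]
        data_p = dict(data)
        data_p["inner_core"] = (t_ao, d_int.copy(), d_mat + delta * (np.arange(4) == 2))
        F = objective(params, data_p, PRINTED_GROWTH, config)
        assert F == pytest.approx(delta**2 / config.sigma2, rel=1e-6)

    def test_sigma_must_be_positive(self, config):
        params, data = self._self_data(config)
        cfg = RunConfig()
        cfg.sigma2 = 0.0
        with pytest.raises(ValueError):
            objective(params, data, PRINTED_GROWTH, cfg)


class TestMaturationTime:
    def test_delay_formula(self):
        p = MaturationParams(variant="burst", kM=0.1, tauM=20.0)
        assert maturation_time(p) == pytest.approx(30.0)

    def test_published_rounding(self):
        p = MaturationParams(variant="burst", kM=1.357, tauM=43.03)
        assert maturation_time(p) == pytest.approx(43.76, abs=0.02)

    def test_zero_rate_unbounded(self):
        p = MaturationParams(variant="burst", kM=0.0, tauM=20.0)
        assert maturation_time(p) == np.inf
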