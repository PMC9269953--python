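"""Fixed-step RK4 and basal equilibration."""

import numpy as np
import pytest

from memconsol import (ParameterSet, equilibrate, integrate, make_schedule,
                       rk4_step)
from memconsol.kernel import STATE_INDEX


class TestRK4Scheme:
    def test_linear_decay_single_step_is_quartic_taylor(self):
        """One RK4 step on dx/dt = -x reproduces the degree-4 Taylor
        polynomial of exp(-h)."""
        for h in (0.1, 0.5, 1.0, 3.0):
            got = rk4_step(lambda t, x: -x, 0.0, 1.0, h)
            expected = 1 - h + h**2 / 2 - h**3 / 6 + h**4 / 24
            assert got == pytest.approx(expected, rel=0, abs=1e-15)

    def test_quartic_convergence_order(self):
        """Global error on linear decay scales as h^4 over h = 12..1.5 s."""
        T = 60.0
        errs = []
        for h in (12.0, 6.0, 3.0, 1.5):
            x, t = 1.0, 0.0
            while t < T - 1e-9:
                x = rk4_step(lambda tt, xx: -0.05 * xx, t, x, h)
                t += h
            errs.append(abs(x - np.exp(-0.05 * T)))
        orders = [np.log2(errs[i] / errs[i + 1]) for i in range(3)]
        assert all(3.6 < o < 4.5 for o in orders), orders

    def test_zero_rhs_constant_trajectory(self):
        got = rk4_step(lambda t, x: 0.0 * x, 0.0, np.array([1.0, 2.0]), 3.0)
        assert np.array_equal(got, [1.0, 2.0])


class TestIntegrate:
    def test_grid_determinism(self, std_params, std_basal):
        sched = make_schedule(0.0, "PSI", 3600.0, std_params)
        a = integrate(std_basal, 0.0, 86400.0, std_params, schedule=sched)
        b = integrate(std_basal, 0.0, 86400.0, std_params, schedule=sched)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.times, b.times)

    def test_constant_at_fixed_point_without_input(self, std_params, std_basal):
        traj = integrate(std_basal, 0.0, 86400.0, std_params)
        assert np.max(np.abs(traj.states - std_basal)) < 1e-9

    def test_step_halving_self_convergence(self, std_params, std_basal):
        """Halving the 3-s step changes day-7 W by well under 0.1%."""
        sched = make_schedule(0.0, None, 0.0, std_params)
        w7 = {}
        for h, stride in ((3.0, 100), (1.5, 200)):
            traj = integrate(std_basal, 0.0, 7 * 86400.0, std_params,
                             schedule=sched, step=h, record_stride=stride)
            w7[h] = traj.value_at(7 * 86400.0, "W")
        assert abs(w7[3.0] - w7[1.5]) / w7[1.5] < 1e-3

    def test_recording_stride_and_final_state(self, std_params, std_basal):
        traj = integrate(std_basal, 0.0, 7 * 86400.0, std_params,
                         record_stride=100)
        assert len(traj.times) == 1 + 7 * 86400 // 3 // 100
        assert traj.times[-1] == 7 * 86400.0
        assert np.all(np.diff(traj.times) == 300.0)

    def test_bad_arguments(self, std_params, std_basal):
        with pytest.raises(ValueError):
            integrate(std_basal, 10.0, 0.0, std_params)
        with pytest.raises(ValueError):
            integrate(std_basal[:5], 0.0, 60.0, std_params)


class TestEquilibrate:
    def test_basal_occupancies_near_tabulated(self, std_basal):
        i = STATE_INDEX
        for name in ("B_Sin3a", "B_HDAC2", "B_MeCP2"):
            assert abs(std_basal[i[name]] - 1.0) < 0.05, name
        assert std_basal[i["Tag"]] == pytest.approx(0.1, rel=0.05)
        assert std_basal[i["GPROD"]] == pytest.approx(0.12, rel=0.05)

    def test_idempotence(self, std_params, std_basal):
        again = equilibrate(std_params, y0=std_basal)
        assert np.max(np.abs(again - std_basal)) < 1e-9

    def test_all_nonnegative(self, std_basal):
        assert np.all(std_basal >= 0.0)

    def test_reduced_camkii_raises_basal_binding(self, std_params, std_basal):
        """Halving basal CaMKII phosphorylation releases the brake on MeCP2
        binding: all three occupancies equilibrate above their standard
        levels (the infant-like basal state)."""
        low = equilibrate(std_params.scaled(k_basalp_CaMKII=0.5))
        i = STATE_INDEX
        for name in ("B_MeCP2", "B_Sin3a", "B_HDAC2"):
            assert low[i[name]] > std_basal[i[name]], name
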