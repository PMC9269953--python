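"""Elementary regulatory functions and the assembled right-hand side."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from memconsol import (ModelVariant, ParameterSet, derivatives, equilibrate,
                       frozen_from_basal, hill2, upstream_drive)
from memconsol.kernel import STATE_INDEX, STATE_NAMES
from memconsol.model import STANDARD


class TestHill2:
    def test_half_saturation(self):
        assert hill2(2.0, 2.0) == pytest.approx(0.5)
        assert hill2(0.011, 0.011) == pytest.approx(0.5)

    def test_zero_input(self):
        assert hill2(0.0, 0.19) == 0.0

    @given(x=st.floats(0, 1e3), K=st.floats(1e-6, 1e3))
    def test_bounded_and_monotone(self, x, K):
        v = hill2(x, K)
        assert 0.0 <= v <= 1.0  # equality only at float rounding
        assert hill2(x + 1.0, K) >= v

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            hill2(-1.0, 1.0)
        with pytest.raises(ValueError):
            hill2(1.0, 0.0)


class TestUpstreamDrive:
    def test_basal_product_gives_zero(self):
        assert upstream_drive(0.1, 0.12, 0.1, 0.12) == 0.0

    def test_positive_excess(self):
        assert upstream_drive(0.2, 0.12, 0.1, 0.12) == pytest.approx(0.012)

    def test_negative_excess_clipped(self):
        assert upstream_drive(0.05, 0.12, 0.1, 0.12) == 0.0

    def test_rejects_negative_inputs(self):
        with pytest.raises(ValueError):
            upstream_drive(-0.1, 0.12, 0.1, 0.12)


class TestDerivatives:
    def test_basal_state_is_fixed_point(self, std_params, std_basal):
        dy = derivatives(std_basal, 0.0, std_params)
        assert np.max(np.abs(dy)) < 1e-12

    def test_stimulus_terms(self, std_params, std_basal):
        """During the pulse the BDNF rate gains r_BDNF*stim and the pCaMKII
        rate gains r_CaMKII*stim*[CaMKII]."""
        from memconsol.schedule import make_schedule

        sched = make_schedule(0.0, None, 0.0, std_params)
        d_off = derivatives(std_basal, 5000.0, std_params, sched)
        d_on = derivatives(std_basal, 30.0, std_params, sched)
        i = STATE_INDEX
        assert d_on[i["BDNF"]] - d_off[i["BDNF"]] == pytest.approx(
            std_params.r_BDNF * 0.03, rel=1e-12)
        free_ck = std_params.pCaMKII_total - std_basal[i["pCaMKII"]]
        assert d_on[i["pCaMKII"]] - d_off[i["pCaMKII"]] == pytest.approx(
            std_params.r_CaMKII * 0.03 * free_ck, rel=1e-12)

    def test_pcreb_fixed_point_without_bdnf(self, std_params):
        """With BDNF = 0 the phospho-CREB balance has the closed-form rest
        k_basal*CREB_total/(k_basal + k_dphos)."""
        y = np.full(len(STATE_NAMES), 1e-4)
        y[STATE_INDEX["BDNF"]] = 0.0
        p = std_params
        target = (p.k_basalp_creb * p.CREB_total
                  / (p.k_basalp_creb + p.k_dphos_creb))
        y[STATE_INDEX["pCREB"]] = target
        dy = derivatives(y, 0.0, p)
        assert target == pytest.approx(2.74e-3, rel=0.01)
        assert abs(dy[STATE_INDEX["pCREB"]]) < 1e-15

    def test_variant_identity(self, std_params, std_basal):
        d0 = derivatives(std_basal, 0.0, std_params)
        d1 = derivatives(std_basal, 0.0, std_params, variant=ModelVariant())
        assert np.array_equal(d0, d1)

    def test_loop_block_requires_frozen(self, std_params, std_basal):
        with pytest.raises(ValueError):
            derivatives(std_basal, 0.0, std_params,
                        variant=ModelVariant(block_w_loop=True))

    def test_loop_blocks_preserve_basal_fixed_point(self, std_params, std_basal):
        frozen = frozen_from_basal(std_basal, std_params)
        for flag in ("block_camkii_loop", "block_cebp_loop", "block_w_loop"):
            v = ModelVariant(**{flag: True})
            dy = derivatives(std_basal, 0.0, std_params, variant=v,
                             frozen=frozen)
            assert np.max(np.abs(dy)) < 1e-12, flag

    def test_no_mecp2_zeroes_both_effects(self, std_params, std_basal):
        v = ModelVariant(no_mecp2_effects=True)
        dy = derivatives(std_basal, 0.0, std_params, variant=v)
        assert dy[STATE_INDEX["E_MeCP2"]] == 0.0
        assert dy[STATE_INDEX["E_comp"]] == 0.0


def test_no_mecp2_basal_bdnf_production(std_params):
    """Without MeCP2 effects, transcription reduces to the basal rate plus
    the C/EBP term with no complex repression in the denominator."""
    v = ModelVariant(no_mecp2_effects=True)
    basal = equilibrate(std_params, v)
    i = STATE_INDEX
    p = std_params
    m, cebp = basal[i["bdnf_m"]], basal[i["CEBP"]]
    expected = (p.k_b_MeCP2 * (1.0 + 0.0)
                + p.k_f_bdnf * cebp ** 2 / (p.K_a_bdnf ** 2 + cebp ** 2)
                - p.k_degb * m / (m + p.K_db))
    dy = derivatives(basal, 0.0, p, variant=v)
    assert dy[i["bdnf_m"]] == pytest.approx(expected, abs=1e-18)
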