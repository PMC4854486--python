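"""ATP/ADP kinetics and the six membrane currents."""

import math

import numpy as np
import pytest

from betacell import currents, metabolism
from betacell.params import load_parameters


class TestMetabolism:
    def test_atd_target_half_saturation(self, params):
        # G = K_GF gives exactly half the saturating ratio
        assert metabolism.atd_target(5200.0, 0.0, params) == pytest.approx(16.0)

    def test_atd_target_zero(self, params):
        assert metabolism.atd_target(0.0, 0.0, params) == 0.0

    def test_atd_target_high_glucose(self, params):
        # direct evaluation of the Hill form at 8 mM
        g = (8000.0 / 5200.0) ** 5
        expected = 32.0 * g / (1.0 + g)
        assert metabolism.atd_target(8000.0, 0.0, params) == pytest.approx(expected)
        assert expected == pytest.approx(28.67, abs=0.01)

    def test_ffa_glucose_equivalent(self, params):
        # 0.5 mM palmitate shifts the effective glucose by k_GFr·500 μM
        with_ffa = metabolism.atd_target(8300.0, 500.0, params)
        pure = metabolism.atd_target(8300.0 + 7.4 * 500.0, 0.0, params)
        assert with_ffa == pytest.approx(pure, rel=1e-12)

    def test_d_atd_fixed_point_and_rate(self, params):
        target = metabolism.atd_target(5200.0, 0.0, params)
        assert metabolism.d_atd(target, 5200.0, 0.0, params) == 0.0
        assert metabolism.d_atd(0.0, 5200.0, 0.0, params) == pytest.approx(0.16)

    def test_relaxation_is_exponential(self, params):
        # closed form: ATD(t) = target + (ATD0 - target)·exp(-t/t_ATD)
        target = metabolism.atd_target(3000.0, 0.0, params)
        atd, dt = 1.5, 0.01
        for _ in range(20000):  # 200 s of forward Euler at fine step
            atd += dt * metabolism.d_atd(atd, 3000.0, 0.0, params)
        expected = target + (1.5 - target) * math.exp(-200.0 / 100.0)
        assert atd == pytest.approx(expected, rel=1e-3)

    def test_nucleotide_partition_algebra(self, params):
        nuc = metabolism.nucleotide_partition(1.5, 0.0, params)
        assert nuc.ADP_f == pytest.approx(1600.0)
        assert nuc.ATP == pytest.approx(2400.0)
        assert nuc.MgADP_f == pytest.approx(88.0)
        assert nuc.ATP + nuc.ADP_f == pytest.approx(params.AT)

    def test_pka_halves_mgadp(self, params):
        base = metabolism.nucleotide_partition(1.5, 0.0, params)
        phos = metabolism.nucleotide_partition(1.5, 1.0, params)
        assert phos.MgADP_f == pytest.approx(base.MgADP_f / 2.0)

    def test_high_atd_limit(self, params):
        nuc = metabolism.nucleotide_partition(1e9, 0.0, params)
        assert nuc.ADP_f == pytest.approx(0.0, abs=1e-3)
        assert nuc.ATP == pytest.approx(4000.0, rel=1e-6)


class TestKATP:
    def test_open_fraction_no_nucleotides(self, params):
        assert currents.katp_open_fraction(0.0, 0.0, params) == pytest.approx(0.08)

    def test_open_fraction_at_kdd(self, params):
        # MgADP = k_dd, no ATP: (0.08·3 + 0.89)/(4·(1+0.45·17/26))
        expected = (0.08 * 3 + 0.89) / (4 * (1 + 0.45 * 17 / 26))
        got = currents.katp_open_fraction(17.0, 0.0, params)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.218, abs=0.001)

    def test_open_fraction_decreasing_in_atp(self, params):
        grid = np.linspace(0.0, 4000.0, 30)
        vals = [currents.katp_open_fraction(60.0, a, params) for a in grid]
        assert np.all(np.diff(vals) < 0)

    def test_current_zero_at_reversal(self, params):
        assert currents.current_ikatp(-75.0, 4200.0, 0.08, 24000.0, params) == 0.0

    def test_pip2_half_activation(self, params):
        full = currents.current_ikatp(-62.0, 1e12, 0.08, 24000.0, params)
        half = currents.current_ikatp(-62.0, 1125.0, 0.08, 24000.0, params)
        assert half == pytest.approx(full / 2.0, rel=1e-6)

    def test_current_magnitude(self, params):
        # g·f_KPI·O·(V−E_K) at V=−62, PIP2=4200, O=0.08
        got = currents.current_ikatp(-62.0, 4200.0, 0.08, 24000.0, params)
        assert got == pytest.approx(24000 * (4200 / 5325) * 0.08 * 13, rel=1e-12)
        assert got == pytest.approx(19695, rel=1e-3)


class TestOtherCurrents:
    def test_ikr_reversal_and_half_activation(self, params):
        assert currents.current_ikr(-75.0, params) == 0.0
        # at the half-activation potential the squared gate gives 1/4
        assert currents.current_ikr(-9.0, params) == pytest.approx(
            45000 * 0.25 * 66, rel=1e-12)

    def test_ica_zero_at_reversal(self, params):
        assert currents.current_ica(100.0, params) == 0.0

    def test_ica_inward_below_reversal(self, params):
        for v in (-70.0, -40.0, -20.0, 0.0):
            assert currents.current_ica(v, params) < 0.0

    def test_ica_frozen_value(self, params):
        # independent evaluation at V = −19 mV:
        # d = 1/(1+e^0+0.01), f = 1/(1+e^{2.5}), I = 900·d·f·(−119)
        d = 1.0 / (2.0 + 0.01)
        f = 1.0 / (1.0 + math.exp(2.5))
        assert currents.current_ica(-19.0, params) == pytest.approx(
            900 * d * f * -119.0, rel=1e-12)
        assert currents.current_ica(-19.0, params) == pytest.approx(-4042.0, rel=1e-3)

    def test_isoc_half_point_and_limits(self, params):
        # f_SOC = 1/2 at Ca_ER = K_NS
        i_half = currents.current_isoc(-62.0, 200.0, params)
        i_empty = currents.current_isoc(-62.0, 0.0, params)
        assert i_half == pytest.approx(i_empty / 2.0, rel=1e-12)
        # Ca_ER = 400: f_SOC = 1/17
        assert currents.current_isoc(-62.0, 400.0, params) == pytest.approx(
            10 * (1 / 17) * (-162.0), rel=1e-12)

    def test_ipca_saturation(self, params):
        assert currents.current_ipca(0.0, params) == 0.0
        assert currents.current_ipca(0.2, params) == pytest.approx(3000.0)
        assert currents.current_ipca(1e6, params) == pytest.approx(6000.0, rel=1e-6)

    def test_inab(self, params):
        assert currents.current_inab(70.0, 0.0, 0.0, params) == 0.0
        assert currents.current_inab(-62.0, 0.0, 0.0, params) == pytest.approx(-1320.0)
        # NALCN contribution: conductance g_mNM3·LRG6
        base = currents.current_inab(-62.0, 0.0, 0.0, params)
        with_nalcn = currents.current_inab(-62.0, 0.01, 35000.0, params)
        assert with_nalcn - base == pytest.approx(350.0 * -132.0, rel=1e-12)

    def test_dvp_sign_convention(self, params):
        outward = currents.CurrentBreakdown(100.0, 0, 0, 0, 0, 0)
        assert currents.d_vp(outward, params) < 0.0  # hyperpolarizing
        zero = currents.CurrentBreakdown(0, 0, 0, 0, 0, 0)
        assert currents.d_vp(zero, params) == 0.0


def test_gating_bounded_over_voltage_grid(params):
    vgrid = np.linspace(-120.0, 60.0, 200)
    for v in vgrid:
        d_kr = math.sqrt(currents.current_ikr(v, params)
                         / (params.g_mKr * (v - params.E_K))) if v != params.E_K else 0
        assert 0.0 <= d_kr <= 1.0
        ica = currents.current_ica(v, params)
        window = abs(ica / (params.g_mCa * (v - params.E_Ca))) if v != params.E_Ca else 0
        assert 0.0 <= window <= 1.0
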