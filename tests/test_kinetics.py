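"""Xanthophyll-cycle simulator: pH activity, DI, in-vitro and in-vivo runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xcquench import kinetics
from xcquench.errors import DataError, DomainError, UndefinedDIError
from xcquench.types import KineticModel, LightSchedule, PigmentProfile, Segment

GRID = np.round(np.arange(4.0, 7.5 + 1e-9, 0.1), 10)


class TestPHActivity:
    def test_unity_at_optimum_for_both_species(self):
        assert kinetics.ph_activity(5.1, kinetics.ARABIDOPSIS_PH) == pytest.approx(1.0)
        assert kinetics.ph_activity(5.1, kinetics.CHLORELLA_PH) == pytest.approx(1.0)

    @pytest.mark.parametrize("profile", [kinetics.ARABIDOPSIS_PH, kinetics.CHLORELLA_PH],
                             ids=["arabidopsis", "chlorella"])
    def test_grid_argmax_at_ph_5_1(self, profile):
        act = kinetics.ph_activity(GRID, profile)
        assert GRID[int(np.argmax(act))] == pytest.approx(5.1)

    def test_chlorella_weaker_than_arabidopsis_on_alkaline_side(self):
        """The algal enzyme loses activity faster above the optimum."""
        hi = GRID[GRID > 5.5]
        a_cv = kinetics.ph_activity(hi, kinetics.CHLORELLA_PH)
        a_at = kinetics.ph_activity(hi, kinetics.ARABIDOPSIS_PH)
        assert np.all(a_cv <= a_at + 1e-12)
        assert kinetics.ph_activity(7.0, kinetics.CHLORELLA_PH) < \
            kinetics.ph_activity(7.0, kinetics.ARABIDOPSIS_PH)

    @given(ph=st.floats(3.0, 9.0))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_unimodal(self, ph):
        for prof in (kinetics.ARABIDOPSIS_PH, kinetics.CHLORELLA_PH):
            a = kinetics.ph_activity(ph, prof)
            assert 0.0 <= a <= 1.0
            # moving away from the optimum never increases activity
            step = 0.05 if ph >= prof.ph_opt else -0.05
            if 3.0 <= ph + step <= 9.0:
                assert kinetics.ph_activity(ph + step, prof) <= a + 1e-9 or \
                    abs(ph - prof.ph_opt) < 0.05

    @pytest.mark.parametrize("ph", [2.9, 9.1])
    def test_out_of_range_ph_rejected(self, ph):
        with pytest.raises(DomainError):
            kinetics.ph_activity(ph, kinetics.CHLORELLA_PH)


class TestComputeDI:
    @pytest.mark.parametrize("vio,ant,zea,expected", [
        (1.0, 0.0, 0.0, 0.0),
        (0.0, 0.0, 3.0, 1.0),
        (2.0, 1.0, 1.0, 0.375),
    ])
    def test_formula(self, vio, ant, zea, expected):
        p = PigmentProfile(vio=vio, ant=ant, zea=zea)
        assert kinetics.compute_di(p) == pytest.approx(expected)

    def test_empty_pool_is_an_error_not_zero(self):
        with pytest.raises(UndefinedDIError):
            kinetics.compute_di(PigmentProfile(vio=0.0, ant=0.0, zea=0.0))

    @given(vio=st.floats(0, 10), ant=st.floats(0, 10), zea=st.floats(0.001, 10))
    @settings(deadline=None, max_examples=50)
    def test_bounded_in_unit_interval(self, vio, ant, zea):
        di = kinetics.compute_di(PigmentProfile(vio=vio, ant=ant, zea=zea))
        assert 0.0 <= di <= 1.0


class TestInVitro:
    def test_arabidopsis_conversion_95_percent(self, at_vitro):
        sim = kinetics.simulate_in_vitro(at_vitro, 5.1, 0.33, 60.0)
        assert sim.conversion == pytest.approx(0.95, abs=1e-4)

    def test_chlorella_conversion_77_percent(self, cv_vitro):
        sim = kinetics.simulate_in_vitro(cv_vitro, 5.1, 0.33, 60.0)
        assert sim.conversion == pytest.approx(0.77, abs=1e-4)

    def test_complete_dtt_inhibition_blocks_conversion(self, cv_vitro):
        sim = kinetics.simulate_in_vitro(cv_vitro, 5.1, 0.33, 60.0, dtt=True)
        assert sim.conversion == pytest.approx(0.0, abs=1e-9)
        assert np.all(sim.di < 1e-9)

    def test_single_step_matches_closed_form(self):
        """With only the first step active, conversion = 1 − e^(−k·a·t)."""
        k = math.log(20.0) / 60.0  # k·a = ln(20)/60 at the optimum (a = 1)
        m = KineticModel(k_de1=k, k_de2=0.0, k_ep=0.0,
                         ph_profile=kinetics.ARABIDOPSIS_PH)
        sim = kinetics.simulate_in_vitro(m, 5.1, 0.33, 60.0)
        assert sim.conversion == pytest.approx(0.95, rel=1e-6)

    def test_fast_second_step_recovers_single_exponential_vio(self, at_vitro):
        m = KineticModel(k_de1=at_vitro.k_de1, k_de2=1e4 * at_vitro.k_de1,
                         k_ep=0.0, ph_profile=at_vitro.ph_profile)
        sim = kinetics.simulate_in_vitro(m, 5.1, 1.0, 60.0)
        expected = np.exp(-at_vitro.k_de1 * sim.time)
        assert np.max(np.abs(sim.vio - expected) / expected) < 1e-3

    def test_mass_conservation_and_monotone_di(self, cv_vitro):
        sim = kinetics.simulate_in_vitro(cv_vitro, 5.1, 0.33, 60.0)
        total = sim.vio + sim.ant + sim.zea
        assert np.max(np.abs(total - 0.33)) < 1e-6 * 0.33
        assert np.all(np.diff(sim.di) >= -1e-12)
        assert np.all((sim.di >= 0) & (sim.di <= 1))

    def test_conversion_increases_with_k_de1(self, cv_vitro):
        convs = []
        for scale in (0.5, 1.0, 2.0):
            m = KineticModel(k_de1=cv_vitro.k_de1 * scale, k_de2=cv_vitro.k_de2,
                             k_ep=0.0, ph_profile=cv_vitro.ph_profile)
            convs.append(kinetics.simulate_in_vitro(m, 5.1, 0.33, 60.0).conversion)
        assert convs[0] < convs[1] < convs[2]

    def test_neutral_dtt_factor_reproduces_uninhibited_run(self, cv_vitro):
        m = KineticModel(k_de1=cv_vitro.k_de1, k_de2=cv_vitro.k_de2, k_ep=0.0,
                         ph_profile=cv_vitro.ph_profile, dtt_inhibition=1.0)
        a = kinetics.simulate_in_vitro(m, 5.1, 0.33, 60.0)
        b = kinetics.simulate_in_vitro(m, 5.1, 0.33, 60.0, dtt=True)
        assert np.array_equal(a.vio, b.vio)
        assert np.array_equal(a.zea, b.zea)

    def test_zea_formed_basis_lags_consumed_basis(self, cv_vitro):
        consumed = kinetics.simulate_in_vitro(cv_vitro, 5.1, 0.33, 60.0).conversion
        formed = kinetics.simulate_in_vitro(
            cv_vitro, 5.1, 0.33, 60.0, conversion_basis="zea_formed").conversion
        assert 0 < formed < consumed

    def test_invalid_inputs_rejected(self, cv_vitro):
        with pytest.raises(DataError):
            kinetics.simulate_in_vitro(cv_vitro, 5.1, vio0=0.0)
        with pytest.raises(DataError):
            kinetics.simulate_in_vitro(cv_vitro, 5.1, t_end=-1.0)
        with pytest.raises(DataError):
            kinetics.simulate_in_vitro(cv_vitro, float("nan"))

    def test_numeric_calibration_matches_closed_form(self):
        k = kinetics.calibrate_k_de(0.77, kinetics.CHLORELLA_PH)
        assert k == pytest.approx(kinetics.K_DE_CHLORELLA, rel=1e-6)


class TestInVivo:
    def test_dark_only_zea_free_start_stays_quiescent(self, cv_vivo):
        sched = LightSchedule(segments=(Segment(600.0, 0.0),))
        sim = kinetics.simulate_in_vivo(cv_vivo, sched,
                                        PigmentProfile(vio=3.0, ant=0.0, zea=0.0))
        assert np.all(sim.di == 0.0)
        assert np.all(sim.npq_total == 0.0)

    def test_npq_components_sum_and_mass_conservation(self, hl_simulation):
        sim = hl_simulation
        assert np.allclose(sim.npq_total, sim.q_e + sim.q_z + sim.q_i)
        total = sim.vio + sim.ant + sim.zea
        assert np.max(np.abs(total - total[0])) < 1e-6 * total[0]
        assert np.all((sim.di >= 0) & (sim.di <= 1))
        assert np.all(sim.q_e >= 0) and np.all(sim.q_z >= 0) and np.all(sim.q_i >= 0)

    def test_dtt_blocks_zeaxanthin_accumulation(self, dtt_simulation):
        assert np.max(dtt_simulation.zea) < 1e-9
        assert np.max(dtt_simulation.q_z) < 1e-9

    def test_high_light_drives_deepoxidation(self, hl_simulation, hl_schedule):
        i_end = int(np.searchsorted(hl_simulation.time, hl_schedule.boundaries()[-2]))
        assert hl_simulation.di[i_end] > 0.3
        assert hl_simulation.npq_total[i_end] > 1.0

    def test_zeaxanthin_persists_through_dark_interval(self, cv_vivo, two_cycle_schedule):
        sim = kinetics.simulate_in_vivo(cv_vivo, two_cycle_schedule,
                                        PigmentProfile(vio=3.0, ant=0.0, zea=0.0))
        di_c1 = sim.di[int(np.searchsorted(sim.time, 60.0))]
        di_c2 = sim.di[int(np.searchsorted(sim.time, 660.0))]
        assert di_c2 > di_c1
        # <15% of the accumulated zeaxanthin reconverts over 5 min of dark
        z_light_end = sim.zea[int(np.searchsorted(sim.time, 360.0))]
        z_dark_end = sim.zea[int(np.searchsorted(sim.time, 660.0))]
        assert z_dark_end > 0.85 * z_light_end

    def test_negative_irradiance_rejected(self, cv_vivo):
        with pytest.raises(DataError):
            LightSchedule(segments=(Segment(60.0, -5.0),))

    def test_empty_pool_rejected(self, cv_vivo):
        sched = LightSchedule(segments=(Segment(60.0, 0.0),))
        with pytest.raises(DataError):
            kinetics.simulate_in_vivo(cv_vivo, sched,
                                      PigmentProfile(vio=0.0, ant=0.0, zea=0.0))
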