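"""77 K spectra: standard normalization, Gaussian deconvolution, quenching."""

import numpy as np
import pytest

from xcquench import spectra77k, synthetic
from xcquench.errors import DataError
from xcquench.types import GaussianComponent, GaussianFit, NoiseSpec, Spectrum77K

AREAS = {"standard": 2.0, "psii_686": 2.0, "psii_698": 1.5, "psi_720": 2.5,
         "vibronic": 0.8}


def _fit(c686, c698, c720):
    return GaussianFit(components=(
        GaussianComponent(686.0, 6.0, c686, "PSII"),
        GaussianComponent(698.0, 8.0, c698, "PSII"),
        GaussianComponent(720.0, 11.0, c720, "PSI"),
        GaussianComponent(748.0, 18.0, 0.5, "vibronic"),
    ), residual_rms=0.0)


class TestNormalize:
    def test_standard_band_area_scaled_to_one(self):
        s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=0, spectrum_sigma=0.0))
        sn = spectra77k.normalize_to_standard(s)
        lo, hi = spectra77k.STANDARD_WINDOW
        mask = (sn.wavelength >= lo) & (sn.wavelength <= hi)
        assert np.trapezoid(sn.intensity[mask], sn.wavelength[mask]) == pytest.approx(1.0)

    def test_global_scaling_removed(self):
        s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=1, spectrum_sigma=0.0))
        s2 = Spectrum77K(s.wavelength, 3.7 * s.intensity)
        a = spectra77k.normalize_to_standard(s)
        b = spectra77k.normalize_to_standard(s2)
        assert np.allclose(a.intensity, b.intensity)

    def test_missing_standard_band_rejected(self):
        s = synthetic.gen_spectrum77k({"psii_686": 1.0},
                                      NoiseSpec(seed=0, spectrum_sigma=0.0))
        with pytest.raises(DataError):
            spectra77k.normalize_to_standard(s)


class TestFitGaussians:
    def test_noiseless_three_band_recovery_within_1_percent(self):
        s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=0, spectrum_sigma=0.0))
        fit = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
        assert fit.area("PSII") == pytest.approx((2.0 + 1.5) / 2.0, rel=0.01)
        assert fit.area("PSI") == pytest.approx(2.5 / 2.0, rel=0.01)
        centers = sorted(c.center for c in fit.components)
        assert centers == pytest.approx([686.0, 698.0, 720.0, 748.0], abs=0.5)

    def test_single_band_input_leaves_other_components_empty(self):
        s = synthetic.gen_spectrum77k({"standard": 1.0, "psii_686": 3.0},
                                      NoiseSpec(seed=0, spectrum_sigma=0.0))
        fit = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
        areas = sorted(c.area for c in fit.components)
        assert sum(areas[:2]) < 0.01 * sum(areas)

    def test_zero_psi_band_not_detected(self):
        areas = dict(AREAS, psi_720=0.0)
        s = synthetic.gen_spectrum77k(areas, NoiseSpec(seed=2, spectrum_sigma=0.0))
        fit = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
        total = sum(c.area for c in fit.components)
        assert fit.area("PSI") < 0.01 * total

    def test_center_errors_below_1_nm_at_default_noise(self):
        errs = []
        for seed in range(100):
            s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=seed))
            fit = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
            centers = sorted(c.center for c in fit.components)
            errs.append(np.max(np.abs(np.asarray(centers)
                                      - np.array([686.0, 698.0, 720.0, 748.0]))))
        assert np.median(errs) < 1.0

    def test_area_recovery_unbiased_within_2_percent_at_default_noise(self):
        psii, psi = [], []
        for seed in range(100):
            s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=seed))
            fit = spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s))
            psii.append(fit.area("PSII"))
            psi.append(fit.area("PSI"))
        assert np.mean(psii) == pytest.approx(1.75, rel=0.02)
        assert np.mean(psi) == pytest.approx(1.25, rel=0.02)

    def test_centers_outside_range_rejected(self):
        s = synthetic.gen_spectrum77k(AREAS, NoiseSpec(seed=0))
        with pytest.raises(DataError):
            spectra77k.fit_gaussians(s, init_centers=(500.0,), roles=("PSII",))


class TestPSQuenching:
    def test_identical_fits_give_zero(self):
        fit = _fit(2.0, 1.5, 2.5)
        q = spectra77k.ps_quenching(fit, fit)
        assert q.psii_q == pytest.approx(0.0)
        assert q.psi_q == pytest.approx(0.0)

    def test_formula_arithmetic(self):
        dark = _fit(1.2, 0.8, 1.5)  # PSII sum 2.0, PSI 1.5
        light = _fit(0.6, 0.4, 1.0)  # PSII sum 1.0, PSI 1.0
        q = spectra77k.ps_quenching(dark, light)
        assert q.psii_q == pytest.approx(1.0)
        assert q.psi_q == pytest.approx(0.5)

    def test_dark_denominator_convention(self):
        dark = _fit(1.2, 0.8, 1.5)
        light = _fit(0.6, 0.4, 1.0)
        q = spectra77k.ps_quenching(dark, light, denominator="dark")
        assert q.psii_q == pytest.approx(0.5)
        assert q.psi_q == pytest.approx(1.0 / 3.0)

    def test_invariant_to_common_rescaling(self):
        dark, light = _fit(2.0, 1.0, 1.6), _fit(1.0, 0.7, 1.2)
        q1 = spectra77k.ps_quenching(dark, light)
        scale = lambda f, c: GaussianFit(  # noqa: E731
            components=tuple(GaussianComponent(x.center, x.sigma, c * x.area, x.role)
                             for x in f.components), residual_rms=f.residual_rms)
        q2 = spectra77k.ps_quenching(scale(dark, 5.0), scale(light, 5.0))
        assert q2.psii_q == pytest.approx(q1.psii_q)
        assert q2.psi_q == pytest.approx(q1.psi_q)

    def test_zero_light_area_rejected(self):
        with pytest.raises(DataError):
            spectra77k.ps_quenching(_fit(1.0, 1.0, 1.0), _fit(0.0, 0.0, 1.0))

    def test_vde_inhibition_weakens_both_psii_and_psi_quenching(self):
        """Synthetic dark/light pairs with and without the inhibitor: the
        weaker de-epoxidation under DTT must yield smaller quenching for
        both photosystems."""
        def pair(q_psii, q_psi, seed):
            dark = {"standard": 1.0, "psii_686": 2.0, "psii_698": 1.5,
                    "psi_720": 2.5, "vibronic": 0.8}
            light = dict(dark,
                         psii_686=2.0 / (1 + q_psii), psii_698=1.5 / (1 + q_psii),
                         psi_720=2.5 / (1 + q_psi))
            fits = []
            for i, areas in enumerate((dark, light)):
                s = synthetic.gen_spectrum77k(areas, NoiseSpec(seed=seed + i,
                                                               spectrum_sigma=0.002))
                fits.append(spectra77k.fit_gaussians(spectra77k.normalize_to_standard(s)))
            return spectra77k.ps_quenching(*fits)

        q_ctrl = pair(1.0, 0.5, seed=10)
        q_dtt = pair(0.3, 0.15, seed=20)
        assert q_dtt.psii_q < q_ctrl.psii_q
        assert q_dtt.psi_q < q_ctrl.psi_q
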