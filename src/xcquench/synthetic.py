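"""Seeded synthetic-instrument generators.

Each generator is the measurable inverse of exactly one analysis
operation: PAM traces invert the NPQ formula (pulse height
Fm/(1 + NPQ(t))), 77 K spectra are sums of the Gaussian bands the
deconvolution fits, decays are IRF-convolved multi-exponentials with
Poisson counting noise, chromatograms are Gaussian peaks whose areas
follow the linear calibration.  Noise models match instrument physics:
multiplicative Gaussian for fluorescence and spectra, additive Gaussian
for chromatogram baselines, Poisson for photon counting.  All randomness
flows through the single seed in :class:`~xcquench.types.NoiseSpec`.
"""

from __future__ import annotations

import numpy as np

from .decay import IRF_FWHM_STREAK, decay_model, _FWHM_TO_SIGMA
from .errors import DataError
from .pigments import DEFAULT_CALIBRATION, PigmentWindow
from .types import (
    Chromatogram,
    DecayTrace,
    LightSchedule,
    NoiseSpec,
    PAMTrace,
    PigmentProfile,
    SimulationResult,
    Spectrum77K,
)

__all__ = [
    "gen_pam_trace",
    "gen_spectrum77k",
    "gen_decay",
    "gen_chromatogram",
    "gen_assay_series",
    "SPECTRUM_CENTERS",
    "SPECTRUM_SIGMAS",
]

PULSE_DURATION = 0.6  # s
PAM_DT = 0.1  # s sampling interval

# the GFP standard band is placed fully inside the 500-540 nm window so the
# window integral equals the band area
SPECTRUM_CENTERS = {"standard": 518.0, "psii_686": 686.0, "psii_698": 698.0,
                    "psi_720": 720.0, "vibronic": 748.0}
SPECTRUM_SIGMAS = {"standard": 4.5, "psii_686": 6.0, "psii_698": 8.0,
                   "psi_720": 11.0, "vibronic": 18.0}


def gen_pam_trace(
    sim: SimulationResult,
    schedule: LightSchedule,
    fm0: float = 2.0,
    fo0: float = 0.4,
    noise: NoiseSpec = NoiseSpec(),
) -> PAMTrace:
    """Synthesize a saturating-pulse fluorometry trace from a simulation.

    Baseline fluorescence fo0/(1 + NPQ(t)); during each 0.6-s pulse the
    signal jumps to fm0/(1 + NPQ(t)) — the inversion of
    NPQ = (Fm − Fm')/Fm'.  Multiplicative Gaussian noise of relative
    amplitude ``noise.pam_sigma``.
    """
    if sim.time_unit != "s":
        raise DataError("PAM generation needs an in-vivo (seconds) simulation")
    duration = schedule.total_duration
    if sim.time[-1] < duration - 1e-9:
        raise DataError("simulation does not cover the schedule duration")
    t = np.arange(0.0, duration + PAM_DT / 2, PAM_DT)
    npq = np.interp(t, sim.time, sim.npq_total)
    f = fo0 / (1.0 + npq)
    pulses = schedule.pulse_times()
    for tp in pulses:
        mask = (t >= tp - PULSE_DURATION / 2) & (t <= tp + PULSE_DURATION / 2)
        # quenching is effectively frozen over the 0.6-s pulse: the plateau
        # height reflects NPQ at the pulse center
        npq_p = float(np.interp(tp, sim.time, sim.npq_total))
        f[mask] = fm0 / (1.0 + npq_p)
    rng = noise.rng("pam")
    f = f * (1.0 + noise.pam_sigma * rng.standard_normal(f.size))
    f = np.clip(f, 1e-6, None)
    return PAMTrace(time=t, fluorescence=f, schedule=schedule, pulse_times=pulses)


def gen_spectrum77k(
    areas: dict[str, float],
    noise: NoiseSpec = NoiseSpec(),
    wavelength: np.ndarray | None = None,
    condition: str = "",
) -> Spectrum77K:
    """Sum-of-Gaussians 77 K emission spectrum with a GFP standard band.

    ``areas`` maps band names (see :data:`SPECTRUM_CENTERS`) to integrated
    areas; missing bands default to 0.  Multiplicative Gaussian noise of
    relative amplitude ``noise.spectrum_sigma`` plus a small additive floor
    tied to the largest band.
    """
    if wavelength is None:
        wavelength = np.arange(500.0, 780.0 + 0.25, 0.5)
    unknown = set(areas) - set(SPECTRUM_CENTERS)
    if unknown:
        raise DataError(f"unknown spectral bands: {sorted(unknown)}")
    y = np.zeros_like(wavelength)
    for name, c in SPECTRUM_CENTERS.items():
        a = float(areas.get(name, 0.0))
        if a < 0:
            raise DataError("band areas must be >= 0")
        s = SPECTRUM_SIGMAS[name]
        y += a / (s * np.sqrt(2 * np.pi)) * np.exp(-0.5 * ((wavelength - c) / s) ** 2)
    rng = noise.rng("spectrum77k")
    floor = 1e-4 * (y.max() if y.max() > 0 else 1.0)
    y = y * (1.0 + noise.spectrum_sigma * rng.standard_normal(y.size)) \
        + floor * noise.spectrum_sigma * rng.standard_normal(y.size)
    return Spectrum77K(wavelength=wavelength, intensity=y, condition=condition)


def gen_decay(
    lifetimes,
    amplitudes,
    irf_fwhm: float = IRF_FWHM_STREAK,
    noise: NoiseSpec = NoiseSpec(),
    t_max: float = 200.0,
    n_bins: int = 400,
    rep_period: float = 12500.0,
    t0: float = 25.0,
    include_irf: bool = False,
) -> DecayTrace:
    """Poisson-noised multi-exponential decay convolved with a Gaussian IRF.

    The noise-free model is scaled so its peak expectation equals
    ``noise.decay_peak_counts``, then Poisson-sampled per bin.
    """
    lifetimes = tuple(float(x) for x in lifetimes)
    amplitudes = tuple(float(x) for x in amplitudes)
    if len(lifetimes) != len(amplitudes) or not lifetimes:
        raise DataError("lifetimes and amplitudes must align and be non-empty")
    t = np.linspace(0.0, t_max, n_bins, endpoint=False)
    model = decay_model(t, lifetimes, amplitudes, irf_fwhm * _FWHM_TO_SIGMA,
                        t0, rep_period=rep_period)
    if model.max() <= 0:
        raise DataError("degenerate decay model")
    expect = model * (noise.decay_peak_counts / model.max())
    rng = noise.rng("decay")
    counts = rng.poisson(expect).astype(float)
    irf = None
    if include_irf:
        sig = irf_fwhm * _FWHM_TO_SIGMA
        irf = np.exp(-0.5 * ((t - t0) / sig) ** 2)
        irf = irf / irf.sum() * noise.decay_peak_counts
    return DecayTrace(time_bins=t, counts=counts, irf=irf, rep_period=rep_period)


def gen_chromatogram(
    profile: PigmentProfile,
    calibration: dict[str, PigmentWindow] = DEFAULT_CALIBRATION,
    noise: NoiseSpec = NoiseSpec(),
    peak_sigma: float = 0.06,
    t_max: float = 15.0,
    dt: float = 0.005,
) -> Chromatogram:
    """Gaussian-peak chromatogram realizing a pigment profile.

    Each pigment with nonzero concentration contributes a Gaussian at its
    calibration window center with area = concentration / response factor
    (the exact inverse of the linear quantification).  Additive Gaussian
    baseline noise of ``noise.chrom_sigma`` mAU.
    """
    t = np.arange(0.0, t_max + dt / 2, dt)
    y = np.zeros_like(t)
    conc = profile.as_dict()
    for name, w in calibration.items():
        c = conc.get(name, 0.0)
        if c <= 0:
            continue
        area = c / w.response_factor
        y += area / (peak_sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((t - w.center) / peak_sigma) ** 2)
    rng = noise.rng("chromatogram")
    y = y + noise.chrom_sigma * rng.standard_normal(y.size)
    return Chromatogram(retention_time=t, absorbance=y)


def gen_assay_series(
    sim: SimulationResult,
    noise: NoiseSpec = NoiseSpec(),
    da_per_zea: float = 0.05,
    a_baseline: float = 0.30,
):
    """Absorption-spectra time series from an in-vitro simulation.

    Zeaxanthin formation raises absorption around 505 nm linearly
    (``da_per_zea`` absorbance units per concentration unit) on top of a
    flat carotenoid background; 540 nm is left untouched, so the
    (A505 − A540) readout tracks Zea(t).  Returns (time, wavelength,
    absorbance matrix).
    """
    wavelength = np.arange(470.0, 560.0 + 0.5, 1.0)
    band = np.exp(-0.5 * ((wavelength - 505.0) / 8.0) ** 2)
    rng = noise.rng("assay")
    rows = []
    for z in sim.zea:
        spec = a_baseline + da_per_zea * z * band
        spec = spec * (1.0 + 0.1 * noise.spectrum_sigma * rng.standard_normal(spec.size))
        rows.append(spec)
    return sim.time, wavelength, np.array(rows)
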