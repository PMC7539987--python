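"""77 K fluorescence emission spectra: normalization, Gaussian deconvolution
and photosystem-resolved quenching.

At liquid-nitrogen temperature the PSII (686 and 698 nm) and PSI (~720 nm)
emission bands are resolvable; a green-fluorescent-protein (GFP) band added
to each sample serves as internal intensity standard.  Quenching per
photosystem is (A_dark − A_light)/A_light over the summed band areas.
"""

from __future__ import annotations

import numpy as np
from lmfit import Parameters, minimize

from .errors import ConvergenceError, DataError
from .types import GaussianComponent, GaussianFit, QuenchingResult, Spectrum77K

__all__ = [
    "normalize_to_standard",
    "fit_gaussians",
    "ps_quenching",
    "DEFAULT_CENTERS",
    "DEFAULT_ROLES",
    "STANDARD_WINDOW",
    "CHL_FIT_RANGE",
]

STANDARD_WINDOW = (500.0, 540.0)  # nm, GFP emission band
CHL_FIT_RANGE = (660.0, 780.0)  # nm, chlorophyll emission region
DEFAULT_CENTERS = (686.0, 698.0, 720.0, 748.0)
DEFAULT_ROLES = ("PSII", "PSII", "PSI", "vibronic")
CENTER_BOUND = 5.0  # nm, allowed shift of each component center


def _band_area(s: Spectrum77K, window: tuple[float, float]) -> float:
    lo, hi = window
    mask = (s.wavelength >= lo) & (s.wavelength <= hi)
    if not np.any(mask):
        raise DataError(f"spectrum does not cover the window {window}")
    return float(np.trapezoid(s.intensity[mask], s.wavelength[mask]))


def normalize_to_standard(
    s: Spectrum77K, standard_window: tuple[float, float] = STANDARD_WINDOW
) -> Spectrum77K:
    """Scale the spectrum so the integrated standard-band area equals 1."""
    area = _band_area(s, standard_window)
    total = float(np.trapezoid(np.abs(s.intensity), s.wavelength))
    if area <= 0 or area < 1e-6 * max(total, np.finfo(float).tiny):
        raise DataError("no signal in the internal-standard window")
    return Spectrum77K(wavelength=s.wavelength, intensity=s.intensity / area,
                       condition=s.condition)


def _gauss(x, center, sigma, area):
    return area / (sigma * np.sqrt(2.0 * np.pi)) * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def fit_gaussians(
    s: Spectrum77K,
    init_centers: tuple[float, ...] = DEFAULT_CENTERS,
    roles: tuple[str, ...] = DEFAULT_ROLES,
    fit_range: tuple[float, float] = CHL_FIT_RANGE,
    init_sigma: float = 8.0,
) -> GaussianFit:
    """Bounded nonlinear least-squares deconvolution into Gaussian bands.

    Component centers are constrained within ±5 nm of their initial guess,
    sigmas to 2–25 nm, areas to be non-negative.
    """
    if len(init_centers) != len(roles):
        raise DataError("init_centers and roles must have equal length")
    lo, hi = fit_range
    if any(c < lo or c > hi for c in init_centers):
        raise DataError("initial centers must lie inside the fit range")
    mask = (s.wavelength >= lo) & (s.wavelength <= hi)
    x, y = s.wavelength[mask], s.intensity[mask]
    if x.size < 3 * len(init_centers):
        raise DataError("too few samples in the fit range")

    params = Parameters()
    for i, c in enumerate(init_centers):
        near = y[np.abs(x - c) < max(2.0, init_sigma)]
        amp0 = max(float(near.max()) if near.size else float(y.max()), 1e-12)
        params.add(f"c{i}", value=c, min=c - CENTER_BOUND, max=c + CENTER_BOUND)
        params.add(f"s{i}", value=init_sigma, min=2.0, max=25.0)
        params.add(f"a{i}", value=amp0 * init_sigma * np.sqrt(2 * np.pi) * 0.5,
                   min=0.0)

    def model(p):
        out = np.zeros_like(x)
        for i in range(len(init_centers)):
            out += _gauss(x, p[f"c{i}"], p[f"s{i}"], p[f"a{i}"])
        return out

    result = minimize(lambda p: model(p) - y, params, method="least_squares")
    if not result.success:
        raise ConvergenceError(
            "Gaussian deconvolution did not converge",
            diagnostics={"message": result.message,
                         "params": {k: float(v.value) for k, v in result.params.items()},
                         "nfev": result.nfev},
        )
    p = result.params
    comps = tuple(
        GaussianComponent(center=float(p[f"c{i}"]), sigma=float(p[f"s{i}"]),
                          area=float(p[f"a{i}"]), role=roles[i])
        for i in range(len(init_centers))
    )
    rms = float(np.sqrt(np.mean(np.asarray(result.residual) ** 2)))
    return GaussianFit(components=comps, residual_rms=rms)


def ps_quenching(
    dark: GaussianFit, light: GaussianFit, denominator: str = "light"
) -> QuenchingResult:
    """Photosystem-resolved quenching from dark vs light band areas.

    Default convention: (A_dark − A_light)/A_light for the PSII (686+698 nm)
    and PSI (720 nm) sums; ``denominator='dark'`` gives the alternative
    (A_dark − A_light)/A_dark.  The vibronic component enters neither sum.
    """
    if denominator not in ("light", "dark"):
        raise DataError(f"unknown denominator convention {denominator!r}")
    out = {}
    for role in ("PSII", "PSI"):
        a_d, a_l = dark.area(role), light.area(role)
        if a_l <= 0 or (denominator == "dark" and a_d <= 0):
            raise DataError(f"zero {role} area in the denominator condition")
        denom = a_l if denominator == "light" else a_d
        out[role] = (a_d - a_l) / denom
    return QuenchingResult(psii_q=out["PSII"], psi_q=out["PSI"])
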