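"""Domain containers for the xanthophyll-cycle / quenching pipeline.

Plain frozen dataclasses with eager validation.  Concentrations carry an
explicit ``unit_label`` (never converted implicitly); times are minutes for
the in-vitro assay and seconds for in-vivo light protocols.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DataError

__all__ = [
    "PigmentProfile",
    "EnzymePHProfile",
    "LightToPH",
    "QuenchingParams",
    "KineticModel",
    "Segment",
    "LightSchedule",
    "SimulationResult",
    "PAMTrace",
    "NPQResult",
    "Spectrum77K",
    "GaussianComponent",
    "GaussianFit",
    "QuenchingResult",
    "DecayTrace",
    "DecayFit",
    "Chromatogram",
    "Peak",
    "PeakTable",
    "AssayKinetics",
    "AsymptoticFit",
    "NoiseSpec",
]

_PIGMENT_FIELDS = ("vio", "ant", "zea", "neo", "lut", "beta_car", "chl_a", "chl_b")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DataError(msg)


def _finite(x) -> bool:
    return bool(np.all(np.isfinite(x)))


@dataclass(frozen=True)
class PigmentProfile:
    """Concentrations of the xanthophyll-cycle and accessory pigments.

    The three cycle pigments (violaxanthin, antheraxanthin, zeaxanthin) are
    mandatory; accessory pigments default to zero.  ``below_detection`` lists
    pigments whose calibration window contained no peak.
    """

    vio: float
    ant: float
    zea: float
    neo: float = 0.0
    lut: float = 0.0
    beta_car: float = 0.0
    chl_a: float = 0.0
    chl_b: float = 0.0
    unit_label: str = "mol / 100 Chl"
    below_detection: tuple[str, ...] = ()

    def __post_init__(self):
        for name in _PIGMENT_FIELDS:
            v = getattr(self, name)
            _require(_finite(v) and v >= 0.0, f"pigment {name!r} must be finite and >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in _PIGMENT_FIELDS}


@dataclass(frozen=True)
class EnzymePHProfile:
    """Normalized pH-activity curve of a violaxanthin de-epoxidase.

    The curve is the product of an acid-side rising logistic and an
    alkaline-side falling logistic; the alkaline center is placed
    analytically so the continuous maximum sits exactly at ``ph_opt``.
    ``slope_acid`` / ``slope_alkaline`` are logistic scale parameters in pH
    units (smaller = steeper).  ``acid_offset`` is the distance (pH units)
    of the acid-side half-rise point below ``ph_opt``.
    """

    ph_opt: float = 5.1
    slope_acid: float = 0.35
    slope_alkaline: float = 0.60
    species_label: str = ""
    acid_offset: float = 1.0

    def __post_init__(self):
        _require(3.0 < self.ph_opt < 9.0, "ph_opt outside plausible range")
        _require(self.slope_acid > 0 and self.slope_alkaline > 0, "slopes must be > 0")
        _require(self.acid_offset > 0, "acid_offset must be > 0")


@dataclass(frozen=True)
class LightToPH:
    """Steady-state lumen pH as a saturating function of irradiance.

    ``ph_ss(I) = ph_dark - ph_span * I / (I + half_sat)`` with first-order
    relaxation time ``tau`` (s).  The lumen pH is a latent driver, not a
    measured quantity.
    """

    ph_dark: float = 7.0
    ph_span: float = 2.0
    half_sat: float = 1000.0  # µmol m⁻² s⁻¹
    tau: float = 30.0  # s

    def __post_init__(self):
        _require(self.ph_span >= 0 and self.half_sat > 0 and self.tau > 0,
                 "light→pH parameters out of range")

    def steady_ph(self, irradiance: float) -> float:
        return self.ph_dark - self.ph_span * irradiance / (irradiance + self.half_sat)


@dataclass(frozen=True)
class QuenchingParams:
    """Coupling of lumen pH / zeaxanthin / light dose to NPQ components.

    qE: fast, requires low lumen pH, amplitude modulated by a saturating
    zeaxanthin term with half-saturation ``qe_zea_half`` (kept small so few
    zeaxanthin molecules suffice to activate qE).  qZ: zeaxanthin-dependent,
    slowly relaxing.  qI: light-dose dependent, slowest.
    Times are seconds; concentrations in the units of the pigment state.
    """

    qe_max: float = 2.4
    qe_tau_ind: float = 45.0
    qe_tau_rel: float = 90.0
    qe_ph_half: float = 6.8
    qe_ph_slope: float = 0.10
    qe_zea_half: float = 0.25
    qe_zea_basal: float = 0.03
    qz_max: float = 4.0
    qz_zea_half: float = 0.8
    qz_tau_ind: float = 600.0
    qz_tau_rel: float = 1800.0
    qi_max: float = 0.6
    qi_irr_half: float = 500.0
    qi_tau_ind: float = 1200.0
    qi_tau_rel: float = 3600.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            _require(getattr(self, f.name) >= 0, f"{f.name} must be >= 0")


@dataclass(frozen=True)
class KineticModel:
    """Rate constants and couplings of the xanthophyll-cycle simulator.

    ``k_de1``/``k_de2`` are the Vio→Ant and Ant→Zea de-epoxidation rate
    constants, ``k_ep`` the (single) epoxidation constant for both reverse
    steps; all in min⁻¹.  ``dtt_inhibition`` is the multiplicative factor
    applied to the de-epoxidation rates when the inhibitor dithiothreitol
    is present (0 = complete inhibition, the default at 1 mM).
    """

    k_de1: float
    k_de2: float
    k_ep: float
    ph_profile: EnzymePHProfile
    dtt_inhibition: float = 0.0
    light_to_ph: LightToPH = field(default_factory=LightToPH)
    q_params: QuenchingParams = field(default_factory=QuenchingParams)
    species_label: str = ""

    def __post_init__(self):
        for name in ("k_de1", "k_de2", "k_ep"):
            v = getattr(self, name)
            _require(_finite(v) and v >= 0, f"{name} must be finite and >= 0")
        _require(0.0 <= self.dtt_inhibition <= 1.0, "dtt_inhibition must lie in [0, 1]")


@dataclass(frozen=True)
class Segment:
    """One constant-irradiance stretch of a light protocol."""

    duration: float  # s
    irradiance: float  # µmol m⁻² s⁻¹
    inhibitor: bool = False

    def __post_init__(self):
        _require(self.duration > 0, "segment duration must be > 0")
        _require(_finite(self.irradiance) and self.irradiance >= 0,
                 "irradiance must be finite and >= 0")


@dataclass(frozen=True)
class LightSchedule:
    """Ordered actinic-light segments plus the saturating-pulse raster.

    Saturating pulses (default 5000 µmol m⁻² s⁻¹) are fired every
    ``pulse_interval`` seconds from the start of the protocol; by convention
    the protocol opens with a dark segment so the first pulse measures the
    dark-adapted Fm.
    """

    segments: tuple[Segment, ...]
    pulse_interval: float = 60.0
    pulse_irradiance: float = 5000.0

    def __post_init__(self):
        _require(len(self.segments) > 0, "schedule must contain at least one segment")
        _require(self.pulse_interval > 0, "pulse_interval must be > 0")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    def boundaries(self) -> np.ndarray:
        """Segment edge times, starting at 0."""
        return np.concatenate([[0.0], np.cumsum([s.duration for s in self.segments])])

    def irradiance_at(self, t: float) -> float:
        edges = self.boundaries()
        idx = min(int(np.searchsorted(edges, t, side="right")) - 1, len(self.segments) - 1)
        return self.segments[max(idx, 0)].irradiance

    def pulse_times(self, offset: float | None = None) -> np.ndarray:
        """Pulse firing times; ``offset`` defaults to half an interval."""
        if offset is None:
            offset = 0.5 * self.pulse_interval
        return np.arange(offset, self.total_duration, self.pulse_interval)


@dataclass(frozen=True)
class SimulationResult:
    """Trajectory of pigments, lumen pH, DI, and NPQ components."""

    time: np.ndarray
    vio: np.ndarray
    ant: np.ndarray
    zea: np.ndarray
    di: np.ndarray
    lumen_ph: np.ndarray
    npq_total: np.ndarray
    q_e: np.ndarray
    q_z: np.ndarray
    q_i: np.ndarray
    time_unit: str = "s"
    conversion: float | None = None  # in-vitro endpoint, if applicable

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time": self.time,
                "vio": self.vio,
                "ant": self.ant,
                "zea": self.zea,
                "di": self.di,
                "lumen_ph": self.lumen_ph,
                "npq_total": self.npq_total,
                "q_e": self.q_e,
                "q_z": self.q_z,
                "q_i": self.q_i,
            }
        )


@dataclass(frozen=True)
class PAMTrace:
    """Raw saturating-pulse fluorometry trace with its light protocol."""

    time: np.ndarray
    fluorescence: np.ndarray
    schedule: LightSchedule
    pulse_times: np.ndarray

    def __post_init__(self):
        _require(len(self.time) == len(self.fluorescence), "time/fluorescence length mismatch")
        _require(_finite(self.fluorescence) and np.all(self.fluorescence > 0),
                 "fluorescence must be finite and > 0")
        pt = np.asarray(self.pulse_times, dtype=float)
        _require(np.all((pt >= self.time[0]) & (pt <= self.time[-1])),
                 "pulse_times must lie within the trace time range")


@dataclass(frozen=True)
class NPQResult:
    """Derived PAM quantities: Fm, Fm' series, NPQ(t), Fv/Fm, qE vs slow NPQ."""

    fm: float
    fm_prime: np.ndarray
    pulse_times: np.ndarray
    npq: np.ndarray
    fv_fm: float | None = None
    q_e: float | None = None
    q_islow: float | None = None


@dataclass(frozen=True)
class Spectrum77K:
    """Low-temperature (77 K) fluorescence emission spectrum."""

    wavelength: np.ndarray
    intensity: np.ndarray
    condition: str = ""  # e.g. "dark/no_dtt"

    def __post_init__(self):
        _require(len(self.wavelength) == len(self.intensity), "wavelength/intensity mismatch")
        _require(bool(np.all(np.diff(self.wavelength) > 0)), "wavelength must be increasing")


@dataclass(frozen=True)
class GaussianComponent:
    center: float  # nm
    sigma: float  # nm
    area: float  # intensity·nm
    role: str  # PSII | PSI | vibronic | standard


@dataclass(frozen=True)
class GaussianFit:
    components: tuple[GaussianComponent, ...]
    residual_rms: float

    def area(self, role: str) -> float:
        return float(sum(c.area for c in self.components if c.role == role))


@dataclass(frozen=True)
class QuenchingResult:
    """(A_dark − A_light)/A_light for the PSII and PSI band sums."""

    psii_q: float
    psi_q: float


@dataclass(frozen=True)
class DecayTrace:
    """Photon-counting fluorescence decay histogram."""

    time_bins: np.ndarray  # ps, uniform
    counts: np.ndarray
    irf: np.ndarray | None = None
    rep_period: float = 12500.0  # ps (80 MHz)

    def __post_init__(self):
        _require(len(self.time_bins) == len(self.counts), "bins/counts mismatch")
        _require(bool(np.all(self.counts >= 0)), "counts must be >= 0")
        dt = np.diff(self.time_bins)
        _require(bool(np.allclose(dt, dt[0])), "time bins must be uniform")
        if self.irf is not None:
            _require(len(self.irf) == len(self.time_bins), "IRF grid mismatch")


@dataclass(frozen=True)
class DecayFit:
    """Multi-exponential decay fit with amplitude- and intensity-weighted means."""

    lifetimes: tuple[float, ...]  # ps
    amplitudes: tuple[float, ...]  # fractions, sum to 1
    tau_avg: float  # amplitude-weighted, ps
    tau_avg_intensity: float  # intensity-weighted, ps
    chi2_reduced: float
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        _require(all(t > 0 for t in self.lifetimes), "lifetimes must be > 0")
        _require(all(a >= 0 for a in self.amplitudes), "amplitudes must be >= 0")
        _require(abs(sum(self.amplitudes) - 1.0) < 1e-6, "amplitudes must sum to 1")


@dataclass(frozen=True)
class Chromatogram:
    """Single-wavelength HPLC absorbance trace."""

    retention_time: np.ndarray  # min
    absorbance: np.ndarray  # mAU
    detection_wavelength: float = 445.0  # nm

    def __post_init__(self):
        _require(len(self.retention_time) == len(self.absorbance), "grid mismatch")
        _require(bool(np.all(np.diff(self.retention_time) > 0)),
                 "retention_time must be strictly increasing")
        _require(_finite(self.absorbance), "absorbance must be finite")


@dataclass(frozen=True)
class Peak:
    apex_time: float  # min
    area: float  # mAU·min
    assigned_pigment: str | None = None

    def __post_init__(self):
        _require(self.area >= 0, "peak area must be >= 0")


@dataclass(frozen=True)
class PeakTable:
    peaks: tuple[Peak, ...]

    def assigned(self) -> dict[str, Peak]:
        return {p.assigned_pigment: p for p in self.peaks if p.assigned_pigment}

    def unassigned(self) -> tuple[Peak, ...]:
        return tuple(p for p in self.peaks if p.assigned_pigment is None)


@dataclass(frozen=True)
class AssayKinetics:
    """Spectrophotometric de-epoxidation readout: (A505 − A540), normalized."""

    time: np.ndarray  # min
    a505: np.ndarray
    a540: np.ndarray
    delta_norm: np.ndarray
    no_activity: bool = False


@dataclass(frozen=True)
class AsymptoticFit:
    """Saturating-exponential relation y = y_max (1 − exp(−rate·x))."""

    y_max: float
    rate: float
    component_label: str = ""
    rmse: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class NoiseSpec:
    """Single seed plus per-modality noise amplitudes for the generators."""

    seed: int = 0
    pam_sigma: float = 0.005  # relative
    spectrum_sigma: float = 0.01  # relative
    chrom_sigma: float = 0.2  # mAU
    decay_peak_counts: int = 10_000

    def __post_init__(self):
        _require(self.seed >= 0, "seed must be >= 0")
        for name in ("pam_sigma", "spectrum_sigma", "chrom_sigma", "decay_peak_counts"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")

    def rng(self, stream: str = "") -> np.random.Generator:
        """Independent generator per named stream, all derived from ``seed``."""
        import zlib

        ss = np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stream.encode()),))
        return np.random.default_rng(ss)
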