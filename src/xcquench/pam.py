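"""Saturating-pulse (PAM) fluorometry analysis.

Extracts Fm / Fm' from pulse windows, computes NPQ = (Fm − Fm')/Fm',
Fv/Fm = (Fm − Fo)/Fm, and the relaxation-based split of end-of-light NPQ
into a fast (qE) and a slowly relaxing (qI or qZ, indistinguishable from a
single dark-recovery protocol) fraction.
"""

from __future__ import annotations

import logging

import numpy as np

from .errors import DataError
from .types import LightSchedule, NPQResult, PAMTrace

__all__ = ["extract_pulses", "compute_npq", "decompose_npq", "fv_fm", "analyze_trace"]

log = logging.getLogger(__name__)

PULSE_WINDOW = 0.4  # s, half-width around each annotated pulse time


def _dark_adapted_end(schedule: LightSchedule) -> float:
    """End time of the initial dark-adapted stretch (0 if none)."""
    edges = schedule.boundaries()
    for seg, t0 in zip(schedule.segments, edges):
        if seg.irradiance > 0:
            return float(t0)
    return float(edges[-1])


def _window_max(trace: PAMTrace, t_pulse: float, window: float) -> float:
    mask = (trace.time >= t_pulse - window) & (trace.time <= t_pulse + window)
    if not np.any(mask):
        raise DataError(f"no samples in pulse window around t={t_pulse:g} s")
    vals = trace.fluorescence[mask]
    imax = int(np.argmax(vals))  # first occurrence on ties
    if np.sum(vals == vals[imax]) > 1:
        log.info("pulse at t=%.3g s: tied maxima, using first occurrence", t_pulse)
    return float(vals[imax])


def extract_pulses(trace: PAMTrace, window: float = PULSE_WINDOW):
    """Return (fm, fm_prime array, fm_prime pulse times).

    Fm is the maximum fluorescence over pulse windows inside the initial
    dark-adapted segment; Fm' is the in-window maximum of every later pulse.
    """
    t_dark = _dark_adapted_end(trace.schedule)
    pulses = np.asarray(trace.pulse_times, dtype=float)
    dark_pulses = pulses[pulses < t_dark]
    if dark_pulses.size == 0:
        raise DataError("no saturating pulse in the dark-adapted segment: Fm undefined")
    fm = max(_window_max(trace, tp, window) for tp in dark_pulses)
    later = pulses[pulses >= t_dark]
    fm_prime = np.array([_window_max(trace, tp, window) for tp in later])
    return fm, fm_prime, later


def compute_npq(fm: float, fm_prime) -> np.ndarray:
    """NPQ = (Fm − Fm')/Fm' elementwise."""
    fm_prime = np.asarray(fm_prime, dtype=float)
    if fm <= 0:
        raise DataError("Fm must be > 0")
    if np.any(fm_prime <= 0):
        raise DataError("all Fm' values must be > 0")
    return (fm - fm_prime) / fm_prime


def decompose_npq(
    npq,
    pulse_times,
    schedule: LightSchedule,
    n_endpoint_pulses: int = 1,
):
    """Split NPQ into fast (qE) and slowly relaxing (qI/qZ) fractions.

    q_islow = NPQ at the last pulse(s) of the trailing dark-recovery
    segment; q_e = NPQ at the last pulse(s) in light minus q_islow.  By
    construction q_e + q_islow equals NPQ at the end of illumination.
    ``n_endpoint_pulses`` averages the last k pulses at each endpoint
    (default 1: single last pulse).
    """
    npq = np.asarray(npq, dtype=float)
    pulse_times = np.asarray(pulse_times, dtype=float)
    if npq.shape != pulse_times.shape:
        raise DataError("npq and pulse_times must align")
    if schedule.segments[-1].irradiance > 0:
        raise DataError("schedule must end with a dark-recovery segment")
    edges = schedule.boundaries()
    # start of the trailing run of dark segments
    i = len(schedule.segments) - 1
    while i > 0 and schedule.segments[i - 1].irradiance == 0:
        i -= 1
    t_dark_start = float(edges[i])
    in_dark = pulse_times >= t_dark_start
    in_light = ~in_dark
    if not np.any(in_dark) or not np.any(in_light):
        raise DataError("need pulses both in light and in the dark-recovery segment")
    k = max(1, int(n_endpoint_pulses))
    q_islow = float(np.mean(npq[in_dark][-k:]))
    npq_light_end = float(np.mean(npq[in_light][-k:]))
    return npq_light_end - q_islow, q_islow


def fv_fm(trace: PAMTrace, window: float = PULSE_WINDOW) -> float:
    """Maximum PSII quantum yield (Fm − Fo)/Fm.

    Fo is the median dark-adapted fluorescence outside pulse windows; Fm
    the dark-adapted pulse maximum.
    """
    t_dark = _dark_adapted_end(trace.schedule)
    if t_dark <= 0:
        raise DataError("no dark-adapted segment: Fo undefined")
    fm, _, _ = extract_pulses(trace, window)
    mask = trace.time < t_dark
    for tp in np.asarray(trace.pulse_times, float):
        mask &= ~((trace.time >= tp - window) & (trace.time <= tp + window))
    if not np.any(mask):
        raise DataError("no pre-pulse dark baseline samples: Fo undefined")
    fo = float(np.median(trace.fluorescence[mask]))
    if fm <= fo:
        raise DataError("Fm <= Fo: trace is not a valid induction measurement")
    return (fm - fo) / fm


def analyze_trace(
    trace: PAMTrace,
    window: float = PULSE_WINDOW,
    n_endpoint_pulses: int = 1,
) -> NPQResult:
    """Full pipeline: pulses → NPQ(t), Fv/Fm, qE / q_islow decomposition."""
    fm, fm_prime, t_pulses = extract_pulses(trace, window)
    npq = compute_npq(fm, fm_prime)
    try:
        q_e, q_islow = decompose_npq(npq, t_pulses, trace.schedule,
                                     n_endpoint_pulses=n_endpoint_pulses)
    except DataError:
        q_e = q_islow = None
    return NPQResult(fm=fm, fm_prime=fm_prime, pulse_times=t_pulses, npq=npq,
                     fv_fm=fv_fm(trace, window), q_e=q_e, q_islow=q_islow)
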