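"""Cardiac and respiratory nuisance regressors for fMRI denoising.

Raw photoplethysmogram and respiration-belt traces (typically 1000 Hz)
are anti-alias downsampled to 40 Hz and zero-phase low-pass filtered
(8 Hz cardiac, 2 Hz respiration). Beats are detected as prominent local
maxima with a refractory period. Two regressors are derived:

- *Heartbeat interval (HBI)*: the median inter-beat interval within a
  centred 6 s sliding window, convolved with the negated cardiac response
  function (Chang, Cunningham & Glover 2009, NeuroImage 44:857-69):

      CRF(t) = 0.6 t^2.7 exp(-t/1.6) - 16/sqrt(18 pi) exp(-(t-12)^2/18)

- *Respiratory variance (RV)*: the variance of the conditioned
  respiration trace within a centred 8 s sliding window, convolved with
  the respiratory response function (Birn et al. 2008, NeuroImage
  40:644-54):

      RRF(t) = 0.6 t^2.1 exp(-t/1.6) - 0.0023 t^3.54 exp(-t/4.25)

Both kernels are sampled on the regressor's output grid over their 60 s
support and normalised to unit peak absolute amplitude (the raw forms
are biphasic with near-zero net area, so peak normalisation is the
stable choice). Output rate defaults to 1 Hz to align with the
annotations; edge windows are truncated rather than padded.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .errors import (
    AliasingError,
    InsufficientDataError,
    InvalidParameterError,
)
from .types import PeakSet, PhysioTrace, RegressorSeries

CONDITIONED_RATE_HZ = 40.0
LOWPASS_HZ = {"cardiac": 8.0, "respiration": 2.0}
HBI_WINDOW_S = 6.0
RV_WINDOW_S = 8.0
RESPONSE_SUPPORT_S = 60.0


def cardiac_response_function(t: np.ndarray) -> np.ndarray:
    """Chang et al. (2009) cardiac response function, unit peak amplitude."""
    t = np.asarray(t, dtype=float)
    raw = 0.6 * t**2.7 * np.exp(-t / 1.6) - (16.0 / np.sqrt(18.0 * np.pi)) * np.exp(
        -((t - 12.0) ** 2) / 18.0
    )
    return raw / np.max(np.abs(raw))


def respiratory_response_function(t: np.ndarray) -> np.ndarray:
    """Birn et al. (2008) respiratory response function, unit peak amplitude."""
    t = np.asarray(t, dtype=float)
    raw = 0.6 * t**2.1 * np.exp(-t / 1.6) - 0.0023 * t**3.54 * np.exp(-t / 4.25)
    return raw / np.max(np.abs(raw))


def condition_trace(trace: PhysioTrace, target_rate_hz: float = CONDITIONED_RATE_HZ) -> PhysioTrace:
    """Anti-aliased downsample to 40 Hz plus zero-phase low-pass filter.

    The cut-off is 8 Hz for cardiac and 2 Hz for respiration traces. The
    filter is a 4th-order Butterworth applied forward-backward, so phase
    (hence peak timing) is preserved.
    """
    cutoff = LOWPASS_HZ[trace.modality]
    if trace.sampling_rate < 2 * target_rate_hz:
        raise AliasingError(
            f"input rate {trace.sampling_rate} Hz below 2x target rate "
            f"{target_rate_hz} Hz"
        )
    if target_rate_hz < 2 * cutoff:
        raise AliasingError(
            f"target rate {target_rate_hz} Hz below 2x the {cutoff} Hz cut-off"
        )
    frac = Fraction(target_rate_hz / trace.sampling_rate).limit_denominator(10_000)
    down = sps.resample_poly(trace.values, frac.numerator, frac.denominator, padtype="line")
    sos = sps.butter(4, cutoff, btype="low", fs=target_rate_hz, output="sos")
    filtered = sps.sosfiltfilt(sos, down)
    return PhysioTrace(
        modality=trace.modality,
        sampling_rate=target_rate_hz,
        values=filtered,
        run_id=trace.run_id,
    )


def detect_peaks(
    trace: PhysioTrace,
    min_period_s: float = 0.5,
    prominence: float | None = None,
    edits: Sequence[tuple[str, float]] = (),
) -> PeakSet:
    """Prominent local maxima with an enforced refractory period.

    ``prominence`` defaults to half the trace SD. ``edits`` mimics the
    manual-supervision step: ("add", t) inserts a peak at time t,
    ("remove", t) deletes the peak nearest t; every edit is logged on the
    returned :class:`PeakSet`.
    """
    fs = trace.sampling_rate
    if prominence is None:
        prominence = 0.5 * float(trace.values.std())
    if prominence <= 0:
        # Constant trace: no local maxima by definition.
        prominence = np.inf
    idx, _ = sps.find_peaks(
        trace.values,
        distance=max(int(round(min_period_s * fs)), 1),
        prominence=prominence,
    )
    times = list(idx / fs)
    if not times:
        warnings.warn("no peaks detected", stacklevel=2)
    log: list[str] = []
    for op, t in edits:
        if op == "add":
            times.append(float(t))
            times.sort()
            log.append(f"add peak at {t:.3f}s")
        elif op == "remove":
            if not times:
                raise InvalidParameterError("cannot remove from empty peak set")
            j = int(np.argmin(np.abs(np.asarray(times) - t)))
            log.append(f"remove peak at {times[j]:.3f}s (requested {t:.3f}s)")
            times.pop(j)
        else:
            raise InvalidParameterError(f"unknown edit operation {op!r}")
    return PeakSet(
        times=np.asarray(times),
        detection_params={"min_period_s": min_period_s, "prominence": float(prominence)},
        edit_log=log,
    )


def _convolve_response(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    full = np.convolve(values, kernel, mode="full")
    return full[: values.size]


def compute_hbi(
    peaks: PeakSet,
    duration_s: float | None = None,
    window_s: float = HBI_WINDOW_S,
    output_rate_hz: float = 1.0,
    response: np.ndarray | str | None = "default",
) -> RegressorSeries:
    """Sliding-window median heartbeat interval, convolved with -CRF.

    Each output sample is the median of the inter-beat intervals whose
    midpoints fall within the centred ``window_s`` window. Windows with
    no interval carry the nearest defined value (logged as a warning).
    ``response`` may be "default" (negated cardiac response function on
    the output grid), an explicit kernel array used as-is, or None to
    skip convolution (the bare windowed series).
    """
    if peaks.times.size < 2:
        raise InsufficientDataError("HBI needs at least 2 peaks")
    if duration_s is None:
        duration_s = float(peaks.times[-1])
    intervals = peaks.intervals
    midpoints = (peaks.times[:-1] + peaks.times[1:]) / 2.0
    n = int(round(duration_s * output_rate_hz))
    t_out = np.arange(n) / output_rate_hz
    half = window_s / 2.0
    hbi = np.full(n, np.nan)
    for i, t in enumerate(t_out):
        sel = (midpoints >= t - half) & (midpoints <= t + half)
        if sel.any():
            hbi[i] = np.median(intervals[sel])
    empty = np.isnan(hbi)
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} HBI windows contained no interval; "
            "carrying nearest defined value",
            stacklevel=2,
        )
        good = np.where(~empty)[0]
        if good.size == 0:
            raise InsufficientDataError("no window contains any inter-beat interval")
        nearest = good[np.argmin(np.abs(np.where(empty)[0][:, None] - good[None, :]), axis=1)]
        hbi[empty] = hbi[nearest]
    hbi = _apply_response(hbi, response, output_rate_hz, kind="HBI")
    return RegressorSeries(kind="HBI", values=hbi, output_rate=output_rate_hz, window_s=window_s)


def compute_rv(
    trace: PhysioTrace,
    window_s: float = RV_WINDOW_S,
    output_rate_hz: float = 1.0,
    response: np.ndarray | str | None = "default",
) -> RegressorSeries:
    """Sliding-window respiration variance, convolved with the RRF.

    Each output sample is the population variance of the conditioned
    respiration trace within the centred ``window_s`` window, truncated
    at the run edges. ``response`` behaves as in :func:`compute_hbi`.
    """
    if trace.duration_s < window_s:
        raise InsufficientDataError(
            f"trace of {trace.duration_s:.1f} s shorter than the "
            f"{window_s} s window"
        )
    fs = trace.sampling_rate
    n = int(round(trace.duration_s * output_rate_hz))
    half = window_s / 2.0
    rv = np.empty(n)
    for i in range(n):
        t = i / output_rate_hz
        lo = max(int(round((t - half) * fs)), 0)
        hi = min(int(round((t + half) * fs)) + 1, trace.values.size)
        rv[i] = trace.values[lo:hi].var()
    rv = _apply_response(rv, response, output_rate_hz, kind="RV")
    return RegressorSeries(kind="RV", values=rv, output_rate=output_rate_hz, window_s=window_s)


def _apply_response(values, response, output_rate_hz, kind):
    if response is None:
        return values
    if isinstance(response, str):
        if response != "default":
            raise InvalidParameterError(f"unknown response {response!r}")
        t = np.arange(0.0, RESPONSE_SUPPORT_S, 1.0 / output_rate_hz)
        if kind == "HBI":
            kernel = -cardiac_response_function(t)
        else:
            kernel = respiratory_response_function(t)
    else:
        kernel = np.asarray(response, dtype=float)
    return _convolve_response(values, kernel)
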