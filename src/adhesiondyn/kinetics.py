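"""Assembly/disassembly kinetics of adhesion tracks.

Each kept track's mean-fluorescence-intensity (MFI) series is
baseline-subtracted (first frame), smoothed with a centred three-frame
running average, and split at its maximum. The rising half is fitted with a
three-parameter logistic ``A / (1 + exp(-r_a (t - t_a)))`` and the falling
half with an exponential decay ``D exp(-r_d (t - t_d))`` anchored at the
peak time. The steepness parameters ``r_a`` and ``r_d`` are the assembly and
disassembly rates (1/s). The quantitative lifetime is the time the fitted
intensity stays above half-maximum:

    lifetime = (t_d + ln 2 / r_d) - t_a

since the logistic reaches half its plateau at its midpoint ``t_a`` and the
decay halves after ``ln 2 / r_d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .track import PunctaTrack

__all__ = [
    "AssemblyFit",
    "DisassemblyFit",
    "KineticsResult",
    "preprocess_mfi",
    "fit_assembly",
    "fit_disassembly",
    "compute_lifetime",
    "analyze_track",
    "analyze_tracks",
]

#: bounds on fitted rates, 1/s
RATE_BOUNDS = (1e-3, 10.0)
#: a fit is rejected when SSE exceeds this fraction of the window's variance
REL_SSE_MAX = 0.2


@dataclass
class AssemblyFit:
    amplitude: float
    rate: float  # r_a, 1/s
    t_mid: float  # logistic midpoint, s (relative to track start)
    sse: float
    ok: bool
    message: str = ""


@dataclass
class DisassemblyFit:
    amplitude: float
    rate: float  # r_d, 1/s
    t_offset: float  # peak time the decay is anchored at, s
    sse: float
    ok: bool
    message: str = ""


@dataclass
class KineticsResult:
    track_id: int
    duration_frames: int
    baseline_subtracted: np.ndarray
    smoothed: np.ndarray
    smoothed_times_s: np.ndarray
    assembly_fit: AssemblyFit | None
    disassembly_fit: DisassemblyFit | None
    lifetime_s: float | None
    fit_ok: bool

    @property
    def assembly_rate(self) -> float | None:
        return self.assembly_fit.rate if self.assembly_fit and self.assembly_fit.ok else None

    @property
    def disassembly_rate(self) -> float | None:
        return self.disassembly_fit.rate if self.disassembly_fit and self.disassembly_fit.ok else None


def preprocess_mfi(mfi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Baseline-subtract then smooth an MFI series.

    The first frame's value is subtracted from every frame; a centred
    three-frame running average then drops both endpoints, so the smoothed
    series is two samples shorter than the input. Subtraction happens first —
    the two operations commute only up to the constant offset.
    """
    mfi = np.asarray(mfi, dtype=float)
    if len(mfi) < 3:
        raise ValueError("need at least 3 frames to smooth")
    baseline_subtracted = mfi - mfi[0]
    smoothed = (
        baseline_subtracted[:-2] + baseline_subtracted[1:-1] + baseline_subtracted[2:]
    ) / 3.0
    return baseline_subtracted, smoothed


def _logistic(t, amplitude, rate, t_mid):
    return amplitude / (1.0 + np.exp(-rate * (t - t_mid)))


def _argmax_first(series: np.ndarray) -> int:
    """Index of the maximum, ties broken to the earliest."""
    return int(np.argmax(series))


def fit_assembly(
    smoothed: np.ndarray, frame_interval_s: float, times_s: np.ndarray | None = None
) -> AssemblyFit:
    """Fit the logistic rise over the window from start through the argmax.

    ``times_s`` defaults to ``(i + 1) * frame_interval_s`` (the smoothed
    series starts one raw frame in). Returns ``ok=False`` for windows that are
    too short, essentially flat, monotone decreasing, poorly fit, or whose
    rate lands on a bound.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if times_s is None:
        times_s = (np.arange(len(smoothed)) + 1) * frame_interval_s
    peak = _argmax_first(smoothed)
    t = times_s[: peak + 1]
    y = smoothed[: peak + 1]
    if len(y) < 4:
        return AssemblyFit(np.nan, np.nan, np.nan, np.nan, False, "assembly window too short")
    amp0 = y.max()
    if amp0 <= 0 or np.ptp(y) <= 1e-12:
        return AssemblyFit(np.nan, np.nan, np.nan, np.nan, False, "no rise in window")
    slopes = np.diff(y) / np.diff(t)
    # max logistic slope is A*r/4
    r0 = np.clip(4.0 * slopes.max() / amp0, *RATE_BOUNDS)
    half_idx = int(np.argmin(np.abs(y - amp0 / 2.0)))
    p0 = (amp0, r0, t[half_idx])
    try:
        popt, _ = curve_fit(
            _logistic,
            t,
            y,
            p0=p0,
            bounds=([1e-9, RATE_BOUNDS[0], t[0] - 100.0], [np.inf, RATE_BOUNDS[1], t[-1] + 100.0]),
            maxfev=20000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except RuntimeError as exc:
        return AssemblyFit(np.nan, np.nan, np.nan, np.nan, False, f"no convergence: {exc}")
    amplitude, rate, t_mid = popt
    sse = float(np.sum((y - _logistic(t, *popt)) ** 2))
    var = float(np.sum((y - y.mean()) ** 2))
    ok = True
    message = ""
    if var > 0 and sse / var > REL_SSE_MAX:
        ok, message = False, "poor fit quality"
    if rate <= RATE_BOUNDS[0] * 1.5 or rate >= RATE_BOUNDS[1] / 1.02:
        ok, message = False, "rate at bounds"
    return AssemblyFit(float(amplitude), float(rate), float(t_mid), sse, ok, message)


def _decay(t, amplitude, rate, t_offset):
    return amplitude * np.exp(-rate * (t - t_offset))


def fit_disassembly(
    smoothed: np.ndarray, frame_interval_s: float, times_s: np.ndarray | None = None
) -> DisassemblyFit:
    """Fit the exponential decay over the window from the argmax to the end.

    The decay amplitude is pinned to the observed peak value ``P`` (the
    smoothed maximum) and the fit adjusts the rate and the peak-crossing
    time ``t_d`` where the curve equals ``P``: the sampled argmax
    systematically precedes the true peak by up to a frame (the rise is
    nearly flat there while the fall is not), so fitting ``t_d`` instead of
    pinning it removes that quantisation bias from the half-max time
    ``t_d + ln 2 / r_d``. The sample at the argmax itself is excluded from
    the fit window because the running average mixes rise and fall there.
    ``ok=False`` for short windows, monotone increasing series, near-flat
    tails, poor fits, or rates at bounds.
    """
    smoothed = np.asarray(smoothed, dtype=float)
    if times_s is None:
        times_s = (np.arange(len(smoothed)) + 1) * frame_interval_s
    peak = _argmax_first(smoothed)
    t = times_s[peak + 1 :]
    y = smoothed[peak + 1 :]
    amp = float(smoothed[peak])
    if len(y) < 4:
        return DisassemblyFit(np.nan, np.nan, np.nan, np.nan, False, "disassembly window too short")
    if amp <= 0:
        return DisassemblyFit(np.nan, np.nan, np.nan, np.nan, False, "non-positive peak")
    var = float(np.sum((y - y.mean()) ** 2))
    if var <= 1e-12:
        return DisassemblyFit(np.nan, np.nan, np.nan, np.nan, False, "flat decay window")
    t0_0 = float(times_s[peak])
    tail = max(float(y[-1]), 1e-12)
    r0 = np.clip(np.log(amp / tail) / max(t[-1] - t0_0, 1e-9), *RATE_BOUNDS)

    def model(tt, rate, t_offset):
        return _decay(tt, amp, rate, t_offset)

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=(r0, t0_0),
            bounds=([RATE_BOUNDS[0], t[0] - 100.0], [RATE_BOUNDS[1], t[-1]]),
            maxfev=20000,
            xtol=1e-12,
            ftol=1e-12,
        )
    except RuntimeError as exc:
        return DisassemblyFit(np.nan, np.nan, np.nan, np.nan, False, f"no convergence: {exc}")
    rate, t_offset = (float(v) for v in popt)
    sse = float(np.sum((y - model(t, *popt)) ** 2))
    ok = True
    message = ""
    if sse / var > REL_SSE_MAX:
        ok, message = False, "poor fit quality"
    if rate <= RATE_BOUNDS[0] * 1.5 or rate >= RATE_BOUNDS[1] / 1.02:
        ok, message = False, "rate at bounds"
    return DisassemblyFit(amp, rate, t_offset, sse, ok, message)


def compute_lifetime(
    assembly_fit: AssemblyFit, disassembly_fit: DisassemblyFit
) -> float | None:
    """Half-max lifetime from the two fitted curves, in seconds.

    ``(t_d + ln 2 / r_d) - t_a``; None (caller flags the track) when either
    fit failed or the value comes out non-positive.
    """
    if not (assembly_fit.ok and disassembly_fit.ok):
        return None
    lifetime = (
        disassembly_fit.t_offset + np.log(2.0) / disassembly_fit.rate - assembly_fit.t_mid
    )
    return float(lifetime) if lifetime > 0 else None


def analyze_track(track: PunctaTrack, frame_interval_s: float) -> KineticsResult:
    """Full kinetic analysis of one kept track."""
    baseline_subtracted, smoothed = preprocess_mfi(track.mfi_series)
    times = (np.arange(len(smoothed)) + 1) * frame_interval_s
    a_fit = fit_assembly(smoothed, frame_interval_s, times)
    d_fit = fit_disassembly(smoothed, frame_interval_s, times)
    lifetime = compute_lifetime(a_fit, d_fit) if (a_fit.ok and d_fit.ok) else None
    fit_ok = bool(a_fit.ok and d_fit.ok and lifetime is not None)
    return KineticsResult(
        track_id=track.track_id,
        duration_frames=track.n_frames,
        baseline_subtracted=baseline_subtracted,
        smoothed=smoothed,
        smoothed_times_s=times,
        assembly_fit=a_fit,
        disassembly_fit=d_fit,
        lifetime_s=lifetime,
        fit_ok=fit_ok,
    )


def analyze_tracks(
    tracks: list[PunctaTrack], frame_interval_s: float
) -> pd.DataFrame:
    """Tabulate kinetics for a list of tracks (one row per track)."""
    rows = []
    for t in tracks:
        res = analyze_track(t, frame_interval_s)
        rows.append(
            {
                "track_id": res.track_id,
                "duration_frames": res.duration_frames,
                "assembly_rate": res.assembly_rate,
                "disassembly_rate": res.disassembly_rate,
                "lifetime_s": res.lifetime_s,
                "fit_ok": res.fit_ok,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "track_id",
            "duration_frames",
            "assembly_rate",
            "disassembly_rate",
            "lifetime_s",
            "fit_ok",
        ],
    )
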