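"""Seven-parameter kinetic curve profiling of Ca2+ fluorescence traces.

Each well trace is reduced to seven characteristics:

* **P1** -- baseline fluorescence immediately before agonist injection
  (median of the last ``baseline_window_samples`` pre-injection samples).
  Because the dye slowly leaks out of the platelets, the baseline drifts
  upward during the pre-injection phase; taking only the terminal window
  makes P1 robust to that drift.  P1 doubles as F0, the reference for the
  baseline-subtracted response F - F0.
* **P2** -- maximal Ca2+ increase, P4 - F0.
* **P3** -- slope 1, the initial rise rate: least-squares slope of the
  rise, from the post-injection minimum (the injection-drop trough) to
  the first sample whose smoothed value reaches ``rise_fit_frac`` (0.9)
  of the response amplitude.  Ending the fit at an amplitude crossing
  rather than at the peak sample keeps every fitted point on the rise
  itself: the peak's argmax jitters by several samples under noise and
  would otherwise mix decay-phase points into the rise fit.
* **P4** -- peak fluorescence after agonist addition.  The peak is located
  on a median-filtered copy of the trace (width ``peak_filter_window_samples``,
  default 7) so that isolated noise spikes are never crowned as peaks;
  the reported value is the raw sample at the filtered argmax (ties
  resolve to the earliest sample, which preserves an exact kinked peak).
* **P5** -- slope 2, the post-peak decline: least-squares slope inside
  [peak, slope3 start), fitted from the first smoothed sample below
  ``F0 + slope2_absent_frac * (P4 - F0)`` over at most
  ``slope2_fit_duration_s`` seconds.  Sustained responses that
  never fall below that fraction of their amplitude have no decline
  phase; P5 is then exactly 0.  The criterion is applied to the
  baseline-subtracted response so that P5 is invariant to adding a
  constant to the whole trace, and anchoring the fit at the amplitude
  crossing keeps the fitted points on the decline itself rather than
  letting the noisy peak argmax shift the window.
* **P6** -- slope 3, the late-phase rate: least-squares slope from the
  configured late-phase start time (650 s for CRP, 500 s for thrombin,
  measured from recording start) to the end of the trace.  The start is
  clamped into the trace: first to ``trace end - 60 s`` when the
  configured time lies beyond the recording, then into
  [peak time, last sample - 5 samples].
* **P7** -- area under the curve: trapezoidal integral of the signed
  response F - F0 from injection to trace end.

All response parameters use the F - F0 convention rather than F/F0
ratios.  An optional diagnostic ratio column is available from
:func:`parameters_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, ProfilingError
from .plate_model import PlateLayout, WellTrace

PARAM_COLUMNS = ["p1", "p2", "p3", "p4", "p5", "p6", "p7"]


@dataclass
class ProfilingConfig:
    """Tunable knobs of the curve profiler.

    ``slope3_start_s`` maps agonist name to the late-phase start time in
    seconds from recording start.  ``slope2_absent_frac`` is the fraction
    of the response amplitude below which the signal must fall, inside the
    slope-2 window, for a decline to be considered present.
    """

    slope3_start_s: dict[str, float] = field(
        default_factory=lambda: {"CRP": 650.0, "thrombin": 500.0}
    )
    baseline_window_samples: int = 15
    smoothing_window_samples: int = 3
    peak_filter_window_samples: int = 7
    slope2_absent_frac: float = 0.97
    slope2_fit_duration_s: float = 60.0
    rise_fit_frac: float = 0.9
    auto_detect_injection: bool = False
    injection_search_halfwidth_s: float = 10.0
    slope3_tail_margin_samples: int = 5
    slope3_overrun_clamp_s: float = 60.0


@dataclass
class CurveParameters:
    """The seven curve characteristics of one trace, plus bookkeeping."""

    plate_id: str
    well_id: str
    p1_baseline_au: float
    p2_max_increase_au: float
    p3_slope1_au_s: float
    p4_peak_au: float
    p5_slope2_au_s: float
    p6_slope3_au_s: float
    p7_auc_au_s: float
    f0_au: float
    injection_index: int
    peak_index: int
    low_confidence_injection: bool = False

    def as_vector(self) -> np.ndarray:
        return np.array(
            [
                self.p1_baseline_au,
                self.p2_max_increase_au,
                self.p3_slope1_au_s,
                self.p4_peak_au,
                self.p5_slope2_au_s,
                self.p6_slope3_au_s,
                self.p7_auc_au_s,
            ]
        )


def locate_injection(
    trace: WellTrace,
    layout_injection_time_s: float,
    config: ProfilingConfig | None = None,
) -> tuple[int, bool]:
    """Return (sample index at injection, low_confidence flag).

    The configured injection time is mapped to the last sample at or before
    it.  In auto-detection mode the index of the largest single-step
    negative deflection within +-``injection_search_halfwidth_s`` of the
    configured time is returned instead; if no step in the window is a
    decrease at all, the configured index is kept and flagged low
    confidence.
    """
    config = config or ProfilingConfig()
    t = trace.time_s
    if not (t[0] <= layout_injection_time_s <= t[-1]):
        raise ParameterError(
            f"injection time {layout_injection_time_s} s outside trace span "
            f"[{t[0]}, {t[-1]}]"
        )
    configured = int(np.searchsorted(t, layout_injection_time_s, side="right") - 1)
    configured = max(configured, 0)
    if not config.auto_detect_injection:
        return configured, False
    half = config.injection_search_halfwidth_s
    in_window = np.where(
        (t >= layout_injection_time_s - half) & (t <= layout_injection_time_s + half)
    )[0]
    # steps[i] = F[i+1] - F[i]; a drop lands at the sample *before* the low point
    steps = np.diff(trace.fluorescence_au)
    candidates = in_window[in_window < len(steps)]
    if candidates.size == 0:
        return configured, True
    best = candidates[np.argmin(steps[candidates])]
    if steps[best] >= 0:  # monotone/flat trace: no drop to anchor on
        return configured, True
    return int(best), False


def compute_baseline(
    trace: WellTrace, injection_index: int, config: ProfilingConfig | None = None
) -> tuple[float, float]:
    """Median of the terminal pre-injection window; returns (P1, F0)."""
    config = config or ProfilingConfig()
    window = config.baseline_window_samples
    if injection_index < window:
        raise ProfilingError(
            f"{trace.plate_id}/{trace.well_id}: {injection_index} pre-injection "
            f"samples < baseline window {window}"
        )
    seg = trace.fluorescence_au[injection_index - window : injection_index]
    p1 = float(np.median(seg))
    return p1, p1


def _lsq_slope(t: np.ndarray, f: np.ndarray) -> float:
    """Least-squares line slope; 0 for degenerate windows (< 2 points)."""
    if t.size < 2:
        return 0.0
    t0 = t - t.mean()
    denom = float(np.dot(t0, t0))
    if denom == 0.0:
        return 0.0
    return float(np.dot(t0, f - f.mean()) / denom)


def _smooth(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or f.size < window:
        return f
    kernel = np.ones(window) / window
    sm = np.convolve(f, kernel, mode="same")
    # edges of 'same' convolution average over fewer real samples; renormalize
    counts = np.convolve(np.ones_like(f), kernel, mode="same")
    return sm / counts


def _median_filter(f: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or f.size < window:
        return f
    half = window // 2
    padded = np.pad(f, half, mode="edge")
    return np.median(np.lib.stride_tricks.sliding_window_view(padded, window), axis=1)


def profile_trace(
    trace: WellTrace,
    agonist: str,
    injection_index: int,
    config: ProfilingConfig | None = None,
    low_confidence_injection: bool = False,
) -> CurveParameters:
    """Extract P1-P7 from a single trace.

    ``injection_index`` is the last pre-injection sample (from
    :func:`locate_injection`); the post-injection segment starts one sample
    later.
    """
    config = config or ProfilingConfig()
    if agonist not in config.slope3_start_s:
        raise ParameterError(f"no slope3 start configured for agonist {agonist!r}")
    t = trace.time_s
    f = trace.fluorescence_au
    n = t.size
    if injection_index >= n - 1:
        raise ProfilingError(
            f"{trace.plate_id}/{trace.well_id}: trace does not extend past injection"
        )
    p1, f0 = compute_baseline(trace, injection_index, config)

    post = slice(injection_index + 1, n)
    f_post = f[post]
    t_post = t[post]

    # peak: argmax of the median-filtered post-injection signal; P4 is the
    # raw sample at that index (ties resolve to the earliest sample)
    sm = _smooth(f_post, config.smoothing_window_samples)
    filt = _median_filter(f_post, config.peak_filter_window_samples)
    local = int(np.argmax(filt))
    peak_index = injection_index + 1 + local
    p4 = float(f[peak_index])
    p2 = p4 - f0

    # slope 1: from the post-injection minimum (injection-drop trough) up
    # the rise, ending at the rise_fit_frac amplitude crossing (smoothed)
    pre_peak = f_post[: local + 1]
    trough = int(np.argmin(pre_peak))
    rise_end = local
    if p2 > 0:
        rise_threshold = f0 + config.rise_fit_frac * p2
        crossed = np.nonzero(sm[: local + 1] >= rise_threshold)[0]
        if crossed.size and crossed[0] > trough:
            rise_end = int(crossed[0])
    p3 = _lsq_slope(t_post[trough : rise_end + 1], f_post[trough : rise_end + 1])

    # slope 3 window start, clamped into the trace
    start_s = min(
        config.slope3_start_s[agonist], t[-1] - config.slope3_overrun_clamp_s
    )
    start_idx = int(np.searchsorted(t, start_s, side="left"))
    last_allowed = n - 1 - config.slope3_tail_margin_samples
    start_idx = int(np.clip(start_idx, peak_index, max(peak_index, last_allowed)))
    p6 = _lsq_slope(t[start_idx:], f[start_idx:])

    # slope 2: the post-peak decline, fitted inside [peak, slope3 start)
    # from the first smoothed sample below slope2_absent_frac of the
    # response amplitude.  No such sample means no decline phase: P5 = 0.
    # Anchoring the fit at the amplitude crossing (not the noisy peak
    # argmax) keeps the fitted points on the decline itself.
    p5 = 0.0
    if p2 > 0 and start_idx - peak_index >= 2:
        threshold = f0 + config.slope2_absent_frac * p2
        rel = slice(peak_index - (injection_index + 1), start_idx - (injection_index + 1))
        below = np.nonzero(sm[rel] < threshold)[0]
        if below.size:
            decline_start = peak_index + int(below[0])
            # fixed-duration fit window: sliding a constant-length window
            # along a linear decline leaves the slope estimate unchanged,
            # so crossing jitter cannot distort the statistic
            decline_end = start_idx
            if config.slope2_fit_duration_s is not None:
                cap = int(
                    np.searchsorted(
                        t, t[decline_start] + config.slope2_fit_duration_s, side="right"
                    )
                )
                decline_end = min(decline_end, cap)
            if decline_end - decline_start >= 2:
                p5 = min(_lsq_slope(t[decline_start:decline_end], f[decline_start:decline_end]), 0.0)

    # AUC of the signed response from injection to trace end
    p7 = float(np.trapezoid(f[injection_index:] - f0, t[injection_index:]))

    return CurveParameters(
        plate_id=trace.plate_id,
        well_id=trace.well_id,
        p1_baseline_au=p1,
        p2_max_increase_au=p2,
        p3_slope1_au_s=p3,
        p4_peak_au=p4,
        p5_slope2_au_s=p5,
        p6_slope3_au_s=p6,
        p7_auc_au_s=p7,
        f0_au=f0,
        injection_index=injection_index,
        peak_index=peak_index,
        low_confidence_injection=low_confidence_injection,
    )


def profile_plate(
    layout: PlateLayout,
    traces: dict[str, WellTrace],
    config: ProfilingConfig | None = None,
) -> pd.DataFrame:
    """Profile every trace of a plate; returns a tidy parameter table.

    Columns: plate, well, role, compound_id, p1..p7, f0, injection_index,
    peak_index, low_confidence_injection.
    """
    config = config or ProfilingConfig()
    rows = []
    for well_id in sorted(traces):
        trace = traces[well_id]
        idx, low_conf = locate_injection(trace, layout.injection_time_s, config)
        params = profile_trace(trace, layout.agonist, idx, config, low_conf)
        assign = layout.wells[well_id]
        rows.append(
            {
                "plate": layout.plate_id,
                "well": well_id,
                "role": assign.role,
                "compound_id": assign.compound_id,
                "p1": params.p1_baseline_au,
                "p2": params.p2_max_increase_au,
                "p3": params.p3_slope1_au_s,
                "p4": params.p4_peak_au,
                "p5": params.p5_slope2_au_s,
                "p6": params.p6_slope3_au_s,
                "p7": params.p7_auc_au_s,
                "f0": params.f0_au,
                "injection_index": params.injection_index,
                "peak_index": params.peak_index,
                "low_confidence_injection": params.low_confidence_injection,
            }
        )
    return pd.DataFrame(rows)


def parameters_table(
    tables: list[pd.DataFrame], include_ratio: bool = False
) -> pd.DataFrame:
    """Concatenate per-plate parameter tables; optional F/F0 diagnostic."""
    out = pd.concat(tables, ignore_index=True)
    if include_ratio:
        out["peak_over_f0"] = out["p4"] / out["f0"]
    return out
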