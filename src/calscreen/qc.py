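"""Duplicate-reproducibility (difference index) QC and artifact detection.

The difference index (DI) quantifies how well a compound's duplicate A/B
traces agree: pointwise ``r_t = |A_t - B_t| / (max(A u B) - min(A u B))``
-- the absolute difference divided by the combined range of both signals
-- summarized as the 95th percentile of the r_t.  DI <= 30 % is the
default consistency threshold.  The percentile uses linear interpolation
between order statistics (rank = q * (n - 1)), and the DI is computed on
the post-injection segments of the raw traces: pre-injection dye-leakage
drift differences would otherwise dominate the statistic.

Artifact detection replaces the visual curve inspection of a manual
workflow with two automated detectors:

* interference: a compound well whose pre-injection median fluorescence
  sits more than k MADs above (autofluorescent) or below (quenching) the
  plate's control pre-injection medians;
* injection failure: no injection-drop step in the trace AND a response
  below 5 % of the plate's control response -- a strong inhibitor with an
  intact drop artifact is never flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import QCError
from .plate_model import WellTrace
from .profiling import CurveParameters

import warnings


@dataclass
class QCConfig:
    di_percentile: float = 95.0
    di_threshold: float = 0.30
    interference_mad_multiplier: float = 6.0
    injection_artifact_min_drop_au: float = 25.0
    # a failed injection leaves only baseline drift + noise, which on a
    # 10-minute recording can reach several percent of the control response;
    # the artifact check (AND-ed) is what protects true strong inhibitors
    injection_failure_response_frac: float = 0.10
    injection_search_halfwidth_s: float = 10.0
    align_from_injection: bool = True
    min_aligned_length: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.di_threshold < 1):
            raise QCError("di_threshold must be in (0, 1)")
        if not (50 <= self.di_percentile <= 100):
            raise QCError("di_percentile must be in [50, 100]")


@dataclass
class DuplicateAssessment:
    compound_id: str
    agonist: str
    di: float
    consistent: bool
    n_timepoints: int


@dataclass
class ArtifactFlags:
    interference: str  # none | autofluorescent | quencher
    injection_failure: bool
    pre_median_au: float
    post_median_au: float


def di_from_arrays(a: np.ndarray, b: np.ndarray, percentile: float = 95.0) -> float:
    """The pure DI formula on two aligned signal arrays.

    Combined range of both signals in the denominator (not per-signal
    ranges); DI defined as 0 when both signals are constant and equal.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise QCError("signals must have equal length after alignment")
    combined_max = max(a.max(), b.max())
    combined_min = min(a.min(), b.min())
    rng = combined_max - combined_min
    if rng == 0.0:
        return 0.0
    r = np.abs(a - b) / rng
    return float(np.percentile(r, percentile))  # linear-interpolation percentile


def _aligned(
    ta: np.ndarray, fa: np.ndarray, tb: np.ndarray, fb: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int]:
    """Align two (time, signal) series on a common grid.

    When the grids differ, both are linearly interpolated onto the coarser
    grid restricted to the overlapping time span.
    """
    if ta.size == tb.size and np.array_equal(ta, tb):
        return fa, fb, ta.size
    lo = max(ta[0], tb[0])
    hi = min(ta[-1], tb[-1])
    if hi <= lo:
        raise QCError("traces do not overlap in time")
    coarser = ta if np.median(np.diff(ta)) >= np.median(np.diff(tb)) else tb
    grid = coarser[(coarser >= lo) & (coarser <= hi)]
    return np.interp(grid, ta, fa), np.interp(grid, tb, fb), grid.size


def difference_index(
    trace_a: WellTrace,
    trace_b: WellTrace,
    config: QCConfig | None = None,
    injection_index_a: int | None = None,
    injection_index_b: int | None = None,
    compound_id: str = "",
    agonist: str = "",
) -> DuplicateAssessment:
    """DI and consistency verdict for one duplicate trace pair."""
    config = config or QCConfig()
    ta, fa_full = trace_a.time_s, trace_a.fluorescence_au
    tb, fb_full = trace_b.time_s, trace_b.fluorescence_au
    if config.align_from_injection:
        if injection_index_a is None or injection_index_b is None:
            raise QCError("injection indices required when aligning from injection")
        ta, fa_full = ta[injection_index_a:], fa_full[injection_index_a:]
        tb, fb_full = tb[injection_index_b:], fb_full[injection_index_b:]
    if min(ta.size, tb.size) < config.min_aligned_length:
        raise QCError(
            f"only {min(ta.size, tb.size)} aligned timepoints "
            f"(< {config.min_aligned_length})"
        )
    fa, fb, n = _aligned(ta, fa_full, tb, fb_full)
    if n < config.min_aligned_length:
        raise QCError(f"only {n} aligned timepoints (< {config.min_aligned_length})")
    di = di_from_arrays(fa, fb, config.di_percentile)
    return DuplicateAssessment(
        compound_id=compound_id,
        agonist=agonist,
        di=di,
        consistent=di <= config.di_threshold,
        n_timepoints=n,
    )


def control_pre_median_summary(
    traces: dict[str, WellTrace],
    control_wells: list[str],
    injection_index: int,
) -> tuple[float, float]:
    """(median, MAD) of control wells' pre-injection median fluorescence."""
    if len(control_wells) < 8:
        raise QCError(f"need >= 8 control wells, got {len(control_wells)}")
    medians = np.array(
        [
            np.median(traces[w].fluorescence_au[:injection_index])
            for w in control_wells
        ]
    )
    center = float(np.median(medians))
    mad = float(np.median(np.abs(medians - center)))
    return center, mad


def detect_interference(
    trace: WellTrace,
    injection_index: int,
    control_pre_medians: tuple[float, float],
    config: QCConfig | None = None,
) -> ArtifactFlags:
    """Flag autofluorescent / quenching compounds from pre-injection medians."""
    config = config or QCConfig()
    center, mad = control_pre_medians
    if mad == 0.0:
        mad = 0.01 * abs(center)  # MAD floor: 1 % of control median
        warnings.warn("zero control MAD; using 1 % floor", stacklevel=2)
    pre = float(np.median(trace.fluorescence_au[:injection_index]))
    post = float(np.median(trace.fluorescence_au[injection_index:]))
    k = config.interference_mad_multiplier
    if pre > center + k * mad:
        flag = "autofluorescent"
    elif pre < center - k * mad:
        flag = "quencher"
    else:
        flag = "none"
    return ArtifactFlags(
        interference=flag, injection_failure=False, pre_median_au=pre, post_median_au=post
    )


def has_injection_drop(
    trace: WellTrace, injection_index: int, config: QCConfig | None = None
) -> bool:
    """True if a single-step decrease >= the configured drop is present
    near the injection time.

    The step scan runs on a 3-sample median-filtered copy of the trace so
    isolated noise excursions neither fake nor mask a drop.
    """
    config = config or QCConfig()
    t = trace.time_s
    f = trace.fluorescence_au
    t_inj = t[injection_index]
    half = config.injection_search_halfwidth_s
    # median filter width 3
    padded = np.pad(f, 1, mode="edge")
    filt = np.median(np.lib.stride_tricks.sliding_window_view(padded, 3), axis=1)
    steps = np.diff(filt)
    in_window = np.where((t[:-1] >= t_inj - half) & (t[:-1] <= t_inj + half))[0]
    if in_window.size == 0:
        return False
    return bool(np.min(steps[in_window]) <= -config.injection_artifact_min_drop_au)


def detect_injection_failure(
    trace: WellTrace,
    injection_index: int,
    params: CurveParameters,
    control_response_summary: tuple[float, float],
    config: QCConfig | None = None,
) -> bool:
    """Flag wells where the agonist was never added.

    Requires BOTH: no injection-drop artifact near the injection time, and
    a maximal response below ``injection_failure_response_frac`` of the
    plate's control median response.
    """
    config = config or QCConfig()
    control_median_p2, _ = control_response_summary
    if has_injection_drop(trace, injection_index, config):
        return False
    return params.p2_max_increase_au < config.injection_failure_response_frac * control_median_p2


def qc_table(assessments: list[DuplicateAssessment], flags: pd.DataFrame) -> pd.DataFrame:
    """Merge pair-level DI verdicts with pair-level artifact flags."""
    di_df = pd.DataFrame(
        [
            {
                "compound_id": a.compound_id,
                "agonist": a.agonist,
                "di": a.di,
                "consistent": a.consistent,
                "n_timepoints": a.n_timepoints,
            }
            for a in assessments
        ]
    )
    return di_df.merge(flags, on=["compound_id", "agonist"], how="left")
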