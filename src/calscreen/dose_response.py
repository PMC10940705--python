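"""Confirmation-stage percent inhibition and four-parameter logistic IC50.

The confirmation filter keeps compounds whose single-dose inhibition
(100 - percent of control) exceeds 25 % (strict).  Dose-response series
are then fitted by least squares to the four-parameter logistic

    R(c) = bottom + (top - bottom) / (1 + (c / IC50)^hill)

with IC50 optimized on the log10 scale and multi-start initialization
over the observed concentration range.  Bounds: hill in [0.2, 10],
bottom in [-10, 50] %, top in [50, 150] %, IC50 within
[min conc / 100, max conc * 100].  No weighting (homoscedastic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import ParameterError

HILL_BOUNDS = (0.2, 10.0)
BOTTOM_BOUNDS = (-10.0, 50.0)
TOP_BOUNDS = (50.0, 150.0)
INHIBITION_FILTER_PCT = 25.0


@dataclass
class DoseResponseSeries:
    compound_id: str
    agonist: str
    points: pd.DataFrame  # columns concentration_um, response_pct
    parameter: str = "p2"

    def __post_init__(self) -> None:
        conc = self.points["concentration_um"].to_numpy(dtype=float)
        if np.any(conc <= 0):
            raise ParameterError("concentrations must be positive")


@dataclass
class FourPLFit:
    bottom_pct: float
    top_pct: float
    hill: float
    ic50_um: float
    rss: float
    converged: bool
    reason: str = ""
    n_points: int = 0


def percent_inhibition(compound_response_pct: float) -> tuple[float, bool]:
    """Inhibition = 100 - percent of control; passes the filter when > 25 %."""
    inhibition = 100.0 - compound_response_pct
    return inhibition, inhibition > INHIBITION_FILTER_PCT


def _model(theta: np.ndarray, log_c: np.ndarray) -> np.ndarray:
    bottom, top, hill, log_ic50 = theta
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (log_c - log_ic50)))


def fit_4pl(series: DoseResponseSeries, init: dict | None = None) -> FourPLFit:
    """Least-squares 4PL fit with multi-start over log IC50.

    Returns ``converged=False`` with a reason when the responses carry no
    downward trend, the optimizer fails, or the fitted IC50 leaves
    [min conc / 100, max conc * 100].
    """
    conc = series.points["concentration_um"].to_numpy(dtype=float)
    resp = series.points["response_pct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(resp)):
        raise ParameterError("responses must be finite")
    if np.unique(conc).size < 4:
        raise ParameterError("need >= 4 distinct concentrations")
    log_c = np.log10(conc)

    order = np.argsort(conc)
    lo_mean = resp[order][: max(2, len(resp) // 3)].mean()
    hi_mean = resp[order][-max(2, len(resp) // 3) :].mean()
    if hi_mean >= lo_mean - 1e-12 and np.ptp(resp) < 1e-9:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, "flat responses", len(resp))
    if hi_mean >= lo_mean:
        return FourPLFit(
            np.nan, np.nan, np.nan, np.nan, np.nan, False, "no downward trend", len(resp)
        )

    lower = np.array([BOTTOM_BOUNDS[0], TOP_BOUNDS[0], HILL_BOUNDS[0], np.log10(conc.min() / 100.0)])
    upper = np.array([BOTTOM_BOUNDS[1], TOP_BOUNDS[1], HILL_BOUNDS[1], np.log10(conc.max() * 100.0)])

    starts = []
    bottom0 = float(np.clip(resp.min(), *BOTTOM_BOUNDS))
    top0 = float(np.clip(resp.max(), *TOP_BOUNDS))
    ic50_grid = np.log10(np.geomspace(conc.min(), conc.max(), 5))
    if init is not None and "ic50_um" in init:
        ic50_grid = np.append(ic50_grid, np.log10(init["ic50_um"]))
    for log_ic50_0 in ic50_grid:
        for hill0 in (0.7, 1.0, 2.0):
            starts.append(np.array([bottom0, top0, hill0, log_ic50_0]))

    best = None
    for theta0 in starts:
        theta0 = np.clip(theta0, lower, upper)
        try:
            result = least_squares(
                lambda th: _model(th, log_c) - resp,
                theta0,
                bounds=(lower, upper),
                method="trf",
            )
        except Exception:  # pragma: no cover - scipy failure path
            continue
        if best is None or result.cost < best.cost:
            best = result
    if best is None:
        return FourPLFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, "optimizer failed", len(resp))

    bottom, top, hill, log_ic50 = best.x
    ic50 = float(10.0 ** log_ic50)
    rss = float(2.0 * best.cost)
    in_range = conc.min() / 100.0 * (1 - 1e-9) <= ic50 <= conc.max() * 100.0 * (1 + 1e-9)
    return FourPLFit(
        bottom_pct=float(bottom),
        top_pct=float(top),
        hill=float(hill),
        ic50_um=ic50,
        rss=rss,
        converged=bool(best.success and in_range),
        reason="" if best.success and in_range else "IC50 outside admissible range",
        n_points=len(resp),
    )


def fit_table(series_list: list[DoseResponseSeries]) -> pd.DataFrame:
    """Fit many series; one row of FourPLFit fields per series."""
    rows = []
    for s in series_list:
        fit = fit_4pl(s)
        rows.append(
            {
                "compound_id": s.compound_id,
                "agonist": s.agonist,
                "parameter": s.parameter,
                "bottom_pct": fit.bottom_pct,
                "top_pct": fit.top_pct,
                "hill": fit.hill,
                "ic50_um": fit.ic50_um,
                "rss": fit.rss,
                "converged": fit.converged,
                "reason": fit.reason,
            }
        )
    return pd.DataFrame(rows)
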