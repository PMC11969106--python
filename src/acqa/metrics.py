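"""Contour-accuracy statistics.

Per-session volume deviations are measured against the multi-threshold
baseline; across a weight-loss series, two summary statistics are reported
per contouring workflow:

* MAD — mean absolute volume deviation from the baseline (cm³); a workflow
  whose MAD exceeds the largest baseline SD of the series disagrees with
  manual contouring beyond its own uncertainty;
* R²% — how well a straight line of body volume against surface-layer
  thickness explains the measured volumes,
  ``R²% = 100 − var(y − y_fit)/var(y) · 100`` with population (1/N)
  variances; an accurate workflow tracks the known linear geometry closely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SessionResult",
    "FitResult",
    "mad",
    "variance",
    "r_squared",
    "summarize_sessions",
]


@dataclass
class SessionResult:
    """Contour volumes of one session, by workflow, against the baseline."""

    session_id: str
    thickness_cm: float
    baseline_mean_cm3: float
    baseline_sd_cm3: float
    volumes_cm3: dict = field(default_factory=dict)  # workflow → volume

    def deviation_cm3(self, source: str) -> float:
        """Signed deviation of one workflow's volume from the baseline mean."""
        return self.volumes_cm3[source] - self.baseline_mean_cm3


@dataclass
class FitResult:
    """Ordinary-least-squares line of volume on thickness."""

    slope: float  # cm³ per cm of surface layer
    intercept: float  # cm³
    fitted: np.ndarray
    r2_percent: float


def mad(deviations_cm3) -> float:
    """Mean absolute deviation (cm³) over a series of signed deviations."""
    deviations_cm3 = np.asarray(deviations_cm3, dtype=float)
    if deviations_cm3.size == 0:
        raise ValueError("MAD of an empty series is undefined")
    return float(np.mean(np.abs(deviations_cm3)))


def variance(x) -> float:
    """Population variance, 1/N normalization."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("variance of an empty series is undefined")
    return float(np.mean((x - x.mean()) ** 2))


def r_squared(x, y) -> tuple[float, FitResult]:
    """Percent of volume variance explained by the linear thickness fit.

    Requires at least 3 points and non-constant y.  Returns the R²% value
    together with the fit itself.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("at least 3 points are needed for the linear fit")
    var_y = variance(y)
    if var_y == 0:
        raise ValueError("R² undefined for constant y")
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    r2 = 100.0 - variance(y - fitted) / var_y * 100.0
    return float(r2), FitResult(
        slope=float(slope), intercept=float(intercept), fitted=fitted,
        r2_percent=float(r2),
    )


def summarize_sessions(
    sessions, max_baseline_sd_cm3: float | None = None, include_reference: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Study table and per-workflow summary over a session series.

    Returns a per-session DataFrame (thickness, baseline mean ± SD, volume
    and deviation per workflow) and a dict per workflow holding MAD, R²
    against thickness, and an ``exceeds_uncertainty`` flag raised when MAD
    is larger than the series' maximum baseline SD.  With
    ``include_reference=False`` the first session (the reference) is left
    out of the MAD.
    """
    sessions = list(sessions)
    if not sessions:
        raise ValueError("no sessions to summarize")
    sources = sorted(sessions[0].volumes_cm3)
    if any(sorted(s.volumes_cm3) != sources for s in sessions):
        raise ValueError("sessions report inconsistent workflow sources")

    rows = []
    for s in sessions:
        row = {
            "session": s.session_id,
            "thickness_cm": s.thickness_cm,
            "baseline_mean_cm3": s.baseline_mean_cm3,
            "baseline_sd_cm3": s.baseline_sd_cm3,
        }
        for src in sources:
            row[f"{src}_cm3"] = s.volumes_cm3[src]
            row[f"{src}_dev_cm3"] = s.deviation_cm3(src)
        rows.append(row)
    table = pd.DataFrame(rows)

    if max_baseline_sd_cm3 is None:
        max_baseline_sd_cm3 = float(table["baseline_sd_cm3"].max())

    mad_sessions = sessions if include_reference else sessions[1:]
    summary = {"max_baseline_sd_cm3": float(max_baseline_sd_cm3), "sources": {}}
    thicknesses = np.array([s.thickness_cm for s in sessions])
    for src in sources:
        devs = [s.deviation_cm3(src) for s in mad_sessions]
        vols = np.array([s.volumes_cm3[src] for s in sessions])
        entry = {"mad_cm3": mad(devs)}
        try:
            r2, _ = r_squared(thicknesses, vols)
            entry["r2_percent"] = r2
        except ValueError:
            entry["r2_percent"] = float("nan")
        entry["exceeds_uncertainty"] = bool(entry["mad_cm3"] > max_baseline_sd_cm3)
        summary["sources"][src] = entry
    return table, summary
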