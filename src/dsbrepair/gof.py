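"""Goodness-of-fit metrics between simulated and experimental curves.

Three complementary curve-comparison metrics quantify how well a simulated
repair or recruitment curve matches an experimental benchmark:

* reduced chi-square -- SEM-weighted squared deviation per point,
  ``sum((sim - exp)^2 / sem^2) / n``; sensitive to deviations relative to
  the experimental uncertainty,
* RMSE -- root mean squared difference, unweighted absolute deviation,
* DTW -- classic unconstrained dynamic time warping with absolute-difference
  local cost and unit step pattern {(1,0), (0,1), (1,1)}, tolerant of
  time-axis distortion between the two curves.

``evaluate_scenario`` pairs each experimental time point with the nearest
simulated grid point (the grid is 30 s, experimental points are hour-scale,
so the matching choice is immaterial but fixed for determinism), optionally
re-normalises both curves to their earliest common point, and reports all
three metrics.  Reduced chi-square divides by the number of points with no
parameter correction, since parameters are frozen before evaluation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .observables import TimeSeriesEnsemble

__all__ = [
    "PairedCurves",
    "GofReport",
    "reduced_chi_square",
    "rmse",
    "dtw",
    "evaluate_scenario",
    "aggregate_reports",
    "reports_table",
]


@dataclass
class PairedCurves:
    """Simulated and experimental values matched on a common time grid."""

    times: np.ndarray
    sim: np.ndarray
    exp: np.ndarray
    exp_sem: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sim = np.asarray(self.sim, dtype=float)
        self.exp = np.asarray(self.exp, dtype=float)
        self.exp_sem = np.asarray(self.exp_sem, dtype=float)
        n = len(self.times)
        if n < 1 or not (len(self.sim) == len(self.exp) == len(self.exp_sem) == n):
            raise ValueError("paired curves need equal lengths >= 1")


@dataclass
class GofReport:
    """The three goodness-of-fit metrics for one sim/experiment curve pair."""

    chi2_red: float
    rmse: float
    dtw: float
    n_points: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def reduced_chi_square(pair: PairedCurves) -> float:
    """SEM-weighted reduced chi-square, ``sum(((sim-exp)/sem)^2) / n``.

    Raises if any SEM is zero; configure an SEM floor on the experimental
    curve before evaluating (noise-free synthetic targets have sem = 0).
    """
    if np.any(pair.exp_sem <= 0):
        raise ValueError(
            "chi-square needs strictly positive experimental SEMs; "
            "apply an SEM floor to the target curve first"
        )
    z = (pair.sim - pair.exp) / pair.exp_sem
    return float(np.sum(z * z) / len(z))


def rmse(pair: PairedCurves) -> float:
    """Root mean squared difference between the matched curves."""
    d = pair.sim - pair.exp
    return float(np.sqrt(np.mean(d * d)))


def dtw(sim: Sequence[float], exp: Sequence[float]) -> float:
    """Classic dynamic-time-warping distance.

    Dynamic programming with local cost ``|x_i - y_j|``, step pattern
    {(1,0), (0,1), (1,1)}, no window and no normalisation; returns the
    minimal cumulative cost of a monotone alignment of the two sequences.
    """
    x = np.asarray(sim, dtype=float)
    y = np.asarray(exp, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) == 0 or len(y) == 0:
        raise ValueError("dtw needs two non-empty 1-D sequences")
    n, m = len(x), len(y)
    cost = np.abs(x[:, None] - y[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        row = acc[i]
        prev = acc[i - 1]
        ci = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = ci[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(acc[n, m])


def _match_times(
    sim_times: np.ndarray, exp_times: np.ndarray
) -> np.ndarray:
    """Index of the nearest simulated grid point for each experimental time."""
    sim_times = np.asarray(sim_times, dtype=float)
    exp_times = np.asarray(exp_times, dtype=float)
    if exp_times.max() > sim_times.max() + 1e-9:
        raise ValueError(
            f"experimental point at t={exp_times.max():g}s beyond the "
            f"simulated horizon ({sim_times.max():g}s)"
        )
    return np.abs(sim_times[None, :] - exp_times[:, None]).argmin(axis=1)


def evaluate_scenario(
    sim_curve: TimeSeriesEnsemble,
    exp_curve: pd.DataFrame,
    normalization: str = "first_point",
    sem_floor: float | None = None,
) -> GofReport:
    """Score a simulated curve against an experimental benchmark curve.

    ``exp_curve`` is a DataFrame with columns ``time_s``, ``mean`` (or
    ``value``) and ``sem``; experimental points are sorted by time and each
    is matched to the nearest simulated grid point.  With
    ``normalization="first_point"`` both curves are self-normalised to their
    value at the earliest matched time point (experimental SEMs are scaled by
    the same factor); ``"none"`` compares raw values.  ``sem_floor`` replaces
    smaller/zero SEMs before the chi-square.
    """
    if normalization not in ("first_point", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    exp = exp_curve.rename(columns={"value": "mean"}).sort_values("time_s")
    idx = _match_times(sim_curve.times, exp["time_s"].to_numpy())
    sim_vals = sim_curve.mean[idx].astype(float).copy()
    exp_vals = exp["mean"].to_numpy(dtype=float).copy()
    exp_sem = exp["sem"].to_numpy(dtype=float).copy()
    if normalization == "first_point":
        if sim_vals[0] != 0:
            sim_vals = sim_vals / sim_vals[0]
        if exp_vals[0] != 0:
            exp_sem = exp_sem / abs(exp_vals[0])
            exp_vals = exp_vals / exp_vals[0]
    if sem_floor is not None:
        exp_sem = np.maximum(exp_sem, sem_floor)
    pair = PairedCurves(
        times=sim_curve.times[idx], sim=sim_vals, exp=exp_vals, exp_sem=exp_sem
    )
    return GofReport(
        chi2_red=reduced_chi_square(pair),
        rmse=rmse(pair),
        dtw=dtw(sim_vals, exp_vals),
        n_points=len(sim_vals),
    )


def aggregate_reports(reports: Sequence[GofReport]) -> GofReport:
    """Arithmetic mean of the metrics over cell systems (scenario average)."""
    if not reports:
        raise ValueError("no reports to aggregate")
    return GofReport(
        chi2_red=float(np.mean([r.chi2_red for r in reports])),
        rmse=float(np.mean([r.rmse for r in reports])),
        dtw=float(np.mean([r.dtw for r in reports])),
        n_points=int(sum(r.n_points for r in reports)),
    )


def reports_table(reports: dict[str, GofReport]) -> pd.DataFrame:
    """Summary table: one row per labelled system, metrics as columns.

    Labels of the form ``"<scenario> - <system>"`` are additionally averaged
    per scenario into ``"<scenario> Average"`` rows, mirroring the usual
    scenario-comparison summary layout.  Column order is deterministic.
    """
    rows = []
    by_scenario: dict[str, list[GofReport]] = {}
    for label in sorted(reports):
        r = reports[label]
        rows.append(
            {
                "system": label,
                "chi2_red": r.chi2_red,
                "rmse": r.rmse,
                "dtw": r.dtw,
                "n_points": r.n_points,
            }
        )
        scenario = label.split(" - ")[0] if " - " in label else None
        if scenario:
            by_scenario.setdefault(scenario, []).append(r)
    for scenario in sorted(by_scenario):
        mean = aggregate_reports(by_scenario[scenario])
        rows.append(
            {
                "system": f"{scenario} Average",
                "chi2_red": mean.chi2_red,
                "rmse": mean.rmse,
                "dtw": mean.dtw,
                "n_points": mean.n_points,
            }
        )
    return pd.DataFrame(rows, columns=["system", "chi2_red", "rmse", "dtw", "n_points"])
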