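"""Measured quantities: recruitment curves, repair kinetics, repair shares.

Converts engine ensembles into the observables that experiments report:

* protein-recruitment curves -- the number of DSB ends currently bearing a
  protein (Ku, DNA-PKcs, Mre11/MRN, CtIP-resected, RNF138) versus time,
  self-normalised to the curve's own maximum, mimicking immunofluorescence
  recruitment data.  Persistence is encoded in the state machine itself
  (Ku/DNA-PKcs persist until synaptic stabilisation or RNF138 stripping;
  MRN persists once loaded; occupancy clears on repair).
* residual-damage kinetics -- the number of DSBs not yet repaired versus
  time, the simulation counterpart of gamma-H2AX focus counts.  A DSB counts
  repaired once both of its ends reach an absorbing repaired state (final
  ligation of a synaptic complex repairs both member ends at once).
* repair shares -- the NHEJ / HR / unrepaired split of all DSBs at the end
  of the run.

Curves carry the across-repeat mean and standard error on the fixed
recording grid and can be exported as ``time_s, mean, sem`` CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import EnsembleResult
from .states import Phase, Protein

__all__ = [
    "TimeSeriesEnsemble",
    "RECRUITMENT_PROTEINS",
    "recruitment_curve",
    "residual_damage_curve",
    "repair_share",
    "ensemble_counts_frame",
    "write_curve",
    "read_curve",
    "plot_curves",
]

#: Observable protein names mapped to occupancy-count series.  "Mre11" is an
#: accepted alias for the MRN complex (the imaging proxy).
RECRUITMENT_PROTEINS = {
    "Ku": Protein.KU.value,
    "DNA-PKcs": Protein.PKCS.value,
    "MRN": Protein.MRN.value,
    "Mre11": Protein.MRN.value,
    "RNF138": Protein.RNF138.value,
    "CtIP": Protein.RESECTED.value,
}


@dataclass
class TimeSeriesEnsemble:
    """A mean curve with its across-repeat standard error."""

    times: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_repeats: int
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sem = np.asarray(self.sem, dtype=float)
        if not (len(self.times) == len(self.mean) == len(self.sem)):
            raise ValueError("times, mean and sem must have equal length")
        if np.any(self.sem < 0):
            raise ValueError("sem must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "mean": self.mean, "sem": self.sem}
        )


def _mean_sem(stacked: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = stacked.mean(axis=0)
    n = stacked.shape[0]
    if n > 1:
        sem = stacked.std(axis=0, ddof=1) / np.sqrt(n)
    else:
        sem = np.zeros_like(mean)
    return mean, sem


def recruitment_curve(
    ensemble: EnsembleResult, protein: str, normalize: bool = True
) -> TimeSeriesEnsemble:
    """Protein-occupancy curve across the ensemble.

    Counts, at every grid time, the DSB ends currently bearing ``protein``
    under the model's persistence rules, averaged over repeats.  With
    ``normalize=True`` (default) the mean curve is self-normalised to its own
    maximum (so it peaks at exactly 1) and the SEM is scaled by the same
    factor; a protein that never loads yields the identically-zero curve.
    """
    if protein not in RECRUITMENT_PROTEINS:
        raise ValueError(
            f"unknown protein {protein!r}; choose from {sorted(RECRUITMENT_PROTEINS)}"
        )
    stacked = ensemble.stack(RECRUITMENT_PROTEINS[protein])
    mean, sem = _mean_sem(stacked)
    if normalize:
        peak = mean.max()
        if peak > 0:
            mean = mean / peak
            sem = sem / peak
    return TimeSeriesEnsemble(
        ensemble.times, mean, sem, ensemble.n_repeats, label=protein
    )


def residual_damage_curve(
    ensemble: EnsembleResult, normalization: str = "per_dsb"
) -> TimeSeriesEnsemble:
    """Unrepaired-DSB curve, the gamma-H2AX focus-count proxy.

    ``normalization="per_dsb"`` divides each repeat by its initial DSB count
    (value 1.0 at t = 0); ``"self_max"`` divides by the repeat's own maximum;
    ``"none"`` keeps raw counts.
    """
    if normalization not in ("per_dsb", "self_max", "none"):
        raise ValueError(f"unknown normalization {normalization!r}")
    rows = []
    for tr in ensemble.trajectories:
        counts = tr.dsb_unrepaired.astype(float)
        if normalization == "per_dsb":
            rows.append(counts / tr.n_dsb if tr.n_dsb else counts)
        elif normalization == "self_max":
            peak = counts.max()
            rows.append(counts / peak if peak > 0 else counts)
        else:
            rows.append(counts)
    mean, sem = _mean_sem(np.stack(rows))
    return TimeSeriesEnsemble(
        ensemble.times, mean, sem, ensemble.n_repeats, label="residual_damage"
    )


def repair_share(ensemble: EnsembleResult) -> dict[str, float]:
    """NHEJ / HR / unrepaired fractions of all DSBs at the end of the run.

    Fractions are pooled over repeats and sum to 1.
    """
    nhej = hr = unrepaired = total = 0
    for tr in ensemble.trajectories:
        nhej += int(tr.dsb_nhej[-1])
        hr += int(tr.dsb_hr[-1])
        unrepaired += int(tr.dsb_unrepaired[-1])
        total += tr.n_dsb
    if total == 0:
        return {"NHEJ": 0.0, "HR": 0.0, "unrepaired": 0.0}
    return {
        "NHEJ": nhej / total,
        "HR": hr / total,
        "unrepaired": unrepaired / total,
    }


def ensemble_counts_frame(ensemble: EnsembleResult) -> pd.DataFrame:
    """Tidy long-format export: time_s, series, mean, sem for every series."""
    frames = []
    series_names = [p.value for p in Phase] + [p.value for p in Protein] + [
        "dsb_unrepaired",
        "dsb_nhej",
        "dsb_hr",
    ]
    for name in series_names:
        mean, sem = _mean_sem(ensemble.stack(name))
        frames.append(
            pd.DataFrame(
                {
                    "time_s": ensemble.times,
                    "series": name,
                    "mean": mean,
                    "sem": sem,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_curve(curve: TimeSeriesEnsemble, path: str | Path) -> None:
    curve.to_frame().to_csv(path, index=False)


def read_curve(path: str | Path) -> pd.DataFrame:
    """Read a curve CSV with columns time_s and mean/value (+ optional sem)."""
    df = pd.read_csv(path)
    if "value" in df.columns and "mean" not in df.columns:
        df = df.rename(columns={"value": "mean"})
    if "time_s" not in df.columns or "mean" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s and mean/value")
    if "sem" not in df.columns:
        df["sem"] = 0.0
    return df[["time_s", "mean", "sem"]]


def plot_curves(
    curves: dict[str, TimeSeriesEnsemble],
    experimental: pd.DataFrame | None = None,
    ax=None,
    ylabel: str = "normalised signal",
):
    """Plot mean +/- SEM bands for a set of curves (panel-style helper)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, c in curves.items():
        hours = c.times / 3600.0
        ax.plot(hours, c.mean, label=label)
        ax.fill_between(hours, c.mean - c.sem, c.mean + c.sem, alpha=0.3)
    if experimental is not None:
        ax.errorbar(
            experimental["time_s"] / 3600.0,
            experimental.get("mean", experimental.get("value")),
            yerr=experimental["sem"],
            fmt="ko",
            capsize=3,
            label="experiment",
        )
    ax.set_xlabel("time post-irradiation (h)")
    ax.set_ylabel(ylabel)
    ax.legend()
    return ax
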