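"""DSB damage input and synthetic data generation.

A repair-choice simulation starts from a pattern of DNA double-strand breaks
(DSBs) inside a cell nucleus.  This module provides the three ways of getting
one:

* reading a damage pattern from a minimal dialect of the Standard DNA Damage
  (SDD) exchange format (:func:`read_sdd` / :func:`write_sdd`),
* generating a synthetic pattern for a given dose and DSB yield
  (:func:`generate_damage`), with DSB count drawn from a Poisson law and
  positions uniform inside the nucleus, and
* generating experimental-style benchmark curves (noisy exponential protein
  recruitment, bi-phasic repair decay) for self-contained calibration and
  goodness-of-fit testing (:func:`generate_benchmark_curve`).

SDD dialect
-----------
Only the fields the repair simulation needs are supported: a header block of
``Key, value;`` lines (dialect version, dose, position unit, nucleus geometry,
entry count, free-form ``# meta key=value`` comments) terminated by
``***EndOfHeader***;``, followed by one record per DSB::

    dsb_id; x, y, z[; key=value,key=value]

Positions are Cartesian micrometres with the nucleus centred at the origin
(``Position unit, nm`` is accepted and converted).  Fields of the full SDD
specification that carry no information for repair-choice kinetics (strand
break structure, chromosome coordinates, lesion complexity, ...) are not
represented; anything unrepresentable is preserved in ``# meta`` comment lines
rather than silently dropped.  Breaks are re-read in file order and the two
ends of DSB ``i`` are enumerated 0-based as ``(2*i, 2*i + 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NucleusGeometry",
    "DamageRecord",
    "DamageSet",
    "read_sdd",
    "write_sdd",
    "generate_damage",
    "generate_benchmark_curve",
    "exp_recruitment",
    "biphasic_decay",
    "BENCHMARK_MODELS",
    "SddParseError",
    "DamageValidationError",
]

SDD_DIALECT_VERSION = "minimal-1.0"


class SddParseError(ValueError):
    """Malformed SDD header or data row (message names the offending line)."""


class DamageValidationError(ValueError):
    """A damage pattern violates its own declared constraints."""


@dataclass(frozen=True)
class NucleusGeometry:
    """Cell-nucleus volume within which breaks live and ends diffuse.

    Parameters
    ----------
    shape:
        ``"sphere"`` or ``"ellipsoid"``.
    radii:
        Semi-axis lengths in micrometres, ``(rx, ry, rz)``.  A sphere must
        have three equal radii.
    """

    shape: str = "sphere"
    radii: tuple[float, float, float] = (5.0, 5.0, 5.0)

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown nucleus shape {self.shape!r}")
        if len(self.radii) != 3 or any(r <= 0 for r in self.radii):
            raise ValueError("nucleus radii must be three positive lengths")
        if self.shape == "sphere" and len(set(self.radii)) != 1:
            raise ValueError("a sphere must have three equal radii")
        object.__setattr__(self, "radii", tuple(float(r) for r in self.radii))

    def contains(self, points: np.ndarray, atol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside (or on) the nucleus surface."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        u = pts / np.asarray(self.radii)
        inside = (u * u).sum(axis=-1) <= 1.0 + atol
        return inside if np.ndim(points) > 1 else bool(inside[0])

    def sample_uniform(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` i.i.d. uniform positions inside the volume (um).

        Uses the exact direction/radius construction (uniform in the unit
        ball, then scaled by the semi-axes), which is uniform in an ellipsoid.
        """
        if n == 0:
            return np.empty((0, 3))
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        radius = rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)
        return direction * radius[:, None] * np.asarray(self.radii)

    def reflect_inside(self, points: np.ndarray) -> np.ndarray:
        """Mirror points that stepped outside back across the surface.

        Reflection is radial in semi-axis-scaled coordinates (where the
        surface is the unit sphere); a step that is still outside after two
        mirrors (pathologically large) is clamped onto the surface.
        """
        pts = np.array(points, dtype=float, copy=True)
        radii = np.asarray(self.radii)
        u = pts / radii
        for _ in range(2):
            r = np.linalg.norm(u, axis=-1)
            outside = r > 1.0
            if not np.any(outside):
                break
            scale = (2.0 - r[outside]) / r[outside]
            u[outside] *= scale[:, None]
        r = np.linalg.norm(u, axis=-1)
        outside = r > 1.0
        if np.any(outside):
            u[outside] /= r[outside][:, None] * (1.0 + 1e-12)
        return u * radii


@dataclass
class DamageRecord:
    """A single DSB: a 3-D position and its two trackable ends."""

    dsb_id: int
    position: np.ndarray  # (3,) micrometres
    end_ids: tuple[int, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if len(self.end_ids) != 2 or self.end_ids[0] == self.end_ids[1]:
            raise ValueError("a DSB has exactly two distinct ends")
        self.end_ids = (int(self.end_ids[0]), int(self.end_ids[1]))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DamageRecord):
            return NotImplemented
        return (
            self.dsb_id == other.dsb_id
            and np.array_equal(self.position, other.position)
            and self.end_ids == other.end_ids
            and self.metadata == other.metadata
        )


@dataclass
class DamageSet:
    """An ordered collection of DSBs delivered to one nucleus.

    Equality compares records, dose, geometry and metadata but *not*
    provenance, so that a written-then-reread synthetic set compares equal to
    the original.
    """

    records: list[DamageRecord]
    dose: float = 0.0
    provenance: str = "synthetic"  # "synthetic" | "sdd_file"
    geometry: NucleusGeometry | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        dsb_ids = [r.dsb_id for r in self.records]
        if len(set(dsb_ids)) != len(dsb_ids):
            raise DamageValidationError("dsb_ids must be unique")
        end_ids = [e for r in self.records for e in r.end_ids]
        if len(set(end_ids)) != len(end_ids):
            raise DamageValidationError("end_ids must be globally unique")
        if self.geometry is not None and self.n_dsb:
            inside = self.geometry.contains(self.positions)
            if not np.all(inside):
                bad = int(np.argmin(inside))
                raise DamageValidationError(
                    f"DSB {self.records[bad].dsb_id} lies outside the nucleus"
                )

    @property
    def n_dsb(self) -> int:
        return len(self.records)

    @property
    def positions(self) -> np.ndarray:
        if not self.records:
            return np.empty((0, 3))
        return np.stack([r.position for r in self.records])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DamageSet):
            return NotImplemented
        return (
            self.records == other.records
            and self.dose == other.dose
            and self.geometry == other.geometry
            and self.metadata == other.metadata
        )


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _parse_value(s: str):
    try:
        f = float(s)
    except ValueError:
        return s
    return int(f) if f.is_integer() and "." not in s and "e" not in s.lower() else f


def write_sdd(damage: DamageSet, path: str | Path) -> None:
    """Write a :class:`DamageSet` in the minimal SDD dialect.

    The file is re-readable by :func:`read_sdd` into an equal set; set-level
    metadata and per-record metadata that have no dedicated dialect field are
    recorded in comment/extra columns instead of being dropped.
    """
    path = Path(path)
    lines = [
        "# dsbrepair minimal SDD dialect",
        f"SDD version, {SDD_DIALECT_VERSION};",
        f"Dose or fluence, {_format_value(float(damage.dose))};",
        "Position unit, um;",
    ]
    if damage.geometry is not None:
        rx, ry, rz = damage.geometry.radii
        lines.append(f"Nucleus shape, {damage.geometry.shape};")
        lines.append(
            f"Nucleus radii, {_format_value(rx)}, {_format_value(ry)}, {_format_value(rz)};"
        )
    lines.append(f"Data entries, {damage.n_dsb};")
    for k, v in damage.metadata.items():
        lines.append(f"# meta {k}={_format_value(v)}")
    lines.append("***EndOfHeader***;")
    for rec in damage.records:
        x, y, z = (repr(float(c)) for c in rec.position)
        row = f"{rec.dsb_id}; {x}, {y}, {z}"
        if rec.metadata:
            row += "; " + ",".join(
                f"{k}={_format_value(v)}" for k, v in rec.metadata.items()
            )
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_sdd(path: str | Path) -> DamageSet:
    """Read a minimal-dialect SDD file into a :class:`DamageSet`.

    Raises :class:`SddParseError` naming the offending line for malformed
    input, and :class:`DamageValidationError` if a position lies outside the
    declared nucleus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = path.read_text().splitlines()

    header: dict[str, str] = {}
    metadata: dict = {}
    body_start = None
    for i, raw in enumerate(lines):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("# meta "):
            key, _, val = line[len("# meta "):].partition("=")
            metadata[key.strip()] = _parse_value(val.strip())
            continue
        if line.startswith("#"):
            continue
        if line.startswith("***EndOfHeader***"):
            body_start = i + 1
            break
        if "," not in line:
            raise SddParseError(f"line {i + 1}: malformed header line {raw!r}")
        key, _, val = line.partition(",")
        header[key.strip().lower()] = val.rstrip(";").strip()
    if body_start is None:
        raise SddParseError("missing ***EndOfHeader*** terminator")
    if "sdd version" not in header:
        raise SddParseError("header does not declare an SDD version")

    unit = header.get("position unit", "um").lower()
    if unit not in ("um", "nm"):
        raise SddParseError(f"unsupported position unit {unit!r}")
    to_um = 1.0 if unit == "um" else 1e-3

    geometry = None
    if "nucleus shape" in header:
        radii_raw = header.get("nucleus radii")
        if radii_raw is None:
            raise SddParseError("nucleus shape declared without nucleus radii")
        radii = tuple(float(v) * to_um for v in radii_raw.split(","))
        geometry = NucleusGeometry(shape=header["nucleus shape"], radii=radii)

    dose = float(header.get("dose or fluence", 0.0))

    records: list[DamageRecord] = []
    n = 0
    for i in range(body_start, len(lines)):
        line = lines[i].strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split(";")]
        if len(parts) < 2:
            raise SddParseError(f"line {i + 1}: expected 'id; x, y, z' record")
        try:
            dsb_id = int(parts[0])
            coords = [float(c) * to_um for c in parts[1].split(",")]
        except ValueError as exc:
            raise SddParseError(f"line {i + 1}: {exc}") from None
        if len(coords) != 3:
            raise SddParseError(f"line {i + 1}: position needs three coordinates")
        rec_meta: dict = {}
        if len(parts) >= 3 and parts[2]:
            for item in parts[2].split(","):
                k, _, v = item.partition("=")
                if not _:
                    raise SddParseError(f"line {i + 1}: malformed metadata {item!r}")
                rec_meta[k.strip()] = _parse_value(v.strip())
        records.append(
            DamageRecord(
                dsb_id=dsb_id,
                position=np.array(coords),
                end_ids=(2 * n, 2 * n + 1),
                metadata=rec_meta,
            )
        )
        n += 1

    declared = header.get("data entries")
    if declared is not None and int(declared) != n:
        raise SddParseError(
            f"header declares {declared} entries but file contains {n}"
        )
    return DamageSet(
        records=records,
        dose=dose,
        provenance="sdd_file",
        geometry=geometry,
        metadata=metadata,
    )


def generate_damage(
    dose: float,
    yield_per_gy: float,
    geometry: NucleusGeometry,
    rng_seed: int | np.random.Generator = 0,
) -> DamageSet:
    """Generate a synthetic DSB pattern for an acute dose.

    The number of DSBs is Poisson(dose x yield) and positions are i.i.d.
    uniform inside the nucleus; this emulates the low-LET limit in which
    breaks are spatially homogeneous at the nuclear scale.  Track-correlated
    clustering of breaks along particle paths is deliberately not modelled
    (an extension point; see docs/methods.md).

    Parameters
    ----------
    dose:
        Absorbed dose in Gy (>= 0).
    yield_per_gy:
        Expected DSBs per Gy per nucleus (> 0); a literature-typical value
        for mammalian nuclei is a few tens per Gy.
    geometry:
        Nucleus volume for position sampling.
    rng_seed:
        Seed (or Generator) making the pattern reproducible.
    """
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if yield_per_gy <= 0:
        raise ValueError("yield_per_gy must be > 0")
    rng = np.random.default_rng(rng_seed)
    n = int(rng.poisson(dose * yield_per_gy))
    positions = geometry.sample_uniform(n, rng)
    records = [
        DamageRecord(dsb_id=i, position=positions[i], end_ids=(2 * i, 2 * i + 1))
        for i in range(n)
    ]
    return DamageSet(
        records=records,
        dose=float(dose),
        provenance="synthetic",
        geometry=geometry,
        metadata={"yield_per_gy": float(yield_per_gy)},
    )


# --------------------------------------------------------------------------
# Experimental-style benchmark curves


def exp_recruitment(t: np.ndarray, tau: float, plateau: float = 1.0) -> np.ndarray:
    """Saturating single-exponential recruitment, ``plateau * (1 - exp(-t/tau))``."""
    t = np.asarray(t, dtype=float)
    return plateau * (1.0 - np.exp(-t / tau))


def biphasic_decay(
    t: np.ndarray,
    fast_fraction: float,
    tau_fast: float,
    tau_slow: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Two-component exponential decay for residual-damage kinetics.

    ``f * exp(-t/tau_fast) + (1 - f) * exp(-t/tau_slow) + baseline`` -- the
    standard fast (end-joining) / slow (resection-mediated) description of
    gamma-H2AX foci loss.  ``fast_fraction = 1`` reduces to a single
    exponential.
    """
    t = np.asarray(t, dtype=float)
    f = fast_fraction
    return f * np.exp(-t / tau_fast) + (1.0 - f) * np.exp(-t / tau_slow) + baseline


BENCHMARK_MODELS: dict[str, Callable] = {
    "exp_recruitment": exp_recruitment,
    "biphasic_decay": biphasic_decay,
}


def generate_benchmark_curve(
    model: str,
    params: dict,
    times: Sequence[float],
    noise_sd: float = 0.0,
    rng_seed: int | np.random.Generator = 0,
    n_rep: int = 1,
) -> pd.DataFrame:
    """Generate an experimental-style (time, value, SEM) curve.

    Stands in for digitized literature curves: the model mean is evaluated on
    ``times`` and perturbed with Gaussian noise of standard deviation
    ``noise_sd / sqrt(n_rep)`` (the SEM of an ``n_rep``-replicate mean); the
    ``sem`` column declares that same value.  ``noise_sd = 0`` returns the
    noise-free model curve with zero SEM.

    Returns a DataFrame with columns ``time_s``, ``value``, ``sem``.
    """
    if model not in BENCHMARK_MODELS:
        raise ValueError(
            f"unknown benchmark model {model!r}; choose from {sorted(BENCHMARK_MODELS)}"
        )
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) == 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be a non-empty strictly increasing sequence")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(rng_seed)
    sem = noise_sd / math.sqrt(n_rep)
    values = BENCHMARK_MODELS[model](t, **params)
    if sem > 0:
        values = values + rng.normal(0.0, sem, size=len(t))
    return pd.DataFrame(
        {"time_s": t, "value": values, "sem": np.full(len(t), sem)}
    )
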