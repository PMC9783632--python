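"""Reduction of raw uniaxial test-rig records to engineering stress–strain curves.

Raw records hold (time s, displacement mm, force N) as sampled by the rig
(125 Hz in the reference protocol); reduced records hold (engineering strain,
engineering stress MPa).  The reduction is

    σ = F / A        (stress, MPa, with F in N and A in mm²)
    ε = ΔL / L0      (strain, dimensionless)

where A is the initial cross-sectional area and L0 the gauge length.  Units
are fixed package-wide: N, mm, s → MPa.

Compression records are stored magnitude-positive (strain and stress both
increase during compression), matching how rigs log them; downstream model
fitting converts to the tension-positive convention via ε → −ε, σ → −σ.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMode",
    "SpecimenGeometry",
    "UniaxialRecord",
    "reduce_record",
    "average_curves",
    "read_csv",
    "write_csv",
]

RAW_COLUMNS = ("time_s", "displacement_mm", "force_N")
REDUCED_COLUMNS = ("strain", "stress_MPa")
RELAXATION_COLUMNS = ("time_s", "stress_MPa")


class LoadingMode(str, Enum):
    COMPRESSION = "compression"
    TENSION = "tension"
    RELAXATION = "relaxation"


@dataclass(frozen=True)
class SpecimenGeometry:
    """Specimen dimensions (mm): cylinder (diameter) or strip (width × thickness).

    ``gauge_length_mm`` is the initial length L0 along the loading axis.
    """

    gauge_length_mm: float
    diameter_mm: float | None = None
    width_mm: float | None = None
    thickness_mm: float | None = None

    def __post_init__(self) -> None:
        dims = [self.gauge_length_mm]
        if self.diameter_mm is not None:
            dims.append(self.diameter_mm)
        elif self.width_mm is not None and self.thickness_mm is not None:
            dims.extend((self.width_mm, self.thickness_mm))
        else:
            raise ValueError("geometry needs a diameter or width+thickness")
        if min(dims) <= 0.0:
            raise ValueError("all specimen dimensions must be positive")

    @property
    def area_mm2(self) -> float:
        """Initial cross-sectional area A (mm²)."""
        if self.diameter_mm is not None:
            return math.pi * self.diameter_mm**2 / 4.0
        return self.width_mm * self.thickness_mm  # type: ignore[operator]

    @classmethod
    def cylinder(cls, diameter_mm: float, height_mm: float) -> "SpecimenGeometry":
        return cls(gauge_length_mm=height_mm, diameter_mm=diameter_mm)

    @classmethod
    def strip(
        cls, length_mm: float, width_mm: float, thickness_mm: float
    ) -> "SpecimenGeometry":
        return cls(gauge_length_mm=length_mm, width_mm=width_mm, thickness_mm=thickness_mm)


@dataclass
class UniaxialRecord:
    """One uniaxial test: raw rig series and/or a reduced stress–strain curve.

    A raw record carries (time_s, displacement_mm, force_N); a reduced one
    carries (strain, stress_MPa).  Relaxation records use (time_s, stress_MPa)
    plus ``hold_strain``.
    """

    specimen_id: str = "unnamed"
    mode: LoadingMode = LoadingMode.COMPRESSION
    strain_rate_per_s: float | None = None
    geometry: SpecimenGeometry | None = None
    time_s: np.ndarray | None = None
    displacement_mm: np.ndarray | None = None
    force_N: np.ndarray | None = None
    strain: np.ndarray | None = None
    stress_MPa: np.ndarray | None = None
    hold_strain: float | None = None  # relaxation: held engineering strain ε0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time_s", "displacement_mm", "force_N", "strain", "stress_MPa"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        lengths = {
            len(getattr(self, n))
            for n in ("time_s", "displacement_mm", "force_N", "strain", "stress_MPa")
            if getattr(self, n) is not None
        }
        if len(lengths) > 1:
            raise ValueError(f"series lengths differ: {sorted(lengths)}")
        if self.time_s is not None and len(self.time_s) > 1:
            if np.any(np.diff(self.time_s) <= 0.0):
                raise ValueError("time series must be strictly increasing")

    @property
    def is_reduced(self) -> bool:
        return self.strain is not None and self.stress_MPa is not None

    @property
    def is_raw(self) -> bool:
        return self.force_N is not None and self.displacement_mm is not None

    @property
    def n_samples(self) -> int:
        for n in ("strain", "stress_MPa", "time_s", "force_N"):
            v = getattr(self, n)
            if v is not None:
                return len(v)
        return 0


def reduce_record(raw: UniaxialRecord) -> UniaxialRecord:
    """Convert a raw (force, displacement) record to engineering stress–strain.

    σ = F/A and ε = ΔL/L0 from the specimen geometry.  Metadata is preserved;
    the raw series are dropped from the returned record.
    """
    if not raw.is_raw:
        raise ValueError("record has no raw force/displacement series")
    if raw.geometry is None:
        raise ValueError("raw record needs specimen geometry for reduction")
    area = raw.geometry.area_mm2
    l0 = raw.geometry.gauge_length_mm
    if area <= 0.0 or l0 <= 0.0:
        raise ValueError("geometry must have positive area and gauge length")
    return replace(
        raw,
        strain=raw.displacement_mm / l0,
        stress_MPa=raw.force_N / area,
        displacement_mm=None,
        force_N=None,
    )


def average_curves(
    records: list[UniaxialRecord], strain_grid: np.ndarray | None = None, n_grid: int = 200
) -> UniaxialRecord:
    """Pointwise mean stress–strain curve over replicate tests.

    Each record is linearly interpolated onto a common strain grid restricted
    to the intersection of all records' strain ranges, then averaged
    arithmetically — the replicate-averaging step used before model fitting.
    """
    if len(records) < 2:
        raise ValueError("averaging needs at least two records")
    if not all(r.is_reduced for r in records):
        raise ValueError("all records must be reduced (strain/stress form)")
    lo = max(float(np.min(r.strain)) for r in records)
    hi = min(float(np.max(r.strain)) for r in records)
    if hi <= lo:
        raise ValueError("records have no overlapping strain range")
    if strain_grid is None:
        strain_grid = np.linspace(lo, hi, n_grid)
    else:
        strain_grid = np.asarray(strain_grid, dtype=float)
        if strain_grid.min() < lo or strain_grid.max() > hi:
            raise ValueError("strain grid extends beyond the common range")
    stacked = np.stack(
        [np.interp(strain_grid, r.strain, r.stress_MPa) for r in records]
    )
    return UniaxialRecord(
        specimen_id=f"mean_of_{len(records)}",
        mode=records[0].mode,
        strain_rate_per_s=records[0].strain_rate_per_s,
        strain=strain_grid,
        stress_MPa=stacked.mean(axis=0),
        meta={"n_averaged": len(records)},
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Raw schema: time_s,displacement_mm,force_N.  Reduced schema:
# strain,stress_MPa.  Relaxation schema: time_s,stress_MPa.  Metadata lives in
# a JSON sidecar <stem>.meta.json next to the CSV.


def _geometry_to_dict(g: SpecimenGeometry | None) -> dict | None:
    return None if g is None else {k: v for k, v in asdict(g).items() if v is not None}


def write_csv(record: UniaxialRecord, path: str | Path) -> Path:
    """Write a record's series as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    if record.mode is LoadingMode.RELAXATION and record.time_s is not None:
        df = pd.DataFrame({"time_s": record.time_s, "stress_MPa": record.stress_MPa})
    elif record.is_raw:
        df = pd.DataFrame(
            {
                "time_s": record.time_s,
                "displacement_mm": record.displacement_mm,
                "force_N": record.force_N,
            }
        )
    elif record.is_reduced:
        df = pd.DataFrame({"strain": record.strain, "stress_MPa": record.stress_MPa})
    else:
        raise ValueError("record has no series to write")
    df.to_csv(path, index=False)
    sidecar = {
        "specimen_id": record.specimen_id,
        "mode": record.mode.value,
        "strain_rate_per_s": record.strain_rate_per_s,
        "geometry": _geometry_to_dict(record.geometry),
        "hold_strain": record.hold_strain,
        "units": {"force": "N", "length": "mm", "time": "s", "stress": "MPa"},
    }
    if "hold_start_index" in record.meta:
        sidecar["hold_start_index"] = int(record.meta["hold_start_index"])
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_csv(path: str | Path) -> UniaxialRecord:
    """Read a record from CSV (+ optional JSON sidecar), inferring the schema."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = tuple(df.columns)
    kwargs: dict = {}
    sidecar = path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        kwargs["specimen_id"] = meta.get("specimen_id", path.stem)
        kwargs["mode"] = LoadingMode(meta.get("mode", "compression"))
        kwargs["strain_rate_per_s"] = meta.get("strain_rate_per_s")
        kwargs["hold_strain"] = meta.get("hold_strain")
        if meta.get("geometry"):
            kwargs["geometry"] = SpecimenGeometry(**meta["geometry"])
        if "hold_start_index" in meta:
            kwargs["meta"] = {"hold_start_index": meta["hold_start_index"]}
    else:
        kwargs["specimen_id"] = path.stem
    if set(RAW_COLUMNS) <= set(cols):
        kwargs.update(
            time_s=df["time_s"].to_numpy(),
            displacement_mm=df["displacement_mm"].to_numpy(),
            force_N=df["force_N"].to_numpy(),
        )
    elif set(RELAXATION_COLUMNS) <= set(cols):
        kwargs.setdefault("mode", LoadingMode.RELAXATION)
        kwargs.update(time_s=df["time_s"].to_numpy(), stress_MPa=df["stress_MPa"].to_numpy())
    elif set(REDUCED_COLUMNS) <= set(cols):
        kwargs.update(strain=df["strain"].to_numpy(), stress_MPa=df["stress_MPa"].to_numpy())
    else:
        raise ValueError(
            f"unrecognised CSV schema {cols}; expected {RAW_COLUMNS}, "
            f"{REDUCED_COLUMNS} or {RELAXATION_COLUMNS}"
        )
    return UniaxialRecord(**kwargs)
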