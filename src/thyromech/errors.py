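"""Prediction-vs-measurement error analysis for tensile validation tests.

Given a predicted stress A and a measured stress L at the same strain, the
absolute error is Δ = A − L (MPa, signed) and the relative error is
η = |Δ|/L × 100 (%).  η is reported as a magnitude — the sign of the
discrepancy lives in Δ only — and is undefined when L = 0 with A ≠ 0 (flagged
rather than raised, so whole tables can still be built).

``predict_tension`` produces the closed-form uniaxial engineering-stress
prediction of a calibrated hyperelastic model on a strain grid; it deliberately
ignores clamped-boundary effects, so users comparing against grip-mounted
strip tests should expect systematic deviations there.  Any externally
computed prediction (e.g. from a finite-element solve) can be supplied as a
reduced record instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mechanics import HyperelasticParams, uniaxial_engineering_stress
from .reduction import LoadingMode, UniaxialRecord

__all__ = ["ErrorRow", "ErrorTable", "error_row", "error_table", "predict_tension"]


@dataclass(frozen=True)
class ErrorRow:
    """One strain level's prediction/measurement comparison."""

    strain: float
    predicted_MPa: float
    measured_MPa: float
    absolute_error_MPa: float  # Δ = predicted − measured, signed
    relative_error_pct: float  # η = |Δ|/measured × 100, NaN when undefined
    eta_undefined: bool = False


@dataclass(frozen=True)
class ErrorTable:
    """Per-strain error rows plus the mean relative error (all rows counted)."""

    rows: tuple[ErrorRow, ...]
    mean_relative_error_pct: float


def error_row(predicted: float, measured: float, strain: float = np.nan) -> ErrorRow:
    """Absolute and relative error between one predicted and measured stress."""
    if measured < 0.0:
        raise ValueError("measured stress must be non-negative")
    delta = predicted - measured
    if measured > 0.0:
        eta, undefined = abs(delta) / measured * 100.0, False
    elif predicted == 0.0:
        eta, undefined = 0.0, False
    else:
        eta, undefined = float("nan"), True
    return ErrorRow(
        strain=float(strain),
        predicted_MPa=float(predicted),
        measured_MPa=float(measured),
        absolute_error_MPa=float(delta),
        relative_error_pct=eta,
        eta_undefined=undefined,
    )


def error_table(predicted: UniaxialRecord, measured: UniaxialRecord) -> ErrorTable:
    """Compare a predicted curve against a measured one on the measured grid.

    The predicted curve is linearly interpolated onto the measured strain
    grid; the mean relative error averages η over *all* rows, including a
    zero-strain row if present (rows with undefined η are excluded from the
    mean but kept in the table).
    """
    for rec, name in ((predicted, "predicted"), (measured, "measured")):
        if not rec.is_reduced:
            raise ValueError(f"{name} record must be reduced")
    p_lo, p_hi = float(np.min(predicted.strain)), float(np.max(predicted.strain))
    m = np.asarray(measured.strain, dtype=float)
    if np.min(m) > p_hi or np.max(m) < p_lo:
        raise ValueError("predicted and measured strain ranges are disjoint")
    pred_on_grid = np.interp(m, predicted.strain, predicted.stress_MPa)
    rows = tuple(
        error_row(a, l, strain=e)
        for e, a, l in zip(m, pred_on_grid, measured.stress_MPa)
    )
    etas = [r.relative_error_pct for r in rows if not r.eta_undefined]
    return ErrorTable(rows=rows, mean_relative_error_pct=float(np.mean(etas)))


def predict_tension(
    params: HyperelasticParams, strain_grid
) -> UniaxialRecord:
    """Closed-form uniaxial tensile prediction T(ε) on a strain grid.

    Tension-positive; strains must be ≥ 0.
    """
    eps = np.asarray(strain_grid, dtype=float)
    if np.any(eps < 0.0):
        raise ValueError("tensile prediction needs strains >= 0")
    te = uniaxial_engineering_stress(params, eps)
    return UniaxialRecord(
        specimen_id="closed_form_prediction",
        mode=LoadingMode.TENSION,
        strain=eps,
        stress_MPa=np.asarray(te, dtype=float),
        meta={"source": "uniaxial closed form"},
    )
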