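"""Three-phase segmentation of quasi-static soft-tissue compression curves.

A quasi-static compression curve of gland parenchyma is concave-up with three
stages: an initial low-stiffness toe region (OA) that is approximately linear,
a nonlinear transition (AB), and a compacted large-deformation stage (BC) that
is again approximately linear and much stiffer.  The slopes of the two linear
stages serve as stage Young's moduli: E1 = k1 (toe) and E2 = k2 (compacted).
The large-deformation stage may include tissue damage, so E2 is a slope of the
recorded curve rather than a purely elastic modulus; results carry a
``may_include_damage`` flag to record that caveat.

The phase boundaries A and B are defined by a growing-window linearity rule:
A is the largest strain such that an ordinary least-squares line fitted to all
samples from zero up to A still counts as linear, and B is the smallest strain
such that the line fitted from B to the end of the curve counts as linear.
Linearity of a window is judged by a *noise-corrected* R²,

    R²* = 1 − max(SSE − c·NoiseSSE, 0) / Syy ≥ r_lin,

where SSE is the residual sum of squares of the window's OLS line, Syy the
total sum of squares, and NoiseSSE = Σ dᵢ²/6 a local noise-floor estimate
built from second differences dᵢ of the stress samples (c = 1.5 guards its
sampling error).  Subtracting the noise floor makes the criterion judge
*systematic* curvature only, so the same threshold works for noiseless and
noisy curves; a plain R² threshold either rejects noisy-but-linear toe
windows or swallows part of the curved transition and biases the slopes.
The default r_lin = 0.9995 tolerates a 0.05% systematic share of the window's
signal variance.  The rule is deterministic and scale-free; both the
threshold and the noise-floor guard assume an (approximately) uniform strain
grid, as produced by constant-rate sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reduction import UniaxialRecord

__all__ = ["PhaseResult", "ReplicateStats", "segment_phases", "replicate_stats"]


@dataclass(frozen=True)
class PhaseResult:
    """Phase boundaries and stage moduli of one compression curve."""

    strain_a: float  # end of the linear toe region (point A)
    strain_b: float  # start of the linear compacted region (point B)
    e1: float  # toe-region Young's modulus k1 (MPa)
    e2: float  # compacted-region Young's modulus k2 (MPa)
    r2_toe: float
    r2_compacted: float
    degenerate: bool = False  # single-phase curve: toe and compacted fits overlap
    may_include_damage: bool = True


@dataclass(frozen=True)
class ReplicateStats:
    """Mean and sample variance (n−1 denominator) over replicate tests."""

    mean: float
    variance: float
    n: int


class SegmentationError(RuntimeError):
    """Raised when no admissible phase boundary exists under the R² rule."""


_NOISE_GUARD = 1.5  # multiplies the second-difference noise-floor estimate


def _running_linear_fits(x: np.ndarray, y: np.ndarray):
    """Slope, plain R² and noise-corrected R² of OLS fits on every prefix and
    suffix window.

    O(n) via cumulative sums.  The noise floor of a window is estimated from
    the second differences of y inside it (E[Σd²] = 6(m−2)σ² for iid noise on
    a locally linear signal), so R²* penalises only residual variance in
    excess of noise.  Entries for windows of fewer than 2 points are NaN.
    """
    n = len(x)
    d2 = np.zeros(n)
    d2[1 : n - 1] = (y[2:] - 2.0 * y[1:-1] + y[:-2]) ** 2  # indexed by centre
    out = {}
    for which in ("prefix", "suffix"):
        if which == "prefix":
            cx, cy = np.cumsum(x), np.cumsum(y)
            cxx, cyy, cxy = np.cumsum(x * x), np.cumsum(y * y), np.cumsum(x * y)
            m = np.arange(1, n + 1, dtype=float)
            # interior second differences of window [0..i] have centres 1..i-1
            noise = np.concatenate([[0.0], np.cumsum(d2)[:-1]]) / 6.0
        else:
            cx, cy = np.cumsum(x[::-1])[::-1], np.cumsum(y[::-1])[::-1]
            cxx = np.cumsum((x * x)[::-1])[::-1]
            cyy = np.cumsum((y * y)[::-1])[::-1]
            cxy = np.cumsum((x * y)[::-1])[::-1]
            m = np.arange(n, 0, -1, dtype=float)
            # window [j..n-1] has second-difference centres j+1..n-2
            rev = np.cumsum(d2[::-1])[::-1]
            noise = np.concatenate([rev[1:], [0.0]]) / 6.0
        sxx = cxx - cx * cx / m
        syy = cyy - cy * cy / m
        sxy = cxy - cx * cy / m
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            sse = syy - sxy * sxy / sxx
            excess = np.maximum(sse - _NOISE_GUARD * noise, 0.0)
            # flat-signal windows (syy≈0) count as linear
            r2 = np.where(syy > 0.0, 1.0 - sse / syy, 1.0)
            r2_star = np.where(syy > 0.0, 1.0 - excess / syy, 1.0)
        slope = np.where(m >= 2, slope, np.nan)
        r2 = np.where(m >= 2, r2, np.nan)
        r2_star = np.where(m >= 2, r2_star, np.nan)
        out[which] = (slope, r2, r2_star)
    return out["prefix"], out["suffix"]


def segment_phases(
    curve: UniaxialRecord | tuple[np.ndarray, np.ndarray],
    r_lin: float = 0.9995,
    min_points: int = 10,
) -> PhaseResult:
    """Segment a compression curve into toe / transition / compacted phases.

    Parameters
    ----------
    curve
        Reduced record (magnitude-positive compression) or a
        ``(strain, stress)`` pair.  Strain must be monotone increasing with at
        least 20 samples.
    r_lin
        Minimum noise-corrected R² for a window to count as linear.
    min_points
        Minimum samples in each linear window.

    Returns
    -------
    PhaseResult with boundaries ε_A < ε_B, slopes E1 = k1 and E2 = k2, and
    per-segment R².  A curve that is linear throughout is flagged
    ``degenerate`` with E1 = E2 = the global slope.
    """
    if isinstance(curve, UniaxialRecord):
        if not curve.is_reduced:
            raise ValueError("segment_phases needs a reduced record")
        strain, stress = curve.strain, curve.stress_MPa
    else:
        strain, stress = (np.asarray(a, dtype=float) for a in curve)
    if len(strain) < 20:
        raise ValueError("segmentation needs at least 20 samples")
    if np.any(np.diff(strain) < 0.0):
        raise ValueError("strain must be monotone non-decreasing")
    n = len(strain)
    min_points = max(int(min_points), 3)

    (slope_pre, r2_pre, rs_pre), (slope_suf, r2_suf, rs_suf) = _running_linear_fits(
        strain, stress
    )

    pre_ok = np.flatnonzero(rs_pre[min_points - 1 :] >= r_lin) + (min_points - 1)
    suf_ok = np.flatnonzero(rs_suf[: n - min_points + 1] >= r_lin)
    if len(pre_ok) == 0:
        raise SegmentationError(
            f"no toe window of >= {min_points} points reaches R²* >= {r_lin} "
            f"(best {np.nanmax(rs_pre[min_points - 1:]):.4f})"
        )
    if len(suf_ok) == 0:
        raise SegmentationError(
            f"no compacted window of >= {min_points} points reaches R²* >= {r_lin} "
            f"(best {np.nanmax(rs_suf[: n - min_points + 1]):.4f})"
        )
    ia = int(pre_ok[-1])  # largest admissible end of the toe window
    ib = int(suf_ok[0])  # smallest admissible start of the compacted window

    degenerate = strain[ia] >= strain[ib]
    return PhaseResult(
        strain_a=float(strain[ia]),
        strain_b=float(strain[ib]),
        e1=float(slope_pre[ia]),
        e2=float(slope_suf[ib]),
        r2_toe=float(r2_pre[ia]),
        r2_compacted=float(r2_suf[ib]),
        degenerate=bool(degenerate),
    )


def replicate_stats(values) -> ReplicateStats:
    """Arithmetic mean and sample variance (n−1) across replicate tests."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("replicate statistics need at least two values")
    return ReplicateStats(
        mean=float(v.mean()), variance=float(v.var(ddof=1)), n=int(v.size)
    )
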