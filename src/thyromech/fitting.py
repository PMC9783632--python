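"""Calibration of hyperelastic strain-energy models to stress–strain curves.

Fitting minimises the unweighted sum of squared residuals between the model's
engineering stress T(ε) and the measured engineering stress, on the curve's
own strain grid.  Goodness of fit is reported as R² = 1 − SS_res/SS_tot with
SS_tot taken about the data mean.

For the neo-Hookean, Mooney–Rivlin and Yeoh families the engineering stress is
*linear* in the coefficients, so the global least-squares optimum is obtained
exactly by a linear solve — deterministic and start-independent.  The Ogden
family is nonlinear in its exponents; it is fitted by multistart nonlinear
least squares over a fixed grid of exponent initialisations, with the moduli
profiled out linearly at each start.

Compression records stored magnitude-positive are converted to the
tension-positive model convention (ε → −ε, σ → −σ) before fitting, so one
closed form serves both loading modes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .mechanics import Family, HyperelasticParams, uniaxial_engineering_stress
from .reduction import LoadingMode, UniaxialRecord

__all__ = ["FitReport", "fit_model", "compare_models"]

#: Exponent initialisation grid for Ogden multistarts (pairs drawn from here).
_OGDEN_ALPHA_GRID = (-8.0, -4.0, -2.0, 2.0, 4.0, 8.0, 12.0)


@dataclass
class FitReport:
    """Result of calibrating one strain-energy family to one curve."""

    family: Family
    params: HyperelasticParams | None
    rss: float
    r2: float
    residuals: np.ndarray
    success: bool
    n_data: int
    strain_range: tuple[float, float]
    iterations: int = 0
    message: str = ""
    warnings: list[str] = field(default_factory=list)

    @property
    def n_parameters(self) -> int:
        return 0 if self.params is None else self.params.n_parameters


def _model_frame(record: UniaxialRecord) -> tuple[np.ndarray, np.ndarray]:
    """Strain/stress in the tension-positive model convention."""
    if not record.is_reduced:
        raise ValueError("fitting needs a reduced record")
    eps = np.asarray(record.strain, dtype=float)
    sig = np.asarray(record.stress_MPa, dtype=float)
    if record.mode is LoadingMode.COMPRESSION:
        eps, sig = -eps, -sig
    if np.any(eps <= -1.0):
        raise ValueError("strains at or below -1 are unphysical")
    return eps, sig


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ss_res = float(np.sum(resid**2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else -np.inf
    return 1.0 - ss_res / ss_tot


def _linear_design(family: Family, lam: np.ndarray) -> np.ndarray:
    """Design matrix of the engineering stress for coefficient-linear families."""
    base = 2.0 * (lam - lam**-2)
    if family is Family.NEO_HOOKEAN:
        return base[:, None]
    if family is Family.MOONEY_RIVLIN:
        return np.column_stack([base, base / lam])
    if family is Family.YEOH:
        x = lam**2 + 2.0 / lam - 3.0
        return np.column_stack([base, 2.0 * base * x, 3.0 * base * x**2])
    raise ValueError(f"{family} is not coefficient-linear")


def _drucker_warning(params: HyperelasticParams, lam: np.ndarray) -> list[str]:
    """Flag non-monotone nominal stress on the fitted range (stability hint)."""
    grid = np.linspace(lam.min(), lam.max(), 101)
    te = uniaxial_engineering_stress(params, grid - 1.0)
    if np.any(np.diff(te) < 0.0):
        return ["fitted response is non-monotone on the data range (stability check)"]
    return []


def fit_model(
    record: UniaxialRecord,
    family: Family | str,
    ogden_order: int = 2,
    relative_weighting: bool = False,
) -> FitReport:
    """Calibrate one strain-energy family to a reduced stress–strain curve.

    Parameters
    ----------
    record
        Reduced curve; compression records may be magnitude-positive.
    family
        Model family to fit.
    ogden_order
        Number of (μ, α) pairs for the Ogden family.
    relative_weighting
        Weight residuals by 1/|σ| (floored at 5% of max |σ|) instead of the
        default unweighted least squares.
    """
    family = Family(family)
    eps, sig = _model_frame(record)
    n_par = {Family.NEO_HOOKEAN: 1, Family.MOONEY_RIVLIN: 2, Family.YEOH: 3}.get(
        family, 2 * ogden_order
    )
    if len(eps) < n_par + 2:
        raise ValueError(f"need at least {n_par + 2} samples to fit {family.value}")
    lam = 1.0 + eps
    if relative_weighting:
        w = 1.0 / np.maximum(np.abs(sig), 0.05 * np.max(np.abs(sig)) + 1e-300)
    else:
        w = np.ones_like(sig)

    if family is not Family.OGDEN:
        design = _linear_design(family, lam)
        coef, *_ = np.linalg.lstsq(design * w[:, None], sig * w, rcond=None)
        params = HyperelasticParams(family, tuple(float(c) for c in coef))
        resid = design @ coef - sig
        report = FitReport(
            family=family,
            params=params,
            rss=float(np.sum((resid * w) ** 2)),
            r2=_r2(sig, resid),
            residuals=resid,
            success=True,
            n_data=len(eps),
            strain_range=(float(eps.min()), float(eps.max())),
            iterations=1,
            message="linear least squares (global optimum)",
        )
        report.warnings += _drucker_warning(params, lam)
        return report

    return _fit_ogden(eps, sig, lam, w, ogden_order)


def _ogden_te(lam: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    basis = lam[:, None] ** (alpha[None, :] - 1.0) - lam[:, None] ** (
        -alpha[None, :] / 2.0 - 1.0
    )
    return basis @ mu


def _fit_ogden(
    eps: np.ndarray, sig: np.ndarray, lam: np.ndarray, w: np.ndarray, order: int
) -> FitReport:
    """Multistart Ogden fit: α's from a fixed grid, μ's profiled by lstsq.

    Exploration runs every start on a ≤400-point subsample with loose
    tolerances; the best candidates are refined on the full data.  Fully
    deterministic (fixed grid, fixed subsample).
    """

    def make_residual(l: np.ndarray, s: np.ndarray, wt: np.ndarray):
        def residual(theta: np.ndarray) -> np.ndarray:
            mu, alpha = theta[:order], theta[order:]
            return (_ogden_te(l, mu, alpha) - s) * wt

        return residual

    def profile_mu(alpha: np.ndarray) -> np.ndarray:
        basis = lam[:, None] ** (alpha[None, :] - 1.0) - lam[:, None] ** (
            -alpha[None, :] / 2.0 - 1.0
        )
        mu, *_ = np.linalg.lstsq(basis * w[:, None], sig * w, rcond=None)
        return mu

    sub = np.unique(np.linspace(0, len(lam) - 1, 400).astype(int))
    res_sub = make_residual(lam[sub], sig[sub], w[sub])
    res_full = make_residual(lam, sig, w)

    starts = [
        np.asarray(combo, dtype=float)
        for combo in itertools.combinations(_OGDEN_ALPHA_GRID, order)
    ]
    candidates = []
    total_nfev = 0
    for alpha0 in starts:
        with np.errstate(over="ignore", invalid="ignore"):
            mu0 = profile_mu(alpha0)
            if not np.all(np.isfinite(mu0)):
                continue
            theta0 = np.concatenate([mu0, alpha0])
            try:
                sol = least_squares(
                    res_sub, theta0, method="lm", xtol=1e-8, ftol=1e-8, max_nfev=400
                )
            except (ValueError, FloatingPointError):
                continue
        total_nfev += sol.nfev
        if np.all(np.isfinite(sol.x)):
            candidates.append(sol)
    candidates.sort(key=lambda s: s.cost)
    best = None
    for cand in candidates[:3]:
        with np.errstate(over="ignore", invalid="ignore"):
            try:
                sol = least_squares(
                    res_full, cand.x, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=2000
                )
            except (ValueError, FloatingPointError):
                continue
        total_nfev += sol.nfev
        if not np.all(np.isfinite(sol.x)):
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return FitReport(
            family=Family.OGDEN,
            params=None,
            rss=np.inf,
            r2=-np.inf,
            residuals=np.full_like(sig, np.nan),
            success=False,
            n_data=len(eps),
            strain_range=(float(eps.min()), float(eps.max())),
            iterations=total_nfev,
            message="all Ogden starts failed to converge",
        )
    mu, alpha = best.x[:order], best.x[order:]
    warnings: list[str] = []
    if np.sum(mu * alpha) <= 0.0:
        # keep the raw solution but flag the unstable ground state
        warnings.append("fitted Ogden ground-state shear modulus is non-positive")
        params = None
        success = False
    else:
        params = HyperelasticParams.ogden(tuple(mu), tuple(alpha))
        success = True
    resid = _ogden_te(lam, mu, alpha) - sig
    report = FitReport(
        family=Family.OGDEN,
        params=params,
        rss=float(np.sum((resid * w) ** 2)),
        r2=_r2(sig, resid),
        residuals=resid,
        success=success,
        n_data=len(eps),
        strain_range=(float(eps.min()), float(eps.max())),
        iterations=total_nfev,
        message=best.message,
        warnings=warnings,
    )
    if params is not None:
        report.warnings += _drucker_warning(params, lam)
    return report


def compare_models(
    record: UniaxialRecord,
    families: tuple[Family | str, ...] = (
        Family.NEO_HOOKEAN,
        Family.MOONEY_RIVLIN,
        Family.YEOH,
        Family.OGDEN,
    ),
    ogden_order: int = 2,
    r2_tie_tol: float = 1e-6,
) -> list[FitReport]:
    """Fit several families to one curve and rank them.

    Ranked by R² descending; fits whose R² differ by less than ``r2_tie_tol``
    are tied and the model with fewer parameters wins (parsimony tie-break).
    Failed fits sort last.
    """
    reports = [fit_model(record, fam, ogden_order=ogden_order) for fam in families]
    reports.sort(key=lambda r: (-r.r2 if np.isfinite(r.r2) else np.inf, r.n_parameters))
    # parsimony pass: promote a simpler model over a tied richer one
    changed = True
    while changed:
        changed = False
        for i in range(len(reports) - 1):
            a, b = reports[i], reports[i + 1]
            if (
                b.success
                and a.success
                and abs(a.r2 - b.r2) < r2_tie_tol
                and b.n_parameters < a.n_parameters
            ):
                reports[i], reports[i + 1] = b, a
                changed = True
    return reports
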