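"""Prony-series stress relaxation: evaluation, fitting and summary statistics.

Under a step strain ε0 held constant, a generalised-Maxwell (Prony-series)
material relaxes with modulus

    G(t) = Σ_{i=1..n} E_i exp(−t/τ_i) + E_∞,

so G(0) = ΣE_i + E_∞ and G(t) → E_∞ as t → ∞.  The equilibrium (long-term)
modulus follows directly from the residual stress: E_∞ = σ_∞ / ε0.

Fitting operates on the relaxation modulus G(t) = σ(t)/ε0 over the hold
period; t = 0 is the moment the ramp stops (the series assumes step strain,
so any ramp segment is excluded from the fit window).  Relaxation-time
initialisation is log-spaced over the record duration and each τ is bounded
below by the sampling interval; fitted terms are returned sorted by τ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .phases import ReplicateStats, replicate_stats
from .reduction import LoadingMode, UniaxialRecord

__all__ = [
    "PronyParams",
    "RelaxationSummary",
    "prony_eval",
    "long_term_modulus",
    "fit_prony",
    "PronyFitReport",
    "summarize_relaxation",
    "relaxation_summary_stats",
]


@dataclass(frozen=True)
class PronyParams:
    """Prony-series parameters: n decaying terms plus an equilibrium modulus.

    ``moduli`` are the E_i (MPa), ``taus`` the relaxation times τ_i (s, sorted
    ascending) and ``equilibrium`` the long-term modulus E_∞ (MPa).
    """

    moduli: tuple[float, ...]
    taus: tuple[float, ...]
    equilibrium: float

    def __post_init__(self) -> None:
        if len(self.moduli) != len(self.taus):
            raise ValueError("moduli and taus must have equal length")
        if len(self.taus) < 1:
            raise ValueError("need at least one Prony term")
        if min(self.taus) <= 0.0:
            raise ValueError("relaxation times must be positive")
        if list(self.taus) != sorted(self.taus):
            raise ValueError("relaxation times must be sorted ascending")

    @property
    def n_terms(self) -> int:
        return len(self.moduli)

    @property
    def instantaneous(self) -> float:
        """G(0) = ΣE_i + E_∞ (MPa)."""
        return float(sum(self.moduli) + self.equilibrium)


@dataclass(frozen=True)
class RelaxationSummary:
    """Initial/residual stress of one relaxation test."""

    initial_stress_MPa: float
    final_stress_MPa: float
    hold_strain: float
    hold_duration_s: float


@dataclass
class PronyFitReport:
    """Diagnostics of a Prony-series fit."""

    params: PronyParams | None
    rss: float
    r2: float
    success: bool
    iterations: int
    message: str = ""


def prony_eval(params: PronyParams, t):
    """Relaxation modulus G(t) (MPa) at times t ≥ 0 (s)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0.0):
        raise ValueError("time must be non-negative")
    e = np.asarray(params.moduli)
    tau = np.asarray(params.taus)
    flat = t_arr.reshape(-1)
    g = (e[None, :] * np.exp(-flat[:, None] / tau[None, :])).sum(axis=1) + params.equilibrium
    g = g.reshape(t_arr.shape)
    return g[()] if np.ndim(t) == 0 else g


def long_term_modulus(summary: RelaxationSummary | None = None, *,
                      residual_stress: float | None = None,
                      hold_strain: float | None = None) -> float:
    """Equilibrium modulus E_∞ = σ_∞ / ε0 (MPa) from a relaxation test."""
    if summary is not None:
        residual_stress = summary.final_stress_MPa
        hold_strain = summary.hold_strain
    if residual_stress is None or hold_strain is None:
        raise ValueError("need residual stress and hold strain")
    if hold_strain <= 0.0:
        raise ValueError("hold strain must be positive")
    return residual_stress / hold_strain


def summarize_relaxation(record: UniaxialRecord) -> RelaxationSummary:
    """Initial and residual stress of a relaxation record's hold period."""
    if record.time_s is None or record.stress_MPa is None:
        raise ValueError("relaxation record needs time and stress series")
    if record.hold_strain is None:
        raise ValueError("relaxation record needs hold_strain metadata")
    return RelaxationSummary(
        initial_stress_MPa=float(record.stress_MPa[0]),
        final_stress_MPa=float(record.stress_MPa[-1]),
        hold_strain=float(record.hold_strain),
        hold_duration_s=float(record.time_s[-1] - record.time_s[0]),
    )


def fit_prony(
    record: UniaxialRecord,
    n_terms: int = 4,
    hold_strain: float | None = None,
) -> tuple[PronyParams | None, PronyFitReport]:
    """Fit an n-term Prony series to a relaxation record.

    The stress series is converted to a modulus G(t) = σ(t)/ε0 with ε0 the
    held strain (from ``hold_strain`` or the record metadata) and fitted by
    bounded nonlinear least squares.  E_i, E_∞ ≥ 0; τ_i ∈ [dt, 100·T] with dt
    the sampling interval and T the hold duration; τ initialisation is
    log-spaced over [T/200, 2T].  Terms are returned sorted by τ.
    """
    if record.mode is not LoadingMode.RELAXATION:
        raise ValueError("fit_prony expects a relaxation record")
    eps0 = hold_strain if hold_strain is not None else record.hold_strain
    if eps0 is None or eps0 <= 0.0:
        raise ValueError("positive hold strain required")
    t = np.asarray(record.time_s, dtype=float)
    g = np.asarray(record.stress_MPa, dtype=float) / eps0
    if len(t) <= 2 * n_terms + 1:
        raise ValueError("too few samples for the requested number of terms")
    t = t - t[0]  # series assumes step strain applied at t = 0
    duration = t[-1]
    dt = float(np.min(np.diff(t)))

    g0, ginf = float(g[0]), float(min(g[-1], g[0]))
    e_scale = max(g0 - ginf, 1e-12 * max(abs(g0), 1.0), 0.0)
    tau0 = np.geomspace(max(duration / 200.0, dt), 2.0 * duration, n_terms)
    theta0 = np.concatenate(
        [np.full(n_terms, e_scale / n_terms), tau0, [max(ginf, 0.0)]]
    )
    lo = np.concatenate([np.zeros(n_terms), np.full(n_terms, dt), [0.0]])
    hi = np.concatenate(
        [np.full(n_terms, 10.0 * max(g0, 1e-12)), np.full(n_terms, 100.0 * duration),
         [10.0 * max(g0, 1e-12)]]
    )
    theta0 = np.clip(theta0, lo + 1e-15, hi - 1e-15)

    def residual(theta: np.ndarray) -> np.ndarray:
        e, tau, einf = theta[:n_terms], theta[n_terms : 2 * n_terms], theta[-1]
        model = (e[None, :] * np.exp(-t[:, None] / tau[None, :])).sum(axis=1) + einf
        return model - g

    def jacobian(theta: np.ndarray) -> np.ndarray:
        e, tau = theta[:n_terms], theta[n_terms : 2 * n_terms]
        decay = np.exp(-t[:, None] / tau[None, :])
        d_tau = e[None, :] * decay * t[:, None] / tau[None, :] ** 2
        return np.hstack([decay, d_tau, np.ones((len(t), 1))])

    sol = least_squares(
        residual, theta0, jac=jacobian, bounds=(lo, hi),
        xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=5000,
    )
    resid = residual(sol.x)
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    if not (sol.success and np.all(np.isfinite(sol.x))):
        return None, PronyFitReport(
            params=None, rss=float(np.sum(resid**2)), r2=r2, success=False,
            iterations=sol.nfev, message=sol.message,
        )
    e, tau, einf = sol.x[:n_terms], sol.x[n_terms : 2 * n_terms], float(sol.x[-1])
    order = np.argsort(tau)
    params = PronyParams(
        moduli=tuple(float(v) for v in e[order]),
        taus=tuple(float(v) for v in tau[order]),
        equilibrium=einf,
    )
    report = PronyFitReport(
        params=params, rss=float(np.sum(resid**2)), r2=r2, success=True,
        iterations=sol.nfev, message=sol.message,
    )
    return params, report


def relaxation_summary_stats(
    records: list[UniaxialRecord] | list[RelaxationSummary],
) -> dict[str, ReplicateStats]:
    """Replicate mean/variance of initial and residual stress across tests."""
    summaries = [
        r if isinstance(r, RelaxationSummary) else summarize_relaxation(r)
        for r in records
    ]
    return {
        "initial_stress_MPa": replicate_stats([s.initial_stress_MPa for s in summaries]),
        "final_stress_MPa": replicate_stats([s.final_stress_MPa for s in summaries]),
    }
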