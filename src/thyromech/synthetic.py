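"""Synthetic quasi-static test data with the statistical structure of real runs.

The generators emulate the reference bench protocol: cylindrical specimens
(⌀10 mm × 6 mm) compressed at a constant strain rate with force/displacement
logged at 125 Hz; stress-relaxation runs ramped at 200 mm/min to a held
compressive strain of 0.25 for 1000 s; strip specimens stretched for tensile
validation.  Stress curves come from the closed-form hyperelastic /
Prony-series forward models, inverted to raw force–displacement series through
the specimen geometry.

The noise model is multiplicative Gaussian on stress (soft-tissue scatter is
roughly proportional to the signal) plus optional additive force-sensor noise;
inter-specimen variability multiplies each material coefficient by a
log-normal factor, which keeps coefficient signs stable.  Every generator is a
pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .mechanics import HyperelasticParams, uniaxial_engineering_stress
from .reduction import LoadingMode, SpecimenGeometry, UniaxialRecord
from .viscoelastic import PronyParams, prony_eval

__all__ = [
    "GeneratorConfig",
    "generate_compression",
    "generate_relaxation",
    "generate_tension",
    "three_phase_curve",
]

_DEFAULT_YEOH = HyperelasticParams.yeoh(1.9e-3, -2.3e-3, 0.04)
_DEFAULT_PRONY = PronyParams(
    moduli=(0.91, 0.82, 0.76, 0.49), taus=(8.83, 88.68, 784.29, 2.89e3), equilibrium=0.51
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Material truth, protocol, noise model and replication for the generators."""

    seed: int
    hyperelastic: HyperelasticParams = _DEFAULT_YEOH
    prony: PronyParams = _DEFAULT_PRONY
    geometry: SpecimenGeometry = field(
        default_factory=lambda: SpecimenGeometry.cylinder(10.0, 6.0)
    )
    max_strain: float = 0.45
    strain_rate_per_s: float = 0.005
    sampling_hz: float = 125.0
    hold_strain: float = 0.25
    hold_duration_s: float = 1000.0
    ramp_speed_mm_per_min: float = 200.0
    relaxation_sampling_hz: float = 5.0
    noise_sd_fraction: float = 0.02  # multiplicative Gaussian sd on stress
    force_noise_sd_N: float = 0.0  # additive sensor noise
    specimen_cv: float = 0.10  # log-normal CV on material coefficients
    replicates: int = 6
    tension_softening: float = 1.0  # measured-like = softening × truth
    tension_max_strain: float = 0.42
    tension_speed_mm_per_s: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd_fraction < 0 or self.force_noise_sd_N < 0 or self.specimen_cv < 0:
            raise ValueError("noise levels must be non-negative")
        if self.sampling_hz <= 0 or self.relaxation_sampling_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def _perturb(params: HyperelasticParams, cv: float, rng: np.random.Generator
             ) -> HyperelasticParams:
    """Per-specimen material variability: log-normal factor per coefficient."""
    if cv == 0.0:
        return params
    sigma = np.sqrt(np.log1p(cv**2))
    factors = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma,
                            size=len(params.coefficients))
    return HyperelasticParams(
        params.family,
        tuple(c * f for c, f in zip(params.coefficients, factors)),
    )


def _perturb_prony(params: PronyParams, cv: float, rng: np.random.Generator) -> PronyParams:
    if cv == 0.0:
        return params
    sigma = np.sqrt(np.log1p(cv**2))
    f_mod = rng.lognormal(-sigma**2 / 2.0, sigma, size=params.n_terms)
    f_eq = rng.lognormal(-sigma**2 / 2.0, sigma)
    return PronyParams(
        moduli=tuple(e * f for e, f in zip(params.moduli, f_mod)),
        taus=params.taus,
        equilibrium=params.equilibrium * f_eq,
    )


def generate_compression(cfg: GeneratorConfig) -> list[UniaxialRecord]:
    """Raw compression records (time, displacement, force), magnitude-positive.

    Each replicate draws perturbed coefficients, evaluates the closed-form
    engineering stress at the protocol's strain ramp, converts to force
    through the specimen area and adds noise.  The strain rate only sets the
    time axis (no rate dependence is modelled, matching the quasi-static
    observation that the two bench rates coincide).
    """
    rng = np.random.default_rng(cfg.seed)
    l0 = cfg.geometry.gauge_length_mm
    area = cfg.geometry.area_mm2
    duration = cfg.max_strain / cfg.strain_rate_per_s
    n = int(np.floor(duration * cfg.sampling_hz)) + 1
    t = np.arange(n) / cfg.sampling_hz
    eps = cfg.strain_rate_per_s * t  # compression magnitude
    records = []
    for k in range(cfg.replicates):
        p = _perturb(cfg.hyperelastic, cfg.specimen_cv, rng)
        # tension-positive model evaluated at λ < 1, flipped to magnitude form
        stress = -uniaxial_engineering_stress(p, -eps)
        noisy = stress * (1.0 + cfg.noise_sd_fraction * rng.standard_normal(n))
        force = noisy * area + cfg.force_noise_sd_N * rng.standard_normal(n)
        records.append(
            UniaxialRecord(
                specimen_id=f"sim_comp_{k + 1:02d}",
                mode=LoadingMode.COMPRESSION,
                strain_rate_per_s=cfg.strain_rate_per_s,
                geometry=cfg.geometry,
                time_s=t,
                displacement_mm=eps * l0,
                force_N=force,
                meta={"truth_coefficients": p.coefficients, "seed": cfg.seed},
            )
        )
    return records


def generate_relaxation(cfg: GeneratorConfig) -> list[UniaxialRecord]:
    """Relaxation records: ramp segment plus a 1000 s hold at strain ε0.

    During the hold, σ(t) = ε0·G(t) with G the Prony-series modulus and t = 0
    at the end of the ramp.  The ramp segment (constant crosshead speed) is
    included and flagged through ``meta['hold_start_index']`` so fitting can
    exclude it.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    l0 = cfg.geometry.gauge_length_mm
    ramp_speed = cfg.ramp_speed_mm_per_min / 60.0  # mm/s
    ramp_time = cfg.hold_strain * l0 / ramp_speed
    dt = 1.0 / cfg.relaxation_sampling_hz
    t_ramp = np.arange(0.0, ramp_time, dt)
    t_hold = np.arange(0.0, cfg.hold_duration_s + dt / 2.0, dt)
    records = []
    for k in range(cfg.replicates):
        p = _perturb_prony(cfg.prony, cfg.specimen_cv, rng)
        g_hold = prony_eval(p, t_hold)
        sigma_hold = cfg.hold_strain * g_hold
        # simple monotone loading ramp up to the instantaneous response
        sigma_ramp = (t_ramp / ramp_time) * cfg.hold_strain * p.instantaneous
        sigma = np.concatenate([sigma_ramp, sigma_hold])
        t_all = np.concatenate([t_ramp, ramp_time + t_hold])
        noisy = sigma * (1.0 + cfg.noise_sd_fraction * rng.standard_normal(len(sigma)))
        records.append(
            UniaxialRecord(
                specimen_id=f"sim_relax_{k + 1:02d}",
                mode=LoadingMode.RELAXATION,
                geometry=cfg.geometry,
                time_s=t_all,
                stress_MPa=noisy,
                hold_strain=cfg.hold_strain,
                meta={
                    "hold_start_index": len(t_ramp),
                    "truth": {
                        "moduli": p.moduli,
                        "taus": p.taus,
                        "equilibrium": p.equilibrium,
                    },
                    "seed": cfg.seed,
                },
            )
        )
    return records


def hold_segment(record: UniaxialRecord) -> UniaxialRecord:
    """Slice a generated relaxation record down to its hold period."""
    i0 = record.meta.get("hold_start_index", 0)
    return replace(
        record,
        time_s=record.time_s[i0:],
        stress_MPa=record.stress_MPa[i0:],
        meta={**record.meta, "hold_start_index": 0},
    )


def generate_tension(cfg: GeneratorConfig) -> tuple[UniaxialRecord, UniaxialRecord]:
    """A (measured-like, truth) pair of tensile curves for error analysis.

    The truth curve is the closed-form prediction of ``cfg.hyperelastic``; the
    measured-like curve is the truth scaled by ``cfg.tension_softening`` (a
    systematic model/experiment discrepancy) plus multiplicative noise.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    geometry = SpecimenGeometry.strip(80.0, 15.0, 5.0)
    duration = cfg.tension_max_strain * geometry.gauge_length_mm / cfg.tension_speed_mm_per_s
    n = int(np.floor(duration * cfg.sampling_hz)) + 1
    t = np.arange(n) / cfg.sampling_hz
    eps = cfg.tension_speed_mm_per_s * t / geometry.gauge_length_mm
    te = np.asarray(uniaxial_engineering_stress(cfg.hyperelastic, eps), dtype=float)
    truth = UniaxialRecord(
        specimen_id="sim_tension_truth",
        mode=LoadingMode.TENSION,
        geometry=geometry,
        strain=eps,
        stress_MPa=te,
        meta={"seed": cfg.seed},
    )
    measured = UniaxialRecord(
        specimen_id="sim_tension_measured",
        mode=LoadingMode.TENSION,
        geometry=geometry,
        strain=eps,
        stress_MPa=cfg.tension_softening
        * te
        * (1.0 + cfg.noise_sd_fraction * rng.standard_normal(n)),
        meta={"softening": cfg.tension_softening, "seed": cfg.seed},
    )
    return measured, truth


def three_phase_curve(
    k1: float = 2.2e-5,
    k2: float = 3.1e-3,
    strain_a: float = 0.1,
    strain_b: float = 0.3,
    max_strain: float = 0.45,
    n: int = 600,
    noise_sd_fraction: float = 0.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """An exact piecewise toe/transition/compacted curve with known slopes.

    Linear with slope ``k1`` on [0, strain_a], a C¹ cubic Hermite blend on
    [strain_a, strain_b], and linear with slope ``k2`` on [strain_b,
    max_strain] — the canonical concave-up shape of gland compression data.
    Optional multiplicative Gaussian noise (fraction of local stress).
    """
    if not 0.0 < strain_a < strain_b < max_strain:
        raise ValueError("need 0 < strain_a < strain_b < max_strain")
    eps = np.linspace(0.0, max_strain, n)
    s_a = k1 * strain_a
    s_b = s_a + 0.5 * (k1 + k2) * (strain_b - strain_a)
    stress = np.empty_like(eps)
    toe = eps <= strain_a
    comp = eps >= strain_b
    mid = ~(toe | comp)
    stress[toe] = k1 * eps[toe]
    stress[comp] = s_b + k2 * (eps[comp] - strain_b)
    h = strain_b - strain_a
    u = (eps[mid] - strain_a) / h  # cubic Hermite on the transition
    h00 = 2 * u**3 - 3 * u**2 + 1
    h10 = u**3 - 2 * u**2 + u
    h01 = -2 * u**3 + 3 * u**2
    h11 = u**3 - u**2
    stress[mid] = h00 * s_a + h10 * h * k1 + h01 * s_b + h11 * h * k2
    if noise_sd_fraction > 0.0:
        rng = np.random.default_rng(seed)
        stress = stress * (1.0 + noise_sd_fraction * rng.standard_normal(n))
    return eps, stress
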