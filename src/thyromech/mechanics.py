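"""Closed-form uniaxial mechanics of incompressible isotropic hyperelastic solids.

The thyroid parenchyma (and soft gland tissue generally) is modelled here as an
incompressible, isotropic hyperelastic material.  A deformation is described by
its principal stretches (λ1, λ2, λ3); the right Cauchy–Green invariants are

    I1 = λ1² + λ2² + λ3²,
    I2 = λ1²λ2² + λ2²λ3² + λ3²λ1²,
    I3 = λ1²λ2²λ3²  (= 1 for incompressible deformation).

The principal Cauchy stresses follow from a strain-energy density W as

    σi = λi ∂W/∂λi − p,

where p is the indeterminate hydrostatic pressure fixed by the boundary
conditions.  For uniaxial loading along direction 1 with traction-free lateral
surfaces, incompressibility gives λ2 = λ3 = λ^(−1/2) and σ2 = σ3 = 0, which
determines p and yields a closed-form axial Cauchy stress σ(λ).  The
engineering (nominal) stress is T = σ/λ, and λ = 1 + ε with ε the engineering
strain.

Four strain-energy families are supported:

    neo-Hookean    W = C10 (I1 − 3)
    Mooney–Rivlin  W = C10 (I1 − 3) + C01 (I2 − 3)
    Yeoh           W = C10 (I1 − 3) + C20 (I1 − 3)² + C30 (I1 − 3)³
    Ogden order-N  W = Σp (μp/αp) (λ1^αp + λ2^αp + λ3^αp − 3)

Coefficients carry MPa units (Ogden α's are dimensionless exponents).  The
sign convention is tension-positive: λ > 1 gives σ > 0, compression (λ < 1)
gives σ < 0.  Full tensors F and C are never materialised — uniaxial states
only need principal stretches.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

__all__ = [
    "Family",
    "PrincipalStretches",
    "Invariants",
    "HyperelasticParams",
    "UniaxialState",
    "invariants_from_stretches",
    "uniaxial_stretches",
    "strain_energy",
    "stretch_stress_unconstrained",
    "hydrostatic_pressure",
    "uniaxial_cauchy_stress",
    "uniaxial_engineering_stress",
    "small_strain_modulus",
]


class Family(str, Enum):
    """Strain-energy model family."""

    NEO_HOOKEAN = "neo_hookean"
    MOONEY_RIVLIN = "mooney_rivlin"
    YEOH = "yeoh"
    OGDEN = "ogden"


@dataclass(frozen=True)
class PrincipalStretches:
    """Principal elongations (λ1, λ2, λ3) of a deformation state."""

    lambda1: float
    lambda2: float
    lambda3: float

    def __post_init__(self) -> None:
        if min(self.lambda1, self.lambda2, self.lambda3) <= 0.0:
            raise ValueError("principal stretches must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda1, self.lambda2, self.lambda3])


@dataclass(frozen=True)
class Invariants:
    """Invariants (I1, I2, I3) of the right Cauchy–Green tensor."""

    I1: float
    I2: float
    I3: float


@dataclass(frozen=True)
class HyperelasticParams:
    """Coefficients of one strain-energy model.

    ``coefficients`` is ordered per family: Yeoh (C10, C20, C30),
    Mooney–Rivlin (C10, C01), neo-Hookean (C10,), Ogden order-N
    (μ1, α1, μ2, α2, ...).  Moduli in MPa; Ogden exponents dimensionless.
    """

    family: Family
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        n = len(self.coefficients)
        expected = {Family.NEO_HOOKEAN: 1, Family.MOONEY_RIVLIN: 2, Family.YEOH: 3}
        if self.family is Family.OGDEN:
            if n < 2 or n % 2:
                raise ValueError("Ogden coefficients must be (mu, alpha) pairs")
            mu, alpha = self.ogden_pairs()
            if np.sum(mu * alpha) <= 0.0:
                raise ValueError(
                    "Ogden parameters must satisfy sum(mu_p * alpha_p) > 0 "
                    "(positive ground-state shear modulus)"
                )
        elif n != expected[self.family]:
            raise ValueError(
                f"{self.family.value} takes {expected[self.family]} coefficients, got {n}"
            )

    @classmethod
    def neo_hookean(cls, c10: float) -> "HyperelasticParams":
        return cls(Family.NEO_HOOKEAN, (c10,))

    @classmethod
    def mooney_rivlin(cls, c10: float, c01: float) -> "HyperelasticParams":
        return cls(Family.MOONEY_RIVLIN, (c10, c01))

    @classmethod
    def yeoh(cls, c10: float, c20: float, c30: float) -> "HyperelasticParams":
        return cls(Family.YEOH, (c10, c20, c30))

    @classmethod
    def ogden(cls, mu: tuple[float, ...], alpha: tuple[float, ...]) -> "HyperelasticParams":
        if len(mu) != len(alpha):
            raise ValueError("mu and alpha must have equal length")
        coeffs: list[float] = []
        for m, a in zip(mu, alpha):
            coeffs.extend((m, a))
        return cls(Family.OGDEN, tuple(coeffs))

    def ogden_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.coefficients, dtype=float)
        return c[0::2], c[1::2]

    @property
    def n_parameters(self) -> int:
        return len(self.coefficients)

    def coefficient_names(self) -> tuple[str, ...]:
        if self.family is Family.NEO_HOOKEAN:
            return ("C10",)
        if self.family is Family.MOONEY_RIVLIN:
            return ("C10", "C01")
        if self.family is Family.YEOH:
            return ("C10", "C20", "C30")
        n = len(self.coefficients) // 2
        names: list[str] = []
        for p in range(1, n + 1):
            names.extend((f"mu{p}", f"alpha{p}"))
        return tuple(names)


@dataclass(frozen=True)
class UniaxialState:
    """A single uniaxial stress state (tension-positive convention)."""

    stretch: float
    engineering_strain: float
    cauchy_stress: float
    engineering_stress: float
    hydrostatic_pressure: float


def invariants_from_stretches(stretches: PrincipalStretches) -> Invariants:
    """Right Cauchy–Green invariants from principal stretches."""
    l2 = stretches.as_array() ** 2
    i1 = float(l2.sum())
    i2 = float(l2[0] * l2[1] + l2[1] * l2[2] + l2[2] * l2[0])
    i3 = float(l2.prod())
    return Invariants(i1, i2, i3)


def uniaxial_stretches(lam: float) -> PrincipalStretches:
    """Incompressible uniaxial state: λ2 = λ3 = λ^(−1/2), so I3 = 1."""
    if lam <= 0.0:
        raise ValueError("stretch must be strictly positive")
    lat = lam ** -0.5
    return PrincipalStretches(lam, lat, lat)


def _check_stretch(lam) -> np.ndarray:
    arr = np.asarray(lam, dtype=float)
    if np.any(arr <= 0.0):
        raise ValueError("stretch must be strictly positive")
    return arr


def _dW_dI(params: HyperelasticParams, i1, i2) -> tuple[np.ndarray, np.ndarray]:
    """Partial derivatives (∂W/∂I1, ∂W/∂I2) for invariant-based families."""
    i1 = np.asarray(i1, dtype=float)
    x = i1 - 3.0
    if params.family is Family.NEO_HOOKEAN:
        (c10,) = params.coefficients
        return np.full_like(i1, c10), np.zeros_like(i1)
    if params.family is Family.MOONEY_RIVLIN:
        c10, c01 = params.coefficients
        return np.full_like(i1, c10), np.full_like(i1, c01)
    if params.family is Family.YEOH:
        c10, c20, c30 = params.coefficients
        return c10 + 2.0 * c20 * x + 3.0 * c30 * x**2, np.zeros_like(i1)
    raise ValueError("Ogden is stretch-based; no invariant derivatives")


def strain_energy(params: HyperelasticParams, stretches: PrincipalStretches) -> float:
    """Strain-energy density W (MPa) at an arbitrary principal-stretch state."""
    if params.family is Family.OGDEN:
        mu, alpha = params.ogden_pairs()
        lams = stretches.as_array()
        return float(
            np.sum(mu / alpha * (np.sum(lams[None, :] ** alpha[:, None], axis=1) - 3.0))
        )
    inv = invariants_from_stretches(stretches)
    x = inv.I1 - 3.0
    y = inv.I2 - 3.0
    if params.family is Family.NEO_HOOKEAN:
        (c10,) = params.coefficients
        return c10 * x
    if params.family is Family.MOONEY_RIVLIN:
        c10, c01 = params.coefficients
        return c10 * x + c01 * y
    c10, c20, c30 = params.coefficients
    return c10 * x + c20 * x**2 + c30 * x**3


def stretch_stress_unconstrained(
    params: HyperelasticParams, stretches: PrincipalStretches
) -> np.ndarray:
    """The three values λi ∂W/∂λi (MPa), before the pressure term is subtracted.

    The principal Cauchy stresses are these minus the hydrostatic pressure p.
    """
    lams = stretches.as_array()
    if params.family is Family.OGDEN:
        mu, alpha = params.ogden_pairs()
        return np.sum(mu[:, None] * lams[None, :] ** alpha[:, None], axis=0)
    inv = invariants_from_stretches(stretches)
    w1, w2 = _dW_dI(params, inv.I1, inv.I2)
    l2 = lams**2
    # ∂I1/∂λi = 2λi,  ∂I2/∂λi = 2λi (I1 − λi²)
    return 2.0 * l2 * w1 + 2.0 * l2 * (inv.I1 - l2) * w2


def hydrostatic_pressure(params: HyperelasticParams, lam):
    """Hydrostatic pressure p (MPa) that makes the lateral stresses vanish.

    In the uniaxial incompressible state, σ2 = σ3 = 0 requires
    p = λ2 ∂W/∂λ2 evaluated at λ2 = λ^(−1/2).
    """
    lam = _check_stretch(lam)
    if params.family is Family.OGDEN:
        mu, alpha = params.ogden_pairs()
        flat = lam.reshape(-1)
        p = np.sum(
            mu[:, None] * flat[None, :] ** (-alpha[:, None] / 2.0), axis=0
        ).reshape(lam.shape)
        return p[()] if np.ndim(lam) == 0 else p
    i1 = lam**2 + 2.0 / lam
    w1, w2 = _dW_dI(params, i1, None)
    # λ2² = 1/λ and I1 − λ2² = λ² + 1/λ at the uniaxial state
    p = 2.0 / lam * w1 + 2.0 * (lam + lam**-2) * w2
    return p[()] if np.ndim(lam) == 0 else p


def uniaxial_cauchy_stress(params: HyperelasticParams, lam):
    """Axial Cauchy (true) stress σ (MPa) at stretch λ, tension-positive.

    Closed form after pressure elimination.  For the I1/I2 families
    σ = 2(λ² − λ⁻¹)(∂W/∂I1 + λ⁻¹ ∂W/∂I2); for Ogden
    σ = Σp μp (λ^αp − λ^(−αp/2)).
    """
    lam = _check_stretch(lam)
    if params.family is Family.OGDEN:
        mu, alpha = params.ogden_pairs()
        flat = lam.reshape(-1)
        s = np.sum(
            mu[:, None] * (flat[None, :] ** alpha[:, None] - flat[None, :] ** (-alpha[:, None] / 2.0)),
            axis=0,
        ).reshape(lam.shape)
        return s[()] if np.ndim(lam) == 0 else s
    i1 = lam**2 + 2.0 / lam
    w1, w2 = _dW_dI(params, i1, None)
    s = 2.0 * (lam**2 - 1.0 / lam) * (w1 + w2 / lam)
    return s[()] if np.ndim(lam) == 0 else s


def uniaxial_engineering_stress(params: HyperelasticParams, strain):
    """Engineering (nominal) stress T (MPa) at engineering strain ε = λ − 1.

    T = σ(1 + ε) / (1 + ε).  Requires ε > −1.
    """
    eps = np.asarray(strain, dtype=float)
    if np.any(eps <= -1.0):
        raise ValueError("engineering strain must exceed -1")
    lam = 1.0 + eps
    return uniaxial_cauchy_stress(params, lam) / lam


def small_strain_modulus(params: HyperelasticParams) -> float:
    """Tangent Young's modulus dT/dε at ε = 0 (MPa).

    6(C10 + C01) for the invariant families (6·C10 for Yeoh and
    neo-Hookean), and (3/2) Σ μp αp for Ogden — the incompressible
    small-strain identity E = 3μ0 with ground-state shear modulus
    μ0 = Σ μp αp / 2.
    """
    if params.family is Family.OGDEN:
        mu, alpha = params.ogden_pairs()
        return float(1.5 * np.sum(mu * alpha))
    w1, w2 = _dW_dI(params, 3.0, 3.0)
    return float(6.0 * (w1 + w2))


def uniaxial_state(params: HyperelasticParams, lam: float) -> UniaxialState:
    """Assemble the full uniaxial state at stretch λ."""
    lam = float(lam)
    _check_stretch(lam)
    sigma = float(uniaxial_cauchy_stress(params, lam))
    return UniaxialState(
        stretch=lam,
        engineering_strain=lam - 1.0,
        cauchy_stress=sigma,
        engineering_stress=sigma / lam,
        hydrostatic_pressure=float(hydrostatic_pressure(params, lam)),
    )
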