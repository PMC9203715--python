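"""Model parameters, non-dimensionalization, and animal presets.

The model lives in the transverse plane: two rigid bodies (fore and hind)
joined at their common centre of mass by a torsional spring, each carrying a
left and a right massless spring leg at roll-lever distance ``D`` from the
COM.  All dynamics are integrated in dimensionless form, obtained by scaling
mass by the total body mass, length by ``D`` and time by ``sqrt(D/g)``.

Dimensionless parameters
------------------------
mu0
    Mean dimensionless moment of inertia of the two bodies,
    ``(I_F + I_H) / (2 M D^2)``.
eps_mu
    Fore-aft inertia asymmetry: ``mu_F = (1 + eps_mu) mu0``,
    ``mu_H = (1 - eps_mu) mu0``.
k0
    Mean dimensionless leg stiffness, ``(K_F + K_H) D / (2 M g)``.
eps_k
    Fore-aft leg-stiffness asymmetry: ``k_F = (1 + eps_k) k0``,
    ``k_H = (1 - eps_k) k0``.
kappa
    Ratio of the body torsional-spring stiffness to the mean leg stiffness,
    ``k_B / k0`` with ``k_B = K_B / (M g D)``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "PhysicalParams",
    "ModelParams",
    "nondimensionalize",
    "preset",
    "physical_preset",
    "load_params",
    "PRESETS",
]


class InvalidParameterError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class PhysicalParams:
    """Dimensional parameter set.

    Attributes
    ----------
    M_total : float
        Total body mass ``M_F + M_H`` (kg).  Only the total enters the
        transverse-plane dynamics.
    I_F, I_H : float
        Roll moments of inertia of the fore and hind bodies about the COM
        (kg m^2).
    D : float
        Distance from the COM to each leg root, i.e. half the hip width (m).
    K_F, K_H : float
        Fore and hind leg spring constants (N/m).
    K_B : float
        Torsional body-spring constant (N m/rad).
    L0 : float
        Nominal (rest) leg length (m).
    g : float
        Gravitational acceleration (m/s^2).
    """

    M_total: float
    I_F: float
    I_H: float
    D: float
    K_F: float
    K_H: float
    K_B: float
    L0: float = 1.0
    g: float = 9.81

    def __post_init__(self) -> None:
        for name in ("M_total", "I_F", "I_H", "D", "K_F", "K_H", "K_B", "L0", "g"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(f"{name} must be strictly positive")


@dataclass(frozen=True)
class ModelParams:
    """Dimensionless parameter bundle of the trotting model."""

    mu0: float
    k0: float
    kappa: float
    eps_mu: float = 0.0
    eps_k: float = 0.0

    def __post_init__(self) -> None:
        if not self.mu0 > 0:
            raise InvalidParameterError("mu0 must be positive")
        if not self.k0 > 0:
            raise InvalidParameterError("k0 must be positive")
        if self.kappa < 0:
            raise InvalidParameterError("kappa must be non-negative")
        if not abs(self.eps_mu) < 1:
            raise InvalidParameterError("|eps_mu| must be < 1")
        if not abs(self.eps_k) < 1:
            raise InvalidParameterError("|eps_k| must be < 1")

    @property
    def mu_F(self) -> float:
        return (1.0 + self.eps_mu) * self.mu0

    @property
    def mu_H(self) -> float:
        return (1.0 - self.eps_mu) * self.mu0

    @property
    def k_F(self) -> float:
        return (1.0 + self.eps_k) * self.k0

    @property
    def k_H(self) -> float:
        return (1.0 - self.eps_k) * self.k0

    @property
    def k_B(self) -> float:
        return self.kappa * self.k0

    @property
    def is_symmetric(self) -> bool:
        return self.eps_mu == 0.0 and self.eps_k == 0.0

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def nondimensionalize(phys: PhysicalParams) -> ModelParams:
    """Map a physical parameter set to the dimensionless bundle.

    Uses the mass scale ``M_total``, length scale ``D`` and time scale
    ``sqrt(D/g)``::

        mu0   = (I_F + I_H) / (2 M D^2)
        eps_mu = (I_F - I_H) / (I_F + I_H)
        k0    = (K_F + K_H) D / (2 M g)
        eps_k = (K_F - K_H) / (K_F + K_H)
        kappa = k_B / k0,  with  k_B = K_B / (M g D)
    """
    M, D, g = phys.M_total, phys.D, phys.g
    mu0 = (phys.I_F + phys.I_H) / (2.0 * M * D**2)
    eps_mu = (phys.I_F - phys.I_H) / (phys.I_F + phys.I_H)
    k0 = (phys.K_F + phys.K_H) * D / (2.0 * M * g)
    eps_k = (phys.K_F - phys.K_H) / (phys.K_F + phys.K_H)
    k_B = phys.K_B / (M * g * D)
    return ModelParams(mu0=mu0, k0=k0, kappa=k_B / k0, eps_mu=eps_mu, eps_k=eps_k)


# Animal presets.  The dimensionless rows are the authoritative values used
# throughout; z_star is the prescribed apex height of the periodic solution.
PRESETS: dict[str, dict] = {
    "dog": dict(mu0=0.62, eps_mu=0.12, eps_k=0.21, k0=1.5, kappa=0.20, z_star=0.06),
    "horse": dict(mu0=0.72, eps_mu=0.14, eps_k=0.25, k0=2.2, kappa=0.21, z_star=0.06),
}

# Measured dimensional quantities behind the presets (large-breed dog,
# warmblood horse).  K_F/K_H is the published fore/hind stiffness ratio; the
# absolute spring constants are reconstructed from the dimensionless k0 so
# that nondimensionalize() round-trips the stiffness scale.
_PHYSICAL: dict[str, dict] = {
    "dog": dict(M_total=35.0, I_F=0.26, I_H=0.17, D=0.10, K_ratio=1.27),
    "horse": dict(M_total=538.0, I_F=23.4, I_H=14.1, D=0.22, K_ratio=1.33),
}


def preset(name: str) -> tuple[ModelParams, float]:
    """Return the dimensionless parameter bundle and apex height z* for an
    animal preset ("dog" or "horse")."""
    try:
        row = PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None
    row = dict(row)
    z_star = row.pop("z_star")
    return ModelParams(**row), z_star


def physical_preset(name: str, g: float = 9.81) -> PhysicalParams:
    """Dimensional parameter set for an animal preset.

    Masses, inertias and D are the measured values; the leg spring constants
    are reconstructed from the calibrated mean stiffness k0 together with the
    measured fore/hind stiffness ratio, and K_B from kappa.  Note the
    measured inertia and stiffness ratios imply asymmetry fractions that
    differ from the preset eps_mu/eps_k (the dimensionless preset is
    authoritative for those).
    """
    try:
        phys = _PHYSICAL[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(_PHYSICAL)}"
        ) from None
    row = PRESETS[name]
    M, D = phys["M_total"], phys["D"]
    K_sum = 2.0 * row["k0"] * M * g / D
    ratio = phys["K_ratio"]
    K_H = K_sum / (1.0 + ratio)
    K_F = K_sum - K_H
    K_B = row["kappa"] * row["k0"] * M * g * D
    return PhysicalParams(
        M_total=M, I_F=phys["I_F"], I_H=phys["I_H"], D=D,
        K_F=K_F, K_H=K_H, K_B=K_B, L0=0.5, g=g,
    )


_DIMLESS_KEYS = {"mu0", "k0", "kappa"}
_PHYS_KEYS = {"M_total", "I_F", "I_H", "D", "K_F", "K_H", "K_B"}


def load_params(path: str | Path) -> tuple[ModelParams, float | None]:
    """Load a parameter file (JSON or YAML, flat key-value).

    Either dimensionless keys {mu0, eps_mu, eps_k, k0, kappa[, z_star]} or
    physical keys {M_total, I_F, I_H, D, K_F, K_H, K_B[, L0, g, z_star]}.
    Returns (ModelParams, z_star or None).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise InvalidParameterError(f"parameter file {path} is not a mapping")
    z_star = data.pop("z_star", None)
    keys = set(data)
    if _DIMLESS_KEYS <= keys:
        return ModelParams(**data), z_star
    if _PHYS_KEYS <= keys:
        return nondimensionalize(PhysicalParams(**data)), z_star
    raise InvalidParameterError(
        f"parameter file {path} must contain either {_DIMLESS_KEYS} or {_PHYS_KEYS}"
    )
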