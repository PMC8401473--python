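"""Tissue material parameters for the nearly incompressible neo-Hookean law.

The breast is modelled as three homogeneous isotropic tissues — adipose,
fibro-glandular and skin — each described by a Young's modulus ``E`` (kPa),
a Poisson's ratio ``nu`` close to the incompressible limit, and a mass
density ``rho`` (kg/m^3).  The hyperelastic solver consumes the derived
initial shear modulus ``mu = E / (2 (1 + nu))`` and bulk modulus
``K = E / (3 (1 - 2 nu))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = [
    "TissueParams",
    "MaterialParams",
    "derive_moduli",
    "default_materials",
    "DEFAULT_STIFFNESS_RATIO",
]

#: fibro-glandular E divided by adipose E used whenever only the adipose
#: modulus is specified (literature-based composition ratio)
DEFAULT_STIFFNESS_RATIO = 7.5

#: standard gravitational acceleration, m/s^2
GRAVITY_M_S2 = 9.81


def derive_moduli(E: float, nu: float) -> tuple[float, float]:
    """Shear and bulk modulus (kPa) from Young's modulus and Poisson's ratio.

    ``mu = E / (2 (1 + nu))``, ``K = E / (3 (1 - 2 nu))``.

    Raises
    ------
    ValueError
        If ``E <= 0`` or ``nu`` lies outside the open interval (0, 0.5);
        at ``nu = 0.5`` the bulk modulus diverges.
    """
    if not E > 0:
        raise ValueError(f"Young's modulus must be positive, got {E}")
    if not 0.0 < nu < 0.5:
        raise ValueError(f"Poisson's ratio must be in (0, 0.5), got {nu}")
    mu = E / (2.0 * (1.0 + nu))
    K = E / (3.0 * (1.0 - 2.0 * nu))
    return mu, K


@dataclass(frozen=True)
class TissueParams:
    """One tissue: Young's modulus kPa, Poisson ratio, density kg/m^3."""

    E: float
    nu: float = 0.49
    rho: float = 1000.0

    def __post_init__(self) -> None:
        derive_moduli(self.E, self.nu)  # validates
        if not self.rho > 0:
            raise ValueError(f"density must be positive, got {self.rho}")

    @property
    def mu(self) -> float:
        return derive_moduli(self.E, self.nu)[0]

    @property
    def K(self) -> float:
        return derive_moduli(self.E, self.nu)[1]

    @property
    def body_force_per_g(self) -> float:
        """|body force| per unit gravity, in kPa/mm per (m/s^2).

        Internally the solver works in mm / kPa units, where the body force
        density is ``rho * g * 1e-6`` kPa/mm for ``rho`` in kg/m^3 and ``g``
        in m/s^2.
        """
        return self.rho * 1e-6


@dataclass(frozen=True)
class MaterialParams:
    """Per-tissue parameter set for the breast model.

    Defaults are the initial literature values used before patient-specific
    optimization: adipose E = 250 kPa (rho 950), fibro-glandular
    E = 1875 kPa (rho 1020), skin E = 1000 kPa (rho 1000), all at
    nu = 0.49.  The fibro-glandular modulus is 7.5x the adipose one.
    """

    adipose: TissueParams = field(default_factory=lambda: TissueParams(E=250.0, nu=0.49, rho=950.0))
    fibroglandular: TissueParams = field(default_factory=lambda: TissueParams(E=1875.0, nu=0.49, rho=1020.0))
    skin: TissueParams = field(default_factory=lambda: TissueParams(E=1000.0, nu=0.49, rho=1000.0))

    @property
    def stiffness_ratio(self) -> float:
        """Fibro-glandular over adipose Young's modulus."""
        return self.fibroglandular.E / self.adipose.E

    def with_adipose_E(
        self, E_adipose: float, stiffness_ratio: float = DEFAULT_STIFFNESS_RATIO
    ) -> "MaterialParams":
        """New parameter set with the adipose modulus replaced and the
        fibro-glandular modulus slaved at ``stiffness_ratio`` times it.

        Skin is left unchanged: the optimization personalises the bulk
        tissues only.
        """
        return MaterialParams(
            adipose=replace(self.adipose, E=float(E_adipose)),
            fibroglandular=replace(
                self.fibroglandular, E=float(E_adipose) * float(stiffness_ratio)
            ),
            skin=self.skin,
        )

    def for_tissue(self, name: str) -> TissueParams:
        try:
            return {"adipose": self.adipose, "fibroglandular": self.fibroglandular,
                    "skin": self.skin}[name]
        except KeyError:
            raise KeyError(f"unknown tissue {name!r}") from None


def default_materials() -> MaterialParams:
    """The initial (pre-optimization) material table."""
    return MaterialParams()
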