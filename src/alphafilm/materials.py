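"""Layer materials and alpha stopping powers.

A :class:`Material` is an elemental mass-fraction mixture with a density.
Mass stopping powers for alpha particles come from the Bethe formula with
Bragg additivity over the elements; continuous-slowing-down (CSDA) ranges
follow by integrating the reciprocal linear stopping power.

The model, briefly:

    S(E) = K z_eff^2 (Z/A) / beta^2 * [ln(2 m_e c^2 beta^2 gamma^2 / I) - beta^2]

per element, in MeV cm^2/g, summed over elements weighted by mass fraction
(Bragg additivity). ``z_eff`` is the Barkas effective charge of the slowing
alpha, ``z_eff = 2 (1 - exp(-125 beta / 2^(2/3)))``; it matters below
~2 MeV, where a bare z = 2 overestimates the stopping power. Below
``E_CLAMP`` (0.5 MeV) the formula degrades and S is clamped to its value at
``E_CLAMP``; transport stops tracking at ``E_CUT`` (0.1 MeV) anyway, and the
residual range below that is sub-micrometre.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elements import ElementData, get_element

__all__ = [
    "Material",
    "StoppingTable",
    "build_material",
    "mass_stopping_power",
    "csda_range",
    "build_stopping_table",
    "build_range_table",
    "PRESETS",
    "WATER",
    "AIR",
    "POLYESTER",
    "EBT3_ACTIVE",
    "EBTXD_ACTIVE",
    "HDV2_ACTIVE",
    "E_MIN",
    "E_MAX",
    "E_CUT",
    "E_CLAMP",
]

# Supported alpha kinetic-energy window (MeV)
E_MIN = 0.1
E_MAX = 10.0
#: transport cutoff: below this the residual energy is deposited locally
E_CUT = 0.1
#: below this the Bethe formula is clamped to its value at E_CLAMP
E_CLAMP = 0.5

_M_ALPHA = 3727.379  # MeV/c^2
_M_E = 0.51099895  # MeV/c^2
_K = 0.307075  # 4 pi N_A r_e^2 m_e c^2, MeV cm^2 / mol
_FRACTION_TOL = 5e-3


class CompositionError(ValueError):
    """Mass fractions are invalid (outside [0,1] or do not sum to ~1)."""


@dataclass(frozen=True)
class Material:
    """An elemental mixture with a density.

    Parameters
    ----------
    name : str
        Label, e.g. ``"EBT3 active layer"``.
    density : float
        g/cm^3.
    fractions : dict[str, float]
        Mass fraction per element symbol; must sum to 1 within 0.5%.
    """

    name: str
    density: float
    fractions: dict[str, float]

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be > 0")
        if not self.fractions:
            raise CompositionError(f"{self.name}: empty composition")
        for sym, w in self.fractions.items():
            get_element(sym)  # raises UnknownElementError
            if not 0.0 <= w <= 1.0:
                raise CompositionError(f"{self.name}: fraction {sym}={w} outside [0,1]")
        total = sum(self.fractions.values())
        if abs(total - 1.0) > _FRACTION_TOL:
            raise CompositionError(
                f"{self.name}: mass fractions sum to {total:.4f}, expected 1 +- {_FRACTION_TOL}"
            )

    @property
    def elements(self) -> list[ElementData]:
        return [get_element(s) for s in self.fractions]

    def with_density(self, density: float, name: str | None = None) -> "Material":
        return Material(name or self.name, density, dict(self.fractions))


def build_material(name: str, fractions: dict[str, float], density: float) -> Material:
    """Validate and construct a :class:`Material` from mass fractions."""
    return Material(name=name, density=density, fractions=dict(fractions))


def _beta2_gamma2(E: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gamma = 1.0 + E / _M_ALPHA
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    return beta2, gamma * gamma


def _element_stopping(E: np.ndarray, elem: ElementData, effective_charge: bool) -> np.ndarray:
    """Bethe mass stopping power of one element, MeV cm^2/g, no clamping."""
    beta2, gamma2 = _beta2_gamma2(E)
    I_mev = elem.I * 1e-6
    arg = 2.0 * _M_E * beta2 * gamma2 / I_mev
    L = np.log(arg) - beta2
    if effective_charge:
        beta = np.sqrt(beta2)
        zeff = 2.0 * (1.0 - np.exp(-125.0 * beta / 2.0 ** (2.0 / 3.0)))
        z2 = zeff * zeff
    else:
        z2 = 4.0
    return _K * z2 * (elem.Z / elem.A) / beta2 * L


def mass_stopping_power(
    material: Material,
    E: float | np.ndarray,
    *,
    effective_charge: bool = True,
) -> float | np.ndarray:
    """Alpha mass stopping power of ``material`` at kinetic energy ``E`` (MeV).

    Returns MeV cm^2/g. Bragg additivity: the mixture value is the
    mass-fraction-weighted sum of the elemental values. Below ``E_CLAMP``
    the value is clamped to S(E_CLAMP).

    Raises
    ------
    ValueError
        If ``E`` is outside [E_MIN, E_MAX].
    """
    E_arr = np.asarray(E, dtype=float)
    if np.any(E_arr < E_MIN) or np.any(E_arr > E_MAX):
        raise ValueError(f"energy outside supported range [{E_MIN}, {E_MAX}] MeV")
    E_eff = np.maximum(E_arr, E_CLAMP)
    S = np.zeros_like(E_eff)
    for sym, w in material.fractions.items():
        S += w * _element_stopping(E_eff, get_element(sym), effective_charge)
    return float(S) if np.isscalar(E) or E_arr.ndim == 0 else S


@dataclass(frozen=True)
class StoppingTable:
    """Tabulated mass stopping power on an ascending energy grid."""

    material: Material
    energies: np.ndarray  # MeV, strictly ascending
    S: np.ndarray  # MeV cm^2/g

    def __post_init__(self) -> None:
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly ascending")
        if np.any(self.S <= 0):
            raise ValueError("stopping powers must be positive")

    def __call__(self, E: float | np.ndarray) -> float | np.ndarray:
        E_arr = np.asarray(E, dtype=float)
        lo, hi = self.energies[0], self.energies[-1]
        if np.any(E_arr < lo) or np.any(E_arr > hi):
            raise ValueError(f"energy outside table bounds [{lo}, {hi}] MeV")
        out = np.interp(E_arr, self.energies, self.S)
        return float(out) if E_arr.ndim == 0 else out

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame({"energy_MeV": self.energies, "S_MeV_cm2_g": self.S}).to_csv(
            path, index=False
        )


def build_stopping_table(
    material: Material,
    E_lo: float = E_MIN,
    E_hi: float = E_MAX,
    n: int = 2000,
    *,
    effective_charge: bool = True,
) -> StoppingTable:
    E = np.geomspace(E_lo, E_hi, n)
    S = mass_stopping_power(material, E, effective_charge=effective_charge)
    return StoppingTable(material=material, energies=E, S=np.asarray(S))


def csda_range(
    material: Material,
    E0: float,
    E_cut: float = E_CUT,
    *,
    effective_charge: bool = True,
    rtol: float = 1e-4,
    return_nodes: bool = False,
) -> float | tuple[float, int]:
    """CSDA range in micrometres: integral of dE / (rho * S(E)) from E_cut to E0.

    The quadrature grid is refined (doubled) until the result changes by
    less than ``rtol`` relative. With ``return_nodes`` also returns the
    number of quadrature nodes at convergence.
    """
    if E0 <= E_cut:
        raise ValueError(f"E0={E0} must exceed E_cut={E_cut}")
    rho = material.density

    def integral(n: int) -> float:
        E = np.geomspace(E_cut, E0, n)
        S = np.asarray(mass_stopping_power(material, E, effective_charge=effective_charge))
        return float(np.trapezoid(1.0 / (rho * S), E))

    n = 512
    prev = integral(n)
    for _ in range(12):
        n *= 2
        cur = integral(n)
        if abs(cur - prev) <= rtol * abs(cur):
            break
        prev = cur
    um = cur * 1e4  # cm -> um
    return (um, n) if return_nodes else um


def build_range_table(
    material: Material,
    E_cut: float = E_CUT,
    E_max: float = 6.0,
    n: int = 4000,
    *,
    effective_charge: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Residual-range table for transport: (E grid MeV, range um), both ascending.

    range(E) = integral from E_cut to E of dE'/(rho S); range(E_cut) = 0.
    Energy <-> residual range conversion is then monotone interpolation in
    either direction.
    """
    E = np.geomspace(E_cut, E_max, n)
    S = np.asarray(mass_stopping_power(material, E, effective_charge=effective_charge))
    integrand = 1.0 / (material.density * S)
    r = np.concatenate(
        ([0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(E)))
    )
    return E, r * 1e4


# ---------------------------------------------------------------------------
# Presets: unlaminated GafChromic active layers, polyester backing, air, water
# ---------------------------------------------------------------------------

EBT3_ACTIVE = build_material(
    "EBT3 active layer",
    {
        "H": 0.0865,
        "Li": 0.0063,
        "C": 0.5001,
        "N": 0.0064,
        "O": 0.3237,
        "Na": 0.0035,
        "Al": 0.0657,
        "S": 0.0024,
        "Cl": 0.0054,
    },
    density=1.15,
)

EBTXD_ACTIVE = build_material(
    "EBT-XD active layer",
    {
        "H": 0.0883,
        "Li": 0.0065,
        "C": 0.5298,
        "N": 0.0086,
        "O": 0.2900,
        "Na": 0.0036,
        "Al": 0.0627,
        "S": 0.0049,
        "Cl": 0.0055,
    },
    density=1.35,
)

HDV2_ACTIVE = build_material(
    "HD-V2 active layer",
    {"H": 0.1080, "Li": 0.0180, "C": 0.7900, "O": 0.0840},
    density=0.95,
)

POLYESTER = build_material(
    "polyester backing",
    {"H": 0.0420, "C": 0.6250, "O": 0.3330},
    density=1.35,
)

WATER = build_material("water", {"H": 0.1119, "O": 0.8881}, density=1.0)

AIR = build_material(
    "air",
    {"C": 0.000124, "N": 0.755267, "O": 0.231781, "Ar": 0.012827},
    density=1.20479e-3,
)

PRESETS: dict[str, Material] = {
    "EBT3": EBT3_ACTIVE,
    "EBT-XD": EBTXD_ACTIVE,
    "HD-V2": HDV2_ACTIVE,
    "polyester": POLYESTER,
    "water": WATER,
    "air": AIR,
}
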