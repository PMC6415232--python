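"""Closed-form physics of the one-dimensional bead-spring polyelectrolyte gel.

The model is a line of identical point charges (beads) joined by zero-rest-length
Hooke springs of constant ``a``.  Coulomb repulsion between beads stretches the
springs; the equilibrium spring length measures "swelling" of this
one-dimensional gel.  Two free-energy branches describe the electrostatics:

* ``g_dh`` — Debye–Hückel screened interactions, valid at low linear charge
  density (bead spacing ``b > z*lB``, no counterion condensation);
* ``g_cc`` — counterion-condensation theory, valid at high charge density
  (``b < z*lB``), where condensed counterions cap the net charge at one per
  ``z*lB`` of contour length and contribute translational entropy.

Units throughout: lengths in nm, spring constants in nm⁻², energies in kBT per
bead, molar salt concentrations converted internally to number densities in
nm⁻³.  All functions are pure and accept scalars or numpy arrays for ``b``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AVOGADRO",
    "BOLTZMANN",
    "ELEMENTARY_CHARGE",
    "VACUUM_PERMITTIVITY",
    "ChainParams",
    "CondensedLayer",
    "ModelDomainError",
    "SolventConditions",
    "ValidityWindowWarning",
    "bjerrum_length",
    "condensed_layer",
    "debye_kappa",
    "effective_spring_constant",
    "g_cc",
    "g_cc_db",
    "g_dh",
    "g_dh_db",
    "molar_to_number_density",
    "salt_1_1",
    "validity_window",
]

# CODATA 2018 exact values
ELEMENTARY_CHARGE = 1.602176634e-19  # C
BOLTZMANN = 1.380649e-23  # J/K
AVOGADRO = 6.02214076e23  # 1/mol
VACUUM_PERMITTIVITY = 8.8541878128e-12  # F/m

ROOM_TEMPERATURE_K = 298.15


class ModelDomainError(ValueError):
    """Raised when an argument lies outside the physical domain of a formula."""


class ValidityWindowWarning(UserWarning):
    """Emitted when lB/b leaves the window where the condensed-layer geometry
    is self-consistent (the condensed-layer radius must exceed lB)."""


def bjerrum_length(temperature: float, dielectric_constant: float) -> float:
    """Bjerrum length lB = e²/(4π ε0 ε kB T) in nm.

    The distance at which two unit charges in the solvent have Coulomb energy
    kBT; larger lB means a poorer solvent for ions.  About 0.71 nm for water
    and 1.7 nm for methanol at room temperature.
    """
    if temperature <= 0:
        raise ModelDomainError(f"temperature must be positive, got {temperature}")
    if dielectric_constant <= 0:
        raise ModelDomainError(
            f"dielectric constant must be positive, got {dielectric_constant}"
        )
    lb_m = ELEMENTARY_CHARGE**2 / (
        4.0
        * math.pi
        * VACUUM_PERMITTIVITY
        * dielectric_constant
        * BOLTZMANN
        * temperature
    )
    return lb_m * 1e9


def molar_to_number_density(molar: float) -> float:
    """Convert mol/L to number density in nm⁻³."""
    return molar * AVOGADRO * 1e-24


def salt_1_1(molar: float) -> tuple[tuple[float, int], ...]:
    """Both small-ion species of a fully dissociated 1:1 salt at ``molar`` mol/L."""
    return ((molar, 1), (molar, 1))


def debye_kappa(lB: float, salt_species) -> float:
    """Debye screening constant κ = sqrt(4π lB Σ ci zi²) in nm⁻¹.

    ``salt_species`` is an iterable of ``(concentration mol/L, unsigned
    valence)`` pairs, one entry per small-ion species (a 1:1 salt therefore
    contributes two entries).  An empty list gives κ = 0 (unscreened).

    Because κ is proportional to sqrt(lB), at fixed molarity κ must be
    recomputed whenever lB changes.
    """
    if lB <= 0:
        raise ModelDomainError(f"lB must be positive, got {lB}")
    total = 0.0
    for conc, valence in salt_species:
        if conc < 0:
            raise ModelDomainError(f"negative salt concentration {conc}")
        if valence < 1:
            raise ModelDomainError(f"valence must be >= 1, got {valence}")
        total += molar_to_number_density(conc) * valence**2
    return math.sqrt(4.0 * math.pi * lB * total)


def _log_one_minus_exp(b, kappa):
    """ln(1 − e^(−κb)), accurate for both small and large κb."""
    x = np.asarray(kappa) * np.asarray(b)
    one_minus = -np.expm1(-x)  # 1 - e^{-κb}
    if np.any(one_minus <= 0.0):
        raise ModelDomainError(
            "1 - exp(-kappa*b) underflowed to zero: the screened-Coulomb lattice "
            "sum diverges as kappa*b -> 0. Add salt (kappa > 0) or increase b."
        )
    return np.log(one_minus)


def _d_log_one_minus_exp(b, kappa):
    """d/db ln(1 − e^(−κb)) = κ / (e^(κb) − 1)."""
    x = np.asarray(kappa) * np.asarray(b)
    denom = np.expm1(x)
    if np.any(denom <= 0.0):
        raise ModelDomainError("kappa*b must be positive")
    return kappa / denom


def _check_b(b):
    if np.any(np.asarray(b) <= 0):
        raise ModelDomainError("bead spacing b must be positive")


def g_dh(b, a: float, lB: float, kappa: float):
    """Debye–Hückel free energy per bead, (1/2)a b² − (lB/b) ln(1 − e^(−κb)).

    In kBT per bead.  Physically valid for ``b > z*lB`` (no condensation);
    evaluates anywhere ``b > 0``.  The electrostatic part is non-negative.
    """
    _check_b(b)
    if lB <= 0:
        raise ModelDomainError("lB must be positive")
    return 0.5 * a * np.asarray(b) ** 2 - (lB / np.asarray(b)) * _log_one_minus_exp(
        b, kappa
    )


def g_dh_db(b, a: float, lB: float, kappa: float):
    """Analytic derivative ∂g_dh/∂b."""
    _check_b(b)
    b = np.asarray(b, dtype=float)
    L = _log_one_minus_exp(b, kappa)
    Lp = _d_log_one_minus_exp(b, kappa)
    return a * b + lB * L / b**2 - lB * Lp / b


def g_cc(b, a: float, z: int, lB: float, kappa: float):
    """Counterion-condensation free energy per bead, in kBT.

    g_cc = (1/2)a b² − (1/z)(2 − b/(z lB)) ln(1 − e^(−κb)) − 1/z + b/(z² lB)

    The last three terms are the nonlinear electrostatic contribution of
    condensation theory: charge renormalisation to one net charge per z·lB,
    plus the translational entropy of the condensed layer.  Physically valid
    for ``b < z*lB``; at the condensation threshold ``b = z*lB`` it matches
    ``g_dh`` exactly, so the two branches join continuously.
    """
    _check_b(b)
    if lB <= 0:
        raise ModelDomainError("lB must be positive")
    if z < 1:
        raise ModelDomainError("counterion valence z must be >= 1")
    b = np.asarray(b, dtype=float)
    L = _log_one_minus_exp(b, kappa)
    return (
        0.5 * a * b**2
        - (1.0 / z) * (2.0 - b / (z * lB)) * L
        - 1.0 / z
        + b / (z**2 * lB)
    )


def g_cc_db(b, a: float, z: int, lB: float, kappa: float):
    """Analytic derivative ∂g_cc/∂b."""
    _check_b(b)
    b = np.asarray(b, dtype=float)
    L = _log_one_minus_exp(b, kappa)
    Lp = _d_log_one_minus_exp(b, kappa)
    return (
        a * b
        + L / (z**2 * lB)
        - (1.0 / z) * (2.0 - b / (z * lB)) * Lp
        + 1.0 / (z**2 * lB)
    )


def effective_spring_constant(a0: float, t: float, lB: float, b: float) -> float:
    """Spring constant stiffened by locally active condensed counterions.

    a = a0 + (1/(8e)) t (lB/b), with e = Euler's number.  The count of
    condensed counterions close enough to a bead to resist its separation from
    its neighbour is (1/8e)(lB/b); each is assumed to add ``t`` (nm⁻²) to the
    spring constant.  This makes the elasticity nonlinear: contraction raises
    the charge density, condenses more counterions, and stiffens the spring
    further (a cascading feedback).

    Emits :class:`ValidityWindowWarning` when ``t > 0`` and lB/b is outside
    the self-consistency window of the condensed-layer geometry.
    """
    if b <= 0:
        raise ModelDomainError("bead spacing b must be positive")
    ratio = lB / b
    if t > 0:
        lo, hi = validity_window()
        if not (lo < ratio < hi):
            warnings.warn(
                f"lB/b = {ratio:.4g} outside condensed-layer validity window "
                f"({lo:.3g}, {hi:.3g})",
                ValidityWindowWarning,
                stacklevel=2,
            )
    return a0 + t * ratio / (8.0 * math.e)


@dataclass(frozen=True)
class CondensedLayer:
    """Geometry of the condensed-counterion layer around the chain.

    ``total_condensed_concentration`` is the local concentration of condensed
    counterions per bead, 1/(8πe lB b²) in nm⁻³; the subpopulation close
    enough to act on individual beads occupies a cylindrical volume π lB² b
    per bead, giving ``active_counterions_per_bead`` = (1/8e)(lB/b).  The full
    layer has cylindrical radius sqrt(8e[(lB/b) − 1] b²); self-consistency of
    the active-subpopulation construction requires this radius to exceed lB.
    """

    radius: float  # nm
    active_counterions_per_bead: float
    total_condensed_concentration: float  # nm^-3


def condensed_layer(lB: float, b: float) -> CondensedLayer:
    """Condensed-layer radius, concentration and active count (needs lB/b > 1)."""
    if b <= 0:
        raise ModelDomainError("bead spacing b must be positive")
    ratio = lB / b
    if ratio <= 1.0:
        raise ModelDomainError(
            f"lB/b = {ratio:.4g} <= 1: below the condensation threshold there "
            "is no condensed layer"
        )
    e = math.e
    total = 1.0 / (8.0 * math.pi * e * lB * b**2)
    active = ratio / (8.0 * e)
    radius = math.sqrt(8.0 * e * (ratio - 1.0)) * b
    return CondensedLayer(
        radius=radius,
        active_counterions_per_bead=active,
        total_condensed_concentration=total,
    )


def validity_window() -> tuple[float, float]:
    """Admissible lB/b range for the condensed-layer construction.

    Requiring the condensed-layer radius sqrt(8e[(lB/b) − 1]) b to exceed lB
    gives the quadratic x² − 8e x + 8e < 0 in x = lB/b; the window is between
    the two real roots 4e ± sqrt(16e² − 8e), about (1.05, 20.7).  Full-precision
    roots are returned.
    """
    e = math.e
    disc = math.sqrt(16.0 * e**2 - 8.0 * e)
    return (4.0 * e - disc, 4.0 * e + disc)


@dataclass(frozen=True)
class SolventConditions:
    """Solvent and salt environment: yields the Bjerrum length and κ.

    Exactly one of ``bjerrum_length_nm`` or ``dielectric_constant`` (with
    ``temperature``) must be given.  ``salt_species`` lists every small-ion
    species as ``(concentration mol/L, unsigned valence)``; use
    :func:`salt_1_1` for a symmetric monovalent salt.  The chain's own
    counterions are not part of the screening sum — only added salt screens.
    """

    temperature: float = ROOM_TEMPERATURE_K  # K
    dielectric_constant: float | None = None
    bjerrum_length_nm: float | None = None
    salt_species: tuple[tuple[float, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if (self.bjerrum_length_nm is None) == (self.dielectric_constant is None):
            raise ModelDomainError(
                "specify exactly one of bjerrum_length_nm or "
                "dielectric_constant (+ temperature)"
            )
        if self.bjerrum_length_nm is not None and self.bjerrum_length_nm <= 0:
            raise ModelDomainError("bjerrum_length_nm must be positive")
        if self.dielectric_constant is not None and self.dielectric_constant <= 0:
            raise ModelDomainError("dielectric_constant must be positive")
        if self.temperature <= 0:
            raise ModelDomainError("temperature must be positive")
        object.__setattr__(self, "salt_species", tuple(
            (float(c), int(z)) for c, z in self.salt_species
        ))
        for conc, valence in self.salt_species:
            if conc < 0:
                raise ModelDomainError(f"negative salt concentration {conc}")
            if valence < 1:
                raise ModelDomainError(f"valence must be >= 1, got {valence}")

    @property
    def lB(self) -> float:
        """Bjerrum length in nm."""
        if self.bjerrum_length_nm is not None:
            return self.bjerrum_length_nm
        return bjerrum_length(self.temperature, self.dielectric_constant)

    def kappa(self, lB: float | None = None) -> float:
        """κ in nm⁻¹ at the given lB (defaults to this solvent's own lB).

        At fixed molarity κ varies with lB, so sweeps over lB pass the swept
        value here rather than rebuilding the solvent.
        """
        return debye_kappa(self.lB if lB is None else lB, self.salt_species)

    def at_bjerrum(self, lB: float) -> "SolventConditions":
        """Copy of these conditions pinned at a different Bjerrum length."""
        return SolventConditions(
            temperature=self.temperature,
            bjerrum_length_nm=lB,
            salt_species=self.salt_species,
        )

    def describe_salt(self) -> str:
        if not self.salt_species:
            return "no added salt"
        return "+".join(f"{c:g}M:z{z}" for c, z in self.salt_species)


@dataclass(frozen=True)
class ChainParams:
    """Bead-spring chain parameters.

    ``z``: unsigned counterion valence; ``a0``: spring constant without
    condensed counterions (nm⁻²); ``t``: stiffening contribution per locally
    active condensed counterion (nm⁻², 0 disables stiffening).  The chain is
    taken as infinitely long (end effects neglected), so no bead count is
    stored.
    """

    z: int = 1
    a0: float = 0.1
    t: float = 0.0

    def __post_init__(self):
        if self.z < 1:
            raise ModelDomainError(f"z must be >= 1, got {self.z}")
        if self.a0 <= 0:
            raise ModelDomainError(f"a0 must be positive, got {self.a0}")
        if self.t < 0:
            raise ModelDomainError(f"t must be >= 0, got {self.t}")
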