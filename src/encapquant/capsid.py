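"""Caspar-Klug icosahedral lattice arithmetic for encapsulin shells.

An icosahedral protein shell built on a Caspar-Klug lattice with
triangulation number ``T = h**2 + h*k + k**2`` (h, k non-negative
integers) contains ``60*T`` subunits arranged as 12 pentameric
capsomers at the vertices and ``10*(T - 1)`` hexameric capsomers on
the faces and edges.  These closed forms, together with sphere-volume
arithmetic, give the assembly mass of a cargo-loaded compartment and
the iron-storage capacity implied by a measured mineral density and a
shell-limited core diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CapsidModel",
    "is_valid_t_number",
    "subunit_count",
    "capsomer_counts",
    "assembly_mass",
    "sphere_volume",
    "volume_ratio_percent",
    "max_iron_capacity",
]

# h,k search bound for the T-number validity check; T = h^2+hk+k^2 with
# h,k <= 50 covers every T up to 2500, far beyond any real capsid.
_HK_SEARCH_LIMIT = 50


def is_valid_t_number(t: int) -> bool:
    """Return True if ``t`` is a Caspar-Klug triangulation number.

    Valid numbers are exactly those expressible as ``h**2 + h*k + k**2``
    for non-negative integers h, k not both zero (1, 3, 4, 7, 9, 12,
    13, ...).  Numbers such as 2, 5 and 6 admit no such representation
    and do not correspond to a closed icosahedral lattice.
    """
    if not isinstance(t, (int,)) or isinstance(t, bool):
        return False
    if t < 1:
        return False
    limit = min(_HK_SEARCH_LIMIT, math.isqrt(t))
    for h in range(limit + 1):
        for k in range(h, limit + 1):
            if h == 0 and k == 0:
                continue
            if h * h + h * k + k * k == t:
                return True
    return False


def _require_valid_t(t: int) -> None:
    if not is_valid_t_number(t):
        raise ValueError(
            f"T={t!r} is not a valid triangulation number: the Caspar-Klug "
            "constraint requires T = h^2 + h*k + k^2 for non-negative "
            "integers h, k (valid: 1, 3, 4, 7, 9, 12, 13, ...)"
        )


def subunit_count(t: int) -> int:
    """Number of capsid subunits in a shell of triangulation number ``t``.

    Parameters
    ----------
    t : int
        Triangulation number; must satisfy the Caspar-Klug constraint.

    Returns
    -------
    int
        ``60 * t`` subunits.  T=1 gives 60, T=3 gives 180, T=4 gives 240.
    """
    _require_valid_t(t)
    return 60 * t


def capsomer_counts(t: int) -> tuple[int, int]:
    """Pentamer and hexamer counts for a shell of triangulation number ``t``.

    Every icosahedral lattice has exactly 12 pentamers (one per vertex)
    and ``10*(t - 1)`` hexamers, so that
    ``12*5 + 6*10*(t-1) == 60*t`` subunits.

    Returns
    -------
    (int, int)
        ``(pentamers, hexamers)``; for T=4 this is (12, 30).
    """
    _require_valid_t(t)
    return 12, 10 * (t - 1)


def assembly_mass(
    n_capsid: int,
    m_capsid_kda: float,
    n_cargo_dimers: int,
    m_cargo_monomer_kda: float,
) -> float:
    """Total mass in MDa of a shell plus its encapsulated cargo dimers.

    Each cargo dimer contributes two monomers, so the total is
    ``(n_capsid*m_capsid + 2*n_cargo_dimers*m_cargo_monomer) / 1000``.

    With 240 capsid subunits of 32.2 kDa and 42 cargo dimers of
    22.6-kDa monomers the fully loaded compartment weighs 9.6252 MDa
    (9.6 MDa at two significant figures).
    """
    if n_capsid < 0 or n_cargo_dimers < 0:
        raise ValueError("subunit and dimer counts must be non-negative")
    if m_capsid_kda <= 0 or m_cargo_monomer_kda <= 0:
        raise ValueError("monomer masses must be positive (kDa)")
    total_kda = n_capsid * m_capsid_kda + n_cargo_dimers * 2.0 * m_cargo_monomer_kda
    return total_kda / 1000.0


def sphere_volume(diameter_nm: float) -> float:
    """Volume in nm^3 of a sphere of the given diameter in nm."""
    if diameter_nm < 0:
        raise ValueError("diameter must be non-negative")
    return (math.pi / 6.0) * diameter_nm**3


def volume_ratio_percent(d_a_nm: float, d_b_nm: float) -> float:
    """Volume of sphere a as an unrounded percentage of sphere b.

    ``100 * (d_a/d_b)**3``.  For the 42-nm T=4 shell against the 24-nm
    T=1 and 32-nm T=3 shells this gives 535.9% and 226.3%.
    """
    if d_a_nm <= 0 or d_b_nm <= 0:
        raise ValueError("diameters must be positive")
    return 100.0 * (d_a_nm / d_b_nm) ** 3


def max_iron_capacity(
    core_diameter_nm: float,
    density_per_nm3: float,
    rounding: int = 1,
) -> int:
    """Iron atoms storable in a spherical core at a volumetric density.

    ``round(sphere_volume(d) * rho)`` rounded to the nearest
    ``rounding`` atoms.  A 36-nm shell-limited core at the highest
    observed mineral density of 3.40 Fe/nm^3 holds ~83,000 atoms
    (nearest thousand).

    Parameters
    ----------
    core_diameter_nm : float
        Mineral core diameter, nm.
    density_per_nm3 : float
        Volumetric iron density, atoms/nm^3.
    rounding : int
        Granularity of the returned count, e.g. 1000 for
        nearest-thousand reporting.
    """
    if core_diameter_nm < 0 or density_per_nm3 < 0:
        raise ValueError("diameter and density must be non-negative")
    if rounding < 1:
        raise ValueError("rounding granularity must be a positive integer")
    atoms = sphere_volume(core_diameter_nm) * density_per_nm3
    return int(round(atoms / rounding)) * rounding


@dataclass(frozen=True)
class CapsidModel:
    """Geometry and composition of one encapsulin compartment.

    Defaults describe the T=4 iron-mineralizing compartment: a 42-nm
    outer shell limiting the mineral core to 36 nm, 32.2-kDa capsid
    monomers and 42 encapsulated 22.6-kDa-monomer cargo dimers.
    """

    T: int = 4
    outer_diameter_nm: float = 42.0
    max_core_diameter_nm: float = 36.0
    capsid_monomer_kda: float = 32.2
    cargo_monomer_kda: float = 22.6
    n_cargo_dimers: int = 42

    def __post_init__(self) -> None:
        _require_valid_t(self.T)
        if self.outer_diameter_nm <= 0 or self.max_core_diameter_nm <= 0:
            raise ValueError("diameters must be positive")
        if self.max_core_diameter_nm > self.outer_diameter_nm:
            raise ValueError("max core diameter cannot exceed the outer diameter")
        if self.capsid_monomer_kda <= 0 or self.cargo_monomer_kda <= 0:
            raise ValueError("monomer masses must be positive")
        if self.n_cargo_dimers < 0:
            raise ValueError("cargo dimer count must be non-negative")

    @property
    def n_subunits(self) -> int:
        return subunit_count(self.T)

    @property
    def n_pentamers(self) -> int:
        return capsomer_counts(self.T)[0]

    @property
    def n_hexamers(self) -> int:
        return capsomer_counts(self.T)[1]

    @property
    def assembly_mass_mda(self) -> float:
        return assembly_mass(
            self.n_subunits,
            self.capsid_monomer_kda,
            self.n_cargo_dimers,
            self.cargo_monomer_kda,
        )

    @property
    def max_core_volume_nm3(self) -> float:
        return sphere_volume(self.max_core_diameter_nm)

    def iron_capacity(self, density_per_nm3: float, rounding: int = 1000) -> int:
        """Extrapolated capacity at ``density_per_nm3`` for the shell-limited core."""
        return max_iron_capacity(self.max_core_diameter_nm, density_per_nm3, rounding)

    def summary(self, density_per_nm3: float | None = None) -> dict:
        out = {
            "T": self.T,
            "subunits": self.n_subunits,
            "pentamers": self.n_pentamers,
            "hexamers": self.n_hexamers,
            "assembly_mass_MDa": self.assembly_mass_mda,
            "outer_diameter_nm": self.outer_diameter_nm,
            "max_core_diameter_nm": self.max_core_diameter_nm,
            "max_core_volume_nm3": self.max_core_volume_nm3,
        }
        if density_per_nm3 is not None:
            out["iron_capacity_atoms"] = self.iron_capacity(density_per_nm3)
        return out
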