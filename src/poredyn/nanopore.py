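"""Anodic-aluminum-oxide (AAO) wafer and pore-loading arithmetic.

Porosity, surface areas, molecule capacity, loading-to-concentration
conversion, pore fill fraction, and mean tether spacing for peptides
covalently attached to cylindrical nanopore walls.  Lengths are SI
internally; the public dataclasses take the units stated in their
docstrings (the ones the vendor and the balance report).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .constants import AVOGADRO

__all__ = [
    "WaferSpec",
    "LoadingReport",
    "AAO20",
    "porosity_from_density",
    "porosity_from_mass",
    "wafer_volume_ul",
    "internal_surface_area_mm2",
    "exterior_surface_area_mm2",
    "molecule_capacity_umol",
    "pore_concentration",
    "fill_fraction",
    "tether_spacing",
]

WATER_DENSITY_G_PER_ML = 0.9982  # at lab temperature


@dataclass(frozen=True)
class WaferSpec:
    """Geometry of a nanoporous wafer.

    diameter_mm, thickness_um, pore_diameter_nm as named;
    pore_density_per_um2 is the areal pore density; porosity may be given
    directly (e.g. a gravimetric value) or derived from the density.
    """

    diameter_mm: float = 13.0
    thickness_um: float = 50.0
    pore_diameter_nm: float = 20.0
    pore_density_per_um2: Optional[float] = 467.0
    porosity: Optional[float] = None

    def __post_init__(self):
        if min(self.diameter_mm, self.thickness_um, self.pore_diameter_nm) <= 0:
            raise ValueError("wafer dimensions must be positive")
        if self.pore_density_per_um2 is None and self.porosity is None:
            raise ValueError("need pore density or porosity")
        if self.pore_density_per_um2 is not None and self.porosity is not None:
            derived = porosity_from_density(self.pore_density_per_um2,
                                            self.pore_diameter_nm)
            if abs(derived - self.porosity) > 1e-6:
                raise ValueError(
                    f"supplied porosity {self.porosity} inconsistent with pore "
                    f"density (implies {derived:.6f})")

    @property
    def effective_porosity(self) -> float:
        if self.porosity is not None:
            return self.porosity
        return porosity_from_density(self.pore_density_per_um2,
                                     self.pore_diameter_nm)


#: the study's wafer: 13 mm x 50 um, 20 nm pores, 467 pores/um^2
AAO20 = WaferSpec()


def porosity_from_density(pore_density_per_um2: float,
                          pore_diameter_nm: float) -> float:
    """Pore volume fraction implied by areal pore density and pore diameter."""
    if pore_density_per_um2 < 0 or pore_diameter_nm <= 0:
        raise ValueError("density must be non-negative and diameter positive")
    r_um = pore_diameter_nm * 1e-3 / 2.0
    phi = pore_density_per_um2 * math.pi * r_um**2
    if phi > 1.0:
        raise ValueError(f"unphysical porosity {phi:.3f} > 1")
    return phi


def wafer_volume_ul(spec: WaferSpec) -> float:
    """Geometric wafer volume pi (D/2)^2 t, in microliters."""
    r_mm = spec.diameter_mm / 2.0
    vol_mm3 = math.pi * r_mm**2 * spec.thickness_um * 1e-3
    return vol_mm3  # 1 mm^3 = 1 ul


def porosity_from_mass(dry_mass_mg: float, wet_mass_mg: float,
                       spec: WaferSpec,
                       water_density_g_per_ml: float = WATER_DENSITY_G_PER_ML) -> float:
    """Gravimetric porosity: water mass gained on soaking / wafer volume."""
    if wet_mass_mg < dry_mass_mg:
        raise ValueError("wet mass must be >= dry mass")
    water_ul = (wet_mass_mg - dry_mass_mg) / water_density_g_per_ml
    phi = water_ul / wafer_volume_ul(spec)
    if phi > 1.0:
        raise ValueError(f"unphysical porosity {phi:.3f} > 1")
    return phi


def _n_pores(spec: WaferSpec) -> float:
    if spec.pore_density_per_um2 is None:
        raise ValueError("pore density required")
    face_um2 = math.pi * (spec.diameter_mm * 1e3 / 2.0) ** 2
    return spec.pore_density_per_um2 * face_um2


def internal_surface_area_mm2(spec: WaferSpec) -> float:
    """Total pore-wall area per wafer (smooth cylindrical walls), mm^2."""
    wall_um2 = math.pi * spec.pore_diameter_nm * 1e-3 * spec.thickness_um
    return _n_pores(spec) * wall_um2 * 1e-6


def exterior_surface_area_mm2(spec: WaferSpec) -> float:
    """Exterior wafer area: flat faces minus pore openings, plus the rim, mm^2."""
    phi = spec.effective_porosity
    r_mm = spec.diameter_mm / 2.0
    faces = 2.0 * math.pi * r_mm**2 * (1.0 - phi)
    rim = math.pi * spec.diameter_mm * spec.thickness_um * 1e-3
    return faces + rim


def molecule_capacity_umol(area_mm2: float, spacing_nm: float = 1.0) -> float:
    """Amount of molecules a surface can hold at a given average spacing."""
    if area_mm2 < 0 or spacing_nm <= 0:
        raise ValueError("area must be non-negative and spacing positive")
    n = area_mm2 * 1e12 / spacing_nm**2  # nm^2 per mm^2 = 1e12
    return n / AVOGADRO * 1e6


def pore_concentration(amount_umol: float, n_wafers: int, spec: WaferSpec,
                       mw_da: Optional[float] = None):
    """Average concentration of loaded molecules inside the pore volume.

    Returns molar concentration in mM and, if a molecular weight (Da) is
    given, the mass concentration in mg/ml.
    """
    if amount_umol < 0 or n_wafers <= 0:
        raise ValueError("amount must be >= 0 and wafer count positive")
    pore_vol_ul = n_wafers * spec.effective_porosity * wafer_volume_ul(spec)
    molar_mm = amount_umol / pore_vol_ul * 1e3  # umol/ul = M; -> mM
    if mw_da is None:
        return molar_mm, None
    mg_per_ml = molar_mm * 1e-3 * mw_da
    return molar_mm, mg_per_ml


def fill_fraction(mass_conc_mg_per_ml: float,
                  peptide_density_g_per_ml: float = 1.4) -> float:
    """Fraction of pore volume occupied by peptide at the given density."""
    if peptide_density_g_per_ml <= 0:
        raise ValueError("peptide density must be positive")
    if mass_conc_mg_per_ml < 0:
        raise ValueError("mass concentration must be non-negative")
    f = mass_conc_mg_per_ml / (peptide_density_g_per_ml * 1e3)
    if f > 1.0:
        raise ValueError(f"unphysical fill fraction {f:.3f} > 1")
    return f


def tether_spacing(molar_mm: float, pore_diameter_nm: float,
                   convention: str = "square-lattice"):
    """Surface density and mean spacing of wall-tethered molecules.

    Projecting all molecules in a cylindrical pore of radius r onto its wall
    gives a surface density sigma = C N_A r / 2.  The mean nearest-neighbor
    spacing is 1/sqrt(sigma) on a square lattice (default) or
    0.5/sqrt(sigma) for a 2-D Poisson point process.

    Returns ``(sigma_per_nm2, spacing_nm)``.
    """
    if molar_mm <= 0 or pore_diameter_nm <= 0:
        raise ValueError("concentration and pore diameter must be positive")
    c_per_nm3 = molar_mm * 1e-3 * 1e3 * AVOGADRO * 1e-27  # mM -> molecules/nm^3
    r_nm = pore_diameter_nm / 2.0
    sigma = c_per_nm3 * r_nm / 2.0
    if convention == "square-lattice":
        spacing = 1.0 / math.sqrt(sigma)
    elif convention == "poisson":
        spacing = 0.5 / math.sqrt(sigma)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return sigma, spacing


@dataclass(frozen=True)
class LoadingReport:
    """Summary of a loading measurement for one sample."""

    amount_umol: float
    n_wafers: int
    loading_nmol_per_mg: Optional[float]
    molar_mm: float
    mass_mg_per_ml: Optional[float]
    fill_fraction: Optional[float]
    sigma_per_nm2: float
    spacing_nm: float

    @classmethod
    def from_loading(cls, amount_umol: float, n_wafers: int, spec: WaferSpec,
                     mw_da: Optional[float] = None,
                     wafer_mass_mg: Optional[float] = None,
                     peptide_density_g_per_ml: float = 1.4) -> "LoadingReport":
        molar, mass = pore_concentration(amount_umol, n_wafers, spec, mw_da)
        sigma, spacing = tether_spacing(molar, spec.pore_diameter_nm)
        fill = None if mass is None else fill_fraction(mass, peptide_density_g_per_ml)
        loading = None
        if wafer_mass_mg:
            loading = amount_umol * 1e3 / (n_wafers * wafer_mass_mg)
        return cls(amount_umol, n_wafers, loading, molar, mass, fill, sigma, spacing)
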