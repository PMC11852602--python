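"""CT-number to bone-material mapping.

Apparent density is linear in the Hounsfield number between model-wide
bounds; Young's modulus follows the cubic power law E = 3790 * rho^3
(MPa, rho in g/cm^3); porosity and density are linked by
rho = (1 - P) * rho0.  Densities are optionally quantized to a fixed
number of material levels before the first FE solve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .mesh import MeshModel, REGION_IMPLANT

log = logging.getLogger(__name__)

MODULUS_COEFF_MPA = 3790.0  # E = 3790 * rho^3 with rho in g/cm^3

CLASS_CORTICAL = 0
CLASS_CANCELLOUS = 1


class MaterialError(ValueError):
    pass


@dataclass
class MaterialMapping:
    """Configuration of the CT-to-material chain.

    rho_a/rho_b are the densities assigned to hu_min/hu_max; rho_0 is the
    fully mineralized (zero-porosity) density.  The material gradient
    quantizes densities to ``n_bins`` levels at initialization.
    """

    rho_a: float = 0.1           # g/cm^3 at hu_min
    rho_b: float = 1.8           # g/cm^3 at hu_max
    rho_0: float = 1.8           # zero-porosity density, g/cm^3
    hu_min: float = 0.0
    hu_max: float = 1700.0
    nu: float = 0.3
    n_bins: int = 50
    cortical_threshold: float = 1.3   # g/cm^3
    implant_E: float = 110_000.0      # MPa, titanium-alloy class
    implant_nu: float = 0.3
    porosity_bounds: tuple[float, float] = (0.01, 0.99)

    def __post_init__(self) -> None:
        if not (self.rho_a < self.rho_b <= self.rho_0):
            raise MaterialError("need rho_a < rho_b <= rho_0")
        if self.hu_max <= self.hu_min:
            raise MaterialError("degenerate HU mapping (hu_max <= hu_min)")
        if not (0.0 < self.nu < 0.5):
            raise MaterialError("Poisson ratio out of (0, 0.5)")
        if self.n_bins < 1:
            raise MaterialError("n_bins must be >= 1")
        if not (self.rho_a < self.cortical_threshold < self.rho_b):
            raise MaterialError("cortical threshold outside (rho_a, rho_b)")


def hu_to_density(hu: np.ndarray, mapping: MaterialMapping) -> np.ndarray:
    """Linear HU -> apparent density (g/cm^3); out-of-range HU is clamped."""
    hu = np.asarray(hu, dtype=float)
    finite = np.isfinite(hu)
    n_out = int(np.sum((hu[finite] < mapping.hu_min) | (hu[finite] > mapping.hu_max)))
    if n_out:
        log.info("hu_to_density: clamped %d out-of-range HU values", n_out)
    hu_c = np.clip(hu, mapping.hu_min, mapping.hu_max)
    frac = (hu_c - mapping.hu_min) / (mapping.hu_max - mapping.hu_min)
    return mapping.rho_a + (mapping.rho_b - mapping.rho_a) * frac


def density_to_modulus(rho: np.ndarray) -> np.ndarray:
    """Cubic density-modulus power law, MPa."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho[np.isfinite(rho)] < 0):
        raise MaterialError("negative density")
    return MODULUS_COEFF_MPA * rho ** 3


def density_to_porosity(rho: np.ndarray, rho_0: float) -> np.ndarray:
    """P = 1 - rho/rho0."""
    rho = np.asarray(rho, dtype=float)
    if np.any(rho[np.isfinite(rho)] > rho_0 * (1 + 1e-12)):
        raise MaterialError("density above the zero-porosity density")
    return 1.0 - rho / rho_0


def porosity_to_density(porosity: np.ndarray, rho_0: float) -> np.ndarray:
    """rho = (1 - P) * rho0."""
    return (1.0 - np.asarray(porosity, dtype=float)) * rho_0


def bin_materials(rho: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantize densities to ``n_bins`` equal-width bin midpoints.

    Idempotent: re-binning a binned field returns it unchanged.
    NaN entries (implant) pass through.
    """
    if n_bins < 1:
        raise MaterialError("n_bins must be >= 1")
    rho = np.asarray(rho, dtype=float)
    finite = np.isfinite(rho)
    lo, hi = rho[finite].min(), rho[finite].max()
    # already quantized to at most n_bins levels: idempotent
    if hi == lo or len(np.unique(rho[finite])) <= n_bins:
        return rho.copy()
    width = (hi - lo) / n_bins
    idx = np.clip(((rho[finite] - lo) / width).astype(int), 0, n_bins - 1)
    out = rho.copy()
    out[finite] = lo + (idx + 0.5) * width
    return out


def classify_bone(rho: np.ndarray, threshold: float) -> np.ndarray:
    """CLASS_CORTICAL where rho >= threshold, else CLASS_CANCELLOUS."""
    rho = np.asarray(rho, dtype=float)
    return np.where(rho >= threshold, CLASS_CORTICAL, CLASS_CANCELLOUS)


@dataclass
class ElementMaterialField:
    """Per-element material state coupled through rho=(1-P)rho0, E=3790 rho^3."""

    hu: np.ndarray
    density: np.ndarray          # g/cm^3, NaN on implant elements
    porosity: np.ndarray
    modulus: np.ndarray          # MPa, implant modulus on implant elements
    bone_class: np.ndarray       # CLASS_CORTICAL / CLASS_CANCELLOUS, -1 implant
    is_implant: np.ndarray
    mapping: MaterialMapping = field(repr=False, default_factory=MaterialMapping)

    @property
    def is_bone(self) -> np.ndarray:
        return ~self.is_implant

    def set_porosity(self, porosity: np.ndarray) -> None:
        """Update the coupled (P, rho, E) state on bone elements."""
        lo, hi = self.mapping.porosity_bounds
        p = np.clip(porosity, lo, hi)
        bone = self.is_bone
        self.porosity[bone] = p[bone]
        self.density[bone] = porosity_to_density(p[bone], self.mapping.rho_0)
        self.modulus[bone] = density_to_modulus(self.density[bone])


def build_material_field(mesh: MeshModel, hu: np.ndarray,
                         mapping: MaterialMapping | None = None,
                         bin_densities: bool = True) -> ElementMaterialField:
    """Run the full chain HU -> density -> (binning) -> porosity/modulus/class.

    Binning is applied once here, at initialization, and never re-applied
    during remodeling.
    """
    if mapping is None:
        mapping = MaterialMapping()
    is_implant = mesh.element_region == REGION_IMPLANT
    rho = hu_to_density(hu, mapping)
    rho[is_implant] = np.nan
    if bin_densities and mapping.n_bins > 1:
        rho = bin_materials(rho, mapping.n_bins)
    lo, hi = mapping.porosity_bounds
    rho_lo = porosity_to_density(hi, mapping.rho_0)
    rho_hi = porosity_to_density(lo, mapping.rho_0)
    with np.errstate(invalid="ignore"):
        rho = np.clip(rho, rho_lo, rho_hi)
    porosity = density_to_porosity(rho, mapping.rho_0)
    modulus = density_to_modulus(np.nan_to_num(rho))
    modulus[is_implant] = mapping.implant_E
    bone_class = classify_bone(rho, mapping.cortical_threshold)
    bone_class[is_implant] = -1
    return ElementMaterialField(
        hu=np.asarray(hu, dtype=float), density=rho, porosity=porosity,
        modulus=modulus, bone_class=bone_class, is_implant=is_implant,
        mapping=mapping,
    )
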