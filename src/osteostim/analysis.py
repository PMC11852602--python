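"""Stress-shielding analysis and scenario orchestration.

The shielding ratio of a bone element is its post-implantation von Mises
stress divided by the stress of the matching element in the intact femur
under the same load case; ratios below one mark shielded tissue.  Element
correspondence between the two meshes is nearest-centroid with a distance
cap.  ``build_study`` wires the full pipeline (fixtures, materials, static
solves, matching, equilibrium stimulus, electrostatics) used by the CLI
and by the remodeling scenario grid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .mesh import MeshModel
from .fixtures import FemurFixtureParams, generate_proximal_femur, synthetic_hu_field
from .materials import MaterialMapping, ElementMaterialField, build_material_field
from .elasticity import LoadCase, StressState, assemble_and_solve, default_load_cases
from .electrostatics import (
    DielectricParams, StimulationProtocol, solve_electrostatics, normalize_potential,
)
from .remodeling import (
    RemodelingParams, RemodelingEngine, FEStimulus, Trajectory, equilibrium_stimulus,
)

RATIO_BIN_WIDTH = 0.1
RATIO_MAX_EDGE = 2.0


class AnalysisError(ValueError):
    pass


# ---------------------------------------------------------------- matching
def match_elements(source: MeshModel, target: MeshModel,
                   cap_fraction: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-centroid matching of target bone elements onto source bone
    elements, with the match rejected beyond ``cap_fraction`` of the local
    element size (cube root of the target element volume).

    Returns (target_indices, source_indices) of accepted pairs.
    """
    src_bone = np.nonzero(source.element_region == 0)[0]
    tgt_bone = np.nonzero(target.element_region == 0)[0]
    if len(src_bone) == 0 or len(tgt_bone) == 0:
        raise AnalysisError("no bone elements to match")
    tree = cKDTree(source.centroids()[src_bone])
    c_t = target.centroids()[tgt_bone]
    dist, nearest = tree.query(c_t)
    size = np.cbrt(np.abs(target.volumes()[tgt_bone]) * 6.0)  # cell-scale length
    ok = dist <= cap_fraction * size
    return tgt_bone[ok], src_bone[nearest[ok]]


# ---------------------------------------------------------------- shielding
def _ratio_histogram(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Counts over (lo, hi] bins of width 0.1 on [0, 2] plus an overflow bin.

    Values on an interior edge go to the lower bin (so r = 1 counts as
    shielded); r = 0 lands in the first bin.
    """
    edges = np.round(np.arange(0.0, RATIO_MAX_EDGE + RATIO_BIN_WIDTH / 2,
                               RATIO_BIN_WIDTH), 10)
    idx = np.searchsorted(edges, r, side="left") - 1
    idx = np.clip(idx, 0, len(edges) - 1)          # r=0 -> bin 0, r>2 -> overflow
    counts = np.bincount(idx, minlength=len(edges))
    return counts, edges


@dataclass
class ShieldingReport:
    """Per-load-case stress-ratio statistics on matched bone elements."""

    load_case: str
    ratios: np.ndarray = field(repr=False)
    element_indices: np.ndarray = field(repr=False)   # on the implanted mesh
    n_excluded: int                                    # intact stress below floor
    bin_edges: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)
    fraction_shielded: float                           # r in [0, 1]
    sub_histogram: np.ndarray = field(repr=False)      # width-0.1 bins of [0, 1]
    region_means: dict[str, float] = field(default_factory=dict)
    region_fraction_shielded: dict[str, float] = field(default_factory=dict)

    @property
    def fractions(self) -> np.ndarray:
        return self.counts / self.counts.sum()


def stress_ratio_report(
    intact: StressState,
    implanted: StressState,
    matching: tuple[np.ndarray, np.ndarray],
    regions: dict[str, np.ndarray] | None = None,
    denominator_floor: float = 1e-6,
) -> ShieldingReport:
    """Element-wise ratio r = sigma_implanted / sigma_intact with histogram.

    Elements whose intact stress is below ``denominator_floor`` (MPa) are
    excluded from the statistics and counted separately.
    """
    tgt_idx, src_idx = matching
    if len(tgt_idx) == 0:
        raise AnalysisError("zero matched elements")
    denom = intact.von_mises[src_idx]
    keep = denom >= denominator_floor
    r = implanted.von_mises[tgt_idx[keep]] / denom[keep]
    elem = tgt_idx[keep]
    counts, edges = _ratio_histogram(r)
    shielded = r <= 1.0
    sub_counts, _ = _ratio_histogram(np.clip(r[shielded], 0.0, 1.0))
    report = ShieldingReport(
        load_case=implanted.load_case, ratios=r, element_indices=elem,
        n_excluded=int(np.sum(~keep)), bin_edges=edges, counts=counts,
        fraction_shielded=float(np.mean(shielded)),
        sub_histogram=sub_counts[:10],
    )
    for name, mask in (regions or {}).items():
        in_region = np.asarray(mask, dtype=bool)[elem]
        if in_region.any():
            report.region_means[name] = float(r[in_region].mean())
            report.region_fraction_shielded[name] = float(
                np.mean(r[in_region] <= 1.0))
    return report


# ---------------------------------------------------------------- density
@dataclass
class DensityDifference:
    delta: np.ndarray = field(repr=False)      # rho_a - rho_b per element
    max_abs: float
    max_loss: float                            # most negative (a below b)
    region_means: dict[str, float]
    neck_section_means: dict[str, float]


def density_difference(
    mesh: MeshModel,
    density_a: np.ndarray,
    density_b: np.ndarray,
    regions: dict[str, np.ndarray] | None = None,
    section_fractions: tuple[float, ...] = (0.25, 0.5, 0.75),
) -> DensityDifference:
    """Per-element density difference between two runs on the same mesh.

    Three cross-sections through the femoral neck (slabs normal to the neck
    axis at the given axial fractions) are summarized separately when the
    mesh is a femur fixture.
    """
    a = np.asarray(density_a, dtype=float)
    b = np.asarray(density_b, dtype=float)
    if a.shape != b.shape or len(a) != mesh.n_elements:
        raise AnalysisError("density fields do not match the mesh")
    delta = a - b
    bone = mesh.element_region == 0
    region_means = {
        name: float(delta[np.asarray(mask, dtype=bool) & bone].mean())
        for name, mask in (regions or {}).items()
        if (np.asarray(mask, dtype=bool) & bone).any()
    }
    sections = {}
    if mesh.metadata.get("fixture") == "femur":
        params = FemurFixtureParams(**mesh.metadata["params"])
        h = mesh.metadata.get("h", 2.0)
        t, _ = params.neck_coords(mesh.centroids())
        for frac in section_fractions:
            t0 = frac * params.neck_length
            slab = bone & (np.abs(t - t0) <= h / 2)
            if slab.any():
                sections[f"neck_section_{frac:g}"] = float(delta[slab].mean())
    finite = np.isfinite(delta) & bone
    return DensityDifference(
        delta=delta,
        max_abs=float(np.nanmax(np.abs(delta[finite]))),
        max_loss=float(np.nanmin(delta[finite])),
        region_means=region_means,
        neck_section_means=sections,
    )


# ---------------------------------------------------------------- study
def femur_regions(mesh: MeshModel) -> dict[str, np.ndarray]:
    """Boolean element masks for the neck and shaft of a femur fixture."""
    if mesh.metadata.get("fixture") != "femur":
        raise AnalysisError("mesh is not a femur fixture")
    params = FemurFixtureParams(**mesh.metadata["params"])
    cent = mesh.centroids()
    t, radial = params.neck_coords(cent)
    head = np.linalg.norm(cent - params.head_center, axis=1) <= params.head_radius
    neck = (t >= 0) & (t <= params.neck_length) & (radial <= params.neck_radius) & ~head
    shaft = params.in_shaft(cent) & ~neck
    return {"neck": neck, "shaft": shaft}


@dataclass
class StudySetup:
    """Everything needed to run and analyze remodeling on one femur pair."""

    intact_mesh: MeshModel
    implanted_mesh: MeshModel
    intact_materials: ElementMaterialField
    implanted_materials: ElementMaterialField
    load_cases_intact: list[LoadCase]
    load_cases_implanted: list[LoadCase]
    intact_stress: list[StressState]
    implanted_stress: list[StressState]
    matching: tuple[np.ndarray, np.ndarray]
    phi0: np.ndarray                 # equilibrium stimulus on the implanted mesh
    phi_hat: np.ndarray              # normalized potential on the implanted mesh
    regions: dict[str, np.ndarray]   # masks on the implanted mesh
    material_mapping: MaterialMapping

    def shielding_reports(self) -> list[ShieldingReport]:
        return [
            stress_ratio_report(si, sp, self.matching, self.regions)
            for si, sp in zip(self.intact_stress, self.implanted_stress)
        ]


def build_study(
    femur_params: FemurFixtureParams | None = None,
    mapping: MaterialMapping | None = None,
    remodeling_params: RemodelingParams | None = None,
    dielectric: DielectricParams | None = None,
    hu_noise_sd: float = 0.0,
    seed: int = 0,
) -> StudySetup:
    """Build the intact/implanted pair and run the static + electrostatic
    analyses that every remodeling scenario shares."""
    femur_params = femur_params or FemurFixtureParams()
    mapping = mapping or MaterialMapping()
    remodeling_params = remodeling_params or RemodelingParams()
    intact_params = replace(femur_params, implanted=False, seed=seed)
    implanted_params = replace(femur_params, implanted=True, seed=seed)

    intact = generate_proximal_femur(intact_params)
    implanted = generate_proximal_femur(implanted_params)
    hu_i = synthetic_hu_field(intact, hu_max_levels(mapping)[0],
                              hu_max_levels(mapping)[1], hu_max_levels(mapping)[2],
                              noise_sd=hu_noise_sd, seed=seed)
    hu_p = synthetic_hu_field(implanted, hu_max_levels(mapping)[0],
                              hu_max_levels(mapping)[1], hu_max_levels(mapping)[2],
                              noise_sd=hu_noise_sd, seed=seed)
    mats_i = build_material_field(intact, hu_i, mapping)
    mats_p = build_material_field(implanted, hu_p, mapping)

    lc_i = default_load_cases(joint_patch="head_surface")
    lc_p = default_load_cases(joint_patch="stem_head")
    stress_i = [assemble_and_solve(intact, mats_i, lc) for lc in lc_i]
    stress_p = [assemble_and_solve(implanted, mats_p, lc) for lc in lc_p]

    matching = match_elements(intact, implanted)
    cycles = np.array([lc.cycles for lc in lc_i], dtype=float)
    vm_intact = np.stack([s.von_mises for s in stress_i])
    phi0_intact = equilibrium_stimulus(vm_intact, cycles, remodeling_params.m,
                                       remodeling_params.phi0_floor)
    phi0 = np.full(implanted.n_elements, np.nan)
    tgt, src = matching
    phi0[tgt] = phi0_intact[src]
    unmatched = (implanted.element_region == 0) & ~np.isfinite(phi0)
    # unmatched bone elements fall back to their own implanted-model stimulus
    if unmatched.any():
        vm_p = np.stack([s.von_mises for s in stress_p])
        phi0[unmatched] = equilibrium_stimulus(
            vm_p[:, unmatched], cycles, remodeling_params.m,
            remodeling_params.phi0_floor)

    phi = solve_electrostatics(implanted, dielectric or DielectricParams())
    phi_hat = normalize_potential(implanted, phi)

    return StudySetup(
        intact_mesh=intact, implanted_mesh=implanted,
        intact_materials=mats_i, implanted_materials=mats_p,
        load_cases_intact=lc_i, load_cases_implanted=lc_p,
        intact_stress=stress_i, implanted_stress=stress_p,
        matching=matching, phi0=phi0, phi_hat=phi_hat,
        regions=femur_regions(implanted), material_mapping=mapping,
    )


def hu_max_levels(mapping: MaterialMapping) -> tuple[float, float, float]:
    """Default cortical/cancellous/marrow HU plateaus inside the mapping range."""
    span = mapping.hu_max - mapping.hu_min
    return (mapping.hu_max, mapping.hu_min + 0.5 * span, mapping.hu_min + 0.03 * span)


def run_remodeling(
    setup: StudySetup,
    params: RemodelingParams | None = None,
    protocol: StimulationProtocol | None = None,
    total_days: int | None = None,
    snapshot_days: tuple[int, ...] = (),
) -> Trajectory:
    """Run the disuse-remodeling loop on a fresh copy of the study materials."""
    params = params or RemodelingParams()
    mats = dataclasses.replace(
        setup.implanted_materials,
        hu=setup.implanted_materials.hu.copy(),
        density=setup.implanted_materials.density.copy(),
        porosity=setup.implanted_materials.porosity.copy(),
        modulus=setup.implanted_materials.modulus.copy(),
        bone_class=setup.implanted_materials.bone_class.copy(),
        is_implant=setup.implanted_materials.is_implant.copy(),
    )
    stimulus = FEStimulus(setup.implanted_mesh, setup.load_cases_implanted,
                          params.m, params.fe_update_interval)
    engine = RemodelingEngine(
        setup.implanted_mesh, mats, params, setup.phi0, stimulus,
        phi_hat=setup.phi_hat, protocol=protocol, region_masks=setup.regions,
    )
    return engine.run(total_days=total_days, snapshot_days=snapshot_days)
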