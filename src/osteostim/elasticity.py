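"""Static linear-elastic solves for the daily load cases.

Joint and abductor-muscle forces are given as magnitude plus an angle
measured from the proximal shaft axis (+z) in the coronal (x-z) plane.
The joint force is compressive (applied along -u(theta)), the muscle force
tensile (+u(theta)); negative angles flip to the opposite side.  Forces are
spread as uniform tractions over named boundary facet patches.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _fem
from .mesh import MeshModel
from .materials import ElementMaterialField

# Daily load cases: cycles, joint force N @ deg, muscle force N @ deg.
# Standing on one leg / hip abduction / hip adduction.
DEFAULT_LOAD_CASES = (
    ("standing", 6000, 2317.0, 24.0, 703.0, 28.0),
    ("abduction", 2000, 1158.0, -15.0, 351.0, -8.0),
    ("adduction", 2000, 1548.0, 56.0, 468.0, 35.0),
)


@dataclass
class LoadCase:
    """One daily loading condition (cycle count + joint and muscle forces)."""

    name: str
    cycles: int
    joint_force_N: float
    joint_angle_deg: float
    muscle_force_N: float
    muscle_angle_deg: float
    joint_patch: str = "head_surface"
    muscle_patch: str = "greater_trochanter"

    def __post_init__(self) -> None:
        if self.cycles <= 0:
            raise ValueError("cycle count must be positive")
        if self.joint_force_N < 0 or self.muscle_force_N < 0:
            raise ValueError("force magnitudes must be non-negative")

    @staticmethod
    def _direction(angle_deg: float) -> np.ndarray:
        a = np.deg2rad(angle_deg)
        return np.array([np.sin(a), 0.0, np.cos(a)])

    def force_vectors(self) -> dict[str, np.ndarray]:
        """Patch name -> resultant force vector (N)."""
        return {
            self.joint_patch: -self.joint_force_N * self._direction(self.joint_angle_deg),
            self.muscle_patch: self.muscle_force_N * self._direction(self.muscle_angle_deg),
        }


def default_load_cases(joint_patch: str = "head_surface") -> list[LoadCase]:
    return [
        LoadCase(name, n, jf, ja, mf, ma, joint_patch=joint_patch)
        for name, n, jf, ja, mf, ma in DEFAULT_LOAD_CASES
    ]


@dataclass
class StressState:
    """Per-element stress summary for one load case."""

    load_case: str
    tensor: np.ndarray            # (n_el, 3, 3) MPa, element-averaged
    principal: np.ndarray         # (n_el, 3) sorted descending
    von_mises: np.ndarray         # (n_el,) MPa
    displacement: np.ndarray = field(repr=False, default=None)


def principal_stresses(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of symmetric stress tensors, sorted sigma1 >= sigma2 >= sigma3."""
    t = np.asarray(tensor, dtype=float)
    single = t.ndim == 2
    t = t.reshape(-1, 3, 3)
    asym = np.abs(t - t.transpose(0, 2, 1)).max()
    scale = max(np.abs(t).max(), 1.0)
    if asym > 1e-9 * scale:
        raise ValueError(f"stress tensor not symmetric (max asymmetry {asym:.2e})")
    vals = np.linalg.eigvalsh(0.5 * (t + t.transpose(0, 2, 1)))[:, ::-1]
    return vals[0] if single else vals


def von_mises(principal: np.ndarray) -> np.ndarray:
    """Equivalent stress from principal stresses.

    sigma_vm = sqrt( ((s1-s2)^2 + (s2-s3)^2 + (s3-s1)^2) / 2 ); invariant
    under hydrostatic offsets.
    """
    p = np.asarray(principal, dtype=float)
    s1, s2, s3 = p[..., 0], p[..., 1], p[..., 2]
    return np.sqrt(0.5 * ((s1 - s2) ** 2 + (s2 - s3) ** 2 + (s3 - s1) ** 2))


def _element_stress(mesh: MeshModel, u: np.ndarray, E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Element-averaged stress tensors from nodal displacements."""
    grads, wvol = _fem.shape_gradients(mesh)
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    ue = u.reshape(-1, 3)[mesh.elements]              # (n_el, nb, 3)
    sigma = np.zeros((mesh.n_elements, 3, 3))
    wtot = wvol.sum(axis=0)
    for q in range(grads.shape[0]):
        gu = np.einsum("eak,eai->eki", ue, grads[q])  # grad u (k: comp, i: deriv)
        eps = 0.5 * (gu + gu.transpose(0, 2, 1))
        tr = np.trace(eps, axis1=1, axis2=2)
        sq = (lam * tr)[:, None, None] * np.eye(3) + 2.0 * mu[:, None, None] * eps
        sigma += wvol[q][:, None, None] * sq
    return sigma / wtot[:, None, None]


def solve_elasticity(
    mesh: MeshModel,
    E: np.ndarray,
    nu: np.ndarray,
    dirichlet: list[tuple[np.ndarray, int | None, float]],
    patch_forces: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Low-level solve: returns (displacement, element stress tensors, reactions).

    ``dirichlet`` entries are (node indices, component or None for all, value);
    ``patch_forces`` maps facet-set names to resultant force vectors (N).
    """
    E = np.broadcast_to(np.asarray(E, dtype=float), (mesh.n_elements,))
    nu = np.broadcast_to(np.asarray(nu, dtype=float), (mesh.n_elements,))
    K = _fem.assemble_elasticity(mesh, E, nu)
    f = np.zeros(3 * mesh.n_nodes)
    for patch, force in patch_forces.items():
        if patch not in mesh.facet_sets:
            raise _fem.SolverError(f"facet set {patch!r} not on mesh")
        f += _fem.traction_load(mesh, mesh.facet_sets[patch], force)
    dofs, vals = [], []
    for nodes, comp, value in dirichlet:
        nodes = np.asarray(nodes, dtype=np.int64)
        comps = range(3) if comp is None else (comp,)
        for c in comps:
            dofs.append(3 * nodes + c)
            vals.append(np.full(len(nodes), float(value)))
    fixed = np.concatenate(dofs) if dofs else np.empty(0, dtype=np.int64)
    fixed, idx = np.unique(fixed, return_index=True)
    vals = np.concatenate(vals)[idx] if len(vals) else np.empty(0)
    u, reactions = _fem.solve_dirichlet(K, f, fixed, vals)
    sigma = _element_stress(mesh, u, E, nu)
    return u, sigma, reactions


def assemble_and_solve(
    mesh: MeshModel,
    materials: ElementMaterialField,
    load_case: LoadCase,
    fixed_facet_set: str = "base",
) -> StressState:
    """Solve one load case: base fully fixed, patch tractions per the case."""
    if fixed_facet_set not in mesh.facet_sets or len(mesh.facet_sets[fixed_facet_set]) == 0:
        raise _fem.SolverError(f"fixed facet set {fixed_facet_set!r} missing or empty")
    nu = np.where(materials.is_implant, materials.mapping.implant_nu, materials.mapping.nu)
    base_nodes = mesh.facet_set_nodes(fixed_facet_set)
    u, sigma, _ = solve_elasticity(
        mesh, materials.modulus, nu,
        dirichlet=[(base_nodes, None, 0.0)],
        patch_forces=load_case.force_vectors(),
    )
    principal = principal_stresses(sigma)
    return StressState(
        load_case=load_case.name, tensor=sigma, principal=principal,
        von_mises=von_mises(principal), displacement=u,
    )
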