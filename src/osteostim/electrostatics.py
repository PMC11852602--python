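"""Electrostatic stimulation field.

Bone is treated as an anisotropic dielectric with a diagonal permittivity
tensor diag(beta11, beta11, beta33) in a material frame whose third axis is
the shaft axis.  A fixed electrode voltage is applied on a neck surface
band, ground on the distal cut plane, and the resulting potential is
rescaled to [0, 1] per element to weight the local stimulation influence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import _fem
from .mesh import MeshModel

log = logging.getLogger(__name__)

BETA11_F_PER_M = 88.54e-12     # transverse permittivity of cortical bone
BETA33_F_PER_M = 106.248e-12   # longitudinal (shaft-axis) permittivity


@dataclass
class DielectricParams:
    """Diagonal permittivity in a material frame (F/m)."""

    beta11: float = BETA11_F_PER_M
    beta33: float = BETA33_F_PER_M
    material_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def tensor(self) -> np.ndarray:
        """World-frame 3x3 SPD tensor: beta33 along the axis, beta11 across."""
        if self.beta11 <= 0 or self.beta33 <= 0:
            raise ValueError("permittivities must be positive")
        a = np.asarray(self.material_axis, dtype=float)
        a = a / np.linalg.norm(a)
        return self.beta11 * (np.eye(3) - np.outer(a, a)) + self.beta33 * np.outer(a, a)


@dataclass
class StimulationProtocol:
    """Electrode setup and dosing window for electrical stimulation.

    amplitude A scales the maximum suppression of the disuse activation
    frequency (fa -> fa * (1 - A * phi_hat)); the window is
    [start_day, start_day + duration_days - 1] inclusive.
    """

    electrode_voltage: float = 32.0
    electrode_set: str = "neck_electrode"
    ground_set: str = "base"
    amplitude: float = 0.0
    start_day: int = 101
    duration_days: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("amplitude must be in [0, 1]")
        if self.start_day < 1 or self.duration_days < 0:
            raise ValueError("start_day >= 1 and duration >= 0 required")
        if self.electrode_set == self.ground_set:
            raise ValueError("electrode and ground facet sets must differ")

    def active(self, day: int) -> bool:
        return self.start_day <= day < self.start_day + self.duration_days


def solve_electrostatics(
    mesh: MeshModel,
    dielectric: DielectricParams | None = None,
    protocol: StimulationProtocol | None = None,
    ground_voltage: float = 0.0,
    element_tensors: np.ndarray | None = None,
) -> np.ndarray:
    """Nodal potential (V) for div(beta grad phi) = 0 with electrode BCs.

    Dirichlet: electrode set at ``electrode_voltage``, ground set at
    ``ground_voltage`` (0 V by default), zero normal flux elsewhere.
    ``element_tensors`` (n_el, 3, 3) overrides the homogeneous dielectric,
    e.g. for layered verification slabs.
    """
    dielectric = dielectric or DielectricParams()
    protocol = protocol or StimulationProtocol()
    for name in (protocol.electrode_set, protocol.ground_set):
        if name not in mesh.facet_sets or len(mesh.facet_sets[name]) == 0:
            raise _fem.SolverError(f"facet set {name!r} missing or empty")
    tensor = dielectric.tensor() if element_tensors is None else element_tensors
    K = _fem.assemble_scalar_diffusion(mesh, tensor)
    elec = mesh.facet_set_nodes(protocol.electrode_set)
    gnd = np.setdiff1d(mesh.facet_set_nodes(protocol.ground_set), elec)
    fixed = np.concatenate([elec, gnd])
    vals = np.concatenate([
        np.full(len(elec), protocol.electrode_voltage),
        np.full(len(gnd), ground_voltage),
    ])
    phi, _ = _fem.solve_dirichlet(K, np.zeros(mesh.n_nodes), fixed, vals)
    return phi


def normalize_potential(mesh: MeshModel, phi: np.ndarray) -> np.ndarray:
    """Per-element normalized potential phi_hat in [0, 1].

    Element value = mean of its nodal potentials, rescaled so the highest
    potential maps to 1 (greatest stimulation influence) and the lowest
    to 0.  A constant field degenerates to phi_hat = 0 with a warning.
    """
    elem_phi = np.asarray(phi, dtype=float)[mesh.elements].mean(axis=1)
    lo, hi = elem_phi.min(), elem_phi.max()
    if hi == lo:
        log.warning("normalize_potential: constant potential field, phi_hat set to 0")
        return np.zeros(mesh.n_elements)
    return (elem_phi - lo) / (hi - lo)
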