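"""BMU-kinetics disuse remodeling with optional electrical stimulation.

The daily mechanical stimulus is a cycle-weighted power mean of the von
Mises stresses of the day's load cases,

    Phi = ( sum_j n_j * sigma_j^m )^(1/m),   m = 4,

and is compared with the element's equilibrium stimulus Phi0 computed on
the intact femur.  Sub-equilibrium stimulus raises the BMU activation
frequency through a sigmoid,

    fa = fa_max / (1 + exp((Phi/Phi0 - kD1)/kD2)),

BMUs are born on internal surfaces at rate fa * Sr(P) per unit volume, and
the populations currently resorbing (N_R, most recent T_R days) and filling
(N_F, days aged T_R+T_I .. T_R+T_I+T_F) drive the porosity rate

    dP/dt = Q_R * N_R - Q_F * N_F,

with BMU geometry rates Q_R from the simplified cortical (cylinder) and
cancellous (semi-elliptic groove) shapes and Q_F closed by the equilibrium
balance Q_F = Q_R * T_R / T_F.  Electrical stimulation multiplies fa by
(1 - A * phi_hat) inside the dosing window, where phi_hat is the normalized
electrostatic potential and A the amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mesh import MeshModel
from .materials import (
    ElementMaterialField, CLASS_CORTICAL, CLASS_CANCELLOUS,
)
from .electrostatics import StimulationProtocol

SPECIFIC_SURFACE_COEFFS = (32.1, -93.9, 134.0, -101.0, 28.8)  # P^1..P^5


class RemodelingError(RuntimeError):
    pass


@dataclass(frozen=True)
class BMUClassParams:
    """BMU stage durations for one bone class (days)."""

    t_r: int   # resorption
    t_i: int   # reversal
    t_f: int   # filling

    @property
    def history_length(self) -> int:
        return self.t_r + self.t_i + self.t_f


@dataclass
class RemodelingParams:
    """Disuse-remodeling constants (Table-2 values as defaults)."""

    m: float = 4.0                      # stimulus exponent
    kappa_d1: float = 0.5               # sigmoid center (in Phi/Phi0)
    kappa_d2: float = 0.1               # sigmoid width
    fa_max: float = 0.1                 # BMUs/(mm^3 day), peak activation
    cortical: BMUClassParams = field(default_factory=lambda: BMUClassParams(24, 8, 64))
    cancellous: BMUClassParams = field(default_factory=lambda: BMUClassParams(60, 57, 197))
    v: float = 0.01                     # BMU advance, mm/day
    d_bmu: float = 0.65                 # cancellous groove width, mm
    d_e: float = 0.05                   # cancellous groove depth, mm
    d_o: float = 0.2                    # cortical osteon diameter, mm
    dt_days: float = 1.0
    total_days: int = 300
    fe_update_interval: int = 1
    phi0_floor: float = 1e-6            # MPa, guards Phi/Phi0

    def class_params(self, bone_class: int) -> BMUClassParams:
        return self.cortical if bone_class == CLASS_CORTICAL else self.cancellous


# ---------------------------------------------------------------- kinetics
def daily_stimulus(von_mises_per_case: np.ndarray, cycles: np.ndarray,
                   m: float) -> np.ndarray:
    """Cycle-weighted power mean Phi = (sum n_j sigma_j^m)^(1/m), MPa."""
    s = np.asarray(von_mises_per_case, dtype=float)
    n = np.asarray(cycles, dtype=float).reshape(-1, *([1] * (s.ndim - 1)))
    return np.power((n * np.power(s, m)).sum(axis=0), 1.0 / m)


def equilibrium_stimulus(intact_von_mises_per_case: np.ndarray,
                         cycles: np.ndarray, m: float,
                         floor: float = 1e-6) -> np.ndarray:
    """Phi0 from the intact-model stresses, floored to stay positive."""
    return np.maximum(daily_stimulus(intact_von_mises_per_case, cycles, m), floor)


def disuse_activation_frequency(phi: np.ndarray, phi0: np.ndarray,
                                kappa_d1: float, kappa_d2: float,
                                fa_max: float) -> np.ndarray:
    """Sigmoidal activation frequency; saturates to fa_max under full disuse."""
    x = (np.asarray(phi, dtype=float) / np.asarray(phi0, dtype=float) - kappa_d1) / kappa_d2
    fa = fa_max / (1.0 + np.exp(np.clip(x, -700.0, 700.0)))
    # saturate cleanly at the limits instead of returning denormals
    return np.where(x >= 700.0, 0.0, fa)


def specific_surface(porosity: np.ndarray) -> np.ndarray:
    """Internal surface per unit volume Sr(P), mm^2/mm^3, quintic in P."""
    p = np.asarray(porosity, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise RemodelingError("porosity outside [0, 1]")
    c1, c2, c3, c4, c5 = SPECIFIC_SURFACE_COEFFS
    return p * (c1 + p * (c2 + p * (c3 + p * (c4 + p * c5))))


def resorption_rate(bone_class: int, params: RemodelingParams) -> float:
    """Volume resorbed per BMU per day, mm^3/day.

    Cortical BMUs are cylinders of diameter d_o; cancellous BMUs are
    semi-elliptic grooves of depth d_e and width d_bmu, both advancing
    at v mm/day.
    """
    if bone_class == CLASS_CORTICAL:
        return np.pi * params.d_o ** 2 * params.v / 4.0
    return np.pi * params.d_e * params.d_bmu * params.v / 4.0


def filling_rate(q_r: float, t_r: int, t_f: int) -> float:
    """Q_F closed by equilibrium balance: constant history => dP/dt = 0."""
    if t_f <= 0:
        raise RemodelingError("t_f must be positive")
    return q_r * t_r / t_f


def porosity_rate(n_r: np.ndarray, n_f: np.ndarray, q_r: float, q_f: float) -> np.ndarray:
    """dP/dt = Q_R N_R - Q_F N_F (positive = bone loss)."""
    return q_r * np.asarray(n_r) - q_f * np.asarray(n_f)


def es_modulated_activation(fa: np.ndarray, phi_hat: np.ndarray, amplitude: float,
                            day: int, protocol: StimulationProtocol | None) -> np.ndarray:
    """fa * (1 - A * phi_hat) inside the stimulation window, fa outside."""
    if protocol is None or not protocol.active(day) or amplitude == 0.0:
        return np.asarray(fa, dtype=float)
    return np.asarray(fa, dtype=float) * (1.0 - amplitude * np.asarray(phi_hat))


# ---------------------------------------------------------------- history
class BMUHistoryBuffer:
    """Ring buffer of daily fa*Sr values for a set of same-class elements.

    Length is T_R + T_I + T_F; entries before day 1 hold the equilibrium
    pre-fill value.  ``counts`` returns the resorbing and filling BMU
    densities as windowed sums (dt = 1 day), gathering entries in
    chronological order so results match a brute-force windowed sum bit
    for bit.
    """

    def __init__(self, n_elements: int, class_params: BMUClassParams,
                 prefill: np.ndarray | float = 0.0):
        self.cp = class_params
        L = class_params.history_length
        self.data = np.empty((n_elements, L), dtype=float)
        self.data[:] = np.asarray(prefill, dtype=float).reshape(-1, 1) \
            if np.ndim(prefill) else prefill
        self.pos = L - 1   # slot of the most recent entry

    def append(self, values: np.ndarray) -> None:
        L = self.data.shape[1]
        self.pos = (self.pos + 1) % L
        self.data[:, self.pos] = values

    def counts(self, dt: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
        """(N_R, N_F): sums over the resorption and filling age windows."""
        cp, L = self.cp, self.data.shape[1]
        # chronological slot indices, oldest first
        idx_r = (self.pos - cp.t_r + 1 + np.arange(cp.t_r)) % L
        start_f = self.pos - cp.history_length + 1
        idx_f = (start_f + np.arange(cp.t_f)) % L
        # force C order: the gathered window must sum in the same pairwise
        # blocking as a plain chronological array for bit-exact results
        win_r = np.ascontiguousarray(self.data[:, idx_r])
        win_f = np.ascontiguousarray(self.data[:, idx_f])
        return win_r.sum(axis=1) * dt, win_f.sum(axis=1) * dt


# ---------------------------------------------------------------- engine
class ConstantStimulus:
    """Fixed stimulus field (used for homeostasis and unit tests)."""

    def __init__(self, phi: np.ndarray):
        self.phi = np.asarray(phi, dtype=float)

    def __call__(self, day: int, materials: ElementMaterialField) -> np.ndarray:
        return self.phi


class FEStimulus:
    """FE-backed stimulus: re-solves the load cases on the current modulus
    field every ``interval`` days and power-means the von Mises stresses."""

    def __init__(self, mesh: MeshModel, load_cases, m: float, interval: int = 1):
        from .elasticity import assemble_and_solve  # local import avoids cycle
        self._solve = assemble_and_solve
        self.mesh = mesh
        self.load_cases = list(load_cases)
        self.cycles = np.array([lc.cycles for lc in self.load_cases], dtype=float)
        self.m = m
        self.interval = max(int(interval), 1)
        self._phi: np.ndarray | None = None
        self.n_solves = 0

    def __call__(self, day: int, materials: ElementMaterialField) -> np.ndarray:
        if self._phi is None or (day - 1) % self.interval == 0:
            vm = np.stack([
                self._solve(self.mesh, materials, lc).von_mises
                for lc in self.load_cases
            ])
            self._phi = daily_stimulus(vm, self.cycles, self.m)
            self.n_solves += 1
        return self._phi


@dataclass
class Trajectory:
    """Daily time series plus density snapshots from a remodeling run."""

    table: pd.DataFrame
    snapshots: dict[int, np.ndarray]
    initial_density: np.ndarray
    final_density: np.ndarray


class RemodelingEngine:
    """Day-stepping disuse-remodeling loop on one mesh.

    Per day: (1) stimulus Phi (FE re-solve on the provider's cadence),
    (2) activation fa, (3) electrical modulation, (4) append fa_eff*Sr(P)
    to each element's history, (5) window the histories into N_R/N_F,
    (6) forward-Euler porosity update with clamping, (7) propagate density
    and modulus.
    """

    def __init__(
        self,
        mesh: MeshModel,
        materials: ElementMaterialField,
        params: RemodelingParams,
        phi0: np.ndarray,
        stimulus,
        phi_hat: np.ndarray | None = None,
        protocol: StimulationProtocol | None = None,
        region_masks: dict[str, np.ndarray] | None = None,
    ):
        self.mesh = mesh
        self.materials = materials
        self.params = params
        self.stimulus = stimulus
        self.protocol = protocol
        self.phi_hat = np.zeros(mesh.n_elements) if phi_hat is None else np.asarray(phi_hat)
        self.region_masks = dict(region_masks or {})
        self.day = 0

        bone = materials.is_bone
        self.phi0 = np.where(bone, np.maximum(phi0, params.phi0_floor), np.nan)
        self.class_idx = {
            cls: np.nonzero(bone & (materials.bone_class == cls))[0]
            for cls in (CLASS_CORTICAL, CLASS_CANCELLOUS)
        }
        fa0 = params.fa_max / (1.0 + np.exp((1.0 - params.kappa_d1) / params.kappa_d2))
        self.buffers = {}
        self.rates_qrqf = {}
        for cls, idx in self.class_idx.items():
            cp = params.class_params(cls)
            prefill = fa0 * specific_surface(materials.porosity[idx])
            self.buffers[cls] = BMUHistoryBuffer(len(idx), cp, prefill)
            q_r = resorption_rate(cls, params)
            self.rates_qrqf[cls] = (q_r, filling_rate(q_r, cp.t_r, cp.t_f))
        self._records: list[dict] = []
        self._last_dpdt = np.zeros(mesh.n_elements)

    # ------------------------------------------------------------------
    def step_day(self) -> None:
        self.day += 1
        p = self.params
        mats = self.materials
        phi = self.stimulus(self.day, mats)
        with np.errstate(invalid="ignore"):
            fa = disuse_activation_frequency(phi, self.phi0, p.kappa_d1,
                                             p.kappa_d2, p.fa_max)
        amplitude = self.protocol.amplitude if self.protocol is not None else 0.0
        fa_eff = es_modulated_activation(fa, self.phi_hat, amplitude,
                                         self.day, self.protocol)
        dpdt = np.zeros(self.mesh.n_elements)
        new_p = mats.porosity.copy()
        for cls, idx in self.class_idx.items():
            if len(idx) == 0:
                continue
            buf = self.buffers[cls]
            buf.append(fa_eff[idx] * specific_surface(mats.porosity[idx]))
            n_r, n_f = buf.counts(p.dt_days)
            q_r, q_f = self.rates_qrqf[cls]
            rate = porosity_rate(n_r, n_f, q_r, q_f)
            dpdt[idx] = rate
            new_p[idx] = mats.porosity[idx] + p.dt_days * rate
        if not np.all(np.isfinite(new_p[mats.is_bone])):
            raise RemodelingError(f"non-finite porosity at day {self.day}")
        mats.set_porosity(new_p)
        self._last_dpdt = dpdt
        self._record()

    def _record(self) -> None:
        mats = self.materials
        rho0 = mats.mapping.rho_0
        row = {"day": self.day}
        groups = {
            "cortical": mats.is_bone & (mats.bone_class == CLASS_CORTICAL),
            "cancellous": mats.is_bone & (mats.bone_class == CLASS_CANCELLOUS),
        }
        for name, mask in self.region_masks.items():
            groups[name] = np.asarray(mask, dtype=bool) & mats.is_bone
        for name, mask in groups.items():
            if mask.any():
                row[f"mean_density_{name}"] = float(mats.density[mask].mean())
                row[f"density_rate_{name}"] = float(
                    -rho0 * self._last_dpdt[mask].mean())
            else:
                row[f"mean_density_{name}"] = np.nan
                row[f"density_rate_{name}"] = np.nan
        self._records.append(row)

    # ------------------------------------------------------------------
    def run(self, total_days: int | None = None,
            snapshot_days: tuple[int, ...] = ()) -> Trajectory:
        total = self.params.total_days if total_days is None else int(total_days)
        initial = self.materials.density.copy()
        snapshots: dict[int, np.ndarray] = {}
        for _ in range(total):
            self.step_day()
            if self.day in snapshot_days:
                snapshots[self.day] = self.materials.density.copy()
        table = pd.DataFrame(self._records)
        return Trajectory(table=table, snapshots=snapshots,
                          initial_density=initial,
                          final_density=self.materials.density.copy())
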