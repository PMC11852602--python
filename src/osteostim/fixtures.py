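"""Synthetic verification and femur-like mesh generators.

Patient CT geometry is not shipped with the package; instead a parametric
proximal femur (shaft + angled neck + spherical head, with a marrow canal)
is sampled on a structured tetrahedral background grid.  The intact and
implanted variants are carved from the *same* grid, so the bone elements
they share coincide exactly — this is what makes element-wise stress-ratio
comparison between the two models well defined.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .mesh import MeshModel, MeshError, REGION_BONE, REGION_IMPLANT

# Kuhn split of the unit cube into 6 path tetrahedra; conforming across
# neighbouring cells without parity flips.
_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _structured_grid(nx: int, ny: int, nz: int, lengths):
    """Nodes and tet4 connectivity of a box split into 6 tets per cell."""
    lx, ly, lz = lengths
    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    zs = np.linspace(0.0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    I, J, K = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    c0 = nid(I, J, K).ravel()
    e = [nid(I + 1, J, K).ravel() - c0, nid(I, J + 1, K).ravel() - c0,
         nid(I, J, K + 1).ravel() - c0]
    c1 = c0 + e[0] + e[1] + e[2]
    tets = []
    for p in _PERMS:
        a = c0
        b = c0 + e[p[0]]
        c = c0 + e[p[0]] + e[p[1]]
        tets.append(np.column_stack([a, b, c, c1]))
    tets = np.concatenate(tets)
    return nodes, tets


def generate_block_fixture(nx: int, ny: int, nz: int, lengths=(10.0, 10.0, 10.0)) -> MeshModel:
    """Structured tetrahedralized box with one facet set per face.

    ``6 * nx * ny * nz`` tetrahedra.  Facet sets: xmin, xmax, ymin, ymax,
    zmin, zmax.  Used for patch, slab and beam verification problems.
    """
    if min(nx, ny, nz) < 1:
        raise MeshError("block dimensions must be >= 1 cells")
    if min(lengths) <= 0:
        raise MeshError("block edge lengths must be positive")
    nodes, tets = _structured_grid(nx, ny, nz, lengths)
    mesh = MeshModel(nodes, tets, np.zeros(len(tets), dtype=np.int64))
    mesh.orient()
    pairs, corners = mesh.boundary_faces()
    cent = nodes[corners].mean(axis=1)
    tol = 1e-9 * max(lengths)
    lx, ly, lz = lengths
    for name, mask in {
        "xmin": cent[:, 0] < tol, "xmax": cent[:, 0] > lx - tol,
        "ymin": cent[:, 1] < tol, "ymax": cent[:, 1] > ly - tol,
        "zmin": cent[:, 2] < tol, "zmax": cent[:, 2] > lz - tol,
    }.items():
        mesh.facet_sets[name] = pairs[mask]
    # aliases used by the solver conventions
    mesh.facet_sets["base"] = mesh.facet_sets["zmin"]
    mesh.metadata = {"fixture": "block", "lengths": list(lengths)}
    return mesh


# ----------------------------------------------------------------------
@dataclass
class FemurFixtureParams:
    """Parameters of the parametric proximal-femur fixture (mm, degrees)."""

    shaft_length: float = 80.0
    shaft_outer_radius: float = 14.0
    shaft_inner_radius: float = 7.0
    neck_length: float = 40.0
    neck_radius: float = 11.0
    neck_angle_deg: float = 55.0          # tilt of neck axis from shaft axis
    head_radius: float = 17.0
    target_element_count: int = 9000
    implanted: bool = False
    implant_stem_radius: float = 6.0
    implant_stem_length: float = 60.0
    implant_ball_radius: float = 10.0
    seed: int = 0
    jitter: float = 0.0                   # interior node jitter, fraction of h

    def validate(self) -> None:
        pos = [self.shaft_length, self.shaft_outer_radius, self.shaft_inner_radius,
               self.neck_length, self.neck_radius, self.head_radius,
               self.implant_stem_radius, self.implant_stem_length,
               self.implant_ball_radius]
        if min(pos) <= 0:
            raise MeshError("all femur lengths must be positive")
        if self.shaft_inner_radius >= self.shaft_outer_radius:
            raise MeshError("inner radius must be below outer radius")
        if self.implanted and self.implant_stem_radius > self.shaft_inner_radius:
            raise MeshError("implant stem does not fit inside the canal")
        if self.target_element_count < 100:
            raise MeshError("target_element_count too small for a femur")

    # implicit-solid membership tests -----------------------------------
    @property
    def neck_start(self) -> np.ndarray:
        return np.array([0.0, 0.0, self.shaft_length])

    @property
    def neck_dir(self) -> np.ndarray:
        a = np.deg2rad(self.neck_angle_deg)
        return np.array([np.sin(a), 0.0, np.cos(a)])

    @property
    def head_center(self) -> np.ndarray:
        return self.neck_start + self.neck_length * self.neck_dir

    def in_shaft(self, p: np.ndarray) -> np.ndarray:
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return (r2 <= self.shaft_outer_radius ** 2) & (p[:, 2] >= 0) & (
            p[:, 2] <= self.shaft_length)

    def in_canal(self, p: np.ndarray) -> np.ndarray:
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        return (r2 <= self.shaft_inner_radius ** 2) & (p[:, 2] >= 0) & (
            p[:, 2] <= self.shaft_length)

    def neck_coords(self, p: np.ndarray):
        rel = p - self.neck_start
        t = rel @ self.neck_dir
        radial = np.linalg.norm(rel - np.outer(t, self.neck_dir), axis=1)
        return t, radial

    def in_neck(self, p: np.ndarray) -> np.ndarray:
        t, radial = self.neck_coords(p)
        return (t >= -10.0) & (t <= self.neck_length) & (radial <= self.neck_radius)

    def in_head(self, p: np.ndarray) -> np.ndarray:
        return np.linalg.norm(p - self.head_center, axis=1) <= self.head_radius

    def in_implant(self, p: np.ndarray) -> np.ndarray:
        r2 = p[:, 0] ** 2 + p[:, 1] ** 2
        stem = (r2 <= self.implant_stem_radius ** 2) & (
            p[:, 2] >= self.shaft_length - self.implant_stem_length) & (
            p[:, 2] <= self.shaft_length)
        t, radial = self.neck_coords(p)
        neck_core = (t >= -self.implant_stem_radius) & (t <= self.neck_length) & (
            radial <= self.implant_stem_radius)
        ball = np.linalg.norm(p - self.head_center, axis=1) <= self.implant_ball_radius
        return stem | neck_core | ball


def _estimate_cell_size(params: FemurFixtureParams, lo, hi) -> float:
    """Grid spacing targeting ``target_element_count`` via volume sampling."""
    n = 25
    axes = [np.linspace(lo[i], hi[i], n) for i in range(3)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    p = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    # always size against the intact union so the intact and implanted
    # variants share one background grid (exact bone-element overlap)
    inside = params.in_shaft(p) | params.in_neck(p) | params.in_head(p)
    box_vol = np.prod(hi - lo)
    solid_vol = box_vol * inside.mean()
    return (6.0 * solid_vol / params.target_element_count) ** (1.0 / 3.0)


def _largest_component(tets: np.ndarray) -> np.ndarray:
    """Element mask of the largest face-connected component.

    Face connectivity (not node connectivity) is required: substructures
    hanging on a single shared node or edge would be zero-energy mechanisms
    in the elastic solve.
    """
    import scipy.sparse as sp
    from scipy.sparse.csgraph import connected_components
    from .mesh import TET_FACES

    n_el = len(tets)
    faces = np.sort(tets[:, TET_FACES].reshape(-1, 3), axis=1)
    _, inv, counts = np.unique(faces, axis=0, return_inverse=True,
                               return_counts=True)
    owner = np.repeat(np.arange(n_el), 4)
    order = np.argsort(inv, kind="stable")
    shared = counts == 2
    # pairs of elements owning the same interior face
    sorted_inv = inv[order]
    firsts = np.searchsorted(sorted_inv, np.nonzero(shared)[0], side="left")
    a = owner[order][firsts]
    b = owner[order][firsts + 1]
    graph = sp.coo_matrix((np.ones(len(a)), (a, b)), shape=(n_el, n_el))
    _, labels = connected_components(graph, directed=False)
    counts = np.bincount(labels)
    return labels == counts.argmax()


def generate_proximal_femur(params: FemurFixtureParams | None = None) -> MeshModel:
    """Build the intact or implanted proximal-femur fixture.

    Intact: hollow-free solid of shaft + neck + head, all region=bone (the
    canal is meshed and later assigned marrow HU).  Implanted: the head is
    removed and a titanium-class stem occupies the canal and neck core,
    ending in a small ball that receives the joint load.

    Facet sets: ``base`` (distal cut plane), ``head_surface`` (intact) or
    ``stem_head`` (implanted) load patch, ``greater_trochanter`` muscle
    patch, ``neck_electrode`` lateral neck band.
    """
    if params is None:
        params = FemurFixtureParams()
    params.validate()

    margin = 2.0
    top = params.head_center[2] + params.head_radius
    reach = params.head_center[0] + params.head_radius
    lo = np.array([-params.shaft_outer_radius - margin,
                   -max(params.shaft_outer_radius, params.neck_radius) - margin,
                   0.0])
    hi = np.array([max(reach, params.shaft_outer_radius) + margin,
                   max(params.shaft_outer_radius, params.neck_radius) + margin,
                   top + margin])
    h = _estimate_cell_size(params, lo, hi)
    shape = np.maximum(np.ceil((hi - lo) / h).astype(int), 2)
    nodes, tets = _structured_grid(*shape, hi - lo)
    nodes = nodes + lo

    if params.jitter > 0:
        rng = np.random.default_rng(params.seed)
        # jitter drawn for the full background grid so intact/implanted match
        dx = rng.normal(0.0, params.jitter * h / 3.0, size=nodes.shape)
        interior = (nodes[:, 2] > 1e-9)  # keep the base plane flat
        nodes = nodes + np.clip(dx, -0.25 * h, 0.25 * h) * interior[:, None]

    cent = nodes[tets].mean(axis=1)
    bone_solid = params.in_shaft(cent) | params.in_neck(cent)
    if params.implanted:
        implant = params.in_implant(cent)
        head_only = params.in_head(cent) & ~bone_solid & ~implant
        keep = (bone_solid | implant) & ~head_only
        region = np.where(implant[keep], REGION_IMPLANT, REGION_BONE)
    else:
        keep = bone_solid | params.in_head(cent)
        region = np.zeros(int(keep.sum()), dtype=np.int64)

    tets = tets[keep]
    # voxel sampling can leave isolated element islands that would make the
    # stiffness matrix singular; keep the largest node-connected component
    main = _largest_component(tets)
    tets, region = tets[main], region[main]
    used, inv = np.unique(tets, return_inverse=True)
    mesh = MeshModel(nodes[used], inv.reshape(tets.shape), region)
    mesh.orient()

    pairs, corners = mesh.boundary_faces()
    fc = mesh.nodes[corners].mean(axis=1)
    base = fc[:, 2] < 0.51 * h
    H = params.head_center
    t, radial = params.neck_coords(fc)
    electrode = ((t >= 0.25 * params.neck_length) & (t <= 0.65 * params.neck_length)
                 & (radial >= params.neck_radius - 1.6 * h)
                 & (np.linalg.norm(fc - H, axis=1) > params.head_radius))
    troch = ((fc[:, 0] < -0.55 * params.shaft_outer_radius)
             & (fc[:, 2] > params.shaft_length - 22.0)
             & (fc[:, 2] < params.shaft_length + 4.0))
    mesh.facet_sets["base"] = pairs[base]
    mesh.facet_sets["neck_electrode"] = pairs[electrode]
    mesh.facet_sets["greater_trochanter"] = pairs[troch]
    if params.implanted:
        ball = (np.linalg.norm(fc - H, axis=1) <= params.implant_ball_radius + 0.6 * h) & (
            fc[:, 2] > H[2] - 0.25 * params.implant_ball_radius)
        mesh.facet_sets["stem_head"] = pairs[ball]
    else:
        cap = (np.linalg.norm(fc - H, axis=1) >= params.head_radius - 1.2 * h) & (
            (fc - H) @ np.array([0.0, 0.0, 1.0]) > 0.3 * params.head_radius)
        mesh.facet_sets["head_surface"] = pairs[cap]

    for name in ("base", "greater_trochanter", "neck_electrode"):
        if len(mesh.facet_sets[name]) == 0:
            raise MeshError(f"femur fixture facet set {name!r} came out empty")
    mesh.metadata = {"fixture": "femur", "params": asdict(params), "h": float(h)}
    return mesh


# ----------------------------------------------------------------------
def synthetic_hu_field(
    mesh: MeshModel,
    hu_cortical: float = 1700.0,
    hu_cancellous: float = 900.0,
    hu_marrow: float = 50.0,
    shell_thickness_mm: float = 4.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Three-level synthetic CT field: cortical shell, cancellous interior,
    marrow canal.  Implant elements get NaN (no CT number).

    The shell is every bone element whose centroid lies within
    ``shell_thickness_mm`` of the outer boundary; the canal (femur fixture
    metadata) is marrow; the remainder is cancellous.  Gaussian noise with
    ``noise_sd`` HU is added and clipped to +-3 sd so the three plateaus
    stay ordered for moderate noise.
    """
    if not (hu_marrow < hu_cancellous < hu_cortical):
        raise ValueError("HU levels must satisfy marrow < cancellous < cortical")
    cent = mesh.centroids()
    hu = np.full(mesh.n_elements, hu_cancellous, dtype=float)

    if mesh.metadata.get("fixture") == "femur":
        params = FemurFixtureParams(**mesh.metadata["params"])
        hu[params.in_canal(cent)] = hu_marrow

    pairs, corners = mesh.boundary_faces()
    tree = cKDTree(mesh.nodes[corners].mean(axis=1))
    dist, _ = tree.query(cent)
    shell = (dist <= shell_thickness_mm) & (hu != hu_marrow)
    hu[shell] = hu_cortical

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noise = rng.normal(0.0, noise_sd, size=mesh.n_elements)
        hu = hu + np.clip(noise, -3.0 * noise_sd, 3.0 * noise_sd)

    hu[mesh.element_region == REGION_IMPLANT] = np.nan
    return hu
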