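"""Tetrahedral mesh container and topology utilities.

Meshes are stored 0-based with linear (4-node) or quadratic (10-node)
tetrahedra.  Boundary facets are tracked as ``(element, local_face)``
pairs so facet sets survive quadratic conversion and file round trips.
Units are mm throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_BONE = 0
REGION_IMPLANT = 1

# Local faces of a tetrahedron, as corner-node triples oriented outward
# for a positively oriented element.
TET_FACES = np.array([[0, 2, 1], [0, 1, 3], [1, 2, 3], [0, 3, 2]])

# Midside node of tet10 for each corner pair (VTK/Gmsh ordering):
# node 4=(0,1), 5=(1,2), 6=(0,2), 7=(0,3), 8=(1,3), 9=(2,3)
TET10_EDGE_NODES = {
    (0, 1): 4, (1, 2): 5, (0, 2): 6, (0, 3): 7, (1, 3): 8, (2, 3): 9,
}
# Midside nodes completing each local face of TET_FACES to a 6-node triangle.
TET10_FACE_MIDS = np.array([[6, 5, 4], [4, 8, 7], [5, 9, 8], [7, 9, 6]])


class MeshError(ValueError):
    """Raised for invalid mesh topology or geometry."""


@dataclass
class MeshModel:
    """An unstructured tetrahedral mesh with regions and boundary facet sets.

    Parameters
    ----------
    nodes : (n_nodes, 3) float array, coordinates in mm.
    elements : (n_elem, 4|10) int array, node indices (0-based).
    element_region : (n_elem,) int array, REGION_BONE or REGION_IMPLANT.
    facet_sets : mapping name -> (n_facets, 2) int array of
        (element index, local face index) pairs on the mesh boundary.
    metadata : free-form generator parameters (not serialized to .msh).
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_region: np.ndarray
    facet_sets: dict[str, np.ndarray] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        self.element_region = np.asarray(self.element_region, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise MeshError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] not in (4, 10):
            raise MeshError("elements must be (n, 4) or (n, 10)")
        if len(self.element_region) != len(self.elements):
            raise MeshError("element_region length mismatch")
        self.facet_sets = {
            k: np.asarray(v, dtype=np.int64).reshape(-1, 2)
            for k, v in self.facet_sets.items()
        }

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def order(self) -> int:
        """1 for tet4, 2 for tet10."""
        return 1 if self.elements.shape[1] == 4 else 2

    def centroids(self) -> np.ndarray:
        """Element centroids (corner-node average), shape (n_elem, 3)."""
        return self.nodes[self.elements[:, :4]].mean(axis=1)

    def volumes(self) -> np.ndarray:
        """Signed volumes of the corner tetrahedra, mm^3."""
        p = self.nodes[self.elements[:, :4]]
        a, b, c = p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0

    def orient(self) -> None:
        """Fix element orientation so all signed volumes are positive."""
        neg = self.volumes() < 0
        if np.any(neg):
            if self.order == 2:
                raise MeshError("cannot reorient quadratic elements in place")
            cols = self.elements[neg][:, [0, 2, 1, 3]]
            self.elements[neg] = cols

    # ------------------------------------------------------------------
    def boundary_faces(self) -> tuple[np.ndarray, np.ndarray]:
        """All boundary facets as (element, local_face) pairs + corner triples.

        Returns
        -------
        pairs : (n_bf, 2) int array
        corners : (n_bf, 3) int array of node indices (outward oriented)
        """
        tets = self.elements[:, :4]
        n_el = len(tets)
        faces = tets[:, TET_FACES]                      # (n_el, 4, 3)
        flat = faces.reshape(-1, 3)
        key = np.sort(flat, axis=1)
        _, inv, counts = np.unique(
            key, axis=0, return_inverse=True, return_counts=True
        )
        on_boundary = counts[inv] == 1
        idx = np.nonzero(on_boundary)[0]
        pairs = np.column_stack([idx // 4, idx % 4])
        assert len(pairs) <= 4 * n_el
        return pairs, flat[idx]

    def facet_corner_nodes(self, pairs: np.ndarray) -> np.ndarray:
        """Corner-node triples for (element, local_face) pairs."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        return self.elements[pairs[:, 0][:, None], TET_FACES[pairs[:, 1]]]

    def facet_all_nodes(self, pairs: np.ndarray) -> np.ndarray:
        """All facet nodes: 3 corners (tet4) or 3 corners + 3 midsides (tet10)."""
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        corners = self.facet_corner_nodes(pairs)
        if self.order == 1:
            return corners
        mids = self.elements[pairs[:, 0][:, None], TET10_FACE_MIDS[pairs[:, 1]]]
        return np.hstack([corners, mids])

    def facet_areas_normals(self, pairs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Areas (mm^2) and outward unit normals of flat facet triangles."""
        tri = self.nodes[self.facet_corner_nodes(pairs)]
        cr = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        area2 = np.linalg.norm(cr, axis=1)
        return area2 / 2.0, cr / area2[:, None]

    def facet_set_nodes(self, name: str) -> np.ndarray:
        """Unique node indices touched by a named facet set."""
        if name not in self.facet_sets:
            raise MeshError(f"facet set {name!r} not on mesh")
        return np.unique(self.facet_all_nodes(self.facet_sets[name]))

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check mesh invariants; raise MeshError on the first violation.

        Checks: node indices in range, positive signed volumes, interior
        faces shared by exactly two elements (watertight boundary), every
        facet-set facet on the boundary, regions covering all elements.
        """
        if self.elements.min(initial=0) < 0 or self.elements.max(initial=-1) >= self.n_nodes:
            raise MeshError("element references node out of range")
        vol = self.volumes()
        if np.any(vol <= 0):
            raise MeshError(f"{int(np.sum(vol <= 0))} non-positive-volume elements")
        tets = self.elements[:, :4]
        key = np.sort(tets[:, TET_FACES].reshape(-1, 3), axis=1)
        _, counts = np.unique(key, axis=0, return_counts=True)
        if np.any(counts > 2):
            raise MeshError("face shared by more than two elements")
        pairs, _ = self.boundary_faces()
        bnd = set(map(tuple, pairs))
        for name, fs in self.facet_sets.items():
            for p in map(tuple, fs):
                if p not in bnd:
                    raise MeshError(f"facet set {name!r} has interior facet {p}")
        if not np.all(np.isin(self.element_region, (REGION_BONE, REGION_IMPLANT))):
            raise MeshError("unknown region label")

    # ------------------------------------------------------------------
    def to_quadratic(self) -> "MeshModel":
        """Return a tet10 mesh by inserting midside nodes on every edge."""
        if self.order == 2:
            return self
        tets = self.elements
        edges = np.array(list(TET10_EDGE_NODES.keys()))        # (6, 2)
        pair_nodes = tets[:, edges]                            # (n_el, 6, 2)
        flat = np.sort(pair_nodes.reshape(-1, 2), axis=1)
        uniq, inv = np.unique(flat, axis=0, return_inverse=True)
        mid_coords = self.nodes[uniq].mean(axis=1)
        mid_index = self.n_nodes + inv.reshape(len(tets), 6)
        elems10 = np.hstack([tets, np.empty_like(mid_index)])
        for e, (a, b) in enumerate(edges):
            local = TET10_EDGE_NODES[(int(a), int(b))]
            elems10[:, local] = mid_index[:, e]
        return MeshModel(
            nodes=np.vstack([self.nodes, mid_coords]),
            elements=elems10,
            element_region=self.element_region.copy(),
            facet_sets={k: v.copy() for k, v in self.facet_sets.items()},
            metadata=dict(self.metadata),
        )
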