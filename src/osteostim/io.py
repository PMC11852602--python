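"""Mesh and field I/O: Gmsh ``.msh`` (v4.1 ASCII), VTK ``.vtu`` (XML ASCII),
and CSV export of per-element fields.

Facet sets are serialized as boundary triangles: indicator cell-data arrays
``facet:<name>`` in ``.vtu``, physical surface groups in ``.msh``.  On read
they are matched back to (element, local face) pairs, so a write/read round
trip preserves connectivity and cell data exactly and coordinates to the
printed precision (%.17g, i.e. bit-exact for doubles).
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .mesh import MeshModel, MeshError, REGION_BONE, REGION_IMPLANT

VTK_TET4, VTK_TET10, VTK_TRI3, VTK_TRI6 = 10, 24, 5, 22
GMSH_TET4, GMSH_TET10, GMSH_TRI3, GMSH_TRI6 = 4, 11, 2, 9
# VTK and Gmsh tet10 orderings differ in the last two midside nodes.
_VTK_TO_GMSH_TET10 = [0, 1, 2, 3, 4, 5, 6, 7, 9, 8]

_REGION_NAMES = {REGION_BONE: "bone", REGION_IMPLANT: "implant"}
_REGION_IDS = {v: k for k, v in _REGION_NAMES.items()}


class UnsupportedFormatError(MeshError):
    pass


class MeshFileError(MeshError):
    pass


def read_mesh(path) -> tuple[MeshModel, dict[str, np.ndarray]]:
    """Read a mesh plus named per-element fields; format from the extension."""
    path = Path(path)
    if path.suffix == ".vtu":
        return _read_vtu(path)
    if path.suffix == ".msh":
        return _read_msh(path)
    raise UnsupportedFormatError(f"unsupported mesh format {path.suffix!r}")


def write_mesh(mesh: MeshModel, path, fields: dict[str, np.ndarray] | None = None) -> None:
    """Write a mesh plus named per-element fields; format from the extension."""
    path = Path(path)
    fields = fields or {}
    for name, v in fields.items():
        if len(np.asarray(v)) != mesh.n_elements:
            raise MeshError(f"field {name!r} length != n_elements")
    if path.suffix == ".vtu":
        _write_vtu(mesh, path, fields)
    elif path.suffix == ".msh":
        _write_msh(mesh, path, fields)
    else:
        raise UnsupportedFormatError(f"unsupported mesh format {path.suffix!r}")


def write_element_field_csv(path, values: np.ndarray, name: str = "value") -> None:
    """CSV export ``element_id,<name>`` (0-based element ids)."""
    values = np.asarray(values)
    with open(path, "w") as fh:
        fh.write(f"element_id,{name}\n")
        for i, v in enumerate(values):
            fh.write(f"{i},{float(v)!r}\n")


def read_element_field_csv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, float_precision="round_trip")
    return df.iloc[:, 1].to_numpy()


# ---------------------------------------------------------------- helpers
def _boundary_triangles(mesh: MeshModel):
    """Unique boundary facets used by any facet set, with per-set membership."""
    pairs_list = []
    seen = {}
    for name, fs in mesh.facet_sets.items():
        for p in map(tuple, fs):
            if p not in seen:
                seen[p] = len(seen)
                pairs_list.append(p)
    pairs = np.array(pairs_list, dtype=np.int64).reshape(-1, 2)
    membership = {
        name: np.isin(
            np.arange(len(pairs)),
            [seen[tuple(p)] for p in mesh.facet_sets[name]],
        ).astype(np.int64)
        for name in mesh.facet_sets
    }
    return pairs, membership


def _facets_from_triangles(mesh: MeshModel, tri_corners: np.ndarray) -> np.ndarray:
    """Map triangle corner triples back to (element, local face) pairs."""
    pairs, corners = mesh.boundary_faces()
    lookup = {tuple(sorted(c)): tuple(p) for c, p in zip(corners.tolist(), pairs.tolist())}
    out = []
    for tri in tri_corners:
        key = tuple(sorted(tri[:3]))
        if key not in lookup:
            raise MeshFileError(f"stored facet {key} is not on the mesh boundary")
        out.append(lookup[key])
    return np.array(out, dtype=np.int64).reshape(-1, 2)


def _fmt_floats(arr: np.ndarray, per_line: int = 3) -> str:
    flat = np.asarray(arr, dtype=float).ravel()
    return "\n".join(
        " ".join("%.17g" % x for x in flat[i:i + per_line])
        for i in range(0, len(flat), per_line)
    )


def _fmt_ints(arr: np.ndarray) -> str:
    flat = np.asarray(arr).ravel()
    return "\n".join(
        " ".join(str(int(x)) for x in flat[i:i + 12]) for i in range(0, len(flat), 12)
    )


# ---------------------------------------------------------------- VTU
def _write_vtu(mesh: MeshModel, path: Path, fields: dict[str, np.ndarray]) -> None:
    tri_pairs, membership = _boundary_triangles(mesh)
    tri_nodes = mesh.facet_all_nodes(tri_pairs) if len(tri_pairs) else np.empty((0, 3), int)
    n_tet, n_tri = mesh.n_elements, len(tri_pairs)

    conn = [mesh.elements.ravel(), tri_nodes.ravel()]
    tet_w = mesh.elements.shape[1]
    tri_w = tri_nodes.shape[1] if n_tri else 3
    offsets = np.concatenate([
        np.arange(1, n_tet + 1) * tet_w,
        n_tet * tet_w + np.arange(1, n_tri + 1) * tri_w,
    ])
    types = np.concatenate([
        np.full(n_tet, VTK_TET4 if tet_w == 4 else VTK_TET10),
        np.full(n_tri, VTK_TRI3 if tri_w == 3 else VTK_TRI6),
    ])

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1",
                      byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(grid, "Piece", NumberOfPoints=str(mesh.n_nodes),
                          NumberOfCells=str(n_tet + n_tri))
    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3",
                       format="ascii")
    da.text = _fmt_floats(mesh.nodes)
    cells = ET.SubElement(piece, "Cells")
    for name, data, typ in (
        ("connectivity", np.concatenate(conn), "Int64"),
        ("offsets", offsets, "Int64"),
        ("types", types, "UInt8"),
    ):
        d = ET.SubElement(cells, "DataArray", type=typ, Name=name, format="ascii")
        d.text = _fmt_ints(data)

    cd = ET.SubElement(piece, "CellData")
    region = np.concatenate([mesh.element_region, np.full(n_tri, -1)])
    d = ET.SubElement(cd, "DataArray", type="Int64", Name="region", format="ascii")
    d.text = _fmt_ints(region)
    for name, memb in membership.items():
        col = np.concatenate([np.zeros(n_tet, dtype=np.int64), memb])
        d = ET.SubElement(cd, "DataArray", type="Int64", Name=f"facet:{name}",
                          format="ascii")
        d.text = _fmt_ints(col)
    for name, values in fields.items():
        col = np.concatenate([np.asarray(values, dtype=float), np.full(n_tri, np.nan)])
        d = ET.SubElement(cd, "DataArray", type="Float64", Name=name, format="ascii")
        d.text = _fmt_floats(col, per_line=6)
    ET.indent(root)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="ascii")


def _read_vtu(path: Path) -> tuple[MeshModel, dict[str, np.ndarray]]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise MeshFileError(f"malformed .vtu file: {exc}") from exc
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshFileError("no <Piece> in .vtu file")
    coords = np.fromstring(piece.find("Points/DataArray").text, sep=" ").reshape(-1, 3)

    arrays = {}
    for da in piece.find("Cells"):
        arrays[da.get("Name")] = np.fromstring(da.text, sep=" ", dtype=np.int64)
    conn, offsets, types = arrays["connectivity"], arrays["offsets"], arrays["types"]
    starts = np.concatenate([[0], offsets[:-1]])

    cell_data = {}
    cd = piece.find("CellData")
    if cd is not None:
        for da in cd:
            cell_data[da.get("Name")] = np.fromstring(da.text, sep=" ")

    tet_mask = np.isin(types, (VTK_TET4, VTK_TET10))
    tri_mask = np.isin(types, (VTK_TRI3, VTK_TRI6))
    if not np.all(tet_mask | tri_mask):
        bad = set(types[~(tet_mask | tri_mask)].tolist())
        raise MeshFileError(f"unsupported VTK cell types {sorted(bad)}")
    tet_idx = np.nonzero(tet_mask)[0]
    if len(tet_idx) == 0:
        raise MeshFileError("no tetrahedra in .vtu file")
    width = offsets[tet_idx[0]] - starts[tet_idx[0]]
    elements = np.stack([conn[starts[i]:offsets[i]] for i in tet_idx])
    region = cell_data.get("region", np.zeros(len(conn)))
    mesh = MeshModel(coords, elements,
                     region[tet_idx].astype(np.int64) if "region" in cell_data
                     else np.zeros(len(tet_idx), dtype=np.int64))

    tri_idx = np.nonzero(tri_mask)[0]
    if len(tri_idx):
        tri_corners = np.stack([conn[starts[i]:starts[i] + 3] for i in tri_idx])
        pairs = _facets_from_triangles(mesh, tri_corners)
        for name, col in cell_data.items():
            if name.startswith("facet:"):
                mesh.facet_sets[name[6:]] = pairs[col[tri_idx] > 0.5]

    fields = {
        name: col[tet_idx]
        for name, col in cell_data.items()
        if name != "region" and not name.startswith("facet:")
    }
    return mesh, fields


# ---------------------------------------------------------------- MSH
def _write_msh(mesh: MeshModel, path: Path, fields: dict[str, np.ndarray]) -> None:
    tri_pairs, membership = _boundary_triangles(mesh)
    set_names = list(mesh.facet_sets)
    lines = ["$MeshFormat", "4.1 0 8", "$EndMeshFormat"]

    # physical groups: surfaces 1..S for facet sets, volumes S+1.. for regions
    regions_present = sorted(set(mesh.element_region.tolist()))
    phys = []
    for i, name in enumerate(set_names):
        phys.append((2, i + 1, f"facet:{name}"))
    vol_phys = {}
    for j, r in enumerate(regions_present):
        tag = len(set_names) + 1 + j
        vol_phys[r] = tag
        phys.append((3, tag, _REGION_NAMES[r]))
    lines += ["$PhysicalNames", str(len(phys))]
    lines += [f'{d} {t} "{n}"' for d, t, n in phys]
    lines.append("$EndPhysicalNames")

    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    bbox = "%.17g %.17g %.17g %.17g %.17g %.17g" % (*lo, *hi)
    lines += ["$Entities", f"0 0 {len(set_names)} {len(regions_present)}"]
    for i, _ in enumerate(set_names):
        lines.append(f"{i + 1} {bbox} 1 {i + 1} 0")
    for r in regions_present:
        lines.append(f"{vol_phys[r]} {bbox} 1 {vol_phys[r]} 0")
    lines.append("$EndEntities")

    n = mesh.n_nodes
    vol_ent = vol_phys[regions_present[0]]
    lines += ["$Nodes", f"1 {n} 1 {n}", f"3 {vol_ent} 0 {n}"]
    lines += [str(i + 1) for i in range(n)]
    lines += ["%.17g %.17g %.17g" % tuple(p) for p in mesh.nodes]
    lines.append("$EndNodes")

    elems = mesh.elements
    if mesh.order == 2:
        elems = elems[:, _VTK_TO_GMSH_TET10]
    tet_type = GMSH_TET4 if mesh.order == 1 else GMSH_TET10
    tri_nodes = mesh.facet_all_nodes(tri_pairs) if len(tri_pairs) else np.empty((0, 3), int)
    tri_type = GMSH_TRI3 if tri_nodes.shape[1] == 3 else GMSH_TRI6

    # element tag = original index + 1, so readers can restore file order
    # even though Gmsh blocks group elements by region entity
    blocks = []
    for r in regions_present:
        idx = np.nonzero(mesh.element_region == r)[0]
        rows = [f"{i + 1} " + " ".join(str(v + 1) for v in elems[i]) for i in idx]
        blocks.append((3, vol_phys[r], tet_type, rows))
    tri_tag0 = mesh.n_elements + 1
    for i, name in enumerate(set_names):
        sel = np.nonzero(membership[name])[0]
        rows = [f"{tri_tag0 + s} " + " ".join(str(v + 1) for v in tri_nodes[s])
                for s in sel]
        blocks.append((2, i + 1, tri_type, rows))
    total = sum(len(b[3]) for b in blocks)
    max_tag = tri_tag0 + len(tri_pairs) - 1 if len(tri_pairs) else mesh.n_elements
    lines += ["$Elements", f"{len(blocks)} {total} 1 {max_tag}"]
    for dim, ent, typ, rows in blocks:
        lines.append(f"{dim} {ent} {typ} {len(rows)}")
        lines += rows
    lines.append("$EndElements")

    tet_tags = np.arange(1, mesh.n_elements + 1)
    for name, values in fields.items():
        vals = np.asarray(values, dtype=float)
        lines += ["$ElementData", "1", f'"{name}"', "1", "0", "3", "0", "1",
                  str(mesh.n_elements)]
        lines += [f"{tet_tags[i]} %.17g" % vals[i] for i in range(mesh.n_elements)]
        lines.append("$EndElementData")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_msh(path: Path) -> tuple[MeshModel, dict[str, np.ndarray]]:
    text = Path(path).read_text().splitlines()
    sections: dict[str, list[list[str]]] = {}
    i = 0
    while i < len(text):
        line = text[i].strip()
        if line.startswith("$") and not line.startswith("$End"):
            name = line[1:]
            j = i + 1
            body = []
            while j < len(text) and text[j].strip() != f"$End{name}":
                body.append(text[j])
                j += 1
            if j == len(text):
                raise MeshFileError(f"unterminated section ${name}")
            sections.setdefault(name, []).append(body)
            i = j + 1
        else:
            i += 1
    if "MeshFormat" not in sections or "Nodes" not in sections:
        raise MeshFileError("not a Gmsh .msh file")

    phys_names = {}
    if "PhysicalNames" in sections:
        body = sections["PhysicalNames"][0]
        for line in body[1:]:
            parts = line.split(maxsplit=2)
            phys_names[(int(parts[0]), int(parts[1]))] = parts[2].strip().strip('"')

    ent_phys = {}  # (dim, entity tag) -> physical tag
    if "Entities" in sections:
        body = sections["Entities"][0]
        np_, nc, ns, nv = map(int, body[0].split())
        row = 1 + np_ + nc
        for dim, count in ((2, ns), (3, nv)):
            for _ in range(count):
                parts = body[row].split()
                tag = int(parts[0])
                n_phys = int(parts[7])
                if n_phys:
                    ent_phys[(dim, tag)] = int(parts[8])
                row += 1

    body = sections["Nodes"][0]
    n_blocks, n_nodes = int(body[0].split()[0]), int(body[0].split()[1])
    node_map, coords = {}, []
    row = 1
    for _ in range(n_blocks):
        cnt = int(body[row].split()[3])
        tags = [int(body[row + 1 + k]) for k in range(cnt)]
        for k in range(cnt):
            node_map[tags[k]] = len(coords)
            coords.append([float(x) for x in body[row + 1 + cnt + k].split()[:3]])
        row += 1 + 2 * cnt

    body = sections["Elements"][0]
    n_blocks = int(body[0].split()[0])
    row = 1
    tets, tet_regions, tet_tags = [], [], []
    tris, tri_sets = [], []
    for _ in range(n_blocks):
        dim, ent, typ, cnt = map(int, body[row].split())
        phys = ent_phys.get((dim, ent))
        name = phys_names.get((dim, phys), "") if phys else ""
        for k in range(cnt):
            parts = [int(x) for x in body[row + 1 + k].split()]
            nodes = [node_map[t] for t in parts[1:]]
            if typ in (GMSH_TET4, GMSH_TET10):
                if typ == GMSH_TET10:
                    nodes = [nodes[c] for c in _VTK_TO_GMSH_TET10]  # involution
                tets.append(nodes)
                tet_tags.append(parts[0])
                tet_regions.append(_REGION_IDS.get(name, REGION_BONE))
            elif typ in (GMSH_TRI3, GMSH_TRI6):
                tris.append(nodes[:3])
                tri_sets.append(name[6:] if name.startswith("facet:") else name)
            else:
                raise MeshFileError(f"unsupported Gmsh element type {typ}")
        row += 1 + cnt
    if not tets:
        raise MeshFileError("no tetrahedra in .msh file")
    order = np.argsort(tet_tags)  # restore tag order
    mesh = MeshModel(np.array(coords), np.array(tets, dtype=np.int64)[order],
                     np.array(tet_regions, dtype=np.int64)[order])
    if tris:
        pairs = _facets_from_triangles(mesh, np.array(tris, dtype=np.int64))
        for name in sorted(set(tri_sets)):
            sel = [k for k, s in enumerate(tri_sets) if s == name]
            mesh.facet_sets[name] = pairs[sel]

    fields = {}
    tag_to_idx = {t: i for i, t in enumerate(np.array(tet_tags)[order].tolist())}
    for body in sections.get("ElementData", []):
        n_str = int(body[0])
        name = body[1].strip().strip('"')
        n_real = int(body[1 + n_str])
        n_int_at = 2 + n_str + n_real
        n_int = int(body[n_int_at])
        n_entries = int(body[n_int_at + n_int])
        vals = np.full(mesh.n_elements, np.nan)
        for line in body[n_int_at + n_int + 1: n_int_at + n_int + 1 + n_entries]:
            t, v = line.split()
            vals[tag_to_idx[int(t)]] = float(v)
        fields[name] = vals
    return mesh, fields
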