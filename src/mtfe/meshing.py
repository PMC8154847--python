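"""Mesh construction for voxel-based micro-FE.

Voxel masks become 8-node hexahedral (HEX8) meshes, one element per bone
voxel, with nodes deduplicated on the integer corner lattice.  Externally
generated 10-node tetrahedral (TET10) meshes are read from Abaqus INP
(C3D10) or legacy VTK; a deterministic 6-tet subdivision of the hex mesh is
provided so the TET10 solver can be exercised on the same geometry.

Node ordering
-------------
HEX8 follows the usual counter-clockwise-bottom-then-top convention
(Abaqus C3D8 / VTK hexahedron): in unit-cube coordinates

    0:(0,0,0) 1:(1,0,0) 2:(1,1,0) 3:(0,1,0)
    4:(0,0,1) 5:(1,0,1) 6:(1,1,1) 7:(0,1,1)

TET10 follows Abaqus C3D10: 4 corners then mid-edge nodes on edges
(0-1), (1-2), (2-0), (0-3), (1-3), (2-3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .image_io import VoxelImage

__all__ = [
    "HexMesh",
    "TetMesh",
    "voxels_to_hex_mesh",
    "hex_to_tet_subdivide",
    "read_tet_mesh",
    "read_mesh_inp",
    "write_mesh_inp",
    "write_mesh_vtk",
    "read_mesh_vtk",
    "tet_volumes",
]

# corner offsets (i, j, k) in the HEX8 ordering above
_HEX_CORNERS = np.array(
    [
        (0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0),
        (0, 0, 1), (1, 0, 1), (1, 1, 1), (0, 1, 1),
    ],
    dtype=np.int64,
)

# 6-tet decomposition of the cube, every tet sharing the 0-6 main diagonal.
# Because the diagonal choice is the same in every cube, triangulations of
# shared faces between adjacent cubes are compatible (conforming mesh).
_CUBE_TETS = np.array(
    [
        (0, 1, 2, 6),
        (0, 2, 3, 6),
        (0, 3, 7, 6),
        (0, 7, 4, 6),
        (0, 4, 5, 6),
        (0, 5, 1, 6),
    ],
    dtype=np.int64,
)

# C3D10 mid-edge node ↔ corner pairs
_TET_EDGES = np.array(
    [(0, 1), (1, 2), (2, 0), (0, 3), (1, 3), (2, 3)], dtype=np.int64
)


@dataclass
class HexMesh:
    """Voxel-conforming hexahedral mesh (one cube per bone voxel)."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 8) node indices
    spacing: float  # cube edge, mm
    voxel_index_of_element: np.ndarray | None = None  # (M, 3) source voxel ijk

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 8:
            raise ValueError("HexMesh elements must be (M, 8)")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise ValueError("element refers to a node out of range")

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)

    def total_volume(self) -> float:
        return self.n_elements * self.spacing ** 3


@dataclass
class TetMesh:
    """Quadratic (10-node) tetrahedral mesh."""

    nodes: np.ndarray  # (N, 3) mm
    elements: np.ndarray  # (M, 10) node indices
    element_volume: np.ndarray = None  # (M,) mm³
    voxel_index_of_element: np.ndarray | None = None  # (M, 3) if voxel-derived

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.elements = np.asarray(self.elements, dtype=np.int64)
        if self.elements.ndim != 2 or self.elements.shape[1] != 10:
            raise ValueError("TetMesh elements must be (M, 10)")
        if self.element_volume is None:
            self.element_volume = tet_volumes(self.nodes, self.elements)
        else:
            self.element_volume = np.asarray(self.element_volume, dtype=float)

    @property
    def n_nodes(self):
        return len(self.nodes)

    @property
    def n_elements(self):
        return len(self.elements)

    def total_volume(self) -> float:
        return float(self.element_volume.sum())


def tet_volumes(nodes, elements) -> np.ndarray:
    """Signed volumes of the corner tetrahedra (first 4 nodes of each)."""
    p = nodes[elements[:, :4]]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0


# ---------------------------------------------------------------------------
# voxel → HEX8


def voxels_to_hex_mesh(mask: VoxelImage, origin=None) -> HexMesh:
    """Convert every masked voxel into one hexahedral element.

    Nodes are deduplicated on the integer corner lattice so face-adjacent
    voxels share 4 nodes.  Element order is lexicographic by (k, j, i)
    (z-slowest source ordering is flattened z-major so slices stay
    contiguous); node order is lexicographic by corner (k, j, i).  The
    output is fully deterministic: identical masks give identical meshes.
    """
    if mask.value_kind != "mask":
        raise ValueError(f"expected a mask image, got {mask.value_kind!r}")
    sel = np.argwhere(mask.data.astype(bool))
    if len(sel) == 0:
        raise ValueError("empty mask: nothing to mesh")
    # sort voxels by (k, j, i)
    order = np.lexsort((sel[:, 0], sel[:, 1], sel[:, 2]))
    sel = sel[order]

    nx, ny, nz = mask.shape
    # corner lattice has (nx+1, ny+1, nz+1) sites; encode (i,j,k) -> key
    corners = sel[:, None, :] + _HEX_CORNERS[None, :, :]  # (M, 8, 3)
    key = (
        corners[..., 2] * (ny + 1) + corners[..., 1]
    ) * (nx + 1) + corners[..., 0]  # k-major so node order is (k, j, i)-lexicographic
    uniq, inv = np.unique(key, return_inverse=True)
    elements = inv.reshape(-1, 8)

    kk, rem = np.divmod(uniq, (nx + 1) * (ny + 1))
    jj, ii = np.divmod(rem, nx + 1)
    h = mask.spacing
    base = np.asarray(origin, dtype=float) if origin is not None else mask.origin
    nodes = np.stack([ii, jj, kk], axis=1).astype(float) * h + base

    return HexMesh(
        nodes=nodes,
        elements=elements,
        spacing=h,
        voxel_index_of_element=sel.copy(),
    )


# ---------------------------------------------------------------------------
# HEX8 → TET10 subdivision


def hex_to_tet_subdivide(hex_mesh: HexMesh) -> TetMesh:
    """Split each cube into 6 linear tets sharing the main diagonal, then
    upgrade to TET10 by inserting deduplicated mid-edge nodes.

    Total tet volume equals total hex volume exactly (the 6 tets tile the
    cube), and adjacent cubes' shared faces triangulate compatibly because
    every cube uses the same diagonal.
    """
    corners = hex_mesh.elements[:, _CUBE_TETS]  # (M, 6, 4)
    tets4 = corners.reshape(-1, 4).copy()
    # fix orientation: tets with negative volume get corners 1,2 swapped
    vols = tet_volumes(hex_mesh.nodes, tets4)
    neg = vols < 0
    if np.any(neg):
        tets4[neg] = tets4[neg][:, [0, 2, 1, 3]]

    # mid-edge nodes, deduplicated by sorted corner pair
    pairs = tets4[:, _TET_EDGES]  # (T, 6, 2)
    pairs_sorted = np.sort(pairs.reshape(-1, 2), axis=1)
    uniq_pairs, inv = np.unique(pairs_sorted, axis=0, return_inverse=True)
    n0 = hex_mesh.n_nodes
    mid_nodes = 0.5 * (
        hex_mesh.nodes[uniq_pairs[:, 0]] + hex_mesh.nodes[uniq_pairs[:, 1]]
    )
    mid_idx = (n0 + inv).reshape(-1, 6)

    elements = np.hstack([tets4, mid_idx])
    nodes = np.vstack([hex_mesh.nodes, mid_nodes])
    voxels = (
        np.repeat(hex_mesh.voxel_index_of_element, 6, axis=0)
        if hex_mesh.voxel_index_of_element is not None
        else None
    )
    return TetMesh(nodes=nodes, elements=elements, voxel_index_of_element=voxels)


# ---------------------------------------------------------------------------
# Abaqus INP / legacy VTK I/O (plain-text, deterministic)


def write_mesh_inp(mesh, path, element_E=None) -> None:
    """Write a HexMesh (C3D8) or TetMesh (C3D10) as an Abaqus INP file.

    If ``element_E`` is given, elements are grouped into per-modulus sets
    with *MATERIAL/*SOLID SECTION blocks.
    """
    is_hex = isinstance(mesh, HexMesh)
    eltype = "C3D8" if is_hex else "C3D10"
    lines = [
        "*HEADING",
        f"mtfe mesh: {eltype}, node ordering counter-clockwise bottom then top"
        if is_hex
        else f"mtfe mesh: {eltype}, corners then mid-edges (0-1,1-2,2-0,0-3,1-3,2-3)",
        "*NODE",
    ]
    for n, (x, y, z) in enumerate(mesh.nodes, start=1):
        lines.append(f"{n}, {x:.9g}, {y:.9g}, {z:.9g}")
    lines.append(f"*ELEMENT, TYPE={eltype}")
    for e, conn in enumerate(mesh.elements, start=1):
        lines.append(f"{e}, " + ", ".join(str(c + 1) for c in conn))
    if element_E is not None:
        element_E = np.asarray(element_E, dtype=float)
        uniq = np.unique(element_E)
        for m, E in enumerate(uniq, start=1):
            els = np.nonzero(element_E == E)[0] + 1
            lines.append(f"*ELSET, ELSET=MAT{m}")
            for i in range(0, len(els), 16):
                lines.append(", ".join(map(str, els[i: i + 16])))
            lines.append(f"*MATERIAL, NAME=MAT{m}")
            lines.append("*ELASTIC")
            lines.append(f"{E:.9g}, 0.3")
            lines.append(f"*SOLID SECTION, ELSET=MAT{m}, MATERIAL=MAT{m}")
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def _parse_inp(path):
    nodes = {}
    elements = []
    eltype = None
    section = None
    pending = []

    def flush_pending():
        if pending:
            elements.append(pending.copy())
            pending.clear()

    with open(path) as f:
        for raw in f:
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                flush_pending()
                kw = line.split(",")[0].strip().upper()
                if kw == "*NODE":
                    section = "node"
                elif kw == "*ELEMENT":
                    section = "element"
                    for part in line.split(",")[1:]:
                        k, _, v = part.partition("=")
                        if k.strip().upper() == "TYPE":
                            eltype = v.strip().upper()
                else:
                    section = None
                continue
            if section == "node":
                parts = [p for p in line.split(",") if p.strip()]
                nodes[int(parts[0])] = [float(p) for p in parts[1:4]]
            elif section == "element":
                vals = [int(p) for p in line.split(",") if p.strip()]
                if not pending:
                    pending.extend(vals)
                else:
                    pending.extend(vals)
                want = 11  # element id + 10 nodes for C3D10
                if eltype == "C3D8":
                    want = 9
                if len(pending) >= want:
                    elements.append(pending[:want])
                    del pending[:want]
    flush_pending()
    return nodes, elements, eltype


def read_mesh_inp(path):
    """Read an Abaqus INP mesh: C3D8 gives a :class:`HexMesh` (edge length
    inferred from the first element), C3D10 a :class:`TetMesh`."""
    node_map, element_rows, eltype = _parse_inp(path)
    if eltype == "C3D10":
        return read_tet_mesh(path)
    if eltype != "C3D8":
        raise ValueError(f"unsupported element type {eltype!r}")
    ids = sorted(node_map)
    remap = {nid: i for i, nid in enumerate(ids)}
    nodes = np.array([node_map[nid] for nid in ids], dtype=float)
    elements = np.array(
        [[remap[n] for n in row[1:9]] for row in element_rows], dtype=np.int64
    )
    edge = float(np.linalg.norm(nodes[elements[0, 1]] - nodes[elements[0, 0]]))
    return HexMesh(nodes=nodes, elements=elements, spacing=edge)


def read_tet_mesh(path) -> TetMesh:
    """Read a quadratic tetrahedral mesh from Abaqus INP (C3D10) or a
    legacy-VTK unstructured grid.

    Elements with negative corner-tet volume are reoriented (corners 1,2
    swapped together with their opposing mid-edge nodes) with a warning;
    zero-volume slivers are an error.
    """
    path = str(path)
    if path.lower().endswith(".vtk"):
        nodes, elements = read_mesh_vtk(path)
        if elements.shape[1] != 10:
            raise ValueError("VTK file does not contain quadratic tetrahedra")
    else:
        node_map, element_rows, eltype = _parse_inp(path)
        if eltype != "C3D10":
            raise ValueError(f"unsupported element type {eltype!r} (need C3D10)")
        ids = sorted(node_map)
        remap = {nid: i for i, nid in enumerate(ids)}
        nodes = np.array([node_map[nid] for nid in ids], dtype=float)
        elements = np.array(
            [[remap[n] for n in row[1:11]] for row in element_rows], dtype=np.int64
        )

    vols = tet_volumes(nodes, elements)
    zero = np.abs(vols) < 1e-18
    if np.any(zero):
        raise ValueError(
            f"zero-volume tetrahedra at element(s) {np.nonzero(zero)[0].tolist()}"
        )
    neg = vols < 0
    if np.any(neg):
        warnings.warn(
            f"reoriented {int(neg.sum())} inverted tetrahedra", stacklevel=2
        )
        fixed = elements.copy()
        # swap corners 1<->2; mid-edges: (0-1)<->(2-0), (1-3)<->(2-3)
        fixed[neg] = elements[neg][:, [0, 2, 1, 3, 6, 5, 4, 7, 9, 8]]
        elements = fixed
    return TetMesh(nodes=nodes, elements=elements)


_VTK_CELLTYPE = {8: 12, 10: 24}  # VTK_HEXAHEDRON, VTK_QUADRATIC_TETRA


def write_mesh_vtk(mesh, path, point_data=None, cell_data=None) -> None:
    """Write a mesh as a legacy-VTK (ASCII) unstructured grid, with optional
    point/cell scalar or vector data arrays."""
    conn = mesh.elements
    npe = conn.shape[1]
    lines = [
        "# vtk DataFile Version 3.0",
        "mtfe unstructured grid",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {len(mesh.nodes)} double",
    ]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in mesh.nodes]
    lines.append(f"CELLS {len(conn)} {len(conn) * (npe + 1)}")
    lines += [f"{npe} " + " ".join(map(str, row)) for row in conn]
    lines.append(f"CELL_TYPES {len(conn)}")
    lines += [str(_VTK_CELLTYPE[npe])] * len(conn)

    def emit(block, name, arr):
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 1:
            block.append(f"SCALARS {name} double 1")
            block.append("LOOKUP_TABLE default")
            block += [f"{v:.9g}" for v in arr]
        else:
            block.append(f"VECTORS {name} double")
            block += [" ".join(f"{v:.9g}" for v in row) for row in arr]

    if point_data:
        lines.append(f"POINT_DATA {len(mesh.nodes)}")
        for name, arr in point_data.items():
            emit(lines, name, arr)
    if cell_data:
        lines.append(f"CELL_DATA {len(conn)}")
        for name, arr in cell_data.items():
            emit(lines, name, arr)
    with open(path, "w") as f:
        f.write("\n".join(lines) + "\n")


def read_mesh_vtk(path):
    """Read points and cells of a legacy ASCII VTK unstructured grid."""
    with open(path) as f:
        tokens = f.read().split()
    it = iter(range(len(tokens)))
    i = 0

    def find(word):
        nonlocal i
        while tokens[i].upper() != word:
            i += 1
        return i

    find("POINTS")
    n_pts = int(tokens[i + 1])
    start = i + 3
    pts = np.array(tokens[start: start + 3 * n_pts], dtype=float).reshape(-1, 3)
    i = start + 3 * n_pts
    find("CELLS")
    n_cells = int(tokens[i + 1])
    total = int(tokens[i + 2])
    start = i + 3
    flat = np.array(tokens[start: start + total], dtype=np.int64)
    npe = int(flat[0])
    cells = flat.reshape(n_cells, npe + 1)[:, 1:]
    return pts, cells
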