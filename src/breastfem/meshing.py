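"""Hexahedral mesh generation from voxel label maps.

The breast volume is meshed with a structured grid of 8-node hexahedra
(voxel "sugar-cube" meshing): each cell of an axis-aligned lattice at the
requested element size becomes one element when the majority of the voxels
it covers belong to the breast.  Hexahedra were preferred over tetrahedra
for efficiency at equal node count.  :func:`add_skin_layer` extrudes an
optional layer of thin solid skin hexahedra from the free surface — the
solver's default skin treatment is a surface membrane instead (see
:mod:`breastfem.fem`), which needs no extrusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .volume import LabelMap, Label

__all__ = ["HexMesh", "voxel_to_hex_mesh", "add_skin_layer", "mesh_convergence_check",
           "write_vtk", "TISSUE_ADIPOSE", "TISSUE_FIBROGLANDULAR", "TISSUE_SKIN"]

TISSUE_ADIPOSE = 1
TISSUE_FIBROGLANDULAR = 2
TISSUE_SKIN = 3

TISSUE_NAMES = {TISSUE_ADIPOSE: "adipose", TISSUE_FIBROGLANDULAR: "fibroglandular",
                TISSUE_SKIN: "skin"}

# local corner offsets in lattice steps, VTK_HEXAHEDRON ordering:
# bottom face counter-clockwise, then top face
_CORNERS = np.array([
    [0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
    [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1],
], dtype=np.int64)

# local faces of a hex (outward-ordered corner quadruples)
_FACES = np.array([
    [0, 3, 2, 1],   # -z
    [4, 5, 6, 7],   # +z
    [0, 1, 5, 4],   # -y
    [3, 7, 6, 2],   # +y
    [0, 4, 7, 3],   # -x
    [1, 2, 6, 5],   # +x
])


@dataclass
class HexMesh:
    """8-node hexahedral mesh with tissue tags and anatomical node sets.

    Attributes
    ----------
    nodes : (N, 3) float array, world mm
    elements : (M, 8) int array, VTK hexahedron corner ordering
    element_tissue : (M,) int array with tissue codes
        (1 adipose, 2 fibro-glandular, 3 skin)
    surface_facets : (F, 4) int array
        Outward-ordered quads on the free breast surface (chest-wall face
        excluded).
    chest_wall_nodes : (C,) int array of node indices on the chest-wall plane
    nipple_node : int
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_tissue: np.ndarray
    surface_facets: np.ndarray
    chest_wall_nodes: np.ndarray
    nipple_node: int = -1
    ap_axis: int = 1  # anteroposterior world axis index
    element_size: float = 0.0
    # integer lattice coordinates per node (set by voxel_to_hex_mesh; skin
    # nodes inherit the coordinates of their base surface node).  Purely
    # topological, so they stay valid when node positions are updated
    # (reference-state estimation); used by the solver's coarse-grid
    # preconditioner.
    lattice_coords: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_volumes(self) -> np.ndarray:
        """Exact volume of each (possibly distorted) trilinear hexahedron."""
        from .fem import _shape_gradients_natural, _GAUSS_8

        X = self.nodes[self.elements]  # (M, 8, 3)
        vol = np.zeros(len(X))
        for xi, w in zip(*_GAUSS_8):
            dN = _shape_gradients_natural(xi)  # (8, 3)
            J = np.einsum("maI,aj->mIj", X, dN)
            vol += w * np.linalg.det(J)
        return vol

    def jacobians_positive(self) -> bool:
        """True when every element has positive Jacobian at all Gauss points."""
        from .fem import _shape_gradients_natural, _GAUSS_8

        X = self.nodes[self.elements]
        for xi, _ in zip(*_GAUSS_8):
            dN = _shape_gradients_natural(xi)
            J = np.einsum("maI,aj->mIj", X, dN)
            if not (np.linalg.det(J) > 0).all():
                return False
        return True

    def surface_node_set(self) -> np.ndarray:
        return np.unique(self.surface_facets)


def voxel_to_hex_mesh(labels: LabelMap, element_size: float, ap_axis: int = 1,
                      nipple_mm: np.ndarray | None = None) -> HexMesh:
    """Mesh the breast region of a label map with structured hexahedra.

    An axis-aligned lattice with step ``element_size`` is laid over the
    bounding box of the breast voxels (labels adipose / fibro-glandular /
    lesion).  A lattice cell becomes an element when at least half of the
    voxels it covers are breast; its tissue tag is the majority label among
    those voxels, ties broken toward fibro-glandular (the stiffer tissue).
    Lesion voxels count as fibro-glandular for the mechanics.

    The lattice is anchored so that a node plane coincides with the posterior
    breast boundary (the chest wall); nodes on that plane form
    ``chest_wall_nodes``.

    Parameters
    ----------
    labels : LabelMap
    element_size : float, mm — must be at least the voxel spacing
    ap_axis : world axis pointing anterior (breast protrudes toward +axis)
    nipple_mm : optional landmark; the nearest surface node becomes
        ``nipple_node``.
    """
    sp = labels.spacing
    if element_size < min(sp) - 1e-9:
        raise ValueError(
            f"element_size {element_size} mm is below the voxel spacing {sp}")
    breast = np.isin(labels.data, (Label.ADIPOSE, Label.FIBROGLANDULAR, Label.LESION))
    if not breast.any():
        raise ValueError("label map contains no breast tissue")

    idx = np.argwhere(breast)                       # (V, 3) voxel indices
    pts = labels.origin + idx * sp                  # world coords of centers
    lab = labels.data[tuple(idx.T)]

    lo = pts.min(axis=0)
    h = float(element_size)
    # cell index of each breast voxel; clamp upper-boundary points into range
    ci = np.floor((pts - lo) / h + 1e-9).astype(np.int64)
    ncell = ci.max(axis=0) + 1
    flat = np.ravel_multi_index(tuple(ci.T), tuple(ncell))
    ncells = int(np.prod(ncell))

    # per-cell voxel counts: total in bounding region, breast, adipose
    # total count uses all voxels of the full map falling inside the lattice
    all_idx = np.indices(labels.data.shape).reshape(3, -1).T
    all_pts = labels.origin + all_idx * sp
    inside = np.all((all_pts >= lo - sp / 2) & (all_pts < lo + ncell * h - sp / 2 + 1e-9), axis=1)
    aci = np.floor((all_pts[inside] - lo) / h + 1e-9).astype(np.int64)
    np.minimum(aci, ncell - 1, out=aci)
    aflat = np.ravel_multi_index(tuple(aci.T), tuple(ncell))
    total = np.bincount(aflat, minlength=ncells)

    breast_ct = np.bincount(flat, minlength=ncells)
    adipose_ct = np.bincount(flat[lab == Label.ADIPOSE], minlength=ncells)

    occupied = breast_ct >= np.maximum(total, 1) * 0.5
    occupied &= breast_ct > 0
    if not occupied.any():
        raise ValueError("no lattice cell is majority breast; mesh is empty")

    cells = np.argwhere(occupied.reshape(tuple(ncell)))       # (M, 3)
    gland_ct = breast_ct - adipose_ct
    occ_flat = np.ravel_multi_index(tuple(cells.T), tuple(ncell))
    tissue = np.where(adipose_ct[occ_flat] > gland_ct[occ_flat],
                      TISSUE_ADIPOSE, TISSUE_FIBROGLANDULAR)

    # node lattice: unique corner lattice coordinates
    corners = cells[:, None, :] + _CORNERS[None, :, :]        # (M, 8, 3)
    corner_flat = np.ravel_multi_index(
        tuple(corners.reshape(-1, 3).T), tuple(ncell + 1))
    uniq, inv = np.unique(corner_flat, return_inverse=True)
    elements = inv.reshape(-1, 8).astype(np.int64)
    node_lattice = np.stack(np.unravel_index(uniq, tuple(ncell + 1)), axis=1)
    nodes = lo + node_lattice * h

    mesh = HexMesh(nodes=nodes, elements=elements,
                   element_tissue=tissue.astype(np.int64),
                   surface_facets=np.empty((0, 4), dtype=np.int64),
                   chest_wall_nodes=np.empty(0, dtype=np.int64),
                   ap_axis=ap_axis, element_size=h,
                   lattice_coords=node_lattice.astype(np.int64))
    mesh.surface_facets, wall_facets = _boundary_facets(mesh)
    wall_y = nodes[:, ap_axis].min()
    mesh.chest_wall_nodes = np.flatnonzero(
        np.abs(nodes[:, ap_axis] - wall_y) < h / 4)
    # drop wall-plane facets from the free surface
    on_wall = np.isin(mesh.surface_facets, mesh.chest_wall_nodes).all(axis=1)
    mesh.surface_facets = mesh.surface_facets[~on_wall]

    if nipple_mm is not None:
        surf = mesh.surface_node_set()
        d = np.linalg.norm(nodes[surf] - np.asarray(nipple_mm, float), axis=1)
        mesh.nipple_node = int(surf[np.argmin(d)])
    return mesh


def _boundary_facets(mesh: HexMesh) -> tuple[np.ndarray, np.ndarray]:
    """Facets belonging to exactly one element (outward-ordered)."""
    quads = mesh.elements[:, _FACES]                  # (M, 6, 4)
    quads = quads.reshape(-1, 4)
    key = np.sort(quads, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    boundary = quads[first[counts == 1]]
    return boundary.astype(np.int64), np.empty((0, 4), dtype=np.int64)


def add_skin_layer(mesh: HexMesh, thickness: float = 1.0) -> HexMesh:
    """Extrude one layer of thin solid hexahedra outward from the free surface.

    The skin is represented by solid trilinear elements of the given
    thickness (default 1 mm) sharing nodes with the underlying tissue so
    the layer is conformal; they carry the same hyperelastic law with the
    skin material parameters.  Offset nodes closer than ``thickness / 4``
    (concave stair-step corners) are merged, with a warning.
    """
    if thickness == 0.0:
        return mesh
    if len(mesh.surface_facets) == 0:
        raise ValueError("mesh has no free-surface facets to extrude")

    nodes = mesh.nodes
    facets = mesh.surface_facets
    # facet normals (planar quads on the voxel surface)
    v1 = nodes[facets[:, 1]] - nodes[facets[:, 0]]
    v2 = nodes[facets[:, 3]] - nodes[facets[:, 0]]
    fn = np.cross(v1, v2)
    fn /= np.linalg.norm(fn, axis=1, keepdims=True)

    surf_nodes = np.unique(facets)
    remap = np.full(mesh.n_nodes, -1, dtype=np.int64)
    remap[surf_nodes] = np.arange(len(surf_nodes))
    nn = np.zeros((len(surf_nodes), 3))
    np.add.at(nn, remap[facets].ravel(), np.repeat(fn, 4, axis=0))
    nn /= np.linalg.norm(nn, axis=1, keepdims=True)
    # scale the offset so adjacent faces move by ~the full thickness: the
    # averaged normal at stair-step edges/corners is oblique to every face,
    # which would otherwise thin the layer there
    cos_sum = np.zeros(len(surf_nodes))
    cos_cnt = np.zeros(len(surf_nodes))
    dots = np.einsum("fi,fci->fc", fn, nn[remap[facets]])
    np.add.at(cos_sum, remap[facets].ravel(), dots.ravel())
    np.add.at(cos_cnt, remap[facets].ravel(), 1.0)
    scale = 1.0 / np.clip(cos_sum / cos_cnt, 0.5, 1.0)

    new_pts = nodes[surf_nodes] + thickness * scale[:, None] * nn
    # merge offset nodes that collapsed together at concavities
    tree = cKDTree(new_pts)
    pairs = tree.query_pairs(thickness / 4, output_type="ndarray")
    parent = np.arange(len(new_pts))
    if len(pairs):
        warnings.warn(f"skin extrusion merged {len(pairs)} close node pair(s) "
                      "at concave corners")
        for a, b in pairs:
            ra, rb = _find(parent, a), _find(parent, b)
            if ra != rb:
                parent[max(ra, rb)] = min(ra, rb)
        roots = np.array([_find(parent, i) for i in range(len(new_pts))])
        uniq_roots, inv = np.unique(roots, return_inverse=True)
        merged = np.zeros((len(uniq_roots), 3))
        cnt = np.bincount(inv)
        np.add.at(merged, inv, new_pts)
        new_pts = merged / cnt[:, None]
        offset_id = inv
    else:
        offset_id = np.arange(len(new_pts))

    base = mesh.n_nodes
    all_nodes = np.vstack([nodes, new_pts])
    top = base + offset_id[remap[facets]]            # (F, 4)
    skin_elems = np.hstack([facets, top])
    elements = np.vstack([mesh.elements, skin_elems])
    tissue = np.concatenate([mesh.element_tissue,
                             np.full(len(skin_elems), TISSUE_SKIN, dtype=np.int64)])
    new_facets = np.column_stack([top[:, 0], top[:, 1], top[:, 2], top[:, 3]])

    out = HexMesh(nodes=all_nodes, elements=elements, element_tissue=tissue,
                  surface_facets=new_facets,
                  chest_wall_nodes=mesh.chest_wall_nodes,
                  nipple_node=mesh.nipple_node, ap_axis=mesh.ap_axis,
                  element_size=mesh.element_size)
    if mesh.lattice_coords is not None:
        # skin offset nodes adopt the lattice coordinates of the surface
        # node group they were extruded from
        skin_lc = np.zeros((len(new_pts), 3), dtype=np.int64)
        skin_lc[offset_id[remap[surf_nodes]]] = mesh.lattice_coords[surf_nodes]
        out.lattice_coords = np.vstack([mesh.lattice_coords, skin_lc])
    if out.nipple_node >= 0:
        # keep the nipple on the outer (skin) surface
        surf = out.surface_node_set()
        d = np.linalg.norm(all_nodes[surf] - all_nodes[mesh.nipple_node], axis=1)
        out.nipple_node = int(surf[np.argmin(d)])
    return out


def _find(parent: np.ndarray, i: int) -> int:
    while parent[i] != i:
        parent[i] = parent[parent[i]]
        i = parent[i]
    return int(i)


def mesh_convergence_check(labels: LabelMap, materials, fem_config, sizes,
                           nipple_mm=None, criterion: float = 0.02) -> dict:
    """Mesh-refinement study of the prone-gravity solve.

    Runs the gravity solve at each element size (descending) and reports the
    relative change in nipple-displacement magnitude and in the 95th
    percentile of surface displacement between successive refinements.  The
    coarsest size whose change against the next refinement is within the
    criterion (default 2%) is flagged as converged.
    """
    from . import fem as _fem

    sizes = list(sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two element sizes")
    if any(b > a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be descending")

    rows = []
    for h in sizes:
        try:
            mesh = voxel_to_hex_mesh(labels, h, nipple_mm=nipple_mm)
            bc = _fem.BoundaryConditions.prone(mesh)
            u = _fem.solve_gravity(mesh, materials, bc, fem_config)
            mag = np.linalg.norm(u.u, axis=1)
            rows.append({
                "size": h,
                "nipple_disp": float(np.linalg.norm(u.u[mesh.nipple_node]))
                if mesh.nipple_node >= 0 else float(mag.max()),
                "surf_p95": float(np.percentile(mag[mesh.surface_node_set()], 95)),
                "n_elements": mesh.n_elements,
                "failed": False,
            })
        except Exception as exc:  # partial report on solver failure
            rows.append({"size": h, "failed": True, "error": str(exc)})

    changes = []
    ok_rows = [r for r in rows if not r["failed"]]
    for a, b in zip(ok_rows, ok_rows[1:]):
        changes.append({
            "sizes": (a["size"], b["size"]),
            "rel_change_nipple": abs(a["nipple_disp"] - b["nipple_disp"])
            / max(abs(b["nipple_disp"]), 1e-30),
            "rel_change_surf_p95": abs(a["surf_p95"] - b["surf_p95"])
            / max(abs(b["surf_p95"]), 1e-30),
        })
    converged_size = None
    for ch in changes:
        if ch["rel_change_nipple"] <= criterion:
            converged_size = ch["sizes"][0]
            break
    return {"runs": rows, "changes": changes, "criterion": criterion,
            "converged_size": converged_size}


def write_vtk(mesh: HexMesh, path, point_data: dict | None = None) -> None:
    """Write the mesh as legacy ASCII VTK (unstructured grid)."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nbreastfem hexahedral mesh\n"
                "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        m = mesh.n_elements
        f.write(f"CELLS {m} {m * 9}\n")
        np.savetxt(f, np.hstack([np.full((m, 1), 8, dtype=np.int64), mesh.elements]),
                   fmt="%d")
        f.write(f"CELL_TYPES {m}\n")
        np.savetxt(f, np.full(m, 12, dtype=np.int64), fmt="%d")
        f.write(f"CELL_DATA {m}\nSCALARS tissue int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, mesh.element_tissue, fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9g")
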