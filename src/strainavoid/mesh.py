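"""Tagged structured finite-element meshes.

All meshes in this package are conforming tensor-product grids of
axis-aligned quadrilaterals (2D) or hexahedra (3D), in millimetres.
Material-region boundaries are snapped onto grid lines, so region tags
partition the element set exactly and mesh volume equals solid volume.

Every element carries exactly one region tag (a string such as
``"pdms"``, ``"hydrogel"``, ``"cell_layer"``); every exterior facet
carries exactly one boundary tag (``"clamped_end"``, ``"moving_end"``,
``"groove_sidewall"``, ``"groove_bottom"`` or ``"free"``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Mesh",
    "coords1d",
    "structured_mesh",
    "write_vtk",
    "write_msh",
    "read_msh",
    "read_vtk",
]

# local node orderings of element boundary facets (consistent with the
# lexicographic corner ordering used by `structured_mesh`)
_QUAD_EDGES = ((0, 1), (1, 2), (2, 3), (3, 0))
_HEX_FACES = (
    (0, 3, 2, 1),  # bottom (z-)
    (4, 5, 6, 7),  # top (z+)
    (0, 1, 5, 4),  # y-
    (3, 7, 6, 2),  # y+
    (0, 4, 7, 3),  # x-
    (1, 2, 6, 5),  # x+
)

TAG_DTYPE = "<U24"


class MeshingError(RuntimeError):
    """Raised when a mesh cannot be generated for the given geometry."""


@dataclass
class Mesh:
    """Conforming mesh with element region tags and exterior facet tags."""

    nodes: np.ndarray       # (n_nodes, dim) coordinates in mm
    elems: np.ndarray       # (n_elems, 4 | 8) connectivity
    regions: np.ndarray     # (n_elems,) region tag per element
    facets: np.ndarray      # (n_facets, 2 | 4) exterior facet connectivity
    facet_tags: np.ndarray  # (n_facets,) boundary tag per exterior facet

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def facet_centroids(self) -> np.ndarray:
        return self.nodes[self.facets].mean(axis=1)

    def element_volumes(self) -> np.ndarray:
        """Volumes (3D, mm^3) or areas (2D, mm^2) of the axis-aligned cells."""
        xe = self.nodes[self.elems]
        spans = xe.max(axis=1) - xe.min(axis=1)
        return np.prod(spans, axis=1)

    def max_edge_length(self, mask: np.ndarray | None = None) -> float:
        """Longest element edge, optionally restricted to a subset of elements."""
        xe = self.nodes[self.elems if mask is None else self.elems[mask]]
        spans = xe.max(axis=1) - xe.min(axis=1)
        return float(spans.max())

    def region_mask(self, region: str) -> np.ndarray:
        return self.regions == region

    def nodes_on(self, predicate: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
        """Indices of nodes where ``predicate(nodes)`` is True."""
        return np.nonzero(np.asarray(predicate(self.nodes), dtype=bool))[0]

    def check_invariants(self) -> None:
        """Assert the tag-partition invariants; raises AssertionError on failure."""
        assert self.regions.shape == (self.n_elems,)
        assert not np.any(self.regions == "")
        assert self.facet_tags.shape == (self.facets.shape[0],)
        assert not np.any(self.facet_tags == "")
        # exterior facets are exactly the faces owned by a single element
        conn, _ = _element_faces(self.elems)
        keys = np.sort(conn, axis=1)
        _, counts = np.unique(keys, axis=0, return_counts=True)
        assert (counts <= 2).all(), "non-conforming face shared by >2 elements"
        assert (counts == 1).sum() == self.facets.shape[0]


def coords1d(
    breakpoints: Sequence[float],
    h: float,
    refine: Iterable[tuple[float, float, float]] = (),
) -> np.ndarray:
    """1D grid coordinates honouring mandatory breakpoints.

    Each interval between consecutive breakpoints is subdivided uniformly
    with spacing <= ``h``, or <= the finer spacing of any ``(lo, hi, h_fine)``
    refinement window containing the interval.
    """
    if h <= 0:
        raise ValueError("target element size must be positive")
    bp = np.unique(np.asarray(breakpoints, dtype=float))
    if bp.size < 2:
        raise ValueError("need at least two distinct breakpoints")
    out = [bp[0]]
    for lo, hi in zip(bp[:-1], bp[1:]):
        h_eff = h
        mid = 0.5 * (lo + hi)
        for rlo, rhi, h_fine in refine:
            if rlo - 1e-12 <= mid <= rhi + 1e-12:
                h_eff = min(h_eff, h_fine)
        n = max(1, int(np.ceil((hi - lo) / h_eff - 1e-9)))
        out.extend(np.linspace(lo, hi, n + 1)[1:])
    return np.asarray(out)


def _element_faces(elems: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All element boundary faces and their owner-element indices."""
    local = _QUAD_EDGES if elems.shape[1] == 4 else _HEX_FACES
    conn = np.concatenate([elems[:, f] for f in local], axis=0)
    owners = np.tile(np.arange(elems.shape[0]), len(local))
    return conn, owners


def structured_mesh(
    axes: Sequence[np.ndarray],
    region_of: Callable[[np.ndarray], np.ndarray],
    tag_of: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> Mesh:
    """Build a tagged tensor-product mesh.

    Parameters
    ----------
    axes:
        Two or three 1D coordinate arrays (from :func:`coords1d`).
    region_of:
        Vectorised classifier mapping cell centroids ``(m, dim)`` to region
        names; cells classified as ``None`` (void) are dropped.
    tag_of:
        Vectorised boundary classifier mapping exterior facet centroids and
        outward unit normals to tag names; defaults to ``"free"`` everywhere.
    """
    dim = len(axes)
    if dim not in (2, 3):
        raise MeshingError("only 2D and 3D tensor grids are supported")
    shape = tuple(len(a) for a in axes)
    if any(s < 2 for s in shape):
        raise MeshingError("each axis needs at least two coordinates")
    grids = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([g.ravel() for g in grids], axis=1)

    def nid(*idx):
        return np.ravel_multi_index(idx, shape)

    nc = tuple(s - 1 for s in shape)
    if dim == 2:
        i, j = np.meshgrid(np.arange(nc[0]), np.arange(nc[1]), indexing="ij")
        i, j = i.ravel(), j.ravel()
        elems = np.stack(
            [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)], axis=1
        )
    else:
        i, j, k = np.meshgrid(
            np.arange(nc[0]), np.arange(nc[1]), np.arange(nc[2]), indexing="ij"
        )
        i, j, k = i.ravel(), j.ravel(), k.ravel()
        elems = np.stack(
            [
                nid(i, j, k), nid(i + 1, j, k), nid(i + 1, j + 1, k), nid(i, j + 1, k),
                nid(i, j, k + 1), nid(i + 1, j, k + 1), nid(i + 1, j + 1, k + 1),
                nid(i, j + 1, k + 1),
            ],
            axis=1,
        )

    centroids = nodes[elems].mean(axis=1)
    raw = np.asarray(region_of(centroids), dtype=object)
    keep = np.array([r is not None for r in raw])
    if not keep.any():
        raise MeshingError("geometry classifies every cell as void")
    elems = elems[keep]
    regions = np.asarray([str(r) for r in raw[keep]], dtype=TAG_DTYPE)

    # compact node numbering
    used, inverse = np.unique(elems, return_inverse=True)
    elems = inverse.reshape(elems.shape).astype(np.int64)
    nodes = nodes[used]

    # exterior facets: faces referenced by exactly one kept element
    conn, owners = _element_faces(elems)
    keys = np.sort(conn, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    ext = counts[inv] == 1
    facets = conn[ext]
    fowners = owners[ext]

    fcent = nodes[facets].mean(axis=1)
    ecent = nodes[elems[fowners]].mean(axis=1)
    delta = fcent - ecent
    axis = np.argmax(np.abs(delta), axis=1)
    normals = np.zeros_like(delta)
    normals[np.arange(len(axis)), axis] = np.sign(delta[np.arange(len(axis)), axis])

    if tag_of is None:
        tags = np.full(facets.shape[0], "free", dtype=TAG_DTYPE)
    else:
        tags = np.asarray(tag_of(fcent, normals), dtype=TAG_DTYPE)
    return Mesh(nodes=nodes, elems=elems, regions=regions, facets=facets, facet_tags=tags)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _pad3(nodes: np.ndarray) -> np.ndarray:
    if nodes.shape[1] == 3:
        return nodes
    return np.column_stack([nodes, np.zeros(len(nodes))])


def write_vtk(
    mesh: Mesh,
    path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the mesh (plus optional fields) as a legacy ASCII VTK unstructured grid.

    Region tags are stored as the integer cell field ``region_id``; the
    name↔id mapping is recorded in the header comment line.
    """
    names = sorted(set(mesh.regions))
    rid = {n: i for i, n in enumerate(names)}
    vtk_type = 9 if mesh.dim == 2 else 12
    pts = _pad3(mesh.nodes)
    lines = ["# vtk DataFile Version 3.0"]
    lines.append("strainavoid mesh; regions: " + ";".join(f"{rid[n]}={n}" for n in names))
    lines.append("ASCII")
    lines.append("DATASET UNSTRUCTURED_GRID")
    lines.append(f"POINTS {len(pts)} double")
    lines.extend(" ".join(f"{v:.9g}" for v in p) for p in pts)
    npe = mesh.elems.shape[1]
    lines.append(f"CELLS {mesh.n_elems} {mesh.n_elems * (npe + 1)}")
    lines.extend(f"{npe} " + " ".join(map(str, e)) for e in mesh.elems)
    lines.append(f"CELL_TYPES {mesh.n_elems}")
    lines.extend([str(vtk_type)] * mesh.n_elems)

    lines.append(f"CELL_DATA {mesh.n_elems}")
    lines.append("SCALARS region_id int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(rid[r]) for r in mesh.regions)
    for name, data in (cell_data or {}).items():
        data = np.asarray(data, dtype=float)
        if data.ndim == 1:
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9g}" for v in data)
        else:
            lines.append(f"FIELD {name}_field 1")
            lines.append(f"{name} {data.shape[1]} {data.shape[0]} double")
            lines.extend(" ".join(f"{v:.9g}" for v in row) for row in data)
    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        for name, data in point_data.items():
            data = np.asarray(data, dtype=float)
            if data.ndim == 1:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.9g}" for v in data)
            else:
                vec = _pad3(data) if data.shape[1] != 3 else data
                lines.append(f"VECTORS {name} double")
                lines.extend(" ".join(f"{v:.9g}" for v in row) for row in vec)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vtk(path) -> Mesh:
    """Read a legacy ASCII VTK unstructured grid written by :func:`write_vtk`.

    Facet tags are not stored in VTK; exterior facets are re-derived and
    tagged ``"free"``. Region names are restored from the header comment.
    """
    with open(path) as fh:
        tokens = fh.read().split("\n")
    rid_map: dict[int, str] = {}
    for line in tokens[:2]:
        if "regions:" in line:
            for pair in line.split("regions:")[1].strip().split(";"):
                if "=" in pair:
                    k, v = pair.split("=")
                    rid_map[int(k)] = v
    it = iter(tokens)
    nodes = elems = rids = None
    for line in it:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "POINTS":
            n = int(parts[1])
            nodes = np.array([next(it).split() for _ in range(n)], dtype=float)
        elif parts[0] == "CELLS":
            n = int(parts[1])
            elems = np.array([next(it).split()[1:] for _ in range(n)], dtype=np.int64)
        elif parts[0] == "SCALARS" and parts[1] == "region_id":
            next(it)  # LOOKUP_TABLE
            rids = np.array([next(it) for _ in range(elems.shape[0])], dtype=int)
    if nodes is None or elems is None:
        raise MeshingError(f"not a VTK unstructured grid: {path}")
    if np.allclose(nodes[:, 2], nodes[0, 2]) and elems.shape[1] == 4:
        nodes = nodes[:, :2]
    if rids is None:
        regions = np.full(elems.shape[0], "solid", dtype=TAG_DTYPE)
    else:
        regions = np.asarray([rid_map.get(i, f"region_{i}") for i in rids], dtype=TAG_DTYPE)
    conn, _ = _element_faces(elems)
    keys = np.sort(conn, axis=1)
    _, inv, counts = np.unique(keys, axis=0, return_inverse=True, return_counts=True)
    facets = conn[counts[inv] == 1]
    tags = np.full(facets.shape[0], "free", dtype=TAG_DTYPE)
    return Mesh(nodes=nodes, elems=elems, regions=regions, facets=facets, facet_tags=tags)


def write_msh(mesh: Mesh, path) -> None:
    """Write Gmsh MSH 2.2 (ASCII); facet tags become physical groups of dim-1."""
    dim = mesh.dim
    enames = sorted(set(mesh.regions))
    fnames = sorted(set(mesh.facet_tags))
    phys = [(dim, i + 1, n) for i, n in enumerate(enames)]
    phys += [(dim - 1, len(enames) + i + 1, n) for i, n in enumerate(fnames)]
    eid = {n: i + 1 for i, n in enumerate(enames)}
    fid = {n: len(enames) + i + 1 for i, n in enumerate(fnames)}
    etype = 3 if dim == 2 else 5           # quad / hexahedron
    ftype = 1 if dim == 2 else 3           # line / quad
    pts = _pad3(mesh.nodes)
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat", "$PhysicalNames", str(len(phys))]
    lines.extend(f'{d} {i} "{n}"' for d, i, n in phys)
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(len(pts)))
    lines.extend(f"{i + 1} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}" for i, p in enumerate(pts))
    lines.append("$EndNodes")
    lines.append("$Elements")
    lines.append(str(mesh.n_elems + mesh.facets.shape[0]))
    k = 1
    for e, r in zip(mesh.elems, mesh.regions):
        lines.append(f"{k} {etype} 2 {eid[r]} {eid[r]} " + " ".join(str(n + 1) for n in e))
        k += 1
    for f, t in zip(mesh.facets, mesh.facet_tags):
        lines.append(f"{k} {ftype} 2 {fid[t]} {fid[t]} " + " ".join(str(n + 1) for n in f))
        k += 1
    lines.append("$EndElements")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_msh(path) -> Mesh:
    """Read a Gmsh MSH 2.2 file written by :func:`write_msh` (tags round-trip)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    phys: dict[int, tuple[int, str]] = {}
    nodes = None
    raw_elems: list[tuple[int, int, list[int]]] = []
    while i < len(lines):
        if lines[i] == "$PhysicalNames":
            n = int(lines[i + 1])
            for row in lines[i + 2 : i + 2 + n]:
                d, pid, name = row.split(maxsplit=2)
                phys[int(pid)] = (int(d), name.strip('"'))
            i += n + 2
        elif lines[i] == "$Nodes":
            n = int(lines[i + 1])
            nodes = np.array(
                [row.split()[1:4] for row in lines[i + 2 : i + 2 + n]], dtype=float
            )
            i += n + 2
        elif lines[i] == "$Elements":
            n = int(lines[i + 1])
            for row in lines[i + 2 : i + 2 + n]:
                parts = list(map(int, row.split()[1:]))
                etype, ntags = parts[0], parts[1]
                ptag = parts[2]
                conn = [c - 1 for c in parts[2 + ntags :]]
                raw_elems.append((etype, ptag, conn))
            i += n + 2
        else:
            i += 1
    if nodes is None or not raw_elems:
        raise MeshingError(f"not an MSH 2.2 mesh: {path}")
    types = {e[0] for e in raw_elems}
    dim = 3 if 5 in types else 2
    etype, ftype = (5, 3) if dim == 3 else (3, 1)
    if dim == 2:
        nodes = nodes[:, :2]
    elems = np.array([c for t, _, c in raw_elems if t == etype], dtype=np.int64)
    regions = np.asarray(
        [phys[p][1] for t, p, _ in raw_elems if t == etype], dtype=TAG_DTYPE
    )
    facets = np.array([c for t, _, c in raw_elems if t == ftype], dtype=np.int64)
    tags = np.asarray([phys[p][1] for t, p, _ in raw_elems if t == ftype], dtype=TAG_DTYPE)
    if facets.size == 0:
        facets = np.empty((0, 2 if dim == 2 else 4), dtype=np.int64)
        tags = np.empty((0,), dtype=TAG_DTYPE)
    return Mesh(nodes=nodes, elems=elems, regions=regions, facets=facets, facet_tags=tags)
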