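"""Static linear elasticity on tagged chamber meshes.

Two load families drive the alignment model:

* ``applied_stretch`` — the peak of the cyclic uniaxial stretch, imposed as
  a prescribed axial end displacement (quasi-static: the 1 Hz protocol is
  represented by its peak-amplitude strain field);
* ``self_condensation`` — homogeneous cellular contraction, encoded as an
  isotropic stress-free eigenstrain over the cell-bearing region
  (restricted to in-plane biaxial contraction for 2D monolayers), with an
  elastic spring (Robin) condition on the groove sidewalls representing
  partial hydrogel detachment.

Elements are bilinear quads (2D) and trilinear hexahedra (3D) on
axis-aligned structured meshes. Near-incompressible materials (nu = 0.49)
are handled by selective reduced integration of the volumetric term, which
preserves exact patch-test behaviour on these affine meshes. 2D solves are
plane-strain by default, optionally with a prescribed out-of-plane normal
strain (generalized plane strain) or plane stress.

Units: lengths mm, moduli Pa, strains dimensionless. Spring stiffness is
accepted in Pa/m and converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import MaterialProps
from .mesh import Mesh, write_vtk

__all__ = [
    "LoadCase",
    "StrainField",
    "SolverError",
    "solve",
    "probe_strain",
    "effective_axial_strain",
]

_AXES = {"x": 0, "y": 1, "z": 2}


class SolverError(RuntimeError):
    """Raised for singular systems or invalid solve configurations."""


@dataclass(frozen=True)
class LoadCase:
    """Boundary/volume load specification for one static solve."""

    kind: str  # applied_stretch | self_condensation
    applied_strain: float | None = None        # engineering strain at the moving end
    applied_displacement: float | None = None  # mm, alternative specification
    contraction_magnitude: float | None = None # isotropic eigenstrain (dimensionless)
    sidewall_spring_stiffness: float = 0.0     # Pa/m; 0 = detached, inf = bonded
    seeding_mode: str = "none"                 # none | layer_2d | hydrogel_3d

    def __post_init__(self):
        if self.kind not in ("applied_stretch", "self_condensation"):
            raise ValueError(f"unknown load kind: {self.kind!r}")
        if self.kind == "applied_stretch":
            given = (self.applied_strain is not None) + (self.applied_displacement is not None)
            if given != 1:
                raise ValueError(
                    "applied_stretch needs exactly one of applied_strain / applied_displacement"
                )
        else:
            if self.contraction_magnitude is None or self.contraction_magnitude <= 0:
                raise ValueError("self_condensation needs contraction_magnitude > 0")
        if self.sidewall_spring_stiffness < 0:
            raise ValueError("sidewall_spring_stiffness must be >= 0")
        if self.seeding_mode not in ("none", "layer_2d", "hydrogel_3d"):
            raise ValueError(f"unknown seeding_mode: {self.seeding_mode!r}")


# ---------------------------------------------------------------------------
# element machinery
# ---------------------------------------------------------------------------

def _gauss_1d(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n == 1:
        return np.array([0.0]), np.array([2.0])
    g = 1.0 / math.sqrt(3.0)
    return np.array([-g, g]), np.array([1.0, 1.0])


def _shape_quad(xi, eta):
    n = np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta), (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    ) / 4.0
    dn = np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    ) / 4.0
    return n, dn


def _shape_hex(xi, eta, zeta):
    signs = np.array(
        [
            (-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1),
            (-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1),
        ],
        dtype=float,
    )
    a = 1 + signs[:, 0] * xi
    b = 1 + signs[:, 1] * eta
    c = 1 + signs[:, 2] * zeta
    n = a * b * c / 8.0
    dn = np.stack(
        [signs[:, 0] * b * c, a * signs[:, 1] * c, a * b * signs[:, 2]], axis=1
    ) / 8.0
    return n, dn


def _gauss_points(dim: int, n: int):
    pts1, w1 = _gauss_1d(n)
    if dim == 2:
        return [
            ((xi, eta), wx * we)
            for xi, wx in zip(pts1, w1)
            for eta, we in zip(pts1, w1)
        ]
    return [
        ((xi, eta, zeta), wx * we * wz)
        for xi, wx in zip(pts1, w1)
        for eta, we in zip(pts1, w1)
        for zeta, wz in zip(pts1, w1)
    ]


def _b_matrices(xe: np.ndarray, local) -> tuple[np.ndarray, np.ndarray]:
    """Strain-displacement matrices at one Gauss point for all elements.

    Returns (B, detJ) with B of shape (n_elems, n_voigt, n_dof_el).
    """
    dim = xe.shape[2]
    if dim == 2:
        _, dn = _shape_quad(*local)
    else:
        _, dn = _shape_hex(*local)
    # J[e, i, j] = sum_a xe[e, a, i] * dn[a, j]
    jac = np.einsum("eai,aj->eij", xe, dn)
    det = np.linalg.det(jac)
    if np.any(det <= 0):
        raise SolverError("degenerate (non-positively oriented) element in mesh")
    inv = np.linalg.inv(jac)
    dndx = np.einsum("aj,eji->eai", dn, inv)  # (E, nodes, dim)
    ne = xe.shape[1]
    nv = 3 if dim == 2 else 6
    b = np.zeros((xe.shape[0], nv, ne * dim))
    if dim == 2:
        b[:, 0, 0::2] = dndx[:, :, 0]
        b[:, 1, 1::2] = dndx[:, :, 1]
        b[:, 2, 0::2] = dndx[:, :, 1]
        b[:, 2, 1::2] = dndx[:, :, 0]
    else:
        b[:, 0, 0::3] = dndx[:, :, 0]
        b[:, 1, 1::3] = dndx[:, :, 1]
        b[:, 2, 2::3] = dndx[:, :, 2]
        b[:, 3, 1::3] = dndx[:, :, 2]
        b[:, 3, 2::3] = dndx[:, :, 1]
        b[:, 4, 0::3] = dndx[:, :, 2]
        b[:, 4, 2::3] = dndx[:, :, 0]
        b[:, 5, 0::3] = dndx[:, :, 1]
        b[:, 5, 1::3] = dndx[:, :, 0]
    return b, det


def _c_matrix(mat: MaterialProps, dim: int, plane: str) -> np.ndarray:
    lam, mu = mat.lame_lambda, mat.lame_mu
    if dim == 3:
        c = np.zeros((6, 6))
        c[:3, :3] = lam
        c[np.arange(3), np.arange(3)] += 2 * mu
        c[3, 3] = c[4, 4] = c[5, 5] = mu
        return c
    if plane == "stress":
        e, nu = mat.young_modulus, mat.poisson_ratio
        f = e / (1 - nu**2)
        return np.array([[f, f * nu, 0], [f * nu, f, 0], [0, 0, f * (1 - nu) / 2]])
    return np.array(
        [[lam + 2 * mu, lam, 0], [lam, lam + 2 * mu, 0], [0, 0, mu]]
    )


def _vol_projector(dim: int) -> np.ndarray:
    nv = 3 if dim == 2 else 6
    m = np.zeros(nv)
    m[: (2 if dim == 2 else 3)] = 1.0
    return m


# ---------------------------------------------------------------------------
# the solve
# ---------------------------------------------------------------------------

@dataclass
class StrainField:
    """Displacement solution and derived strain field of one solve.

    The strain tensor returned by :meth:`strain_at` is the full symmetric
    3x3 small-strain tensor in laboratory axes (x = stretch, y = transverse,
    z = height); for 2D solves the out-of-plane components come from the
    plane assumption (plane strain / generalized plane strain / plane
    stress).
    """

    mesh: Mesh
    displacement: np.ndarray          # (n_nodes, dim), mm
    load: LoadCase
    materials: dict[str, MaterialProps]
    plane_axes: tuple[str, str] | None = None  # lab axes of the 2D plane
    plane: str = "strain"
    out_of_plane_strain: float = 0.0
    energy: float = 0.0               # discrete potential energy (Pa mm^dim)

    _bboxes: np.ndarray | None = None

    @property
    def dim(self) -> int:
        return self.mesh.dim

    def _locate(self, point: np.ndarray) -> int:
        if self._bboxes is None:
            xe = self.mesh.nodes[self.mesh.elems]
            self._bboxes = np.stack([xe.min(axis=1), xe.max(axis=1)], axis=2)
        tol = 1e-9
        lo, hi = self._bboxes[:, :, 0], self._bboxes[:, :, 1]
        inside = np.all((point >= lo - tol) & (point <= hi + tol), axis=1)
        idx = np.nonzero(inside)[0]
        if idx.size == 0:
            raise SolverError(f"probe point {point} lies outside the mesh")
        return int(idx[0])

    def _plane_strain_tensor(self, eps2: np.ndarray, gamma: float) -> np.ndarray:
        """Embed the 2D in-plane strain into the 3x3 lab tensor."""
        a, b = (_AXES[ax] for ax in self.plane_axes)
        c = ({0, 1, 2} - {a, b}).pop()
        t = np.zeros((3, 3))
        t[a, a], t[b, b] = eps2[0], eps2[1]
        t[a, b] = t[b, a] = 0.5 * gamma
        if self.plane == "stress":
            # recovered from sigma_out = 0 for the (single) probed material
            nu = next(iter(self.materials.values())).poisson_ratio
            t[c, c] = -nu / (1 - nu) * (eps2[0] + eps2[1])
        else:
            t[c, c] = self.out_of_plane_strain
        return t

    def strain_at(self, point: Sequence[float]) -> np.ndarray:
        """Full 3x3 lab-frame strain tensor interpolated at a mesh point.

        ``point`` is given in mesh coordinates (2 components for section
        meshes, 3 for chamber meshes).
        """
        point = np.asarray(point, dtype=float)
        if point.shape != (self.dim,):
            raise SolverError(
                f"probe point must have {self.dim} coordinates for this mesh"
            )
        e = self._locate(point)
        xe = self.mesh.nodes[self.mesh.elems[e]]
        lo, hi = xe.min(axis=0), xe.max(axis=0)
        local = tuple(2 * (point - lo) / np.where(hi > lo, hi - lo, 1.0) - 1)
        b, _ = _b_matrices(xe[None, :, :], local)
        ue = self.displacement[self.mesh.elems[e]].ravel()
        voigt = b[0] @ ue
        if self.dim == 2:
            return self._plane_strain_tensor(voigt[:2], voigt[2])
        t = np.zeros((3, 3))
        t[0, 0], t[1, 1], t[2, 2] = voigt[:3]
        t[1, 2] = t[2, 1] = 0.5 * voigt[3]
        t[0, 2] = t[2, 0] = 0.5 * voigt[4]
        t[0, 1] = t[1, 0] = 0.5 * voigt[5]
        return t

    def element_strains(self) -> np.ndarray:
        """Centroid strain in Voigt order for every element."""
        xe = self.mesh.nodes[self.mesh.elems]
        local = (0.0, 0.0) if self.dim == 2 else (0.0, 0.0, 0.0)
        b, _ = _b_matrices(xe, local)
        ue = self.displacement[self.mesh.elems].reshape(self.mesh.n_elems, -1)
        return np.einsum("eij,ej->ei", b, ue)

    def export_vtk(self, path) -> None:
        comps = ["aa", "bb", "ab"] if self.dim == 2 else ["xx", "yy", "zz", "yz", "xz", "xy"]
        strains = self.element_strains()
        cell_data = {f"strain_{c}": strains[:, i] for i, c in enumerate(comps)}
        write_vtk(self.mesh, path, point_data={"displacement": self.displacement},
                  cell_data=cell_data)


def _lab_eigenstrain(load: LoadCase) -> dict[str, np.ndarray]:
    """Stress-free eigenstrain (diagonal, lab axes) per region for a load."""
    if load.kind != "self_condensation":
        return {}
    c = load.contraction_magnitude
    out: dict[str, np.ndarray] = {}
    if load.seeding_mode == "hydrogel_3d":
        out["hydrogel"] = np.array([-c, -c, -c])
    elif load.seeding_mode == "layer_2d":
        # isometric biaxial contraction in the substrate (x-y) plane
        out["cell_layer"] = np.array([-c, -c, 0.0])
    return out


def solve(
    mesh: Mesh,
    materials: dict[str, MaterialProps],
    load: LoadCase,
    *,
    plane_axes: tuple[str, str] = ("x", "z"),
    plane: str = "strain",
    out_of_plane_strain: float = 0.0,
    stretch_axis: int = 0,
    clamp: str = "built_in",
    eigenstrain: dict[str, np.ndarray] | None = None,
    extra_dirichlet: Sequence[tuple[Callable[[np.ndarray], np.ndarray], int, float]] = (),
    pin_rigid_body: bool = False,
    selective_integration: bool = True,
) -> StrainField:
    """Solve the discrete linear-elastic equilibrium for one load case.

    Boundary conditions are derived from facet tags: ``clamped_end`` is
    fully built-in (or axial-only with ``clamp="roller"``); ``moving_end``
    receives the prescribed axial displacement for ``applied_stretch`` loads
    and is traction-free for ``self_condensation``; ``groove_bottom`` is
    bonded (zero displacement, rigid-substrate limit); ``groove_sidewall``
    carries the detachment spring (Robin) with the load's stiffness
    (``inf`` = bonded, ``0`` = traction-free).

    ``pin_rigid_body`` adds minimal point constraints for otherwise
    unconstrained (self-equilibrated) problems, e.g. a section driven purely
    by out-of-plane stretch or eigenstrain.
    """
    dim = mesh.dim
    missing = set(mesh.regions) - set(materials)
    if missing:
        raise SolverError(f"regions without material properties: {sorted(missing)}")
    if dim == 3 and plane == "stress":
        raise SolverError("plane stress applies to 2D meshes only")

    ndof = mesh.n_nodes * dim
    xe = mesh.nodes[mesh.elems]
    nv = 3 if dim == 2 else 6
    nde = mesh.elems.shape[1] * dim

    # per-element elasticity
    names = sorted(set(mesh.regions))
    c_by = {n: _c_matrix(materials[n], dim, plane) for n in names}
    kap_by = {
        n: materials[n].lame_lambda + 2 * materials[n].lame_mu / 3 for n in names
    }
    c_e = np.stack([c_by[r] for r in mesh.regions])
    m = _vol_projector(dim)
    mm = np.outer(m, m)
    if plane == "stress":
        selective = False  # plane stress never locks
        c_dev = c_e
        kap_e = np.zeros(mesh.n_elems)
    else:
        selective = selective_integration
        kap_e = np.array([kap_by[r] for r in mesh.regions])
        c_dev = c_e - kap_e[:, None, None] * mm if selective else c_e

    # eigenstrain / out-of-plane coupling -> constant element stress offset
    estar = dict(_lab_eigenstrain(load))
    if eigenstrain:
        estar.update(eigenstrain)
    sig0 = np.zeros((mesh.n_elems, nv))
    if estar or out_of_plane_strain != 0.0:
        if dim == 2:
            a_i, b_i = (_AXES[ax] for ax in plane_axes)
            c_i = ({0, 1, 2} - {a_i, b_i}).pop()
        lam_by = {n: materials[n].lame_lambda for n in names}
        for i, r in enumerate(mesh.regions):
            es = np.asarray(estar.get(r, np.zeros(3)), dtype=float)
            if dim == 2:
                ev = np.array([es[a_i], es[b_i], 0.0])
                sig0[i] = -c_by[r] @ ev
                if plane != "stress":
                    sig0[i] += lam_by[r] * (out_of_plane_strain - es[c_i]) * m
            else:
                ev = np.concatenate([es, np.zeros(3)])
                sig0[i] = -c_by[r] @ ev

    # --- stiffness assembly ------------------------------------------------
    ke = np.zeros((mesh.n_elems, nde, nde))
    fe = np.zeros((mesh.n_elems, nde))
    for local, w in _gauss_points(dim, 2):
        b, det = _b_matrices(xe, local)
        ke += w * np.einsum("eki,ekl,elj,e->eij", b, c_dev, b, det)
        if sig0.any():
            fe -= w * np.einsum("eki,ek,e->ei", b, sig0, det)
    if selective:
        for local, w in _gauss_points(dim, 1):
            b, det = _b_matrices(xe, local)
            bv = np.einsum("k,eki->ei", m, b)  # volumetric strain row
            ke += w * np.einsum("ei,ej,e,e->eij", bv, bv, kap_e, det)

    edof = (mesh.elems[:, :, None] * dim + np.arange(dim)).reshape(mesh.n_elems, nde)
    rows = np.repeat(edof, nde, axis=1).ravel()
    cols = np.tile(edof, (1, nde)).ravel()
    k = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(ndof, ndof)).tocsr()
    f = np.zeros(ndof)
    np.add.at(f, edof.ravel(), fe.ravel())

    # --- Robin springs on groove sidewalls ---------------------------------
    k_spring = load.sidewall_spring_stiffness
    bonded_sidewalls = math.isinf(k_spring)
    if k_spring > 0 and not bonded_sidewalls and mesh.facets.size:
        wall = mesh.facet_tags == "groove_sidewall"
        if wall.any():
            k_mm = k_spring * 1e-3  # Pa/m -> Pa/mm
            fconn = mesh.facets[wall]
            xf = mesh.nodes[fconn]
            nn = fconn.shape[1]
            if dim == 2:  # line facets
                length = np.linalg.norm(xf[:, 1] - xf[:, 0], axis=1)
                me = (np.array([[2.0, 1.0], [1.0, 2.0]]) / 6.0)[None] * length[:, None, None]
            else:  # bilinear quad facets (axis-aligned rectangles)
                spans = xf.max(axis=1) - xf.min(axis=1)
                spans = np.sort(spans, axis=1)[:, 1:]  # two non-degenerate spans
                area = spans[:, 0] * spans[:, 1]
                mloc = np.array(
                    [
                        [4, 2, 1, 2],
                        [2, 4, 2, 1],
                        [1, 2, 4, 2],
                        [2, 1, 2, 4],
                    ],
                    dtype=float,
                ) / 36.0
                me = mloc[None] * area[:, None, None]
            me = k_mm * me
            for comp in range(dim):
                fdof = fconn * dim + comp
                r = np.repeat(fdof, nn, axis=1).ravel()
                cc = np.tile(fdof, (1, nn)).ravel()
                k = k + sp.coo_matrix((me.ravel(), (r, cc)), shape=(ndof, ndof)).tocsr()

    # --- Dirichlet conditions ----------------------------------------------
    fixed = np.zeros(ndof, dtype=bool)
    vals = np.zeros(ndof)

    def fix_nodes(node_idx, comp, value):
        d = node_idx * dim + comp
        fixed[d] = True
        vals[d] = value

    def facet_nodes(tag):
        sel = mesh.facet_tags == tag
        return np.unique(mesh.facets[sel]) if sel.any() else np.array([], dtype=int)

    clamped = facet_nodes("clamped_end")
    if clamped.size:
        if clamp == "built_in":
            for comp in range(dim):
                fix_nodes(clamped, comp, 0.0)
        elif clamp == "roller":
            fix_nodes(clamped, stretch_axis, 0.0)
        else:
            raise SolverError(f"unknown clamp mode: {clamp!r}")

    moving = facet_nodes("moving_end")
    if moving.size and load.kind == "applied_stretch":
        if load.applied_displacement is not None:
            u_end = load.applied_displacement
        else:
            ax = mesh.nodes[:, stretch_axis]
            u_end = load.applied_strain * (ax.max() - ax.min())
        fix_nodes(moving, stretch_axis, u_end)

    bottom = facet_nodes("groove_bottom")
    if bottom.size and load.kind == "self_condensation":
        for comp in range(dim):
            fix_nodes(bottom, comp, 0.0)
    if bonded_sidewalls:
        wall_nodes = facet_nodes("groove_sidewall")
        for comp in range(dim):
            fix_nodes(wall_nodes, comp, 0.0)

    for mask_fn, comp, value in extra_dirichlet:
        idx = mesh.nodes_on(mask_fn)
        if idx.size == 0:
            raise SolverError("extra Dirichlet constraint selects no nodes")
        fix_nodes(idx, comp, value)

    if pin_rigid_body:
        _pin_rigid_modes(mesh, dim, fixed, vals)

    if not fixed.any():
        raise SolverError("no constraints: the system is singular")

    free = ~fixed
    kff = k[free][:, free]
    rhs = f[free] - k[free][:, fixed] @ vals[fixed]
    try:
        uf = spla.spsolve(kff.tocsc(), rhs)
    except Exception as exc:  # pragma: no cover - scipy raises various types
        raise SolverError(f"linear solve failed: {exc}") from exc
    if not np.all(np.isfinite(uf)):
        raise SolverError("singular system: insufficient constraints")
    u = np.empty(ndof)
    u[free] = uf
    u[fixed] = vals[fixed]

    energy = 0.5 * float(u @ (k @ u)) - float(f @ u)
    return StrainField(
        mesh=mesh,
        displacement=u.reshape(-1, dim),
        load=load,
        materials={n: materials[n] for n in names},
        plane_axes=plane_axes if dim == 2 else None,
        plane=plane,
        out_of_plane_strain=out_of_plane_strain,
        energy=energy,
    )


def _pin_rigid_modes(mesh: Mesh, dim: int, fixed: np.ndarray, vals: np.ndarray) -> None:
    """Minimal point constraints removing remaining rigid-body modes.

    Intended for self-equilibrated loads, where the pin reactions vanish.
    """
    nodes = mesh.nodes

    def fix(node, comp):
        d = node * dim + comp
        fixed[d] = True
        vals[d] = 0.0

    def constrained(comp):
        return fixed[comp::dim].any()

    corner = int(np.lexsort(nodes.T[::-1])[0])  # lexicographically smallest node
    if dim == 2:
        if not constrained(0):
            fix(corner, 0)
        if not constrained(1):
            fix(corner, 1)
            # block in-plane rotation: second pin of the same component at the
            # far end of the first axis, same transverse coordinate
            same = np.isclose(nodes[:, 1], nodes[corner, 1])
            far = int(np.argmax(np.where(same, nodes[:, 0], -np.inf)))
            fix(far, 1)
    else:
        x, y, z = nodes.T
        if not constrained(0):
            fix(corner, 0)
        if not constrained(1):
            fix(corner, 1)
            same = np.isclose(x, x[corner]) & np.isclose(y, y[corner])
            far = int(np.argmax(np.where(same, z, -np.inf)))
            if far != corner:
                fix(far, 1)
        if not constrained(2):
            fix(corner, 2)
            same = np.isclose(z, z[corner]) & np.isclose(y, y[corner])
            far = int(np.argmax(np.where(same, x, -np.inf)))
            if far != corner:
                fix(far, 2)


def probe_strain(field: StrainField, point: Sequence[float]) -> np.ndarray:
    """Full 3x3 lab-frame strain tensor at a point (error outside the mesh)."""
    return field.strain_at(point)


def effective_axial_strain(field: StrainField, point: Sequence[float]) -> float:
    """Axial (stretch-direction) normal strain at a point, in percent."""
    return 100.0 * float(probe_strain(field, point)[0, 0])
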