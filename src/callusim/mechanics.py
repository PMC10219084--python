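"""Small-strain linear-elastic voxel finite-element mechanics.

The tissue distribution is homogenized voxel-wise to an isotropic Young's
modulus (concentration-weighted mixture rule; Poisson's ratio uniform) and
the displacement field under body-weight-scaled loading is computed with
trilinear hexahedral elements on the voxel grid.  Boundary conditions:
distal cross-section fully fixed, proximal cross-section loaded by
consistent surface tractions representing the axial force and bending
moment resultants.

The per-voxel outputs driving tissue differentiation are the two strain
invariants used as mechanical stimuli: dilatational strain (trace of the
strain tensor) and distortional strain (octahedral shear strain of the
deviator).

The sparsity pattern of the stiffness matrix is precomputed once per
domain; per-day reassembly only rescales element contributions by the
current voxel moduli.  The solve is a Jacobi-preconditioned conjugate
gradient (warm-started across days) or a sparse LU factorization for small
systems; both are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import LinearOperator, cg, splu

from .cohort import ConfigurationError, PatientCase
from .grid import Domain, Region
from .state import TISSUES, TissueState

__all__ = [
    "MaterialTable",
    "LoadCoefficients",
    "LoadCase",
    "StrainField",
    "SingularSystemError",
    "VoxelFEM",
    "hex_element_stiffness",
    "homogenize",
    "assemble_and_solve",
    "strain_invariants",
    "body_weight_load",
]

G_ACCEL = 9.81  # m/s^2

# local node a = dx + 2*dy + 4*dz, voxel corners in [0, h]^3
_CORNERS = np.array([[dx, dy, dz]
                     for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)])
_CORNERS = _CORNERS[np.argsort(_CORNERS[:, 0] + 2 * _CORNERS[:, 1] + 4 * _CORNERS[:, 2])]


class SingularSystemError(RuntimeError):
    """The elastic system is singular (a fragment has no fixation)."""


@dataclass(frozen=True)
class MaterialTable:
    """Young's moduli (MPa) and Poisson's ratio for tissues and implants.

    Literature-typical defaults; all configurable.  Cortical bone is
    identified with lamellar bone; marrow in the canal is treated as
    connective tissue.
    """

    moduli: dict = field(default_factory=lambda: {
        "connective": 3.0,
        "cartilage": 10.0,
        "woven": 1000.0,
        "lamellar": 10000.0,
    })
    cortex_modulus: float = 10000.0
    nail_modulus: float = 110000.0  # titanium alloy
    poisson: float = 0.3
    mixture_rule: str = "voigt"  # "voigt" (arithmetic) or "reuss" (harmonic)

    def __post_init__(self) -> None:
        for key in TISSUES:
            if key not in self.moduli:
                raise ConfigurationError(f"moduli: missing tissue key {key!r}")
        for key, val in self.moduli.items():
            if key not in TISSUES:
                raise ConfigurationError(f"moduli: unknown tissue key {key!r}")
            if val <= 0:
                raise ConfigurationError(f"moduli[{key}]: must be > 0")
        if not (0 < self.poisson < 0.5):
            raise ConfigurationError("poisson: must be in (0, 0.5)")
        if self.mixture_rule not in ("voigt", "reuss"):
            raise ConfigurationError(
                f"mixture_rule: unknown rule {self.mixture_rule!r}")


@dataclass(frozen=True)
class LoadCoefficients:
    """Body-weight scaling of the proximal load resultants.

    ``axial_bw`` multiplies body weight (in N) to give the compressive
    axial force; the lever arms (mm) convert body weight to the bending
    moment components.  Defaults approximate peak gait loading at the
    femoral mid-shaft with full weight-bearing.
    """

    axial_bw: float = 2.5
    lever_x: float = 65.0  # mm; moment about x (bending toward medial/lateral)
    lever_y: float = 160.0  # mm; moment about y (bending toward anterior/posterior)


@dataclass(frozen=True)
class LoadCase:
    """Resultant loading on the proximal cross-section.

    ``axial_force`` > 0 is compressive; moments are in N*mm about the
    anatomical x (anterior) and y axes.
    """

    axial_force: float
    moment_x: float = 0.0
    moment_y: float = 0.0

    def scaled(self, factor: float) -> "LoadCase":
        return LoadCase(self.axial_force * factor, self.moment_x * factor,
                        self.moment_y * factor)


@dataclass
class StrainField:
    """Per-voxel strain invariants (zero outside the meshed region)."""

    distortional: np.ndarray  # octahedral shear strain of the deviator
    dilatational: np.ndarray  # volumetric strain (trace)
    element_strain: np.ndarray  # (n_active, 6) Voigt engineering strains
    element_index: tuple  # voxel indices of active elements


def body_weight_load(patient: PatientCase,
                     coefficients: LoadCoefficients = LoadCoefficients()) -> LoadCase:
    """Load resultants scaled by patient body weight (full weight-bearing)."""
    w_newton = patient.weight * G_ACCEL
    return LoadCase(axial_force=coefficients.axial_bw * w_newton,
                    moment_x=coefficients.lever_x * w_newton,
                    moment_y=coefficients.lever_y * w_newton)


# ---------------------------------------------------------------------------
# element matrices


def _elastic_d(E: float, nu: float) -> np.ndarray:
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[3:, 3:] = np.eye(3) * mu  # engineering shear strains
    return D


def _shape_gradients(xi: np.ndarray, h: float) -> np.ndarray:
    """dN/dx (8, 3) for a cube of edge h at natural coordinates xi in [-1,1]^3."""
    signs = 2.0 * _CORNERS - 1.0  # node natural coordinates
    grads = np.empty((8, 3))
    for a in range(8):
        s = signs[a]
        grads[a, 0] = s[0] * (1 + s[1] * xi[1]) * (1 + s[2] * xi[2]) / 8
        grads[a, 1] = s[1] * (1 + s[0] * xi[0]) * (1 + s[2] * xi[2]) / 8
        grads[a, 2] = s[2] * (1 + s[0] * xi[0]) * (1 + s[1] * xi[1]) / 8
    return grads * (2.0 / h)  # J = (h/2) I


def _b_matrix(grads: np.ndarray) -> np.ndarray:
    """Strain-displacement matrix (6, 24); Voigt order xx,yy,zz,xy,yz,zx."""
    B = np.zeros((6, 24))
    for a in range(8):
        gx, gy, gz = grads[a]
        c = 3 * a
        B[0, c] = gx
        B[1, c + 1] = gy
        B[2, c + 2] = gz
        B[3, c] = gy
        B[3, c + 1] = gx
        B[4, c + 1] = gz
        B[4, c + 2] = gy
        B[5, c] = gz
        B[5, c + 2] = gx
    return B


def hex_element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """Stiffness matrix (24, 24) of a trilinear hexahedron of edge h (2x2x2 Gauss)."""
    D = _elastic_d(E, nu)
    g = 1.0 / math.sqrt(3.0)
    detJ = (h / 2) ** 3
    K = np.zeros((24, 24))
    for sx in (-g, g):
        for sy in (-g, g):
            for sz in (-g, g):
                B = _b_matrix(_shape_gradients(np.array([sx, sy, sz]), h))
                K += B.T @ D @ B * detJ
    return K


def center_b_matrix(h: float) -> np.ndarray:
    """B matrix at the element center (used for strain recovery)."""
    return _b_matrix(_shape_gradients(np.zeros(3), h))


# ---------------------------------------------------------------------------
# strain invariants


def strain_invariants(tensor: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distortional (octahedral shear) and dilatational strain invariants.

    Accepts strain as a symmetric (..., 3, 3) tensor or a (..., 6) Voigt
    vector with engineering shears (xx, yy, zz, xy, yz, zx).  Returns
    ``(distortional, dilatational)``; both dimensionless scalars.
    """
    t = np.asarray(tensor, dtype=float)
    if t.shape[-2:] == (3, 3):
        exx, eyy, ezz = t[..., 0, 0], t[..., 1, 1], t[..., 2, 2]
        exy, eyz, ezx = t[..., 0, 1], t[..., 1, 2], t[..., 2, 0]
    elif t.shape[-1] == 6:
        exx, eyy, ezz = t[..., 0], t[..., 1], t[..., 2]
        exy, eyz, ezx = t[..., 3] / 2, t[..., 4] / 2, t[..., 5] / 2
    else:
        raise ValueError("expected a (...,3,3) tensor or (...,6) Voigt vector")
    dilatational = exx + eyy + ezz
    distortional = (2.0 / 3.0) * np.sqrt(
        (exx - eyy) ** 2 + (eyy - ezz) ** 2 + (ezz - exx) ** 2
        + 6.0 * (exy**2 + eyz**2 + ezx**2))
    return distortional, dilatational


# ---------------------------------------------------------------------------
# homogenization


def homogenize(state: TissueState, table: MaterialTable,
               domain: Domain) -> np.ndarray:
    """Per-voxel Young's modulus from the tissue concentrations.

    Gap, envelope and canal voxels get the concentration-weighted mixture
    of the tissue moduli (Voigt arithmetic or Reuss harmonic rule); cortex
    and nail voxels use their fixed materials.  Outside voxels get 0 and
    are excluded from the mesh.
    """
    region = domain.region
    meshed = region != Region.OUTSIDE
    sums = state.concentration_sum()[meshed]
    if not np.allclose(sums, 1.0, atol=1e-6):
        raise ConfigurationError(
            "concentrations: not normalized (violates homogenize precondition)")
    E = np.zeros(state.shape)
    mixture = region == Region.CANAL
    mixture |= (region == Region.GAP) | (region == Region.ENVELOPE)
    if table.mixture_rule == "voigt":
        acc = np.zeros(state.shape)
        for tissue in TISSUES:
            acc += state.concentration(tissue) * table.moduli[tissue]
    else:  # reuss
        inv = np.zeros(state.shape)
        for tissue in TISSUES:
            inv += state.concentration(tissue) / table.moduli[tissue]
        with np.errstate(divide="ignore"):
            acc = np.where(inv > 0, 1.0 / np.where(inv > 0, inv, 1.0), 0.0)
    E[mixture] = acc[mixture]
    E[region == Region.CORTEX] = table.cortex_modulus
    E[region == Region.NAIL] = table.nail_modulus
    return E


# ---------------------------------------------------------------------------
# the voxel FE solver


class VoxelFEM:
    """Trilinear-hexahedron elasticity on an active-voxel mask.

    The mask, node numbering, Dirichlet constraints and stiffness sparsity
    pattern are computed once; per-call assembly only rescales element
    contributions by the supplied per-element moduli.
    """

    def __init__(self, active: np.ndarray, voxel_size: float, nu: float = 0.3,
                 origin: tuple[float, float, float] | None = None):
        if not active.any():
            raise ValueError("active mask is empty")
        self.shape = active.shape
        self.h = float(voxel_size)
        self.nu = float(nu)
        nx, ny, nz = self.shape
        if origin is None:
            origin = (-nx * self.h / 2, -ny * self.h / 2, 0.0)
        self.origin = origin

        self.elem_index = np.nonzero(active)
        ei, ej, ek = (a.astype(np.int64) for a in self.elem_index)
        self.n_elem = ei.size

        stride_y = nz + 1
        stride_x = (ny + 1) * (nz + 1)
        base = ei * stride_x + ej * stride_y + ek
        offs = (_CORNERS[:, 0] * stride_x + _CORNERS[:, 1] * stride_y
                + _CORNERS[:, 2]).astype(np.int64)
        enodes_global = base[:, None] + offs[None, :]  # (ne, 8)

        self.used_nodes, enodes = np.unique(enodes_global, return_inverse=True)
        self.enodes = enodes.reshape(self.n_elem, 8).astype(np.int64)
        self.n_nodes = self.used_nodes.size
        self.ndof = 3 * self.n_nodes
        self.edofs = (3 * self.enodes[:, :, None]
                      + np.arange(3)[None, None, :]).reshape(self.n_elem, 24)

        self.k_unit = hex_element_stiffness(1.0, nu, self.h)
        self.b_center = center_b_matrix(self.h)
        self._pattern = None
        self._factor = None
        # CG iterations triggering a refactor; balances the cost of one
        # factorization against accumulated iteration cost as the factor ages
        self.refactor_threshold = 40

    def node_coords(self) -> np.ndarray:
        """Coordinates (n_nodes, 3) in mm of the used FE nodes."""
        nz1 = self.shape[2] + 1
        ny1 = self.shape[1] + 1
        ids = self.used_nodes
        iz = ids % nz1
        iy = (ids // nz1) % ny1
        ix = ids // (nz1 * ny1)
        ox, oy, oz = self.origin
        return np.column_stack([ix * self.h + ox, iy * self.h + oy, iz * self.h + oz])

    # -- constraints and pattern

    def set_fixed(self, fixed_dofs: np.ndarray) -> None:
        """Set homogeneous Dirichlet constraints and build the sparsity pattern.

        Raises :class:`SingularSystemError` if any connected component of
        the mesh contains no fixed degree of freedom (a floating fragment).
        """
        fixed_dofs = np.asarray(fixed_dofs, dtype=bool)
        if fixed_dofs.shape != (self.ndof,):
            raise ValueError("fixed_dofs must be a bool array over all dofs")
        self._check_connected(fixed_dofs)
        self.fixed = fixed_dofs
        free = ~fixed_dofs
        self.n_free = int(free.sum())
        perm = np.full(self.ndof, -1, dtype=np.int64)
        perm[free] = np.arange(self.n_free)
        efree = perm[self.edofs]  # (ne, 24), -1 where fixed

        r = np.broadcast_to(efree[:, :, None], (self.n_elem, 24, 24)).ravel()
        c = np.broadcast_to(efree[:, None, :], (self.n_elem, 24, 24)).ravel()
        keep = (r >= 0) & (c >= 0)
        r, c = r[keep], c[keep]
        order = np.lexsort((c, r))
        rs, cs = r[order], c[order]
        first = np.empty(rs.size, dtype=bool)
        first[0] = True
        np.not_equal(rs[1:], rs[:-1], out=first[1:])
        first[1:] |= cs[1:] != cs[:-1]
        pos_sorted = np.cumsum(first) - 1
        nnz = int(pos_sorted[-1]) + 1
        pos = np.empty(rs.size, dtype=np.int64)
        pos[order] = pos_sorted

        entry_elem = np.repeat(np.arange(self.n_elem, dtype=np.int64), 576)[keep]
        entry_w = np.broadcast_to(self.k_unit.ravel()[None, :],
                                  (self.n_elem, 576)).ravel()[keep].copy()

        indices = cs[first].astype(np.int32)
        counts = np.bincount(rs[first], minlength=self.n_free)
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._pattern = {
            "pos": pos.astype(np.int64),
            "elem": entry_elem,
            "w": entry_w,
            "nnz": nnz,
            "indices": indices,
            "indptr": indptr,
        }
        self._K = sparse.csr_matrix(
            (np.zeros(nnz), indices, indptr), shape=(self.n_free, self.n_free))
        self._factor = None

    def _check_connected(self, fixed_dofs: np.ndarray) -> None:
        fixed_nodes = fixed_dofs.reshape(-1, 3).any(axis=1)
        a = self.enodes[:, :-1].ravel()
        b = self.enodes[:, 1:].ravel()
        adj = sparse.coo_matrix(
            (np.ones(a.size, dtype=np.int8), (a, b)),
            shape=(self.n_nodes, self.n_nodes))
        n_comp, labels = csgraph.connected_components(adj, directed=False)
        if n_comp > 1 or not fixed_nodes.any():
            anchored = np.zeros(n_comp, dtype=bool)
            np.logical_or.at(anchored, labels[fixed_nodes], True)
            for comp in np.nonzero(~anchored)[0]:
                members = np.nonzero(labels == comp)[0]
                xyz = self.node_coords()[members[0]]
                raise SingularSystemError(
                    f"floating fragment: mesh component {comp} "
                    f"({members.size} nodes, near x={xyz[0]:.1f} y={xyz[1]:.1f} "
                    f"z={xyz[2]:.1f} mm) has no fixed degree of freedom")

    # -- assembly and solve

    def assemble(self, E_elem: np.ndarray) -> sparse.csr_matrix:
        """Stiffness matrix on the free dofs for per-element moduli."""
        if self._pattern is None:
            raise RuntimeError("call set_fixed() before assemble()")
        E_elem = np.asarray(E_elem, dtype=float)
        if E_elem.shape != (self.n_elem,):
            raise ValueError("E_elem must have one modulus per active element")
        if np.any(E_elem <= 0):
            raise ConfigurationError("moduli: all element moduli must be > 0")
        p = self._pattern
        data = np.bincount(p["pos"], weights=p["w"] * E_elem[p["elem"]],
                           minlength=p["nnz"])
        self._K.data[:] = data
        return self._K

    def solve(self, E_elem: np.ndarray, f: np.ndarray, x0: np.ndarray | None = None,
              rtol: float = 1e-8, solver: str = "auto",
              maxiter: int = 20000) -> np.ndarray:
        """Solve K u = f; returns the full displacement vector (fixed dofs 0).

        ``solver`` is "auto" (LU below 60k free dofs, else CG), "lu" or
        "cg".  ``x0`` warm-starts the CG iteration (full-length vector).
        """
        K = self.assemble(E_elem)
        f = np.asarray(f, dtype=float)
        f_free = f[~self.fixed]
        u = np.zeros(self.ndof)
        if not np.any(f_free):
            return u
        if solver == "auto":
            solver = "factor_cg"
        x0_free = None if x0 is None else np.asarray(x0)[~self.fixed]
        if solver == "lu":
            u_free = self._splu(K).solve(f_free)
        elif solver == "cg":
            d = K.diagonal()
            M = LinearOperator(K.shape, matvec=lambda v: v / d)
            u_free, info = cg(K, f_free, x0=x0_free, rtol=rtol, atol=0.0,
                              maxiter=maxiter, M=M)
            if info != 0:
                raise RuntimeError(f"CG failed to converge (info={info})")
        elif solver == "factor_cg":
            u_free = self._factored_cg(K, f_free, x0_free, rtol, maxiter)
        else:
            raise ValueError(f"unknown solver {solver!r}")
        u[~self.fixed] = u_free
        return u

    @staticmethod
    def _splu(K):
        return splu(K.tocsc(), permc_spec="MMD_AT_PLUS_A",
                    options=dict(SymmetricMode=True))

    def _factored_cg(self, K, b, x0, rtol, maxiter):
        """CG preconditioned by a cached LU factor of a (possibly stale)
        stiffness matrix; refactors when convergence degrades.

        As the tissue stiffens over simulated weeks the cached factor ages;
        once CG needs more than ``refactor_threshold`` iterations the
        factor is rebuilt from the current matrix.  Deterministic.
        """
        fresh = False
        if self._factor is None:
            self._factor = self._splu(K)
            self.n_factorizations = getattr(self, "n_factorizations", 0) + 1
            fresh = True
        for _ in range(2):
            M = LinearOperator(K.shape, matvec=self._factor.solve)
            iters = [0]

            def _count(_x):
                iters[0] += 1

            u, info = cg(K, b, x0=x0, rtol=rtol, atol=0.0, M=M,
                         maxiter=min(maxiter, 4 * self.refactor_threshold),
                         callback=_count)
            self.last_iterations = iters[0]
            if info == 0 and iters[0] <= self.refactor_threshold:
                return u
            if info == 0:
                # converged but slowly: accept, refactor for next call
                self._factor = self._splu(K)
                self.n_factorizations += 1
                return u
            if fresh:
                break
            self._factor = self._splu(K)
            self.n_factorizations += 1
            fresh = True
        raise RuntimeError("preconditioned CG failed to converge")

    def element_strains(self, u: np.ndarray) -> np.ndarray:
        """Voigt strains (n_elem, 6) at element centers."""
        ue = u[self.edofs]  # (ne, 24)
        return ue @ self.b_center.T

    # -- boundary condition / load helpers

    def distal_face_fixed(self) -> np.ndarray:
        """Bool dof array fixing all dofs of nodes on the z = 0 plane."""
        coords = self.node_coords()
        fixed_nodes = np.isclose(coords[:, 2], self.origin[2])
        return np.repeat(fixed_nodes, 3)

    def proximal_traction_load(self, load: LoadCase) -> np.ndarray:
        """Consistent nodal forces for the resultants on the top cross-section.

        The normal traction sigma_zz(x, y) = -F/A + Mx*y/Ixx - My*x/Iyy is
        integrated over the exposed top faces of the active elements
        (positive ``axial_force`` is compression).
        """
        nz = self.shape[2]
        top = self.elem_index[2] == nz - 1
        if not top.any():
            raise ValueError("no active elements on the proximal face")
        h = self.h
        coords = self.node_coords()
        # face-center coordinates of top faces
        ex = self.elem_index[0][top] * h + self.origin[0] + h / 2
        ey = self.elem_index[1][top] * h + self.origin[1] + h / 2
        area = top.sum() * h * h
        Ixx = float(np.sum(h * h * (ey**2 + h * h / 12)))
        Iyy = float(np.sum(h * h * (ex**2 + h * h / 12)))
        c0 = -load.axial_force / area
        c1 = -load.moment_y / Iyy if Iyy > 0 else 0.0  # sigma from My: -My*x/Iyy
        c2 = load.moment_x / Ixx if Ixx > 0 else 0.0   # sigma from Mx: +Mx*y/Ixx
        sigma_c = c0 + c1 * ex + c2 * ey

        f = np.zeros(self.ndof)
        top_elems = np.nonzero(top)[0]
        face_nodes = self.enodes[top_elems][:, 4:]  # local dz=1 nodes: 4..7
        for a in range(4):
            nodes = face_nodes[:, a]
            xi_x = coords[nodes, 0] - ex
            xi_y = coords[nodes, 1] - ey
            fa = (h * h / 4) * sigma_c + (h * h / 12) * (c1 * xi_x + c2 * xi_y)
            np.add.at(f, 3 * nodes + 2, fa)
        return f


# ---------------------------------------------------------------------------
# domain-level wrapper


def make_fem(domain: Domain, table: MaterialTable) -> VoxelFEM:
    """Construct and constrain the FE problem for a built domain.

    Canal marrow is excluded from the mesh (its stiffness is negligible and
    the nail-to-bone load path runs through the locking screws); everything
    else non-outside is meshed.
    """
    active = (domain.region != Region.OUTSIDE) & (domain.region != Region.CANAL)
    fem = VoxelFEM(active, domain.voxel_size, nu=table.poisson)
    fem.set_fixed(fem.distal_face_fixed())
    return fem


def assemble_and_solve(domain: Domain, moduli: np.ndarray, load: LoadCase,
                       fem: VoxelFEM | None = None,
                       x0: np.ndarray | None = None,
                       rtol: float = 1e-8,
                       solver: str = "auto") -> tuple[StrainField, np.ndarray]:
    """Solve the elastostatic problem for per-voxel moduli.

    ``moduli`` is the full-grid Young's-modulus array from
    :func:`homogenize`.  Returns the strain field and the displacement
    vector (reusable as the next warm start).  A prebuilt ``fem`` (pattern
    cached across days) may be supplied.
    """
    if fem is None:
        fem = make_fem(domain, MaterialTable())
    E_elem = moduli[fem.elem_index]
    f = fem.proximal_traction_load(load)
    u = fem.solve(E_elem, f, x0=x0, rtol=rtol, solver=solver)
    eps = fem.element_strains(u)
    distortional, dilatational = strain_invariants(eps)
    dist_grid = np.zeros(domain.grid_shape)
    dil_grid = np.zeros(domain.grid_shape)
    dist_grid[fem.elem_index] = distortional
    dil_grid[fem.elem_index] = dilatational
    field = StrainField(distortional=dist_grid, dilatational=dil_grid,
                        element_strain=eps, element_index=fem.elem_index)
    return field, u
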