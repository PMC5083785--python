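"""Nonlinear mechanics of the pressurized cell-wall patch.

The wall patch is modelled as a thin, initially flat Saint Venant–Kirchhoff
(SVK) shell under follower (surface-normal) turgor pressure with fully fixed
edges. The formulation is a geometrically nonlinear membrane — in-plane
Green–Lagrange strain of the mid-surface map, plane-stress SVK response
through the thickness — augmented with a linear Reissner–Mindlin bending
term at the physical thickness. The bending term supplies the out-of-plane
stiffness of the flat reference state (a flat membrane alone has a singular
tangent at load onset) and the correct small-load plate limit; at the loads
of interest the response is membrane-dominated (h/L = 0.5/20) and the
reported stresses are mid-surface membrane stresses.

Equilibrium δW = ∫ S : δE dV − ∫ t₀·δv dA = 0 (no body force) is solved by
incremental load stepping with Newton iterations; the pressure load follows
the deformed surface normal, making the tangent nonsymmetric.

Units: lengths in μm, moduli and pressures in MPa, forces in MPa·μm²
(μN), consistent throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .geometry import ShellMesh

ATMOSPHERE_MPA = 0.101325  # 1 atm, exactly


class IncompressibilityError(ValueError):
    """Poisson ratio at or beyond the incompressible limit."""


class NonConvergenceError(RuntimeError):
    def __init__(self, msg: str, load_fraction: float):
        super().__init__(msg)
        self.load_fraction = load_fraction


class InvertedElementError(RuntimeError):
    """Element area stretch J <= 0."""


# ---------------------------------------------------------------------------
# Material
# ---------------------------------------------------------------------------

def lame_from_engineering(E_Y: float, nu: float) -> tuple[float, float]:
    """Lamé coefficients (λ, μ) from Young's modulus and Poisson ratio.

    Inverts E_Y = μ(2μ + 3λ)/(λ + μ), ν = λ/(2(λ + μ)).
    """
    if E_Y <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0 <= nu < 0.5:
        raise IncompressibilityError("Poisson ratio must lie in [0, 0.5)")
    mu = E_Y / (2.0 * (1.0 + nu))
    lam = E_Y * nu / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return lam, mu


@dataclass(frozen=True)
class MaterialParams:
    """Isotropic SVK material (MPa)."""

    E_Y: float
    nu: float
    lam: float = field(init=False)
    mu: float = field(init=False)

    def __post_init__(self):
        lam, mu = lame_from_engineering(self.E_Y, self.nu)
        object.__setattr__(self, "lam", lam)
        object.__setattr__(self, "mu", mu)

    @property
    def lam_plane_stress(self) -> float:
        """Effective λ enforcing zero through-thickness stress."""
        return 2.0 * self.lam * self.mu / (self.lam + 2.0 * self.mu)

    def stiffness_matrix(self) -> np.ndarray:
        """Plane-stress constitutive matrix for [E11, E22, 2E12] (MPa)."""
        lam, mu = self.lam_plane_stress, self.mu
        return np.array([
            [lam + 2 * mu, lam, 0.0],
            [lam, lam + 2 * mu, 0.0],
            [0.0, 0.0, mu],
        ])


def svk_stress(E: np.ndarray, material: MaterialParams,
               mode: str = "plane_stress") -> np.ndarray:
    """Second Piola–Kirchhoff stress S = λ tr(E) I + 2μ E.

    ``mode='plane_stress'`` substitutes λ → 2λμ/(λ+2μ) so that the
    through-thickness normal stress vanishes; ``mode='3D'`` uses the bulk λ.
    """
    E = np.asarray(E, dtype=float)
    if not np.allclose(E, np.swapaxes(E, -1, -2)):
        raise ValueError("strain tensor must be symmetric")
    if mode == "plane_stress":
        lam = material.lam_plane_stress
    elif mode == "3D":
        lam = material.lam
    else:
        raise ValueError("mode must be '3D' or 'plane_stress'")
    tr = np.trace(E, axis1=-2, axis2=-1)
    eye = np.eye(E.shape[-1])
    return lam * tr[..., None, None] * eye + 2.0 * material.mu * E


# ---------------------------------------------------------------------------
# Loads and options
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LoadField:
    """Turgor pressures per region; the applied load is turgor − 1 atm."""

    pressure_outer: float = 0.2
    pressure_inner: float = 0.2
    atmospheric: float = ATMOSPHERE_MPA

    def effective(self, region: str) -> float:
        p = self.pressure_inner if region == "inner" else self.pressure_outer
        eff = p - self.atmospheric
        if eff < 0:
            raise ValueError(f"effective load in region '{region}' is negative")
        return eff


@dataclass
class SolverOptions:
    n_load_steps: int = 10
    rtol: float = 1e-8
    max_iterations: int = 50
    max_step_halvings: int = 4


@dataclass
class KinematicState:
    """Converged kinematics and per-element mid-surface stress measures."""

    displacements: np.ndarray       # (n_nodes, 3)
    rotations: np.ndarray           # (n_nodes, 2) bending rotations
    F: np.ndarray                   # (n_el, 3, 2) mid-surface deformation gradient
    E: np.ndarray                   # (n_el, 2, 2) Green–Lagrange strain
    S: np.ndarray                   # (n_el, 2, 2) second Piola–Kirchhoff, MPa
    sigma: np.ndarray               # (n_el, 3, 3) Cauchy stress, MPa
    J: np.ndarray                   # (n_el,) area stretch
    mesh: ShellMesh = None
    load_fraction: float = 1.0
    residual_history: list = field(default_factory=list)


@dataclass
class StressField:
    """Principal in-plane Cauchy stresses and directions per element."""

    sigma_1: np.ndarray             # (n_el,) max principal, MPa
    sigma_2: np.ndarray             # (n_el,) min principal, MPa
    dir_1: np.ndarray               # (n_el, 3) unit vectors, global frame
    dir_2: np.ndarray
    sigma: np.ndarray               # (n_el, 3, 3) full Cauchy tensors
    centroids: np.ndarray           # (n_el, 2) reference centroids
    mesh: ShellMesh = None

    @property
    def max_magnitude(self) -> np.ndarray:
        return np.maximum(np.abs(self.sigma_1), np.abs(self.sigma_2))


# ---------------------------------------------------------------------------
# Element groups (vectorized over elements)
# ---------------------------------------------------------------------------

_GP2 = 1.0 / np.sqrt(3.0)


def _quad_shape(xi, eta):
    N = 0.25 * np.array([(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
                         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)])
    dN = 0.25 * np.array([
        [-(1 - eta), -(1 - xi)],
        [(1 - eta), -(1 + xi)],
        [(1 + eta), (1 + xi)],
        [-(1 + eta), (1 - xi)],
    ])
    return N, dN


class _ElementGroup:
    """Precomputed reference-geometry quantities for one element family."""

    def __init__(self, conn: np.ndarray, nodes_xy: np.ndarray, kind: str):
        self.conn = conn
        self.kind = kind
        self.nel, self.nn = conn.shape
        if kind == "quad":
            pts = [(-_GP2, -_GP2), (_GP2, -_GP2), (_GP2, _GP2), (-_GP2, _GP2)]
            shapes = [_quad_shape(*p) for p in pts]
            self.N = np.array([s[0] for s in shapes])            # (G, nn)
            self.dNdxi = np.array([s[1] for s in shapes])        # (G, nn, 2)
            self.wgp = np.ones(4)
            Nc, dNc = _quad_shape(0.0, 0.0)
            self.N_c, self.dNdxi_c = Nc, dNc
        else:  # linear triangle, 1-point rule
            self.N = np.array([[1 / 3, 1 / 3, 1 / 3]])
            self.dNdxi = np.array([[[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]]])
            self.wgp = np.array([0.5])
            self.N_c, self.dNdxi_c = self.N[0], self.dNdxi[0]
        self.ngp = len(self.wgp)

        X = nodes_xy[conn]                                        # (E, nn, 2)
        # reference Jacobian per element per GP
        Jref = np.einsum("enk,gnl->egkl", X, self.dNdxi)          # (E, G, 2, 2)
        self.detJ = np.linalg.det(Jref)
        if np.any(self.detJ <= 0):
            raise InvertedElementError("non-positive reference Jacobian")
        Jinv = np.linalg.inv(Jref)
        self.dNdX = np.einsum("gnk,egkl->egnl", self.dNdxi, Jinv)  # (E, G, nn, 2)
        # center-point quantities (shear term)
        Jc = np.einsum("enk,nl->ekl", X, self.dNdxi_c)
        self.detJ_c = np.linalg.det(Jc)
        self.dNdX_c = np.einsum("nk,ekl->enl", self.dNdxi_c, np.linalg.inv(Jc))
        self.w_c = 4.0 if kind == "quad" else 0.5


def _element_groups(mesh: ShellMesh):
    groups = []
    if len(mesh.quads):
        groups.append(_ElementGroup(mesh.quads, mesh.nodes[:, :2], "quad"))
    if len(mesh.tris):
        groups.append(_ElementGroup(mesh.tris, mesh.nodes[:, :2], "tri"))
    return groups


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class _Model:
    """Assembled discrete model: membrane internal force/tangent, constant
    bending/shear stiffness, follower pressure load."""

    SHEAR_CORRECTION = 5.0 / 6.0

    def __init__(self, mesh: ShellMesh, materials: dict[str, MaterialParams],
                 loads: LoadField):
        self.mesh = mesh
        self.ndof = 5 * len(mesh.nodes)
        self.groups = _element_groups(mesh)
        # per-element material/load in global element order (quads then tris)
        D = np.empty((mesh.n_elements, 3, 3))
        self.h = np.asarray(mesh.thickness, dtype=float)
        self.p_eff = np.empty(mesh.n_elements)
        for e in range(mesh.n_elements):
            region = mesh.region_label[e]
            D[e] = materials[region].stiffness_matrix()
            self.p_eff[e] = loads.effective(region)
        self.D = D
        # group slices in global element order
        off = 0
        self.slices = []
        for g in self.groups:
            self.slices.append(slice(off, off + g.nel))
            off += g.nel

        self.K_bend = self._assemble_bending(materials)
        self._index_cache = {}

        fixed = np.asarray(mesh.fixed_node_set, dtype=int)
        mask = np.ones(self.ndof, dtype=bool)
        for k in range(5):
            mask[5 * fixed + k] = False
        self.free = np.flatnonzero(mask)

    # -- dof index helpers ---------------------------------------------------
    def _trans_dofs(self, g: _ElementGroup) -> np.ndarray:
        """(E, 3*nn) translation dof ids per element."""
        return (5 * g.conn[:, :, None] + np.arange(3)).reshape(g.nel, -1)

    def _block_indices(self, dofs: np.ndarray):
        key = (dofs.shape, dofs[0, 0], dofs[-1, -1])
        if key not in self._index_cache:
            m = dofs.shape[1]
            rows = np.repeat(dofs, m, axis=1).ravel()
            cols = np.tile(dofs, (1, m)).ravel()
            self._index_cache[key] = (rows, cols)
        return self._index_cache[key]

    # -- constant bending + shear stiffness ----------------------------------
    def _assemble_bending(self, materials) -> sp.csr_matrix:
        rows, cols, vals = [], [], []
        for g, sl in zip(self.groups, self.slices):
            h = self.h[sl]
            Dps = self.D[sl]                                    # (E,3,3)
            Db = Dps * (h**3 / 12.0)[:, None, None]
            mu = Dps[:, 2, 2]                                   # μ per element
            Gs = self.SHEAR_CORRECTION * mu * h                 # (E,)

            # bending dofs per node: (w, bx, by) -> local layout per node a:
            # dofs [5n+2, 5n+3, 5n+4]
            dofs = (5 * g.conn[:, :, None] + np.array([2, 3, 4])).reshape(g.nel, -1)
            nn = g.nn
            Kb = np.zeros((g.nel, 3 * nn, 3 * nn))
            # curvature term (full integration)
            for gp in range(g.ngp):
                dN = g.dNdX[:, gp]                              # (E, nn, 2)
                B = np.zeros((g.nel, 3, 3 * nn))
                B[:, 0, 1::3] = dN[:, :, 0]                     # bx,x
                B[:, 1, 2::3] = dN[:, :, 1]                     # by,y
                B[:, 2, 1::3] = dN[:, :, 1]
                B[:, 2, 2::3] = dN[:, :, 0]
                w = g.wgp[gp] * g.detJ[:, gp]
                Kb += w[:, None, None] * np.einsum("eci,ecd,edj->eij", B, Db, B)
            # shear term (single-point integration against locking)
            Bs = np.zeros((g.nel, 2, 3 * nn))
            Bs[:, 0, 0::3] = g.dNdX_c[:, :, 0]
            Bs[:, 1, 0::3] = g.dNdX_c[:, :, 1]
            Bs[:, 0, 1::3] = -g.N_c
            Bs[:, 1, 2::3] = -g.N_c
            w = g.w_c * g.detJ_c * Gs
            Kb += w[:, None, None] * np.einsum("eci,ecj->eij", Bs, Bs)

            m = 3 * nn
            rows.append(np.repeat(dofs, m, axis=1).ravel())
            cols.append(np.tile(dofs, (1, m)).ravel())
            vals.append(Kb.ravel())
        return sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof)).tocsr()

    # -- membrane kinematics ---------------------------------------------------
    def _deformed(self, d: np.ndarray, g: _ElementGroup) -> np.ndarray:
        """Deformed nodal positions (E, nn, 3)."""
        u = d.reshape(-1, 5)[:, :3]
        return (self.mesh.nodes + u)[g.conn]

    def membrane_force_tangent(self, d: np.ndarray, want_tangent: bool = True):
        """Membrane internal force and (optionally) tangent stiffness."""
        f = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        for g, sl in zip(self.groups, self.slices):
            xdef = self._deformed(d, g)                         # (E, nn, 3)
            h = self.h[sl]
            D = self.D[sl]
            dofs = self._trans_dofs(g)
            nn = g.nn
            Ke = np.zeros((g.nel, 3 * nn, 3 * nn)) if want_tangent else None
            fe = np.zeros((g.nel, 3 * nn))
            for gp in range(g.ngp):
                dN = g.dNdX[:, gp]                              # (E, nn, 2)
                G = np.einsum("eni,enk->eik", xdef, dN)         # (E, 3, 2)
                C = np.einsum("eik,eil->ekl", G, G)
                Ev = np.stack([
                    0.5 * (C[:, 0, 0] - 1.0),
                    0.5 * (C[:, 1, 1] - 1.0),
                    C[:, 0, 1],
                ], axis=1)                                      # [E11,E22,2E12]
                Sv = np.einsum("ecd,ed->ec", D, Ev)
                # B matrix (E, 3, 3nn)
                B = np.zeros((g.nel, 3, 3 * nn))
                for a in range(nn):
                    cols3 = slice(3 * a, 3 * a + 3)
                    B[:, 0, cols3] = dN[:, a, 0, None] * G[:, :, 0]
                    B[:, 1, cols3] = dN[:, a, 1, None] * G[:, :, 1]
                    B[:, 2, cols3] = (dN[:, a, 0, None] * G[:, :, 1]
                                      + dN[:, a, 1, None] * G[:, :, 0])
                w = h * g.wgp[gp] * g.detJ[:, gp]
                fe += w[:, None] * np.einsum("eci,ec->ei", B, Sv)
                if want_tangent:
                    Ke += w[:, None, None] * np.einsum("eci,ecd,edj->eij", B, D, B)
                    Smat = np.empty((g.nel, 2, 2))
                    Smat[:, 0, 0] = Sv[:, 0]
                    Smat[:, 1, 1] = Sv[:, 1]
                    Smat[:, 0, 1] = Smat[:, 1, 0] = Sv[:, 2]
                    sab = np.einsum("eak,ekl,ebl->eab", dN, Smat, dN)
                    Ke += w[:, None, None] * np.kron(sab, np.eye(3))
            np.add.at(f, dofs.ravel(), fe.ravel())
            if want_tangent:
                r, c = self._block_indices(dofs)
                rows.append(r)
                cols.append(c)
                vals.append(Ke.ravel())
        K = None
        if want_tangent:
            K = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.ndof, self.ndof)).tocsr()
        return f, K

    def membrane_energy(self, d: np.ndarray) -> float:
        U = 0.0
        for g, sl in zip(self.groups, self.slices):
            xdef = self._deformed(d, g)
            h, D = self.h[sl], self.D[sl]
            for gp in range(g.ngp):
                dN = g.dNdX[:, gp]
                G = np.einsum("eni,enk->eik", xdef, dN)
                C = np.einsum("eik,eil->ekl", G, G)
                Ev = np.stack([0.5 * (C[:, 0, 0] - 1), 0.5 * (C[:, 1, 1] - 1),
                               C[:, 0, 1]], axis=1)
                w = h * g.wgp[gp] * g.detJ[:, gp]
                U += np.sum(0.5 * w * np.einsum("ec,ecd,ed->e", Ev, D, Ev))
        return U

    def internal_force(self, d, want_tangent=True):
        f, K = self.membrane_force_tangent(d, want_tangent)
        f = f + self.K_bend @ d
        if want_tangent:
            K = K + self.K_bend
        return f, K

    def total_energy(self, d) -> float:
        return self.membrane_energy(d) + 0.5 * d @ (self.K_bend @ d)

    # -- follower pressure -----------------------------------------------------
    def external_force_tangent(self, d: np.ndarray, want_tangent: bool = True):
        f = np.zeros(self.ndof)
        rows, cols, vals = [], [], []
        for g, sl in zip(self.groups, self.slices):
            xdef = self._deformed(d, g)
            p = self.p_eff[sl]
            dofs = self._trans_dofs(g)
            nn = g.nn
            fe = np.zeros((g.nel, 3 * nn))
            Ke = np.zeros((g.nel, 3 * nn, 3 * nn)) if want_tangent else None
            for gp in range(g.ngp):
                dNxi = g.dNdxi[gp]                              # (nn, 2)
                a1 = np.einsum("eni,n->ei", xdef, dNxi[:, 0])
                a2 = np.einsum("eni,n->ei", xdef, dNxi[:, 1])
                n_vec = np.cross(a1, a2)                        # (E, 3)
                w = g.wgp[gp] * p
                fe += w[:, None] * np.einsum("n,ei->eni", g.N[gp], n_vec
                                             ).reshape(g.nel, -1)
                if want_tangent:
                    A1 = _cross_matrix(a1)
                    A2 = _cross_matrix(a2)
                    # d(a1 x a2)/du_b = -[a2]x dN_b,xi + [a1]x dN_b,eta
                    Kb = (-np.einsum("eij,n->enij", A2, dNxi[:, 0])
                          + np.einsum("eij,n->enij", A1, dNxi[:, 1]))  # (E,nn,3,3)
                    Ke += w[:, None, None] * _expand_load_tangent(g.N[gp], Kb)
            np.add.at(f, dofs.ravel(), fe.ravel())
            if want_tangent:
                r, c = self._block_indices(dofs)
                rows.append(r)
                cols.append(c)
                vals.append(Ke.ravel())
        K = None
        if want_tangent:
            K = sp.coo_matrix(
                (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
                shape=(self.ndof, self.ndof)).tocsr()
        return f, K

    # -- stress recovery -------------------------------------------------------
    def stresses(self, d: np.ndarray):
        nel = self.mesh.n_elements
        F = np.zeros((nel, 3, 2))
        Emat = np.zeros((nel, 2, 2))
        Smat = np.zeros((nel, 2, 2))
        sigma = np.zeros((nel, 3, 3))
        Jout = np.zeros(nel)
        for g, sl in zip(self.groups, self.slices):
            xdef = self._deformed(d, g)
            D = self.D[sl]
            Gsum = np.zeros((g.nel, 3, 2))
            wsum = np.zeros(g.nel)
            for gp in range(g.ngp):
                dN = g.dNdX[:, gp]
                G = np.einsum("eni,enk->eik", xdef, dN)
                w = g.wgp[gp] * g.detJ[:, gp]
                Gsum += w[:, None, None] * G
                wsum += w
            G = Gsum / wsum[:, None, None]
            C = np.einsum("eik,eil->ekl", G, G)
            E2 = 0.5 * (C - np.eye(2))
            Ev = np.stack([E2[:, 0, 0], E2[:, 1, 1], 2 * E2[:, 0, 1]], axis=1)
            Sv = np.einsum("ecd,ed->ec", D, Ev)
            S2 = np.empty_like(E2)
            S2[:, 0, 0], S2[:, 1, 1] = Sv[:, 0], Sv[:, 1]
            S2[:, 0, 1] = S2[:, 1, 0] = Sv[:, 2]
            J = np.linalg.norm(np.cross(G[:, :, 0], G[:, :, 1], axis=1), axis=1)
            if np.any(J <= 0):
                raise InvertedElementError("element area stretch J <= 0")
            sig = np.einsum("eik,ekl,ejl->eij", G, S2, G) / J[:, None, None]
            F[sl], Emat[sl], Smat[sl], sigma[sl], Jout[sl] = G, E2, S2, sig, J
        return F, Emat, Smat, sigma, Jout


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    """Skew matrices [v]x for an (E, 3) array."""
    E = len(v)
    M = np.zeros((E, 3, 3))
    M[:, 0, 1], M[:, 0, 2] = -v[:, 2], v[:, 1]
    M[:, 1, 0], M[:, 1, 2] = v[:, 2], -v[:, 0]
    M[:, 2, 0], M[:, 2, 1] = -v[:, 1], v[:, 0]
    return M


def _expand_load_tangent(N: np.ndarray, Kb: np.ndarray) -> np.ndarray:
    """Assemble (E, 3nn, 3nn) follower-load tangent from nodal weights N (nn,)
    and per-node 3×3 blocks Kb (E, nn, 3, 3): block (a, b) = N_a * Kb[:, b]."""
    E, nn = Kb.shape[0], Kb.shape[1]
    out = np.zeros((E, 3 * nn, 3 * nn))
    for a in range(nn):
        for b in range(nn):
            out[:, 3 * a:3 * a + 3, 3 * b:3 * b + 3] = N[a] * Kb[:, b]
    return out


# ---------------------------------------------------------------------------
# Solver
# ---------------------------------------------------------------------------

def solve_equilibrium(mesh: ShellMesh, materials: dict[str, MaterialParams],
                      loads: LoadField,
                      options: SolverOptions | None = None) -> KinematicState:
    """Static equilibrium under follower turgor pressure.

    Incremental loading to the full effective pressure with Newton iterations
    per step; residual convergence ‖R‖ ≤ rtol·‖f_ext‖. Deterministic for a
    fixed mesh and options. On Newton divergence the increment is halved (up
    to ``max_step_halvings``); persistent failure raises
    :class:`NonConvergenceError` reporting the last converged load fraction.
    """
    options = options or SolverOptions()
    model = _Model(mesh, materials, loads)
    d = np.zeros(model.ndof)
    free = model.free
    history = []

    if np.all(model.p_eff == 0.0):
        F, E2, S2, sig, J = model.stresses(d)
        return KinematicState(d.reshape(-1, 5)[:, :3], d.reshape(-1, 5)[:, 3:],
                              F, E2, S2, sig, J, mesh=mesh,
                              residual_history=history)

    lam_done = 0.0
    dlam = 1.0 / options.n_load_steps
    halvings = 0
    while lam_done < 1.0 - 1e-12:
        lam = lam_done + dlam
        if lam > 1.0 - 1e-9:
            lam = 1.0
        d_trial = d.copy()
        converged = False
        for it in range(options.max_iterations):
            f_int, K_int = model.internal_force(d_trial)
            f_ext, K_ext = model.external_force_tangent(d_trial)
            R = f_int - lam * f_ext
            ref = max(np.linalg.norm(lam * f_ext[free]), 1e-30)
            res = np.linalg.norm(R[free]) / ref
            history.append((lam, it, res))
            if res < options.rtol:
                converged = True
                break
            K = (K_int - lam * K_ext).tocsc()[free][:, free]
            delta = spsolve(K, -R[free])
            if not np.all(np.isfinite(delta)):
                break
            d_trial[free] += delta
        if converged:
            d = d_trial
            lam_done = lam
        else:
            halvings += 1
            dlam *= 0.5
            if halvings > options.max_step_halvings:
                raise NonConvergenceError(
                    f"Newton failed at load fraction {lam:.4f}", lam_done)

    F, E2, S2, sig, J = model.stresses(d)
    u = d.reshape(-1, 5)
    return KinematicState(u[:, :3].copy(), u[:, 3:].copy(), F, E2, S2, sig, J,
                          mesh=mesh, load_fraction=lam_done,
                          residual_history=history)


# ---------------------------------------------------------------------------
# Principal stresses
# ---------------------------------------------------------------------------

def cauchy_and_principal(state: KinematicState) -> StressField:
    """Principal in-plane Cauchy stresses from a converged state.

    The Cauchy tensor σ = (1/J) F S Fᵀ lives in the deformed tangent plane;
    its two in-plane eigenpairs are extracted in an orthonormal tangent basis
    and the directions are reported in the global frame.
    """
    if np.any(state.J <= 0):
        raise InvertedElementError("state contains inverted elements")
    G = state.F
    e1 = G[:, :, 0] / np.linalg.norm(G[:, :, 0], axis=1, keepdims=True)
    g2 = G[:, :, 1] - np.einsum("ei,ei->e", G[:, :, 1], e1)[:, None] * e1
    e2 = g2 / np.linalg.norm(g2, axis=1, keepdims=True)
    basis = np.stack([e1, e2], axis=2)                          # (E, 3, 2)
    sig2 = np.einsum("eik,eij,ejl->ekl", basis, state.sigma, basis)
    evals, evecs = np.linalg.eigh(sig2)                         # ascending
    s1, s2 = evals[:, 1], evals[:, 0]
    d1 = np.einsum("eik,ek->ei", basis, evecs[:, :, 1])
    d2 = np.einsum("eik,ek->ei", basis, evecs[:, :, 0])
    mesh = state.mesh
    return StressField(sigma_1=s1, sigma_2=s2, dir_1=d1, dir_2=d2,
                       sigma=state.sigma, centroids=mesh.element_centroids,
                       mesh=mesh)
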