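"""Finite-strain hyperelastic deformation of the clamped intimal flap.

Solves the structural momentum balance ``rho_s dv/dt = div(sigma_s)`` (or
its static limit) for the planar flap strip under interface tractions, with
plane-strain kinematics, quadratic triangles, a total-Lagrangian Newton
iteration, and near-incompressibility through the materials-module
volumetric penalty.  Clamped edges carry zero displacement.

Units: geometry mm, stresses MPa, tractions supplied in Pa (converted
internally), density kg/m^3 (converted to tonne/mm^3), time s.
Displacements are mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from ._fem import (
    EDGE_QP,
    EDGE_QW,
    TRI_QP,
    TRI_QW,
    P2Mesh,
    edge_lengths_normals,
    p2_basis,
    p2_edge_basis,
    physical_gradients,
    scatter,
)
from .materials import energy_density_plane_strain, pk1_plane_strain

__all__ = [
    "SolidProperties",
    "TractionField",
    "DisplacementField",
    "solve_flap_statics",
    "solve_flap_dynamics",
    "SolidSolverError",
]

PA_PER_MPA = 1e6
#: kg/m^3 -> tonne/mm^3 (consistent mm-N-MPa-s unit system)
DENSITY_FACTOR = 1e-12


class SolidSolverError(RuntimeError):
    pass


@dataclass(frozen=True)
class SolidProperties:
    """Flap density (kg/m^3; the value is not critical for steady results and
    defaults to a typical silicone) and constitutive parameters."""

    material: object
    density: float = 1100.0

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass
class TractionField:
    """Tractions (Pa) on tagged boundary edges of the solid mesh.

    ``per_edge`` maps an edge-tag name to an (m, 2) array aligned with the
    tag's edge list (or a single (2,) vector applied to every edge).
    """

    per_edge: dict[str, np.ndarray]

    def edge_values(self, tag: str, n_edges: int) -> np.ndarray:
        v = np.asarray(self.per_edge[tag], dtype=float)
        if v.ndim == 1:
            v = np.tile(v, (n_edges, 1))
        if v.shape != (n_edges, 2) or not np.all(np.isfinite(v)):
            raise ValueError(f"traction on {tag!r} must be finite with shape ({n_edges}, 2)")
        return v


@dataclass
class DisplacementField:
    """Displacement (mm) and, on the dynamic path, velocity (mm/s) at P2
    nodes; ``history`` holds per-load-step/time-step convergence info."""

    displacement: np.ndarray
    mesh: P2Mesh
    velocity: np.ndarray | None = None
    history: list = field(default_factory=list)
    internal_energy: float = 0.0  # N mm per unit out-of-plane mm

    def on_tag(self, tag: str) -> np.ndarray:
        nodes = np.unique(self.mesh.edge_tags[tag].ravel())
        return self.displacement[nodes]


class _SolidOperators:
    def __init__(self, mesh: P2Mesh):
        self.mesh = mesh
        self.g, self.detJ = physical_gradients(mesh)  # reference config, mm
        if np.any(self.detJ <= 0):
            raise ValueError("solid mesh has inverted elements")
        self.phi = p2_basis(TRI_QP)
        self.wq = TRI_QW[None, :] * self.detJ[:, None]
        n = mesh.n_nodes
        rows = np.repeat(mesh.t2, 6, axis=1)
        cols = np.tile(mesh.t2, (1, 6))
        Me = np.einsum("eq,qi,qj->eij", self.wq, self.phi, self.phi)
        self.M = scatter(rows, cols, Me, (n, n))
        self._rows = rows
        self._cols = cols

    def deformation_gradient(self, u: np.ndarray):
        ue = u[self.mesh.t2]  # (ne, 6, 2)
        gradu = np.einsum("eqid,eic->eqcd", self.g, ue)
        F = gradu.copy()
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        return F

    def internal_force(self, u: np.ndarray, material) -> np.ndarray:
        F = self.deformation_gradient(u)
        P = pk1_plane_strain(F, material)  # MPa
        fe = np.einsum("eq,eqcd,eqid->eic", self.wq, P, self.g)
        out = np.zeros((self.mesh.n_nodes, 2))
        np.add.at(out, self.mesh.t2.ravel(), fe.reshape(-1, 2))
        return out

    def tangent(self, u: np.ndarray, material, eps: float = 1e-7) -> sp.csr_matrix:
        """Consistent tangent by directional finite differences of P(F)."""
        F = self.deformation_gradient(u)
        P0 = pk1_plane_strain(F, material)
        A = np.empty(F.shape[:2] + (2, 2, 2, 2))  # (ne,nq,c,d,e,f)
        scale = max(1.0, float(np.abs(F).max()))
        h = eps * scale
        for e_ in range(2):
            for f_ in range(2):
                Fp = F.copy()
                Fp[..., e_, f_] += h
                A[..., e_, f_] = (pk1_plane_strain(Fp, material) - P0) / h
        # K[(i,c),(j,e)] = sum_q w A[c,d,e,f] g_j,f g_i,d
        Ke = np.einsum("eq,eqcdxf,eqjf,eqid->eicjx", self.wq, A, self.g, self.g)
        n = self.mesh.n_nodes
        t2 = self.mesh.t2
        # expand to dof indices (node*2 + comp)
        dofs = (t2[:, :, None] * 2 + np.arange(2)[None, None, :]).reshape(-1, 12)
        rows = np.repeat(dofs, 12, axis=1)
        cols = np.tile(dofs, (1, 12))
        return scatter(rows, cols, Ke.reshape(-1, 12, 12), (2 * n, 2 * n))

    def strain_energy(self, u: np.ndarray, material) -> float:
        F = self.deformation_gradient(u)
        return float(np.sum(self.wq * energy_density_plane_strain(F, material)))


def external_load(mesh: P2Mesh, traction: TractionField) -> np.ndarray:
    """Consistent nodal load (N/mm, i.e. MPa*mm) from edge tractions in Pa,
    integrated over the reference configuration (dead load)."""
    fext = np.zeros((mesh.n_nodes, 2))
    sh = p2_edge_basis(EDGE_QP)
    w_int = np.einsum("q,qi->i", EDGE_QW, sh)
    for tag, _ in traction.per_edge.items():
        edges = mesh.edge_tags[tag]
        if len(edges) == 0:
            continue
        t = traction.edge_values(tag, len(edges)) / PA_PER_MPA  # MPa
        L, _ = edge_lengths_normals(mesh, edges)
        contrib = np.einsum("m,i,md->mid", L, w_int, t)
        np.add.at(fext, edges.ravel(), contrib.reshape(-1, 2))
    return fext


def _clamp_dofs(mesh: P2Mesh, clamp_tags) -> np.ndarray:
    nodes = np.unique(
        np.concatenate([mesh.edge_tags[t].ravel() for t in clamp_tags])
    )
    return np.concatenate([2 * nodes, 2 * nodes + 1])


def _newton(ops, material, fext_flat, u0, fixed, tol, max_iter, extra_lhs=None, extra_res=None):
    """Newton loop for R(u) = f_int(u) [+ extra_res(u)] - f_ext = 0."""
    n = ops.mesh.n_nodes
    u = u0.copy()
    u.reshape(-1)[fixed] = 0.0
    ref = max(np.linalg.norm(fext_flat), 1e-12)
    ref_from_residual = np.linalg.norm(fext_flat) == 0.0
    free_mask = np.ones(2 * n)
    free_mask[fixed] = 0.0
    Pf = sp.diags(free_mask)
    Df = sp.diags(1.0 - free_mask)
    hist = []
    for _ in range(max_iter):
        R = ops.internal_force(u, material).reshape(-1) - fext_flat
        if extra_res is not None:
            R = R + extra_res(u)
        R[fixed] = 0.0
        rnorm = np.linalg.norm(R)
        if ref_from_residual:
            # unloaded (free-motion) solves: reference the initial imbalance
            ref = max(rnorm, 1e-12)
            ref_from_residual = False
        hist.append(rnorm / ref)
        if rnorm <= tol * ref:
            return u, hist, True
        if not np.isfinite(rnorm) or rnorm > 1e8 * ref:
            return u, hist, False
        K = ops.tangent(u, material)
        if extra_lhs is not None:
            K = K + extra_lhs
        K = (Pf @ K @ Pf + Df).tocsc()
        du = spla.spsolve(K, -R)
        if not np.all(np.isfinite(du)):
            return u, hist, False
        # keep elements from inverting: backtrack if needed
        alpha = 1.0
        for _bt in range(25):
            u_try = u + alpha * du.reshape(-1, 2)
            F = ops.deformation_gradient(u_try)
            J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
            if np.all(J > 0):
                break
            alpha *= 0.5
        else:
            return u, hist, False
        u = u + alpha * du.reshape(-1, 2)
    return u, hist, hist[-1] < 1e3 * tol


def solve_flap_statics(
    mesh: P2Mesh,
    props: SolidProperties,
    traction: TractionField,
    clamp_tags: tuple[str, ...] = ("clamp",),
    tol: float = 1e-8,
    max_iter: int = 30,
    initial_steps: int = 1,
    max_step_halvings: int = 8,
    u0: np.ndarray | None = None,
) -> DisplacementField:
    """Static equilibrium of the clamped flap under edge tractions.

    Newton iteration with adaptive load stepping: the traction is ramped in
    ``initial_steps`` increments and the increment halves (up to
    ``max_step_halvings`` times) whenever the Newton loop diverges.
    """
    ops = _SolidOperators(mesh)
    fext = external_load(mesh, traction).reshape(-1)
    fixed = _clamp_dofs(mesh, clamp_tags)
    u = np.zeros((mesh.n_nodes, 2)) if u0 is None else u0.copy()
    history = []
    lam = 0.0
    dlam = 1.0 / initial_steps
    halvings = 0
    while lam < 1.0 - 1e-12:
        step = min(dlam, 1.0 - lam)
        u_new, hist, ok = _newton(
            ops, props.material, (lam + step) * fext, u, fixed, tol, max_iter
        )
        if ok:
            lam += step
            u = u_new
            history.append({"load_fraction": lam, "newton": hist})
        else:
            dlam = step / 2.0
            halvings += 1
            if halvings > max_step_halvings:
                raise SolidSolverError(
                    f"static solve diverged at load fraction {lam:.3f} "
                    f"after {halvings} step halvings"
                )
    return DisplacementField(
        displacement=u,
        mesh=mesh,
        history=history,
        internal_energy=ops.strain_energy(u, props.material),
    )


def solve_flap_dynamics(
    mesh: P2Mesh,
    props: SolidProperties,
    traction,
    dt: float = 2e-4,
    t_end: float = 2.0,
    clamp_tags: tuple[str, ...] = ("clamp",),
    tol: float = 1e-8,
    max_iter: int = 25,
    store_every: int = 0,
) -> DisplacementField:
    """Implicit (backward-Euler) dynamics of the flap from rest.

    ``traction`` is a :class:`TractionField` (held constant) or a callable
    ``t -> TractionField``.  Under a constant load the trajectory relaxes to
    the static equilibrium as t grows (the implicit integrator's numerical
    dissipation removes the undamped transient).
    """
    if dt <= 0 or t_end <= 0:
        raise ValueError("dt and t_end must be positive")
    ops = _SolidOperators(mesh)
    fixed = _clamp_dofs(mesh, clamp_tags)
    rho = props.density * DENSITY_FACTOR  # tonne/mm^3 ~ consistent with MPa
    n = mesh.n_nodes
    M2 = sp.block_diag([ops.M, ops.M]).tocsr()
    # interleave dof ordering (node*2+comp): build permuted mass
    perm = np.empty(2 * n, dtype=np.int64)
    perm[0::2] = np.arange(n)
    perm[1::2] = np.arange(n) + n
    Pm = sp.csr_matrix((np.ones(2 * n), (np.arange(2 * n), perm)), shape=(2 * n, 2 * n))
    M2 = (Pm @ M2 @ Pm.T).tocsr()
    u = np.zeros((n, 2))
    v = np.zeros((n, 2))
    steps = int(round(t_end / dt))
    history = []
    snapshots = []
    const_traction = traction if isinstance(traction, TractionField) else None
    fext_const = (
        external_load(mesh, const_traction).reshape(-1) if const_traction else None
    )
    for k in range(steps):
        t_new = (k + 1) * dt
        fext = (
            fext_const
            if fext_const is not None
            else external_load(mesh, traction(t_new)).reshape(-1)
        )
        u_old_flat = u.reshape(-1)
        v_old_flat = v.reshape(-1)
        coef = rho / dt**2
        lhs = coef * M2

        def extra_res(u_cur, _u0=u_old_flat, _v0=v_old_flat, _c=coef):
            return _c * (M2 @ (u_cur.reshape(-1) - _u0 - dt * _v0))

        u_new, hist, ok = _newton(
            ops, props.material, fext, u, fixed, tol, max_iter,
            extra_lhs=lhs, extra_res=extra_res,
        )
        if not ok:
            raise SolidSolverError(f"dynamic step {k + 1} (t={t_new:.4g}s) diverged")
        v = (u_new - u) / dt
        u = u_new
        history.append({"t": t_new, "newton_iters": len(hist)})
        if store_every and (k + 1) % store_every == 0:
            snapshots.append((t_new, u.copy()))
    out = DisplacementField(
        displacement=u,
        mesh=mesh,
        velocity=v,
        history=history if not snapshots else snapshots,
        internal_energy=ops.strain_energy(u, props.material),
    )
    return out
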