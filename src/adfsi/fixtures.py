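"""Analytically anchored verification fixtures for every solver stage.

Each fixture packages a small mesh, properties, boundary data, and a
closed-form (or symmetry / refinement) reference that is evaluable without
running the coupled pipeline, so every solver can be checked fast and
deterministically: a plane Poiseuille channel, a clamped flap strip under
uniform pressure, a forced (manufactured-solution) Navier-Stokes case for
convergence-order studies, a symmetric two-outlet channel, and a miniature
two-lumen collapsible-channel FSI case.  ``refinement_study`` provides the
reusable mesh-independence harness.

The pipeline has no random components; parameter-sampling tests elsewhere
use fixed seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._fem import TRI_QP, TRI_QW, P2Mesh, build_p2, p2_basis
from .fluid_solver import FlowBCs, FluidProperties, SolverOptions, branch_mass_flux, solve_flow
from .geometry import _triangulate_grid, build_reduced_ad_geometry, generate_meshes

__all__ = [
    "FixtureCase",
    "rect_mesh",
    "poiseuille_case",
    "clamped_beam_case",
    "manufactured_solution_case",
    "symmetric_branch_case",
    "collapsible_channel_case",
    "refinement_study",
    "mms_velocity_error",
]


@dataclass
class FixtureCase:
    name: str
    mesh: P2Mesh | None
    properties: dict
    bcs: object
    reference: dict
    tolerance: float
    extras: dict = field(default_factory=dict)


def rect_mesh(
    lx: float,
    ly: float,
    nx: int,
    ny: int,
    tag_style: str = "channel",
) -> P2Mesh:
    """Structured rectangle triangulation.

    ``tag_style='channel'`` tags left edge ``inlet``, right edge ``outlet``
    and the horizontal walls ``wall``; ``'dirichlet'`` tags the whole
    boundary ``boundary``.
    """
    xb = np.linspace(0.0, lx, nx + 1)
    yb = np.linspace(0.0, ly, ny + 1)
    pts, tris, bnd, _ = _triangulate_grid(xb, yb, np.ones((nx, ny), bool))
    mids = 0.5 * (pts[bnd[:, 0]] + pts[bnd[:, 1]])
    tol = 1e-9
    if tag_style == "dirichlet":
        tags = {"boundary": bnd}
    else:
        tags = {
            "inlet": bnd[np.abs(mids[:, 0]) < tol],
            "outlet": bnd[np.abs(mids[:, 0] - lx) < tol],
            "wall": bnd[(np.abs(mids[:, 1]) < tol) | (np.abs(mids[:, 1] - ly) < tol)],
        }
    return build_p2(pts, tris, tags)


def poiseuille_case(resolution: int = 1, q_lmin: float = 1.0, depth: float = 20.0) -> FixtureCase:
    """Plane Poiseuille channel with analytic pressure-drop and profile
    references: dp = 12 mu L Q / (w h^3), centerline velocity 1.5x mean."""
    n = 2**resolution
    L, h = 60.0, 10.0  # mm
    mesh = rect_mesh(L, h, 15 * n, 4 * n)
    props = FluidProperties()
    bcs = FlowBCs(
        inflow={"inlet": q_lmin},
        outlet_tags=("outlet",),
        wall_tags=("wall",),
        inlet_profile="parabolic",
        depth=depth,
    )
    q = q_lmin / 60000.0 / (depth * 1e-3)  # m^2/s per unit depth
    dp = 12.0 * props.viscosity * (L * 1e-3) * q / (h * 1e-3) ** 3
    return FixtureCase(
        name="poiseuille",
        mesh=mesh,
        properties={"fluid": props},
        bcs=bcs,
        reference={
            "pressure_drop_pa": dp,
            "centerline_over_mean": 1.5,
            "mean_velocity": q / (h * 1e-3),
        },
        tolerance=0.02,
    )


def clamped_beam_case(load_pa: float = 1000.0, E: float = 100.0, nu: float = 0.3) -> FixtureCase:
    """Clamped-clamped flap strip under uniform pressure with the
    small-deflection reference w_mid = q L^4 / (384 E' I), E' = E/(1-nu^2)
    (plane strain), I = t^3/12 per unit depth."""
    L, t = 20.0, 1.0  # mm
    mesh = rect_mesh(L, t, 40, 3)
    # re-tag for the solid solver: clamp the short ends, load the top
    bnd = np.concatenate([v[:, :2] for v in mesh.edge_tags.values()])
    pts = mesh.points
    m = 0.5 * (pts[bnd[:, 0]] + pts[bnd[:, 1]])
    tol = 1e-9
    tags = {
        "clamp": bnd[(np.abs(m[:, 0]) < tol) | (np.abs(m[:, 0] - L) < tol)],
        "top": bnd[np.abs(m[:, 1] - t) < tol],
        "bottom": bnd[np.abs(m[:, 1]) < tol],
    }
    mesh = build_p2(pts, mesh.tris, tags)
    Eprime = E / (1.0 - nu**2)
    I = t**3 / 12.0
    w_mid = (load_pa / 1e6) * L**4 / (384.0 * Eprime * I)  # mm, downward
    return FixtureCase(
        name="clamped_beam",
        mesh=mesh,
        properties={"E": E, "nu": nu},
        bcs={"top_traction_pa": (0.0, -load_pa)},
        reference={"midspan_deflection_mm": -w_mid},
        tolerance=0.05,
    )


def _mms_fields(rho: float, mu: float):
    """Divergence-free manufactured solution on the unit square and its
    body force, via symbolic differentiation."""
    import sympy as sp

    x, y = sp.symbols("x y")
    psi = sp.sin(sp.pi * x) ** 2 * sp.sin(sp.pi * y) ** 2  # streamfunction, no-slip
    u = sp.diff(psi, y)
    v = -sp.diff(psi, x)
    p = sp.cos(sp.pi * x) * sp.cos(sp.pi * y)
    fx = rho * (u * sp.diff(u, x) + v * sp.diff(u, y)) + sp.diff(p, x) - mu * (
        sp.diff(u, x, 2) + sp.diff(u, y, 2)
    )
    fy = rho * (u * sp.diff(v, x) + v * sp.diff(v, y)) + sp.diff(p, y) - mu * (
        sp.diff(v, x, 2) + sp.diff(v, y, 2)
    )
    fu = sp.lambdify((x, y), u, "numpy")
    fv = sp.lambdify((x, y), v, "numpy")
    fp = sp.lambdify((x, y), p, "numpy")
    ffx = sp.lambdify((x, y), fx, "numpy")
    ffy = sp.lambdify((x, y), fy, "numpy")
    div = sp.simplify(sp.diff(u, x) + sp.diff(v, y))
    return fu, fv, fp, ffx, ffy, div


def manufactured_solution_case(level: int = 0, rho: float = 1.0, mu: float = 0.05) -> FixtureCase:
    """Forced Navier-Stokes with a smooth exact solution (streamfunction
    ``sin^2(pi x) sin^2(pi y)``, exactly divergence-free) for
    convergence-order verification."""
    n = 8 * 2**level
    mesh = rect_mesh(1.0, 1.0, n, n, tag_style="dirichlet")
    fu, fv, fp, ffx, ffy, div = _mms_fields(rho, mu)
    props = FluidProperties(density=rho, viscosity=mu)

    def body_force(xy):
        return np.column_stack([ffx(xy[:, 0], xy[:, 1]), ffy(xy[:, 0], xy[:, 1])])

    def exact_velocity(xy):
        return np.column_stack([fu(xy[:, 0], xy[:, 1]), fv(xy[:, 0], xy[:, 1])])

    bcs = FlowBCs(
        inflow={},
        outlet_tags=("boundary",),  # placeholder; all-Dirichlet below
        wall_tags=(),
        depth=1000.0,
    )
    opts = SolverOptions(
        scale=1.0,
        body_force=body_force,
        velocity_bc={"boundary": exact_velocity},
        pin_pressure=True,
        pin_value=float(fp(mesh.points[0, 0], mesh.points[0, 1])),
        tol=1e-10,
        picard_iters=2,
    )
    return FixtureCase(
        name="mms",
        mesh=mesh,
        properties={"fluid": props},
        bcs=bcs,
        reference={"exact_velocity": exact_velocity, "exact_divergence": div},
        tolerance=0.0,
        extras={"options": opts, "level": level},
    )


def mms_velocity_error(case: FixtureCase) -> float:
    """L2 velocity error of the solved manufactured-solution case."""
    field = solve_flow(case.mesh, case.properties["fluid"], case.bcs, case.extras["options"])
    mesh = case.mesh
    phi = p2_basis(TRI_QP)
    coords = mesh.nodes
    xq = np.einsum("qi,eid->eqd", phi, coords[mesh.t2])
    uh = np.einsum("qi,eid->eqd", phi, field.velocity[mesh.t2])
    ue = case.reference["exact_velocity"](xq.reshape(-1, 2)).reshape(xq.shape)
    p = mesh.nodes[mesh.tris]
    detJ = np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    err2 = np.einsum("eq,q,e->", np.sum((uh - ue) ** 2, axis=2), TRI_QW, detJ)
    return float(np.sqrt(err2))


def symmetric_branch_case(q_lmin: float = 0.5) -> FixtureCase:
    """Straight channel with two mirror-image outlet stubs: the outflow must
    split 50/50 by symmetry."""
    L, h, w, stub = 40.0, 10.0, 4.0, 8.0
    xb = np.unique(np.concatenate([np.linspace(0, L, 21), [18.0, 22.0]]))
    yb = np.unique(np.concatenate([np.linspace(0, h, 6), [-stub, h + stub]]))
    yb = np.unique(np.concatenate([yb, np.linspace(-stub, 0, 5), np.linspace(h, h + stub, 5)]))
    nx, ny = len(xb) - 1, len(yb) - 1
    cx = 0.5 * (xb[:-1] + xb[1:])
    cy = 0.5 * (yb[:-1] + yb[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    mask = (CY > 0) & (CY < h)
    mask |= (CX > 18.0) & (CX < 22.0) & (CY > -stub) & (CY < h + stub)
    pts, tris, bnd, _ = _triangulate_grid(xb, yb, mask)
    mids = 0.5 * (pts[bnd[:, 0]] + pts[bnd[:, 1]])
    tol = 1e-9
    tags = {
        "inlet": bnd[np.abs(mids[:, 0]) < tol],
        "out_top": bnd[np.abs(mids[:, 1] - (h + stub)) < tol],
        "out_bottom": bnd[np.abs(mids[:, 1] + stub) < tol],
    }
    sel = np.ones(len(bnd), bool)
    for arr in tags.values():
        for e in arr:
            sel &= ~((bnd[:, 0] == e[0]) & (bnd[:, 1] == e[1]))
    tags["wall"] = bnd[sel]
    mesh = build_p2(pts, tris, tags)
    bcs = FlowBCs(
        inflow={"inlet": q_lmin},
        outlet_tags=("out_top", "out_bottom"),
        wall_tags=("wall",),
        inlet_profile="parabolic",
        depth=20.0,
    )
    del w
    return FixtureCase(
        name="symmetric_branch",
        mesh=mesh,
        properties={"fluid": FluidProperties()},
        bcs=bcs,
        reference={"split": 0.5},
        tolerance=0.01,
    )


def collapsible_channel_case(level: int = 1) -> FixtureCase:
    """Miniature two-lumen + flap + tears FSI smoke case on the reduced
    four-branch geometry; references are the rigid-limit flow oracle and the
    monotone-collapse sweep orderings."""
    spec = build_reduced_ad_geometry()
    meshes = generate_meshes(spec, level=level)
    return FixtureCase(
        name="collapsible_channel",
        mesh=meshes.fluid,
        properties={"spec": spec},
        bcs=None,
        reference={
            "rigid_limit_rel_tol": 0.01,
            "orderings": ["higher flow -> smaller A*", "dual feed -> smaller dP"],
        },
        tolerance=0.01,
        extras={"meshes": meshes},
    )


def refinement_study(case_builder, levels, metric) -> dict:
    """Mesh-independence harness: evaluates ``metric(case)`` per level and
    reports values, successive drifts, and (when positive) the observed
    convergence order from a log-log Richardson fit."""
    vals = []
    for lv in levels:
        vals.append(float(metric(case_builder(lv))))
    vals = np.asarray(vals)
    drift = np.abs(np.diff(vals)) / np.maximum(np.abs(vals[1:]), 1e-30)
    order = None
    if np.all(vals > 0) and len(vals) >= 2:
        h = 0.5 ** np.arange(len(vals))
        slope = np.polyfit(np.log(h), np.log(vals), 1)[0]
        order = float(slope)
    return {"levels": list(levels), "values": vals.tolist(), "drift": drift.tolist(), "order": order}
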