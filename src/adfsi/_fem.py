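"""Shared finite-element kernels: quadratic triangles, quadrature, writers.

Both field solvers use straight-edged six-node (P2) triangles; the fluid
solver pairs them with a P1 pressure on the vertices (Taylor-Hood).  All
assembly is vectorized over elements with numpy einsum and scattered into
scipy sparse matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

# --- reference P2 basis on the unit triangle (L1 = 1-x-y, L2 = x, L3 = y) ---
# node order: 3 vertices, then midpoints of edges (1-2), (2-3), (3-1)


def p2_basis(xi: np.ndarray) -> np.ndarray:
    """P2 shape functions at reference points xi (n, 2) -> (n, 6)."""
    x, y = xi[:, 0], xi[:, 1]
    l1 = 1.0 - x - y
    return np.stack(
        [
            l1 * (2 * l1 - 1),
            x * (2 * x - 1),
            y * (2 * y - 1),
            4 * l1 * x,
            4 * x * y,
            4 * y * l1,
        ],
        axis=1,
    )


def p2_grad(xi: np.ndarray) -> np.ndarray:
    """Reference gradients of P2 shape functions, (n, 6, 2)."""
    x, y = xi[:, 0], xi[:, 1]
    l1 = 1.0 - x - y
    g = np.empty((xi.shape[0], 6, 2))
    g[:, 0, 0] = 1 - 4 * l1
    g[:, 0, 1] = 1 - 4 * l1
    g[:, 1, 0] = 4 * x - 1
    g[:, 1, 1] = 0.0
    g[:, 2, 0] = 0.0
    g[:, 2, 1] = 4 * y - 1
    g[:, 3, 0] = 4 * (l1 - x)
    g[:, 3, 1] = -4 * x
    g[:, 4, 0] = 4 * y
    g[:, 4, 1] = 4 * x
    g[:, 5, 0] = -4 * y
    g[:, 5, 1] = 4 * (l1 - y)
    return g


def p1_basis(xi: np.ndarray) -> np.ndarray:
    x, y = xi[:, 0], xi[:, 1]
    return np.stack([1.0 - x - y, x, y], axis=1)


# 7-point degree-5 rule on the unit triangle (weights sum to 1/2)
_A1 = 0.0597158717
_B1 = 0.4701420641
_A2 = 0.7974269853
_B2 = 0.1012865073
TRI_QP = np.array(
    [
        [1 / 3, 1 / 3],
        [_A1, _B1],
        [_B1, _A1],
        [_B1, _B1],
        [_A2, _B2],
        [_B2, _A2],
        [_B2, _B2],
    ]
)
TRI_QW = 0.5 * np.array(
    [0.225, 0.1323941527, 0.1323941527, 0.1323941527, 0.1259391805, 0.1259391805, 0.1259391805]
)

# 3-point Gauss on [0, 1] (degree 5) for boundary edges
EDGE_QP = 0.5 * (1.0 + np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)]))
EDGE_QW = 0.5 * np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])


def p2_edge_basis(t: np.ndarray) -> np.ndarray:
    """1D quadratic shape functions on an edge, nodes (end0, end1, mid)."""
    return np.stack([(1 - t) * (1 - 2 * t), t * (2 * t - 1), 4 * t * (1 - t)], axis=1)


@dataclass
class P2Mesh:
    """Six-node triangle mesh with named boundary-edge tags.

    ``points`` are vertex coordinates (nv, 2); ``tris`` vertex connectivity
    (ne, 3); ``nodes`` all P2 node coordinates (vertices then edge
    midpoints); ``t2`` P2 connectivity (ne, 6); ``edge_tags`` maps a tag
    name to an array of boundary edges (m, 3) = (v0, v1, midnode).
    """

    points: np.ndarray
    tris: np.ndarray
    nodes: np.ndarray
    t2: np.ndarray
    edge_tags: dict[str, np.ndarray]

    @property
    def n_vertices(self) -> int:
        return self.points.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.tris.shape[0]

    def with_nodes(self, nodes: np.ndarray) -> "P2Mesh":
        """Same topology on displaced node coordinates."""
        return P2Mesh(
            points=nodes[: self.n_vertices].copy(),
            tris=self.tris,
            nodes=nodes,
            t2=self.t2,
            edge_tags=self.edge_tags,
        )


def build_p2(points: np.ndarray, tris: np.ndarray, boundary_tags: dict[str, np.ndarray]) -> P2Mesh:
    """Promote a vertex triangulation to P2 and resolve tagged boundary edges.

    ``boundary_tags`` maps names to arrays of vertex pairs (m, 2).
    """
    points = np.asarray(points, dtype=float)
    tris = np.asarray(tris, dtype=np.int64)
    nv = points.shape[0]
    # unique edges
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    e_sorted = np.sort(e, axis=1)
    uniq, inv = np.unique(e_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (points[uniq[:, 0]] + points[uniq[:, 1]])
    nodes = np.vstack([points, mid])
    t2 = np.empty((tris.shape[0], 6), dtype=np.int64)
    t2[:, :3] = tris
    ne = tris.shape[0]
    t2[:, 3] = nv + inv[0:ne]
    t2[:, 4] = nv + inv[ne : 2 * ne]
    t2[:, 5] = nv + inv[2 * ne : 3 * ne]

    # map vertex pair -> midpoint node
    key = uniq[:, 0].astype(np.int64) * (nv + 1) + uniq[:, 1]
    order = np.argsort(key)
    key_sorted = key[order]

    def edge_mid(pairs: np.ndarray) -> np.ndarray:
        ps = np.sort(pairs, axis=1)
        k = ps[:, 0].astype(np.int64) * (nv + 1) + ps[:, 1]
        idx = np.searchsorted(key_sorted, k)
        if np.any(key_sorted[idx] != k):
            raise ValueError("tagged boundary edge not present in triangulation")
        return nv + order[idx]

    edge_tags = {}
    for name, pairs in boundary_tags.items():
        pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
        if pairs.size == 0:
            edge_tags[name] = np.empty((0, 3), dtype=np.int64)
            continue
        edge_tags[name] = np.column_stack([pairs, edge_mid(pairs)])
    return P2Mesh(points=points, tris=tris, nodes=nodes, t2=t2, edge_tags=edge_tags)


def element_geometry(mesh: P2Mesh):
    """Affine per-element Jacobians: returns (detJ (ne,), Jinv (ne, 2, 2))."""
    p = mesh.nodes[mesh.tris]
    J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]], axis=2)  # (ne,2,2) cols
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    Jinv = np.empty_like(J)
    Jinv[:, 0, 0] = J[:, 1, 1]
    Jinv[:, 0, 1] = -J[:, 0, 1]
    Jinv[:, 1, 0] = -J[:, 1, 0]
    Jinv[:, 1, 1] = J[:, 0, 0]
    Jinv /= detJ[:, None, None]
    return detJ, Jinv


def physical_gradients(mesh: P2Mesh):
    """P2 gradients at quadrature points: (ne, nq, 6, 2), plus detJ (ne,)."""
    detJ, Jinv = element_geometry(mesh)
    gref = p2_grad(TRI_QP)  # (nq, 6, 2)
    # grad_phys = Jinv^T @ grad_ref
    g = np.einsum("eji,qnj->eqni", Jinv, gref)
    return g, detJ


def scatter(rows: np.ndarray, cols: np.ndarray, vals: np.ndarray, shape) -> sp.csr_matrix:
    return sp.coo_matrix((vals.ravel(), (rows.ravel(), cols.ravel())), shape=shape).tocsr()


def min_angle_deg(mesh: P2Mesh) -> float:
    """Smallest interior angle over all triangles, degrees."""
    p = mesh.points[mesh.tris]
    angles = []
    for i in range(3):
        a = p[:, (i + 1) % 3] - p[:, i]
        b = p[:, (i + 2) % 3] - p[:, i]
        cos = np.einsum("ij,ij->i", a, b) / (
            np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1)
        )
        angles.append(np.degrees(np.arccos(np.clip(cos, -1, 1))))
    return float(np.min(angles))


def edge_lengths_normals(mesh: P2Mesh, edges: np.ndarray):
    """Lengths and unit normals of boundary edges (m, 3).

    Normals are the edge tangent rotated by -90 deg; the mesh builders
    orient boundary edges counterclockwise around the fluid domain so these
    normals point outward.
    """
    a = mesh.nodes[edges[:, 0]]
    b = mesh.nodes[edges[:, 1]]
    t = b - a
    L = np.linalg.norm(t, axis=1)
    n = np.column_stack([t[:, 1], -t[:, 0]]) / L[:, None]
    return L, n


def write_vtk(path, mesh: P2Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Legacy ASCII VTK export of the vertex triangulation (P1 view of data)."""
    nv = mesh.n_vertices
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nadfsi mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {nv} double\n")
        for x, y in mesh.points:
            f.write(f"{x:.9g} {y:.9g} 0\n")
        ne = mesh.n_cells
        f.write(f"CELLS {ne} {4 * ne}\n")
        for t in mesh.tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {ne}\n")
        f.write("5\n" * ne)
        if point_data:
            f.write(f"POINT_DATA {nv}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)[:nv]
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    for v in arr:
                        f.write(f"{v:.9g}\n")
                else:
                    f.write(f"VECTORS {name} double\n")
                    for v in arr:
                        f.write(f"{v[0]:.9g} {v[1]:.9g} 0\n")


def write_msh(path, mesh: P2Mesh) -> None:
    """Minimal Gmsh 2.2 ASCII export of the vertex triangulation."""
    with open(path, "w") as f:
        f.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        f.write(f"$Nodes\n{mesh.n_vertices}\n")
        for i, (x, y) in enumerate(mesh.points, start=1):
            f.write(f"{i} {x:.9g} {y:.9g} 0\n")
        f.write("$EndNodes\n")
        f.write(f"$Elements\n{mesh.n_cells}\n")
        for i, t in enumerate(mesh.tris, start=1):
            f.write(f"{i} 2 2 0 1 {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
        f.write("$EndElements\n")
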