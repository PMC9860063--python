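"""Parametric specific-idealized dissected-aorta geometry and planar meshing.

The three-dimensional dissected aorta — nine branches, a large primary entry
tear (98.45 mm^2) in the proximal descending segment, a small re-entry tear
(3.73 mm^2) at the left common iliac artery, and a 1 mm intimal flap — is
reduced to a mid-plane planar analogue: a channel of height ``channel_height``
split over the dissected extent into a true lumen (bottom, carrying the
visceral ostia) and a false-lumen pocket (top) by the flap strip.  Tears
become gaps in the flap strip of planar width ``area / out_of_plane_depth``.
The false-lumen pocket is sealed at both ends by rigid walls; the deformable
flap spans between the two tear gaps and is clamped at its tear-adjacent
ends, standing in for the three-dimensional attachment of the flap sheet
around the tear perimeters.

Meshes are conforming block-masked rectilinear triangulations (fluid and
solid share every interface node location exactly); resolution is controlled
by an integer refinement level that halves the target spacing per level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._fem import P2Mesh, build_p2, min_angle_deg

__all__ = [
    "BranchSpec",
    "TearSpec",
    "FlapSpec",
    "VesselSpec",
    "MeshPair",
    "build_default_ad_geometry",
    "build_reduced_ad_geometry",
    "tear_area",
    "planar_tear_width",
    "generate_meshes",
    "lumen_connectivity",
    "branch_station",
    "measurement_station",
    "FULL_BRANCH_NAMES",
]

FULL_BRANCH_NAMES = ("BT", "LCCA", "LSA", "CA", "SMA", "RA_L", "RA_R", "CIA_L", "CIA_R")

#: minimum acceptable interior angle (degrees) for generated triangles;
#: rectilinear meshes with strong local grading are deliberately anisotropic
MIN_ANGLE_DEG = 1.0


@dataclass(frozen=True)
class BranchSpec:
    """A branch stub: ``station`` is the proximal edge of the ostium (mm from
    the brachiocephalic end), ``width`` the vessel diameter, ``side`` the
    channel wall it leaves from."""

    name: str
    station: float
    width: float
    side: str  # "top" | "bottom" | "west" (proximal end face)
    length: float = 12.0

    def __post_init__(self):
        if self.width <= 0 or self.length <= 0:
            raise ValueError(f"branch {self.name}: dimensions must be positive")
        if self.side not in ("top", "bottom", "west"):
            raise ValueError(f"branch {self.name}: side must be 'top', 'bottom' or 'west'")

    def planar_width(self, channel_height: float) -> float:
        """Area-preserving planar reduction of the branch ostium.

        A circular branch of diameter D on an aorta of diameter H occupies
        an area fraction ~(D/H)^2 of the cross-section; a planar slot of
        width D would occupy D/H.  Using w = D^2/H preserves the area
        fraction, and with it the relative branch/aorta resistance balance
        that sets the flow split.  A 'west' branch is the axial continuation
        of the vessel itself (the arch feeding the descending aorta), not a
        side ostium, and keeps its stated width.
        """
        if self.side == "west":
            return self.width
        return self.width**2 / channel_height


@dataclass(frozen=True)
class TearSpec:
    """Elliptical tear: ``station`` is the proximal edge of its planar gap;
    area is pi*a*b with semi-axes in mm."""

    id: str  # "entry" | "reentry"
    station: float
    side: str
    semi_axes: tuple[float, float]

    def __post_init__(self):
        if self.id not in ("entry", "reentry"):
            raise ValueError("tear id must be 'entry' or 'reentry'")
        if min(self.semi_axes) < 0:
            raise ValueError("semi-axes must be non-negative")

    @property
    def area(self) -> float:
        return math.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class FlapSpec:
    thickness: float = 1.0
    start: float = 0.0
    end: float = 0.0
    edge_condition: str = "clamped"

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("flap thickness must be positive")
        if self.end <= self.start:
            raise ValueError("flap extent must have end > start")


@dataclass(frozen=True)
class VesselSpec:
    """Planar dissected-aorta description (lengths in mm)."""

    length: float
    channel_height: float
    true_lumen_height: float
    out_of_plane_depth: float
    branches: tuple[BranchSpec, ...]
    flap: FlapSpec
    tears: tuple[TearSpec, ...]
    seal_thickness: float = 2.0
    kind: str = "full"
    segments: tuple[tuple[str, float, float], ...] = field(default_factory=tuple)

    def __post_init__(self):
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError("branch names must be unique")
        if self.kind == "full" and tuple(sorted(names)) != tuple(sorted(FULL_BRANCH_NAMES)):
            raise ValueError(f"full model requires exactly the nine branches {FULL_BRANCH_NAMES}")
        for v in (
            self.length,
            self.channel_height,
            self.true_lumen_height,
            self.out_of_plane_depth,
        ):
            if v <= 0:
                raise ValueError("all dimensions must be positive")
        if self.true_lumen_height + self.flap.thickness >= self.channel_height:
            raise ValueError("true lumen + flap must fit inside the channel")
        ids = [t.id for t in self.tears]
        if sorted(ids) != ["entry", "reentry"]:
            raise ValueError("exactly one entry and one reentry tear required")

    def tear(self, tear_id: str) -> TearSpec:
        for t in self.tears:
            if t.id == tear_id:
                return t
        raise KeyError(f"unknown tear id {tear_id!r}")

    @property
    def flap_bottom(self) -> float:
        return self.true_lumen_height

    @property
    def flap_top(self) -> float:
        return self.true_lumen_height + self.flap.thickness

    def tear_gap(self, tear_id: str) -> tuple[float, float]:
        """Planar y-extent of a tear slot.

        Tears are vertical slots in the rigid walls sealing the ends of the
        false-lumen pocket, opening just above the flap so the oncoming
        axial flow faces them (the entry slot at the proximal seal receives
        the dynamic head of the inflow; the re-entry slot at the distal seal
        drains the pocket).  Slot height is area / out-of-plane depth.
        """
        y0 = self.flap_top
        return (y0, y0 + planar_tear_width(self, tear_id))

    def tear_slot_x(self, tear_id: str) -> tuple[float, float]:
        """x-extent (the seal wall) a tear slot perforates."""
        if tear_id == "entry":
            return (self.flap.start - self.seal_thickness, self.flap.start)
        if tear_id == "reentry":
            return (self.flap.end, self.flap.end + self.seal_thickness)
        raise KeyError(f"unknown tear id {tear_id!r}")

    def branch_gap(self, name: str) -> tuple[float, float]:
        """Planar x-extent of a branch ostium slot (area-preserving width,
        centered on the anatomical ostium)."""
        for b in self.branches:
            if b.name == name:
                if b.side == "west":
                    raise ValueError(f"branch {name!r} is on the proximal face (no x-gap)")
                c = b.station + 0.5 * b.width
                w = b.planar_width(self.channel_height)
                return (c - 0.5 * w, c + 0.5 * w)
        raise KeyError(f"unknown branch {name!r}")

    @property
    def flap_span(self) -> tuple[float, float]:
        """x-extent of the deformable flap strip (clamped at both seals)."""
        return (self.flap.start, self.flap.end)


def _ellipse_axes(area: float, aspect: float) -> tuple[float, float]:
    # pi*a*b = area with a/b = aspect
    b = math.sqrt(area / (math.pi * aspect))
    return (aspect * b, b)


def build_default_ad_geometry(overrides: dict | None = None) -> VesselSpec:
    """Default nine-branch planar model.

    Printed dimensions: entry tear 98.45 mm^2, re-entry tear 3.73 mm^2, flap
    thickness 1 mm.  The remaining dimensions (channel 24 mm, branch widths
    6-12 mm, stations) are anatomy-typical defaults and overridable through
    ``overrides`` with keys ``entry_area``, ``reentry_area``,
    ``entry_semi_axes``, ``reentry_semi_axes``, ``flap_thickness``,
    ``channel_height``, ``true_lumen_height``, ``out_of_plane_depth``.
    """
    ov = dict(overrides or {})
    entry_axes = ov.pop("entry_semi_axes", None)
    reentry_axes = ov.pop("reentry_semi_axes", None)
    if entry_axes is None:
        entry_axes = _ellipse_axes(ov.pop("entry_area", 98.45), aspect=1.5)
    else:
        ov.pop("entry_area", None)
    if reentry_axes is None:
        reentry_axes = _ellipse_axes(ov.pop("reentry_area", 3.73), aspect=1.5)
    else:
        ov.pop("reentry_area", None)
    thickness = ov.pop("flap_thickness", 1.0)
    H = ov.pop("channel_height", 24.0)
    h_tl = ov.pop("true_lumen_height", 11.5)
    depth = ov.pop("out_of_plane_depth", 20.0)
    if ov:
        raise ValueError(f"unknown overrides: {sorted(ov)}")

    w_entry = math.pi * entry_axes[0] * entry_axes[1] / depth
    branches = (
        # the arch feeds the planar channel axially through the proximal face
        BranchSpec("BT", 0.0, H, "west", length=20.0),
        BranchSpec("LCCA", 30.0, 8.0, "top"),
        BranchSpec("LSA", 46.0, 8.0, "top"),
        BranchSpec("CA", 148.0, 7.0, "bottom"),
        BranchSpec("SMA", 168.0, 7.0, "bottom"),
        BranchSpec("RA_L", 188.0, 6.0, "bottom"),
        BranchSpec("RA_R", 206.0, 6.0, "bottom"),
        BranchSpec("CIA_L", 288.0, 10.0, "bottom"),
        BranchSpec("CIA_R", 306.0, 10.0, "bottom"),
    )
    spec = VesselSpec(
        length=322.0,
        channel_height=H,
        true_lumen_height=h_tl,
        out_of_plane_depth=depth,
        branches=branches,
        flap=FlapSpec(thickness=thickness, start=70.0, end=300.0),
        tears=(
            TearSpec("entry", station=70.0, side="proximal_descending", semi_axes=entry_axes),
            TearSpec("reentry", station=300.0, side="CIA_L", semi_axes=reentry_axes),
        ),
        kind="full",
        segments=(
            ("arch", 70.0, H),
            ("dissected", 230.0, H),
            ("distal", 22.0, H),
        ),
    )
    del w_entry
    return spec


def build_reduced_ad_geometry() -> VesselSpec:
    """Shortened four-branch preset (BT, CA, CIA_L, CIA_R) used for coupled
    runs: same channel section, tears, and flap thickness as the full model,
    shorter segments and a single visceral branch."""
    entry_axes = _ellipse_axes(98.45, aspect=1.5)
    reentry_axes = _ellipse_axes(3.73, aspect=1.5)
    depth = 20.0
    branches = (
        BranchSpec("BT", 0.0, 24.0, "west", length=20.0),
        BranchSpec("CA", 82.0, 7.0, "bottom"),
        BranchSpec("CIA_L", 116.0, 10.0, "bottom"),
        BranchSpec("CIA_R", 138.0, 10.0, "bottom"),
    )
    return VesselSpec(
        length=160.0,
        channel_height=24.0,
        true_lumen_height=11.5,
        out_of_plane_depth=depth,
        branches=branches,
        flap=FlapSpec(thickness=1.0, start=40.0, end=132.0),
        tears=(
            TearSpec("entry", station=40.0, side="proximal_descending", semi_axes=entry_axes),
            TearSpec("reentry", station=132.0, side="CIA_L", semi_axes=reentry_axes),
        ),
        kind="reduced",
    )


def tear_area(spec: VesselSpec, tear_id: str, method: str = "analytic", level: int = 1) -> float:
    """Tear opening area in mm^2.

    ``analytic`` evaluates pi*a*b; ``polygon`` integrates the discretized
    elliptical opening (shoelace on an inscribed polygon whose vertex count
    doubles per refinement level), which must agree with the analytic value
    within 1% at the default level.
    """
    t = spec.tear(tear_id)
    if method == "analytic":
        return t.area
    if method == "polygon":
        n = 32 * 2**level
        th = 2.0 * math.pi * np.arange(n) / n
        x = t.semi_axes[0] * np.cos(th)
        y = t.semi_axes[1] * np.sin(th)
        return float(0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    raise ValueError(f"unknown method {method!r}")


def planar_tear_width(spec: VesselSpec, tear_id: str) -> float:
    """Planar gap width (mm) of a tear: area / out-of-plane depth."""
    return tear_area(spec, tear_id) / spec.out_of_plane_depth


def branch_station(spec: VesselSpec, name: str) -> float:
    """Mid-ostium x-station of a branch (mm)."""
    for b in spec.branches:
        if b.name == name:
            return b.station + 0.5 * b.width
    raise KeyError(f"unknown branch {name!r}")


def measurement_station(spec: VesselSpec, name: str) -> float:
    """Flap station adjacent to a branch ostium, clamped to the deformable
    span; used for pressure-difference and area-ratio sampling."""
    x0, x1 = spec.flap_span
    s = branch_station(spec, name)
    margin = 1e-6 * (x1 - x0)
    return min(max(s, x0 + margin), x1 - margin)


# ---------------------------------------------------------------------------
# meshing
# ---------------------------------------------------------------------------


@dataclass
class MeshPair:
    """Conforming fluid/solid meshes and their interface pairing.

    ``interface`` maps side ("tl" | "fl") to a pair of edge arrays
    (fluid_edges, solid_edges), index-aligned so facet i of one matches facet
    i of the other with coincident nodes and opposite outward normals.
    """

    fluid: P2Mesh
    solid: P2Mesh
    interface: dict[str, tuple[np.ndarray, np.ndarray]]
    spec: VesselSpec
    level: int
    cell_grid: dict


def _interval_breaks(stations: list[float], h: float) -> np.ndarray:
    s = np.unique(np.asarray(stations, dtype=float))
    out = [s[0]]
    for a, b in zip(s[:-1], s[1:]):
        n = max(1, int(math.ceil((b - a) / h - 1e-9)))
        out.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(out)


def _rects_of(spec: VesselSpec):
    """Active/excluded rectangles of the planar fluid domain."""
    H, h0, t = spec.channel_height, spec.flap_bottom, spec.flap.thickness
    active = [(0.0, spec.length, 0.0, H)]
    for b in spec.branches:
        if b.side == "west":
            # axial inflow run on the proximal face, y in [station, station+width]
            active.append((-b.length, 0.0, b.station, b.station + b.width))
            continue
        x0, x1 = spec.branch_gap(b.name)
        if b.side == "top":
            active.append((x0, x1, H, H + b.length))
        else:
            active.append((x0, x1, -b.length, 0.0))
    yg_e = spec.tear_gap("entry")
    yg_r = spec.tear_gap("reentry")
    xs_e = spec.tear_slot_x("entry")
    xs_r = spec.tear_slot_x("reentry")
    excluded = [
        # the flap strip itself
        (spec.flap.start, spec.flap.end, h0, h0 + t),
        # seal walls closing the false-lumen pocket, perforated by the tear
        # slots (entry slot in the proximal seal, re-entry in the distal)
        (xs_e[0], xs_e[1], h0, yg_e[0]),
        (xs_e[0], xs_e[1], yg_e[1], H),
        (xs_r[0], xs_r[1], h0, yg_r[0]),
        (xs_r[0], xs_r[1], yg_r[1], H),
    ]
    return active, excluded


def _grid_breaks(spec: VesselSpec, level: int):
    hx = 8.0 / 2**level
    hy = 4.0 / 2**level
    H, h0, t = spec.channel_height, spec.flap_bottom, spec.flap.thickness
    xs = [0.0, spec.length, spec.flap.start, spec.flap.end,
          spec.flap.start - spec.seal_thickness, spec.flap.end + spec.seal_thickness]
    for b in spec.branches:
        if b.side == "west":
            xs += [-b.length, 0.0]
        else:
            xs += list(spec.branch_gap(b.name))
    ys = [0.0, h0, h0 + t, H]
    for b in spec.branches:
        if b.side == "west":
            ys += [b.station, b.station + b.width]
    ys += list(spec.tear_gap("entry")) + list(spec.tear_gap("reentry"))
    stub_top = max((b.length for b in spec.branches if b.side == "top"), default=0.0)
    stub_bot = max((b.length for b in spec.branches if b.side == "bottom"), default=0.0)
    if stub_top:
        ys.append(H + stub_top)
    if stub_bot:
        ys.append(-stub_bot)
    return _interval_breaks(xs, hx), _interval_breaks(ys, hy)


def _mask_cells(xb, yb, active, excluded):
    cx = 0.5 * (xb[:-1] + xb[1:])
    cy = 0.5 * (yb[:-1] + yb[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    mask = np.zeros(CX.shape, dtype=bool)
    for x0, x1, y0, y1 in active:
        mask |= (CX > x0) & (CX < x1) & (CY > y0) & (CY < y1)
    for x0, x1, y0, y1 in excluded:
        mask &= ~((CX > x0) & (CX < x1) & (CY > y0) & (CY < y1))
    return mask


def _triangulate_grid(xb, yb, mask):
    """Triangulate active cells of a rectilinear grid; returns (points, tris,
    directed boundary edges (CCW), vertex grid-index map)."""
    nx, ny = len(xb) - 1, len(yb) - 1
    vid = -np.ones((nx + 1, ny + 1), dtype=np.int64)
    ii, jj = np.nonzero(mask)
    for di, dj in ((0, 0), (1, 0), (0, 1), (1, 1)):
        vid[ii + di, jj + dj] = 0
    used = np.nonzero(vid >= 0)
    vid[used] = np.arange(len(used[0]))
    points = np.column_stack([xb[used[0]], yb[used[1]]])
    v00 = vid[ii, jj]
    v10 = vid[ii + 1, jj]
    v01 = vid[ii, jj + 1]
    v11 = vid[ii + 1, jj + 1]
    tris = np.concatenate(
        [
            np.column_stack([v00, v10, v11]),
            np.column_stack([v00, v11, v01]),
        ]
    )
    # boundary edges: directed triangle edges whose reverse is absent
    e = np.concatenate([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    nvert = points.shape[0]
    fwd = e[:, 0] * nvert + e[:, 1]
    rev = e[:, 1] * nvert + e[:, 0]
    boundary = e[~np.isin(fwd, rev)]
    return points, tris, boundary, (vid, ii, jj)


def _tag_edges(points, boundary, spec: VesselSpec, tol=1e-9):
    mids = 0.5 * (points[boundary[:, 0]] + points[boundary[:, 1]])
    H = spec.channel_height
    tags = {name: [] for name in [b.name for b in spec.branches]}
    tags["wall"] = []
    tags["interface_tl"] = []
    tags["interface_fl"] = []
    x0f, x1f = spec.flap_span
    h0, h1 = spec.flap_bottom, spec.flap_top
    assigned = np.zeros(len(boundary), dtype=bool)
    for b in spec.branches:
        if b.side == "west":
            sel = (np.abs(mids[:, 0] + b.length) < tol) & (
                mids[:, 1] > b.station - tol
            ) & (mids[:, 1] < b.station + b.width + tol)
            tags[b.name] = boundary[sel]
            assigned |= sel
            continue
        yend = H + b.length if b.side == "top" else -b.length
        x0, x1 = spec.branch_gap(b.name)
        sel = (np.abs(mids[:, 1] - yend) < tol) & (mids[:, 0] > x0 - tol) & (
            mids[:, 0] < x1 + tol
        )
        tags[b.name] = boundary[sel]
        assigned |= sel
    sel_tl = (np.abs(mids[:, 1] - h0) < tol) & (mids[:, 0] > x0f - tol) & (mids[:, 0] < x1f + tol)
    sel_fl = (np.abs(mids[:, 1] - h1) < tol) & (mids[:, 0] > x0f - tol) & (mids[:, 0] < x1f + tol)
    tags["interface_tl"] = boundary[sel_tl & ~assigned]
    tags["interface_fl"] = boundary[sel_fl & ~assigned]
    assigned |= sel_tl | sel_fl
    tags["wall"] = boundary[~assigned]
    return tags


def _solid_mesh(spec: VesselSpec, xb_fluid: np.ndarray, n_through: int = 3) -> P2Mesh:
    x0, x1 = spec.flap_span
    xs = xb_fluid[(xb_fluid > x0 - 1e-9) & (xb_fluid < x1 + 1e-9)]
    ys = spec.flap_bottom + np.linspace(0.0, spec.flap.thickness, n_through + 1)
    nx, ny = len(xs) - 1, len(ys) - 1
    mask = np.ones((nx, ny), dtype=bool)
    points, tris, boundary, _ = _triangulate_grid(xs, ys, mask)
    mids = 0.5 * (points[boundary[:, 0]] + points[boundary[:, 1]])
    tol = 1e-9
    tags = {
        "clamp": boundary[
            (np.abs(mids[:, 0] - xs[0]) < tol) | (np.abs(mids[:, 0] - xs[-1]) < tol)
        ],
        "interface_tl": boundary[np.abs(mids[:, 1] - ys[0]) < tol],
        "interface_fl": boundary[np.abs(mids[:, 1] - ys[-1]) < tol],
    }
    return build_p2(points, tris, tags)


def _pair_interface(fluid: P2Mesh, solid: P2Mesh, side: str):
    fe = fluid.edge_tags[f"interface_{side}"]
    se = solid.edge_tags[f"interface_{side}"]
    if len(fe) != len(se):
        raise ValueError(f"interface_{side}: facet counts differ ({len(fe)} vs {len(se)})")
    fx = fluid.nodes[fe[:, 2], 0]
    sx = solid.nodes[se[:, 2], 0]
    fo, so = np.argsort(fx), np.argsort(sx)
    fe, se = fe[fo], se[so]
    d = np.abs(fluid.nodes[fe[:, 2]] - solid.nodes[se[:, 2]]).max()
    if d > 1e-9:
        raise ValueError(f"interface_{side}: facet midpoints mismatch by {d:g} mm")
    return fe, se


def generate_meshes(spec: VesselSpec, level: int = 1, n_through: int = 3) -> MeshPair:
    """Generate conforming planar fluid/solid meshes at a refinement level.

    Raises a diagnostic error when the requested spacing cannot resolve the
    domain or the triangle quality falls below ``MIN_ANGLE_DEG``.
    """
    xb, yb = _grid_breaks(spec, level)
    active, excluded = _rects_of(spec)
    mask = _mask_cells(xb, yb, active, excluded)
    if not mask.any():
        raise ValueError("meshing failure: no active cells (check spec dimensions)")
    points, tris, boundary, grid = _triangulate_grid(xb, yb, mask)
    tags = _tag_edges(points, boundary, spec)
    for b in spec.branches:
        if len(tags[b.name]) == 0:
            raise ValueError(f"meshing failure: branch {b.name} produced no outlet facets")
    fluid = build_p2(points, tris, tags)
    solid = _solid_mesh(spec, xb, n_through=n_through)
    interface = {s: _pair_interface(fluid, solid, s) for s in ("tl", "fl")}
    ang = min(min_angle_deg(fluid), min_angle_deg(solid))
    if ang < MIN_ANGLE_DEG:
        raise ValueError(f"meshing failure: min triangle angle {ang:.3f} deg below threshold")
    return MeshPair(
        fluid=fluid,
        solid=solid,
        interface=interface,
        spec=spec,
        level=level,
        cell_grid={"xb": xb, "yb": yb, "mask": mask},
    )


def lumen_connectivity(spec: VesselSpec, level: int = 1) -> dict:
    """Region-growing audit: the true and false lumens must form one connected
    fluid region through the tears and fall apart into (at least) two when the
    tear-gap cells are removed."""
    from scipy import ndimage

    xb, yb = _grid_breaks(spec, level)
    active, excluded = _rects_of(spec)
    mask = _mask_cells(xb, yb, active, excluded)
    n_with = ndimage.label(mask)[1]
    cx = 0.5 * (xb[:-1] + xb[1:])
    cy = 0.5 * (yb[:-1] + yb[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")
    mask2 = mask.copy()
    for tid in ("entry", "reentry"):
        x0, x1 = spec.tear_slot_x(tid)
        y0, y1 = spec.tear_gap(tid)
        mask2 &= ~((CX > x0) & (CX < x1) & (CY > y0) & (CY < y1))
    n_without = ndimage.label(mask2)[1]
    return {"components_with_tears": int(n_with), "components_without_tears": int(n_without)}


def apply_overrides(spec: VesselSpec, **kwargs) -> VesselSpec:
    """Dataclass-level override helper (validates via __post_init__)."""
    return replace(spec, **kwargs)


def station_table(spec: VesselSpec):
    """Branch/tear station bookkeeping as a DataFrame (CSV-ready): name,
    kind, station (mm), anatomical width/area, planar slot extent."""
    import pandas as pd

    rows = []
    for b in spec.branches:
        if b.side == "west":
            extent = (-b.length, 0.0)
        else:
            extent = spec.branch_gap(b.name)
        rows.append(
            {
                "name": b.name,
                "kind": "branch",
                "side": b.side,
                "station_mm": b.station,
                "size_mm": b.width,
                "planar_extent_lo_mm": extent[0],
                "planar_extent_hi_mm": extent[1],
            }
        )
    for t in spec.tears:
        y0, y1 = spec.tear_gap(t.id)
        rows.append(
            {
                "name": t.id,
                "kind": "tear",
                "side": t.side,
                "station_mm": t.station,
                "size_mm": t.area,
                "planar_extent_lo_mm": y0,
                "planar_extent_hi_mm": y1,
            }
        )
    return pd.DataFrame(rows)
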