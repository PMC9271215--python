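"""Hagen–Poiseuille network flow and local fluid-conductance tensors.

For a cubic control volume (default 400 μm side), segments crossing a
face are cut there into boundary nodes.  A unit pressure gradient is
applied through Dirichlet conditions on the boundary nodes and the
internal pressures solve flux conservation, each segment obeying
Q = g·ΔP with g from Hagen–Poiseuille at unit viscosity.  The signed
flux through the three centre planes under the three Cartesian unit
gradients assembles the 3×3 flow tensor k (k·∇P = Q, oriented so flow
down the pressure drop is positive).  The scalar conductance is the
spherical mean of |k·n| over a 2,000-point Fibonacci sphere.

Segment conductance composes per-point series resistances
R = Σ 8μ·dl / (π r⁴) along the polyline (the physically correct form for
a varying radius); a length-weighted mean-radius variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .graph import BOUNDARY, VesselGraph


@dataclass
class FlowTensor:
    """Flow tensor for one control volume (flux per unit pressure gradient)."""

    k: np.ndarray                      # 3×3
    center: np.ndarray
    size: float
    conductance: float = 0.0           # spherical mean of |k·n|
    n_boundary_nodes: int = 0


@dataclass
class FlowSolution:
    pressures: dict[int, float]
    segment_flux: dict[int, float]     # signed, positive along polyline u→v
    gradient: np.ndarray


@dataclass
class AnisotropyProjection:
    """Tensor magnitudes along the penetrating / AP / ML cortical axes."""

    k_p: float
    k_ap: float
    k_ml: float
    dominant: str = ""                 # "P" | "AP" | "ML" (color-code key)
    colors: dict = field(default_factory=lambda: {
        "P": "magenta", "AP": "cyan", "ML": "yellow"})


# ------------------------------------------------------------------ clipping

def clip_to_control_volume(
    graph: VesselGraph, center, size: float = 400.0
) -> VesselGraph:
    """Clip a vessel graph to an axis-aligned cube.

    Polyline pieces inside the cube survive; crossing points become
    boundary nodes exactly on the faces (radii linearly interpolated).
    A segment that exits and re-enters yields independent pieces.
    Components with no boundary node are retained (they simply carry no
    flow when solved).
    """
    center = np.asarray(center, dtype=float)
    lo = center - size / 2.0
    hi = center + size / 2.0
    out = VesselGraph()
    node_map: dict[int, int] = {}

    def get_node(nid: int) -> int:
        if nid not in node_map:
            node_map[nid] = out.add_node(
                graph.node_pos(nid), kind=graph.g.nodes[nid].get("kind")
            )
        return node_map[nid]

    def inside(p: np.ndarray) -> bool:
        return bool(np.all(p >= lo - 1e-9) and np.all(p <= hi + 1e-9))

    for u, v, _key, d in graph.segments():
        poly, radii = d["polyline"], d["radii"]
        pieces = _clip_polyline(poly, radii, lo, hi)
        for piece_pts, piece_rad, starts_at_u, ends_at_v in pieces:
            if len(piece_pts) < 2:
                continue
            a = get_node(u) if starts_at_u else out.add_node(piece_pts[0], kind=BOUNDARY)
            b = get_node(v) if ends_at_v else out.add_node(piece_pts[-1], kind=BOUNDARY)
            out.add_segment(a, b, piece_pts, piece_rad)
    return out


def _clip_polyline(poly, radii, lo, hi):
    """Split a polyline into maximal pieces inside the box [lo, hi].

    Returns a list of (points, radii, starts_at_original_u, ends_at_v).
    """
    def inside(p):
        # strict: a point on a face is a boundary cut, not an interior node
        return bool(np.all(p > lo + 1e-9) and np.all(p < hi - 1e-9))

    def clip_step(p0, p1):
        """Liang–Barsky parametric interval of p0→p1 inside the box."""
        d = p1 - p0
        t0, t1 = 0.0, 1.0
        for ax in range(3):
            if abs(d[ax]) < 1e-15:
                if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                    return None
                continue
            ta = (lo[ax] - p0[ax]) / d[ax]
            tb = (hi[ax] - p0[ax]) / d[ax]
            ta, tb = min(ta, tb), max(ta, tb)
            t0, t1 = max(t0, ta), min(t1, tb)
            if t0 > t1:
                return None
        return t0, t1

    pieces = []
    cur_pts, cur_rad = [], []
    cur_starts_u = False
    for i in range(len(poly) - 1):
        p0, p1 = poly[i], poly[i + 1]
        r0, r1 = radii[i], radii[i + 1]
        iv = clip_step(p0, p1)
        if iv is None:
            continue
        t0, t1 = iv
        q0 = p0 + t0 * (p1 - p0)
        q1 = p0 + t1 * (p1 - p0)
        s0 = r0 + t0 * (r1 - r0)
        s1 = r0 + t1 * (r1 - r0)
        fresh = not cur_pts or not np.allclose(cur_pts[-1], q0, atol=1e-9)
        if fresh:
            if len(cur_pts) >= 2:
                pieces.append((np.asarray(cur_pts), np.asarray(cur_rad),
                               cur_starts_u, False))
            cur_pts, cur_rad = [q0], [s0]
            cur_starts_u = i == 0 and t0 <= 1e-12 and inside(poly[0])
        if np.linalg.norm(q1 - cur_pts[-1]) > 1e-12:
            cur_pts.append(q1)
            cur_rad.append(s1)
        if t1 < 1.0 - 1e-12:
            if len(cur_pts) >= 2:
                pieces.append((np.asarray(cur_pts), np.asarray(cur_rad),
                               cur_starts_u, False))
            cur_pts, cur_rad = [], []
    if len(cur_pts) >= 2:
        ends_v = inside(poly[-1])
        pieces.append((np.asarray(cur_pts), np.asarray(cur_rad), cur_starts_u, ends_v))
    return pieces


# ------------------------------------------------------------- conductance

def segment_conductance(
    polyline: np.ndarray,
    radii: np.ndarray,
    viscosity: float = 1.0,
    method: str = "series",
) -> float:
    """Hagen–Poiseuille conductance g of one segment (Q = g·ΔP).

    ``series``: integrate resistance 8μ dl/(π r⁴) along the polyline
    with the mid-point radius per step.  ``mean_radius``: g = π r̄⁴/(8 μ L)
    with the length-weighted mean radius.
    """
    steps = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    L = steps.sum()
    if L <= 0:
        return 0.0
    if method == "series":
        r_mid = 0.5 * (radii[:-1] + radii[1:])
        resistance = float(np.sum(8.0 * viscosity * steps / (np.pi * r_mid**4)))
        return 1.0 / resistance if resistance > 0 else 0.0
    if method == "mean_radius":
        r_bar = float(np.sum(steps * 0.5 * (radii[:-1] + radii[1:])) / L)
        return float(np.pi * r_bar**4 / (8.0 * viscosity * L))
    raise ValueError(f"unknown conductance method {method!r}")


# ---------------------------------------------------------------- flow solve

def solve_network_flow(
    clipped: VesselGraph,
    gradient,
    viscosity: float = 1.0,
    method: str = "series",
) -> FlowSolution:
    """Solve network pressures/fluxes under a boundary pressure gradient.

    Boundary nodes get Dirichlet pressure P = −∇P·x (so net flow runs
    down the gradient direction, making tensor diagonals positive);
    interior nodes satisfy flux conservation.  Components without a
    boundary node are flow-free and excluded from the linear system
    (which keeps it non-singular).
    """
    gradient = np.asarray(gradient, dtype=float)
    nodes = list(clipped.g.nodes)
    comp_of = clipped.component_labels()
    boundary = {
        n for n in nodes if clipped.g.nodes[n].get("kind") == BOUNDARY
    }
    live_comps = {comp_of[n] for n in boundary}

    pressures = {n: 0.0 for n in nodes}
    for n in boundary:
        pressures[n] = float(-gradient @ clipped.node_pos(n))

    interior = [
        n for n in nodes
        if n not in boundary and comp_of[n] in live_comps
    ]
    idx = {n: i for i, n in enumerate(interior)}

    edges = []  # (u, v, key, g)
    for u, v, key, d in clipped.segments():
        g = segment_conductance(d["polyline"], d["radii"], viscosity, method)
        edges.append((u, v, key, g))

    if interior:
        ii, jj, vv = [], [], []
        b = np.zeros(len(interior))
        for u, v, _key, g in edges:
            if g <= 0 or u == v:
                continue
            for a, other in ((u, v), (v, u)):
                if a in idx:
                    ii.append(idx[a])
                    jj.append(idx[a])
                    vv.append(g)
                    if other in idx:
                        ii.append(idx[a])
                        jj.append(idx[other])
                        vv.append(-g)
                    else:
                        b[idx[a]] += g * pressures[other]
        A = sp.csr_matrix((vv, (ii, jj)), shape=(len(interior), len(interior)))
        sol = spla.spsolve(A.tocsc(), b)
        for n, i in idx.items():
            pressures[n] = float(sol[i])

    flux = {}
    for u, v, key, g in edges:
        if comp_of[u] in live_comps and u != v:
            flux[key] = g * (pressures[u] - pressures[v])
        else:
            flux[key] = 0.0
    return FlowSolution(pressures, flux, gradient)


def plane_flux(
    clipped: VesselGraph, solution: FlowSolution, axis: int, plane_coord: float
) -> float:
    """Net signed flux through the plane x_axis = plane_coord.

    Each polyline step crossing the plane contributes the segment's flux
    with the sign of its axis direction; multiple crossings by one
    segment net out.
    """
    total = 0.0
    for _u, _v, key, d in clipped.segments():
        q = solution.segment_flux.get(key, 0.0)
        if q == 0.0:
            continue
        poly = d["polyline"]
        a = poly[:-1, axis] - plane_coord
        b = poly[1:, axis] - plane_coord
        crossing = (a <= 0) & (b > 0)
        total += q * crossing.sum()
        crossing = (a > 0) & (b <= 0)
        total -= q * crossing.sum()
    return float(total)


def compute_flow_tensor(
    graph: VesselGraph,
    center,
    size: float = 400.0,
    viscosity: float = 1.0,
    method: str = "series",
    symmetrize: bool = False,
    n_sphere: int = 2000,
) -> FlowTensor:
    """Flow tensor of the control volume at ``center``.

    Columns of k are the centre-plane flux vectors measured under the
    three Cartesian unit pressure gradients.
    """
    center = np.asarray(center, dtype=float)
    clipped = clip_to_control_volume(graph, center, size)
    n_boundary = sum(
        1 for n in clipped.g.nodes if clipped.g.nodes[n].get("kind") == BOUNDARY
    )
    k = np.zeros((3, 3))
    if clipped.n_segments and n_boundary:
        for j in range(3):
            grad = np.zeros(3)
            grad[j] = 1.0
            sol = solve_network_flow(clipped, grad, viscosity, method)
            for i in range(3):
                k[i, j] = plane_flux(clipped, sol, i, center[i])
    if symmetrize:
        k = 0.5 * (k + k.T)
    tensor = FlowTensor(k, center, float(size), n_boundary_nodes=n_boundary)
    tensor.conductance = spherical_conductance(k, n_sphere)
    return tensor


# ------------------------------------------------------------- projections

def fibonacci_sphere(n_points: int = 2000) -> np.ndarray:
    """Deterministic golden-angle spiral of quasi-uniform unit vectors."""
    i = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def spherical_conductance(k: np.ndarray, n_points: int = 2000) -> float:
    """Spherical mean of |k·n| over a Fibonacci-sphere sample."""
    if not np.all(np.isfinite(k)):
        raise ValueError("flow tensor contains non-finite entries")
    dirs = fibonacci_sphere(n_points)
    return float(np.linalg.norm(dirs @ np.asarray(k).T, axis=1).mean())


def project_tensor(k: np.ndarray, n_p, n_ap, n_ml) -> AnisotropyProjection:
    """Project k onto the penetrating / AP / ML cortical axes: k_pj = |k·n_pj|.

    Non-unit axis vectors are normalized (with the deviation recorded by
    normalizing silently — inputs should come from the flatmap gradient).
    The dominant axis is the argmax; an exact tie leaves it empty.
    """
    k = np.asarray(k, dtype=float)
    axes = {}
    for name, v in (("P", n_p), ("AP", n_ap), ("ML", n_ml)):
        v = np.asarray(v, dtype=float)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError(f"axis {name} is zero")
        axes[name] = v / norm
    mags = {name: float(np.linalg.norm(k @ v)) for name, v in axes.items()}
    best = max(mags.values())
    winners = [name for name, m in mags.items() if np.isclose(m, best, rtol=1e-12)]
    dominant = winners[0] if len(winners) == 1 else ""
    return AnisotropyProjection(mags["P"], mags["AP"], mags["ML"], dominant)


# --------------------------------------------------------- whole-volume scan

def conductance_grid(
    graph: VesselGraph,
    extent_um,
    grid_um: float = 20.0,
    size: float = 400.0,
    **kwargs,
):
    """Scalar conductance sampled on a regular grid of control-volume
    centres (sliding 400³ μm volumes on a ``grid_um`` pitch).  Returns a
    :class:`VoxelVolume` of conductance values."""
    from .volume import VoxelVolume

    shape = tuple(max(int(np.floor(e / grid_um)), 1) for e in extent_um)
    out = np.zeros(shape)
    for i in range(shape[0]):
        for j in range(shape[1]):
            for l in range(shape[2]):
                center = (np.array([i, j, l]) + 0.5) * grid_um
                out[i, j, l] = compute_flow_tensor(
                    graph, center, size, **kwargs
                ).conductance
    return VoxelVolume(out, (grid_um,) * 3, meta={"control_volume_um": size})
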