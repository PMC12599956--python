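"""Stochastic, cell-autonomous simulator of giant-cell fate in a growing,
dividing polygonal tissue.

Per cell, three variables evolve under chemical Langevin dynamics integrated
with a Heun predictor-corrector under the Itô convention: a transcription
factor A with constitutive production, Hill self-activation and linear
degradation; its target T with Hill activation by A and linear degradation;
and a Timer accumulating at a constant rate.  Noise amplitude is
c0·sqrt(Σ|deterministic terms| / (2·ε_i)) with ε_i = E0 · cell area.

The tissue is a shared-vertex polygonal mesh growing by a prescribed
anisotropic exponential map about the tissue center; growth dilutes the
modeled variables.  Timer thresholds trigger S-phase (ploidy doubling) and
then either division (shortest wall through the cell centroid) or — for
cells whose T crossed the commitment threshold while post-S — an absorbing
endoreduplication cycle that keeps doubling ploidy, producing giant cells.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import draw as skdraw

from giantcell.errors import ConfigError, GeometryError
from giantcell.tissue import CellTable, LabeledTissue


@dataclasses.dataclass
class SimParams:
    """Rates, thresholds, growth and integration settings."""

    # A (self-activating transcription factor)
    P_A: float = 0.05
    V_A: float = 2.0
    K_A: float = 1.0
    n_A: float = 4.0
    G_A: float = 1.0
    # T (target)
    V_T: float = 1.0
    K_T: float = 1.3
    n_T: float = 4.0
    G_T: float = 0.3
    # Timer
    P_C: float = 0.05
    theta_CS: float = 0.5
    theta_CD: float = 1.0
    theta_T: float = 0.55
    # noise
    E0: float = 20.0
    c0: float = 1.0
    # growth (exponential rates; axial = y)
    k_radial: float = 0.009
    k_axial: float = 0.017
    # integration
    dt: float = 0.1
    t_end: float = 135.0
    t_select: float = 55.0
    dilute_timer: bool = True
    division_angle_step_deg: float = 1.0
    n_init_rings: int = 2
    init_cell_size: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("P_A", "V_A", "K_A", "G_A", "V_T", "K_T", "G_T", "P_C",
                     "E0", "c0", "k_radial", "k_axial"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 < self.theta_CS < self.theta_CD:
            raise ConfigError("need 0 < theta_CS < theta_CD")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.n_A < 1 or self.n_T < 1:
            raise ConfigError("Hill exponents must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimParams":
        params = cls(**d)
        params.validate()
        return params


def _polygon_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    x, y = points[:, 0], points[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    area = 0.5 * cross.sum()
    if abs(area) < 1e-12:
        return points.mean(axis=0)
    cx = ((x + np.roll(x, -1)) * cross).sum() / (6 * area)
    cy = ((y + np.roll(y, -1)) * cross).sum() / (6 * area)
    return np.array([cx, cy])


class SimState:
    """Growing polygonal tissue with per-cell chemical state and ploidy.

    Cells are loops of indices into a shared vertex array, so walls stay
    consistent across divisions; chemistry lives in parallel numpy arrays.
    """

    def __init__(self, vertices: np.ndarray, loops: list[list[int]],
                 params: SimParams, rng: np.random.Generator):
        n = len(loops)
        self.vertices = vertices.astype(float)
        self.loops = loops
        self.params = params
        self.rng = rng
        self.time = 0.0
        self.A = np.zeros(n)
        self.T = np.zeros(n)
        self.C = np.zeros(n)
        self.ploidy = np.full(n, 2, dtype=np.int64)
        self.post_S = np.zeros(n, dtype=bool)
        self.committed = np.zeros(n, dtype=bool)
        self.divisions = np.zeros(n, dtype=np.int64)
        self.last_division_time = np.full(n, -np.inf)
        self.ids = list(range(1, n + 1))
        self.lineage = list(range(1, n + 1))
        self.next_id = n + 1
        self.areas = np.array([_polygon_area(self.vertices[lp]) for lp in loops])
        if np.any(self.areas <= 0):
            raise GeometryError("initial loops must be positively oriented")

    @property
    def n_cells(self) -> int:
        return len(self.loops)

    def cell_polygon(self, i: int) -> np.ndarray:
        return self.vertices[self.loops[i]]

    def total_area(self) -> float:
        return float(self.areas.sum())

    def _edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Directed edge index arrays over all cell loops (cached; interior
        edges appear twice with opposite orientation and cancel in region
        integrals)."""
        key = (self.n_cells, sum(len(lp) for lp in self.loops), len(self.vertices))
        cache = getattr(self, "_edge_cache", None)
        if cache is None or cache[0] != key:
            ei = np.concatenate([np.array(lp) for lp in self.loops])
            ej = np.concatenate(
                [np.roll(np.array(lp), -1) for lp in self.loops]
            )
            self._edge_cache = (key, ei, ej)
        return self._edge_cache[1], self._edge_cache[2]

    def center_of_mass(self) -> np.ndarray:
        """Area-weighted centroid of the tissue region (shoelace over all
        directed cell edges; interior edges cancel)."""
        ei, ej = self._edges()
        p = self.vertices[ei]
        q = self.vertices[ej]
        cross = p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1]
        area = cross.sum() / 2.0
        if abs(area) < 1e-12:
            return self.vertices.mean(axis=0)
        cx = ((p[:, 0] + q[:, 0]) * cross).sum() / (6 * area)
        cy = ((p[:, 1] + q[:, 1]) * cross).sum() / (6 * area)
        return np.array([cx, cy])

    def to_table(self, pixel_size: float = 1.0) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                id=self.ids,
                area_um2=self.areas,
                ploidy=self.ploidy,
                committed=self.committed,
                divisions=self.divisions,
                lineage=self.lineage,
            )
        )


# ---------------------------------------------------------------------------
# Initialization


def _hex_patch(rings: int, size: float, rng: np.random.Generator,
               jitter: float = 0.08) -> tuple[np.ndarray, list[list[int]]]:
    """Hexagon patch (pointy-top axial grid), shared vertices, small jitter."""
    centers = []
    for q in range(-rings, rings + 1):
        for r in range(-rings, rings + 1):
            if abs(q + r) <= rings:
                x = size * math.sqrt(3) * (q + r / 2.0)
                y = size * 1.5 * r
                centers.append((x, y))
    vertex_index: dict[tuple[int, int], int] = {}
    vertices: list[tuple[float, float]] = []
    loops: list[list[int]] = []
    for cx, cy in centers:
        loop = []
        for k in range(6):
            ang = math.pi / 6 + k * math.pi / 3
            vx = cx + size * math.cos(ang)
            vy = cy + size * math.sin(ang)
            key = (round(vx * 1e6), round(vy * 1e6))
            if key not in vertex_index:
                vertex_index[key] = len(vertices)
                vertices.append((vx, vy))
            loop.append(vertex_index[key])
        loops.append(loop)
    verts = np.array(vertices)
    verts += rng.uniform(-jitter * size, jitter * size, size=verts.shape)
    # ensure CCW orientation in (x right, y up) convention
    for lp in loops:
        if _polygon_area(verts[lp]) < 0:
            lp.reverse()
    return verts, loops


def init_simulation(params: SimParams) -> SimState:
    """Initial patch with A ~ U[0,1), T ~ U[0,0.1), Timer correlated with
    cell area (rank fraction of theta_CD with ±10% multiplicative noise),
    all cells 2C and uncommitted."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    verts, loops = _hex_patch(params.n_init_rings, params.init_cell_size, rng)
    state = SimState(verts, loops, params, rng)
    n = state.n_cells
    state.A = rng.uniform(0.0, 1.0, n)
    state.T = rng.uniform(0.0, 0.1, n)
    rank = np.empty(n)
    rank[np.argsort(state.areas, kind="stable")] = (np.arange(n) + 0.5) / n
    state.C = params.theta_CD * rank * (1.0 + rng.uniform(-0.1, 0.1, n))
    return state


# ---------------------------------------------------------------------------
# Langevin chemistry


def _drift(A: np.ndarray, T: np.ndarray, p: SimParams):
    hill_A = p.V_A * A**p.n_A / (p.K_A**p.n_A + A**p.n_A)
    hill_T = p.V_T * A**p.n_T / (p.K_T**p.n_T + A**p.n_T)
    fA = p.P_A + hill_A - p.G_A * A
    fT = hill_T - p.G_T * T
    return fA, fT, hill_A, hill_T


def langevin_step(state: SimState, params: SimParams | None = None) -> SimState:
    """One Heun-Itô step of the chemical Langevin equations.

    Noise amplitudes use the step's start state (Itô convention):
    g_X = c0 · sqrt(Σ|terms of X| / (2 ε_i)), ε_i = E0 · area_i; independent
    standard normal draws per variable per cell; negatives clamped to 0.
    """
    p = params or state.params
    if p.dt * max(p.G_A, p.G_T) > 1:
        warnings.warn("dt·max degradation rate > 1: integration may be unstable",
                      stacklevel=2)
    A, T, C = state.A, state.T, state.C
    dt = p.dt
    sqdt = math.sqrt(dt)
    eps = p.E0 * state.areas
    fA, fT, hill_A, hill_T = _drift(A, T, p)
    gA = p.c0 * np.sqrt((p.P_A + hill_A + p.G_A * A) / (2 * eps))
    gT = p.c0 * np.sqrt((hill_T + p.G_T * T) / (2 * eps))
    gC = p.c0 * np.sqrt(p.P_C / (2 * eps))
    xi = state.rng.standard_normal((3, state.n_cells))

    A_pred = A + fA * dt + gA * sqdt * xi[0]
    T_pred = T + fT * dt + gT * sqdt * xi[1]
    fA2, fT2, _, _ = _drift(np.maximum(A_pred, 0.0), np.maximum(T_pred, 0.0), p)
    state.A = np.maximum(A + 0.5 * (fA + fA2) * dt + gA * sqdt * xi[0], 0.0)
    state.T = np.maximum(T + 0.5 * (fT + fT2) * dt + gT * sqdt * xi[1], 0.0)
    state.C = np.maximum(C + p.P_C * dt + gC * sqdt * xi[2], 0.0)
    return state


# ---------------------------------------------------------------------------
# Growth and dilution


def grow_and_dilute(state: SimState, params: SimParams | None = None) -> SimState:
    """Anisotropic exponential vertex displacement about the tissue center of
    mass, then dilution of the modeled variables by area_before/area_after."""
    p = params or state.params
    if p.k_radial == 0 and p.k_axial == 0:
        return state
    com = state.center_of_mass()
    sx = math.exp(p.k_radial * p.dt)
    sy = math.exp(p.k_axial * p.dt)
    state.vertices = com + (state.vertices - com) * np.array([sx, sy])
    factor = 1.0 / (sx * sy)  # affine determinant: uniform per cell
    state.areas = state.areas / factor
    state.A = state.A * factor
    state.T = state.T * factor
    if p.dilute_timer:
        state.C = state.C * factor
    return state


# ---------------------------------------------------------------------------
# Division geometry


def shortest_centroid_wall(points: np.ndarray, angle_step_deg: float = 1.0,
                           anchor: np.ndarray | None = None
                           ) -> list[tuple[float, float, int, float, int, float]]:
    """Candidate division walls through the polygon centroid.

    Scans orientations at ``angle_step_deg`` resolution; for each, finds the
    chord through the centroid (the pair of boundary intersections bracketing
    the centroid along the line).  Returns candidates sorted by wall length:
    (length, angle, edge1, s1, edge2, s2) with s the position along the edge.
    ``anchor`` overrides the centroid (fallback for degenerate polygons whose
    centroid falls outside).
    """
    c = _polygon_centroid(points) if anchor is None else anchor
    p1 = points
    p2 = np.roll(points, -1, axis=0)
    e = p2 - p1  # (E,2)
    angles = np.arange(0.0, math.pi, math.radians(angle_step_deg))
    d = np.stack([np.cos(angles), np.sin(angles)], axis=1)  # (Angles,2)
    # cross products, broadcast (Angles, E)
    cross_de = d[:, None, 0] * e[None, :, 1] - d[:, None, 1] * e[None, :, 0]
    rel = p1 - c  # (E,2)
    cross_rel_e = rel[:, 0] * e[:, 1] - rel[:, 1] * e[:, 0]  # (E,)
    cross_rel_d = rel[None, :, 0] * d[:, None, 1] - rel[None, :, 1] * d[:, None, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross_rel_e[None, :] / cross_de
        s = cross_rel_d / cross_de
    valid = (np.abs(cross_de) > 1e-12) & (s >= 0.0) & (s < 1.0)
    t_pos = np.where(valid & (t > 1e-9), t, np.inf)
    t_neg = np.where(valid & (t < -1e-9), t, -np.inf)
    i_pos = t_pos.argmin(axis=1)
    i_neg = t_neg.argmax(axis=1)
    rows = np.arange(len(angles))
    length = t_pos[rows, i_pos] - t_neg[rows, i_neg]
    ok = np.isfinite(length)
    cands = [
        (float(length[a]), float(angles[a]), int(i_pos[a]), float(s[a, i_pos[a]]),
         int(i_neg[a]), float(s[a, i_neg[a]]))
        for a in rows[ok]
    ]
    cands.sort(key=lambda r: r[0])
    return cands


def _split_loop(loop: list[int], e1: int, w1: int, e2: int, w2: int
                ) -> tuple[list[int], list[int]]:
    """Split a loop by a wall from new vertex w1 on edge e1 to w2 on edge e2."""
    n = len(loop)
    a: list[int] = [w1]
    k = (e1 + 1) % n
    while True:
        a.append(loop[k])
        if k == e2:
            break
        k = (k + 1) % n
    a.append(w2)
    b: list[int] = [w2]
    k = (e2 + 1) % n
    while True:
        b.append(loop[k])
        if k == e1:
            break
        k = (k + 1) % n
    b.append(w1)
    return a, b


def _dedupe_loop(loop: list[int], vertices: np.ndarray, tol: float = 1e-9
                 ) -> list[int]:
    """Drop consecutive (and wrap-around) coincident vertices from a loop."""
    out: list[int] = []
    for v in loop:
        if out and (v == out[-1]
                    or float(((vertices[v] - vertices[out[-1]]) ** 2).sum()) < tol**2):
            continue
        out.append(v)
    while len(out) > 1 and (
        out[0] == out[-1]
        or float(((vertices[out[0]] - vertices[out[-1]]) ** 2).sum()) < tol**2
    ):
        out.pop()
    return out


def _loop_is_valid(loop: list[int], vertices: np.ndarray) -> bool:
    from shapely.geometry import Polygon as _ShPoly

    if len(loop) < 3:
        return False
    poly = _ShPoly(vertices[loop])
    return poly.is_valid and poly.area > 0


def divide_cell_geometry(state: SimState, i: int) -> tuple[list[int], list[int]]:
    """Insert the shortest centroid wall into the mesh and return the two
    daughter loops.  Neighbor loops sharing the cut edges receive the new
    vertices, keeping the tiling consistent.  Chord endpoints landing
    (nearly) on an existing vertex are snapped to it so no degenerate
    slivers accumulate; falls back to the next-shortest valid chord on
    pathological splits, and to a representative interior anchor when the
    centroid lies outside a non-simple polygon."""
    loop = state.loops[i]
    points = state.cell_polygon(i)
    n = len(loop)
    mother_area = _polygon_area(points)
    scale = math.sqrt(abs(mother_area))
    cands = shortest_centroid_wall(points, state.params.division_angle_step_deg)
    if not cands:
        from shapely.geometry import Polygon as _ShPoly

        anchor = _ShPoly(points).representative_point()
        cands = shortest_centroid_wall(
            points, state.params.division_angle_step_deg,
            anchor=np.array([anchor.x, anchor.y]),
        )
    for length, _ang, e1, s1, e2, s2 in cands:
        if e1 == e2:
            continue
        n_prev = len(state.vertices)
        new_vertices = []
        endpoints = []
        inserts = []  # (edge_start_vertex, edge_end_vertex, new_vertex_index)
        for e, s in ((e1, s1), (e2, s2)):
            va, vb = loop[e], loop[(e + 1) % n]
            v = points[e] + s * (points[(e + 1) % n] - points[e])
            edge_len = float(np.linalg.norm(points[(e + 1) % n] - points[e]))
            snap = 1e-6 * scale
            if s * edge_len < snap:
                endpoints.append(va)
            elif (1 - s) * edge_len < snap:
                endpoints.append(vb)
            else:
                idx = n_prev + len(new_vertices)
                new_vertices.append(v)
                endpoints.append(idx)
                inserts.append((va, vb, idx))
        if endpoints[0] == endpoints[1]:
            continue
        if new_vertices:
            state.vertices = np.vstack([state.vertices] + new_vertices)
        la, lb = _split_loop(loop, e1, endpoints[0], e2, endpoints[1])
        la = _dedupe_loop(la, state.vertices)
        lb = _dedupe_loop(lb, state.vertices)
        area_a = _polygon_area(state.vertices[la]) if len(la) >= 3 else 0.0
        area_b = _polygon_area(state.vertices[lb]) if len(lb) >= 3 else 0.0
        if (
            # balanced daughters: a valid centroid chord never cuts off a
            # sliver; this also stops degenerate lineages from accumulating
            area_a > 0.05 * mother_area
            and area_b > 0.05 * mother_area
            and abs(area_a + area_b - mother_area) <= 1e-6 * mother_area
            and _loop_is_valid(la, state.vertices)
            and _loop_is_valid(lb, state.vertices)
        ):
            for va, vb, idx in inserts:
                _insert_into_neighbor(state, i, va, vb, idx)
            return la, lb
        state.vertices = state.vertices[:n_prev]  # undo and try next chord
    raise GeometryError(f"no valid division wall found for cell index {i}")


def _insert_into_neighbor(state: SimState, cell_i: int, va: int, vb: int,
                          w: int) -> None:
    """Insert vertex w between va and vb in the neighbor loop sharing that edge."""
    for j, lp in enumerate(state.loops):
        if j == cell_i:
            continue
        n = len(lp)
        for k in range(n):
            if lp[k] == vb and lp[(k + 1) % n] == va:
                lp.insert(k + 1, w)
                return


# ---------------------------------------------------------------------------
# Cell-cycle events


def cycle_events(state: SimState, params: SimParams | None = None) -> SimState:
    """S-phase (ploidy doubling), commitment (absorbing), and the Timer
    division/endocycle rule, applied after each Langevin step."""
    p = params or state.params
    rng = state.rng

    # (i) S-phase
    s_phase = (state.C >= p.theta_CS) & ~state.post_S
    state.ploidy[s_phase] *= 2
    state.post_S[s_phase] = True

    # (ii) commitment to endoreduplication (absorbing)
    state.committed |= state.post_S & (state.T >= p.theta_T)

    # (iii) Timer threshold: endocycle reset or division
    over = np.flatnonzero(state.C >= p.theta_CD)
    dividers = [int(i) for i in over if not state.committed[i]]
    endo = [int(i) for i in over if state.committed[i]]
    for i in endo:
        state.C[i] = rng.uniform(0.0, 0.5)
        state.post_S[i] = False
    for i in sorted(dividers, reverse=True):
        _divide(state, i)
    return state


def _divide(state: SimState, i: int) -> None:
    """Divide cell i: shortest centroid wall; daughters inherit A and T,
    draw independent Timers from U[0, 0.5), reset post_S, and return to
    2C-equivalent bookkeeping."""
    rng = state.rng
    la, lb = divide_cell_geometry(state, i)
    area_a = _polygon_area(state.vertices[la])
    area_b = _polygon_area(state.vertices[lb])

    def scalar_arrays():
        return ("A", "T", "C", "ploidy", "post_S", "committed",
                "divisions", "last_division_time")

    A, T = state.A[i], state.T[i]
    divs = state.divisions[i] + 1
    lin = state.lineage[i]
    # daughter a replaces the mother in place; daughter b is appended
    state.loops[i] = la
    state.areas[i] = area_a
    state.loops.append(lb)
    state.areas = np.append(state.areas, area_b)
    for name in scalar_arrays():
        arr = getattr(state, name)
        setattr(state, name, np.append(arr, arr[i]))
    for j in (i, state.n_cells - 1):
        state.A[j] = A
        state.T[j] = T
        state.C[j] = rng.uniform(0.0, 0.5)
        state.ploidy[j] = 2
        state.post_S[j] = False
        state.committed[j] = False
        state.divisions[j] = divs
        state.last_division_time[j] = state.time
    state.ids.append(state.next_id + 1)
    state.lineage.append(lin)
    state.ids[i] = state.next_id
    state.next_id += 2


def divide_cell(state: SimState, i: int) -> tuple[int, int]:
    """Public division entry point; returns the indices of the two daughters."""
    _divide(state, i)
    return i, state.n_cells - 1


# ---------------------------------------------------------------------------
# Rasterization and cropping


def rasterize(state: SimState, raster_scale: float = 6.0, pad: int = 3
              ) -> tuple[LabeledTissue, CellTable]:
    """Rasterize the polygonal tissue to a labeled image.

    ``raster_scale`` is pixels per simulation length unit; pixel_size of the
    output is 1/raster_scale so raster areas stay in simulation units.
    Seam pixels between polygons are filled by nearest-label competition
    inside the tissue silhouette.
    """
    verts = state.vertices
    lo = verts.min(axis=0)
    hi = verts.max(axis=0)
    W = int(math.ceil((hi[0] - lo[0]) * raster_scale)) + 2 * pad + 1
    H = int(math.ceil((hi[1] - lo[1]) * raster_scale)) + 2 * pad + 1
    labels = np.zeros((H, W), dtype=np.int32)
    for i in range(state.n_cells):
        poly = state.cell_polygon(i)
        cols = (poly[:, 0] - lo[0]) * raster_scale + pad
        rows = (poly[:, 1] - lo[1]) * raster_scale + pad
        rr, cc = skdraw.polygon(rows, cols, shape=labels.shape)
        labels[rr, cc] = state.ids[i]
    filled = ndimage.binary_fill_holes(labels > 0)
    gaps = filled & (labels == 0)
    if gaps.any():
        _, (ir, ic) = ndimage.distance_transform_edt(labels == 0, return_indices=True)
        labels[gaps] = labels[ir[gaps], ic[gaps]]
    tissue = LabeledTissue(labels, pixel_size=1.0 / raster_scale)
    present = tissue.cell_ids
    frame = state.to_table()
    frame = frame[frame["id"].isin(present)]
    # use rasterized areas so downstream size thresholds match the image
    areas = tissue.areas_um2()
    frame = frame.assign(area_um2=[areas[i] for i in frame["id"]])
    border = tissue.border_ids
    frame = frame.assign(is_border=[i in border for i in frame["id"]],
                         cell_type="pavement")
    return tissue, CellTable(frame, provenance=f"sim(t={state.time:.1f})")


def largest_interior_rectangle(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Maximal axis-aligned rectangle of True pixels: (r0, c0, h, w)."""
    H, W = mask.shape
    heights = np.zeros(W, dtype=int)
    best = (0, 0, 0, 0)
    best_area = 0
    for r in range(H):
        heights = np.where(mask[r], heights + 1, 0)
        stack: list[int] = []
        for c in range(W + 1):
            h = int(heights[c]) if c < W else 0
            while stack and heights[stack[-1]] >= h:
                top = stack.pop()
                height = int(heights[top])
                left = stack[-1] + 1 if stack else 0
                width = c - left
                area = height * width
                if area > best_area and height > 0:
                    best_area = area
                    best = (r - height + 1, left, height, width)
            stack.append(c)
    return best


def crop_maximal_rectangle(tissue: LabeledTissue) -> LabeledTissue:
    """Crop the image to the maximal rectangle fully inside the tissue."""
    r0, c0, h, w = largest_interior_rectangle(tissue.labels > 0)
    if h == 0 or w == 0:
        raise GeometryError("tissue contains no interior rectangle")
    return LabeledTissue(tissue.labels[r0 : r0 + h, c0 : c0 + w].copy(),
                         tissue.pixel_size)


def table_for_tissue(tissue: LabeledTissue, full_table: CellTable) -> CellTable:
    """Rebuild a snapshot table for a derived (e.g. cropped) raster: areas and
    border flags come from the raster, ploidy/commitment/lineage carry over."""
    present = tissue.cell_ids
    frame = full_table.frame[full_table.frame["id"].isin(present)].copy()
    areas = tissue.areas_um2()
    border = tissue.border_ids
    frame["area_um2"] = [areas[i] for i in frame["id"]]
    frame["is_border"] = [i in border for i in frame["id"]]
    return CellTable(frame, provenance=full_table.provenance + "+crop")


# ---------------------------------------------------------------------------
# Driver


@dataclasses.dataclass
class SimResult:
    state: SimState
    snapshots: dict[float, tuple[LabeledTissue, CellTable]]


def run_simulation(params: SimParams,
                   snapshot_times: Sequence[float] = (),
                   raster_scale: float = 6.0) -> SimResult:
    """Integrate the full model: Langevin step → growth/dilution → cycle
    events, from t=0 to t_end with step dt; snapshots rasterized at the
    requested times (and always at t_end)."""
    params.validate()
    state = init_simulation(params)
    pending = sorted(set(snapshot_times))
    snapshots: dict[float, tuple[LabeledTissue, CellTable]] = {}
    n_steps = int(round(params.t_end / params.dt))
    for step in range(n_steps):
        langevin_step(state, params)
        grow_and_dilute(state, params)
        cycle_events(state, params)
        state.time = (step + 1) * params.dt
        while pending and state.time >= pending[0] - 1e-9:
            t_snap = pending.pop(0)
            snapshots[t_snap] = rasterize(state, raster_scale)
    if params.t_end not in snapshots:
        snapshots[params.t_end] = rasterize(state, raster_scale)
    return SimResult(state=state, snapshots=snapshots)


# ---------------------------------------------------------------------------
# Giant-cell identification in simulation outputs


def sim_giant_set(table: CellTable, mode: str = "ploidy-threshold",
                  ploidy_floor: int = 16) -> set[int]:
    """Identify giant cells in a simulation snapshot table.

    'ploidy-threshold': the size threshold is the minimum area among cells
    with ploidy ≥ ``ploidy_floor``; every cell at or above that area is giant
    (so all ≥16C cells are giant, and lower-ploidy cells exceeding the
    threshold are included too).  'first-arising': cells committed to
    endoreduplication (they stopped dividing at commitment).
    """
    frame = table.frame
    if mode == "ploidy-threshold":
        high = frame[frame["ploidy"] >= ploidy_floor]
        # cells cut by the image border have truncated areas; they must not
        # set the size threshold (they may still be flagged giant by it)
        if "is_border" in frame.columns and not high[high["is_border"] != True].empty:  # noqa: E712
            high = high[high["is_border"] != True]  # noqa: E712
        if high.empty:
            warnings.warn("no cells at or above the ploidy floor; empty giant set",
                          stacklevel=2)
            return set()
        threshold = float(high["area_um2"].min())
        by_size = frame["area_um2"] >= threshold
        by_ploidy = frame["ploidy"] >= ploidy_floor  # guarantee for cut cells
        return set(int(i) for i in frame.loc[by_size | by_ploidy, "id"])
    if mode == "first-arising":
        if "committed" not in frame.columns:
            raise ConfigError("table lacks a 'committed' column")
        return set(int(i) for i in frame.loc[frame["committed"] == True, "id"])  # noqa: E712
    raise ConfigError(f"unknown giant-set mode {mode!r}")
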