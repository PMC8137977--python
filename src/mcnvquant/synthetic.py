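"""Synthetic OCTA-like CNV networks with exact ground truth.

Because no per-eye raw angiograms of published mCNV cohorts are deposited,
every upstream stage of the pipeline is validated against generated vessel
networks whose skeleton, junctions, branch lengths and calibers are known by
construction.  The generator grows a depth-limited stochastic bifurcation
tree with Gaussian-perturbed branch angles and exponential caliber decay
(child caliber = parent caliber x ``caliber_decay``), in the four phenotypes
seen on baseline mCNV angiograms:

* ``medusa`` — branches radiate in all directions from the lesion center;
* ``sea_fan`` — branches radiate from a single point on the lesion border;
* ``tree_in_bud`` — compact round lesion without a dominant trunk;
* ``disorganized_loops`` — short sparse segments with anastomotic loops.

A treatment-effect transform mimics the anti-VEGF response seen clinically:
small-caliber branches disappear while the main, larger-caliber vessels
persist (and may dilate slightly).  Rendering adds the first-order OCTA
appearance: bright tubes on a darker background with multiplicative lognormal
speckle and optical blur.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull

from .biomarkers import BiomarkerPanel, box_counts
from .imaging import EnFaceImage, LesionMask, normalize, rasterize_contour

PATTERNS = ("medusa", "sea_fan", "tree_in_bud", "disorganized_loops")


@dataclass
class NetworkParams:
    """Growth-model parameters (all lengths in pixels).

    ``segment_steps`` bounds the number of ~``step_px`` steps per branch, so
    branch length is roughly ``step_px * segment_steps``; the lower bound also
    keeps bifurcation points well separated relative to vessel caliber, which
    is what makes junction counts recoverable from rendered images.
    """

    n_primary_branches: int = 6
    branching_prob: float = 0.85
    max_depth: int = 3
    caliber_root_px: float = 4.0
    caliber_decay: float = 0.8
    loop_prob: float = 0.0
    lesion_radius_px: float = 120.0
    step_px: float = 2.5
    segment_steps: tuple[int, int] = (10, 16)
    angle_jitter_rad: float = 0.12
    child_angle_rad: tuple[float, float] = (0.6, 1.0)
    length_decay: float = 0.85
    min_separation_px: float = 8.0  # growth stops before touching another vessel
    # shorter attempts are rejected; the bound exceeds the kin radius
    # (2 x min_separation) so siblings always face the collision check
    min_segment_pts: int = 8


@dataclass
class Segment:
    """One branch: a polyline in (x, y) pixel coordinates with a caliber."""

    id: int
    points: np.ndarray  # (n, 2) float, (x, y)
    caliber_px: float
    parent: Optional[int]
    depth: int

    @property
    def arclength_px(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def chord_px(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class Junction:
    """A bifurcation or anastomosis: position plus the incident segment arms.

    ``arms`` lists (segment_id, kind) pairs where kind is ``"end"`` for a
    parent terminating here, ``"start"`` for a child originating here, and
    ``"mid"`` for a segment an anastomosis attaches to (two arms' worth).
    """

    position: np.ndarray  # (x, y)
    arms: list[tuple[int, str]]

    def degree(self, alive: set[int]) -> int:
        d = 0
        for seg_id, kind in self.arms:
            if seg_id in alive:
                d += 2 if kind == "mid" else 1
        return d


@dataclass
class VesselNetworkTruth:
    """A generated network plus everything needed to score the pipeline."""

    segments: list[Segment]
    junctions: list[Junction]
    pattern: str
    lesion_polygon: np.ndarray  # (m, 2) in (x, y)
    seed: int
    shape: tuple[int, int] = (304, 304)
    params: NetworkParams = field(default_factory=NetworkParams)

    @property
    def junction_points(self) -> np.ndarray:
        alive = {s.id for s in self.segments}
        return np.array(
            [j.position for j in self.junctions if j.degree(alive) >= 3]
        ).reshape(-1, 2)

    @property
    def n_junctions(self) -> int:
        return len(self.junction_points)

    @property
    def total_length_px(self) -> float:
        return sum(s.arclength_px for s in self.segments)

    def centerline_mask(self) -> np.ndarray:
        """Rasterized 1-px (8-connected) centerlines: the true skeleton."""
        from skimage.draw import line as _bline

        mask = np.zeros(self.shape, dtype=bool)
        h, w = self.shape
        for seg in self.segments:
            pts = np.round(seg.points[:, ::-1]).astype(int)  # (row, col)
            for (r0, c0), (r1, c1) in zip(pts[:-1], pts[1:]):
                rr, cc = _bline(r0, c0, r1, c1)
                keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
                mask[rr[keep], cc[keep]] = True
        return mask

    def tube_mask(self) -> np.ndarray:
        """Rasterized union of vessel tubes (disk of radius caliber/2)."""
        h, w = self.shape
        rows, cols = np.mgrid[0:h, 0:w]
        mask = np.zeros(self.shape, dtype=bool)
        for seg in self.segments:
            rad = seg.caliber_px / 2.0
            ri = int(math.ceil(rad))
            for x, y in _densify(seg.points, 0.5):
                r0, c0 = int(round(y)), int(round(x))
                rr = slice(max(r0 - ri, 0), min(r0 + ri + 1, h))
                cc = slice(max(c0 - ri, 0), min(c0 + ri + 1, w))
                dy = rows[rr, cc] - y
                dx = cols[rr, cc] - x
                mask[rr, cc] |= dy * dy + dx * dx <= rad * rad
        return mask

    def true_skeleton_length_mm(self, pixel_scale_mm: float = 3.0 / 304.0) -> float:
        """Step-sum length of the true raster skeleton (same metric as the
        pipeline's total length: 1 px per orthogonal, sqrt(2) per diagonal
        step).  This is the apples-to-apples reference for skeleton-length
        recovery; the continuous polyline arclength in :meth:`true_metrics`
        is shorter by the well-known digitization factor of ~5%."""
        from .skeleton import SkeletonMap, total_length_mm

        return total_length_mm(SkeletonMap(self.centerline_mask()), pixel_scale_mm)

    def true_metrics(self, pixel_scale_mm: float = 3.0 / 304.0) -> BiomarkerPanel:
        """Ground-truth biomarker panel computed from the continuous centerlines."""
        nan = float("nan")
        lesion = rasterize_contour(self.lesion_polygon, self.shape)
        lesion_area = lesion.n_pixels * pixel_scale_mm**2
        if not self.segments:
            return BiomarkerPanel(
                mcnv_area_mm2=0.0, vessel_area_mm2=0.0, vessel_density=0.0,
                vessel_length_mm=0.0, vessel_diameter_um=nan,
                fractal_dimension=nan, vessel_junctions=0,
                junction_density_per_mm=nan, vessel_tortuosity=nan,
            )
        tube = self.tube_mask()
        va = float(tube.sum()) * pixel_scale_mm**2
        vl = self.total_length_px * pixel_scale_mm
        tort = []
        for s in self.segments:
            if s.chord_px > 1e-9:
                tort.append(s.arclength_px / s.chord_px)
            else:  # closed loop: chord convention is the loop diameter
                diff = s.points[:, None, :] - s.points[None, :, :]
                diam = float(np.sqrt((diff**2).sum(-1)).max())
                if diam > 0:
                    tort.append(s.arclength_px / diam)
        center = self.centerline_mask()
        try:
            from .biomarkers import fractal_dimension as _fd

            fd = _fd(center)
        except ValueError:
            fd = nan
        vj = self.n_junctions
        return BiomarkerPanel(
            mcnv_area_mm2=lesion_area,
            vessel_area_mm2=va,
            vessel_density=va / lesion_area if lesion_area > 0 else nan,
            vessel_length_mm=vl,
            vessel_diameter_um=1000.0 * va / vl if vl > 0 else nan,
            fractal_dimension=fd,
            vessel_junctions=vj,
            junction_density_per_mm=vj / vl if vl > 0 else nan,
            vessel_tortuosity=float(np.mean(tort)) if tort else nan,
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "pattern": self.pattern,
                "seed": self.seed,
                "shape": list(self.shape),
                "lesion_polygon": self.lesion_polygon.tolist(),
                "segments": [
                    {
                        "id": s.id,
                        "points": np.round(s.points, 3).tolist(),
                        "caliber_px": s.caliber_px,
                        "parent": s.parent,
                        "depth": s.depth,
                    }
                    for s in self.segments
                ],
                "junction_points": np.round(self.junction_points, 3).tolist(),
            }
        )


def _densify(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at roughly ``spacing``-px intervals."""
    out = [points[0]]
    for a, b in zip(points[:-1], points[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(int(math.ceil(d / spacing)), 1)
        for i in range(1, n + 1):
            out.append(a + (b - a) * (i / n))
    return np.asarray(out)


def _grow_segment(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: float,
    n_steps: int,
    params: NetworkParams,
    center: np.ndarray,
    occupied: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Random-walk a polyline; stops at the lesion boundary or before
    coming within ``min_separation_px`` of an already grown vessel."""
    pts = [start.copy()]
    theta = direction
    pos = start.copy()
    for _ in range(n_steps):
        theta += rng.normal(0.0, params.angle_jitter_rad)
        nxt = pos + params.step_px * np.array([math.cos(theta), math.sin(theta)])
        if np.linalg.norm(nxt - center) > params.lesion_radius_px:
            break
        if occupied is not None and len(occupied):
            if np.linalg.norm(occupied - nxt, axis=1).min() < params.min_separation_px:
                break
        pos = nxt
        pts.append(pos.copy())
    return np.asarray(pts), theta


def generate_network(
    pattern: str,
    seed: int,
    params: Optional[NetworkParams] = None,
    shape: tuple[int, int] = (304, 304),
) -> VesselNetworkTruth:
    """Grow a seeded stochastic vessel network of the given phenotype.

    The same ``(pattern, seed, params)`` always regenerates the identical
    network.  Bifurcations only count as junctions when at least two children
    actually grew, so the recorded junction set matches the realized topology
    exactly.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"unknown pattern {pattern!r}; choose from {PATTERNS}")
    params = params or _pattern_defaults(pattern)
    rng = np.random.default_rng(seed)
    center = np.array([shape[1] / 2.0, shape[0] / 2.0])

    segments: list[Segment] = []
    junctions: list[Junction] = []
    next_id = [0]
    cloud: list[tuple[int, np.ndarray]] = []  # (segment id, dense centerline)

    def occupied_for(start: np.ndarray, kin_ids: set[int]) -> Optional[np.ndarray]:
        """Obstacle cloud: kin (parent/sibling) points count only away from the
        junction region around ``start``; unrelated vessels count everywhere."""
        parts = []
        for sid, pts in cloud:
            if sid in kin_ids:
                far = np.linalg.norm(pts - start, axis=1) > 2.0 * params.min_separation_px
                pts = pts[far]
            if len(pts):
                parts.append(pts)
        return np.vstack(parts) if parts else None

    def grow(start, direction, depth, caliber, parent_id, steps_scale=1.0,
             kin_ids: Optional[set[int]] = None):
        lo, hi = params.segment_steps
        n_steps = int(round(rng.integers(lo, hi + 1) * steps_scale))
        occupied = occupied_for(start, kin_ids or set())
        pts, end_theta = _grow_segment(
            rng, start, direction, n_steps, params, center, occupied
        )
        if len(pts) < params.min_segment_pts:  # reject stubs: a bifurcation
            return None                         # must produce two real branches
        seg_id = next_id[0]
        cloud.append((seg_id, _densify(pts, 1.0)))
        seg = Segment(seg_id, pts, caliber, parent_id, depth)
        next_id[0] += 1
        segments.append(seg)
        if depth < params.max_depth and rng.random() < params.branching_prob:
            spread = rng.uniform(*params.child_angle_rad)
            children = []
            for sign in (+1, -1):
                child = grow(
                    pts[-1].copy(),
                    end_theta + sign * spread / 2.0 + rng.normal(0, 0.08),
                    depth + 1,
                    caliber * params.caliber_decay,
                    seg.id,
                    steps_scale * params.length_decay,
                    kin_ids={seg.id} | {c.id for c in children},
                )
                if child is not None:
                    children.append(child)
            if len(children) >= 2:
                junctions.append(
                    Junction(
                        position=pts[-1].copy(),
                        arms=[(seg.id, "end")] + [(c.id, "start") for c in children],
                    )
                )
        return seg

    if pattern == "medusa":
        # primaries start on a small ring so tubes stay resolvable at the hub
        r0 = 2.5 * params.caliber_root_px
        for k in range(params.n_primary_branches):
            theta = 2 * math.pi * k / params.n_primary_branches + rng.normal(0, 0.12)
            start = center + r0 * np.array([math.cos(theta), math.sin(theta)])
            grow(start, theta, 0, params.caliber_root_px, None)
    elif pattern == "sea_fan":
        # primaries originate on a 60-degree arc of the lesion border and fan
        # inward; origins are staggered so the trunks stay resolvable
        theta0 = rng.uniform(0, 2 * math.pi)
        sector = math.radians(60.0)
        r_origin = params.lesion_radius_px * 0.9
        for k in range(params.n_primary_branches):
            frac = (k + 0.5) / params.n_primary_branches - 0.5
            phi = theta0 + frac * sector
            origin = center + r_origin * np.array([math.cos(phi), math.sin(phi)])
            inward = phi + math.pi + rng.normal(0, 0.1)
            grow(origin, inward, 0, params.caliber_root_px, None)
    elif pattern == "tree_in_bud":
        for _ in range(params.n_primary_branches):
            r = rng.uniform(0, params.lesion_radius_px / 3.0)
            phi = rng.uniform(0, 2 * math.pi)
            start = center + r * np.array([math.cos(phi), math.sin(phi)])
            grow(start, rng.uniform(0, 2 * math.pi), 1,
                 params.caliber_root_px * params.caliber_decay, None)
    else:  # disorganized_loops
        for _ in range(params.n_primary_branches):
            r = rng.uniform(0, params.lesion_radius_px / 2.0)
            phi = rng.uniform(0, 2 * math.pi)
            start = center + r * np.array([math.cos(phi), math.sin(phi)])
            if rng.random() < params.loop_prob:
                # the phenotype's namesake: a closed vascular loop
                loop_pts = _grow_closed_loop(rng, start, params, cloud)
                if loop_pts is not None:
                    seg = Segment(next_id[0], loop_pts,
                                  params.caliber_root_px * params.caliber_decay,
                                  None, 1)
                    next_id[0] += 1
                    segments.append(seg)
                    cloud.append((seg.id, _densify(loop_pts, 1.0)))
            else:
                grow(start, rng.uniform(0, 2 * math.pi), params.max_depth - 1,
                     params.caliber_root_px * params.caliber_decay, None)
        _add_loops(rng, segments, junctions, next_id, params)

    if not segments:
        poly = center + 10.0 * np.array(
            [[1, 0], [0, 1], [-1, 0], [0, -1]], dtype=float
        )
        return VesselNetworkTruth([], [], pattern, poly, seed, shape, params)

    pts = np.vstack([s.points for s in segments])
    hull = ConvexHull(pts)
    hull_pts = pts[hull.vertices]
    centroid = hull_pts.mean(axis=0)
    margin = params.caliber_root_px + 6.0
    vecs = hull_pts - centroid
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    poly = hull_pts + vecs / np.maximum(norms, 1e-9) * margin
    poly[:, 0] = np.clip(poly[:, 0], 0, shape[1])
    poly[:, 1] = np.clip(poly[:, 1], 0, shape[0])
    return VesselNetworkTruth(segments, junctions, pattern, poly, seed, shape, params)


def _grow_closed_loop(
    rng: np.random.Generator,
    anchor: np.ndarray,
    params: NetworkParams,
    cloud: list,
) -> Optional[np.ndarray]:
    """A closed, gently irregular loop polyline anchored at ``anchor``;
    ``None`` when it cannot keep clear of already grown vessels."""
    radius = rng.uniform(9.0, 16.0)
    phi0 = rng.uniform(0, 2 * math.pi)
    loop_center = anchor + radius * np.array([math.cos(phi0), math.sin(phi0)])
    n = 28
    jitter = rng.normal(0, 0.06 * radius, size=n)
    # smooth the radial jitter so the loop stays simple (non-self-crossing)
    jitter = np.convolve(np.r_[jitter[-2:], jitter, jitter[:2]],
                         np.ones(5) / 5, "valid")
    thetas = phi0 + math.pi + np.linspace(0, 2 * math.pi, n, endpoint=False)
    pts = loop_center[None, :] + (radius + jitter)[:, None] * np.column_stack(
        [np.cos(thetas), np.sin(thetas)])
    pts = np.vstack([pts, pts[:1]])  # close the polyline
    if cloud:
        occupied = np.vstack([p for _, p in cloud])
        d = np.linalg.norm(pts[:, None, :] - occupied[None, :, :], axis=2)
        if d.min() < params.min_separation_px:
            return None
    return pts


def _add_loops(rng, segments, junctions, next_id, params: NetworkParams) -> None:
    """Anastomose segment endpoints to nearby mid-segment points.

    A connector is only accepted when its path keeps ``min_separation_px``
    from every unrelated vessel and its attachment point stays clear of
    existing junctions, so the recorded anastomoses are exactly the ones a
    skeleton of the rendered image can show.
    """
    sep = params.min_separation_px
    dense = {s.id: _densify(s.points, 1.0) for s in segments}
    junction_pos = [j.position for j in junctions]
    by_id = {s.id: s for s in segments}

    # union-find over connected components (tree links + placed connectors):
    # an anastomosis inside one component closes an actual vascular loop,
    # which is what the phenotype is named for, so those targets come first
    comp = {s.id: s.id for s in segments}

    def find(i):
        while comp[i] != i:
            comp[i] = comp[comp[i]]
            i = comp[i]
        return i

    def union(a, b):
        comp[find(a)] = find(b)

    for s in segments:
        if s.parent is not None and s.parent in comp:
            union(s.id, s.parent)

    endpoints = [(s, s.points[-1]) for s in list(segments)]
    for seg, ep in endpoints:
        if rng.random() >= params.loop_prob:
            continue
        best = None
        for same_component_only in (True, False):
            for other in segments:
                if other.id not in comp or seg.id not in comp:
                    continue
                if (find(other.id) == find(seg.id)) != same_component_only:
                    continue
                if (other.id == seg.id or other.parent == seg.id
                        or seg.parent == other.id):
                    continue
                # attachment points keep well clear of the target's own ends,
                # so the anastomosis forms an unambiguous T on the skeleton
                far_from_ends = (
                    (np.linalg.norm(other.points - other.points[0], axis=1)
                     > 1.5 * sep)
                    & (np.linalg.norm(other.points - other.points[-1], axis=1)
                       > 1.5 * sep)
                )
                interior = other.points[far_from_ends]
                if len(interior) == 0:
                    continue
                d = np.linalg.norm(interior - ep, axis=1)
                i = int(np.argmin(d))
                reach = 60.0 if same_component_only else 45.0
                if 10.0 < d[i] < reach and (best is None or d[i] < best[2]):
                    best = (other, interior[i], d[i])
            if best is not None:
                break
        if best is None:
            continue
        target, attach, _ = best
        if any(np.linalg.norm(attach - jp) < 1.5 * sep for jp in junction_pos):
            continue
        # gentle arc from endpoint to attachment point
        mid = (ep + attach) / 2.0
        normal = np.array([-(attach - ep)[1], (attach - ep)[0]])
        nl = np.linalg.norm(normal)
        if nl > 0:
            mid = mid + normal / nl * rng.uniform(-5, 5)
        conn_pts = _densify(np.array([ep, mid, attach]), params.step_px)
        if not _connector_clear(conn_pts, seg, target, ep, attach, dense, sep):
            continue
        conn = Segment(next_id[0], conn_pts,
                       min(seg.caliber_px, target.caliber_px), seg.id,
                       max(seg.depth, target.depth))
        next_id[0] += 1
        segments.append(conn)
        dense[conn.id] = _densify(conn_pts, 1.0)
        junctions.append(
            Junction(position=attach.copy(),
                     arms=[(target.id, "mid"), (conn.id, "end")])
        )
        junction_pos.append(attach.copy())
        comp[conn.id] = conn.id
        union(conn.id, seg.id)
        union(conn.id, target.id)


def _connector_clear(conn_pts, seg, target, ep, attach, dense, sep) -> bool:
    """True if the connector path stays clear of every vessel it does not join."""
    interior = conn_pts[
        (np.linalg.norm(conn_pts - ep, axis=1) > sep)
        & (np.linalg.norm(conn_pts - attach, axis=1) > sep)
    ]
    for sid, pts in dense.items():
        if sid == seg.id:
            ref = pts[np.linalg.norm(pts - ep, axis=1) > sep]
        elif sid == target.id:
            ref = pts[np.linalg.norm(pts - attach, axis=1) > sep]
        else:
            ref = pts
        if len(ref) == 0:
            continue
        body = interior if sid in (seg.id, target.id) else conn_pts
        if len(body) == 0:
            continue
        d = np.linalg.norm(body[:, None, :] - ref[None, :, :], axis=2)
        if d.min() < sep:
            return False
    return True


def _pattern_defaults(pattern: str) -> NetworkParams:
    if pattern == "tree_in_bud":
        return NetworkParams(n_primary_branches=8, max_depth=3,
                             lesion_radius_px=90.0, segment_steps=(8, 13))
    if pattern == "disorganized_loops":
        return NetworkParams(n_primary_branches=7, branching_prob=0.35,
                             max_depth=3, loop_prob=0.5,
                             lesion_radius_px=70.0, segment_steps=(8, 14),
                             caliber_root_px=3.5)
    return NetworkParams()


def apply_anti_vegf(
    truth: VesselNetworkTruth,
    prune_caliber_px: float,
    trunk_dilation: float = 1.0,
    seed: Optional[int] = None,
) -> VesselNetworkTruth:
    """Simulate the anti-VEGF response: prune thin vessels, keep the trunks.

    Removes every segment with caliber below ``prune_caliber_px`` together
    with its orphaned descendants, multiplies surviving calibers by
    ``trunk_dilation`` (>= 1, modest dilation of persisting vessels), and
    shrinks the lesion outline to the survivors' hull.  Pruning everything is
    legal and yields an empty network (the fully regressed lesion).
    """
    if trunk_dilation < 1.0:
        raise ValueError("trunk_dilation must be >= 1")
    survivors_ids: set[int] = set()
    by_id = {s.id: s for s in truth.segments}
    for s in truth.segments:
        if s.caliber_px < prune_caliber_px:
            continue
        # require the whole ancestor chain to survive (no orphans)
        p, ok = s.parent, True
        while p is not None:
            if by_id[p].caliber_px < prune_caliber_px:
                ok = False
                break
            p = by_id[p].parent
        if ok:
            survivors_ids.add(s.id)
    survivors = [
        replace(by_id[i], caliber_px=by_id[i].caliber_px * trunk_dilation)
        for i in sorted(survivors_ids)
    ]
    if not survivors:
        center = np.array([truth.shape[1] / 2.0, truth.shape[0] / 2.0])
        poly = center + 5.0 * np.array([[1, 0], [0, 1], [-1, 0], [0, -1]], float)
        return VesselNetworkTruth([], [], truth.pattern, poly,
                                  truth.seed, truth.shape, truth.params)
    pts = np.vstack([s.points for s in survivors])
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            hull_pts = pts[hull.vertices]
        except Exception:
            hull_pts = pts
    else:
        hull_pts = pts
    centroid = hull_pts.mean(axis=0)
    margin = truth.params.caliber_root_px * trunk_dilation + 5.0
    vecs = hull_pts - centroid
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    poly = hull_pts + vecs / np.maximum(norms, 1e-9) * margin
    poly[:, 0] = np.clip(poly[:, 0], 0, truth.shape[1])
    poly[:, 1] = np.clip(poly[:, 1], 0, truth.shape[0])
    return VesselNetworkTruth(survivors, truth.junctions, truth.pattern, poly,
                              truth.seed, truth.shape, truth.params)


def generate_cohort(
    n_eyes: int = 30,
    seed: int = 0,
    prune_caliber_range: tuple[float, float] = (2.1, 2.7),
    trunk_dilation_range: tuple[float, float] = (1.02, 1.15),
    pixel_scale_mm: float = 3.0 / 304.0,
) -> list:
    """Simulate a treated cohort: per-eye baseline/post panels from ground truth.

    Each eye draws a phenotype (the observed baseline mix: mostly organized
    interlacing, a minority of disorganized loops), grows a network, applies
    the anti-VEGF transform with a per-eye pruning caliber and trunk dilation,
    and records the ground-truth biomarker panels at both timepoints.  Central
    retinal thickness is co-simulated so that its percent change tracks the
    lesion-area percent change with noise (the structural response correlates
    with the angiographic one).  Injection counts follow the observed 1-4
    range with a stable (<= 2) majority.
    """
    from .cohort import EyeRecord

    rng = np.random.default_rng(seed)
    patterns = ["medusa", "tree_in_bud", "sea_fan", "disorganized_loops"]
    pattern_p = [0.39, 0.35, 0.10, 0.16]
    records = []
    for i in range(n_eyes):
        pattern = rng.choice(patterns, p=pattern_p)
        eye_seed = int(rng.integers(0, 2**31 - 1))
        truth = generate_network(pattern, seed=eye_seed)
        base = truth.true_metrics(pixel_scale_mm)
        prune = rng.uniform(*prune_caliber_range)
        dil = rng.uniform(*trunk_dilation_range)
        post_truth = apply_anti_vegf(truth, prune_caliber_px=prune, trunk_dilation=dil)
        post = post_truth.true_metrics(pixel_scale_mm)

        crt0 = float(np.clip(rng.normal(316.0, 70.0), 180.0, 600.0))
        if base.mcnv_area_mm2 > 0:
            pc_area = (post.mcnv_area_mm2 - base.mcnv_area_mm2) / base.mcnv_area_mm2
        else:
            pc_area = 0.0
        # CRT ratio tracks the area ratio (moderate coupling plus noise)
        rr_crt = float(np.clip(0.55 + 0.35 * (1.0 + pc_area) + rng.normal(0, 0.06),
                               0.45, 1.15))
        base.crt_um = crt0
        post.crt_um = crt0 * rr_crt

        is_oi = pattern != "disorganized_loops"
        records.append(
            EyeRecord(
                patient_id=f"sim{i+1:03d}",
                eye=rng.choice(["L", "R"]),
                age_years=float(np.clip(rng.normal(44.5, 12.5), 20, 75)),
                sex=rng.choice(["M", "F"]),
                se_diopters=float(np.clip(rng.normal(-12.6, 3.2), -18.5, -6.0)),
                overall_pattern="OI" if is_oi else "DVL",
                exuberant_capillaries="Y" if is_oi else "N",
                anastomoses_loops="Y" if rng.random() < 0.97 else "N",
                hypointense_halo="Y" if rng.random() < 0.81 else "N",
                feeder_vessel="Y" if (is_oi and rng.random() < 0.23) else "N",
                n_injections=int(rng.choice([1, 2, 3, 4], p=[0.25, 0.37, 0.32, 0.06])),
                baseline=base,
                post_ivi=post,
            )
        )
    return records


@dataclass
class RenderNoise:
    """First-order OCTA appearance model (all levels on the [0, 1] scale)."""

    speckle_sigma: float = 0.3  # lognormal sigma of multiplicative speckle
    background_level: float = 0.12
    blur_px: float = 0.8


def render_octa(
    truth: VesselNetworkTruth,
    noise: Optional[RenderNoise] = None,
    seed: Optional[int] = None,
    pixel_scale_mm: float = 3.0 / 304.0,
) -> tuple[EnFaceImage, LesionMask]:
    """Rasterize the network as a bright-vessel angiogram plus its lesion mask."""
    noise = noise or RenderNoise()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    img = truth.tube_mask().astype(float)
    img = img + noise.background_level
    if noise.speckle_sigma > 0:
        img = img * rng.lognormal(0.0, noise.speckle_sigma, size=img.shape)
    if noise.blur_px > 0:
        img = ndimage.gaussian_filter(img, noise.blur_px, mode="reflect")
    lesion = rasterize_contour(truth.lesion_polygon, truth.shape)
    return EnFaceImage(normalize(img), pixel_scale_mm=pixel_scale_mm), lesion
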