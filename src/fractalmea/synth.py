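"""Synthetic fluorescence scenes with exact ground truth.

Emulates tiled three-channel fluorescence imaging of dissociated
retinal neuron/glia co-cultures on patterned VACNT/SiO2 substrates:

* neuron somas are placed by surface-specific Poisson processes, a
  configurable fraction aggregated into clusters;
* neurites grow as persistent random walks (unit steps of one pixel,
  turning noise set by a tortuosity parameter) that preferentially
  align with electrode edges when within a capture distance, and
  occasionally "bundle" by duplicating an existing path with a
  sub-pixel offset;
* glia are vector blobs (radially-perturbed ellipses, elongated along
  the local branch axis on electrode tops) added until a target area
  coverage per surface is reached;
* nuclei are disks at somas and glial centres.

Channels are rendered per FOV (bilinear path splatting, Gaussian PSF,
background plus signal-dependent Gaussian noise) while the ground truth
(polyline lengths, glial areas) is kept analytic and exact, so the
measurement pipeline can be validated against numbers that do not
depend on any rasterization choice.

Everything is deterministic given the seed in :class:`CultureParams`.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import shapely
from scipy import ndimage as ndi
from shapely.geometry import LineString, Polygon, box as shapely_box
from shapely.ops import unary_union

from .geometry import ElectrodeLayout, ParameterError
from .masks import FOVPlan


@dataclass(frozen=True)
class CultureParams:
    """Parameters of the synthetic culture.

    Densities are somas per mm^2 of the respective surface; coverages
    are target area fractions; ``tortuosity`` in [0, 1] sets direction
    persistence of the neurite walks (1 = straight); ``p_edge_follow``
    is the per-step probability that a walk within ``d_edge`` um of an
    electrode boundary steps along the boundary tangent; ``p_bundle``
    is the probability that a new neurite duplicates an existing path
    with a sub-pixel offset.  Defaults are loosely calibrated to a
    dissociated retinal co-culture seeded at ~3.7e6 cells/mL, scaled to
    the areal density of adherent, marker-positive cells at 17 DIV.
    """

    seed: int = 0
    neuron_density_si: float = 40.0
    neuron_density_cnt: float = 120.0
    processes_per_soma: tuple[int, int] = (2, 4)
    mean_process_length: float = 150.0
    tortuosity: float = 0.9
    d_edge: float = 3.0
    p_edge_follow: float = 0.6
    p_bundle: float = 0.15
    cluster_rate: float = 0.25
    cluster_size_mean: float = 4.0
    glia_coverage_si: float = 0.30
    glia_coverage_cnt: float = 0.08
    glia_blob_radius: float = 12.0
    glia_elongation_cnt: float = 3.0
    soma_radius: float = 5.0
    nucleus_radius: float = 3.0
    psf_sigma: float = 0.5
    background_level: float = 200.0
    signal_level: float = 3000.0
    noise_scale: float = 1.0
    #: paths within this distance (um) of an earlier path are considered
    #: one route: they render as one unresolvable ribbon, so the
    #: measurement-comparable ("merged") truth counts them once
    collapse_radius: float = 2.0

    def __post_init__(self) -> None:
        for name in ("neuron_density_si", "neuron_density_cnt", "mean_process_length"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for name in ("tortuosity", "p_edge_follow", "p_bundle", "cluster_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        for name in ("glia_coverage_si", "glia_coverage_cnt"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ParameterError(f"{name} must lie in [0, 1), got {v}")


@dataclass(frozen=True)
class SurfaceTruth:
    raw_length: float
    merged_length: float
    glial_area: float
    soma_count: int
    cluster_count: int


@dataclass(frozen=True)
class SceneTruth:
    """Exact planted quantities of one FOV, per surface ('si'/'cnt')."""

    fov_index: tuple[int, int]
    surfaces: dict[str, SurfaceTruth]

    def __post_init__(self) -> None:
        for s in self.surfaces.values():
            if s.merged_length > s.raw_length + 1e-6:
                raise ValueError("merged_length may not exceed raw_length")


@dataclass
class FOVImage:
    """One rendered 3-channel tile (uint16, row 0 at the image bottom)."""

    fov_index: tuple[int, int]
    neurons: np.ndarray
    glia: np.ndarray
    nuclei: np.ndarray
    pixel_size: float


# ---------------------------------------------------------------------------
# Edge distance / tangent field
# ---------------------------------------------------------------------------


class _EdgeField:
    """Gridded distance-to-boundary and boundary-tangent lookup.

    Built from a coarse raster of the electrode; gives O(1) per-step
    queries for the neurite walks.
    """

    def __init__(self, layout: ElectrodeLayout, bounds, resolution: float = 1.0):
        from .geometry import rasterize_rectangles

        self.res = resolution
        self.x0, self.y0, x1, y1 = bounds
        ny = max(2, int(math.ceil((y1 - self.y0) / resolution)))
        nx = max(2, int(math.ceil((x1 - self.x0) / resolution)))
        cnt = rasterize_rectangles(
            layout.rectangles, (self.x0, self.y0), (ny, nx), resolution
        )
        # distance to the opposite phase = distance to the boundary
        d_out, idx_out = ndi.distance_transform_edt(~cnt, return_indices=True)
        d_in, idx_in = ndi.distance_transform_edt(cnt, return_indices=True)
        self.dist = np.where(cnt, d_in, d_out).astype(np.float32) * resolution
        self.inside = cnt
        self.nearest_j = np.where(cnt, idx_in[0], idx_out[0]).astype(np.int32)
        self.nearest_i = np.where(cnt, idx_in[1], idx_out[1]).astype(np.int32)
        self.ny, self.nx = ny, nx

    def _index(self, x: float, y: float) -> tuple[int, int]:
        i = min(self.nx - 1, max(0, int((x - self.x0) / self.res)))
        j = min(self.ny - 1, max(0, int((y - self.y0) / self.res)))
        return j, i

    def query(self, x: float, y: float) -> tuple[float, float, float]:
        """(distance to boundary, unit direction to boundary (dx, dy))."""
        j, i = self._index(x, y)
        ex = float(self.nearest_i[j, i]) - i
        ey = float(self.nearest_j[j, i]) - j
        nrm = math.hypot(ex, ey)
        if nrm == 0.0:
            ex, ey, nrm = 1.0, 0.0, 1.0
        return float(self.dist[j, i]), ex / nrm, ey / nrm


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------


@dataclass
class _Blob:
    center: tuple[float, float]
    surface: str
    pieces: list[np.ndarray]  # exterior rings of the surface-clipped polygon(s)


@dataclass
class CultureScene:
    """Fully built synthetic scene: vector truth plus a per-FOV renderer."""

    layout: ElectrodeLayout
    plan: FOVPlan
    params: CultureParams
    polylines: list[np.ndarray]
    is_copy: np.ndarray
    somas: np.ndarray  # (N, 2)
    soma_surface: np.ndarray  # (N,) of 'si'/'cnt'
    cluster_centers: np.ndarray
    cluster_surface: np.ndarray
    blobs: list[_Blob]
    glia_union: dict[str, shapely.Geometry]
    surface_polys: dict[str, shapely.Geometry]
    _line_geoms: list[LineString] = field(default_factory=list, repr=False)
    _line_bounds: np.ndarray | None = field(default=None, repr=False)
    _merged_geoms: list[LineString] = field(default_factory=list, repr=False)
    _merged_bounds: np.ndarray | None = field(default=None, repr=False)

    # -- truth ------------------------------------------------------------

    def _sum_lengths(
        self, geoms: list[LineString], bounds_arr: np.ndarray, region
    ) -> float:
        if not geoms:
            return 0.0
        rx0, ry0, rx1, ry1 = region.bounds
        b = bounds_arr
        hit = ~((b[:, 2] < rx0) | (b[:, 0] > rx1) | (b[:, 3] < ry0) | (b[:, 1] > ry1))
        total = 0.0
        prepared = shapely.prepared.prep(region)
        for k in np.flatnonzero(hit):
            g = geoms[k]
            if prepared.contains(g):
                total += g.length
            else:
                total += g.intersection(region).length
        return total

    def _ensure_geoms(self) -> None:
        if self._line_bounds is None:
            self._line_geoms = [LineString(p) for p in self.polylines]
            self._line_bounds = (
                np.array([g.bounds for g in self._line_geoms])
                if self._line_geoms
                else np.zeros((0, 4))
            )
            merged = merged_polylines(self.polylines, self.params.collapse_radius)
            self._merged_geoms = [LineString(p) for p in merged]
            self._merged_bounds = (
                np.array([g.bounds for g in self._merged_geoms])
                if self._merged_geoms
                else np.zeros((0, 4))
            )

    def _lines_in(self, region: shapely.Geometry) -> tuple[float, float]:
        """(raw, merged) polyline length inside ``region``.

        raw sums every planted centreline; merged counts each route
        once (stretches lying within ``collapse_radius`` of an earlier
        path are collapsed, mirroring what any intensity-based detector
        can resolve).
        """
        self._ensure_geoms()
        raw = self._sum_lengths(self._line_geoms, self._line_bounds, region)
        merged = self._sum_lengths(self._merged_geoms, self._merged_bounds, region)
        return raw, merged

    def truth_for_region(self, bounds) -> dict[str, SurfaceTruth]:
        bx = shapely_box(*bounds)
        out = {}
        for name in ("si", "cnt"):
            region = self.surface_polys[name].intersection(bx)
            if region.is_empty:
                out[name] = SurfaceTruth(0.0, 0.0, 0.0, 0, 0)
                continue
            raw, merged = self._lines_in(region)
            glial = self.glia_union[name].intersection(bx).area
            in_fov = (
                (self.somas[:, 0] >= bounds[0])
                & (self.somas[:, 0] < bounds[2])
                & (self.somas[:, 1] >= bounds[1])
                & (self.somas[:, 1] < bounds[3])
                & (self.soma_surface == name)
            )
            in_cl = (
                (self.cluster_centers[:, 0] >= bounds[0])
                & (self.cluster_centers[:, 0] < bounds[2])
                & (self.cluster_centers[:, 1] >= bounds[1])
                & (self.cluster_centers[:, 1] < bounds[3])
                & (self.cluster_surface == name)
            ) if len(self.cluster_centers) else np.zeros(0, dtype=bool)
            out[name] = SurfaceTruth(
                raw_length=raw,
                merged_length=merged,
                glial_area=float(glial),
                soma_count=int(in_fov.sum()),
                cluster_count=int(in_cl.sum()),
            )
        return out

    def truth_for_fov(self, fov_index, owned: bool = False) -> SceneTruth:
        bounds = (
            self.plan.owned_bounds(fov_index) if owned else self.plan.tile_bounds(fov_index)
        )
        return SceneTruth(fov_index=fov_index, surfaces=self.truth_for_region(bounds))

    def global_truth(self) -> dict[str, SurfaceTruth]:
        return self.truth_for_region(self.plan.domain_bounds)

    # -- rendering --------------------------------------------------------

    def render_fov(self, fov_index) -> FOVImage:
        plan, p = self.plan, self.params
        n = plan.fov_size_px
        res = plan.pixel_size
        ox, oy = plan.tile_origin(fov_index)
        x1, y1 = ox + plan.fov_size_um, oy + plan.fov_size_um

        neurons = np.zeros((n, n), dtype=np.float32)
        glia = np.zeros((n, n), dtype=np.float32)
        nuclei = np.zeros((n, n), dtype=np.float32)

        # neurites: bilinear splat of the walk points (1 px apart)
        for k, pts in enumerate(self.polylines):
            bx0, by0 = pts.min(axis=0)
            bx1, by1 = pts.max(axis=0)
            if bx1 < ox or bx0 > x1 or by1 < oy or by0 > y1:
                continue
            self._splat(neurons, pts, ox, oy, res, amplitude=1.0)
        # the splat deposits ~1 unit per pixel of path; scale to signal
        neurons *= p.signal_level

        from skimage.draw import disk as draw_disk, polygon as draw_polygon

        def um_to_px(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            cols = (xy[..., 0] - ox) / res - 0.5
            rows = (xy[..., 1] - oy) / res - 0.5
            return rows, cols

        for (sx, sy), _surf in zip(self.somas, self.soma_surface):
            if not (ox - 20 <= sx <= x1 + 20 and oy - 20 <= sy <= y1 + 20):
                continue
            rr, cc = draw_disk(
                ((sy - oy) / res - 0.5, (sx - ox) / res - 0.5),
                p.soma_radius / res,
                shape=neurons.shape,
            )
            neurons[rr, cc] = np.maximum(neurons[rr, cc], p.signal_level * 1.5)
            rr, cc = draw_disk(
                ((sy - oy) / res - 0.5, (sx - ox) / res - 0.5),
                p.nucleus_radius / res,
                shape=nuclei.shape,
            )
            nuclei[rr, cc] = p.signal_level

        glia_mask = np.zeros((n, n), dtype=bool)
        margin = 4 * p.glia_blob_radius * max(1.0, p.glia_elongation_cnt)
        for blob in self.blobs:
            bx, by = blob.center
            if not (ox - margin <= bx <= x1 + margin and oy - margin <= by <= y1 + margin):
                continue
            for ring in blob.pieces:
                rows, cols = um_to_px(ring)
                rr, cc = draw_polygon(rows, cols, shape=glia_mask.shape)
                glia_mask[rr, cc] = True
            rr, cc = draw_disk(
                ((by - oy) / res - 0.5, (bx - ox) / res - 0.5),
                p.nucleus_radius / res,
                shape=nuclei.shape,
            )
            nuclei[rr, cc] = p.signal_level
        glia[glia_mask] = p.signal_level

        out = {}
        for ci, (name, img) in enumerate(
            (("neurons", neurons), ("glia", glia), ("nuclei", nuclei))
        ):
            if p.psf_sigma > 0:
                img = ndi.gaussian_filter(img, p.psf_sigma / res)
            img = img + p.background_level
            rng = np.random.default_rng(
                [p.seed % (2**31), 1000 + ci, fov_index[0], fov_index[1]]
            )
            if p.noise_scale > 0:
                img = img + rng.standard_normal(img.shape, dtype=np.float32) * (
                    p.noise_scale * np.sqrt(np.maximum(img, 0.0), dtype=np.float32)
                )
            out[name] = np.clip(img, 0, 65535).astype(np.uint16)
        return FOVImage(
            fov_index=fov_index,
            neurons=out["neurons"],
            glia=out["glia"],
            nuclei=out["nuclei"],
            pixel_size=res,
        )

    @staticmethod
    def _splat(img, pts_um, ox, oy, res, amplitude=1.0):
        n = img.shape[0]
        cols = (pts_um[:, 0] - ox) / res - 0.5
        rows = (pts_um[:, 1] - oy) / res - 0.5
        keep = (cols > -1) & (cols < n) & (rows > -1) & (rows < n)
        if not keep.any():
            return
        cols, rows = cols[keep], rows[keep]
        c0 = np.floor(cols).astype(int)
        r0 = np.floor(rows).astype(int)
        fc = cols - c0
        fr = rows - r0
        for dr, dc, w in (
            (0, 0, (1 - fr) * (1 - fc)),
            (0, 1, (1 - fr) * fc),
            (1, 0, fr * (1 - fc)),
            (1, 1, fr * fc),
        ):
            rr = r0 + dr
            cc = c0 + dc
            ok = (rr >= 0) & (rr < n) & (cc >= 0) & (cc < n)
            np.add.at(img, (rr[ok], cc[ok]), amplitude * w[ok])


def merged_polylines(
    polylines: list[np.ndarray], collapse_radius: float
) -> list[np.ndarray]:
    """Collapse co-located routes: the measurement-comparable centrelines.

    Processing paths in order, every point lying within
    ``collapse_radius`` of a point of an *earlier* path is dropped, and
    the surviving runs of consecutive points form the merged set.
    Exact duplicates (bundles) vanish entirely; partial co-travel is
    collapsed only over the shared stretch.
    """
    if collapse_radius <= 0:
        return [p.copy() for p in polylines]
    cell = collapse_radius
    occupied: dict[tuple[int, int], list[np.ndarray]] = {}
    out: list[np.ndarray] = []
    r2 = collapse_radius**2
    for pts in polylines:
        novel = np.ones(len(pts), dtype=bool)
        for i, (x, y) in enumerate(pts):
            cx, cy = int(math.floor(x / cell)), int(math.floor(y / cell))
            found = False
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    bucket = occupied.get((cx + dx, cy + dy))
                    if bucket is None:
                        continue
                    for arr in bucket:
                        d = arr - (x, y)
                        if (d[:, 0] ** 2 + d[:, 1] ** 2 <= r2).any():
                            found = True
                            break
                    if found:
                        break
                if found:
                    break
            novel[i] = not found
        # keep surviving runs of at least two points
        runs = np.flatnonzero(np.diff(np.concatenate([[0], novel.view(np.int8), [0]])))
        for s, e in zip(runs[::2], runs[1::2]):
            if e - s >= 2:
                out.append(pts[s:e].copy())
        # register this path's points for subsequent paths
        keys = np.stack(
            [np.floor(pts[:, 0] / cell), np.floor(pts[:, 1] / cell)], axis=1
        ).astype(int)
        order = np.lexsort((keys[:, 1], keys[:, 0]))
        sk = keys[order]
        sp = pts[order]
        boundaries = np.flatnonzero(
            np.any(np.diff(sk, axis=0) != 0, axis=1)
        )
        startstops = np.concatenate([[0], boundaries + 1, [len(sk)]])
        for a, b in zip(startstops[:-1], startstops[1:]):
            if b <= a:
                continue
            key = (int(sk[a, 0]), int(sk[a, 1]))
            occupied.setdefault(key, []).append(sp[a:b])
    return out


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def _sample_in_polygon(poly, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points in a shapely polygon by rejection sampling."""
    if n == 0:
        return np.zeros((0, 2))
    x0, y0, x1, y1 = poly.bounds
    pts = []
    need = n
    for _ in range(1000):
        cand = rng.uniform((x0, y0), (x1, y1), size=(max(32, 4 * need), 2))
        ok = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        pts.append(cand[ok])
        got = sum(len(a) for a in pts)
        if got >= n:
            break
        need = n - got
    out = np.concatenate(pts)[:n]
    if len(out) < n:
        raise RuntimeError("polygon rejection sampling failed to converge")
    return out


class _SomaGrid:
    """Occupancy raster of soma disks; neurite walks steer around them
    so that no planted centreline hides underneath a cell body."""

    def __init__(self, somas: np.ndarray, radius: float, bounds, resolution: float = 1.0):
        self.res = resolution
        self.x0, self.y0, x1, y1 = bounds
        self.ny = max(2, int(math.ceil((y1 - self.y0) / resolution)))
        self.nx = max(2, int(math.ceil((x1 - self.x0) / resolution)))
        self.grid = np.zeros((self.ny, self.nx), dtype=bool)
        r_px = radius / resolution
        for sx, sy in somas:
            ci = (sx - self.x0) / resolution
            cj = (sy - self.y0) / resolution
            j0, j1 = max(0, int(cj - r_px) - 1), min(self.ny, int(cj + r_px) + 2)
            i0, i1 = max(0, int(ci - r_px) - 1), min(self.nx, int(ci + r_px) + 2)
            if j1 <= j0 or i1 <= i0:
                continue
            jj, ii = np.mgrid[j0:j1, i0:i1]
            self.grid[j0:j1, i0:i1] |= (jj - cj) ** 2 + (ii - ci) ** 2 <= r_px**2

    def occupied(self, x: float, y: float) -> bool:
        i = min(self.nx - 1, max(0, int((x - self.x0) / self.res)))
        j = min(self.ny - 1, max(0, int((y - self.y0) / self.res)))
        return bool(self.grid[j, i])


def _grow_walk(
    start: np.ndarray,
    n_steps: int,
    step: float,
    turn_sigma: float,
    field: _EdgeField,
    p_follow: float,
    d_edge: float,
    bounds,
    rng: np.random.Generator,
    soma_grid: "_SomaGrid | None" = None,
) -> np.ndarray:
    """Persistent random walk with electrode-edge following."""
    x0, y0, x1, y1 = bounds
    theta = rng.uniform(0, 2 * math.pi)
    turns = rng.normal(0.0, turn_sigma, n_steps)
    follows = rng.random(n_steps) < p_follow
    pts = np.empty((n_steps + 1, 2))
    pts[0] = start
    x, y = float(start[0]), float(start[1])
    dx, dy = math.cos(theta), math.sin(theta)
    push = 0.8  # um: keep followers slightly off the exact boundary
    for i in range(n_steps):
        d, ex, ey = field.query(x, y)
        if d < d_edge and follows[i]:
            # boundary tangent, sign matched to the current heading
            tx, ty = -ey, ex
            if tx * dx + ty * dy < 0:
                tx, ty = -tx, -ty
            if d < push:
                # ease away from the boundary to keep surface attribution clean
                tx -= 0.35 * ex
                ty -= 0.35 * ey
                nrm = math.hypot(tx, ty)
                tx, ty = tx / nrm, ty / nrm
            # filopodial wiggle: followers drift laterally so that two
            # walks on the same edge do not stay exactly co-located
            jit = 0.1 * turns[i] / max(turn_sigma, 1e-9)
            cos_j, sin_j = math.cos(jit), math.sin(jit)
            dx, dy = tx * cos_j - ty * sin_j, tx * sin_j + ty * cos_j
        else:
            cos_t, sin_t = math.cos(turns[i]), math.sin(turns[i])
            dx, dy = dx * cos_t - dy * sin_t, dx * sin_t + dy * cos_t
        nx_, ny_ = x + dx * step, y + dy * step
        if soma_grid is not None and soma_grid.occupied(nx_, ny_):
            # steer around cell bodies rather than growing underneath them
            sign = 1.0 if turns[i] >= 0 else -1.0
            for ang in (0.785, -0.785, 1.571, -1.571, 2.356, -2.356, 3.142):
                a = sign * ang
                ca, sa = math.cos(a), math.sin(a)
                tdx, tdy = dx * ca - dy * sa, dx * sa + dy * ca
                tx_, ty_ = x + tdx * step, y + tdy * step
                if not soma_grid.occupied(tx_, ty_):
                    dx, dy, nx_, ny_ = tdx, tdy, tx_, ty_
                    break
            else:
                return pts[: i + 1].copy()
        if nx_ < x0 or nx_ > x1 or ny_ < y0 or ny_ > y1:
            # the scene border is open: the neurite leaves the field
            return pts[: i + 1].copy()
        x, y = nx_, ny_
        pts[i + 1] = (x, y)
    return pts


def _make_blob(
    center,
    mean_radius: float,
    elongation: float,
    axis_angle: float,
    rng: np.random.Generator,
    n_vertices: int = 48,
) -> Polygon:
    """Radially-perturbed ellipse: a smooth organic blob."""
    R = mean_radius * rng.lognormal(0.0, 0.25)
    a = R * math.sqrt(elongation)
    b = R / math.sqrt(elongation)
    phi = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    pert = np.ones_like(phi)
    for h in (2, 3, 4):
        pert += 0.08 * rng.normal() * np.cos(h * phi + rng.uniform(0, 2 * math.pi))
    ex = a * np.cos(phi) * pert
    ey = b * np.sin(phi) * pert
    ca, sa = math.cos(axis_angle), math.sin(axis_angle)
    xs = center[0] + ex * ca - ey * sa
    ys = center[1] + ex * sa + ey * ca
    poly = Polygon(np.column_stack([xs, ys]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def build_scene(
    layout: ElectrodeLayout, plan: FOVPlan, params: CultureParams
) -> CultureScene:
    """Build the full deterministic vector scene for a layout/plan."""
    p = params
    bounds = plan.domain_bounds
    domain = shapely_box(*bounds)
    electrode = unary_union(
        [shapely_box(*r) for r in layout.rectangles]
    ).intersection(domain)
    surface_polys = {"cnt": electrode, "si": domain.difference(electrode)}
    field_ = _EdgeField(layout, bounds)
    step = plan.pixel_size
    turn_sigma = (1.0 - p.tortuosity) * 0.5

    seed = int(p.seed) % (2**31)
    rng_somas = np.random.default_rng([seed, 1])
    rng_walks = np.random.default_rng([seed, 2])
    rng_glia = np.random.default_rng([seed, 3])

    # --- somas (clustered + single), per surface ---
    somas: list[np.ndarray] = []
    soma_surface: list[str] = []
    cl_centers: list[np.ndarray] = []
    cl_surface: list[str] = []
    for name, density in (("si", p.neuron_density_si), ("cnt", p.neuron_density_cnt)):
        poly = surface_polys[name]
        if poly.is_empty or density <= 0:
            continue
        n = rng_somas.poisson(density * poly.area / 1e6)
        if n == 0:
            continue
        n_clustered = rng_somas.binomial(n, p.cluster_rate)
        n_single = n - n_clustered
        pts = _sample_in_polygon(poly, n_single, rng_somas)
        for xy in pts:
            somas.append(xy)
            soma_surface.append(name)
        placed = 0
        while placed < n_clustered:
            size = min(
                n_clustered - placed,
                1 + rng_somas.poisson(max(p.cluster_size_mean - 1.0, 0.0)),
            )
            center = _sample_in_polygon(poly, 1, rng_somas)[0]
            cl_centers.append(center)
            cl_surface.append(name)
            members = center + rng_somas.normal(0, 1.2 * p.soma_radius, (size, 2))
            for xy in members:
                xy[0] = min(max(xy[0], bounds[0]), bounds[2])
                xy[1] = min(max(xy[1], bounds[1]), bounds[3])
                somas.append(xy)
                soma_surface.append(name)
            placed += size
    somas_arr = np.asarray(somas) if somas else np.zeros((0, 2))
    soma_surf_arr = np.asarray(soma_surface) if somas else np.zeros(0, dtype="<U3")

    # --- neurite walks ---
    polylines: list[np.ndarray] = []
    is_copy: list[bool] = []
    lo, hi = p.processes_per_soma
    soma_grid = (
        _SomaGrid(somas_arr, p.soma_radius, bounds) if len(somas_arr) else None
    )
    for xy in somas_arr:
        n_proc = int(rng_walks.integers(lo, hi + 1))
        for _ in range(n_proc):
            if polylines and rng_walks.random() < p.p_bundle:
                k = int(rng_walks.integers(0, len(polylines)))
                ref = polylines[k]
                ang = rng_walks.uniform(0, 2 * math.pi)
                off = rng_walks.uniform(0.1, 0.5) * step
                dup = ref + off * np.array([math.cos(ang), math.sin(ang)])
                polylines.append(dup)
                is_copy.append(True)
                continue
            target = rng_walks.gamma(2.0, p.mean_process_length / 2.0)
            n_steps = max(2, int(round(target / step)))
            theta0 = rng_walks.uniform(0, 2 * math.pi)
            direction = np.array([math.cos(theta0), math.sin(theta0)])
            # launch just outside the soma (and outside neighbouring
            # somas in a cluster) so the centreline is observable
            start = None
            for radius in np.arange(p.soma_radius + 1.0, 4.0 * p.soma_radius, 1.0):
                cand = xy + radius * direction
                cand[0] = min(max(cand[0], bounds[0]), bounds[2])
                cand[1] = min(max(cand[1], bounds[1]), bounds[3])
                if soma_grid is None or not soma_grid.occupied(cand[0], cand[1]):
                    start = cand
                    break
            if start is None:
                continue
            pts = _grow_walk(
                start,
                n_steps,
                step,
                turn_sigma,
                field_,
                p.p_edge_follow,
                p.d_edge,
                bounds,
                rng_walks,
                soma_grid,
            )
            if len(pts) < 2:
                continue
            polylines.append(pts)
            is_copy.append(False)

    # --- glia ---
    blobs: list[_Blob] = []
    glia_union: dict[str, shapely.Geometry] = {}
    for name, target in (("si", p.glia_coverage_si), ("cnt", p.glia_coverage_cnt)):
        poly = surface_polys[name]
        union = shapely.Polygon()
        if poly.is_empty or target <= 0:
            glia_union[name] = union
            continue
        elong_base = p.glia_elongation_cnt if name == "cnt" else 1.15
        blob_area = math.pi * p.glia_blob_radius**2
        guard = 0
        while union.area < target * poly.area and guard < 10_000:
            deficit = target * poly.area - union.area
            cov = union.area / poly.area
            batch = max(1, int(deficit / (blob_area * max(1e-3, 1.0 - cov)) * 0.6))
            radius = p.glia_blob_radius
            if deficit < 8 * blob_area:
                # fine-grained final approach: smaller blobs, one at a
                # time, so the target is not overshot by a full cell
                batch = 1
                radius = min(radius, max(3.0, math.sqrt(deficit / math.pi)))
            centers = _sample_in_polygon(poly, batch, rng_glia)
            new = []
            for c in centers:
                if name == "cnt":
                    _, ex, ey = field_.query(c[0], c[1])
                    axis = math.atan2(ex, -ey)  # along-boundary direction
                else:
                    axis = rng_glia.uniform(0, 2 * math.pi)
                blob = _make_blob(c, radius, elong_base, axis, rng_glia)
                clipped = blob.intersection(poly)
                if clipped.is_empty:
                    continue
                pieces = []
                geoms = (
                    clipped.geoms if clipped.geom_type == "MultiPolygon" else [clipped]
                )
                for g in geoms:
                    if g.geom_type == "Polygon" and g.area > 0:
                        pieces.append(np.asarray(g.exterior.coords))
                if pieces:
                    blobs.append(_Blob(center=(c[0], c[1]), surface=name, pieces=pieces))
                    new.append(clipped)
            if new:
                union = unary_union([union, *new])
            guard += 1
        glia_union[name] = union

    return CultureScene(
        layout=layout,
        plan=plan,
        params=params,
        polylines=polylines,
        is_copy=np.asarray(is_copy, dtype=bool),
        somas=somas_arr,
        soma_surface=soma_surf_arr,
        cluster_centers=np.asarray(cl_centers) if cl_centers else np.zeros((0, 2)),
        cluster_surface=(
            np.asarray(cl_surface) if cl_surface else np.zeros(0, dtype="<U3")
        ),
        blobs=blobs,
        glia_union=glia_union,
        surface_polys=surface_polys,
    )


def default_study_layout() -> ElectrodeLayout:
    """Reduced grid used for the synthetic recovery studies.

    A 9x9-chamber grid, 1150 um overall width and 20 um walls: both
    surfaces are well represented, and the 2x2 FOV plan it induces at
    the default tile size keeps a multi-seed study tractable.
    """
    from .geometry import GridSpec, build_grid

    return build_grid(GridSpec(W=1150.0, n=9, W_CNT=20.0))


def simulate_culture(
    layout: ElectrodeLayout, plan: FOVPlan, params: CultureParams
) -> Iterator[tuple[FOVImage, SceneTruth]]:
    """Stream the scene one FOV at a time (deterministic given the seed)."""
    scene = build_scene(layout, plan, params)
    for fov_index in plan.iter_indices():
        yield scene.render_fov(fov_index), scene.truth_for_fov(fov_index)


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------

_CHANNELS = ("neurons", "glia", "nuclei")
_TRUTH_COLUMNS = (
    "fov_row",
    "fov_col",
    "surface",
    "raw_length_um",
    "merged_length_um",
    "glial_area_um2",
    "soma_count",
    "cluster_count",
)


class SceneIOError(RuntimeError):
    pass


def write_scene(
    directory: str | Path,
    fovs: list[tuple[FOVImage, SceneTruth]],
    params: CultureParams,
) -> Path:
    """Write a scene: one 16-bit TIFF per channel per FOV, a truth CSV
    and a params JSON carrying the truth-file hash."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for img, truth in fovs:
        r, c = img.fov_index
        for ch in _CHANNELS:
            tifffile.imwrite(
                directory / f"fov_r{r}_c{c}_{ch}.tif", getattr(img, ch)
            )
        for surface, t in sorted(truth.surfaces.items()):
            rows.append(
                (
                    r,
                    c,
                    surface,
                    repr(t.raw_length),
                    repr(t.merged_length),
                    repr(t.glial_area),
                    t.soma_count,
                    t.cluster_count,
                )
            )
    truth_path = directory / "truth.csv"
    lines = [",".join(_TRUTH_COLUMNS)]
    lines += [",".join(str(v) for v in row) for row in rows]
    truth_bytes = ("\n".join(lines) + "\n").encode()
    truth_path.write_bytes(truth_bytes)
    meta = {
        "params": _params_to_dict(params),
        "pixel_size": fovs[0][0].pixel_size if fovs else None,
        "truth_sha256": hashlib.sha256(truth_bytes).hexdigest(),
    }
    (directory / "params.json").write_text(json.dumps(meta, indent=1))
    return directory


def _params_to_dict(params: CultureParams) -> dict:
    d = asdict(params)
    d["processes_per_soma"] = list(d["processes_per_soma"])
    return d


def params_from_dict(d: dict) -> CultureParams:
    d = dict(d)
    d["processes_per_soma"] = tuple(d["processes_per_soma"])
    return CultureParams(**d)


def read_scene(directory: str | Path) -> tuple[list[tuple[FOVImage, SceneTruth]], CultureParams]:
    """Round-trip loader for :func:`write_scene`; verifies the truth hash."""
    import tifffile

    directory = Path(directory)
    meta = json.loads((directory / "params.json").read_text())
    truth_bytes = (directory / "truth.csv").read_bytes()
    if hashlib.sha256(truth_bytes).hexdigest() != meta["truth_sha256"]:
        raise SceneIOError("truth.csv does not match the recorded hash")
    params = params_from_dict(meta["params"])
    lines = truth_bytes.decode().strip().split("\n")
    header = lines[0].split(",")
    if tuple(header) != _TRUTH_COLUMNS:
        raise SceneIOError(f"unexpected truth columns: {header}")
    per_fov: dict[tuple[int, int], dict[str, SurfaceTruth]] = {}
    for line in lines[1:]:
        vals = line.split(",")
        rec = dict(zip(header, vals))
        key = (int(rec["fov_row"]), int(rec["fov_col"]))
        per_fov.setdefault(key, {})[rec["surface"]] = SurfaceTruth(
            raw_length=float(rec["raw_length_um"]),
            merged_length=float(rec["merged_length_um"]),
            glial_area=float(rec["glial_area_um2"]),
            soma_count=int(rec["soma_count"]),
            cluster_count=int(rec["cluster_count"]),
        )
    out = []
    for key in sorted(per_fov):
        r, c = key
        channels = {}
        for ch in _CHANNELS:
            path = directory / f"fov_r{r}_c{c}_{ch}.tif"
            if not path.exists():
                raise SceneIOError(f"missing channel file {path.name}")
            channels[ch] = tifffile.imread(path)
        img = FOVImage(
            fov_index=key,
            neurons=channels["neurons"],
            glia=channels["glia"],
            nuclei=channels["nuclei"],
            pixel_size=float(meta["pixel_size"]),
        )
        out.append((img, SceneTruth(fov_index=key, surfaces=per_fov[key])))
    return out, params
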