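"""Electrode layout construction and exact geometric measurement.

Two vertically-aligned carbon nanotube (VACNT) electrode families are
modelled as unions of axis-aligned rectangles on a SiO2 substrate:

* an 'open' H-tree fractal, built from ``K = 2m`` perpendicular segment
  generations whose lengths shrink by ``r = 2**(-1/D)`` per generation
  (``D`` is the fractal dimension, ``m`` the number of repeating levels),
  each branch drawn as a rectangle of width ``W_CNT``;
* a 'closed' grid of ``(n+1) + (n+1)`` wall strips of width ``W_CNT``
  enclosing ``n x n`` open square chambers.

All derived quantities (edge length ``E``, material area ``A_CNT``, gap
area ``A_Si``, bounding area, separations) are computed exactly with a
coordinate-compression sweep over the rectilinear arrangement, and the
gap topology (connectedness, proximity, corridor widths) by rasterized
morphology.

Units are micrometres throughout; coordinates are y-up with the layout
centred on the origin.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy import ndimage as ndi


class ParameterError(ValueError):
    """An electrode design parameter violates its constraints."""


class GeometryIntegrityError(RuntimeError):
    """The constructed layout violates a structural invariant."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HTreeSpec:
    """Design parameters of the fractal (H-tree) electrode.

    Parameters
    ----------
    D:
        Fractal dimension; sets the per-generation length ratio
        ``r = 2**(-1/D)``.  Must lie in ``(0, 2]`` (1..2 for physical
        designs; D=2 is space filling).
    m:
        Number of repeating levels.  Each level contributes one
        horizontal and one vertical segment generation, so the tree has
        ``K = 2m`` generations and ``2**K - 1`` branches.
    W_CNT:
        Branch width (um).
    W:
        Overall electrode width (um): centreline horizontal extent plus
        one branch width contributed by the two terminal vertical
        rectangles.
    W_Si_min_nominal:
        Nominal smallest gap width (um); informational only.
    """

    D: float
    m: int
    W_CNT: float
    W: float
    W_Si_min_nominal: float | None = None

    def __post_init__(self) -> None:
        if not (isinstance(self.m, (int, np.integer)) and self.m >= 1):
            raise ParameterError(f"m must be a positive integer, got {self.m!r}")
        if not (0 < self.D <= 2):
            raise ParameterError(f"D must lie in (0, 2], got {self.D}")
        if not (0 < self.W_CNT < self.W):
            raise ParameterError(
                f"need 0 < W_CNT < W, got W_CNT={self.W_CNT}, W={self.W}"
            )

    @property
    def r(self) -> float:
        """Per-generation length ratio ``2**(-1/D)``."""
        return 2.0 ** (-1.0 / self.D)

    @property
    def K(self) -> int:
        """Number of segment generations ``2m``."""
        return 2 * self.m

    @property
    def L1(self) -> float:
        """Seed branch length solving the overall-width calibration.

        The horizontal centreline half-extent is the geometric sum
        ``(L1/2) * (1 - r**(2m)) / (1 - r**2)`` over the m horizontal
        generations; the overall width adds one branch width:
        ``W = 2*half + W_CNT``.
        """
        r2 = self.r**2
        s = (1.0 - r2**self.m) / (1.0 - r2)
        return (self.W - self.W_CNT) / s

    @property
    def total_centerline_length(self) -> float:
        """Closed form ``L1 * ((2r)**K - 1) / (2r - 1)``."""
        q = 2.0 * self.r
        return self.L1 * (q**self.K - 1.0) / (q - 1.0)


@dataclass(frozen=True)
class GridSpec:
    """Design parameters of the grid electrode.

    ``W`` is the overall width of the square electrode, ``n`` the number
    of chambers per row and ``W_CNT`` the wall width.  The chamber side
    is derived: ``c = (W - (n+1)*W_CNT) / n``.
    """

    W: float
    n: int
    W_CNT: float

    def __post_init__(self) -> None:
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ParameterError(f"n must be a positive integer, got {self.n!r}")
        if self.W_CNT <= 0:
            raise ParameterError("W_CNT must be positive")
        if self.W <= (self.n + 1) * self.W_CNT:
            raise ParameterError(
                f"W must exceed (n+1)*W_CNT = {(self.n + 1) * self.W_CNT}, got {self.W}"
            )

    @property
    def chamber_side(self) -> float:
        return (self.W - (self.n + 1) * self.W_CNT) / self.n


#: Published design of the fractal electrode (D=2, m=5, 20 um branches,
#: 6.26 mm overall width, nominal 60 um smallest gap).
PAPER_HTREE = HTreeSpec(D=2.0, m=5, W_CNT=20.0, W=6.26e3, W_Si_min_nominal=60.0)

#: Published design of the grid electrode (3.51 mm wide, 43 chambers per
#: row, 20 um walls; chamber side ~61.2 um, printed nominally as 60).
PAPER_GRID = GridSpec(W=3.51e3, n=43, W_CNT=20.0)


# ---------------------------------------------------------------------------
# Layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Segment:
    """One H-tree centreline segment."""

    orientation: Literal["horizontal", "vertical"]
    center: tuple[float, float]
    length: float
    generation: int

    @property
    def tips(self) -> tuple[tuple[float, float], tuple[float, float]]:
        cx, cy = self.center
        h = self.length / 2.0
        if self.orientation == "horizontal":
            return (cx - h, cy), (cx + h, cy)
        return (cx, cy - h), (cx, cy + h)


@dataclass(frozen=True)
class ElectrodeLayout:
    """Set of axis-aligned rectangles forming one electrode.

    ``rectangles`` is an ``(N, 4)`` float array of ``(x0, y0, x1, y1)``
    in um; ``generations`` tags each rectangle with its H-tree
    generation (0 for grid walls).  ``bounds`` is the tight bounding box
    of the material.
    """

    kind: Literal["htree", "grid"]
    rectangles: np.ndarray
    generations: np.ndarray
    spec: HTreeSpec | GridSpec
    segments: tuple[Segment, ...] = field(default=(), repr=False)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        r = self.rectangles
        return (
            float(r[:, 0].min()),
            float(r[:, 1].min()),
            float(r[:, 2].max()),
            float(r[:, 3].max()),
        )

    @property
    def n_rectangles(self) -> int:
        return int(self.rectangles.shape[0])

    def scaled(self, s: float) -> "ElectrodeLayout":
        """Layout with all coordinates multiplied by ``s`` (spec kept)."""
        if s <= 0:
            raise ParameterError("scale factor must be positive")
        return ElectrodeLayout(
            kind=self.kind,
            rectangles=self.rectangles * s,
            generations=self.generations.copy(),
            spec=self.spec,
            segments=self.segments,
        )


def build_htree(spec: HTreeSpec) -> ElectrodeLayout:
    """Construct the H-tree layout.

    The seed is a single horizontal segment of length ``spec.L1``
    centred at the origin; generation ``k`` holds ``2**(k-1)`` segments
    of length ``L1 * r**(k-1)``, each perpendicular to its parent and
    centred on one of the parent's tips.  Every segment becomes a
    rectangle of width ``W_CNT`` centred on its centreline.
    """
    r = spec.r
    L1 = spec.L1
    segments: list[Segment] = [Segment("horizontal", (0.0, 0.0), L1, 1)]
    frontier = [segments[0]]
    for k in range(2, spec.K + 1):
        length = L1 * r ** (k - 1)
        orient = "horizontal" if k % 2 == 1 else "vertical"
        nxt: list[Segment] = []
        for parent in frontier:
            for tip in parent.tips:
                nxt.append(Segment(orient, tip, length, k))
        segments.extend(nxt)
        frontier = nxt

    half_w = spec.W_CNT / 2.0
    rects = np.empty((len(segments), 4), dtype=float)
    gens = np.empty(len(segments), dtype=int)
    for i, seg in enumerate(segments):
        cx, cy = seg.center
        h = seg.length / 2.0
        if seg.orientation == "horizontal":
            rects[i] = (cx - h, cy - half_w, cx + h, cy + half_w)
        else:
            rects[i] = (cx - half_w, cy - h, cx + half_w, cy + h)
        gens[i] = seg.generation

    layout = ElectrodeLayout(
        kind="htree",
        rectangles=rects,
        generations=gens,
        spec=spec,
        segments=tuple(segments),
    )
    expected = 2**spec.K - 1
    if layout.n_rectangles != expected:
        raise GeometryIntegrityError(
            f"expected {expected} rectangles, built {layout.n_rectangles}"
        )
    return layout


def build_grid(spec: GridSpec) -> ElectrodeLayout:
    """Construct the grid layout: (n+1)+(n+1) wall strips on a W x W square."""
    c = spec.chamber_side
    pitch = c + spec.W_CNT
    half = spec.W / 2.0
    rects = []
    for i in range(spec.n + 1):
        lo = -half + i * pitch
        rects.append((-half, lo, half, lo + spec.W_CNT))  # horizontal wall
    for j in range(spec.n + 1):
        lo = -half + j * pitch
        rects.append((lo, -half, lo + spec.W_CNT, half))  # vertical wall
    arr = np.asarray(rects, dtype=float)
    return ElectrodeLayout(
        kind="grid",
        rectangles=arr,
        generations=np.zeros(len(rects), dtype=int),
        spec=spec,
    )


def build_layout(spec: HTreeSpec | GridSpec) -> ElectrodeLayout:
    if isinstance(spec, HTreeSpec):
        return build_htree(spec)
    if isinstance(spec, GridSpec):
        return build_grid(spec)
    raise ParameterError(f"unknown spec type {type(spec).__name__}")


# ---------------------------------------------------------------------------
# Exact union measurement (coordinate-compression sweep)
# ---------------------------------------------------------------------------


def union_area_perimeter(rectangles: np.ndarray) -> tuple[float, float]:
    """Exact area and perimeter of a union of axis-aligned rectangles.

    Coordinates are compressed to the sorted unique rectangle edges; each
    elementary cell is either fully covered or fully empty, so the union
    area is a sum of covered cell areas and the perimeter a sum of
    covered/uncovered cell interfaces (including the domain border).
    """
    rects = np.asarray(rectangles, dtype=float)
    if rects.size == 0:
        return 0.0, 0.0
    xs = np.unique(np.concatenate([rects[:, 0], rects[:, 2]]))
    ys = np.unique(np.concatenate([rects[:, 1], rects[:, 3]]))
    nx, ny = len(xs) - 1, len(ys) - 1
    covered = np.zeros((nx, ny), dtype=bool)
    i0 = np.searchsorted(xs, rects[:, 0])
    i1 = np.searchsorted(xs, rects[:, 2])
    j0 = np.searchsorted(ys, rects[:, 1])
    j1 = np.searchsorted(ys, rects[:, 3])
    for a, b, c, d in zip(i0, i1, j0, j1):
        covered[a:b, c:d] = True
    dx = np.diff(xs)
    dy = np.diff(ys)
    area = float(dx @ covered @ dy)
    # vertical interfaces between x-adjacent cells (length = cell height)
    vert = np.zeros((nx + 1, ny), dtype=bool)
    vert[0, :] = covered[0, :]
    vert[-1, :] = covered[-1, :]
    vert[1:-1, :] = covered[1:, :] ^ covered[:-1, :]
    horiz = np.zeros((nx, ny + 1), dtype=bool)
    horiz[:, 0] = covered[:, 0]
    horiz[:, -1] = covered[:, -1]
    horiz[:, 1:-1] = covered[:, 1:] ^ covered[:, :-1]
    perimeter = float(vert.sum(axis=0) @ dy + dx @ horiz.sum(axis=1))
    return area, perimeter


def htree_analytic_area_perimeter(spec: HTreeSpec) -> tuple[float, float]:
    """Junction-overlap closed forms for the H-tree union.

    Each of the ``2**K - 2`` parent-child junctions overlaps by a
    ``W_CNT x W_CNT/2`` rectangle (child centred on the parent tip), so
    ``A = W_CNT*L_total - (W_CNT^2/2)*N_j`` and
    ``E = 2*L_total + 2*W_CNT*N_seg - 3*W_CNT*N_j``.
    """
    n_seg = 2**spec.K - 1
    n_junction = n_seg - 1
    l_total = spec.total_centerline_length
    area = spec.W_CNT * l_total - (spec.W_CNT**2 / 2.0) * n_junction
    perim = 2.0 * l_total + 2.0 * spec.W_CNT * n_seg - 3.0 * spec.W_CNT * n_junction
    return area, perim


def grid_analytic_area_perimeter(spec: GridSpec) -> tuple[float, float]:
    """Chamber closed forms: ``A = W^2 - (W-(n+1)Wc)^2``; ``E = 4n^2 c + 4W``."""
    open_side = spec.W - (spec.n + 1) * spec.W_CNT
    area = spec.W**2 - open_side**2
    perim = 4.0 * spec.n**2 * spec.chamber_side + 4.0 * spec.W
    return area, perim


# ---------------------------------------------------------------------------
# Rasterization helper (shared with the mask module)
# ---------------------------------------------------------------------------


def rasterize_rectangles(
    rectangles: np.ndarray,
    origin: tuple[float, float],
    shape: tuple[int, int],
    resolution: float,
) -> np.ndarray:
    """Boolean raster of the rectangle union on a pixel-centre grid.

    A pixel (row j from the bottom, column i) has centre
    ``origin + ((i+0.5)*res, (j+0.5)*res)`` and is set iff the centre
    lies in some rectangle under the half-open rule ``x0 <= x < x1``
    (lower-left inclusive, upper-right exclusive), which prevents
    double-counting at rectangle seams.  Returned array is indexed
    ``[row, col]`` with row 0 at the *bottom* (y-up).
    """
    ny, nx = shape
    out = np.zeros((ny, nx), dtype=bool)
    ox, oy = origin
    rects = np.asarray(rectangles, dtype=float)
    for x0, y0, x1, y1 in rects:
        i0 = max(0, math.ceil((x0 - ox) / resolution - 0.5))
        i1 = min(nx, math.ceil((x1 - ox) / resolution - 0.5))
        j0 = max(0, math.ceil((y0 - oy) / resolution - 0.5))
        j1 = min(ny, math.ceil((y1 - oy) / resolution - 0.5))
        if i1 > i0 and j1 > j0:
            out[j0:j1, i0:i1] = True
    return out


def ideal_bounds(layout: ElectrodeLayout) -> tuple[float, float, float, float]:
    """Idealized bounding box (the convention behind ``A_bounding``).

    ``W x W/sqrt(2)`` centred on the origin for the H-tree (slightly
    taller than the tight box, leaving a thin gap margin above and
    below the terminal branches), ``W x W`` for the grid (identical to
    the tight box: the outer walls close the square).
    """
    w = layout.spec.W
    if layout.kind == "htree":
        h = w / math.sqrt(2.0)
        return (-w / 2, -h / 2, w / 2, h / 2)
    return (-w / 2, -w / 2, w / 2, w / 2)


def rasterize_layout(
    layout: ElectrodeLayout,
    resolution: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize the whole layout over its (tight) bounding box."""
    x0, y0, x1, y1 = bounds if bounds is not None else layout.bounds
    nx = int(round((x1 - x0) / resolution))
    ny = int(round((y1 - y0) / resolution))
    mask = rasterize_rectangles(layout.rectangles, (x0, y0), (ny, nx), resolution)
    return mask, (x0, y0)


# ---------------------------------------------------------------------------
# Gap statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GapStats:
    n_gap_components: int
    largest_gap_fraction: float
    mean_gap_distance: float
    W_Si_min_measured: float | None
    W_Si_max_measured: float | None
    resolution: float


_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)


def _prune_skeleton_spurs(skeleton: np.ndarray, n_iter: int) -> np.ndarray:
    """Remove endpoint pixels ``n_iter`` times (kills spurs shorter than
    ``n_iter`` pixels of axis length; interior corridor axes survive
    because their ends terminate at junctions, which are never endpoints
    for longer than the spur length)."""
    sk = skeleton.copy()
    kernel = np.ones((3, 3), dtype=int)
    for _ in range(n_iter):
        neigh = ndi.convolve(sk.astype(int), kernel, mode="constant") - sk
        endpoints = sk & (neigh <= 1)
        if not endpoints.any():
            break
        sk &= ~endpoints
    return sk


def gap_metrics(
    layout: ElectrodeLayout,
    resolution: float = 1.0,
    compute_corridors: bool = True,
) -> GapStats:
    """Rasterized gap topology and proximity statistics.

    The gap is the complement of the electrode within the idealized
    bounding box (see :func:`ideal_bounds`).  Connected components use
    4-connectivity; the Euclidean distance transform of gap pixels
    gives the mean distance to the nearest electrode pixel; corridor
    widths are twice the distance sampled on the gap medial axis, after
    pruning axis spurs shorter than ``W_CNT`` (corner artefacts).
    """
    w_cnt = layout.spec.W_CNT
    if resolution > w_cnt / 4.0:
        raise ParameterError(
            f"resolution {resolution} too coarse for W_CNT={w_cnt} (need <= W_CNT/4)"
        )
    # pad the box by a thin gap ring: the substrate physically extends
    # beyond the pattern, so gap regions that touch the box boundary are
    # connected to each other outside it.  Components that exist only in
    # the pad (e.g. the ring around a grid's outer walls) do not count.
    pad = 3
    x0, y0, x1, y1 = ideal_bounds(layout)
    p = pad * resolution
    cnt, _ = rasterize_layout(
        layout, resolution, bounds=(x0 - p, y0 - p, x1 + p, y1 + p)
    )
    gap = ~cnt
    inside = np.zeros_like(gap)
    inside[pad:-pad, pad:-pad] = True
    n_gap = int((gap & inside).sum())
    if n_gap == 0:
        raise GeometryIntegrityError("layout has no gap pixels at this resolution")
    labels, _ = ndi.label(gap, structure=_FOUR_CONN)
    sizes_inside = np.bincount(labels[inside].ravel(), minlength=labels.max() + 1)[1:]
    n_comp = int((sizes_inside > 0).sum())
    largest_fraction = float(sizes_inside.max() / n_gap)
    dist = ndi.distance_transform_edt(gap) * resolution
    mean_gap_distance = float(dist[gap & inside].mean())
    w_min = w_max = None
    if compute_corridors:
        from skimage.morphology import medial_axis

        axis = medial_axis(gap) & inside
        axis = _prune_skeleton_spurs(axis, max(1, int(round(w_cnt / resolution))))
        if axis.any():
            widths = 2.0 * dist[axis]
            w_min = float(widths.min())
            w_max = float(widths.max())
    return GapStats(
        n_gap_components=n_comp,
        largest_gap_fraction=largest_fraction,
        mean_gap_distance=mean_gap_distance,
        W_Si_min_measured=w_min,
        W_Si_max_measured=w_max,
        resolution=resolution,
    )


# ---------------------------------------------------------------------------
# Geometry report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeometryReport:
    """All derived design quantities of one electrode layout.

    ``A_bounding`` uses the idealized boxes (``W^2/sqrt(2)`` for the
    H-tree, whose tight box differs by <0.5%, and ``W^2`` for the grid);
    the tight raster box is also reported as ``A_bounding_tight``.
    ``W_Si_max`` is the maximum electrode separation: the seed length
    ``L1`` (centre-to-centre separation of the two second-generation
    branches) for the H-tree, the chamber side for the grid; the
    edge-to-edge H-tree value is ``W_Si_max_edge``.
    """

    kind: str
    W: float
    E: float
    A_CNT: float
    A_bounding: float
    A_bounding_tight: float
    A_Si: float
    area_ratio: float
    W_Si_max: float
    W_Si_max_edge: float
    gap: GapStats | None = None

    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "W": self.W,
            "E": self.E,
            "A_CNT": self.A_CNT,
            "A_Si": self.A_Si,
            "A_bounding": self.A_bounding,
            "A_bounding_tight": self.A_bounding_tight,
            "ratio": self.area_ratio,
            "W_Si_max": self.W_Si_max,
            "W_Si_max_edge": self.W_Si_max_edge,
            "W_Si_min": None,
        }
        if self.gap is not None:
            d.update(
                W_Si_min=self.gap.W_Si_min_measured,
                n_gap_components=self.gap.n_gap_components,
                largest_gap_fraction=self.gap.largest_gap_fraction,
                mean_gap_distance=self.gap.mean_gap_distance,
            )
        return d


def measure_geometry(
    layout: ElectrodeLayout,
    gap_resolution: float | None = None,
    integrity_rtol: float = 1e-9,
) -> GeometryReport:
    """Exact union measurement of a layout.

    The sweep-line union is cross-validated against the junction-overlap
    closed form for H-trees; disagreement signals rectangle overlaps
    other than parent-child junctions, i.e. a construction bug.
    """
    area, perim = union_area_perimeter(layout.rectangles)
    spec = layout.spec
    if layout.kind == "htree":
        assert isinstance(spec, HTreeSpec)
        a_ref, _ = htree_analytic_area_perimeter(spec)
        if abs(area - a_ref) > integrity_rtol * a_ref + 1e-9:
            raise GeometryIntegrityError(
                "union area disagrees with the junction-overlap closed form: "
                f"{area} vs {a_ref}; unexpected rectangle intersections"
            )
        a_bounding = spec.W**2 / math.sqrt(2.0)
        w_si_max = spec.L1
    else:
        assert isinstance(spec, GridSpec)
        a_bounding = spec.W**2
        w_si_max = spec.chamber_side
    x0, y0, x1, y1 = layout.bounds
    a_tight = (x1 - x0) * (y1 - y0)
    a_si = a_bounding - area
    gap = gap_metrics(layout, gap_resolution) if gap_resolution is not None else None
    return GeometryReport(
        kind=layout.kind,
        W=spec.W,
        E=perim,
        A_CNT=area,
        A_bounding=a_bounding,
        A_bounding_tight=a_tight,
        A_Si=a_si,
        area_ratio=a_si / area,
        W_Si_max=w_si_max,
        W_Si_max_edge=w_si_max - spec.W_CNT if layout.kind == "htree" else w_si_max,
        gap=gap,
    )


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_layout(layout: ElectrodeLayout, path: str | Path, fmt: str | None = None) -> Path:
    """Write a layout as ``svg``, ``geojson`` or ``csv`` (um, y-up)."""
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "svg":
        _write_svg(layout, path)
    elif fmt == "geojson":
        _write_geojson(layout, path)
    elif fmt == "csv":
        _write_csv(layout, path)
    else:
        raise ParameterError(f"unknown export format {fmt!r}")
    return path


def _write_svg(layout: ElectrodeLayout, path: Path) -> None:
    x0, y0, x1, y1 = layout.bounds
    w, h = x1 - x0, y1 - y0
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="{x0:.6g} {-y1:.6g} '
        f'{w:.6g} {h:.6g}">',
        # y-up coordinates: flip into SVG's y-down space
        f'<g fill="black" stroke="none">',
    ]
    for rx0, ry0, rx1, ry1 in layout.rectangles:
        lines.append(
            f'<rect x="{rx0:.6g}" y="{-ry1:.6g}" width="{rx1 - rx0:.6g}" '
            f'height="{ry1 - ry0:.6g}"/>'
        )
    lines += ["</g>", "</svg>"]
    path.write_text("\n".join(lines))


def _write_geojson(layout: ElectrodeLayout, path: Path) -> None:
    features = []
    for (rx0, ry0, rx1, ry1), gen in zip(layout.rectangles, layout.generations):
        ring = [[rx0, ry0], [rx1, ry0], [rx1, ry1], [rx0, ry1], [rx0, ry0]]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"generation": int(gen)},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {"kind": layout.kind, "units": "um"},
    }
    path.write_text(json.dumps(doc))


def _write_csv(layout: ElectrodeLayout, path: Path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["x0", "y0", "x1", "y1", "generation"])
        for (rx0, ry0, rx1, ry1), gen in zip(layout.rectangles, layout.generations):
            wr.writerow(
                [repr(float(rx0)), repr(float(ry0)), repr(float(rx1)), repr(float(ry1)), int(gen)]
            )


def import_layout_csv(path: str | Path, kind: str, spec: HTreeSpec | GridSpec) -> ElectrodeLayout:
    """Re-read a CSV rectangle table written by :func:`export_layout`."""
    rows = []
    gens = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append([float(rec[k]) for k in ("x0", "y0", "x1", "y1")])
            gens.append(int(rec["generation"]))
    return ElectrodeLayout(
        kind=kind,  # type: ignore[arg-type]
        rectangles=np.asarray(rows, dtype=float),
        generations=np.asarray(gens, dtype=int),
        spec=spec,
    )


def import_layout_geojson(path: str | Path, spec: HTreeSpec | GridSpec) -> ElectrodeLayout:
    doc = json.loads(Path(path).read_text())
    rows, gens = [], []
    for feat in doc["features"]:
        ring = feat["geometry"]["coordinates"][0]
        xs = [p[0] for p in ring]
        ys = [p[1] for p in ring]
        rows.append([min(xs), min(ys), max(xs), max(ys)])
        gens.append(int(feat["properties"].get("generation", 0)))
    return ElectrodeLayout(
        kind=doc.get("properties", {}).get("kind", "htree"),
        rectangles=np.asarray(rows, dtype=float),
        generations=np.asarray(gens, dtype=int),
        spec=spec,
    )
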