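"""Per-FOV binary surface masks matching the microscope tiling scheme.

The fluorescence data come as square fields of view (FOVs) of
2048 x 2048 px covering 662.65 x 662.65 um^2, tiled with a 10% border
overlap for stitching.  Each FOV is partitioned into VACNT (electrode)
pixels and SiO2 (gap) pixels by a pixel-centre point-in-rectangle test;
pixels outside the electrode's bounding box are out-of-domain and
belong to neither surface.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .geometry import (
    ElectrodeLayout,
    ParameterError,
    rasterize_rectangles,
)

DEFAULT_FOV_PX = 2048
DEFAULT_FOV_UM = 662.65
DEFAULT_OVERLAP = 0.10


@dataclass(frozen=True)
class FOVPlan:
    """Tiling plan covering a layout's bounding box.

    Tile (row, col) has its lower-left corner at
    ``(x0 + col*stride, y0 + row*stride)``; rows index y (bottom to
    top).  The stride is the nominal ``fov_size_um * (1 -
    overlap_fraction)`` snapped to a whole number of pixels (see
    :attr:`stride_px`).
    """

    fov_size_px: int
    fov_size_um: float
    overlap_fraction: float
    origin: tuple[float, float]
    rows: int
    cols: int
    domain_bounds: tuple[float, float, float, float]

    @property
    def pixel_size(self) -> float:
        return self.fov_size_um / self.fov_size_px

    @property
    def stride_px(self) -> int:
        """Tile stride in whole pixels.

        Snapping the stride to the pixel lattice keeps all tiles on one
        common grid, so the overlap strips of neighbouring FOVs carry
        bit-identical mask and image content.
        """
        return max(1, round(self.fov_size_px * (1.0 - self.overlap_fraction)))

    @property
    def stride(self) -> float:
        return self.stride_px * self.pixel_size

    def tile_origin(self, fov_index: tuple[int, int]) -> tuple[float, float]:
        row, col = fov_index
        if not (0 <= row < self.rows and 0 <= col < self.cols):
            raise IndexError(f"fov_index {fov_index} outside {self.rows}x{self.cols} plan")
        return (self.origin[0] + col * self.stride, self.origin[1] + row * self.stride)

    def tile_bounds(self, fov_index: tuple[int, int]) -> tuple[float, float, float, float]:
        ox, oy = self.tile_origin(fov_index)
        return (ox, oy, ox + self.fov_size_um, oy + self.fov_size_um)

    def owned_bounds(self, fov_index: tuple[int, int]) -> tuple[float, float, float, float]:
        """Sub-rectangle of this tile owned by it for de-duplication.

        Each physical point is owned by the covering tile whose origin
        is nearest, i.e. overlap strips belong to the later (upper /
        right) tile: tile (r, c) owns x in [ox, ox + stride) except the
        last column which owns through the tile's right edge (same in y).
        """
        row, col = fov_index
        x0, y0 = self.tile_origin(fov_index)
        x1 = x0 + (self.fov_size_um if col == self.cols - 1 else self.stride)
        y1 = y0 + (self.fov_size_um if row == self.rows - 1 else self.stride)
        return (x0, y0, x1, y1)

    def iter_indices(self):
        for row in range(self.rows):
            for col in range(self.cols):
                yield (row, col)

    def to_dict(self) -> dict:
        return {
            "fov_size_px": self.fov_size_px,
            "fov_size_um": self.fov_size_um,
            "overlap_fraction": self.overlap_fraction,
            "origin": list(self.origin),
            "rows": self.rows,
            "cols": self.cols,
            "domain_bounds": list(self.domain_bounds),
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "FOVPlan":
        return cls(
            fov_size_px=int(d["fov_size_px"]),
            fov_size_um=float(d["fov_size_um"]),
            overlap_fraction=float(d["overlap_fraction"]),
            origin=tuple(d["origin"]),
            rows=int(d["rows"]),
            cols=int(d["cols"]),
            domain_bounds=tuple(d["domain_bounds"]),
        )


def plan_fovs(
    layout: ElectrodeLayout,
    fov_size_um: float = DEFAULT_FOV_UM,
    overlap_fraction: float = DEFAULT_OVERLAP,
    fov_size_px: int = DEFAULT_FOV_PX,
) -> FOVPlan:
    """Lay out the FOV grid that covers the layout's bounding box."""
    if fov_size_um <= 0:
        raise ParameterError("fov_size_um must be positive")
    if not (0 <= overlap_fraction < 0.5):
        raise ParameterError(f"overlap_fraction must be in [0, 0.5), got {overlap_fraction}")
    x0, y0, x1, y1 = layout.bounds
    stride = max(1, round(fov_size_px * (1.0 - overlap_fraction))) * (
        fov_size_um / fov_size_px
    )
    cols = max(1, math.ceil((x1 - x0) / stride))
    rows = max(1, math.ceil((y1 - y0) / stride))
    return FOVPlan(
        fov_size_px=fov_size_px,
        fov_size_um=fov_size_um,
        overlap_fraction=overlap_fraction,
        origin=(x0, y0),
        rows=rows,
        cols=cols,
        domain_bounds=(x0, y0, x1, y1),
    )


@dataclass
class SurfaceMaskPair:
    """Binary partition of one FOV into electrode and gap pixels.

    ``cnt_mask`` marks VACNT (electrode) pixels, ``si_mask`` SiO2 (gap)
    pixels; both are ``[row, col]`` with row 0 at the bottom (y-up).
    Pixels outside the electrode bounding box are in neither mask.
    """

    fov_index: tuple[int, int]
    cnt_mask: np.ndarray
    si_mask: np.ndarray
    pixel_size: float

    @property
    def domain_mask(self) -> np.ndarray:
        return self.cnt_mask | self.si_mask

    def surface(self, name: str) -> np.ndarray:
        if name == "cnt":
            return self.cnt_mask
        if name == "si":
            return self.si_mask
        raise ParameterError(f"unknown surface {name!r} (expected 'cnt' or 'si')")


def rasterize_fov(
    layout: ElectrodeLayout, plan: FOVPlan, fov_index: tuple[int, int]
) -> SurfaceMaskPair:
    """Rasterize one FOV's surface masks.

    A pixel is electrode iff its centre lies inside the closed rectangle
    union (half-open tie rule, see
    :func:`fractalmea.geometry.rasterize_rectangles`); a pixel is gap
    iff it is in-domain and not electrode.
    """
    ox, oy = plan.tile_origin(fov_index)
    n = plan.fov_size_px
    res = plan.pixel_size
    cnt = rasterize_rectangles(layout.rectangles, (ox, oy), (n, n), res)
    dx0, dy0, dx1, dy1 = plan.domain_bounds
    domain = rasterize_rectangles(
        np.array([[dx0, dy0, dx1, dy1]]), (ox, oy), (n, n), res
    )
    si = domain & ~cnt
    cnt = cnt & domain
    return SurfaceMaskPair(fov_index=fov_index, cnt_mask=cnt, si_mask=si, pixel_size=res)


def adjust_mask(pair: SurfaceMaskPair, offset_px: int) -> SurfaceMaskPair:
    """Dilate (positive) or erode (negative) the electrode mask.

    Mirrors the manual mask corrections applied when registering design
    masks to images where the fabricated wall width differs from
    nominal; the gap mask is recomputed as the in-domain complement.
    """
    if abs(offset_px) > 10:
        raise ParameterError(f"|offset_px| must be <= 10, got {offset_px}")
    if offset_px == 0:
        return SurfaceMaskPair(
            fov_index=pair.fov_index,
            cnt_mask=pair.cnt_mask.copy(),
            si_mask=pair.si_mask.copy(),
            pixel_size=pair.pixel_size,
        )
    from skimage.morphology import disk, dilation, erosion

    selem = disk(abs(offset_px))
    if offset_px > 0:
        cnt = dilation(pair.cnt_mask, selem)
    else:
        cnt = erosion(pair.cnt_mask, selem)
    domain = pair.domain_mask
    cnt = cnt & domain
    return SurfaceMaskPair(
        fov_index=pair.fov_index,
        cnt_mask=cnt,
        si_mask=domain & ~cnt,
        pixel_size=pair.pixel_size,
    )


def ownership_mask(plan: FOVPlan, fov_index: tuple[int, int]) -> np.ndarray:
    """Boolean mask of the pixels of this FOV that it owns (de-duplication).

    A pixel is owned iff its centre lies in :meth:`FOVPlan.owned_bounds`.
    Owned regions of all tiles partition the covered area exactly.
    """
    ox, oy = plan.tile_origin(fov_index)
    n = plan.fov_size_px
    res = plan.pixel_size
    bx0, by0, bx1, by1 = plan.owned_bounds(fov_index)
    return rasterize_rectangles(
        np.array([[bx0, by0, bx1, by1]]), (ox, oy), (n, n), res
    )


def write_mask_png(pair: SurfaceMaskPair, directory: str | Path, electrode: str) -> list[Path]:
    """Write the two masks as 8-bit PNGs named
    ``{electrode}_{row}_{col}_{cnt|si}.png`` (row 0 at image bottom)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    row, col = pair.fov_index
    out = []
    for name, mask in (("cnt", pair.cnt_mask), ("si", pair.si_mask)):
        p = directory / f"{electrode}_{row}_{col}_{name}.png"
        iio.imwrite(p, (mask[::-1].astype(np.uint8) * 255))
        out.append(p)
    return out
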