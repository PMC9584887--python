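"""Measurement pipeline: stitching, neurite length, glial coverage, metrics.

Per-FOV quantification mirrors how patterned-electrode cultures are
scored from fluorescence images:

* the neuron channel is background-subtracted, binarized (one automatic
  threshold per FOV over in-domain pixels, or a manual override),
  restricted to the chosen surface mask, cleared of soma/cluster
  bodies, skeletonized, and the spur-pruned skeleton's weighted chain
  length gives the process length.  Bundled neurites that follow a
  common route collapse to one skeleton path by construction, so the
  measurement is compared against the *merged* planted length;
* the glia channel is thresholded (Otsu by default, or a manual
  override) and small debris removed; the surviving pixel area gives
  the glial area;
* per-electrode totals over the included FOVs (overlap strips counted
  once via tile ownership) are normalized by the corresponding surface
  areas into the four headline metrics

  ``N_Si = N_LSi / A_Si``,  ``N_CNT = N_LCNT / A_CNT``  (um^-1)
  ``G_Si = G_ASi / A_Si``,  ``G_CNT = G_ACNT / A_CNT``  (dimensionless)
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .geometry import GeometryReport, ParameterError
from .masks import FOVPlan, SurfaceMaskPair, ownership_mask

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "N_LSi",
    "N_LCNT",
    "G_ASi",
    "G_ACNT",
    "A_Si",
    "A_CNT",
    "N_Si",
    "N_CNT",
    "G_Si",
    "G_CNT",
]


@dataclass(frozen=True)
class QuantifyParams:
    """Tunable measurement parameters (lengths in um, areas in um^2).

    ``threshold`` of ``"otsu"`` selects automatic Otsu thresholding on
    in-surface pixels; a float fixes the threshold (the manual,
    semi-automated path).  ``r_bg`` is the background estimation radius,
    ``r_soma`` the inscribed-disk radius above which objects count as
    somas/clusters and are removed, ``l_min`` the skeleton spur-pruning
    length, ``a_min`` the smallest glial object kept.
    ``length_weights`` chooses the chain-code step weighting:
    ``"sqrt2"`` counts orthogonal steps as 1 and diagonal as sqrt(2);
    ``"calibrated"`` uses the Vossepoel-Smeulders weights
    (0.948, 1.340), which remove most of the orientation bias of the
    naive weighting.
    """

    r_bg: float = 15.0
    threshold: float | Literal["otsu"] = "otsu"
    r_soma: float = 5.0
    l_min: float = 2.0
    a_min: float = 20.0
    #: holes smaller than this (um^2) inside detected ribbons are
    #: threshold speckle at the resolution limit; filling them keeps the
    #: skeleton from looping around every noise pore
    hole_area: float = 4.0
    length_weights: Literal["sqrt2", "calibrated"] = "calibrated"
    #: thinning erodes each free skeleton end by roughly the ribbon
    #: half-width; each endpoint is credited this many pixels back
    end_extension_px: float = 2.5
    min_contrast_snr: float = 4.0
    saturation_limit: float = 0.2
    background_mode: Literal["gaussian", "rolling_ball"] = "gaussian"


@dataclass
class FOVMeasurement:
    """Per-FOV, per-surface measured quantities on the tile-owned region."""

    fov_index: tuple[int, int]
    process_length: dict[str, float]
    glial_area: dict[str, float]
    surface_area: dict[str, float]
    qc_flag: str = "included"
    qc_reason: str = ""


# ---------------------------------------------------------------------------
# Stitching
# ---------------------------------------------------------------------------


def stitch_tiles(
    tiles: dict[tuple[int, int], np.ndarray],
    plan: FOVPlan,
    jitter_search_px: int = 5,
    min_confidence: float = 0.2,
) -> np.ndarray:
    """Assemble per-FOV tiles into one mosaic.

    Pairwise translation offsets between neighbours are estimated by
    normalized cross-correlation over the nominal overlap strips within
    ``+/- jitter_search_px``; tiles are chained from (0, 0) along row 0
    and down each column (a spanning tree), and overlapping pixels are
    blended with a feathered average.  Low-confidence pairs (blank
    strips, weak correlation) fall back to the nominal offsets with a
    warning.

    Tiles are indexed ``[row, col]`` with row 0 at the *bottom*; the
    returned mosaic keeps that orientation.
    """
    n = plan.fov_size_px
    for idx, t in tiles.items():
        if t.shape != (n, n):
            raise ParameterError(f"tile {idx} has shape {t.shape}, expected {(n, n)}")
    stride_px = plan.stride / plan.pixel_size
    overlap_px = n - stride_px
    if overlap_px < 1:
        raise ParameterError("plan has no overlap; nothing to correlate")

    def pair_offset(a: np.ndarray, b: np.ndarray, axis: int) -> tuple[float, float]:
        """Offset (drow, dcol) of tile b relative to its nominal position."""
        ov = int(round(overlap_px))
        if axis == 1:  # b to the right of a
            strip_a = a[:, -ov:]
            strip_b = b[:, :ov]
        else:  # b above a (higher row = higher y)
            strip_a = a[-ov:, :]
            strip_b = b[:ov, :]
        shift = _ncc_shift(strip_a, strip_b, jitter_search_px, min_confidence)
        if shift is None:
            warnings.warn(
                "stitching: low-confidence overlap, falling back to nominal offset",
                stacklevel=2,
            )
            return (0.0, 0.0)
        return shift

    pos: dict[tuple[int, int], tuple[float, float]] = {(0, 0): (0.0, 0.0)}
    for col in range(1, plan.cols):
        if (0, col) not in tiles:
            continue
        dr, dc = pair_offset(tiles[(0, col - 1)], tiles[(0, col)], axis=1)
        pr, pc = pos[(0, col - 1)]
        pos[(0, col)] = (pr + dr, pc + stride_px + dc)
    for col in range(plan.cols):
        for row in range(1, plan.rows):
            if (row, col) not in tiles or (row - 1, col) not in pos:
                continue
            dr, dc = pair_offset(tiles[(row - 1, col)], tiles[(row, col)], axis=0)
            pr, pc = pos[(row - 1, col)]
            pos[(row, col)] = (pr + stride_px + dr, pc + dc)

    rmin = min(p[0] for p in pos.values())
    cmin = min(p[1] for p in pos.values())
    rmax = max(p[0] for p in pos.values()) + n
    cmax = max(p[1] for p in pos.values()) + n
    H = int(math.ceil(rmax - rmin))
    W = int(math.ceil(cmax - cmin))
    acc = np.zeros((H, W), dtype=np.float64)
    wacc = np.zeros((H, W), dtype=np.float64)
    ramp = np.minimum(np.arange(1, n + 1), np.arange(n, 0, -1)).astype(float)
    feather = np.minimum.outer(ramp, ramp)
    for idx, tile in tiles.items():
        if idx not in pos:
            continue
        r0 = int(round(pos[idx][0] - rmin))
        c0 = int(round(pos[idx][1] - cmin))
        acc[r0 : r0 + n, c0 : c0 + n] += tile.astype(np.float64) * feather
        wacc[r0 : r0 + n, c0 : c0 + n] += feather
    with np.errstate(invalid="ignore", divide="ignore"):
        mosaic = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0)
    return mosaic


def _ncc_shift(
    a: np.ndarray, b: np.ndarray, search: int, min_confidence: float
) -> tuple[float, float] | None:
    """Best (drow, dcol) of b vs a by exhaustive NCC within +/- search."""
    a = a.astype(np.float64)
    b = b.astype(np.float64)
    if a.std() < 1e-9 or b.std() < 1e-9:
        return None
    best, best_shift = -2.0, (0, 0)
    for dr in range(-search, search + 1):
        for dc in range(-search, search + 1):
            aa = a[
                max(0, dr) : a.shape[0] + min(0, dr),
                max(0, dc) : a.shape[1] + min(0, dc),
            ]
            bb = b[
                max(0, -dr) : b.shape[0] + min(0, -dr),
                max(0, -dc) : b.shape[1] + min(0, -dc),
            ]
            if aa.size < 64:
                continue
            av = aa - aa.mean()
            bv = bb - bb.mean()
            denom = math.sqrt((av**2).sum() * (bv**2).sum())
            if denom < 1e-12:
                continue
            ncc = float((av * bv).sum() / denom)
            if ncc > best:
                best, best_shift = ncc, (dr, dc)
    if best < min_confidence:
        return None
    return (float(best_shift[0]), float(best_shift[1]))


# ---------------------------------------------------------------------------
# Process length
# ---------------------------------------------------------------------------

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_ORTH_SHIFTS = ((0, 1), (1, 0))
_DIAG_SHIFTS = ((1, 1), (1, -1))
_WEIGHTS = {"sqrt2": (1.0, math.sqrt(2.0)), "calibrated": (0.948, 1.340)}


def _subtract_background(img: np.ndarray, r_bg_px: float, mode: str) -> np.ndarray:
    img = img.astype(np.float32)
    if r_bg_px <= 0:
        return img
    if mode == "rolling_ball":
        from skimage.restoration import rolling_ball

        bg = rolling_ball(img, radius=r_bg_px)
    elif mode == "gaussian":
        # the background is smooth by construction: estimate it on a
        # 4x-decimated image and bilinearly upsample
        if r_bg_px >= 8 and min(img.shape) >= 64 and all(s % 4 == 0 for s in img.shape):
            f = 4
            ny, nx = img.shape
            small = img.reshape(ny // f, f, nx // f, f).mean(axis=(1, 3))
            small = ndi.gaussian_filter(small, r_bg_px / f)
            bg = ndi.zoom(small, f, order=1, grid_mode=True, mode="nearest").astype(
                img.dtype
            )
        else:
            bg = ndi.gaussian_filter(img, r_bg_px)
    else:
        raise ParameterError(f"unknown background mode {mode!r}")
    # negatives are kept: clipping at zero skews the robust noise
    # statistics used to guard the automatic threshold
    return img - bg


def _threshold_in_mask(
    values: np.ndarray, threshold, min_snr: float, mode: str = "blobs"
) -> float | None:
    """Threshold for in-surface pixel values; None if no credible signal.

    With automatic (Otsu) selection a contrast guard rejects thresholds
    that merely split the noise: the foreground median must exceed the
    background median by ``min_snr`` robust standard deviations.
    """
    if values.size < 64:
        return None
    if threshold != "otsu":
        return float(threshold)
    from skimage.filters import threshold_multiotsu, threshold_otsu

    if np.ptp(values) < 1e-9:
        return None
    # candidate cuts: the neuron channel is tri-modal (background,
    # neurite ridges, bright somas) so the lowest three-class Otsu cut
    # is tried first; when that one merely splits the noise (sparse
    # signal), the upper cut may still isolate it.  Glia are bimodal
    # and use plain Otsu.
    if mode == "neurites":
        try:
            candidates = [float(t) for t in threshold_multiotsu(values, classes=3)]
        except ValueError:  # fewer than 3 distinct grey levels
            candidates = [float(threshold_otsu(values))]
    else:
        candidates = [float(threshold_otsu(values))]
    for t in candidates:
        fg = values[values > t]
        bg = values[values <= t]
        if fg.size == 0 or bg.size == 0:
            continue
        # accept only a cut that separates classes by well more than the
        # background's own spread — otherwise it is splitting noise
        mad_bg = float(np.median(np.abs(bg - np.median(bg)))) * 1.4826
        if np.median(fg) - np.median(bg) >= min_snr * 1.5 * max(mad_bg, 1e-9):
            return t
    return None


def _remove_somas(binary: np.ndarray, r_soma_px: float) -> np.ndarray:
    """Remove regions whose maximal inscribed disk radius exceeds r_soma.

    Core pixels deeper than ``0.7*r_soma`` are found by the distance
    transform and grown back to the full body (plus a small margin for
    PSF spreading) before subtraction, so neurite ribbons attached to a
    soma are cut flush with the soma boundary.
    """
    if not binary.any():
        return binary
    dt = ndi.distance_transform_edt(binary)
    core_depth = 0.7 * r_soma_px
    cores = dt > core_depth
    if not cores.any():
        return binary
    # growing cores back by core_depth reclaims exactly the body that
    # produced them; +2 px margin absorbs PSF spreading of the boundary.
    # The dilation is computed locally around each core for speed.
    grow = core_depth + 2.0
    pad = int(math.ceil(grow)) + 1
    labels, n = ndi.label(cores)
    out = binary.copy()
    for sl in ndi.find_objects(labels):
        r0 = max(0, sl[0].start - pad)
        r1 = min(binary.shape[0], sl[0].stop + pad)
        c0 = max(0, sl[1].start - pad)
        c1 = min(binary.shape[1], sl[1].stop + pad)
        local = cores[r0:r1, c0:c1]
        d_local = ndi.distance_transform_edt(~local)
        out[r0:r1, c0:c1] &= d_local > grow
    return out


def _remove_slivers(binary: np.ndarray) -> np.ndarray:
    """Drop components nowhere thicker than ~2 px.

    A genuine neurite ribbon (drawn width plus PSF) always exceeds the
    threshold over a band at least 3 px wide; thinner components are
    edge artefacts — typically the spill-over of a ribbon that hugs the
    *other* side of a surface boundary.
    """
    if not binary.any():
        return binary
    # a pixel deeper than 1 px survives erosion by the 4-neighbour cross
    eroded = ndi.binary_erosion(binary, _FOUR_CONN)
    labels, n = ndi.label(binary, structure=np.ones((3, 3)))
    if n == 0:
        return binary
    thick = np.zeros(n + 1, dtype=bool)
    thick[np.unique(labels[eroded])] = True
    thick[0] = False
    return binary & thick[labels]


def _skeleton_neighbors(sk: np.ndarray) -> np.ndarray:
    kernel = np.ones((3, 3), dtype=np.uint8)
    return ndi.convolve(sk.astype(np.uint8), kernel, mode="constant") - sk


def _prune_spurs(sk: np.ndarray, l_min_px: int) -> np.ndarray:
    """Remove terminal branches that reach a junction within l_min_px.

    Walks inward from every endpoint; only branches that terminate at a
    junction (3+ neighbours) within the limit are deleted, so genuine
    process ends keep their full length.
    """
    if l_min_px <= 0 or not sk.any():
        return sk
    sk = sk.copy()
    neigh = _skeleton_neighbors(sk)
    endpoints = np.argwhere(sk & (neigh == 1))
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for r0, c0 in endpoints:
        path = [(int(r0), int(c0))]
        prev = None
        r, c = int(r0), int(c0)
        junction_hit = False
        for _ in range(l_min_px):
            nbrs = [
                (r + dr, c + dc)
                for dr, dc in offsets
                if 0 <= r + dr < sk.shape[0]
                and 0 <= c + dc < sk.shape[1]
                and sk[r + dr, c + dc]
                and (r + dr, c + dc) != prev
            ]
            if len(nbrs) == 0:
                break
            if len(nbrs) > 1:
                junction_hit = True
                break
            prev = (r, c)
            r, c = nbrs[0]
            nn = _count_neighbors_at(sk, r, c)
            if nn >= 3:
                junction_hit = True
                break
            path.append((r, c))
        if junction_hit:
            for rr, cc in path:
                sk[rr, cc] = False
    return sk


def _count_neighbors_at(sk: np.ndarray, r: int, c: int) -> int:
    r0, r1 = max(0, r - 1), min(sk.shape[0], r + 2)
    c0, c1 = max(0, c - 1), min(sk.shape[1], c + 2)
    return int(sk[r0:r1, c0:c1].sum()) - 1


def skeleton_length_um(
    sk: np.ndarray, pixel_size: float, weights: str = "calibrated"
) -> float:
    """Weighted chain length of a 1-px skeleton.

    Counts 4-adjacent pixel pairs as orthogonal steps and strictly
    diagonal pairs (with no shared orthogonal neighbour on the skeleton)
    as diagonal steps.
    """
    w_o, w_d = _WEIGHTS[weights]
    n_orth = 0
    for dr, dc in _ORTH_SHIFTS:
        n_orth += int((sk[dr:, dc:] & sk[: sk.shape[0] - dr, : sk.shape[1] - dc]).sum())
    n_diag = 0
    a = sk
    # diagonal pair (r,c)-(r+1,c+1) only counts when neither elbow pixel
    # is on the skeleton (otherwise the path goes through the elbow)
    d1 = a[1:, 1:] & a[:-1, :-1] & ~a[1:, :-1] & ~a[:-1, 1:]
    d2 = a[1:, :-1] & a[:-1, 1:] & ~a[1:, 1:] & ~a[:-1, :-1]
    n_diag = int(d1.sum()) + int(d2.sum())
    return (w_o * n_orth + w_d * n_diag) * pixel_size


def measure_process_length(
    neuron_channel: np.ndarray,
    mask: SurfaceMaskPair,
    surface: str,
    params: QuantifyParams = QuantifyParams(),
    region: np.ndarray | None = None,
) -> float:
    """Total neurite length (um) on one surface of one FOV.

    ``region`` optionally restricts the measurement (e.g. to the
    tile-owned sub-rectangle for overlap de-duplication).
    """
    surf = mask.surface(surface)
    if region is not None:
        surf = surf & region
    if not surf.any():
        return 0.0
    if neuron_channel.shape != surf.shape:
        raise ParameterError("image and mask are not congruent")
    px = mask.pixel_size
    sub = _subtract_background(neuron_channel, params.r_bg / px, params.background_mode)
    # one threshold per FOV, estimated on all in-domain pixels: both
    # surfaces share the illumination, and the dimmer surface provides
    # the background reference for the brighter one
    t = _threshold_in_mask(
        sub[mask.domain_mask], params.threshold, params.min_contrast_snr,
        mode="neurites",
    )
    return _length_in_surface(sub, surf, px, params, t)


def _length_in_surface(
    sub: np.ndarray, surf: np.ndarray, px: float, params: QuantifyParams, t
) -> float:
    """Skeleton length (um) of the background-subtracted neuron channel
    within one surface mask, at threshold ``t``."""
    if t is None:
        return 0.0
    binary = (sub > t) & surf
    binary = _remove_somas(binary, params.r_soma / px)
    from skimage.morphology import (
        remove_small_holes,
        remove_small_objects,
        skeletonize,
    )

    binary = remove_small_holes(binary, max_size=max(4, int(params.hole_area / px**2)))
    binary = remove_small_objects(binary, max_size=max(4, int((1.0 / px) ** 2)) - 1)
    binary = _remove_slivers(binary)
    if not binary.any():
        return 0.0
    # Lee's thinning: the classic two-subiteration scheme can erase
    # uniform diagonal ribbons entirely (2x2 blocks are not preserved)
    sk = skeletonize(binary, method="lee").astype(bool)
    sk = _prune_spurs(sk, int(round(params.l_min / px)))
    length = skeleton_length_um(sk, px, params.length_weights)
    if params.end_extension_px > 0 and sk.any():
        # thinning erodes every skeleton terminus (true process ends and
        # mask-cut ends alike) by about the ribbon half-width
        n_end = int((sk & (_skeleton_neighbors(sk) == 1)).sum())
        length += n_end * params.end_extension_px * px
    return length


# ---------------------------------------------------------------------------
# Glial area
# ---------------------------------------------------------------------------


def measure_glial_area(
    glia_channel: np.ndarray,
    mask: SurfaceMaskPair,
    surface: str,
    params: QuantifyParams = QuantifyParams(),
    region: np.ndarray | None = None,
) -> float:
    """Glial area (um^2) on one surface of one FOV."""
    surf = mask.surface(surface)
    if region is not None:
        surf = surf & region
    if not surf.any():
        return 0.0
    if glia_channel.shape != surf.shape:
        raise ParameterError("image and mask are not congruent")
    px = mask.pixel_size
    img = glia_channel.astype(np.float32)
    # global per-FOV threshold (in-domain pixels): the uncovered surface
    # anchors the background mode even when the other is fully covered
    t = _threshold_in_mask(
        img[mask.domain_mask], params.threshold, params.min_contrast_snr
    )
    if t is None:
        return 0.0
    binary = (img > t) & surf
    from skimage.morphology import remove_small_objects

    min_px = max(1, int(round(params.a_min / px**2)))
    binary = remove_small_objects(binary, max_size=min_px - 1)
    return float(binary.sum()) * px**2


# ---------------------------------------------------------------------------
# Per-FOV driver and aggregation
# ---------------------------------------------------------------------------


def measure_fov(
    neurons: np.ndarray,
    glia: np.ndarray,
    mask: SurfaceMaskPair,
    plan: FOVPlan,
    params: QuantifyParams = QuantifyParams(),
    deduplicate: bool = True,
) -> FOVMeasurement:
    """Measure one FOV on both surfaces, restricted to its owned region.

    Each surface is binarized, skeletonized and measured on its own cut
    of the image (the background estimate is shared): a ribbon that
    straddles an electrode edge is thereby split at the boundary and
    each side contributes to its own surface, which mirrors how
    surface-specific masks were applied to the imaging data.
    """
    region = ownership_mask(plan, mask.fov_index) if deduplicate else None
    px = mask.pixel_size
    qc_flag, qc_reason = "included", ""
    sat = float((neurons >= 65535).mean())
    if sat > params.saturation_limit:
        qc_flag, qc_reason = "excluded", f"saturated fraction {sat:.2f}"

    lengths = {"si": 0.0, "cnt": 0.0}
    areas = {"si": 0.0, "cnt": 0.0}
    surf_areas = {"si": 0.0, "cnt": 0.0}
    sub = _subtract_background(neurons, params.r_bg / px, params.background_mode)
    t = _threshold_in_mask(
        sub[mask.domain_mask], params.threshold, params.min_contrast_snr,
        mode="neurites",
    )
    for s in ("si", "cnt"):
        surf = mask.surface(s)
        if region is not None:
            surf = surf & region
        surf_areas[s] = float(surf.sum()) * px**2
        if surf.any():
            lengths[s] = _length_in_surface(sub, surf, px, params, t)
            areas[s] = measure_glial_area(glia, mask, s, params, region)
    return FOVMeasurement(
        fov_index=mask.fov_index,
        process_length=lengths,
        glial_area=areas,
        surface_area=surf_areas,
        qc_flag=qc_flag,
        qc_reason=qc_reason,
    )


def measurements_frame(measurements: Iterable[FOVMeasurement]) -> pd.DataFrame:
    rows = []
    for m in measurements:
        for s in ("si", "cnt"):
            rows.append(
                {
                    "fov_row": m.fov_index[0],
                    "fov_col": m.fov_index[1],
                    "surface": s,
                    "process_length_um": m.process_length[s],
                    "glial_area_um2": m.glial_area[s],
                    "surface_area_um2": m.surface_area[s],
                    "qc_flag": m.qc_flag,
                    "qc_reason": m.qc_reason,
                }
            )
    return pd.DataFrame(rows)


def aggregate_metrics(
    measurements: Sequence[FOVMeasurement],
    report: GeometryReport,
    exclusions: Sequence[tuple[int, int]] = (),
) -> pd.Series:
    """Electrode-level totals and the four normalized metrics.

    ``exclusions`` lists FOV indices to drop (mirroring the manual
    exclusion of FOVs with imaging or fabrication defects); an index
    both measured-as-excluded and force-included is an error.
    """
    if report.A_Si <= 0 or report.A_CNT <= 0:
        raise ParameterError("surface areas must be positive")
    excluded = set(tuple(e) for e in exclusions)
    seen = set()
    tot = {"N_LSi": 0.0, "N_LCNT": 0.0, "G_ASi": 0.0, "G_ACNT": 0.0}
    for m in measurements:
        if m.fov_index in seen:
            raise ParameterError(f"duplicate measurement for FOV {m.fov_index}")
        seen.add(m.fov_index)
        if m.fov_index in excluded and m.qc_flag == "included":
            m = FOVMeasurement(
                m.fov_index,
                m.process_length,
                m.glial_area,
                m.surface_area,
                "excluded",
                "listed exclusion",
            )
        if m.qc_flag == "excluded":
            continue
        tot["N_LSi"] += m.process_length["si"]
        tot["N_LCNT"] += m.process_length["cnt"]
        tot["G_ASi"] += m.glial_area["si"]
        tot["G_ACNT"] += m.glial_area["cnt"]
    out = pd.Series(
        {
            **tot,
            "A_Si": report.A_Si,
            "A_CNT": report.A_CNT,
            "N_Si": tot["N_LSi"] / report.A_Si,
            "N_CNT": tot["N_LCNT"] / report.A_CNT,
            "G_Si": tot["G_ASi"] / report.A_Si,
            "G_CNT": tot["G_ACNT"] / report.A_CNT,
        }
    )[METRIC_COLUMNS]
    return out
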