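"""Corrected FRET index and NFRET maps, region statistics and rendering.

The cross-talk-corrected FRET index follows Youvan's method,

    F_index = I_FRET − A·I_D − B·I_A,

computed on background-subtracted channels, and is normalized pixelwise to

    NFRET = 100 · F_index / sqrt(I_D · I_A),

an intensity-independent measure of FRET on the conventional ×100 scale.
Negative NFRET pixels (possible after the subtractions) are clamped to
zero; pixels where either the donor or the acceptor channel is at or below
a signal floor are marked invalid rather than silently zeroed. Maps are
rendered with the "fire" lookup table, by default displayed over 0–60.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.filters import threshold_otsu
from skimage.morphology import dilation, disk, skeletonize

from .calibration import BleedThroughParams
from .images import ImageSet


@dataclass
class FIndexMap:
    """Per-pixel corrected FRET index (counts); may be negative."""

    values: np.ndarray


@dataclass
class NFRETMap:
    """Per-pixel NFRET on the ×100 scale.

    ``values`` are non-negative on ``valid_mask`` (raw negatives clamped to
    0); pixels outside ``valid_mask`` had insufficient donor or acceptor
    signal and carry NaN.
    """

    values: np.ndarray
    valid_mask: np.ndarray
    raw: np.ndarray = field(repr=False, default=None)


@dataclass
class LineProfile:
    positions: np.ndarray
    values: np.ndarray


@dataclass
class RegionStats:
    mean: float
    sem: float
    sd: float
    n: int
    region: str
    per_cell: bool = False


def compute_fret_index(images: ImageSet, bleed: BleedThroughParams) -> FIndexMap:
    """F_index = I_FRET − A·I_D − B·I_A on background-subtracted channels."""
    return FIndexMap(values=images.fret - bleed.A * images.donor - bleed.B * images.acceptor)


def compute_nfret(
    images: ImageSet, bleed: BleedThroughParams, signal_floor: float = 6.0
) -> NFRETMap:
    """NFRET = 100·F_index/√(I_D·I_A), clamped at 0, ×100 scale.

    Pixels where donor or acceptor is at or below ``signal_floor`` are
    invalid (NaN), distinguishing "no signal" from a clamped zero.
    """
    findex = compute_fret_index(images, bleed).values
    valid = (images.donor > signal_floor) & (images.acceptor > signal_floor)
    if not valid.any():
        warnings.warn("no valid pixels for NFRET (all below signal floor)", stacklevel=2)
    denom = np.sqrt(np.where(valid, images.donor * images.acceptor, 1.0))
    raw = np.where(valid, 100.0 * findex / denom, np.nan)
    values = np.where(valid, np.maximum(raw, 0.0), np.nan)
    return NFRETMap(values=values, valid_mask=valid, raw=raw)


def filament_mask(structure_image: np.ndarray, smooth_sigma: float = 1.0) -> np.ndarray:
    """Segment filamentous structures from a structure channel.

    Otsu thresholding is applied hierarchically on the smoothed image:
    a first threshold separates the cell from the background, a second —
    computed within the cell — separates bright filaments from diffuse
    cytosolic signal. The binary result is skeletonized and dilated by
    1 px, yielding a thin ribbon centered on each filament.
    """
    img = np.asarray(structure_image, dtype=float)
    smoothed = gaussian_filter(img, smooth_sigma)
    if np.ptp(smoothed) == 0:
        warnings.warn("blank structure image; empty filament mask", stacklevel=2)
        return np.zeros(img.shape, dtype=bool)
    fg = smoothed > threshold_otsu(smoothed)
    inside = smoothed[fg]
    thresh = threshold_otsu(inside) if np.ptp(inside) > 0 else np.inf
    binary = smoothed > thresh
    return dilation(skeletonize(binary), disk(1))


def extract_line_profile(
    image: np.ndarray, polyline: np.ndarray, step: float = 1.0
) -> LineProfile:
    """Sample an image along a polyline at uniform arc-length steps
    (bilinear interpolation, single-pixel width)."""
    img = np.asarray(image, dtype=float)
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 2:
        raise ValueError("polyline needs at least two (row, col) points")
    nr, nc = img.shape
    if (poly[:, 0].min() < 0 or poly[:, 0].max() > nr - 1
            or poly[:, 1].min() < 0 or poly[:, 1].max() > nc - 1):
        raise ValueError("polyline extends outside the image")
    seg = np.diff(poly, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    arclen = np.concatenate([[0.0], np.cumsum(seglen)])
    positions = np.arange(0.0, arclen[-1] + step / 2, step)
    rows = np.interp(positions, arclen, poly[:, 0])
    cols = np.interp(positions, arclen, poly[:, 1])
    values = map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return LineProfile(positions=positions, values=values)


def region_nfret_stats(
    nfret: NFRETMap,
    mask: np.ndarray,
    cell_labels: np.ndarray | None = None,
    region: str = "filament",
) -> RegionStats:
    """Mean / SEM / SD of NFRET over a mask.

    With ``cell_labels`` the statistic is computed per cell first and then
    summarized across cells (n = cells), matching per-cell box plots;
    otherwise it is per-pixel (n = pixels). Invalid pixels are excluded.
    """
    mask = np.asarray(mask, dtype=bool) & nfret.valid_mask
    if not mask.any():
        raise ValueError("empty mask (no valid pixels)")
    if cell_labels is not None:
        labels = np.asarray(cell_labels)
        cells = np.unique(labels[mask & (labels > 0)])
        vals = np.array([nfret.values[mask & (labels == c)].mean() for c in cells])
        per_cell = True
    else:
        vals = nfret.values[mask]
        per_cell = False
    n = vals.size
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return RegionStats(
        mean=float(vals.mean()),
        sem=sd / np.sqrt(n) if n > 1 else 0.0,
        sd=sd,
        n=int(n),
        region=region,
        per_cell=per_cell,
    )


def pearson_colocalization(img1: np.ndarray, img2: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two channels over masked pixels."""
    a = np.asarray(img1, dtype=float)
    b = np.asarray(img2, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        a, b = a[m], b[m]
    else:
        a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ValueError("need at least 2 pixels")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance input; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


# ImageJ "fire" LUT control points (32 anchors, linearly interpolated to 256).
_FIRE_R = [0, 0, 1, 25, 49, 73, 98, 122, 146, 162, 173, 184, 195, 207, 217, 229,
           240, 252, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255, 255]
_FIRE_G = [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 14, 35, 57,
           79, 101, 117, 133, 147, 161, 175, 190, 205, 219, 234, 248, 255, 255, 255, 255]
_FIRE_B = [0, 61, 96, 130, 165, 192, 220, 227, 210, 181, 151, 122, 93, 64, 35, 5,
           0, 0, 0, 0, 0, 0, 0, 0, 0, 35, 98, 160, 223, 255, 255, 255]


def fire_lut() -> np.ndarray:
    """256×3 uint8 fire lookup table (black → red → yellow → white)."""
    xi = np.linspace(0, 31, 256)
    x = np.arange(32)
    return np.stack(
        [np.rint(np.interp(xi, x, c)).astype(np.uint8) for c in (_FIRE_R, _FIRE_G, _FIRE_B)],
        axis=1,
    )


def render_false_color(
    nfret: NFRETMap, display_range: tuple[float, float] = (0.0, 60.0)
) -> np.ndarray:
    """Render an NFRET map through the fire LUT as an 8-bit RGB image.

    Values are mapped linearly from ``display_range`` onto LUT indices
    0–255 (round-half-even), clipped at the range ends; invalid pixels are
    black.
    """
    lo, hi = display_range
    if hi <= lo:
        raise ValueError("display_range must be increasing")
    scaled = (np.nan_to_num(nfret.values, nan=lo) - lo) / (hi - lo)
    idx = np.rint(np.clip(scaled, 0, 1) * 255).astype(np.uint8)
    rgb = fire_lut()[idx]
    rgb[~nfret.valid_mask] = 0
    return rgb


def nfret_timecourse(
    image_sets: list[tuple[float, ImageSet]],
    bleed: BleedThroughParams,
    structure_channel: str = "acceptor",
    mask_policy: str = "per-frame",
    signal_floor: float = 6.0,
) -> pd.DataFrame:
    """Per-timepoint on-filament NFRET statistics.

    ``mask_policy`` is ``'per-frame'`` (mask recomputed each frame) or
    ``'frozen'`` (mask from the first frame reused throughout). Channels
    must already be background-subtracted.
    """
    if len(image_sets) < 2:
        raise ValueError("need at least 2 timepoints")
    if mask_policy not in ("per-frame", "frozen"):
        raise ValueError("mask_policy must be 'per-frame' or 'frozen'")
    frozen = None
    rows = []
    for t, imset in image_sets:
        struct = imset.channels()[structure_channel]
        if mask_policy == "frozen":
            if frozen is None:
                frozen = filament_mask(struct)
            mask = frozen
        else:
            mask = filament_mask(struct)
        nmap = compute_nfret(imset, bleed, signal_floor=signal_floor)
        stats = region_nfret_stats(nmap, mask)
        rows.append(
            {"time_s": t, "mean_nfret": stats.mean, "sem": stats.sem,
             "sd": stats.sd, "n_pixels": stats.n, "mask_area": int(mask.sum())}
        )
    return pd.DataFrame(rows)
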