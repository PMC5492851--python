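"""Synthetic fluorescence microscopy generator with known ground truth.

The generator is the exact algebraic inverse of the quantification
pipeline's correction formulas, so parameter recovery is well-posed:

* filament scenes draw a cell body containing persistent-random-walk
  filament polylines with a ~2 px Gaussian cross-section; clean donor and
  acceptor signals are proportional to the local fluorophore density, and
  the sensitized-emission term is constructed pixelwise from the target
  NFRET level, S = (NFRET_truth/100)·√(D·Acc);
* channels are emitted as I_D = bg + D + ε, I_A = bg + Acc + ε,
  I_FRET = bg + A·D + B·Acc + S + ε, with Poisson shot noise scaled so the
  clean-signal maximum is ``noise_scale`` counts plus Gaussian read noise;
* FRAP traces follow the two-phase exponential association ground truth
  g(t) = A1*(1−exp(−t/τ1)) + A2*(1−exp(−t/τ2)) with a pre-bleach plateau,
  a bleach drop to the residual fraction f0, and a smooth multiplicative
  acquisition-photobleaching loss L(t) shared by ROI and whole-cell traces.

All outputs are deterministic for a fixed (preset, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk

from .frap import FRAPTrace
from .images import ImageSet
from .presets import ScenePreset

BACKGROUND = 20.0  # counts, all channels
READ_NOISE_SD = 2.0  # counts
CYTOSOL_DENSITY = 0.15  # relative to filament peak density
ACCEPTOR_GAIN = 0.95  # acceptor channel gain relative to donor
SATURATION_CEILING = 65535.0
N_FILAMENTS_512 = 12  # polylines per 512x512 field, scaled by area


class SceneConfigError(ValueError):
    """Preset implies a physically impossible scene (e.g. saturation)."""


@dataclass
class SceneTruth:
    """Ground truth accompanying one generated filament scene."""

    filament_mask: np.ndarray
    cell_mask: np.ndarray
    filament_polylines: list[np.ndarray]
    nfret_truth: np.ndarray
    clean_donor: np.ndarray
    clean_acceptor: np.ndarray
    background: float = BACKGROUND


@dataclass
class FRAPTruth:
    """Ground truth for one simulated FRAP trace."""

    A1_star: float
    A2_star: float
    tau1: float
    tau2: float
    bleach_residual: float
    loss_curve: np.ndarray
    background: float = BACKGROUND

    def g(self, t: np.ndarray) -> np.ndarray:
        """Normalized recovery: 0 at bleach, A1*+A2* at infinite time."""
        t = np.asarray(t, dtype=float)
        return self.A1_star * (1 - np.exp(-t / self.tau1)) + self.A2_star * (
            1 - np.exp(-t / self.tau2)
        )


def _cell_body_mask(n: int, rng: np.random.Generator) -> np.ndarray:
    """Irregular convex-ish cell outline: ellipse with low-order radial ripple."""
    yy, xx = np.mgrid[:n, :n]
    cy = cx = (n - 1) / 2.0
    dy, dx = (yy - cy) / (0.42 * n), (xx - cx) / (0.36 * n)
    theta = np.arctan2(dy, dx)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    ripple = 1 + 0.07 * np.sin(3 * theta + p1) + 0.05 * np.sin(5 * theta + p2)
    return np.hypot(dy, dx) <= ripple


def _random_walk_polyline(
    cell: np.ndarray, rng: np.random.Generator, step: float = 2.0, turn_sd: float = 0.12
) -> np.ndarray:
    """Persistent random walk from near the cell center until it exits the cell."""
    n = cell.shape[0]
    c = (n - 1) / 2.0
    start = np.array([c, c]) + rng.uniform(-0.12 * n, 0.12 * n, size=2)
    heading = rng.uniform(0, 2 * np.pi)
    pts = [start]
    pos = start.copy()
    for _ in range(4 * n):
        heading += rng.normal(0, turn_sd)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        r, ccol = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < n and 0 <= ccol < n) or not cell[r, ccol]:
            break
        pts.append(pos.copy())
    return np.array(pts)


def _draw_polylines(shape: tuple[int, int], polylines: list[np.ndarray]) -> np.ndarray:
    img = np.zeros(shape, dtype=bool)
    for poly in polylines:
        pix = np.round(poly).astype(int)
        for (r0, c0), (r1, c1) in zip(pix[:-1], pix[1:]):
            rr, cc = draw_line(r0, c0, r1, c1)
            img[rr, cc] = True
    return img


def _scene_geometry(preset: ScenePreset, rng: np.random.Generator, keep_fraction: float = 1.0):
    """Cell mask, filament polylines (subset), filament mask and density."""
    n = preset.field_size
    if n < 64:
        raise SceneConfigError("field_size must be at least 64 px")
    cell = _cell_body_mask(n, rng)
    n_fil = max(3, round(N_FILAMENTS_512 * (n / 512) ** 2))
    polylines = [_random_walk_polyline(cell, rng) for _ in range(n_fil)]
    polylines = [p for p in polylines if len(p) >= 3]
    keep = max(1, int(np.ceil(keep_fraction * len(polylines))))
    kept = polylines[:keep]
    drawn = _draw_polylines((n, n), kept)
    mask = dilation(drawn, disk(1)) & cell
    density = gaussian_filter(drawn.astype(float), sigma=1.0)
    peak = density.max()
    if peak > 0:
        density = density / peak
    return cell, kept, mask, density


def _emit_channels(
    clean_d: np.ndarray,
    clean_a: np.ndarray,
    sensitized: np.ndarray,
    preset: ScenePreset,
    rng: np.random.Generator,
) -> ImageSet:
    clean_f = preset.bleed_A * clean_d + preset.bleed_B * clean_a + sensitized
    meta = {"bit_depth": 16, "background": BACKGROUND, "preset": preset.name}
    chans = []
    for clean in (clean_d, clean_a, clean_f):
        mean = clean + BACKGROUND
        if mean.max() > SATURATION_CEILING:
            raise SceneConfigError("clean signal exceeds the 16-bit saturation ceiling")
        if preset.noise_scale > 0:
            img = rng.poisson(mean).astype(float) + rng.normal(0, READ_NOISE_SD, size=mean.shape)
            img = np.clip(img, 0, SATURATION_CEILING)
        else:
            img = mean
        chans.append(img)
    return ImageSet(donor=chans[0], acceptor=chans[1], fret=chans[2], metadata=meta)


def _truth_and_clean(
    preset: ScenePreset,
    cell: np.ndarray,
    mask: np.ndarray,
    density: np.ndarray,
    nfret_filament: float | None = None,
):
    nfret_fil = preset.nfret_filament if nfret_filament is None else nfret_filament
    unit = preset.noise_scale if preset.noise_scale > 0 else 1000.0
    total_density = CYTOSOL_DENSITY * cell + density
    clean_d = unit * total_density
    clean_a = ACCEPTOR_GAIN * clean_d
    nfret_truth = np.where(mask, nfret_fil, np.where(cell, preset.nfret_cytosol, 0.0))
    sensitized = (nfret_truth / 100.0) * np.sqrt(clean_d * clean_a)
    return clean_d, clean_a, sensitized, nfret_truth


def generate_filament_scene(preset: ScenePreset, seed: int) -> tuple[ImageSet, SceneTruth]:
    """Three-channel filament scene with per-pixel NFRET ground truth."""
    rng = np.random.default_rng(seed)
    cell, polylines, mask, density = _scene_geometry(preset, rng)
    clean_d, clean_a, sens, nfret_truth = _truth_and_clean(preset, cell, mask, density)
    images = _emit_channels(clean_d, clean_a, sens, preset, rng)
    truth = SceneTruth(
        filament_mask=mask,
        cell_mask=cell,
        filament_polylines=polylines,
        nfret_truth=nfret_truth,
        clean_donor=clean_d,
        clean_acceptor=clean_a,
    )
    return images, truth


def generate_calibration_scene(kind: str, preset: ScenePreset, seed: int) -> ImageSet:
    """Single-fluorophore reference scene for bleed-through calibration.

    ``kind`` is ``"donor-only"`` (FRET channel carries bleed_A·D) or
    ``"acceptor-only"`` (bleed_B·Acc); the other channel is background only.
    The filament-scene density spans a wide intensity range, which keeps the
    calibration regression well-conditioned.
    """
    if kind not in ("donor-only", "acceptor-only"):
        raise ValueError("kind must be 'donor-only' or 'acceptor-only'")
    rng = np.random.default_rng(seed)
    cell, _, mask, density = _scene_geometry(preset, rng)
    clean_d, clean_a, _, _ = _truth_and_clean(preset, cell, mask, density)
    zero = np.zeros_like(clean_d)
    if kind == "donor-only":
        return _emit_channels(clean_d, zero, zero, preset, rng)
    return _emit_channels(zero, clean_a, zero, preset, rng)


def loss_curve(n_frames: int, dt: float, loss_total: float) -> np.ndarray:
    """Smooth exponential acquisition-loss factor: L[0]=1, L[-1]=1−loss_total."""
    if loss_total <= 0:
        return np.ones(n_frames)
    t = np.arange(n_frames) * dt
    k = -np.log(1.0 - loss_total) / t[-1]
    return np.exp(-k * t)


ROI_RADIUS_PX = 8.0  # 2 um bleach-spot radius at 0.25 um/px
WHOLECELL_N_PIXELS = 20000  # pixels inside a typical whole-cell mask
WHOLECELL_MEAN_FRACTION = 0.6  # whole-cell mean intensity vs ROI pre-bleach


def _pixel_mean_noise(
    mean_trace: np.ndarray, n_pixels: int, rng: np.random.Generator
) -> np.ndarray:
    """Noisy mean intensity of ``n_pixels`` pixels sharing a per-pixel mean.

    Matches the statistics of averaging an ROI in a simulated image stack:
    Poisson shot noise pools over pixels, read noise averages down by
    sqrt(n_pixels).
    """
    pooled = rng.poisson(mean_trace * n_pixels) / n_pixels
    return pooled + rng.normal(0, READ_NOISE_SD / np.sqrt(n_pixels), mean_trace.shape)


def generate_frap_series(
    preset: ScenePreset,
    seed: int,
    n_traces: int,
    roi_radius_px: float = ROI_RADIUS_PX,
    wholecell_n_pixels: int = WHOLECELL_N_PIXELS,
) -> list[tuple[FRAPTrace, FRAPTruth]]:
    """Simulate FRAP experiments as (raw trace, ground truth) pairs.

    Each trace has ``preset.n_pre`` pre-bleach frames followed by
    ``preset.n_post`` post-bleach frames at ``preset.frame_interval``
    seconds. ROI and whole-cell series are pixel averages (a circular ROI
    of ``roi_radius_px`` and a whole-cell mask of ``wholecell_n_pixels``
    pixels), so shot noise pools over the averaged pixels exactly as it
    would when extracting the trace from a simulated image stack. The
    per-pixel pre-bleach ROI level is ``preset.noise_scale`` counts
    (noise disabled entirely when 0). Deterministic per (seed, trace index).
    """
    if n_traces < 1:
        raise ValueError("n_traces must be >= 1")
    a1s, a2s = preset.frap_fractions
    tau1, tau2 = preset.frap_taus
    f0 = preset.bleach_residual
    n_pre, n_post, dt = preset.n_pre, preset.n_post, preset.frame_interval
    n_frames = n_pre + n_post
    times = np.arange(n_frames) * dt
    L = loss_curve(n_frames, dt, preset.acquisition_loss_total)
    noisy = preset.noise_scale > 0
    f_pre = preset.noise_scale if noisy else 1000.0
    w_pre = WHOLECELL_MEAN_FRACTION * f_pre
    n_roi = max(1, round(np.pi * roi_radius_px**2))

    out = []
    for i in range(n_traces):
        rng = np.random.default_rng([seed, i])
        truth = FRAPTruth(
            A1_star=a1s, A2_star=a2s, tau1=tau1, tau2=tau2,
            bleach_residual=f0, loss_curve=L.copy(),
        )
        t_post = times[n_pre:] - times[n_pre]
        recovery = f0 + (1 - f0) * truth.g(t_post)
        roi = BACKGROUND + np.concatenate(
            [L[:n_pre] * f_pre, L[n_pre:] * f_pre * recovery]
        )
        cell = BACKGROUND + L * w_pre
        if noisy:
            roi = _pixel_mean_noise(roi, n_roi, rng)
            cell = _pixel_mean_noise(cell, wholecell_n_pixels, rng)
        out.append((FRAPTrace(time=times, roi_intensity=roi, wholecell_intensity=cell, n_pre=n_pre), truth))
    return out


def generate_nocodazole_timecourse(
    preset: ScenePreset,
    seed: int,
    timepoints: list[float],
    half_time_s: float = 600.0,
) -> list[tuple[float, ImageSet, SceneTruth]]:
    """Microtubule-disassembly time course after nocodazole addition.

    The on-filament NFRET excess over the cytosolic level halves every
    ``half_time_s`` seconds, and the filament network thins out on the same
    half-time (polylines are dropped), emulating progressive microtubule
    depolymerization. The frame at t = 0 is identical to
    :func:`generate_filament_scene` for the same seed.
    """
    tp = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(tp) < 0):
        raise ValueError("timepoints must be nondecreasing")
    out = []
    for t in tp:
        survival = 0.5 ** (t / half_time_s)
        nfret_t = preset.nfret_cytosol + (preset.nfret_filament - preset.nfret_cytosol) * survival
        rng = np.random.default_rng(seed)
        cell, polylines, mask, density = _scene_geometry(preset, rng, keep_fraction=survival)
        clean_d, clean_a, sens, nfret_truth = _truth_and_clean(
            preset, cell, mask, density, nfret_filament=nfret_t
        )
        images = _emit_channels(clean_d, clean_a, sens, preset, rng)
        truth = SceneTruth(
            filament_mask=mask,
            cell_mask=cell,
            filament_polylines=polylines,
            nfret_truth=nfret_truth,
            clean_donor=clean_d,
            clean_acceptor=clean_a,
        )
        out.append((float(t), images, truth))
    return out
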