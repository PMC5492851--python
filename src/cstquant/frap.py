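"""FRAP trace normalization and two-phase exponential association fitting.

A FRAP experiment records a pre-bleach phase (baseline), a bleach event in a
circular cytoplasmic ROI, and a post-bleach recovery phase. Raw ROI traces
are normalized in four steps:

1. background subtraction (ROI and whole-cell series);
2. division by the mean pre-bleach ROI intensity;
3. acquisition-photobleaching correction — each post-bleach point is
   multiplied by (mean pre-bleach whole-cell) / (whole-cell at that frame),
   so slow fluorescence loss from repeated imaging cancels;
4. the first post-bleach value v0 is subtracted and the trace rescaled by
   1/(1 − v0), so 0 marks the bleach floor and 1 full recovery.

The normalized recovery is fitted with the two-phase exponential
association model

    y(t) = y0 + A1* (1 − exp(−t/τ1)) + A2* (1 − exp(−t/τ2)),

whose amplitudes are attributed to a fast freely-diffusing pool (τ1) and a
slower pool exchanging with a bound state (τ2). Derived quantities are the
overall mobile fraction Mob = A1* + A2* and the normalized shares
A1 = A1*/(A1* + A2*), A2 = 1 − A1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares


class CorruptTraceError(ValueError):
    """Whole-cell intensity is non-positive after background subtraction."""


class UndefinedFractionsError(ZeroDivisionError):
    """Both amplitudes are zero; normalized shares are undefined."""


@dataclass
class FRAPTrace:
    """Raw ROI and whole-cell intensity series of one FRAP experiment.

    ``n_pre`` pre-bleach frames come first; frame ``n_pre`` is the first
    post-bleach frame (the bleach event itself is not recorded).
    """

    time: np.ndarray
    roi_intensity: np.ndarray
    wholecell_intensity: np.ndarray
    n_pre: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.roi_intensity = np.asarray(self.roi_intensity, dtype=float)
        self.wholecell_intensity = np.asarray(self.wholecell_intensity, dtype=float)
        n = self.time.size
        if self.roi_intensity.size != n or self.wholecell_intensity.size != n:
            raise ValueError("time, roi and whole-cell series must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 1 <= self.n_pre < n:
            raise ValueError("n_pre must leave at least one post-bleach frame")

    @property
    def bleach_index(self) -> int:
        return self.n_pre

    def to_frame(self) -> pd.DataFrame:
        phase = np.where(np.arange(self.time.size) < self.n_pre, "pre", "post")
        return pd.DataFrame(
            {
                "time_s": self.time,
                "roi_intensity": self.roi_intensity,
                "wholecell_intensity": self.wholecell_intensity,
                "phase": phase,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FRAPTrace":
        n_pre = int((df["phase"] == "pre").sum())
        return cls(
            time=df["time_s"].to_numpy(),
            roi_intensity=df["roi_intensity"].to_numpy(),
            wholecell_intensity=df["wholecell_intensity"].to_numpy(),
            n_pre=n_pre,
        )


@dataclass
class NormalizedTrace:
    """Recovery trace after four-step normalization.

    ``time`` starts at 0 at the first post-bleach frame; ``value[0]`` is 0
    by construction.
    """

    time: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.size != self.value.size:
            raise ValueError("time and value must have equal length")


@dataclass
class FRAPFit:
    """Two-phase exponential association fit with derived fractions."""

    y0: float
    A1_star: float
    tau1: float
    A2_star: float
    tau2: float
    rss: float
    converged: bool
    ill_conditioned: bool = False
    A1: float = field(init=False)
    A2: float = field(init=False)
    Mob_calc: float = field(init=False)

    def __post_init__(self) -> None:
        # canonical component order: tau1 <= tau2
        if self.tau1 > self.tau2:
            self.tau1, self.tau2 = self.tau2, self.tau1
            self.A1_star, self.A2_star = self.A2_star, self.A1_star
        total = self.A1_star + self.A2_star
        if total > 0:
            self.A1, self.A2, self.Mob_calc = derive_fractions(self.A1_star, self.A2_star)
        else:  # fully immobile / failed fit: shares undefined
            self.A1, self.A2, self.Mob_calc = float("nan"), float("nan"), 0.0


def extract_roi_trace(
    stack: np.ndarray,
    times: np.ndarray,
    center: tuple[float, float],
    radius: float,
    wholecell_mask: np.ndarray,
    n_pre: int,
) -> FRAPTrace:
    """Mean intensity per frame over a circular ROI and over a whole-cell mask.

    ``stack`` is (frames, rows, cols); ``center`` is (row, col) in pixels.
    A radius of 0 selects the single nearest pixel.
    """
    stack = np.asarray(stack, dtype=float)
    nr, nc = stack.shape[1:]
    cy, cx = center
    if not (0 <= cy < nr and 0 <= cx < nc):
        raise ValueError(f"ROI center {center} outside image of shape {(nr, nc)}")
    yy, xx = np.ogrid[:nr, :nc]
    roi = (yy - cy) ** 2 + (xx - cx) ** 2 <= max(radius, 0.5) ** 2
    if not roi.any():
        roi[int(round(cy)), int(round(cx))] = True
    wholecell_mask = np.asarray(wholecell_mask, dtype=bool)
    return FRAPTrace(
        time=times,
        roi_intensity=stack[:, roi].mean(axis=1),
        wholecell_intensity=stack[:, wholecell_mask].mean(axis=1),
        n_pre=n_pre,
    )


def normalize_trace(trace: FRAPTrace, background: float = 0.0, background_wholecell: float | None = None) -> NormalizedTrace:
    """Apply the four-step FRAP normalization (see module docstring)."""
    if background_wholecell is None:
        background_wholecell = background
    roi = trace.roi_intensity - background
    cell = trace.wholecell_intensity - background_wholecell
    if np.any(cell <= 0):
        raise CorruptTraceError("whole-cell intensity <= 0 after background subtraction")
    n_pre = trace.n_pre

    pre_roi = roi[:n_pre].mean()
    if pre_roi <= 0:
        raise CorruptTraceError("non-positive mean pre-bleach ROI intensity")
    norm = roi / pre_roi

    # time-resolved whole-cell loss correction on the post-bleach frames
    pre_cell = cell[:n_pre].mean()
    post = norm[n_pre:] * (pre_cell / cell[n_pre:])

    v0 = post[0]
    if v0 >= 1:
        raise CorruptTraceError("first post-bleach value >= 1; no bleach depth to normalize")
    post = (post - v0) / (1.0 - v0)

    t = trace.time[n_pre:] - trace.time[n_pre]
    return NormalizedTrace(time=t, value=post)


def two_phase_model(t: np.ndarray, y0: float, a1: float, tau1: float, a2: float, tau2: float) -> np.ndarray:
    """y0 + A1*(1 − exp(−t/τ1)) + A2*(1 − exp(−t/τ2))."""
    t = np.asarray(t, dtype=float)
    return y0 + a1 * (1.0 - np.exp(-t / tau1)) + a2 * (1.0 - np.exp(-t / tau2))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    plateau = float(np.mean(y[max(1, y.size * 9 // 10) :]))
    plateau = max(plateau, 1e-3)
    # tau1 guess: time to reach 25% of the final plateau
    above = np.nonzero(y >= 0.25 * plateau)[0]
    tau1 = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(t[-1]) / 20
    tau1 = max(tau1, 1e-3)
    return np.array([0.0, 0.3 * plateau, tau1, 0.7 * plateau, 8.0 * tau1])


def fit_two_phase(
    trace: NormalizedTrace,
    n_restarts: int = 3,
    tau_ratio_floor: float = 1.5,
    seed: int = 0,
) -> FRAPFit:
    """Bounded nonlinear least-squares fit of the two-phase recovery model.

    Components are relabeled after fitting so tau1 <= tau2. On failure the
    fit is retried from ``n_restarts`` perturbed initializations; persistent
    failure is reported via ``converged=False`` rather than an exception.
    A fit with tau2/tau1 below ``tau_ratio_floor`` is flagged
    ``ill_conditioned`` (the two components are not separable).
    """
    t, y = trace.time, trace.value
    if t.size < 7:
        raise ValueError("need at least 7 points to fit 5 parameters")
    x0 = _initial_guess(t, y)
    lo = np.array([-1.0, 0.0, 1e-6, 0.0, 1e-6])
    hi = np.array([1.0, 2.0, 1e6, 2.0, 1e6])
    x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)

    def resid(p):
        return two_phase_model(t, *p) - y

    rng = np.random.default_rng(seed)
    best, best_cost = None, np.inf
    starts = [x0]
    for _ in range(n_restarts):
        pert = x0 * rng.uniform(0.5, 2.0, size=x0.size)
        pert[0] = x0[0] + rng.normal(0, 0.05)
        starts.append(np.clip(pert, lo + 1e-9, hi - 1e-9))
    converged = False
    for s in starts:
        try:
            res = least_squares(resid, s, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if res.cost < best_cost:
            best, best_cost = res, res.cost
        if res.success:
            converged = True
    if best is None:
        return FRAPFit(0.0, 0.0, 1.0, 0.0, 2.0, rss=np.inf, converged=False)
    y0, a1, tau1, a2, tau2 = best.x
    rss = float(np.sum(resid(best.x) ** 2))
    lo_t, hi_t = sorted((tau1, tau2))
    ill = hi_t / lo_t < tau_ratio_floor or min(a1, a2) < 1e-9
    return FRAPFit(
        y0=float(y0), A1_star=float(a1), tau1=float(tau1),
        A2_star=float(a2), tau2=float(tau2),
        rss=rss, converged=bool(converged), ill_conditioned=bool(ill),
    )


def derive_fractions(A1_star: float, A2_star: float) -> tuple[float, float, float]:
    """Normalized shares (A1, A2) and mobile fraction Mob = A1* + A2*."""
    total = A1_star + A2_star
    if total <= 0:
        raise UndefinedFractionsError("A1* + A2* must be positive")
    return A1_star / total, A2_star / total, total


def summarize_condition(fits: list[FRAPFit], label: str) -> pd.DataFrame:
    """Mean ± SEM of the fit parameters across converged traces.

    Non-converged fits are excluded and counted in ``n_failed``.
    """
    ok = [f for f in fits if f.converged]
    if not ok:
        raise ValueError(f"no converged fits for condition {label!r}")
    if len(ok) < 2:
        raise ValueError("need at least 2 converged fits to summarize")
    cols = ["Mob_calc", "A1", "A2", "tau1", "tau2", "A1_star", "A2_star"]
    data = {c: np.array([getattr(f, c) for f in ok]) for c in cols}
    rows = []
    for c in cols:
        v = data[c]
        rows.append(
            {
                "condition": label,
                "parameter": c,
                "mean": v.mean(),
                "sem": v.std(ddof=1) / np.sqrt(v.size),
                "sd": v.std(ddof=1),
                "n": v.size,
                "n_failed": len(fits) - len(ok),
            }
        )
    return pd.DataFrame(rows)
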