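"""Named ground-truth parameter sets for simulated experimental conditions.

Each :class:`ScenePreset` bundles every number the synthetic generator needs
to emit a condition: the on-filament and cytosolic NFRET levels (on the
conventional ×100 scale), the spectral bleed-through fractions of donor (A)
and acceptor (B) into the FRET channel, and the FRAP kinetics — amplitudes
A1*, A2* and time constants tau1 < tau2 of the two-phase exponential
association model, plus acquisition details (bleach residual, cumulative
acquisition-photobleaching loss, frame counts and interval).

The registry presets encode the measured parameter values for the
conformational-sensitive Tau sensor (CST) under each condition: untreated,
nocodazole, paclitaxel, and the P301L / ΔK280 / AT8 pseudo-phosphorylation
mutants, so that parameter-recovery tests run against known truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


class UnknownPresetError(KeyError):
    """Raised when a preset name is not in the registry."""


@dataclass(frozen=True)
class ScenePreset:
    """Ground-truth parameters for one simulated condition.

    NFRET values are on the ×100 scale (dimensionless); taus in seconds;
    bleed and loss terms are fractions. ``noise_scale`` is the photon count
    at the clean-signal maximum (0 disables noise entirely).
    """

    name: str
    nfret_filament: float
    nfret_cytosol: float
    bleed_A: float = 0.1
    bleed_B: float = 0.25
    frap_fractions: tuple[float, float] = (0.21128, 0.54872)  # (A1*, A2*)
    frap_taus: tuple[float, float] = (4.9, 35.2)  # (tau1, tau2) s
    bleach_residual: float = 0.2
    acquisition_loss_total: float = 0.08
    noise_scale: float = 1000.0
    field_size: int = 512
    frame_interval: float = 1.0
    n_pre: int = 10
    n_post: int = 120
    notes: str = ""

    def __post_init__(self) -> None:
        a1s, a2s = self.frap_fractions
        t1, t2 = self.frap_taus
        if not (0 <= self.bleed_A < 1 and 0 <= self.bleed_B < 1):
            raise ValueError("bleed fractions must lie in [0, 1)")
        if t1 >= t2:
            raise ValueError("frap_taus must satisfy tau1 < tau2")
        if a1s < 0 or a2s < 0 or a1s + a2s > 1 + 1e-12:
            raise ValueError("amplitudes must be >= 0 with A1* + A2* <= 1")
        if not (self.nfret_filament >= self.nfret_cytosol >= 0):
            raise ValueError("need nfret_filament >= nfret_cytosol >= 0")
        if not (0 <= self.bleach_residual < 1):
            raise ValueError("bleach_residual must lie in [0, 1)")
        if not (0 <= self.acquisition_loss_total <= 0.2):
            raise ValueError("acquisition_loss_total must lie in [0, 0.2]")

    @property
    def mobile_fraction(self) -> float:
        return self.frap_fractions[0] + self.frap_fractions[1]

    def with_(self, **changes) -> "ScenePreset":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


def _frap(mob: float, share_fast: float) -> tuple[float, float]:
    """(A1*, A2*) from an overall mobile fraction and its fast-phase share."""
    a1s = mob * share_fast
    return (a1s, mob - a1s)


_REGISTRY: dict[str, ScenePreset] = {}


def _register(p: ScenePreset) -> ScenePreset:
    _REGISTRY[p.name] = p
    return p


# Reference calibration condition: typical cross-talk fractions A=0.1, B=0.25
# measured from donor-only / acceptor-only expressing cells.
_register(
    ScenePreset(
        name="paper-typical-bleedthrough",
        nfret_filament=14.5,
        nfret_cytosol=2.0,
        bleed_A=0.1,
        bleed_B=0.25,
        notes="typical donor/acceptor leak-through fractions A=0.1, B=0.25",
    )
)

# Untreated CST reporter cells: on-microtubule NFRET 14.5; mobile fraction
# 0.76 split 27.8% diffusive (tau1=4.9 s) / 72.2% microtubule-exchange
# (tau2=35.2 s).
_register(
    ScenePreset(
        name="CST-untreated",
        nfret_filament=14.5,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.76, 0.278),
        frap_taus=(4.9, 35.2),
        notes="untreated: Mob 0.76, diffusive share 0.278, taus 4.9/35.2 s",
    )
)

# Nocodazole-depolymerized microtubules: Tau soluble, FRET lost, mobility up
# (Mob 0.91, diffusive share 0.53).
_register(
    ScenePreset(
        name="CST-nocodazole",
        nfret_filament=2.5,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.91, 0.53),
        notes="nocodazole: Mob 0.91, diffusive share 0.53; NFRET collapsed",
    )
)

# Paclitaxel competes Tau off intact microtubules: Mob 0.93, share 0.55.
_register(
    ScenePreset(
        name="CST-paclitaxel",
        nfret_filament=2.5,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.93, 0.55),
        notes="paclitaxel: Mob 0.93, diffusive share 0.55; NFRET collapsed",
    )
)

# P301L mutant: extended conformation on microtubules halves NFRET
# (14.5 -> 8); Mob 0.85 with doubled diffusive share 0.47.
_register(
    ScenePreset(
        name="CST-P301L",
        nfret_filament=8.0,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.85, 0.47),
        notes="P301L: NFRET 8, Mob 0.85, diffusive share 0.47",
    )
)

# ΔK280 mutant: recovery very similar to P301L.
_register(
    ScenePreset(
        name="CST-dK280",
        nfret_filament=8.0,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.85, 0.47),
        notes="ΔK280: kinetics as P301L",
    )
)

# AT8 pseudo-phosphorylation mutant: slower recovery, Mob 0.54; diffusive
# share kept at the untreated value (not separately measured).
_register(
    ScenePreset(
        name="CST-AT8mut",
        nfret_filament=10.0,
        nfret_cytosol=2.0,
        frap_fractions=_frap(0.54, 0.278),
        notes="AT8mut: Mob 0.54",
    )
)


def list_presets() -> dict[str, ScenePreset]:
    """Return the registry of named presets (a copy; safe to mutate)."""
    return dict(_REGISTRY)


def get_preset(name: str) -> ScenePreset:
    """Look up a preset by name, raising :class:`UnknownPresetError` if absent."""
    try:
        return _REGISTRY[name]
    except KeyError:
        known = ", ".join(sorted(_REGISTRY))
        raise UnknownPresetError(f"unknown preset {name!r}; known: {known}") from None
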