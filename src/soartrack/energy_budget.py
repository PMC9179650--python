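"""Climb/glide distance budget of a soaring migration leg.

The question the budget answers: did the altitude harvested while circling,
plus the ambient tailwind, provide enough forward progress to cover the
direct migration distance without flapping?  Circling is assumed to
contribute no airspeed-driven progress — during the total circling time
``Tc`` the bird only drifts downwind, giving ``Dc = tailwind * Tc``.  During
the gliding time ``Tg`` it advances at the mean glide ground speed,
``Dg = GS_glide * Tg``.  The leg is energetically sufficient when
``Dt = Dc + Dg >= direct_distance``.

The companion L/D check converts total glide altitude loss into a still-air
glide range (``|loss| * L/D``) and compares the achieved ground distance
against it; ratios above 1 are expected with a tailwind and are flagged as
such, not as errors.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._errors import ContractError
from .aero import AeroConfig
from .maneuvers import ManeuverSummary

__all__ = ["EnergyBudget", "compute_energy_budget", "budget_from_summary",
           "LDConsistencyReport", "ld_consistency_check"]


@dataclass(frozen=True)
class EnergyBudget:
    """Climb/glide budget quantities (SI internally; km properties for display)."""

    height_gain_m: float          # H: total positive circling altitude gain
    time_circling_s: float        # Tc
    time_gliding_s: float         # Tg
    tailwind_ms: float
    mean_glide_ground_speed_ms: float
    lift_drag_ratio: float
    circling_progress_m: float    # Dc = tailwind * Tc
    gliding_progress_m: float     # Dg = GS_glide * Tg
    total_progress_m: float       # Dt = Dc + Dg
    direct_distance_m: float
    sufficient: bool              # Dt >= direct distance
    required_sink_at_ld_ms: float  # GS_glide / (L/D): still-air sink implied by L/D
    source: str = "explicit"      # "explicit" (printed constants) or "summary"

    @property
    def circling_progress_km(self) -> float:
        return self.circling_progress_m / 1000.0

    @property
    def gliding_progress_km(self) -> float:
        return self.gliding_progress_m / 1000.0

    @property
    def total_progress_km(self) -> float:
        return self.total_progress_m / 1000.0


def compute_energy_budget(*, tailwind: float, time_circling_s: float, time_gliding_s: float,
                          mean_glide_ground_speed: float, direct_distance_m: float,
                          height_gain_m: float = 0.0, cfg: AeroConfig | None = None,
                          source: str = "explicit") -> EnergyBudget:
    """Apply the budget identities to explicit inputs (times in seconds)."""
    cfg = cfg or AeroConfig()
    if time_circling_s < 0 or time_gliding_s < 0:
        raise ContractError("times must be non-negative")
    if tailwind < 0:
        raise ContractError("tailwind must be non-negative")
    dc = tailwind * time_circling_s
    dg = mean_glide_ground_speed * time_gliding_s
    dt = dc + dg
    return EnergyBudget(
        height_gain_m=height_gain_m, time_circling_s=time_circling_s,
        time_gliding_s=time_gliding_s, tailwind_ms=tailwind,
        mean_glide_ground_speed_ms=mean_glide_ground_speed,
        lift_drag_ratio=cfg.lift_drag_ratio, circling_progress_m=dc,
        gliding_progress_m=dg, total_progress_m=dt,
        direct_distance_m=direct_distance_m, sufficient=bool(dt >= direct_distance_m),
        required_sink_at_ld_ms=mean_glide_ground_speed / cfg.lift_drag_ratio,
        source=source)


def budget_from_summary(summary: ManeuverSummary, tailwind: float, direct_distance_m: float,
                        cfg: AeroConfig | None = None) -> EnergyBudget:
    """Budget with Tc, Tg, glide speed and H recomputed from a maneuver summary."""
    return compute_energy_budget(
        tailwind=tailwind,
        time_circling_s=summary.time_circling_s,
        time_gliding_s=summary.time_glide_down_s,
        mean_glide_ground_speed=summary.mean_glide_down_speed,
        direct_distance_m=direct_distance_m,
        height_gain_m=summary.circling_height_gain_m,
        cfg=cfg, source="summary")


@dataclass(frozen=True)
class LDConsistencyReport:
    """Still-air glide range implied by L/D versus the achieved ground distance."""

    still_air_range_m: float
    glide_ground_distance_m: float
    achieved_ratio: float
    tailwind_assisted: bool  # ratio > 1: expected with tailwind, not an error


def ld_consistency_check(losses_m: float, lift_drag_ratio: float,
                         glide_ground_distance_m: float) -> LDConsistencyReport:
    """Compare achieved glide ground distance against |losses| * L/D."""
    if lift_drag_ratio <= 0:
        raise ContractError("lift_drag_ratio must be positive")
    still_air = abs(losses_m) * lift_drag_ratio
    ratio = glide_ground_distance_m / still_air if still_air > 0 else 0.0
    return LDConsistencyReport(still_air_range_m=still_air,
                               glide_ground_distance_m=glide_ground_distance_m,
                               achieved_ratio=ratio, tailwind_assisted=ratio > 1.0)
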