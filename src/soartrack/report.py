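"""Plain-text/markdown rendering of the maneuver summary and energy budget.

The maneuver table lists the labels as columns with one row per statistic;
the budget table lists one parameter per row with value and provenance
(recomputed from the classification vs supplied explicitly).  Distances are
shown in km to one decimal, rates to one decimal.
"""

from __future__ import annotations

from typing import Sequence

from .energy_budget import EnergyBudget
from .maneuvers import ManeuverSummary

LABEL_TITLES = {
    "circle_ccw": "CC Circle", "circle_cw": "C Circle", "meander": "Meander",
    "glide_up": "Glide Up", "glide_down": "Glide Down",
}
ROW_TITLES = {
    "n_segments": ("Number of classified segments", "{:.0f}"),
    "mean_duration_s": ("Average segment time (s)", "{:.1f}"),
    "mean_altitude_change_m": ("Average altitude change (m)", "{:.1f}"),
    "mean_climb_rate_ms": ("Average climb/descent rate (m/s)", "{:.1f}"),
    "mean_ground_speed_ms": ("Average ground speed (m/s)", "{:.1f}"),
    "total_time_min": ("Total time in maneuver (min)", "{:.1f}"),
    "percent_classified_time": ("Percent of classified time", "{:.1f}"),
    "net_altitude_change_m": ("Net altitude change for maneuver (m)", "{:.1f}"),
}


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    out = ["| " + " | ".join(header) + " |",
           "|" + "|".join("---" for _ in header) + "|"]
    for r in rows:
        out.append("| " + " | ".join(r) + " |")
    return "\n".join(out)


def render_maneuver_table(summary: ManeuverSummary) -> str:
    labels = [l for l in summary.table.columns]
    header = [""] + [LABEL_TITLES.get(l, l) for l in labels]
    rows = []
    for key, (title, fmt) in ROW_TITLES.items():
        row = [title]
        for l in labels:
            v = summary.stat(l, key)
            if key == "mean_ground_speed_ms" and l.startswith(("circle", "meander")):
                row.append("n/a")
            else:
                row.append(fmt.format(v) if v == v else "n/a")
        rows.append(row)
    note = (f"\nUnclassified/missing time: {summary.unclassified_time_s / 60.0:.1f} min "
            "(excluded from percentages).")
    return _md_table(header, rows) + note


def render_budget_table(budget: EnergyBudget, tailwind_source: str | None = None) -> str:
    src = budget.source
    tw_src = tailwind_source or src
    rows = [
        ["Height gain during circling (H)", f"{budget.height_gain_m:.0f} m", src],
        ["Time circling (Tc)", f"{budget.time_circling_s / 60.0:.1f} min", src],
        ["Time down gliding (Tg)", f"{budget.time_gliding_s / 60.0:.1f} min", src],
        ["Tailwind speed at flight level", f"{budget.tailwind_ms:.1f} m/s", tw_src],
        ["Average ground speed during glides", f"{budget.mean_glide_ground_speed_ms:.1f} m/s", src],
        ["Lift/drag ratio (L/D)", f"{budget.lift_drag_ratio:.0f}:1", "assumed"],
        ["Dc: progress distance during circling", f"{budget.circling_progress_km:.1f} km", "calculated"],
        ["Dg: progress distance during gliding", f"{budget.gliding_progress_km:.1f} km", "calculated"],
        ["Dt: total climb-and-glide distance", f"{budget.total_progress_km:.1f} km", "calculated"],
        ["Direct migration distance", f"{budget.direct_distance_m / 1000.0:.1f} km", "measured"],
        ["Sufficient (Dt >= direct)", "yes" if budget.sufficient else "no", "calculated"],
        ["Still-air sink implied by L/D", f"{budget.required_sink_at_ld_ms:.2f} m/s", "calculated"],
    ]
    return _md_table(["Parameter", "Value", "Source"], rows)


def render_report(summary: ManeuverSummary, budget: EnergyBudget, winds: Sequence = (),
                  path_stats=None, clusters: Sequence = (),
                  tailwind_source: str | None = None) -> str:
    parts = ["# Soaring-flight analysis report", ""]
    if path_stats is not None:
        parts += [
            f"Path distance {path_stats.path_distance / 1000.0:.1f} km, "
            f"direct distance {path_stats.direct_distance / 1000.0:.1f} km, "
            f"duration {path_stats.duration / 60.0:.1f} min, "
            f"average speed {path_stats.average_speed:.1f} m/s.", ""]
    if clusters:
        gains = sum(c.total_gain for c in clusters)
        parts += [f"{len(clusters)} circle clusters (>= 3 consecutive circles), "
                  f"net cluster altitude gain {gains:.0f} m.", ""]
    parts += ["## Flight maneuvers", "", render_maneuver_table(summary), ""]
    if winds:
        tas = sum(w.tas for w in winds) / len(winds)
        ws = sum(w.wind_speed for w in winds) / len(winds)
        parts += [f"Wind estimated from {len(winds)} circles: mean TAS {tas:.1f} m/s, "
                  f"mean wind speed {ws:.1f} m/s.", ""]
    parts += ["## Climb/glide energy budget", "", render_budget_table(budget, tailwind_source), ""]
    return "\n".join(parts)
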