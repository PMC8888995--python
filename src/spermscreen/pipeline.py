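"""End-to-end screen rehearsal: plate simulation through hit calls.

Wells are processed one at a time (simulate both fields, link, compute
kinematics, summarize), so a full 384-well plate never has to hold all
of its detections in memory simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .kinematics import ClassThresholds, kinematics_table, summarize_well
from .plates import call_hits, normalize_plate, summaries_to_table
from .synthetic import PlateSimulation
from .tracking import filter_tracks, link_detections

__all__ = ["ScreenResult", "run_screen"]


@dataclass
class ScreenResult:
    """Everything the primary screen produces for one plate."""

    well_summaries: pd.DataFrame
    normalized: pd.DataFrame
    hit_calls: pd.DataFrame
    layout: pd.DataFrame


def run_screen(
    plate: PlateSimulation,
    cutoff_percent_increase: float = 20.0,
    max_displacement: float | None = None,
    memory: int = 1,
    min_track_length: int = 5,
    thresholds: ClassThresholds = ClassThresholds(),
    plate_id: str = "PLATE01",
) -> ScreenResult:
    """Process one simulated plate through the full primary screen.

    ``max_displacement`` defaults to twice the expected maximum
    per-frame displacement of a progressive cell (its speed mean plus
    3 SD, over one frame interval).
    """
    pop = plate.config.population
    if max_displacement is None:
        pm = plate.class_params["PM"]
        top_speed = pm.speed_mean + 3.0 * pm.speed_sd
        # compound wells move faster; budget for the strongest effect
        top_mult = max(
            (e.max_speed_multiplier for e in plate.config.effects.values()), default=1.0
        )
        max_displacement = 2.0 * top_mult * top_speed / pop.frame_rate

    summaries = []
    for well in plate.wells:
        field_records = []
        for f in range(plate.config.n_fields_per_well):
            sim = plate.field(well, f)
            linked = link_detections(sim.detections, max_displacement, memory=memory)
            linked = filter_tracks(linked, min_track_length)
            field_records.append(kinematics_table(linked, pop.frame_rate, thresholds))
        summaries.append(summarize_well(well, field_records))

    summary_df = summaries_to_table(summaries)
    normalized = normalize_plate(summary_df, plate.layout, plate_id=plate_id)
    hits = call_hits(normalized, cutoff_percent_increase)
    return ScreenResult(
        well_summaries=summary_df,
        normalized=normalized,
        hit_calls=hits,
        layout=plate.layout,
    )
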