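"""Plate normalization, hit calling and library-level reporting.

Every compound well is normalized to the in-plate vehicle controls:

    % of control = (well VCL median / DMSO median) x 100

where the DMSO median is the median of the (default 16) DMSO control
wells' own well values on the same plate.  A compound is a primary hit
when its % of control is at least 100 plus the library's cutoff
(20 or 40 percentage points); the boundary is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .kinematics import WellSummary

__all__ = [
    "HitCall",
    "LibraryReport",
    "call_hits",
    "dmso_reference",
    "library_report",
    "library_totals",
    "normalize_plate",
    "percent_of_control",
    "summaries_to_table",
]


def summaries_to_table(summaries: Iterable[WellSummary]) -> pd.DataFrame:
    """Stack :class:`~spermscreen.kinematics.WellSummary` objects into a
    well-summary table (columns well, well_value, valid, n_tracks)."""
    rows = [
        (s.well, s.well_value, s.valid, sum(s.n_tracks)) for s in summaries
    ]
    return pd.DataFrame(rows, columns=["well", "well_value", "valid", "n_tracks"])


def dmso_reference(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    pooled: bool = False,
) -> float:
    """Median well value of the plate's DMSO control wells, in um/s.

    ``well_summaries`` needs columns well, well_value (and optionally
    valid); ``layout`` needs well, role.  Invalid control wells are
    excluded; a plate with no valid control well is rejected.  The
    default reads "median of all control wells" as the median of the 16
    per-well values; ``pooled=True`` is a placeholder for the
    pooled-track alternative and requires per-track input upstream
    (well values built with ``summarize_well(..., pool_fields=True)``).
    """
    controls = set(layout.loc[layout["role"] == "control", "well"])
    sel = well_summaries[well_summaries["well"].isin(controls)]
    if "valid" in sel.columns:
        sel = sel[sel["valid"].astype(bool)]
    values = sel["well_value"].to_numpy(dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("plate rejected: no valid DMSO control wells")
    del pooled  # semantic choice lives upstream in summarize_well
    return float(np.median(values))


def percent_of_control(well_value, reference: float):
    """(well value / DMSO reference) x 100; scalar or array."""
    if not np.isfinite(reference) or reference <= 0:
        raise ValueError("DMSO reference must be > 0")
    out = np.asarray(well_value, dtype=float) / reference * 100.0
    return float(out) if np.isscalar(well_value) else out


def normalize_plate(
    well_summaries: pd.DataFrame,
    layout: pd.DataFrame,
    plate_id: str = "",
) -> pd.DataFrame:
    """Normalize every valid well of one plate to its DMSO reference.

    Returns columns plate_id, well, role, compound_id,
    percent_of_control (controls included so their scatter around 100
    can be inspected).
    """
    ref = dmso_reference(well_summaries, layout)
    merged = well_summaries.merge(
        layout[["well", "role", "compound_id"]], on="well", how="inner"
    )
    if "valid" in merged.columns:
        merged = merged[merged["valid"].astype(bool)]
    merged = merged[merged["role"] != "empty"].copy()
    merged["percent_of_control"] = percent_of_control(
        merged["well_value"].to_numpy(dtype=float), ref
    )
    merged.insert(0, "plate_id", plate_id)
    return merged[["plate_id", "well", "role", "compound_id", "percent_of_control"]]


@dataclass(frozen=True)
class HitCall:
    compound_id: str
    percent_of_control: float
    cutoff_percent_increase: float
    is_hit: bool


def call_hits(
    normalized: pd.DataFrame,
    cutoff_percent_increase: float,
) -> pd.DataFrame:
    """Call motility-enhancing hits among compound wells.

    A compound is a hit iff percent_of_control >= 100 + cutoff
    (inclusive boundary).  Control wells are excluded.  Returns columns
    compound_id, percent_of_control, cutoff_percent_increase, is_hit.
    """
    if cutoff_percent_increase <= 0:
        raise ValueError("cutoff must be > 0")
    sel = normalized
    if "role" in sel.columns:
        sel = sel[sel["role"] == "compound"]
    out = sel[["compound_id", "percent_of_control"]].copy()
    out["cutoff_percent_increase"] = float(cutoff_percent_increase)
    out["is_hit"] = out["percent_of_control"] >= 100.0 + cutoff_percent_increase
    return out.reset_index(drop=True)


def _round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LibraryReport:
    library_id: str
    n_compounds: int
    n_hits: int
    hit_rate_percent: float


def library_report(
    hits: "pd.DataFrame | int",
    library_id: str,
    n_compounds: int,
) -> LibraryReport:
    """Library-level hit summary: rate = 100 * hits / compounds, one
    decimal, round half-up (the precision screening tables report).

    ``hits`` is either a hit-call table (is_hit column) or directly the
    hit count.
    """
    if n_compounds <= 0:
        raise ValueError("n_compounds must be > 0")
    n_hits = int(hits["is_hit"].sum()) if isinstance(hits, pd.DataFrame) else int(hits)
    if n_hits < 0 or n_hits > n_compounds:
        raise ValueError("hit count must be within [0, n_compounds]")
    rate = _round_half_up(100.0 * n_hits / n_compounds, 1)
    return LibraryReport(library_id, int(n_compounds), n_hits, rate)


def library_totals(reports: Sequence[LibraryReport]) -> dict:
    """Aggregate several library reports.

    A single "total" hit rate is ambiguous, so both views are reported
    explicitly: the pooled rate (total hits / total compounds) and the
    unweighted mean of the per-library rates.
    """
    n_compounds = sum(r.n_compounds for r in reports)
    n_hits = sum(r.n_hits for r in reports)
    return {
        "n_compounds": n_compounds,
        "n_hits": n_hits,
        "pooled_hit_rate_percent": _round_half_up(100.0 * n_hits / n_compounds, 1),
        "mean_of_library_rates_percent": _round_half_up(
            float(np.mean([r.hit_rate_percent for r in reports])), 1
        ),
    }
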