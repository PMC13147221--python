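"""Modelled documentation-time calculation.

Compares the time a clinician would need to type the final notes manually
against the modelled time to produce them with the AI scribe, which is the
sum of three components:

* generation — a constant per-note machine generation time,
* review — reading the AI draft at an adult reading speed,
* editing — typing the added plus deleted words at the clinician's
  typing speed.

Both times derive from five aggregate corpus counts: total words of the final
EMR notes (``w_final``), total words of the initial AI notes (``w_ai``),
words added (``w_added``), words deleted (``w_deleted``), and the number of
notes (``n_notes``). These are independent inputs, not derived from one
another.

Two reporting modes are provided. ``exact`` keeps full precision throughout.
``paper_rounding`` rounds each component to one decimal hour *before*
summation and computes savings and efficiency from the rounded figures — the
arithmetic style of the published study figures (e.g. 0.7 + 3.1 + 6.5 =
10.3 h), which differs slightly from exact arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from pydantic import BaseModel, Field

__all__ = [
    "TimeModelParams",
    "CorpusCounts",
    "TimeReport",
    "round_half_up",
    "manual_typing_time",
    "ai_assisted_time",
    "savings_and_efficiency",
    "time_report",
    "paper_rounding_report",
]

EXACT = "exact"
PAPER_ROUNDING = "paper_rounding"


class TimeModelParams(BaseModel):
    """Speed and generation-time parameters.

    Defaults: 52 WPM for an average typist and 65 WPM for a fast typist,
    238 WPM adult reading speed, and 10 s of machine generation per note.
    """

    v_type_avg: float = Field(default=52.0, gt=0)
    v_type_fast: float = Field(default=65.0, gt=0)
    v_read: float = Field(default=238.0, gt=0)
    t_gen_per_note: float = Field(default=10.0, ge=0)


class CorpusCounts(BaseModel):
    """The five aggregate counts the time model consumes."""

    w_final: int = Field(ge=0)
    w_ai: int = Field(ge=0)
    w_added: int = Field(ge=0)
    w_deleted: int = Field(ge=0)
    n_notes: int = Field(ge=0)

    @property
    def w_edited(self) -> int:
        return self.w_added + self.w_deleted


@dataclass(frozen=True)
class TimeReport:
    """Component and total documentation times for one typist speed.

    All fields are in the unit their name states. In ``exact`` mode
    ``t_ai_total_h == t_gen_h + t_read_h + t_edit_h`` without rounding; in
    ``paper_rounding`` mode the component hours are rounded to one decimal
    first and the total, savings and efficiency follow from the rounded
    figures.
    """

    typist: str  # "average" | "fast"
    mode: str  # "exact" | "paper_rounding"
    t_manual_min: float
    t_manual_h: float
    t_gen_s: float
    t_gen_h: float
    t_read_min: float
    t_read_h: float
    t_edit_min: float
    t_edit_h: float
    t_ai_total_h: float
    savings_h: float
    efficiency_pct: float


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (0.05 -> 0.1), as in the study's figures."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * math.copysign(1.0, x)


def manual_typing_time(w_final: int, v_type: float) -> float:
    """Minutes to type ``w_final`` words manually at ``v_type`` WPM."""
    if v_type <= 0:
        raise ValueError("typing speed must be positive")
    return w_final / v_type


def ai_assisted_time(
    counts: CorpusCounts, params: TimeModelParams, v_type: float
) -> tuple[float, float, float]:
    """AI-assisted component times ``(t_gen_s, t_read_min, t_edit_min)``.

    Generation is ``n_notes * t_gen_per_note`` seconds; review is the AI word
    total read at ``v_read`` WPM; editing is the added plus deleted words
    typed at ``v_type`` WPM.
    """
    if v_type <= 0:
        raise ValueError("typing speed must be positive")
    t_gen_s = counts.n_notes * params.t_gen_per_note
    t_read_min = counts.w_ai / params.v_read
    t_edit_min = counts.w_edited / v_type
    return t_gen_s, t_read_min, t_edit_min


def savings_and_efficiency(t_manual_h: float, t_ai_total_h: float) -> tuple[float, float]:
    """Hours saved and the percentage efficiency gain over manual typing."""
    if t_manual_h < 0:
        raise ValueError("manual time must be non-negative")
    savings = t_manual_h - t_ai_total_h
    efficiency = 100.0 * savings / t_manual_h if t_manual_h > 0 else 0.0
    return savings, efficiency


def time_report(
    counts: CorpusCounts,
    params: TimeModelParams | None = None,
    typist: str = "average",
    mode: str = EXACT,
) -> TimeReport:
    """Full time report for one typist speed in the requested mode."""
    params = params or TimeModelParams()
    if typist == "average":
        v_type = params.v_type_avg
    elif typist == "fast":
        v_type = params.v_type_fast
    else:
        raise ValueError(f"unknown typist class {typist!r}")
    if mode not in (EXACT, PAPER_ROUNDING):
        raise ValueError(f"unknown mode {mode!r}")

    t_manual_min = manual_typing_time(counts.w_final, v_type)
    t_gen_s, t_read_min, t_edit_min = ai_assisted_time(counts, params, v_type)

    t_manual_h = t_manual_min / 60.0
    t_gen_h = t_gen_s / 3600.0
    t_read_h = t_read_min / 60.0
    t_edit_h = t_edit_min / 60.0

    if mode == PAPER_ROUNDING:
        t_manual_min = round_half_up(t_manual_min)
        t_read_min = round_half_up(t_read_min)
        t_edit_min = round_half_up(t_edit_min)
        t_manual_h = round_half_up(t_manual_h, 1)
        t_gen_h = round_half_up(t_gen_h, 1)
        t_read_h = round_half_up(t_read_h, 1)
        t_edit_h = round_half_up(t_edit_h, 1)
        t_ai_total_h = round(t_gen_h + t_read_h + t_edit_h, 10)
        savings_h, efficiency_pct = savings_and_efficiency(t_manual_h, t_ai_total_h)
        savings_h = round_half_up(savings_h, 1)
        efficiency_pct = round_half_up(efficiency_pct, 1)
    else:
        t_ai_total_h = t_gen_h + t_read_h + t_edit_h
        savings_h, efficiency_pct = savings_and_efficiency(t_manual_h, t_ai_total_h)

    return TimeReport(
        typist=typist,
        mode=mode,
        t_manual_min=t_manual_min,
        t_manual_h=t_manual_h,
        t_gen_s=t_gen_s,
        t_gen_h=t_gen_h,
        t_read_min=t_read_min,
        t_read_h=t_read_h,
        t_edit_min=t_edit_min,
        t_edit_h=t_edit_h,
        t_ai_total_h=t_ai_total_h,
        savings_h=savings_h,
        efficiency_pct=efficiency_pct,
    )


def paper_rounding_report(
    counts: CorpusCounts, params: TimeModelParams | None = None
) -> tuple[TimeReport, TimeReport]:
    """(average-typist, fast-typist) reports in paper-rounding mode."""
    params = params or TimeModelParams()
    return (
        time_report(counts, params, typist="average", mode=PAPER_ROUNDING),
        time_report(counts, params, typist="fast", mode=PAPER_ROUNDING),
    )
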