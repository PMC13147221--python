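"""Attribute edit events to clinical-note sections and cross-tabulate them.

Additions are located in the *final* note (the inserted tokens exist only
there); deletions are located in the *initial* note (a deleted token has no
final-note position). An event spanning a section boundary is assigned to the
section of its first token.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import pandas as pd

from .diff_engine import ADDITION, DELETION, EditEvent
from .note_io import Note
from .time_model import round_half_up

__all__ = ["SectionRow", "SectionTable", "classify_event", "classify_events", "section_table"]


class AnchorError(Exception):
    """An event anchor falls outside the note it should lie in."""


def classify_event(event: EditEvent, initial_note: Note, final_note: Note) -> str:
    """Canonical section name for one edit event.

    Additions resolve ``final_anchor`` against the final note's section
    spans; deletions resolve ``anchor`` against the initial note's. Events in
    a leading headerless span classify as ``Unsectioned``.
    """
    try:
        if event.kind == ADDITION:
            if event.final_anchor is None:
                raise AnchorError("addition event lacks a final_anchor")
            return final_note.section_of_token(event.final_anchor)
        return initial_note.section_of_token(event.anchor)
    except IndexError as exc:
        raise AnchorError(str(exc)) from exc


def classify_events(
    events: list[EditEvent], initial_note: Note, final_note: Note
) -> list[EditEvent]:
    """Return copies of ``events`` with their ``section`` field filled."""
    return [
        replace(ev, section=classify_event(ev, initial_note, final_note))
        for ev in events
    ]


@dataclass(frozen=True)
class SectionRow:
    """One section's row of the edit cross-tabulation."""

    section: str
    n_additions: int
    n_additions_in_transcript: int | None
    n_additions_not_in_transcript: int | None
    n_deletions: int
    n_total: int
    pct_of_all_alterations: float


@dataclass(frozen=True)
class SectionTable:
    """Per-section addition/deletion counts with a grand-total row.

    Rows are sorted by total alterations, descending. When provenance has
    run, additions split into in-transcript and not-in-transcript columns.
    Percentages are of all alterations, rounded to one decimal.
    """

    rows: tuple[SectionRow, ...]
    totals: SectionRow

    def to_dataframe(self) -> pd.DataFrame:
        records = [vars(r) for r in self.rows] + [vars(self.totals)]
        return pd.DataFrame.from_records(records)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "rows": [vars(r) for r in self.rows],
            "totals": vars(self.totals),
        }


def section_table(events: list[EditEvent], provenance_done: bool = False) -> SectionTable:
    """Cross-tabulate classified events by section.

    Requires every event to carry a section label. Section totals partition
    the alterations: the grand total equals the event count, and per section
    ``n_total == n_additions + n_deletions``.
    """
    buckets: dict[str, dict[str, int]] = {}
    for ev in events:
        if ev.section is None:
            raise ValueError("all events must be classified before tabulation")
        b = buckets.setdefault(
            ev.section, {"add": 0, "add_in": 0, "add_out": 0, "del": 0}
        )
        if ev.kind == ADDITION:
            b["add"] += 1
            if provenance_done:
                if ev.in_transcript is None:
                    raise ValueError(
                        "provenance_done=True but an addition lacks its flag"
                    )
                b["add_in" if ev.in_transcript else "add_out"] += 1
        elif ev.kind == DELETION:
            b["del"] += 1

    n_alterations = len(events)

    def make_row(name: str, b: dict[str, int]) -> SectionRow:
        total = b["add"] + b["del"]
        pct = (
            round_half_up(100.0 * total / n_alterations, 1) if n_alterations else 0.0
        )
        return SectionRow(
            section=name,
            n_additions=b["add"],
            n_additions_in_transcript=b["add_in"] if provenance_done else None,
            n_additions_not_in_transcript=b["add_out"] if provenance_done else None,
            n_deletions=b["del"],
            n_total=total,
            pct_of_all_alterations=pct,
        )

    rows = sorted(
        (make_row(name, b) for name, b in buckets.items()),
        key=lambda r: (-r.n_total, r.section),
    )
    grand = {
        "add": sum(r.n_additions for r in rows),
        "add_in": sum(r.n_additions_in_transcript or 0 for r in rows),
        "add_out": sum(r.n_additions_not_in_transcript or 0 for r in rows),
        "del": sum(r.n_deletions for r in rows),
    }
    return SectionTable(rows=tuple(rows), totals=make_row("Total", grand))
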