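"""End-to-end pipeline orchestration and cohort-level reporting.

For every encounter: extract the AI-generated body from the EMR note via the
banner markers, tokenize and section-parse both note versions, diff them into
addition/deletion events, attribute each event to a section, and check each
addition against the transcript. Aggregates follow: corpus word counts, edit
statistics, the section cross-tabulation, per-note distribution summaries,
and the modelled time comparison in both exact and paper-rounding modes.

Encounters whose final EMR note contains no banner markers were not produced
by the scribe; they are excluded from every aggregate and logged as skips.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .config import RunConfig
from .diff_engine import ADDITION, DiffStats, EditEvent, diff_stats, word_diff
from .note_io import (
    Encounter,
    MalformedNoteError,
    count_words,
    extract_ai_note_from_emr,
    parse_note,
    read_corpus,
    tokenize,
)
from .provenance import in_transcript
from .section_classifier import SectionTable, classify_events, section_table
from .time_model import CorpusCounts, TimeReport, paper_rounding_report, time_report

__all__ = ["EncounterResult", "CohortReport", "run_pipeline", "median_iqr", "render_report"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EncounterResult:
    """Per-encounter products of the pipeline."""

    id: str
    role: str
    events: tuple[EditEvent, ...]
    w_ai: int
    w_final: int
    stats: DiffStats


@dataclass(frozen=True)
class CohortReport:
    """Cohort aggregates over all included encounters."""

    n_encounters: int
    n_by_role: dict[str, int]
    counts: CorpusCounts
    stats: DiffStats
    table: SectionTable
    distributions: dict[str, dict[str, float]]
    time_paper_rounding: tuple[TimeReport, TimeReport]
    time_exact: tuple[TimeReport, TimeReport]
    skipped: tuple[dict[str, str], ...]
    encounters: tuple[EncounterResult, ...] = field(repr=False)
    config: RunConfig = field(repr=False, default_factory=RunConfig)

    def to_dict(self) -> dict:
        tr = lambda r: vars(r).copy()
        return {
            "n_encounters": self.n_encounters,
            "n_by_role": self.n_by_role,
            "counts": self.counts.model_dump(),
            "stats": {
                **{k: getattr(self.stats, k) for k in (
                    "words_added", "words_deleted", "chars_added", "chars_deleted",
                    "n_additions", "n_deletions",
                )},
                "n_alterations": self.stats.n_alterations,
            },
            "section_table": self.table.to_dict(),
            "distributions": self.distributions,
            "time_paper_rounding": [tr(r) for r in self.time_paper_rounding],
            "time_exact": [tr(r) for r in self.time_exact],
            "skipped": list(self.skipped),
            "config": self.config.model_dump(mode="json"),
        }


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """``(median, q1, q3)`` with linearly interpolated quartiles.

    Raises ``ValueError`` on an empty input.
    """
    if len(values) == 0:
        raise ValueError("median_iqr requires at least one value")
    q1, med, q3 = np.percentile(np.asarray(values, dtype=float), [25, 50, 75])
    return float(med), float(q1), float(q3)


def _distribution(values: Sequence[float]) -> dict[str, float]:
    med, q1, q3 = median_iqr(values)
    return {"median": med, "q1": q1, "q3": q3}


def process_encounter(enc: Encounter, config: RunConfig) -> EncounterResult | None:
    """Run the per-encounter stages; ``None`` if the note is not AI-generated."""
    final_body = extract_ai_note_from_emr(
        enc.final_note_text, config.start_marker, config.end_marker
    )
    if final_body is None:
        return None
    initial_tokens = tokenize(enc.initial_note_text)
    final_tokens = tokenize(final_body)
    initial_note = parse_note(enc.initial_note_text, config.header_lexicon, source="initial")
    final_note = parse_note(final_body, config.header_lexicon, source="final")
    transcript_tokens = tokenize(enc.transcript_text)

    events = word_diff(initial_tokens, final_tokens)
    events = classify_events(events, initial_note, final_note)
    flagged: list[EditEvent] = []
    for ev in events:
        if ev.kind == ADDITION:
            flag, score = in_transcript(ev, transcript_tokens, config.provenance)
            ev = EditEvent(
                kind=ev.kind,
                tokens=ev.tokens,
                anchor=ev.anchor,
                final_anchor=ev.final_anchor,
                section=ev.section,
                in_transcript=flag,
                score=score,
            )
        flagged.append(ev)

    return EncounterResult(
        id=enc.id,
        role=enc.role,
        events=tuple(flagged),
        w_ai=len(initial_tokens),
        w_final=len(final_tokens),
        stats=diff_stats(flagged),
    )


def run_pipeline(
    manifest_path: str | Path, config: RunConfig | None = None
) -> CohortReport:
    """Audit a whole corpus and aggregate the results.

    Deterministic for fixed inputs. Encounters without banner markers are
    skipped and logged; malformed notes (one marker only) are skipped with
    the reason recorded. An empty or fully skipped corpus is an error.
    """
    config = config or RunConfig()
    encounters = read_corpus(manifest_path)
    if not encounters:
        raise ValueError(f"empty corpus: {manifest_path}")

    results: list[EncounterResult] = []
    skipped: list[dict[str, str]] = []
    for enc in encounters:
        try:
            result = process_encounter(enc, config)
        except MalformedNoteError as exc:
            logger.warning("skipping encounter %s: %s", enc.id, exc)
            skipped.append({"id": enc.id, "reason": str(exc)})
            continue
        if result is None:
            logger.info("skipping encounter %s: no banner markers", enc.id)
            skipped.append({"id": enc.id, "reason": "no banner markers"})
            continue
        results.append(result)
    if skipped:
        logger.info("skipped %d of %d encounters", len(skipped), len(encounters))
    if not results:
        raise ValueError("no AI-generated encounters in corpus")

    all_events = [ev for r in results for ev in r.events]
    stats = diff_stats(all_events)
    counts = CorpusCounts(
        w_final=sum(r.w_final for r in results),
        w_ai=sum(r.w_ai for r in results),
        w_added=stats.words_added,
        w_deleted=stats.words_deleted,
        n_notes=len(results),
    )
    n_by_role: dict[str, int] = {}
    for r in results:
        n_by_role[r.role] = n_by_role.get(r.role, 0) + 1

    distributions = {
        "ai_note_words": _distribution([r.w_ai for r in results]),
        "final_note_words": _distribution([r.w_final for r in results]),
        "words_added": _distribution([r.stats.words_added for r in results]),
        "words_deleted": _distribution([r.stats.words_deleted for r in results]),
    }

    return CohortReport(
        n_encounters=len(results),
        n_by_role=n_by_role,
        counts=counts,
        stats=stats,
        table=section_table(all_events, provenance_done=True),
        distributions=distributions,
        time_paper_rounding=paper_rounding_report(counts, config.time),
        time_exact=(
            time_report(counts, config.time, "average", "exact"),
            time_report(counts, config.time, "fast", "exact"),
        ),
        skipped=tuple(skipped),
        encounters=tuple(results),
        config=config,
    )


def _markdown(report: CohortReport) -> str:
    avg, fast = report.time_paper_rounding
    c = report.counts
    s = report.stats
    lines = [
        "# AI-scribe documentation audit",
        "",
        "## Corpus totals",
        f"- {report.n_encounters} encounters ({report.n_by_role})",
        f"- Final EMR notes: {c.w_final} words over {c.n_notes} entries",
        f"- Initial AI notes: {c.w_ai} words",
        "",
        "## Clinician edits",
        f"- {s.n_alterations} alterations: {s.n_additions} additions, "
        f"{s.n_deletions} deletions",
        f"- {c.w_added} words added, {c.w_deleted} deleted "
        f"({c.w_edited} edited in total)",
        "",
        "## Modelled documentation time (paper-rounding mode)",
        f"- Manual typing: {avg.t_manual_min:.0f} min ({avg.t_manual_h} h) at average "
        f"speed; {fast.t_manual_min:.0f} min ({fast.t_manual_h} h) fast",
        f"- AI-assisted (average typist): {avg.t_gen_h} + {avg.t_read_h} + "
        f"{avg.t_edit_h} = {avg.t_ai_total_h} h",
        f"- AI-assisted (fast typist): {fast.t_gen_h} + {fast.t_read_h} + "
        f"{fast.t_edit_h} = {fast.t_ai_total_h} h",
        f"- Savings: {avg.savings_h} h (efficiency {avg.efficiency_pct}%) average; "
        f"{fast.savings_h} h ({fast.efficiency_pct}%) fast",
        "",
        "## Edits by section",
        "",
        "```",
        report.table.to_dataframe().to_string(index=False),
        "```",
        "",
    ]
    return "\n".join(lines)


def render_report(report: CohortReport, fmt: str, out: str | Path) -> Path:
    """Write the report as ``json``, ``markdown``, or a ``csv-bundle`` dir."""
    out = Path(out)
    if fmt == "json":
        out.write_text(json.dumps(report.to_dict(), indent=1), encoding="utf-8")
    elif fmt == "markdown":
        out.write_text(_markdown(report), encoding="utf-8")
    elif fmt == "csv-bundle":
        out.mkdir(parents=True, exist_ok=True)
        report.table.to_csv(out / "section_table.csv")
        import pandas as pd

        pd.DataFrame([report.counts.model_dump()]).to_csv(
            out / "corpus_counts.csv", index=False
        )
        pd.DataFrame(
            [vars(r) for r in (*report.time_paper_rounding, *report.time_exact)]
        ).to_csv(out / "time_model.csv", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return out
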