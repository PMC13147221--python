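"""Synthetic encounter corpora with planted, fully known clinician edits.

The study corpus cannot be shared, so verification rests on generated
encounters in which every ground-truth quantity is known by construction:
sectioned notes of realistic length, dialogue-style transcripts, and edits
planted per section with a configured addition/deletion mix and in-transcript
fraction. Edits never overlap, sit at least two unchanged tokens away from
section headers and from each other, and use vocabulary pools disjoint from
the surrounding note, so the word-level diff has a unique minimal alignment
and recovery of the planted edits is exactly checkable.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

from pydantic import BaseModel, Field, field_validator

from ._vocab import BASE_VOCAB, NOVEL_VOCAB, TRANSCRIPT_VOCAB
from .diff_engine import ADDITION, DELETION
from .note_io import (
    CANONICAL_SECTIONS,
    DEFAULT_END_MARKER,
    DEFAULT_START_MARKER,
    Encounter,
)

__all__ = ["GeneratorConfig", "PlantedEdit", "GroundTruth", "generate_corpus", "write_corpus"]

_WORDS_PER_LINE = 10
_EDIT_MARGIN = 2  # unchanged tokens kept between any edit and its neighbours


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic corpus.

    Defaults emulate the study's scale: 248 encounters, six-section notes
    with a median around 170 words, roughly 3.5 additions and one deletion
    per note, 82.8% of additions sourced from the transcript, and 74.6% of
    encounters documented by trainees.
    """

    n_encounters: int = Field(default=248, ge=1)
    section_names: tuple[str, ...] = CANONICAL_SECTIONS
    words_per_section: tuple[int, int] = (20, 36)
    p_addition_per_section: float = Field(default=0.6, ge=0.0, le=1.0)
    p_deletion_per_section: float = Field(default=0.18, ge=0.0, le=1.0)
    addition_length: tuple[int, int] = (4, 20)
    p_addition_from_transcript: float = Field(default=0.828, ge=0.0, le=1.0)
    transcript_turns: tuple[int, int] = (8, 16)
    seed: int = 0
    trainee_fraction: float = Field(default=0.746, ge=0.0, le=1.0)

    @field_validator("words_per_section", "addition_length", "transcript_turns")
    @classmethod
    def _check_range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if lo < 1 or lo > hi:
            raise ValueError(f"range must satisfy 1 <= low <= high, got {v}")
        return v

    @field_validator("section_names")
    @classmethod
    def _check_sections(cls, v: tuple[str, ...]) -> tuple[str, ...]:
        if not v:
            raise ValueError("at least one section name is required")
        if len(set(v)) != len(v):
            raise ValueError("section names must be unique")
        return v


@dataclass(frozen=True)
class PlantedEdit:
    """One planted ground-truth edit, in whole-note token coordinates.

    ``anchor`` indexes the initial note's token sequence (insertion point for
    additions, run start for deletions); ``final_anchor`` is the inserted
    run's start in the final note (additions only). ``in_transcript`` is set
    for additions only.
    """

    kind: str
    section: str
    tokens: tuple[str, ...]
    anchor: int
    final_anchor: int | None = None
    in_transcript: bool | None = None


@dataclass(frozen=True)
class GroundTruth:
    """Planted edits per encounter id, ordered by initial-note anchor."""

    edits: dict[str, tuple[PlantedEdit, ...]]

    def to_json(self) -> str:
        payload = {
            enc_id: [
                {
                    "kind": e.kind,
                    "section": e.section,
                    "tokens": list(e.tokens),
                    "anchor": e.anchor,
                    "final_anchor": e.final_anchor,
                    "in_transcript": e.in_transcript,
                }
                for e in edits
            ]
            for enc_id, edits in self.edits.items()
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        payload = json.loads(text)
        return cls(
            edits={
                enc_id: tuple(
                    PlantedEdit(
                        kind=rec["kind"],
                        section=rec["section"],
                        tokens=tuple(rec["tokens"]),
                        anchor=rec["anchor"],
                        final_anchor=rec["final_anchor"],
                        in_transcript=rec["in_transcript"],
                    )
                    for rec in recs
                )
                for enc_id, recs in payload.items()
            }
        )


def _render(section_chunks: list[tuple[str, list[str]]]) -> str:
    """Render (header, body tokens) chunks as a line-structured note."""
    lines: list[str] = []
    for header, body in section_chunks:
        lines.append(header)
        for i in range(0, len(body), _WORDS_PER_LINE):
            lines.append(" ".join(body[i : i + _WORDS_PER_LINE]))
    return "\n".join(lines) + "\n"


def _sample_distinct(rng: random.Random, pool: tuple[str, ...], k: int, used: set[str]) -> list[str]:
    available = [w for w in pool if w not in used]
    if k > len(available):
        raise ValueError(
            f"vocabulary pool exhausted: need {k} fresh words, {len(available)} left"
        )
    chosen = rng.sample(available, k)
    used.update(chosen)
    return chosen


def _plan_section_edits(
    rng: random.Random, body_len: int, cfg: GeneratorConfig
) -> tuple[tuple[int, int] | None, int | None]:
    """Choose a deletion run (start, length) and an insertion point.

    The deletion lives in the first half of the body and the insertion in the
    second, each at least ``_EDIT_MARGIN`` tokens from the section boundaries
    and from one another, so planted edits never merge under the diff.
    """
    mid = body_len // 2
    deletion = None
    if rng.random() < cfg.p_deletion_per_section:
        max_len = mid - 2 * _EDIT_MARGIN
        if max_len >= 1:
            d_len = min(rng.randint(*cfg.addition_length), max_len)
            d_start = rng.randint(_EDIT_MARGIN, mid - _EDIT_MARGIN - d_len)
            deletion = (d_start, d_len)
    insertion = None
    if rng.random() < cfg.p_addition_per_section:
        lo, hi = mid + _EDIT_MARGIN, body_len - _EDIT_MARGIN
        if lo <= hi:
            insertion = rng.randint(lo, hi)
    return deletion, insertion


def generate_corpus(config: GeneratorConfig) -> tuple[list[Encounter], GroundTruth]:
    """Generate encounters and their planted-edit ground truth.

    Deterministic for a fixed seed. For every encounter, applying the planted
    edits to the initial note's tokens reproduces the final note's tokens,
    and each in-transcript addition appears verbatim as one transcript turn.
    """
    rng = random.Random(config.seed)
    encounters: list[Encounter] = []
    ground_truth: dict[str, tuple[PlantedEdit, ...]] = {}

    for idx in range(config.n_encounters):
        enc_id = f"enc{idx:04d}"
        role = "trainee" if rng.random() < config.trainee_fraction else "consultant"

        used_base: set[str] = set()
        used_add: set[str] = set()
        initial_chunks: list[tuple[str, list[str]]] = []
        final_chunks: list[tuple[str, list[str]]] = []
        edits: list[PlantedEdit] = []
        transcript_payloads: list[list[str]] = []

        offset = 0  # initial-note token index at the start of each section
        delta = 0  # final-note index minus initial-note index so far
        for name in config.section_names:
            header = f"{name}:"
            header_len = len(header.split())
            body = _sample_distinct(
                rng, BASE_VOCAB, rng.randint(*config.words_per_section), used_base
            )
            deletion, insertion = _plan_section_edits(rng, len(body), config)
            body_start = offset + header_len

            final_body = list(body)
            if deletion is not None:
                d_start, d_len = deletion
                edits.append(
                    PlantedEdit(
                        kind=DELETION,
                        section=name,
                        tokens=tuple(body[d_start : d_start + d_len]),
                        anchor=body_start + d_start,
                    )
                )
                final_body = body[:d_start] + body[d_start + d_len :]
                delta -= d_len
            if insertion is not None:
                from_transcript = rng.random() < config.p_addition_from_transcript
                pool = TRANSCRIPT_VOCAB if from_transcript else NOVEL_VOCAB
                payload = _sample_distinct(
                    rng, pool, rng.randint(*config.addition_length), used_add
                )
                anchor = body_start + insertion
                edits.append(
                    PlantedEdit(
                        kind=ADDITION,
                        section=name,
                        tokens=tuple(payload),
                        anchor=anchor,
                        final_anchor=anchor + delta,
                        in_transcript=from_transcript,
                    )
                )
                at = insertion - (deletion[1] if deletion is not None else 0)
                final_body = final_body[:at] + payload + final_body[at:]
                delta += len(payload)
                if from_transcript:
                    transcript_payloads.append(payload)

            initial_chunks.append((header, body))
            final_chunks.append((header, final_body))
            offset = body_start + len(body)

        initial_text = _render(initial_chunks)
        final_text = _render(final_chunks)
        transcript_text = _make_transcript(rng, config, transcript_payloads)
        emr_text = (
            "ED attendance record\n"
            f"{DEFAULT_START_MARKER}\n{final_text}{DEFAULT_END_MARKER}\n"
            "Electronically signed.\n"
        )

        encounters.append(
            Encounter(
                id=enc_id,
                role=role,
                transcript_text=transcript_text,
                initial_note_text=initial_text,
                final_note_text=emr_text,
            )
        )
        ground_truth[enc_id] = tuple(edits)

    return encounters, GroundTruth(edits=ground_truth)


def _make_transcript(
    rng: random.Random, config: GeneratorConfig, payloads: list[list[str]]
) -> str:
    """Alternating DOCTOR/PATIENT turns; each payload becomes one PATIENT turn."""
    n_turns = rng.randint(*config.transcript_turns)
    turns = []
    for t in range(n_turns):
        speaker = "DOCTOR:" if t % 2 == 0 else "PATIENT:"
        words = [rng.choice(BASE_VOCAB) for _ in range(rng.randint(5, 12))]
        turns.append(f"{speaker} {' '.join(words)}")
    for payload in payloads:
        pos = rng.randint(0, len(turns))
        turns.insert(pos, f"PATIENT: {' '.join(payload)}")
    return "\n".join(turns) + "\n"


def write_corpus(
    encounters: list[Encounter], ground_truth: GroundTruth, directory: str | Path
) -> Path:
    """Write a corpus directory and return the manifest path.

    Layout: ``<id>.transcript.txt``, ``<id>.ai.txt``, ``<id>.emr.txt`` per
    encounter, a JSONL ``manifest.jsonl`` (id, relative paths, role), and
    ``ground_truth.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.jsonl"
    with open(manifest_path, "w", encoding="utf-8") as manifest:
        for enc in encounters:
            files = {
                "transcript": f"{enc.id}.transcript.txt",
                "ai": f"{enc.id}.ai.txt",
                "emr": f"{enc.id}.emr.txt",
            }
            (directory / files["transcript"]).write_text(
                enc.transcript_text, encoding="utf-8"
            )
            (directory / files["ai"]).write_text(enc.initial_note_text, encoding="utf-8")
            (directory / files["emr"]).write_text(enc.final_note_text, encoding="utf-8")
            manifest.write(json.dumps({"id": enc.id, "role": enc.role, **files}) + "\n")
    (directory / "ground_truth.json").write_text(
        ground_truth.to_json(), encoding="utf-8"
    )
    return manifest_path
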