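"""Corpus I/O, banner-marker extraction, tokenization, and section parsing.

Every word count in the pipeline is defined by :func:`tokenize`: a "word" is a
maximal run of non-whitespace characters. Character counts default to
non-whitespace characters only. Both conventions are fixed here so that all
downstream statistics share a single unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

__all__ = [
    "CANONICAL_SECTIONS",
    "UNSECTIONED",
    "DEFAULT_HEADER_LEXICON",
    "DEFAULT_START_MARKER",
    "DEFAULT_END_MARKER",
    "Encounter",
    "Section",
    "Note",
    "CorpusError",
    "MalformedNoteError",
    "tokenize",
    "count_words",
    "count_chars",
    "extract_ai_note_from_emr",
    "parse_note",
    "read_corpus",
]

#: Canonical section names of an ED clinical note, in customary note order.
CANONICAL_SECTIONS: tuple[str, ...] = (
    "HOPC",
    "PMHx",
    "Medications",
    "Social History",
    "Impression",
    "Management Plan",
)

#: Label for leading note text that precedes any recognized header.
UNSECTIONED = "Unsectioned"

#: Surface forms recognized (case-insensitively, at line start, optional
#: trailing colon) for each canonical section.
DEFAULT_HEADER_LEXICON: dict[str, tuple[str, ...]] = {
    "HOPC": (
        "HOPC",
        "History of Presenting Complaint",
        "History of Presenting Illness",
        "HPI",
    ),
    "PMHx": ("Pmx", "PMHx", "Past Medical History"),
    "Medications": ("Medications", "Meds"),
    "Social History": ("Social History", "SHx"),
    "Impression": ("Impression", "Assessment"),
    "Management Plan": ("Plan", "Management", "Management Plan"),
}

# Sentinel strings bracketing AI-generated content in the EMR, required by the
# study's ethics approval; they identify which EMR notes came from the scribe.
DEFAULT_START_MARKER = (
    "******* AI‐Generated note for research approved by "
    "StV Ethics Committee *******"
)
DEFAULT_END_MARKER = "******* End of AI‐generated note *******"


class CorpusError(Exception):
    """Raised for manifest / corpus-file problems (missing file, bad line)."""


class MalformedNoteError(Exception):
    """Raised when exactly one of the two banner markers is present."""


@dataclass(frozen=True)
class Encounter:
    """One ED presentation: transcript, initial AI note, final EMR note."""

    id: str
    role: str  # "consultant" | "trainee"
    transcript_text: str
    initial_note_text: str
    final_note_text: str


@dataclass(frozen=True)
class Section:
    """A parsed note section.

    ``header_span`` and ``body_span`` are half-open token-index intervals into
    the note's full token sequence; the header span is empty for the leading
    ``Unsectioned`` span.
    """

    canonical_name: str
    header_text: str
    header_span: tuple[int, int]
    body_span: tuple[int, int]

    @property
    def span(self) -> tuple[int, int]:
        """Full extent of the section (header plus body)."""
        return (self.header_span[0], self.body_span[1])


@dataclass(frozen=True)
class Note:
    """A note parsed into ordered, non-overlapping sections."""

    sections: tuple[Section, ...]
    tokens: tuple[str, ...]
    source: str = "final"  # "initial" | "final"

    def section_of_token(self, index: int) -> str:
        """Canonical section name owning token ``index``.

        ``index == len(tokens)`` (an insertion at the very end) resolves to the
        last section.
        """
        if index < 0 or index > len(self.tokens):
            raise IndexError(
                f"token index {index} outside note of {len(self.tokens)} tokens"
            )
        for sec in self.sections:
            lo, hi = sec.span
            if lo <= index < hi:
                return sec.canonical_name
        if self.sections:
            return self.sections[-1].canonical_name
        return UNSECTIONED


def tokenize(text: str) -> list[str]:
    """Split ``text`` into whitespace-delimited tokens.

    Punctuation stays attached to its token; empty or all-whitespace text
    yields an empty list.
    """
    return text.split()


def count_words(text: str) -> int:
    """Number of whitespace-delimited tokens in ``text``."""
    return len(tokenize(text))


def count_chars(text: str, include_whitespace: bool = False) -> int:
    """Number of characters in ``text``.

    By default whitespace is excluded, so the count is the total length of the
    tokens; set ``include_whitespace`` to count every character.
    """
    if include_whitespace:
        return len(text)
    return sum(1 for c in text if not c.isspace())


def extract_ai_note_from_emr(
    emr_text: str,
    start_marker: str = DEFAULT_START_MARKER,
    end_marker: str = DEFAULT_END_MARKER,
) -> str | None:
    """Return the note body between the banner markers, or ``None``.

    The text strictly between the first ``start_marker`` and the first
    subsequent ``end_marker`` is returned with surrounding whitespace trimmed;
    the markers themselves never reach downstream word/character counts. A
    note containing neither marker is not AI-generated and yields ``None``.

    Raises
    ------
    MalformedNoteError
        If exactly one of the two markers occurs, or the end marker precedes
        the start marker.
    ValueError
        If either marker string is empty.
    """
    if not start_marker or not end_marker:
        raise ValueError("marker strings must be non-empty")
    start = emr_text.find(start_marker)
    if start == -1:
        if end_marker in emr_text:
            raise MalformedNoteError("end marker present without start marker")
        return None
    body_start = start + len(start_marker)
    end = emr_text.find(end_marker, body_start)
    if end == -1:
        raise MalformedNoteError("start marker present without end marker")
    return emr_text[body_start:end].strip()


def _header_map(header_lexicon: Mapping[str, Sequence[str]]) -> dict[str, str]:
    mapping: dict[str, str] = {}
    for canonical, surfaces in header_lexicon.items():
        if not surfaces:
            raise ValueError(f"no surface forms for section {canonical!r}")
        for surface in surfaces:
            mapping[surface.casefold()] = canonical
    return mapping


def _match_header(line: str, surface_to_canonical: Mapping[str, str]) -> str | None:
    candidate = line.strip()
    if candidate.endswith(":"):
        candidate = candidate[:-1]
    return surface_to_canonical.get(candidate.strip().casefold())


def parse_note(
    text: str,
    header_lexicon: Mapping[str, Sequence[str]] | None = None,
    source: str = "final",
) -> Note:
    """Parse ``text`` into a :class:`Note` of ordered sections.

    A line is a header iff, after trimming and removing one trailing colon, it
    case-insensitively equals a surface form of ``header_lexicon`` (defaults
    to :data:`DEFAULT_HEADER_LEXICON`). Headers are recognized only as whole
    lines. Text before the first header parses as a single leading
    ``Unsectioned`` span; a headerless note is one ``Unsectioned`` section.
    """
    lexicon = header_lexicon if header_lexicon is not None else DEFAULT_HEADER_LEXICON
    surface_to_canonical = _header_map(lexicon)

    all_tokens: list[str] = []
    # (canonical, header_text, header_span, body_start) for open sections
    sections: list[Section] = []
    current: tuple[str, str, tuple[int, int]] | None = None
    body_start = 0

    def close_current(body_end: int) -> None:
        nonlocal current
        if current is not None:
            name, header_text, header_span = current
            sections.append(Section(name, header_text, header_span, (body_start, body_end)))
        elif body_end > 0:
            sections.append(Section(UNSECTIONED, "", (0, 0), (0, body_end)))
        current = None

    for line in text.splitlines():
        line_tokens = tokenize(line)
        canonical = _match_header(line, surface_to_canonical) if line_tokens else None
        if canonical is not None:
            close_current(len(all_tokens))
            header_lo = len(all_tokens)
            all_tokens.extend(line_tokens)
            current = (canonical, line.strip(), (header_lo, len(all_tokens)))
            body_start = len(all_tokens)
        else:
            all_tokens.extend(line_tokens)

    if current is not None:
        name, header_text, header_span = current
        sections.append(Section(name, header_text, header_span, (body_start, len(all_tokens))))
    elif all_tokens or not sections:
        sections.append(Section(UNSECTIONED, "", (0, 0), (0, len(all_tokens))))

    return Note(sections=tuple(sections), tokens=tuple(all_tokens), source=source)


def read_corpus(manifest_path: str | Path) -> list[Encounter]:
    """Load encounters listed in a JSONL manifest.

    Each manifest line is a JSON object with keys ``id``, ``role``,
    ``transcript``, ``ai`` and ``emr``; file paths are resolved relative to
    the manifest's directory. Texts are loaded verbatim.

    Raises
    ------
    CorpusError
        On a missing manifest, an unparseable line (the message names the
        line number), a duplicate encounter id, or a missing referenced file
        (the message names the encounter id).
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise CorpusError(f"manifest not found: {manifest_path}")
    base = manifest_path.parent
    encounters: list[Encounter] = []
    seen: set[str] = set()
    with open(manifest_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(
                    f"manifest line {lineno}: invalid JSON ({exc.msg})"
                ) from exc
            try:
                enc_id = record["id"]
                role = record["role"]
                paths = {k: base / record[k] for k in ("transcript", "ai", "emr")}
            except KeyError as exc:
                raise CorpusError(f"manifest line {lineno}: missing key {exc}") from exc
            if enc_id in seen:
                raise CorpusError(f"duplicate encounter id {enc_id!r}")
            seen.add(enc_id)
            texts = {}
            for kind, path in paths.items():
                if not path.exists():
                    raise CorpusError(
                        f"encounter {enc_id!r}: missing {kind} file {path}"
                    )
                texts[kind] = path.read_text(encoding="utf-8")
            encounters.append(
                Encounter(
                    id=enc_id,
                    role=role,
                    transcript_text=texts["transcript"],
                    initial_note_text=texts["ai"],
                    final_note_text=texts["emr"],
                )
            )
    return encounters
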