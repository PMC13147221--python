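"""Word-level diff between the initial AI note and the final EMR note.

The diff is a minimal longest-common-subsequence alignment over tokens.
Clinician "alterations" are the grouped gaps of that alignment: each maximal
contiguous run of inserted tokens is one addition event and each maximal run
of deleted tokens is one deletion event, so a replacement yields one deletion
plus one addition. Token equality is case- and punctuation-sensitive — under
a word-count time model an edit to case or punctuation is a real edit.

Among equally minimal alignments one is fixed deterministically: matches are
taken as early (leftmost) as possible and, within a gap, the deletion precedes
the insertion. Any fixed rule yields the same added/deleted token totals; one
is pinned so event anchors are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "EditEvent",
    "DiffStats",
    "word_diff",
    "apply_events",
    "diff_stats",
    "lcs_length",
    "events_to_jsonl",
    "events_from_jsonl",
]

ADDITION = "addition"
DELETION = "deletion"


@dataclass(frozen=True)
class EditEvent:
    """One maximal contiguous addition or deletion.

    ``anchor`` is a token index into the *initial* sequence: for deletions the
    start of the removed run; for additions the number of initial tokens
    consumed before the insertion point. ``final_anchor`` (additions only) is
    the start of the inserted run in the *final* sequence. ``section``,
    ``in_transcript`` and ``score`` are filled by later pipeline stages.
    """

    kind: str
    tokens: tuple[str, ...]
    anchor: int
    final_anchor: int | None = None
    section: str | None = None
    in_transcript: bool | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (ADDITION, DELETION):
            raise ValueError(f"unknown edit kind {self.kind!r}")
        if not self.tokens:
            raise ValueError("an edit event carries at least one token")

    @property
    def word_count(self) -> int:
        return len(self.tokens)

    @property
    def char_count(self) -> int:
        """Non-whitespace characters across the event's tokens."""
        return sum(len(t) for t in self.tokens)


@dataclass(frozen=True)
class DiffStats:
    """Aggregate edit volume over a collection of events."""

    words_added: int = 0
    words_deleted: int = 0
    chars_added: int = 0
    chars_deleted: int = 0
    n_additions: int = 0
    n_deletions: int = 0

    @property
    def n_alterations(self) -> int:
        return self.n_additions + self.n_deletions

    @property
    def words_edited(self) -> int:
        return self.words_added + self.words_deleted


def lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    """Length of the longest common subsequence of ``a`` and ``b``."""
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        curr = [0]
        best = 0
        for j, y in enumerate(b):
            best = prev[j] + 1 if x == y else max(prev[j + 1], curr[j])
            curr.append(best)
        prev = curr
    return prev[-1]


def _lcs_matches(a: Sequence[str], b: Sequence[str]) -> list[tuple[int, int]]:
    """Matched index pairs of the leftmost maximal LCS alignment."""
    n, m = len(a), len(b)
    # suffix table: L[i][j] = LCS length of a[i:], b[j:]
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row, below = L[i], L[i + 1]
        ai = a[i]
        for j in range(m - 1, -1, -1):
            if ai == b[j]:
                row[j] = below[j + 1] + 1
            else:
                bj = below[j]
                rj = row[j + 1]
                row[j] = bj if bj >= rj else rj
    matches: list[tuple[int, int]] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j] and L[i][j] == L[i + 1][j + 1] + 1:
            matches.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return matches


def word_diff(
    initial_tokens: Sequence[str], final_tokens: Sequence[str]
) -> list[EditEvent]:
    """Compute the addition/deletion events turning ``initial`` into ``final``.

    Events are ordered by their position in the initial sequence; applying
    them with :func:`apply_events` reconstructs ``final_tokens`` exactly. The
    total edited token count equals ``len(a) + len(b) - 2 * LCS(a, b)``
    (minimality).
    """
    a = list(initial_tokens)
    b = list(final_tokens)
    matches = _lcs_matches(a, b)
    events: list[EditEvent] = []
    prev_i = prev_j = 0
    # sentinel closes the trailing gap
    for mi, mj in matches + [(len(a), len(b))]:
        if mi > prev_i:
            events.append(
                EditEvent(DELETION, tuple(a[prev_i:mi]), anchor=prev_i)
            )
        if mj > prev_j:
            events.append(
                EditEvent(
                    ADDITION, tuple(b[prev_j:mj]), anchor=mi, final_anchor=prev_j
                )
            )
        prev_i, prev_j = mi + 1, mj + 1
    return events


def apply_events(
    initial_tokens: Sequence[str], events: Iterable[EditEvent]
) -> list[str]:
    """Replay ``events`` against ``initial_tokens``.

    Inverse check for :func:`word_diff`: deletions remove the run starting at
    ``anchor``; an addition's tokens are inserted once ``anchor`` initial
    tokens have been consumed (after any deletion ending there).
    """
    deletions: dict[int, EditEvent] = {}
    additions: dict[int, EditEvent] = {}
    for ev in events:
        table = deletions if ev.kind == DELETION else additions
        if ev.anchor in table:
            raise ValueError(f"two {ev.kind} events share anchor {ev.anchor}")
        table[ev.anchor] = ev

    out: list[str] = []
    i = 0
    n = len(initial_tokens)
    while i <= n:
        if i in deletions:
            deleted = deletions.pop(i)
            if tuple(initial_tokens[i : i + deleted.word_count]) != deleted.tokens:
                raise ValueError(f"deletion at anchor {i} does not match initial tokens")
            i += deleted.word_count
            continue
        if i in additions:
            out.extend(additions.pop(i).tokens)
        if i < n:
            out.append(initial_tokens[i])
        i += 1
    if deletions or additions:
        dangling = sorted([*deletions, *additions])
        raise ValueError(f"event anchors outside initial sequence: {dangling}")
    return out


def diff_stats(events: Iterable[EditEvent]) -> DiffStats:
    """Sum word/character volume and event counts over ``events``."""
    wa = wd = ca = cd = na = nd = 0
    for ev in events:
        if ev.kind == ADDITION:
            na += 1
            wa += ev.word_count
            ca += ev.char_count
        else:
            nd += 1
            wd += ev.word_count
            cd += ev.char_count
    return DiffStats(
        words_added=wa,
        words_deleted=wd,
        chars_added=ca,
        chars_deleted=cd,
        n_additions=na,
        n_deletions=nd,
    )


def events_to_jsonl(events: Iterable[EditEvent], encounter_id: str | None = None) -> str:
    """Serialize events, one JSON object per line."""
    lines = []
    for ev in events:
        record = {
            "kind": ev.kind,
            "tokens": list(ev.tokens),
            "word_count": ev.word_count,
            "char_count": ev.char_count,
            "anchor": ev.anchor,
            "final_anchor": ev.final_anchor,
            "section": ev.section,
            "in_transcript": ev.in_transcript,
            "score": ev.score,
        }
        if encounter_id is not None:
            record = {"encounter_id": encounter_id, **record}
        lines.append(json.dumps(record))
    return "\n".join(lines) + ("\n" if lines else "")


def events_from_jsonl(text: str) -> list[EditEvent]:
    events = []
    for line in text.splitlines():
        if not line.strip():
            continue
        rec = json.loads(line)
        events.append(
            EditEvent(
                kind=rec["kind"],
                tokens=tuple(rec["tokens"]),
                anchor=rec["anchor"],
                final_anchor=rec.get("final_anchor"),
                section=rec.get("section"),
                in_transcript=rec.get("in_transcript"),
                score=rec.get("score"),
            )
        )
    return events
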