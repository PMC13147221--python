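"""Deterministic transcript-provenance check for clinician additions.

Decides whether text a clinician added to the final note was already present
in the encounter transcript. Added text rarely matches the transcript
verbatim even when it conveys the same information, so the check is fuzzy: it
slides a window across the normalized transcript and scores each window
against the addition by multiset Jaccard similarity, flagging the addition as
in-transcript when the best window reaches the threshold. The procedure is
fully deterministic and tunable; it deliberately trades semantic power for
reproducibility and does not attempt paraphrase understanding.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import Sequence

from pydantic import BaseModel, Field

from .diff_engine import ADDITION, EditEvent

__all__ = ["ProvenanceParams", "normalize_tokens", "in_transcript"]

_EDGE_PUNCT = re.compile(r"^\W+|\W+$", re.UNICODE)
_SPEAKER_LABEL = re.compile(r"^(doctor|patient|dr|pt)[.:]$", re.IGNORECASE)


class ProvenanceParams(BaseModel):
    """Tuning knobs for the sliding-window containment check.

    ``window_slack`` widens the candidate transcript windows to the addition's
    length ± slack tokens, tolerating minor rewording. Ties at the threshold
    count as in-transcript.
    """

    window_slack: int = Field(default=2, ge=0)
    similarity_threshold: float = Field(default=0.6, ge=0.0, le=1.0)
    lowercase: bool = True
    strip_punctuation: bool = True
    strip_speaker_labels: bool = True


def normalize_tokens(
    tokens: Sequence[str], params: ProvenanceParams | None = None
) -> list[str]:
    """Normalize tokens for fuzzy matching.

    Speaker labels ("DOCTOR:", "PATIENT:") are dropped, tokens are lowercased
    and stripped of leading/trailing punctuation (interior punctuation such as
    "120/80" survives), and tokens emptied by stripping are removed.
    """
    params = params or ProvenanceParams()
    out: list[str] = []
    for tok in tokens:
        if params.strip_speaker_labels and _SPEAKER_LABEL.match(tok):
            continue
        if params.strip_punctuation:
            tok = _EDGE_PUNCT.sub("", tok)
        if params.lowercase:
            tok = tok.casefold()
        if tok:
            out.append(tok)
    return out


def _best_window_score(
    needle: Counter[str], k: int, haystack: list[str], lengths: range
) -> float:
    """Max multiset-Jaccard over all haystack windows with length in ``lengths``."""
    best = 0.0
    n = len(haystack)
    needle_total = k
    for w in lengths:
        if w > n:
            w = n  # a short transcript is its own only window
        window = Counter(haystack[:w])
        inter = sum(min(c, needle[t]) for t, c in window.items())
        for start in range(n - w + 1):
            union = needle_total + w - inter
            score = inter / union if union else 0.0
            if score > best:
                best = score
                if best == 1.0:
                    return 1.0
            if start + w < n:
                out_tok = haystack[start]
                in_tok = haystack[start + w]
                if out_tok != in_tok:
                    # update intersection incrementally as the window slides
                    if window[out_tok] <= needle[out_tok]:
                        inter -= 1
                    window[out_tok] -= 1
                    window[in_tok] += 1
                    if window[in_tok] <= needle[in_tok]:
                        inter += 1
        if w >= n:
            break
    return best


def in_transcript(
    event: EditEvent,
    transcript_tokens: Sequence[str],
    params: ProvenanceParams | None = None,
) -> tuple[bool, float]:
    """Score an addition against the transcript.

    Returns ``(flag, score)`` where ``score`` is the maximum multiset Jaccard
    similarity between the normalized addition and any transcript window of
    length ``len(addition) ± window_slack``, and ``flag`` is
    ``score >= similarity_threshold``. The score is 1.0 exactly when some
    window is a token-multiset match. An addition or transcript that
    normalizes to nothing scores 0.0.

    Raises
    ------
    ValueError
        If called on a deletion event.
    """
    params = params or ProvenanceParams()
    if event.kind != ADDITION:
        raise ValueError("provenance applies to addition events only")
    needle_tokens = normalize_tokens(event.tokens, params)
    haystack = normalize_tokens(transcript_tokens, params)
    if not needle_tokens or not haystack:
        return False, 0.0
    k = len(needle_tokens)
    lengths = range(max(1, k - params.window_slack), k + params.window_slack + 1)
    score = _best_window_score(Counter(needle_tokens), k, haystack, lengths)
    return score >= params.similarity_threshold, score
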