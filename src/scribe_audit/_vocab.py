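"""Bundled clinical-flavoured filler vocabulary for the synthetic generator.

Three mutually disjoint pools. Note bodies draw from ``BASE_VOCAB``;
transcript-sourced additions draw from ``TRANSCRIPT_VOCAB`` (their sentences
are also planted in the transcript); fabricated additions draw from
``NOVEL_VOCAB`` and never appear in any transcript, so the provenance stage
has an unambiguous ground truth. Realistic medical language is a non-goal:
only the token-level structure matters, so each pool is a hand-written seed
list deterministically extended with hyphenated compounds of its own words.
"""

from __future__ import annotations

_BASE_SEED = [
    "patient", "presented", "with", "acute", "onset", "chest", "pain",
    "radiating", "left", "arm", "associated", "nausea", "diaphoresis",
    "denies", "fever", "cough", "shortness", "breath", "symptoms", "began",
    "hours", "ago", "while", "resting", "reports", "similar", "episode",
    "last", "year", "hypertension", "diabetes", "asthma", "managed",
    "metformin", "ramipril", "salbutamol", "aspirin", "daily", "allergies",
    "penicillin", "lives", "alone", "independent", "activities", "smokes",
    "ten", "cigarettes", "alcohol", "occasionally", "examination", "alert",
    "oriented", "vitals", "stable", "heart", "sounds", "dual", "murmurs",
    "chest", "clear", "auscultation", "abdomen", "soft", "nontender",
    "likely", "angina", "differential", "includes", "reflux",
    "musculoskeletal", "cause", "plan", "serial", "troponins", "ecg",
    "monitoring", "analgesia", "review", "cardiology", "admit", "short",
    "stay", "unit", "discharge", "pending", "results", "followup",
    "general", "practitioner", "widowed", "retired", "teacher", "mobilises",
    "frame", "supportive", "family", "nearby", "worsening", "dyspnoea",
    "orthopnoea", "ankle", "swelling", "two", "weeks", "duration",
    "paroxysmal", "nocturnal", "gained", "three", "kilograms", "frusemide",
    "dose", "increased", "recently", "ischaemic", "disease", "stent",
    "inserted", "atrial", "fibrillation", "apixaban", "therapy", "renal",
    "function", "checked", "electrolytes", "repeated", "morning", "fluid",
    "restriction", "advised", "daily", "weighs", "education", "provided",
]

_TRANSCRIPT_SEED = [
    "dizzy", "standing", "quickly", "blurred", "vision", "moments",
    "palpitations", "racing", "skipped", "beats", "sweaty", "clammy",
    "vomited", "twice", "overnight", "appetite", "poor", "since",
    "tuesday", "headache", "frontal", "throbbing", "light", "sensitivity",
    "neck", "stiffness", "absent", "tingling", "fingers", "numbness",
    "toes", "cramping", "calves", "walking", "uphill", "relieved",
    "rest", "burning", "urination", "frequency", "urgency", "flank",
    "ache", "dull", "constant", "nights", "woke", "gasping", "pillow",
    "propped", "wheeze", "audible", "sputum", "green", "streaked",
    "travelled", "interstate", "overseas", "contact", "unwell", "relatives",
]

_NOVEL_SEED = [
    "escalated", "registrar", "discussed", "consultant", "bedside",
    "reassessment", "planned", "repeat", "imaging", "requested",
    "orthostatic", "observations", "charted", "telemetry", "continued",
    "physiotherapy", "referral", "completed", "dietitian", "consulted",
    "ceftriaxone", "commenced", "intravenous", "fluids", "titrated",
    "oxygen", "weaned", "room", "air", "pressure", "areas", "inspected",
    "falls", "risk", "assessed", "social", "work", "involved", "interpreter",
    "booked", "fasted", "midnight", "anaesthetics", "notified", "consent",
    "obtained", "marked", "site", "checklist", "signed", "handover",
    "documented", "disposition", "confirmed", "transport", "arranged",
]


def _extend(seed: list[str], target: int) -> tuple[str, ...]:
    """Deduplicate a seed list and pad it with hyphen compounds of itself."""
    words: list[str] = []
    seen: set[str] = set()
    for w in seed:
        if w not in seen:
            seen.add(w)
            words.append(w)
    base = list(words)
    pairs = ((a, b) for a in base for b in base if a != b)
    for a, b in pairs:
        if len(words) >= target:
            break
        compound = f"{a}-{b}"
        if compound not in seen:
            seen.add(compound)
            words.append(compound)
    if len(words) < target:
        raise ValueError(f"seed list too small to reach {target} words")
    return tuple(words)


BASE_VOCAB: tuple[str, ...] = _extend(_BASE_SEED, 300)
TRANSCRIPT_VOCAB: tuple[str, ...] = _extend(_TRANSCRIPT_SEED, 160)
NOVEL_VOCAB: tuple[str, ...] = _extend(_NOVEL_SEED, 160)

assert not set(BASE_VOCAB) & set(TRANSCRIPT_VOCAB)
assert not set(BASE_VOCAB) & set(NOVEL_VOCAB)
assert not set(TRANSCRIPT_VOCAB) & set(NOVEL_VOCAB)
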