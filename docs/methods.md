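# Methods

## The documentation-time model

The package models, rather than measures, documentation time. For a corpus
of `N` notes it consumes five aggregate counts — final-note words `W_final`,
AI-draft words `W_ai`, words added `W_added`, words deleted `W_deleted`,
and `N` — and two typing speeds plus a reading speed:

* fully manual documentation: `T_manual = W_final / v_type`;
* scribe-assisted documentation: machine generation (`N · t_gen`), clinician
  review (`W_ai / v_read`), and editing (`(W_added + W_deleted) / v_type`).

Defaults are population estimates: 52 WPM for an average typist, 65 WPM for
a fast typist, 238 WPM adult reading speed, and a constant 10 s of machine
generation per note. All are configurable (`TimeModelParams`, YAML `time:`
block). The five counts are treated as independent inputs and never derived
from one another: real corpora do not reconcile them exactly (moved text,
markers, formatting), and the model's purpose is arithmetic on whatever
counts the user supplies.

Assumptions worth stating: editing is priced at typing speed even for
deletions; review time covers the whole AI draft once; generation time is
constant per note; speeds come from general-population literature, not from
ED clinicians. These are the standard simplifications of digital-scribe
efficiency modelling, and they mean the outputs are modelled, comparative
quantities — not wall-clock measurements.

### Rounding modes

`exact` keeps full precision: the total is the unrounded sum of components.
`paper_rounding` reproduces the arithmetic style of published efficiency
studies: every component is converted to hours and rounded (half-up) to one
decimal *before* summation, the savings are differenced on the rounded
figures, and the efficiency percentage is rounded to one decimal. The two
modes can differ by ~0.1 h / ~0.5 percentage points (e.g. 6.999 h exact vs
7.1 h rounded savings on the same inputs); scientific users should prefer
`exact`, while `paper_rounding` exists so printed study figures are exactly
recomputable. Minute displays round half-up to the nearest minute.

## Counting conventions

A **word** is a maximal run of non-whitespace characters (Unicode
whitespace delimits; punctuation stays attached). The word-count literature
behind WPM rates does not fix a tokenizer; this is the simplest convention
and only internal consistency matters, since the time model takes aggregate
counts as inputs. **Characters** are non-whitespace by default; a
`chars_include_whitespace` switch exists because published word:character
ratios are also consistent with whitespace-inclusive counting, and nothing
downstream depends on the choice.

Banner markers — the fixed sentinel strings bracketing AI content in the
EMR — are stripped *before* any counting: they are study artifacts, not
clinician documentation. Section headers, by contrast, are counted: they are
part of the note a clinician would otherwise type. A note with exactly one
of the two markers is malformed and the encounter is skipped with a logged
reason; a note with neither is not AI-generated and is excluded from all
aggregates rather than treated as a fully manual note.

## Edit identification

Additions and deletions are the gaps of a longest-common-subsequence
alignment between the tokenized initial and final notes. The implementation
is an `O(nm)` dynamic program — clinical notes are short (hundreds of
tokens), so quadratic cost is immaterial — and the alignment is minimal by
construction: total edited tokens equal `len(A) + len(B) − 2·LCS(A,B)`,
which the test suite checks against an independent exhaustive-recursion
oracle. Among equally minimal alignments, ties are broken deterministically
(matches leftmost; within a gap, the deletion precedes the insertion), so
event anchors are reproducible run to run. Equality is case- and
punctuation-sensitive. Moves are counted as delete + insert; no move
detection is attempted.

An **alteration** is one maximal contiguous run of inserted or deleted
tokens. A replacement therefore counts as two alterations (one of each
kind). This grouping is exercised against planted ground truth on synthetic
corpora; on real corpora different grouping conventions would shift event
*counts* (not word totals), which is why word totals, not event counts, feed
the time model.

Additions are attributed to the section containing their insertion point in
the **final** note; deletions to the section containing the removed run in
the **initial** note (a deleted token has no final-note position, so this is
the only well-defined symmetric rule). An edit that swallows a section
boundary takes the section of its first token. Headers are matched only as
whole lines, case-insensitively, with an optional trailing colon, through a
configurable synonym lexicon ("Plan" → Management Plan, "Pmx" → PMHx, …);
text before the first recognized header is "Unsectioned".

## Transcript provenance

Whether an addition's content was already present in the transcript is
decided by a deterministic surrogate for human/LLM judgement: after
normalization (lowercasing, stripping edge punctuation and speaker labels
"DOCTOR:"/"PATIENT:"), the addition is scored against every transcript
window of length `len(addition) ± window_slack` (default slack 2) by
multiset Jaccard similarity; the flag is `score ≥ 0.6`, ties counting as
in-transcript. The score is 1.0 exactly when some window is a token-multiset
match, and lowering the threshold can only turn flags on, never off (both
properties are tested). The surrogate is reproducible and oracle-checkable
but deliberately not semantic: paraphrases with disjoint vocabulary score 0.
In-transcript rates on real data therefore depend on how literally
clinicians copy from the conversation, and the package makes no claim of
equivalence to an LLM-based judgement.

## The synthetic corpus generator

The generator emulates the *structure* of a scribe study corpus — not its
language. Each encounter gets a six-section note (bodies of 20–36 filler
words per section; median note length ≈ 175 words, matching the scale of ED
scribe notes), an alternating DOCTOR:/PATIENT: transcript, and planted
edits: per section, an addition with probability 0.6 and a deletion with
probability 0.18 (≈ 3.5 additions and 1 deletion per note), additions of
4–20 words, 82.8% of them sourced verbatim from the transcript, and roles
sampled 74.6% trainee. All defaults live in `GeneratorConfig` and a single
seed drives everything, so corpora are byte-identical across runs.

Three design constraints make ground truth exactly recoverable:

1. **Disjoint vocabulary pools.** Note bodies, transcript-sourced additions
   and fabricated ("novel") additions draw from three disjoint pools, and
   words are sampled without replacement within a note, so no planted edit
   shares boundary tokens with its context.
2. **Separated placement.** Within a section body the deletion lives in the
   first half and the insertion point in the second, each ≥ 2 unchanged
   tokens from section boundaries and from each other; edits never overlap.
3. **Provenance by construction.** Each transcript-sourced addition is
   planted verbatim as one transcript turn; novel additions share no
   vocabulary with any transcript.

Consequently the minimal LCS alignment is unique, diff recovery of planted
edits is one-to-one in kind, payload, anchor and section, and the provenance
stage separates the two addition classes at 100%/0% — *by construction*.
Passing these checks demonstrates that the machinery is correct, not that it
would achieve any particular accuracy on real clinical text, where edits
overlap, repeat vocabulary, and paraphrase. Realistic medical language,
clinical plausibility and audio simulation are explicit non-goals.

## Numerical and degenerate-input choices

* Rounding is half-up (away from zero) everywhere a display rounds; Python's
  banker's rounding is never used for reported figures.
* Quantiles (per-note medians/IQRs) use linear interpolation between order
  statistics (`numpy.percentile` default); the convention is declared
  because small-sample IQRs differ across conventions.
* Empty inputs: an empty token list diffs to no events; a headerless note
  parses as one Unsectioned section; an addition that normalizes to nothing
  (pure punctuation) scores 0.0; `efficiency = 0` when manual time is 0;
  an empty or fully skipped corpus is an error, a partially skipped one is
  not.
* Problem sizes: the test suite and acceptance script use corpora of 30–200
  encounters and 1,000 random diff pairs — sizes at which every ground-truth
  check is exhaustive yet the whole suite runs in well under a minute.

## Known limitations

* Time savings are modelled, not observed; per-clinician variation,
  interruptions and EMR navigation are out of scope.
* The provenance surrogate cannot credit paraphrase; its in-transcript rates
  are not comparable to semantic (LLM or human) judgements.
* Alteration counts depend on the grouping convention; only word totals are
  convention-free.
* Section attribution trusts the header lexicon; unheadered or
  unconventional notes fall into "Unsectioned" rather than being inferred.
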