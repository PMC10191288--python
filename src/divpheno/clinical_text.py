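"""Rule-based detection of diverticular-disease mentions in clinical text.

Implements a NegEx/ConText-style assertion pipeline: sentence splitting,
closed-vocabulary mention finding for the ``diverticul*`` family, and
trigger/scope assertion classification (negated, hypothetical, attributed
to another experiencer, historical). The trigger lexicon is a plain TSV
shipped with the package and fully editable by the user.

Offsets are 0-based half-open into the original document text throughout.
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from typing import Iterable, Sequence


class Concept(str, enum.Enum):
    DIVERTICULUM_ANY = "DIVERTICULUM_ANY"
    DIVERTICULITIS = "DIVERTICULITIS"


class Assertion(str, enum.Enum):
    AFFIRMED = "affirmed"
    NEGATED = "negated"
    HYPOTHETICAL = "hypothetical"
    OTHER_EXPERIENCER = "other_experiencer"
    HISTORICAL_AFFIRMED = "historical_affirmed"


class TriggerCategory(str, enum.Enum):
    PRE_NEGATION = "pre_negation"
    POST_NEGATION = "post_negation"
    PSEUDO_NEGATION = "pseudo_negation"
    TERMINATION = "termination"
    HYPOTHETICAL = "hypothetical"
    EXPERIENCER_OTHER = "experiencer_other"
    HISTORICAL = "historical"


#: assertion statuses that count as a positive finding for phenotyping;
#: historical mentions count because diverticulosis is a chronic, lifetime
#: phenotype. Configurable at the summarize_document call site.
POSITIVE_ASSERTIONS = frozenset({Assertion.AFFIRMED, Assertion.HISTORICAL_AFFIRMED})

# precedence when scopes of several categories cover the same mention
_PRECEDENCE = (
    Assertion.NEGATED,
    Assertion.OTHER_EXPERIENCER,
    Assertion.HYPOTHETICAL,
    Assertion.HISTORICAL_AFFIRMED,
)

_CATEGORY_TO_ASSERTION = {
    TriggerCategory.PRE_NEGATION: Assertion.NEGATED,
    TriggerCategory.POST_NEGATION: Assertion.NEGATED,
    TriggerCategory.HYPOTHETICAL: Assertion.HYPOTHETICAL,
    TriggerCategory.EXPERIENCER_OTHER: Assertion.OTHER_EXPERIENCER,
    TriggerCategory.HISTORICAL: Assertion.HISTORICAL_AFFIRMED,
}

#: closed stem list — deliberately NOT a raw ``diverticul*`` wildcard so that
#: surgical-history terms such as "diverticulectomy" are not matched.
_STEMS = (
    "diverticula",
    "diverticulae",
    "diverticular",
    "diverticuli",
    "diverticulitis",
    "diverticulosis",
    "diverticulum",
)
_MENTION_RE = re.compile(r"\b(" + "|".join(_STEMS) + r")\b", re.IGNORECASE)

_SENTENCE_DELIMS = ".!?;"


class LexiconError(ValueError):
    """Raised when a trigger lexicon file is malformed."""


@dataclass(frozen=True)
class ReportDocument:
    """One clinical report: a colonoscopy/imaging/other note with free text."""

    patient_id: str
    report_type: str  # "colonoscopy" | "abdominal_imaging" | "other"
    report_date: date
    text: str

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValueError("patient_id must be non-empty")


@dataclass(frozen=True)
class ContextTrigger:
    phrase: str
    category: TriggerCategory
    scope_direction: str  # "forward" | "backward" | "bidirectional"
    max_scope_tokens: int | None  # None => scope runs to the sentence boundary

    def __post_init__(self) -> None:
        if not self.phrase:
            raise LexiconError("trigger phrase must be non-empty")


@dataclass
class Mention:
    concept: Concept
    char_start: int
    char_end: int
    sentence_index: int
    matched_text: str
    assertion: Assertion | None = None


@dataclass(frozen=True)
class DocumentAssertion:
    positive_diverticulosis: bool
    positive_diverticulitis: bool
    any_negated_mention: bool
    mention_count: int


def _load_lines(name: str) -> list[str]:
    with resources.files("divpheno.data").joinpath(name).open("r", encoding="utf-8") as fh:
        return fh.read().splitlines()


def default_abbreviations() -> frozenset[str]:
    """Abbreviation guard list for the sentence splitter (no trailing dots)."""
    out = []
    for line in _load_lines("abbreviations.txt"):
        line = line.strip().lower()
        if line and not line.startswith("#"):
            out.append(line)
    return frozenset(out)


def load_trigger_lexicon(path=None) -> list[ContextTrigger]:
    """Load a trigger lexicon TSV (phrase, category, direction, max_scope).

    ``max_scope`` is a positive integer or the sentinel ``sent`` meaning
    "until the sentence boundary". With no ``path`` the packaged default
    lexicon is loaded.
    """
    if path is None:
        rows = csv.DictReader(_load_lines("context_triggers.tsv"), delimiter="\t")
    else:
        with open(path, "r", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh, delimiter="\t"))
    triggers = []
    for row in rows:
        try:
            category = TriggerCategory(row["category"].strip())
        except ValueError as exc:
            raise LexiconError(
                f"unknown trigger category {row['category']!r} for phrase {row['phrase']!r}"
            ) from exc
        direction = row["direction"].strip()
        if direction not in {"forward", "backward", "bidirectional"}:
            raise LexiconError(f"unknown scope direction {direction!r}")
        raw_scope = row["max_scope"].strip().lower()
        max_scope = None if raw_scope in {"sent", "sentence_end"} else int(raw_scope)
        triggers.append(ContextTrigger(row["phrase"].strip().lower(), category, direction, max_scope))
    return triggers


def split_sentences(
    text: str, abbreviations: Iterable[str] | None = None
) -> list[tuple[int, int]]:
    """Split text into ordered, disjoint sentence spans (0-based half-open).

    Splits after ``. ! ? ;`` followed by whitespace (or end of text) and at
    newlines, guarding against decimal numbers ("35.5 cm") and a configurable
    abbreviation list ("Dr.", "e.g."). Empty text yields an empty list.
    """
    if not text:
        return []
    abbrevs = default_abbreviations() if abbreviations is None else {a.lower() for a in abbreviations}
    boundaries: list[int] = []
    n = len(text)
    for i, ch in enumerate(text):
        if ch == "\n":
            boundaries.append(i + 1)
            continue
        if ch not in _SENTENCE_DELIMS:
            continue
        nxt = text[i + 1] if i + 1 < n else None
        if nxt is not None and not nxt.isspace():
            continue  # also guards "35.5" (digit follows the dot)
        if ch == "." and _ends_with_abbreviation(text, i, abbrevs):
            continue
        boundaries.append(i + 1)
    spans = []
    start = 0
    for b in boundaries + [n]:
        seg = text[start:b]
        lead = len(seg) - len(seg.lstrip())
        trail = len(seg) - len(seg.rstrip())
        if seg.strip():
            spans.append((start + lead, b - trail))
        start = b
    return spans


def _ends_with_abbreviation(text: str, dot_index: int, abbrevs: set[str] | frozenset[str]) -> bool:
    prefix = text[:dot_index].lower()
    for abbr in abbrevs:
        if prefix.endswith(abbr):
            before = dot_index - len(abbr) - 1
            if before < 0 or not (text[before].isalnum() or text[before] == "."):
                return True
    return False


def find_mentions(text: str) -> list[Mention]:
    """Locate every ``diverticul*`` mention (closed stem list), assertion unset."""
    spans = split_sentences(text)
    mentions = []
    for m in _MENTION_RE.finditer(text):
        stem = m.group(1).lower()
        concept = Concept.DIVERTICULITIS if stem == "diverticulitis" else Concept.DIVERTICULUM_ANY
        sent_idx = _sentence_index(spans, m.start())
        mentions.append(
            Mention(
                concept=concept,
                char_start=m.start(),
                char_end=m.end(),
                sentence_index=sent_idx,
                matched_text=m.group(0),
            )
        )
    return mentions


def _sentence_index(spans: Sequence[tuple[int, int]], pos: int) -> int:
    for i, (s, e) in enumerate(spans):
        if s <= pos < e:
            return i
    # a mention outside every span can only happen with exotic whitespace;
    # attribute it to the nearest preceding sentence
    for i in range(len(spans) - 1, -1, -1):
        if spans[i][0] <= pos:
            return i
    return 0


@dataclass(frozen=True)
class _Token:
    start: int
    end: int
    norm: str


_TOKEN_RE = re.compile(r"\S+")
_EDGE_PUNCT = ".,;:!?()\"'[]{}"


def _tokenize(text: str, span: tuple[int, int]) -> list[_Token]:
    tokens = []
    for m in _TOKEN_RE.finditer(text, span[0], span[1]):
        raw = m.group(0)
        lead = len(raw) - len(raw.lstrip(_EDGE_PUNCT))
        core = raw.strip(_EDGE_PUNCT)
        if not core:
            continue
        start = m.start() + lead
        tokens.append(_Token(start, start + len(core), core.lower()))
    return tokens


@dataclass(frozen=True)
class _TriggerMatch:
    tok_start: int  # token index, inclusive
    tok_end: int  # token index, exclusive
    trigger: ContextTrigger

    def __len__(self) -> int:
        return self.tok_end - self.tok_start


def _match_triggers(tokens: list[_Token], triggers: Sequence[ContextTrigger]) -> list[_TriggerMatch]:
    phrase_tokens = [(t, t.phrase.split()) for t in triggers]
    raw: list[_TriggerMatch] = []
    for i in range(len(tokens)):
        for trig, words in phrase_tokens:
            k = len(words)
            if i + k <= len(tokens) and all(tokens[i + j].norm == words[j] for j in range(k)):
                raw.append(_TriggerMatch(i, i + k, trig))
    # longest-match resolution: prefer longer matches; among equal lengths a
    # pseudo-negation match wins so that it can suppress what it contains
    raw.sort(key=lambda m: (-len(m), m.trigger.category != TriggerCategory.PSEUDO_NEGATION, m.tok_start))
    kept: list[_TriggerMatch] = []
    for m in raw:
        if not any(m.tok_start < k.tok_end and k.tok_start < m.tok_end for k in kept):
            kept.append(m)
    kept.sort(key=lambda m: m.tok_start)
    return kept


def _scope_tokens(match: _TriggerMatch, matches: list[_TriggerMatch], n_tokens: int) -> set[int]:
    """Token indices covered by a trigger's scope within one sentence."""
    trig = match.trigger
    cap = trig.max_scope_tokens
    covered: set[int] = set()
    if trig.scope_direction in ("forward", "bidirectional"):
        end = n_tokens if cap is None else min(n_tokens, match.tok_end + cap)
        for other in matches:
            if other is match or other.tok_start < match.tok_end:
                continue
            if other.trigger.category in (TriggerCategory.TERMINATION, trig.category):
                end = min(end, other.tok_start)
        covered.update(range(match.tok_end, end))
    if trig.scope_direction in ("backward", "bidirectional"):
        start = 0 if cap is None else max(0, match.tok_start - cap)
        for other in matches:
            if other is match or other.tok_end > match.tok_start:
                continue
            if other.trigger.category in (TriggerCategory.TERMINATION, trig.category):
                start = max(start, other.tok_end)
        covered.update(range(start, match.tok_start))
    return covered


def apply_context(
    text: str,
    mentions: list[Mention],
    triggers: Sequence[ContextTrigger] | None = None,
    sentences: Sequence[tuple[int, int]] | None = None,
) -> list[Mention]:
    """Assign an assertion status to every mention via trigger scopes.

    Per sentence: triggers are located by longest match (pseudo-negation
    matches absorb any negation phrase they contain and assign nothing);
    each remaining trigger opens a scope in its direction that ends at a
    termination trigger, another trigger of the same category, its token
    cap, or the sentence boundary. A mention covered by several scopes takes
    the highest-precedence status: negated > other_experiencer >
    hypothetical > historical_affirmed; uncovered mentions are affirmed.
    """
    if triggers is None:
        triggers = load_trigger_lexicon()
    if sentences is None:
        sentences = split_sentences(text)
    by_sentence: dict[int, list[Mention]] = {}
    for m in mentions:
        by_sentence.setdefault(m.sentence_index, []).append(m)
    for idx, span in enumerate(sentences):
        sent_mentions = by_sentence.get(idx)
        if not sent_mentions:
            continue
        tokens = _tokenize(text, span)
        matches = _match_triggers(tokens, triggers)
        active = [
            m
            for m in matches
            if m.trigger.category
            not in (TriggerCategory.PSEUDO_NEGATION, TriggerCategory.TERMINATION)
        ]
        scope_status: dict[int, set[Assertion]] = {}
        for match in active:
            status = _CATEGORY_TO_ASSERTION[match.trigger.category]
            for tok_idx in _scope_tokens(match, matches, len(tokens)):
                scope_status.setdefault(tok_idx, set()).add(status)
        for mention in sent_mentions:
            tok_idx = next(
                (
                    i
                    for i, t in enumerate(tokens)
                    if t.start < mention.char_end and mention.char_start < t.end
                ),
                None,
            )
            statuses = scope_status.get(tok_idx, set()) if tok_idx is not None else set()
            mention.assertion = next((s for s in _PRECEDENCE if s in statuses), Assertion.AFFIRMED)
    for m in mentions:
        if m.assertion is None:  # mention in a sentence with no tokens (cannot normally happen)
            m.assertion = Assertion.AFFIRMED
    return mentions


def annotate(text: str, triggers: Sequence[ContextTrigger] | None = None) -> list[Mention]:
    """find_mentions + apply_context in one call."""
    return apply_context(text, find_mentions(text), triggers)


def summarize_document(
    mentions: Sequence[Mention],
    positive_assertions: frozenset[Assertion] = POSITIVE_ASSERTIONS,
) -> DocumentAssertion:
    """Collapse annotated mentions into document-level positivity flags.

    A single positively asserted mention dominates any number of negated
    ones; a positively asserted diverticulitis mention implies
    diverticulosis positivity (diverticulitis is inflammation of existing
    diverticula).
    """
    if any(m.assertion is None for m in mentions):
        raise ValueError("all mentions must carry an assertion; run apply_context first")
    pos_any = any(m.assertion in positive_assertions for m in mentions)
    pos_itis = any(
        m.concept is Concept.DIVERTICULITIS and m.assertion in positive_assertions
        for m in mentions
    )
    return DocumentAssertion(
        positive_diverticulosis=pos_any or pos_itis,
        positive_diverticulitis=pos_itis,
        any_negated_mention=any(m.assertion is Assertion.NEGATED for m in mentions),
        mention_count=len(mentions),
    )
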