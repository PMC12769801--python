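"""Clinical text processing: sections, sentences, concept extraction, assertion.

This is the "clinical text processing" half of the phenotype: a configurable
lexicon of literal surface patterns is matched case-insensitively
(longest-match per position), and each match is resolved for assertion
(affirmed / negated / hypothetical) and experiencer (patient / other) with a
NegEx-style token-window rule.  Section segmentation recognises line-anchored
headers ("FAMILY HISTORY:") from a configurable header dictionary; mentions
inside a family-history section, or in a sentence naming a relative, are
attributed to someone other than the patient and carry no evidential weight
downstream.
"""
from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .corpus_io import ClinicalNote, Section

__all__ = [
    "Lexicon",
    "ConceptMention",
    "segment_sections",
    "split_sentences",
    "extract_mentions",
    "assert_mention",
]

AFFIRMED = "affirmed"
NEGATED = "negated"
HYPOTHETICAL = "hypothetical"
PATIENT = "patient"
OTHER = "other"

_TOKEN_RE = re.compile(r"[A-Za-z0-9']+")


def _norm(phrase: str) -> str:
    return re.sub(r"\s+", " ", phrase.strip().lower())


@dataclass
class Lexicon:
    """Concept patterns plus context-rule configuration, loaded from YAML."""

    concepts: dict[str, list[str]]
    negation_triggers: list[str]
    scope_terminators: list[str]
    hypothetical_triggers: list[str]
    family_triggers: list[str]
    section_headers: dict[str, str]
    dx_sections: frozenset[str]
    abbreviations: list[str] = field(default_factory=list)
    negation_window: int = 5

    _pattern_re: Optional[re.Pattern] = field(default=None, repr=False, compare=False)
    _pattern_to_concept: dict[str, str] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.concepts:
            raise ValueError("lexicon has no concepts")
        seen: dict[str, str] = {}
        for cid, patterns in self.concepts.items():
            if not patterns:
                raise ValueError(f"concept {cid!r} has no patterns")
            for p in patterns:
                key = _norm(p)
                if not key:
                    raise ValueError(f"concept {cid!r} has an empty pattern")
                if key in seen and seen[key] != cid:
                    raise ValueError(f"pattern {p!r} maps to both {seen[key]!r} and {cid!r}")
                seen[key] = cid
        self._pattern_to_concept = seen

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "Lexicon":
        with Path(path).open("r", encoding="utf-8") as fh:
            cfg = yaml.safe_load(fh)
        return cls.from_config(cfg)

    @classmethod
    def from_config(cls, cfg: dict) -> "Lexicon":
        trig = cfg.get("triggers", {})
        sect = cfg.get("sections", {})
        return cls(
            concepts={str(k): [str(p) for p in v] for k, v in cfg["concepts"].items()},
            negation_triggers=[str(t) for t in trig.get("negation", [])],
            scope_terminators=[str(t) for t in trig.get("scope_terminators", [])],
            hypothetical_triggers=[str(t) for t in trig.get("hypothetical", [])],
            family_triggers=[str(t) for t in trig.get("family", [])],
            section_headers={_norm(k): str(v) for k, v in sect.get("headers", {}).items()},
            dx_sections=frozenset(sect.get("dx_sections", [])),
            abbreviations=[str(a) for a in cfg.get("abbreviations", [])],
            negation_window=int(trig.get("negation_window", 5)),
        )

    @classmethod
    def default(cls) -> "Lexicon":
        """The packaged default lexicon covering every PAC evidence concept."""
        path = resources.files("pacpheno").joinpath("data/default_lexicon.yaml")
        with resources.as_file(path) as p:
            return cls.from_yaml(p)

    @property
    def matcher(self) -> re.Pattern:
        """Compiled alternation over all patterns, longest-alternative first.

        Python's regex engine tries alternatives left to right at each
        position, so sorting by descending length yields longest-match-per-
        position; ``finditer`` then never emits overlapping matches.
        """
        if self._pattern_re is None:
            pats = sorted(self._pattern_to_concept, key=len, reverse=True)
            alts = "|".join(re.escape(p).replace(r"\ ", r"\s+") for p in pats)
            self._pattern_re = re.compile(rf"(?<!\w)(?:{alts})(?!\w)", re.IGNORECASE)
        return self._pattern_re

    def concept_for(self, matched_text: str) -> str:
        return self._pattern_to_concept[_norm(matched_text)]


@dataclass(frozen=True)
class ConceptMention:
    """An extracted PAC-relevant concept with its context attributes."""

    concept_id: str
    patient_id: str
    note_id: str
    note_date: dt.date
    span: tuple[int, int]  # character offsets into the note text
    section_label: str
    assertion: str  # affirmed | negated | hypothetical
    experiencer: str  # patient | other


# ---------------------------------------------------------------------------
# section segmentation

_HEADER_LINE_RE = re.compile(r"^[ \t]*([A-Za-z][A-Za-z /]{0,58}?)[ \t]*:")


def segment_sections(note: ClinicalNote, lexicon: Lexicon) -> ClinicalNote:
    """Populate ``note.sections`` by line-anchored header matching.

    Any text before the first recognised header becomes a section labelled
    ``unknown``; a headerless note is one big ``unknown`` section.  Section
    spans tile the document (the header line itself belongs to its section).
    """
    if not note.text:
        raise ValueError("segment_sections: note text is empty")
    boundaries: list[tuple[int, str]] = []
    for m in re.finditer(r"[^\n]*", note.text):
        if m.start() == m.end():
            continue
        hm = _HEADER_LINE_RE.match(m.group(0))
        if hm:
            label = lexicon.section_headers.get(_norm(hm.group(1)))
            if label:
                boundaries.append((m.start(), label))
    sections: list[Section] = []
    if not boundaries or boundaries[0][0] > 0:
        first = boundaries[0][0] if boundaries else len(note.text)
        sections.append(Section("unknown", 0, first))
    for i, (start, label) in enumerate(boundaries):
        end = boundaries[i + 1][0] if i + 1 < len(boundaries) else len(note.text)
        sections.append(Section(label, start, end))
    return ClinicalNote(
        patient_id=note.patient_id,
        note_id=note.note_id,
        note_date=note.note_date,
        text=note.text,
        provider_type=note.provider_type,
        sections=[s for s in sections if s.start < s.end],
    )


# ---------------------------------------------------------------------------
# sentence splitting

_WORD_BEFORE_DOT = re.compile(r"([A-Za-z]\w*)$")


def split_sentences(
    text: str, abbreviations: Sequence[str] = (), offset: int = 0
) -> list[tuple[int, int]]:
    """Deterministic rule-based sentence spans over ``text``.

    Splits on ``.!?`` and newlines; a period closing a guarded abbreviation
    ("Dr.", "vs.") or sitting between two digits does not end a sentence.
    Returned spans are half-open, shifted by ``offset``, and cover every
    non-whitespace character in order.
    """
    guard = {a.lower().rstrip(".") for a in abbreviations}
    spans: list[tuple[int, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "\n" or ch in "!?":
            boundary = True
        elif ch == ".":
            boundary = True
            if 0 < i < len(text) - 1 and text[i - 1].isdigit() and text[i + 1].isdigit():
                boundary = False
            else:
                m = _WORD_BEFORE_DOT.search(text, max(start, i - 20), i)
                if m and m.group(1).lower() in guard:
                    boundary = False
        else:
            boundary = False
        if boundary:
            if text[start : i + 1].strip():
                spans.append((start + offset, i + 1 + offset))
            start = i + 1
    if text[start:].strip():
        spans.append((start + offset, len(text) + offset))
    return spans


# ---------------------------------------------------------------------------
# assertion / experiencer

def _trigger_spans(
    tokens: list[tuple[str, int, int]], triggers: Sequence[str]
) -> list[tuple[int, int]]:
    """Token-index ranges ``(i, j)`` (inclusive) where a trigger phrase sits."""
    out = []
    trigger_tokens = [tuple(t.lower().split()) for t in triggers]
    words = [t[0] for t in tokens]
    for tt in trigger_tokens:
        k = len(tt)
        for i in range(len(words) - k + 1):
            if tuple(words[i : i + k]) == tt:
                out.append((i, i + k - 1))
    return out


def assert_mention(
    sentence: str,
    concept_span: tuple[int, int],
    lexicon: Lexicon,
    section_label: str = "unknown",
) -> tuple[str, str]:
    """Resolve (assertion, experiencer) for a concept span inside a sentence.

    A negation trigger within ``negation_window`` tokens before the concept,
    with no scope terminator ("but", "however", ...) in between, yields
    ``negated``; hypothetical triggers the same way yield ``hypothetical``.
    A family trigger anywhere in the sentence, or a family-history section,
    yields experiencer ``other``.  Default: (affirmed, patient).
    """
    tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(sentence)]
    cidx = next((i for i, t in enumerate(tokens) if t[2] > concept_span[0]), len(tokens))
    terminators = {t.lower() for t in lexicon.scope_terminators}

    def in_scope(spans: list[tuple[int, int]]) -> bool:
        for _, j in spans:
            if j < cidx and (cidx - j) <= lexicon.negation_window:
                if not any(tokens[k][0] in terminators for k in range(j + 1, cidx)):
                    return True
        return False

    if in_scope(_trigger_spans(tokens, lexicon.negation_triggers)):
        assertion = NEGATED
    elif in_scope(_trigger_spans(tokens, lexicon.hypothetical_triggers)):
        assertion = HYPOTHETICAL
    else:
        assertion = AFFIRMED

    experiencer = PATIENT
    if section_label == "family_history" or _trigger_spans(tokens, lexicon.family_triggers):
        experiencer = OTHER
    return assertion, experiencer


# ---------------------------------------------------------------------------
# extraction

def extract_mentions(note: ClinicalNote, lexicon: Lexicon) -> list[ConceptMention]:
    """Extract all lexicon concept mentions from one note.

    Sections must be populated (a note with none is treated as one ``unknown``
    section).  Matching is case-insensitive and longest-match per position, so
    a phrase like "nocturnal cough and wheeze" is one mention, not three.
    """
    if not lexicon.concepts:
        raise ValueError("extract_mentions: empty lexicon")
    if not note.text:
        return []
    sections = note.sections or [Section("unknown", 0, len(note.text))]
    mentions: list[ConceptMention] = []
    for sec in sections:
        sec_text = note.text[sec.start : sec.end]
        for ss, se in split_sentences(sec_text, lexicon.abbreviations, offset=0):
            sent_text = sec_text[ss:se]
            for m in lexicon.matcher.finditer(sent_text):
                assertion, experiencer = assert_mention(
                    sent_text, (m.start(), m.end()), lexicon, sec.label
                )
                mentions.append(
                    ConceptMention(
                        concept_id=lexicon.concept_for(m.group(0)),
                        patient_id=note.patient_id,
                        note_id=note.note_id,
                        note_date=note.note_date,
                        span=(sec.start + ss + m.start(), sec.start + ss + m.end()),
                        section_label=sec.label,
                        assertion=assertion,
                        experiencer=experiencer,
                    )
                )
    return mentions
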