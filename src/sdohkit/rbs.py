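"""Rule-based SDoH extraction: sentence segmentation, lexicon-based entity
matching, contextual disambiguation, and note prescreening.

The pipeline mirrors classic clinical information-extraction systems: a
sentence splitter feeds a dictionary matcher whose hits ("mentions") are
disambiguated by a simplified ConText-style cue engine.  A cue rule (e.g.
the negation trigger "denies") projects a scope — forward, backward, or
both — bounded by terminator tokens and a token cap; any mention inside the
scope inherits the cue's attribute.  Mentions surviving the positivity
predicate contribute their target subcategory and its parent domain to the
segment's label set.

Prescreening locates candidate mentions in whole notes and cuts windows of
``window`` characters of context on either side (default 150), merging
overlapping windows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Sequence

from .lexicon import Lexicon, LexiconEntry
from .schema import (
    ConfigError,
    ContextAttributes,
    LabelSet,
    Segment,
    Taxonomy,
    is_positive_case,
)

__all__ = [
    "CueRule",
    "Mention",
    "classify_segment_rbs",
    "default_cue_rules_path",
    "default_lexicon_path",
    "detect_context",
    "load_cue_rules",
    "match_entities",
    "prescreen_note",
    "segment_sentences",
]

_CUE_CLASSES = ("negation", "historical", "experiencer", "hypothetical", "uncertainty")
_DIRECTIONS = ("forward", "backward", "bidirectional")


@dataclass(frozen=True)
class Mention:
    """A lexicon hit inside a segment, with its contextual attributes."""

    segment_id: str
    matched_text: str
    span: tuple[int, int]
    entry: LexiconEntry
    attrs: ContextAttributes


@dataclass(frozen=True)
class CueRule:
    """A contextual trigger with its scope model."""

    cue_pattern: str
    cue_class: str
    direction: str = "forward"
    scope_terminators: tuple[str, ...] = ("but", "however")
    max_scope_tokens: int = 10

    def __post_init__(self) -> None:
        if self.cue_class not in _CUE_CLASSES:
            raise ValueError(f"bad cue_class: {self.cue_class!r}")
        if self.direction not in _DIRECTIONS:
            raise ValueError(f"bad direction: {self.direction!r}")
        if self.max_scope_tokens < 1:
            raise ValueError("max_scope_tokens must be >= 1")


def default_lexicon_path() -> Path:
    return Path(str(resources.files("sdohkit").joinpath("data/lexicon.tsv")))


def default_cue_rules_path() -> Path:
    return Path(str(resources.files("sdohkit").joinpath("data/cue_rules.tsv")))


def load_cue_rules(path: str | Path) -> list[CueRule]:
    """Read cue rules from a tab-delimited file (see the shipped default)."""
    rules: list[CueRule] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ConfigError(f"{path}:{lineno}: expected 5 tab-separated columns")
            pattern, cls, direction, terms, cap = (c.strip() for c in cols)
            rules.append(
                CueRule(
                    cue_pattern=pattern,
                    cue_class=cls,
                    direction=direction,
                    scope_terminators=tuple(t for t in terms.split(";") if t),
                    max_scope_tokens=int(cap),
                )
            )
    return rules


# --- sentence segmentation ---------------------------------------------------

_BOUNDARY = re.compile(r"[.!?]+(?=\s|$)|\n+")


def segment_sentences(text: str) -> list[tuple[int, int]]:
    """Split ``text`` into sentence spans (0-based, half-open).

    Rules, in full: a run of terminal punctuation ``. ! ?`` followed by
    whitespace or end-of-text closes a sentence (the punctuation belongs to
    the sentence); any newline run is also a boundary, accommodating
    list-style clinical notes.  Leading/trailing whitespace is trimmed from
    each span, and whitespace-only chunks are dropped, so the returned spans
    are disjoint, ordered, and jointly cover every non-whitespace character.
    """
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _BOUNDARY.finditer(text):
        end = m.end() if m.group()[0] != "\n" else m.start()
        _append_trimmed(spans, text, start, end)
        start = m.end()
    _append_trimmed(spans, text, start, len(text))
    return spans


def _append_trimmed(spans: list, text: str, start: int, end: int) -> None:
    chunk = text[start:end]
    lead = len(chunk) - len(chunk.lstrip())
    trail = len(chunk) - len(chunk.rstrip())
    if start + lead < end - trail:
        spans.append((start + lead, end - trail))


# --- entity matching ---------------------------------------------------------

def match_entities(
    sentence_text: str, lex: Lexicon, segment_id: str = ""
) -> list[Mention]:
    """All lexicon matches in ``sentence_text``, attributes defaulted.

    Literal patterns are word-boundary anchored; case sensitivity honored
    per entry.  Every occurrence of every entry is reported once, ordered by
    (start, end, pattern).
    """
    mentions: list[Mention] = []
    for entry in lex:
        for m in entry.compiled().finditer(sentence_text):
            if m.start() == m.end():
                continue
            mentions.append(
                Mention(
                    segment_id=segment_id,
                    matched_text=m.group(),
                    span=(m.start(), m.end()),
                    entry=entry,
                    attrs=ContextAttributes(),
                )
            )
    mentions.sort(key=lambda mn: (mn.span, mn.entry.pattern))
    return mentions


# --- contextual disambiguation ----------------------------------------------

_TOKEN = re.compile(r"\S+")


def _token_spans(text: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in _TOKEN.finditer(text)]


def _norm(tok: str) -> str:
    return tok.strip(".,;:!?()[]'\"").lower()


def detect_context(
    sentence_text: str,
    mention_span: tuple[int, int],
    rules: Sequence[CueRule],
) -> ContextAttributes:
    """Resolve the contextual attributes of a mention within its sentence.

    Each cue whose scope covers any token of the mention sets its attribute;
    cue classes fire independently (the attributes are orthogonal flags, and
    positivity is a conjunction, so precedence is immaterial).  A scope runs
    from the cue in its stated direction, up to ``max_scope_tokens`` tokens,
    stopping before any terminator token; the sentence edge always
    terminates it.
    """
    toks = _token_spans(sentence_text)
    mention_toks = {
        i for i, (s, e) in enumerate(toks)
        if s < mention_span[1] and e > mention_span[0]
    }
    attrs = ContextAttributes()
    lowered = sentence_text.lower()

    for rule in rules:
        pat = rule.cue_pattern.lower()
        for m in re.finditer(r"(?<!\w)" + re.escape(pat) + r"(?!\w)", lowered):
            cue_toks = [
                i for i, (s, e) in enumerate(toks) if s < m.end() and e > m.start()
            ]
            if not cue_toks:
                continue
            # a cue inside the mention itself does not modify it
            if set(cue_toks) <= mention_toks:
                continue
            covered: set[int] = set()
            if rule.direction in ("forward", "bidirectional"):
                covered |= _scope(toks, sentence_text, cue_toks[-1] + 1, +1, rule)
            if rule.direction in ("backward", "bidirectional"):
                covered |= _scope(toks, sentence_text, cue_toks[0] - 1, -1, rule)
            if covered & mention_toks:
                attrs = _apply_cue(attrs, rule.cue_class)
    return attrs


def _scope(
    toks: list[tuple[int, int]],
    text: str,
    start_idx: int,
    step: int,
    rule: CueRule,
) -> set[int]:
    terminators = {t.lower() for t in rule.scope_terminators}
    covered: set[int] = set()
    idx = start_idx
    for _ in range(rule.max_scope_tokens):
        if idx < 0 or idx >= len(toks):
            break
        tok = _norm(text[toks[idx][0]:toks[idx][1]])
        if tok in terminators:
            break
        covered.add(idx)
        idx += step
    return covered


def _apply_cue(attrs: ContextAttributes, cue_class: str) -> ContextAttributes:
    if cue_class == "negation":
        return replace(attrs, negated=True)
    if cue_class == "historical":
        return replace(attrs, temporality="historical")
    if cue_class == "experiencer":
        return replace(attrs, experiencer="other")
    if cue_class == "hypothetical":
        return replace(attrs, hypothetical=True)
    return replace(attrs, uncertain=True)


# --- segment classification --------------------------------------------------

def extract_mentions(
    seg: Segment, lex: Lexicon, rules: Sequence[CueRule]
) -> list[Mention]:
    """Lexicon mentions in a segment with contextual attributes resolved,
    sentence by sentence."""
    out: list[Mention] = []
    for s_start, s_end in segment_sentences(seg.text):
        sent = seg.text[s_start:s_end]
        for mn in match_entities(sent, lex, seg.segment_id):
            attrs = detect_context(sent, mn.span, rules)
            out.append(
                replace(
                    mn,
                    span=(mn.span[0] + s_start, mn.span[1] + s_start),
                    attrs=attrs,
                )
            )
    return out


def classify_segment_rbs(
    seg: Segment,
    lex: Lexicon,
    rules: Sequence[CueRule],
    tax: Taxonomy,
) -> LabelSet:
    """Label one segment: subcategories are the targets of mentions passing
    the positivity predicate, domains their parents; no surviving mention
    yields the sentinel labels at both levels."""
    subs = {
        mn.entry.target_subcategory
        for mn in extract_mentions(seg, lex, rules)
        if is_positive_case(mn.attrs)
    }
    if not subs:
        return LabelSet.sentinel(tax)
    doms = {tax.parent_map[s] for s in subs}
    return LabelSet.of(doms, subs)


# --- prescreening ------------------------------------------------------------

def prescreen_note(
    note_text: str,
    lex: Lexicon,
    window: int = 150,
    patient_id: str = "",
    note_id: str = "",
) -> list[Segment]:
    """Cut candidate segments around every lexicon match in a note.

    Each match yields the window ``[max(0, start - window),
    min(len, end + window))``; overlapping or touching windows are merged.
    Output segments are disjoint and sorted by position.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    n = len(note_text)
    intervals: list[tuple[int, int]] = []
    for entry in lex:
        for m in entry.compiled().finditer(note_text):
            intervals.append((max(0, m.start() - window), min(n, m.end() + window)))
    intervals.sort()
    merged: list[list[int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [
        Segment(
            segment_id=f"{note_id}:{s}-{e}",
            patient_id=patient_id,
            note_id=note_id,
            text=note_text[s:e],
            start=s,
            end=e,
        )
        for s, e in merged
    ]
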