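"""Prompt construction, pluggable completion backends, and response parsing
for LLM-based SDoH classification.

The classifier treats SDoH extraction as hierarchical multilabel
classification over a text segment: the model is asked for domain
categories first, then their subcategories, answering in a fixed
machine-readable dialect::

    DOMAINS: <name>; <name> | none
    SUBCATEGORIES: <name>; <name> | N/A

Three prompting *styles* vary only the inclusion threshold: ``strict``
requires explicit evidence, ``balanced`` accepts strongly implied evidence,
``liberal`` additionally accepts information reasonably likely from
context.  Few-shot blocks append worked examples (optionally with
reasoning) drawn from ``easy`` / ``hard`` / ``synthetic`` banks.

Backends implement a single ``complete(system_prompt, user_prompt) -> str``
contract.  The built-in :class:`MockBackend` is a pure keyword classifier
used for testing and offline pipelines: same inputs, same output, always.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import subprocess
import time
import urllib.request
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Protocol, Sequence, runtime_checkable

from .schema import LabelSet, Segment, Taxonomy

__all__ = [
    "BackendError",
    "CommandBackend",
    "FewShotExample",
    "HTTPBackend",
    "MockBackend",
    "PromptSpec",
    "ResponseParseError",
    "build_few_shot_block",
    "build_system_prompt",
    "build_user_prompt",
    "classify_segment_llm",
    "format_answer",
    "load_example_bank",
    "parse_response",
]

logger = logging.getLogger(__name__)

STYLES = ("strict", "balanced", "liberal")
EXAMPLE_SETS = ("easy", "hard", "synthetic", "none")

_STYLE_CLAUSES = {
    "strict": (
        "Inclusion threshold (strict): assign a label only when the text "
        "provides explicit evidence for it."
    ),
    "balanced": (
        "Inclusion threshold (balanced): assign a label when the text "
        "provides explicit evidence or the finding is strongly implied."
    ),
    "liberal": (
        "Inclusion threshold (liberal): assign a label for explicit or "
        "strongly implied evidence, and also for information deemed "
        "reasonably likely from the context."
    ),
}


class BackendError(RuntimeError):
    """Transport-level backend failure (retriable)."""


class ResponseParseError(ValueError):
    """The backend's response could not be mapped to a label set."""

    def __init__(self, message: str, raw_response: str):
        super().__init__(message)
        self.raw_response = raw_response


@dataclass(frozen=True)
class PromptSpec:
    """Configuration of one prompting strategy."""

    style: str = "balanced"
    shots: int = 0
    example_set: str = "none"
    with_explanations: bool = False

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValueError(f"bad style: {self.style!r}")
        if self.example_set not in EXAMPLE_SETS:
            raise ValueError(f"bad example_set: {self.example_set!r}")
        if self.shots < 0:
            raise ValueError("shots must be >= 0")
        if (self.shots == 0) != (self.example_set == "none"):
            raise ValueError("shots=0 if and only if example_set='none'")


@dataclass(frozen=True)
class FewShotExample:
    segment_text: str
    gold: LabelSet
    explanation: str | None = None


@runtime_checkable
class BackendContract(Protocol):
    is_deterministic: bool

    def complete(self, system_prompt: str, user_prompt: str) -> str: ...


# --- prompt construction -----------------------------------------------------

def build_system_prompt(tax: Taxonomy, spec: PromptSpec) -> str:
    """Three-component system prompt: role, label definitions, instructions.

    The instruction component fixes the hierarchical order (domains first,
    then subcategories), the no-finding sentinel, the contextual exclusion
    rule, the answer dialect, and the style-specific inclusion threshold.
    """
    if not tax.domains:
        raise ValueError("taxonomy has no domains")
    defs = "\n".join(
        f"- {dom}: subcategories = {', '.join(tax.children(dom)) or '(none)'}"
        for dom in tax.domains
    )
    return (
        "### 1. Role\n"
        "You are a clinical annotation assistant specializing in social "
        "determinants of health (SDoH). You read short clinical text "
        "segments and identify SDoH findings.\n"
        "\n"
        "### 2. Label definitions\n"
        f"{defs}\n"
        "\n"
        "### 3. Instructions\n"
        "Work step by step. Identify SDoH domain categories first, then "
        "their corresponding subcategories.\n"
        "Extract only current, patient-specific, and confirmed SDoH "
        "information; exclude historical mentions, findings about family "
        "members or other people, hypothetical or merely discussed "
        "situations (e.g. a clinician's recommendation), and uncertain or "
        "negated statements.\n"
        "If no relevant information is present, return 'none' for domains "
        f"and '{tax.subcategory_sentinel}' for subcategories.\n"
        f"{_STYLE_CLAUSES[spec.style]}\n"
        f"Style: {spec.style}\n"
        "Answer in exactly two lines:\n"
        "DOMAINS: <domain>; <domain> (or: none)\n"
        f"SUBCATEGORIES: <subcategory>; <subcategory> (or: {tax.subcategory_sentinel})\n"
    )


def format_answer(labels: LabelSet, tax: Taxonomy) -> str:
    """Serialize a label set in the answer dialect the parser reads."""
    doms = sorted(labels.positive_domains(tax)) or ["none"]
    subs = sorted(labels.positive_subcategories(tax)) or [tax.subcategory_sentinel]
    return f"DOMAINS: {'; '.join(doms)}\nSUBCATEGORIES: {'; '.join(subs)}"


def build_few_shot_block(examples: Sequence[FewShotExample], spec: PromptSpec, tax: Taxonomy) -> str:
    """Serialize worked examples as segment -> expected structured answer."""
    if len(examples) != spec.shots:
        raise ValueError(
            f"example count {len(examples)} does not match shots={spec.shots}"
        )
    parts = []
    for i, ex in enumerate(examples, start=1):
        if spec.with_explanations and not ex.explanation:
            raise ValueError(f"example {i} lacks the required explanation")
        block = (
            f"Example {i}:\nSegment: {ex.segment_text}\n"
            f"{format_answer(ex.gold, tax)}"
        )
        if spec.with_explanations:
            block += f"\nExplanation: {ex.explanation}"
        parts.append(block)
    return "\n\n".join(parts)


def build_user_prompt(seg: Segment, few_shot_block: str = "") -> str:
    prompt = ""
    if few_shot_block:
        prompt += few_shot_block + "\n\n"
    prompt += f"SEGMENT:\n<<<\n{seg.text}\n>>>\nAnswer:"
    return prompt


def load_example_bank(name: str, tax: Taxonomy) -> list[FewShotExample]:
    """Load one of the shipped example banks: easy, hard, or synthetic."""
    raw = json.loads(
        resources.files("sdohkit").joinpath("data/few_shot.json").read_text("utf-8")
    )
    if name not in raw or name.startswith("_"):
        raise KeyError(f"unknown example bank: {name!r}")
    return [
        FewShotExample(
            segment_text=r["segment_text"],
            gold=LabelSet.of(r["domains"], r["subcategories"]),
            explanation=r.get("explanation"),
        )
        for r in raw[name]
    ]


# --- response parsing --------------------------------------------------------

_LINE = re.compile(r"^\s*(domains|subcategories)\s*:\s*(.*)$", re.IGNORECASE)


def parse_response(text: str, tax: Taxonomy, strict: bool = False) -> LabelSet:
    """Map a backend response in the answer dialect to a :class:`LabelSet`.

    Sentinel tokens ('none', 'N/A', 'NA') yield sentinel labels; label
    matching is case-insensitive against the taxonomy.  Labels outside the
    taxonomy are dropped with a warning, or raise when ``strict``.
    Responses containing neither answer line raise
    :class:`ResponseParseError` carrying the raw text.
    """
    found: dict[str, list[str]] = {}
    for line in text.splitlines():
        m = _LINE.match(line)
        if m:
            key = m.group(1).lower()
            found.setdefault(key, [
                t.strip() for t in re.split(r"[;,]", m.group(2)) if t.strip()
            ])
    if not found:
        raise ResponseParseError("no DOMAINS/SUBCATEGORIES lines in response", text)

    dom_lookup = {d.lower(): d for d in tax.domains}
    sub_lookup = {s.lower(): s for s in tax.subcategories}

    def _resolve(tokens: list[str], lookup: Mapping[str, str], level: str) -> set[str]:
        out: set[str] = set()
        for tok in tokens:
            low = tok.lower().strip(".")
            if low in ("none", "n/a", "na", "none of the above"):
                continue
            if low in lookup:
                out.add(lookup[low])
            elif strict:
                raise ResponseParseError(
                    f"label outside taxonomy at {level} level: {tok!r}", text
                )
            else:
                logger.warning("dropping out-of-taxonomy %s label %r", level, tok)
        return out

    doms = _resolve(found.get("domains", []), dom_lookup, "domain")
    subs = _resolve(found.get("subcategories", []), sub_lookup, "subcategory")
    return LabelSet.of(
        doms or {tax.domain_sentinel}, subs or {tax.subcategory_sentinel}
    )


# --- backends ----------------------------------------------------------------

class MockBackend:
    """Deterministic keyword-table classifier posing as a completion backend.

    The mock scans the segment (extracted from the ``<<< >>>`` block of the
    user prompt) for phrases in its keyword table and emits the targeted
    subcategories plus their parent domains in the answer dialect.  A small
    table of context words modulates the decision per prompting style
    (read from the ``Style:`` line of the system prompt):

    - ``strict``  drops a phrase hit when any blocking context word
      (negation, historical, experiencer, hypothetical, or uncertainty)
      appears earlier in the same sentence;
    - ``balanced`` drops all but uncertainty blockers;
    - ``liberal`` drops only negation blockers.

    Pure function of its inputs — no state, no randomness.
    """

    is_deterministic = True

    _BLOCKERS = {
        "negation": ("denies", "denied", "does not", "negative for", "without"),
        "historical": ("history of", "previously", "formerly"),
        "experiencer": ("mother", "father", "husband", "wife", "daughter", "son",
                        "brother", "sister"),
        "hypothetical": ("applying for", "considering", "plans to",
                         "recommended", "discussed"),
        "uncertainty": ("possible", "possibly", "unclear if", "may have",
                        "questionable"),
    }
    _DROP_BY_STYLE = {
        "strict": ("negation", "historical", "experiencer", "hypothetical",
                   "uncertainty"),
        "balanced": ("negation", "historical", "experiencer", "hypothetical"),
        "liberal": ("negation",),
    }

    def __init__(self, keyword_map: Mapping[str, str], tax: Taxonomy):
        for sub in keyword_map.values():
            if sub not in tax.subcategories:
                raise ValueError(f"keyword targets unknown subcategory {sub!r}")
        self.keyword_map = dict(keyword_map)
        self.tax = tax

    @classmethod
    def from_lexicon(cls, lex, tax: Taxonomy) -> "MockBackend":
        """Build the keyword table from the literal entries of a lexicon."""
        table = {
            e.pattern.lower(): e.target_subcategory
            for e in lex
            if e.match_kind == "literal"
        }
        return cls(table, tax)

    def complete(self, system_prompt: str, user_prompt: str) -> str:
        style_m = re.search(r"^Style:\s*(\w+)", system_prompt, re.MULTILINE)
        style = style_m.group(1) if style_m else "balanced"
        drop_classes = self._DROP_BY_STYLE.get(style, self._DROP_BY_STYLE["balanced"])

        seg_m = re.search(r"<<<\n(.*?)\n>>>", user_prompt, re.DOTALL)
        text = seg_m.group(1) if seg_m else user_prompt

        subs: set[str] = set()
        for sentence in re.split(r"(?<=[.!?])\s+|\n+", text):
            low = sentence.lower()
            for phrase, sub in self.keyword_map.items():
                idx = low.find(phrase)
                if idx < 0:
                    continue
                prefix = low[:idx]
                blocked = any(
                    blocker in prefix
                    for cls_ in drop_classes
                    for blocker in self._BLOCKERS[cls_]
                )
                if not blocked:
                    subs.add(sub)
        doms = {self.tax.parent_map[s] for s in subs}
        return format_answer(LabelSet.of(doms, subs), self.tax)


class CommandBackend:
    """Adapter that pipes prompts to an external command on stdin.

    Input: JSON ``{"system": ..., "user": ...}``; output: the raw response
    text on stdout.  Non-zero exit raises :class:`BackendError`.
    """

    is_deterministic = False

    def __init__(self, argv: Sequence[str], timeout: float = 120.0):
        self.argv = list(argv)
        self.timeout = timeout

    def complete(self, system_prompt: str, user_prompt: str) -> str:
        payload = json.dumps({"system": system_prompt, "user": user_prompt})
        try:
            proc = subprocess.run(
                self.argv, input=payload, capture_output=True, text=True,
                timeout=self.timeout,
            )
        except (OSError, subprocess.TimeoutExpired) as exc:
            raise BackendError(str(exc)) from exc
        if proc.returncode != 0:
            raise BackendError(f"command exited {proc.returncode}: {proc.stderr[:500]}")
        return proc.stdout


class HTTPBackend:
    """Generic chat-completion HTTP adapter (OpenAI-compatible shape).

    Decoding parameters (temperature etc.) are passed through ``params``
    and recorded in the run log; they default to deterministic decoding.
    """

    is_deterministic = False

    def __init__(self, url: str, model: str, api_key: str = "",
                 params: Mapping | None = None, timeout: float = 120.0):
        self.url = url
        self.model = model
        self.api_key = api_key
        self.params = dict(params or {"temperature": 0})
        self.timeout = timeout

    def complete(self, system_prompt: str, user_prompt: str) -> str:
        body = json.dumps({
            "model": self.model,
            "messages": [
                {"role": "system", "content": system_prompt},
                {"role": "user", "content": user_prompt},
            ],
            **self.params,
        }).encode()
        req = urllib.request.Request(
            self.url, data=body, headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
        )
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                data = json.loads(resp.read().decode())
        except Exception as exc:  # urllib raises a zoo of types
            raise BackendError(str(exc)) from exc
        try:
            return data["choices"][0]["message"]["content"]
        except (KeyError, IndexError) as exc:
            raise BackendError(f"unexpected response shape: {data!r:.500}") from exc


# --- classification ----------------------------------------------------------

def classify_segment_llm(
    seg: Segment,
    spec: PromptSpec,
    backend: BackendContract,
    tax: Taxonomy,
    examples: Sequence[FewShotExample] | None = None,
    max_retries: int = 3,
    backoff: float = 0.5,
    strict_parse: bool = False,
) -> LabelSet:
    """Classify one segment: build prompts, call the backend (retrying
    transport failures with exponential backoff), parse the answer.

    Parse failures are *not* retried — they are content errors, surfaced as
    :class:`ResponseParseError` for the caller to mark the segment
    unclassified.
    """
    if spec.shots > 0 and examples is None:
        examples = load_example_bank(spec.example_set, tax)[: spec.shots]
    system = build_system_prompt(tax, spec)
    fs_block = build_few_shot_block(examples, spec, tax) if spec.shots else ""
    user = build_user_prompt(seg, fs_block)

    last_exc: Exception | None = None
    for attempt in range(1, max_retries + 1):
        try:
            raw = backend.complete(system, user)
            break
        except BackendError as exc:
            last_exc = exc
            logger.warning("backend failure on attempt %d/%d: %s",
                           attempt, max_retries, exc)
            if attempt < max_retries:
                time.sleep(backoff * 2 ** (attempt - 1))
    else:
        raise BackendError(
            f"backend failed after {max_retries} attempts: {last_exc}"
        ) from last_exc

    logger.debug(
        "segment=%s prompt_sha=%s raw=%r",
        seg.segment_id,
        hashlib.sha256((system + user).encode()).hexdigest()[:12],
        raw[:200],
    )
    labels = parse_response(raw, tax, strict=strict_parse)
    labels.validate(tax)
    return labels
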