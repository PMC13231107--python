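"""Lexicon data model, tab-delimited I/O, embedding-based semantic
expansion, and exclusion filtering.

A lexicon is the dictionary of query terms the rule-based system matches
against clinical text; each entry targets one SDoH subcategory.  Expansion
ranks candidate terms by cosine similarity to seed terms under a
caller-supplied embedding function — the embedding provider is a contract
(term -> fixed-length vector), not a bundled model.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .schema import ConfigError, Taxonomy

__all__ = [
    "Lexicon",
    "LexiconEntry",
    "apply_exclusions",
    "expand_by_embedding",
    "load_lexicon",
    "write_lexicon",
]

logger = logging.getLogger(__name__)

_PROVENANCES = ("seed", "expanded", "manual")
_MATCH_KINDS = ("literal", "regex")


@dataclass(frozen=True)
class LexiconEntry:
    """One query pattern targeting one subcategory."""

    pattern: str
    match_kind: str = "literal"  # {"literal", "regex"}
    case_sensitive: bool = False
    target_subcategory: str = ""
    provenance: str = "manual"  # {"seed", "expanded", "manual"}

    def __post_init__(self) -> None:
        if self.match_kind not in _MATCH_KINDS:
            raise ValueError(f"bad match_kind: {self.match_kind!r}")
        if self.provenance not in _PROVENANCES:
            raise ValueError(f"bad provenance: {self.provenance!r}")
        if self.match_kind == "regex":
            re.compile(self.pattern)  # raises re.error on bad pattern

    def compiled(self) -> re.Pattern:
        flags = 0 if self.case_sensitive else re.IGNORECASE
        if self.match_kind == "regex":
            return re.compile(self.pattern, flags)
        # literal patterns are word-boundary anchored
        return re.compile(r"(?<!\w)" + re.escape(self.pattern) + r"(?!\w)", flags)


@dataclass(frozen=True)
class Lexicon:
    entries: tuple[LexiconEntry, ...]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_lexicon(path: str | Path, tax: Taxonomy) -> Lexicon:
    """Read a tab-delimited lexicon file and validate it against ``tax``.

    Columns: pattern, match_kind, case_sensitive, target_subcategory,
    provenance.  Lines starting with '#' are comments.  Duplicate
    (pattern, target) pairs are dropped with a warning.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 5:
                raise ConfigError(f"{path}:{lineno}: expected 5 tab-separated columns")
            pattern, kind, cs, target, prov = (c.strip() for c in cols)
            if target not in tax.subcategories:
                raise ConfigError(f"{path}:{lineno}: unknown subcategory {target!r}")
            try:
                entry = LexiconEntry(
                    pattern=pattern,
                    match_kind=kind,
                    case_sensitive=cs.lower() in ("1", "true", "yes"),
                    target_subcategory=target,
                    provenance=prov,
                )
            except re.error as exc:
                raise ConfigError(f"{path}:{lineno}: bad regex {pattern!r}: {exc}") from exc
            key = (pattern, target)
            if key in seen:
                logger.warning("%s:%d: duplicate entry %r skipped", path, lineno, key)
                continue
            seen.add(key)
            entries.append(entry)
    return Lexicon(tuple(entries))


def write_lexicon(lex: Lexicon, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pattern\tmatch_kind\tcase_sensitive\ttarget_subcategory\tprovenance\n")
        for e in lex.entries:
            fh.write(
                f"{e.pattern}\t{e.match_kind}\t{str(e.case_sensitive).lower()}"
                f"\t{e.target_subcategory}\t{e.provenance}\n"
            )


def expand_by_embedding(
    seeds: Sequence[str],
    candidates: Sequence[str],
    embed: Callable[[str], np.ndarray],
    k: int,
    min_sim: float = 0.0,
) -> dict[str, list[tuple[str, float]]]:
    """Semantic search: for each seed, the top-``k`` candidate terms by
    cosine similarity, restricted to similarity >= ``min_sim``.

    Ties are broken lexicographically on the candidate term so the result
    is invariant to candidate input order.  Candidates (or seeds) whose
    embedding has zero norm are skipped with a warning.

    Returns
    -------
    dict mapping each seed to a descending-similarity list of
    ``(candidate, similarity)`` pairs.
    """
    if k < 1:
        raise ValueError("k must be >= 1")

    def _unit(term: str) -> np.ndarray | None:
        v = np.asarray(embed(term), dtype=float)
        n = np.linalg.norm(v)
        if n == 0.0 or not np.isfinite(n):
            logger.warning("zero/invalid-norm embedding for %r; skipped", term)
            return None
        return v / n

    cand_vecs = [(c, _unit(c)) for c in sorted(set(candidates))]
    cand_vecs = [(c, v) for c, v in cand_vecs if v is not None]

    out: dict[str, list[tuple[str, float]]] = {}
    for seed in seeds:
        sv = _unit(seed)
        if sv is None:
            out[seed] = []
            continue
        scored = [(c, float(sv @ v)) for c, v in cand_vecs]
        scored = [(c, s) for c, s in scored if s >= min_sim]
        # descending similarity, lexicographic tie-break (cand_vecs pre-sorted)
        scored.sort(key=lambda cs: -cs[1])
        out[seed] = scored[:k]
    return out


def apply_exclusions(lex: Lexicon, exclusion_terms: Iterable[str]) -> Lexicon:
    """Drop entries whose pattern matches any exclusion regex (full or
    partial match, case-insensitive).  Idempotent; removal count is logged."""
    excl = [re.compile(t, re.IGNORECASE) for t in exclusion_terms]
    if not excl:
        return lex
    kept = tuple(
        e for e in lex.entries if not any(rx.search(e.pattern) for rx in excl)
    )
    removed = len(lex.entries) - len(kept)
    if removed:
        logger.info("apply_exclusions removed %d entries", removed)
    return Lexicon(kept)
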