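"""Late-fusion ensembling of label sets.

Two stages, applied per segment:

1. *Committee aggregation* combines the label sets of several prompt
   variants of the same LLM classifier (e.g. strict / balanced / liberal
   styles) by majority vote, union, or intersection; ``strict_only``
   bypasses aggregation and keeps the single strict-prompt output.
2. *Rule-LLM fusion* combines the aggregated committee output with the
   rule-based system's output by union or intersection — at the domain
   level only.  Subcategory labels always come from the committee alone.

Sentinels are not votable labels: they are stripped before any set
operation and re-inserted only when the result at a level is empty.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .schema import LabelSet, Taxonomy

__all__ = ["FusionConfig", "fuse_committee", "fuse_rbs_gpt", "run_ensemble"]

COMMITTEE_METHODS = ("majority", "union", "intersection", "strict_only")
RBS_FUSION_METHODS = ("union", "intersection", "none")


@dataclass(frozen=True)
class FusionConfig:
    """One ensemble configuration.

    ``committee_method='strict_only'`` uses a single committee member (the
    strict-prompt output) without aggregation.  ``rbs_fusion`` applies at
    the domain level only.
    """

    committee_method: str = "majority"
    rbs_fusion: str = "union"

    def __post_init__(self) -> None:
        if self.committee_method not in COMMITTEE_METHODS:
            raise ValueError(f"bad committee_method: {self.committee_method!r}")
        if self.rbs_fusion not in RBS_FUSION_METHODS:
            raise ValueError(f"bad rbs_fusion: {self.rbs_fusion!r}")


def _aggregate(member_labels: Sequence[frozenset[str]], method: str) -> frozenset[str]:
    if method == "union":
        return frozenset().union(*member_labels)
    if method == "intersection":
        out = member_labels[0]
        for m in member_labels[1:]:
            out &= m
        return out
    # majority: strictly more than half ("most"); even committees break
    # ties toward exclusion
    votes = Counter(lbl for m in member_labels for lbl in set(m))
    need = len(member_labels) / 2
    return frozenset(lbl for lbl, n in votes.items() if n > need)


def fuse_committee(
    members: Sequence[frozenset[str] | set[str]],
    method: str,
    sentinel: str,
) -> frozenset[str]:
    """Aggregate one level's label sets across committee members.

    ``majority`` keeps labels assigned by strictly more than half the
    members, ``union`` by any member, ``intersection`` by all members.
    The sentinel is excluded from voting and re-inserted only when the
    aggregate is empty.
    """
    if not members:
        raise ValueError("empty committee")
    if method == "strict_only" and len(members) != 1:
        raise ValueError("strict_only requires exactly one committee member")
    if method == "majority" and len(members) < 2:
        raise ValueError("majority voting requires >= 2 members")
    stripped = [frozenset(m) - {sentinel} for m in members]
    if method == "strict_only":
        out = stripped[0]
    else:
        out = _aggregate(stripped, method)
    return out if out else frozenset({sentinel})


def fuse_rbs_gpt(
    rbs: frozenset[str] | set[str],
    committee: frozenset[str] | set[str],
    method: str,
    sentinel: str,
) -> frozenset[str]:
    """Fuse rule-based and committee outputs at the domain level by set
    union or intersection, with sentinel stripping/re-insertion."""
    if method not in ("union", "intersection"):
        raise ValueError(f"bad fusion method: {method!r}")
    a = frozenset(rbs) - {sentinel}
    b = frozenset(committee) - {sentinel}
    out = a | b if method == "union" else a & b
    return out if out else frozenset({sentinel})


def run_ensemble(
    committee: Sequence[LabelSet],
    cfg: FusionConfig,
    tax: Taxonomy,
    rbs: LabelSet | None = None,
) -> LabelSet:
    """Full per-segment ensemble with level-specific routing.

    Domain labels: committee aggregation, then (optionally) fusion with the
    rule-based domain output.  Subcategory labels: committee aggregation
    only — the rule-based system never influences subcategories.
    """
    if not committee:
        raise ValueError("no committee predictions provided")
    if cfg.rbs_fusion != "none" and rbs is None:
        raise ValueError("rbs_fusion requested but no RBS prediction provided")

    members = committee[:1] if cfg.committee_method == "strict_only" else committee
    doms = fuse_committee(
        [m.domains for m in members], cfg.committee_method, tax.domain_sentinel
    )
    subs = fuse_committee(
        [m.subcategories for m in members],
        cfg.committee_method,
        tax.subcategory_sentinel,
    )
    if cfg.rbs_fusion != "none":
        doms = fuse_rbs_gpt(rbs.domains, doms, cfg.rbs_fusion, tax.domain_sentinel)
    return LabelSet(doms, subs)
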