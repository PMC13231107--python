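"""Core data model: the two-level SDoH taxonomy, contextual attributes,
text segments, and multilabel annotation records.

The taxonomy is a tree of 7 domain categories over 23 subcategories (in the
shipped default config), plus two *sentinel* labels — ``none of the above``
at the domain level and ``N/A`` at the subcategory level — used when a
segment carries no positive finding at that level.  A mention counts as an
SDoH-positive case only when it is current, patient-specific,
non-hypothetical, not negated, and not uncertain; every other contextual
reading is an exclusion.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ConfigError",
    "ContextAttributes",
    "GoldAnnotation",
    "LabelSet",
    "Segment",
    "Taxonomy",
    "default_taxonomy_path",
    "derive_domains",
    "is_positive_case",
    "load_taxonomy",
    "parent_domain",
]

DOMAIN_SENTINEL = "none of the above"
SUBCATEGORY_SENTINEL = "N/A"


class ConfigError(ValueError):
    """Raised when a taxonomy or lexicon configuration file is invalid."""


@dataclass(frozen=True)
class Taxonomy:
    """Two-level SDoH label space.

    Attributes
    ----------
    domains : tuple of str
        Ordered domain-category names.
    subcategories : tuple of str
        Ordered subcategory names.
    parent_map : mapping of str to str
        Subcategory name -> its unique parent domain.
    domain_sentinel, subcategory_sentinel : str
        The "no finding" labels at each level; never members of
        ``domains`` / ``subcategories``.
    """

    domains: tuple[str, ...]
    subcategories: tuple[str, ...]
    parent_map: Mapping[str, str]
    domain_sentinel: str = DOMAIN_SENTINEL
    subcategory_sentinel: str = SUBCATEGORY_SENTINEL

    def __post_init__(self) -> None:
        if len(set(self.domains)) != len(self.domains):
            raise ConfigError("duplicate domain names")
        if len(set(self.subcategories)) != len(self.subcategories):
            raise ConfigError("duplicate subcategory names")
        for sub, dom in self.parent_map.items():
            if dom not in self.domains:
                raise ConfigError(f"subcategory {sub!r} has unknown parent {dom!r}")
        missing = set(self.subcategories) - set(self.parent_map)
        if missing:
            raise ConfigError(f"subcategories without a parent: {sorted(missing)}")
        if self.domain_sentinel in self.domains:
            raise ConfigError("domain sentinel collides with a domain name")
        if self.subcategory_sentinel in self.subcategories:
            raise ConfigError("subcategory sentinel collides with a subcategory name")

    def children(self, domain: str) -> tuple[str, ...]:
        """Subcategories under ``domain``, in taxonomy order."""
        if domain not in self.domains:
            raise KeyError(f"unknown domain: {domain!r}")
        return tuple(s for s in self.subcategories if self.parent_map[s] == domain)


@dataclass(frozen=True)
class ContextAttributes:
    """Per-mention contextual flags driving the positivity predicate.

    Defaults encode the assertion reading of an unmodified mention:
    current, about the patient, factual, certain, affirmed.
    """

    temporality: str = "current"  # {"current", "historical"}
    experiencer: str = "patient"  # {"patient", "other"}
    hypothetical: bool = False
    uncertain: bool = False
    negated: bool = False

    def __post_init__(self) -> None:
        if self.temporality not in ("current", "historical"):
            raise ValueError(f"bad temporality: {self.temporality!r}")
        if self.experiencer not in ("patient", "other"):
            raise ValueError(f"bad experiencer: {self.experiencer!r}")


@dataclass(frozen=True)
class Segment:
    """A unit of note text with provenance and 0-based half-open offsets."""

    segment_id: str
    patient_id: str
    note_id: str
    text: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"segment {self.segment_id}: start must be < end")

    def to_record(self) -> dict:
        return {
            "segment_id": self.segment_id,
            "patient_id": self.patient_id,
            "note_id": self.note_id,
            "text": self.text,
            "start": self.start,
            "end": self.end,
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "Segment":
        return cls(
            segment_id=rec["segment_id"],
            patient_id=rec["patient_id"],
            note_id=rec["note_id"],
            text=rec["text"],
            start=int(rec["start"]),
            end=int(rec["end"]),
        )


@dataclass(frozen=True)
class LabelSet:
    """Multilabel assignment for one segment at both taxonomy levels.

    A sentinel never co-occurs with a positive label at the same level;
    an empty level is represented by its sentinel alone.
    """

    domains: frozenset[str]
    subcategories: frozenset[str]

    @classmethod
    def of(cls, domains: Iterable[str] = (), subcategories: Iterable[str] = ()) -> "LabelSet":
        return cls(frozenset(domains), frozenset(subcategories))

    @classmethod
    def sentinel(cls, tax: Taxonomy) -> "LabelSet":
        return cls(frozenset({tax.domain_sentinel}), frozenset({tax.subcategory_sentinel}))

    def validate(self, tax: Taxonomy) -> None:
        for d in self.domains:
            if d != tax.domain_sentinel and d not in tax.domains:
                raise ValueError(f"label outside taxonomy: {d!r}")
        for s in self.subcategories:
            if s != tax.subcategory_sentinel and s not in tax.subcategories:
                raise ValueError(f"label outside taxonomy: {s!r}")
        if tax.domain_sentinel in self.domains and len(self.domains) > 1:
            raise ValueError("domain sentinel co-occurring with positive labels")
        if tax.subcategory_sentinel in self.subcategories and len(self.subcategories) > 1:
            raise ValueError("subcategory sentinel co-occurring with positive labels")

    def positive_domains(self, tax: Taxonomy) -> frozenset[str]:
        return self.domains - {tax.domain_sentinel}

    def positive_subcategories(self, tax: Taxonomy) -> frozenset[str]:
        return self.subcategories - {tax.subcategory_sentinel}

    def to_record(self) -> dict:
        return {
            "domains": sorted(self.domains),
            "subcategories": sorted(self.subcategories),
        }

    @classmethod
    def from_record(cls, rec: Mapping) -> "LabelSet":
        return cls.of(rec.get("domains", ()), rec.get("subcategories", ()))


@dataclass(frozen=True)
class GoldAnnotation:
    """Gold-standard labels for one segment, with optional per-mention context."""

    segment_id: str
    label_set: LabelSet
    attrs: tuple[ContextAttributes, ...] = field(default_factory=tuple)

    def to_record(self) -> dict:
        rec = {"segment_id": self.segment_id, **self.label_set.to_record()}
        if self.attrs:
            rec["attrs"] = [
                {
                    "temporality": a.temporality,
                    "experiencer": a.experiencer,
                    "hypothetical": a.hypothetical,
                    "uncertain": a.uncertain,
                    "negated": a.negated,
                }
                for a in self.attrs
            ]
        return rec

    @classmethod
    def from_record(cls, rec: Mapping) -> "GoldAnnotation":
        attrs = tuple(ContextAttributes(**a) for a in rec.get("attrs", ()))
        return cls(rec["segment_id"], LabelSet.from_record(rec), attrs)


def default_taxonomy_path() -> Path:
    """Path to the YAML taxonomy config shipped with the package."""
    return Path(str(resources.files("sdohkit").joinpath("data/taxonomy.yaml")))


def load_taxonomy(config_path: str | Path | None = None) -> Taxonomy:
    """Load a taxonomy from a YAML config file.

    The file maps each domain to a list of subcategory entries (``name`` plus
    an optional ``placeholder`` marker) and names the two sentinel labels.
    The shipped default yields 7 domains and 23 subcategories; user configs
    may define any counts.
    """
    path = Path(config_path) if config_path is not None else default_taxonomy_path()
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "domains" not in raw:
        raise ConfigError(f"{path}: taxonomy config must contain a 'domains' mapping")
    sentinels = raw.get("sentinels", {})
    domains: list[str] = []
    subcategories: list[str] = []
    parent_map: dict[str, str] = {}
    for dom, subs in raw["domains"].items():
        if dom in domains:
            raise ConfigError(f"{path}: duplicate domain {dom!r}")
        domains.append(dom)
        for entry in subs or ():
            name = entry["name"] if isinstance(entry, dict) else str(entry)
            if name in parent_map:
                raise ConfigError(f"{path}: duplicate subcategory {name!r}")
            subcategories.append(name)
            parent_map[name] = dom
    return Taxonomy(
        domains=tuple(domains),
        subcategories=tuple(subcategories),
        parent_map=parent_map,
        domain_sentinel=sentinels.get("domain", DOMAIN_SENTINEL),
        subcategory_sentinel=sentinels.get("subcategory", SUBCATEGORY_SENTINEL),
    )


def parent_domain(sub: str, tax: Taxonomy) -> str:
    """Return the unique parent domain of subcategory ``sub``."""
    try:
        return tax.parent_map[sub]
    except KeyError:
        raise KeyError(f"unknown subcategory: {sub!r}") from None


def is_positive_case(attrs: ContextAttributes) -> bool:
    """Whether a mention with these contextual attributes is SDoH-positive.

    A positive case must be current, patient-specific, non-hypothetical,
    certain, and affirmed; any single exclusion flag defeats it.
    """
    return (
        attrs.temporality == "current"
        and attrs.experiencer == "patient"
        and not attrs.hypothetical
        and not attrs.uncertain
        and not attrs.negated
    )


def derive_domains(subcategories: Iterable[str], tax: Taxonomy) -> frozenset[str]:
    """Opt-in helper: parent domains implied by a set of subcategories.

    Domain and subcategory levels are annotated (and scored) as independent
    tasks; this helper is for pipelines that want hierarchical propagation.
    Sentinels are ignored.
    """
    return frozenset(
        tax.parent_map[s] for s in subcategories if s != tax.subcategory_sentinel
    )
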