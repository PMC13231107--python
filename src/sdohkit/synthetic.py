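"""Seeded generator of synthetic clinical text segments with gold labels.

The generator stands in for a PHI-restricted corpus: it emits short,
telegraphic clinical-style segments (the kind produced by prescreening a
note with ~150 characters of context around a trigger mention), grouped by
synthetic patient for cluster-bootstrap evaluation.  Every template is
original text; none is drawn from real notes.

Each segment plants one SDoH mention in one of eight *variants* —
positive, negated, historical, other-experiencer (family member),
hypothetical, uncertain, questionnaire (answered or unanswered), or a
trigger-free distractor.  Gold labels follow the positivity predicate:
only the positive and answered-questionnaire variants yield positive
labels; every other variant is sentinel-only.

Templates are co-designed with the shipped demonstration lexicon and cue
rules: each records which lexicon trigger and cue rule it exercises, and
the generator also emits the label set the fixture rule-based system is
*expected* to produce per segment (``expected_rbs``).  For the unanswered
questionnaire variant that expectation deliberately differs from gold —
the trigger is present but the answer is missing — planting a known
false-positive, the classic questionnaire failure mode of keyword systems.

Patients carry a preferred subcategory; segments reuse it with probability
``patient_propensity``, inducing intra-patient correlation so that the
patient-level cluster bootstrap is meaningfully wider than an i.i.d.
segment bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .schema import (
    ContextAttributes,
    GoldAnnotation,
    LabelSet,
    Segment,
    Taxonomy,
    is_positive_case,
)

__all__ = [
    "GeneratorConfig",
    "SyntheticCorpus",
    "VARIANTS",
    "default_triggers",
    "generate_corpus",
    "generate_questionnaire_segment",
]

VARIANTS = (
    "positive",
    "negated",
    "historical",
    "other_experiencer",
    "hypothetical",
    "uncertain",
    "questionnaire",
    "distractor",
)

# Default variant proportions: positives dominate (the corpus this emulates
# was keyword-enriched), with every contextual failure mode represented.
_DEFAULT_MIX = {
    "positive": 0.45,
    "negated": 0.12,
    "historical": 0.08,
    "other_experiencer": 0.08,
    "hypothetical": 0.07,
    "uncertain": 0.05,
    "questionnaire": 0.10,
    "distractor": 0.05,
}

# One lexicon trigger per subcategory of the default taxonomy; each phrase
# is a literal entry of the shipped demonstration lexicon.
_TRIGGERS = {
    "financial hardship": "financial hardship",
    "financial stability": "financially stable",
    "financial strain from medical costs": "medical bills",
    "employed": "currently employed",
    "unemployment": "unemployed",
    "job loss": "job loss",
    "retirement": "retired",
    "other job insecurity and employment issues": "job insecurity",
    "stable housing": "stable housing",
    "housing instability": "housing instability",
    "homelessness": "homelessness",
    "subsidized/public housing": "public housing",
    "adequate insurance coverage": "adequate insurance",
    "lack of insurance": "uninsured",
    "government-assisted insurance": "medicaid",
    "food security": "enough food",
    "food insecurity": "food running out",
    "living with or accompanied by someone": "lives with",
    "living alone": "lives alone",
    "good social resources": "strong support system",
    "poor social resources": "socially isolated",
    "physically active": "exercises regularly",
    "physically inactive": "sedentary",
}

# Variant -> (template, planted attributes, cue rule exercised).
_VARIANT_TEMPLATES = {
    "positive": (
        "Pt note: {t} at this time.",
        ContextAttributes(),
        None,
    ),
    "negated": (
        "Patient denies {t}.",
        ContextAttributes(negated=True),
        "denies",
    ),
    "historical": (
        "History of {t} several years back.",
        ContextAttributes(temporality="historical"),
        "history of",
    ),
    "other_experiencer": (
        "Her mother has {t} currently.",
        ContextAttributes(experiencer="other"),
        "mother",
    ),
    "hypothetical": (
        "Social worker discussed applying for {t}.",
        ContextAttributes(hypothetical=True),
        "applying for",
    ),
    "uncertain": (
        "Possible {t}, unclear details.",
        ContextAttributes(uncertain=True),
        "possible",
    ),
}

_DISTRACTORS = (
    "Routine follow-up visit; vital signs stable.",
    "Medication list reviewed and reconciled today.",
    "Wound healing well, no drainage noted.",
    "Plan: repeat labs in two weeks.",
)


def default_triggers(tax: Taxonomy) -> dict[str, str]:
    """Trigger phrase per subcategory, validated against the taxonomy."""
    missing = set(tax.subcategories) - set(_TRIGGERS)
    if missing:
        raise ValueError(f"no trigger template for subcategories: {sorted(missing)}")
    return {s: _TRIGGERS[s] for s in tax.subcategories}


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition knobs for the synthetic corpus.

    ``variant_mix`` proportions must sum to 1; ``subcategory_weights``
    defaults to uniform prevalence over the taxonomy.  ``patient_propensity``
    is the probability that a segment reuses its patient's preferred
    subcategory (intra-patient correlation).
    """

    n_patients: int = 50
    segments_per_patient: tuple[int, int] = (2, 6)
    variant_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MIX)
    )
    subcategory_weights: Mapping[str, float] | None = None
    patient_propensity: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.segments_per_patient
        if not 1 <= lo <= hi:
            raise ValueError("bad segments_per_patient range")
        unknown = set(self.variant_mix) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")
        total = sum(self.variant_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"variant mix sums to {total}, not 1")
        if any(v < 0 for v in self.variant_mix.values()):
            raise ValueError("negative variant proportion")


@dataclass
class SyntheticCorpus:
    """Generated segments with gold labels and planted RBS expectations."""

    segments: list[Segment]
    gold: list[GoldAnnotation]
    patient_of: dict[str, str]
    expected_rbs: dict[str, LabelSet]
    variant_of: dict[str, str]


def generate_questionnaire_segment(
    sub: str,
    answered: bool,
    tax: Taxonomy,
    malformed: bool = False,
) -> tuple[str, LabelSet]:
    """A question-answer formatted segment for one subcategory.

    An affirmative answer makes the finding current and patient-specific
    (positive gold); a missing answer means nothing can be assigned
    (sentinel gold), regardless of the question text.  The ``malformed``
    flag perturbs whitespace the way pasted questionnaires often do; gold
    is independent of formatting.
    """
    trigger = default_triggers(tax)[sub]
    answer = "yes" if answered else "___"
    if malformed:
        text = f"Screening:   any problems with {trigger}  in the last month ?\n\n Answer :  {answer}"
    else:
        text = f"Screening: any problems with {trigger} in the last month?\nAnswer: {answer}"
    if answered:
        gold = LabelSet.of({tax.parent_map[sub]}, {sub})
    else:
        gold = LabelSet.sentinel(tax)
    return text, gold


def generate_corpus(cfg: GeneratorConfig, tax: Taxonomy) -> SyntheticCorpus:
    """Generate a patient-grouped synthetic corpus; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    triggers = default_triggers(tax)
    subs = list(tax.subcategories)
    if cfg.subcategory_weights is None:
        weights = np.full(len(subs), 1.0 / len(subs))
    else:
        weights = np.array([cfg.subcategory_weights.get(s, 0.0) for s in subs])
        weights = weights / weights.sum()
    variant_names = [v for v in VARIANTS if cfg.variant_mix.get(v, 0.0) > 0]
    variant_p = np.array([cfg.variant_mix[v] for v in variant_names])
    variant_p = variant_p / variant_p.sum()

    segments: list[Segment] = []
    gold: list[GoldAnnotation] = []
    patient_of: dict[str, str] = {}
    expected_rbs: dict[str, LabelSet] = {}
    variant_of: dict[str, str] = {}

    for pi in range(cfg.n_patients):
        pid = f"patient-{pi:04d}"
        preferred = subs[rng.choice(len(subs), p=weights)]
        n_seg = int(rng.integers(cfg.segments_per_patient[0],
                                 cfg.segments_per_patient[1] + 1))
        for si in range(n_seg):
            sid = f"{pid}:seg-{si:03d}"
            variant = variant_names[rng.choice(len(variant_names), p=variant_p)]
            if variant == "distractor":
                text = _DISTRACTORS[int(rng.integers(len(_DISTRACTORS)))]
                gold_ls = LabelSet.sentinel(tax)
                expected = LabelSet.sentinel(tax)
                attrs: tuple[ContextAttributes, ...] = ()
            else:
                if rng.random() < cfg.patient_propensity:
                    sub = preferred
                else:
                    sub = subs[rng.choice(len(subs), p=weights)]
                if variant == "questionnaire":
                    answered = bool(rng.random() < 0.5)
                    malformed = bool(rng.random() < 0.3)
                    text, gold_ls = generate_questionnaire_segment(
                        sub, answered, tax, malformed=malformed
                    )
                    # keyword systems see the trigger either way: the
                    # unanswered form plants a known false positive
                    expected = LabelSet.of({tax.parent_map[sub]}, {sub})
                    attrs = (ContextAttributes(),) if answered else ()
                else:
                    template, planted, _cue = _VARIANT_TEMPLATES[variant]
                    text = template.format(t=triggers[sub])
                    attrs = (planted,)
                    if is_positive_case(planted):
                        gold_ls = LabelSet.of({tax.parent_map[sub]}, {sub})
                    else:
                        gold_ls = LabelSet.sentinel(tax)
                    expected = gold_ls
            seg = Segment(
                segment_id=sid,
                patient_id=pid,
                note_id=f"{pid}:note-{si:03d}",
                text=text,
                start=0,
                end=len(text),
            )
            segments.append(seg)
            gold.append(GoldAnnotation(sid, gold_ls, attrs))
            patient_of[sid] = pid
            expected_rbs[sid] = expected
            variant_of[sid] = variant

    return SyntheticCorpus(segments, gold, patient_of, expected_rbs, variant_of)
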