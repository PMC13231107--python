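"""Multilabel scoring, patient-level cluster bootstrap, and inter-annotator
agreement.

Scoring treats each taxonomy level (domain, subcategory) as an independent
multilabel task.  Per positive label L: TP counts segments carrying L in
both gold and prediction, FP in prediction only, FN in gold only.  Sentinel
labels carry no counts — a gold 'N/A' contributes no TP or FN for any
positive label, so per label TP+FN always equals the gold positive count.

Micro metrics pool counts across labels before computing
P = ΣTP/(ΣTP+ΣFP), R = ΣTP/(ΣTP+ΣFN), F1 = 2PR/(P+R); macro metrics
average per-label P/R/F1 over labels observed in gold or prediction.
Zero denominators yield 0 by convention.

Confidence intervals use a percentile cluster bootstrap: patients are
resampled with replacement (each draw carrying all the patient's
segments), the metric is recomputed per replicate, and the 2.5th/97.5th
percentiles are reported.  Resampling whole patients respects
within-patient correlation that an i.i.d. segment bootstrap would ignore.

Krippendorff's alpha for multilabel annotations is computed by binarizing
each (unit, label) pair into one nominal presence/absence decision per
coder and pooling all decisions into a single coincidence matrix;
alpha = 1 − observed/expected disagreement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import GoldAnnotation, LabelSet, Taxonomy

__all__ = [
    "LabelCounts",
    "MetricsReport",
    "cluster_bootstrap_ci",
    "count_errors",
    "evaluate_predictions",
    "krippendorff_alpha",
    "macro_prf",
    "micro_f1_metric",
    "micro_prf",
    "report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelCounts:
    """Per-label TP/FP/FN at one taxonomy level."""

    level: str  # {"domain", "subcategory"}
    counts: Mapping[str, tuple[int, int, int]]  # label -> (tp, fp, fn)

    def totals(self) -> tuple[int, int, int]:
        tp = sum(c[0] for c in self.counts.values())
        fp = sum(c[1] for c in self.counts.values())
        fn = sum(c[2] for c in self.counts.values())
        return tp, fp, fn


@dataclass
class MetricsReport:
    """Micro/macro precision-recall-F1 plus per-label detail and optional CIs."""

    level: str
    micro: tuple[float, float, float]
    macro: tuple[float, float, float]
    per_label: dict[str, tuple[float, float, float, int, int, int]]
    ci: dict[str, tuple[float, float, int, int]] = field(default_factory=dict)
    # ci maps metric name -> (lower, upper, n_boot, seed)


def _level_labels(ls: LabelSet, tax: Taxonomy, level: str) -> frozenset[str]:
    if level == "domain":
        return ls.positive_domains(tax)
    if level == "subcategory":
        return ls.positive_subcategories(tax)
    raise ValueError(f"bad level: {level!r}")


def _counts_from_pairs(
    pairs: Iterable[tuple[LabelSet, LabelSet]], tax: Taxonomy, level: str
) -> LabelCounts:
    counts: dict[str, list[int]] = {}
    for gold_ls, pred_ls in pairs:
        g = _level_labels(gold_ls, tax, level)
        p = _level_labels(pred_ls, tax, level)
        for lbl in g | p:
            c = counts.setdefault(lbl, [0, 0, 0])
            if lbl in g and lbl in p:
                c[0] += 1
            elif lbl in p:
                c[1] += 1
            else:
                c[2] += 1
    return LabelCounts(level, {k: tuple(v) for k, v in counts.items()})


def count_errors(
    gold: Sequence[GoldAnnotation],
    pred: Sequence[tuple[str, LabelSet]],
    tax: Taxonomy,
    level: str,
) -> LabelCounts:
    """Per-label TP/FP/FN over a gold/prediction pairing by segment id.

    Every prediction must reference a gold segment (unknown ids raise);
    gold segments without a prediction are scored as if the system
    predicted the sentinel, so their positive labels become FNs.
    """
    gold_by_id = {g.segment_id: g for g in gold}
    if len(gold_by_id) != len(gold):
        raise ValueError("duplicate segment_id in gold annotations")
    pred_by_id: dict[str, LabelSet] = {}
    for sid, ls in pred:
        if sid not in gold_by_id:
            raise ValueError(f"prediction references unknown segment {sid!r}")
        if sid in pred_by_id:
            raise ValueError(f"duplicate prediction for segment {sid!r}")
        pred_by_id[sid] = ls
    pairs = [
        (g.label_set, pred_by_id.get(sid, LabelSet.sentinel(tax)))
        for sid, g in gold_by_id.items()
    ]
    return _counts_from_pairs(pairs, tax, level)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def micro_prf(counts: LabelCounts) -> tuple[float, float, float]:
    """Micro-averaged precision, recall, F1 (counts pooled across labels)."""
    return _prf(*counts.totals())


def macro_prf(counts: LabelCounts) -> tuple[float, float, float]:
    """Macro-averaged precision, recall, F1: the unweighted mean of
    per-label metrics over labels with any gold or predicted occurrence."""
    eligible = [c for c in counts.counts.values() if c[0] + c[1] + c[2] > 0]
    if not eligible:
        raise ValueError("no eligible labels for macro averaging")
    per = np.array([_prf(*c) for c in eligible])
    return tuple(per.mean(axis=0))


def micro_f1_metric(tax: Taxonomy, level: str) -> Callable:
    """A metric function (gold list, prediction list -> micro F1) suitable
    for :func:`cluster_bootstrap_ci`; predictions align positionally."""

    def fn(gold: Sequence[GoldAnnotation], pred: Sequence[LabelSet]) -> float:
        pairs = [(g.label_set, p) for g, p in zip(gold, pred, strict=True)]
        return micro_prf(_counts_from_pairs(pairs, tax, level))[2]

    return fn


def cluster_bootstrap_ci(
    metric_fn: Callable[[Sequence[GoldAnnotation], Sequence[LabelSet]], float],
    gold: Sequence[GoldAnnotation],
    pred: Sequence[tuple[str, LabelSet]],
    patient_of: Mapping[str, str],
    n_boot: int = 2000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile CI from ``n_boot`` patient-level cluster bootstrap
    resamples of the metric.

    Patients are drawn with replacement; each draw carries all the
    patient's segments.  ``metric_fn`` receives positionally aligned gold
    and prediction lists (see :func:`micro_f1_metric`).  A fixed seed makes
    the interval reproducible.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    pred_by_id = dict(pred)
    by_patient: dict[str, list[tuple[GoldAnnotation, LabelSet]]] = {}
    for g in gold:
        pid = patient_of[g.segment_id]
        pl = pred_by_id.get(g.segment_id)
        if pl is None:
            raise ValueError(f"no prediction for segment {g.segment_id!r}")
        by_patient.setdefault(pid, []).append((g, pl))
    patients = sorted(by_patient)
    if len(patients) == 1:
        logger.warning("single patient: bootstrap CI degenerates to the point")
    rng = np.random.default_rng(seed)
    stats = np.empty(n_boot)
    clusters = [by_patient[p] for p in patients]
    for b in range(n_boot):
        draw = rng.integers(0, len(clusters), size=len(clusters))
        g_rep: list[GoldAnnotation] = []
        p_rep: list[LabelSet] = []
        for i in draw:
            for ga, pl in clusters[i]:
                g_rep.append(ga)
                p_rep.append(pl)
        stats[b] = metric_fn(g_rep, p_rep)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def krippendorff_alpha(
    units: Sequence[tuple[str, str, Iterable[str]]],
    label_space: Sequence[str],
    distance: str = "nominal",
) -> float:
    """Krippendorff's alpha for multilabel annotations, nominal distance.

    ``units`` holds ``(unit_id, coder_id, label set)`` triples.  Each
    (unit, label) pair is binarized into one presence/absence decision per
    coder; all decisions are pooled into a single coincidence matrix and
    alpha = 1 − D_o/D_e.  Perfect agreement gives 1; systematic
    disagreement can go below 0.
    """
    if distance != "nominal":
        raise ValueError("only nominal distance is implemented")
    coders = {c for _, c, _ in units}
    if len(coders) < 2:
        raise ValueError("need >= 2 coders")
    by_unit: dict[str, dict[str, frozenset[str]]] = {}
    for uid, coder, labels in units:
        by_unit.setdefault(uid, {})[coder] = frozenset(labels)
    if not any(len(c) >= 2 for c in by_unit.values()):
        raise ValueError("no unit coded by >= 2 coders")

    # pooled coincidence matrix over values {0, 1}
    o = np.zeros((2, 2))
    for coder_sets in by_unit.values():
        m = len(coder_sets)
        if m < 2:
            continue
        decisions = list(coder_sets.values())
        for lbl in label_space:
            vals = [int(lbl in d) for d in decisions]
            for i, vi in enumerate(vals):
                for j, vj in enumerate(vals):
                    if i != j:
                        o[vi, vj] += 1.0 / (m - 1)
    n_v = o.sum(axis=1)
    n = n_v.sum()
    d_o = o[0, 1] + o[1, 0]
    d_e = 2 * n_v[0] * n_v[1] / (n - 1) if n > 1 else 0.0
    if d_e == 0.0:
        return 1.0  # no variation at all: vacuous perfect agreement
    return float(1.0 - d_o / d_e)


def evaluate_predictions(
    gold: Sequence[GoldAnnotation],
    pred: Sequence[tuple[str, LabelSet]],
    tax: Taxonomy,
    level: str,
    patient_of: Mapping[str, str] | None = None,
    n_boot: int = 2000,
    seed: int = 0,
) -> MetricsReport:
    """Convenience wrapper: counts, micro/macro PRF, optional bootstrap CI
    on micro F1 (when a patient map is given)."""
    counts = count_errors(gold, pred, tax, level)
    per_label = {
        lbl: (*_prf(*c), *c) for lbl, c in sorted(counts.counts.items())
    }
    rep = MetricsReport(
        level=level,
        micro=micro_prf(counts),
        macro=macro_prf(counts) if counts.counts else (0.0, 0.0, 0.0),
        per_label=per_label,
    )
    if patient_of is not None:
        lo, hi = cluster_bootstrap_ci(
            micro_f1_metric(tax, level), gold, pred, patient_of,
            n_boot=n_boot, seed=seed,
        )
        rep.ci["micro_f1"] = (lo, hi, n_boot, seed)
        if not lo <= rep.micro[2] <= hi:
            logger.warning(
                "percentile CI (%.3f, %.3f) excludes the point estimate %.3f",
                lo, hi, rep.micro[2],
            )
    return rep


def report(
    metrics: Mapping[str, MetricsReport],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Comparison table across systems/configurations.

    One row per system with pooled counts and micro/macro PRF at 2-decimal
    display precision, sorted by micro F1 descending; CIs included when
    present.  Written as CSV when ``path`` is given.
    """
    rows = []
    for name, rep in metrics.items():
        tp = sum(c[3] for c in rep.per_label.values())
        fp = sum(c[4] for c in rep.per_label.values())
        fn = sum(c[5] for c in rep.per_label.values())
        row = {
            "system": name,
            "level": rep.level,
            "tp": tp,
            "fp": fp,
            "fn": fn,
            "micro_precision": round(rep.micro[0], 2),
            "micro_recall": round(rep.micro[1], 2),
            "micro_f1": round(rep.micro[2], 2),
            "macro_precision": round(rep.macro[0], 2),
            "macro_recall": round(rep.macro[1], 2),
            "macro_f1": round(rep.macro[2], 2),
        }
        if "micro_f1" in rep.ci:
            lo, hi, nb, sd = rep.ci["micro_f1"]
            row.update(
                micro_f1_ci_lower=round(lo, 2),
                micro_f1_ci_upper=round(hi, 2),
                n_boot=nb,
                boot_seed=sd,
            )
        rows.append(row)
    df = pd.DataFrame(rows).sort_values(
        ["micro_f1", "system"], ascending=[False, True]
    ).reset_index(drop=True)
    if path is not None:
        df.to_csv(path, index=False)
    return df
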