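# sdohkit

Hybrid extraction of **social determinants of health (SDoH)** from clinical
text: a rule-based system (RBS) with ConText-style contextual
disambiguation, prompt-based LLM classification behind a pluggable backend,
late-fusion ensembles of the two, and a full multilabel evaluation stack —
exercisable end to end on synthetic clinical text with no protected data.

## Who this is for

Clinical NLP and health-informatics researchers who need to identify
social factors — housing, food security, employment, insurance, social
support, finances, physical activity — documented only in unstructured
notes, and who want a cost-efficient pipeline (rules + prompted models, no
fine-tuning) with honest, cluster-aware uncertainty estimates.

## The task and the models

Extraction is **hierarchical multilabel classification** over short text
segments: assign zero or more of 7 SDoH *domain categories* and 23
*subcategories* (sentinels "none of the above" / "N/A" mark the empty
case). A mention counts as SDoH-positive only when it is *current,
patient-specific, non-hypothetical, certain, and affirmed*; negated,
historical, family-member, hypothetical, and uncertain mentions are
exclusions, detected by a cue-scope model (trigger word + direction +
terminators + token cap).

Three classification routes:

- **RBS** — sentence segmentation → word-boundary lexicon matching →
  cue-based attribute resolution → positivity filter. Also used to
  *prescreen* whole notes, cutting candidate segments with 150 characters
  of context on either side of each match.
- **LLM** — a three-part system prompt (role, label definitions,
  step-by-step instructions) asks for domains first, then subcategories,
  in a fixed two-line answer dialect. Styles `strict` / `balanced` /
  `liberal` vary only the inclusion threshold; zero- or few-shot with
  `easy` / `hard` / `synthetic` example banks. A deterministic keyword
  `MockBackend` ships for offline use; external-command and HTTP adapters
  cover real models.
- **Ensemble** — the three style variants form a committee aggregated by
  majority vote, union, or intersection; at the *domain level only*, the
  committee output is then fused (∪ or ∩) with the RBS output.
  Subcategories always come from the committee alone.

Scoring: per-label TP/FP/FN (sentinels carry no counts, so TP+FN equals
the gold positive total), micro/macro precision–recall–F1, 95% percentile
CIs from 2000 patient-level cluster bootstrap resamples, and multilabel
Krippendorff α (binarized per (unit, label), pooled nominal coincidence
matrix).

## Worked example

```bash
sdohkit pipeline --out run --n-patients 20 --seed 3
```

generates a synthetic 20-patient corpus, classifies it with the RBS and a
strict/balanced/liberal mock-LLM committee, fuses them
(majority vote, then ∪ with the RBS at the domain level), and prints:

```
              system       level  tp  fp  fn  micro_precision  micro_recall  micro_f1  ...  micro_f1_ci_lower  micro_f1_ci_upper
          rbs/domain      domain  30   3   0             0.91           1.0      0.95                    0.88               1.00
     rbs/subcategory subcategory  30   3   0             0.91           1.0      0.95                    0.88               1.00
     ensemble/domain      domain  30   8   0             0.79           1.0      0.88                    0.78               0.96
ensemble/subcategory subcategory  30   8   0             0.79           1.0      0.88                    0.78               0.96
```

Reading it: the RBS recovers every planted positive mention (recall 1.0)
because generator and lexicon are co-designed; its three false positives
are unanswered questionnaire segments, where the trigger phrase appears
but no answer is given — the classic keyword failure mode. The ensemble
here is *less* precise than the RBS alone because the liberal committee
member accepts uncertain and hypothetical mentions; on real text, where
the RBS misses paraphrases the LLM catches, the trade goes the other way.
The CI columns are patient-level cluster bootstrap percentiles.

Library use mirrors the CLI:

```python
from sdohkit import load_taxonomy, GeneratorConfig, generate_corpus
from sdohkit.rbs import classify_segment_rbs, default_lexicon_path, \
    default_cue_rules_path, load_cue_rules
from sdohkit.lexicon import load_lexicon

tax = load_taxonomy()
lex = load_lexicon(default_lexicon_path(), tax)
rules = load_cue_rules(default_cue_rules_path())
corpus = generate_corpus(GeneratorConfig(n_patients=50, seed=1), tax)
labels = classify_segment_rbs(corpus.segments[0], lex, rules, tax)
```

## Layout

| Module | Contents |
| --- | --- |
| `sdohkit.schema` | taxonomy, contextual attributes, segments, label sets, positivity predicate |
| `sdohkit.lexicon` | lexicon I/O, embedding-based expansion, exclusion filtering |
| `sdohkit.rbs` | sentence splitter, entity matcher, cue engine, prescreening |
| `sdohkit.llm` | prompt construction, backends (mock/command/HTTP), response parsing |
| `sdohkit.ensemble` | committee aggregation and rule–LLM late fusion |
| `sdohkit.evaluation` | counts, micro/macro PRF, cluster bootstrap, Krippendorff α, reports |
| `sdohkit.synthetic` | seeded corpus generator with planted contextual structure |
| `sdohkit.cli` / `sdohkit.io` | subcommands, JSONL/CSV readers and writers, manifests |

See `docs/methods.md` for the modeling choices, defaults, and limitations.
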