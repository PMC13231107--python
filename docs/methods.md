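# Methods

## Label space and positivity

The taxonomy is a two-level tree: 7 domain categories over 23
subcategories, shipped as an editable YAML config
(`sdohkit/data/taxonomy.yaml`). All code is name-agnostic — user configs
may define any counts. Eleven subcategory names are attested in the
clinical SDoH literature this schema follows; the remaining twelve are
plausible stand-ins, flagged `placeholder: true` in the config so users
can rename them without touching code. Sentinels ("none of the above" at
the domain level, "N/A" at the subcategory level) represent the empty
outcome and are never members of the label sets proper.

A mention is SDoH-positive iff it is current, patient-specific,
non-hypothetical, not uncertain, and not negated. The first three
conditions are the classic contextual attributes of clinical IE;
uncertainty and negation are folded into the same conjunction because an
unconfirmed or denied finding cannot ground a positive label — the
annotation logic the predicate encodes is "current, patient-specific, and
confirmed". The two levels are scored as independent tasks: gold
subcategories are *not* auto-propagated to their parent domains
(`derive_domains` exists but is opt-in), since domain and subcategory
annotation are separate decisions and auto-propagation would silently
change gold totals.

## Rule-based system

**Sentence segmentation** is rule-based and fully specified: a run of
terminal punctuation (`. ! ?`) followed by whitespace or end-of-text
closes a sentence; any newline run is also a boundary (clinical notes are
often line-structured lists); spans are whitespace-trimmed. No
abbreviation list is used — "Dr. Smith" splits. This is acceptable for
segment-level classification because labels are unioned across a
segment's sentences, so an over-split can only narrow a cue's scope, and
the cue and trigger of interest almost always share a clause.

**Entity matching**: literal lexicon patterns are word-boundary anchored
(`art` does not match inside `heart`) and case-insensitive unless flagged
(acronyms like `WIC` stay case-sensitive); regex patterns are taken as
written. Every occurrence of every entry is reported.

**Contextual disambiguation** is a simplified ConText-style scope model.
Each cue rule carries a trigger pattern, a class (negation, historical,
experiencer, hypothetical, uncertainty), a direction (forward, backward,
bidirectional), terminator tokens, and a token cap. Defaults:
`max_scope_tokens=10` (5 for short-range cues like "without" and
"possible"), terminators `but / however / although`, and the sentence edge
always terminates. These are the standard ConText defaults. Cue classes
fire independently with no precedence: the attributes are orthogonal
flags and positivity is a conjunction, so ordering cannot change the
outcome. A cue token lying inside the mention itself (e.g. "no" in "no
health insurance") does not modify that mention.

**Prescreening** cuts a window of `window` characters (default 150) of
context on either side of each lexicon match, clipped to the note;
overlapping or touching windows are merged into one segment, avoiding
near-duplicate segments when triggers cluster.

## LLM prompting

The system prompt has three delimited components — role-playing
instructions, label definitions enumerating every domain with its
subcategories, and step-by-step instructions — and fixes: hierarchical
order (domains first, then their corresponding subcategories), the
sentinel convention ('none' / 'N/A'), the contextual exclusion rule, the
answer dialect, and a style-specific inclusion threshold (strict =
explicit evidence; balanced = explicit or strongly implied; liberal =
also reasonably likely from context). The three styles differ only in
that threshold section, so they are pairwise distinct by construction.

The answer dialect is two lines (`DOMAINS: a; b` / `SUBCATEGORIES: x; y`)
chosen so the prompt and parser co-evolve: the parser accepts
case-insensitive keys and labels, treats `none`/`N/A`/`NA` as sentinels,
drops out-of-taxonomy labels with a warning (or raises in strict mode),
and raises a parse error carrying the raw response when neither line is
present. Wording of the templates is original to this package.

Few-shot blocks serialize examples as segment → expected answer, with an
optional explanation line; the three shipped banks (easy, hard,
synthetic, 5 examples each) are original synthetic text modeled on the
annotation situations that matter in practice — unambiguous statements,
questionnaire question–answer pairs with present or missing answers,
hypothetical applications, family-member attributions, and telegraphic
paraphrases.

Backends implement `complete(system, user) -> str`. Transport failures
are retried 3 times with exponential backoff; parse failures are not
retried (content, not transport). Decoding parameters belong to the
backend adapter and default to deterministic decoding. The built-in
`MockBackend` is a pure keyword classifier whose per-style blocking table
mirrors the cue vocabulary, giving a committee with a genuine
precision–recall spread while keeping the whole LLM path bit-for-bit
reproducible.

## Ensembling

Committee aggregation: majority keeps labels voted by strictly more than
half the members ("most"); even committees break ties toward exclusion —
the conservative reading. Union/intersection are the obvious set
operations; `strict_only` bypasses aggregation. Sentinels are not votable
labels: they are stripped before any set operation and re-inserted only
when a level comes out empty, so an abstaining member can never outvote a
positive finding and an all-sentinel committee yields the sentinel.
Rule–LLM fusion (∪ or ∩) applies at the domain level only; subcategory
labels always come from the committee alone, reflecting the large
precision gap of keyword rules at the fine-grained level.

## Evaluation

Counting: per positive label, TP/FP/FN over segments; sentinels carry no
counts, so per label TP+FN equals the gold positive count regardless of
the predictions (a conservation law the tests enforce). Gold segments
with no prediction are scored as sentinel predictions. Micro metrics pool
counts; macro averages per-label P/R/F1 over labels present in gold or
prediction (labels absent from both have undefined PRF and are excluded,
keeping macro comparable across systems; sentinel classes are likewise
excluded). Zero denominators give 0. Display rounds to 2 decimals; full
precision is kept internally.

CIs use the percentile cluster bootstrap — the minimal-assumption choice
when only a resample count is specified — with patients as clusters and
2000 resamples by default. Percentile intervals can, pathologically,
exclude the point estimate; this is not "fixed" but logged as a warning.
A single-patient input degenerates to a zero-width interval with a
warning.

Multilabel Krippendorff α: each (unit, label) pair becomes one binary
nominal decision per coder; all decisions pool into a single coincidence
matrix and α = 1 − D_o/D_e. This is the simplest construction consistent
with reporting a single α per task level; it weights every label's
absence/presence decision equally, so rare labels contribute little to
disagreement mass. A completely variation-free matrix returns 1 by
convention. The implementation is validated against an independent
pairwise-disagreement oracle in the tests.

## Synthetic corpus generator

The generator emulates the kind of corpus produced by prescreening notes
for trigger mentions: short telegraphic segments grouped by patient, with
positive mentions across all 7 domains / 23 subcategories plus negated,
historical, family-member, hypothetical, uncertain,
questionnaire-formatted, and distractor variants. Default mix: 45%
positive, 12% negated, 10% questionnaire (half unanswered), 8% each
historical and other-experiencer, 7% hypothetical, 5% each uncertain and
distractor — positives dominate because the emulated corpus was
keyword-enriched, and every contextual failure mode stays represented.
Defaults of 50 patients with 2–6 segments each give a corpus of the same
order as a realistic annotated validation set while keeping every test
fast.

Templates are original and co-designed with the shipped demonstration
lexicon and cue rules: each variant exercises exactly one cue rule, and
the generator records the label set the fixture RBS is *expected* to
produce. For the unanswered-questionnaire variant that expectation
deliberately differs from gold — the trigger is present but the answer is
missing, planting a known false positive. The end-to-end test asserts the
RBS output equals the planted expectation on every segment, which
verifies the whole matching/scoping/positivity chain, not a measured
accuracy.

Patients draw a preferred subcategory and reuse it with probability 0.5
per segment, inducing intra-patient correlation so the patient-level
cluster bootstrap is meaningfully different from (wider than) an i.i.d.
segment bootstrap — a tested property.

What passing on synthetic data does **not** show: robustness to
paraphrase, misspellings, long-range context, section structure, or
vocabulary outside the demonstration lexicon. The lexicon is
illustrative, not a curated clinical vocabulary, and the mock backend
cannot exhibit the semantic generalization (or the reasoning-calibration
errors) of a real LLM.

## Scope and numerical choices

- Embedding-based lexicon expansion takes the embedding *function* as an
  argument rather than bundling a model; cosine similarity on raw
  vectors, descending sort with lexicographic tie-break (making results
  order-invariant), zero-norm vectors skipped with a warning. Thesaurus
  (hypernym/hyponym) expansion via licensed medical vocabularies is out
  of scope; the entry provenance tag (`seed`/`expanded`/`manual`)
  reserves the slot.
- Section detection, weighted voting/stacking ensembles, cost/latency
  accounting, and demographic-subgroup analyses are out of scope.
- Bootstrap, generator, and mock-LLM paths consume a single integer seed
  each; the acceptance script threads its `--seed` through all of them.
- The `pipeline` command chains the stages in-process; each stage writes
  a manifest (config hash, seed, artifact digests) so identical configs
  are verifiably byte-identical.
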