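# Methods

This note records the evaluation model implemented by `heleval`, the
choices made where the definitions leave room, and what the synthetic
experiments do and do not demonstrate.

## Vocabulary model

A vocabulary is a rooted, multi-parent directed acyclic graph whose edges
are subClassOf (is-a) relations, stored child → parent. Real biomedical
vocabularies are poly-hierarchies — a MeSH descriptor commonly has several
parents — so no quantity assumes a tree: depth is the minimum over parent
paths to any root, and every distance is a minimum over upward paths.
Only is-a edges are read; `part_of` and other relations are out of scope,
as are reasoning and similarity measures beyond path distance.

Obsolete OBO terms are dropped at load time together with any edge touching
them (warned, since they are not valid link targets), while an `is_a`
target with no stanza at all is an error: the first is routine vocabulary
lifecycle, the second is a broken file.

Vocabularies with several roots or disconnected components are accepted.
By default a pair spanning two components has no common ancestor and is
reported as a distinct `no_common_ancestor` outcome rather than given a
fabricated distance; an optional virtual super-root (`--virtual-root`)
bridges components for users who prefer every pair to be scorable.

## Match classification and distance

The subset semantics of subClassOf are interpreted through ancestor
closure: `E_p ⊂ E_t` iff `E_t` is reachable from `E_p` by upward edges.
Exact / overspecific / underspecific / orthogonal are therefore mutually
exclusive and exhaustive for connected pairs.

Distance counts edges. For nested pairs it is the one-directional ancestor
distance (equivalently the summed distance through their LCA, since the
nested entity's LCA is the ancestor itself). For orthogonal pairs it is the
minimum over common ancestors `E_x` of
`dist(E_t, E_x) + dist(E_p, E_x)` — paths run up–up through a common
ancestor only; zig-zag routes through unrelated descendants are not
admitted, so sibling entities are at distance 2 regardless of how bushy
their subtrees are. When several ancestors minimise the sum, all are
reported as LCAs; the distance is shared, so the tie never affects a
metric, and displays use the lexicographically smallest id.

Three outcomes are carried outside the four types and excluded from every
characteristic denominator: a prediction that is missing (the model linked
nothing at the gold span), an out-of-vocabulary id, and a cross-component
pair without a virtual root. A flag folds missing predictions into the
orthogonal count for users who want unlinked spans to depress accuracy.

## Location

Location is the relative depth of the **target** entity (never the
prediction) within its branch. The ratio "depth over shortest root-to-leaf
distance" is ambiguous about which leaf is meant, and a global shallowest
leaf can push the ratio above 1 for deep targets. The default
operationalisation divides `depth(E_t)` by the length of the shortest
root-to-leaf path *through the target* — `depth(E_t)` plus the shortest
downward distance from the target to a leaf descendant. This pins roots at
0, leaves at 1, and bounds the value in [0, 1] on any DAG. The literal
global-minimum-leaf denominator remains available
(`--loc-denominator global-min-leaf`) for comparison; it is not bounded.
Location is monotone along any chain realising a shortest root-to-leaf
path; an arbitrary parent→child step in a poly-hierarchy can move to a
shallower branch and legitimately lower the value.

Location histograms use right-closed decile bins by default, with location
0 assigned to the first bin.

## Alignment policy

Evaluation is isolated from span finding: a prediction is paired with a
gold annotation only when the (document, start, end) span matches exactly.
Gold spans without a matching prediction are scored as missing;
predictions without a gold counterpart are listed in an unmatched report
and never scored. PubTator offsets are 0-based and end-exclusive over
title + single space + abstract; a span-text mismatch warns rather than
fails because released corpora contain encoding drift.

Composite gold ids (`A|B` at one span) expand into separate pairs. When
both sides of a span carry several ids, predicted ids are assigned to gold
ids by exhaustive minimal-total-distance search (spans carry few ids, so
brute force is exact); leftover gold ids score as missing, leftover
predictions go to the unmatched report. Duplicate identical gold records
are collapsed with a count — they re-enter the evaluation only through the
Global set's natural repetition. Gold ids absent from the vocabulary are
excluded and reported: version skew between a corpus and a vocabulary
release is not a model error.

## Evaluation sets

Repetition and novelty are judged on the pair key (normalised mention
text, entity id). Mention normalisation defaults to casefolding with
whitespace collapse and can be set to exact; novelty can alternatively be
keyed on the mention alone or the entity alone for comparison with
mention-level generalisation analyses. With no train/dev annotations the
Novel set equals the Global set by construction.

Unique sets keep one representative per duplicate class, the first in
document order. A context-sensitive model can disagree with itself across
duplicates; in that case the modal prediction represents the class, and a
tie deliberately prefers a mismatching prediction (logged) so that a
split decision is not silently scored as correct.

## Characteristics

The six metrics are pure functions of the four type counts; the identities
`coverage = accuracy + (1−accuracy)·cautiousness`,
`specificity = accuracy + (1−accuracy)·braveness` and
`braveness + cautiousness + orthogonality = 1` hold to machine precision
and are asserted in the test suite. With no mismatches the three
error-profile metrics are undefined and reported as null. Reports carry
proportions at full precision; percentages rounded to two decimals are a
display convention only.

Scenario presets filter the report to the metrics a use case cares about:
`position_focus` (where do mismatches sit, plus accuracy),
`coverage_priority` (accuracy, coverage, cautiousness, orthogonality, mean
mismatch distance) and `neighbourhood` (accuracy, mean mismatch distance,
location table). The mean match distance averages over mismatches only —
exact rows at distance 0 would dilute the signal — and a mismatch-free
profile reports 0 rather than null, since "no mismatch" is the best
possible neighbourhood outcome. Both conventions are configurable.

## Synthetic data

The generator emulates the three inputs: vocabularies, gold corpora,
predictions.

* **Vocabularies** are random single-root DAGs built in topological order,
  each new node drawing 1..`max_parents` parents uniformly among earlier
  nodes (default `max_parents=2`), so acyclicity holds by construction.
* **Gold corpora** sample unique (mention, entity) pairs — synthetic
  mention tokens, entities drawn by default from internal nodes (those
  with both a parent and a child), so that every corruption outcome is
  feasible and realised outcome frequencies track the configured mixture —
  then distribute repetitions multinomially around `duplication_factor`
  and pack occurrences into PubTator documents with exact offsets.
* **Predictions** corrupt each pair by drawing one of four outcomes
  (default mixture 0.8 exact / 0.05 overspecific / 0.1 underspecific /
  0.05 orthogonal) with geometric hop counts (`step_mean` 1.5).
  Overspecific walks descend, underspecific walks ascend, orthogonal
  targets are sampled by up-then-down walks with an exact fallback to the
  orthogonal complement. An outcome infeasible for a particular entity is
  redrawn and the redraw counted. Corruption applies per unique pair key
  by default (a lexicon-driven model links identical mentions
  identically); `--per-occurrence` models context-sensitive behaviour and
  re-opens a Global vs Global-Unique gap.

Every realised outcome is logged, and the log is ground truth: the
closed-loop test requires the full pipeline — file round trip included —
to reproduce the log's type counts exactly, and the parameter-recovery
test requires braveness/cautiousness/orthogonality to recover the
configured mixture within three binomial standard errors. The stochastic
suites run at 20 seeds × 2000 pairs on 150-node vocabularies, with
150–200 random DAGs of up to 50 nodes for the brute-force
distance/LCA cross-checks; these sizes exercise every code path while
keeping the default suite quick.

All randomness derives from a single seed through `numpy.SeedSequence`
spawning (one child stream per stage: entity sampling, document layout,
train selection, corruption), so stages are independently reproducible and
outputs are byte-identical per seed.

What passing these tests does **not** show: synthetic mentions are opaque
tokens, so nothing here validates mention-text phenomena (abbreviations,
casing variants, nested spans), corpus-specific offset quirks, or the
behaviour of any real linker; the corruption process is memoryless per
pair, unlike real models whose errors correlate across related entities.

## Numerical and degenerate-input conventions

Integer edge counts and exact rational locations leave little numerical
surface; identity checks in tests use 1e-12 absolute tolerance, and
comparisons against two-decimal published percentages use 0.02 points to
absorb their rounding. Degenerate inputs: a single-node vocabulary has
location 0 (it is a root, taking precedence over its leafhood) and admits
no corruption; an empty profile subset yields an empty profile without
error; all-zero counts raise; an empty novel set warns and yields no
characteristics downstream.
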