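# Methods

This note documents the model implemented in `ratparse`, the choices made
where the design was genuinely open, and what the synthetic fixtures do and
do not establish.

## Declarative memory and activation

Memory is a store of chunks (slot→value records). Activation is the sum of
a history component and a context component.

**Base level.** `B = ln(Σ_k t_k^(−d))` over the ages `t_k` of the chunk's
presentations, with decay `d = 0.5` (the conventional default; not fitted).
Chunks harvested from a corpus do not have literal presentation timestamps;
their frequency `n` is mapped to a *surrogate schedule* of `n` presentations
spread uniformly over an exposure lifetime, giving the closed form
`B = ln(n · span^(−d) / (1 − d))`. Defaults: lifetime 15 years,
exposure scale 1.0. The closed form agrees with an explicit evenly spaced
schedule to well under 5% relative error for `n ≥ 10` at corpus-scale spans
(tested). Natural logarithms throughout.

**Spreading.** A cue `j` present in the context boosts every chunk carrying
`j` as a slot value by `S_max − ln(fan_j)`, weighted by `W` (default 1,
undivided across cues; a divided-by-`n` mode is available as a switch).
`S_max = 20` keeps strengths positive at realistic fans. Two choices here
were open:

* *Cue identity.* For the parser, a cue is the slot-qualified feature atom
  (`s1_label=NP`, not bare `NP`): the same category in different structural
  positions is different evidence, and the fan of a cue counts the parsing
  steps sharing that positional property. With unqualified atoms, a shift
  step and a reduce step harvested from the same sentence can carry
  identical value sets and become indistinguishable to retrieval, which
  collapses the action choice; positional qualification restores the
  discrimination that a parser needs. (For plain lexical memories, cues are
  ordinary value atoms and the textbook worked example goes through
  unchanged.)
* *Absent features.* A feature whose value is the reserved `none` atom
  contributes no cue: absence of structure is not treated as positive
  evidence. One consequence is that sentence-initial words, with an empty
  stack, receive little spreading — they are outliers in the model, which is
  one reason the corpus fit models only words 2..n−1.

**No activation noise** by default: retrieval, parsing and simulation are
fully deterministic, and all stochasticity lives in the generators and the
fitted likelihood. A logistic noise hook (`noise_scale`) exists but is off
everywhere.

**Retrieval.** `T = F · exp(−f · A)`. Top-k retrieval (k = 3) is exact
scoring over the store with a stable (insertion-order) tie-break, so runs
are reproducible without a seed.

## The parser

A shift–reduce constituency parser over a stack of partial trees and a
queue of (word, lemma, POS) items, with four actions: shift, unary reduce,
binary reduce, and postulate-gap (which pushes an empty element bound to a
previously shifted wh-filler). Legality: no shift on an empty queue, no
reduce on an empty stack, no binary reduce with fewer than two trees, at
most two gaps between shifts, and a gap only when a filler is registered.
Every applied action is validated, so a legality violation is impossible by
construction rather than merely untested.

The retrieval context is a 19-feature snapshot of the state (three stack
positions: category, head lemma, head POS; daughter categories of the top
two; two queue positions: lemma and POS; the gap counter; a filler flag).
The set is configurable; the default realizes "some features of the trees
and upcoming words, including lexical heads" at the granularity the parser
needs. At each step, candidate chunks are restricted to those whose action
is legal, the top-3 are retrieved, and the majority action is applied (ties
go to the highest-activation chunk's action). A word's activation record is
the mean of the step activations up to and including its shift; reduces
executed after the final shift close off the tree and are charged to the
last word's simulated time but belong to no word's activation record (the
modeled corpus words 2..n−1 are unaffected). A step budget of 10× sentence
length guards against pathological memories; exceeding it returns a partial
parse flagged incomplete.

Gold-guided mode replays the oracle action sequence of a provided tree,
recording the same top-3 retrieval activations at each gold state — used
for corpus simulation, where the parser is corrected to the gold structure
at every word.

## Treebank preparation

Bracketed trees are right-factored into binary trees with `|`-decorated
intermediate labels (an exact bijection; `unbinarize ∘ binarize = id`),
heads are annotated with a compact Collins-style percolation table shipped
as package data (unknown categories fall back to the rightmost child, with
a warning), numeric coreference indices are stripped (function tags are
kept), terminals are lemmatized by a deterministic dictionary with identity
fallback, and wh-trace sites (`*T*` under `-NONE-`) become gap leaves;
other empty elements are deleted. Harvesting walks each tree's oracle,
forms a chunk from (features, action) at every step, merges identical
chunks with summed counts, and converts counts to surrogate schedules.

## The reading model

Per word: attend (50 ms), lexical retrieval, parsing-step retrievals until
a shift, a wh-filler retrieval per postulated gap, key press (150 ms).
Each memory process also costs one procedural firing `r = 33 ms`. The
attention shift to the next word fires concurrently with the key press and
adds no time, so

```
RT = 50 + (33 + T_lex) + Σ_steps (33 + T_step) + Σ_gaps (33 + T_wh) + 150  [ms]
```

and a word with all-zero retrieval latencies and one parsing step takes
exactly 266 ms. Lexical retrieval uses base-level activation only (no
lexical spreading is part of the model). The wh-filler is a chunk with an
explicit presentation at its encoding time on the simulation clock; each
successful retrieval re-presents it. The clock advances by every process
and resets at sentence boundaries — the modeled words exclude sentence
edges, so cross-sentence decay would be invisible to the fit anyway.

## Fitting

Only `F` and `f` are estimated (d, W, S_max, r are fixed as above). Priors
`F ~ Gamma(2, rate 10)` (mean 0.2) and `f ~ Gamma(2, rate 4)` (mean 0.5);
likelihood Normal with sd 20 ms over per-word mean RTs, summed jointly over
all modeled words. Data preparation keeps the first two stories, drops the
first ten sentences of each, and models word positions 2..n−1.

Because only the retrieval terms depend on (F, f), the likelihood evaluates
against a cached simulation context: one guided simulation at the
prior-mean parameters records each word's fixed cost and retrieval-event
activations, and `RT(F, f) = fixed + Σ 1000·F·exp(−f·A)` is recomputed per
draw. The within-sentence clock (hence wh-filler decay) is frozen at the
reference run inside this cache; the synthetic-data generator runs the full
simulation at the true parameters, so parameter-recovery tests include this
approximation honestly. The sampler is a seeded random-walk Metropolis with
a full-covariance proposal taken from a Laplace approximation at the MAP;
because the posterior has a spurious mode near `f = 0`, the MAP search is
seeded from a coarse log-spaced grid before the local polish. Default
schedule: 1,200 draws, 2 chains, 400 burn-in; rank-normalized split-Rhat
(via arviz) is reported and a value above 1.1 triggers a warning rather
than a silent pass. With an empty dataset the same machinery returns the
prior (a prior-predictive check).

## Evaluation

Garden-path pairs are parsed freely; the summary reports the control minus
garden-path mean activation at the critical word and one spillover word
(the minimal window). The corpus regression is OLS of observed on predicted
RTs with the standard surface confounds (story, z-scored zone/position and
their interactions, z-scored length, log unigram/bigram/trigram, and the
length×frequency interaction); z-scores use the modeled subset, p-values
are two-sided from the t distribution with residual df, and rank-deficient
designs raise an error naming the collinear columns. Decile summaries cut
on quantiles of the split variable with ties kept in one bin (so a dominant
repeated value can reduce the bin count), and report the Pearson
correlation of per-decile mean predicted and observed RTs.

## Synthetic fixtures

The toy grammar covers S, NP, VP, PP, SBAR with a Zipf-skewed lexicon and
three structural properties that the model's predictions hinge on: a
frequency skew (lexical and structural), an NP-vs-bare-S complement
ambiguity, and wh-relative clauses containing one trace. Every generator is
a pure function of its seed.

The garden-path fixture harvests memory from 300 generated trees in which
an overt-`that` complement clause is a *frequent* construction (45% of
complement-verb expansions) while the locally ambiguous onset "V the N ..."
continues as a plain direct object with probability `ambiguity_bias`
(default 0.9) and as a bare sentential complement otherwise. The paired
sentences share the embedded clause; only the complementizer differs. At
bias 0.9 the control-minus-garden-path activation difference at the
disambiguating verb is positive in 30 of 30 tested seeds; the difference
shrinks (but need not flip sign) as the bias falls, because the control
construction remains well-practiced regardless of the bias. The harvest
corpus size (300 trees) was chosen so that the continuation statistics the
fixture encodes are not dominated by sampling noise.

The synthetic reading corpus simulates ~160 sentences (two "stories",
~550 modeled words after filtering) and adds Normal noise matching the
likelihood sd. Recovery tests at the reduced schedule (400 draws, one
chain) recover the generating parameters within two posterior sd. These
problem sizes keep the full pipeline — harvest, parse, simulate, fit —
under a minute on one CPU.

What the fixtures do *not* emulate: English lexical statistics, attachment
ambiguity beyond the single NP/S contrast, discourse effects, and the long,
structurally diverse sentences of a real treebank. Passing tests establish
the mechanics and directional predictions of the model at toy scale, not
corpus-level effect sizes; paper-scale numbers require the external
treebank and reading-time corpus through the same interfaces.

## Known limitations

* Free parsing is greedy (one path, no beam, no error recovery); early
  misretrievals propagate, as they do in the human data the model targets.
* The feature list is a reconstruction at the stated granularity (19
  features including lexical heads) and is deliberately configurable.
* The surrogate-schedule mapping from corpus frequency to base level is a
  closed-form stand-in for a presentation-history model; lifetime and
  exposure scale are configuration values, not fitted quantities.
* Retrieval failure is not modeled (no retrieval threshold is fitted); the
  optional `tau` threshold exists for exploration.
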