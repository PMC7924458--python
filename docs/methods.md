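# Methods

This note documents the models, conventions and numerical choices behind
`formamentis`, in the order the pipeline applies them.

## Corpus preprocessing

Documents are short texts, one per line (or a CSV `text` column). Cleaning
removes URLs and pictographic/emoji codepoints outright and strips the `#`
and `@` markers while keeping the token text — a hashtagged topic word is
still a word. Whether `@` is stripped is a switch (`strip_mentions`,
default on): handle treatment is a corpus-level editorial choice, and we
default to treating handles symmetrically with hashtags. Documents with
fewer than three whitespace tokens after cleaning are not admitted (the
count of discards is logged). Sentences split on terminal punctuation
(`.`, `!`, `?`); this naive splitter mis-splits abbreviations ("Dr."),
which a pluggable parser backend with its own sentenciser can avoid.

## From sentences to content-word edges

Each sentence is parsed into a Universal-Dependencies-style tree by a
pluggable backend (any callable mapping a sentence to tokens with lemma +
coarse POS and head→dependent arcs). Nodes whose POS lies in
`{ADP, AUX, DET, PART, PUNCT, CCONJ, SCONJ, SYM, X}` are then deleted and
their dependency neighbours bridged pairwise, chains of deleted nodes
collapsing transitively. The design intent: function words connect content
but carry no standalone meaning, so "love is weakness" contracts to the
single edge love–weakness, while the content verb in "the cat sat on the
chair" survives and keeps *cat* and *chair* connected through *sit*. The
negation particle ("not"/"n't") is exempt from removal: it modifies
meaning, is retained as a network node, and drives the antonym expansion
in emotional profiling. Edges are undirected and unweighted — all distance,
closeness, clustering and community measures downstream operate on simple
undirected graphs, and repeated pairs collapse.

Stemming happens at the network level: edge endpoints are replaced by
their stems, duplicates merge, and edges whose endpoints collapse onto one
stem are dropped. The stemmer is the classic Porter suffix-stripping
algorithm iterated to a fixed point, which makes the mapping idempotent
(plain Porter is single-pass and not idempotent on every input); a repeat
guard returns the lexicographically smallest member should the iteration
ever cycle. Any deterministic, idempotent word→stem callable can be
substituted.

## The multiplex network

The syntactic layer is the union of stemmed content edges over all
sentences of all documents — shared stems bridge sentences and documents.
The synonym layer adds an edge for every synonym pair whose two stems both
already occur as nodes; it never introduces nodes. Valence labels come
from continuous norms: scores are averaged over words sharing a stem, the
25th/75th percentiles (linear interpolation) of the stem-score
distribution define the class cut-offs, and labels use *strict*
inequalities — stems tied with a quartile are neutral, a conservative and
deterministic convention. The tails therefore hold at most ⌊n/4⌋ ± 1 stems
each on tie-free scores. Stems absent from the norms are labelled
`unknown`: they stay in the graph, count as neutral inside valence auras,
and are excluded from positive-vs-negative statistics, since user-supplied
norms cannot be assumed to cover a corpus.

## Measures

* **Closeness** is component-relative, `c(i) = N / Σ_j d_ij` with `N` the
  size of i's connected component, held internally as exact integers
  (component size and distance sum). This differs from the conventional
  `(N−1)/Σd` by a constant factor within a component; the conventional
  form sits behind a flag. Because the value is not comparable across
  components, rankings run on the largest connected component only, with
  lexicographic tie-breaks. Singleton components have undefined closeness
  (flagged, not zero).
* **Valence auras** report the fraction of a concept's neighbours in each
  valence class (summing to 1) and the arg-max label, `mixed` on ties.
* **Mean clustering** averages local clustering coefficients over all
  nodes (degree < 2 contributes 0); summation runs in sorted node order so
  the float result is independent of graph construction order.
* **Configuration models** are seeded double-edge-swap randomisations:
  10·|E| attempted swaps over a canonical sorted edge list, each swap
  rejected if it would create a self-loop or multi-edge. The degree
  sequence is preserved exactly, and degree sequences with a unique simple
  realisation (stars, triangles) return unchanged — deliberately, since
  the null is "same degrees, reshuffled links", not "any random graph".
  This is implemented in-repo rather than via the library routine, which
  raises on unswappable graphs instead of returning them.
* **Communities** use the Louvain modularity algorithm (networkx
  implementation), seeded; community ids are renumbered by smallest member
  for cross-run stability.
* **Mann–Whitney U** uses exact enumeration of all C(m+n, m) group
  assignments when m + n ≤ 10 (midrank handling of ties; two-sided p as
  `2·min(P(U≤u), P(U≥u))` capped at 1) and the tie-corrected normal
  approximation otherwise (scipy). `U(x,y) + U(y,x) = mn` always.

## Emotional profiling

A frame (network neighbourhood, or Louvain community, of a focus concept)
is first expanded: every member adjacent to a negation node contributes
all its listed antonyms alongside itself (members with no listed antonym
pass through with a warning). The profile counts, over the *m* distinct
frame words carrying at least one emotion, the fraction evoking each of
the eight basic emotions (anger, disgust, fear, trust, joy, sadness,
surprise, anticipation); fractions need not sum to 1. Emotion lookup falls
back from the surface form to the stem (a stem inherits the union of its
member words' emotions), because network nodes are stems while emotion
lexicons index surface words.

The null model fixes *m* and draws *m* distinct words uniformly from the
emotion-bearing vocabulary — without replacement, since a frame is a set
of distinct words — 1,000 times by default, recording per-emotion mean and
standard deviation. Significance is declared at `z ≥ 1.96`, one-sided by
construction (petals mark emotions evoked *more* than chance) while using
the conventional two-sided critical value as the radius; with a zero null
sd the z-score is undefined and never significant. Calibration: for frames
drawn from the null itself, z is mean ≈ 0, sd ≈ 1 per emotion and the flag
fires at ≤ 5% (the acceptance suite verifies this over 1,000 simulated
frames at 1,000 repetitions each).

## Benchmark

One network is built per topic from all of that topic's documents pooled
(a topic text is a small collection of sentences about one concept). Its
top-10 closeness concepts are mapped onto a reference association network
— resolution tries the surface form, then the stem — and each resolved
word contributes its shortest-path distance to the topic word (the topic
itself is excluded; unresolvable or disconnected words are skipped and
counted). The null repeats the *entire* ranking pipeline on
degree-preserving rewirings of each topic network, 50 realisations by
default, pooling all distances: reshuffling links severs the relation
between structure and meaning, so re-derived rankings are the honest null.
The two samples meet in a two-sided Mann–Whitney test; distances pool per
word across topics.

## Synthetic study conditions

The fixtures module makes the whole pipeline testable offline.

* **Fallback parser**: a deterministic rule-based parser over a tiny
  grammar — optional determiners, SVO order, copular/auxiliary runs,
  prepositional phrases, negation; unknown tokens default to NOUN and the
  parser never fails. It is not general English: real corpora should use a
  pluggable UD backend. It does parse the constructions that define the
  contraction semantics correctly, which is what the tests require.
* **Mini-lexicons**: `n` synthetic words (pronounceable CV-syllable forms
  filtered to be stemmer fixed points with distinct stems, so surface
  forms equal network nodes). Valence scores are constructed so the
  quartile labelling recovers requested class sizes *exactly*, using
  plateaus at the quartile values where the strict-inequality convention
  requires ties (an infeasible request raises). Defaults, 10/20/10
  positive/neutral/negative, echo the roughly 1:2:1 quartile split of the
  method. Emotion tags are assigned at exact planted base rates
  (0.16–0.35 per emotion, unequal on purpose — real emotion lexicons tag
  many more fear/trust/joy words than sadness words). Six synonym and six
  antonym pairs are planted with ground truth returned.
* **Planted-topic corpus**: 3 topics × 5 documents, ~18 words per
  document. Each topic word appears in copular sentences with its 8
  associates (so after contraction the topic is the hub of a star), and
  20 filler words hang off the associates in chains, giving fillers
  degree profiles similar to associates but peripheral positions. The
  emitted reference network wires associates at distance 1 from their
  topic and all fillers at distance 3 (through a shared hub). Closeness
  on the real network therefore ranks associates into the top-10
  (empirical median distance 1), while on rewired networks hub adjacency
  is randomised and fillers flood the rankings (null median 3). A 10%
  negation rate plants "not" nodes for the antonym-expansion path.
  What this generator does *not* emulate: realistic syntax diversity,
  polysemy, hashtag/emoji noise, or vocabulary overlap between topic
  documents — power against this fixture shows the machinery ranks
  planted structure correctly, not that real tweets are this clean.
* **Lexical corpus**: copular sentences over the lexicon's own
  vocabulary, covering every planted synonym/antonym pair, so a single
  corpus exercises valence labelling and the synonym layer together.

## Problem sizes

Defaults throughout are the method's stated conditions: 1,000 null
repetitions, 50 configuration-model realisations, top-10 rankings,
`z ≥ 1.96` / alpha 0.05, three-word admission. The acceptance script runs
the benchmark at full defaults (3 topics, 50 realisations) and the
emotion-null calibration at 200 frames × 1,000 repetitions; the test suite
runs the full 1,000 × 1,000 calibration. All randomness flows from one
seed; results are reproducible bit-for-bit across processes (canonical
orderings are used wherever floating-point summation or seeded graph
algorithms would otherwise depend on hash-dependent iteration order).

## Known limitations

* The fallback parser handles one clause per sentence; coordination and
  subordinate clauses degrade to flat attachments (extra words hang off
  the root). Plug in a real UD parser for natural corpora.
* Porter stemming is English-only and occasionally aggressive
  ("famous" → "famou"); any idempotent stemmer can be swapped in.
* Valence labels are population-level norms; population-specific
  perceptions (e.g. a cohort that dislikes a nominally neutral concept)
  surface only through auras and frames, not through the labels
  themselves.
* The synonym layer only links stems already present in the corpus;
  out-of-corpus WordNet neighbours are never imported.
* With ties and m + n ≤ 10 the exact Mann–Whitney p-value uses midrank
  enumeration, which has no scipy counterpart to cross-check against;
  tie-free cases are verified against scipy's exact method.
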