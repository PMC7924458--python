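# formamentis

Textual forma mentis networks ("mindset networks") for stance analysis of
short-text corpora.

Given a collection of short documents — tweets, survey answers, paragraph-long
texts — this package reconstructs how the authors structured and emotionally
perceived the concepts they wrote about. It builds a **multiplex lexical
network** whose nodes are stemmed concepts and whose edges come from two
layers: *syntactic* dependencies extracted sentence by sentence (with
meaning-free function words contracted away, so that in "love is weakness"
the copula disappears and *love* links directly to *weakness*), and
*synonym* relations from a WordNet-style lexicon. Every concept carries a
valence label from psycholinguistic norms, discretised by quartiles into
positive / neutral / negative. On top of the network the package computes
the stance-analysis measures of cognitive network science: closeness
rankings of semantically prominent concepts, valence auras of semantic
frames, emotional profiles with a sampling null model ("emotional
flowers"), configuration-model comparisons, Louvain community frames, and a
topic-relevance benchmark against reference free-association networks.

It is aimed at computational social scientists and psycholinguists who want
a *glass-box* alternative to black-box sentiment classifiers: every reported
stance can be traced back to explicit conceptual associations in the text.

## The measures

**Closeness (component-relative).** For a node *i* in a connected component
of *N* nodes,

```
c(i) = N / Σ_j d_ij
```

where `d_ij` is the shortest-path length on the aggregate network (both
layers treated as equivalent — the multiplex has no weights or inter-layer
links, so multiplex closeness reduces to this). Because the component size
enters the formula, rankings are restricted to the largest connected
component. The conventional `(N−1)/Σd` variant is available behind a flag.

**Valence aura.** The modal valence label among a concept's neighbours; a
word linked mostly to positive words has a positive aura even if the word
itself is neutral (contextual valence shifting).

**Emotional flowers.** A frame's emotional profile is the fraction of its
emotion-bearing words evoking each of Plutchik's eight basic emotions.
Fixing *m*, the number of frame words with at least one emotion, the null
model draws *m* words uniformly without replacement from the emotion
lexicon, 1,000 times; per-emotion z-scores `(observed − null mean)/null sd`
are significant at `z ≥ 1.96`. Concepts linked to a negation ("not")
contribute their antonyms alongside themselves.

**Benchmark.** One network per topic text; its top-10 closeness concepts
are mapped to shortest-path distances from the topic word on a reference
free-association network. Degree-preserving rewiring (configuration models,
50 realisations, re-ranked from scratch) gives the null distances, and a
two-sided Mann–Whitney test compares the two samples.

## Worked example

```python
from formamentis import *
from formamentis.fixtures import fallback_parse
from formamentis.corpus import Document
from formamentis.lexicons import LexiconBundle, ValenceNorms, EmotionLexicon, PairLexicon

bundle = LexiconBundle(
    valence=ValenceNorms({"love": 8.0, "weakness": 2.5, "fear": 2.0,
                          "strength": 7.5, "doubt": 3.0, "hope": 7.8,
                          "change": 5.2, "time": 5.0}),
    emotions=EmotionLexicon({"love": {"joy", "trust"}, "fear": {"fear"},
                             "hope": {"anticipation", "joy"},
                             "doubt": {"fear", "sadness"}}),
    synonyms=PairLexicon.from_pairs([("defeat", "conquer")]),
    antonyms=PairLexicon.from_pairs([("love", "hate")]),
)
docs = [Document.from_raw(str(i), t) for i, t in enumerate([
    "love is weakness", "fear is weakness",
    "hope defeats fear", "love conquers doubt",
])]
tfmn = assemble_tfmn(docs, bundle, fallback_parse)
print("nodes:", sorted(tfmn.nodes))
print("syntactic edges:", tfmn.n_syntactic, "| synonym edges:", tfmn.n_synonym)
ranked = closeness_ranking(tfmn, k=3)
print("top-3 closeness:", [(w, round(c, 3)) for w, c in ranked])
aura = valence_aura(tfmn, "weak")
print("aura of 'weak':", aura.aura, {k: round(v, 2) for k, v in aura.fractions.items()})
```

This prints:

```
nodes: ['conquer', 'defeat', 'doubt', 'fear', 'hope', 'love', 'weak']
syntactic edges: 6 | synonym edges: 1
top-3 closeness: [('conquer', 0.778), ('defeat', 0.778), ('fear', 0.636)]
aura of 'weak': mixed {'positive': 0.5, 'neutral': 0.0, 'negative': 0.5}
```

The copulas have been contracted ("love is weakness" → the edge
love–weak), "weakness" and inflected forms merged onto the stem *weak*,
and the synonym pair defeat/conquer realised as a synonym-layer edge
because both stems occur in the corpus. *weak* is linked to one positive
concept (*love*) and one negative one (*fear*), hence a mixed aura with
fractions 0.5/0.5 — the per-neighbour-fraction convention used throughout.

## Command line

```bash
formamentis fixtures --seed 1 --out demo          # synthetic lexicons + corpus
formamentis build --input docs.txt --lexicons demo/lexicons --seed 1 --out net
formamentis frame gender gap --input docs.txt --lexicons demo/lexicons --out frames
formamentis benchmark --input demo/corpus --lexicons demo/lexicons --out bench
```

`build` writes the network (GraphML + TSV edge list), the closeness ranking
and a summary (layer sizes, valence class counts, clustering ± its
configuration-model null). `frame` writes per-focus JSON reports with frame
members, aura, emotional profile, null and flower z-scores. All commands
honour `--seed` and produce byte-identical JSON on repeated runs.

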