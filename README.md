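# laylink

`laylink` annotates clinical note text by linking medical terms to lay
definitions — definitions written at or below average adult literacy level —
and ships the two lexicon-construction tools that make such a resource
practical to build: a distant-supervision term-importance ranker and an
embedding-based synonym miner with pseudo-relevance-feedback reranking.

## How linking works

1. **Recognition.** A deterministic dictionary tagger finds candidate term
   spans by greedy leftmost-longest token-window matching against a concept
   table (surface form → concept id, preferred name, semantic types).
   Precomputed spans from an external concept tagger can be imported instead.
2. **Gating.** Each match is classified by its semantic types: any
   *prioritized* type → full lookup; all types *deprioritized* → ignored;
   otherwise a shallow lookup (stages 1–2 only).
3. **Four-stage lookup.** (1) exact surface match in the lexicon; (2) the
   concept's preferred name; (3) the surface with common modifier words
   (e.g. *chronic*, *severe*, *left*) removed; (4) per-word fallback — each
   word of the trimmed term is looked up and every hit is displayed with a
   bracketed label (`[rhythm]: …`), marking a *partial* match. Interim
   results are memoized; caching never changes output.
4. **Display rules.** Acronyms show only their top-ranked (most frequent)
   sense; drugs show all senses, or fall back to a drug-class definition
   when no term-level definition exists; plain terms show all senses in
   rank order. Output renders as JSON records or HTML with hover titles.

## Lexicon construction tools

- `laylink.importance` — extracts candidate terms from a corpus, labels
  them distantly by consumer-vocabulary membership, fits an L2-regularized
  logistic model, and optionally adapts it on a small manually labeled set
  (stacking: base score as an extra feature) to correct the bias from
  important terms missing from the vocabulary. Outputs a probability
  ranking.
- `laylink.synmine` — candidate synonyms are a target's neighbors in an
  interwiki-link edge list; ranked by embedding cosine similarity, then
  reranked against a Rocchio-style feedback vector built from the top-k
  candidates.

`laylink.fixtures` generates seeded synthetic inputs for all of the above,
including notes with gold annotations verified by an independent stage
evaluation at generation time.

## CLI

```bash
# generate synthetic inputs to play with
laylink gen-fixtures --kind bundle --seed 1 --out fx/

# annotate a note
laylink annotate --text fx/notes/note_000.txt --concepts fx/concepts.tsv \
    --lexicon fx/lexicon.tsv --drug-classes fx/drug_classes.tsv \
    --config fx/config.txt --format records --out out.json

# rank candidate terms by importance
laylink rank-terms --corpus fx/notes --concepts fx/concepts.tsv \
    --vocab vocab.txt --out ranked.tsv

# mine and rerank synonyms
laylink gen-fixtures --kind embedding --seed 1 --out emb/
laylink synonyms --edges emb/edges.tsv --vectors emb/vectors.txt \
    --target targ000 --out synonyms.tsv
```

File dialects (all plain-text TSV / sectioned config) are documented in
`laylink/lexicon.py` and `laylink/synmine.py`.

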