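# sparqlforge

Schema-driven SPARQL query generation from natural-language questions, with
execution-based evaluation — for life-science knowledge graphs such as
UniProt, Rhea and Bgee, whose RDF schemas are too intricate for most users to
query by hand.

## The idea

Letting a language model write SPARQL directly invites structural
hallucination: grammatically plausible queries over property paths that do
not exist. `sparqlforge` splits the task in two so the model never touches
SPARQL:

1. **Word extraction.** A model (or a deterministic mock) reads the question
   together with a listing of a curated schema's variables — human-readable
   names like `uniprot_taxonomy` with example values and short explanations —
   and emits *variables* (what to retrieve) and *parameters*
   (variable, value) pairs (the constraints), reasoning through four
   chain-of-thought steps: extract the user's request, convert it to
   variables, extract the stated conditions, convert them to parameters.
2. **Rule-based query building.** The schema is a forest: each database
   entry class is a subject root with `rdf:type` terms, and every property
   path introduces a named variable. Walking from the root to each needed
   variable yields the triple patterns; requested variables populate
   `SELECT DISTINCT`, and each constrained variable gets a `VALUES` block.
   The builder is total and deterministic, so every generated query is
   syntactically valid by construction.

Generated and ground-truth queries are compared by **executing both** and
scoring the result tables. With G the truth table (N_g rows) and Q the
generated one (N_q rows), each row a set of cell values:

- S_ij = Jaccard(G_i, Q_j) for all row pairs,
- M = maximum-weight one-to-one matching on S,
- score = (1 / max(N_g, N_q)) · Σ_{(i,j)∈M} S_ij,

so unmatched rows on either side are penalized. Variable selection and
parameter extraction are scored by set Jaccard over names and exact
(variable, value) pairs.

## Worked example

A minimal UniProt schema (`uniprot.yaml`):

```yaml
name: uniprot
prefixes:
  up: <http://purl.uniprot.org/core/>
  taxonomy: <http://purl.uniprot.org/taxonomy/>
  citation: <http://purl.uniprot.org/citations/>
model:
  - "UniProt up:Q9BYF1":
      - a: up:Protein
      - explanation: A protein entry identified by its UniProt accession.
      - up:organism:
          uniprot_taxonomy: taxonomy:9606
      - up:citation:
          uniprot_citation: citation:15174051
```

Asking for citation IDs of human (taxon 9606) proteins:

```sh
sparqlforge generate --schema uniprot.yaml \
    --var uniprot_citation --param uniprot_taxonomy=taxonomy:9606
```

prints

```sparql
PREFIX taxonomy: <http://purl.uniprot.org/taxonomy/>
PREFIX up: <http://purl.uniprot.org/core/>

SELECT DISTINCT ?uniprot_citation
WHERE {
  ?UniProt a up:Protein .
  ?UniProt up:organism ?uniprot_taxonomy .
  ?UniProt up:citation ?uniprot_citation .
  VALUES ?uniprot_taxonomy { taxonomy:9606 }
}
```

The root type pattern anchors the entry class, the two edge patterns are the
property paths from the schema, and the `VALUES` block binds the constraint.
Executed against a 3-entry fixture graph in which two entries carry taxon
9606, the query returns exactly those two citation rows. Scoring that table
against itself gives 1.0; scoring it against a table with one extra spurious
row gives 2/3 — the unmatched-row penalty at work.

The same library surface is available in Python (`parse_schema`,
`build_query`, `execute_local`, `table_similarity`, `run_campaign`, ...),
and the other subcommands cover extraction (`extract`), end-to-end question
answering (`ask`), scored benchmark campaigns (`benchmark`), metric-only
scoring of two result tables (`eval-tables`) and synthetic fixture
generation (`make-fixture`).

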