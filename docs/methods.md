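# Methods

This note documents the models, conventions and design decisions behind
`sparqlforge`, in the order the pipeline runs.

## Schema model

A schema abstracts an RDF database whose entries all follow one triple
structure: a forest of named variables. Subject roots carry one or more
`rdf:type` terms; every edge is a predicate (prefixed name or absolute IRI)
leading to a child variable. Example values and curated explanations are
documentation for humans and for the extraction prompt; they never
participate in query generation.

The YAML dialect accepted by `parse_schema` is a deliberate, documented
subset of the schema grammars used by community schema repositories (those
grammars also carry cardinality annotations, language tags and endpoint
metadata that play no role here). Anything outside the subset is rejected
with a precise error rather than being guessed at. The canonical serializer
`render_schema` emits the same dialect, and `parse(render(s)) == s`
structurally, which the test suite checks on randomly generated schemas.

**Connector classification.** Upstream schemas do not mark connector nodes
explicitly, so a rule plus an override is used: a non-root node is a
connector iff it has children and carries no `selectable: true` flag.
Connectors never appear in variable listings or prompts; they surface only
as intermediate variables inside generated queries.

**Identifiers.** Variable names must match an identifier pattern (letters,
digits, underscore, not starting with a digit; Unicode letters allowed) so
they can be emitted as SPARQL variable names unchanged.

**Merging.** Cross-database questions use `merge_schemas`, which
concatenates disjoint schemas into one forest. Variable names must be
globally disjoint; prefix labels may repeat only with identical namespaces.

## Query construction

`resolve_triple_patterns` walks from each contributing root to every needed
variable and returns, in root-then-document order, the root's `rdf:type`
pattern(s) followed by the deduplicated union of path edges. Consequences
worth noting:

- adding a variable to a request never removes a pattern (monotonicity);
- a merged-forest request emits each root's pattern group into one WHERE
  block with no implicit join — joining two databases is expressed by
  binding the same value to variables of both schemas.

`build_query` puts the requested variables — and only those — into
`SELECT DISTINCT` (DISTINCT always, so result-table comparisons cannot
depend on store internals; constrained variables are not auto-selected). If
a request has parameters but no variables, the parameter variables are
selected, since an empty projection is not valid SPARQL. Each constrained
variable gets exactly one `VALUES` block listing its values in request order
(multiple values are a disjunction); constraints never use FILTER.
Aggregation (COUNT/GROUP BY), ASK, OPTIONAL, UNION and REGEX are
deliberately not generated — the builder covers simple searches and leaves
richer operations to downstream post-editing.

**Value typing.** A parameter value shaped like `label:local` with a
declared prefix is emitted as a prefixed name; an `http(s)://...` value as
an IRI; a double-quoted value as a plain literal with the quotes stripped;
anything else as a plain literal. A prefixed-name-shaped value with an
undeclared label is an error, because emitting it as a literal would
silently change its meaning.

**Rendering** is a fixed template (sorted PREFIX lines, one pattern per
line, VALUES last) and is byte-deterministic. Validity is not asserted by
the renderer but verified externally: the test suite feeds hundreds of
random queries to an independent SPARQL 1.1 grammar.

## Extraction

The prompt presents the variables-info listing and the four reasoning steps
(extract requests → map to variables → extract conditions → map to
parameters), and requires the model to end with a fenced block tagged
`answer` holding one JSON object `{"variables": [...], "parameters":
[[name, value], ...]}`. JSON was chosen so values round-trip byte-exact;
the last such block in the response wins, which tolerates models that quote
the format earlier in their reasoning. Three listing modes exist: `VwE`
(names, examples, explanations — the default), `VwoE` (no explanations) and
`VinS` (the raw schema text in place of the listing).

Validation is strict: unknown variable names and duplicated variables are
hard errors naming the offenders — no fuzzy matching, no silent dropping —
so model-induced errors stay isolated from builder correctness. The
strict-copy guard separately warns (never blocks) when a parameter value is
not a verbatim substring of the question, the typical copy hallucination
(an `=` drifting to `=>`); it checks the question only, since a faithfully
copied value that mismatches database vocabulary is an entity-normalization
problem, not a copy error. Entity recognition/normalization is a
pre-processing hook left to the caller: the pipeline assumes binding values
in the question already match database terms.

Clients implement a two-method contract (`complete`, plus `model_id` /
`temperature` metadata). The bundled mock is a pure function of the prompt,
which makes the whole extract pipeline deterministic and bit-reproducible;
the HTTP client requests temperature 0 and surfaces transport failures as a
distinct error type.

## Execution

Local execution parses Turtle with `rdflib` and runs its SPARQL engine;
remote execution speaks the SPARQL Protocol over HTTP POST via the standard
library, accepting JSON results with XML fallback. Both convert solutions
identically: one row per solution, the row being the *set* of normalized
values of its bound variables. Normalization: IRIs as full IRI strings,
literals by lexical form (datatype and language tag stripped,
case-sensitive), blank nodes relabeled `_:b0, _:b1, ...` in first-occurrence
order per table. Truncation by a configured result limit raises a warning;
there are no retries by default.

## Evaluation metric

Rows are value sets: column identity is ignored and duplicate values within
a row collapse, because row similarity is defined on sets of values.
Conventions the normalized-matching formula leaves open, fixed as package
policy: two empty tables score 1.0 (a correctly empty answer); one empty
table scores 0.0 (this one follows from the formula). The matching uses
`scipy`'s rectangular assignment solver; the total weight is unique among
maximizers, and the reported pair set is canonicalized (zero-weight pairs
omitted, lexicographically smallest maximizer chosen by greedy refinement
with solver feasibility checks) so reports are deterministic. Tables of up
to six rows are cross-checked against exhaustive enumeration over injective
assignments at 1e-12.

The metric's known limitation is preserved, not repaired: semantically
equivalent but lexically different values ("Mouse" vs "Mus musculus") score
zero. Score distributions are reported over five exact-boundary bins:
x=0, 0<x<0.5, x=0.5, 0.5<x<1.0, x=1.0.

## Synthetic data

The fixture generator materializes what the schema abstraction presumes:
n entries per subject root, each with the same triple structure — one minted
subject IRI, one `rdf:type` triple per root type, one triple per schema
edge. Object values are drawn reproducibly from per-variable pools when
given (pools smaller than the entry count make parameter filters selective
but typically non-empty, like benchmark questions) and synthesized as
`<variable>_<k>` otherwise; connector nodes become blank nodes. Output is
byte-deterministic for a given spec and seed.

What the generator does *not* emulate about real databases: multi-valued
predicates (one value per edge per entry), missing/optional properties,
shared objects across entries beyond pool collisions, and the vocabulary
drift between question phrasing and database terms. Passing tests therefore
demonstrate structural and semantic correctness of the pipeline —
generation, execution and scoring agree with independent oracles — not
extraction accuracy on real questions, which depends on the model behind
the client contract.

`oracle_answer` is the independent cross-check for the builder: it answers a
request by backtracking over plain triple lookups along schema paths,
applying parameters as exact term filters and deduplicating projected
solutions — no SPARQL anywhere on that path. Agreement between
`execute_local(build_query(...))` and `oracle_answer` on random
schema/graph/request triples is the package's central soundness property.

## Benchmark campaigns

Ground truth is stored as variables + parameters (the queries are derived
through the same builder, mirroring how expert benchmarks are constructed
with schema-based builders); a record may alternatively carry an explicit
expected table. A failed record — extraction, build or execution error —
scores 0 for table similarity and is flagged distinctly from a legitimate
empty-vs-empty comparison (which scores 1.0); it never aborts the campaign.
Reports carry per-record scores, arithmetic means, five-bin distributions
and run metadata (seed, mode, client id), and serialize to
byte-reproducible JSON. Paraphrase links between records are carried but
paraphrase generation itself is out of scope.

## Problem sizes and numerical choices

Randomized suites use small forests (up to ~3 levels, ≤3 children per node,
1–2 roots), 4-entry fixture graphs, tables up to 6×6 for exhaustive
matching checks, and hundreds of draws per property — sizes at which the
independent oracles (exhaustive assignment enumeration, per-variable
pattern unions, breadth-first depth) are exact and fast while still
exercising connectors, multi-root forests, both value typings and empty
results. Matching feasibility checks use a 1e-12 tolerance; scores are exact
rationals of small integers in the analytic tests. Degenerate inputs are
pinned by tests: empty tables, empty graphs, root-only schemas, requests
with parameters only, zero-weight similarity matrices.

## Known limitations

- The builder emits only SELECT DISTINCT queries over tree-shaped patterns;
  cross-root joins must be expressed through shared parameter values.
- The extraction prompt follows the four documented steps but is this
  package's own wording; hosted-model accuracy will vary with it.
- Remote execution trusts endpoint solution order and offers no paging;
  truncation is surfaced, not worked around.
- The metric is exact-match at the cell level by design; apply entity
  normalization upstream if semantic equivalence matters.
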