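"""Synthetic fixtures and benchmark campaigns.

This module makes the whole pipeline testable offline.  It can

* generate random schemas of the kind the schema model accepts (small
  forests with connectors, explanations and example values),
* materialize a Turtle graph that conforms to a schema — every entry follows
  the same triple structure, which is exactly the regularity the schema
  abstraction relies on,
* answer a query request by direct graph traversal (an oracle that never
  touches SPARQL, used to cross-check built queries end to end), and
* run scored benchmark campaigns: question/ground-truth records through
  extraction, query building, execution and the evaluation metric, with
  per-record scores, means and five-bin score distributions.

Everything is seeded and bit-reproducible with the deterministic mock
client.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import rdflib
import yaml

from .builder import QueryRequest, build_query, value_to_term
from .errors import SchemaError, SparqlForgeError
from .evaluation import (
    BIN_LABELS,
    ResultTable,
    score_distribution,
    set_jaccard,
    table_similarity,
)
from .execution import _BlankLabeler, _normalize_rdflib_term
from .extraction import LlmClient, extract
from .schema import (
    CONNECTOR,
    OBJECT,
    ROOT,
    PrefixMap,
    Schema,
    SchemaEdge,
    SchemaNode,
    path_to_root,
)

__all__ = [
    "FixtureSpec",
    "BenchmarkRecord",
    "RecordScore",
    "CampaignReport",
    "generate_fixture_graph",
    "oracle_answer",
    "make_random_schema",
    "make_value_pools",
    "make_random_request",
    "load_benchmark",
    "run_campaign",
]

_BASE = "http://example.org"


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic graph conforming to a schema."""

    schema: Schema
    n_entries: int
    seed: int = 0
    value_pools: dict[str, list[str]] | None = None

    def __post_init__(self):
        if self.n_entries < 1:
            raise ValueError("n_entries must be >= 1")
        for name, pool in (self.value_pools or {}).items():
            if not pool:
                raise ValueError(f"value pool for {name!r} is empty")


def _term_for_value(value: str, schema: Schema):
    """rdflib term for a lexical value, mirroring the builder's typing rule."""
    t = value_to_term(value, schema)
    if t.kind == "prefixed":
        return rdflib.URIRef(schema.prefixes.resolve(t.text))
    if t.kind == "iri":
        return rdflib.URIRef(t.text)
    return rdflib.Literal(t.text)


def _turtle_term(term) -> str:
    if isinstance(term, rdflib.URIRef):
        return f"<{term}>"
    if isinstance(term, rdflib.BNode):
        return f"_:{term}"
    escaped = str(term).replace("\\", "\\\\").replace('"', '\\"')
    return f'"{escaped}"'


def generate_fixture_graph(spec: FixtureSpec) -> str:
    """Emit a deterministic Turtle document with n_entries per subject root.

    Each entry gets a minted subject IRI, one rdf:type triple per root type,
    and one triple per schema edge.  Object values come from the variable's
    pool when one is given (drawn reproducibly from the seed) and are
    synthesized as ``<variable>_<k>`` otherwise; connector nodes become
    blank nodes shared by the edges passing through them.
    """
    schema = spec.schema
    rng = random.Random(spec.seed)
    pools = spec.value_pools or {}
    lines = []
    for k in range(spec.n_entries):
        for root in schema.roots:
            subject = rdflib.URIRef(f"{_BASE}/{schema.name}/{root}/{k}")
            terms: dict[str, object] = {root: subject}
            node = schema.node(root)
            for t in node.rdf_types:
                lines.append(
                    f"{_turtle_term(subject)} "
                    f"<http://www.w3.org/1999/02/22-rdf-syntax-ns#type> "
                    f"<{schema.prefixes.resolve(t)}> ."
                )
            for e in schema.edges:
                if e.parent not in terms:
                    continue
                if schema.is_connector(e.child):
                    obj = rdflib.BNode(f"{e.child}_{k}")
                elif any(x.parent == e.child for x in schema.edges):
                    # selectable intermediate: minted IRI, comparable across runs
                    obj = rdflib.URIRef(f"{_BASE}/{schema.name}/{e.child}/{k}")
                elif e.child in pools:
                    obj = _term_for_value(rng.choice(pools[e.child]), schema)
                else:
                    obj = _term_for_value(f"{e.child}_{k}", schema)
                terms[e.child] = obj
                pred = schema.prefixes.resolve(e.predicate)
                lines.append(
                    f"{_turtle_term(terms[e.parent])} <{pred}> {_turtle_term(obj)} ."
                )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# the traversal oracle
# ---------------------------------------------------------------------------


def oracle_answer(schema: Schema, request: QueryRequest, graph: str | rdflib.Graph
                  ) -> ResultTable:
    """Answer a request by direct traversal of the graph — no SPARQL involved.

    Enumerates bindings by walking schema paths with plain triple lookups,
    applies parameter bindings as exact term filters, projects the requested
    variables and deduplicates projected solutions, mirroring what a
    DISTINCT SELECT returns.
    """
    request.validate_against(schema)
    if isinstance(graph, rdflib.Graph):
        g = graph
    else:
        g = rdflib.Graph()
        g.parse(data=graph, format="turtle")
    needed = list(dict.fromkeys(
        list(request.variables) + [v for v, _ in request.parameters]))
    by_root: dict[str, list[str]] = {}
    for v in needed:
        by_root.setdefault(schema.root_of(v), []).append(v)

    solutions: list[dict[str, object]] = [{}]
    rdf_type = rdflib.URIRef("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
    for root in schema.roots:
        if root not in by_root:
            continue
        node = schema.node(root)
        type_iris = [rdflib.URIRef(schema.prefixes.resolve(t)) for t in node.rdf_types]
        subjects = sorted(
            {s for s in g.subjects(rdf_type, type_iris[0])
             if all((s, rdf_type, t) in g for t in type_iris[1:])},
            key=str,
        )
        solutions = [dict(sol, **{root: s}) for sol in solutions for s in subjects]
        wanted = {
            (e.parent, e.predicate, e.child)
            for v in by_root[root]
            for e in path_to_root(schema, v)
        }
        for e in schema.edges:
            if (e.parent, e.predicate, e.child) not in wanted:
                continue
            pred = rdflib.URIRef(schema.prefixes.resolve(e.predicate))
            extended = []
            for sol in solutions:
                for obj in sorted(g.objects(sol[e.parent], pred), key=str):
                    extended.append(dict(sol, **{e.child: obj}))
            solutions = extended

    # parameter filters: disjunction over the values bound to one variable
    allowed: dict[str, list] = {}
    for var, value in request.parameters:
        allowed.setdefault(var, []).append(_term_for_value(value, schema))
    for var, terms in allowed.items():
        solutions = [sol for sol in solutions if sol[var] in terms]

    select = request.variables or tuple(dict.fromkeys(v for v, _ in request.parameters))
    blanks = _BlankLabeler()
    seen: set[tuple] = set()
    rows: list[frozenset[str]] = []
    for sol in solutions:
        projected = tuple(
            _normalize_rdflib_term(sol[v], blanks) for v in select if v in sol
        )
        if projected in seen:
            continue
        seen.add(projected)
        rows.append(frozenset(projected))
    return ResultTable(rows=tuple(rows), origin="oracle")


# ---------------------------------------------------------------------------
# random schema / request generation
# ---------------------------------------------------------------------------


def make_random_schema(rng: random.Random, n_roots: int | None = None,
                       max_depth: int = 3, max_children: int = 3,
                       name: str = "synthetic") -> Schema:
    """A random small schema forest with occasional connectors and explanations."""
    n_roots = n_roots or rng.choice([1, 1, 1, 2])
    prefixes = PrefixMap({
        "ex": f"{_BASE}/ns/",
        "id": f"{_BASE}/id/",
    })
    nodes: list[SchemaNode] = []
    edges: list[SchemaEdge] = []
    roots: list[str] = []
    counter = [0]

    def fresh(stem: str) -> str:
        counter[0] += 1
        return f"{stem}{counter[0]}"

    def grow(parent: str, depth: int) -> None:
        for _ in range(rng.randint(1, max_children)):
            is_connector = depth < max_depth and rng.random() < 0.25
            child = fresh("hub" if is_connector else "var")
            if is_connector:
                nodes.append(SchemaNode(variable_name=child, kind=CONNECTOR))
            else:
                nodes.append(SchemaNode(
                    variable_name=child,
                    kind=OBJECT,
                    example_value=f"id:{child}_ex" if rng.random() < 0.5
                    else f"{child} sample",
                    explanation=f"Synthetic attribute {child}."
                    if rng.random() < 0.6 else None,
                ))
            edges.append(SchemaEdge(parent=parent, predicate=f"ex:{fresh('p')}",
                                    child=child))
            if is_connector:
                grow(child, depth + 1)

    for r in range(n_roots):
        root = fresh("Root")
        nodes.append(SchemaNode(
            variable_name=root, kind=ROOT,
            example_value=f"id:{root}_ex",
            rdf_types=(f"ex:Type{r}",),
            explanation=f"Synthetic entry identifier for {root}.",
        ))
        roots.append(root)
        grow(root, 1)
    return Schema(name=name, prefixes=prefixes, nodes=tuple(nodes),
                  edges=tuple(edges), roots=tuple(roots))


def _leaf_variables(schema: Schema) -> list[str]:
    have_children = {e.parent for e in schema.edges}
    return [n.variable_name for n in schema.nodes
            if n.kind != ROOT and n.variable_name not in have_children]


def make_value_pools(rng: random.Random, schema: Schema, pool_size: int = 3
                     ) -> dict[str, list[str]]:
    """Small per-leaf value pools mixing prefixed names and plain literals.

    Pools smaller than the entry count make parameter filters selective but
    usually non-empty, which is what benchmark questions look like.
    """
    pools = {}
    for name in _leaf_variables(schema):
        if rng.random() < 0.5:
            pools[name] = [f"id:{name}_{i}" for i in range(pool_size)]
        else:
            pools[name] = [f"{name} value {i}" for i in range(pool_size)]
    return pools


def make_random_request(rng: random.Random, schema: Schema,
                        pools: dict[str, list[str]] | None = None,
                        max_vars: int = 3) -> QueryRequest:
    """A random valid request: 1..max_vars selectable variables, maybe a filter."""
    selectable = [n.variable_name for n in schema.nodes
                  if not schema.is_connector(n.variable_name)]
    k = rng.randint(1, min(max_vars, len(selectable)))
    variables = tuple(rng.sample(selectable, k))
    parameters: list[tuple[str, str]] = []
    leaves = [v for v in _leaf_variables(schema) if pools and v in pools]
    if leaves and rng.random() < 0.7:
        var = rng.choice(leaves)
        parameters.append((var, rng.choice(pools[var])))
    return QueryRequest(variables=variables, parameters=tuple(parameters))


# ---------------------------------------------------------------------------
# benchmark records and campaigns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkRecord:
    """One question with its expert ground truth (variables + parameters)."""

    id: str
    question: str
    truth_variables: tuple[str, ...] = ()
    truth_parameters: tuple[tuple[str, str], ...] = ()
    expected_table: ResultTable | None = None
    paraphrase_of: str | None = None


def load_benchmark(text: str) -> list[BenchmarkRecord]:
    """Read a benchmark file (YAML or JSON) into records.

    Document shape: ``{records: [{id, question, truth_variables,
    truth_parameters, expected_rows?, paraphrase_of?}, ...]}`` where
    ``expected_rows`` is a list of lists of cell values.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "records" not in doc:
        raise SparqlForgeError("benchmark document must have a 'records' key")
    records = []
    ids = set()
    for raw in doc["records"]:
        rec = BenchmarkRecord(
            id=str(raw["id"]),
            question=str(raw["question"]),
            truth_variables=tuple(raw.get("truth_variables", ())),
            truth_parameters=tuple(
                (str(v), str(x)) for v, x in raw.get("truth_parameters", ())),
            expected_table=ResultTable.from_rows(raw["expected_rows"])
            if raw.get("expected_rows") is not None else None,
            paraphrase_of=raw.get("paraphrase_of"),
        )
        records.append(rec)
        ids.add(rec.id)
    for rec in records:
        if rec.paraphrase_of is not None and rec.paraphrase_of not in ids:
            raise SparqlForgeError(
                f"record {rec.id!r} paraphrases unknown record {rec.paraphrase_of!r}")
    return records


@dataclass(frozen=True)
class RecordScore:
    """Scores for one benchmark record."""

    id: str
    table_similarity: float
    variable_jaccard: float
    parameter_jaccard: float
    warnings: tuple[str, ...] = ()
    failed: bool = False
    error: str | None = None


@dataclass(frozen=True)
class CampaignReport:
    """Per-record scores plus aggregate means, bins and run metadata."""

    records: tuple[RecordScore, ...]
    means: dict[str, float]
    bins: dict[str, dict[str, int]]
    metadata: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "metadata": self.metadata,
            "means": self.means,
            "bins": self.bins,
            "records": [
                {
                    "id": r.id,
                    "table_similarity": r.table_similarity,
                    "variable_jaccard": r.variable_jaccard,
                    "parameter_jaccard": r.parameter_jaccard,
                    "warnings": list(r.warnings),
                    "failed": r.failed,
                    "error": r.error,
                }
                for r in self.records
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=2) + "\n"

    def to_text(self) -> str:
        """Plain-text summary: means line plus the five-bin distributions."""
        lines = [
            "metric                mean",
            f"table_similarity      {self.means['table_similarity']:.3f}",
            f"variable_jaccard      {self.means['variable_jaccard']:.3f}",
            f"parameter_jaccard     {self.means['parameter_jaccard']:.3f}",
            "",
            "bins: " + "  ".join(BIN_LABELS),
        ]
        for metric, counts in self.bins.items():
            joined = "  ".join(str(counts[b]) for b in BIN_LABELS)
            lines.append(f"{metric}: {joined}")
        return "\n".join(lines) + "\n"


def _mean(xs: list[float]) -> float:
    return sum(xs) / len(xs) if xs else 0.0


def run_campaign(records, schema: Schema, client: LlmClient, executor,
                 mode: str = "VwE", explanations=None, seed: int = 0
                 ) -> CampaignReport:
    """Score every record through the full pipeline; never abort on a record.

    *executor* maps query text to a :class:`ResultTable` (e.g. a closure
    over :func:`sparqlforge.execution.execute_local` with a fixture graph,
    or over ``execute_remote`` with an endpoint).  Ground-truth tables are
    obtained by building and executing the truth request, unless a record
    carries an explicit expected table.  A record whose extraction, build or
    execution fails scores 0 for table similarity and is flagged; it never
    stops the campaign.
    """
    scores: list[RecordScore] = []
    for rec in records:
        truth_request = QueryRequest(variables=rec.truth_variables,
                                     parameters=rec.truth_parameters)
        if rec.expected_table is not None:
            truth_table = rec.expected_table
        else:
            truth_table = executor(build_query(schema, truth_request).text)
        variable_j = 0.0
        parameter_j = 0.0
        warnings: tuple[str, ...] = ()
        try:
            result = extract(rec.question, schema, explanations=explanations,
                             client=client, mode=mode)
            variable_j = set_jaccard(result.variables, rec.truth_variables)
            parameter_j = set_jaccard(result.parameters, rec.truth_parameters)
            warnings = result.warnings
            generated = build_query(schema, QueryRequest(
                variables=result.variables, parameters=result.parameters))
            generated_table = executor(generated.text)
            scores.append(RecordScore(
                id=rec.id,
                table_similarity=table_similarity(truth_table, generated_table),
                variable_jaccard=variable_j,
                parameter_jaccard=parameter_j,
                warnings=warnings,
            ))
        except (SparqlForgeError, SchemaError) as exc:
            scores.append(RecordScore(
                id=rec.id, table_similarity=0.0,
                variable_jaccard=variable_j, parameter_jaccard=parameter_j,
                warnings=warnings, failed=True, error=str(exc),
            ))
    means = {
        "table_similarity": _mean([s.table_similarity for s in scores]),
        "variable_jaccard": _mean([s.variable_jaccard for s in scores]),
        "parameter_jaccard": _mean([s.parameter_jaccard for s in scores]),
    }
    bins = {
        metric: score_distribution([getattr(s, metric) for s in scores])
        for metric in ("table_similarity", "variable_jaccard", "parameter_jaccard")
    }
    metadata = {
        "seed": seed,
        "mode": mode,
        "client": getattr(client, "model_id", "unknown"),
        "n_records": len(scores),
        "n_failed": sum(1 for s in scores if s.failed),
    }
    return CampaignReport(records=tuple(scores), means=means, bins=bins,
                          metadata=metadata)
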