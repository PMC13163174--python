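"""Deterministic SPARQL SELECT construction from a schema and a request.

The builder is the rule-based half of the two-stage pipeline: given the
variables a user wants to retrieve and the parameters (variable, value)
constraining the search, it walks the schema forest from each root to the
needed variables, collects the property-path triple patterns, and renders a
syntactically valid SPARQL 1.1 SELECT query.  No language model is involved,
so the output is fully reproducible: byte-identical text for identical input.

Constraints are always expressed with VALUES blocks (one per constrained
variable, listing its values as a disjunction), never FILTER or inlined
constants.  Aggregations, OPTIONAL, UNION and REGEX are deliberately not
generated; the builder covers simple SELECT searches and leaves anything
richer to downstream post-processing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import QueryBuildError
from .schema import Schema, path_to_root

__all__ = [
    "QueryRequest",
    "TriplePattern",
    "SparqlQuery",
    "Term",
    "resolve_triple_patterns",
    "build_query",
    "render",
    "value_to_term",
]

_PREFIXED_VALUE_RE = re.compile(r"^([A-Za-z_][\w.\-]*):([A-Za-z0-9_.\-]+)$")
_ABS_IRI_VALUE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*://[^\s<>]+$")


@dataclass(frozen=True)
class QueryRequest:
    """Variables to retrieve plus parameter (variable, value) bindings."""

    variables: tuple[str, ...] = ()
    parameters: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(
            self, "parameters", tuple((v, str(x)) for v, x in self.parameters)
        )
        if not self.variables and not self.parameters:
            raise QueryBuildError("request must name at least one variable or parameter")
        if len(set(self.variables)) != len(self.variables):
            raise QueryBuildError("duplicate names in requested variables")

    def validate_against(self, schema: Schema) -> None:
        unknown = [v for v in self.variables if v not in schema]
        unknown += [v for v, _ in self.parameters if v not in schema and v not in unknown]
        if unknown:
            raise QueryBuildError(f"unknown variable(s) in request: {unknown}")


@dataclass(frozen=True)
class Term:
    """A constant RDF term in a query: prefixed name, IRI, or literal."""

    kind: str  # "prefixed" | "iri" | "literal"
    text: str  # prefixed name as written, IRI without brackets, or literal lexical form

    def sparql(self) -> str:
        if self.kind == "prefixed":
            return self.text
        if self.kind == "iri":
            return f"<{self.text}>"
        escaped = self.text.replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'


@dataclass(frozen=True)
class TriplePattern:
    """One WHERE-clause pattern; the object is a variable name or constant Term."""

    subject_var: str
    predicate: str  # prefixed name, absolute IRI, or "a"
    object_var_or_term: str | Term

    def sparql(self) -> str:
        obj = self.object_var_or_term
        obj_text = f"?{obj}" if isinstance(obj, str) else obj.sparql()
        pred = self.predicate
        if pred != "a" and _ABS_IRI_VALUE_RE.match(pred):
            pred = f"<{pred}>"
        return f"?{self.subject_var} {pred} {obj_text} ."


@dataclass(frozen=True)
class SparqlQuery:
    """Structured query plus its deterministic rendered text."""

    prefix_decls: tuple[tuple[str, str], ...]
    select_vars: tuple[str, ...]
    patterns: tuple[TriplePattern, ...]
    values_blocks: tuple[tuple[str, tuple[Term, ...]], ...]
    text: str = field(default="", compare=False)

    def to_record(self) -> dict:
        """Machine-readable export of the structured form."""
        return {
            "prefixes": [list(p) for p in self.prefix_decls],
            "select": list(self.select_vars),
            "patterns": [
                {
                    "subject": p.subject_var,
                    "predicate": p.predicate,
                    "object": p.object_var_or_term
                    if isinstance(p.object_var_or_term, str)
                    else {"kind": p.object_var_or_term.kind,
                          "text": p.object_var_or_term.text},
                }
                for p in self.patterns
            ],
            "values": [
                {"variable": v, "terms": [t.sparql() for t in terms]}
                for v, terms in self.values_blocks
            ],
            "text": self.text,
        }


def value_to_term(value: str, schema: Schema) -> Term:
    """Type a parameter value as written by the user or extractor.

    A value matching ``label:local`` with a declared prefix becomes a prefixed
    name; an ``http(s)://...``-style value becomes an IRI; a value wrapped in
    double quotes becomes a plain literal (quotes stripped); anything else is a
    plain literal.  A prefixed-name-shaped value whose label is undeclared is
    an error, since it would silently change meaning if emitted as a literal.
    """
    m = _PREFIXED_VALUE_RE.match(value)
    if m:
        if m.group(1) in schema.prefixes:
            return Term("prefixed", value)
        raise QueryBuildError(
            f"value {value!r} looks like a prefixed name but prefix "
            f"{m.group(1)!r} is not declared in the schema"
        )
    if _ABS_IRI_VALUE_RE.match(value):
        return Term("iri", value)
    if len(value) >= 2 and value.startswith('"') and value.endswith('"'):
        return Term("literal", value[1:-1])
    return Term("literal", value)


def resolve_triple_patterns(schema: Schema, needed: set[str] | list[str]
                            ) -> list[TriplePattern]:
    """Patterns for retrieving *needed* variables, in root-then-document order.

    For every root whose subtree contributes a needed variable: one rdf:type
    pattern per declared type, then the union of the edge patterns along each
    needed variable's path to that root, ordered as the edges appear in the
    schema document.  Connector variables appear as plain intermediate
    variables wherever a path passes through them.
    """
    needed = list(dict.fromkeys(needed))
    if not needed:
        raise QueryBuildError("needed variable set is empty")
    unknown = [v for v in needed if v not in schema]
    if unknown:
        raise QueryBuildError(f"unknown variable(s): {unknown}")
    by_root: dict[str, list[str]] = {}
    for v in needed:
        by_root.setdefault(schema.root_of(v), []).append(v)
    patterns: list[TriplePattern] = []
    for root in schema.roots:
        if root not in by_root:
            continue
        root_node = schema.node(root)
        for t in root_node.rdf_types:
            m = _PREFIXED_VALUE_RE.match(t)
            kind = "prefixed" if m and m.group(1) in schema.prefixes else "iri"
            patterns.append(TriplePattern(root, "a", Term(kind, t)))
        wanted_edges = {
            (e.parent, e.predicate, e.child)
            for v in by_root[root]
            for e in path_to_root(schema, v)
        }
        for e in schema.edges:
            if (e.parent, e.predicate, e.child) in wanted_edges:
                patterns.append(TriplePattern(e.parent, e.predicate, e.child))
    return patterns


def build_query(schema: Schema, request: QueryRequest) -> SparqlQuery:
    """Assemble the full SELECT query for a request against a schema.

    SELECT lists exactly the requested variables (DISTINCT always emitted);
    parameter variables are constrained via VALUES but not auto-selected.
    Only prefixes actually used by the query are declared, sorted by label.
    """
    request.validate_against(schema)
    needed = list(request.variables) + [v for v, _ in request.parameters]
    patterns = tuple(resolve_triple_patterns(schema, needed))

    values_order: list[str] = []
    values_map: dict[str, list[Term]] = {}
    for var, value in request.parameters:
        if var not in values_map:
            values_order.append(var)
            values_map[var] = []
        values_map[var].append(value_to_term(value, schema))
    values_blocks = tuple((v, tuple(values_map[v])) for v in values_order)

    used_labels: set[str] = set()

    def note(term: str | Term) -> None:
        if isinstance(term, Term):
            if term.kind != "prefixed":
                return
            term = term.text
        if term == "a" or _ABS_IRI_VALUE_RE.match(term):
            return
        label = term.split(":", 1)[0]
        if label in schema.prefixes:
            used_labels.add(label)

    for p in patterns:
        note(p.predicate)
        note(p.object_var_or_term)
    for _, terms in values_blocks:
        for t in terms:
            note(t)
    prefix_decls = tuple(
        (label, schema.prefixes[label]) for label in sorted(used_labels)
    )

    select_vars = tuple(request.variables) or tuple(values_order)
    query = SparqlQuery(
        prefix_decls=prefix_decls,
        select_vars=select_vars,
        patterns=patterns,
        values_blocks=values_blocks,
    )
    return SparqlQuery(
        prefix_decls=query.prefix_decls,
        select_vars=query.select_vars,
        patterns=query.patterns,
        values_blocks=query.values_blocks,
        text=render(query),
    )


def render(query: SparqlQuery) -> str:
    """Render the canonical text: PREFIX lines, SELECT DISTINCT, WHERE block.

    Total and deterministic on valid structures; VALUES blocks come last
    inside WHERE, one pattern per line, two-space indentation.
    """
    lines: list[str] = []
    for label, iri in query.prefix_decls:
        lines.append(f"PREFIX {label}: <{iri}>")
    if query.prefix_decls:
        lines.append("")
    select = " ".join(f"?{v}" for v in query.select_vars)
    lines.append(f"SELECT DISTINCT {select}")
    lines.append("WHERE {")
    for p in query.patterns:
        lines.append(f"  {p.sparql()}")
    for var, terms in query.values_blocks:
        rendered = " ".join(t.sparql() for t in terms)
        lines.append(f"  VALUES ?{var} {{ {rendered} }}")
    lines.append("}")
    return "\n".join(lines) + "\n"
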