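"""Schema model for RDF databases, in the style of curated query-builder configs.

A schema describes the common triple structure shared by every entry of an RDF
database as a small forest: each subject class is a *root* carrying one or more
``rdf:type`` terms, and each property path away from it introduces a named
variable.  Domain experts assign human-readable variable names (``UniProt``,
``uniprot_taxonomy``) and example values so that non-experts can pick what to
retrieve without reading the underlying RDF.  Intermediate nodes that exist only
to link paths together are *connectors*: they never surface in user-facing
variable lists and are resolved internally during query construction.

The YAML dialect accepted here (one document):

.. code-block:: yaml

    name: uniprot
    prefixes:
      up: <http://purl.uniprot.org/core/>
      taxonomy: <http://purl.uniprot.org/taxonomy/>
    model:
      - "UniProt up:Q9BYF1":
          - a: up:Protein
          - explanation: A protein entry accession.
          - up:organism:
              uniprot_taxonomy: taxonomy:9606
          - up:citation:
              uniprot_citation: citation:15174051

Each ``model`` item is a subject block whose header string is
``"<VariableName> <example>"`` (the example is optional).  Entries are
one-key mappings: ``a:`` declares an rdf:type (roots need at least one),
``explanation:`` / ``selectable:`` annotate the current node, and
``<predicate>:`` introduces either an object leaf (nested one-key mapping
``variable_name: example``, optionally with ``explanation`` / ``selectable``
side keys) or a connector subtree (a nested list whose first item declares the
connector variable and whose remaining items are entries).

This dialect is a deliberate, documented subset of the upstream schema
grammar; anything outside it is rejected with a precise error rather than
guessed at.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import yaml

from .errors import SchemaError

__all__ = [
    "PrefixMap",
    "SchemaNode",
    "SchemaEdge",
    "Schema",
    "VariableDescription",
    "parse_schema",
    "render_schema",
    "list_selectable_variables",
    "merge_schemas",
    "path_to_root",
]

# Node kinds
ROOT = "subject-root"
OBJECT = "object"
CONNECTOR = "connector"

_IDENT_RE = re.compile(r"^[^\W\d]\w*$", re.UNICODE)
# Absolute IRI: a scheme followed by ":", no whitespace or angle brackets.
_ABS_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.\-]*:[^\s<>]*$")
_PREFIXED_RE = re.compile(r"^([A-Za-z_][\w.\-]*):([^\s/][^\s]*)$")

_RESERVED_ENTRY_KEYS = frozenset({"a", "explanation", "selectable"})
_RESERVED_LEAF_KEYS = frozenset({"explanation", "selectable"})


def is_identifier(name: str) -> bool:
    """True when *name* is usable verbatim as a SPARQL variable name."""
    return bool(_IDENT_RE.match(name))


@dataclass(frozen=True)
class PrefixMap:
    """Mapping from prefix label to absolute namespace IRI.

    The label ``a`` is reserved (rdf:type shorthand) and may not be declared.
    """

    entries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for label, iri in self.entries.items():
            if label == "a":
                raise SchemaError("prefix label 'a' is reserved for rdf:type")
            if not _ABS_IRI_RE.match(iri):
                raise SchemaError(
                    f"namespace for prefix '{label}' is not an absolute IRI: {iri!r}"
                )

    def __contains__(self, label: str) -> bool:
        return label in self.entries

    def __getitem__(self, label: str) -> str:
        return self.entries[label]

    def resolve(self, term: str) -> str:
        """Expand a prefixed name or pass through an absolute IRI.

        Raises :class:`SchemaError` for a prefixed name whose label is not
        declared, or for a term that is neither.
        """
        if term == "a":
            return "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
        m = _PREFIXED_RE.match(term)
        if m and m.group(1) in self.entries:
            return self.entries[m.group(1)] + m.group(2)
        if m:
            raise SchemaError(f"undeclared prefix '{m.group(1)}' in term {term!r}")
        if _ABS_IRI_RE.match(term):
            return term
        raise SchemaError(f"term {term!r} is neither a prefixed name nor an absolute IRI")

    def is_resolvable(self, term: str) -> bool:
        try:
            self.resolve(term)
            return True
        except SchemaError:
            return False


@dataclass(frozen=True)
class SchemaNode:
    """One named variable in the schema tree."""

    variable_name: str
    kind: str  # ROOT, OBJECT or CONNECTOR
    example_value: str | None = None
    rdf_types: tuple[str, ...] = ()
    explanation: str | None = None
    selectable_flag: bool = False  # explicit `selectable: true` override

    def __post_init__(self):
        if not is_identifier(self.variable_name):
            raise SchemaError(
                f"variable name {self.variable_name!r} is not a valid identifier"
            )
        if self.kind not in (ROOT, OBJECT, CONNECTOR):
            raise SchemaError(f"unknown node kind {self.kind!r}")
        if self.kind == ROOT and not self.rdf_types:
            raise SchemaError(
                f"subject-root {self.variable_name!r} declares no rdf:type"
            )
        if self.kind != ROOT and self.rdf_types:
            raise SchemaError(
                f"non-root node {self.variable_name!r} may not declare rdf:type"
            )
        if self.example_value is not None and self.example_value == "":
            raise SchemaError(
                f"example value for {self.variable_name!r} must be non-empty when given"
            )


@dataclass(frozen=True)
class SchemaEdge:
    """A predicate linking a parent variable to a child variable."""

    parent: str
    predicate: str
    child: str


@dataclass(frozen=True)
class Schema:
    """A validated forest of named variables describing one (or more) databases."""

    name: str
    prefixes: PrefixMap
    nodes: tuple[SchemaNode, ...]
    edges: tuple[SchemaEdge, ...]
    roots: tuple[str, ...]

    def __post_init__(self):
        names = [n.variable_name for n in self.nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise SchemaError(f"duplicate variable name(s): {sorted(dupes)}")
        name_set = set(names)
        if not self.roots:
            raise SchemaError("schema has no subject-root")
        for e in self.edges:
            if e.parent not in name_set or e.child not in name_set:
                raise SchemaError(f"edge {e} references unknown variable")
            if not self.prefixes.is_resolvable(e.predicate):
                raise SchemaError(f"predicate {e.predicate!r} is not resolvable")
        # forest: every non-root has exactly one parent, no cycles, all reachable
        parent_of: dict[str, str] = {}
        for e in self.edges:
            if e.child in parent_of:
                raise SchemaError(f"variable {e.child!r} has multiple parents")
            parent_of[e.child] = e.parent
        for r in self.roots:
            if r in parent_of:
                raise SchemaError(f"root {r!r} has a parent edge")
        if len(self.nodes) != len(self.edges) + len(self.roots):
            raise SchemaError("schema is not a forest (node/edge/root count mismatch)")
        reachable = set(self.roots)
        frontier = list(self.roots)
        children = self.children_map()
        while frontier:
            v = frontier.pop()
            for c in children.get(v, ()):
                if c in reachable:
                    raise SchemaError(f"cycle detected at variable {c!r}")
                reachable.add(c)
                frontier.append(c)
        if reachable != name_set:
            raise SchemaError(
                f"unreachable variable(s): {sorted(name_set - reachable)}"
            )

    # -- lookups -----------------------------------------------------------

    def node(self, name: str) -> SchemaNode:
        for n in self.nodes:
            if n.variable_name == name:
                return n
        raise SchemaError(f"unknown variable {name!r}")

    def __contains__(self, name: str) -> bool:
        return any(n.variable_name == name for n in self.nodes)

    def children_map(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for e in self.edges:
            out.setdefault(e.parent, []).append(e.child)
        return out

    def parent_edge(self, name: str) -> SchemaEdge | None:
        for e in self.edges:
            if e.child == name:
                return e
        return None

    def root_of(self, name: str) -> str:
        """The subject-root whose subtree contains *name*."""
        cur = name
        seen = {cur}
        while True:
            e = self.parent_edge(cur)
            if e is None:
                return cur
            cur = e.parent
            if cur in seen:  # pragma: no cover - excluded by forest invariant
                raise SchemaError("cycle")
            seen.add(cur)

    def is_connector(self, name: str) -> bool:
        """A non-root node with children and no explicit ``selectable: true``."""
        node = self.node(name)
        if node.kind == ROOT:
            return False
        has_children = any(e.parent == name for e in self.edges)
        return has_children and not node.selectable_flag


@dataclass(frozen=True)
class VariableDescription:
    """One line of the variables-info listing shown to the extractor."""

    name: str
    example: str
    explanation: str


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _strip_angle(iri) -> str:
    s = str(iri).strip()
    if s.startswith("<") and s.endswith(">"):
        s = s[1:-1]
    return s


def _scalar(value) -> str | None:
    if value is None:
        return None
    s = str(value)
    return s if s != "" else None


def _parse_header(header: str) -> tuple[str, str | None]:
    parts = str(header).split(None, 1)
    if not parts or not is_identifier(parts[0]):
        raise SchemaError(f"malformed subject header {header!r}")
    example = parts[1].strip() if len(parts) > 1 else None
    return parts[0], example or None


class _Builder:
    """Accumulates nodes/edges in document order during parsing."""

    def __init__(self, prefixes: PrefixMap):
        self.prefixes = prefixes
        self.nodes: list[SchemaNode] = []
        self.edges: list[SchemaEdge] = []
        self.roots: list[str] = []

    def _parse_leaf(self, parent: str, predicate: str, mapping: dict) -> None:
        var_keys = [k for k in mapping if k not in _RESERVED_LEAF_KEYS]
        if len(var_keys) != 1:
            raise SchemaError(
                f"object under predicate {predicate!r} must declare exactly one "
                f"variable, got keys {sorted(map(str, mapping))}"
            )
        name = str(var_keys[0])
        self.nodes.append(
            SchemaNode(
                variable_name=name,
                kind=OBJECT,
                example_value=_scalar(mapping[var_keys[0]]),
                explanation=_scalar(mapping.get("explanation")),
                selectable_flag=bool(mapping.get("selectable", False)),
            )
        )
        self._check_predicate(predicate)
        self.edges.append(SchemaEdge(parent=parent, predicate=predicate, child=name))

    def _check_predicate(self, predicate: str) -> None:
        if not self.prefixes.is_resolvable(predicate):
            raise SchemaError(f"predicate {predicate!r} uses an undeclared prefix")

    def _parse_entries(self, owner: str, entries, *, is_root: bool) -> SchemaNode:
        """Parse the entry list of a subject block or connector subtree.

        Returns the (re-built) owner node with its annotations applied; the
        owner is expected to already occupy a slot in ``self.nodes``.
        """
        if not isinstance(entries, list):
            raise SchemaError(f"entries of {owner!r} must be a list")
        rdf_types: list[str] = []
        explanation: str | None = None
        selectable = False
        for entry in entries:
            if not isinstance(entry, dict) or len(entry) != 1:
                raise SchemaError(
                    f"entry under {owner!r} must be a one-key mapping, got {entry!r}"
                )
            (key, value), = entry.items()
            key = str(key)
            if key == "a":
                if not is_root:
                    raise SchemaError(
                        f"rdf:type entry not allowed on non-root {owner!r}"
                    )
                t = _scalar(value)
                t = _strip_angle(t) if t is not None else None
                if t is None or not self.prefixes.is_resolvable(t):
                    raise SchemaError(f"unresolvable rdf:type {value!r} on {owner!r}")
                rdf_types.append(t)
            elif key == "explanation":
                explanation = _scalar(value)
            elif key == "selectable":
                selectable = bool(value)
            elif isinstance(value, dict):
                self._parse_leaf(owner, key, value)
            elif isinstance(value, list):
                self._parse_connector(owner, key, value)
            else:
                raise SchemaError(
                    f"entry {key!r} under {owner!r} must map to an object or subtree"
                )
        idx = next(
            i for i, n in enumerate(self.nodes) if n.variable_name == owner
        )
        old = self.nodes[idx]
        rebuilt = SchemaNode(
            variable_name=old.variable_name,
            kind=old.kind,
            example_value=old.example_value,
            rdf_types=tuple(rdf_types) if is_root else (),
            explanation=explanation,
            selectable_flag=selectable,
        )
        self.nodes[idx] = rebuilt
        return rebuilt

    def _parse_connector(self, parent: str, predicate: str, items: list) -> None:
        if not items:
            raise SchemaError(
                f"connector subtree under predicate {predicate!r} is empty"
            )
        head = items[0]
        if not isinstance(head, dict) or len(head) != 1:
            raise SchemaError(
                f"first item of connector subtree under {predicate!r} must declare "
                "the connector variable as a one-key mapping"
            )
        (name_key, example), = head.items()
        name = str(name_key)
        self.nodes.append(
            SchemaNode(variable_name=name, kind=CONNECTOR, example_value=_scalar(example))
        )
        self._check_predicate(predicate)
        self.edges.append(SchemaEdge(parent=parent, predicate=predicate, child=name))
        self._parse_entries(name, items[1:], is_root=False)

    def parse_subject(self, block: dict) -> None:
        if not isinstance(block, dict) or len(block) != 1:
            raise SchemaError(f"model item must be a one-key subject block: {block!r}")
        (header, entries), = block.items()
        name, example = _parse_header(header)
        self.nodes.append(SchemaNode(
            variable_name=name, kind=ROOT, example_value=example,
            rdf_types=("placeholder",),  # replaced by _parse_entries
        ))
        self.roots.append(name)
        node = self._parse_entries(name, entries, is_root=True)
        if not node.rdf_types:
            raise SchemaError(f"subject-root {name!r} declares no rdf:type ('a:' entry)")


def parse_schema(yaml_text: str) -> Schema:
    """Parse one YAML schema document into a validated :class:`Schema`.

    Node and edge order follow document order, so parsing is deterministic.
    Raises :class:`SchemaError` for anything outside the documented dialect.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"not well-formed YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("schema document must be a YAML mapping")
    unknown = set(doc) - {"name", "prefixes", "model"}
    if unknown:
        raise SchemaError(f"unknown top-level key(s): {sorted(unknown)}")
    name = str(doc.get("name") or "schema")
    raw_prefixes = doc.get("prefixes") or {}
    if not isinstance(raw_prefixes, dict):
        raise SchemaError("'prefixes' must be a mapping")
    prefixes = PrefixMap({str(k): _strip_angle(v) for k, v in raw_prefixes.items()})
    model = doc.get("model")
    if not isinstance(model, list) or not model:
        raise SchemaError("'model' must be a non-empty list of subject blocks")
    builder = _Builder(prefixes)
    for block in model:
        builder.parse_subject(block)
    return Schema(
        name=name,
        prefixes=prefixes,
        nodes=tuple(builder.nodes),
        edges=tuple(builder.edges),
        roots=tuple(builder.roots),
    )


# ---------------------------------------------------------------------------
# canonical serialization (round-trip partner of parse_schema)
# ---------------------------------------------------------------------------


def _node_entries(schema: Schema, name: str) -> list:
    node = schema.node(name)
    entries: list = []
    for t in node.rdf_types:
        entries.append({"a": t})
    if node.explanation is not None:
        entries.append({"explanation": node.explanation})
    if node.selectable_flag:
        entries.append({"selectable": True})
    for e in schema.edges:
        if e.parent != name:
            continue
        child = schema.node(e.child)
        if child.kind == CONNECTOR:
            sub = [{child.variable_name: child.example_value}]
            sub.extend(_node_entries(schema, child.variable_name))
            entries.append({e.predicate: sub})
        else:
            leaf: dict = {child.variable_name: child.example_value}
            if child.explanation is not None:
                leaf["explanation"] = child.explanation
            if child.selectable_flag:
                leaf["selectable"] = True
            entries.append({e.predicate: leaf})
    return entries


def render_schema(schema: Schema) -> str:
    """Serialize a schema back to the YAML dialect accepted by parse_schema.

    ``parse_schema(render_schema(s))`` is structurally the identity.
    """
    doc: dict = {"name": schema.name}
    if schema.prefixes.entries:
        doc["prefixes"] = {k: f"<{v}>" for k, v in schema.prefixes.entries.items()}
    model = []
    for root in schema.roots:
        node = schema.node(root)
        header = root if node.example_value is None else f"{root} {node.example_value}"
        model.append({header: _node_entries(schema, root)})
    doc["model"] = model
    return yaml.safe_dump(doc, sort_keys=False, indent=2, allow_unicode=True,
                          default_flow_style=False)


# ---------------------------------------------------------------------------
# derived listings and traversal
# ---------------------------------------------------------------------------


def list_selectable_variables(
    schema: Schema, explanations: dict[str, str] | None = None
) -> list[VariableDescription]:
    """All non-connector variables in document order, with example + explanation.

    *explanations* overrides/extends the explanations embedded in the schema;
    its keys must name schema variables.  Connector variables are excluded:
    they only link paths and are resolved internally by the query builder.
    """
    explanations = dict(explanations or {})
    unknown = [k for k in explanations if k not in schema]
    if unknown:
        raise SchemaError(f"explanation(s) for unknown variable(s): {sorted(unknown)}")
    out = []
    for node in schema.nodes:
        name = node.variable_name
        if schema.is_connector(name):
            continue
        explanation = explanations.get(name, node.explanation or "")
        out.append(VariableDescription(
            name=name,
            example=node.example_value or "",
            explanation=explanation,
        ))
    return out


def merge_schemas(schemas: list[Schema]) -> Schema:
    """Concatenate disjoint schemas into one forest (cross-database setting).

    Variable names must be disjoint; prefix labels may repeat only when they
    map to the same IRI.
    """
    if not schemas:
        raise SchemaError("merge_schemas requires at least one schema")
    if len(schemas) == 1:
        return schemas[0]
    prefixes: dict[str, str] = {}
    seen: set[str] = set()
    for s in schemas:
        for n in s.nodes:
            if n.variable_name in seen:
                raise SchemaError(
                    f"variable name collision on merge: {n.variable_name!r}"
                )
            seen.add(n.variable_name)
        for label, iri in s.prefixes.entries.items():
            if label in prefixes and prefixes[label] != iri:
                raise SchemaError(
                    f"prefix label conflict on merge: {label!r} maps to both "
                    f"{prefixes[label]!r} and {iri!r}"
                )
            prefixes[label] = iri
    return Schema(
        name="+".join(s.name for s in schemas),
        prefixes=PrefixMap(prefixes),
        nodes=tuple(n for s in schemas for n in s.nodes),
        edges=tuple(e for s in schemas for e in s.edges),
        roots=tuple(r for s in schemas for r in s.roots),
    )


def path_to_root(schema: Schema, variable: str) -> list[SchemaEdge]:
    """The unique edge sequence from the variable's root down to the variable.

    Empty when *variable* is itself a root.
    """
    if variable not in schema:
        raise SchemaError(f"unknown variable {variable!r}")
    edges: list[SchemaEdge] = []
    cur = variable
    while True:
        e = schema.parent_edge(cur)
        if e is None:
            break
        edges.append(e)
        cur = e.parent
    edges.reverse()
    return edges
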