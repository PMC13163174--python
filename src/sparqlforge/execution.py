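"""Query execution against a remote SPARQL endpoint or a local Turtle graph.

Both paths converge on the same conversion: each solution (binding set)
becomes one row — the set of normalized cell values of its bound variables —
and solution order is preserved.  Normalization policy: IRIs compare as full
IRI strings, literals by lexical form with datatype and language tag
stripped, case-sensitive; blank nodes are relabeled to a stable per-table
sequence (``_:b0``, ``_:b1``, ...) in first-occurrence order so equal
structures compare equal across runs.

The remote path speaks the SPARQL Protocol over HTTP POST and parses the
standard results serializations (JSON preferred, XML fallback).  Transport
failures, HTTP error statuses, timeouts and malformed result documents are
surfaced as distinct error kinds.  No retries by default: reproducibility
over robustness.
"""

from __future__ import annotations

import json
import socket
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Callable

import rdflib

from .errors import (
    ExecutionTimeoutError,
    HttpStatusError,
    MalformedResultsError,
    TransportError,
)
from .evaluation import ResultTable

__all__ = [
    "EndpointConfig",
    "execute_remote",
    "execute_local",
    "bindings_to_table",
]

_SRX_NS = "{http://www.w3.org/2005/sparql-results#}"

# transport: (url, form_data, headers, timeout) -> (content_type, body_bytes)
Transport = Callable[[str, bytes, dict, float], tuple[str, bytes]]


@dataclass(frozen=True)
class EndpointConfig:
    """Where and how to reach a SPARQL endpoint."""

    url: str
    timeout: float = 60.0
    limit: int | None = None
    headers: dict = field(default_factory=dict)

    def __post_init__(self):
        parsed = urllib.parse.urlparse(self.url)
        if parsed.scheme not in ("http", "https") or not parsed.netloc:
            raise ValueError(f"endpoint url is not a valid HTTP(S) IRI: {self.url!r}")
        if self.timeout <= 0:
            raise ValueError("timeout must be positive")
        if self.limit is not None and self.limit <= 0:
            raise ValueError("limit must be positive when given")


class _BlankLabeler:
    """Stable per-table labels for blank nodes, in first-occurrence order."""

    def __init__(self):
        self._labels: dict[str, str] = {}

    def __call__(self, key: str) -> str:
        if key not in self._labels:
            self._labels[key] = f"_:b{len(self._labels)}"
        return self._labels[key]


def _normalize_rdflib_term(term, blanks: _BlankLabeler) -> str:
    if isinstance(term, rdflib.BNode):
        return blanks(str(term))
    if isinstance(term, rdflib.Literal):
        return str(term)  # lexical form; datatype/lang dropped
    return str(term)


def bindings_to_table(
    solutions: list[dict[str, dict]], origin: str | None = None
) -> ResultTable:
    """Convert SPARQL-results-style binding dicts into a ResultTable.

    Each solution maps variable name -> {"type": iri|literal|bnode,
    "value": lexical}; unbound variables are simply absent.
    """
    blanks = _BlankLabeler()
    rows = []
    for sol in solutions:
        cells = set()
        for binding in sol.values():
            kind = binding.get("type", "literal")
            value = binding["value"]
            if kind in ("bnode", "blank"):
                value = blanks(value)
            cells.add(str(value))
        rows.append(frozenset(cells))
    return ResultTable(rows=tuple(rows), origin=origin)


# ---------------------------------------------------------------------------
# results-document parsing
# ---------------------------------------------------------------------------


def _parse_json_results(body: bytes) -> list[dict[str, dict]]:
    try:
        doc = json.loads(body.decode("utf-8"))
        return list(doc["results"]["bindings"])
    except (ValueError, KeyError, TypeError, UnicodeDecodeError) as exc:
        raise MalformedResultsError(f"bad SPARQL JSON results: {exc}") from exc


def _parse_xml_results(body: bytes) -> list[dict[str, dict]]:
    try:
        root = ET.fromstring(body)
        solutions = []
        for result in root.iter(f"{_SRX_NS}result"):
            sol: dict[str, dict] = {}
            for b in result.findall(f"{_SRX_NS}binding"):
                name = b.attrib["name"]
                child = list(b)[0]
                tag = child.tag.removeprefix(_SRX_NS)
                kind = {"uri": "iri", "literal": "literal", "bnode": "bnode"}[tag]
                sol[name] = {"type": kind, "value": child.text or ""}
            solutions.append(sol)
        return solutions
    except (ET.ParseError, KeyError, IndexError) as exc:
        raise MalformedResultsError(f"bad SPARQL XML results: {exc}") from exc


def _default_transport(url: str, data: bytes, headers: dict, timeout: float
                       ) -> tuple[str, bytes]:
    req = urllib.request.Request(url, data=data, headers=headers, method="POST")
    try:
        with urllib.request.urlopen(req, timeout=timeout) as resp:
            return resp.headers.get("Content-Type", ""), resp.read()
    except urllib.error.HTTPError as exc:
        raise HttpStatusError(exc.code, exc.reason or "") from exc
    except (socket.timeout, TimeoutError) as exc:
        raise ExecutionTimeoutError(f"endpoint timed out after {timeout}s") from exc
    except urllib.error.URLError as exc:
        if isinstance(exc.reason, (socket.timeout, TimeoutError)):
            raise ExecutionTimeoutError(
                f"endpoint timed out after {timeout}s") from exc
        raise TransportError(f"cannot reach endpoint: {exc.reason}") from exc


def execute_remote(
    query_text: str,
    endpoint: EndpointConfig,
    transport: Transport | None = None,
    origin: str | None = None,
) -> ResultTable:
    """POST a query per the SPARQL Protocol and convert the bindings.

    *transport* is injectable for testing; the default uses urllib.  When a
    configured result limit is reached exactly, a truncation warning is
    attached nowhere silent — it is raised as a logged warning on stderr via
    the warnings machinery.
    """
    if not query_text.strip():
        raise ValueError("query_text is empty")
    transport = transport or _default_transport
    text = query_text
    if endpoint.limit is not None:
        text = f"{text.rstrip()}\nLIMIT {endpoint.limit}\n"
    data = urllib.parse.urlencode({"query": text}).encode("utf-8")
    headers = {
        "Accept": ("application/sparql-results+json, "
                   "application/sparql-results+xml;q=0.9"),
        "Content-Type": "application/x-www-form-urlencoded",
        **endpoint.headers,
    }
    content_type, body = transport(endpoint.url, data, headers, endpoint.timeout)
    if "json" in content_type:
        solutions = _parse_json_results(body)
    elif "xml" in content_type:
        solutions = _parse_xml_results(body)
    else:
        # sniff: endpoints are sloppy about content types
        stripped = body.lstrip()
        if stripped.startswith(b"{"):
            solutions = _parse_json_results(body)
        elif stripped.startswith(b"<"):
            solutions = _parse_xml_results(body)
        else:
            raise MalformedResultsError(
                f"unrecognized results content type {content_type!r}")
    if endpoint.limit is not None and len(solutions) >= endpoint.limit:
        import warnings

        warnings.warn(
            f"endpoint returned {len(solutions)} solutions at the configured "
            f"limit {endpoint.limit}; results may be truncated",
            stacklevel=2,
        )
    return bindings_to_table(solutions, origin=origin)


def execute_local(query_text: str, graph_source: str | rdflib.Graph,
                  origin: str | None = None) -> ResultTable:
    """Evaluate a query in-process over a Turtle document or parsed graph.

    Produces the same ResultTable conversion as :func:`execute_remote`, so
    local fixtures can stand in for endpoints in tests and benchmarks.
    """
    if isinstance(graph_source, rdflib.Graph):
        graph = graph_source
    else:
        graph = rdflib.Graph()
        graph.parse(data=graph_source, format="turtle")
    result = graph.query(query_text)
    blanks = _BlankLabeler()
    rows = []
    for binding_row in result:
        cells = set()
        for term in binding_row:
            if term is None:
                continue
            cells.add(_normalize_rdflib_term(term, blanks))
        rows.append(frozenset(cells))
    return ResultTable(rows=tuple(rows), origin=origin)
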