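"""Exception hierarchy shared across the package.

Every error raised deliberately by sparqlforge derives from
:class:`SparqlForgeError`, so callers can catch one type at a pipeline
boundary while tests can still assert on the precise kind.
"""


class SparqlForgeError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SparqlForgeError):
    """A schema document violates the dialect or its structural invariants."""


class QueryBuildError(SparqlForgeError):
    """A query request cannot be satisfied against the given schema."""


class ExtractionError(SparqlForgeError):
    """The language-model output could not be parsed or validated."""


class UnknownVariableError(ExtractionError):
    """The model named variables that do not exist in the schema."""

    def __init__(self, names: list[str]):
        self.names = list(names)
        super().__init__(f"unknown variable name(s): {', '.join(self.names)}")


class LlmTransportError(SparqlForgeError):
    """A network-backed language-model client failed at the transport level."""


class ExecutionError(SparqlForgeError):
    """Base class for SPARQL execution failures."""


class TransportError(ExecutionError):
    """The endpoint could not be reached (connection-level failure)."""


class HttpStatusError(ExecutionError):
    """The endpoint answered with a non-success HTTP status."""

    def __init__(self, status: int, message: str = ""):
        self.status = status
        super().__init__(f"HTTP {status}: {message}" if message else f"HTTP {status}")


class ExecutionTimeoutError(ExecutionError):
    """The request exceeded the configured timeout."""


class MalformedResultsError(ExecutionError):
    """The results document could not be parsed as SPARQL JSON/XML results."""
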