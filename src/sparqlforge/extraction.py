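"""Slot extraction: turning a natural-language question into a query request.

The language model's only job in this pipeline is word selection: pick the
schema variables a question asks for, and copy the constraining values out of
the question text to form parameters.  The model never sees SPARQL and never
invents graph structure, which is what keeps structural hallucination out of
the generated queries.

The prompt shows the model a listing of the schema's selectable variables
(connector variables are excluded — the builder resolves those internally)
and walks it through four chain-of-thought steps:

1. Extracting User Requests — keywords reflecting what the user wants back;
2. Converting User Request to Variables — map those keywords to variable names;
3. Extracting User-Specified Condition — the filter conditions in the question;
4. Converting Conditions to Parameters — (variable, value) pairs for each.

The model must finish with a fenced block tagged ``answer`` containing one
JSON object ``{"variables": [...], "parameters": [[name, value], ...]}``;
JSON keeps parameter values byte-exact through the round trip.  Three
presentation modes for the variable listing are supported: names with
examples and explanations (VwE, the default), names with examples only
(VwoE), and the raw schema text itself (VinS).

Extraction output is validated hard: a variable name absent from the schema
is an error, never silently dropped or fuzzily matched, so model-induced
mistakes stay isolated from builder correctness.  A separate advisory guard
flags parameter values that are not verbatim substrings of the question —
the typical copy hallucination (e.g. "=" drifting to "=>").
"""

from __future__ import annotations

import json
import re
import urllib.error
import urllib.request
from dataclasses import dataclass
from typing import Callable, Mapping, Protocol

from .errors import ExtractionError, LlmTransportError, UnknownVariableError
from .schema import Schema, VariableDescription, list_selectable_variables, render_schema

__all__ = [
    "PromptBundle",
    "ExtractionResult",
    "LlmClient",
    "MockLlmClient",
    "HttpLlmClient",
    "MODES",
    "format_variables_info",
    "build_extraction_prompt",
    "parse_extraction_output",
    "serialize_extraction_result",
    "check_strict_copy",
    "extract",
]

MODES = ("VwE", "VwoE", "VinS")

DEFAULT_SYSTEM_TEXT = (
    "You are an assistant that maps natural-language questions over a "
    "biological RDF database onto the variables of a predefined schema. "
    "You select variable names from the provided list and copy condition "
    "values verbatim from the question. You never write SPARQL."
)

STEP_HEADINGS = (
    "Step 1. Extracting User Requests",
    "Step 2. Converting User Request to Variables",
    "Step 3. Extracting User-Specified Condition",
    "Step 4. Converting Conditions to Parameters",
)

DEFAULT_USER_TEMPLATE = """\
Answer the user's question by selecting variables and parameters from the
database schema variables listed below.

Available variables:
{variables_info}

User question:
{user_question}

Work through the following four steps, writing your reasoning under each
heading in order.

Step 1. Extracting User Requests
Identify the keywords in the question that reflect what the user wants to
retrieve.

Step 2. Converting User Request to Variables
Map the extracted keywords to variable names from the list above. Use only
names that appear in the list.

Step 3. Extracting User-Specified Condition
Identify the filter conditions the question imposes on the data.

Step 4. Converting Conditions to Parameters
Map each condition to a variable name and copy its value exactly as written
in the question, forming (variable, value) pairs.

Finish with exactly one fenced block tagged `answer` containing a single
JSON object with keys "variables" (list of variable names) and "parameters"
(list of [variable, value] pairs), for example:

```answer
{{"variables": ["example_variable"], "parameters": [["other_variable", "value"]]}}
```
"""

_ANSWER_BLOCK_RE = re.compile(r"```answer\s*\n(.*?)```", re.DOTALL)


@dataclass(frozen=True)
class PromptBundle:
    """System and user messages with both template slots substituted."""

    system_text: str
    user_text: str


@dataclass(frozen=True)
class ExtractionResult:
    """Validated variables and parameters plus the verbatim reasoning trace."""

    variables: tuple[str, ...]
    parameters: tuple[tuple[str, str], ...]
    trace: str = ""
    warnings: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "parameters",
                           tuple((str(v), str(x)) for v, x in self.parameters))
        for _, value in self.parameters:
            if value == "":
                raise ExtractionError("parameter value must be non-empty")


class LlmClient(Protocol):
    """Contract every language-model backend satisfies."""

    model_id: str
    temperature: float

    def complete(self, prompt: PromptBundle) -> str: ...


@dataclass
class MockLlmClient:
    """Deterministic offline client: a pure function of the prompt.

    *script* is either a fixed response string, a mapping from question text
    to response (matched by substring of the user message), or a callable
    receiving the bundle.
    """

    script: str | Mapping[str, str] | Callable[[PromptBundle], str]
    model_id: str = "mock"
    temperature: float = 0.0

    def complete(self, prompt: PromptBundle) -> str:
        if callable(self.script):
            return self.script(prompt)
        if isinstance(self.script, str):
            return self.script
        for question, response in self.script.items():
            if question in prompt.user_text:
                return response
        raise LlmTransportError("mock client has no scripted response for this prompt")


@dataclass
class HttpLlmClient:
    """Minimal chat-completions client for OpenAI-compatible HTTP APIs.

    Deterministic settings (temperature 0) are requested by default.
    Credentials come from the caller, never from this module.
    """

    url: str
    api_key: str | None = None
    model_id: str = "gpt-4o-mini"
    temperature: float = 0.0
    timeout: float = 120.0

    def complete(self, prompt: PromptBundle) -> str:
        payload = json.dumps({
            "model": self.model_id,
            "temperature": self.temperature,
            "messages": [
                {"role": "system", "content": prompt.system_text},
                {"role": "user", "content": prompt.user_text},
            ],
        }).encode("utf-8")
        headers = {"Content-Type": "application/json"}
        if self.api_key:
            headers["Authorization"] = f"Bearer {self.api_key}"
        req = urllib.request.Request(self.url, data=payload, headers=headers,
                                     method="POST")
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                doc = json.loads(resp.read().decode("utf-8"))
        except urllib.error.HTTPError as exc:
            raise LlmTransportError(f"model API returned HTTP {exc.code}") from exc
        except (urllib.error.URLError, TimeoutError, OSError) as exc:
            raise LlmTransportError(f"cannot reach model API: {exc}") from exc
        try:
            return doc["choices"][0]["message"]["content"]
        except (KeyError, IndexError, TypeError) as exc:
            raise LlmTransportError("unexpected model API response shape") from exc


# ---------------------------------------------------------------------------
# prompt construction
# ---------------------------------------------------------------------------


def format_variables_info(descriptions: list[VariableDescription],
                          include_explanations: bool = True) -> str:
    """One line per variable: name, example value, explanation (in order)."""
    if not descriptions:
        raise ExtractionError("variables-info listing requires at least one variable")
    lines = []
    for d in descriptions:
        line = f"- {d.name} (example: {d.example})"
        if include_explanations:
            line += f": {d.explanation}"
        lines.append(line)
    return "\n".join(lines)


def build_extraction_prompt(question: str, variables_info: str,
                            system_text: str = DEFAULT_SYSTEM_TEXT,
                            user_template: str = DEFAULT_USER_TEMPLATE) -> PromptBundle:
    """Substitute the question and listing into the four-step template."""
    if not question.strip():
        raise ExtractionError("question must be non-empty")
    user_text = user_template.format(user_question=question,
                                     variables_info=variables_info)
    return PromptBundle(system_text=system_text, user_text=user_text)


# ---------------------------------------------------------------------------
# output parsing and validation
# ---------------------------------------------------------------------------


def serialize_extraction_result(result: ExtractionResult) -> str:
    """Emit the fenced answer block this module's parser accepts."""
    payload = {
        "variables": list(result.variables),
        "parameters": [list(p) for p in result.parameters],
    }
    return f"```answer\n{json.dumps(payload, ensure_ascii=False)}\n```"


def parse_extraction_output(raw: str, schema: Schema) -> ExtractionResult:
    """Extract and validate the final fenced answer block of a model response.

    Value strings are preserved byte-exact (JSON decoding only).  Unknown
    variable names are a hard error listing every offending name; a variable
    repeated in the variables list is likewise an error.
    """
    if not raw.strip():
        raise ExtractionError("model output is empty")
    blocks = _ANSWER_BLOCK_RE.findall(raw)
    if not blocks:
        raise ExtractionError("no fenced `answer` block found in model output")
    try:
        payload = json.loads(blocks[-1])
    except ValueError as exc:
        raise ExtractionError(f"answer block is not valid JSON: {exc}") from exc
    if not isinstance(payload, dict):
        raise ExtractionError("answer block must contain a JSON object")
    variables = payload.get("variables", [])
    parameters = payload.get("parameters", [])
    if not isinstance(variables, list) or not all(isinstance(v, str) for v in variables):
        raise ExtractionError("'variables' must be a list of strings")
    if (not isinstance(parameters, list)
            or not all(isinstance(p, (list, tuple)) and len(p) == 2
                       and all(isinstance(x, str) for x in p) for p in parameters)):
        raise ExtractionError("'parameters' must be a list of [variable, value] pairs")
    if len(set(variables)) != len(variables):
        raise ExtractionError("duplicate variable in the variables list")
    unknown = sorted({v for v in variables if v not in schema}
                     | {v for v, _ in parameters if v not in schema})
    if unknown:
        raise UnknownVariableError(unknown)
    return ExtractionResult(
        variables=tuple(variables),
        parameters=tuple((v, x) for v, x in parameters),
        trace=raw,
    )


def check_strict_copy(result: ExtractionResult, question: str) -> list[str]:
    """Advisory guard against copy hallucination in parameter values.

    One warning per parameter whose value is not a verbatim (case-sensitive)
    substring of the question.  Checks the question only — a value that
    diverges from database vocabulary but was copied faithfully is not
    flagged.  Never raises.
    """
    warnings = []
    for var, value in result.parameters:
        if value not in question:
            warnings.append(
                f"parameter ({var}, {value!r}) is not a verbatim substring "
                "of the question; possible extraction hallucination"
            )
    return warnings


# ---------------------------------------------------------------------------
# the full extraction pipeline
# ---------------------------------------------------------------------------


def extract(question: str, schema: Schema,
            explanations: Mapping[str, str] | None = None,
            client: LlmClient | None = None,
            mode: str = "VwE") -> ExtractionResult:
    """List variables, build the prompt, call the client, parse and validate.

    *mode* selects the listing presentation: "VwE" (names, examples,
    explanations), "VwoE" (names and examples only) or "VinS" (the schema's
    canonical text in place of the listing).  Strict-copy warnings are
    attached to the result; client transport and parse errors propagate
    unchanged.  The schema is never mutated.
    """
    if client is None:
        raise ExtractionError("no language-model client configured")
    if mode not in MODES:
        raise ExtractionError(f"unknown prompt mode {mode!r}; expected one of {MODES}")
    if mode == "VinS":
        variables_info = render_schema(schema)
    else:
        descriptions = list_selectable_variables(schema, dict(explanations or {}))
        variables_info = format_variables_info(
            descriptions, include_explanations=(mode == "VwE"))
    prompt = build_extraction_prompt(question, variables_info)
    raw = client.complete(prompt)
    result = parse_extraction_output(raw, schema)
    warnings = tuple(check_strict_copy(result, question))
    return ExtractionResult(
        variables=result.variables,
        parameters=result.parameters,
        trace=result.trace,
        warnings=warnings,
    )
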