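"""Prompt construction, answer parsing, strict-copy guard, pipeline purity."""

import random
import string

import pytest

import sparqlforge as sf
from sparqlforge.errors import ExtractionError, UnknownVariableError
from sparqlforge.extraction import (
    STEP_HEADINGS,
    build_extraction_prompt,
    format_variables_info,
    parse_extraction_output,
    serialize_extraction_result,
)

from conftest import CITATION_ANSWER, UNIPROT_EXPLANATIONS


def make_result(rng: random.Random, schema) -> sf.ExtractionResult:
    names = [n.variable_name for n in schema.nodes]
    variables = tuple(rng.sample(names, rng.randint(0, len(names))))
    alphabet = string.ascii_letters + string.digits + ' =>:+-()"\\{}'
    parameters = tuple(
        (rng.choice(names),
         "".join(rng.choice(alphabet) for _ in range(rng.randint(1, 12))))
        for _ in range(rng.randint(0, 3))
    )
    return sf.ExtractionResult(variables=variables, parameters=parameters)


class TestVariablesInfo:
    def test_worked_example_listing(self, uniprot_schema):
        descs = sf.list_selectable_variables(uniprot_schema, UNIPROT_EXPLANATIONS)
        info = format_variables_info(descs)
        lines = info.splitlines()
        assert len(lines) == 3
        assert any("uniprot_taxonomy" in line for line in lines)
        assert "taxonomy identifier" in info

    def test_empty_explanation_still_one_line(self):
        info = format_variables_info(
            [sf.VariableDescription(name="v", example="e", explanation="")])
        assert info == "- v (example: e): "

    def test_empty_list_rejected(self):
        with pytest.raises(ExtractionError):
            format_variables_info([])

    def test_injective_on_names(self, uniprot_schema):
        descs = sf.list_selectable_variables(uniprot_schema)
        for i, d in enumerate(descs):
            renamed = list(descs)
            renamed[i] = sf.VariableDescription(
                name=d.name + "_x", example=d.example, explanation=d.explanation)
            assert format_variables_info(renamed) != format_variables_info(descs)


class TestPrompt:
    def test_question_and_steps_verbatim(self, uniprot_schema):
        question = "What is the protein ID of ACE2 gene registered in UniProt?"
        info = format_variables_info(sf.list_selectable_variables(uniprot_schema))
        bundle = build_extraction_prompt(question, info)
        assert question in bundle.user_text
        assert info in bundle.user_text
        positions = [bundle.user_text.index(h) for h in STEP_HEADINGS]
        assert positions == sorted(positions)

    def test_empty_question_rejected(self, uniprot_schema):
        with pytest.raises(ExtractionError):
            build_extraction_prompt("  ", "- v (example: e): x")

    def test_no_residual_placeholders(self):
        rng = random.Random(17)
        alphabet = string.ascii_letters + string.digits + " ?!.,;:=+-'\""
        for _ in range(100):
            question = "q" + "".join(rng.choice(alphabet)
                                     for _ in range(rng.randint(1, 40)))
            bundle = build_extraction_prompt(question, "- v (example: e): x")
            assert "{user_question}" not in bundle.user_text
            assert "{variables_info}" not in bundle.user_text


class TestParseOutput:
    def test_worked_example_block(self, uniprot_schema):
        result = parse_extraction_output(CITATION_ANSWER, uniprot_schema)
        assert result.variables == ("uniprot_citation",)
        assert result.parameters == (("uniprot_taxonomy", "taxonomy:9606"),)
        assert result.trace == CITATION_ANSWER

    def test_unknown_variable_named_in_error(self, uniprot_schema):
        raw = '```answer\n{"variables": ["protein_id"], "parameters": []}\n```'
        with pytest.raises(UnknownVariableError) as err:
            parse_extraction_output(raw, uniprot_schema)
        assert "protein_id" in str(err.value)

    def test_duplicate_variable_rejected(self, uniprot_schema):
        raw = ('```answer\n{"variables": ["UniProt", "UniProt"], '
               '"parameters": []}\n```')
        with pytest.raises(ExtractionError, match="duplicate"):
            parse_extraction_output(raw, uniprot_schema)

    def test_missing_block_rejected(self, uniprot_schema):
        with pytest.raises(ExtractionError, match="answer"):
            parse_extraction_output("no block here", uniprot_schema)

    def test_serialize_embed_parse_round_trip(self, uniprot_schema):
        rng = random.Random(23)
        for _ in range(300):
            result = make_result(rng, uniprot_schema)
            embedded = (f"Some reasoning...\n{serialize_extraction_result(result)}"
                        f"\ntrailing prose")
            parsed = parse_extraction_output(embedded, uniprot_schema)
            assert parsed.variables == result.variables
            assert parsed.parameters == result.parameters

    def test_last_block_wins(self, uniprot_schema):
        raw = ('```answer\n{"variables": ["UniProt"], "parameters": []}\n```\n'
               '```answer\n{"variables": ["uniprot_citation"], '
               '"parameters": []}\n```')
        assert parse_extraction_output(raw, uniprot_schema).variables == \
            ("uniprot_citation",)


class TestStrictCopy:
    def test_operator_drift_flagged(self):
        # the classic copy hallucination: "=" extracted as "=>"
        question = ("Which reaction matches angiotensin II + H2O = "
                    "angiotensin-(1-7) + L-phenylalanine?")
        result = sf.ExtractionResult(
            variables=(),
            parameters=(("rhea_equation",
                         "angiotensin II + H2O => angiotensin-(1-7) "
                         "+ L-phenylalanine"),))
        warnings = sf.check_strict_copy(result, question)
        assert len(warnings) == 1

    def test_verbatim_value_not_flagged(self):
        result = sf.ExtractionResult(
            variables=(), parameters=(("gene", "ACE2"),))
        assert sf.check_strict_copy(result, "Tell me about ACE2 please") == []

    def test_guard_checks_question_not_database(self):
        # "breast cells" copied faithfully from the question is fine even if
        # the database vocabulary says "breast"
        result = sf.ExtractionResult(
            variables=(), parameters=(("anatomy", "breast cells"),))
        assert sf.check_strict_copy(result, "expression in breast cells?") == []


class TestExtractPipeline:
    def test_mock_echo_yields_request(self, uniprot_schema):
        client = sf.MockLlmClient(script=CITATION_ANSWER)
        result = sf.extract("any question", uniprot_schema, client=client)
        assert result.variables == ("uniprot_citation",)
        assert result.parameters == (("uniprot_taxonomy", "taxonomy:9606"),)

    def test_unknown_variable_surfaces(self, uniprot_schema):
        client = sf.MockLlmClient(
            script='```answer\n{"variables": ["ghost"], "parameters": []}\n```')
        with pytest.raises(UnknownVariableError):
            sf.extract("q", uniprot_schema, client=client)

    def test_pipeline_is_pure_with_mock(self, uniprot_schema):
        client = sf.MockLlmClient(script=CITATION_ANSWER)
        a = sf.extract("q one", uniprot_schema, client=client)
        b = sf.extract("q one", uniprot_schema, client=client)
        assert a == b

    @pytest.mark.parametrize("mode", ["VwE", "VwoE", "VinS"])
    def test_all_presentation_modes_build_prompts(self, uniprot_schema, mode):
        seen = {}

        def spy(bundle):
            seen["user"] = bundle.user_text
            return CITATION_ANSWER

        client = sf.MockLlmClient(script=spy)
        sf.extract("q", uniprot_schema, explanations=UNIPROT_EXPLANATIONS,
                   client=client, mode=mode)
        assert "q" in seen["user"]
        if mode == "VwE":
            assert "taxonomy identifier" in seen["user"]
        elif mode == "VwoE":
            assert "taxonomy identifier" not in seen["user"]
            assert "uniprot_taxonomy" in seen["user"]
        else:
            assert "up:organism" in seen["user"]  # raw schema text

    def test_connector_names_never_leak_into_prompt(self):
        schema = sf.parse_schema(
            "name: c\nprefixes: {ex: <http://e.org/>}\nmodel:\n"
            "  - R:\n      - a: ex:T\n      - ex:link:\n"
            "          - hiddenhub:\n          - ex:leafp:\n              leaf: v\n")
        seen = {}

        def spy(bundle):
            seen["user"] = bundle.user_text
            return '```answer\n{"variables": ["leaf"], "parameters": []}\n```'

        sf.extract("q", schema, client=sf.MockLlmClient(script=spy))
        assert "hiddenhub" not in seen["user"]
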