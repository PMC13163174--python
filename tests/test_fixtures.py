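"""Synthetic graphs, the traversal oracle, benchmark records and campaigns."""

import random

import pytest

import sparqlforge as sf

from conftest import CITATION_ANSWER, random_pipeline_case


class TestGenerateFixtureGraph:
    def test_triple_count_matches_schema_arithmetic(self, uniprot_schema):
        # 3 entries x (1 type + 2 edges) = 9 triples
        ttl = sf.generate_fixture_graph(
            sf.FixtureSpec(schema=uniprot_schema, n_entries=3, seed=0))
        assert len([l for l in ttl.splitlines() if l.strip()]) == 9

    def test_single_entry_root_only_schema(self):
        s = sf.parse_schema("name: t\nprefixes: {ex: <http://e.org/>}\nmodel:\n"
                            "  - Only:\n      - a: ex:T\n")
        ttl = sf.generate_fixture_graph(sf.FixtureSpec(schema=s, n_entries=1))
        assert len([l for l in ttl.splitlines() if l.strip()]) == 1

    def test_byte_identical_for_same_spec(self, uniprot_schema):
        spec = sf.FixtureSpec(schema=uniprot_schema, n_entries=5, seed=42,
                              value_pools={"uniprot_taxonomy":
                                           ["taxonomy:9606", "taxonomy:10090"]})
        assert sf.generate_fixture_graph(spec) == sf.generate_fixture_graph(spec)

    def test_invalid_spec_rejected(self, uniprot_schema):
        with pytest.raises(ValueError):
            sf.FixtureSpec(schema=uniprot_schema, n_entries=0)
        with pytest.raises(ValueError):
            sf.FixtureSpec(schema=uniprot_schema, n_entries=1,
                           value_pools={"uniprot_taxonomy": []})


class TestOracleAnswer:
    def test_all_entries_share_bound_value(self, uniprot_schema, citation_request):
        ttl = sf.generate_fixture_graph(sf.FixtureSpec(
            schema=uniprot_schema, n_entries=3, seed=0,
            value_pools={"uniprot_taxonomy": ["taxonomy:9606"]}))
        table = sf.oracle_answer(uniprot_schema, citation_request, ttl)
        assert len(table.rows) == 3
        assert all(len(r) == 1 for r in table.rows)

    def test_absent_parameter_value_gives_zero_rows(self, uniprot_schema):
        ttl = sf.generate_fixture_graph(sf.FixtureSpec(
            schema=uniprot_schema, n_entries=3, seed=0,
            value_pools={"uniprot_taxonomy": ["taxonomy:10090"]}))
        request = sf.QueryRequest(variables=("uniprot_citation",),
                                  parameters=(("uniprot_taxonomy",
                                               "taxonomy:9606"),))
        assert sf.oracle_answer(uniprot_schema, request, ttl).rows == ()

    def test_agrees_with_built_query_execution(self):
        # the central dual-route check: SPARQL-free traversal vs built query
        rng = random.Random(404)
        for _ in range(25):
            schema, _, request, ttl = random_pipeline_case(rng)
            via_sparql = sf.execute_local(sf.build_query(schema, request).text, ttl)
            via_oracle = sf.oracle_answer(schema, request, ttl)
            assert len(via_sparql.rows) == len(via_oracle.rows)
            assert sf.table_similarity(via_sparql, via_oracle) == 1.0


class TestBenchmarkFiles:
    def test_load_round(self):
        text = """
records:
  - id: q1
    question: citations for taxonomy:9606 proteins?
    truth_variables: [uniprot_citation]
    truth_parameters: [[uniprot_taxonomy, "taxonomy:9606"]]
  - id: q2
    question: same thing, rephrased
    truth_variables: [uniprot_citation]
    truth_parameters: [[uniprot_taxonomy, "taxonomy:9606"]]
    paraphrase_of: q1
"""
        records = sf.load_benchmark(text)
        assert [r.id for r in records] == ["q1", "q2"]
        assert records[0].truth_parameters == (("uniprot_taxonomy",
                                                "taxonomy:9606"),)
        assert records[1].paraphrase_of == "q1"

    def test_dangling_paraphrase_rejected(self):
        with pytest.raises(sf.SparqlForgeError, match="paraphrases unknown"):
            sf.load_benchmark(
                "records:\n  - {id: a, question: x, paraphrase_of: ghost}\n")


def four_records():
    return [
        sf.BenchmarkRecord(
            id=f"r{i}", question=f"citations for marker{i} taxonomy:9606",
            truth_variables=("uniprot_citation",),
            truth_parameters=(("uniprot_taxonomy", "taxonomy:9606"),))
        for i in range(4)
    ]


@pytest.fixture
def campaign_setup(uniprot_schema, uniprot_fixture_graph):
    records = four_records()
    executor = lambda q: sf.execute_local(q, uniprot_fixture_graph)
    script = {r.question: CITATION_ANSWER for r in records}
    return records, executor, script


class TestRunCampaign:
    def test_perfect_mock_scores_one(self, uniprot_schema, campaign_setup):
        records, executor, script = campaign_setup
        report = sf.run_campaign(records, uniprot_schema,
                                 sf.MockLlmClient(script=script), executor)
        assert report.means == {"table_similarity": 1.0,
                                "variable_jaccard": 1.0,
                                "parameter_jaccard": 1.0}
        assert report.metadata["n_failed"] == 0

    def test_one_bad_record_scores_three_quarters(self, uniprot_schema,
                                                  campaign_setup):
        records, executor, script = campaign_setup
        script = dict(script)
        script[records[0].question] = (
            '```answer\n{"variables": ["nonexistent"], "parameters": []}\n```')
        report = sf.run_campaign(records, uniprot_schema,
                                 sf.MockLlmClient(script=script), executor)
        assert report.means["table_similarity"] == pytest.approx(0.75)
        failed = [r for r in report.records if r.failed]
        assert len(failed) == 1 and failed[0].id == "r0"
        assert "nonexistent" in failed[0].error

    def test_report_conservation(self, uniprot_schema, campaign_setup):
        records, executor, script = campaign_setup
        report = sf.run_campaign(records, uniprot_schema,
                                 sf.MockLlmClient(script=script), executor)
        for metric, counts in report.bins.items():
            assert sum(counts.values()) == len(report.records)
        recomputed = sum(r.table_similarity for r in report.records) / 4
        assert abs(recomputed - report.means["table_similarity"]) < 1e-12

    def test_seeded_campaign_bit_reproducible(self, uniprot_schema,
                                              campaign_setup):
        records, executor, script = campaign_setup
        client = sf.MockLlmClient(script=script)
        a = sf.run_campaign(records, uniprot_schema, client, executor, seed=5)
        b = sf.run_campaign(records, uniprot_schema, client, executor, seed=5)
        assert a.to_json() == b.to_json()

    def test_degradation_is_monotone(self, uniprot_schema, campaign_setup):
        records, executor, script = campaign_setup
        means = []
        for n_bad in range(5):
            corrupted = dict(script)
            for rec in records[:n_bad]:
                corrupted[rec.question] = (
                    '```answer\n{"variables": ["UniProt"], "parameters": []}\n```')
            report = sf.run_campaign(records, uniprot_schema,
                                     sf.MockLlmClient(script=corrupted), executor)
            means.append(report.means["table_similarity"])
        assert all(a >= b for a, b in zip(means, means[1:]))

    def test_expected_table_short_circuits_truth_execution(self, uniprot_schema,
                                                           campaign_setup):
        records, executor, script = campaign_setup
        with_table = [sf.BenchmarkRecord(
            id="t0", question=records[0].question,
            truth_variables=records[0].truth_variables,
            truth_parameters=records[0].truth_parameters,
            expected_table=executor(
                sf.build_query(uniprot_schema, sf.QueryRequest(
                    variables=records[0].truth_variables,
                    parameters=records[0].truth_parameters)).text))]
        report = sf.run_campaign(with_table, uniprot_schema,
                                 sf.MockLlmClient(script=script), executor)
        assert report.means["table_similarity"] == 1.0
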