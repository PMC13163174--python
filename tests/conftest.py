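"""Shared fixtures: the UniProt worked-example schema and helpers.

All fixture data is generated programmatically; nothing is read from disk.
"""

import random

import pytest

import sparqlforge as sf

UNIPROT_YAML = """\
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
"""

UNIPROT_EXPLANATIONS = {
    "UniProt": "A protein entry identified by its UniProt accession.",
    "uniprot_taxonomy": "The NCBI taxonomy identifier of the protein's organism.",
    "uniprot_citation": "A literature citation identifier attached to the entry.",
}

# A scripted model response emitting the worked-example request:
# retrieve citation IDs of proteins from taxon 9606.
CITATION_ANSWER = (
    "Step 1. Extracting User Requests\nThe user wants citation IDs.\n"
    "Step 2. Converting User Request to Variables\nuniprot_citation\n"
    "Step 3. Extracting User-Specified Condition\ntaxonomy:9606\n"
    "Step 4. Converting Conditions to Parameters\n"
    "(uniprot_taxonomy, taxonomy:9606)\n"
    "```answer\n"
    '{"variables": ["uniprot_citation"], '
    '"parameters": [["uniprot_taxonomy", "taxonomy:9606"]]}\n'
    "```\n"
)


@pytest.fixture(scope="session")
def uniprot_schema():
    return sf.parse_schema(UNIPROT_YAML)


@pytest.fixture(scope="session")
def citation_request():
    return sf.QueryRequest(
        variables=("uniprot_citation",),
        parameters=(("uniprot_taxonomy", "taxonomy:9606"),),
    )


def three_entry_turtle(schema):
    """A 3-entry graph where exactly 2 entries carry taxonomy 9606."""
    up = schema.prefixes["up"]
    tax = schema.prefixes["taxonomy"]
    cit = schema.prefixes["citation"]
    rdf_type = "http://www.w3.org/1999/02/22-rdf-syntax-ns#type"
    lines = []
    taxa = ["9606", "10090", "9606"]
    for k in range(3):
        s = f"<http://example.org/uniprot/P{k}>"
        lines.append(f"{s} <{rdf_type}> <{up}Protein> .")
        lines.append(f"{s} <{up}organism> <{tax}{taxa[k]}> .")
        lines.append(f"{s} <{up}citation> <{cit}CIT{k}> .")
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def uniprot_fixture_graph(uniprot_schema):
    return three_entry_turtle(uniprot_schema)


def random_table(rng: random.Random, max_rows: int = 6, max_cells: int = 4,
                 vocab: int = 8) -> sf.ResultTable:
    rows = []
    for _ in range(rng.randint(0, max_rows)):
        rows.append({f"c{rng.randrange(vocab)}"
                     for _ in range(rng.randint(1, max_cells))})
    return sf.ResultTable.from_rows(rows)


def random_pipeline_case(rng: random.Random, n_entries: int = 4):
    """(schema, pools, request, turtle) drawn from the synthetic generators."""
    schema = sf.make_random_schema(rng)
    pools = sf.make_value_pools(rng, schema)
    request = sf.make_random_request(rng, schema, pools)
    turtle = sf.generate_fixture_graph(sf.FixtureSpec(
        schema=schema, n_entries=n_entries, seed=rng.randrange(2**31),
        value_pools=pools))
    return schema, pools, request, turtle
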