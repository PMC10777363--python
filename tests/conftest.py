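import pytest

from pgxgraph import (
    build_graph,
    make_worked_example,
    match_guidelines,
    serialize_pathway,
    serialize_report,
)


@pytest.fixture(scope="session")
def worked_example():
    return make_worked_example()


@pytest.fixture(scope="session")
def clomipramine_graph(worked_example):
    pathway, record = worked_example
    guidelines = match_guidelines(record, record.prescriptions[0])
    return build_graph(pathway, guidelines, record.variants)


@pytest.fixture()
def example_files(tmp_path, worked_example):
    """Worked-example inputs written to disk for path-based APIs and the CLI."""
    pathway, record = worked_example
    ppath = tmp_path / "pathway.tsv"
    rpath = tmp_path / "report.json"
    ppath.write_text(serialize_pathway(pathway), encoding="utf-8")
    rpath.write_text(serialize_report(record), encoding="utf-8")
    return ppath, rpath
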