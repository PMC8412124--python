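import pytest

from regulonscan.simulate import Table1Fixture, table1_fixture


@pytest.fixture(scope="session")
def table1() -> Table1Fixture:
    """Count-faithful two-species fixture, built once per session."""
    return table1_fixture()


@pytest.fixture()
def tiny_de(tmp_path):
    """Three-row DE table file: significant, non-significant, untested."""
    path = tmp_path / "de.tsv"
    path.write_text(
        "gene_id\tlog2fc\tpadj\tmean_case\tmean_control\n"
        "GENEA\t1.5\t0.01\t10.0\t3.0\n"
        "GENEB\t-0.4\t0.2\t5.0\t6.0\n"
        "GENEC\t0.9\t\t2.0\t2.0\n"
    )
    return path
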