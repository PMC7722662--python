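import pytest

from crossprobe import fixtures


@pytest.fixture(scope="session")
def std_fixture():
    """One mixed-scenario planted fixture shared by read-only tests."""
    return fixtures.make_fixture(n_probes=24, seed=11)


@pytest.fixture()
def std_fixture_dir(std_fixture, tmp_path):
    return std_fixture.write(tmp_path / "fx")
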