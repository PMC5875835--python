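import pytest

from vmatadapt.mlc_geometry import HD_MODEL, SD_MODEL, build_geometry
from vmatadapt.adaptation import build_correspondence
from vmatadapt.rtplan_io import read_plan
from vmatadapt.synthetic_plans import write_fixture_suite


@pytest.fixture(scope="session")
def hd_geom():
    return build_geometry(HD_MODEL)


@pytest.fixture(scope="session")
def sd_geom():
    return build_geometry(SD_MODEL)


@pytest.fixture(scope="session")
def correspondence(hd_geom, sd_geom):
    return build_correspondence(hd_geom, sd_geom)


@pytest.fixture(scope="session")
def fixture_paths(tmp_path_factory):
    """The documented synthetic RT Plan suite, generated once per session."""
    directory = tmp_path_factory.mktemp("rtplans")
    return write_fixture_suite(directory)


@pytest.fixture(scope="session")
def fixture_docs(fixture_paths):
    return {name: read_plan(path) for name, path in fixture_paths.items()}
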