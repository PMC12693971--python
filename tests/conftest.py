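"""Shared fixtures: reference bundles are built once per session."""

import pytest

from archvar.fixtures import build_fixture


@pytest.fixture(scope="session")
def catalog42_bundle(tmp_path_factory):
    return build_fixture("catalog42", tmp_path_factory.mktemp("catalog42"))


@pytest.fixture(scope="session")
def table1_bundle(tmp_path_factory):
    return build_fixture("table1", tmp_path_factory.mktemp("table1"))


@pytest.fixture(scope="session")
def table2_bundle(tmp_path_factory):
    return build_fixture("table2_tktl1", tmp_path_factory.mktemp("table2"))


@pytest.fixture(scope="session")
def ssh2_bundle(tmp_path_factory):
    return build_fixture("ssh2_cohort", tmp_path_factory.mktemp("ssh2"))


@pytest.fixture(scope="session")
def tktl1_imaging_bundle(tmp_path_factory):
    return build_fixture("tktl1_imaging", tmp_path_factory.mktemp("tktl1_img"))


@pytest.fixture(scope="session")
def tktl1_qualification_bundle(tmp_path_factory):
    return build_fixture("tktl1_qualification", tmp_path_factory.mktemp("tktl1_qual"))
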