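"""Shared fixtures: the shipped panel and a seed-pinned synthetic cohort.

The study-scale fixture (78 cases / 256 controls plus 5% duplicates) is
generated once per session at a pinned seed chosen so that QC reproduces the
study's structure: the intentionally monomorphic locus is the only excluded
SNP, leaving 25 analyzed.
"""

import pytest

from pancprs import SimConfig, default_panel, simulate_cohort, write_fixture

FIXTURE_SEED = 5


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def study_cohort(panel):
    cfg = SimConfig.from_panel(panel, seed=FIXTURE_SEED)
    matrix, subjects = simulate_cohort(cfg)
    return matrix, subjects, cfg


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, panel, study_cohort):
    matrix, subjects, cfg = study_cohort
    directory = tmp_path_factory.mktemp("cohort")
    write_fixture(matrix, subjects, directory, panel=panel, config=cfg)
    return directory
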