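import pytest

from clptrap import (
    DEFAULT_EXCLUSIONS,
    EvidenceRecord,
    EvidenceTable,
    ExclusionList,
    FilterParams,
    Role,
    StudyDesign,
    aggregate,
    apply_score_filter,
    build_paper_fixture,
    classify,
)


@pytest.fixture
def design():
    return StudyDesign.from_samples([
        ("ctrl", Role.CONTROL, 3),
        ("wt", Role.BAIT_REFERENCE, 3),
        ("trap", Role.BAIT_TRAP, 3),
    ])


@pytest.fixture
def default_params():
    return FilterParams()


@pytest.fixture(scope="session")
def fixture_data():
    return build_paper_fixture()


@pytest.fixture(scope="session")
def fixture_results():
    """Default-parameter cascade output on the published-table fixture."""
    table, truth = build_paper_fixture()
    return run_cascade(table), truth


def run_cascade(table, params=None, exclusions=None):
    """Score filter -> aggregate -> classify, with study defaults."""
    params = params or FilterParams()
    if exclusions is None:
        exclusions = ExclusionList(DEFAULT_EXCLUSIONS)
    filtered = apply_score_filter(table, params.score_min)
    return classify(aggregate(filtered, params), table.design, params, exclusions)


def make_table(design, rows):
    """rows: (sample, replicate, protein, score, unique, spectral)."""
    return EvidenceTable(design, tuple(EvidenceRecord(*r) for r in rows))
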