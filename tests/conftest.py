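"""Shared fixtures: record factories and count-encoded rate tables."""

from __future__ import annotations

import pytest

from awagkit.scoring import BinaryAWA
from awagkit.survey_io import ItemResponse, RespondentRecord, default_catalog


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


def make_record(
    respondent_id: str = "r1",
    responses: dict[str, ItemResponse] | None = None,
    **overrides,
) -> RespondentRecord:
    """A valid record with sensible defaults, overridable per field."""
    fields = dict(
        respondent_id=respondent_id,
        hospital="A",
        sex=1,
        age=45,
        marital=1,
        residence=1,
        education=12,
        income_tier="middle",
        srh5=3,
        chronic=1,
        eheals_items=(3,) * 8,
        pu_items=(4,) * 4,
        peou_items=(3,) * 4,
        responses=responses or {},
    )
    fields.update(overrides)
    return RespondentRecord(**fields)


@pytest.fixture
def record_factory():
    return make_record


def awa_from_counts(n: int, aware: int, want: int, adopt: int) -> list[BinaryAWA]:
    """Per-respondent indicator list realizing exact marginal counts.

    Field patterns are assigned independently (first `aware` respondents
    aware, etc.); rates depend only on the marginals.
    """
    return [
        BinaryAWA(int(i < aware), int(i < want), int(i < adopt)) for i in range(n)
    ]


#: published category counts over n=1322 (aware, want, adopt)
TABLE3_COUNTS = {
    "overall": (1204, 1169, 847),
    "information_based": (1128, 1037, 704),
    "treatment_intermediary": (1182, 1142, 753),
    "treatment": (986, 924, 310),
}


@pytest.fixture(scope="session")
def table3_counts():
    return TABLE3_COUNTS
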