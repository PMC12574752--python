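"""Deterministic coding and scoring of survey responses.

Dependent variables: each service item's raw codes are dichotomized —
awareness = heard of the service, want = stated intention to use it, and
adoption = used it either independently or with family help.

Independent variables: Likert instruments are sum-scored (eHEALS over 8
items, range 8-40; perceived usefulness and perceived ease of use over 4
items each, range 4-20), 5-level self-rated health collapses to
negative/fair/positive, and raw yearly income is categorized against a
reference per-capita disposable income (lowest <40%, middle 40-100%,
highest >100% of the reference).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .survey_io import ItemResponse, RespondentRecord

__all__ = [
    "BinaryAWA",
    "CovariateVector",
    "code_awa",
    "score_likert_sum",
    "recode_srh",
    "categorize_income",
    "score_record",
]

MissingPolicy = Literal["strict", "person_mean"]


@dataclass(frozen=True)
class BinaryAWA:
    """Dichotomized awareness / want / adoption indicators (0, 1, or None)."""

    awareness: int | None
    want: int | None
    adoption: int | None


@dataclass(frozen=True)
class CovariateVector:
    """Scored regression covariates for one respondent."""

    sex: int
    age: int
    marital: int
    residence: int
    education: int
    income_tier: str | None
    srh3: str
    chronic: int
    eheals: float | None
    pu: float | None
    peou: float | None


def code_awa(resp: ItemResponse) -> BinaryAWA:
    """Dichotomize one item's raw codes.

    awareness = 1 iff heard==2; want = 1 iff intention==2; adoption = 1 iff
    use in {2, 3} (family-assisted use counts as adoption).  Missing codes
    propagate field-wise.
    """
    aware = None if resp.heard is None else int(resp.heard == 2)
    want = None if resp.intention is None else int(resp.intention == 2)
    adopt = None if resp.use is None else int(resp.use in (2, 3))
    return BinaryAWA(aware, want, adopt)


def score_likert_sum(
    items: Sequence[int | None],
    k: int,
    *,
    missing: MissingPolicy = "strict",
) -> float | None:
    """Sum-score a k-item 5-point Likert instrument (range [k, 5k]).

    Under the default strict policy the score is missing if any item is
    missing.  ``missing="person_mean"`` rescales the observed-item mean to
    the full instrument length (requires at least one observed item).
    """
    items = list(items)
    if len(items) != k:
        raise ValueError(f"expected {k} items, got {len(items)}")
    observed = [int(v) for v in items if v is not None]
    for v in observed:
        if not 1 <= v <= 5:
            raise ValueError(f"Likert code {v} outside 1-5")
    if len(observed) < len(items):
        if missing == "strict":
            return None
        if not observed:
            return None
        return k * (sum(observed) / len(observed))
    return float(sum(observed))


def recode_srh(srh5: int) -> str:
    """Collapse 5-level self-rated health to negative / fair / positive."""
    if srh5 in (1, 2):
        return "negative"
    if srh5 == 3:
        return "fair"
    if srh5 in (4, 5):
        return "positive"
    raise ValueError(f"srh5 code {srh5!r} outside 1-5")


def categorize_income(amount: float, reference_income: float) -> str:
    """Assign an income tier relative to per-capita disposable income.

    lowest: below 40% of the reference; middle: between 40% and 100%
    inclusive; highest: above the reference.  Both boundary points belong
    to the middle tier.
    """
    if reference_income <= 0:
        raise ValueError("reference_income must be positive")
    if amount < 0:
        raise ValueError("income amount must be >= 0")
    if amount < 0.4 * reference_income:
        return "lowest"
    if amount <= reference_income:
        return "middle"
    return "highest"


def score_record(
    record: RespondentRecord,
    *,
    reference_income: float | None = None,
    missing: MissingPolicy = "strict",
) -> CovariateVector:
    """Score one respondent's covariates.

    A raw ``income_amount`` is categorized against ``reference_income``;
    supplying an amount without a reference raises (the reference is a
    city statistic that must come from configuration, never a default).
    """
    tier = record.income_tier
    if tier is None and record.income_amount is not None:
        if reference_income is None:
            raise ValueError(
                "record carries a raw income amount; reference_income required"
            )
        tier = categorize_income(record.income_amount, reference_income)
    return CovariateVector(
        sex=record.sex,
        age=record.age,
        marital=record.marital,
        residence=record.residence,
        education=record.education,
        income_tier=tier,
        srh3=recode_srh(record.srh5),
        chronic=record.chronic,
        eheals=score_likert_sum(record.eheals_items, 8, missing=missing),
        pu=score_likert_sum(record.pu_items, 4, missing=missing),
        peou=score_likert_sum(record.peou_items, 4, missing=missing),
    )
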