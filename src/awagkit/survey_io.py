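"""Data model and CSV input/output for eHealth-service survey tables.

A survey table has one row per respondent: demographics, health status,
three Likert instruments (8-item eHEALS, 4-item perceived usefulness,
4-item perceived ease of use), a hospital/cluster label, and — for each
service item in the catalog — the three raw survey codes

* ``<item_id>_heard``     (1=no, 2=yes)
* ``<item_id>_intention`` (1=no, 2=yes)
* ``<item_id>_use``       (1=no, 2=used with family help, 3=used independently)

Missing cells are empty strings in CSV and ``None`` in memory; the reader
never imputes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Category",
    "ServiceItem",
    "ServiceCatalog",
    "ItemResponse",
    "RespondentRecord",
    "SurveyValidationError",
    "default_catalog",
    "read_survey_csv",
    "write_survey_csv",
    "records_to_frame",
]


class Category(str, enum.Enum):
    """Functional role of an eHealth service."""

    INFORMATION_BASED = "information_based"
    TREATMENT_INTERMEDIARY = "treatment_intermediary"
    TREATMENT = "treatment"


#: pseudo-category meaning "all items in the catalog"
OVERALL = "overall"


class SurveyValidationError(ValueError):
    """Raised for structurally invalid survey input (bad header, dup ids...)."""


@dataclass(frozen=True)
class ServiceItem:
    item_id: str
    label: str
    category: Category


@dataclass(frozen=True)
class ServiceCatalog:
    """Ordered collection of service items partitioned into categories."""

    items: tuple[ServiceItem, ...]

    def __post_init__(self) -> None:
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            raise SurveyValidationError("duplicate item_id in catalog")
        if not self.items:
            raise SurveyValidationError("catalog must contain at least one item")

    @property
    def item_ids(self) -> tuple[str, ...]:
        return tuple(it.item_id for it in self.items)

    def categories(self) -> tuple[Category, ...]:
        seen: list[Category] = []
        for it in self.items:
            if it.category not in seen:
                seen.append(it.category)
        return tuple(seen)

    def items_in(self, category: Category | str) -> tuple[ServiceItem, ...]:
        """Items belonging to ``category``; the string ``"overall"`` selects all."""
        if category == OVERALL:
            return self.items
        category = Category(category)
        return tuple(it for it in self.items if it.category is category)

    def category_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for it in self.items:
            out[it.category.value] = out.get(it.category.value, 0) + 1
        return out


_MISSING = None

# valid raw codes for the three per-item questions
_HEARD_CODES = frozenset({1, 2})
_INTENT_CODES = frozenset({1, 2})
_USE_CODES = frozenset({1, 2, 3})


@dataclass(frozen=True)
class ItemResponse:
    """Raw survey codes for one service item; any field may be missing."""

    heard: int | None = None
    intention: int | None = None
    use: int | None = None

    def __post_init__(self) -> None:
        if self.heard is not None and self.heard not in _HEARD_CODES:
            raise SurveyValidationError(f"heard code {self.heard!r} not in {{1,2}}")
        if self.intention is not None and self.intention not in _INTENT_CODES:
            raise SurveyValidationError(
                f"intention code {self.intention!r} not in {{1,2}}"
            )
        if self.use is not None and self.use not in _USE_CODES:
            raise SurveyValidationError(f"use code {self.use!r} not in {{1,2,3}}")


def _check_likert(items: Sequence[int | None], k: int, name: str) -> tuple:
    items = tuple(items)
    if len(items) != k:
        raise SurveyValidationError(f"{name} needs {k} items, got {len(items)}")
    for v in items:
        if v is not None and not (1 <= int(v) <= 5):
            raise SurveyValidationError(f"{name} item code {v!r} outside 1-5")
    return items


@dataclass(frozen=True)
class RespondentRecord:
    """One surveyed inpatient.

    Raw codes follow the questionnaire conventions: sex 1=male/2=female,
    marital 1=married/2=unmarried, residence 1=urban/2=rural, srh5 1 (very
    poor) .. 5 (very good), chronic 1=no/2=yes.  ``income_tier`` holds either
    a tier label (lowest/middle/highest) or ``None`` when ``income_amount``
    carries a raw yearly amount to be categorized downstream.
    """

    respondent_id: str
    hospital: str
    sex: int
    age: int
    marital: int
    residence: int
    education: int
    srh5: int
    chronic: int
    eheals_items: tuple[int | None, ...]
    pu_items: tuple[int | None, ...]
    peou_items: tuple[int | None, ...]
    responses: Mapping[str, ItemResponse]
    income_tier: str | None = None
    income_amount: float | None = None

    def __post_init__(self) -> None:
        if self.age < 15:
            raise SurveyValidationError(f"age {self.age} violates inclusion age >= 15")
        if self.sex not in (1, 2):
            raise SurveyValidationError(f"sex code {self.sex!r} not in {{1,2}}")
        if self.marital not in (1, 2):
            raise SurveyValidationError(f"marital code {self.marital!r} not in {{1,2}}")
        if self.residence not in (1, 2):
            raise SurveyValidationError(
                f"residence code {self.residence!r} not in {{1,2}}"
            )
        if self.education < 0:
            raise SurveyValidationError("education years must be >= 0")
        if not 1 <= self.srh5 <= 5:
            raise SurveyValidationError(f"srh5 code {self.srh5!r} outside 1-5")
        if self.chronic not in (1, 2):
            raise SurveyValidationError(f"chronic code {self.chronic!r} not in {{1,2}}")
        if self.income_tier is not None and self.income_tier not in (
            "lowest",
            "middle",
            "highest",
        ):
            raise SurveyValidationError(f"unknown income tier {self.income_tier!r}")
        if self.income_amount is not None and self.income_amount < 0:
            raise SurveyValidationError("income_amount must be >= 0")
        object.__setattr__(
            self, "eheals_items", _check_likert(self.eheals_items, 8, "eheals")
        )
        object.__setattr__(self, "pu_items", _check_likert(self.pu_items, 4, "pu"))
        object.__setattr__(
            self, "peou_items", _check_likert(self.peou_items, 4, "peou")
        )
        object.__setattr__(self, "responses", dict(self.responses))


_TABLE_ITEMS: tuple[tuple[str, str, Category], ...] = (
    (
        "info_seek_health",
        "Seek disease or health information online",
        Category.INFORMATION_BASED,
    ),
    (
        "info_seek_provider",
        "Seek doctor or hospital information online",
        Category.INFORMATION_BASED,
    ),
    (
        "info_seek_review",
        "Seek medical review information online (patients' evaluation of doctors)",
        Category.INFORMATION_BASED,
    ),
    (
        "info_peer_feedback",
        "Give or receive peer-to-peer feedback about health status in online "
        "communities or chat platforms",
        Category.INFORMATION_BASED,
    ),
    (
        "inter_outpatient_booking",
        "Outpatient appointment booking online",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "inter_pay_bills",
        "Pay medical bills online",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "inter_records_access",
        "Access electronic medical records and medical examination reports online",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "inter_exam_booking",
        "Appoint a medical examination or surgery online",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "inter_hospitalization",
        "Online hospitalization appointment",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "inter_pharmacy",
        "Online drugstore purchases or online pharmacy, excluding dietary supplements",
        Category.TREATMENT_INTERMEDIARY,
    ),
    (
        "treat_econsult",
        "Electronic consulting, including email, chat, or video health care "
        "consultations",
        Category.TREATMENT,
    ),
    (
        "treat_monitoring",
        "Chronic disease monitoring and management via telemonitoring, telehealth "
        "and mobile health, including wearable devices or apps",
        Category.TREATMENT,
    ),
)


def default_catalog() -> ServiceCatalog:
    """The 12-item eHealth service catalog (4 information-based, 6 treatment
    intermediary, 2 treatment services)."""
    return ServiceCatalog(
        tuple(ServiceItem(i, label, cat) for i, label, cat in _TABLE_ITEMS)
    )


# ---------------------------------------------------------------------------
# CSV layer
# ---------------------------------------------------------------------------

_BASE_COLUMNS = (
    "respondent_id",
    "hospital",
    "sex",
    "age",
    "marital",
    "residence",
    "education",
    "income_tier",
    "income_amount",
    "srh5",
    "chronic",
)
_EHEALS_COLS = tuple(f"eheals_{i}" for i in range(1, 9))
_PU_COLS = tuple(f"pu_{i}" for i in range(1, 5))
_PEOU_COLS = tuple(f"peou_{i}" for i in range(1, 5))


def _columns(catalog: ServiceCatalog) -> list[str]:
    cols = list(_BASE_COLUMNS) + list(_EHEALS_COLS) + list(_PU_COLS) + list(_PEOU_COLS)
    for item_id in catalog.item_ids:
        cols += [f"{item_id}_heard", f"{item_id}_intention", f"{item_id}_use"]
    return cols


def _cell(value) -> int | None:
    """Parse an optionally missing integer-coded CSV cell."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    return int(float(value))


def _record_from_row(row: Mapping, catalog: ServiceCatalog) -> RespondentRecord:
    tier = row.get("income_tier")
    if tier is None or (isinstance(tier, float) and pd.isna(tier)) or tier == "":
        tier = None
    amount = row.get("income_amount")
    amount = None if amount in ("", None) or pd.isna(amount) else float(amount)
    responses: dict[str, ItemResponse] = {}
    for item_id in catalog.item_ids:
        resp = ItemResponse(
            heard=_cell(row.get(f"{item_id}_heard")),
            intention=_cell(row.get(f"{item_id}_intention")),
            use=_cell(row.get(f"{item_id}_use")),
        )
        if (resp.heard, resp.intention, resp.use) != (None, None, None):
            responses[item_id] = resp
    return RespondentRecord(
        respondent_id=str(row["respondent_id"]),
        hospital=str(row["hospital"]),
        sex=_cell(row["sex"]),
        age=_cell(row["age"]),
        marital=_cell(row["marital"]),
        residence=_cell(row["residence"]),
        education=_cell(row["education"]),
        income_tier=tier,
        income_amount=amount,
        srh5=_cell(row["srh5"]),
        chronic=_cell(row["chronic"]),
        eheals_items=tuple(_cell(row[c]) for c in _EHEALS_COLS),
        pu_items=tuple(_cell(row[c]) for c in _PU_COLS),
        peou_items=tuple(_cell(row[c]) for c in _PEOU_COLS),
        responses=responses,
    )


def read_survey_csv(
    path: str | Path,
    catalog: ServiceCatalog | None = None,
    *,
    strict: bool = False,
) -> tuple[list[RespondentRecord], list[tuple[int, str]]]:
    """Read and validate a respondent-level survey CSV.

    Returns ``(records, diagnostics)`` where each diagnostic is a
    ``(row_index, message)`` pair for a rejected row (0-based data-row
    index).  Rows are rejected, never silently dropped:
    ``len(records) + len(diagnostics)`` equals the number of data rows.
    With ``strict=True`` the first invalid row raises instead.
    """
    catalog = catalog or default_catalog()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    mandatory = set(_BASE_COLUMNS) | set(_EHEALS_COLS) | set(_PU_COLS) | set(_PEOU_COLS)
    missing = sorted(mandatory - set(df.columns))
    if missing:
        raise SurveyValidationError(f"header missing mandatory columns: {missing}")
    ids = df["respondent_id"]
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise SurveyValidationError(f"duplicate respondent_id values: {sorted(set(dup))}")

    records: list[RespondentRecord] = []
    diagnostics: list[tuple[int, str]] = []
    for idx, row in enumerate(df.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row, catalog))
        except (SurveyValidationError, KeyError, ValueError) as exc:
            if strict:
                raise SurveyValidationError(f"row {idx}: {exc}") from exc
            diagnostics.append((idx, str(exc)))
    return records, diagnostics


def records_to_frame(
    records: Iterable[RespondentRecord], catalog: ServiceCatalog | None = None
) -> pd.DataFrame:
    """Flatten records into the canonical survey table (one row/respondent)."""
    catalog = catalog or default_catalog()
    cols = _columns(catalog)
    rows = []
    for r in records:
        row: dict[str, object] = {
            "respondent_id": r.respondent_id,
            "hospital": r.hospital,
            "sex": r.sex,
            "age": r.age,
            "marital": r.marital,
            "residence": r.residence,
            "education": r.education,
            "income_tier": r.income_tier,
            "income_amount": r.income_amount,
            "srh5": r.srh5,
            "chronic": r.chronic,
        }
        for c, v in zip(_EHEALS_COLS, r.eheals_items):
            row[c] = v
        for c, v in zip(_PU_COLS, r.pu_items):
            row[c] = v
        for c, v in zip(_PEOU_COLS, r.peou_items):
            row[c] = v
        for item_id in catalog.item_ids:
            resp = r.responses.get(item_id)
            row[f"{item_id}_heard"] = None if resp is None else resp.heard
            row[f"{item_id}_intention"] = None if resp is None else resp.intention
            row[f"{item_id}_use"] = None if resp is None else resp.use
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def write_survey_csv(
    records: Iterable[RespondentRecord],
    path: str | Path,
    catalog: ServiceCatalog | None = None,
) -> None:
    """Write records as CSV with a deterministic column order.

    Missing values are written as empty cells; ``read_survey_csv`` on the
    output reproduces the records exactly.
    """
    catalog = catalog or default_catalog()
    df = records_to_frame(records, catalog)
    # keep integer codes free of trailing ".0" in the text form
    out = df.astype(object).where(pd.notna(df), "")

    def _fmt(v):
        if isinstance(v, float) and float(v).is_integer():
            return int(v)
        return v

    out = out.map(_fmt)
    out.to_csv(path, index=False)
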