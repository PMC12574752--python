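"""Awareness-want-adoption-gap (AWAG) statistics and segmentation matrix.

The adoption gap ratio measures, among people who are aware of or want a
service (whichever group is smaller), the share who never used it:

    gap = 100 * (min(A, W) - U) / min(A, W)

where A, W, U are awareness, want and adoption counts over a common n
(the n cancels, so the ratio can be computed from raw counts or rates).

The segmentation matrix places each service category at (awareness rate,
want rate) on a [0, 100]^2 plane cut by the technology-adoption-lifecycle
cumulative breakpoints 15 / 50 / 85.  The 50-cut defines four groups —
opened (both high), desire deficiency (aware but not wanting), perception
deficiency (wanting but unaware), closed (both low) — and the 15/85 cuts
split each group into strong, generic, want-bias and awareness-bias
subregions.  Bubble size encodes the gap ratio.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .scoring import BinaryAWA, code_awa
from .survey_io import Category, ItemResponse, RespondentRecord, ServiceCatalog

_EMPTY = ItemResponse()

__all__ = [
    "CategoryRates",
    "AwagCell",
    "MatrixFigureData",
    "aggregate_category",
    "compute_rates",
    "adoption_gap_ratio",
    "classify_awag",
    "build_matrix_figure",
    "round_half_away",
]

GROUP_LETTER = {
    "opened": "O",
    "perception_deficiency": "P",
    "desire_deficiency": "D",
    "closed": "C",
}
SUBREGION_LETTER = {
    "strong": "S",
    "generic": "G",
    "want_bias": "Wb",
    "awareness_bias": "Ab",
}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention of the reported tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class AwagCell:
    """One of the 16 cells of the segmentation matrix."""

    group: str
    subregion: str

    @property
    def code(self) -> str:
        return f"{GROUP_LETTER[self.group]} _ {SUBREGION_LETTER[self.subregion]}"

    @classmethod
    def from_code(cls, code: str) -> "AwagCell":
        g, s = (p.strip() for p in code.split("_"))
        group = {v: k for k, v in GROUP_LETTER.items()}[g]
        sub = {v: k for k, v in SUBREGION_LETTER.items()}[s]
        return cls(group, sub)


@dataclass(frozen=True)
class CategoryRates:
    """Counts, percentage rates and gap ratio for one service category."""

    category: str
    n: int
    aware_count: int
    want_count: int
    adopt_count: int
    aware_rate: float
    want_rate: float
    adopt_rate: float
    gap_ratio: float

    @property
    def cell(self) -> AwagCell:
        return classify_awag(self.aware_rate, self.want_rate)

    def rounded(self, ndigits: int = 1) -> dict:
        """Presentation form: rates rounded half-away-from-zero."""
        return {
            "category": self.category,
            "n": self.n,
            "aware_count": self.aware_count,
            "want_count": self.want_count,
            "adopt_count": self.adopt_count,
            "aware_rate": round_half_away(self.aware_rate, ndigits),
            "want_rate": round_half_away(self.want_rate, ndigits),
            "adopt_rate": round_half_away(self.adopt_rate, ndigits),
            "gap_ratio": round_half_away(self.gap_ratio, ndigits),
            "cell_code": self.cell.code,
        }


def adoption_gap_ratio(
    aware_count: float, want_count: float, adopt_count: float
) -> float:
    """Adoption gap ratio in percent, computed on raw counts (or rates).

    Returns 100*(min(A,W)-U)/min(A,W); 0 when adoption saturates the
    smaller of the aware/want groups, 100 when nobody adopted.  A U
    exceeding min(A, W) (possible under any-item aggregation) is clipped
    to a gap of 0 with a warning rather than reported negative.
    """
    if aware_count < 0 or want_count < 0 or adopt_count < 0:
        raise ValueError("counts must be non-negative")
    m = min(aware_count, want_count)
    if m == 0:
        raise ValueError("gap ratio undefined when min(aware, want) == 0")
    if adopt_count > m:
        warnings.warn(
            f"adoption count {adopt_count} exceeds min(aware, want)={m}; "
            "gap clipped to 0",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * (m - adopt_count) / m


def _or_reduce(values: Sequence[int | None]) -> int | None:
    """Any-item OR with missing-propagation: missing only if all missing."""
    seen = [v for v in values if v is not None]
    if not seen:
        return None
    return int(any(seen))


def aggregate_category(
    records: Iterable[RespondentRecord],
    catalog: ServiceCatalog,
    category: Category | str,
) -> list[BinaryAWA]:
    """Per-respondent category-level indicators under the any-item rule.

    A respondent is aware of (wants / adopted) a category iff the
    corresponding indicator is 1 for at least one item in it; ``"overall"``
    pools all items.  A field is missing only when it is missing for every
    item in the category.
    """
    items = catalog.items_in(category)
    if not items:
        raise ValueError(f"unknown or empty category {category!r}")
    ids = [it.item_id for it in items]
    out: list[BinaryAWA] = []
    for rec in records:
        coded = [code_awa(rec.responses.get(i, _EMPTY)) for i in ids]
        out.append(
            BinaryAWA(
                awareness=_or_reduce([c.awareness for c in coded]),
                want=_or_reduce([c.want for c in coded]),
                adoption=_or_reduce([c.adoption for c in coded]),
            )
        )
    return out


def compute_rates(awa: Sequence[BinaryAWA], n_label: str) -> CategoryRates:
    """Counts and percentage rates over non-missing respondents.

    ``n`` is the number of respondents with at least one non-missing field;
    each count is taken over respondents non-missing on that field.
    """
    rows = [a for a in awa if (a.awareness, a.want, a.adoption) != (None, None, None)]
    if not rows:
        raise ValueError("no non-missing respondents")
    n = len(rows)
    aware = sum(a.awareness for a in rows if a.awareness is not None)
    want = sum(a.want for a in rows if a.want is not None)
    adopt = sum(a.adoption for a in rows if a.adoption is not None)
    return CategoryRates(
        category=str(getattr(n_label, "value", n_label)),
        n=n,
        aware_count=int(aware),
        want_count=int(want),
        adopt_count=int(adopt),
        aware_rate=100.0 * aware / n,
        want_rate=100.0 * want / n,
        adopt_rate=100.0 * adopt / n,
        gap_ratio=adoption_gap_ratio(aware, want, adopt),
    )


# Tier index along one axis: 0=[0,15), 1=[15,50), 2=[50,85), 3=[85,100].
def _tier(rate: float) -> int:
    if not 0.0 <= rate <= 100.0:
        raise ValueError(f"rate {rate} outside [0, 100]")
    if rate < 15.0:
        return 0
    if rate < 50.0:
        return 1
    if rate < 85.0:
        return 2
    return 3


def classify_awag(aware_rate: float, want_rate: float) -> AwagCell:
    """Classify a (awareness, want) rate pair into one of the 16 cells.

    Groups split at 50 on both axes.  Within a group each axis falls in
    either its moderate tier or its extreme tier (85+ on a high axis,
    <15 on a low axis); strong = both extreme, generic = both moderate,
    want-bias = awareness extreme only (high awareness, lagging want in
    the opened group), awareness-bias = want extreme only.
    """
    ta, tw = _tier(aware_rate), _tier(want_rate)
    high_a, high_w = ta >= 2, tw >= 2
    if high_a and high_w:
        group = "opened"
    elif high_a:
        group = "desire_deficiency"
    elif high_w:
        group = "perception_deficiency"
    else:
        group = "closed"
    # an axis is in its quadrant's extreme tier at 85+ (high half) or <15 (low half)
    ext_a = ta == 3 if high_a else ta == 0
    ext_w = tw == 3 if high_w else tw == 0
    if ext_a and ext_w:
        sub = "strong"
    elif not ext_a and not ext_w:
        sub = "generic"
    elif ext_a:
        sub = "want_bias"
    else:
        sub = "awareness_bias"
    return AwagCell(group, sub)


@dataclass(frozen=True)
class MatrixFigureData:
    """Bubble-plot data for the segmentation matrix.

    One bubble per category at (awareness rate, want rate); bubble size is
    strictly increasing in the gap ratio; grid lines at 15/50/85 on both
    axes.
    """

    bubbles: tuple[dict, ...]
    grid_lines: tuple[float, ...] = (15.0, 50.0, 85.0)

    def to_json(self) -> str:
        return json.dumps(
            {"grid_lines": list(self.grid_lines), "bubbles": list(self.bubbles)},
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "MatrixFigureData":
        obj = json.loads(text)
        return cls(
            bubbles=tuple(obj["bubbles"]), grid_lines=tuple(obj["grid_lines"])
        )


def build_matrix_figure(
    rates: Iterable[CategoryRates], *, size_range: tuple[float, float] = (200.0, 2000.0)
) -> MatrixFigureData:
    """Figure data for the AWAG matrix: one bubble per category.

    Bubble areas map the gap ratio affinely from [0, 100] onto
    ``size_range`` so equal gaps get equal sizes and larger gaps strictly
    larger bubbles.
    """
    lo, hi = size_range
    bubbles = []
    for r in rates:
        cell = r.cell
        bubbles.append(
            {
                "category": r.category,
                "x": r.aware_rate,
                "y": r.want_rate,
                "gap_ratio": r.gap_ratio,
                "bubble_size": lo + (hi - lo) * r.gap_ratio / 100.0,
                "cell_code": cell.code,
                "group": cell.group,
                "subregion": cell.subregion,
            }
        )
    return MatrixFigureData(bubbles=tuple(bubbles))


def render_matrix_figure(fig_data: MatrixFigureData, path: str) -> None:
    """Optional thin rendering layer (PNG/SVG) over the exported data."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    for g in fig_data.grid_lines:
        ax.axvline(g, color="0.8", lw=0.8, zorder=0)
        ax.axhline(g, color="0.8", lw=0.8, zorder=0)
    for b in fig_data.bubbles:
        ax.scatter(b["x"], b["y"], s=b["bubble_size"], alpha=0.5)
        ax.annotate(
            f"{b['category']}\n{b['cell_code']}",
            (b["x"], b["y"]),
            fontsize=7,
            ha="center",
        )
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("Awareness rate (%)")
    ax.set_ylabel("Want rate (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
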