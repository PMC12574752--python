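"""Gap-ratio statistic, rate computation, 16-cell segmentation, figure data."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from awagkit.awag import (
    AwagCell,
    MatrixFigureData,
    adoption_gap_ratio,
    aggregate_category,
    build_matrix_figure,
    classify_awag,
    compute_rates,
    round_half_away,
)
from awagkit.scoring import BinaryAWA
from awagkit.survey_io import ItemResponse
from conftest import awa_from_counts, make_record


class TestGapRatio:
    @pytest.mark.parametrize(
        "a,w,u,expected",
        [
            (1128, 1037, 704, 32.1),  # information-based
            (1182, 1142, 753, 34.1),  # treatment intermediary
            (986, 924, 310, 66.5),  # treatment
            (1204, 1169, 847, 27.5),  # overall (computed from counts)
            (500, 400, 400, 0.0),  # adoption saturates min(A, W)
            (500, 400, 0, 100.0),  # nobody adopted
        ],
    )
    def test_reference_values(self, a, w, u, expected):
        assert round_half_away(adoption_gap_ratio(a, w, u)) == expected

    def test_undefined_when_no_aware_or_want(self):
        with pytest.raises(ValueError):
            adoption_gap_ratio(0, 10, 0)

    def test_excess_adoption_clips_to_zero_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert adoption_gap_ratio(50, 40, 45) == 0.0

    @given(
        a=st.integers(1, 2000),
        w=st.integers(1, 2000),
        u=st.integers(0, 2000),
        c=st.integers(2, 17),
    )
    def test_scale_invariance(self, a, w, u, c):
        u = min(u, min(a, w))
        assert adoption_gap_ratio(a, w, u) == pytest.approx(
            adoption_gap_ratio(c * a, c * w, c * u)
        )

    @given(a=st.integers(1, 500), w=st.integers(1, 500))
    def test_strictly_decreasing_in_adoption(self, a, w):
        m = min(a, w)
        gaps = [adoption_gap_ratio(a, w, u) for u in range(m + 1)]
        assert all(x > y for x, y in zip(gaps, gaps[1:]))
        assert gaps[0] == 100.0 and gaps[-1] == 0.0

    def test_counts_agree_with_rates_formula(self):
        # n cancels: gap from raw counts equals gap from unrounded rates
        n = 1322
        for a, w, u in [(1128, 1037, 704), (986, 924, 310)]:
            from_counts = adoption_gap_ratio(a, w, u)
            from_rates = adoption_gap_ratio(100 * a / n, 100 * w / n, 100 * u / n)
            assert from_counts == pytest.approx(from_rates, abs=1e-12)


class TestComputeRates:
    def test_published_row(self):
        r = compute_rates(awa_from_counts(1322, 1204, 1169, 847), "overall")
        assert (r.aware_count, r.want_count, r.adopt_count) == (1204, 1169, 847)
        assert round_half_away(r.aware_rate) == 91.1
        assert round_half_away(r.want_rate) == 88.4
        assert round_half_away(r.adopt_rate) == 64.1

    def test_treatment_row_reports_computed_rate(self):
        # printed "23.1" is inconsistent with its own counts; 310/1322 = 23.4%
        r = compute_rates(awa_from_counts(1322, 986, 924, 310), "treatment")
        assert round_half_away(r.adopt_rate) == 23.4

    def test_saturated(self):
        r = compute_rates(awa_from_counts(10, 10, 10, 10), "x")
        assert r.aware_rate == r.want_rate == r.adopt_rate == 100.0
        assert r.gap_ratio == 0.0

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            compute_rates([BinaryAWA(None, None, None)], "x")


class TestClassify:
    @pytest.mark.parametrize(
        "aware,want,code",
        [
            (85.3, 78.4, "O _ Wb"),
            (89.4, 86.4, "O _ S"),
            (74.6, 69.9, "O _ G"),
            (91.1, 88.4, "O _ S"),
            (10, 10, "C _ S"),
            (30, 30, "C _ G"),
            (60, 30, "D _ G"),
            (30, 60, "P _ G"),
            (90, 10, "D _ S"),
        ],
    )
    def test_examples(self, aware, want, code):
        assert classify_awag(aware, want).code == code

    def test_boundary_convention(self):
        # >= at each upper-tier boundary
        assert classify_awag(85.0, 85.0).code == "O _ S"
        assert classify_awag(50.0, 50.0).code == "O _ G"
        assert classify_awag(15.0, 15.0).code == "C _ G"
        assert classify_awag(49.999, 49.999).code == "C _ G"

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_awag(101.0, 50.0)
        with pytest.raises(ValueError):
            classify_awag(50.0, -0.1)

    def test_sixteen_cell_partition(self):
        """Every point of [0,100]^2 maps to exactly one of the 16 cells and
        all 16 are reachable."""
        grid = np.linspace(0, 100, 201)
        seen = set()
        for a in grid:
            for w in grid:
                cell = classify_awag(float(a), float(w))
                assert cell.group in (
                    "opened", "perception_deficiency", "desire_deficiency", "closed",
                )
                assert cell.subregion in (
                    "strong", "generic", "want_bias", "awareness_bias",
                )
                seen.add((cell.group, cell.subregion))
        assert len(seen) == 16

    def test_code_round_trip(self):
        for g in ("opened", "perception_deficiency", "desire_deficiency", "closed"):
            for s in ("strong", "generic", "want_bias", "awareness_bias"):
                cell = AwagCell(g, s)
                assert AwagCell.from_code(cell.code) == cell


class TestAggregate:
    def _record_with_pattern(self, catalog, pattern, rid="r"):
        """pattern: dict item_id -> (heard, intention, use)."""
        responses = {
            k: ItemResponse(heard=h, intention=i, use=u)
            for k, (h, i, u) in pattern.items()
        }
        return make_record(respondent_id=rid, responses=responses)

    def test_single_aware_item_flags_category(self, catalog):
        info_ids = [it.item_id for it in catalog.items_in("information_based")]
        pattern = {i: (1, 1, 1) for i in info_ids}
        pattern[info_ids[2]] = (2, 1, 1)
        rec = self._record_with_pattern(catalog, pattern)
        (awa,) = aggregate_category([rec], catalog, "information_based")
        assert (awa.awareness, awa.want, awa.adoption) == (1, 0, 0)

    def test_all_zero_patterns(self, catalog):
        pattern = {i: (1, 1, 1) for i in catalog.item_ids}
        rec = self._record_with_pattern(catalog, pattern)
        for cat in ("information_based", "treatment_intermediary", "treatment", "overall"):
            (awa,) = aggregate_category([rec], catalog, cat)
            assert (awa.awareness, awa.want, awa.adoption) == (0, 0, 0)

    def test_any_item_rule_is_logical_or_exhaustive(self, catalog):
        """Brute-force enumeration over all 2^4 awareness patterns of the
        four information items."""
        info_ids = [it.item_id for it in catalog.items_in("information_based")]
        for bits in itertools.product([0, 1], repeat=4):
            pattern = {i: (2 if b else 1, 1, 1) for i, b in zip(info_ids, bits)}
            rec = self._record_with_pattern(catalog, pattern)
            (awa,) = aggregate_category([rec], catalog, "information_based")
            assert awa.awareness == int(any(bits))

    def test_missing_only_if_all_items_missing(self, catalog):
        info_ids = [it.item_id for it in catalog.items_in("information_based")]
        pattern = {info_ids[0]: (2, None, None)}
        rec = self._record_with_pattern(catalog, pattern)
        (awa,) = aggregate_category([rec], catalog, "information_based")
        assert awa.awareness == 1 and awa.want is None and awa.adoption is None

    def test_random_fixtures_match_numpy_oracle(self, catalog):
        rng = np.random.default_rng(42)
        ids = list(catalog.item_ids)
        heard = rng.integers(1, 3, size=(30, 12))
        recs = [
            self._record_with_pattern(
                catalog,
                {i: (int(heard[r, j]), 1, 1) for j, i in enumerate(ids)},
                rid=f"r{r}",
            )
            for r in range(30)
        ]
        got = [a.awareness for a in aggregate_category(recs, catalog, "overall")]
        expected = (heard == 2).any(axis=1).astype(int).tolist()
        assert got == expected

    def test_unknown_category_rejected(self, catalog):
        with pytest.raises(ValueError):
            aggregate_category([], catalog, "nonexistent")


class TestFigureData:
    def _rates(self, table3_counts):
        return [
            compute_rates(awa_from_counts(1322, *table3_counts[c]), c)
            for c in ("information_based", "treatment_intermediary", "treatment")
        ]

    def test_three_bubbles_largest_is_treatment(self, table3_counts):
        fig = build_matrix_figure(self._rates(table3_counts))
        assert len(fig.bubbles) == 3
        largest = max(fig.bubbles, key=lambda b: b["bubble_size"])
        assert largest["category"] == "treatment"

    def test_bubble_size_monotone_in_gap(self, table3_counts):
        fig = build_matrix_figure(self._rates(table3_counts))
        by_gap = sorted(fig.bubbles, key=lambda b: b["gap_ratio"])
        sizes = [b["bubble_size"] for b in by_gap]
        assert sizes == sorted(sizes) and len(set(sizes)) == len(sizes)

    def test_equal_gaps_equal_sizes(self):
        r1 = compute_rates(awa_from_counts(100, 80, 70, 35), "a")
        r2 = compute_rates(awa_from_counts(200, 160, 140, 70), "b")
        fig = build_matrix_figure([r1, r2])
        assert fig.bubbles[0]["bubble_size"] == fig.bubbles[1]["bubble_size"]

    def test_json_round_trip_preserves_codes(self, table3_counts):
        fig = build_matrix_figure(self._rates(table3_counts))
        back = MatrixFigureData.from_json(fig.to_json())
        assert [b["cell_code"] for b in back.bubbles] == [
            b["cell_code"] for b in fig.bubbles
        ]
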