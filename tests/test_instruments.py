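"""Instrument scoring: printed endpoints, formula fidelity, monotonicity,
and the interval reconstruction rule."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_record
from psoriastat.instruments import (
    AREAS,
    DEFAULT_AREA_WEIGHTS,
    DigitFlags,
    PaseAnswers,
    PsaaItems,
    PwesiArea,
    RegionAssessment,
    extent_category,
    region_intervals_from_total,
    score_digit_count,
    score_pase,
    score_pasi,
    score_psaa,
    score_pwesi,
    score_xl_pasi,
    validate_record,
)
from psoriastat.intervals import Interval


class TestExtentCategory:
    @pytest.mark.parametrize(
        "pct,expected",
        [
            (0, 0),
            (0.5, 1),
            (1, 1),
            (9, 1),
            (9.9, 1),
            (10, 2),
            (29, 2),
            (30, 3),
            (49.9, 3),
            (50, 4),
            (69, 4),
            (70, 5),
            (89.5, 5),
            (90, 6),
            (100, 6),
        ],
    )
    def test_printed_bins(self, pct, expected):
        assert extent_category(pct) == expected

    def test_monotone_and_surjective(self):
        grid = np.linspace(0, 100, 2001)
        cats = [extent_category(p) for p in grid]
        assert all(b >= a for a, b in zip(cats, cats[1:]))
        assert set(cats) == set(range(7))

    @pytest.mark.parametrize("pct", [-1, 101, 150.0])
    def test_domain_error(self, pct):
        with pytest.raises(ValueError):
            extent_category(pct)


class TestPasi:
    @pytest.mark.parametrize(
        "args,expected",
        [
            ((100, 4, 4, 4), 72),  # printed scale maximum
            ((0, 0, 0, 0), 0),
            ((35, 2, 1, 3), 18),  # category(35)=3, 3*(2+1+3)
        ],
    )
    def test_printed_formula(self, args, expected):
        assert score_pasi(*args) == expected

    @given(
        pct=st.floats(0, 100),
        e=st.integers(0, 4),
        s=st.integers(0, 4),
        t=st.integers(0, 4),
    )
    def test_equals_product_formula(self, pct, e, s, t):
        assert score_pasi(pct, e, s, t) == extent_category(pct) * (e + s + t)

    @pytest.mark.parametrize("bad", [(50, 5, 0, 0), (50, 0, -1, 0), (50, 0, 0, 2.5)])
    def test_out_of_range_items(self, bad):
        with pytest.raises(ValueError):
            score_pasi(*bad)


def _regions(extent=0.0, e=0, t=0, s=0):
    return [RegionAssessment(a, extent, e, t, s) for a in AREAS]


class TestXlPasi:
    def test_printed_endpoints(self):
        assert score_xl_pasi(_regions(100.0, 4, 4, 4), 4, 4, 4, 4) == pytest.approx(148.0)
        assert score_xl_pasi(_regions()) == 0.0

    def test_single_area_composite(self):
        regions = _regions()
        regions[3] = RegionAssessment(AREAS[3], 100.0, 4, 4, 4)
        assert score_xl_pasi(regions) == pytest.approx(148 * 12 / 136)

    def test_interval_extent_gives_interval_score(self):
        regions = _regions()
        regions[0] = RegionAssessment(AREAS[0], Interval(20, 80), 2, 2, 2)
        out = score_xl_pasi(regions)
        assert isinstance(out, Interval)
        lo_regions, hi_regions = _regions(), _regions()
        lo_regions[0] = RegionAssessment(AREAS[0], 20.0, 2, 2, 2)
        hi_regions[0] = RegionAssessment(AREAS[0], 80.0, 2, 2, 2)
        assert out.lo == pytest.approx(score_xl_pasi(lo_regions))
        assert out.hi == pytest.approx(score_xl_pasi(hi_regions))

    def test_skin_only_variant_maximum(self):
        assert score_xl_pasi(
            _regions(100.0, 4, 4, 4), include_globals=False
        ) == pytest.approx(148.0)
        # globals do not move the skin-only score
        assert score_xl_pasi(
            _regions(50.0, 2, 2, 2), 4, 4, 4, 4, include_globals=False
        ) == score_xl_pasi(_regions(50.0, 2, 2, 2), include_globals=False)

    @given(st.data())
    def test_monotone_in_every_item(self, data):
        r = data.draw(st.randoms(use_true_random=False))
        regions = [
            RegionAssessment(
                a,
                float(r.randint(0, 99)),
                r.randint(0, 3),
                r.randint(0, 3),
                r.randint(0, 3),
            )
            for a in AREAS
        ]
        base = score_xl_pasi(regions)
        k = r.randrange(10)
        item = r.choice(["extent", "erythema", "thickness", "scaling"])
        bumped = list(regions)
        kwargs = {
            f: getattr(regions[k], f)
            for f in ("extent", "erythema", "thickness", "scaling")
        }
        kwargs[item] = kwargs[item] + 1
        bumped[k] = RegionAssessment(AREAS[k], **kwargs)
        assert score_xl_pasi(bumped) >= base

    def test_order_invariance(self, rng):
        regions = [
            RegionAssessment(a, float(rng.integers(0, 101)), 1, 2, 3) for a in AREAS
        ]
        shuffled = [regions[i] for i in rng.permutation(10)]
        assert score_xl_pasi(regions) == pytest.approx(score_xl_pasi(shuffled))

    def test_duplicate_area_rejected(self):
        regions = _regions()
        regions[1] = RegionAssessment(AREAS[0], 10.0, 1, 1, 1)
        with pytest.raises(ValueError):
            score_xl_pasi(regions)


class TestPwesi:
    def test_printed_endpoints_and_single_area(self):
        assert score_pwesi([PwesiArea(a, 4, 4) for a in AREAS]) == pytest.approx(50.0)
        assert score_pwesi([PwesiArea(a, 0, 0) for a in AREAS]) == 0.0
        areas = [PwesiArea(a, 0, 0) for a in AREAS]
        areas[0] = PwesiArea(AREAS[0], 4, 4)
        assert score_pwesi(areas) == pytest.approx(5.0)

    def test_order_invariance_and_monotonicity(self, rng):
        areas = [
            PwesiArea(a, int(rng.integers(0, 5)), int(rng.integers(0, 4))) for a in AREAS
        ]
        shuffled = [areas[i] for i in rng.permutation(10)]
        assert score_pwesi(areas) == pytest.approx(score_pwesi(shuffled))
        bumped = list(areas)
        bumped[2] = PwesiArea(AREAS[2], areas[2].extent, areas[2].severity + 1)
        assert score_pwesi(bumped) > score_pwesi(areas)

    def test_out_of_range(self):
        areas = [PwesiArea(a, 0, 0) for a in AREAS]
        areas[0] = PwesiArea(AREAS[0], 5, 0)
        with pytest.raises(ValueError):
            score_pwesi(areas)


class TestQuestionnaires:
    @pytest.mark.parametrize(
        "answer,expected",
        [(1, (7, 8, 15)), (5, (35, 40, 75)), (3, (21, 24, 45))],
    )
    def test_pase_subscores(self, answer, expected):
        assert score_pase(PaseAnswers([answer] * 7, [answer] * 8)) == expected

    @pytest.mark.parametrize(
        "answers",
        [
            PaseAnswers([1] * 6, [1] * 8),  # wrong symptom count
            PaseAnswers([1] * 7, [1] * 9),  # wrong function count
            PaseAnswers([0] + [1] * 6, [1] * 8),  # below scale
            PaseAnswers([1] * 7, [6] + [1] * 7),  # above scale
        ],
    )
    def test_pase_domain_errors(self, answers):
        with pytest.raises(ValueError):
            score_pase(answers)

    @pytest.mark.parametrize(
        "items,expected",
        [
            (PsaaItems([0, 0], [0] * 6), 0.0),
            (PsaaItems([1, 1], [4] * 6), 26.0),
            (PsaaItems([1, 0], [1, 0, 0, 0, 0, 0]), 2.0),
        ],
    )
    def test_psaa_default_map(self, items, expected):
        assert score_psaa(items) == expected

    def test_psaa_custom_item_map(self):
        items = PsaaItems([1, 1], [2] * 6)
        assert score_psaa(items, item_weights=[2, 2] + [0.5] * 6) == pytest.approx(10.0)

    def test_psaa_invalid_counts(self):
        with pytest.raises(ValueError):
            score_psaa(PsaaItems([1], [0] * 6))
        with pytest.raises(ValueError):
            score_psaa(PsaaItems([1, 0], [0] * 5))

    @pytest.mark.parametrize(
        "flags,expected",
        [([1] * 10, 10), ([0] * 10, 0), ([1, 0, 1, 0, 0, 0, 0, 0, 0, 0], 2)],
    )
    def test_digit_count(self, flags, expected):
        assert score_digit_count(DigitFlags(flags)) == expected

    def test_digit_count_rejects_nonbinary(self):
        with pytest.raises(ValueError):
            score_digit_count(DigitFlags([2] + [0] * 9))
        with pytest.raises(ValueError):
            score_digit_count(DigitFlags([0] * 9))


class TestRegionIntervals:
    def test_degenerate_totals(self):
        zero = region_intervals_from_total(0.0)
        full = region_intervals_from_total(100.0)
        for a in AREAS:
            assert (zero[a].lo, zero[a].hi) == (0.0, 0.0)
            assert (full[a].lo, full[a].hi) == (100.0, 100.0)

    def test_worked_bounds(self):
        # a 5%-weight region under 97% total involvement: at least
        # (0.97-0.95)/0.05 = 40% of it must be involved
        iv = region_intervals_from_total(97.0)["hands_fingers"]
        assert iv.lo == pytest.approx(40.0)
        assert iv.hi == pytest.approx(100.0)

    def test_feasible_allocations_are_contained(self, rng):
        """Brute-force oracle: random allocations with a given total always
        fall inside the reconstructed intervals."""
        weights = DEFAULT_AREA_WEIGHTS
        warr = np.array([weights[a] for a in AREAS])
        for _ in range(40):
            # random feasible allocation via random per-region extents
            extents = rng.uniform(0, 100, 10) * rng.integers(0, 2, 10)
            total = float(warr @ extents)
            ivs = region_intervals_from_total(total)
            for a, e in zip(AREAS, extents):
                assert ivs[a].lo - 1e-9 <= e <= ivs[a].hi + 1e-9

    def test_bounds_are_attainable(self, rng):
        """Each reported bound is realized by some feasible allocation:
        put as much (or as little) as possible in the region and spread
        the remainder greedily over the others."""
        warr = np.array([DEFAULT_AREA_WEIGHTS[a] for a in AREAS])
        for total in (3.0, 20.0, 55.0, 97.0):
            ivs = region_intervals_from_total(total)
            T = total / 100.0
            for k, a in enumerate(AREAS):
                for bound in (ivs[a].lo, ivs[a].hi):
                    rest = T - warr[k] * bound / 100.0
                    capacity = 1.0 - warr[k]
                    assert -1e-12 <= rest <= capacity + 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            region_intervals_from_total(101.0)
        bad = dict(DEFAULT_AREA_WEIGHTS)
        bad["hands_fingers"] = 0.0
        bad["feet_toes"] += 0.05
        with pytest.raises(ValueError):
            region_intervals_from_total(50.0, bad)


class TestValidateRecord:
    def test_valid_record_is_clean(self):
        assert validate_record(make_record(extent=30.0, severity=2, pase_answer=3)) == []

    def test_out_of_range_erythema_names_region(self):
        rec = make_record()
        rec.regions[2].erythema = 5
        violations = validate_record(rec)
        assert len(violations) == 1
        assert AREAS[2] in violations[0] and "erythema" in violations[0]

    def test_short_digit_flags_names_length_rule(self):
        rec = make_record()
        rec.nails.flags = [0] * 9
        assert any("nails" in v and "10" in v for v in validate_record(rec))

    def test_missing_area_detected(self):
        rec = make_record()
        rec.regions = rec.regions[:9]
        assert any("one assessment per body area" in v for v in validate_record(rec))
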