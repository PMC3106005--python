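"""Clinical severity instruments for psoriasis and psoriatic arthritis.

Implements the scoring rules for the seven assessment tools used in the
analysis:

* **PASI** — global extent category (0–6) × sum of erythema, scaling and
  thickness scores (each 0–4); range 0–72.
* **XL-PASI** — ten body areas, each with a numerically estimated percent
  extent and 0–4 erythema/thickness/scaling, plus four global items
  (arthritis, quality of life, pain, itch); composite rescaled to 0–148.
* **PWESI** — ten body areas, extent and severity each 0–4; composite
  rescaled to 0–50.
* **PASE** — patient questionnaire, 7 symptom + 8 function items each 1–5;
  subscores and total (15–75).
* **PsAA** — physician arthritis assessment: 2 binary history items plus
  6 ordinal 0–4 exam components, summed (0–26 with unit weights).
* **NA / JA** — per-digit binary nail / joint involvement on the ten
  fingers; tool score is the digit count (0–10).

Also implements the interval reconstruction rule for an assessor who
recorded only total body involvement: each region's extent is then known
only up to the interval of values consistent with that total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from numbers import Real
from typing import Mapping, Sequence

from .intervals import Interval, as_interval

# The ten assessed body areas, in canonical order.
AREAS: tuple[str, ...] = (
    "scalp_hairline",
    "face_neck",
    "arms_axillae",
    "hands_fingers",
    "chest_abdomen",
    "back_shoulders",
    "genitalia_perineum",
    "buttocks_thighs",
    "knees_lower_legs",
    "feet_toes",
)

# Rule-of-nines-inspired body-surface fractions; configurable, must sum to 1.
DEFAULT_AREA_WEIGHTS: dict[str, float] = {
    "scalp_hairline": 0.05,
    "face_neck": 0.05,
    "arms_axillae": 0.15,
    "hands_fingers": 0.05,
    "chest_abdomen": 0.15,
    "back_shoulders": 0.15,
    "genitalia_perineum": 0.01,
    "buttocks_thighs": 0.14,
    "knees_lower_legs": 0.15,
    "feet_toes": 0.10,
}

#: Maximum raw XL-PASI: 10 areas × (1.0 extent × 12 severity) + 4 globals × 4.
_XL_PASI_RAW_MAX = 10 * 12 + 4 * 4
_XL_PASI_SKIN_RAW_MAX = 10 * 12
XL_PASI_MAX = 148.0
PWESI_MAX = 50.0
PASI_MAX = 72.0


def validate_area_weights(weights: Mapping[str, float]) -> None:
    """Raise ValueError unless `weights` covers the 10 areas, positive, sum 1."""
    if set(weights) != set(AREAS):
        raise ValueError("weights must cover exactly the 10 canonical body areas")
    if any(w <= 0 for w in weights.values()):
        raise ValueError("area weights must be strictly positive")
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"area weights must sum to 1.0, got {total}")


# ---------------------------------------------------------------------------
# Record containers.  These are plain data holders; scoring functions and
# validate_record() enforce the range rules, so malformed records can be
# constructed deliberately (e.g. for data-entry validation tests).
# ---------------------------------------------------------------------------


@dataclass
class RegionAssessment:
    """One body area's XL-PASI items: extent % (scalar or interval) and
    0–4 erythema / thickness / scaling / arthritis."""

    area: str
    extent: "Real | Interval"
    erythema: int
    thickness: int
    scaling: int
    arthritis: int = 0


@dataclass
class PwesiArea:
    """One body area's PWESI items: extent and severity, each 0–4."""

    area: str
    extent: int
    severity: int


@dataclass
class PaseAnswers:
    """PASE questionnaire answers: 7 symptom + 8 function items, each 1–5."""

    symptom: Sequence[int]
    function: Sequence[int]


@dataclass
class DigitFlags:
    """Binary involvement flags for the ten fingers (left thumb → right
    little finger); ``domain`` distinguishes nail (NA) from joint (JA)."""

    flags: Sequence[int]
    domain: str = "nail"


@dataclass
class PsaaItems:
    """PsAA items: (patient history, family history) binaries plus six
    ordinal 0–4 physical-exam components."""

    history: Sequence[int]
    exam: Sequence[int]


@dataclass
class PatientRecord:
    """All instrument items for one patient."""

    patient_id: str
    assessor_id: str
    regions: list[RegionAssessment]
    pwesi: list[PwesiArea]
    pase: PaseAnswers
    psaa: PsaaItems
    nails: DigitFlags
    joints: DigitFlags
    global_pga: int
    quality_of_life: int = 0
    pain: int = 0
    itch: int = 0
    toe_nail_any: int | None = None
    toe_joint_any: int | None = None
    extras: dict = field(default_factory=dict)

    def region(self, area: str) -> RegionAssessment:
        for r in self.regions:
            if r.area == area:
                return r
        raise KeyError(area)

    def pwesi_area(self, area: str) -> PwesiArea:
        for p in self.pwesi:
            if p.area == area:
                return p
        raise KeyError(area)

    @property
    def global_arthritis(self) -> int:
        """XL-PASI global arthritis indicator: worst per-region arthritis."""
        return max(int(r.arthritis) for r in self.regions)


# ---------------------------------------------------------------------------
# Scoring operations
# ---------------------------------------------------------------------------


def _check_ordinal(value, name: str, lo: int = 0, hi: int = 4) -> int:
    if not isinstance(value, Real) or value != int(value) or not lo <= value <= hi:
        raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {value!r}")
    return int(value)


_CATEGORY_EDGES = (0.0, 10.0, 30.0, 50.0, 70.0, 90.0)


def extent_category(pct: float) -> int:
    """PASI extent-of-involvement category for a percent body surface area.

    Bins: 0 → 0; (0, 10) → 1; [10, 30) → 2; [30, 50) → 3; [50, 70) → 4;
    [70, 90) → 5; [90, 100] → 6.  Printed closed integer ranges (1–9,
    10–29, …) are treated as half-open at the upper edge for fractional
    inputs; 100 belongs to the top category.
    """
    if not isinstance(pct, Real):
        raise ValueError(f"extent percent must be numeric, got {pct!r}")
    pct = float(pct)
    if not 0.0 <= pct <= 100.0:
        raise ValueError(f"extent percent must lie in [0, 100], got {pct}")
    cat = 0
    for edge in _CATEGORY_EDGES:
        if pct > edge or (cat >= 1 and pct == edge):
            cat += 1
        else:
            break
    return cat


def score_pasi(extent_pct: float, erythema: int, scaling: int, thickness: int) -> int:
    """PASI as printed on the study form: extent category × (E + S + T).

    Range 0–72.  Note this is the single-category variant used in the
    source analysis, not the classical four-region-weighted PASI.
    """
    cat = extent_category(extent_pct)
    e = _check_ordinal(erythema, "erythema")
    s = _check_ordinal(scaling, "scaling")
    t = _check_ordinal(thickness, "thickness")
    return cat * (e + s + t)


def _check_region(region: RegionAssessment) -> None:
    if region.area not in AREAS:
        raise ValueError(f"unknown body area {region.area!r}")
    iv = as_interval(region.extent)
    if not (0.0 <= iv.lo <= iv.hi <= 100.0):
        raise ValueError(f"{region.area}: extent interval must lie in [0, 100]")
    for name in ("erythema", "thickness", "scaling", "arthritis"):
        _check_ordinal(getattr(region, name), f"{region.area}.{name}")


def _check_unique_areas(items, what: str) -> None:
    areas = [getattr(it, "area") for it in items]
    if sorted(areas) != sorted(AREAS):
        raise ValueError(f"{what} must contain exactly one entry per body area")


def score_xl_pasi(
    regions: Sequence[RegionAssessment],
    quality_of_life: int = 0,
    pain: int = 0,
    itch: int = 0,
    global_arthritis: int = 0,
    rescale: bool = True,
    include_globals: bool = True,
) -> "float | Interval":
    """XL-PASI composite over ten areas plus four global items.

    raw = Σ_areas (extent/100)·(erythema + thickness + scaling)
          + arthritis + quality_of_life + pain + itch,

    linearly rescaled so the maximum is exactly 148 (``rescale=False``
    returns the raw sum; the downstream rank-based analysis is invariant
    to this strictly increasing rescale).  If any region extent is an
    :class:`Interval`, the result is the interval of composites obtained
    at the extent lower / upper bounds (the composite is monotone in
    every extent).

    ``include_globals=False`` drops the four extension items (arthritis,
    quality of life, pain, itch) from the composite, leaving the pure
    skin score, again linearized to the 0–148 endpoint.  This is the
    variant used for tool-level correlations: the instrument *records*
    the extension items, but a skin-severity tool score that contained
    an arthritis item would correlate with the joint instruments by
    construction.
    """
    _check_unique_areas(regions, "regions")
    for r in regions:
        _check_region(r)
    globals_sum = sum(
        _check_ordinal(v, n)
        for v, n in (
            (global_arthritis, "global_arthritis"),
            (quality_of_life, "quality_of_life"),
            (pain, "pain"),
            (itch, "itch"),
        )
    )
    lo_raw = hi_raw = float(globals_sum) if include_globals else 0.0
    interval_input = False
    for r in regions:
        sev = r.erythema + r.thickness + r.scaling
        lo, hi = as_interval(r.extent).lo, as_interval(r.extent).hi
        interval_input |= lo != hi
        lo_raw += lo / 100.0 * sev
        hi_raw += hi / 100.0 * sev
    raw_max = _XL_PASI_RAW_MAX if include_globals else _XL_PASI_SKIN_RAW_MAX
    scale = XL_PASI_MAX / raw_max if rescale else 1.0
    if interval_input:
        return Interval(lo_raw * scale, hi_raw * scale)
    return lo_raw * scale


def score_pwesi(areas: Sequence[PwesiArea], rescale: bool = True) -> float:
    """PWESI composite: Σ (extent + severity) over ten areas, rescaled to
    a maximum of 50 (raw maximum 80)."""
    _check_unique_areas(areas, "pwesi areas")
    raw = 0
    for a in areas:
        if a.area not in AREAS:
            raise ValueError(f"unknown body area {a.area!r}")
        raw += _check_ordinal(a.extent, f"{a.area}.extent")
        raw += _check_ordinal(a.severity, f"{a.area}.severity")
    return raw * (PWESI_MAX / 80.0) if rescale else float(raw)


def score_pase(answers: PaseAnswers) -> tuple[int, int, int]:
    """PASE (symptom subscore, function subscore, total).

    7 symptom items → 7–35; 8 function items → 8–40; total 15–75.
    """
    if len(answers.symptom) != 7:
        raise ValueError("PASE requires exactly 7 symptom answers")
    if len(answers.function) != 8:
        raise ValueError("PASE requires exactly 8 function answers")
    symptom = sum(_check_ordinal(a, "symptom answer", 1, 5) for a in answers.symptom)
    function = sum(_check_ordinal(a, "function answer", 1, 5) for a in answers.function)
    return symptom, function, symptom + function


def score_psaa(items: PsaaItems, item_weights: Sequence[float] | None = None) -> float:
    """PsAA composite: history indicators plus six exam components.

    With the default unit item map the range is 0–26 (2 binary history
    items + 6 exam components each 0–4).  ``item_weights`` (length 8:
    2 history then 6 exam) reweights the sum.
    """
    if len(items.history) != 2:
        raise ValueError("PsAA requires exactly 2 history indicators")
    if len(items.exam) != 6:
        raise ValueError("PsAA requires exactly 6 exam components")
    hx = [_check_ordinal(h, "history indicator", 0, 1) for h in items.history]
    ex = [_check_ordinal(e, "exam component", 0, 4) for e in items.exam]
    values = hx + ex
    if item_weights is None:
        return float(sum(values))
    if len(item_weights) != 8:
        raise ValueError("PsAA item map must have 8 weights (2 history + 6 exam)")
    return float(sum(w * v for w, v in zip(item_weights, values)))


def score_digit_count(flags: DigitFlags) -> int:
    """NA / JA tool score: number of involved digits (0–10)."""
    if len(flags.flags) != 10:
        raise ValueError("digit flags must have exactly 10 entries")
    total = 0
    for f in flags.flags:
        total += _check_ordinal(f, "digit flag", 0, 1)
    return total


def region_intervals_from_total(
    total_pct: float, weights: Mapping[str, float] | None = None
) -> dict[str, Interval]:
    """Sharpest per-region extent intervals consistent with a total BSA.

    For a region of body-surface fraction ``w`` and total involved
    fraction ``T = total_pct/100``:

    * at most ``min(w, T)`` of the body can be involved in the region, so
      ``hi = 100·min(1, T/w)``;
    * at least ``T − (1 − w)`` must be, since the other regions can absorb
      at most ``1 − w``, so ``lo = 100·max(0, (T − (1 − w))/w)``.

    Every feasible allocation of the total across regions lies within the
    returned intervals, and each bound is attained by some allocation.
    """
    if weights is None:
        weights = DEFAULT_AREA_WEIGHTS
    validate_area_weights(weights)
    if not isinstance(total_pct, Real) or not 0.0 <= float(total_pct) <= 100.0:
        raise ValueError(f"total percent must lie in [0, 100], got {total_pct!r}")
    T = float(total_pct) / 100.0
    out: dict[str, Interval] = {}
    for area in AREAS:
        w = weights[area]
        # bounds rounded to 1e-9 %: well below any clinical resolution,
        # keeps the degenerate totals (0, 100) exact and CSV round trips
        # bit-identical
        hi = round(100.0 * min(1.0, T / w), 9)
        lo = round(100.0 * max(0.0, (T - (1.0 - w)) / w), 9)
        out[area] = Interval(min(lo, hi), hi)
    return out


# ---------------------------------------------------------------------------
# Record validation
# ---------------------------------------------------------------------------


def _ordinal_ok(v, lo: int, hi: int) -> bool:
    return isinstance(v, Real) and v == int(v) and lo <= v <= hi


def validate_record(record: PatientRecord) -> list[str]:
    """Check every invariant of a patient record.

    Returns a list of human-readable violations (empty iff the record is
    valid); violations are data, never exceptions, so a whole cohort can
    be screened in one pass.
    """
    v: list[str] = []

    areas = [r.area for r in record.regions]
    if sorted(areas) != sorted(AREAS):
        v.append("regions: must contain exactly one assessment per body area")
    for r in record.regions:
        try:
            iv = as_interval(r.extent)
            if not (0.0 <= iv.lo <= iv.hi <= 100.0):
                v.append(f"regions[{r.area}].extent: interval outside [0, 100]")
        except (ValueError, TypeError):
            v.append(f"regions[{r.area}].extent: malformed interval")
        for name in ("erythema", "thickness", "scaling", "arthritis"):
            if not _ordinal_ok(getattr(r, name), 0, 4):
                v.append(f"regions[{r.area}].{name}: must be an integer in [0, 4]")

    pareas = [p.area for p in record.pwesi]
    if sorted(pareas) != sorted(AREAS):
        v.append("pwesi: must contain exactly one entry per body area")
    for p in record.pwesi:
        for name in ("extent", "severity"):
            if not _ordinal_ok(getattr(p, name), 0, 4):
                v.append(f"pwesi[{p.area}].{name}: must be an integer in [0, 4]")

    if len(record.pase.symptom) != 7:
        v.append("pase.symptom: must have exactly 7 answers")
    if len(record.pase.function) != 8:
        v.append("pase.function: must have exactly 8 answers")
    for part in ("symptom", "function"):
        for i, a in enumerate(getattr(record.pase, part)):
            if not _ordinal_ok(a, 1, 5):
                v.append(f"pase.{part}[{i}]: must be an integer in [1, 5]")

    if len(record.psaa.history) != 2:
        v.append("psaa.history: must have exactly 2 indicators")
    for i, h in enumerate(record.psaa.history):
        if not _ordinal_ok(h, 0, 1):
            v.append(f"psaa.history[{i}]: must be binary")
    if len(record.psaa.exam) != 6:
        v.append("psaa.exam: must have exactly 6 components")
    for i, e in enumerate(record.psaa.exam):
        if not _ordinal_ok(e, 0, 4):
            v.append(f"psaa.exam[{i}]: must be an integer in [0, 4]")

    for name, flags in (("nails", record.nails), ("joints", record.joints)):
        if len(flags.flags) != 10:
            v.append(f"{name}: must have exactly 10 digit flags")
        for i, f in enumerate(flags.flags):
            if not _ordinal_ok(f, 0, 1):
                v.append(f"{name}[{i}]: must be binary")

    if not _ordinal_ok(record.global_pga, 0, 7):
        v.append("global_pga: must be an integer in [0, 7]")
    for name in ("quality_of_life", "pain", "itch"):
        if not _ordinal_ok(getattr(record, name), 0, 4):
            v.append(f"{name}: must be an integer in [0, 4]")
    for name in ("toe_nail_any", "toe_joint_any"):
        val = getattr(record, name)
        if val is not None and not _ordinal_ok(val, 0, 1):
            v.append(f"{name}: must be binary when present")
    return v
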