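"""Interval-valued observations.

An :class:`Interval` represents a measurement known only to lie in
``[lo, hi]``.  Exact (scalar) observations are the degenerate case
``lo == hi``; every comparison routine in :mod:`psoriastat.ustat` treats
scalars and degenerate intervals identically.
"""

from __future__ import annotations

from dataclasses import dataclass
from numbers import Real


@dataclass(frozen=True, slots=True)
class Interval:
    """A value known only to lie between ``lo`` and ``hi`` (inclusive)."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (self.lo <= self.hi):
            raise ValueError(f"malformed interval: lo={self.lo} > hi={self.hi}")

    @property
    def is_point(self) -> bool:
        return self.lo == self.hi

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def __contains__(self, x: float) -> bool:
        return self.lo <= x <= self.hi


def as_interval(value: "Real | Interval") -> Interval:
    """Coerce a scalar or Interval to an Interval (scalars become points)."""
    if isinstance(value, Interval):
        return value
    if isinstance(value, Real):
        v = float(value)
        return Interval(v, v)
    raise TypeError(f"cannot interpret {value!r} as an interval")


def bounds(value: "Real | Interval") -> tuple[float, float]:
    """Return ``(lo, hi)`` for a scalar or interval value."""
    iv = as_interval(value)
    return iv.lo, iv.hi
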