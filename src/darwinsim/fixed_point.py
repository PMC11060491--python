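"""Saturating signed fixed-point arithmetic.

All neuron-core state is held in a single two's-complement fixed-point
format.  Values are stored as raw Python integers (``raw``); the real value
is ``raw / 2**fraction_bits``.  Products are computed in double width and
rescaled by an arithmetic right shift (floor), then saturated to the
representable range.  Python integers are unbounded, so "double width" is
exact by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Union

Number = Union[int, float, Fraction]


@dataclass(frozen=True)
class FixedPointFormat:
    """A signed, saturating Qm.n fixed-point format.

    Parameters
    ----------
    total_bits : int
        Total word width including the sign bit (default 16).
    fraction_bits : int
        Number of fractional bits (default 8, i.e. Q8.8).
    saturating : bool
        If True (default) out-of-range results clamp to the representable
        extremes; otherwise an :class:`OverflowError` is raised.
    """

    total_bits: int = 16
    fraction_bits: int = 8
    saturating: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.fraction_bits < self.total_bits):
            raise ValueError(
                f"fraction_bits must satisfy 0 <= f < total_bits, got "
                f"{self.fraction_bits}/{self.total_bits}"
            )

    # -- range -------------------------------------------------------------
    @property
    def raw_max(self) -> int:
        return (1 << (self.total_bits - 1)) - 1

    @property
    def raw_min(self) -> int:
        return -(1 << (self.total_bits - 1))

    @property
    def one(self) -> int:
        """Raw representation of the real value 1.0."""
        return 1 << self.fraction_bits

    @property
    def ulp(self) -> Fraction:
        return Fraction(1, 1 << self.fraction_bits)

    def in_range(self, raw: int) -> bool:
        return self.raw_min <= raw <= self.raw_max

    # -- conversion --------------------------------------------------------
    def saturate(self, raw: int) -> int:
        if raw > self.raw_max:
            if not self.saturating:
                raise OverflowError(f"raw value {raw} exceeds format range")
            return self.raw_max
        if raw < self.raw_min:
            if not self.saturating:
                raise OverflowError(f"raw value {raw} below format range")
            return self.raw_min
        return raw

    def quantize(self, value: Number) -> int:
        """Real value -> raw, rounding toward minus infinity (floor)."""
        if isinstance(value, float):
            value = Fraction(value).limit_denominator(1 << 30)
        raw = (Fraction(value) * self.one).__floor__()
        return self.saturate(raw)

    def to_float(self, raw: int) -> float:
        return raw / self.one

    def to_fraction(self, raw: int) -> Fraction:
        return Fraction(raw, self.one)

    # -- arithmetic on raw values -----------------------------------------
    def add(self, a: int, b: int) -> int:
        return self.saturate(a + b)

    def sub(self, a: int, b: int) -> int:
        return self.saturate(a - b)

    def neg(self, a: int) -> int:
        return self.saturate(-a)

    def mul(self, a: int, b: int) -> int:
        """Double-width product, floor-rescaled, saturated.

        ``floor(a*b / 2**f)`` matches an arithmetic right shift of the
        exact product for both signs.
        """
        return self.saturate((a * b) >> self.fraction_bits)

    def shift(self, a: int, amount: int) -> int:
        """Arithmetic shift of the raw value; positive = left."""
        if amount >= 0:
            return self.saturate(a << amount)
        return self.saturate(a >> (-amount))

    def mul_round(self, a: int, b: int) -> int:
        """Round-to-nearest product (ties toward +inf); used by the
        lookup-table microcode where floor bias would accumulate."""
        f = self.fraction_bits
        return self.saturate((a * b + (1 << (f - 1))) >> f)
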