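"""Exact affine-rational coefficients.

Every count and polynomial coefficient in this package is an expression of
the form ``c0 + c1 * t`` where ``t`` is an optional formal repeat parameter
(the number of repeating units in a polymer chain) and ``c0``, ``c1`` are
exact rationals.  Concrete graphs have ``c1 == 0``.  Keeping the arithmetic
in :class:`fractions.Fraction` end-to-end guarantees that operator chains
such as Ix^3 Q_-2 J Dx^3 Dy^3 never accumulate floating-point error.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational


RationalLike = int | Fraction


def _as_fraction(value: object) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, Rational):  # covers int
        return Fraction(value)
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"expected an exact rational, got {value!r} ({type(value).__name__})")


@dataclass(frozen=True)
class AffineCount:
    """An exact expression ``c0 + c1 * parameter``.

    Addition, subtraction and scalar multiplication/division by rationals are
    closed; multiplying two non-constant expressions is undefined here (the
    operator calculus only ever scales and shifts coefficients) and raises.
    """

    c0: Fraction = Fraction(0)
    c1: Fraction = Fraction(0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "c0", _as_fraction(self.c0))
        object.__setattr__(self, "c1", _as_fraction(self.c1))

    # -- queries ---------------------------------------------------------
    @property
    def is_constant(self) -> bool:
        return self.c1 == 0

    @property
    def is_zero(self) -> bool:
        return self.c0 == 0 and self.c1 == 0

    def __call__(self, value: RationalLike) -> Fraction:
        """Evaluate at a concrete parameter value."""
        return self.c0 + self.c1 * _as_fraction(value)

    def constant_value(self) -> Fraction:
        if not self.is_constant:
            raise ValueError(f"{self} depends on the formal parameter")
        return self.c0

    # -- ring-ish operations --------------------------------------------
    def __add__(self, other: "AffineCount | RationalLike") -> "AffineCount":
        other = AffineCount.coerce(other)
        return AffineCount(self.c0 + other.c0, self.c1 + other.c1)

    __radd__ = __add__

    def __sub__(self, other: "AffineCount | RationalLike") -> "AffineCount":
        other = AffineCount.coerce(other)
        return AffineCount(self.c0 - other.c0, self.c1 - other.c1)

    def __rsub__(self, other: "AffineCount | RationalLike") -> "AffineCount":
        return AffineCount.coerce(other) - self

    def __neg__(self) -> "AffineCount":
        return AffineCount(-self.c0, -self.c1)

    def __mul__(self, scalar: object) -> "AffineCount":
        if isinstance(scalar, AffineCount):
            if scalar.is_constant:
                scalar = scalar.c0
            elif self.is_constant:
                return AffineCount(self.c0 * scalar.c0, self.c0 * scalar.c1)
            else:
                raise ValueError(
                    "product of two parameter-dependent expressions is not affine"
                )
        s = _as_fraction(scalar)
        return AffineCount(self.c0 * s, self.c1 * s)

    __rmul__ = __mul__

    def __truediv__(self, scalar: RationalLike) -> "AffineCount":
        s = _as_fraction(scalar)
        if s == 0:
            raise ZeroDivisionError("division of an affine count by zero")
        return AffineCount(self.c0 / s, self.c1 / s)

    # -- misc ------------------------------------------------------------
    @staticmethod
    def coerce(value: "AffineCount | RationalLike") -> "AffineCount":
        if isinstance(value, AffineCount):
            return value
        return AffineCount(_as_fraction(value))

    def render(self, parameter: str | None = None) -> str:
        """Human-readable form, e.g. ``11s + 2`` or ``343/36``."""
        t = parameter or "t"
        if self.c1 == 0:
            return str(self.c0)
        slope = "" if self.c1 == 1 else ("-" if self.c1 == -1 else f"{self.c1}*")
        head = f"{slope}{t}"
        if self.c0 == 0:
            return head
        sign = "+" if self.c0 > 0 else "-"
        return f"{head} {sign} {abs(self.c0)}"

    def __str__(self) -> str:
        return self.render()


ZERO = AffineCount()
ONE = AffineCount(Fraction(1))
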