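"""Exact scalar arithmetic: rationals and rational-plus-infinitesimal values.

All edge lengths and scores in this package are either :class:`~fractions.Fraction`
or :class:`Eps` values of the form ``a + b*eps`` where ``eps`` is a positive
infinitesimal.  Comparisons on :class:`Eps` are lexicographic on ``(a, b)``,
which is the order induced by letting ``eps`` tend to zero from above.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Union

Rational = Union[int, Fraction]
Scalar = Union[int, Fraction, "Eps"]

__all__ = ["Eps", "EPS", "as_fraction", "constant_part", "eps_part", "realize", "to_decimal_string"]


def as_fraction(value: Rational) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    raise TypeError(f"expected a rational, got {type(value).__name__}")


class Eps:
    """A number ``a + b*eps`` with exact rational ``a`` and ``b``.

    Supports addition/subtraction with other :class:`Eps` or rationals and
    multiplication/division by rationals (the algebra stays linear in ``eps``,
    which is all the constructions in this package require).
    """

    __slots__ = ("a", "b")

    def __init__(self, a: Rational = 0, b: Rational = 0):
        self.a = as_fraction(a)
        self.b = as_fraction(b)

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: Scalar) -> "Eps":
        if isinstance(other, Eps):
            return Eps(self.a + other.a, self.b + other.b)
        return Eps(self.a + as_fraction(other), self.b)

    __radd__ = __add__

    def __sub__(self, other: Scalar) -> "Eps":
        return self + (-_coerce(other))

    def __rsub__(self, other: Scalar) -> "Eps":
        return _coerce(other) + (-self)

    def __neg__(self) -> "Eps":
        return Eps(-self.a, -self.b)

    def __mul__(self, other: Rational) -> "Eps":
        if isinstance(other, Eps):
            raise TypeError("product of two infinitesimal-bearing values is not supported")
        q = as_fraction(other)
        return Eps(self.a * q, self.b * q)

    __rmul__ = __mul__

    def __truediv__(self, other: Rational) -> "Eps":
        q = as_fraction(other)
        return Eps(self.a / q, self.b / q)

    # -- order --------------------------------------------------------------
    def _key(self):
        return (self.a, self.b)

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Eps):
            return self._key() == other._key()
        if isinstance(other, (int, Fraction)):
            return self.a == other and self.b == 0
        return NotImplemented

    def __lt__(self, other: Scalar) -> bool:
        return self._key() < _coerce(other)._key()

    def __le__(self, other: Scalar) -> bool:
        return self._key() <= _coerce(other)._key()

    def __gt__(self, other: Scalar) -> bool:
        return self._key() > _coerce(other)._key()

    def __ge__(self, other: Scalar) -> bool:
        return self._key() >= _coerce(other)._key()

    def __hash__(self) -> int:
        if self.b == 0:
            return hash(self.a)
        return hash(self._key())

    def __bool__(self) -> bool:
        return self.a != 0 or self.b != 0

    def is_positive(self) -> bool:
        return self._key() > (0, 0)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.b == 0:
            return f"Eps({self.a})"
        sign = "+" if self.b >= 0 else "-"
        return f"Eps({self.a} {sign} {abs(self.b)}*eps)"


EPS = Eps(0, 1)


def _coerce(value: Scalar) -> Eps:
    if isinstance(value, Eps):
        return value
    return Eps(as_fraction(value), 0)


def constant_part(value: Scalar) -> Fraction:
    """The ``eps -> 0`` limit of a scalar."""
    if isinstance(value, Eps):
        return value.a
    return as_fraction(value)


def eps_part(value: Scalar) -> Fraction:
    if isinstance(value, Eps):
        return value.b
    return Fraction(0)


def realize(value: Scalar, eps_value: Rational) -> Fraction:
    """Substitute a concrete positive rational for ``eps``."""
    q = as_fraction(eps_value)
    if q <= 0:
        raise ValueError("eps realisation must be positive")
    if isinstance(value, Eps):
        return value.a + value.b * q
    return as_fraction(value)


def to_decimal_string(value: Fraction, places: int) -> str:
    """Round a rational half-up to ``places`` decimals, as a fixed-point string."""
    q = as_fraction(value)
    scale = 10**places
    scaled = q * scale
    # round half up (matches how the reference tables were printed)
    n = scaled.numerator
    d = scaled.denominator
    if n >= 0:
        units = (2 * n + d) // (2 * d)
    else:
        units = -((-2 * n + d) // (2 * d))
    sign = "-" if units < 0 else ""
    units = abs(units)
    whole, frac = divmod(units, scale)
    if places == 0:
        return f"{sign}{whole}"
    return f"{sign}{whole}.{frac:0{places}d}"
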