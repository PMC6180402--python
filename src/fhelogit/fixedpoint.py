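"""Balanced base-p fixed-point numbers.

A value x = sum_{i=-f}^{l-1} x_i p^i with balanced digits
x_i in [-(p-1)/2, (p-1)/2] is stored as the scaled integer
x~ = round(p^f x), a centered residue modulo p^r with r = l + 2f (the
extra f digits absorb one un-rescaled product).  Addition is exact;
multiplication computes x~ y~ and drops the f lowest balanced digits:

    z~ = scale(x~ y~, p^f) = (x~ y~  -  x~ y~ mod* p^f) / p^f,

where mod* is the balanced (centered) remainder.  Dropping balanced
digits equals rounding x~ y~ / p^f to the nearest integer (p odd, so no
ties); it is exactly what the homomorphic bscale operation computes, so
this module doubles as the bit-exact oracle for the encrypted pipeline.
Scaling may be deferred across a sum of products (multiply-accumulate,
one scale at the end).

Constants are prepared with either the floor or the nearest variant of
c * p^scale because the reference constants mix both conventions (floor
for the cubic-sigmoid coefficients, nearest for the learning-rate
digit).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .params import ParameterError
from .ring import balanced_scale, centered


def _to_fraction(x) -> Fraction:
    if isinstance(x, Fraction):
        return x
    if isinstance(x, str):
        return Fraction(x)
    return Fraction(x)


@dataclass(frozen=True)
class FixedPointCodec:
    """Base p, l integral digits, f fractional digits; modulus p^r, r = l + 2f."""

    p: int
    l: int
    f: int

    def __post_init__(self):
        if self.p < 3 or self.p % 2 == 0:
            raise ParameterError("fixed-point base must be an odd prime")
        if self.f < 0 or self.l < 0:
            raise ParameterError("digit counts must be non-negative")

    @property
    def r(self) -> int:
        return self.l + 2 * self.f

    @property
    def modulus(self) -> int:
        return self.p**self.r

    @property
    def scale(self) -> int:
        return self.p**self.f

    @property
    def max_abs(self) -> Fraction:
        """Approximate representable magnitude, p^l / 2."""
        return Fraction(self.p**self.l, 2)


@dataclass(frozen=True)
class FixedPointNumber:
    rep: int
    codec: FixedPointCodec

    def __post_init__(self):
        object.__setattr__(self, "rep", centered(self.rep, self.codec.modulus))

    def value(self) -> Fraction:
        return Fraction(self.rep, self.codec.scale)

    def __add__(self, other):
        self._check(other)
        return FixedPointNumber(self.rep + other.rep, self.codec)

    def __sub__(self, other):
        self._check(other)
        return FixedPointNumber(self.rep - other.rep, self.codec)

    def _check(self, other):
        if self.codec != other.codec:
            raise ParameterError("fixed-point codec mismatch")


def fp_encode(x, codec: FixedPointCodec, mode: str = "nearest") -> FixedPointNumber:
    """Encode a rational: rep = round(p^f x) (half away from zero), or
    floor(p^f x) with ``mode="floor"`` (the x~ = floor(xp)
    convention for worked constants)."""
    xf = _to_fraction(x)
    if abs(xf) > codec.max_abs:
        raise ParameterError(f"{x} outside representable range +-{codec.max_abs}")
    return FixedPointNumber(fp_scale_const(xf, codec.f, codec.p, mode), codec)


def _round_half_away(x: Fraction) -> int:
    n, d = x.numerator, x.denominator
    if n >= 0:
        return (2 * n + d) // (2 * d)
    return -((-2 * n + d) // (2 * d))


def fp_decode(a: FixedPointNumber) -> Fraction:
    """Inverse of fp_encode up to half an ulp (p^-f / 2)."""
    return a.value()


def fp_scale(rep: int, codec: FixedPointCodec, digits: int | None = None) -> int:
    """Drop the lowest ``digits`` balanced digits (default f) of a centered
    residue; the plaintext mirror of bscale."""
    d = codec.f if digits is None else digits
    rep = centered(rep, codec.modulus)
    return centered(balanced_scale(rep, codec.p**d), codec.modulus)


def fp_mul(a: FixedPointNumber, b: FixedPointNumber,
           codec: FixedPointCodec | None = None) -> FixedPointNumber:
    """Multiply then drop f balanced digits; |error| <= p^-f per product."""
    codec = codec or a.codec
    a._check(b)
    prod = centered(a.rep * b.rep, codec.modulus)
    return FixedPointNumber(fp_scale(prod, codec), codec)


def fp_dot_deferred(reps_a, reps_b, codec: FixedPointCodec) -> int:
    """Multiply-accumulate with a single trailing scale: the deferred
    scaling rule (scale after the sum, not after each product)."""
    acc = 0
    for x, y in zip(reps_a, reps_b):
        acc = centered(acc + x * y, codec.modulus)
    return fp_scale(acc, codec)


def fp_scale_const(c, scale: int, p: int, mode: str = "floor") -> int:
    """Prepare a constant: floor(c * p^scale) or round(c * p^scale).

    The cubic-sigmoid coefficients use the floor variant (e.g. 0.5 at
    p=127, scale 2 -> 8064); the learning-rate digit uses nearest
    (0.0447 at p=127, scale 1 -> 6).
    """
    cf = _to_fraction(c) * p**scale
    if mode == "floor":
        return cf.numerator // cf.denominator
    if mode == "nearest":
        return _round_half_away(cf)
    raise ParameterError(f"unknown constant mode {mode!r}")
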