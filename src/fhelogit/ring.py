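"""Negacyclic polynomial ring arithmetic: Z_m[x]/(x^n + 1).

Coefficients are kept as Python integers (arbitrary precision; toy
moduli reach 2^900) in the *centered* representative system
[-m/2, m/2).  Multiplication replaces x^n by -1 at every step.  Two
multiplication kernels are provided: schoolbook negacyclic convolution
(the canonical one, used for n <= 64) and a negacyclic NTT usable when
the modulus is a prime with 2n | (m - 1); they agree bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import sympy


def centered(x: int, m: int) -> int:
    """Centered representative of x modulo m, in [-m/2, m/2)."""
    half = m // 2
    return (x + half) % m - half


def round_div(a: int, b: int) -> int:
    """Round a/b to the nearest integer, halves away from zero."""
    if b < 0:
        a, b = -a, -b
    if a >= 0:
        return (2 * a + b) // (2 * b)
    return -((-2 * a + b) // (2 * b))


def balanced_mod(x: int, m: int) -> int:
    """Balanced remainder mod* m: the representative in (-m/2, m/2].

    For odd m this is the sum of the lowest balanced base-p digits; it
    satisfies x = m * round(x/m) + mod*(x, m) with round half away from
    zero never occurring at a tie (m odd).
    """
    return x - m * round_div(x, m)


def balanced_scale(x: int, m: int) -> int:
    """Drop the lowest balanced digits: (x - mod*(x, m)) / m = round(x/m)."""
    return round_div(x, m)


@dataclass(frozen=True)
class RingElement:
    """Element of Z_modulus[x]/(x^n + 1) with centered coefficients."""

    coeffs: tuple
    modulus: int

    def __post_init__(self):
        object.__setattr__(
            self, "coeffs", tuple(centered(c, self.modulus) for c in self.coeffs)
        )

    @property
    def n(self) -> int:
        return len(self.coeffs)

    @classmethod
    def zero(cls, n: int, modulus: int) -> "RingElement":
        return cls((0,) * n, modulus)

    @classmethod
    def constant(cls, c: int, n: int, modulus: int) -> "RingElement":
        return cls((c,) + (0,) * (n - 1), modulus)

    def __add__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        return RingElement(
            tuple(a + b for a, b in zip(self.coeffs, other.coeffs)), self.modulus
        )

    def __sub__(self, other: "RingElement") -> "RingElement":
        self._check(other)
        return RingElement(
            tuple(a - b for a, b in zip(self.coeffs, other.coeffs)), self.modulus
        )

    def __neg__(self) -> "RingElement":
        return RingElement(tuple(-a for a in self.coeffs), self.modulus)

    def __mul__(self, other) -> "RingElement":
        if isinstance(other, int):
            return RingElement(tuple(other * a for a in self.coeffs), self.modulus)
        self._check(other)
        prod = negacyclic_mul(self.coeffs, other.coeffs)
        return RingElement(prod, self.modulus)

    __rmul__ = __mul__

    def scalar_int_coeffs(self) -> list:
        return list(self.coeffs)

    def automorphism(self, a: int) -> "RingElement":
        """Apply x -> x^a (a odd, invertible mod 2n); x^n == -1."""
        n = self.n
        if a % 2 == 0:
            raise ValueError("automorphism exponent must be odd")
        out = [0] * n
        for j, c in enumerate(self.coeffs):
            k = (a * j) % (2 * n)
            if k >= n:
                out[k - n] -= c
            else:
                out[k] += c
        return RingElement(tuple(out), self.modulus)

    def norm_inf(self) -> int:
        return max(abs(c) for c in self.coeffs)

    def to_modulus(self, m: int) -> "RingElement":
        """Reinterpret coefficients mod a new modulus (reduces centered reps)."""
        return RingElement(self.coeffs, m)

    def _check(self, other: "RingElement") -> None:
        if self.modulus != other.modulus or self.n != other.n:
            raise ValueError("ring element mismatch (modulus or degree)")


def negacyclic_mul(a, b):
    """Schoolbook negacyclic convolution over Z (caller reduces)."""
    n = len(a)
    out = [0] * n
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        for j, bj in enumerate(b):
            if bj == 0:
                continue
            k = i + j
            if k >= n:
                out[k - n] -= ai * bj
            else:
                out[k] += ai * bj
    return tuple(out)


# ---------------------------------------------------------------------------
# NTT kernel (prime modulus with a 2n-th root of unity)


def _find_primitive_2n_root(n: int, q: int) -> int:
    """A primitive 2n-th root of unity modulo the prime q."""
    if (q - 1) % (2 * n) != 0:
        raise ValueError("modulus does not support a 2n-th root of unity")
    g = sympy.primitive_root(q)
    return pow(g, (q - 1) // (2 * n), q)


def ntt_negacyclic_mul(a, b, q: int):
    """Negacyclic product via the psi-twisted NTT; bit-exact with schoolbook.

    Requires q prime, 2n | q - 1.  Used as a cross-checked alternative
    kernel; the schoolbook path remains the default at toy ring sizes.
    """
    n = len(a)
    psi = _find_primitive_2n_root(n, q)
    w = pow(psi, 2, q)
    # twist by psi^i, forward transform, pointwise, inverse, untwist
    at = [(a[i] % q) * pow(psi, i, q) % q for i in range(n)]
    bt = [(b[i] % q) * pow(psi, i, q) % q for i in range(n)]
    fa = _ntt(at, w, q)
    fb = _ntt(bt, w, q)
    fc = [x * y % q for x, y in zip(fa, fb)]
    c = _ntt(fc, pow(w, q - 2, q), q)
    n_inv = pow(n, q - 2, q)
    psi_inv = pow(psi, q - 2, q)
    return tuple(centered(c[i] * n_inv % q * pow(psi_inv, i, q) % q, q) for i in range(n))


def _ntt(vec, w: int, q: int):
    n = len(vec)
    if n == 1:
        return list(vec)
    even = _ntt(vec[0::2], pow(w, 2, q), q)
    odd = _ntt(vec[1::2], pow(w, 2, q), q)
    out = [0] * n
    wk = 1
    for k in range(n // 2):
        t = wk * odd[k] % q
        out[k] = (even[k] + t) % q
        out[k + n // 2] = (even[k] - t) % q
        wk = wk * w % q
    return out
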