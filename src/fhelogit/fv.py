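"""The Fan-Vercauteren scheme over Z_q[x]/(x^n + 1).

Plaintexts live in R_t, t = p^r; a ciphertext is a pair (or, before
relinearisation, a triple) of ring elements mod q and decrypts through

    (t/q) (c0 + c1 s + c2 s^2 + ...) = m + v + b t,

where v is the noise polynomial; decryption is correct iff the noise
||v||_inf < 1/2 and is computed exactly here (test-only API) since all
arithmetic is big-integer exact.

Multiplication is the textbook tensor-then-scale construction with
relinearisation by base-w digit decomposition.  Galois keys support the
slot rotations of the batching layer; the bootstrapping key (an
encryption of the secret key under the intermediate plaintext modulus
p^e) is generated here but consumed by the bootstrap module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .params import EncryptionParams, ParameterError, make_rng
from .ring import RingElement, centered, negacyclic_mul, round_div


@dataclass(frozen=True)
class Plaintext:
    """A ring element modulo the plaintext modulus t."""

    elem: RingElement

    @property
    def t(self) -> int:
        return self.elem.modulus


@dataclass
class Ciphertext:
    """parts holds >= 2 ring elements mod q; ``t`` tags the plaintext
    modulus the ciphertext currently decrypts under (free division and
    bootstrapping retag it)."""

    parts: list
    q: int
    t: int

    @property
    def size(self) -> int:
        return len(self.parts)

    @property
    def n(self) -> int:
        return self.parts[0].n

    def copy(self) -> "Ciphertext":
        return Ciphertext(list(self.parts), self.q, self.t)


@dataclass
class KeySet:
    params: EncryptionParams
    sk: RingElement
    pk: tuple
    relin_keys: list
    galois_keys: dict = field(default_factory=dict)
    boot_key: "Ciphertext | None" = None


# ---------------------------------------------------------------------------
# sampling


def _sample_ternary(rng, n: int, bound: int = 3):
    lo, hi = -(bound // 2), (bound - 1) // 2
    return tuple(int(x) for x in rng.integers(lo, hi + 1, size=n))


def _sample_gaussian(rng, n: int, sigma: float):
    """Discrete Gaussian by rejection from a 6-sigma-truncated range."""
    if sigma == 0:
        return (0,) * n
    bound = int(math.floor(6 * sigma))
    out = []
    while len(out) < n:
        x = int(rng.integers(-bound, bound + 1))
        if rng.random() < math.exp(-x * x / (2 * sigma * sigma)):
            out.append(x)
    return tuple(out)


def _sample_uniform(rng, n: int, q: int):
    nbytes = (q.bit_length() + 7) // 8 + 8
    return tuple(int.from_bytes(rng.bytes(nbytes), "little") % q for _ in range(n))


def _num_digits(q: int, w: int) -> int:
    return (q.bit_length() + w.bit_length() - 2) // (w.bit_length() - 1)


# ---------------------------------------------------------------------------
# key generation


def _keyswitch_key(target: RingElement, s: RingElement, params, rng):
    """Key material: pseudo-encryptions of w^i * target under s."""
    q, w = params.q, params.relin_base
    keys = []
    wi = 1
    for _ in range(_num_digits(q, w)):
        a = RingElement(_sample_uniform(rng, params.n, q), q)
        e = RingElement(_sample_gaussian(rng, params.n, params.sigma_err), q)
        k0 = -(a * s + e) + wi * target
        keys.append((k0, a))
        wi *= w
    return keys


def keygen(params: EncryptionParams, seed=0) -> KeySet:
    """Generate secret, public, relinearisation, Galois and bootstrapping
    keys.  The pk residual p0 + p1*s equals -e with ||e||_inf <= 6*sigma."""
    rng = make_rng(seed)
    n, q = params.n, params.q
    s = RingElement(_sample_ternary(rng, n, params.ternary_bound), q)
    a = RingElement(_sample_uniform(rng, n, q), q)
    e = RingElement(_sample_gaussian(rng, n, params.sigma_err), q)
    pk = (-(a * s + e), a)
    relin = _keyswitch_key(s * s, s, params, rng)
    galois = {}
    for exp in range(1, 2 * n, 2):
        if math.gcd(exp, 2 * n) == 1 and exp != 1:
            galois[exp] = _keyswitch_key(s.automorphism(exp), s, params, rng)
    ks = KeySet(params, s, pk, relin, galois)
    if params.boot_e:
        # encryption of the secret key under plaintext modulus p^e
        pe = params.p**params.boot_e
        sk_pt = Plaintext(RingElement(s.coeffs, pe))
        ks.boot_key = encrypt(sk_pt, ks.pk, params, rng, plain_modulus=pe)
    return ks


# ---------------------------------------------------------------------------
# encryption / decryption / noise


def encrypt(m: Plaintext, pk, params: EncryptionParams, seed=0,
            plain_modulus: int | None = None) -> Ciphertext:
    rng = make_rng(seed)
    q, n = params.q, params.n
    t = plain_modulus or m.t
    if m.elem.n != n:
        raise ParameterError("plaintext degree does not match ring dimension")
    delta = q // t
    u = RingElement(_sample_ternary(rng, n, params.ternary_bound), q)
    e1 = RingElement(_sample_gaussian(rng, n, params.sigma_err), q)
    e2 = RingElement(_sample_gaussian(rng, n, params.sigma_err), q)
    mq = RingElement(m.elem.coeffs, q)
    c0 = delta * mq + pk[0] * u + e1
    c1 = pk[1] * u + e2
    return Ciphertext([c0, c1], q, t)


def _raw_decrypt_int(ct: Ciphertext, sk: RingElement):
    """c0 + c1 s + c2 s^2 ... as centered integers mod the ciphertext's
    (possibly switched) modulus."""
    if sk.modulus != ct.q:
        sk = RingElement(sk.coeffs, ct.q)
    acc = ct.parts[0]
    spow = sk
    for part in ct.parts[1:]:
        acc = acc + part * spow
        spow = spow * sk
    return acc


def decrypt(ct: Ciphertext, sk: RingElement) -> Plaintext:
    """m = round((t/q)(c0 + c1 s)) reduced mod t, coefficient-wise."""
    P = _raw_decrypt_int(ct, sk)
    t, q = ct.t, ct.q
    coeffs = tuple(round_div(t * c, q) for c in P.coeffs)
    return Plaintext(RingElement(coeffs, t))


def noise(ct: Ciphertext, sk: RingElement) -> Fraction:
    """Exact noise ||v||_inf with (t/q)(c0 + c1 s) = m + v + bt."""
    P = _raw_decrypt_int(ct, sk)
    t, q = ct.t, ct.q
    worst = Fraction(0)
    for c in P.coeffs:
        rem = centered(t * c, q)
        worst = max(worst, Fraction(abs(rem), q))
    return worst


def is_valid(ct: Ciphertext, sk: RingElement, m_expected: Plaintext) -> bool:
    """Test helper: does ct decrypt to the expected plaintext?"""
    return decrypt(ct, sk).elem.coeffs == m_expected.elem.coeffs


# ---------------------------------------------------------------------------
# homomorphic operations


def _check_compat(ct1: Ciphertext, ct2: Ciphertext):
    if ct1.q != ct2.q or ct1.t != ct2.t or ct1.n != ct2.n:
        raise ParameterError("ciphertext parameter mismatch")


def add(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    _check_compat(ct1, ct2)
    k = max(ct1.size, ct2.size)
    zero = RingElement.zero(ct1.n, ct1.q)
    p1 = ct1.parts + [zero] * (k - ct1.size)
    p2 = ct2.parts + [zero] * (k - ct2.size)
    return Ciphertext([a + b for a, b in zip(p1, p2)], ct1.q, ct1.t)


def sub(ct1: Ciphertext, ct2: Ciphertext) -> Ciphertext:
    _check_compat(ct1, ct2)
    k = max(ct1.size, ct2.size)
    zero = RingElement.zero(ct1.n, ct1.q)
    p1 = ct1.parts + [zero] * (k - ct1.size)
    p2 = ct2.parts + [zero] * (k - ct2.size)
    return Ciphertext([a - b for a, b in zip(p1, p2)], ct1.q, ct1.t)


def plainmult(ct: Ciphertext, pt: Plaintext | RingElement | int) -> Ciphertext:
    """Multiply by a plaintext polynomial; consumes no relinearisation."""
    if isinstance(pt, Plaintext):
        pt = pt.elem
    if isinstance(pt, int):
        return Ciphertext([pt * c for c in ct.parts], ct.q, ct.t)
    ptq = RingElement(pt.coeffs, ct.q)
    return Ciphertext([c * ptq for c in ct.parts], ct.q, ct.t)


def multiply(ct1: Ciphertext, ct2: Ciphertext, relin_keys=None) -> Ciphertext:
    """Tensor, scale by t/q with rounding, then (optionally) relinearise."""
    _check_compat(ct1, ct2)
    if ct1.size != 2 or ct2.size != 2:
        raise ParameterError("multiply expects 2-part ciphertexts")
    q, t = ct1.q, ct1.t
    a = [p.coeffs for p in ct1.parts]
    b = [p.coeffs for p in ct2.parts]
    raw = [None] * 3
    for i in range(2):
        for j in range(2):
            prod = negacyclic_mul(a[i], b[j])
            if raw[i + j] is None:
                raw[i + j] = list(prod)
            else:
                raw[i + j] = [x + y for x, y in zip(raw[i + j], prod)]
    parts = [
        RingElement(tuple(round_div(t * c, q) for c in comp), q) for comp in raw
    ]
    out = Ciphertext(parts, q, t)
    if relin_keys is not None:
        out = relinearize(out, relin_keys)
    return out


def _decompose(elem: RingElement, w: int, count: int):
    """Base-w digit polynomials of the non-negative representative."""
    coeffs = [c % elem.modulus for c in elem.coeffs]
    digits = []
    for _ in range(count):
        digits.append(RingElement(tuple(c % w for c in coeffs), elem.modulus))
        coeffs = [c // w for c in coeffs]
    return digits


def _keyswitch(c0: RingElement, c_target: RingElement, keys, q: int, w: int):
    """Fold c_target (valid under some other key) back onto (c0', c1')."""
    digits = _decompose(c_target, w, len(keys))
    acc0, acc1 = c0, RingElement.zero(c0.n, q)
    for d, (k0, k1) in zip(digits, keys):
        acc0 = acc0 + k0 * d
        acc1 = acc1 + k1 * d
    return acc0, acc1


def relinearize(ct: Ciphertext, relin_keys, relin_base: int = 1 << 64) -> Ciphertext:
    if ct.size == 2:
        return ct
    if ct.size != 3:
        raise ParameterError("relinearisation supports 3-part ciphertexts")
    if relin_keys is None:
        raise ParameterError("missing relinearisation keys")
    c0, c1 = _keyswitch(ct.parts[0], ct.parts[2], relin_keys, ct.q, relin_base)
    return Ciphertext([c0 + RingElement.zero(ct.n, ct.q), c1 + ct.parts[1]], ct.q, ct.t)


def apply_galois(ct: Ciphertext, exp: int, galois_keys, relin_base: int = 1 << 64):
    """Apply x -> x^exp to the plaintext, key-switching back to sk."""
    if ct.size != 2:
        raise ParameterError("apply automorphisms to 2-part ciphertexts")
    if exp == 1:
        return ct.copy()
    if exp not in galois_keys:
        raise ParameterError(f"missing Galois key for exponent {exp}")
    d0 = ct.parts[0].automorphism(exp)
    d1 = ct.parts[1].automorphism(exp)
    c0, c1 = _keyswitch(d0, d1, galois_keys[exp], ct.q, relin_base)
    return Ciphertext([c0, c1], ct.q, ct.t)


def rotate(ct: Ciphertext, j: int, keys: KeySet, codec) -> Ciphertext:
    """Cyclic right-rotation of the slot vector by j positions.

    Realised as masked Galois automorphisms per the codec's rotation
    plan; rotation by 0 is the identity.
    """
    j %= codec.k
    if j == 0:
        return ct.copy()
    plan = codec.rotation_plan(j)
    acc = None
    for exp, mask in plan:
        if all(mask):
            piece = ct
        else:
            piece = plainmult(ct, codec.encode(mask))
        moved = apply_galois(piece, exp, keys.galois_keys, keys.params.relin_base)
        acc = moved if acc is None else add(acc, moved)
    return acc


def mod_switch(ct: Ciphertext, q_new: int) -> Ciphertext:
    """Rescale ciphertext parts to a new coefficient modulus."""
    if q_new == ct.q:
        return ct.copy()
    parts = [
        RingElement(tuple(round_div(q_new * c, ct.q) for c in p.coeffs), q_new)
        for p in ct.parts
    ]
    return Ciphertext(parts, q_new, ct.t)
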