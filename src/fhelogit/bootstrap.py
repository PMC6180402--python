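"""Bootstrapping fused with fixed-point rescaling (bscale).

To divide an encrypted fixed-point integer m (mod p^r) by p and refresh
its noise in one go:

1. move slot values into plaintext coefficients (a homomorphic linear
   transform built from rotations and plaintext masks);
2. a free division retags the ciphertext at plaintext modulus p^(r-1);
3. modulus-switch down to q' = p^(e-1); the ciphertext's b*t wrap
   becomes the "upper garbage" alpha;
4. dot product with the bootstrapping key (an encryption of sk under
   the intermediate plaintext modulus p^e): each plaintext coefficient
   now holds  v + p^(e-r)*floor(m/p) + p^(e-1)*alpha  (mod p^e) with
   |v| <= p^(e-r)/2;
5. move coefficients back into slots and kill the v term: e-r rounds of
   (one-digit removal polynomial, free division) — a single polynomial
   removing several digits at once does not exist mod p^e, so the
   removal and the exact division must interleave — ending at plaintext
   modulus p^r with  floor(m/p) + p^(r-1)*alpha;
6. strip the upper-garbage digit alpha: extract the clean digits one at
   a time (digit 0 is x - remove1(x)) and re-merge them through a
   garbage-free modulus-raising bootstrap (dot product at q' = p^e).

"floor" here is balanced-digit dropping (round to nearest; p odd, no
ties), matching the plaintext fixed-point codec exactly.  bscale(ct, i)
iterates the single-digit pipeline i times — dropping one balanced
digit i times equals dropping i digits, by uniqueness of the balanced
expansion.  Sign extraction is bscale(ct, r-1): the sign of a fixed
point number is the most significant balanced digit.

Digit-removal polynomials are built by sequential Newton (Mahler-basis)
interpolation over Z_{p^e}; any function representable mod p^e has a
canonical representative of degree < min{d : p^e | d!} ~ e*p, far below
the e*p^(e-r) worst-case bound, which keeps homomorphic evaluation
(Paterson-Stockmeyer) cheap.

The module also defines the backend contract: the same training program
runs on the real FV backend or on a trace emulator that carries plain
slot values plus the consumed multiplicative-degree budget.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
import sympy

from . import fv
from .batching import SlotCodec
from .params import EncryptionParams, ParameterError, preset
from .ring import RingElement, balanced_mod, balanced_scale, centered

# ---------------------------------------------------------------------------
# digit removal / retain polynomials


class NotPolynomialError(ArithmeticError):
    """The target function admits no polynomial representative mod p^e."""


def _interpolate_function_mod(f, p: int, e: int, dmax: int):
    """Minimal-degree polynomial agreeing with f on every residue mod p^e.

    Sequential Newton solve on the points 0, 1, 2, ...: at point d the
    Newton coefficient c_d must satisfy c_d * d! = residual(d) (mod p^e),
    solvable iff p^{v_p(d!)} divides the residual.  Returns ascending
    coefficients mod p^e.
    """
    m = p**e
    npts = dmax + 2
    vals = [f(x) % m for x in range(npts)]
    nvals = [1] * npts           # N_d(x) = x(x-1)...(x-d+1)
    npoly = [1]                  # same, as coefficients
    coeffs = [0]
    fact_unit = 1                # unit part of d! mod m
    fact_v = 0                   # v_p(d!)
    for d in range(npts):
        if all(v % m == 0 for v in vals[d:]):
            break
        if d > dmax or fact_v >= e:
            raise NotPolynomialError(
                f"no polynomial of degree <= {dmax} represents target mod {p}^{e}"
            )
        rhs = vals[d] % m
        pv = p**fact_v
        if rhs % pv:
            raise NotPolynomialError("Newton coefficient not p-integral")
        c = (rhs // pv) * pow(fact_unit, -1, m) % m
        if c:
            for x in range(d, npts):
                vals[x] = (vals[x] - c * nvals[x]) % m
            while len(coeffs) < len(npoly):
                coeffs.append(0)
            for j, a in enumerate(npoly):
                coeffs[j] = (coeffs[j] + c * a) % m
        # advance N_d -> N_{d+1} = N_d * (x - d), and d! -> (d+1)!
        for x in range(npts):
            nvals[x] = nvals[x] * (x - d) % m
        old = npoly
        npoly = [0] * (len(old) + 1)
        for j, a in enumerate(old):
            npoly[j] = (npoly[j] - d * a) % m
            npoly[j + 1] = (npoly[j + 1] + a) % m
        step = d + 1
        while step % p == 0:
            fact_v += 1
            step //= p
        fact_unit = fact_unit * step % m
    while len(coeffs) > 1 and coeffs[-1] == 0:
        coeffs.pop()
    return coeffs


def _poly_eval_mod(coeffs, xs, m):
    acc = np.zeros_like(xs)
    for c in reversed(coeffs):
        acc = (acc * xs + c) % m
    return acc


@lru_cache(maxsize=None)
def digit_remove_poly(p: int, e: int, j: int):
    """F with F(x) = x - (x mod* p^j) (mod p^e) for every integer x.

    mod* is the balanced remainder, so F zeroes the j lowest balanced
    digits.  Such a polynomial exists for j = 1 (degree (e-1)(p-1)+1,
    within the e*p^j bound); for j >= 2 no polynomial represents the
    function mod p^e and NotPolynomialError is raised — multi-digit
    removal must interleave one-digit removal with free division.
    Verified by brute force over all residues when p^e is small, by
    sampling otherwise.
    """
    if not 1 <= j < e:
        raise ParameterError(f"digit removal needs 1 <= j < e, got j={j}, e={e}")
    pj = p**j
    coeffs = _interpolate_function_mod(
        lambda x: x - balanced_mod(x, pj), p, e, dmax=e * pj + p
    )
    _verify_digit_poly(coeffs, p, e, lambda x: x - balanced_mod(x, pj))
    return tuple(coeffs)


@lru_cache(maxsize=None)
def digit_retain_poly(p: int, e: int, j: int):
    """G with G(x) = x mod* p^j (mod p^e): keeps the j lowest balanced
    digits and strips everything above them."""
    if not 1 <= j < e:
        raise ParameterError(f"digit retain needs 1 <= j < e, got j={j}, e={e}")
    pj = p**j
    coeffs = _interpolate_function_mod(
        lambda x: balanced_mod(x, pj), p, e, dmax=e * pj + p
    )
    _verify_digit_poly(coeffs, p, e, lambda x: balanced_mod(x, pj))
    return tuple(coeffs)


def _verify_digit_poly(coeffs, p, e, f, exhaustive_limit=200_000):
    m = p**e
    if m <= exhaustive_limit:
        xs = np.arange(m, dtype=np.int64)
    else:
        rng = np.random.default_rng(12345)
        xs = rng.integers(0, m, size=4096)
    got = _poly_eval_mod(np.asarray([c % m for c in coeffs], dtype=np.int64), xs, m)
    want = np.asarray([f(int(x)) % m for x in xs], dtype=np.int64)
    if not np.array_equal(got, want):
        raise NotPolynomialError("digit polynomial failed verification")


# ---------------------------------------------------------------------------
# free division and the bootstrapping dot product


def free_divide(ct: fv.Ciphertext, i: int, p: int) -> fv.Ciphertext:
    """Retag the ciphertext at plaintext modulus t/p^i: division by p^i
    at zero homomorphic cost (the dropped digits become noise)."""
    if i < 1 or p**i >= ct.t:
        raise ParameterError(f"free division by p^{i} out of range for t={ct.t}")
    if ct.t % p**i:
        raise ParameterError("plaintext modulus not divisible by p^i")
    return fv.Ciphertext(list(ct.parts), ct.q, ct.t // p**i)


def boot_dot_product(ct_switched: fv.Ciphertext, boot_key: fv.Ciphertext,
                     pe: int) -> fv.Ciphertext:
    """c0' + c1' * sk evaluated under encryption, at plaintext modulus p^e.

    ct_switched must live at a small modulus q' (its centered parts are
    reinterpreted as plaintexts mod p^e); boot_key encrypts sk under p^e.
    """
    if boot_key.t != pe:
        raise ParameterError("bootstrapping key plaintext modulus mismatch")
    c0 = RingElement(ct_switched.parts[0].coeffs, pe)
    c1 = RingElement(ct_switched.parts[1].coeffs, pe)
    out = fv.plainmult(boot_key, c1)
    return add_plain_poly(out, c0)


def add_plain_poly(ct: fv.Ciphertext, pt: RingElement) -> fv.Ciphertext:
    """Add a plaintext polynomial (mod t) into a ciphertext for free."""
    delta = ct.q // ct.t
    lifted = RingElement(pt.coeffs, ct.q)
    parts = list(ct.parts)
    parts[0] = parts[0] + delta * lifted
    return fv.Ciphertext(parts, ct.q, ct.t)


def add_plain_const(ct: fv.Ciphertext, c: int) -> fv.Ciphertext:
    return add_plain_poly(ct, RingElement.constant(c, ct.n, ct.t))


# ---------------------------------------------------------------------------
# homomorphic polynomial evaluation (Paterson-Stockmeyer)


def eval_poly_encrypted(coeffs, ct: fv.Ciphertext, keys: fv.KeySet) -> fv.Ciphertext:
    """Evaluate sum_i coeffs[i] x^i on an encrypted x, slot-wise."""
    t = ct.t
    coeffs = [centered(c, t) for c in coeffs]
    d = len(coeffs) - 1
    if d == 0:
        zero = fv.plainmult(ct, 0)
        return add_plain_const(zero, coeffs[0])
    bs = max(2, math.isqrt(d) + 1)
    powers = {1: ct}

    def power(i):
        if i not in powers:
            lo = i // 2
            powers[i] = fv.multiply(power(lo), power(i - lo), keys.relin_keys)
        return powers[i]

    def block(cs):
        acc = None
        for i, c in enumerate(cs):
            if i == 0 or c == 0:
                continue
            term = fv.plainmult(power(i), c)
            acc = term if acc is None else fv.add(acc, term)
        if acc is None:
            acc = fv.plainmult(ct, 0)
        if cs[0]:
            acc = add_plain_const(acc, cs[0])
        return acc

    blocks = [coeffs[j:j + bs] for j in range(0, d + 1, bs)]
    giant = power(bs) if len(blocks) > 1 else None
    res = block(blocks[-1])
    for cs in reversed(blocks[:-1]):
        res = fv.multiply(res, giant, keys.relin_keys)
        res = fv.add(res, block(cs))
    return res


# ---------------------------------------------------------------------------
# the bootstrapper


class Bootstrapper:
    """Caches codecs, slot<->coefficient transforms and digit polynomials
    for one key set, and exposes bscale / sign_extract on ciphertexts."""

    def __init__(self, keys: fv.KeySet, codec: SlotCodec):
        params = keys.params
        if not params.boot_e:
            raise ParameterError("parameters carry no bootstrapping exponent e")
        if keys.boot_key is None:
            raise ParameterError("key set has no bootstrapping key")
        self.keys = keys
        self.params = params
        self.p, self.r, self.e = params.p, params.r, params.boot_e
        self.codec_r = codec
        self.codec_e = SlotCodec(params.n, params.p, self.e, codec.generator)
        self.k = codec.k
        # codecs and slots->coeffs transforms for every working modulus
        # p^s (s = 2..r; digit merging passes through the lower moduli)
        self._codecs = {self.r: codec, self.e: self.codec_e}
        for s in range(2, self.r):
            self._codecs[s] = SlotCodec(params.n, params.p, s, codec.generator)
        if self.k > 1:
            if not codec.fully_split:
                raise ParameterError(
                    "real-backend bootstrapping needs a fully-splitting codec "
                    "(or k = 1); run this preset on the trace backend instead"
                )
            self._s2c_diags = {
                s: self._transform_diagonals(self._eval_matrix(self._codecs[s]),
                                             self._codecs[s])
                for s in range(2, self.r + 1)
            }
            inv = self._invert_matrix(self._eval_matrix(self.codec_e),
                                      self.codec_e.modulus)
            self._c2s_diags = self._transform_diagonals(inv, self.codec_e)

    # noise margin of the mod-switch + dot-product step, used to pick e
    @staticmethod
    def dot_product_noise_bound(n: int) -> float:
        """Worst-case |delta| = |d0 + d1*s| from modulus-switch rounding."""
        return 0.5 * (1 + n)

    # -- linear transforms --------------------------------------------------

    @staticmethod
    def _eval_matrix(codec: SlotCodec):
        """V[i][j] = rho_i^j: slots of sum_j c_j x^j equal V*c."""
        m = codec.modulus
        roots = codec.roots
        return [[pow(rho, j, m) for j in range(codec.k)] for rho in roots]

    @staticmethod
    def _invert_matrix(mat, modulus):
        M = sympy.Matrix(mat)
        return [[int(x) % modulus for x in row] for row in M.inv_mod(modulus).tolist()]

    @staticmethod
    def _transform_diagonals(mat, codec: SlotCodec):
        """Generalised diagonals for out = sum_j diag_j . rotate(in, j)."""
        k = codec.k
        diags = []
        for j in range(k):
            diag = [mat[i][(i - j) % k] for i in range(k)]
            diags.append(None if all(d % codec.modulus == 0 for d in diag) else diag)
        return diags

    def _apply_slot_transform(self, ct: fv.Ciphertext, diags, codec: SlotCodec):
        acc = None
        for j, diag in enumerate(diags):
            if diag is None:
                continue
            rotated = fv.rotate(ct, j, self.keys, codec)
            term = fv.plainmult(rotated, codec.encode(diag))
            acc = term if acc is None else fv.add(acc, term)
        return acc if acc is not None else fv.plainmult(ct, 0)

    def _texp(self, ct: fv.Ciphertext) -> int:
        """Exponent s with ct.t == p^s."""
        s, t = 0, ct.t
        while t % self.p == 0:
            t //= self.p
            s += 1
        if t != 1:
            raise ParameterError("plaintext modulus is not a power of p")
        return s

    def slots_to_coeffs(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        """Make plaintext coefficient i equal slot value i (mod ct.t)."""
        if self.k == 1:
            return ct.copy()  # integer slot content is the constant coefficient
        s = self._texp(ct)
        return self._apply_slot_transform(ct, self._s2c_diags[s], self._codecs[s])

    def coeffs_to_slots(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        """Make slot i equal plaintext coefficient i (mod p^e)."""
        if self.k == 1:
            # trace down to the constant coefficient: (P + tau_{-1}(P)) / n
            n = self.params.n
            if n != 2:
                raise ParameterError("k=1 bootstrapping implemented for n=2 only")
            conj = fv.apply_galois(ct, 2 * n - 1, self.keys.galois_keys,
                                   self.params.relin_base)
            summed = fv.add(ct, conj)
            inv_n = pow(n, -1, self.codec_e.modulus)
            return fv.plainmult(summed, inv_n)
        return self._apply_slot_transform(ct, self._c2s_diags, self.codec_e)

    # -- the pipeline -------------------------------------------------------

    def _remove_lowest(self, ct: fv.Ciphertext, rounds: int) -> fv.Ciphertext:
        """Iterate (one-digit removal polynomial, free division): the only
        form in which multi-digit removal exists as polynomial evaluation."""
        for _ in range(rounds):
            s = self._texp(ct)
            ct = eval_poly_encrypted(digit_remove_poly(self.p, s, 1), ct, self.keys)
            ct = free_divide(ct, 1, self.p)
        return ct

    def _raise_modulus(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        """Garbage-free re-encryption of a clean value u (mod p^s) as p*u
        at modulus p^(s+1): mod-switch to q' = p^e makes the b*t wrap
        vanish mod p^e, so no alpha term appears."""
        p, e = self.p, self.e
        s = self._texp(ct)
        st = self.slots_to_coeffs(ct)
        switched = fv.mod_switch(st, p**e)
        dot = boot_dot_product(switched, self.keys.boot_key, p**e)
        slots = self.coeffs_to_slots(dot)  # p^(e-s)*u + v, |v| single digit
        return self._remove_lowest(slots, e - s - 1)

    def _strip_top_digit(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        """Input: u + p^(s-1)*alpha (mod p^s) with |u| < p^(s-1)/2.
        Output: u, same modulus, garbage removed.

        The clean digits are extracted one at a time (digit 0 is
        mod*(x, p) = x - remove1(x), untouched by the top garbage) and
        re-merged via the modulus-raising bootstrap."""
        p = self.p
        s = self._texp(ct)
        if s == 2:
            return eval_poly_encrypted(digit_retain_poly(p, 2, 1), ct, self.keys)
        removed = eval_poly_encrypted(digit_remove_poly(p, s, 1), ct, self.keys)
        d0 = fv.sub(ct, removed)
        rest = free_divide(removed, 1, p)       # (u - d0)/p + p^(s-2)*alpha
        rest = self._strip_top_digit(rest)      # clean, mod p^(s-1)
        return fv.add(d0, self._raise_modulus(rest))

    def _bscale_once(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        p, r, e = self.p, self.r, self.e
        if ct.t != p**r:
            raise ParameterError("bscale input must live at plaintext modulus p^r")
        st = self.slots_to_coeffs(ct)
        low = free_divide(st, 1, p)
        switched = fv.mod_switch(low, p ** (e - 1))
        dot = boot_dot_product(switched, self.keys.boot_key, p**e)
        slots = self.coeffs_to_slots(dot)
        # v + p^(e-r)*floor(m/p) + p^(e-1)*alpha  ->  floor(m/p) + p^(r-1)*alpha
        back = self._remove_lowest(slots, e - r)
        return self._strip_top_digit(back)

    def bscale(self, ct: fv.Ciphertext, i: int = 1) -> fv.Ciphertext:
        """Refresh noise and drop the i lowest balanced digits (divide by
        p^i in fixed point).  Default i = 1."""
        if not 1 <= i < self.r:
            raise ParameterError(f"bscale digit count must be in [1, r), got {i}")
        out = ct
        for _ in range(i):
            out = self._bscale_once(out)
        return out

    def sign_extract(self, ct: fv.Ciphertext) -> fv.Ciphertext:
        """Most significant balanced digit == the sign of the fixed-point
        value (caller guarantees the MSD is in {-1, 0, 1})."""
        return self.bscale(ct, self.r - 1)


# ---------------------------------------------------------------------------
# backend contract: real FV pipeline vs trace emulator


class TraceCipher:
    """Emulator handle: plain slot values + consumed multiplicative degree."""

    __slots__ = ("values", "degree")

    def __init__(self, values, degree=1):
        self.values = list(values)
        self.degree = degree


class TraceBackend:
    """Plaintext mirror of the encrypted pipeline with identical
    fixed-point semantics; slot values equal decrypt-and-decode of the
    real backend for any program of supported operations."""

    is_encrypted = False

    def __init__(self, p: int, r: int, e: int, k: int):
        self.p, self.r, self.e, self.k = p, r, e, k
        self.modulus = p**r
        self.rotations = 0
        self.bscale_charges = []

    def _wrap(self, values, degree=1):
        return TraceCipher([centered(v, self.modulus) for v in values], degree)

    def encrypt_vec(self, values):
        if len(values) != self.k:
            raise ValueError(f"expected {self.k} slot values")
        return self._wrap(values)

    def decrypt_vec(self, ct):
        return list(ct.values)

    def add(self, a, b):
        return self._wrap([x + y for x, y in zip(a.values, b.values)],
                          max(a.degree, b.degree))

    def sub(self, a, b):
        return self._wrap([x - y for x, y in zip(a.values, b.values)],
                          max(a.degree, b.degree))

    def mul(self, a, b):
        return self._wrap([x * y for x, y in zip(a.values, b.values)],
                          a.degree + b.degree)

    def plainmult(self, a, plain):
        if isinstance(plain, int):
            plain = [plain] * self.k
        return self._wrap([x * c for x, c in zip(a.values, plain)], a.degree + 1)

    def add_const(self, a, c: int):
        return self._wrap([x + c for x in a.values], a.degree)

    def rotate(self, a, j: int):
        self.rotations += 1
        j %= self.k
        return TraceCipher(a.values[-j:] + a.values[:-j] if j else list(a.values),
                           a.degree)

    def bscale(self, a, i: int = 1):
        if not 1 <= i < self.r:
            raise ParameterError(f"bscale digit count must be in [1, r), got {i}")
        charge = self.e * self.r * self.p ** (self.e - i)
        self.bscale_charges.append(charge)
        return self._wrap([balanced_scale(v, self.p**i) for v in a.values], 1)

    def sign_extract(self, a):
        charge = self.e * self.r * self.p ** (self.e - self.r + 1)
        self.bscale_charges.append(charge)
        return self._wrap([balanced_scale(v, self.p ** (self.r - 1))
                           for v in a.values], 1)


class FVBackend:
    """The real thing: FV ciphertexts, Galois rotations and bootstrapped
    rescaling behind the same operation surface as the trace emulator."""

    is_encrypted = True

    def __init__(self, params: EncryptionParams, seed=0):
        self.params = params
        self.keys = fv.keygen(params, seed)
        self.codec = SlotCodec(params.n, params.p, params.r)
        self.boot = Bootstrapper(self.keys, self.codec) if params.boot_e else None
        self.p, self.r, self.e = params.p, params.r, params.boot_e
        self.k = self.codec.k
        self.modulus = params.t
        self.rotations = 0
        self.bscale_charges = []
        self._enc_seed = 10_000

    def _next_rng(self):
        self._enc_seed += 1
        return self._enc_seed

    def encrypt_vec(self, values):
        pt = fv.Plaintext(self.codec.encode(values))
        return fv.encrypt(pt, self.keys.pk, self.params, self._next_rng())

    def decrypt_vec(self, ct):
        return self.codec.decode(fv.decrypt(ct, self.keys.sk).elem)

    def add(self, a, b):
        return fv.add(a, b)

    def sub(self, a, b):
        return fv.sub(a, b)

    def mul(self, a, b):
        return fv.multiply(a, b, self.keys.relin_keys)

    def plainmult(self, a, plain):
        if isinstance(plain, int):
            return fv.plainmult(a, plain)
        return fv.plainmult(a, self.codec.encode(plain))

    def add_const(self, a, c: int):
        return add_plain_const(a, c)

    def rotate(self, a, j: int):
        self.rotations += 1
        return fv.rotate(a, j, self.keys, self.codec)

    def bscale(self, a, i: int = 1):
        charge = self.e * self.r * self.p ** (self.e - i)
        self.bscale_charges.append(charge)
        return self.boot.bscale(a, i)

    def sign_extract(self, a):
        charge = self.e * self.r * self.p ** (self.e - self.r + 1)
        self.bscale_charges.append(charge)
        return self.boot.sign_extract(a)


def make_backend(kind: str, params_or_preset, seed=0):
    """Factory: ``kind`` is "real" or "trace"."""
    params = (preset(params_or_preset) if isinstance(params_or_preset, str)
              else params_or_preset)
    if kind == "real":
        return FVBackend(params, seed)
    if kind == "trace":
        k = SlotCodec(params.n, params.p, params.r).k
        return TraceBackend(params.p, params.r, params.boot_e or params.r + 2, k)
    raise ParameterError(f"unknown backend kind {kind!r}")
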