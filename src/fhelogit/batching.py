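"""SIMD batching: length-k integer vectors <-> plaintext ring elements.

Choosing the plaintext modulus t = p^r so that p is coprime to 2n makes
R_t isomorphic to a k-fold product of Galois rings, k = n / ord_{2n}(p).
The pipeline stores only integer (degree-0) slot content, i.e. the
subring Z_t of each slot, which is all the training method needs.

The codec factors x^n + 1 modulo p (sympy), Hensel-lifts the
factorization to p^m, and encodes through the CRT idempotents.  Slot
order is fixed at construction along the orbit of the rotation
generator; cyclic rotation by j slots is realised as at most two Galois
automorphisms glued together with 0/1 masks (the automorphism group of
a power-of-two cyclotomic is rarely cyclic, so a single automorphism
cannot in general rotate all k slots).
"""

from __future__ import annotations

import sympy
from sympy.abc import x as _x

from .params import ParameterError
from .ring import RingElement, centered


def slot_count(n: int, p: int, r: int = 1) -> int:
    """Number of SIMD slots: n / ord_{2n}(p).  Independent of r."""
    if 2 * n % p == 0:
        raise ParameterError(f"p={p} divides 2n={2 * n}")
    order = sympy.n_order(p, 2 * n)
    return n // order


# ---------------------------------------------------------------------------
# dense polynomial helpers over Z_m (ascending coefficient lists)


def _ptrim(a):
    while len(a) > 1 and a[-1] == 0:
        a = a[:-1]
    return a


def _pmul(a, b, m):
    out = [0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        for j, bj in enumerate(b):
            out[i + j] = (out[i + j] + ai * bj) % m
    return _ptrim(out)


def _padd(a, b, m):
    n = max(len(a), len(b))
    a = a + [0] * (n - len(a))
    b = b + [0] * (n - len(b))
    return _ptrim([(u + v) % m for u, v in zip(a, b)])


def _psub(a, b, m):
    n = max(len(a), len(b))
    a = a + [0] * (n - len(a))
    b = b + [0] * (n - len(b))
    return _ptrim([(u - v) % m for u, v in zip(a, b)])


def _pdivmod_monic(a, b, m):
    """Divide a by the *monic* polynomial b over Z_m."""
    a = [c % m for c in a]
    db, da = len(b) - 1, len(a) - 1
    if da < db:
        return [0], _ptrim(a)
    q = [0] * (da - db + 1)
    rem = list(a)
    for i in range(da - db, -1, -1):
        c = rem[i + db] % m
        if c:
            q[i] = c
            for j, bj in enumerate(b):
                rem[i + j] = (rem[i + j] - c * bj) % m
    return _ptrim(q), _ptrim(rem[:db] if db else [0])


def _pgcdext(a, b, p):
    """Extended Euclid over GF(p): returns (g, s, t) with s*a + t*b = g."""
    r0, r1 = [c % p for c in a], [c % p for c in b]
    s0, s1 = [1], [0]
    t0, t1 = [0], [1]
    while _ptrim(r1) != [0]:
        lead = r1[-1] % p
        inv = pow(lead, -1, p)
        r1m = [c * inv % p for c in r1]
        q, r2 = _pdivmod_monic(r0, r1m, p)
        q = [c * inv % p for c in q]
        r0, r1 = r1, r2
        s0, s1 = s1, _psub(s0, _pmul(q, s1, p), p)
        t0, t1 = t1, _psub(t0, _pmul(q, t1, p), p)
    lead = r0[-1] % p
    inv = pow(lead, -1, p)
    return ([c * inv % p for c in r0], [c * inv % p for c in s0],
            [c * inv % p for c in t0])


def _hensel_pair(F, g, h, p, target):
    """Lift F = g*h from mod p to mod p^target (g, h monic, coprime mod p)."""
    _, s, t = _pgcdext(g, h, p)
    mod = p
    while mod < target:
        mod2 = mod * p
        d = _psub(F, _pmul(g, h, mod2), mod2)
        assert all(c % mod == 0 for c in d)
        dd = [(c // mod) % p for c in d]
        # u*h + w*g = dd (mod p): u = t*dd mod g, w = s*dd + q*h
        tq, u = _pdivmod_monic(_pmul(t, dd, p), g, p)
        w = _padd(_pmul(s, dd, p), _pmul(tq, h, p), p)
        g = _padd(g, [c * mod % mod2 for c in u], mod2)
        h = _padd(h, [c * mod % mod2 for c in w], mod2)
        mod = mod2
        assert _psub(F, _pmul(g, h, mod), mod) == [0]
    return g, h


def _lift_factors(F, factors, p, target):
    """Hensel-lift a coprime monic factorization of F from mod p to p^target."""
    if len(factors) == 1:
        return [[c % target for c in F]]
    g = factors[0]
    h = [1]
    for f in factors[1:]:
        h = _pmul(h, f, p)
    g_l, h_l = _hensel_pair(F, g, h, p, target)
    return [g_l] + _lift_factors(h_l, factors[1:], p, target)


def _poly_inverse_mod(a, f, p, target):
    """Inverse of a modulo (f, p^target), f monic, gcd(a, f) = 1 mod p."""
    g, s, _ = _pgcdext(a, f, p)
    if g != [1]:
        raise ParameterError("polynomial not invertible in slot ring")
    b = s  # inverse mod p
    mod = p
    while mod < target:
        mod = min(mod * mod, target)
        while target % mod:
            mod *= p
        two_minus = _psub([2], _pmul(a, b, mod), mod)
        b = _pdivmod_monic(_pmul(b, two_minus, mod), f, mod)[1]
    return b


class SlotCodec:
    """Encode/decode integer slot vectors for plaintext modulus p^m.

    Parameters
    ----------
    n : ring dimension
    p : odd prime base
    m : exponent (modulus p^m); m = r for data, m = e inside bootstrapping
    generator : preferred rotation generator (Galois exponent, default 3)
    """

    def __init__(self, n: int, p: int, m: int, generator: int = 3):
        self.n, self.p, self.m = n, p, m
        self.modulus = p**m
        self.k = slot_count(n, p, m)
        F = [1] + [0] * (n - 1) + [1]  # x^n + 1
        poly = sympy.Poly(_x**n + 1, _x, modulus=p)
        fac = poly.factor_list()[1]
        factors_p = []
        for f, mult in fac:
            if mult != 1:
                raise ParameterError("x^n+1 not squarefree mod p")
            cs = [int(c) % p for c in reversed(f.all_coeffs())]
            factors_p.append(cs)
        assert len(factors_p) == self.k
        self.factors = _lift_factors(F, factors_p, p, self.modulus)
        self._build_idempotents(F)
        self._build_rotation_structure(generator)

    # -- CRT plumbing -------------------------------------------------------

    def _build_idempotents(self, F):
        m = self.modulus
        self.idempotents = []
        for f in self.factors:
            G, rem = _pdivmod_monic(F, f, m)
            assert rem == [0]
            Gmod = _pdivmod_monic(G, f, m)[1]
            inv = _poly_inverse_mod(Gmod, f, self.p, m)
            E = _pmul(G, inv, m)
            E = _pdivmod_monic(E, F, m)[1] if len(E) > self.n else E
            self.idempotents.append(E)

    @property
    def fully_split(self) -> bool:
        return all(len(f) == 2 for f in self.factors)

    @property
    def roots(self):
        """Roots of x^n+1 mod p^m in slot order (fully-split codecs only)."""
        if not self.fully_split:
            raise ParameterError("roots only defined for fully-splitting codecs")
        return [(-f[0]) % self.modulus for f in self.factors]

    def encode(self, values) -> RingElement:
        values = list(values)
        if len(values) != self.k:
            raise ValueError(f"expected {self.k} slot values, got {len(values)}")
        m = self.modulus
        out = [0] * self.n
        for v, E in zip(values, self.idempotents):
            v = v % m
            if v == 0:
                continue
            for j, c in enumerate(E):
                out[j] = (out[j] + v * c) % m
        return RingElement(tuple(out), m)

    def decode(self, pt: RingElement):
        if pt.modulus != self.modulus or pt.n != self.n:
            raise ValueError("plaintext does not match codec")
        coeffs = [c % self.modulus for c in pt.coeffs]
        out = []
        for f in self.factors:
            rem = _pdivmod_monic(coeffs, f, self.modulus)[1]
            if len(rem) > 1:
                raise ValueError("slot holds non-integer (degree > 0) content")
            out.append(centered(rem[0], self.modulus))
        return out

    # -- rotations ----------------------------------------------------------

    def _slot_perm(self, a: int):
        """Permutation sigma_a with tau_a moving slot i -> sigma_a(i)."""
        perm = [None] * self.k
        for i in range(self.k):
            basis = self.encode([1 if j == i else 0 for j in range(self.k)])
            moved = self.decode(basis.automorphism(a))
            perm[i] = moved.index(1)
        return tuple(perm)

    def _build_rotation_structure(self, generator: int):
        n2 = 2 * self.n
        if self.k == 1:
            self.generator = 1
            self.auto_perms = {1: (0,)}
            return
        # candidate generators: preferred one first, then all odd exponents
        candidates = [generator % n2] + [a for a in range(3, n2, 2)]
        best = None
        for g in candidates:
            if g % 2 == 0 or sympy.gcd(g, n2) != 1:
                continue
            perm = self._slot_perm(g)
            orbit = [0]
            while True:
                nxt = perm[orbit[-1]]
                if nxt == 0:
                    break
                orbit.append(nxt)
            if len(orbit) == self.k:
                best = (g, orbit, None)
                break
            if len(orbit) == self.k // 2 and best is None:
                best = (g, orbit, "half")
        if best is None:
            raise ParameterError("no usable rotation generator found")
        g, orbit, kind = best
        if kind == "half":
            # find an involution h mapping the g-orbit onto its complement
            comp = [i for i in range(self.k) if i not in orbit]
            order = None
            for h in range(3, n2, 2):
                if sympy.gcd(h, n2) != 1:
                    continue
                ph = self._slot_perm(h)
                if ph[orbit[0]] in comp and ph[ph[orbit[0]]] == orbit[0]:
                    row1 = [ph[s] for s in orbit]
                    if set(row1) == set(comp):
                        order = orbit + row1
                        break
            if order is None:
                raise ParameterError("cannot order slots for cyclic rotation")
        else:
            order = orbit
        # relabel slots along the orbit order
        self.factors = [self.factors[i] for i in order]
        self.idempotents = [self.idempotents[i] for i in order]
        self.generator = g
        # permutations of every automorphism, in the new order
        self.auto_perms = {}
        for a in range(1, n2, 2):
            if sympy.gcd(a, n2) == 1:
                self.auto_perms[a] = self._slot_perm(a)

    def rotation_plan(self, j: int):
        """Decompose cyclic right-rotation by j into masked automorphisms.

        Returns a list of (automorphism exponent a, source-slot 0/1 mask)
        such that summing tau_a(mask * pt) over the list rotates the slot
        vector right by j.  At most two automorphisms are ever needed for
        the shipped presets.
        """
        j %= self.k
        if j == 0:
            return [(1, [1] * self.k)]
        remaining = set(range(self.k))
        plan = []
        for a, perm in self.auto_perms.items():
            if not remaining:
                break
            hit = [i for i in remaining if perm[i] == (i + j) % self.k]
            if hit:
                mask = [1 if i in hit else 0 for i in range(self.k)]
                plan.append((a, mask))
                remaining -= set(hit)
        if remaining:
            raise ParameterError(f"rotation by {j} not realisable with this codec")
        return plan

    def rotate_values(self, values, j: int):
        """Plaintext-side right rotation by j (the contract rotate obeys)."""
        j %= self.k
        return values[-j:] + values[:-j] if j else list(values)
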