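"""Encryption parameters, named presets and seeded randomness.

The FV scheme works over R_q = Z_q[x]/(x^n + 1) with plaintexts in
R_t, t = p^r a power of an odd prime.  ``delta`` is the scaling factor
floor(q/t) used when embedding plaintexts into ciphertexts.  Presets
bundle the ring parameters together with the bootstrapping exponent
``e`` (intermediate plaintext modulus p^e) and the fixed-point digit
split (l integral, f fractional digits, r = l + 2f).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import sympy


class ParameterError(ValueError):
    """Raised when encryption parameters are inconsistent."""


def _is_power_of_two(x: int) -> bool:
    return x > 0 and (x & (x - 1)) == 0


@dataclass(frozen=True)
class EncryptionParams:
    """Static parameters of an FV instantiation.

    Attributes
    ----------
    n : ring dimension, a power of two.
    q : ciphertext coefficient modulus (possibly a product of primes).
    p : odd prime plaintext base.
    r : plaintext exponent; the plaintext modulus is t = p^r.
    sigma_err : standard deviation of the discrete Gaussian error chi.
    ternary_bound : k of the uniform secret distribution U_k (3 = ternary).
    relin_base : decomposition base w for relinearisation / key switching.
    boot_e : intermediate exponent e > r used by bootstrapping (0 = none).
    fp_l, fp_f : fixed-point integral / fractional digit counts (l + 2f = r).
    """

    n: int
    q: int
    p: int
    r: int
    sigma_err: float = 3.2
    ternary_bound: int = 3
    relin_base: int = 1 << 64
    boot_e: int = 0
    fp_l: int = 0
    fp_f: int = 0

    def __post_init__(self) -> None:
        if not _is_power_of_two(self.n):
            raise ParameterError(f"ring dimension n={self.n} is not a power of 2")
        if not sympy.isprime(self.p) or self.p == 2:
            raise ParameterError(f"plaintext base p={self.p} must be an odd prime")
        if self.r < 1:
            raise ParameterError("plaintext exponent r must be >= 1")
        if self.q <= self.t:
            raise ParameterError(f"ciphertext modulus q={self.q} must exceed t={self.t}")
        if self.boot_e and self.boot_e <= self.r:
            raise ParameterError("bootstrapping exponent e must exceed r")

    @property
    def t(self) -> int:
        """Plaintext modulus p^r."""
        return self.p**self.r

    @property
    def delta(self) -> int:
        """Delta = floor(q / t)."""
        return self.q // self.t

    @property
    def key_hash(self) -> str:
        blob = f"{self.n}|{self.q}|{self.p}|{self.r}|{self.sigma_err}".encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _sixty_bit_primes(count: int) -> list[int]:
    """Deterministic list of distinct 60-bit primes (full-scale q factors)."""
    primes: list[int] = []
    x = (1 << 60) - (1 << 32)
    while len(primes) < count:
        x = sympy.nextprime(x)
        primes.append(int(x))
    return primes


def full_scale_params() -> EncryptionParams:
    """The production-sized configuration: n = 2^15, q ~ 2^1020 as a
    product of 17 sixty-bit primes, t = 127^3 (64 slots).  Provided as
    configuration only; key generation at this size is out of scope for
    the test suite."""
    q = math.prod(_sixty_bit_primes(17))
    return EncryptionParams(n=2**15, q=q, p=127, r=3, boot_e=5, fp_l=1, fp_f=1)


def preset(name: str) -> EncryptionParams:
    """Named parameter presets.

    ``toy-p3`` / ``toy-p5``   tiny rings for exhaustive bootstrapping sweeps
    ``toy-train``             n=8, p=17 fully-splitting ring (k=8 slots) large
                              enough to run encrypted training end to end
    ``toy-batch``             n=16, p=97 fully-splitting batching playground
    ``toy-subfield``          n=8, p=3: k=2 < n, slots are Galois rings
    ``idash-shape``           the full-scale configuration (config only)
    """
    presets = {
        "toy-p3": EncryptionParams(n=2, q=1 << 400, p=3, r=2, boot_e=5, fp_l=0, fp_f=1),
        "toy-p5": EncryptionParams(n=2, q=1 << 400, p=5, r=2, boot_e=4, fp_l=0, fp_f=1),
        "toy-train": EncryptionParams(
            n=8, q=1 << 1600, p=17, r=3, boot_e=6, fp_l=1, fp_f=1
        ),
        "toy-batch": EncryptionParams(n=16, q=1 << 240, p=97, r=2, fp_l=0, fp_f=1),
        "toy-subfield": EncryptionParams(n=8, q=1 << 240, p=3, r=2, fp_l=0, fp_f=1),
    }
    if name == "idash-shape":
        return full_scale_params()
    try:
        return presets[name]
    except KeyError:
        raise ParameterError(f"unknown preset {name!r}; options: "
                             f"{sorted(presets) + ['idash-shape']}") from None


def make_rng(seed) -> np.random.Generator:
    """Single injected source of randomness for every sampling routine."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)
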