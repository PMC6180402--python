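"""Minimax polynomial approximation by the Remez exchange algorithm.

The degree-d minimax approximation of a continuous f on [a, b] is the
polynomial minimising the uniform norm ||f - p||; at the optimum the
error equioscillates at d + 2 points.  The exchange iteration solves,
on the current reference nodes x_0 < ... < x_{d+1},

    sum_j c_j x_i^j + (-1)^i E = f(x_i),

then replaces all nodes with the extrema of the new error curve
(multi-point exchange), starting from Chebyshev nodes.  Linear solves
run in mpmath at 50 significant digits so that coefficients reported to
three decimals are insensitive to conditioning.

Applied to the logistic sigmoid on [-5, 5] this yields the linear and
cubic approximations used by the encrypted trainers,
sigma1(x) = 0.125x + 0.5 and sigma3(x) = -0.004x^3 + 0.197x + 0.5
(coefficients to three decimals).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import mpmath as mp


class RemezConvergenceError(RuntimeError):
    """Exchange iteration failed to converge; carries diagnostics."""


def sigmoid(x):
    return 1 / (1 + mp.e ** (-mp.mpf(x)))


@dataclass(frozen=True)
class PolyApprox:
    """Minimax polynomial: ascending coefficients, uniform error, and the
    equioscillation reference."""

    degree: int
    interval: tuple
    coeffs: tuple            # ascending, floats
    max_error: float
    alternation_points: tuple

    def __call__(self, x):
        acc = 0.0
        for c in reversed(self.coeffs):
            acc = acc * x + c
        return acc

    def rounded(self, decimals: int = 3) -> tuple:
        return tuple(round(c, decimals) for c in self.coeffs)


def _eval_poly(coeffs, x):
    acc = mp.mpf(0)
    for c in reversed(coeffs):
        acc = acc * x + c
    return acc


def remez(f, a, b, d, tol=1e-12, max_iter=80, dps=50, grid=4000) -> PolyApprox:
    """Minimax approximation of f on [a, b] by a degree-d polynomial.

    Multi-point exchange with Chebyshev-node initialisation; converges
    when the relative change of the levelled error drops below tol.
    """
    if d < 0:
        raise ValueError("degree must be non-negative")
    with mp.workdps(dps):
        a, b = mp.mpf(a), mp.mpf(b)
        mid, half = (a + b) / 2, (b - a) / 2
        nodes = [mid + half * mp.cos(mp.pi * i / (d + 1)) for i in range(d + 2)]
        nodes.sort()
        E_prev = None
        for _ in range(max_iter):
            # solve for coefficients and levelled error E
            A = mp.matrix(d + 2, d + 2)
            rhs = mp.matrix(d + 2, 1)
            for i, x in enumerate(nodes):
                xp = mp.mpf(1)
                for j in range(d + 1):
                    A[i, j] = xp
                    xp *= x
                A[i, d + 1] = (-1) ** i
                rhs[i] = f(x)
            sol = mp.lu_solve(A, rhs)
            coeffs = [sol[j] for j in range(d + 1)]
            E = sol[d + 1]
            err = lambda x: f(x) - _eval_poly(coeffs, x)
            nodes = _extrema(err, a, b, d + 2, grid)
            if E_prev is not None and abs(abs(E) - abs(E_prev)) <= tol * max(
                abs(E), mp.mpf(tol)
            ):
                scan = max(abs(err(a + (b - a) * mp.mpf(i) / grid))
                           for i in range(grid + 1))
                return PolyApprox(
                    degree=d,
                    interval=(float(a), float(b)),
                    coeffs=tuple(float(c) for c in coeffs),
                    max_error=float(scan),
                    alternation_points=tuple(float(x) for x in nodes),
                )
            E_prev = E
    raise RemezConvergenceError(
        f"no convergence in {max_iter} iterations (last E={float(E)!r})"
    )


def _extrema(err, a, b, count, grid):
    """Alternating extrema of the error on a dense grid (multi-point
    exchange reference), endpoints included."""
    xs = [a + (b - a) * mp.mpf(i) / grid for i in range(grid + 1)]
    es = [err(x) for x in xs]
    cand = [0]
    for i in range(1, grid):
        if (es[i] - es[i - 1]) * (es[i + 1] - es[i]) <= 0:
            cand.append(i)
    cand.append(grid)
    # deduplicate neighbours, keep largest |err| per sign run
    pts = []
    for i in cand:
        if pts and mp.sign(es[i]) == mp.sign(es[pts[-1]]):
            if abs(es[i]) > abs(es[pts[-1]]):
                pts[-1] = i
        else:
            pts.append(i)
    # degenerate case: the error is numerically zero (f itself a polynomial
    # of degree <= d); any reference set works, take evenly spaced nodes
    if len(pts) < count:
        return [a + (b - a) * mp.mpf(i) / (count - 1) for i in range(count)]
    # keep the `count` consecutive alternating points with largest amplitude
    best, best_amp = None, -1
    for s in range(len(pts) - count + 1):
        amp = min(abs(es[i]) for i in pts[s:s + count])
        if amp > best_amp:
            best, best_amp = s, amp
    return [xs[i] for i in pts[best:best + count]]


def poly_error_scan(approx: PolyApprox, f, grid_size: int = 2000) -> float:
    """Dense-grid maximum absolute deviation |f - p| on the interval."""
    a, b = approx.interval
    worst = 0.0
    for i in range(grid_size + 1):
        x = a + (b - a) * i / grid_size
        worst = max(worst, abs(float(f(x)) - approx(x)))
    return worst


@lru_cache(maxsize=None)
def sigmoid_minimax(degree: int, a: float = -5.0, b: float = 5.0) -> PolyApprox:
    """The minimax sigmoid approximations the trainers consume (cached)."""
    return remez(sigmoid, a, b, degree)
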