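"""Logistic-regression training: floating point, fixed point, encrypted.

Three synchronised implementations of the same two algorithms:

* float reference — full gradient descent  w <- w - alpha (sigma(Xw) - y) X^T
  and 1-bit gradient descent, which applies only the sign of each
  gradient coordinate and feeds the quantisation remainder back through
  a residue with decay beta:  u = g + beta*residue,
  w' = w - alpha*sign(u), residue' = u - alpha*sign(u);

* fixed-point oracle — the same loops in balanced base-p integers with
  explicit bscale rescaling, mirroring the encrypted circuit operation
  for operation (this is the ground truth the encrypted path must
  reproduce bit for bit);

* encrypted pipeline — the fixed-point circuit expressed through the
  cipher-backend contract: the dataset is encoded vertically (one
  ciphertext holds one feature across k samples), inner products use
  slot-wise multiply plus sumslots (log2 k rotations), the cubic
  sigmoid is evaluated as
      sigma3(x) ~ bscale(C0 + C1*x~ - bscale(bscale(C8*x~)^2) * x~)
  with C0 = floor(0.5 p^2), C1 = floor(0.197 p), C8 = floor(0.063 p),
  and the learning rate is applied through its square root's digit:
      alpha*x ~ bscale(a~ * bscale(a~ * x~)),  a~ = round(sqrt(alpha) p).
  Weight updates optionally batch the D per-feature scalings into
  ceil(D/k) ciphertexts via combine/expand.

Feature values are small integers encrypted at scale p^0; weights,
sigmoid outputs and labels live at scale p^f.  Labels are encoded at
the sigmoid output's scale so the residual subtraction needs no
rescaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .fixedpoint import FixedPointCodec, fp_scale_const
from .params import ParameterError
from .remez import sigmoid_minimax
from .ring import balanced_scale, centered

# ---------------------------------------------------------------------------
# configuration and containers


@dataclass
class TrainConfig:
    alpha: float = 0.002
    beta: float = 0.2
    iterations: int = 10
    sigmoid: str = "s3"              # exact | s1 | s3
    use_combine: bool = True
    residue_strategy: str = "residual"   # residual | decay_after
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ParameterError("learning rate alpha must be positive")
        if not 0 <= self.beta <= 1:
            raise ParameterError("residue decay beta must be in [0, 1]")
        if self.iterations < 1:
            raise ParameterError("iteration count must be >= 1")
        if self.sigmoid not in ("exact", "s1", "s3"):
            raise ParameterError(f"unknown sigmoid variant {self.sigmoid!r}")


@dataclass
class Dataset:
    """X: N x D int matrix whose first column is all ones (bias); y in {0,1}."""

    X: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or self.y.ndim != 1 or len(self.y) != len(self.X):
            raise ParameterError("dataset shapes are inconsistent")
        if not np.all(self.X[:, 0] == 1):
            raise ParameterError("first column of X must be the all-ones bias")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ParameterError("labels must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelState:
    """Weights (and, for 1-bit GD, residues): floats, fixed-point integers
    or ciphertext handles depending on the trainer."""

    w: list
    residue: list | None = None


@dataclass
class EncodedDataset:
    """Vertically batched dataset: Xenc[b][j] encrypts feature j of block
    b across k samples; masks zero the padding of the last block."""

    Xenc: list
    Yenc: list
    masks: list
    n_samples: int
    k: int


# ---------------------------------------------------------------------------
# sigmoid variants (float)


def sigmoid_exact(z):
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def sigmoid_fn(name: str):
    if name == "exact":
        return sigmoid_exact
    if name == "s1":
        p1 = sigmoid_minimax(1)
        return lambda z: np.polyval(p1.coeffs[::-1], np.asarray(z, dtype=float))
    if name == "s3":
        p3 = sigmoid_minimax(3)
        return lambda z: np.polyval(p3.coeffs[::-1], np.asarray(z, dtype=float))
    raise ParameterError(f"unknown sigmoid variant {name!r}")


def logistic_loss(w, X, y):
    z = X @ np.asarray(w, dtype=float)
    return float(np.mean(np.log1p(np.exp(-z)) + (1 - np.asarray(y)) * z))


# ---------------------------------------------------------------------------
# float trainers


def gd_step(w, X, y, alpha, sigmoid="exact"):
    """One full-gradient step: w <- w - alpha (sigma(Xw) - y) X^T."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if X.shape[1] != len(w) or X.shape[0] != len(y):
        raise ParameterError("shape mismatch in gd_step")
    sig = sigmoid if callable(sigmoid) else sigmoid_fn(sigmoid)
    return w - alpha * ((sig(X @ w) - y) @ X)


def onebit_gd_step(w, residue, X, y, alpha, beta, sigmoid="s1",
                   strategy="residual"):
    """One 1-bit step: only sign(g + beta*residue) reaches the weights;
    the unused remainder feeds the residue (sign(0) = 0)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    residue = np.asarray(residue, dtype=float)
    sig = sigmoid if callable(sigmoid) else sigmoid_fn(sigmoid)
    g = (sig(X @ w) - y) @ X
    u = g + beta * residue
    step = alpha * np.sign(u)
    if strategy == "residual":
        new_res = u - step
    elif strategy == "decay_after":
        new_res = beta * (u - step)
    else:
        raise ParameterError(f"unknown residue strategy {strategy!r}")
    return w - step, new_res


def train_gd(data: Dataset, config: TrainConfig, w0=None):
    """Run T float GD steps; returns the model and per-iteration losses."""
    w = np.zeros(data.n_features) if w0 is None else np.asarray(w0, dtype=float)
    losses = []
    for _ in range(config.iterations):
        w = gd_step(w, data.X, data.y, config.alpha, config.sigmoid)
        losses.append(logistic_loss(w, data.X, data.y))
    return ModelState(w=list(w)), losses


def train_onebit(data: Dataset, config: TrainConfig, w0=None):
    w = np.zeros(data.n_features) if w0 is None else np.asarray(w0, dtype=float)
    res = np.zeros_like(w)
    losses = []
    for _ in range(config.iterations):
        w, res = onebit_gd_step(w, res, data.X, data.y, config.alpha,
                                config.beta, config.sigmoid,
                                config.residue_strategy)
        losses.append(logistic_loss(w, data.X, data.y))
    return ModelState(w=list(w), residue=list(res)), losses


# ---------------------------------------------------------------------------
# fixed-point constants and the plaintext trace oracle


@dataclass(frozen=True)
class SigmaConstants:
    """Scaled circuit constants for one base p (floor variant, except the
    learning-rate digit which is nearest)."""

    c_half: int      # floor(0.5 p^2), scale 2
    c_lin3: int      # floor(0.197 p), scale 1
    c_cub: int       # floor(0.063 p), scale 1 (0.004 ~ 0.063^2)
    c_lin1: int      # floor(0.125 p), scale 1

    @classmethod
    def for_base(cls, p: int) -> "SigmaConstants":
        return cls(
            c_half=fp_scale_const("0.5", 2, p),
            c_lin3=fp_scale_const("0.197", 1, p),
            c_cub=fp_scale_const("0.063", 1, p),
            c_lin1=fp_scale_const("0.125", 1, p),
        )


def alpha_digit(alpha: float, p: int) -> int:
    """Fixed-point digit of sqrt(alpha): the factor applied twice (with a
    bscale after each) to realise multiplication by alpha."""
    return fp_scale_const(math.sqrt(alpha), 1, p, mode="nearest")


def _cmod(a, m):
    half = m // 2
    return (a + half) % m - half


def _bscale_arr(a, pi, m):
    """Balanced digit dropping on an integer array: round(a / p^i)."""
    a = _cmod(np.asarray(a, dtype=np.int64), m)
    q = np.where(a >= 0, (2 * a + pi) // (2 * pi), -((-2 * a + pi) // (2 * pi)))
    return _cmod(q, m)


class FixedTrace:
    """Plaintext fixed-point trainer: the exact-arithmetic oracle for the
    encrypted circuit (same constants, same rescaling points)."""

    def __init__(self, codec: FixedPointCodec):
        self.codec = codec
        self.p = codec.p
        self.m = codec.modulus
        self.consts = SigmaConstants.for_base(codec.p)

    def sigma3(self, z):
        c, p, m = self.consts, self.p, self.m
        inner = _bscale_arr(_cmod(c.c_cub * z, m), p, m)
        sq = _bscale_arr(_cmod(inner * inner, m), p, m)
        acc = _cmod(c.c_half + c.c_lin3 * z - _cmod(sq * z, m), m)
        return _bscale_arr(acc, p, m)

    def sigma1(self, z):
        c, p, m = self.consts, self.p, self.m
        acc = _cmod(fp_scale_const("0.5", 2, p) + c.c_lin1 * z, m)
        return _bscale_arr(acc, p, m)

    def apply_alpha(self, g, adigit):
        p, m = self.p, self.m
        once = _bscale_arr(_cmod(adigit * g, m), p, m)
        return _bscale_arr(_cmod(adigit * once, m), p, m)

    def gd_iteration(self, wq, data: Dataset, adigit: int):
        """One full-GD step on scaled integer weights; returns new weights."""
        p, m = self.p, self.m
        X = data.X
        z = _cmod(X @ np.asarray(wq, dtype=np.int64), m)
        s = self.sigma3(z)
        d = _cmod(s - p * data.y, m)
        g = _cmod(d @ X, m)
        return list(_cmod(np.asarray(wq) - self.apply_alpha(g, adigit), m))

    def onebit_iteration(self, wq, resq, data: Dataset, alpha: float,
                         beta: float):
        p, m = self.p, self.m
        a_int = fp_scale_const(alpha, 1, p, mode="nearest")
        b_int = fp_scale_const(beta, 1, p, mode="nearest")
        X = data.X
        z = _cmod(X @ np.asarray(wq, dtype=np.int64), m)
        s = self.sigma1(z)
        d = _cmod(s - p * data.y, m)
        g = _cmod(d @ X, m)
        u = _cmod(g + _bscale_arr(_cmod(b_int * np.asarray(resq), m), p, m), m)
        sgn = _bscale_arr(u, p ** (self.codec.r - 1), m)
        step = _cmod(a_int * sgn, m)
        return (list(_cmod(np.asarray(wq) - step, m)),
                list(_cmod(u - step, m)))


# ---------------------------------------------------------------------------
# encrypted pipeline (backend-generic)


def sumslots(backend, ct):
    """Every slot becomes the sum of all k slots: log2(k) rotations and
    additions (rotate by 1, 2, 4, ...)."""
    k = backend.k
    if k & (k - 1):
        raise ParameterError("sumslots needs a power-of-two slot count")
    step = 1
    while step < k:
        ct = backend.add(ct, backend.rotate(ct, step))
        step *= 2
    return ct


def combine(backend, cts):
    """Pack k constant-vector ciphertexts into one holding (d0,...,d_{k-1})."""
    k = backend.k
    if len(cts) > k:
        raise ParameterError(f"combine takes at most {k} ciphertexts")
    acc = None
    for i, ct in enumerate(cts):
        unit = [1 if s == i else 0 for s in range(k)]
        term = backend.plainmult(ct, unit)
        acc = term if acc is None else backend.add(acc, term)
    return acc


def expand(backend, ct, count=None):
    """Inverse of combine: k constant-vector ciphertexts via mask+sumslots."""
    k = backend.k
    out = []
    for i in range(count if count is not None else k):
        unit = [1 if s == i else 0 for s in range(k)]
        out.append(sumslots(backend, backend.plainmult(ct, unit)))
    return out


def eval_sigma3_encrypted(backend, ct, consts: SigmaConstants):
    """bscale(C0 + C1 x~ - bscale(bscale(C8 x~)^2) x~), slot-wise."""
    inner = backend.bscale(backend.plainmult(ct, consts.c_cub))
    sq = backend.bscale(backend.mul(inner, inner))
    cube = backend.mul(sq, ct)
    acc = backend.add_const(backend.sub(backend.plainmult(ct, consts.c_lin3),
                                        cube), consts.c_half)
    return backend.bscale(acc)


def eval_sigma1_encrypted(backend, ct, consts: SigmaConstants):
    acc = backend.add_const(backend.plainmult(ct, consts.c_lin1), consts.c_half)
    return backend.bscale(acc)


def mult_learning_rate(backend, ct, adigit: int):
    """alpha*x ~ bscale(a~ * bscale(a~ * x~)) via the sqrt-alpha digit."""
    return backend.bscale(backend.plainmult(backend.bscale(
        backend.plainmult(ct, adigit)), adigit))


def encode_dataset(backend, data: Dataset) -> EncodedDataset:
    """Vertical encoding: ceil(N/k) x D ciphertext matrix, one feature per
    ciphertext across k samples; labels at the sigmoid output scale."""
    k, p = backend.k, backend.p
    N, D = data.n_samples, data.n_features
    Xenc, Yenc, masks = [], [], []
    for start in range(0, N, k):
        idx = list(range(start, min(start + k, N)))
        pad = k - len(idx)
        mask = [1] * len(idx) + [0] * pad
        Xenc.append([
            backend.encrypt_vec([int(data.X[i, j]) for i in idx] + [0] * pad)
            for j in range(D)
        ])
        Yenc.append(backend.encrypt_vec(
            [p * int(data.y[i]) for i in idx] + [0] * pad))
        masks.append(mask)
    return EncodedDataset(Xenc, Yenc, masks, N, k)


def init_encrypted_model(backend, n_features: int, w0=None) -> ModelState:
    k = backend.k
    vals = [0] * n_features if w0 is None else list(w0)
    return ModelState(
        w=[backend.encrypt_vec([int(v)] * k) for v in vals],
        residue=[backend.encrypt_vec([0] * k) for _ in range(n_features)],
    )


def _gradient_blocks(backend, model, enc: EncodedDataset, consts, variant):
    """Accumulated per-feature gradient ciphertexts (constant vectors)."""
    D = len(model.w)
    grad = [None] * D
    for Xb, Yb, mask in zip(enc.Xenc, enc.Yenc, enc.masks):
        z = None
        for j in range(D):
            term = backend.mul(Xb[j], model.w[j])
            z = term if z is None else backend.add(z, term)
        s = (eval_sigma3_encrypted(backend, z, consts) if variant == "s3"
             else eval_sigma1_encrypted(backend, z, consts))
        d = backend.sub(s, Yb)
        if not all(mask):
            d = backend.plainmult(d, mask)
        for j in range(D):
            delta = sumslots(backend, backend.mul(d, Xb[j]))
            grad[j] = delta if grad[j] is None else backend.add(grad[j], delta)
    return grad


def _apply_alpha_batched(backend, cts, adigit, use_combine):
    """alpha * each constant-vector ciphertext, batching ceil(D/k) scalings
    through combine/expand when enabled."""
    if not use_combine:
        return [mult_learning_rate(backend, ct, adigit) for ct in cts]
    k = backend.k
    out = []
    for start in range(0, len(cts), k):
        chunk = cts[start:start + k]
        packed = combine(backend, chunk)
        scaled = mult_learning_rate(backend, packed, adigit)
        out.extend(expand(backend, scaled, count=len(chunk)))
    return out


def encrypted_gd_iteration(backend, model: ModelState, enc: EncodedDataset,
                           config: TrainConfig) -> ModelState:
    """One full-GD step over encrypted data (cubic sigmoid)."""
    consts = SigmaConstants.for_base(backend.p)
    adigit = alpha_digit(config.alpha, backend.p)
    grad = _gradient_blocks(backend, model, enc, consts, "s3")
    upd = _apply_alpha_batched(backend, grad, adigit, config.use_combine)
    new_w = [backend.sub(w, u) for w, u in zip(model.w, upd)]
    return ModelState(w=new_w, residue=model.residue)


def encrypted_onebit_iteration(backend, model: ModelState, enc: EncodedDataset,
                               config: TrainConfig) -> ModelState:
    """One 1-bit GD step over encrypted data: the gradient (plus decayed
    residue) passes through homomorphic sign extraction; only the sign,
    scaled by alpha, reaches the weights."""
    p = backend.p
    consts = SigmaConstants.for_base(p)
    a_int = fp_scale_const(config.alpha, 1, p, mode="nearest")
    b_int = fp_scale_const(config.beta, 1, p, mode="nearest")
    grad = _gradient_blocks(backend, model, enc, consts, "s1")
    new_w, new_res = [], []
    for w_ct, r_ct, g_ct in zip(model.w, model.residue, grad):
        u = backend.add(g_ct, backend.bscale(backend.plainmult(r_ct, b_int)))
        sgn = backend.sign_extract(u)
        step = backend.plainmult(sgn, a_int)
        new_w.append(backend.sub(w_ct, step))
        new_res.append(backend.sub(u, step))
    return ModelState(w=new_w, residue=new_res)


def decrypt_model(backend, model: ModelState):
    """Constant-slot weight ciphertexts -> scaled integer weights."""
    out = []
    for ct in model.w:
        vals = backend.decrypt_vec(ct)
        if len(set(vals)) != 1:
            raise ParameterError("weight ciphertext is not a constant vector")
        out.append(vals[0])
    return out


def train_encrypted(backend, data: Dataset, config: TrainConfig,
                    algorithm: str = "gd"):
    """Full encrypted training loop; returns the final ModelState."""
    enc = encode_dataset(backend, data)
    model = init_encrypted_model(backend, data.n_features)
    step = (encrypted_gd_iteration if algorithm == "gd"
            else encrypted_onebit_iteration)
    for _ in range(config.iterations):
        model = step(backend, model, enc, config)
    return model
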