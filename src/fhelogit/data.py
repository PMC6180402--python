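"""Synthetic data, evaluation and file I/O.

The synthetic generator emulates the shape of the genomic training task
the method targets: ~1500 records with 18 binary genotype features and
a binary phenotype drawn from a ground-truth logistic model
Pr(y=1|x) = sigma(w*.x), with optional label-flip noise.  An
image-compression helper reproduces the preprocessing used for the
handwritten-digit benchmark: integer-divide 28x28 grey levels by 32 and
2x2 average-pool (floored) to 196 integer features in [0, 8).

Evaluation is 10-fold cross-validated AUC: the probability that a
random positive sample outranks a random negative one (Mann-Whitney
rank statistic, ties scored 1/2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .params import ParameterError, make_rng
from .training import Dataset, sigmoid_exact


@dataclass
class SynthSpec:
    """Ground-truth model for the synthetic generator.

    The default shape mirrors the genomic setting (N=1579 samples, 18
    binary features); a reduced preset (N=64, D=4) serves the encrypted
    path.  At noise 0, labels follow Pr(y=1|x) = sigma(w*.x) exactly.
    """

    n_samples: int = 1579
    n_features: int = 18
    w_true: np.ndarray | None = None
    bias: float = -0.5
    noise: float = 0.0
    feature_high: int = 2     # features uniform integers in [0, feature_high)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1 or self.n_features < 1:
            raise ParameterError("empty synthetic specification")
        if not 0 <= self.noise <= 1:
            raise ParameterError("label noise rate must be in [0, 1]")


def small_preset() -> SynthSpec:
    """Reduced shape for encrypted-path tests."""
    return SynthSpec(n_samples=64, n_features=4)


def generate_synthetic(spec: SynthSpec) -> Dataset:
    """Binary/integer features plus bias column; logistic labels with
    optional flip noise; deterministic given the seed."""
    rng = make_rng(spec.seed)
    X = rng.integers(0, spec.feature_high,
                     size=(spec.n_samples, spec.n_features)).astype(np.int64)
    if spec.w_true is None:
        w = rng.normal(0, 2.0, size=spec.n_features)
    else:
        w = np.asarray(spec.w_true, dtype=float)
        if len(w) != spec.n_features:
            raise ParameterError("w_true length does not match n_features")
    logits = spec.bias + X @ w
    y = (rng.random(spec.n_samples) < sigmoid_exact(logits)).astype(np.int64)
    if spec.noise > 0:
        flips = rng.random(spec.n_samples) < spec.noise
        y = np.where(flips, 1 - y, y)
    Xb = np.hstack([np.ones((spec.n_samples, 1), dtype=np.int64), X])
    return Dataset(Xb, y)


def avg_pool_compress(images) -> np.ndarray:
    """28x28 grey images -> 196 integer features in [0, 8): divide each
    pixel by 32 (integer floor), then 2x2 average pooling (floored)."""
    arr = np.asarray(images, dtype=np.int64)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.shape[-2:] != (28, 28):
        raise ParameterError(f"expected 28x28 images, got {arr.shape[-2:]}")
    if arr.min() < 0 or arr.max() > 255:
        raise ParameterError("pixel values must lie in [0, 256)")
    scaled = arr // 32
    pooled = (scaled.reshape(-1, 14, 2, 14, 2).sum(axis=(2, 4))) // 4
    out = pooled.reshape(-1, 196)
    return out[0] if single else out


def auc(scores, labels) -> float:
    """P(random positive outranks random negative), ties 1/2: the
    Mann-Whitney rank statistic."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC needs both classes present")
    ranks = rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class EvalReport:
    fold_aucs: list
    mean_auc: float
    fold_weights: list
    config: dict = field(default_factory=dict)


def kfold_cv(data: Dataset, trainer, folds: int = 10, seed: int = 0,
             score_fn=None) -> EvalReport:
    """Shuffled k-fold cross-validation: train on k-1 folds, AUC on the
    held-out fold.  ``trainer(train_data) -> weights``;
    ``score_fn(weights, X)`` defaults to the linear score X @ w."""
    rng = make_rng(seed)
    N = data.n_samples
    if folds < 2 or folds > N:
        raise ParameterError("fold count out of range")
    idx = rng.permutation(N)
    splits = np.array_split(idx, folds)
    if score_fn is None:
        score_fn = lambda w, X: X @ np.asarray(w, dtype=float)
    fold_aucs, fold_ws = [], []
    for f, test_idx in enumerate(splits):
        if len(set(data.y[test_idx].tolist())) < 2:
            raise ParameterError(f"fold {f} holds a single class; cannot score")
        train_idx = np.setdiff1d(idx, test_idx)
        sub = Dataset(data.X[train_idx], data.y[train_idx])
        w = trainer(sub)
        fold_ws.append(list(np.asarray(w, dtype=float)))
        fold_aucs.append(auc(score_fn(w, data.X[test_idx]), data.y[test_idx]))
    return EvalReport(fold_aucs, float(np.mean(fold_aucs)), fold_ws)


# ---------------------------------------------------------------------------
# file I/O


def load_dataset(path, label_column: str = "y", add_bias: bool = True) -> Dataset:
    """CSV/TSV with header, one row per sample; integer-valued features."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ParameterError(f"label column {label_column!r} missing")
    y = df[label_column].to_numpy()
    X = df.drop(columns=[label_column]).to_numpy()
    if not np.issubdtype(np.asarray(X).dtype, np.integer):
        if not np.allclose(X, np.round(X)):
            raise ParameterError("feature values must be integers")
        X = np.round(X).astype(np.int64)
    if add_bias:
        X = np.hstack([np.ones((len(y), 1), dtype=np.int64), X])
    return Dataset(X, y)


def save_dataset(data: Dataset, path, label_column: str = "y") -> None:
    cols = {f"x{j}": data.X[:, j] for j in range(1, data.n_features)}
    cols[label_column] = data.y
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    pd.DataFrame(cols).to_csv(path, index=False, sep=sep)
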