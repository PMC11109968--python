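"""K-mer-frequency linear baseline.

A probe is summarized by the frequencies of all 4^k k-mers among its sliding
windows, and the binding score is modelled as an L1-regularized (LASSO)
linear function of those features — optionally with non-negative weights and
truncation to the largest few weights.  This is the reference model against
which the thermodynamic regressor's mean absolute error is compared; it
predicts well but hides the motif inside its k-mer weights.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .probeio import ProbeSet
from .thermo import BASES, encode_sequence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KmerFeatures:
    """Probe-by-k-mer frequency matrix with its vocabulary."""

    k: int
    vocabulary: tuple[str, ...]  # lexicographic, A < C < G < T
    matrix: np.ndarray           # (n_probes, 4^k), rows sum to 1


@dataclass
class BaselineResult:
    weights: np.ndarray
    intercept: float
    mae: float
    alpha: float
    vocabulary: tuple[str, ...]

    def predict(self, features: KmerFeatures) -> np.ndarray:
        return features.matrix @ self.weights + self.intercept

    def nonzero(self) -> dict[str, float]:
        return {kmer: float(w)
                for kmer, w in zip(self.vocabulary, self.weights) if w != 0}


def kmer_vocabulary(k: int) -> tuple[str, ...]:
    return tuple("".join(t) for t in itertools.product(BASES, repeat=k))


def kmer_featurize(ps: ProbeSet, k: int) -> KmerFeatures:
    """Sliding-window k-mer frequencies (counts / number of windows)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    min_len = min(len(s) for s in ps.sequences)
    if k > min_len:
        raise ValueError(f"k={k} exceeds shortest probe length {min_len}")
    n_feat = 4 ** k
    powers = 4 ** np.arange(k - 1, -1, -1)
    X = np.zeros((len(ps), n_feat))
    for i, seq in enumerate(ps.sequences):
        codes = encode_sequence(seq).astype(np.int64)
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        idx = windows @ powers
        counts = np.bincount(idx, minlength=n_feat)
        X[i] = counts / windows.shape[0]
    return KmerFeatures(k, kmer_vocabulary(k), X)


def fit_l1_baseline(features: KmerFeatures, signals: np.ndarray,
                    alpha: float | None = None, nonneg: bool = True,
                    top_n: int | None = 10, cv_folds: int = 5,
                    seed: int = 0) -> BaselineResult:
    """LASSO fit of signals on k-mer frequencies.

    ``alpha=None`` selects the penalty by cross-validation over a log grid.
    After the LASSO step, only the ``top_n`` largest-magnitude weights are
    kept and the model is refit restricted to the surviving features.
    """
    from sklearn.linear_model import Lasso, LassoCV, LinearRegression

    X = features.matrix
    y = np.asarray(signals, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("feature/signal length mismatch")

    if alpha is None:
        cv = LassoCV(alphas=np.logspace(-6, 0, 25), positive=nonneg,
                     cv=cv_folds, random_state=seed, max_iter=50_000)
        cv.fit(X, y)
        alpha = float(cv.alpha_)
    lasso = Lasso(alpha=alpha, positive=nonneg, max_iter=50_000)
    lasso.fit(X, y)
    weights = lasso.coef_.copy()
    intercept = float(lasso.intercept_)

    if not np.any(weights):
        logger.warning("all weights zeroed at alpha=%g; intercept-only model",
                       alpha)
        intercept = float(y.mean())
        weights = np.zeros(X.shape[1])
    else:
        if top_n is not None and np.count_nonzero(weights) > top_n:
            order = np.argsort(np.abs(weights))[::-1]
            keep = order[:top_n]
            mask = np.zeros_like(weights, dtype=bool)
            mask[keep] = True
            weights[~mask] = 0.0
        support = weights != 0
        if support.any():
            refit = LinearRegression(positive=nonneg)
            refit.fit(X[:, support], y)
            weights = np.zeros(X.shape[1])
            weights[support] = refit.coef_
            intercept = float(refit.intercept_)

    pred = X @ weights + intercept
    mae = float(np.mean(np.abs(pred - y)))
    return BaselineResult(weights, intercept, mae, float(alpha),
                          features.vocabulary)
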