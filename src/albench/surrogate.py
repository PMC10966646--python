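"""Gaussian-process regression with a Tanimoto kernel on binary fingerprints.

The surrogate interface any model must satisfy is minimal:
``fit(fingerprints, labels)`` then ``predict(fingerprints) -> (mean, variance)``
with per-compound predictive means (pK units) and latent variances (pK^2).
A dropout or ensemble neural regressor can implement the same contract.

Model: y ~ GP(m, sigma_f^2 * T(x, x')) + N(0, sigma_n^2) with T the Tanimoto
similarity of fingerprint bit sets. Labels are standardized internally (zero
mean, unit sd over the training set); predictions are de-standardized back to
pK units. The reported variance is for the latent function (sigma_n^2 is not
added): acquisition ranks are unchanged either way, and callers can add the
noise variance if they want a predictive-observation variance.

Hyperparameters (kernel amplitude, noise variance, constant mean) are either
fixed or optimized by gradient ascent on the per-point log marginal
likelihood from a fixed initialization (amplitude 1.0, noise 0.1, mean 0.0;
200 iterations at rate 0.1), which keeps fits fully reproducible. Because the
Tanimoto Gram matrix is fixed during optimization, its eigendecomposition is
computed once and each gradient step costs O(n^2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.linalg import cholesky, solve_triangular

from .featurization import tanimoto_matrix

JITTER_FLOOR = 1e-6
JITTER_CEIL = 1e-4


@dataclass
class GPHyperparams:
    """Kernel and likelihood parameters in standardized label space."""

    amplitude: float = 1.0  # sigma_f^2
    noise_variance: float = 0.1  # sigma_n^2
    mean_constant: float = 0.0
    fit_iterations: int = 200
    learning_rate: float = 0.1

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.noise_variance < JITTER_FLOOR:
            raise ValueError(f"noise_variance must be >= {JITTER_FLOOR}")


@dataclass
class SurrogatePosterior:
    """Predictive mean (pK units) and latent variance (pK^2) per query compound."""

    mean: np.ndarray
    variance: np.ndarray


def kernel_matrix(X: np.ndarray, Y: np.ndarray, amplitude: float = 1.0) -> np.ndarray:
    """K[i, j] = amplitude * tanimoto(X[i], Y[j])."""
    return amplitude * tanimoto_matrix(X, Y)


class TanimotoGP:
    """Exact GP regressor with the Tanimoto kernel.

    Parameters
    ----------
    hyper:
        Fixed :class:`GPHyperparams`, or the string ``"optimize"`` to maximize
        the log marginal likelihood from the default initialization.
    optimize_params:
        Which parameters the optimizer moves (subset of
        ``{"amplitude", "noise", "mean"}``); only consulted when optimizing.
    """

    def __init__(
        self,
        hyper: Union[GPHyperparams, str] = "optimize",
        optimize_params: Sequence[str] = ("amplitude", "noise", "mean"),
    ) -> None:
        if isinstance(hyper, str) and hyper != "optimize":
            raise ValueError(f"hyper must be GPHyperparams or 'optimize', got {hyper!r}")
        self._spec = hyper
        self._optimize_params = frozenset(optimize_params)
        self.hyper: Optional[GPHyperparams] = None
        self._fitted = False

    # -- fitting -----------------------------------------------------------

    def fit(self, fingerprints: np.ndarray, labels: np.ndarray) -> "TanimotoGP":
        X = np.asarray(fingerprints)
        y = np.asarray(labels, dtype=float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("need an (n, d) fingerprint matrix and n labels")
        if len(y) < 1:
            raise ValueError("need at least one training point")
        if not np.all(np.isfinite(y)):
            raise ValueError("labels must be finite")

        self._X = X
        self._y_mean = float(y.mean())
        sd = float(y.std())
        self._y_sd = sd if sd > 0 else 1.0
        z = (y - self._y_mean) / self._y_sd

        T = tanimoto_matrix(X, X)
        if self._spec == "optimize":
            self.hyper = self._optimize(T, z)
        else:
            self.hyper = self._spec

        K = self.hyper.amplitude * T + self.hyper.noise_variance * np.eye(len(z))
        self._L = self._chol_with_jitter(K)
        r = z - self.hyper.mean_constant
        self._alpha = solve_triangular(
            self._L, solve_triangular(self._L, r, lower=True), lower=True, trans="T"
        )
        self._fitted = True
        return self

    def _optimize(self, T: np.ndarray, z: np.ndarray) -> GPHyperparams:
        """Gradient ascent on the mean log marginal likelihood.

        With T = Q diag(lam) Q^T fixed, K = sf2*T + sn2*I shares eigenvectors,
        so the likelihood and its gradients reduce to elementwise operations
        on the eigenvalues. Amplitude and noise move in log space to stay
        positive; the noise is floored at the jitter level.
        """
        n = len(z)
        hp = GPHyperparams()
        iters, lr = hp.fit_iterations, hp.learning_rate
        lam, Q = np.linalg.eigh(T)
        lam = np.clip(lam, 0.0, None)
        w_full = Q.T @ z
        ones_q = Q.T @ np.ones(n)

        la = np.log(hp.amplitude)
        lb = np.log(hp.noise_variance)
        m = hp.mean_constant
        for _ in range(iters):
            sf2, sn2 = np.exp(la), max(np.exp(lb), JITTER_FLOOR)
            d = sf2 * lam + sn2
            w = w_full - m * ones_q
            wd = w / d
            if "mean" in self._optimize_params:
                m += lr * float(ones_q @ wd) / n
            if "amplitude" in self._optimize_params:
                grad_a = 0.5 * sf2 * float(np.sum(lam * wd**2) - np.sum(lam / d))
                la += lr * grad_a / n
            if "noise" in self._optimize_params:
                grad_b = 0.5 * sn2 * float(np.sum(wd**2) - np.sum(1.0 / d))
                lb += lr * grad_b / n
            la = float(np.clip(la, np.log(1e-4), np.log(1e4)))
            lb = float(np.clip(lb, np.log(JITTER_FLOOR), np.log(1e4)))
        return GPHyperparams(
            amplitude=float(np.exp(la)),
            noise_variance=float(max(np.exp(lb), JITTER_FLOOR)),
            mean_constant=float(m),
            fit_iterations=iters,
            learning_rate=lr,
        )

    @staticmethod
    def _chol_with_jitter(K: np.ndarray) -> np.ndarray:
        jitter = 0.0
        while True:
            try:
                return cholesky(K + jitter * np.eye(len(K)), lower=True)
            except np.linalg.LinAlgError:
                jitter = JITTER_FLOOR if jitter == 0.0 else jitter * 100
                if jitter > JITTER_CEIL:
                    raise np.linalg.LinAlgError(
                        "kernel matrix not positive definite after jitter escalation"
                    )

    # -- prediction --------------------------------------------------------

    def predict(self, fingerprints: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        if not self._fitted:
            raise RuntimeError("model is not fitted")
        Xq = np.asarray(fingerprints)
        if Xq.ndim != 2 or Xq.shape[1] != self._X.shape[1]:
            raise ValueError(
                f"fingerprint length mismatch: query {Xq.shape} vs "
                f"training {self._X.shape}"
            )
        hp = self.hyper
        Ks = hp.amplitude * tanimoto_matrix(Xq, self._X)  # (nq, n)
        mean_std = hp.mean_constant + Ks @ self._alpha
        V = solve_triangular(self._L, Ks.T, lower=True)
        var_std = np.clip(hp.amplitude - np.sum(V**2, axis=0), 0.0, None)
        mean = self._y_mean + self._y_sd * mean_std
        variance = self._y_sd**2 * var_std
        return mean, variance


def fit_gp(
    train_fp: np.ndarray,
    train_y: np.ndarray,
    hyper: Union[GPHyperparams, str] = "optimize",
) -> TanimotoGP:
    """Fit a Tanimoto-kernel GP; ``hyper`` is fixed values or ``"optimize"``."""
    return TanimotoGP(hyper=hyper).fit(train_fp, train_y)


def predict(model: TanimotoGP, query_fp: np.ndarray) -> SurrogatePosterior:
    mean, variance = model.predict(query_fp)
    return SurrogatePosterior(mean=mean, variance=variance)
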