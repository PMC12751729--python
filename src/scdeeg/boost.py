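"""Discrete AdaBoost over decision stumps, with exact Shapley attribution.

The classifier is the classic discrete (SAMME-equivalent, two-class)
AdaBoost over depth-1 threshold stumps: 50 rounds, learning rate 1.0, no
hyperparameter tuning.  Implemented directly on numpy arrays because

* the stump search is vectorized over features and split points, which is
  what makes wrapper-style sequential forward selection (hundreds of
  candidate evaluations per step, each a 10-fold CV) tractable; and
* the fitted ensemble is additive over single-feature functions, so
  Shapley attributions are exact and cheap (see :meth:`StumpBoost.shap_values`),
  with the additivity identity base + sum(phi) = margin holding to machine
  precision.

Predictions agree with scikit-learn's ``AdaBoostClassifier`` (SAMME
algorithm, depth-1 trees) on identical data; the test suite cross-checks
this.
"""

from __future__ import annotations

import numpy as np

__all__ = ["StumpBoost"]


class StumpBoost:
    """Boosted decision stumps for binary classification (positive class = 1).

    Parameters
    ----------
    n_rounds : boosting iterations (default 50).
    learning_rate : shrinkage on the stump weights (default 1.0).
    """

    def __init__(self, n_rounds: int = 50, learning_rate: float = 1.0) -> None:
        self.n_rounds = n_rounds
        self.learning_rate = learning_rate
        self.features_: np.ndarray | None = None
        self.thresholds_: np.ndarray | None = None
        self.polarities_: np.ndarray | None = None
        self.alphas_: np.ndarray | None = None

    # -- fitting -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "StumpBoost":
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y).astype(int)
        if set(np.unique(y01)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        ys = np.where(y01 == 1, 1.0, -1.0)
        n, k = X.shape

        order = np.argsort(X, axis=0, kind="stable")          # n x k
        Xs = np.take_along_axis(X, order, axis=0)
        valid = Xs[:-1] < Xs[1:]                              # (n-1) x k valid cuts
        ys_sorted = ys[order]                                 # n x k

        w = np.full(n, 1.0 / n)
        feats, thrs, pols, alphas = [], [], [], []
        for _ in range(self.n_rounds):
            wsorted = w[order]                                # n x k
            # cum_pos[i, j] = sum of weights of positive samples at sorted
            # positions <= i for feature j
            wy = wsorted * (ys_sorted > 0)
            cum_pos = np.cumsum(wy, axis=0)
            tot_pos = cum_pos[-1]
            cum_w = np.cumsum(wsorted, axis=0)
            # stump "predict +1 when x > threshold", cut after position i:
            # error = (positives on the left) + (negatives on the right)
            err_plus = cum_pos[:-1] + (1.0 - tot_pos) - (cum_w[:-1] - cum_pos[:-1])
            err_plus = np.where(valid, err_plus, np.inf)
            err_minus = np.where(valid, 1.0 - err_plus, np.inf)

            best_p = np.unravel_index(np.argmin(err_plus), err_plus.shape)
            best_m = np.unravel_index(np.argmin(err_minus), err_minus.shape)
            if err_plus[best_p] <= err_minus[best_m]:
                cut, j, pol, err = best_p[0], best_p[1], 1.0, err_plus[best_p]
            else:
                cut, j, pol, err = best_m[0], best_m[1], -1.0, err_minus[best_m]
            if not np.isfinite(err):      # all features constant
                break
            err = float(min(max(err, 1e-10), 1 - 1e-10))
            if err >= 0.5:
                break
            theta = 0.5 * (Xs[cut, j] + Xs[cut + 1, j])
            alpha = self.learning_rate * np.log((1.0 - err) / err)
            h = np.where(X[:, j] > theta, pol, -pol)
            feats.append(int(j))
            thrs.append(float(theta))
            pols.append(pol)
            alphas.append(float(alpha))
            w = w * np.exp(alpha * (h != ys))
            w /= w.sum()
            if err <= 1e-9:               # perfect stump; ensemble is done
                break

        if not feats:                     # degenerate: constant majority vote
            feats, thrs = [0], [np.inf]
            pols = [1.0 if ys.mean() >= 0 else -1.0]
            # predict -pol everywhere (nothing exceeds +inf)
            pols = [-p for p in pols]
            alphas = [1.0]
        self.features_ = np.array(feats, dtype=int)
        self.thresholds_ = np.array(thrs, dtype=float)
        self.polarities_ = np.array(pols, dtype=float)
        self.alphas_ = np.array(alphas, dtype=float)
        self.n_features_in_ = k
        return self

    # -- prediction --------------------------------------------------------

    def _stump_outputs(self, X: np.ndarray) -> np.ndarray:
        """Per-stump votes in {-1, +1}: samples x stumps."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"model was fit with {self.n_features_in_} features, got {X.shape[1]}"
            )
        gt = X[:, self.features_] > self.thresholds_[None, :]
        return np.where(gt, self.polarities_, -self.polarities_)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Normalized margin sum(alpha_t h_t(x)) / sum(alpha); positive -> class 1."""
        H = self._stump_outputs(X)
        return H @ self.alphas_ / self.alphas_.sum()

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)

    # -- attribution -------------------------------------------------------

    def shap_values(
        self, X: np.ndarray, background: np.ndarray
    ) -> tuple[np.ndarray, float]:
        """Exact Shapley attributions of the margin w.r.t. a background set.

        Because every stump reads a single feature, the margin decomposes
        additively over features and the Shapley value of feature j at x is

            phi_j(x) = sum over stumps t on j of a_t (h_t(x) - mean_bg h_t)

        with a_t the normalized stump weight and base value
        mean_bg margin.  Returns ``(phi, base)`` with ``phi`` of shape
        samples x features; by construction base + phi.sum(1) equals the
        margin exactly.
        """
        a = self.alphas_ / self.alphas_.sum()
        H = self._stump_outputs(X)                       # n x T
        Hbg = self._stump_outputs(np.asarray(background, dtype=float))
        h_ref = Hbg.mean(axis=0)                         # T
        contrib = a[None, :] * (H - h_ref[None, :])      # n x T
        n, k = X.shape[0], self.n_features_in_
        phi = np.zeros((n, k))
        np.add.at(phi.T, self.features_, contrib.T)
        base = float((Hbg @ a).mean())
        return phi, base
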