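"""The misbinding-probability model.

A REM-generated sequence S with structural plausibility score P_S competes
against the gating integrity G of the REM physiology it occurs in. The
probability that the simulation is mis-encoded as veridical autobiographical
memory is

    P(M = veridical | S) = sigma(alpha * P_S - beta * G),

with sigma the logistic function. There is deliberately no intercept: at
the origin of the standardized predictor scale the model is maximally
uncertain (P = 0.5), and the decision boundary P = 0.5 is exactly the line
alpha * P_S = beta * G. Statistically this is a conventional no-intercept
two-predictor logistic regression; alpha and beta are identified only
relative to the scales of P_S and G (rescaling P_S by c and alpha by 1/c
leaves every probability unchanged).

``MobiusLogistic`` estimates (alpha, beta) by maximum likelihood via
iteratively reweighted least squares, with standard errors from the inverse
observed information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import ConvergenceError, InvalidConfigError

__all__ = [
    "sigmoid",
    "MobiusParams",
    "misbinding_probability",
    "PhaseSpaceGrid",
    "compute_phase_space",
    "simulate_outcomes",
    "plausibility_score",
    "MobiusLogistic",
    "fit_parameters",
]


def sigmoid(x):
    """Numerically stable logistic function 1 / (1 + exp(-x)).

    Exact at 0 (returns 0.5); no overflow anywhere in the double range.
    Accepts scalars or arrays.
    """
    x_arr = np.asarray(x, dtype=float)
    scalar = x_arr.ndim == 0
    x_arr = np.atleast_1d(x_arr)
    out = np.empty_like(x_arr)
    pos = x_arr >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x_arr[pos]))
    ex = np.exp(x_arr[~pos])
    out[~pos] = ex / (1.0 + ex)
    return float(out[0]) if scalar else out


@dataclass(frozen=True)
class MobiusParams:
    """Weights of the two competing terms.

    alpha scales structural plausibility (drives encoding), beta scales
    gating integrity (suppresses encoding). Negative values are allowed
    numerically but break the intended interpretation, hence the warning.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise InvalidConfigError("alpha and beta must be finite")
        if self.alpha < 0 or self.beta < 0:
            warnings.warn(
                "negative alpha/beta invert the intended monotonicity", stacklevel=2
            )


def misbinding_probability(p_s, g, params: MobiusParams):
    """P(M = veridical | S) = sigma(alpha * P_S - beta * G).

    Strictly increasing in P_S and strictly decreasing in G when
    alpha, beta > 0; vectorized over array inputs.
    """
    p_s = np.asarray(p_s, dtype=float)
    g = np.asarray(g, dtype=float)
    return sigmoid(params.alpha * p_s - params.beta * g)


@dataclass
class PhaseSpaceGrid:
    """Misbinding probability over the (P_S, G) plane.

    ``prob[i, j]`` is the probability at G = g_axis[i], P_S = p_axis[j].
    The P = 0.5 level set is the line G = (alpha / beta) * P_S, available
    through :meth:`boundary_g` when beta != 0.
    """

    p_axis: np.ndarray
    g_axis: np.ndarray
    prob: np.ndarray
    params: MobiusParams

    @property
    def has_boundary(self) -> bool:
        return self.params.beta != 0

    def boundary_g(self, p_s) -> np.ndarray:
        """G on the P = 0.5 contour for given P_S values."""
        if not self.has_boundary:
            raise InvalidConfigError("beta = 0: the P = 0.5 boundary is not a finite line in G")
        return (self.params.alpha / self.params.beta) * np.asarray(p_s, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns P_S, G, prob."""
        pp, gg = np.meshgrid(self.p_axis, self.g_axis)
        return pd.DataFrame(
            {"P_S": pp.ravel(), "G": gg.ravel(), "prob": self.prob.ravel()}
        )


def compute_phase_space(
    p_range: tuple[float, float] = (-3.0, 3.0),
    g_range: tuple[float, float] = (-3.0, 3.0),
    n_grid: int = 201,
    params: MobiusParams = MobiusParams(1.0, 1.0),
) -> PhaseSpaceGrid:
    """Evaluate the model on a regular (P_S, G) grid.

    The high-P_S / low-G corner carries the maximal misbinding
    probability (maximal vulnerability); with beta = 0 the grid is still
    produced but carries no finite P = 0.5 boundary line (flagged on the
    result).
    """
    if n_grid < 2:
        raise InvalidConfigError("n_grid must be >= 2")
    p_axis = np.linspace(*p_range, n_grid)
    g_axis = np.linspace(*g_range, n_grid)
    pp, gg = np.meshgrid(p_axis, g_axis)
    prob = misbinding_probability(pp, gg, params)
    if params.beta == 0:
        warnings.warn("beta = 0: no finite P = 0.5 boundary", stacklevel=2)
    return PhaseSpaceGrid(p_axis=p_axis, g_axis=g_axis, prob=prob, params=params)


def simulate_outcomes(
    p_s,
    g,
    params: MobiusParams,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Independent Bernoulli draws with the model probabilities (1 = the
    simulated sequence is mis-encoded as memory)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    prob = np.atleast_1d(misbinding_probability(p_s, g, params))
    return (rng.random(prob.shape) < prob).astype(int)


def plausibility_score(sub_scores, standardize: bool = True) -> np.ndarray:
    """Placeholder scorer mapping bounded structural sub-scores (e.g.
    narrative coherence, goal-directedness, temporal continuity; rows =
    sequences) to a scalar P_S per sequence: the row mean, optionally
    z-standardized across sequences.

    The structural term has no agreed operationalization; treat this as a
    convenience for simulations, not a validated instrument.
    """
    arr = np.atleast_2d(np.asarray(sub_scores, dtype=float))
    score = arr.mean(axis=1)
    if standardize:
        sd = score.std(ddof=1) if score.size > 1 else 0.0
        if sd == 0:
            raise InvalidConfigError("cannot standardize constant sub-scores")
        score = (score - score.mean()) / sd
    return score


class MobiusLogistic(ClassifierMixin, BaseEstimator):
    """No-intercept two-predictor logistic regression (sklearn API).

    ``X`` has columns (P_S, G); the design matrix is (P_S, -G) so both
    fitted coefficients (``alpha_``, ``beta_``) are positive when the data
    follow the intended monotonicity. Fitting is IRLS on the exact
    log-likelihood; convergence when the log-likelihood changes by less
    than ``tol`` (default 1e-10) or after ``max_iter`` iterations.

    Attributes
    ----------
    alpha_, beta_ : float
        Maximum-likelihood weights.
    se_alpha_, se_beta_ : float
        Standard errors from the inverse observed information.
    loglik_ : float
        Log-likelihood at the optimum.
    n_iter_ : int
        IRLS iterations used.
    """

    def __init__(self, max_iter: int = 100, tol: float = 1e-10):
        self.max_iter = max_iter
        self.tol = tol

    def _validate(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise InvalidConfigError("X must be (n, 2) with columns (P_S, G)")
        if X.shape[0] != y.shape[0]:
            raise InvalidConfigError("X and y length mismatch")
        if X.shape[0] < 10:
            raise InvalidConfigError("need >= 10 observations")
        classes = np.unique(y)
        if not np.all(np.isin(classes, [0, 1])):
            raise InvalidConfigError("y must be binary 0/1")
        if classes.size < 2:
            raise InvalidConfigError("both outcome classes must be present")
        if np.linalg.matrix_rank(X) < 2:
            raise InvalidConfigError("P_S and G are collinear; model not identified")
        return X, y.astype(float)

    def fit(self, X, y) -> "MobiusLogistic":
        X, y = self._validate(X, y)
        Z = np.column_stack([X[:, 0], -X[:, 1]])
        theta = np.zeros(2)
        ll_old = -np.inf
        converged = False
        for it in range(1, self.max_iter + 1):
            eta = Z @ theta
            mu = sigmoid(eta)
            # stable log-likelihood: y*eta - log(1 + e^eta)
            ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
            w = mu * (1.0 - mu)
            hess = Z.T @ (Z * w[:, None])
            grad = Z.T @ (y - mu)
            try:
                step = np.linalg.solve(hess, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(
                    "information matrix singular — perfect separation or "
                    "collinear predictors"
                ) from exc
            theta = theta + step
            if abs(ll - ll_old) < self.tol:
                converged = True
                break
            ll_old = ll
        eta = Z @ theta
        ll_final = float(y @ eta - np.logaddexp(0.0, eta).sum())
        if ll_final > -1e-8:
            # zero residual deviance: the MLE does not exist at finite theta
            raise ConvergenceError(
                "perfect separation: a linear combination of P_S and G "
                "splits the outcomes, so alpha/beta diverge"
            )
        if not converged or np.abs(theta).max() > 1e6:
            raise ConvergenceError(
                "IRLS did not converge: quasi-separation or ill-conditioned data"
            )
        mu = sigmoid(eta)
        hess = Z.T @ (Z * (mu * (1 - mu))[:, None])
        cov = np.linalg.inv(hess)
        self.alpha_, self.beta_ = (float(t) for t in theta)
        self.se_alpha_, self.se_beta_ = (float(s) for s in np.sqrt(np.diag(cov)))
        self.loglik_ = ll_final
        self.n_iter_ = it
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = 2
        return self

    @property
    def params_(self) -> MobiusParams:
        check_is_fitted(self, "alpha_")
        return MobiusParams(self.alpha_, self.beta_)

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "alpha_")
        X = np.asarray(X, dtype=float)
        return self.alpha_ * X[:, 0] - self.beta_ * X[:, 1]

    def predict_proba(self, X) -> np.ndarray:
        p = sigmoid(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0).astype(int)


def fit_parameters(p_s, g, outcomes, max_iter: int = 100, tol: float = 1e-10):
    """Functional wrapper over :class:`MobiusLogistic`.

    Returns ``(MobiusParams, info)`` where ``info`` holds standard errors,
    the log-likelihood and n.
    """
    X = np.column_stack([np.asarray(p_s, float), np.asarray(g, float)])
    est = MobiusLogistic(max_iter=max_iter, tol=tol).fit(X, np.asarray(outcomes))
    info = {
        "se_alpha": est.se_alpha_,
        "se_beta": est.se_beta_,
        "loglik": est.loglik_,
        "n": int(X.shape[0]),
        "n_iter": est.n_iter_,
    }
    return est.params_, info
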