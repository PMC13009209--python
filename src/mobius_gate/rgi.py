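"""REM Gating Integrity (RGI) composites.

Given the three oriented gating features, this module builds the two
per-subject composites used for group comparison:

* ``rgi_min`` — the minimum of the three control-z-scored features, a
  weakest-link summary (gating is only as tight as its loosest component);
* ``signed_distance`` — a shrinkage-covariance Mahalanobis distance from
  the control centroid, signed by the mean z so that negative values mean
  net looser gating than controls.

Coupling vector length is logit-transformed before z-scoring (variance
stabilization on [0, 1]); z-scores use control mean/SD only — epic rows
never leak into the reference. The control covariance is computed on the
z scale and shrunk as ``Sigma_lam = (1 - lam) * Sigma + lam * I`` with
``lam = 0.20`` by default, which bounds its smallest eigenvalue below by
``lam`` and so guarantees invertibility at n = 4.

The weakest-link definition of ``rgi_min`` and the mean-z sign rule for
the distance are this package's design decisions (documented in
docs/methods.md), not field-standard conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .exceptions import (
    DegenerateReferenceError,
    InsufficientDataError,
    InvalidConfigError,
    NumericalSingularityError,
)
from .synthetic import FEATURE_NAMES

__all__ = [
    "logit",
    "ControlReference",
    "fit_control_reference",
    "control_zscore",
    "rgi_min",
    "signed_distance_to_control",
    "RGIComposite",
    "compute_rgi_table",
    "RGI_CSV_COLUMNS",
]

RGI_CSV_COLUMNS = [
    "subject_id",
    "group",
    "channel",
    "z_coupling",
    "z_bout",
    "z_steepness",
    "rgi_min",
    "signed_distance",
]


def logit(p, eps: float = 1e-6):
    """log(p / (1 - p)) with clipping of p into [eps, 1 - eps].

    Accepts scalars or arrays; values outside [0, 1] raise, values at the
    boundary are clipped so the transform stays finite.
    """
    if not 0 < eps <= 0.01:
        raise InvalidConfigError("eps must lie in (0, 0.01]")
    p_arr = np.asarray(p, dtype=float)
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise InvalidConfigError("logit input must lie in [0, 1]")
    clipped = np.clip(p_arr, eps, 1 - eps)
    out = np.log(clipped) - np.log1p(-clipped)
    return float(out) if np.isscalar(p) or p_arr.ndim == 0 else out


@dataclass
class ControlReference:
    """Control-group moments defining the z scale and the shrunk covariance.

    ``mu``/``sigma`` are means/SDs of (logit coupling, REM mean bout [min],
    1/f steepness) over controls; ``Sigma`` is the covariance of the control
    z-vectors (n-1 denominator throughout).
    """

    mu: np.ndarray
    sigma: np.ndarray
    Sigma: np.ndarray
    lam: float = 0.20
    eps: float = 1e-6

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        if self.mu.shape != (3,) or self.sigma.shape != (3,) or self.Sigma.shape != (3, 3):
            raise InvalidConfigError("reference needs mu/sigma of shape (3,) and Sigma (3, 3)")
        if not np.all(self.sigma > 0):
            raise DegenerateReferenceError("all control SDs must be strictly positive")
        if not np.allclose(self.Sigma, self.Sigma.T, atol=1e-8):
            raise InvalidConfigError("Sigma must be symmetric")
        if not 0 <= self.lam <= 1:
            raise InvalidConfigError("shrinkage lam must lie in [0, 1]")

    @property
    def shrunk_covariance(self) -> np.ndarray:
        """(1 - lam) * Sigma + lam * I."""
        return (1 - self.lam) * self.Sigma + self.lam * np.eye(3)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "mu": self.mu.tolist(),
                    "sigma": self.sigma.tolist(),
                    "Sigma": self.Sigma.tolist(),
                    "lambda": self.lam,
                    "eps": self.eps,
                },
                indent=2,
                sort_keys=True,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ControlReference":
        d = json.loads(Path(path).read_text())
        return cls(
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            Sigma=np.array(d["Sigma"]),
            lam=float(d["lambda"]),
            eps=float(d.get("eps", 1e-6)),
        )


def _feature_matrix(X) -> np.ndarray:
    """Coerce a DataFrame with the canonical feature columns, or an (n, 3)
    array in canonical order, to a float matrix."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise InvalidConfigError(f"feature table missing columns {missing}")
        X = X.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != 3:
        raise InvalidConfigError("expected 3 feature columns (coupling, bout, steepness)")
    return X


def _transform_raw(X: np.ndarray, eps: float) -> np.ndarray:
    out = X.copy()
    out[:, 0] = logit(out[:, 0], eps=eps)
    return out


def fit_control_reference(X, lam: float = 0.20, eps: float = 1e-6) -> ControlReference:
    """Fit mu/sigma/Sigma from control rows (coupling logit-transformed first).

    ``X`` is a DataFrame with the canonical feature columns or an (n, 3)
    array (coupling on the raw [0, 1] scale). Requires n >= 2 complete rows
    and strictly positive SDs.
    """
    X = _feature_matrix(X)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < 2:
        raise InsufficientDataError("need >= 2 complete control rows")
    t = _transform_raw(X, eps)
    mu = t.mean(axis=0)
    sigma = t.std(axis=0, ddof=1)
    if np.any(sigma <= 0):
        raise DegenerateReferenceError("zero control variance on at least one feature")
    z = (t - mu) / sigma
    Sigma = np.cov(z, rowvar=False, ddof=1)
    return ControlReference(mu=mu, sigma=sigma, Sigma=Sigma, lam=lam, eps=eps)


def control_zscore(row, ref: ControlReference) -> np.ndarray:
    """Control z-vector(s): (logit coupling, bout, steepness) minus mu over sigma.

    Missing features propagate as NaN with a warning, never as zeros.
    """
    X = _feature_matrix(row)
    nan_rows = np.isnan(X).any(axis=1)
    if nan_rows.any():
        warnings.warn(f"{int(nan_rows.sum())} row(s) with missing features -> NaN z", stacklevel=2)
    with np.errstate(invalid="ignore"):
        t = X.copy()
        ok = ~np.isnan(t[:, 0])
        t[ok, 0] = logit(t[ok, 0], eps=ref.eps)
        z = (t - ref.mu) / ref.sigma
    return z[0] if z.shape[0] == 1 and np.asarray(row).ndim == 1 else z


def rgi_min(z) -> float:
    """Weakest-link gating summary: the minimum of the three oriented z's."""
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        return float("nan")
    return float(z.min())


def signed_distance_to_control(z, ref: ControlReference) -> float:
    """Shrinkage Mahalanobis distance from the control centroid, signed.

    Magnitude sqrt(z' Sigma_lam^{-1} z); sign of mean(z) (negative = net
    looser gating than controls; mean(z) = 0 counts as positive).
    """
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        return float("nan")
    S = ref.shrunk_covariance
    try:
        sol = np.linalg.solve(S, z)
    except np.linalg.LinAlgError as exc:  # only reachable at lam = 0
        raise NumericalSingularityError("shrunk covariance is singular (lam = 0?)") from exc
    if np.linalg.cond(S) > 1e12:
        raise NumericalSingularityError("shrunk covariance is numerically singular")
    magnitude = float(np.sqrt(max(z @ sol, 0.0)))
    return magnitude if z.mean() >= 0 else -magnitude


class RGIComposite(TransformerMixin, BaseEstimator):
    """Control-referenced RGI transformer (sklearn API).

    ``fit`` consumes *control* rows only — an (n, 3) array of
    (coupling_vl, rem_mean_bout_min, one_over_f_steepness) or a DataFrame
    with those columns — and stores the control reference. ``transform``
    maps any rows to the 5 composite columns
    (z_coupling, z_bout, z_steepness, rgi_min, signed_distance).

    Parameters
    ----------
    lam : float, default 0.20
        Fixed shrinkage weight of the identity in the control covariance.
    eps : float, default 1e-6
        Clip bound for the coupling logit transform.
    """

    def __init__(self, lam: float = 0.20, eps: float = 1e-6):
        self.lam = lam
        self.eps = eps

    def fit(self, X, y=None) -> "RGIComposite":
        self.reference_ = fit_control_reference(X, lam=self.lam, eps=self.eps)
        self.n_features_in_ = 3
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        Z = control_zscore(_feature_matrix(X), self.reference_)
        Z = np.atleast_2d(Z)
        out = np.empty((Z.shape[0], 5))
        out[:, :3] = Z
        for i, z in enumerate(Z):
            out[i, 3] = rgi_min(z)
            out[i, 4] = signed_distance_to_control(z, self.reference_)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.array(["z_coupling", "z_bout", "z_steepness", "rgi_min", "signed_distance"])


def compute_rgi_table(
    features: pd.DataFrame,
    lam: float = 0.20,
    eps: float = 1e-6,
    control_label: str = "control",
) -> tuple[pd.DataFrame, ControlReference]:
    """Fit the reference on control rows of a feature table, score all rows.

    Returns the RGI table (``RGI_CSV_COLUMNS``) and the fitted reference.
    """
    if "group" not in features.columns:
        raise InvalidConfigError("feature table must have a 'group' column")
    controls = features[features["group"] == control_label]
    if controls.empty:
        raise InsufficientDataError(f"no rows with group == {control_label!r}")
    est = RGIComposite(lam=lam, eps=eps).fit(controls)
    comp = est.transform(features)
    out = pd.DataFrame(comp, columns=est.get_feature_names_out(), index=features.index)
    meta_cols = [c for c in ("subject_id", "group", "channel") if c in features.columns]
    out = pd.concat([features[meta_cols], out], axis=1)
    return out, est.reference_
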