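"""Suitability models: presence-background Maxent, binomial GLM, random forest.

All three estimators follow the scikit-learn contract: hyperparameters in
``__init__``, data in ``fit(X, y)`` (``y`` = 1 for presences, 0 for
background/pseudo-absence points), fitted state in trailing-underscore
attributes, ``get_params``/``set_params`` inherited from ``BaseEstimator``.
``predict_suitability`` returns values in [0, 1] for any environment
vector, including extrapolated ones; by default projection-time values are
clamped to the training range of each variable before prediction
(toggleable per call).

The Maxent model is authored here: a Gibbs (maximum-entropy) density over
the background sample with linear and quadratic features of each
standardized variable, an L1 penalty scaled by a regularization multiplier,
and the classical logistic output transform so that suitability is a
surrogate for probability of occurrence. Restricting the feature set to
linear + quadratic keeps the three algorithms comparable and the
optimization convex; the exponent of the fitted Gibbs density is then a
quadratic form, matching a Gaussian response per variable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier

from .grids import ClimateGrid, SuitabilityMap

__all__ = [
    "MaxentSDM",
    "LogisticSDM",
    "RandomForestSDM",
    "fit_maxent",
    "fit_glm",
    "fit_rf",
    "predict_map",
    "model_to_json",
    "model_from_json",
    "ALGORITHMS",
]


def _as_array(X, variable_names=None):
    """Coerce an env table to a float array, reordering DataFrame columns."""
    if isinstance(X, pd.DataFrame):
        if variable_names is not None:
            missing = [v for v in variable_names if v not in X.columns]
            if missing:
                raise KeyError(f"environment table lacks variables: {missing}")
            X = X[list(variable_names)]
        return X.to_numpy(dtype=float), list(X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a 2-D environment table")
    return arr, None


class _SDMBase(BaseEstimator):
    """Shared fit bookkeeping and the clamped prediction path."""

    algorithm: str = ""

    def _register_training(self, X, y):
        X, names = _as_array(X)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("y must be binary (1 = presence, 0 = contrast)")
        self.variable_names_ = names
        self.n_features_in_ = X.shape[1]
        # Training range of presences + contrast points: the reference set
        # for clamping and extrapolation diagnostics.
        self.reference_min_ = X.min(axis=0)
        self.reference_max_ = X.max(axis=0)
        self.n_presence_ = int((y == 1).sum())
        self.n_contrast_ = int((y == 0).sum())
        # Presences + contrast points double as the reference sample for
        # extrapolation diagnostics (MESS) at projection time.
        self.training_env_ = X.copy()
        return X, y.astype(int)

    def _prediction_input(self, X, clamp):
        X, _ = _as_array(X, self.variable_names_)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} variables, got {X.shape[1]}"
            )
        if clamp:
            X = np.clip(X, self.reference_min_, self.reference_max_)
        return X

    # -- sklearn-compatible surface -------------------------------------
    @property
    def classes_(self):
        return np.array([0, 1])

    def predict_proba(self, X):
        p = self.predict_suitability(X)
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.predict_suitability(X) >= 0.5).astype(int)


def _quadratic_features(Z: np.ndarray) -> np.ndarray:
    return np.hstack([Z, Z**2])


class MaxentSDM(_SDMBase):
    """Presence-background maximum-entropy suitability model.

    Parameters
    ----------
    max_iterations : int
        Optimizer iteration cap (default 1000).
    regularization_multiplier : float
        Scales the per-feature L1 penalty (default 1.0).
    convergence_tol : float
        Optimizer convergence tolerance (default 1e-5).
    output : {"logistic", "cloglog"}
        Transform from the raw Gibbs density to [0, 1] suitability.
    clamp : bool
        Default for clamping prediction-time values to the training range.

    Fitted attributes include ``weights_`` (L1-penalized feature
    coefficients), ``mean_``/``scale_`` (the z-scoring against the
    background sample, replayed at prediction), ``entropy_`` (entropy of
    the fitted density over the background, used by the logistic
    transform) and ``converged_``.
    """

    algorithm = "maxent"

    def __init__(self, max_iterations: int = 1000,
                 regularization_multiplier: float = 1.0,
                 convergence_tol: float = 1e-5,
                 output: str = "logistic",
                 clamp: bool = True):
        self.max_iterations = max_iterations
        self.regularization_multiplier = regularization_multiplier
        self.convergence_tol = convergence_tol
        self.output = output
        self.clamp = clamp

    def fit(self, X, y):
        if self.output not in ("logistic", "cloglog"):
            raise ValueError(f"unknown output transform {self.output!r}")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        X, y = self._register_training(X, y)
        P, B = X[y == 1], X[y == 0]
        if len(P) < 5:
            raise ValueError(f"need at least 5 presences, got {len(P)}")
        if len(B) == 0:
            raise ValueError("background sample is empty")

        # Standardize against the background so the per-feature penalty is
        # comparable across variables of different units.
        self.mean_ = B.mean(axis=0)
        self.scale_ = B.std(axis=0)
        self.scale_[self.scale_ == 0] = 1.0

        FP = _quadratic_features((P - self.mean_) / self.scale_)
        FB = _quadratic_features((B - self.mean_) / self.scale_)
        n_feat = FP.shape[1]

        # Maxent-style penalty scaled by the feature spread over the
        # presences, at the lasso universal rate sqrt(2 ln p / n): strong
        # enough to zero noise features when presences mirror the
        # background, weak enough to leave genuine niche signal intact.
        s = FP.std(axis=0)
        rate = np.sqrt(2.0 * np.log(n_feat) / len(P))
        lam = self.regularization_multiplier * np.maximum(s, 1e-3) * rate

        fbar = FP.mean(axis=0)

        def objective(uv):
            w = uv[:n_feat] - uv[n_feat:]
            eta = FB @ w
            lse = logsumexp(eta)
            nll = -fbar @ w + lse - np.log(len(B))
            q = np.exp(eta - lse)
            g = -fbar + q @ FB
            grad = np.concatenate([g + lam, -g + lam])
            return nll + lam @ uv[:n_feat] + lam @ uv[n_feat:], grad

        x0 = np.zeros(2 * n_feat)
        res = minimize(objective, x0, jac=True, method="L-BFGS-B",
                       bounds=[(0, None)] * (2 * n_feat),
                       options={"maxiter": self.max_iterations,
                                "ftol": self.convergence_tol * 1e-4,
                                "gtol": self.convergence_tol})
        self.converged_ = bool(res.success)
        if not self.converged_:
            warnings.warn(
                f"maxent did not converge within {self.max_iterations} "
                f"iterations: {res.message}", stacklevel=2)
        self.weights_ = res.x[:n_feat] - res.x[n_feat:]

        eta_b = FB @ self.weights_
        self.log_partition_ = float(logsumexp(eta_b))
        q = np.exp(eta_b - self.log_partition_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-np.sum(np.where(q > 0, q * np.log(q), 0.0)))
        self.training_summary_ = {
            "n_presence": self.n_presence_, "n_contrast": self.n_contrast_,
            "settings": {"max_iterations": self.max_iterations,
                         "regularization_multiplier": self.regularization_multiplier,
                         "convergence_tol": self.convergence_tol,
                         "output": self.output},
            "converged": self.converged_,
        }
        return self

    def _raw_log_density(self, X):
        Z = (X - self.mean_) / self.scale_
        return _quadratic_features(Z) @ self.weights_ - self.log_partition_

    def predict_suitability(self, X, clamp: bool | None = None):
        clamp = self.clamp if clamp is None else clamp
        X = self._prediction_input(X, clamp)
        log_q = self._raw_log_density(X)
        # Logistic transform: suitability 0.5 where the density equals the
        # background average (eta = entropy in log space).
        t = self.entropy_ + log_q
        if self.output == "logistic":
            return expit(t)
        return 1.0 - np.exp(-np.exp(t))


class LogisticSDM(_SDMBase):
    """Binomial GLM with logistic link, linear + quadratic features.

    Fitted by maximum likelihood (statsmodels GLM) on the raw variable
    scale so coefficients are directly interpretable; on complete
    separation the fit falls back to a small ridge penalty
    (``ridge_alpha``, default 1e-6) with a warning instead of failing.
    """

    algorithm = "glm"

    def __init__(self, ridge_alpha: float = 1e-6):
        self.ridge_alpha = ridge_alpha

    @staticmethod
    def _design(X):
        return np.hstack([np.ones((X.shape[0], 1)), X, X**2])

    def fit(self, X, y):
        X, y = self._register_training(X, y)
        if self.n_presence_ == 0 or self.n_contrast_ == 0:
            raise ValueError("both presence and pseudo-absence classes required")
        D = self._design(X)
        self.separation_fallback_ = False
        try:
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                fit = sm.GLM(y, D, family=sm.families.Binomial()).fit(maxiter=200)
            separated = any(issubclass(w.category, PerfectSeparationWarning)
                            for w in caught)
            coef = np.asarray(fit.params)
            ok = (not separated and np.isfinite(coef).all()
                  and np.abs(coef).max() < 1e4
                  and getattr(fit, "converged", True))
        except Exception:
            ok = False
        if not ok:
            warnings.warn(
                "GLM detected (near-)complete separation; refitting with a "
                f"small ridge penalty (alpha={self.ridge_alpha})", stacklevel=2)
            self.separation_fallback_ = True
            fit = sm.GLM(y, D, family=sm.families.Binomial()).fit_regularized(
                alpha=self.ridge_alpha, L1_wt=0.0)
            coef = np.asarray(fit.params)
        self.coef_ = coef
        names = self.variable_names_ or [f"x{j}" for j in range(self.n_features_in_)]
        self.param_names_ = (["const"] + list(names)
                             + [f"{n}^2" for n in names])
        self.training_summary_ = {
            "n_presence": self.n_presence_, "n_contrast": self.n_contrast_,
            "settings": {"ridge_alpha": self.ridge_alpha},
            "separation_fallback": self.separation_fallback_,
        }
        return self

    def params(self) -> pd.Series:
        """Fitted coefficients labelled const, x_j, x_j^2."""
        return pd.Series(self.coef_, index=self.param_names_)

    def predict_suitability(self, X, clamp: bool | None = None):
        clamp = True if clamp is None else clamp
        X = self._prediction_input(X, clamp)
        return expit(self._design(X) @ self.coef_)


class RandomForestSDM(_SDMBase):
    """Bagged classification-tree ensemble for presence/pseudo-absence data.

    Suitability is the mean per-tree presence probability (scikit-learn's
    ``predict_proba``). 500 trees is the conventional stabilization point;
    ``min_samples_leaf`` defaults to 5 so leaves carry genuine probability
    estimates rather than pure 0/1 votes — the usual setting when a forest
    is read as a continuous suitability surface (it matches the R
    randomForest regression nodesize default widely used in SDM work).
    """

    algorithm = "rf"

    def __init__(self, n_trees: int = 500, min_samples_leaf: int = 5,
                 seed: int = 0):
        self.n_trees = n_trees
        self.min_samples_leaf = min_samples_leaf
        self.seed = seed

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        X, y = self._register_training(X, y)
        if self.n_presence_ == 0 or self.n_contrast_ == 0:
            raise ValueError("both presence and pseudo-absence classes required")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed)
        self.forest_.fit(X, y)
        self._train_X, self._train_y = X.copy(), y.copy()
        self.training_summary_ = {
            "n_presence": self.n_presence_, "n_contrast": self.n_contrast_,
            "settings": {"n_trees": self.n_trees, "seed": self.seed},
        }
        return self

    def predict_suitability(self, X, clamp: bool | None = None):
        clamp = True if clamp is None else clamp
        X = self._prediction_input(X, clamp)
        proba = self.forest_.predict_proba(X)
        col = list(self.forest_.classes_).index(1)
        return proba[:, col]


ALGORITHMS = {"maxent": MaxentSDM, "glm": LogisticSDM, "rf": RandomForestSDM}


# -- thin functional wrappers over the estimators ------------------------

def _stack(presence_env, contrast_env):
    if isinstance(presence_env, pd.DataFrame):
        X = pd.concat([presence_env, contrast_env[presence_env.columns]],
                      ignore_index=True)
    else:
        X = np.vstack([presence_env, contrast_env])
    y = np.concatenate([np.ones(len(presence_env), dtype=int),
                        np.zeros(len(contrast_env), dtype=int)])
    return X, y


def fit_maxent(presence_env, background_env, max_iterations: int = 1000,
               regularization_multiplier: float = 1.0,
               convergence_tol: float = 1e-5, **kwargs) -> MaxentSDM:
    """Fit a Maxent model from presence and background environment tables."""
    X, y = _stack(presence_env, background_env)
    return MaxentSDM(max_iterations=max_iterations,
                     regularization_multiplier=regularization_multiplier,
                     convergence_tol=convergence_tol, **kwargs).fit(X, y)


def fit_glm(presence_env, pseudoabsence_env, **kwargs) -> LogisticSDM:
    """Fit the binomial logistic GLM from presence/pseudo-absence tables."""
    X, y = _stack(presence_env, pseudoabsence_env)
    return LogisticSDM(**kwargs).fit(X, y)


def fit_rf(presence_env, pseudoabsence_env, n_trees: int = 500,
           seed: int = 0) -> RandomForestSDM:
    """Fit the random-forest model from presence/pseudo-absence tables."""
    X, y = _stack(presence_env, pseudoabsence_env)
    return RandomForestSDM(n_trees=n_trees, seed=seed).fit(X, y)


def predict_map(model, grid: ClimateGrid, species_id: str = "",
                clamp: bool | None = None) -> SuitabilityMap:
    """Predict a suitability surface over a climate grid.

    Nodata cells propagate as NaN. The model's variables must all be
    present on the grid; extra grid variables are ignored.
    """
    names = model.variable_names_
    if names is not None:
        missing = [v for v in names if v not in grid.variables]
        if missing:
            raise KeyError(f"grid lacks model variable(s): {missing}")
        order = names
    else:
        order = grid.var_names
        if len(order) != model.n_features_in_:
            raise ValueError("grid variable count differs from model's")
    rows, cols = np.nonzero(grid.valid_mask)
    env = pd.DataFrame({v: grid.variables[v][rows, cols] for v in order})
    values = np.full(grid.geometry.shape, np.nan)
    if len(rows):
        values[rows, cols] = model.predict_suitability(env, clamp=clamp)
    return SuitabilityMap(geometry=grid.geometry, values=values, age=grid.age,
                          species_id=species_id, algorithm=model.algorithm)


# -- JSON serialization ---------------------------------------------------

_FORMAT_VERSION = 1


def model_to_json(model) -> dict:
    """Serialize a fitted model to a portable JSON-able document.

    Maxent and GLM store their fitted weights; the random forest stores its
    (small) training table plus seed and is refitted identically on load.
    """
    doc = {
        "format_version": _FORMAT_VERSION,
        "algorithm": model.algorithm,
        "params": model.get_params(),
        "variable_names": model.variable_names_,
        "n_features_in": model.n_features_in_,
        "reference_min": model.reference_min_.tolist(),
        "reference_max": model.reference_max_.tolist(),
        "n_presence": model.n_presence_,
        "n_contrast": model.n_contrast_,
        "training_summary": model.training_summary_,
    }
    if isinstance(model, MaxentSDM):
        doc.update(weights=model.weights_.tolist(), mean=model.mean_.tolist(),
                   scale=model.scale_.tolist(),
                   log_partition=model.log_partition_,
                   entropy=model.entropy_, converged=model.converged_)
    elif isinstance(model, LogisticSDM):
        doc.update(coef=model.coef_.tolist(), param_names=model.param_names_,
                   separation_fallback=model.separation_fallback_)
    elif isinstance(model, RandomForestSDM):
        doc.update(train_X=model._train_X.tolist(),
                   train_y=model._train_y.tolist())
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return doc


def model_from_json(doc: dict):
    """Rebuild a fitted model from :func:`model_to_json` output."""
    if doc.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format {doc.get('format_version')}")
    cls = ALGORITHMS[doc["algorithm"]]
    model = cls(**doc["params"])
    if cls is RandomForestSDM:
        X = np.asarray(doc["train_X"], dtype=float)
        y = np.asarray(doc["train_y"], dtype=int)
        if doc["variable_names"] is not None:
            X = pd.DataFrame(X, columns=doc["variable_names"])
        model.fit(X, y)
        return model
    model.variable_names_ = doc["variable_names"]
    model.n_features_in_ = doc["n_features_in"]
    model.reference_min_ = np.asarray(doc["reference_min"], dtype=float)
    model.reference_max_ = np.asarray(doc["reference_max"], dtype=float)
    model.n_presence_ = doc["n_presence"]
    model.n_contrast_ = doc["n_contrast"]
    model.training_summary_ = doc["training_summary"]
    if cls is MaxentSDM:
        model.weights_ = np.asarray(doc["weights"], dtype=float)
        model.mean_ = np.asarray(doc["mean"], dtype=float)
        model.scale_ = np.asarray(doc["scale"], dtype=float)
        model.log_partition_ = doc["log_partition"]
        model.entropy_ = doc["entropy"]
        model.converged_ = doc["converged"]
    else:
        model.coef_ = np.asarray(doc["coef"], dtype=float)
        model.param_names_ = doc["param_names"]
        model.separation_fallback_ = doc["separation_fallback"]
    return model
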