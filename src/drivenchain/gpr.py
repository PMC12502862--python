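"""Gaussian-process regression from flattened scattering maps to scalar targets.

One independent regressor is trained per inversion target. The prior is a GP
with constant mean (fixed to the training-target mean) and covariance

    k(x, x') = exp(-d(x, x')² / (2 l²)) + σ² δ_{x x'} ,

a unit-amplitude RBF kernel plus white observational noise; ``d`` is the
Euclidean distance between flattened maps. The hyperparameters (l, σ) are
found by maximizing the log marginal likelihood

    log p(y | X, l, σ) = -½ (y-m)ᵀ K⁻¹ (y-m) - ½ log|K| - (n/2) log 2π

with L-BFGS-B in (log l, log σ) space using analytic gradients, from several
seeded random restarts. σ² sits inside the kernel matrix; the *reported*
number is σ itself. Inputs are raw intensities — no log transform or
standardization by default, so correlation lengths are comparable across
targets.

``DrivenChainGPR`` follows the scikit-learn estimator contract (get_params /
set_params, fitted attributes with trailing underscores) and composes with
sklearn pipelines and model selection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.metrics import r2_score as _sk_r2
from sklearn.utils.validation import check_is_fitted

from .dataset import TARGET_COLUMNS, ScatteringDataset

__all__ = [
    "KernelSpec",
    "kernel_matrix",
    "log_marginal_likelihood",
    "DrivenChainGPR",
    "InversionReport",
    "fit_inversion",
    "evaluate_inversion",
    "invert_map",
    "r2_score",
    "save_models",
    "load_models",
]

ENERGY_TARGETS = ("kappa", "f", "gammaL")
CONFORMATION_TARGETS = ("r2_over_L2", "rg2_norm", "rxz_norm")


@dataclass(frozen=True)
class KernelSpec:
    """RBF + white-noise kernel hyperparameters and the constant prior mean.

    ``noise_scale`` is σ: the kernel diagonal receives σ².
    """

    correlation_length: float
    noise_scale: float
    constant_mean: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.correlation_length) and self.correlation_length > 0):
            raise ValueError("correlation_length must be finite and > 0")
        if not (np.isfinite(self.noise_scale) and self.noise_scale >= 0):
            raise ValueError("noise_scale must be finite and >= 0")


def _check_dims(X: np.ndarray, Xp: np.ndarray) -> None:
    if X.ndim != 2 or Xp.ndim != 2:
        raise ValueError("inputs must be 2D (n_samples, n_features)")
    if X.shape[1] != Xp.shape[1]:
        raise ValueError(f"feature dimensions differ: {X.shape[1]} vs {Xp.shape[1]}")


def kernel_matrix(
    X: np.ndarray, Xp: np.ndarray | None, spec: KernelSpec
) -> np.ndarray:
    """Covariance matrix between row sets.

    With ``Xp=None`` the matrix is the training covariance K(X, X): the σ²
    diagonal applies (same-index pairs of the same set). Between distinct sets
    the white-noise term never contributes.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    same = Xp is None
    Xp_arr = X if same else np.atleast_2d(np.asarray(Xp, dtype=float))
    _check_dims(X, Xp_arr)
    d2 = cdist(X, Xp_arr, metric="sqeuclidean")
    K = np.exp(-d2 / (2.0 * spec.correlation_length**2))
    if same:
        K[np.diag_indices_from(K)] += spec.noise_scale**2
    return K


def log_marginal_likelihood(
    X: np.ndarray,
    y: np.ndarray,
    spec: KernelSpec,
    return_grad: bool = False,
    jitter: float = 0.0,
):
    """Log evidence of the GP prior, optionally with its gradient.

    The gradient is with respect to (log l, log σ), the coordinates the
    optimizer works in: ∂LML/∂θ_j = ½ tr[(ααᵀ - K⁻¹) ∂K/∂θ_j] with
    α = K⁻¹(y - m). ``jitter`` adds a fixed value to the diagonal for
    numerical stability near σ = 0 (default 0: a singular covariance raises
    rather than being silently regularized).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    yc = y - spec.constant_mean
    d2 = cdist(X, X, metric="sqeuclidean")
    K_rbf = np.exp(-d2 / (2.0 * spec.correlation_length**2))
    K = K_rbf.copy()
    K[np.diag_indices_from(K)] += spec.noise_scale**2 + jitter
    L, lower = cho_factor(K, lower=True)
    alpha = cho_solve((L, lower), yc)
    lml = (
        -0.5 * float(yc @ alpha)
        - float(np.sum(np.log(np.diag(L))))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    if not return_grad:
        return lml
    K_inv = cho_solve((L, lower), np.eye(n))
    tmp = np.outer(alpha, alpha) - K_inv
    dK_dlogl = K_rbf * (d2 / spec.correlation_length**2)
    dK_dlogs = np.zeros_like(K)
    dK_dlogs[np.diag_indices_from(K)] = 2.0 * spec.noise_scale**2
    grad = np.array(
        [0.5 * np.sum(tmp * dK_dlogl), 0.5 * np.sum(tmp * dK_dlogs)]
    )
    return lml, grad


class DrivenChainGPR(RegressorMixin, BaseEstimator):
    """Scalar-output GP regressor with an RBF + white-noise kernel.

    Parameters
    ----------
    length_scale : float
        Initial correlation length l.
    noise : float
        Initial noise scale σ (σ² enters the kernel diagonal).
    optimize : bool
        Maximize the log marginal likelihood over (l, σ) during fit; if False
        the initial values are used as-is.
    n_restarts : int
        Number of seeded log-uniform random restarts added to the initial
        point.
    length_scale_bounds, noise_bounds : tuple
        Box bounds of the search.
    normalize_y : bool
        Standardize the target to zero mean and unit variance before fitting
        (predictions are mapped back). The kernel has unit amplitude, so the
        target must be on an O(1) scale for the (l, σ) landscape to behave;
        this matches the normalize_y convention of sklearn's GP regressor.
        The constant prior mean is the training-target mean either way.
    random_state : int or None
        Seed for the restart draws.

    Fitted attributes end in an underscore: ``length_scale_``, ``noise_``,
    ``constant_mean_``, ``y_scale_``, ``lml_``, ``X_train_``, ``alpha_``.
    Hyperparameters (l, σ) and the log marginal likelihood refer to the
    standardized target when ``normalize_y`` is on.
    """

    def __init__(
        self,
        length_scale: float = 1.0,
        noise: float = 0.1,
        optimize: bool = True,
        n_restarts: int = 5,
        length_scale_bounds: tuple = (1e-2, 1e3),
        noise_bounds: tuple = (1e-8, 1.0),
        normalize_y: bool = True,
        random_state: int | None = None,
    ):
        self.length_scale = length_scale
        self.noise = noise
        self.optimize = optimize
        self.n_restarts = n_restarts
        self.length_scale_bounds = length_scale_bounds
        self.noise_bounds = noise_bounds
        self.normalize_y = normalize_y
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    #: diagonal stabilizer used during fitting, the sklearn GPR convention
    _jitter = 1e-10

    def _objective(self, theta, X, y, mean):
        spec = KernelSpec(np.exp(theta[0]), np.exp(theta[1]), mean)
        try:
            lml, grad = log_marginal_likelihood(
                X, y, spec, return_grad=True, jitter=self._jitter
            )
        except np.linalg.LinAlgError:
            return np.inf, np.zeros(2)
        return -lml, -grad

    def fit(self, X, y):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        y_raw = np.asarray(y, dtype=float).ravel()
        if X.shape[0] != y_raw.size:
            raise ValueError("X and y disagree on n_samples")
        if X.shape[0] < 1:
            raise ValueError("need at least one training row")
        mean = float(y_raw.mean())
        scale = float(y_raw.std()) if self.normalize_y else 1.0
        if scale == 0.0:
            scale = 1.0
        # standardized working target; the constant prior mean becomes 0 here
        y = (y_raw - mean) / scale
        mean_w = 0.0

        bounds = [
            tuple(np.log(self.length_scale_bounds)),
            tuple(np.log(np.maximum(self.noise_bounds, 1e-300))),
        ]
        starts = [np.array([np.log(self.length_scale), np.log(max(self.noise, 1e-8))])]
        if self.optimize:
            rng = np.random.default_rng(self.random_state)
            for _ in range(self.n_restarts):
                starts.append(
                    np.array([rng.uniform(*bounds[0]), rng.uniform(*bounds[1])])
                )
            best = None
            trace = []
            for x0 in starts:
                res = minimize(
                    self._objective,
                    x0,
                    args=(X, y, mean_w),
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                )
                trace.append(
                    {"x0": x0.tolist(), "theta": res.x.tolist(), "lml": -float(res.fun)}
                )
                if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                    best = res
            if best is None:
                raise RuntimeError(f"hyperparameter optimization failed: {trace}")
            self.optimization_trace_ = trace
            theta = best.x
        else:
            theta = starts[0]

        self.length_scale_ = float(np.exp(theta[0]))
        self.noise_ = float(np.exp(theta[1]))
        self.constant_mean_ = mean
        self.y_scale_ = scale
        spec = KernelSpec(self.length_scale_, self.noise_, mean_w)
        self.lml_ = float(log_marginal_likelihood(X, y, spec, jitter=self._jitter))
        K = kernel_matrix(X, None, spec)
        K[np.diag_indices_from(K)] += self._jitter
        L, lower = cho_factor(K, lower=True)
        self.X_train_ = X
        self.alpha_ = cho_solve((L, lower), y)
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def kernel_spec_(self) -> KernelSpec:
        check_is_fitted(self, "length_scale_")
        return KernelSpec(self.length_scale_, self.noise_, self.constant_mean_)

    # -- prediction ----------------------------------------------------------

    def predict(self, X):
        """Posterior mean m + K*ᵀ K⁻¹ (y - m) at new inputs."""
        check_is_fitted(self, "alpha_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        k_star = kernel_matrix(X, self.X_train_, self.kernel_spec_)
        return self.constant_mean_ + self.y_scale_ * (k_star @ self.alpha_)


def r2_score(reference, predicted) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Raises on mismatched lengths, fewer than two points, or zero reference
    variance (where r² is undefined).
    """
    reference = np.asarray(reference, dtype=float).ravel()
    predicted = np.asarray(predicted, dtype=float).ravel()
    if reference.size != predicted.size:
        raise ValueError("length mismatch")
    if reference.size < 2:
        raise ValueError("need at least two points")
    if np.var(reference) == 0:
        raise ValueError("zero reference variance: r² undefined")
    return float(_sk_r2(reference, predicted))


# ---------------------------------------------------------------------------
# dataset-level API
# ---------------------------------------------------------------------------


@dataclass
class InversionReport:
    """Per-target hyperparameters, log marginal likelihood and test r²."""

    table: pd.DataFrame  # columns target, l, sigma, lml, r2
    predictions: pd.DataFrame
    reference: pd.DataFrame

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.table.to_dict(orient="records"), fh, indent=2)


def _resolve_targets(targets) -> list[str]:
    if targets in (None, "all"):
        return list(TARGET_COLUMNS)
    if isinstance(targets, str):
        targets = [targets]
    unknown = set(targets) - set(TARGET_COLUMNS)
    if unknown:
        raise ValueError(f"unknown targets: {sorted(unknown)}")
    return list(targets)


def fit_inversion(
    train: ScatteringDataset,
    targets="all",
    n_restarts: int = 5,
    random_state: int = 0,
) -> dict[str, DrivenChainGPR]:
    """Train one GP regressor per requested target on a training dataset.

    Each model remembers the dataset's grid hash so prediction on maps from a
    different Q grid is refused.
    """
    models: dict[str, DrivenChainGPR] = {}
    for i, name in enumerate(_resolve_targets(targets)):
        model = DrivenChainGPR(
            n_restarts=n_restarts, random_state=random_state + i
        )
        model.fit(train.F, train.targets[name].to_numpy())
        model.grid_hash_ = train.grid.hash
        model.target_name_ = name
        models[name] = model
    return models


def evaluate_inversion(
    models: dict[str, DrivenChainGPR], test: ScatteringDataset
) -> InversionReport:
    """Predict every modelled target on the test rows and score against MC."""
    rows, preds = [], {}
    for name, model in models.items():
        grid_hash = getattr(model, "grid_hash_", None)
        if grid_hash is not None and grid_hash != test.grid.hash:
            raise ValueError(f"grid hash mismatch for target {name!r}")
        yhat = model.predict(test.F)
        preds[name] = yhat
        ref = test.targets[name].to_numpy()
        rows.append(
            {
                "target": name,
                "l": model.length_scale_,
                "sigma": model.noise_,
                "lml": model.lml_,
                "r2": r2_score(ref, yhat),
            }
        )
    return InversionReport(
        table=pd.DataFrame(rows),
        predictions=pd.DataFrame(preds),
        reference=test.targets[list(preds)].copy(),
    )


def invert_map(models: dict[str, DrivenChainGPR], smap) -> dict[str, float]:
    """Predict all modelled targets from one scattering map.

    ``smap`` is a :class:`~drivenchain.scattering.ScatteringMap`; its grid
    hash must match the one the models were trained on.
    """
    x = smap.flatten()[None, :]
    out = {}
    for name, model in models.items():
        grid_hash = getattr(model, "grid_hash_", None)
        if grid_hash is not None and grid_hash != smap.grid.hash:
            raise ValueError(
                f"scattering map grid differs from the training grid (target {name!r})"
            )
        out[name] = float(model.predict(x)[0])
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def save_models(models: dict[str, DrivenChainGPR], path) -> None:
    """Persist trained regressors (hyperparameters + training references)."""
    with h5py.File(path, "w") as h5:
        first = next(iter(models.values()))
        h5.create_dataset("X_train", data=first.X_train_)
        for name, model in models.items():
            g = h5.create_group(name)
            g.create_dataset("alpha", data=model.alpha_)
            g.attrs["meta"] = json.dumps(
                {
                    "length_scale": model.length_scale_,
                    "noise": model.noise_,
                    "constant_mean": model.constant_mean_,
                    "y_scale": model.y_scale_,
                    "lml": model.lml_,
                    "grid_hash": getattr(model, "grid_hash_", None),
                    "target": name,
                }
            )


def load_models(path) -> dict[str, DrivenChainGPR]:
    models: dict[str, DrivenChainGPR] = {}
    with h5py.File(path, "r") as h5:
        X = h5["X_train"][:]
        for name in h5:
            if name == "X_train":
                continue
            meta = json.loads(h5[name].attrs["meta"])
            model = DrivenChainGPR(optimize=False)
            model.length_scale_ = meta["length_scale"]
            model.noise_ = meta["noise"]
            model.constant_mean_ = meta["constant_mean"]
            model.y_scale_ = meta["y_scale"]
            model.lml_ = meta["lml"]
            model.X_train_ = X
            model.alpha_ = h5[name]["alpha"][:]
            model.n_features_in_ = X.shape[1]
            if meta["grid_hash"] is not None:
                model.grid_hash_ = meta["grid_hash"]
            model.target_name_ = meta["target"]
            models[name] = model
    return models
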