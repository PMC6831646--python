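"""Multivariate calibration of traits from mean spectra.

Five regression families are supported: partial least squares (PLSR),
principal component regression (PCR), ridge-penalized multiple linear
regression, epsilon support vector regression with a radial kernel, and
random forests.  Latent-variable and ridge models select their complexity
(component count, penalty) by cross-validated RMSEP; all linear models
collapse to a per-wavelength coefficient vector beta plus intercept, which
is what wavelength selection and pixel-level mapping consume.

Model quality is summarized by the chemometric triple (R^2, RMSE, RPD):

    RMSE = sqrt( mean( (yhat_i - y_i)^2 ) )
    RPD  = sd(y) / RMSE            (sd with n-1 denominator)

with R^2 the squared Pearson correlation between predictions and reference
values (the ratio form sum((yhat-ybar)^2)/sum((y-ybar)^2) is also reported,
but it can exceed 1 for biased predictors and is not the headline metric).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVR

from .chemometrics import Preprocessor
from .dataset import SpectralDataset
from .errors import InvalidSplitError, UnsupportedModelError

LINEAR_METHODS = ("plsr", "pcr", "mlr_ridge")
ML_METHODS = ("svr", "rf")


# --- containers ------------------------------------------------------------

@dataclass
class FitMetrics:
    """Goodness-of-fit triple for one partition."""

    r2: float
    rmse: float
    rpd: float
    partition: str = ""
    n: int = 0
    r2_ratio: float = float("nan")
    flags: tuple[str, ...] = ()


@dataclass
class RegressionModel:
    """A fitted trait model with enough state to score new spectra.

    ``grid`` lists the wavelengths of the columns the estimator actually
    sees (after any selection); ``training_grid`` is the full preprocessed
    grid and ``selection`` the indices into it, so pixel-level prediction can
    preprocess a full spectrum and then restrict it.  ``beta``/``intercept``
    exist only for the linear families.
    """

    method: str
    grid: np.ndarray
    beta: np.ndarray | None = None
    intercept: float = 0.0
    preprocess: Preprocessor | None = None
    training_grid: np.ndarray | None = None
    selection: np.ndarray | None = None
    hyperparams: dict = field(default_factory=dict)
    estimator: object = None
    rmsep_curve: np.ndarray | None = None

    @property
    def is_linear(self) -> bool:
        return self.beta is not None

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Score spectra given on ``self.grid`` (already preprocessed)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.grid.size:
            raise ValueError("input column count does not match model grid")
        if self.beta is not None:
            return X @ self.beta + self.intercept
        if self.estimator is None:
            raise UnsupportedModelError("model has neither beta nor estimator")
        return np.asarray(self.estimator.predict(X), dtype=float)


@dataclass
class WavelengthSelection:
    """Retained wavelength indices with provenance."""

    indices: np.ndarray
    wavelengths: np.ndarray
    method: str  # "coef_fraction" | "feature_windows"
    trait: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.indices.size != np.unique(self.indices).size:
            raise ValueError("selection indices must be unique")
        if np.any(np.diff(self.indices) < 0):
            raise ValueError("selection indices must be sorted")


@dataclass(frozen=True)
class FeatureWindow:
    """A known absorption feature and the wavelength window around it."""

    center: float
    lo: float
    hi: float
    assignation: str
    trait: str


#: Absorption features associated with foliar water content; windows are
#: 40 nm centered on the feature except the broad 1400-1450 nm O-H band.
WATER_FEATURE_WINDOWS = tuple(
    FeatureWindow(c, lo, hi, a, "water")
    for c, lo, hi, a in [
        (600, 580, 620, "O-H hydrogen bonding"),
        (680, 660, 700, "electron transition"),
        (810, 790, 830, "C-H"),
        (820, 800, 840, "C-H"),
        (860, 840, 880, "C-H"),
        (900, 880, 920, "C-H"),
        (970, 950, 990, "O-H bend"),
        (1240, 1220, 1260, "C-H"),
        (1530, 1510, 1550, "N-H secondary amines"),
        (1550, 1530, 1570, "N-H secondary amines"),
        (1720, 1700, 1740, "C-H"),
        (1750, 1730, 1770, "C-H secondary overtones"),
        (2080, 2060, 2100, "N-H and C-H, O-H stretch and deformation"),
        (2350, 2330, 2370, "C-H combinations"),
        (1425, 1400, 1450, "O-H bend and stretch"),
    ]
)

#: Absorption features associated with foliar nitrogen content.
NITROGEN_FEATURE_WINDOWS = tuple(
    FeatureWindow(c, lo, hi, a, "nitrogen")
    for c, lo, hi, a in [
        (460, 440, 480, "electron transition, chlorophyll a,b"),
        (530, 510, 550, "electron transition, carotenoids"),
        (670, 650, 690, "electron transition, chlorophyll a,b"),
        (1440, 1420, 1460, "O-H bend, first overtone, starch"),
        (1500, 1480, 1520, "N-H stretch"),
        (1680, 1660, 1700, "C-H stretch, aromatic"),
        (1712, 1692, 1732, "C-H stretch, CH3"),
        (1770, 1750, 1790, "C-H stretch, CH2"),
        (1900, 1880, 1920, "O-H stretch, C=O, starch, CO2H"),
        (1960, 1940, 1980, "N-H, CONH2"),
        (2080, 2060, 2100, "N-H stretch, proteins"),
        (2115, 2095, 2135, "N-H stretch, CONH2, CONHR"),
        (2140, 2120, 2160, "amide, proteins"),
        (2230, 2210, 2250, "N-H stretch, C=H stretch, amino acid"),
        (2300, 2280, 2320, "N-H stretch, C=O stretch, amino acid"),
        (2400, 2380, 2420, "CH2 bend, C-H deformation, cellulose"),
    ]
)


# --- splitting -------------------------------------------------------------

def split_by_replicate(
    dataset: SpectralDataset, validation_replicates
) -> tuple[SpectralDataset, SpectralDataset]:
    """Partition samples by experimental replicate membership.

    Samples whose replicate label is in ``validation_replicates`` form the
    validation set; the rest form the training set.  The split must be a
    proper, non-empty subset of the observed replicate labels.
    """
    val_set = set(validation_replicates)
    observed = set(np.unique(dataset.replicate).tolist())
    if not val_set:
        raise InvalidSplitError("validation replicate set is empty")
    if not val_set.issubset(observed):
        raise InvalidSplitError(f"unknown replicate labels: {sorted(val_set - observed)}")
    if val_set == observed:
        raise InvalidSplitError("validation set cannot contain every replicate")
    is_val = np.isin(dataset.replicate, list(val_set))
    train = dataset.take(np.flatnonzero(~is_val))
    val = dataset.take(np.flatnonzero(is_val))
    train.partition = np.full(train.n_samples, "train")
    val.partition = np.full(val.n_samples, "validation")
    return train, val


# --- metrics ---------------------------------------------------------------

def evaluate(model: RegressionModel, dataset: SpectralDataset, partition: str = "") -> FitMetrics:
    """Compute (R^2, RMSE, RPD) of a model on a dataset.

    The dataset spectra must already be on the model's (preprocessed) grid,
    or on its full training grid, in which case the stored wavelength
    selection is applied first.
    """
    X = dataset.X
    if X.shape[1] != model.grid.size:
        if (
            model.selection is not None
            and model.training_grid is not None
            and X.shape[1] == model.training_grid.size
        ):
            X = X[:, model.selection]
        else:
            raise ValueError("dataset grid matches neither model grid nor training grid")
    yhat = model.predict(X)
    return compute_metrics(dataset.y, yhat, partition=partition)


def compute_metrics(y: np.ndarray, yhat: np.ndarray, partition: str = "") -> FitMetrics:
    """(R^2, RMSE, RPD) for predictions against reference values."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    n = y.size
    if n < 2:
        raise ValueError("metrics need at least 2 samples")
    flags: list[str] = []
    resid = yhat - y
    rmse = float(np.sqrt(np.mean(resid**2)))
    sd = float(np.std(y, ddof=1))
    ss_y = float(np.sum((y - y.mean()) ** 2))
    ss_yhat = float(np.sum((yhat - yhat.mean()) ** 2))
    r2_ratio = ss_yhat / ss_y if ss_y > 0 else float("nan")
    if ss_yhat == 0 or ss_y == 0:
        r2 = 0.0
        flags.append("constant-prediction" if ss_yhat == 0 else "constant-reference")
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
        r2 = r * r
    if rmse == 0:
        rpd = float("inf")
        flags.append("zero-rmse")
    else:
        rpd = sd / rmse
    return FitMetrics(
        r2=r2, rmse=rmse, rpd=rpd, partition=partition, n=n,
        r2_ratio=r2_ratio, flags=tuple(flags),
    )


# --- model fitting ---------------------------------------------------------

def _collapse_pls(pls: PLSRegression, X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    # PLS predicts ybar + (X - xbar) @ beta; collapse to beta/intercept form
    beta = np.asarray(pls.coef_).reshape(-1)
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    return beta, intercept


def _fit_pcr(X: np.ndarray, y: np.ndarray, k: int):
    pca = PCA(n_components=k).fit(X)
    scores = pca.transform(X)
    lr = LinearRegression().fit(scores, y)
    beta = pca.components_.T @ lr.coef_
    intercept = float(lr.intercept_ - pca.mean_ @ beta)
    return beta, intercept


def _predict_latent(X, y, Xv, method: str, k: int) -> np.ndarray:
    if method == "plsr":
        pls = PLSRegression(n_components=k, scale=False).fit(X, y)
        return pls.predict(Xv).reshape(-1)
    beta, intercept = _fit_pcr(X, y, k)
    return Xv @ beta + intercept


def fit_latent(
    train: SpectralDataset,
    method: str = "plsr",
    max_components: int = 10,
    cv_folds: int = 10,
    seed: int = 0,
    preprocessor: Preprocessor | None = None,
    n_components: int | None = None,
) -> RegressionModel:
    """Fit PLSR or PCR, picking the component count by cross-validated RMSEP.

    The RMSEP curve over 1..max_components is computed with seeded k-fold
    cross-validation; the chosen count is the smallest one whose RMSEP lies
    within one standard error of the curve minimum (fewer components are
    preferred when the curve is flat).  ``n_components`` overrides the
    automatic choice.  The fitted model is collapsed to ``beta``/``intercept``
    so that prediction is a plain dot product.
    """
    if method not in ("plsr", "pcr"):
        raise ValueError("latent method must be 'plsr' or 'pcr'")
    X, y = train.X, train.y
    n = X.shape[0]
    if n <= max_components:
        raise ValueError("need more training samples than max_components")
    kmax = int(min(max_components, np.linalg.matrix_rank(X - X.mean(axis=0))))
    if kmax < 1:
        raise ValueError("training matrix has rank < 1")

    rmsep = None
    if n_components is None:
        folds = min(cv_folds, n)
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
        sq_err = [[] for _ in range(kmax)]  # per-k, per-fold MSE
        for tr_idx, va_idx in kf.split(X):
            for k in range(1, kmax + 1):
                kk = min(k, np.linalg.matrix_rank(X[tr_idx] - X[tr_idx].mean(axis=0)))
                pred = _predict_latent(X[tr_idx], y[tr_idx], X[va_idx], method, kk)
                sq_err[k - 1].append(np.mean((pred - y[va_idx]) ** 2))
        fold_rmse = np.sqrt(np.asarray(sq_err))  # (kmax, folds)
        rmsep = fold_rmse.mean(axis=1)
        best = int(np.argmin(rmsep))
        se = fold_rmse[best].std(ddof=1) / np.sqrt(folds)
        n_components = int(np.flatnonzero(rmsep <= rmsep[best] + se)[0]) + 1
    if not 1 <= n_components <= kmax:
        raise ValueError(f"n_components must lie in [1, {kmax}]")

    if method == "plsr":
        pls = PLSRegression(n_components=n_components, scale=False).fit(X, y)
        beta, intercept = _collapse_pls(pls, X, y)
    else:
        beta, intercept = _fit_pcr(X, y, n_components)
    return RegressionModel(
        method=method,
        grid=train.grid.copy(),
        beta=beta,
        intercept=intercept,
        preprocess=preprocessor,
        training_grid=train.grid.copy(),
        hyperparams={"n_components": n_components, "max_components": max_components},
        rmsep_curve=rmsep,
    )


def _ridge_path_predict(Xtr, ytr, Xva, lambdas):
    """Validation predictions for every ridge penalty via one SVD."""
    xm, ym = Xtr.mean(axis=0), ytr.mean()
    U, s, Vt = np.linalg.svd(Xtr - xm, full_matrices=False)
    uty = U.T @ (ytr - ym)
    proj = (Xva - xm) @ Vt.T  # (n_va, r)
    shrink = s[:, np.newaxis] / (s[:, np.newaxis] ** 2 + lambdas[np.newaxis, :])
    return ym + proj @ (shrink * uty[:, np.newaxis])  # (n_va, n_lambda)


def fit_ridge(
    train: SpectralDataset,
    lambda_grid: np.ndarray | None = None,
    cv_folds: int = 10,
    n_repeats: int = 10,
    seed: int = 0,
    preprocessor: Preprocessor | None = None,
) -> RegressionModel:
    """Ridge-penalized multiple linear regression with CV penalty choice.

    The default penalty grid is 0.1 to 10 in steps of 0.1 (100 candidates);
    the cross-validation is repeated ``n_repeats`` times with different
    seeded fold assignments and the RMSEP averaged, then the penalty with the
    lowest mean RMSEP is kept.  X and y are centered; the intercept is
    recovered from the means.
    """
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(0.1, 10.0 + 1e-9, 0.1), 10)
    lambdas = np.asarray(lambda_grid, dtype=float)
    if lambdas.size == 0:
        raise ValueError("lambda grid must be nonempty")
    X, y = train.X, train.y
    n = X.shape[0]
    folds = min(cv_folds, n)
    sq = np.zeros(lambdas.size)
    count = 0
    for rep in range(n_repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for tr_idx, va_idx in kf.split(X):
            pred = _ridge_path_predict(X[tr_idx], y[tr_idx], X[va_idx], lambdas)
            sq += np.sum((pred - y[va_idx, np.newaxis]) ** 2, axis=0)
            count += va_idx.size
    rmsep = np.sqrt(sq / count)
    best = int(np.argmin(rmsep))
    lam = float(lambdas[best])

    xm, ym = X.mean(axis=0), y.mean()
    U, s, Vt = np.linalg.svd(X - xm, full_matrices=False)
    beta = Vt.T @ ((s / (s**2 + lam)) * (U.T @ (y - ym)))
    intercept = float(ym - xm @ beta)
    return RegressionModel(
        method="mlr_ridge",
        grid=train.grid.copy(),
        beta=beta,
        intercept=intercept,
        preprocess=preprocessor,
        training_grid=train.grid.copy(),
        hyperparams={"lambda": lam, "n_repeats": n_repeats},
        rmsep_curve=rmsep,
    )


def fit_ml(
    train: SpectralDataset,
    method: str = "svr",
    seed: int = 0,
    preprocessor: Preprocessor | None = None,
    **params,
) -> RegressionModel:
    """Fit a kernel or ensemble regressor (no coefficient vector).

    Defaults follow common practice for spectra: epsilon-SVR with a radial
    basis kernel and cost 50, or a 1000-tree random forest.  These models
    expose the same ``predict`` contract but carry no ``beta``, so they are
    excluded from coefficient-based wavelength selection and pixel maps.
    """
    if method == "svr":
        est = SVR(kernel=params.pop("kernel", "rbf"), C=params.pop("C", 50.0),
                  epsilon=params.pop("epsilon", 0.1), **params)
        hyper = {"kernel": est.kernel, "C": est.C, "epsilon": est.epsilon}
    elif method == "rf":
        est = RandomForestRegressor(
            n_estimators=params.pop("n_estimators", 1000),
            random_state=seed, n_jobs=1, **params,
        )
        hyper = {"n_estimators": est.n_estimators, "seed": seed}
    else:
        raise ValueError("ml method must be 'svr' or 'rf'")
    est.fit(train.X, train.y)
    return RegressionModel(
        method=method,
        grid=train.grid.copy(),
        beta=None,
        preprocess=preprocessor,
        training_grid=train.grid.copy(),
        hyperparams=hyper,
        estimator=est,
    )


# --- wavelength selection --------------------------------------------------

def select_by_coefficients(model: RegressionModel, fraction: float = 0.30) -> WavelengthSelection:
    """Retain the wavelengths with the largest |beta|.

    ``round(fraction * n_wavelengths)`` bands are kept (e.g. 132 of 440 at
    the default 30%); ties at the cut are broken toward the lower wavelength.
    """
    if model.beta is None:
        raise UnsupportedModelError("coefficient selection needs a linear model")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n = model.beta.size
    k = int(np.floor(fraction * n + 0.5))
    k = max(k, 1)
    order = np.lexsort((model.grid, -np.abs(model.beta)))
    keep = np.sort(order[:k])
    return WavelengthSelection(
        indices=keep,
        wavelengths=model.grid[keep],
        method="coef_fraction",
        params={"fraction": fraction, "n_retained": int(k)},
    )


def select_by_features(grid: np.ndarray, trait: str) -> WavelengthSelection:
    """Retain bands inside the known absorption-feature windows of a trait."""
    if trait == "water":
        windows = WATER_FEATURE_WINDOWS
    elif trait == "nitrogen":
        windows = NITROGEN_FEATURE_WINDOWS
    else:
        raise ValueError("trait must be 'water' or 'nitrogen'")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    keep = np.zeros(grid.size, dtype=bool)
    for w in windows:
        keep |= (grid >= w.lo) & (grid <= w.hi)
    idx = np.flatnonzero(keep)
    return WavelengthSelection(
        indices=idx,
        wavelengths=grid[idx],
        method="feature_windows",
        trait=trait,
        params={"n_windows": len(windows)},
    )


def refit_on_selection(
    train: SpectralDataset,
    validation: SpectralDataset,
    selection: WavelengthSelection,
    method: str = "plsr",
    **fit_kwargs,
) -> tuple[RegressionModel, tuple[FitMetrics, FitMetrics]]:
    """Refit a latent model on the selected wavelengths and evaluate it."""
    if selection.indices.size == 0:
        raise ValueError("selection is empty")
    if np.any(selection.indices >= train.grid.size):
        raise ValueError("selection indices fall outside the dataset grid")
    tr = train.with_X(train.X[:, selection.indices], grid=train.grid[selection.indices])
    va = validation.with_X(
        validation.X[:, selection.indices], grid=validation.grid[selection.indices]
    )
    model = fit_latent(tr, method=method, **fit_kwargs)
    model.training_grid = train.grid.copy()
    model.selection = selection.indices.copy()
    m_train = evaluate(model, tr, partition="train")
    m_val = evaluate(model, va, partition="validation")
    return model, (m_train, m_val)
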