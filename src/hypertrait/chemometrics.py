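"""Spectral preprocessing treatments applied to mean spectra before modelling.

Ten treatments are supported, named by their conventional chemometric
abbreviations:

====== =====================================================================
RAW    untouched reflectance
SMO    Savitzky-Golay smoothing (0th derivative)
SGD1   1st-order Savitzky-Golay derivative of reflectance
SGD2   2nd-order Savitzky-Golay derivative of reflectance
ASGD1  1st-order Savitzky-Golay derivative of absorbance log10(1/R)
ASGD2  2nd-order Savitzky-Golay derivative of absorbance
MSC    multiplicative scatter correction against a reference spectrum
EMSC   extended MSC with a polynomial wavelength baseline
SNV    standard normal variate (per-spectrum center and scale)
NBR    normalization by range to [0, 1]
====== =====================================================================

MSC and EMSC estimate their reference spectrum from the *training* partition
only and reuse it frozen for validation samples and pixel-level prediction,
so no information leaks from the evaluation data into the correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.signal import savgol_filter

from .dataset import SpectralDataset

METHODS = ("RAW", "SMO", "SGD1", "SGD2", "ASGD1", "ASGD2", "MSC", "EMSC", "SNV", "NBR")

#: Treatments that are linear maps of the spectrum (f(ax+by) = af(x)+bf(y)).
#: Pixel-level prediction through these commutes with spatial averaging;
#: through the others it need not.
LINEAR_METHODS = frozenset({"RAW", "SMO", "SGD1", "SGD2"})


@dataclass
class PreprocessSpec:
    """Configuration of one preprocessing treatment.

    ``window``/``polyorder`` apply to the Savitzky-Golay family (window 11,
    polynomial order 2 by default); ``emsc_degree`` is the order of the EMSC
    polynomial baseline; ``per_nm`` scales derivatives by the band spacing so
    they are per-nm rather than per-index; ``reference`` optionally supplies
    an MSC/EMSC reference spectrum instead of the training mean.
    """

    method: str = "RAW"
    window: int = 11
    polyorder: int = 2
    emsc_degree: int = 6
    per_nm: bool = True
    reference: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown preprocessing method '{self.method}'")
        if self.window % 2 == 0 or self.window <= self.polyorder:
            raise ValueError("window must be odd and greater than polyorder")

    @property
    def is_linear(self) -> bool:
        return self.method in LINEAR_METHODS


def to_absorbance(values: np.ndarray) -> np.ndarray:
    """Apparent absorbance log10(1/R) of a reflectance spectrum."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("absorbance requires strictly positive reflectance")
    return np.log10(1.0 / values)


def savitzky_golay(
    values: np.ndarray,
    window: int = 11,
    polyorder: int = 2,
    deriv: int = 0,
    delta: float = 1.0,
) -> np.ndarray:
    """Savitzky-Golay smoothing/derivative along the last axis.

    Each point is replaced by the ``deriv``-th derivative of a least-squares
    polynomial of order ``polyorder`` fitted over the centered window of
    ``window`` points, divided by ``delta**deriv`` (``delta`` = band spacing
    for per-nm derivatives).  The terminal half-windows are handled by
    evaluating the polynomial fitted to the first/last window off-center, so
    the output has the same length as the input.
    """
    values = np.asarray(values, dtype=float)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and greater than polyorder")
    if values.shape[-1] < window:
        raise ValueError("spectrum shorter than the filter window")
    return savgol_filter(
        values, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, mode="interp", axis=-1,
    )


def msc(X: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Multiplicative scatter correction of a (n, bands) spectra matrix.

    Each spectrum ``s`` is regressed on the reference (by default the column
    mean of ``X``): ``s ≈ a + b·ref``; the corrected spectrum is
    ``(s − a) / b``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("mean-reference MSC needs at least 2 spectra")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if np.ptp(reference) == 0:
        raise ValueError("MSC reference has zero variance")
    D = np.column_stack([np.ones_like(reference), reference])
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    a, b = coef[0], coef[1]
    if np.any(b == 0):
        raise ValueError("MSC slope estimate is zero for at least one spectrum")
    return (X - a[:, np.newaxis]) / b[:, np.newaxis]


def emsc(
    X: np.ndarray,
    grid: np.ndarray,
    degree: int = 6,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Extended MSC: scatter correction with a polynomial baseline.

    Each spectrum is fitted as ``s ≈ a + b·ref + Σ c_k P_k(t)`` where the
    ``P_k`` are Legendre polynomials on the wavelength grid rescaled to
    [-1, 1]; the physical-baseline part ``a + Σ c_k P_k`` is subtracted and
    the result divided by ``b``.  ``degree=0`` reduces to plain MSC.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    grid = np.asarray(grid, dtype=float)
    if reference is None:
        if X.shape[0] < 2:
            raise ValueError("mean-reference EMSC needs at least 2 spectra")
        reference = X.mean(axis=0)
    reference = np.asarray(reference, dtype=float)
    if np.ptp(reference) == 0:
        raise ValueError("EMSC reference has zero variance")
    t = 2.0 * (grid - grid[0]) / (grid[-1] - grid[0]) - 1.0
    basis = [np.ones_like(t), reference]
    for k in range(1, degree + 1):
        basis.append(legendre.legval(t, [0.0] * k + [1.0]))
    D = np.column_stack(basis)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ValueError("EMSC design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(D, X.T, rcond=None)
    b = coef[1]
    if np.any(b == 0):
        raise ValueError("EMSC slope estimate is zero for at least one spectrum")
    baseline_cols = np.delete(np.arange(D.shape[1]), 1)
    baseline = D[:, baseline_cols] @ coef[baseline_cols]
    return (X - baseline.T) / b[:, np.newaxis]


def snv(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centering and scaling (n-1 sd)."""
    values = np.asarray(values, dtype=float)
    if np.any(np.ptp(values, axis=-1) == 0):
        raise ValueError("SNV undefined for a constant spectrum")
    sd = values.std(axis=-1, ddof=1, keepdims=True)
    return (values - values.mean(axis=-1, keepdims=True)) / sd


def nbr(values: np.ndarray) -> np.ndarray:
    """Normalization by range: rescale each spectrum to [0, 1]."""
    values = np.asarray(values, dtype=float)
    lo = values.min(axis=-1, keepdims=True)
    hi = values.max(axis=-1, keepdims=True)
    if np.any(hi == lo):
        raise ValueError("range normalization undefined for a constant spectrum")
    return (values - lo) / (hi - lo)


class Preprocessor:
    """A preprocessing treatment with frozen training-derived state.

    ``fit`` estimates any data-dependent state (the MSC/EMSC reference
    spectrum) from training spectra; ``transform`` applies the treatment to
    any spectra on the same grid — validation samples or unfolded pixels —
    reusing the frozen state.
    """

    def __init__(self, spec: PreprocessSpec):
        self.spec = spec
        self.grid_: np.ndarray | None = None
        self.reference_: np.ndarray | None = None

    def fit(self, X: np.ndarray, grid: np.ndarray) -> "Preprocessor":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.grid_ = np.asarray(grid, dtype=float)
        if self.spec.method in ("MSC", "EMSC"):
            if self.spec.reference is not None:
                self.reference_ = np.asarray(self.spec.reference, dtype=float)
            else:
                if X.shape[0] < 2:
                    raise ValueError(f"{self.spec.method} needs >= 2 training spectra")
                self.reference_ = X.mean(axis=0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.grid_ is None:
            raise RuntimeError("Preprocessor used before fit()")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        m = self.spec.method
        delta = float(np.mean(np.diff(self.grid_))) if self.spec.per_nm else 1.0
        sg = lambda v, d: savitzky_golay(
            v, self.spec.window, self.spec.polyorder, deriv=d, delta=delta
        )
        if m == "RAW":
            return X.copy()
        if m == "SMO":
            return sg(X, 0)
        if m == "SGD1":
            return sg(X, 1)
        if m == "SGD2":
            return sg(X, 2)
        if m == "ASGD1":
            return sg(to_absorbance(X), 1)
        if m == "ASGD2":
            return sg(to_absorbance(X), 2)
        if m == "MSC":
            return msc(X, reference=self.reference_)
        if m == "EMSC":
            return emsc(X, self.grid_, degree=self.spec.emsc_degree, reference=self.reference_)
        if m == "SNV":
            return snv(X)
        if m == "NBR":
            return nbr(X)
        raise ValueError(f"unknown method '{m}'")  # pragma: no cover

    def fit_transform(self, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
        return self.fit(X, grid).transform(X)


def apply_preprocess(
    dataset: SpectralDataset, spec: PreprocessSpec
) -> tuple[SpectralDataset, Preprocessor]:
    """Apply a treatment to a whole dataset, fitting on the training rows.

    If the dataset carries a ``partition`` column, MSC/EMSC references are
    computed from the ``train`` rows only; otherwise from all rows.  Trait
    and replicate columns pass through untouched.
    """
    pre = Preprocessor(spec)
    if dataset.partition is not None:
        fit_rows = dataset.X[dataset.partition == "train"]
        if fit_rows.shape[0] == 0:
            fit_rows = dataset.X
    else:
        fit_rows = dataset.X
    pre.fit(fit_rows, dataset.grid)
    return dataset.with_X(pre.transform(dataset.X)), pre
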