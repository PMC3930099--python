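"""Vector autoregressive modelling and generalised partial directed coherence.

A stationary k-channel series ``Y_t`` is modelled as

    Y_t = v + sum_{l=1..p} A_l Y_{t-l} + eps_t,     eps_t ~ N(0, Sigma)

where the entry ``a_ij^(l)`` of ``A_l`` is the causality coefficient from
channel ``j`` to channel ``i`` at lag ``l``.  Generalised partial directed
coherence (GPDC) is the frequency-domain representation of the implied
Granger-causal structure: with the transfer polynomial

    abar_ij(lam) = delta_ij - sum_l a_ij^(l) exp(-i 2 pi lam l)

the (squared-modulus) GPDC from source ``j`` to target ``i`` at normalised
frequency ``lam`` (cycles/sample) is

    |abar_ij(lam) / sigma_i|^2  /  sum_m |abar_mj(lam)|^2 / sigma_m^2 ,

the share of source j's outflow received by channel i after partialling out
the remaining channels, weighted by inverse residual standard deviations so
the measure is invariant to per-channel scale.  Each source column sums to 1
over targets and every value lies in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import BandDefinition, bandpass_filter

__all__ = [
    "VARModel",
    "TransferSpectrum",
    "GPDCSpectrum",
    "OrderSelection",
    "companion_matrix",
    "spectral_radius",
    "fit_var",
    "select_order_group",
    "var_bic",
    "band_bin_centres",
    "transfer_spectrum",
    "gpdc_spectrum",
    "subject_gpdc",
]

#: default analysis band (Hz) and spectral pitch used throughout the package
DEFAULT_BAND = BandDefinition(0.05, 0.15)
DEFAULT_BIN_WIDTH = 0.002
DEFAULT_SAMPLING_INTERVAL = 2.0


@dataclass(frozen=True)
class VARModel:
    """A fitted (or constructed) vector autoregression.

    Attributes
    ----------
    intercept : (k,) array — the constant vector v.
    coefficients : (p, k, k) array — stacked lag matrices A_1..A_p, with
        ``coefficients[l-1, i, j]`` the coefficient from channel j to i at lag l.
    residual_covariance : (k, k) array — Sigma; its diagonal holds sigma_i^2.
    n_samples_fit : number of time points the model was estimated from
        (0 for constructed generators).
    """

    intercept: np.ndarray
    coefficients: np.ndarray
    residual_covariance: np.ndarray
    n_samples_fit: int = 0

    def __post_init__(self) -> None:
        A = np.asarray(self.coefficients, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError("coefficients must have shape (p, k, k)")
        object.__setattr__(self, "coefficients", A)
        object.__setattr__(self, "intercept", np.asarray(self.intercept, dtype=float))
        S = np.asarray(self.residual_covariance, dtype=float)
        object.__setattr__(self, "residual_covariance", S)
        if not np.all(np.isfinite(A)) or not np.all(np.isfinite(S)):
            raise ValueError("model parameters must be finite")
        if np.any(np.diag(S) <= 0):
            raise ValueError("residual variances must be positive")
        if self.p < 1:
            raise ValueError("order must be >= 1")

    @property
    def k(self) -> int:
        return self.coefficients.shape[1]

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]

    @property
    def sigma2(self) -> np.ndarray:
        """Per-channel residual variances sigma_i^2 (diagonal of Sigma)."""
        return np.diag(self.residual_covariance)

    def is_stable(self, tol: float = 0.0) -> bool:
        return spectral_radius(self.coefficients) < 1.0 - tol


@dataclass(frozen=True)
class TransferSpectrum:
    """Complex transfer polynomial abar(lam) evaluated on a frequency grid.

    ``abar[b, i, j] = delta_ij - sum_l A_l[i, j] exp(-i 2 pi lam_b l)``.
    """

    frequencies_hz: np.ndarray
    lambdas: np.ndarray  # normalised frequencies, cycles/sample
    abar: np.ndarray  # (n_bins, k, k) complex


@dataclass(frozen=True)
class GPDCSpectrum:
    """GPDC values per frequency bin for every ordered path.

    ``values[b, i, j]`` is the coherence on path j -> i at bin centre
    ``bins_hz[b]``.  With ``squared=True`` (default) values are squared
    moduli, so each source column j sums to exactly 1 over targets i
    (the diagonal "self" term included) and lies in [0, 1].  Diagonal
    entries are retained for the normalisation but are not paths.
    """

    bins_hz: np.ndarray
    values: np.ndarray  # (n_bins, k, k)
    squared: bool = True
    order: int = 0

    @property
    def k(self) -> int:
        return self.values.shape[1]

    def path(self, source: int, target: int) -> np.ndarray:
        """Per-bin values on the ordered path source -> target."""
        if source == target:
            raise ValueError("diagonal entries are not paths")
        return self.values[:, target, source]

    def path_table(self) -> pd.DataFrame:
        """Long-format (source, target, bin_hz, value) table of the off-diagonal paths."""
        k = self.k
        rows = []
        for j in range(k):
            for i in range(k):
                if i == j:
                    continue
                for b, f in enumerate(self.bins_hz):
                    rows.append((j, i, f, self.values[b, i, j]))
        return pd.DataFrame(rows, columns=["source", "target", "bin_hz", "value"])


@dataclass(frozen=True)
class OrderSelection:
    """Result of group-level BIC order selection."""

    order: int
    table: pd.DataFrame = field(repr=False)  # index p, columns subject BICs + "total"


# ---------------------------------------------------------------------------
# model construction / stability utilities
# ---------------------------------------------------------------------------

def companion_matrix(coefficients: np.ndarray) -> np.ndarray:
    """Companion form of stacked lag matrices (p, k, k) -> (kp, kp)."""
    A = np.asarray(coefficients, dtype=float)
    p, k = A.shape[0], A.shape[1]
    C = np.zeros((k * p, k * p))
    C[:k, :] = np.concatenate([A[l] for l in range(p)], axis=1)
    if p > 1:
        C[k:, :-k] = np.eye(k * (p - 1))
    return C


def spectral_radius(coefficients: np.ndarray) -> float:
    """Largest eigenvalue modulus of the companion matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coefficients)))))


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def fit_var(timecourses: np.ndarray, order: int) -> VARModel:
    """Least-squares fit of a VAR(p) with intercept.

    Parameters
    ----------
    timecourses : (k, T) array, one row per channel.
    order : lag order p >= 1.

    Returns
    -------
    VARModel with Sigma estimated from residual cross-products over the
    T - p usable time points (effective-sample-size divisor T - p).
    """
    Y = np.asarray(timecourses, dtype=float)
    if Y.ndim != 2:
        raise ValueError("timecourses must be a (k, T) matrix")
    k, T = Y.shape
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    if T <= k * p + p + 10:
        raise ValueError(
            f"T={T} too short for k={k}, p={p}: need T > k*p + p + 10"
        )
    # regressors: [1, Y_{t-1}, ..., Y_{t-p}] for t = p..T-1
    n_eff = T - p
    X = np.empty((n_eff, 1 + k * p))
    X[:, 0] = 1.0
    for l in range(1, p + 1):
        X[:, 1 + (l - 1) * k : 1 + l * k] = Y[:, p - l : T - l].T
    target = Y[:, p:].T  # (n_eff, k)
    B, _, rank, _ = np.linalg.lstsq(X, target, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            "rank-deficient regressor matrix (collinear or constant channels)"
        )
    resid = target - X @ B
    sigma = resid.T @ resid / n_eff
    intercept = B[0]
    coeffs = np.empty((p, k, k))
    for l in range(p):
        coeffs[l] = B[1 + l * k : 1 + (l + 1) * k].T
    return VARModel(intercept, coeffs, sigma, n_samples_fit=T)


def var_bic(model: VARModel) -> float:
    """BIC of a fitted VAR: log det Sigma + (log T_eff / T_eff) (p k^2 + k)."""
    T_eff = model.n_samples_fit - model.p
    sign, logdet = np.linalg.slogdet(model.residual_covariance)
    if sign <= 0:
        raise np.linalg.LinAlgError("residual covariance not positive definite")
    n_params = model.p * model.k**2 + model.k
    return float(logdet + np.log(T_eff) / T_eff * n_params)


def select_order_group(
    subject_timecourses: list[np.ndarray], p_max: int = 10
) -> OrderSelection:
    """Group-level BIC order selection.

    For each candidate order p in 1..p_max the per-subject BIC is computed
    and summed over subjects; the argmin of the summed criterion is the
    group order.  The full per-subject BIC table is returned for logging.
    """
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    min_T = min(np.asarray(tc).shape[1] for tc in subject_timecourses)
    k = np.asarray(subject_timecourses[0]).shape[0]
    if p_max >= min_T / (2 * k):
        raise ValueError(f"p_max={p_max} too large for shortest series T={min_T}")
    orders = range(1, p_max + 1)
    table = pd.DataFrame(
        index=pd.Index(orders, name="order"),
        columns=[f"subject_{s}" for s in range(len(subject_timecourses))],
        dtype=float,
    )
    for p in orders:
        for s, tc in enumerate(subject_timecourses):
            table.loc[p, f"subject_{s}"] = var_bic(fit_var(tc, p))
    table["total"] = table.sum(axis=1)
    best = int(table["total"].idxmin())
    return OrderSelection(order=best, table=table)


# ---------------------------------------------------------------------------
# GPDC
# ---------------------------------------------------------------------------

def band_bin_centres(
    band: BandDefinition = DEFAULT_BAND, bin_width: float = DEFAULT_BIN_WIDTH
) -> np.ndarray:
    """Bin-centre grid covering the band at the given pitch.

    The default band 0.05-0.15 Hz at 0.002 Hz pitch yields the 50 centres
    0.051, 0.053, ..., 0.149 Hz.
    """
    n = int(round((band.high - band.low) / bin_width))
    return band.low + bin_width * (np.arange(n) + 0.5)


def transfer_spectrum(
    model: VARModel,
    bins_hz: np.ndarray,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
) -> TransferSpectrum:
    """Evaluate abar(lam) = I - sum_l A_l exp(-i 2 pi lam l) at each bin centre."""
    bins_hz = np.asarray(bins_hz, dtype=float)
    nyquist = 0.5 / sampling_interval
    if np.any(bins_hz <= 0) or np.any(bins_hz >= nyquist):
        raise ValueError(f"bins must lie strictly inside (0, {nyquist}) Hz")
    lambdas = bins_hz * sampling_interval
    lags = np.arange(1, model.p + 1)
    # phase[b, l] = exp(-i 2 pi lam_b l)
    phase = np.exp(-2j * np.pi * lambdas[:, None] * lags[None, :])
    abar = np.eye(model.k)[None, :, :] - np.einsum(
        "bl,lij->bij", phase, model.coefficients
    )
    return TransferSpectrum(frequencies_hz=bins_hz, lambdas=lambdas, abar=abar)


def gpdc_spectrum(
    model: VARModel,
    bins_hz: np.ndarray | None = None,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    squared: bool = True,
) -> GPDCSpectrum:
    """Generalised partial directed coherence of a VAR model on a bin grid.

    Parameters
    ----------
    model : the (fitted or constructed) VAR.
    bins_hz : frequency bin centres; defaults to the 50-bin 0.05-0.15 Hz grid.
    squared : report squared moduli (default; source columns then sum to 1)
        or amplitudes (their square root).
    """
    if bins_hz is None:
        bins_hz = band_bin_centres()
    sigma2 = model.sigma2
    if np.any(sigma2 <= 0):
        raise ValueError("residual variances must be positive for GPDC")
    ts = transfer_spectrum(model, bins_hz, sampling_interval)
    # numerator |abar_ij|^2 / sigma_i^2 ; denominator sums it over targets i
    weighted = np.abs(ts.abar) ** 2 / sigma2[None, :, None]
    denom = weighted.sum(axis=1, keepdims=True)
    vals = weighted / denom
    if not squared:
        vals = np.sqrt(vals)
    return GPDCSpectrum(
        bins_hz=np.asarray(bins_hz, dtype=float),
        values=vals,
        squared=squared,
        order=model.p,
    )


def subject_gpdc(
    timecourses: np.ndarray,
    order: int,
    band: BandDefinition = DEFAULT_BAND,
    sampling_interval: float = DEFAULT_SAMPLING_INTERVAL,
    bin_width: float = DEFAULT_BIN_WIDTH,
    squared: bool = True,
) -> GPDCSpectrum:
    """Band-pass the channels, fit a VAR(order) and evaluate GPDC on the band grid."""
    Y = np.asarray(timecourses, dtype=float)
    filtered = np.vstack(
        [bandpass_filter(row, band, sampling_interval) for row in Y]
    )
    model = fit_var(filtered, order)
    if not model.is_stable():
        warnings.warn(
            "fitted VAR is unstable; GPDC values may be unreliable", stacklevel=2
        )
    bins = band_bin_centres(band, bin_width)
    return gpdc_spectrum(model, bins, sampling_interval, squared=squared)
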