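"""Multivariate autoregressive (MVAR) modelling and the spectral transfer matrix.

The MVAR model expresses each channel's current sample as a weighted sum of
the past ``p`` samples of *all* channels plus innovation noise:

    x(t) = sum_{m=1..p} A_m x(t-m) + e(t),      Cov[e] = V.

The joint fit over all channels is what separates direct influences from
common-source effects; its frequency-domain inverse

    H(f) = [I - sum_m A_m exp(-i 2 pi f m / fs)]^{-1}

is the transfer matrix that the Directed Transfer Function is built from.

Follows the Model/Results pattern: ``MVAR(recording).fit(order)`` returns an
:class:`MVARResults` carrying coefficients, residual covariance, standard
errors and stability diagnostics, with ``transfer_matrix`` /
``spectral_density`` / ``summary`` methods.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import MultichannelRecording


class StabilityError(RuntimeError):
    """Raised when an MVAR coefficient set is unstable where stability is required."""


class RankDeficiencyError(ValueError):
    """Raised when the lagged-regressor matrix is rank deficient (e.g. duplicated channels)."""


def companion_matrix(coefficients: np.ndarray) -> np.ndarray:
    """Companion form of a coefficient tensor (order, K, K) -> (pK, pK)."""
    A = np.asarray(coefficients, dtype=float)
    p, k, _ = A.shape
    F = np.zeros((p * k, p * k))
    F[:k] = np.concatenate(list(A), axis=1)
    if p > 1:
        F[k:, :-k] = np.eye((p - 1) * k)
    return F


def default_frequency_grid(sampling_rate: float, step: float = 0.5) -> np.ndarray:
    """0 .. Nyquist inclusive in ``step``-Hz increments (resolves the usual EEG bands)."""
    nyq = sampling_rate / 2.0
    return np.arange(0.0, nyq + step / 2, step)


@dataclass
class SpectralTransfer:
    """Transfer matrix H on a frequency grid; H[f][i, j] is transfer j -> i."""

    frequencies: np.ndarray
    H: np.ndarray  # (n_freqs, K, K) complex
    sampling_rate: float
    channel_labels: list

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if not np.all(np.isfinite(self.H)):
            raise ValueError("transfer matrix contains non-finite values")


class MVAR:
    """MVAR model specification bound to a recording.

    Parameters
    ----------
    recording : MultichannelRecording
    demean : bool
        Remove each channel's mean before fitting (default True).
    standardize : bool
        Also scale each channel to unit variance (default True); makes DTF
        values comparable across channels of different amplitude.
    """

    def __init__(self, recording: MultichannelRecording, demean: bool = True,
                 standardize: bool = True):
        self.recording = recording
        self.demean = demean
        self.standardize = standardize
        x = recording.data.astype(float).copy()
        if demean:
            x -= x.mean(axis=0)
        if standardize:
            sd = x.std(axis=0)
            if np.any(sd == 0):
                flat = [lab for lab, s in zip(recording.channel_labels, sd) if s == 0]
                raise ValueError(f"constant channels cannot be standardized: {flat}")
            x /= sd
        self._x = x

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, sampling_rate: float, **kwargs) -> "MVAR":
        rec = MultichannelRecording(df.to_numpy(dtype=float), sampling_rate,
                                    list(df.columns))
        return cls(rec, **kwargs)

    # -- estimation --------------------------------------------------------

    def fit(self, order: int = 5) -> "MVARResults":
        """Joint least-squares fit of all channels at the given order.

        Coefficients minimize the one-step-ahead squared prediction error
        summed over channels (multichannel OLS on the stacked lag regression);
        V is the residual covariance.  Stability is checked afterwards:
        borderline-unstable fits are returned with ``is_stable=False`` and a
        warning rather than an exception.
        """
        if order < 1:
            raise ValueError("order must be >= 1")
        x = self._x
        n, k = x.shape
        if n - order <= order * k:
            raise ValueError(
                f"order {order} too large for {n} samples of {k} channels")
        if n <= 10 * order * k:
            warnings.warn(
                f"few samples ({n}) for order {order} with {k} channels; "
                "coefficient estimates will be noisy", stacklevel=2)
        Y, Z = _lag_regression(x, order)
        coeffs, V, stderr = _solve_ols(Y, Z, order, k,
                                       self.recording.channel_labels, x)
        radius = float(np.max(np.abs(np.linalg.eigvals(companion_matrix(coeffs)))))
        if radius >= 1.0:
            warnings.warn(
                f"fitted MVAR is unstable (companion spectral radius {radius:.4f})",
                stacklevel=2)
        return MVARResults(
            model=self, order=order, coefficients=coeffs, resid_cov=V,
            coef_stderr=stderr, spectral_radius=radius, n_effective=n - order)

    def select_order(self, max_order: int, criterion: str = "aic") -> int:
        """Order in 1..max_order minimizing an information criterion.

        All candidate orders are fitted on the common sample span (the first
        ``max_order`` samples serve as presample for every fit) so the
        criteria are comparable.
        """
        if max_order < 1:
            raise ValueError("max_order must be >= 1")
        x = self._x
        n, k = x.shape
        if n - max_order <= max_order * k:
            raise ValueError(
                f"max_order {max_order} too large for {n} samples of {k} channels")
        crits = [self._criterion(p, max_order, criterion) for p in
                 range(1, max_order + 1)]
        return int(np.argmin(crits)) + 1

    def _criterion(self, order: int, presample: int, criterion: str) -> float:
        x = self._x
        n, k = x.shape
        Y = x[presample:]
        Z = np.hstack([x[presample - m: n - m] for m in range(1, order + 1)])
        B, *_ = np.linalg.lstsq(Z, Y, rcond=None)
        E = Y - Z @ B
        n_eff = Y.shape[0]
        v_mle = (E.T @ E) / n_eff
        sign, logdet = np.linalg.slogdet(v_mle)
        if sign <= 0:
            return np.inf
        n_par = order * k * k
        if criterion == "aic":
            return logdet + 2.0 * n_par / n_eff
        if criterion == "bic":
            return logdet + np.log(n_eff) * n_par / n_eff
        raise ValueError(f"unknown criterion {criterion!r} (use 'aic' or 'bic')")


def _lag_regression(x: np.ndarray, order: int):
    n = x.shape[0]
    Y = x[order:]
    Z = np.hstack([x[order - m: n - m] for m in range(1, order + 1)])
    return Y, Z


def _solve_ols(Y, Z, order, k, labels, x):
    G = Z.T @ Z
    rank = np.linalg.matrix_rank(G)
    if rank < order * k:
        # identify near-duplicated channels for the error message
        c = np.corrcoef(x.T)
        dup = [(labels[i], labels[j]) for i in range(k) for j in range(i + 1, k)
               if abs(c[i, j]) > 1 - 1e-10]
        raise RankDeficiencyError(
            "lagged regressor matrix is rank deficient"
            + (f"; near-duplicated channels: {dup}" if dup else ""))
    B = np.linalg.solve(G, Z.T @ Y)          # (order*K, K)
    E = Y - Z @ B
    dof = max(Y.shape[0] - order * k, 1)
    V = (E.T @ E) / dof
    Ginv_diag = np.diag(np.linalg.inv(G))
    # se of B[q, i] = sqrt(V[i,i] * Ginv[q,q]); reshape to (order, K, K)
    se_flat = np.sqrt(np.outer(Ginv_diag, np.diag(V)))   # (order*K, K)
    coeffs = np.empty((order, k, k))
    stderr = np.empty((order, k, k))
    for m in range(order):
        coeffs[m] = B[m * k:(m + 1) * k].T
        stderr[m] = se_flat[m * k:(m + 1) * k].T
    return coeffs, (V + V.T) / 2, stderr


@dataclass
class MVARResults:
    """Fitted MVAR: coefficient tensor, residual covariance, diagnostics."""

    model: MVAR
    order: int
    coefficients: np.ndarray   # (order, K, K); [m, i, j] = influence of j at lag m+1 on i
    resid_cov: np.ndarray      # (K, K) symmetric PSD
    coef_stderr: np.ndarray    # (order, K, K)
    spectral_radius: float
    n_effective: int

    @property
    def is_stable(self) -> bool:
        return self.spectral_radius < 1.0

    @property
    def n_channels(self) -> int:
        return self.coefficients.shape[1]

    @property
    def sampling_rate(self) -> float:
        return self.model.recording.sampling_rate

    @property
    def channel_labels(self) -> list:
        return self.model.recording.channel_labels

    def aic(self) -> float:
        n_eff = self.n_effective
        k = self.n_channels
        v_mle = self.resid_cov * (n_eff - self.order * k) / n_eff
        _, logdet = np.linalg.slogdet(v_mle)
        return float(logdet + 2.0 * self.order * k * k / n_eff)

    # -- spectral quantities ----------------------------------------------

    def transfer_matrix(self, frequencies=None) -> SpectralTransfer:
        """H(f) = [I - sum_m A_m e^{-i 2 pi f m / fs}]^{-1} on the grid."""
        freqs = _check_grid(frequencies, self.sampling_rate)
        k, p = self.n_channels, self.order
        H = np.empty((len(freqs), k, k), dtype=complex)
        eye = np.eye(k)
        for fi, f in enumerate(freqs):
            phase = np.exp(-2j * np.pi * f * np.arange(1, p + 1) / self.sampling_rate)
            Af = eye - np.tensordot(phase, self.coefficients, axes=(0, 0))
            try:
                H[fi] = np.linalg.inv(Af)
            except np.linalg.LinAlgError as exc:
                raise np.linalg.LinAlgError(
                    f"characteristic matrix singular at f = {f} Hz") from exc
        return SpectralTransfer(freqs, H, self.sampling_rate, self.channel_labels)

    def spectral_density(self, frequencies=None) -> np.ndarray:
        """One-sided cross-spectral density S(f) = H V H^dagger, per-Hz units.

        Scaled by 2/fs (1/fs at 0 and Nyquist) so the diagonal matches a
        one-sided Welch periodogram of a realization.  Returns an array of
        shape (n_freqs, K, K); the diagonal is real and non-negative.
        """
        transfer = self.transfer_matrix(frequencies)
        H = transfer.H
        S = H @ self.resid_cov @ np.conj(np.swapaxes(H, 1, 2))
        scale = np.full(len(transfer.frequencies), 2.0 / self.sampling_rate)
        nyq = self.sampling_rate / 2.0
        scale[np.isclose(transfer.frequencies, 0.0)] = 1.0 / self.sampling_rate
        scale[np.isclose(transfer.frequencies, nyq)] = 1.0 / self.sampling_rate
        S = S * scale[:, None, None]
        # enforce exact Hermitian symmetry against rounding
        S = (S + np.conj(np.swapaxes(S, 1, 2))) / 2
        return S

    def dtf(self, frequencies=None):
        """Directed Transfer Function spectrum of this fit (see estimators.dtf)."""
        from .estimators import dtf as _dtf
        return _dtf(self.transfer_matrix(frequencies))

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        k = self.n_channels
        lines = [
            "MVAR model fit",
            "=" * 46,
            f"channels:           {k} ({', '.join(self.channel_labels)})",
            f"order:              {self.order}",
            f"effective samples:  {self.n_effective}",
            f"sampling rate:      {self.sampling_rate:g} Hz",
            f"spectral radius:    {self.spectral_radius:.4f} "
            f"({'stable' if self.is_stable else 'UNSTABLE'})",
            f"AIC:                {self.aic():.4f}",
            "",
        ]
        for m in range(self.order):
            lines.append(f"A_{m + 1} (coefficient / std. error):")
            df = pd.DataFrame(self.coefficients[m], index=self.channel_labels,
                              columns=self.channel_labels)
            se = pd.DataFrame(self.coef_stderr[m], index=self.channel_labels,
                              columns=self.channel_labels)
            lines.append(df.round(3).to_string())
            lines.append(("(se) " + se.round(3).to_string()).replace("\n", "\n(se) "))
            lines.append("")
        return "\n".join(lines)


def fit_mvar(recording: MultichannelRecording, order: int = 5,
             **model_kwargs) -> MVARResults:
    """Convenience wrapper: ``MVAR(recording, **kw).fit(order)``."""
    return MVAR(recording, **model_kwargs).fit(order)


def select_order(recording: MultichannelRecording, max_order: int,
                 criterion: str = "aic", **model_kwargs) -> int:
    """Convenience wrapper: ``MVAR(recording, **kw).select_order(...)``."""
    return MVAR(recording, **model_kwargs).select_order(max_order, criterion)


def transfer_matrix(results: MVARResults, frequencies=None) -> SpectralTransfer:
    return results.transfer_matrix(frequencies)


def spectral_density(results: MVARResults, frequencies=None) -> np.ndarray:
    return results.spectral_density(frequencies)


def _check_grid(frequencies, sampling_rate: float) -> np.ndarray:
    if frequencies is None:
        return default_frequency_grid(sampling_rate)
    freqs = np.asarray(frequencies, dtype=float)
    nyq = sampling_rate / 2.0
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("frequency grid must be a non-empty 1-D array")
    if freqs.min() < 0 or freqs.max() > nyq + 1e-9:
        raise ValueError(f"frequencies must lie in [0, {nyq}] Hz")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    return freqs
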