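"""Connectivity estimators: DTF (+ short-time variant), coherence, SL.

Three estimators with very different blind spots:

* **DTF** — multivariate, directed.  gamma^2_ij(f) = |H_ij(f)|^2 /
  sum_m |H_im(f)|^2 is the fraction of the total spectral inflow to channel i
  contributed by channel j; rows sum to 1 at every frequency and a common
  source feeding several channels does not create sink-sink inflow.
* **Coherence** — bivariate, symmetric; saturates between any two channels
  that share a source, regardless of whether they influence each other.
* **Synchronization likelihood (SL)** — bivariate, nonlinear; probability
  that state-space recurrences (after time-delay embedding) in one channel
  coincide with recurrences in another, normalized so chance level equals the
  reference recurrence rate ``p_ref`` and identical signals give 1.

``band_integrate`` averages a spectrum over a closed frequency band, yielding
the single (target, source) matrix the network-analysis stage consumes.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.spatial.distance import cdist

from .mvar import SpectralTransfer, _check_grid
from .recording import MultichannelRecording


@dataclass
class ConnectivitySpectrum:
    """Per-frequency (target, source) connectivity values in [0, 1]."""

    estimator_id: str                 # "DTF" or "COH"
    frequencies: np.ndarray
    values: np.ndarray                # (K, K, n_freqs), [target, source, f]
    directed: bool
    channel_labels: list

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("connectivity values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)


@dataclass
class PairMatrix:
    """Symmetric (channel, channel) association matrix with unit diagonal."""

    estimator_id: str                 # "SL"
    values: np.ndarray
    channel_labels: list
    params: dict | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("pair matrix must be symmetric")
        if self.values.min() < -1e-9 or self.values.max() > 1 + 1e-9:
            raise ValueError("pair values must lie in [0, 1]")
        self.values = np.clip(self.values, 0.0, 1.0)

    @property
    def directed(self) -> bool:
        return False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.channel_labels,
                            columns=self.channel_labels)


@dataclass(frozen=True)
class SLParams:
    """Time-delay-embedding parameters for synchronization likelihood.

    ``p_ref`` is the per-channel recurrence rate the critical distances are
    tuned to; the Theiler window excludes temporally close (autocorrelated)
    vector pairs from the recurrence statistics.
    """

    delay: int = 10
    embedding_dim: int = 10
    p_ref: float = 0.05
    theiler_window: int | None = None   # default: delay * embedding_dim

    def __post_init__(self):
        if self.delay < 1 or self.embedding_dim < 2:
            raise ValueError("need delay >= 1 and embedding_dim >= 2")
        if not 0 < self.p_ref < 1:
            raise ValueError("p_ref must lie in (0, 1)")

    @property
    def window(self) -> int:
        return self.delay * self.embedding_dim if self.theiler_window is None \
            else self.theiler_window


@dataclass
class IntegratedConnectivity:
    """Band-averaged (target, source) connectivity matrix."""

    estimator_id: str
    band: tuple                       # (f_lo, f_hi) Hz
    matrix: np.ndarray                # (K, K), [target, source]
    directed: bool
    channel_labels: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.channel_labels,
                            columns=self.channel_labels)


@dataclass
class TimeVaryingConnectivity:
    """SDTF output: one connectivity spectrum per sliding-window position."""

    window_starts: np.ndarray         # in samples, relative to trial start
    spectra: list                     # list of ConnectivitySpectrum
    window_length: int
    sampling_rate: float

    @property
    def window_times(self) -> np.ndarray:
        """Window start times in seconds."""
        return self.window_starts / self.sampling_rate


# ---------------------------------------------------------------------------
# DTF
# ---------------------------------------------------------------------------

def dtf(transfer: SpectralTransfer) -> ConnectivitySpectrum:
    """Normalized squared DTF from a spectral transfer matrix.

    values[i, j, f] = |H_ij(f)|^2 / sum_m |H_im(f)|^2 — the inflow from
    channel j to channel i as a fraction of all inflows to i.  Every row sums
    to 1 at every frequency.
    """
    power = np.abs(transfer.H) ** 2           # (F, K, K)
    denom = power.sum(axis=2)                 # (F, K) total inflow per target
    bad = np.argwhere(denom == 0)
    if bad.size:
        fi, i = bad[0]
        raise ValueError(
            f"all-zero transfer row for channel {transfer.channel_labels[i]!r} "
            f"at f = {transfer.frequencies[fi]} Hz")
    values = np.moveaxis(power / denom[:, :, None], 0, 2)   # (K, K, F)
    return ConnectivitySpectrum("DTF", transfer.frequencies, values,
                                directed=True,
                                channel_labels=list(transfer.channel_labels))


def sdtf(trials, window_length: int, step: int, order: int,
         frequencies=None, demean: bool = True) -> TimeVaryingConnectivity:
    """Short-time DTF: ensemble averaging over trials with a sliding window.

    For each window position one MVAR is fitted to the pooled windowed data
    (the lag-regression normal equations are accumulated across trials, the
    standard short-window ensemble practice), then the DTF of that fit is
    computed.  Requires repeated realizations of the same process (trials of
    equal length and channel set).
    """
    trials = list(trials)
    if not trials:
        raise ValueError("need at least one trial")
    n, k = trials[0].data.shape
    labels = trials[0].channel_labels
    fs = trials[0].sampling_rate
    for t in trials[1:]:
        if t.data.shape != (n, k) or t.channel_labels != labels:
            raise ValueError("all trials must share length and channel set")
    if window_length <= order:
        raise ValueError("window_length must exceed the model order")
    n_eq = len(trials) * (window_length - order)
    if n_eq <= 3 * order * k:
        raise ValueError(
            f"under-determined: {len(trials)} trials x {window_length - order} "
            f"equations per trial cannot support order {order} with {k} channels")
    if len(trials) < 10:
        warnings.warn(f"only {len(trials)} trials; SDTF estimates will be "
                      "noisy (>= 10 recommended)", stacklevel=2)

    freqs = _check_grid(frequencies, fs)
    starts = np.arange(0, n - window_length + 1, step)
    spectra = []
    for s in starts:
        G = np.zeros((order * k, order * k))
        Zy = np.zeros((order * k, k))
        for t in trials:
            x = t.data[s: s + window_length].astype(float)
            if demean:
                x = x - x.mean(axis=0)
            Y = x[order:]
            Z = np.hstack([x[order - m: window_length - m]
                           for m in range(1, order + 1)])
            G += Z.T @ Z
            Zy += Z.T @ Y
        B = np.linalg.solve(G, Zy)
        coeffs = np.stack([B[m * k:(m + 1) * k].T for m in range(order)])
        H = _transfer_from_coeffs(coeffs, freqs, fs)
        spectra.append(dtf(SpectralTransfer(freqs, H, fs, labels)))
    return TimeVaryingConnectivity(starts, spectra, window_length, fs)


def _transfer_from_coeffs(coeffs, freqs, fs):
    p, k, _ = coeffs.shape
    H = np.empty((len(freqs), k, k), dtype=complex)
    eye = np.eye(k)
    for fi, f in enumerate(freqs):
        phase = np.exp(-2j * np.pi * f * np.arange(1, p + 1) / fs)
        H[fi] = np.linalg.inv(eye - np.tensordot(phase, coeffs, axes=(0, 0)))
    return H


# ---------------------------------------------------------------------------
# Coherence
# ---------------------------------------------------------------------------

def coherence(recording: MultichannelRecording, segment_length: int = 256,
              overlap: float = 0.5, frequencies=None) -> ConnectivitySpectrum:
    """Magnitude-squared coherence via Welch-averaged windowed cross-spectra.

    Hann taper, ``overlap`` fractional segment overlap.  Symmetric in the
    channel pair with unit diagonal; interpolated onto ``frequencies`` when a
    grid is given.
    """
    x = recording.data
    n, k = x.shape
    if segment_length > n:
        raise ValueError(f"segment_length {segment_length} exceeds {n} samples")
    noverlap = int(round(segment_length * overlap))
    n_segments = 1 + (n - segment_length) // max(segment_length - noverlap, 1)
    if n_segments < 4:
        raise ValueError(
            f"only {n_segments} Welch segments; need >= 4 (shorten segment_length)")
    fs = recording.sampling_rate
    f_native, _ = sps.csd(x[:, 0], x[:, 0], fs=fs, window="hann",
                          nperseg=segment_length, noverlap=noverlap)
    S = np.empty((k, k, len(f_native)), dtype=complex)
    for i in range(k):
        for j in range(i, k):
            _, sij = sps.csd(x[:, i], x[:, j], fs=fs, window="hann",
                             nperseg=segment_length, noverlap=noverlap)
            S[i, j] = sij
            S[j, i] = np.conj(sij)
    auto = np.real(np.einsum("iif->if", S))
    coh = np.abs(S) ** 2 / (auto[:, None, :] * auto[None, :, :])
    for i in range(k):
        coh[i, i] = 1.0
    coh = np.clip(np.real(coh), 0.0, 1.0)

    if frequencies is not None:
        freqs = _check_grid(frequencies, fs)
        coh = np.stack([
            [np.interp(freqs, f_native, coh[i, j]) for j in range(k)]
            for i in range(k)])
    else:
        freqs = f_native
    return ConnectivitySpectrum("COH", freqs, coh, directed=False,
                                channel_labels=list(recording.channel_labels))


# ---------------------------------------------------------------------------
# Synchronization likelihood
# ---------------------------------------------------------------------------

def synchronization_likelihood(recording: MultichannelRecording,
                               params: SLParams = SLParams()) -> PairMatrix:
    """Pairwise synchronization likelihood after time-delay embedding.

    Each channel is embedded with ``params.delay`` and
    ``params.embedding_dim``; its critical distance is the ``p_ref`` quantile
    of the inter-vector distances (Theiler-excluded), so every channel's
    recurrence rate is exactly ``p_ref``.  For a pair (X, Y),

        SL = P(recurrence in X and in Y simultaneously) / p_ref,

    giving 1 for identical channels and ~``p_ref`` for independent ones.
    """
    x = recording.data
    n, k = x.shape
    m, tau = params.embedding_dim, params.delay
    span = (m - 1) * tau
    if span >= n:
        raise ValueError(
            f"embedding span {span} samples exceeds the {n}-sample series")
    n_vec = n - span
    if n_vec - params.window < 10:
        raise ValueError("too few embedded vectors after the Theiler exclusion")

    # valid (i < j) vector pairs, Theiler-excluded, as a flat boolean mask
    ii, jj = np.triu_indices(n_vec, k=params.window + 1)

    recur = []
    for c in range(k):
        emb = np.lib.stride_tricks.sliding_window_view(
            x[:, c], span + 1)[:, ::tau].astype(np.float32)   # (n_vec, m)
        d = cdist(emb, emb, metric="euclidean").astype(np.float32)[ii, jj]
        eps = np.quantile(d, params.p_ref)
        recur.append(d <= eps)

    values = np.eye(k)
    for a in range(k):
        for b in range(a + 1, k):
            joint = np.mean(recur[a] & recur[b])
            values[a, b] = values[b, a] = min(joint / params.p_ref, 1.0)
    return PairMatrix("SL", values, list(recording.channel_labels),
                      params={"delay": tau, "embedding_dim": m,
                              "p_ref": params.p_ref,
                              "theiler_window": params.window})


# ---------------------------------------------------------------------------
# Band integration
# ---------------------------------------------------------------------------

def band_integrate(spectrum: ConnectivitySpectrum, f_lo: float,
                   f_hi: float) -> IntegratedConnectivity:
    """Arithmetic mean of the spectrum over grid points with f_lo <= f <= f_hi.

    Band edges are inclusive on both sides.
    """
    if not f_lo < f_hi:
        raise ValueError("need f_lo < f_hi")
    mask = (spectrum.frequencies >= f_lo) & (spectrum.frequencies <= f_hi)
    if not mask.any():
        raise ValueError(
            f"band [{f_lo}, {f_hi}] Hz contains no grid frequencies")
    matrix = spectrum.values[:, :, mask].mean(axis=2)
    return IntegratedConnectivity(spectrum.estimator_id, (f_lo, f_hi), matrix,
                                  spectrum.directed,
                                  list(spectrum.channel_labels))
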