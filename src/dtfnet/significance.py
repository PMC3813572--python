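"""Edge significance: surrogate null thresholds, bootstrap CIs, binarization.

Deciding whether a band-integrated DTF value reflects a real coupling needs a
null distribution in which cross-channel dependence is absent but everything
else (each channel's spectrum, the sample size, the fitting procedure) is
preserved.  Phase randomization delivers exactly that: each channel's Fourier
phases are scrambled independently, destroying all cross-channel coupling
while keeping the per-channel amplitude spectrum; re-fitting the MVAR and
recomputing the DTF per surrogate yields the null, and the per-pair threshold
is a quantile (default the 90th percentile) of it.

A plain epoch-resampling bootstrap is provided separately for confidence
intervals around SDTF estimates — resampling the original data preserves the
coupling under test, so it cannot serve as an existence null.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import IntegratedConnectivity, band_integrate, sdtf
from .mvar import MVAR
from .recording import MultichannelRecording


@dataclass
class SignificanceThresholds:
    """Per ordered (target, source) pair: the null-quantile threshold."""

    values: np.ndarray        # (K, K); diagonal fixed at 1 (never significant)
    level: float              # quantile used, e.g. 0.9
    n_resamples: int
    channel_labels: list
    band: tuple
    max_statistic: float = 1.0  # level-quantile of the per-surrogate max over pairs

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("thresholds must lie in [0, 1]")

    @property
    def max_threshold(self) -> float:
        """Highest off-diagonal per-pair threshold — the single-cutoff reading."""
        off = ~np.eye(len(self.channel_labels), dtype=bool)
        return float(self.values[off].max())


@dataclass
class Adjacency:
    """Binary (target, source) edge matrix with zero diagonal."""

    matrix: np.ndarray
    directed: bool
    channel_labels: list
    threshold: object = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=bool)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("adjacency must be square")
        if self.matrix.diagonal().any():
            raise ValueError("adjacency diagonal must be empty")
        if not self.directed and not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("undirected adjacency must be symmetric")

    @property
    def n_edges(self) -> int:
        total = int(self.matrix.sum())
        return total if self.directed else total // 2

    def edge_list(self) -> list:
        """(source_label, target_label) pairs; unordered pairs listed once."""
        k = len(self.channel_labels)
        out = []
        for i in range(k):          # target
            for j in range(k):      # source
                if not self.matrix[i, j]:
                    continue
                if not self.directed and j > i:
                    continue
                out.append((self.channel_labels[j], self.channel_labels[i]))
        return out


def phase_randomize(data: np.ndarray, rngs) -> np.ndarray:
    """Independent per-channel phase randomization (spectrum-preserving).

    ``rngs`` supplies one random Generator per column so surrogate streams
    can be tied to channel identity rather than column position.
    """
    n, k = data.shape
    out = np.empty_like(data, dtype=float)
    for c in range(k):
        spec = np.fft.rfft(data[:, c])
        phases = rngs[c].uniform(0, 2 * np.pi, size=spec.shape[0])
        phases[0] = 0.0
        if n % 2 == 0:
            phases[-1] = 0.0   # Nyquist bin must stay real
        out[:, c] = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n=n)
    return out


def _fit_univariate_ar(x: np.ndarray, order: int):
    """Per-channel AR fit; returns (coefficients, residuals)."""
    n = x.shape[0]
    y = x[order:]
    Z = np.column_stack([x[order - m: n - m] for m in range(1, order + 1)])
    phi, *_ = np.linalg.lstsq(Z, y, rcond=None)
    # guard: shrink the rare unstable univariate fit back inside the unit circle
    for _ in range(50):
        roots = np.roots(np.concatenate([[1.0], -phi]))
        if roots.size == 0 or np.max(np.abs(roots)) < 0.999:
            break
        phi = phi * 0.98 ** np.arange(1, order + 1)
    return phi, y - Z @ phi


def _diagonal_ar_surrogate(phis, resid, n: int, rng) -> np.ndarray:
    """Simulate channels from their own ARs driven by jointly resampled residuals.

    Residual *vectors* (rows) are resampled with replacement, preserving the
    instantaneous cross-channel covariance while destroying every lagged
    cross-channel relation — the null of 'no directed influence'.
    """
    k = len(phis)
    order = len(phis[0])
    burn = 10 * order
    idx = rng.integers(0, resid.shape[0], size=n + burn)
    innov = resid[idx]
    out = np.empty((n, k))
    from scipy.signal import lfilter
    for c in range(k):
        den = np.concatenate([[1.0], -phis[c]])
        out[:, c] = lfilter([1.0], den, innov[:, c])[burn:]
    return out


def resampling_thresholds(recording: MultichannelRecording,
                          order: int = 5,
                          band: tuple = (4.0, 60.0),
                          n_resamples: int = 200,
                          level: float = 0.9,
                          seed: int = 0,
                          frequencies=None,
                          method: str = "diagonal",
                          standardize: bool = True) -> SignificanceThresholds:
    """Null thresholds for band-integrated DTF via surrogate recordings.

    Two nulls are available:

    * ``method="diagonal"`` (default): each channel is refitted with its own
      univariate AR and surrogates are simulated from those ARs driven by
      jointly resampled residual vectors.  This preserves each channel's
      spectrum *and* the instantaneous cross-channel covariance while
      destroying all lagged coupling — the null hypothesis of a directed
      (Granger-type) edge.  Zero-phase volume conduction is part of this
      null, so it does not trigger significance.
    * ``method="phase"``: independent per-channel phase randomization
      (preserves spectra, destroys all dependence including the zero-lag
      part).  Appropriate when any dependence at all counts as coupling.

    The per-pair threshold is the ``level`` quantile of the band-integrated
    DTF over surrogates.  Surrogate randomness is keyed by sorted channel
    label, so relabeling/permuting channels permutes the thresholds exactly.
    """
    if n_resamples < 1:
        raise ValueError("n_resamples must be >= 1")
    if n_resamples < 100:
        warnings.warn(f"{n_resamples} resamples is few for level {level}; "
                      "thresholds will be noisy", stacklevel=2)
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if method not in ("diagonal", "phase"):
        raise ValueError("method must be 'diagonal' or 'phase'")

    labels = recording.channel_labels
    k = len(labels)
    n = recording.n_samples
    ss = np.random.SeedSequence([int(seed), 0x5A])
    if method == "phase":
        children = ss.spawn(k)
        # stream per label, assigned by sorted label order -> permutation equivariance
        by_label = {lab: np.random.default_rng(c)
                    for lab, c in zip(sorted(labels), children)}
        rngs = [by_label[lab] for lab in labels]
    else:
        rng = np.random.default_rng(ss)
        x = recording.data - recording.data.mean(axis=0)
        fits = [_fit_univariate_ar(x[:, c], order) for c in range(k)]
        phis = [f[0] for f in fits]
        resid = np.column_stack([f[1] for f in fits])

    f_lo, f_hi = band
    nulls = np.empty((n_resamples, k, k))
    for r in range(n_resamples):
        if method == "phase":
            surr_data = phase_randomize(recording.data, rngs)
        else:
            surr_data = _diagonal_ar_surrogate(phis, resid, n, rng)
        surr = MultichannelRecording(surr_data, recording.sampling_rate, labels)
        res = MVAR(surr, standardize=standardize).fit(order)
        integ = band_integrate(res.dtf(frequencies), f_lo, f_hi)
        nulls[r] = integ.matrix
    thresholds = np.quantile(nulls, level, axis=0)
    np.fill_diagonal(thresholds, 1.0)
    off = ~np.eye(k, dtype=bool)
    max_stat = float(np.quantile(nulls[:, off].max(axis=1), level))
    return SignificanceThresholds(thresholds, level, n_resamples,
                                  list(labels), (f_lo, f_hi),
                                  max_statistic=max_stat)


def epoch_bootstrap_ci(trials, window_length: int, step: int, order: int,
                       band: tuple = (4.0, 60.0), n_resamples: int = 100,
                       ci: float = 0.9, seed: int = 0, frequencies=None):
    """Percentile bootstrap CI for band-integrated SDTF by resampling trials.

    Returns (lower, upper) arrays of shape (n_windows, K, K).  This quantifies
    estimator variability; it is *not* a null for edge existence (resampling
    epochs preserves the coupling).
    """
    trials = list(trials)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB5]))
    stats = []
    for _ in range(n_resamples):
        idx = rng.integers(0, len(trials), size=len(trials))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            tv = sdtf([trials[i] for i in idx], window_length, step, order,
                      frequencies=frequencies)
        stats.append(np.stack([band_integrate(s, *band).matrix
                               for s in tv.spectra]))
    stack = np.stack(stats)
    alpha = (1 - ci) / 2
    return np.quantile(stack, alpha, axis=0), np.quantile(stack, 1 - alpha, axis=0)


def binarize(integrated: IntegratedConnectivity,
             threshold) -> Adjacency:
    """Edges where the integrated value is strictly above its threshold.

    ``threshold`` is a scalar in [0, 1] (the paper-style fixed cutoff) or a
    complete :class:`SignificanceThresholds` table.  The diagonal is always
    absent; ties at the threshold are excluded.
    """
    m = integrated.matrix
    if isinstance(threshold, SignificanceThresholds):
        if threshold.channel_labels != integrated.channel_labels:
            raise ValueError("threshold table does not cover these channels")
        thr = threshold.values
    else:
        thr = float(threshold)
        if not 0 <= thr <= 1:
            raise ValueError("scalar threshold must lie in [0, 1]")
    adj = m > thr
    np.fill_diagonal(adj, False)
    if not integrated.directed:
        adj = adj | adj.T   # asymmetric per-pair thresholds could break symmetry
    return Adjacency(adj, integrated.directed,
                     list(integrated.channel_labels), threshold)
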