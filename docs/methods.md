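# Methods

This note documents the models, estimators, synthetic-data generators,
significance procedures and numerical choices implemented in `dtfnet`, and
what the package's tests do and do not demonstrate about real recordings.

## MVAR model and estimation

All channels are modelled jointly as a stationary multivariate autoregressive
process of order *p*: `x(t) = Σ_m A_m x(t−m) + e(t)` with innovation
covariance `V`. Coefficients are estimated by multichannel ordinary least
squares on the stacked lag regression — unbiased, closed-form, and adequate
at the problem sizes the package targets (tens of channels, thousands of
samples). `V` is the residual covariance with degrees-of-freedom correction
`n_eff − pK`. Coefficient standard errors come from the OLS covariance
`V ⊗ (ZᵀZ)⁻¹`.

Channels are zero-meaned and (by default) scaled to unit variance before
fitting; standardization makes DTF inflow fractions comparable across
channels of different amplitude and can be disabled
(`MVAR(rec, standardize=False)`) when raw coefficients are the target.

Stability is checked after fitting via the companion-matrix spectral radius.
Borderline-unstable *fits* are returned with `is_stable=False` and a warning
rather than an exception, because noisy real fits can legitimately sit at the
boundary; *simulations* from explicitly unstable coefficient sets raise
`StabilityError`.

Order selection minimizes AIC (`log det V_mle + 2pK²/n`; BIC available) over
1..max_order, with all candidates fitted on a common sample span so the
criteria are comparable. A rank-deficient lag regression (e.g. duplicated
channels) raises an error naming the near-duplicated channels.

### Spectral quantities

The transfer matrix is `H(f) = [I − Σ_m A_m e^(−2πi f m / fs)]⁻¹`, evaluated
on a default grid of 0.5 Hz steps from 0 to Nyquist — fine enough that the
conventional analysis bands (0.5–40, 1–45, 4–60 Hz) align exactly with grid
points. The one-sided cross-spectral density is `S(f) = H V H† · 2/fs`
(`1/fs` at 0 and Nyquist) so its diagonal matches a Welch periodogram of a
realization; this equivalence is verified against a 2¹⁷-sample realization at
a mean relative error below 10% in 2–40 Hz (per-frequency comparison is
limited by Welch estimator variance, so the check is on the mean).

## Connectivity estimators

**DTF.** Reported in normalized squared form,
`γ²_ij(f) = |H_ij(f)|²/Σ_m|H_im(f)|²` — the inflow from channel *j* to
channel *i* as a fraction of all inflows to *i* (the self-inflow is part of
the denominator). Rows sum to 1 at every frequency (asserted to 1e−9). Users
comparing against the non-squared DTF convention should square-root
accordingly.

**SDTF.** For repeated trials, one MVAR per sliding-window position is
fitted to the pooled windowed data by accumulating the lag-regression normal
equations across trials, then the DTF of that fit is computed. This is the
standard ensemble short-window practice; at least 10 trials are recommended
(a warning below that) and an under-determined window/trial combination is an
error.

**Coherence.** Magnitude-squared coherence from Hann-tapered Welch
cross-spectra; defaults segment length 256 samples, 50 % overlap (at 128 Hz
this puts the native frequency grid exactly on the default 0.5 Hz grid).
Magnitude-*squared* was chosen and is documented here because the two
conventions are easy to confuse; the spurious-link behaviour is identical.

**Synchronization likelihood.** Each channel is time-delay embedded (default
delay 10 samples, dimension 10 — the conventional setting for alpha-band EEG
at 128 Hz). The per-channel critical distance is the `p_ref` quantile
(default 0.05) of all Theiler-excluded inter-vector distances, so every
channel's recurrence rate is exactly `p_ref`; the Theiler window is
`delay × embedding_dim` samples, excluding autocorrelated neighbour pairs.
For a channel pair, SL = P(simultaneous recurrence)/`p_ref`: 1 for identical
channels, ≈`p_ref` (the chance floor) for independent ones. Distances are
computed in float32; the quantile construction replaces an iterative
critical-distance search with an exact one-shot solution.

**Band integration.** Arithmetic mean of the spectrum over grid points in
the closed interval `[f_lo, f_hi]`.

## Synthetic-data generators

All generators hang off a `SimulationConfig` (defaults: 2560 samples at
128 Hz — a 20 s resting-style epoch — SNR 2, seed 0). SNR is defined as
RMS(source)/RMS(additive noise) per channel. Randomness is split into
independent sub-streams per generator and per channel, keyed by the master
seed, so identical configs give bit-identical output.

**Source surrogate.** An *exact* stable AR(4) with pole pairs at 10 Hz
(modulus 0.95; the alpha rhythm) and 20 Hz (modulus 0.5; broad beta content),
standardized to zero mean and unit variance. The spectral peak falls in
8–13 Hz and power below 3 Hz stays under 5 % — the highpass character of
preprocessed scalp EEG — without any explicit filter. Exact finite AR order
matters: it guarantees that an MVAR of order ≥ 4 represents the process (and
zero-lag mixtures of such processes) without truncation error, which is what
makes the volume-conduction immunity below exact rather than approximate.

**Common source.** Channel 1 is the source plus sensor noise; each of the N
sink channels is the *channel-1 signal* (source including its noise) delayed
by an integer number of samples, plus extra noise from its own stream. It is
the recorded mixture that propagates, so channel 1's past explains every sink
completely and the true directed graph is exactly the N source→sink edges.
Had the clean source been delayed instead, sinks with shorter delays would
carry genuinely earlier source copies than later sinks receive, making
sink→sink Granger influence real — an instructive degenerate case, but not
the scenario the contrast experiment is about. A consequence of the
propagating-mixture construction is that sink variances are `1 + 2σ²` against
the source channel's `1 + σ²`; at the contrast experiment's SNR 4 this is a
6 % spread.

**MVAR networks.** Exact recursion from a user-supplied coefficient tensor
and innovation covariance (Cholesky-factored), with a discarded burn-in of
10 × order × K samples; instability and non-PD covariances are errors. Truth
edges are all ordered pairs with any nonzero cross-coefficient.

**Volume conduction.** Every channel is weight × the *same* source at zero
lag plus an independent background that has the source's own spectral shape,
scaled to the per-channel SNR. Because source and backgrounds share one AR
polynomial, the joint process is exactly a scalar-coefficient VAR whose
zero-lag dependence lives entirely in the innovation covariance: there are no
lagged cross-channel influences for a directed estimator to find, which is
the precise sense in which instantaneous field spread generates "no phase
difference". The spectral-shape assumption is load-bearing and is a
limitation worth knowing: if the additive noise is spectrally distinct from
the source (e.g. white sensor noise under an autocorrelated source), a joint
MVAR fit genuinely improves its prediction of each channel by pooling the
other channels' noisy copies of the source, and off-diagonal DTF becomes
nonzero for a real statistical reason — at 2560 samples we measured
band-integrated off-diagonal DTF of 0.03–0.55 growing with SNR and shrinking
with channel count. Real EEG sits between the two idealizations.

**Modular networks.** Each channel carries its own AR(2) rhythm (10 Hz pole
pair, modulus 0.5, leaving stability headroom); every channel receives lag-1
inflow from 2 randomly chosen members of its own module at gain
intra_gain × U(0.5, 1), and from channels of other modules with probability
0.1 at inter_gain × U(0.5, 1) (defaults intra 0.5, inter 0.02). If unstable,
all couplings are rescaled uniformly — preserving the intra/inter ratio —
until the companion radius drops below 0.95, and the rescaling is logged.
An in-degree-regular intra graph was chosen over all-pairs coupling because
complete intra-coupling forces the stability rescale to crush every gain
(factor ≈ 0.09 for an 8-channel module), leaving no DTF value above any
useful cutoff. The default four-module partition groups the 10-20 montage
into frontal (Fp1, Fp2, Fpz, F3, F4, Fz, F7, F8), central (C3, Cz, C4, Cp5,
Cp6) and two parietal modules (P7, P3, Pz, O1 / P8, P4, O2); Pz is
conventionally listed in both parietal groups, which a partition cannot
represent, so it is assigned to PL by default with a `pz_module` override.

What these generators deliberately do *not* emulate: realistic head-model
forward mixing, artifacts (blinks, muscle), non-stationary drift, and
sub-sample propagation delays. Passing tests therefore demonstrate the
estimators' structural properties (common-source rejection, zero-phase
immunity, modular recovery), not their behaviour under real-world
preprocessing imperfections.

## Edge significance

The null hypothesis for a *directed* edge is "no lagged cross-channel
influence" — not "no dependence at all". The default surrogate null
(`method="diagonal"`) therefore preserves instantaneous covariance while
destroying all lagged coupling: each channel is refitted with its own
univariate AR, residual *rows* are resampled jointly (keeping the
cross-sectional correlation), channels are re-simulated through their own
ARs, and the full MVAR → DTF → band-integration chain is recomputed per
surrogate. Zero-phase volume conduction is part of this null by
construction. Independent per-channel phase randomization
(`method="phase"`), which destroys the zero-lag dependence as well, remains
available for questions where any dependence counts. Surrogate streams are
keyed by sorted channel label, so permuting channels permutes thresholds
exactly.

Thresholds are per ordered pair: the `level` quantile (default 0.9) of the
band-integrated DTF over surrogates (default 200; a warning below 100). For
"is anything significant anywhere" questions the familywise `max_statistic`
— the level-quantile of the per-surrogate maximum over all pairs — controls
the multiple-comparison problem; comparing each of K(K−1) pairs against its
own 90th percentile flags ~10 % of pairs on null data by design. Calibration
is verified: on independent-channel recordings ~10 % of per-pair values
exceed their 0.9-level thresholds over 500 fresh draws. The
volume-conduction immunity check is itself a calibrated test (the
zero-phase-mixed data is a draw from the null), so its per-seed success
probability sits slightly above the nominal level rather than at certainty.

Binarization uses strictly-greater comparison (ties at the cutoff are
excluded) and forces the diagonal absent. The fixed 0.05 cutoff — the
conventional single-threshold reading — is the default for the contrast
experiment; SL uses the same fixed-cutoff path (no SL surrogate null is
defined). An epoch-resampling bootstrap is provided separately for SDTF
confidence intervals; resampling the original epochs preserves the coupling
under test and must not be used as an existence null.

## Network analysis

Node degrees are exact counts on the binarized graph (out/in for directed,
single degree for undirected). `classify_edges` scores an adjacency against
a ground-truth network — direction-sensitive for directed estimators,
against the undirected truth skeleton for bivariate ones — and conserves
`true_detected + missed = |truth|` by construction.

The mixing matrix **E** sums the band-integrated connectivity values strictly
above a cutoff over ordered channel pairs (target module = row, source
module = column, self-pairs excluded), then normalizes the whole matrix to
sum 1. A mean-over-qualifying-pairs variant is available (`agg="mean"`);
the sum matches the "fraction of edges" reading and differs from the mean
only by module-size factors. The modularity experiment derives its cutoff
from the surrogate `max_statistic` by default — the same move as deriving a
fixed cutoff from bootstrap thresholds — because sensible absolute DTF
values scale inversely with channel count. The assortativity report compares
each module's diagonal entry `E_kk` with the mean of its off-diagonal row and
column entries; the global flag requires every module to dominate, and
infinite intra/inter ratios are capped at 1e6 for serializability.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` use the canonical 2560-sample /
128 Hz epoch for pipeline experiments, 10 seeds per stochastic claim, 100–200
surrogates per threshold, 500 fresh draws for calibration, and a 2¹⁷-sample
realization for the spectral oracle — sizes at which every verified property
holds with margin while the whole suite runs in well under a minute. All
randomness flows from explicit seeds through `numpy` `SeedSequence` streams;
experiment bundles embed the config hash in every output file and re-runs are
byte-identical.
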