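# dtfnet

Multivariate versus bivariate connectivity estimation for multichannel neural
time series: the Directed Transfer Function (DTF) against pairwise coherence
and synchronization likelihood (SL), with surrogate-based edge significance
and assortative-mixing network analysis — all driven by synthetic-data
generators with known ground-truth networks.

## The problem

EEG channels are strongly interdependent: a single cortical source recorded
at *N* electrodes induces up to *N(N−1)/2* spurious pairwise associations
among those electrodes even when no direct coupling exists, while only *N*
links are real. Bivariate estimators (coherence, SL, correlation) cannot
distinguish shared input from direct influence, so connectivity graphs built
from them are dense and close to random. Multivariate estimators fitted
jointly to all channels can.

The package is for researchers studying effective (directed) connectivity in
multichannel electrophysiology who want a tested, reproducible implementation
of this comparison.

## The model

All channels are modelled jointly as a multivariate autoregressive (MVAR)
process

```
x(t) = Σ_{m=1..p} A_m x(t−m) + e(t),    Cov[e] = V,
```

whose frequency-domain transfer matrix is
`H(f) = [I − Σ_m A_m e^(−2πi f m / fs)]^(−1)`. The normalized squared DTF

```
γ²_ij(f) = |H_ij(f)|² / Σ_m |H_im(f)|²  ∈ [0, 1]
```

is the inflow from channel *j* to channel *i* as a fraction of all inflows to
*i*; rows sum to 1 at every frequency. Band-integrated DTF values are
thresholded (fixed cutoff or surrogate null quantiles) into directed graphs,
summarized by node in/out degrees, scored against ground truth, and
aggregated into the module-by-module assortative-mixing matrix **E**
(normalized so Σ_kl E_kl = 1); diagonal dominance of **E** indicates modular
organization. A short-time variant (SDTF) pools repeated trials in sliding
windows for time-varying connectivity.

## Worked example

```python
from dtfnet import (MVAR, SimulationConfig, band_integrate, binarize,
                    classify_edges, coherence, simulate_common_source)

cfg = SimulationConfig(n_samples=2560, sampling_rate=128.0, snr=4.0, seed=1)
rec, truth = simulate_common_source(5, [1, 2, 3, 4, 5], cfg)

results = MVAR(rec).fit(order=7)
dtf_adj = binarize(band_integrate(results.dtf(), 4, 60), 0.05)
coh_adj = binarize(band_integrate(coherence(rec), 4, 60), 0.05)

for name, adj, directed in [("DTF", dtf_adj, True), ("COH", coh_adj, False)]:
    cls = classify_edges(adj, truth, respect_direction=directed)
    print(name, "true:", cls.n_true_detected, "false:", cls.n_false_positives)
```

prints

```
DTF true: 5 false: 0
COH true: 5 false: 10
```

One alpha-peaked source feeds five sink channels with sample delays; the
jointly fitted DTF recovers exactly the 5 true source→sink edges, while
pairwise coherence additionally reports all 10 sink–sink pairs — precisely
the N(N−1)/2 spurious links predicted for N = 5. The same pipeline is
available from the shell:

```
dtfnet contrast --seed 1 --out results/contrast
dtfnet modularity --seed 1 --out results/modularity
```

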