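# flyolf

Information transmission in the *Drosophila* olfactory circuit: a stochastic
binary-network model of odor → antennal lobe → mushroom body signalling with
activity-dependent feedback inhibition, and the mutual-information machinery
used to ask how well Kenyon-cell population states identify odors.

It is written for computational neuroscientists who want to study — or
stress-test — how connectivity rate, firing threshold, odor concentration and
inhibition strength shape the efficiency of a sparse sensory code, using a
model small enough to sweep exhaustively on a laptop.

## The model

An *odor* k is a subset of the 50 antennal-lobe glomeruli (one olfactory
projection neuron, OPN, per glomerulus) plus a concentration c ∈ (0, 1]. The
number of reachable OPNs per odor is drawn once from round(𝒩(μ=35, σ²=8)),
clamped to [1, 50]. On every trial each reached OPN j fires independently,

    p_OPN = 1 − exp(−β·c),        β = 1.32,

giving a binary antennal-lobe state χ. A fly is a binary connectome C drawn
entrywise Bernoulli(r); Kenyon cell i fires iff its summed input strictly
exceeds its threshold:

    ψ_i = 1  iff  Σ_j C_ij χ_j > Θ,        Θ ∈ {1, …, 20}.

Optional feedback inhibition deletes each KC spike independently with
probability

    p_I = exp(−α·χ̃),

where χ̃ is the pre-inhibition mushroom-body activity of the trial (by
default the active *fraction* of KCs; a raw-count convention is available via
`inhibition_activity="count"`). Larger α means weaker inhibition.

Transmission efficiency is the mutual information between odor identity and
the 2^N_KC-state KC response,

    MI = Σ_n Σ_k p(n,k) log₂ p(n,k) / (p(n) p(k)),

estimated from 100 trials per odor and bias-corrected by quadratic
extrapolation: the plug-in MI is recomputed on disjoint halves and quarters
of the trials, MI(N) = MI_∞ + a/N + b/N² is solved exactly, and MI_∞ is
reported. Experiments average MI over 20 independent fly replicates.

## Worked example

```python
from flyolf import ExperimentConfig, sweep, argmax_threshold, mean_over_thresholds

cfg = ExperimentConfig(
    concentration=0.75, r=0.3, theta=tuple(range(1, 21)),
    alpha=(None, 0.1, 0.4, 0.7, 0.9, 1.3, 1.7), seed=1,
)
result = sweep(cfg)
print(argmax_threshold(result, fixed={"alpha": None}))
print(mean_over_thresholds(result))
```

prints (formatted):

```
best threshold without inhibition: 6
alpha= 0.1: theta-averaged MI = 0.062 bits
alpha= 0.4: theta-averaged MI = 0.279 bits
alpha= 0.7: theta-averaged MI = 0.431 bits
alpha= 0.9: theta-averaged MI = 0.454 bits
alpha= 1.3: theta-averaged MI = 0.414 bits
alpha= 1.7: theta-averaged MI = 0.356 bits
alpha=none: theta-averaged MI = 0.352 bits
```

Reading: at high odor concentration (c = 0.75) and the fly-like connectivity
rate r = 0.3, the feed-forward circuit alone transmits ≈ 0.35 bits of the
log₂ 5 ≈ 2.32 bits available about which of the five odors was presented,
and the best firing threshold sits just above the mean synaptic input per
Kenyon cell (≈ 6.6 active inputs). Moderate feedback inhibition (α = 0.9)
raises the threshold-averaged MI by ≈ 30 %, very strong inhibition (α = 0.1,
which deletes > 90 % of spikes) destroys the code, and very weak inhibition
(α = 1.7) converges back to the uninhibited circuit — the inverted-U in α is
the model's central prediction about GABAergic gain control.

A command-line interface mirrors the library: `flyolf sweep`,
`flyolf figure4` … `flyolf figure8` (the standard protocols, written as tidy
CSV plus heatmaps), `flyolf panel`, and `flyolf selftest`. All commands take
`--seed`, `--out-dir`, `--jobs` and a YAML config file; one master seed fixes
panels, connectomes, trial noise and subsampling partitions bit-for-bit,
independent of worker count.

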