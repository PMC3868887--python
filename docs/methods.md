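# Methods

## Model overview and assumptions

The package models olfactory information transmission as a two-stage
stochastic binary channel. The antenna and antennal lobe are collapsed into
a single input layer of 50 binary OPNs (one per glomerulus), because ORNs of
one receptor class converge onto one glomerulus; receptor-level detail,
odor chemistry, mixtures and temporal dynamics are out of scope. The
mushroom body is a population of N_KC binary threshold units (default 10;
20 supported) read out once per trial — there is no membrane dynamics,
spike timing or plasticity. Lateral-horn and mushroom-body inhibition are
lumped into a single probabilistic spike-deletion stage.

## Synthetic environment

`environment.draw_odor_panel` generates the study conditions; there are no
empirical inputs. Each odor is (i) a reachable OPN subset, drawn uniformly
without replacement, of size round(𝒩(35, √8)) clamped to [1, n_glomeruli]
— σ² = 8 is a variance, so the sd is √8 ≈ 2.83; clamping at the defaults is
astronomically rare and exists only to keep every odor detectable — and
(ii) a concentration shared by the whole panel, because each experiment
presents "odors of the same concentration". Panels default to 5 odors (the
figure-level condition); panel size is configurable, and 100-odor panels
were checked to leave the threshold read-outs unchanged.

What the generator does **not** emulate: correlated glomerular tuning
(real odors do not recruit glomeruli uniformly at random), concentration-
dependent recruitment of additional glomeruli, and trial-to-trial
correlations. Passing tests therefore show the estimator and circuit
behave correctly under the model's idealized statistics, not that the model
fits recorded fly data.

## Circuit conventions

- OPN activation: `p = 1 − exp(−β c)` per reached OPN per trial,
  independent across OPNs and trials; β = 1.32.
- Connectome: entrywise Bernoulli(r), drawn once per fly and reused across
  all odors, trials, thresholds and α values of that fly's experiment.
- KC thresholding is strict (`input > Θ`); a cell at exactly Θ stays
  silent. `kc_response` is pure (consumes no random stream).
- Inhibition is a single simultaneous pass: the deletion probability
  `p_I = exp(−α χ̃)` is computed from the pre-inhibition state, then each
  spike is deleted independently; there is no iteration to a fixed point.

### The activity convention in p_I

"Average mushroom-body activity" admits two readings: the raw count of
active KCs or the active fraction (mean activity per cell). The circuit
functions take χ̃ as the caller provides it (count by default, with a
`fraction` switch); the experiment layer defaults to **fraction**. This is
a deliberate design choice: with the fraction convention α is a per-cell
gain that is comparable across KC population sizes, and the θ-averaged MI
at high concentration shows the expected inverted-U in α with an interior
optimum (α ≈ 0.9 on the tested grid) and a benefit over the uninhibited
circuit at moderate strengths. Under the count convention, inhibition is
effectively off whenever more than a few cells fire (e^(−αχ̃) ≈ 0), the
inverted-U disappears, and the strongest tested inhibition (α = 0.1) is
the only value that changes the code appreciably. Both conventions remain
available via `inhibition_activity`.

## Mutual-information estimation

- Plug-in MI uses the empirical joint over (odor, encoded KC state) with
  equiprobable odors; log base 2 (bits) by default so the log₂K ceiling is
  interpretable, natural log via `log_base`. Terms with p(n,k) = 0
  contribute 0; the conventional substitution p(n) = 10⁻⁸ for never-
  observed states is applied literally and is numerically inert under that
  convention.
- States are stored sparsely (observed codes only); this is exact, since
  unobserved states contribute nothing.
- Quadratic extrapolation: trials are permuted once per estimate (from the
  provided stream), stratified per odor so every subsample keeps the odors
  equiprobable; MI is computed on the full data, the 2 disjoint halves
  (averaged) and the 4 disjoint quarters (averaged); the three points solve
  MI(N) = MI_∞ + a/N + b/N² exactly (`extrapolate_quadratic`). N must be
  ≥ 8 and divisible by 4.
- A negative MI_∞ (possible at very low N or near-zero information) is an
  extrapolation artifact and is floored at 0. The floor is logged at
  WARNING once per process and at DEBUG thereafter, because near-zero MI
  cells occur routinely in large sweeps.
- Known limitation: with 2^10 states and 100 trials per odor the channel is
  deeply undersampled at low thresholds; the 1/N expansion then removes
  only part of the positive bias (verified in the zero-information test).
  Conclusions should rest on comparisons across parameters estimated the
  same way, not on absolute bit values in that regime.

## Experimental protocol and randomness

Default study conditions: 10 KCs, 5 odors, 100 trials per odor, 20 fly
replicates, β = 1.32, Θ grid 1–20, fly-like r = 0.3 for cross-sections,
r grid 0.05–0.95 (step 0.05) for surfaces, α grid {0.1, 0.4, 0.7, 0.9,
1.3, 1.7} (endpoints 0.05/1.75 available), concentrations 0.15 (low) and
0.75 (high), concentration grid {0.05 … 0.90} for concentration curves.
"Averaged over thresholds" is the unweighted mean over Θ = 1..20. Each fly
gets its own odor panel by default, so replicate averages marginalize over
both connectome and odor-structure variability (`shared_panel=True` gives
all flies one panel).

Every random consumer derives its generator from a SeedSequence whose
entropy is (master_seed, r_index, c_index, fly_index) plus a fixed
spawn-key tag — (1,) connectome, (2,) trial noise, (3, t, a) inhibition,
(4, t, a) extrapolation partition for the t-th threshold and a-th α.
Panels use (master_seed, 161, c_index[, fly_index]). Consequently a sweep
is bit-for-bit reproducible and independent of `--jobs`. Trial noise is
shared across thresholds and α values within a fly — the same presentations
read out at different parameter settings — which reduces comparison
variance without coupling the estimates' subsampling partitions.

Ties in the argmax read-outs are broken toward the smaller parameter value
and logged; both read-outs of the MI surface are provided
(`argmax_threshold` at fixed r, `argmax_connectivity` at fixed Θ).

## Problem sizes used in the test suite

The acceptance-level checks run the full study conditions (20 flies, 100
trials, 20 master seeds; ~1 minute total). The structural checks use
deliberately reduced grids — the Θ*-vs-r trend uses a 0.1-step r grid over
3 master seeds, and the 10-vs-20-KC surface comparison a 5-point r grid
with 10 flies — chosen as the smallest designs at which the one-sided
tests at α = 0.01 are decisively powered.

## Observed deviations from the reference description

Three figure-level claims do not emerge from the equations as printed, and
the corresponding checks are left failing rather than tuned:

1. At c = 0.15, r = 0.3 the mean synaptic input per KC is
   r·N_reach·p ≈ 0.3·35·0.18 ≈ 1.9 spikes, so corrected MI decreases
   monotonically in Θ (optimum Θ = 1, MI ≈ 0 for Θ ≥ 7), not Θ = 7.
2. At c = 0.75 the optimum is Θ = 6 (mean input ≈ 6.6), not 8. No single β
   can place the optima at 7 and 8 simultaneously: a one-step shift between
   the two concentrations requires near-saturated activation at both,
   i.e. β ≈ 10, incompatible with β = 1.32.
3. θ-averaged MI at r = 0.3 is *higher* at c = 0.75 (≈ 0.37 bits) than at
   c = 0.15 (≈ 0.14 bits): the stronger activation contrast between
   reachable and unreachable OPNs outweighs the larger per-OPN trial
   noise, so the model as specified does not show the reported
   high-concentration degradation without inhibition.

The inhibition results (interior optimum at α = 0.9; moderate inhibition
beating the uninhibited circuit at high concentration) do reproduce under
the fraction convention described above.
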