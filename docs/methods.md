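# Methods

This note documents the models and procedures implemented in `sleepdyn`,
the defaults and why they were chosen, the numerical conventions, and the
limits of what the synthetic-data tests can show.

## Population trajectories and recurrence quantification

Spike trains are binned into non-overlapping, half-open windows
`[start, start + Δ)` (Δ = 50 ms by default; a trailing partial bin is
dropped). The T×N count matrix is treated as a trajectory in N-dimensional
phase space. The recurrence plot marks pairs of bins whose count vectors
lie within a tolerance ε of each other (Euclidean norm by default,
Chebyshev available); the comparison is inclusive (`≤ ε`) so that ε = 0
meaningfully marks exact repeats of a firing pattern.

**Tolerance.** ε is one standard deviation (across time, ddof = 0) of the
neuron-summed firing count over all wakefulness bins of the session; each
Wake epoch is binned separately so no bin straddles a state boundary. For
simulator output, where there is no hypnogram, the non-silenced baseline
run plays the role of wakefulness. A multiplier (0–4 SD) supports
robustness sweeps.

**Metrics.** RR is the density of the full matrix (identity included).
Diagonal statistics exclude the identity line from numerator and
denominator — a Theiler window of one — both for DET and for the L_max
used in DIV = 1/L_max; when only isolated points remain, L_max is defined
as 1 and DIV = 1. Vertical statistics (LAM, TT) keep all columns,
including runs through the identity, because a vertical structure through
the main diagonal is genuine trapping. Minimum line lengths are
l_min = v_min = 2, the standard RQA convention. TT with no qualifying
vertical line is defined as 0 to avoid 0/0. A consequence of the Theiler
exclusion worth noting: a fully recurrent T×T plot has DET slightly below
1 (the two off-identity corner diagonals have length 1).

The line-histogram implementation is validated against an independent
brute-force line-enumeration oracle, exactly, on random symmetric
matrices.

**Windowing.** Windowed RQA splits a trajectory into non-overlapping 10 s
windows (T = 200 at 50 ms) and computes the metrics per window; state
comparisons average windows within a session and state.

## DOWN/OFF states

Two rules reflect the two recorded regions. The neocortical rule finds
maximal gaps of the merged population spike train lasting 50–1250 ms (OFF
periods); ON periods are the inter-OFF segments with ≥10 merged spikes and
200–4000 ms duration. The hippocampal rule marks a 50 ms bin as DOWN when
strictly fewer than 10% of neurons fired in it (hippocampal populations
keep residual firing during DOWN states).

Rasterizing OFF intervals onto bins uses a majority rule (a bin is DOWN
iff ≥50% of its width is covered) for the DOWN-vs-recurrence correlation,
where a symmetric assignment is wanted. UP-only trajectories instead keep
only bins fully inside detected **ON** periods: selecting the complement
of OFF would retain silent stretches that fall outside the OFF duration
bounds (for example a silence slightly longer than 1250 ms), and any
partial silence in a boundary bin contaminates the UP-only signal. The
UP-only trajectory concatenates the surviving bins; downstream windows may
therefore span removed time, which is the intended trade-off (re-windowing
within segments would discard most short UP periods).

The DOWN/recurrence association uses the point-biserial correlation
between the binary DOWN series and the per-bin recurrence count (the
column sums of the recurrence matrix), computed on the SWS-restricted
50 ms series.

## Synthetic local field potentials and spectra

Each spike is assumed to generate an exponentially decaying postsynaptic
potential. Binned counts of every excitatory neuron are convolved with a
causal kernel `exp(−t/τ)` (τ = 24 ms, a typical mEPSP time-scale for
frontal-cortex pyramidal cells; unit peak; truncated at 10 τ, beyond which
the kernel is below 5·10⁻⁵) and averaged across neurons. The default bin
width is 8 ms, i.e. a 125 Hz sampling rate: this is the rate needed for
Welch spectra with 1 s Hann segments (1 Hz resolution, no overlap) and for
coherence against down-sampled field recordings; an 80 ms bin is available
through the same argument for coarse-grained variants. Spectral decay
exponents α come from an ordinary least-squares fit of log10 PSD on
log10 f over a caller-chosen band.

## Complexity measures

Permutation entropy: ordinal patterns of order D = 3 at embedding delay
τ = 5 samples, sliding windows by default (a non-overlapping mode exists);
ties are ranked by order of appearance, which matters for count-valued
signals. Natural-log Shannon entropy of the pattern distribution, bounded
by ln 3! and attaining it for iid input.

Sample entropy: signals are decimated by 5 (matching the PE delay), then
SE = −ln(A/B) with A and B the counts of template pairs of length m+1 and
m (m = 3) whose Chebyshev distance is strictly below r = 0.1·SD.
Self-matches are excluded and both template sets share the same start
indices, so a constant signal gives A = B and SE = 0 exactly; when the
tolerance degenerates to r = 0 matching falls back to exact equality.
When no pair matches, NaN is returned rather than an arbitrary cap.

Lempel-Ziv: the signal is binarized at its mean ("greater than" — a
constant signal becomes all zeros), parsed by the exhaustive LZ-76
procedure, and the phrase count c is normalized as `c/(w/log2 w)`, which
approaches 1 for a fair-coin sequence. Log bases (natural for PE/SE,
base-2 for LZ) only rescale values and never affect comparisons.

All three measures are invariant to affine rescaling of the input.

## Avalanches and crackling noise

The merged population train is binned at its average inter-spike interval
(computed per session and state; a fixed width can be supplied). An
avalanche is a maximal run of occupied bins delimited by empty bins; runs
touching the recording edges are discarded as undelimited. Sizes (total
spikes) and durations (bins) are fitted with a discrete power law by
maximum likelihood, `P(x) ∝ x^−a / ζ(a, xmin)`, with the Hurwitz-zeta
normalization evaluated exactly; `xmin` is chosen by minimizing the
Kolmogorov–Smirnov distance over candidate values leaving at least 50 tail
observations. Exponent uncertainty is a percentile bootstrap at fixed
xmin (500 resamples by default). The scaling exponent 1/(σνz) is the OLS
slope of log10 mean size against log10 duration over all duration
classes, and the crackling-noise check compares it with
(τ_t − 1)/(τ − 1) under joint bootstrap confidence intervals.

The exponent-recovery tests draw from the exact discrete distribution by
inverse-CDF sampling (bulk by table, far tail by bisection on the
Hurwitz-zeta CCDF).

## Critical branching model

Fifty units, each resting, firing, or refractory (exactly one step), on
an undirected Erdős–Rényi graph with attachment probability 0.03. At each
1 ms step a resting unit fires if any neighbour that fired on the
previous step succeeds in an independent Bernoulli attempt with
`P_prop = σ/⟨k⟩` (⟨k⟩ the realized mean degree; clamped at 1 with a
warning when σ > ⟨k⟩), or if its Poisson drive spikes
(probability 1 − e^−λ, λ = 0.014/step). DOWN states are induced by
periodically suppressing the *noise drive only* of a fixed random subset
of units — propagation is untouched — for 250 ms out of every 500 ms by
default. The stated "4 Hz" silencing cadence is internally inconsistent
with a 250 ms silence (a 4 Hz cycle *is* 250 ms), so the default is an
equal-duty delta-band alternation; both the duration and the period are
configurable.

The phase transition behaves as advertised: with the noise off and a
single seeded spike, σ = 0.5 cascades die within a few steps in every
run, σ = 1 is marginal, and σ = 1.8 survives essentially always.
Single-seed cascades at σ = 1 provide the avalanche ensemble for the
crackling-noise check (the small-noise limit in which avalanches are
isolated events); cascades still alive after the step cap are censored
and discarded, which truncates the extreme tail — the self-consistency
check is between exponents fitted to the same censored ensemble.

**Known limitation — driven stationary state at σ = 1.** With the noise
drive at λ = 0.014 per step, the critical network does not remain in a
sparse noise-dominated regime: the critical response to a drive of this
strength is large, and degree heterogeneity of the sparse graph
(⟨k⟩ ≈ 1.5 with a per-link probability of ≈ 0.68) makes the connected
cluster locally supercritical, so the driven system settles into an
elevated self-sustained state (~13 spikes/ms across the population).
Recurrence metrics of that state are high (RR ≈ 0.9, DET/LAM ≈ 0.99) and
periodic noise silencing barely perturbs it, since propagation alone
sustains the activity. This behaviour is intrinsic to the stated update
rules and parameters — it persists under directed links, per-source or
per-target degree normalization, longer refractory periods, and weaker
noise — and should be kept in mind when comparing the simulator's driven
statistics against sparse-regime expectations. The phase-transition and
avalanche properties above are unaffected (they are probed at λ = 0).

## Synthetic sessions

A session has 50 units with lognormal rates (median 2 Hz, shape 1.0 —
the field-standard log-dynamic rate distribution), of which 20% are
fast-spiking putatively inhibitory units at 4× rates (present in the
emulated recordings; excluded from the sLFP). Wake and REM epochs are
independent Poisson processes. SWS alternates UP periods
(uniform 200–4000 ms) with DOWN periods (uniform 50–1250 ms), starting
with UP and truncating at epoch boundaries; a lognormal duration variant
is available. During DOWN, firing is zero (neocortex-like) or confined to
10% of units at 10% rate (hippocampus-like). UP-state rates equal Wake
rates — as in the recorded data, where UP-state trajectories resemble
wakefulness — so the SWS state-mean rate is lower than Wake by the UP
occupancy fraction; a variant that rescales UP rates to match the state
mean exists for sensitivity analyses. The exact DOWN intervals are
returned as ground truth. Identical spec and seed give byte-identical
output.

What the generator does **not** emulate: slow rate covariations and
correlated excitability fluctuations during Wake/REM (its Wake is exactly
Poisson), theta/ripple oscillations, refractoriness, and non-Poisson ISI
statistics. Consequences observed in testing: the SWS > Wake recurrence
ordering, while robust over moderate tolerances (0.5–1.5 SD) and bin
widths (20–100 ms), flattens at extreme tolerances (≥2 SD) where the
Poisson Wake plot saturates toward RR = 1 — real recordings, with their
larger Wake variability, need not behave this way. Passing tests on this
generator therefore establish the correctness and directionality of the
pipeline, not quantitative agreement with any in-vivo value.

## Statistics

State comparisons pool per-session means (windows within a session are
averaged first), run a Friedman omnibus over the paired per-session
values, and follow up with pairwise Wilcoxon signed-rank tests under
Benjamini–Hochberg correction at α = 0.05; Cohen's d (pooled-SD,
ddof = 1) is reported alongside, with |d| > 0.8 read as a large effect.
Confidence intervals are percentile bootstraps. Cohort sizes in the tests
are ≥ 6 because the discrete signed-rank null cannot reach p < 0.05 after
BH correction below that.

## Problem sizes used in the test suite

The suite exercises the chain at sizes chosen for statistical adequacy:
cohorts of 6–8 sessions with 5–6 minutes per state for directional
statistics; 10⁵ draws for exponent recovery (±0.05); 100 random matrices
for the RQA oracle; 100 seeded runs per phase for the transition check;
3×10⁵-step realizations for model recurrence in the suite, with the
acceptance script running the full 10×10⁶-step protocol.
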