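# Methods

`scism` extracts a discrete state description — states, steady-state
network, escape kinetics, and an effective free-energy landscape — from a
noisy one-dimensional single-molecule time series such as a FRET
efficiency trajectory. This note records the model, the numerical
choices, and the limits of what the bundled simulations demonstrate.

## Segments as local distributions

The trajectory is cut into consecutive, non-overlapping windows of `L`
points (default 33 bins of 3 ms, i.e. 99 ms per segment). Each segment
g_i is treated as an empirical distribution of the observable rather than
a single summary value: the local distribution shape is what
distinguishes states that project to similar means (the degeneracy
problem of 1-D observables). The premise is local equilibrium — within
one segment the molecule stays in one underlying state — so the segment
length must sit well below the state dwell times while holding enough
points to beat sampling noise. Windows containing invalid bins (too few
photons) are dropped whole; the segment prior p(g_i) is uniform.

Dissimilarity between segments is the Kantorovich (Wasserstein-1)
distance, the area between the two empirical CDFs. It is computed exactly
on the merged support — no observable-axis binning — and, for the
all-pairs matrix where every segment has the same L, via the equivalent
quantile form mean|sorted_a − sorted_b|. A classical-MDS embedding of the
distance matrix is available as a diagnostic plot; it plays no role in
any decision.

## Rate-distortion soft clustering

Segments are compressed into states S_1..S_K by minimizing

    F = I(S; g) + β ⟨d⟩,

where I is the mutual information between states and segments (the
description cost, reported in bits) and

    ⟨d⟩ = Σ_k p(S_k) Σ_{ij} p(g_i|S_k) p(g_j|S_k) d_ij

is the mean within-state pairwise distance (the distortion). The
stationary point of F over row-stochastic assignments p(S_k|g_i) is the
Boltzmann form

    p(S_k|g_i) ∝ p(S_k) exp(−β d_eff(g_i, S_k)),
    d_eff(g_i,S_k) = 2 Σ_j p(g_j|S_k) d_ij − Σ_{jl} p(g_j|S_k) p(g_l|S_k) d_jl,

iterated alternately with the marginal update p(S_k) = Σ_i p(g_i)
p(S_k|g_i) (Blahut-Arimoto-style alternation). The d_eff form is the
exact gradient of F with respect to the assignments; the test suite
verifies this against central finite differences to 1e-6. Internally the
information term is kept in nats so the exponential update is exactly
stationary; mutual information is converted to bits for reporting.

Numerics: exponentials are evaluated in log space with per-row max
subtraction, so arbitrarily large β cannot underflow the normalization.
The functional is evaluated once per iteration from the same K×N product
that drives the update. Convergence is |ΔF| ≤ 1e-8·|F| (relative), at
most 1000 iterations. The functional is non-increasing under the
alternation; an increase beyond 1e-9 relative terminates that restart and
flags it, which in practice never triggers on the tested data. The
assignment is randomly initialized and the best of several restarts wins
(defaults: 20 for direct calls; 8 initial plus warm start and 2 fresh
restarts per annealing step inside the model-selection sweep).

States with marginal below 1e-10 are frozen out. Two states are treated
as duplicates when their membership distributions p(g|S_k) coincide
(conditional columns proportional, relative sup-distance below 0.05):
exact duplication leaves both I and ⟨d⟩ invariant, so the optimizer
frequently parks surplus states on copies of a real state, and the
*effective* state count — distinct membership patterns — is the
scientifically meaningful number reported everywhere. Empirically
duplicates sit at relative distance ≤ 5e-3 and genuinely distinct states
at ≈ 1, so the 0.05 threshold is not delicate.

## Error model and distortion cutoff

Measurement error and finite sampling both blur segment distributions. A
bootstrap realization of a segment resamples its L points with
replacement and perturbs each draw by a Gaussian with that point's error
SD (for FRET, the shot-noise SD sqrt(E(1−E)/n) unless the user supplies
an error column); FRET realizations are clipped to [0, 1]. Distances
between independent realizations of the *same* segment pool into the
self-distortion distribution — the distortion that error alone produces.
Its 95th percentile (configurable) is the distortion cutoff: a model
whose distortion falls within this range has reached the minimum
achievable distortion, and further states would fit noise.

The pool grows in batches of 100 realizations per segment until a
two-sample Kolmogorov-Smirnov test (α = 0.05) finds the pooled
distribution unchanged by the newest batch (cap 5000). Candidate-model
distortion distributions come from bootstrap distance matrices — one
all-pairs matrix per joint realization of every segment (default 50,
stored float32) — evaluated with the candidate's assignment held fixed,
so both sides of the cutoff comparison carry the same error inflation.

## Model selection

For each K = 1..N_max (default 10), β is annealed geometrically from
β_min = 0.01/⟨d⟩₁ (scaled by the one-state distortion, hence unit-free)
with ratio 1.5, warm-starting each step, until either the candidate
passes the cutoff (median of its bootstrap ⟨d⟩ samples ≤ cutoff; "all"
and "fraction" rules available) or the ⟨d⟩ distribution stops changing
between consecutive β values by the K-S test. Because the bootstrap
matrices are fixed along the anneal, consecutive distributions are also
indistinguishable *before* the anneal takes off; the stagnation stop is
therefore armed only after at least one comparison has detected a change.
A single state is β-independent and is evaluated once.

Among all passing candidates the one with the smallest I(S; g) is
selected — the simplest description consistent with the data to within
the noise — with ties broken toward fewer effective states. The K loop
stops early once a passing model exists and two consecutive K values
fail to improve the best passing I. If nothing passes, the candidate
with the smallest median distortion is returned flagged "no adequate
model".

## Kinetics and the landscape

The most probable sequence (per-segment argmax, ties to the lowest
index) provides the reported network: transition counts N_ij over
temporally adjacent segment pairs only (never across trajectory
boundaries), with self-pairs counted. Escape times are means of complete
residence runs (runs touching a trajectory boundary are censored and
excluded) times the segment duration τ_seg; their 95% CIs are percentile
intervals over sequence realizations drawn independently per segment
from p(S_k|g_i). Survival curves get a χ² test against the
maximum-likelihood single exponential (rate = 1/mean residence) on
equal-probability bins with expected counts ≥ 5 and df = bins − 2.
Detailed balance is tested per state pair by an exact two-sided binomial
test of N_ij against N_ij + N_ji at p₀ = ½, Bonferroni-corrected.

State free energies follow from occupancies, F_i = −k_B T ln(N_i/N) with
N = Σ N_ij total transition observations, zeroed at the most populous
state (T defaults to 298 K). Barriers follow from Kramers' relation with
pre-exponential timescale τ₀ = 1 μs: eliminating F_i gives
F_IJ = −k_B T ln((τ₀/τ_seg)·N_cut/N), where N_cut is the symmetrized
transition flow across the minimum cut separating the two sets of
states. All pairwise min-cuts come from the Gomory-Hu tree of the
symmetrized count network; the disconnectivity tree merges states from
the lowest barrier upward (single linkage — the min-cut values form an
ultrametric, which the tests assert on all triples). Symmetrization
(C_ij = (N_ij+N_ji)/2, kept fractional) is only meaningful under
detailed balance, so the test above is run and logged first.

The per-state observable distribution exposed by the pipeline pools the
member values of segments whose most probable state is k, weighted by
the assignment confidence p(S_k|g_i); ambiguous segments (e.g. windows
straddling a transition) are thereby downweighted. A fully soft variant
(every segment weighted by its conditional) is available.

## Scalability

Above `max_train_segments` (default 1500) the distance matrix, error
bootstrap and sweep run on a uniformly spaced subset of segments; the
selected model then assigns *every* segment through the same Boltzmann
rule, using its distances to the training segments and the fitted
cluster memberships. Kinetics and the landscape always use the full
sequence. This keeps the expensive O(N²) stages bounded while the final
state description covers all data.

## What the simulators emulate — and what they do not

The Langevin generator integrates overdamped diffusion on a sum of five
Gaussian wells (equal depths 4 k_B T, width 0.035, centers equally
spaced on [0, 1]) by Euler-Maruyama at dt = 1e-5, observing every 3 ms
with additive noise (Gaussian by default; Student-t and uniform
families available). SNR is defined as well spacing over noise SD
(default SD 0.025 → SNR 8). Friction defaults to 10 so the mean well
escape time (~1.2 s) comfortably exceeds the segment length, matching
the separation of time scales the segmentation assumes; friction leaves
the Boltzmann occupancies untouched. True labels are by nearest well
center, which mislabels brief barrier excursions — a documented
approximation, not a committor.

The photon generator runs a Gillespie simulation of a continuous-time
Markov chain (default 3 states, apparent FRET levels 0.3/0.55/0.8,
exit rate 2 /s), emits photons as a Poisson process at 3.3e4 /s within
each dwell, routes each photon to the acceptor channel with probability
E, applies donor→acceptor crosstalk (5%) and adds 300 background
photons/s per channel. Neither simulator includes detector dead time,
afterpulsing, photobleaching or triplet blinking, and observation noise
is white — passing tests say nothing about colored noise or drift in
real measurements.

With exit rate 2 /s and τ_seg = 99 ms, about 18% of segments straddle a
state transition. Two consequences are visible in the validation runs
and are properties of the method at this time-scale ratio, not bugs:
(i) mean-of-runs escape times are biased upward by the segment
granularity (≈ τ_seg/(1−exp(−kτ_seg)) ≈ 0.55 s for a true 0.5 s dwell)
while realization-resampled CIs are biased slightly downward by run
breakage, so true escape times are recovered only to roughly one
segment of resolution; (ii) at large data volumes the minimal-I
adequate model may carry an extra, ~1%-population state collecting
transition-straddling segments; (iii) segments straddling a low↔high
jump have mixture pmfs that sit near the middle state in Wasserstein
geometry, so the middle state's recovered distribution carries a few
percent of foreign mass (its truth overlap lands around 92–95% across
seeds, against ~97% for the outer states). Slower dynamics (or shorter
segments) shrink all three effects.

## Problem sizes used in the shipped runs

The acceptance script runs the Langevin study at 2e5 observation points
(20 trajectories × 1e4 points) and the photon study at 20 traces × 60 s
(≈ 4e7 photons). The test suite exercises the same pipelines at 1e5
Langevin points and 10 photon traces × 30 s, and the overfitting-guard
suite at 30 segments × 100 seeds, sizes chosen to keep a full run on a
single CPU within minutes while leaving every stage (including the
training-subset cap) active.
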