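# Methods

## Parsing spikes into a symbol sequence

The bin width Δ is the mean inter-spike interval of the pooled ensemble
(all spikes of all cells, sorted; simultaneous spikes contribute zero
intervals, which stay in the mean).  The bin grid is anchored at the first
spike — the anchor is arbitrary in principle, and fixing it to the data
makes parsing deterministic; recording edges count as flanking silence so no
edge avalanche is discarded.  An avalanche is a maximal run of occupied
bins; its size is its spike count.

Within an avalanche, one neuron's spikes with successive gaps below
maxISI = 50 ms form a single burst stamped with its first spike time.
Bursts never chain across avalanche boundaries.  Bursts across neurons are
ordered by onset; exact ties (possible with discretized timestamps) break by
ascending neuron id, which keeps the output independent of input file
order.  Words are concatenated with one `0` per empty bin.

The null for the heavy-tail tests permutes each neuron's ISI multiset
independently (train rebuilt from zero), preserving rate and burstiness and
destroying cross-neuron correlations.  The large-avalanche threshold is the
last integer whose pooled-null CDF is strictly below 0.99; because the
distribution is discrete, the realized tail probability p0 = 1 − q is
slightly above 0.01 and is the one used in the binomial test.  The test is
upper-tailed, P[X ≥ k], since the question is an *excess* of large
avalanches.  On uncorrelated Poisson ensembles the test rejects at
α = 0.01 at roughly the nominal rate (measured ≈ 2 % over 50–100
simulations).

## VLMC fitting

The probabilistic suffix tree keeps a context σ of length k (1 ≤ k ≤ d) if

1. its occurrence frequency is at least P_min = 0.006,
2. some next symbol has P̂(s|σ) ≥ γ = 0.001, and
3. that symbol's probability differs from the one-symbol-shorter suffix's by
   a factor of at least r = 1.05 (either direction).

Suffixes of kept contexts are always stored (tree property); the root is
always present.  Stored rows are floor-smoothed,
P̃ = (1 − |S|γ)·P̂ + γ, which bounds every conditional below by γ and keeps
log-losses and log ratios finite.  Evaluation uses the longest stored suffix
of the history, so early positions fall back to shorter contexts and
ultimately the marginal.  An unpruned mode (`prune=False`) retains every
observed context; its conditionals equal empirical d-gram frequencies up to
smoothing and serve as the oracle route in tests.

Cross-validation folds are ten contiguous blocks with boundaries snapped to
the nearest word break (a cut is admissible when either neighbor is `0`), so
no burst word is split and concatenating training blocks creates junctions
that look like ordinary avalanche boundaries.  Depth is the argmin of the
average held-out log-loss; ties resolve to the shallower model.  NI is
definitionally 0 at depth 0 and 1 at the selected depth; when no depth
improves on the marginal (I_opt ≤ 0) NI is reported as all zeros.

Word-frequency predictions embed the depth-d model in the equivalent
order-d chain over d-grams (smoothing makes it irreducible), find the
stationary law by power iteration (tolerance 1e−12), and propagate it
through the word's transitions; the expected count is the per-symbol rate
times the sequence length.  This stationary-rate definition is validated
against direct occurrence counting in 10⁵–10⁶-symbol simulations.

## Enrichment statistics

The AIM is estimated by transition counting: P00 and P0b from transitions
out of silence, Pb0 and Pbb from transitions out of bursts, burst rates from
nonzero symbol counts.  Burst→burst entries are Pbb·P_i so that every row is
a probability vector while silence↔burst rates are preserved; the variant
without the Pbb factor (whose burst rows sum to Pb0 + 1) is available behind
`variant="printed"` for comparison but is not a stochastic matrix.  Sequence
probabilities condition the first symbols on the longest available context,
bottoming out at the empirical marginal.

Fold z-scores use the population SD exactly as defined,
z = ⟨l_i⟩ / √(⟨l_i²⟩ − ⟨l_i⟩²), with each fold's fitted model *and* AIM
refit on that fold's training data, and a one-sided upper-tail normal p
(enrichment claims are directional).  Zero fold variance with nonzero mean
reports an infinite z with a degeneracy flag rather than a silently huge
number; identically-zero folds raise.

A calibration caveat documented deliberately: the ten folds share 90 % of
their training data, so the spread of l_i understates the sampling
variability of their mean by roughly 0.9·√10 ≈ 2.8.  On data generated from
the AIM itself (no planted enrichment), about half of random probe
sequences exceed |z| = 1.96 — consistent with z ~ N(0, 2.8) — rather than
the ~5 % a calibrated test would give.  The z-score is therefore a
signal-to-jitter descriptor, not a frequentist test statistic; planted-
enrichment recoveries in the test suite use it only comparatively (enriched
vs. null data), and the acceptance script reports the measured null
exceedance fraction alongside the enrichment results.

Permutation analysis enumerates all m! orderings of the RUN sequence
(guarded at m ≤ 9) and reports the fraction of permutations whose
likelihood ratio is at least the RUN sequence's — a quantile locating the
RUN order among comparable sequences, explicitly not a p-value.

The R matrix rows default to the fitted model's deepest contexts; the AIM
conditional for a digram context uses its last symbol.  The enriched network
takes arcs where R exceeds a threshold (default 0) between nonzero symbols.
The digram class test pools first-order log ratios into
place–place / place–other / other–other groups and compares them pairwise by
two-sample KS statistics with permutation p-values over cell-label
relabelings (add-one correction, (x+1)/(n+1)).  Context clustering uses
cosine similarity (zero rows defined as similarity 0 to everything),
average-linkage ordering on 1 − similarity, and greedy modularity
communities on the similarity graph with negative similarities clipped to
zero — boundaries are visualization aids only.

## RUN-optimal chains

The rate of a sequence under a first-order chain is
π(s₁)·∏ P(s_{k+1}|s_k) — the expected number of (possibly overlapping)
occurrences per symbol position, validated by simulation counting.  The
RUN-optimal chain maximizes this rate subject to a fixed stationary
distribution (the measured symbol frequencies, silence included) and a fixed
silence self-transition P(0|0).  The log objective over the path entries is
concave and the constraints are linear, but the stationarity constraint set
is rank-deficient together with the row sums, which stalls SLSQP; one
stationarity component is dropped (it is implied) and P(0|0) is pinned
through its bounds.  The solver runs from the AIM, a greedy RUN-loaded
start, and Dirichlet-random restarts (10 by default); candidates are
projected back to row-stochastic form and kept only if their exact
stationary law matches the target within 1e−6.  The AIM itself is always a
candidate, so r_max ≥ r_AIM holds structurally.  On the 3-symbol reduced
problem the solver matches an exhaustive grid to well under 1 %.

## Place fields

Rate maps are spikes-per-pixel over occupancy time on 1 × 1 cm pixels, spike
positions assigned by the nearest trajectory sample in time, no smoothing
(the classic coherence definition uses raw rates).  Spatial coherence is the
Pearson correlation between each occupied pixel's rate and the mean of its
occupied 8-neighbors; fields are the largest 8-connected component at
≥ 3× the session mean rate and must exceed nine pixels (strict).  Angular
concentration slides an 80-bin window over a 200-bin circular histogram and
requires > 70 % of spikes inside.  Classical place cells must also pass the
rate filters (> 50 RUN spikes, < 10 Hz in POST).  The RUN sequence orders
classical place cells by their angular peak along the travel direction from
a configurable anchor (the session start/reward position); with fewer than
two classical place cells no RUN sequence is defined and the enrichment
stages are skipped.  `RateMap.peak_position` ignores pixels occupied below
0.5 s, since a lone spike during a 20 ms traversal otherwise dominates the
unsmoothed map; field localization tests use the rate-weighted field
centroid, which averages over the whole field.

## Synthetic data

The sleep generator samples a first-order chain with the AIM structure
built from p00 = 0.5, p_b0 = 0.35 and uniform burst rates over 15 cells —
values chosen to give mean word lengths near 3 and roughly 40 % silent
bins, matching the scale of real sleep sessions — with the RUN sequence
1…7.  Enrichment multiplies each consecutive RUN transition by f, holds the
boosted entries fixed, and rescales the remainder of the row (boosted mass
≥ 1 is rejected as infeasible).  A second-order variant boosts chosen
P(c|a,b) conditionals the same way; depth-2 recovery uses a 6-cell ensemble
because with 15 cells the modulated digram contexts fall below P_min and are
correctly pruned — second-order structure at that alphabet size is invisible
to the method at these sequence lengths, which is a property of the
estimator, not the generator.

Rendering symbols as spikes places each nonzero symbol's burst (1–3 spikes,
log-normal fast ISIs with median 4 ms capped at 7.5 % of the bin) with its
onset uniform in the first 30 % of a 100 ms bin, and the very first burst
exactly at its bin start.  This geometry guarantees the round trip: spikes
stay inside their bins, within-burst gaps stay far below maxISI, and bursts
of the same neuron in *adjacent* bins remain ≥ 55 ms apart — onsets spread
over the first half of the bin would break that last margin.  Re-parsing
recovers the symbol sequence exactly, up to leading/trailing silent bins,
which leave no trace in the spike data because the parser anchors its grid
at the first spike.  The pooled log-ISI distribution is bimodal with a
structurally silent gap between ~7.5 ms and ~55 ms; its midpoint (the
histogram trough) brackets maxISI = 50 ms.  Within-burst spike-count
statistics are free parameters (uniform on {1, 2, 3}); no published values
constrain them.

The RUN-session generator drives a constant-speed counterclockwise
trajectory (1 m diameter, 1 cm radial jitter, 20 ms samples, 30 laps of
15 s) and inhomogeneous-Poisson spiking: place cells get single von Mises
fields (κ = 12, 10 Hz peak) at centers offset half a spacing from the
session start so the firing order is unambiguous; other pyramidal cells get
three equally spaced low-concentration bumps (κ = 1, 3 Hz), position-
modulated but failing the field and concentration criteria.  Laps and peak
rates are at the low end of realistic sessions to keep test runtimes small;
the classification margins (coherence ≈ 0.35–0.5 vs. the 0.3 threshold)
are therefore tighter than a full 20-minute session would give.

What the generators do *not* emulate: theta/ripple oscillations, sharp-wave
waveforms, rate heterogeneity across cells beyond the configured vectors,
behavioral variability in running speed, and drift in place fields.  Passing
tests demonstrate that each estimator recovers the structure it targets
under its own model assumptions — they do not certify performance on real
recordings, where binning timescales, cell-count limits, and
non-stationarity add error modes the synthetic conditions exclude.

## Problem sizes and numerical choices

Synthetic sessions use 5 × 10⁴ symbols (2–3× smaller than a one-hour sleep
session at ~100 ms bins), 10–20 seeds per recovery suite, 20 ISI
randomizations per tail-test simulation, and 200–1000 label permutations —
sizes at which every recovery statistic in the test suite has comfortable
margins.  Power iteration tolerance is 1e−12; optimizer tolerance 1e−9 with
≤ 400 SLSQP iterations per start; probability floors come from γ.  All
randomness flows through explicit integer seeds; generators are
bit-reproducible.
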