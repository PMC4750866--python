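# avaseq — sequential structure in hippocampal spike avalanches

`avaseq` analyzes the sequential firing of hippocampal pyramidal-cell
ensembles during sleep.  It is aimed at systems neuroscientists who record
multi-neuron spike trains after a behavioral session and want to ask: beyond
the population bursting itself, do the cells fire in *preferred orders*, and
are behaviorally defined sequences (replay of a RUN sequence) enriched in
that order structure?

## The analysis

Spike trains are binned at the ensemble's mean inter-spike interval; runs of
occupied bins flanked by silence are **spike avalanches**.  Within an
avalanche each neuron's spikes chain into **bursts** (gaps < maxISI = 50 ms),
and the time-ordered bursts form a **burst word**; words joined by one `0`
per silent bin give the **burst sequence** — a symbol series over
S = {0, 1, …, C}.

A **variable-length Markov chain** (VLMC, learned as a probabilistic suffix
tree with parameters P_min = 0.006, γ = 0.001, r = 1.05) models
P(s_i | s_1 … s_{i−1}).  Model depth d is chosen by 10-fold cross-validated
**log-loss** L_M = −(1/N) Σ log₂ P_M(s_i | history); the **sequential
information** I_d = L_0 − L_d, normalized as NI_d = I_d / I_opt, measures how
much order structure each depth captures.

The comparator is the **avalanche independent model** (AIM), the first-order
chain that preserves silence↔burst transition rates and per-cell burst rates
but has no burst-to-burst preference:

    P_AI(0|0) = P00    P_AI(i|0) = P0b·P_i
    P_AI(0|i) = Pb0    P_AI(i|j) = Pbb·P_i

A sequence s is **enriched** when its likelihood ratio
L(s) = P_fit(s)/P_AI(s) exceeds 1; significance comes from the z-score of the
per-fold log₂ ratios (one-sided normal p, Bonferroni over the RUN-order
set).  The package also builds the **conditional log-likelihood matrix**
R(σ, j) = log₂(P(j|σ)/P_AI(j|σ)), the directed network of enriched
transitions, context clustering by cosine similarity, **RUN-optimal Markov
chains** (the maximal RUN-sequence rate given measured burst rates), and
place-cell classification from circular-track RUN epochs (coherence > 0.3,
field > 9 contiguous pixels at ≥ 3× mean rate, > 70 % of spikes in a 40 %
arc).

Because no recordings ship with the package, a first-class synthetic-data
module generates spike trains from planted chains (including RUN-transition
enrichment and second-order variants) and circular-track sessions with
von Mises place fields, so every stage is testable against known ground
truth.

## Worked example

```python
import numpy as np
from avaseq import (SleepSynthConfig, generate_burst_markov, symbols_to_spikes,
                    detect_avalanches, parse_burst_words, cross_validate,
                    fit_pst, build_aim, enumerate_run_order)
from avaseq.enrichment import build_fold_models, enrichment_analysis

cfg = SleepSynthConfig(n_symbols=50_000, enrichment_factor=2.0, seed=1)
symbols, truth = generate_burst_markov(cfg)     # planted 2x RUN enrichment
spikes = symbols_to_spikes(symbols, cfg)

avalanches = detect_avalanches(spikes, cfg.bin_width_s)
burst_seq = parse_burst_words(spikes, avalanches, cfg.max_isi_s)
cv = cross_validate(burst_seq.symbols, alphabet_size=16)

fitted = fit_pst(burst_seq.symbols, cv.selected_depth, alphabet_size=16)
aim = build_aim(burst_seq.symbols, alphabet_size=16, gamma=0.001)
folds = build_fold_models(burst_seq.symbols, cv.selected_depth,
                          cv.fold_spans, alphabet_size=16)
results = enrichment_analysis(fitted, aim, folds,
                              enumerate_run_order(cfg.run_sequence))
```

Output:

```
59001 spikes from 15 cells
10165 avalanches, mean size 5.80, mean word length 2.90
selected depth d = 1
NI by depth: [0.    1.    0.711 0.457 0.448 0.444]
RUN sequence L = 45.3, z = 57.1, p = 0.00e+00, significant = True
98/120 RUN-order sequences enriched, 94 significant
```

Cross validation correctly selects depth 1 for this first-order planted
chain (NI peaks at 1 there and declines as deeper models overfit).  The
planted 2-fold boost on each of the six consecutive RUN transitions
compounds to a likelihood ratio of ~2⁶ ≈ 64 for the full seven-cell
sequence — the fitted estimate is 45 — and most gapped subsequences of the
RUN sequence (RUN-order sequences; there are 2⁷ − 7 − 1 = 120 of them) are
enriched as well.

The same stages are scriptable from a shell: `avaseq simulate | parse | fit |
enrich | optimize | placecells | report` operate on delimited-text spike
tables and JSON models.

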