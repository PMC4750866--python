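"""Avalanche detection and burst-word parsing of multi-neuron spike trains.

A *spike avalanche* is a run of consecutive occupied time bins (any neuron
spiking) flanked by empty bins; its *size* is its total spike count.  Within
an avalanche, each neuron's spikes are chained into *bursts* (successive gaps
< ``maxISI``), and the time-ordered burst onsets across neurons form a *burst
word*.  Words from successive avalanches, separated by one ``0`` symbol per
empty bin, make up the session's *burst sequence* — the symbolic series all
downstream sequence modeling consumes.

The null model for heavy-tail tests is per-neuron ISI randomization, which
preserves each neuron's firing rate and burstiness while destroying
cross-neuron correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class DegenerateNullError(ValueError):
    """Raised when the pooled null distribution cannot define a 0.99 tail."""


@dataclass
class SpikeEnsemble:
    """Per-neuron sorted spike timestamps for one epoch.

    Parameters
    ----------
    spike_times : dict[int, np.ndarray]
        Maps neuron id (1..C) to a strictly increasing array of spike times
        in seconds.
    epoch : str
        Label, e.g. ``"POST"`` or ``"RUN"``.
    """

    spike_times: dict[int, np.ndarray]
    epoch: str = "POST"

    def __post_init__(self) -> None:
        clean = {}
        for nid, t in self.spike_times.items():
            arr = np.asarray(t, dtype=float)
            if arr.ndim != 1:
                raise ValueError(f"neuron {nid}: times must be 1-D")
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            if arr.size and arr[0] < 0:
                raise ValueError(f"neuron {nid}: negative spike time")
            clean[int(nid)] = arr
        self.spike_times = clean

    @property
    def n_cells(self) -> int:
        return max(self.spike_times) if self.spike_times else 0

    @property
    def n_spikes(self) -> int:
        return sum(t.size for t in self.spike_times.values())

    def pooled_times(self) -> np.ndarray:
        """All spike times of all neurons, sorted."""
        if not self.spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.spike_times.values())))


@dataclass
class Avalanche:
    start_bin: int
    end_bin: int  # inclusive
    size: int     # total spike count
    # (neuron_id, time) pairs, time-sorted
    spikes: np.ndarray = field(repr=False)


@dataclass
class AvalancheSet:
    bin_width_s: float
    t0: float                       # bin-grid anchor (first spike time)
    n_bins: int                     # grid length, first to last occupied bin
    avalanches: list[Avalanche]

    @property
    def sizes(self) -> np.ndarray:
        return np.array([a.size for a in self.avalanches], dtype=int)


@dataclass
class BurstSequence:
    """Symbolized ensemble activity: 1..C for neuron bursts, 0 per empty bin."""

    symbols: np.ndarray             # ints in {0..C}
    onset_times: np.ndarray         # NaN at zero symbols, burst onset otherwise
    max_isi_s: float
    n_cells: int
    # (start, stop) index pairs of maximal nonzero runs (the burst words)
    word_spans: list[tuple[int, int]]

    @property
    def words(self) -> list[np.ndarray]:
        return [self.symbols[a:b] for a, b in self.word_spans]

    @property
    def word_lengths(self) -> np.ndarray:
        return np.array([b - a for a, b in self.word_spans], dtype=int)


@dataclass
class TailTestResult:
    threshold: int
    p0: float          # null tail probability 1 - q
    k: int             # observed values above threshold
    n: int             # total observed values
    p_value: float


def ensemble_bin_size(ensemble: SpikeEnsemble) -> float:
    """Mean ISI of the pooled ensemble spike train, used as the bin width.

    All timestamps of all cells are pooled and sorted; the mean successive
    difference is returned.  Duplicated timestamps across neurons contribute
    zero intervals to the mean.
    """
    pooled = ensemble.pooled_times()
    if pooled.size < 2:
        raise ValueError("bin size undefined: fewer than 2 spikes in ensemble")
    return float(np.mean(np.diff(pooled)))


def detect_avalanches(ensemble: SpikeEnsemble, bin_width_s: float) -> AvalancheSet:
    """Partition spikes into avalanches: runs of occupied bins flanked by silence.

    The bin grid is anchored at the first spike time; the recording edges are
    treated as flanking silence.
    """
    if bin_width_s <= 0:
        raise ValueError("bin width must be positive")
    pooled = []
    for nid, t in ensemble.spike_times.items():
        if t.size:
            pooled.append(np.column_stack([np.full(t.size, nid, dtype=float), t]))
    if not pooled:
        return AvalancheSet(bin_width_s, 0.0, 0, [])
    spikes = np.concatenate(pooled)            # columns: neuron id, time
    order = np.lexsort((spikes[:, 0], spikes[:, 1]))
    spikes = spikes[order]
    t0 = spikes[0, 1]
    bins = np.floor((spikes[:, 1] - t0) / bin_width_s).astype(int)
    n_bins = int(bins[-1]) + 1

    occupied = np.unique(bins)
    # runs of consecutive occupied bins
    breaks = np.flatnonzero(np.diff(occupied) > 1)
    run_starts = np.concatenate([[0], breaks + 1])
    run_ends = np.concatenate([breaks, [occupied.size - 1]])

    avalanches = []
    for rs, re in zip(run_starts, run_ends):
        b0, b1 = int(occupied[rs]), int(occupied[re])
        lo = np.searchsorted(bins, b0, side="left")
        hi = np.searchsorted(bins, b1, side="right")
        avalanches.append(Avalanche(b0, b1, hi - lo, spikes[lo:hi]))
    return AvalancheSet(bin_width_s, float(t0), n_bins, avalanches)


def _neuron_burst_onsets(times: np.ndarray, max_isi_s: float) -> np.ndarray:
    """Onset times of bursts: maximal spike groups with successive gaps < maxISI."""
    if times.size == 0:
        return times
    starts = np.concatenate([[True], np.diff(times) >= max_isi_s])
    return times[starts]


def parse_burst_words(
    ensemble: SpikeEnsemble,
    avalanches: AvalancheSet,
    max_isi_s: float = 0.05,
) -> BurstSequence:
    """Symbolize avalanches into burst words joined by one '0' per empty bin.

    Within each avalanche, each neuron's spikes chain into bursts (gaps
    < ``max_isi_s``), each represented by its first spike time; bursts never
    cross avalanche boundaries.  Bursts across the whole avalanche are ordered
    by onset time (ties broken by ascending neuron id) to form the word.
    """
    n_cells = ensemble.n_cells
    symbols: list[int] = []
    onsets: list[float] = []
    spans: list[tuple[int, int]] = []
    prev_end: int | None = None
    for av in avalanches.avalanches:
        if prev_end is not None:
            n_zero = av.start_bin - prev_end - 1
            symbols.extend([0] * n_zero)
            onsets.extend([np.nan] * n_zero)
        prev_end = av.end_bin
        ids = av.spikes[:, 0].astype(int)
        entries = []
        for nid in np.unique(ids):
            t = np.sort(av.spikes[ids == nid, 1])
            for onset in _neuron_burst_onsets(t, max_isi_s):
                entries.append((onset, int(nid)))
        entries.sort()  # onset time, then neuron id
        start = len(symbols)
        for onset, nid in entries:
            symbols.append(nid)
            onsets.append(onset)
        spans.append((start, len(symbols)))
    return BurstSequence(
        symbols=np.array(symbols, dtype=int),
        onset_times=np.array(onsets, dtype=float),
        max_isi_s=max_isi_s,
        n_cells=n_cells,
        word_spans=spans,
    )


def isi_randomize(ensemble: SpikeEnsemble, seed: int | np.random.Generator) -> SpikeEnsemble:
    """Surrogate ensemble with each neuron's ISIs independently permuted.

    Each neuron's spike train is rebuilt starting at zero by sampling its own
    ISI multiset without replacement, preserving spike count, rate, and
    burstiness while destroying cross-neuron correlations.  Neurons with fewer
    than two spikes are returned unchanged.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out = {}
    for nid, t in ensemble.spike_times.items():
        if t.size < 2:
            out[nid] = t.copy()
            continue
        isis = np.diff(t)
        perm = rng.permutation(isis)
        out[nid] = np.concatenate([[0.0], np.cumsum(perm)])
    return SpikeEnsemble(out, epoch=ensemble.epoch)


def tail_test(
    observed_values: np.ndarray,
    null_values_pooled: np.ndarray,
    q_nominal: float = 0.99,
) -> TailTestResult:
    """Binomial test for an excess of large values relative to a pooled null.

    The threshold is the largest integer whose empirical null CDF is strictly
    below ``q_nominal``; the corresponding exceedance probability ``p0 = 1 - q``
    parameterizes an upper-tail binomial test on the number of observed values
    above the threshold.
    """
    obs = np.asarray(observed_values)
    null = np.asarray(null_values_pooled)
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null samples must be nonempty")
    vals, counts = np.unique(null, return_counts=True)
    cdf = np.cumsum(counts) / null.size
    below = np.flatnonzero(cdf < q_nominal)
    if below.size == 0:
        raise DegenerateNullError(
            "null distribution too concentrated to define the tail threshold"
        )
    threshold = int(vals[below[-1]])
    p0 = float(1.0 - cdf[below[-1]])
    k = int(np.sum(obs > threshold))
    n = int(obs.size)
    # P[X >= k] for X ~ Binomial(n, p0)
    p_value = float(stats.binom.sf(k - 1, n, p0)) if k > 0 else 1.0
    return TailTestResult(threshold=threshold, p0=p0, k=k, n=n, p_value=p_value)
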