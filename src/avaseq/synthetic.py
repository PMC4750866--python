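"""Synthetic spike-train and behavior generators with known ground truth.

Two kinds of dataset are emulated so that every stage of the analysis is
testable without recordings:

* **Sleep-like burst sequences** sampled from a first-order chain with the
  avalanche-independent structure (silence self-transitions, silence<->burst
  rates, per-cell burst rates) plus an optional multiplicative enrichment of
  the transitions along a planted RUN sequence, and an optional second-order
  planted variant for depth-selection tests.  Symbol sequences are rendered
  into spike ensembles whose pooled log-ISI distribution is bimodal (fast
  within-burst mode, slow between-burst mode).
* **Circular-track RUN sessions** with von-Mises-tuned place cells firing as
  inhomogeneous Poisson processes along laps, for place-field classification
  and RUN-sequence definition.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .parsing import SpikeEnsemble


@dataclass
class SleepSynthConfig:
    """Parameters of the planted burst-sequence generator.

    ``burst_rates`` must sum to one; the silence structure (``p00``,
    ``p_b0``) and the rates define the baseline avalanche-independent chain,
    and ``enrichment_factor`` multiplies the transitions between consecutive
    RUN-sequence cells (the boosted entries are held fixed and the rest of
    the row is rescaled).  The log-ISI modes are log-normal with the given
    natural-log location and scale, in seconds.
    """

    n_cells: int = 15
    run_sequence: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7)
    enrichment_factor: float = 1.0
    p00: float = 0.5
    p_b0: float = 0.35
    burst_rates: np.ndarray | None = None   # uniform if None
    n_symbols: int = 50_000
    bin_width_s: float = 0.1
    max_isi_s: float = 0.05
    fast_isi_log_params: tuple[float, float] = (np.log(0.004), 0.5)
    slow_isi_log_params: tuple[float, float] = (0.0, 0.6)
    # second-order planted structure: {(a, b): {c: factor}} boosts P(c | a,b)
    second_order_boosts: dict[tuple[int, int], dict[int, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burst_rates is None:
            self.burst_rates = np.full(self.n_cells, 1.0 / self.n_cells)
        self.burst_rates = np.asarray(self.burst_rates, dtype=float)

    def validate(self) -> None:
        C = self.n_cells
        if C < 1:
            raise ValueError("need at least one cell")
        if abs(self.burst_rates.sum() - 1.0) > 1e-12:
            raise ValueError("burst_rates must sum to 1 within 1e-12")
        if self.burst_rates.size != C:
            raise ValueError("burst_rates length must equal n_cells")
        ids = list(self.run_sequence)
        if len(set(ids)) != len(ids) or any(not (1 <= i <= C) for i in ids):
            raise ValueError("run_sequence ids must be distinct and in 1..C")
        if not (0.0 <= self.p00 <= 1.0 and 0.0 <= self.p_b0 <= 1.0):
            raise ValueError("p00 and p_b0 must be probabilities")
        if self.enrichment_factor < 0:
            raise ValueError("enrichment_factor must be >= 0")
        mu_f, sd_f = self.fast_isi_log_params
        mu_s, sd_s = self.slow_isi_log_params
        if stats.lognorm.cdf(self.max_isi_s, sd_f, scale=np.exp(mu_f)) < 0.999:
            raise ValueError("fast ISI mode extends beyond maxISI")
        if stats.lognorm.sf(self.bin_width_s, sd_s, scale=np.exp(mu_s)) < 0.999:
            raise ValueError("slow ISI mode extends below the bin width")


@dataclass
class GroundTruthChain:
    """The exact chain a burst sequence was sampled from.

    ``first_order`` is the (C+1)x(C+1) row-stochastic matrix; when
    second-order boosts are planted, ``second_order`` maps modulated digram
    contexts to their conditional rows (all other digrams fall back to the
    first-order row of their last symbol).
    """

    first_order: np.ndarray
    second_order: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    @property
    def order(self) -> int:
        return 2 if self.second_order else 1

    def conditional(self, prev2: int, prev1: int) -> np.ndarray:
        row = self.second_order.get((prev2, prev1))
        return row if row is not None else self.first_order[prev1]

    def stationary(self, tol: float = 1e-13) -> np.ndarray:
        """Stationary distribution of the first-order skeleton."""
        P = self.first_order
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()

    def to_dict(self) -> dict:
        return {
            "first_order": self.first_order.tolist(),
            "second_order": {
                f"{a} {b}": row.tolist() for (a, b), row in self.second_order.items()
            },
        }


def _boost_row(row: np.ndarray, boosts: dict[int, float]) -> np.ndarray:
    """Multiply selected entries, hold them fixed, rescale the rest to sum 1."""
    out = row.copy()
    idx = np.array(sorted(boosts), dtype=int)
    out[idx] = row[idx] * np.array([boosts[i] for i in sorted(boosts)])
    fixed = out[idx].sum()
    if fixed >= 1.0:
        raise ValueError(
            "invalid enrichment_factor: boosted transition mass reaches 1 "
            f"({fixed:.4f}) before the remaining entries"
        )
    rest = np.setdiff1d(np.arange(row.size), idx)
    rest_mass = row[rest].sum()
    if rest_mass > 0:
        out[rest] = row[rest] * (1.0 - fixed) / rest_mass
    return out


def build_ground_truth(config: SleepSynthConfig) -> GroundTruthChain:
    """The enriched avalanche-independent chain defined by the config."""
    config.validate()
    C = config.n_cells
    A = C + 1
    rates = config.burst_rates
    P = np.zeros((A, A))
    P[0, 0] = config.p00
    P[0, 1:] = (1.0 - config.p00) * rates
    P[1:, 0] = config.p_b0
    P[1:, 1:] = (1.0 - config.p_b0) * rates[None, :]

    f = config.enrichment_factor
    if f != 1.0:
        boosts_by_row: dict[int, dict[int, float]] = {}
        for a, b in zip(config.run_sequence[:-1], config.run_sequence[1:]):
            boosts_by_row.setdefault(a, {})[b] = f
        for a, boosts in boosts_by_row.items():
            P[a] = _boost_row(P[a], boosts)

    second: dict[tuple[int, int], np.ndarray] = {}
    for (a, b), boosts in config.second_order_boosts.items():
        second[(a, b)] = _boost_row(P[b], boosts)
    return GroundTruthChain(first_order=P, second_order=second)


def generate_burst_markov(config: SleepSynthConfig) -> tuple[np.ndarray, GroundTruthChain]:
    """Sample a burst sequence from the planted chain.

    Returns the symbol sequence over {0..C} and the exact chain used.  With
    ``enrichment_factor == 1`` and no second-order boosts the chain is exactly
    the avalanche-independent model built from (p00, p_b0, burst_rates).
    """
    chain = build_ground_truth(config)
    rng = np.random.default_rng(config.seed)
    N = config.n_symbols
    A = config.n_cells + 1
    seq = np.empty(N, dtype=np.int64)
    if N == 0:
        return seq, chain
    pi = chain.stationary()
    cum_pi = np.cumsum(pi)
    cum_rows = np.cumsum(chain.first_order, axis=1)
    cum_second = {k: np.cumsum(v) for k, v in chain.second_order.items()}
    u = rng.random(N)
    seq[0] = np.searchsorted(cum_pi, u[0])
    for i in range(1, N):
        if chain.second_order and i >= 2:
            key = (int(seq[i - 2]), int(seq[i - 1]))
            cr = cum_second.get(key)
            if cr is None:
                cr = cum_rows[seq[i - 1]]
        else:
            cr = cum_rows[seq[i - 1]]
        seq[i] = np.searchsorted(cr, u[i])
    return seq, chain


#: Burst rendering geometry, as fractions of the bin width: onsets fall in the
#: first ONSET_FRAC of the bin and each within-burst ISI is capped at ISI_FRAC,
#: so a burst spans at most ONSET_FRAC + 2*ISI_FRAC = 0.45 of its bin and two
#: bursts of the same neuron in adjacent bins are >= 0.55 bins apart.
ONSET_FRAC = 0.3
ISI_FRAC = 0.075
MAX_SPIKES_PER_BURST = 3


def symbols_to_spikes(sequence: np.ndarray, config: SleepSynthConfig) -> SpikeEnsemble:
    """Render a symbol sequence as spikes: one within-bin burst per nonzero symbol.

    Each nonzero symbol becomes a burst of 1-3 spikes of that neuron inside
    its bin, with fast-mode ISIs; '0' bins stay empty.  The first burst is
    placed exactly at its bin start so that re-parsing with the same bin
    width (grid anchored at the first spike) recovers the symbols.
    """
    config.validate()
    seq = np.asarray(sequence, dtype=np.int64)
    if seq.size and (seq.min() < 0 or seq.max() > config.n_cells):
        raise ValueError("sequence symbols must lie in {0..C}")
    dt = config.bin_width_s
    mu_f, sd_f = config.fast_isi_log_params
    isi_cap = ISI_FRAC * dt
    if stats.lognorm.cdf(isi_cap, sd_f, scale=np.exp(mu_f)) < 0.5:
        raise ValueError(
            f"bin width {dt} s too small to hold a fast burst "
            f"(ISI cap {isi_cap * 1e3:.1f} ms below the fast-mode median)"
        )
    gap = dt * (1.0 - ONSET_FRAC - MAX_SPIKES_PER_BURST * ISI_FRAC + ISI_FRAC)
    if gap <= config.max_isi_s:
        raise ValueError("bin width too small: adjacent-bin bursts would merge")
    rng = np.random.default_rng(config.seed + 1 if isinstance(config.seed, int) else config.seed)
    times: dict[int, list[float]] = {nid: [] for nid in range(1, config.n_cells + 1)}
    first = True
    for b, s in enumerate(seq):
        if s == 0:
            continue
        onset = b * dt if first else b * dt + rng.uniform(0.0, ONSET_FRAC * dt)
        first = False
        n_spk = rng.integers(1, MAX_SPIKES_PER_BURST + 1)
        isis = np.minimum(rng.lognormal(mu_f, sd_f, size=n_spk - 1), isi_cap)
        times[int(s)].extend(onset + np.concatenate([[0.0], np.cumsum(isis)]))
    return SpikeEnsemble(
        {nid: np.array(t) for nid, t in times.items() if t}, epoch="POST"
    )


@dataclass
class RunSynthConfig:
    """Circular-track session generator parameters.

    The first ``n_place_cells`` cells are single-field place cells with
    von Mises tuning (concentration ``field_concentrations``) around their
    ``field_centers``; the remaining cells get three equally spaced low-
    concentration bumps, giving position-modulated but spatially diffuse
    firing.  The animal runs counterclockwise at constant angular speed.
    """

    n_cells: int = 15
    n_place_cells: int = 7
    field_centers: np.ndarray | None = None        # radians, length n_cells
    field_concentrations: np.ndarray | None = None
    peak_rates: np.ndarray | None = None           # Hz
    n_laps: int = 30
    lap_duration_s: float = 15.0
    track_radius_m: float = 0.5
    sample_dt_s: float = 0.02
    radial_jitter_m: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        C, P = self.n_cells, self.n_place_cells
        rng = np.random.default_rng(self.seed + 977)
        if self.field_centers is None:
            centers = np.empty(C)
            # fields sit mid-arc so the session start (angle 0) falls between
            # the last and first field and the firing order is unambiguous
            centers[:P] = (np.arange(P) + 0.5) * 2 * np.pi / max(P, 1)
            centers[P:] = rng.uniform(0, 2 * np.pi, C - P)
            self.field_centers = centers
        self.field_centers = np.asarray(self.field_centers, dtype=float)
        if self.field_concentrations is None:
            conc = np.empty(C)
            conc[:P] = 12.0
            conc[P:] = 1.0
            self.field_concentrations = conc
        self.field_concentrations = np.asarray(self.field_concentrations, dtype=float)
        if self.peak_rates is None:
            pr = np.empty(C)
            pr[:P] = 10.0
            pr[P:] = 3.0
            self.peak_rates = pr
        self.peak_rates = np.asarray(self.peak_rates, dtype=float)

    def validate(self) -> None:
        if self.n_place_cells > self.n_cells:
            raise ValueError("n_place_cells cannot exceed n_cells")
        pc = self.field_centers[: self.n_place_cells]
        if np.unique(np.round(pc, 9)).size != pc.size:
            raise ValueError("place-cell field centers must be distinct")
        for name in ("field_centers", "field_concentrations", "peak_rates"):
            if getattr(self, name).size != self.n_cells:
                raise ValueError(f"{name} must have length n_cells")


def cell_rate(config: RunSynthConfig, cell: int, theta: np.ndarray) -> np.ndarray:
    """Angular firing-rate profile of one cell (1-based id), in Hz."""
    i = cell - 1
    mu = config.field_centers[i]
    kappa = config.field_concentrations[i]
    peak = config.peak_rates[i]
    if i < config.n_place_cells:
        return peak * np.exp(kappa * (np.cos(theta - mu) - 1.0))
    bumps = mu + np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
    r = sum(np.exp(kappa * (np.cos(theta - b) - 1.0)) for b in bumps)
    return peak * r / 3.0


def generate_run_session(config: RunSynthConfig) -> tuple[np.ndarray, SpikeEnsemble]:
    """Simulate laps on the circular track with place-modulated Poisson spiking.

    Returns a trajectory array with columns (time_s, x_m, y_m) and the RUN
    spike ensemble.  Spike times are jittered uniformly within each
    trajectory sample interval.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    T = config.n_laps * config.lap_duration_s
    t = np.arange(0.0, T, config.sample_dt_s)
    theta = (2 * np.pi * t / config.lap_duration_s) % (2 * np.pi)
    radius = config.track_radius_m + rng.normal(0.0, config.radial_jitter_m, t.size)
    x = radius * np.cos(theta)
    y = radius * np.sin(theta)
    trajectory = np.column_stack([t, x, y])

    spike_times: dict[int, np.ndarray] = {}
    for cell in range(1, config.n_cells + 1):
        lam = cell_rate(config, cell, theta)
        counts = rng.poisson(lam * config.sample_dt_s)
        idx = np.repeat(np.arange(t.size), counts)
        if idx.size:
            st = t[idx] + rng.uniform(0.0, config.sample_dt_s, idx.size)
            spike_times[cell] = np.sort(st)
        else:
            spike_times[cell] = np.empty(0)
    return trajectory, SpikeEnsemble(spike_times, epoch="RUN")


def poisson_ensemble(
    n_cells: int, rate_hz: float | np.ndarray, duration_s: float, seed: int,
    epoch: str = "POST",
) -> SpikeEnsemble:
    """Homogeneous Poisson spike trains — the fully uncorrelated control."""
    rng = np.random.default_rng(seed)
    rates = np.broadcast_to(np.asarray(rate_hz, dtype=float), (n_cells,))
    out = {}
    for i, r in enumerate(rates, start=1):
        n = rng.poisson(r * duration_s)
        out[i] = np.sort(rng.uniform(0.0, duration_s, n))
    return SpikeEnsemble(out, epoch=epoch)
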