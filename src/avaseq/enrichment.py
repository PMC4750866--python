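"""Sequence-enrichment statistics against the avalanche independent model.

The *avalanche independent model* (AIM) is the first-order chain that keeps
the measured silence structure (P00, P0b, Pb0, Pbb) and per-cell burst rates
P_1..P_C but has no sequential preference between bursts:

    P_AI(0|0) = P00          P_AI(i|0) = P0b * P_i
    P_AI(0|i) = Pb0          P_AI(i|j) = Pbb * P_i

(The burst-to-burst entries carry the Pbb factor so every row is a
probability vector; a variant without it is available for comparison.)

A sequence's *likelihood ratio* L = P_fit / P_AI measures how strongly the
fitted model's sequential correlations favor it; L > 1 is *enrichment*.
Significance uses the z-score of the per-fold log2 ratios from 10-fold cross
validation, compared to the standard normal (one-sided, Bonferroni-corrected
over the probe set).  The *conditional log-likelihood matrix*
R(ctx, j) = log2(P(j|ctx) / P_AI(j|ctx)) maps context-specific up- and
down-regulation; its positive entries define the enriched-transition network
and its rows are clustered by cosine similarity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from . import vlmc as _vlmc


class DegenerateVarianceError(ValueError):
    """All fold log-ratios identical and zero: no z-score can be formed."""


@dataclass
class AIMModel:
    """The avalanche independent comparator chain.

    Stored parameters are exact empirical estimates; ``gamma`` adds the same
    probability floor used by the fitted models so that log ratios stay
    finite (``gamma=0`` keeps the rows exact).
    """

    P00: float
    Pb0: float
    burst_rates: np.ndarray           # P_1..P_C, sums to 1
    marginal: np.ndarray              # empirical symbol frequencies incl. 0
    gamma: float = 0.0
    variant: str = "normalized"       # or "printed": P_AI(i|j) = P_i
    max_depth: int = 1

    @property
    def P0b(self) -> float:
        return 1.0 - self.P00

    @property
    def Pbb(self) -> float:
        return 1.0 - self.Pb0

    @property
    def alphabet_size(self) -> int:
        return self.burst_rates.size + 1

    @property
    def transition_matrix(self) -> np.ndarray:
        """Exact (unsmoothed) row-stochastic AIM transition table."""
        A = self.alphabet_size
        P = np.zeros((A, A))
        P[0, 0] = self.P00
        P[0, 1:] = self.P0b * self.burst_rates
        P[1:, 0] = self.Pb0
        bb = self.burst_rates if self.variant == "printed" else self.Pbb * self.burst_rates
        P[1:, 1:] = bb[None, :]
        return P

    def _smooth(self, row: np.ndarray) -> np.ndarray:
        if self.gamma <= 0:
            return row
        return (1.0 - self.alphabet_size * self.gamma) * row + self.gamma

    def cond_row(self, history) -> np.ndarray:
        h = tuple(int(s) for s in history)
        if not h:
            return self._smooth(self.marginal)
        return self._smooth(self.transition_matrix[h[-1]])

    def cond_probs(self, sequence: np.ndarray) -> np.ndarray:
        seq = np.asarray(sequence, dtype=np.int64)
        P = np.apply_along_axis(self._smooth, 1, self.transition_matrix)
        probs = np.empty(seq.size)
        if seq.size:
            probs[0] = self._smooth(self.marginal)[seq[0]]
            probs[1:] = P[seq[:-1], seq[1:]]
        return probs

    def stationary(self) -> np.ndarray:
        P = self.transition_matrix
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.abs(np.real(vecs[:, i]))
        return pi / pi.sum()

    def to_dict(self) -> dict:
        return {
            "P00": self.P00, "Pb0": self.Pb0, "gamma": self.gamma,
            "variant": self.variant,
            "burst_rates": self.burst_rates.tolist(),
            "marginal": self.marginal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AIMModel":
        return cls(
            P00=float(d["P00"]), Pb0=float(d["Pb0"]),
            burst_rates=np.asarray(d["burst_rates"], dtype=float),
            marginal=np.asarray(d["marginal"], dtype=float),
            gamma=float(d.get("gamma", 0.0)),
            variant=d.get("variant", "normalized"),
        )


def build_aim(
    burst_sequence: np.ndarray,
    alphabet_size: int | None = None,
    gamma: float = 0.0,
    variant: str = "normalized",
) -> AIMModel:
    """Estimate the AIM from a burst sequence.

    P00/P0b come from transitions out of silence, Pb0/Pbb from transitions
    out of bursts, and the burst rates from the nonzero symbol counts.
    """
    seq = np.asarray(burst_sequence, dtype=np.int64)
    if seq.size < 2:
        raise ValueError("need at least two symbols to estimate transitions")
    A = alphabet_size if alphabet_size is not None else int(seq.max()) + 1
    src, dst = seq[:-1], seq[1:]
    from_zero = src == 0
    from_burst = ~from_zero
    if not from_zero.any() or not (seq != 0).any():
        raise ValueError("AIM unestimable: need both silence and burst symbols")
    if not from_burst.any():
        raise ValueError("AIM unestimable: no transitions out of bursts")
    P00 = float(np.mean(dst[from_zero] == 0))
    Pb0 = float(np.mean(dst[from_burst] == 0))
    bursts = seq[seq != 0]
    counts = np.bincount(bursts, minlength=A)[1:]
    rates = counts / counts.sum()
    marginal = np.bincount(seq, minlength=A) / seq.size
    return AIMModel(P00=P00, Pb0=Pb0, burst_rates=rates, marginal=marginal,
                    gamma=gamma, variant=variant)


def sequence_probability(model, seq) -> float:
    """Product of conditionals, longest-available-suffix evaluation.

    Initial symbols with insufficient history fall back through shorter
    contexts down to the depth-0 marginal.
    """
    s = [int(x) for x in seq]
    p = 1.0
    for i, sym in enumerate(s):
        hist = tuple(s[max(0, i - model.max_depth):i])
        p *= float(model.cond_row(hist)[sym])
    return p


@dataclass
class EnrichmentResult:
    sequence: tuple[int, ...]
    likelihood_ratio: float
    log2_ratio: float
    fold_log_ratios: np.ndarray | None = None
    z: float | None = None
    p_value: float | None = None
    significant: bool | None = None
    degenerate: bool = False

    @property
    def enriched(self) -> bool:
        return self.likelihood_ratio > 1.0


def likelihood_ratio(fitted, aim, seq) -> EnrichmentResult:
    """L(s) = P_fit(s) / P_AI(s) and its log2."""
    p_fit = sequence_probability(fitted, seq)
    p_aim = sequence_probability(aim, seq)
    L = p_fit / p_aim
    return EnrichmentResult(
        sequence=tuple(int(x) for x in seq),
        likelihood_ratio=L,
        log2_ratio=math.log2(L) if L > 0 else -math.inf,
    )


def zscore(per_fold_log_ratios) -> tuple[float, float, bool]:
    """Fold-jitter z-score: mean over population SD of the fold log2 ratios.

    Returns (z, one-sided upper-tail p, degenerate flag).  Zero variance with
    a nonzero mean yields an infinite z with the flag set; identically-zero
    folds raise :class:`DegenerateVarianceError`.
    """
    l = np.asarray(per_fold_log_ratios, dtype=float)
    if l.size < 2:
        raise ValueError("need at least 2 folds")
    mean = float(l.mean())
    sd = float(l.std())  # population SD, <l^2> - <l>^2
    if sd == 0.0:
        if mean == 0.0:
            raise DegenerateVarianceError("all fold log-ratios are zero")
        z = math.inf if mean > 0 else -math.inf
        return z, 0.0 if mean > 0 else 1.0, True
    z = mean / sd
    return z, float(stats.norm.sf(z)), False


def fold_log_ratios(fold_models: list, seq) -> np.ndarray:
    """Per-fold l_i = log2(P_i(s)/P_AI,i(s)) from (fitted, AIM) pairs."""
    out = []
    for fitted_i, aim_i in fold_models:
        p_fit = sequence_probability(fitted_i, seq)
        p_aim = sequence_probability(aim_i, seq)
        out.append(math.log2(p_fit / p_aim))
    return np.array(out)


def build_fold_models(
    sequence: np.ndarray,
    depth: int,
    fold_spans,
    p_min: float = _vlmc.P_MIN_DEFAULT,
    gamma: float = _vlmc.GAMMA_DEFAULT,
    r: float = _vlmc.R_DEFAULT,
    alphabet_size: int | None = None,
) -> list[tuple]:
    """(fitted, AIM) pairs refit on each fold's training data."""
    seq = np.asarray(sequence, dtype=np.int64)
    A = alphabet_size if alphabet_size is not None else int(seq.max()) + 1
    pairs = []
    for m, train in _vlmc.fit_fold_models(
        seq, depth, fold_spans, p_min=p_min, gamma=gamma, r=r, alphabet_size=A
    ):
        pairs.append((m, build_aim(train, alphabet_size=A, gamma=gamma)))
    return pairs


def enrichment_analysis(
    fitted,
    aim,
    fold_models: list,
    probes,
    alpha: float = 0.05,
    bonferroni_m: int | None = None,
) -> list[EnrichmentResult]:
    """Full enrichment result (L, fold ratios, z, p, significance) per probe.

    The Bonferroni threshold is ``alpha / m`` with ``m`` defaulting to the
    number of probes tested.
    """
    m = bonferroni_m if bonferroni_m is not None else len(probes)
    results = []
    for seq in probes:
        res = likelihood_ratio(fitted, aim, seq)
        l_i = fold_log_ratios(fold_models, seq)
        res.fold_log_ratios = l_i
        try:
            res.z, res.p_value, res.degenerate = zscore(l_i)
        except DegenerateVarianceError:
            res.z, res.p_value, res.degenerate = float("nan"), float("nan"), True
            res.significant = False
            results.append(res)
            continue
        res.significant = bool(res.p_value < alpha / max(m, 1))
        results.append(res)
    return results


def enumerate_run_order(run_sequence) -> list[tuple[int, ...]]:
    """All order-preserving gapped subsequences of length >= 2.

    For a RUN sequence of length m there are 2^m - m - 1 of them, including
    the full sequence (120 for m = 7).
    """
    rs = tuple(int(x) for x in run_sequence)
    m = len(rs)
    if m < 2 or len(set(rs)) != m:
        raise ValueError("run_sequence must have >= 2 distinct symbols")
    out = []
    for k in range(2, m + 1):
        out.extend(itertools.combinations(rs, k))
    return out


def permutation_enrichment(
    fitted, aim, run_sequence, max_m: int = 9
) -> tuple[np.ndarray, float, float]:
    """Likelihood ratios of every permutation of the RUN sequence.

    Returns (ratios over all m! permutations, the RUN sequence's own ratio,
    and its top-quantile: the fraction of permutations with a ratio at least
    as large).  The quantile situates the RUN sequence within comparable
    place-cell sequences; it is not a p-value.
    """
    rs = tuple(int(x) for x in run_sequence)
    m = len(rs)
    if m > max_m:
        raise ValueError(f"{m}! permutations exceed the max_m={max_m} guard")
    ratios = np.array([
        likelihood_ratio(fitted, aim, perm).likelihood_ratio
        for perm in itertools.permutations(rs)
    ])
    run_L = likelihood_ratio(fitted, aim, rs).likelihood_ratio
    quantile = float(np.mean(ratios >= run_L))
    return ratios, run_L, quantile


@dataclass
class ConditionalLogLikMatrix:
    contexts: list[tuple[int, ...]]
    values: np.ndarray            # (n_contexts, alphabet_size)

    @property
    def alphabet_size(self) -> int:
        return self.values.shape[1]

    def context_labels(self) -> list[str]:
        return ["-".join(str(s) for s in c) for c in self.contexts]


def conditional_loglik_matrix(
    fitted, aim, context_length: int | None = None
) -> ConditionalLogLikMatrix:
    """R(ctx, j) = log2(P(j|ctx) / P_AI(j|ctx)) over the fitted contexts.

    Rows default to the fitted model's deepest stored contexts (digrams for a
    depth-2 model); the AIM conditional for a context uses its last symbol,
    since the AIM is first order.
    """
    if context_length is None:
        context_length = fitted.max_depth
    contexts = [c for c in fitted.contexts() if len(c) == context_length]
    if not contexts:
        contexts = [c for c in fitted.contexts() if 0 < len(c) <= context_length]
    rows = []
    for ctx in contexts:
        p_fit = fitted.cond_row(ctx)
        p_aim = aim.cond_row(ctx)
        rows.append(np.log2(p_fit / p_aim))
    return ConditionalLogLikMatrix(contexts=contexts, values=np.array(rows))


def first_order_loglik_matrix(fitted, aim) -> ConditionalLogLikMatrix:
    """Single-symbol (burst) contexts only — the cell-to-cell regulation view."""
    R = conditional_loglik_matrix(fitted, aim, context_length=1)
    keep = [i for i, c in enumerate(R.contexts) if c[0] != 0]
    return ConditionalLogLikMatrix(
        contexts=[R.contexts[i] for i in keep], values=R.values[keep]
    )


def enriched_network(
    R: ConditionalLogLikMatrix,
    threshold: float = 0.0,
    run_sequence=None,
) -> nx.DiGraph:
    """Directed graph of enriched transitions: arcs where R > threshold.

    For single-symbol contexts nodes are cells; arcs from a context's cell to
    each up-regulated symbol, weighted by the log ratio.  Arcs whose endpoints
    appear in RUN order (source before target in ``run_sequence``) carry
    ``run_order=True``.
    """
    rs = list(run_sequence) if run_sequence is not None else []
    pos = {c: i for i, c in enumerate(rs)}
    G = nx.DiGraph()
    for ctx, row in zip(R.contexts, R.values):
        src = ctx[0] if len(ctx) == 1 else ctx
        for j in range(R.alphabet_size):
            if row[j] > threshold and j != 0:
                is_run = (
                    isinstance(src, int)
                    and src in pos and j in pos and pos[src] < pos[j]
                )
                G.add_edge(src, j, weight=float(row[j]), run_order=is_run)
    return G


@dataclass
class DigramClassTest:
    pools: dict[str, np.ndarray]              # place-place, place-other, other-other
    ks_stats: dict[tuple[str, str], float]
    p_values: dict[tuple[str, str], float]
    skipped: list[str] = field(default_factory=list)


def digram_class_test(
    R_first_order: ConditionalLogLikMatrix,
    cell_classes: dict[int, str],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> DigramClassTest:
    """KS permutation test comparing digram log ratios across cell-class pairs.

    Digram entries R(i, j) for nonzero i, j are pooled into place-place,
    place-other (either direction), and other-other groups by the classes of
    the two cells; pairwise two-sample KS statistics get permutation p-values
    from ``n_perm`` random relabelings of the cells.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = sorted(cell_classes)
    labels = np.array([cell_classes[c] == "place" for c in cells])
    idx_of = {c: i for i, c in enumerate(cells)}

    pairs, values = [], []
    for ctx, row in zip(R_first_order.contexts, R_first_order.values):
        i = ctx[-1]
        if i == 0 or i not in idx_of:
            continue
        for j in range(1, R_first_order.alphabet_size):
            if j in idx_of:
                pairs.append((idx_of[i], idx_of[j]))
                values.append(row[j])
    pairs = np.array(pairs)
    values = np.array(values)

    def pool(lab: np.ndarray) -> dict[str, np.ndarray]:
        a, b = lab[pairs[:, 0]], lab[pairs[:, 1]]
        return {
            "place-place": values[a & b],
            "place-other": values[a ^ b],
            "other-other": values[~a & ~b],
        }

    pools = pool(labels)
    names = ["place-place", "place-other", "other-other"]
    combos = [(x, y) for x, y in itertools.combinations(names, 2)]
    stats_obs, skipped = {}, []
    for x, y in combos:
        if pools[x].size == 0 or pools[y].size == 0:
            skipped.append(f"{x} vs {y}: empty class")
            continue
        stats_obs[(x, y)] = float(stats.ks_2samp(pools[x], pools[y]).statistic)

    exceed = {k: 0 for k in stats_obs}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pp = pool(perm)
        for (x, y) in stats_obs:
            if pp[x].size and pp[y].size:
                s = stats.ks_2samp(pp[x], pp[y]).statistic
                if s >= stats_obs[(x, y)]:
                    exceed[(x, y)] += 1
    p_values = {k: (exceed[k] + 1) / (n_perm + 1) for k in stats_obs}
    return DigramClassTest(pools=pools, ks_stats=stats_obs, p_values=p_values,
                           skipped=skipped)


def cosine_similarity_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarity; any zero row has similarity 0 to everything."""
    norms = np.linalg.norm(rows, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = rows / safe[:, None]
    sim = unit @ unit.T
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    np.fill_diagonal(sim, np.where(zero, 0.0, 1.0))
    return sim


@dataclass
class ContextClustering:
    order: np.ndarray                 # dendrogram leaf order of contexts
    similarity: np.ndarray
    linkage: np.ndarray
    communities: list[set[int]]       # modularity clusters (visual boundaries)


def cluster_contexts(R: ConditionalLogLikMatrix) -> ContextClustering:
    """Average-linkage clustering of R rows by cosine similarity.

    The dendrogram (distance = 1 - similarity) provides a row ordering;
    cluster boundaries come from greedy modularity maximization on the
    similarity graph with negative similarities clipped to zero.  Boundaries
    are visualization aids, not a statistical claim.
    """
    n = len(R.contexts)
    if n < 2:
        raise ValueError("need at least 2 contexts to cluster")
    sim = cosine_similarity_matrix(R.values)
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(Z)
    W = np.clip(sim, 0.0, None)
    np.fill_diagonal(W, 0.0)
    G = nx.from_numpy_array(W)
    if G.number_of_edges() == 0:
        communities = [set(range(n))]
    else:
        communities = [set(c) for c in nx.community.greedy_modularity_communities(G, weight="weight")]
    return ContextClustering(order=order, similarity=sim, linkage=Z, communities=communities)
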