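"""Variable-length Markov chains fit by the probabilistic suffix tree algorithm.

A VLMC predicts the next symbol of a sequence from a variable-length history
(*context*).  The PST learner keeps a context only if it occurs often enough
(``p_min``), predicts some symbol with probability at least ``gamma``, and
changes that prediction relative to its one-symbol-shorter suffix by a factor
of at least ``r`` — so depth-2 models fit to first-order data prune back to
first order.  Stored conditional rows are floor-smoothed,
``P~(s|ctx) = (1 - A*gamma) * P^(s|ctx) + gamma`` (``A`` the alphabet size),
which keeps log-losses finite.

Model goodness of fit is the *log-loss* (average negative log2 conditional
probability, in bits per symbol).  Depth is selected by 10-fold cross
validation; the *sequential information* ``I_d`` is the log-loss improvement
of the depth-``d`` model over depth 0, and ``NI_d = I_d / I_opt`` normalizes
it by the best depth's improvement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: PST hyperparameter defaults: minimum context frequency, smoothing/threshold
#: floor, and predictive-ratio threshold.
P_MIN_DEFAULT = 0.006
GAMMA_DEFAULT = 0.001
R_DEFAULT = 1.05


def _context_codes(seq: np.ndarray, alphabet_size: int, max_depth: int) -> list[np.ndarray]:
    """codes[k][i] = integer code of the length-k context preceding position i.

    The most recent symbol is the lowest base-``alphabet_size`` digit, so the
    length-(k-1) suffix of a context is its code modulo ``A**(k-1)``.
    Entries at positions ``i < k`` are invalid (history too short).
    """
    N = seq.size
    A = alphabet_size
    codes = [np.zeros(N, dtype=np.int64)]
    for k in range(1, max_depth + 1):
        c = np.zeros(N, dtype=np.int64)
        if N > 0:
            c[k:] = seq[k - 1:N - 1] + A * codes[k - 1][k - 1:N - 1]
        codes.append(c)
    return codes


def _level_counts(seq, codes, k, alphabet_size):
    """Unsmoothed context->next-symbol count rows for contexts of length k."""
    A = alphabet_size
    N = seq.size
    if N <= k:
        return np.empty(0, dtype=np.int64), np.empty((0, A))
    joint = codes[k][k:] * A + seq[k:]
    uniq, cnt = np.unique(joint, return_counts=True)
    ctx = uniq // A
    sym = uniq % A
    ctx_codes, inverse = np.unique(ctx, return_inverse=True)
    rows = np.zeros((ctx_codes.size, A))
    rows[inverse, sym] = cnt
    return ctx_codes, rows


@dataclass
class VLMCModel:
    """A fitted context tree with smoothed conditional next-symbol probabilities.

    ``levels[k]`` holds the stored contexts of length ``k`` as a sorted array
    of integer codes and the aligned matrix of conditional probability rows.
    """

    alphabet_size: int
    max_depth: int
    gamma: float
    levels: dict[int, tuple[np.ndarray, np.ndarray]]
    hyperparams: dict = field(default_factory=dict)
    train_length: int = 0

    # -- context bookkeeping -------------------------------------------------
    def decode(self, code: int, k: int) -> tuple[int, ...]:
        """Context tuple (oldest .. most recent) for an integer code."""
        out = []
        for _ in range(k):
            out.append(int(code % self.alphabet_size))
            code //= self.alphabet_size
        return tuple(reversed(out))

    def encode(self, context: tuple[int, ...]) -> int:
        code = 0
        for s in context:
            code = code * self.alphabet_size + int(s)
        return code

    def contexts(self) -> list[tuple[int, ...]]:
        out = []
        for k in sorted(self.levels):
            out.extend(self.decode(c, k) for c in self.levels[k][0])
        return out

    @property
    def n_contexts(self) -> int:
        return sum(c.size for c, _ in self.levels.values())

    # -- evaluation ----------------------------------------------------------
    def cond_row(self, history: tuple[int, ...] | list[int] | np.ndarray) -> np.ndarray:
        """Conditional distribution given a history, via its longest stored suffix."""
        h = tuple(int(s) for s in history)
        for k in range(min(self.max_depth, len(h)), 0, -1):
            codes, rows = self.levels.get(k, (None, None))
            if codes is None or codes.size == 0:
                continue
            code = self.encode(h[-k:])
            idx = np.searchsorted(codes, code)
            if idx < codes.size and codes[idx] == code:
                return rows[idx]
        return self.levels[0][1][0]

    def cond_probs(self, sequence: np.ndarray) -> np.ndarray:
        """P(s_i | longest stored suffix of s_1..s_{i-1}) for every position."""
        seq = np.asarray(sequence, dtype=np.int64)
        N = seq.size
        if N == 0:
            return np.empty(0)
        if seq.min(initial=0) < 0 or seq.max(initial=0) >= self.alphabet_size:
            raise ValueError("sequence symbol outside model alphabet")
        codes = _context_codes(seq, self.alphabet_size, self.max_depth)
        probs = np.empty(N)
        unassigned = np.ones(N, dtype=bool)
        for k in range(self.max_depth, 0, -1):
            lv = self.levels.get(k)
            if lv is None or lv[0].size == 0:
                continue
            ctx_codes, rows = lv
            pos = np.flatnonzero(unassigned)
            pos = pos[pos >= k]
            if pos.size == 0:
                continue
            c = codes[k][pos]
            idx = np.searchsorted(ctx_codes, c)
            idx_c = np.clip(idx, 0, ctx_codes.size - 1)
            hit = ctx_codes[idx_c] == c
            p = pos[hit]
            probs[p] = rows[idx_c[hit], seq[p]]
            unassigned[p] = False
        rest = np.flatnonzero(unassigned)
        probs[rest] = self.levels[0][1][0][seq[rest]]
        return probs

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        ctx_map = {}
        for k in sorted(self.levels):
            codes, rows = self.levels[k]
            for c, row in zip(codes, rows):
                key = " ".join(str(s) for s in self.decode(int(c), k))
                ctx_map[key] = [float(x) for x in row]
        return {
            "alphabet_size": self.alphabet_size,
            "max_depth": self.max_depth,
            "gamma": self.gamma,
            "hyperparams": self.hyperparams,
            "train_length": self.train_length,
            "contexts": ctx_map,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VLMCModel":
        A = int(d["alphabet_size"])
        tmp = cls(A, int(d["max_depth"]), float(d["gamma"]), {}, d.get("hyperparams", {}),
                  int(d.get("train_length", 0)))
        by_level: dict[int, list[tuple[int, list[float]]]] = {}
        for key, row in d["contexts"].items():
            ctx = tuple(int(s) for s in key.split()) if key else ()
            by_level.setdefault(len(ctx), []).append((tmp.encode(ctx), row))
        levels = {}
        for k, items in by_level.items():
            items.sort()
            codes = np.array([c for c, _ in items], dtype=np.int64)
            rows = np.array([r for _, r in items])
            levels[k] = (codes, rows)
        tmp.levels = levels
        return tmp


def fit_pst(
    sequence: np.ndarray,
    max_depth: int,
    p_min: float = P_MIN_DEFAULT,
    gamma: float = GAMMA_DEFAULT,
    r: float = R_DEFAULT,
    alphabet_size: int | None = None,
    prune: bool = True,
) -> VLMCModel:
    """Fit a VLMC of maximum depth ``max_depth`` to an integer sequence.

    With ``prune=False`` every observed context up to ``max_depth`` is kept and
    the conditionals equal the empirical d-gram frequencies (up to the
    smoothing floor); with pruning, a context of length k is kept only if its
    frequency reaches ``p_min`` and some next-symbol probability is at least
    ``gamma`` while differing from the length-(k-1) suffix's prediction by a
    factor of at least ``r``.  Suffixes of kept contexts are always stored
    (tree property).
    """
    seq = np.asarray(sequence, dtype=np.int64)
    if seq.size == 0:
        raise ValueError("cannot fit a model to an empty sequence")
    if seq.min() < 0:
        raise ValueError("symbols must be non-negative integers")
    A = alphabet_size if alphabet_size is not None else int(seq.max()) + 1
    if seq.max() >= A:
        raise ValueError("sequence symbol outside alphabet {0..C}")
    if not (0 <= p_min < 1):
        raise ValueError("p_min must be in [0, 1)")
    if not (0 < gamma < 1.0 / A):
        raise ValueError("gamma must be in (0, 1/|S|)")
    if r <= 1:
        raise ValueError("r must exceed 1")
    N = seq.size

    codes = _context_codes(seq, A, max_depth)
    raw: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(max_depth + 1):
        raw[k] = _level_counts(seq, codes, k, A)

    # retained context codes per level
    kept: dict[int, set[int]] = {0: {0}}
    parent_rows = {int(c): row / row.sum() for c, row in zip(*raw[0])}
    for k in range(1, max_depth + 1):
        ctx_codes, rows = raw[k]
        kept[k] = set()
        if ctx_codes.size == 0:
            parent_rows = {}
            continue
        totals = rows.sum(axis=1)
        phat = rows / totals[:, None]
        level_rows = {}
        for c, tot, p in zip(ctx_codes, totals, phat):
            c = int(c)
            level_rows[c] = p
            if prune:
                if tot / max(N - k, 1) < p_min:
                    continue
                parent = parent_rows.get(c % (A ** (k - 1)))
                if parent is None:
                    continue
                with np.errstate(divide="ignore", invalid="ignore"):
                    ratio = np.where(parent > 0, p / np.where(parent > 0, parent, 1.0), np.inf)
                ok = (p >= gamma) & ((ratio >= r) | (ratio <= 1.0 / r))
                if not np.any(ok):
                    continue
            kept[k].add(c)
        parent_rows = level_rows

    # tree closure: every suffix of a kept context is stored
    for k in range(max_depth, 1, -1):
        for c in kept[k]:
            kept[k - 1].add(c % (A ** (k - 1)))

    levels: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for k in range(max_depth + 1):
        ctx_codes, rows = raw[k]
        if k == 0:
            sel = np.arange(ctx_codes.size)
        else:
            keep = kept[k]
            sel = np.array([i for i, c in enumerate(ctx_codes) if int(c) in keep], dtype=int)
        codes_k = ctx_codes[sel] if sel.size else np.empty(0, dtype=np.int64)
        if sel.size:
            counts_k = rows[sel]
            phat = counts_k / counts_k.sum(axis=1, keepdims=True)
            smoothed = (1.0 - A * gamma) * phat + gamma
        else:
            smoothed = np.empty((0, A))
        levels[k] = (codes_k, smoothed)

    return VLMCModel(
        alphabet_size=A,
        max_depth=max_depth,
        gamma=gamma,
        levels=levels,
        hyperparams={"p_min": p_min, "gamma": gamma, "r": r, "prune": prune},
        train_length=N,
    )


def log_loss(model, sequence: np.ndarray) -> float:
    """Average negative log2 conditional probability of the sequence, in bits."""
    seq = np.asarray(sequence, dtype=np.int64)
    if seq.size == 0:
        raise ValueError("log-loss undefined for an empty sequence")
    probs = model.cond_probs(seq)
    return float(-np.mean(np.log2(probs)))


def _snap_fold_boundaries(seq: np.ndarray, folds: int) -> list[tuple[int, int]]:
    """Contiguous fold blocks with boundaries snapped to word breaks.

    A cut at position p splits a burst word iff both neighbors are nonzero, so
    admissible cuts are positions where either neighbor is the silence symbol.
    """
    N = seq.size
    naive = [round(j * N / folds) for j in range(1, folds)]
    admissible = np.flatnonzero((seq[1:] == 0) | (seq[:-1] == 0)) + 1
    cuts = []
    for b in naive:
        if admissible.size:
            i = np.searchsorted(admissible, b)
            cands = []
            if i > 0:
                cands.append(admissible[i - 1])
            if i < admissible.size:
                cands.append(admissible[i])
            b = int(min(cands, key=lambda c: abs(c - b)))
        cuts.append(b)
    bounds = [0] + cuts + [N]
    bounds = sorted(set(bounds))
    if len(bounds) != folds + 1:  # snapping collapsed folds; fall back to naive
        bounds = [0] + naive + [N]
    return [(bounds[i], bounds[i + 1]) for i in range(folds)]


@dataclass
class CVResult:
    depths: list[int]
    fold_spans: list[tuple[int, int]]
    losses: np.ndarray        # (n_depths, n_folds) held-out log-losses
    avg_losses: np.ndarray    # L_d
    seq_information: np.ndarray   # I_d = L_0 - L_d
    normalized_information: np.ndarray  # NI_d = I_d / I_opt
    selected_depth: int

    @property
    def L_opt(self) -> float:
        return float(self.avg_losses.min())


def cross_validate(
    sequence: np.ndarray,
    depths=range(6),
    folds: int = 10,
    p_min: float = P_MIN_DEFAULT,
    gamma: float = GAMMA_DEFAULT,
    r: float = R_DEFAULT,
    alphabet_size: int | None = None,
    prune: bool = True,
) -> CVResult:
    """Select model depth by k-fold cross-validated log-loss.

    Folds are contiguous blocks of the sequence with boundaries snapped to
    word breaks so no burst word is split; each fold's model is fit on the
    concatenation of the other blocks.  ``I_d`` and ``NI_d`` follow from the
    per-depth average held-out losses; the selected depth is the argmin (ties
    resolved toward the shallower model).
    """
    seq = np.asarray(sequence, dtype=np.int64)
    depths = list(depths)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    if seq.size < folds:
        raise ValueError("fewer symbols than folds")
    A = alphabet_size if alphabet_size is not None else int(seq.max()) + 1
    spans = _snap_fold_boundaries(seq, folds)
    losses = np.empty((len(depths), len(spans)))
    for j, (a, b) in enumerate(spans):
        train = np.concatenate([seq[:a], seq[b:]])
        test = seq[a:b]
        for i, d in enumerate(depths):
            m = fit_pst(train, d, p_min=p_min, gamma=gamma, r=r,
                        alphabet_size=A, prune=prune)
            losses[i, j] = log_loss(m, test)
    avg = losses.mean(axis=1)
    i0 = depths.index(0) if 0 in depths else 0
    info = avg[i0] - avg
    i_opt = info.max()
    if i_opt > 0:
        ni = info / i_opt
    else:
        ni = np.zeros_like(info)
    sel = int(depths[int(np.argmin(avg))])
    return CVResult(
        depths=depths,
        fold_spans=spans,
        losses=losses,
        avg_losses=avg,
        seq_information=info,
        normalized_information=ni,
        selected_depth=sel,
    )


def fit_fold_models(
    sequence: np.ndarray,
    depth: int,
    fold_spans: list[tuple[int, int]],
    p_min: float = P_MIN_DEFAULT,
    gamma: float = GAMMA_DEFAULT,
    r: float = R_DEFAULT,
    alphabet_size: int | None = None,
    prune: bool = True,
) -> list[tuple[VLMCModel, np.ndarray]]:
    """Refit the per-fold models at one depth; returns (model, training seq) pairs."""
    seq = np.asarray(sequence, dtype=np.int64)
    A = alphabet_size if alphabet_size is not None else int(seq.max()) + 1
    out = []
    for a, b in fold_spans:
        train = np.concatenate([seq[:a], seq[b:]])
        m = fit_pst(train, depth, p_min=p_min, gamma=gamma, r=r,
                    alphabet_size=A, prune=prune)
        out.append((m, train))
    return out


def scramble_bursts(sequence: np.ndarray, seed: int | np.random.Generator) -> np.ndarray:
    """Permute the nonzero symbols among their positions, fixing every '0'.

    Preserves each neuron's burst count and the full avalanche/silence
    structure while destroying all sequential correlations between bursts.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    seq = np.asarray(sequence, dtype=np.int64).copy()
    idx = np.flatnonzero(seq != 0)
    seq[idx] = rng.permutation(seq[idx])
    return seq


def stationary_context_distribution(model, tol: float = 1e-12, max_iter: int = 100_000):
    """Stationary distribution over the order-d state space of the model.

    The VLMC of depth d is embedded in the equivalent order-d chain over all
    ``A**d`` d-grams (smoothing makes the chain irreducible); the stationary
    distribution is found by power iteration.  Returns (pi, trans_rows,
    next_state) where ``trans_rows[g, s]`` is P(s | g) and ``next_state[g, s]``
    the successor d-gram.
    """
    A = model.alphabet_size
    d = model.max_depth
    S = A ** d
    if S > 300_000:
        raise ValueError("state space too large for stationary computation")
    trans = np.empty((S, A))
    nxt = np.empty((S, A), dtype=np.int64)
    for g in range(S):
        # decode d-gram code: low digit = most recent symbol
        ctx = []
        c = g
        for _ in range(d):
            ctx.append(c % A)
            c //= A
        ctx = tuple(reversed(ctx))
        trans[g] = model.cond_row(ctx)
        nxt[g] = (g * A) % S + np.arange(A) if d > 0 else 0
    if d == 0:
        return np.ones(1), trans, nxt
    pi = np.full(S, 1.0 / S)
    for _ in range(max_iter):
        new = np.zeros(S)
        np.add.at(new, nxt.ravel(), (pi[:, None] * trans).ravel())
        if np.abs(new - pi).sum() < tol:
            pi = new
            break
        pi = new
    return pi, trans, nxt


def word_rate(model, word: np.ndarray, _cache: dict | None = None) -> float:
    """Per-symbol stationary occurrence rate of ``word`` under the model."""
    word = np.asarray(word, dtype=np.int64)
    if word.size == 0:
        return 1.0
    A = model.alphabet_size
    if word.min() < 0 or word.max() >= A:
        raise ValueError("word contains a symbol outside the model alphabet")
    d = model.max_depth
    if d == 0:
        return float(np.prod(model.levels[0][1][0][word]))
    if _cache is not None and "stationary" in _cache:
        pi, trans, nxt = _cache["stationary"]
    else:
        pi, trans, nxt = stationary_context_distribution(model)
        if _cache is not None:
            _cache["stationary"] = (pi, trans, nxt)
    S = pi.size
    v = pi.copy()
    for s in word:
        new = np.zeros(S)
        np.add.at(new, nxt[:, s], v * trans[:, s])
        v = new
    return float(v.sum())


def predicted_word_frequencies(model, words, sequence_length: int | None = None) -> np.ndarray:
    """Expected occurrence counts of each word under the model's stationary law.

    Expected count = training-sequence length times the per-symbol stationary
    occurrence rate of the word.
    """
    N = sequence_length if sequence_length is not None else model.train_length
    cache: dict = {}
    return np.array([N * word_rate(model, w, _cache=cache) for w in words])
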