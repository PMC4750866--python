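"""RUN-optimal Markov chains: maximal sequence rates under rate constraints.

Given the measured symbol frequencies (including silence) and the measured
silence self-transition probability, the RUN-optimal chain is the first-order
chain maximizing the stationary occurrence rate of the RUN sequence,

    rate(s) = pi(s_1) * prod_k P(s_{k+1} | s_k),

the expected number of (possibly overlapping) occurrences per symbol
position.  The AIM built from the same rates satisfies the constraints, so
the maximal rate r_max is never below the independent rate r_AIM; the fitted
model's rate r_fit sits in between whenever the data carry genuine
sequential enrichment.

The problem is non-convex (the stationarity constraint couples all rows), so
the maximization runs SLSQP from multiple starts — always including the AIM
itself — and keeps the best feasible solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .enrichment import AIMModel
from .vlmc import word_rate


@dataclass
class TransitionChain:
    """A first-order chain with its stationary distribution."""

    matrix: np.ndarray
    stationary: np.ndarray

    def __post_init__(self) -> None:
        P = np.asarray(self.matrix, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if np.any(P < -1e-12):
            raise ValueError("transition matrix entries must be non-negative")
        if np.max(np.abs(P.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("rows must sum to 1 within 1e-9")
        if np.max(np.abs(pi @ P - pi)) > 1e-8:
            raise ValueError("stationary distribution residual exceeds 1e-8")
        self.matrix = P
        self.stationary = pi

    @property
    def alphabet_size(self) -> int:
        return self.matrix.shape[0]

    def to_dict(self) -> dict:
        return {"matrix": self.matrix.tolist(), "stationary": self.stationary.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "TransitionChain":
        return cls(np.asarray(d["matrix"]), np.asarray(d["stationary"]))


def chain_from_aim(aim: AIMModel) -> TransitionChain:
    return TransitionChain(aim.transition_matrix, aim.stationary())


def sequence_rate(chain: TransitionChain, seq) -> float:
    """Expected overlapping occurrences of ``seq`` per symbol position."""
    s = [int(x) for x in seq]
    if not s:
        raise ValueError("sequence must be nonempty")
    rate = float(chain.stationary[s[0]])
    for a, b in zip(s[:-1], s[1:]):
        rate *= float(chain.matrix[a, b])
    return rate


def aim_from_targets(pi_target: np.ndarray, p00_target: float) -> np.ndarray:
    """The AIM-structured matrix with the given stationary law and P(0|0).

    Burst rates are the stationary masses renormalized over cells; Pb0
    follows from stationarity of the silence symbol.
    """
    pi = np.asarray(pi_target, dtype=float)
    A = pi.size
    pi0 = pi[0]
    if not (0 < pi0 < 1):
        raise ValueError("silence must have stationary mass strictly in (0,1)")
    rates = pi[1:] / (1.0 - pi0)
    pb0 = pi0 * (1.0 - p00_target) / (1.0 - pi0)
    if pb0 > 1.0 + 1e-12:
        raise ValueError("infeasible constraints: implied Pb0 exceeds 1")
    pb0 = min(pb0, 1.0)
    P = np.zeros((A, A))
    P[0, 0] = p00_target
    P[0, 1:] = (1.0 - p00_target) * rates
    P[1:, 0] = pb0
    P[1:, 1:] = (1.0 - pb0) * rates[None, :]
    return P


def optimize_run_chain(
    pi_target: np.ndarray,
    p00_target: float,
    run_sequence,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 400,
) -> tuple[TransitionChain, float, bool]:
    """Maximize the RUN-sequence rate over chains with fixed pi and P(0|0).

    Returns (best chain, r_max, converged).  ``converged`` is False when no
    optimizer start improved on the feasible AIM baseline (the AIM is always
    retained as a candidate, so r_max >= r_AIM).
    """
    pi = np.asarray(pi_target, dtype=float)
    if np.any(pi <= 0) or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("pi_target must be a strictly positive probability vector")
    seq = [int(x) for x in run_sequence]
    A = pi.size
    aim_P = aim_from_targets(pi, p00_target)
    if len(seq) == 1:
        return TransitionChain(aim_P, pi), float(pi[seq[0]]), True

    path = list(zip(seq[:-1], seq[1:]))
    flat_path = [a * A + b for a, b in path]
    floor = 1e-12

    def objective(x):
        P = x.reshape(A, A)
        vals = np.array([x[i] for i in flat_path])
        vals = np.maximum(vals, floor)
        f = -np.sum(np.log(vals))
        g = np.zeros_like(x)
        for i, v in zip(flat_path, vals):
            g[i] += -1.0 / v
        return f, g

    # row sums plus stationarity at symbols 1..A-1; the silence component is
    # implied by the others (full set is rank deficient and stalls SLSQP),
    # and P(0|0) is pinned through its bounds
    def row_sums(x):
        return x.reshape(A, A).sum(axis=1) - 1.0

    def row_sums_jac(x):
        J = np.zeros((A, A * A))
        for i in range(A):
            J[i, i * A:(i + 1) * A] = 1.0
        return J

    def stat_con(x):
        P = x.reshape(A, A)
        return (pi @ P - pi)[1:]

    def stat_jac(x):
        J = np.zeros((A - 1, A * A))
        for j in range(1, A):
            for i in range(A):
                J[j - 1, i * A + j] = pi[i]
        return J

    constraints = [
        {"type": "eq", "fun": row_sums, "jac": row_sums_jac},
        {"type": "eq", "fun": stat_con, "jac": stat_jac},
    ]
    bounds = [(0.0, 1.0)] * (A * A)
    bounds[0] = (p00_target, p00_target)
    rng = np.random.default_rng(seed)

    def greedy_start():
        # pile mass on the RUN path, then mix with the AIM for feasibility slack
        P = 0.3 * aim_P + 0.7 * np.full((A, A), 1.0 / A)
        for a, b in path:
            P[a] = P[a] * 0.2
            P[a, b] += 0.8
        P /= P.sum(axis=1, keepdims=True)
        return P

    starts = [aim_P, greedy_start()]
    while len(starts) < n_restarts:
        starts.append(rng.dirichlet(np.ones(A), size=A))

    def exact_stationary(P):
        vals, vecs = np.linalg.eig(P.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        v = np.abs(np.real(vecs[:, i]))
        return v / v.sum()

    def repair(x):
        # project back onto the simplex rows (holding P(0|0) fixed), then
        # insist the chain's exact stationary law matches the target to 1e-6
        P = np.clip(x.reshape(A, A), 0.0, None)
        rest = P[0, 1:].sum()
        if rest <= 0:
            return None
        P[0, 0] = p00_target
        P[0, 1:] *= (1.0 - p00_target) / rest
        sums = P[1:].sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            return None
        P[1:] /= sums
        if np.max(np.abs(pi @ P - pi)) > 1e-6:
            return None
        st = exact_stationary(P)
        if np.max(np.abs(st - pi)) > 1e-6:
            return None
        return P, st

    best_P, best_pi, best_rate = aim_P, pi, _path_rate(aim_P, pi, seq)
    improved = False
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective, x0.ravel(), jac=True, bounds=bounds,
                constraints=constraints, method="SLSQP",
                options={"maxiter": max_iter, "ftol": tol},
            )
        rep = repair(res.x)
        if rep is None:
            continue
        P, st = rep
        rate = _path_rate(P, st, seq)
        if rate > best_rate:
            best_P, best_pi, best_rate, improved = P, st, rate, True
    if not improved:
        warnings.warn("optimizer did not improve on the AIM baseline; "
                      "reporting best found", RuntimeWarning)
    return TransitionChain(best_P, best_pi), float(best_rate), improved


def _path_rate(P: np.ndarray, pi: np.ndarray, seq: list[int]) -> float:
    rate = pi[seq[0]]
    for a, b in zip(seq[:-1], seq[1:]):
        rate *= P[a, b]
    return float(rate)


@dataclass
class RateTable:
    r_aim: float
    r_fit: float
    r_max: float

    @property
    def fit_over_aim(self) -> float:
        return self.r_fit / self.r_aim

    @property
    def max_over_aim(self) -> float:
        return self.r_max / self.r_aim


def rate_table(aim: AIMModel, fitted, optimal: TransitionChain, run_sequence) -> RateTable:
    """r_AIM, r_fit, r_max and their ratios for one RUN sequence.

    r_fit comes from the fitted VLMC's stationary context distribution;
    r_AIM and r_max from the closed-form first-order rate.
    """
    seq = [int(x) for x in run_sequence]
    r_aim = sequence_rate(chain_from_aim(aim), seq)
    r_fit = word_rate(fitted, np.asarray(seq))
    r_max = sequence_rate(optimal, seq)
    return RateTable(r_aim=r_aim, r_fit=r_fit, r_max=r_max)
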