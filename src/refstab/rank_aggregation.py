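"""Consensus ranking by cross-entropy Monte Carlo rank aggregation.

Given several full-length orderings of the same gene set (one per stability
algorithm), the consensus is the permutation minimizing the total (weighted)
Spearman footrule distance to the inputs.  The optimizer is a cross-entropy
Monte Carlo scheme over a gene x position probability matrix; for small
panels an exhaustive enumeration provides the exact optimum.

The footrule objective makes the problem a linear assignment in disguise
(cost of putting gene g at position j is sum_l w_l * |j - pos_l(g)|), which
is what makes independent verification of the stochastic optimizer easy.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ConsensusRanking",
    "footrule_distance",
    "kendall_distance",
    "aggregate_ce",
    "aggregate_exhaustive",
]

MAX_EXHAUSTIVE = 8


@dataclass
class ConsensusRanking:
    """Aggregated ordering with its footrule objective value."""

    ranking: list[str]
    objective: float
    n_iterations: int
    converged: bool
    seed: int | None = None


def _check_universe(lists: Sequence[Sequence[str]]) -> list[str]:
    if len(lists) < 2:
        raise ValueError("rank aggregation needs >=2 input lists")
    universe = list(lists[0])
    uset = set(universe)
    if len(uset) != len(universe):
        raise ValueError("input list contains duplicate genes")
    for l in lists[1:]:
        if set(l) != uset or len(l) != len(universe):
            raise ValueError("input lists cover different gene universes")
    return universe


def footrule_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Spearman footrule: sum over genes of |pos_a(g) - pos_b(g)| (1-based)."""
    if set(a) != set(b) or len(a) != len(b) or len(set(a)) != len(a):
        raise ValueError("rankings must be permutations of the same set")
    pos_b = {g: i for i, g in enumerate(b)}
    return int(sum(abs(i - pos_b[g]) for i, g in enumerate(a)))


def kendall_distance(a: Sequence[str], b: Sequence[str]) -> int:
    """Number of discordant pairs between two permutations."""
    if set(a) != set(b) or len(a) != len(b) or len(set(a)) != len(a):
        raise ValueError("rankings must be permutations of the same set")
    pos_b = {g: i for i, g in enumerate(b)}
    seq = [pos_b[g] for g in a]
    return int(
        sum(1 for i, j in itertools.combinations(range(len(seq)), 2) if seq[i] > seq[j])
    )


def _positions(lists: Sequence[Sequence[str]], universe: list[str]) -> np.ndarray:
    """L x n matrix: positions[l, gene_index] = 0-based rank in list l."""
    idx = {g: i for i, g in enumerate(universe)}
    out = np.empty((len(lists), len(universe)), dtype=np.intp)
    for li, l in enumerate(lists):
        for j, g in enumerate(l):
            out[li, idx[g]] = j
    return out


def _objective_matrix(pos: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """n x n cost matrix C[g, j] = sum_l w_l |j - pos_l(g)| (footrule only)."""
    n = pos.shape[1]
    j = np.arange(n)
    # |j - pos| -> L x n x n, weighted sum over lists
    diff = np.abs(j[None, None, :] - pos[:, :, None])
    return np.einsum("l,lgj->gj", weights, diff)


def _score_perms(perms: np.ndarray, pos: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted footrule objective for each candidate permutation.

    ``perms`` is (N, n) of gene indices in rank order.
    """
    n_cand, n = perms.shape
    rows = np.arange(n_cand)[:, None]
    cand_pos = np.empty_like(perms)
    cand_pos[rows, perms] = np.arange(n)[None, :]
    obj = np.zeros(n_cand)
    for w, p in zip(weights, pos):
        obj += w * np.abs(cand_pos - p[None, :]).sum(axis=1)
    return obj


def _sample_perms(p: np.ndarray, n_samples: int, rng: np.random.Generator) -> np.ndarray:
    """Sample permutations position-by-position without replacement.

    At each position the row of the probability matrix is restricted to the
    still-unassigned genes and renormalized; a degenerate row falls back to
    uniform over the remaining genes.
    """
    n = p.shape[0]
    perms = np.empty((n_samples, n), dtype=np.intp)
    avail = np.ones((n_samples, n), dtype=bool)
    rows = np.arange(n_samples)
    for j in range(n):
        w = p[:, j][None, :] * avail
        tot = w.sum(axis=1)
        deg = tot <= 0
        if deg.any():
            w[deg] = avail[deg]
            tot = w.sum(axis=1)
        c = np.cumsum(w, axis=1)
        u = rng.random(n_samples) * tot
        g = (u[:, None] >= c).sum(axis=1)
        np.minimum(g, n - 1, out=g)
        perms[:, j] = g
        avail[rows, g] = False
    return perms


def aggregate_ce(
    lists: Sequence[Sequence[str]],
    weights: Sequence[float] | None = None,
    *,
    seed: int | None = None,
    samples_per_iter: int | None = None,
    rho: float = 0.1,
    smoothing: float = 0.25,
    stagnation_limit: int = 15,
    max_iterations: int = 200,
) -> ConsensusRanking:
    """Cross-entropy Monte Carlo minimization of the total footrule distance.

    A gene x position probability matrix starts uniform; each iteration
    samples ``samples_per_iter`` candidate permutations, re-estimates the
    matrix from the elite ``rho`` fraction, and blends it with the previous
    matrix (``smoothing`` is the weight retained by the old matrix).  The
    input lists themselves are injected into the first candidate pool, so
    the returned consensus can never score worse than any input.  Stops
    after ``stagnation_limit`` iterations without improvement.

    Bit-reproducible for a fixed ``seed``.
    """
    universe = _check_universe(lists)
    n = len(universe)
    n_lists = len(lists)
    w = np.ones(n_lists) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n_lists,):
        raise ValueError("weights must match the number of input lists")
    if samples_per_iter is None:
        samples_per_iter = max(2000, 40 * n)
    rng = np.random.default_rng(seed)
    pos = _positions(lists, universe)

    if n == 1:
        return ConsensusRanking([universe[0]], 0.0, 0, True, seed)

    p = np.full((n, n), 1.0 / n)
    n_elite = max(1, int(np.ceil(rho * samples_per_iter)))
    best_perm: np.ndarray | None = None
    best_obj = np.inf
    stagnant = 0
    it = 0
    converged = False
    for it in range(1, max_iterations + 1):
        perms = _sample_perms(p, samples_per_iter, rng)
        if it == 1:
            perms = np.vstack([pos.argsort(axis=1, kind="stable"), perms])
        obj = _score_perms(perms, pos, w)
        order = np.argsort(obj, kind="stable")
        elite = perms[order[:n_elite]]
        if obj[order[0]] < best_obj - 1e-12:
            best_obj = float(obj[order[0]])
            best_perm = perms[order[0]].copy()
            stagnant = 0
        else:
            stagnant += 1
            if stagnant >= stagnation_limit:
                converged = True
                break
        freq = np.zeros((n, n))
        cols = np.arange(n)
        for e in elite:
            freq[e, cols] += 1.0
        freq /= n_elite
        p = smoothing * p + (1.0 - smoothing) * freq

    assert best_perm is not None
    ranking = [universe[i] for i in best_perm]
    return ConsensusRanking(
        ranking=ranking,
        objective=float(best_obj),
        n_iterations=it,
        converged=converged,
        seed=seed,
    )


def aggregate_exhaustive(
    lists: Sequence[Sequence[str]],
    weights: Sequence[float] | None = None,
) -> ConsensusRanking:
    """Global footrule optimum by full permutation enumeration (n <= 8).

    Permutations are visited in lexicographic order of gene input order and
    only a strictly better objective replaces the incumbent, so ties break
    deterministically toward the lexicographically first optimum.
    """
    universe = _check_universe(lists)
    n = len(universe)
    if n > MAX_EXHAUSTIVE:
        raise ValueError(
            f"{n} genes is too many for exhaustive enumeration "
            f"(limit {MAX_EXHAUSTIVE}); use aggregate_ce"
        )
    n_lists = len(lists)
    w = np.ones(n_lists) if weights is None else np.asarray(weights, dtype=float)
    pos = _positions(lists, universe)
    cost = _objective_matrix(pos, w)  # cost[g, j]
    best_obj = np.inf
    best: tuple[int, ...] | None = None
    cols = np.arange(n)
    for perm in itertools.permutations(range(n)):
        o = cost[perm, cols].sum()
        if o < best_obj - 1e-12:
            best_obj = float(o)
            best = perm
    assert best is not None
    return ConsensusRanking(
        ranking=[universe[i] for i in best],
        objective=float(best_obj),
        n_iterations=0,
        converged=True,
        seed=None,
    )
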