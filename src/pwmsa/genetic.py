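"""Genetic-algorithm optimization of PWM populations.

A population of random PWMs ("organisms") is evolved under the objective
``mF`` — the summed global alignment scores of every input sequence
against the matrix.  Each generation the matrices are ranked, the best one
is preserved unchanged (elitism), the two worst are discarded and replaced
by two children made by one-point column crossover of rank-selected
parents, and a batch of non-elite, non-child matrices receives a point
mutation (one cell redrawn uniformly).  Every new or edited matrix is
re-normalized to the common (R^2, K_d) scale before scoring, so the
population stays comparable.  Evolution stops once the best objective has
not improved for a fixed window of generations.

Because the sequences in a set differ in length, the matrix length is not
known a priori: the whole evolution is repeated for every candidate length
in a band around the mean sequence length and the best (matrix, length)
pair wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .align import _score_only
from .io import SequenceSet
from .pwm import ScoringParams, WeightMatrix, build_random_pwm, transform_pwm

logger = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass(frozen=True)
class GAConfig:
    """Knobs of the evolutionary search.

    Defaults reproduce the full-scale configuration (population 500, 50
    point mutations per generation, mutated cells redrawn uniformly on
    [-10, 10], stop after 10 stagnant generations, matrix lengths scanned
    over +/-10% of the mean sequence length in steps of 1).  ``fast``
    builds a reduced desk-scale preset.
    """

    population_size: int = 500
    mutants_per_generation: int = 50
    mutation_low: float = -10.0
    mutation_high: float = 10.0
    stagnation_window: int = 10
    length_span: float = 0.10
    length_step: int = 1
    k_random: int = 1000  # multinomial draws per column for random PWMs
    max_generations: int | None = None  # hard cap; None = stop rule only

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.stagnation_window < 1:
            raise ValueError("stagnation_window must be >= 1")
        if self.mutation_high <= self.mutation_low:
            raise ValueError("empty mutation range")
        if not (0.0 <= self.length_span < 1.0):
            raise ValueError("length_span must be in [0, 1)")
        if self.length_step < 1:
            raise ValueError("length_step must be >= 1")

    @classmethod
    def fast(cls, mean_length: float | None = None, **overrides) -> "GAConfig":
        """Desk-scale preset: small population, coarse length scan.

        The stagnation window is widened to 50 generations so that the
        patience before stopping, measured in point-mutation trials, stays
        at the full configuration's 500 (10 generations x 50 mutants
        there, 50 x 10 here); a hard generation cap bounds the wall time
        of signal-rich searches that would otherwise keep improving.
        """
        step = 1 if mean_length is None else max(1, round(0.02 * mean_length))
        base = dict(population_size=50, mutants_per_generation=10,
                    stagnation_window=50, length_step=step, k_random=100,
                    max_generations=120)
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class GAResult:
    """Outcome of the length scan: the winning matrix and its provenance."""

    best_pwm: WeightMatrix
    best_length: int
    best_objective: float
    generations_run: int
    objective_trace: tuple[float, ...]


def _rank_weights(objectives: np.ndarray) -> np.ndarray:
    """Linear rank weights (best gets P, worst gets 1), ties averaged.

    Averaging tied ranks makes equal-scoring matrices equally likely, so a
    flat population is sampled uniformly.
    """
    p = len(objectives)
    order = np.argsort(-objectives, kind="stable")
    ranks = np.empty(p, dtype=float)
    pos = 0
    while pos < p:
        end = pos
        while end + 1 < p and objectives[order[end + 1]] == objectives[order[pos]]:
            end += 1
        mean_rank = (pos + end) / 2.0 + 1.0  # 1-based
        for t in range(pos, end + 1):
            ranks[order[t]] = mean_rank
        pos = end + 1
    return p - ranks + 1.0


def select_parent(population: list[WeightMatrix], objectives: np.ndarray,
                  rng: np.random.Generator) -> WeightMatrix:
    """Rank-based selection: higher mF means strictly higher probability."""
    weights = _rank_weights(np.asarray(objectives, dtype=float))
    probs = weights / weights.sum()
    return population[rng.choice(len(population), p=probs)]


def _select_index(objectives: np.ndarray, rng: np.random.Generator) -> int:
    weights = _rank_weights(objectives)
    return int(rng.choice(len(objectives), p=weights / weights.sum()))


def crossover(parent_a: WeightMatrix, parent_b: WeightMatrix,
              rng: np.random.Generator,
              params: ScoringParams | None = None) -> WeightMatrix:
    """One-point column crossover ("gluing") with re-normalization.

    A cut point c is drawn uniformly on 1..L-1; the child takes columns
    [0, c) from parent_a and [c, L) from parent_b.  With a single column no
    cut exists and the child is a copy of a randomly chosen parent.
    """
    L = parent_a.n_columns
    if parent_b.n_columns != L:
        raise ValueError("parents must have equal column counts")
    if L == 1:
        pick = parent_a if rng.integers(2) == 0 else parent_b
        child = WeightMatrix(pick.weights.copy(), pick.p1, pick.p2)
    else:
        c = int(rng.integers(1, L))
        glued = np.concatenate(
            [parent_a.weights[:, :c], parent_b.weights[:, c:]], axis=1
        )
        child = WeightMatrix(glued, parent_a.p1, parent_a.p2)
    if params is not None:
        child = transform_pwm(child, params)
    return child


def _mutate(w: WeightMatrix, cfg: GAConfig, params: ScoringParams,
            rng: np.random.Generator) -> WeightMatrix:
    """Replace one random cell with a uniform draw, then re-normalize."""
    edited = w.weights.copy()
    i = int(rng.integers(edited.shape[0]))
    j = int(rng.integers(edited.shape[1]))
    edited[i, j] = rng.uniform(cfg.mutation_low, cfg.mutation_high)
    return transform_pwm(WeightMatrix(edited, w.p1, w.p2), params)


def evolve_population(si: SequenceSet, n_columns: int, params: ScoringParams,
                      cfg: GAConfig, rng: np.random.Generator
                      ) -> tuple[WeightMatrix, float, tuple[float, ...]]:
    """Evolve one population at a fixed matrix length.

    Returns the best matrix, its objective mF(1), and the per-generation
    trace of mF(1) (non-decreasing by elitism).  Objectives of unchanged
    matrices are cached across generations.
    """
    codes = [seq.codes for seq in si]
    d, e = params.d, params.e

    def objective(w: WeightMatrix) -> float:
        total = 0.0
        for c in codes:
            total += _score_only(np.ascontiguousarray(w.weights[c, :]), d, e)
        return total

    population = [build_random_pwm(si, n_columns, params, rng, k=cfg.k_random)
                  for _ in range(cfg.population_size)]
    scores = np.array([objective(w) for w in population])
    trace = [float(scores.max())]
    stagnant = 0
    while stagnant < cfg.stagnation_window:
        if cfg.max_generations is not None and len(trace) > cfg.max_generations:
            break
        order = np.argsort(-scores, kind="stable")
        ranked = [population[i] for i in order]
        ranked_scores = scores[order]
        survivors = ranked[:-2]
        survivor_scores = ranked_scores[:-2]
        children = []
        for _ in range(2):
            ia = _select_index(survivor_scores, rng)
            ib = _select_index(survivor_scores, rng)
            children.append(crossover(survivors[ia], survivors[ib], rng, params))
        population = survivors + children
        scores = np.concatenate([survivor_scores,
                                 [objective(c) for c in children]])
        # point mutations: skip the elite (index 0) and this step's children
        eligible = np.arange(1, len(survivors))
        n_mut = min(cfg.mutants_per_generation, len(eligible))
        if n_mut > 0:
            picked = rng.choice(eligible, size=n_mut, replace=False)
            for idx in picked:
                population[idx] = _mutate(population[idx], cfg, params, rng)
                scores[idx] = objective(population[idx])
        best = float(scores.max())
        if best > trace[-1] + _EPS:
            stagnant = 0
        else:
            stagnant += 1
            best = max(best, trace[-1])
        trace.append(best)
        logger.debug("L=%d generation %d: mF(1)=%.4f (stagnant %d)",
                     n_columns, len(trace) - 1, best, stagnant)
    best_idx = int(np.argmax(scores))
    return population[best_idx], float(scores[best_idx]), tuple(trace)


def length_range(mean_length: float, cfg: GAConfig) -> list[int]:
    """Candidate matrix lengths: round((1 +/- span) * mean), stepped."""
    lo = max(1, round((1.0 - cfg.length_span) * mean_length))
    hi = max(lo, round((1.0 + cfg.length_span) * mean_length))
    return list(range(lo, hi + 1, cfg.length_step))


def find_best_pwm(si: SequenceSet, params: ScoringParams, cfg: GAConfig,
                  rng: np.random.Generator) -> GAResult:
    """Scan candidate lengths, evolve each, and keep the best matrix."""
    best: GAResult | None = None
    for L in length_range(si.mean_length, cfg):
        pwm, obj, trace = evolve_population(si, L, params, cfg, rng)
        logger.info("length %d: mF_L(1)=%.4f after %d generations",
                    L, obj, len(trace) - 1)
        if best is None or obj > best.best_objective:
            best = GAResult(pwm, L, obj, len(trace) - 1, trace)
    assert best is not None
    return best
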