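"""Position weight matrices: construction, normalization, extraction.

A PWM here is the "image" of a multiple alignment: a 20 x L real matrix
whose cell (i, j) scores amino acid i at alignment column j.  Random PWMs
are built by standardizing the counts of a random sequence (with the input
set's residue composition) laid against a tandem repeat of the column
indices 1..L; a PWM of an existing alignment is the same standardization of
its per-column residue counts.  Every PWM used by the optimizer is then
mapped onto a common scale by an affine transform enforcing two moments:

* sum of squared cells equals ``R^2 = R_L * 20 * L``;
* the background-weighted cell sum equals ``K_d``.

The two constraints make the score distributions of different random PWMs
against the same sequences comparable, which is what lets a single
objective ``mF`` rank the population of the genetic algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ALPHABET, ALPHABET_SIZE, GAP, MultipleAlignment, SequenceSet


class DegeneratePWMError(ValueError):
    """The affine normalization has no real, order-preserving solution."""


class GappyAlignmentError(ValueError):
    """Column filtering removed every alignment column."""


@dataclass(frozen=True)
class ScoringParams:
    """Alignment and normalization parameters.

    d, e        affine gap penalties: a gap run of length g costs d + (g-1)e
    r_l         multiplier setting the squared-norm target R^2 = r_l * 20 * L
    k_d         target for the background-weighted cell sum (an expectation
                analog: the mean PWM score of a random residue/column pair)
    """

    d: float = 40.0
    e: float = 1.0
    r_l: float = 5.0
    k_d: float = -1.0

    def __post_init__(self) -> None:
        if not (self.d >= self.e > 0):
            raise ValueError(f"require d >= e > 0, got d={self.d}, e={self.e}")
        if self.r_l <= 0:
            raise ValueError("r_l must be positive")

    def r2_target(self, n_columns: int) -> float:
        return self.r_l * ALPHABET_SIZE * n_columns


@dataclass(frozen=True)
class FrequencyMatrix:
    """Residue-by-column counts with their marginals."""

    counts: np.ndarray  # (20, L) nonnegative

    @property
    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


@dataclass(frozen=True)
class WeightMatrix:
    """A 20 x L PWM with the background distributions used to normalize it.

    ``p1`` is the residue background (20-vector), ``p2`` the column
    background (L-vector); both are probability vectors.
    """

    weights: np.ndarray  # (20, L) float
    p1: np.ndarray       # (20,)
    p2: np.ndarray       # (L,)

    @property
    def n_columns(self) -> int:
        return self.weights.shape[1]

    def r2(self) -> float:
        """Sum of squared cells."""
        return float(np.sum(self.weights ** 2))

    def kd(self) -> float:
        """Background-weighted cell sum."""
        return float(self.p1 @ self.weights @ self.p2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("residue\t" + "\t".join(str(j) for j in range(self.n_columns)) + "\n")
            for i, aa in enumerate(ALPHABET):
                fh.write(aa + "\t"
                         + "\t".join(repr(float(v)) for v in self.weights[i])
                         + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path, p1: np.ndarray | None = None,
                 p2: np.ndarray | None = None) -> "WeightMatrix":
        rows = []
        with open(path) as fh:
            next(fh)  # header
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(v) for v in parts[1:]])
        w = np.asarray(rows, dtype=float)
        if p1 is None:
            p1 = np.full(ALPHABET_SIZE, 1.0 / ALPHABET_SIZE)
        if p2 is None:
            p2 = np.full(w.shape[1], 1.0 / w.shape[1])
        return cls(w, np.asarray(p1, float), np.asarray(p2, float))


def standardize_counts(fm: FrequencyMatrix) -> np.ndarray:
    """Binomial z-standardization of a count matrix.

    With marginals x(i), y(j) and grand total T, each cell becomes
    ``(M(i,j) - T p(i,j)) / sqrt(T p(i,j) (1 - p(i,j)))`` where
    ``p(i,j) = x(i) y(j) / T^2`` is the independence expectation.  Counts
    must be strictly positive (callers add a pseudocount of 1).
    """
    m = np.asarray(fm.counts, dtype=float)
    x = m.sum(axis=1)
    y = m.sum(axis=0)
    total = m.sum()
    p = np.outer(x, y) / total ** 2
    if np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("degenerate cell probability; add a pseudocount")
    expected = total * p
    return (m - expected) / np.sqrt(expected * (1.0 - p))


def transform_pwm(w: WeightMatrix, params: ScoringParams) -> WeightMatrix:
    """Affine-map a PWM onto the prescribed (R^2, K_d) scale.

    Solves ``w' = a w + b`` with ``sum w'^2 = R^2`` and
    ``sum w' p1 p2 = K_d``.  Eliminating b via the K_d constraint leaves a
    quadratic in a whose positive root preserves the sign structure of the
    matrix.  A matrix already on scale maps to itself (a=1, b=0).
    """
    r2_target = params.r2_target(w.n_columns)
    k_d = params.k_d
    n_cells = w.weights.size
    s1 = w.kd()
    u = w.weights - s1
    a2 = float(np.sum(u ** 2))
    if a2 < 1e-12:
        raise DegeneratePWMError(
            "all PWM cells equal their background mean; the (R^2, K_d) "
            "constraints cannot both be met by an affine map"
        )
    a1 = 2.0 * k_d * float(np.sum(u))
    a0 = n_cells * k_d ** 2 - r2_target
    disc = a1 ** 2 - 4.0 * a2 * a0
    if disc < 0:
        raise DegeneratePWMError("no real solution for the affine transform")
    a = (-a1 + np.sqrt(disc)) / (2.0 * a2)
    if a <= 0:
        raise DegeneratePWMError("no positive-scale solution for the transform")
    b = k_d - a * s1
    return WeightMatrix(a * w.weights + b, w.p1, w.p2)


def build_random_pwm(si: SequenceSet, n_columns: int, params: ScoringParams,
                     rng: np.random.Generator, k: int = 1000) -> WeightMatrix:
    """Build one random, normalized PWM of ``n_columns`` columns.

    Conceptually a random sequence of length ``n_columns * k`` with the
    residue frequencies of ``si`` is paired with the k-fold tandem repeat
    of the column indices; each column therefore receives exactly k i.i.d.
    residue draws, which is sampled here directly as one multinomial per
    column.  The resulting counts (plus a pseudocount of 1 per cell) are
    z-standardized and affine-normalized.
    """
    if n_columns < 1:
        raise ValueError("n_columns must be >= 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    freqs = si.residue_frequencies()
    counts = rng.multinomial(k, freqs, size=n_columns).T  # (20, L)
    fm = FrequencyMatrix(counts + 1)
    raw = standardize_counts(fm)
    p2 = np.full(n_columns, 1.0 / n_columns)
    return transform_pwm(WeightMatrix(raw, freqs, p2), params)


def filter_gappy_columns(ma: MultipleAlignment) -> tuple[MultipleAlignment, np.ndarray]:
    """Drop columns holding fewer than alpha/2 residues.

    Returns the filtered alignment and the surviving original column
    indices (the map from filtered column j to its source column).
    """
    threshold = ma.alpha / 2.0
    keep = [j for j in range(ma.k) if ma.residue_count(j) >= threshold]
    if not keep:
        raise GappyAlignmentError("alignment too gappy: no column retains "
                                  "at least half of the rows")
    rows = ["".join(row[j] for j in keep) for row in ma.rows]
    # Filtering can leave an all-gap row; such a row would contribute no
    # residue to the PWM and is rejected by the container.
    filtered = MultipleAlignment(ma.row_ids, rows)
    return filtered, np.asarray(keep, dtype=np.int64)


def pwm_from_msa(ma: MultipleAlignment,
                 params: ScoringParams) -> tuple[WeightMatrix, np.ndarray]:
    """Extract a normalized PWM from an existing alignment.

    Columns with fewer than alpha/2 residues are removed first; the
    per-column residue counts V of the surviving columns (pseudocount 1)
    are z-standardized and affine-normalized.  Returns the PWM and the map
    from PWM column to original alignment column.
    """
    if ma.alpha < 2:
        raise ValueError("alignment must have at least 2 rows")
    filtered, column_map = filter_gappy_columns(ma)
    counts = np.zeros((ALPHABET_SIZE, filtered.k), dtype=np.int64)
    for row in filtered.rows:
        for j, c in enumerate(row):
            if c != GAP:
                counts[ALPHABET.index(c), j] += 1
    fm = FrequencyMatrix(counts + 1)
    raw = standardize_counts(fm)
    p1 = fm.row_sums / fm.total
    p2 = np.full(filtered.k, 1.0 / filtered.k)
    return transform_pwm(WeightMatrix(raw, p1, p2), params), column_map
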