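"""Monte Carlo significance of multiple alignments.

The null model shuffles the residues within every input sequence, which
preserves lengths and per-sequence composition while destroying positional
signal.  The Z-score compares the observed alignment weight with the mean
and standard deviation of the weight over shuffled replicas:

    Z = (observed - null_mean) / null_sd

For an alignment produced here, the weight is the objective mF of the
optimized PWM.  For an arbitrary externally produced alignment, a PWM is
first extracted from the alignment itself (after dropping columns more
than half gaps) and the alignment's weight F_MA is its summed PWM cells
minus affine gap charges; the null re-aligns shuffled de-gapped rows to
that PWM.  Alignments with Z at or above the threshold (default 10, the
calibrated protein threshold) are flagged significant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .align import set_objective
from .io import ALPHABET, GAP, MultipleAlignment, ProteinSequence, SequenceSet
from .pwm import ScoringParams, WeightMatrix, filter_gappy_columns, pwm_from_msa

#: Calibrated significance threshold for protein alignments.
DEFAULT_Z_THRESHOLD = 10.0
DEFAULT_N_SHUFFLES = 300


class DegenerateNullError(ValueError):
    """The shuffled-null scores have zero spread."""


@dataclass(frozen=True)
class ZResult:
    """Monte Carlo significance verdict for one alignment."""

    observed: float
    null_mean: float
    null_sd: float
    z: float
    n_shuffles: int
    threshold: float = DEFAULT_Z_THRESHOLD

    @property
    def significant(self) -> bool:
        return self.z >= self.threshold

    def report_rows(self) -> list[tuple[str, str]]:
        return [
            ("observed", f"{self.observed:.4f}"),
            ("null_mean", f"{self.null_mean:.4f}"),
            ("null_sd", f"{self.null_sd:.4f}"),
            ("Z", f"{self.z:.4f}"),
            ("n_shuffles", str(self.n_shuffles)),
            ("significant", str(self.significant)),
        ]


@dataclass(frozen=True)
class DelVector:
    """Counts of maximal gap runs by length: counts[g] runs of exactly g."""

    counts: dict[int, int]

    @property
    def openings(self) -> int:
        return sum(self.counts.values())

    @property
    def total_gaps(self) -> int:
        return sum(g * n for g, n in self.counts.items())

    def gap_charge(self, params: ScoringParams) -> float:
        """Total affine penalty: each run of length g costs d + (g-1) e."""
        return sum(n * (params.d + (g - 1) * params.e)
                   for g, n in self.counts.items())


def _row_gap_runs(row: str):
    run = 0
    for c in row:
        if c == GAP:
            run += 1
        elif run:
            yield run
            run = 0
    if run:
        yield run


def del_vector(ma: MultipleAlignment) -> DelVector:
    """Gap-run length spectrum over all rows (terminal runs included)."""
    counts: Counter[int] = Counter()
    for row in ma.rows:
        counts.update(_row_gap_runs(row))
    return DelVector(dict(counts))


def gap_statistics(ma: MultipleAlignment) -> tuple[int, int]:
    """(number of gap openings, total gap characters) over all rows."""
    dels = del_vector(ma)
    return dels.openings, dels.total_gaps


def shuffle_set(si: SequenceSet, rng: np.random.Generator) -> SequenceSet:
    """Independently permute the residues of every sequence."""
    out = []
    for seq in si:
        perm = rng.permutation(len(seq))
        out.append(ProteinSequence(
            seq.id, "".join(seq.residues[i] for i in perm)
        ))
    return SequenceSet(out)


def z_for_pwm(si: SequenceSet, pwm_m: WeightMatrix, params: ScoringParams,
              n_shuffles: int = DEFAULT_N_SHUFFLES,
              rng: np.random.Generator | None = None,
              threshold: float = DEFAULT_Z_THRESHOLD) -> ZResult:
    """Z-score of the objective mF of a PWM against shuffled sequence sets."""
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    observed = set_objective(si, pwm_m, params)
    nulls = np.array([
        set_objective(shuffle_set(si, rng), pwm_m, params)
        for _ in range(n_shuffles)
    ])
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    if null_sd == 0.0:
        raise DegenerateNullError("shuffled-null scores have zero spread")
    z = (observed - null_mean) / null_sd
    return ZResult(observed, null_mean, null_sd, z, n_shuffles, threshold)


def ma_weight(ma_filtered: MultipleAlignment, pwm_prime: WeightMatrix,
              params: ScoringParams, dels: DelVector,
              column_map: np.ndarray | None = None) -> float:
    """Weight F_MA of an alignment under its own extracted PWM.

    Sums PWM cells over every (residue, column) of the filtered alignment
    (gap cells skipped; filtered column j indexes PWM column j directly,
    so ``column_map`` is informational) and subtracts the affine charge of
    every maximal gap run of the *original* alignment, described by
    ``dels``.
    """
    if pwm_prime.n_columns != ma_filtered.k:
        raise ValueError("PWM and filtered alignment disagree on columns")
    total = 0.0
    for row in ma_filtered.rows:
        for j, c in enumerate(row):
            if c != GAP:
                total += pwm_prime.weights[ALPHABET.index(c), j]
    return float(total - dels.gap_charge(params))


def z_for_msa(ma: MultipleAlignment, params: ScoringParams,
              n_shuffles: int = DEFAULT_N_SHUFFLES,
              rng: np.random.Generator | None = None,
              threshold: float = DEFAULT_Z_THRESHOLD) -> ZResult:
    """Z-score of an arbitrary alignment.

    Extracts a PWM from the alignment, takes F_MA as the observed weight,
    and builds the null by shuffling the de-gapped rows and globally
    re-aligning each shuffled sequence to the extracted PWM (objective mF).
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if rng is None:
        rng = np.random.default_rng()
    filtered, _column_map = filter_gappy_columns(ma)
    pwm_prime, _ = pwm_from_msa(ma, params)
    observed = ma_weight(filtered, pwm_prime, params, del_vector(ma))
    degapped = ma.degap()
    nulls = np.array([
        set_objective(shuffle_set(degapped, rng), pwm_prime, params)
        for _ in range(n_shuffles)
    ])
    null_mean = float(nulls.mean())
    null_sd = float(nulls.std(ddof=1))
    if null_sd == 0.0:
        raise DegenerateNullError("shuffled-null scores have zero spread")
    z = (observed - null_mean) / null_sd
    return ZResult(observed, null_mean, null_sd, z, n_shuffles, threshold)
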