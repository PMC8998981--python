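"""Artificial protein families with calibrated divergence.

A family is a star phylogeny: one random ancestor of length L, and
descendants generated independently by applying a prescribed number of
substitution events (uniform positions, sampled with replacement;
replacement residue uniform over all 20, so the incumbent may recur) and
indel events (contiguous insertions or deletions of a fixed length),
interleaved in random order.

Because substitution positions are drawn with replacement, the chance that
a given position survives s events untouched is P0 = (1 - 1/L)^s, and the
match probability between ancestor and descendant is

    Pm = P0 + (1 - P0)/20.

Two independent descendants, each carrying s2 events, match with
probability Pm3 = P02^2 + (1 - P02^2)/20 where P02 = (1 - 1/L)^(s2);
since P02^2 = (1 - 1/L)^(2 s2), a descendant pair is exactly as diverged
as an ancestor-descendant pair with s1 = 2 s2 events.  The divergence x
(substitutions per symbol) of a pair is therefore 2 x the per-descendant
substitution load, and can be estimated from an observed identity by
inverting Pm in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import ALPHABET, ALPHABET_SIZE, ProteinSequence, SequenceSet


class IndelLoadError(ValueError):
    """A deletion event would exhaust the sequence."""


class SaturatedDivergenceError(ValueError):
    """Observed identity at or below the random floor of 1/20."""


def _uniform_freqs() -> np.ndarray:
    return np.full(ALPHABET_SIZE, 1.0 / ALPHABET_SIZE)


@dataclass(frozen=True)
class SimulationConfig:
    """One grid point of the family simulator.

    Defaults are the study conditions of the full grid's first point:
    ancestor length 600, 100 descendants, substitution load 0.3 per
    residue (pairwise divergence x = 0.6), 2 indels of length 1 per
    descendant.  Insertions and deletions are equally likely.
    """

    length: int = 600
    n_descendants: int = 100
    subs_per_residue: float = 0.3
    indel_count: int = 2
    indel_length: int = 1
    residue_frequencies: tuple[float, ...] | None = None
    insertion_prob: float = 0.5

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.subs_per_residue < 0:
            raise ValueError("subs_per_residue must be >= 0")
        if self.indel_count < 0 or self.indel_length < 0:
            raise ValueError("indel parameters must be >= 0")

    @property
    def frequencies(self) -> np.ndarray:
        if self.residue_frequencies is None:
            return _uniform_freqs()
        f = np.asarray(self.residue_frequencies, dtype=float)
        if f.shape != (ALPHABET_SIZE,) or abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("residue_frequencies must be 20 values summing to 1")
        return f

    @property
    def pair_divergence(self) -> float:
        """Expected substitutions per symbol between two descendants."""
        return 2.0 * self.subs_per_residue


@dataclass(frozen=True)
class DivergenceModel:
    """Closed-form match probabilities for s1 substitution events.

    p0   chance a position survives all s1 events unchanged
    p1   chance the last event restores the original residue
    pm   ancestor-descendant match probability (p0 + p1)
    p02  survival probability of each member of a descendant pair
         carrying s1/2 events
    pm3  descendant-descendant match probability (equals pm)
    """

    p0: float
    p1: float
    pm: float
    p02: float
    pm3: float


def expected_identity(s1: float, length: int) -> DivergenceModel:
    """Evaluate the match-probability model for s1 events on length L."""
    if s1 < 0 or length < 1:
        raise ValueError("require s1 >= 0 and length >= 1")
    base = 1.0 - 1.0 / length
    p0 = base ** s1
    p1 = (1.0 - p0) / ALPHABET_SIZE
    p02 = base ** (s1 / 2.0)
    pm3 = p02 ** 2 + (1.0 - p02 ** 2) / ALPHABET_SIZE
    return DivergenceModel(p0, p1, p0 + p1, p02, pm3)


def estimate_x(observed_identity: float, length: int) -> float:
    """Invert the match-probability model: identity -> substitutions/symbol.

    Solves Pm = P0 + (1 - P0)/20 for P0 = (20 Pm - 1)/19, then
    s1 = ln(P0) / ln(1 - 1/L); returns x = s1 / L.  Identities at or below
    the random floor 1/20 are unresolvable.
    """
    if not (0.0 <= observed_identity <= 1.0):
        raise ValueError("identity must lie in [0, 1]")
    p0 = (ALPHABET_SIZE * observed_identity - 1.0) / (ALPHABET_SIZE - 1.0)
    if p0 <= 0.0:
        raise SaturatedDivergenceError(
            f"identity {observed_identity:.4f} is beyond resolvable divergence"
        )
    if p0 >= 1.0:
        return 0.0
    s1 = math.log(p0) / math.log(1.0 - 1.0 / length)
    return s1 / length


def pairwise_identity(a: ProteinSequence, b: ProteinSequence) -> float:
    """Fraction of positions with equal residues (equal-length sequences)."""
    if len(a) != len(b):
        raise ValueError("pairwise identity requires equal lengths")
    return float(np.mean(a.codes == b.codes))


def make_ancestor(cfg: SimulationConfig, rng: np.random.Generator,
                  seq_id: str = "anc") -> ProteinSequence:
    """Random ancestor: i.i.d. residues from the configured frequencies."""
    codes = rng.choice(ALPHABET_SIZE, size=cfg.length, p=cfg.frequencies)
    return ProteinSequence(seq_id, "".join(ALPHABET[c] for c in codes))


def make_descendant(anc: ProteinSequence, cfg: SimulationConfig,
                    rng: np.random.Generator,
                    seq_id: str = "des") -> ProteinSequence:
    """Mutate the ancestor: interleaved substitution and indel events.

    The substitution count is round(subs_per_residue * len(anc)); each
    event hits a uniform position of the *current* sequence and writes a
    uniform residue (possibly the incumbent).  Each indel event is an
    insertion or deletion (fair coin by default) of ``indel_length``
    contiguous symbols at a uniform position; inserted residues follow the
    configured frequencies.
    """
    n_subs = round(cfg.subs_per_residue * len(anc))
    events = np.array([0] * n_subs + [1] * cfg.indel_count)
    rng.shuffle(events)
    chars = list(anc.residues)
    freqs = cfg.frequencies
    for ev in events:
        if ev == 0:
            pos = int(rng.integers(len(chars)))
            chars[pos] = ALPHABET[int(rng.choice(ALPHABET_SIZE))]
        elif rng.random() < cfg.insertion_prob:
            pos = int(rng.integers(len(chars) + 1))
            ins = [ALPHABET[int(c)] for c in
                   rng.choice(ALPHABET_SIZE, size=cfg.indel_length, p=freqs)]
            chars[pos:pos] = ins
        else:
            if len(chars) < cfg.indel_length + 1:
                raise IndelLoadError(
                    f"sequence too short for indel load "
                    f"(length {len(chars)}, deletion of {cfg.indel_length})"
                )
            pos = int(rng.integers(len(chars) - cfg.indel_length + 1))
            del chars[pos:pos + cfg.indel_length]
    return ProteinSequence(seq_id, "".join(chars))


def make_family(cfg: SimulationConfig, rng: np.random.Generator,
                prefix: str = "des") -> SequenceSet:
    """One ancestor, ``n_descendants`` independent descendants of it.

    The ancestor itself is not part of the returned set.
    """
    anc = make_ancestor(cfg, rng)
    return SequenceSet([
        make_descendant(anc, cfg, rng, seq_id=f"{prefix}_{i + 1:04d}")
        for i in range(cfg.n_descendants)
    ])


def standard_grid(scale: float = 1.0) -> list[SimulationConfig]:
    """The 81-point benchmark grid of family configurations.

    Substitution loads 0.3..2.7 (step 0.3) crossed with indel counts
    {2, 5, 10} and indel lengths {1, 5, 20}.  ``scale`` < 1 shrinks the
    ancestor length and descendant count proportionally for desk-scale
    runs (indel sizes are kept, so gap structure is preserved).
    """
    if not (0.0 < scale <= 1.0):
        raise ValueError("scale must be in (0, 1]")
    length = max(20, round(600 * scale))
    n_desc = max(2, round(100 * scale))
    # worst case on the grid: 10 deletions of 20 residues each
    if length <= 10 * 20:
        raise ValueError(
            "scale too small: the grid's heaviest indel load (10 deletions "
            "of length 20) would exhaust the ancestor; need scale > 1/3"
        )
    grid = []
    for subs in [round(0.3 * i, 1) for i in range(1, 10)]:
        for n_indels in (2, 5, 10):
            for indel_len in (1, 5, 20):
                grid.append(SimulationConfig(
                    length=length, n_descendants=n_desc,
                    subs_per_residue=subs, indel_count=n_indels,
                    indel_length=indel_len,
                ))
    return grid
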