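"""End-to-end pipeline: sequences in, significant alignment out.

Chains the stages: genetic-algorithm search for the best PWM over the
length band, global alignment of every sequence to the winning matrix,
assembly of the induced multiple alignment, and the Monte Carlo Z-score
of the optimized objective against shuffled sequences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import AlignmentPath, global_align
from .genetic import GAConfig, GAResult, find_best_pwm
from .io import MultipleAlignment, SequenceSet
from .msa_builder import assemble_msa
from .pwm import ScoringParams
from .significance import (DEFAULT_N_SHUFFLES, DEFAULT_Z_THRESHOLD, ZResult,
                           z_for_pwm)


@dataclass(frozen=True)
class PipelineResult:
    ga: GAResult
    paths: tuple[AlignmentPath, ...]
    msa: MultipleAlignment
    zscore: ZResult


def align_sequences(si: SequenceSet, params: ScoringParams | None = None,
                    cfg: GAConfig | None = None,
                    n_shuffles: int = DEFAULT_N_SHUFFLES,
                    threshold: float = DEFAULT_Z_THRESHOLD,
                    seed: int | np.random.Generator = 0) -> PipelineResult:
    """Run the full method on a sequence set.

    ``seed`` may be an integer or a ready ``numpy.random.Generator``; a
    fixed integer makes the whole run (alignment, report, Z) reproducible
    bit for bit.
    """
    if si.n < 2:
        raise ValueError("need at least 2 sequences to align")
    params = params or ScoringParams()
    cfg = cfg or GAConfig()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ga = find_best_pwm(si, params, cfg, rng)
    paths = tuple(global_align(seq, ga.best_pwm, params) for seq in si)
    msa = assemble_msa(si, ga.best_pwm, list(paths))
    zres = z_for_pwm(si, ga.best_pwm, params, n_shuffles=n_shuffles,
                     rng=rng, threshold=threshold)
    return PipelineResult(ga, paths, msa, zres)
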