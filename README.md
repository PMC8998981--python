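# pwmsa

Multiple alignment of **highly diverged protein sequences** by optimizing a
position-weight-matrix (PWM) "image" of the alignment, with Monte Carlo
significance testing.

Progressive and iterative aligners build a multiple sequence alignment
(MSA) from pairwise comparisons, which stops working once homologs have
accumulated more than roughly 2.4 substitutions per residue: pairwise
signal vanishes even though family-level positional structure remains.
`pwmsa` sidesteps pairwise comparison entirely. It represents a candidate
MSA as a 20 × L real matrix (the alignment's image), evolves a population
of such matrices with a genetic algorithm to maximize

    mF(PWM) = Σ_l Fmax(l),

the sum over input sequences of each sequence's optimal **global
sequence-vs-PWM alignment score** (affine gaps: a run of length g costs
d + (g−1)e), and then reads the final MSA off the per-sequence alignment
tracebacks against the winning matrix PWM_m. Every matrix is normalized to
a common scale — Σ w² = R_L·20·L and Σ w·p₁·p₂ = K_d — so objective values
are comparable across the population. Significance is a Monte Carlo
Z-score: the optimized mF against its distribution over within-sequence
residue shuffles, with Z ≥ 10 the calibrated threshold for proteins. The
same machinery scores *any* existing alignment (PWM extracted from the
alignment itself; weight F_MA = Σ cell scores − affine gap charges).

The package also ships the calibrated family simulator used to
characterize the method — ancestor plus independently mutated descendants,
where a per-descendant load of s substitutions/residue yields pairwise
divergence x = 2s exactly, by the closed-form match-probability model
P_m = P₀ + (1 − P₀)/20 with P₀ = (1 − 1/L)^{sL} — and the reference-based
column score CS.

Intended users: anyone aligning protein families in the twilight zone
(identity < 20%, x up to ~4.8) or wanting a probabilistic significance
verdict on an alignment produced by any tool.

## Worked example

```python
import numpy as np
from pwmsa import (GAConfig, ScoringParams, SimulationConfig,
                   align_sequences, make_family)

family = make_family(
    SimulationConfig(length=60, n_descendants=12, subs_per_residue=0.3,
                     indel_count=1, indel_length=1),
    np.random.default_rng(1),
)
result = align_sequences(family, ScoringParams(),
                         GAConfig.fast(family.mean_length),
                         n_shuffles=50, seed=1)
```

Output (`python examples/align_family.py`):

```
matrix length chosen (L_m) : 59
objective mF at the optimum: -302.0
generations run            : 120
alignment size             : 12 x 69
Z = (-302.0 - -859.1) / 51.2 = 10.89  (significant: True)
```

The sequences here are simulated siblings at x = 0.6 substitutions per
residue (≈ 57% identity). The search settles on a 59-column matrix; the
12 tracebacks assemble into a 69-column MSA (insertions relative to the
matrix widen shared junctions). The raw objective is negative — cell
scores are standardized deviations, not log-odds — but what matters is
its distance from the shuffled null: 10.9 standard deviations, clearing
the Z ≥ 10 significance bar. The other scripts in `examples/` demonstrate
the simulator's divergence calibration, Z-scoring an externally built
alignment, and the column score.

A command-line interface wraps the same pipeline:

```bash
pwmsa simulate -o fams --length 150 --n-descendants 20 --seed 1
pwmsa align fams/set000_s0.3_n2_l1.fasta -o out.afa --preset fast --seed 1
pwmsa zscore out.afa --seed 1
pwmsa cs out.afa reference.afa
```

`--preset full` reproduces the full-scale configuration (population 500,
50 mutants/generation, 300 shuffles, unit length scan) — sized for a
cluster, not a laptop; `--preset fast` is the desk-scale reduction used
throughout the test suite (see `docs/methods.md`).

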