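# Methods

## The model

An MSA of N protein sequences is represented by its *image*: a 20 × L
position weight matrix W whose cell W(a, j) scores amino acid a at
alignment column j. Rather than building the MSA by pairwise comparison,
the image is optimized directly: candidate matrices are scored by

    mF(W) = Σ_{l=1..N} Fmax(l),

where Fmax(l) is the optimal **global** alignment score of sequence l
against the columns of W under an affine gap model (a maximal gap run of
length g, in either the sequence or the matrix, costs d + (g − 1)e;
terminal gaps are charged the same way, so the optimum is read at the
full-length corner of the dynamic-programming table). The MSA induced by
a matrix is obtained from the N tracebacks: each matrix column becomes an
alignment column, a sequence skipping a column gets a gap there, and
residues inserted between two matrix columns widen that junction once,
shared by all sequences (shorter insertions left-justified). By
construction every row de-gaps to its input sequence and the column count
is L plus the summed per-junction maximum insertion lengths.

### PWM construction and normalization

A *random* image is made by drawing, for every column, k i.i.d. residues
from the input set's residue frequencies (equivalently: a random sequence
of length L·k laid against the k-fold tandem repeat of the column
indices), counting the resulting 20 × L table M, adding a pseudocount of
1 per cell, and standardizing each cell against the independence model:

    W(a, j) = (M(a, j) − T·p(a, j)) / sqrt(T·p(a, j)·(1 − p(a, j))),

with marginals x(a), y(j), total T and p(a, j) = x(a)·y(j)/T². The same
standardization applied to the per-column residue counts of an existing
alignment (after dropping columns that are more than half gaps) gives the
alignment's extracted PWM.

Matrices are only comparable under mF if they share a scale, so every
matrix entering the optimizer — initial, mutated, or crossed over — is
affinely mapped, W′ = aW + b, onto two fixed moments: Σ W′² = R_L·20·L
and Σ W′(a,j)·p₁(a)·p₂(j) = K_d, where p₁ is the residue background and
p₂ the (uniform) column background. Eliminating b through the second
constraint leaves a quadratic in a; the positive root preserves the sign
structure, and a matrix already on scale maps to itself. A matrix whose
cells all equal the background mean (e.g. from a single-residue input, or
any count table whose columns are identical — one column is always such a
case) carries no information and is rejected as degenerate rather than
silently rescaled. The affine map itself is this package's construction;
it is the minimal two-parameter transform meeting both constraints.

### Genetic algorithm

Matrices are organisms; mF is fitness. Each generation: rank the
population; keep the best matrix untouched (elitism — it is also exempt
from mutation, so the best-objective trace is non-decreasing); drop the
two worst; create two children by one-point column crossover of parents
drawn with rank-proportional probability (linear weights, tied ranks
averaged so equal scores are equally likely); give a fixed number of
randomly chosen non-elite, non-child matrices a point mutation (one cell
redrawn uniformly on [−10, 10]); re-normalize everything edited; re-score
only what changed. Evolution stops when the best objective has not
improved for a stagnation window of generations. Because sequence lengths
vary, the whole search runs once per candidate matrix length in
[0.9·L̄, 1.1·L̄] (L̄ = mean sequence length) and the best (matrix, length)
pair wins.

### Significance

The null model shuffles residues within each sequence — lengths and
compositions preserved, positional structure destroyed. For an optimized
matrix, Z = (mF_observed − mean_null) / sd_null over n independent
shuffled sets (sample standard deviation, ddof = 1; the observed−null
distance in sd units is the only reading that makes the calibrated
threshold Z_t = 10 ≈ null mean + 3·spread coherent). For an arbitrary
alignment, the observed statistic is the alignment weight
F_MA = Σ extracted-PWM cells over its residues − Σ affine charges of its
maximal gap runs (terminal runs count as openings), and the null
re-aligns shuffled de-gapped rows to the extracted PWM by the same global
DP.

**Self-extraction bias.** F_MA scores an alignment with a matrix counted
from that same alignment, so even a random gapless stack of unrelated
sequences carries a positive offset (≈ Z 25 at 20 rows × 40 columns,
growing with size): the statistic is meant for comparing *competing
alignments of the same sequences* — where gap charges and column
coherence dominate — not as an absolute test that a stack of rows is
non-random. The absolute null calibration belongs to the pipeline
Z-score (optimizer + shuffle null), which on pure noise at desk scale
averages Z ≈ 4, well under the significance threshold.

### The family simulator

A family is a star phylogeny: a random ancestor of length L (default 600,
uniform residue frequencies) and n independent descendants (default 100).
Each descendant receives round(s·L) substitution events — position
uniform *with replacement*, replacement residue uniform over all 20, so
the incumbent may recur — and a configured number of indel events
(insertion or deletion by fair coin, fixed run length, uniform position,
inserted residues from the background), all interleaved in random order.
Under this process the chance a position survives s·L events is
P₀ = (1 − 1/L)^{sL} and the ancestor–descendant match probability is
P_m = P₀ + (1 − P₀)/20; two independent descendants match like a single
branch carrying twice the load, so pairwise divergence is x = 2s exactly,
and an observed identity inverts to x in closed form (identities at or
below the 1/20 random floor are unresolvable). The benchmark grid crosses
s ∈ {0.3, …, 2.7} with indel counts {2, 5, 10} and lengths {1, 5, 20}
(81 configurations); scaled-down grids shrink L and n but keep indel
sizes, and are refused below L = 200 where the heaviest grid point's
deletions could exhaust the ancestor.

What the simulator does *not* emulate: substitution-matrix-biased
exchange (PAM/BLOSUM), site-rate heterogeneity, tree-structured descent,
compositional drift. Tests passing on simulated families therefore
demonstrate recovery of positional signal under uniform mutational noise,
not performance on realistic evolutionary processes.

### Column score

CS = (matching columns) / (columns of the evaluated alignment), a column
matching only if its complete configuration — which ordinal residue of
each sequence it holds and which sequences are gapped — occurs as a
reference column. This is the strict full-column criterion; no
core-column or reliability annotations are used.

## Parameters

| parameter | default | meaning |
|---|---|---|
| d | 40 | gap opening penalty (score units of the normalized PWM) |
| e | 1 | gap extension penalty per additional gapped position |
| R_L | 5.0 | scale multiplier; squared-norm target is R_L·20·L |
| K_d | −1.0 | background-weighted cell-sum target (expected score of a random residue/column pair) |
| population | 500 | matrices per length |
| mutants/generation | 50 | point mutations per generation |
| mutation range | [−10, 10] | uniform redraw interval for a mutated cell |
| stagnation window | 10 | generations without improvement before stopping |
| length scan | 0.9L̄–1.1L̄ step 1 | candidate matrix lengths |
| k | 1000 | residue draws per column for random PWMs |
| n_shuffles | 300 | Monte Carlo null size |
| Z_t | 10.0 | significance threshold for proteins |

d = 40, e = 1, K_d = −1 at R_L = 5 is the combination calibrated for
protein alignment quality and significance; R_L only sets the overall
scale and the others are quoted relative to it.

## Desk-scale preset and problem sizes

The defaults above are sized for a cluster (the full benchmark ran a
121-length scan with 500 matrices per length on 36 cores). `GAConfig.fast`
is the package's desk-scale preset, used throughout the test suite:
population 50, 10 mutants/generation, k = 100, length step
max(1, 0.02·L̄), 50 shuffles. Two of its choices need justification:

* **stagnation window 50** — patience is meaningful in units of mutation
  *trials*, not generations; 50 generations × 10 mutants matches the full
  configuration's 500 trials.
* **generation cap 120** — signal-rich searches improve almost
  indefinitely at small population sizes; the cap bounds each length's
  search. At this preset, simulated families at x = 0.6 reach Z ≈ 14–19
  (comfortably past Z_t), Z falls monotonically through x = 1.8 and 3.0,
  and pure-noise inputs average Z ≈ 4 — the same level the full-scale
  null calibration exhibits. The full preset leaves the cap off.

Test-suite problem sizes (package choices): divergence calibration uses
200 descendant pairs at L = 600; null calibration 20 noise subsets of
20 × 100; signal/noise families 20 × 150; Monte Carlo module examples run
3–10 seeded replicates with pass fractions fixed in advance.

## Numerical and design notes

* DP is exact (no banding), double precision, three-state affine
  (match / gap-in-sequence / gap-in-PWM) with gap-to-gap transitions
  charged as fresh openings; ties broken MATCH > gap-in-sequence >
  gap-in-PWM identically in the forward pass and traceback, so results
  are bit-reproducible. Kernels are numba-jitted; a score-only
  rolling-array kernel serves the optimizer, a full-table kernel serves
  traceback. Equivalence to exhaustive path enumeration is asserted for
  all instances up to 6 × 6 in the suite.
* Boundary conditions charge terminal gaps affinely:
  F(i, 0) = −d − (i−1)e and symmetrically.
* Random-PWM counts are sampled directly as one multinomial(k) per
  column — identical in distribution to materializing the L·k random
  sequence, at a fraction of the cost.
* All randomness flows through a single `numpy.random.Generator`; a fixed
  seed makes simulation, optimization, assembly, and Z bit-identical,
  including via the CLI.
* Ordering of the Monte Carlo null stream means reordering input
  sequences re-pairs permutations with different sequences: the observed
  statistic is exactly order-invariant, the Z only in distribution.
* Strict input validation: ambiguity codes (B, J, O, U, X, Z, '*') have
  no PWM row and are rejected by default (lenient mode maps them to a
  placeholder with a warning); '.' gaps are normalized to '-'; alignment
  containers refuse unequal rows and all-gap columns or rows.

## Known limitations

* The objective optimizes image similarity, not column correctness:
  alignments are statistically stronger but can be structurally coarser
  than progressive-aligner output on closely related families (low CS,
  high Z).
* F_MA's self-extraction bias (above) rules it out as an absolute
  randomness test.
* The desk preset's generation cap trades optimization depth for wall
  time; absolute Z values at desk scale are smaller than full-scale ones,
  and only trends and threshold crossings are meaningful.
* Single-threaded; the per-sequence alignments inside a generation are
  embarrassingly parallel but no worker pool is wired in.
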