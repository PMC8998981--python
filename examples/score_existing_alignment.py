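"""Z-score an existing multiple alignment (built by any tool).

A PWM is extracted from the alignment itself (columns more than half
gaps dropped), the alignment's weight F_MA is its summed PWM cells minus
affine gap charges, and the null re-aligns shuffled rows to the same
PWM.  Here the input is a family stacked without any alignment effort:
for closely related sequences even that is highly significant, while
the same rows loaded with long artificial gap runs lose significance.
"""

import numpy as np

from pwmsa import MultipleAlignment, ScoringParams, SimulationConfig, make_family, z_for_msa

family = make_family(
    SimulationConfig(length=50, n_descendants=15, subs_per_residue=0.1,
                     indel_count=0),
    np.random.default_rng(3),
)
stacked = MultipleAlignment([s.id for s in family],
                            [s.residues for s in family])
z = z_for_msa(stacked, ScoringParams(), n_shuffles=100,
              rng=np.random.default_rng(0))
print(f"stacked family : Z = {z.z:8.2f}  (observed {z.observed:.1f}, "
      f"null {z.null_mean:.1f} +/- {z.null_sd:.1f})")

gappy_rows = [s.residues[:25] + "-" * 30 + s.residues[25:]
              for s in family]
# one row offset differently so every column keeps at least one residue
gappy_rows[0] = "-" * 13 + family[0].residues + "-" * 17
gappy = MultipleAlignment([s.id for s in family], gappy_rows)
zg = z_for_msa(gappy, ScoringParams(), n_shuffles=100,
               rng=np.random.default_rng(0))
print(f"gap-loaded     : Z = {zg.z:8.2f}")
# Gap runs are charged d + (len-1)e each, so needless gapping drives the
# alignment weight, and with it Z, down.
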