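"""Assembly of the final multiple alignment from per-sequence PWM paths.

Every PWM column becomes one alignment column; a sequence whose path skips
a column (GAP_IN_SEQ) gets '-' there.  Residues a path inserts relative to
the PWM (GAP_IN_PWM runs) live between two PWM columns: that junction is
widened once, to the longest insertion any sequence places there, and is
shared — shorter insertions are left-justified and padded with gaps.
Junctions exist before the first and after the last PWM column as well, so
terminal insertions are handled identically.
"""

from __future__ import annotations

from .align import AlignmentPath, StepKind, validate_path
from .io import GAP, MultipleAlignment, SequenceSet
from .pwm import WeightMatrix


def _decompose(path: AlignmentPath, residues: str, n_columns: int
               ) -> tuple[list[str], list[str]]:
    """Split a path into per-column cells and per-junction insertions.

    Returns (cells, inserts): cells[j] is the residue or '-' this sequence
    places at PWM column j; inserts[j] is the run of residues it inserts at
    junction j (between columns j-1 and j; 0 = before the first column,
    n_columns = after the last).
    """
    cells = [GAP] * n_columns
    inserts = [""] * (n_columns + 1)
    cols_done = 0
    for step in path.steps:
        if step.kind is StepKind.MATCH:
            cells[step.col_index] = residues[step.seq_index]
            cols_done = step.col_index + 1
        elif step.kind is StepKind.GAP_IN_SEQ:
            cols_done = step.col_index + 1
        else:  # GAP_IN_PWM: insertion at the current junction
            inserts[cols_done] += residues[step.seq_index]
    return cells, inserts


def assemble_msa(si: SequenceSet, pwm_m: WeightMatrix,
                 paths: list[AlignmentPath]) -> MultipleAlignment:
    """Merge one global path per sequence into a multiple alignment.

    Requires one path per sequence, each consuming all PWM columns.  The
    result has ``K = L + sum over junctions of the maximum insertion
    length``, and de-gapping any row reproduces its input sequence.
    """
    if len(paths) != si.n:
        raise ValueError(f"{si.n} sequences but {len(paths)} paths")
    L = pwm_m.n_columns
    per_seq = []
    for seq, path in zip(si, paths):
        validate_path(path, len(seq), L)
        per_seq.append(_decompose(path, seq.residues, L))
    widths = [max(len(ins[j]) for _, ins in per_seq)
              for j in range(L + 1)]
    rows = []
    for cells, inserts in per_seq:
        parts = []
        for j in range(L + 1):
            parts.append(inserts[j].ljust(widths[j], GAP))
            if j < L:
                parts.append(cells[j])
        rows.append("".join(parts))
    return MultipleAlignment([s.id for s in si], rows)
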