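"""Global alignment of a protein sequence against a PWM (affine gaps).

The scoring scheme replaces a substitution matrix with PWM cells: matching
residue ``s(i)`` to PWM column ``j`` scores ``PWM(s(i), j)``; every maximal
gap run of length g (in either the sequence or the PWM) costs
``d + (g-1) e``.  Alignment is global end to end, terminal gaps included,
so the optimum is read at cell (L1, L).

The recurrence is the standard three-state Gotoh formulation (match state
plus one insertion state per direction), which resolves the path-history
ambiguity of charging d versus e deterministically.  Ties are broken with
the fixed priority MATCH > GAP_IN_SEQ > GAP_IN_PWM in both the forward
pass and the traceback, making results reproducible bit for bit.

The inner loops are numba-jitted; a score-only rolling-array kernel serves
the optimizer (which needs millions of alignments) and a full-matrix
kernel with backpointers serves traceback.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from numba import njit

from .io import GAP, ProteinSequence, SequenceSet
from .pwm import ScoringParams, WeightMatrix

_NEG = -1e30

# state codes shared by the kernels: 0 = match, 1 = gap in sequence
# (consumes a PWM column), 2 = gap in PWM (consumes a residue)
_M, _Y, _X = 0, 1, 2


class StepKind(enum.Enum):
    MATCH = "match"
    GAP_IN_SEQ = "gap_in_seq"
    GAP_IN_PWM = "gap_in_pwm"


class Step(NamedTuple):
    kind: StepKind
    seq_index: Optional[int]  # residue consumed (0-based), None for GAP_IN_SEQ
    col_index: Optional[int]  # PWM column consumed (0-based), None for GAP_IN_PWM


@dataclass(frozen=True)
class AlignmentPath:
    """A global sequence-vs-PWM alignment: ordered steps and the score."""

    steps: tuple[Step, ...]
    fmax: float

    def n_matches(self) -> int:
        return sum(1 for s in self.steps if s.kind is StepKind.MATCH)

    def aligned_row(self, residues: str) -> str:
        """Render the sequence row implied by the path ('-' at GAP_IN_SEQ)."""
        out = []
        for s in self.steps:
            if s.kind is StepKind.GAP_IN_SEQ:
                out.append(GAP)
            else:
                out.append(residues[s.seq_index])
        return "".join(out)


@njit(cache=True)
def _score_only(s, d, e):
    """Terminal global score for a precomputed match-score matrix s (n x L)."""
    n, L = s.shape
    prev_m = np.full(L + 1, _NEG)
    prev_x = np.full(L + 1, _NEG)
    prev_y = np.full(L + 1, _NEG)
    cur_m = np.empty(L + 1)
    cur_x = np.empty(L + 1)
    cur_y = np.empty(L + 1)
    prev_m[0] = 0.0
    for j in range(1, L + 1):
        prev_y[j] = -d - (j - 1) * e
    for i in range(1, n + 1):
        cur_m[0] = _NEG
        cur_y[0] = _NEG
        cur_x[0] = -d - (i - 1) * e
        for j in range(1, L + 1):
            best = prev_m[j - 1]
            if prev_y[j - 1] > best:
                best = prev_y[j - 1]
            if prev_x[j - 1] > best:
                best = prev_x[j - 1]
            cur_m[j] = best + s[i - 1, j - 1]
            vx = prev_m[j] - d
            if prev_y[j] - d > vx:
                vx = prev_y[j] - d
            if prev_x[j] - e > vx:
                vx = prev_x[j] - e
            cur_x[j] = vx
            vy = cur_m[j - 1] - d
            if cur_y[j - 1] - e > vy:
                vy = cur_y[j - 1] - e
            if cur_x[j - 1] - d > vy:
                vy = cur_x[j - 1] - d
            cur_y[j] = vy
        prev_m, cur_m = cur_m, prev_m
        prev_x, cur_x = cur_x, prev_x
        prev_y, cur_y = cur_y, prev_y
    best = prev_m[L]
    if prev_y[L] > best:
        best = prev_y[L]
    if prev_x[L] > best:
        best = prev_x[L]
    return best


@njit(cache=True)
def _full_dp(s, d, e):
    """Full three-state DP with backpointers (predecessor state per cell)."""
    n, L = s.shape
    m = np.full((n + 1, L + 1), _NEG)
    x = np.full((n + 1, L + 1), _NEG)
    y = np.full((n + 1, L + 1), _NEG)
    pm = np.zeros((n + 1, L + 1), dtype=np.int8)
    px = np.zeros((n + 1, L + 1), dtype=np.int8)
    py = np.zeros((n + 1, L + 1), dtype=np.int8)
    m[0, 0] = 0.0
    for j in range(1, L + 1):
        if j == 1:
            y[0, j] = m[0, 0] - d
            py[0, j] = _M
        else:
            y[0, j] = y[0, j - 1] - e
            py[0, j] = _Y
    for i in range(1, n + 1):
        if i == 1:
            x[i, 0] = m[0, 0] - d
            px[i, 0] = _M
        else:
            x[i, 0] = x[i - 1, 0] - e
            px[i, 0] = _X
        for j in range(1, L + 1):
            # match: priority M > Y > X at ties
            best = m[i - 1, j - 1]
            st = _M
            if y[i - 1, j - 1] > best:
                best = y[i - 1, j - 1]
                st = _Y
            if x[i - 1, j - 1] > best:
                best = x[i - 1, j - 1]
                st = _X
            m[i, j] = best + s[i - 1, j - 1]
            pm[i, j] = st
            # gap in PWM (consume residue i)
            best = m[i - 1, j] - d
            st = _M
            if y[i - 1, j] - d > best:
                best = y[i - 1, j] - d
                st = _Y
            if x[i - 1, j] - e > best:
                best = x[i - 1, j] - e
                st = _X
            x[i, j] = best
            px[i, j] = st
            # gap in sequence (consume column j)
            best = m[i, j - 1] - d
            st = _M
            if y[i, j - 1] - e > best:
                best = y[i, j - 1] - e
                st = _Y
            if x[i, j - 1] - d > best:
                best = x[i, j - 1] - d
                st = _X
            y[i, j] = best
            py[i, j] = st
    return m, x, y, pm, px, py


def _match_scores(seq: ProteinSequence, w: WeightMatrix) -> np.ndarray:
    return np.ascontiguousarray(w.weights[seq.codes, :])


def global_align(seq: ProteinSequence, w: WeightMatrix,
                 params: ScoringParams) -> AlignmentPath:
    """Optimal global alignment of ``seq`` against the PWM, with traceback."""
    s = _match_scores(seq, w)
    m, x, y, pm, px, py = _full_dp(s, params.d, params.e)
    n, L = s.shape
    # terminal state, priority M > Y > X
    state = _M
    best = m[n, L]
    if y[n, L] > best:
        best, state = y[n, L], _Y
    if x[n, L] > best:
        best, state = x[n, L], _X
    fmax = float(best)
    steps: list[Step] = []
    i, j = n, L
    while i > 0 or j > 0:
        if state == _M:
            steps.append(Step(StepKind.MATCH, i - 1, j - 1))
            state = int(pm[i, j])
            i -= 1
            j -= 1
        elif state == _Y:
            steps.append(Step(StepKind.GAP_IN_SEQ, None, j - 1))
            state = int(py[i, j])
            j -= 1
        else:
            steps.append(Step(StepKind.GAP_IN_PWM, i - 1, None))
            state = int(px[i, j])
            i -= 1
    steps.reverse()
    return AlignmentPath(tuple(steps), fmax)


def alignment_score(seq: ProteinSequence, w: WeightMatrix,
                    params: ScoringParams) -> float:
    """Fmax only (no traceback); the optimizer's inner call."""
    return float(_score_only(_match_scores(seq, w), params.d, params.e))


def set_objective(si: SequenceSet, w: WeightMatrix,
                  params: ScoringParams) -> float:
    """The objective mF: sum of Fmax over all sequences of the set."""
    return sum(alignment_score(seq, w, params) for seq in si)


def replay_score(path: AlignmentPath, seq: ProteinSequence, w: WeightMatrix,
                 params: ScoringParams) -> float:
    """Recompute the score of a path from its steps (independent of the DP).

    Sums PWM cells over MATCH steps and charges each maximal gap run of
    length g (in either direction) d + (g-1) e.  Used to validate that a
    traceback reproduces Fmax exactly.
    """
    total = 0.0
    codes = seq.codes
    run_kind: StepKind | None = None
    run_len = 0
    for step in path.steps:
        if step.kind is StepKind.MATCH:
            if run_kind is not None:
                total -= params.d + (run_len - 1) * params.e
                run_kind, run_len = None, 0
            total += w.weights[codes[step.seq_index], step.col_index]
        else:
            if step.kind is run_kind:
                run_len += 1
            else:
                if run_kind is not None:
                    total -= params.d + (run_len - 1) * params.e
                run_kind, run_len = step.kind, 1
    if run_kind is not None:
        total -= params.d + (run_len - 1) * params.e
    return total


def validate_path(path: AlignmentPath, seq_length: int, n_columns: int) -> None:
    """Check step bookkeeping: residues and columns each consumed exactly once."""
    i = j = 0
    for step in path.steps:
        if step.kind is StepKind.MATCH:
            if step.seq_index != i or step.col_index != j:
                raise ValueError("path steps out of order")
            i += 1
            j += 1
        elif step.kind is StepKind.GAP_IN_SEQ:
            if step.col_index != j:
                raise ValueError("path steps out of order")
            j += 1
        else:
            if step.seq_index != i:
                raise ValueError("path steps out of order")
            i += 1
    if i != seq_length or j != n_columns:
        raise ValueError(
            f"path consumes {i} residues / {j} columns, "
            f"expected {seq_length} / {n_columns}"
        )
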