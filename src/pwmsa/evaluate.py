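"""Column score: fraction of alignment columns agreeing with a reference.

A test column counts as correct only if its complete residue/gap
configuration — which ordinal residue of each sequence it holds, and which
sequences are gapped — occurs as a column of the reference alignment.
The denominator is the number of columns of the evaluated alignment, so
the score lies in [0, 1] and equals 1 exactly for the reference itself.
"""

from __future__ import annotations

from .io import GAP, MultipleAlignment


class AlignmentMismatchError(ValueError):
    """Test and reference alignments do not contain the same sequences."""


def _column_signatures(ma: MultipleAlignment, id_order: list[str]):
    """Per-column tuples of residue ordinals (None where gapped).

    The ordinal identifies *which* residue of the original sequence sits
    in the column, so the signature is invariant to row order and to the
    actual residue letters' positions within the alignment.
    """
    row_of = {rid: i for i, rid in enumerate(ma.row_ids)}
    rows = [ma.rows[row_of[rid]] for rid in id_order]
    ordinals = [0] * len(rows)
    sigs = []
    for j in range(ma.k):
        sig = []
        for r, row in enumerate(rows):
            if row[j] == GAP:
                sig.append(None)
            else:
                sig.append(ordinals[r])
                ordinals[r] += 1
        sigs.append(tuple(sig))
    return sigs


def column_score(test: MultipleAlignment,
                 reference: MultipleAlignment) -> float:
    """CS of ``test`` against ``reference`` (same sequences required)."""
    if set(test.row_ids) != set(reference.row_ids):
        raise AlignmentMismatchError(
            "test and reference alignments have different sequence ids"
        )
    test_seqs = {s.id: s.residues for s in test.degap()}
    ref_seqs = {s.id: s.residues for s in reference.degap()}
    for rid, res in test_seqs.items():
        if ref_seqs[rid] != res:
            raise AlignmentMismatchError(
                f"sequence {rid!r} differs between test and reference"
            )
    id_order = sorted(test.row_ids)
    ref_columns = set(_column_signatures(reference, id_order))
    test_columns = _column_signatures(test, id_order)
    matches = sum(1 for sig in test_columns if sig in ref_columns)
    return matches / test.k
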