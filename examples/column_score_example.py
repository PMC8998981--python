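"""Column score: compare a test alignment against a reference.

A column counts as correct only when its complete residue/gap
configuration occurs in the reference; CS is the fraction of such
columns among the test alignment's columns.
"""

from pwmsa import MultipleAlignment, column_score

reference = MultipleAlignment(
    ["a", "b", "c"],
    ["ACDE-FG",
     "ACDEWFG",
     "AC-EWFG"],
)
# same sequences, one gap placed differently in row a
test = MultipleAlignment(
    ["a", "b", "c"],
    ["ACD-EFG",
     "ACDEWFG",
     "AC-EWFG"],
)
print(f"CS(reference, reference) = {column_score(reference, reference):.4f}")
print(f"CS(test, reference)      = {column_score(test, reference):.4f}")
# Moving one gap disturbs every column between the two placements; only
# the columns left of the first gap and right of the re-synchronization
# point still match the reference.
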