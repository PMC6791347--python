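"""Indel coordinate normalization shared by the simulator and the caller.

Indels inside repeats have several equivalent placements; both the
lesion injector (truth records) and the mutation caller left-align
before reporting, so coordinates are comparable exactly.
"""

from __future__ import annotations


def left_normalize_deletion(ref: str, pos0: int, length: int) -> int:
    """Leftmost equivalent start (0-based) of deleting ``ref[pos0:pos0+length]``."""
    while pos0 > 0 and ref[pos0 - 1] == ref[pos0 + length - 1]:
        pos0 -= 1
    return pos0


def left_normalize_insertion(ref: str, pos0: int, ins: str) -> tuple[int, str]:
    """Leftmost equivalent placement of inserting ``ins`` before ``ref[pos0]``.

    Returns the normalized 0-based insertion point and the rotated
    inserted string.
    """
    while pos0 > 0 and ins and ref[pos0 - 1] == ins[-1]:
        ins = ref[pos0 - 1] + ins[:-1]
        pos0 -= 1
    return pos0, ins
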