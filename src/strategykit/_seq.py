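"""Low-level sequence and coordinate helpers shared across modules.

Genomic coordinates are 1-based inclusive at every public surface (matching
GenBank); slicing helpers convert to 0-based half-open internally.  Circular
genomes wrap through position ``length`` back to 1.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# A,C,G,T -> 0..3; anything else (ambiguity codes) -> 4
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i

BASES = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 (A=0,C=1,G=2,T=3, other=4)."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def is_acgt(seq: str) -> bool:
    return bool((encode(seq) < 4).all())


def wrap_coord(pos: int, length: int) -> int:
    """Fold a 1-based coordinate onto a circular genome of ``length`` bp."""
    return (pos - 1) % length + 1


def circular_slice(sequence: str, start: int, end: int) -> str:
    """1-based inclusive slice that may wrap through the origin (start > end)."""
    n = len(sequence)
    start = wrap_coord(start, n)
    end = wrap_coord(end, n)
    if start <= end:
        return sequence[start - 1 : end]
    return sequence[start - 1 :] + sequence[:end]


def interval_length(start: int, end: int, genome_length: int) -> int:
    """Length of a 1-based inclusive interval, wrapping if start > end."""
    if start <= end:
        return end - start + 1
    return genome_length - start + 1 + end
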