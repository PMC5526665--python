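"""Nucleotide string helpers shared across modules."""
from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (A=0,C=1,G=2,T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    """Reverse complement; ambiguity codes collapse to N upstream of here."""
    return seq.translate(_COMPLEMENT)[::-1]


def sanitize(seq: str) -> str:
    """Uppercase and map every character outside {A,C,G,T} to N."""
    seq = seq.upper()
    if set(seq) <= set("ACGT"):
        return seq
    return "".join(c if c in "ACGTN" else "N" for c in seq)


def hamming_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (no gaps)."""
    if len(a) != len(b):
        raise ValueError("hamming_identity requires equal-length sequences")
    if not a:
        raise ValueError("empty sequences")
    ea, eb = encode(a), encode(b)
    matches = int(np.sum((ea == eb) & (ea < 4)))
    return 100.0 * matches / len(a)
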