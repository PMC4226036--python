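"""Small DNA sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# numeric encoding used by the vectorised detectors
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.int8)  # A<->T, C<->G, N->N


def normalize(seq: str) -> str:
    """Uppercase and collapse every non-ACGT character (ambiguity codes, gaps) to N."""
    s = seq.upper()
    return "".join(c if c in "ACGT" else "N" for c in s)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGTN as int8 codes 0..4 (4 = N, matches nothing)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def complement_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes]


def gc_percent(seq: str) -> float:
    """GC content as 100*(G+C)/(A+C+G+T); raises ValueError if no unambiguous base."""
    a = seq.count("A")
    c = seq.count("C")
    g = seq.count("G")
    t = seq.count("T")
    denom = a + c + g + t
    if denom == 0:
        raise ValueError("GC content undefined: sequence contains no unambiguous base")
    return 100.0 * (g + c) / denom
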