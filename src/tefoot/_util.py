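"""Small shared helpers: sequence codes and reverse complements."""
from __future__ import annotations

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMP = str.maketrans("ACGTN", "TGCAN")

UNIFORM_COLUMN = np.full(4, 0.25)


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string (N allowed)."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3). Raises on other letters."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for base, code in _CODE.items():
        out[arr == ord(base)] = code
    if (out == 255).any():
        bad = chr(arr[int(np.argmax(out == 255))])
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return out


def decode(codes: np.ndarray) -> str:
    """uint8 codes -> DNA string."""
    lut = np.frombuffer("ACGT".encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")
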