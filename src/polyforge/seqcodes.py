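"""Shared base encodings and the four alignment roles.

Sequences travel through the simulator as uint8 arrays (A=0, C=1, G=2, T=3)
and through alignments as ASCII byte matrices; both encodings live here.
"""

from __future__ import annotations

import numpy as np

#: the four rows of an orthologous alignment: tetraploid subgenome A,
#: tetraploid subgenome B, and two accessions of the A-lineage diploid.
ROLES = ("tet_A", "tet_B", "dip_1", "dip_2")
TET_A, TET_B, DIP_1, DIP_2 = ROLES

BASES = "ACGT"
GAP = "-"

#: code (0..3) -> complement code
COMP_CODE = np.array([3, 2, 1, 0], dtype=np.uint8)

_CODE_OF = {b: i for i, b in enumerate(BASES)}

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """ACGT string -> uint8 code array."""
    raw = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(raw.size, 255, dtype=np.uint8)
    for base, code in _CODE_OF.items():
        out[raw == ord(base)] = code
    if (out == 255).any():
        raise ValueError("sequence contains characters outside ACGT")
    return out


def decode(codes: np.ndarray) -> str:
    """uint8 code array -> ACGT string."""
    return _DECODE[codes].tobytes().decode()


def complement_base(b: str) -> str:
    return {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}[b]


def random_codes(rng: np.random.Generator, n: int, gc: float = 0.38) -> np.ndarray:
    """Random sequence codes with the given GC content."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)
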