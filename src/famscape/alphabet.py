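"""Amino-acid alphabet, background composition and substitution matrices.

Everything downstream works on integer-encoded sequences: the 20 standard
residues are coded 0..19 in BLOSUM order, and any other letter (ambiguity
codes B/Z/X/J/U/O, or stray characters) is coded 20 and scores 0 against
everything.
"""

from __future__ import annotations

import warnings

import numpy as np
from Bio.Align import substitution_matrices

#: Standard residues in BLOSUM ordering; index in this string is the residue code.
RESIDUES = "ARNDCQEGHILKMFPSTWYV"

#: Code used for ambiguous / unknown letters.
UNKNOWN_CODE = 20

#: Average amino-acid composition of proteins (Robinson & Robinson frequencies,
#: the standard BLAST background), ordered as ``RESIDUES``.
BACKGROUND = np.array(
    [
        0.07805,  # A
        0.05129,  # R
        0.04487,  # N
        0.05364,  # D
        0.01925,  # C
        0.04264,  # Q
        0.06295,  # E
        0.07377,  # G
        0.02199,  # H
        0.05142,  # I
        0.09019,  # L
        0.05744,  # K
        0.02243,  # M
        0.03856,  # F
        0.05203,  # P
        0.07120,  # S
        0.05841,  # T
        0.01330,  # W
        0.03216,  # Y
        0.06441,  # V
    ]
)
BACKGROUND = BACKGROUND / BACKGROUND.sum()

_CODE_OF = {aa: i for i, aa in enumerate(RESIDUES)}


def encode(seq: str, warn_unknown: bool = True) -> np.ndarray:
    """Encode a residue string to an int8 array (unknowns -> ``UNKNOWN_CODE``)."""
    if not seq:
        raise ValueError("empty sequence")
    codes = np.fromiter(
        (_CODE_OF.get(c, UNKNOWN_CODE) for c in seq.upper()), dtype=np.int8, count=len(seq)
    )
    if warn_unknown and (codes == UNKNOWN_CODE).any():
        bad = sorted({c for c in seq.upper() if c not in _CODE_OF})
        warnings.warn(f"non-standard residues {bad} scored as neutral", stacklevel=2)
    return codes


def decode(codes: np.ndarray) -> str:
    return "".join(RESIDUES[c] if c < 20 else "X" for c in codes)


def load_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Return a 21x21 float substitution matrix over our code space.

    Row/column 20 (unknown) scores 0 against everything.
    """
    m = substitution_matrices.load(name)
    out = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(RESIDUES):
        for j, b in enumerate(RESIDUES):
            out[i, j] = m[a][b]
    return out


def random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    """Draw an int8 sequence of the given length from the background composition."""
    return rng.choice(20, size=length, p=BACKGROUND).astype(np.int8)
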