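"""Five-state RNA alphabet shared by all modules.

The state order is fixed as ``(-, A, C, G, U)`` with the gap in position 0;
the gap doubles as the reference state of the mean-field inversion, so the
order is part of the numerical contract and must not be changed.
"""

from __future__ import annotations

import numpy as np

GAP = "-"
ALPHABET: tuple[str, ...] = (GAP, "A", "C", "G", "U")
Q = len(ALPHABET)
GAP_STATE = 0

_INDEX = {c: i for i, c in enumerate(ALPHABET)}

#: Watson-Crick pairs plus the G-U wobble pair, the combinations eligible
#: for base pairing on a specific sequence.
WC_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")})
WOBBLE_PAIRS = frozenset({("G", "U"), ("U", "G")})
PAIRABLE = WC_PAIRS | WOBBLE_PAIRS


def can_pair(a: str, b: str) -> bool:
    """True if nucleotides *a*, *b* form a Watson-Crick or wobble pair."""
    return (a, b) in PAIRABLE


def normalize_char(c: str) -> str:
    """Map one raw alignment character onto the 5-letter alphabet.

    ``T``/``t`` become ``U``; lowercase is uppercased; anything that is not
    then one of ``ACGU`` (dots, ``N``, IUPAC degenerate codes, ``*`` ...)
    becomes the gap character.
    """
    c = c.upper()
    if c == "T":
        return "U"
    return c if c in ("A", "C", "G", "U") else GAP


def normalize_sequence(s: str) -> str:
    return "".join(normalize_char(c) for c in s)


def encode(rows: list[str]) -> np.ndarray:
    """Encode normalized rows as an ``(M, L)`` int8 matrix of state indices."""
    mat = np.empty((len(rows), len(rows[0]) if rows else 0), dtype=np.int8)
    for m, row in enumerate(rows):
        mat[m] = [_INDEX[c] for c in row]
    return mat


def decode(mat: np.ndarray) -> list[str]:
    letters = np.array(ALPHABET)
    return ["".join(letters[row]) for row in np.asarray(mat)]
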