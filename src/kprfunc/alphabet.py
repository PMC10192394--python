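"""The 24-letter peptide alphabet and the canonical pair-feature order.

Peptide windows are written over 24 characters: the 20 standard amino
acids, the ambiguity codes B, Z, X, and ``*`` which both pads windows
beyond protein termini and is a scored symbol of the substitution
matrix. Embedding features are indexed by unordered character pairs
{a, b} with repetition, giving 24 * 25 / 2 = 300 features in a fixed
canonical order: standard residues alphabetically, then B, Z, X, ``*``
(so the first features are S_AA, S_AC, S_AD, ... and the last is S_**).
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

#: 20 standard residues (alphabetical), then the non-canonical symbols.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY" + "BZX*"

#: Characters accepted in protein sequences (no padding symbol).
SEQUENCE_ALPHABET: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWYBZX")

ALPHABET_SIZE = len(ALPHABET)  # 24
N_PAIRS = ALPHABET_SIZE * (ALPHABET_SIZE + 1) // 2  # 300

CHAR_INDEX: dict[str, int] = {c: i for i, c in enumerate(ALPHABET)}

#: PAIR_INDEX[i, j] -> feature index of the unordered pair {ALPHABET[i], ALPHABET[j]}.
PAIR_INDEX = np.empty((ALPHABET_SIZE, ALPHABET_SIZE), dtype=np.intp)
_pairs: list[tuple[str, str]] = []
for _k, (_i, _j) in enumerate(
    itertools.combinations_with_replacement(range(ALPHABET_SIZE), 2)
):
    PAIR_INDEX[_i, _j] = _k
    PAIR_INDEX[_j, _i] = _k
    _pairs.append((ALPHABET[_i], ALPHABET[_j]))

#: Feature k corresponds to the unordered pair PAIR_LABELS[k].
PAIR_LABELS: tuple[tuple[str, str], ...] = tuple(_pairs)
del _pairs


def pair_feature_index(a: str, b: str) -> int:
    """Feature index of the unordered character pair {a, b}."""
    try:
        return int(PAIR_INDEX[CHAR_INDEX[a], CHAR_INDEX[b]])
    except KeyError as exc:
        raise ValueError(f"character {exc.args[0]!r} outside the 24-letter alphabet")


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide string to integer character indices.

    Raises ValueError naming the offending character and its position.
    """
    try:
        return np.fromiter(
            (CHAR_INDEX[c] for c in peptide), dtype=np.intp, count=len(peptide)
        )
    except KeyError:
        for pos, c in enumerate(peptide, start=1):
            if c not in CHAR_INDEX:
                raise ValueError(
                    f"character {c!r} at peptide position {pos} is outside "
                    f"the 24-letter alphabet"
                ) from None
        raise  # pragma: no cover


def blosum62() -> np.ndarray:
    """BLOSUM62 as a symmetric (24, 24) float array in canonical order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((ALPHABET_SIZE, ALPHABET_SIZE), dtype=float)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out
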