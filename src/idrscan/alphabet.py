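"""Amino-acid alphabets and residue classes.

The 20 canonical one-letter codes are kept in a fixed order so that
composition vectors and interaction matrices index consistently across
modules.  Residues are split into the two classes commonly used in
intrinsic-disorder work: disorder-promoting (P, E, S, K, Q, H, D, R, G, A)
and order-promoting (T, C, N, V, L, M, I, Y, F, W).
"""

from __future__ import annotations

import numpy as np

#: Canonical residues, alphabetical by one-letter code.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Ambiguity / rare codes tolerated in lenient mode (NCBI predicted
#: proteins frequently contain X runs).
NONSTANDARD = "BZXUOJ"

DISORDER_PROMOTING = frozenset("PESKQHDRGA")
ORDER_PROMOTING = frozenset("TCNVLMIYFW")

assert DISORDER_PROMOTING | ORDER_PROMOTING == frozenset(CANONICAL)
assert not (DISORDER_PROMOTING & ORDER_PROMOTING)

#: Index of each canonical residue in ``CANONICAL``.
AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL)}

#: Sentinel index used for nonstandard residues in encoded sequences.
NONSTANDARD_INDEX = len(CANONICAL)


def validate_sequence(sequence: str, strict: bool = False) -> None:
    """Raise ``ValueError`` if *sequence* contains letters outside the
    accepted alphabet (canonical only when *strict*)."""
    allowed = set(CANONICAL) if strict else set(CANONICAL + NONSTANDARD)
    for pos, aa in enumerate(sequence, start=1):
        if aa not in allowed:
            raise ValueError(
                f"invalid residue {aa!r} at position {pos}"
                + ("" if strict else " (not canonical or ambiguity code)")
            )


def encode(sequence: str, strict: bool = False) -> np.ndarray:
    """Encode a sequence as integer indices into ``CANONICAL``.

    Nonstandard residues map to ``NONSTANDARD_INDEX`` in lenient mode and
    raise in strict mode.
    """
    validate_sequence(sequence, strict=strict)
    return np.array(
        [AA_INDEX.get(aa, NONSTANDARD_INDEX) for aa in sequence], dtype=np.intp
    )
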