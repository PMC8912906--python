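"""Small shared DNA-string helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); N excluded from the denominator."""
    g = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return g / denom
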