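"""Amplicon complexity: diversity of the structure decomposition.

A focal amplification whose copy counts are explained by a single walk is
structurally simple; one requiring many comparably weighted walks is complex.
We quantify this as the Shannon entropy (base 2) of the normalised walk
weights: 0 bits for a single structure, log2(k) bits for k equally weighted
structures.  Values are in bits and comparable only within this package.
"""

from __future__ import annotations

import numpy as np

from .graphio import Decomposition


def complexity_score(decomp: Decomposition) -> float:
    """Shannon entropy H = -sum f_i log2 f_i of positive decomposition weights.

    Raises ValueError when the decomposition has no positive-weight element.
    Scale-invariant and permutation-invariant; bounded by log2(#elements).
    """
    weights = np.array([c.weight for c in decomp.cycles if c.weight > 0], dtype=float)
    if weights.size == 0:
        raise ValueError(
            f"decomposition {decomp.amplicon_id!r} has no positive-weight walk"
        )
    f = weights / weights.sum()
    return float(-(f * np.log2(f)).sum())
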