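"""Mass bookkeeping: adduct counts from observed-vs-theoretical mass gaps.

Inputs are in kDa for species masses and Da for the adduct, matching how
SEC-MALS results are usually reported; the conversion is explicit here.
"""

from __future__ import annotations

import math
from typing import Sequence

__all__ = ["count_adducts", "complex_mass"]


def count_adducts(observed_kda: float, theoretical_kda: float, adduct_da: float) -> int:
    """Number of adducts accounting for the observed - theoretical mass gap.

    count = floor((observed - theoretical) * 1000 / adduct). The floor matches
    the "approximately N" convention used when quoting such counts.
    """
    if adduct_da <= 0:
        raise ValueError("adduct mass must be positive")
    diff_da = (observed_kda - theoretical_kda) * 1000.0
    if diff_da < 0:
        raise ValueError(
            f"observed mass {observed_kda} kDa below theoretical {theoretical_kda} kDa"
        )
    return math.floor(diff_da / adduct_da)


def complex_mass(components: Sequence[tuple[float, int]]) -> float:
    """Total mass (kDa) of a complex given (subunit mass kDa, copy count) pairs."""
    total = 0.0
    for mass, count in components:
        if count < 1:
            raise ValueError("component count must be >= 1")
        total += mass * count
    return total
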