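"""Beta-diversity between adjacent elevational belts: Jaccard and Cody.

With ``a`` = species unique to the first belt, ``b`` = unique to the
second, ``c`` = shared:

* Jaccard similarity  beta_j = c / (a + b + c)  — 1 for identical belts,
  0 for disjoint ones;
* Cody turnover       beta_c = (gains + losses) / 2 = (|A| + |B| - 2c) / 2.

Printed formulations of these indices sometimes define ``a`` and ``b`` as
the *total* richness of the two communities, which breaks the identity
beta_j(A, A) = 1; both readings are therefore available, with the standard
one as the default, and every output records which convention produced it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .belts import BeltMatrix

logger = logging.getLogger(__name__)

__all__ = ["BeltPairStats", "jaccard_similarity", "cody_index", "adjacent_belt_profile"]


@dataclass(frozen=True)
class BeltPairStats:
    """Partition counts and indices for one pair of adjacent belts."""

    belt_lo_1: float
    belt_lo_2: float
    a: int  # unique to first belt
    b: int  # unique to second belt
    c: int  # shared
    beta_j: float
    beta_c: float
    jaccard_convention: str = "unique_counts"
    cody_convention: str = "half"


def _partition(set_a: set, set_b: set) -> tuple[int, int, int]:
    c = len(set_a & set_b)
    return len(set_a) - c, len(set_b) - c, c


def jaccard_similarity(set_a: set, set_b: set, convention: str = "unique_counts") -> float:
    """Jaccard similarity between two assemblages.

    ``unique_counts`` (default): c/(a+b+c) with a, b the belt-unique
    species counts — the standard Jaccard c/(|A|+|B|-c). ``literal_totals``:
    c/(|A|+|B|+c), a literal reading with a, b as total richness.
    """
    if not set_a and not set_b:
        raise ValueError("Jaccard undefined for two empty assemblages")
    a, b, c = _partition(set_a, set_b)
    if convention == "unique_counts":
        return c / (a + b + c)
    if convention == "literal_totals":
        return c / (len(set_a) + len(set_b) + c)
    raise ValueError(f"unknown Jaccard convention {convention!r}")


def cody_index(set_a: set, set_b: set, convention: str = "half") -> float:
    """Cody turnover between two assemblages.

    ``half`` (default): (|A|+|B|-2c)/2, i.e. (gains+losses)/2 — the
    standard Cody index. ``over_c``: (|A|+|B|-2c)/c, undefined when the
    assemblages share nothing.
    """
    if not set_a and not set_b:
        raise ValueError("Cody index undefined for two empty assemblages")
    _a, _b, c = _partition(set_a, set_b)
    num = len(set_a) + len(set_b) - 2 * c
    if convention == "half":
        return num / 2.0
    if convention == "over_c":
        if c == 0:
            raise ValueError("Cody 'over_c' convention undefined when no species are shared")
        return num / c
    raise ValueError(f"unknown Cody convention {convention!r}")


def adjacent_belt_profile(
    matrix: BeltMatrix,
    jaccard_convention: str = "unique_counts",
    cody_convention: str = "half",
) -> list[BeltPairStats]:
    """Beta-diversity between each pair of consecutive non-empty belts.

    Empty belts are skipped (with a warning), not treated as
    zero-similarity partners. Needs at least two non-empty belts.
    """
    non_empty = [
        (lo, matrix.belt_taxa(i))
        for i, lo in enumerate(matrix.grid.lower_bounds)
        if matrix.presence.iloc[i].sum() > 0
    ]
    n_skipped = matrix.grid.n_belts - len(non_empty)
    if n_skipped:
        logger.warning("%d empty belts skipped in beta-diversity profile", n_skipped)
    if len(non_empty) < 2:
        raise ValueError("need at least 2 non-empty belts for a beta-diversity profile")
    out = []
    for (lo1, s1), (lo2, s2) in zip(non_empty, non_empty[1:]):
        a, b, c = _partition(s1, s2)
        out.append(
            BeltPairStats(
                lo1, lo2, a, b, c,
                beta_j=jaccard_similarity(s1, s2, jaccard_convention),
                beta_c=cody_index(s1, s2, cody_convention),
                jaccard_convention=jaccard_convention,
                cody_convention=cody_convention,
            )
        )
    return out


def profile_to_frame(profile: list[BeltPairStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "belt_pair": [f"{p.belt_lo_1:g}-{p.belt_lo_2:g}" for p in profile],
            "a": [p.a for p in profile],
            "b": [p.b for p in profile],
            "c": [p.c for p in profile],
            "beta_j": [p.beta_j for p in profile],
            "beta_c": [p.beta_c for p in profile],
            "jaccard_convention": [p.jaccard_convention for p in profile],
            "cody_convention": [p.cody_convention for p in profile],
        }
    )
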