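"""Independent reference implementations used to check the statistics.

Everything here avoids scipy on purpose: upper-tail hypergeometric
probabilities are computed with exact integer arithmetic (``math.comb``),
and for very small populations additionally by literal enumeration of all
draws with ``itertools.combinations``.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def hypergeom_upper_tail_exact(k: int, population: int, successes: int,
                               draws: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population, successes, draws).

    Exact rational arithmetic; independent of scipy.
    """
    if k <= 0:
        return 1.0
    total = math.comb(population, draws)
    acc = 0
    upper = min(successes, draws)
    for x in range(k, upper + 1):
        acc += math.comb(successes, x) * math.comb(
            population - successes, draws - x
        )
    return float(Fraction(acc, total))


def hypergeom_upper_tail_enumerate(k: int, population: int, successes: int,
                                   draws: int) -> float:
    """P(X >= k) by enumerating every possible draw (tiny populations)."""
    items = [1] * successes + [0] * (population - successes)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(population), draws):
        total += 1
        if sum(items[i] for i in combo) >= k:
            hits += 1
    return hits / total
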