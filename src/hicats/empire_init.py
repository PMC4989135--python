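"""Empire formation: rank countries, pick imperialists, allocate colonies.

The strongest ``n_imp`` countries become imperialists; the remaining
``n_col = n_pop - n_imp`` countries are distributed as colonies in
proportion to normalised imperialist power: fitnesses are min-shifted
(the weakest imperialist maps to 0), normalised to sum to 1, and colony
counts are ``round(p_m * n_col)`` with an exact-sum repair and a floor
of one colony per empire.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Country

__all__ = [
    "Empire",
    "normalize_imperialist_fitness",
    "imperialist_powers",
    "allocate_colonies",
    "initialize_empires",
]


@dataclass
class Empire:
    """An imperialist country and its colonies."""

    imperialist: Country
    colonies: list[Country] = field(default_factory=list)

    @property
    def size(self) -> int:
        """Total countries in the empire (imperialist included)."""
        return 1 + len(self.colonies)


def normalize_imperialist_fitness(fits) -> np.ndarray:
    """Min-shift imperialist fitnesses so the weakest maps to 0."""
    fits = np.asarray(fits, dtype=float)
    if fits.size == 0:
        raise ValueError("need at least one imperialist")
    return fits - fits.min()


def imperialist_powers(normalized) -> np.ndarray:
    """Normalise shifted fitnesses to a probability vector.

    When every imperialist ties the shift is all-zero (0/0); the uniform
    distribution is returned so a cold start still allocates colonies.
    """
    normalized = np.asarray(normalized, dtype=float)
    if np.any(normalized < 0):
        raise ValueError("normalized fitnesses must be non-negative")
    total = normalized.sum()
    if total == 0.0:
        return np.full(normalized.shape, 1.0 / normalized.size)
    return normalized / total


def allocate_colonies(powers, n_col: int) -> np.ndarray:
    """Integer colony counts per imperialist, summing exactly to ``n_col``.

    Counts start from ``round(p_m * n_col)``. Rounding can break the sum:
    an excess is removed from the holders with the largest fractional
    remainder first, a deficit is added there first. Finally, when there
    are at least as many colonies as empires, each empire is guaranteed
    one colony by moving a colony from the richest empire to every empty
    one — an empire starting with zero colonies would be eliminated on
    the first competition step, degenerating the multi-population search.
    """
    if n_col < 0:
        raise ValueError(f"n_col must be non-negative, got {n_col}")
    powers = np.asarray(powers, dtype=float)
    raw = powers * n_col
    counts = np.rint(raw).astype(int)
    frac = raw - np.floor(raw)
    while counts.sum() > n_col:
        candidates = np.flatnonzero(counts > 0)
        i = candidates[np.argmax(frac[candidates])]
        counts[i] -= 1
        frac[i] -= 1.0
    while counts.sum() < n_col:
        i = int(np.argmax(frac))
        counts[i] += 1
        frac[i] -= 1.0
    if n_col >= powers.size:
        for i in np.flatnonzero(counts == 0):
            counts[int(np.argmax(counts))] -= 1
            counts[i] += 1
    return counts


def initialize_empires(
    population: list[Country], n_imp: int, rng: np.random.Generator
) -> list[Empire]:
    """Form empires from an evaluated population.

    The ``n_imp`` highest-fitness countries (ties broken by lower index)
    become imperialists; the rest are shuffled and dealt to empires
    according to :func:`allocate_colonies`.
    """
    if n_imp < 1:
        raise ValueError("need at least one imperialist")
    if len(population) <= n_imp:
        raise ValueError(
            f"population of {len(population)} cannot support {n_imp} imperialists"
        )
    fits = np.array([c.fitness for c in population], dtype=float)
    order = np.argsort(-fits, kind="stable")
    imperialists = [population[i] for i in order[:n_imp]]
    rest = [population[i] for i in sorted(order[n_imp:])]

    powers = imperialist_powers(
        normalize_imperialist_fitness([c.fitness for c in imperialists])
    )
    counts = allocate_colonies(powers, len(rest))
    shuffled = [rest[i] for i in rng.permutation(len(rest))]
    empires, start = [], 0
    for imp, k in zip(imperialists, counts):
        empires.append(Empire(imp, shuffled[start : start + int(k)]))
        start += int(k)
    return empires
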