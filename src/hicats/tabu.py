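"""Tabu-search refinement of imperialists.

Neighbours of a country are single-bit flips. Each step samples ``k``
distinct flip positions, evaluates the neighbours, and moves to the best
*admissible* one — a neighbour is admissible when its flipped position
is not on the tabu list, or when its fitness beats the best fitness seen
so far (the aspiration criterion, the canonical global-best override).
The accepted move's position becomes tabu for ``tenure`` iterations.
Accepting the best admissible neighbour even when it is worse than the
current solution is what lets the search walk out of local optima; the
caller keeps the best country ever visited, so refinement never loses
ground.

Full neighbourhoods are infeasible at microarray dimension (~10^4 genes,
each neighbour costing a cross-validated classifier), hence the sampled
neighbourhood of size ``k``.
"""

from __future__ import annotations

import numpy as np

from .core import Country, repair_country
from .evaluation import FitnessWeights, SubsetEvaluator

__all__ = ["TabuList", "flip_neighbor", "sample_neighborhood", "tabu_step", "tabu_search"]


class TabuList:
    """Recency memory over flipped bit positions.

    A position is tabu at iteration ``t`` while its recorded expiry
    exceeds ``t``; with ``tenure == 0`` nothing is ever tabu.
    """

    def __init__(self, tenure: int):
        if tenure < 0:
            raise ValueError("tenure must be non-negative")
        self.tenure = tenure
        self.entries: dict[int, int] = {}

    def is_tabu(self, position: int, iteration: int) -> bool:
        return self.entries.get(position, -1) > iteration

    def add(self, position: int, iteration: int) -> None:
        self.entries[position] = iteration + self.tenure

    def active(self, iteration: int) -> list[int]:
        """Positions currently blocked."""
        return [p for p, e in self.entries.items() if e > iteration]


def flip_neighbor(country: Country, position: int) -> Country:
    """Flip one bit (1-based position); all other bits are unchanged."""
    if not 1 <= position <= country.n_genes:
        raise ValueError(f"position {position} outside 1..{country.n_genes}")
    bits = country.bits.copy()
    bits[position - 1] ^= 1
    return Country(bits)


def sample_neighborhood(
    country: Country, k: int, rng: np.random.Generator
) -> list[tuple[int, Country]]:
    """Sample ``min(k, n)`` distinct flip positions uniformly; repair empties."""
    if k < 1:
        raise ValueError("k must be positive")
    n = country.n_genes
    positions = rng.choice(n, size=min(k, n), replace=False) + 1
    out = []
    for p in positions:
        nb = flip_neighbor(country, int(p))
        out.append((int(p), repair_country(nb, rng)))
    return out


def tabu_step(
    current: Country,
    best_so_far_fitness: float,
    tlist: TabuList,
    iteration: int,
    evaluator: SubsetEvaluator,
    weights: FitnessWeights,
    k: int,
    rng: np.random.Generator,
) -> tuple[Country, int | None]:
    """One move: best admissible sampled neighbour, or stay put.

    Returns the next country and the flipped position (``None`` when no
    neighbour was admissible; the tabu list is then left untouched).
    """
    best_pos: int | None = None
    best_nb: Country | None = None
    for pos, nb in sample_neighborhood(current, k, rng):
        evaluator.evaluate(nb, weights)
        admissible = (
            not tlist.is_tabu(pos, iteration) or nb.fitness > best_so_far_fitness
        )
        if admissible and (best_nb is None or nb.fitness > best_nb.fitness):
            best_nb, best_pos = nb, pos
    if best_nb is None:
        return current, None
    tlist.add(best_pos, iteration)
    return best_nb, best_pos


def tabu_search(
    imperialist: Country,
    evaluator: SubsetEvaluator,
    weights: FitnessWeights,
    iters: int,
    k: int,
    tenure: int,
    rng: np.random.Generator,
) -> Country:
    """Refine an evaluated imperialist; returns the best country visited.

    The start is included in the archive, so the returned fitness is
    never below the input fitness.
    """
    best = imperialist
    current = imperialist
    tlist = TabuList(tenure)
    for it in range(iters):
        current, _ = tabu_step(
            current, best.fitness, tlist, it, evaluator, weights, k, rng
        )
        if current.fitness > best.fitness:
            best = current
    return best
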