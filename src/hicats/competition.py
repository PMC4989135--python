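"""Imperialist competition: swap, total power, colony transfer, elimination.

Each generation, after refinement and assimilation: a colony that
out-performs its imperialist takes its place; each empire's total power
is its imperialist fitness plus a damped (``xi``) mean colony fitness;
the weakest empire loses its weakest colony to a stronger empire drawn
by roulette over min-shifted total powers; and empires with no colonies
are dissolved, their imperialist demoted to a colony of the strongest
survivor (demotion, not deletion, keeps the population size constant).
"""

from __future__ import annotations

import numpy as np

from .empire_init import Empire

__all__ = [
    "swap_best_colony",
    "empire_total_power",
    "imperialist_competition",
    "eliminate_empty",
]


def swap_best_colony(empire: Empire) -> Empire:
    """Promote the best colony when it strictly beats the imperialist."""
    if not empire.colonies:
        return empire
    fits = np.array([c.fitness for c in empire.colonies], dtype=float)
    best = int(np.argmax(fits))  # ties -> lowest colony index
    if fits[best] > empire.imperialist.fitness:
        old = empire.imperialist
        empire.imperialist = empire.colonies[best]
        empire.colonies[best] = old
    return empire


def empire_total_power(empire: Empire, xi: float) -> float:
    """Imperialist fitness plus ``xi`` times the mean colony fitness."""
    power = float(empire.imperialist.fitness)
    if empire.colonies:
        power += xi * float(np.mean([c.fitness for c in empire.colonies]))
    return power


def imperialist_competition(
    empires: list[Empire], xi: float, rng: np.random.Generator
) -> list[Empire]:
    """Transfer the weakest empire's weakest colony to a roulette winner.

    Winning probabilities are proportional to total power minus the
    minimum total power; the losing empire is excluded from the draw
    (uniform over the others when all powers tie). A colony-less weakest
    empire is left alone for :func:`eliminate_empty`.
    """
    if len(empires) < 1:
        raise ValueError("need at least one empire")
    if len(empires) < 2:
        return empires
    powers = np.array([empire_total_power(e, xi) for e in empires], dtype=float)
    loser = int(np.argmin(powers))  # ties -> lowest index
    if not empires[loser].colonies:
        return empires
    col_fits = np.array([c.fitness for c in empires[loser].colonies], dtype=float)
    colony = empires[loser].colonies.pop(int(np.argmin(col_fits)))

    candidates = [i for i in range(len(empires)) if i != loser]
    weights = powers[candidates] - powers.min()
    total = weights.sum()
    probs = weights / total if total > 0 else np.full(len(candidates), 1 / len(candidates))
    winner = candidates[rng.choice(len(candidates), p=probs)]
    empires[winner].colonies.append(colony)
    return empires


def eliminate_empty(empires: list[Empire], xi: float = 0.1) -> list[Empire]:
    """Dissolve colony-less empires; their imperialists join the strongest.

    The demoted imperialist becomes a colony of the highest-total-power
    survivor. A single remaining empire is never dissolved.
    """
    if len(empires) <= 1:
        return empires
    survivors = [e for e in empires if e.colonies]
    dissolved = [e for e in empires if not e.colonies]
    if not dissolved:
        return empires
    if not survivors:
        # keep the strongest colony-less empire alive
        fits = np.array([e.imperialist.fitness for e in empires], dtype=float)
        keep = int(np.argmax(fits))
        survivors = [empires[keep]]
        dissolved = [e for i, e in enumerate(empires) if i != keep]
    powers = np.array([empire_total_power(e, xi) for e in survivors], dtype=float)
    strongest = survivors[int(np.argmax(powers))]
    for e in dissolved:
        strongest.colonies.append(e.imperialist)
    return survivors
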