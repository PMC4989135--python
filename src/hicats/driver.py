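"""The HICATS main loop.

One run: draw a random binary population, evaluate it, form empires;
then per generation refine each imperialist by tabu search, assimilate
every colony toward its imperialist, promote colonies that overtake
their imperialist, run the imperialist competition, and dissolve
colony-less empires. The best country ever evaluated is archived
independently of the final population, so the reported result never
regresses. Setting ``tabu_enabled=False`` skips the refinement step and
yields the plain binary imperialist-competition baseline used for
ablation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .assimilation import assimilate
from .competition import (
    eliminate_empty,
    imperialist_competition,
    swap_best_colony,
)
from .core import Country, GeneDataset, random_country, selected_indices
from .empire_init import Empire, initialize_empires
from .evaluation import FitnessWeights, SubsetEvaluator, evaluate_population
from .tabu import tabu_search

__all__ = ["HicatsConfig", "GenerationRecord", "HicatsResult", "run_hicats", "run_ica_baseline"]


@dataclass(frozen=True)
class HicatsConfig:
    """Run parameters.

    Population structure (15 countries, 4 imperialists, hence 11
    colonies), 50 generations and the fitness weights w1=0.8 / w2=0.2
    are the method's standard settings; the remaining knobs (initial
    bit density, tabu-search budget, competition damping ``xi``) default
    to values sized for wrapper selection on expression data, where
    every fitness call costs a cross-validated classifier.
    """

    n_pop: int = 15
    n_imp: int = 4
    generations: int = 50
    w1: float = 0.8
    init_density: float = 0.1
    ts_iters: int = 5
    ts_neighbors: int = 20
    ts_tenure: int = 7
    xi: float = 0.1
    classifier: str = "svm"
    cv: str | int = "loocv"
    seed: int = 0
    tabu_enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_pop <= self.n_imp:
            raise ValueError("n_pop must exceed n_imp")
        if self.n_imp < 1:
            raise ValueError("need at least one imperialist")
        if not 0.0 <= self.w1 <= 1.0:
            raise ValueError("w1 must be in [0, 1]")
        if self.generations < 0:
            raise ValueError("generations must be non-negative")

    @property
    def w2(self) -> float:
        return 1.0 - self.w1

    @property
    def n_col(self) -> int:
        return self.n_pop - self.n_imp

    @property
    def weights(self) -> FitnessWeights:
        return FitnessWeights(self.w1)


@dataclass(frozen=True)
class GenerationRecord:
    generation: int
    best_fitness: float
    best_accuracy: float
    best_n_selected: int
    mean_fitness: float
    evaluations: int
    n_countries: int
    n_empires: int


@dataclass
class HicatsResult:
    """Outcome of one run: elitist best country plus the convergence log."""

    best_country: Country
    best_fitness: float
    best_accuracy: float
    best_n_selected: int
    selected_genes: list[int]
    selected_gene_names: list[str]
    log: list[GenerationRecord] = field(default_factory=list)
    config: HicatsConfig | None = None
    n_evaluations: int = 0


def _all_countries(empires: list[Empire]) -> list[Country]:
    out = []
    for e in empires:
        out.append(e.imperialist)
        out.extend(e.colonies)
    return out


def _record(
    generation: int, empires: list[Empire], evaluator: SubsetEvaluator
) -> GenerationRecord:
    best = evaluator.best
    fits = [c.fitness for c in _all_countries(empires)]
    return GenerationRecord(
        generation=generation,
        best_fitness=float(best.fitness),
        best_accuracy=float(best.accuracy),
        best_n_selected=best.n_selected,
        mean_fitness=float(np.mean(fits)),
        evaluations=evaluator.n_fits,
        n_countries=len(fits),
        n_empires=len(empires),
    )


def run_hicats(
    dataset: GeneDataset,
    config: HicatsConfig = HicatsConfig(),
    rng: np.random.Generator | None = None,
) -> HicatsResult:
    """Run the full search on a dataset; deterministic under a fixed seed."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    weights = config.weights
    evaluator = SubsetEvaluator(dataset, config.classifier, config.cv)

    population = [
        random_country(dataset.n, config.init_density, rng)
        for _ in range(config.n_pop)
    ]
    evaluate_population(population, evaluator, weights)
    empires = initialize_empires(population, config.n_imp, rng)
    log = [_record(0, empires, evaluator)]

    for gen in range(1, config.generations + 1):
        if config.tabu_enabled:
            for empire in empires:
                empire.imperialist = tabu_search(
                    empire.imperialist,
                    evaluator,
                    weights,
                    config.ts_iters,
                    config.ts_neighbors,
                    config.ts_tenure,
                    rng,
                )
        for empire in empires:
            empire.colonies = [
                evaluator.evaluate(assimilate(empire.imperialist, c, rng), weights)
                for c in empire.colonies
            ]
        for empire in empires:
            swap_best_colony(empire)
        if len(empires) >= 2:
            imperialist_competition(empires, config.xi, rng)
        empires = eliminate_empty(empires, config.xi)
        log.append(_record(gen, empires, evaluator))

    best = evaluator.best
    genes = selected_indices(best)
    return HicatsResult(
        best_country=best,
        best_fitness=float(best.fitness),
        best_accuracy=float(best.accuracy),
        best_n_selected=best.n_selected,
        selected_genes=genes,
        selected_gene_names=[dataset.gene_names[g - 1] for g in genes],
        log=log,
        config=config,
        n_evaluations=evaluator.n_fits,
    )


def run_ica_baseline(
    dataset: GeneDataset,
    config: HicatsConfig = HicatsConfig(),
    rng: np.random.Generator | None = None,
) -> HicatsResult:
    """Ablation baseline: the identical loop with tabu refinement disabled."""
    return run_hicats(dataset, replace(config, tabu_enabled=False), rng)
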