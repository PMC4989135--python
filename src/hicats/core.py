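"""Binary country encoding and the expression dataset container.

A *country* is one candidate gene subset: a fixed-length bit vector over
the genes of a dataset, where bit ``i`` set means gene ``i+1`` (1-based)
is included in the subset. Countries carry their cached fitness and
cross-validated accuracy once evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Country",
    "GeneDataset",
    "random_country",
    "selected_indices",
    "repair_country",
]


@dataclass
class Country:
    """A candidate gene subset encoded as a bit vector.

    Parameters
    ----------
    bits
        uint8 array of 0/1 of length ``n_genes``. The length is fixed for
        the life of the country.
    fitness, accuracy
        Cached evaluation results; ``None`` until evaluated.
    """

    bits: np.ndarray
    fitness: float | None = None
    accuracy: float | None = None

    def __post_init__(self) -> None:
        self.bits = np.ascontiguousarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("country bits must be one-dimensional")
        if not np.all((self.bits == 0) | (self.bits == 1)):
            raise ValueError("country bits must be 0/1")

    @property
    def n_genes(self) -> int:
        return self.bits.shape[0]

    @property
    def n_selected(self) -> int:
        """Number of selected genes (1-bits)."""
        return int(self.bits.sum())

    def copy(self) -> "Country":
        return Country(self.bits.copy(), self.fitness, self.accuracy)

    def key(self) -> bytes:
        """Hashable identity of the bit pattern (used as cache key)."""
        return self.bits.tobytes()


@dataclass
class GeneDataset:
    """Expression matrix (samples x genes) with per-sample class labels.

    ``labels`` may be any hashable sample annotations (strings or ints);
    classifiers receive them as given. ``n`` is the total gene count, the
    denominator of the subset-size term in the fitness.
    """

    matrix: np.ndarray
    labels: np.ndarray
    gene_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.matrix.ndim != 2:
            raise ValueError("expression matrix must be 2-dimensional")
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError(
                f"{self.matrix.shape[0]} samples but {self.labels.shape[0]} labels"
            )
        if self.matrix.shape[0] < 2:
            raise ValueError("need at least 2 samples")
        if not self.gene_names:
            self.gene_names = [f"g{i + 1}" for i in range(self.matrix.shape[1])]
        if len(self.gene_names) != self.matrix.shape[1]:
            raise ValueError(
                f"{self.matrix.shape[1]} genes but {len(self.gene_names)} gene names"
            )

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        """Total number of genes."""
        return self.matrix.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def random_country(n_genes: int, density: float, rng: np.random.Generator) -> Country:
    """Draw a random country with each bit set independently with ``density``.

    The result is repaired so that at least one gene is selected.
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be positive, got {n_genes}")
    if not 0.0 < density <= 1.0:
        raise ValueError(f"density must be in (0, 1], got {density}")
    bits = (rng.random(n_genes) < density).astype(np.uint8)
    return repair_country(Country(bits), rng)


def selected_indices(country: Country) -> list[int]:
    """1-based positions of the selected genes, ascending."""
    return [int(i) + 1 for i in np.flatnonzero(country.bits)]


def repair_country(country: Country, rng: np.random.Generator) -> Country:
    """Guarantee a non-empty subset.

    An all-zero country selects one uniformly chosen gene; any other
    country is returned unchanged (repair is idempotent).
    """
    if country.n_selected > 0:
        return country
    bits = country.bits.copy()
    bits[rng.integers(bits.shape[0])] = 1
    return Country(bits)
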