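"""Colony assimilation: Baldwinian transfer of difference genes plus
template-masked retention.

A colony learns from its imperialist in two moves:

1. *Difference transfer.* The difference mask marks genes the
   imperialist selects but the colony does not (the asymmetric binary
   difference: 1 - 0 = 1, all other combinations 0). A learning rate
   beta, drawn uniformly from (0, 1) per colony per generation, fixes
   how many difference genes transfer: ``round(beta * |diff|)`` with
   halves rounded up, sampled uniformly without replacement.
2. *Template retention.* A random fair-coin binary template BT of
   length max(|imperialist subset|, |colony subset|) is drawn; its
   complement BTF gives the colony template COBT (first |colony subset|
   bits). The colony keeps its own selected genes only where COBT is 1,
   matching genes to template positions in ascending gene order.

The assimilated colony is the union of transferred and kept genes.
Because the template halves the colony's retained genes in expectation
while the transfer adds only a fraction of the difference, assimilation
shrinks subsets over generations — the mechanism behind the method's
small final gene subsets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Country, repair_country

__all__ = [
    "AssimilationTemplates",
    "difference_mask",
    "transfer_count",
    "make_templates",
    "apply_assimilation",
    "assimilate",
]


@dataclass(frozen=True)
class AssimilationTemplates:
    """Random binary templates used during assimilation.

    ``bt`` is the master template (length = larger subset size), ``btf``
    its bitwise complement; ``imbt``/``cobt`` are the prefixes matching
    the imperialist's and colony's subset sizes. Only ``cobt`` affects
    the assimilation result; ``imbt`` is carried for completeness of the
    template family.
    """

    bt: np.ndarray
    btf: np.ndarray
    imbt: np.ndarray
    cobt: np.ndarray


def difference_mask(imperialist: Country, colony: Country) -> np.ndarray:
    """Bits set where the imperialist selects a gene the colony lacks."""
    if imperialist.n_genes != colony.n_genes:
        raise ValueError("imperialist and colony must have equal length")
    return (imperialist.bits & (1 - colony.bits)).astype(np.uint8)


def transfer_count(diff_count: int, beta: float) -> int:
    """Number of difference genes to transfer: beta * diff, half rounded up."""
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    return min(int(np.floor(beta * diff_count + 0.5)), diff_count)


def make_templates(
    n_im_selected: int, n_co_selected: int, rng: np.random.Generator
) -> AssimilationTemplates:
    """Draw the BT/BTF/IMBT/COBT template family with fair-coin bits."""
    if n_im_selected < 1 or n_co_selected < 1:
        raise ValueError("subset sizes must be positive")
    length = max(n_im_selected, n_co_selected)
    bt = rng.integers(0, 2, size=length, dtype=np.uint8)
    btf = (1 - bt).astype(np.uint8)
    return AssimilationTemplates(
        bt=bt, btf=btf, imbt=bt[:n_im_selected], cobt=btf[:n_co_selected]
    )


def apply_assimilation(
    colony: Country, transfer_positions: np.ndarray, cobt: np.ndarray
) -> Country:
    """Deterministic core of assimilation, given the random draws.

    ``transfer_positions`` are 0-based gene indices to acquire;
    ``cobt`` masks the colony's own selected genes (ascending order).
    """
    bits = np.zeros(colony.n_genes, dtype=np.uint8)
    own = np.flatnonzero(colony.bits)
    kept = own[cobt[: own.size].astype(bool)]
    bits[kept] = 1
    bits[np.asarray(transfer_positions, dtype=int)] = 1
    return Country(bits)


def assimilate(
    imperialist: Country, colony: Country, rng: np.random.Generator
) -> Country:
    """Produce the assimilated colony (repaired to a non-empty subset)."""
    diff = difference_mask(imperialist, colony)
    diff_positions = np.flatnonzero(diff)
    beta = rng.uniform()
    while beta == 0.0:  # open interval (0, 1)
        beta = rng.uniform()
    k = transfer_count(diff_positions.size, beta) if diff_positions.size else 0
    transferred = (
        rng.choice(diff_positions, size=k, replace=False)
        if k
        else np.empty(0, dtype=int)
    )
    templates = make_templates(
        max(imperialist.n_selected, 1), max(colony.n_selected, 1), rng
    )
    new = apply_assimilation(colony, transferred, templates.cobt)
    return repair_country(new, rng)
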