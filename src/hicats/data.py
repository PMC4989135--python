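"""Expression-table I/O, result serialisation, and synthetic data.

The synthetic generator emulates the regime of public microarray
benchmarks: tens of samples, hundreds to thousands of genes, a handful
of classes, and only a few genes that actually carry class signal.
Informative genes follow an additive ladder — class ``c`` has mean
``c * effect_size * noise_sd`` — while every other gene is pure noise,
so any reasonable classifier can exploit the planted genes and nothing
else.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneDataset
from .driver import HicatsResult

__all__ = ["SyntheticSpec", "read_expression_table", "make_synthetic", "write_result"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-signal generator.

    ``effect_size`` is the separation of adjacent class means in units
    of ``noise_sd``; 3.0 gives clearly separable but noisy classes.
    """

    n_samples: int = 40
    n_genes: int = 200
    n_informative: int = 5
    n_classes: int = 3
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative cannot exceed n_genes")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_table(
    path,
    orientation: str = "samples-in-rows",
    label_source: str | None = None,
    labels_path=None,
) -> GeneDataset:
    """Read a delimited expression table into a :class:`GeneDataset`.

    Parameters
    ----------
    path
        CSV (comma) or TSV/TXT (tab) file with a header row.
    orientation
        ``"samples-in-rows"`` (default) or ``"genes-in-rows"`` (the
        common repository layout; transposed on read).
    label_source
        Name of the label column inside the table (samples-in-rows
        only), or ``None`` when labels come from ``labels_path``.
    labels_path
        Separate single-column file of labels, one per sample in order.
    """
    path = Path(path)
    if orientation not in ("samples-in-rows", "genes-in-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=_delimiter(path), index_col=0)

    labels = None
    if label_source is not None:
        if orientation != "samples-in-rows":
            raise ValueError("a label column requires samples-in-rows orientation")
        if label_source not in df.columns:
            raise ValueError(f"label column {label_source!r} not found in {path.name}")
        labels = df[label_source].to_numpy()
        df = df.drop(columns=[label_source])

    if orientation == "genes-in-rows":
        df = df.T
    gene_names = [str(c) for c in df.columns]

    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            try:
                pd.to_numeric(df[col])
            except (ValueError, TypeError) as exc:
                raise ValueError(
                    f"non-numeric expression value in column {col!r} of {path.name}"
                ) from exc
        values = df.astype(float).to_numpy()

    if labels_path is not None:
        lab_df = pd.read_csv(labels_path, sep=_delimiter(Path(labels_path)), header=None)
        labels = lab_df.iloc[:, -1].to_numpy()
    if labels is None:
        raise ValueError("labels required: pass label_source or labels_path")
    if labels.shape[0] != values.shape[0]:
        raise ValueError(
            f"{values.shape[0]} samples but {labels.shape[0]} labels in {path.name}"
        )
    return GeneDataset(values, labels, gene_names)


def make_synthetic(spec: SyntheticSpec) -> tuple[GeneDataset, list[int]]:
    """Generate a planted-signal dataset; returns (dataset, planted positions).

    Samples are split as evenly as possible across classes (earlier
    classes get the remainder). Planted positions are 1-based, sorted.
    Pure function of the spec: the same seed reproduces the same data.
    """
    rng = np.random.default_rng(spec.seed)
    base, extra = divmod(spec.n_samples, spec.n_classes)
    counts = [base + (1 if c < extra else 0) for c in range(spec.n_classes)]
    labels = np.repeat([f"C{c}" for c in range(spec.n_classes)], counts)
    codes = np.repeat(np.arange(spec.n_classes), counts)

    planted = np.sort(
        rng.choice(spec.n_genes, size=spec.n_informative, replace=False)
    )
    matrix = rng.normal(0.0, spec.noise_sd, size=(spec.n_samples, spec.n_genes))
    if spec.n_informative:
        shift = codes[:, None] * spec.effect_size * spec.noise_sd
        matrix[:, planted] += shift
    dataset = GeneDataset(matrix, labels)
    return dataset, [int(p) + 1 for p in planted]


def write_result(result: HicatsResult, out_prefix) -> dict[str, Path]:
    """Write summary text, TSV convergence log, and a JSON run manifest.

    Returns the mapping of artifact kind to path. Accuracy is printed as
    a percentage with two decimals in the summary.
    """
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "summary": prefix.with_name(prefix.name + "_summary.txt"),
        "log": prefix.with_name(prefix.name + "_log.tsv"),
        "manifest": prefix.with_name(prefix.name + "_manifest.json"),
    }

    cfg = asdict(result.config) if result.config is not None else {}
    lines = [
        "HICATS run summary",
        f"best cross-validated accuracy (%): {result.best_accuracy * 100:.2f}",
        f"best fitness: {result.best_fitness:.6f}",
        f"selected gene count: {result.best_n_selected}",
        "selected genes: " + ", ".join(result.selected_gene_names),
        f"classifier fits used: {result.n_evaluations}",
        "config: " + json.dumps(cfg),
    ]
    paths["summary"].write_text("\n".join(lines) + "\n")

    log_df = pd.DataFrame([asdict(r) for r in result.log])
    log_df.to_csv(paths["log"], sep="\t", index=False)

    manifest = {
        "config": cfg,
        "best_accuracy": result.best_accuracy,
        "best_fitness": result.best_fitness,
        "best_n_selected": result.best_n_selected,
        "selected_genes": result.selected_genes,
        "selected_gene_names": result.selected_gene_names,
        "n_evaluations": result.n_evaluations,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
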