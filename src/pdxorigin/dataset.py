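"""Core in-memory containers: expression matrix plus per-sample tissue labels.

The pipeline operates on continuous log-scale expression values, genes in
rows and samples in columns, with one categorical tissue-class label per
sample.  Every downstream stage (feature ranking, SVM evaluation, rule
induction) consumes a :class:`LabeledDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ExpressionMatrix",
    "LabeledDataset",
    "DatasetError",
]


class DatasetError(ValueError):
    """Invalid expression matrix or label assignment."""


@dataclass
class ExpressionMatrix:
    """Rectangular gene x sample matrix of log-scale expression values.

    Parameters
    ----------
    genes
        Ordered gene symbols; order defines feature indices ``0..N-1``.
    samples
        Ordered sample identifiers (column order).
    values
        Array of shape ``(len(genes), len(samples))``; all entries finite.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DatasetError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if any(not g for g in self.genes):
            raise DatasetError("empty gene symbol")
        if len(set(self.genes)) != len(self.genes):
            raise DatasetError("duplicate gene symbols in matrix")
        if len(set(self.samples)) != len(self.samples):
            raise DatasetError("duplicate sample identifiers in matrix")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DatasetError(
                f"non-finite value at gene {self.genes[bad[0]]!r}, "
                f"sample {self.samples[bad[1]]!r} (missing values are not supported)"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class LabeledDataset:
    """An :class:`ExpressionMatrix` with one tissue-class label per sample."""

    matrix: ExpressionMatrix
    labels: list[str]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.matrix.n_samples:
            raise DatasetError(
                f"{len(self.labels)} labels for {self.matrix.n_samples} samples"
            )
        if not self.classes:
            # order of first appearance, deterministic in the label sequence
            self.classes = list(dict.fromkeys(self.labels))
        else:
            self.classes = [str(c) for c in self.classes]
        class_set = set(self.classes)
        if len(class_set) != len(self.classes):
            raise DatasetError("duplicate entries in classes")
        missing = sorted(set(self.labels) - class_set)
        if missing:
            raise DatasetError(f"labels not listed in classes: {missing}")
        unused = sorted(class_set - set(self.labels))
        if unused:
            raise DatasetError(f"classes with no samples: {unused}")

    # -- convenience accessors -------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return self.matrix.genes

    @property
    def samples(self) -> list[str]:
        return self.matrix.samples

    @property
    def values(self) -> np.ndarray:
        """Gene x sample value array."""
        return self.matrix.values

    @property
    def n_genes(self) -> int:
        return self.matrix.n_genes

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def X(self) -> np.ndarray:
        """Sample x gene design matrix (the scikit-learn orientation)."""
        return self.matrix.values.T

    @property
    def y(self) -> np.ndarray:
        """Integer class index per sample, following ``classes`` order."""
        index = {c: i for i, c in enumerate(self.classes)}
        return np.array([index[l] for l in self.labels], dtype=int)

    def class_counts(self) -> dict[str, int]:
        return {c: self.labels.count(c) for c in self.classes}

    def gene_index(self, symbols: Sequence[str]) -> np.ndarray:
        """Map gene symbols (case-sensitively) to row indices."""
        index = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([index[s] for s in symbols], dtype=int)
        except KeyError as exc:
            raise DatasetError(f"gene not in matrix: {exc.args[0]!r}") from None

    def with_labels(self, labels: Sequence[str]) -> "LabeledDataset":
        """Same matrix with a new label assignment (used by permutation tests)."""
        return LabeledDataset(self.matrix, list(labels), list(self.classes))

    def subset_samples(self, idx: Sequence[int]) -> "LabeledDataset":
        idx = np.asarray(idx, dtype=int)
        mat = ExpressionMatrix(
            list(self.matrix.genes),
            [self.matrix.samples[i] for i in idx],
            self.matrix.values[:, idx],
        )
        labels = [self.labels[i] for i in idx]
        classes = [c for c in self.classes if c in set(labels)]
        return LabeledDataset(mat, labels, classes)
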