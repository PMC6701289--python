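"""Synthetic multi-class expression data with planted marker genes.

Emulates the 8-tissue PDX cohort shape: unbalanced class sizes, continuous
log-scale expression, and a small set of class-specific marker genes against
a large uninformative background.  Background values are i.i.d.
Normal(mu0, sigma); a marker gene of class c is shifted by the effect size
delta (log units) in samples of that class only.  Ground truth (which gene
marks which class) is returned alongside the dataset so feature-recovery and
rule-induction behaviour can be tested without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataset import ExpressionMatrix, LabeledDataset

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "ConfigError",
    "generate_dataset",
    "default_pdx_config",
    "PDX_CLASS_SIZES",
    "PDX_CLASS_NAMES",
    "PDX_N_GENES",
]

# Cohort shape of the deposited PDX expression study: eight tissues,
# 594 samples, 20,502 genes.
PDX_CLASS_NAMES = (
    "breast",
    "kidney",
    "large intestine",
    "lung",
    "ovary",
    "pancreas",
    "skin",
    "soft tissue",
)
PDX_CLASS_SIZES = (79, 41, 121, 99, 52, 94, 46, 62)
PDX_N_GENES = 20502


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """World description for one synthetic cohort.

    Defaults put markers on a log2-like scale comparable to published
    threshold rules (baseline ~4, shifts of ~3 log units, unit noise).
    """

    seed: int = 0
    class_names: tuple[str, ...] = PDX_CLASS_NAMES
    class_sizes: tuple[int, ...] = PDX_CLASS_SIZES
    n_genes: int = PDX_N_GENES
    markers_per_class: int = 5
    effect_size: float = 3.0
    baseline_mean: float = 4.0
    noise_sd: float = 1.0
    marker_overlap: bool = False

    def validate(self) -> None:
        if len(self.class_names) != len(self.class_sizes):
            raise ConfigError("class_names and class_sizes length mismatch")
        if len(set(self.class_names)) != len(self.class_names):
            raise ConfigError("duplicate class names")
        if not self.class_sizes or any(s < 1 for s in self.class_sizes):
            raise ConfigError("every class needs at least one sample")
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        if self.markers_per_class < 0:
            raise ConfigError("markers_per_class must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if (
            not self.marker_overlap
            and self.markers_per_class * len(self.class_names) > self.n_genes
        ):
            raise ConfigError(
                "disjoint markers require markers_per_class * n_classes <= n_genes"
            )

    @property
    def n_samples(self) -> int:
        return int(sum(self.class_sizes))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)


@dataclass(frozen=True)
class GroundTruth:
    """Planted-marker map (class -> gene symbols) plus a config echo."""

    marker_map: dict[str, list[str]]
    config: SyntheticConfig

    def all_markers(self) -> list[str]:
        seen: dict[str, None] = {}
        for genes in self.marker_map.values():
            for g in genes:
                seen.setdefault(g, None)
        return list(seen)


def _gene_names(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(cfg: SyntheticConfig) -> tuple[LabeledDataset, GroundTruth]:
    """Draw one labeled cohort and its ground truth from ``cfg``.

    A single ``numpy`` generator seeded with ``cfg.seed`` drives marker
    placement and then the value matrix, so the same seed reproduces the
    dataset bit-identically.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_genes, n_samples = cfg.n_genes, cfg.n_samples
    genes = _gene_names(n_genes)
    samples = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    labels: list[str] = []
    for name, size in zip(cfg.class_names, cfg.class_sizes):
        labels.extend([name] * size)

    # marker placement first so it is independent of the matrix draw order
    k = cfg.markers_per_class
    marker_map: dict[str, list[int]] = {}
    if k > 0:
        if cfg.marker_overlap:
            for name in cfg.class_names:
                marker_map[name] = sorted(
                    rng.choice(n_genes, size=k, replace=False).tolist()
                )
        else:
            pool = rng.permutation(n_genes)[: k * cfg.n_classes]
            for i, name in enumerate(cfg.class_names):
                marker_map[name] = sorted(pool[i * k : (i + 1) * k].tolist())
    else:
        marker_map = {name: [] for name in cfg.class_names}

    values = rng.normal(cfg.baseline_mean, cfg.noise_sd, size=(n_genes, n_samples))
    col = 0
    for name, size in zip(cfg.class_names, cfg.class_sizes):
        idx = marker_map[name]
        if idx:
            values[np.ix_(idx, range(col, col + size))] += cfg.effect_size
        col += size

    ds = LabeledDataset(
        ExpressionMatrix(genes, samples, values), labels, list(cfg.class_names)
    )
    truth = GroundTruth(
        marker_map={name: [genes[i] for i in idx] for name, idx in marker_map.items()},
        config=cfg,
    )
    return ds, truth


def default_pdx_config(scale: float = 1.0, seed: int = 0, **overrides) -> SyntheticConfig:
    """Cohort-shaped config at a fraction of the full 594-sample study.

    At ``scale=1`` the class sizes are exactly the published cohort
    (79/41/121/99/52/94/46/62, 594 total) with 20,502 genes.  Smaller scales
    shrink class sizes proportionally with half-up rounding and a floor of
    5 samples per class, and the gene count proportionally with a floor of
    200.  Extra keyword arguments override any :class:`SyntheticConfig`
    field (seed, effect size, ...).
    """
    if not (0 < scale <= 1):
        raise ConfigError(f"scale must be in (0, 1], got {scale}")
    sizes = tuple(
        max(5, int(np.floor(s * scale + 0.5))) for s in PDX_CLASS_SIZES
    )
    n_genes = max(200, int(np.floor(PDX_N_GENES * scale + 0.5)))
    cfg = SyntheticConfig(seed=seed, class_sizes=sizes, n_genes=n_genes)
    if overrides:
        cfg = replace(cfg, **overrides)
    cfg.validate()
    return cfg


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Two-column TSV (class, gene) listing the planted markers."""
    with open(path, "w") as fh:
        fh.write("class\tgene\n")
        for name, genes in truth.marker_map.items():
            for g in genes:
                fh.write(f"{name}\t{g}\n")
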