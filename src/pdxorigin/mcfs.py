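"""Monte Carlo feature selection: projection-tree ensembles and RI scores.

Many decision trees are grown, each on a random projection of ``m`` genes
and a random (stratified) train/held-out split of the samples.  Each gene
accumulates a relative importance (RI) score over all nodes of all trees
where it is the splitter:

    RI(g) = sum over nodes n_g(tau)  (wAcc)^u * IG(n_g(tau))
            * (no.in n_g(tau) / no.in tau)^v

with ``wAcc`` the tree's class-balanced held-out accuracy, ``IG`` the
information gain of the node, and the last factor the fraction of the
tree's training samples reaching the node; ``u = v = 1`` by default.
Features are ranked by descending RI, and the informative-feature threshold
comes from a permutation test on class labels: the maximal RI of each
label-permuted run is recorded and a one-sided Student-t prediction bound
on a new maximum marks the significance cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .dataset import LabeledDataset
from .metrics import confusion_from_predictions, weighted_accuracy

logger = logging.getLogger(__name__)

__all__ = [
    "MCFSParams",
    "TreeRecord",
    "TreeEnsemble",
    "RIThreshold",
    "weighted_accuracy",
    "grow_projection_trees",
    "compute_relative_importance",
    "rank_features",
    "permutation_threshold",
]


@dataclass(frozen=True)
class MCFSParams:
    """Ensemble parameters.

    ``m`` genes per random projection ("auto" = max(ceil(0.05 N), 2)),
    ``t`` projections, ``p`` trees per projection, exponents ``u``/``v`` on
    weighted accuracy and node-sample fraction, and the training fraction of
    each stratified split.  ``resample='bootstrap'`` draws the training set
    with replacement (held-out = out-of-bag) instead of splitting.
    """

    m: int | str = "auto"
    t: int = 100
    p: int = 5
    u: float = 1.0
    v: float = 1.0
    train_fraction: float = 0.66
    seed: int = 0
    resample: str = "split"
    max_retries: int = 10

    def resolve_m(self, n_genes: int) -> int:
        if self.m == "auto":
            return min(n_genes, max(math.ceil(0.05 * n_genes), 2))
        return int(self.m)

    def validate(self, n_genes: int | None = None) -> None:
        if self.m != "auto":
            if int(self.m) < 1 or (n_genes is not None and int(self.m) > n_genes):
                raise ValueError(f"m must be in [1, N], got {self.m}")
        if self.t < 1 or self.p < 1:
            raise ValueError("t and p must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")
        if self.resample not in ("split", "bootstrap"):
            raise ValueError(f"unknown resample mode {self.resample!r}")


@dataclass(frozen=True)
class TreeRecord:
    """One grown tree: held-out wAcc, root size, and per-node split stats.

    ``nodes`` holds ``(gene_index, information_gain, n_node_samples)`` for
    every internal node; gene indices refer to the full dataset.
    """

    wacc: float
    root_n: int
    nodes: tuple[tuple[int, float, int], ...]


@dataclass(frozen=True)
class TreeEnsemble:
    trees: tuple[TreeRecord, ...]
    params: MCFSParams
    n_genes: int

    def __len__(self) -> int:
        return len(self.trees)


@dataclass(frozen=True)
class RIThreshold:
    """Permutation-test significance cutoff for RI scores."""

    threshold: float
    alpha: float
    permutation_max_ris: tuple[float, ...]
    n_permutations: int


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class split; every class is represented in the training half."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        idx = idx[rng.permutation(idx.size)]
        n_train = max(1, math.ceil(train_fraction * idx.size))
        n_train = min(n_train, idx.size)
        train.append(idx[:n_train])
        test.append(idx[n_train:])
    return np.concatenate(train), np.concatenate(test)


def _bootstrap_draw(
    y: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified bootstrap: draw each class with replacement, OOB held out."""
    n = y.shape[0]
    train = []
    for cls in np.unique(y):
        idx = np.nonzero(y == cls)[0]
        train.append(rng.choice(idx, size=idx.size, replace=True))
    train = np.concatenate(train)
    oob = np.setdiff1d(np.arange(n), np.unique(train))
    return train, oob


def _extract_nodes(
    tree: DecisionTreeClassifier, cols: np.ndarray
) -> tuple[tuple[int, float, int], ...]:
    """Internal-node (gene, IG, n_samples) triples from a fitted sklearn tree.

    IG is the entropy decrease at the node: H(node) minus the sample-weighted
    child entropies (sklearn's 'entropy' impurity is log2-based).
    """
    t = tree.tree_
    nodes = []
    for nid in range(t.node_count):
        left, right = t.children_left[nid], t.children_right[nid]
        if left == -1:
            continue
        n_node = int(t.n_node_samples[nid])
        ig = float(
            t.impurity[nid]
            - (t.n_node_samples[left] / n_node) * t.impurity[left]
            - (t.n_node_samples[right] / n_node) * t.impurity[right]
        )
        nodes.append((int(cols[t.feature[nid]]), max(ig, 0.0), n_node))
    return tuple(nodes)


def grow_projection_trees(ds: LabeledDataset, params: MCFSParams) -> TreeEnsemble:
    """Grow the p x t projection-tree ensemble.

    For each of ``t`` gene subsets (``m`` genes sampled uniformly without
    replacement), ``p`` trees are grown, each on an independent stratified
    resample, and scored by class-balanced accuracy on the held-out samples.
    Gene subsets are drawn against the symbol-sorted gene order, so the same
    seed selects the same *genes* regardless of the row order of the input
    matrix.  Fully reproducible from ``params.seed``.
    """
    params.validate(ds.n_genes)
    m = params.resolve_m(ds.n_genes)
    y = ds.y
    C = ds.n_classes
    if np.unique(y).size < 2:
        raise ValueError("tree growing needs at least two classes")
    canonical = np.array(
        sorted(range(ds.n_genes), key=lambda i: ds.genes[i]), dtype=int
    )
    ss = np.random.SeedSequence(params.seed)
    subset_ss, split_ss = ss.spawn(2)
    subset_rng = np.random.default_rng(subset_ss)
    split_rng = np.random.default_rng(split_ss)
    X_all = ds.X

    trees: list[TreeRecord] = []
    for _ in range(params.t):
        chosen = subset_rng.choice(ds.n_genes, size=m, replace=False)
        cols = canonical[np.sort(chosen)]
        X_proj = X_all[:, cols]
        for _ in range(params.p):
            for attempt in range(params.max_retries + 1):
                if params.resample == "bootstrap":
                    train_idx, test_idx = _bootstrap_draw(y, split_rng)
                else:
                    train_idx, test_idx = _stratified_split(
                        y, params.train_fraction, split_rng
                    )
                if np.unique(y[train_idx]).size == C and test_idx.size > 0:
                    break
            else:
                raise RuntimeError(
                    "could not draw a training split containing every class"
                )
            tree_seed = int(split_rng.integers(0, 2**31 - 1))
            clf = DecisionTreeClassifier(
                criterion="entropy", min_samples_leaf=2, random_state=tree_seed
            )
            clf.fit(X_proj[train_idx], y[train_idx])
            pred = clf.predict(X_proj[test_idx])
            conf = confusion_from_predictions(y[test_idx], pred, C)
            wacc = weighted_accuracy(conf)
            trees.append(
                TreeRecord(
                    wacc=wacc,
                    root_n=train_idx.size,
                    nodes=_extract_nodes(clf, cols),
                )
            )
    return TreeEnsemble(tuple(trees), params, ds.n_genes)


def compute_relative_importance(ens: TreeEnsemble) -> np.ndarray:
    """Aggregate per-gene RI over every internal node of every tree."""
    if not ens.trees:
        raise ValueError("empty ensemble")
    u, v = ens.params.u, ens.params.v
    ri = np.zeros(ens.n_genes)
    for tree in ens.trees:
        w = tree.wacc**u
        for gene, ig, n_node in tree.nodes:
            ri[gene] += w * ig * (n_node / tree.root_n) ** v
    return ri


def rank_features(ri: np.ndarray) -> np.ndarray:
    """Gene indices by descending RI; ties broken by ascending gene index."""
    ri = np.asarray(ri, dtype=float)
    return np.lexsort((np.arange(ri.size), -ri))


def permutation_threshold(
    ds: LabeledDataset,
    params: MCFSParams,
    n_permutations: int = 20,
    alpha: float = 0.05,
    observed_ri: np.ndarray | None = None,
) -> tuple[RIThreshold, np.ndarray]:
    """Informative-feature cutoff from label-permuted MCFS runs.

    The full RI computation is repeated on ``n_permutations`` label-permuted
    copies of the data and each run's maximal RI recorded.  The threshold is
    the one-sided upper (1 - alpha) Student-t prediction bound on a new
    maximum, ``mean + t_{1-alpha, K-1} * sd * sqrt(1 + 1/K)``; genes whose
    observed RI exceeds it are the informative features (returned as sorted
    gene indices).
    """
    if n_permutations < 3:
        raise ValueError("need at least 3 permutations")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if observed_ri is None:
        observed_ri = compute_relative_importance(grow_projection_trees(ds, params))
    perm_ss = np.random.SeedSequence(params.seed).spawn(3)[2]
    label_rng = np.random.default_rng(perm_ss)
    max_ris = []
    for k in range(n_permutations):
        perm = label_rng.permutation(ds.n_samples)
        permuted = ds.with_labels([ds.labels[i] for i in perm])
        run_params = replace(params, seed=int(label_rng.integers(0, 2**31 - 1)))
        ri_perm = compute_relative_importance(
            grow_projection_trees(permuted, run_params)
        )
        max_ris.append(float(ri_perm.max()))
    arr = np.asarray(max_ris)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        logger.warning(
            "permutation_threshold: zero variance across permutation maxima; "
            "falling back to the max observed permuted RI"
        )
        threshold = float(arr.max())
    else:
        K = n_permutations
        t_crit = stats.t.ppf(1 - alpha, K - 1)
        threshold = float(arr.mean() + t_crit * sd * math.sqrt(1 + 1 / K))
    informative = np.nonzero(observed_ri > threshold)[0]
    return (
        RIThreshold(threshold, alpha, tuple(max_ris), n_permutations),
        informative,
    )
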