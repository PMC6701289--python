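"""Ordered IF-THEN threshold rules: representation, application, induction.

A rule set is an ordered list of conjunctive rules ``IF g1 >= c1 AND g2 <= c2
THEN class`` closed by a single default rule with no conditions.  Rules are
applied first-match; comparison operators are inclusive.  Induction follows
the rough-set recipe: entropy/MDL discretization (Fayyad-Irani), a greedy
Johnson reducer over the discernibility pairs, and RIPPER-style sequential
covering (FOIL-gain growing, (p-n)/(p+n) pruning, MDL stopping) on the
reduced gene set.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import gammaln

from .dataset import LabeledDataset
from .metrics import PerformanceReport, confusion_from_predictions

logger = logging.getLogger(__name__)

__all__ = [
    "Condition",
    "Rule",
    "RuleSet",
    "RuleError",
    "RuleParseError",
    "RipperParams",
    "apply_rules",
    "apply_rules_to_dataset",
    "serialize_rules",
    "parse_rules",
    "discretize_mdl",
    "johnson_reducer",
    "ripper_induce",
    "evaluate_ruleset",
]

_LN2 = math.log(2.0)


class RuleError(ValueError):
    """Invalid rule structure or application context."""


class RuleParseError(RuleError):
    """Malformed rule text; carries the offending line number."""


def _norm_label(label: str) -> str:
    return label.strip().casefold()


# ---------------------------------------------------------------------------
# representation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Condition:
    """Single threshold test on one gene; operators are inclusive."""

    gene: str
    op: str  # ">=" or "<="
    threshold: float

    def __post_init__(self) -> None:
        if self.op not in (">=", "<="):
            raise RuleError(f"operator must be '>=' or '<=', got {self.op!r}")
        if not math.isfinite(self.threshold):
            raise RuleError(f"non-finite threshold for gene {self.gene!r}")

    def holds(self, value: float) -> bool:
        return value >= self.threshold if self.op == ">=" else value <= self.threshold

    def __str__(self) -> str:
        return f"{self.gene} {self.op} {self.threshold:.12g}"


@dataclass(frozen=True)
class Rule:
    """Conjunction of conditions with a class consequent; empty = default."""

    conditions: tuple[Condition, ...]
    consequent: str

    @property
    def is_default(self) -> bool:
        return len(self.conditions) == 0

    def matches(self, sample: Mapping[str, float]) -> bool:
        return all(c.holds(sample[c.gene]) for c in self.conditions)

    def __str__(self) -> str:
        lhs = " AND ".join(str(c) for c in self.conditions)
        return f"IF {lhs} THEN {self.consequent}".replace("IF  THEN", "IF THEN")


@dataclass
class RuleSet:
    """Ordered rules with exactly one trailing default rule."""

    rules: list[Rule]

    def __post_init__(self) -> None:
        if not self.rules:
            raise RuleError("a rule set needs at least the default rule")
        defaults = [i for i, r in enumerate(self.rules) if r.is_default]
        if defaults != [len(self.rules) - 1]:
            raise RuleError(
                "exactly one default (condition-free) rule is allowed and it "
                f"must be last; found default rules at positions {defaults}"
            )

    def __len__(self) -> int:
        return len(self.rules)

    def __iter__(self):
        return iter(self.rules)

    @property
    def default_class(self) -> str:
        return self.rules[-1].consequent

    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            for c in r.conditions:
                seen.setdefault(c.gene, None)
        return list(seen)

    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.rules:
            seen.setdefault(r.consequent, None)
        return list(seen)


def apply_rules(rs: RuleSet, sample: Mapping[str, float]) -> str:
    """Classify one sample: the first rule whose conditions all hold fires.

    Every gene referenced by the rule set must be present in ``sample``.
    """
    missing = [g for g in rs.genes() if g not in sample]
    if missing:
        raise RuleError(f"sample is missing genes referenced by rules: {missing}")
    for rule in rs.rules:
        if rule.matches(sample):
            return rule.consequent
    # unreachable: the default rule always matches
    raise AssertionError("no rule fired despite a default rule")


def apply_rules_to_dataset(rs: RuleSet, ds: LabeledDataset) -> list[str]:
    """Vectorized first-match application over all samples of a dataset."""
    gene_rows = {g: ds.values[i] for g, i in zip(rs.genes(), ds.gene_index(rs.genes()))}
    n = ds.n_samples
    pred = [rs.default_class] * n
    unassigned = np.ones(n, dtype=bool)
    for rule in rs.rules[:-1]:
        mask = unassigned.copy()
        for c in rule.conditions:
            row = gene_rows[c.gene]
            mask &= (row >= c.threshold) if c.op == ">=" else (row <= c.threshold)
            if not mask.any():
                break
        for i in np.nonzero(mask)[0]:
            pred[i] = rule.consequent
        unassigned &= ~mask
    return pred


# ---------------------------------------------------------------------------
# text serialization
# ---------------------------------------------------------------------------

_COND_RE = re.compile(r"^(?P<gene>.+?)\s*(?P<op>>=|<=|≥|≤)\s*(?P<thr>[-+0-9.eE]+)$")
_RULE_RE = re.compile(r"^IF\s*(?P<conds>.*?)\s*THEN\s+(?P<cls>.+?)\s*$")
_OP_CANON = {">=": ">=", "<=": "<=", "≥": ">=", "≤": "<="}


def serialize_rules(rs: RuleSet) -> str:
    """One rule per line, ``>=``/``<=`` canonical; default rule as ``IF THEN cls``."""
    return "\n".join(str(r) for r in rs.rules) + "\n"


def parse_rules(text: str) -> RuleSet:
    """Inverse of :func:`serialize_rules`; accepts unicode operators on input."""
    raw_lines = text.splitlines()
    content = [
        (i + 1, line.strip())
        for i, line in enumerate(raw_lines)
        if line.strip() and not line.strip().startswith("#")
    ]
    if not content:
        raise RuleParseError("no rules found")
    rules: list[Rule] = []
    last_no = content[-1][0]
    for lineno, line in content:
        m = _RULE_RE.match(line)
        if not m:
            raise RuleParseError(f"line {lineno}: cannot parse rule {line!r}")
        conds_text = m.group("conds").strip()
        consequent = m.group("cls")
        if not conds_text:
            if lineno != last_no:
                raise RuleParseError(
                    f"line {lineno}: default (condition-free) rule before the last line"
                )
            rules.append(Rule((), consequent))
            continue
        conditions = []
        for part in re.split(r"\s+AND\s+", conds_text):
            cm = _COND_RE.match(part.strip())
            if not cm:
                raise RuleParseError(f"line {lineno}: cannot parse condition {part!r}")
            conditions.append(
                Condition(
                    cm.group("gene").strip(),
                    _OP_CANON[cm.group("op")],
                    float(cm.group("thr")),
                )
            )
        rules.append(Rule(tuple(conditions), consequent))
    return RuleSet(rules)


# ---------------------------------------------------------------------------
# entropy/MDL discretization (Fayyad-Irani)
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _mdlp_recurse(v: np.ndarray, y: np.ndarray, n_classes: int, cuts: list[float]) -> None:
    n = v.shape[0]
    if n < 4:  # need >= 2 samples on each side
        return
    order = np.argsort(v, kind="mergesort")
    v, y = v[order], y[order]
    counts = np.bincount(y, minlength=n_classes)
    ent_s = _entropy(counts)
    k = int((counts > 0).sum())
    if k < 2 or ent_s == 0.0:
        return

    left = np.zeros(n_classes, dtype=int)
    best = None  # (weighted entropy, cut, i, left counts snapshot)
    for i in range(n - 1):
        left[y[i]] += 1
        if v[i + 1] <= v[i]:  # not a boundary between distinct values
            continue
        right = counts - left
        w_ent = ((i + 1) * _entropy(left) + (n - i - 1) * _entropy(right)) / n
        if best is None or w_ent < best[0] - 1e-12:
            best = (w_ent, (v[i] + v[i + 1]) / 2.0, i + 1, left.copy())
    if best is None:
        return
    w_ent, cut, n_left, left_counts = best
    right_counts = counts - left_counts
    gain = ent_s - w_ent
    k1 = int((left_counts > 0).sum())
    k2 = int((right_counts > 0).sum())
    delta = math.log2(3**k - 2) - (
        k * ent_s - k1 * _entropy(left_counts) - k2 * _entropy(right_counts)
    )
    if gain <= (math.log2(n - 1) + delta) / n:
        return
    cuts.append(float(cut))
    _mdlp_recurse(v[:n_left], y[:n_left], n_classes, cuts)
    _mdlp_recurse(v[n_left:], y[n_left:], n_classes, cuts)


def discretize_mdl(
    ds: LabeledDataset, genes: Sequence[str] | None = None
) -> dict[str, list[float]]:
    """Per-gene cut points by recursive entropy/MDL partitioning.

    Genes for which the MDL criterion accepts no cut (uninformative or
    constant genes) fall back to a single median cut and are logged.
    """
    if ds.n_classes < 2:
        raise RuleError("discretization needs at least two classes")
    genes = list(genes) if genes is not None else list(ds.genes)
    rows = ds.gene_index(genes)
    y = ds.y
    out: dict[str, list[float]] = {}
    for g, r in zip(genes, rows):
        cuts: list[float] = []
        _mdlp_recurse(ds.values[r].copy(), y, ds.n_classes, cuts)
        if not cuts:
            logger.info("discretize_mdl: no MDL cut for gene %s, using median", g)
            cuts = [float(np.median(ds.values[r]))]
        out[g] = sorted(cuts)
    return out


# ---------------------------------------------------------------------------
# Johnson reducer (greedy discernibility cover)
# ---------------------------------------------------------------------------


def johnson_reducer(
    ds: LabeledDataset,
    candidate_genes: Sequence[str],
    ri: Mapping[str, float] | None = None,
    seed: int = 0,
    max_pairs_samples: int = 2000,
    cuts: Mapping[str, list[float]] | None = None,
) -> list[str]:
    """Greedy set cover over between-class sample pairs.

    Repeatedly picks the discretized gene that discerns the most
    not-yet-covered pairs of differently labeled samples.  Ties go to the
    gene with the higher relative-importance score (if given), then to the
    earlier gene in ``candidate_genes``.  Exact over all pairs for up to
    ``max_pairs_samples`` samples; above that the samples entering the pair
    set are subsampled with ``seed``.
    """
    candidate_genes = list(candidate_genes)
    if not candidate_genes:
        raise RuleError("johnson_reducer needs a non-empty candidate gene set")
    if cuts is None:
        cuts = discretize_mdl(ds, candidate_genes)
    y = ds.y
    n = ds.n_samples
    sample_idx = np.arange(n)
    if n > max_pairs_samples:
        rng = np.random.default_rng(seed)
        sample_idx = np.sort(rng.choice(n, size=max_pairs_samples, replace=False))
    a_idx, b_idx = np.triu_indices(sample_idx.size, k=1)
    a, b = sample_idx[a_idx], sample_idx[b_idx]
    diff = y[a] != y[b]
    a, b = a[diff], b[diff]
    if a.size == 0:
        return []

    rows = ds.gene_index(candidate_genes)
    bins = {
        g: np.searchsorted(np.asarray(cuts[g], dtype=float), ds.values[r], side="left")
        for g, r in zip(candidate_genes, rows)
    }
    discerns = {g: bins[g][a] != bins[g][b] for g in candidate_genes}

    uncovered = np.ones(a.size, dtype=bool)
    reduct: list[str] = []
    remaining = list(candidate_genes)
    while uncovered.any() and remaining:
        best_gene, best_key = None, None
        for pos, g in enumerate(remaining):
            cover = int(np.count_nonzero(discerns[g] & uncovered))
            key = (cover, ri.get(g, 0.0) if ri else 0.0, -pos)
            if best_key is None or key > best_key:
                best_gene, best_key = g, key
        if best_key[0] == 0:
            break
        reduct.append(best_gene)
        uncovered &= ~discerns[best_gene]
        remaining.remove(best_gene)
    left = int(np.count_nonzero(uncovered))
    if left:
        logger.warning("johnson_reducer: %d sample pairs remain indiscernible", left)
    return reduct


# ---------------------------------------------------------------------------
# RIPPER-style induction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RipperParams:
    """Knobs of the sequential-covering rule learner (classical defaults)."""

    grow_fraction: float = 2.0 / 3.0
    mdl_slack: float = 64.0
    optimization_passes: int = 2
    seed: int = 0
    max_rules_per_class: int = 64

    def validate(self) -> None:
        if not (0 < self.grow_fraction < 1):
            raise RuleError("grow_fraction must be in (0, 1)")
        if self.mdl_slack < 0 or self.optimization_passes < 0:
            raise RuleError("mdl_slack and optimization_passes must be >= 0")


def _foil_grow(
    X: np.ndarray, pos: np.ndarray, active: np.ndarray
) -> tuple[Condition, ...]:
    """Grow one conjunctive rule on the active set by greedy FOIL gain.

    Conditions take the forms ``gene >= c`` / ``gene <= c`` with ``c`` a
    midpoint of observed values in the currently covered set.
    """
    d = X.shape[1]
    covered = active.copy()
    conds: list[tuple[int, str, float]] = []
    while True:
        p0 = int(np.count_nonzero(pos & covered))
        n0 = int(np.count_nonzero(~pos & covered))
        if p0 == 0 or n0 == 0:
            break
        base = math.log2(p0 / (p0 + n0))
        best = None  # (gain, -j, op_rank, thr, op)
        for j in range(d):
            v = X[covered, j]
            pj = pos[covered]
            order = np.argsort(v, kind="mergesort")
            v_s, p_s = v[order], pj[order]
            distinct = np.nonzero(v_s[1:] > v_s[:-1])[0]  # cut after position i
            if distinct.size == 0:
                continue
            cpos = np.cumsum(p_s)
            total_p = int(cpos[-1])
            m = v.shape[0]
            for i in distinct:
                thr = (v_s[i] + v_s[i + 1]) / 2.0
                # gene >= thr keeps the suffix
                p_ge = total_p - int(cpos[i])
                n_ge = (m - i - 1) - p_ge
                if p_ge > 0:
                    gain = p_ge * (math.log2(p_ge / (p_ge + n_ge)) - base)
                    cand = (gain, -j, 1, -thr, ">=")
                    if best is None or cand > best:
                        best = cand
                # gene <= thr keeps the prefix
                p_le = int(cpos[i])
                n_le = (i + 1) - p_le
                if p_le > 0:
                    gain = p_le * (math.log2(p_le / (p_le + n_le)) - base)
                    cand = (gain, -j, 0, thr, "<=")
                    if best is None or cand > best:
                        best = cand
        if best is None or best[0] <= 1e-12:
            break
        gain, neg_j, _, signed_thr, op = best
        j = -neg_j
        thr = -signed_thr if op == ">=" else signed_thr
        conds.append((j, op, thr))
        col = X[:, j]
        covered &= (col >= thr) if op == ">=" else (col <= thr)
    return tuple(conds)


def _cond_mask(X: np.ndarray, conds: Iterable[tuple[int, str, float]]) -> np.ndarray:
    mask = np.ones(X.shape[0], dtype=bool)
    for j, op, thr in conds:
        mask &= (X[:, j] >= thr) if op == ">=" else (X[:, j] <= thr)
    return mask


def _prune(
    conds: tuple, X: np.ndarray, pos: np.ndarray, prune_active: np.ndarray
) -> tuple:
    """Drop trailing conditions to maximize (p - n)/(p + n) on the prune set."""
    if not conds:
        return conds
    best_len, best_val = len(conds), None
    for k in range(len(conds), 0, -1):
        mask = prune_active & _cond_mask(X, conds[:k])
        p = int(np.count_nonzero(pos & mask))
        n = int(np.count_nonzero(~pos & mask))
        val = 0.0 if p + n == 0 else (p - n) / (p + n)
        if best_val is None or val >= best_val:  # >= favors shorter rules on ties
            best_val, best_len = val, k
    return conds[:best_len]


def _log2_choose(n: int, k: int) -> float:
    if k <= 0 or k >= n:
        return 0.0
    return float((gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)) / _LN2)


def _description_length(
    rule_conds: list[tuple], X: np.ndarray, pos: np.ndarray, active: np.ndarray,
    n_candidate_conditions: int,
) -> float:
    """MDL proxy: rule-theory bits plus binomial exception-coding bits."""
    theory = 0.0
    for conds in rule_conds:
        k = len(conds)
        theory += 0.5 * (math.log2(k + 1) + k * math.log2(max(2, n_candidate_conditions)))
    covered = np.zeros(X.shape[0], dtype=bool)
    for conds in rule_conds:
        covered |= _cond_mask(X, conds)
    covered &= active
    uncovered = active & ~covered
    fp = int(np.count_nonzero(covered & ~pos))
    fn = int(np.count_nonzero(uncovered & pos))
    ncov = int(np.count_nonzero(covered))
    nunc = int(np.count_nonzero(uncovered))
    data = (
        math.log2(ncov + 1) + _log2_choose(ncov, fp)
        + math.log2(nunc + 1) + _log2_choose(nunc, fn)
    )
    return theory + data


def ripper_induce(
    ds: LabeledDataset,
    genes: Sequence[str] | None = None,
    params: RipperParams | None = None,
) -> RuleSet:
    """Sequential-covering rule induction over the given genes.

    Classes are processed from least to most frequent; the most frequent
    class becomes the condition-free default rule.  Per class, rules are
    grown by FOIL gain on a grow split, pruned on a prune split, accepted
    while the description length stays within ``mdl_slack`` bits of the best
    seen and the prune-set error is below 1/2, then revised on the full
    not-yet-covered data (see docs for the deviation from split-based
    revision).
    """
    params = params or RipperParams()
    params.validate()
    genes = list(genes) if genes is not None else list(ds.genes)
    if not genes:
        counts = ds.class_counts()
        default = max(ds.classes, key=lambda c: counts[c])
        return RuleSet([Rule((), default)])
    rows = ds.gene_index(genes)
    X = ds.X[:, rows]
    y = ds.y
    counts = ds.class_counts()
    # least -> most frequent; ties keep dataset class order
    ordered = sorted(ds.classes, key=lambda c: (counts[c], ds.classes.index(c)))
    default = ordered[-1]
    rng = np.random.default_rng(params.seed)
    n = ds.n_samples
    # candidate-condition count for theory bits: 2 ops x (distinct values - 1)
    n_cand = int(
        sum(2 * max(0, np.unique(X[:, j]).size - 1) for j in range(X.shape[1]))
    )

    out_rules: list[Rule] = []
    remaining = np.ones(n, dtype=bool)
    for cls in ordered[:-1]:
        cls_idx = ds.classes.index(cls)
        pos_all = y == cls_idx
        class_rules: list[tuple] = []
        active0 = remaining.copy()
        best_dl = _description_length([], X, pos_all, active0, n_cand)
        while len(class_rules) < params.max_rules_per_class:
            active = remaining.copy()
            if not np.any(pos_all & active):
                break
            # stratified grow/prune split of the active samples
            act_idx = np.nonzero(active)[0]
            grow_mask = np.zeros(n, dtype=bool)
            for is_pos in (True, False):
                grp = act_idx[pos_all[act_idx] == is_pos]
                grp = grp[rng.permutation(grp.size)]
                n_grow = max(1, int(round(params.grow_fraction * grp.size))) if grp.size else 0
                grow_mask[grp[:n_grow]] = True
            prune_mask = active & ~grow_mask
            if not np.any(pos_all & grow_mask):
                break
            conds = _foil_grow(X, pos_all, grow_mask)
            if not conds:
                break
            if np.any(prune_mask):
                conds = _prune(conds, X, pos_all, prune_mask)
            covered = active & _cond_mask(X, conds)
            p = int(np.count_nonzero(covered & pos_all))
            np_neg = int(np.count_nonzero(covered & ~pos_all))
            if p == 0:
                break
            # prune-set error stop
            pr_cov = prune_mask & _cond_mask(X, conds)
            pr_p = int(np.count_nonzero(pr_cov & pos_all))
            pr_n = int(np.count_nonzero(pr_cov & ~pos_all))
            if pr_p + pr_n > 0 and pr_n >= pr_p:
                break
            dl = _description_length(class_rules + [conds], X, pos_all, active0, n_cand)
            if dl > best_dl + params.mdl_slack:
                break
            best_dl = min(best_dl, dl)
            class_rules.append(conds)
            remaining &= ~covered
            if np_neg == 0 and not np.any(pos_all & remaining):
                break
        # revision passes: re-grow each rule on the full data not covered by
        # the other rules of this class, keep whichever errs less there
        for _ in range(params.optimization_passes):
            improved = False
            for i, conds in enumerate(class_rules):
                others = np.zeros(n, dtype=bool)
                for k, other in enumerate(class_rules):
                    if k != i:
                        others |= _cond_mask(X, other)
                scope = active0 & ~others
                if not np.any(pos_all & scope) or not np.any(~pos_all & scope):
                    continue
                new_conds = _foil_grow(X, pos_all, scope)
                if not new_conds:
                    continue

                def _err(cs):
                    cov = scope & _cond_mask(X, cs)
                    return (
                        int(np.count_nonzero(cov & ~pos_all))
                        + int(np.count_nonzero(~cov & scope & pos_all)),
                        len(cs),
                    )

                if _err(new_conds) < _err(conds):
                    class_rules[i] = new_conds
                    improved = True
            if not improved:
                break
        for conds in class_rules:
            out_rules.append(
                Rule(tuple(Condition(genes[j], op, thr) for j, op, thr in conds), cls)
            )
        # recompute remaining against possibly revised rules
        remaining = np.ones(n, dtype=bool)
        for r_done in out_rules:
            mask = np.ones(n, dtype=bool)
            for c in r_done.conditions:
                col = X[:, genes.index(c.gene)]
                mask &= (col >= c.threshold) if c.op == ">=" else (col <= c.threshold)
            remaining &= ~mask

    out_rules.append(Rule((), default))
    return RuleSet(out_rules)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _match_classes(consequents: Iterable[str], classes: Sequence[str]) -> dict[str, int]:
    lookup = {_norm_label(c): i for i, c in enumerate(classes)}
    mapping = {}
    for cons in consequents:
        key = _norm_label(cons)
        if key not in lookup:
            raise RuleError(f"rule consequent {cons!r} is not a dataset class")
        mapping[cons] = lookup[key]
    return mapping


def evaluate_ruleset(
    rs: RuleSet | None,
    ds: LabeledDataset,
    mode: str = "self_consistency",
    cv: "CVConfig | None" = None,
    genes: Sequence[str] | None = None,
    ripper: RipperParams | None = None,
    ri: Mapping[str, float] | None = None,
    reinduce: bool = True,
) -> PerformanceReport:
    """Score a rule set by self-consistency or cross-validation.

    ``self_consistency`` applies ``rs`` to every sample (the optimistic
    evaluation).  ``cv`` runs stratified k-fold CV, by default re-inducing
    rules on each training fold (Johnson reducer + RIPPER on ``genes``) —
    the honest protocol; with ``reinduce=False`` the fixed ``rs`` is applied
    to held-out folds instead.  Fold confusions are pooled over all repeats.
    """
    from .ifs import CVConfig  # local import avoids a hard module cycle

    y = ds.y
    C = ds.n_classes
    if mode == "self_consistency":
        if rs is None:
            raise RuleError("self_consistency needs a rule set")
        preds = apply_rules_to_dataset(rs, ds)
        mapping = _match_classes(set(preds), ds.classes)
        conf = confusion_from_predictions(y, np.array([mapping[p] for p in preds]), C)
        return PerformanceReport(list(ds.classes), conf)
    if mode != "cv":
        raise RuleError(f"unknown evaluation mode {mode!r}")

    cv = cv or CVConfig(repeats=3)
    from sklearn.model_selection import StratifiedKFold

    counts = ds.class_counts()
    folds = min(cv.folds, min(counts.values()))
    if folds < cv.folds:
        logger.warning("evaluate_ruleset: folds reduced from %d to %d", cv.folds, folds)
    if folds < 2:
        raise RuleError("cross-validation needs every class to have >= 2 samples")
    conf = np.zeros((C, C), dtype=int)
    for rep in range(cv.repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cv.seed + rep)
        for train_idx, test_idx in skf.split(np.zeros(ds.n_samples), y):
            train = ds.subset_samples(train_idx)
            if reinduce:
                cand = list(genes) if genes is not None else list(ds.genes)
                reduct = johnson_reducer(train, cand, ri=ri, seed=cv.seed + rep)
                rs_fold = ripper_induce(train, reduct or cand, ripper)
            else:
                if rs is None:
                    raise RuleError("reinduce=False needs a fixed rule set")
                rs_fold = rs
            test = ds.subset_samples(test_idx)
            preds = apply_rules_to_dataset(rs_fold, test)
            mapping = _match_classes(set(preds), ds.classes)
            conf += confusion_from_predictions(
                y[test_idx], np.array([mapping[p] for p in preds]), C
            )
    return PerformanceReport(list(ds.classes), conf)
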