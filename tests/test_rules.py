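"""Rule engine: application semantics, serialization, discretization,
Johnson reducer, and RIPPER induction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pdxorigin import load_table2_rules
from pdxorigin.ifs import CVConfig
from pdxorigin.rules import (
    Condition,
    RipperParams,
    Rule,
    RuleError,
    RuleParseError,
    RuleSet,
    apply_rules,
    apply_rules_to_dataset,
    discretize_mdl,
    evaluate_ruleset,
    johnson_reducer,
    parse_rules,
    ripper_induce,
    serialize_rules,
)
from pdxorigin.simulate import SyntheticConfig, generate_dataset

from conftest import make_dataset


def brute_force_apply(rs, sample):
    """Oracle: scan every rule in order, return the first full match."""
    for rule in rs.rules:
        if all(
            (sample[c.gene] >= c.threshold if c.op == ">=" else sample[c.gene] <= c.threshold)
            for c in rule.conditions
        ):
            return rule.consequent
    raise AssertionError


def neutral_table2_sample():
    """Values that fire no condition rule of the published table."""
    rs = load_table2_rules()
    sample = {}
    for rule in rs.rules[:-1]:
        for c in rule.conditions:
            # pick a value on the non-firing side of every threshold
            v = c.threshold - 1.0 if c.op == ">=" else c.threshold + 1.0
            if c.gene in sample:
                v = min(v, sample[c.gene]) if c.op == ">=" else max(v, sample[c.gene])
            sample[c.gene] = v
    return sample


# -- application --------------------------------------------------------------


def test_table2_rule1_fires():
    rs = load_table2_rules()
    sample = neutral_table2_sample()
    sample.update({"ANGPTL4": 6.5, "BHMT2": 4.9})
    assert apply_rules(rs, sample) == "Kidney"


def test_table2_boundary_inclusive_rule2():
    rs = load_table2_rules()
    sample = neutral_table2_sample()
    sample["UPK1A"] = 6.474  # exactly the printed threshold
    assert apply_rules(rs, sample) == "Kidney"


def test_table2_default_class():
    rs = load_table2_rules()
    assert apply_rules(rs, neutral_table2_sample()) == "Large intestine"


def test_rule_order_sensitivity():
    rs = load_table2_rules()
    sample = neutral_table2_sample()
    # satisfies both Rule-1 (Kidney) and Rule-11 (Pancreas): first match wins
    sample.update({"ANGPTL4": 7.0, "BHMT2": 5.0, "ADAM28": 4.0, "BTBD6": 7.0})
    assert apply_rules(rs, sample) == "Kidney"


def test_missing_gene_named():
    rs = load_table2_rules()
    sample = neutral_table2_sample()
    del sample["VIM"]
    with pytest.raises(RuleError, match="VIM"):
        apply_rules(rs, sample)


@settings(derandomize=True, max_examples=50)
@given(st.integers(0, 10**6))
def test_apply_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(6)]
    classes = ["c1", "c2", "c3"]
    rules = []
    for _ in range(rng.integers(1, 6)):
        conds = tuple(
            Condition(genes[rng.integers(0, 6)], rng.choice([">=", "<="]),
                      float(rng.normal(5, 2)))
            for _ in range(rng.integers(1, 4))
        )
        rules.append(Rule(conds, str(rng.choice(classes))))
    rules.append(Rule((), "default"))
    rs = RuleSet(rules)
    for _ in range(20):
        sample = {g: float(rng.normal(5, 2)) for g in genes}
        assert apply_rules(rs, sample) == brute_force_apply(rs, sample)


def test_vectorized_dataset_application_matches_per_sample():
    rng = np.random.default_rng(4)
    rs = RuleSet([
        Rule((Condition("g1", ">=", 5.0), Condition("g2", "<=", 3.0)), "A"),
        Rule((Condition("g3", ">=", 4.0),), "B"),
        Rule((), "C"),
    ])
    ds = make_dataset(rng.normal(4, 2, (3, 50)), ["A", "B", "C"] * 16 + ["A", "B"],
                      genes=["g1", "g2", "g3"])
    fast = apply_rules_to_dataset(rs, ds)
    slow = [
        brute_force_apply(rs, {g: ds.values[i, j] for i, g in enumerate(ds.genes)})
        for j in range(ds.n_samples)
    ]
    assert fast == slow


# -- serialization -------------------------------------------------------------


def test_round_trip_table2():
    rs = load_table2_rules()
    assert parse_rules(serialize_rules(rs)) == rs


def test_unicode_operators_accepted_canonical_ascii_out():
    rs = parse_rules("IF FOO ≥ 1.5 AND BAR ≤ 2 THEN X\nIF THEN Y\n")
    assert rs.rules[0].conditions[0].op == ">="
    assert ">=" in serialize_rules(rs) and "≥" not in serialize_rules(rs)


def test_default_rule_must_be_last():
    with pytest.raises(RuleParseError, match="line 1"):
        parse_rules("IF THEN X\nIF A >= 1 THEN Y\n")
    with pytest.raises(RuleParseError):
        parse_rules("completely wrong line\n")


def test_ruleset_structure_invariants():
    with pytest.raises(RuleError):
        RuleSet([Rule((Condition("g", ">=", 1.0),), "A")])  # no default
    with pytest.raises(RuleError):
        RuleSet([Rule((), "A"), Rule((), "B")])  # two defaults


# -- discretization ------------------------------------------------------------


def test_mdl_perfect_split_single_cut():
    ds = make_dataset([[1.0, 1.0, 2.0, 2.0] * 3], ["A", "A", "B", "B"] * 3)
    cuts = discretize_mdl(ds)["g1"]
    assert len(cuts) == 1 and 1.0 < cuts[0] < 2.0


def test_mdl_uninformative_gene_falls_back_to_median():
    rng = np.random.default_rng(0)
    vals = rng.normal(0, 1, 40)
    ds = make_dataset(vals[None, :], ["A", "B"] * 20)
    cuts = discretize_mdl(ds)["g1"]
    assert cuts == [float(np.median(vals))]


def test_mdl_two_clusters_per_class_two_cuts():
    # class B occupies the middle band: two boundaries must be found
    a = np.r_[np.random.default_rng(1).normal(0, 0.1, 20),
              np.random.default_rng(2).normal(10, 0.1, 20)]
    b = np.random.default_rng(3).normal(5, 0.1, 40)
    ds = make_dataset(np.r_[a, b][None, :], ["A"] * 40 + ["B"] * 40)
    assert len(discretize_mdl(ds)["g1"]) >= 2


# -- Johnson reducer -----------------------------------------------------------


def test_johnson_single_gene_covers_all():
    values = np.array([[1.0, 1.0, 9.0, 9.0], [1.0, 9.0, 1.0, 9.0]])
    ds = make_dataset(values, ["A", "A", "B", "B"])
    assert johnson_reducer(ds, ["g1", "g2"]) == ["g1"]


def test_johnson_complementary_pair():
    # g1 discerns A-vs-B pairs only, g2 discerns A-vs-C pairs only; both needed
    values = np.array([
        [0.0, 0.0, 9.0, 9.0, 0.0, 0.0],   # g1: separates B from A and C...
        [0.0, 0.0, 0.0, 0.0, 9.0, 9.0],   # g2: separates C from A and B
    ])
    ds = make_dataset(values, ["A", "A", "B", "B", "C", "C"])
    reduct = johnson_reducer(ds, ["g1", "g2"])
    assert sorted(reduct) == ["g1", "g2"]


def test_johnson_reduct_preserves_discernibility(planted_world):
    ds, gt = planted_world
    candidates = gt.all_markers()
    cuts = discretize_mdl(ds, candidates)
    reduct = johnson_reducer(ds, candidates, cuts=cuts)
    assert set(reduct) <= set(candidates)

    def covered_pairs(genes):
        rows = ds.gene_index(genes)
        y = ds.y
        a, b = np.triu_indices(ds.n_samples, k=1)
        diff = y[a] != y[b]
        a, b = a[diff], b[diff]
        cov = np.zeros(a.size, dtype=bool)
        for g, r in zip(genes, rows):
            bins = np.searchsorted(np.asarray(cuts[g]), ds.values[r])
            cov |= bins[a] != bins[b]
        return cov

    np.testing.assert_array_equal(covered_pairs(reduct), covered_pairs(candidates))


# -- RIPPER ---------------------------------------------------------------------


def test_ripper_recovers_separating_threshold():
    rng = np.random.default_rng(7)
    lo = rng.uniform(1, 4.5, 20)
    hi = rng.uniform(5.5, 9, 10)
    ds = make_dataset(np.r_[lo, hi][None, :], ["maj"] * 20 + ["min"] * 10)
    rs = ripper_induce(ds, ["g1"])
    assert rs.default_class == "maj"
    assert len(rs) == 2
    (cond,) = rs.rules[0].conditions
    assert cond.op == ">=" and lo.max() < cond.threshold < hi.min()
    assert rs.rules[0].consequent == "min"


def test_ripper_single_class_degenerates_to_default():
    ds = make_dataset(np.random.default_rng(0).normal(0, 1, (3, 8)), ["A"] * 8)
    rs = ripper_induce(ds, ds.genes)
    assert len(rs) == 1 and rs.default_class == "A"


def test_ripper_default_is_largest_class(planted_world):
    ds, gt = planted_world
    # make alpha clearly largest by keeping only 8 samples of each other class
    keep = [i for i, l in enumerate(ds.labels) if l == "alpha"]
    for other in ("beta", "gamma", "delta"):
        keep += [i for i, l in enumerate(ds.labels) if l == other][:8]
    sub = ds.subset_samples(sorted(keep))
    counts = sub.class_counts()
    rs = ripper_induce(sub, gt.all_markers(), RipperParams(seed=1))
    assert rs.default_class == max(counts, key=counts.get)


def test_ripper_empty_gene_list_gives_default_only(planted_world):
    ds, _ = planted_world
    rs = ripper_induce(ds, [])
    assert len(rs) == 1


# -- evaluation -----------------------------------------------------------------


def test_evaluate_constructed_fixture_perfect():
    rs = RuleSet([
        Rule((Condition("g1", ">=", 5.0),), "A"),
        Rule((Condition("g2", ">=", 5.0),), "B"),
        Rule((), "C"),
    ])
    # each sample fires exactly its intended rule
    values = np.array([
        [9.0, 9.0, 1.0, 1.0, 1.0, 1.0],
        [1.0, 1.0, 9.0, 9.0, 1.0, 1.0],
    ])
    ds = make_dataset(values, ["A", "A", "B", "B", "C", "C"], genes=["g1", "g2"])
    rep = evaluate_ruleset(rs, ds, mode="self_consistency")
    assert rep.overall_accuracy == 1.0 and rep.mcc == 1.0


def test_evaluate_label_normalization():
    rs = RuleSet([Rule((Condition("g1", ">=", 5.0),), "  a "), Rule((), "B")])
    ds = make_dataset([[9.0, 1.0, 1.0, 9.0]], ["A", "B", "B", "A"])
    rep = evaluate_ruleset(rs, ds, mode="self_consistency")
    assert rep.overall_accuracy == 1.0


def test_evaluate_cv_pools_repeats(planted_world):
    ds, gt = planted_world
    rep = evaluate_ruleset(
        None, ds, mode="cv", cv=CVConfig(folds=5, repeats=3, seed=0),
        genes=gt.all_markers(),
    )
    assert rep.confusion.sum() == 3 * ds.n_samples


def test_self_consistency_not_worse_than_cv_on_average(planted_world):
    ds, gt = planted_world
    genes = gt.all_markers()
    self_mccs, cv_mccs = [], []
    for seed in range(3):
        rs = ripper_induce(ds, genes, RipperParams(seed=seed))
        self_mccs.append(evaluate_ruleset(rs, ds, mode="self_consistency").mcc)
        cv_mccs.append(
            evaluate_ruleset(
                None, ds, mode="cv", cv=CVConfig(folds=5, repeats=1, seed=seed),
                genes=genes,
            ).mcc
        )
    assert np.mean(self_mccs) >= np.mean(cv_mccs)


def test_evaluate_fixed_rules_cv(planted_world):
    ds, gt = planted_world
    rs = ripper_induce(ds, gt.all_markers(), RipperParams(seed=3))
    rep = evaluate_ruleset(
        rs, ds, mode="cv", cv=CVConfig(folds=5, repeats=1, seed=1), reinduce=False
    )
    assert rep.confusion.sum() == ds.n_samples
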