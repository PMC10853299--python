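import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from rimsift import (ConfusionMetrics, P5RimClassifier, evaluate, fisher_exact,
                     select_cutoff, stratified_split)
from rimsift.phantom import NPRWML, PRL


def make_table(prl_p5, npr_p5):
    return pd.DataFrame({
        "class": [PRL] * len(prl_p5) + [NPRWML] * len(npr_p5),
        "p5_t1pre": list(prl_p5) + list(npr_p5),
    })


def brute_force_cutoff(train, spec_constraint):
    """Exhaustive oracle over every candidate threshold."""
    p5 = train["p5_t1pre"].to_numpy(dtype=float)
    is_prl = (train["class"] == PRL).to_numpy()
    uniq = np.unique(p5)
    cands = np.concatenate([[uniq[0]], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1] + 1]])
    best = None
    for c in cands:
        pred = p5 < c
        tp = (pred & is_prl).sum(); fn = (~pred & is_prl).sum()
        fp = (pred & ~is_prl).sum(); tn = (~pred & ~is_prl).sum()
        sens, spec = tp / (tp + fn), tn / (tn + fp)
        if spec < spec_constraint:
            continue
        key = (sens, spec, -c)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    return best


def enum_fisher_p(table):
    """Hypergeometric enumeration oracle for the two-sided Fisher test."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-7):
            total += pk
    return min(1.0, total)


def test_split_paper_counts_every_seed():
    table = make_table(np.arange(39), 100 + np.arange(1075))
    for seed in range(5):
        s = stratified_split(table, 0.5, seed)
        assert (s.train["class"] == PRL).sum() == 20
        assert (s.train["class"] == NPRWML).sum() == 538
        assert (s.test["class"] == PRL).sum() == 19
        assert (s.test["class"] == NPRWML).sum() == 537


def test_split_partition_and_determinism():
    table = make_table(np.arange(7), 50 + np.arange(12))
    a = stratified_split(table, 0.5, seed=3)
    b = stratified_split(table, 0.5, seed=3)
    assert a.train.index.tolist() == b.train.index.tolist()
    assert sorted(a.train.index.tolist() + a.test.index.tolist()) == \
        list(table.index)
    c = stratified_split(table, 0.5, seed=4)
    assert c.train.index.tolist() != a.train.index.tolist()


def test_split_rejects_bad_fraction_and_missing_class():
    table = make_table([1.0], [2.0])
    with pytest.raises(ValueError):
        stratified_split(table, 1.0, 0)
    with pytest.raises(ValueError, match="cannot stratify"):
        stratified_split(make_table([], [1.0, 2.0]), 0.5, 0)


def test_select_cutoff_separable_case():
    train = make_table([5.0, 6.0], [50.0, 60.0])
    m = select_cutoff(train, 0.95)
    assert m.train_sensitivity == 1.0
    assert m.train_specificity == 1.0
    assert 6.0 < m.cutoff < 50.0


def test_cutoff_boundary_predicts_negative():
    train = make_table([5.0, 6.0], [50.0, 60.0])
    m = select_cutoff(train, 0.95)
    assert not m.predict([m.cutoff])[0]
    assert m.predict([m.cutoff - 1e-9])[0]


def test_select_cutoff_respects_constraint(rng):
    for _ in range(30):
        n_prl = rng.integers(2, 8)
        n_npr = rng.integers(5, 20)
        train = make_table(rng.normal(20, 15, n_prl), rng.normal(50, 15, n_npr))
        m = select_cutoff(train, 0.9)
        assert m.train_specificity >= 0.9


def test_select_cutoff_matches_exhaustive_oracle(rng):
    for _ in range(60):
        n_prl = int(rng.integers(1, 10))
        n_npr = int(rng.integers(1, 21))
        train = make_table(np.round(rng.normal(25, 20, n_prl), 1),
                           np.round(rng.normal(55, 20, n_npr), 1))
        constraint = float(rng.choice([0.0, 0.5, 0.8, 0.95]))
        oracle = brute_force_cutoff(train, constraint)
        if oracle is None:
            with pytest.raises(ValueError):
                select_cutoff(train, constraint)
            continue
        m = select_cutoff(train, constraint)
        assert m.cutoff == pytest.approx(oracle[1])
        assert m.train_sensitivity == pytest.approx(oracle[2])
        assert m.train_specificity == pytest.approx(oracle[3])


def test_select_cutoff_degenerate_overlap_falls_back_to_all_negative():
    # the PRL and a non-PRL share one p5 value: at full specificity the
    # only admissible rule is all-negative (sentinel cutoff = min p5)
    train = make_table([50.0], [50.0])
    m = select_cutoff(train, 1.0)
    assert m.train_sensitivity == 0.0
    assert m.train_specificity == 1.0
    assert not m.predict([50.0])[0]


def test_evaluate_identities_and_printed_metrics():
    m = ConfusionMetrics.from_counts(tp=10, fn=9, fp=22, tn=515)
    assert m.sensitivity == pytest.approx(10 / 19)
    assert m.specificity == pytest.approx(515 / 537)
    assert m.ppv == pytest.approx(10 / 32)
    assert m.npv == pytest.approx(515 / 524)
    assert m.f1 == pytest.approx(2 * m.ppv * m.sensitivity / (m.ppv + m.sensitivity))
    assert m.undefined == ()


def test_perfect_classifier_metrics_all_one():
    m = ConfusionMetrics.from_counts(tp=5, fn=0, fp=0, tn=10)
    for name in ("sensitivity", "specificity", "ppv", "npv", "f1"):
        assert getattr(m, name) == 1.0


def test_all_negative_predictions_flag_undefined():
    table = make_table([10.0, 12.0], [50.0, 60.0, 70.0])
    from rimsift.classify import CutoffModel
    model = CutoffModel(cutoff=0.0, spec_constraint=0.95,
                        train_sensitivity=0.0, train_specificity=1.0)
    m = evaluate(table, model)
    assert m.sensitivity == 0.0
    assert m.ppv is None
    assert "ppv" in m.undefined


def test_fisher_hand_enumeration():
    assert fisher_exact([[2, 0], [0, 2]]) == pytest.approx(1 / 3)


def test_fisher_zero_row_and_symmetry():
    assert fisher_exact([[0, 0], [3, 4]]) == pytest.approx(1.0)
    t = [[5, 2], [1, 7]]
    tt = [[5, 1], [2, 7]]
    assert fisher_exact(t) == pytest.approx(fisher_exact(tt))


def test_fisher_rejects_negative():
    with pytest.raises(ValueError):
        fisher_exact([[-1, 2], [3, 4]])


def test_fisher_matches_enumeration_small_margins():
    rng = np.random.default_rng(0)
    picks = rng.integers(0, 7, size=(80, 4))
    for a, b, c, d in picks:
        if a + b + c + d == 0:
            continue
        table = [[int(a), int(b)], [int(c), int(d)]]
        assert fisher_exact(table) == pytest.approx(enum_fisher_p(table), rel=1e-7), table


def test_model_results_summary_and_rounding():
    rng = np.random.default_rng(5)
    table = make_table(rng.normal(5, 3, 12), rng.normal(60, 5, 40))
    res = P5RimClassifier(table, spec_constraint=0.9).fit(seed=2)
    assert res.cutoff_model.train_specificity >= 0.9
    d = res.to_dict()
    assert d["split"]["train_prl"] + d["split"]["test_prl"] == 12
    text = res.summary()
    assert "cutoff" in text and "specificity" in text
    # half-up reporting precision
    from rimsift._stats import round_half_up
    assert round_half_up(0.3125) == 0.313
    assert round_half_up(10 / 19) == 0.526
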