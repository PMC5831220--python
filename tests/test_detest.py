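import numpy as np
import pytest
from scipy.stats import nbinom

from groupsil import (
    ExpressionMatrix,
    GroupLabels,
    SimulationConfig,
    auc_vs_truth,
    bh_adjust,
    exact_nb_test,
    norm_factors,
    p_deg,
    p_true_deg,
    run_de,
    simulate_counts,
    zero_filter,
)
from groupsil.detest import _split_pvalue
from groupsil.iolib import MODE_COUNTS


def _counts(vals, samples=None):
    vals = np.asarray(vals, dtype=float)
    samples = samples or [f"s{j}" for j in range(vals.shape[1])]
    return ExpressionMatrix([f"g{i}" for i in range(vals.shape[0])], samples,
                            vals, MODE_COUNTS)


def _labels(n_a, n_b):
    return GroupLabels({f"s{j}": ("A" if j < n_a else "B") for j in range(n_a + n_b)})


# ---------------------------------------------------------------- norm factors

def test_equal_columns_give_unit_factors(rng):
    col = rng.integers(1, 50, size=40).astype(float)
    m = _counts(np.column_stack([col] * 4))
    for method in ("libsize", "tmm"):
        f = norm_factors(m, _labels(2, 2), method)
        np.testing.assert_allclose(f.to_numpy(), 1.0, atol=1e-12)


def test_libsize_factors_proportional_to_column_sums(rng):
    a = rng.integers(1, 50, size=60).astype(float)
    m = _counts(np.column_stack([a, 2 * a, a, 2 * a]))
    f = norm_factors(m, _labels(2, 2), "libsize")
    assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0)
    assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)


def test_tmm_on_null_simulation_close_to_one():
    ds = simulate_counts(SimulationConfig(n_genes=2000, p_deg=0.0,
                                          n_rep_A=5, n_rep_B=5, seed=8))
    m, _ = zero_filter(ds.matrix)
    f = norm_factors(m, ds.labels, "tmm")
    assert np.all(np.abs(f.to_numpy() - 1.0) < 0.05)


def test_zero_column_sum_is_error():
    m = _counts([[0, 1], [0, 2]])
    with pytest.raises(ValueError):
        norm_factors(m, _labels(1, 1), "libsize")


def test_degespipe_runs_and_stays_near_one_on_null():
    ds = simulate_counts(SimulationConfig(n_genes=500, p_deg=0.0,
                                          n_rep_A=4, n_rep_B=4, seed=21))
    m, _ = zero_filter(ds.matrix)
    f = norm_factors(m, ds.labels, "degespipe")
    assert np.all(np.abs(f.to_numpy() - 1.0) < 0.1)


# ------------------------------------------------------------------ exact test

def test_balanced_split_gives_p_one():
    assert _split_pvalue(10, 20, 3, 3, 0.2) == pytest.approx(1.0)
    assert _split_pvalue(10, 20, 3, 3, 0.0) == pytest.approx(1.0)


def _oracle_split_pvalue(y_a, t, n_a, n_b, phi, mu=7.3):
    """Direct construction: NB pmfs of the two group sums, conditioned on t."""
    from scipy.stats import poisson

    if phi == 0:
        ks = np.arange(t + 1)
        fa = poisson.pmf(ks, n_a * mu)
        fb = poisson.pmf(ks, n_b * mu)
    else:
        ra, rb = n_a / phi, n_b / phi
        pa = ra / (ra + n_a * mu)
        pb = rb / (rb + n_b * mu)
        ks = np.arange(t + 1)
        fa = nbinom.pmf(ks, ra, pa)
        fb = nbinom.pmf(ks, rb, pb)
    joint = fa * fb[::-1]
    cond = joint / joint.sum()
    return float(cond[cond <= cond[y_a] * (1 + 1e-9)].sum())


def test_small_total_pvalues_match_enumeration_oracle(rng):
    for _ in range(100):
        n_a, n_b = rng.integers(2, 6), rng.integers(2, 6)
        t = int(rng.integers(1, 51))
        y_a = int(rng.integers(0, t + 1))
        phi = float(rng.choice([0.0, 0.05, 0.3, 1.5]))
        got = _split_pvalue(y_a, t, int(n_a), int(n_b), phi)
        want = _oracle_split_pvalue(y_a, t, int(n_a), int(n_b), phi)
        assert got == pytest.approx(want, abs=1e-8)


def test_windowed_large_total_matches_full_enumeration():
    """The >4000-total window must not change the p-value materially."""
    from groupsil import detest

    cases = [(4600, 10000, 4, 4, 0.15), (5200, 10000, 3, 5, 0.02),
             (4990, 10000, 4, 4, 0.0)]
    for y_a, t, n_a, n_b, phi in cases:
        windowed = _split_pvalue(y_a, t, n_a, n_b, phi)
        old = detest._FULL_ENUM_MAX
        try:
            detest._FULL_ENUM_MAX = 10**9
            full = _split_pvalue(y_a, t, n_a, n_b, phi)
        finally:
            detest._FULL_ENUM_MAX = old
        assert windowed == pytest.approx(full, rel=1e-6, abs=1e-12)


def test_null_simulation_type_one_error_calibrated():
    ds = simulate_counts(SimulationConfig(n_genes=2000, p_deg=0.0,
                                          n_rep_A=5, n_rep_B=5, seed=11))
    m, _ = zero_filter(ds.matrix)
    p = exact_nb_test(m, ds.labels)
    p = p[np.isfinite(p)]
    frac = float((p <= 0.05).mean())
    assert 0.03 <= frac <= 0.07


def test_pvalues_invariant_to_group_label_swap():
    ds = simulate_counts(SimulationConfig(n_genes=300, p_deg=0.2,
                                          n_rep_A=3, n_rep_B=5, seed=4))
    m, _ = zero_filter(ds.matrix)
    p1 = exact_nb_test(m, ds.labels)
    swapped = GroupLabels({s: ("B" if g == "A" else "A")
                           for s, g in ds.labels.assignment.items()}, ["A", "B"])
    p2 = exact_nb_test(m, swapped)
    np.testing.assert_allclose(p1, p2, atol=1e-10)


def test_group_with_one_sample_is_error():
    m = _counts([[1, 2, 3], [4, 5, 6]])
    with pytest.raises(ValueError):
        exact_nb_test(m, _labels(1, 2))


# ------------------------------------------------------------------- BH / AUC

def test_bh_trivial_cases():
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


def _bh_oracle(p):
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        q[i] = min(min(1.0, p[j] * m / (list(order).index(j) + 1))
                   for j in order[pos:])
    return q


def test_bh_matches_brute_force_and_statsmodels(rng):
    sm = pytest.importorskip("statsmodels.stats.multitest")
    for _ in range(100):
        p = rng.random(rng.integers(1, 30))
        q = bh_adjust(p)
        np.testing.assert_allclose(q, _bh_oracle(p), atol=1e-12)
        np.testing.assert_allclose(q, sm.multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)
        assert np.all(q >= p - 1e-15)  # BH multiplier never shrinks a p-value


def test_bh_monotone_on_sorted_input(rng):
    p = np.sort(rng.random(50))
    q = bh_adjust(p)
    assert np.all(np.diff(q) >= -1e-15)


def test_p_deg_counts_and_monotone_in_fdr(rng):
    q = rng.random(500)
    assert p_deg(q, 0.0) <= p_deg(q, 0.1) <= p_deg(q, 0.5) <= p_deg(q, 1.0)
    assert p_deg(np.ones(10), 0.1) == 0.0
    assert p_deg(np.zeros(10), 0.1) == 100.0
    assert p_deg(q, 0.3) == pytest.approx(100.0 * (q <= 0.3).mean())


def test_p_true_deg_worked_example():
    assert round(p_true_deg(0.78, 0.40), 2) == 0.47
    assert p_true_deg(5.0, 0.0) == 5.0
    assert p_true_deg(0.0, 0.3) == 0.0


def test_auc_extremes_and_errors():
    p = np.array([0.01, 0.02, 0.8, 0.9])
    truth = np.array([True, True, False, False])
    assert auc_vs_truth(p, truth) == 1.0
    assert auc_vs_truth(p, ~truth) == 0.0
    with pytest.raises(ValueError):
        auc_vs_truth(p, np.ones(4, bool))


def test_auc_matches_pair_counting_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(5, 40))
        p = rng.choice([0.1, 0.2, 0.5, 0.9], size=n)  # force ties
        truth = rng.random(n) < 0.4
        if truth.all() or not truth.any():
            continue
        wins = ties = 0
        for i in np.flatnonzero(truth):
            for j in np.flatnonzero(~truth):
                wins += p[i] < p[j]
                ties += p[i] == p[j]
        want = (wins + 0.5 * ties) / (truth.sum() * (~truth).sum())
        assert auc_vs_truth(p, truth) == pytest.approx(want, abs=1e-12)


def test_run_de_table_invariants():
    ds = simulate_counts(SimulationConfig(n_genes=400, p_deg=0.2,
                                          n_rep_A=4, n_rep_B=4, seed=13))
    m, _ = zero_filter(ds.matrix)
    res = run_de(m, ds.labels, truth=ds.truth["is_deg"].reindex(m.gene_ids))
    tab = res.table.dropna()
    assert np.all(tab["q_value"] >= tab["p_value"] - 1e-15)
    assert res.p_true_deg <= res.p_deg
    assert 0.0 <= res.p_deg <= 100.0
    assert sorted(tab["rank"]) == list(range(1, len(tab) + 1))
    assert res.auc is not None and res.auc > 0.8
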