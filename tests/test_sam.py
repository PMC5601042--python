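"""SAM engine tests, including independent brute-force oracles.

The oracles re-implement the relative-difference statistic and the balanced
permutation enumeration in plain Python, independently of the vectorized
engine.
"""

import itertools
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tapnet.exceptions import ConfigurationError
from tapnet.io import ExpressionMatrix
from tapnet.sam import (
    SamSettings,
    SamTwoClassDE,
    balanced_assignments,
    call_down_regulated,
    choose_s0,
    d_statistic,
    default_delta_grid,
    fdr_at_delta,
    permutation_null,
    q_values,
)
from tapnet.simulate import SimConfig, simulate_cascade


# ---------------------------------------------------------------------------
# Oracles


def oracle_d_s(ref, treat, s0):
    n1, n2 = len(ref), len(treat)
    m1, m2 = sum(ref) / n1, sum(treat) / n2
    ss = sum((x - m1) ** 2 for x in ref) + sum((x - m2) ** 2 for x in treat)
    a = (1 / n1 + 1 / n2) / (n1 + n2 - 2)
    s = (a * ss) ** 0.5
    return (m2 - m1) / (s + s0), s


def oracle_dbar_table(data, n_ref, s0):
    """Sorted permuted d rows via exhaustive combination enumeration."""
    n = data.shape[1]
    rows = []
    for ref_ix in itertools.combinations(range(n), n_ref):
        treat_ix = [j for j in range(n) if j not in ref_ix]
        d = sorted(
            oracle_d_s(list(data[g, list(ref_ix)]), list(data[g, treat_ix]), s0)[0]
            for g in range(data.shape[0])
        )
        rows.append(d)
    table = np.array(rows)
    return table.mean(axis=0), table


def make_matrix(data, n_ref=3, n_treat=3):
    genes = [f"G{i:03d}" for i in range(data.shape[0])]
    cols = [f"wt_{i}" for i in range(n_ref)] + [f"mut_{i}" for i in range(n_treat)]
    design = {c: ("wt" if c.startswith("wt") else "mut") for c in cols}
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=cols), design)


# ---------------------------------------------------------------------------
# d statistic


class TestDStatistic:
    def test_equal_groups_give_zero(self):
        d, _ = d_statistic([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], s0=0.5)
        assert d == 0.0

    def test_zero_variance_groups(self):
        d, s = d_statistic([4.0, 4.0, 4.0], [1.0, 1.0, 1.0], s0=1.0)
        assert (d, s) == (-3.0, 0.0)

    def test_zero_denominator_reported(self):
        with pytest.raises(ZeroDivisionError, match="gene rows"):
            d_statistic([4.0, 4.0], [1.0, 1.0], s0=0.0)

    @given(
        st.lists(st.floats(0.1, 100), min_size=3, max_size=3),
        st.lists(st.floats(0.1, 100), min_size=3, max_size=3),
        st.floats(0.01, 5),
    )
    def test_matches_oracle_to_12_digits(self, ref, treat, s0):
        d, s = d_statistic(ref, treat, s0)
        d_exp, s_exp = oracle_d_s(ref, treat, s0)
        assert d == pytest.approx(d_exp, rel=1e-12, abs=1e-12)
        assert s == pytest.approx(s_exp, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------------------------
# s0 selection


class TestChooseS0:
    def test_constant_s_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant s"):
            s0 = choose_s0(np.ones(200), lambda c: np.ones(200))
        assert s0 == 0.0

    def test_small_s_inflation_detected(self, rng):
        # 500 genes whose |d| blows up at s0=0 because s is tiny for half
        s = np.concatenate([np.full(250, 1e-3), np.full(250, 1.0)])
        s += rng.uniform(0, 1e-4, size=500)
        numer = rng.normal(0, 1, size=500)  # same spread regardless of s
        d_fn = lambda s0: numer / (s + s0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            chosen = choose_s0(s, d_fn)
        assert chosen > 0
        # chosen candidate attains the minimum criterion over all candidates
        from tapnet.sam import _window_mad_cv

        candidates = [0.0] + list(np.percentile(s, np.arange(0, 100, 5)))
        cvs = [_window_mad_cv(d_fn(c), s) for c in candidates]
        assert _window_mad_cv(d_fn(chosen), s) == min(cvs)

    def test_fixed_mode_bypasses_selection(self, small_study):
        pair = small_study.matrix.subset_conditions(["wt", "dyt1"])
        calls = call_down_regulated(
            pair, SamSettings(s0_mode="fixed", s0_value=0.123)
        )
        assert calls.s0 == 0.123


# ---------------------------------------------------------------------------
# Permutations


class TestPermutationNull:
    def test_all_3v3_gives_20_assignments_including_identity(self):
        assignments = balanced_assignments(3, 3, "all")
        assert len(assignments) == 20
        assert any(np.array_equal(a, [0, 1, 2]) for a in assignments)

    def test_single_gene_dbar_is_mean_of_permuted_d(self, rng):
        data = rng.uniform(1, 10, size=(1, 6))
        matrix = make_matrix(data)
        dbar, table = permutation_null(matrix, s0=0.1, n_permutations="all")
        expected, _ = oracle_dbar_table(data, 3, 0.1)
        assert dbar == pytest.approx(expected, rel=1e-12)
        assert table.shape == (20, 1)

    def test_null_data_dbar_tracks_observed_order_statistics(self, rng):
        # labels exchangeable: mean dbar ~ mean of observed sorted d
        data = rng.lognormal(3, 0.5, size=(500, 6))
        matrix = make_matrix(data)
        dbar, _ = permutation_null(matrix, s0=0.05, n_permutations="all")
        d, _ = d_statistic(data[:, :3], data[:, 3:], 0.05)
        assert np.mean(np.sort(d)) == pytest.approx(np.mean(dbar), abs=0.05)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(ConfigurationError):
            balanced_assignments(3, 3, 1)


# ---------------------------------------------------------------------------
# FDR / q-values


class TestFdrAndQ:
    @pytest.fixture()
    def run(self, rng):
        data = rng.lognormal(3, 0.4, size=(100, 6))
        data[:10, 3:] *= 0.2  # ten strong down genes
        d, _ = d_statistic(np.log2(data[:, :3]), np.log2(data[:, 3:]), 0.1)
        order = np.argsort(d)
        log_data = np.log2(data)
        from tapnet.sam import _permutation_d_table

        table = _permutation_d_table(log_data, 3, 0.1, balanced_assignments(3, 3))
        return d[order], table.mean(axis=0), table

    def test_infinite_delta_calls_nothing(self, run):
        d_sorted, dbar, table = run
        res = fdr_at_delta(d_sorted, dbar, table, delta=1e9)
        assert res.n_called == 0 and res.fdr == 0.0

    def test_zero_delta_calls_everything(self, run):
        d_sorted, dbar, table = run
        res = fdr_at_delta(d_sorted, dbar, table, delta=0.0)
        assert res.called.all()

    def test_q_extremal_gene_has_min_q(self, run):
        d_sorted, dbar, table = run
        q = q_values(d_sorted, dbar, table)
        extreme = np.argmax(np.abs(d_sorted - dbar))
        assert q[extreme] == q.min()

    def test_q_monotone_in_offset(self, run):
        d_sorted, dbar, table = run
        q = q_values(d_sorted, dbar, table)
        offsets = np.abs(d_sorted - dbar)
        order = np.argsort(offsets)
        assert (np.diff(q[order]) <= 1e-12).all()

    def test_gene_called_at_no_delta_gets_q_one(self, run):
        d_sorted, dbar, table = run
        grid = np.array([np.abs(d_sorted - dbar).max() + 1.0])
        q = q_values(d_sorted, dbar, table, grid)
        assert (q == 1.0).all()

    def test_q_agrees_with_brute_force_grid_scan(self, run):
        d_sorted, dbar, table = run
        grid = default_delta_grid(d_sorted, dbar, 50)
        q = q_values(d_sorted, dbar, table, grid)
        offsets = np.abs(d_sorted - dbar)
        for g in range(0, 100, 7):
            fdrs = [
                fdr_at_delta(d_sorted, dbar, table, dl).fdr
                for dl in grid
                if dl <= offsets[g]
            ]
            assert q[g] == (min(fdrs) if fdrs else 1.0)

    def test_empty_grid_rejected(self, run):
        d_sorted, dbar, table = run
        with pytest.raises(ConfigurationError):
            q_values(d_sorted, dbar, table, np.array([]))


# ---------------------------------------------------------------------------
# End-to-end calls


class TestCallDownRegulated:
    def test_noise_free_limit_recovers_planted_set_exactly(self):
        study = simulate_cascade(
            SimConfig(n_genes=200, replicate_sd=1e-4, effect_log2_sd=1e-6, seed=5)
        )
        pair = study.matrix.subset_conditions(["wt", "dyt1"])
        calls = call_down_regulated(pair, SamSettings())
        planted = {t.gene for t in study.truth if "dyt1" in t.affected_mutants}
        assert calls.down_genes == planted

    def test_fold_change_filter_vetoes_extreme_d(self, rng):
        # one gene with tiny variance (huge |d|) but fold change 0.6
        data = rng.lognormal(4, 0.3, size=(150, 6))
        data[0, :3] = [100.0, 100.1, 99.9]
        data[0, 3:] = [60.0, 60.05, 59.95]
        matrix = make_matrix(data)
        calls = call_down_regulated(matrix, SamSettings(delta=0.5))
        assert "G000" not in calls.down_genes

    def test_paper_mode_per_mutant_deltas_accepted(self, small_study):
        for mutant, delta in {"dyt1": 1.43, "tdf1": 2.2, "ams": 1.55,
                              "ms188": 1.47}.items():
            pair = small_study.matrix.subset_conditions(["wt", mutant])
            calls = call_down_regulated(pair, SamSettings(delta=delta))
            assert calls.delta == delta
            assert calls.mutant_label == mutant

    def test_requires_exactly_two_conditions(self, small_study):
        with pytest.raises(ConfigurationError):
            call_down_regulated(small_study.matrix, SamSettings())

    def test_replicate_order_exchangeability(self, small_study):
        pair = small_study.matrix.subset_conditions(["wt", "tdf1"])
        shuffled_cols = ["wt_3", "wt_1", "wt_2", "tdf1_2", "tdf1_3", "tdf1_1"]
        shuffled = ExpressionMatrix(
            pair.values[shuffled_cols].copy(),
            {c: pair.design[c] for c in shuffled_cols},
        )
        a = call_down_regulated(pair, SamSettings())
        b = call_down_regulated(shuffled, SamSettings())
        assert a.down_genes == b.down_genes
        assert {r.gene: r.d for r in a.per_gene} == {r.gene: r.d for r in b.per_gene}
        assert {r.gene: r.q_value for r in a.per_gene} == {
            r.gene: r.q_value for r in b.per_gene
        }

    def test_sklearn_selector_contract(self, small_study):
        pair = small_study.matrix.subset_conditions(["wt", "dyt1"])
        X = pair.values.to_numpy().T
        y = np.array([pair.design[s] for s in pair.values.columns])
        est = SamTwoClassDE().fit(X, y)
        assert est.get_support().sum() == est.transform(X).shape[1]
        params = est.get_params()
        assert params["reference"] == "wt"
        clone_mask = SamTwoClassDE(**params).fit(X, y).get_support()
        assert (clone_mask == est.get_support()).all()
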