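import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from diffcornet import (
    ConfigurationError,
    DataError,
    DifferentialEdge,
    PermutationPlan,
    differential_correlation,
    edges_to_frame,
    fisher_z,
    overlap_fraction,
    pairwise_correlations,
    permutation_test,
    select_edges,
    significant_pairs,
)
from diffcornet.tables import GROUP_POST, GROUP_PRE

from conftest import make_table


class TestFisherZ:
    def test_zero_fixed_point(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * math.log(3), rel=1e-12)
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_degenerate_correlation_raises(self, r):
        with pytest.raises(DataError):
            fisher_z(r)

    @given(st.floats(min_value=-0.999, max_value=0.999))
    @settings(max_examples=50, deadline=None)
    def test_odd_function(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)


class TestDifferentialCorrelation:
    def test_equal_groups_cancel(self):
        assert differential_correlation(0.8, 0.8, 55, 55) == 0.0

    def test_unequal_sizes_weighting(self):
        # atanh(0.8) * (sqrt(26) - sqrt(30.5))
        d = differential_correlation(0.8, 0.8, 55, 64)
        assert d == pytest.approx(-0.4655, abs=1e-4)

    def test_one_sided_change(self):
        # sqrt(20) * atanh(0.6), atanh(0.6) = 0.5 ln 4
        d = differential_correlation(0.6, 0.0, 43, 43)
        assert d == pytest.approx(math.sqrt(20) * 0.5 * math.log(4), rel=1e-9)
        assert d == pytest.approx(3.0998, abs=1e-4)

    def test_direction_flag_flips_sign(self):
        d = differential_correlation(0.6, 0.2, 50, 60)
        flipped = differential_correlation(0.6, 0.2, 50, 60, direction="post_minus_pre")
        assert flipped == -d

    @given(
        st.floats(min_value=-0.95, max_value=0.95),
        st.floats(min_value=-0.95, max_value=0.95),
        st.integers(min_value=5, max_value=200),
        st.integers(min_value=5, max_value=200),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_under_group_swap(self, r1, r2, n1, n2):
        d = differential_correlation(r1, r2, n1, n2)
        swapped = differential_correlation(r2, r1, n2, n1)
        assert swapped == pytest.approx(-d, abs=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(DataError):
            differential_correlation(0.5, 0.5, 3, 50)


class TestPairwiseCorrelations:
    def test_pair_counts(self, toy_table):
        corr = pairwise_correlations(toy_table, GROUP_PRE)
        assert corr.pair_count() == 6
        assert corr.n == 4

    def test_matrix_structure(self, toy_table):
        corr = pairwise_correlations(toy_table, GROUP_POST)
        r = corr.r.to_numpy()
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r, r.T)
        assert np.all(np.abs(r) <= 1.0)

    def test_pvalues_match_scipy(self, small_study):
        from diffcornet import run_preprocessing

        clean, _ = run_preprocessing(small_study.table)
        corr = pairwise_correlations(clean, GROUP_PRE)
        sub = clean.values_for(GROUP_PRE)
        for i, j in [(0, 1), (2, 7), (5, 19)]:
            ref = stats.pearsonr(sub.iloc[:, i], sub.iloc[:, j])
            assert corr.r.iloc[i, j] == pytest.approx(ref.statistic, abs=1e-12)
            assert corr.p.iloc[i, j] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_variance_named(self):
        table = make_table(
            np.column_stack([np.r_[np.ones(4), np.arange(4.0)], np.arange(8.0)]),
            ["pre"] * 4 + ["post"] * 4,
        )
        with pytest.raises(DataError, match="M000"):
            pairwise_correlations(table, GROUP_PRE)


class TestSignificantPairs:
    def _corr(self, pvals, names):
        import pandas as pd

        from diffcornet import GroupCorrelation

        m = len(names)
        p = np.full((m, m), np.nan)
        r = np.eye(m)
        for (i, j), v in pvals.items():
            p[i, j] = p[j, i] = v
        return GroupCorrelation(
            group=GROUP_PRE, n=10,
            r=pd.DataFrame(r, index=names, columns=names),
            p=pd.DataFrame(p, index=names, columns=names),
        )

    def test_bonferroni_boundary_is_strict(self):
        names = ["A", "B", "C"]
        corr = self._corr({(0, 1): 1e-9, (0, 2): 0.05 / 3, (1, 2): 0.9}, names)
        assert significant_pairs(corr, alpha=0.05) == {("A", "B")}

    def test_all_unit_pvalues_give_empty_set(self):
        names = ["A", "B", "C"]
        corr = self._corr({(0, 1): 1.0, (0, 2): 1.0, (1, 2): 1.0}, names)
        assert significant_pairs(corr) == set()

    def test_monotone_in_alpha(self, small_study):
        from diffcornet import run_preprocessing

        clean, _ = run_preprocessing(small_study.table)
        corr = pairwise_correlations(clean, GROUP_POST)
        assert significant_pairs(corr, alpha=0.025) <= significant_pairs(corr, alpha=0.05)


class TestOverlap:
    def test_identical_sets(self):
        s = {("A", "B"), ("A", "C")}
        assert overlap_fraction(s, set(s)) == 1.0

    def test_disjoint_sets(self):
        assert overlap_fraction({("A", "B")}, {("C", "D")}) == 0.0

    def test_partial_overlap(self):
        assert overlap_fraction({("A", "B"), ("A", "C")}, {("A", "B"), ("B", "D")}) == 0.5

    def test_empty_pre_set_defined_as_zero(self):
        assert overlap_fraction(set(), {("A", "B")}) == 0.0


def _naive_permutation_test(table, permutations):
    """Independent per-pair reimplementation: scipy pearsonr + scalar math."""
    values = table.values
    names = list(values.columns)
    groups = table.metadata["group"].to_numpy()
    n_pre = int((groups == "pre").sum())
    X = values.to_numpy(float)

    def rdiff(pre_rows, post_rows, i, j):
        r1 = stats.pearsonr(X[pre_rows, i], X[pre_rows, j]).statistic
        r2 = stats.pearsonr(X[post_rows, i], X[post_rows, j]).statistic
        w1 = math.sqrt((len(pre_rows) - 3) / 2)
        w2 = math.sqrt((len(post_rows) - 3) / 2)
        return w1 * math.atanh(r1) - w2 * math.atanh(r2)

    obs_pre = np.flatnonzero(groups == "pre")
    obs_post = np.flatnonzero(groups == "post")
    result = {}
    for i, j in itertools.combinations(range(len(names)), 2):
        obs = rdiff(obs_pre, obs_post, i, j)
        count = sum(
            abs(rdiff(row[:n_pre], row[n_pre:], i, j)) >= abs(obs)
            for row in permutations
        )
        result[(names[i], names[j])] = (obs, (1 + count) / (len(permutations) + 1))
    return result


class TestPermutationTest:
    def test_matches_naive_oracle_exactly(self, toy_table):
        """4 metabolites x 8 samples, 10 fixed group-size-preserving
        permutations: p_perm matches a naive reimplementation exactly."""
        rng = np.random.default_rng(123)
        perms = []
        identity = np.arange(8)
        while len(perms) < 10:
            cand = rng.permutation(8)
            if not (set(cand[:4]) == set(identity[:4])):  # exclude identity grouping
                perms.append(cand)
        plan = PermutationPlan(permutations=np.array(perms))
        edges = permutation_test(toy_table, plan)
        oracle = _naive_permutation_test(toy_table, np.array(perms))
        assert len(edges) == 6
        for e in edges:
            obs, p = oracle[(e.met_i, e.met_j)]
            assert e.p_perm == p
            assert e.r_diff == pytest.approx(obs, abs=1e-12)

    def test_seed_reproducibility(self, toy_table):
        a = permutation_test(toy_table, PermutationPlan(n_permutations=50, seed=9))
        b = permutation_test(toy_table, PermutationPlan(n_permutations=50, seed=9))
        assert [e.p_perm for e in a] == [e.p_perm for e in b]
        c = permutation_test(toy_table, PermutationPlan(n_permutations=50, seed=10))
        assert [e.p_perm for e in a] != [e.p_perm for e in c]

    def test_pvalue_floor_is_add_one(self, toy_table):
        edges = permutation_test(toy_table, PermutationPlan(n_permutations=50, seed=3))
        assert all(e.p_perm >= 1 / 51 for e in edges)
        assert all(e.p_perm <= 1.0 for e in edges)

    def test_direction_flag_negates_rdiff(self, toy_table):
        plan = PermutationPlan(n_permutations=20, seed=4)
        fwd = permutation_test(toy_table, plan)
        rev = permutation_test(toy_table, plan, direction="post_minus_pre")
        for a, b in zip(fwd, rev):
            assert b.r_diff == pytest.approx(-a.r_diff, abs=1e-12)
            assert b.p_perm == a.p_perm

    def test_permutation_p_tracks_normal_approximation(self):
        """On normal-scale null data the permutation p agrees with the
        two-sided N(0,1) tail of r_diff up to Monte-Carlo error."""
        from diffcornet import SimulationConfig, generate_study, normalize

        cfg = SimulationConfig(
            n_metabolites=30, shared_blocks=(), lod_quantile=0.0, missing_rate=0.0, seed=11
        )
        study = generate_study(cfg)
        table = study.table
        table.values = np.log(table.values)
        clean = normalize(table)
        edges = permutation_test(clean, PermutationPlan(n_permutations=1000, seed=12))
        rd = np.array([e.r_diff for e in edges])
        pp = np.array([e.p_perm for e in edges])
        analytic = 2 * stats.norm.sf(np.abs(rd))
        diff = np.abs(pp - analytic)
        assert diff.mean() < 0.05
        assert np.quantile(diff, 0.95) < 0.15

    def test_invalid_plan_rejected(self):
        with pytest.raises(ConfigurationError):
            PermutationPlan(n_permutations=0)
        with pytest.raises(ConfigurationError):
            PermutationPlan(permutations=np.array([[0, 0, 1, 2]])).realize(4)


def _edge(met_i, met_j, r_diff, p_perm):
    return DifferentialEdge(
        met_i=met_i, met_j=met_j, r_pre=0.0, r_post=0.0,
        z_pre=0.0, z_post=0.0, r_diff=r_diff, p_perm=p_perm,
    )


class TestSelectEdges:
    def test_threshold_inclusive_and_sorted(self):
        edges = [
            _edge("A", "B", -1.0, 0.01),
            _edge("A", "C", 3.0, 0.002),
            _edge("B", "C", 2.0, 0.5),
        ]
        out = select_edges(edges, 0.01)
        assert [(e.met_i, e.met_j) for e in out] == [("A", "C"), ("A", "B")]

    def test_threshold_one_returns_everything(self):
        edges = [_edge("A", "B", 0.5, 0.9), _edge("A", "C", 0.1, 1.0)]
        assert len(select_edges(edges, 1.0)) == 2

    def test_unattainable_threshold_returns_empty(self, toy_table):
        edges = permutation_test(toy_table, PermutationPlan(n_permutations=10, seed=1))
        assert select_edges(edges, 1 / 12) == []

    def test_tie_break_by_name(self):
        edges = [_edge("B", "C", 1.0, 0.01), _edge("A", "B", -1.0, 0.01)]
        out = select_edges(edges, 0.05)
        assert [(e.met_i, e.met_j) for e in out] == [("A", "B"), ("B", "C")]

    def test_sign_attribute(self):
        assert _edge("A", "B", -0.5, 0.1).sign == "negative"
        assert _edge("A", "B", 0.5, 0.1).sign == "positive"


def test_edges_frame_schema(toy_table):
    edges = permutation_test(toy_table, PermutationPlan(n_permutations=10, seed=1))
    frame = edges_to_frame(edges)
    assert list(frame.columns) == [
        "met_i", "met_j", "r_pre", "r_post", "z_pre", "z_post", "r_diff", "p_perm", "sign",
    ]
    assert (frame["met_i"] < frame["met_j"]).all()
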