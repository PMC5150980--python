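import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp
from scipy.spatial.distance import braycurtis as scipy_braycurtis
from scipy.stats import rankdata

from oxylume import stats as st


def _table(values, species, health):
    return pd.DataFrame({"value": values, "species": species, "health": health})


class TestTwoWayAnova:
    def test_empty_cell_refused(self):
        df = _table(
            [1.0, 2.0, 3.0, 4.0],
            ["a", "a", "b", "b"],
            ["x", "x", "x", "y"],
        )
        with pytest.raises(ValueError, match="empty design cells"):
            st.two_way_anova(df)

    def test_one_factor_f_equals_t_squared(self):
        # balanced two-group design: ANOVA F == pooled t^2
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        df = pd.DataFrame(
            {
                "value": np.concatenate([a, b]),
                "species": ["s1"] * 12 + ["s2"] * 12,
                "health": ["h"] * 24,
            }
        )
        # single-level second factor is refused; run the equivalent via t
        t_res = st.two_sample_t(a, b, variant="pooled")
        import statsmodels.formula.api as smf
        import statsmodels.api as sm

        model = smf.ols("value ~ C(species)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        f = float(table.loc["C(species)", "F"])
        assert f == pytest.approx(t_res.t**2, rel=1e-9)

    def test_balanced_type2_equals_classical_decomposition(self):
        # on a balanced design Type II equals the textbook two-way SS
        rng = np.random.default_rng(2)
        species = np.repeat(["s1", "s2", "s3"], 8)
        health = np.tile(np.repeat(["b", "p"], 4), 3)
        y = rng.normal(0, 1, 24)
        df = _table(y, species, health)
        result = st.two_way_anova(df)

        frame = df.copy()
        grand = frame["value"].mean()
        ss_a = sum(
            g["value"].size * (g["value"].mean() - grand) ** 2
            for _, g in frame.groupby("species")
        )
        ss_b = sum(
            g["value"].size * (g["value"].mean() - grand) ** 2
            for _, g in frame.groupby("health")
        )
        cell_means = frame.groupby(["species", "health"])["value"].transform("mean")
        ss_resid = float(((frame["value"] - cell_means) ** 2).sum())
        ms_resid = ss_resid / (24 - 6)
        f_a = (ss_a / 2) / ms_resid
        f_b = (ss_b / 1) / ms_resid
        assert result["species"].F == pytest.approx(f_a, rel=1e-10)
        assert result["health"].F == pytest.approx(f_b, rel=1e-10)

    def test_type_one_error_rate(self):
        # 200 seeded null simulations: rejection rate at alpha=0.05 in [0.03, 0.07]
        rng = np.random.default_rng(3)
        species = np.repeat(["s1", "s2", "s3"], 10)
        health = np.tile(np.repeat(["b", "p"], 5), 3)
        rejections = {"species": 0, "health": 0, "interaction": 0}
        for _ in range(200):
            df = _table(rng.normal(0, 1, 30), species, health)
            result = st.two_way_anova(df)
            for effect in rejections:
                if result[effect].p < 0.05:
                    rejections[effect] += 1
        for effect, count in rejections.items():
            assert 0.03 <= count / 200 <= 0.07, effect

    def test_power_detects_species_shift_only(self):
        # species means 5 sd apart, health null, n = 10/cell
        rng = np.random.default_rng(42)
        species = np.repeat(["s1", "s2", "s3"], 20)
        health = np.tile(np.repeat(["b", "p"], 10), 3)
        shift = np.select([species == "s1", species == "s2"], [0.0, 5.0], 10.0)
        df = _table(rng.normal(0, 1, 60) + shift, species, health)
        result = st.two_way_anova(df)
        assert result["species"].p < 0.001
        assert result["health"].p > 0.05

    def test_df_reflect_design(self):
        rng = np.random.default_rng(0)
        species = np.repeat(["s1", "s2", "s3", "s4", "s5"], 6)
        health = np.tile(np.repeat(["b", "p"], 3), 5)
        result = st.two_way_anova(_table(rng.normal(0, 1, 30), species, health))
        assert result["species"].df_num == 4
        assert result["health"].df_num == 1
        assert result["interaction"].df_num == 4
        assert result["species"].df_den == 30 - 10


class TestTukeyHsd:
    def test_identical_groups_p_near_one(self):
        rng = np.random.default_rng(8)
        base = rng.normal(0, 1, 15)
        df = pd.DataFrame(
            {"value": np.tile(base, 3), "species": np.repeat(["a", "b", "c"], 15)}
        )
        pvals = st.tukey_hsd(df, "species")
        assert all(p > 0.99 for p in pvals.values())

    def test_single_shifted_group_flagged(self):
        rng = np.random.default_rng(9)
        values = np.concatenate(
            [rng.normal(0, 1, 12), rng.normal(0, 1, 12), rng.normal(8, 1, 12)]
        )
        df = pd.DataFrame(
            {"value": values, "species": np.repeat(["a", "b", "c"], 12)}
        )
        pvals = st.tukey_hsd(df, "species")
        assert pvals[("a", "c")] < 0.001
        assert pvals[("b", "c")] < 0.001
        assert pvals[("a", "b")] > 0.05

    def test_hsd_monotone_in_separation(self):
        rng = np.random.default_rng(10)
        values = np.concatenate(
            [rng.normal(0, 1, 10), rng.normal(1.2, 1, 10), rng.normal(2.4, 1, 10)]
        )
        df = pd.DataFrame(
            {"value": values, "species": np.repeat(["lo", "mid", "hi"], 10)}
        )
        pvals = st.tukey_hsd(df, "species")
        assert pvals[("hi", "lo")] < pvals[("lo", "mid")]
        assert pvals[("hi", "lo")] < pvals[("hi", "mid")]

    def test_two_groups_refused(self):
        df = pd.DataFrame({"value": [1.0, 2.0, 3.0, 4.0], "species": ["a", "a", "b", "b"]})
        with pytest.raises(ValueError, match="3 groups"):
            st.tukey_hsd(df, "species")


class TestTwoSampleT:
    def test_identical_samples(self):
        result = st.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "pooled")
        assert result.t == pytest.approx(0.0, abs=1e-12)
        assert result.p == pytest.approx(1.0)

    def test_textbook_pooled_case(self):
        result = st.two_sample_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], "pooled")
        assert result.t == pytest.approx(-1.2247, abs=1e-4)
        assert result.df == 4

    def test_degenerate_zero_variance_convention(self):
        result = st.two_sample_t([2.0, 2.0], [2.0, 2.0])
        assert result.t == 0.0 and result.p == 1.0

    def test_welch_df_never_exceeds_pooled(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(3, 12)))
            b = rng.normal(0, rng.uniform(0.2, 5.0), int(rng.integers(3, 12)))
            welch = st.two_sample_t(a, b, "unequal_variance")
            pooled_df = a.size + b.size - 2
            assert welch.df <= pooled_df + 1e-9


class TestBrayCurtis:
    def test_identical_samples_zero(self):
        x = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert st.bray_curtis(x)[0, 1] == 0.0

    def test_disjoint_taxa_one(self):
        x = np.array([[1.0, 0.0], [0.0, 3.0]])
        assert st.bray_curtis(x)[0, 1] == 1.0

    def test_hand_computed_value(self):
        x = np.array([[1.0, 1.0], [1.0, 3.0]])
        assert st.bray_curtis(x)[0, 1] == pytest.approx(2.0 / 6.0, rel=1e-12)

    def test_all_zero_sample_named(self):
        x = pd.DataFrame(
            [[1.0, 2.0], [0.0, 0.0]], index=["good", "empty"]
        )
        with pytest.raises(ValueError, match="empty"):
            st.bray_curtis(x)

    def test_matches_scipy_pairwise(self):
        rng = np.random.default_rng(13)
        x = rng.poisson(15, size=(6, 9)).astype(float) + 0.5
        d = st.bray_curtis(x)
        for i, j in itertools.combinations(range(6), 2):
            assert d[i, j] == pytest.approx(scipy_braycurtis(x[i], x[j]), rel=1e-12)

    @given(
        hnp.arrays(
            np.float64,
            shape=(5, 7),
            elements=hst.floats(0.01, 100.0, allow_nan=False),
        )
    )
    @settings(max_examples=40, deadline=None)
    def test_metric_properties_and_taxon_order_invariance(self, x):
        d = st.bray_curtis(x)
        assert np.allclose(d, d.T)
        assert np.allclose(np.diag(d), 0.0)
        assert np.all((d >= 0.0) & (d <= 1.0 + 1e-12))
        perm = np.random.default_rng(0).permutation(x.shape[1])
        assert np.allclose(d, st.bray_curtis(x[:, perm]))


def _brute_force_anosim(d, labels):
    """Independent enumeration oracle: R for every distinct label assignment."""
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(d[iu, ju])
    m = ranks.size
    results = {}
    for perm in set(itertools.permutations(labels)):
        lab = np.asarray(perm)
        within = lab[iu] == lab[ju]
        results[perm] = (ranks[~within].mean() - ranks[within].mean()) / (m / 2.0)
    return results


class TestAnosim:
    @pytest.fixture
    def separated(self):
        rng = np.random.default_rng(14)
        x = rng.poisson(20, size=(6, 10)).astype(float)
        x[:3, :5] += 200.0  # group "a" dominated by the first taxa block
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        return st.bray_curtis(st.relative_abundance(x)), labels

    def test_perfect_separation_r_is_one(self, separated):
        d, labels = separated
        within = d[np.ix_([0, 1, 2], [0, 1, 2])][np.triu_indices(3, 1)]
        between = d[np.ix_([0, 1, 2], [3, 4, 5])].ravel()
        assert within.max() < between.min()  # construction check
        result = st.anosim(d, labels, exact=True)
        assert result.R == pytest.approx(1.0, rel=1e-12)

    def test_exact_p_matches_enumeration(self, separated):
        d, labels = separated
        result = st.anosim(d, labels, exact=True)
        oracle = _brute_force_anosim(d, tuple(labels))
        assert result.n_permutations == 20
        expected_p = np.mean(
            [r >= result.R - 1e-12 for r in oracle.values()]
        )
        assert result.p == pytest.approx(expected_p, rel=1e-12)
        assert result.R == pytest.approx(oracle[tuple(labels)], rel=1e-12)

    def test_exhaustive_agreement_n8(self):
        rng = np.random.default_rng(15)
        x = rng.poisson(25, size=(8, 12)).astype(float)
        labels = np.array(["a"] * 4 + ["b"] * 4)
        d = st.bray_curtis(st.relative_abundance(x))
        result = st.anosim(d, labels, exact=True)
        oracle = _brute_force_anosim(d, tuple(labels))
        expected_p = np.mean([r >= result.R - 1e-12 for r in oracle.values()])
        assert result.p == pytest.approx(expected_p, rel=1e-12)

    def test_null_r_near_zero(self):
        rng = np.random.default_rng(16)
        rs = []
        for _ in range(30):
            x = rng.poisson(20, size=(20, 15)).astype(float)
            labels = rng.permutation(np.repeat(["a", "b"], 10))
            d = st.bray_curtis(st.relative_abundance(x))
            rs.append(st.anosim(d, labels, n_permutations=99, seed=1).R)
        assert abs(np.mean(rs)) < 0.05

    def test_r_bounded_on_random_inputs(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            x = rng.uniform(0.1, 10.0, size=(7, 5))
            labels = rng.permutation(["a", "a", "a", "b", "b", "b", "b"])
            result = st.anosim(st.bray_curtis(x), labels, n_permutations=99, seed=2)
            assert -1.0 <= result.R <= 1.0

    def test_seeded_reproducibility_and_label_renaming(self):
        rng = np.random.default_rng(18)
        x = rng.poisson(20, size=(10, 8)).astype(float)
        d = st.bray_curtis(x)
        labels = np.repeat(["a", "b"], 5)
        renamed = np.repeat(["group-1", "group-2"], 5)
        first = st.anosim(d, labels, n_permutations=499, seed=7)
        second = st.anosim(d, labels, n_permutations=499, seed=7)
        third = st.anosim(d, renamed, n_permutations=499, seed=7)
        assert first.p == second.p == third.p
        assert first.R == third.R

    def test_matches_skbio_r_statistic(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(19)
        x = rng.poisson(20, size=(9, 12)).astype(float)
        x[:3] += rng.poisson(30, size=(3, 12))
        labels = np.array(["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        d = st.bray_curtis(st.relative_abundance(x))
        mine = st.anosim(d, labels, n_permutations=999, seed=1)
        theirs = skbio_distance.anosim(
            skbio_distance.DistanceMatrix(d), labels, permutations=999
        )
        assert mine.R == pytest.approx(float(theirs["test statistic"]), rel=1e-12)

    def test_singleton_group_refused(self):
        d = st.bray_curtis(np.random.default_rng(20).uniform(1, 5, size=(5, 4)))
        with pytest.raises(ValueError, match="fewer than 2"):
            st.anosim(d, ["a", "a", "a", "a", "b"], n_permutations=99)

    def test_p_floor_at_99_permutations(self):
        # with 99 permutations the smallest attainable p is 1/100 = 0.01
        rng = np.random.default_rng(21)
        x = rng.poisson(20, size=(10, 10)).astype(float)
        x[:5, :5] += 500.0
        labels = np.repeat(["a", "b"], 5)
        result = st.anosim(st.bray_curtis(x), labels, n_permutations=99, seed=3)
        assert result.p >= 0.01
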