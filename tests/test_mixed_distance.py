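import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgidclust import (CohortTable, Variable, VariableSchema,
                       fit_attribute_stats, jensen_shannon_divergence,
                       midpoint_cdf_distance, normalized_mutual_information,
                       numeric_block_distance, ordinal_value_distance,
                       pairwise_distances)
from fgidclust.mixed_distance import AttributeStats, DistanceMatrix

from conftest import random_cohort


def make_table(columns: dict, schema_vars) -> CohortTable:
    df = pd.DataFrame(columns)
    df.index = pd.Index([f"r{i}" for i in range(len(df))], name="record_id")
    return CohortTable(df, VariableSchema(tuple(schema_vars)))


@st.composite
def prob_vectors(draw, length=4):
    raw = draw(st.lists(st.floats(0.01, 1.0), min_size=length, max_size=length))
    arr = np.asarray(raw)
    return arr / arr.sum()


class TestJensenShannon:
    def test_identical_distributions_have_zero_divergence(self):
        p = np.array([0.2, 0.3, 0.5])
        assert jensen_shannon_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_attain_ln2(self):
        assert jensen_shannon_divergence([1, 0], [0, 1]) == pytest.approx(math.log(2))

    def test_hand_computed_value(self):
        # H(m) - (H(p)+H(q))/2 evaluated directly with m = (0.375, 0.625)
        assert jensen_shannon_divergence([0.5, 0.5], [0.25, 0.75]) == pytest.approx(
            0.0338219, abs=1e-6)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            jensen_shannon_divergence([1.2, -0.2], [0.5, 0.5])

    @settings(deadline=None, max_examples=50)
    @given(prob_vectors(), prob_vectors())
    def test_symmetric_and_bounded(self, p, q):
        d1 = jensen_shannon_divergence(p, q)
        d2 = jensen_shannon_divergence(q, p)
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert -1e-12 <= d1 <= math.log(2) + 1e-12


class TestMidpointCdf:
    def _stats(self, marginal):
        p = np.asarray(marginal, dtype=float)
        return AttributeStats(
            feature_set="gi_only", ordinal_names=["v"], continuous_names=[],
            levels={"v": len(p)}, marginals={"v": p},
            midpoint_cdf={"v": np.cumsum(p) - 0.5 * p}, conditionals={},
            num_conditionals={}, nmi=pd.DataFrame([[1.0]], index=["v"], columns=["v"]),
            cov=None, lam=0.1, bins=8)

    def test_equal_marginal_extreme_levels(self):
        stats = self._stats([0.25, 0.25, 0.25, 0.25])
        assert midpoint_cdf_distance("v", 0, 3, stats) == pytest.approx(0.75)

    def test_skewed_marginal_adjacent_levels(self):
        stats = self._stats([0.7, 0.1, 0.1, 0.1])
        assert midpoint_cdf_distance("v", 0, 1, stats) == pytest.approx(0.40)

    def test_same_level_is_zero(self):
        stats = self._stats([0.5, 0.5])
        assert midpoint_cdf_distance("v", 1, 1, stats) == 0.0

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            midpoint_cdf_distance("v", 0, 9, self._stats([0.5, 0.5]))

    @settings(deadline=None, max_examples=30)
    @given(prob_vectors(length=5))
    def test_additive_along_level_order(self, marginal):
        stats = self._stats(marginal)
        d_ab = midpoint_cdf_distance("v", 0, 2, stats)
        d_bc = midpoint_cdf_distance("v", 2, 4, stats)
        d_ac = midpoint_cdf_distance("v", 0, 4, stats)
        assert d_ac == pytest.approx(d_ab + d_bc, abs=1e-12)


class TestNormalizedMutualInformation:
    VARS = [Variable(name="a", vtype="ordinal", group="upper_gi", levels=2),
            Variable(name="b", vtype="ordinal", group="lower_gi", levels=2)]

    def test_self_nmi_is_one(self):
        t = make_table({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]}, self.VARS)
        assert normalized_mutual_information("a", "a", t) == pytest.approx(1.0)

    def test_independent_outer_product_is_zero(self):
        # contingency [[2,2],[2,2]] = outer product of its margins
        t = make_table({"a": [0, 0, 0, 0, 1, 1, 1, 1],
                        "b": [0, 0, 1, 1, 0, 0, 1, 1]}, self.VARS)
        assert normalized_mutual_information("a", "b", t) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_is_one(self):
        # contingency [[2,0],[0,2]]: I = H = ln 2
        t = make_table({"a": [0, 0, 1, 1], "b": [0, 0, 1, 1]}, self.VARS)
        assert normalized_mutual_information("a", "b", t) == pytest.approx(1.0)

    def test_constant_variable_gives_zero(self):
        t = make_table({"a": [0, 0, 0, 0], "b": [0, 1, 0, 1]}, self.VARS)
        assert normalized_mutual_information("a", "b", t) == 0.0


class TestFitAttributeStats:
    def test_equal_count_marginal(self, flat_cohort):
        n = flat_cohort.n_records
        col = flat_cohort.data.columns[0]
        flat_cohort.data[col] = np.arange(n) % 4
        stats = fit_attribute_stats(flat_cohort, "gi_only")
        assert stats.marginals[col] == pytest.approx([0.25] * 4)

    def test_nmi_diagonal_is_one(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        assert np.diag(stats.nmi.to_numpy()) == pytest.approx(1.0)

    def test_conditional_rows_sum_to_one(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        for tab in list(stats.conditionals.values()) + list(stats.num_conditionals.values()):
            assert tab.sum(axis=1) == pytest.approx(1.0)
            assert (tab > 0).all()  # additive smoothing leaves no zeros

    def test_zero_variance_continuous_named_in_error(self, flat_cohort):
        flat_cohort.data["ghq12"] = 5.0
        with pytest.raises(ValueError, match="ghq12"):
            fit_attribute_stats(flat_cohort, "gi_plus_psych")

    def test_too_few_records_rejected(self, flat_cohort):
        small = flat_cohort.subset_records(flat_cohort.record_ids[:5])
        with pytest.raises(ValueError):
            fit_attribute_stats(small, "gi_only")


def brute_force_ordinal_distance(j, a, b, stats):
    """Independent evaluation of the level-distance formula from the fitted
    tables: intra midpoint-CDF term plus NMI-weighted JSD context terms."""
    fm = stats.midpoint_cdf[j]
    total = abs(fm[a] - fm[b]) ** 2
    contexts = [k for k in stats.ordinal_names + stats.continuous_names if k != j]
    nmi_row = np.array([stats.nmi.loc[j, k] for k in contexts])
    if nmi_row.sum() > 0:
        for k, w in zip(contexts, nmi_row / nmi_row.sum()):
            tab = stats.conditionals.get((j, k), stats.num_conditionals.get((j, k)))
            p, q = tab[a], tab[b]
            m = (p + q) / 2
            ent = lambda v: -sum(x * math.log(x) for x in v if x > 0)
            jsd = ent(m) - (ent(p) + ent(q)) / 2
            total += w * jsd / math.log(2)
    return math.sqrt(total)


class TestOrdinalValueDistance:
    def test_same_level_is_zero(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_only")
        assert ordinal_value_distance("heartburn", 2, 2, stats) == 0.0

    def test_single_attribute_reduces_to_midpoint_distance(self):
        t = make_table({"g": [0, 1, 2, 3, 0, 1, 0, 0, 2, 1]},
                       [Variable(name="g", vtype="ordinal", group="upper_gi", levels=4)])
        stats = fit_attribute_stats(t, "gi_only")
        for a in range(4):
            for b in range(4):
                assert ordinal_value_distance("g", a, b, stats) == pytest.approx(
                    midpoint_cdf_distance("g", a, b, stats))

    def test_matches_brute_force_on_two_attribute_toy(self):
        rng = np.random.default_rng(42)
        t = make_table({"u": rng.integers(0, 3, 20), "v": rng.integers(0, 4, 20)},
                       [Variable(name="u", vtype="ordinal", group="upper_gi", levels=3),
                        Variable(name="v", vtype="ordinal", group="lower_gi", levels=4)])
        stats = fit_attribute_stats(t, "gi_only")
        for a in range(3):
            for b in range(3):
                assert ordinal_value_distance("u", a, b, stats) == pytest.approx(
                    brute_force_ordinal_distance("u", a, b, stats), abs=1e-12)

    def test_matches_brute_force_with_continuous_context(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        for a, b in [(0, 1), (0, 3), (2, 3)]:
            assert ordinal_value_distance("bloating", a, b, stats) == pytest.approx(
                brute_force_ordinal_distance("bloating", a, b, stats), abs=1e-12)


class TestNumericBlock:
    def test_identical_vectors_are_zero(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        x = flat_cohort.data[stats.continuous_names].iloc[0].to_numpy()
        assert numeric_block_distance(x, x, stats) == 0.0

    def test_identity_covariance_gives_euclidean(self):
        stats = AttributeStats(
            feature_set="gi_plus_psych", ordinal_names=[], continuous_names=["a", "b"],
            levels={}, marginals={}, midpoint_cdf={}, conditionals={},
            num_conditionals={}, nmi=pd.DataFrame(), cov=np.eye(2), lam=0.1,
            bins=8, _chol=np.eye(2))
        x, y = np.array([1.0, 2.0]), np.array([4.0, 6.0])
        assert numeric_block_distance(x, y, stats) == pytest.approx(5.0)

    def test_rescaling_one_variable_leaves_distances_unchanged(self, flat_cohort):
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        cont = stats.continuous_names
        x = flat_cohort.data[cont].iloc[3].to_numpy(float)
        y = flat_cohort.data[cont].iloc[17].to_numpy(float)
        before = numeric_block_distance(x, y, stats)

        scaled = flat_cohort.data.copy()
        scaled[cont[0]] = scaled[cont[0]] * 10.0
        schema_vars = []
        for v in flat_cohort.schema.variables:
            if v.name == cont[0]:
                schema_vars.append(Variable(name=v.name, vtype=v.vtype, group=v.group,
                                            vrange=(v.vrange[0], v.vrange[1] * 10)))
            else:
                schema_vars.append(v)
        t2 = CohortTable(scaled, VariableSchema(tuple(schema_vars)))
        stats2 = fit_attribute_stats(t2, "gi_plus_psych")
        x2, y2 = x.copy(), y.copy()
        x2[0] *= 10.0
        y2[0] *= 10.0
        assert numeric_block_distance(x2, y2, stats2) == pytest.approx(before, rel=1e-9)


class TestPairwiseDistances:
    def test_metric_axioms_on_random_cohort(self, flat_cohort):
        D = pairwise_distances(flat_cohort, "gi_plus_psych")
        d = D.d
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        assert np.all(d >= 0) and np.all(np.isfinite(d))

    def test_duplicated_record_has_zero_distance(self, flat_cohort):
        df = flat_cohort.data.copy()
        df.iloc[1] = df.iloc[0]
        t = CohortTable(df, flat_cohort.schema)
        D = pairwise_distances(t, "gi_plus_psych")
        assert D.d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_block_balance_matches_attribute_fractions(self, flat_cohort):
        # reconstruct both blocks and check their mean squared off-diagonal
        # contributions are in a 30:8 ratio after scaling
        from fgidclust.mixed_distance import _value_distance_tables
        from scipy.spatial.distance import cdist
        stats = fit_attribute_stats(flat_cohort, "gi_plus_psych")
        D = pairwise_distances(flat_cohort, "gi_plus_psych", stats=stats)
        n = flat_cohort.n_records
        off = ~np.eye(n, dtype=bool)

        tables = _value_distance_tables(stats)
        a2 = np.zeros((n, n))
        for j in stats.ordinal_names:
            codes = flat_cohort.data[j].to_numpy(np.int64)
            a2 += (tables[j] ** 2)[codes[:, None], codes[None, :]]
        x = flat_cohort.data[stats.continuous_names].to_numpy(float)
        z = np.linalg.solve(stats._chol, x.T).T
        b2 = cdist(z, z, "sqeuclidean")

        s_ord = (30 / 38) / a2[off].mean()
        s_num = (8 / 38) / b2[off].mean()
        combined = s_ord * a2 + s_num * b2
        assert np.allclose(np.sqrt(combined[off]), D.d[off], atol=1e-9)
        assert (s_ord * a2)[off].mean() == pytest.approx(30 / 38, abs=1e-9)
        assert (s_num * b2)[off].mean() == pytest.approx(8 / 38, abs=1e-9)

    def test_gi_only_ignores_psych_columns(self, flat_cohort):
        D1 = pairwise_distances(flat_cohort, "gi_only")
        shuffled = flat_cohort.data.copy()
        rng = np.random.default_rng(0)
        for v in flat_cohort.schema.subset("gi_plus_psych"):
            if v.group == "psych":
                shuffled[v.name] = rng.permutation(shuffled[v.name].to_numpy())
        D2 = pairwise_distances(CohortTable(shuffled, flat_cohort.schema), "gi_only")
        assert np.array_equal(D1.d, D2.d)

    def test_too_few_records_rejected(self, tiny_table):
        small = tiny_table.subset_records(tiny_table.record_ids[:2])
        with pytest.raises(ValueError):
            pairwise_distances(small, "gi_only")


class TestDistanceMatrixInvariants:
    def test_asymmetry_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], d=d)

    def test_nonzero_diagonal_rejected(self):
        d = np.array([[0.5, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="diagonal"):
            DistanceMatrix(ids=["a", "b"], d=d)

    def test_negative_entries_rejected(self):
        d = np.array([[0.0, -1.0], [-1.0, 0.0]])
        with pytest.raises(ValueError):
            DistanceMatrix(ids=["a", "b"], d=d)
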