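"""Preprocessing: receptor parsing, subtype rules, gene filters, scaling,
stratified splitting."""

import math

import numpy as np
import pytest

import sparseae as sa
from sparseae.preprocess import ReceptorStatus, Split


def st(er, pr, her2):
    return ReceptorStatus(er, pr, her2)


class TestSubtypeAssignment:
    @pytest.mark.parametrize(
        "er,pr,her2,expected",
        [
            ("negative", "negative", "negative", "TNBC"),
            ("negative", "negative", "positive", "HER2-enriched"),
            ("negative", "positive", "positive", "HER2-enriched"),
            ("negative", "unknown", "positive", "HER2-enriched"),
            ("positive", "positive", "negative", "LuminalA"),
            ("positive", "positive", "positive", "LuminalB"),
            ("positive", "negative", "positive", "LuminalB"),
            ("positive", "unknown", "positive", "LuminalB"),
            ("positive", "negative", "negative", "LuminalB"),
            ("unknown", "positive", "negative", "unassigned"),
            ("negative", "positive", "negative", "unassigned"),
            ("positive", "unknown", "negative", "unassigned"),
            ("negative", "unknown", "negative", "unassigned"),
        ],
    )
    def test_receptor_rules(self, er, pr, her2, expected):
        assert sa.assign_subtype(st(er, pr, her2)) == expected

    def test_override_table_takes_precedence(self):
        overrides = {("positive", "negative", "negative"): "LuminalA"}
        assert sa.assign_subtype(
            st("positive", "negative", "negative"), overrides
        ) == "LuminalA"

    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("Positive", "positive"),
            ("pos", "positive"),
            ("+", "positive"),
            ("NEGATIVE", "negative"),
            ("neg", "negative"),
            ("-", "negative"),
            ("equivocal", "unknown"),
            (None, "unknown"),
            (float("nan"), "unknown"),
        ],
    )
    def test_receptor_value_parsing(self, raw, expected):
        assert sa.parse_receptor_value(raw) == expected


class TestZeroFilter:
    def test_boundary_is_kept_strictly_greater_removed(self):
        # one gene zero in exactly 3/4 samples (0.75, kept), one in 4/4 (removed)
        values = np.array([[0, 0], [0, 0], [0, 0], [1, 0]], dtype=float)
        X = sa.ExpressionMatrix(values, ["g_kept", "g_gone"], list("abcd"))
        out = sa.filter_zero_genes(X, 0.75)
        assert out.gene_ids == ["g_kept"]

    def test_counts_on_known_zero_fractions(self):
        # zero fractions 0.0, 0.5, 0.76, 0.8, 1.0 over 25 samples -> 2 genes kept
        n = 25
        rng = np.random.default_rng(1)
        fracs = [0.0, 0.5, 0.76, 0.8, 1.0]
        cols = []
        for f in fracs:
            col = rng.uniform(1, 2, n)
            col[: int(round(f * n))] = 0.0
            cols.append(col)
        X = sa.ExpressionMatrix(
            np.column_stack(cols), [f"g{i}" for i in range(5)],
            [f"s{i}" for i in range(n)],
        )
        out = sa.filter_zero_genes(X, 0.75)
        assert out.gene_ids == ["g0", "g1"]

    def test_empty_result_raises_with_threshold(self):
        X = sa.ExpressionMatrix(
            np.zeros((4, 2)), ["g0", "g1"], list("abcd")
        )
        with pytest.raises(ValueError, match="0.75"):
            sa.filter_zero_genes(X)


class TestOutlierFilter:
    def test_population_sd_convention_removes_extreme_gene(self):
        # gene means (0, 0, 0, 100): mu=25, population sd ~43.3 -> 4th removed
        values = np.tile([0.0, 0.0, 0.0, 100.0], (3, 1))
        X = sa.ExpressionMatrix(values, list("abcd"), ["s0", "s1", "s2"])
        out = sa.remove_outlier_genes(X, 1.0)
        assert out.gene_ids == ["a", "b", "c"]

    def test_zero_spread_warns_and_removes_nothing(self):
        X = sa.ExpressionMatrix(
            np.ones((3, 4)), list("abcd"), ["s0", "s1", "s2"]
        )
        with pytest.warns(UserWarning):
            out = sa.remove_outlier_genes(X)
        assert out.gene_ids == list("abcd")

    def test_infinite_band_is_identity(self):
        rng = np.random.default_rng(2)
        X = sa.ExpressionMatrix(
            rng.uniform(0, 50, (5, 8)),
            [f"g{i}" for i in range(8)], [f"s{i}" for i in range(5)],
        )
        assert sa.remove_outlier_genes(X, math.inf).gene_ids == X.gene_ids

    def test_pipeline_order_zero_filter_first(self):
        # gene c is mostly zero with one huge value; while it is present its
        # inflated mean widens the outlier band enough to shelter gene d, so
        # the two filters do not commute. The pipeline order (zero filter
        # first) removes d; the reverse order keeps it.
        values = np.array(
            [
                [4.0, 5.0, 1000.0, 30.0],
                [5.0, 5.0, 0.0, 30.0],
                [6.0, 5.0, 0.0, 30.0],
                [5.0, 5.0, 0.0, 30.0],
                [5.0, 5.0, 0.0, 30.0],
            ]
        )
        X = sa.ExpressionMatrix(values, list("abcd"), [f"s{i}" for i in range(5)])
        ordered = sa.remove_outlier_genes(sa.filter_zero_genes(X))
        reversed_order = sa.filter_zero_genes(sa.remove_outlier_genes(X))
        assert ordered.gene_ids == ["a", "b"]
        assert reversed_order.gene_ids == ["a", "b", "d"]


class TestMinMax:
    def test_midpoint_maps_to_half(self):
        X = sa.ExpressionMatrix(np.array([[2.0], [6.0]]), ["g"], ["a", "b"])
        params = sa.fit_minmax(X)
        q = sa.ExpressionMatrix(np.array([[4.0]]), ["g"], ["q"])
        assert sa.apply_minmax(q, params).values[0, 0] == pytest.approx(0.5)

    def test_constant_gene_maps_to_zero(self):
        X = sa.ExpressionMatrix(
            np.full((3, 1), 5.0), ["g"], ["a", "b", "c"]
        )
        out = sa.apply_minmax(X, sa.fit_minmax(X))
        assert np.all(out.values == 0.0)

    def test_fit_set_in_unit_interval_with_exact_extrema(self, rng):
        X = sa.ExpressionMatrix(
            rng.uniform(0, 100, (20, 10)),
            [f"g{i}" for i in range(10)], [f"s{i}" for i in range(20)],
        )
        out = sa.apply_minmax(X, sa.fit_minmax(X))
        assert out.values.min() >= 0.0 and out.values.max() <= 1.0
        assert np.allclose(out.values.min(axis=0), 0.0)
        assert np.allclose(out.values.max(axis=0), 1.0)

    def test_new_data_may_leave_unit_interval_unclipped(self):
        X = sa.ExpressionMatrix(np.array([[2.0], [6.0]]), ["g"], ["a", "b"])
        params = sa.fit_minmax(X)
        q = sa.ExpressionMatrix(np.array([[10.0]]), ["g"], ["q"])
        assert sa.apply_minmax(q, params).values[0, 0] == pytest.approx(2.0)

    def test_gene_mismatch_raises(self):
        X = sa.ExpressionMatrix(np.array([[2.0], [6.0]]), ["g"], ["a", "b"])
        params = sa.fit_minmax(X)
        other = sa.ExpressionMatrix(np.array([[1.0]]), ["other"], ["q"])
        with pytest.raises((ValueError, KeyError)):
            sa.apply_minmax(other, params)


class TestAlignment:
    def test_filters_commute_with_gene_permutation(self, rng):
        values = rng.uniform(0, 10, (8, 12))
        values[:, 3] = 0.0
        values[:, 7] = 500.0
        genes = [f"g{i:02d}" for i in range(12)]
        X = sa.ExpressionMatrix(values, genes, [f"s{i}" for i in range(8)])
        perm = rng.permutation(12)
        Xp = sa.ExpressionMatrix(
            values[:, perm], [genes[i] for i in perm], X.sample_ids
        )
        for op in (sa.filter_zero_genes, sa.remove_outlier_genes):
            a, b = op(X), op(Xp)
            assert set(a.gene_ids) == set(b.gene_ids)
            for g in a.gene_ids:
                ia, ib = a.gene_ids.index(g), b.gene_ids.index(g)
                np.testing.assert_array_equal(a.values[:, ia], b.values[:, ib])


class TestStratifiedSplit:
    @staticmethod
    def _dataset(counts, seed=3):
        rng = np.random.default_rng(seed)
        sample_ids, labels = [], []
        for c, n in counts.items():
            for i in range(n):
                sample_ids.append(f"{c}_{i}")
                labels.append(c)
        X = sa.ExpressionMatrix(
            rng.uniform(0, 5, (len(sample_ids), 4)),
            [f"g{i}" for i in range(4)], sample_ids,
        )
        return X, sa.SubtypeLabelSet(sample_ids, labels)

    def test_exact_proportional_sizes(self):
        X, y = self._dataset({"TNBC": 40, "HER2-enriched": 30, "LuminalA": 20, "LuminalB": 10})
        split = sa.stratified_split(X, y, 0.8, seed=0)
        assert split.y_train.class_counts == {
            "TNBC": 32, "HER2-enriched": 24, "LuminalA": 16, "LuminalB": 8
        }
        assert split.x_train.n + split.x_test.n == 100

    def test_partition_is_disjoint_and_exhaustive(self):
        X, y = self._dataset({"TNBC": 13, "LuminalA": 29})
        split = sa.stratified_split(X, y, 0.8, seed=5)
        train, test = set(split.x_train.sample_ids), set(split.x_test.sample_ids)
        assert train.isdisjoint(test)
        assert train | test == set(X.sample_ids)

    def test_per_class_proportion_within_one_sample(self):
        X, y = self._dataset({"TNBC": 7, "HER2-enriched": 11, "LuminalA": 23, "LuminalB": 5})
        split = sa.stratified_split(X, y, 0.8, seed=1)
        for c, n_v in y.class_counts.items():
            train_v = split.y_train.class_counts.get(c, 0)
            assert abs(train_v / n_v - 0.8) <= 1.0 / n_v

    def test_same_seed_reproduces_partition(self):
        X, y = self._dataset({"TNBC": 9, "LuminalB": 17})
        s1 = sa.stratified_split(X, y, 0.8, seed=42)
        s2 = sa.stratified_split(X, y, 0.8, seed=42)
        assert s1.x_train.sample_ids == s2.x_train.sample_ids
        assert s1.x_test.sample_ids == s2.x_test.sample_ids

    def test_degenerate_fractions_raise(self):
        X, y = self._dataset({"TNBC": 4, "LuminalA": 4})
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                sa.stratified_split(X, y, frac, seed=0)

    def test_too_small_class_raises(self):
        X, y = self._dataset({"TNBC": 1, "LuminalA": 6})
        with pytest.raises(ValueError, match="TNBC"):
            sa.stratified_split(X, y, 0.8, seed=0)


class TestPreprocessEndToEnd:
    def test_class_matrices_are_scaled_and_partition_samples(self, default_sim):
        X, labels, _truth = default_sim
        class_mats, scaler, report = sa.preprocess(X, labels)
        assert set(class_mats) == set(sa.SUBTYPES)
        total = sum(m.n for m in class_mats.values())
        assert total == labels.n_assigned
        for mat in class_mats.values():
            assert mat.values.min() >= 0.0 and mat.values.max() <= 1.0
        assert report.stages["zero_filter"]["n_genes"] >= report.stages["outlier_filter"]["n_genes"]
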