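import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from hormscreen.assoc import (
    MEASURES,
    benjamini_hochberg,
    drug_correlations,
    expression_association,
    group_scalar_test,
    mutation_association,
    robustness_filter,
    subtype_association,
)
from hormscreen.features import CollinearGroup


def make_group(samples, mutants, genes=("GENEA",), hyper_only=False, large=False):
    pattern = tuple(1 if s in mutants else 0 for s in samples)
    return CollinearGroup(
        group_id="MG001",
        samples=tuple(samples),
        pattern=pattern,
        genes=tuple(genes),
        hypermutant_only=hyper_only,
        large_group=large,
        n_mutant_samples=sum(pattern),
    )


def make_measures(values: dict[str, list[float]], samples) -> pd.DataFrame:
    df = pd.DataFrame(values, index=pd.Index(samples, name="sample"))
    for m in MEASURES:
        if m not in df:
            df[m] = df[MEASURES[0]]
    return df


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_hand_computed_mixed(self):
        # m=4: p=(0.005, 0.04, 0.03, 0.9) -> sorted (0.005,0.03,0.04,0.9)
        # adj sorted: min-cascade of (0.02, 0.06, 0.04->0.06? ) compute:
        # raw*m/rank = 0.02, 0.06, 0.0533.., 0.9 -> cummin from right: 0.02, 0.0533.., 0.0533.., 0.9
        out = benjamini_hochberg([0.005, 0.04, 0.03, 0.9])
        np.testing.assert_allclose(out, [0.02, 0.16 / 3, 0.16 / 3, 0.9])

    def test_empty(self):
        assert benjamini_hochberg([]).size == 0

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_properties(self, p):
        adj = benjamini_hochberg(p)
        assert (adj >= np.asarray(p) - 1e-15).all()
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_matches_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)


class TestMutationAssociation:
    def setup_method(self):
        self.samples = [f"S{i}" for i in range(8)]

    def test_identical_distributions_not_significant(self):
        # mutant and wild-type measure values are identical multisets
        vals = [1.0, 2.0, 3.0, 4.0, 1.0, 2.0, 3.0, 4.0]
        measures = make_measures({"auc_trap": vals}, self.samples)
        group = make_group(self.samples, mutants=self.samples[:4])
        records, skipped = mutation_association(measures, [group])
        assert not skipped
        for rec in records:
            assert rec.statistic == pytest.approx(0.0)
            assert rec.p == pytest.approx(1.0)
            assert not rec.significant

    def test_direction_sensitizing(self):
        vals = [1.0, 1.1, 0.9, 1.0, 5.0, 5.2, 4.9, 5.1]
        measures = make_measures({"auc_trap": vals}, self.samples)
        group = make_group(self.samples, mutants=self.samples[:4])
        records, _ = mutation_association(measures, [group])
        assert all(r.direction == "sensitizing" for r in records)

    def test_small_groups_skipped(self):
        measures = make_measures({"auc_trap": [1.0] * 8}, self.samples)
        group = make_group(self.samples, mutants=self.samples[:1])
        records, skipped = mutation_association(measures, [group])
        assert records == [] and skipped == ["GENEA"]

    def test_missing_measure_errors(self):
        df = pd.DataFrame({"auc_trap": [1.0] * 8}, index=self.samples)
        with pytest.raises(ValueError, match="lacks columns"):
            mutation_association(df, [])

    def test_flags_propagate_to_records(self):
        vals = list(range(8))
        measures = make_measures({"auc_trap": [float(v) for v in vals]}, self.samples)
        group = make_group(self.samples, mutants=self.samples[:4], hyper_only=True, large=True)
        records, _ = mutation_association(measures, [group])
        assert all(r.hypermutant_only and r.large_group for r in records)

    def test_bh_is_per_measure_across_groups(self, rng):
        vals = rng.normal(size=8)
        measures = make_measures({"auc_trap": list(vals)}, self.samples)
        groups = [
            make_group(self.samples, mutants=self.samples[i : i + 4], genes=(f"G{i}",))
            for i in range(3)
        ]
        records, _ = mutation_association(measures, groups)
        for measure in MEASURES:
            recs = [r for r in records if r.measure == measure]
            expected = benjamini_hochberg([r.p for r in recs])
            np.testing.assert_allclose([r.p_adj for r in recs], expected)


class TestExpressionAssociation:
    def setup_method(self):
        self.samples = [f"S{i}" for i in range(10)]
        self.measures = make_measures(
            {"auc_trap": list(np.linspace(1, 5, 10))}, self.samples
        )

    def test_self_correlation(self):
        expr = pd.DataFrame(
            [self.measures["auc_trap"].to_numpy()], index=["SELF"], columns=self.samples
        )
        records, skipped = expression_association(self.measures, expr)
        rec = [r for r in records if r.measure == "auc_trap"][0]
        assert rec.statistic == pytest.approx(1.0)
        assert rec.significant and not skipped

    def test_constant_gene_skipped(self):
        expr = pd.DataFrame(
            [[1.0] * 10, self.measures["auc_trap"].to_numpy()],
            index=["CONST", "SELF"],
            columns=self.samples,
        )
        records, skipped = expression_association(self.measures, expr)
        assert skipped == ["CONST"]
        assert {r.feature_id for r in records} == {"SELF"}

    def test_too_few_samples_errors(self):
        expr = pd.DataFrame([[1.0, 2.0]], index=["G"], columns=["S0", "S1"])
        with pytest.raises(ValueError, match=">= 3"):
            expression_association(self.measures.iloc[:2], expr)

    def test_inclusive_threshold(self):
        # construct a gene with |r| exactly ~0.5 is fp-fragile; check semantics
        # via the cutoff parameter instead
        expr = pd.DataFrame(
            [self.measures["auc_trap"].to_numpy()], index=["SELF"], columns=self.samples
        )
        records, _ = expression_association(self.measures, expr, r_cutoff=1.0)
        assert all(r.significant for r in records if r.measure == "auc_trap")


class TestRobustnessFilter:
    def _records(self, n_sig):
        from hormscreen.assoc import AssociationRecord

        return [
            AssociationRecord(
                feature_id="F",
                feature_kind="mutation_group",
                measure=m,
                direction="sensitizing",
                statistic=1.0,
                p=0.01,
                p_adj=0.02,
                significant=(i < n_sig),
                hypermutant_only=True,
                large_group=False,
            )
            for i, m in enumerate(MEASURES)
        ]

    def test_two_retained(self):
        robust = robustness_filter(self._records(2))
        assert len(robust) == 1 and robust[0].n_significant_measures == 2

    def test_one_dropped(self):
        assert robustness_filter(self._records(1)) == []

    def test_four_retained(self):
        robust = robustness_filter(self._records(4))
        assert robust[0].n_significant_measures == 4

    def test_flags_propagate(self):
        robust = robustness_filter(self._records(3))
        assert robust[0].hypermutant_only and not robust[0].large_group


class TestGroupScalarTest:
    def test_identical_groups_p_one(self):
        values = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        labels = ["a", "a", "a", "b", "b", "b"]
        t, p = group_scalar_test(values, labels)
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_t_squared_equals_anova_f(self, rng):
        values = rng.normal(size=12)
        labels = ["a"] * 5 + ["b"] * 7
        t, _ = group_scalar_test(values, labels, equal_var=True)
        f, _ = stats.f_oneway(values[:5], values[5:])
        assert t**2 == pytest.approx(f, rel=1e-10)

    def test_degenerate_group_errors(self):
        with pytest.raises(ValueError):
            group_scalar_test([1.0, 2.0, 3.0], ["a", "b", "b"])

    def test_permutation_null_uniform(self, rng):
        values = rng.normal(size=20)
        pvals = []
        for _ in range(500):
            labels = rng.permutation(["a"] * 10 + ["b"] * 10)
            _, p = group_scalar_test(values, labels)
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSubtypeAssociation:
    def test_equal_groups_f_zero(self):
        values = [1.0, 2.0, 3.0] * 3
        labels = ["x"] * 3 + ["y"] * 3 + ["z"] * 3
        f, p = subtype_association(values, labels)
        assert f == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_power_with_shifted_level(self, rng):
        hits = 0
        for _ in range(100):
            values = np.concatenate([rng.normal(0, 1, 6), rng.normal(5, 1, 6)])
            labels = ["x"] * 6 + ["y"] * 6
            _, p = subtype_association(values, labels)
            hits += p < 0.01
        assert hits >= 95

    def test_two_level_f_equals_t_squared(self, rng):
        values = rng.normal(size=10)
        labels = ["x"] * 4 + ["y"] * 6
        f, _ = subtype_association(values, labels)
        t, _ = group_scalar_test(values, labels, equal_var=True)
        assert f == pytest.approx(t**2, rel=1e-10)

    def test_small_levels_merged_with_warning(self):
        values = [1.0, 2.0, 3.0, 4.0, 1.5, 2.5, 9.0]
        labels = ["x", "x", "x", "x", "y", "y", "z"]
        with pytest.warns(UserWarning, match="other"):
            subtype_association(values, labels)

    def test_single_level_errors(self):
        with pytest.raises(ValueError):
            subtype_association([1.0, 2.0, 3.0], ["x", "x", "x"])


class TestDrugCorrelations:
    def make_panel(self, rng, n=12, d=5):
        data = rng.normal(4, 1, size=(n, d))
        cols = ["FOCAL"] + [f"D{j}" for j in range(1, d)]
        return pd.DataFrame(data, index=[f"S{i}" for i in range(n)], columns=cols)

    def test_duplicated_column_r_one(self, rng):
        panel = self.make_panel(rng)
        panel["COPY"] = panel["FOCAL"]
        corr, ranked = drug_correlations(panel, focal="FOCAL")
        assert corr.loc["FOCAL", "COPY"] == pytest.approx(1.0)
        assert ranked.index[0] == "COPY"

    def test_symmetric_unit_diagonal(self, rng):
        panel = self.make_panel(rng)
        corr, _ = drug_correlations(panel, focal="FOCAL")
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr.to_numpy()), 1.0)

    def test_pairwise_complete_oracle(self, rng):
        panel = self.make_panel(rng, n=15)
        mask = rng.random(panel.shape) < 0.2
        panel = panel.mask(mask)
        corr, _ = drug_correlations(panel, focal="FOCAL", min_pairs=3)
        for a in panel.columns:
            for b in panel.columns:
                both = panel[[a, b]].dropna()
                if a == b:
                    expected = 1.0
                elif len(both) < 3 or both[a].std() == 0 or both[b].std() == 0:
                    expected = np.nan
                else:
                    expected = stats.pearsonr(both[a], both[b]).statistic
                got = corr.loc[a, b]
                if np.isnan(expected):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(expected, abs=1e-12)

    def test_min_pairs_gives_na(self, rng):
        panel = self.make_panel(rng, n=4)
        panel.iloc[0:2, 1] = np.nan  # only 2 complete pairs against column 1
        corr, _ = drug_correlations(panel, focal="FOCAL", min_pairs=3)
        assert np.isnan(corr.loc["FOCAL", panel.columns[1]])

    def test_missing_focal_errors(self, rng):
        panel = self.make_panel(rng)
        with pytest.raises(ValueError, match="NOPE"):
            drug_correlations(panel, focal="NOPE")

    def test_ranking_descending(self, rng):
        panel = self.make_panel(rng)
        _, ranked = drug_correlations(panel, focal="FOCAL")
        vals = ranked.dropna().to_numpy()
        assert (np.diff(vals) <= 1e-12).all()
        assert "FOCAL" not in ranked.index


class TestSampleOrderInvariance:
    def test_mutation_association_invariant(self, rng):
        samples = [f"S{i}" for i in range(10)]
        measures = make_measures({"auc_trap": list(rng.normal(size=10))}, samples)
        group = make_group(samples, mutants=samples[:4])
        r1, _ = mutation_association(measures, [group])
        shuffled = measures.sample(frac=1, random_state=1)
        r2, _ = mutation_association(shuffled, [group])
        for a, b in zip(r1, r2):
            assert a.statistic == pytest.approx(b.statistic, rel=1e-12)
            assert a.p == pytest.approx(b.p, rel=1e-12)
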