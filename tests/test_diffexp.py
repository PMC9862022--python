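import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import brcaprog as bp
from brcaprog.synthetic_data import DEFAULT_RECEPTOR_SPEC


def bh_stepup_oracle(p):
    """Independent step-up implementation for cross-checking."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * m / rank)
        adj[i] = running_min
    return adj


class TestWelch:
    def test_identical_groups_give_null_result(self):
        t, df, p = bp.welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (t, p) == (0.0, 1.0)

    def test_hand_evaluated_formula(self):
        a, b = np.array([0.0, 1.0, 2.0]), np.array([3.0, 4.0, 5.0])
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_hand = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_hand = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        t, df, p = bp.welch_t(a, b)
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert df == pytest.approx(df_hand, abs=1e-10)

    def test_swapping_groups_negates_t_preserves_p(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 2, 15)
        t1, _, p1 = bp.welch_t(a, b)
        t2, _, p2 = bp.welch_t(b, a)
        assert t1 == pytest.approx(-t2, abs=1e-12)
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestSummaryT:
    def test_cohort_age_comparison_is_highly_significant(self):
        t, df, p = bp.t_from_summary(54.3, 11.7, 200, 63.7, 14.5, 101)
        assert p < 0.0001

    def test_equal_summaries(self):
        assert bp.t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)[::2] == (0.0, 1.0)

    def test_agrees_with_welch_on_moment_matched_data(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1.5, 9)
        t1, df1, p1 = bp.welch_t(a, b)
        t2, df2, p2 = bp.t_from_summary(
            a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
        )
        assert (t1, df1, p1) == pytest.approx((t2, df2, p2), abs=1e-10)


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bp.bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_calculation(self):
        q = bp.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_matches_independent_stepup_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            assert bp.bh_adjust(p) == pytest.approx(bh_stepup_oracle(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_adjusted_dominates_raw_and_is_monotone(self, pvals):
        p = np.array(pvals)
        q = bp.bh_adjust(p)
        assert (np.sort(q) >= np.sort(p) - 1e-12).all()
        assert (q >= 0).all() and (q <= 1).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bp.bh_adjust([0.5, 1.5])


def _matrix_from_groups(vals_a, vals_b, gene="G"):
    n_a, n_b = len(vals_a), len(vals_b)
    cols = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    values = pd.DataFrame(
        [list(vals_a) + list(vals_b)], index=pd.Index([gene], name="gene"),
        columns=cols,
    )
    return bp.ExpressionMatrix(values=values), cols[:n_a], cols[n_b:]


class TestDifferentialExpression:
    def test_unit_fold_change_is_ns_despite_significance(self):
        """Shift below the doubling threshold cannot be called over."""
        rng = np.random.default_rng(0)
        a = 100.0 + rng.normal(0, 0.5, 30)
        b = 110.0 + rng.normal(0, 0.5, 30)  # FC 1.1, tiny p
        expr, ga, gb = _matrix_from_groups(a, b)
        de = bp.differential_expression(expr, ga, gb)
        assert de.loc["G", "q"] < 0.05
        assert de.loc["G", "volcano_class"] == "ns"

    def test_halving_with_significance_is_under(self):
        rng = np.random.default_rng(1)
        a = 100.0 * np.exp(rng.normal(0, 0.05, 30))
        b = 40.0 * np.exp(rng.normal(0, 0.05, 30))  # FC 0.4
        expr, ga, gb = _matrix_from_groups(a, b)
        de = bp.differential_expression(expr, ga, gb)
        assert de.loc["G", "volcano_class"] == "under"
        assert de.loc["G", "log2fc"] == pytest.approx(np.log2(0.4), abs=0.05)

    def test_constant_gene_is_ns_with_p_one(self):
        expr, ga, gb = _matrix_from_groups([5.0] * 5, [5.0] * 5)
        de = bp.differential_expression(expr, ga, gb)
        assert de.loc["G", "p"] == 1.0
        assert de.loc["G", "volcano_class"] == "ns"

    def test_q_dominates_p(self, small_cohort):
        expr, _, truth = small_cohort
        arm = truth.arm
        de = bp.differential_expression(
            expr, list(arm.index[arm == "Normal"]), list(arm.index[arm == "PP"])
        )
        assert (de["q"] >= de["p"] - 1e-12).all()
        assert de["q"].between(0, 1).all()

    def test_planted_overexpression_detected_across_seeds(self):
        """A +2 log2 planted effect at n=50/50 is classed over >= 95%."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.normal(1.5, 0.1)
            a = 10 ** (base + 0.3 * rng.standard_normal(50))
            b = 10 ** (base + 2 * np.log10(2) + 0.3 * rng.standard_normal(50))
            expr, ga, gb = _matrix_from_groups(a, b)
            de = bp.differential_expression(expr, ga, gb)
            hits += de.loc["G", "volcano_class"] == "over"
        assert hits >= 10 * 0.95

    def test_null_simulation_yields_no_discoveries(self):
        """Empty planted sets: BH leaves non-receptor genes unflagged."""
        receptor = set(DEFAULT_RECEPTOR_SPEC)
        for seed in range(3):
            cfg = bp.CohortConfig(
                n_normal=50, n_gp=50, n_pp=50, n_genes=500,
                de_spec=bp.DESpec(), hazard_spec=[],
            )
            expr, _, truth = bp.simulate_cohort(cfg, seed=seed)
            arm = truth.arm
            de = bp.differential_expression(
                expr, list(arm.index[arm == "Normal"]),
                list(arm.index[arm == "PP"]),
            )
            null = de.drop(index=[g for g in receptor if g in de.index])
            assert (null["q"] < 0.05).sum() <= 1


class TestSelection:
    def _de_frame(self, classes):
        return pd.DataFrame(
            {"volcano_class": pd.Series(classes)},
            index=pd.Index(list(classes), name="gene"),
        )

    def test_set_algebra_example(self):
        de_pp = self._de_frame({"a": "over", "b": "over", "c": "over", "d": "ns"})
        de_gp = self._de_frame({"a": "ns", "b": "over", "c": "ns", "d": "ns"})
        sel = bp.select_group_specific(de_pp, de_gp)
        assert sel.pp_only_over == {"a", "c"}
        assert sel.shared_over == {"b"}
        assert sel.gp_only_over == set()

    def test_identical_inputs_leave_only_shared(self):
        de = self._de_frame({"a": "over", "b": "under", "c": "ns"})
        sel = bp.select_group_specific(de, de.copy())
        assert sel.pp_only_over == sel.gp_only_under == frozenset()
        assert sel.shared_over == {"a"} and sel.shared_under == {"b"}

    def test_mismatched_universes_rejected(self):
        de1 = self._de_frame({"a": "over"})
        de2 = self._de_frame({"b": "over"})
        with pytest.raises(ValueError, match="universe"):
            bp.select_group_specific(de1, de2)

    def test_selection_partitions_significant_sets(self, small_cohort):
        expr, _, truth = small_cohort
        arm = truth.arm
        n = list(arm.index[arm == "Normal"])
        de_pp = bp.differential_expression(expr, n, list(arm.index[arm == "PP"]))
        de_gp = bp.differential_expression(expr, n, list(arm.index[arm == "GP"]))
        sel = bp.select_group_specific(de_pp, de_gp)
        pp_over = set(de_pp.index[de_pp["volcano_class"] == "over"])
        assert sel.pp_only_over | sel.shared_over == pp_over
        assert not sel.pp_only_over & sel.shared_over


class TestPCA:
    def test_collinear_samples_put_all_variance_on_pc1(self):
        t = np.linspace(0, 1, 8)
        values = pd.DataFrame(
            [2 ** (1 + t) - 1, 2 ** (2 + 2 * t) - 1, 2 ** (3 * t) - 1],
            index=pd.Index(["G1", "G2", "G3"], name="gene"),
            columns=[f"S{i}" for i in range(8)],
        )
        expr = bp.ExpressionMatrix(values=values)
        _, explained = bp.pca2(expr, ["G1", "G2", "G3"], standardize=False)
        assert explained[0] == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_covariance_eigendecomposition(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(
            rng.uniform(0, 50, size=(10, 20)),
            index=pd.Index([f"G{i}" for i in range(10)], name="gene"),
            columns=[f"S{i}" for i in range(20)],
        )
        expr = bp.ExpressionMatrix(values=values)
        scores, explained = bp.pca2(expr, list(values.index), standardize=False)
        X = np.log2(values.to_numpy().T + 1)
        X = X - X.mean(axis=0)
        cov = X.T @ X / (X.shape[0] - 1)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        var = scores.var(ddof=1).to_numpy()
        assert var == pytest.approx(evals[:2], abs=1e-8)
        assert explained[:2] == pytest.approx(evals[:2] / evals.sum(), abs=1e-8)

    def test_signature_genes_separate_tumor_from_normal(self, small_cohort):
        """Normal/tumor centroid distance exceeds within-group spread."""
        expr, _, truth = small_cohort
        arm = truth.arm
        sig = sorted(truth.de_sets.all_genes())
        scores, _ = bp.pca2(expr, sig)
        pts = scores.to_numpy()
        is_norm = (arm == "Normal").to_numpy()
        c_norm, c_tum = pts[is_norm].mean(0), pts[~is_norm].mean(0)
        spread = max(
            np.linalg.norm(pts[is_norm] - c_norm, axis=1).mean(),
            np.linalg.norm(pts[~is_norm] - c_tum, axis=1).mean(),
        )
        assert np.linalg.norm(c_norm - c_tum) > spread

    def test_too_few_genes_rejected(self, tiny_matrix):
        with pytest.raises(ValueError):
            bp.pca2(tiny_matrix, ["GA"])
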