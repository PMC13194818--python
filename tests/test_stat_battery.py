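import numpy as np
import pytest
from scipy import stats

from _oracles import anova_icc_oracle, brute_force_friedman
from varqa.stat_battery import (
    PairedScoreMatrix,
    UndefinedStatisticError,
    abs_diff_summary,
    agreement_report,
    bootstrap_ci,
    compare_systems,
    friedman_w,
    holm_adjust,
    icc_2_2,
    weighted_kappa,
    wilcoxon_holm,
)


def matrix(values, systems=None):
    arr = np.asarray(values, dtype=float)
    systems = systems or tuple(f"S{i}" for i in range(arr.shape[1]))
    return PairedScoreMatrix(arr, tuple(systems))


class TestPairedScoreMatrix:
    def test_shape_validation(self):
        with pytest.raises(ValueError):
            matrix([[1, 2]])  # n < 2
        with pytest.raises(ValueError):
            PairedScoreMatrix(np.ones((3, 2)), ("A",))

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            matrix([[1, np.nan], [2, 3]])


class TestBootstrapCi:
    def test_constant_sequence_degenerate(self):
        assert bootstrap_ci([7, 7, 7, 7], seed=0) == (7.0, 7.0)

    def test_two_point_interval_contains_five(self):
        # resample means of (0, 10) are 0, 5, 10 with binomial weights
        # (1/4, 1/2, 1/4); the central 95% therefore spans all three values
        low, high = bootstrap_ci([0, 10], reps=10_000, seed=1)
        assert low <= 5 <= high
        assert (low, high) == (0.0, 10.0)

    def test_same_seed_identical(self):
        a = bootstrap_ci(np.arange(20), seed=3)
        b = bootstrap_ci(np.arange(20), seed=3)
        assert a == b

    def test_level_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1, 2], level=1.0)
        with pytest.raises(ValueError):
            bootstrap_ci([])

    def test_width_shrinks_with_n(self):
        rng = np.random.default_rng(0)
        widths = []
        for n in (20, 200, 2000):
            vals = rng.normal(size=n)
            low, high = bootstrap_ci(vals, reps=2000, seed=5)
            widths.append(high - low)
        assert widths[0] > widths[1] > widths[2]


class TestFriedmanW:
    def test_perfect_concordance_w_is_one(self):
        x = [[10, 5, 1], [9, 6, 2], [8, 4, 0], [10, 7, 3]]
        chi2, p, w = friedman_w(matrix(x))
        assert w == pytest.approx(1.0)
        assert chi2 == pytest.approx(len(x) * 2)

    def test_identity_chi2_equals_nkw(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 11, size=(12, 4)).astype(float)
        chi2, _, w = friedman_w(matrix(x))
        n, k = x.shape
        assert chi2 == pytest.approx(n * (k - 1) * w, abs=1e-12)

    def test_shuffled_ranks_w_near_zero(self):
        rng = np.random.default_rng(3)
        x = np.array([rng.permutation([1.0, 2.0, 3.0]) for _ in range(500)])
        _, _, w = friedman_w(matrix(x))
        assert w < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_rank_definition_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 11, size=(4, 3)).astype(float)
        if np.all(np.ptp(x, axis=1) == 0):
            return
        chi2, _, _ = friedman_w(matrix(x))
        assert chi2 == pytest.approx(brute_force_friedman(x), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy(self, seed):
        rng = np.random.default_rng(seed + 100)
        x = rng.normal(size=(15, 3))
        chi2, p, _ = friedman_w(matrix(x))
        ref = stats.friedmanchisquare(*[x[:, j] for j in range(3)])
        assert chi2 == pytest.approx(ref.statistic, abs=1e-10)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_all_constant_rows_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            friedman_w(matrix([[5, 5, 5], [3, 3, 3]]))


class TestHolm:
    def test_family_of_one_identity(self):
        assert holm_adjust([0.037]) == [0.037]

    def test_hand_stepdown(self):
        # sorted: .01 -> 3*.01=.03; .03 -> max(.03, 2*.03)=.06; .04 -> max(.06, .04)=.06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(4)
        raw = rng.uniform(size=10)
        adj = np.asarray(holm_adjust(raw))
        assert np.all(adj >= raw)
        order = np.argsort(raw)
        assert np.all(np.diff(np.asarray(adj)[order]) >= -1e-12)

    def test_capped_at_one(self):
        assert max(holm_adjust([0.9, 0.8, 0.7])) <= 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        raw = rng.uniform(size=6)
        _, ref, _, _ = multipletests(raw, method="holm")
        assert holm_adjust(raw) == pytest.approx(ref, abs=1e-12)


class TestWilcoxonHolm:
    def test_all_pairs_present(self):
        rng = np.random.default_rng(6)
        x = rng.integers(0, 51, size=(10, 3)).astype(float)
        results = wilcoxon_holm(matrix(x, systems=("A", "B", "C")))
        assert [r.pair for r in results] == [("A", "B"), ("A", "C"), ("B", "C")]

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(20, 4))
        for r in wilcoxon_holm(matrix(x)):
            assert r.p_adjusted >= r.p_raw

    def test_degenerate_pair_flagged(self):
        x = np.column_stack([np.arange(5.0), np.arange(5.0)])
        results = wilcoxon_holm(matrix(x))
        assert results[0].degenerate
        assert results[0].p_raw == 1.0

    def test_median_paired_difference(self):
        x = np.array([[5.0, 1.0], [7.0, 2.0], [9.0, 2.0]])
        results = wilcoxon_holm(matrix(x))
        assert results[0].median_diff == 5.0

    def test_exact_p_small_sample(self):
        # n=6 strictly positive differences: one-sided exact p = 1/64,
        # two-sided = 1/32
        x = np.column_stack([np.arange(6.0) + np.array([1, 2, 3, 2, 1, 4]), np.arange(6.0)])
        results = wilcoxon_holm(matrix(x))
        assert results[0].p_raw == pytest.approx(2 / 64)

    def test_pratt_rule_available(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 5, size=(12, 2)).astype(float)
        if np.all(x[:, 0] == x[:, 1]):
            return
        res = wilcoxon_holm(matrix(x), zero_method="pratt")
        assert 0 <= res[0].p_raw <= 1


class TestIcc:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0) * 3 + 5] * 2)
        assert icc_2_2(x) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_anova_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(30, 5, size=(8, 1)) + rng.normal(0, 2, size=(8, 2))
        assert icc_2_2(x) == pytest.approx(anova_icc_oracle(x), abs=1e-10)

    def test_matches_pingouin(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        x = rng.normal(30, 5, size=(15, 1)) + rng.normal(0, 2, size=(15, 2))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(15), 2),
                "raters": np.tile([0, 1], 15),
                "scores": x.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        # two-way random effects, absolute agreement, average measures
        ref_icc = float(ref.loc[ref["Type"].isin(["ICC2k", "ICC(A,k)"]), "ICC"].iloc[0])
        assert icc_2_2(x) == pytest.approx(ref_icc, abs=1e-10)

    def test_zero_between_question_variance_undefined(self):
        x = np.full((5, 2), 7.0)
        with pytest.raises(UndefinedStatisticError):
            icc_2_2(x)

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            icc_2_2(np.ones((5, 3)))
        with pytest.raises(ValueError):
            icc_2_2(np.ones((2, 2)))

    def test_can_be_negative(self):
        x = np.array(
            [
                [3.18, 5.97], [7.42, 4.74], [7.94, -1.15], [4.45, 7.09],
                [0.28, 5.38], [7.70, 5.18], [-0.78, 2.10], [8.35, 5.55],
                [6.33, 7.68], [7.17, 2.88],
            ]
        )
        assert -1 < icc_2_2(x) < 0
        assert icc_2_2(x) == pytest.approx(anova_icc_oracle(x), abs=1e-10)


class TestWeightedKappa:
    def test_identical_raters_give_one(self):
        assert weighted_kappa([0, 10, 25, 50], [0, 10, 25, 50]) == pytest.approx(1.0)

    def test_hand_computed_three_category_table(self):
        # K=3, r1=[0,1,2,1,0,2], r2=[0,2,2,0,1,2]: po - pe over 1 - pe
        # works out to exactly 2/3 (verified against the definition and
        # an independent quadratic-kappa implementation)
        k = weighted_kappa([0, 1, 2, 1, 0, 2], [0, 2, 2, 0, 1, 2], n_categories=3)
        assert k == pytest.approx(2 / 3, abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        r1 = rng.integers(0, 51, size=100)
        noise = rng.integers(-5, 6, size=100)
        r2 = np.clip(r1 + noise, 0, 50)
        ref = cohen_kappa_score(r1, r2, weights="quadratic", labels=np.arange(51))
        assert weighted_kappa(r1, r2) == pytest.approx(ref, abs=1e-12)

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(10)
        r1 = rng.integers(0, 51, size=2000)
        r2 = rng.integers(0, 51, size=2000)
        assert abs(weighted_kappa(r1, r2)) < 0.05

    def test_single_category_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            weighted_kappa([5, 5, 5], [5, 5, 5])

    def test_relabeling_raters_invariant(self):
        rng = np.random.default_rng(11)
        r1 = rng.integers(0, 51, size=50)
        r2 = rng.integers(0, 51, size=50)
        assert weighted_kappa(r1, r2) == pytest.approx(weighted_kappa(r2, r1), abs=1e-12)

    def test_non_integral_rejected(self):
        with pytest.raises(ValueError):
            weighted_kappa([1.5, 2], [1, 2])


class TestAbsDiffSummary:
    def test_identical(self):
        assert abs_diff_summary([4, 5], [4, 5]) == (0.0, 0.0, 0.0)

    def test_worked_values(self):
        assert abs_diff_summary([10, 20], [12, 16]) == (3.0, 3.0, 4.0)

    def test_symmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.integers(0, 51, size=(2, 30))
        assert abs_diff_summary(a, b) == abs_diff_summary(b, a)


@pytest.fixture(scope="module")
def sim_table():
    from varqa.synthetic_data import ScoreSimulationConfig, simulate_scores

    cfg = ScoreSimulationConfig(
        n_questions=40,
        systems={"A": 8.0, "B": 5.0, "C": 3.0},
        rater_noise_sd=1.0,
        between_question_sd=1.0,
        seed=21,
    )
    return simulate_scores(cfg)


class TestReports:
    def test_compare_by_criterion_blocks(self, sim_table):
        reports = compare_systems(sim_table, by="criterion", reps=500, seed=0)
        assert [r.block for r in reports][0] == "total"
        assert len(reports) == 6
        for r in reports:
            for s in r.systems:
                assert r.ci_low[s] <= r.means[s] <= r.ci_high[s]
            assert 0 <= r.kendall_w <= 1
            assert r.friedman_chi2 == pytest.approx(
                r.n_questions * (len(r.systems) - 1) * r.kendall_w
            )

    def test_compare_by_category(self, sim_table):
        cats = {f"sim{i + 1}": ("even" if i % 2 else "odd") for i in range(40)}
        reports = compare_systems(sim_table, by="category", categories=cats, reps=200, seed=0)
        assert {r.block for r in reports} == {"even", "odd"}

    def test_agreement_report_fields(self, sim_table):
        rep = agreement_report(sim_table)
        assert rep.n == 120  # 40 questions x 3 systems
        assert rep.icc_2_2 <= 1
        assert rep.quadratic_weighted_kappa <= 1
        assert rep.abs_diff_median <= rep.abs_diff_max
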