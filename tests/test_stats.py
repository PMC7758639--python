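"""Statistics: percent changes, t-tests, Hotelling T², sphericity and the
2x4 mixed ANOVA against brute-force oracles and pingouin cross-checks."""

import numpy as np
import pytest

from isletscope.isletquant import PancreasResult
from isletscope.stats import (
    GroupDesign,
    hotelling_two_sample,
    mauchly_and_epsilon,
    mixed_anova_2x4,
    percent_increase,
    sem,
    study_report,
    unpaired_t,
)


class TestPercentIncrease:
    def test_printed_islet_count_means(self):
        # group means 7962 -> 9631 round to the reported 21%
        assert round(percent_increase(7962, 9631)) == 21

    def test_printed_medium_bin_counts(self):
        # 2300 -> 3458 is the reported 50.3%
        assert round(percent_increase(2300, 3458), 1) == 50.3

    def test_no_change_is_zero(self):
        assert percent_increase(123.4, 123.4) == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_increase(0.0, 5.0)


class TestUnpairedT:
    def test_identical_groups(self):
        r = unpaired_t([1, 2, 3], [1, 2, 3])
        assert r.t == 0.0 and r.p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=7), rng.normal(1, 1, size=7)
        r1, r2 = unpaired_t(a, b), unpaired_t(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_df_for_seven_per_group(self):
        rng = np.random.default_rng(1)
        r = unpaired_t(rng.normal(size=7), rng.normal(size=7))
        assert r.df == 12

    def test_matches_scipy_pooled(self):
        from scipy import stats as sps

        rng = np.random.default_rng(2)
        a, b = rng.normal(size=6), rng.normal(0.8, 1.2, size=9)
        mine = unpaired_t(a, b)
        ref = sps.ttest_ind(a, b, equal_var=True)
        assert mine.t == pytest.approx(ref.statistic, rel=1e-12)
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            unpaired_t([1, 1, 1], [2, 2, 2])


def hotelling_oracle(a, b):
    """Definitional matrix-arithmetic evaluation of T²."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1, n2 = len(a), len(b)
    d = a.mean(0) - b.mean(0)
    s = ((a - a.mean(0)).T @ (a - a.mean(0))
         + (b - b.mean(0)).T @ (b - b.mean(0))) / (n1 + n2 - 2)
    return n1 * n2 / (n1 + n2) * d @ np.linalg.inv(s) @ d


class TestHotelling:
    def test_identical_means_t2_zero(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]])
        r = hotelling_two_sample(a, a.copy())
        assert r.T2 == pytest.approx(0.0)
        assert r.p == 1.0

    def test_p1_reduces_to_squared_t(self):
        rng = np.random.default_rng(4)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a, b = rng.normal(size=(7, 1)), rng.normal(0.5, 1, size=(7, 1))
            t = unpaired_t(a[:, 0], b[:, 0]).t
            assert hotelling_two_sample(a, b).T2 == pytest.approx(t ** 2, rel=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_definitional_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(7, 2))
        b = rng.normal(0.7, 1.3, size=(7, 2))
        r = hotelling_two_sample(a, b)
        assert r.T2 == pytest.approx(hotelling_oracle(a, b), rel=1e-10)
        # F transformation invariant
        assert r.F == pytest.approx(r.T2 * (7 + 7 - 2 - 1) / (2 * (7 + 7 - 2)), rel=1e-12)

    def test_singular_covariance_advises(self):
        a = np.ones((4, 3))
        a[:, 1] = a[:, 0]
        b = np.zeros((4, 3))
        b[:, 1] = b[:, 0]
        with pytest.raises(ValueError, match="singular|dimension"):
            hotelling_two_sample(a, b)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="n1\\+n2"):
            hotelling_two_sample(np.zeros((2, 3)), np.zeros((2, 3)))


def sphericity_oracle(x):
    """Eigen-decomposition oracle on the (single-group) contrast covariance."""
    x = np.asarray(x, float)
    n, k = x.shape
    c = np.zeros((k - 1, k))
    for i in range(k - 1):
        c[i, : i + 1] = 1.0
        c[i, i + 1] = -(i + 1.0)
        c[i] /= np.linalg.norm(c[i])
    y = x @ c.T
    s = (y - y.mean(0)).T @ (y - y.mean(0)) / (n - 1)
    lam = np.linalg.eigvalsh(s)
    w = np.prod(lam) / lam.mean() ** (k - 1)
    eps = lam.sum() ** 2 / ((k - 1) * (lam ** 2).sum())
    return w, eps


class TestSphericity:
    def test_k2_trivially_spherical(self):
        r = mauchly_and_epsilon(np.random.default_rng(0).normal(size=(6, 2)))
        assert r.W == 1.0 and r.epsilon_gg == 1.0 and r.p == 1.0

    def test_compound_symmetric_covariance(self):
        rng = np.random.default_rng(1)
        # exchangeable columns: shared subject effect + iid noise, large n
        subj = rng.normal(size=(4000, 1))
        x = subj + rng.normal(size=(4000, 4))
        r = mauchly_and_epsilon(x)
        assert r.W > 0.99 and r.epsilon_gg > 0.99

    def test_matches_eigen_oracle_random_8x4(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=(8, 4)) @ rng.normal(size=(4, 4))
        r = mauchly_and_epsilon(x)
        w, eps = sphericity_oracle(x)
        assert r.W == pytest.approx(w, rel=1e-10)
        assert r.epsilon_gg == pytest.approx(eps, rel=1e-10)

    def test_matches_pingouin_single_group(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        n, k = 9, 4
        x = rng.normal(size=(n, k)) @ rng.normal(size=(k, k))
        df = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                           "cat": np.tile(np.arange(k), n), "y": x.ravel()})
        sph = pg.sphericity(df, dv="y", within="cat", subject="subject")
        eps = pg.epsilon(df, dv="y", within="cat", subject="subject", correction="gg")
        mine = mauchly_and_epsilon(x)
        assert mine.W == pytest.approx(sph.W, rel=1e-9)
        assert mine.chi2 == pytest.approx(sph.chi2, rel=1e-9)
        assert mine.df == sph.dof
        assert mine.epsilon_gg == pytest.approx(eps, rel=1e-9)

    def test_epsilon_bounds(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(8, 4))
            r = mauchly_and_epsilon(x)
            assert 1.0 / 3 - 1e-12 <= r.epsilon_gg <= 1.0 + 1e-12
            assert 0 < r.W <= 1.0

    def test_k1_rejected(self):
        with pytest.raises(ValueError):
            mauchly_and_epsilon(np.zeros((5, 1)))


def anova_oracle(x, groups):
    """Brute-force cell-means sums-of-squares decomposition by explicit loops."""
    x = np.asarray(x, float)
    n, k = x.shape
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    grand = x.mean()
    ss_total = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_bs = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_treat = sum(k * (groups == g).sum() * (x[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_subj = ss_bs - ss_treat
    ss_cat = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_cells = sum((groups == g).sum() * (x[groups == g][:, j].mean() - grand) ** 2
                   for g in labels for j in range(k))
    ss_inter = ss_cells - ss_cat - ss_treat
    ss_err = ss_total - ss_bs - ss_cat - ss_inter
    return dict(treatment=ss_treat, subjects_within_groups=ss_subj,
                category=ss_cat, interaction=ss_inter, error_within=ss_err,
                total=ss_total)


class TestMixedAnova:
    def _data(self, n_per=7, k=4, seed=0, shift=1.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n_per, k)) + np.linspace(0, 2, k)
        x[n_per:] += shift
        groups = ["vehicle"] * n_per + ["treated"] * n_per
        return x, groups

    def test_df_1_12_and_3_36_for_seven_per_group(self):
        x, groups = self._data()
        r = mixed_anova_2x4(x, groups, alpha_sphericity=0.0)  # no GG: raw df
        assert (r.treatment.df1, r.treatment.df2) == (1, 12)
        assert (r.category.df1, r.category.df2) == (3, 36)
        assert (r.interaction.df1, r.interaction.df2) == (3, 36)

    def test_location_invariance(self):
        x, groups = self._data(seed=5)
        r1 = mixed_anova_2x4(x, groups)
        r2 = mixed_anova_2x4(x + 77.7, groups)
        assert r1.treatment.F == pytest.approx(r2.treatment.F)
        assert r1.category.F == pytest.approx(r2.category.F)
        assert r1.interaction.F == pytest.approx(r2.interaction.F)

    @pytest.mark.parametrize("n_per,k,seed", [(4, 3, 0), (4, 3, 1), (5, 4, 2)])
    def test_ss_match_brute_force_decomposition(self, n_per, k, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n_per, k))
        groups = ["a"] * n_per + ["b"] * n_per
        r = mixed_anova_2x4(x, groups)
        oracle = anova_oracle(x, groups)
        for key, val in oracle.items():
            assert r.ss[key] == pytest.approx(val, rel=1e-8), key

    def test_ss_additive(self):
        x, groups = self._data(seed=9)
        r = mixed_anova_2x4(x, groups)
        parts = sum(v for k_, v in r.ss.items() if k_ != "total")
        assert parts == pytest.approx(r.ss["total"], rel=1e-8)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        x, groups = self._data(seed=12)
        n, k = x.shape
        df = pd.DataFrame({"subject": np.repeat(np.arange(n), k),
                           "group": np.repeat(groups, k),
                           "cat": np.tile(np.arange(k), n), "y": x.ravel()})
        aov = pg.mixed_anova(df, dv="y", within="cat", subject="subject",
                             between="group").set_index("Source")
        r = mixed_anova_2x4(x, groups, alpha_sphericity=0.0)
        assert r.treatment.F == pytest.approx(aov.loc["group", "F"], rel=1e-9)
        assert r.category.F == pytest.approx(aov.loc["cat", "F"], rel=1e-9)
        assert r.interaction.F == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)

    def test_gg_correction_never_lowers_small_p(self):
        # df shrinkage (epsilon <= 1) makes nominally significant
        # within-subject effects more conservative; for clearly null effects
        # (large raw p, F < 1) the tail probability can move either way, so
        # the conservativity check applies where the correction matters.
        checked = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(10, 4)) @ rng.normal(size=(4, 4))
            x += np.linspace(0, 2, 4)
            groups = ["a"] * 5 + ["b"] * 5
            raw = mixed_anova_2x4(x, groups, alpha_sphericity=0.0)
            corrected = mixed_anova_2x4(x, groups, alpha_sphericity=1.1)
            assert corrected.sphericity.epsilon_gg <= 1.0 + 1e-12
            for eff in ("category", "interaction"):
                if getattr(raw, eff).p <= 0.10:
                    checked += 1
                    assert getattr(corrected, eff).p >= getattr(raw, eff).p - 1e-15
        assert checked > 10

    def test_subject_relabeling_invariance(self):
        x, groups = self._data(seed=3)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(groups))
        r1 = mixed_anova_2x4(x, groups)
        r2 = mixed_anova_2x4(x[perm], np.asarray(groups)[perm])
        assert r1.treatment.F == pytest.approx(r2.treatment.F)
        assert r1.category.F == pytest.approx(r2.category.F)

    def test_missing_cell_rejected(self):
        x, groups = self._data()
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            mixed_anova_2x4(x, groups)


def _pancreas(sample_id, counts, volumes, ki67=None):
    bins = ("small", "medium", "large", "very_large")
    return PancreasResult(
        sample_id=sample_id,
        total_islets=sum(counts),
        total_beta_volume_mm3=sum(volumes),
        bin_counts=dict(zip(bins, counts)),
        bin_volumes_mm3=dict(zip(bins, volumes)),
        bin_ki67_positive=dict(zip(bins, ki67)) if ki67 else None,
        total_ki67_cells=sum(ki67) if ki67 else None,
    )


class TestStudyReport:
    def _design(self, shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        groups, results = {}, {}
        for g, label in ((0, "vehicle"), (1, "s961")):
            for i in range(4):
                sid = f"{label}{i}"
                groups[sid] = label
                base = np.array([3300, 2300, 450, 45], float)
                counts = np.maximum(rng.normal(base * (1 + shift * g), base * 0.05), 1)
                vols = np.maximum(rng.normal([0.26, 0.93, 1.19, 0.55], 0.03), 0.01)
                results[sid] = _pancreas(sid, counts.astype(int).tolist(), vols.tolist())
        return GroupDesign(groups=groups, results=results, reference_group="vehicle")

    def test_sem_hand_computation(self):
        vals = [2.0, 4.0, 9.0]
        assert sem(vals) == pytest.approx(np.std(vals, ddof=1) / np.sqrt(3))

    def test_identical_groups_null_report(self):
        groups = {}
        results = {}
        for g in ("a", "b"):
            for i in range(3):
                sid = f"{g}{i}"
                groups[sid] = g
                # identical per-subject values across groups (by index)
                results[sid] = _pancreas(sid, [100 + i, 50 + i, 10, 2],
                                         [0.3 + 0.01 * i, 0.9, 1.1, 0.5])
        rep = study_report(GroupDesign(groups=groups, results=results))
        assert rep["metrics"]["total_islets"]["percent_increase"] == pytest.approx(0.0)
        assert rep["metrics"]["total_islets"]["t_test"]["p"] == pytest.approx(1.0)

    def test_report_structure_and_effect_detection(self):
        rep = self._design(shift=0.5, seed=1).pipe_report if False else None
        design = self._design(shift=0.5, seed=1)
        rep = study_report(design)
        assert set(rep["per_bin"]) == {"small", "medium", "large", "very_large"}
        assert rep["metrics"]["total_islets"]["percent_increase"] > 10
        assert "counts" in rep["mixed_anova"]
        assert rep["mixed_anova"]["counts"]["treatment"]["p"] < 0.05

    def test_reference_group_must_exist(self):
        with pytest.raises(ValueError, match="exactly two|reference"):
            GroupDesign(groups={"a1": "a"}, results={"a1": _pancreas("a1", [1, 1, 1, 1], [1, 1, 1, 1])})
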