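import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from fdindex import (
    CohortTable,
    bonferroni,
    chi_squared,
    mann_whitney_u,
    quade_ancova,
    roc_auc,
    spearman_bonferroni,
)


class TestBonferroni:
    def test_scaling_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01], 6), [0.06])
        np.testing.assert_allclose(bonferroni([0.3], 6), [1.0])
        np.testing.assert_allclose(bonferroni([0.2], 1), [0.2])

    def test_adjusted_never_below_raw(self):
        p = np.array([0.001, 0.02, 0.5, 0.9])
        adj = bonferroni(p)
        assert np.all(adj >= p) and np.all(adj <= 1.0)


class TestQuade:
    def test_constant_covariates_reduce_to_rank_anova(self):
        from scipy.stats import f_oneway, rankdata

        rng = np.random.default_rng(0)
        y = rng.standard_normal(24)
        groups = np.repeat(["A", "B", "C"], 8)
        res = quade_ancova(y, groups, np.ones((24, 2)))
        r = rankdata(y)
        f_ref = f_oneway(r[:8], r[8:16], r[16:]).statistic
        assert res.f_stat == pytest.approx(f_ref, rel=1e-10)
        assert res.df == (2, 21)  # constant covariates consume no df

    def test_type_one_error_calibrated(self):
        """Null simulation at the study's group sizes (20 vs 11) with three
        covariates: rejection rate at alpha=0.05 must be near nominal."""
        rng = np.random.default_rng(123)
        groups = np.array(["HC"] * 20 + ["SCZ"] * 11)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            y = rng.standard_normal(31)
            cov = np.column_stack(
                [
                    rng.standard_normal(31),
                    rng.integers(0, 2, 31),
                    rng.integers(1, 4, 31),
                ]
            )
            if quade_ancova(y, groups, cov).p_raw < 0.05:
                rejections += 1
        assert 0.03 < rejections / n_sim < 0.07

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        y = np.concatenate([np.arange(15.0), 50 + np.arange(15.0)])
        groups = np.repeat(["A", "B"], 15)
        cov = rng.standard_normal((30, 3))
        assert quade_ancova(y, groups, cov).p_raw < 0.001

    def test_constant_response_degenerate(self):
        res = quade_ancova(np.ones(12), np.repeat(["A", "B"], 6), None)
        assert res.p_raw == 1.0 and res.degenerate

    def test_bonferroni_adjustment_applied(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(20)
        res = quade_ancova(y, np.repeat(["A", "B"], 10), None, n_comparisons=6)
        assert res.p_adj == pytest.approx(min(1.0, 6 * res.p_raw))


class TestSpearman:
    def test_perfect_antimonotone(self):
        table = pd.DataFrame(
            {
                "group": ["SCZ"] * 5,
                "FDI_SAN": [1.0, 2, 3, 4, 5],
                "PANSS_P": [5.0, 4, 3, 2, 1],
            }
        )
        (res,) = spearman_bonferroni(table, ["FDI_SAN"], ["PANSS_P"])
        assert res.rho == pytest.approx(-1.0)
        # exactly 2 of 5! = 120 permutations reach |rho| = 1
        assert res.p_raw == pytest.approx(2 / 120)
        assert res.method == "exact"

    def test_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(12)
        y = rng.standard_normal(12)
        t1 = pd.DataFrame({"group": ["SCZ"] * 12, "FDI_A": x, "s": y})
        t2 = pd.DataFrame(
            {"group": ["SCZ"] * 12, "FDI_A": np.exp(3 * x), "s": y**3}
        )
        (a,) = spearman_bonferroni(t1, ["FDI_A"], ["s"])
        (b,) = spearman_bonferroni(t2, ["FDI_A"], ["s"])
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        assert a.p_raw == pytest.approx(b.p_raw, abs=1e-12)

    def test_family_size_is_pair_count(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(
            {
                "group": ["SCZ"] * 11,
                "FDI_A": rng.standard_normal(11),
                "FDI_B": rng.standard_normal(11),
                "s1": rng.standard_normal(11),
                "s2": rng.standard_normal(11),
                "s3": rng.standard_normal(11),
            }
        )
        results = spearman_bonferroni(df, ["FDI_A", "FDI_B"], ["s1", "s2", "s3"])
        assert len(results) == 6
        for r in results:
            assert r.p_adj == pytest.approx(min(1.0, 6 * r.p_raw))

    def test_too_few_pairs_flagged_unusable(self):
        df = pd.DataFrame(
            {
                "group": ["SCZ"] * 5,
                "FDI_A": [1.0, 2, np.nan, np.nan, np.nan],
                "s": [1.0, 2, 3, np.nan, np.nan],
            }
        )
        (r,) = spearman_bonferroni(df, ["FDI_A"], ["s"])
        assert not r.usable and np.isnan(r.rho)

    def test_builtin_negative_panss_link_recovered(self):
        """Simulated patients' PANSS-P falls with their complexity by
        construction; running the full pipeline and correlating the
        whole-brain FDI with PANSS-P must recover a negative Spearman rho
        in nearly all seeded replicates.  (At this reduced scale the
        whole-brain value is the precise estimate; 60-source single
        networks are dominated by windowing noise.)"""
        import warnings

        from fdindex import SimulationConfig, make_cohort, run_cohort
        from fdindex.stats import spearman

        hits = 0
        for rep in range(10):
            config = SimulationConfig(
                n_sources=400, fs=125.0, duration=10.0, hurst=0.3,
                group_effect=0.4, seed=50 + rep,
            )
            space, mats, table = make_cohort(2, 11, config, seed=50 + rep)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                tab, _ = run_cohort(space, mats, table, networks=("Brain",))
            scz = tab.df[tab.df.group == "SCZ"]
            rho, _, _ = spearman(
                scz["FDI_Brain"].to_numpy(), scz["PANSS_P"].to_numpy()
            )
            hits += rho < 0
        assert hits >= 9


class TestMannWhitneyChi2:
    def test_two_vs_two_exact(self):
        u, p = mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_symmetric(self):
        x = np.arange(6.0)
        u, _ = mann_whitney_u(x, x)
        assert u == pytest.approx(18.0)  # n1*n2/2

    def test_chi2_diagonal_table(self):
        chi2, p = chi_squared([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert p < 1e-4


class TestRoc:
    def test_tie_example(self):
        fdi = np.array([5.0, 6.0, 7.0, 3.0, 4.0, 5.0])
        groups = np.array(["HC", "HC", "HC", "SCZ", "SCZ", "SCZ"])
        res = roc_auc(fdi, groups)
        assert res.auc == pytest.approx(8.5 / 9)

    def test_perfect_separation(self):
        fdi = np.array([5.0, 6.0, 1.0, 2.0])
        groups = np.array(["HC", "HC", "SCZ", "SCZ"])
        assert roc_auc(fdi, groups).auc == pytest.approx(1.0)

    def test_identical_groups_chance(self):
        fdi = np.array([4.0, 5.0, 4.0, 5.0])
        groups = np.array(["HC", "HC", "SCZ", "SCZ"])
        assert roc_auc(fdi, groups).auc == pytest.approx(0.5)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            roc_auc([1.0, 2.0], np.array(["HC", "HC"]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=12),
    )
    def test_auc_equals_normalised_u_statistic(self, hc, scz):
        """Trapezoidal AUC must equal U/(n1*n2) with half-credit for ties,
        on arbitrary inputs (pairwise brute force as the oracle)."""
        fdi = np.array(hc + scz)
        groups = np.array(["HC"] * len(hc) + ["SCZ"] * len(scz))
        res = roc_auc(fdi, groups)
        pairs = list(itertools.product(scz, hc))
        u = sum(1.0 if s < h else 0.5 if s == h else 0.0 for s, h in pairs)
        assert res.auc == pytest.approx(u / len(pairs), abs=1e-9)
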