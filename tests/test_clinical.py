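"""Clinical descriptives, partial correlations, FDR, EEG-clinical linking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import partial_corr_recursive
from sst_ersp import clinical as cli
from sst_ersp import synth as sy


@pytest.fixture(scope="module")
def cohort():
    return cli.load_reference_cohort()


class TestDescriptives:
    def test_reference_cohort_summary_values(self, cohort):
        """The bundled CTD cohort reproduces its published summary values at
        printed rounding."""
        age = cli.describe(cohort.age)
        assert round(age.mean, 1) == 13.3
        ygtss = cli.describe(cohort.ygtss_total_tic)
        assert round(ygtss.mean, 0) == 23 and round(ygtss.sd, 1) == 9.3
        puts = cli.describe(cohort.puts_total)
        assert round(puts.mean, 0) == 22 and round(puts.sd, 1) == 5.9
        assert puts.median == 20.0
        assert (cohort.sex == "F").sum() == 3
        assert len(cohort) == 14

    def test_ygtss_median_is_midpoint(self, cohort):
        # even-n midpoint median of the column is 22.5 (reported rounded)
        assert cli.describe(cohort.ygtss_total_tic).median == 22.5

    def test_constant_column_has_zero_sd(self):
        d = cli.describe([5.0, 5.0, 5.0])
        assert d.sd == 0.0 and d.mean == 5.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            cli.describe([1.0])


class TestPartialCorrelation:
    def test_constant_covariate_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal((2, 30))
        r_plain = cli.partial_corr(x, y).r
        r_const = cli.partial_corr(x, y, covariates=[np.ones(30)]).r
        assert np.isclose(r_plain, r_const, atol=1e-12)
        assert np.isclose(r_plain, np.corrcoef(x, y)[0, 1], atol=1e-12)

    def test_self_correlation_is_one(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 9.0])
        res = cli.partial_corr(x, x)
        assert res.r == 1.0 and res.p == 0.0

    def test_toy_matches_recursive_closed_form(self):
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 4, 3, 5]
        z = [1.0, 1, 2, 2, 3]
        got = cli.partial_corr(x, y, covariates=[z]).r
        assert np.isclose(got, partial_corr_recursive(x, y, z), atol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_residual_route_equals_recursion_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        x, y, z = rng.standard_normal((3, 12))
        got = cli.partial_corr(x, y, covariates=[z]).r
        assert np.isclose(got, partial_corr_recursive(x, y, z), atol=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            df = pd.DataFrame(rng.standard_normal((20, 3)),
                              columns=["x", "y", "z"])
            ref = pg.partial_corr(df, x="x", y="y", covar="z")
            got = cli.partial_corr(df.x, df.y, covariates=[df.z])
            assert np.isclose(got.r, ref["r"].iloc[0], atol=1e-10)
            assert np.isclose(got.p, ref["p_val"].iloc[0], atol=1e-10)

    def test_zero_residual_variance_rejected(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError):
            cli.partial_corr(2 * z + 1, np.random.default_rng(0).standard_normal(10),
                             covariates=[z])

    def test_insufficient_n_rejected(self):
        with pytest.raises(ValueError):
            cli.partial_corr([1.0, 2], [3.0, 4], covariates=[[1.0, 2]])


class TestFDR:
    def test_single_p_unchanged(self):
        adj, rej = cli.fdr_adjust([0.03])
        assert adj[0] == 0.03 and rej[0]

    def test_hand_computed_example(self):
        adj, _ = cli.fdr_adjust([0.01, 0.02, 0.03])
        np.testing.assert_allclose(adj, [0.03, 0.03, 0.03])

    def test_all_ones(self):
        adj, rej = cli.fdr_adjust([1.0, 1.0, 1.0])
        assert (adj == 1.0).all() and not rej.any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cli.fdr_adjust([0.5, 1.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12),
           st.integers(0, 1000))
    def test_monotone_and_permutation_invariant(self, ps, seed):
        adj, _ = cli.fdr_adjust(ps)
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all() and (adj <= 1).all()
        perm = np.random.default_rng(seed).permutation(len(ps))
        adj_perm, _ = cli.fdr_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(adj_perm, adj[perm])


class TestEEGClinicalCorrelation:
    def _cohort_tables(self, n=14, r=0.66, seed=0):
        df = sy.draw_linked_clinical(n, r, seed=seed)
        clinical = pd.DataFrame({
            "subject": [f"CTD{i:02d}" for i in range(n)],
            "diagnosis": "CTD",
            "age": df.age,
            "ygtss_total_tic": df.ygtss_total_tic,
            "cybocs": np.random.default_rng(seed).uniform(0, 20, n),
            "dupaul_adhd": np.random.default_rng(seed + 1).uniform(0, 30, n),
        })
        extracted = pd.Series(df.delta_db.to_numpy(), index=clinical.subject)
        return extracted, clinical

    def test_gating_on_significant_cluster(self):
        extracted, clinical = self._cohort_tables()
        assert cli.correlate_eeg_clinical(extracted, clinical,
                                          has_significant_cluster=False) == []

    def test_fdr_family_is_the_three_scales(self):
        extracted, clinical = self._cohort_tables()
        res = cli.correlate_eeg_clinical(extracted, clinical)
        assert len(res) == 3
        assert all(r.p_fdr >= r.p for r in res)
        assert all(r.covariates == ("age",) for r in res)

    def test_unmatched_subjects_rejected(self):
        extracted, clinical = self._cohort_tables()
        extracted = extracted.rename({"CTD00": "ghost"})
        with pytest.raises(ValueError, match="ghost"):
            cli.correlate_eeg_clinical(extracted, clinical)

    def test_null_linkage_rejection_rate_controlled(self):
        """With no built-in EEG-clinical correlation, FDR rejections across
        the three scales stay at or below the nominal 5% family rate."""
        rejections = 0
        n_cohorts = 300
        for c in range(n_cohorts):
            extracted, clinical = self._cohort_tables(r=0.0, seed=c)
            res = cli.correlate_eeg_clinical(extracted, clinical)
            rejections += any(r.p_fdr <= 0.05 for r in res)
        assert rejections / n_cohorts <= 0.08  # 0.05 + Monte-Carlo slack


class TestBehaviorClinicalCorrelation:
    def _tables(self, ssrt, item10):
        n = len(ssrt)
        clinical = pd.DataFrame({
            "subject": [f"S{i}" for i in range(n)],
            "diagnosis": "CTD",
            "puts_item10": item10,
        })
        return pd.Series(ssrt, index=clinical.subject), clinical

    def test_sign_convention(self):
        # better self-rated suppressibility (higher item 10) with faster
        # (smaller) SSRT must yield a negative correlation
        ssrt, clinical = self._tables([300.0, 280, 260, 240, 220],
                                      [1, 2, 2, 3, 4])
        res = cli.behavior_clinical_corr(ssrt, clinical)
        assert res.r < -0.9

    def test_constant_ssrt_rejected(self):
        ssrt, clinical = self._tables([250.0] * 5, [1, 2, 3, 4, 1])
        with pytest.raises(ValueError):
            cli.behavior_clinical_corr(ssrt, clinical)

    def test_too_few_subjects_rejected(self):
        ssrt, clinical = self._tables([250.0, 260, 270], [1, 2, 3])
        with pytest.raises(ValueError):
            cli.behavior_clinical_corr(ssrt, clinical)

    def test_built_in_correlation_recovered_on_average(self):
        """Cohorts with a built-in SSRT vs suppressibility correlation of
        -0.58 recover it within +/-0.12 on average (n = 14 per cohort)."""
        rng = np.random.default_rng(5)
        rs = []
        for _ in range(500):
            z = rng.multivariate_normal([0, 0], [[1, -0.58], [-0.58, 1]], 14)
            ssrt = 250 + 36 * z[:, 0]
            item10 = 2.5 + 1.0 * z[:, 1]
            s, clin = self._tables(ssrt, item10)
            rs.append(cli.behavior_clinical_corr(s, clin).r)
        assert abs(np.mean(rs) + 0.58) <= 0.12
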