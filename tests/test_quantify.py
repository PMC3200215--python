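import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lfqpipe import normalization as N
from lfqpipe import quantify as Q
from lfqpipe.errors import DataValidationError, InferenceError
from lfqpipe.synthetic import SPIKEIN_ACCESSION, SyntheticConfig, generate_peptide_table


def design_r1(n_case=3, n_ctrl=3):
    rows = []
    for i in range(n_case):
        rows.append((f"AT{i}::1", f"AT{i}", "AT", 1))
    for i in range(n_ctrl):
        rows.append((f"C{i}::1", f"C{i}", "control", 1))
    df = pd.DataFrame(rows, columns=["injection", "sample", "group", "replicate"])
    return Q.StudyDesign(df.set_index("injection"))


class TestRollup:
    def make_matrix(self, data, proteins, peptides, columns):
        idx = pd.MultiIndex.from_arrays([proteins, peptides],
                                        names=["protein", "peptide"])
        m = pd.DataFrame(data, index=idx, columns=columns)
        m.attrs["scale"] = N.NORMALIZED
        return m

    def test_mean_of_two_peptides(self):
        m = self.make_matrix([[4.0], [6.0]], ["P", "P"], ["a", "b"], ["i1"])
        out = Q.rollup_protein(m)
        assert out.loc["P", "i1"] == 5.0

    def test_single_peptide_identity(self):
        m = self.make_matrix([[7.3]], ["P"], ["a"], ["i1"])
        assert Q.rollup_protein(m).loc["P", "i1"] == 7.3

    def test_missing_peptide_excluded_from_mean(self):
        m = self.make_matrix([[4.0], [np.nan], [8.0]], ["P"] * 3,
                             ["a", "b", "c"], ["i1"])
        assert Q.rollup_protein(m).loc["P", "i1"] == 6.0

    def test_peptide_order_irrelevant(self):
        m1 = self.make_matrix([[4.0, 1.0], [6.0, 3.0]], ["P", "P"],
                              ["a", "b"], ["i1", "i2"])
        m2 = m1.iloc[::-1]
        m2.attrs["scale"] = N.NORMALIZED
        pd.testing.assert_frame_equal(Q.rollup_protein(m1), Q.rollup_protein(m2))


class TestGroupSampleModel:
    def test_hand_computed_one_way_anova(self):
        """{1,2,3} vs {4,5,6}: diff 3, F = 13.5 on (1,4) df, p ~ 0.0213."""
        y = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                      index=[f"C{i}::1" for i in range(3)]
                      + [f"AT{i}::1" for i in range(3)])
        fit = Q.fit_group_sample_model(y, design_r1())
        assert fit.diff_log2 == pytest.approx(3.0)
        assert fit.f_statistic == pytest.approx(13.5, abs=1e-9)
        assert fit.df == (1, 4)
        assert fit.p_value == pytest.approx(stats.f.sf(13.5, 1, 4), abs=1e-6)

    def test_f_equals_squared_t_with_single_replicates(self):
        rng = np.random.default_rng(3)
        case = rng.normal(1.0, 1.0, 5)
        ctrl = rng.normal(0.0, 1.0, 4)
        y = pd.Series(
            np.concatenate([case, ctrl]),
            index=[f"AT{i}::1" for i in range(5)] + [f"C{i}::1" for i in range(4)],
        )
        fit = Q.fit_group_sample_model(y, design_r1(5, 4))
        t, p = stats.ttest_ind(case, ctrl)
        assert fit.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert fit.p_value == pytest.approx(p, rel=1e-10)

    def test_nested_model_variance_components(self):
        """Balanced 2-replicate data with known variance structure."""
        rng = np.random.default_rng(5)
        sigma_s, sigma_e, r = 0.5, 0.2, 2
        rows, idx = [], []
        for g, n in (("AT", 40), ("control", 40)):
            for s in range(n):
                b = rng.normal(0, sigma_s)
                for rep in range(r):
                    idx.append(f"{g}{s}::{rep + 1}")
                    rows.append(b + rng.normal(0, sigma_e))
        design = pd.DataFrame(
            {
                "injection": idx,
                "sample": [i.split("::")[0] for i in idx],
                "group": ["AT" if i.startswith("AT") else "control" for i in idx],
                "replicate": [int(i.split("::")[1]) for i in idx],
            }
        ).set_index("injection")
        fit = Q.fit_group_sample_model(pd.Series(rows, index=idx),
                                       Q.StudyDesign(design))
        assert fit.sigma2_rep == pytest.approx(sigma_e**2, rel=0.35)
        assert fit.sigma2_sample == pytest.approx(sigma_s**2, rel=0.35)
        assert fit.n_replicates == 2

    def test_sigma_sample_truncated_at_zero(self):
        # replicate noise only: MS_sample < MS_rep on average; estimate >= 0
        rng = np.random.default_rng(11)
        hits = []
        for trial in range(10):
            idx = [f"{g}{s}::{rep}" for g in ("AT", "C") for s in range(3)
                   for rep in (1, 2)]
            design = pd.DataFrame(
                {
                    "injection": idx,
                    "sample": [i.split("::")[0] for i in idx],
                    "group": ["AT" if i.startswith("AT") else "control" for i in idx],
                    "replicate": [int(i.split("::")[1]) for i in idx],
                }
            ).set_index("injection")
            y = pd.Series(rng.normal(0, 1, len(idx)), index=idx)
            fit = Q.fit_group_sample_model(y, Q.StudyDesign(design))
            assert fit.sigma2_sample >= 0.0
            hits.append(fit.sigma2_sample == 0.0)
        assert any(hits)  # truncation actually occurs

    def test_constant_data_report_p_one(self):
        y = pd.Series([5.0] * 6, index=[f"AT{i}::1" for i in range(3)]
                      + [f"C{i}::1" for i in range(3)])
        fit = Q.fit_group_sample_model(y, design_r1())
        assert fit.p_value == 1.0
        assert fit.diff_log2 == 0.0

    def test_zero_noise_with_signal_reports_p_zero(self):
        y = pd.Series([1.0, 1.0, 1.0, 2.0, 2.0, 2.0],
                      index=[f"C{i}::1" for i in range(3)]
                      + [f"AT{i}::1" for i in range(3)])
        with pytest.warns(UserWarning):
            fit = Q.fit_group_sample_model(y, design_r1())
        assert fit.p_value == 0.0
        assert fit.diff_log2 == 1.0

    def test_too_few_samples_rejected(self):
        y = pd.Series([1.0, 2.0, 3.0],
                      index=["AT0::1", "AT1::1", "C0::1"])
        with pytest.raises(InferenceError):
            Q.fit_group_sample_model(y, design_r1(2, 1))


class TestFoldChange:
    @pytest.mark.parametrize(
        "diff,expected", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (0.5, 2**0.5)]
    )
    def test_sign_convention(self, diff, expected):
        assert Q.fold_change(diff) == pytest.approx(expected)

    def test_antisymmetry(self):
        for d in (0.3, 1.7, 2.5):
            assert Q.fold_change(-d) == pytest.approx(-Q.fold_change(d))

    def test_magnitude_never_below_one(self):
        rng = np.random.default_rng(0)
        for d in rng.normal(0, 2, 50):
            assert abs(Q.fold_change(d)) >= 1.0


class TestQvalues:
    def test_hand_computed_bh(self):
        q = Q.estimate_qvalues([0.01, 0.02, 0.03])
        assert np.allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert Q.estimate_qvalues([0.04])[0] == pytest.approx(0.04)

    def test_all_ones(self):
        assert np.allclose(Q.estimate_qvalues([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=40)
        q = Q.estimate_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()
        assert (q >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            Q.estimate_qvalues([0.5, 1.2])


class TestCvSummaries:
    def test_hand_computed_replicate_cv(self):
        raw = pd.DataFrame(
            [[100.0, 110.0, 90.0, 100.0, 110.0, 90.0]],
            index=pd.Index(["P"], name="protein"),
            columns=["S1::1", "S1::2", "S1::3", "S2::1", "S2::2", "S2::3"],
        )
        design = pd.DataFrame(
            {
                "sample": ["S1"] * 3 + ["S2"] * 3,
                "group": ["AT"] * 3 + ["control"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            },
            index=raw.columns,
        )
        table, medians = Q.cv_summaries(raw, Q.StudyDesign(design))
        assert table.loc["P", "cv_replicate"] == pytest.approx(10.0)
        assert medians["median_cv_replicate"] == pytest.approx(10.0)

    def test_constant_intensities_zero_cv(self):
        raw = pd.DataFrame(
            [[50.0] * 4],
            index=pd.Index(["P"], name="protein"),
            columns=["S1::1", "S1::2", "S2::1", "S2::2"],
        )
        design = pd.DataFrame(
            {
                "sample": ["S1", "S1", "S2", "S2"],
                "group": ["AT", "AT", "control", "control"],
                "replicate": [1, 2, 1, 2],
            },
            index=raw.columns,
        )
        table, _ = Q.cv_summaries(raw, Q.StudyDesign(design))
        assert table.loc["P", "cv_replicate"] == 0.0
        assert table.loc["P", "cv_rep_sample"] == 0.0

    def test_total_cv_exceeds_replicate_cv_on_average(self, quantified):
        results, _, _, _ = quantified
        valid = results.dropna(subset=["cv_replicate", "cv_rep_sample"])
        assert valid["cv_rep_sample"].mean() > valid["cv_replicate"].mean()


class TestSignificanceAndQC:
    @pytest.mark.parametrize(
        "fc,q,expected",
        [(1.52, 0.01, True), (1.2, 0.001, False), (-1.46, 0.04, True),
         (2.0, 0.06, False), (1.3, 0.049, True)],
    )
    def test_flag_significant(self, fc, q, expected):
        assert Q.flag_significant(fc, q) is expected

    def test_spikein_pass_and_fail(self):
        results = pd.DataFrame(
            {"fold_change": [-1.1, 2.0, 1.0], "q_value": [0.77, 0.001, 0.5]},
            index=["spike_pass", "spike_fail", "spike_exact"],
        )
        assert Q.qc_spikein_check(results, "spike_pass").passed
        assert not Q.qc_spikein_check(results, "spike_fail").passed
        assert Q.qc_spikein_check(results, "spike_exact").passed

    def test_missing_spikein_errors(self):
        with pytest.raises(DataValidationError):
            Q.qc_spikein_check(pd.DataFrame({"fold_change": [], "q_value": []}),
                               "nope")


class TestPipelineRecovery:
    def test_noise_free_chain_recovers_fold_changes_exactly(self):
        """log2 -> rollup -> ANOVA reproduces every true fold-change."""
        cfg = SyntheticConfig(
            n_proteins=25, frac_changed=0.4, effect_log2=0.7,
            sigma_sample=0.0, sigma_rep=0.0, seed=21,
        )
        table, truth = generate_peptide_table(cfg)
        m = N.peptide_table_to_matrix(table)
        log2m = N.log2_transform(m)
        log2m.attrs["scale"] = N.NORMALIZED  # columns already comparable
        design = Q.StudyDesign(N.injection_design(table))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = Q.quantify_proteins(Q.rollup_protein(log2m), design)
        joined = truth.table.join(res)
        assert np.allclose(joined["diff_log2"], joined["delta_log2"], atol=1e-9)
        assert np.allclose(joined["fold_change"], joined["true_fold_change"],
                           atol=1e-9)

    def test_peptide_row_permutation_leaves_results_unchanged(self, small_dataset):
        _, table, _ = small_dataset
        shuffled = table.sample(frac=1.0, random_state=0)

        def run(t):
            m = N.peptide_table_to_matrix(t)
            d = Q.StudyDesign(N.injection_design(t))
            normed = N.quantile_normalize(N.log2_transform(m))
            return Q.quantify_proteins(Q.rollup_protein(normed), d)

        pd.testing.assert_frame_equal(run(table), run(shuffled))

    def test_spikein_survives_full_chain(self, quantified):
        results, truth, _, _ = quantified
        qc = Q.qc_spikein_check(results)
        assert abs(qc.fold_change) < 1.5
        assert SPIKEIN_ACCESSION in results.index
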