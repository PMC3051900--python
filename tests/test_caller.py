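"""Per-CGI design assembly, calling, and methylation scoring."""

import numpy as np
import pandas as pd
import pytest

import qrmeth
from qrmeth.caller import (
    CgiSkipped,
    InferenceSettings,
    build_design,
    call_cgi,
    call_dataset,
    derive_seed,
    methylation_scores,
)
from qrmeth.io import LogRatioMatrix, ProbeAnnotation
from qrmeth.quantreg import check_loss


def make_matrix(n_probes, n_samples, values, cgi_id="C1", probes_per_cgi=None):
    """Annotation + matrix helper; optionally split probes across CGIs."""
    probe_ids = [f"P{i + 1}" for i in range(n_probes)]
    if probes_per_cgi is None:
        cgis = [cgi_id] * n_probes
    else:
        cgis = []
        for ci, count in enumerate(probes_per_cgi):
            cgis += [f"C{ci + 1}"] * count
    annotation = [
        ProbeAnnotation(p, c, (f"G_{c}",), "chr1", 100 * i, 100 * i + 60)
        for i, (p, c) in enumerate(zip(probe_ids, cgis))
    ]
    matrix = LogRatioMatrix(probe_ids, [f"S{j + 1}" for j in range(n_samples)], values)
    return annotation, matrix


class TestBuildDesign:
    def test_counts_full_grid(self, rng):
        annotation, matrix = make_matrix(5, 40, rng.normal(size=(5, 40)))
        design = build_design("C1", annotation, matrix)
        assert design.y.size == 200
        assert design.n_samples == 40
        assert design.n_probes == 5
        assert design.n_params == 44

    def test_single_probe_cgi_has_no_probe_columns(self, rng):
        annotation, matrix = make_matrix(1, 10, rng.normal(size=(1, 10)))
        design = build_design("C1", annotation, matrix)
        assert design.n_params == 10

    def test_missing_cells_dropped(self, rng):
        values = rng.normal(size=(5, 40))
        values[0, 0] = values[2, 7] = values[4, 39] = np.nan
        annotation, matrix = make_matrix(5, 40, values)
        design = build_design("C1", annotation, matrix)
        assert design.y.size == 197

    def test_all_missing_sample_excluded(self, rng):
        values = rng.normal(size=(4, 6))
        values[:, 2] = np.nan
        annotation, matrix = make_matrix(4, 6, values)
        design = build_design("C1", annotation, matrix)
        assert design.excluded_samples == ["S3"]
        assert design.n_samples == 5
        assert design.all_sample_ids == matrix.sample_ids

    def test_unknown_cgi(self, rng):
        annotation, matrix = make_matrix(3, 4, rng.normal(size=(3, 4)))
        with pytest.raises(KeyError, match="nope"):
            build_design("nope", annotation, matrix)


class TestCallCgi:
    def test_null_input_all_not_significant(self):
        annotation, matrix = make_matrix(5, 8, np.zeros((5, 8)))
        design = build_design("C1", annotation, matrix)
        res = call_cgi(design, 0.75, InferenceSettings(n_boot=60, seed=1))
        np.testing.assert_allclose(res.sample_effects, 0.0, atol=1e-9)
        assert np.all(res.sample_p_values >= 0.5)

    def test_probe_effects_sum_to_zero(self, rng):
        annotation, matrix = make_matrix(6, 10, rng.normal(size=(6, 10)))
        design = build_design("C1", annotation, matrix)
        res = call_cgi(design, 0.85, InferenceSettings(n_boot=60, seed=2))
        assert abs(res.probe_effects.sum()) < 1e-8
        assert len(res.probe_effects) == 6

    def test_sample_effect_is_probe_adjusted_quantile(self, rng):
        # the fit objective can never be beaten by any (quantile, probe) guess
        annotation, matrix = make_matrix(8, 6, rng.normal(size=(8, 6)))
        design = build_design("C1", annotation, matrix)
        res = call_cgi(design, 0.75, InferenceSettings(n_boot=60, seed=3))
        X = qrmeth.caller.design_matrix(design)
        beta = np.concatenate([
            [res.sample_effects[design.all_sample_ids.index(s)]
             for s in design.sample_ids],
            res.probe_effects[:-1],
        ])
        assert check_loss(design.y - X @ beta, 0.75) == pytest.approx(
            res.objective, abs=1e-8
        )
        # brute-force oracle on a 1-probe design: per-sample tau-quantile
        ann1, mat1 = make_matrix(1, 3, rng.normal(size=(1, 3)))
        d1 = build_design("C1", ann1, mat1)
        with pytest.raises(CgiSkipped):
            call_cgi(d1, 0.75, InferenceSettings(n_boot=60, seed=3))

    def test_shifted_samples_detected(self):
        # samples 1..20 shifted by +2.0: every shifted sample must be
        # called at p0 = 0.01 and must rank strictly above every
        # unshifted one (whose tau-quantile is positive but small)
        rng = np.random.default_rng(1234)
        P, N = 10, 40
        values = rng.normal(0.0, 0.5, size=(P, N))
        values[:, :20] += 2.0
        annotation, matrix = make_matrix(P, N, values)
        design = build_design("C1", annotation, matrix)
        res = call_cgi(design, 0.85, InferenceSettings(n_boot=200, seed=7))
        assert np.all(res.sample_p_values[:20] < 0.01)
        assert res.sample_p_values[:20].max() < res.sample_p_values[20:].min()
        shift = res.sample_effects[:20].mean() - res.sample_effects[20:].mean()
        assert shift == pytest.approx(2.0, abs=0.3)

    def test_insufficient_data_skipped_with_reason(self, rng):
        annotation, matrix = make_matrix(2, 4, rng.normal(size=(2, 4)))
        design = build_design("C1", annotation, matrix)
        with pytest.raises(CgiSkipped) as exc:
            call_cgi(design, 0.85)
        assert exc.value.reason == "insufficient_data"

    def test_excluded_sample_reported_not_significant(self, rng):
        values = rng.normal(size=(8, 6))
        values[:, 4] = np.nan
        annotation, matrix = make_matrix(8, 6, values)
        design = build_design("C1", annotation, matrix)
        res = call_cgi(design, 0.75, InferenceSettings(n_boot=60, seed=4))
        i = res.sample_ids.index("S5")
        assert np.isnan(res.sample_effects[i])
        assert res.sample_p_values[i] == 1.0
        assert res.excluded_samples == ["S5"]


class TestMethylationScores:
    def make_result(self, cgi_id, pvals, tau=0.85):
        n = len(pvals)
        return qrmeth.QuantRegResult(
            cgi_id=cgi_id,
            tau=tau,
            sample_ids=[f"S{i}" for i in range(n)],
            sample_effects=np.zeros(n),
            sample_p_values=np.asarray(pvals, dtype=float),
            probe_ids=["P1"],
            probe_effects=np.zeros(1),
            objective=0.0,
            residuals=np.zeros(n),
            excluded_samples=[],
            converged=True,
        )

    def test_worked_example_38_of_40(self):
        pvals = np.full(40, 0.001)
        pvals[:2] = 0.5
        table = methylation_scores([self.make_result("C1", pvals)], [0.01])
        assert table.loc["C1", 0.01] == 38

    def test_all_insignificant_scores_zero(self):
        table = methylation_scores(
            [self.make_result("C1", np.ones(26))], [0.01, 0.02, 0.05]
        )
        assert (table.loc["C1"] == 0).all()

    def test_full_count_equals_n(self):
        table = methylation_scores(
            [self.make_result("C1", np.full(26, 0.001))], [0.01]
        )
        assert table.loc["C1", 0.01] == 26

    def test_strict_inequality_at_cutoff(self):
        table = methylation_scores(
            [self.make_result("C1", [0.01, 0.009, 0.5])], [0.01]
        )
        assert table.loc["C1", 0.01] == 1

    def test_monotone_in_p0(self, rng):
        results = [
            self.make_result(f"C{i}", rng.uniform(size=30)) for i in range(20)
        ]
        table = methylation_scores(results, [0.05, 0.04, 0.03, 0.02, 0.01])
        ordered = table[[0.01, 0.02, 0.03, 0.04, 0.05]]
        diffs = ordered.to_numpy()[:, 1:] - ordered.to_numpy()[:, :-1]
        assert (diffs >= 0).all()

    def test_duplicate_cgi_id_is_error(self):
        r = self.make_result("C1", np.ones(5))
        with pytest.raises(ValueError, match="duplicate"):
            methylation_scores([r, r], [0.01])

    def test_mixed_tau_is_error(self):
        a = self.make_result("C1", np.ones(5), tau=0.85)
        b = self.make_result("C2", np.ones(5), tau=0.75)
        with pytest.raises(ValueError, match="quantile"):
            methylation_scores([a, b], [0.01])


class TestCallDataset:
    def test_small_run_scores_bounded(self, small_dataset, small_call):
        score_tables, _, report = small_call
        table = score_tables[0.85]
        assert ((table >= 0) & (table <= 12)).all().all()
        assert (report["status"] == "fitted").all()

    def test_permutation_invariance(self):
        rng = np.random.default_rng(88)
        values = rng.normal(size=(6, 8))
        values[:, 1] += 1.5
        annotation, matrix = make_matrix(6, 8, values)
        st1, res1, _ = call_dataset(
            annotation, matrix, [0.8], [0.05], InferenceSettings(n_boot=60, seed=6)
        )
        perm = [3, 1, 0, 7, 6, 5, 2, 4]
        matrix2 = LogRatioMatrix(
            matrix.probe_ids,
            [matrix.sample_ids[j] for j in perm],
            values[:, perm],
        )
        st2, res2, _ = call_dataset(
            annotation, matrix2, [0.8], [0.05], InferenceSettings(n_boot=60, seed=6)
        )
        assert st1[0.8].loc["C1", 0.05] == st2[0.8].loc["C1", 0.05]
        assert res1[0.8][0].objective == pytest.approx(res2[0.8][0].objective,
                                                       abs=1e-8)
        e1 = dict(zip(res1[0.8][0].sample_ids, res1[0.8][0].sample_effects))
        e2 = dict(zip(res2[0.8][0].sample_ids, res2[0.8][0].sample_effects))
        for sid in e1:
            assert e1[sid] == pytest.approx(e2[sid], abs=1e-6)

    def test_worker_count_does_not_change_results(self, rng):
        values = rng.normal(size=(12, 6))
        annotation, matrix = make_matrix(
            12, 6, values, probes_per_cgi=[6, 6]
        )
        kw = dict(
            taus=[0.85],
            p0_grid=[0.01, 0.05],
            inference=InferenceSettings(n_boot=60, seed=8),
        )
        st1, _, _ = call_dataset(annotation, matrix, n_workers=1, **kw)
        st2, _, _ = call_dataset(annotation, matrix, n_workers=3, **kw)
        pd.testing.assert_frame_equal(st1[0.85], st2[0.85])

    def test_tiny_cgi_reported_skipped(self, rng):
        annotation, matrix = make_matrix(
            8, 4, rng.normal(size=(8, 4)), probes_per_cgi=[6, 2]
        )
        _, _, report = call_dataset(
            annotation, matrix, [0.85], [0.05], InferenceSettings(n_boot=60, seed=9)
        )
        skipped = report.set_index("cgi_id").loc["C2"]
        assert skipped["status"] == "skipped"
        assert skipped["reason"] == "insufficient_data"


def test_derived_seed_stable_and_bounded():
    s1 = derive_seed(123, "CGI_00042", 0.85)
    s2 = derive_seed(123, "CGI_00042", 0.85)
    assert s1 == s2
    assert 0 <= s1 < 2**31
    assert derive_seed(123, "CGI_00042", 0.8) != s1
    assert derive_seed(124, "CGI_00042", 0.85) != s1
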