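"""RDM construction, model matrices, decoding RDMs, and fusion."""

import numpy as np
import pytest

from speechtrack import group_stats as gs
from speechtrack import rsa_fusion as rf
from speechtrack.data_model import ALL_CONDITIONS, canonical_condition_index


def random_rdm_series(rng, n_t=12, scale=1.0):
    vals = np.zeros((n_t, 16, 16))
    idx = np.tril_indices(16, k=-1)
    for t in range(n_t):
        m = np.zeros((16, 16))
        m[idx] = 1.0 + scale * rng.standard_normal(120)
        vals[t] = np.clip(m + m.T, 0, 2)
    times = np.arange(n_t) * 1000.0 / 128.0
    return rf.RdmSeries(values=vals, times_ms=times)


class TestRdmContracts:
    def test_trf_rdm_basic_contracts(self, rng):
        w = rng.standard_normal((16, 8, 20))
        series = rf.trf_rdm_series(w, np.arange(-5, 15) * 1000.0 / 128.0,
                                   n_points=10)
        assert series.values.shape == (10, 16, 16)
        for t in range(10):
            rf.check_rdm(series.values[t], lo=0.0, hi=2.0)

    def test_identical_and_negated_conditions(self, rng):
        w = rng.standard_normal((16, 10, 4))
        w[3] = w[2]
        w[5] = -w[4]
        series = rf.trf_rdm_series(w, np.arange(4) * 7.8125, n_points=4)
        assert series.values[:, 2, 3] == pytest.approx(0.0, abs=1e-10)
        assert series.values[:, 4, 5] == pytest.approx(2.0, abs=1e-10)

    def test_invariance_under_common_monotone_transform(self, rng):
        w = rng.uniform(0.1, 2.0, size=(16, 12, 5))
        s1 = rf.trf_rdm_series(w, np.arange(5) * 7.8125, n_points=5)
        s2 = rf.trf_rdm_series(np.exp(w), np.arange(5) * 7.8125, n_points=5)
        assert np.allclose(s1.values, s2.values, atol=1e-12)

    def test_permutation_consistency(self, rng):
        w = rng.standard_normal((16, 8, 3))
        perm = rng.permutation(16)
        s = rf.trf_rdm_series(w, np.arange(3) * 7.8125, n_points=3)
        s_perm = rf.trf_rdm_series(w[perm], np.arange(3) * 7.8125, n_points=3)
        assert np.allclose(s_perm.values[:, :, :],
                           s.values[:, perm][:, :, perm], atol=1e-12)

    def test_check_rdm_rejects_violations(self):
        bad = np.ones((16, 16))
        with pytest.raises(ValueError, match="diagonal"):
            rf.check_rdm(bad)
        asym = np.zeros((16, 16))
        asym[0, 1] = 1.0
        with pytest.raises(ValueError, match="symmetric"):
            rf.check_rdm(asym)

    def test_rank_scale_is_display_only_in_unit_range(self, rng):
        m = np.zeros((16, 16))
        idx = np.tril_indices(16, k=-1)
        m[idx] = rng.uniform(0, 2, 120)
        scaled = rf.rank_scale(m + m.T)
        assert scaled.min() >= 0 and scaled.max() <= 1
        rf.check_rdm(scaled, lo=0, hi=1)


class TestModelRdm:
    def test_task_main_effect_block_structure(self):
        m = rf.model_rdm("task")
        assert np.array_equal(m[:8, :8], np.zeros((8, 8)))
        assert np.array_equal(m[8:, 8:], np.zeros((8, 8)))
        assert np.array_equal(m[:8, 8:], np.ones((8, 8)))

    def test_auditory_main_effect_definition(self):
        m = rf.model_rdm("auditory")
        for i, a in enumerate(ALL_CONDITIONS):
            for j, b in enumerate(ALL_CONDITIONS):
                assert m[i, j] == float(a.auditory != b.auditory)

    def test_interaction_differs_from_both_mains(self):
        inter = rf.model_rdm("task:auditory")
        assert not np.array_equal(inter, rf.model_rdm("task"))
        assert not np.array_equal(inter, rf.model_rdm("auditory"))
        rf.check_rdm(inter, lo=0, hi=1)

    def test_unknown_factor_rejected(self):
        with pytest.raises(ValueError, match="unknown factor"):
            rf.model_rdm("flavour")


class TestModelCorrelation:
    def test_model_correlates_perfectly_with_itself(self):
        model = rf.model_rdm("task")
        series = [rf.RdmSeries(np.repeat(model[None], 3, axis=0),
                               np.arange(3) * 7.8125, subject=s)
                  for s in ("a", "b")]
        tbl = rf.rdm_model_correlation(series, model, apply_fdr=False)
        assert np.allclose(tbl["mean_r"], 1.0)

    def test_model_plus_noise_detected_after_fdr(self, rng):
        model = rf.model_rdm("task")
        idx = np.tril_indices(16, k=-1)
        series = []
        for s in range(4):
            vals = []
            for t in range(10):
                m = np.zeros((16, 16))
                m[idx] = model[idx] + 0.3 * rng.standard_normal(120)
                vals.append(m + m.T)
            series.append(rf.RdmSeries(np.array(vals),
                                       np.arange(10) * 7.8125, subject=str(s)))
        tbl = rf.rdm_model_correlation(series, model)
        assert (tbl["mean_r"] > 0).all()
        assert tbl["significant"].all()

    def test_independent_rdms_reject_near_alpha(self, rng):
        model = rf.model_rdm("task")
        ps = []
        for _ in range(40):
            series = [random_rdm_series(rng, n_t=1, scale=0.5)
                      for _ in range(8)]
            tbl = rf.rdm_model_correlation(series, model, apply_fdr=False)
            ps.append(tbl["p"].iloc[0])
        assert np.mean(np.array(ps) < 0.05) < 0.2


class TestPairwiseDecodingRdm:
    def _patterns(self, rng, sep):
        means = rng.standard_normal((16, 5)) * sep
        pats = rng.standard_normal((16, 3, 4, 5)) + means[:, None, None, :]
        return pats

    def test_separable_conditions_decode_perfectly(self, rng):
        rdm = self._patterns(rng, sep=25.0)
        out = rf.pairwise_decoding_rdm(rdm)
        rf.check_rdm(out, lo=0, hi=1)
        tri = rf.lower_triangle(out)
        assert np.allclose(tri, 1.0)

    def test_identical_distributions_decode_at_chance(self, rng):
        out = rf.pairwise_decoding_rdm(self._patterns(rng, sep=0.0))
        tri = rf.lower_triangle(out)
        se = np.std(tri) / np.sqrt(tri.size)
        assert abs(tri.mean() - 0.5) < max(3 * se, 0.05)

    def test_injected_structure_matches_target_model(self, rng):
        model = rf.model_rdm("task")
        means = np.zeros((16, 6))
        means[:8, 0] = 4.0  # attend conditions shifted along one axis
        pats = rng.standard_normal((16, 3, 6, 6)) + means[:, None, None, :]
        out = rf.pairwise_decoding_rdm(pats)
        r = gs.partial_spearman(rf.lower_triangle(out),
                                rf.lower_triangle(model))
        assert r > 0.5

    def test_run_requirements(self, rng):
        with pytest.raises(ValueError):
            rf.pairwise_decoding_rdm(rng.standard_normal((16, 1, 4, 5)))


class TestFuse:
    def _setup(self, rng, n_t=8):
        series = {"dialogue": random_rdm_series(rng, n_t),
                  "background": random_rdm_series(rng, n_t)}
        return series

    def test_control_covariate_annihilates_task_model_roi(self, rng):
        series = self._setup(rng)
        task = rf.model_rdm("task")
        fmri = {"task-roi": np.repeat(task[None], 6, axis=0)}
        result = rf.fuse(series, fmri)
        assert np.nanmax(np.abs(result.table["mean_r"])) < 0.05

    def test_no_controls_reduces_to_plain_spearman(self, rng):
        series = self._setup(rng, n_t=3)
        roi = random_rdm_series(rng, 1).values[0]
        fmri = {"r": np.stack([roi, roi + 0.01])}
        res = rf.fuse(series, fmri, task_model=None, control_opposite=False)
        row = res.table[(res.table.stream == "dialogue")
                        & (res.table.time_ms == series["dialogue"].times_ms[0])]
        expected = np.mean([
            gs.partial_spearman(
                rf.lower_triangle(series["dialogue"].values[0]),
                rf.lower_triangle(m)) for m in fmri["r"]
        ])
        assert row["mean_r"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_structured_roi_peaks_at_assigned_time(self, rng):
        series = self._setup(rng, n_t=10)
        t_idx = 6
        template = series["dialogue"].values[t_idx]
        stack = np.stack([
            template + 0.02 * _sym_noise(rng) for _ in range(6)
        ])
        res = rf.fuse(series, {"structured": stack})
        peak = res.peak_latency_ms("structured", "dialogue")
        assert peak == pytest.approx(series["dialogue"].times_ms[t_idx])

    def test_mismatched_time_axes_rejected(self, rng):
        series = {"dialogue": random_rdm_series(rng, 4),
                  "background": random_rdm_series(rng, 5)}
        with pytest.raises(ValueError, match="time axes"):
            rf.fuse(series, {})


def _sym_noise(rng):
    m = np.zeros((16, 16))
    idx = np.tril_indices(16, k=-1)
    m[idx] = rng.standard_normal(120)
    return m + m.T
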