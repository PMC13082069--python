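"""Observable alignment, significance-masked correlation, pooling and
variant contrasts."""
import numpy as np
import pytest

from channelmd import (
    ObservableMatrix,
    ScalarTrace,
    TraceSpec,
    build_observable_matrix,
    contrast_reports,
    make_correlated_traces,
    pearson_report,
    pool_replicates,
)
from channelmd.errors import AlignmentError, ContrastError, DegenerateDataError, PoolingError


def two_traces(rho, n=5000, seed=1, relax=1.0, names=("a", "b")):
    spec = TraceSpec(
        n_frames=n,
        means=[0.0, 0.0],
        sds=[1.0, 1.0],
        target_correlation=[[1.0, rho], [rho, 1.0]],
        relaxation_frames=relax,
        seed=seed,
        names=list(names),
    )
    return make_correlated_traces(spec)


class TestBuildObservableMatrix:
    def test_same_grid_is_column_stack(self):
        a = ScalarTrace("a", np.arange(10.0))
        b = ScalarTrace("b", np.arange(10.0) ** 2)
        obs = build_observable_matrix([a, b])
        np.testing.assert_array_equal(obs.samples[:, 0], a.values)
        np.testing.assert_array_equal(obs.samples[:, 1], b.values)

    def test_intersect_stride_keeps_common_frames(self):
        fine = ScalarTrace("fine", np.arange(100.0), frame_dt=1.0)
        coarse = ScalarTrace("coarse", np.arange(10.0), frame_dt=10.0)
        obs = build_observable_matrix([fine, coarse], alignment="intersect_stride")
        assert obs.samples.shape == (10, 2)
        np.testing.assert_array_equal(obs.samples[:, 0], np.arange(0.0, 100.0, 10.0))

    def test_resample_exact_for_linear_signals(self):
        a = ScalarTrace("a", 2.0 * np.arange(31.0), frame_dt=2.0)  # t = 0..60
        b = ScalarTrace("b", 1.0 + 3.0 * np.arange(21.0), frame_dt=3.0)
        obs = build_observable_matrix([a, b], alignment="resample")
        t = np.arange(obs.samples.shape[0]) * obs.frame_dt
        np.testing.assert_allclose(obs.samples[:, 0], t, atol=1e-9)
        np.testing.assert_allclose(obs.samples[:, 1], 1.0 + t, atol=1e-9)

    def test_non_commensurate_strides_suggest_resample(self):
        # grids share only t = 0 within the trace extent
        a = ScalarTrace("a", np.arange(50.0), frame_dt=0.7)
        b = ScalarTrace("b", np.arange(50.0), frame_dt=0.73)
        with pytest.raises(AlignmentError, match="resample"):
            build_observable_matrix([a, b], alignment="intersect_stride")

    def test_angular_trace_unwrapped_and_flagged(self):
        # angle drifting across the -180/180 seam: unwrapping keeps it smooth
        drift = np.linspace(160.0, 220.0, 50)
        wrapped = (drift + 180.0) % 360.0 - 180.0
        ang = ScalarTrace("theta", wrapped, angular=True)
        other = ScalarTrace("d", np.linspace(0, 1, 50))
        obs = build_observable_matrix([ang, other])
        np.testing.assert_allclose(np.diff(obs.samples[:, 0]), np.diff(drift), atol=1e-9)
        assert obs.provenance["theta"]["linearization_reliable"]


class TestPearsonReport:
    def test_self_correlation_significant(self):
        x = np.random.default_rng(0).normal(size=200)
        obs = ObservableMatrix(["a", "b"], np.column_stack([x, x * 2.0 + 1.0]), 1.0)
        rep = pearson_report(obs)
        assert rep.r[0, 1] == pytest.approx(1.0)
        assert rep.mask[0, 1]

    def test_planted_correlation_recovered_and_significant(self):
        a, b = two_traces(0.8, n=5000, seed=1)
        obs = build_observable_matrix([a, b])
        rep = pearson_report(obs)
        assert rep.r[0, 1] == pytest.approx(0.8, abs=0.05)
        assert rep.p[0, 1] < 0.05 and rep.mask[0, 1]

    def test_type_one_error_rate_without_correction(self):
        # ~5% of independent white-noise pairs look significant at alpha=0.05
        rng = np.random.default_rng(42)
        hits = 0
        n_pairs = 200
        for _ in range(n_pairs):
            x = rng.normal(size=(1000, 2))
            rep = pearson_report(
                ObservableMatrix(["a", "b"], x, 1.0), autocorrelation_correction=False
            )
            hits += int(rep.mask[0, 1])
        # generous binomial band around the nominal 0.05 for 200 trials
        assert 0.01 <= hits / n_pairs <= 0.10

    def test_uncorrected_p_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(3)
        x = rng.normal(size=(300, 2))
        rep = pearson_report(
            ObservableMatrix(["a", "b"], x, 1.0), autocorrelation_correction=False
        )
        r_ref, p_ref = pearsonr(x[:, 0], x[:, 1])
        assert rep.r[0, 1] == pytest.approx(r_ref, abs=1e-12)
        assert rep.p[0, 1] == pytest.approx(p_ref, rel=1e-6)

    def test_zero_variance_column_named(self):
        x = np.column_stack([np.arange(10.0), np.full(10, 2.0)])
        with pytest.raises(DegenerateDataError, match="b"):
            pearson_report(ObservableMatrix(["a", "b"], x, 1.0))

    def test_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(500, 3))
        rep0 = pearson_report(ObservableMatrix(list("abc"), x, 1.0))
        scales = rng.uniform(0.5, 5.0, 3)
        shifts = rng.uniform(-10, 10, 3)
        rep1 = pearson_report(ObservableMatrix(list("abc"), x * scales + shifts, 1.0))
        np.testing.assert_allclose(rep0.r, rep1.r, atol=1e-12)

    def test_mask_monotone_in_alpha(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(400, 6))
        obs = ObservableMatrix([f"o{i}" for i in range(6)], x, 1.0)
        prev = None
        for alpha in (0.001, 0.01, 0.05, 0.2):
            mask = pearson_report(obs, alpha=alpha).mask
            if prev is not None:
                assert np.all(mask | ~prev)  # prev subset of mask
            prev = mask


class TestPooling:
    def test_identical_replicates_concat_fixed_point(self):
        a, b = two_traces(0.6, n=2000, seed=5)
        obs = build_observable_matrix([a, b])
        single = pearson_report(obs)
        pooled = pool_replicates([obs, obs, obs], method="concat")
        assert pooled.r[0, 1] == pytest.approx(single.r[0, 1], abs=1e-12)

    def test_fisher_z_fixed_point(self):
        a, b = two_traces(0.5, n=2000, seed=8)
        rep = pearson_report(build_observable_matrix([a, b]))
        pooled = pool_replicates([rep, rep], method="fisher_z")
        assert pooled.r[0, 1] == pytest.approx(rep.r[0, 1], abs=1e-12)

    def test_mean_shift_attenuation_without_standardization(self):
        reps = []
        raw = []
        for k, seed in enumerate((11, 12, 13)):
            a, b = two_traces(0.8, n=3000, seed=seed)
            x = np.column_stack([a.values, b.values])
            x[:, 0] += 10.0 * k  # between-replicate mean shift on one observable
            reps.append(ObservableMatrix(["a", "b"], x, 1.0))
            raw.append(x)
        pooled = pool_replicates(reps, method="concat")
        assert pooled.r[0, 1] == pytest.approx(0.8, abs=0.05)
        naive = np.corrcoef(np.vstack(raw), rowvar=False)[0, 1]
        assert naive < pooled.r[0, 1] - 0.1  # attenuated without standardization

    def test_roster_mismatch(self):
        a, b = two_traces(0.5, n=100, seed=1)
        c, d = two_traces(0.5, n=100, seed=2, names=("c", "d"))
        with pytest.raises(PoolingError):
            pool_replicates(
                [build_observable_matrix([a, b]), build_observable_matrix([c, d])]
            )


class TestContrast:
    def report_with(self, rho_ab, seed, extra_names=("c",)):
        names = ["a", "b", *extra_names]
        m = len(names)
        corr = np.eye(m)
        corr[0, 1] = corr[1, 0] = rho_ab
        spec = TraceSpec(
            n_frames=4000,
            means=np.zeros(m),
            sds=np.ones(m),
            target_correlation=corr,
            relaxation_frames=1.0,
            seed=seed,
            names=names,
        )
        traces = make_correlated_traces(spec)
        return pearson_report(build_observable_matrix(traces))

    def test_identical_reports_all_preserved(self):
        rep = self.report_with(0.8, seed=1)
        contrast = contrast_reports(rep, rep, r_change_min=0.3)
        assert set(contrast.rows.status) <= {"preserved"}
        assert ("a", "b") in contrast.pairs_with_status("preserved")

    def test_lost_coupling_detected(self):
        ref = self.report_with(0.8, seed=1)
        var = self.report_with(0.0, seed=2)
        contrast = contrast_reports(ref, var, r_change_min=0.3)
        assert contrast.pairs_with_status("lost") == [("a", "b")]
        assert not contrast.pairs_with_status("gained")

    def test_sign_flip_detected(self):
        ref = self.report_with(0.6, seed=3)
        var = self.report_with(-0.6, seed=4)
        contrast = contrast_reports(ref, var, r_change_min=0.3)
        assert contrast.pairs_with_status("sign_flipped") == [("a", "b")]

    def test_roster_mismatch_rejected(self):
        ref = self.report_with(0.5, seed=1)
        var = self.report_with(0.5, seed=1, extra_names=("z",))
        with pytest.raises(ContrastError):
            contrast_reports(ref, var)
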