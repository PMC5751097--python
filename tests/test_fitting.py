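"""Weight fitting, accuracy functionals, frequency search, segmentation, AICc."""

import numpy as np
import pytest

from cnmotion import (
    BasisConfig,
    MarkerTrajectory,
    Segmentation,
    SynthSpec,
    accuracy_report,
    aicc,
    average_marker_search,
    fit_at_frequencies,
    fit_segmented,
    fit_weights,
    generate_segmented,
    generate_trajectory,
    model_scan,
    predict,
    predict_segmented,
    search_frequencies,
    transfer_fit,
)
from cnmotion.errors import (
    ConfigError,
    DataError,
    DegenerateChannelError,
    InvalidParameterError,
    SmallSampleError,
)
from cnmotion.fitting import (
    GridSearch,
    RandomSearch,
    _objective_batch,
    _objective_loop,
)
from cnmotion.oscillators import hz_to_rad

#: the standard recovery grid used across these tests (Hz)
RECOVERY_GRID = GridSearch(lo_hz=0.05, hi_hz=2.0, step_hz=0.01)


class TestFitWeights:
    def test_recovers_exact_weights(self):
        rng = np.random.default_rng(0)
        D = rng.standard_normal((60, 8))
        W0 = rng.standard_normal((3, 8))
        W = fit_weights(D, D @ W0.T, ridge=0.0)
        assert np.abs(W - W0).max() < 1e-8

    def test_zero_targets_zero_weights(self):
        rng = np.random.default_rng(1)
        D = rng.standard_normal((20, 5))
        assert np.abs(fit_weights(D, np.zeros((20, 2)))).max() == 0.0

    def test_residual_matches_pseudoinverse_oracle(self):
        rng = np.random.default_rng(2)
        D = rng.standard_normal((40, 10))
        Y = rng.standard_normal((40, 3))
        W = fit_weights(D, Y, ridge=0.0)
        W_pinv = (np.linalg.pinv(D) @ Y).T
        r1 = np.linalg.norm(Y - D @ W.T)
        r2 = np.linalg.norm(Y - D @ W_pinv.T)
        assert abs(r1 - r2) < 1e-8
        assert np.abs(W - W_pinv).max() < 1e-8

    def test_ridge_shrinks_norm(self):
        rng = np.random.default_rng(3)
        D = rng.standard_normal((30, 6))
        Y = rng.standard_normal((30, 2))
        w0 = np.linalg.norm(fit_weights(D, Y, ridge=0.0))
        w1 = np.linalg.norm(fit_weights(D, Y, ridge=10.0))
        assert w1 < w0

    def test_rejects_non_finite(self):
        with pytest.raises(DataError):
            fit_weights(np.array([[np.nan]]), np.array([[1.0]]))


class TestPredictAndAccuracy:
    def test_zero_weights_zero_output(self, two_center_clip):
        traj, truth = two_center_clip
        model = type(truth.model)(
            bank=truth.model.bank,
            basis=truth.model.basis,
            W=np.zeros_like(truth.model.W),
            channels=truth.model.channels,
        )
        assert np.abs(predict(model, traj.times)).max() == 0.0

    def test_prediction_matches_direct_formula(self, two_center_clip):
        traj, truth = two_center_clip
        from cnmotion.basis import design_matrix
        from cnmotion.oscillators import harmonic_states

        states = harmonic_states(truth.model.bank, traj.times)
        direct = design_matrix(states, truth.model.basis) @ truth.model.W.T
        assert np.abs(predict(truth.model, traj.times) - direct).max() < 1e-12

    def test_perfect_prediction_zero_error(self):
        obs = np.random.default_rng(0).standard_normal((50, 3))
        rep = accuracy_report(obs, obs)
        assert rep.rss == 0.0 and rep.integral_rel == 0.0 and rep.abs_error == 0.0

    def test_hand_arithmetic(self):
        # X=(1,2) observed vs (0,2) predicted on one axis
        obs = np.column_stack([[1.0, 2.0], [1.0, 1.0], [1.0, 1.0]])
        pred = np.column_stack([[0.0, 2.0], [1.0, 1.0], [1.0, 1.0]])
        rep = accuracy_report(obs, pred)
        assert rep.eps2[0] == pytest.approx(1.0)
        assert rep.eps2_rel[0] == pytest.approx(1.0 / 5.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        obs = rng.standard_normal((30, 3))
        pred = rng.standard_normal((30, 3))
        rep = accuracy_report(obs, pred)
        for a in range(3):
            e2 = sum((obs[k, a] - pred[k, a]) ** 2 for k in range(30))
            assert rep.eps2[a] == pytest.approx(e2, rel=1e-12)
            assert rep.eps2_rel[a] == pytest.approx(
                e2 / sum(obs[k, a] ** 2 for k in range(30)), rel=1e-12
            )
        d = np.mean([np.linalg.norm(obs[k] - pred[k]) for k in range(30)])
        assert rep.abs_error == pytest.approx(d, rel=1e-12)

    def test_zero_denominator_names_axis(self):
        obs = np.zeros((10, 3))
        obs[:, 0] = 1.0
        obs[:, 2] = 1.0
        with pytest.raises(DegenerateChannelError, match="'y'"):
            accuracy_report(obs, obs)

    def test_scale_equivariance(self, two_center_clip):
        traj, truth = two_center_clip
        pred = predict(truth.model, traj.times) + 0.05
        obs = traj.marker_xyz("m01")
        rep1 = accuracy_report(obs, pred)
        c = 3.7
        rep2 = accuracy_report(c * obs, c * pred)
        assert np.allclose(rep2.eps2, c**2 * rep1.eps2, rtol=1e-12)
        assert np.allclose(rep2.eps2_rel, rep1.eps2_rel, rtol=1e-12)
        assert rep2.abs_error == pytest.approx(c * rep1.abs_error, rel=1e-12)


class TestObjectiveEngine:
    def test_batch_equals_scalar_loop(self, two_center_clip, rbf25):
        traj, _ = two_center_clip
        Y, _ = traj.channel_matrix()
        times = traj.times - traj.times[0]
        rng = np.random.default_rng(6)
        cands = np.sort(hz_to_rad(rng.uniform(0.1, 2.0, (12, 2))), axis=1)
        ob = _objective_batch(times, Y, cands, rbf25, None)
        ol = _objective_loop(times, Y, cands, rbf25, None)
        assert np.abs(ob - ol).max() < 1e-9

    def test_nested_satellites_monotone_rss(self, two_center_clip):
        # nested center subsets of one 160-point placement, shared sharpness,
        # exact least squares: adding satellites can only reduce error
        traj, truth = two_center_clip
        from cnmotion.basis import default_sharpness, place_center_indices
        from cnmotion.oscillators import harmonic_states

        states = harmonic_states(truth.model.bank, traj.times)
        base = states.q[place_center_indices(traj.K, 160)]
        b = default_sharpness(base)
        prev = np.inf
        for step in (16, 8, 4, 2, 1):
            centers = base[::step]
            cfg = BasisConfig(
                "rbf", centers.shape[0], centers=centers, sharpness=b
            )
            _, reports = fit_at_frequencies(
                traj, truth.model.bank.omega, cfg, ridge=0.0
            )
            val = reports["m01"].integral_rel2
            assert val <= prev + 1e-12
            prev = val


class TestFrequencySearch:
    def test_recovers_generator_frequencies(self, two_center_clip, rbf25):
        traj, truth = two_center_clip
        res = search_frequencies(traj, "m01", 2, RECOVERY_GRID, rbf25)
        assert np.abs(res.omega_hz - truth.freqs_hz).max() <= 0.01 + 1e-9
        assert res.reports["m01"].integral_rel < 1e-3

    def test_dc_channel_tie_breaks_to_smallest(self):
        times = np.arange(120) / 120.0
        coords = np.full((120, 1, 3), 2.0)
        traj = MarkerTrajectory(
            times=times, markers=["m01"], coords=coords, sampling_rate=120.0
        )
        grid = GridSearch(0.2, 0.4, 0.1)
        res = search_frequencies(
            traj, "m01", 1, grid, BasisConfig("rbf", 10)
        )
        assert res.omega_hz[0] == pytest.approx(0.2, abs=1e-12)

    def test_grid_candidates_and_validation(self):
        g = GridSearch(0.1, 0.3, 0.1)
        assert np.allclose(g.candidates(1).ravel(), [0.1, 0.2, 0.3])
        assert g.candidates(2).shape == (6, 2)
        with pytest.raises(ConfigError):
            GridSearch(0.5, 0.1, 0.01).candidates(1)
        with pytest.raises(ConfigError):
            g.candidates(3)
        with pytest.raises(InvalidParameterError):
            search_frequencies(None, "m", 6, g, BasisConfig("rbf", 5))

    def test_random_search_deterministic(self, two_center_clip, rbf25):
        traj, _ = two_center_clip
        rs = RandomSearch(seed=9, budget=50, lo_hz=0.2, hi_hz=1.6)
        r1 = search_frequencies(traj, "m01", 3, rs, rbf25)
        r2 = search_frequencies(traj, "m01", 3, rs, rbf25)
        assert np.array_equal(r1.omega, r2.omega)
        assert np.array_equal(r1.trace_objective, r2.trace_objective)

    def test_time_shift_invariance_full_period(self, rbf25):
        # sampling the generator one common full period later reproduces the
        # same values, so the searched objective is unchanged
        spec = SynthSpec(seed=13, n_centers=2, freqs_hz=(0.5, 1.5),
                         n_satellites=25, duration_s=8.0)
        traj, truth = generate_trajectory(spec)
        vals = predict(truth.model, traj.times + 2.0)  # 1 and 3 full periods
        shifted = MarkerTrajectory(
            times=traj.times,
            markers=traj.markers,
            coords=vals.reshape(traj.K, 1, 3),
            sampling_rate=traj.sampling_rate,
        )
        grid = GridSearch(0.3, 1.7, 0.05)
        r1 = search_frequencies(traj, "m01", 2, grid, rbf25)
        r2 = search_frequencies(shifted, "m01", 2, grid, rbf25)
        assert np.array_equal(r1.omega, r2.omega)
        assert r2.objective == pytest.approx(r1.objective, abs=1e-9)

    def test_time_axis_relabel_invariance(self, rbf25):
        # the oscillator phase is anchored at the first fitted frame, so
        # relabeling the time axis (same samples, shifted stamps) leaves the
        # whole search unchanged
        spec = SynthSpec(seed=14, n_centers=2, freqs_hz=(0.5, 1.3),
                         n_satellites=25, duration_s=6.0)
        traj, _ = generate_trajectory(spec)
        relabeled = MarkerTrajectory(
            times=traj.times + 17.03,
            markers=traj.markers,
            coords=traj.coords,
            sampling_rate=traj.sampling_rate,
        )
        grid = GridSearch(0.4, 1.4, 0.05)
        r1 = search_frequencies(traj, "m01", 2, grid, rbf25)
        r2 = search_frequencies(relabeled, "m01", 2, grid, rbf25)
        assert np.array_equal(r1.omega, r2.omega)
        # rebasing to the segment start reproduces the relative time grid up
        # to float rounding of the stamps
        assert np.allclose(r1.trace_objective, r2.trace_objective,
                           rtol=1e-6, atol=1e-8)


    def test_cosine_family_self_consistency(self):
        # data generated from the cosine basis itself is reproduced exactly
        # at the generating frequency and recovered by a local grid search
        # (the cosine family spans only functions even in q, so subharmonic
        # aliases exist on wide grids; see docs/methods.md)
        spec = SynthSpec(seed=17, n_centers=1, freqs_hz=(1.0,),
                         n_satellites=8, family="harmonic", duration_s=6.0)
        traj, truth = generate_trajectory(spec)
        cfg = BasisConfig("harmonic", 8)
        _, reports = fit_at_frequencies(traj, truth.model.bank.omega, cfg)
        assert reports["m01"].integral_rel < 1e-8
        res = search_frequencies(
            traj, "m01", 1, GridSearch(0.7, 1.3, 0.01), cfg
        )
        assert res.omega_hz[0] == pytest.approx(1.0, abs=1e-12)

    def test_accuracy_wrapper_selects_marker_channels(self, four_marker_clip):
        from cnmotion import accuracy

        traj, truth = four_marker_clip
        pred = predict(truth.model, traj.times)
        rep = accuracy(traj, pred, "m03", channels=truth.model.channels)
        obs = traj.marker_xyz("m03")
        cols = [truth.model.channels.index(f"m03/{a}") for a in "xyz"]
        direct = accuracy_report(obs, pred[:, cols])
        assert rep.integral_rel == direct.integral_rel


class TestTransfer:
    def test_shared_generator_transfers(self, four_marker_clip, rbf25):
        traj, truth = four_marker_clip
        res = search_frequencies(traj, "m01", 2, RECOVERY_GRID, rbf25)
        _, reports = transfer_fit(res.omega, traj, rbf25)
        for rep in reports.values():
            assert rep.integral_rel < 1e-3

    def test_idempotent_on_source_marker(self, four_marker_clip, rbf25):
        traj, _ = four_marker_clip
        res = search_frequencies(traj, "m01", 2, RECOVERY_GRID, rbf25)
        _, reports = transfer_fit(res.omega, traj, rbf25, markers=["m01"])
        assert reports["m01"].integral_rel == pytest.approx(
            res.reports["m01"].integral_rel, rel=1e-9, abs=1e-15
        )

    def test_mismatched_generator_transfers_worse(self, rbf25):
        # build a 2-marker trajectory whose markers come from different
        # frequency pairs; frequencies learned on marker 1 fit marker 2 worse
        # than marker 2's own search
        t1, _ = generate_trajectory(
            SynthSpec(seed=15, freqs_hz=(0.5, 1.3), n_satellites=25)
        )
        t2, _ = generate_trajectory(
            SynthSpec(seed=16, freqs_hz=(0.7, 0.9), n_satellites=25)
        )
        traj = MarkerTrajectory(
            times=t1.times,
            markers=["a", "b"],
            coords=np.concatenate([t1.coords, t2.coords], axis=1),
            sampling_rate=t1.sampling_rate,
        )
        grid = GridSearch(0.3, 1.5, 0.01)
        res_a = search_frequencies(traj, "a", 2, grid, rbf25)
        _, transferred = transfer_fit(res_a.omega, traj, rbf25, markers=["b"])
        res_b = search_frequencies(traj, "b", 2, grid, rbf25)
        assert (
            transferred["b"].integral_rel2 > res_b.reports["b"].integral_rel2
        )


class TestAverageMarkerSearch:
    def test_reduces_to_single_marker(self, two_center_clip, rbf25):
        traj, _ = two_center_clip
        grid = GridSearch(0.3, 1.5, 0.05)
        r1 = search_frequencies(traj, "m01", 2, grid, rbf25)
        r2 = average_marker_search(traj, 2, grid, rbf25)
        assert np.array_equal(r1.omega, r2.omega)
        assert np.allclose(r1.trace_objective, r2.trace_objective)

    def test_objective_is_sum_of_marker_objectives(self, four_marker_clip, rbf25):
        traj, _ = four_marker_clip
        grid = GridSearch(0.4, 0.6, 0.1)
        avg = average_marker_search(traj, 1, grid, rbf25)
        per_marker = [
            search_frequencies(traj, m, 1, grid, rbf25).trace_objective
            for m in traj.markers
        ]
        assert np.allclose(avg.trace_objective, np.sum(per_marker, axis=0),
                           rtol=1e-10, atol=1e-12)

    def test_consistent_with_single_marker_grid_step(self, four_marker_clip, rbf25):
        traj, truth = four_marker_clip
        grid = GridSearch(0.4, 1.4, 0.01)
        avg = average_marker_search(traj, 2, grid, rbf25)
        single = search_frequencies(traj, "m02", 2, grid, rbf25)
        assert np.abs(avg.omega_hz - single.omega_hz).max() <= 0.01 + 1e-9


class TestSegmentation:
    def test_boundary_conventions(self):
        seg = Segmentation([1, 601, 1201])
        assert seg.frame_slices(1200) == [(0, 600), (600, 1200)]
        # trailing boundary K+1 clips to K; a single segment covers all frames
        assert Segmentation([1, 1201]).frame_slices(1200) == [(0, 1200)]
        assert Segmentation([1, 1200]).frame_slices(1200) == [(0, 1200)]

    def test_validation(self):
        with pytest.raises(InvalidParameterError):
            Segmentation([5, 5])
        with pytest.raises(InvalidParameterError):
            Segmentation([0, 10])
        with pytest.raises(InvalidParameterError):
            Segmentation([1, 50]).frame_slices(20)

    def test_single_segment_equals_plain_fit(self, two_center_clip, rbf25):
        traj, _ = two_center_clip
        grid = GridSearch(0.4, 1.4, 0.05)
        seg_fit = fit_segmented(
            traj, Segmentation([1, traj.K + 1]), 2, grid, rbf25
        )
        plain = search_frequencies(traj, "m01", 2, grid, rbf25)
        assert np.array_equal(seg_fit.results[0].omega, plain.omega)
        assert seg_fit.results[0].reports["m01"].integral_rel == pytest.approx(
            plain.reports["m01"].integral_rel, rel=1e-9, abs=1e-15
        )

    def test_piecewise_recovery_and_improvement(self, rbf25):
        spec = SynthSpec(
            seed=21, n_centers=1, freqs_hz=None, n_satellites=25,
            segments=((5.0, (0.5,)), (5.0, (1.5,))),
        )
        traj, seg, truth = generate_segmented(spec)
        grid = GridSearch(0.05, 2.0, 0.01)
        sf = fit_segmented(traj, seg, 1, grid, rbf25)
        for res, f_true in zip(sf.results, truth.segment_freqs_hz):
            assert np.abs(res.omega_hz - f_true).max() <= 0.01 + 1e-9
        pred = predict_segmented(sf, traj)
        rss_seg = float(np.sum((traj.channel_matrix()[0] - pred) ** 2))
        single = search_frequencies(traj, "m01", 1, grid, rbf25)
        assert rss_seg < single.reports["m01"].rss
        assert sf.seam_jumps.shape == (1,)

    def test_prediction_covers_each_frame_once(self, rbf25):
        spec = SynthSpec(
            seed=22, n_centers=1, freqs_hz=None, n_satellites=20,
            segments=((3.0, (0.6,)), (3.0, (1.1,))),
        )
        traj, seg, _ = generate_segmented(spec)
        sf = fit_segmented(traj, seg, 1, GridSearch(0.4, 1.4, 0.05), rbf25)
        pred = predict_segmented(sf, traj)
        assert pred.shape == (traj.K, 3)
        assert np.all(np.isfinite(pred))


class TestAicc:
    def test_monotone_in_rss(self):
        assert aicc(0.5, 100, 10) < aicc(1.0, 100, 10)

    def test_closed_form_when_rss_equals_n(self):
        n, k = 100, 10
        assert aicc(float(n), n, k) == pytest.approx(
            2 * k + 2 * k * (k + 1) / (n - k - 1)
        )

    def test_arithmetic_oracle(self):
        n, k, rss = 100, 10, 1.0
        expected = n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(rss, n, k) == pytest.approx(expected, rel=1e-15)

    def test_small_sample_guard(self):
        with pytest.raises(SmallSampleError):
            aicc(1.0, 12, 11)

    def test_scan_single_candidate_and_recomputation(self, two_center_clip):
        traj, _ = two_center_clip
        sc = model_scan(
            traj, [2], [20], grid=GridSearch(0.4, 1.4, 0.05), seed=0
        )
        assert (sc.best_n, sc.best_satellites) == (2, 20)
        row = sc.table.iloc[0]
        fit = sc.fits[(2, 20)]
        rss = sum(r.rss for r in fit.reports.values())
        k = fit.model.W.size + 2
        assert row["aicc"] == pytest.approx(
            aicc(rss, 3 * traj.K * len(traj.markers), k)
        )
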