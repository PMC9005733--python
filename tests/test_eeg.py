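"""RCA, projection, time-expanded deconvolution and slope extraction."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg

from jointddm import eeg, prep, synthetic
from jointddm.eeg import (EEGRecording, ReliableComponent, choose_lambda,
                          deconvolve, extract_slope, modal_lambda, project,
                          rca)
from jointddm.synthetic import EEGSimConfig, GroundTruth


def _rank1_epochs(n_trials=40, n_ch=6, n_t=50, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    topo = np.array([0.1, 0.4, 0.9, 1.0, 0.6, 0.2])[:n_ch]
    wave = np.sin(np.linspace(0, 2 * np.pi, n_t))
    epochs = np.stack([np.outer(topo, wave * rng.normal(1.0, 0.2))
                       + noise * rng.standard_normal((n_ch, n_t))
                       for _ in range(n_trials)])
    return epochs, topo, wave


class TestRCA:
    def test_rank1_forward_projection_recovers_topography(self):
        epochs, topo, _ = _rank1_epochs(noise=0.01)
        comp = rca(epochs, n_components=1)[0]
        r = np.corrcoef(comp.forward, topo)[0, 1]
        assert abs(r) > 0.999

    def test_eigenvalues_match_dense_generalized_eigensolver(self):
        """3-channel toy: RCA reliabilities equal an independent dense
        generalized-eigenvalue solution to 1e-8."""
        rng = np.random.default_rng(1)
        epochs = rng.standard_normal((12, 3, 30))
        epochs += 0.5 * epochs.mean(axis=0, keepdims=True)  # shared signal
        comps = rca(epochs, n_components=3, shrinkage=0.01)
        # independent covariance computation: explicit pair loop
        n, c, t = epochs.shape
        across = np.zeros((c, c))
        for i in range(n):
            for j in range(n):
                if i != j:
                    across += epochs[i] @ epochs[j].T
        across /= n * (n - 1) * t
        within = sum(e @ e.T for e in epochs) / (n * t)
        within_reg = within + 0.01 * (np.trace(within) / c) * np.eye(c)
        ref = np.sort(scipy.linalg.eigvals(np.linalg.inv(within_reg) @ across).real)[::-1]
        got = np.array([cp.reliability for cp in comps])
        np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_trial_order_permutation_invariance(self):
        epochs, _, _ = _rank1_epochs(noise=0.3, seed=2)
        comps1 = rca(epochs, n_components=2)
        perm = np.random.default_rng(3).permutation(len(epochs))
        comps2 = rca(epochs[perm], n_components=2)
        for c1, c2 in zip(comps1, comps2):
            np.testing.assert_allclose(c1.weights, c2.weights, atol=1e-10)
            assert abs(c1.reliability - c2.reliability) < 1e-12

    def test_explained_fractions_sum_to_at_most_one(self):
        epochs, _, _ = _rank1_epochs(noise=0.5, seed=4)
        comps = rca(epochs, n_components=6)
        fr = [c.explained for c in comps]
        assert all(f >= 0 for f in fr)
        assert sum(fr) <= 1.0 + 1e-9
        assert fr == sorted(fr, reverse=True)

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            rca(np.zeros((1, 3, 10)))


class TestProject:
    def _rec(self, signal):
        ev = pd.DataFrame({"type": ["stimulus"], "sample": [0],
                           "difficulty": ["easy"], "rt": [0.5], "trial": [0]})
        return EEGRecording(signal=signal, rate=250.0, events=ev)

    def test_unit_weight_selects_channel(self):
        sig = np.random.default_rng(0).standard_normal((4, 100))
        w = np.zeros(4)
        w[2] = 1.0
        comp = ReliableComponent(weights=w, forward=w, reliability=1.0,
                                 explained=1.0)
        np.testing.assert_array_equal(project(self._rec(sig), comp), sig[2])

    def test_linearity_in_weights(self):
        sig = np.random.default_rng(1).standard_normal((4, 100))
        w1 = np.array([1.0, 0, 0, 0])
        w2 = np.array([0, 2.0, 0, 0])
        mk = lambda w: ReliableComponent(weights=w, forward=w, reliability=1, explained=1)
        rec = self._rec(sig)
        np.testing.assert_allclose(project(rec, mk(w1 + w2)),
                                   project(rec, mk(w1)) + project(rec, mk(w2)),
                                   rtol=1e-12)


def _isolated_series(rate=250.0, n_events=8, gap=3.0, seed=0, noise=0.0):
    """Events spaced far beyond the deconvolution window: the regression
    ERP must equal the plain epoch average."""
    rng = np.random.default_rng(seed)
    kern = {"easy": np.hanning(50) * 2.0, "difficult": np.hanning(50)}
    n = int((n_events + 2) * gap * rate)
    series = noise * rng.standard_normal(n)
    rows = []
    for i in range(n_events):
        s = int((i + 1) * gap * rate)
        level = "easy" if i % 2 == 0 else "difficult"
        series[s:s + 50] += kern[level]
        rows.append({"type": "stimulus", "sample": s, "difficulty": level,
                     "rt": 0.5, "trial": i})
    return series, pd.DataFrame(rows), kern


class TestDeconvolve:
    def test_orthogonal_design_equals_epoch_average(self):
        series, events, kern = _isolated_series()
        betas, times = deconvolve(series, events, 250.0, window=(-0.2, 0.4))
        for level in ("easy", "difficult"):
            got = betas[("stimulus", level)]
            sel = (times >= 0) & (times < 0.2)
            np.testing.assert_allclose(got[sel], kern[level], atol=1e-8)
            np.testing.assert_allclose(got[~sel], 0.0, atol=1e-8)

    def test_ols_matches_dense_lstsq_oracle(self):
        rng = np.random.default_rng(5)
        series = rng.standard_normal(400)
        events = pd.DataFrame({
            "type": ["stimulus", "response", "stimulus", "response"],
            "sample": [50, 120, 200, 290],
            "difficulty": ["easy", "easy", "difficult", "difficult"],
            "rt": [0.3] * 4, "trial": [0, 0, 1, 1]})
        betas, times = deconvolve(series, events, 250.0, window=(-0.02, 0.04))
        nl = len(times)
        # dense design built independently
        X = np.zeros((400, 4 * nl))
        cols = [("stimulus", "difficult"), ("stimulus", "easy"),
                ("response", "difficult"), ("response", "easy")]
        for _, ev in events.iterrows():
            ci = cols.index((ev["type"], ev["difficulty"]))
            for k, lag in enumerate(range(-5, 10)):
                r = ev["sample"] + lag
                if 0 <= r < 400:
                    X[r, ci * nl + k] = 1.0
        ref, *_ = np.linalg.lstsq(X, series, rcond=None)
        got = np.concatenate([betas[c] for c in cols])
        np.testing.assert_allclose(got, ref, atol=1e-8)

    def test_ridge_shrinks_coefficients_monotonically(self):
        series, events, _ = _isolated_series(noise=0.5, seed=6)
        norms = []
        for lam in (0.0, 1.0, 10.0, 100.0, 1000.0):
            betas, _ = deconvolve(series, events, 250.0, window=(-0.2, 0.4),
                                  ridge_lambda=lam)
            norms.append(np.sqrt(sum(np.sum(b**2) for b in betas.values())))
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))
        assert norms[-1] < 0.1 * norms[0]

    def test_high_amplitude_segments_excluded(self):
        series, events, kern = _isolated_series()
        spiked = series.copy()
        spiked[10:20] = 500.0   # artifact far from events
        betas1, _ = deconvolve(series, events, 250.0, window=(-0.2, 0.4))
        betas2, _ = deconvolve(spiked, events, 250.0, window=(-0.2, 0.4),
                               artifact_threshold=250.0)
        for key in betas1:
            np.testing.assert_allclose(betas1[key], betas2[key], atol=1e-8)

    def test_negative_ridge_rejected(self):
        series, events, _ = _isolated_series()
        with pytest.raises(ValueError):
            deconvolve(series, events, 250.0, ridge_lambda=-1.0)


class TestChooseLambda:
    def test_noiseless_data_prefers_smallest_penalty(self):
        series, events, _ = _isolated_series()
        best, errors = choose_lambda(series, events, 250.0,
                                     grid=[0.01, 1.0, 100.0],
                                     window=(-0.2, 0.4))
        assert best == 0.01

    def test_modal_value_across_participants(self):
        assert modal_lambda([4.5, 4.5, 6.0]) == 4.5
        assert modal_lambda([4.5, 6.0]) == 4.5   # tie -> smaller

    def test_cv_error_dips_for_noisy_overlapping_data(self):
        """With noise and overlap the CV curve is not minimized at the
        largest penalty and heavy penalties hurt."""
        rng = np.random.default_rng(7)
        rate = 250.0
        kern = np.hanning(80)
        n = 6000
        series = 1.5 * rng.standard_normal(n)
        rows = []
        t = 100
        i = 0
        while t < n - 300:
            series[t:t + 80] += kern
            rows.append({"type": "stimulus", "sample": t, "difficulty": "easy",
                         "rt": 0.3, "trial": i})
            t += int(rng.uniform(0.35, 0.6) * rate)
            i += 1
        events = pd.DataFrame(rows)
        grid = [0.1, 10.0, 1e5]
        best, errors = choose_lambda(series, events, rate, grid=grid,
                                     window=(-0.1, 0.4))
        assert errors[1e5] > min(errors.values())


class TestExtractSlope:
    def _betas(self, values, times):
        return {("response", "easy"): values}, times

    def test_exact_linear_waveform(self):
        times = np.arange(-250, 250) / 250.0
        betas, _ = self._betas(3.0 + 2.0 * times, times)
        assert abs(extract_slope(betas, times, "easy") - 2.0) < 1e-10

    def test_constant_waveform_has_zero_slope(self):
        times = np.arange(-250, 250) / 250.0
        betas, _ = self._betas(np.full_like(times, 1.7), times)
        assert abs(extract_slope(betas, times, "easy")) < 1e-12

    def test_window_has_51_samples_at_250hz(self):
        times = np.arange(-250, 250) / 250.0
        m = (times >= -0.2 - 1e-9) & (times <= 0.0 + 1e-9)
        assert m.sum() == 51

    def test_gain_recovery_through_full_pipeline(self):
        """A rank-1 response ramp of known gain survives projection,
        deconvolution and slope fitting within 10% at moderate noise."""
        truth = GroundTruth(seed=60, eeg_noise_sd=5.0)
        parts = synthetic.generate_participants(6, truth)
        design = prep.build_design("motion_coherence", blocks=2)
        beh = synthetic.generate_behaviour(parts, design, seed=61)
        cfg = EEGSimConfig(n_channels=16, stim_amp=0.0)   # rank-1 limit
        recs, true_slopes = synthetic.generate_eeg(parts, beh, cfg=cfg,
                                                   truth=truth, seed=62)
        table = eeg.compute_slopes(recs, ridge_lambda=None)
        mg = table.merge(true_slopes, on="participant",
                         suffixes=("_rec", "_true"))
        gain = np.polyfit(mg["eeg_mean_true"], mg["eeg_mean_rec"], 1)[0]
        assert abs(gain - 1.0) < 0.1


def test_full_pipeline_slope_recovery(pipeline_recovery):
    """Pooled-RCA + deconvolution slopes correlate > 0.9 with the
    ground-truth ramp slopes across 50 participants at default noise."""
    mg = pipeline_recovery
    rec = np.concatenate([mg["slope_easy_rec"], mg["slope_difficult_rec"]])
    tru = np.concatenate([mg["slope_easy_true"], mg["slope_difficult_true"]])
    assert np.corrcoef(rec, tru)[0, 1] > 0.9
    assert np.corrcoef(mg["eeg_mean_rec"], mg["eeg_mean_true"])[0, 1] > 0.9


def test_recording_save_load_round_trip(tmp_path):
    rng = np.random.default_rng(8)
    ev = pd.DataFrame({"type": ["stimulus", "response"], "sample": [10, 60],
                       "difficulty": ["easy", "easy"], "rt": [0.2, 0.2],
                       "trial": [0, 0]})
    rec = EEGRecording(signal=rng.standard_normal((3, 100)), rate=250.0,
                       events=ev, participant="p0")
    eeg.save_recording(rec, tmp_path / "rec")
    back = eeg.load_recording(tmp_path / "rec")
    np.testing.assert_allclose(back.signal, rec.signal, atol=1e-6)
    assert back.rate == rec.rate
    pd.testing.assert_frame_equal(back.events, rec.events)


def test_recording_validation():
    ev = pd.DataFrame({"type": ["stimulus"], "sample": [500],
                       "difficulty": ["easy"], "rt": [0.4], "trial": [0]})
    with pytest.raises(ValueError):
        EEGRecording(signal=np.zeros((2, 100)), rate=250.0, events=ev)
    with pytest.raises(ValueError):
        EEGRecording(signal=np.zeros((2, 1000)), rate=0.0, events=ev)
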