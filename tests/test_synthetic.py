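"""Synthetic-data generator: distributional correctness, seeded
reproducibility, and the configured links to EEG slopes and ADHD scores."""

import numpy as np
import pandas as pd
import pytest

from jointddm import eeg, prep, synthetic, wfpt
from jointddm.synthetic import EEGSimConfig, GroundTruth


class TestGroundTruth:
    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(hyper_sds={"a": -0.1, "z": 0.1, "ter": 0.1,
                                   "v_diff": 0.1, "v_mean": 0.1})

    def test_missing_parameter_rejected(self):
        with pytest.raises(ValueError):
            GroundTruth(hyper_means={"a": 0.2})


class TestGenerateParticipants:
    def test_invariants_hold(self):
        parts = synthetic.generate_participants(50, GroundTruth(seed=1))
        assert len(parts) == 100
        assert (parts["a"] > 0).all()
        assert (parts["ter"] > 0).all()
        assert parts["z_rel"].between(0, 1, inclusive="neither").all()
        assert (parts["s"] == 0.1).all()

    def test_zero_offsets_give_equal_group_means(self):
        parts = synthetic.generate_participants(1000, GroundTruth(seed=2))
        for k in ("a", "z_rel", "ter", "v_diff", "v_mean"):
            aut = parts.loc[parts["group"] == "autistic", k]
            cmp_ = parts.loc[parts["group"] == "comparison", k]
            se = np.sqrt(aut.var() / len(aut) + cmp_.var() / len(cmp_))
            assert abs(aut.mean() - cmp_.mean()) < 3 * se

    def test_half_difference_convention(self):
        """delta_a = 0.02 shifts the group means apart by ~0.04."""
        truth = GroundTruth(seed=3).with_offsets(a=0.02)
        parts = synthetic.generate_participants(2000, truth)
        diff = (parts.loc[parts["group"] == "autistic", "a"].mean()
                - parts.loc[parts["group"] == "comparison", "a"].mean())
        assert abs(diff - 0.04) < 0.005

    def test_same_seed_reproduces_bit_exactly(self):
        t = GroundTruth(seed=9)
        pd.testing.assert_frame_equal(synthetic.generate_participants(20, t),
                                      synthetic.generate_participants(20, t))


class TestGenerateBehaviour:
    def _design(self, **kw):
        return prep.build_design("motion_coherence", **kw)

    def test_no_rt_below_nondecision_time_without_contamination(self):
        truth = GroundTruth(hyper_means={"a": 0.12, "z": 0.5, "ter": 0.3,
                                         "v_diff": 0.1, "v_mean": 0.25},
                            hyper_sds={"a": 0.01, "z": 0.02, "ter": 0.001,
                                       "v_diff": 0.01, "v_mean": 0.02},
                            seed=4)
        parts = synthetic.generate_participants(3, truth)
        beh = synthetic.generate_behaviour(parts, self._design(blocks=1), seed=5)
        assert np.nanmin(beh["rt"]) > parts["ter"].min()

    def test_deadline_below_ter_censors_all(self):
        truth = GroundTruth(seed=4)
        parts = synthetic.generate_participants(2, truth)
        design = prep.build_design("motion_coherence", blocks=1,
                                   deadline=min(parts["ter"]) * 0.5)
        beh = synthetic.generate_behaviour(parts, design, seed=5)
        assert beh["censored"].all()

    def test_strong_drift_gives_high_easy_accuracy(self):
        """v.mean = 0.4 at a = 0.1, s = 0.1: easy accuracy above 0.9
        (the closed-form absorption probability is ~0.98)."""
        truth = GroundTruth(hyper_means={"a": 0.1, "z": 0.5, "ter": 0.3,
                                         "v_diff": 0.0, "v_mean": 0.4},
                            hyper_sds={"a": 1e-6, "z": 1e-6, "ter": 1e-6,
                                       "v_diff": 1e-6, "v_mean": 1e-6},
                            seed=6)
        parts = synthetic.generate_participants(5, truth)
        design = self._design(blocks=5, repetitions=100, catch_per_block=0)
        beh = synthetic.generate_behaviour(parts, design, seed=7)
        easy = beh[(beh["difficulty"] == "easy") & (~beh["censored"])]
        acc = (easy["response"] == easy["direction"]).mean()
        assert len(easy) >= 9000
        assert acc > 0.9

    def test_contamination_exercises_rt_floor(self):
        truth = GroundTruth(seed=8)
        parts = synthetic.generate_participants(10, truth)
        beh = synthetic.generate_behaviour(parts, self._design(),
                                           contamination_rate=0.03, seed=9)
        fast = beh["rt"] < 0.2
        frac = fast.mean()
        assert 0.01 < frac < 0.06
        tab, report = prep.filter_trials(beh)
        assert (tab.loc[fast, "exclusion_reason"] == "rt_floor").all()

    def test_censoring_matches_survivor_function(self):
        """Generated censoring fraction equals the survivor function at
        the deadline within binomial error."""
        truth = GroundTruth(hyper_means={"a": 0.2, "z": 0.5, "ter": 0.3,
                                         "v_diff": 0.0, "v_mean": 0.05},
                            hyper_sds={"a": 1e-9, "z": 1e-9, "ter": 1e-9,
                                       "v_diff": 1e-9, "v_mean": 1e-9},
                            seed=10)
        parts = synthetic.generate_participants(1, truth).iloc[:1]
        design = self._design(blocks=4, repetitions=250, catch_per_block=0)
        beh = synthetic.generate_behaviour(parts, design, seed=11)
        row = parts.iloc[0]
        p = wfpt.DDMParams(a=row["a"], z=row["z"], ter=row["ter"],
                           v1=row["v1"], v2=row["v2"], s=row["s"])
        s_easy = wfpt.survivor(2.5, p, row["v1"])
        easy = beh[beh["difficulty"] == "easy"]
        n = len(easy)
        tol = 4 * np.sqrt(max(s_easy * (1 - s_easy), 1e-4) / n)
        assert abs(easy["censored"].mean() - s_easy) < tol

    def test_behavioural_marginals_match_analytic_cdf(self):
        """KS distance between generated RTs and the analytic defective
        CDF below 0.02 at 1e5 trials for one parameter set."""
        truth = GroundTruth(hyper_means={"a": 0.12, "z": 0.45, "ter": 0.3,
                                         "v_diff": 0.1, "v_mean": 0.2},
                            hyper_sds={"a": 1e-9, "z": 1e-9, "ter": 1e-9,
                                       "v_diff": 1e-9, "v_mean": 1e-9},
                            seed=12)
        parts = synthetic.generate_participants(1, truth).iloc[:1]
        design = self._design(blocks=1, repetitions=25000, catch_per_block=0)
        beh = synthetic.generate_behaviour(parts, design, seed=13)
        row = parts.iloc[0]
        p = wfpt.DDMParams(a=row["a"], z=row["z"], ter=row["ter"],
                           v1=row["v1"], v2=row["v2"], s=row["s"])
        sub = beh[(beh["difficulty"] == "easy") & (beh["direction"] == "right")
                  & (~beh["censored"])]
        rts = np.sort(sub["rt"].to_numpy())
        theo = wfpt.defective_cdf(rts, "upper", p, row["v1"])
        theo_err = wfpt.defective_cdf(rts, "lower", p, row["v1"])
        correct = sub["response"] == "right"
        # joint (response, rt) defective CDF against the analytic one
        rts_up = np.sort(sub["rt"][correct].to_numpy())
        emp_up = np.searchsorted(rts_up, rts, side="right") / len(sub)
        tot = wfpt.defective_cdf(2.5, "upper", p, row["v1"]) + \
            wfpt.defective_cdf(2.5, "lower", p, row["v1"])
        assert np.abs(emp_up * tot - theo).max() < 0.02

    def test_missing_participant_error(self):
        truth = GroundTruth(seed=8)
        parts = synthetic.generate_participants(2, truth)
        with pytest.raises(ValueError):
            synthetic.generate_behaviour(parts, self._design(),
                                         participants=["ghost"], seed=1)

    def test_invalid_contamination_rate(self):
        truth = GroundTruth(seed=8)
        parts = synthetic.generate_participants(1, truth)
        with pytest.raises(ValueError):
            synthetic.generate_behaviour(parts, self._design(),
                                         contamination_rate=0.2)

    def test_seeded_reproducibility(self):
        truth = GroundTruth(seed=8)
        parts = synthetic.generate_participants(3, truth)
        b1 = synthetic.generate_behaviour(parts, self._design(blocks=1), seed=21)
        b2 = synthetic.generate_behaviour(parts, self._design(blocks=1), seed=21)
        pd.testing.assert_frame_equal(b1, b2)


class TestGenerateEEG:
    def _setup(self, n=3, seed=30, **truth_kw):
        truth = GroundTruth(seed=seed, **truth_kw)
        parts = synthetic.generate_participants(n, truth)
        design = prep.build_design("motion_coherence", blocks=1,
                                   repetitions=4, catch_per_block=0)
        beh = synthetic.generate_behaviour(parts, design, seed=seed + 1)
        return truth, parts, beh

    def test_noiseless_epoch_average_reproduces_ramp(self):
        """With zero noise and non-overlapping events the response-locked
        epoch average is exactly the ramp kernel (slope over the last
        200 ms equals the ground-truth slope)."""
        truth, parts, beh = self._setup(eeg_noise_sd=0.0)
        cfg = EEGSimConfig(n_channels=8, stim_amp=0.0,
                           fixation=(2.0, 2.0), random_motion=(2.0, 2.0),
                           offset_period=(2.0, 2.0))
        recs, slopes = synthetic.generate_eeg(parts, beh, cfg=cfg,
                                              truth=truth, seed=32)
        pid = parts["participant"].iloc[0]
        rec = recs[pid]
        epochs = eeg.epoch_response_locked(rec)
        avg = epochs.mean(axis=0)       # channels x time
        peak_ch = np.argmax(np.abs(avg).max(axis=1))
        t = np.arange(avg.shape[1]) / rec.rate - 0.6
        win = (t >= -0.2) & (t <= 0.0)
        tc = t[win] - t[win].mean()
        slope = tc @ (avg[peak_ch, win] - avg[peak_ch, win].mean()) / (tc @ tc)
        true_easy = slopes.loc[slopes["participant"] == pid, "slope_easy"].iloc[0]
        true_hard = slopes.loc[slopes["participant"] == pid, "slope_difficult"].iloc[0]
        # the epoch average pools both difficulties
        pooled = np.average(
            [true_easy, true_hard],
            weights=[(rec.events.query("type=='response'")["difficulty"] == "easy").sum(),
                     (rec.events.query("type=='response'")["difficulty"] == "difficult").sum()])
        assert abs(slope - pooled) < 0.05 * max(abs(pooled), 1.0)

    def test_zero_gain_decouples_slopes_from_drift(self):
        truth, parts, beh = self._setup(n=50, eeg_slope_gain=0.0)
        slopes = synthetic.generate_slope_measures(parts, truth, seed=33)
        r = np.corrcoef(slopes["eeg_mean"], parts["v_mean"])[0, 1]
        assert abs(r) < 0.3   # ~2/sqrt(50) sampling noise around zero

    def test_rho_target_yields_expected_sample_correlation(self):
        """rho target 0.6 at n = 100: sample r lands in the sampling
        distribution's central range [0.45, 0.72]."""
        truth, parts, _ = self._setup(n=50, rho_eeg=0.6)
        slopes = synthetic.generate_slope_measures(parts, truth, seed=34)
        r = np.corrcoef(slopes["eeg_mean"], parts["v_mean"])[0, 1]
        assert 0.45 <= r <= 0.72

    def test_event_list_and_ground_truth_stored(self):
        truth, parts, beh = self._setup()
        recs, slopes = synthetic.generate_eeg(parts, beh, truth=truth, seed=35,
                                              cfg=EEGSimConfig(n_channels=8))
        pid = parts["participant"].iloc[0]
        ev = recs[pid].events
        assert set(ev["type"]) == {"random_onset", "stimulus", "response"}
        assert (ev["sample"] >= 0).all()
        assert len(slopes) == len(recs)

    def test_invalid_rho_rejected(self):
        truth, parts, beh = self._setup(rho_eeg=1.4)
        with pytest.raises(ValueError):
            synthetic.generate_slope_measures(parts, truth, seed=1)


class TestGenerateQuestionnaires:
    def _parts(self, n=1000, seed=40):
        return synthetic.generate_participants(n, GroundTruth(seed=seed))

    def test_scores_bounded(self):
        scores = synthetic.generate_questionnaires(self._parts(200), seed=41)
        assert scores["inatt"].between(0, 1).all()
        assert scores["hyper"].between(0, 1).all()

    def test_zero_rho_gives_null_correlation(self):
        parts = self._parts(1000)
        scores = synthetic.generate_questionnaires(parts, rho_target=0.0, seed=42)
        merged = scores.merge(parts, on="participant")
        r = np.corrcoef(merged["inatt"], merged["v_mean"])[0, 1]
        assert abs(r) < 0.08

    def test_group_means_match_reference_values(self):
        """Defaults reproduce the reported group item averages (0.17
        comparison, 0.58 autistic inattentiveness) within 2 SE."""
        parts = self._parts(4000)
        scores = synthetic.generate_questionnaires(parts, seed=43)
        for group, target, sd in (("comparison", 0.17, 0.23),
                                  ("autistic", 0.58, 0.29)):
            vals = scores.loc[scores["group"] == group, "inatt"]
            se = sd / np.sqrt(len(vals))
            # clipping to [0,1] shifts the realized mean slightly; allow
            # 2 SE plus the analytic clipping bias bound (< 0.035)
            assert abs(vals.mean() - target) < 2 * se + 0.035

    def test_negative_rho_recovered_by_monte_carlo(self):
        """Copula check: rho = -0.31 recovered within +/-0.03 at n=5000."""
        parts = self._parts(5000)
        scores = synthetic.generate_questionnaires(
            parts, rho_target={"autistic": -0.31, "comparison": 0.0}, seed=44)
        merged = scores.merge(parts, on="participant")
        aut = merged[merged["group_y"] == "autistic"] if "group_y" in merged else \
            merged[merged["group"] == "autistic"]
        r = np.corrcoef(aut["inatt"], aut["v_mean"])[0, 1]
        assert abs(r - (-0.31)) < 0.03

    def test_invalid_rho_and_link_rejected(self):
        parts = self._parts(10)
        with pytest.raises(ValueError):
            synthetic.generate_questionnaires(parts, rho_target=2.0)
        with pytest.raises(ValueError):
            synthetic.generate_questionnaires(parts, link="z")


def test_generate_dataset_is_seed_reproducible():
    truth = GroundTruth(seed=55)
    design = prep.build_design("motion_coherence", blocks=1, repetitions=3,
                               catch_per_block=0)
    d1 = synthetic.generate_dataset(truth, 3, design)
    d2 = synthetic.generate_dataset(truth, 3, design)
    pd.testing.assert_frame_equal(d1["behaviour"], d2["behaviour"])
    pd.testing.assert_frame_equal(d1["scores"], d2["scores"])
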