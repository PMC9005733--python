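"""Synthetic study generator with known ground truth.

Emulates the statistical structure the analysis assumes: two groups of
children (labelled ``autistic`` and ``comparison``), per-participant
diffusion parameters drawn from the hierarchical group distributions,
trial-level behaviour from the diffusion process with a 2500 ms deadline
and occasional sub-200 ms contaminant responses, continuous EEG containing
overlapping stimulus-locked and response-locked activity whose pre-response
ramp slope tracks drift-rate, and bounded ADHD item-average scores coupled
to a chosen model parameter through a Gaussian copula.

Everything is seeded: the same :class:`GroundTruth` (which stores its seed)
reproduces a dataset bit-exactly.

Default population values
-------------------------
Group-level means default to the centres of the analysis priors
(a=0.2, z/a=0.5, ter=0.3 s, v.diff=0, v.mean=0.3 at s=0.1). Group-level
SDs default to spreads typical of hierarchical diffusion studies of
children (see docs/methods.md); the between-participant SD implied by the
Gamma(1,1) prior mean would swamp the deadline and is a prior, not a
population description. Recovery tests exercise explicit configurations,
not only these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .eeg import EEGRecording
from .prep import TrialDesign
from . import wfpt

__all__ = [
    "GroundTruth",
    "EEGSimConfig",
    "generate_participants",
    "generate_behaviour",
    "generate_eeg",
    "generate_slope_measures",
    "generate_questionnaires",
    "generate_dataset",
]

PARAMS = ("a", "z", "ter", "v_diff", "v_mean")

_DEFAULT_MEANS = {"a": 0.2, "z": 0.5, "ter": 0.3, "v_diff": 0.0, "v_mean": 0.3}
_DEFAULT_SDS = {"a": 0.05, "z": 0.08, "ter": 0.05, "v_diff": 0.05, "v_mean": 0.08}
_DEFAULT_OFFSETS = {k: 0.0 for k in PARAMS}

#: Group means / SDs of the ADHD item-average subscales (bounded to [0,1]).
DEFAULT_ADHD_MEANS = {
    "comparison": {"inatt": 0.17, "hyper": 0.08},
    "autistic": {"inatt": 0.58, "hyper": 0.55},
}
DEFAULT_ADHD_SDS = {
    "comparison": {"inatt": 0.23, "hyper": 0.19},
    "autistic": {"inatt": 0.29, "hyper": 0.34},
}


@dataclass(frozen=True)
class GroundTruth:
    """Generator settings plus everything needed to reproduce a dataset.

    ``group_offsets`` follow the half-difference convention: the autistic
    group mean is ``mu + delta`` and the comparison group mean ``mu -
    delta``, so the group difference is ``2 delta`` (positive = higher in
    the autistic group).
    """

    hyper_means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    hyper_sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    group_offsets: dict = field(default_factory=lambda: dict(_DEFAULT_OFFSETS))
    eeg_slope_gain: float = 60.0      # slope units (uV/s) per drift unit
    eeg_noise_sd: float = 10.0        # continuous EEG noise (uV RMS)
    rho_eeg: float | None = None      # target corr(slope mean, v.mean)
    rho_adhd: dict | float | None = None
    s: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, sd in self.hyper_sds.items():
            if not sd > 0:
                raise ValueError(f"hyper SD for {name} must be positive, got {sd}")
        for d in (self.hyper_means, self.hyper_sds, self.group_offsets):
            missing = set(PARAMS) - set(d)
            if missing:
                raise ValueError(f"missing entries for {sorted(missing)}")

    def with_offsets(self, **deltas) -> "GroundTruth":
        off = dict(self.group_offsets)
        off.update(deltas)
        return replace(self, group_offsets=off)


def _truncnorm(rng, lo, hi, loc, scale, size):
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return stats.truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def generate_participants(n_per_group: int, truth: GroundTruth,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw participant diffusion parameters from the group distributions.

    a and ter come from positive-truncated normals, relative start z/a from
    a normal truncated to (0,1), the drift mean and drift difference from
    plain normals — exactly the participant-level model of the analysis,
    with the +/- delta group offsets applied.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    mu, sd, dl = truth.hyper_means, truth.hyper_sds, truth.group_offsets
    rows = []
    for group, sign, tag in (("autistic", 1.0, "aut"), ("comparison", -1.0, "cmp")):
        n = n_per_group
        a = _truncnorm(rng, 0, np.inf, mu["a"] + sign * dl["a"], sd["a"], n)
        w = _truncnorm(rng, 0, 1, mu["z"] + sign * dl["z"], sd["z"], n)
        ter = _truncnorm(rng, 0, np.inf, mu["ter"] + sign * dl["ter"], sd["ter"], n)
        vd = rng.normal(mu["v_diff"] + sign * dl["v_diff"], sd["v_diff"], n)
        vm = rng.normal(mu["v_mean"] + sign * dl["v_mean"], sd["v_mean"], n)
        for i in range(n):
            rows.append({
                "participant": f"{tag}{i:03d}", "group": group, "group_sign": sign,
                "a": a[i], "z_rel": w[i], "z": w[i] * a[i], "ter": ter[i],
                "v_mean": vm[i], "v_diff": vd[i],
                "v1": vm[i] + vd[i] / 2.0, "v2": vm[i] - vd[i] / 2.0,
                "s": truth.s,
            })
    return pd.DataFrame(rows)


def _participant_params(row) -> wfpt.DDMParams:
    return wfpt.DDMParams(a=row["a"], z=row["z"], ter=row["ter"],
                          v1=row["v1"], v2=row["v2"], s=row["s"])


def generate_behaviour(params: pd.DataFrame, design: TrialDesign,
                       contamination_rate: float = 0.0,
                       rng: np.random.Generator | None = None,
                       seed: int | None = None,
                       participants=None,
                       catch_drift_factor: float = 2.0) -> pd.DataFrame:
    """Simulate every scheduled trial for every participant.

    Responses and RTs come from the exact diffusion simulator under
    stimulus coding (upper bound = rightward response, drift sign set by
    the true direction). Decision times exceeding the deadline become
    censored no-response trials. A ``contamination_rate`` fraction of
    trials is replaced by anticipatory responses with uniform RTs on
    [0, 0.2) s to exercise the RT-floor filter; the diffusion model itself
    has no contaminant component. Catch (full-strength) trials use
    ``catch_drift_factor`` times the easy drift.
    """
    if not (0 <= contamination_rate < 0.05):
        raise ValueError("contamination_rate must be in [0, 0.05)")
    rng = np.random.default_rng(seed) if rng is None else rng
    if participants is not None:
        missing = set(participants) - set(params["participant"])
        if missing:
            raise ValueError(f"participants missing from parameter table: {sorted(missing)}")
        params = params[params["participant"].isin(participants)]
    tables = []
    for _, row in params.iterrows():
        p = _participant_params(row)
        sched = design.schedule(seed=int(rng.integers(2**31)))
        sched = sched.copy()
        sched["participant"] = row["participant"]
        sched["group"] = row["group"]
        rts = np.full(len(sched), np.nan)
        resps = np.empty(len(sched), dtype=object)
        for (diff, direction), idx in sched.groupby(["difficulty", "direction"]).groups.items():
            if diff == "easy":
                v = row["v1"]
            elif diff == "difficult":
                v = row["v2"]
            else:
                v = catch_drift_factor * row["v1"]
            v_signed = v if direction == "right" else -v
            bnd, rt = wfpt.simulate_trials(len(idx), p, v_signed, design.deadline, rng)
            rts[np.asarray(idx)] = rt
            resps[np.asarray(idx)] = np.where(bnd == 1, "right",
                                              np.where(bnd == -1, "left", "none"))
        if contamination_rate > 0:
            contam = rng.random(len(sched)) < contamination_rate
            n_c = int(contam.sum())
            rts[contam] = rng.uniform(0.0, design.rt_floor, n_c)
            resps[contam] = np.where(rng.random(n_c) < 0.5, "left", "right")
        sched["response"] = resps
        sched["rt"] = rts
        sched["censored"] = sched["response"] == "none"
        tables.append(sched)
    out = pd.concat(tables, ignore_index=True)
    cols = ["participant", "group", "task", "block", "trial", "difficulty",
            "direction", "response", "rt", "censored"]
    return out[cols]


# ---------------------------------------------------------------------------
# EEG
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EEGSimConfig:
    """Shape of the simulated recordings.

    32 channels by default (desk scale; raise to 128 to emulate a
    high-density net). The response-locked component is a linear ramp whose
    slope over the last ``ramp_duration`` seconds before the response is
    the participant's ground-truth slope; the stimulus-locked component is
    a biphasic evoked transient. Both are projected through fixed smooth
    topographies and buried in 1/f noise.
    """

    n_channels: int = 32
    rate: float = 250.0
    ramp_duration: float = 0.4    # s of pre-response build-up
    ramp_fall: float = 0.2        # s of post-response decay
    stim_amp: float = 5.0         # uV peak of the stimulus-locked kernel
    slope_noise_sd: float = 4.0   # uV/s around gain * v
    fixation: tuple = (0.8, 1.0)  # s, uniform
    random_motion: tuple = (0.8, 1.0)
    offset_period: tuple = (0.2, 0.4)
    # the generator emulates *cleaned* continuous data: 1/f noise with the
    # slow drift below the cleaning high-pass removed (band-passed 0.3 Hz up)
    noise_highpass: float = 0.3   # Hz


def _topography(n_channels: int, centre_frac: float, width_frac: float = 0.18) -> np.ndarray:
    x = np.arange(n_channels)
    topo = np.exp(-0.5 * ((x - centre_frac * n_channels) / (width_frac * n_channels)) ** 2)
    return topo / np.abs(topo).max()


def _pink_noise(rng, n_channels, n_samples, sd, rate, highpass=0.3):
    white = rng.standard_normal((n_channels, n_samples))
    f = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    shape = np.zeros_like(f)
    band = f >= max(highpass, 1e-6)
    shape[band] = 1.0 / np.sqrt(f[band])
    x = np.fft.irfft(np.fft.rfft(white, axis=1) * shape, n=n_samples, axis=1)
    x *= sd / x.std()
    return x


def _slope_settings(params: pd.DataFrame, truth: GroundTruth,
                    slope_noise_sd: float):
    """Resolve (gain, noise_sd) for the slope link; when a target
    correlation is set, the noise SD is solved from the sample spread of
    v.mean so corr(mean slope, mean drift) hits the target in population."""
    gain = truth.eeg_slope_gain
    if truth.rho_eeg is None:
        return gain, slope_noise_sd
    rho = truth.rho_eeg
    if not (-1 <= rho <= 1):
        raise ValueError("rho_eeg must be in [-1, 1]")
    sv = float(params["v_mean"].std())
    if abs(rho) < 1e-12:
        return 0.0, (slope_noise_sd if slope_noise_sd > 0 else 1.0)
    noise_sd = abs(gain) * sv * np.sqrt(max(1.0 / rho**2 - 1.0, 0.0))
    return abs(gain) * np.sign(rho), noise_sd


def generate_slope_measures(params: pd.DataFrame,
                            truth: GroundTruth | None = None,
                            slope_noise_sd: float = 4.0,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """Ground-truth pre-response slopes per participant x difficulty.

    ``slope_pi = gain * v_pi + eps_p`` with participant noise shared
    across difficulty levels, so the slope difference tracks the drift
    difference. This is the statistical structure the joint EEG model
    assumes; :func:`generate_eeg` embeds exactly these slopes in
    continuous recordings.
    """
    truth = truth or GroundTruth()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed) if rng is None else rng
    gain, noise_sd = _slope_settings(params, truth, slope_noise_sd)
    rows = []
    for _, row in params.iterrows():
        shared = rng.normal(0.0, noise_sd)
        easy = gain * row["v1"] + shared
        hard = gain * row["v2"] + shared
        rows.append({"participant": row["participant"],
                     "slope_easy": easy, "slope_difficult": hard,
                     "eeg_mean": (easy + hard) / 2.0,
                     "eeg_diff": easy - hard})
    return pd.DataFrame(rows)


def generate_eeg(params: pd.DataFrame, behaviour: pd.DataFrame,
                 cfg: EEGSimConfig | None = None,
                 truth: GroundTruth | None = None,
                 rng: np.random.Generator | None = None,
                 seed: int | None = None):
    """Continuous EEG per participant with ground-truth ramp slopes.

    The per-participant, per-difficulty ramp slope is
    ``gain * v_difficulty + noise`` (see :func:`generate_slope_measures`).
    Returns ``(recordings, true_slopes)``.
    """
    cfg = cfg or EEGSimConfig()
    truth = truth or GroundTruth()
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed) if rng is None else rng
    gain, noise_sd = _slope_settings(params, truth, cfg.slope_noise_sd)

    rate = cfg.rate
    topo_resp = _topography(cfg.n_channels, 0.5)
    topo_stim = _topography(cfg.n_channels, 0.28)
    n_ramp = int(round(cfg.ramp_duration * rate))
    n_fall = int(round(cfg.ramp_fall * rate))
    ramp_unit = np.concatenate([
        np.linspace(0.0, cfg.ramp_duration, n_ramp, endpoint=False),
        np.linspace(cfg.ramp_duration, 0.0, n_fall + 1),
    ])
    tk = np.arange(int(0.6 * rate)) / rate
    stim_kernel = cfg.stim_amp * (np.exp(-0.5 * ((tk - 0.15) / 0.05) ** 2)
                                  - 0.6 * np.exp(-0.5 * ((tk - 0.32) / 0.09) ** 2))

    recordings = {}
    slope_rows = []
    for _, row in params.iterrows():
        pid = row["participant"]
        trials = behaviour[behaviour["participant"] == pid].sort_values("trial")
        if len(trials) == 0:
            continue
        shared = rng.normal(0.0, noise_sd)
        slopes = {
            "easy": gain * row["v1"] + shared,
            "difficult": gain * row["v2"] + shared,
            "catch": gain * row["v1"] + shared,
        }
        # schedule trial timings
        events = []
        t = 0.0
        spans = []
        for _, tr in trials.iterrows():
            t += rng.uniform(*cfg.fixation)
            t_random = t
            t += rng.uniform(*cfg.random_motion)
            t_stim = t
            rt = tr["rt"]
            stim_dur = rt if np.isfinite(rt) else 2.5
            t_resp = t_stim + rt if np.isfinite(rt) else np.nan
            t = t_stim + stim_dur + rng.uniform(*cfg.offset_period)
            spans.append((tr["trial"], tr["difficulty"], t_random, t_stim, t_resp, rt))
        total = int(np.ceil((t + 1.0) * rate))
        comp = np.zeros((2, total))   # row 0: stimulus component, 1: response
        for trial, diff, t_random, t_stim, t_resp, rt in spans:
            i_random = int(round(t_random * rate))
            i_stim = int(round(t_stim * rate))
            events.append(("random_onset", i_random, diff, rt, trial))
            events.append(("stimulus", i_stim, diff, rt, trial))
            seg = comp[0, i_stim:i_stim + len(stim_kernel)]
            seg += stim_kernel[:len(seg)]
            if np.isfinite(t_resp):
                i_resp = int(round(t_resp * rate))
                events.append(("response", i_resp, diff, rt, trial))
                kern = slopes[diff] * ramp_unit
                i0 = i_resp - n_ramp
                lo = max(i0, 0)
                seg = comp[1, lo:i0 + len(kern)]
                seg += kern[lo - i0:lo - i0 + len(seg)]
        signal = (np.outer(topo_stim, comp[0]) + np.outer(topo_resp, comp[1]))
        if truth.eeg_noise_sd > 0:
            signal = signal + _pink_noise(rng, cfg.n_channels, total,
                                          truth.eeg_noise_sd, rate,
                                          cfg.noise_highpass)
        ev = pd.DataFrame(events, columns=["type", "sample", "difficulty", "rt", "trial"])
        recordings[pid] = EEGRecording(signal=signal, rate=rate, events=ev, participant=pid)
        slope_rows.append({
            "participant": pid, "slope_easy": slopes["easy"],
            "slope_difficult": slopes["difficult"],
            "eeg_mean": (slopes["easy"] + slopes["difficult"]) / 2.0,
            "eeg_diff": slopes["easy"] - slopes["difficult"],
        })
    return recordings, pd.DataFrame(slope_rows)


def generate_questionnaires(params: pd.DataFrame, link: str = "v_mean",
                            rho_target=None, group_means=None, group_sds=None,
                            rng: np.random.Generator | None = None,
                            seed: int | None = None) -> pd.DataFrame:
    """ADHD item-average scores coupled to a diffusion parameter.

    Scores for the inattentiveness and hyperactivity/impulsivity subscales
    are generated per group from a Gaussian copula with the linked
    parameter (standardized within group), transformed to the requested
    group mean/SD and squashed to [0, 1]. ``rho_target`` may be a scalar or
    a mapping ``{group: rho}``.
    """
    if link not in ("v_mean", "a", "ter"):
        raise ValueError(f"link must be one of v_mean, a, ter; got {link!r}")
    rng = np.random.default_rng(seed) if rng is None else rng
    group_means = group_means or DEFAULT_ADHD_MEANS
    group_sds = group_sds or DEFAULT_ADHD_SDS
    if rho_target is None:
        rho_target = 0.0
    out = []
    for group, sub in params.groupby("group", sort=False):
        rho = rho_target[group] if isinstance(rho_target, dict) else float(rho_target)
        if not (-1 <= rho <= 1):
            raise ValueError(f"invalid correlation target {rho} for group {group!r}")
        x = sub[link].to_numpy(dtype=float)
        sx = x.std()
        zx = (x - x.mean()) / (sx if sx > 0 else 1.0)
        scores = {"participant": sub["participant"].to_numpy()}
        for scale in ("inatt", "hyper"):
            z = rho * zx + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(len(sub))
            raw = group_means[group][scale] + group_sds[group][scale] * z
            scores[scale] = np.clip(raw, 0.0, 1.0)
        df = pd.DataFrame(scores)
        df["group"] = group
        out.append(df)
    return pd.concat(out, ignore_index=True)


def generate_dataset(truth: GroundTruth, n_per_group: int, design: TrialDesign,
                     contamination_rate: float = 0.0, with_eeg: bool = False,
                     eeg_cfg: EEGSimConfig | None = None,
                     adhd_link: str = "v_mean"):
    """One self-contained synthetic study, reproducible from ``truth.seed``.

    Returns a dict with keys ``participants``, ``behaviour``, ``scores``
    and (when ``with_eeg``) ``recordings`` and ``true_slopes``.
    """
    rng = np.random.default_rng(truth.seed)
    participants = generate_participants(n_per_group, truth, rng=rng)
    behaviour = generate_behaviour(participants, design,
                                   contamination_rate=contamination_rate, rng=rng)
    scores = generate_questionnaires(participants, link=adhd_link,
                                     rho_target=truth.rho_adhd, rng=rng)
    out = {"participants": participants, "behaviour": behaviour,
           "scores": scores, "truth": truth}
    if with_eeg:
        rec, slopes = generate_eeg(participants, behaviour, cfg=eeg_cfg,
                                   truth=truth, rng=rng)
        out["recordings"] = rec
        out["true_slopes"] = slopes
    return out
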