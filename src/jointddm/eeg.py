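"""From cleaned continuous EEG to the per-participant pre-response slope.

The pipeline mirrors a model-based EEG analysis of perceptual decisions:

1. epoch the continuous recording around each response and baseline to the
   last 100 ms of the random-motion period;
2. Reliable Components Analysis (RCA) pooled over participants to find the
   spatial filter maximizing trial-to-trial covariance (the most reliable
   component is a centro-parietal build-up signal);
3. project each participant's continuous data through the component weights;
4. unmix temporally overlapping stimulus- and response-locked activity with
   a time-expanded linear deconvolution (regression ERP), optionally with
   ridge regularisation whose parameter is chosen by cross-validation per
   participant and then fixed at the mode across participants;
5. fit an ordinary least-squares slope to the deconvolved response-locked
   waveform from 200 ms before the response to the response itself.

The resulting slope per participant x difficulty is the neural measure
(``EEG.mean`` / ``EEG.diff``) entering the joint models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse as sp

__all__ = [
    "EEGRecording",
    "ReliableComponent",
    "epoch_response_locked",
    "rca",
    "project",
    "deconvolve",
    "choose_lambda",
    "modal_lambda",
    "extract_slope",
    "slopes_table",
    "compute_slopes",
]

_EVENT_TYPES = ("random_onset", "stimulus", "response")


@dataclass
class EEGRecording:
    """Continuous multichannel EEG plus its event list.

    signal : (channels, samples) array in microvolts
    rate : sampling rate in Hz (250 by default across the pipeline)
    events : DataFrame with columns ``type`` (random_onset | stimulus |
        response), ``sample`` (index into the recording), ``difficulty``,
        ``rt`` (seconds, NaN for non-response trials) and ``trial``.
    """

    signal: np.ndarray
    rate: float
    events: pd.DataFrame
    participant: str = ""

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        s = self.events["sample"].to_numpy()
        if len(s) and (s.min() < 0 or s.max() >= self.signal.shape[1]):
            raise ValueError("event samples outside the recording span")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]


@dataclass
class ReliableComponent:
    """A spatial filter from RCA with its forward model and reliability."""

    weights: np.ndarray            # channels
    forward: np.ndarray            # channels; covariance-mapped weights
    reliability: float             # generalized eigenvalue
    explained: float               # fraction of across-trial covariance


def save_recording(rec: EEGRecording, stem) -> None:
    """Write a recording as ``<stem>.bin`` (float32 channels x samples,
    C order), ``<stem>.json`` (channels, samples, rate, participant) and
    ``<stem>.events.csv``."""
    import json
    from pathlib import Path

    stem = Path(stem)
    rec.signal.astype(np.float32).tofile(stem.with_suffix(".bin"))
    stem.with_suffix(".json").write_text(json.dumps({
        "channels": int(rec.n_channels),
        "samples": int(rec.signal.shape[1]),
        "rate": float(rec.rate),
        "participant": rec.participant,
        "dtype": "float32",
    }))
    rec.events.to_csv(stem.with_suffix(".events.csv"), index=False)


def load_recording(stem) -> EEGRecording:
    """Read a recording written by :func:`save_recording`."""
    import json
    from pathlib import Path

    stem = Path(stem)
    header = json.loads(stem.with_suffix(".json").read_text())
    signal = np.fromfile(stem.with_suffix(".bin"), dtype=np.float32)
    signal = signal.reshape(header["channels"], header["samples"]).astype(float)
    events = pd.read_csv(stem.with_suffix(".events.csv"))
    return EEGRecording(signal=signal, rate=header["rate"], events=events,
                        participant=header.get("participant", ""))


def epoch_response_locked(rec: EEGRecording, pre: float = 0.6, post: float = 0.2,
                          baseline: float = 0.1, rt_window=(0.2, 2.5)) -> np.ndarray:
    """Epoch around each response; baseline to the last ``baseline`` seconds
    of the random-motion period (i.e. just before stimulus onset).

    Only responses with RT inside ``rt_window`` are used. Returns an array
    of shape (trials, channels, time).
    """
    ev = rec.events
    npre = int(round(pre * rec.rate))
    npost = int(round(post * rec.rate))
    nbase = max(int(round(baseline * rec.rate)), 1)
    stim = ev[ev["type"] == "stimulus"].set_index("trial")["sample"]
    resp = ev[ev["type"] == "response"]
    epochs = []
    for _, row in resp.iterrows():
        if not (rt_window[0] <= row["rt"] <= rt_window[1]):
            continue
        r = int(row["sample"])
        if r - npre < 0 or r + npost + 1 > rec.signal.shape[1]:
            continue
        trial = row["trial"]
        if trial not in stim.index:
            continue
        s0 = int(stim.loc[trial])
        base = rec.signal[:, max(s0 - nbase, 0):s0].mean(axis=1, keepdims=True)
        epochs.append(rec.signal[:, r - npre:r + npost + 1] - base)
    if not epochs:
        raise ValueError("no epochs available in the requested RT window")
    return np.stack(epochs)


def _rca_covariances(epochs: np.ndarray):
    """Across-trial and within-trial channel covariance of the epochs.

    With trial data ``X_i`` (channels x time), the across-trial covariance
    averages ``X_i X_j^T`` over distinct trial pairs (signal that repeats
    across trials survives; trial-unique noise cancels), while the
    within-trial covariance averages ``X_i X_i^T``.
    """
    n, _, t = epochs.shape
    if n < 2:
        raise ValueError("RCA needs at least 2 trials")
    S = epochs.sum(axis=0)                       # channels x time
    within = np.einsum("ict,idt->cd", epochs, epochs)
    across = (S @ S.T - within) / (n * (n - 1) * t)
    within = within / (n * t)
    return across, within


def rca(epochs: np.ndarray, n_components: int = 3, shrinkage: float = 0.01,
        cp_channels=None) -> list[ReliableComponent]:
    """Reliable Components Analysis of baselined response-locked epochs.

    Solves the generalized eigenproblem ``C_across w = lambda C_within w``
    maximizing across-trial relative to within-trial covariance. The
    within-trial covariance receives diagonal loading (``shrinkage`` times
    its average eigenvalue) to stabilise rank-deficient data; a warning is
    logged when the raw matrix is numerically singular. Components are
    ordered by reliability and sign-fixed so the mean forward projection
    over ``cp_channels`` (default: the middle third of channels, standing
    in for centro-parietal sites) is positive.
    """
    across, within = _rca_covariances(epochs)
    nch = within.shape[0]
    avg_eig = np.trace(within) / nch
    cond = np.linalg.cond(within)
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("within-trial covariance is rank-deficient; relying on diagonal loading")
    within_reg = within + shrinkage * avg_eig * np.eye(nch)
    eigvals, eigvecs = scipy.linalg.eigh(across, within_reg)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = np.clip(eigvals, 0.0, None)
    total = pos.sum() if pos.sum() > 0 else 1.0
    if cp_channels is None:
        cp_channels = np.arange(nch // 3, 2 * nch // 3)
    comps = []
    for i in range(min(n_components, nch)):
        w = eigvecs[:, i]
        fwd = within @ w
        scale = w @ within @ w
        if scale > 0:
            fwd = fwd / scale
        if fwd[cp_channels].mean() < 0:
            w, fwd = -w, -fwd
        # scale so the forward projection peaks at 1: the projected series
        # is then in scalp microvolts at the component's peak channel
        peak = np.abs(fwd).max()
        if peak > 0:
            w, fwd = w * peak, fwd / peak
        comps.append(ReliableComponent(weights=w, forward=fwd,
                                       reliability=float(eigvals[i]),
                                       explained=float(pos[i] / total)))
    return comps


def project(rec: EEGRecording, component: ReliableComponent) -> np.ndarray:
    """Project the continuous recording onto the component weights,
    yielding a single-channel series (linear in the weights)."""
    return component.weights @ rec.signal


# ---------------------------------------------------------------------------
# time-expanded deconvolution (regression ERP)
# ---------------------------------------------------------------------------


def _design_matrix(n_samples: int, events: pd.DataFrame, rate: float,
                   window, levels):
    """Sparse time-expanded design: one predictor per (event type x
    difficulty x lag). Returns (X, names, lags)."""
    lag0 = int(round(window[0] * rate))
    lag1 = int(round(window[1] * rate))
    lags = np.arange(lag0, lag1)
    nlags = len(lags)
    cols = [(etype, level) for etype in ("stimulus", "response") for level in levels]
    col_index = {c: i for i, c in enumerate(cols)}
    rows, ccols = [], []
    for _, ev in events.iterrows():
        key = (ev["type"], ev["difficulty"])
        if key not in col_index:
            continue
        base = col_index[key] * nlags
        s = int(ev["sample"])
        lo = max(lag0, -s)
        hi = min(lag1, n_samples - s)
        for k in range(lo, hi):
            rows.append(s + k)
            ccols.append(base + (k - lag0))
    data = np.ones(len(rows))
    X = sp.csr_matrix((data, (rows, ccols)), shape=(n_samples, len(cols) * nlags))
    return X, cols, lags


def deconvolve(series: np.ndarray, events: pd.DataFrame, rate: float,
               window=(-1.0, 1.0), ridge_lambda: float | None = None,
               artifact_threshold: float = 250.0,
               levels=("difficult", "easy")):
    """Estimate event-locked waveforms by time-expanded linear regression.

    Every sampled timepoint in ``window`` around each stimulus/response
    event gets its own predictor per difficulty level, so overlapping
    stimulus- and response-locked activity is unmixed by least squares.
    Samples with absolute amplitude above ``artifact_threshold`` (microvolts)
    are dropped from the system. ``ridge_lambda`` adds an L2 penalty on the
    coefficients (None or 0 gives ordinary least squares; a singular OLS
    system falls back to the minimum-norm solution with a warning).

    Returns ``(betas, times)`` with ``betas[(event_type, difficulty)]`` the
    regression-ERP waveform over ``times`` (seconds relative to the event).
    """
    if ridge_lambda is not None and ridge_lambda < 0:
        raise ValueError("ridge penalty must be >= 0")
    n = series.shape[0]
    if len(events) and events["sample"].max() >= n:
        raise ValueError("events outside the modelled series")
    X, cols, lags = _design_matrix(n, events, rate, window, levels)
    keep = np.abs(series) <= artifact_threshold
    Xk = X[keep]
    yk = series[keep]
    XtX = (Xk.T @ Xk).toarray()
    Xty = Xk.T @ yk
    lam = 0.0 if ridge_lambda is None else float(ridge_lambda)
    if lam > 0:
        beta = np.linalg.solve(XtX + lam * np.eye(XtX.shape[0]), Xty)
    else:
        try:
            c, low = scipy.linalg.cho_factor(XtX)
            beta = scipy.linalg.cho_solve((c, low), Xty)
        except np.linalg.LinAlgError:
            warnings.warn("singular deconvolution system; returning minimum-norm solution")
            beta, *_ = np.linalg.lstsq(XtX, Xty, rcond=None)
    nlags = len(lags)
    times = lags / rate
    betas = {c: beta[i * nlags:(i + 1) * nlags] for i, c in enumerate(cols)}
    return betas, times


def choose_lambda(series: np.ndarray, events: pd.DataFrame, rate: float,
                  grid, window=(-1.0, 1.0), n_folds: int = 5,
                  artifact_threshold: float = 250.0,
                  levels=("difficult", "easy")):
    """Cross-validated ridge parameter for one participant.

    Folds are contiguous temporal segments of the recording. Returns
    ``(best_lambda, cv_error)`` where ``cv_error`` maps each grid value to
    its summed held-out squared error.
    """
    n = series.shape[0]
    X, _, _ = _design_matrix(n, events, rate, window, levels)
    keep = np.abs(series) <= artifact_threshold
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    fold_of = np.zeros(n, dtype=int)
    for f in range(n_folds):
        fold_of[bounds[f]:bounds[f + 1]] = f
    errors = {float(lam): 0.0 for lam in grid}
    for f in range(n_folds):
        train = keep & (fold_of != f)
        test = keep & (fold_of == f)
        Xtr, ytr = X[train], series[train]
        Xte, yte = X[test], series[test]
        XtX = (Xtr.T @ Xtr).toarray()
        Xty = Xtr.T @ ytr
        eye = np.eye(XtX.shape[0])
        for lam in grid:
            lam = float(lam)
            ridge = XtX + max(lam, 1e-10) * eye
            beta = np.linalg.solve(ridge, Xty)
            resid = yte - Xte @ beta
            errors[lam] += float(resid @ resid)
    best = min(errors, key=lambda k: (errors[k], k))
    return best, errors


def modal_lambda(per_participant) -> float:
    """Study-level ridge parameter: the mode of the per-participant values
    (ties broken toward the smaller value)."""
    vals = pd.Series(list(per_participant))
    counts = vals.value_counts()
    top = counts[counts == counts.max()].index
    return float(min(top))


def extract_slope(betas, times, difficulty: str, window=(-0.2, 0.0),
                  event_type: str = "response") -> float:
    """OLS slope (microvolts/s) of the deconvolved waveform on the
    pre-response window, endpoints inclusive (51 samples at 250 Hz)."""
    y = betas[(event_type, difficulty)]
    m = (times >= window[0] - 1e-9) & (times <= window[1] + 1e-9)
    t = times[m]
    yy = y[m]
    t0 = t - t.mean()
    denom = float(t0 @ t0)
    if denom == 0:
        raise ValueError("slope window contains fewer than 2 samples")
    return float(t0 @ (yy - yy.mean()) / denom)


def slopes_table(per_participant_betas, times, levels=("easy", "difficult"),
                 window=(-0.2, 0.0)) -> pd.DataFrame:
    """Slope per participant x difficulty, plus the mean and (easy minus
    difficult) difference entering the joint models.

    The difference convention matches the drift-rate convention where
    level 1 is the easy condition (``v.diff = v_easy - v_difficult``).
    """
    rows = []
    for pid, betas in per_participant_betas.items():
        entry = {"participant": pid}
        for level in levels:
            entry[f"slope_{level}"] = extract_slope(betas, times, level, window)
        entry["eeg_mean"] = (entry["slope_easy"] + entry["slope_difficult"]) / 2.0
        entry["eeg_diff"] = entry["slope_easy"] - entry["slope_difficult"]
        rows.append(entry)
    return pd.DataFrame(rows)


def compute_slopes(recordings, ridge_grid=None, ridge_lambda=None,
                   window=(-1.0, 1.0), slope_window=(-0.2, 0.0),
                   n_components: int = 1, epoch_kwargs=None) -> pd.DataFrame:
    """Full pipeline: pooled RCA -> projection -> deconvolution -> slopes.

    ``recordings`` maps participant id to :class:`EEGRecording`. Epochs are
    pooled across all participants for RCA (both groups together). The
    ridge parameter, when a grid is given, is chosen per participant by
    cross-validation and then fixed at the modal value for everyone;
    alternatively pass ``ridge_lambda`` directly (None = plain OLS).
    """
    epoch_kwargs = epoch_kwargs or {}
    pooled = []
    for rec in recordings.values():
        pooled.append(epoch_response_locked(rec, **epoch_kwargs))
    epochs = np.concatenate(pooled, axis=0)
    comp = rca(epochs, n_components=max(n_components, 1))[0]
    series = {pid: project(rec, comp) for pid, rec in recordings.items()}
    if ridge_grid is not None:
        per_part = []
        for pid, rec in recordings.items():
            best, _ = choose_lambda(series[pid], rec.events, rec.rate,
                                    ridge_grid, window=window)
            per_part.append(best)
        ridge_lambda = modal_lambda(per_part)
    betas = {}
    times = None
    for pid, rec in recordings.items():
        betas[pid], times = deconvolve(series[pid], rec.events, rec.rate,
                                       window=window, ridge_lambda=ridge_lambda)
    table = slopes_table(betas, times, window=slope_window)
    table.attrs["ridge_lambda"] = ridge_lambda
    table.attrs["component"] = comp
    return table
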