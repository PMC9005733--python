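"""The hierarchical group-difference diffusion model.

Five participant-level parameters (boundary separation ``a``, relative
start ``z/a``, non-decision time ``ter``, drift difference ``v.diff`` and
drift mean ``v.mean``) each get three group-level hyperparameters: a mean
``mu``, a spread ``sigma`` and a half group difference ``delta``. A
participant in the autistic group is drawn around ``mu + delta`` and a
comparison participant around ``mu - delta``, so the plotted group
difference is ``2 delta`` and a point null on ``delta`` tests "no group
difference" directly.

Participant level::

    a_p        ~ N+(mu_a +/- delta_a, sigma_a)
    z_p / a_p  ~ TN01(mu_z +/- delta_z, sigma_z)
    ter_p      ~ N+(mu_ter +/- delta_ter, sigma_ter)
    v_p1 - v_p2        ~ N(mu_v.diff +/- delta_v.diff, sigma_v.diff)
    (v_p1 + v_p2) / 2  ~ N(mu_v.mean +/- delta_v.mean, sigma_v.mean)

Hyperpriors::

    mu_a ~ N+(0.2, 0.2)    mu_z ~ TN01(0.5, 0.2)   mu_ter ~ N+(0.3, 0.3)
    mu_v.diff ~ N(0, 0.1)  mu_v.mean ~ N(0.3, 0.3)
    sigma_* ~ Gamma(1, 1)  delta_* ~ N(0, 0.01)

All second arguments are standard deviations; Gamma(1,1) is the unit
exponential. Truncated-normal terms include their normalizing constants
(they depend on the hyperparameters, so they matter for sampling).
Difficulty level 1 is the easy condition, so positive ``v.diff`` means
faster accumulation on easy trials.

Covariate partialling: a standardized covariate ``x`` enters the
group-level mean of every model parameter linearly, ``mu +/- delta +
beta * x_p`` with ``beta ~ N(0, 0.5)`` per parameter, so ``delta``
reflects the group difference with the covariate held fixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import wfpt
from .wfpt import trial_arrays

__all__ = [
    "PARAMS",
    "HyperParams",
    "CovariateSpec",
    "HierarchicalDDM",
    "transform_drifts",
    "drift_stats",
    "log_norm",
    "log_pos_norm",
    "log_tn01",
]

PARAMS = ("a", "z", "ter", "v_diff", "v_mean")

#: (location, sd) of the hyper-mean priors; positivity/unit-interval
#: truncation is applied per parameter as in the model block above.
MU_PRIOR = {"a": (0.2, 0.2), "z": (0.5, 0.2), "ter": (0.3, 0.3),
            "v_diff": (0.0, 0.1), "v_mean": (0.3, 0.3)}
DELTA_PRIOR_SD = 0.01
BETA_PRIOR_SD = 0.5

_LOG_2PI = math.log(2.0 * math.pi)
_SQRT2 = math.sqrt(2.0)


def _phi(x: float) -> float:
    return 0.5 * math.erfc(-x / _SQRT2)


# vectorized counterparts (used for whole-population prior evaluation)

def _v_log_norm(x, m, s):
    z = (x - m) / s
    return -0.5 * z * z - np.log(s) - 0.5 * _LOG_2PI


def _v_log_pos_norm(x, m, s):
    from scipy.special import ndtr
    Z = ndtr(m / s)
    out = np.where((x > 0) & (Z > 0),
                   _v_log_norm(x, m, s) - np.log(np.maximum(Z, 1e-300)),
                   -np.inf)
    return out


def _v_log_tn01(x, m, s):
    from scipy.special import ndtr
    Z = ndtr((1 - m) / s) - ndtr(-m / s)
    out = np.where((x > 0) & (x < 1) & (Z > 0),
                   _v_log_norm(x, m, s) - np.log(np.maximum(Z, 1e-300)),
                   -np.inf)
    return out


def log_norm(x: float, m: float, s: float) -> float:
    """Normal log-density (s is a standard deviation)."""
    if s <= 0:
        return -np.inf
    z = (x - m) / s
    return -0.5 * z * z - math.log(s) - 0.5 * _LOG_2PI


def log_pos_norm(x: float, m: float, s: float) -> float:
    """Positive-truncated normal log-density, normalizer included."""
    if x <= 0 or s <= 0:
        return -np.inf
    Z = _phi(m / s)
    if Z <= 0:
        return -np.inf
    return log_norm(x, m, s) - math.log(Z)


def log_tn01(x: float, m: float, s: float) -> float:
    """Normal truncated to (0, 1), normalizer included."""
    if not (0 < x < 1) or s <= 0:
        return -np.inf
    Z = _phi((1 - m) / s) - _phi(-m / s)
    if Z <= 0:
        return -np.inf
    return log_norm(x, m, s) - math.log(Z)


def transform_drifts(v_mean: float, v_diff: float):
    """(v.mean, v.diff) -> (v1, v2); exact round-trip with drift_stats."""
    return v_mean + v_diff / 2.0, v_mean - v_diff / 2.0


def drift_stats(v1: float, v2: float):
    """(v1, v2) -> (v.mean, v.diff)."""
    return (v1 + v2) / 2.0, v1 - v2


@dataclass(frozen=True)
class HyperParams:
    """Named view of the 15 group-level parameters."""

    mu: dict
    sigma: dict
    delta: dict

    @classmethod
    def from_vector(cls, h: np.ndarray) -> "HyperParams":
        return cls(mu={k: h[i] for i, k in enumerate(PARAMS)},
                   sigma={k: h[5 + i] for i, k in enumerate(PARAMS)},
                   delta={k: h[10 + i] for i, k in enumerate(PARAMS)})

    def to_vector(self) -> np.ndarray:
        return np.array([self.mu[k] for k in PARAMS]
                        + [self.sigma[k] for k in PARAMS]
                        + [self.delta[k] for k in PARAMS])


@dataclass(frozen=True)
class CovariateSpec:
    """A per-participant covariate to partial out of the group-level means.

    ``values`` must align with the model's participant order and be
    standardized (mean 0, SD 1); pass ``standardize=True`` to
    :meth:`from_series` to do this on entry.
    """

    name: str
    values: np.ndarray
    prior_sd: float = BETA_PRIOR_SD

    @classmethod
    def from_series(cls, name: str, series: pd.Series, participants,
                    standardize: bool = True) -> "CovariateSpec":
        vals = series.reindex(participants).to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)):
            raise ValueError(f"covariate {name!r} missing for some participants")
        if standardize:
            vals = (vals - vals.mean()) / vals.std(ddof=0)
        return cls(name=name, values=vals)


class HierarchicalDDM:
    """Hierarchical diffusion model bound to a filtered trial table.

    Exposes the blocked-parameter interface the DE-MCMC sampler consumes:
    a hyper block (15 group-level parameters plus 5 regression weights per
    covariate) and one 5-vector block per participant, with the priors and
    Wiener first-passage likelihood documented at module level.
    """

    part_param_names = ("a", "z_rel", "ter", "v_diff", "v_mean")

    def __init__(self, trials: pd.DataFrame, covariates=None,
                 deadline: float = 2.5, coding: str = "stimulus",
                 s: float = 0.1):
        required = {"participant", "group", "difficulty", "direction",
                    "response", "rt", "censored", "excluded"}
        missing = required - set(trials.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}; "
                             "run prep.filter_trials first")
        self.deadline = float(deadline)
        self.coding = coding
        self.s = float(s)
        self.participants = sorted(trials["participant"].unique())
        self._pindex = {p: i for i, p in enumerate(self.participants)}
        groups = trials.drop_duplicates("participant").set_index("participant")["group"]
        self.group_signs = np.array(
            [1.0 if groups[p] == "autistic" else -1.0 for p in self.participants])
        self._trial_data = []
        for p in self.participants:
            sub = trials[trials["participant"] == p]
            self._trial_data.append(trial_arrays(sub, coding))
        # flat storage for the batched chains x participants likelihood
        ptr = np.zeros(len(self._trial_data) + 1, dtype=np.int64)
        for i, td in enumerate(self._trial_data):
            ptr[i + 1] = ptr[i] + len(td[0])
        self._flat_ptr = ptr
        self._flat = tuple(np.concatenate([td[j] for td in self._trial_data])
                           for j in range(5))
        self.covariates = list(covariates) if covariates else []
        for cov in self.covariates:
            if len(cov.values) != len(self.participants):
                raise ValueError(f"covariate {cov.name!r} has {len(cov.values)} values "
                                 f"for {len(self.participants)} participants")

    # -- sampler interface -------------------------------------------------

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_part_params(self) -> int:
        return 5

    @property
    def n_hyper(self) -> int:
        return 15 + 5 * len(self.covariates)

    @property
    def hyper_blocks(self):
        """Index groups for blocked hyper updates: one (mu, sigma, delta,
        betas...) triple-plus per model parameter. Low-dimensional blocks
        mix far better than one joint 15+-dimensional update when the
        chain count is modest."""
        blocks = []
        for k in range(5):
            idx = [k, 5 + k, 10 + k]
            for c in range(len(self.covariates)):
                idx.append(15 + 5 * c + k)
            blocks.append(np.array(idx))
        return blocks

    @property
    def hyper_names(self):
        names = ([f"mu_{k}" for k in PARAMS] + [f"sigma_{k}" for k in PARAMS]
                 + [f"delta_{k}" for k in PARAMS])
        for cov in self.covariates:
            names += [f"beta_{cov.name}_{k}" for k in PARAMS]
        return names

    @property
    def param_names(self):
        names = list(self.hyper_names)
        for p in self.participants:
            names += [f"{k}[{p}]" for k in self.part_param_names]
        return names

    def log_hyper_prior(self, h: np.ndarray) -> float:
        lp = 0.0
        lp += log_pos_norm(h[0], *MU_PRIOR["a"])
        lp += log_tn01(h[1], *MU_PRIOR["z"])
        lp += log_pos_norm(h[2], *MU_PRIOR["ter"])
        lp += log_norm(h[3], *MU_PRIOR["v_diff"])
        lp += log_norm(h[4], *MU_PRIOR["v_mean"])
        if lp == -np.inf:
            return -np.inf
        for i in range(5, 10):        # sigma ~ Gamma(1,1) == Exp(1)
            if h[i] <= 0:
                return -np.inf
            lp += -h[i]
        for i in range(10, 15):
            lp += log_norm(h[i], 0.0, DELTA_PRIOR_SD)
        for c, cov in enumerate(self.covariates):
            for i in range(15 + 5 * c, 20 + 5 * c):
                lp += log_norm(h[i], 0.0, cov.prior_sd)
        return lp

    def part_means(self, h: np.ndarray, p: int) -> np.ndarray:
        """Group-level means seen by participant p (group offset applied,
        covariates partialled in)."""
        g = self.group_signs[p]
        m = h[0:5] + g * h[10:15]
        for c, cov in enumerate(self.covariates):
            m = m + h[15 + 5 * c:20 + 5 * c] * cov.values[p]
        return m

    def log_part_prior_batch(self, H: np.ndarray, X: np.ndarray,
                             participants=None) -> np.ndarray:
        """Participant-level log prior, vectorized over chains and
        participants: ``H`` is (C, n_hyper), ``X`` is (C, Psub, 5) and the
        result (C, Psub). ``participants`` selects a subset of participant
        indices (default: all). Row-by-row equal to :meth:`log_part_prior`."""
        H = np.asarray(H)
        X = np.asarray(X)
        idx = (np.arange(self.n_participants) if participants is None
               else np.asarray(participants))
        g = self.group_signs[idx]
        sig = H[:, None, 5:10]
        M = H[:, None, 0:5] + g[None, :, None] * H[:, None, 10:15]
        for c, cov in enumerate(self.covariates):
            M = M + cov.values[idx][None, :, None] * H[:, None, 15 + 5 * c:20 + 5 * c]
        with np.errstate(divide="ignore", invalid="ignore"):
            out = _v_log_pos_norm(X[..., 0], M[..., 0], sig[..., 0])
            out = out + _v_log_tn01(X[..., 1], M[..., 1], sig[..., 1])
            out = out + _v_log_pos_norm(X[..., 2], M[..., 2], sig[..., 2])
            out = out + self._drift_prior_batch(H, X, M, sig, idx)
        bad = np.any(H[:, 5:10] <= 0, axis=1)
        out[bad] = -np.inf
        return out

    def log_part_prior_all(self, h: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Participant-level log prior for one hyper vector over all
        participants; X has shape (P, 5)."""
        return self.log_part_prior_batch(h[None, :], X[None])[0]

    def _drift_prior_batch(self, H, X, M, sig, idx) -> np.ndarray:
        return (_v_log_norm(X[..., 3], M[..., 3], sig[..., 3])
                + _v_log_norm(X[..., 4], M[..., 4], sig[..., 4]))

    def log_part_prior(self, h: np.ndarray, x: np.ndarray, p: int) -> float:
        if h[5] <= 0 or h[6] <= 0 or h[7] <= 0 or h[8] <= 0 or h[9] <= 0:
            return -np.inf
        m = self.part_means(h, p)
        sig = h[5:10]
        lp = log_pos_norm(x[0], m[0], sig[0])
        lp += log_tn01(x[1], m[1], sig[1])
        lp += log_pos_norm(x[2], m[2], sig[2])
        lp += self._log_drift_prior(h, x, p, m, sig)
        return lp

    def _log_drift_prior(self, h, x, p, m, sig) -> float:
        # overridden by the joint models (bivariate terms with EEG/ADHD)
        return log_norm(x[3], m[3], sig[3]) + log_norm(x[4], m[4], sig[4])

    def log_lik(self, x: np.ndarray, p: int) -> float:
        rt, resp, cens, diff_idx, sign = self._trial_data[p]
        if len(rt) == 0:
            return 0.0
        v1, v2 = transform_drifts(x[4], x[3])
        return wfpt.loglik_arrays(rt, resp, cens, diff_idx, sign,
                                  x[0], x[1], x[2], v1, v2, self.s, self.deadline)

    def log_lik_batch(self, Xp: np.ndarray, p: int, skip=None) -> np.ndarray:
        """Likelihood of participant p's trials under many candidate
        parameter vectors (rows of ``Xp``); ``skip`` rows return -inf."""
        rt, resp, cens, diff_idx, sign = self._trial_data[p]
        n = Xp.shape[0]
        if len(rt) == 0:
            return np.zeros(n)
        params = np.column_stack([Xp[:, 0], Xp[:, 1], Xp[:, 2],
                                  Xp[:, 4] + Xp[:, 3] / 2.0,
                                  Xp[:, 4] - Xp[:, 3] / 2.0])
        return wfpt.loglik_arrays_many(rt, resp, cens, diff_idx, sign,
                                       params, self.s, self.deadline, skip)

    def log_lik_all_batch(self, Xall: np.ndarray, skip: np.ndarray) -> np.ndarray:
        """Likelihood for all participants under many chains at once;
        ``Xall`` is (C, P, 5), ``skip`` a (C, P) boolean mask of rows to
        return -inf without evaluation."""
        rt, resp, cens, diff_idx, sign = self._flat
        params = np.empty_like(Xall)
        params[..., 0] = Xall[..., 0]
        params[..., 1] = Xall[..., 1]
        params[..., 2] = Xall[..., 2]
        params[..., 3] = Xall[..., 4] + Xall[..., 3] / 2.0
        params[..., 4] = Xall[..., 4] - Xall[..., 3] / 2.0
        return wfpt.loglik_flat(rt, resp, cens, diff_idx, sign,
                                self._flat_ptr, params, self.s,
                                self.deadline, np.ascontiguousarray(skip))

    def log_posterior(self, h: np.ndarray, X: np.ndarray) -> float:
        """Full joint log-density: hyper prior + participant priors +
        likelihoods. ``X`` has shape (n_participants, 5)."""
        lp = self.log_hyper_prior(h)
        if lp == -np.inf:
            return -np.inf
        for p in range(self.n_participants):
            lpp = self.log_part_prior(h, X[p], p)
            if lpp == -np.inf:
                return -np.inf
            lp += lpp + self.log_lik(X[p], p)
        return lp

    # -- initialization ----------------------------------------------------

    def draw_hyper(self, rng: np.random.Generator) -> np.ndarray:
        h = np.empty(15 + 5 * len(self.covariates))
        for i, k in enumerate(PARAMS):
            loc, sd = MU_PRIOR[k]
            if k in ("a", "ter"):
                val = -1.0
                while val <= 0:
                    val = rng.normal(loc, sd)
            elif k == "z":
                val = 0.0
                while not (0 < val < 1):
                    val = rng.normal(loc, sd)
            else:
                val = rng.normal(loc, sd)
            h[i] = val
        h[5:10] = rng.exponential(1.0, 5)
        h[10:15] = rng.normal(0.0, DELTA_PRIOR_SD, 5)
        for c, cov in enumerate(self.covariates):
            h[15 + 5 * c:20 + 5 * c] = rng.normal(0.0, cov.prior_sd, 5)
        return h

    def draw_part(self, rng: np.random.Generator, h: np.ndarray, p: int) -> np.ndarray:
        m = self.part_means(h, p)
        sig = h[5:10]
        x = np.empty(5)
        for i in (0, 2):
            val = -1.0
            while val <= 0:
                val = rng.normal(m[i], sig[i])
            x[i] = val
        val = 0.0
        while not (0 < val < 1):
            val = rng.normal(m[1], sig[1])
        x[1] = val
        x[3] = rng.normal(m[3], sig[3])
        x[4] = rng.normal(m[4], sig[4])
        return x

    # -- reporting ---------------------------------------------------------

    def model_card(self) -> dict:
        """JSON-serializable description of the fitted model structure."""
        return {
            "parameters": list(PARAMS),
            "mu_priors": {k: {"loc": MU_PRIOR[k][0], "sd": MU_PRIOR[k][1]} for k in PARAMS},
            "sigma_prior": "Gamma(1, 1)",
            "delta_prior_sd": DELTA_PRIOR_SD,
            "covariates": [c.name for c in self.covariates],
            "n_participants": self.n_participants,
            "deadline_s": self.deadline,
            "response_coding": self.coding,
            "noise_s": self.s,
        }
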