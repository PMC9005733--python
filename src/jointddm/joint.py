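"""Joint models linking diffusion parameters to EEG slopes and ADHD scores.

Both joint models keep the hierarchical diffusion structure and replace
one (or two) univariate participant-level prior terms with bivariate
normals that couple a behavioural parameter to an observed measure:

EEG joint model
    The drift terms become bivariate with the response-locked slope
    measure: ``[v.diff_p, EEG.diff_p]`` and ``[v.mean_p, EEG.mean_p]``
    are each bivariate normal with their own correlation ``rho`` (one
    correlation per equation, either shared across groups or estimated
    per group). EEG hyper-priors: ``mu_EEG.diff ~ N(0, 0.5)``,
    ``mu_EEG.mean ~ N(0, 1)``, ``sigma ~ Gamma(1,1)``,
    ``delta ~ N(0, 0.01)``, ``rho ~ U(-1, 1)``. Participants without EEG
    contribute the univariate (marginal) drift terms, keeping sample
    sizes comparable to the behaviour-only fits.

ADHD joint model
    One model per (parameter of interest, subscale) pair: the linked
    parameter's prior term becomes bivariate with the observed item
    average (``mu_subscale ~ N(0.5, 0.2)``; correlations estimated per
    group by default). The printed model is an untruncated bivariate
    normal even for ``a`` and ``ter``; a support-respecting variant is
    available behind ``respect_support``.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import demcmc
from .demcmc import SamplerSchedule
from .model import (PARAMS, DELTA_PRIOR_SD, HierarchicalDDM, log_norm,
                    log_pos_norm)

__all__ = ["JointEEGModel", "JointADHDModel", "fit_joint"]

_LOG_2PI = math.log(2.0 * math.pi)


def _v_log_bn(x, y, mx, my, sx, sy, r):
    """Vectorized bivariate-normal log-density (elementwise over arrays)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        om = 1.0 - r * r
        zx = (x - mx) / sx
        zy = (y - my) / sy
        q = (zx * zx - 2.0 * r * zx * zy + zy * zy) / om
        val = -_LOG_2PI - np.log(sx * sy) - 0.5 * np.log(om) - 0.5 * q
    valid = (sx > 0) & (sy > 0) & (np.abs(r) < 1.0)
    return np.where(valid, val, -np.inf)


def log_bivariate_normal(x, y, mx, my, sx, sy, r) -> float:
    """Bivariate normal log-density; -inf when the covariance is not
    positive-definite (|r| >= 1 or a non-positive SD), so the sampler
    rejects such proposals instead of raising."""
    if sx <= 0 or sy <= 0 or not (-1.0 < r < 1.0):
        return -np.inf
    zx = (x - mx) / sx
    zy = (y - my) / sy
    om = 1.0 - r * r
    q = (zx * zx - 2.0 * r * zx * zy + zy * zy) / om
    return -_LOG_2PI - math.log(sx * sy) - 0.5 * math.log(om) - 0.5 * q


class JointEEGModel(HierarchicalDDM):
    """Hierarchical diffusion model jointly distributed with EEG slopes.

    ``slopes`` is a table with columns ``participant``, ``eeg_mean`` and
    ``eeg_diff`` (the pre-response slope averaged over / differenced
    between difficulty levels). Missing participants are allowed and
    enter through the marginal drift terms. Covariates (e.g. age) are
    partialled out of every behavioural *and* EEG group-level mean.
    """

    def __init__(self, trials: pd.DataFrame, slopes: pd.DataFrame,
                 rho_by_group: bool = False, covariates=None,
                 standardize: bool = True, **kwargs):
        super().__init__(trials, covariates=covariates, **kwargs)
        self.rho_by_group = bool(rho_by_group)
        s = slopes.set_index("participant")
        self.eeg_mean = np.full(self.n_participants, np.nan)
        self.eeg_diff = np.full(self.n_participants, np.nan)
        for p, pid in enumerate(self.participants):
            if pid in s.index:
                self.eeg_mean[p] = s.loc[pid, "eeg_mean"]
                self.eeg_diff[p] = s.loc[pid, "eeg_diff"]
        self.has_eeg = np.isfinite(self.eeg_mean) & np.isfinite(self.eeg_diff)
        # The EEG hyper-priors (mu ~ N(0,1)/N(0,0.5), sigma ~ Gamma(1,1))
        # describe a unit-scale measure, so the slope columns are z-scored
        # on entry by default; the correlation of interest is invariant to
        # this, and mu/sigma/delta_EEG are then in SD units of the measure.
        self.standardized = bool(standardize) and self.has_eeg.any()
        if self.standardized:
            for arr in (self.eeg_mean, self.eeg_diff):
                vals = arr[self.has_eeg]
                sd = vals.std(ddof=0)
                arr[self.has_eeg] = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
        self._base_nh = super().n_hyper

    # hyper layout: [base | mu_Ed, mu_Em, sig_Ed, sig_Em, del_Ed, del_Em,
    #                beta_cov_Ed, beta_cov_Em (per covariate) | rhos]
    @property
    def n_rho(self) -> int:
        return 4 if self.rho_by_group else 2

    @property
    def n_hyper(self) -> int:
        return self._base_nh + 6 + 2 * len(self.covariates) + self.n_rho

    @property
    def hyper_names(self):
        names = list(super().hyper_names)
        names += ["mu_eeg_diff", "mu_eeg_mean", "sigma_eeg_diff",
                  "sigma_eeg_mean", "delta_eeg_diff", "delta_eeg_mean"]
        for cov in self.covariates:
            names += [f"beta_{cov.name}_eeg_diff", f"beta_{cov.name}_eeg_mean"]
        if self.rho_by_group:
            names += ["rho_diff_autistic", "rho_diff_comparison",
                      "rho_mean_autistic", "rho_mean_comparison"]
        else:
            names += ["rho_diff", "rho_mean"]
        return names

    @property
    def hyper_blocks(self):
        blocks = list(super().hyper_blocks)
        b0 = self._base_nh
        ncov = len(self.covariates)
        rho0 = b0 + 6 + 2 * ncov
        # EEG.diff block: mu, sigma, delta, betas, its rho(s)
        diff_idx = [b0, b0 + 2, b0 + 4] + [b0 + 6 + 2 * c for c in range(ncov)]
        mean_idx = [b0 + 1, b0 + 3, b0 + 5] + [b0 + 7 + 2 * c for c in range(ncov)]
        if self.rho_by_group:
            diff_idx += [rho0, rho0 + 1]
            mean_idx += [rho0 + 2, rho0 + 3]
        else:
            diff_idx += [rho0]
            mean_idx += [rho0 + 1]
        blocks.append(np.array(diff_idx))
        blocks.append(np.array(mean_idx))
        return blocks

    def log_hyper_prior(self, h: np.ndarray) -> float:
        lp = super().log_hyper_prior(h[:self._base_nh])
        if lp == -np.inf:
            return -np.inf
        b0 = self._base_nh
        lp += log_norm(h[b0], 0.0, 0.5)       # mu_EEG.diff
        lp += log_norm(h[b0 + 1], 0.0, 1.0)   # mu_EEG.mean
        for i in (b0 + 2, b0 + 3):            # sigma ~ Exp(1)
            if h[i] <= 0:
                return -np.inf
            lp += -h[i]
        lp += log_norm(h[b0 + 4], 0.0, DELTA_PRIOR_SD)
        lp += log_norm(h[b0 + 5], 0.0, DELTA_PRIOR_SD)
        for c, cov in enumerate(self.covariates):
            lp += log_norm(h[b0 + 6 + 2 * c], 0.0, cov.prior_sd)
            lp += log_norm(h[b0 + 7 + 2 * c], 0.0, cov.prior_sd)
        rho0 = b0 + 6 + 2 * len(self.covariates)
        for i in range(rho0, rho0 + self.n_rho):
            if not (-1.0 < h[i] < 1.0):
                return -np.inf
            lp += -math.log(2.0)              # U(-1, 1)
        return lp

    def _eeg_means(self, h: np.ndarray, p: int):
        b0 = self._base_nh
        g = self.group_signs[p]
        m_d = h[b0] + g * h[b0 + 4]
        m_m = h[b0 + 1] + g * h[b0 + 5]
        for c, cov in enumerate(self.covariates):
            m_d += h[b0 + 6 + 2 * c] * cov.values[p]
            m_m += h[b0 + 7 + 2 * c] * cov.values[p]
        return m_d, m_m

    def _rhos(self, h: np.ndarray, p: int):
        rho0 = self._base_nh + 6 + 2 * len(self.covariates)
        if self.rho_by_group:
            j = 0 if self.group_signs[p] > 0 else 1
            return h[rho0 + j], h[rho0 + 2 + j]
        return h[rho0], h[rho0 + 1]

    def _log_drift_prior(self, h, x, p, m, sig) -> float:
        if not self.has_eeg[p]:
            return log_norm(x[3], m[3], sig[3]) + log_norm(x[4], m[4], sig[4])
        m_d, m_m = self._eeg_means(h, p)
        b0 = self._base_nh
        s_d, s_m = h[b0 + 2], h[b0 + 3]
        r_d, r_m = self._rhos(h, p)
        lp = log_bivariate_normal(x[3], self.eeg_diff[p], m[3], m_d,
                                  sig[3], s_d, r_d)
        lp += log_bivariate_normal(x[4], self.eeg_mean[p], m[4], m_m,
                                   sig[4], s_m, r_m)
        return lp

    def _drift_prior_batch(self, H, X, M, sig, idx) -> np.ndarray:
        from .model import _v_log_norm
        uni = (_v_log_norm(X[..., 3], M[..., 3], sig[..., 3])
               + _v_log_norm(X[..., 4], M[..., 4], sig[..., 4]))
        has = self.has_eeg[idx]
        if not has.any():
            return uni
        b0 = self._base_nh
        g = self.group_signs[idx]
        m_d = H[:, None, b0] + g[None, :] * H[:, None, b0 + 4]
        m_m = H[:, None, b0 + 1] + g[None, :] * H[:, None, b0 + 5]
        for c, cov in enumerate(self.covariates):
            m_d = m_d + H[:, None, b0 + 6 + 2 * c] * cov.values[idx][None, :]
            m_m = m_m + H[:, None, b0 + 7 + 2 * c] * cov.values[idx][None, :]
        s_d = H[:, None, b0 + 2]
        s_m = H[:, None, b0 + 3]
        rho0 = b0 + 6 + 2 * len(self.covariates)
        aut = (g > 0)[None, :]
        if self.rho_by_group:
            r_d = np.where(aut, H[:, None, rho0], H[:, None, rho0 + 1])
            r_m = np.where(aut, H[:, None, rho0 + 2], H[:, None, rho0 + 3])
        else:
            r_d = np.broadcast_to(H[:, None, rho0], m_d.shape)
            r_m = np.broadcast_to(H[:, None, rho0 + 1], m_m.shape)
        with np.errstate(invalid="ignore", divide="ignore"):
            biv = (_v_log_bn(X[..., 3], self.eeg_diff[idx][None, :],
                             M[..., 3], m_d, sig[..., 3], s_d, r_d)
                   + _v_log_bn(X[..., 4], self.eeg_mean[idx][None, :],
                               M[..., 4], m_m, sig[..., 4], s_m, r_m))
        return np.where(has[None, :], biv, uni)

    def draw_hyper(self, rng: np.random.Generator) -> np.ndarray:
        h = np.empty(self.n_hyper)
        h[:self._base_nh] = super().draw_hyper(rng)
        b0 = self._base_nh
        h[b0] = rng.normal(0.0, 0.5)
        h[b0 + 1] = rng.normal(0.0, 1.0)
        h[b0 + 2:b0 + 4] = rng.exponential(1.0, 2)
        h[b0 + 4:b0 + 6] = rng.normal(0.0, DELTA_PRIOR_SD, 2)
        for c, cov in enumerate(self.covariates):
            h[b0 + 6 + 2 * c:b0 + 8 + 2 * c] = rng.normal(0.0, cov.prior_sd, 2)
        rho0 = b0 + 6 + 2 * len(self.covariates)
        h[rho0:rho0 + self.n_rho] = rng.uniform(-1.0, 1.0, self.n_rho)
        return h

    def model_card(self) -> dict:
        card = super().model_card()
        card["joint"] = {
            "measure": "eeg_slope",
            "rho_by_group": self.rho_by_group,
            "n_with_eeg": int(self.has_eeg.sum()),
            "rho_prior": "U(-1, 1)",
        }
        return card


class JointADHDModel(HierarchicalDDM):
    """Hierarchical diffusion model with one parameter coupled to an ADHD
    subscale through a bivariate normal (exactly as printed, i.e. without
    truncating the linked parameter unless ``respect_support``)."""

    LINKABLE = {"a": 0, "ter": 2, "v_mean": 4}

    def __init__(self, trials: pd.DataFrame, scores: pd.DataFrame,
                 link: str = "v_mean", subscale: str = "inatt",
                 rho_by_group: bool = True, respect_support: bool = False,
                 **kwargs):
        if link not in self.LINKABLE:
            raise ValueError(f"link must be one of {sorted(self.LINKABLE)}, got {link!r}")
        if subscale not in ("inatt", "hyper"):
            raise ValueError(f"subscale must be 'inatt' or 'hyper', got {subscale!r}")
        super().__init__(trials, **kwargs)
        self.link = link
        self.link_idx = self.LINKABLE[link]
        self.subscale = subscale
        self.rho_by_group = bool(rho_by_group)
        self.respect_support = bool(respect_support)
        s = scores.set_index("participant")
        self.score = np.full(self.n_participants, np.nan)
        for p, pid in enumerate(self.participants):
            if pid in s.index:
                self.score[p] = s.loc[pid, subscale]
        self.has_score = np.isfinite(self.score)
        self._base_nh = super().n_hyper

    @property
    def n_rho(self) -> int:
        return 2 if self.rho_by_group else 1

    @property
    def n_hyper(self) -> int:
        return self._base_nh + 3 + self.n_rho

    @property
    def hyper_names(self):
        names = list(super().hyper_names)
        sc = self.subscale
        names += [f"mu_{sc}", f"sigma_{sc}", f"delta_{sc}"]
        if self.rho_by_group:
            names += ["rho_autistic", "rho_comparison"]
        else:
            names += ["rho"]
        return names

    @property
    def hyper_blocks(self):
        blocks = list(super().hyper_blocks)
        b0 = self._base_nh
        blocks.append(np.arange(b0, self.n_hyper))
        return blocks

    def log_hyper_prior(self, h: np.ndarray) -> float:
        lp = super().log_hyper_prior(h[:self._base_nh])
        if lp == -np.inf:
            return -np.inf
        b0 = self._base_nh
        lp += log_norm(h[b0], 0.5, 0.2)       # mu_subscale
        if h[b0 + 1] <= 0:
            return -np.inf
        lp += -h[b0 + 1]                      # sigma ~ Exp(1)
        lp += log_norm(h[b0 + 2], 0.0, DELTA_PRIOR_SD)
        for i in range(b0 + 3, b0 + 3 + self.n_rho):
            if not (-1.0 < h[i] < 1.0):
                return -np.inf
            lp += -math.log(2.0)
        return lp

    def _rho(self, h: np.ndarray, p: int) -> float:
        b0 = self._base_nh
        if self.rho_by_group:
            return h[b0 + 3] if self.group_signs[p] > 0 else h[b0 + 4]
        return h[b0 + 3]

    def log_part_prior(self, h: np.ndarray, x: np.ndarray, p: int) -> float:
        if np.any(h[5:10] <= 0):
            return -np.inf
        m = self.part_means(h, p)
        sig = h[5:10]
        li = self.link_idx
        lp = 0.0
        for i, kind in ((0, "pos"), (1, "tn01"), (2, "pos"), (3, "norm"), (4, "norm")):
            if i == li and self.has_score[p]:
                continue
            if kind == "pos":
                lp += log_pos_norm(x[i], m[i], sig[i])
            elif kind == "tn01":
                from .model import log_tn01
                lp += log_tn01(x[i], m[i], sig[i])
            else:
                lp += log_norm(x[i], m[i], sig[i])
            if lp == -np.inf:
                return -np.inf
        if self.has_score[p]:
            b0 = self._base_nh
            g = self.group_signs[p]
            m_s = h[b0] + g * h[b0 + 2]
            s_s = h[b0 + 1]
            lp_link = log_bivariate_normal(x[li], self.score[p], m[li], m_s,
                                           sig[li], s_s, self._rho(h, p))
            if self.respect_support and li in (0, 2):
                # reject out-of-support values and renormalize the
                # linked parameter's marginal (approximate truncation)
                if x[li] <= 0:
                    return -np.inf
                from .model import _phi
                Z = _phi(m[li] / sig[li])
                if Z <= 0:
                    return -np.inf
                lp_link -= math.log(Z)
            lp += lp_link
        return lp

    def log_part_prior_batch(self, H, X, participants=None) -> np.ndarray:
        from .model import _v_log_norm, _v_log_pos_norm, _v_log_tn01
        from scipy.special import ndtr
        H = np.asarray(H)
        X = np.asarray(X)
        idx = (np.arange(self.n_participants) if participants is None
               else np.asarray(participants))
        g = self.group_signs[idx]
        sig = H[:, None, 5:10]
        M = H[:, None, 0:5] + g[None, :, None] * H[:, None, 10:15]
        for c, cov in enumerate(self.covariates):
            M = M + cov.values[idx][None, :, None] * H[:, None, 15 + 5 * c:20 + 5 * c]
        li = self.link_idx
        kinds = {0: _v_log_pos_norm, 1: _v_log_tn01, 2: _v_log_pos_norm,
                 3: _v_log_norm, 4: _v_log_norm}
        out = np.zeros(X.shape[:-1])
        b0 = self._base_nh
        with np.errstate(divide="ignore", invalid="ignore"):
            for i, fn in kinds.items():
                term = fn(X[..., i], M[..., i], sig[..., i])
                if i == li and self.has_score[idx].any():
                    m_s = H[:, None, b0] + g[None, :] * H[:, None, b0 + 2]
                    s_s = H[:, None, b0 + 1]
                    if self.rho_by_group:
                        r = np.where((g > 0)[None, :],
                                     H[:, None, b0 + 3], H[:, None, b0 + 4])
                    else:
                        r = np.broadcast_to(H[:, None, b0 + 3], m_s.shape)
                    biv = _v_log_bn(X[..., li], self.score[idx][None, :],
                                    M[..., li], m_s, sig[..., li], s_s, r)
                    if self.respect_support and li in (0, 2):
                        Z = ndtr(M[..., li] / sig[..., li])
                        biv = np.where((X[..., li] > 0) & (Z > 0),
                                       biv - np.log(np.maximum(Z, 1e-300)),
                                       -np.inf)
                    term = np.where(self.has_score[idx][None, :], biv, term)
                out = out + term
        bad = np.any(H[:, 5:10] <= 0, axis=1)
        out[bad] = -np.inf
        return out

    def draw_hyper(self, rng: np.random.Generator) -> np.ndarray:
        h = np.empty(self.n_hyper)
        h[:self._base_nh] = super().draw_hyper(rng)
        b0 = self._base_nh
        h[b0] = rng.normal(0.5, 0.2)
        h[b0 + 1] = rng.exponential(1.0)
        h[b0 + 2] = rng.normal(0.0, DELTA_PRIOR_SD)
        h[b0 + 3:b0 + 3 + self.n_rho] = rng.uniform(-1.0, 1.0, self.n_rho)
        return h

    def model_card(self) -> dict:
        card = super().model_card()
        card["joint"] = {
            "measure": f"adhd_{self.subscale}",
            "link_parameter": self.link,
            "rho_by_group": self.rho_by_group,
            "respect_support": self.respect_support,
            "n_with_scores": int(self.has_score.sum()),
        }
        return card


def fit_joint(model, schedule: SamplerSchedule | None = None,
              n_chains: int = 15, seed: int = 0) -> demcmc.SamplerResult:
    """Fit a joint model with DE-MCMC (defaults: 15 chains, 3000
    iterations, 1000 burn-in, no migration — the joint models are more
    computationally intensive, so the run is shorter)."""
    schedule = schedule or SamplerSchedule.joint_default()
    return demcmc.fit(model, schedule, n_chains=n_chains, seed=seed)
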