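"""Posterior summaries, Savage-Dickey Bayes factors and fit checks.

The group-difference questions are tested with Savage-Dickey density
ratios: for a nested point null (delta = 0), BF10 = prior(0) / posterior(0).
Bayes factors above 3 are read as moderate evidence for a group difference,
below 1/3 as moderate evidence for the null, and anything between as weak,
anecdotal evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import wfpt
from .demcmc import SamplerResult, gelman_rubin
from .model import transform_drifts

__all__ = [
    "BFResult",
    "savage_dickey",
    "bf_band",
    "summarize",
    "posterior_predictive_cdf",
    "plot_prior_posterior",
]


def bf_band(bf10: float) -> str:
    """Interpretation band with boundaries exactly at 3 and 1/3."""
    if bf10 > 3.0:
        return "moderate-alt"
    if bf10 < 1.0 / 3.0:
        return "moderate-null"
    return "anecdotal"


@dataclass(frozen=True)
class BFResult:
    """Savage-Dickey Bayes factor for a point null on one parameter."""

    parameter: str
    prior_density: float
    posterior_density: float
    bf10: float
    band: str
    low_confidence: bool = False


def _prior_density_at(prior, point: float) -> float:
    if callable(prior):
        return float(prior(point))
    if np.isscalar(prior):
        return float(prior)
    loc, sd = prior
    return float(stats.norm.pdf(point, loc, sd))


def savage_dickey(draws: np.ndarray, prior, point: float = 0.0,
                  parameter: str = "delta", method: str = "kde") -> BFResult:
    """Savage-Dickey ratio BF10 = prior(point) / posterior(point).

    ``draws`` are post-burn-in posterior samples of the nested parameter.
    ``prior`` is the prior density at the null: a (loc, sd) pair for a
    normal prior, a callable pdf, or the density value itself (e.g. 0.5
    for a U(-1, 1) prior on a correlation). The posterior density is
    estimated by a Gaussian KDE with Silverman bandwidth; ``method=
    "normal"`` instead uses a moment-matched normal (a sensitivity check).
    A result based on few draws near the null is flagged low-confidence
    rather than silently returned.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if len(draws) < 1000:
        raise ValueError("Savage-Dickey estimation needs >= 1000 posterior draws")
    p0 = _prior_density_at(prior, point)
    low = False
    if method == "kde":
        kde = stats.gaussian_kde(draws, bw_method="silverman")
        post0 = float(kde(point)[0])
        bw = float(kde.factor * draws.std(ddof=1))
        near = np.abs(draws - point) < 3.0 * bw
        if near.sum() < 10:
            low = True
            warnings.warn(
                f"only {int(near.sum())} draws within 3 bandwidths of {point}; "
                "the Savage-Dickey estimate is unstable")
    elif method == "normal":
        post0 = float(stats.norm.pdf(point, draws.mean(), draws.std(ddof=1)))
    else:
        raise ValueError(f"unknown density method {method!r}")
    if post0 <= 0:
        bf10 = np.inf
        low = True
    else:
        bf10 = p0 / post0
    return BFResult(parameter=parameter, prior_density=p0,
                    posterior_density=post0, bf10=bf10,
                    band=bf_band(bf10), low_confidence=low)


def summarize(result: SamplerResult, params=None) -> pd.DataFrame:
    """Posterior mean, SD, central 95% credible interval and PSRF per
    parameter (the standard summary shape for reporting joint-model
    correlations and group-difference parameters)."""
    names = list(result.param_names) if params is None else list(params)
    post = result.posterior(flat=False)
    idx = [result.param_names.index(n) for n in names]
    flat = post.reshape(-1, post.shape[-1])
    psrf = gelman_rubin(post)
    rows = []
    for n, i in zip(names, idx):
        d = flat[:, i]
        lo, hi = np.percentile(d, [2.5, 97.5])
        rows.append({"parameter": n, "mean": d.mean(), "sd": d.std(ddof=1),
                     "ci_2.5": lo, "ci_97.5": hi, "psrf": psrf[i]})
    return pd.DataFrame(rows).set_index("parameter")


def posterior_predictive_cdf(result: SamplerResult, model, rng=None,
                             n_draws: int = 100, grid=None, ngrid_sim: int = 256):
    """Posterior-predictive defective CDFs per group x difficulty.

    For each posterior draw, every participant's trials are re-simulated
    with their sampled parameters (same per-cell trial counts and deadline
    as the data), pooled within group x difficulty, and summarized as
    correct/error defective CDFs on ``grid``; the 2.5/50/97.5 percentile
    curves across draws form the predictive band. The observed data's
    defective CDFs are returned alongside for overlay, and the censored
    mass in each cell equals one minus the cell's defective CDFs at the
    deadline (i.e. the average survivor function) by construction.
    """
    if n_draws < 1:
        raise ValueError("need at least one posterior draw")
    rng = np.random.default_rng(0) if rng is None else rng
    post = result.posterior(flat=True)
    if post.shape[0] == 0:
        raise ValueError("sampler result contains no post-burn-in draws")
    nh = model.n_hyper
    deadline = model.deadline
    grid = np.linspace(0.0, deadline, 51) if grid is None else np.asarray(grid)

    # observed per-cell structure
    cells = {}   # (group, difficulty) -> list of (p, n_right, n_left)
    obs = {}
    for p, pid in enumerate(model.participants):
        rt, resp, cens, diff_idx, sign = model._trial_data[p]
        group = "autistic" if model.group_signs[p] > 0 else "comparison"
        for d, dname in ((0, "easy"), (1, "difficult")):
            m = diff_idx == d
            if m.sum() == 0:
                continue
            key = (group, dname)
            cells.setdefault(key, []).append(
                (p, int((m & (sign > 0)).sum()), int((m & (sign < 0)).sum())))
            o = obs.setdefault(key, {"rt": [], "correct": [], "n": 0})
            o["n"] += int(m.sum())
            resp_m = m & ~cens
            o["rt"].append(rt[resp_m])
            o["correct"].append((resp[resp_m] == sign[resp_m]))

    out = {"time_grid": grid, "cells": {}}
    draws_idx = rng.integers(post.shape[0], size=n_draws)
    for key, members in cells.items():
        n_cell = sum(nr + nl for _, nr, nl in members)
        curves_c = np.empty((n_draws, len(grid)))
        curves_e = np.empty((n_draws, len(grid)))
        d_idx = 0 if key[1] == "easy" else 1
        for j, di in enumerate(draws_idx):
            draw = post[di]
            rts_c, rts_e, n_tot = [], [], 0
            for p, nr, nl in members:
                x = draw[nh + 5 * p: nh + 5 * p + 5]
                v1, v2 = transform_drifts(x[4], x[3])
                v = (v1, v2)[d_idx]
                try:
                    params = wfpt.DDMParams(a=x[0], z=x[1] * x[0], ter=x[2],
                                            v1=v1, v2=v2, s=model.s)
                except ValueError:
                    continue
                for n_sub, sgn in ((nr, 1.0), (nl, -1.0)):
                    if n_sub == 0:
                        continue
                    bnd, rt_sim = wfpt.simulate_trials(
                        n_sub, params, sgn * v, deadline, rng, ngrid=ngrid_sim)
                    resp_m = bnd != 0
                    correct = bnd[resp_m] == (1 if sgn > 0 else -1)
                    rts_c.append(rt_sim[resp_m][correct])
                    rts_e.append(rt_sim[resp_m][~correct])
                    n_tot += n_sub
            rc = np.concatenate(rts_c) if rts_c else np.empty(0)
            re = np.concatenate(rts_e) if rts_e else np.empty(0)
            denom = max(n_tot, 1)
            curves_c[j] = np.searchsorted(np.sort(rc), grid, side="right") / denom
            curves_e[j] = np.searchsorted(np.sort(re), grid, side="right") / denom
        o = obs[key]
        rt_all = np.concatenate(o["rt"])
        cor_all = np.concatenate(o["correct"])
        denom = max(o["n"], 1)
        out["cells"][key] = {
            "correct": {
                "lo": np.percentile(curves_c, 2.5, axis=0),
                "median": np.percentile(curves_c, 50, axis=0),
                "hi": np.percentile(curves_c, 97.5, axis=0),
                "observed": np.searchsorted(np.sort(rt_all[cor_all]), grid,
                                            side="right") / denom,
            },
            "error": {
                "lo": np.percentile(curves_e, 2.5, axis=0),
                "median": np.percentile(curves_e, 50, axis=0),
                "hi": np.percentile(curves_e, 97.5, axis=0),
                "observed": np.searchsorted(np.sort(rt_all[~cor_all]), grid,
                                            side="right") / denom,
            },
            "observed_censored_mass": 1.0 - len(rt_all) / denom,
            "predicted_censored_mass": float(
                1.0 - curves_c[:, -1].mean() - curves_e[:, -1].mean()),
        }
    return out


def plot_prior_posterior(draws, prior, parameter: str = "delta", ax=None,
                         point: float = 0.0):
    """Overlay the prior density and a KDE of the posterior draws, with
    the Savage-Dickey evaluation point marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    draws = np.asarray(draws).ravel()
    lo, hi = np.percentile(draws, [0.1, 99.9])
    span = hi - lo
    x = np.linspace(min(lo - 0.2 * span, point - 0.1 * span),
                    max(hi + 0.2 * span, point + 0.1 * span), 400)
    kde = stats.gaussian_kde(draws, bw_method="silverman")
    if callable(prior):
        pr = np.array([prior(xi) for xi in x])
    elif np.isscalar(prior):
        pr = np.full_like(x, float(prior))
    else:
        pr = stats.norm.pdf(x, *prior)
    ax.plot(x, pr, label="prior", color="tab:blue")
    ax.plot(x, kde(x), label="posterior", color="tab:purple")
    ax.axvline(point, color="k", lw=0.8, ls=":")
    ax.set_xlabel(parameter)
    ax.set_ylabel("density")
    ax.legend()
    return ax
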