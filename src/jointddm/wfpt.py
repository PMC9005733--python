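"""Exact numerics for the two-boundary Wiener diffusion process.

This module is the likelihood engine of the package: first-passage-time
densities and defective CDFs for a diffusion process between two absorbing
bounds, the survivor function used to score response-deadline timeouts,
an exact trial simulator, and the per-participant log-likelihood.

Model
-----
Evidence ``X(t)`` starts at ``z`` between absorbing bounds at 0 (lower,
"left") and ``a`` (upper, "right") and evolves as ``dX = v dt + s dW``.
A response is emitted when a bound is first reached, at time
``rt = ter + T`` where ``T`` is the first-passage time and ``ter`` the
non-decision time. Trials that have not terminated by the response
deadline are censored and contribute the survivor function at the
deadline to the likelihood.

The density is evaluated through the classic small-time / large-time
series with automatic switching, with term counts chosen so the
truncation error is far below 1e-7. All kernels work internally in
unit-noise coordinates (``a/s``, ``v/s``, ``w = z/a``); densities and
CDFs are invariant under common rescaling of (a, z, v, s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "wfpt_density",
    "defective_cdf",
    "survivor",
    "simulate_trial",
    "simulate_trials",
    "loglik_participant",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
# Normalized decision time below which the large-time CDF tail series is
# abandoned for direct Gauss-Legendre integration of the density.
_TAU_SWITCH = 0.25
_GL_X, _GL_W = np.polynomial.legendre.leggauss(96)


@dataclass(frozen=True)
class DDMParams:
    """One participant's diffusion parameters.

    a : boundary separation (evidence units), > 0
    z : starting point (evidence units), 0 < z < a
    ter : non-decision time (s), >= 0
    v1, v2 : drift-rates for the easy (1) and difficult (2) level
    s : within-trial noise, fixed at 0.1 by convention
    """

    a: float
    z: float
    ter: float
    v1: float
    v2: float
    s: float = 0.1

    def __post_init__(self) -> None:
        if not (self.a > 0):
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not (0 < self.z < self.a):
            raise ValueError(f"starting point must satisfy 0 < z < a, got z={self.z}, a={self.a}")
        if self.ter < 0:
            raise ValueError(f"non-decision time must be non-negative, got ter={self.ter}")
        if not (self.s > 0):
            raise ValueError(f"noise must be positive, got s={self.s}")

    @property
    def w(self) -> float:
        """Relative starting point z/a."""
        return self.z / self.a

    def with_drifts(self, v1: float, v2: float) -> "DDMParams":
        return replace(self, v1=v1, v2=v2)


# ---------------------------------------------------------------------------
# numba kernels (unit-noise coordinates; "lower" = bound at 0)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _f1_log(tau, w):
    """log of the standard first-passage density at the lower bound of the
    unit interval at normalized time tau, zero drift, start w in (0,1)."""
    if tau <= 1e-14:
        return -np.inf
    err = 1e-12
    # Term counts for the requested truncation error (small vs large time).
    if 2.0 * math.sqrt(2.0 * math.pi * tau) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tau * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tau)))
        if ks < math.sqrt(tau) + 1.0:
            ks = math.sqrt(tau) + 1.0
    else:
        ks = 2.0
    if math.pi * tau * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tau * err) / (math.pi * math.pi * tau))
        if kl < 1.0 / (math.pi * math.sqrt(tau)):
            kl = 1.0 / (math.pi * math.sqrt(tau))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tau))
    if ks < kl:
        K = int(math.ceil(ks))
        acc = 0.0
        for k in range(-K, K + 1):
            wk = w + 2.0 * k
            acc += wk * math.exp(-wk * wk / (2.0 * tau))
        f1 = acc / math.sqrt(2.0 * math.pi * tau * tau * tau)
    else:
        K = int(math.ceil(kl))
        acc = 0.0
        for k in range(1, K + 1):
            acc += k * math.exp(-k * k * math.pi * math.pi * tau / 2.0) * math.sin(k * math.pi * w)
        f1 = math.pi * acc
    if f1 <= 0.0:
        return -np.inf
    return math.log(f1)


@njit(cache=True)
def _logdens_lower(td, v, a, w):
    """log density of absorption at the lower bound at decision time td
    (unit noise, bounds 0 and a, start w*a, drift v)."""
    if td <= 0.0:
        return -np.inf
    tau = td / (a * a)
    lf1 = _f1_log(tau, w)
    if lf1 == -np.inf:
        return -np.inf
    return lf1 - 2.0 * math.log(a) - v * a * w - v * v * td / 2.0


@njit(cache=True)
def _plower(v, a, w):
    """Probability of absorption at the lower bound (t -> infinity)."""
    if abs(v) * a < 1e-10:
        return 1.0 - w
    if v > 0.0:
        pu = math.expm1(-2.0 * v * a * w) / math.expm1(-2.0 * v * a)
        return 1.0 - pu
    # reflection: P_low(v, w) = P_up(-v, 1-w)
    return math.expm1(2.0 * v * a * (1.0 - w)) / math.expm1(2.0 * v * a)


@njit(cache=True)
def _cdf_lower(td, v, a, w, glx, glw):
    """Defective CDF of lower-bound absorption at decision time td."""
    if td <= 0.0:
        return 0.0
    pl = _plower(v, a, w)
    tau = td / (a * a)
    if tau < _TAU_SWITCH:
        # direct integration of the (small-time) density
        half = td / 2.0
        acc = 0.0
        for i in range(glx.shape[0]):
            t = half * (glx[i] + 1.0)
            ld = _logdens_lower(t, v, a, w)
            if ld > -700.0:
                acc += glw[i] * math.exp(ld)
        F = half * acc
    else:
        # analytic tail of the large-time series, integrated term by term
        tail = 0.0
        pref = math.pi / (a * a)
        k = 1
        while k <= 1000:
            lam = 0.5 * (v * v + k * k * math.pi * math.pi / (a * a))
            e = -v * a * w - lam * td
            term = 0.0
            if e > -700.0:
                term = pref * k * math.sin(k * math.pi * w) * math.exp(e) / lam
            tail += term
            # remaining terms are bounded by the same envelope without sin
            env = 0.0
            if e > -700.0:
                env = pref * k * math.exp(e) / lam
            if k > 2 and env < 1e-15:
                break
            k += 1
        F = pl - tail
    if F < 0.0:
        F = 0.0
    if F > pl:
        F = pl
    return F


@njit(cache=True)
def _survivor(td, v, a, w, glx, glw):
    s = 1.0 - _cdf_lower(td, v, a, w, glx, glw) - _cdf_lower(td, -v, a, 1.0 - w, glx, glw)
    if s < 0.0:
        s = 0.0
    return s


@njit(cache=True)
def _cdf_grids(v, a, w, dl_dec, ngrid, glx, glw):
    ts = np.linspace(0.0, dl_dec, ngrid)
    Fu = np.empty(ngrid)
    Fl = np.empty(ngrid)
    for i in range(ngrid):
        Fl[i] = _cdf_lower(ts[i], v, a, w, glx, glw)
        Fu[i] = _cdf_lower(ts[i], -v, a, 1.0 - w, glx, glw)
    return ts, Fu, Fl


@njit(cache=True)
def _sample_from_grids(ts, Fu, Fl, u_cat, u_t):
    """Inverse-CDF sampling of (bound, decision time) from tabulated
    defective CDFs; bound +1 upper, -1 lower, 0 censored."""
    n = u_cat.shape[0]
    resp = np.zeros(n, dtype=np.int8)
    t = np.full(n, np.nan)
    FU = Fu[Fu.shape[0] - 1]
    FL = Fl[Fl.shape[0] - 1]
    for i in range(n):
        if u_cat[i] < FU:
            F = Fu
            target = u_t[i] * FU
            r = 1
        elif u_cat[i] < FU + FL:
            F = Fl
            target = u_t[i] * FL
            r = -1
        else:
            continue
        lo = 0
        hi = ts.shape[0] - 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if F[mid] < target:
                lo = mid
            else:
                hi = mid
        df = F[hi] - F[lo]
        frac = 0.5 if df <= 0.0 else (target - F[lo]) / df
        resp[i] = r
        t[i] = ts[lo] + frac * (ts[hi] - ts[lo])
    return resp, t


@njit(cache=True)
def _loglik_kernel(rt, resp, cens, diff_idx, sign, a, w, ter, v1, v2, s, deadline, glx, glw):
    """Sum of log WFPT densities (responded) and log survivors (censored).

    resp: +1 upper (right), -1 lower (left); sign: drift sign from the
    stimulus direction (+1 rightward). diff_idx: 0 easy (v1), 1 difficult
    (v2). Returns -inf on invalid parameters or any rt <= ter.
    """
    if not (a > 0.0) or not (0.0 < w < 1.0) or ter < 0.0 or not (s > 0.0):
        return -np.inf
    a_s = a / s
    v1_s = v1 / s
    v2_s = v2 / s
    dl_dec = deadline - ter
    # survivor cache over (diff_idx, sign) combinations
    sv = np.full(4, np.nan)
    total = 0.0
    for i in range(rt.shape[0]):
        base = v1_s if diff_idx[i] == 0 else v2_s
        v = base * sign[i]
        if cens[i]:
            key = diff_idx[i] * 2 + (0 if sign[i] > 0 else 1)
            if np.isnan(sv[key]):
                if dl_dec <= 0.0:
                    sv[key] = 1.0
                else:
                    sv[key] = _survivor(dl_dec, v, a_s, w, glx, glw)
            p = sv[key]
            if p <= 0.0:
                return -np.inf
            total += math.log(p)
        else:
            td = rt[i] - ter
            if td <= 0.0:
                return -np.inf
            if resp[i] > 0:
                lf = _logdens_lower(td, -v, a_s, 1.0 - w)
            else:
                lf = _logdens_lower(td, v, a_s, w)
            if lf == -np.inf:
                return -np.inf
            total += lf
    return total


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def _scaled(p: DDMParams, v: float) -> tuple[float, float, float]:
    return p.a / p.s, p.w, v / p.s


def wfpt_density(t, bound: str, p: DDMParams, v: float):
    """First-passage density (1/s) of responding at ``bound`` at time ``t``.

    ``t`` is the full response time (decision time + ``p.ter``); the density
    is zero for ``t <= p.ter``. ``bound`` is ``"upper"`` or ``"lower"``;
    ``v`` is the signed drift-rate for this trial.
    """
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
    a, w, vs = _scaled(p, v)
    if bound == "upper":
        vs, w = -vs, 1.0 - w
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        ld = _logdens_lower(ti - p.ter, vs, a, w)
        out[i] = math.exp(ld) if ld > -700.0 else 0.0
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def defective_cdf(t, bound: str, p: DDMParams, v: float):
    """Defective CDF of responding at ``bound`` by time ``t``.

    Non-decreasing in ``t``; its limit at infinity is the absorption
    probability of the bound, and the two bounds' limits sum to 1.
    """
    if bound not in ("upper", "lower"):
        raise ValueError(f"bound must be 'upper' or 'lower', got {bound!r}")
    a, w, vs = _scaled(p, v)
    if bound == "upper":
        vs, w = -vs, 1.0 - w
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty_like(t_arr)
    for i, ti in enumerate(t_arr):
        out[i] = _cdf_lower(ti - p.ter, vs, a, w, _GL_X, _GL_W)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def survivor(deadline: float, p: DDMParams, v: float) -> float:
    """Probability that no bound has been reached by ``deadline``."""
    a, w, vs = _scaled(p, v)
    td = deadline - p.ter
    if td <= 0:
        return 1.0
    return float(_survivor(td, vs, a, w, _GL_X, _GL_W))


def simulate_trials(n: int, p: DDMParams, v: float, deadline: float,
                    rng: np.random.Generator, ngrid: int = 1024):
    """Draw ``n`` trials by exact inverse-CDF sampling.

    Returns ``(resp, rt)`` where ``resp`` is +1 (upper), -1 (lower) or 0
    (no response by the deadline) and ``rt = ter + decision time`` (NaN for
    censored trials).
    """
    a, w, vs = _scaled(p, v)
    dl_dec = deadline - p.ter
    if dl_dec <= 0:
        return np.zeros(n, dtype=np.int8), np.full(n, np.nan)
    ts, Fu, Fl = _cdf_grids(vs, a, w, dl_dec, ngrid, _GL_X, _GL_W)
    resp, t = _sample_from_grids(ts, Fu, Fl, rng.random(n), rng.random(n))
    return resp, np.where(resp != 0, t + p.ter, np.nan)


def simulate_trial(p: DDMParams, v: float, deadline: float, rng: np.random.Generator):
    """Simulate a single trial; returns (bound or None, rt)."""
    resp, rt = simulate_trials(1, p, v, deadline, rng)
    if resp[0] == 0:
        return None, float("nan")
    return ("upper" if resp[0] > 0 else "lower"), float(rt[0])


def trial_arrays(trials, coding: str = "stimulus"):
    """Compile a filtered trial table into flat arrays for the likelihood.

    Excluded rows and catch trials are dropped (the model has exactly two
    difficulty drifts). Under stimulus coding the upper bound is the
    rightward response and the drift sign follows the true stimulus
    direction; under accuracy coding the upper bound is the correct
    response and the drift is always positive.
    """
    if coding not in ("stimulus", "accuracy"):
        raise ValueError(f"unknown response coding {coding!r}")
    keep = trials[(~trials["excluded"]) & (trials["difficulty"].isin(["easy", "difficult"]))]
    rt = keep["rt"].to_numpy(dtype=float)
    cens = keep["censored"].to_numpy(dtype=np.bool_)
    rt = np.where(cens, 0.0, rt)
    diff_idx = (keep["difficulty"] == "difficult").to_numpy().astype(np.int8)
    if coding == "stimulus":
        sign = np.where(keep["direction"] == "right", 1, -1).astype(np.int8)
        resp = np.where(keep["response"] == "right", 1, -1).astype(np.int8)
    else:
        sign = np.ones(len(keep), dtype=np.int8)
        resp = np.where(keep["response"] == keep["direction"], 1, -1).astype(np.int8)
    return rt, resp, cens, diff_idx, sign


def loglik_participant(trials, p: DDMParams, deadline: float = 2.5,
                       coding: str = "stimulus") -> float:
    """Log-likelihood of one participant's filtered trial table.

    Responded trials contribute log WFPT densities at the response bound;
    censored (no-response) trials contribute the log survivor function at
    the deadline; excluded trials contribute nothing. Any responded
    ``rt <= ter`` yields ``-inf`` rather than raising, so a sampler can
    simply reject the proposal.
    """
    rt, resp, cens, diff_idx, sign = trial_arrays(trials, coding)
    if len(rt) == 0:
        return 0.0
    if np.any(rt[~cens] < 0):
        raise ValueError("negative RT in trial table")
    return float(_loglik_kernel(rt, resp, cens, diff_idx, sign,
                                p.a, p.w, p.ter, p.v1, p.v2, p.s,
                                deadline, _GL_X, _GL_W))


def loglik_arrays(rt, resp, cens, diff_idx, sign, a, w, ter, v1, v2, s,
                  deadline) -> float:
    """Array-level likelihood entry point used by the hierarchical model."""
    return float(_loglik_kernel(rt, resp, cens, diff_idx, sign,
                                a, w, ter, v1, v2, s, deadline, _GL_X, _GL_W))


@njit(cache=True)
def _loglik_many_kernel(rt, resp, cens, diff_idx, sign, params, s, deadline,
                        skip, glx, glw):
    n = params.shape[0]
    out = np.empty(n)
    for c in range(n):
        if skip[c]:
            out[c] = -np.inf
            continue
        out[c] = _loglik_kernel(rt, resp, cens, diff_idx, sign,
                                params[c, 0], params[c, 1], params[c, 2],
                                params[c, 3], params[c, 4], s, deadline,
                                glx, glw)
    return out


@njit(cache=True)
def _loglik_flat_kernel(rt, resp, cens, diff_idx, sign, ptr, params, s,
                        deadline, skip, glx, glw):
    """Likelihood for every (chain, participant) pair; trials are stored
    flat with ``ptr`` giving each participant's slice."""
    nG = params.shape[0]
    P = params.shape[1]
    out = np.empty((nG, P))
    for p in range(P):
        lo = ptr[p]
        hi = ptr[p + 1]
        for c in range(nG):
            if skip[c, p]:
                out[c, p] = -np.inf
            else:
                out[c, p] = _loglik_kernel(
                    rt[lo:hi], resp[lo:hi], cens[lo:hi], diff_idx[lo:hi],
                    sign[lo:hi], params[c, p, 0], params[c, p, 1],
                    params[c, p, 2], params[c, p, 3], params[c, p, 4],
                    s, deadline, glx, glw)
    return out


def loglik_flat(rt, resp, cens, diff_idx, sign, ptr, params, s, deadline,
                skip) -> np.ndarray:
    """Batched likelihood over chains x participants (see flat kernel)."""
    params = np.ascontiguousarray(params, dtype=float)
    return _loglik_flat_kernel(rt, resp, cens, diff_idx, sign, ptr, params,
                               s, deadline, skip, _GL_X, _GL_W)


def loglik_arrays_many(rt, resp, cens, diff_idx, sign, params, s, deadline,
                       skip=None) -> np.ndarray:
    """Likelihood of one trial set under many parameter vectors at once.

    ``params`` has rows (a, w, ter, v1, v2); rows flagged in ``skip``
    return -inf without evaluation (used for already-rejected proposals).
    """
    params = np.ascontiguousarray(params, dtype=float)
    if skip is None:
        skip = np.zeros(params.shape[0], dtype=np.bool_)
    return _loglik_many_kernel(rt, resp, cens, diff_idx, sign, params,
                               s, deadline, skip, _GL_X, _GL_W)
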