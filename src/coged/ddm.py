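"""Wiener diffusion model of effort-based binary choice.

The two-boundary drift-diffusion model treats each choice between the
effortful and the effortless option as noisy evidence accumulation from
a starting point ``z * a`` toward an upper boundary ``a`` (choose the
effortful option) or a lower boundary 0 (choose the effortless option),
with drift rate ``v`` (positive favors effort), diffusion coefficient
fixed at 1, and non-decision time ``t0`` added to the passage time.

This module provides the forward simulator, the first-passage-time
density (small-time / large-time series with adaptive truncation), and
a hierarchical Bayesian fit in which drift varies by group x effort
level while boundary separation and non-decision time are per-subject,
sampled by Metropolis-within-Gibbs with conjugate group-level updates.
Convergence is monitored with the split-chain Gelman-Rubin statistic and
models are compared by DIC (a drop greater than 5 counts as a
substantial improvement).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

UPPER = "effortful"
LOWER = "effortless"

__all__ = [
    "DDMParams",
    "simulate_wiener",
    "wfpt_logdensity",
    "choice_probability_closed_form",
    "mean_decision_time_closed_form",
    "compute_rhat",
    "compute_dic",
    "compare_dic",
    "HierarchicalDDM",
    "FitDiagnostics",
]


@dataclass(frozen=True)
class DDMParams:
    """Wiener parameters: drift v, boundary a > 0, relative start z in
    (0,1), non-decision time t0 >= 0 (seconds).  Diffusion coefficient 1."""

    v: float
    a: float
    z: float = 0.5
    t0: float = 0.0

    def __post_init__(self):
        if self.a <= 0:
            raise ValueError("boundary separation a must be positive")
        if not 0 < self.z < 1:
            raise ValueError("relative starting point z must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be nonnegative")


def choice_probability_closed_form(params: DDMParams) -> float:
    """P(absorb at the upper/effortful boundary) for drifted Brownian
    motion: (1 - exp(-2 v z a)) / (1 - exp(-2 v a)); z a / a for v = 0.
    Reduces to 1/(1 + exp(-v a)) at z = 1/2."""
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-12:
        return z
    return float(np.expm1(-2 * v * z * a) / np.expm1(-2 * v * a))

def mean_decision_time_closed_form(params: DDMParams) -> float:
    """Mean first-passage time (either boundary, t0 excluded); for
    z = 1/2 this is (a / 2v) tanh(v a / 2), and a**2 z (1-z) ... /1 ->
    the unbiased-start limit a**2/4 as v -> 0."""
    v, a, z = params.v, params.a, params.z
    if abs(v) < 1e-9:
        return a * a * z * (1 - z)
    za = z * a
    return float(
        (a / v) * (1 - np.exp(-2 * v * za)) / (1 - np.exp(-2 * v * a)) - za / v
    )


def _simulate_fpt(v, a, z, rng, dt):
    """Bridge-corrected Euler first passage for per-trial parameter arrays.

    Within each Euler step the probability that the unobserved Brownian
    bridge crossed a boundary is exp(-2 d0 d1 / dt) for endpoint
    distances d0, d1, which removes the O(sqrt(dt)) crossing bias of the
    plain scheme.  Returns (upper: bool array, decision_time: array).
    """
    v = np.asarray(v, float)
    n = v.shape[0]
    a = np.broadcast_to(np.asarray(a, float), (n,)).copy()
    x = np.broadcast_to(np.asarray(z, float), (n,)) * a
    upper = np.zeros(n, bool)
    t_dec = np.zeros(n)
    active = np.arange(n)
    sdt = np.sqrt(dt)
    t = 0.0
    max_t = 300.0
    while active.size:
        t += dt
        xa = x[active]
        aa = a[active]
        xn = xa + v[active] * dt + sdt * rng.standard_normal(active.size)
        hit_up = xn >= aa
        hit_dn = xn <= 0.0
        inside = ~(hit_up | hit_dn)
        if np.any(inside):
            # Brownian-bridge crossing probabilities within the step
            idx = np.where(inside)[0]
            x0, x1, ab = xa[idx], xn[idx], aa[idx]
            p_up = np.exp(-2.0 * (ab - x0) * (ab - x1) / dt)
            p_dn = np.exp(-2.0 * x0 * x1 / dt)
            u = rng.random(idx.size)
            bridge_up = u < p_up
            bridge_dn = (~bridge_up) & (u < p_up + p_dn)
            hit_up[idx[bridge_up]] = True
            hit_dn[idx[bridge_dn]] = True
        done = hit_up | hit_dn
        if np.any(done) or t > max_t:
            gidx = active[done]
            upper[gidx] = hit_up[done]
            t_dec[gidx] = t
            keep = ~done
            x[active[keep]] = xn[keep]
            active = active[keep]
            if t > max_t:  # pragma: no cover - pathological parameters
                upper[active] = x[active] > a[active] / 2
                t_dec[active] = t
                break
        else:
            x[active] = xn
    return upper, t_dec


def simulate_wiener(
    params: DDMParams, n_trials: int, rng: np.random.Generator, dt: float = 1e-3
) -> pd.DataFrame:
    """Simulate first-passage records (boundary, rt in seconds).

    rt = passage time + t0; the upper boundary codes the effortful
    choice.  A too-coarse step relative to the boundary separation
    (a / sqrt(dt) < 10) triggers a warning and automatic refinement.
    """
    if n_trials < 1:
        raise ValueError("need at least one trial")
    if dt <= 0:
        raise ValueError("dt must be positive")
    while params.a / np.sqrt(dt) < 10.0:
        warnings.warn(
            f"dt={dt} too coarse for boundary separation a={params.a}; refining",
            stacklevel=2,
        )
        dt /= 10.0
    upper, t_dec = _simulate_fpt(
        np.full(n_trials, params.v), params.a, params.z, rng, dt
    )
    return pd.DataFrame(
        {
            "boundary": np.where(upper, UPPER, LOWER),
            "rt": t_dec + params.t0,
        }
    )


# ---------------------------------------------------------------------------
# first-passage-time density (small/large-time series)
# ---------------------------------------------------------------------------

def _fpt_lower_density_scaled(w, v, a, z, tol):
    """Density of passage through the LOWER boundary at scaled time
    w = t / a**2, for arrays broadcast to a common shape.

    Uses the small-time and large-time series with truncation chosen
    per element to meet ``tol``, switching to whichever needs fewer
    terms (the standard crossover criterion).
    """
    w = np.asarray(w, float)
    v, a, z = (np.broadcast_to(np.asarray(q, float), w.shape) for q in (v, a, z))
    out = np.zeros_like(w)
    ok = w > 0
    if not np.any(ok):
        return out
    ww, vv, aa, zz = w[ok], v[ok], a[ok], z[ok]

    # required number of terms for each series (Navarro & Fuss, 2009)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = 2.0 * np.sqrt(2.0 * np.pi * ww) * tol
        ks = np.where(
            arg < 1,
            2.0 + np.sqrt(np.maximum(-2.0 * ww * np.log(arg), 0.0)),
            np.sqrt(ww) + 1.0,
        )
        ks = np.maximum(ks, np.sqrt(ww) + 1.0)
        argl = np.pi * ww * tol
        kl = np.where(
            argl < 1,
            np.sqrt(np.maximum(-2.0 * np.log(argl), 0.0) / (np.pi**2 * ww)),
            1.0 / (np.pi * np.sqrt(ww)),
        )
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(ww)))

    use_small = ks < kl
    dens = np.zeros_like(ww)

    if np.any(use_small):
        i = use_small
        K = int(np.ceil(ks[i].max()))
        k = np.arange(-K, K + 1)[:, None]
        zk = zz[i][None, :] + 2.0 * k
        terms = zk * np.exp(-(zk**2) / (2.0 * ww[i][None, :]))
        dens[i] = terms.sum(axis=0) / np.sqrt(2.0 * np.pi * ww[i] ** 3)
    if np.any(~use_small):
        i = ~use_small
        K = int(np.ceil(kl[i].max()))
        k = np.arange(1, K + 1)[:, None]
        terms = (
            k
            * np.exp(-(k**2) * np.pi**2 * ww[i][None, :] / 2.0)
            * np.sin(k * np.pi * zz[i][None, :])
        )
        dens[i] = np.pi * terms.sum(axis=0)

    # reattach drift and boundary scaling: f(t) = f_w(w) / a^2 * exp(-v a z - v^2 t / 2)
    dens = np.maximum(dens, 0.0)
    full = dens / aa**2 * np.exp(-vv * aa * zz - vv**2 * ww * aa**2 / 2.0)
    out[ok] = full
    return out


def wfpt_logdensity(rt, boundary, params: DDMParams, tol: float = 1e-7):
    """Log density of observing (rt, boundary) under ``params``.

    The lower-boundary (effortless) density is the base series; the
    upper-boundary density follows by the reflection (v, z) ->
    (-v, 1 - z).  rt <= t0 contributes -inf.
    """
    rt = np.atleast_1d(np.asarray(rt, float))
    scalar_bound = isinstance(boundary, str)
    bnd = np.broadcast_to(
        np.atleast_1d(np.asarray(boundary)), rt.shape
    )
    t = rt - params.t0
    upper = bnd == UPPER
    v = np.where(upper, -params.v, params.v)
    z = np.where(upper, 1.0 - params.z, params.z)
    w = np.where(t > 0, t, np.nan) / params.a**2
    dens = _fpt_lower_density_scaled(np.nan_to_num(w, nan=-1.0), v, params.a, z, tol)
    with np.errstate(divide="ignore"):
        ld = np.where(t > 0, np.log(np.maximum(dens, 1e-300)), -np.inf)
    if scalar_bound and ld.size == 1:
        return float(ld[0])
    return ld


def _loglik_trials(t, upper, v, a, z, t0, tol=1e-7):
    """Vectorized per-trial log likelihood with per-trial parameters."""
    tt = t - t0
    vv = np.where(upper, -v, v)
    zz = np.where(upper, 1.0 - z, z)
    valid = tt > 0
    w = np.where(valid, tt, 1.0) / a**2
    dens = _fpt_lower_density_scaled(w, vv, a, zz, tol)
    with np.errstate(divide="ignore"):
        ll = np.where(valid, np.log(np.maximum(dens, 1e-300)), -np.inf)
    return ll


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def compute_rhat(chains) -> float:
    """Split-chain Gelman-Rubin potential scale reduction factor.

    ``chains`` is an (n_chains, n_draws) array; each chain is split in
    half, and R-hat is sqrt(((n-1)/n W + B/n) / W) over the split
    halves.  Degenerate (zero within-chain variance) input raises.
    """
    x = np.asarray(chains, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 10:
        raise ValueError("need >= 2 chains with >= 10 draws each")
    n = x.shape[1] // 2
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    m = halves.shape[0]
    W = halves.var(axis=1, ddof=1).mean()
    if W <= 0:
        raise ValueError("zero within-chain variance; R-hat undefined")
    B = n * halves.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    # sampling noise can push the ratio marginally below 1; clamp there
    return float(max(np.sqrt(var_plus / W), 1.0))


def compute_dic(deviance_draws, deviance_at_mean: float) -> tuple[float, float, float]:
    """DIC = mean deviance + pD with pD = mean deviance - D(posterior mean).

    Returns (dic, p_d, mean_deviance)."""
    d = np.asarray(deviance_draws, float).ravel()
    if not np.all(np.isfinite(d)) or not np.isfinite(deviance_at_mean):
        raise ValueError("non-finite deviance; cannot compute DIC")
    dbar = float(d.mean())
    p_d = dbar - float(deviance_at_mean)
    return dbar + p_d, p_d, dbar


def compare_dic(dic_a: float, dic_b: float, threshold: float = 5.0) -> dict:
    """Model comparison helper: ΔDIC = dic_b - dic_a; |Δ| > threshold is
    flagged as a substantial difference (lower DIC preferred)."""
    delta = dic_b - dic_a
    return {
        "delta_dic": float(delta),
        "substantial": bool(abs(delta) > threshold),
        "preferred": "a" if delta > 0 else "b",
    }


@dataclass
class FitDiagnostics:
    rhat: dict
    dic: float
    p_d: float
    mean_deviance: float
    converged: bool
    rhat_threshold: float = 1.1
    n_invalid_rt: int = 0


# ---------------------------------------------------------------------------
# hierarchical fit
# ---------------------------------------------------------------------------

@dataclass
class _Chain:
    """Raw state of one MCMC chain (internal)."""

    group_draws: dict = field(default_factory=dict)
    deviance: np.ndarray | None = None


class HierarchicalDDM(BaseEstimator):
    """Hierarchical Bayesian drift-diffusion model.

    Drift rate varies by condition cell (by default group x effort
    level); boundary separation and non-decision time are per-subject;
    the starting point is fixed at z = 0.5.  Subject-by-cell drifts are
    partially pooled toward the group-level cell means mu_v[g, e] with a
    common between-subject SD sigma_v.

    Priors: mu_v ~ Normal(0, 2); log a_s ~ Normal(mu_loga, sigma_loga)
    with mu_loga ~ Normal(log 1.5, 1); t0_s ~ Normal(mu_t0, sigma_t0)
    truncated to (0, min rt); variances get Inv-Gamma(2, 0.1) priors so
    the group-level updates are conjugate.

    Sampling is Metropolis-within-Gibbs: all subject-by-cell drifts are
    updated in one vectorized random-walk sweep (the blocks are
    conditionally independent), then per-subject a and t0, then the
    conjugate group-level draws.  Proposal scales adapt during burn-in
    only.

    Parameters
    ----------
    drift_by : tuple of column names defining drift condition cells.
    n_chains, n_iter, burn_in : MCMC settings (post-burn-in draws are
        kept); defaults follow the 4 x 5000 / 200 convention.
    rhat_threshold : fits with any group-level R-hat above this are
        flagged non-converged.
    seed : master seed; chains draw independent substreams.

    Attributes (after fit)
    ----------------------
    posterior_ : dict of group-level parameter draws, shape (chains, draws).
    group_drift_ : DataFrame of posterior mean / sd / 2.5% / 97.5% per cell.
    diagnostics_ : FitDiagnostics (R-hat per parameter, DIC, pD).
    converged_ : bool.
    """

    def __init__(
        self,
        drift_by=("group", "effort_level"),
        n_chains: int = 4,
        n_iter: int = 5000,
        burn_in: int = 200,
        rhat_threshold: float = 1.1,
        seed: int = 0,
        tol: float = 1e-7,
    ):
        self.drift_by = drift_by
        self.n_chains = n_chains
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.rhat_threshold = rhat_threshold
        self.seed = seed
        self.tol = tol

    # -- internal -----------------------------------------------------------

    def _prepare(self, df: pd.DataFrame):
        req = {"subject_id", "choice", "rt_s"} | set(self.drift_by)
        missing = req - set(df.columns)
        if missing:
            raise ValueError(f"choice table lacks columns {sorted(missing)}")
        d = df.copy()
        subjects = np.unique(d["subject_id"])
        if "group" in d.columns and d.groupby("group")["subject_id"].nunique().min() < 2:
            raise ValueError("need at least two subjects per group")
        subj_idx = pd.Categorical(d["subject_id"], categories=subjects).codes
        cell_key = list(zip(*(d[c] for c in self.drift_by)))
        cells = sorted(set(cell_key))
        cell_lookup = {c: i for i, c in enumerate(cells)}
        cell_idx = np.array([cell_lookup[c] for c in cell_key])
        # subject x cell blocks
        block_key = subj_idx.astype(np.int64) * len(cells) + cell_idx
        blocks, block_idx = np.unique(block_key, return_inverse=True)
        block_subj = (blocks // len(cells)).astype(int)
        block_cell = (blocks % len(cells)).astype(int)
        return {
            "t": d["rt_s"].to_numpy(float),
            "upper": d["choice"].to_numpy(int).astype(bool),
            "subj": subj_idx,
            "subjects": subjects,
            "cells": cells,
            "n_blocks": blocks.size,
            "block_idx": block_idx,
            "block_subj": block_subj,
            "block_cell": block_cell,
            "min_rt": np.array(
                [d["rt_s"][subj_idx == s].min() for s in range(subjects.size)]
            ),
        }

    def _run_chain(self, data, rng, n_iter, burn_in):
        nb, ns, nc = data["n_blocks"], data["subjects"].size, len(data["cells"])
        t, upper = data["t"], data["upper"]
        bidx, sidx = data["block_idx"], data["subj"]
        bs, bc = data["block_subj"], data["block_cell"]

        # initial values: drift from each block's choice fraction
        p_eff = np.bincount(bidx, upper) / np.bincount(bidx)
        v = 1.5 * (2.0 * np.clip(p_eff, 0.05, 0.95) - 1.0) + 0.1 * rng.standard_normal(nb)
        a = np.full(ns, 1.5) * np.exp(0.05 * rng.standard_normal(ns))
        t0 = np.minimum(0.5 * data["min_rt"], 0.4)
        mu_v = np.zeros(nc)
        sig_v = 0.3
        mu_la, sig_la = np.log(1.5), 0.2
        mu_t0, sig_t0 = 0.4, 0.1

        def trial_ll(v_b, a_s, t0_s):
            return _loglik_trials(
                t, upper, v_b[bidx], a_s[sidx], 0.5, t0_s[sidx], self.tol
            )

        ll = trial_ll(v, a, t0)
        ll_block = np.bincount(bidx, ll, minlength=nb)
        ll_subj = np.bincount(sidx, ll, minlength=ns)

        s_v, s_a, s_t0 = 0.25, 0.08, 0.03  # proposal scales
        acc = np.zeros(3)
        keep = n_iter - burn_in
        draws = {
            "mu_v": np.empty((keep, nc)),
            "sigma_v": np.empty(keep),
            "mu_log_a": np.empty(keep),
            "mu_t0": np.empty(keep),
        }
        dev = np.empty(keep)
        # running means for D(theta_bar)
        mean_v = np.zeros(nb)
        mean_a = np.zeros(ns)
        mean_t0 = np.zeros(ns)

        for it in range(n_iter):
            # 1) subject-by-cell drifts (vectorized independent blocks)
            v_prop = v + s_v * rng.standard_normal(nb)
            ll_prop = trial_ll(v_prop, a, t0)
            lp_block = np.bincount(bidx, ll_prop, minlength=nb)
            prior_cur = -0.5 * ((v - mu_v[bc]) / sig_v) ** 2
            prior_prop = -0.5 * ((v_prop - mu_v[bc]) / sig_v) ** 2
            accept = np.log(rng.random(nb)) < (
                lp_block - ll_block + prior_prop - prior_cur
            )
            v = np.where(accept, v_prop, v)
            ll = np.where(accept[bidx], ll_prop, ll)
            ll_block = np.where(accept, lp_block, ll_block)
            ll_subj = np.bincount(sidx, ll, minlength=ns)
            acc[0] += accept.mean()

            # 2) per-subject boundary separation (random walk on log a)
            la_prop = np.log(a) + s_a * rng.standard_normal(ns)
            a_prop = np.exp(la_prop)
            ll_prop = trial_ll(v, a_prop, t0)
            lp_subj = np.bincount(sidx, ll_prop, minlength=ns)
            pr_cur = -0.5 * ((np.log(a) - mu_la) / sig_la) ** 2
            pr_prop = -0.5 * ((la_prop - mu_la) / sig_la) ** 2
            accept = np.log(rng.random(ns)) < (lp_subj - ll_subj + pr_prop - pr_cur)
            a = np.where(accept, a_prop, a)
            ll = np.where(accept[sidx], ll_prop, ll)
            ll_subj = np.where(accept, lp_subj, ll_subj)
            ll_block = np.bincount(bidx, ll, minlength=nb)
            acc[1] += accept.mean()

            # 3) per-subject non-decision time (truncated to (0.01, min rt))
            t0_prop = t0 + s_t0 * rng.standard_normal(ns)
            valid = (t0_prop > 0.01) & (t0_prop < data["min_rt"] - 1e-6)
            t0_try = np.where(valid, t0_prop, t0)
            ll_prop = trial_ll(v, a, t0_try)
            lp_subj = np.bincount(sidx, ll_prop, minlength=ns)
            pr_cur = -0.5 * ((t0 - mu_t0) / sig_t0) ** 2
            pr_prop = -0.5 * ((t0_try - mu_t0) / sig_t0) ** 2
            accept = valid & (
                np.log(rng.random(ns)) < (lp_subj - ll_subj + pr_prop - pr_cur)
            )
            t0 = np.where(accept, t0_try, t0)
            ll = np.where(accept[sidx], ll_prop, ll)
            ll_subj = np.where(accept, lp_subj, ll_subj)
            ll_block = np.bincount(bidx, ll, minlength=nb)
            acc[2] += accept.mean()

            # 4) conjugate group-level updates
            for c in range(nc):
                vc = v[bc == c]
                prec = vc.size / sig_v**2 + 1.0 / 4.0  # prior N(0, 2)
                mean = (vc.sum() / sig_v**2) / prec
                mu_v[c] = mean + rng.standard_normal() / np.sqrt(prec)
            resid = v - mu_v[bc]
            sig_v = np.sqrt(
                1.0 / rng.gamma(2.0 + nb / 2.0, 1.0 / (0.1 + 0.5 * resid @ resid))
            )
            la = np.log(a)
            prec = ns / sig_la**2 + 1.0
            mu_la = (la.sum() / sig_la**2 + np.log(1.5)) / prec + rng.standard_normal() / np.sqrt(prec)
            r = la - mu_la
            sig_la = np.sqrt(1.0 / rng.gamma(2.0 + ns / 2.0, 1.0 / (0.1 + 0.5 * r @ r)))
            prec = ns / sig_t0**2 + 1.0
            mu_t0 = (t0.sum() / sig_t0**2 + 0.4) / prec + rng.standard_normal() / np.sqrt(prec)
            r = t0 - mu_t0
            sig_t0 = np.sqrt(1.0 / rng.gamma(2.0 + ns / 2.0, 1.0 / (0.1 + 0.5 * r @ r)))

            if it < burn_in:
                # Robbins-Monro adaptation toward ~35% acceptance
                if (it + 1) % 25 == 0:
                    rates = acc / 25.0
                    s_v *= np.exp(rates[0] - 0.35)
                    s_a *= np.exp(rates[1] - 0.35)
                    s_t0 *= np.exp(rates[2] - 0.35)
                    acc[:] = 0.0
            else:
                k = it - burn_in
                draws["mu_v"][k] = mu_v
                draws["sigma_v"][k] = sig_v
                draws["mu_log_a"][k] = mu_la
                draws["mu_t0"][k] = mu_t0
                dev[k] = -2.0 * ll.sum()
                mean_v += v
                mean_a += a
                mean_t0 += t0

        mean_v /= keep
        mean_a /= keep
        mean_t0 /= keep
        ll_at_mean = trial_ll(mean_v, mean_a, mean_t0).sum()
        return draws, dev, -2.0 * ll_at_mean

    # -- public -------------------------------------------------------------

    def fit(self, choices: pd.DataFrame):
        """Fit the hierarchical model to a long-format choice table with
        columns subject_id, the ``drift_by`` columns, choice (1 =
        effortful) and rt_s."""
        data = self._prepare(choices)
        n_invalid = int(np.sum(data["t"] <= 0))
        ss = np.random.SeedSequence(self.seed)
        chains = [np.random.default_rng(s) for s in ss.spawn(self.n_chains)]
        all_draws, all_dev, dev_at_mean = [], [], []
        for rng in chains:
            draws, dev, dmean = self._run_chain(data, rng, self.n_iter, self.burn_in)
            all_draws.append(draws)
            all_dev.append(dev)
            dev_at_mean.append(dmean)

        nc = len(data["cells"])
        post = {}
        for c, cell in enumerate(data["cells"]):
            name = "mu_v[" + ",".join(str(x) for x in cell) + "]"
            post[name] = np.stack([d["mu_v"][:, c] for d in all_draws])
        for p in ("sigma_v", "mu_log_a", "mu_t0"):
            post[p] = np.stack([d[p] for d in all_draws])
        self.posterior_ = post
        self.deviance_ = np.stack(all_dev)
        self.cells_ = data["cells"]

        rhat = {p: compute_rhat(post[p]) for p in post}
        dic, p_d, dbar = compute_dic(self.deviance_, float(np.mean(dev_at_mean)))
        converged = max(rhat.values()) <= self.rhat_threshold
        self.diagnostics_ = FitDiagnostics(
            rhat=rhat,
            dic=dic,
            p_d=p_d,
            mean_deviance=dbar,
            converged=converged,
            rhat_threshold=self.rhat_threshold,
            n_invalid_rt=n_invalid,
        )
        self.converged_ = converged

        rows = []
        for c, cell in enumerate(data["cells"]):
            x = np.concatenate([d["mu_v"][:, c] for d in all_draws])
            row = dict(zip(self.drift_by, cell))
            row.update(
                mean=x.mean(),
                sd=x.std(ddof=1),
                ci_lo=np.quantile(x, 0.025),
                ci_hi=np.quantile(x, 0.975),
            )
            rows.append(row)
        self.group_drift_ = pd.DataFrame(rows)
        return self

    def posterior_frame(self) -> pd.DataFrame:
        """posterior.csv schema: chain, iteration, parameter, value."""
        rows = []
        for p, arr in self.posterior_.items():
            for ch in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": ch,
                            "iteration": np.arange(arr.shape[1]),
                            "parameter": p,
                            "value": arr[ch],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def generate_choice_rt_table(agents, spec, rng, n_trials_per_cell=30, dt=1e-3):
    """Simulate a choices.csv table from agents' diffusion parameters.

    One block of Wiener trials per subject x effort level (the delay
    factor does not enter the default diffusion model); choice = 1 codes
    the effortful boundary.
    """
    frames = []
    for agent in agents:
        n_e = len(agent.effort_levels)
        v = np.repeat(agent.drift_by_effort, n_trials_per_cell)
        upper, t_dec = _simulate_fpt(v, agent.ddm_a, agent.ddm_z, rng, dt)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": agent.subject_id,
                    "group": agent.group,
                    "effort_level": np.repeat(list(agent.effort_levels), n_trials_per_cell),
                    "trial": np.tile(np.arange(n_trials_per_cell), n_e),
                    "choice": upper.astype(int),
                    "rt_s": t_dec + agent.ddm_t0,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
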