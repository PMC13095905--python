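"""Statistical analysis chain for subjective-value tables.

Mirrors the behavioral analysis strategy: signal-detection d' from the
n-back battery, a linear mixed-effects model of SV with treatment
contrasts (reference levels: highest effort, "right now", nondepressed),
a random-effects simplification ladder, planned Tukey-adjusted pairwise
delay comparisons within each effort level, and Spearman trait
correlations.

Fixed-effect p-values use the large-sample normal approximation (the
numerical stack provides no Satterthwaite degrees of freedom); at the
sample sizes of these designs the two are practically indistinguishable,
and all calibration properties (type-I error, power) are defined on the
realized rejection rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats
from sklearn.base import BaseEstimator
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .cohort import AgentProfile, CohortSpec, true_sv_matrix
from .titration import halving_titration_batch, run_design_grid

__all__ = [
    "compute_dprime",
    "SVMixedModel",
    "fit_sv_lmm",
    "planned_pairwise",
    "trait_correlations",
    "simulate_sv_table",
    "attach_covariates",
]


def compute_dprime(hits, misses, false_alarms, correct_rejections):
    """Signal-detection sensitivity d' = Φ⁻¹(hit rate) − Φ⁻¹(FA rate).

    Extreme rates are clamped to [1/(2N), 1 − 1/(2N)] within each
    response class (N = trials of that class), so perfect performance
    yields a finite d'.  Accepts scalars or arrays.
    """
    h, m, f, c = (np.asarray(x, float) for x in (hits, misses, false_alarms, correct_rejections))
    if np.any(h < 0) or np.any(m < 0) or np.any(f < 0) or np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    n_sig = h + m
    n_noise = f + c
    if np.any(n_sig == 0) or np.any(n_noise == 0):
        raise ValueError("each response class needs at least one trial")
    hr = np.clip(h / n_sig, 1.0 / (2 * n_sig), 1.0 - 1.0 / (2 * n_sig))
    fr = np.clip(f / n_noise, 1.0 / (2 * n_noise), 1.0 - 1.0 / (2 * n_noise))
    out = stats.norm.ppf(hr) - stats.norm.ppf(fr)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# SV table simulation (generator -> titration -> long table)
# ---------------------------------------------------------------------------

def simulate_sv_table(agents: list[AgentProfile], spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Run the titration design grid for every agent, long format.

    The halving variant is vectorized across all subjects and cells;
    cell order is irrelevant to the logistic agents, whose choices are
    exchangeable across cells.  The reversal variant runs the integer
    staircase per cell.
    """
    ss = np.random.SeedSequence(seed)
    n_e, n_d = len(spec.effort_levels), len(spec.delay_points)
    if spec.titration == "halving":
        rng = np.random.default_rng(ss)
        truth = np.stack([true_sv_matrix(a) for a in agents])  # (n, e, d)
        ip, _, _ = halving_titration_batch(truth, spec.tau, spec.reward, rng)
        rows = {
            "subject_id": np.repeat([a.subject_id for a in agents], n_e * n_d),
            "group": np.repeat([a.group for a in agents], n_e * n_d),
            "effort_level": np.tile(np.repeat(list(spec.effort_levels), n_d), len(agents)),
            "delay_code": np.tile(list(spec.delay_points), n_e * len(agents)),
            "indifference_point": ip.ravel(),
            "sv": ip.ravel() / spec.reward,
            "boundary_flag": "none",
        }
        return pd.DataFrame(rows)
    frames = []
    for agent, sub_ss in zip(agents, ss.spawn(len(agents))):
        rng = np.random.default_rng(sub_ss)
        res = run_design_grid(agent, spec, rng)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [r.subject_id for r in res],
                    "group": agent.group,
                    "effort_level": [r.effort_level for r in res],
                    "delay_code": [r.delay_code for r in res],
                    "indifference_point": [r.indifference_point for r in res],
                    "sv": [r.sv for r in res],
                    "boundary_flag": [r.boundary_flag for r in res],
                }
            )
        )
    return pd.concat(frames, ignore_index=True).sort_values(
        ["subject_id", "effort_level", "delay_code"], kind="stable"
    ).reset_index(drop=True)


def attach_covariates(sv_long: pd.DataFrame, battery: pd.DataFrame | None = None,
                      cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Join per-subject covariates onto the long SV table.

    ``battery`` contributes the subject's mean d' across effort levels;
    ``cohort`` contributes age, gender and GAD-7.
    """
    out = sv_long.copy()
    if battery is not None:
        d = battery.assign(
            d_prime=compute_dprime(
                battery["hits"], battery["misses"],
                battery["false_alarms"], battery["correct_rejections"],
            )
        )
        out = out.merge(
            d.groupby("subject_id", as_index=False)["d_prime"].mean(), on="subject_id"
        )
    if cohort is not None:
        cols = [c for c in ("age", "gender", "gad7") if c in cohort.columns]
        out = out.merge(cohort[["subject_id"] + cols], on="subject_id")
    return out


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMSpec:
    """Fixed/random structure of the SV mixed model."""

    reference_effort: str | None = None   # default: last effort level in the table
    reference_delay: int = 0
    reference_group: str = "nondepressed"
    random: str = "auto"                  # "auto" | "intercept+slopes" | "intercept"
    covariates: tuple = ("d_prime", "age", "gender", "gad7")


class SVMixedModel(BaseEstimator):
    """Linear mixed-effects model of subjective value.

    Fixed effects: effort level x delay (x group when two groups are
    present), all categorical with treatment contrasts against the
    highest effort level, the immediate timepoint, and the nondepressed
    group; optional subject-level covariates (d', standardized age,
    gender indicator, GAD-7).  Random effects: by-subject intercept,
    optionally uncorrelated by-subject effort slopes.

    The maximal structure (intercept + uncorrelated effort slopes) is
    simplified to intercept-only when it fails to converge or the slope
    variance collapses to zero; the structure actually fitted is
    recorded in ``random_structure_``.  REML estimation throughout.

    Attributes after fit: ``result_`` (statsmodels wrapper), ``fe_``
    (fixed-effect table: estimate, se, z, p), ``random_structure_``,
    ``converged_``.
    """

    def __init__(
        self,
        reference_effort: str | None = None,
        reference_delay: int = 0,
        reference_group: str = "nondepressed",
        random: str = "auto",
        covariates: tuple = ("d_prime", "age", "gender", "gad7"),
    ):
        self.reference_effort = reference_effort
        self.reference_delay = reference_delay
        self.reference_group = reference_group
        self.random = random
        self.covariates = covariates

    def _formula(self, table: pd.DataFrame) -> str:
        ref_e = self.reference_effort or pd.unique(table["effort_level"])[-1]
        if ref_e not in set(table["effort_level"]):
            raise ValueError(f"reference effort level {ref_e!r} not in table")
        if self.reference_delay not in set(table["delay_code"]):
            raise ValueError(f"reference delay {self.reference_delay!r} not in table")
        terms = [
            f"C(effort_level, Treatment(reference={ref_e!r}))",
            f"C(delay_code, Treatment(reference={self.reference_delay}))",
        ]
        self.two_group_ = "group" in table.columns and table["group"].nunique() > 1
        if self.two_group_:
            if self.reference_group not in set(table["group"]):
                raise ValueError(f"reference group {self.reference_group!r} not in table")
            terms.append(f"C(group, Treatment(reference={self.reference_group!r}))")
        rhs = " * ".join(terms)
        used = [
            c
            for c in self.covariates
            if c in table.columns and table[c].nunique() > 1
        ]
        self.covariates_used_ = tuple(used)
        for c in used:
            rhs += f" + {'z_age' if c == 'age' else c}"
        return f"sv ~ {rhs}"

    def fit(self, table: pd.DataFrame):
        t = table.copy()
        if "age" in t.columns and "age" in self.covariates:
            sd = t["age"].std(ddof=0)
            t["z_age"] = (t["age"] - t["age"].mean()) / (sd if sd > 0 else 1.0)
        formula = self._formula(t)
        self.formula_ = formula
        attempts = (
            ["intercept+slopes", "intercept"]
            if self.random == "auto"
            else [self.random]
        )
        last_err = None
        for structure in attempts:
            kw = {}
            if structure == "intercept+slopes":
                kw["vc_formula"] = {"effort": "0 + C(effort_level)"}
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    warnings.simplefilter("ignore", RuntimeWarning)
                    warnings.simplefilter("ignore", UserWarning)
                    model = smf.mixedlm(formula, t, groups=t["subject_id"], **kw)
                    res = model.fit(reml=True, maxiter=200)
                bad = not np.all(np.isfinite(res.fe_params)) or not np.all(
                    np.isfinite(res.bse_fe)
                )
                if structure == "intercept+slopes" and not bad:
                    # drop slopes that explain (numerically) zero variance
                    if res.vcomp.size and np.all(res.vcomp < 1e-6 * res.scale):
                        bad = True
                if bad:
                    raise RuntimeError("degenerate fit")
            except Exception as err:  # try the next, simpler structure
                last_err = err
                continue
            self.result_ = res
            self.random_structure_ = structure
            self.converged_ = bool(getattr(res, "converged", True))
            break
        else:
            raise RuntimeError(
                f"mixed model did not converge under any random structure: {last_err}"
            )
        k = len(self.result_.fe_params)
        self.fe_ = pd.DataFrame(
            {
                "estimate": self.result_.fe_params,
                "se": self.result_.bse_fe,
                "z": self.result_.fe_params / self.result_.bse_fe,
            }
        )
        self.fe_["p"] = 2 * stats.norm.sf(np.abs(self.fe_["z"]))
        self.cov_fe_ = np.asarray(self.result_.cov_params())[:k, :k]
        self.table_ = t
        self.df_resid_ = len(t) - k
        return self

    # -- marginal means and planned contrasts -------------------------------

    def _cell_design(self, cells: pd.DataFrame) -> np.ndarray:
        """Design rows for cells with covariates at their sample means."""
        base = cells.copy()
        for c in self.covariates_used_:
            col = "z_age" if c == "age" else c
            base[col] = self.table_[col].mean()
        di = self.result_.model.data.design_info
        return np.asarray(patsy.dmatrix(di, base, return_type="matrix"))

    def delay_contrasts(self, adjust: str = "tukey") -> pd.DataFrame:
        """All C(6,2) = 15 delay-pair comparisons within each effort
        level (and group), on estimated marginal means, with Tukey
        adjustment over each 15-comparison family via the studentized
        range distribution (``adjust="none"`` skips the adjusted p for
        speed in calibration loops; compare |t| to
        :func:`tukey_critical` instead)."""
        efforts = list(pd.unique(self.table_["effort_level"]))
        delays = sorted(pd.unique(self.table_["delay_code"]))
        groups = (
            sorted(pd.unique(self.table_["group"])) if self.two_group_ else [None]
        )
        k = len(delays)
        fe = np.asarray(self.result_.fe_params)
        rows = []
        for g in groups:
            for e in efforts:
                cells = pd.DataFrame(
                    {"effort_level": e, "delay_code": delays}
                    | ({"group": g} if g is not None else {})
                )
                X = self._cell_design(cells)
                for i in range(k):
                    for j in range(i + 1, k):
                        c = X[j] - X[i]
                        est = float(c @ fe)
                        se = float(np.sqrt(c @ self.cov_fe_ @ c))
                        tval = est / se
                        p_raw = 2 * stats.t.sf(abs(tval), self.df_resid_)
                        if adjust == "tukey":
                            p_adj = float(
                                stats.studentized_range.sf(
                                    abs(tval) * np.sqrt(2.0), k, self.df_resid_
                                )
                            )
                        else:
                            p_adj = np.nan
                        rows.append(
                            {
                                "group": g,
                                "effort_level": e,
                                "delay_a": delays[i],
                                "delay_b": delays[j],
                                "estimate": est,
                                "se": se,
                                "df": self.df_resid_,
                                "t": tval,
                                "p_raw": p_raw,
                                "p_tukey": max(p_adj, p_raw) if adjust == "tukey" else np.nan,
                            }
                        )
        out = pd.DataFrame(rows)
        if not self.two_group_:
            out = out.drop(columns="group")
        return out

    def delay_t_matrix(self) -> pd.DataFrame:
        """Raw t statistics of all delay pairs (no adjustment); used with
        :func:`tukey_critical` for fast family-wise calibration checks."""
        cols = ["effort_level", "delay_a", "delay_b", "t"]
        if self.two_group_:
            cols = ["group"] + cols
        return self.delay_contrasts(adjust="none")[cols]

    def summary_dict(self) -> dict:
        """JSON-ready model summary (coefficients, variances, convergence)."""
        res = self.result_
        return {
            "formula": self.formula_,
            "random_structure": self.random_structure_,
            "converged": self.converged_,
            "n_obs": int(len(self.table_)),
            "n_subjects": int(self.table_["subject_id"].nunique()),
            "coefficients": {
                name: {
                    "estimate": float(self.fe_.loc[name, "estimate"]),
                    "se": float(self.fe_.loc[name, "se"]),
                    "z": float(self.fe_.loc[name, "z"]),
                    "p": float(self.fe_.loc[name, "p"]),
                }
                for name in self.fe_.index
            },
            "residual_var": float(res.scale),
            "random_effects_var": {
                str(kk): float(vv) for kk, vv in res.cov_re.iloc[0].items()
            }
            if res.cov_re.size
            else {},
        }


def tukey_critical(alpha: float, k: int, df: float) -> float:
    """Critical |t| for Tukey-adjusted significance at level ``alpha``
    over a k-level family: q_{alpha,k,df} / sqrt(2)."""
    return float(stats.studentized_range.ppf(1 - alpha, k, df) / np.sqrt(2.0))


def fit_sv_lmm(table: pd.DataFrame, spec: LMMSpec | None = None) -> SVMixedModel:
    """Functional wrapper over :class:`SVMixedModel`."""
    spec = spec or LMMSpec()
    return SVMixedModel(
        reference_effort=spec.reference_effort,
        reference_delay=spec.reference_delay,
        reference_group=spec.reference_group,
        random=spec.random,
        covariates=spec.covariates,
    ).fit(table)


def planned_pairwise(model: SVMixedModel, within: object = None) -> pd.DataFrame:
    """ContrastTable of Tukey-adjusted delay comparisons; optionally
    restricted to one effort level."""
    tab = model.delay_contrasts()
    if within is not None:
        if within not in set(tab["effort_level"]):
            raise ValueError(f"effort level {within!r} absent from the model")
        tab = tab[tab["effort_level"] == within].reset_index(drop=True)
    return tab


def trait_correlations(subject_means: pd.Series, traits: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of per-subject mean SV with each trait.

    Mid-rank ties, two-sided p.  Constant traits yield rho = NaN with a
    ``degenerate`` flag instead of an error.
    """
    aligned = traits.loc[subject_means.index]
    if len(subject_means) < 5:
        raise ValueError("need at least 5 paired observations")
    rows = []
    for col in traits.columns:
        x = aligned[col].to_numpy(float)
        if np.allclose(x, x[0]):
            rows.append({"trait": col, "rho": np.nan, "p": np.nan, "degenerate": True})
            continue
        rho, p = stats.spearmanr(subject_means.to_numpy(float), x)
        rows.append({"trait": col, "rho": float(rho), "p": float(p), "degenerate": False})
    return pd.DataFrame(rows)
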