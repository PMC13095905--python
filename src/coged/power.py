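"""Repeated-measures ANOVA power for within-subject designs.

Power for the test of a within-subject factor with ``m`` repeated
measurements follows the noncentral-F formulation used by G*Power's
"ANOVA: repeated measures, within factors" module:

    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    lambda = n * m * f**2 * eps / (1 - rho)

where ``f`` is Cohen's effect size, ``rho`` the mean correlation among
repeated measures and ``eps`` the nonsphericity correction.  Power is
P(F' > F_crit) with F' noncentral F(df1, df2, lambda) and F_crit the
central-F critical value at ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

__all__ = ["RMPowerSpec", "rm_anova_power", "rm_anova_min_n"]


@dataclass(frozen=True)
class RMPowerSpec:
    """Specification of a one-group repeated-measures power problem.

    Parameters
    ----------
    f : Cohen's effect size (>= 0).
    alpha : type-I error rate.
    target_power : desired power 1 - beta (used by :func:`rm_anova_min_n`).
    m : number of repeated measurements per subject (>= 2).
    rho : mean correlation among repeated measures, in (0, 1).
    eps : nonsphericity correction, in (0, 1].
    n_groups : number of between-subject groups (kept for interface
        completeness; the within-factor test here assumes one group).
    """

    f: float = 0.20
    alpha: float = 0.05
    target_power: float = 0.80
    m: int = 24
    rho: float = 0.5
    eps: float = 1.0
    n_groups: int = 1

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError("effect size f must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1); rho = 1 gives an infinite noncentrality")
        if not 0 < self.eps <= 1:
            raise ValueError("nonsphericity eps must lie in (0, 1]")
        if self.m < 2:
            raise ValueError("need at least m = 2 repeated measurements")


def rm_anova_power(spec: RMPowerSpec, n: int) -> float:
    """Power of the within-subject F test at sample size ``n``.

    With f = 0 the noncentrality vanishes and the function returns
    exactly ``alpha``.
    """
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    df1 = (spec.m - 1) * spec.eps
    df2 = (n - 1) * (spec.m - 1) * spec.eps
    lam = n * spec.m * spec.f**2 * spec.eps / (1.0 - spec.rho)
    f_crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0.0:
        return float(spec.alpha)
    return float(stats.ncf.sf(f_crit, df1, df2, lam))


def rm_anova_min_n(spec: RMPowerSpec, n_max: int = 10**6) -> tuple[int, float]:
    """Smallest integer n whose power reaches ``spec.target_power``.

    Returns ``(min_n, achieved_power)``.  Scans linearly from n = 2;
    power is monotone increasing in n (both df2 and lambda grow), so the
    first hit is the minimum.
    """
    if not spec.alpha < spec.target_power < 1:
        raise ValueError("target power must lie in (alpha, 1)")
    for n in range(2, n_max + 1):
        p = rm_anova_power(spec, n)
        if p >= spec.target_power:
            return n, p
    raise RuntimeError(f"no n <= {n_max} reaches power {spec.target_power}")
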