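"""Synthetic agent cohorts for temporal cognitive-effort discounting.

Agents carry a known subjective-value (SV) surface over effort level and
temporal delay, a logistic choice rule, questionnaire scores consistent
with their depression-screening group, and Wiener diffusion parameters
for response-time generation.  The generator's defaults embody the
structure the behavioral studies report:

* SV declines with effort level;
* a delay-related SV increase confined to the higher effort levels in
  nondepressed agents (top-level deltas 0.090 / 0.077 / 0.056 at one
  week / two weeks / one month) and absent in depressed agents;
* an overall SV deficit of 0.313 in depressed agents;
* n-back performance with d' falling and RT rising with load;
* PHQ-9 / CES-D scores straddling the screening cutoffs (depressed:
  CES-D >= 16 and PHQ-9 >= 15; nondepressed: CES-D < 16 and PHQ-9 <= 4).

These defaults are calibration anchors taken from printed group-level
statistics, not claims of replicating any particular dataset; every one
is overridable through :class:`CohortSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import stats

NONDEPRESSED = "nondepressed"
DEPRESSED = "depressed"
EXCLUDED = "excluded"

#: canonical delay grid, coded in days (categorical in all analyses)
DELAY_CODES = (0, 1, 3, 7, 14, 30)
DELAY_LABELS = {0: "right now", 1: "1 day", 3: "3 days", 7: "1 week", 14: "2 weeks", 30: "1 month"}

# printed top-effort delay coefficients (1 wk, 2 wk, 1 mo); the 1- and
# 3-day values interpolate the same rising-then-easing profile
_TOP_DELAY_DELTAS = (0.0, 0.040, 0.070, 0.090, 0.077, 0.056)

# group-level drift-rate means per effort level (evidence units/s;
# positive favors choosing the effortful option)
DRIFT_NONDEPRESSED = (0.471, 0.334, 0.180, -0.108, -0.291, -0.445)
DRIFT_DEPRESSED = (-0.187, -0.115, -0.190, -0.060, -0.297, -0.126)

# n-back battery anchors (per effort level)
DPRIME_TARGETS = (3.70, 2.63, 1.85, 1.38, 1.04, 0.86)
RT_TARGETS_MS = (587.92, 713.34, 801.13, 818.92, 817.91, 849.16)

TLX_DIMENSIONS = (
    "mental_demand",
    "physical_demand",
    "temporal_demand",
    "estimated_performance",
    "perceived_effort",
    "frustration",
    "fun",
)
# (level-1 mean, level-6 mean) anchors on the 0-21 response scale
_TLX_ANCHORS = {
    "mental_demand": (7.47, 17.71),
    "physical_demand": (3.87, 8.02),
    "temporal_demand": (6.02, 9.18),
    "estimated_performance": (17.40, 8.20),
    "perceived_effort": (8.96, 16.53),
    "frustration": (3.62, 10.96),
    "fun": (9.64, 6.04),
}

# questionnaire/trait distributions per group: (mean, sd, low, high)
_TRAIT_DISTS = {
    NONDEPRESSED: {
        "phq9": (1.3, 1.4, 0, 4),
        "cesd": (5.3, 3.9, 0, 15),
        "gad7": (1.8, 2.8, 0, 21),
        "age": (36.8, 10.4, 18, 75),
    },
    DEPRESSED: {
        "phq9": (18.9, 3.6, 15, 27),
        "cesd": (40.4, 7.5, 16, 60),
        "gad7": (15.3, 3.8, 0, 21),
        "age": (33.2, 10.3, 18, 75),
    },
}
_P_MALE = {NONDEPRESSED: 33 / 58, DEPRESSED: 29 / 50}


def screen_group(phq9: int, cesd: int) -> str:
    """Depression screening by questionnaire cutoffs.

    depressed iff CES-D >= 16 and PHQ-9 >= 15; nondepressed iff
    CES-D < 16 and PHQ-9 <= 4; anything else is excluded.
    """
    if not 0 <= phq9 <= 27:
        raise ValueError(f"PHQ-9 score {phq9} outside [0, 27]")
    if not 0 <= cesd <= 60:
        raise ValueError(f"CES-D score {cesd} outside [0, 60]")
    if cesd >= 16 and phq9 >= 15:
        return DEPRESSED
    if cesd < 16 and phq9 <= 4:
        return NONDEPRESSED
    return EXCLUDED


@dataclass(frozen=True)
class CohortSpec:
    """All generator constants for one experiment's cohort.

    ``base_sv`` is the noise-free SV of the nondepressed group at delay
    "right now" per effort level; ``delay_delta`` is the additive SV
    shift per effort level x delay point (nondepressed; depressed agents
    always get zeros); ``group_sv_offset`` shifts every depressed SV.
    """

    n_per_group: int = 50
    effort_levels: tuple = tuple(f"{k}-back" for k in range(1, 7))
    delay_points: tuple = DELAY_CODES
    reward: float = 2.0
    titration: str = "halving"
    groups: tuple = (NONDEPRESSED,)
    base_sv: tuple = tuple(np.round(np.linspace(0.92, 0.60, 6), 4))
    delay_delta: tuple = ()  # filled in __post_init__ if empty
    group_sv_offset: float = -0.313
    subject_sd: float = 0.1
    tau: float = 0.2
    # diffusion-parameter population
    drift_means: dict = field(default_factory=lambda: {
        NONDEPRESSED: DRIFT_NONDEPRESSED, DEPRESSED: DRIFT_DEPRESSED})
    drift_sd: float = 0.15
    a_mean: float = 1.5
    a_sd: float = 0.1  # sd of log a
    t0_mean: float = 0.4
    t0_sd: float = 0.05
    # n-back battery
    n_signal: int = 32
    n_noise: int = 96
    dprime_targets: tuple = DPRIME_TARGETS
    rt_targets_ms: tuple = RT_TARGETS_MS
    dprime_subject_sd: float = 0.8
    rt_subject_sd_ms: float = 150.0
    tlx_sd: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.reward <= 0:
            raise ValueError("base reward must be positive")
        if len(self.delay_points) != 6:
            raise ValueError("the design uses exactly 6 delay points")
        if self.tau <= 0:
            raise ValueError("choice temperature tau must be positive")
        if len(self.base_sv) != len(self.effort_levels):
            raise ValueError("base_sv must give one value per effort level")
        if not self.delay_delta:
            object.__setattr__(self, "delay_delta", default_delay_delta(len(self.effort_levels)))
        dd = np.asarray(self.delay_delta, float)
        if dd.shape != (len(self.effort_levels), 6):
            raise ValueError("delay_delta must be effort x delay (6 columns)")

    @property
    def n_cells(self) -> int:
        return len(self.effort_levels) * len(self.delay_points)


def default_delay_delta(n_effort: int) -> tuple:
    """Delay-shift matrix: zero at low effort, ramping to the printed
    top-effort profile; with 4 effort levels only the top level carries
    the delay effect."""
    top = np.array(_TOP_DELAY_DELTAS)
    if n_effort == 6:
        scale = np.array([0.0, 0.0, 0.4, 0.6, 0.8, 1.0])
    elif n_effort == 4:
        scale = np.array([0.0, 0.0, 0.0, 1.0])
    else:
        scale = np.concatenate([np.zeros(n_effort - 1), [1.0]])
    return tuple(map(tuple, np.outer(scale, top)))


def exp1_spec(n: int = 40, seed: int = 0, **kw) -> CohortSpec:
    """Word-typing design: 4 effort levels, reward 10, reversal staircase."""
    params = dict(
        n_per_group=n,
        effort_levels=("50-word", "100-word", "150-word", "200-word"),
        base_sv=tuple(np.round(np.linspace(0.90, 0.60, 4), 4)),
        reward=10.0,
        titration="reversal",
        groups=(NONDEPRESSED,),
        seed=seed,
    )
    params.update(kw)
    return CohortSpec(**params)


def exp2_spec(n: int = 45, seed: int = 0, **kw) -> CohortSpec:
    """n-back design: 6 effort levels, reward 2, halving titration."""
    params = dict(n_per_group=n, groups=(NONDEPRESSED,), seed=seed)
    params.update(kw)
    return CohortSpec(**params)


def exp3_spec(n_per_group: int = 50, seed: int = 0, **kw) -> CohortSpec:
    """Two-group n-back design with depression screening."""
    params = dict(
        n_per_group=n_per_group, groups=(NONDEPRESSED, DEPRESSED), seed=seed
    )
    params.update(kw)
    return CohortSpec(**params)


def null_spec(base: CohortSpec) -> CohortSpec:
    """Copy of ``base`` with every effect size zeroed: no effort
    gradient (base SV flat at the mid value), no delay shifts, no group
    deficit.  Under this spec all design cells are exchangeable, which
    is the reference condition for type-I calibration."""
    zeros = tuple(map(tuple, np.zeros((len(base.effort_levels), 6))))
    flat = float(np.mean(base.base_sv))
    return replace(
        base,
        delay_delta=zeros,
        group_sv_offset=0.0,
        base_sv=tuple([flat] * len(base.effort_levels)),
    )


@dataclass
class AgentProfile:
    """One synthetic participant's ground truth."""

    subject_id: str
    group: str
    effort_levels: tuple
    delay_points: tuple
    base_sv_by_effort: np.ndarray  # noise-free SV at "right now", per level
    delay_delta: np.ndarray        # effort x delay additive SV shifts
    tau: float                     # logistic choice temperature (currency)
    subject_intercept: float = 0.0
    phq9: int = 0
    cesd: int = 0
    gad7: int = 0
    age: float = 35.0
    gender: int = 0                # 1 = male indicator
    drift_by_effort: np.ndarray | None = None
    ddm_a: float = 1.5
    ddm_z: float = 0.5
    ddm_t0: float = 0.4

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("choice temperature tau must be positive")
        base = np.asarray(self.base_sv_by_effort, float)
        if np.any(np.diff(base) > 1e-12):
            raise ValueError("base_sv_by_effort must be nonincreasing in effort")

    def _indices(self, effort, delay) -> tuple[int, int]:
        try:
            e = self.effort_levels.index(effort)
        except ValueError:
            raise KeyError(f"unknown effort level {effort!r}") from None
        try:
            d = self.delay_points.index(delay)
        except ValueError:
            raise KeyError(f"unknown delay point {delay!r}") from None
        return e, d

    def ddm_params(self, effort):
        """Wiener parameters for choices at one effort level."""
        from .ddm import DDMParams

        e = self.effort_levels.index(effort)
        return DDMParams(
            v=float(self.drift_by_effort[e]), a=self.ddm_a, z=self.ddm_z, t0=self.ddm_t0
        )


def true_sv(profile: AgentProfile, effort, delay) -> float:
    """Noise-free subjective value for one design cell, clamped to [0, 1]."""
    e, d = profile._indices(effort, delay)
    raw = (
        float(profile.base_sv_by_effort[e])
        + float(profile.delay_delta[e, d])
        + profile.subject_intercept
    )
    return float(min(max(raw, 0.0), 1.0))


def true_sv_matrix(profile: AgentProfile) -> np.ndarray:
    """All effort x delay true SVs at once (same clamping as true_sv)."""
    raw = (
        np.asarray(profile.base_sv_by_effort, float)[:, None]
        + np.asarray(profile.delay_delta, float)
        + profile.subject_intercept
    )
    return np.clip(raw, 0.0, 1.0)


def sample_choice(
    profile: AgentProfile, offer: float, effort, delay, reward: float, rng
) -> str:
    """One logistic-noise choice between the effortless offer and the
    effortful reward: P(effortful) = logistic((SV * reward − offer) / tau)."""
    from .titration import EFFORTFUL, EFFORTLESS

    if offer < 0:
        raise ValueError("offer must be nonnegative")
    if reward <= 0:
        raise ValueError("base reward must be positive")
    p = choice_probability(profile, offer, effort, delay, reward)
    return EFFORTFUL if rng.random() < p else EFFORTLESS


def choice_probability(profile, offer, effort, delay, reward) -> float:
    value = true_sv(profile, effort, delay) * reward
    return float(1.0 / (1.0 + np.exp(-(value - offer) / profile.tau)))


def _trunc_norm(rng, mean, sd, low, high, size=None):
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_agents(spec: CohortSpec) -> list[AgentProfile]:
    """Seed-reproducible cohort; each agent passes its group's screening."""
    rng = np.random.default_rng(spec.seed)
    n_e = len(spec.effort_levels)
    agents: list[AgentProfile] = []
    counter = 0
    for group in spec.groups:
        traits = _TRAIT_DISTS[group]
        for _ in range(spec.n_per_group):
            counter += 1
            offset = spec.group_sv_offset if group == DEPRESSED else 0.0
            delay_delta = (
                np.zeros((n_e, 6))
                if group == DEPRESSED
                else np.asarray(spec.delay_delta, float)
            )
            drift_mu = np.asarray(spec.drift_means[group][:n_e], float)
            phq9 = int(round(_trunc_norm(rng, *traits["phq9"])))
            cesd = int(round(_trunc_norm(rng, *traits["cesd"])))
            agent = AgentProfile(
                subject_id=f"S{counter:04d}",
                group=group,
                effort_levels=tuple(spec.effort_levels),
                delay_points=tuple(spec.delay_points),
                base_sv_by_effort=np.asarray(spec.base_sv, float) + offset,
                delay_delta=delay_delta,
                tau=spec.tau,
                subject_intercept=float(rng.normal(0.0, spec.subject_sd)),
                phq9=phq9,
                cesd=cesd,
                gad7=int(round(_trunc_norm(rng, *traits["gad7"]))),
                age=float(_trunc_norm(rng, *traits["age"])),
                gender=int(rng.random() < _P_MALE[group]),
                drift_by_effort=drift_mu + rng.normal(0.0, spec.drift_sd, n_e),
                ddm_a=float(np.exp(rng.normal(np.log(spec.a_mean), spec.a_sd))),
                ddm_z=0.5,
                ddm_t0=float(_trunc_norm(rng, spec.t0_mean, spec.t0_sd, 0.1, 1.0)),
            )
            assert screen_group(agent.phq9, agent.cesd) == group
            agents.append(agent)
    return agents


@dataclass
class TaskBatteryRecord:
    """n-back performance and workload ratings for one subject x level."""

    subject_id: str
    effort_level: object
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    mean_rt_ms: float
    tlx_ratings: dict

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("trial counts must be nonnegative")


def generate_task_battery(
    profiles: Sequence[AgentProfile], spec: CohortSpec, rng: np.random.Generator
) -> list[TaskBatteryRecord]:
    """Simulate the n-back practice battery for every agent.

    Hit/false-alarm probabilities are set from per-level target d'
    (equal-bias criterion: hit rate Φ(d/2), false-alarm rate Φ(−d/2))
    with subject-level jitter, so expected estimated d' decreases and
    expected RT increases with load.  TLX ratings vary linearly in level
    between the level-1 and level-6 anchors on a 0–21 scale.
    """
    if spec.n_signal < 8 or spec.n_noise < 8:
        raise ValueError("need at least 8 trials per response class to estimate rates")
    n_e = len(spec.effort_levels)
    levels = np.arange(n_e)
    records = []
    for prof in profiles:
        d_subj = np.clip(
            np.asarray(spec.dprime_targets[:n_e], float)
            + rng.normal(0.0, spec.dprime_subject_sd, n_e),
            0.05,
            None,
        )
        hit_p = stats.norm.cdf(d_subj / 2.0)
        fa_p = stats.norm.cdf(-d_subj / 2.0)
        hits = rng.binomial(spec.n_signal, hit_p)
        fas = rng.binomial(spec.n_noise, fa_p)
        rts = rng.normal(np.asarray(spec.rt_targets_ms[:n_e], float), spec.rt_subject_sd_ms)
        rts = np.clip(rts, 200.0, None)
        for e in levels:
            tlx = {}
            for dim in TLX_DIMENSIONS:
                lo_anchor, hi_anchor = _TLX_ANCHORS[dim]
                mean = lo_anchor + (hi_anchor - lo_anchor) * e / max(n_e - 1, 1)
                tlx[dim] = float(np.clip(rng.normal(mean, spec.tlx_sd), 0.0, 21.0))
            records.append(
                TaskBatteryRecord(
                    subject_id=prof.subject_id,
                    effort_level=spec.effort_levels[e],
                    hits=int(hits[e]),
                    misses=int(spec.n_signal - hits[e]),
                    false_alarms=int(fas[e]),
                    correct_rejections=int(spec.n_noise - fas[e]),
                    mean_rt_ms=float(rts[e]),
                    tlx_ratings=tlx,
                )
            )
    return records


def cohort_frame(agents: Sequence[AgentProfile]):
    """cohort.csv schema: ids, group, traits and per-level base SV."""
    import pandas as pd

    rows = []
    for a in agents:
        row = {
            "subject_id": a.subject_id,
            "group": a.group,
            "phq9": a.phq9,
            "cesd": a.cesd,
            "gad7": a.gad7,
            "age": a.age,
            "gender": a.gender,
            "tau": a.tau,
        }
        for lvl, sv in zip(a.effort_levels, a.base_sv_by_effort):
            row[f"base_sv_{lvl}"] = sv
        rows.append(row)
    return pd.DataFrame(rows)


def battery_frame(records: Sequence[TaskBatteryRecord]):
    """battery.csv schema (one row per subject x effort level)."""
    import pandas as pd

    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "effort_level": r.effort_level,
            "hits": r.hits,
            "misses": r.misses,
            "false_alarms": r.false_alarms,
            "correct_rejections": r.correct_rejections,
            "mean_rt_ms": r.mean_rt_ms,
        }
        row.update({dim: r.tlx_ratings[dim] for dim in TLX_DIMENSIONS})
        rows.append(row)
    return pd.DataFrame(rows)
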