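"""Adaptive titration of indifference points for effort-discounting choices.

Two algorithms estimate the effortless-offer amount at which a decider is
indifferent between a smaller no-effort reward and a fixed larger reward
requiring cognitive effort:

``run_reversal_staircase``
    Integer-offer bisection that stops once two offers one currency unit
    apart elicit opposite preferences (the word-typing design, base
    reward 10).  The indifference point is the smaller offer at which
    the effortless option is preferred.

``run_halving_titration``
    Six-trial procedure starting at half the base reward; after each
    choice the offer moves toward the preferred option and the
    adjustment magnitude halves (the n-back design, base reward 2).  The
    offer presented on the final trial is the indifference point.

Subjective value (SV) is the indifference point divided by the base
reward, a fraction in [0, 1]; lower SV means steeper effort discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

EFFORTFUL = "effortful"
EFFORTLESS = "effortless"

FLAG_NONE = "none"
FLAG_FLOOR = "floor"
FLAG_CEILING = "ceiling"

ChoiceOracle = Callable[[float], str]


@dataclass
class TitrationResult:
    """One design cell's titration outcome."""

    indifference_point: float
    sv: float
    boundary_flag: str = FLAG_NONE
    history: list[tuple[float, str]] = field(default_factory=list)
    subject_id: str | None = None
    effort_level: object = None
    delay_code: int | None = None


def compute_sv(indifference_point: float, reward: float) -> float:
    """SV = indifference point / base reward (a fraction of the reward)."""
    if reward <= 0:
        raise ValueError("base reward must be positive")
    if not 0 <= indifference_point <= reward:
        raise ValueError(
            f"indifference point {indifference_point} outside [0, {reward}]"
        )
    return indifference_point / reward


def _normalize_choice(choice) -> str:
    if choice in (EFFORTFUL, EFFORTLESS):
        return choice
    if isinstance(choice, (bool, np.bool_)):
        return EFFORTFUL if choice else EFFORTLESS
    raise ValueError(f"oracle returned unrecognized choice {choice!r}")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def run_reversal_staircase(
    choice_oracle: ChoiceOracle,
    reward: float = 10.0,
    offer_min: int = 1,
    offer_max: int | None = None,
) -> TitrationResult:
    """Integer bisection staircase stopping at a one-unit preference reversal.

    Offers are integers in [offer_min, offer_max] (offer_max defaults to
    reward − 1).  The first offer is round(reward / 2); choosing the
    effortful option raises the offer to the midpoint of the remaining
    upper bracket, choosing the effortless option lowers it, with
    round-half-up midpoints.  The procedure stops when two adjacent
    integers have elicited opposite preferences, and returns the smaller
    offer at which the effortless option was preferred.  If the agent
    prefers the effortless option even at offer_min the result is
    offer_min with a ``floor`` flag; if it prefers the effortful option
    even at offer_max the result is the full reward with a ``ceiling``
    flag (SV = 1).
    """
    if offer_max is None:
        offer_max = int(round(reward)) - 1
    if not offer_min < offer_max:
        raise ValueError("offer_min must be below offer_max")

    # lo = highest offer at which the effortful option was chosen,
    # hi = lowest offer at which the effortless option was chosen;
    # the open endpoints encode "not yet observed".
    lo, hi = offer_min - 1, offer_max + 1
    history: list[tuple[float, str]] = []
    while True:
        offer = _round_half_up((lo + hi) / 2.0)
        if not float(offer).is_integer():  # pragma: no cover - guarded by construction
            raise RuntimeError("staircase schedule produced a non-integer offer")
        choice = _normalize_choice(choice_oracle(offer))
        history.append((float(offer), choice))
        if choice == EFFORTFUL:
            lo = offer
            if offer == offer_max:
                return TitrationResult(
                    indifference_point=float(reward),
                    sv=compute_sv(reward, reward),
                    boundary_flag=FLAG_CEILING,
                    history=history,
                )
        else:
            hi = offer
            if offer == offer_min:
                return TitrationResult(
                    indifference_point=float(offer_min),
                    sv=compute_sv(offer_min, reward),
                    boundary_flag=FLAG_FLOOR,
                    history=history,
                )
        if hi - lo == 1:
            return TitrationResult(
                indifference_point=float(hi),
                sv=compute_sv(hi, reward),
                boundary_flag=FLAG_NONE,
                history=history,
            )


def run_halving_titration(
    choice_oracle: ChoiceOracle,
    reward: float = 2.0,
    n_trials: int = 6,
) -> TitrationResult:
    """Titration whose offer adjustment halves after every choice.

    Trial 1 offers reward/2; the first adjustment is reward/4 and each
    subsequent one is half the previous.  The offer presented on trial
    ``n_trials`` is the indifference point (its choice is still recorded
    but moves nothing).  Offers are clamped to [0, reward], although the
    geometric schedule can never leave that interval.
    """
    if reward <= 0:
        raise ValueError("base reward must be positive")
    if n_trials < 2:
        raise ValueError("need at least two trials")
    offer = reward / 2.0
    step = reward / 4.0
    history: list[tuple[float, str]] = []
    for trial in range(1, n_trials + 1):
        choice = _normalize_choice(choice_oracle(offer))
        history.append((offer, choice))
        if trial == n_trials:
            break
        offer = offer + step if choice == EFFORTFUL else offer - step
        offer = min(max(offer, 0.0), reward)
        step /= 2.0
    return TitrationResult(
        indifference_point=offer,
        sv=compute_sv(offer, reward),
        history=history,
    )


def halving_titration_batch(
    true_values: np.ndarray,
    tau: float | np.ndarray,
    reward: float,
    rng: np.random.Generator,
    n_trials: int = 6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized halving titration for logistic-noise agents.

    ``true_values`` are true SVs (fractions of ``reward``) for any number
    of design cells; each cell is titrated independently with
    P(effortful) = logistic((sv * reward - offer) / tau).  Returns
    (indifference_points, offer_history, choice_history) with histories
    shaped (n_cells, n_trials); choices are 1 for effortful.
    """
    sv = np.asarray(true_values, dtype=float)
    value = sv * reward
    offers = np.full(sv.shape, reward / 2.0)
    step = reward / 4.0
    offer_hist = np.empty(sv.shape + (n_trials,))
    choice_hist = np.empty(sv.shape + (n_trials,), dtype=np.int8)
    for trial in range(n_trials):
        if np.isscalar(tau) and tau == 0:
            p = (value >= offers).astype(float)
        else:
            p = 1.0 / (1.0 + np.exp(-(value - offers) / tau))
        effortful = rng.random(sv.shape) < p
        offer_hist[..., trial] = offers
        choice_hist[..., trial] = effortful
        if trial < n_trials - 1:
            offers = np.clip(offers + np.where(effortful, step, -step), 0.0, reward)
            step /= 2.0
    return offers, offer_hist, choice_hist


def run_design_grid(profile, spec, rng: np.random.Generator) -> list[TitrationResult]:
    """Titrate every effort × delay cell of the design for one agent.

    Cell order is randomized per subject (seed-reproducible through
    ``rng``).  The titration variant follows the spec: reversal
    staircase for the integer-offer design (reward 10), halving
    titration otherwise (reward 2).
    """
    from .cohort import sample_choice, true_sv  # local import avoids a cycle

    n_e, n_d = len(spec.effort_levels), len(spec.delay_points)
    if spec.titration == "reversal" and not float(spec.reward).is_integer():
        raise ValueError("reversal staircase requires an integer base reward")
    cells = [(e, d) for e in spec.effort_levels for d in spec.delay_points]
    order = rng.permutation(n_e * n_d)
    results = []
    for idx in order:
        effort, delay = cells[idx]

        def oracle(offer, _e=effort, _d=delay):
            return sample_choice(profile, offer, _e, _d, spec.reward, rng)

        if spec.titration == "reversal":
            res = run_reversal_staircase(oracle, reward=spec.reward)
        elif spec.titration == "halving":
            res = run_halving_titration(oracle, reward=spec.reward)
        else:
            raise ValueError(f"unknown titration variant {spec.titration!r}")
        res.subject_id = profile.subject_id
        res.effort_level = effort
        res.delay_code = delay
        results.append(res)
    return results


def titration_table(results: Sequence[TitrationResult], group: str | None = None):
    """Long-format DataFrame of titration results (sv_long.csv schema)."""
    import pandas as pd

    rows = [
        {
            "subject_id": r.subject_id,
            "group": group,
            "effort_level": r.effort_level,
            "delay_code": r.delay_code,
            "indifference_point": r.indifference_point,
            "sv": r.sv,
            "boundary_flag": r.boundary_flag,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
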