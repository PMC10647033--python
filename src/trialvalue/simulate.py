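"""Synthetic swing-weighting surveys with the structure the analysis assumes.

The generator emulates the elicitation study's respondent population: a mix of
stakeholder backgrounds, a completion rate (dropouts answer only a prefix of
the rank/weight questions), and a concordance rate.  A concordant respondent's
raw weights are a noisy, positively perturbed copy of a latent true weight
vector, ranked consistently and quantised to the survey instrument's integer
scale (top-ranked criterion fixed at 100, all others 0-99).  A discordant
respondent additionally has adjacent weight pairs swapped against the ranks,
the minimal controllable violation of concordance.

All randomness flows through a single integer seed.  Per respondent the draw
order is fixed (background, affiliation, experience, completion, concordance,
weight noise, discordance swaps, dropout cut), so output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .criteria import CONTINUOUS, CriteriaSet, default_criteria_set
from .datasets import reference_background_mix
from .pvf import MidpointElicitation
from .utils import round_half_up
from .weights import SwingResponse, WeightVector, standardise_weights

__all__ = [
    "SurveySimConfig",
    "simulate_survey",
    "representable_weights",
    "simulate_midpoint_elicitations",
]

_AFFILIATION_MIX = {"no": 0.91, "yes": 0.09}
_EXPERIENCE_MIX = {
    "none": 0.25,
    "under_10_years": 0.35,
    "10_plus_years": 0.36,
    "other": 0.04,
}


def representable_weights(weights: WeightVector | Mapping[str, float]) -> WeightVector:
    """Quantise a weight vector onto the survey instrument's integer scale.

    The instrument records the top criterion as 100 and the rest as integers
    0-99, so only vectors proportional to such integers can be recovered
    exactly from noise-free responses.  This returns the nearest one.
    """
    w = weights.weights if isinstance(weights, WeightVector) else weights
    top = max(w.values())
    raw = {k: round_half_up(v / top * 100.0, 0) for k, v in w.items()}
    return WeightVector(weights=standardise_weights(raw), provenance="manual")


@dataclass
class SurveySimConfig:
    """Conditions of a simulated elicitation survey.

    Defaults mirror the original study: 157 respondents, 80 of whom complete
    the survey, 43 of those concordant, backgrounds in the published
    proportions, and a latent truth equal to the published mean weights
    quantised to the instrument scale.
    """

    n_respondents: int = 157
    completion_rate: float = 80.0 / 157.0
    concordance_rate: float = 43.0 / 80.0
    true_weights: WeightVector | None = None  # default: published means, quantised
    weight_noise_sd: float = 8.0  # on the 0-100 standardised-weight scale
    background_mix: Mapping[str, float] = field(default_factory=reference_background_mix)
    n_swaps: int = 1  # adjacent-pair weight swaps inducing discordance
    exact_counts: bool = False  # fix complete/concordant counts instead of Bernoulli draws
    seed: int = 0

    def validate(self) -> None:
        if self.n_respondents < 0:
            raise ValueError("n_respondents must be >= 0")
        for name in ("completion_rate", "concordance_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.weight_noise_sd < 0:
            raise ValueError("weight_noise_sd must be >= 0")
        if self.n_swaps < 1:
            raise ValueError("n_swaps must be >= 1")
        total = sum(self.background_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"background_mix must sum to 1, sums to {total}")


def _default_truth() -> WeightVector:
    from .datasets import reference_weights

    return representable_weights(reference_weights().renormalised())


def _integer_instrument_weights(s: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Scale latent scores so the top is 100, round, clamp others to 0..99."""
    scaled = s / s[order[0]] * 100.0
    raw = np.array([round_half_up(v, 0) for v in scaled])
    raw[order[0]] = 100.0
    for idx in order[1:]:
        raw[idx] = min(99.0, max(0.0, raw[idx]))
    return raw


def _make_discordant(raw: np.ndarray, order: np.ndarray, rng: np.random.Generator, n_swaps: int) -> None:
    """Swap adjacent (by rank) weight pairs against the ranking, in place.

    Only ranks 2..n participate (the instrument pins rank 1 at weight 100).
    If no strictly decreasing adjacent pair exists, a one-point perturbation
    creates a violation instead.
    """
    n = len(order)
    for _ in range(n_swaps):
        candidates = [
            k for k in range(1, n - 1) if raw[order[k]] > raw[order[k + 1]]
        ]
        if candidates:
            k = int(rng.choice(candidates))
            a, b = order[k], order[k + 1]
            raw[a], raw[b] = raw[b], raw[a]
        elif raw[order[1]] >= 1:
            raw[order[1]] -= 1  # now strictly below the rank-3 weight
        else:
            raw[order[-1]] = 1  # all non-top weights were 0
            break


def _sample_category(rng: np.random.Generator, mix: Mapping[str, float]) -> str:
    keys = list(mix.keys())
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def simulate_survey(config: SurveySimConfig, criteria: CriteriaSet | None = None) -> list[SwingResponse]:
    """Generate a reproducible synthetic survey under the configured conditions."""
    config.validate()
    criteria = criteria or default_criteria_set()
    ids = list(criteria.ids)
    n_crit = len(ids)
    truth = config.true_weights or _default_truth()
    true = np.array([truth[cid] for cid in ids], dtype=float)
    rng = np.random.default_rng(config.seed)

    n = config.n_respondents
    if config.exact_counts:
        n_complete = int(round(n * config.completion_rate))
        n_conc = int(round(n_complete * config.concordance_rate))
        complete_idx = rng.permutation(n)[:n_complete]
        complete_flags = np.zeros(n, dtype=bool)
        complete_flags[complete_idx] = True
        conc_idx = rng.permutation(n_complete)[:n_conc]
        conc_flags_among_complete = np.zeros(n_complete, dtype=bool)
        conc_flags_among_complete[conc_idx] = True
    complete_counter = 0

    responses: list[SwingResponse] = []
    for i in range(n):
        background = _sample_category(rng, config.background_mix)
        affiliation = _sample_category(rng, _AFFILIATION_MIX)
        experience = _sample_category(rng, _EXPERIENCE_MIX)
        if config.exact_counts:
            is_complete = bool(complete_flags[i])
            rng.random()  # keep the per-respondent draw count fixed
        else:
            is_complete = bool(rng.random() < config.completion_rate)
        if config.exact_counts:
            if is_complete:
                intends_concordant = bool(conc_flags_among_complete[complete_counter])
                complete_counter += 1
            else:
                intends_concordant = True
            rng.random()
        else:
            intends_concordant = bool(rng.random() < config.concordance_rate)

        noise = rng.normal(0.0, config.weight_noise_sd, size=n_crit)
        s = np.maximum(true + (noise if config.weight_noise_sd > 0 else 0.0), 0.5)
        order = np.argsort(-s, kind="stable")  # ties broken by criterion order
        ranks = {ids[idx]: int(pos + 1) for pos, idx in enumerate(order)}
        raw = _integer_instrument_weights(s, order)
        if not intends_concordant:
            _make_discordant(raw, order, rng, config.n_swaps)
        raw_weights = {ids[j]: float(raw[j]) for j in range(n_crit)}

        if not is_complete:
            # dropout: answers stop partway through the rank/weight questions
            answered = int(rng.integers(0, 2 * n_crit))  # < 2*n_crit => incomplete
            keep_ranks = {cid: ranks[cid] for cid in ids[: min(answered, n_crit)]}
            keep_weights = {
                cid: raw_weights[cid] for cid in ids[: max(0, answered - n_crit)]
            }
            ranks, raw_weights = keep_ranks, keep_weights

        responses.append(
            SwingResponse(
                respondent_id=f"R{i + 1:04d}",
                background=background,
                paid_affiliation=affiliation,
                trial_experience=experience,
                country="Australia",
                ranks=ranks,
                raw_weights=raw_weights,
            )
        )
    return responses


def simulate_midpoint_elicitations(
    criteria: CriteriaSet | None = None,
    n_raters: int = 6,
    rel_sd: float = 0.10,
    seed: int = 0,
) -> list[MidpointElicitation]:
    """Synthetic bisection-interview answers for every continuous criterion.

    Midpoints are drawn around the centre of each criterion's range with a
    spread of ``rel_sd`` times the range, truncated to the open interval, as a
    stand-in for a panel of interviewees.
    """
    criteria = criteria or default_criteria_set()
    rng = np.random.default_rng(seed)
    out: list[MidpointElicitation] = []
    for crit in criteria:
        if crit.kind != CONTINUOUS:
            continue
        lo, hi = crit.raw_interval()
        span = hi - lo
        centre = (lo + hi) / 2.0
        for r in range(n_raters):
            m = float(
                np.clip(
                    rng.normal(centre, rel_sd * span),
                    lo + 0.02 * span,
                    hi - 0.02 * span,
                )
            )
            out.append(
                MidpointElicitation(
                    criterion_id=crit.id, respondent_id=f"P{r + 1}", midpoint_raw=m
                )
            )
    return out
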