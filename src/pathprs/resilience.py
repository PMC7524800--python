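"""Resilience-versus-risk effect-size comparison.

For each score the *change in effect size* is the ratio between the
magnitude of the resilience association (log OR, centenarians vs
population) and the magnitude of the risk association (log OR, AD cases vs
population). A value below 1 means the score acts more strongly on disease
risk than on resilience; above 1, the reverse. Because the panel variants
were selected for their AD association, values below 1 are the default
expectation.

Confidence intervals come from parametric Monte-Carlo: each log OR is
drawn independently from its asymptotic normal, the ratio of absolute
values is formed per draw, and the 2.5/97.5 percentiles are reported. The
with- versus without-APOE ratios are compared by a Welch t-test on the two
draw samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import AssociationResult
from .datatypes import MissingDataError, PathPRSError

logger = logging.getLogger("pathprs")

MIN_DRAWS = 1000


class RatioError(PathPRSError):
    """Undefined or unstable effect-size ratio."""


@dataclass
class EffectRatio:
    """Resilience/risk log-OR magnitude ratio with a sampled 95% CI."""

    score_name: str
    apoe_included: bool
    ratio: float
    #: True iff the two log-ORs point in opposite directions
    #: (risk-increasing and resilience-increasing), the concordant pattern.
    concordant: bool
    ci95: tuple[float, float]
    n_draws: int
    seed: int
    draws: np.ndarray | None = field(default=None, repr=False)
    #: fraction of Monte-Carlo draws whose risk log-OR changed sign
    sign_discordant_fraction: float = 0.0


@dataclass
class RatioComparison:
    """Welch t-test between the with- and without-APOE ratio draw samples."""

    score_name: str
    ratio_with_apoe: float
    ratio_without_apoe: float
    t_stat: float
    p: float
    n_draws: int


def _check_pair(risk: AssociationResult, resilience: AssociationResult) -> None:
    if risk.comparison != "A_vs_P" or resilience.comparison != "C_vs_P":
        raise ValueError("expected an A_vs_P (risk) and a C_vs_P (resilience) result")
    if risk.score_name != resilience.score_name:
        raise ValueError(
            f"score mismatch: {risk.score_name!r} vs {resilience.score_name!r}"
        )
    if risk.apoe_included != resilience.apoe_included:
        raise ValueError("APOE mode mismatch between risk and resilience results")


def change_in_effect_size(
    risk: AssociationResult, resilience: AssociationResult
) -> float:
    """``|log OR_CvsP| / |log OR_AvsP|`` for one score and APOE mode."""
    _check_pair(risk, resilience)
    if risk.beta_hat == 0.0:
        raise RatioError(
            f"{risk.score_name}: risk log-OR is exactly 0; ratio undefined"
        )
    return abs(resilience.beta_hat) / abs(risk.beta_hat)


def sample_ratio_ci(
    risk: AssociationResult,
    resilience: AssociationResult,
    n_draws: int = 10_000,
    seed: int = 0,
) -> EffectRatio:
    """Monte-Carlo 95% CI for the effect-size ratio.

    Log-OR pairs are drawn independently from ``N(beta_hat, se)`` for each
    contrast (the two contrasts share only the population cohort; their
    dependence is ignored). Draws where the risk coefficient crosses zero
    are kept — the ratio of absolute values remains defined — and their
    fraction is reported as a stability diagnostic.
    """
    _check_pair(risk, resilience)
    if n_draws < MIN_DRAWS:
        raise RatioError(f"n_draws must be at least {MIN_DRAWS} for a stable CI")
    if not (np.isfinite(risk.se) and np.isfinite(resilience.se)):
        raise RatioError("finite standard errors required for sampling")
    point = change_in_effect_size(risk, resilience)
    rng = np.random.default_rng(seed)
    draws_a = rng.normal(risk.beta_hat, risk.se, n_draws)
    draws_c = rng.normal(resilience.beta_hat, resilience.se, n_draws)
    ratios = np.abs(draws_c) / np.abs(draws_a)
    discordant = float(np.mean(np.sign(draws_a) != np.sign(risk.beta_hat)))
    if discordant > 0.0:
        logger.warning(
            "%s: %.2f%% of draws flipped the sign of the risk log-OR",
            risk.score_name,
            100 * discordant,
        )
    lo, hi = np.percentile(ratios, [2.5, 97.5])
    return EffectRatio(
        score_name=risk.score_name,
        apoe_included=risk.apoe_included,
        ratio=point,
        concordant=bool(np.sign(risk.beta_hat) != np.sign(resilience.beta_hat)),
        ci95=(float(lo), float(hi)),
        n_draws=n_draws,
        seed=seed,
        draws=ratios,
        sign_discordant_fraction=discordant,
    )


def compare_ratios(with_apoe: EffectRatio, without_apoe: EffectRatio) -> RatioComparison:
    """Welch two-sample t-test on the two Monte-Carlo ratio samples.

    Positive ``t_stat`` means the without-APOE ratio sample is larger. The
    p-value depends on the draw count, which is therefore reported.
    """
    if with_apoe.draws is None or without_apoe.draws is None:
        raise MissingDataError("ratio draw samples unavailable; rerun sample_ratio_ci")
    if with_apoe.score_name != without_apoe.score_name:
        raise ValueError("score mismatch between APOE modes")
    t, p = stats.ttest_ind(without_apoe.draws, with_apoe.draws, equal_var=False)
    return RatioComparison(
        score_name=with_apoe.score_name,
        ratio_with_apoe=with_apoe.ratio,
        ratio_without_apoe=without_apoe.ratio,
        t_stat=float(t),
        p=float(p),
        n_draws=min(with_apoe.n_draws, without_apoe.n_draws),
    )


def ratios_frame(ratios: list[EffectRatio]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score_name": r.score_name,
                "apoe_included": r.apoe_included,
                "ratio": r.ratio,
                "concordant": r.concordant,
                "ci_low": r.ci95[0],
                "ci_high": r.ci95[1],
                "n_draws": r.n_draws,
                "seed": r.seed,
            }
            for r in ratios
        ]
    )


def comparisons_frame(comparisons: list[RatioComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "score_name": c.score_name,
                "ratio_with_apoe": c.ratio_with_apoe,
                "ratio_without_apoe": c.ratio_without_apoe,
                "t": c.t_stat,
                "p": c.p,
                "n_draws": c.n_draws,
            }
            for c in comparisons
        ]
    )
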