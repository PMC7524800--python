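"""Case/control and resilience association of the (pathway-)PRS.

Two contrasts are fitted: AD cases versus population subjects (``A_vs_P``,
the risk association) and cognitively healthy centenarians versus
population subjects (``C_vs_P``, the resilience association). Each is a
maximum-likelihood logistic regression of status on one z-scaled score
plus principal components 1-5; the coefficient is the log odds ratio per
one SD of score, with Wald standard errors, two-sided p-values and 95%
CIs. Sex is handled by stratification, never as a covariate.
Non-convergence or (quasi-)separation is a hard error — with a curated
variant score and thousands of subjects it signals a data problem.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score

from .datatypes import FitFailureError, MissingDataError, PhenotypeTable
from .scores import ScoreMatrix

logger = logging.getLogger("pathprs")

COMPARISONS = ("A_vs_P", "C_vs_P")
STRATA = ("all", "male", "female")

#: displayed significance thresholds: *, **, ***
SIGNIFICANCE_THRESHOLDS = (5e-2, 5e-4, 5e-6)

_PC_COLS = [f"pc{i}" for i in range(1, 6)]


@dataclass
class AssociationResult:
    """One fitted score-status contrast."""

    comparison: str
    score_name: str
    apoe_included: bool
    stratum: str
    beta_hat: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p: float
    n_case: int
    n_control: int
    auc: float | None = None

    @property
    def significance(self) -> str:
        return "*" * sum(self.p < t for t in SIGNIFICANCE_THRESHOLDS)

    def to_record(self) -> dict:
        rec = asdict(self)
        rec["ci95_low"], rec["ci95_high"] = rec.pop("ci95")
        rec["significance"] = self.significance
        return rec


def _case_control_frame(
    scores: ScoreMatrix,
    phenotypes: PhenotypeTable,
    comparison: str,
    score_name: str,
    stratum: str = "all",
) -> tuple[pd.DataFrame, str]:
    if comparison not in COMPARISONS:
        raise ValueError(f"comparison must be one of {COMPARISONS}")
    if stratum not in STRATA:
        raise ValueError(f"stratum must be one of {STRATA}")
    case_cohort = comparison[0]  # "A" or "C"
    phe = phenotypes.indexed()
    score = scores.column(score_name, scaled=True)
    shared = score.index.intersection(phe.index)
    df = phe.loc[shared].copy()
    df["score"] = score.loc[shared]
    df = df[df["cohort"].isin((case_cohort, "P"))]
    if stratum != "all":
        df = df[df["sex"] == stratum]  # "unknown" excluded from strata only
    df["status"] = (df["cohort"] == case_cohort).astype(int)
    if df["status"].sum() == 0 or (1 - df["status"]).sum() == 0:
        raise MissingDataError(
            f"{comparison} stratum {stratum!r}: need both cases and controls"
        )
    return df, case_cohort


def fit_score_association(
    scores: ScoreMatrix,
    phenotypes: PhenotypeTable,
    comparison: str,
    score_name: str,
    stratum: str = "all",
    include_auc: bool = True,
) -> AssociationResult:
    """Logistic fit of case status on one scaled score + PC1-5."""
    df, _ = _case_control_frame(scores, phenotypes, comparison, score_name, stratum)
    X = sm.add_constant(df[["score", *_PC_COLS]].astype(float), has_constant="add")
    y = df["status"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.filterwarnings(
            "error", category=sm.tools.sm_exceptions.PerfectSeparationWarning
        )
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        except (Exception,) as exc:
            raise FitFailureError(
                f"{comparison}/{score_name}/{stratum}: logistic fit failed ({exc})"
            ) from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitFailureError(
            f"{comparison}/{score_name}/{stratum}: logistic fit did not converge"
        )
    beta = float(fit.params["score"])
    se = float(fit.bse["score"])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        raise FitFailureError(
            f"{comparison}/{score_name}/{stratum}: quasi-separated fit "
            f"(beta={beta:.3g}, se={se:.3g})"
        )
    p = float(fit.pvalues["score"])
    auc = None
    if include_auc:
        auc = float(roc_auc_score(df["status"], df["score"]))
    return AssociationResult(
        comparison=comparison,
        score_name=score_name,
        apoe_included=scores.apoe_included,
        stratum=stratum,
        beta_hat=beta,
        se=se,
        or_=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se))),
        p=p,
        n_case=int(df["status"].sum()),
        n_control=int((1 - df["status"]).sum()),
        auc=auc,
    )


def compute_auc(
    scores: ScoreMatrix,
    phenotypes: PhenotypeTable,
    comparison: str,
    score_name: str,
) -> float:
    """Rank-based AUC (Mann-Whitney, ties averaged) of a score for a contrast."""
    df, _ = _case_control_frame(scores, phenotypes, comparison, score_name)
    return float(roc_auc_score(df["status"], df["score"]))


def run_association_panel(
    scores_by_mode: dict[bool, ScoreMatrix],
    phenotypes: PhenotypeTable,
    score_names: list[str] | None = None,
) -> tuple[list[AssociationResult], list[dict]]:
    """Full cross of scores x contrasts x APOE modes x sex strata.

    ``scores_by_mode`` maps ``apoe_included`` (True/False) to a scaled
    ScoreMatrix. Per-cell failures are captured in the returned error list;
    the remaining cells are unaffected.
    """
    results: list[AssociationResult] = []
    errors: list[dict] = []
    for apoe_included, scores in scores_by_mode.items():
        names = score_names
        if names is None:
            names = [c for c in scores.scaled.columns if c != "unmapped"]
        for score_name in names:
            for comparison in COMPARISONS:
                for stratum in STRATA:
                    try:
                        results.append(
                            fit_score_association(
                                scores, phenotypes, comparison, score_name, stratum
                            )
                        )
                    except Exception as exc:
                        errors.append(
                            {
                                "comparison": comparison,
                                "score_name": score_name,
                                "apoe_included": apoe_included,
                                "stratum": stratum,
                                "error": str(exc),
                            }
                        )
    if errors:
        logger.warning("%d association cells failed", len(errors))
    return results, errors


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_record() for r in results])


def write_associations(
    results: list[AssociationResult],
    tsv_path: str | Path,
    json_path: str | Path | None = None,
) -> None:
    df = results_frame(results)
    df.to_csv(tsv_path, sep="\t", index=False, float_format="%.12g")
    if json_path is not None:
        Path(json_path).write_text(json.dumps(df.to_dict(orient="records"), indent=2))
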