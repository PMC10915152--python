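"""Treatment outcomes and stepwise regression of outcome on the FC score.

Outcome after 8 weeks of antidepressant monotherapy is summarized two ways
from the 17-item Hamilton depression total (HRSD-17): the percentage
reduction from baseline, and the posttreatment total itself.  Clinically
meaningful binary outcomes are *response* (strictly more than 50% reduction)
and *remission* (posttreatment total <= 7).  Linear and logistic models are
selected by classical stepwise fitting (forward entry at p < 0.05, backward
removal at p > 0.10) over a candidate set that by default holds the
component-1 FC score plus age of onset and duration of the current episode;
the fitted logistic model is evaluated by ROC/AUC and accuracy at a 0.5
probability threshold.  Linear models report coefficients per standard
deviation of each predictor ("standardized B"); logistic models report odds
ratios per raw predictor unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "OutcomeRecord",
    "PredictionModel",
    "compute_outcomes",
    "outcome_table",
    "stepwise_fit",
    "evaluate_classifier",
    "roc_metrics",
    "DEFAULT_CANDIDATES",
]

DEFAULT_CANDIDATES: tuple[str, ...] = ("fc_score", "age_of_onset", "episode_duration")


@dataclass
class OutcomeRecord:
    subject_id: str
    baseline_hrsd: int
    post_hrsd: int
    pct_reduction: float
    response: bool
    remission: bool


@dataclass
class PredictionModel:
    outcome_name: str
    family: str                         # "linear" | "logistic"
    selected_predictors: list[str]
    coefficients: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    odds_ratios: dict[str, float] = field(default_factory=dict)
    or_ci_low: dict[str, float] = field(default_factory=dict)
    or_ci_high: dict[str, float] = field(default_factory=dict)
    auc: float | None = None
    accuracy: float | None = None
    classification_threshold: float = 0.5
    n_used: int = 0
    separation_flag: bool = False
    fitted_probabilities: np.ndarray | None = None
    fitted_values: np.ndarray | None = None
    observed: np.ndarray | None = None


def compute_outcomes(subject_id: str, baseline: int, post: int) -> OutcomeRecord:
    """Percentage HRSD-17 reduction and the derived response/remission flags.

    reduction% = (baseline - post) / baseline * 100, with response defined by
    a *strict* >50% reduction and remission by posttreatment total <= 7.
    Flags are decided in exact rational arithmetic so boundary cases (e.g. a
    reduction of exactly half) are unambiguous.
    """
    baseline = int(baseline)
    post = int(post)
    if baseline <= 0:
        raise ValueError("baseline HRSD-17 must be a positive integer")
    if post < 0:
        raise ValueError("posttreatment HRSD-17 cannot be negative")
    frac = Fraction(baseline - post, baseline)
    return OutcomeRecord(
        subject_id=subject_id,
        baseline_hrsd=baseline,
        post_hrsd=post,
        pct_reduction=float(frac * 100),
        response=frac > Fraction(1, 2),
        remission=post <= 7,
    )


def outcome_table(df: pd.DataFrame,
                  baseline_col: str = "baseline_hrsd",
                  post_col: str = "post_hrsd",
                  id_col: str = "subject_id") -> pd.DataFrame:
    """Vectorized outcome computation for completers.

    Rows with a missing posttreatment score are dropped (completer analysis;
    the number excluded is reported in a warning), mirroring a study design
    in which only a subset of the baseline sample finishes follow-up.
    """
    if df.empty:
        raise ValueError("empty subject table")
    n_all = len(df)
    complete = df[df[post_col].notna() & df[baseline_col].notna()]
    n_missing = n_all - len(complete)
    if n_missing:
        warnings.warn(
            f"excluding {n_missing}/{n_all} subjects without posttreatment scores",
            UserWarning,
            stacklevel=2,
        )
    records = [
        compute_outcomes(str(row[id_col]), int(row[baseline_col]), int(row[post_col]))
        for _, row in complete.iterrows()
    ]
    return pd.DataFrame(
        {
            id_col: [r.subject_id for r in records],
            "baseline_hrsd": [r.baseline_hrsd for r in records],
            "post_hrsd": [r.post_hrsd for r in records],
            "pct_reduction": [r.pct_reduction for r in records],
            "response": [r.response for r in records],
            "remission": [r.remission for r in records],
        }
    )


def _fit_once(y: np.ndarray, X: pd.DataFrame, family: str):
    design = sm.add_constant(X, has_constant="add")
    if family == "linear":
        return sm.OLS(y, design).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.Logit(y, design).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        # (quasi-)separation leaves the likelihood unbounded
        raise PerfectSeparationError("logistic fit did not converge")
    return res


def _term_pvalues(result, terms: list[str]) -> dict[str, float]:
    return {t: float(result.pvalues[t]) for t in terms}


def stepwise_fit(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str] | None = None,
    family: str = "linear",
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> PredictionModel:
    """Forward selection with backward pruning on Wald p-values.

    At each step the candidate with the smallest p-value below ``p_enter``
    joins the model; any included term whose p-value rises above ``p_remove``
    is dropped.  The final model is refit on complete cases.  An empty
    selection is a legitimate result (reported, not raised).  Perfect
    separation in a logistic fit is flagged and the coefficients fall back to
    a ridge-penalized fit (no confidence intervals in that case).
    """
    if family not in ("linear", "logistic"):
        raise ValueError("family must be 'linear' or 'logistic'")
    candidates = list(candidates) if candidates is not None else list(DEFAULT_CANDIDATES)
    cols = [outcome] + candidates
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    work = data[cols].dropna()
    n = len(work)
    if n < 10:
        raise ValueError(f"need >= 10 complete cases, got {n}")

    y = work[outcome].to_numpy(dtype=float)
    if family == "logistic" and set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    preds = work[candidates].astype(float)
    if family == "linear":
        # coefficients per predictor SD
        preds = (preds - preds.mean()) / preds.std(ddof=1)

    selected: list[str] = []
    separation = False
    # cap guards against enter/remove cycling on borderline terms
    for _ in range(2 * len(candidates) + 5):
        # forward step: smallest p-value below the entry threshold
        best_term, best_p = None, p_enter
        for cand in candidates:
            if cand in selected:
                continue
            try:
                res = _fit_once(y, preds[selected + [cand]], family)
                pv = float(res.pvalues[cand])
            except np.linalg.LinAlgError:
                continue
            except PerfectSeparationError:
                # a separating predictor is maximally informative
                pv = 0.0
            if np.isfinite(pv) and pv < best_p:
                best_term, best_p = cand, pv
        if best_term is not None:
            selected.append(best_term)
        # backward step: prune terms whose joint-model p exceeds p_remove
        dropped: list[str] = []
        while selected:
            try:
                res = _fit_once(y, preds[selected], family)
            except (np.linalg.LinAlgError, PerfectSeparationError):
                break
            pvals = _term_pvalues(res, selected)
            worst = max(pvals, key=pvals.get)
            if pvals[worst] > p_remove:
                selected.remove(worst)
                dropped.append(worst)
            else:
                break
        if best_term is None and not dropped:
            break
        if best_term is not None and dropped == [best_term]:
            break  # add-then-remove cycle on a borderline term

    model = PredictionModel(
        outcome_name=outcome,
        family=family,
        selected_predictors=list(selected),
        n_used=n,
        observed=y,
    )
    if not selected:
        return model

    try:
        res = _fit_once(y, preds[selected], family)
        if family == "logistic" and not res.mle_retvals.get("converged", True):
            raise sm.tools.sm_exceptions.PerfectSeparationError("did not converge")
        conf = res.conf_int()
        for t in selected:
            model.coefficients[t] = float(res.params[t])
            model.ci_low[t] = float(conf.loc[t, 0])
            model.ci_high[t] = float(conf.loc[t, 1])
            model.p_values[t] = float(res.pvalues[t])
        if family == "logistic":
            for t in selected:
                model.odds_ratios[t] = float(np.exp(res.params[t]))
                model.or_ci_low[t] = float(np.exp(conf.loc[t, 0]))
                model.or_ci_high[t] = float(np.exp(conf.loc[t, 1]))
            model.fitted_probabilities = np.asarray(res.predict())
        else:
            model.fitted_values = np.asarray(res.fittedvalues)
    except (sm.tools.sm_exceptions.PerfectSeparationError, np.linalg.LinAlgError):
        # quasi-separated logistic likelihood: ridge-penalized point estimates
        separation = True
        clf = LogisticRegression(C=100.0, solver="lbfgs", max_iter=1000)
        clf.fit(preds[selected].to_numpy(), y)
        for i, t in enumerate(selected):
            model.coefficients[t] = float(clf.coef_[0, i])
            model.odds_ratios[t] = float(np.exp(clf.coef_[0, i]))
        model.fitted_probabilities = clf.predict_proba(preds[selected].to_numpy())[:, 1]
        warnings.warn(
            f"separation detected fitting {outcome}; penalized fallback used "
            "(no confidence intervals)",
            UserWarning,
            stacklevel=2,
        )
    model.separation_flag = separation
    return model


def roc_metrics(
    probabilities: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
) -> tuple[float, float, pd.DataFrame]:
    """(AUC, accuracy at ``threshold``, ROC curve) for binary labels.

    AUC is the trapezoidal area under the threshold-swept ROC, which equals
    the normalized count of concordant probability/label pairs (the
    Mann-Whitney statistic).  Raises if only one class is present.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present for ROC analysis")
    fpr, tpr, thr = _sk_roc_curve(labels, probabilities)
    auc = float(np.trapezoid(tpr, fpr))
    accuracy = float(np.mean((probabilities >= threshold) == (labels == 1)))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, accuracy, curve


def evaluate_classifier(
    model: PredictionModel,
    outcomes: np.ndarray | None = None,
    threshold: float = 0.5,
) -> tuple[float, float, pd.DataFrame]:
    """ROC evaluation of a fitted logistic model; fills auc/accuracy in place."""
    if model.family != "logistic":
        raise ValueError("ROC evaluation applies to logistic models")
    if model.fitted_probabilities is None:
        raise ValueError("model has no fitted probabilities (empty selection?)")
    labels = np.asarray(outcomes if outcomes is not None else model.observed)
    auc, accuracy, curve = roc_metrics(model.fitted_probabilities, labels, threshold)
    model.auc = auc
    model.accuracy = accuracy
    model.classification_threshold = threshold
    return auc, accuracy, curve
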