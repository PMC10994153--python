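"""Longitudinal analysis: dysglycemia labels, paired change tests, and the
seven-predictor logistic / ROC comparison.

Dysglycemia is the composite FPG > 100 mg/dL or 2-h glucose > 140 mg/dL
(strict inequalities).  Within the longitudinal subset (follow-up at least
6 months after baseline), seven baseline predictor sets are compared for
predicting follow-up dysglycemia with unpenalized maximum-likelihood
logistic regression and in-sample ROC/AUC — no train/test split, matching
a small-cohort design where holding out data is not affordable.  AUC is
the Mann-Whitney concordance probability with ties counted one half.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

FPG_THRESHOLD = 100.0   # mg/dL, strict
PG2H_THRESHOLD = 140.0  # mg/dL, strict

#: canonical predictor-set names, in reporting order
PREDICTOR_SETS = ("FPG", "2hrPG", "HbA1c", "shape",
                  "glucose FPCs", "insulin FPCs", "glucose+insulin FPCs")


def label_dysglycemia(fpg: float, pg2h: float,
                      fpg_gt: float = FPG_THRESHOLD,
                      pg2h_gt: float = PG2H_THRESHOLD) -> bool:
    """Composite dysglycemia: FPG > 100 or 2hrPG > 140 (both strict)."""
    if not (np.isfinite(fpg) and np.isfinite(pg2h)):
        raise ValueError("missing FPG or 2hrPG")
    return bool(fpg > fpg_gt or pg2h > pg2h_gt)


def label_cohort(fpg: np.ndarray, pg2h: np.ndarray, **kw) -> np.ndarray:
    fpg = np.asarray(fpg, float)
    pg2h = np.asarray(pg2h, float)
    return np.array([label_dysglycemia(a, b, **kw) for a, b in zip(fpg, pg2h)])


def paired_change_tests(baseline: pd.DataFrame,
                        followup: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon signed-rank tests of baseline vs follow-up for continuous
    columns, McNemar's test for the boolean ``dysglycemia`` column.

    McNemar uses the exact binomial distribution when the discordant count
    is below 25 and the (uncorrected) chi-square approximation otherwise.
    Pairs with a missing value in either visit are dropped per variable.
    """
    if baseline.shape[0] != followup.shape[0]:
        raise ValueError("baseline and follow-up must be paired row-for-row")
    if baseline.shape[0] == 0:
        raise ValueError("zero pairs")
    rows = []
    for col in baseline.columns:
        if col not in followup.columns:
            continue
        b = baseline[col]
        f = followup[col]
        ok = b.notna() & f.notna()
        b, f = b[ok], f[ok]
        if col == "dysglycemia":
            b = b.astype(bool)
            f = f.astype(bool)
            table = np.array([
                [int((~b & ~f).sum()), int((~b & f).sum())],
                [int((b & ~f).sum()), int((b & f).sum())],
            ])
            n_disc = table[0, 1] + table[1, 0]
            res = mcnemar(table, exact=(n_disc < 25), correction=False)
            rows.append({"variable": col, "test": "mcnemar",
                         "statistic": float(res.statistic),
                         "p_value": float(min(res.pvalue, 1.0)),
                         "n": int(ok.sum())})
        else:
            diff = (f - b).to_numpy(float)
            if np.all(diff == 0):
                stat, p = 0.0, 1.0  # degenerate: no change anywhere
            else:
                stat, p = stats.wilcoxon(b.to_numpy(float), f.to_numpy(float))
            rows.append({"variable": col, "test": "wilcoxon_signed_rank",
                         "statistic": float(stat), "p_value": float(p),
                         "n": int(ok.sum())})
    return pd.DataFrame(rows)


def roc_auc(scores, labels):
    """ROC points and tie-aware AUC for one score vector.

    AUC is computed as the Mann-Whitney U statistic over all
    (event, non-event) pairs divided by n_pos x n_neg, with tied scores
    counted 1/2 — the rank-sum form, exact for any tie pattern.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute ROC/AUC")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(labels, scores)
    return {"auc": float(auc), "fpr": fpr, "tpr": tpr,
            "thresholds": thresholds, "n_pos": n_pos, "n_neg": n_neg}


@dataclass
class PredictorComparison:
    """One fitted predictor set: coefficients, probabilities, ROC, AUC."""

    name: str
    columns: list[str]
    coefficients: np.ndarray
    probabilities: np.ndarray
    auc: float
    roc: dict = field(repr=False)
    n: int = 0
    events: int = 0
    separated: bool = False


def _fit_logistic(X: np.ndarray, y: np.ndarray):
    """Unpenalized ML logistic fit with separation detection.

    Constant (zero-variance) feature columns are aliased with the
    intercept and dropped up front; if nothing remains, every participant
    gets the same probability (AUC exactly 0.5 by the tie convention).
    On (quasi-)separation the ML estimate diverges; probabilities are then
    taken from a weakly ridge-stabilized refit — which preserves the
    separating ranking — and the comparison is flagged.
    """
    X = np.atleast_2d(np.asarray(X, float))
    keep = X.std(axis=0) > 0
    if not keep.any():
        p0 = y.mean()
        return (np.array([np.log(p0 / (1 - p0))]),
                np.full(len(y), p0), False)
    Xk = X[:, keep]
    Xc = sm.add_constant(Xk, has_constant="add")
    separated = False
    fit = None
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = np.asarray(fit.params, float)
        if not fit.mle_retvals.get("converged", True) or \
                np.any(np.abs(params) > 1e3):
            separated = True
    except (PerfectSeparationError, np.linalg.LinAlgError):
        separated = True
    if separated:
        logger.warning("separation detected; using ridge-stabilized score")
        from sklearn.linear_model import LogisticRegression
        lr = LogisticRegression(C=1e4, max_iter=2000).fit(Xk, y)
        params = np.concatenate([lr.intercept_, lr.coef_.ravel()])
        probs = lr.predict_proba(Xk)[:, 1]
    else:
        probs = np.asarray(fit.predict(Xc), float)
    probs = np.clip(probs, 1e-12, 1 - 1e-12)
    return params, probs, separated


def fit_predictor_models(
    features: pd.DataFrame,
    labels,
    predictor_sets: dict[str, list[str]] | None = None,
) -> dict[str, PredictorComparison]:
    """Fit the seven logistic predictor sets and their in-sample ROC/AUC.

    ``features`` must contain columns for each predictor set: ``fpg``,
    ``pg2h``, ``hba1c``, the two shape dummies (``shape_biphasic``,
    ``shape_monotonically_increasing``; monophasic is the reference), and
    the standardized FPC scores ``glu_fpc1..3`` / ``ins_fpc1..3``.
    """
    if predictor_sets is None:
        predictor_sets = default_predictor_sets()
    y = np.asarray(labels).astype(int)
    if y.sum() < 1:
        raise ValueError("need at least one event to fit predictors")
    out: dict[str, PredictorComparison] = {}
    for name, cols in predictor_sets.items():
        missing = [c for c in cols if c not in features.columns]
        if missing:
            raise KeyError(f"predictor set {name!r}: missing columns {missing}")
        X = features[cols].to_numpy(float)
        params, probs, separated = _fit_logistic(X, y)
        roc = roc_auc(probs, y.astype(bool))
        out[name] = PredictorComparison(
            name=name, columns=list(cols), coefficients=params,
            probabilities=probs, auc=roc["auc"], roc=roc,
            n=len(y), events=int(y.sum()), separated=separated,
        )
    return out


def default_predictor_sets() -> dict[str, list[str]]:
    return {
        "FPG": ["fpg"],
        "2hrPG": ["pg2h"],
        "HbA1c": ["hba1c"],
        "shape": ["shape_biphasic", "shape_monotonically_increasing"],
        "glucose FPCs": ["glu_fpc1", "glu_fpc2", "glu_fpc3"],
        "insulin FPCs": ["ins_fpc1", "ins_fpc2", "ins_fpc3"],
        "glucose+insulin FPCs": ["glu_fpc1", "glu_fpc2", "glu_fpc3",
                                 "ins_fpc1", "ins_fpc2", "ins_fpc3"],
    }


def auc_table(models: dict[str, PredictorComparison]) -> pd.DataFrame:
    return pd.DataFrame([
        {"predictor_set": m.name, "auc": m.auc, "n": m.n,
         "events": m.events, "separated": m.separated}
        for m in models.values()
    ])
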