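"""Cross-sectional association battery.

Spearman rank correlations of the curve summaries (shape indicator columns
and standardized FPC scores) against timed glucose/insulin values and
metabolic labs, with a Bonferroni flag at alpha / 171; Kruskal-Wallis and
Fisher's-exact group-difference tests across shape classes; and ordinary
least-squares models of each FPC on one metabolic exposure adjusted for
age, sex, race and ethnicity.  Every association is complete-case for its
own variable pair, so per-variable n varies with missingness.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

BONFERRONI_N = 171
EXACT_PERMUTATION_MAX_N = 10


@dataclass(frozen=True)
class AssociationResult:
    feature: str
    target: str
    spearman_r: float
    p_value: float
    n: int
    significant: bool


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Exact two-sided permutation p-value for Spearman's rho (small n).

    Enumerates all n! pairings of the rank vectors; rho is monotone in the
    inner product of permuted ranks, so only that product is computed.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc**2).sum() * (ryc**2).sum())
    if denom == 0:
        return np.nan, np.nan
    r_obs = float(rxc @ ryc / denom)
    n = len(x)
    count = total = 0
    chunk: list[tuple] = []

    def flush(chunk):
        nonlocal count, total
        perm = np.array(chunk)
        rs = (ryc[perm] @ rxc) / denom
        count += int(np.sum(np.abs(rs) >= abs(r_obs) - 1e-12))
        total += len(chunk)

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        if len(chunk) == 100_000:
            flush(chunk)
            chunk = []
    if chunk:
        flush(chunk)
    return r_obs, count / total


def spearman_with_p(x, y) -> tuple[float, float, int]:
    """Spearman rho and two-sided p: exact permutation for n <= 10,
    t-approximation otherwise.  Returns (rho, p, n) on complete cases."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 3:
        return np.nan, np.nan, n
    if np.all(x == x[0]) or np.all(y == y[0]):
        return np.nan, np.nan, n
    if n <= EXACT_PERMUTATION_MAX_N:
        r, p = _spearman_exact_p(x, y)
        return r, p, n
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue), n


def spearman_matrix(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    alpha: float = 0.05,
    n_comparisons: int = BONFERRONI_N,
) -> pd.DataFrame:
    """All feature x target Spearman correlations with a Bonferroni flag.

    Pairs with an undefined correlation (constant column after complete-case
    filtering) are reported with NaN r/p and excluded from significance
    flagging.  The Bonferroni threshold is ``alpha / n_comparisons``
    (0.05 / 171 ~= 2.92e-4 under the defaults).
    """
    threshold = alpha / n_comparisons
    rows = []
    for feat in features.columns:
        for targ in targets.columns:
            r, p, n = spearman_with_p(features[feat], targets[targ])
            if np.isnan(r):
                logger.info("undefined correlation for %s vs %s (constant "
                            "column); excluded from flag count", feat, targ)
            rows.append(AssociationResult(
                feature=feat, target=targ, spearman_r=r, p_value=p, n=n,
                significant=bool(np.isfinite(p) and p < threshold),
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def group_difference_tests(
    labels: pd.Series, variables: pd.DataFrame,
    categorical: list[str] | None = None,
) -> pd.DataFrame:
    """Kruskal-Wallis (continuous) or Fisher's exact (categorical) tests of
    each variable across shape-class groups."""
    labels = pd.Series(labels)
    groups = labels.dropna().unique()
    if len(groups) < 2:
        raise ValueError("need at least 2 non-empty groups")
    categorical = set(categorical or [])
    rows = []
    for col in variables.columns:
        v = variables[col]
        is_cat = col in categorical or not pd.api.types.is_numeric_dtype(v)
        if is_cat:
            table = pd.crosstab(labels, v)
            stat, p = fisher_exact_table(table.to_numpy())
            test = "fisher_exact"
            n = int(table.to_numpy().sum())
        else:
            samples = [v[(labels == g) & v.notna()].to_numpy()
                       for g in groups]
            samples = [s for s in samples if len(s) > 0]
            if len(samples) < 2:
                raise ValueError(f"variable {col!r}: fewer than 2 groups "
                                 "with data")
            stat, p = stats.kruskal(*samples)
            test = "kruskal_wallis"
            n = int(sum(len(s) for s in samples))
        rows.append({"variable": col, "test": test, "statistic": float(stat),
                     "p_value": float(p), "n": n})
    return pd.DataFrame(rows)


def fisher_exact_table(table: np.ndarray, n_resamples: int = 20_000,
                       seed: int = 0) -> tuple[float, float]:
    """Fisher's exact test; 2x2 exactly, larger tables by a seeded
    Monte-Carlo permutation of the contingency margins."""
    table = np.asarray(table)
    if table.shape == (2, 2):
        res = stats.fisher_exact(table)
        return float(res.statistic), float(res.pvalue)
    # Monte-Carlo version for r x c: permute category labels
    rows = np.repeat(np.arange(table.shape[0]), table.sum(axis=1))
    cols = np.repeat(np.arange(table.shape[1]), table.sum(axis=0))
    obs = _table_logprob(table)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_resamples):
        perm = rng.permutation(cols)
        t = _crosstab_counts(rows, perm, table.shape)
        if _table_logprob(t) <= obs + 1e-12:
            count += 1
    return np.nan, (count + 1) / (n_resamples + 1)


def _crosstab_counts(rows, cols, shape):
    t = np.zeros(shape, dtype=int)
    np.add.at(t, (rows, cols), 1)
    return t


def _table_logprob(table: np.ndarray) -> float:
    from scipy.special import gammaln
    t = np.asarray(table, float)
    return float(
        gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1) - gammaln(t + 1).sum()
    )


@dataclass(frozen=True)
class AdjustedModelResult:
    outcome: str
    exposure: str
    coefficient: float
    std_err: float
    p_value: float
    n: int


def adjusted_fpc_models(
    scores: pd.DataFrame,
    exposures: pd.DataFrame,
    covariates: pd.DataFrame,
) -> pd.DataFrame:
    """OLS of each FPC score on each exposure, adjusted for demographics.

    ``covariates`` must contain ``age``, ``sex``, ``race``, ``ethnicity``;
    the categorical ones are reference-coded.  Complete cases per model.
    Rank-deficient designs raise with the aliased column names.
    """
    cov = pd.get_dummies(covariates, columns=[c for c in covariates.columns
                                              if covariates[c].dtype == object],
                         drop_first=True, dtype=float)
    rows = []
    for fpc in scores.columns:
        for exp_name in exposures.columns:
            df = pd.concat(
                [scores[fpc].rename("_y"), exposures[exp_name].rename("_x"),
                 cov], axis=1,
            ).dropna()
            X = sm.add_constant(df.drop(columns="_y"), has_constant="add")
            rank = np.linalg.matrix_rank(X.to_numpy())
            if rank < X.shape[1]:
                aliased = _aliased_columns(X)
                raise ValueError(
                    f"rank-deficient design for {fpc} ~ {exp_name}: "
                    f"aliased column(s) {aliased}"
                )
            fit = sm.OLS(df["_y"], X).fit()
            rows.append(AdjustedModelResult(
                outcome=fpc, exposure=exp_name,
                coefficient=float(fit.params["_x"]),
                std_err=float(fit.bse["_x"]),
                p_value=float(fit.pvalues["_x"]),
                n=int(fit.nobs),
            ))
    return pd.DataFrame([r.__dict__ for r in rows])


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    cols = list(X.columns)
    aliased = []
    kept: list[str] = []
    for c in cols:
        trial = X[kept + [c]].to_numpy()
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            aliased.append(c)
        else:
            kept.append(c)
    return aliased
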