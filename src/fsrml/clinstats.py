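"""Univariate and multivariable statistics for cohort feature validation.

Binary predictors are compared between nodule-negative and -positive groups
with Pearson's chi-square (no continuity correction); normally-distributed
continuous predictors with the pooled-variance two-sample t test, computable
from printed (mean, sd, n) summaries alone.  Multivariable validation is a
forward-stepwise logistic regression with backward removal, reporting beta,
SE, Wald = (beta/SE)^2, p, EXP(B) and the log-symmetric 95% CI
exp(beta +/- 1.96 SE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ContingencyTable",
    "GroupSummary",
    "chi_square",
    "pooled_t",
    "univariate_screen",
    "stepwise_logistic",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: rows = feature yes/no, columns = nodule negative/positive."""

    counts: tuple  # ((a, b), (c, d))

    def __post_init__(self):
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or np.any(arr < 0):
            raise ValueError("counts must be a 2x2 array of non-negative integers")
        if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
            raise ValueError("all row and column sums must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class GroupSummary:
    """(mean, sd, n) per group for a continuous feature."""

    mean_neg: float
    sd_neg: float
    n_neg: int
    mean_pos: float
    sd_pos: float
    n_pos: int
    units: str = ""

    def __post_init__(self):
        if self.sd_neg <= 0 or self.sd_pos <= 0:
            raise ValueError("standard deviations must be positive")
        if self.n_neg < 2 or self.n_pos < 2:
            raise ValueError("each group needs n >= 2")


def chi_square(table: ContingencyTable, correction: bool = False):
    """Pearson chi-square (1 df) on a 2x2 table; Yates correction optional."""
    stat, p, _, _ = stats.chi2_contingency(table.array, correction=correction)
    return float(stat), float(p)


def pooled_t(summary: GroupSummary):
    """Pooled-variance two-sample t from summary statistics.

    The statistic is reported as a positive magnitude with a two-sided p on
    n1 + n2 - 2 degrees of freedom.
    """
    res = stats.ttest_ind_from_stats(
        summary.mean_neg, summary.sd_neg, summary.n_neg,
        summary.mean_pos, summary.sd_pos, summary.n_pos,
        equal_var=True,
    )
    return float(abs(res.statistic)), float(res.pvalue)


def _binary_table(x: np.ndarray, y: np.ndarray) -> ContingencyTable:
    a = int(np.sum((x == 1) & (y == 0)))  # yes, negative
    b = int(np.sum((x == 1) & (y == 1)))  # yes, positive
    c = int(np.sum((x == 0) & (y == 0)))
    d = int(np.sum((x == 0) & (y == 1)))
    return ContingencyTable(((a, b), (c, d)))


def univariate_screen(cohort, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature two-group tests in the cohort's declared schema.

    Binary columns get the chi-square test with a (yes/no) x (neg/pos)
    table; continuous columns get the pooled t test on raw data.  Constant
    or single-class-degenerate columns are skipped with a note.
    """
    y = np.asarray(cohort.y, dtype=int)
    rows = []
    for name in cohort.feature_names:
        kind = cohort.schema[name]["kind"]
        x = cohort.X[name].to_numpy()
        row = {"feature": name, "kind": kind, "test": None,
               "statistic": np.nan, "p": np.nan, "significant": False,
               "note": ""}
        if np.all(x == x[0]):
            row["note"] = "skipped: constant column"
            rows.append(row)
            continue
        if kind == "binary":
            table = _binary_table(x.astype(int), y)
            try:
                stat, p = chi_square(table)
            except ValueError as exc:
                row["note"] = f"skipped: {exc}"
                rows.append(row)
                continue
            row.update(test="chi_square", statistic=stat, p=p)
            row.update(
                rate_neg=float(np.mean(x[y == 0])),
                rate_pos=float(np.mean(x[y == 1])),
            )
        else:
            g0, g1 = x[y == 0].astype(float), x[y == 1].astype(float)
            summ = GroupSummary(
                mean_neg=float(np.mean(g0)), sd_neg=float(np.std(g0, ddof=1)),
                n_neg=len(g0),
                mean_pos=float(np.mean(g1)), sd_pos=float(np.std(g1, ddof=1)),
                n_pos=len(g1),
            )
            stat, p = pooled_t(summ)
            row.update(test="pooled_t", statistic=stat, p=p,
                       mean_neg=summ.mean_neg, sd_neg=summ.sd_neg,
                       mean_pos=summ.mean_pos, sd_pos=summ.sd_pos)
        row["significant"] = bool(row["p"] < alpha)
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    """Maximum-likelihood logistic fit (IRLS via Newton), quietly."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
        return model.fit(disp=0, maxiter=100)


def stepwise_logistic(cohort, candidate_features=None,
                      enter_p: float = 0.05, remove_p: float = 0.10,
                      design: pd.DataFrame | None = None) -> pd.DataFrame:
    """Forward-stepwise logistic regression with backward removal.

    At each forward step the candidate with the smallest likelihood-ratio p
    enters if below ``enter_p``; after every entry, terms whose Wald p
    exceeds ``remove_p`` are removed (largest first).  Returns one row per
    retained feature: beta, se, wald, p, odds_ratio and the log-symmetric
    95% CI.  Coefficients with |beta| > 15 trigger a separation warning.

    ``design`` overrides the raw predictor matrix (e.g. a standardized
    design for comparison against generating coefficients).
    """
    y = np.asarray(cohort.y, dtype=int)
    X = (design if design is not None else cohort.X).astype(float)
    candidates = list(candidate_features or cohort.feature_names)
    missing = [c for c in candidates if c not in X.columns]
    if missing:
        raise ValueError(f"candidate features not in cohort: {missing}")
    # constant columns can never enter
    candidates = [c for c in candidates if X[c].nunique() > 1]

    selected: list[str] = []
    while True:
        changed = False
        # ---- forward: best LRT p among remaining candidates
        remaining = [c for c in candidates if c not in selected]
        if remaining:
            base_fit = _fit_logit(y, X[selected])
            best_c, best_p = None, np.inf
            for c in remaining:
                try:
                    fit = _fit_logit(y, X[selected + [c]])
                except Exception:
                    continue
                lr = 2.0 * (fit.llf - base_fit.llf)
                p = float(stats.chi2.sf(max(lr, 0.0), df=1))
                if p < best_p:
                    best_c, best_p = c, p
            if best_c is not None and best_p < enter_p:
                selected.append(best_c)
                changed = True
        # ---- backward: drop worst Wald p above remove_p
        if selected:
            fit = _fit_logit(y, X[selected])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) > remove_p:
                selected.remove(worst)
                changed = True
        if not changed:
            break

    rows = []
    if selected:
        fit = _fit_logit(y, X[selected])
        for name in selected:
            beta = float(fit.params[name])
            se = float(fit.bse[name])
            if abs(beta) > 15:
                warnings.warn(
                    f"possible separation: |beta| for {name} exceeds 15",
                    RuntimeWarning,
                )
            rows.append({
                "feature": name,
                "beta": beta,
                "se": se,
                "wald": (beta / se) ** 2 if se > 0 else np.inf,
                "p": float(fit.pvalues[name]),
                "odds_ratio": float(np.exp(beta)),
                "ci_low": float(np.exp(beta - 1.96 * se)),
                "ci_high": float(np.exp(beta + 1.96 * se)),
            })
    return pd.DataFrame(
        rows, columns=["feature", "beta", "se", "wald", "p",
                       "odds_ratio", "ci_low", "ci_high"],
    )
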