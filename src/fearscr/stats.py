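"""Inferential layer: group-by-time interaction with covariates, paired
contrasts, baseline comparisons, (partial) correlations and
practice-hour regressions.

With exactly two occasions, the group-by-time interaction of a repeated
measures ANCOVA is algebraically the between-group effect in a linear
model of the change score (post - pre) on group plus the
between-subject covariates; :class:`ChangeScoreAncova` implements it
that way, which keeps every sum of squares auditable. Covariates are
mean-centered before entry (this does not change the F). The F carries
(1, n - k) degrees of freedom where k counts the model columns, and the
effect size is partial eta-squared, SS_effect / (SS_effect + SS_error).

No multiplicity correction is applied anywhere; every summary and
report states this caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .errors import AnalysisError, DegenerateDataError

__all__ = [
    "TestResult",
    "ChangeScoreAncova",
    "ChangeScoreAncovaResults",
    "group_by_time_interaction",
    "paired_t",
    "baseline_difference",
    "correlation",
    "practice_regression",
    "practice_hours_total",
    "MULTIPLICITY_CAVEAT",
]

MULTIPLICITY_CAVEAT = "p-values are not corrected for multiple comparisons"


@dataclass(frozen=True)
class TestResult:
    """One test statistic with its df, two-sided p and effect size."""

    statistic: float
    family: str  # "F", "t", "r" or "beta"
    df: tuple[float, ...]
    pvalue: float
    effect_size: float | None = None  # partial eta^2 for F tests
    n: int = 0
    description: str = ""

    def __str__(self) -> str:
        df_txt = ",".join(f"{d:g}" for d in self.df)
        txt = f"{self.family}({df_txt}) = {self.statistic:.4g}, p = {self.pvalue:.4g}"
        if self.effect_size is not None:
            txt += f", partial eta^2 = {self.effect_size:.3f}"
        return txt


def _as_2d(covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame()
    return pd.DataFrame(covariates).astype(float)


class ChangeScoreAncova:
    """Group-by-time interaction model for a two-occasion design.

    Parameters
    ----------
    change
        Per-subject change scores (post minus pre) of the endpoint.
    group
        Group label per subject; exactly two levels.
    covariates
        Optional between-subject covariates (columns), centered
        internally.

    Use :meth:`from_records` to build the model from a long-format
    subject-visit table.
    """

    def __init__(self, change: Sequence[float], group: Sequence,
                 covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None):
        self.change = np.asarray(change, dtype=float)
        self.group = np.asarray(group)
        self.covariates = _as_2d(covariates)
        if self.change.size != self.group.size:
            raise AnalysisError("change and group must have equal length")
        levels = pd.unique(self.group)
        if len(levels) != 2:
            raise AnalysisError(f"exactly two groups required, got {list(levels)}")
        self.levels = tuple(levels)
        counts = pd.Series(self.group).value_counts()
        if counts.min() < 2:
            raise AnalysisError("each group needs at least 2 subjects")

    @classmethod
    def from_records(cls, records: pd.DataFrame, endpoint: str,
                     group_col: str = "group", subject_col: str = "subject_id",
                     visit_col: str = "visit", visits: tuple[str, str] = ("pre", "post"),
                     covariates: Sequence[str] = ()) -> "ChangeScoreAncova":
        """Build from long-format records (one row per subject-visit).

        Subjects lacking either visit or any required value are dropped
        with a warning; covariates are taken from the pre-visit row.
        """
        pre_v, post_v = visits
        cols = [subject_col, group_col, endpoint, *covariates]
        pre = records[records[visit_col] == pre_v].set_index(subject_col)
        post = records[records[visit_col] == post_v].set_index(subject_col)
        common = pre.index.intersection(post.index)
        dropped = sorted(set(records[subject_col]) - set(common))
        wide = pd.DataFrame({
            "change": post.loc[common, endpoint].astype(float)
                      - pre.loc[common, endpoint].astype(float),
            "group": pre.loc[common, group_col],
        })
        for c in covariates:
            wide[c] = pre.loc[common, c].astype(float)
        complete = wide.dropna()
        dropped += sorted(set(common) - set(complete.index))
        if dropped:
            warnings.warn(f"dropping unpaired/incomplete subjects: {dropped}")
        return cls(complete["change"].to_numpy(), complete["group"].to_numpy(),
                   complete[list(covariates)] if covariates else None)

    def _design(self) -> tuple[np.ndarray, list[str]]:
        n = self.change.size
        g = (self.group == self.levels[1]).astype(float)
        cols = [np.ones(n), g]
        names = ["const", f"group[{self.levels[1]}]"]
        for c in self.covariates.columns:
            x = self.covariates[c].to_numpy(dtype=float)
            cols.append(x - x.mean())
            names.append(c)
        return np.column_stack(cols), names

    def fit(self) -> "ChangeScoreAncovaResults":
        X, names = self._design()
        n, k = X.shape
        if n - k < 1:
            raise AnalysisError(f"insufficient residual df: n={n}, model columns={k}")
        if np.linalg.matrix_rank(X) < k:
            raise AnalysisError("rank-deficient design (covariate collinear with group?)")
        ols = sm.OLS(self.change, X).fit()
        reduced = np.delete(X, 1, axis=1)  # drop the group column
        ols0 = sm.OLS(self.change, reduced).fit()
        ss_effect = float(ols0.ssr - ols.ssr)
        ss_error = float(ols.ssr)
        df_err = n - k
        if ss_error <= 0:
            raise DegenerateDataError("zero residual variance in change scores")
        f = (ss_effect / 1.0) / (ss_error / df_err)
        p = float(scipy.stats.f.sf(f, 1, df_err))
        eta = ss_effect / (ss_effect + ss_error)
        return ChangeScoreAncovaResults(
            model=self, ols_results=ols, param_names=names,
            f_statistic=float(f), df=(1.0, float(df_err)), pvalue=p,
            partial_eta_sq=float(eta), n=n,
        )


@dataclass
class ChangeScoreAncovaResults:
    """Fitted group-by-time interaction: F, df, p, partial eta^2.

    ``ols_results`` exposes the underlying statsmodels OLS fit of the
    change scores (coefficients, standard errors, residuals).
    """

    model: ChangeScoreAncova
    ols_results: object
    param_names: list[str]
    f_statistic: float
    df: tuple[float, float]
    pvalue: float
    partial_eta_sq: float
    n: int

    def as_test_result(self, description: str = "group x time interaction") -> TestResult:
        return TestResult(self.f_statistic, "F", self.df, self.pvalue,
                          self.partial_eta_sq, self.n, description)

    def group_change_means(self) -> dict:
        m = self.model
        return {lv: float(m.change[m.group == lv].mean()) for lv in m.levels}

    def summary(self) -> str:
        lines = [
            "Group x time interaction (change-score ANCOVA)",
            "=" * 54,
            f"n subjects (paired)     : {self.n}",
            f"groups                  : {self.model.levels[0]} vs {self.model.levels[1]}",
            f"covariates (centered)   : {list(self.model.covariates.columns) or 'none'}",
            f"F({self.df[0]:g}, {self.df[1]:g})                : {self.f_statistic:.4f}",
            f"p (two-sided)           : {self.pvalue:.4f}",
            f"partial eta^2           : {self.partial_eta_sq:.4f}",
        ]
        for lv, mu in self.group_change_means().items():
            lines.append(f"mean change [{lv:<8}]   : {mu:+.4f}")
        lines += [
            "-" * 54,
            "Interaction computed as the group effect on post-pre change",
            "scores, algebraically identical to the two-occasion repeated",
            "measures ANCOVA interaction. " + MULTIPLICITY_CAVEAT + ".",
        ]
        return "\n".join(lines)

    def plot(self, pre: Sequence[float] | None = None, post: Sequence[float] | None = None,
             ax=None):
        """Bar plot of mean change per group (simple pre/post summary)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        means = self.group_change_means()
        ax.bar(list(map(str, means)), list(means.values()))
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_ylabel("mean change (post - pre)")
        ax.set_title(f"F({self.df[0]:g},{self.df[1]:g}) = {self.f_statistic:.3g}, "
                     f"p = {self.pvalue:.3g}")
        return ax


def group_by_time_interaction(records: pd.DataFrame, endpoint: str,
                              covariates: Sequence[str] = (),
                              group_col: str = "group", subject_col: str = "subject_id",
                              visit_col: str = "visit") -> TestResult:
    """Group-by-time interaction F for a two-occasion endpoint."""
    model = ChangeScoreAncova.from_records(
        records, endpoint, group_col=group_col, subject_col=subject_col,
        visit_col=visit_col, covariates=covariates,
    )
    return model.fit().as_test_result(f"group x time interaction on {endpoint}")


def paired_t(pre: Sequence[float], post: Sequence[float],
             description: str = "paired t") -> TestResult:
    """Classical paired t-test on post - pre, two-sided."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size:
        raise AnalysisError("pre and post must have equal length")
    if pre.size < 2:
        raise AnalysisError("paired t needs at least 2 complete pairs")
    diff = post - pre
    if np.allclose(diff.std(ddof=1), 0.0):
        raise DegenerateDataError("zero variance of paired differences")
    t, p = scipy.stats.ttest_rel(post, pre)
    return TestResult(float(t), "t", (float(pre.size - 1),), float(p),
                      n=int(pre.size), description=description)


def baseline_difference(records_pre: pd.DataFrame, endpoint: str,
                        covariates: Sequence[str] = (),
                        group_col: str = "group") -> TestResult:
    """One-way ANCOVA F for group on a pre-visit endpoint."""
    data = records_pre.dropna(subset=[endpoint, group_col, *covariates])
    y = data[endpoint].to_numpy(dtype=float)
    group = data[group_col].to_numpy()
    levels = pd.unique(group)
    if len(levels) != 2:
        raise AnalysisError(f"exactly two groups required, got {list(levels)}")
    if min((group == lv).sum() for lv in levels) < 2:
        raise AnalysisError("each group needs at least 2 subjects")
    n = y.size
    g = (group == levels[1]).astype(float)
    cols = [np.ones(n), g] + [
        data[c].to_numpy(dtype=float) - data[c].to_numpy(dtype=float).mean()
        for c in covariates
    ]
    X = np.column_stack(cols)
    k = X.shape[1]
    if np.linalg.matrix_rank(X) < k:
        raise AnalysisError("rank-deficient design (covariate collinear with group?)")
    if n - k < 1:
        raise AnalysisError(f"insufficient residual df: n={n}, model columns={k}")
    full = sm.OLS(y, X).fit()
    red = sm.OLS(y, np.delete(X, 1, axis=1)).fit()
    ss_effect = float(red.ssr - full.ssr)
    ss_error = float(full.ssr)
    if ss_error <= 0:
        raise DegenerateDataError("zero residual variance at baseline")
    df_err = n - k
    f = ss_effect / (ss_error / df_err)
    p = float(scipy.stats.f.sf(f, 1, df_err))
    return TestResult(float(f), "F", (1.0, float(df_err)), p,
                      effect_size=ss_effect / (ss_effect + ss_error), n=n,
                      description=f"baseline group difference on {endpoint}")


def correlation(x: Sequence[float], y: Sequence[float],
                partial_covariates: Mapping[str, Sequence[float]] | pd.DataFrame | None = None,
                description: str = "correlation") -> TestResult:
    """Pearson correlation, optionally partial.

    Partial correlation controls for covariates by correlating the
    residuals of x and y after least-squares projection on the
    covariates (plus intercept); the t transform uses n - 2 - k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AnalysisError("x and y must have equal length")
    cov = _as_2d(partial_covariates)
    k = cov.shape[1]
    if x.size < k + 3:
        raise AnalysisError(f"need at least {k + 3} pairs for {k} covariates, got {x.size}")
    if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
        raise DegenerateDataError("zero variance in x or y")
    if k:
        Z = np.column_stack([np.ones(x.size)] + [cov[c].to_numpy(dtype=float) for c in cov])
        x = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
        y = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        if np.allclose(x.std(), 0) or np.allclose(y.std(), 0):
            raise DegenerateDataError("zero residual variance after partialling")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2 - k
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return TestResult(r, "r", (float(df),), p, n=int(x.size), description=description)


def practice_regression(post_scores: Sequence[float],
                        practice_hours: Sequence[float],
                        description: str = "practice regression") -> TestResult:
    """Simple regression of a post score on total practice hours.

    Reports the standardized slope (beta), its t with n - 2 df and the
    two-sided p.
    """
    y = np.asarray(post_scores, dtype=float)
    x = np.asarray(practice_hours, dtype=float)
    if x.size != y.size:
        raise AnalysisError("scores and hours must have equal length")
    if x.size < 3:
        raise AnalysisError("regression needs at least 3 points")
    if np.allclose(x.std(ddof=0), 0):
        raise DegenerateDataError("constant practice-hours predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    beta = slope * x.std(ddof=1) / y.std(ddof=1) if y.std(ddof=1) > 0 else 0.0
    t = float(fit.tvalues[1])
    p = float(fit.pvalues[1])
    return TestResult(beta, "beta", (float(x.size - 2),), p, n=int(x.size),
                      description=description)


def practice_hours_total(daily_logs_minutes: Sequence[float | None],
                         n_expected_logs: int | None = None) -> float:
    """Total practice hours with mean imputation of missing daily logs.

    Missing entries (None/NaN) are replaced by the individual's mean
    over the available logs; ``n_expected_logs`` pads the log list with
    missing days if longer than the supplied sequence.
    """
    logs = [np.nan if v is None else float(v) for v in daily_logs_minutes]
    if n_expected_logs is not None:
        if n_expected_logs < len(logs):
            raise AnalysisError(
                f"n_expected_logs={n_expected_logs} smaller than supplied {len(logs)} logs"
            )
        logs = logs + [np.nan] * (n_expected_logs - len(logs))
    arr = np.asarray(logs, dtype=float)
    observed = arr[~np.isnan(arr)]
    if observed.size == 0:
        raise AnalysisError("all practice logs missing; cannot impute")
    arr[np.isnan(arr)] = observed.mean()
    return float(arr.sum() / 60.0)
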