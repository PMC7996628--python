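"""Method-comparison and group-comparison statistics.

Implements the validation toolkit used to compare the video path against the
gyroscope benchmark: Pearson correlation with the conventional strength
bands, Bland–Altman limits of agreement (bias ± 1.96·SD of the paired
differences), Cohen's d with the conventional magnitude bands, and an
age/BMI-adjusted group comparison via ordinary least squares.

Sign convention for Bland–Altman: differences are method A − method B, and by
package convention A is the benchmark (sensor-based) method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ComputationError, ValidationError

#: correlation strength bands (on |r|)
R_BANDS = (
    (0.80, "very strong"),
    (0.60, "strong"),
    (0.40, "moderate"),
    (0.0, "weak"),
)

#: Cohen's d magnitude bands
D_BANDS = (
    (1.30, "very large"),
    (0.80, "large"),
    (0.50, "medium"),
    (0.20, "small"),
    (0.0, "none"),
)

LOA_FACTOR = 1.96
ALPHA = 0.05


def correlation_label(r: float) -> str:
    a = abs(r)
    for lo, label in R_BANDS:
        if a >= lo:
            return label
    return "weak"


def effect_size_label(d: float) -> str:
    a = abs(d)
    for lo, label in D_BANDS:
        if a >= lo:
            return label
    return "none"


@dataclass
class PairedMeasurements:
    """The same feature measured by two methods on the same subjects."""

    subject_ids: list[str]
    a: np.ndarray  # benchmark method
    b: np.ndarray

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.subject_ids = [str(s) for s in self.subject_ids]
        if not (len(self.subject_ids) == self.a.size == self.b.size):
            raise ValidationError("paired measurements must have equal lengths")
        if self.a.size < 3:
            raise ValidationError("need at least 3 paired measurements")
        if not (np.all(np.isfinite(self.a)) and np.all(np.isfinite(self.b))):
            raise ValidationError("paired measurements must be finite")


@dataclass
class AgreementReport:
    pearson_r: float
    pearson_p: float
    r_label: str
    bias: float  # mean(a − b)
    sd_diff: float
    loa_lower: float
    loa_upper: float
    mean_points: np.ndarray  # (a+b)/2, for plotting
    diff_points: np.ndarray  # a−b


@dataclass
class GroupComparison:
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    adjusted_p: float
    significant: bool  # at alpha = 0.05
    cohens_d: float  # from raw group statistics
    d_label: str
    adjusted_d: float  # group coefficient / residual sd of the adjusted model
    group_coefficient: float


def pearson(pairs: PairedMeasurements) -> tuple[float, float, str]:
    """Sample Pearson r, two-sided p (t transform, n−2 df) and strength label."""
    if np.std(pairs.a) == 0 or np.std(pairs.b) == 0:
        raise ComputationError("correlation undefined: one series has zero variance")
    res = stats.pearsonr(pairs.a, pairs.b)
    r, p = float(res.statistic), float(res.pvalue)
    return r, p, correlation_label(r)


def bland_altman(pairs: PairedMeasurements) -> AgreementReport:
    """Bland–Altman agreement: bias, SD of differences and ±1.96·SD limits."""
    d = pairs.a - pairs.b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r, p, label = pearson(pairs)
    except ComputationError:
        r, p, label = float("nan"), float("nan"), "undefined"
    return AgreementReport(
        pearson_r=r,
        pearson_p=p,
        r_label=label,
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - LOA_FACTOR * sd,
        loa_upper=bias + LOA_FACTOR * sd,
        mean_points=0.5 * (pairs.a + pairs.b),
        diff_points=d,
    )


def cohens_d(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, str]:
    """|standardised mean difference| with pooled (n−2) SD, plus magnitude label."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 values")
    pooled_var = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / (
        a.size + b.size - 2
    )
    if pooled_var == 0:
        d = 0.0 if a.mean() == b.mean() else None
        if d is None:
            raise ComputationError("zero pooled SD with unequal means")
    else:
        d = float(abs(a.mean() - b.mean()) / np.sqrt(pooled_var))
    return d, effect_size_label(d)


def adjusted_compare(
    outcome: np.ndarray,
    group: np.ndarray,
    age: np.ndarray,
    bmi: np.ndarray,
) -> GroupComparison:
    """Compare an outcome between two groups, adjusting for age and BMI.

    Ordinary least squares of the outcome on intercept + group indicator +
    age + BMI; the reported p-value is the two-sided t-test on the group
    coefficient.  Cohen's d is computed from the raw (unadjusted) group
    values; an adjusted variant (group coefficient over residual SD) is also
    reported, clearly distinguished.
    """
    y = np.asarray(outcome, dtype=float)
    g = np.asarray(group)
    levels = np.unique(g)
    if levels.size != 2:
        raise ValidationError(f"group must be binary; got levels {levels}")
    gi = (g == levels[1]).astype(float)
    X = pd.DataFrame(
        {
            "group": gi,
            "age": np.asarray(age, dtype=float),
            "bmi": np.asarray(bmi, dtype=float),
        }
    )
    # a constant covariate carries no information and is absorbed by the intercept
    for cov in ("age", "bmi"):
        if X[cov].std() == 0:
            X = X.drop(columns=cov)
    Xd = sm.add_constant(X, has_constant="add")
    if y.size < Xd.shape[1] + 1:
        raise ValidationError(f"need at least {Xd.shape[1] + 1} subjects")
    if np.linalg.matrix_rank(Xd.to_numpy()) < Xd.shape[1]:
        collinear = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(Xd.drop(columns=c).to_numpy())
            == np.linalg.matrix_rank(Xd.to_numpy())
        ]
        raise ValidationError(f"design matrix rank-deficient; collinear columns: {collinear}")
    fit = sm.OLS(y, Xd).fit()
    a, b = y[gi == 0], y[gi == 1]
    d_raw, label = cohens_d(a, b)
    p = float(fit.pvalues["group"])
    coef = float(fit.params["group"])
    resid_sd = float(np.sqrt(fit.scale))
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
        adjusted_p=p,
        significant=p < ALPHA,
        cohens_d=d_raw,
        d_label=label,
        adjusted_d=float(abs(coef) / resid_sd) if resid_sd > 0 else float("nan"),
        group_coefficient=coef,
    )


def compare_feature_tables(df_a: pd.DataFrame, df_b: pd.DataFrame) -> pd.DataFrame:
    """Per-feature agreement between two feature tables (A = benchmark).

    Both tables must be indexed by the same subject ids.  Returns one row per
    shared feature column: n, Pearson r (+label, p), bias, SD of differences
    and the limits of agreement.
    """
    if set(df_a.index) != set(df_b.index):
        only_a = sorted(set(df_a.index) - set(df_b.index))
        only_b = sorted(set(df_b.index) - set(df_a.index))
        raise ValidationError(
            f"subject ids do not match (only in A: {only_a}; only in B: {only_b})"
        )
    df_b = df_b.loc[df_a.index]
    rows = []
    for col in [c for c in df_a.columns if c in df_b.columns]:
        a = pd.to_numeric(df_a[col], errors="coerce")
        b = pd.to_numeric(df_b[col], errors="coerce")
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            continue
        pairs = PairedMeasurements(
            subject_ids=list(df_a.index[ok]), a=a[ok].to_numpy(), b=b[ok].to_numpy()
        )
        rep = bland_altman(pairs)
        rows.append(
            {
                "feature": col,
                "n": int(ok.sum()),
                "pearson_r": rep.pearson_r,
                "r_label": rep.r_label,
                "pearson_p": rep.pearson_p,
                "bias": rep.bias,
                "sd_diff": rep.sd_diff,
                "loa_lower": rep.loa_lower,
                "loa_upper": rep.loa_upper,
            }
        )
    columns = [
        "feature", "n", "pearson_r", "r_label", "pearson_p",
        "bias", "sd_diff", "loa_lower", "loa_upper",
    ]
    return pd.DataFrame(rows, columns=columns).set_index("feature")


def bland_altman_plot(report: AgreementReport, ax=None, title: str | None = None):
    """Mean-vs-difference plot with the bias and limits of agreement drawn."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(report.mean_points, report.diff_points, s=18)
    for y, style in ((report.bias, "-"), (report.loa_lower, "--"), (report.loa_upper, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (A − B)")
    if title:
        ax.set_title(title)
    return ax


def method_scatter_plot(pairs: PairedMeasurements, ax=None, title: str | None = None):
    """Method-A vs method-B scatter with the identity line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(pairs.b, pairs.a, s=18)
    lo = min(pairs.a.min(), pairs.b.min())
    hi = max(pairs.a.max(), pairs.b.max())
    ax.plot([lo, hi], [lo, hi], "k--", linewidth=1)
    ax.set_xlabel("method B")
    ax.set_ylabel("method A (benchmark)")
    if title:
        ax.set_title(title)
    return ax
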