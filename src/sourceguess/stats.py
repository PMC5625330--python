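"""Inference on observed vs. predicted source errors.

Covers the analysis set of the paired-recall design: one-tailed paired
comparisons with the d_av effect size, two-way mixed ANOVA, within-
subject confidence intervals (Cousineau–Morey), standardized-mean-change
effects with inverse-variance fixed-effect pooling, and one-tailed
(half-normal prior) Bayes factors following the Dienes calculator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats

__all__ = [
    "PairedTestResult",
    "BFResult",
    "SMCResult",
    "MetaResult",
    "paired_t_onetailed",
    "mixed_anova",
    "within_subject_ci",
    "dienes_bf",
    "smc_effect",
    "fixed_effect_summary",
]


@dataclass(frozen=True)
class PairedTestResult:
    n: int
    mean_diff: float
    t: float
    df: int
    p_one_tailed: float
    d_av: float
    degenerate: bool = False


@dataclass(frozen=True)
class BFResult:
    """Bayes factor for a half-normal (mode 0, one-tailed) effect prior."""

    bf10: float
    bf10_numeric: float
    log_bf10: float
    log_bf10_numeric: float
    prior_sd: float
    data_mean: float
    data_se: float
    method: str = "closed_form"


@dataclass(frozen=True)
class SMCResult:
    study_id: str
    smc: float
    var_smc: float
    n: int

    @property
    def weight(self) -> float:
        return 1.0 / self.var_smc


@dataclass(frozen=True)
class MetaResult:
    summary_effect: float
    se_summary: float
    ci95: tuple[float, float]
    per_study: tuple[SMCResult, ...]
    norm_weights: tuple[float, ...]


def paired_t_onetailed(
    observed: Sequence[float],
    predicted: Sequence[float],
    effect: str = "d_av",
) -> PairedTestResult:
    """Paired t test, one-tailed for observed > predicted.

    ``d_av`` divides the mean difference by the average of the two
    condition SDs; ``effect="d_z"`` standardizes by the SD of the
    differences instead.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d and equal length")
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = obs - pred
    mean_diff = float(np.mean(diffs))
    sd_diff = float(np.std(diffs, ddof=1))
    sd_obs = float(np.std(obs, ddof=1))
    sd_pred = float(np.std(pred, ddof=1))

    if effect == "d_av":
        denom = (sd_obs + sd_pred) / 2.0
        d = mean_diff / denom if denom > 0 else 0.0
    elif effect == "d_z":
        d = mean_diff / sd_diff if sd_diff > 0 else 0.0
    else:
        raise ValueError(f"unknown effect {effect!r}")

    if sd_diff == 0.0:
        # Constant differences: no sampling variance in the contrast.
        if mean_diff == 0.0:
            return PairedTestResult(n, 0.0, 0.0, n - 1, 0.5, 0.0, degenerate=True)
        t = math.inf if mean_diff > 0 else -math.inf
        p = 0.0 if mean_diff > 0 else 1.0
        return PairedTestResult(n, mean_diff, t, n - 1, p, d, degenerate=True)

    res = stats.ttest_rel(obs, pred, alternative="greater")
    return PairedTestResult(
        n=n,
        mean_diff=mean_diff,
        t=float(res.statistic),
        df=n - 1,
        p_one_tailed=float(res.pvalue),
        d_av=d,
    )


def mixed_anova(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant_id",
    between: str = "group",
    within: str = "condition",
) -> pd.DataFrame:
    """Two-way mixed-design ANOVA by classical sums of squares.

    One between-subjects factor (subjects nested in its levels) crossed
    with one within-subjects factor; the between effect is tested
    against subjects-within-groups and the within effect and the
    interaction against the within-error term.  Requires a complete,
    balanced within design (every subject measured once per level).
    """
    df = data[[subject, between, within, dv]].copy()
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise ValueError(
            "unbalanced within-subject cells; apply listwise deletion so every "
            "subject has exactly one value per within level"
        )
    per_subject = df.groupby(subject, observed=True)[within].nunique()
    b = df[within].nunique()
    if (per_subject != b).any():
        raise ValueError(
            "unbalanced within-subject cells; apply listwise deletion so every "
            "subject has exactly one value per within level"
        )
    a = df[between].nunique()
    if a < 2:
        raise ValueError("between factor needs at least 2 levels")

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    n_subj = df[subject].nunique()

    subj_means = df.groupby(subject, observed=True)[dv].mean()
    subj_group = df.groupby(subject, observed=True)[between].first()
    group_means = df.groupby(between, observed=True)[dv].mean()
    group_sizes = subj_group.value_counts()
    within_means = df.groupby(within, observed=True)[dv].mean()
    cell_means = df.groupby([between, within], observed=True)[dv].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_a = float(b * sum(group_sizes[g] * (group_means[g] - grand) ** 2
                         for g in group_means.index))
    ss_subj_within = ss_between_subj - ss_a
    ss_b = float(n_subj * ((within_means - grand) ** 2).sum())
    ss_cells = float(sum(group_sizes[g] * (cell_means[(g, w)] - grand) ** 2
                         for (g, w) in cell_means.index))
    ss_ab = ss_cells - ss_a - ss_b
    ss_err_within = ss_total - ss_between_subj - ss_b - ss_ab

    df_a, df_b, df_ab = a - 1, b - 1, (a - 1) * (b - 1)
    df_subj = n_subj - a
    df_err = df_subj * df_b

    ms_a, ms_subj = ss_a / df_a, ss_subj_within / df_subj
    ms_b, ms_ab, ms_err = ss_b / df_b, ss_ab / df_ab, ss_err_within / df_err

    def row(source, ss, dfn, ms, ms_e, dfd):
        f = ms / ms_e if ms_e > 0 else (0.0 if ss == 0 else math.inf)
        p = float(stats.f.sf(f, dfn, dfd)) if math.isfinite(f) else 0.0
        ss_err = ms_e * dfd
        np2 = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
        return {
            "source": source, "ss": ss, "df1": dfn, "df2": dfd,
            "ms": ms, "mse": ms_e, "F": f, "p": p, "np2": np2,
        }

    return pd.DataFrame([
        row(between, ss_a, df_a, ms_a, ms_subj, df_subj),
        row(within, ss_b, df_b, ms_b, ms_err, df_err),
        row("interaction", ss_ab, df_ab, ms_ab, ms_err, df_err),
    ])


def within_subject_ci(matrix: np.ndarray, confidence: float = 0.95) -> np.ndarray:
    """Cousineau–Morey within-subject CI half-widths per condition.

    Subject-centers the participants x conditions matrix (removing pure
    between-subject offsets), restores the grand mean, rescales by the
    Morey bias correction sqrt(C/(C-1)) and returns t-based half-widths.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a participants x conditions matrix")
    n, c = x.shape
    if c < 2:
        raise ValueError("need at least 2 conditions for a within-subject CI")
    if np.isnan(x).any():
        raise ValueError("missing cells are not allowed")
    centered = x - x.mean(axis=1, keepdims=True) + x.mean()
    morey = math.sqrt(c / (c - 1))
    sds = centered.std(axis=0, ddof=1) * morey
    tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
    return tcrit * sds / math.sqrt(n)


def dienes_bf(data_mean: float, data_se: float, prior_sd: float) -> BFResult:
    """Bayes factor BF10 for a half-normal effect prior vs. the point null.

    The data enter as a normal likelihood in the effect parameter with
    mean ``data_mean`` and SD ``data_se``; the alternative places a
    half-normal prior (mode 0, scale ``prior_sd``, positive effects
    only) on the parameter.  BF10 is the prior-marginal likelihood over
    the likelihood at zero, computed in closed form (product of normals
    with a normal-CDF truncation factor) and by adaptive quadrature.
    """
    if data_se <= 0 or prior_sd <= 0:
        raise ValueError("data_se and prior_sd must be > 0")
    m, s, sd = float(data_mean), float(data_se), float(prior_sd)

    # Everything in log space: with a tight SE and a large |mean| the null
    # likelihood underflows long before the Bayes factor is meaningless.
    var_sum = s * s + sd * sd
    post_mean = m * sd * sd / var_sum
    post_sd = math.sqrt(s * s * sd * sd / var_sum)
    log_marginal = (
        math.log(2.0)
        + stats.norm.logpdf(m, 0.0, math.sqrt(var_sum))
        + stats.norm.logcdf(post_mean / post_sd)
    )
    log_null = stats.norm.logpdf(m, 0.0, s)
    log_bf_closed = float(log_marginal - log_null)

    def log_integrand(theta: float) -> float:
        return (
            stats.norm.logpdf(m, theta, s)
            + math.log(2.0)
            + stats.norm.logpdf(theta, 0.0, sd)
        )

    shift = log_integrand(max(0.0, post_mean))  # mode of the integrand
    # the integrand is a (truncated) Gaussian bump of scale post_sd;
    # a finite upper limit keeps quad from overlooking narrow spikes
    upper = max(0.0, post_mean) + 15.0 * post_sd
    num, _ = integrate.quad(
        lambda t: math.exp(log_integrand(t) - shift), 0.0, upper, limit=200
    )
    log_bf_numeric = float(shift + math.log(num) - log_null)

    with np.errstate(over="ignore"):
        bf_closed = float(np.exp(log_bf_closed))
        bf_numeric = float(np.exp(log_bf_numeric))
    return BFResult(
        bf10=bf_closed,
        bf10_numeric=bf_numeric,
        log_bf10=log_bf_closed,
        log_bf10_numeric=log_bf_numeric,
        prior_sd=sd,
        data_mean=m,
        data_se=s,
    )


def smc_effect(
    observed: Sequence[float], predicted: Sequence[float], study_id: str
) -> SMCResult:
    """Standardized mean change for one study.

    smc = mean(observed - predicted) / sd(observed - predicted), with
    the change-score sampling variance 1/n + smc^2/(2n).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1:
        raise ValueError("observed and predicted must be 1-d and equal length")
    n = obs.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    diffs = obs - pred
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        raise ValueError("zero variance of differences; SMC undefined")
    smc = float(np.mean(diffs)) / sd
    var = 1.0 / n + smc * smc / (2.0 * n)
    return SMCResult(study_id=study_id, smc=smc, var_smc=var, n=n)


def fixed_effect_summary(studies: Sequence[SMCResult]) -> MetaResult:
    """Inverse-variance fixed-effect pooling of per-study effects."""
    if not studies:
        raise ValueError("need at least one study")
    effects = np.array([s.smc for s in studies])
    weights = np.array([s.weight for s in studies])
    total = weights.sum()
    summary = float((weights * effects).sum() / total)
    se = float(math.sqrt(1.0 / total))
    return MetaResult(
        summary_effect=summary,
        se_summary=se,
        ci95=(summary - 1.96 * se, summary + 1.96 * se),
        per_study=tuple(studies),
        norm_weights=tuple(weights / total),
    )
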