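"""Survival and association statistics downstream of classification.

Kaplan-Meier medians, the logrank test and Cox model fits delegate to
lifelines; this module adds the pieces the pipeline defines on top: BIC-based
Cox model comparison with the ΔBIC ≥ 10 advancement rule, the extreme-fifths
relative-odds diagnostic, contingency enrichment with an exact-test fallback,
the immunohistochemistry H-score and correlation utilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import ValidationError

DELTA_BIC_MEANINGFUL = 10.0  # absolute BIC reduction advancing a model


# ---------------------------------------------------------------------------
# Kaplan-Meier and logrank
# ---------------------------------------------------------------------------


def km_median(
    surv: pd.DataFrame,
    group: str | pd.Series = "group",
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Product-limit survival per group with median survival in months.

    The median is the first time at which S(t) ≤ 0.5; groups whose curve
    never drops to 0.5 report ``inf`` (median not reached).  Survival curves
    are attached under ``result.attrs['curves']``.
    """
    labels = surv[group] if isinstance(group, str) else group.reindex(surv.index)
    rows, curves = [], {}
    for name, sub in surv.groupby(labels, observed=True):
        if len(sub) == 0:
            continue
        if sub[event_col].sum() < 1:
            warnings.warn(f"group {name!r} has no events; median undefined", stacklevel=2)
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col], event_observed=sub[event_col], label=str(name))
        rows.append(
            {
                "group": name,
                "n": len(sub),
                "n_events": int(sub[event_col].sum()),
                "median_months": float(kmf.median_survival_time_),
            }
        )
        curves[name] = kmf.survival_function_
    if not rows:
        raise ValidationError("no non-empty groups")
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["curves"] = curves
    return out


def logrank(
    surv: pd.DataFrame,
    group: str | pd.Series = "group",
    time_col: str = "time_months",
    event_col: str = "event",
) -> tuple[float, float]:
    """Two-group logrank test; returns (chi-square statistic, p)."""
    labels = surv[group] if isinstance(group, str) else group.reindex(surv.index)
    levels = pd.unique(labels.dropna())
    if len(levels) != 2:
        raise ValidationError(f"logrank requires exactly 2 groups, got {len(levels)}")
    a = surv[labels == levels[0]]
    b = surv[labels == levels[1]]
    if surv[event_col].sum() < 1:
        raise ValidationError("logrank requires at least one event")
    res = logrank_test(
        a[time_col], b[time_col], event_observed_A=a[event_col], event_observed_B=b[event_col]
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox model comparison by BIC
# ---------------------------------------------------------------------------


def _null_partial_loglik(time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood of the covariate-free model (Efron ties)."""
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    n = len(time)
    ll = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = int(event[i:j].sum())
        at_risk = n - i
        for el in range(d):
            ll -= math.log(at_risk - el)
        i = j
    return ll


def _design(surv: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric design: categorical covariates dummy-coded with a dropped level."""
    parts = []
    for cov in covariates:
        col = surv[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float).to_frame(cov))
    return pd.concat(parts, axis=1)


def bic_compare(
    surv: pd.DataFrame,
    model_specs: dict[str, list[str]],
    time_col: str = "time_months",
    event_col: str = "event",
) -> pd.DataFrame:
    """Fit each candidate Cox model and rank by BIC.

    BIC = −2·loglik + k·ln(n_events), with k the number of estimated
    coefficients and the effective sample size taken as the event count
    (standard for the Cox partial likelihood).  The empty covariate set is
    the null model (k = 0).  Rows are sorted by BIC; ``delta_bic`` is the
    gap to the best model and ``meaningful`` flags the best model when its
    advantage over the runner-up reaches 10 BIC points (the advancement
    rule used for clinical stratifiers).  Non-converging fits are excluded
    with a warning.
    """
    n_events = int(surv[event_col].sum())
    if n_events < 1:
        raise ValidationError("need at least one event")
    rows = []
    for name, covs in model_specs.items():
        if len(covs) == 0:
            ll = _null_partial_loglik(
                surv[time_col].to_numpy(float), surv[event_col].to_numpy(float)
            )
            k = 0
        else:
            if n_events < len(covs):
                warnings.warn(
                    f"model {name!r}: more covariates than events; skipped",
                    stacklevel=2,
                )
                continue
            df = _design(surv, covs)
            df[time_col] = surv[time_col]
            df[event_col] = surv[event_col]
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col=time_col, event_col=event_col)
            except Exception as exc:  # lifelines raises ConvergenceError et al.
                warnings.warn(f"model {name!r} failed to fit: {exc}", stacklevel=2)
                continue
            ll = float(cph.log_likelihood_)
            k = len(cph.params_)
        rows.append(
            {
                "model": name,
                "covariates": ",".join(covs),
                "loglik": ll,
                "k": k,
                "bic": -2.0 * ll + k * math.log(n_events) if n_events > 0 else np.nan,
            }
        )
    if not rows:
        raise ValidationError("no candidate model could be fitted")
    out = pd.DataFrame(rows).set_index("model").sort_values("bic", kind="stable")
    out["delta_bic"] = out["bic"] - out["bic"].iloc[0]
    out["best"] = False
    out.iloc[0, out.columns.get_loc("best")] = True
    out["meaningful"] = False
    if len(out) > 1 and out["delta_bic"].iloc[1] >= DELTA_BIC_MEANINGFUL:
        out.iloc[0, out.columns.get_loc("meaningful")] = True
    return out


# ---------------------------------------------------------------------------
# relative odds from extreme fifths
# ---------------------------------------------------------------------------


@dataclass
class RelativeOdds:
    """Odds ratio of a binary phenotype between the extreme score fifths."""

    n_extreme: int
    p_top: float
    p_bottom: float
    odds_ratio: float
    counts: pd.DataFrame  # 2x2: fifth x phenotype
    degenerate: bool


def relative_odds(score: pd.Series, phenotype: pd.Series) -> RelativeOdds:
    """Odds ratio between the highest and lowest fifths of a score.

    Samples are sorted by score (ties broken by a stable sort on sample id);
    the top and bottom ceil(n/5) samples form the extreme groups.
    OR = [p_top/(1−p_top)] / [p_bottom/(1−p_bottom)], where p is the
    phenotype-positive proportion.  Degenerate proportions (0 or 1) yield an
    infinite/zero/NaN OR with the ``degenerate`` flag set rather than an
    exception.
    """
    phenotype = phenotype.reindex(score.index)
    if len(score) < 10:
        raise ValidationError("relative odds needs at least 10 samples")
    pos = phenotype.astype(bool)
    if pos.all() or (~pos).all():
        raise ValidationError("both phenotype levels must be present")

    df = pd.DataFrame({"score": score, "pos": pos, "_id": score.index.astype(str)})
    df = df.sort_values(["score", "_id"], kind="stable")  # ties broken by sample id
    k = math.ceil(len(df) / 5)
    bottom = df.iloc[:k]
    top = df.iloc[-k:]

    counts = pd.DataFrame(
        {
            "positive": [int(top["pos"].sum()), int(bottom["pos"].sum())],
            "negative": [int((~top["pos"]).sum()), int((~bottom["pos"]).sum())],
        },
        index=pd.Index(["top_fifth", "bottom_fifth"], name="fifth"),
    )
    a, b = counts.loc["top_fifth", "positive"], counts.loc["top_fifth", "negative"]
    c, d = counts.loc["bottom_fifth", "positive"], counts.loc["bottom_fifth", "negative"]
    p_top = a / k
    p_bottom = c / k
    degenerate = p_top in (0.0, 1.0) or p_bottom in (0.0, 1.0)
    # odds computed from the integer counts: p/(1-p) with p = a/k equals a/b
    if b == 0 or c == 0:
        oratio = math.inf if a > 0 and d > 0 else math.nan
    elif a == 0 or d == 0:
        oratio = 0.0
    else:
        oratio = (a / b) / (c / d)
    return RelativeOdds(
        n_extreme=k,
        p_top=float(p_top),
        p_bottom=float(p_bottom),
        odds_ratio=float(oratio),
        counts=counts,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# contingency enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    counts: pd.DataFrame
    test: str  # 'chi2' or 'fisher'
    statistic: float
    p: float


def enrichment_table(class_calls: pd.Series, labels: pd.Series) -> EnrichmentResult:
    """Contingency test between class calls and a categorical label.

    Chi-square without continuity correction by default; Fisher's exact test
    when the table is 2×2 and any expected count is below 5.  Empty factor
    levels are dropped with a warning.
    """
    labels = labels.reindex(class_calls.index)
    counts = pd.crosstab(class_calls, labels)
    empty_rows = counts.index[(counts.sum(axis=1) == 0)]
    empty_cols = counts.columns[(counts.sum(axis=0) == 0)]
    if len(empty_rows) or len(empty_cols):
        warnings.warn("empty factor level(s) dropped from contingency table", stacklevel=2)
        counts = counts.drop(index=empty_rows, columns=empty_cols)
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValidationError("both factors need at least 2 non-empty levels")

    chi2, p, _, expected = stats.chi2_contingency(counts.to_numpy(), correction=False)
    if counts.shape == (2, 2) and (
        (expected < 5).any() or (counts.to_numpy() < 5).any()
    ):
        odds, p = stats.fisher_exact(counts.to_numpy())
        return EnrichmentResult(counts=counts, test="fisher", statistic=float(odds), p=float(p))
    return EnrichmentResult(counts=counts, test="chi2", statistic=float(chi2), p=float(p))


# ---------------------------------------------------------------------------
# H-score and correlation
# ---------------------------------------------------------------------------


def h_score(pct_weak: float, pct_moderate: float, pct_strong: float) -> float:
    """Immunohistochemistry H-score on a 0-3 scale.

    (1·%weak + 2·%moderate + 3·%strong) / 100; percentages must be
    non-negative and sum to at most 100.
    """
    pcts = (pct_weak, pct_moderate, pct_strong)
    if any(p < 0 for p in pcts):
        raise ValidationError("staining percentages must be >= 0")
    if sum(pcts) > 100 + 1e-9:
        raise ValidationError("staining percentages sum above 100")
    return (1.0 * pct_weak + 2.0 * pct_moderate + 3.0 * pct_strong) / 100.0


def assoc(x, y, method: str = "pearson") -> tuple[float, float]:
    """Correlation coefficient and two-sided p (t approximation)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("x and y must have equal length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero-variance input; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return float(r), float(p)
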