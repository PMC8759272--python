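"""Prognostic gene detection, stage-trend classification, and risk modelling.

Prognosis: patients are split at a gene's median expression (ties to the low
group) and the two Kaplan-Meier curves compared by the log-rank test; genes
with p < 0.05 are prognostic.  Trends: Kruskal-Wallis across stages I-IV
with Dunn's post-hoc (Benjamini-Hochberg adjusted) classifies each gene as
stage-ascending, stage-descending, outset-cancer (shifted between normal and
stage I without a monotone trend), or none.  Risk: covariates are pruned by
iterated variance-inflation-factor elimination, a Cox proportional-hazards
model is fitted (Efron ties), and patients are stratified at the Q1/Q3
quartiles of their predicted relative risk exp(linear predictor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

from .synthetic import STAGES

__all__ = [
    "RiskModel",
    "TrendCall",
    "km_logrank",
    "classify_trends",
    "dunn_posthoc",
    "vif_select",
    "fit_cox",
    "quartile_strata",
    "stratify_risk",
    "strata_logrank",
    "svm_validate",
]


@dataclass
class RiskModel:
    covariates: list[str]
    coefficients: pd.Series
    hazard_ratios: pd.Series
    covariate_p: pd.Series
    lr_test_p: float
    c_index: float
    strata_thresholds: tuple[float, float]
    fitter: CoxPHFitter


@dataclass
class TrendCall:
    gene: str
    trend: str  # ascending / descending / outset-cancer / none
    kw_p: float
    posthoc_p: pd.Series
    outset_t_p: float
    shapiro_p: pd.Series
    stage_medians: pd.Series


def km_logrank(expr_gene: pd.Series, surv: pd.DataFrame) -> dict:
    """Median-split log-rank comparison of survival between Low and High expressors.

    Values equal to the median go to the Low group.  Returns the p-value, the
    test statistic, fitted KM curves, and the group labels.
    """
    common = expr_gene.index.intersection(surv.index)
    x = expr_gene[common]
    s = surv.loc[common]
    med = x.median()
    low = x <= med
    if low.sum() < 2 or (~low).sum() < 2:
        raise ValueError("median split leaves fewer than 2 patients in a group")
    res = logrank_test(
        s.loc[low, "time"], s.loc[~low, "time"],
        event_observed_A=s.loc[low, "event"], event_observed_B=s.loc[~low, "event"],
    )
    curves = {}
    for name, mask in (("Low", low), ("High", ~low)):
        km = KaplanMeierFitter()
        km.fit(s.loc[mask, "time"], s.loc[mask, "event"], label=name)
        curves[name] = km
    groups = pd.Series(np.where(low, "Low", "High"), index=common)
    return {
        "p": float(res.p_value),
        "statistic": float(res.test_statistic),
        "groups": groups,
        "curves": curves,
        "prognostic": bool(res.p_value < 0.05),
    }


def dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.Series:
    """Dunn's pairwise rank test after Kruskal-Wallis, two-sided normal p-values.

    Uses the tie-corrected pooled rank variance; returns raw p per pair
    (adjustment is the caller's concern).
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = values.size
    ranks = stats.rankdata(values)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start : start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    out = {}
    for i, gi in enumerate(names):
        for gj in names[i + 1 :]:
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se if se > 0 else 0.0
            out[f"{gi}|{gj}"] = 2.0 * stats.norm.sf(abs(z))
    return pd.Series(out)


def classify_trends(expr_gene: pd.Series, design: pd.DataFrame) -> TrendCall:
    """Classify a gene's expression trajectory across conditions.

    ascending / descending require Kruskal-Wallis p < 0.05 across stages
    I-IV, monotone stage medians, and at least one BH-adjusted Dunn pairwise
    p < 0.05; outset-cancer requires a normal-vs-stage-I t-test p < 0.05
    without a monotone stage trend.
    """
    cond = design["condition"]
    groups = {}
    for c in ("normal",) + STAGES:
        vals = expr_gene[cond.index[cond == c].intersection(expr_gene.index)].to_numpy(float)
        if vals.size < 3:
            raise ValueError(f"condition {c!r} has fewer than 3 samples")
        groups[c] = vals

    shapiro = pd.Series(
        {c: stats.shapiro(v).pvalue if len(v) >= 3 else np.nan for c, v in groups.items()}
    )
    stage_groups = {s: groups[s] for s in STAGES}
    kw_p = float(stats.kruskal(*stage_groups.values()).pvalue)
    raw = dunn_posthoc(stage_groups)
    adj = pd.Series(
        multipletests(raw.to_numpy(), method="fdr_bh")[1], index=raw.index
    )
    medians = pd.Series({s: float(np.median(v)) for s, v in stage_groups.items()})
    diffs = np.diff(medians.to_numpy())
    ascending = bool(np.all(diffs >= 0) and np.any(diffs > 0))
    descending = bool(np.all(diffs <= 0) and np.any(diffs < 0))
    any_pair = bool((adj < 0.05).any())
    t_p = float(stats.ttest_ind(groups["normal"], groups["I"]).pvalue)

    if kw_p < 0.05 and ascending and any_pair:
        trend = "ascending"
    elif kw_p < 0.05 and descending and any_pair:
        trend = "descending"
    elif t_p < 0.05:
        trend = "outset-cancer"
    else:
        trend = "none"
    return TrendCall(
        gene=str(expr_gene.name),
        trend=trend,
        kw_p=kw_p,
        posthoc_p=adj,
        outset_t_p=t_p,
        shapiro_p=shapiro,
        stage_medians=medians,
    )


def _vif(x: np.ndarray, j: int) -> float:
    """VIF of column j regressed (with intercept) on the remaining columns."""
    y = x[:, j]
    others = np.delete(x, j, axis=1)
    design = np.column_stack([np.ones(x.shape[0]), others])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - resid @ resid / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return float(1.0 / (1.0 - r2))


def vif_select(covariates: pd.DataFrame, threshold: float = 10.0) -> list[str]:
    """Iteratively drop the highest-VIF covariate until all VIFs are below threshold.

    ``covariates`` is samples x genes.  Perfect collinearity gives infinite
    VIF and is eliminated first.  Column order of survivors is preserved.
    """
    cols = list(covariates.columns)
    if len(cols) < 2:
        return cols
    if covariates.shape[0] <= len(cols):
        raise ValueError("need more samples than covariates for VIF selection")
    while len(cols) > 1:
        x = covariates[cols].to_numpy(float)
        vifs = np.array([_vif(x, j) for j in range(len(cols))])
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        cols.pop(worst)
    return cols


def fit_cox(
    selected: list[str], expr: pd.DataFrame, surv: pd.DataFrame
) -> RiskModel:
    """Cox proportional-hazards fit (Efron ties) over the selected genes.

    ``expr`` is genes x samples; ``surv`` carries ``time`` and ``event``.
    Reports per-covariate hazard ratios and p-values, the global
    likelihood-ratio p, Harrell's c-index on the fitting cohort, and the
    Q1/Q3 risk-score thresholds used for stratification.
    """
    if not selected:
        raise ValueError("no covariates selected")
    common = expr.columns.intersection(surv.index)
    df = expr.loc[selected, common].T.copy()
    df["time"] = surv.loc[common, "time"].astype(float)
    df["event"] = surv.loc[common, "event"].astype(int)
    if df["event"].sum() < 1:
        raise ValueError("no observed events")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    risk = np.exp(cph.predict_log_partial_hazard(df[selected]))
    q1, q3 = np.percentile(risk, [25, 75])
    return RiskModel(
        covariates=list(selected),
        coefficients=cph.params_.copy(),
        hazard_ratios=np.exp(cph.params_),
        covariate_p=cph.summary["p"].copy(),
        lr_test_p=float(cph.log_likelihood_ratio_test().p_value),
        c_index=float(cph.concordance_index_),
        strata_thresholds=(float(q1), float(q3)),
        fitter=cph,
    )


def quartile_strata(scores: pd.Series, thresholds: tuple[float, float] | None = None) -> pd.Series:
    """Assign low / medium / high by the Q1/Q3 quartiles of the risk scores.

    ``risk < Q1`` -> low, ``Q1 <= risk <= Q3`` -> medium, ``risk > Q3`` ->
    high; identical scores all land in medium.
    """
    s = pd.Series(scores, dtype=float)
    q1, q3 = np.percentile(s, [25, 75]) if thresholds is None else thresholds
    out = pd.Series("medium", index=s.index)
    out[s < q1] = "low"
    out[s > q3] = "high"
    return out


def stratify_risk(model: RiskModel, expr: pd.DataFrame) -> pd.Series:
    """Stratify patients by exp(linear predictor) at the model's Q1/Q3 thresholds."""
    df = expr.loc[model.covariates].T
    risk = np.exp(model.fitter.predict_log_partial_hazard(df))
    return quartile_strata(pd.Series(risk, index=df.index), model.strata_thresholds)


def strata_logrank(strata: pd.Series, surv: pd.DataFrame) -> float:
    """Multivariate log-rank p across the risk strata."""
    common = strata.index.intersection(surv.index)
    res = multivariate_logrank_test(
        surv.loc[common, "time"], strata[common], surv.loc[common, "event"]
    )
    return float(res.p_value)


def svm_validate(
    expr: pd.DataFrame,
    labels: pd.Series,
    positive_label: str = "I",
    n_splits: int = 5,
    seed: int = 0,
) -> dict:
    """Five-fold stratified linear-margin classification of two conditions.

    ``expr`` is genes x samples restricted to the discriminating gene set
    (e.g. outset-cancer genes); metrics (accuracy, precision, specificity,
    on the 0-100 scale) are averaged over folds with seeded fold assignment.
    """
    common = expr.columns.intersection(labels.index)
    x = expr[common].T.to_numpy(float)
    y = labels[common].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    if counts.min() < n_splits:
        raise ValueError(f"each class needs at least {n_splits} samples")
    pos = positive_label if positive_label in classes else sorted(classes)[0]
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    acc, prec, spec = [], [], []
    for train, test in skf.split(x, y):
        clf = SVC(kernel="linear")
        clf.fit(x[train], y[train])
        pred = clf.predict(x[test])
        yb = (y[test] == pos).astype(int)
        pb = (pred == pos).astype(int)
        tn, fp, fn, tp = confusion_matrix(yb, pb, labels=[0, 1]).ravel()
        acc.append((tp + tn) / len(yb))
        prec.append(tp / (tp + fp) if tp + fp else 0.0)
        spec.append(tn / (tn + fp) if tn + fp else 0.0)
    return {
        "accuracy": 100.0 * float(np.mean(acc)),
        "precision": 100.0 * float(np.mean(prec)),
        "specificity": 100.0 * float(np.mean(spec)),
        "positive_label": str(pos),
    }
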