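"""Standardized benchmark statistics for ICB-response biomarkers.

Response stratification combines the RECIST category with a 6-month PFS
threshold: CR/PR/SD with PFS > 6 months are responders, PD (any PFS) and
SD with PFS < 6 months are nonresponders; samples at the 6-month boundary,
or lacking the PFS the rule needs, are unevaluable and excluded.

Continuous scores are tested with a one-sided Wilcoxon rank-sum test whose
alternative is oriented by the score's expected direction (positive:
responders higher); the AUC is read off the same Mann-Whitney U statistic.
Categorical scores use Fisher's exact test. Survival uses a mean-split of
the score followed by a two-group log-rank test and a univariate Cox model
(Efron ties) on the dichotomized group (continuous optional).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _lifelines_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateDataError, DegenerateWarning
from .io import ClinicalTable, ExpressionMatrix
from .registry import Registry
from .scoring import ScoreTable, compute_all_scores

RESPONDER, NONRESPONDER, UNEVALUABLE = "responder", "nonresponder", "unevaluable"
PFS_THRESHOLD_MONTHS = 6.0


@dataclass
class BenchmarkRecord:
    """Result of one statistical test of one score on one dataset."""

    score_name: str
    dataset_name: str
    test: str
    statistic: float
    p_value: float
    auc: float | None = None
    hr: float | None = None
    ci95: tuple[float, float] | None = None
    n_responder: int | None = None
    n_nonresponder: int | None = None
    direction_used: str | None = None
    endpoint: str | None = None
    effect: float | None = None  # e.g. paired mean change, odds ratio
    flagged: str | None = None  # degenerate / non-converged note

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC {self.auc} outside [0, 1]")
        if self.hr is not None and self.hr <= 0:
            raise ValueError(f"hazard ratio {self.hr} must be positive")


def records_to_frame(records: list[BenchmarkRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = r.__dict__.copy()
        ci = row.pop("ci95")
        row["ci95_low"] = ci[0] if ci else np.nan
        row["ci95_high"] = ci[1] if ci else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def stratify_response(clinical: ClinicalTable) -> pd.Series:
    """Responder / nonresponder / unevaluable label per sample."""
    df = clinical.data
    labels = []
    for cat, pfs in zip(df["response_category"], df["pfs_months"]):
        if cat == "PD":
            labels.append(NONRESPONDER)
        elif cat in ("CR", "PR", "SD"):
            if pd.isna(pfs):
                labels.append(UNEVALUABLE)
            elif pfs > PFS_THRESHOLD_MONTHS:
                labels.append(RESPONDER)
            elif pfs < PFS_THRESHOLD_MONTHS:
                labels.append(NONRESPONDER if cat == "SD" else UNEVALUABLE)
            else:  # exactly at the boundary
                labels.append(UNEVALUABLE)
        else:  # NA category
            labels.append(UNEVALUABLE)
    return pd.Series(labels, index=df["sample_id"].to_numpy(), name="label")


def mann_whitney_auc(oriented_scores: pd.Series, labels: pd.Series) -> tuple:
    """One-sided rank-sum p (responders > nonresponders) and AUC from U."""
    resp = oriented_scores[labels == RESPONDER].dropna()
    nonresp = oriented_scores[labels == NONRESPONDER].dropna()
    if len(resp) == 0 or len(nonresp) == 0:
        raise DegenerateDataError("empty responder or nonresponder group")
    n1, n2 = len(resp), len(nonresp)
    pooled = np.concatenate([resp.to_numpy(), nonresp.to_numpy()])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (n1 + n2 <= 20 and no_ties) else "asymptotic"
    result = stats.mannwhitneyu(
        resp, nonresp, alternative="greater", method=method
    )
    auc = float(result.statistic) / (n1 * n2)
    return float(result.statistic), float(result.pvalue), auc, n1, n2


def test_continuous_score(
    scores: pd.Series,
    labels: pd.Series,
    direction: str = "positive",
    score_name: str = "",
    dataset_name: str = "",
) -> BenchmarkRecord:
    """Directional one-sided Wilcoxon rank-sum test plus AUC for one score."""
    scores, labels = scores.align(labels, join="inner")
    oriented = scores if direction == "positive" else -scores
    statistic, p_value, auc, n1, n2 = mann_whitney_auc(oriented, labels)
    return BenchmarkRecord(
        score_name=score_name,
        dataset_name=dataset_name,
        test="wilcoxon_one_sided",
        statistic=statistic,
        p_value=p_value,
        auc=auc,
        n_responder=n1,
        n_nonresponder=n2,
        direction_used=direction,
    )


def test_categorical_score(
    categories: pd.Series,
    labels: pd.Series,
    score_name: str = "",
    dataset_name: str = "",
    max_exact_tables: int = 2_000_000,
    seed: int = 0,
) -> BenchmarkRecord:
    """Fisher's exact test of a categorical score against response labels.

    2x2 tables use the hypergeometric exact test (one-sided); 2xk tables
    are tested exactly by enumerating tables with the observed margins,
    falling back to a seeded Monte Carlo tail estimate when the
    enumeration would exceed ``max_exact_tables``.
    """
    categories, labels = categories.align(labels, join="inner")
    mask = labels.isin([RESPONDER, NONRESPONDER]) & categories.notna()
    categories, labels = categories[mask], labels[mask]
    levels = sorted(categories.unique())
    if len(levels) < 2:
        raise DegenerateDataError("categorical score has a single level")
    table = np.array(
        [
            [(labels == grp)[categories == lvl].sum() for lvl in levels]
            for grp in (RESPONDER, NONRESPONDER)
        ],
        dtype=int,
    )
    n1 = int(table[0].sum())
    n2 = int(table[1].sum())
    odds = None
    if table.shape == (2, 2):
        odds, p_value = stats.fisher_exact(table, alternative="greater")
        statistic = float(table[0, 0])
    else:
        p_value = _fisher_2xk(table, max_exact_tables, seed)
        statistic = float(p_value)
    return BenchmarkRecord(
        score_name=score_name,
        dataset_name=dataset_name,
        test="fisher_exact",
        statistic=statistic,
        p_value=float(p_value),
        n_responder=n1,
        n_nonresponder=n2,
        effect=float(odds) if odds is not None and np.isfinite(odds) else None,
    )


def _table_log_prob(table: np.ndarray) -> float:
    """Log probability of a 2xk table under fixed margins (hypergeometric)."""
    from scipy.special import gammaln

    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = table.sum()
    return float(
        gammaln(row + 1).sum()
        + gammaln(col + 1).sum()
        - gammaln(n + 1)
        - gammaln(table + 1).sum()
    )


def _fisher_2xk(table: np.ndarray, max_tables: int, seed: int) -> float:
    """Exact (enumerated) or Monte Carlo Fisher p for a 2xk table."""
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    n_tables_bound = int(np.prod([c + 1 for c in col]))
    observed = _table_log_prob(table)
    if n_tables_bound <= max_tables:
        total = 0.0
        tail = 0.0
        for top in itertools.product(*[range(c + 1) for c in col]):
            if sum(top) != n1:
                continue
            candidate = np.array([list(top), list(col - np.array(top))])
            lp = _table_log_prob(candidate)
            p = np.exp(lp)
            total += p
            if lp <= observed + 1e-9:
                tail += p
        return min(1.0, tail / total)
    # Monte Carlo: permute group labels, compare table probabilities
    rng = np.random.default_rng(seed)
    pool = np.repeat(np.arange(len(col)), col)
    hits = 0
    n_sim = 20_000
    for _ in range(n_sim):
        rng.shuffle(pool)
        top = np.bincount(pool[:n1], minlength=len(col))
        candidate = np.array([top, col - top])
        if _table_log_prob(candidate) <= observed + 1e-9:
            hits += 1
    return (hits + 1) / (n_sim + 1)


def paired_pre_on_test(
    scores_pre: pd.Series,
    scores_on: pd.Series,
    pairing: pd.DataFrame | None = None,
    score_name: str = "",
    dataset_name: str = "",
) -> BenchmarkRecord:
    """Two-sided paired t-test of on- vs pre-treatment scores.

    ``pairing`` optionally maps patients to (pre_sample, on_sample); when
    omitted, the two series are aligned on their shared index. All-zero
    differences report p = 1; a constant non-zero difference has an
    undefined t and is returned as a flagged record with the mean change.
    """
    if pairing is not None:
        pre = scores_pre.reindex(pairing["pre_sample"]).to_numpy(dtype=float)
        on = scores_on.reindex(pairing["on_sample"]).to_numpy(dtype=float)
    else:
        pre_s, on_s = scores_pre.align(scores_on, join="inner")
        pre, on = pre_s.to_numpy(dtype=float), on_s.to_numpy(dtype=float)
    keep = ~(np.isnan(pre) | np.isnan(on))
    pre, on = pre[keep], on[keep]
    if len(pre) < 3:
        raise DegenerateDataError("paired test needs >=3 complete pairs")
    diff = on - pre
    mean_change = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            statistic, p_value, flag = 0.0, 1.0, None
        else:
            statistic, p_value = np.nan, np.nan
            flag = "constant non-zero differences: t undefined"
            warnings.warn(flag, DegenerateWarning, stacklevel=2)
    else:
        result = stats.ttest_rel(on, pre)
        statistic, p_value = float(result.statistic), float(result.pvalue)
        flag = None
    return BenchmarkRecord(
        score_name=score_name,
        dataset_name=dataset_name,
        test="paired_t",
        statistic=statistic,
        p_value=p_value,
        effect=mean_change,
        flagged=flag,
    )


def dichotomize_by_mean(scores: pd.Series) -> pd.Series:
    """Split samples into high (> mean) and low (<= mean) groups."""
    scores = scores.dropna()
    if len(scores) < 2:
        raise DegenerateDataError("need >=2 samples to dichotomize")
    if scores.nunique() == 1:
        raise DegenerateDataError("constant scores cannot be dichotomized")
    return pd.Series(
        np.where(scores > scores.mean(), "high", "low"), index=scores.index
    )


def logrank_test(
    groups: pd.Series,
    time: pd.Series,
    event: pd.Series,
    score_name: str = "",
    dataset_name: str = "",
    endpoint: str | None = None,
) -> BenchmarkRecord:
    """Two-group log-rank test (chi-square with 1 df)."""
    groups, time = groups.align(time, join="inner")
    _, event = groups.align(event, join="inner")
    mask = time.notna() & event.notna()
    groups, time, event = groups[mask], time[mask], event[mask]
    names = pd.unique(groups)
    if len(names) != 2 or (groups == names[0]).sum() == 0:
        raise DegenerateDataError("log-rank needs two non-empty groups")
    if event.sum() == 0:
        raise DegenerateDataError("log-rank needs at least one event")
    in_a = groups == names[0]
    result = _lifelines_logrank(
        time[in_a], time[~in_a], event_observed_A=event[in_a],
        event_observed_B=event[~in_a],
    )
    return BenchmarkRecord(
        score_name=score_name,
        dataset_name=dataset_name,
        test="logrank",
        statistic=float(result.test_statistic),
        p_value=float(result.p_value),
        endpoint=endpoint,
    )


def cox_univariate(
    covariate: pd.Series,
    time: pd.Series,
    event: pd.Series,
    score_name: str = "",
    dataset_name: str = "",
    endpoint: str | None = None,
) -> BenchmarkRecord:
    """Univariate Cox proportional-hazards fit (Efron tie handling).

    Returns HR = exp(beta) with a Wald 95% CI and p-value; a binary
    high/low group covariate is coded high = 1. Non-convergence yields a
    flagged record rather than an exception.
    """
    covariate, time = covariate.align(time, join="inner")
    _, event = covariate.align(event, join="inner")
    if covariate.dtype == object:
        covariate = covariate.map({"low": 0.0, "high": 1.0}).astype(float)
    df = pd.DataFrame(
        {"x": covariate.astype(float), "time": time.astype(float),
         "event": event.astype(float)}
    ).dropna()
    if df["x"].nunique() < 2:
        raise DegenerateDataError("constant covariate in Cox model")
    if df["event"].sum() == 0:
        raise DegenerateDataError("Cox model needs at least one event")
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(df, duration_col="time", event_col="event")
    except ConvergenceError as err:
        return BenchmarkRecord(
            score_name=score_name, dataset_name=dataset_name, test="cox",
            statistic=np.nan, p_value=np.nan, endpoint=endpoint,
            flagged=f"non-convergence: {err}",
        )
    beta = float(fitter.params_["x"])
    se = float(fitter.standard_errors_["x"])
    return BenchmarkRecord(
        score_name=score_name,
        dataset_name=dataset_name,
        test="cox",
        statistic=beta / se if se > 0 else np.nan,
        p_value=float(fitter.summary.loc["x", "p"]),
        hr=float(np.exp(beta)),
        ci95=(float(np.exp(beta - 1.959964 * se)),
              float(np.exp(beta + 1.959964 * se))),
        endpoint=endpoint,
    )


def spearman_correlation_matrix(
    score_table: ScoreTable | pd.DataFrame,
    exclude: list[str] | None = None,
    min_samples: int = 3,
) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations between continuous scores.

    ``exclude`` names categorical columns to drop; columns with fewer than
    ``min_samples`` non-NA values are excluded with a warning.
    """
    table = (
        score_table.values if isinstance(score_table, ScoreTable) else score_table
    ).copy()
    for name in exclude or []:
        if name in table.columns:
            table = table.drop(columns=name)
    thin = [c for c in table.columns if table[c].notna().sum() < min_samples]
    if thin:
        warnings.warn(
            f"excluding columns with <{min_samples} values: {thin}",
            DegenerateWarning,
            stacklevel=2,
        )
        table = table.drop(columns=thin)
    if table.shape[0] < min_samples:
        raise DegenerateDataError("need >=3 samples for correlations")
    corr = table.corr(method="spearman", min_periods=min_samples)
    np.fill_diagonal(corr.to_numpy(), 1.0)
    return corr


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    arr = np.asarray(p_values, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def run_dataset_benchmark(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    registry: Registry,
    adapters: dict[str, pd.Series] | None = None,
    dataset_name: str = "dataset",
    alpha_level: float = 0.05,
    cox_on_continuous: bool = False,
    adjust_p: bool = False,
    seed: int = 0,
) -> tuple[list[BenchmarkRecord], pd.DataFrame]:
    """Score a cohort with the full registry and test every score.

    Per score: the directional response test with AUC (Fisher for
    categorical scores), and, when OS/PFS columns are present, a mean-split
    log-rank test and a Cox model per endpoint. Returns the records plus a
    per-score summary with the count of significant tests (the dot-plot
    bar). Scores that are entirely NA (unsupplied adapters) or degenerate
    on this dataset are skipped.
    """
    shared = [s for s in expr.sample_ids if s in set(clinical.sample_ids)]
    if not shared:
        raise DegenerateDataError("no overlapping samples between inputs")
    expr = ExpressionMatrix(
        expr.values[shared], log_transformed=expr.log_transformed
    )
    clin = ClinicalTable(
        clinical.data[clinical.data["sample_id"].isin(shared)].copy()
    )
    table = compute_all_scores(expr, registry, adapter_tables=adapters,
                               oe_seed=seed)
    labels = stratify_response(clin)
    surv = clin.data.set_index("sample_id")
    records: list[BenchmarkRecord] = []
    for spec in registry.entries:
        scores = table.values[spec.name]
        if scores.notna().sum() == 0:
            continue
        try:
            if spec.continuous:
                records.append(
                    test_continuous_score(
                        scores, labels, direction=spec.direction,
                        score_name=spec.name, dataset_name=dataset_name,
                    )
                )
            else:
                records.append(
                    test_categorical_score(
                        scores, labels, score_name=spec.name,
                        dataset_name=dataset_name, seed=seed,
                    )
                )
        except DegenerateDataError:
            pass
        for endpoint in ("os", "pfs"):
            time = surv[f"{endpoint}_months"]
            event = surv[f"{endpoint}_event"]
            if time.notna().sum() == 0 or event.fillna(0).sum() == 0:
                continue
            try:
                if spec.continuous:
                    groups = dichotomize_by_mean(scores)
                else:
                    groups = scores.dropna().astype(str)
                    if groups.nunique() != 2:
                        continue
                records.append(
                    logrank_test(
                        groups, time, event, score_name=spec.name,
                        dataset_name=dataset_name, endpoint=endpoint,
                    )
                )
                covariate = (
                    scores if (cox_on_continuous and spec.continuous) else groups
                )
                records.append(
                    cox_univariate(
                        covariate, time, event, score_name=spec.name,
                        dataset_name=dataset_name, endpoint=endpoint,
                    )
                )
            except DegenerateDataError:
                continue
    frame = records_to_frame(records)
    if adjust_p and not frame.empty:
        frame["p_adjusted"] = bh_adjust(frame["p_value"].fillna(1.0))
        p_col = "p_adjusted"
    else:
        p_col = "p_value"
    if frame.empty:
        return records, pd.DataFrame(columns=["score_name", "n_significant"])
    summary = (
        frame.assign(significant=frame[p_col] < alpha_level)
        .groupby("score_name", sort=False)["significant"]
        .sum()
        .rename("n_significant")
        .reset_index()
        .sort_values("n_significant", ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )
    return records, summary
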