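"""Survival analysis and immune characterization of genomic subgroups.

Kaplan-Meier curves with log-rank tests, univariate and covariate-adjusted
Cox proportional-hazards models (Efron ties; covariates age, sex, T stage
and Fuhrman grade), a univariate screen of events (optionally stratified by
clonality) feeding the subtyping stage, single-sample GSEA scores of immune
gene sets, and the Th17/Th2 and CD8/Treg score ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .enrichment import fdr_adjust
from .io import ClinicalRecord

__all__ = [
    "SurvivalResult",
    "clinical_frame",
    "km_logrank",
    "cox_model",
    "univariate_screen",
    "ssgsea_scores",
    "ImmuneScores",
    "immune_ratios",
    "compare_groups",
]


@dataclass
class SurvivalResult:
    term: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str  # km_logrank | cox_univariate | cox_multivariate
    statistic: float = float("nan")


def clinical_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    """Clinical table as a DataFrame indexed by sample with numeric covariates.

    T stage and Fuhrman grade become ordinal integers 1..4; sex becomes a
    0/1 indicator (first level alphabetically is 0).
    """
    df = pd.DataFrame(
        [
            (r.sample_id, r.survival_time, int(r.event_observed), r.age, r.sex, r.t_stage, r.fuhrman_grade)
            for r in records
        ],
        columns=["sample_id", "survival_time", "event_observed", "age", "sex", "t_stage", "fuhrman_grade"],
    ).set_index("sample_id")
    df["t_stage_num"] = df["t_stage"].str[1].astype(int)
    df["grade_num"] = df["fuhrman_grade"].str[1].astype(int)
    levels = sorted(df["sex"].unique())
    df["sex_num"] = df["sex"].map({lvl: i for i, lvl in enumerate(levels)}).astype(int)
    return df


def km_logrank(groups: pd.Series, clinical: pd.DataFrame):
    """Kaplan-Meier estimate per group and log-rank test across groups.

    ``groups`` maps sample_id to a group label; ``clinical`` is a
    clinical_frame.  Returns (SurvivalResult, curves DataFrame with columns
    group, time, survival).
    """
    groups = groups.dropna()
    common = clinical.index.intersection(groups.index)
    cl = clinical.loc[common]
    g = groups.loc[common]
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank test needs at least two groups")
    if (counts < 1).any():
        raise ValueError("every group needs at least one subject")
    res = multivariate_logrank_test(
        cl["survival_time"], g, cl["event_observed"]
    )
    curves = []
    for label in sorted(g.unique(), key=str):
        mask = g == label
        kmf = KaplanMeierFitter()
        kmf.fit(cl.loc[mask, "survival_time"], cl.loc[mask, "event_observed"])
        sf = kmf.survival_function_
        for t, s in zip(sf.index, sf.iloc[:, 0]):
            curves.append((label, float(t), float(s)))
    result = SurvivalResult(
        term="groups",
        hazard_ratio=float("nan"),
        ci_low=float("nan"),
        ci_high=float("nan"),
        p_value=float(res.p_value),
        model="km_logrank",
        statistic=float(res.test_statistic),
    )
    return result, pd.DataFrame(curves, columns=["group", "time", "survival"])


def km_survival(times, events) -> pd.DataFrame:
    """Product-limit estimator for one group (time, survival columns)."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


COX_COVARIATES = ["age", "sex_num", "t_stage_num", "grade_num"]


def cox_model(terms: pd.DataFrame, clinical: pd.DataFrame, adjusted: bool = False) -> list[SurvivalResult]:
    """Cox proportional-hazards fit (Efron ties) of one or more terms.

    ``terms``: samples x terms numeric covariates of interest, indexed by
    sample_id.  With ``adjusted`` the four clinical covariates (age, sex,
    T stage, Fuhrman grade) are added.  Returns HR, 95% CI and Wald p per
    term of interest.
    """
    common = clinical.index.intersection(terms.index)
    df = terms.loc[common].copy()
    for c in df.columns:
        if df[c].nunique() <= 1:
            raise ValueError(f"term {c!r} is constant across subjects")
    model = "cox_univariate"
    if adjusted:
        df = df.join(clinical.loc[common, COX_COVARIATES])
        model = "cox_multivariate"
    df["survival_time"] = clinical.loc[common, "survival_time"]
    df["event_observed"] = clinical.loc[common, "event_observed"]
    n_events = int(df["event_observed"].sum())
    n_params = df.shape[1] - 2
    if n_events < n_params:
        raise ValueError(f"{n_events} events observed for {n_params} parameters")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="survival_time", event_col="event_observed")
    except Exception as exc:  # noqa: BLE001 - surface convergence diagnostics
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    out = []
    for term in terms.columns:
        s = cph.summary.loc[term]
        out.append(
            SurvivalResult(
                term=term,
                hazard_ratio=float(s["exp(coef)"]),
                ci_low=float(s["exp(coef) lower 95%"]),
                ci_high=float(s["exp(coef) upper 95%"]),
                p_value=float(s["p"]),
                model=model,
                statistic=float(s["z"]),
            )
        )
    return out


def univariate_screen(
    events,
    calls: pd.DataFrame,
    clinical: pd.DataFrame,
    stratify_clonality: bool = False,
    alpha: float = 0.05,
    min_carriers: int = 5,
) -> pd.DataFrame:
    """Kaplan-Meier screen of events for survival association.

    For each event, carriers are compared with non-carriers by log-rank; in
    stratified mode the clonal and subclonal carriers are tested separately
    against non-carriers.  Events with fewer than ``min_carriers`` carriers
    in the tested stratum are skipped with a warning.  The unadjusted-p
    selection at ``alpha`` feeds the subtyping stage; the FDR column is
    always emitted.
    """
    rows = []
    all_samples = clinical.index
    for event in events:
        ev = calls[calls["event_id"] == event]
        strata = [("any", ev)]
        if stratify_clonality:
            strata = [
                ("clonal", ev[ev["clonality"] == "clonal"]),
                ("subclonal", ev[ev["clonality"] == "subclonal"]),
            ]
        for stratum, sub in strata:
            carriers = set(sub["sample_id"]) & set(all_samples)
            if len(carriers) < min_carriers:
                warnings.warn(f"event {event} ({stratum}): {len(carriers)} carriers < {min_carriers}; skipped")
                continue
            grp = pd.Series(
                ["carrier" if s in carriers else "non_carrier" for s in all_samples],
                index=all_samples,
            )
            if grp.nunique() < 2:
                continue
            res, _ = km_logrank(grp, clinical)
            rows.append((event, stratum, len(carriers), res.statistic, res.p_value))
    df = pd.DataFrame(rows, columns=["event_id", "stratum", "n_carriers", "chi2", "p_value"])
    if len(df):
        df["fdr"] = fdr_adjust(df["p_value"].to_numpy())
        df["selected"] = df["p_value"] < alpha
    return df


def _ssgsea_sample(expr: pd.Series, genes_in_set: set, weight_exponent: float) -> float:
    """Integrated weighted KS running-sum score for one sample (raw)."""
    # stable deterministic order: descending expression, gene name as tie-break
    order = sorted(expr.index, key=lambda g: (-expr[g], g))
    N = len(order)
    in_set = np.array([g in genes_in_set for g in order])
    n_in = int(in_set.sum())
    if n_in == 0:
        return np.nan
    ranks = np.arange(N, 0, -1, dtype=float)  # highest expression gets rank N
    w = np.abs(ranks) ** weight_exponent
    w_in = np.where(in_set, w, 0.0)
    p_in = np.cumsum(w_in) / w_in.sum()
    out = (~in_set).astype(float)
    p_out = np.cumsum(out) / (N - n_in)
    return float(np.sum(p_in - p_out))


class ImmuneScores:
    """ssGSEA scores: raw integrated statistic, per-gene-count scaled, min-max."""

    def __init__(self, raw: pd.DataFrame):
        self.raw = raw
        self.scaled = raw / raw.attrs["n_genes"]
        rng = raw.max(axis=1) - raw.min(axis=1)
        rng = rng.replace(0, 1.0)
        self.minmax = raw.sub(raw.min(axis=1), axis=0).div(rng, axis=0)


def ssgsea_scores(
    expression: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    weight_exponent: float = 0.25,
) -> ImmuneScores:
    """Single-sample GSEA of every gene set for every sample.

    ``expression`` is genes x samples.  Scores depend on within-sample ranks
    only, so they are invariant under strictly monotone transformations of
    the expression values.  Sets with no expressed member score NA.
    """
    raw = pd.DataFrame(index=list(gene_sets), columns=expression.columns, dtype=float)
    expressed = set(expression.index)
    for name, genes in gene_sets.items():
        members = set(genes) & expressed
        if not members:
            warnings.warn(f"gene set {name!r} has no expressed member; scores NA")
            raw.loc[name] = np.nan
            continue
        for sample in expression.columns:
            raw.loc[name, sample] = _ssgsea_sample(expression[sample], members, weight_exponent)
    raw.attrs["n_genes"] = expression.shape[0]
    return ImmuneScores(raw)


def immune_ratios(
    scores: ImmuneScores | pd.DataFrame,
    pairs=(("Th17", "Th2"), ("CD8", "Treg")),
    epsilon: float = 1e-6,
) -> pd.DataFrame:
    """Per-sample score ratios (e.g. Th17/Th2, CD8/Treg).

    ssGSEA scores can be negative, so both scores of a pair are shifted by
    the cohort-wide minimum over the two sets plus ``epsilon`` before
    dividing; the ratio is invariant to adding a constant to all scores of
    both sets.
    """
    raw = scores.raw if isinstance(scores, ImmuneScores) else scores
    out = {}
    for num, den in pairs:
        for s in (num, den):
            if s not in raw.index:
                raise ValueError(f"gene set {s!r} missing from scores")
        lo = float(min(raw.loc[num].min(), raw.loc[den].min()))
        a = raw.loc[num] - lo + epsilon
        b = raw.loc[den] - lo + epsilon
        out[f"{num}/{den}"] = a / b
    return pd.DataFrame(out)


def compare_groups(values, labels, test: str = "mann_whitney"):
    """Two-group comparison: Mann-Whitney, Student's t, or Fisher on binaries.

    Returns (statistic, p_value).  Use :func:`clonarch.enrichment.fdr_adjust`
    to control FDR across a tested panel.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) != 2:
        raise ValueError("compare_groups expects exactly two groups")
    a = values[labels == uniq[0]]
    b = values[labels == uniq[1]]
    if test == "mann_whitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if test == "t_test":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("t-test needs at least two observations per group")
        res = stats.ttest_ind(a, b)
        return float(res.statistic), float(res.pvalue)
    if test == "fisher":
        table = [
            [int((a == 1).sum()), int((a != 1).sum())],
            [int((b == 1).sum()), int((b != 1).sum())],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return float(odds), float(p)
    raise ValueError(f"unknown test {test!r}")
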