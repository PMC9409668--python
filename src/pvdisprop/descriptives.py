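"""Descriptive epidemiology of the case series: summary tables,
stratified comparisons, and yearly reporting trends.

Two denominator policies coexist in published report-series tables and are
therefore explicit here: ``all_cases`` (sex, country, reporter
qualification, seriousness — unknowns shown as a category) and
``available_only`` (outcome — unknown outcomes excluded from the
denominator). Percentages are rounded half-up to one decimal at rendering;
internal values keep full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .case_noncase import ExposureDefinition, exposed_report_ids
from .data_model import EXPOSURE_ROLES, ReportDatabase, report_years
from ._util import percent

logger = logging.getLogger(__name__)

HCP_QUALIFICATIONS = frozenset(
    {"physician", "pharmacist", "other_health_professional"})


@dataclass
class SummaryTable:
    """Counts and percentages for one categorical variable."""

    variable: str
    rows: pd.DataFrame  # columns: label, count, percent
    denominator_policy: str  # "all_cases" | "available_only"
    denominator: int


@dataclass
class NumericSummary:
    variable: str
    n: int
    median: float
    q1: float
    q3: float
    mean: float
    sd: float


@dataclass
class StratifiedComparison:
    variable: str
    stratum_labels: tuple
    stratum_stats: tuple  # per-stratum proportion or (mean, sd, n)
    test_name: str
    statistic: float
    p_value: float


def _case_reports(db: ReportDatabase, pt: str) -> pd.DataFrame:
    ids = db.case_ids(pt)
    return db.reports.loc[db.reports["report_id"].isin(ids)]


def _categorical_table(series: pd.Series, variable: str,
                       available_only: bool = False) -> SummaryTable:
    s = series
    if available_only:
        s = s[s != "unknown"]
    denom = len(s)
    counts = s.value_counts()
    rows = pd.DataFrame({
        "label": counts.index, "count": counts.to_numpy(),
        "percent": [percent(c, denom) for c in counts.to_numpy()]})
    policy = "available_only" if available_only else "all_cases"
    return SummaryTable(variable, rows.reset_index(drop=True), policy, denom)


def _numeric_summary(values: pd.Series, variable: str) -> NumericSummary:
    v = values.dropna()
    if v.empty:
        return NumericSummary(variable, 0, np.nan, np.nan, np.nan, np.nan,
                              np.nan)
    return NumericSummary(variable, len(v), float(v.median()),
                          float(v.quantile(0.25)), float(v.quantile(0.75)),
                          float(v.mean()), float(v.std(ddof=1)))


def summarize_cases(db: ReportDatabase, pt: str) -> dict:
    """Table-1-style summaries for the case series of ``pt``.

    Sex, country, reporter qualification and seriousness use the all-cases
    denominator; outcome uses available outcomes only. Age and per-report
    time to onset (earliest recorded onset among exposed mentions) are
    summarized as median (IQR) and mean ± SD.
    """
    cases = _case_reports(db, pt)
    out = {
        "sex": _categorical_table(cases["sex"], "sex"),
        "country": _categorical_table(cases["country"], "country"),
        "reporter_qualification": _categorical_table(
            cases["reporter_qualification"], "reporter_qualification"),
        "seriousness": _categorical_table(cases["serious"], "seriousness"),
        "outcome": _categorical_table(cases["outcome"], "outcome",
                                      available_only=True),
        "age": _numeric_summary(cases["age_years"], "age"),
    }
    dm = db.drug_mentions
    dm = dm.loc[dm["role"].isin(EXPOSURE_ROLES)
                & dm["report_id"].isin(cases["report_id"])]
    tto = dm.groupby("report_id")["time_to_onset_days"].min()
    out["time_to_onset"] = _numeric_summary(tto, "time_to_onset")
    return out


def _chi2_2x2(x_a: pd.Series, x_b: pd.Series, positive) -> tuple:
    table = np.array([
        [int((x_a == positive).sum()), int((x_a != positive).sum())],
        [int((x_b == positive).sum()), int((x_b != positive).sum())]])
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return np.nan, np.nan
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def compare_strata(db: ReportDatabase, pt: str, group: str,
                   roles=EXPOSURE_ROLES, welch: bool = False
                   ) -> list[StratifiedComparison]:
    """Compare case reports exposed to ``group`` against the other cases.

    Sex (female share among known) and reporter-is-healthcare-professional
    (among known qualifications) via Pearson chi-square without continuity
    correction; age via the two-sample t-test (pooled variance by default,
    Welch with ``welch=True``).
    """
    cases = _case_reports(db, pt)
    exposure = ExposureDefinition(group=group, role_filter=frozenset(roles))
    in_group = pd.Index(exposed_report_ids(db, exposure.resolve(db), roles))
    mask = cases["report_id"].isin(in_group)
    stratum_a, stratum_b = cases[mask], cases[~mask]
    if stratum_a.empty or stratum_b.empty:
        raise ValueError("both strata must be non-empty")
    labels = (group, "other drugs")
    results = []

    sex_a = stratum_a.loc[stratum_a["sex"] != "unknown", "sex"]
    sex_b = stratum_b.loc[stratum_b["sex"] != "unknown", "sex"]
    stat, p = _chi2_2x2(sex_a, sex_b, "female")
    results.append(StratifiedComparison(
        "female", labels,
        ((sex_a == "female").mean(), (sex_b == "female").mean()),
        "pearson_chi2", stat, p))

    q_a = stratum_a.loc[stratum_a["reporter_qualification"] != "unknown",
                        "reporter_qualification"]
    q_b = stratum_b.loc[stratum_b["reporter_qualification"] != "unknown",
                        "reporter_qualification"]
    hcp_a = q_a.isin(HCP_QUALIFICATIONS).map({True: "hcp", False: "other"})
    hcp_b = q_b.isin(HCP_QUALIFICATIONS).map({True: "hcp", False: "other"})
    stat, p = _chi2_2x2(hcp_a, hcp_b, "hcp")
    results.append(StratifiedComparison(
        "reported_by_hcp", labels,
        ((hcp_a == "hcp").mean(), (hcp_b == "hcp").mean()),
        "pearson_chi2", stat, p))

    age_a = stratum_a["age_years"].dropna()
    age_b = stratum_b["age_years"].dropna()
    if age_a.empty or age_b.empty:
        logger.warning("age comparison skipped: a stratum has no "
                       "recorded ages")
    else:
        res = stats.ttest_ind(age_a, age_b, equal_var=not welch)
        results.append(StratifiedComparison(
            "age", labels,
            ((age_a.mean(), age_a.std(ddof=1), len(age_a)),
             (age_b.mean(), age_b.std(ddof=1), len(age_b))),
            "welch_t" if welch else "student_t",
            float(res.statistic), float(res.pvalue)))
    return results


def yearly_trend(db: ReportDatabase, pt: str, split: str | None = None,
                 roles=EXPOSURE_ROLES) -> pd.DataFrame:
    """Case-report counts per calendar year, optionally split by a group.

    With ``split`` set, counts are divided into reports exposed to the
    named dictionary group versus all other case reports. Reports with an
    unparseable entry date are counted under year ``"unknown"`` (warned).
    Column sums always equal the total case count.
    """
    ids = db.case_ids(pt)
    years = report_years(db)
    case_years = years.loc[years.index.isin(ids)]
    if (case_years == "unknown").any():
        logger.warning("%d case report(s) with unparseable entry dates",
                       int((case_years == "unknown").sum()))
    if case_years.empty:
        cols = ["year", "n"] if split is None else ["year", "in_group",
                                                    "other"]
        return pd.DataFrame(columns=cols)
    if split is None:
        counts = case_years.value_counts().sort_index()
        return pd.DataFrame({"year": counts.index,
                             "n": counts.to_numpy()})
    exposure = ExposureDefinition(group=split, role_filter=frozenset(roles))
    in_group = exposed_report_ids(db, exposure.resolve(db), roles)
    frame = pd.DataFrame({
        "year": case_years,
        "in_group": case_years.index.isin(in_group)})
    counts = (frame.groupby(["year", "in_group"]).size()
              .unstack(fill_value=0).reindex(columns=[True, False],
                                             fill_value=0))
    counts.columns = ["in_group", "other"]
    counts = counts[["in_group", "other"]]
    out = counts.reset_index().sort_values("year", ignore_index=True)
    return out
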