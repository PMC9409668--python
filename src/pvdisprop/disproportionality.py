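"""Reporting odds ratio and information component signal statistics.

Given the 2×2 case/non-case table (a, b, c, d) for one exposure and one
Preferred Term in a database of N reports:

* ROR = (a/b)/(c/d), with the Wald 95% confidence interval
  exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d)). An exposure is
  ROR-significant when the lower bound exceeds 1. When any cell is zero the
  Haldane–Anscombe correction adds 0.5 to all four cells (flagged).

* IC = log2((O + 0.5)/(E + 0.5)) with observed O = a and expected
  E = (a+b)(a+c)/N — the shrunk observed-to-expected ratio used for
  signal detection on large spontaneous-report databases. Its 95% credibility
  lower bound is approximated as
  IC025 = IC − 3.3·(O+0.5)^(−1/2) − 2·(O+0.5)^(−3/2); a positive IC025
  constitutes a signal. The shrinkage offsets keep every input finite, pull
  small-count associations toward zero, and make IC exactly 0 when O = E.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .case_noncase import ContingencyTable, ExposureDefinition, build_table, \
    per_drug_case_counts
from .data_model import EXPOSURE_ROLES, ReportDatabase
from .errors import UndefinedEstimateError
from ._util import percent

Z_95 = 1.96  # two-sided 95% normal quantile; the CI level is fixed by design


@dataclass(frozen=True)
class RorResult:
    ror: float
    ci_low: float
    ci_high: float
    zero_cell_corrected: bool


@dataclass(frozen=True)
class IcResult:
    ic: float
    ic025: float


@dataclass(frozen=True)
class DisproportionalityResult:
    """Full signal statistics for one exposure against one PT."""

    exposure_label: str
    a: float
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    ic: float
    ic025: float
    zero_cell_corrected: bool

    @property
    def ror_significant(self) -> bool:
        return self.ror_ci_low > 1.0

    @property
    def ic_signal(self) -> bool:
        return self.ic025 > 0.0


def compute_ror(t: ContingencyTable, allow_correction: bool = True
                ) -> RorResult:
    """ROR with Wald 95% CI; Haldane–Anscombe 0.5 on all cells if any is 0.

    The correction is applied only when a zero cell occurs, so tables with
    all cells positive are evaluated exactly. With correction disabled a
    zero ``b`` or ``d`` raises :class:`UndefinedEstimateError`.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if a + b < 1 or c + d < 1:
        raise UndefinedEstimateError(
            "ROR requires at least one exposed and one unexposed report")
    corrected = False
    if min(a, b, c, d) == 0:
        if not allow_correction:
            raise UndefinedEstimateError(
                "zero cell and zero-cell correction disabled")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    ror = (a / b) / (c / d)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return RorResult(ror, ror * np.exp(-Z_95 * se), ror * np.exp(Z_95 * se),
                     corrected)


def compute_ic(t: ContingencyTable, ic025_method: str = "approximation"
               ) -> IcResult:
    """Information component and its 95% credibility lower bound IC025.

    ``ic025_method="approximation"`` (default) uses the closed-form
    normal-approximation penalty 3.3·(O+0.5)^(−1/2) + 2·(O+0.5)^(−3/2);
    ``"gamma"`` takes the exact 2.5% quantile of the conjugate
    Gamma(O + 0.5, E + 0.5) posterior of the observed-to-expected ratio.
    The two agree closely for O above a few dozen.
    """
    n = t.n_total
    if n < 1:
        raise ValueError("empty database")
    observed = t.a
    expected = (t.a + t.b) * (t.a + t.c) / n
    o_shrunk = observed + 0.5
    e_shrunk = expected + 0.5
    ic = np.log2(o_shrunk / e_shrunk)
    if ic025_method == "approximation":
        ic025 = ic - 3.3 * o_shrunk ** -0.5 - 2.0 * o_shrunk ** -1.5
    elif ic025_method == "gamma":
        q = scipy_stats.gamma.ppf(0.025, a=o_shrunk, scale=1.0 / e_shrunk)
        ic025 = np.log2(q)
    else:
        raise ValueError(f"unknown ic025_method '{ic025_method}'")
    return IcResult(float(ic), float(ic025))


def implied_table(a: float, ror: float, n_cases: float, n_total: float
                  ) -> ContingencyTable:
    """Reconstruct the 2×2 table implied by a published (a, ROR, margins).

    Published signal tables print the exposed-case count a and the point
    ROR but not the exposed non-case count b. Given also the case total
    a + c and the database total N, b solves
    b = (N − cases) / (1 + ROR·c/a) and d = N − cases − b, which allows
    re-evaluating the Wald confidence interval from print alone.
    """
    c = n_cases - a
    b = (n_total - n_cases) / (1.0 + ror * c / a)
    d = n_total - n_cases - b
    return ContingencyTable(a, b, c, d)


def evaluate_exposure(db: ReportDatabase, exposure: ExposureDefinition,
                      pt: str) -> DisproportionalityResult:
    """All signal statistics for one exposure definition."""
    t = build_table(db, exposure, pt)
    return _from_cells(t.a, t.b, t.c, t.d, exposure.display_label)


def _from_cells(a, b, c, d, label) -> DisproportionalityResult:
    t = ContingencyTable(a, b, c, d, label)
    r = compute_ror(t)
    ic = compute_ic(t)
    return DisproportionalityResult(label, a, r.ror, r.ci_low, r.ci_high,
                                    ic.ic, ic.ic025, r.zero_cell_corrected)

SIGNAL_COLUMNS = ["exposure_label", "is_group", "group_label", "n_cases",
                  "pct_cases", "pct_of_group", "ror", "ror_ci_low",
                  "ror_ci_high", "ic", "ic025", "ror_significant",
                  "ic_signal", "zero_cell_corrected"]


def signal_table(db: ReportDatabase, pt: str, min_cases: int = 30,
                 roles=EXPOSURE_ROLES) -> pd.DataFrame:
    """Ranked signal table: IC-signalling exposures with ≥ ``min_cases`` cases.

    One row per drug and one per dictionary group label, filtered to
    IC025 > 0 and case count ≥ ``min_cases``, sorted by case count
    descending (ties by label). ``pct_cases`` is the exposed-case count as
    a percentage of all cases; drugs belonging to a group additionally
    report ``pct_of_group``, their share of the group's case count.
    """
    counts = per_drug_case_counts(db, pt, roles)
    total_cases = len(db.case_ids(pt))

    dd = db.drug_dictionary
    group_labels = sorted({g for gs in dd["group_labels"] for g in gs})
    group_counts = {}
    rows = []
    for g in group_labels:
        t = build_table(db, ExposureDefinition(group=g, role_filter=roles),
                        pt)
        group_counts[g] = t.a
        if t.a >= min_cases:
            res = _from_cells(t.a, t.b, t.c, t.d, g)
            if res.ic_signal:
                rows.append(_row(res, True, None, total_cases, None))

    membership = dict(zip(dd["drug_id"], dd["group_labels"]))
    names = dict(zip(dd["drug_id"], dd["name"]))
    for rec in counts.itertuples(index=False):
        if rec.a < min_cases:
            continue
        res = _from_cells(rec.a, rec.b, rec.c, rec.d, names[rec.drug_id])
        if not res.ic_signal:
            continue
        groups = membership[rec.drug_id]
        glabel = groups[0] if groups else None
        gshare = (percent(rec.a, group_counts[glabel])
                  if glabel and group_counts.get(glabel) else None)
        rows.append(_row(res, False, glabel, total_cases, gshare))

    out = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    if len(out):
        out = out.sort_values(["n_cases", "exposure_label"],
                              ascending=[False, True], kind="mergesort",
                              ignore_index=True)
    return out


def _row(res: DisproportionalityResult, is_group: bool, group_label,
         total_cases: int, pct_of_group):
    return {"exposure_label": res.exposure_label, "is_group": is_group,
            "group_label": group_label, "n_cases": res.a,
            "pct_cases": percent(res.a, total_cases),
            "pct_of_group": pct_of_group, "ror": res.ror,
            "ror_ci_low": res.ror_ci_low, "ror_ci_high": res.ror_ci_high,
            "ic": res.ic, "ic025": res.ic025,
            "ror_significant": res.ror_significant,
            "ic_signal": res.ic_signal,
            "zero_cell_corrected": res.zero_cell_corrected}
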