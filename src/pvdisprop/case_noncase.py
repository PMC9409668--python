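"""Case/non-case cross-classification for one target Preferred Term.

Cases are the reports listing the target PT; non-cases are *all* other
reports in the database. Exposure is report-level: a report is exposed to a
drug (or drug group, or ATC class) if any of its drug mentions matches with
an allowed role — by default suspect or interacting, never concomitant.
Every report counts once per distinct exposure regardless of how many
matching mentions it carries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .data_model import EXPOSURE_ROLES, ReportDatabase
from .errors import DefinitionError
from ._util import percent

logger = logging.getLogger(__name__)

#: ATC truncation length per hierarchy level (letter / +2 digits / +letter
#: / +letter / +2 digits)
ATC_LEVEL_LENGTH = {1: 1, 2: 3, 3: 4, 4: 5, 5: 7}


@dataclass(frozen=True)
class ContingencyTable:
    """2×2 case/non-case table for one exposure × one PT.

    ``a``: exposed cases, ``b``: exposed non-cases, ``c``: unexposed cases,
    ``d``: unexposed non-cases. Cells partition all reports:
    a + b + c + d = N and a + c is the PT's total case count.
    """

    a: float
    b: float
    c: float
    d: float
    exposure_label: str = ""
    pt: str = ""

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def n_cases(self) -> float:
        return self.a + self.c

    def swapped(self) -> "ContingencyTable":
        """The same table with exposed/unexposed labels interchanged."""
        return ContingencyTable(self.c, self.d, self.a, self.b,
                                f"not({self.exposure_label})", self.pt)


@dataclass(frozen=True)
class ExposureDefinition:
    """One of: a single drug, a named dictionary group, or an ATC prefix.

    ``role_filter`` restricts which mention roles confer exposure; the
    default {suspect, interacting} matches standard case/non-case practice
    (concomitant drugs are background, not putative causes).
    """

    drug_id: str | None = None
    group: str | None = None
    atc_prefix: str | None = None
    role_filter: frozenset = field(
        default_factory=lambda: frozenset(EXPOSURE_ROLES))
    label: str | None = None

    def __post_init__(self):
        given = [x for x in (self.drug_id, self.group, self.atc_prefix)
                 if x is not None]
        if len(given) != 1:
            raise DefinitionError(
                "exactly one of drug_id / group / atc_prefix must be given")
        if not self.role_filter:
            raise DefinitionError("role_filter must be non-empty")

    @property
    def display_label(self) -> str:
        return self.label or (self.drug_id or self.group or
                              f"ATC:{self.atc_prefix}")

    def resolve(self, db: ReportDatabase) -> set[str]:
        """Drug ids covered by this definition; error if the set is empty."""
        dd = db.drug_dictionary
        if self.drug_id is not None:
            ids = set(dd.loc[dd["drug_id"] == self.drug_id, "drug_id"])
        elif self.group is not None:
            mask = dd["group_labels"].map(lambda gs: self.group in gs)
            ids = set(dd.loc[mask, "drug_id"])
        else:
            mask = dd["atc_codes"].map(
                lambda cs: any(c.startswith(self.atc_prefix) for c in cs))
            ids = set(dd.loc[mask, "drug_id"])
        if not ids:
            raise DefinitionError(
                f"exposure '{self.display_label}' resolves to no drugs")
        return ids


def exposed_report_ids(db: ReportDatabase, drug_ids: set[str],
                       roles=EXPOSURE_ROLES) -> pd.Index:
    """Distinct report ids with ≥1 mention of a listed drug in an allowed role."""
    dm = db.drug_mentions
    mask = dm["drug_id"].isin(drug_ids) & dm["role"].isin(roles)
    return pd.Index(dm.loc[mask, "report_id"].unique())


def build_table(db: ReportDatabase, exposure: ExposureDefinition,
                pt: str) -> ContingencyTable:
    """Build the 2×2 table for one exposure definition and one PT."""
    drug_ids = exposure.resolve(db)
    exposed = exposed_report_ids(db, drug_ids, exposure.role_filter)
    cases = db.case_ids(pt)
    a = len(exposed.intersection(cases))
    b = len(exposed) - a
    c = len(cases) - a
    d = db.n_total - a - b - c
    t = ContingencyTable(a, b, c, d, exposure.display_label, pt)
    assert t.n_total == db.n_total and t.n_cases == len(cases)
    return t


def per_drug_case_counts(db: ReportDatabase, pt: str, roles=EXPOSURE_ROLES
                         ) -> pd.DataFrame:
    """Per-drug 2×2 cell counts for every drug in the dictionary.

    Vectorized equivalent of calling :func:`build_table` per drug; returns
    columns drug_id, name, a, b, c, d.
    """
    cases = db.case_ids(pt)
    n_cases = len(cases)
    dm = db.drug_mentions
    dm = dm.loc[dm["role"].isin(roles), ["report_id", "drug_id"]]
    dm = dm.drop_duplicates()
    n_exposed = dm.groupby("drug_id").size()
    a = dm.loc[dm["report_id"].isin(cases)].groupby("drug_id").size()
    out = db.drug_dictionary[["drug_id", "name"]].copy()
    out["a"] = out["drug_id"].map(a).fillna(0).astype(int)
    out["b"] = (out["drug_id"].map(n_exposed).fillna(0).astype(int)
                - out["a"])
    out["c"] = n_cases - out["a"]
    out["d"] = db.n_total - n_cases - out["b"]
    return out


def rank_exposures(db: ReportDatabase, pt: str, min_cases: int = 30,
                   roles=EXPOSURE_ROLES) -> pd.DataFrame:
    """Drugs with ≥ ``min_cases`` exposed cases, ranked by case count.

    Sorted by exposed-case count descending; ties broken by drug name
    ascending. Columns: drug_id, name, n_cases, pct_cases.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    counts = per_drug_case_counts(db, pt, roles)
    total_cases = len(db.case_ids(pt))
    out = counts.loc[counts["a"] >= min_cases,
                     ["drug_id", "name", "a"]].copy()
    out = out.rename(columns={"a": "n_cases"})
    out["pct_cases"] = [percent(n, total_cases) for n in out["n_cases"]]
    out = out.sort_values(["n_cases", "name"], ascending=[False, True],
                          kind="mergesort", ignore_index=True)
    return out


def _atc_classes(codes: list[str], level: int) -> set[str]:
    width = ATC_LEVEL_LENGTH[level]
    return {c[:width] for c in codes if len(c) >= width}


def rollup(db: ReportDatabase, pt: str, level: int | str = 1,
           roles=EXPOSURE_ROLES) -> pd.DataFrame:
    """Case counts per ATC class (``level`` 1–5) or per ``"group"`` label.

    A case report with several drugs in the same class counts once for that
    class; percentages use the total case count as denominator. Drugs with
    no ATC code accumulate under "unclassified" (warned once).
    """
    cases = db.case_ids(pt)
    total_cases = len(cases)
    dm = db.drug_mentions
    dm = dm.loc[dm["role"].isin(roles) & dm["report_id"].isin(cases),
                ["report_id", "drug_id"]].drop_duplicates()
    if dm.empty:
        return pd.DataFrame(columns=["class_label", "n_reports",
                                     "pct_cases"])
    dd = db.drug_dictionary.set_index("drug_id")
    if level == "group":
        labels = dd["group_labels"].map(set)
    else:
        labels = dd["atc_codes"].map(lambda cs: _atc_classes(cs, int(level)))
        n_unclassified = int((labels.map(len) == 0).sum())
        if n_unclassified:
            logger.warning("%d drug(s) without ATC code rolled up as "
                           "'unclassified'", n_unclassified)
        labels = labels.map(lambda s: s or {"unclassified"})
    pairs = dm.assign(class_label=dm["drug_id"].map(labels))
    pairs = pairs.explode("class_label").dropna(subset=["class_label"])
    counts = (pairs.drop_duplicates(["report_id", "class_label"])
              .groupby("class_label").size())
    out = counts.rename("n_reports").reset_index()
    out["pct_cases"] = [percent(n, total_cases) for n in out["n_reports"]]
    out = out.sort_values(["n_reports", "class_label"],
                          ascending=[False, True], kind="mergesort",
                          ignore_index=True)
    return out
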