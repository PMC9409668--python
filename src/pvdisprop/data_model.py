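"""Normalized ICSR (individual case safety report) data model.

A spontaneous-report database is held as four normalized tables, mirroring
the many-to-many structure of real pharmacovigilance data (one report can
mention several drugs and several reactions):

* ``reports`` — one row per report: demographics, seriousness, outcome,
  entry date, reporter qualification.
* ``drug_mentions`` — one row per (report, drug, role), role being
  suspect / interacting / concomitant.
* ``reaction_mentions`` — one row per (report, MedDRA Preferred Term).
* ``drug_dictionary`` — one row per drug: name, ATC codes, optional
  analysis group labels (e.g. "COVID-19 vaccine").

On-disk format is strict UTF-8 comma-separated CSV with a mandatory header;
list-valued dictionary columns are semicolon-joined. Dates are ISO-8601
strings; only the calendar year is used analytically.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError

logger = logging.getLogger(__name__)

REPORTER_QUALIFICATIONS = frozenset(
    {"physician", "pharmacist", "other_health_professional", "lawyer",
     "consumer", "unknown"}
)
SERIOUS_VALUES = frozenset({"yes", "no", "unknown"})
SEX_VALUES = frozenset({"female", "male", "unknown"})
OUTCOME_VALUES = frozenset(
    {"recovered", "recovering", "not_recovered", "recovered_with_sequelae",
     "fatal", "unknown"}
)
DRUG_ROLES = frozenset({"suspect", "interacting", "concomitant"})
#: roles that define exposure in the case/non-case analysis
EXPOSURE_ROLES = frozenset({"suspect", "interacting"})

REPORT_COLUMNS = ["report_id", "entry_date", "country",
                  "reporter_qualification", "serious", "sex", "age_years",
                  "outcome"]
DRUG_MENTION_COLUMNS = ["report_id", "drug_id", "role", "time_to_onset_days"]
REACTION_COLUMNS = ["report_id", "pt"]
DRUG_DICT_COLUMNS = ["drug_id", "name", "atc_codes", "group_labels"]

FILE_NAMES = {
    "reports": "reports.csv",
    "drug_mentions": "report_drugs.csv",
    "reaction_mentions": "report_reactions.csv",
    "drug_dictionary": "drug_dict.csv",
}

# ATC codes: level-1 letter through level-5, i.e. truncations of
# letter / 2 digits / letter / letter / 2 digits.
_ATC_RE = re.compile(r"^[A-Z](\d{2}([A-Z]([A-Z](\d{2})?)?)?)?$")

MAX_AGE_YEARS = 130.0


@dataclass
class LoadConfig:
    """Options controlling validation at load time.

    ``study_start`` / ``study_end`` (ISO dates) define the study window;
    entry dates outside it raise a :class:`SchemaError` when ``strict_dates``
    is set and are otherwise counted in a warning.
    """

    study_start: str | None = None
    study_end: str | None = None
    strict_dates: bool = False


@dataclass
class ReportDatabase:
    """The four validated tables plus the grand total of distinct reports."""

    reports: pd.DataFrame
    drug_mentions: pd.DataFrame
    reaction_mentions: pd.DataFrame
    drug_dictionary: pd.DataFrame
    warning_counts: dict = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        """Number of distinct reports (the database grand total N)."""
        return len(self.reports)

    def case_ids(self, pt: str) -> pd.Index:
        """Report ids listing Preferred Term ``pt`` at least once."""
        mask = self.reaction_mentions["pt"] == pt
        return pd.Index(self.reaction_mentions.loc[mask, "report_id"].unique())

    def _sorted(self):
        r = self.reports.sort_values("report_id", kind="mergesort",
                                     ignore_index=True)
        dm = self.drug_mentions.sort_values(
            ["report_id", "drug_id", "role"], kind="mergesort",
            ignore_index=True)
        rm = self.reaction_mentions.sort_values(
            ["report_id", "pt"], kind="mergesort", ignore_index=True)
        dd = self.drug_dictionary.sort_values("drug_id", kind="mergesort",
                                              ignore_index=True)
        return r, dm, rm, dd

    def equals(self, other: "ReportDatabase") -> bool:
        """Equality up to row order (list columns compared element-wise)."""
        for a, b in zip(self._sorted(), other._sorted()):
            if list(a.columns) != list(b.columns) or len(a) != len(b):
                return False
            for col in a.columns:
                av, bv = a[col], b[col]
                if av.dtype == object:
                    if not all(x == y or (_isna(x) and _isna(y))
                               for x, y in zip(av, bv)):
                        return False
                else:
                    if not np.allclose(av, bv, equal_nan=True):
                        return False
        return True


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and np.isnan(x))


def _require_columns(df: pd.DataFrame, required: list[str], table: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"table '{table}' is missing required column(s): "
            + ", ".join(missing)
        )


def _map_enum(series: pd.Series, allowed: frozenset, name: str,
              warnings: dict) -> pd.Series:
    s = series.fillna("unknown").astype(str).str.strip().str.lower()
    s = s.replace("", "unknown")
    bad = ~s.isin(allowed)
    n_bad = int(bad.sum())
    if n_bad:
        warnings[f"unmapped_{name}"] = n_bad
        logger.warning("%d value(s) in '%s' not recognized; mapped to "
                       "'unknown'", n_bad, name)
        s = s.where(~bad, "unknown")
    return s


def _split_list(value) -> list[str]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return []
    return [v for v in str(value).split(";") if v]


def load_database(reports_path, drug_mentions_path, reactions_path,
                  drug_dict_path, config: LoadConfig | None = None
                  ) -> ReportDatabase:
    """Read and validate the four CSV tables into a :class:`ReportDatabase`.

    Duplicate ``(report_id, drug_id, role)`` and ``(report_id, pt)`` rows are
    collapsed; unrecognized demographic/outcome enum values are mapped to
    ``"unknown"`` with a logged warning count; out-of-range ages are set to
    missing. A missing column raises :class:`SchemaError` naming the column;
    an unresolvable foreign key raises :class:`ReferentialError` listing the
    offending report ids.
    """
    config = config or LoadConfig()
    warnings: dict = {}

    reports = pd.read_csv(reports_path, dtype=str, keep_default_na=False,
                          na_values=[""])
    _require_columns(reports, REPORT_COLUMNS, "reports")
    reports = reports[REPORT_COLUMNS].copy()
    if reports["report_id"].isna().any():
        raise SchemaError("reports table contains empty report_id values")
    dup = reports["report_id"].duplicated()
    if dup.any():
        raise SchemaError(
            "duplicate report_id values: "
            + ", ".join(reports.loc[dup, "report_id"].head(10)))
    for col, allowed in [("reporter_qualification", REPORTER_QUALIFICATIONS),
                         ("serious", SERIOUS_VALUES), ("sex", SEX_VALUES),
                         ("outcome", OUTCOME_VALUES)]:
        reports[col] = _map_enum(reports[col], allowed, col, warnings)
    reports["age_years"] = pd.to_numeric(reports["age_years"],
                                         errors="coerce")
    bad_age = reports["age_years"].notna() & (
        (reports["age_years"] < 0) | (reports["age_years"] > MAX_AGE_YEARS))
    if bad_age.any():
        warnings["age_out_of_range"] = int(bad_age.sum())
        logger.warning("%d age(s) outside [0, %g] set to missing",
                       int(bad_age.sum()), MAX_AGE_YEARS)
        reports.loc[bad_age, "age_years"] = np.nan
    reports["country"] = reports["country"].fillna("unknown")
    _check_dates(reports["entry_date"], config, warnings)

    drugs = pd.read_csv(drug_mentions_path, dtype=str, keep_default_na=False,
                        na_values=[""])
    _require_columns(drugs, DRUG_MENTION_COLUMNS, "report_drugs")
    drugs = drugs[DRUG_MENTION_COLUMNS].copy()
    drugs["role"] = drugs["role"].fillna("").astype(str).str.strip().str.lower()
    bad_role = ~drugs["role"].isin(DRUG_ROLES)
    if bad_role.any():
        raise SchemaError(
            "invalid drug role value(s): "
            + ", ".join(sorted(drugs.loc[bad_role, "role"].unique())[:10]))
    drugs["time_to_onset_days"] = pd.to_numeric(
        drugs["time_to_onset_days"], errors="coerce")
    n_before = len(drugs)
    drugs = drugs.drop_duplicates(["report_id", "drug_id", "role"],
                                  ignore_index=True)
    if len(drugs) < n_before:
        warnings["duplicate_drug_mentions"] = n_before - len(drugs)

    reactions = pd.read_csv(reactions_path, dtype=str, keep_default_na=False,
                            na_values=[""])
    _require_columns(reactions, REACTION_COLUMNS, "report_reactions")
    reactions = reactions[REACTION_COLUMNS].copy()
    if reactions["pt"].isna().any() or (reactions["pt"] == "").any():
        raise SchemaError("report_reactions contains empty pt values")
    n_before = len(reactions)
    reactions = reactions.drop_duplicates(["report_id", "pt"],
                                          ignore_index=True)
    if len(reactions) < n_before:
        warnings["duplicate_reactions"] = n_before - len(reactions)

    ddict = pd.read_csv(drug_dict_path, dtype=str, keep_default_na=False,
                        na_values=[""])
    _require_columns(ddict, DRUG_DICT_COLUMNS, "drug_dict")
    ddict = ddict[DRUG_DICT_COLUMNS].copy()
    if ddict["drug_id"].duplicated().any():
        raise SchemaError("duplicate drug_id values in drug_dict")
    ddict["atc_codes"] = ddict["atc_codes"].map(_split_list)
    ddict["group_labels"] = ddict["group_labels"].map(_split_list)
    n_bad_atc = 0
    cleaned = []
    for codes in ddict["atc_codes"]:
        good = [c for c in codes if _ATC_RE.match(c)]
        n_bad_atc += len(codes) - len(good)
        cleaned.append(good)
    if n_bad_atc:
        warnings["invalid_atc_codes"] = n_bad_atc
        logger.warning("%d malformed ATC code(s) dropped", n_bad_atc)
    ddict["atc_codes"] = cleaned

    known_reports = pd.Index(reports["report_id"])
    for tab, name in [(drugs, "report_drugs"), (reactions,
                                                "report_reactions")]:
        orphans = tab.loc[~tab["report_id"].isin(known_reports), "report_id"]
        if len(orphans):
            ids = sorted(orphans.unique())
            raise ReferentialError(
                f"{name} references unknown report_id(s): "
                + ", ".join(ids[:10]), ids)
    unknown_drugs = drugs.loc[~drugs["drug_id"].isin(ddict["drug_id"])]
    if len(unknown_drugs):
        ids = sorted(unknown_drugs["report_id"].unique())
        raise ReferentialError(
            "report_drugs references drug_id(s) absent from drug_dict "
            "(report ids: " + ", ".join(ids[:10]) + ")", ids)

    return ReportDatabase(reports, drugs, reactions, ddict, warnings)


def _check_dates(dates: pd.Series, config: LoadConfig, warnings: dict):
    parsed = pd.to_datetime(dates, format="%Y-%m-%d", errors="coerce")
    n_bad = int(parsed.isna().sum())
    if n_bad:
        warnings["unparseable_dates"] = n_bad
        logger.warning("%d unparseable entry date(s)", n_bad)
    out_of_window = pd.Series(False, index=dates.index)
    if config.study_start is not None:
        out_of_window |= parsed < pd.Timestamp(config.study_start)
    if config.study_end is not None:
        out_of_window |= parsed > pd.Timestamp(config.study_end)
    n_out = int(out_of_window.sum())
    if n_out:
        if config.strict_dates:
            raise SchemaError(
                f"{n_out} entry date(s) fall outside the study window "
                f"[{config.study_start}, {config.study_end}]")
        warnings["dates_outside_window"] = n_out
        logger.warning("%d entry date(s) outside the study window", n_out)


def load_database_dir(directory, config: LoadConfig | None = None
                      ) -> ReportDatabase:
    """Load the four tables from ``directory`` using the standard filenames."""
    d = Path(directory)
    return load_database(d / FILE_NAMES["reports"],
                         d / FILE_NAMES["drug_mentions"],
                         d / FILE_NAMES["reaction_mentions"],
                         d / FILE_NAMES["drug_dictionary"], config)


def write_database(db: ReportDatabase, directory) -> dict[str, Path]:
    """Write the four tables as CSV; returns the mapping of table → path.

    Rows are written in canonical sorted order and missing values as empty
    fields, so ``load_database`` on the output reproduces ``db`` up to row
    order and re-running a pipeline yields byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    r, dm, rm, dd = db._sorted()
    dd = dd.copy()
    dd["atc_codes"] = dd["atc_codes"].map(";".join)
    dd["group_labels"] = dd["group_labels"].map(";".join)
    paths = {}
    for name, frame in [("reports", r), ("drug_mentions", dm),
                        ("reaction_mentions", rm), ("drug_dictionary", dd)]:
        path = d / FILE_NAMES[name]
        frame.to_csv(path, index=False, na_rep="", lineterminator="\n")
        paths[name] = path
    return paths


def report_years(db: ReportDatabase) -> pd.Series:
    """Calendar year per report; ``"unknown"`` where the date is unparseable."""
    parsed = pd.to_datetime(db.reports["entry_date"], format="%Y-%m-%d",
                            errors="coerce")
    years = parsed.dt.year.astype("Int64").astype(str)
    years = years.where(parsed.notna(), "unknown")
    years.index = pd.Index(db.reports["report_id"])
    return years
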