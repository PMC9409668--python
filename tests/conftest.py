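import numpy as np
import pandas as pd
import pytest

from pvdisprop import (DrugSpec, PlantedEffect, PtSpec, ReportDatabase,
                       SyntheticConfig, default_parosmia_scenario, generate)


def make_config(n_reports=1000, seed=0, n_drugs=6, baseline=0.05,
                effects=(), extra_pts=(), concomitant_fraction=0.25):
    """Small uniform-catalog config for unit and property tests."""
    weight = 1.8 / n_drugs
    drugs = [DrugSpec(f"d{i}", f"Drug {i}", weight, (f"J01AA{i:02d}",))
             for i in range(n_drugs)]
    # a common filler PT so conditioning on >=1 reaction per report does
    # not distort the target PT's marginal frequency
    pts = ([PtSpec("Parosmia", baseline)]
           + [PtSpec(p, b) for p, b in extra_pts]
           + [PtSpec("Background symptom", 0.6)])
    return SyntheticConfig(
        n_reports=n_reports, seed=seed, drugs=drugs, pts=pts,
        planted_effects=[PlantedEffect(d, pt, lam) for d, pt, lam in effects],
        concomitant_fraction=concomitant_fraction)


def frame_db(reports, drug_mentions, reaction_mentions, drug_dictionary):
    """Build a ReportDatabase straight from column dicts (tests only)."""
    dd = pd.DataFrame(drug_dictionary,
                      columns=["drug_id", "name", "atc_codes",
                               "group_labels"])
    return ReportDatabase(
        pd.DataFrame(reports, columns=["report_id", "entry_date", "country",
                                       "reporter_qualification", "serious",
                                       "sex", "age_years", "outcome"]),
        pd.DataFrame(drug_mentions, columns=["report_id", "drug_id", "role",
                                             "time_to_onset_days"]),
        pd.DataFrame(reaction_mentions, columns=["report_id", "pt"]),
        dd)


def simple_report(report_id, **overrides):
    row = {"report_id": report_id, "entry_date": "2021-06-01",
           "country": "US", "reporter_qualification": "physician",
           "serious": "no", "sex": "female", "age_years": 50.0,
           "outcome": "recovered"}
    row.update(overrides)
    return row


@pytest.fixture
def ten_report_db():
    """10 reports; drugA exposed in 4, 'Parosmia' in 3, overlap 2.

    Expected contingency table for drugA x Parosmia: (a,b,c,d) = (2,2,1,5).
    """
    reports = [simple_report(f"R{i}") for i in range(10)]
    drug_mentions = (
        [{"report_id": f"R{i}", "drug_id": "drugA", "role": "suspect",
          "time_to_onset_days": np.nan} for i in (0, 1, 2, 3)]
        + [{"report_id": f"R{i}", "drug_id": "drugB", "role": "suspect",
            "time_to_onset_days": np.nan} for i in (4, 5)])
    reactions = ([{"report_id": f"R{i}", "pt": "Parosmia"}
                  for i in (0, 1, 4)]
                 + [{"report_id": f"R{i}", "pt": "Nausea"}
                    for i in range(10)])
    ddict = [{"drug_id": "drugA", "name": "Drug A",
              "atc_codes": ["J01FA09"], "group_labels": []},
             {"drug_id": "drugB", "name": "Drug B",
              "atc_codes": ["J01MA02"], "group_labels": []}]
    return frame_db(reports, drug_mentions, reactions, ddict)


@pytest.fixture(scope="session")
def scenario_db():
    """Default smell-disorder scenario at 100k reports (shared, read-only)."""
    db, truth = generate(default_parosmia_scenario(n_reports=100_000,
                                                   seed=11))
    return db, truth


@pytest.fixture(scope="session")
def scenario_db_large():
    """Default scenario at 200k reports for rank/signal recovery checks."""
    db, truth = generate(default_parosmia_scenario(n_reports=200_000,
                                                   seed=7))
    return db, truth
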