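import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pvdisprop import (ContingencyTable, compute_ic, compute_ror,
                       implied_table, signal_table)
from pvdisprop.errors import UndefinedEstimateError

from conftest import frame_db, simple_report


class TestRor:
    def test_proportional_table_gives_unity(self):
        r = compute_ror(ContingencyTable(10, 90, 100, 900))
        assert r.ror == pytest.approx(1.0)
        assert r.ci_low < 1.0 < r.ci_high
        assert not r.zero_cell_corrected

    def test_reconstructed_strong_signal_table(self):
        """Implied table for a = 83 exposed cases at point ROR 144.5 in a
        29,978,090-report database with 14,032 cases."""
        t = implied_table(a=83, ror=144.5, n_cases=14_032,
                          n_total=29_978_090)
        assert t.c == 13_949
        assert t.b == pytest.approx(1233.8, abs=0.5)
        r = compute_ror(t)
        assert r.ror == pytest.approx(144.5, abs=1e-6)
        assert round(r.ci_low, 1) == 115.6
        assert round(r.ci_high, 1) == 180.6

    def test_zero_cell_correction(self):
        r = compute_ror(ContingencyTable(0, 100, 50, 1000))
        assert r.zero_cell_corrected
        assert 0 < r.ror < math.inf
        assert r.ci_low < r.ror < r.ci_high

    def test_zero_cell_without_correction_errors(self):
        with pytest.raises(UndefinedEstimateError):
            compute_ror(ContingencyTable(5, 0, 50, 1000),
                        allow_correction=False)

    def test_all_exposed_or_all_unexposed_rejected(self):
        with pytest.raises(UndefinedEstimateError):
            compute_ror(ContingencyTable(0, 0, 50, 1000))

    def test_monotone_in_exposed_cases(self):
        base = ContingencyTable(20, 500, 100, 10_000)
        shifted = ContingencyTable(21, 500, 99, 10_000)
        assert compute_ror(shifted).ror > compute_ror(base).ror

    @pytest.mark.parametrize("k", [2, 5, 10])
    def test_scaling_cells_fixes_ror_and_narrows_ci(self, k):
        t = ContingencyTable(20, 500, 100, 10_000)
        tk = ContingencyTable(20 * k, 500 * k, 100 * k, 10_000 * k)
        r, rk = compute_ror(t), compute_ror(tk)
        assert rk.ror == pytest.approx(r.ror)
        assert rk.ci_high - rk.ci_low < r.ci_high - r.ci_low

    def test_matches_statsmodels_on_random_tables(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(12345)
        cells = rng.integers(1, 1000, size=(1000, 4))
        for a, b, c, d in cells:
            mine = compute_ror(ContingencyTable(a, b, c, d))
            tab = sm.stats.Table2x2(np.array([[a, b], [c, d]]),
                                    shift_zeros=False)
            lo, hi = tab.oddsratio_confint(alpha=0.05)
            assert mine.ror == pytest.approx(tab.oddsratio, rel=1e-10)
            # statsmodels uses the exact 97.5% quantile; this package fixes
            # the conventional 1.96, so bounds agree only to ~2e-5
            assert mine.ci_low == pytest.approx(lo, rel=1e-4)
            assert mine.ci_high == pytest.approx(hi, rel=1e-4)


class TestIc:
    def test_zero_when_observed_equals_expected(self):
        # margins chosen so E = (a+b)(a+c)/N equals a exactly
        for a, b, c, d in [(10, 90, 90, 810), (100, 900, 900, 8100),
                           (4, 4, 4, 4)]:
            t = ContingencyTable(a, b, c, d)
            ic = compute_ic(t)
            assert ic.ic == 0.0
            assert ic.ic025 < 0.0

    def test_known_value(self):
        ic = compute_ic(ContingencyTable(100, 900, 900, 98_100))
        assert ic.ic == pytest.approx(math.log2(100.5 / 10.5), rel=1e-12)
        assert ic.ic == pytest.approx(3.259, abs=5e-4)
        assert ic.ic025 == pytest.approx(2.928, abs=5e-4)

    def test_gamma_quantile_variant_agrees_for_large_counts(self):
        t = ContingencyTable(500, 9500, 2000, 500_000)
        approx = compute_ic(t)
        exact = compute_ic(t, ic025_method="gamma")
        assert exact.ic == approx.ic
        assert exact.ic025 == pytest.approx(approx.ic025, abs=0.05)
        assert exact.ic025 < exact.ic

    def test_absence_gives_no_signal(self):
        ic = compute_ic(ContingencyTable(0, 10_000, 500, 1_000_000))
        assert ic.ic < 0
        assert ic.ic025 < 0

    @settings(derandomize=True)
    @given(cells=st.tuples(st.integers(0, 5000), st.integers(1, 5000),
                           st.integers(0, 5000), st.integers(1, 5000)))
    def test_credibility_bound_below_point_estimate(self, cells):
        ic = compute_ic(ContingencyTable(*cells))
        assert ic.ic025 < ic.ic

    def test_sign_concordance_with_ror_on_large_cells(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 200:
            a = int(rng.integers(100, 2000))
            b = int(rng.integers(100, 50_000))
            c = int(rng.integers(100, 5000))
            d = int(rng.integers(10_000, 1_000_000))
            t = ContingencyTable(a, b, c, d)
            e = (a + b) * (a + c) / t.n_total
            if e < 1:
                continue
            lnror = math.log(compute_ror(t).ror)
            ic = compute_ic(t).ic
            if abs(lnror) < 1e-3:  # knife-edge tables excluded
                continue
            assert np.sign(ic) == np.sign(lnror)
            checked += 1


class TestSignalTable:
    def _db(self, n_cases_drug=40):
        reports, mentions, reactions = [], [], []
        idx = 0

        def add(drug, pt_flag, n, role="suspect"):
            nonlocal idx
            for _ in range(n):
                rid = f"R{idx}"; idx += 1
                reports.append(simple_report(rid))
                if drug:
                    mentions.append({"report_id": rid, "drug_id": drug,
                                     "role": role,
                                     "time_to_onset_days": np.nan})
                reactions.append(
                    {"report_id": rid,
                     "pt": "Parosmia" if pt_flag else "Nausea"})

        add("drugA", True, n_cases_drug)   # strongly associated
        add("drugA", False, 60)
        add("drugB", True, 29)             # below the case threshold
        add("drugB", False, 3000)
        add(None, True, 100)
        add(None, False, 50_000)
        ddict = [{"drug_id": "drugA", "name": "Alpha",
                  "atc_codes": ["J01FA09"], "group_labels": ["grp"]},
                 {"drug_id": "drugB", "name": "Beta",
                  "atc_codes": ["J01FA10"], "group_labels": []}]
        return frame_db(reports, mentions, reactions, ddict)

    def test_min_cases_threshold_excludes_small_counts(self):
        out = signal_table(self._db(), "Parosmia", min_cases=30)
        labels = set(out["exposure_label"])
        assert "Alpha" in labels
        assert "Beta" not in labels

    def test_group_rows_and_group_share(self):
        out = signal_table(self._db(), "Parosmia", min_cases=30)
        grp = out[out["is_group"]]
        assert list(grp["exposure_label"]) == ["grp"]
        alpha = out[out["exposure_label"] == "Alpha"].iloc[0]
        assert alpha["group_label"] == "grp"
        assert alpha["pct_of_group"] == 100.0
        assert (out["ic025"] > 0).all()

    def test_flags_consistent_with_bounds(self):
        out = signal_table(self._db(), "Parosmia", min_cases=10)
        assert (out["ror_significant"] == (out["ror_ci_low"] > 1)).all()
        assert (out["ic025"] < out["ic"]).all()

    def test_empty_case_set_yields_empty_table(self, ten_report_db):
        out = signal_table(ten_report_db, "Absent PT")
        assert out.empty
        assert "exposure_label" in out.columns

    def test_strongest_planted_effect_has_largest_ror(self,
                                                      scenario_db_large):
        db, truth = scenario_db_large
        out = signal_table(db, "Parosmia", min_cases=30)
        assert len(out) > 0
        drugs = out[~out["is_group"]]
        top = drugs.sort_values("ror", ascending=False).iloc[0]
        assert top["exposure_label"] == "Flunisolide"
        assert top["ror"] > 50

    def test_null_database_signals_rare(self):
        """Without planted effects IC025 > 0 should be a rare event."""
        from pvdisprop import generate
        from conftest import make_config
        n_flagged = n_tested = 0
        for seed in range(6):
            db, _ = generate(make_config(n_reports=30_000, seed=100 + seed,
                                         n_drugs=12, baseline=0.02))
            out = signal_table(db, "Parosmia", min_cases=30)
            counts = __import__("pvdisprop").per_drug_case_counts(
                db, "Parosmia")
            n_tested += int((counts["a"] >= 30).sum())
            n_flagged += len(out)
        assert n_tested > 40
        assert n_flagged / n_tested <= 0.075
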