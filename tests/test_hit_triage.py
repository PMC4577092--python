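"""Hit-triage cascade: hand-traced stage rules, audit invariants, monotonicity."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq
from scipy.stats import norm

from fpscreen.assay_quality import ControlStats, per_plate_control_stats
from fpscreen.curve_fits import logistic_model
from fpscreen.hit_triage import (
    REASON_HIGH_FP,
    REASON_LOW_INHIBITION,
    REASON_LOW_INTENSITY,
    REASON_RISING_DOSE,
    REASON_UNTESTED,
    TriageConfig,
    call_hits,
    confirm_retest,
    dose_qc,
    filter_high_fp,
    filter_low_intensity,
    run_cascade,
)
from fpscreen.plate_io import ROWS, ScreenTable, WellRecord
from fpscreen.screen_sim import (
    SimConfig,
    default_dose_series,
    simulate_dose_series,
    simulate_retest,
    simulate_screen,
)


def build_table(sample_fp, sample_intensity=None, mu_n=200.0, mu_p=100.0):
    """One plate: given sample readings plus noiseless controls."""
    n = len(sample_fp)
    inten = sample_intensity if sample_intensity is not None else [1e4] * n
    recs = []
    for i, r in enumerate(ROWS):
        recs.append(WellRecord("P01", r, 1, "", "neg_control",
                               mu_n + (0.1 if i % 2 else -0.1), 1e4, 0.0))
        recs.append(WellRecord("P01", r, 24, "", "pos_control",
                               mu_p + (0.1 if i % 2 else -0.1), 1e4, 0.0))
    for k, (fp, it) in enumerate(zip(sample_fp, inten)):
        r, c = ROWS[k % 16], 2 + k // 16
        recs.append(WellRecord("P01", r, c, f"C{k:04d}", "sample", fp, it, 10.0))
    return ScreenTable.from_records(recs)


class TestHighFPFilter:
    def test_outlier_removed_with_reason(self):
        fp = [160.0, 180.0] * 50 + [250.0]
        table = build_table(fp)
        kept, removed, stats = filter_high_fp(table, TriageConfig())
        assert len(removed) == 1
        assert removed.iloc[0]["reason"] == REASON_HIGH_FP
        assert 250.0 not in kept.samples()["fp_mP"].values
        # stage statistics are the raw, unfiltered sample statistics
        assert stats.mean == pytest.approx(np.mean(fp))
        assert stats.sigma == pytest.approx(np.std(fp, ddof=1))

    def test_identical_wells_nothing_removed(self):
        table = build_table([170.0] * 50)
        _, removed, _ = filter_high_fp(table, TriageConfig())
        assert removed.empty

    def test_threshold_exactly_attained_is_kept(self):
        # find b such that b == mean + 2*sigma of {base, b}; the boundary
        # well must survive the strict inequality
        base = [160.0, 180.0] * 10

        def gap(b):
            v = np.array(base + [b])
            return v.mean() + 2 * v.std(ddof=1) - b

        b = brentq(gap, 171.0, 1e4)
        table = build_table(base + [b])
        _, removed, _ = filter_high_fp(table, TriageConfig())
        assert removed.empty


class TestLowIntensityFilter:
    def test_low_fp_low_intensity_removed(self):
        # one well 4 sigma below the FP mean whose intensity is far below the
        # intensity mean; intensity sigma here ~1% of mean
        rng = np.random.default_rng(5)
        fp = list(175 + 2.0 * rng.standard_normal(100)) + [167.0]
        inten = list(1e4 + 100 * rng.standard_normal(100)) + [4000.0]
        table = build_table(fp, inten)
        kept, removed = filter_low_intensity(table, TriageConfig())
        assert list(removed["compound_id"]) == ["C0100"]
        assert removed.iloc[0]["reason"] == REASON_LOW_INTENSITY

    def test_low_fp_normal_intensity_kept(self):
        rng = np.random.default_rng(5)
        fp = list(175 + 2.0 * rng.standard_normal(100)) + [100.0]
        inten = list(1e4 + 100 * rng.standard_normal(100)) + [1e4]
        table = build_table(fp, inten)
        _, removed = filter_low_intensity(table, TriageConfig())
        assert removed.empty

    def test_high_fp_wells_never_intensity_filtered(self):
        # the filter only inspects FP-decreasing wells
        rng = np.random.default_rng(5)
        fp = list(175 + 2.0 * rng.standard_normal(100)) + [220.0]
        inten = list(1e4 + 100 * rng.standard_normal(100)) + [3000.0]
        _, removed = filter_low_intensity(build_table(fp, inten), TriageConfig())
        assert removed.empty

    def test_two_sided_catches_autofluorescence(self):
        rng = np.random.default_rng(5)
        fp = list(175 + 2.0 * rng.standard_normal(100)) + [168.0]
        inten = list(1e4 + 100 * rng.standard_normal(100)) + [2.5e4]
        cfg = TriageConfig(intensity_filter_direction="two_sided")
        _, removed = filter_low_intensity(build_table(fp, inten), cfg)
        assert list(removed["compound_id"]) == ["C0100"]

    def test_fp_channel_compatibility_mode(self):
        # the alternative convention reads the 5 sigma rule on the FP axis
        rng = np.random.default_rng(5)
        fp = list(175 + 2.0 * rng.standard_normal(100)) + [150.0]
        table = build_table(fp)
        cfg = TriageConfig(intensity_filter_channel="fp")
        _, removed = filter_low_intensity(table, cfg)
        assert list(removed["compound_id"]) == ["C0100"]


class TestCallHits:
    def test_deep_inhibitor_selected(self):
        rng = np.random.default_rng(8)
        fp = list(180 + 3.0 * rng.standard_normal(200)) + [100.0]
        table = build_table(fp)
        hits, _, _ = call_hits(table, TriageConfig(),
                               per_plate_control_stats(table))
        assert "C0200" in set(hits["compound_id"])

    def test_inhibition_floor_rejects_shallow_assay_window(self):
        # well at ~3.5 sigma below the sample mean, but only ~24% inhibition
        rng = np.random.default_rng(9)
        fp = list(190 + 4.0 * rng.standard_normal(200)) + [176.0]
        table = build_table(fp, mu_n=200.0, mu_p=100.0)
        hits, rejected, stats = call_hits(table, TriageConfig(),
                                          per_plate_control_stats(table))
        assert 176.0 < stats.mean - 3 * stats.sigma
        assert "C0200" not in set(hits["compound_id"])
        reason = rejected.set_index("compound_id").loc["C0200", "reason"]
        assert reason == REASON_LOW_INHIBITION

    def test_pure_noise_false_positive_rate_matches_tail_mass(self):
        # without the inhibition floor, the 3 sigma rule alone should select
        # about norm.cdf(-3) of pure-noise wells
        rng = np.random.default_rng(123)
        cfg = TriageConfig(min_inhibition=0.0)
        n, total, expected = 352, 0, 0.0
        for _ in range(30):
            fp = list(180 + 5.0 * rng.standard_normal(n))
            table = build_table(fp)
            hits, _, _ = call_hits(table, cfg, per_plate_control_stats(table))
            total += len(hits)
            expected += n * norm.cdf(-3)
        assert 0.4 * expected < total < 2.0 * expected

    def test_raising_thresholds_never_enlarges_hit_set(self, small_sim):
        _, screen, _ = small_sim
        controls = per_plate_control_stats(screen)
        base, _, _ = call_hits(screen, TriageConfig(), controls)
        base_ids = set(base["compound_id"])
        for cfg in (TriageConfig(hit_sigma=4.0), TriageConfig(min_inhibition=70.0)):
            tighter, _, _ = call_hits(screen, cfg, controls)
            assert set(tighter["compound_id"]) <= base_ids


class TestRetest:
    def test_empty_hit_list(self, small_sim):
        cfg, _, truths = small_sim
        retest = simulate_retest(cfg, truths, [])
        # no samples on the plate at all -> nothing to confirm
        confirmed, rejected = confirm_retest([], retest, TriageConfig())
        assert confirmed == [] and rejected.empty

    def test_reproducing_hit_confirmed_and_regressor_rejected(self):
        rng = np.random.default_rng(4)
        primary = build_table(list(180 + 3.0 * rng.standard_normal(100)))
        _, _, stats = call_hits(primary, TriageConfig(),
                                per_plate_control_stats(primary))
        retest = build_table([100.0, 179.0] + list(180 + 3.0 * rng.standard_normal(50)))
        confirmed, rejected = confirm_retest(
            ["C0000", "C0001"], retest, TriageConfig(), primary_stats=stats
        )
        assert confirmed == ["C0000"]
        assert "C0001" in set(rejected["compound_id"])

    def test_missing_compound_reported_untested(self):
        rng = np.random.default_rng(4)
        primary = build_table(list(180 + 3.0 * rng.standard_normal(100)))
        _, _, stats = call_hits(primary, TriageConfig(),
                                per_plate_control_stats(primary))
        retest = build_table([100.0])
        confirmed, rejected = confirm_retest(
            ["C0000", "GHOST"], retest, TriageConfig(), primary_stats=stats
        )
        assert confirmed == ["C0000"]
        row = rejected.set_index("compound_id").loc["GHOST"]
        assert row["reason"] == REASON_UNTESTED


class TestDoseQC:
    doses = default_dose_series()

    def test_true_inhibitor_passes_and_ic50_recovered(self):
        # log-logistic series falling with dose, IC50 = 2 uM
        fp = 60 + logistic_model(self.doses, 120.0, np.log10(2.0), -1.0)
        series = pd.DataFrame(
            {"compound_id": "INH", "dose_uM": self.doses, "fp_mP": fp}
        )
        passed, failed, fits = dose_qc(series, TriageConfig(), fp_free_reference=60.0)
        assert passed == ["INH"] and failed.empty
        assert fits["INH"].converged
        assert fits["INH"].ic50 == pytest.approx(2.0, rel=1e-3)

    def test_rising_series_fails(self):
        fp = [170 + 10 * np.log10(d + 1) for d in self.doses]
        series = pd.DataFrame({"compound_id": "AGG", "dose_uM": self.doses,
                               "fp_mP": fp})
        passed, failed, _ = dose_qc(series, TriageConfig())
        assert passed == []
        assert failed.iloc[0]["reason"] == REASON_RISING_DOSE

    def test_flat_series_passes_but_fit_flagged(self):
        series = pd.DataFrame({"compound_id": "FLAT", "dose_uM": self.doses,
                               "fp_mP": [170.0] * len(self.doses)})
        passed, failed, fits = dose_qc(series, TriageConfig())
        assert passed == ["FLAT"] and failed.empty
        assert not fits["FLAT"].converged

    def test_too_few_doses_unevaluable(self):
        series = pd.DataFrame({"compound_id": "SHORT", "dose_uM": [1, 2, 4],
                               "fp_mP": [170, 160, 150]})
        passed, failed, _ = dose_qc(series, TriageConfig())
        assert passed == []
        assert "too few doses" in failed.iloc[0]["reason"]


class TestCascade:
    def test_full_cascade_audit_trail(self, small_sim):
        cfg, screen, truths = small_sim
        tcfg = TriageConfig()
        kept, _, _ = filter_high_fp(screen, tcfg)
        kept, _ = filter_low_intensity(kept, tcfg)
        hits, _, _ = call_hits(kept, tcfg, per_plate_control_stats(kept))
        ids = hits["compound_id"].tolist()
        retest = simulate_retest(cfg, truths, ids)
        doses = simulate_dose_series(cfg, truths, ids)
        report = run_cascade(screen, retest, doses, tcfg)
        report.validate()  # telescoping counts, single reason per removal
        stages = [s.stage for s in report.stages]
        assert stages == [
            "high_fp_filter", "low_intensity_filter", "hit_call",
            "retest_confirmation", "dose_response_qc",
        ]
        assert report.n_library == 300
        assert set(report.final_hits) <= {t.compound_id for t in truths}
        # artifact removal narrows the FP distribution
        assert report.fp_stats_filtered.sigma < report.fp_stats_raw.sigma

    def test_cascade_deterministic(self, small_sim):
        cfg, screen, truths = small_sim
        r1 = run_cascade(screen, None, None, TriageConfig())
        r2 = run_cascade(screen, None, None, TriageConfig())
        assert r1.final_hits == r2.final_hits
        assert r1.summary() == r2.summary()

    def test_no_actives_wide_window_no_hits(self):
        cfg = SimConfig(
            n_compounds=200, frac_inhibitor=0.0, frac_aggregator=0.0,
            frac_quencher=0.0, frac_autofluorescent=0.0, noise=0.005, seed=3,
        )
        screen, _ = simulate_screen(cfg)
        report = run_cascade(screen, None, None, TriageConfig())
        assert report.final_hits == []
        assert report.hit_rate == 0.0
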