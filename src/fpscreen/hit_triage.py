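"""Multi-stage hit-triage cascade for a single-concentration FP screen.

The cascade turns raw screen wells into confirmed hits in five ordered stages,
each with an explicit audit trail:

A. ``filter_high_fp``      — drop samples reading *above* mean + 2σ of the raw
                             sample FP distribution (suspected protein
                             precipitation / fluorescence quenching).
B. ``filter_low_intensity``— among FP-decreasing samples, drop wells whose
                             total-fluorescence reading is more than 5σ below
                             the sample mean of that channel (compound
                             intrinsic fluorescence masquerading as
                             displacement).
C. ``call_hits``           — recompute mean/σ on the surviving samples; hit ⇔
                             FP < mean − 3σ AND percent inhibition > 50%.
D. ``confirm_retest``      — re-measure primary hits under the original
                             conditions and re-apply the hit cutoff.
E. ``dose_qc``             — dose-response sanity: compounds whose FP *rises*
                             with dose are discarded; survivors get
                             log-logistic IC50 fits.

All σ thresholds use strict inequalities; a well sitting exactly on a
threshold is kept.  Counts telescope stage to stage and every removed well
carries exactly one primary reason, so the whole cascade is auditable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import theilslopes

from .assay_quality import ControlStats, percent_inhibition, per_plate_control_stats
from .curve_fits import LogisticFit, TitrationPoint, fit_logistic
from .plate_io import ScreenTable

__all__ = [
    "TriageConfig",
    "StageResult",
    "TriageReport",
    "FPStats",
    "filter_high_fp",
    "filter_low_intensity",
    "call_hits",
    "confirm_retest",
    "dose_qc",
    "run_cascade",
]

REASON_HIGH_FP = "suspected precipitation/quenching"
REASON_LOW_INTENSITY = "intrinsic fluorescence"
REASON_NOT_HIT = "above hit threshold"
REASON_LOW_INHIBITION = "below inhibition floor"
REASON_NOT_CONFIRMED = "did not reproduce on retest"
REASON_UNTESTED = "absent from retest plate"
REASON_RISING_DOSE = "FP increases with dose"
REASON_UNEVALUABLE = "too few doses"


@dataclass(frozen=True)
class TriageConfig:
    """Thresholds of the cascade; defaults mirror the published protocol."""

    high_fp_sigma: float = 2.0
    low_intensity_sigma: float = 5.0
    hit_sigma: float = 3.0
    min_inhibition: float = 50.0
    #: channel the 5σ artifact filter reads: the total-fluorescence channel
    #: (the method statement) or, as a compatibility option, the FP channel.
    intensity_filter_channel: str = "total_intensity"
    intensity_filter_direction: str = "below"  # below | above | two_sided
    dose_qc_enabled: bool = True
    #: Theil–Sen slope above which a dose series counts as "rising" (mP/decade)
    dose_slope_threshold: float = 5.0
    #: retest cutoff statistics: frozen from the filtered primary screen
    #: ("primary") or recomputed within the retest batch ("batch")
    retest_stats: str = "primary"
    #: percent-inhibition reference controls: per-plate or assay-global
    inhibition_scope: str = "plate"  # plate | global

    def __post_init__(self) -> None:
        for name in ("high_fp_sigma", "low_intensity_sigma", "hit_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.min_inhibition <= 100:
            raise ValueError("min_inhibition must lie in [0, 100]")
        if self.intensity_filter_channel not in ("total_intensity", "fp"):
            raise ValueError("intensity_filter_channel must be total_intensity|fp")
        if self.intensity_filter_direction not in ("below", "above", "two_sided"):
            raise ValueError("intensity_filter_direction must be below|above|two_sided")
        if self.retest_stats not in ("primary", "batch"):
            raise ValueError("retest_stats must be primary|batch")
        if self.inhibition_scope not in ("plate", "global"):
            raise ValueError("inhibition_scope must be plate|global")


@dataclass(frozen=True)
class FPStats:
    """Mean/σ (sample, n−1 denominator) of a set of sample-well FP readings."""

    mean: float
    sigma: float
    n: int


@dataclass
class StageResult:
    stage: str
    n_in: int
    n_removed: int
    n_out: int
    removed: pd.DataFrame  # columns: plate_id, well, compound_id, reason

    def __post_init__(self) -> None:
        if self.n_in - self.n_removed != self.n_out:
            raise AssertionError(
                f"stage {self.stage}: counts do not telescope "
                f"({self.n_in} - {self.n_removed} != {self.n_out})"
            )


@dataclass
class TriageReport:
    stages: list[StageResult]
    fp_stats_raw: FPStats
    fp_stats_filtered: FPStats
    final_hits: list[str]
    n_library: int
    ic50_fits: dict[str, LogisticFit] = field(default_factory=dict)

    @property
    def hit_rate(self) -> float:
        """Final hits as a percentage of the screened library."""
        return 100.0 * len(self.final_hits) / self.n_library

    def validate(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if nxt.n_in != prev.n_out:
                raise AssertionError(
                    f"stage counts do not telescope: {prev.stage} out "
                    f"{prev.n_out} != {nxt.stage} in {nxt.n_in}"
                )
        for s in self.stages:
            if s.removed["reason"].isna().any() or (s.removed["reason"] == "").any():
                raise AssertionError(f"stage {s.stage}: removal without a reason")

    def summary(self) -> dict:
        return {
            "n_library": self.n_library,
            "stages": [
                {
                    "stage": s.stage,
                    "n_in": s.n_in,
                    "n_removed": s.n_removed,
                    "n_out": s.n_out,
                }
                for s in self.stages
            ],
            "fp_stats_raw": asdict(self.fp_stats_raw),
            "fp_stats_filtered": asdict(self.fp_stats_filtered),
            "final_hits": list(self.final_hits),
            "hit_rate_percent": self.hit_rate,
            "ic50": {
                cid: {"ic50": f.ic50, "unit": f.x_unit, "hill": f.p,
                      "converged": f.converged}
                for cid, f in self.ic50_fits.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.summary(), indent=2, **kwargs)


def _sample_fp_stats(df: pd.DataFrame) -> FPStats:
    fp = df.loc[df["role"] == "sample", "fp_mP"].to_numpy()
    if fp.size < 2:
        raise ValueError("need >= 2 sample wells to compute FP statistics")
    return FPStats(float(fp.mean()), float(fp.std(ddof=1)), int(fp.size))


def _removed_frame(df: pd.DataFrame, mask: np.ndarray, reason: str) -> pd.DataFrame:
    out = df.loc[mask, ["plate_id", "well", "compound_id"]].copy()
    out["reason"] = reason
    return out.reset_index(drop=True)


def _empty_removed() -> pd.DataFrame:
    return pd.DataFrame(columns=["plate_id", "well", "compound_id", "reason"])


def _subset_table(table: ScreenTable, keep_sample_mask: pd.Series) -> ScreenTable:
    """Drop the masked-out sample wells; controls always ride along."""
    df = table.df
    keep = (df["role"] != "sample") | keep_sample_mask
    return ScreenTable(df=df[keep].reset_index(drop=True), meta=table.meta)


def filter_high_fp(
    table: ScreenTable, cfg: TriageConfig
) -> tuple[ScreenTable, pd.DataFrame, FPStats]:
    """Stage A: remove samples with FP > mean + ``high_fp_sigma``·σ (raw stats).

    Mean and σ are computed over *all* sample wells of the unfiltered screen.
    Returns (kept table, removed wells with reasons, the raw FP statistics).
    """
    stats = _sample_fp_stats(table.df)
    df = table.df
    is_sample = df["role"] == "sample"
    cut = stats.mean + cfg.high_fp_sigma * stats.sigma
    reject = is_sample & (df["fp_mP"] > cut)  # strict: fp == cut is kept
    removed = _removed_frame(df, reject, REASON_HIGH_FP)
    return _subset_table(table, ~reject), removed, stats


def filter_low_intensity(
    table: ScreenTable, cfg: TriageConfig
) -> tuple[ScreenTable, pd.DataFrame]:
    """Stage B: among FP-decreasing samples, remove intensity outliers.

    "FP-decreasing" means FP below the current sample-FP mean.  The outlier
    test reads the configured channel (total fluorescence by default; FP as
    the compatibility option) and removes wells beyond
    ``low_intensity_sigma``·σ from that channel's own sample mean, in the
    configured direction.
    """
    df = table.df
    is_sample = df["role"] == "sample"
    samples = df[is_sample]
    if samples.empty:
        return table, _empty_removed()
    fp_mean = float(samples["fp_mP"].mean())
    channel = "fp_mP" if cfg.intensity_filter_channel == "fp" else "total_intensity"
    if channel not in df.columns:
        raise KeyError(f"intensity filter channel {channel!r} missing from table")
    ch = samples[channel].to_numpy()
    mu, sd = float(ch.mean()), float(ch.std(ddof=1))
    lo, hi = mu - cfg.low_intensity_sigma * sd, mu + cfg.low_intensity_sigma * sd

    decreasing = df["fp_mP"] < fp_mean
    if cfg.intensity_filter_direction == "below":
        outlier = df[channel] < lo
    elif cfg.intensity_filter_direction == "above":
        outlier = df[channel] > hi
    else:
        outlier = (df[channel] < lo) | (df[channel] > hi)
    reject = is_sample & decreasing & outlier
    removed = _removed_frame(df, reject, REASON_LOW_INTENSITY)
    return _subset_table(table, ~reject), removed


def _inhibition_for(
    df: pd.DataFrame,
    controls: ControlStats | Mapping[str, ControlStats],
) -> np.ndarray:
    if isinstance(controls, ControlStats):
        return percent_inhibition(df["fp_mP"].to_numpy(), controls)
    out = np.empty(len(df))
    for i, (plate, fp) in enumerate(zip(df["plate_id"], df["fp_mP"])):
        if plate not in controls:
            raise ValueError(f"no control statistics for plate {plate}")
        out[i] = percent_inhibition(fp, controls[plate])
    return out


def call_hits(
    table: ScreenTable,
    cfg: TriageConfig,
    controls: ControlStats | Mapping[str, ControlStats],
) -> tuple[pd.DataFrame, pd.DataFrame, FPStats]:
    """Stage C: σ-threshold hit call with an inhibition floor.

    Mean/σ are *recomputed* on the sample wells that survived the artifact
    filters.  A sample is a hit iff FP < mean − ``hit_sigma``·σ (strict) and
    percent inhibition > ``min_inhibition`` (strict).  Returns
    (hits, rejected-with-reason, the recomputed FP statistics).
    """
    stats = _sample_fp_stats(table.df)
    df = table.df
    samples = df[df["role"] == "sample"].reset_index(drop=True)
    cut = stats.mean - cfg.hit_sigma * stats.sigma
    low_fp = samples["fp_mP"].to_numpy() < cut
    inh = _inhibition_for(samples, controls)
    deep = inh > cfg.min_inhibition

    hits = samples[low_fp & deep].copy()
    hits["percent_inhibition"] = inh[low_fp & deep]
    # primary reason: the σ criterion is checked first
    rej_sigma = _removed_frame(samples, ~low_fp, REASON_NOT_HIT)
    rej_floor = _removed_frame(samples, low_fp & ~deep, REASON_LOW_INHIBITION)
    rejected = pd.concat([rej_sigma, rej_floor], ignore_index=True)
    return hits.reset_index(drop=True), rejected, stats


def confirm_retest(
    primary_hits: Sequence[str],
    retest_table: ScreenTable,
    cfg: TriageConfig,
    primary_stats: FPStats | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Stage D: re-apply the hit cutoff to retest measurements.

    The cutoff statistics come either frozen from the filtered primary screen
    (``cfg.retest_stats == "primary"``, requires ``primary_stats``) or are
    recomputed within the retest batch.  Percent inhibition is referenced to
    the retest plate's own controls.  Primary hits absent from the retest
    plate are reported as untested, never silently dropped.
    """
    primary_hits = list(primary_hits)
    if not primary_hits:
        return [], _empty_removed()
    df = retest_table.df
    samples = df[df["role"] == "sample"]
    present = set(samples["compound_id"])
    untested = [c for c in primary_hits if c not in present]

    if cfg.retest_stats == "primary":
        if primary_stats is None:
            raise ValueError('retest_stats="primary" requires primary_stats')
        stats = primary_stats
    else:
        stats = _sample_fp_stats(df)
    if cfg.inhibition_scope == "plate":
        controls: ControlStats | Mapping[str, ControlStats] = per_plate_control_stats(
            retest_table
        )
    else:
        from .assay_quality import control_stats

        controls = control_stats(retest_table)

    tested = samples[samples["compound_id"].isin(primary_hits)].reset_index(drop=True)
    cut = stats.mean - cfg.hit_sigma * stats.sigma
    low_fp = tested["fp_mP"].to_numpy() < cut
    inh = _inhibition_for(tested, controls)
    deep = inh > cfg.min_inhibition
    ok = low_fp & deep

    confirmed = [c for c in primary_hits if c in set(tested.loc[ok, "compound_id"])]
    rej = pd.concat(
        [
            _removed_frame(tested, ~ok, REASON_NOT_CONFIRMED),
            pd.DataFrame(
                {
                    "plate_id": "",
                    "well": "",
                    "compound_id": untested,
                    "reason": REASON_UNTESTED,
                }
            ),
        ],
        ignore_index=True,
    )
    return confirmed, rej


def dose_qc(
    series: pd.DataFrame,
    cfg: TriageConfig,
    fp_free_reference: float | None = None,
    min_doses: int = 5,
) -> tuple[list[str], pd.DataFrame, dict[str, LogisticFit]]:
    """Stage E: discard compounds whose FP rises with dose; fit IC50s.

    ``series`` is long format with columns compound_id, dose_uM, fp_mP.  The
    monotone-trend test is the Theil–Sen slope of FP against log10(dose); a
    slope above ``cfg.dose_slope_threshold`` (mP per decade) fails the
    compound.  Survivors are fit with the log-logistic displacement equation
    on ΔP = FP − FP(free probe); compounds with fewer than ``min_doses``
    doses are flagged unevaluable rather than judged.
    """
    need = {"compound_id", "dose_uM", "fp_mP"}
    if not need.issubset(series.columns):
        raise KeyError(f"dose series lacks columns {sorted(need - set(series.columns))}")
    passed: list[str] = []
    failed_rows: list[dict] = []
    fits: dict[str, LogisticFit] = {}
    for cid, grp in series.groupby("compound_id", sort=True):
        grp = grp[grp["dose_uM"] > 0]
        if len(grp) < min_doses:
            failed_rows.append(
                {"plate_id": "", "well": "", "compound_id": cid,
                 "reason": REASON_UNEVALUABLE}
            )
            continue
        logx = np.log10(grp["dose_uM"].to_numpy())
        fp = grp["fp_mP"].to_numpy()
        slope = theilslopes(fp, logx).slope if np.ptp(fp) > 0 else 0.0
        if slope > cfg.dose_slope_threshold:
            failed_rows.append(
                {"plate_id": "", "well": "", "compound_id": cid,
                 "reason": REASON_RISING_DOSE}
            )
            continue
        passed.append(cid)
        ref = fp_free_reference if fp_free_reference is not None else float(fp.min())
        pts = [TitrationPoint(x, f - ref) for x, f in zip(grp["dose_uM"], fp)]
        try:
            fits[cid] = fit_logistic(pts, x_unit="uM")
        except ValueError:
            # series too narrow to fit; QC verdict stands, no IC50 reported
            pass
    failed = (
        pd.DataFrame(failed_rows, columns=["plate_id", "well", "compound_id", "reason"])
        if failed_rows
        else _empty_removed()
    )
    return passed, failed, fits


def run_cascade(
    screen: ScreenTable,
    retest: ScreenTable | None,
    doses: pd.DataFrame | None,
    cfg: TriageConfig | None = None,
) -> TriageReport:
    """Run all five stages in order and assemble the telescoping audit report.

    ``retest`` and ``doses`` may be None, in which case the corresponding
    stages pass primary hits through unchanged (the report still records them
    with zero removals).
    """
    cfg = cfg or TriageConfig()
    stages: list[StageResult] = []
    n0 = int((screen.df["role"] == "sample").sum())

    kept, removed_a, raw_stats = filter_high_fp(screen, cfg)
    n1 = int((kept.df["role"] == "sample").sum())
    stages.append(StageResult("high_fp_filter", n0, len(removed_a), n1, removed_a))

    kept, removed_b = filter_low_intensity(kept, cfg)
    n2 = int((kept.df["role"] == "sample").sum())
    stages.append(StageResult("low_intensity_filter", n1, len(removed_b), n2, removed_b))

    if cfg.inhibition_scope == "plate":
        controls: ControlStats | Mapping[str, ControlStats] = per_plate_control_stats(kept)
    else:
        from .assay_quality import control_stats

        controls = control_stats(kept)
    hits, rejected, filtered_stats = call_hits(kept, cfg, controls)
    stages.append(StageResult("hit_call", n2, len(rejected), len(hits), rejected))
    hit_ids = hits["compound_id"].tolist()

    if retest is not None:
        confirmed, rej_retest = confirm_retest(hit_ids, retest, cfg, filtered_stats)
        stages.append(
            StageResult("retest_confirmation", len(hit_ids), len(rej_retest),
                        len(confirmed), rej_retest)
        )
    else:
        confirmed = hit_ids
        stages.append(
            StageResult("retest_confirmation", len(hit_ids), 0, len(hit_ids),
                        _empty_removed())
        )

    fits: dict[str, LogisticFit] = {}
    if cfg.dose_qc_enabled and doses is not None and confirmed:
        sub = doses[doses["compound_id"].isin(confirmed)]
        ref = None
        if retest is not None:
            try:
                from .assay_quality import control_stats

                ref = control_stats(retest).mu_p  # displaced probe ≈ free probe
            except ValueError:
                ref = None
        passed, failed, fits = dose_qc(sub, cfg, fp_free_reference=ref)
        # keep only compounds that entered the stage with dose data or were
        # removed; compounds lacking any dose series count as unevaluable
        have = set(sub["compound_id"])
        missing = [c for c in confirmed if c not in have]
        if missing:
            failed = pd.concat(
                [failed, pd.DataFrame({"plate_id": "", "well": "",
                                       "compound_id": missing,
                                       "reason": REASON_UNEVALUABLE})],
                ignore_index=True,
            )
        final = [c for c in confirmed if c in set(passed)]
        stages.append(
            StageResult("dose_response_qc", len(confirmed), len(failed), len(final),
                        failed)
        )
    else:
        final = confirmed
        stages.append(
            StageResult("dose_response_qc", len(confirmed), 0, len(confirmed),
                        _empty_removed())
        )

    report = TriageReport(
        stages=stages,
        fp_stats_raw=raw_stats,
        fp_stats_filtered=filtered_stats,
        final_hits=final,
        n_library=n0,
        ic50_fits=fits,
    )
    report.validate()
    return report
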