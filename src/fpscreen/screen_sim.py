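"""Synthetic 384-well FP screen generator with planted ground truth.

Emulates a single-concentration displacement screen of a 1,597-compound
library: 50 nM protein, 10 nM labeled RNA probe (Kd 20 nM), compounds at
10 µM, DMSO negative controls and 10 µM-unlabeled-RNA positive controls in
the outer columns of each 384-well plate.  Sample signals come from the exact
competitive-binding equilibrium (:mod:`fpscreen.equilibria`); on top of the
true inhibitors, three artifact classes are planted so that every stage of
the triage cascade has something to catch:

* ``aggregator``      — light-scattering/precipitation: positive FP offset and
                        a mild intensity increase (caught by the 2σ high-FP
                        filter);
* ``quencher``        — quenches the probe and fluoresces weakly at low
                        polarization: strong intensity loss plus an apparent
                        FP drop (caught by the 5σ intensity filter);
* ``autofluorescent`` — adds its own nearly unpolarized light: intensity gain
                        with a diluted FP reading.

Each simulated compound carries a :class:`CompoundTruth` record so cascade
performance (recall, stage-wise artifact removal) can be scored exactly.
Measurement noise is multiplicative Gaussian on the two readout channels (FP
and total intensity); the 2% default puts per-plate Z′ in the mid-0.8s, the
operating regime of a well-behaved FP displacement assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .curve_fits import TitrationPoint
from .equilibria import BindingSystem, FPSignalModel, fp_signal, solve_competitive, solve_single
from .plate_io import AssayMeta, ROWS, ScreenTable, WellRecord

__all__ = [
    "CompoundTruth",
    "SimConfig",
    "simulate_screen",
    "simulate_retest",
    "simulate_titration",
    "simulate_dose_series",
    "true_displacement",
    "score_recovery",
]

EFFECT_CLASSES = ("inactive", "inhibitor", "aggregator", "quencher", "autofluorescent")


@dataclass(frozen=True)
class CompoundTruth:
    """Ground truth for one simulated compound."""

    compound_id: str
    effect_class: str
    ki: float = math.nan  # nM; inhibitors only
    artifact_magnitude: float = math.nan  # class-specific, see module docstring

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")
        if self.effect_class == "inhibitor" and not self.ki > 0:
            raise ValueError("inhibitors need ki > 0")


@dataclass(frozen=True)
class SimConfig:
    """Study-design constants of the simulated screen.

    Defaults are the published assay: 1,597 compounds at 10 µM against 50 nM
    protein + 10 nM probe with Kd ≈ 20 nM; positive controls carry 10 µM
    unlabeled RNA competing with the probe's own affinity (ki = kd).
    """

    n_compounds: int = 1597
    p_tot: float = 50.0  # nM
    l_tot: float = 10.0  # nM
    kd: float = 20.0  # nM
    compound_conc_uM: float = 10.0
    pos_control_rna_uM: float = 10.0
    fp_free: float = 60.0
    fp_bound: float = 235.0
    q_ratio: float = 1.0
    intensity_free: float = 10000.0
    noise: float = 0.02  # multiplicative Gaussian σ per readout channel
    # planted class prevalences (fractions of the library)
    frac_inhibitor: float = 0.02
    frac_aggregator: float = 0.01
    frac_quencher: float = 0.01
    frac_autofluorescent: float = 0.005
    # inhibitor potencies: log-uniform Ki range, nM
    ki_range: tuple[float, float] = (10.0, 10000.0)
    aggregator_fp_offset: tuple[float, float] = (40.0, 100.0)
    aggregator_intensity_gain: tuple[float, float] = (1.05, 1.3)
    quencher_intensity_loss: tuple[float, float] = (0.1, 0.35)
    quencher_fp_offset: tuple[float, float] = (-80.0, -30.0)
    autofluor_intensity_gain: tuple[float, float] = (1.5, 3.0)
    autofluor_fp: float = 20.0  # polarization of the compound's own light, mP
    samples_per_plate: int = 352  # 16 neg + 16 pos controls in columns 1 and 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        total = (
            self.frac_inhibitor
            + self.frac_aggregator
            + self.frac_quencher
            + self.frac_autofluorescent
        )
        if total > 1:
            raise ValueError(f"class prevalences sum to {total} > 1")
        if self.noise < 0:
            raise ValueError("noise must be >= 0")

    @property
    def signal_model(self) -> FPSignalModel:
        return FPSignalModel(
            fp_free=self.fp_free,
            fp_bound=self.fp_bound,
            q_ratio=self.q_ratio,
            intensity_free=self.intensity_free,
        )

    @property
    def meta(self) -> AssayMeta:
        return AssayMeta(
            protein_conc_nM=self.p_tot,
            probe_conc_nM=self.l_tot,
            compound_conc_uM=self.compound_conc_uM,
        )


def _baseline_signal(cfg: SimConfig) -> tuple[float, float]:
    state = solve_single(BindingSystem(cfg.p_tot, cfg.l_tot, cfg.kd))
    return fp_signal(state, cfg.signal_model)


def _displaced_signal(cfg: SimConfig, i_tot_nM: float, ki: float) -> tuple[float, float]:
    state = solve_competitive(
        BindingSystem(cfg.p_tot, cfg.l_tot, cfg.kd, i_tot=i_tot_nM, ki=ki)
    )
    return fp_signal(state, cfg.signal_model)


def _assign_classes(cfg: SimConfig, rng: np.random.Generator) -> list[CompoundTruth]:
    n = cfg.n_compounds
    counts = {
        "inhibitor": round(cfg.frac_inhibitor * n),
        "aggregator": round(cfg.frac_aggregator * n),
        "quencher": round(cfg.frac_quencher * n),
        "autofluorescent": round(cfg.frac_autofluorescent * n),
    }
    labels = []
    for cls, k in counts.items():
        labels += [cls] * k
    labels += ["inactive"] * (n - len(labels))
    labels = [labels[i] for i in rng.permutation(n)]

    lo, hi = cfg.ki_range
    truths = []
    for i, cls in enumerate(labels):
        cid = f"CMPD{i + 1:05d}"
        if cls == "inhibitor":
            ki = float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))
            truths.append(CompoundTruth(cid, cls, ki=ki))
        elif cls == "aggregator":
            mag = float(rng.uniform(*cfg.aggregator_fp_offset))
            truths.append(CompoundTruth(cid, cls, artifact_magnitude=mag))
        elif cls == "quencher":
            mag = float(rng.uniform(*cfg.quencher_intensity_loss))
            truths.append(CompoundTruth(cid, cls, artifact_magnitude=mag))
        elif cls == "autofluorescent":
            mag = float(rng.uniform(*cfg.autofluor_intensity_gain))
            truths.append(CompoundTruth(cid, cls, artifact_magnitude=mag))
        else:
            truths.append(CompoundTruth(cid, cls))
    return truths


def _true_well_signal(
    cfg: SimConfig, truth: CompoundTruth, dose_uM: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Noise-free (fp, intensity) of a sample well for a given compound dose."""
    fp0, i0 = _baseline_signal(cfg)
    if truth.effect_class == "inactive":
        return fp0, i0
    if truth.effect_class == "inhibitor":
        return _displaced_signal(cfg, dose_uM * 1000.0, truth.ki)
    # artifact strength tracks dose, saturating (scattering/quenching plateau)
    scale = min(dose_uM / cfg.compound_conc_uM, 3.0)
    if truth.effect_class == "aggregator":
        return fp0 + truth.artifact_magnitude * scale, i0 * (
            1.0 + (float(np.mean(cfg.aggregator_intensity_gain)) - 1.0) * scale
        )
    if truth.effect_class == "quencher":
        loss = truth.artifact_magnitude ** scale if scale > 0 else 1.0
        offset = float(np.mean(cfg.quencher_fp_offset)) * scale
        return fp0 + offset, i0 * loss
    # autofluorescent: the compound's own light mixes into both channels
    extra = (truth.artifact_magnitude - 1.0) * scale * i0
    fp = (fp0 * i0 + cfg.autofluor_fp * extra) / (i0 + extra)
    return fp, i0 + extra


def _noisy(fp: float, intensity: float, cfg: SimConfig, rng: np.random.Generator):
    if cfg.noise == 0:
        return fp, intensity
    return (
        fp * (1.0 + cfg.noise * rng.standard_normal()),
        intensity * (1.0 + cfg.noise * rng.standard_normal()),
    )


def _control_wells(
    cfg: SimConfig, plate_id: str, rng: np.random.Generator
) -> list[WellRecord]:
    fp_n, i_n = _baseline_signal(cfg)
    fp_p, i_p = _displaced_signal(cfg, cfg.pos_control_rna_uM * 1000.0, cfg.kd)
    out = []
    for r in ROWS:  # column 1: DMSO vehicle; column 24: unlabeled-RNA displaced
        fp, it = _noisy(fp_n, i_n, cfg, rng)
        out.append(WellRecord(plate_id, r, 1, "", "neg_control", fp, it, 0.0))
    for r in ROWS:
        fp, it = _noisy(fp_p, i_p, cfg, rng)
        out.append(WellRecord(plate_id, r, 24, "", "pos_control", fp, it, 0.0))
    return out


def _sample_well_positions() -> list[tuple[str, int]]:
    return [(r, c) for c in range(2, 24) for r in ROWS]


def simulate_screen(cfg: SimConfig) -> tuple[ScreenTable, list[CompoundTruth]]:
    """Simulate the full single-concentration primary screen.

    Returns the screen table (samples + 16+16 controls per plate) and the
    per-compound ground truth.  Deterministic for a fixed ``cfg.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truths = _assign_classes(cfg, rng)
    positions = _sample_well_positions()
    records: list[WellRecord] = []
    plate_no, slot = 1, 0
    plate_id = f"P{plate_no:02d}"
    records += _control_wells(cfg, plate_id, rng)
    for truth in truths:
        if slot >= min(cfg.samples_per_plate, len(positions)):
            plate_no += 1
            slot = 0
            plate_id = f"P{plate_no:02d}"
            records += _control_wells(cfg, plate_id, rng)
        r, c = positions[slot]
        slot += 1
        fp, it = _true_well_signal(cfg, truth, cfg.compound_conc_uM, rng)
        fp, it = _noisy(fp, it, cfg, rng)
        records.append(
            WellRecord(plate_id, r, c, truth.compound_id, "sample", fp, it,
                       cfg.compound_conc_uM)
        )
    return ScreenTable.from_records(records, meta=cfg.meta), truths


def simulate_retest(
    cfg: SimConfig, truths: Sequence[CompoundTruth], compound_ids: Iterable[str]
) -> ScreenTable:
    """Re-measure the given compounds under the original screen conditions."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    by_id = {t.compound_id: t for t in truths}
    ids = list(compound_ids)
    unknown = [c for c in ids if c not in by_id]
    if unknown:
        raise KeyError(f"compounds without ground truth: {unknown}")
    positions = _sample_well_positions()
    if len(ids) > len(positions):
        raise ValueError("retest batch exceeds one plate")
    records = _control_wells(cfg, "RT01", rng)
    for (r, c), cid in zip(positions, ids):
        fp, it = _true_well_signal(cfg, by_id[cid], cfg.compound_conc_uM, rng)
        fp, it = _noisy(fp, it, cfg, rng)
        records.append(
            WellRecord("RT01", r, c, cid, "sample", fp, it, cfg.compound_conc_uM)
        )
    return ScreenTable.from_records(records, meta=cfg.meta)


def simulate_titration(
    cfg: SimConfig,
    mode: str,
    doses: Sequence[float],
    noise: float = 0.0,
) -> list[TitrationPoint]:
    """Exact-equilibrium titration curves, as ΔP against titrant concentration.

    ``mode="saturation"`` varies total protein (nM) at fixed probe;
    ``mode="displacement"`` varies unlabeled competitor (nM, ki = kd) at the
    screen's protein/probe composition.  ``noise`` adds multiplicative
    Gaussian error on ΔP (0 = exact).
    """
    if len(doses) == 0:
        raise ValueError("empty dose list")
    if mode not in ("saturation", "displacement"):
        raise ValueError(f"unknown titration mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    model = cfg.signal_model
    pts = []
    for x in doses:
        if mode == "saturation":
            state = solve_single(BindingSystem(float(x), cfg.l_tot, cfg.kd))
        else:
            state = solve_competitive(
                BindingSystem(cfg.p_tot, cfg.l_tot, cfg.kd, i_tot=float(x), ki=cfg.kd)
            )
        fp, _ = fp_signal(state, model)
        dp = fp - cfg.fp_free
        if noise > 0:
            dp *= 1.0 + noise * rng.standard_normal()
        pts.append(TitrationPoint(float(x), dp))
    return pts


def default_dose_series(start_uM: float = 250.0, n: int = 10, factor: float = 2.0):
    """Two-fold serial dilution from 250 µM, matching the confirmation design."""
    return [start_uM / factor**k for k in range(n)]


def simulate_dose_series(
    cfg: SimConfig,
    truths: Sequence[CompoundTruth],
    compound_ids: Iterable[str],
    doses: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Dose-response series for the given compounds (long format).

    Columns: compound_id, dose_uM, fp_mP, total_intensity.  Inhibitor series
    fall monotonically with dose; aggregator/autofluorescence artifacts grow
    with dose, so their FP rises — exactly what the dose-QC stage removes.
    """
    by_id = {t.compound_id: t for t in truths}
    ids = list(compound_ids)
    unknown = [c for c in ids if c not in by_id]
    if unknown:
        raise KeyError(f"compounds without ground truth: {unknown}")
    if doses is None:
        doses = default_dose_series()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    rows = []
    for cid in ids:
        for d in doses:
            fp, it = _true_well_signal(cfg, by_id[cid], float(d), rng)
            fp, it = _noisy(fp, it, cfg, rng)
            rows.append(
                {"compound_id": cid, "dose_uM": float(d), "fp_mP": fp,
                 "total_intensity": it}
            )
    return pd.DataFrame(rows, columns=["compound_id", "dose_uM", "fp_mP",
                                       "total_intensity"])


def true_displacement(cfg: SimConfig, truth: CompoundTruth) -> float:
    """Fraction of bound probe displaced by the compound at screen dose.

    1 − [PL](with compound)/[PL](without); 0 for non-inhibitors.
    """
    if truth.effect_class != "inhibitor":
        return 0.0
    pl0 = solve_single(BindingSystem(cfg.p_tot, cfg.l_tot, cfg.kd)).pl
    pl = solve_competitive(
        BindingSystem(cfg.p_tot, cfg.l_tot, cfg.kd,
                      i_tot=cfg.compound_conc_uM * 1000.0, ki=truth.ki)
    ).pl
    return 1.0 - pl / pl0


def score_recovery(cfg: SimConfig, truths: Sequence[CompoundTruth], report) -> dict:
    """Score a TriageReport against ground truth.

    Returns inhibitor recall (restricted to inhibitors with true displacement
    > 50%, the population the cascade is designed to keep) and the fraction
    of each planted artifact class removed at its intended stage.
    """
    by_stage = {s.stage: s for s in report.stages}
    removed_a = set(by_stage["high_fp_filter"].removed["compound_id"])
    removed_b = set(by_stage["low_intensity_filter"].removed["compound_id"])
    final = set(report.final_hits)

    strong = [
        t for t in truths
        if t.effect_class == "inhibitor" and true_displacement(cfg, t) > 0.5
    ]
    aggregators = [t for t in truths if t.effect_class == "aggregator"]
    quenchers = [t for t in truths if t.effect_class == "quencher"]

    def frac(selected: set, pop) -> float:
        return (
            sum(t.compound_id in selected for t in pop) / len(pop) if pop else math.nan
        )

    return {
        "n_strong_inhibitors": len(strong),
        "inhibitor_recall": frac(final, strong),
        "aggregator_removed_stage_a": frac(removed_a, aggregators),
        "quencher_removed_stage_b": frac(removed_b, quenchers),
        "n_final_hits": len(final),
        "hit_rate_percent": report.hit_rate,
    }


def truth_frame(truths: Sequence[CompoundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "compound_id": t.compound_id,
                "effect_class": t.effect_class,
                "ki_nM": t.ki,
                "artifact_magnitude": t.artifact_magnitude,
            }
            for t in truths
        ]
    )
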