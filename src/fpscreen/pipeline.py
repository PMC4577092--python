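"""End-to-end orchestration: simulate → QC → triage → fits → report.

``run_all`` executes the whole pipeline from a YAML configuration and writes a
report directory containing the screen tables, per-plate QC, per-stage triage
CSVs, an IC50 table, a JSON summary, and a run manifest (tool version, config
snapshot, input digests, seed).  Given the same seed and configuration, every
CSV and the JSON summary are byte-identical across reruns; only the manifest's
timestamp differs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .assay_quality import control_stats, qc_report, zprime
from .curve_fits import fit_logistic, fit_saturation
from .hit_triage import TriageConfig, TriageReport, run_cascade
from .plate_io import read_screen, write_screen
from .screen_sim import (
    SimConfig,
    default_dose_series,
    score_recovery,
    simulate_dose_series,
    simulate_retest,
    simulate_screen,
    simulate_titration,
    truth_frame,
)

__all__ = ["RunManifest", "PipelineConfig", "run_all"]


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class RunManifest:
    tool_version: str
    seed: int
    config: dict
    input_digests: dict[str, str]
    created_utc: str

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level run configuration: simulate a screen or load one from disk."""

    sim: SimConfig | None = None
    screen_path: str | None = None
    retest_path: str | None = None
    doses_path: str | None = None
    layout_path: str | None = None
    triage: TriageConfig = TriageConfig()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        sim = None
        if "simulate" in raw:
            try:
                sim = SimConfig(**(raw["simulate"] or {}))
            except TypeError as e:
                raise ConfigurationError(f"bad simulate section: {e}") from None
        inputs = raw.get("inputs", {}) or {}
        try:
            triage = TriageConfig(**(raw.get("triage", {}) or {}))
        except TypeError as e:
            raise ConfigurationError(f"bad triage section: {e}") from None
        cfg = cls(
            sim=sim,
            screen_path=inputs.get("screen"),
            retest_path=inputs.get("retest"),
            doses_path=inputs.get("doses"),
            layout_path=inputs.get("layout"),
            triage=triage,
        )
        if cfg.sim is None and cfg.screen_path is None:
            raise ConfigurationError(
                "config must provide either a 'simulate' section or inputs.screen"
            )
        return cfg

    def to_dict(self) -> dict:
        out: dict = {"triage": dataclasses.asdict(self.triage)}
        if self.sim is not None:
            out["simulate"] = dataclasses.asdict(self.sim)
        inputs = {
            k: v
            for k, v in {
                "screen": self.screen_path,
                "retest": self.retest_path,
                "doses": self.doses_path,
                "layout": self.layout_path,
            }.items()
            if v
        }
        if inputs:
            out["inputs"] = inputs
        return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.write_text(df.to_csv(index=False, lineterminator="\n"))


def run_all(
    config: PipelineConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Run the full pipeline; returns the JSON-serializable summary.

    ``seed`` overrides the seed in the simulate section (ignored for
    file-based runs, whose inputs are already fixed).
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, str] = {}
    truths = None

    if config.sim is not None:
        sim = config.sim if seed is None else dataclasses.replace(config.sim, seed=seed)
        screen, truths = simulate_screen(sim)
        write_screen(screen, out / "screen.csv")
    else:
        sim = None
        p = Path(config.screen_path)
        if not p.exists():
            raise ConfigurationError(f"screen input not found: {p}")
        digests[str(p)] = _sha256(p)
        screen = read_screen(p, layout=config.layout_path)
    screen.check_control_minima()

    # --- assay quality -----------------------------------------------------
    qc = qc_report(screen)
    _write_csv(qc, out / "qc_per_plate.csv")
    assay_stats = control_stats(screen)
    assay_zprime = zprime(assay_stats)

    # --- hit triage (with retest / dose follow-up) --------------------------
    cfg_t = config.triage
    if sim is not None:
        from .hit_triage import call_hits, filter_high_fp, filter_low_intensity
        from .assay_quality import per_plate_control_stats

        kept, _, _ = filter_high_fp(screen, cfg_t)
        kept, _ = filter_low_intensity(kept, cfg_t)
        controls = (
            per_plate_control_stats(kept)
            if cfg_t.inhibition_scope == "plate"
            else control_stats(kept)
        )
        primary_hits, _, _ = call_hits(kept, cfg_t, controls)
        hit_ids = primary_hits["compound_id"].tolist()
        retest = simulate_retest(sim, truths, hit_ids) if hit_ids else None
        doses = (
            simulate_dose_series(sim, truths, hit_ids, default_dose_series())
            if hit_ids
            else None
        )
        if retest is not None:
            write_screen(retest, out / "retest.csv")
        if doses is not None:
            _write_csv(doses, out / "doses.csv")
        _write_csv(truth_frame(truths), out / "truth.csv")
    else:
        retest = None
        doses = None
        if config.retest_path:
            p = Path(config.retest_path)
            digests[str(p)] = _sha256(p)
            retest = read_screen(p)
        if config.doses_path:
            p = Path(config.doses_path)
            digests[str(p)] = _sha256(p)
            doses = pd.read_csv(p)

    report: TriageReport = run_cascade(screen, retest, doses, cfg_t)
    for s in report.stages:
        _write_csv(s.removed, out / f"stage_{s.stage}_removed.csv")

    ic50_rows = [
        {
            "compound_id": cid,
            "ic50": f.ic50,
            "unit": f.x_unit,
            "hill_slope": f.p,
            "converged": f.converged,
        }
        for cid, f in sorted(report.ic50_fits.items())
    ]
    _write_csv(
        pd.DataFrame(ic50_rows, columns=["compound_id", "ic50", "unit",
                                         "hill_slope", "converged"]),
        out / "ic50.csv",
    )

    summary = {
        "schema_version": 1,
        "assay_zprime": assay_zprime,
        "per_plate_zprime": dict(zip(qc["plate_id"], qc["zprime"])),
        "triage": report.summary(),
    }
    if sim is not None and truths is not None:
        summary["recovery"] = score_recovery(sim, truths, report)

    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest = RunManifest(
        tool_version=__version__,
        seed=(sim.seed if sim is not None else -1),
        config=(
            config.to_dict()
            if sim is None
            else dataclasses.replace(config, sim=sim).to_dict()
        ),
        input_digests=digests,
        created_utc=datetime.now(timezone.utc).isoformat(),
    )
    (out / "manifest.json").write_text(manifest.to_json())
    return summary


def fit_titrations(sim: SimConfig, out_dir: str | Path | None = None) -> dict:
    """Fit the two printed equations to exact-equilibrium titrations.

    Saturation: 8-point protein titration at fixed probe → apparent Kd.
    Displacement: half-log competitor doses → IC50 from the log-logistic.
    """
    sat_doses = [1, 5, 10, 20, 50, 100, 200, 500]
    sat = fit_saturation(simulate_titration(sim, "saturation", sat_doses))
    disp_doses = [10 ** (0.25 * k) for k in range(0, 17)]  # 1 nM … 10 µM
    disp = fit_logistic(simulate_titration(sim, "displacement", disp_doses))
    result = {
        "saturation": {"kd_apparent_nM": sat.kd, "delta_p_max": sat.delta_p_max,
                       "converged": sat.converged},
        "displacement": {"ic50_nM": disp.ic50, "hill_slope": disp.p,
                         "converged": disp.converged},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "titration_fits.json").write_text(
            json.dumps(result, indent=2, sort_keys=True)
        )
    return result
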