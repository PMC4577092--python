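"""Run the five-stage hit-triage cascade on the simulated screen.

Reads results/screen/, simulates the retest plate and dose series for the
primary hits, and writes results/triage/: per-stage removal tables, the IC50
table for final hits, and the JSON summary with the hit rate.
"""

from pathlib import Path

from fpscreen.assay_quality import per_plate_control_stats
from fpscreen.hit_triage import (
    TriageConfig,
    call_hits,
    filter_high_fp,
    filter_low_intensity,
    run_cascade,
)
from fpscreen.plate_io import read_screen, write_screen
from fpscreen.screen_sim import SimConfig, simulate_dose_series, simulate_retest
import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    out = ROOT / "triage"
    out.mkdir(parents=True, exist_ok=True)
    screen = read_screen(ROOT / "screen" / "screen.csv")
    truth = pd.read_csv(ROOT / "screen" / "truth.csv")
    cfg = SimConfig(seed=SEED)
    tcfg = TriageConfig()

    # primary pass to learn which compounds need follow-up plates
    kept, _, _ = filter_high_fp(screen, tcfg)
    kept, _ = filter_low_intensity(kept, tcfg)
    hits, _, _ = call_hits(kept, tcfg, per_plate_control_stats(kept))
    ids = hits["compound_id"].tolist()

    from fpscreen.screen_sim import CompoundTruth

    truths = [
        CompoundTruth(r.compound_id, r.effect_class,
                      ki=r.ki_nM, artifact_magnitude=r.artifact_magnitude)
        for r in truth.itertuples(index=False)
    ]
    retest = simulate_retest(cfg, truths, ids)
    doses = simulate_dose_series(cfg, truths, ids)
    write_screen(retest, out / "retest.csv")
    doses.to_csv(out / "doses.csv", index=False, lineterminator="\n")

    report = run_cascade(screen, retest, doses, tcfg)
    for s in report.stages:
        s.removed.to_csv(out / f"stage_{s.stage}_removed.csv", index=False,
                         lineterminator="\n")
        print(f"{s.stage:24s} in={s.n_in:5d} removed={s.n_removed:4d} "
              f"out={s.n_out:5d}")
    (out / "triage_summary.json").write_text(report.to_json())
    print(f"\nFP sigma raw -> filtered: {report.fp_stats_raw.sigma:.1f} -> "
          f"{report.fp_stats_filtered.sigma:.1f}")
    print(f"final hits: {len(report.final_hits)} "
          f"(hit rate {report.hit_rate:.2f}% of {report.n_library})")


if __name__ == "__main__":
    main()
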