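"""Simulate the primary screen: 1,597 compounds, 384-well plates, planted truth.

Writes results/screen/: the screen table, the per-compound ground truth, and a
class census.  Everything downstream (02-05) reads these files.
"""

from pathlib import Path

from fpscreen.plate_io import write_screen
from fpscreen.screen_sim import SimConfig, simulate_screen, truth_frame

OUT = Path(__file__).resolve().parent.parent / "results" / "screen"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=SEED)
    screen, truths = simulate_screen(cfg)
    write_screen(screen, OUT / "screen.csv")
    tf = truth_frame(truths)
    tf.to_csv(OUT / "truth.csv", index=False, lineterminator="\n")
    census = tf["effect_class"].value_counts()
    census.to_csv(OUT / "class_census.csv", lineterminator="\n")
    print(f"simulated {len(truths)} compounds on {len(screen.plates())} plates "
          f"(seed {SEED})")
    print(census.to_string())
    print(f"tables in {OUT}")


if __name__ == "__main__":
    main()
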