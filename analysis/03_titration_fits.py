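"""Characterize the binding before screening: saturation Kd and displacement IC50.

Generates exact-equilibrium titrations at the assay composition (10 nM probe,
Kd 20 nM; 50 nM protein for displacement) and fits the two standard equations:
the depletion-free hyperbola (apparent Kd) and the log-logistic (IC50).
Writes results/titration_fits.json.
"""

import json
from pathlib import Path

from fpscreen.pipeline import fit_titrations
from fpscreen.screen_sim import SimConfig

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    result = fit_titrations(SimConfig(seed=1), ROOT)
    print(json.dumps(result, indent=2, sort_keys=True))
    kd = result["saturation"]["kd_apparent_nM"]
    ic50 = result["displacement"]["ic50_nM"]
    print(f"\napparent Kd = {kd:.1f} nM (true 20 nM: the hyperbolic fit ignores "
          f"probe depletion, biasing Kd high)")
    print(f"displacement IC50 = {ic50:.1f} nM (exact half-displacement dose "
          f"105.95 nM at ki = kd = 20 nM)")


if __name__ == "__main__":
    main()
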