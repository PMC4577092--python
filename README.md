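# fpscreen

Analysis pipeline for fluorescence-polarization (FP) displacement screens of
protein–RNA interactions, plus a synthetic 384-well screen generator for
validating every stage of the analysis against known ground truth.

## The problem

A small fluorescently labeled RNA probe tumbles quickly in solution and emits
depolarized light (low mP); bound to its target protein it tumbles slowly and
the polarization rises.  A compound that displaces the probe from the protein
pulls the FP reading back down.  That readout supports a competitive
high-throughput screen: wells with protein + probe + compound at a single
dose, DMSO vehicle wells as the high-FP negative control, and wells with
excess unlabeled RNA as the low-FP (fully displaced) positive control.

`fpscreen` implements the pieces a screener needs around that readout:

- **Equilibria** — exact mass-balance solutions of P + L ⇌ PL and the
  two-ligand competition P + L ⇌ PL, P + I ⇌ PI (no "free ≈ total"
  shortcut), mapped to (FP, total intensity) readings.
- **Curve fits** — the two standard equations:
  saturation ΔP = ΔPmax·[P]/(K_d + [P]) for apparent affinity, and the
  log-logistic ΔP = ΔPmax/(1 + 10^((log x₀ − X)·p)) with X = log₁₀(dose) for
  IC50s.
- **Assay quality** — Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| per plate and
  assay-wide, and percent inhibition anchored to the controls.
- **Hit triage** — a five-stage cascade with a full audit trail:
  (A) drop wells > mean + 2σ FP (precipitation/quenching artifacts),
  (B) drop FP-decreasing wells whose total fluorescence is > 5σ below the
  sample mean (intrinsically fluorescent compounds), (C) recompute mean/σ and
  call hits at FP < mean − 3σ with > 50% inhibition, (D) confirm by retest at
  the same cutoff, (E) reject compounds whose FP *rises* with dose and fit
  IC50s for the rest.
- **Screen simulator** — a 1,597-compound library at 10 µM against 50 nM
  protein + 10 nM probe (K_d 20 nM), with planted inhibitors (log-uniform
  K_i), aggregators, quenchers and autofluorescent compounds, each carrying
  ground truth for recovery scoring.

## Worked example

```python
from fpscreen import BindingSystem, solve_single, solve_competitive

# assay operating point: 50 nM protein, 10 nM probe, Kd 20 nM
solve_single(BindingSystem(50, 10, 20)).frac_bound          # 0.683
# add 10 uM of a Ki = 100 nM competitor: probe almost fully displaced
solve_competitive(BindingSystem(50, 10, 20, 10000, 100)).frac_bound  # 0.024
```

The numbered scripts under `analysis/` run the whole study on the simulator
(each writes its tables under `results/`):

```text
$ python analysis/01_simulate_screen.py
simulated 1597 compounds on 5 plates (seed 1)
inactive 1525 / inhibitor 32 / aggregator 16 / quencher 16 / autofluorescent 8

$ python analysis/02_assay_quality.py
assay-wide Z' = 0.882; mean per-plate Z' = 0.884

$ python analysis/03_titration_fits.py
apparent Kd = 26.7 nM (true 20 nM: the hyperbolic fit ignores probe
depletion, biasing Kd high)
displacement IC50 = 109.0 nM (exact half-displacement dose 105.95 nM)

$ python analysis/04_triage_cascade.py
high_fp_filter           in= 1597 removed=  16 out= 1581
low_intensity_filter     in= 1581 removed=  16 out= 1565
hit_call                 in= 1565 removed=1529 out=   36
retest_confirmation      in=   36 removed=   0 out=   36
dose_response_qc         in=   36 removed=   0 out=   36
FP sigma raw -> filtered: 18.3 -> 15.8
final hits: 36 (hit rate 2.25% of 1597)
```

A Z′ near 0.88 means the control separation dwarfs control noise — a
comfortably HTS-ready window.  The 2σ stage removes exactly the 16 planted
aggregators; the 5σ stage catches the quenchers; the recovered hit list is
dominated by the planted inhibitors potent enough to displace > 50% of the
probe at 10 µM.  `analysis/05_recovery_benchmark.py` repeats this over 20
replicate screens (mean inhibitor recall 0.99, aggregator removal 1.00,
quencher removal 0.96).

The same pipeline runs from a shell on real or simulated CSV tables:

```bash
fpscreen simulate --seed 1 --out run/
fpscreen qc --screen run/screen.csv
fpscreen triage --screen run/screen.csv --out run/report/
fpscreen run-all --config config.yaml --seed 1 --out run/report/
```

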