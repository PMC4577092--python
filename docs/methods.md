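# Methods

## Binding model

The assay is modeled as two coupled dissociation equilibria over total
concentrations (all nM internally):

    P + L ⇌ PL   K_d = [P][L]/[PL]
    P + I ⇌ PI   K_i = [P][I]/[PI]

with mass balances P_tot = [P] + [PL] + [PI], L_tot = [L] + [PL],
I_tot = [I] + [PI].  L is the labeled RNA probe, I an unlabeled competitor
(unlabeled RNA or a screening compound).  The single-site case has the
closed-form physical root of the binding quadratic, evaluated in the
cancellation-free form 2pl/(b + √(b² − 4pl)).  The competitive case is solved
by a bracketed Brent root find on free protein over [0, P_tot]: given [P],
both complexes follow analytically, and the protein-balance residual is
strictly monotone in [P], so the bracket always contains exactly one root.
Solutions are post-checked against all three mass balances at 1e−9 relative
tolerance.  Assumptions: one binding site per protein, no cooperativity, no
oligomer-linked binding, no ternary complexes.

The FP reading of a mixed population is the intensity-weighted average
fp = (q·[PL]·fp_bound + [L]·fp_free)/(q·[PL] + [L]), with q the bound/free
quantum-yield ratio (default 1: binding changes polarization, not
brightness); total intensity is proportional to the summed weight, normalized
to `intensity_free` for fully free probe.  With q = 1, FP is exactly linear
in the bound fraction.

## Fit equations

Two deliberately simplified equations are fit to titration data, because they
are what screeners actually fit:

- saturation: ΔP = ΔPmax·x/(K_d + x), x = total protein.  This ignores probe
  depletion; with 10 nM probe against K_d = 20 nM the apparent K_d fitted to
  exact-equilibrium data is ≈ 27 nM versus the true 20 nM.  The package keeps
  the simplified equation for fitting (the field's convention) and documents
  the bias rather than hiding it; the exact solver is used for simulation.
- log-logistic: ΔP = ΔPmax/(1 + 10^((log x₀ − X)·p)), X = log₁₀(dose),
  IC50 = 10^{log x₀}.  The Hill slope p may take either sign so the same
  equation serves rising responses and falling displacement curves.

Both use bounded least squares (`scipy.optimize.least_squares`) with analytic
starting values (ΔPmax from the data extreme, K_d / log x₀ from interpolated
half-max, p = ±1 from the data trend).  Degenerate inputs (flat signal,
half-max outside the dose range by > 2 decades, |p| < 1e−6) are returned with
`converged=False`, never as silent numbers.  Parameter standard errors come
from the Gauss–Newton covariance (JᵀJ)⁻¹·s².

At the screen composition, the exact dose of a K_i = K_d = 20 nM competitor
that halves [PL] is 105.95 nM; the log-logistic IC50 fitted to the exact
displacement curve lands within 3% of it.  The logistic is an approximation
to the exact competition isotherm, which is why the agreement is close but
not exact.

## Assay quality

Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| over positive (displaced, low-FP) and
negative (DMSO, high-FP) controls; σ uses the sample (n−1) denominator, the
right choice for 16-well control sets.  Percent inhibition is
100·(μ_n − FP)/(μ_n − μ_p), deliberately unclipped: readings outside [0, 100]
are diagnostic of artifacts.  Per-plate control statistics are the default
reference for inhibition (robust to plate-to-plate drift); assay-global
statistics are available by configuration.

## Hit-triage cascade

Stages, in order, with all σ thresholds strict (a well exactly on a threshold
is kept — the rule is declared once and boundary-tested):

1. **High-FP filter (2σ)** — statistics over all raw sample wells; removes
   FP > mean + 2σ.  Targets scattering/precipitation artifacts.
2. **Low-intensity filter (5σ)** — among FP-decreasing wells only (FP below
   the sample mean), removes wells whose total-fluorescence reading is more
   than 5σ below that channel's sample mean.  The channel is configurable:
   the default reads the total-intensity channel's own statistics; a
   compatibility option applies the 5σ rule on the FP axis instead, since
   both conventions exist in practice and they differ in what they catch.
3. **Hit call (3σ + inhibition floor)** — mean/σ recomputed over survivors;
   hit ⇔ FP < mean − 3σ AND inhibition > 50%.  The σ criterion is evaluated
   first, so each rejection carries a single primary reason.
4. **Retest** — primary hits re-measured under original conditions and
   re-judged.  The cutoff statistics are frozen from the filtered primary
   screen by default ("the same cutoff"): a retest batch consists mostly of
   true actives, so recomputing mean − 3σ within the batch would move the
   threshold below almost every genuine hit.  Batch-local statistics remain
   available (`retest_stats="batch"`) for screens whose primary hit lists are
   noise-dominated.
5. **Dose-response QC** — a compound whose FP *rises* with dose is behaving
   like an aggregator, not an inhibitor.  The trend test is the Theil–Sen
   slope of FP against log₁₀(dose) with a minimum magnitude of 5 mP/decade
   (median-based, so a single bad well cannot flip the verdict; the magnitude
   floor keeps flat-but-jittery series from failing).  Survivors get
   log-logistic IC50 fits referenced to the displaced-control FP.

No multiple-testing correction is applied: the cascade uses fixed σ cutoffs,
and its false-positive behavior is characterized by simulation instead (the
3σ stage alone selects ≈ Φ(−3) ≈ 0.13% of pure-noise wells; the inhibition
floor then removes essentially all of them when the assay window is wide).

Report invariants, asserted on every run: stage counts telescope
(inₖ₊₁ = inₖ − removedₖ), every removed well carries exactly one reason, and
the final hit list is a subset of the library.  Raising any threshold can
only shrink the hit set.

## Screen simulator

The simulator emulates a single-concentration screen of 1,597 compounds at
10 µM against 50 nM protein + 10 nM probe with K_d = 20 nM, on 384-well
plates of 352 samples plus 16 negative (column 1) and 16 positive (column 24)
controls; positive controls carry 10 µM unlabeled competitor at K_i = K_d.
Default planted classes: 2% inhibitors (K_i log-uniform on 10 nM–10 µM, so
the library spans complete to negligible displacement at screen dose), 1%
aggregators (FP offset +40–100 mP, mild intensity gain), 1% quenchers
(intensity × 0.10–0.35 plus an apparent FP drop of 30–80 mP — a compound
whose absorbance/emission overwhelms the probe signal), 0.5% autofluorescent
compounds (1.5–3× intensity of nearly unpolarized light, diluting the FP
reading).  Artifact strength scales with dose and saturates at 3× the screen
dose.

Noise is multiplicative Gaussian, default 2%, applied independently to the
two reported readout channels (FP in mP and total intensity).  This yields
per-plate Z′ ≈ 0.88 and inactive-well FP σ ≈ 3.6 mP — the operating regime of
a well-behaved FP assay; the sample-well FP σ (~18 mP raw) is dominated by
the planted effect classes, not by measurement noise.

What the simulator does **not** model: plate spatial gradients and edge
effects (off by default, not simulated), compound-compound interactions,
liquid-handling failures, probe photobleaching, or mechanism beyond direct
competition — an inhibitor acting by disrupting protein oligomerization is
signal-equivalent at the FP readout and is not modeled separately.  Passing
recovery tests therefore demonstrates that the cascade implements its rules
correctly and recovers planted effects under realistic noise; it does not
certify performance on real screens, whose artifact prevalences and shapes
are unknown.

Determinism: every entry point takes a single seed, fanned out to named
substreams (class assignment, screen noise, retest noise, dose noise) via
`numpy.random.SeedSequence`, so stages rerun in isolation reproduce exactly.
Identical seed + config gives byte-identical CSV output; CSVs are written
with full float precision and read back with round-trip parsing.

## Problem sizes

The recovery benchmark and the acceptance script use 20 replicate
full-library screens (1,597 compounds each) — enough to average the
per-seed variability of the small artifact classes (16 wells per class) —
and 1,000 randomized systems for the solver/oracle comparison.  Recovery
criteria are stated as 20-seed means: single-seed artifact-removal fractions
fluctuate because the 5σ intensity threshold depends on the channel σ, which
the autofluorescent class inflates in some replicates.

## Known limitations

- The apparent K_d from the saturation fit is a *conditional* constant of the
  assay composition, not a thermodynamic K_d, whenever probe ≈ K_d.
- IC50s from single-dose-series fits inherit the usual identifiability
  caveats when the tested range does not bracket the half-displacement dose;
  such fits are flagged, not suppressed.
- The autofluorescent class is deliberately *not* removed by the default
  (one-sided) intensity filter; with a strong artifact it can survive to the
  final hit list, mirroring the false-positive classes that downstream
  orthogonal assays exist to catch.  The two-sided filter option removes it
  at stage B.
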