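# Methods

## Disposition model behind the simulator

Plasma kinetics are generated from a linear two-compartment model
parameterized by micro-constants: clearance CL (mL/min/kg), central
volume V1 (mL/kg), inter-compartmental clearance Q (mL/min/kg) and
peripheral volume V2 (mL/kg). With k10 = CL/V1, k12 = Q/V1,
k21 = Q/V2, the disposition exponents are the roots of
λ² − (k10+k12+k21)λ + k10·k21, and an IV bolus gives

    C(t) = A e^(−αt) + B e^(−βt),   A = C0(α−k21)/(α−β),
    B = C0(k21−β)/(α−β),            C0 = Dose/V1.

Setting Q = 0 collapses the model to one compartment exactly
(β = 0 with a vanishing coefficient), which keeps the simple closed
forms available for oracle tests. Oral dosing adds first-order
absorption ka into the central compartment with the dose scaled by the
true bioavailability F; the standard three-exponential solution is
used, flip-flop (ka < β) included. When ka coincides with a
disposition exponent the closed form is degenerate; ka is perturbed by
a relative 1e−6 and a warning is raised.

The micro-constant parameterization was chosen over (A, α, B, β)
macro-constants so that every non-compartmental truth value is
analytic: CL and Vss = V1 + V2 are inputs, AUC∞ = F·Dose/CL follows
from mass balance, and the terminal half-life is ln2/β.

### Default population (the study conditions)

| parameter | default | unit | rationale |
|---|---|---|---|
| CL | 31.4 | mL/min/kg | IV group-mean clearance |
| V1 / V2 | 1100 / 3204 | mL/kg | Vss = 4304 mL/kg split so that, with Q, t½ matches |
| Q | 15 | mL/min/kg | gives terminal t½ ≈ 227 min (reported 226 ± 34) and MRT 137 min |
| ka | 0.03 | 1/min | Tmax in the reported 30–60 min band |
| F | 0.0229 | — | reported oral bioavailability at 10 mg/kg |
| fe (IV) | 0.00839 | — | urinary recovery 0.839 % of dose |
| GI24 (IV) | 0.0344 | — | GI-tract recovery 3.44 % of dose |
| ω | 0.25 | — | log-normal between-subject SD, matching the reported ±20–40 % spreads |
| σ_prop | 0.10 | — | proportional residual error |
| LLOQ | 1e−3 | μg/mL | 1 ng/mL quantitation limit |
| schedules | 0,1,5,…,360 (IV); 0,5,…,360 (oral) | min | study sampling times |

Between-subject variability is applied log-normally and independently
to CL, V1, Q, V2 and ka — no correlation structure is imposed because
none is identifiable from group summaries. Residual error is
proportional only; the LLOQ censoring stands in for an additive noise
floor. Censored points are flagged and kept, never dropped.
Excretion, dialysis and S9 noise is multiplicative log-normal
(exp(σz)), which keeps the records positive and makes the zero-noise
case an exact identity; the S9 generator additionally clips the
proportional form at zero.

What the generator does **not** emulate: tissue concentrations are
plasma × a target T/P ratio rather than a mechanistic PBPK
distribution; peak lists are centroided sticks (no chromatographic
peak shapes, isotope patterns or co-eluting interferences); and
enterohepatic recirculation is absent. Passing tests therefore show
that the analysis chain inverts data with the assumed statistical
structure — not that real mouse data satisfy those assumptions.

## Non-compartmental analysis

- **AUC/AUMC**: linear trapezoid, or linear-up/log-down (default,
  standard for bolus decline): a segment uses
  (C1−C2)Δt/ln(C1/C2) only when C1 > C2 > 0, linear otherwise, with
  the matching exact log-segment AUMC formula.
- **λz**: unweighted least squares of ln C vs t over all suffixes of
  the post-Cmax quantifiable points (Cmax itself excluded for oral
  profiles) with ≥ 3 points; the window maximizing adjusted R² wins,
  ties (within 1e−9) broken toward more points; a positive slope in
  every window raises a named "not estimable" error, in which case the
  extrapolated parameters are withheld but AUC_last is still reported.
- **Extrapolation**: AUC∞ = AUC_last + Ĉ_last/λz with Ĉ_last the
  λz-fit prediction at the last quantifiable time;
  AUMC∞ = AUMC_last + t_last·Ĉ_last/λz + Ĉ_last/λz².
- **BLQ policy**: leading censored points (pre-absorption) count as
  zero; embedded and trailing censored points are excluded from both
  integration and the terminal fit.
- **IV t = 0**: the observed value is used when sampled; if absent, C0
  is back-extrapolated log-linearly from the first two points.
- **Cmax/Tmax** are read from observed quantifiable points without
  interpolation; group Tmax is summarized as median (range), all other
  parameters as mean ± SD of per-subject values (group statistics are
  computed on per-subject parameters, not on the mean profile).

On noise-free dense profiles (Δt = 1 min to 10 terminal half-lives,
the problem size used throughout the tests and the acceptance script)
the chain recovers CL to ≪ 1 % and Vss to ≪ 1 %; on the sparse
360-min study schedule the truncation costs a few percent, tracked by
auc_extrap_pct (kept below 20 %).

## Dose linearity

The verdict is keyed to the omnibus test on dose-normalized
per-subject values: classical equal-variance one-way ANOVA for ≥ 3
groups (unpaired two-sided t-test for 2), dose-independent iff
p ≥ α = 0.05. Tukey HSD pairwise comparisons on the ANOVA residual
variance are reported as supporting evidence only. The classical
equal-variance forms are used deliberately, matching standard practice
for this design; tests validate them against label-permutation oracles
(agreement within 0.02 in p).

## Derived ADME metrics

- T/P ratio = homogenate concentration × dilution factor / plasma
  concentration. The default factor 5 reflects homogenization of one
  part tissue with four volumes of water and is configurable.
- Binding: bound% = 100(C_plasma − C_buffer)/C_plasma, fu = 1 −
  bound%/100. Buffer > plasma pairs are flagged, not rejected.
- CL_R,fu = CL_R/fu, compared against the mouse GFR reference
  14.0 mL/min/kg; values below it are consistent with excretion by
  glomerular filtration alone.
- F_unabs: the subtractive correction GI24_oral − F·GI24_iv is the
  default because it reproduces the reported 0.434 from the study's
  group means; a normalized variant dividing by (1 − F) is selectable.
  The function is monotone increasing in GI24_oral and decreasing in F
  and GI24_iv; out-of-range results are flagged, not clipped.
- S9 disappearance = 100(1 − remaining/spiked); negative values
  (assay noise) are clipped to zero with a warning.

## Metabolite annotation

Rule shifts are recomputed at load time from elemental compositions
via monoisotopic atomic masses (pyteomics), never hard-coded: the
computed glucuronide/bis-glucuronide shifts are 176.0321/352.0642 Da
(internally exactly 2:1), and the integer nominal shifts are reported
alongside for parity with common reporting practice. The default
precursor and fragment tolerances are 0.5 Da — unit-resolution
triple-quadrupole data; the largest mass error in the bundled
reference list is ≈ 0.36 Da — and both are configurable. Fragment
evidence counts observed product ions matching the prenyl-loss
templates (−56.063, −112.125) and, for conjugates, the glucuronide
losses and the aglycone-minus-prenyl cascade; each observed ion counts
once. The retention-time polarity check (all classes earlier than the
parent except methylation, co-elution allowed for "earlier") is a
reported flag, never a hard filter, because polarity is supporting
evidence rather than an exclusion criterion. Ties within tolerance are
all returned, ranked by |mass error|. Positional isomers within a
class are not distinguished — the mass shift cannot separate them.

## Numerical and design choices

- Suffix regressions for λz are computed from reversed cumulative
  sums, so dense profiles (thousands of points) fit in milliseconds.
- Annotation output ordering is deterministic (RT, then m/z);
  duplicate peak ids are rejected by a named error.
- All simulators accept an integer seed and are byte-for-byte
  reproducible; the CLI threads one config seed through every stage
  and records it with a config hash in the run log.
- CSV dialects store censored values as the literal `<LLOQ` token;
  write∘read is byte-identical on the canonical form.
- Statistical test sizes in the suite: 1000 null replicates for the
  ANOVA type-I calibration, 10–20k label permutations for the
  oracle-agreement checks, 200 seeded replicates for the noisy-λz
  median-error check, 20 random parameter draws for NCA recovery.

## Known limitations

- No compartmental fitting to observed data, sparse-sampling NCA, or
  urine-interval renal-clearance time course.
- No power-model (log AUC vs log dose) dose-proportionality analysis
  or equivalence-interval testing; the verdict is purely the classical
  hypothesis test, so "dose_independent" means "no significant
  difference detected", not proven equivalence.
- No nonlinear protein-binding model, Kp/PBPK estimation, isotope
  scoring or in-silico fragmentation beyond the neutral-loss
  templates; mzML ingestion is left as an extension point (CSV peak
  lists only).
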