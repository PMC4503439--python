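# mangopk

A mouse ADME pharmacokinetics toolkit built around the kind of study in
which a poorly absorbed natural product — here α-mangostin, the major
xanthone of mangosteen (*Garcinia mangostana*) — is dosed intravenously
(5–20 mg/kg) and orally (10–100 mg/kg) with automated micro-sampling,
and its absorption, distribution, metabolism and excretion are
characterized end to end. The package is for pharmacokineticists and
DMPK scientists who want that whole analysis chain as tested,
scriptable code:

- **Non-compartmental analysis** (`mangopk.nca`) — trapezoidal AUC/AUMC
  (linear or linear-up/log-down), terminal slope λz by best
  adjusted-R² window search, t½ = ln2/λz, MRT = AUMC/AUC,
  CL = Dose/AUC∞, Vss = CL·MRT, CL_R = Ae/AUC∞, CL_NR = CL − CL_R,
  F% = 100·(AUC_po/Dose_po)/(AUC_iv/Dose_iv), dose normalization.
- **Dose linearity** (`mangopk.linearity`) — classical one-way ANOVA
  (Tukey HSD as evidence) or unpaired t-test on dose-normalized
  per-subject parameters; non-significance at α = 0.05 ⇒
  dose-independent kinetics.
- **Derived ADME metrics** (`mangopk.adme`) — tissue-to-plasma ratios
  with homogenate-dilution correction, equilibrium-dialysis protein
  binding (fu = C_buffer/C_plasma), unbound renal clearance CL_R/fu
  flagged against the mouse GFR (14.0 mL/min/kg), the
  fraction-unabsorbed correction F_unabs = GI24_oral − F·GI24_iv, S9
  metabolic-stability disappearance, excretion recoveries.
- **Metabolite identification** (`mangopk.biotransform`) — matches
  precursor m/z against biotransformation mass shifts recomputed from
  elemental compositions (+176.032 glucuronidation, +352.064
  bis-glucuronidation, ±2.016 (de)hydrogenation, +15.995 oxidation,
  +14.016 methylation), counts diagnostic neutral losses (56.063 Da
  prenyl, 176.032 Da glucuronide) in the product-ion list, and flags
  retention-time polarity consistency.
- **Synthetic data** (`mangopk.simulate`) — two-compartment IV bolus
  and first-order-absorption oral kinetics with log-normal
  between-subject variability, proportional residual error and LLOQ
  censoring at 1 ng/mL on the study sampling schedules, plus dialysis,
  S9, excretion and MS peak-list generators, so the entire pipeline is
  testable without animal data.

## Worked example

Simulate three IV dose groups, run NCA per subject, and test dose
proportionality of the normalized AUC:

```python
import numpy as np
from mangopk import (PKPopulationSpec, simulate_study, run_nca,
                     GroupedParameter, linearity_verdict)

groups = []
for dose, seed in [(5, 1), (10, 2), (20, 3)]:
    spec = PKPopulationSpec(n_subjects=8, seed=seed)
    profiles, doses, excretion = simulate_study(spec, dose)
    results = run_nca(profiles, doses, excretion)
    vals = np.array([r.dose_normalized_auc for r in results])
    groups.append((dose, vals))
    print(f"dose {dose:>2} mg/kg: CL {np.mean([r.cl for r in results]):.1f} "
          f"mL/min/kg, normalized AUC {vals.mean():.1f} ± {vals.std(ddof=1):.2f}")
report = linearity_verdict(GroupedParameter("dose_normalized_auc", groups))
print(f"verdict: {report.verdict} (ANOVA F={report.statistic:.2f}, "
      f"p={report.p_value:.3f})")
```

prints

```
dose  5 mg/kg: CL 32.2 mL/min/kg, normalized AUC 32.4 ± 7.59
dose 10 mg/kg: CL 33.8 mL/min/kg, normalized AUC 30.4 ± 5.64
dose 20 mg/kg: CL 29.3 mL/min/kg, normalized AUC 38.0 ± 12.31
verdict: dose_independent (ANOVA F=1.55, p=0.235)
```

Per-subject clearance estimates scatter around the generating
31.4 mL/min/kg; dose-normalized AUC does not differ significantly
across the dose groups, so the kinetics are declared dose-independent
— the behaviour the generator encodes.

The same chain is available from the shell:

```sh
mangopk simulate --route iv --dose 5 --n-subjects 8 --seed 1 --out run/
mangopk nca --conc run/conc_iv_5.csv --excretion run/excretion_iv_5.csv --out run/
mangopk annotate --peaks src/mangopk/data/reference_peaklist.csv --out run/
mangopk report --in run/ --out run/report.csv
```

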