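# codsig

Cluster-derived gene-signature subtyping, survival analysis and mutation
profiling for diffuse-type gastric cancer cohorts.

Diffuse-type gastric cancer is clinically heterogeneous: histologically
similar tumors differ widely in prognosis and treatment response. codsig
implements, as a tested reusable pipeline, the derivation of a
**COD signature** from a mixed-histology expression cohort and its
downstream use:

- **derive** — variance filter (SD > 0.9) → unsupervised hierarchical
  clustering of samples into normal-like (N), intestinal-like (INT) and
  core diffuse-type (COD) groups → per-gene Welch t screens on
  diffuse-type samples (list A: N vs INT; list B: INT vs COD, each at
  P < 0.001) → Venn partition; the *only-B* genes (differential for
  progression into the core diffuse phenotype, not for tumorigenesis)
  form the signature, with per-gene direction signs;
- **classify** — two-subtype (INT/COD) assignment of new cohorts on
  per-gene z-scores of the signature genes, by two-group clustering with
  EMT-score orientation, or by a single-sample centroid rule;
- **survival** — Kaplan–Meier curves, log-rank tests, Cox
  proportional-hazards models (Efron/Breslow ties, Newton–Raphson with a
  step-halving guard, Wald CIs `exp(β ± 1.96·SE)`), backward variable
  selection, and per-subtype chemotherapy models with a
  subtype × treatment interaction term;
- **mutations** — tumor mutation burden (TMB) contrasts, a per-gene
  Fisher-exact mutation-frequency screen, and χ² association with the
  EBV/MSI/GS/CIN molecular subtypes;
- **simulate** — a ground-truth cohort generator (latent expression
  groups with planted INT/COD gene modules, proportional-hazards survival
  with a chemotherapy benefit concentrated in the COD subtype,
  overdispersed mutation counts with designated marker loci) so every
  stage is testable without any external download.

The statistical core (Welch t, exact two-sided Fisher, χ², point-biserial
correlation, the Cox partial likelihood) is implemented self-contained and
cross-checked in the test suite against scipy, lifelines and R's
`survival::coxph`. See `docs/methods.md` for the models, assumptions and
numerical choices.

## Worked example

Simulate a cohort at a combined-cohort scale (400 diffuse-type tumors plus
normal and intestinal-type anchors), derive the signature, classify the
diffuse samples and run the downstream analyses:

```python
import numpy as np, pandas as pd
from codsig import (SimulationConfig, simulate_cohort, derive_signature_detailed,
                    classify_cohort, logrank_test, cox_fit, interaction_analysis,
                    clinical_frame)

cfg = SimulationConfig(n_diffuse=400, effect_size=2.0, noise_sd=0.5, seed=7)
expr, clinical, mutations, truth = simulate_cohort(cfg)

res = derive_signature_detailed(expr, clinical)
print("partition:", res.partition.counts())

hist = {a.sample_id: a.histology for a in clinical}
diffuse = [s for s in expr.sample_ids if hist[s] == "diffuse"]
subtypes = classify_cohort(expr.subset(samples=diffuse), res.signature)

frame = clinical_frame(clinical).loc[subtypes.sample_ids]
times, events = frame.os_time.to_numpy(), frame.os_event.astype(bool).to_numpy()
cod = np.array([lab == "COD" for lab in subtypes.labels])

lr = logrank_test(times, events, cod.astype(int))
fit = cox_fit(pd.DataFrame({"cod_signature": cod.astype(float),
                            "age": frame.age.to_numpy(float),
                            "ajcc_stage": frame.ajcc_stage.to_numpy(float)}),
              times, events)
inter = interaction_analysis(np.where(cod, "COD", "INT"),
                             frame.chemo.astype(bool).to_numpy(), times, events)
```

Output (seed 7):

```
partition: {'a': 376, 'b': 650, 'only_a': 1, 'a_and_b': 375, 'only_b': 275}
subtype counts: {'INT': 193, 'COD': 207}
log-rank chi2 = 4.05, p = 4.43e-02
adjusted HR = 1.55 (1.22-1.95), p = 2.9e-04
chemo HR in COD: 0.426 (0.306-0.594), p = 4.73e-07
chemo HR in INT: 0.667 (0.476-0.937), p = 0.0193
interaction p = 0.021
```

Reading the numbers: the 650-gene list B splits into 375 genes shared with
list A (the planted proliferation-like module plus genes the normal-like
contrast also catches) and a 275-gene only-B signature (the planted
EMT-like module plus screen noise). Classification splits the 400 diffuse
tumors 193/207; COD assignment carries a stage- and age-adjusted mortality
hazard ratio of 1.55, and the chemotherapy benefit is stronger in the COD
stratum (HR 0.43) than in the INT stratum (HR 0.67) — the generator's
truth is HR 2.0 for COD at fixed age and stage, with chemotherapy HRs
0.333/0.576, marginally attenuated here by the simulated age and stage
frailty. Single-cohort log-rank contrasts at this size are only
borderline, which is why multi-cohort pooling matters for signatures of
this kind.

The same stages are available from the shell. With a config such as

```yaml
# cfg.yaml
seed: 7
simulation:
  n_diffuse: 400
  effect_size: 2.0
  noise_sd: 0.5
```

```sh
codsig run-all --config cfg.yaml --out run1   # or: codsig simulate|derive|classify
```

writing `report.json` (machine-readable, byte-deterministic for a given
seed) and `report.md` (human summary) plus the signature, subtype table,
KM curves, TMB and mutation-screen exports.

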