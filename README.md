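# mastagree

Inter-method agreement analysis for multiple-allergen simultaneous test
(MAST) analyzers. MAST panels report semi-quantitative allergen-specific
IgE results as class levels 0–6; `mastagree` compares two analyzers over
the same patients by building matched pairs, dichotomizing at a positivity
cutoff, and computing:

- **total agreement percentage** — `(N − discordant) × 100 / N`
- **concordant positive rate** — `n_pp × 100 / N`, guarding against
  agreement inflated by rare positives
- **Cohen's kappa** with a Fleiss–Cohen–Everitt delta-method standard
  error and normal 95% CI (bounds untruncated by default; `--clip-ci`
  clamps to [−1, 1]); kappa is reported as UNDEFINED (NA) exactly when the
  expected agreement is 1
- **positive propensity** — the signed one-sided discordance excess
  `(n_pn − n_np) × 100 / N`; ≥10% flags a positive propensity of analyzer
  A, <5% is "not significant" (both thresholds configurable)
- **cutoff sweeps** (class 1/2/3), per-analyzer **positivity profiles**,
  and **multi-positive-per-patient** summaries.

A synthetic paired-data generator produces class-level datasets with a
target prevalence, kappa, and propensity per allergen (the kappa
definition is inverted analytically into 2×2 cell probabilities), so the
whole pipeline is testable without patient data.

## Input format

Long-format CSV (or TSV, chosen by extension) with header
`patient_id,analyzer,panel,allergen,class`; `panel` is `food` or
`inhalant`, `class` an integer 0–6. Allergen names are canonicalized
(lower-case, trimmed, whitespace-collapsed) through a registry with an
alias map; a default registry for the analyzers `alloscreen`, `smart2`,
`protia`, `rida` ships with the package, and custom registries load from
YAML (`--registry`). `--allow-unregistered` accepts any analyzer/allergen
found in the file.

## CLI

```sh
# agreement + propensity report for one analyzer pair
mastagree compare --input results.csv --a smart2 --b rida \
    --panel food --cutoff 2 --out report/
# writes agreement.tsv, propensity.tsv, drop_log.tsv

# agreement/CPR across cutoffs
mastagree sweep --input results.csv --a smart2 --b rida \
    --panel food --cutoffs 1,2,3 --out report/

# synthetic paired dataset from a YAML config
mastagree simulate --config sim.yaml --out sim.csv --seed 1

# per-allergen positivity for one analyzer
mastagree positivity --input results.csv --analyzer smart2 \
    --panel inhalant --cutoff 1 --out report/
```

A simulation config looks like:

```yaml
n_patients: 90
panel: inhalant
analyzer_a: smart2
analyzer_b: rida
seed: 1
cutoff: 2          # generative positivity cutoff
allergens:
  - allergen: dermatophagoides farinae
    prevalence_a: 0.4
    kappa_target: 0.8
    propensity_delta: 0.1   # prevalence_a - prevalence_b
    class_shape: 0.5        # severity distribution over positive classes
```

Reports round percentages to 1 decimal place and kappa-scale values to 2
(half-up), with full-precision columns alongside.

## Library use

```python
from mastagree import (build_pair_set, summarize_agreement,
                       positive_propensity, reference_fixture, tabulate)

ds = reference_fixture("dfarinae_food")     # deterministic worked example
ps = build_pair_set(ds, "alloscreen", "smart2", "food")
s = summarize_agreement(ps.pairs, cutoff=2)
s.agreement_pct, s.kappa, (s.ci_low, s.ci_high)
```
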