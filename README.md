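# dissolvekit

Quality-control toolkit for in vitro dissolution testing of
immediate-release solid dosage forms. It takes a study from
chromatographic peak areas (or directly from percent-released tables)
to a regulatory pass/fail answer: is each generic's dissolution profile
*similar* to the innovator's?

The package ships a complete worked study: the innovator vildagliptin
50 mg tablet (Galvus) and six marketed generics, tested by the USP
apparatus 2 paddle method (0.01 N HCl, 1000 mL, 50 rpm, 37 °C) with
sampling at 10, 15, 20, 30 and 45 min, n = 3 replicates per product.
Vildagliptin is BCS class I (highly soluble, highly permeable), so an
in vitro profile comparison can stand in for an in vivo bioequivalence
study.

## The statistics

Profiles are compared with the model-independent Moore–Flanner factors
over the n shared sampling times, using per-time mean percent released
R_t (reference) and T_t (test):

    f1 = 100 · Σ_t |R_t − T_t| / Σ_t R_t
    f2 = 50 · log10( 100 · [ 1 + (1/n) Σ_t (R_t − T_t)² ]^(−1/2) )

f1 is the cumulative relative difference (0 for identical profiles);
f2 shrinks from 100 as the mean squared difference grows. The FDA
acceptance bands are f1 ∈ 0–15 and f2 ∈ 50–100; a product inside both
bands is declared similar.

Upstream of the comparison, peak areas A are converted to concentration
against an external standard (C = C_std · A / A_std) and to cumulative
percent of label claim with a mass-balance correction for the drug
carried out of the vessel by each sampling aliquot, in either
replaced-medium or non-replaced mode.

A seeded synthetic-study generator (Weibull release with optional
post-peak decline plus truncated Gaussian replicate noise) emulates the
bundled study's structure so every stage is testable offline.

## Worked example

```sh
dissolvekit compare --outdir qc_out
```

compares the six bundled generics against the reference and prints

```
test_label   f1    f2  n_used verdict
       V-1 1.13 90.27       5 similar
       V-2 3.94 67.79       5 similar
       V-3 0.68 93.58       5 similar
       V-4 1.05 91.39       5 similar
       V-5 1.70 85.10       5 similar
       V-6 0.33 98.46       5 similar

6 of 6 test products similar to reference.
```

Every generic sits well inside both acceptance bands — the closest call
is V-2 (f2 = 67.8), whose profile overshoots the reference by ~4 % from
15 min on — so all six are pharmaceutically equivalent to the brand by
dissolution profile. `qc_out/` receives `results.csv`, a `report.txt`
echoing thresholds, policy and the input file hash, and tidy
`plot_data.csv` (product, time, mean, SD) for plotting.

The same library surface is scriptable:

```python
from dissolvekit import load_vildagliptin_study, assess_equivalence

study = load_vildagliptin_study()
for r in assess_equivalence(study):          # policy="all" by default
    print(r.test_label, round(r.f1, 2), round(r.f2, 2), r.verdict)
```

Other subcommands: `dissolvekit quantify` (peak-area CSV + quantitation
YAML → percent-released CSV), `dissolvekit synth --seed N` (synthetic
study from a preset), `dissolvekit report` (comparison plus per-product
CV screening). Input CSV layouts (`long`, `summary`, `wide`) are
described in `dissolvekit.profiles`; wide columns are named
`product:replicate`.

The numbered scripts under `analysis/` run the same pipeline as a
narrative — profile summary and CV screening, similarity verdicts,
quantitation round-trip, generator benchmark — writing their tables to
`results/`.

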