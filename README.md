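# cytostrat

Cytokine-panel patient stratification for septic shock.

In sepsis, circulating cytokines, chemokines and growth factors mediate the
host response, but single markers measured at variable times have been poor
prognosticators. `cytostrat` implements the alternative: treat the whole
multiplex panel — here a 39-analyte Luminex-style panel measured at
enrollment (baseline) and 24 hours — as a fingerprint, cluster patients
hierarchically into Low / (Medium) / High overall-cytokine subgroups, and
ask what those chemically defined subgroups mean clinically. It is written
for biostatisticians and translational researchers working with multiplex
panels and censored assay values.

The pipeline covers:

* **Panel I/O** — long-format TSV input with censor encodings (`<x`, `>x`,
  zeros); limit-censored values keep the limit, zeros become half the
  global nonzero minimum; pg/mL → pM conversion via a molecular-weight
  catalog; log10 views.
* **Subgrouping** — agglomerative clustering of patients (and analytes) on
  z-scored log10 pM; dendrogram cut at user-chosen k; ordered labels by
  overall level.
* **Comparison tables** — per-analyte medians/IQRs in pM, ratios of
  medians, Welch's t on log10 values, Benjamini–Hochberg q over the
  analyte family.
* **Enrichment** — hypergeometric upper-tail over-representation of
  clinical features in subgroups (and pathway memberships in analyte
  clusters), BH-corrected: p = P(X ≥ k), X ~ Hypergeom(N, K, n).
* **Survival** — Kaplan–Meier curves, the G-rho family of weighted
  log-rank tests (rho = 0 → standard log-rank), and a baseline → 24 h
  subgroup transition table with per-cell mortality and survival tests.
* **Marker models** — forward-selected one-vs-rest logistic regression on
  raw pM concentrations, optionally with pairwise product (interaction)
  terms, Wald inference, Mann–Whitney AUC, and a label-permutation AUC
  null.
* **Matched mortality** — repeated APACHE II-matched subsampling (identical
  score multisets across subgroups) with two-sided Fisher exact tests,
  summarised as median odds ratios with empirical 95% intervals.
* **Synthetic cohorts** — a fully specified generator (`vasst_like`)
  emulating a 363-patient paired-timepoint septic-shock cohort, used by the
  test suite to verify every stage against planted truth.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from cytostrat import (vasst_like, generate_cohort, resolve_censored,
                       to_molar, log10_view, cluster_rows)
from cytostrat.panel_io import global_nonzero_min
from cytostrat.group_stats import subgroup_summary_table
from cytostrat.markers import forward_select
from cytostrat.survival import g_rho_test

spec = vasst_like(seed=1)                      # 363 patients, 39 analytes
baseline, late, clinical, truth = generate_cohort(spec)

half = global_nonzero_min(baseline, late) / 2   # zero-replacement value
molar = to_molar(resolve_censored(baseline, zero_fill=half), spec.catalog)
groups = cluster_rows(log10_view(molar), k=3)
print("subgroup sizes:", groups.sizes().to_dict())

table = subgroup_summary_table(molar, groups, [("High", "Low")])
print(table[["analyte_id", "ratio_of_medians", "q_bh"]].head(3).to_string(index=False))

model = forward_select(molar, groups, "High")
print("High-subgroup marker model:", model.term_ids, f"AUC={model.auc:.2f}")
```

prints

```
subgroup sizes: {'Low': 204, 'Medium': 122, 'High': 37}
analyte_id  ratio_of_medians          q_bh
      CSF3        249.428982  4.125705e-76
     IL1RN        181.591388  4.110263e-33
       IL6        167.087224 1.686542e-144
High-subgroup marker model: ['IL6', 'CCL2', 'CCL22'] AUC=1.00
```

The clustering splits the cohort into a large low-cytokine subgroup, a
medium subgroup and a small high-cytokine subgroup; the top analytes
separate High from Low by two orders of magnitude in median concentration,
and a three-cytokine logistic model reproduces High-subgroup membership
essentially perfectly. Clustering the 24-hour matrix instead (`k=2`) and
testing survival:

```python
molar24 = to_molar(resolve_censored(late, zero_fill=half), spec.catalog)
g24 = cluster_rows(log10_view(molar24), k=2)
res = g_rho_test(clinical.table["survival_time"], clinical.table["event"], g24.labels)
```

gives `24h subgroup sizes: {'Low': 281, 'High': 82}` and
`chisq=16.1, df=1, p=5.86e-05` — the High subgroup carries 55% day-90
mortality against 34% in Low, the survival difference the stratification
exists to expose.

The same stages are available from the shell:

```bash
cytostrat simulate --n-patients 363 --seed 1 --out data/
cytostrat cluster --assay data/assay.tsv --clinical data/clinical.tsv \
                  --timepoint baseline --k 3 --out subgroups.tsv
cytostrat run --config run.json        # full pipeline with manifest
```

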