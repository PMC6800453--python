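# methagesig

Age-stratified DNA-methylation analysis for breast tumours: discovery of
young-patient-specific methylation signatures by a contrast-and-subtract
procedure, genomic/functional-context enrichment, epigenetic (DNAm) age
estimation with age-acceleration statistics, and permutation-balanced
methylation–expression integration — plus a synthetic-cohort generator so
the whole pipeline is testable without any array data.

## The problem

Breast cancer in very young women (BCVY, ≤ 35 years) behaves more
aggressively than in older patients (BCO, ≥ 45 years), and part of that
difference is epigenetic. Given Illumina 450K/EPIC β-values (per-CpG
methylation fractions in [0, 1]) for four groups — young tumours (BCVY),
old tumours (BCO) and matched normal tissues (NVY, NO) — the questions
are:

1. Which CpG sites are differentially methylated *because of patient
   age*, rather than because of tumourigenesis in general?
2. Where do these sites sit in the genome (CpG island / shore / shelf /
   open sea, promoters, enhancers, TFBS), and how much of the signal is
   only measurable on the newer EPIC array?
3. Do young tumours show epigenetic age acceleration — a DNAm age well
   above chronological age?
4. Do the methylation changes propagate to expression of the genes they
   regulate?

## Methods in brief

**Signature extraction (contrast-and-subtract).** Per probe, a two-sided
Wilcoxon rank-sum test with Benjamini–Hochberg FDR; a site is called at
q ≤ 0.05 and |Δβ| ≥ 0.1, where Δβ = mean β(young) − mean β(old). Stage 1
contrasts each tumour group against the pooled normals; probes
significant in *both* contrasts are shared tumour biology and are
subtracted. Stage 2 keeps the BCVY-only significant probes (the
*specific pool*). Stage 3 contrasts BCVY vs BCO: over all probes outside
the shared set (→ *global signature*, q ≤ 0.05) and within the specific
pool at the stricter q ≤ 0.01 (→ *distinctive signature*, a subset of
the pool by construction). Per-probe GLM checks (β ~ age group + subtype
+ ER status) and a chi-squared subtype-balance test guard against
confounding.

**Context enrichment.** Welch's t-test (p ≤ 0.001) on per-probe group
means within each annotation category; hyper/hypo fractions per
category; EPIC-only vs 450K-shared splits; average-linkage hierarchical
clustering of samples on the median-centred signature.

**Epigenetic age.** DNAmAge = F⁻¹(intercept + Σⱼ wⱼ βⱼ) over clock CpGs,
with F the Horvath age transform (log-linear below `adult_age` = 20,
linear above). Age-acceleration difference AAD = DNAmAge − age;
age-acceleration residual AAR = residual of DNAmAge regressed on age;
groups compared by rank-sum test, per-group Pearson r reported.

**Expression integration.** 50 subtype-balanced random subsamples; per
draw a rank-sum test per gene; Fisher combination (χ², 2k df) of the k
p-values; BH FDR over tested genes; a gene is retained when q < 0.01,
|Δexpr| ≥ 0.1 (log scale) and the direction is consistent with its
linked probes (hypomethylated → overexpressed in the young group,
hypermethylated → repressed). ΔΔCt fold-change analytics
(2^(−ΔΔCt), housekeeping-normalised) cover qRT-PCR validation data.

## Worked example

```python
from methagesig import *
from methagesig.synthetic_data import SimulationConfig, simulate_methylation, simulate_clock

cfg = SimulationConfig(n_probes=5000, n_planted_global=100,
                       n_planted_distinct=30, n_clock_cpgs=100, seed=42)
bm, sheet, ann, truth = simulate_methylation(cfg)

res = run_signature_pipeline(bm, sheet)
for k, v in res.counts.items():
    print(f"{k}: {v}")

clock = simulate_clock(cfg)
dnam = predict_dnam_age(bm.subset_samples(sheet.samples_in_group(("BCVY", "BCO"))), clock)
est, comp = age_acceleration(dnam, sheet)
print("mean AAD BCVY: %.2f  BCO: %.2f" % (comp["group_mean_accel_diff"]["BCVY"],
                                          comp["group_mean_accel_diff"]["BCO"]))
print("rank-sum p (AAD): %.3g" % comp["rank_sum_p_accel_diff"])
```

prints

```
n_probes_tested: 5000
n_sig_bco_vs_normal: 100
n_sig_bcvy_vs_normal: 30
n_common: 0
n_specific_pool: 30
n_global_signature: 131
n_distinctive_signature: 30
mean AAD BCVY: 14.56  BCO: -0.29
rank-sum p (AAD): 6.8e-08
```

The cohort planted 100 global and 30 distinctive effects (Δβ = 0.2) and
a +15-year age acceleration in BCVY. The pipeline recovers all 30
distinctive probes inside the specific pool, calls 131 probes in the
global young-vs-old signature (the planted 130 plus one false positive),
and the clock reads the young tumours ≈ 15 years older than their
chronological age (AAD +14.6 y vs −0.3 y in BCO, rank-sum p ≈ 7 × 10⁻⁸).

The same analysis runs from the shell:

```sh
methagesig simulate --out-dir sim --seed 42
methagesig diffmeth --beta sim/beta_matrix.tsv --sheet sim/sample_sheet.csv
methagesig clock --beta sim/beta_matrix.tsv --sheet sim/sample_sheet.csv --clock sim/clock.csv
methagesig run config.yaml        # full pipeline from a YAML config
```

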