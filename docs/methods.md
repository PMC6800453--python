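# Methods notes

This note documents the models, parameter choices, numerical decisions
and known limitations of `methagesig`, in the spirit of a statistical
software appendix. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design and containers

The analysis operates on four sample groups defined by tissue and age:
tumours from women aged ≤ 35 (BCVY) or ≥ 45 (BCO) and the corresponding
normal tissues (NVY, NO). The cut-offs (35/45 years) are parameters of
`assign_groups`; samples in the open interval between them are flagged
excluded rather than forced into a group, because the design uses none.
β-values live in [0, 1]; missingness is explicit NaN and every per-probe
test drops missing samples pairwise — no imputation is performed
anywhere except for clock probes (below). Matrix I/O is delimited text
with the delimiter inferred from the extension and overridable.

## Differential methylation and the signature flow

Per-probe testing is the two-sided Wilcoxon rank-sum test. Exact
enumeration is used when both groups have ≤ 8 observations and the
pooled values are tie-free; otherwise the normal approximation with
midranks, tie-corrected variance and continuity correction. β-values
from FFPE material are quantised enough that ties are a practical
concern, hence the midrank policy. When the pooled sample is constant
the statistic carries no information and p = 1 is returned explicitly
rather than letting a 0/0 variance propagate.

FDR is Benjamini–Hochberg, computed *within each contrast* over the
probes tested in that contrast — the staged design calls for a separate
testing universe per stage, not a pooled one. A probe is significant at
q ≤ `q_max` (0.05) **and** |Δβ| ≥ `delta_min` (0.1). The sign convention
is fixed everywhere: Δβ = mean β(first-named group) − mean β(second),
so positive means hypermethylated in the younger/experimental group.

The three-stage flow:

1. BCO vs normals and BCVY vs normals at q ≤ 0.05, |Δβ| ≥ 0.1.
2. Probes significant in both tumour contrasts ("common") are shared
   tumour-vs-normal biology; `specific_pool` = BCVY-significant minus
   common (the count identity |pool| = |BCVY-sig| − |common| is asserted
   exactly).
3. BCVY vs BCO: (a) over all probes except the common set → the global
   age signature at q ≤ 0.05; (b) within the specific pool → the
   distinctive signature at the stricter cut-off.

The stage-3b cut-off of 0.01 is interpreted as a BH-adjusted q, matching
the FDR framing of every other threshold in the procedure; a
`distinct_use_raw_p` flag switches to the raw p for users who prefer the
other reading. The distinctive signature is a subset of the specific
pool by construction and the code asserts it.

Known age-predictive CpGs can be removed before any testing via an
exclusion list (`exclude_probes`), so age-related methylation drift
cannot masquerade as a tumour signature; the published age-CpG catalogues
are inputs, not bundled data.

The covariate check fits, per probe, ordinary least squares
β ~ age_group + subtype + ER status on tumour samples and reports the
age-group coefficient p plus a Wald F-test per covariate block. OLS on β
was chosen over a logit-linked model because β is bounded but interior
in practice; an M-value option (log2 β/(1−β), clipped at 10⁻³) is
provided for users who prefer variance stabilisation. Rank-deficient
designs (fully confounded covariates) skip the probe with a warning;
constant probes are flagged degenerate with p = 1. Subtype/ER balance
between age groups is a Pearson chi-squared test without continuity
correction.

## Genomic context

Category summaries cover three vocabularies: CpG context (exactly one
label per probe: island, N/S shore, N/S shelf, open sea), gene region
and regulatory element (possibly several labels per probe — such probes
count once per label, and the output metadata says so; CpG-context
counts, being single-label, sum exactly to the signature size).

The category test is Welch's unequal-variance t-test comparing the
per-probe group-A mean β-vector against the group-B mean β-vector across
the probes of the category, significant at p ≤ 0.001. The comparison
unit was genuinely open (probe-level Δβ against zero would be the
alternative); the two-mean-vector reading matches a literal two-sample
Welch test and is the one implemented.

Clustering of samples on a signature median-centres each probe across
samples and applies average-linkage hierarchical clustering on Euclidean
distance (both configurable; only the median-centring is fixed by the
design). The two-cluster cut is scored against BCVY-vs-rest by adjusted
Rand index, which is invariant to cluster relabelling and to sample
order. The dendrogram is exported as Newick with branch lengths derived
from merge heights.

## Epigenetic age

The clock is linear in β with a Horvath-style age transform:
F(a) = log(a+1) − log(adult+1) for a ≤ adult, (a − adult)/(adult+1)
above, with adult_age = 20; both branches vanish at the knot and the
inverse is exact. Clock coefficients are always an input file (CSV with
`intercept` and `adult_age` metadata rows) — the published 353-CpG
coefficient table is external and licence-encumbered, and the synthetic
clock serves as the test fixture.

Clock probes absent from the matrix are dropped (an error is raised
below 50 % coverage, configurable, listing the missing probes); probes
present but missing in individual samples are imputed at the probe's
cohort mean β, the one place imputation is used, with the count logged.
AAR comes from a single least-squares line fitted over the analysed
(tumour) cohort, the standard definition; its cohort mean is zero by
construction and the tests assert it to 1e-9.

## Expression integration

The balanced permutation scheme draws, per molecular subtype,
min(n_young, n_old) samples from each age group without replacement;
subtypes lacking two samples on either side are dropped from the
balancing with a warning. The per-draw test is the same rank-sum test
used for methylation (nothing in the design calls for a different one).
The k p-values per gene are combined by Fisher's method (−2 Σ ln p ~
χ²₂ₖ), the common default of the p-value-combination utilities; Stouffer
is available behind a flag. At k = 1 both reduce to the identity.

Because the k draws overlap heavily in samples, the per-gene p-values
are positively dependent and the Fisher combination is anti-conservative
under the null. Two things keep the retained set clean anyway: the BH
step over genes, and above all the effect-size filter — a null gene's
|Δexpr| (full-cohort group-mean difference, log scale) concentrates near
zero, so the ±0.1 requirement removes essentially all dependence-driven
false positives. Null-gene retention is measured, not assumed, by the
acceptance suite. Uniformity of the p-values under the null is asserted
within a single draw, where genes are independent; pooling across
overlapping draws would invalidate the KS test's sampling assumptions.

The FDR universe for integration is the set of genes linked to
significant probes (the pipeline builds the gene→probe map that way);
`integrate` itself tests whatever map it is given, which is what lets
the test suite score false retention on deliberately-null genes. A
gene's methylation direction is the sign of the mean Δβ over its linked
probes; retention requires q < 0.01, |Δexpr| ≥ 0.1 and direction
consistency (hypo → up, hyper → down in the young group). Expression
differences are computed on the full cohort rather than within draws —
the draws exist to stabilise the p-value, not the effect estimate.

ΔΔCt analytics: ΔCt = target − reference (housekeeping) per sample,
ΔΔCt relative to the old-group mean, fold change 2^(−ΔΔCt), groups
compared by rank-sum on fold changes. Samples without a reference Ct are
dropped with a log message.

## Synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions used throughout the test and acceptance suites: 20/20/5/5
samples per group, 20 000 probes, 200 global + 50 distinctive planted
effects of magnitude Δβ = 0.2, 69 % of global effects hypomethylated in
BCVY (allocated deterministically by rounding, so 100 planted probes at
0.69 give exactly 69 hypo), 16 % of distinctive effects hypomethylated
(84 % hyper), β-scale Gaussian noise SD 0.05 clamped to [0, 1], a
100-CpG clock, and a planted +15-year BCVY age acceleration. Group ages
are truncated normals matching the discovery cohort (32.5 ± 2.7 and
65.5 ± 8.5 years).

Planted classes and their rationale:

- **distinctive** probes shift the BCVY group against tumours *and*
  normals — the profile the distinctive signature is defined to capture.
- **global** probes shift the BCO group against everyone else: the
  young-vs-old contrast sees them while the BCVY-vs-normal contrast does
  not, so they enter the global signature and stay out of the specific
  pool. This makes the two planted classes separable by the pipeline's
  own logic, which is what lets sensitivity and false-discovery
  proportion be scored per signature.
- **clock** probes encode β = c + d·F(age + acceleration) with the
  per-probe offsets and slopes solved against the drawn weights so the
  linear predictor returns the transformed age *exactly* at zero noise
  (weights ~ N(0, 2.5/√K), slopes d = w/Σw², offsets centred at β = 0.5
  over the adult range, so β stays far from the clamp for K ≳ 20).
- **null** probes are background only.

The β background is a two-mode Beta mixture (modes near 0.15 and 0.85),
the familiar bimodality of methylation arrays, which leaves realistic
dynamic range for ±0.1 thresholds. Planted probes draw their baseline
from the mode that leaves headroom for the shifted group (an upward
shift starts from the unmethylated mode and vice versa), so [0, 1]
clamping cannot silently erode a planted effect below the call
threshold. With a zero effect size the generator plants nothing and the
truth table says so.

Annotation is random with two planted structures used by the context
tests: distinctive probes are enriched for open sea (80 % vs 40 %
background) and open-sea probes for EPIC-only membership (50 % vs 15 %).
ER status tracks subtype with a 10 % flip rate — a deterministic mapping
would make the GLM design exactly collinear, which real cohorts are not.
Expression couples each planted probe to one synthetic gene,
expr = baseline + coupling·β + noise with coupling ∈ [−1, 0] (−0.8
default, noise SD 0.1), plus an equal number of uncoupled genes mapped
to null probes so false retention is measurable.

All randomness flows from one seed through tagged child generators, so
`simulate_clock` and `simulate_methylation` agree on the clock without
sharing state, and identical configs are bit-identical.

What the generator does **not** emulate — and hence what green tests do
not certify about real arrays: probe-wise variance heterogeneity and
spatial correlation along the genome, batch and FFPE-quality effects,
cell-composition heterogeneity, subtype-linked methylation structure,
age-dependent drift outside the clock probes, and realistic
missing-value patterns. Recovery rates on this generator are an upper
bound on real-data performance.

## Problem sizes and numerical choices

The acceptance suite runs the full planted-recovery check at the
generator's native scale (20 000 probes, ten seeds) because the
vectorised rank-sum contrasts make a full cohort run take a few seconds;
the null-calibration and integration checks use 5 000- and 4 000-probe
cohorts, which already give stable rates. The module-level test fixture
uses a 2 000-probe cohort for speed. p-values are clipped to the
smallest positive float before logs; BH is delegated to the standard
step-up implementation and cross-checked against the direct formula in
the tests; exact rank-sum enumeration is cross-checked against a
brute-force combination oracle.

## Known limitations

- OLS on β for the covariate check ignores heteroscedasticity near the
  [0, 1] boundaries; the M-value option mitigates but changes the scale
  of effects.
- The Fisher combination's dependence anti-conservatism (above) means
  `combined_p` should not be interpreted as a calibrated tail
  probability; it is a ranking statistic feeding an empirically
  validated filter.
- The Welch category test treats probes as independent observations;
  neighbouring CpGs are correlated on real arrays, so category p-values
  there are optimistic.
- No region-level (DMR) calling, no normalisation or batch correction:
  the pipeline starts at β-values on purpose.
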