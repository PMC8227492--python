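# Methods

`mirdupscreen` implements an in-silico screen for tumor-suppressor
candidates regulated by both strands of a miRNA duplex. This note records
the model behind each stage, the defaults and why they were chosen, what the
synthetic cohorts do and do not emulate, and the numerical decisions a
maintainer would otherwise have to reverse-engineer.

## The screen

The pipeline is a funnel with four stages.

**1. Small-RNA signature.** Counts are normalized to counts per million
(each sample column scaled to 10^6). Per mature miRNA, the fold change is

    log2FC = log2((mean_T + c) / (mean_N + c))

where the means are arithmetic means of normalized values over the tumor
and normal groups and `c` is a pseudocount (default 0.5 normalized units)
that keeps the ratio finite on zero counts. A feature is called
up-regulated when log2FC exceeds 1.5 *strictly*. This is a fold-change
ranking, not a count-model test: no dispersion estimation and no p-values,
which is what the screen's published cut expresses. CPM was chosen as the
simplest defensible normalization for a ranking; it is configurable, and
with very small libraries the compositional coupling of CPM (a few strongly
shifted features deflate everyone else's fold change) is measurable — the
recovery tests therefore run at realistic library sizes (hundreds of
mature miRNAs).

**2. Duplex detection.** Mature names ending in `-5p`/`-3p` are mapped to a
precursor stem; a precursor is a duplex hit when *both* arms are in the
up-regulated list. Names without an arm suffix never contribute.

**3. Seed-site prediction.** The seed is nucleotides 2–8 of the mature
strand (5'→3'). Writing `rc()` for reverse complement in DNA space, the
canonical site patterns on a UTR are

    7mer-m8: rc(positions 2-8)
    8mer:    rc(positions 2-8) + "A"
    7mer-A1: rc(positions 2-7) + "A"

The trailing adenosine is a literal `A` on the target regardless of the
miRNA's position-1 base. UTRs are scanned as given (single-stranded, DNA
alphabet, U→T on ingest); coordinates are 0-based half-open. Because the
7mer-m8 and 7mer-A1 patterns are the prefix and suffix of the 8mer, every
8mer occurrence embeds both sub-matches; the scanner suppresses those two
co-located sub-matches so each site is counted once at its strongest type,
while overlapping *distinct* sites are all reported. Only canonical site
identification is implemented — no context scoring, 3'-supplementary
pairing, or conservation weighting, which belong to the target-prediction
databases this package does not reproduce.

**4. Survival filters.** Candidates are the per-arm intersection of
predicted targets with genes down-regulated below −2.0 log2 units
(strict); a gene targeted by both arms appears in both partitions, as in
the packaged candidate table. Each candidate is then tested on the tumor
cohort:

* *Kaplan–Meier filter.* Patients are dichotomized at the cohort median of
  the gene's expression (ties at the median go to the low group, which
  makes the split deterministic). Follow-up is truncated at the horizon
  (default 60 months — a 5-year analysis; later events are recoded
  censored at 60). The two-group log-rank test must reject at alpha
  (default 0.05) *and* the low-expression arm must have the lower KM
  estimate at the horizon — the screen looks specifically for the
  "low expression, worse outcome" tumor-suppressor pattern, so the nominal
  5% two-sided test acts as a ~2.5% directional filter under the null.
* *Cox filter.* Per gene, one multivariate proportional-hazards model:
  expression group (low = 1) plus stage, grade, and age, entered as single
  ordinal/numeric slopes (one forest row per covariate). The gene survives
  if the expression term's Wald p < alpha — it is an independent
  prognostic factor after adjustment.

No multiple-testing correction is applied by default (the screen operates
at raw p < 0.05); a Benjamini–Hochberg option exists for users who want
FDR control. The overall-survival endpoint is the default; a disease-free
endpoint is selectable when the clinical table carries `dfs_time`/
`dfs_event` columns.

## Survival machinery

The statistics are implemented from first principles; scipy supplies only
distribution functions for p-values.

* **Kaplan–Meier**: product-limit estimator S(t) = Π_{t_i ≤ t} (1 − d_i/n_i)
  over distinct event times; censored-only data gives S ≡ 1.
* **Log-rank**: χ² = (Σ(O_A − E_A))² / ΣV with the hypergeometric variance
  at each event time; zero events (or degenerate variance) reports
  χ² = 0, p = 1 rather than failing.
* **Cox regression**: Newton–Raphson on the partial likelihood with the
  *Efron* tie correction — month-resolution survival data is heavily tied
  and Efron is markedly less biased than Breslow there. Covariates are
  standardized internally for conditioning and estimates transformed back.
  Convergence is declared when the largest score component is below 1e-8;
  after 50 iterations the fit returns flagged `converged=False` instead of
  raising. Step-halving guards the rare likelihood-degrading step near
  separable data. Constant or collinear covariates are rejected with the
  offending column named. Wald CIs use log HR ± 1.96·SE. The test suite
  verifies the classical identity that the score at β = 0 for a binary
  covariate equals the log-rank O − E, and cross-checks full fits against
  an independent survival package.
* **Spearman**: Pearson correlation of mid-ranks (average ranks on ties);
  p from the t approximation with n − 2 df.

P-values are carried at full double precision; rounding happens only at
the presentation layer.

## Synthetic cohorts

The generator plants exactly the structure the screen assumes, with the
ground truth returned beside the data. Defaults describe a cohort of
518 tumors and 44 normals — the scale of the public clinical cohort this
kind of screen is run against — with 200 mature miRNAs, 7 planted duplex
precursors at +2.5 log2 units, 400 genes of which 20 are true targets at
−2.8 log2 units, and 5 prognostic genes at hazard ratio 2.5 for the
below-median group.

* **miRNA counts** are negative binomial with variance μ + μ²·φ
  (φ = 0.2 by default, an ordinary bulk small-RNA overdispersion);
  baseline means are log-normal. For each planted precursor *both* arms
  get tumor mean = normal mean × 2^planted_log2fc; everything else is null.
* **Gene expression** is generated on the log2 scale as baseline −
  corr_strength × standardized(driver) + noise, plus a tumor shift of
  target_log2fc for true targets, then exponentiated to a linear scale.
  The driver is the cohort CPM of the planted duplex's 3p arm, so targets
  are anti-correlated with the driver the way repressed targets are.
* **Survival** times are exponential with hazard baseline × HR^(low) per
  prognostic gene, multiplicative across prognostic genes, with
  independent uniform censoring on (0, censor_horizon] and independent
  stage (uniform 1–4), grade (uniform 1–3) and age (normal(60,10)
  truncated to [18, 90]) covariates. The covariates carry no hazard of
  their own; they exist to exercise the multivariate adjustment.
* **UTRs** are i.i.d. uniform DNA with sites planted at recorded,
  non-overlapping positions; any *accidental* occurrence of the driver's
  own patterns is removed by rejection-resampling of the colliding
  window's unprotected bases, so the planted truth is exact for the tested
  miRNA (and only for it — other miRNAs may match by chance, by design).

Each generator draws from its own stream seeded by `(seed, operation
offset)`, so adding one generator never perturbs another and every output
is bit-reproducible under a fixed seed.

What the synthetic cohorts deliberately do **not** emulate: read-level
sequencing artifacts, batch effects, isomiR complexity, competing risks,
non-proportional hazards, and realistic gene–gene correlation beyond the
single shared driver. One consequence worth knowing: because all true
targets share the latent driver, non-prognostic targets are correlated
with the prognostic ones and can pass the survival filters — the same
confounding a real cohort exhibits. Recovery is therefore scored as
"all planted prognostic genes are found", not "only they are found".
Passing tests demonstrate the machinery is correct and calibrated under
the stated model; they do not certify performance on any real cohort.

## Calibration and recovery (what the tests compute)

The acceptance suite recomputes, from scratch: the packaged candidate
table's funnel counts (146 rows; 24 5p / 122 3p) and spot-checked cells;
exact equivalence of the scanner with exhaustive window enumeration on
random UTRs up to 10 kb; exact agreement of KM/log-rank/Cox/Spearman with
independent oracles; null calibration of the screens (directional KM
filter ≈ 2.5%, Cox filter ≈ 5%, binomial 99% bands); Cox recovery of a
planted hazard ratio of 2 (|bias| < 0.15 on the log scale, ~95% CI
coverage); and end-to-end recovery of ≥ 80% of planted prognostic genes
over 20 default-configuration seeds, with byte-identical fixed-seed
reruns. Replicate counts (e.g. 200 × 100 null replicates at n = 200
patients) were chosen so the binomial bands are tight while the whole
suite stays fast.

## Known limitations

* The candidate table's printed site counts come from an external
  target-prediction database; this package's scanner reproduces canonical
  site *identification*, not that database's per-gene totals, which depend
  on its UTR annotation and version.
* The ordinal coding of stage and grade assumes a linear log-hazard trend
  across levels; factor coding would need a different forest layout.
* The Cox implementation covers right-censored data with time-constant
  covariates only — no stratification, time-varying effects, or
  interval censoring.
* Median dichotomization discards information relative to modeling
  expression continuously; it is used because it is what the screen
  being reproduced does.
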