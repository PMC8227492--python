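# mirdupscreen

From a small-RNA expression signature to prognostic tumor-suppressor
candidates regulated by **both strands of a miRNA duplex**.

A precursor miRNA hairpin yields two mature strands (the `-5p` and `-3p`
arms). The guide strand loads the silencing complex; the passenger strand
was long assumed to be degraded — yet in several cancers both arms of some
duplexes (miR-31 among them) are up-regulated and functional. When an
oncogenic duplex is over-expressed in tumors, the genes it represses are
candidate tumor suppressors: they should be down-regulated in tumors, carry
seed-matched binding sites in their 3'-UTRs, and their low expression should
predict worse patient survival.

`mirdupscreen` implements that screen as a tested, reusable library:

1. **Signature** — CPM normalization and per-miRNA fold change
   `log2FC = log2((mean_T + c)/(mean_N + c))`, with up-regulation called at
   log2FC > 1.5 and duplexes detected when both arms pass.
2. **Seed sites** — canonical TargetScan-style site types on a UTR, derived
   from seed nucleotides 2–8 of the mature strand: `8mer`
   (rc(2–8) + A), `7mer-m8` (rc(2–8)), `7mer-A1` (rc(2–7) + A), with 8mer
   occurrences absorbing their embedded 7mer sub-matches.
3. **Candidate funnel** — per-arm intersection of predicted targets with
   genes at log2FC < −2.0.
4. **Survival screen** — per gene: median split of expression, follow-up
   truncated at 60 months, log-rank test with the requirement that *low*
   expression is the worse arm (Kaplan–Meier filter), then a multivariate
   Cox model (expression group + stage + grade + age) keeping genes whose
   expression term has Wald p < 0.05 — independent prognostic factors.

The Kaplan–Meier estimator, log-rank test, Cox partial-likelihood fit
(Newton–Raphson, Efron tie correction) and Spearman correlation are
first-principles implementations, cross-checked in the test suite against
independent oracles. A synthetic-cohort generator plants every assumed
structure — both-arm up-regulation, driver-coupled target repression, seed
sites at recorded positions, expression-dependent hazards — with the ground
truth returned beside the data, so the whole pipeline is testable without
any download. The printed 146-gene candidate table ships as package data
(`mirdupscreen.TABLE1_PATH`).

## Worked example

```bash
python examples/05_full_screen.py
```

```
funnel:
  n_upregulated_mirnas     14
  n_duplex_precursors      7
  n_predicted_5p           5
  n_predicted_3p           15
  n_downregulated          20
  n_candidates_5p          5
  n_candidates_3p          15
  n_km_survivors           20
  n_final                  20

final genes: ['GENE0001', ..., 'GENE0020']
planted prognostic genes recovered: 5/5
```

On this synthetic cohort (518 tumors / 44 normals, seed 1) the signature
calls 14 miRNAs up-regulated, all 7 planted duplex precursors are detected,
the 20 planted targets carry seed sites and pass the −2.0 fold-change cut,
and the survival filters retain all 5 genes planted with a hazard signal
(the other 15 pass too because they share the latent driver with the
prognostic genes — the confounding a real cohort shows). The other examples
walk each stage separately: cohort simulation, signature and duplex calls,
seed-site scanning, and single-gene survival analysis with KM/log-rank/Cox
numbers printed and interpreted.

There is also a thin CLI over the same functions:

```bash
mirdupscreen simulate --seed 7 --out bundle/
mirdupscreen screen --counts bundle/mirna_counts.tsv --annotation bundle/annotation.tsv \
    --mirnas bundle/mature_mirnas.fasta --mirna-5p hsa-miR-31-5p --mirna-3p hsa-miR-31-3p \
    --utrs bundle/utrs.fasta --expression bundle/expression.tsv \
    --clinical bundle/clinical.csv --out report/
```

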