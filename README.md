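# teprof

Translational-efficiency (TE) analysis of paired total and polysomal
RNA-seq count matrices, with companion tools for polysome-profile (A254
trace) quantification and qPCR relative expression, plus a ground-truth
simulator for end-to-end testing.

## What it does

Starting from a gene × sample count matrix and a sample sheet
(strain, RNA fraction ∈ {total, polysomal}, replicate), the pipeline:

1. **Normalizes** libraries with median-of-ratios size factors
   (`teprof.normalization`).
2. **Estimates NB dispersions** per gene (Cox–Reid adjusted profile
   likelihood at the fitted group means), fits a parametric
   mean–dispersion trend `a0 + a1/mu`, and shrinks genewise estimates
   toward the trend under a log-normal prior (`teprof.dispersion`).
3. **Fits a per-gene negative-binomial GLM**
   `log mu = b0 + b1*strain + b2*fraction + b3*strain:fraction`
   by IRLS at the fixed shrunken dispersion; coefficients are reported in
   log2 (`teprof.nb_glm`).
4. **Tests** coefficients with two-sided Wald statistics and adjusts
   p-values by Benjamini–Hochberg.
5. **Differential TE** is the Wald test of the interaction `b3`; the
   plug-in estimate `log2((A_poly/A_total)/(B_poly/B_total))` from
   normalized group means is reported alongside and coincides with `b3`
   for the saturated 2×2 design (`teprof.te_analysis`). Separate
   per-fraction DE runs feed a Venn-style gene classification
   (poly-only / both / total-only, up and down).
6. **Polysome profiles**: peak detection on smoothed A254 traces,
   valley-bounded trapezoidal AUCs with a zero or chord baseline, fold
   changes versus a reference peak, and per-peak t tests with Holm–Šidák
   adjustment (`teprof.polysome_profiles`).
7. **qPCR**: relative expression normalized to the geometric mean of
   reference genes, fold changes between conditions, and replicate tests
   (Holm–Šidák t or one-way ANOVA with Šidák pairwise contrasts)
   (`teprof.qpcr`).
8. **Simulation** (`teprof.synthetic_data`): NB counts with a
   mean–dispersion trend, library-size variation, and planted
   strain/fraction/TE effects; sum-of-Gaussian traces; Cq tables — all
   fully determined by a seed.

Two annotated gene tables (polysomally enriched OXPHOS transcripts and
polysomally reduced translation-machinery transcripts) ship as package
fixtures, loadable with `teprof.load_table_fixture`.

## CLI

```sh
# simulate a dataset with known truth
teprof simulate --config sim.yaml --out simdir/

# per-fraction differential expression
teprof de simdir/counts.tsv --samples simdir/samples.tsv \
    --subset fraction=total --contrast strain:mutant:rescue --out de_total.tsv

# differential translational efficiency (interaction Wald test)
teprof te simdir/counts.tsv --samples simdir/samples.tsv \
    --strain-a mutant --strain-b rescue --sf-scope joint --out te.tsv

# Venn-style classification from two DE tables
teprof classify de_poly.tsv de_total.tsv --alpha 0.01 --out classes.tsv

# trace quantification and group comparison
teprof trace quantify trace.tsv --min-prominence 0.3 --out peaks.tsv
teprof trace compare groupA.tsv groupB.tsv --out cmp.tsv

# qPCR relative expression
teprof qpcr cq.tsv --refs Y45F10D.4,tba-1,csq-1 --condition-ref wt --out qpcr.tsv
```

A minimal `sim.yaml`:

```yaml
seed: 11
n_genes: 5000
effect_sets:
  - name: TEup
    n_genes: 250
    beta_te: 1.0
```

## Layout

```
src/teprof/
  io_fixtures.py        count-matrix / sample-sheet IO, packaged tables
  synthetic_data.py     NB count, trace, and Cq simulators
  normalization.py      median-of-ratios size factors
  dispersion.py         genewise / trend / shrunken NB dispersions
  nb_glm.py             IRLS NB GLM, Wald tests, BH adjustment
  te_analysis.py        interaction TE test, plug-in LFC, classification
  polysome_profiles.py  trace IO, peak detection, AUC, Holm-Šidák
  qpcr.py               relative expression and replicate testing
  cli.py                click command group `teprof`
tests/                  pytest suite; test_acceptance.py holds the
                        acceptance criteria
scripts/acceptance.py   acceptance report generator
```
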