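# srtkit

Entropy-based expression specificity of RNA transcripts across tissue,
cancer and cell-line types: scoring, SRT classification, dual-specificity
cross-tabulation, and diagnostic-candidate ranking.

## The problem

Many RNA transcripts — including isoforms of broadly expressed genes — are
transcribed almost exclusively in one tissue, one tumor type, or one cell
lineage. Such *specific RNA transcripts* (SRTs) are natural biomarker
candidates, but a transcript that looks tumor-specific in a paired
tumor/normal comparison may in fact be active in an unrelated normal tissue
(testis is a frequent offender) or in other cancer types, which would
confound a diagnostic assay such as liquid biopsy. srtkit quantifies
specificity transcript-by-transcript from TPM expression matrices, joins the
calls across contexts, and ranks candidates with a composite score that
penalises exactly these confounders.

## The model

For transcript *t* with aggregated expression *x*<sub>it</sub> over *N*
types, the expression ratios are

> p<sub>it</sub> = x<sub>it</sub> / Σ<sub>i</sub> x<sub>it</sub>

and the specificity score is the entropy deficit

> S<sub>t</sub> = log₂(N) − ( −Σ<sub>i</sub> p<sub>it</sub> log₂ p<sub>it</sub> )

S<sub>t</sub> = 0 for perfectly uniform expression and log₂(N) for
single-type expression. A transcript is an SRT in its top type when the top
ratio is more than twice the second-largest ratio **and** S<sub>t</sub> > 1
(both strict).

Diagnostic candidates for a cancer type *c* are transcripts expressed
(> 0.1 TPM) in at least one tumor sample of *c* but in no sample of the
matched normal tissue. Each candidate is ranked by the signed composite

> S<sub>tc</sub> = β₁ · log₂(x<sub>tc</sub> + 1) · s<sub>tc</sub> · r<sub>tc</sub> + β₁ · β₂ · s<sub>tt</sub>

where x<sub>tc</sub> is mean tumor TPM, s<sub>tc</sub> the cancer-context
specificity score, r<sub>tc</sub> the fraction of tumor samples expressing
the transcript, and s<sub>tt</sub> the tissue-context score (set to 1 when
the transcript is tissue-specific nowhere). β₁ = −1 when the transcript is
specific in a *different* cancer (the score flips negative); β₂ = 0 when it
is specific in an unrelated tissue (the tissue credit is withheld).

## Worked example

```
$ python examples/01_specificity_scores.py
 transcript_id    score top_type  top_ratio  second_ratio  is_specific specific_type
  housekeeping 0.000000    brain   0.250000      0.250000        False
  brain_marker 1.718385    brain   0.963855      0.012048         True         brain
testis_leaning 1.524366   testis   0.930233      0.023256         True        testis
        silent      NaN                 NaN           NaN        False
```

The uniform transcript scores exactly 0; the two concentrated transcripts
clear both parts of the SRT rule (dominant top ratio, score above 1 out of a
possible log₂(4) = 2); the all-zero transcript is reported with an undefined
score rather than dropped. `examples/02_simulate_and_recover.py` recovers
planted specific transcripts from a noisy simulated cohort (precision =
recall = 1.000 at 8-fold enrichment, σ = 0.25), and
`examples/03_diagnostic_ranking.py` ranks planted diagnostic markers above
every planted confounder in a paired tumor/normal simulation.

## Command line

The same stages are exposed as composable subcommands operating on TSV:

```
srt simulate --config sim.cfg --out-dir fixtures/
srt filter   --matrix m.tsv --metadata meta.tsv --tpm 0.1 --out filtered.tsv
srt aggregate --matrix filtered.tsv --metadata meta.tsv --stat mean --out profile.tsv
srt score    --profile profile.tsv --out scores.tsv
srt crosstab --tumor-calls a.tsv --tissue-calls b.tsv --out-prefix dual
srt diagnose --tumor-matrix t.tsv --tumor-metadata tm.tsv \
             --normal-matrix n.tsv --normal-metadata nm.tsv --cancer LIHC --out ranked.tsv
srt run      --config cohort.cfg --out-dir results/   # end-to-end on a simulated cohort
```

Each command writes a manifest (parameters, input digests) next to its
outputs; result tables are byte-reproducible for a fixed seed and inputs.

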