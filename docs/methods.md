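# Methods

## Specificity model

srtkit measures how concentrated a transcript's expression is across a set
of N tissue/cancer/cell-line types. Per-type expression x_it (TPM) is
converted to a ratio vector p_it = x_it / Σ_i x_it, and the specificity
score is the entropy deficit S_t = log2(N) − H(p), with the standard
convention 0·log2(0) = 0. S_t ranges from 0 (uniform) to log2(N)
(single-type); the implementation clamps to this interval so floating-point
underflow can never produce a nominally negative score or one above the
bound. Log base 2 is fixed throughout.

A transcript is called a specific RNA transcript (SRT) in the type of its
largest ratio when (a) that ratio strictly exceeds twice the second-largest
ratio and (b) S_t strictly exceeds 1. Both thresholds are exposed as
parameters (`fold_threshold`, default 2; `score_threshold`, default 1) so
sensitivity analyses are possible, but the defaults define the method. An
exact tie at the top can never satisfy the dominance condition and is
classified non-specific. Note that for N = 2 the maximum possible score is
exactly 1, so no two-type profile can ever be an SRT at the default
threshold; at least three types are needed for a call.

Transcripts with zero total expression have undefined ratios; they are
reported with a NaN score, `is_specific = False`, rather than silently
dropped, so a caller can always account for every input row.

## Aggregation and filtering

The expressed-transcript filter keeps a transcript when its TPM is strictly
greater than 0.1 in at least one sample (evaluated per type; a transcript
expressed in any type is retained matrix-wide). "Strictly greater" follows
the literal threshold definition; a value of exactly 0.1 is removed.

Per-type aggregation uses the arithmetic mean of TPM across the type's
samples by default, with median as an option. The mean is the conventional
TPM summary and matches the "average expression" term in the diagnostic
score; the choice is surfaced because the two can disagree on skewed
per-sample distributions. Type columns are ordered lexicographically so all
outputs are deterministic.

Top-variable selection (default n = 2000) ranks transcripts by the variance
of log2(TPM + 1) across samples, ties broken by transcript id. The log
transform is standard practice for heavy-tailed expression; raw-TPM variance
would be dominated by a handful of highly expressed transcripts.

GTF structure summaries treat coordinates as 1-based inclusive (the GTF
standard): an exon [s, e] contributes e − s + 1 bases. Novel-vs-annotated
status is inferred from a configurable id pattern (default: assembler-style
`MSTRG.`/`STRG.` prefixes). The median transcript length of an even-sized
set is the lower of the two middle values, so it is always an observed
length. Exon-count histogram bins are {1, 2–5, 6–10, 11–20, >20}.

## Diagnostic score

For cancer type c, candidates are transcripts expressed (> 0.1 TPM) in at
least one tumor sample of c and expressed in zero samples of the matched
normal tissue. The zero-tolerance rule in normals is deliberately strict; a
configurable `normal_tolerance` fraction (default 0) allows a stated share
of outlier normal samples to exceed the threshold. Cancers with no matched
normal tissue are compared against the union of all normal samples and the
resulting records carry a `comparator_all_tissues` flag.

Each candidate that is cancer-specific in some type is scored

    S_tc = b1 * log2(x_tc + 1) * s_tc * r_tc + b1 * b2 * s_tt

with x_tc the mean tumor TPM in c, s_tc the cancer-context specificity
score, r_tc the expression frequency (fraction of c's tumor samples above
threshold) and s_tt the tissue-context specificity score. Weight rules:

* b1 = +1 if specific in c, −1 if specific in another cancer; a transcript
  specific nowhere has no defined b1 and is reported as unrankable rather
  than scored.
* b2 = 0 if tissue-specific in a tissue other than c's origin, else 1.
* s_tt = 1 when the transcript is not tissue-specific anywhere. In that case
  b2 is also set to 1 — the only reading under which the unit credit has any
  effect; the case is not covered by the printed b2 rules, so it is
  documented here and kept configurable in spirit (the record stores both
  weights so any variant is recomputable).
* The tissue term carries b1 as well, so a cross-cancer confounder flips
  *both* terms negative.

Ranking is by descending S_tc, ties broken by transcript id; the emitted
table stores every component so the score can be reconstructed exactly from
its own row (asserted to 1e−12 in the tests).

A consequence worth stating: a transcript that is tissue-specific in the
matched tissue at *appreciable* absolute expression is removed by the
tumor-only filter before scoring. The matched-tissue credit (b2 = 1 with
s_tt > 1) can therefore only fire for transcripts whose normal-tissue
expression is concentrated but below the expressed threshold — specificity
is a property of ratios and is scale-invariant, so sub-threshold expression
can still be sharply tissue-specific. The cohort simulator plants exactly
this shape.

## Cross-context joins

Dual-specificity tables place every tumor SRT in exactly one of three
categories by comparing its tissue-context `specific_type` with the tumor's
origin tissue: matched tissue, other tissue, not tissue-specific. A
transcript absent from the tissue calls counts as not-specific there, so the
partition always sums to the tumor SRT count. The reverse table (tissue SRTs
vs tumors originating from that tissue) is computed symmetrically, and the
dual-pair count agrees from both sides by construction (asserted in tests).
Testis overlap is the per-tumor-type fraction of SRTs whose tissue call is
the testis label.

Gene-level (SRG) analysis reuses the same scoring on a gene-aggregated
profile: a gene's per-type expression is the exact ordered sum of its member
transcripts' TPM (TPM is additive over a gene's transcripts). Isoform
switching between types can cancel at the gene level, which is precisely the
signal the SRT-vs-SRG fraction quantifies.

The shipped cancer→tissue origin map pairs each TCGA-style cancer code with
its GTEx-style tissue where the anatomy is unambiguous (LIHC→liver,
LAML→blood, SKCM→skin, ...). Cancer types with no same-organ normal tissue
(CHOL, SARC, DLBC, HNSC, MESO, READ, THYM, UVM) are left unmatched rather
than guessed — READ→colon in particular is *not* assumed — and users can
override the map with a two-column TSV.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, not
any particular dataset. A single-cohort simulation over N types (default
N = 10, 20 samples per type) contains housekeeping transcripts (mean
`baseline_tpm`, default 10, in every type — the maximum-entropy null),
type-specific transcripts (baseline × `fold_change`, default 8, in the
dominant type and baseline / fold elsewhere), shared-subset transcripts
(elevated in a random 2–3 types; their top ratios tie, exercising the
dominance rejection), and all-zero silent transcripts (exercising the
undefined-score path). Per-sample values are the class mean times 2^ε with
ε ~ Normal(0, `noise_sigma`) on the log2 scale (default σ = 0.25, a
realistic between-sample spread for bulk TPM), optionally zeroed by
Bernoulli dropout. Defaults were chosen once as the reference study
conditions: 8-fold enrichment over a uniform floor is a moderately strong
tissue-marker effect, and σ = 0.25 leaves type means well resolved at 20
samples per type.

The paired-cohort generator plants, per cancer type: tumor-only markers
(expressed only in that cancer's tumors) whose normal-tissue fate follows
the configured overlap fractions (tissue-specific in the matched tissue, in
testis, in another tissue — all at sub-threshold absolute TPM, default
0.04, per the scale-invariance point above — or fully silent), plus
cross-cancer confounders (specific in the next cancer type but expressed in
the target cancer, silent in normals). Genes own 1–4 transcripts with
independently assigned classes, enabling gene-level cancellation scenarios.
Everything derives from one seeded generator, so identical seed + config
give bit-identical matrices.

What the simulations do **not** emulate: compositional coupling between
transcripts (each row is independent), read-level sampling noise,
batch/library effects, correlated samples, or assembly artifacts. Passing
recovery tests therefore demonstrates correctness of the scoring machinery
under its own model, not performance on real cohorts, whose absolute SRT
counts depend on data this package deliberately does not require.

## Numerical and design choices

* Entropy terms use the 0·log 0 = 0 convention via masked evaluation; no
  epsilon is added to ratios.
* Scores are clamped to [0, log2 N]; ratio vectors are validated to sum to 1
  within 1e−8 when supplied directly.
* TSV writes use `%.17g` and reads use round-trip float parsing, so a write →
  read cycle reproduces float64 values bit-exactly (the basis of the
  pipeline determinism guarantee). Manifest files contain a timestamp and
  are excluded from the byte-identity statement, which covers result tables.
* The test suite and the acceptance script run their simulations at modest
  sizes (hundreds of transcripts, tens of samples per type, 20–50
  replicates), chosen so the full suite completes in seconds while keeping
  pooled counts large enough (≥ 1000 planted calls, ≥ 6000 null transcripts)
  for stable rate estimates.
* The independent reference used in tests computes ratios as exact rationals
  and entropy with 50-digit arithmetic; it shares no code with the numpy
  path.

## Known limitations

* Specificity with N = 2 types can never clear the score > 1 threshold (see
  above); callers comparing two conditions should use a differential test,
  not this index.
* The tumor-only filter's zero-tolerance rule makes candidate sets sensitive
  to a single contaminated normal sample; `normal_tolerance` exists for that
  reason but defaults to strict.
* Expression frequency r_tc uses the same fixed threshold as the expressed
  filter; very low but consistent expression contributes log2(x+1) ≈ x/ln 2
  but zero frequency, sending S_tc to the bare tissue term.
* The shipped origin map is a reconstruction from public tissue/cancer
  pairings and is intentionally conservative about ambiguous anatomy.
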