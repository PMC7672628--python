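# Methods

This note documents the models and procedures implemented in `utrzga`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical details a maintainer would need.

## 3′UTR definition and extraction

A transcript's 3′UTR is taken from the base **after** the stop codon to the
transcript end. The CDS is assumed to include the stop codon (RefSeq
convention), so on the + strand the UTR is the genomic interval
`(cds_end+1 … transcript_end)` and on the − strand
`(transcript_start … cds_start−1)`, reverse-complemented; sequences are
always reported 5′→3′ with T folded to U. Coordinates are GFF3-style
(1-based, inclusive) throughout; conversions to Python slices happen only
at the sequence-access boundary.

Two modes are provided. The default **span** mode takes the contiguous
genomic slice, which is the plain reading of "stop codon to transcript
end"; **spliced** mode additionally removes intronic gaps using the exon
structure. Span-mode length is exactly `transcript_end − stop_end` (+) or
`stop_start − transcript_start` (−); spliced length is ≤ span length, with
equality when no intron lies in the UTR. Zero-length UTRs are legal and
produce all-zero motif counts. `N` bases are retained; a window containing
`N` never matches any motif.

When a gene has several variants, one **primary variant** is chosen
deterministically: curated accessions (`NM_`) beat predicted ones (`XM_`),
then the lowest numeric accession component, then the longest 3′UTR, then
the lexicographically smallest id. The rule is a repository definition (no
external authority specifies one); it is deterministic so that reruns are
byte-identical. Genes with no coding transcript are skipped and reported
in a skipped-genes table rather than silently dropped.

## Motif model

The six DAZL-binding motifs are degenerate only at single positions, so a
motif compiles to an explicit set of equal-length RNA words (e.g.
`UGUU(U/A)` → {`UGUUU`,`UGUUA`}). Counting is a step-1 sliding window over
the 5′→3′ sequence; **overlapping matches are counted** (a step-1 window
visits every start position), each motif is counted independently even
where motifs nest, and matching is case-insensitive with DNA input folded
T→U. The scanner is a direct window/set-membership loop; tests compare it
against an independent overlapping-regex (lookahead) oracle.

## TMM normalization

Factors follow the standard trimmed-mean-of-M-values recipe: the reference
sample is the one whose 75th-percentile count fraction is closest to the
mean across samples; per sample, genes zero in either the sample or the
reference are dropped pairwise; M (log2 fraction ratio) and A (mean log2
abundance) are computed; the M-distribution is trimmed 30% on each side and
the A-distribution 5% (the method's conventional defaults; configurable);
the factor is 2 to the precision-weighted mean of the surviving M-values
(delta-method weights `(N−x)/(Nx) + (N_r−r)/(N_r r)`), and factors are
rescaled to geometric mean 1. Normalized expression is counts-per-million
on the **effective** library (library size × factor); log2 values use a
pseudocount of 1 (bounded at 0 for zero counts; configurable). The exact
normalized scale used by the original workflow is not published; CPM on
effective libraries is the standard choice and is documented as such.
Stage profiles are the mean of replicate log2 values per stage, in the
fixed stage order oocyte, zygote, EGK.I, EGK.III, EGK.VI, EGK.VIII, EGK.X.

A note on assumptions: TMM estimates relative scale from the trimmed
majority of genes and is only identified when most genes are not
differentially expressed between samples. This matters for simulation
design (below).

## Negative-binomial GLM and consecutive-stage tests

Per gene, `log E(count_ij) = β_stage(i) + offset_j` with
`offset_j = log(effective library size)` and NB variance `μ + φμ²`.
Because the stage factor saturates the design, the likelihood factorizes
over stages and each coefficient is a one-dimensional NB mean fit, solved
by Newton scoring (score `Σ (y−μ)/(1+φμ)`, step clipped to ±5, relative
tolerance 1e-10, 100 iterations max; all-zero groups pin β at a floor of
−50, whose likelihood limit is exact). With φ = 0 the fit reduces to the
closed-form Poisson MLE and the exact Poisson likelihood is used, so the
Poisson limit is reproduced to machine precision.

**Dispersion** is estimated once on the full stage model. The common φ
maximizes the summed Cox–Reid adjusted profile likelihood (APL; the
adjustment subtracts `½ Σ_s log Σ_j μ/(1+φμ)`), optimized on a bounded
log-scale. Per-gene dispersions maximize `APL_g + n₀·mean(APL)` on a grid
of 21 points spanning ±10 doublings around the common value with quadratic
interpolation between grid points, clamped at 1e-8. The prior weight
n₀ = 10 genes moderates noisy per-gene estimates toward the common value.
The original workflow names edgeR; this implementation reproduces the
common + moderated-tagwise scheme but not edgeR's trended shrinkage —
a documented divergence. (The source description "the dispersion parameter
of each sample" is read as per-gene dispersion, the convention for NB
count models; per-sample NB dispersion is not identifiable here.)

Each of the six consecutive-stage contrasts is a likelihood-ratio test of
the model that merges the two stages against the model that separates
them: statistic `2·Δ logLik` against χ²(1). Small negative statistics
(numerical noise) are clamped at 0; anything below −1e-6 is an error.
BH adjustment is applied **within each contrast** (the standard practice;
whether the original pooled across contrasts is unstated). Calls:
up ⇔ FDR < 0.05 ∧ log2FC > 1; down ⇔ FDR < 0.05 ∧ log2FC < −1;
unchanged ⇔ significant but between the bounds; not significant otherwise.

Reported log2FC uses group abundances (group count sum over effective
library sum) with a small library-proportional prior count (0.125 per
average library) to avoid ±∞ on zero-count groups; the LRT itself uses
unpenalized fits.

## Temporal archetype classification

Rule order per gene, given its six contrast calls and log2 stage profile:
(1) `low_expressed` if no stage mean reaches log2-CPM 1 (operationalizing
"detected in only a few transcripts"); (2) otherwise the earliest contrast
called *up* sets the label — oocyte→zygote ⇒ `zga1_activated`; any of
zygote→EGK.I, EGK.I→EGK.III, EGK.III→EGK.VI ⇒ `zga2_activated`;
EGK.VI→EGK.VIII or EGK.VIII→EGK.X ⇒ `post_zga_activated`; (3) otherwise
any *down* call ⇒ `maternal_decay`; (4) otherwise `constitutive`.
A decline flag — a *down* call at either of the last two contrasts — is
set independently, so a transiently activated gene (the DAZL-like shape)
reads as `zga1_activated` + decline. The qualitative wave descriptions
("slightly/sharply increased") carry no published numeric thresholds; the
DE-call-based rules are this package's definition.

## 2^−ΔΔCt

Per test-stage replicate: ΔCt = Ct_target − Ct_reference-gene;
ΔΔCt = ΔCt − mean(ΔCt at the reference stage); fold = 2^−ΔΔCt. The method
assumes perfect (factor-2) amplification efficiency. Significance uses a
t-test on the ΔCt replicates between the two stages, Welch by default
(equal variances are not assumed). Adding a constant to every Ct value
leaves all folds unchanged.

## Synthetic-data generator

The generator builds the entire test universe from one seed, so identical
configs produce byte-identical bundles.

**Genome/annotation.** Genes alternate strands on one chromosome. Each
primary transcript is an ATG, a T-free CDS body (T-free codons cannot
spell a stop), a TAA stop, and the UTR; ~30% of genes carry a canonical
GT…AG intron inside the CDS (two exons), and ~25% get a decoy `XM_`
variant with a half-length UTR to exercise the primary-variant rule.

**Planted motifs.** UTR backgrounds are drawn from {A,C,G}: all six motifs
require U, so the background can never match. Planted words are separated
by ≥7 T-free spacer bases so no 7-bp window spans two plants. One subtlety
is unavoidable: a planted word ending in …UU followed by any T-free base
creates a `GUU(U/A)`/`GUUG`/`GUUC` match at the junction. Truth counts are
therefore recorded by an exact regex recount of the finished sequence —
they remain exact by construction (nothing probabilistic), and the scanner
is required to reproduce them perfectly, gene by gene and motif by motif.

**Counts.** Archetypes are step functions on log2 stage means with step
size `effect_size` (default 2.0 log2): `zga1` steps up at the zygote,
holds to EGK.VI and returns at EGK.VIII (the transient minor-wave,
DAZL-like shape); `zga2` steps up at EGK.III; `post_zga` at EGK.VIII;
`maternal_decay` declines monotonically (steps down at EGK.I and EGK.X);
`silent` sits near zero (mean 0.05). Counts are NB with dispersion
φ = 0.1 (a typical bulk RNA-seq replicate dispersion) around
`stage mean × library factor`, where per-sample factors derive from
target totals drawn once from `lib_size_range`. Base means are uniform on
100–800 so planted effects sit in the well-powered regime. The default
design is the study's: 7 stages × 3 replicates = 21 samples.

**Archetype mix.** Defaults are majority-constitutive (constitutive 0.55,
maternal decay 0.10, zga1 0.10, zga2 0.10, post-ZGA 0.08, silent 0.07).
This is deliberate and load-bearing: TMM normalization is only valid when
most genes are stable at every contrast, which is true of real whole
transcriptomes. A mix in which most genes change somewhere makes every
logFC estimate biased by construction — a property of such data, not of
any implementation — so the generator emulates the realistic regime
(≤ ~18% of genes moving at any single contrast).

**Problem sizes.** Default bundles use 200 genes with 80k–160k total
counts per sample (several hundred counts per gene per sample). Larger
simulations (e.g. 2,000 genes for calibration studies) scale
`lib_size_range` proportionally to preserve per-gene depth; at fixed
totals, adding genes dilutes counts below the regime the planted effect
sizes are specified for.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic base composition or UTR length
distributions (backgrounds are T-free by design); read-level artifacts
(mapping, multimapping, positional bias — simulation starts at the count
matrix); trended mean–dispersion relationships (φ is a single value);
correlated genes (counts are independent across genes given library
factors); partial or mis-annotated UTRs beyond simple non-coding decoys.

## Numerical and degenerate-input policy

- TMM: samples sharing no expressed gene with the reference are an error
  naming the sample; a single sample gets factor 1; zero library sizes are
  errors.
- Dispersion: all-zero matrices are errors; all-zero genes inherit the
  common dispersion; estimates are clamped at 1e-8.
- LRT: identical fits give statistic 0, p = 1; non-nested calls are
  errors.
- BH: empty input returns empty; adjusted values are monotone and capped
  at 1 (step-up with a stable mergesort).
- Classifier: a missing contrast is an error; every gene receives exactly
  one primary label.
- Pipeline: the manifest (seed, parameters, per-file row counts, stage
  timings) is written even when a stage fails, with the failing stage
  named; reruns under a fixed seed are byte-identical.

## Known limitations

- Dispersion moderation is a fixed-weight prior toward the common value,
  not an abundance-trended prior; genes far from the typical
  mean–dispersion trend are moderated toward a global, not local, value.
- The χ²(1) reference for the LRT is asymptotic; at n = 3 replicates the
  test is mildly liberal at extreme significance levels (measured type-I
  fraction at p < 0.05 stays within [0.03, 0.07] in the bundled
  calibration run).
- TMM residual composition bias: with ~10% of genes changing at a
  contrast, estimated logFC carries a small bias (observed ≤ ~0.15 log2 at
  the default conditions); this is inherent to scale normalization, not
  removable by implementation.
- Span-mode UTRs may cross introns by construction; spliced mode is
  provided but the generator never places introns inside UTRs, so that
  path is exercised only by hand-built cases in the tests.
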