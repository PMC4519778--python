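# Methods

## Scope and data model

`ateseq` analyses alternative transcript usage in a 2×2 design (two macrophage
types × two treatments, donors as replicates). Inputs are an Ensembl-dialect
GTF (exon and CDS rows with `gene_id`/`transcript_id`), a transcript × sample
count table, and a sample sheet (`sample_id`, `mf_type` ∈ {MDM, IPSDM},
`treatment` ∈ {naive, LPS}, `donor`). Internally all coordinates are 0-based
half-open; GTF I/O converts to and from the 1-based inclusive convention.
Book-ended exons are merged on read (with a warning) because they are
indistinguishable in exonic space; transcripts of one gene on conflicting
strands are a hard error because the event algebra is undefined across
strands.

## Event algebra

Given two isoforms of a gene, divergence is defined per base: the exonic
symmetric difference, anchored at the first and last genomic positions
present in both transcripts. Divergent intervals entirely before the first
shared base form one upstream event and after the last shared base one
downstream event; each maximal internal run of divergent intervals — split
only where a shared exonic base intervenes, not by introns common to both
isoforms — forms one contained event. Positional classes are mapped to
transcript orientation by strand, so upstream ↔ alternative promoter,
contained ↔ alternative splicing, downstream ↔ alternative 3′ end.

Design choices made where several definitions were defensible:

- **Base anchoring, not exon anchoring.** Partial terminal-exon extensions —
  the dominant mode of 3′ UTR shortening — only register as events when
  divergence is defined per base.
- **One event per maximal internal run.** Internal runs are not subdivided
  into donor/acceptor subtypes; the three positional classes are the unit of
  reporting, and several internal runs in one gene yield several events.
- **Coding consequence.** An event is `coding` when the CDS symmetric
  difference restricted to its divergent intervals exceeds 100 bp (strictly).
  If neither transcript has an annotated CDS the event is non-coding; if one
  side has CDS, the change is computed on what exists. This conservative rule
  keeps UTR-only 3′ events cleanly separated for the UTR-length analysis.
- **Pairs sharing no exonic base** are kept as a single whole-transcript
  `contained` event with a warning rather than dropped.

Event annotations are built per event as two synthetic transcripts
(`<event>.ref`, `<event>.alt`): the divergent exons of each alternative plus
up to `flank_exons` (default 1) shared exonic intervals on each side that
touches shared space — upstream events are flanked only downstream and vice
versa. One flanking exon anchors junction-informative signal, in the spirit
of event-centred isoform models, while keeping annotations short.

The algebra is verified exhaustively: all ~16 000 ordered pairs of exon
chains with ≤ 4 exons on an 8-point coordinate grid, on both strands, are
compared against an independent per-base brute-force classifier, together
with the strand-flip symmetry (promoter ↔ 3′ end labels swap, splicing is
fixed).

## Quantification

Counts become TPM by dividing by transcript length and rescaling each sample
to 10⁶. Transcript proportions are TPM divided by the gene's TPM sum;
samples where a gene is silent are flagged missing rather than zero-filled.
The expressed-gene filter computes mean gene TPM within each of the four
condition groups and keeps genes strictly above 2 TPM in all groups (an
`any_condition` mode exists for gene-level analyses).

Events are re-quantified by structural compatibility: a transcript whose
exonic structure, restricted to the event's genomic span, equals one
alternative's structure contributes its TPM to that alternative; transcripts
matching neither are ignored. The event proportion is ref/(ref+alt). This
aggregation replaces a re-run of read assignment on the reduced annotation;
it is identical in expectation when transcript-level estimates are unbiased,
which the synthetic recovery experiments confirm at the scales used here.

## Model selection

Per-sample proportions are clamped to [10⁻³, 1−10⁻³] and logit-transformed;
the clamp bounds the influence of zero-expression samples. Five nested
Gaussian linear models over LPS and macrophage type are scored by the
closed-form evidence of Zellner's g-prior (g = n, the unit-information
default) with a reference prior on intercept and variance; for a constant
response the R² → 0 limit is used, so richer models are penalised purely by
their dimension. Posteriors combine the evidences with the prior
(0.6, 0.1, 0.1, 0.1, 0.1) — most transcripts are not expected to change —
and significance is posterior(null) < 0.05. The best non-null model maps to
an effect class: LPS, MF type, both (same direction), or — for the
interaction model — `opposite` when the LPS response changes sign between
cell types and `both_same` otherwise. Features with fewer than two usable
samples in any condition group are skipped (flagged, not errored).

This closed-form selector is deterministic and calibrated by simulation: on
1000 null genes (logit noise sd 0.2, 5+4 donors) fewer than 1 % reach
significance; a pure LPS shift of 3 logit units is detected as the LPS model
in essentially every replicate; and evidence for the true model grows with
sample size (checked at n = 8, 16, 32). It does not attempt to reproduce
posterior values of MCMC-based samplers that integrate quantification
uncertainty; its decision rule (prior vector plus the 0.05 threshold on the
null posterior) is the preserved contract.

## Two-step pipeline

Step 1 screens annotated transcripts of expressed multi-isoform genes and,
per gene, pairs the most highly expressed transcript (highest mean TPM over
all samples, identity fixed across conditions; ties to the lexicographically
smallest id, logged) with the most significantly changed one (minimum
posterior-null; ties by larger maximal proportion change, then smallest id;
p-null ties are compared with a relative tolerance because mirrored
proportions of a two-isoform gene produce exactly tied evidences up to
rounding). Genes whose best transcript is not significant, or whose top
transcript is itself the most significant, are skipped.

Step 2 decomposes each pair into events, re-quantifies, re-tests, and keeps
events with posterior-null < 0.05 **and** a mean-proportion change of at
least 0.10 in one of three contrasts: naive MDM vs naive IPSDM, naive vs LPS
within MDM, naive vs LPS within IPSDM. The 10 % filter's contrast set is a
concrete choice — the maximum over the three listed contrasts, logged per
event — since "between two conditions" admits several readings. Retained
events get effect classes, UTR-length labels (which alternative of a
non-coding 3′ event has the longer exonic extent; ties toward the reference,
logged) and are exported as TSV plus event GTF, with every threshold echoed
into a run manifest. The analysis path contains no randomness; reruns are
byte-identical.

## Gene-level differential expression

A deliberately simple log-normal working model stands behind the gene-level
module: median-of-ratios size factors, then per-gene OLS of
log2(normalised count + 0.5) on LPS, MF and LPS×MF (vectorised across genes
via one shared hat matrix), t-tests per contrast, BH correction per term.
Defaults flag main effects at FDR < 0.01 with fold change > 2 and the
differential-response rule at interaction FDR < 0.1 with a fold-change
difference > 2 between the cell types' LPS responses (applied to raw, not
shrunken, estimates). This is not a negative-binomial Wald test with
dispersion shrinkage; its job is synthetic recovery at the configured
thresholds, which it meets with ≥ 90 % power at 4-fold effects
(NB dispersion 0.05, 5+4 donors) and honest null calibration.

## Downstream summaries

- **Proportion PCA**: genes × samples matrix of top-transcript proportions
  (natural scale; the logit alternative was considered and not taken since
  proportions are the reported quantity), column-centred SVD, signs fixed by
  making each component's largest-magnitude loading positive.
- **UTR asymmetry**: per UTR-only 3′ event, the long alternative's mean
  proportion within each condition group, grouped by effect class.
- **Overlap and enrichment**: hypergeometric upper tail for gene-set
  overlaps, two-sided Fisher exact by the probability-mass rule, and a
  chi-square goodness-of-fit on decile-binned absolute PC loadings for
  flagged genes (with an exact multinomial fallback below 10 flagged genes).
  The decile binning of |loadings| is this package's concrete
  operationalisation of "higher than expected weights" on a component.

## Synthetic cohorts

The generator emulates the study design: 5 MDM and 4 IPSDM donors, each
naive and LPS-stimulated (18 samples). Each gene carries two isoforms
differing by exactly one event — distinct first exon (promoter), one cassette
exon (splicing), or a terminal-exon extension (3′ end; by default 25 % of
these also rewrite > 100 bp of CDS, the rest are UTR-only) — with strands
alternating so both orientations are exercised. Default class mixtures:
events 30/30/30 % promoter/splicing/3′ plus 10 % structural-only ("none")
genes, whose proportions are held constant; effect classes among the rest
are 40 % null, 20 % LPS, 15 % MF type, 20 % both, 5 % opposite. The focal
isoform's proportion starts at 0.5 and moves by Δ = 0.3 (natural scale,
clipped to [0.02, 0.98]) in the affected groups; the focal isoform is named
`.t2` so the step-1 tie-break on exactly mirrored two-isoform evidences
resolves to a usable (top, changed) pair. Gene totals are log-normal
(median 500, log-sd 0.8); 15 % of genes additionally change total expression
4-fold under LPS (half up, half down) to exercise the gene-level DE branch;
transcript means are total × proportion × length factor and counts are drawn
NB with dispersion 0.05. Donor random effects are off by default (donors are
treated as replicates) but available (`donor_sd`) for robustness checks.

Problem sizes were chosen to keep the full validation suite fast at
workstation scale: five 200-gene cohorts for recovery, 1000 features for
calibration, two cohorts at Δ = 0.05 for the weak-effect check.

What the simulations do **not** contain — and hence what passing tests do not
demonstrate about real data: quantification uncertainty and read-level bias
(counts are drawn per transcript, not assigned from reads), genes with more
than two isoforms, compound events on one transcript pair, per-event spread
in effect sizes (every affected gene moves by the same Δ, which makes
between-cell-type effect-size correlations cluster rather than spread),
correlated gene-level and transcript-level regulation (the DE and ATE gene
sets are drawn independently, so their overlap is null by construction), and
donor structure in the default setting.

## Numerical conventions

Logit clamp 10⁻³; g = n; p-null tie tolerance 10⁻⁶ relative; top-transcript
and UTR-length ties resolved lexicographically / toward the reference and
logged; all-zero expression columns kept as zero TPM with a log entry;
missing proportions excluded sample-wise with ≥ 2 samples per group required;
BH values capped at 1; PCA deterministic up to the stated sign rule. The
weak-effect criterion is measured on the final retained event table, where
the 10 % filter acts jointly with the significance gate.
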