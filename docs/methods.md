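# Methods

`retrocount` implements a repeat-compartment analysis of DNA methylation and
transcription: class-level differential methylation from HpaII-representation
(HELP-seq-style) tag libraries, per-locus methylation and expression fold
changes from uniquely mapped reads, a shifted-window control for read-through
transcription at LTR retrotransposons, and the integration of the two assays.
This note records the statistical model, the choices made where the design
was genuinely open, and what the synthetic validation scenes do and do not
establish.

## The methylation statistic

HpaII cuts CCGG only when the internal cytosine is unmethylated, while its
isoschizomer MspI cuts regardless of methylation. A sequenced HpaII
representation therefore samples the *unmethylated* fraction of a genome's
CCGG sites, and the MspI library run in parallel controls for copy number
and experimental variability. Comparing two HpaII libraries (tester = mutant,
driver = control), the class-level statistic for repeat stratum *S* is the
2×2 contingency table

|            | tester | driver |
|------------|--------|--------|
| tags in S  |   a    |   c    |
| tags not in S |  b  |   d    |

over repeat-overlapping tags only (non-overlapping tags are discarded before
counting), with odds ratio OR = (a·d)/(b·c), a two-sided Fisher exact test
and Bonferroni correction over the strata tested at the chosen level (class,
class/family, or repeat name). OR > 1 means a relative excess of
unmethylated-site tags — hypomethylation — in the tester.

Numerical choices:

- **Fisher's exact test** sums hypergeometric probabilities ≤ the observed
  table's probability, evaluated in log space (`gammaln`) so arbitrarily
  large library margins neither overflow nor lose precision; tail membership
  uses a 1e-7 relative tolerance on the float comparison. A table with an
  empty row or column margin returns p = 1 — a degenerate table carries no
  evidence against independence.
- **Zero cells** in the odds ratio get the Haldane–Anscombe +0.5 added to
  every cell; such results are flagged in the output.
- **Low-complexity and simple repeats** are excluded from class-level tests
  by default (these compartments are essentially unmethylated in wild-type
  somatic cells, so the contrast is uninformative); a flag re-includes them.

The in-class/out-of-class construction has a known compositional property:
when one class gains unmethylated mass, every other class's share of the
library shrinks, so unplanted classes drift to OR < 1 as
OR(X) = (W_d − w_X)/(W_t − w_X), with W the total unmethylated repeat mass
and w_X the class's own (unchanged) mass. This is not an artefact of the
implementation but of the statistic itself — with several strongly
hypomethylated compartments, untouched classes show mild "hypermethylation"
odds ratios. Interpreting class tables should therefore lean on the strongly
deviating strata, not on small deviations of the remainder.

Per-locus methylation uses depth-normalised pseudocounted fold changes,
`log2(((a+0.5)/N_t)/((c+0.5)/N_d))` (positive = HpaII tag excess = less
methylation), a locus-vs-rest-of-library Fisher test, and
Benjamini–Hochberg correction restricted to loci passing the MspI
copy-number filter (both MspI counts ≥ `min_mspi`, default 2). Loci failing
the filter never enter the BH family: copy-number artefacts would otherwise
dominate the discovery list, which is precisely what the MspI control
exists to prevent.

## The expression statistic

Expression is counted per repeat locus from uniquely mapped reads using the
same overlap rules as tag assignment (≥1 bp overlap; multi-overlaps resolve
to the largest overlap, ties to the leftmost locus — a declared convention,
since custom counting scripts rarely document theirs). Read strand is taken
as transcript strand; converting dUTP (`fr-firststrand`) SAM flags is a
documented pre-processing rule (first-in-pair is antisense to the
transcript).

Differential expression between two conditions uses a conditional exact
binomial test: given the per-locus total n = m + c, the mutant count m is
Binomial(n, N_m/(N_m+N_c)) under the null of equal normalised expression.
This is the zero-dispersion limit of a negative-binomial exact test; with a
single library pair and no replicate structure, a dispersion parameter is
not estimable, so the fully specified conditional test is preferred. The
consequence is acknowledged: true biological over-dispersion would inflate
the test's significance, which the synthetic scenes (Poisson by
construction) cannot reveal. Two-sided p-values double the smaller tail,
capped at 1 — a conservative rule for discrete tests (each tail is exact at
α/2). Only informative loci (total ≥ `min_total`, default 5) enter the BH
family; a Fisher-type exact test has no power below that.

Fold-change distributions are summarised as Gaussian kernel densities
(Silverman bandwidth by default) with the fractions beyond the ±5 log2
thresholds computed on raw values, not on the smoothed curve; degenerate
all-identical inputs fall back to a normalised histogram. The activation
fraction is the share of informative loci with positive (or
threshold-exceeding) fold change.

## The read-through control

Transcription entering an LTR from an upstream promoter mimics autonomous
activation. The control re-runs the differential test on width-matched
windows shifted 10 kb up- and downstream of each LTR (reference
orientation; strand-aware shifting is available behind a flag, but the
default is symmetric since the published control treats both directions
equivalently). Windows leaving chromosome bounds are dropped. Each window
records whether it overlaps any annotated repeat; signal in a flagged
window is attributed to the neighbouring repeat, not to read-through, so
flagged windows are excluded from read-through calls. A locus is classified
`read_through` when its upstream window is significant and unflagged,
`autonomous` when the body is significant and the windows are quiet or
flagged, `ambiguous` when the downstream window is also significant and
unflagged, and `none` otherwise.

## Integration

The joined per-locus table reports the expression log2 fold change against
the methylation change. Sign convention: per-locus HELP statistics are fold
changes in HpaII *tag abundance* (positive = hypomethylation); the joined
`meth_log2fc` is negated into *methylation* direction so hypomethylated
loci sit below zero. Quadrants use ±5 (expression) and ±1 (methylation)
log2 thresholds; `hypo+up` marks loci that both lose methylation and gain
expression. Conditional summaries filter on the raw p-value (< 0.05) by
default — matching the published filtering — with BH filtering behind a
flag. Gene-distance comparisons between upregulated loci and the
genome-average baseline use a two-sided Mann–Whitney rank-sum test, chosen
because the distance distributions are heavy-tailed and no parametric form
is defensible.

## Assay arithmetic

- Bisulfite clone matrices code each clone × CpG cell as
  methylated/unmethylated/unknown/non-consensus; percent methylation is
  100·M/(M+U) with unknown *and* non-consensus cells excluded from the
  denominator (the published figures distinguish non-consensus CpGs
  visually but state no arithmetic rule; excluding them is the
  conservative reading). Column subsets give single-site percentages.
- ChIP enrichment is 100·IP/(input/input_fraction), the input fraction
  scaling the measured aliquot to its whole-chromatin equivalent.
- qRT-PCR relative expression is the ΔCt method, efficiency^−(Ct_target −
  Ct_reference) with efficiency 2 assumed (perfect doubling; the standard
  assumption when no standard curve is reported). Undetermined Ct or a
  positive no-RT control yields expression 0 with a QC flag.

## The synthetic scenes

The generator builds a toy genome (default: four chromosomes totalling
100 Mb) with non-overlapping repeat loci from a fixed taxonomy
(LINE/L1/L1Md_A, LTR/ERVK/IAPEz-int, LTR/ERVK/IAPLTR1, LTR/ERVL/MERVL-int,
SINE/B1/B1_Mm, Satellite/major/GSAT_MM, tRNA/tRNA-Lys), 350/60/450/120/150
loci for LINE/LTR/SINE/Satellite/tRNA of 0.5–3 kb, CCGG sites at 2/kb
inside repeats plus a 0.02/kb background, and 300 genes of 2 kb.

**Methylation model.** Bulk DNA pools many cells, so a site carries a
methylated *fraction* (its class/genotype probability), not an on/off
state: each sampled fragment is methylated independently with that
probability. Conditional on the fixed library budget, the HpaII library is
multinomial over sites with weights ∝ (1 − meth_prob) and the MspI library
is uniform over all sites. This matters at toy scale: drawing one Bernoulli
state per genomic site would add extra-multinomial variance that a genome
with ~2 million CCGG sites dilutes to irrelevance but a 6,000-site toy does
not, and it would make the class-level Fisher test anti-conservative for
spurious reasons. The fragment-level model keeps every closed-form
expectation (per-class HpaII expectation ∝ n_sites·(1−meth_prob); a planted
0.9→0.4 delta multiplies the class's tag odds by exactly 6) while leaving
the null scene calibrated. Spatial autocorrelation of methylation between
neighbouring CpGs — observed in real data — is deliberately not modelled.

**Expression model.** Reads per repeat locus are Poisson with mean
`base_expression · 2^(log2FC·[mutant])` (default 20 reads/locus), placed
uniformly on the locus strand. Genes contribute Poisson(500) reads each in
*both* conditions: the stable transcriptome bulk. This background is
essential, not cosmetic — without it, repeat reads are the whole library,
planted activation inflates the mutant total ~3-fold, and raw-total depth
normalisation absorbs ~1.1 log2 of a +5 planted effect. With the gene
background the residual composition shift is ~0.2 log2, comparable to what
trimmed-mean normalisation would remove in a real analysis; observed fold
changes at planted +5 loci centre near +4.8 rather than +5.0, and the
summaries account for that honestly rather than normalising it away.

**Read-through model.** A configurable fraction (default 0.1) of
expression-planted LTR loci transcribe from exactly 12 kb upstream through
the locus, fully covering the 10 kb shifted window. Read-through is planted
only at differential loci: a read-through transcript at a non-differential
locus produces no signal in either window and is unclassifiable by the
shifted-window logic, so planting it would test nothing.

**Study conditions.** Control methylation {LTR 0.9, LINE 0.85,
Satellite 0.9, SINE 0.6, tRNA 0.3}; the default (coupled) mutant loses
methylation at LTR and LINE (→0.4) and satellite (→0.6) while expression
is planted only at IAP names (+5 log2) — LINEs hypomethylated but silent,
the central dissociation the analysis must resolve. Named variants:
`null_config` (no deltas), `ltr_delta_config` (LTR 0.9→0.4 only),
`readthrough_config(fraction)`. Library depths default to 100k tags per
HpaII/MspI library (50k in the calibration scenes). The class composition
keeps the planted LTR unmethylated-mass delta small relative to the
out-of-class mass so that compositional OR shrinkage of unplanted classes
stays mild (closed form ≈ 0.85–0.92); with large planted classes the
shrinkage is intrinsic to the statistic, as discussed above.

**What passing tests show — and don't.** The scenes establish that the
statistics are calibrated under their own sampling model (multinomial tags,
Poisson reads) and that planted truth of realistic magnitude is recovered
through the full pipeline. They do not establish robustness to
over-dispersion between biological replicates, mappability structure,
methylation autocorrelation, or annotation error, none of which the
generator emulates.

## Problem sizes and determinism

Calibration runs use 200 null seeds at 50k tags/library; recovery runs use
50 seeds (class level) and 20 seeds (per-locus and integration) at the
default depths — sizes at which the binomial uncertainty of the reported
rates is a few percent, chosen as the package's own validation conditions.
Per-locus methylation sensitivity is evaluated over planted-class loci
containing ≥1 CCGG site, since a locus with no HpaII site is outside the
assay's universe. All randomness flows from `numpy.random.default_rng`
seeded per scene; a fixed seed reproduces every output file byte for byte,
and the pipeline manifest records seed, thresholds and input checksums.

## Known limitations

- Single library pair per condition; no replicate-based dispersion
  estimation (see the expression section).
- The tag-to-locus tie-break (largest overlap, then leftmost) is a declared
  convention; other counting scripts may differ on the small minority of
  boundary-spanning reads.
- Whether class-level odds ratios should be MspI-normalised is left as an
  option (off by default): the contingency construction already conditions
  on library totals, and at class level copy number is identical between
  genotypes by design.
- The joined analysis inner-joins loci observed in both assays; loci
  informative in only one assay are counted and logged, never imputed.
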