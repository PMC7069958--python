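# Methods

This note documents the statistical procedures implemented in `bioidflow`,
their assumptions, the tunable parameters, and the design choices made where
the conventions in common use are under-specified.

## Enrichment calling

**Model.** For a bait condition (wild-type or DNA-binding-deficient mutant)
versus the GFP control in one tissue, each replicate contributes one
statistic per protein group: the log2 ratio of LFQ intensities,
`r = log2(case / control)`. An intensity of 0 means "not quantified"; three
cell states follow: finite ratio (both quantified), `+INF` (case quantified,
control not), `NA` (case not quantified, regardless of the control). The
procedure is a threshold rule, not a model fit: no distributional inference
(moderated-t, permutation FDR) is attempted, because the replicate-level
threshold-and-consensus rule *is* the method being reproduced.

**Pipeline order.** ratios → infinite-ratio imputation → median
normalization → threshold → consensus call. The centring median is computed
over all finite values per replicate, which after imputation includes the
imputed cells; `+INF` markers never enter a median.

**Imputation of infinite ratios** (`imputation.strategy`):

- `control-floor` (default): `+INF → log2(case / m)` where `m` is the
  minimum positive intensity observed in that replicate's control sample —
  the control's empirical detection floor. This keeps the case-intensity
  information: a strongly detected case with an absent control receives a
  large but finite ratio. Requires the control sample to contain at least
  one positive intensity.
- `max-finite-plus`: `+INF →` (largest finite ratio in the replicate) + 0.5,
  a rank-preserving cap useful when control floors are unstable.

**Threshold.** Per replicate, with `trim_mass = 0.90` and `k = 2`:

    upper = median(all finite values)
            + k · SD(values within the [5th, 95th] percentile interval)

Percentiles use linear interpolation between closest ranks with inclusive
bounds; the SD uses the n−1 denominator; at least 5 finite values are
required. Trimming is symmetric (central 90%); an upper-tail-only trim would
be an alternative reading of "90% of the distribution" and is a worthwhile
sensitivity analysis, but the symmetric version is the one that yields a
median ± 2·SD confidence band. With `trim_mass = 1.0` the rule reduces
exactly to `median + k·SD`. Only the upper bound is interpreted; depleted
proteins are not called.

**Consensus.** A protein is a member of the interactome when its ratio is
*strictly* above `upper` in at least `min_replicates = 2` replicates; `NA`
counts as not enriched. Membership is monotone in `k` and invariant under a
constant shift of any replicate's ratios (the median cancels it); both
properties are asserted in the test suite.

## Compartment classification

With `W` and `M` the wild-type and DNA-binding-deficient interactomes of the
same tissue: chromatin = `W \ M`, nucleus = `W ∩ M`, nucleoplasm = `M \ W`.
The three sets partition `W ∪ M` by construction. The interpretation relies
on the mutant bait sampling the same nuclear neighbourhood as the wild type
except for chromatin engagement; violations (e.g. mutant mislocalisation)
would shift chromatin partners into the nucleus class.

## Multi-tissue comparison and QC

`tissue_venn` computes the exact membership partition over all non-empty
tissue combinations; identities `n_unique + n_shared = n_total` and
"per-tissue total = Σ of combinations containing the tissue" hold on every
input. Proteins are compared by `protein_id` (first entry of the majority
protein identifier list) rather than gene name, to avoid collapsing isoforms.

Replicate QC uses Pearson correlation of log10 LFQ intensities on
pairwise-complete cells (both samples quantified); pairs with fewer than 3
complete cells are reported NA. Imputed values are deliberately excluded
from QC. For PCA/heat maps, `embedding_matrix` fills missing cells per
sample from `Normal(mean − 1.8·SD, (0.3·SD)²)` of the observed log10 values
— the de-facto downshifted-normal convention of interactive proteomics
software, whose parameters (1.8, 0.3) are exposed and logged.

## TF co-binding

Peaks are resized to `window = 1000` bp centred on `floor((start+end)/2)`,
clipped at 0. A **co-bound locus** is a connected component of overlapping
resized intervals (strictly overlapping; abutting intervals do not merge)
containing at least one peak from each factor, computed by a sweep line per
chromosome. Counting merged components rather than per-A-peak events makes
the co-bound count symmetric in the two factors, which a single Venn-cell
number requires; `n_a`/`n_b` contributor counts per locus are retained.

Signature comparison overlaps the co-bound loci of two TF pairs at ≥ 1 bp,
again as connected components; `n_shared` is the number of mixed components
and exclusivity per side is `1 − shared/total` (percent, rounded).

Gene assignment: a gene is assigned to a region if its promoter window
(strand-aware `[TSS − 2000, TSS)` on +, `(TSS, TSS + 2000]` on −, half-open
0-based) or gene body overlaps it; otherwise the nearest-TSS gene within
`max_distance = 5000` bp is assigned, keeping ties. "Vicinity" has no
standard definition; 5 kb is a conservative regulatory-neighbourhood radius
and is exposed in the API. Feature classification uses precedence
promoter > gene body > intergenic so a region is never double-counted.
Coordinates are BED-convention (0-based half-open) internally; GFF3 is
converted on read/write.

## Category enrichment

One-sided Fisher exact test per category: `p = P[X ≥ k]` with
`X ~ Hypergeom(N, n, K)` (background size N, category hits in background n,
foreground size K, foreground hits k), fold = `(k/K)/(n/N)`, BH-FDR across
tested categories. Enrichment only — depletion is not tested. The
recommended background universe is all proteins passing canonical filtering
and quantified in ≥ 1 replicate of the relevant experiment; the universe is
an explicit argument, never implicit. The hypergeometric tail comes from
scipy and the BH step-up from statsmodels; both are verified against
exhaustive enumeration and the textbook definition in the test suite.

The imaging ratio `relative_signal_over_background` is the ratio of
(reporter/DAPI) channel means in the signal region to the same quantity in a
background region; segmentation is out of scope.

## Synthetic data: what it emulates and what it does not

**LFQ generator.** 3 conditions (WT, N51A, GFP) × 4 replicates. Per protein,
a baseline log10 intensity `~ Normal(6.5, 0.6)` (the span of label-free
intensities for a few-thousand-protein experiment). Planted interactors add
`effect_size` (default 3 log2 units ≈ 8-fold) in the conditions implied by
their class: chromatin → WT only, nucleus → WT and N51A, nucleoplasm → N51A
only. Noise is specified at the replicate-ratio level: `noise_sd` (default
`effect_size/4`) is the SD of the log2 case/control ratio, implemented as
independent per-sample noise of `noise_sd/√2`. Detection is Bernoulli with
logistic probability in the realised log10 intensity (midpoint 5.1, slope 10
per decade — a 10–90% transition of ≈ 0.44 decades around the detection
limit, giving ≈ 5% overall missingness concentrated at low abundance).
Dropout is applied after enrichment, per sample, so planted interactors
regularly lose their control measurement and exercise the infinite-ratio
imputation path. Decoy and contaminant rows receive ordinary intensities but
carry flags; they test the canonical filter, not the statistic.

The slope matters: with a broad detection transition (≲ 4 per decade),
mid-abundance proteins frequently lose only their control measurement while
sitting far above the control's detection floor, and control-floor
imputation then dominates the false-call rate regardless of the caller —
a property of the instrument model, not of the threshold rule. The defaults
describe a reasonably sharp detection limit; they are calibration knobs of
the benchmark, not claims about any particular instrument.

Not emulated: peptide-to-protein inference, shared peptides, batch effects,
intensity-dependent noise, correlated replicates. Passing recovery tests
therefore shows the caller is correct under its own assumptions, not that
those assumptions hold for any given instrument.

**Genome generator.** A single toy chromosome. Peaks occupy randomly chosen
slots of 3× the resize window, so unpaired peaks are > 2 kb from everything
else and chance co-binding is excluded by construction; exactly
`round(planted_cobind_fraction · n_peaks_a)` A-peaks get a partner B-peak at
a midpoint offset < window, guaranteeing overlap after resizing. The
recovered co-binding count is therefore an exact read-out of the planted
fraction. Genes are non-overlapping (one per genome bin), strand-random, and
independent of peak placement, so the expressed fraction among assigned
genes estimates `fraction_expressed` unbiasedly. Not emulated: peak shape,
signal strength, clustered binding, multiple chromosomes.

## Problem sizes and numerical choices

The acceptance script simulates 10 LFQ experiments of 2000 protein groups
(50 planted per class) and 20 genome fixtures of 200 + 200 peaks — sizes at
which the recovery estimates have standard errors well below the margins
they are compared against, while the whole script completes in seconds.
Ties at the threshold are resolved strictly (`>`; a value equal to the
cutoff is not enriched). Degenerate inputs raise typed errors rather than
propagating NaN: fewer than 5 finite ratios per replicate, a replicate with
no finite values, a control sample with no positive intensity, an empty
gene list. All generators and the embedding imputation are deterministic
under their seed.

## Known limitations

- The trimmed-SD rule is anticonservative by construction (the trimmed SD
  underestimates the background SD), so the effective per-replicate false
  call rate at `k = 2` is above the nominal 2.3%; the ≥ 2-replicate
  consensus is what keeps the final false-call rate low.
- Control-floor imputation overstates enrichment for proteins far above the
  control's detection floor; the `max-finite-plus` alternative caps this at
  the cost of discarding case-intensity information.
- Compartment labels inherit any miscall from either contrast; accuracy
  among weakly enriched interactors degrades before interactome recall does.
- Co-binding counts depend on the resizing and merged-component conventions
  declared above; other conventions (per-peak counting, different windows)
  yield different absolute counts on the same data.
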