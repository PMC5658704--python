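# Methods

This note documents the models, parameters and numerical conventions
behind `rslscreen`, and what the synthetic screens it generates do and do
not demonstrate about real data.

## Counting model

Reads follow a fixed-structure amplicon: a 20-base guide read from a custom
sequencing primer, a 6-base sample index (i5) and a 6-base RSL (i7), read
as three positionally synchronized FASTQ streams. Counting is exact-match
by default. The opt-in Hamming-distance-1 mode assigns a read to the unique
library guide within distance 1 and discards ambiguous reads; note that a
read identical to one guide but within distance 1 of a second is treated as
ambiguous, not resolved in favor of the exact hit. Reads are uppercased
first; any non-ACGT symbol in the guide or RSL read discards the read
(tallied, never raised). Sample indices match exactly with no mismatch
tolerance — 6-bp indices in small index sets make collisions unlikely, and
tolerating mismatches would risk sample bleed-through. RSLs are raw labels:
no error-correction network collapses near-identical RSLs, because each
observed 6-mer is treated as (part of) a lineage tag, not a molecule tag.

QC categories partition all reads with the precedence: N-containing, then
unmatched sample index, then unmatched/ambiguous guide.

## Table operations

The pipeline order is: **filter raw pair totals, then normalize, then
bin**. Filtering first matches the rule's formulation in read units;
normalizing before binning would not change bin totals' ratios but
binning-then-filtering would retain low-count lineages inside bins and is
deliberately not done. The low-count filter removes lineages with
`control + treatment < 5` (a pair total of exactly 5 is kept).

Normalization scales each column to the common target `(Σc + Σt)/2` and is
computed per replicate pair (one control and one treatment column), never
across experimental replicates. A zero column total is an error naming the
column. After subsampling by RSL prefix, normalization is recomputed
within the subsample.

Binning sums counts within (guide, RSL prefix); bins with no surviving
member lineage are absent rather than materialized as (0, 0) rows — an
empty bin carries no sampled lineages, and imputing zeros would inject
artificial `ES = 0` values into the guide median. Bin labels are literal
prefixes so outputs are self-describing.

## Guide and gene statistics

Medians of an even number of values are the mean of the two central order
statistics throughout. `MAD` is scaled by 1.4826 ≈ 1/Φ⁻¹(3/4), making it a
consistent SD estimate under normality. The control null pools all
non-targeting units into a single `MES_CON`/`MAD_CON` rather than
aggregating per-control-guide statistics; with asymmetric control sets the
two orders differ and the pooled form is used. `SSMD` is undefined (NaN,
flagged `undefined_ssmd`) when both MADs are zero and the MES differs from
the null; such guides keep their MES for fallback ranking rather than
being dropped, preserving a complete ranked list for gene aggregation.
Guides with fewer than 5 surviving units are flagged `low_units` but still
scored. A per-guide z-score standardizes the ranking score against the
mean and SD of the non-targeting guide-sets' scores; `|z| ≥ 3` sets a
`hit` flag. The threshold is a package default, chosen as the conventional
three-sigma rule, since only the null mean/SD computation itself is
prescribed.

TCA is an explicit total-count stand-in for a conventional read-count
pipeline: per-guide sums, the same total-count normalization applied at
guide level, pseudo-count-1 log2 fold changes, ascending ranking. It does
not implement a negative-binomial count test; comparisons against it
measure the value of lineage information relative to a plain fold-change
baseline fed into the same gene-ranking stage.

For LDA, presence at Day 4 mirrors the treatment-side dropout rule
(`count ≥ 2`): a lineage seen once at Day 4 is indistinguishable from a
sequencing artifact by the same logic that defines dropout. Dropout is
assessed on raw counts after the shared pair-total filter. The lineage
effect size `log2((n_day28 + 1)/(n_day4 + 1))` uses a pseudo-count of 1 on
lineage counts, by analogy with the read-level effect size, to handle
total loss. Late-appearing lineages (present only at Day 28) are reported
separately (`n_late`) and never inflate survival.

Gene ranking uses alpha-truncated robust rank aggregation: for a gene with
`k` guides at normalized ranks `u_(1) ≤ … ≤ u_(k)`,
`rho = min_{j: u_(j) ≤ alpha} P(Beta(j, k−j+1) ≤ u_(j))`, with `rho = 1`
when no guide ranks inside the top `alpha` fraction (default 0.25).
Significance comes from a permutation null — the gene's `k` ranks redrawn
uniformly without replacement — shared across genes with equal guide
counts, with the add-one estimator `p = (1 + #{rho_null ≤ rho_obs})/(1 +
n_perm)` so p-values are never zero, and Benjamini–Hochberg FDR across
genes. With `alpha < 1` the null `rho` has an atom at 1 (genes with no
guide inside the cutoff), so null p-values are uniform-with-atom:
conservative, not exactly uniform. Depletion and enrichment are separate
one-sided runs (ascending and descending guide ranking); ties in guide
ranking break lexicographically on `guide_id` for reproducibility. The
default `n_perm = 10,000` puts the p-value floor (1/10,001) far below a 1%
FDR cutoff even for screens of a few thousand genes; fewer permutations
silently make stringent FDR cutoffs unreachable.

## Simulator

The generator models the lineage story directly, in discrete divisions
grouped into passages:

| parameter | default | meaning |
|---|---|---|
| `n_genes` × `guides_per_gene` | 200 × 10 | targeting library (desk scale) |
| `n_control_guides` | 20 | non-targeting guides, efficiency 0 |
| `frac_essential` | 0.1 | fraction of genes whose loss is lethal |
| `cells_per_guide` | 400 | screen size: founders per guide |
| `rsl_space` | 256 | distinct 6-mers circulating in the library |
| `p_edit_per_division` | 0.3 | geometric editing hazard per division |
| `guide_efficiency` | Beta(8, 2) | per-guide P(cutting), mean 0.8 |
| `q_null` | 0.7 | P(a cut destroys gene function), ~2/3 frameshift |
| `sigma_lineage` | 0.04 | per-division log growth-rate SD |
| `survival_after_null` | 0.5 | per-division survival of arrested lineages |
| `n_passages` × `divisions_per_passage` | 8 × 3 | 24 divisions ≈ 28 days |
| `day4_passage` | 1 | control harvest after the first passage |
| `bottleneck_cells` | 4 × founders | reseeded population per passage |
| `depth_per_guide` | 1,000 | sequencing reads per guide per time point |

Founders per (guide, RSL) are Poisson with mean
`cells_per_guide / rsl_space`, so most observed RSL-guides trace one or
two cell lineages. Each lineage draws one edit time (geometric), one
outcome (function-destroying with probability `efficiency × q_null`), and
one constant per-division growth multiplier `2·exp(N(0, sigma_lineage))`.
A null edit in an essential gene arrests the lineage, which then decays by
`survival_after_null` per division — early edits extinguish the lineage
(dropout), late edits deplete it. Passaging applies Poisson thinning to
the reseeded population; read counts are multinomial over lineage cell
abundances at each time point. All randomness descends from one seed
through named substreams; replicates share the library but are independent
transductions.

Two calibration choices deserve explanation. `sigma_lineage` compounds
over ~24 divisions, so the total log clone-size dispersion is
`24 × sigma`; the default 0.04 yields roughly e-fold (≈2.6×) clone-size
spread, which is substantial heterogeneity while keeping the median
lineage detectable at Day 28 — much larger values let a few giant clones
absorb nearly all late reads, which contradicts how real screens of this
design behave (non-targeting guide-sets center near zero effect size, and
most early lineages are re-detected late). The default bottleneck of 4×
the founder count keeps the per-lineage population near four cells between
passages, a near-critical branching process that loses roughly 10–30% of
neutral lineages to drift over the culture — the realistic undersampling
regime in which some lineages appear in only one time point.

The simulator does **not** model: sequencing errors in guides or RSLs,
off-target editing, copy-number effects, multi-guide (passenger)
integrations, within-lineage growth drift, or lineage birth other than by
transduction. Passing tests on simulated screens therefore demonstrate the
statistical machinery under the intended lineage-kinetic model, not
robustness to sequence-level artifacts.

## Evaluation harness

Accuracy is the (median) rank of known positive-control genes — for
synthetic screens, the simulator's essential genes. Precision is the
percent overlap of the top-ranked `floor(0.05·n)` genes between two
replicates. Power is the number and overlap of depletion hits below a 1%
FDR. Smaller screen sizes are emulated by RSL-prefix subsampling: quarter
= the four groups of RSLs starting A/C/G/T analyzed separately, sixteenth
= the four groups AA/AC/AG/AT (of the sixteen 2-prefix groups, only these
four are analyzed). Because subsampling fixes leading RSL bases, binning
depth adapts per size (prefix 2 at full size, prefix 3 within subsamples)
so each subsample still yields multiple internal replicates per guide.

Desk-scale problem sizes are used throughout the test suite and the
acceptance script (hundreds of genes, tens of cells per guide); the
full-scale regime of the original experimental design (thousands of cells
per guide, 30,000 reads per guide, 4,096-RSL space with 64 bins) is
reachable through `SimConfig` without code changes.

## Known limitations

* The ambiguity rule in Hamming-1 matching rejects exact hits that have a
  distance-1 neighbor in the library; libraries designed with minimum
  pairwise distance ≥ 3 are unaffected.
* Guide-level hit z-scores require at least two non-targeting guide-sets
  with defined scores; otherwise `z` is NaN.
* `rra_rho` requires distinct integer ranks; tied guide scores must be
  resolved upstream (the provided ranking breaks ties lexicographically).
* The LDA Day-4 presence rule discards lineages extinguished before the
  control harvest; in kinetics where essentially all editing happens
  before Day 4, the observed loss fraction understates lethality (the
  simulator's ground-truth extinction fractions remain monotone in editing
  speed and are the quantity to check in that regime).
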