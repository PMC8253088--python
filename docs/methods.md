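# Methods

`migexpress` identifies putative migration-control genes by contrasting
molecular abundance between fast- and slow-migrating cancer cell lines.
This note documents the models and procedures each module implements, the
parameters that matter, what the synthetic screen does and does not
emulate, and the design decisions taken where the design was open.

## Migration quantification and classification

Exclusion-zone (ORIS-style) assays report % migration as the fraction of
the initially cell-free zone covered at time *t*:
`100 × (A₀ − A_t) / A₀`, clipped to [0, 100]. Scratch assays report a
migrated area as the difference of mean gap widths (three positions per
timepoint); a widening gap is clipped to 0 with a warning, since negative
migration is measurement noise below the wound mask. Proliferation is
summarized as population doublings `log2(N_t / N₀)` and is checked for
correlation with migration capacity — proliferation is a potential
confounder of area-closure assays, and the screen design assumes the two
are uncorrelated.

Classification operates on the **replicate mean % migration at the 48-h
endpoint** per (line, coating). The 24-h values are retained for reporting
only; 48 h is the endpoint at which the coating surfaces are compared. A
line is *fast* on a coating when its mean is strictly above 60 %
(uncoated), 75 % (collagen) or 60 % (fibronectin), *slow* when strictly
below 25 % on any coating, and *medium* otherwise. Comparisons are strict,
so boundary values fall to medium. The consensus class is the class
reached on at least two of the three surfaces. Two degenerate cases the
threshold rule does not determine are resolved as follows:

- a line measured on a single coating (e.g. it fails to attach on the
  others) carries that coating's class, and the output flags it
  (`single_coating`) so downstream users can exclude it;
- when all measured classes are distinct (no 2-vote majority), the line
  falls to *medium*, the residual category — this keeps every line
  classifiable without inventing a direction.

The per-coating value fed to classification is the replicate **mean**
(median would be equally defensible with ≥3 replicates; mean is used
throughout).

## TMT proteomics normalization

Protein intensities from multi-plex TMT runs carry two nuisance layers:
per-sample loading/labeling differences and per-plex (run-level) batch
effects. Normalization is two-stage and runs entirely on log2 intensities:

1. **Quantile alignment.** For each sample, the 11 quantiles at levels
   0.25, 0.30, …, 0.75 of its non-missing log2 intensities are computed
   (linear interpolation between order statistics — the deterministic
   default). A least-squares line maps the sample's quantiles onto the
   anchor sample's quantiles, and the fitted affine transform is applied
   to all of the sample's values. The central quantile band is used so
   that the tails (where missingness and true regulation concentrate) do
   not drive the fit. The alignment is exactly idempotent, and exactly
   inverts any affine log-space distortion. By default alignment runs
   *within each plex*, anchored at the plex's first channel: aligning all
   samples jointly to one global anchor would itself absorb the plex-level
   batch shift and leave nothing for the reference correction to estimate
   (a `joint` mode is available when no plex structure exists).
2. **Reference-channel correction.** Each plex carries a pooled reference
   sample in 2 of its 10 channels. For protein *p* and plex *k* the log2
   correction factor is the plex's mean reference value of *p* minus the
   grand mean of the per-plex reference means of *p*; all of plex *k*'s
   values of *p* are shifted down by it. The grand mean is arithmetic in
   log space, i.e. geometric on the linear scale — with only a handful of
   plexes, the geometric mean is the more robust centre for multiplicative
   factors, and both conventions differ only by a global constant per
   protein, which cancels in fold changes. Proteins with no reference
   measurement in a plex are left unchanged in that plex; proteins absent
   from every reference are flagged and never corrected. Missing values
   are excluded from every statistic and never imputed.

The correction subtracts a per-plex constant per protein, so within-plex
channel ratios are untouched. On screens with injected batch factors the
pipeline removes ≥90 % of the plex-level mean variance and recovers the
injected (mean-centered) factors with R > 0.99 (20-seed medians; both are
recomputed by `scripts/acceptance.py`).

The **detection filter** keeps proteins with a measurable signal in at
least `ceil(min_frac × n_lines)` lines (default 0.5 → 27 of 54): with an
intensity-dependent detection limit, proteins quantified in few lines have
both biased means and untrustworthy variances.

## Candidate selection

Groups: per coating, the fast and slow lines of *that coating's*
classification define the fold-change contrast; the Welch test uses the
overall consensus classes. Medium lines never enter either. Both
groupings are emitted for audit.

Per feature: FC = (mean over fast + pc) / (mean over slow + pc) on the
**linear** scale, computed per coating and averaged arithmetically
(available-value mean when a coating lacks one of the groups); FPKM
ratios are the natural fold-change language, while testing happens on
log2 values where the noise is approximately normal. The pseudocount
(default 0.01 FPKM, RNA only) guards the ratio against zero means without
materially moving expressed genes relative to the FC ≥ 3 gate. Protein
matrices arrive in log2 from the normalization; their FCs are ratios of
linearized means with no pseudocount.

Significance is a two-sided Welch *t*-test (unequal variances,
Welch–Satterthwaite df) on log2 values. Features with fewer than 2
non-missing values in either group get p = NA; zero variance in both
groups gives p = 1 when the means agree (no evidence of difference) and
p = 0 when they differ exactly.

The funnel applies, in order: (1) expression floor — RNA: mean FPKM over
**all** lines ≥ 1 (the mean over all lines, rather than the fast+slow
subset or an any-line max, is the least class-dependent reading and is
configurable); protein: the detection gate; (2) regulation — mean FC ≥
cutoff or ≤ 1/cutoff (RNA and circRNA: 3, protein: 2); (3) raw p < 0.05.
No multiple-testing correction enters selection; BH q-values are reported
alongside for reference. Counts in and out of every stage are logged and
written to the funnel JSON so the selection is auditable.

`timecourse_compare` handles wound-confluence timecourses: at each
timepoint a two-sided variance-ratio F-test (α = 0.05) routes to the
pooled-variance *t*-test when variances are compatible and to Welch's
test otherwise.

## circRNA analysis

Back-splice junction reads quantify circRNA abundance. Counts are
normalized to reads per million of each line's library; a junction counts
as *detected* in a line when its raw count is nonzero. The gene-level
analysis sums raw junction counts per gene **before** normalizing —
counts are additive only on the raw scale. Candidate selection mirrors
the RNA funnel (detection ≥ 50 % of lines, mean FC across coatings ≥ 3)
with one difference: significance is computed per coating and the
**arithmetic mean of the three per-coating p-values** is compared to α.
A mean of p-values is not itself a p-value — it is a conservative
consensus score that demands consistent evidence across surfaces; a
Fisher combined-p alternative is available (`combine="fisher"`) but is
never the default. Welch tests run on log2(per-million + 0.5); the 0.5
per-million pseudocount stabilizes log-variances at the count depths
where back-splice reads live.

## RNA–protein integration

The overlap partitions the RNA candidate list: not detected at the
protein level at all; overlapping a protein candidate with agreeing
direction (up/down); overlapping with opposing direction (reported even
when 0); detected but not a protein candidate. Protein-only candidates
are counted symmetrically. Gene matching is exact string match after
uppercasing — the synthetic screen controls its own namespace, and real
inputs can be pre-mapped. Fold-change concordance takes the genes with
p < α in **both** layers that pass both expression gates and reports the
Pearson R of their log2 mean FCs (two-sided, symmetric in up/down).

## The synthetic screen

The generator's defaults are the study conditions, not tuning knobs:
54 lines targeted at 18 fast / 10 medium / 26 slow; 3 coatings × 2
timepoints × 3 replicates of % migration; 2000 genes, 1500 proteins
(a random gene subset), 300 back-splice junctions; 5 % of features
migration-associated; replicate noise sd 3 % migration; expression noise
sd 0.5 log2 units; 7 TMT 10-plexes with 2 pooled-reference channels each,
per-plex batch factors of log2-sd 0.3 and reference-channel technical
noise of sd 0.1; logistic intensity-dependent missingness (midpoint 18,
slope 1 in log2 units); library sizes uniform in 20–60 M reads.

Mechanics and the reasoning behind the open choices:

- Each line draws a latent percentile and maps it into its class's
  % migration window per coating; the windows keep a margin of
  max(2, 2 × replicate noise sd) from the thresholds, so designated and
  observed classes agree (exactly so at zero noise), and infeasible
  noise/threshold combinations raise an error. A common latent percentile
  across coatings reproduces the high between-surface correlations a real
  screen shows (R ≥ 0.9).
- Planted effects are signed log2 fold changes with magnitude from
  N(2.0, 0.5) **truncated below at log2 3**, the screen's own regulation
  cutoff: "migration-associated" is defined as regulated at at least the
  magnitude the funnel targets. Planted genes are drawn from genes with
  baseline log2 FPKM ≥ 2, so the expression floor never hides a planted
  gene. Fast lines carry the full effect, slow lines none, medium lines
  half.
- Protein effects are attenuated copies of the RNA effects
  (0.8 × |effect| + noise of sd 1.3, sign preserved by construction),
  chosen so the RNA–protein effect correlation is ≈ 0.8 — concordant but
  imperfect, as between transcript and protein levels in real data. Sign
  preservation makes "no discordant overlap" an exact property of the
  generator, mirroring the biological expectation that transcript and
  protein move together for genuinely regulated genes.
- Reference channels carry the pooled mean of all lines' clean signals
  plus small technical noise; batch factors multiply whole plexes,
  references included — exactly the structure the reference correction
  assumes and removes.
- Back-splice counts are Poisson with rate ∝ library size; planted
  junctions are drawn from the detectable-rate stratum (≥ 0.5 per
  million).
- All randomness flows through a single `numpy` generator seeded from the
  spec; identical specs give bit-identical screens.

What the generator does **not** emulate: correlated gene-gene expression
structure, compositional/length biases of FPKM, peptide-level rollup and
shared-peptide ambiguity in MS, overdispersion beyond Poisson in junction
counts, and cell-line-specific global scaling. Passing recovery tests
therefore demonstrate that the pipeline's logic is correct under its own
model assumptions, not that the thresholds are optimal for any real
dataset.

## Problem sizes and numerical conventions

The validation studies run at the screen's stated conditions: parameter
recovery as the median over 20 simulated screens, null calibration
(fraction of Welch p < 0.05 with nothing planted) as the mean over 50,
TMT batch-removal metrics as 20-seed medians, and the Welch-vs-permutation
comparison with 10,000 permutation draws on 9-vs-9 fixtures. Quantile
alignment exactness is asserted at 1e-6 (affine recovery) and 1e-9
(idempotence). Each study takes seconds; `scripts/acceptance.py`
recomputes all of them from one base seed.

## Known limitations

- The mean-of-p circRNA criterion has no frequentist error-rate
  guarantee; it is used because it demands cross-surface consistency, and
  the Fisher alternative is provided for users who want a calibrated
  combined p.
- With only 7 plexes, plex-level variance summaries are themselves noisy;
  the batch-removal metrics are therefore reported as multi-seed medians.
- Raw-p selection (no FDR control) reproduces the screen's published
  logic; the reported BH q-values show how much survives correction.
- Protein-layer recovery is intentionally weaker than RNA recovery
  (attenuation, missingness, FC ≥ 2 on noisier data); only the RNA funnel
  carries a recovery guarantee.
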