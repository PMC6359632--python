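# Methods

## The quantification model

Label-free spectral counting treats the number of MS/MS spectra assigned to
a protein in one LC-MS/MS run (the spectral count, SC) as a semi-quantitative
abundance proxy.  Longer proteins yield more tryptic peptides and therefore
more spectra at equal molar abundance, and total spectra per run is set by
instrument time, not biology.  The normalized spectral abundance factor
removes both effects:

    NSAF_i = (SC_i / L_i) / Σ_j (SC_j / L_j)

with `L_i` the protein length in residues and the sum running over every
protein in that run.  NSAF is computed run by run and then averaged over the
technical replicates of a group, so each injection contributes equally
regardless of its depth.  The alternative — summing counts over replicates
before normalizing — would weight deeper runs more; with balanced triplicate
designs the two differ little, but per-run-then-average is the variant
consistent with testing replicate NSAF values (below).

Because each run's NSAF vector sums to one, NSAF is *compositional*: a
protein's NSAF can change solely because other proteins changed.  The
consequences are discussed under limitations.

## The abundance-tiered classifier

For a reference group and a comparison group the model computes, per
protein: the mean SC in each group, the NSAF ratio (comparison/reference),
and a two-sided pooled-variance Student t-test on the per-run NSAF values.
The t-test is run on NSAF rather than raw counts because the effect-size
cutoff is an NSAF ratio; testing the same quantity that is thresholded keeps
the two criteria coherent.

Counting noise scales with abundance, so the significance cutoffs are
stratified by mean spectral count:

| tier      | mean SC         | p ≤    | overexpressed ratio ≥ | underexpressed ratio ≤ |
|-----------|-----------------|--------|-----------------------|------------------------|
| very low  | 0 < SC < 8      | 0.001  | 2.5                   | 0.4                    |
| low       | 8 ≤ SC < 20     | 0.01   | 2.5                   | 0.4                    |
| medium    | 20 ≤ SC < 80    | 0.05   | 2.0                   | 0.5                    |
| high      | SC ≥ 80         | 0.05   | 1.5                   | 2/3                    |

Scarce proteins must clear a stricter p-value (their ratios are noisy);
abundant proteins, whose counts are stable, are allowed a smaller fold
change.  Design choices worth recording:

* **Boundaries are half-open** with break points at 8, 20 and 80; a mean of
  exactly 80 is high.  Published tier ranges are often quoted from observed
  data (e.g. a "1.7–7" very-low range); we treat sub-range values such as a
  mean of 0.7 as very low rather than unclassifiable.
* **All threshold comparisons are inclusive** (≥ / ≤) at the boundary.
* **The underexpression cutoff is the exact reciprocal** of the
  overexpression cutoff — the high tier uses 2/3, not a rounded 0.67.  This
  makes calls symmetric under swapping the groups: every ratio r maps to
  1/r and every overexpressed call flips to underexpressed, exactly.
* **When the two groups fall in different tiers, the higher tier governs.**
  The max rule is symmetric in the groups, and it is the rule consistent
  with reference calls in the bundled tables (e.g. RALB: low in one group,
  medium in the other, ratio 2.25 reported overexpressed — admissible under
  the medium cutoff 2.0 but not the low cutoff 2.5).
* **Presence/absence is resolved before tiering.**  A protein with zero
  mean in exactly one group is "unique to" the other group, with no test;
  zero in both groups removes it from the comparison.  The ratio convention
  is 0 when absent from the comparison group and ∞ when absent from the
  reference.

The DEP fraction reported alongside the calls divides by the number of
distinct proteins detected in either compared group (the union), the
denominator under which a DEP percentage is comparable across experiments
of different depth.

## t-test degeneracies

The pooled-variance two-sample t-test is computed explicitly (p-value from
the t survival function) so that degenerate inputs resolve
deterministically rather than as NaN: when the pooled variance is zero, or
there are no residual degrees of freedom (single pseudo-replicates), equal
means give p = 1 and unequal means give p = 0.  These rules are exercised
whenever a published table of group means is re-analyzed as zero-variance
pseudo-replicates.  On non-degenerate input the implementation agrees with
an independent pooled-variance t-test to 1e-10 (tested on 1,000 random
small samples).

## Externally supplied NSAF ratios

A published DEP table prints the group-mean spectral counts of the
*differential* proteins only, while the NSAF denominators ranged over the
full detected proteome (a thousand proteins or more).  Ratios recomputed
from the tabulated rows alone are therefore systematically off (we observe
discrepancy factors of roughly 0.8–0.9 against reported ratios), and one
reported call (ACTN4, ratio 0.47 vs a ratio of ~0.52 recomputable from its
counts) sits on the wrong side of its cutoff under any truncated
denominator.  The model therefore accepts an externally supplied
accession→ratio mapping; the bundled reference tables carry their reported
ratios, and the full pipeline computes ratios itself when none are
supplied.

## Replicate QC and the interference verdict

Intra-assay variability is the coefficient of variation of the per-run
protein totals (proteins with SC > 0) across the technical replicates of a
group, in percent.  The sample (n−1) standard deviation is the default —
with triplicates the ddof choice is material, so it is exposed as a
parameter.  The interference verdict then compares the DEP fraction between
two conditions with the largest group CV: a DEP percentage that does not
exceed what repeated injections of the *same* sample produce is judged
within technical variability (the boundary is inclusive, a stability choice
that only matters at exact equality).

## Control-proteome annotation

Each DEP from the study comparison is looked up in a control proteome
(e.g. a pure cultured leukocyte sample): its control mean SC and tier, the
NSAF ratio control/reference, and a status from the same tiered classifier
with the governing tier taken as max(reference tier, control tier).  A
protein absent from the control cannot have been contributed by the control
cell type.  The `n_shared_all_three` statistic counts DEPs detected in the
reference group, the comparison group, and the control.

## Bundled reference tables

`nsafde.datasets` ships three transcribed tables from a published
sperm-proteome comparison (neat semen with high vs low round-cell content,
the same contrast after density-gradient processing, and a leukocyte
culture control), used as fixtures and worked examples.  Three cells of the
source tables are internally inconsistent and are encoded by what their
numbers support rather than the printed cell:

* FAM210A prints ratio 0.14 with an "overexpressed" label while the
  accompanying text lists it as underexpressed; 0.14 at the very-low cutoff
  0.4 is underexpressed, and the dataset encodes that.
* One tier label (SC 23.3 printed "low") contradicts the stated 20–79
  medium range, and one control tier label (SC 1.3 printed "medium")
  contradicts every range; both are marked as misprints in the datasets
  module and excluded from label-agreement tests.  Neither affects any
  expression call.
* ACTN4's control status prints "overexpressed" at ratio 1.73, but both
  relevant means are medium tier (cutoff 2.0), so the classifier reports
  not-significant there; tests document this single divergence.

## The synthetic-data generator

`simulate_counts` emulates the targeted study design: two pooled samples
measured as `n_replicates` technical LC-MS/MS injections each.  Protein
lengths are log-normal (median 400 aa, sdlog 0.5, clipped to 50–5000) and
relative abundances log-normal (sdlog 1.6, a ~3.5-decade dynamic range
matching the spread of spectral counts seen in deep shotgun runs).
Expected counts are proportional to abundance × length — precisely the
length bias NSAF removes — normalized so each run's expected total equals
`depth` (default 50,000 spectra), since instrument time fixes spectra per
run.  A planted fold change multiplies the abundance of a randomly chosen
DEP subset in the comparison group; folds below 1 plant underexpression.
Replicate noise is Poisson (technical replicates of one pooled extract
carry counting noise only); setting `dispersion` > 0 switches to a
gamma-Poisson (negative binomial) law with variance λ + dispersion·λ².
Counts below `detection_floor` (default 2) are zeroed, a deliberately crude
proxy for the two-peptide identification rule — it models detection
dropout, not peptide evidence.

What the generator does *not* emulate: biological replication and
between-donor variance (the emulated design pools donors before
measurement), peptide-level effects (shared peptides, parsimony grouping,
missed cleavages), run-to-run retention or ionization drift, and
search-engine scoring.  Passing recovery tests therefore demonstrate that
the pipeline's arithmetic and thresholds behave as specified under counting
noise — not that the thresholds have any particular error rate on real
biological comparisons.

`evaluate_recovery` scores calls against the planted truth: a DEP counts as
recovered only when called in the direction of its true fold (unique-to-
comparison counts as "up"); any other non-null call is false.  The false
discovery proportion divides false calls by max(1, total calls).

## Known limitations

* **NSAF compositionality under strong one-sided effects.**  If planted
  (or real) upregulation concentrates a fraction *s* of the abundance mass
  at fold *f*, every unchanged protein's NSAF ratio deflates toward
  1/(1+(f−1)s).  With 10% of proteins planted at fold 10 this is ≈0.53 —
  below the high-tier underexpression cutoff of 2/3 — and the shift is
  systematic, so abundant unchanged proteins are *confidently* miscalled as
  underexpressed.  The simulation-recovery test records this: sensitivity
  is high, but the false-discovery proportion under that harsh planting
  regime is far above what the same classifier achieves when differential
  mass is a percent or less of the proteome (the regime the bundled tables
  come from, where 26 DEPs stood among ~2,200 proteins).  Ratio-based
  spectral-count classifiers should not be trusted when a large share of
  total abundance is expected to move in one direction.
* **Presence/absence flicker at the detection floor.**  A protein whose
  expected count sits near the floor can vanish from all replicates of one
  group by chance and be reported unique to the other.  In null
  simulations at 50,000 depth this affects roughly 5% of 1,000 proteins,
  all at very low abundance; p-thresholded over/underexpression calls stay
  within the binomial error of their tier ceilings (0–1 per 1,000).
  Unique-to-one-group findings at very low counts deserve independent
  confirmation.
* **No multiple-testing correction** is applied, matching the tiered
  scheme as published; the tier-specific p ceilings are the only error
  control.
* With three technical replicates per group the t-test has four degrees of
  freedom; p-values are coarse and the very-low tier's p ≤ 0.001 is
  reachable only for near-zero within-group variance.

## Problem sizes in the test suite

The tests run the classifier end-to-end on the three bundled tables (26, 6
and 26 rows plus 100 background proteins each) and on simulations of 150–
1,000 proteins at depths of 2,000–50,000 with triplicate runs — sizes at
which every stage, including the 1,000-sample t-test cross-check, completes
in seconds on one CPU.
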