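# Methods

`clonevo` analyzes paired diagnosis/relapse tumor variant calls from deep
targeted sequencing and asks whether subclonal dynamics are consistent with
neutral evolution, how treatment reshapes the mutation burden, and whether a
recurrence shows the temozolomide (TMZ) hypermutator signature.  A
branching-process cohort generator with known ground truth makes every stage
testable without access to patient data.

## Variant retention

Calls are filtered per sample with the chain: caller p-value < 0.05
(strict), Phred quality >= 20, depth > 100 (strict), alternate reads >= 50,
VAF >= 0.08, and — only for variants with a *recorded* population minor
allele frequency — MAF <= 0.05.  A missing MAF means "not a known common
polymorphism" and is kept.  Boundary semantics follow the quoted wording of
each rule ("at least" inclusive, "greater than" exclusive) and each boundary
has a dedicated test.  Cohort-wide, a variant key seen in more than 50% of
distinct patients (either timepoint counts once) is removed everywhere as a
platform artifact.  Quality filters run before artifact exclusion; the
order is logged.  Removal reports attribute each dropped variant to the
first failing rule, in the order above, for reproducible accounting.

## Paired comparison

Variant identity is `(chrom, pos, ref, alt)`; annotations never enter
identity.  Each patient's calls partition into shared / unique-to-diagnosis
/ unique-to-relapse sets, from which burden tables (optionally restricted
to nonsynonymous + splice-site) and per-treatment-group means are derived.
High-burden outlier patients are flagged by an iterated two-sided Grubbs
test on relapse-unique counts (critical value from the usual t-quantile
form; one-sided available) rather than by a hard-coded patient id, and are
excluded from group means.  TP53-mutant status requires a nonsynonymous
TP53 variant *with* a damaging/deleterious prediction (a flag relaxes this
to the nonsynonymous-only rule).  Clinical summaries use midpoint medians
for even-sized groups — the convention needed to reproduce the nine-month
treated median time to recurrence from the shipped 21-patient table.

## Mutational spectrum and hypermutator calls

Single-base substitutions are collapsed to the pyrimidine strand (six
classes).  For C:G>T:A transitions the dinucleotide context is written
5'->3' with the mutated cytosine first (CpN), so "CpC and CpT" means the
base 3' of the mutated C; for a reference G>A call the 5' neighbor is
complemented.  The alternative 5'-neighbor convention is one flag away; the
two conventions are complement-conjugate and the tests assert the
bijection.

No numeric rule for "hypermutator" exists in the signature literature, so
the call is an explicit, conservative operationalization: among >= 10
relapse-unique SNVs, C>T fraction >= 0.60 AND CpC/CpT context fraction
>= 0.60 AND (by default) the patient's relapse-unique burden is a Grubbs
outlier within the cohort.  The thresholds sit well below the ~72%/73%
proportions of a genuine TMZ hypermutator and well above the ~17%/50%
expected from a uniform background, and are configurable.

## Purity and VAF adjustment

LUMP purity is `min(1, mean beta / 0.85)` over a leukocyte-unmethylated
probe panel, dropping probes whose detection p-value is not below 0.05.
The published panel identity is not available, so the package ships a
clearly-synthetic 44-probe placeholder used by the simulator and tests;
real analyses must supply their own panel, and externally computed purities
(ABSOLUTE-style) enter through the same interface tagged `external`.

MGMT promoter status is `methylated` iff the sentinel probe cg12981137 beta
exceeds 0.2 (strictly) and the mean over the available 12 promoter probes
also exceeds 0.2; a missing sentinel yields `indeterminate`.

Samples enter the evolution analysis only at purity >= 0.55 (normal
contamination <= 45%; boundary inclusive).  Observed VAFs are divided by
purity and capped at 1 — the copy-neutral diploid admixture correction.
The underlying study does not print its correction formula; this choice is
the simplest model consistent with its stated assumptions and is flagged
here because CNV-dense genomes violate it.

## The neutral-evolution test

Under neutral exponential growth the cumulative count of subclonal
mutations with allelic frequency at least f is M(f) = (mu/beta)(1/f -
1/f_max): linear in 1/f, zero intercept at f_max, slope the effective
mutation rate per effective division.  The test takes purity-adjusted SNV
frequencies in the open window (0.10, 0.25) — clonal events, ploidy
artifacts and germline leakage live above it, unreliable detection below —
sorts them descending, sets M_i = i and x_i = 1/f_i - 1/f_max (ties share x
but occupy consecutive ranks), and fits M = slope * x through the origin by
least squares.  R^2 is computed about the mean of M, so pathological fits
can go negative; that is intentional.  Classification is `neutral` iff
R^2 > 0.98 (strict).  For n < 10 the fit is re-run with each point deleted
and flagged when any single deletion flips the call.  A public-data mode
uses an inclusive lower bound and a 12-variant minimum, reflecting the
shallower sequencing of public cohorts.

Collective ("pooled") fits concatenate the windowed frequencies of many
samples before fitting.  This matters: the window of a *single* tumor is
populated by a handful of early lineages whose sizes are dominated by
genealogical drift, so per-sample R^2 is intrinsically noisy and the strict
threshold under-calls neutrality per sample — the pooled fit is the
reliable discriminator, and the per-sample fits are reported with that
caveat.

## The synthetic cohort generator

Growth is a discrete-generation Galton-Watson process: each cell makes two
daughters, each daughter survives with probability `1 - death_prob` (default
0.2) and acquires Poisson(`mu`, default 10) novel mutations; growth stops at
`n_final` (default 10^4) cells, with extinction retried.  Per-generation
growth is m = 2(1 - death_prob), and the expected windowed spectrum is
linear in 1/f with VAF-scale slope `mu * m / (2(m-1))`.  A nonzero death
probability is essential: with synchronous doubling and no death, lineage
sizes are exact powers of two and the subclonal window degenerates to a
single smeared atom.

Two scale corrections make a 10^4-cell simulation statistically resemble
targeted-panel data from a ~10^9-cell tumor:

* **Deep lineages.**  The tree contributes only ~8 correlated early
  lineages to the window, each carrying a packet of ~mu co-occurring
  mutations, whereas a full-scale near-critical tumor feeds the window with
  hundreds of independent small lineages.  The generator therefore adds
  mutations drawn iid from the neutral 1/f^2 law at VAF-scale rate
  `deep_rate` (default 20, added to the expected slope), instantiated once
  the population reaches 200 cells and carried as lineage counts: they grow
  at the neutral baseline (so selective sweeps deflate them) and are
  binomially resampled — treatment-sensitive — at bottlenecks.
* **Selection as extra offspring.**  An advantaged lineage gains
  Poisson(2(1-death_prob) * s) additional daughters, making its expected
  offspring exactly 2(1-death_prob)(1+s) for any s >= 0; capping daughter
  survival instead would saturate and make s = 0.5 and s = 1
  indistinguishable.

Sequencing draws per-site depth Poisson around the mean (default 1272) and
alternate reads Binomial(depth, purity * cell_fraction / 2); mutations with
fewer than 5 alternate reads fall below the caller's reporting floor.
Substitution classes are sampled from a configurable background spectrum
(default uniform over the six classes), contexts uniform over bases.

**Paired design.**  The diagnosis sample is drawn from the grown tumor.
Untreated patients then pass an unbiased bottleneck (surgical debulking,
survival 0.1) and regrow neutrally.  Treated patients pass a much deeper
bottleneck (0.01; chemoradiation log-kill) that is biased: two disjoint
pre-existing subclones — polyclonal resistance — survive with probability
`0.01^(1/(1+s))` (resistance divides the log-kill by 1+s) and are chosen so
their predicted post-bottleneck fractions land near 0.46 and 0.36 cell
fraction, i.e. in the upper subclonal window where a mutation cluster
breaks the zero-intercept fit hardest.  Regrowth is neutral: a continued
growth advantage would complete the sweep, and a completed sweep
paradoxically restores an apparently neutral window.  One designated
patient can additionally receive `tmz_injection_count` (default 200)
injected C>T mutations at subclonal fractions, 75% at CpC/CpT contexts —
reproducing the ~72%/73% signature proportions of a genuine TMZ
hypermutator over the generator's treated background.

Methylation tables are generated by inverting the LUMP formula around each
sample's configured purity (recovered within +/-0.02) plus MGMT probe betas
matching the patient's configured status.  Everything is reproducible from
a single seed.

**What the generator does not emulate:** copy-number change and loss of
heterozygosity (the diploid VAF correction would be wrong there), spatial
sampling, FFPE damage chemistry, germline contamination (population-MAF
annotations must be supplied), overlapping generations, and any explicit
radiotherapy dose model — "treatment" is the biased-bottleneck-plus-
injection abstraction.  Passing tests therefore certify the statistical
machinery, not robustness to those real-data complications.

## Problem sizes and numerics

The simulation suites use 20 replicate runs of 13-tumor cohorts for
neutral-parameter recovery (the collective-fit design), 10-pair cohorts for
the paired-shift study, and 10^4-cell tumors throughout; these sizes give
stable medians while keeping a full run of the test suite and the
acceptance script in the minutes range.  Exact-law recovery is asserted to
1e-9; slope recovery from simulation to 30% of mu/beta (median over runs);
classification fractions to the thresholds stated above.  Zero-variance
input to Grubbs, empty windows, n < 2 distinct x in the fit, and zero
informative LUMP probes all raise or return `insufficient` rather than
guessing.
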