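# clonevo

Mutation dynamics of paired primary/recurrent tumors: variant filtering,
shared/unique burden partitioning, TMZ mutational-spectrum analysis,
methylation-based purity (LUMP) and MGMT calls, and the neutral-evolution
1/f power-law test — plus a branching-process cohort simulator so the whole
pipeline is testable with known ground truth.

## Who this is for

Cancer-genomics analysts with matched diagnosis/relapse variant call tables
(deep targeted sequencing, no matched normal) who want to ask: did
treatment change the mutation burden?  Is there a temozolomide hypermutator
among the recurrences?  And centrally — do subclonal variant frequencies
follow the neutral-evolution prediction, and does that change after
therapy?

## The core statistic

Under neutral exponential growth, the cumulative number of subclonal
mutations with allelic frequency at least *f* is

    M(f) = (μ/β) · (1/f − 1/f_max)

— linear in 1/*f* with zero intercept at *f*_max and slope μ/β, the
effective mutation rate per effective cell division.  `clonevo` takes
purity-adjusted VAFs in the open window (0.10, 0.25), forms the ordered
pairs (1/f_(i) − 1/f_max, i), fits the line through the origin, and calls a
sample (or a pooled collection of samples) *neutral* iff R² > 0.98
(strict).  A drop in R² from diagnosis to relapse is the signature of
selection acting on the recurrence.

Around that core sit the supporting stages: a quality/frequency filter
chain (caller p < 0.05, Q ≥ 20, depth > 100, alt reads ≥ 50, VAF ≥ 8%,
population MAF ≤ 5%, cross-patient artifact removal), shared/unique
partitioning with Grubbs outlier screening, the six-class pyrimidine
substitution spectrum with CpN dinucleotide contexts for C>T (the TMZ
signature), LUMP purity with a ≥ 55% gate, and MGMT promoter methylation
calls.  See `docs/methods.md` for the full model description and design
choices.

## Worked example

Simulate a six-patient cohort (two untreated controls) and run the whole
pipeline:

```python
from clonevo import CohortSimConfig, PipelineConfig, run_pipeline

sim = CohortSimConfig(n_patients=6, fraction_untreated=0.33, seed=7)
summary = run_pipeline(PipelineConfig(sim=sim, seed=7, outdir="demo_out"))
print(open("demo_out/report.txt").read())
```

prints

```
clonevo cohort report
====================

patients: 6
treated: n=4, median time to recurrence = 12.5 months
untreated: n=2, median time to recurrence = 9.5 months
pooled_diagnosis: R^2=0.9924 slope=195 n=1097 -> neutral
pooled_relapse: R^2=0.96 slope=170 n=854 -> non_neutral
paired R^2 decreased at relapse: 4 of 6
hypermutator-positive: none
```

Reading it: pooled across samples, the diagnosis tumors' subclonal
spectrum is linear in 1/f (R² = 0.9924 > 0.98 → neutral), while at relapse
the fit degrades below the threshold (R² = 0.96 → non-neutral) — the
treated relapses carry partially swept resistant subclones that cluster in
the frequency window.  Four of the six patients individually shifted
downward; no recurrence met the TMZ-hypermutator rule (this cohort had no
injected hypermutator).  `demo_out/` also holds `summary.json` (full
precision), the filtered variant table, and an audit log of every threshold
applied.

The same stages are available as subcommands of the `clonevo` CLI
(`simulate`, `filter`, `purity`, `mgmt`, `compare`, `spectrum`,
`hypermutator`, `neutral`, `run`); `clonevo run --simulate --seed 7
--outdir demo_out` reproduces the bundle above.

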