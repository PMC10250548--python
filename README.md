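# nascentquant

Post-search analytics for metabolic-labeling quantitative proteomics.

When cells are fed a clickable amino-acid analog (for example an
alkyne-bearing threonine analog), the analog is incorporated into nascent
polypeptides, and newly synthesized proteins (NSPs) can be enriched by
click chemistry and quantified by LC-MS/MS label-free quantification.
`nascentquant` implements the computational stages that sit downstream of
the search engine in such a study:

* **Incorporation-rate estimation.** With both the analog and a heavy
  isotopologue of the same amino acid in the medium, each single-threonine
  tryptic peptide appears in matched modification states. For peptide *i*
  the intensity ratio r_i = I_analog,i / I_heavy,i estimates the odds of
  analog substitution at a threonine site, f_i = r_i / (1 + r_i) its
  probability, and the study-level rate is reported as "one in N"
  threonines replaced, N = 1 / mean_i(f_i).
* **NSP calling with background subtraction.** Proteins not significantly
  enriched over an untreated control (FC > 1.5, Benjamini–Hochberg
  adjusted p < 0.05) among those detected in the control are background
  binders and are removed; a protein is an NSP when detected in every
  treated replicate and either absent from all control replicates or
  significantly enriched at the same thresholds.
* **Imputation-stability differential enrichment.** Missing LFQ values are
  left-censored (below the detection limit), so they are imputed by the
  MinProb model — draws from a Gaussian centered at a low quantile of each
  sample's observed log2 intensities. Because a single imputation is
  random, imputation is repeated (default 1000×) and a protein is called
  differentially enriched only if it passes |log2FC| > log2 1.5 with
  adjusted p < 0.05 in more than 80% of iterations. The per-iteration test
  is an empirical-Bayes moderated t-test: per-protein variances s²_g with
  d_g degrees of freedom are shrunk toward a prior (d₀, s₀²) estimated by
  moment-matching on log s²_g, giving s̃² = (d₀s₀² + d_g s²_g) / (d₀ + d_g)
  and t = Δmean / (s̃ √(1/n_a + 1/n_b)) on d₀ + d_g degrees of freedom.
* **Forward/reverse IQR outlier test** for label-swap (dimethyl) ratio
  designs: significant proteins must exceed Q3 + 1.5·IQR in one run and
  fall below Q1 − 1.5·IQR in the other.
* **Pulse-labeling time-course analytics**: heavy-lysine label specificity,
  presence dynamics across time windows (steady-state proteins lost after
  stimulation and regained later), z-scored abundance profiles, and
  per-protein one-way ANOVA with Bonferroni-corrected consecutive pairwise
  comparisons.
* **Proteome composition utilities**: residue content of protein sets
  (e.g. threonine content of enriched NSPs vs the whole proteome) and
  monoisotopic mass deltas of residue substitutions from elemental
  arithmetic (the threonine-to-analog shift {C:+1, H:−2} = +9.984 Da).

Everything is exercisable offline through a bundled synthetic-data
generator that emits search-engine-style peptide and protein tables with
known ground truth, including intensity-dependent left-censored
missingness.

## Worked example

Estimate the analog incorporation rate on a simulated experiment with a
true substitution probability of 1/40.8 (three replicates, 20% CV):

```python
from nascentquant import (
    SimulationConfig, simulate_incorporation_dataset,
    select_matched_peptides, estimate_incorporation,
)
from nascentquant.io_tables import peptide_records_from_frame

cfg = SimulationConfig(n_proteins=150, incorporation_p=1 / 40.8,
                       replicate_cv=0.2, missing_curve=None, seed=7)
table, truth = simulate_incorporation_dataset(cfg)
records = peptide_records_from_frame(table)
matched = select_matched_peptides(records)
result = estimate_incorporation(matched, seed=7)
print(result.summary())
```

prints

```
Analog incorporation estimate
  matched peptides: 150
  substitution fraction f (fraction summary): 0.02408
  one in N threonines replaced: N = 41.5
  mean analog/heavy ratio: 0.02469 (one-in-N under the mean-ratio reading: 41.5)
```

i.e. the estimator recovers the planted rate (true N = 40.8) from noisy
matched peptide intensities; both summaries of the per-peptide ratios
agree in this small-ratio regime.

Calling NSPs on a simulated enrichment experiment:

```python
from nascentquant import (SimulationConfig, simulate_nsp_experiment,
                          identify_background, call_nsps, set_overlap)

cfg = SimulationConfig(n_proteins=100, nsp_fraction=0.2, replicate_cv=0.1, seed=7)
matrix, truth = simulate_nsp_experiment(cfg)
background = identify_background(matrix, "treated", "control", seed=7)
calls = call_nsps(matrix, "treated", "control", background, seed=7)
called = set(calls.index[calls["status"] == "NSP"])
print("background removed:", len(background))   # background removed: 80
print("NSPs called:", len(called))              # NSPs called: 19
print(set_overlap(called, set(truth.true_nsp_ids)))  # (95.0, 0.0, 5.0)
```

19 of the 20 planted NSPs are recovered with no false calls; the twentieth
fell below the detection curve in one treated replicate and is correctly
left uncalled under the all-replicates identification rule.

A command-line interface mirrors the library:

```sh
nascentquant simulate --kind nsp --seed 4 --out demo/
nascentquant call-nsp --matrix demo/proteinGroups.tsv \
    --treated treated --control control --out demo/calls.tsv
nascentquant dea-stability --matrix demo/proteinGroups.tsv \
    --groups treated,control --iters 1000 --seed 2 --out demo/stab.tsv
nascentquant mass-delta --name 'Thr->bES'    # +9.9843 Da
```

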