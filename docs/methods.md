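# Methods

This note documents the statistical models and procedures implemented in
`nascentquant`, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the design choices made where the
design was genuinely open.

## Data model

All quantitative analyses operate on a `QuantMatrix`: a protein (or
peptide) × sample matrix of log2 intensities with an explicit missing mask
and a design annotation (condition, replicate, optional time window)
parsed from sample names of the form `<condition>[@<window>]_<replicate>`.
Raw LFQ intensities are log2-transformed exactly once at read time; a raw
intensity of 0, an empty cell or `NaN` is a non-detection. Base 2 is the
proteomics convention, and all fold-change thresholds are interpreted on
the raw scale (FC > 1.5 ⇔ |log2FC| > log2 1.5 ≈ 0.585).

"Identified" / "detected" throughout means a non-missing LFQ value.
Search-engine identification FDR is upstream of this package and assumed
already applied.

## Left-censored missingness and MinProb imputation

Label-free LC-MS intensities go missing predominantly because peptides
fall below the detection limit, so missingness is not at random: it
concentrates at low abundance (left censoring). Missing cells are imputed
by the MinProb model: per sample, independent draws from a Gaussian
centered at the q-quantile (default q = 0.01) of that sample's observed
log2 intensities, with standard deviation `tune_sigma` (default 1.0) times
the median of the per-row observed standard deviations. These defaults are
the conventional ones for this imputation family. A sample with fewer than
three observed values has no usable censoring center and is rejected by
name. Observed cells are never modified, and imputation is deterministic
under a seed.

## Moderated t-test

Per-protein two-sample comparisons use empirical-Bayes variance
moderation. With per-row pooled variance s²_g on d_g = n_a + n_b − 2
degrees of freedom, a prior (d₀, s₀²) is estimated across rows by
moment-matching on log s²_g: under the hierarchical model the log
variances follow a scaled log-F distribution, so the excess spread of
log s²_g beyond trigamma(d_g/2) identifies d₀ through the inverse
trigamma, and the location identifies s₀². The posterior variance is
s̃² = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and t = Δmean/(s̃√(1/n_a + 1/n_b)) is
referred to a t distribution on d₀ + d_g degrees of freedom (normal when
d₀ is effectively infinite). Moment matching was chosen over exact
marginal maximum likelihood; at these scales the difference is negligible
and the moment estimator is closed-form and robust. Setting the prior df
to zero recovers the ordinary equal-variance t-test exactly, which the
test suite verifies against an independent implementation to 1e−10.

Multiple testing uses Benjamini–Hochberg step-up adjustment (delegated to
statsmodels; an exhaustive brute-force step-up oracle is kept in the test
suite as an independent check).

## Stability-filtered differential enrichment

Because each MinProb imputation is a random draw, a single-pass DEA on
imputed data is itself random. The stability procedure repeats the full
impute → moderated t → BH pipeline `n_iter` times (default 1000) on
independent substreams of one seed, restricted to proteins detected in all
replicates of at least one condition, and flags a protein as
differentially enriched only if it passes |log2FC| > log2(fc) with
adjusted p < alpha in more than a `stability` share (default 0.8) of
iterations. Fold changes are recomputed from the imputed data in every
iteration. Both median and mean per-iteration log2FC and adjusted p are
reported; the flag uses only the per-iteration criterion, since how the
per-iteration statistics should be pooled into a single summary is
otherwise an open choice.

A consequence worth knowing: a true effect whose control-side values sit
below the detection curve rides almost entirely on imputed cells. Its
per-iteration p-value then fluctuates around the threshold and the
stability fraction lands well under 0.8 — the procedure deliberately
withholds calls that depend on imputation luck. In simulations with 16-fold
spiked effects and ~25% marginal censoring this shows up as an occasional
spike (one whose baseline falls in the bottom few percent of the abundance
distribution) being left unflagged; every simulated run still recovers at
least 9 of 10 spikes and none produces spurious flags in the pure-null
setting.

## NSP calling and background subtraction

Click-chemistry enrichment co-purifies bead binders, so an untreated
control is measured alongside. Background = proteins with any observed
control value that fail significant enrichment of treated over control
(moderated t on imputed values, FC > 1.5, BH p.adj < 0.05, tested across
all control-detected proteins). Background proteins are removed before
calling. An NSP must be detected in every treated replicate and either be
missing in every control replicate ("absent-in-control" evidence) or pass
the same enrichment test ("enriched" evidence). "Absent in the untreated
condition" is read strictly as missing in all control replicates; the
detection rule is configurable. Background removal precedes the
all-replicates candidate filter; the opposite order is equally defensible
but changes nothing for proteins that satisfy both rules.

## Incorporation-rate estimation

Single-threonine peptides are grouped by modification state (analog,
heavy, unlabeled); rows sharing (sequence, group) are summed per replicate
across other modification combinations (e.g. with and without
acetylation); a group retains a peptide detected in ≥ 2 replicates; the
matched set is the intersection of the three groups. Remaining missing
cells of the matched set are MinProb-imputed on the log2 scale (the three
group matrices are stacked so each sample's censoring center is estimated
from all of that replicate's observed intensities), then replicate
intensities are averaged per group on the linear scale — matching the
convention of averaging raw peptide intensities — and per-peptide ratios
r_i = analog/heavy are formed.

The default summary is f = mean_i[r_i/(1+r_i)], the mean per-peptide
substitution fraction, with N = 1/f: it is bounded, robust to a few large
r_i, and equals the naive mean-ratio reading to first order when r is
small. The mean-ratio summary (f = r̄/(1+r̄)) is available as an option and
both are reported side by side, since which convention a given "one in N"
figure uses is generally not stated. Swapping the analog and heavy labels
maps f to 1 − f exactly.

Under left censoring the estimator is biased downward (about −13% relative
at the default conditions): censored low-intensity analog forms are
imputed near the detection floor, dragging the analog means down. The test
suite documents this direction rather than hiding it; rate estimation is
best performed on data dense enough that the matched set is nearly
complete.

The heavy-threonine (¹³C₄,¹⁵N) mass shift computes to +5.0105 Da from
exact isotope mass differences. Search configurations sometimes carry
+5.0145 Da for this substitution; the ~0.004 Da discrepancy is surfaced
here rather than reconciled, since the package derives all deltas from the
elemental composition.

## Time-course analytics

Label specificity is the percentage of peptides carrying at least one
heavy-lysine modification. Presence dynamics use the all-replicates
detection rule per window (configurable to any-replicate): `n_steady`
counts proteins detected at the first (steady-state) window, `n_lost`
those undetected at the first post-stimulation window, and `n_regained`
those lost proteins detected again at any later window. z-score profiles
standardize each complete protein's replicate-mean window values to zero
mean and unit sample s.d. (n − 1 denominator); constant rows are flagged
rather than given arbitrary values; replicate-level standardization is
available as an option. Per-protein significance uses one-way
fixed-effects ANOVA across windows on replicate values (F = 0, p = 1 for
exactly constant data), with consecutive-window two-sample t-tests
Bonferroni-corrected by the number of comparisons and capped at 1.

## Forward/reverse IQR outlier test

For label-swap ratio designs, thresholds Q1 − 1.5·IQR and Q3 + 1.5·IQR are
computed independently per run from that run's full log2-ratio
distribution (quartiles by linear interpolation). Ratios are stored in
label order, so a true change inverts its sign between the forward and
reverse runs; a protein is significant only when it exceeds the upper
threshold in one run and the lower threshold in the other (strict
inequalities). Proteins present in only one run are excluded and counted
in an `n_unpaired` tally.

## Synthetic-data generator

The generator emulates the statistical structure the analyses consume, at
the study conditions: three biological replicates, log-normal protein and
peptide abundances (log2 mean 25, s.d. 1.5 — typical LFQ dynamic range),
mean-one multiplicative replicate noise at 20% CV, a per-threonine analog
substitution probability of 1/40.8, a heavy-lysine labeling fraction of
0.97, and a logistic detection curve P(detect) = 1/(1 + e^{−slope(x −
midpoint)}) in latent log2 intensity x (default midpoint 20, slope 1).
The logistic curve is the standard LC-MS detection surrogate and is what
MinProb-style imputation presumes; `midpoint_for_missing_fraction` solves
the Gaussian-logistic integral for the midpoint that yields a stated
marginal missing fraction, so simulations can be pinned to conditions like
"25% censoring". A single seed is split into per-stage substreams
(sequences, abundances, noise, censoring), making each stage independently
reproducible; ground truth (true substitution probability, true NSP and
background sets, planted effects, censored-cell list, latent abundances)
is serialized alongside every dataset.

Deliberately not modeled: chromatographic or spectral realism, peptide
ionization efficiency, protein inference, match-between-runs, batch
effects, and normalization errors. Passing tests therefore demonstrate
correctness of the statistical pipeline under the assumed intensity and
censoring model, not robustness to acquisition artifacts in real data.

## Problem sizes and numerical choices

Simulation-backed tests use 100–1000 proteins or peptides, 3 replicates
and 100–200 imputation iterations — sizes at which the parameter-recovery
and calibration properties are already stable, keeping the full suite
around a minute. The inverse trigamma uses Newton iteration with the
conventional starting point y = 0.5 + 1/x and converges to 1e−10; prior
estimation falls back to an infinite-df (fully shrunk) prior when the
observed spread of log variances does not exceed the sampling noise, and
errors out only if every row has zero variance. Quantiles use linear
interpolation throughout. Ties at exactly the IQR thresholds are not
significant (strict inequalities); a moderated t with zero standard error
reports t = 0, p = 1 when the mean difference is also zero, ±∞ otherwise.

## Known limitations

* Matching of peptide forms is by (sequence, modification state) only — no
  isotope-envelope or elution-profile pairing.
* The incorporation estimator's censoring bias (above) is documented, not
  corrected; no censoring-aware likelihood is fitted.
* BH is the only FDR procedure offered; q-value estimation with π₀ is out
  of scope.
* The time-course heatmap clustering often shown with such data is not
  implemented; profiles are returned unclustered.
* Composition statistics exclude nonstandard residues (U, X, B, Z) from
  numerator and denominator, with a count of exclusions reported.
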