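# Methods

## Counting model

The unit of analysis is the merged capture target ("exon"): BED targets
on the same chromosome closer than 50 bp are merged, because fragment
midpoints cannot disambiguate them.  A fragment is a consistent read
pair — both mates on the same chromosome, convergent orientation,
spanning < 1000 bp, minimum mapping quality 20 (applied to both mates)
— counted once at the exon whose half-open interval contains the
midpoint `(leftmost_start + rightmost_end) // 2` (floor on even spans;
midpoints falling between targets are dropped and tallied).  Analysis is
restricted to autosomes by default (sex chromosomes would require
sex-stratified references); a flag keeps them.  Coordinates are 0-based
half-open internally; printed `chr:a-b` coordinates are treated as
1-based inclusive, so a printed span is `b − a + 1` bp.

## Robust test-vs-reference model

With test count `X_i` and aggregate reference count `Y_i`, the model
conditions on `N_i = X_i + Y_i`, which eliminates per-exon capture
efficiency without estimating it.  The null fit is a two-stage
procedure:

1. **Mean:** binomial logistic regression of `X_i` out of `N_i` on an
   intercept (plus GC percentage if requested), assuming diploid copy
   number everywhere, via iteratively reweighted least squares
   (statsmodels GLM).  GC enters as the raw percentage; the GC covariate
   is off by default since its effect on the dispersion is consistently
   small.
2. **Dispersion:** with fitted proportions held fixed, the beta-binomial
   intraclass correlation φ is estimated by bounded one-dimensional
   maximum likelihood, separately within depth strata (default: two
   strata split at the median `N_i`; strata under 50 exons are merged
   with a warning).  Keeping the stages separate keeps each fit
   one-dimensional and stable.  Each stratum's estimate is anchored at
   its median depth and `φ(N)` is the linear interpolation between
   anchors, clamped to the boundary anchor outside their range and
   floored at 0.

The beta-binomial uses shape parameters `a = p(1−φ)/φ`,
`b = (1−p)(1−φ)/φ`, so the mean is `Np` and the variance
`Np(1−p)(1+(N−1)φ)`; for φ < 1e−10 the binomial log-pmf is substituted
(the analytic limit).  Exons inside user-supplied common-CNV regions
(≥ 1 bp overlap) and exons with `N_i = 0` are excluded from *fitting*
only; fitted proportions are produced for every exon so calling runs on
the full set.

The dispersion summary `Rs = mean_i sqrt(1 + (N_i − 1) φ(N_i))` is the
arithmetic mean over fitted exons of the per-exon beta-binomial:binomial
standard-error ratio (the mean rather than a median or per-stratum
average is a deliberate, documented choice; it equals 1 exactly iff
φ ≡ 0).  Confidence bands for the observed proportion are central
equal-tail intervals of the (beta-)binomial pmf with coverage ≥ the
nominal level, built from quantile functions — deterministic, with a
guaranteed-coverage convention at the discrete boundaries.

## CNV calling

Copy ratios act multiplicatively on the odds of the null proportion:
`p' = r·μ / (r·μ + 1 − μ)` with r = 0.5, 1, 1.5 for copy numbers 1, 2, 3.
Three states suffice: more extreme events (homozygous deletions,
high-level amplifications) reject the diploid state even more strongly
and are recovered afterwards from the read ratio, as relative copy
number `round(2 · Σobs/Σexp)` floored at 0 — *relative* because a CNV
shared with the reference shifts the baseline; absolute copy number is
not identifiable here.

The chain over exons uses entry probability `q = ne / (2n)` per CNV type
(`ne` = expected CNV calls, default 20; `n` = exon count), so the
a-priori expected number of CNV-state entries is about `ne`.  Whether
the denominator should be `n` or `2n` is not sharply determined; both
`ne` and `n` are exposed as parameters (`expected_cnvs`,
`prior_n_exons`), and by default `n` is the analysed exon set's size —
when calling on a genome-wide exome, pass 229,056 or rely on the matrix
itself having that many rows.  CNV states revert to diploid with
probability 0.5 and persist with 0.5; there are no direct cn1↔cn3
transitions.  The chain restarts at each chromosome and ignores
inter-exon genomic distance.  Decoding is exact Viterbi in log space
with ties broken toward diploid.  Exons with zero depth emit a neutral
likelihood triplet (and are flagged on any call containing them) so a
single capture dropout cannot split a long call.

A call's posterior is the two-path odds of the decoded path against the
identical path with the call's exons reset to diploid, including
transition terms.  This reproduces per-call semantics in which a
multi-exon call accumulates evidence — two exons whose individual
posteriors each sit below 80% can jointly exceed 99.9% because the
entry cost is paid once.  Forward–backward marginals would be a
reasonable alternative definition; the two-path odds is used because it
is deterministic, cheap and directly testable against hand computation.
One caveat established during testing: the *number of called exons* is
monotone in `expected_cnvs` only in aggregate, not per instance — a
cheaper re-entry can break a bridged run and drop one weakly supported
middle exon.

## Reference selection

Candidates are ranked by Pearson correlation of FPKM vectors with the
test sample (FPKM, not raw counts, so sequencing depth differences do
not drive the ranking; undefined correlations rank last with a
warning).  Samples are added in rank order; after each addition the
robust model is refitted (same stratification as the final fit, for
comparability) and the objective — the mean over fitted exons of the
expected posterior of a single-exon heterozygous deletion, at the
calling prior `20/(2·229,056)` — is evaluated.  Iteration stops at the
first strict decrease below the running maximum and the argmax prefix
is returned, which is robust to flat stretches.  The expected posterior
is computed by exact enumeration of beta-binomial outcomes up to depth
5000, above which a ±8-standard-deviation window is enumerated and
renormalised (mass loss < 1e−10).  Because φ is refitted at every step,
the trajectory carries ~1e−3-scale estimation jitter; the variance-
reduction property (more depth never hurts at fixed parameters) is
exact, the refitted trajectory only approximately so.

## Power analysis

A power scenario fixes the dispersion regime via a target Rs value
(presets 1.0 / 1.6 / 2.5: no technical noise, well-matched batch,
poorly matched batch), the reference:test depth ratio R, the CNV type
and the prior.  φ is calibrated as `(Rs² − 1)/(N − 1)` at the
scenario's calibration depth `N = test_reads·(1 + R)` (default
calibration point: 100 test reads) and **held fixed along depth
sweeps**.  Holding φ fixed is what isolates the role of depth: the
proportion's standard deviation floors at `sqrt(p(1−p)φ)`, so the
expected posterior plateaus — at Rs = 2.5 and ratio 10 it never exceeds
~3% for a single-exon heterozygous deletion up to 500 test reads,
whereas the same sweep at Rs = 1 is essentially certain from ~300
reads.  A `recalibrate_phi` flag instead re-derives φ at each swept
depth (holding Rs rather than the noise floor constant); this answers a
different question and gives much higher apparent power.  Multi-exon
CNVs multiply independent exon likelihoods; the total log-Bayes-factor
distribution is obtained by discretising the single-exon distribution
on a 0.02-wide grid and convolving.  Homozygous-deletion power replaces
the copy ratio by a residual background mapping rate ε (default 0.01 —
a parameterisation choice, since the true background depends on
mapability; the detection threshold is reported as a function of it).

## Synthetic data generator

The generator mirrors the fitted model so every stage is testable
without sequencing data: exon lengths log-normal (median 250 bp, σ =
0.35), capture efficiencies log-normal (σ = 0.4) shared by all samples,
per-sample depth factors log-normal (σ = 0.1), exon totals Poisson, and
the test sample's share of each total beta-binomial with the configured
φ — GC bias and implanted copy ratios enter on the log-odds scale, and
the reference share is split multinomially among reference samples.
CNVs are implanted in the test sample only (the caller assumes a
CNV-free reference).  Preset φ values are calibrated by root-finding so
that the *expected* Rs over the theoretical depth distribution equals
the preset target (calibrating at the mean depth alone would bias Rs
upward under depth spread).  In presets with implanted events the event
exons are pinned at nominal capture efficiency, so the scenario's stated
depth (e.g. "300 test reads per exon") holds exactly at the event.

What the generator does *not* emulate: GC-dependent dispersion,
mapability structure, correlated noise between neighbouring exons,
batch-level sample clustering, and reference samples carrying CNVs.
Passing tests therefore demonstrate correctness of the inference
machinery under the stated noise model, not performance on any
particular real capture platform.

Scenario sizes (1,200–1,500 exons, 10–16 samples, 100-seed replication
for detection and 50 for specificity) were chosen so the full suite
exercises every stage end-to-end in well under a minute per criterion
while keeping Monte-Carlo error far from the asserted margins.

## Numerical notes and limitations

- φ maximisation is bounded in [0, 0.99] with an explicit boundary
  check at 0; its standard error comes from the observed curvature.
- The binomial GLM's standard errors understate parameter uncertainty
  under over-dispersion by roughly the Rs factor; recovery tests
  account for this.
- Posterior odds are computed via `expit` of log odds throughout; no
  probability is ever formed by subtracting near-equal exponentials.
- Calls are relative to the chosen reference; common CNVs present in
  the reference are attenuated or missed (use the common-CNV exclusion
  for fitting, and interpret `estimated_copies` as relative).
- Viterbi returns a single best path; marginal per-exon confidence is
  only summarised through the two-path call posterior.
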