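# Methods

## Quantification

A back-spliced site is a genomic interval `(chrom, start, end, strand)` in
0-based half-open coordinates: `start` is the acceptor (first base inside
the circle), `end` one past the donor. Detector dialects are harmonized on
input: CIRI2 reports 1-based inclusive pairs (`start − 1` maps to the
canonical form); CIRCexplorer2 and DCC output BED-convention coordinates
and are taken as already half-open. Loci identical up to strand are kept
distinct, since detectors report strand and collapsing would merge
antisense circles. Duplicate rows for one locus within a detector file
(isoform-resolved output) are summed with a warning.

The circular junction count CJC comes from the detector; the linear
junction count LJC is computed from spliced alignments. A read supports the
upstream linear junction when one of its splice gaps (CIGAR `N`) ends
exactly at `start`, and the downstream junction when a gap begins exactly
at `end`, with at least `min_overhang` aligned bases on each side of that
gap. Only primary, non-duplicate, non-supplementary alignments with mapping
quality ≥ `min_mapq` count; a read contributes at most once to each
boundary per locus; gaps internal to the circle (exon skipping) are
ignored, as is unspliced read-through, which is confounded by the circle's
own exons. Counting is strand-agnostic. LJC is the **sum** of the two
boundary junction counts — the division by two that makes the large-circle
psi equal `CJC/(LJC/2 + CJC)` lives in the effective length `Il = 4L`, which
spans two junctions of `2L` start positions each. A read spanning both
boundary junctions in one alignment contributes to both counts. STAR
`SJ.out.tab` files are accepted as an alternative source (unique-read
counts; junctions below the overhang threshold excluded).

Effective lengths use `L = read_len − min_overhang` with defaults
`read_len` from the user and `min_overhang = 6` bases, a conventional
junction-anchor minimum; `min_mapq` defaults to 10. The circRNA length `e`
is estimated from a GTF: among transcripts on the locus's chromosome (and
strand, when known) with exon edges exactly matching both back-splice
coordinates, the one with the most exons inside the circle wins, ties
broken by the largest clipped exonic sum; `e` is that transcript's exonic
length clipped to the circle. Exact edge matching is deliberate — fuzzy
(±2 bp) rescue would silently change `e`. Loci without a matching
transcript fall back to the genomic span and are flagged. With no
annotation at all, every locus takes the large-circle limit `e ≥ 2L`, under
which psi is the plain ratio used by detector-native quantification; a
locus→length override table (e.g. from full-length isoform reconstruction)
wins over every other source.

## Test

Per locus, with `n_k = CJC_k + LJC_k` junction reads in replicate *k* and
the length-corrected circular read fraction
`p(psi) = psi·Ic / (psi·Ic + (1 − psi)·Il)` (the exact inverse of the psi
formula):

    CJC_k | psi_k       ~ Binomial(n_k, p(psi_k))
    logit(psi_k)        ~ Normal(logit(mu_g), sigma_g^2)

Paired mode replaces the second line with a bivariate normal over the two
members of pair *k*, with per-group means and variances and a shared
correlation `rho` estimated jointly (pinned to (−0.99, 0.99)). Replicates
with `n_k = 0` carry no information and are skipped; a locus needs at least
one informative replicate per group. The unconstrained fit maximizes the
marginal likelihood over `(mu_1, mu_2, sigma_1, sigma_2[, rho])`; the
constrained fit enforces `|mu_1 − mu_2| ≤ delta`, and since the constrained
optimum lies on the boundary whenever the unconstrained fit violates it,
the constrained problem is solved with `mu_2` tied to `mu_1 ∓ delta` on the
natural scale. The statistic `LLR = 2(ll_unconstrained − ll_constrained)`
(floored at 0) is referred to chi-square with 1 df — one active constraint.
This boundary-constrained LRT is conservative; observed false-positive
rates on null simulations sit well below nominal, and no correction is
applied. `delta` defaults to 0.05 (a 5-percentage-point shift), reachable
down to 0.01 by flag; the same `delta` is used inside the constraint and in
the final DEC filter (`fdr < alpha` **and** `|delta psi| > delta`), where
`delta psi` is the difference of unweighted per-sample psi means, reported
alongside the model-based `mu` estimates. Multiple testing uses
Benjamini–Hochberg step-up FDR.

### Numerics

Replicate marginals are one- (or two-) dimensional integrals of a binomial
likelihood against a (bivariate) normal on the logit scale. They are
evaluated by fixed-order Gauss–Hermite quadrature, order 32, recentred at
the integrand's mode with the curvature there setting the node scale: the
mode solves a logistic-Gaussian problem by Newton iteration (the binomial
term is logit-linear with offset `a = log(Ic/Il)`, so gradient and Hessian
are closed-form), and in the paired case a 2×2 Newton solve plus the
inverse negative Hessian's Cholesky factor orient the tensor-product grid.
Recentring keeps the quadrature accurate (≲1e-8 against dense-grid
integration) even when deep counts make the likelihood much narrower than
the prior. Optimization is multi-start bounded L-BFGS-B (`sigma` starts 0.1
and 0.7) from moment-based initial values (pooled circular fraction per
group; pairwise logit correlation for `rho`), with analytic gradients
computed as posterior expectations of the prior score at the same nodes.
`sigma` is bounded to [1e-4, 5] to avoid degenerate likelihood spikes; `mu`
is kept in (1e-6, 1 − 1e-6). A locus whose optimization fails reports
p-value 1 with a convergence flag rather than aborting the run.

## Simulator

The generator emulates the evaluation design at the junction-count level —
it produces counts, not reads, so alignment artifacts, sequencing error,
GC/positional bias and detector behavior are outside what passing tests can
show; it exercises the statistical machinery under known truth.

Defaults are the study conditions: 10,000 loci, 3 vs 3 groups, group ratio
pairs drawn 9,500 from Beta(1, 12) and 500 from Beta(7, 10), intragroup SD
in {0.01, 0.02, 0.05, 0.10, 0.20}, DEC threshold 0.05. Exactly half of all
pairs must differ by more than the threshold; since the raw strata do not
naturally yield 50%, each stratum is rejection-resampled to a half-and-half
quota of DEC/non-DEC pairs. This convention is isolated in
`draw_ratio_pairs` so it can be swapped; it shifts the realized stratum
means from the analytic `p/(p+q)` by under 0.003. Per-locus depth is drawn
once from a log-normal (mean-log 3.0, sd-log 1.0, median ≈ 20 junction
reads) as a configurable stand-in for an empirical depth distribution that
would require external data; per-sample totals are Poisson around it.
Per-sample ratios are Normal(group ratio, SD) re-truncated (clipped) to
[0, 1] — at SD 0.2 clipping shifts the realized mean, which is accepted.
Circular/linear splits are Binomial at the length-corrected rate
(noise-then-round), with circRNA lengths log-uniform in [200, 2000] at read
length 100 so both effective-length branches occur. Half the loci carry two
circular isoforms whose reads split by a per-locus Uniform(0,1) fraction,
aggregated back to one CJC per site in the emitted tables (dataset 1); the
isoform-resolved variant (dataset 2) draws ratio pairs per isoform,
resamples until each gene has exactly one isoform-level DEC and the two
ratios sum below 1, and allocates reads multinomially with weights
`r_i · Ic` and `(1 − Σr) · Il`. All randomness flows from one seeded
generator; emitted files carry the seed and a config hash in a header
comment.

Depth stratification for evaluation uses the total CJC across all samples
at a locus (thresholds 5–40); ROC curves order loci by significance, AUROC
uses the trapezoid rule, and TPR at 5% FPR is linearly interpolated.

## Benchmark sizes

The packaged checks run the simulator at 1,200–2,000 loci per condition
(strata scaled pro rata), 800 per SD level in the acceptance script, 20
seeds of 40 loci for the paired comparison, and 200 loci for parameter
recovery. These sizes keep the whole suite at a few CPU-minutes while
leaving Monte-Carlo error well inside the asserted margins; the generator's
defaults remain the full-scale conditions.

## Known limitations

* The hierarchical framework is a reconstruction at the model-family level;
  exact numerical agreement with other implementations of the same family
  is not claimed.
* The boundary-constrained chi-square(1) reference is conservative,
  especially at 3 replicates per group, where a consistent group shift can
  be partially absorbed by the group-level variance; power grows with
  replicate number and depth.
* Intergenic circles without a linear counterpart have no LJC and hence no
  usable psi denominator.
* No UMI handling, no multi-mapper fractional assignment, no
  strand-specific counting, no lift-over between genome builds.
* Isoform-level differential calls (dataset 2) are out of scope for the
  test itself; the simulator emits isoform-resolved tables only so that
  aggregate-level behavior can be studied under isoform mixtures.
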