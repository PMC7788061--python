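# Methods

This note records the statistical models implemented in `pathassoc`, the
defaults and why they were chosen, what the synthetic cohorts emulate, and
the numerical decisions that pin down exact behaviour.

## Aggregate association test

For a set of `m` variants with minor-allele dosages `g_1..g_m`, case
indicator `y` and a null logistic model of `y` on the covariates
(intercept only by default, fitted values `mu`), define weighted scores
`S_j = w_j g_j' (y - mu)` and the family of statistics

```
Q_rho = (1 - rho) ||S||^2 + rho (1'S)^2,    rho in {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}
```

`rho = 0` is the variance-component (kernel) statistic, `rho = 1` the
squared weighted burden. Weights default to the Beta(1, 25) density on
the sample MAF — the standard choice that up-weights rare variants; a
flat scheme `weight_beta=(1, 1)` suits common-variant architectures and
is used by the planted-effect recovery experiments, whose effects sit
uniformly across the allele-frequency spectrum.

Under the null, `S ~ N(0, Sigma)` with `Sigma = W G' P0 G W`, where `P0`
is the covariate-projected variance matrix of the null model. Without
covariates `Sigma` is multiplied by `n/(n-1)`: this is the *exact*
covariance of `S` under random permutation of the observed residuals, so
the analytic and permutation versions of the test share second moments
exactly. Per-rho tail probabilities use a four-moment (Liu-type) match
of the chi-square mixture to a scaled non-central chi-square.

**Omnibus combination.** The reported p-value for the grid minimum
`T = min_rho p_rho` is computed from the joint law of the `Q_rho`, which
are all functions of the pair `(||S||^2, (1'S)^2)`. Conditional on the
burden component `eta = 1'S`, the residual `||S||^2` is a *non-central*
chi-square mixture whose non-centralities scale with `eta^2`; the
acceptance probability is a one-dimensional integral over
`eta^2 / Var(eta) ~ chi^2_1` of that conditional CDF. The integral is
evaluated piecewise-smoothly between the analytic kinks of the acceptance
boundary (with the substitution `x = z^2` to remove the chi-square-1
density singularity), and the conditional CDF by Imhof numerical
inversion on a period-matched quadrature grid with an
integration-by-parts tail correction (absolute accuracy ~1e-6;
cross-checked against Monte Carlo under the Gaussian law to ~3e-4).
Near-deterministic mixture components (tiny eigenvalue, possibly large
non-centrality) are folded into a linear shift; when `T < 1e-12` the
Bonferroni cap `K*T` over the grid is returned directly (the exact value
lies in `[T, K*T]`). The result is exact under the Gaussian null law up
to quadrature error — the classical approximation that treats the burden
and residual parts as independent was measured to err by up to 0.03 in
the bulk and is not used.

**Permutation mode** computes the tail probability of the same min-p
statistic under seed-controlled case/control label permutations. The
per-rho p-transformation is monotone in `Q_rho`, so permutations are
scored by threshold crossings without evaluating p-values; with an
intercept-only null the residuals are two-valued and a permutation
reduces to a multivariate hypergeometric draw over distinct
weighted-genotype rows, which makes 1e5 permutations cheap.

**Known limitation — small binary samples.** The randomization law of
`Q` at, say, 60 samples and 3 variants is discrete (atoms of 0.01–0.02),
and Beta(1, 25) weights can make one low-MAF variant dominate, leaving a
lattice-valued burden. No continuous approximation can match an exact
permutation p closer than about half an atom there. The analytic test
agrees with 1e5-permutation p-values to within Monte-Carlo error for
balanced designs with common variants from roughly 8000 samples down to
~0.005 absolute at 2000; the permutation mode is the recommended route
for small sets, and the agreement battery in the acceptance suite is run
in the asymptotic operating regime (n = 8000, 4–6 common variants, flat
weights).

## Single-variant test and FDR

Per variant, a logistic Wald test of status on dosage; when any expected
cell of the 2x2 allelic table is below 5 or the fit fails to converge, a
2x2 allelic test with Haldane–Anscombe 0.5 correction (applied only when
a cell is empty) is used instead. Monomorphic variants are skipped with
a recorded reason. Missing genotypes: complete-case per variant
(aggregate tests instead mean-impute, keeping score statistics defined).
FDR control is Benjamini–Hochberg step-up (the field default), written
directly because it is itself a tested primitive; statsmodels serves as
a cross-check in the tests. Convenience flags: suggestive significance
at p < 1e-4, gene-level Bonferroni at 0.05 / genes tested.

## Sequential elimination

Round by round: test all remaining pathways on genes not yet eliminated,
BH-adjust within the round, select the top pathway if its FDR < 0.05,
remove its member genes from every remaining pathway, repeat until
nothing is significant. The FDR family shrinks with the rounds by
construction. With two pathways sharing all causal genes, whichever is
selected first strips the other of its signal, so exactly one survives
(up to the ~5% chance that a leftover null gene clears the threshold in
a one-set family).

## Pathway PRS and positivity

Weights are the signed natural-log odds ratios of the minor allele for
LD-independent, nominally significant (p < 0.05) variants; protective
variants therefore contribute negative weights (a risk-allele-oriented
mode is available). LD pruning is greedy by ascending p with r^2 < 0.2
within 500 kb — standard clumping-style defaults, applied genome-wide.
The score of individual `i` for pathway `P` is
`sum over weighted SNVs v in P of weight(v) * dosage(i, v)` with missing
dosages replaced by the cohort mean. Positivity: strictly greater than
the linear-interpolation 97.5th percentile of control scores (at least
20 controls required). Weights estimated on the cohort being scored are
reproduced as an in-sample mode with a prominent log warning — selection
noise inflates the fitting sample's score spread, so in-sample
positivity rates run slightly below nominal; the calibration experiment
therefore estimates weights, thresholds and fresh-control rates on
disjoint samples, where the fresh-control exceedance is binomially
calibrated at 2.5% provided each pathway carries enough weighted
variants (~10+) for the score distribution to be effectively continuous.

## Stratification

Scores are standardised per pathway by the control mean and sample SD
(ddof = 1); zero-variance pathways are dropped with a warning. Patients
are clustered with Ward linkage on Euclidean distance and the tree cut
at exactly k = 4 clusters (both configurable; the count is a parameter,
not estimated). Labels are renumbered by descending cluster size for
reproducible reporting. Group comparisons default to non-parametric
tests (Mann–Whitney for two groups, Kruskal–Wallis for more, chi-square
with Fisher fallback for small 2x2 tables) because the damage index is
an ordinal count; the family-wise threshold is 0.05 / family size. The
planted-subgroup recovery experiment places four blob centres pairwise 3
control-SDs apart with within-blob SD of 0.5 control-SDs — a molecular
subgroup is modelled as more coherent than the case population at large;
with within-blob SD equal to the control SD the blobs overlap enough
that Ward's ARI plateaus near 0.8 regardless of sample size.

## Synthetic cohorts

The generator emulates a targeted-sequencing case–control design: genes
laid out round-robin over 22 chromosomes (1 Mb apart, variants 100 bp
apart), per-variant MAFs from a rare-skewed `0.5 * Beta(0.3, 1)`
spectrum by default (configurable, e.g. `Beta(2, 2)` for common-variant
experiments), optional LD blocks via a Gaussian-copula haplotype model
with an AR(1) latent correlation calibrated so adjacent indicator
correlation is about `sqrt(r2)`, and consequence labels assigned so the
expected number of rare non-synonymous sites per gene equals
`rare_nonsyn_rate` (default 3.0 — at the full 1832-gene design this
implies roughly 32 carried rare non-synonymous variants per individual,
the scale reported for comparable cohorts). Default cohort size is 958
cases / 1026 controls with a desk-scale gene complement (100 genes, 20
variants each, 10 pathways); `SimulationConfig.reference_scale()` gives
the full 1832-gene / ~287k-variant / 35-pathway design.

Two disease models: a liability threshold (standard-normal polygenic
noise plus the planted genetic score; the top liability ranks become
cases, matching a case-enriched ascertainment without fixing prevalence)
and a logistic model whose planted coefficients are ln-ORs preserved
under case-control ascertainment — pools are drawn from one fixed
variant blueprint until both quotas are met (bounded rounds). Planted
ln-ORs refer to the ALT allele, which carries the target MAF; a
bookkeeping column records where the cohort minor allele differs so
effects keep their sign. The true liability is stored per individual for
recovery tests. The damage index is Poisson with a log link on the
standardised genetic burden (non-negative integers matching organ-damage
score semantics) and autoantibody flags are Bernoulli with a logit link;
zero slopes give clinical variables independent of genotype. Case-only
variants are injected as rare missense carried by 1–5 case samples only
and absent from the simulated external panels.

What the simulator does **not** emulate: realistic human haplotype
structure (LD is block-local and exchangeable), population stratification
and relatedness, genotyping batch effects, sequencing error, and any
correlation between consequence class and effect size. Passing tests
therefore validate the statistical machinery under the stated generative
assumptions, not robustness to those artefacts.

## Numerical and reporting conventions

Minor alleles are defined on the combined sample; exact 0.5 frequency
ties go to the lexicographically smaller allele string. VCF positions
are 1-based inclusive, gene regions 0-based half-open. Variants outside
every gene region are kept but excluded from gene/pathway sets. MAF
strata follow the strict conventions common > 0.05 and rare < 0.01,
computed on the combined sample. All randomness flows from explicit
seeds; identical configuration and seed reproduce byte-identical
outputs, and the pipeline writes a manifest with SHA-256 hashes of every
output.

## Experiment sizes

The acceptance experiments run on one CPU in a few minutes: 500
twenty-variant null sets of 400 samples for calibration; 24
permutation-agreement fixtures (n = 8000, 1e5 permutations each); 10
positivity replicates (1000 association samples, 2000 threshold
controls, 400 fresh controls, 1000 variants in 5 pathways); 100
elimination replicates (2000 samples, 500 variants, 5 disjoint
pathways, ln-OR 0.3 on 20% of SNVs in two of them) plus 20
overlapping-twin replicates; 100 clustering replicates; 100
coverage replicates of a planted ln(1.5) effect at 4000 chromosomes.
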