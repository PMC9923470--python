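# Methods

This note records the models, defaults and design decisions behind
`invcline`, and what the synthetic-data tests do and do not establish.

## Synthetic transects (`simdata`)

The generator reproduces the statistical structure the downstream analyses
assume, not a population-genetic history. Its defaults are the study
conditions of the motivating system:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | (128, 167) | snails on the southern / northern 175 m transect |
| `cline_center`, `cline_width` | 85 m, 65 m | sigmoid cline of the D arrangement |
| `qmin`, `qmax` | 0.03, 0.97 | D frequency at the exposed / sheltered end |
| `lg_length` | 69 cM | one linkage group |
| `inv_start`, `inv_span` | 11, 47 cM | inversion interval on the map |
| `m_t`, `peak_t`, `sag_t` | 0.02, 0.55, 0.20 | W&C F_ST targets outside / at breakpoints / mid-inversion |
| `fraction_fixed` | 0.01 | inside SNPs with fixed arrangement differences |
| `n_snps`, `n_contigs` | 2000, 250 | background SNPs / mapped contigs |
| `n_ak_snps`, `ak_cm` | 70, 23 cM | allozyme-like contig (12 cM inside the left breakpoint) |
| `ak_allele_freqs` | (0.19, 0.81) | 80 : 100 allele ratio within the L pool |
| `size_means`, `size_sd` | (9.0, 7.5, 6.0), 0.8 mm | L/L, L/D, D/D sizes — ratio 1.5 large : dwarf |
| `mean_depth` | 5× | per-genotype Poisson depth; depth 0 ⇒ missing call |

Each snail draws a position uniformly on the transect, a karyotype from
Hardy–Weinberg proportions at the local cline frequency, and genotypes as
two haplotype draws from arrangement-specific allele pools. Key modeling
choices:

- **Divergence is calibrated on the Weir–Cockerham scale.** For two pools at
  p̄ ± d the large-sample two-deme W&C estimate is 2d²/(p̄q̄ + d²) (the
  observed-heterozygosity terms cancel), so a target θ requires
  d² = θ·p̄q̄/(2 − θ). The Nei G_ST rule d = √(θ·p̄q̄) is exposed as
  `pool_freqs_for_target_fst` for completeness; at θ = 0.32 the two differ
  substantially (G_ST-calibrated pools give θ̂ ≈ 0.49).
- **Per-SNP targets are overdispersed.** Inside the inversion, per-SNP
  targets are Beta-distributed around the bridge curve with concentration
  0.5 — a U-shaped (bimodal) distribution: most SNPs weakly differentiated
  plus a tail of near-fixed differences, which is what real inversion data
  look like, and the only way a 0.32 regional mean coexists with
  homokaryotype heterozygosity near 0.15. Draws are stratified (separately
  inside and outside the inversion) so the realized regional means stay
  pinned at the configured levels.
- **Mean allele frequencies follow a U-shaped spectrum** (Beta(0.12, 0.12)
  rescaled to [0.02, 0.98]), putting background observed heterozygosity near
  0.1–0.16 as in filtered WGS SNP sets; draws whose pools would leave [0, 1]
  are resampled.
- **The allozyme-like locus** is three haplotype classes (80, 100, 120) on
  one designated contig. Two diagnostic SNPs are fixed one-vs-rest for the
  120 and the 80 class, so the three alleles are exactly recoverable from
  two biallelic dosages; the remaining Ak SNPs cycle through the three
  one-vs-rest bipartitions at 0.977/0.023 within-class frequencies,
  calibrated so homozygote-class H_obs sits near 0.045 (the observed level
  for such clusters). The 120 allele rides only on D haplotypes; 80 and 100
  only on L.
- The bridge shape defaults (peak 0.55, sag 0.20) are chosen so the
  parabola's spatial average plus the fixed fraction gives the 0.32
  inside-inversion mean. The much higher landscape (peak ≈ 0.8, sag ≈ 0.55)
  reported for contig means in the motivating data reflects SNP-density and
  ascertainment effects a flat-density simulator cannot reproduce at the
  same time as the 0.32 regional mean; the recovery tests for `bridgefit`
  therefore simulate that profile directly at the contig level.
- The default seed (20180401) is stored in the truth file; every draw flows
  from one root generator, making the written VCF byte-identical across
  runs. At the default conditions, rare genotype classes are genuinely
  sparse — e.g. 80/80 homozygotes have expectation ≈ 3.7 and can be a
  singleton (the default seed yields exactly one), in which case no
  clustering method can resolve six allozyme clusters. Tests of the
  six-cluster structure use a replicate seed for this reason; the sparsity
  itself is faithful to the study scale.

What passing tests show: the estimators recover the parameters the
generator encodes under binomial sampling, missingness and the configured
divergence structure. What they do not show: robustness to linked selection
beyond the inversion, within-arrangement coalescent structure, gene flux
gradients, sequencing error beyond missingness, or reference bias — none of
which the generator emulates.

## Filters and pruning (`genio`)

Filters run in a fixed order (MAF → call rate → H_obs → mean depth), with
each removed site charged to the first rule it fails, so reported counts are
reproducible. MAF uses called genotypes only. Pruning is greedy keep-first
by physical distance with a half-open window [x, x + 1000 bp); VCF positions
are 1-based.

## Population structure (`popstruct`)

PCA is dosage PCA: per-site mean imputation of missing calls, mean
centering, no variance scaling; component signs are fixed by making the
largest-magnitude score positive.

Cluster-number selection uses k-means (20 seeded restarts) with an
information score on the total within-cluster sum of squares,
n·ln(WSS/n) + penalty (2k for AIC, k·ln n for BIC), and retains the
smallest k within 4 units of the minimum — the same
more-parameters-must-earn-their-keep rule as the cline competition. Two
practical findings drove this design, verified on simulation: (i) the
multivariate pooled-variance Gaussian AIC (penalty 2kd) essentially always
overfits near-discrete clusters, and (ii) even the 1-D AIC keeps paying to
peel off small clumps (e.g. individuals displaced by mean imputation), so
the allozyme-contig analysis uses the BIC penalty, which is also the default
of the clustering workflow this mirrors. Selection is reliable only when
many PCs are retained (the noise floor across dimensions is what makes
splitting unprofitable); the pipeline retains all n − 1 components.

Karyotype labeling: the heterokaryotype cluster has the highest mean
observed heterozygosity (an ordering margin below 0.03 raises an error
asking for manual labels); between homokaryotype clusters, L/L is the one
with larger mean size, with an override for shores where the association
runs the other way. Allozyme-genotype labeling uses triangle geometry
(mid-edge clusters match the nearest corner-pair midpoint), the constraint
that the D arrangement carries the 120 allele, and the rarer L allele being
80. The source material contains one internally inconsistent sentence on
this polarity; the genotype-by-karyotype table (120 count = D count) is the
authority followed here.

Weir–Cockerham θ̂ is the two-population variance-components estimator
a/(a + b + c) with sample-size and observed-heterozygosity corrections,
computed per site on called genotypes; undefined denominators give NaN and
regional means ignore them. LD r² is composite (squared Pearson correlation
of dosages over individuals called at both sites) since the data are
unphased.

## Cline fitting (`clinefit`)

Seven shapes: constant, linear, sigmoid, sigmoid with a left / right /
mirrored-both / independent tails. The "linear" competitor is constrained to
stay inside [0, 1] over the observed range — without that constraint a
clipped line is a 2-parameter ramp-shaped cline mimic and steals wins from
the sigmoid it is supposed to contrast with. Optimization is multi-start
L-BFGS-B on transformed scales (c raw, ln w, logit p, ln δ, logit τ); tail
models additionally start from the fitted sigmoid with tails pushed outside
the data, which reproduces its likelihood exactly and guarantees the
nesting property. Model choice: minimum AIC, but any simpler model within 4
units is retained.

Confidence intervals are Wald intervals from a central-difference Hessian on
the transformed scales. Profile likelihood would be preferable for
boundary-adjacent parameters but costs an optimization per grid point per
parameter; for the quantities consumed downstream (coverage of the center,
width order of magnitude) the transformed-scale Wald intervals are adequate
and are the documented trade-off.

Goodness of fit is the deviance pseudo-R² of a binomial regression of the
observed counts on the fitted logit frequency (1 − residual/null deviance).

F_IS bins are equal-width over [min, max] position, the last bin closed.
The bootstrap p-value uses the mid-p convention (ties at the observed
heterozygote count weighted half), without which the discreteness of the
statistic makes p-values conservative and non-uniform under the null. The
multi-allelic variant renormalizes the per-allele fitted clines to sum to
one before computing H_exp = 1 − Σ p̂_a².

The per-SNP scan measures end frequencies in the terminal 25 m windows,
skips SNPs with an end difference below 0.10, and flags a SNP clinal when
the sigmoid beats both the constant and the linear model by more than 4 AIC
units, separately per transect.

The selection estimate s\* = (1.732 σ / w)² assumes an abrupt habitat
change and no dominance. Note that at σ = 10 m and w = 65 m it gives 0.07;
the formula's value at σ = 20 m is 0.28, not the 0.11 sometimes quoted
alongside it — the discrepancy is documented rather than resolved, and only
the σ = 10 case is used.

Path projection is piecewise-linear with user-supplied waypoints (the
original 3-D-to-1-D transform is not specified to this package); ties
resolve to the lower arc length. Legacy sampling sites map to the path
position of the nearest current snail.

## Suspension bridge (`bridgefit`)

Likelihood: logit F_obs,j ~ Normal(logit F(p_j), s), constant s. Priors,
weakly informative and scale-matched to cM units: logit m ~ N(−4, 2),
a₀ ~ HalfNormal(1), a₁ ~ N(0, 0.1), a₂ ~ N(0, 0.01), b ~ U(0, L),
k ~ U(0, L − b), l, r ~ Exp(1), s ~ HalfNormal(2); parameter sets driving
F outside (0, 1) anywhere (checked at the junctions and the parabola
vertex) are rejected. The sign of a₂ is left unconstrained.

Sampling uses the affine-invariant ensemble sampler (32 walkers; defaults
8000 steps, 3000 burn-in), initialized from a moment-based guess with
seeded jitter. Convergence is summarized by classic split R̂ computed on
four walker-group mean chains; R̂ ≥ 1.05 on any parameter flags the fit
(it is still returned). Fixed seeds reproduce posterior summaries exactly.

Contig means are averaged on the natural F_ST scale, clamped to
[10⁻⁴, 1 − 10⁻⁴], then logit-transformed; averaging-before-logit is a
documented choice where the order is ambiguous. The bridge verdict requires
all three parabola parameters' central 95% intervals to exclude zero.
Outliers are one-sided: standardized residuals (posterior-mean curve and s)
above 3, i.e. elevated differentiation only, matching the question "is this
contig more differentiated than its position in the inversion predicts?".

## Sequence utilities (`seqtools`)

Substitution counting is observational and codon-level: a codon pair's
nucleotide differences count as nonsynonymous when the translated amino
acids differ, else synonymous; codons containing N are skipped. This is a
description of observed haplotype differences, not a Nei–Gojobori-style
evolutionary-path estimate, and the two differ for codons with multiple
hits.

The isoelectric point solves net charge(pH) = 0 by bisection to 10⁻⁴ with
Henderson–Hasselbalch charges under the EMBOSS pKa set (printed here for
bit-exactness): N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1. For Gly-Gly only the termini ionize and the pI is their pKa
midpoint, 6.1.

Neighbor joining uses the Saitou–Nei Q-criterion with ties broken toward
the lexicographically smallest label pair; negative branch lengths are
clamped to zero with the excess moved to the sister branch. Bootstrap
support resamples alignment columns, recomputes JC distances and topology,
and reports bipartition frequencies. Rooting by outgroup splits the
outgroup's pendant edge when the outgroup is adjacent to the root
trifurcation, and otherwise leaves the unrooted tree.

## Problem sizes used in the test suite

The suite runs the full pipeline at its default scale (295 snails, 2070
SNPs, both transects; the cline scan over both transects is the single
largest step at a few minutes) and the operating-characteristic checks at
50 replicates (cline model selection), 20 replicates (bridge null
verdicts, with 1500-step chains whose convergence flag is not asserted),
150 replicates × 2000 bootstrap draws (F_IS calibration), and exhaustive
enumeration of two-group genotype tables up to 4 diploids per group
(estimator oracle equivalence). These sizes are the package's chosen
demonstration scale; the same code paths accept larger inputs unchanged.

## Known limitations

- The generator has no within-arrangement haplotype structure (pool
  frequencies only), so LD decay within arrangements and recombination
  gradients cannot be studied with it.
- Cluster-number selection degrades gracefully but genuinely fails when a
  genotype class has ≤ 1 member; the labeling functions then require a
  manual k.
- Wald intervals can be poor for tail parameters at the edge of
  identifiability; they are reported on the transformed scales for this
  reason.
- The bridge model's b and b + k are differentiation maxima and need not
  coincide with physical breakpoints.
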