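# Methods

`qtlblup` quantifies what genomic prediction gains when the causal variants
(QTL) behind a quantitative trait are genotyped and modelled explicitly. It
has three parts: a forward-in-time simulator of a selected livestock
population in which the QTL and their effects are known exactly; mixed-model
machinery (GBLUP and two-component variants fitted by AI-REML); and an
evaluation layer that builds QTL-inclusion scenarios and scores every model
by accuracy and dispersion bias against true breeding values (TBV).

## Population simulation

**Genome.** Equal-length chromosomes (default 29 x 100 cM) carry SNP markers
and QTL at uniform-random positions (default 2,000 SNPs and 350 QTL per
chromosome). Meiosis follows the Haldane model: crossover counts per
chromosome are Poisson with mean equal to the map length in Morgans,
breakpoints uniform, no interference; each chromosome starts on a fair-coin
parental haplotype. The implementation converts crossovers to parental-origin
parity along the locus grid, which is vectorised over thousands of gametes
and distributionally identical to simulating each meiosis separately.

**Historic phase.** Founders start with Bernoulli(0.5) alleles. Population
size follows linearly interpolated anchors (default 2,800 -> 2,000 at
generation 2,250 -> 200 at generation 2,500 -> 10,000 at generation 2,505),
with random mating and discrete generations. Recurrent allele-flip mutation
is applied at SNP loci (default 2.5e-5 per allele per generation; 2.5e-4 in
the scaled-down profile, keeping 4Nu comparable). Mutation is needed on
first principles: conditional on still segregating, pure drift from an
interior starting frequency converges to a flat spectrum, never a U-shaped
one, whereas mutation-drift balance produces the U-shaped marker spectrum
(and the near-complete marker segregation) characteristic of ascertained
livestock SNP panels. QTL receive no mutation, so a realistic fraction
(~20%) of them drifts to fixation during the historic phase.

**Trait.** Allelic substitution effects for all QTL are drawn from a
gamma(shape 0.42) distribution with random sign — a heavy tail in which a
handful of QTL carry most of the variance — and rescaled by one common factor
so that Var(TBV) in the final historic cohort ("generation 0") equals the
target additive variance sigma_g^2 (default 1.0). The environmental variance
is set from the heritability, h^2 = 0.25 by default, so sigma_e^2 = 3
sigma_g^2. Phenotype = TBV + N(0, sigma_e^2). Variances are anchored on
generation 0; later generations lose variance to selection (Bulmer effect),
which is accepted, not corrected.

**Selection phase.** Twenty generations; each generation every dam produces
one offspring by a randomly assigned sire (default 20 sires, 5,000 dams).
Parents are chosen on a pseudo-EBV that emulates a pedigree evaluation of
stated accuracy r = 0.8:

    ebv = mean(tbv) + r (tbv - mean) + sqrt(1 - r^2) sd(tbv) eps .

The index is deliberately kept on the *trait scale*. An earlier formulation
standardised TBV within cohort, which silently placed every cohort's EBVs on
a mean-zero scale; since the dam herd retains its best half each generation
and therefore ranks mixed-age cohorts against each other, elite old dams were
never overtaken by the genetic trend and stayed in the herd near-indefinitely.
That artifact froze the relationship structure between late test generations
and the training window and suppressed the expected decay of prediction
accuracy across generations. With trait-scale EBVs the dam age distribution
is realistic (mean age ~2 generations) and accuracy declines from generation
16 to 20 as relationships decay. All sires are replaced each generation by
the top male offspring; the dam herd keeps its best half plus the best female
offspring.

**Datasets.** Training = random half of generations 11-15 with phenotypes
(default 2,500 x 5 = 12,500 animals); test = 500 random animals from
generation 16 (primary) and from each of generations 17-20 (persistence
analysis), scored on TBV only. Loci fixed in generation 0 are excluded from
all model features (they still contribute to TBV).

## Relationship matrices and the mixed models

The genomic relationship matrix follows VanRaden's first method,
G = WW' / (2 sum_j p_j (1-p_j)) with w_ij = x_ij - 2 p_j. Centering
frequencies are taken from all genotyped animals (training plus test) so a
single consistent G covers both roles; ranking/weight frequencies use the
generation-0 truth (below). The weighted variant G1 = WDW' / (2 sum p q)
takes D = diag(w / mean(w)); normalising to mean one keeps diag(G1) near 1 so
variance components stay comparable, and any positive rescaling of the
weights is absorbed by the component variance.

Models, all with a single overall mean:

- **GBLUP** — one genomic effect, G from SNPs plus included QTL, equal weight.
- **2GBLUP** — two genomic effects: G1 from included QTL (equal weights), G2
  from all SNPs; sigma_u1^2 + sigma_u2^2 estimates the total additive variance.
- **w2GBLUP** — as 2GBLUP with per-QTL weights 2 p q alpha^2 in G1.

Variance components are estimated by average-information REML with EM
safeguards: an AI step that decreases the restricted likelihood falls back to
an EM step (with step-halving toward the current point); variances proposed
below the floor (1e-8 x Var(y)) are pinned there and the AI system is
re-solved for the free parameters (active-set handling), which is what makes
boundary fits — e.g. a SNP component collapsing to zero once all QTL are
modelled — converge quickly. Starting values put 75% of Var(y) on the
residual; convergence requires relative parameter changes and the
log-likelihood change below 1e-6 (parameter changes are measured relative to
max(theta, 1e-3 Var(y)) so floored components cannot stall the test).
Cholesky failures add diagonal jitter of 1e-8 x mean diagonal (escalating,
reported in the summary); persistent failure raises. Standard errors come
from the inverse average-information matrix.

Breeding values for unphenotyped animals use the conditional expectation
u_k = sigma_k^2 G_k[:, train] V^{-1} (y - 1 mu_hat), mathematically identical
to augmenting the mixed-model equations but cheaper; the test suite verifies
the identity against directly solved MME and against ridge-regression
SNP-BLUP. Marker effects behind a fit are recovered by backsolving
a = W' G^{-1} u / scale with per-locus variances 2 p q a^2 normalised to
sum to one.

## Scenarios and evaluation

QTL are ranked by the variance they explain, 2 p q alpha^2, using
generation-0 frequencies (the simulation truth; the effects are likewise
simulation truth, mirroring a study in which causal variants are known).
QTL whose individual share is below 0.0005% of the total are dropped from the
ranking — an individual threshold, not a cumulative one, so only truly
negligible loci are excluded. Scenario QTLx takes
the smallest top prefix reaching x% of the (included) QTL variance; QTL0 is
SNPs only, where both two-component models reduce exactly to GBLUP and the
pipeline reuses the single-component fit. Loci fixed in the genotyped sample
are dropped from model features at fit time.

Accuracy = Pearson correlation of prediction with TBV in the test set;
dispersion bias = OLS slope of TBV on prediction (1 is ideal; > 1 means
underdispersed predictions). Overfitting is diagnosed by the training-set
correlation between prediction and phenotype, whose expectation cannot exceed
sqrt(h^2) = 0.5 for a predictor that captures only genetic signal. Random
forest and support-vector regression are fitted on raw 0/1/2 dosages without
standardisation (RF: 1,500 trees, 2,500 candidate features per split; SVR:
RBF kernel, C = 1, scikit-learn defaults elsewhere) and evaluated exactly
like the GBLUP family, their predictions standing in for GEBV.

## Scaled-down profile

The default (`full_scale`) preset reproduces the full study design and is a
multi-hour, ~10 GB job. The `mini_ci` preset is the package's own scaled-down
study used by the test suite and the acceptance script: 5 chromosomes x
(70 QTL + 400 SNPs), historic anchors 280 -> 200 at generation 250 -> 50 at
generation 280 -> 1,000 at generation 300, 10 sires x 500 dams, training =
120 x generations 11-15 (600 animals), test = 100 per generation 16-20, RF
with 300 trees and 100 candidate features (~4% of the features, the same
fraction as the full design). At this scale the qualitative structure of the
full study holds and is asserted by the tests: a U-shaped marker spectrum;
positive selection response at EBV accuracy 0.8 and none at 0; 2GBLUP beating
GBLUP once informative QTL are separated (and peaking near QTL80, with
accuracy dropping again when near-zero-effect QTL are added); weighting
rescuing that drop so w2GBLUP keeps improving through QTL100; GBLUP > SVR;
RF overfitting (training correlation ~0.99) and trailing GBLUP; accuracy of
every model decaying from generation 16 to 20. Absolute accuracies are lower
than at full scale (~0.4-0.66 versus ~0.5-0.83) because the training set is
20x smaller; orderings, not levels, are the reproducible quantity at desk
scale, and the replicate-averaged orderings are what the tests assert.

What the mini profile does *not* emulate about real data: a single pair of
scales (it is one point between toy and full, not a continuum), real
linkage-map heterogeneity (equal-length chromosomes, uniform marker spacing),
genotyping error and missingness (genotypes are complete and exact), and any
non-additive genetic variance (the trait is purely additive by design, which
is also why linear mixed models dominate the ML baselines here).

## Numerical choices and limitations

- Haplotypes are uint8 bit vectors; crossover parity is accumulated in uint8
  (wraparound preserves parity). Seeded runs are bit-reproducible; every
  stage draws from `numpy.random.SeedSequence` children of one master seed.
- Dense linear algebra throughout; the full-scale GRM over 13,000 genotyped
  animals (~1.4 GB in float64) is the memory high-water mark.
- GRMs are used without blending toward the identity; near-singularity is
  handled by the REML jitter described above.
- Ties in the QTL ranking are broken by locus index; scenario prefixes use
  the smallest k whose cumulative share reaches the threshold, since exact
  equality is a measure-zero event.
- Degenerate inputs are rejected loudly: odd founder counts, empty reference
  sets, all-fixed locus sets, negative weights, constant vectors in the
  metrics, insufficient selection candidates.
- The scaled-down RF is genuinely competitive with GBLUP in some seeds at
  very small numbers of segregating QTL; its reliably inferior accuracy
  depends on the trait being spread over many informative loci, which the
  mini genome (~270 segregating QTL) only just reaches.
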