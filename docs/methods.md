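# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package. It is written for a user deciding whether the
implementation matches their analysis, and for a maintainer wondering why a
particular convention was chosen.

## Study design being modelled

Open-pollinated (maternal half-sib) families from several genetic clusters,
planted in a common garden at two sites with randomized incomplete blocks
and single-tree plots. The maternal trees are genotyped (biallelic SNPs,
missingness allowed); offspring are phenotyped per cambial ring (ring
number = cambial age) for six wood and growth traits — stem diameter (DBH,
mm), ring width (RW, mm), wood density (WD, kg/m³), tracheid radial and
tangential width and wall thickness (TRW, TTW, TWT, μm) — plus the age at
breast height (ABH, years), an inverse proxy of early growth rate.

## Mixed models and REML

All three trial models are Gaussian variance-component models with
categorical random effects: block nested in site (encoded as composite
`site:block` labels), half-sib family, and — in the divergence model — the
genetic cluster. Fixed parts are small (intercept, site, ABH, cluster and
ABH interactions). Fits use REML.

Numerics: with V = I + Σᵢ γᵢ ZᵢZᵢ′ (γᵢ = σ²ᵢ/σ², the variance ratios), the
restricted likelihood is profiled over the fixed effects and σ², leaving a
criterion in γ alone:

    -2 l_R(γ) = log|K| + log|X′V⁻¹X| + (n−p) log y′Py + const,

where K = I_q + Λ Z′Z Λ (Λ = diag √γ) reduces every evaluation to dense
q×q operations via the Woodbury identity, q being the total number of
random-effect levels (a few hundred here, so evaluations are milliseconds
regardless of n). The analytic gradient is used. Optimisation is bounded
L-BFGS-B directly on γ ∈ [0, 10⁸] — on the ratio scale rather than its log,
so the zero boundary (singular fit) is an attainable point rather than an
asymptote — from three default starts (γ = 0.01, 0.1, 1), keeping the best
optimum; convergence tolerances are tight enough that balanced one-way
designs reproduce the closed-form ANOVA estimators σ̂²F = (MSB−MSW)/n,
σ̂² = MSW to better than 1e-6 relative. A fit with any γᵢ ≤ 1e-6 is flagged
`singular_`; non-convergence is flagged and warned, never silent. Fits on a
simulated trial agree with lme4 (variances, REML criterion, fixed-effect
standard errors) to the precision of lme4's own optimizer (~1e-5 relative).

Missing values are handled by listwise deletion per trait×ring fit. Fixed
factors use treatment contrasts (first level in sorted order as reference);
rank-deficient fixed designs drop aliased columns with a warning and reduce
the Wald degrees of freedom accordingly.

Type-II Wald χ² tests: each fixed term is tested after all other terms
except its higher-order relatives. Terms with no relatives are tested
marginally from the full-model covariance; a term with relatives (e.g. the
cluster main effect in the presence of ABH×cluster) is tested by refitting
the model without those relatives and Wald-testing the term there. For the
interaction-free models this is exactly the marginal Wald test; with
interactions it is the refit formulation of the type-II principle.
Predicted random effects (BLUPs) are computed as û = γ ⊙ Z′V⁻¹(y − Xβ̂) and
feed the family-effect PCA.

## Heritability and Q_ST

- h² = 4·σ²F/(σ²F + σ²B + σ²), the half-sib intraclass correlation. The
  block variance is included in the phenotypic denominator, following the
  source convention this package replicates; values above 1 are permitted
  and flagged rather than truncated.
- Q_ST = σ²A/(σ²A + 2·σ²F), with σ²A the cluster variance from the
  divergence model, averaged unweighted across rings 3–13. Note the
  convention: with ideal half-sib families σ²F = V_A/4, so Spitze's
  definition (twice the within-population *additive* variance in the
  denominator) would read σ²A/(σ²A + 8·σ²F). The 2σ²F form is the package
  default because it is the convention of the analysis being replicated;
  `family_var_scale=8` selects the Spitze form. The neutral-equivalence
  machinery (below) is built so that the default form is the calibrated one
  in its intended use.

## F_ST estimation

Per-SNP Weir–Cockerham θ̂ = a/(a+b+c) from the 1984 variance components
(sample-size weighted, using observed heterozygosity), vectorised over
loci. A locus is evaluable for a population pair when both populations have
at least two genotyped individuals; loci with a+b+c = 0 are undefined and
excluded. For more than two clusters the default distribution averages,
per SNP, the defined pair estimates ("pair-averaged"); a joint
multi-population θ per SNP is also provided. Negative per-SNP estimates are
preserved in the raw distribution; the "positive part" used as the neutral
reference discards (not truncates) them. Quantiles of the positive part use
type-7 linear interpolation.

Two genome-wide means are reported and kept distinct on purpose:

- `mean_fst` — the mean of per-SNP (pair-averaged) ratios. This is the
  descriptive summary most often printed alongside per-SNP distributions,
  but as a mean of ratios it carries a Jensen bias of order −5% relative at
  50 diploids per cluster (measured: 0.0905 at a true drift parameter of
  0.10; 0.0469 at 0.05).
- `ratio_of_sums` — Σa/Σ(a+b+c) pooled over loci and pairs (the "weighted"
  Weir–Cockerham summary, as printed by common VCF tools). This is the
  consistent estimator of the drift parameter and is the quantity used in
  the simulation-consistency tests.

## The divergence decision and its calibration

A trait is called divergent when its ring-averaged Q_ST exceeds the 95th
percentile of the positive part of the per-SNP F_ST distribution; the
empirical p-value is the fraction of positive per-SNP values ≥ Q_ST (no
continuity correction, since the null is a genome-wide SNP set rather than
a permutation sample; a variant including non-positive values is available
behind a flag).

Which per-SNP distribution should supply the 95th percentile matters. A
neutral polygenic trait's between-cluster variance carries r−1 degrees of
freedom of drift (r clusters), exactly like the multi-population θ of a
single locus — whereas averaging each SNP's θ over the r(r−1)/2 cluster
pairs shrinks the per-SNP noise and narrows the distribution. Measured on
explicit-locus neutral simulations (6 clusters, drift 0.10), the q95 rule
rejects ~5% of neutral traits against the multi-population per-SNP null and
~12–15% against the pair-averaged null. Both distributions are first-class
(`pairwise_fst_distribution`, `multi_fst_distribution`); the pair-averaged
one remains the default descriptive distribution, and the calibration tests
use the multi-population null. Users should be aware that the pair-averaged
q95 is anti-conservative as a neutrality threshold.

## Synthetic data

The generator's defaults emulate the modelled trial: 6 clusters ordered by
latitude, 66 families per cluster (396 total), 6 offspring per family per
site at 2 sites, 20/23 incomplete blocks, drift parameter 0.0488 (the
genome-wide average of the replicated study), genotype missingness 0.2, and
per-trait variance components on the mean-normalised scale taken from the
replicated stem-diameter fit (σ²F = 3.03e-2, σ²B+σ² = 2.15e-1 split 20/80
between block and residual — the split is not published and 20% block share
is our choice; σ²A = 2.37e-2, back-computed from the published Q_ST of
0.281). ABH has its own components on the years scale. The default SNP
count is 20,000 (a desk-scale panel; set `n_snps` higher for exome-scale
runs). Cluster mean offsets default to ±5% ordered by latitude rank;
ontogenetic trends are linear in ring number (the functional form is not
published), with the stem-diameter slope chosen so DBH roughly quadruples
over rings 3–13 and the other traits vary by ~50%.

Trait values are generated multiplicatively around the nominal trait mean,
value = mean·(1 + offset + trend + cluster + block + family + residual), so
the configured components are the components of the mean-normalised trait
regardless of measurement units, and mean-normalisation in the analysis
recovers them directly. Family effects are shared across a family's
offspring at both sites; block membership is randomised within site
(`balanced_blocks` gives a round-robin layout for oracle tests). Formation
years are derived as 1989 + round(ABH) + ring, so the calendar-year ring
filter is exercised. All randomness flows from one seed through
deterministically spawned substreams; identical config + seed gives
bit-identical output.

`exact_component_variance=True` standardises each realised effect vector to
its nominal variance. This exists for estimator-recovery tests: with only 6
cluster levels the realised cluster variance has ~63% sampling CV (χ²₅), so
no estimator can recover the nominal σ²A to 25% unconditionally; the option
conditions the check on the realised components, isolating estimator error.
It is off by default and not meant for scientific simulations.

The explicit-locus neutral mode builds a polygenic trait as a dosage-
weighted sum over randomly chosen causal loci, and offspring records
inherit the maternal genetic value wholesale (clone-like families) plus
residual noise. This makes the family variance estimate the full
within-cluster genetic variance, which is what the 2σ²F denominator of the
default Q_ST requires for the neutral expectation Q_ST = F_ST to hold. With
true half-sib sampling of offspring genotypes the same check would require
the 8σ²F denominator.

What the generator does *not* emulate: paternal structure of open-pollinated
seed (ideal half-sibs assumed), spatial autocorrelation within sites,
genetic correlations between traits, selection during simulation, linkage
between SNPs, and real growth physiology. Passing tests therefore
demonstrate correctness of the estimators under the assumed
variance-component structure, not robustness to these real-data features.

## Preparation filters and conventions

- Ring filters: drop the two innermost rings, keep rings ≤ 13, drop rings
  formed after the cutoff calendar year (default 2008).
- Family filter: keep families with ≥ 4 offspring at every site; when a
  stand column is present, drop stands with < 3 surviving families.
- Genotype QC: loci need ≥ 5 carriers of each genotype class (a leverage
  guard that doubles as a MAF filter); missingness thresholds are strict
  ("more than 70%" removes), samples filtered before loci. The
  sample-then-locus order is recorded in the report; note the two-pass
  filter is not exactly idempotent for adversarial missingness patterns,
  because the locus pass changes the surviving samples' recomputed
  missingness.
- Trait normalisation divides each trait by its grand mean over retained
  rows; ABH stays in years (it is reported on the raw scale in the source
  material and its components are on that scale).
- Genotype PCA: per-locus mean imputation of missing dosages, locus
  centring, no variance scaling by default (EIGENSTRAT-like; `scale=True`
  available).

## Problem sizes used in tests

The acceptance-level tests run at: 20,000 SNPs × 6 clusters × 50 mothers
for drift-recovery (3 targets × 3 seeds); 6×30×12 offspring designs for
REML recovery (10 seeds); 200 neutral trait replicates at 5,000 SNPs for
the q95 calibration; 500 null trials of a 6×25×6 design for Wald
calibration. These sizes were chosen so each property's Monte-Carlo error
is small against its tolerance while the whole suite stays desk-scale.

## Known limitations

- Wald χ² tests use estimated variance components as fixed (no
  Kenward–Roger or Satterthwaite correction); they are mildly liberal in
  very small designs.
- Q_ST has no confidence interval; a family-bootstrap would be the natural
  extension.
- The empirical p-value inherits the granularity of the positive SNP set.
- Only Gaussian responses, intercept random effects and maternal half-sib
  pedigrees are supported.
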