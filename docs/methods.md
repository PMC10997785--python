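# Methods

## Estimators and model

**GRM.** The allele-frequency-standardised IBS estimator (off-diagonal and
diagonal forms given in the README) is computed with sample allele
frequencies from the analysed individuals unless a frequency vector is
supplied. The counted allele is the PLINK/GCTA A1 allele. Standardising by
2p(1−p) up-weights rare alleles, which raises relatedness estimates for
pairs sharing alleles identical by descent relative to chance IBS sharing —
the property the kinship partition relies on.

Missing genotypes: a missing dosage contributes zero to each pair's sum
(equivalently it is replaced by its mean 2p_z) and the denominator N stays
at the panel size; this is deterministic and keeps the matrix a simple
average. The GCTA-style alternative — dividing each pair by its own count
of jointly non-missing SNPs — is available as `per_pair_n=True`. The two
coincide on complete panels, which imputed hard-call data nearly are.

**Thresholded (kinship) GRM.** Off-diagonal entries less than or equal to t
are set to zero; entries above t and the whole diagonal are copied
unchanged. The boundary is inclusive into the zero set for relatedness
(≤ t → 0) and strict for the MAF subsets (MAF < threshold kept), matching
the respective verbal rules. Self-relatedness must survive thresholding or
the matrix could not serve as a covariance structure. Note the thresholded
matrix is generally indefinite; the REML code never assumes positive
definiteness of individual structures, only of the total covariance V.

**Region and chromosome scopes.** Coordinates are 1-based inclusive
(.bim convention); the causal-gene scope takes SNPs within the gene span
± 1 Mb. Any scope resolving to fewer than 10 SNPs is refused and recorded
as a skipped row, never an aborted run.

**Pedigree A.** Henderson's recursion after an internal topological sort;
unknown parents contribute zero and individuals absent from the pedigree
can be appended as unrelated founders (`extend_pedigree`) so A can cover
every genotyped individual. Fhat3 inbreeding is the standardised GRM
diagonal minus one.

## REML

The restricted log-likelihood is evaluated as
−½[log|V| + log|XᵀV⁻¹X| − log|XᵀX| + yᵀPy + (n−p)·log 2π] with
V = Σ_k σ²_k G_k + σ²_e I, genetic structures mapped to records through the
incidence W (W M Wᵀ) and grouping factors through Z Zᵀ. Including the
|XᵀX| term makes the value the exact log-density of an orthonormal
error-contrast basis, hence invariant to the fixed-effect parameterisation
— verified in tests against an explicit contrast-basis oracle.

Optimisation: 3 EM-REML steps (stable from rough starts) then
average-information updates with step-halving (25 halvings maximum per
iteration). Convergence requires |Δ log L| < 1e−8 and maximum relative
parameter change < 1e−6 within 200 iterations; non-convergence returns a
flagged fit, never an exception. Under the default non-negativity
constraint, components are floored at 1e−8 × phenotypic variance; floored
components whose score points outward are frozen out of the AI solve
(active set), so the free components reach the reduced problem's optimum —
this is what guarantees nested fits never lose likelihood. Because
thresholded and MAF GRMs are indefinite, V can be non-positive-definite
even at positive variances; the initial point is shrunk toward a
residual-dominated start until V is PD, and step-halving handles the same
situation during iteration. An unconstrained mode (`constrain=False`) is
available; it is what a boundary-unbiased null assessment needs.

Standard errors come from the inverse average-information matrix at the
optimum (rows of floored components reported as NaN); heritabilities are
ratios of component sums to the total with delta-method SEs over the full
component covariance. h²_pk is definitionally h²_pop + h²_kin — the joint
ratio of both components to the same total.

**Likelihood-ratio tests.** Λ = max(0, 2Δ log L) against the reduced model.
The default null is central χ² with 1 df, reproducing the common reporting
convention; `null_mode="mixture_50_50"` gives the boundary-correct equal
mixture of a point mass at zero and χ²₁, which calibrates to the nominal
level (empirically ~5–7% at α = 0.05 in the null simulations). The
chi-square default is conservative.

**Categorical monogenic traits** are coded 0/1 (two classes) or 0/1/2
(three classes, sorted class order) and fitted with the same linear
machinery on the observed scale; no threshold model is attempted.

## Synthetic data

The generator emulates a long-term study of a promiscuous wild ungulate:
discrete generations with 25% chance per parent of drawing from two
generations back (overlap), litters of 1 + Poisson(0.08), dams and sires
drawn uniformly per litter. Defaults (100 founders, 120 offspring per
generation, 5 generations) give half-sib:full-sib pair ratios around 20:1
and mean pedigree relatedness ~0.017 — the qualitative structure of a wild
pedigree (abundant half-sibs, sparse kinship), at desk scale. SNPs are
unlinked, gene-dropped from Hardy–Weinberg founders with counted-allele
frequencies Uniform(0.05, 0.5); no linkage disequilibrium is simulated, so
tagging-related phenomena are outside what these simulations can show.

Quantitative traits sum independent parts, each scaled to a target fraction
of unit total variance: additive breeding values from 200 random causal
panel SNPs; a family-associated effect; maternal, cohort (birth-year) and
permanent-environment deviates; fixed sex and age effects; fresh residuals
per record (adults can carry repeated records sharing all individual-level
parts).

The family-associated effect has three modes, because "family variance"
is not one thing:

* `genetic` (default): drawn MVN with covariance c·(M_t + λI), where M_t is
  the realised thresholded GRM, λ is the smallest spectrum lift making the
  indefinite M_t positive semidefinite, and the white c·λ part is charged
  to the residual budget. The coefficient on M_t — exactly what the two-GRM
  model's σ²_kt estimates — is then precisely the configured fraction, so
  this mode is the right one for estimator-recovery experiments. (Sampling
  from the clipped-PSD part of M_t instead would make the generative
  covariance differ from M_t and biases the kinship estimate downward by
  roughly 10–15% — measured, and the reason for this construction.)
* `common_env`: one shared deviate per maternal family. Its covariance is a
  family-block matrix, not the thresholded GRM, so the kinship component
  recovers it only partially (roughly half in our simulations) and LRT
  power is modest. This mirrors the method's real-data interpretation:
  h²_kin indicates family-associated variance, it does not measure the
  shared-environment variance itself.
* `dominance`: per-causal-SNP heterozygote deviations. These load only
  weakly on the thresholded GRM (rejection near the nominal rate in our
  simulations), consistent with the empirical finding that the partition
  detects little for architectures dominated by single-locus dominance.

Monogenic traits map the causal genotype through dominant or codominant
patterns, optionally per sex (e.g. dominant in males, codominant in
females), with an optional misclassification rate.

## Problem sizes used by the test and acceptance runs

Estimator oracles run on tiny fixtures (≤ 20 × 50 GRMs, ≤ 200-member
pedigrees, n ≤ 50 REML). The end-to-end recovery experiment uses 25
replicates of n = 1000 individuals × 3000 SNPs (truth h²_pop = 0.30,
family fraction 0.15, `genetic` mode, t = 0.1). Null calibration splits
into a rejection-rate leg (150 replicates at n = 400, where constrained
fits are cheap and the empirical rate has useful resolution) and a
mean-bias leg (40 replicates at n = 800 with unconstrained fits: at small
n the positive-definiteness boundary of V clips the lower tail of the
unconstrained kinship estimate and would inflate its mean by ~0.02; at
n = 800 the clip lies far outside the sampling distribution). The
common-environment power experiment uses 25 replicates at n = 1000.

## Known limitations

* Dense linear algebra throughout: fits are comfortable to a few thousand
  records, not tens of thousands.
* Univariate models only; no genetic correlations, no binary-liability
  (threshold) models, no dominance GRMs.
* The simulator has no linkage disequilibrium, selection or demographic
  mortality structure; passing tests show estimator correctness under the
  stated generative models, not robustness to every feature of real data.
* QC's duplicate-IBS rule removes the later-listed member of a pair — a
  deterministic convention, not an optimality claim.
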