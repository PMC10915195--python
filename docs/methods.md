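# Methods

This note records the statistical model, the numerical choices, what the
synthetic-data generator does and does not emulate, and the design decisions
taken where the design was genuinely open.

## Model and estimation

The core is a 3-trait repeatability animal model for repeated records
(semen volume VOL, sperm number NS, motility MOT):

    y = Xb + Za a + Zp p + e,
    Var(a) = Va ⊗ H,  Var(p) = Vp ⊗ I,  Var(e) block-diagonal per record.

Fixed effects are contemporary group (year-month, dummy-coded with a
dropped reference level), ejaculate order, bull age (months), ambient
temperature (°C) and the heterosis covariate
f_H(sire)(1−f_H(dam)) + (1−f_H(sire))f_H(dam).  Age and temperature enter
as linear covariates because their continuous units are given; covariate
columns with zero variance are dropped, and any residual rank deficiency is
fatal with the aliased columns named.  A record may miss individual traits;
its residual covariance is the corresponding submatrix of Ve, and records
are grouped by missingness pattern for assembly.

**Relationship matrices.**  A is built by the tabular method
(a_ii = 1 + F_i).  G22 uses allele-2 dosages centered by 2p_j with p_j
observed in the genotyped animals (the base-population frequency is not
otherwise identifiable from the inputs), divisor 2Σp_j(1−p_j).  G is first
rescaled so its diagonal and off-diagonal means equal those of A22 (the
two-parameter linear system a·G + b·J), then blended
G* = αG_scaled + βA22 with α = 0.95, β = 0.05; scaling precedes blending.
H⁻¹ adds τG*⁻¹ − ωA22⁻¹ (τ = ω = 1) on the genotyped block of A⁻¹; the
dense four-block H is also built and the two are verified to be mutual
inverses in tests.  The γ/δ weights are accepted in `BlendParams` but
inert (reserved).  All linear algebra is dense; the package targets
populations of at most a few thousand animals.

**REML.**  Estimation maximises the restricted likelihood through
Henderson's mixed-model equations.  The engine takes exact multivariate
EM steps —

    Va ← (â'H⁻¹â + tr(H⁻¹ C^aa)) / q,
    Vp ← (p̂'p̂ + tr(C^pp)) / m,
    Ve ← (1/n) Σ_i [ ẽ_i ẽ_i' + S_i (W_i C⁻¹ W_i') S_i' + Schur_i ],

where missing-trait records are completed by their conditional expectation
(S_i = Ve[:,o] Ve[o,o]⁻¹, Schur_i the conditional covariance) — accelerated
by average-information (AI) steps whose scores reuse the EM trace
quantities and whose AI matrix is ½ f_k' P f_l with the projections done by
MME solves.  Guards, in order: two EM warm-up iterations before any AI
step; a trust region capping one AI move at 10× the current parameter
scale; step-halving of the AI direction; and a likelihood guard on *every*
step (AI and EM alike) that damps toward the previous iterate and stops
with a warning if no likelihood-increasing step exists.  The EM guard
exists because near the positive-semidefinite boundary the coefficient
matrix becomes ill-conditioned enough (condition number ~10⁹ observed)
that a numerically computed EM step can lower the likelihood even though
the exact step cannot.  The recorded likelihood path is therefore
non-decreasing by construction; the exactness of the undamped EM step is
separately verified on well-conditioned problems.  Component matrices are
projected to the PD cone by eigenvalue clipping at 10⁻⁶ of the largest
eigenvalue; convergence is a maximum absolute relative parameter change
below 10⁻⁸ (default).  The reported restricted log-likelihood omits the
−n/2·log 2π constant.  Starting values are Va = Vp = Ve = diag(sample
variance)/3.

On small datasets (≲60 bulls) the 18-parameter optimum frequently sits on
the PSD boundary (a genetic or permanent-environment correlation pinned at
±1); estimates there carry a non-convergence warning and should be read as
boundary solutions, not interior maxima.

**Back-solving and window variances.**  Marker effects are
u = Z'G*⁻¹â/(2Σp(1−p)) per trait.  The per-SNP variance is the empirical
(n−1) variance of z_·j u_j across genotyped animals; the parametric
2p_j(1−p_j)u_j² form is available behind a flag.  This definition is the
single most consequential under-determined choice in the pipeline (the
upstream literature states only "the sum of the variances of the SNPs in
the window") and is therefore made explicit here.  The percentage
denominator is the REML estimate of the trait's total additive variance,
not the sum of per-SNP variances.  Window variance is the plain sum over
member markers; overlapping windows shift by one marker, non-overlapping by
the window size, with the final partial non-overlapping window kept and a
chromosome shorter than the window contributing no overlapping window.
Selection is inclusive (pct ≥ threshold).

**Gene mapping.**  A SNP inside one or more genes takes the smallest-span
containing gene; otherwise the nearest gene on the same chromosome by
distance to the closer gene boundary (not the TSS — the distance bins are
symmetric around genes), ties broken by gene id.  Bins have inclusive upper
edges (exactly 2,500 bp falls in the 1–2,500 bin).  A chromosome without
annotated genes yields gene "NA" in the farthest bin.  A band-reporting
mode (all genes within a distance) exists behind the `all_within` flag.

**Enrichment.**  Two-sided hypergeometric p by tail doubling capped at 1
(minimum-likelihood-sum available behind a flag), computed with scipy's
stable distribution functions; Holm step-down across the pathways with at
least one background member (pathways with none are skipped and do not
count toward the correction multiplicity); significance is p_adj strictly
below α = 0.05.  The background universe defaults to annotation genes that
appear in the pathway database — a results-sensitive choice that callers
can override.  Correction is applied per scheme (and per pooled-trait gene
set); gene sets are pooled across the three traits before testing, matching
the pooled framing of the scheme comparison.

**Scheme comparison.**  NP[i][j] counts significant pathways shared by
schemes i and j; NG[i][j] counts genes identified by *both* schemes that
belong to those shared pathways (intersection; union available and always
labelled).  Diagonals are each scheme's own counts.

## Synthetic data

The generator emulates a small multibreed stud: founder sires and dams with
Holstein fractions drawn in [0.625, 1.0] (offspring fraction = parental
mean, so descendants stay in range, matching the bulls' observed range);
Mendelian gene drop with founder allele-2 frequencies uniform in
(maf_low, maf_high) and independent segregation per marker; repeated
3-trait records built from pedigree-MVN breeding values (covariance A⊗Va,
drawn as L_A N L_Va') plus explicit marker-QTL contributions added on
centered genotype scores, i.i.d. MVN permanent-environment effects,
i.i.d. MVN residuals, and the five fixed effects (contemporary groups
cycle over year-month labels staggered by bull so they are not aliased
with ejaculate order or age; ejaculate order is randomised).  Defaults are
the reference study's conditions: 131 bulls (offspring of 62 sires and 112
dams; 305-animal pedigree), 100 records per bull, 72 genotyped animals (61
bulls + 11 dams), 2,000 markers on 5 chromosomes.  Where magnitudes are
not externally fixed, traits are simulated on a standardized scale with
phenotypic variance ≈ 1, heritability 0.3, repeatability 0.5, and moderate
correlations (genetic 0.5, permanent-environment 0.3, residual 0.2); these
are deliberate, arbitrary choices of a plausible dairy-trait regime, and
parameter-recovery tests are run against them, not against any published
estimate.  The X chromosome is treated as an autosome.

What the generator does **not** emulate: linkage disequilibrium from
physical linkage (each marker segregates independently; the only LD is
family structure), selection or assortative mating, genotyping error,
unequal per-trait recording schedules beyond a simple per-trait missingness
rate, and real gene/pathway structure (the synthetic annotation tiles the
genome with uniform genes; synthetic pathways are random gene sets,
optionally seeded with causal genes).  Passing tests therefore demonstrate
the pipeline's internal correctness and its behaviour under the assumed
statistical structure — not performance on real LD patterns or real
annotation.

## Test problem sizes and scaled conditions

The suite chooses problem sizes where each property is identifiable and
stable: parameter recovery uses 10 replicates of 400 bulls × 5 records
(half-sib families from 25 sires separate additive from permanent
environment); the planted-region check uses 300 genotyped bulls, 400
markers on 2 chromosomes and a 5-marker region with a lead SNP, explaining
~40% of the additive variance — at desk scale the back-solve spreads a
region's signal over all markers (n animals ≪ n markers), so a region near
the bare 20% mark tops the single-SNP scheme only about half the time, and
chromosomes must exceed the largest window size or the 100-SNP window
degenerates to the whole chromosome.  The printed per-size selection
thresholds are calibrated to a 76,519-marker genome (they sit just below
the mean window share there); on a few-hundred-marker synthetic genome
every window clears them, so the scaled comparison analog selects at each
scheme's own 90th-percentile window percentage instead — a self-scaling
top-decile rule — with pathways seeded from causal-gene neighbourhoods.
End-to-end determinism, QC, windowing and enrichment oracles run at small
sizes chosen for speed; the full synthetic reference run (the acceptance
script) executes at the 131-bull study scale in a few minutes.

## Known limitations

- Dense O(n³) linear algebra bounds practical use to a few thousand
  pedigree animals and a similar number of markers per back-solve.
- Boundary REML solutions (singular Va/Vp) converge slowly and are
  reported with a warning; interior problems converge in 10–25 AI
  iterations.
- The per-SNP variance definition and the enrichment background universe
  are both under-determined by the upstream literature; both defaults are
  explicit and overridable, and results can be sensitive to them.
- Iterated SNP-weighted ssGWAS, dominance/maternal effects, unknown-parent
  groups, metafounders and bp-length-based windows are out of scope.
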