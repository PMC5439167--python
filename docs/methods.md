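# Methods

## Model and scope

`crossrel` predicts the reliability (squared accuracy) of genomic EBV for
crossbred performance of purebred (breed A) selection candidates in a
two-way A×B crossbreeding program.  Reliability is defined through the
prediction error variance (PEV) relative to the base-population additive
variance, assuming no selection: r²ᵢ = 1 − PEVᵢ/Var(cᵢ).  Phenotypes are
assumed pre-corrected for all effects other than additive genetic effects;
reference animals have genotypes and phenotypes, candidates genotypes only.

Two SNP-effect models are covered.  Under **ASGM** a single allele
substitution effect per locus drives crossbred performance in all
populations, and purebred vs crossbred differences are absorbed by the
genetic correlation r_PC between the two traits.  Under **BSAM** each
crossbred allele carries an effect specific to its breed of origin, which
requires partial genomic relationship matrices G⁽ᴬ⁾ and G⁽ᴮ⁾ built from the
origin-labelled alleles of the crossbreds.

Three reference-population scenarios are supported: purebred only (PB–PB),
crossbred only (CB–PB) and mixed (CB+PB–PB).  BSAM is undefined for PB–PB
(single breed, no origin split).

## Relationship matrices

Genotypes are standardized per locus with VanRaden's second method,
Z = (M − 2p)/√(2p(1−p)), and G = ZZ′/m.  When two populations are involved
(breed A candidates vs crossbred reference animals) each population is
standardized with its own allele frequencies before the stacked product is
formed.  For partial matrices, a crossbred's breed-b origin allele
(M ∈ {0,1}) is standardized as (M − p_b)/√(2p_b(1−p_b)) with the purebred
breed-b frequency; purebred animals keep the full 0/1/2 coding with the
same frequencies.

Frequency conventions (a genuinely open choice; fixed here once):

* each population's frequencies are computed from **all genotyped animals
  of that population entering the analysis** (reference animals and
  candidates pooled); crossbreds form their own frequency population for
  ASGM blocks;
* breed-of-origin standardization always uses purebred parental-breed
  frequencies; in the validation workflow these come from the purebred
  cohorts of the reference generation pooled with any purebred animals
  already in the analysis;
* loci fixed (p ∈ {0,1}) in any population used for standardization are
  dropped from all panels and from m (logged), since the standardization is
  undefined there; m is always the retained locus count, shared by all
  blocks of one set.

The pedigree numerator relationship matrix A is computed by the tabular
method, swept level by level so that only animals still needed (targets and
parents of later animals) stay in memory; founders and unknown parents are
unrelated and non-inbred.  The pedigree base is the breed-founding
generation: the simulator starts recording at breed foundation, so the
related-vs-unrelated breed contrast lives entirely in G, which is what the
Mₑ estimator measures.  Pedigree depth is the full recorded pedigree.

## Effective number of chromosome segments

Mₑ between candidates S and reference animals R is the reciprocal of the
empirical variance of the element-wise differences between G_{S,R} —
rescaled to the pedigree base as G* = (1−F̄)G + 2F̄J, with F̄ the mean
pedigree inbreeding over the union of the two animal sets — and A_{S,R}.
The variance uses the n−1 denominator over the flattened rectangular block
("empirical variance" is ambiguous; the n denominator is available via
`ddof=0` for sensitivity checks).  A zero variance yields an
infinite-flagged estimate rather than a division error.

The design-stage closed form Mₑ = 2NₑL/ln(4NₑL) (Nₑ effective population
size, L genome length in Morgan) is provided for use when no genotypes
exist at all.

The breed-specific Mₑ⁽ᴬ⁾ (breed-A-origin segments shared between breed A
candidates and crossbred reference animals) is taken **equal to Mₑ between
the same candidates and purebred breed A reference animals**.  This is
justified when purebred and crossbred reference animals descend from the
same parental pool, which holds by construction in the simulated program.
An experimental variance-of-differences estimator on partial relationships
(`me_partial_from_g_a`, differencing against A/2) exists behind its own
function but is not used in validation.

## Parametric equations

Single-source forms are Daetwyler-type: r² = N h²/(N h² + Mₑ), scaled by
r²_PC when the reference trait is purebred performance, and with Mₑ
replaced by 2Mₑ⁽ᴬ⁾ in the breed-specific crossbred-reference form — the
factor 2 accounts for the doubled number of effects estimated when each
allele's origin gets its own effect.  Mixed-reference forms are two-source
selection-index systems b′Q⁻¹b solved as a 2×2 linear system with a
condition-number guard (>1e12 raises); a source with N = 0 is dropped
analytically rather than forming 1/N, so the N_AB = 0 limit of the mixed
equations equals the single-source value exactly.

The breed-specific crossbred-reference equation is implemented in its
simplified form (error shrinkage term dropped, valid for low h²); the full
self-referential form, which retains (1 − ½h²_{c_A}r² − ½h²_{c_B}r²) in the
denominator, is available via `simplified=False` and solved by fixed-point
iteration started at the simplified value (tolerance 1e-10, ≤100
iterations; the same per-breed effect reliability is assumed for A and B).

`break_even_rpc(N, h², Mₑ) = √((N h² + Mₑ)/(N h² + 2Mₑ))` gives the genetic
correlation at which a purebred-only ASGM reference matches an equally
large crossbred-only BSAM reference.

## Selection-index equations and the PEV oracle

All with-data reliabilities share one pattern: numerator = candidate
relationship row into the reference set, solved against the reference-side
matrix (relationship blocks plus a diagonal shrinkage (1−h²)/h²; for BSAM
the crossbred block is G⁽ᴬ⁾ + G⁽ᴮ⁾h²_{c_B}/h²_{c_A} with shrinkage
(1 − ½h²_{c_A} − ½h²_{c_B})/h²_{c_A}), divided by the candidate's own
genomic diagonal.  The reference-side matrix is Cholesky-factorized once
per call and reused across candidates; no explicit inverse is formed.
h² = 1 is allowed (zero shrinkage), supporting deregressed-EBV style
pseudo-phenotypes with h² ≈ 0.95.  Candidates with genomic diagonal below
1e-8 are reported as missing (NaN) rather than divided; negative diagonals
raise.  The mixed-reference BSAM equation is implemented per candidate
(numerator inside the candidate average), which is the internally
consistent reading of the per-candidate derivation.

`gblup_pev_reliability` is the independent cross-check: it assembles the
joint covariance of reference phenotypes and the candidate's target genetic
effect on the raw variance-component scale (phenotypic variances set to 1,
so σ²ₐ = h²ₐ etc.; for BSAM σ²_{e_AB} = 1 − σ²_{c_A}/2 − σ²_{c_B}/2) and
computes r²ᵢ = cov′ Var(y)⁻¹ cov / Var(cᵢ) by conditioning.  The closed
forms agree with this route to machine precision; the tests additionally
verify the oracle against a naive explicit-inverse implementation, keeping
the two routes genuinely independent.

A weighted variant supports repeated records and deregressed proofs through
an incidence matrix W and diagonal weight matrix R (1 for raw records,
1/weight for pseudo-phenotypes); with W = R = I it reproduces the plain
purebred equation exactly.

## Simulator

The generator emulates the validation design: (1) a historical
random-mating population (default 1000 generations at N = 10,000, then 1000
generations declining linearly to 2000 — the decline schedule is not
otherwise constrained, linear is this package's choice); (2) two breeds
founded by disjoint random samples of 500 males + 500 females, diverging
for 10 (related) or 100 (unrelated) generations with litters of four (2M/2F)
per dam, 500 randomly selected sires and a female ramp 500→800 over four
generations; (3) five crossbreeding generations with purebred replacement
cohorts of 1000 males + 3000 females per breed and 4000 F1 crossbreds per
generation from random A×B matings, parents drawn from the same pools for
purebred and crossbred offspring.

Genome: 10 chromosomes × 1 Morgan × 4000 candidate SNPs, positions uniform;
crossover counts Poisson(L) per chromosome without interference; recurrent
symmetric allele-flip mutation at 2.5×10⁻⁴ per transmission.  Founder
frequencies are drawn uniform(0.05, 0.95) per locus (the initialization is
otherwise unspecified; the 2000 generations of drift and mutation then
shape the spectrum).  The analysis panel takes, per chromosome, 2000 random
SNPs among those with MAF ≥ 0.05 (inclusive) in the last historical
generation.

Crossbred matings alternate the sire breed by offspring index (the design
does not fix which breed provides sires); the gamete from the breed-A
parent is stored as the A-origin haplotype, so the breed-origin split is
exact by construction, and the reconstruction identity (A-allele + B-allele
= genotype) is tested exactly.  One master seed spawns per-phase child
generators deterministically.

What the generator does **not** emulate: QTL and phenotypes (the validation
needs none — both reliability routes use only relationships and
parameters), selection (random selection throughout), crossover
interference, and realistic MAF ascertainment of commercial chips.  Passing
tests therefore establish the internal consistency of the two reliability
routes under neutral drift-generated LD, not their accuracy under selection
or with real-chip ascertainment.

## Validation workflow and problem sizes

Per replicate and relatedness setting, the workflow samples reference
groups from crossbreeding generation 2 and three candidate groups (G1–G3,
one per later generation), builds the scenario's relationship blocks,
estimates Mₑ within the replicate (per candidate group), and evaluates the
matching with/without equations over the grid h² ∈ {0.20, 0.40, 0.95} and
r_PC ∈ {0.3, 0.7}.  Cells that fail are flagged and the run continues.

The default desk profile (`SimConfig.scaled()`) uses 100 + 100 historical
generations (400→200 animals), 5 chromosomes × 400 candidate SNPs with a
200-SNP panel per chromosome, breed founders 50+50, crossbred cohorts of
400, reference groups of 200/400 and candidate groups of 100.  At this
scale the replicate-level reliabilities are not expected to match
full-scale values numerically; the workflow's checks are directional
(parametric underestimates selection-index at moderate/high h², the gap is
largest for G1, BSAM gains from breed divergence while ASGM barely moves,
ASGM dominates BSAM with data in the crossbred scenario).  The full-scale
configuration reproduces the published design but takes hours; it is
exposed through the same `SimConfig` defaults.

## Numerical choices and limitations

* Sample variance (n−1) in the Mₑ estimator; switchable.
* Cholesky solves with shared factorization; singular reference systems
  raise rather than silently pseudo-inverting.
* Square relationship blocks are symmetrized (tolerance 1e-10 on input
  asymmetry) and PSD is enforced only where required (the PEV oracle
  rejects non-PSD phenotype covariances at −1e-8 on eigenvalues).
* Mixed-model equivalence holds only without selection; reliabilities here
  are *not* cross-validation reliabilities of selection under truncation.
* The Mₑ estimator is known to overstate Mₑ when candidates are closely
  related to the reference set (one generation apart), which is exactly
  where the parametric equations underestimate most — visible in the
  validation output as the G1 gap.
* The parametric forms ignore the reduction of the error variance that
  occurs when many loci are fitted simultaneously (a small additional
  source of underestimation that grows with h²); the simplified forms are
  used and validated as such, with the self-referential crossbred-reference
  variant available behind `simplified=False`.
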