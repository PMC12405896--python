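# Methods

## Models and Hamiltonians

Both models act on a design matrix X whose columns are chromosomal bins:
adjacent SNPs collapsed left-to-right until the bin span (last SNP position −
first SNP position + 1) reaches 50 kb, each bin scored per accession by its
mean reference-allele dosage — the sum of reference-allele counts over
non-missing SNPs divided by twice the number of non-missing SNPs, a value in
[0, 1].  Span is measured between SNP positions rather than as a fixed
genomic window because bins are grown by *adding SNPs*; the final bin of a
chromosome may be shorter than 50 kb and is kept as-is (merging it backward
would silently change its neighbor's content) with a log entry making the
choice auditable.  An accession×bin cell whose SNPs are all missing takes the
bin's column mean; this path is rare because upstream genotype panels are
normally imputed.  Coordinates are 1-based inclusive throughout, matching
VCF convention.

**Linear model.**  Y = Xβ + ε with Hamiltonian
H = (Y − Xβ)′V⁻¹(Y − Xβ), V diagonal and *fixed* at each observation's
accession trait sample variance.  Accessions with fewer than two
observations, or sample variance below a floor of 1e−6 trait-units², take
max(pooled within-accession variance, floor); if every accession is a
singleton the global sample variance is used (warned).  Note the deliberate
absence of a ½ factor: the stationary ensemble over β is Gaussian with
covariance ½(X′V⁻¹X)⁻¹, which the sampler tests assert.

**Mixed linear model.**  Y = Xβ + Zu + ε with Zᵢ = Xᵢ.  Marginalizing u
gives V = Σᵢ xᵢxᵢ′σ²ⱼ₍ᵢ₎ + σ²I = X S X′ + σ²I with
S = Σᵢ xᵢxᵢ′σ²ⱼ₍ᵢ₎, the sum running over observation rows i (replicated
accessions therefore contribute once per plant; the per-observation sum is
the model definition adopted here, even though a per-accession random effect
would count each accession once).  The Hamiltonian is the exact negative
MVN log density ½(Y−Xβ)′V⁻¹(Y−Xβ) + (n/2)ln 2π + ½ln|V|, which can be
negative.  Parameters are the per-accession *scales* σⱼ ≥ 0 (square roots of
the variance components) and the residual scale σ > 0; proposals driving any
scale negative are rejected outright (reflecting them would change the
proposal law).

The ensemble probability Q ∝ exp(−H) is only ever used through Metropolis
ratios, so its normalization is never computed.

## Sampler

One sweep is p single-parameter update attempts with the index drawn
uniformly — a visit to each parameter on average once.  Proposals are
β_k′ = β_k + S·U(−1, 1).  Defaults follow the full-scale practice: 10,000
equilibration sweeps, then 1,000 stored vectors separated by 1,000
decorrelation sweeps; test and study profiles scale all three down via
configuration.  β is initialized i.i.d. uniform(−0.1, 0.1) and sigmas at the
trait's overall sample standard deviation (the initialization law is
otherwise unconstrained).

**Stepwidth adjuster.**  Two parameter classes (betas; sigmas) carry
independent stepwidths, updated every 1,000 sweeps from an acceptance-rate
moving average over 1,000 sweeps (both configurable).  The update
S_i = f_i S_{i−1} uses f = 1 inside the target band [r_min, r_max] = [0.3,
0.7] or when S has left the guard band [E_S·S̄, S̄/E_S] (S̄ the running mean
of past stepwidths, E_S ∈ [1e−6, 1e−4], default 1e−5); f = 2/3 on first
falling below r_min (steps too large → shrink), f = 3/2 on first exceeding
r_max, f = f_prev when out of band on the same side twice, and f = 1/f_prev
when the band was crossed.  The orientation — low acceptance shrinks the
step — is the one that drives the rate toward the band, since larger steps
produce larger ΔH and lower acceptance.

**Incremental updates.**  The linear model keeps the residual r and the
cached V⁻¹X columns, so a move costs O(n) (ΔH = −2δ·x_k′V⁻¹r + δ²·x_k′V⁻¹x_k);
the mixed model reuses its Cholesky factorization while only β moves and
refactorizes V when a σ moves.  The incrementally tracked Hamiltonian is
checked against a full recomputation (and re-synchronized) at every adjuster
update and at every accumulation store, so stored Hamiltonians always equal
exact recomputation.

## MINE criterion and selectors

Prediction moments are plain ensemble averages over the N stored parameter
vectors; D (covariance) or E (correlation) is assembled from them and its
log-determinant computed as Σ log max(λ, floor) with
floor = 1e−12·max(λ_max, 1): the eigenvalue route tolerates PSD rank
deficiency and avoids the under/overflow a raw determinant hits near K ≈ 80.

* *Suboptimal*: score all p_t-tuples, sort descending, harvest individual
  accessions in tuple-rank order (input order within a tuple, duplicates
  skipped) until p_a are collected.  Enumeration refuses above 2×10⁶ tuples
  by default.
* *Monte Carlo*: Metropolis swap search over panels with Hamiltonian
  −log det and temperature 1.0 (default); the best panel seen is returned.
* *Nc3+2*: one top triple, then top doublets; each round's tuple is scored
  jointly with the accessions already selected (scoring tuples in isolation
  would ignore accumulated information), and chosen accessions leave the
  pool.  The alternating triple/doublet cycling variant is available behind
  a flag.
* *Greedy*: seed with the top triple, then repeatedly add the single best
  accession.  Its score trace need not be monotone under the correlation
  criterion.

Exact score ties are broken by accession-label lexicographic order, making
every selector deterministic given a seed.

## Feature selection

The projection filter eigendecomposes X′V⁻¹X, sorts eigenvalues descending,
zeroes rotated β components whose eigenvalue is below 1e−10·λ_max (a
relative threshold, because the idealized "all eigenvalues from rank+1 on
are exactly zero" does not survive floating point), and rotates back; fitted
values Xβ are preserved to numerical precision.  The projection itself is a
transform, not a mask — its *selection* is realized as the interval test on
the projected ensemble, while the Bayesian-interval and BH filters run on
the raw ensemble; a region must survive all three.  The Bayesian interval
uses the sorted-sample convention (q-quantile = value at 1-based index
⌈qM⌉); BH uses z = ensemble mean / ensemble sd, two-sided normal p-values
and the standard step-up rule (the non-step-up per-p comparison is available
as a `literal` flag and always keeps a subset of the step-up survivors).
The one-at-a-time control regresses the trait on each column separately by
GLS with intercept — the classical strategy whose overfit the joint-model
filters avoid.  The year-effect statistic is oriented as
−2 ln Λ = 2(H_noyear − Σ H_year), positive when the per-year model fits
better; because a single run's terminal Hamiltonian is noisy, the statistic
is also resampled (one stored Hamiltonian drawn uniformly from each
ensemble per draw, 1,000 draws) and the fraction of draws below zero is
reported as the vote for no year effect.  The degrees of freedom are passed
through from the declared parameter-count difference, not derived.

## Synthetic data

The generator emulates: SNPs at a mean spacing of 2.5 kb (positions by
cumulative uniform gaps), per-SNP reference-allele frequencies uniform on
(0.05, 0.95), genotypes with excess homozygosity F = s/(2 − s) from a
selfing rate of s = 0.85 by default, independent across SNPs (an
LD-free law is sufficient because the models operate at bin level);
accessions replicated in randomized blocks over years; traits under either
model with a chosen number of causal bins.  Effect sizes default to a
0.5–2.0 grid in residual-sd units per sd of bin dosage (the magnitudes are a
package choice, configurable, not an external reference); mixed-model
accession scales are drawn uniform on (0, 0.5·σ).  What passing tests on
these data do *not* show: robustness to within-bin LD structure, genotyping
error, non-normal trait noise, or genotype-by-environment interaction.

**Power/FPR study.**  The bundled study design uses 300 distinct
unreplicated accessions over 4 chromosomes (≈200 bins, 10 causal), the
linear-model fit at a reduced profile (1,500 equilibration sweeps, 300
stored vectors, 10 decorrelation sweeps) and the interval+BH filter pair,
10 seeds.  The design matrix is full column rank by construction: with
replicated accessions the plant-level X has rank equal to the number of
accessions, the unconstrained β directions wander, and an interval+BH-only
pipeline (without the projection filter) has no defense against them — the
full-rank design isolates what this filter pair is meant to measure.  With
all accessions singleton, V falls back to the global trait sample variance.

## Numerical notes and limitations

* V matrices are symmetrized before factorization; Cholesky failure raises
  rather than regularizes.
* The sampler is single-chain; convergence is assessed only by the
  last-quartile Hamiltonian slope (tolerance 1e−3 per sweep by default) and
  the acceptance/stepwidth traces, not by multi-chain statistics.
* Mixed-model σ moves refactorize V at O(n³); the mixed sampler is intended
  for accession-level or modest plant-level n.
* Heritability estimation, kinship matrices, REML solvers, phasing and
  multiallelic decomposition are out of scope.
* The gene finder matches closed genomic intervals (≥1 bp overlap) after
  normalizing chromosome names (chr prefixes, leading zeros); distances to
  nearby non-overlapping genes are not computed.
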