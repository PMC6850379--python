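# Methods

`fastz` implements the inference chain used in fast-Z / fast-X studies of
molecular evolution: per-gene polymorphism and divergence statistics from
codon alignments, sex-bias classification from expression data, the
classic McDonald–Kreitman (MK) estimate of the adaptive proportion α, a
gamma-DFE model fitted to site frequency spectra (SFS) that yields α,
ω_a and ω_na corrected for segregating deleterious variants, gene
bootstrap intervals, and Z/autosome diversity summaries. A
synthetic-data generator produces datasets from exactly the model family
the fitter assumes, so every estimator can be validated by parameter
recovery.

## Counting model (codon statistics)

Alignments are n ingroup haplotypes plus one outgroup sequence, in
frame. Counting is equal-weight Nei–Gojobori:

* **Usable codons.** A codon column is used only if every sequence
  (ingroup and outgroup) carries an unambiguous, non-stop codon there;
  N, gaps and stops exclude the whole column (complete-case rule,
  mirroring upstream missing-genotype masking). `codons_used` counts the
  surviving columns.
* **Site totals.** Each position of the ingroup consensus codon
  contributes f = (#synonymous single-nucleotide changes)/3 synonymous
  sites and 1−f nonsynonymous sites. Changes that would create a stop
  codon count as nonsynonymous, which preserves the identity
  L_n + L_s = 3 × codons_used exactly (e.g. TTT → L_s = 1/3).
* **Polymorphism.** A site with ≥2 segregating ingroup alleles is a
  polymorphism; each non-major allele is classified by its amino-acid
  effect on the majority-background codon. SFS bins are derived-allele
  counts when the outgroup matches one segregating allele, otherwise the
  minor-allele (folded) bin; the number of unpolarizable entries is
  recorded.
* **Divergence.** A site where the monomorphic ingroup differs from the
  outgroup is a fixed difference. A site that is both polymorphic and
  divergent counts as polymorphism only. Codons with several fixed
  differences are resolved by averaging synonymous/nonsynonymous counts
  over all minimal mutational pathways that avoid stop codons
  (fractional D_n/D_s are possible).
* **Diversity.** π per class is Σ_sites 2p̂(1−p̂)·n/(n−1) divided by the
  class site total — algebraically identical to the average pairwise
  difference per site, which the tests verify by brute force.
* Divergence is left uncorrected for multiple hits by default (at the
  dS ≈ 0.15 regime this toolkit targets the correction is small); a
  Jukes–Cantor helper (`codon.jukes_cantor`) is provided.

## Classic MK α

α = 1 − (dS·p_n)/(dN·p_s) with per-site polymorphism p_n = P_n/L_n and
p_s = P_s/L_s, equivalently the raw-count form 1 − (D_s·P_n)/(D_n·P_s).
Both ratios compare like with like, so α = 0 exactly when
dN/dS = p_n/p_s (the neutral null), α ≤ 1 with equality only when
P_n = 0, and α < 0 when weakly deleterious variants inflate P_n. The
estimate is reported per pooled stratum (ratio-of-sums); per-gene values
are available but frequently undefined (P_s = 0 or D_n = 0) and noisy.

## DFE model (the "modelling" MK approach)

Counts in every frequency class of both compartments are independent
Poisson variables (Poisson random field). The stationary density of a
derived allele with population-scaled selection coefficient S is

    f(x; S) = [θ/(x(1−x))] · (1−e^{−S(1−x)})/(1−e^{−S}),

binomial sampling of n alleles gives the expected class occupancy
H(S, i, n), and the relative fixation rate is S/(1−e^{−S}). Deleterious
effects follow a gamma distribution on −S (shape, mean S ≤ 0); the
synonymous class is neutral (H → 1/i). A per-class nuisance factor r_i,
shared between compartments with r_1 ≡ 1, absorbs demography and
ascertainment distortions.

**Likelihood and optimization.** Because θ·r_i enters both compartments
linearly, its per-bin MLE is closed-form given (shape, mean S):
λ̂_i = (s_i + n_i)/(L_s·h_i + L_n·g_i). The profile likelihood is
maximized over (log shape, log |mean S|) by bounded L-BFGS-B from five
dispersed starts (ftol 1e−8); θ̂ = λ̂_1 and r̂_i = λ̂_i/λ̂_1 are recovered
afterwards. Bootstrap replicates warm-start from the point estimate
(single start); convergence status and boundary hits are recorded.

**Outputs.** The expected near-neutral dN/dS is E_φ[S/(1−e^{−S})] under
the fitted DFE; α = 1 − expected/observed, ω_a = α·(dN/dS),
ω_na = (1−α)·(dN/dS). The decomposition ω_a + ω_na = dN/dS holds to
machine precision by construction. When D_n or D_s is zero the
observed dN/dS — and hence α, ω_a, ω_na — is reported as undefined.

**Folding.** Folded fitting (bins i and n−i combined) is the default for
real data, where outgroup polarization errors distort the high-frequency
tail; unfolded mode is available and is what recovery experiments use,
since the generator polarizes perfectly.

**Quadrature.** The x-integral uses split Gauss–Legendre (32+32 nodes)
with the breakpoint at ≈20/|S|, because the kernel concentrates in a
boundary layer near x = 0 under strong selection. The DFE expectation
integrates in log t (t = −S) with composite 16-point Gauss–Legendre
panels of width 2 from t = 1e−8 up to 60× the gamma scale, plus an
analytic term for the gamma mass below 1e−8 (where all integrands take
their neutral limit). A Laguerre-type rule is *not* used: with strongly
deleterious means the near-neutral power-law tail of the gamma — which
dominates both the SFS and the fixation integral — falls below its
smallest node. The rule is validated in the tests against adaptive
quadrature to 1e−4 relative and is self-converged to ~1e−10; the
simulator's independent ω_na integral uses `scipy.integrate.quad` at
relative tolerance 1e−8.

## Expression classification

RPKM = N_c·10⁹/(N_tot·L_c) per gene and sample; per-gene levels are
unweighted means over the relevant samples (5 female + 5 male abdomens
by default). Sex bias: RPKM_f/RPKM_m > 1.5 → female-biased, < 0.66 →
male-biased, otherwise unbiased (strict inequalities; boundary values
are unbiased). A gene expressed only in females has an infinite ratio
and is female-biased; a gene expressed in neither sex is unbiased and
flagged unexpressed. Tissue bias thresholds an externally produced
ovary-vs-gut differential-expression table (adjusted p < 0.05 and
|log2FC| > 1.5); differential-expression modelling itself is out of
scope — only the thresholding and the RPKM classifier are defined here.
Z-vs-autosome × ovary-vs-gut enrichment uses the Pearson chi-square
(no continuity correction), warning when an expected count is < 5.

## Resampling

95% intervals are percentile bootstrap over genes: resample with
replacement to the original gene count, recompute the pooled statistic,
take the 2.5th/97.5th percentiles of 1000 replicates (the minimal
reading of a "bootstrap the genes" protocol — no BCa acceleration).
Replicates with undefined statistics are dropped and counted. Stratum
comparisons use the interval-overlap rule. DFE refits inside replicates
warm-start at the point estimate; cold-start refitting is available for
validation and agrees (the profile surface is unimodal in practice).

## Synthetic-data generator

The generator draws from the PRF model the fitter assumes — recovery
tests are exact-model tests, and a full dataset simulates in well under
a second:

* sfs_s[i] ~ Poisson(θ_s·L_s/i); sfs_n[i] ~ Poisson(θ_s·L_n·E_φ[H(S,i,n)]);
* D_s ~ Poisson(L_s·div_s); D_n ~ Poisson(L_n·div_s·(ω_na + ω_a)) with
  ω_na = E_φ[S/(1−e^{−S})] and ω_a = p_adaptive/(1−p_adaptive)·ω_na, so
  the adaptive fraction of nonsynonymous substitutions is exactly
  p_adaptive;
* Z-linked genes scale θ by ne_ratio_Z (polymorphism only — the neutral
  substitution rate is independent of N_e); an optional per-class
  divergence multiplier models male-biased mutation (default 1);
* spectra are generated unfolded; folding is a downstream transform.

Defaults emulate a Heliconius-like regime: θ_s = 0.025/site (autosomal
π_s ≈ 0.027), div_s = 0.15 (the melpomene–erato synonymous divergence),
n_alleles = 20 (10 diploids), gamma shape 0.4 with mean S = −2000
(leptokurtic, strongly deleterious DFE typical of large-N_e insects;
implies ω_na ≈ 0.04), p_adaptive = 0.5, ne_ratio_Z = 0.75 (neutral
equilibrium, 1:1 sex ratio), 10% Z-linked genes, 16.5%/16.5% true
female-/male-biased genes, mean gene length 450 codons (log-normal).

`emit_alignments` realizes genes as codon alignments: a random stop-free
coding sequence, each variant placed on its own codon as a
single-nucleotide change of the required class and derived count, fixed
differences carried by the outgroup, the outgroup retaining the
ancestral allele at polymorphic sites. Re-counting therefore reproduces
the simulated totals *exactly*; genes too short for their variant count
are regenerated longer, with a bounded retry. Expression is
negative-binomial (dispersion 0.1, log-normal library sizes around 30 M
reads) with true fold changes applied to the biased sex.

**What the generator does not emulate** — and hence what passing
recovery tests do not establish for real data: linkage and background
selection (all counts independent), demographic change (equilibrium
spectra; the r_i nuisance is exercised only at r ≡ 1), selection on
synonymous sites, polarization error, alignment error, multi-nucleotide
mutation, sweeps affecting linked polymorphism (adaptive substitutions
contribute to divergence only — the standard MK assumption), and
expression batch effects. Real-data runs should treat the folded mode
and the nuisance vector as load-bearing; the simulation validates the
estimator's internal consistency, not these robustness properties.

## Problem sizes in the validation suite

Validation experiments are sized for precision, not spectacle: 2000
genes (half Z-linked) pin the diversity ratio to ±0.01 Monte-Carlo
error; 500 genes suffice for the MK neutral null at ±0.05; DFE recovery
uses 3000 genes (~10⁵ segregating sites pooled), where the fitted α is
within ±0.02 of truth; bootstrap calibration uses 200 datasets × 200
genes × 1000 replicates. The pipeline demo reduces bootstrap replicates
to 40 (1000 in production runs).

## Known limitations

* Pathway averaging for multi-variant codons is a convention, not an
  inference; tri-allelic sites are decomposed against the majority
  background and contribute approximately to π.
* The DFE family is gamma-on-deleterious only: no beneficial mass in the
  polymorphism model, no lognormal/displaced alternatives.
* Percentile intervals slightly undercover for strongly skewed
  statistics at small gene counts (calibration is tested at 200 genes).
* Classic α and the DFE α answer subtly different questions when the
  DFE has substantial weakly deleterious mass; on such data classic α is
  expected to sit below the model α (this is the method's point, not a
  defect).
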