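# Methods

## Scope and data model

paleopipe covers the post-alignment stages of a low-coverage ancient-DNA
study: QC/authentication, genotype-likelihood construction at the sites of
a phased reference panel, imputation with a haplotype-copying model,
validation by downsampling, and downstream population-genetic summaries
(PCA placement, runs of homozygosity, trait-SNP genotypes). Read
trimming, alignment, duplicate removal and haplogroup assignment are out
of scope; the pipeline starts from per-site read observations
(position, base, Phred quality, strand, distance from each read end).

All analyses run against synthetic data produced by the package's own
generators, so every claim the test suite makes is a parameter-recovery or
oracle-equivalence statement about known truth, not a reproduction of any
real dataset.

## Synthetic study

`simulate_panel` draws per-site derived-allele frequencies (default
uniform on [0.05, 0.95]), realizes K phased haplotypes (default K=100)
Bernoulli-independently per site, and redraws any site whose minor allele
count is ≤ 1 — panels used for imputation exclude near-private variants.
Ref/alt base pairs are transitions (C/T or G/A) for a configurable
fraction of sites, default 0.66, matching the transition bias of human
SNPs; this fraction is what the deamination mask later removes from the
likelihood signal. Sites are uniform positions on a 5 Mb chromosome
(M=5000 by default, ~1 SNP/kb).

`simulate_truth` builds a diploid target as a mosaic of a founder subset
of panel haplotypes (default 10 founders), switching founders as a Poisson
process at 1e-6 per bp — about one switch per 1,000 sites at the default
density, matching the HMM's default switch rate. Truth genotypes are the
sum of the two haplotype alleles.

`simulate_reads` gives each site Poisson(coverage) reads. A read copies a
uniformly chosen truth haplotype, or with probability α (default 0.01) a
contaminant allele drawn from the panel frequency — a modern-like human
contaminant, the scenario the contamination estimators target. Fragment
lengths are a discretized normal (mean 60, s.d. 15, truncated to
[30, 150] bp), consistent with post-trimming ancient-DNA length filters;
the read's offset within the fragment gives its distances from the 5′ and
3′ ends. Deamination converts a true C to T with probability
δ5·exp(−(i−1)/λ) at distance i from the 5′ end, and G to A analogously
from the 3′ end (defaults δ5 = δ3 = 0.2, λ = 3 positions). Damage is
applied at the site level by end distance; full sequence-context
simulation is not attempted because the analysis consumes only site-level
alleles and end distances. Sequencing error then substitutes a uniform
other base at the Phred-implied rate (default Q30).

Dedicated generators produce the QC inputs: an invariant-site
damage-control read set (homozygous-reference target over C/G reference
positions — the analogue of profiling damage against the reference genome,
where almost every position is invariant); mtDNA reads at diagnostic
positions where an endogenous consensus differs from a contaminant
haplotype (transversion differences by default, the damage-robust choice);
X reads for a hemizygous male; X/Y read counts (male R_y expectation
0.089); and a modern reference genotype matrix under the Balding–Nichols
model (two populations, F_ST = 0.05 by default) around the panel's allele
frequencies.

What the generator does **not** emulate: linkage disequilibrium within the
panel itself (haplotypes are site-independent draws, so the target's
mosaic structure is the only haplotype signal), reference bias, mapping
error, indels, UDG treatment profiles, and multi-chromosome structure.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, and realistic qualitative behaviour — not performance
guarantees on real libraries, where panel mismatch and reference bias
reduce imputation accuracy.

## Genotype likelihoods

For a read r with quality Q, e_r = 10^(−Q/10); the read supports an allele
with likelihood 1−e_r if it matches, e_r/3 otherwise; reads carrying
neither panel allele are discarded. A genotype's per-read likelihood is
the mean of its two allele likelihoods; per-site accumulation is in log
space with one final normalization to a triple summing to 1 (contract:
within 1e-12). A site with no usable read emits exactly (1/3, 1/3, 1/3)
and an `uncovered` flag.

Deamination masking has two modes. The default `site-flat` resets the
whole triple to the flat value at any C/T or G/A site: resetting some
genotypes but not others both breaks normalization and leaves
damage-driven information in place, so treating the site as uninformative
— deferring entirely to the copying prior — is the conservative choice.
The alternate `genotype-flat` mode resets only genotypes containing the
damage-product allele (T at C/T sites, A at G/A sites) to 1/3 and
renormalizes. Masking is idempotent in both modes, and is deliberately
not strand-aware: the mask is keyed on genotype identity, not read
orientation.

## The copying HMM

The imputation model is a diploid Li–Stephens HMM. The hidden state at
site m is an ordered pair (j, k) of panel haplotypes (K² states, uniform
start). Each haplotype independently stays with probability exp(−ρ) or
jumps to a uniform haplotype; ρ defaults to 1e-3 per site (≈10 switches
per 10⁴ sites). Copying is imperfect: each target allele differs from its
copied panel allele with miscopy probability ε. The emission at site m
for state (j, k) is Σ_g GL_m(g)·A(g | h_j[m], h_k[m], ε), where A
convolves two independent miscopy-ε Bernoulli draws. The per-site
genotype posterior divides the site's own emission out of the state
posterior and re-weights by GL·A, then normalizes.

ε defaults to 0.001. This matters analytically: the maximum GP attainable
at a flat-likelihood (masked or uncovered) site is ≈ (1−ε)² + ε², so with
ε = 0.01 no such site could ever clear the 0.99 genome-wide call
threshold and the call rate would collapse to the directly covered
non-transition sites; ε = 0.001 keeps confidently copied sites callable,
which is the regime real imputation pipelines operate in. Both ε and ρ
are exposed in the config.

Implementation: the jump-uniform transition is rank-1, giving the
standard O(M·K²) forward–backward; per-site rescaling prevents underflow
at M = 10⁴, K = 100. The backward pass re-derives forward matrices from
block checkpoints (block = 64 sites) rather than holding all M K×K
matrices — identical output, much lower memory traffic. An exhaustive
path-sum oracle (`brute_force_posterior`) is exported for the test suite
and agrees with the fast recursion to 1e-10 on random tiny instances.

Calls are argmax-GP where max GP ≥ threshold, ties and sub-threshold
posteriors are missing. Thresholds: 0.99 genome-wide, 0.85 single-locus.

## Validation metrics

Concordance conditions on evaluable (truth-called) loci. Call rate =
called/evaluable; overall concordance = matching/called; heterozygote
concordance conditions on truth-heterozygous called loci (the natural
reading of "X% of heterozygotes"), with the alternate call-conditioned
figure also reported; non-reference discordance is the mismatch fraction
among called loci where truth or call is non-reference. The coverage
sweep re-simulates the read layer per replicate with derived seeds and
holds panel and truth fixed. At study scale (K=100, M=5000, 1×, default
damage, t=0.99) the sweep lands in the published qualitative regime for
1× imputation — call rate ~0.7–0.9 with >0.99 accuracy — and call rate
increases monotonically over 0.1–5×; exact published percentages are not
reproduction targets, since they depend on real genomes and panels.

## Sex, contamination

R_y = n_Y/(n_X+n_Y) with a normal-approximation binomial CI; call XX if
the CI upper bound is below 0.016, XY if the lower bound exceeds 0.075
(bounds from the shotgun sex-typing literature; exposed in config).

mtDNA contamination is the fraction of reads carrying the contaminant
allele among reads carrying either allele at diagnostic positions, with a
binomial CI. By default, read observations whose contaminant support is
damage-consistent (observed T at an endogenous-C position, A at
endogenous-G) are excluded from numerator and denominator; with
transversion diagnostics (the default simulation and standard practice)
this exclusion removes nothing and the estimator is unbiased.

X contamination (males only) is moment-based: d_poly, the fraction of
reads off the site-majority allele across polymorphic X sites with depth
≥ 2, estimates e + α·h̄ where e is the supplied autosomal error rate and
h̄ the mean of 2p(1−p) over used sites (the chance a contaminant read
carries the other allele); the estimate is max(0, (d_poly − e)/h̄),
clipped to [0, 1], with a site-level bootstrap CI. The error rate is
supplied, not re-estimated here. This is a deliberate simple stand-in for
likelihood-based X-contamination models; recovery simulations show it is
unbiased to within ±0.02 at α ≤ 0.1 under the generator's model.

## PCA placement

Reference PCA mean-imputes missing modern dosages per site, centers at
the mean dosage and scales by sqrt((μ/2)(1−μ/2)), drops monomorphic
sites, and takes the top D = 2 axes by SVD. Each ancient sample is placed
by (1) refitting the modern PCA restricted to the sample's non-missing
sites, (2) passively projecting the ancient dosages onto those axes — the
low-coverage sample never drives the axes, avoiding shrinkage of the
reference space toward it — and (3) mapping the restricted modern
configuration onto the canonical one with a full Procrustes transform
(translation, scale, rotation and reflection; reflection must be
allowed because PCA axes carry arbitrary sign). The fitted transform
carries the ancient projection into the canonical frame. With no
missingness this reduces exactly to the canonical projection. A joint
decomposition that includes the ancient sample was rejected: at desk
scale the near-degenerate trailing axes rotate under a single added
sample, which breaks placement stability.

## Runs of homozygosity

Sliding windows of 50 SNPs count as homozygous with ≤ 1 heterozygous and
≤ 5 missing calls; a SNP is in-run when ≥ 5% of the windows spanning it
are homozygous; maximal in-run stretches are split at > 1 Mb physical
gaps and filtered to ≥ 500 kb and ≥ 50 SNPs. These are conventional
PLINK-style values, with the minimum SNP count set to 50 to match
desk-scale SNP density; all are configurable. Segments are classed short
vs long at 1.6 Mb, with a segment of exactly 1.6 Mb classed long (the
boundary must belong to one side; the long class owns it). Total ROH per
sample is regressed on median sample age by OLS with a two-sided slope
test.

## Trait loci

Single-locus genotypes are argmax-GP calls at threshold 0.85; dosages are
oriented by each locus's effect allele and loci absent from the panel are
reported as absent rather than raised. The temporal table derives, per
locus, the oldest called sample carrying the effect allele and the oldest
effect-homozygote. Phenotype prediction systems (HirisPlex-style) are a
pluggable interface accepting an external coefficient table; no
coefficients are bundled and none are re-derived.

## Orchestration and reproducibility

A single global seed deterministically derives per-stage and per-sample
seeds (via `numpy.random.SeedSequence`), so stages re-run standalone with
identical randomness and a full rerun is byte-identical (fixed float
formatting in every TSV). The manifest echoes the seed, full parameter
set and artifact list. Default problem sizes (demo: K=60, M=1500, three
1× samples; validation: K=100, M=5000) were chosen so the full test suite
and demo complete in minutes on one CPU while keeping the statistical
checks well-powered.

## Known limitations

- Panel haplotypes carry no LD, so imputation accuracy here reflects
  mosaic-recovery of panel members, an easier problem than real-panel
  imputation; absolute call rates/concordances are not transferable.
- The X-contamination estimator ignores panel allele-frequency error and
  assumes a single contaminant drawn from the same frequencies.
- The damage model is site-level; no nick/overhang model, no UDG-treated
  library profiles.
- ROH detection implements one window heuristic; inbreeding coefficients
  and Ne inference from length spectra are out of scope.
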