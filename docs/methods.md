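# Methods

## The problem

Most trait-associated variants found by GWAS sit in regulatory sequence.
When a variant is associated with both a complex trait and a molecular
trait measured in cis — DNA methylation at a CpG site, or a transcript —
that overlap may reflect a single causal variant influencing both
(pleiotropy, whether or not the effects are causally chained), or two
distinct causal variants that happen to be in linkage disequilibrium
(linkage). Summary-data Mendelian randomization (SMR) tests for the shared
signal using only summary statistics, and the HEIDI heterogeneity test
separates the two explanations. This package implements both, the
orchestration around them (harmonization, multiple testing, replication,
cross-tissue and mQTL/eQTL comparisons, novelty flags, multi-trait
clustering), and a generative simulator that makes every stage testable
without access to cohort data.

## The SMR test

For a probe, the instrument is the cis SNP with the smallest QTL p-value
among SNPs present in both studies, used only if that p-value clears the
per-dataset instrument threshold (defaults: 1e-10 for a well-powered blood
mQTL study, 1e-8 for a smaller fetal-brain study, 5e-8 for eQTLs). With
z1 = b_gwas/se_gwas and z2 = b_qtl/se_qtl at that SNP,

    b_SMR  = b_gwas / b_qtl
    T_SMR  = z1^2 z2^2 / (z1^2 + z2^2)        (1 df chi-square)
    se_SMR = |b_SMR| / sqrt(T_SMR)

The p-value always comes from the chi-square survival function of T_SMR,
never from a normal approximation to b_SMR/se_SMR, so deep tails are
stable. T_SMR is harmonic in the two arms and can never exceed the weaker
arm's z^2. Ties in instrument selection break by larger |z|, then smaller
genomic position, then SNP id, making runs deterministic.

## The HEIDI test

Under pleiotropy the Wald ratio b_xy = b_gwas/b_qtl is the same whichever
cis SNP serves as instrument; under linkage it varies. HEIDI takes up to
20 alternative instruments with QTL p < 1.57e-3 (|z| > 3.16) and r^2 to
the top SNP in [0.05, 0.9] (at least 3 required), forms deviations
d_i = b_xy(i) − b_xy(top), and tests whether all d_i are zero.

The covariance of the d vector comes from the first-order delta method.
For instruments i, j with LD correlation r_ij (computed from the reference
panel on the harmonized allele frame),

    cov(b_xy_i, b_xy_j) = r_ij se_g_i se_g_j / (b_q_i b_q_j)
                        + b_xy_i b_xy_j r_ij se_q_i se_q_j / (b_q_i b_q_j)

(the GWAS and QTL samples are independent, so there are no cross-study
terms), and cov(d_i, d_j) follows by including the shared top-SNP term.
We propagate the top SNP's QTL sampling uncertainty like every other
coefficient. The commonly used shortcut of freezing the top-SNP QTL effect
at its estimate drops a negative covariance component; in our Monte-Carlo
calibration that shortcut inflated se(d) enough to push the rejection rate
at perfect causal LD from the nominal 0.05 down to ~0.01 (E[stat]/k ~
0.87). With the full delta method the statistic's mean matches its degrees
of freedom and the size is correct.

The statistic is sum_i (d_i/se(d_i))^2. Under the null it is a weighted
sum of independent 1-df chi-squares with weights equal to the eigenvalues
of the correlation matrix of the standardized d vector. The tail is
evaluated by Imhof's characteristic-function inversion (mapped to a finite
interval and integrated adaptively; absolute accuracy ~1e-6), with a
fixed-seed 10^6-draw Monte-Carlo fallback when the quadrature reports an
unusable error; each result records which path produced it. If the LD
submatrix of the selected instruments has condition number above 1e8, the
most collinear alternative (largest |r| to any other selected SNP, ties by
larger QTL p) is dropped and the test retried.

An SMR-significant association is called pleiotropic when HEIDI p > 0.05,
linkage when HEIDI p <= 0.05, and remains untested when fewer than 3
alternative instruments are available.

## Harmonization and LD

All statistics are expressed on the QTL study's effect-allele frame.
Swapped alleles negate beta and complement the frequency; non-palindromic
strand flips are resolved by complementing; palindromic (A/T, C/G) SNPs
are resolved by allele frequency only when both studies' frequencies are
outside [0.3, 0.7] (freq_tol 0.2), and are otherwise excluded as
ambiguous — at eaf 0.5 a palindromic SNP is unresolvable in principle.
LD correlations are Pearson correlations of reference-panel dosages over
individuals with complete data, with a per-SNP orientation sign so that r
always refers to the harmonized alleles.

## Multiple testing and downstream analyses

The family-wise SMR threshold is alpha (0.05) divided by the number of
distinct probes that actually entered SMR in the dataset — not per trait.
This convention reproduces a multi-dataset study's distinct thresholds
from its distinct test counts (35,263 -> 1.42e-6; 5,966 -> 8.38e-6;
9,265 -> 5.40e-6 at 3 significant figures). Replication applies the same
rule within the replication dataset. Sign concordance between runs uses a
two-sided exact binomial test computed in log space, because with several
hundred concordant pairs the p-value magnitude (1e-170 and below) is at or
beyond the double-precision underflow threshold; the report carries both
the float p and log10 p. A probe-trait association is flagged novel when
no GWAS SNP with p < 5e-8 lies within 500 kb (inclusive) of the probe
position — the probe, not the instrument, anchors the distance, since
novelty is a property of the site's locus. The trait-by-probe matrix holds
t_SMR = b_SMR/se_SMR and is ordered by average-linkage hierarchical
clustering on Euclidean distances with pairwise-complete masking, rescaled
by sqrt(p/m) for m shared coordinates; missing cells are never imputed.

## The generative model

Haplotype alleles are indicator variables Z < Phi^-1(maf) of a latent
first-order autoregressive Gaussian with adjacent correlation `ld_rho`;
dosages are sums of two independent haplotypes. Thresholding attenuates
correlation (the tetrachoric map), so the generator exposes the forward
map for prediction and inverts it numerically where the dosage-scale LD
must hit a target: in the linkage scenario, the LD between the two causal
SNPs realizes `causal_r` on the dosage scale to within sampling error.
At `causal_r = 1` the second causal column is an exact copy of the first,
the regime where linkage and pleiotropy are indistinguishable by
construction.

Scenarios per locus: pleiotropy (m = b_zx g + e in the QTL sample;
y = b_xy m* + e in a disjoint GWAS sample with m* regenerated from the
same causal SNP), linkage (y = b_zy g' at the second causal SNP), and null
(y is noise). A `b_direct` parameter adds a horizontal-pleiotropy path
(direct SNP-to-phenotype effect alongside mediation) for robustness
experiments. Summary statistics are per-SNP simple linear regressions with
two-sided normal p-values floored at the smallest positive float. Samples
never overlap; overlapping ids are rejected.

Defaults and why: maf ~ U[0.05, 0.5] with causal maf >= 0.2 (instruments
need real signal at cohort-scale n); n_qtl = 639 and n_qtl2 = 665 (the
two blood-cohort sizes the design emulates), n_gwas = 20,000 (well-powered
GWAS at desk scale); b_zx = 0.6 (a strong cis-mQTL, ~13% variance
explained — the regime that clears p < 1e-10 at n = 639); b_xy = b_zy =
0.3; causal_r = 0.5; sd_m = sd_y = 1. `ld_rho = 0.95` on the latent scale
gives adjacent dosage r^2 ~ 0.7 at 5 kb SNP spacing, a realistic cis
block; with much weaker LD a 20-SNP locus rarely yields the three
alternative instruments HEIDI needs, leaving most probes untestable.

The benchmark study (`make_benchmark`) cycles 60 loci through the three
scenarios and three traits, hosts a second CpG on every fifth locus (genes
with multiple annotated probes), adds a second tissue sharing the causal
variant for 90% of probes and optionally an expression dataset driven by
the same causal variants, and writes everything — GWAS `.ma` files,
long-format QTL tables, a dosage-matrix LD reference, and a generative
truth table — as plain text, byte-identical under a fixed seed. Each
trait's GWAS is assembled from independent per-locus samples; this is
equivalent to a polygenic architecture with independent loci and is the
one deliberate departure from a single-cohort GWAS design.

What the simulator does not emulate: realistic human LD maps (no
recombination hotspots or long-range structure), array annotation,
bounded-[0,1] methylation beta values (effects are on an M-value-like
scale), case-control traits on the liability scale, or sample overlap
between studies. Passing tests therefore validate the statistics and the
pipeline logic, not robustness to those features of real data.

## Validation regimes and problem sizes

Calibration and power properties are asymptotic statements and are tested
in a well-powered regime (n_qtl 2,000-5,000, n_gwas 5,000-10,000,
1,000-2,000 replicates): SMR null type-I error within 3 Monte-Carlo SEs
of alpha; HEIDI size ~0.05 under pleiotropy; HEIDI power non-increasing
in the causal-variant LD with size recovered at r = 1. At cohort-scale
n_qtl (~639) the instrument-inclusion threshold (|z| > 3.16) removes the
weakly-correlated witnesses of the second causal variant, which lowers
HEIDI power at the low-LD end and can make the power curve non-monotone
there — a finite-sample selection effect, not a property of the test
statistic. In the same regime HEIDI is mildly anticonservative under
pleiotropy (~8% rejection at the 5% level across benchmark seeds), the
delta-method price of instruments whose QTL z-scores sit near the
inclusion threshold; this is the dominant source of missed pleiotropic
pairs in the end-to-end benchmark. The HEIDI tail computation is cross-checked against a
10^6-draw multivariate-normal oracle on 3-instrument cases, and the exact
sign test against arbitrary-precision rational arithmetic up to n = 600.

## Known limitations

Single-instrument SMR only (no multi-SNP extensions), no conditional
analysis of secondary QTL signals, no genome-build liftover or dbSNP id
resolution, no genotype imputation. Horizontal pleiotropy violates the MR
assumptions here as everywhere; the simulator can generate it, but the
test cannot detect it. Genetic-correlation conditioning of trait overlaps
is accepted as a user-supplied table and passed through, never computed.
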