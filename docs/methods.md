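# Methods

This note documents the models implemented in `flockdiv`, the defaults
and units of the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical and design
decisions taken where several reasonable choices existed. No empirical
claim is made here beyond what the test suite and `scripts/acceptance.py`
themselves compute.

## Pedigree representation and validation

A pedigree is an animal/sire/dam table with sex, birth year and flock.
Validation enforces: unique identifiers, an acyclic parent graph (Kahn
topological sort; a cycle is a hard error naming one member), no
identifier used both as sire and dam (a `allow_selfing` flag exists
solely for monoecious test constructions), and known parent birth years
strictly earlier than the offspring's. Identifiers referenced as parents
without a record of their own are appended as founder records — the
convention of flock-book extracts "traced until all ancestors are
unknown". Records are stored in topological order so every downstream
recursion is a single forward or backward pass.

Generation-depth metrics per animal: *maximum generations* (depth of the
deepest known ancestor), *complete generations* (deepest generation with
all 2^g ancestor slots known; founder = 0; note the unavoidable ±1
convention ambiguity — we count fully known ancestral generations, not
the animal's own), and *equivalent complete generations*
t = Σ_ancestors (1/2)^n counted path-wise, which equals the generation
number in a fully known pedigree. The completeness index (MacCluer) over
d generations (default 5) computes, for each parent line, C = (1/d)Σa_i
with a_i the proportion of known ancestors in generation i of that line,
and combines the two lines as 2·C_s·C_d/(C_s+C_d); a fully unknown side
gives 0.

The generation interval uses the four-path method (sire–son,
sire–daughter, dam–son, dam–daughter). A parent–offspring pair counts
only if the offspring itself has recorded progeny — the classical
"parents of selected offspring" rule, stated here explicitly because
flock-book descriptions usually leave it implicit. The overall L is the
count-weighted mean of the four path means; its standard error combines
the per-path standard errors by error propagation with the same weights
(the weighting scheme is a documented choice, as summary tables rarely
state one).

## Inbreeding and relatedness

F is computed by the Meuwissen–Luo ancestor-tracing algorithm: for
animal i, accumulate L-coefficients over its ancestor list from youngest
to oldest and evaluate 1 + F_i = Σ_j L_j² d_j, with d_j the Mendelian
sampling variance (1 for founders, 0.75 − 0.25·F_s with one known
parent, 0.5 − 0.25(F_s + F_d) with two). Memory is linear in pedigree
size; no relationship matrix is formed. The test suite checks exact
agreement (1e-10) with a brute-force tabular **A** on hundreds of random
pedigrees.

Average relatedness AR_i (twice the mean coancestry of i with every
animal, itself included) is the i-th entry of **A**·**1**/n, evaluated
indirectly through **A** = **T D T**′ as three linear passes
(Colleau-style): one backward pass for **T**′x, a diagonal scaling, one
forward pass for **T**y. The same product underlies the coancestry-based
flock FST and the pairwise-coancestry Ne estimator, so none of them ever
materialize **A**.

ΔF is computed on cohorts of width L years anchored at the earliest
birth year (the anchoring is a documented choice);
ΔF_g = (F̄_g − F̄_{g−1})/(1 − F̄_{g−1}), and a two-sided OLS test of the
slope of ΔF on cohort index reports whether the rate itself is changing.

## Probability of gene origin

Expected founder contributions are propagated down the pedigree
(C_offspring = ½C_sire + ½C_dam). Every unknown parent slot of a
non-founder becomes a distinct *phantom founder*, so contributions always
sum to one; f_e = 1/Σq_k² over all slots. The effective number of
ancestors uses the greedy marginal-contribution algorithm: each round
propagates reference-set genome weight upward, blocking paths through
already-selected ancestors (their genes are attributed), and selects the
candidate with the largest remaining weight; ties break by older birth
year then lexical id so results are reproducible. f_a = 1/Σp_i² over the
selected marginal contributions; n_50 is the smallest prefix reaching
50%. The per-animal GCI applies 1/ΣP_i² to the animal's own founder
shares. By construction f_a ≤ f_e, and the ratio grows with bottleneck
severity; both identities are property-tested.

Coancestry-based flock structure: with f = a/2 and self-pairs
f_ii,self = (1+F_i)/2 included in all means (the within-flock mean f̄ is
size-weighted; the population mean f̃ averages all ordered pairs over
the labeled animals), F_ST = (f̄ − f̃)/(1 − f̃) and Nei's minimum
distance D_ij = (f_ii + f_jj)/2 − f_ij. Inclusion of self-pairs is a
stated convention; the qualitative ordering of flocks does not depend on
it.

## Effective population size

All regressions are ordinary least squares. The seven pedigree
estimators: Ne = 1/(2b) with b the slope of F on each of the three
generation metrics; Ne = 1/(2·mean ΔF_i) with
ΔF_i = 1 − (1 − F_i)^{1/(t_i − 1)} over a reference set (animals with
t ≤ 1 excluded); Ne = 1/(2·b_year·L) from the regression of F on birth
year; Ne = −1/(2s) with s the slope of ln(1 − F̄_g) on generation; and
the pairwise-coancestry rate Δc_jk = 1 − (1 − c_jk)^{2/(g_j + g_k)} with
Ne = 1/(2·mean Δc), subsampled deterministically beyond 5·10⁶ pairs. A
non-positive rate returns a single flagged "undefined" result — every
estimator returns the identical flag on a zero-inbreeding pedigree
rather than a spurious number.

The LD method uses the mean squared genotype correlation across pairs of
SNPs on *different* chromosomes (physical linkage would otherwise
inflate r²), computed through the sample-side Gram matrix in
O(L·S²). The sample-size expectation (1/S + 3.19/S² for S ≥ 30,
0.0018 + 0.907/S + 4.44/S² below) is subtracted and the random-mating
drift relationship inverted:
Ne = (1/3 + √(1/9 − 2.76·r̂²'))/(2·r̂²') for S ≥ 30. A corrected r̂²' ≤ 0
is reported as unbounded. The confidence interval is a delete-one
jackknife over individuals (optionally capped, with a seeded subset, for
large samples). Monomorphic markers are excluded globally, not per
subset; residual missing genotypes are mean-imputed per marker.

## Genotype container and QC

Genotypes are int8 minor-allele dosages {0,1,2} with −1 missing, plus a
position-sorted marker map (1-based, PLINK convention) and sample
metadata. PED/MAP and BED/BIM/FAM (v1.9 SNP-major) readers/writers are
included; on read, dosage is normalized to count the lower-frequency
allele (ties break lexicographically).

The QC stages, in order: (1) drop genotyped animals with unknown
parentage when a pedigree is supplied; (2) drop animals with call rate
< 0.90; (3) keep autosomal markers (chromosomes 1–26 by default) with
call rate > 0.90; (4) LD-prune at r² > 0.5 to give the **full** set;
(5) remove MAF < 0.01 from full to give **reduced**; (6) remove
MAF < 0.01 from the unpruned step-3 markers to give **LD**. The report
closes arithmetically at every stage and an empty output names its
stage. Pruning uses sliding windows of 50 SNPs advancing by 5: the
most-correlated pair above threshold loses its lower-MAF member (tie:
the later position), and passes repeat until no window holds an
offending pair — a deterministic rule, documented because common tools
prune in VIF order instead; window and step are configurable since only
the r² threshold is ever stated in study reports.

## ROH detection and F_ROH

Windows of 50 SNPs advance one SNP at a time; a window is compliant with
at most 1 heterozygote and 1 missing call. Each SNP's score is the
fraction of covering windows that are compliant; SNPs scoring strictly
above 0.05 are run-eligible. Maximal eligible stretches are split where
adjacent SNPs are more than 250 kb apart and kept if they span ≥ 1 Mb
and ≥ 30 SNPs. Segment length is the bp span between its first and last
SNP. F_ROH divides the summed segment lengths by the genome span covered
by post-QC SNPs (Σ per chromosome of last − first bp), partitioned into
the 1–6, >6–12, >12–24 and >24 Mb classes whose components sum exactly
to the total. Note a geometric consequence of the window rules: a
homozygous tract shorter than the window can contain no compliant window
on a heterozygous background, so the effective minimum detectable tract
is about the window size, not `min_snps`. The detector is tested for
exact equality against a naive per-SNP enumeration.

## Homozygosity-by-descent model

A two-state (HBD / non-HBD) hidden Markov model per animal per
chromosome. Over map distance d Morgans (bp × cM/Mb at a constant rate,
default 1 cM/Mb) the chain stays with probability exp(−R·d) and
otherwise re-draws the state from the mixing prior (ρ, 1−ρ) — a
single-rate model with one segment-length scale R rather than a
multi-class age mixture; same posterior semantics, far fewer moving
parts. Emissions: the HBD state emits a heterozygote with the genotyping
error probability e and homozygotes in proportion to allele frequency;
non-HBD emits Hardy–Weinberg probabilities; missing genotypes emit 1.
Defaults R = 20/Morgan (≈5 cM expected segments), ρ = 0.05, e = 0.002;
frequencies come from the analyzed sample (founder frequencies can be
supplied in simulations) and are clipped to [1e-4, 1−1e-4] inside
emissions so drift-fixed markers cannot zero the likelihood. Scaled
forward–backward gives per-SNP posteriors (forward and backward
log-likelihoods agree to 1e-8 by construction and by test); F_HBD is the
mean posterior over all markers.

## GRM, heterozygosity, LD decay, correlations

VanRaden method 1: **G** = **ZZ**′/Σ2p(1−p) with **Z** the dosages
centered by 2p and missing values mean-imputed per marker;
F_GRM = G_ii − 1. Frequencies default to the analyzed sample, which
makes F_GRM strongly frequency-weighted — its level and even sign depend
on the frequency reference, which is why it correlates less with
segment-based estimators. H_E is the marker-mean of 2p(1−p), H_O the
observed heterozygote fraction, Hnb = H_E·2n/(2n−1),
F_IND = (H_E − H_O,i)/H_E per animal (per-individual reading of the
heterozygosity deficit), F_IS = 1 − H_O/Hnb per group on that group's
own frequencies. LD decay bins within-chromosome pairwise r² by physical
distance and reports the adjacent-pair mean distance and r² separately.
Estimator correlations are plain Pearson on complete rows; zero-variance
columns are reported as undefined rather than silently NaN.

## Genomic population structure

Pairwise flock FST is Weir–Cockerham θ: per-locus variance components
(a, b, c) for the pair, combined across loci as Σa/Σ(a+b+c)
(ratio-of-sums, not mean-of-ratios), loci without calls in either flock
dropping out. Negative θ estimates are retained. Confidence intervals
are percentile bootstrap over loci (default 100 resamples); flocks with
fewer than two genotyped animals are excluded with a warning. The
overall mean is the unweighted mean of pairwise estimates
(size-weighting is available, since either convention is defensible).
PCA eigendecomposes the double-centered VanRaden GRM of per-flock
subsamples (at most 30 per flock per replicate, smaller flocks always
fully included), equivalent to variance-standardized genotype PCA;
scores are eigenvectors scaled by √eigenvalue (zero column means by
construction) and percent variance is each eigenvalue over the sum of
non-negative eigenvalues.

## Synthetic data: what it emulates and what it does not

The litter-based generator emulates a flock-book population: several
flocks, per-dam litters, a progeny cap per sire (relaxed only if the cap
saturates a generation), optional between-flock ram migration, a
repeated full-sib `inbred_line` scheme, and birth years at
generation × span (default 3 y) with ±1 y jitter (only when the span
permits it without violating parent<offspring ordering). The
Wright–Fisher helper provides the idealized discrete-generation
random-mating population that effective-size theory assumes. Gene
dropping draws founder haplotypes i.i.d. per locus with allele frequency
from Beta(0.5, 0.5) truncated to [0.01, 0.5] — the U-shaped-then-filtered
spectrum of a medium-density array — recombines each meiosis under the
Haldane (no-interference) map, and carries founder-haplotype labels so
the per-animal autozygous fraction is exact. Genotyping error flips one
allele symmetrically; error and missingness are applied after the truth
is recorded.

Not emulated: selection on phenotypes, mutation, sex chromosomes,
per-chromosome linkage-map variation, linkage disequilibrium among
founder haplotypes, and real flock-size distributions (no public
description of those exists, so the defaults are plausible free
parameters, not calibrated claims). Consequently, passing tests
demonstrate correctness of the estimators under drift, recombination and
pedigree structure — not robustness to ascertainment bias or founder LD
in real array data.

Default validation problem sizes, chosen to exercise the estimators at
desk scale: random-pedigree oracles at ≤300 animals; gene-dropping
consistency at 200 replicate genomes; estimator-vs-truth correlations at
200 animals × 2,000 SNPs; effective-size recovery at N = 50 over 10
generations × 20 replicates; drift-FST at Ne = 100, t = 10, 1,000 SNPs
× 10 replicates; the acceptance script at ≈5,800 pedigree animals with
≈1,450 genotyped at 2,000 SNPs.

## Known limitations

* The marginal-ancestor algorithm is the standard greedy procedure; it
  does not guarantee the globally optimal ancestor set (no efficient
  exact algorithm exists), only deterministic, well-defined marginals.
* The LD-method jackknife assumes approximately independent individual
  contributions; with strong family structure the interval is
  optimistic.
* F_GRM with sample frequencies can be strongly negative for animals
  carrying rare-allele heterozygosity; this is a property of the
  estimator, not a bug, and is why the frequency reference is
  configurable.
* The HBD model's single rate R trades the age partition of multi-class
  models for robustness; F_HBD totals agree closely with segment-based
  estimates, but no historic-vs-recent decomposition is offered.
* Bootstrap-over-loci FST intervals treat loci as exchangeable; linked
  loci make them slightly narrow.
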