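# Methods

## The model

The unit of analysis is the star allele: a haplotype of the OCT1 coding
region identified with the set of amino-acid variants it carries. The
reference allele `*1` carries none; 15 further major alleles each carry one
or two of the 21 variants the pipeline tracks; sub-alleles (`*1A`, `*2A`,
…) add activity-neutral variants to a major allele's functional core. The
in-frame deletion of codon 420 (Met420del) is treated as one biallelic
marker, exactly like a substitution — its 3-bp length never enters any
statistic. This matches how the variant segregates (a single segregating
unit) and keeps every per-site estimator well defined.

Individuals are diploid, so each carries an ordered pair of alleles (a
diplotype). The carrier phenotype is the number of *fully active* alleles
(0, 1 or 2), with the active set {`*1`, `*8`, `*9`} under the default
classification thresholds.

## Activity classification

Transport activity per allele and substrate is expressed as percent of
`*1`. The rules, applied with strict inequalities:

* **major vs sub**: major when some substrate is < 50 % or > 150 %
  ("more than 50 % decrease or increase");
* **gain**: some substrate > 150 % and none < 50 %;
* **substrate-wide complete loss**: all substrates at or below a 5 % floor
  (the floor absorbs assay noise in a matrix transcribed from published bar
  charts);
* **substrate-specific loss**: some substrate < 50 % while another retains
  > 90 %;
* **substrate-wide partial loss**: the remaining loss pattern;
* **phenotype inactivity**: some substrate < 35 % of reference — i.e. a
  more than 65 % reduction — unless the allele is in the configured active
  set. With the shipped matrix the derived active set equals the configured
  default {`*1`, `*8`, `*9`}, a consistency check the tests assert.

Sub-alleles inherit their parent's mode (they are defined as activity-
neutral extensions). Variants are classified LOF / non-LOF from the
single-variant allele that carries them; the three variants never observed
alone (Cys88Arg, Arg206Cys, Gly465Arg — each rides with Met420del) take
shipped override labels, since no single-variant measurement exists.

## Phasing

Haplotype frequencies are estimated by EM on the multinomial
Hardy–Weinberg likelihood: an individual's genotype contributes the sum of
2·f_h1·f_h2 (f_h² for homotypes) over all compatible haplotype pairs. The
ambiguous phase space is enumerated per individual (2^(h−1) pairs for h
heterozygous sites), which caps the usable sites at 25 — far above the
~20 coding sites of a single pharmacogene. EM's log-likelihood is
non-decreasing (asserted in tests); random Dirichlet restarts plus a
repeated-seed protocol (default seeds 2, 1536, 2936, 3123, 4957, 5283,
6757, 7992, 8633, 9045) detect label-switching saddles and report the
fraction of individuals whose diplotype call is seed-stable. Bayesian
coalescent-prior phasing is deliberately out of scope: for a single short
gene with star-shaped haplotype structure, the EM maximum-likelihood
solution and coalescent-prior phasing coincide in practice, and the
multi-seed agreement report plays the same diagnostic role. Individuals
missing a genotype at any site are excluded from their group's phasing.

Diplotype assignment maximizes f_h1·f_h2 (×2 when heterotypic) over
compatible pairs; exact ties are broken lexicographically by haplotype
bitmask and flagged; a genotype with zero probability under the estimated
frequencies gets a uniform tie-break and a flag.

## Diversity statistics

For a sample of n chromosomes scored at biallelic sites with alternate
counts k (0 < k < n segregating), normalized by coding length L:

* π = [n/(n−1)] Σ 2p(1−p) / L, the unbiased mean pairwise difference per
  site (equal to the brute-force average over all C(n,2) pairs, an
  equivalence the tests assert on random instances);
* θ_W = S / (a₁L), a₁ = Σ_{i<n} 1/i;
* Tajima's D with the 1989 constants; D is independent of L.

L defaults to 1665 bp — a 554-codon coding sequence plus stop codon. The
source survey says only that π and θ were "normalized to the size of the
coding region", so L is a configuration knob and every normalized output
records the L used; region ranking, ratios and D are unaffected by L.

Sites are stratified by the functional class of their variant, giving
π_LOF, π_non-LOF and their ratio per geographic region. Admixed panels are
excluded from all region-level statistics. D's p-value comes from a
fixed-S neutral null: Kingman genealogies are simulated for matched n, S
mutations dropped proportionally to branch length, and D recomputed per
replicate. The default alternative in the stratified table is one-sided
"less" (a deficit of diversity, the direction purifying selection
predicts and the convention under which the survey's significance stars
are quoted); a two-sided |D| comparison and the opposite tail are
available. The sampler is validated against the expected total tree
length 2Σ1/i, the exact 1/i frequency-spectrum law under Poisson mutation
numbers, and an msprime genealogy oracle.

## AMOVA and Φ statistics

Molecular variance is decomposed from squared pairwise distances using
SSD(group) = Σ_{i,j} d²(i,j) / 2n, with haplotype distance = number of
differing variant sites, or squared 0/1/2 code difference for the
phenotype analysis (individuals, not chromosomes, are the units there,
matching the coding). Variance components use the standard hierarchical
expectations for unequal sample sizes; negative components are truncated
to zero (flagged) before percentages and reported Φ values are formed.
Permutation p-values permute chromosomes among populations (Φ_ST),
chromosomes within regions (Φ_SC), or whole populations among regions
(Φ_CT); the permuted comparisons use the *untruncated* statistics, since
truncation would pile permuted values onto the observed one and make the
p-values needlessly conservative. P-values use the (hits+1)/(perms+1)
convention. A region with a single population is allowed in three-level
mode and simply contributes no among-population degrees of freedom.

## Exact multinomial outlier test

The probability that a small population's 0/1/2-active composition arose
from a reference carrier distribution is the multinomial point mass
n!/(∏kᵢ!)·∏pᵢ^kᵢ. The point mass is the default (it reproduces the
survey's printed chance probabilities: the European split 53/38/8 gives
6.4×10⁻⁸ for the Surui composition; HWE from the Brahui active-allele
frequency 0.62 gives 4.9×10⁻⁶); a conservative tail — the summed mass of
all outcomes at most as probable — is available by exact enumeration up to
n = 20. Carrier distributions under HWE are (p², 2pq, q²).

## Synthetic data

The simulator draws each individual's two alleles from its population's
allele-frequency vector — independently with probability 1−F, identical by
descent with probability F — then expands alleles to variant sets and
emits unphased 0/1/2 counts, with optional symmetric per-site flip error.
This is exactly the Hardy–Weinberg sampling model the frequency-based
analyses invoke, so simulated panels are the matched test bed for every
stage; truth files carry the drawn diplotypes and realized counts. What it
does *not* emulate: linkage to flanking variation, genotype missingness
patterns, allele-frequency uncertainty, or within-population substructure
— so passing recovery tests demonstrates correctness of the pipeline's
inference under its own model, not robustness to violations of it.
World-scale panels mirror the packaged survey's population sizes and
frequencies; alleles with unknown composition (`*16` by default) are
dropped with renormalization and a log entry.

## Packaged fixtures and their provenance

Per-population major-allele frequencies, population sizes and region
labels are transcribed at printed precision from the survey's summary
table; recomputed region means therefore match the printed ones to one
unit in the last printed digit. Three printed rows are internally
inconsistent (percentages summing slightly above 100); they are kept as
printed, and probability vectors renormalize. The activity matrix and the
sub-allele compositions are approximate reconstructions (flagged as such)
that reproduce every qualitative classification statement; the per-
population frequencies of the five activity-neutral variants that ride
only on sub-alleles are a synthetic regional table guided by the survey's
qualitative descriptions (most frequent: Met408Val; Pro341Leu enriched in
East Asia; Arg342His African, absent from Europe and America). All
fixtures are sha256-verified on load.

Because of those approximate inputs, the stratified-diversity and
structure results are validated at the level of ranks, signs and
directions (East Asia & Oceania has the smallest π_LOF and π ratio with
significantly negative D; America the reverse; phenotype-level
among-region variance exceeds haplotype-level; the America–East Asia pair
is the most diverged, Φ_ST ≈ 0.72), while purely arithmetic quantities
(frequency summaries, pooled variant frequencies, multinomial
probabilities) are validated against the printed numbers directly.

## Problem sizes and numerical choices

The acceptance runs use the survey's own sample sizes (62 non-admixed
populations, 3,688 chromosomes) for simulated panels, 10,000 replicates
for the neutral D null and 10,000 permutations for AMOVA; phasing-recovery
checks use 500 individuals per population over the 10 default seeds. EM
converges at a 1e-10 log-likelihood gain with a 2,000-iteration cap.
Frequencies-to-counts conversion rounds percent × 2N to the nearest
integer. Known limitations: the pairwise Φ_ST permutation loop is
quadratic in the number of groups; the exact multinomial tail is
enumeration-bound at n = 20; and the EM phasing cap of 25 sites precludes
genome-scale use — all comfortable margins for single-gene panels.
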