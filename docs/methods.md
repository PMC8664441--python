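# Methods

## Setting

Two taxa (here called Bv and Bb after the *Bombina* cross that motivated
the design) are crossed: one F0 pair (Bv grandsire × Bb granddam), an F1
full-sib intercross with one father and one mother per F2 family, and F2
offspring. Each enrichment target ("locus", a few hundred bp) is treated
as non-recombining; the quantity of interest per sample and locus is the
ancestry diplotype BbHOM / HET / BvHOM. Input is the per-sample 6 × *n*
matrix of read counts over reference positions (A, C, G, T, N, DEL),
parsed from the PoPoolation2 sync dialect (column order A:T:C:G:N:del,
remapped internally to alphabetical order; sync positions are 1-based,
internal columns 0-based). Insertions relative to the reference are not
representable in this matrix.

## Polarization

Grandparental count matrices are converted to column frequencies
(zero-depth columns stay zero). Each column *i* is weighted by
1 − Sig(*i*): Sig(*i*) is the upper-tail chi-square p-value of the G-test
G = 2(lnL_separate − lnL_pooled) between the two grandparents' count
vectors, with df = (number of states in the pooled counts) − 1. Columns
with no testable contrast (either grandparent unobserved, or one pooled
state) get weight 0. The signed, weighted difference of the frequency
matrices is the polarized matrix **M**ₚ; every entry lies in [−1, 1].
Sig is treated as a p-value; the chi-square reference is an approximation
adequate at capture depths (~150×), and no continuity correction is
applied. A locus is flagged `no_variants` when no column's test is
decisive (p < 10⁻⁶): scattered sequencing errors produce mid-range
weights but cannot reach decisive significance at realistic depth.

Sample scores divide the positive and negative parts of counts ⊙ **M**ₚ
by the number of informative (weight > 0) columns, so scores scale with
coverage but are comparable across loci of different lengths. N-state
reads participate in frequencies and scores (their depth affects column
totals) but N is never a haplotype state.

## Clustering

Samples are clustered on their score angle (0° = pure Bv axis), weighted
by score radius; samples below 5% of the locus's maximum radius are
excluded from cluster statistics but still diplotyped. The partition is
the optimal weighted 1-D k-means (dynamic programming) for each k in
1..6; k is selected by a BIC under a shared-variance Gaussian model,
subject to a separation criterion: adjacent cluster means must differ by
at least 5 pooled within-cluster standard deviations *and* 8° absolute.
The relative part prevents shattering one noisy blob (splitting a unimodal
cluster yields means ~1.6 sd apart); the absolute part encodes the
geometry that distinct diplotype groups of one haplotype pair sit tens of
degrees apart, so groups closer than a few degrees — e.g. carriers of a
dominant sex-limited haplotype whose other allele barely moves them —
belong together for every downstream purpose. More than three clusters
form when more than two haplotypes segregate.

**M**ₚ is then rebuilt once from the pooled counts of the two clusters
nearest 0° and 90° (ties broken toward larger pooled depth), with the
G-test weights recomputed on these high-coverage pools, followed by one
re-scoring and re-clustering pass. The update is accepted only if the
re-clustering keeps at least as many groups as before: a strongly
diverged within-taxon haplotype can otherwise scramble the updated
polarization (the update is meant to sharpen, not reshape, the partition).

## Consensus haplotypes and positional QC

Each cluster's pooled counts are reduced to a strict-majority consensus:
a column is called for the state carried by more than half its reads,
provided the lead over 50% exceeds 3 binomial standard deviations;
ties, N-majorities, zero depth, and sub-threshold leads give NOCALL. The
margin matters in deep pools that mix two haplotypes 50:50 — sampling
noise would otherwise assign arbitrary states with high apparent depth.

Overmerged reads (mis-mapped reads from elsewhere in a repetitive genome)
hit *every* sample at a locus, so they are visible in the pooled axis
clusters, where sequencing error alone predicts near-purity: any column
whose minor-state fraction exceeds 0.2 in an axis pool (pool accepted only
if its cluster is within 37° of its axis, i.e. clearly not the
heterozygote group) is masked from the likelihood model. This positional
QC is what makes the calls robust when contamination happens to coincide
with a diagnostic position; contamination at non-diagnostic columns
cancels between the three diplotype models and needs no special handling.

## Mendelian likelihood

Given a taxon haplotype pair (columns where either haplotype is NOCALL are
masked), a sample's counts have per-column expected distribution
π(x) = Σ_h μ(h)[(1 − ε) if x = h else ε/5] with μ a point mass on the
haplotype state for a homozygote and the α : (1 − α) mixture of the two
taxon states for a heterozygote. ε defaults to 0.005 (configurable). The
α-profile log-likelihood reduces to
C_v ln(αp + (1−α)q) + C_b ln(αq + (1−α)p) + const
(p = 1 − ε, q = ε/5; C_v, C_b the read totals on the variegata and
bombina states over differing columns), a concave function whose maximizer
is computed in closed form and clipped to the admixture bounds.

The bounds are **[0.1, 0.9]**: enrichment bias shifts a true
heterozygote's variegata read fraction moderately (the baits come from one
taxon; the observed bias is ~0.55), and leaving α free to approach 0 or 1
would let the HET model nest both homozygote models, destroying the
identifiability of the three diplotypes — homozygote supports would then
be capped at ~10⁻³ ln units per matching read regardless of coverage.

Candidate pairs are all distinct unordered pairs of cluster consensuses
(candidates that agree on every jointly called position and call no extra
position are collapsed first, keeping the deeper pool's version); the
member nearer 0° is taken as the variegata haplotype, angle ties trying
both orientations. The ML pair maximizes the summed best-state
ln-likelihood over all samples with data; `pair_support` is the margin
over the runner-up. Per-sample calls are the argmax state with support =
best − second-best ln-likelihood; samples with no reads on unmasked
columns are MISSING (`low_depth`). Each taxon haplotype is then refined
once from the pooled counts of all samples called homozygous for it, and
all samples are recalled once. Loci whose F0/F1 calls violate the expected
(BvHOM, BbHOM, HET, HET, HET) pattern are flagged — not dropped — and form
the queue for the manual-annotation rescoring path, which reruns the same
likelihood restricted to whitelisted (position, Bv-state, Bb-state)
triples.

## Segregation QC and bin reduction

Per locus and F2 family, non-missing calls are tested against 1:2:1
(χ², df 2). Two thresholds: per-test α/24 (Bonferroni over chromosome
arms; with df 2 the critical value is −2 ln(α/24) in closed form) and
Benjamini–Hochberg step-up across all locus × family p-values. For the
reduced map, loci above the Bonferroni threshold are removed; within each
(LG, cM) bin, pairwise diplotype differences are counted over F2s
(pairs with a MISSING member skipped); while any pair differs at more
than 3 individuals the locus with the largest summed differences is
removed greedily (ties broken by locus id); one survivor is picked
uniformly at random under the run seed.

## Sex-determining region

b = (N[male BbHOM] + N[female BvHOM]) / N[HOM] over sexed F2
(uncertain/unknown excluded); its null is 0.5 and its exact one-sided
binomial lower-tail p-value is reported (the SD signal is exclusively a
deficit). The scan reports the global b minimum and the contiguous cM
interval around it with b ≤ 0.05 (configurable), with significance stated
conservatively as the minimum locus's p alone.

For heterogamety, clusters at each locus are ranked by male proportion
p_m; *pMaleInMaleClusters* is the mean p_m of the minimal descending
prefix jointly holding >50% of all males (female statistic mirrored). A
locus is an outlier only with the full sex-limited-haplotype signature:
statistic > 0.9, the minimal prefix is a *single* cluster, and that
cluster sits off the axes (15°–75°). The last two conditions come from
the biology: a diverged Y (or W) dominates its carriers' read signal and
gathers nearly all of one sex into one obligate-heterozygote (off-axis)
cluster, while the other sex splits by its ordinary allele; conversely,
the spuriously sex-pure clusters that arise at or near the SD region by
linkage alone are the on-axis homozygote clusters, one of which holds a
bare majority of a sex about half the time by sampling noise. Male-side
outliers with none on the female side give the XY verdict; the mirror
gives ZW; anything else is inconclusive. Detection requires the carrier
cluster to actually merge — when the carriers split by their other allele
the locus yields "inconclusive", never the wrong system.

## Simulator

The generator draws founder haplotypes per locus with divergence d_xy
lognormal (mean 0.0202, mode 0.013; occasional loci draw zero differences
and are legitimately undiagnosable), mean length 673 bp, and places loci
on 12 linkage groups of 132 cM. Transmission is Mendelian with inter-locus
recombination from the inverse Kosambi map r = tanh(2d)/2, no
interference. Reads: Poisson depth around 147× × a lognormal per-sample
factor (sd 0.25) × a trapezoid profile (flat over the central 250 bp bait
span, decaying linearly to 10% at the termini); heterozygotes draw
variegata-copy reads with probability 0.55 (capture bias); errors flip
reads to a uniform other state at rate 0.005; overmerging adds
genotype-independent paralog reads to all samples at 15% of positions of
20% of loci at half the local depth. An optional SD locus assigns sex by
transmission (XY: the F1 father's variegata-labeled copy is the Y); a
diverged sex-limited haplotype (default divergence 0.15) can be placed
5 cM from the SD locus, optionally at a target where the taxa are
otherwise identical (`sd_sex_hap_dxy = 0`) — the cleanest real-world
signature, since such a locus is invisible to ordinary diplotyping but
glows in the cluster-sex scan. The overmerge position/depth fractions and
the per-sample coverage spread are plausible choices, not measured
values. A single integer seed determines all output byte-for-byte.

What the simulations do not emulate: indel/structural variation (real
loci with whole-locus deletions go through the manual rescore path),
mapping artifacts beyond additive contamination, crossover interference,
within-taxon standing variation other than the sex-limited haplotype, and
recombination within a locus. Passing tests therefore establish the
statistical machinery under the stated noise model, not performance on
artifacts outside it.

## Problem sizes and numerical choices

The test suite runs scenarios from 40 to 162 F2 and 2–20 loci (the noise
benchmark uses the full 162-F2, 147× conditions at 20 loci), and the
brute-force likelihood oracle checks 50 random small loci on an α grid of
step 10⁻⁴. Supports are finite because ε > 0; the closed-form α maximizer
agrees with the grid to <10⁻⁶ ln units. Degenerate inputs: zero-depth
columns are legal everywhere; all-masked likelihoods raise and the caller
records MISSING; loci with a single distinct candidate haplotype are
flagged `unresolvable`. MISSING calls are written to Lep-MAP3 as the
all-equal (uninformative) vector — the file format offers no explicit
missing code, and the uniform vector is how an absent observation enters
a likelihood-based mapper.
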