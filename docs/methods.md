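# Methods

This note documents the statistical models and procedures implemented in
`ssrpop`, the parameters that matter, the design choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Data model

SSR (microsatellite) genotypes are co-dominant integer fragment sizes.
A diploid call is stored as two sorted sizes (homozygotes as a duplicated
size, so every scored diploid call contributes exactly two gene copies —
this keeps all frequency arithmetic uniform); a missing call is empty; a
putative triploid call carries three sizes. Wide and long CSV layouts and
a Structure-format export (two rows per individual, −9 missing) are
supported; both CSV layouts round-trip losslessly for any table in which
no accession and no locus is entirely missing.

### Cross-laboratory harmonization

Fragment-size offsets between genotyping platforms are integer and
constant per locus. The harmonization utility therefore estimates each
locus offset as the **mode** of the pairwise size differences
(reference − other) over all matched allele pairs of shared reference
accessions, applies it to the whole table, and flags loci whose observed
differences are not constant (`consistent=False`) for manual review. The
mode, not the mean, is used because a single mis-scored shared accession
should not shift the estimate. Harmonization is idempotent.

## Duplicate resolution and ploidy screening

Two accessions are duplicates when, over loci diploid-scored in both
(at least `min_shared_loci`, default 12 of 16), no locus shows fully
disjoint genotypes and at most two loci differ by a single allele copy.
"One allelic difference" is interpreted as a multiset intersection of
size 1 — the signature of a single mutation or scoring slip; a locus
where the two genotypes share no copy disqualifies the pair outright.
Duplicate groups are the **connected components** of this relation
(transitive closure): group codes imply partition semantics, so chained
near-matches collapse even when distant members exceed the pairwise
tolerance. The representative is the lexicographically smallest member,
for determinism. Grouping is verified against a brute-force union-find
oracle in the tests.

An accession is a putative triploid when ≥ 3 loci show three distinct
alleles. Triploids are excluded from grouping by default (a switch
compares them on their diploid loci instead) and are removed, together
with accessions missing more than `max_missing_loci` (default 4) calls,
before any diploid statistics.

## Diversity statistics

Per locus: allele count N_A; rare alleles N_B (frequency strictly below
the 5 % threshold, with a secondary 1 % report available); effective
alleles N_E = 1/Σp²; observed heterozygosity Ho; expected heterozygosity
with Nei's small-sample correction He = (1 − Σp²)·N/(N−1) on N gene
copies (the uncorrected gene diversity is also exposed, since published
tables do not always state which convention they use). Probability of
identity per locus is

    P_ID = Σᵢ pᵢ⁴ + Σᵢ<ⱼ (2 pᵢ pⱼ)²,

the probability that two unrelated Hardy–Weinberg genotypes coincide;
the cumulative P_ID is the product over (unlinked) loci. Allelic richness
uses hypergeometric rarefaction on gene copies,
A_R(g) = Σᵢ [1 − C(N−Nᵢ, g)/C(N, g)], scaled to the smallest group when
groups are compared. Private alleles occur in exactly one group of a
partition; unique alleles are carried by exactly one accession.

Frequent-allele composition across groups is compared per locus by a
Pearson chi-square on copy counts, with alleles at or below the frequent
threshold pooled into an "other" column; when expected counts still fall
below 1 the asymptotic p-value is replaced by a seeded Monte-Carlo
permutation p-value (10,000 permutations by default).

## Admixture model

The clustering model is the standard Bayesian admixture model with
correlated allele frequencies. Each individual i has ancestry qᵢ over K
clusters with a symmetric Dirichlet(α) prior; each allele copy has a
latent origin z; cluster frequencies P_k,l follow the F-model prior
Dirichlet(p_anc,l · (1−F_k)/F_k) around inferred ancestral frequencies
p_anc (Dirichlet(λ=1) prior). Updates per sweep:

* z | q, P and q | z and P | z — Gibbs (categorical / Dirichlet);
* α — random-walk Metropolis, uniform step 0.025, prior U(0, 10);
* F_k — Gaussian random-walk Metropolis (step 0.01), prior
  Gamma(mean 0.01, sd 0.05), the conventional drift prior;
* p_anc — one symmetric two-allele mass-transfer Metropolis move per
  locus per sweep (step 0.02).

Numerical choices: sampled frequencies are floored at 1e−9 before
normalization so that log-frequency terms stay finite; missing allele
copies are simply absent from the likelihood; argmax ties in assignment
break toward the lowest cluster index and are logged. The data
log-likelihood is accumulated every sweep at no extra cost (it is the
normalizing sum of the z-update), and the model evidence is estimated
the conventional way as lnP(D) = mean(lnL) − var(lnL)/2 over post-burn-in
samples.

Two deliberate departures from textbook initialization, both affecting
only convergence speed, not the stationary distribution:

* **F starts at 0.05**, not at the prior mean 0.01. Starting at 0.01
  pins every cluster to the ancestral vector (prior concentration
  ≈ 99·p_anc) and short chains take thousands of sweeps to escape the
  symmetric no-structure mode.
* **Warm start for z**: individuals are pre-clustered by k-means (with a
  per-run random initialization) on the top principal components of the
  allele-dosage matrix, and allele-copy origins start from those labels.
  Desk-scale chains then reach a stationary trace within the 2,000-sweep
  burn-in.

Chain-length profiles: *desk* (2,000 burn-in + 10,000 iterations, 3
replicate runs) is the default and is what all tests and the acceptance
script use; *full* (200,000 + 500,000, 10 runs) matches production-scale
germplasm practice and is never exercised by the test suite.

### Replicate alignment and model choice

Replicate runs are aligned to the first run by the column permutation
minimizing the Frobenius distance between Q matrices. Because that cost
decomposes over columns, the Hungarian algorithm finds the exact optimum
for any K — an exhaustive K! search would be equivalent but slower.
Evanno's ΔK = |mean L(K+1) − 2·mean L(K) + mean L(K−1)| / sd(L(K)) is
computed over the swept K values and its argmax (interior K only) is the
selected K; the full table is exposed so secondary peaks can be examined,
but no automatic secondary-peak decision is made. Membership thresholds
follow germplasm convention: max q ≥ 0.80 is a strong assignment, and
max q < 0.55 marks unambiguous admixture.

### Nested substructure

Each top-level group (every individual joins its argmax group, admixed
ones included, matching practice where all genotypes are re-analyzed) is
re-run independently with its own K sweep and ΔK choice; subgroups are
labelled K2.1, K2.3, … Groups smaller than 25 members are skipped with a
warning, keeping ΔK's run-to-run variance meaningful.

## Differentiation

Pairwise F_ST is the multi-allelic Weir–Cockerham θ: variance components
a, b, c are summed over alleles and loci before the ratio is taken
(ratio of sums). AMOVA decomposes allelic variance among vs within
groups at the gene-copy level using the infinite-allele 0/1 mismatch
distance — the usual non-stepwise treatment of SSR data; stepwise
(R_ST-like) distances are out of scope. Negative among-group components
are reported as computed with the percentage clamped at 0. Significance
for both comes from permuting whole individuals (both copies together)
between groups, p = (#{perm ≥ obs} + 1)/(n_perm + 1), default 999
permutations. Null permutation p-values are verified uniform by a KS
test in the acceptance suite, and θ is verified to recover a simulated
Balding–Nichols F of 0.10 within ±0.02.

## Ordination and trees

The simple-matching dissimilarity between diploid profiles is
1 − mean_l (shared copies at l)/2 over loci scored in both (multiset
overlap over ploidy — the standard diploid convention; cruder 0/1
genotype matching was rejected). Pairs with zero comparable loci raise
an error rather than silently propagating NAs. PCoA is classical metric
scaling (eigendecomposition of the double-centered −d²/2 matrix);
negative eigenvalues are *reported, not corrected* — an optional
Cailliez correction is available but off by default, because silent
correction hides non-Euclidean structure. Neighbor joining is the
Saitou–Nei agglomeration (delegated to scikit-bio); negative branch
lengths are clamped to zero only in the exported Newick, with the raw
tree retained. NJ reconstructs additive matrices exactly, which the
tests verify against independently generated random trees.

## Parentage

Only complete two-parent trios are inferred; single-parent inference is
deliberately excluded as too speculative at 16 loci. The per-locus
likelihood ratio compares Mendelian segregation from a candidate pair
with a random Hardy–Weinberg draw. The error model is per transmitted
allele copy: with probability e (default 0.01) the copy is replaced by a
random draw from the population frequencies, so the transmission
probability for allele a from parent P is (1−e)·M_P(a) + e·p(a) with
M_P the Mendelian share. LOD sums the log ratios over loci jointly
scored in all three members. A trio's mismatch count is its number of
Mendelian-impossible loci at e = 0; at most one mismatch is tolerated in
any reported trio. Candidate pairs are pre-filtered by a necessary
sharing condition (a parent must share ≥ 1 allele with the offspring at
all but ≤ 1 loci) to keep enumeration near-linear in practice.

Delta is the LOD gap between the best and second-best surviving pair
(the best LOD itself when no competitor survives, clamped at 0). The
acceptance threshold is calibrated by simulation: offspring are
generated from random parent pairs drawn from the observed unique
genotypes (each true parent present in the candidate pool with
probability 0.9), the scan is run on each, and the threshold is the
smallest Delta at which the fraction of correct assignments above it
reaches the requested confidence (95 %). Clones of the offspring
(identical profiles) are excluded as candidate parents. Parent pairs are
unordered and reported sorted by id, since co-dominant markers cannot
assign parental sex.

## Synthetic-data generator

The generator emulates the statistical structure of a multi-collection
apple-type germplasm dataset, with all rates chosen to mirror the
regimes reported for such collections:

* 16 loci, 8–30 alleles each on a 2-bp ladder, ancestral frequencies
  from a symmetric Dirichlet(0.5) — skewed, so most alleles are rare and
  mean He sits near 0.8 (verified band 0.75–0.85);
* K genepools by Balding–Nichols drift (group frequencies
  ~ Dirichlet(p_anc(1−F)/F)), default F = 0.05, the weak-differentiation
  regime; optional nested subgroups by a second drift level;
* ancestry per individual ~ Dirichlet with weight 8 on the home pool and
  0.4 elsewhere, giving a majority of near-pure individuals plus a
  visible admixed fringe;
* clone groups of size 2–9, each copy perturbed at 0–2 loci by moving
  one allele copy a single ladder step — guaranteed to stay inside the
  duplicate tolerance, so planted groups are exactly recoverable;
* triploids (default 8 % when enabled) gain a third distinct allele at
  ≥ 3 heterozygous loci;
* trio offspring receive one Mendelian copy per parent with the same
  per-copy error model used by the parentage likelihood.

Every generator is a pure function of (config, seed). What it does *not*
emulate: linkage between loci (the real panels span many linkage
groups), mutation-history realism (no stepwise-mutation coalescent),
collection-specific ascertainment, null alleles, and scoring error on
the base (non-clone, non-offspring) genotypes. Passing tests therefore
demonstrate correctness of the algorithms under the stated statistical
structure, not robustness to every artifact of real fragment data.

## Problem sizes used in tests and the acceptance script

Admixture recovery runs the desk profile on 150 individuals × 16 loci
with K swept 1–6 (18 chains, ≈ 5 minutes); differentiation recovery uses
20 replicates of 2 × 100 individuals × 20 loci plus 200 null replicates
at 199 permutations; parentage uses 50 planted trios among ≈ 500 unique
genotypes with a 3,000-offspring calibration, and 10–20 null replicates
with 800-offspring calibrations. These sizes were chosen as the smallest
at which the recovery targets are comfortably identifiable.

## Known limitations

* The admixture sampler updates one ancestral-frequency pair per locus
  per sweep; for panels with hundreds of alleles per locus, p_anc mixing
  would become the bottleneck.
* lnP(D) is the mean-minus-half-variance evidence surrogate; it is only
  as good as trace stationarity, which the warm start provides at desk
  scale but which should be checked (acceptance rates and traces are
  exposed) for other data regimes.
* AMOVA is strictly two-level (among/within); three-level nested designs
  are out of scope.
* Exact replication of any published collection's numbers is not claimed
  anywhere: raw genotype matrices for such studies are typically not
  deposited, and all verification here is oracle- and simulation-based.
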