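# Methods

## Biological model

One sexual cycle of *Zymoseptoria tritici* is modelled as: (i) assignment of
female/male roles to the two haploid parents, (ii) zygote formation with the
female's mitochondria, (iii) an optional mechanism-specific amplification of
supernumerary chromosomes, (iv) meiosis I (homolog disjunction), meiosis II
(chromatid disjunction), and (v) one post-meiotic mitosis that duplicates
each of the four meiotic products into a pair of identical twin ascospores.
An ascus therefore holds an octad: eight spores, four twin pairs. Core
(essential) chromosomes are represented only through six segregating PCR
markers that always split 4:4; supernumerary chromosomes chr14–chr21 are
tracked as per-parent copy numbers in every spore.

### Sexual roles and mitochondria

The data motivating the role model show only a monotone effect — the parent
inoculated at lower density tends to take the female role — without a
functional form. We adopt the simplest ratio model with one shape parameter,

P(parent 1 female) = d₂ᵃ / (d₁ᵃ + d₂ᵃ),  a > 0 (default 1),

which is symmetric at equal densities and monotone in the density ratio.
All spores of an octad inherit the female parent's mitochondrial haplotype
(uniparental inheritance); this is what lets downstream statistics condition
on "which parent was female" from spore genotypes alone.

### Transmission mechanisms

* **mendelian** — paired homologs disjoin at meiosis I; an unpaired
  chromosome migrates to a uniformly random pole. Exactly 4 of 8 spores
  carry each parental homolog and each unpaired chromosome (4:4 and 4:0).
* **female_drive** — at the start of meiosis each unpaired chromosome
  inherited from the female is duplicated with per-chromosome penetrance
  (default 1.0; chr14 is the documented exception and is modelled simply as
  penetrance 0, no mechanistic account attempted). The two copies behave as
  a pair, so all eight spores inherit the chromosome (8:0).
* **premeiotic_amplification** — every female supernumerary chromosome is
  duplicated before karyogamy. With the default copy-loss step (extra copies
  of paired chromosomes are lost again before meiosis I) the outcome is
  indistinguishable from `female_drive`; with `premeiotic_copy_loss=False`
  the zygote stays trisomic for paired chromosomes, which forces biparental
  disomies — the observable consequence that lets the data falsify this
  mechanism.
* **preferential_segregation** — an unpaired chromosome is sent to a
  designated pole with probability `preferential_bias` ∈ [0.5, 1]. This
  biases co-segregation but cannot exceed four carrier spores.
* **spore_killing** — segregation is Mendelian, but spores lacking the
  designated `killer_chromosome` are destroyed after the post-meiotic
  mitosis, so complete octads cannot be recovered when the killer is
  unpaired.

### Nuisance processes

The real data attribute deviations to chromosome loss and to
non-disjunction at either meiotic division, without stage-resolved rates.
We collapse this into two one-parameter processes acting on supernumerary
chromosomes only:

* **Loss** (`loss_rate`, per parental chromosome instance per meiosis):
  one randomly chosen chromatid of the instance is dropped at meiosis I.
  One event removes the chromosome from one meiotic product, i.e. two
  spores: a paired homolog falls from 4 to 2 carriers, a drive-amplified
  chromosome from 8 to 6 (the six-spore asci seen in real octads).
* **Non-disjunction** (`nondisjunction_rate`, per chromosome per meiosis).
  For a chromosome with paired copies the event is modelled as one chromatid
  migrating with the opposite homolog at meiosis I (premature sister
  separation). The observable octad pattern is two disomic spores with one
  copy from *each* parent, two nullisomic spores and four normal spores —
  the pattern reported for chr21 disomies. (Textbook meiosis-II
  non-disjunction of one homolog would instead give same-parent doubles;
  the chromatid-migration event is the one that reproduces the biparental
  disomy-plus-absence octad, so it is what the simulator implements for
  paired chromosomes.) For an unpaired chromosome both sister chromatids
  enter one meiosis-II product, giving a same-parent two-copy spore pair.

### Core markers and twin resolution

Each of the six core markers splits its parental alleles 2:2 over the four
meiotic products, drawn uniformly from the six 2-of-4 chromatid patterns
(mixing first- and second-division segregation; the markers are treated as
unlinked, though two of the real markers share a chromosome). The draw is
conditioned, by rejection sampling, on the four products being pairwise
distinct over the six-marker panel. Without this conditioning about 0.8% of
simulated octads would contain two genotypically identical meiotic products
and hence ambiguous twins — an artefact of the unlinked-marker
simplification, since the real panel was chosen precisely for its resolving
power. The conditioning is what makes octad verification complete (100% of
genuine zero-rate octads pass).

## Verification rule

A candidate ascus is accepted iff it has exactly eight spores, every core
marker splits 4:4, and profile-identical twin pairing (six core markers plus
the mitochondrial marker, which is ascus-constant and thus never splits true
twins) yields exactly four pairs. Failure codes: `wrong_spore_count`,
`marker_ratio`, `twin_missing`, `twin_multiple`; all violated rules are
reported. Supernumerary chromosomes are deliberately ignored, so loss and
drive never disqualify a genuine octad, while asci decimated by spore
killing always fail — which is exactly the argument that complete octads
falsify post-meiotic drive.

## Segregation labels

Per ascus × chromosome, carriers are counted at marker level (≥1 copy;
copy number beyond presence is consulted only for disomy, total ≥2). One
label is assigned with priority
disomy > total_absence > drive_8_0 / partial_drive > mendelian >
loss_deviation. `partial_drive` (5–7 carriers) is named here so that
six-carrier drive asci are countable as a class of their own. The expected
carrier count recorded with each label (4; or 8 for female-unpaired under
the drive hypothesis) is set by an explicit `drive_hypothesis` argument,
never inferred from the data.

## Statistics

* **Binomial drive test** — exact, two-sided against p = 0.5 by the
  minimum-likelihood rule (all outcomes no more likely than the observed one
  are summed). The source experiments report a two-sided binomial p = 0.25
  for an 18-vs-6 split of female roles; the standard exact computation for
  k = 6, n = 24 gives ≈ 0.023, so that printed value is not reproduced here
  and the discrepancy is simply noted.
* **Contingency tests** — Fisher's exact test for totals below 200 or any
  expected cell below 5 (2×2 via the hypergeometric distribution; larger
  tables by margin-constrained enumeration up to N = 120), otherwise
  Pearson's chi-squared without continuity correction. The result records
  which branch ran. The published analyses say only "for large datasets";
  the 200 / expected-count-5 rule is this package's concrete choice.
* **One spore per ascus** — mitochondrial (and drive) genotypes are
  perfectly correlated within an ascus, so transmission tests draw one
  uniformly random spore per ascus, reproducibly from a seed.
* **Loss rate** — events per parental chromosome instance per meiosis:
  a parental homolog of a paired chromosome seen in fewer than four spores
  counts one event; two instances per paired record; disomy-labelled
  records are excluded from the event count because their deficits stem
  from non-disjunction. This estimator is unbiased for the generator's
  `loss_rate`. Because published loss counts may have been tallied per
  ascospore rather than per instance, the per-spore absence fraction is
  reported alongside (it is ≈ half the per-instance rate under this loss
  model). Heterogeneity across chromosomes is a chi-squared test on the
  per-chromosome loss/no-loss table; the synthetic generator is homogeneous
  by construction, so a significant heterogeneity can only echo real data,
  not the defaults.
* **Mechanism discrimination** — falsification rules, each with a recorded
  reason: ≥90% complete verified octads exclude `spore_killing`; ≤10%
  completeness excludes the four octad-preserving mechanisms; a majority of
  8:0 female-unpaired instances excludes `mendelian` and
  `preferential_segregation` (support capped at four); paired instances
  mostly 4:4 with ≤5% disomy exclude `premeiotic_amplification` (no
  trisomy signal), while >5% paired disomy excludes the meiosis-restricted
  mechanisms instead. Mechanisms never positively excluded remain in the
  consistent set; when no drive signature exists, the drive mechanisms are
  flagged as indistinguishable from Mendelian segregation at zero
  penetrance rather than silently retained.

## SNP spectrum

The generator lays n SNPs (alternate-parent alleles) on one chromosome,
assigns the alternate haplotype to two of four chromatids, and draws
Poisson crossovers whose breakpoints swap distal segments between one
chromatid of each homolog — every SNP stays on exactly two chromatids, so
each SNP starts in exactly four spores while haplotype blocks alternate
along the chromosome. Gene-conversion tracts convert a single DNA strand of
one chromatid; the heteroduplex resolves at the post-meiotic mitosis, so
the allele flips in exactly one twin — the classic 5:3 / 3:5 aberrant
octad ratios, and the only source of k > 4 sharing outside
drive/disomy contexts. Read depth is negative-binomial per site and spore
(mean and dispersion configurable; the published analyses give no coverage
model) and detection requires nonzero coverage, minus optional dropout.

The coverage filters read "more than 8×" strictly (> 8 reads; a flag allows
≥). `min_cov_any` requires one spore above threshold. For "above threshold
at all occurrences" two readings are implemented behind `all_scope`: the
default `"spores"` (all eight spores above threshold) keeps the filter
chain strictly nested, which is what the monotonicity properties test;
`"carriers"` (above threshold wherever the allele was detected, scored in
all eight) is the laxer reading of the same wording.

## Problem sizes and determinism

Every stochastic component consumes a `numpy` Generator seeded from a
single master seed; per-ascus substreams are derived by counter
(`SeedSequence(seed, spawn_key=(i,))`) so extending an experiment never
perturbs earlier asci, and identical configs reproduce output files byte
for byte. The bundled analyses use desk-scale sizes chosen to make the
statistical signatures unambiguous while staying instant on one CPU: a
nine-cross panel at 40 asci per cross, 1,000 octads for the Mendelian
transmission check, ~10,080 paired instances (840 asci) for loss-rate
recovery, and 20,000 SNPs for the spectrum.

## What the synthetic data do and do not show

The generator reproduces the *structure* of real octad data — uniparental
mitochondria, 4:4 core markers, twin pairs, the 8:0/4:0/4:4 segregation
classes, six-spore partial-drive asci, biparental disomies, coverage-driven
spectrum distortion — under exactly the configured mechanism. Passing tests
therefore demonstrate that the pipeline detects and discriminates these
signatures when they are present, not that any particular field isolate
shows them. Real phenomena deliberately left out: partial-chromosome
amplification (the incompletely amplified chr18 case), the ~400 kb chr14
insertion polymorphism and any chromosome-size effect on drive,
per-chromosome loss-rate differences, linkage between core markers,
sequence-level chromosome models, and read mapping/variant calling
upstream of the SNP matrix.
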