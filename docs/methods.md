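# Methods

This note documents the models, decision rules, parameters and numerical
choices behind `wolbshift`, and what the synthetic-data experiments do and
do not establish about real data.

## Problem setting

*Wolbachia*-like endosymbionts are maternally transmitted bacteria whose
strains can also move between host species horizontally (via shared
ecology) or introgressively (via host hybridisation, dragging the donor's
mitochondrial genome along).  Given whole-genome read sets from specimens
of host sister-species pairs, the pipeline answers four questions: which
symbiont strains does each specimen carry; do sister species share strains
more than random species pairs; are symbiont split times congruent with
host split times; and do the strain genomes carry candidate loci for
cytoplasmic incompatibility (cifA/cifB toxin–antidote operons) and male
killing (wmk)?

## Strain typing (anikit, straincall)

**Fragment ANI.**  Average nucleotide identity between two genomes is
estimated by cutting the query into consecutive 1,000 bp fragments
(terminal partial fragment dropped, to avoid identity inflation on short
tails), placing each fragment at its best location in the reference via
shared 15-mer seed anchoring plus bounded-error alignment (edlib, infix
mode), and averaging fragment identities.  A fragment counts as aligned
when its identity reaches the 80% floor; the aligned fraction (MAF) is the
share of aligned fragments.  ANI is asymmetric, so both directions are
computed wherever a threshold is applied.  The fragment length is a
compromise: at the 20 kb working scale it yields 20 fragments per genome,
enough resolution for the 99% threshold while keeping the alignment work
trivial; it is configurable.

**Dereplication.**  Genomes are processed longest-first (id ascending as
tie-break) and greedily join the first cluster whose representative they
match at ANI > 99% in both directions with min(MAF) >= 0.90; otherwise
they found a new cluster.  Because of the processing order the founder is
always the longest member, so representative choice is deterministic and
the clustering is invariant to input file order.  The bidirectional
threshold is the conservative reading of an asymmetric similarity.

**Competitive mapping.**  Reads are single-end; each read is placed at its
single lowest-edit-distance location across all references (edlib, infix
mode), with ties broken by reference input order and then leftmost
position.  A read whose best distance exceeds 10% of its length is
unmapped.  This deliberately simple mapper implements exactly the contract
the decision algorithm relies on — a single best competitive placement —
without paired-end rescue or quality modelling.  One practical consequence,
verified in the tests: reads from a strain ~8% diverged from a panel genome
still map broadly (8% < the 10% cap), so an absent-but-related strain is
detected through the heterozygosity excess, not through low breadth; only
strains diverged beyond the cap produce low breadth.

**Coverage statistics and the het rule.**  Breadth is the fraction of
reference positions with depth >= 1.  A site is "heterozygous" when at
least two distinct bases each have >= 2 supporting reads — the two-read
support requirement makes the statistic robust to singleton sequencing
errors (at 0.5% error and 25x the expected false-het density stays well
under the threshold).  The density of such sites per kb of covered
reference is the co-infection signal: 10 sites/kb is the density
equivalent of ANI < 99%, i.e. of a second strain past the dereplication
threshold hiding in the pileup.

**Iterative assignment.**  A sample is screened against all dereplicated
representatives; if the best breadth is below 0.10 ("almost no mapped
reads", quantified here as a tenth of the genome) it is uninfected.
Otherwise the sample is mapped against the top-breadth genome only, and
while any genome in the current set shows > 10 het sites/kb the
next-ranked genome is added.  If three or more genomes were needed, a
re-mapping against only the first and last added genomes checks whether
the intermediates were redundant (similar representatives can soak up
reads from the same strain); if those two alone satisfy the het rule they
become the final set.  A sample is infected when any final genome exceeds
90% breadth; an exhausted ranking with persistent het excess is flagged
`unresolved_coinfection`.  The het threshold is applied per reference
genome in the current set.

**Consensus.**  Per position, the majority allele where depth >= 3, the
reference base elsewhere (ties go to the alphabetically first base).  This
replaces a full variant-calling step; at the 99%+ identities involved a
deterministic majority call is adequate and keeps the pipeline
dependency-free.

## Sharing statistics (sharestats)

**Randomization test.**  The statistic is the mean over sister pairs of a
pair-level quantity: the shared-strain count, or the mean directed ANI
over all cross-species strain occurrences (shared strains contribute 100
when included, are skipped when excluded; a pair with no remaining
cross-occurrences is missing, never zero).  The null re-pairs the filtered
species uniformly at random — a shuffle of the species list chunked into
consecutive disjoint pairs is a uniform draw from the perfect matchings.
Three filters exist (all pairs / at least one infected / both infected);
headline reporting uses both-infected.  The default is 30,000 replicates
with the observed value included as one of them, so the empirical p-value
`(1 + #{null >= observed}) / n` is bounded below by 1/n and is exactly
uniform under exchangeability when the statistic is continuous.
Calibration is therefore checked with the continuous mean-ANI statistic;
with the integer shared-count statistic ties make the p-value mildly
conservative.

**Incidence and prevalence.**  Incidence is the percent of species with at
least one infected specimen (reported as an integer percent); prevalence
per species gets a Wilson 95% interval (a method choice made here; the
interval is well-behaved at the 0/7 and 7/7 boundaries that small specimen
counts produce).

**Sharing model.**  logit P(share) = b0 + b1·time + b2·sympatry +
b3·time·sympatry, with split time in host generations or My.  Predictors
are standardized; the interaction is the product of standardized main
effects; coefficients are reported on both scales (the back-transform is
exact and tested).  The sampler is random-walk Metropolis with
Normal(0, 5²) priors on standardized coefficients — weakly informative,
and enough to regularize separation at n ~ 12 pairs — run for 60,000
iterations (10,000 burn-in, thin 10, so 5,000 kept draws), with the
proposal scale adapted toward ~25% acceptance during burn-in only.
Significance is summarized by pMCMC = 2·min(P(beta > 0), P(beta < 0)).

## Dating and turnover (divtime)

Distances (1 − ANI/100, or direct p-distances between consensus
sequences) are Jukes–Cantor corrected, d_JC = −(3/4)·ln(1 − (4/3)d), and
rejected as saturated at d >= 0.75.  Symbiont split ranges in host
generations are [d_JC/(f·r_max), d_JC/(f·r_min)] with rate bounds
r_min = 2.76e-10 and r_max = 1.5e-9 substitutions/site/generation; the
divergence factor f defaults to 2 because per-lineage rates applied to a
pairwise distance accrue on both branches (f = 1 remains available and is
logged, since published range figures may correspond to either
convention).  Year ranges additionally span the 1–3 host generations/year
bounds, giving the widest defensible interval.  Mitochondrial ranges use
the 2.3 and 1.5 percent-distance-per-My clocks, which are defined on the
pairwise distance, so no divergence factor applies; following the
procedure literally, the JC-corrected distance is fed to these clocks even
though they were calibrated on uncorrected distances — the
internally-consistent alternative is a one-line change and the difference
is negligible below a few percent divergence.

Two ranges are congruent when the narrower lies inside the wider, or when
the wider range's midpoint falls inside the narrower (bounds inclusive);
otherwise the symbiont split is older or younger according to its
midpoint.  Comparisons are categorized 2×2 by same/different host species
and same/different strain, and per-category envelopes take
[min of lows, max of highs].

**Turnover.**  Assuming equal acquisition and loss rates, the estimator
counts strain-set symmetric differences D across pairs and divides by the
total branch length G = sum of f·split_gen: rate = 1e6·D/G events per
million host generations; the waiting time is 1/(rate·gpy) My.  Because
repeated events on a lineage can cancel (a strain lost on both branches,
or gained and re-lost), the estimator is a lower bound; in the recovery
experiment branch lengths are kept short enough (~0.25 expected events per
branch, ~100 events total per replicate) that the downward bias stays
below ~10%.

## Synthetic data (simdata)

The generator emulates the study's inputs with known truth:

* **Strain radiation** — a star topology with non-negative per-lineage
  branch lengths fitted (NNLS) to a target pairwise-distance matrix;
  mutations are Poisson(branch × L) events at uniform positions *with
  replacement*, so multiple hits occur and realized p-distances fall
  slightly below targets — matching the JC correction applied downstream.
  Distances above 0.70 are rejected (JC saturates).
* **Reads** — single-end, uniform starts on the linear genome,
  substitution-only errors, dummy qualities, truth labels per read.
  Defaults mirror the study's sequencing design where it matters to the
  decision logic: 150 bp reads at 25x expected coverage, 0.2% error.
* **Host system** — per pair, a split time, a sympatry value and a
  scenario: co-divergence (symbiont split = host split), horizontal
  (symbiont split drawn independently, 0.1–4× the host split),
  introgressive (symbiont and mito splits equal and younger than the
  nuclear split), loss (one species uninfected), or uninfected.  Symbiont
  sequences evolve at 6.4e-10 subs/site/generation per lineage (the
  geometric midpoint of the clock bounds), mitogenomes at 1.9%/My pairwise
  (between the two mito clocks), 2 host generations/year, 6 specimens per
  species, genome working lengths 20 kb (symbiont) and 15 kb (mito).  Two
  isolates count as the same strain when their expected divergence is
  below the 99%-ANI dereplication threshold.
* **Hit tables** — planted loci receive e-values < 1e-20, coverage > 60%,
  a concordant top reciprocal hit and an overlapping same-strand gene;
  each decoy violates exactly one criterion (weak e-value, low coverage,
  discordant reciprocal top hit, or no overlapping gene), recorded in a
  truth table.

What the generator does *not* emulate: paired-end structure, indels and
structural variation, quality-score error profiles, circular genomes,
within-species host population structure, repeat content, and
contamination.  Passing tests therefore establish the correctness of the
decision logic and estimators under the stated models, not robustness to
every artefact of real sequencing data.

## Locus screen (lociscreen)

Hits are kept at e-value < 1e-20 AND query coverage > 60% (both strict, as
printed thresholds); query coverage is consumed per hit from the table's
qcovs-style column.  Confirmation requires the top reciprocal hit (lowest
e-value, ties by bit score then subject id) to belong to the originating
family, and an annotated gene on the same contig and strand overlapping at
least half of the hit span.  "Consecutive" cifA+cifB means adjacent
predicted genes on the same contig and strand with no intervening gene and
no base-pair gap limit; pairing is greedy left-to-right, each gene joins
at most one operon, and unpaired cif assignments are orphans, so per
family confirmed = 2·operons + orphans.

## Problem sizes and determinism

All stochastic components run from explicit seeds and are byte-reproducible.
The validation experiments use: a 20-sample panel over six 20 kb strains at
3% pairwise divergence for caller recovery; 200 + 500 null datasets of 16
species at 500 permutation replicates each for calibration; 50 replicates
of 200 gain/loss pairs (~100 events each) for turnover recovery; 5 kb
genomes for the full-DP ANI oracle; and 20 replicates for co-divergence
clock containment.  These sizes were chosen so each check has adequate
statistical resolution while the whole suite runs in minutes on one CPU.

## Known limitations

* The mapper reports one best placement; repeat-induced multi-mapping and
  paired-end disambiguation are out of scope.
* The het-site definition (>= 2 alleles with >= 2 reads) is a declared
  operationalisation; other depth filters before breadth computation are
  not applied.
* The turnover estimator is a lower bound under repeated gain/loss.
* The sharing model's sampler is a generic Metropolis scheme, not a
  reproduction of any particular GLMM implementation's priors.
* ANI on highly diverged pairs (beyond ~20%) loses aligned fragments and
  the estimate becomes conditional on the alignable fraction.
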