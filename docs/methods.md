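# Methods

## Problem setting

Germplasm collections of clonally propagated crops accumulate duplicate
accessions, mislabelled material and undocumented pedigree links.  With
a few hundred dominant binary markers (band presence/absence, blind to
allele dosage) one can measure pairwise genetic similarity across the
whole collection; with a small panel of codominant SSR loci one can then
test specific parentage hypotheses.  orchardkin implements that
two-tier strategy, together with the cluster-number diagnostics used
when the collection is also run through Bayesian admixture clustering.

## Similarity model

Pairwise similarity is the Jaccard coefficient over markers scored in
both accessions: `J = a/(a+b+c)` with `a` joint presences and `b`, `c`
the two one-sided mismatch counts.  Joint absences are excluded —
for dominant markers an absent band is the recessive (uninformative)
state, and including 0/0 cells (simple matching) would inflate
similarity for pairs sharing rare-band profiles.  Missing calls are
handled pairwise-complete; the co-observed marker count is exported per
pair so users can filter pairs whose overlap is too small for a stable
score.  Scores are printed to three decimals in all outputs, the
precision at which threshold decisions are made.

The implementation is three matrix products over presence and observed
indicator matrices; a brute-force per-pair contingency loop is kept in
the test suite as an independent oracle and the two agree exactly (not
merely to tolerance) on random fixtures.

## Thresholds

* `clone = 0.90` — scores at or above generally signify clonality or
  duplication.  The band is closed at the bottom so a 0.90 score lands
  in it and must then be cleared or retained via the SSR/ploidy flags.
* `borderline = 0.88` — clone groups of some cultivars (notably
  triploids) cohere only at ~0.88; scores in `[0.88, 0.90)` raise a
  review flag rather than an automatic call.
* `close = 0.80` — the conservative lower bound for "closer than a
  standard parent-offspring or full-sibling" relationships.  True
  inbreeding likely extends below it; the cut-off trades recall for a
  low false-positive rate.

All three are configurable, validated as `0 < close <= borderline <=
clone <= 1`.

## Clone collapse and close groups

Edges at or above the clone threshold define single-linkage connected
components; each collapses to one representative (lowest accession id,
overridable with a keep-list, since any member represents the genotype).
Before collapsing, pairs indistinguishable by markers but differing at
two or more commonly scored SSR loci are treated as suspected collecting
errors: the edge is dropped, both genotypes survive, and the pair is
flagged (`collecting_error_suspect`, `ssr_conflict`).  The two-locus
rule operationalizes a narrative criterion; one differing locus is
within SSR scoring noise (null alleles, one-repeat drift), two
commonly-scored disagreements are not.

Close groups are single-linkage components over edges in
`[close, clone)` on the collapsed matrix.  Single linkage is a
formalization choice: a shared parent links its offspring into one group
even when some offspring pairs score below the threshold, which is
exactly the observed topology of unreduced-gamete families.  Groups are
classified by member ploidy: `diploid_sibling_group` (all known 2x),
`heteroploid_group` (any polyploid member), `mixed_unknown` otherwise.

Relationship tier summaries (population / documented siblings /
parent-offspring / full sibs) are computed on the collapsed matrix.
Known polyploids are excluded from the relationship tiers by default:
the tiers characterize standard haploid-gamete transmission, and
unreduced-gamete offspring sit far above them (they are what the close
groups catch).  The population tier always covers all pairs.

## SSR parentage rules

Profiles are per-locus multisets of integer fragment sizes.  A single
reported size means "at least one copy, possibly homozygous"; copy
number is never inferred at read time, and each compatibility rule
resolves the ambiguity explicitly, in favour of consistency but under a
distinct status (`consistent_homozygous_ambiguous`) so ambiguous loci
can be counted.  Loci missing in either profile are `no_data` and never
act as wildcards.  Allele equality is exact integer match; a +-2 bp
one-repeat shift comparison exists but only annotates (such shifts are
plausible mutation/scoring drift and should warn, not exclude).

* **Haploid model (diploid trios).**  A locus is consistent iff the
  offspring shares an allele with the parent; any inconsistent scored
  locus excludes (tolerance 0 by default).  The residual — what the
  other parent owes — is enumerated over all valid assignments when the
  parent could have contributed either offspring allele.
* **Unreduced-diploid model (triploid offspring).**  The donating
  parent's both alleles must appear in the triploid.  One absent
  parent allele across the comparison is tolerated by default
  (`tolerance=1`): first-division restitution largely preserves
  heterozygosity but a crossover can render a locus homozygous, and a
  single missing allele is the empirically observed failure mode.
  Strict mode (`tolerance=0`) is available and is provably stricter
  (verdicts are monotone in the tolerance).
* **Triploid model (tetraploid offspring).**  Loci are categorized:
  `full_complement` (all three distinct parent alleles present),
  `indistinguishable` (parent reports fewer than three distinct sizes,
  all present), `partial` (one absent), `inconsistent` (two or more
  absent); category counts are part of the report because real cases
  are argued from the category split rather than a single verdict.

**Exclusion search for a missing parent.**  Given a compatible known
parent, the per-locus residual alternatives define what the unknown
co-parent must carry.  A candidate survives iff at every commonly
scored locus it can supply one alternative; survivors are ranked by
fully consistent locus count, and a unique survivor is flagged — the
standard of evidence for asserting a recovered pedigree.  Survivor sets
are monotone: adding loci can only shrink them.

**Full-sibling plausibility.**  Residual alternatives of the two
putative siblings are unified per locus; the pair is plausible iff some
assignment needs at most two distinct alleles of the co-parent (a
diploid genotype) everywhere.

**Timeline check.**  Parent documented later than offspring is a
`conflict` flag, never an exclusion: many dates are "pre-YYYY" upper
bounds (the flag and the `pre` annotation are both carried through).

## Delta-K

Per replicate `r`, curvature `L''_r(K) = L_r(K+1) - 2 L_r(K) +
L_r(K-1)`; `dK(K) = mean_r |L''_r(K)| / sd_r(L_r(K))` with the sample
(ddof=1) SD.  Endpoints carry no value; `sd = 0` or a single replicate
makes `dK` undefined there (flagged, not fabricated).  When replicate
labels do not span every K, curvature falls back to the second
difference of per-K means (flagged `unpaired_replicates`).  All local
maxima are reported, ranked, with prominence = peak value / median dK —
secondary peaks carry real information and an argmax-only report would
hide them.  `dK` is invariant under shifting or positively scaling all
log-probabilities, and under input row order.

The plateau diagnostic is an explicit operationalization of the visual
"log-probability stops improving" criterion: the smallest K with
`(m(K+1) - m(K)) / |m(K+1) - m(1)| < rel_tol` (default 0.01, always
recorded in the output); monotone steep growth yields an explicit
"none".

## Marker screening

Two stages: (1) batch intersection — with accessions genotyped in
several assay batches, keep only markers reporting (>=1 non-missing
call) in every batch; (2) redundancy — collapse identical call vectors
(missing pattern included) to the lexicographically first marker id, or
apply an explicit keep-list.  The identical-vector rule is a stand-in
for sequence-based redundancy information that is typically proprietary;
the keep-list path exists precisely so a user with that information can
apply it.  Screening is idempotent and never alters surviving calls.

## Synthetic collections

The simulator draws unrelated diploid founders in Hardy-Weinberg
proportions: dominant-marker presence-allele frequencies uniform on
(0.05, 0.95) (band frequency `1-(1-p)^c` for `c` copies), SSR allele
frequencies symmetric-Dirichlet over up to 8 sizes spaced 2 bp apart on
each of 12 independent loci.  Transmission supports haploid, unreduced
diploid and unreduced triploid gametes.  Unreduced gametes carry the
parent's full per-locus complement except, with probability
`lambda = 0.05` per locus, a crossover-loss event replaces the pair with
two copies of one allele.  Crossover loss is modelled per locus, not
positionally: the SSR panel sits on separate chromosomes, so linkage is
irrelevant at this scale.  Unreduced gametes are maternal by default,
matching the observed transmission route for triploid offspring.

Clones ("sports") flip each rendered dominant call independently at
`epsilon = 0.005`, leave SSRs untouched, and log their events.  With
562 markers this yields clone-pair similarity of about 0.97-1, the band
observed between replicate samples of one accession; `epsilon` and
`lambda` are calibration choices against those observations, not fitted
estimates.  Rendering is dosage-blind, as the assays are: a band is
present iff any presence allele exists across all copies; SSRs report
distinct sizes only.  Missing calls are injected at 1%; optional
redundant marker duplicates and corrupted documented-parent entries
exercise the screening and mis-documentation paths.  Identical
configuration (including seed) reproduces identical output files.

What the simulator does **not** emulate: population structure and
admixture (founders are unrelated and exchangeable), linkage, null
alleles and allele-size homoplasy at SSRs, genotyping batch effects
beyond the batch-reporting mask, and realistic collection-scale
pedigree depth.  Passing tests therefore demonstrate correctness of the
decision rules under their stated error models — clone-band separation,
exclusion power at given panel sizes, heteroploid recovery — not
performance on any particular real collection, where structure can
compress the gap between the close-relation band and the population
bulk.

## Problem sizes and numerical choices

The default planted study is ~84 accessions (40 founders, 4 clone
groups of 5, six full-sib families of 3 across 3 mothers, 8 triploids,
1 tetraploid) at 562 markers; recovery statistics aggregate 50 such
collections.  Exclusion power uses a 200-candidate panel and 100 trios
at 12 loci; clone-band calibration uses 1,000 clone and 1,000 unrelated
pairs; collection-scale behaviour is checked once at 2,138 accessions
(~2.28M pairs), which the matrix-product implementation handles in
seconds.  These sizes are chosen so the statistics they estimate are
stable at the asserted margins.

KDE for similarity-distribution profiles is Gaussian with the bandwidth
as the kernel SD on the caller's scale (bandwidth 0.75 corresponds to
percent-scaled similarity values), 512 grid points spanning the data
+-3 bandwidths; all-identical input sets a degenerate flag.  The
density integrates to 1 within 1e-3 by trapezoid rule.

## Known limitations

* The close-relation band cannot separate inbreeding from heteroploid
  parentage by similarity alone; the SSR stage is required, and with
  only 12 loci homozygous-ambiguous verdicts are common (they are
  counted, not hidden).
* Shared-gamete detection between two triploids is not implemented
  beyond shared-allele counts; the hypothesis space (which two of three
  alleles travelled together) is under-determined at this panel size.
* Likelihood-based parentage (LOD scores) is out of scope; all rules
  are exclusion-based and report no posterior strength of evidence.
* The clustering itself (admixture model, membership matrices) is
  consumed, never computed; delta-K inherits whatever pathologies the
  upstream runs have (e.g. degenerate replicate SDs, which are flagged).
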