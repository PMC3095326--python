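# Methods

`mycolib` re-implements, as a tested pipeline, the analysis chain of a
clone-library ITS survey of root-associated fungi sampled under a nested
spatial design (main localities > sub-localities > root systems > cloned
ITS fragments).  This note records the models, the defaults and the design
choices, and what the synthetic validation does and does not demonstrate.

## The synthetic survey

The generator (`mycolib.simulate`) emulates the data-generating process the
analysis assumes, with complete ground truth per clone.

**Reference community.** `n_true_otus` (default 137) reference ITS
sequences descend from one random ancestor along a star phylogeny.  Sites
in ITS1/ITS2 (defaults 150/180 bp) mutate independently at rate
`interspecies_divergence / 2` per branch so the mean pairwise ITS distance
is close to `interspecies_divergence` (default 0.10); the 5.8S core
(160 bp) never mutates, giving every OTU an identical conserved region used
for boundary detection.  Candidates are rejection-sampled until every pair
differs at ≥ `min_interspecies_divergence` (default 0.065) of ITS sites.
The floor matters: a 10% *mean* divergence alone leaves a tail of OTU pairs
within 3% of each other, and single-linkage clustering at 97% would then
legitimately merge distinct OTUs, making "perfect recovery" an incoherent
expectation rather than a test of the code.  Taxonomy labels are assigned
structurally (3 species per genus, 4 genera per family by default) so that
genus-level chimera screening has realistic same-genus collisions.

**Within-OTU variation.** Each OTU owns up to three genotype variants: the
reference and two sequences with the same three ITS positions substituted
by two different alternative bases.  All pairwise distances are exactly 3,
which (a) stays within `intraspecies_divergence` (default 0.01 ≈ 4.9 bases
over the 490-bp amplicon), (b) keeps variants inside one 97% OTU, and (c)
is just beyond the ≤2-substitution PCR-collapse rule, so quality control
can never erase true variation.  Each root system uses a random 1–3-variant
subset per OTU (probabilities 0.7/0.2/0.1).

**Community structure.** OTUs are partitioned into pools: one private pool
per root system, one per sub-locality, one per main locality, and one
shared by the whole metacommunity, with pool sizes (and per-clone draw
probabilities) proportional to the `turnover` fractions (default 0.75 /
0.10 / 0.10, remainder 0.05 shared).  Within a pool, draw probabilities
follow a lognormal abundance distribution (σ = 1.5), producing the
few-dominants / long-tail pattern typical of ECM clone libraries.  The
defaults yield ~75–85% of OTUs in a single root system and sharing means
that decrease from within-sub-locality to between-main-locality pairs —
the strong patchiness with weak geographic structure the analysis is meant
to characterise.

**Noise.** Each clone acquires i.i.d. per-base substitutions at
`pcr_error_rate` (default 2 × 10⁻⁴, ≈0.1 errors per 490-bp clone — rare
polymerase errors at the scale where the collapse rule matters).  With
probability `chimera_rate` (default 0.008) a clone is a chimera: the ITS1
of its template joined, at the ITS1/5.8S junction, to the 5.8S+ITS2 of a
template from a different OTU.  The junction breakpoint is the detectable
case for a split-marker screen; a uniform-breakpoint mode exists for
stress-testing.  By default chimeras are emitted *in addition to* the
authentic quota (each root system always yields 24 authentic clones,
mirroring how chimaeric clones are replaced by newly sequenced ones in
practice); `replace_chimeras=False` makes the chimera count exactly
Binomial(n, p) for calibration tests.

**What the generator does not emulate:** indels and length variation,
primer/cloning bias, ITS secondary structure, chimeras with non-junction
breakpoints (by default), or taxon-dependent error rates.  Passing tests
therefore validate the *statistical machinery* under the stated model, not
robustness to alignment-heavy real-world ITS data.

## Sequence QC

**Region bounds.** The conserved 5.8S profile (majority consensus of the
reference panel) is slid along each clone; the best Hamming window, if
≥90% identical, defines ITS1 = prefix and ITS2 = suffix.  No acceptable
window → the clone is "unsplittable": excluded from the chimera screen,
retained everywhere else.

**Chimera screen.** A clone observed identically in ≥2 root systems is
authentic by definition.  A singleton is chimaeric iff its ITS1 and ITS2
best-match references of different genera with both region identities
≥ `min_region_identity` (default 0.80); a region match below the floor is
a no-call and the clone passes (insufficient evidence).

**PCR-error collapse** (within one root system).  Exact duplicates pool
first.  A singleton with ≤2 substitutions from an equal-length, more
abundant sequence merges into it; two lone clones differing at 1–2
positions merge into their IUPAC consensus ('Y' for C/T, etc.).  Three or
more unique substitutions are accepted as real.  Determinism and safety
rules: candidates are ranked by original clone abundance with
lexicographic tie-breaks; distances are always measured to the merge
target's original sequence (no chaining, so merged sequences can never
drift beyond 2 differences); length-differing sequences never merge (the
rule is about point mutations, and indel handling is deliberately out of
scope); a lone clone that has itself absorbed another does not merge
onward.  The procedure is idempotent (property-tested).

## OTU clustering and naming

**Identity** is computed on a global alignment with free end gaps
(match +1, mismatch −1, gap −2 linear, via Biopython's PairwiseAligner):
identity = matches / aligned columns after trimming terminal-gap columns,
internal gaps counting as mismatch columns.  Two guards were needed in
practice: (1) a minimum-overlap rule — an optimal alignment spanning fewer
columns than half the shorter sequence is a chance micro-overlap, not
evidence of homology, and scores identity 0 (the analogue of an
assembler's minimum-overlap setting); (2) pairs are aligned in canonical
order so the value is exactly symmetric despite co-optimal alignments.
Ambiguity codes match only themselves; a consensus genotype is thus
slightly penalised against its parents, which is conservative and
irrelevant at the 3% threshold.

**Clustering** at 97% uses single linkage (connected components of the
≥-threshold identity graph), mirroring contig-assembly semantics; a greedy
abundance-ordered centroid mode is available for comparison.  Equal-length
pairs whose Hamming identity falls below threshold − 0.03 are skipped
without a full alignment — with substitution-structured divergence the
ungapped alignment is score-optimal, so the screen is safe there, and it
can be disabled (`prefilter_margin=1.0`).  Output is canonicalised
(clusters ordered by abundance, representatives = most abundant member,
lexicographic tie-breaks) and is invariant to input permutation.

**Naming** follows the best full-length reference match: ≥97% → the
reference's species name; 90–97% → "<genus> sp.N"; <90% → "<family> N",
with deterministic numbering in OTU order.  The literal thresholds are
implemented; borderline conventions in published tables (e.g. a 96% match
labelled at genus rank) are consistent with them.

## Richness: accumulation and T-S extrapolation

Sample-based accumulation curves come in two modes: Monte-Carlo
permutation of sample order, and the closed form
E[S_k] = Σ_j [1 − C(N−n_j, k)/C(N, k)], which the permutation mode must
match within Monte-Carlo error (tested).

The total-species (T-S) procedure treats root systems as sub-areas: for
every k, the mean terminal richness T_k over combinations of k sub-areas
is computed (all C(K,k) combinations when ≤ `max_combinations` = 200,
else a seeded random subset — C(24,12) ≈ 2.7 M is not enumerable), T_k is
regressed on ln(sampling effort), and the fitted line is evaluated at the
target effort (default 10⁶ sub-areas of the observed mean size; the
prediction is invariant to the per-sub-area sample count, which only
shifts the intercept).  The fit uses all K terminal points by default; a
"last m points" window is configurable since log-linear behaviour is a
tail property.  Natural logs throughout.  Uncertainty: K sub-areas are
resampled with replacement, the whole T-S computation is repeated, and the
SD over 100 replicates is reported (labelled SD; replicates in which all K
draws are the same sub-area are redrawn).  An exhaustive mode enumerates
the full K^K resample space for oracle testing at tiny K.

**What the estimator can and cannot do.** Extrapolation to 10⁶ sub-areas
answers "how many species in a vastly larger area with this between-area
heterogeneity", not "how many species in the sampled region"; applied to a
closed simulated community it necessarily overshoots.  The parameter-
recovery experiment therefore simulates a 240-root-system region, samples
the survey design (2 root systems per sub-locality = 24 × 24 clones) and
extrapolates to the region's true size.  Across 50 replicates the T-S
estimate exceeds observed richness in every run and roughly halves the
negative bias (median |error| ≈ 108 vs 144 against a true richness of
200) — the estimator reduces, but does not eliminate, undersampling bias,
exactly the qualitative behaviour the method claims.

## Community structure and ordination

Sharing statistics stratify all root-system pairs into within-sub-locality
/ between-sub-locality / between-main-locality and report mean pairwise
OTU intersections; Venn counts summarise the three sub-locality OTU sets
per main locality.  Dissimilarity is Sørensen's index,
1 − 2|A∩B|/(|A|+|B|) (the presence/absence reduction of percentage
dissimilarity); a both-empty pair is defined as distance 0 (arises only in
degenerate synthetic inputs).

**CA/DCA.** CA is the SVD of the chi-square-standardised matrix, site
scores in principal coordinates (eigenvalues in [0,1), checked against a
dense eigen-decomposition).  DCA detrends axis 2 against axis 1 by
subtracting within-segment means over 26 equal-width segments, iterating
with re-orthogonalisation under the row-mass inner product and ending on a
detrending pass (so within-segment means are exactly zero).  Hill's
non-linear rescaling is *not* implemented — it is an intricate legacy
algorithm orthogonal to the analyses here — so axis "gradient lengths" are
a labelled approximation (score range / mean within-site weighted SD of
species scores) and carry an `approximate` flag.  They are indicative
only.

**NMDS.** Kruskal stress-1 minimisation (sklearn SMACOF with isotonic
regression), 100 random starts, 1000 iterations, 2 dimensions.  The
quoted stress-reduction-ratio stopping rule (0.99999) has no exact SMACOF
counterpart; it is mapped to a conservative absolute criterion
(eps = (1−ratio)·10⁻⁴) so that starts landing in the same basin converge
to configurations agreeing within the acceptance tolerance.  The best
solution is *accepted* only if at least one other start matches it within
a symmetric Procrustes RMSE of 1% of the configuration scale; the result
is centred and rotated to principal axes.  Method concordance is Kendall's
tau-b over the 2×2 axis grid, compared sign-invariantly (axis reflection
is arbitrary).

The ordination validation community is a coenocline: 24 sites, 80 species
with contiguous niches of width 20 sites (≈ one full compositional
turnover).  Narrower niches saturate Sørensen distances between distant
sites (d = 1 carries no rank information) and bend the NMDS configuration
into the classic horseshoe, capping CA–NMDS rank concordance regardless of
implementation; the chosen width keeps the concordance check well posed
(|tau| ≈ 0.94–1.0 across seeds).

**ANOVA.** One-way fixed-effects F test of per-root-system OTU counts by
main locality (scipy), with explicit errors for degenerate input; type-I
error calibration is simulation-tested.

## Problem sizes and numerical choices

Defaults everywhere reproduce the emulated survey (24 root systems × 24
clones, 137 OTUs).  The test suite uses the same scale for end-to-end
checks and smaller designs (2×2×2×12) for pipeline plumbing; the
recovery experiment uses 50 replicates of a 240-root-system region.
Bootstrap B = 100; accumulation permutations 10⁴ in oracle tests.
All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so every artifact is reproducible
byte for byte.  Ties are broken lexicographically wherever an order is
needed (merge targets, representatives, cluster numbering).

## Known limitations

- No indel-aware QC: length-differing sequences never collapse, and the
  simulator never produces indels, so this path is untested against real
  length-variable ITS data.
- Chimera detection requires genus-level disagreement between region
  matches: within-genus chimeras are invisible by design, as are chimeras
  of taxa absent from the reference panel.
- DCA gradient lengths are approximate (no non-linear rescaling) and must
  not be compared numerically against rescaled DCA output from other
  software.
- The T-S extrapolation inherits the log-linearity assumption; at targets
  far beyond the sampled effort (10⁶ sub-areas) it is an index of
  undersampled heterogeneity, not an unbiased richness estimate.
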