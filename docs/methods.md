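# Methods

This note documents the models and procedures implemented in `srna_seeker`,
the parameter choices that matter, what the synthetic study does and does not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Mapping model

Reads are placed only at exact full-length matches, on either strand
(the library is unstranded; only forward coordinates are recorded). Error
tolerance comes from the iterative trim loop: an unmapped read loses its
lower-quality terminal base and is retried, up to 50 cycles, stopping before
the read would fall below 50 nt. Ties between terminal qualities trim the 3′
base, since terminal-cycle errors concentrate there. Multi-mapping reads are
placed at every matching locus rather than discarded; the discovery stage's
repeat flag marks calls whose sequence recurs elsewhere so users can treat
them with caution. The exact matcher is a 20-mer seed table with full-length
verification; a naive full-scan matcher is kept alongside as an oracle and
the two are asserted equal on uncorrupted reads.

Mapping each read once through the loop (rather than merging per-cycle
alignment files) avoids any ambiguity about duplicate placements across
cycles.

## Coverage and normalization

Coverage depth sᵢ is the count of mapped reads spanning nucleotide i,
strand-blind. For library-size normalization, positions inside annotated
rRNA and tRNA genes are excluded from the total (structural RNA dominates
small-RNA libraries and would otherwise drive the scale), and every sample
is multiplied by `target_total / masked_total`. The conventional target of
10⁸ bases corresponds to roughly 25–30× mean depth on a ~3.6 Mb
cyanobacterial genome. The synthetic study's genome is ~110 kb, so the demo
uses the design-expected masked total of the simulated libraries as its
target instead: scale factors stay near 1 and normalized depths remain on
the planted scale, preserving the selectivity of the 50× calling threshold.
The 10⁸ default remains in place for real-scale inputs, and normalization is
exact (relative error < 10⁻⁶) and idempotent by construction at any target.

## Discovery tiers

1. **Segmentation**: maximal runs of sᵢ strictly above the depth threshold
   (default 50×). Runs shorter than 50 bp are kept until the final length
   filter so that merging can still join fragments.
2. **Rescue**: a previously reported locus is retained when its inside mean
   depth is positive and at least `rescue_ratio` (default 2.0, since "clear
   coverage reduction" is inherently qualitative) times the mean of each
   50 bp flank.
3. **Support**: per-sample detections are clustered by positional overlap
   (single linkage); the consensus interval is the position-wise median of
   member starts/ends; a sample supports a cluster when one of its members
   has Jaccard overlap ≥ 0.5 with the consensus; clusters with ≥ 3
   supporting samples (of 18) survive.
4. **Merging**: neighbours with an inter-candidate gap < 50 bp are merged
   when their per-sample expression vectors correlate positively (Pearson
   r > 0; sign concordance available as an alternative), iterated to a
   fixpoint. The gap reading (rather than bounding the candidates' lengths)
   is deliberate: merging candidates each ≥ 50 bp would otherwise be
   vacuous given the later discard rule.
5. **Boundary refinement**: each end moves within ±20 nt to the position of
   the maximum single-step coverage drop (rise for the 5′ side), ties
   resolved toward the unrefined boundary. The window half-width replaces a
   manual curation step; ±20 nt comfortably covers the ramp created by
   terminal-base trimming.
6. **Classification** (precedence order): gene-body overlap → asRNA;
   overlap with a gene's strand-aware 100 nt-upstream / 50 nt-downstream
   window → UTR; otherwise ncRNA. The library carries no strand
   information, so "asRNA" means gene-body overlap on either strand;
   resolving orientation requires bench work outside this package's scope.
7. **Repeat flag**: a call is flagged when its sequence has a second site
   elsewhere in the genome with an ungapped alignment > 50 bp at identity
   > 80%, found by exact 20-mer seeding on both strands with greedy
   extension (X-drop 5 mismatches). This is a deliberate, deterministic
   replacement for an E-value-based search: on genomes of this size an
   exact-seed contract is both stricter and easier to reason about.

External annotations (protein-database hits at E < 10⁻¹⁰, ncRNA-family
assignments, ORF/RBS/terminator predictions) are ingested from tables and
attached as labels; the tools that produce them are not run here.

## Quantification and differential expression

Expression of an sRNA of length j in a sample is Σ sᵢ / j over its interval,
i.e. mean normalized depth; this makes merged intervals exactly the
length-weighted mean of their parts.

The DE stage is an explicit, pluggable stand-in for DESeq-style analysis
(the workflow's scientific content is the thresholds, not the test's
internals):

- **Size factors**: median-of-ratios to the per-sRNA geometric-mean
  reference, over sRNAs with all-positive counts.
- **Dispersion**: method-of-moments per sRNA and replicate group on
  normalized counts (α solves var = μ + αμ²), pooled across sRNAs by plain
  mean, clipped at zero. Per-sRNA estimates at n = 3 are individually noisy
  but roughly unbiased; a median or trimmed mean would bias the pooled value
  low because the sampling distribution is right-skewed, making the test
  anti-conservative.
- **Test**: two-sided NB exact-style test conditioning on the sum of the
  two per-condition totals; a sum of n replicates with per-observation
  dispersion α is NB with dispersion α/n. The p value adds probabilities of
  all splits no more probable than the observed one. All-zero input returns
  p = 1, fold change 1.
- **Fold change**: (mean_B + 0.5)/(mean_A + 0.5) on normalized counts; the
  0.5 pseudocount stabilizes ratios at zero counts.
- **Multiplicity**: Benjamini–Hochberg step-up within each comparison
  (delegated to statsmodels; property-tested against a hand-written
  step-up oracle).
- **Significance**: strictly fold change > 1.5 (either direction) and
  strictly adjusted p < 0.05.

Replication: the study design has one library per condition × time point.
By default the three time points of a condition are treated as replicates
(3 vs 3 against the control), which is the grouping that yields per-condition
DE counts; a per-time-point mode (1 vs 1, low power) is exposed for
early-response profiling. This grouping is an analysis choice, exposed in
config rather than hard-coded.

Correspondence analysis is the classical algorithm: divide by the grand
total, subtract the independence model, scale by √(row mass × column mass),
SVD, principal coordinates = mass-rescaled singular vectors × singular
values; total inertia equals the Pearson chi-square statistic divided by the
grand total. The expression matrix enters untransformed (CA operates on a
nonnegative contingency-like table; a log transform would break the inertia
identity).

## Network construction

Target predictions (sRNA, gene, hybridization free energy ΔG, rank) are
ingested, never computed. Filters, in order:

1. rank ≤ 100 and ΔG ≤ −10 kcal/mol (inclusive at the cutoff);
2. Pearson correlation between the sRNA's expression and each candidate
   target's transcriptome profile across shared samples: keep |r| > 0.4
   (strict) with two-sided p < 0.05. Significance uses the Fisher
   z-transform, the standard two-sided test for a correlation coefficient
   (an "exact test" does not apply to r; this substitution is deliberate
   and documented here). Both correlation signs are kept, since sRNAs act
   both positively and negatively.
3. per-sRNA hypergeometric enrichment over the pathway-annotated gene
   universe N (not the whole genome): report pathways with m ≥ 2 hits and
   upper-tail P < 0.05.

`hypergeom_p` is computed in log space (gammaln + logsumexp) by summing the
upper tail directly over its support; tests compare it with an
exact-rational enumeration oracle over the full N ≤ 30 grid at 10⁻¹².
Passing (sRNA, pathway) pairs become edges of a bipartite graph whose edge
attributes carry P, m and the dominant correlation sign among the sRNA's
supporting targets; a strand attribute from the prediction table is carried
for display only. Export is GraphML (attributes preserved; round-trips
exactly through the package's reader) and SIF (topology only).

## The synthetic study

The generator emulates the *statistical shape* the pipeline assumes, not any
real organism's sequence:

- **Genome**: one 100 kb "chromosome" + one 10 kb "plasmid" of i.i.d.
  bases at GC 0.48 — small enough that every stage runs in seconds.
- **Annotation**: ~60 CDS of 600–1200 nt with 500–900 nt intergenic gaps,
  two 4.5 kb rRNA operons, five 80 nt tRNAs, random strands.
- **Planted sRNAs**: 20 intergenic (≥ 101 nt from every gene boundary),
  10 antisense (inside CDS bodies), 10 UTR-proximal (inside upstream
  windows), lengths 60–100 nt, pairwise separated by ≥ 200 nt so support
  clustering and merging cannot conflate them. Baseline depth 150–300×
  with a 1.5–2.5× up-shift in one randomly assigned condition; one
  intergenic feature is salt-only (high in salt, ~5× elsewhere) to give the
  ordination a condition-specific marker. Five intergenic decoys sit at
  20×, below the 50× threshold.
- **Reads**: background reads of 100 nt at Poisson rate 1×; each planted
  feature emits full-transcript reads at Poisson rate equal to its
  per-sample depth (the features are 50–100 nt, i.e. within one read — the
  same size class the trim loop exists to capture), so planted coverage is
  near-rectangular and boundary recovery is a meaningful score. Single-end
  reads stand in for paired ends: pairing adds no information to
  coverage-threshold calling. A configurable fraction (default 10%) of
  reads has one terminal base flipped and assigned quality 10 (< Q20),
  giving the trim rule a concrete operational meaning.
- **Counts**: NB draws with specified per-condition fold changes and
  dispersion (α = 0 degenerates to Poisson) for calibrating the DE stage
  in isolation.
- **Network truth**: a disjoint 20-pathway × 10-gene universe; planted
  (sRNA, pathway) enrichments get 5 true targets each with ΔG ≤ −12 and
  transcriptome profiles rejection-sampled to |r| > 0.6 against the sRNA;
  decoys get ΔG > −10 or profiles with |r| < 0.2. Predictions carry a
  `true_target` ground-truth column.

Everything regenerates bit-identically from one integer seed via
`numpy.random.SeedSequence` spawning in a fixed order, and ground-truth
tables are emitted alongside every fixture.

**What passing does not show.** The generator omits realistic base-error
profiles, adapter contamination, GC and coverage biases, overlapping or
nested transcripts, rRNA-depletion artifacts and real sequence composition.
Recovery scores on it validate the calling logic and its thresholds, not
performance on real libraries; in particular the near-perfect boundary
recovery reflects the sharp-edged transcript model and should be read as a
correctness check, not an accuracy claim.

## Problem sizes and numeric conventions

Default study: 110 kb genome, 18 samples of ~10–14 k reads; discovery
benchmarks use ~40 planted features + 5 decoys. DE calibration uses 1000
sRNAs (3 vs 3, dispersion 0.1, mean 200) for the null and 100 planted
4-fold changes among 1000 for power. Network specificity uses 100
no-enrichment seeds over 5 sRNAs × 20 pathways. These sizes keep the whole
suite and the acceptance script in the tens of seconds on one CPU while
leaving every statistical check adequately powered.

Coordinates are 1-based inclusive at every interface (GFF3 convention);
BedGraph files use the format's native 0-based half-open convention on disk
and are converted at the boundary. Degenerate inputs fail loudly and
specifically: all-zero samples at normalization, all-zero rows/columns in
CA (naming the offender), duplicate prediction rows, empty pathway
universes. Ties are deterministic everywhere (trim 3′ on quality ties;
boundary refinement keeps the position closest to the unrefined end; node
insertion order in the network is sorted).

## Known limitations

- Exact-match mapping with trim-based error tolerance does not model
  internal mismatches or indels; it is adequate for the simulator's error
  model and for small genomes, not a BWA replacement.
- The NB exact-style test enumerates the conditioned sum; for very deep
  counts (sums ≫ 10⁵) it becomes slow and a normal-approximation variant
  would be preferable.
- The repeat flag's seed-and-extend contract requires an exact shared
  20-mer; diverged repeats below ~90% local identity can escape seeding in
  principle (at > 80% identity over > 50 bp a shared 20-mer is very likely,
  but not guaranteed).
- "Support" counts samples via a Jaccard ≥ 0.5 rule against the cluster
  consensus; pathological many-sample mosaics could in principle split
  clusters. Not observed on the study conditions tested.
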