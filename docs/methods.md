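# Methods

## Co-binding from summit proximity

Two transcription factors are taken to co-bind a region when their
ChIP-Seq peak summits lie within a threshold distance of each other. For
each peak of a query cistrome the package finds the nearest reference
summit on the same chromosome (binary search on per-chromosome sorted
summit arrays; validated against an all-pairs scan) and classifies the
peak as proximal when the distance is strictly below the threshold
(default 120 bp). The co-binding ratio is proximal count over
non-proximal count. Key conventions:

- **Tie at the threshold.** A distance of exactly 120 bp is classed
  non-proximal. The defining phrases "< 120 bp" proximal and "> 120 bp"
  non-proximal leave the boundary unassigned; assigning it to the
  non-proximal class is the conservative choice for co-binding claims and
  is applied consistently (`CobindConfig.proximal_threshold_bp`).
- **Fold-enrichment stringency.** `filter_by_fe` keeps peaks with
  FE ≥ cutoff (inclusive: "FE30" is read as fold enrichment 30 and
  above). The default tiers are 10/20/30 with 30 as high stringency; only
  the high tier has a conventional name, so the lower two are defaults
  the caller can override. Filtering requires every peak to carry an FE
  score and fails otherwise, naming the offending peaks.
- **Orphans.** Query peaks whose chromosome has no reference peak
  contribute no distance; they are counted separately (`n_orphans`) and
  excluded from the ratio and medians. The underlying convention is not
  settled in the field; excluding-and-counting keeps the information
  visible without distorting the statistic.
- **Medians.** Both the median over proximal distances only
  (`median_proximal_bp`) and over all nearest-neighbor distances
  (`median_all_bp`) are reported, since published figures rarely say
  which was used. Even-count medians are midpoint averages.
- **Self-comparison.** When query and reference are the same cistrome
  object, a peak is prevented from matching itself by name identity
  only; a different peak at zero distance still counts.
- **Degenerate cases.** An all-proximal distance set yields an infinite
  ratio sentinel (`math.inf`), logged rather than raised; empty query or
  reference cistromes are errors.
- **Pooling.** Reference cistromes from multiple timepoints are pooled
  by multiset concatenation (duplicates retained). Nearest-distance to a
  pooled reference equals the elementwise minimum over components, which
  the tests verify.
- **Chance proximity.** For a uniformly placed reference of density
  ρ = n/G the nearest-summit distance from a random point is
  approximately exponential with rate 2ρ, so the chance-proximal rate is
  1 − e^(−2τρ). `estimate_cobound_fraction` subtracts this from the
  observed proximal fraction. The estimator is slightly biased low
  because a planted offset |X| ~ Laplace(40 bp) exceeds 120 bp with
  probability e^(−3) ≈ 5%; the bias (≤ 0.04 at f = 0.5) is accepted
  rather than corrected, keeping the estimator free of distributional
  assumptions about the offsets.

Interval overlap (blacklist filtering, cistrome overlap counts) is
any-overlap: one shared base suffices, consistent with half-open BED
coordinates throughout. Chromosome names are matched exactly; a warning
is logged when an input and a blacklist share no names, since a "chr"
prefix mismatch silently filters nothing.

## Peak-to-gene assignment and stratification

Peaks are assigned to the gene whose TSS is nearest the peak summit on
the same chromosome, with distance signed in transcription orientation
(positive = downstream). Ties are broken toward the lexicographically
smallest gene id — deterministic and order-independent. "Close to a
co-bound site" means the gene is the nearest-TSS assignment of the
co-bound query peak; no fixed base-pair window is imposed, matching
TSS-centric annotators' default behaviour. A window mode was considered
and rejected as a second knob that the available evidence cannot set.

Stratification takes four condition-labelled DE gene sets (genotype
WT/KO × time day/night, produced upstream by a differential-expression
pipeline — this package never re-derives DE). For genotype g and time t:

    t-exclusive co-bound(g) = (genes_t(g) \ genes_other(g)) ∩ cobound

and the lost-plus-gained set for time t combines each genotype's
t-exclusive co-bound genes that are absent from the other genotype's
t-responsive set — the genes whose glucocorticoid response at that time
depends on genotype.

## Metagene profiles

Coverage enters as read-start counts per 100-bp bin (or a pre-binned
bedGraph). Each gene contributes a symmetric ±2 kb TSS window (40 bins)
and a 1-kb baseline (10 bins) immediately preceding the window. Two
baseline conventions are implemented because "preceding" is ambiguous:

- **strand-oriented (default):** upstream in transcription direction; a
  minus-strand gene's baseline lies at higher genomic coordinates and its
  window is mirrored so the position axis runs 5′→3′;
- **genomic (`strand_oriented=False`):** always lower coordinates, no
  mirroring.

Per site, fold change = bin count / mean baseline count; the profile is
the unweighted mean over sites. Numerical choices: sites with zero
baseline are excluded and counted (no pseudocount — a pseudocount would
make the profile depend on sequencing depth); windows truncated by a
chromosome edge or overlapping the blacklist are dropped entirely so
every profile bin is backed by sequence; window edges are snapped down to
the track's bin grid (exact when TSSs lie on the grid, as the synthetic
generator guarantees; off-grid TSSs shift the window by < 1 bin).
Profile positions are bin centers (−1950 … +1950 for the defaults).
Uniform coverage yields a profile identically 1, and scaling all counts
by a positive constant leaves the profile unchanged; both are tested.
Read position means the 5′ start; fragment extension is not modelled.

## Motif enrichment

Known motifs are position probability matrices scanned with a log-odds
score (pseudocount 10⁻³, uniform background 0.25) at every offset. A hit
is an offset where either strand reaches the motif threshold, so a
palindromic match counts once; offsets containing N are skipped. The
default threshold is 80% of the motif's maximal attainable score — a
standard operating point when per-motif calibrated thresholds are not
published. Per motif, the observed fraction is the proportion of target
regions with ≥ 1 hit, the expected fraction the same in background
regions; %Ratio = observed/expected (per-region frequencies, an explicit
assumption), and coverage = observed fraction × 100. Tables are filtered
(%Ratio ≥ 1.5 and coverage ≥ 5%), deduplicated and ranked by descending
%Ratio. "Duplicate motifs" is operationalised as identical IUPAC
consensus after degenerate-base collapse at probability 0.6 (single base
if it reaches 0.6, else a two-base code if the top pair does, else N);
the higher-%Ratio member is kept. Background regions, when not supplied,
are sampled length-matched and uniformly from the non-target genome.

## ddPCR spike-in normalization

One sample's spike-in concentration (copies/µl of the PCR reaction) is
the reference; each sample's factor is reference spike-in divided by its
own spike-in, and targets are multiplied by the factor. The reference
sample is an explicit argument defaulting to the first sample, since no
selection rule is standard. Consequences verified by tests: the
reference's values are unchanged; rescaling all spike-ins by a common
constant changes nothing; changing the reference rescales all outputs by
one constant, so between-sample ratios are reference-independent. Note
that rescaling the *target* values rescales outputs linearly — the
invariance is in the spike-ins only.

## Synthetic studies

The generator emulates the structure the analysis assumes, not real
chromatin. Defaults: a 2 × 5 Mb two-chromosome genome, 1000 reference
and 2000 query peaks, co-bound fraction 0.3, Laplace offset scale 40 bp,
400 genes, per-condition DE overlap 0.2, Poisson coverage rates 5
(background) and 15 (enriched) per 100-bp bin. Rationale for the main
choices:

- Reference summits are uniform; co-bound query summits sit at a random
  reference summit plus a discretized signed Laplace offset — heavy
  tailed like observed summit scatter, and with a closed-form median
  (b ln 2) that the tests exploit. Peak intervals are summit ± 150 bp
  (typical TF peak width; irrelevant to summit statistics).
- Fold enrichment is lognormal with a higher location for co-bound peaks
  (e^3.6 ≈ 37 vs e^2.6 ≈ 13, σ = 0.5), so FE-stringency filtering
  enriches for planted co-binding as it does in real data.
- The four DE sets are built from disjoint planted subsets of the
  co-bound genes (k = round(de_overlap × n_cobound) per condition, which
  bounds de_overlap at 0.25 since 4k planted genes must exist) plus
  shared and condition-specific non-co-bound fillers, so every exclusive
  count is known exactly by construction and the stratifier can be
  checked for exact equality. The default de_overlap of 0.2 sits safely
  inside that bound.
- Coverage enrichment spans ±500 bp around enriched TSSs; TSSs lie on
  the 100-bp bin grid with a 3.5-kb margin from chromosome ends so all
  windows have full geometry.
- Generators are pure functions of (config, seed); stages draw from
  independent substreams so, e.g., regenerating coverage does not
  perturb the cistromes. A genome smaller than 300 bp per requested peak
  is rejected.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: mappability and GC structure,
clustered/correlated binding sites, peak-width variation, replicate
variability, read-level noise, assembly differences (no liftOver), and
chromatin-state spatial correlation. Ground-truth recovery here verifies
the statistics' implementation, not their biological power.

## Problem sizes

The test suite and the acceptance script run at the generator's default
scale: ≤ 500 peaks per side for oracle cross-checks (100 random
instances), 2000 query peaks × 20 replicates for fraction recovery and
subsampling robustness, 5000 planted offsets for median recovery, and
200 genes for metagene profiles — sizes at which the sampling error of
every checked quantity is comfortably below its assertion tolerance.

## Known limitations

- Whether published medians were computed over proximal pairs only or
  over all nearest-neighbor distances is unknowable from figure legends;
  both are reported and neither is asserted as canonical.
- The metagene baseline convention (strand-oriented vs genomic) changes
  profiles for minus-strand genes when coverage is asymmetric; both
  modes are provided and the default is a documented choice, not a
  reproduction claim.
- %Ratio uses per-region hit frequencies; per-occurrence frequencies
  would differ for long regions with repeated motifs.
- Nearest-TSS assignment ignores annotation complexities (alternative
  TSSs, bidirectional promoters); callers supply one TSS per gene.
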