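# Methods

## The fingerprinting model

t-RFLP reads a community out as the size spectrum of fluorescently labeled
terminal restriction fragments. Only the fragment carrying the 5' label on
the forward primer is detected, so each amplified taxon contributes exactly
one fragment: from the forward-primer start to the first restriction cut.
The pipeline's virtual digest predicts those sizes for a curated reference
library; observed peak sizes are then matched back to taxa.

Conventions the field leaves open, declared here:

* **TRF length includes the primer.** The labeled molecule that runs on the
  capillary begins at the 5' end of the forward primer, so the predicted
  length is measured from the primer start to the cut. This is a declared
  convention, not something the assay itself pins down; assignments only
  require that prediction and the synthetic generator agree, which they do
  by construction and by test.
* **No cut site → full-length fragment, flagged.** An uncut amplicon is a
  real labeled molecule and keeps its full length with `no_site = True`.
* **A cut at coordinate zero is skipped** — a zero-length labeled fragment
  is undetectable. No built-in enzyme can produce one (all cut offsets ≥ 1).
* **Leftmost matches.** Only the leftmost forward-primer match is used
  (5'-most priming), and the amplicon ends at the leftmost
  reverse-complement site downstream of it (the shortest product dominates
  PCR). Primer matching honours IUPAC degeneracy and allows zero mismatches
  by default (configurable); ambiguous bases in the target never match.

## Peak processing

Four steps, each with its stated constant:

1. **Noise filter.** Retain peaks with height > noise_mean + k·noise_sd,
   k = 3. The boundary is strict: a peak exactly on the threshold is
   excluded ("within" read as inclusive exclusion). Noise statistics are
   per-sample inputs carried in a sidecar table. Height is filtered, area is
   quantified: baseline statistics are signal heights, abundance is
   peak-area share.
2. **Binning.** Peaks within 1 bp of another represent the same taxon:
   greedy single-linkage chaining over ascending sizes, gap ≤ 1 bp. A chain
   can exceed 1 bp total width — accepted and documented, since the in-assay
   rule is pairwise. The bin representative is the area-weighted mean size.
3. **Relative abundance** = bin area / total area, summing to 1.
4. **Assignment.** Each bin goes to the nearest predicted TRF within 1 bp.
   Ties (equal distance, or several taxa sharing a TRF) keep the whole tied
   set, flagged ambiguous; the trophic role survives only if all tied taxa
   agree. P/C is computed over relative-abundance mass, not bin counts, and
   the mass carried by unassigned or role-ambiguous bins is reported. A
   community with no consumer mass yields an infinite-flagged ratio that is
   excluded from regression.

## Community statistics

Profiles from different samples are aligned onto common bins by re-running
the same 1 bp chaining over all samples' representatives before computing
Bray–Curtis. Grouping uses group-average (UPGMA) linkage cut at 0.40
dissimilarity — the group-average convention of the PRIMER-style workflow.

NMDS minimises Kruskal stress-1, √(Σ(d−d̂)²/Σd²), where disparities d̂ are
fitted to configuration distances by pool-adjacent-violators monotone
regression on the observed dissimilarities. Coordinates update by Guttman
transform; a candidate step is accepted only if it lowers stress (with up to
six step-halvings toward the current configuration), so the accepted-stress
sequence is non-increasing by construction. The first start is the classical
(Torgerson) metric solution, the rest random from the seeded generator; the
best of 20 starts is reported, with the configuration centred and rotated to
principal axes under a fixed sign convention for reproducibility. An
all-equal dissimilarity matrix triggers a degeneracy warning and
`converged = False` while still returning a configuration.

The climate regression is ordinary least squares of untransformed P/C on one
predictor (growing season by default; a log-P/C option exists but is off —
the conventional presentation of this statistic is linear). The slope's
two-sided p-value comes from the t distribution with n−2 df. Before
fitting, the order-of-magnitude outlier rule excludes communities whose P/C
is ≥ 10× both its location mean and the overall mean, means computed without
the candidate; a community that is its location's only member has no peer
mean, so the location criterion cannot be evaluated and it is retained.
Because a signed "R²" is sometimes printed in fingerprinting studies even
though a coefficient of determination cannot be negative, the result carries
r, r² and sign(r)·r² explicitly.

## Read QC and diversity

The de-noising filter evaluates all six criteria for every read — minimum
length 300 bp (untrimmed, barcode and primer in place), mean phred ≥ 25
(arithmetic mean, no windowing), no ambiguous base outside the barcode
prefix, no homopolymer run longer than 6 nt (the run-length reading; a
count-of-runs reading is biologically unmotivated), primer present, barcode
present — so a verdict lists every failure reason. Barcodes match as exact
5' prefixes and the table must be prefix-free.

Rarefaction is the analytic hypergeometric expectation
E[S(m)] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)), evaluated via the hypergeometric pmf;
coverage is E[S(m)]/S. The diazotroph screen matches a curated, editable
lineage-pattern list (Burkholderiales, Rhizobiales, Rhodospirillales,
Nostocales) shipped as package data — curated, not canonical.

## The synthetic generator

The generator provides ground truth for every stage. Defaults define the
study conditions:

| parameter | default | meaning |
|---|---|---|
| n_taxa / producer_fraction | 30 / 0.5 | library size and trophic split |
| n_sites | 64 | communities over 11 locations, g ∈ [0, 92] d/yr |
| β₀, β₁ | ln 2.5, −ln 5/92 | log(P/C) = β₀ + β₁·g; noise-free P/C spans 2.5 → 0.5 |
| σ_pc | 0.3 | between-community log-P/C spread |
| σ_size | 0.15 bp | capillary size-calling error |
| TRF spacing | ≥ 3 bp | engineered separability of library fragments |
| area_scale / σ_area | 60000 / 0.15 | signal strength and lognormal area noise of a well-run assay |
| spurious rate / noise | 5 per sample / mean 50, SD 10 | baseline artifacts; spurious heights drawn below the 3-SD threshold |
| reads per sample / defect rate / error rate | 1000 / 0.1 / 0.005 | sequencing emulation for 4 representative communities |

Reference sequences are engineered (flank + primer + insert + site + tail +
reverse-complement primer + flank) so the first cut lands exactly at the
intended TRF, verified by running the actual digest on every record before
acceptance. Inserts are homopolymer-capped at runs of 5 and the synthesised
barcode+primer head of each read is error-free, so defect-free reads pass
the QC filter deterministically. The log-linear P/C model deliberately
differs from the linear fit applied downstream: recovery tests check sign
and monotonicity of the relationship, not agreement of functional forms.

**What the generator does not emulate:** phylogenetically realistic
sequence evolution, 454 flowgram noise structure, shared community
composition within locations (each site's within-class split is an
independent symmetric Dirichlet, so ordination groups are many and NMDS
stress is high relative to a field study with location structure),
replicate-stone variance structure, and partial-digest or pseudo-TRF
artifacts. Passing tests therefore demonstrate correctness of the
computations and recoverability of the planted climate signal, not that
field data would show these effect sizes.

## Problem sizes and numerical choices

Acceptance-level checks use 1,000 random 300–900 nt sequences per enzyme
for oracle equivalence, 20 count vectors × 10,000 resamples for rarefaction,
100 replicate 64-site studies for slope-sign recovery, and 1,000
permutations for type-I control — sizes chosen to keep the full validation
fast on one CPU while leaving Monte-Carlo error well below the margins
being tested. Ties in bin assignment use an absolute 10⁻⁹ bp tolerance;
profile normalisation is checked to 10⁻⁹; NMDS convergence tolerance is
10⁻⁶ stress with 300 max iterations. Seeds are explicit everywhere; a study
is byte-reproducible from `(config, seed)` including its manifest checksums.

## Known limitations

* Cross-sample bin alignment uses the same greedy 1 bp chain rule as
  within-sample binning; dense peak fields could chain across more than
  1 bp, merging distinct taxa.
* The 82%-style assignment rate is reported over bins, not raw peaks.
* The outlier rule's location grouping relies on the optional `location`
  metadata column; without it all samples share one location label.
* Barcode matching is exact; error-correcting barcodes are out of scope.
* OTU construction at 97% identity is out of scope — OTU count vectors are
  inputs, produced here from generator truth.
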