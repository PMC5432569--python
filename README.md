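# hypolith

Analysis pipeline for bacterial communities that colonise the undersides of
translucent desert stones (hypoliths), fingerprinted by terminal restriction
fragment length polymorphism (t-RFLP) of the 16S rRNA gene and validated by
amplicon sequencing.

Hypolithic biofilms are dominated by cyanobacterial primary producers with a
less abundant heterotrophic consumer assemblage. Two questions drive the
analysis: how community composition groups across deserts worldwide, and
whether the balance of producers to consumers tracks macroclimate — in
particular the *growing season* g, the number of days per year when
temperature, moisture and light jointly permit photosynthesis.

## What the pipeline computes

**Virtual digest.** For each curated reference sequence, the amplicon
delimited by the labeled 341F primer (`CCTACGGGAGGCAGCAG`) and 907R
(`CCGTCAATTCMTTTGAGTTT`, IUPAC degeneracy honoured) is extracted and cut in
silico with a restriction enzyme (MspI `C^CGG` by default; HaeIII and HinfI
are built in). The terminal restriction fragment (TRF) runs from the 5'
labeled end to the first cut; an uncut amplicon is kept at full length and
flagged.

**Fingerprint processing.** Electropherogram peaks are filtered against the
baseline (retain height > mean + 3·SD), merged when within 1 bp of a
neighbour (greedy single linkage over sorted sizes), normalised by peak-area
share, and assigned to the nearest predicted TRF within 1 bp. Producer mass
P and consumer mass C are the relative-abundance sums over assigned bins,
giving the producer/consumer ratio **P/C = P / C**.

**Community statistics.** Pairwise Bray–Curtis dissimilarity
d = 1 − 2·Σmin(aᵢ,bᵢ)/(Σa+Σb) over profiles aligned onto common bins;
group-average (UPGMA) clustering cut at 40% dissimilarity; non-metric
multidimensional scaling minimising Kruskal stress-1 with monotone
(pool-adjacent-violators) regression; ordinary least squares of P/C on
growing season, mean annual precipitation, and winter/summer temperature
extremes, after excluding communities whose P/C exceeds both its location
mean and the overall mean by an order of magnitude.

**Read QC and diversity.** 454-style de-noising (discard reads shorter than
300 bp, mean phred < 25, ambiguous bases, homopolymer runs > 6 nt, or a
missing primer/barcode), exact-prefix demultiplexing, analytic hypergeometric
rarefaction E[S(m)] = Σᵢ (1 − C(N−Nᵢ, m)/C(N, m)), Venn-region OTU sharing,
diazotroph screening against a curated lineage list, and nitrogenase (nifH)
OTU tallies.

**Synthetic studies.** A generator emulates the whole study with known
truth: a primer-flanked reference library with unique, well-spaced TRFs;
per-site communities drawn from log(P/C) = β₀ + β₁·g + ε; electropherograms
with size-calling error and spurious baseline peaks; reads with planted QC
defects. Every pipeline stage is validated against this ground truth.

## Worked example

The numbered scripts under `analysis/` run the full study on a 64-community
synthetic bundle (11 locations, growing seasons 0–92 d/yr) and write their
tables under `results/`:

```
$ python analysis/01_simulate_study.py
study: 64 communities over 11 locations, 30 reference taxa, 4000 reads for 4 sequenced communities
$ python analysis/03_fingerprints_pc.py
fingerprints: 64 communities processed
median |P/C error| = 0.057; 62/64 within 20% of truth
mean peak-to-taxon assignment rate = 1.000
$ python analysis/04_ordination_climate.py
ordination: 36 groups at 40% cutoff, NMDS stress-1 = 0.313
outliers excluded: none
P/C ~ growing season: slope = -0.0245, r^2 = 0.594, p = 9.4e-14 (n = 64)
```

The negative slope says communities with shorter growing seasons carry a
larger producer share — the fingerprint pipeline recovers the sign and
strength of the relationship the generator planted, through size-calling
noise, spurious peaks and the full peak-to-taxon assignment chain.
`05_read_qc_rarefaction.py` additionally shows ~91% of reads passing QC
(the generator plants defects in 10%, and a small fraction of defective
reads carry unmatched barcodes) and a deep benchmark community whose
12,000-read subsample informs ~98% of observed richness.

The same stages are available as a CLI
(`hypolith simulate|digest|trflp|stats|qc|rarefy|run`); `hypolith run
--config cfg.yml` executes everything and writes a versioned JSON report.

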