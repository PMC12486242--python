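# Methods

## Scope and model

`muflap` analyses the activity of temperate phages integrated in bacterial
chromosomes, for the two excision biologies seen in marine *Citromicrobium*
polylysogens and many other systems:

* **Mu-like (transposition-type) prophages** integrate and replicate by DNA
  transposition. Insertion duplicates a 5-bp host target with consensus
  **NYSRN** (N any; Y = C/T; S = G/C; R = A/G) at both prophage ends. During
  lytic growth, replicative transposition copies the genome into new
  chromosomal sites; headful packaging then carries ~tens to hundreds of
  nucleotides of flanking host DNA into each capsid. The 20 nt of host
  sequence immediately outside each genome end (the **5'flap**) identifies
  the chromosomal site that copy occupied.
* **Integrase (site-specific) prophages** excise by attL × attR
  recombination, restoring attP on the excised circle and attB on the
  chromosome; rolling-circle replication and cos cutting define the packaged
  genome termini.

From these two observables the package derives:

1. **Burst size** — each mature Mu-like particle corresponds to one
   transposon copy, and a cell's transposon load is the original copy plus
   *n* duplicates, so with original-flap count *x* and new-flap count *y*
   the average burst size is `(x + y) / x = 1 + y/x = 1 + n`.
2. **Transposition target preference (TTP)** — per gene, new-flap hits
   normalized by the gene's NYSRN count; genes ranked and split into six
   bins; per (subsystem category, bin) a hypergeometric tail test at raw
   P < .01; a category enriched in top bins *and* depleted in low bins is a
   hot spot, the mirror image a cold spot.
3. **Spontaneous induction (SPI)** — in cellular DNA, new flaps evidence
   Mu-type induction; 20-mers spanning the restored attP junction
   (L-attP-R), screened to be absent from the lysogen chromosome on either
   strand, evidence integrase-type excision.
4. **Abundance scaling (Piggyback-the-Winner diagnostics)** — RPKM (reads
   per kb of genome per Mbp of sample) per entity and fraction, strict
   abundance filters (host > 0.1, prophage > 0.01), per-station virus-host
   ratios, and an OLS fit of log10 phage on log10 host abundance whose
   exponent classifies the scaling.

## Matching policy

All sequence matching is exact over the A/C/G/T/N alphabet: anchors
(20 nt of prophage terminus), flap mapping (unique exact 20-mer occurrence,
both strands, origin-crossing windows on circular chromosomes), and junction
signatures. This mirrors a 100%-identity / 100%-coverage mapping stance:
substitution errors cost sensitivity but cannot create a perfectly mapping
spurious flap. Genomic `N` is unknown sequence, never a wildcard, so masked
regions (`mask_regions`) contribute neither motifs nor matches. Ambiguity
codes other than N are rejected at parse time.

Coordinates are 0-based half-open everywhere internally. Multi-mapping
(ambiguous) flaps are excluded from both x and y — conservative and
symmetric. Identical flap sequences from independent reads are counted once
per read (reads proxy particles); an opt-in dedup mode counts distinct
flaps once.

## TTP details and choices

* Flap-to-gene crediting requires the flap's full 20-nt interval inside the
  gene, symmetric with motif crediting (the 5-mer fully inside the gene), so
  numerator and denominator use the same ruler. Boundary-spanning events
  count genome-wide only.
* NYSRN is its own reverse-complement pattern, so a single-strand scan
  suffices; a both-strand count would be exactly 2× and leaves every rank,
  bin and call unchanged. Overlapping occurrences all count.
* Genes with zero NYSRN sites cannot host targeted events; they are excluded
  from scoring (0/0 undefined) and reported separately.
* Ranking ties break on motif count (descending) then gene id, so binning is
  deterministic. Bins are contiguous rank blocks as equal as possible,
  earlier bins taking the remainder.
* "Top" bins default to {1, 2} and "low" bins to {4, 5, 6}; the split is a
  documented, configurable choice.
* Raw P < .01 without multiplicity correction is the deliberate default
  (matching the procedure the analysis reproduces); a BH-FDR helper exists
  but is off by default.

## Burst-size estimation regimes

The lossless regime (`simulate_reads(mode="tile_junctions")`) emits the same
number of junction-covering windows for every molecule end, which makes the
estimator identity exact: burst = 1 + n bit-for-bit, for any n. The uniform
regime draws random fragment starts at a target depth with substitution
errors; there the estimate carries binomial sampling error, and a
delta-method standard error for y/x (`(y/x)·sqrt(1/x + 1/y)`) describes the
subsampling spread well (checked over 20 subsample replicates).

Burst is undefined when x = 0 (no original flaps recovered) and raises.

## Induction signatures

The junction of the excised circle is built as (last 20 nt of prophage
genome) + attP + (first 20 nt). Signature 20-mers must span the entire attP
— this guarantees they cannot arise from attL or attR alone — and are
discarded if they occur anywhere on the lysogen chromosome or its reverse
complement. An empty signature set (attP context re-occurring elsewhere) is
a warning at build time and an error at detection time. One signature read
suffices for an induction call by default (`min_evidence=1`).

The terminus detector is a deliberately simple read-start-pileup heuristic
(positions with start counts ≥ 20× the median nonzero start count per
strand), not a full terminal-redundancy analysis; it recovers a cos cut
when molecule ends are obligate fragment boundaries, as in sequencing of
packaged particles. It is therefore run on particle-like reads from the
cos-linearized circle, not on dilute cellular DNA.

## Abundance scaling details

RPKM = reads / (length/1e3) / (sample_bp/1e6), with the sample size taken
as post-quality-filter base pairs. Filters are strict inequalities and
idempotent. VHR pairs the virion-fraction phage RPKM with the
cellular-fraction host RPKM of the same station. The power-law exponent is
fitted by OLS on log10 scales (the slope is log-base invariant); the 95% CI
classifies it — sublinear if the CI is inside (0, 1), linear if it contains
1 and excludes 0, superlinear if the lower bound exceeds 1, else
indeterminate. Classification by CI rather than point estimate is an
explicit substitute for an unstated significance procedure; at n = 60
stations with lognormal noise sd 0.2 the per-seed reliability of the
classification is the nominal CI level, so occasional misclassifications
across seeds are expected sampling variation. Spearman correlations use
average ranks; a correlation against a constant vector (e.g. VHR on exact
linear data) is reported as 0.

## The synthetic-data generator

The generator defines the study conditions; every default is fixed once:

| parameter | default | why |
|---|---|---|
| genome_length | 50 kb | desk-scale chromosome, ~6.2k NYSRN sites (density 1/8) |
| n_genes / gene_length | 40 genes, 800 bp mean, lengths in [0.5, 1.5]× | variable lengths make per-gene motif counts informative |
| categories | 18 hot / 18 cold / 4 hypothetical | with six ~7-gene bins, depletion at k=0 reaches P<.01 only when a category covers ≳45% of genes; smaller categories could never satisfy the hot/cold conjunction |
| hot/cold multipliers | 10× / 0× | planted preference and avoidance |
| mu/ss prophage length | 2 kb each | desk scale; attP 12 nt, cos 12 nt |
| immunity_margin | 100 nt | Mu self-immunity: no targets inside or near the resident copy (also keeps new flaps distinct from native flanks) |
| n_events | scenario-dependent (5 default, 5000 for TTP) | the transposon copy number *n* |
| replacement | without (default); with, for population-scale TTP | distinct sites keep burst = 1+n exact; independent cells may hit the same site, and 5000 events exceed the distinct eligible sites on a 50-kb chromosome |
| flank_capture | 150 nt | ≥20 enforced so flap extraction always has material |
| read_length / depth / error_rate | 100 nt / 30× / 0 | substitution-only error model; indels are pure noise to an exact-match pipeline |
| cell_reads / spi_rate | 30 000 × 150 nt / 0–0.05 | ~45 induced reads per prophage at spi 0.01, enough for reliable ≥1-read detection |
| metagenome | 60 stations, host log10 ~ N(0.5, 0.4), noise sd 0.2 | slope SE ≈ 0.065, so exponents 0.5 and 1.0 separate cleanly |

Emitted counts in the metagenome tables are expected read numbers
(consistent with the RPKM formula to machine precision), so a noise-free
simulation is recovered exactly by the estimator.

What the generator does **not** emulate: platform error profiles, indels,
paired-end inserts, GC or coverage bias, strain mixtures, real subsystem
ontologies, or transposition strand bias (copies insert in the forward
orientation). Passing tests therefore demonstrate correctness of the
estimators under their stated assumptions, not robustness to every real
sequencing artifact.

## Numerical and degenerate-input choices

* Hypergeometric tails come from `scipy.stats.hypergeom`; tests verify them
  against exact rational enumeration (`math.comb` + `Fraction`) for every
  population up to N = 25 at |Δ| < 1e-12.
* Circular sequences are stored linearly; wrap-around operations extend the
  sequence by k−1 virtually. Positions are reported modulo the length.
* Genomes shorter than the motif (linear) scan to an empty hit list; empty
  annotation sets, all-zero abundance weights, fewer scored genes than bins,
  <3 paired stations, and x = 0 all raise with specific messages.
* All generator randomness flows from a single integer seed through
  per-stage `numpy` Generator streams; identical configs produce identical
  output bytes.

## Problem sizes

Default scenarios run on a single core in seconds: the largest routine
analysis (5000-event TTP with one junction read per molecule end, ~10k
reads) completes in ~1.5 s; the full test suite including twenty-seed
controls runs in a few minutes. These sizes were chosen as comfortable
desk-scale conditions for a 50-kb synthetic chromosome; the in-memory exact
matcher is not intended for real 3-Mb chromosome read sets, where an
external mapper produces the count tables this package consumes.

## Known limitations

* Flap extraction assumes the prophage terminal 20-mers are unique within
  the packaged molecules; terminal repeats would need longer anchors.
* The cos detector is a pileup heuristic and will miss termini in data
  without end-biased fragment starts.
* TTP depletion power is bounded by bin size: with six bins over 40 genes,
  only large categories can be called; finer systems need more genes or
  fewer bins.
* The accession-scale quantities reported for the real induced-phage
  datasets (tens of thousands of new flaps, burst sizes ~10²) are not
  reproduced here; they require the deposited read sets.
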