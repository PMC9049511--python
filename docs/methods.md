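# Methods

`haplodate` implements the inference chain used to place a landrace dog
population among modern herding breeds and to date breed divergences from
SNP array genotypes. This note records the models, the defaults and why,
the numerical choices, and what the built-in simulator does and does not
emulate.

## The analysis chain

1. **Genotype QC and merging** (`haplodate.io`). Diploid biallelic SNPs in
   PLINK PED/MAP or VCF. Call-rate filtering removes samples first, then
   markers (default threshold 0.90 for both — the filter used for array
   genotype calling; whether it was applied per sample, per marker, or
   both is not derivable from the protocol text, so both are applied by
   default and each is configurable). Merging intersects marker sets on
   (chromosome, bp), reconciles swapped or strand-flipped allele
   encodings, and drops strand-ambiguous A/T and C/G markers rather than
   guessing strand, because a silently flipped allele corrupts
   D-statistics downstream.

2. **IBS/NJ phylogeny** (`haplodate.phylo`). Pairwise distance is the
   mean per-marker allele-mismatch fraction (identical genotypes 0, het
   vs hom 0.5, opposite homozygotes 1), with markers missing in either
   sample dropped from that pair's denominator only ("flat missing").
   Trees are Saitou–Nei neighbor joining. Q-criterion ties are broken by
   the lowest index pair, making the output deterministic; negative
   branch lengths are clamped to zero after counting (the analyses use
   cladogram topology and support, so lengths are secondary). Support is
   the percentage of marker-bootstrap replicates (markers resampled with
   replacement, default 100 replicates) containing each bipartition of
   the full-data tree. Consensus is extended majority rule: >50%
   bipartitions first, then compatible ones in decreasing frequency.
   Rooting places the root at the midpoint of the outgroup's pendant
   edge. `monophyly_frequency` reports how often a label group (or group
   + query breed — both readings of "clustered with" are exposed) forms a
   clade across replicates.

3. **Haplotype sharing** (`haplodate.sharing`). On phased haplotypes,
   shared segments are maximal runs of marker-wise identity between any
   of the four haplotype combinations of a sample pair. Runs are found in
   windows of 1,000 markers with consecutive windows sharing 25 markers,
   then merged across window boundaries; thresholds (default ≥25
   informative markers and ≥1.0 cM) are applied after merging, which
   makes the output provably independent of the window step (tested
   against a genome-wide scan). The window overlap exists only so that no
   segment is split at a boundary; "overlap of 25" is read as
   25 shared markers between consecutive windows (step 975), not step 25.
   Missing sites are wildcards: they neither break a run nor count toward
   the marker minimum — conservative under array no-calls. A sample
   pair's total is the summed bp length over all four combinations and
   all chromosomes (a max-combination alternative is provided). Exact
   matching on phased input replaces a probabilistic, genotype-error
   tolerant IBD HMM; it is deterministic and equivalent on error-free
   simulated data, and real-data use requires externally phased input.

   **Significance rule.** A breed pair's sharing is the median of its
   cross-breed sample-pair totals. The threshold is the 95th percentile
   (linear interpolation, "type 7") of across-clade sharing, and a pair
   is flagged when its median strictly exceeds it. Two threshold bases
   are provided. The default takes the percentile over the across-clade
   breed-pair *medians*; note that this flags the top ~5% of across-clade
   pairs by construction whenever their medians differ, which is how an
   empirical-null cutoff behaves. `threshold_basis="pair-totals"` pools
   the individual sample-pair totals of across-clade pairs instead, so a
   breed-pair median is compared against the bulk of cross-clade sharing
   and an all-negative across-clade outcome is possible. The published
   description does not disambiguate the two.

4. **Divergence dating** (`haplodate.dating`). Total shared length y (bp)
   is modelled as linear in years since divergence x:
   `y = m·x + b`. The built-in published line is
   `y = −8,736,150·x + 1,501,072,917` (r² = 1), anchored at sampling year
   2019 and calibrated on events 35–160 years before sampling; fitting
   uses ordinary least squares. Inversion x̂ = (y − b)/m converts a breed
   pair's median sharing into years, and calendar year = sampling year −
   x̂. Estimates above the intercept (negative x̂) or outside the 35–160
   year regime are flagged, never clipped — the published tables
   themselves report one out-of-regime value with a footnote. Per-breed
   date ranges are the min/max calendar year over a partner set.
   A known caveat reproduced in simulation: for very recent splits the
   inverted age has strongly inflated relative variance (the calibration
   is least reliable for closely related pairs).

5. **Diversity statistics** (`haplodate.diversity`).
   * Inbreeding F per sample by method-of-moments homozygosity excess
     (O − E)/(N − E) with E from cohort allele frequencies under the
     2n/(2n−1) small-sample correction; monomorphic markers excluded.
     The frequency cohort (all samples vs per breed) is configurable and
     defaults to the full analysis cohort.
   * Nucleotide diversity per SNP as (2n/(2n−1))·2p(1−p) with 2n the
     typed allele count, summed per non-overlapping 500-kb window and
     divided by the full 500,000 bp span, so SNP-free sequence dilutes
     diversity exactly as invariant sites do.
   * Ne from LD via Sved's relation E(r²) = 1/(1 + 4Nc): dosage r² per
     genetic-distance bin, adjusted by 1/n for sample size (no mutation
     correction by default; the α = 2.2 variant of the distance scale is
     out of scope), inverted to Ne(t) with t = 1/(2c̄) per bin; default
     bins span 13–150 generations ago. Bins with fewer than 30 marker
     pairs are suppressed.
   * ABBA-BABA D on population allele frequencies:
     abba = (1−p1)p2p3(1−p4), baba = p1(1−p2)p3(1−p4),
     D = Σ(abba−baba)/Σ(abba+baba), with a leave-one-block-out jackknife
     over 5-Mb physical blocks (configurable) for SE and Z = D/SE.

## The breed-formation simulator

`haplodate.simulate` is a forward Wright–Fisher diploid simulator:
a root pool of standing variation, scheduled splits, optional admixture
pulses, recombination, no new mutation. Defaults define the standard
study conditions used throughout the test suite:

| parameter | default | why |
|---|---|---|
| genome | 2 chromosomes × 100 cM × 5,000 markers | desk-scale stand-in for a ~150k-SNP array at realistic marker density (1 cM ≈ 1 Mb) |
| founder frequency law | Uniform(0.05, 0.95) | mimics common-SNP array ascertainment; avoids near-fixed markers |
| branch Ne | 200 diploids | small, breed-like effective sizes |
| root pool | 500 diploids, 100 generations of pre-split mating | see below |
| samples | 10 per population | matches the study's random groups of 10 |
| generation time | 3.0 years | conventional dog value; only converts simulated generations to years |

Recombination draws a Poisson number of crossovers per chromosome and
gamete (no interference) with uniform placement on the cM map. A split
copies the parent pool into each branch; a pulse at generation g redraws
each parent of the target from the source with probability f (f = 1
replaces the population). Everything is driven by one seed;
identical configs and seeds are bit-identical.

**Why the root pool has its own history.** If the radiation starts
directly from i.i.d. founder haplotypes, no haplotype sharing exists
across the first split at all — every cross-population pair is unrelated
— and the dating signal vanishes. Conversely a small root pool left to
drift for a long time fixes most markers and sharing saturates. A root
of 500 diploids with 100 pre-split generations sits between these
regimes and produces a monotone, roughly linear decay of median sharing
over splits of 10–50 generations, which is the regime the linear
calibration targets.

**Calibration panels.** `make_calibration_panel` simulates pairs with
known split times. By default all pairs branch off one shared ancestral
pool in a single simulation, the way real calibration breed pairs share
one genomic background. The alternative (`independent=True`) simulates
each pair in an isolated world; it is provided for completeness but the
independent ancestral-pool realizations contribute ~9% noise to total
sharing, which a leave-one-out fit over four points amplifies to ~50%
median age error — the shared-background design is both more faithful to
how the published calibration was built and statistically usable.

**What the simulator does not emulate.** Genotyping error and missing
calls (phasing is exact by construction, so the exact-match IBD detector
sees error-free input); array ascertainment beyond the founder frequency
law; sex chromosomes; mutation; selection; overlapping generations;
pedigree structure within breeds. Passing tests therefore demonstrate
the statistical machinery under clean, known demography — not robustness
to real-data noise, for which externally phased, QC'd input is assumed.

## Numerical choices and degenerate inputs

* Percentiles use linear interpolation between order statistics.
* NJ on fewer than 3 taxa, a pair with zero co-typed markers, an all-x
  calibration, empty monophyly groups, windows with no typed SNPs, LD
  bins with <30 pairs, and D with no informative sites each either raise
  a named error or report a missing value with a warning, as documented
  per function.
* PED round-trips: markers monomorphic in a file load as dosage 0 with a
  placeholder second allele, since PED carries no allele order.
* Internal interval arithmetic is 0-based half-open; file formats are
  1-based at the boundary. Physical segment length is
  bp(last marker) − bp(first marker) + 1.

## Test-suite problem sizes

The simulation-based suite runs the standard conditions above: the
three-clade significance scenario (9 breeds × 8 dogs, splits 15/150
generations) over 10 seeds, the calibration panel at splits
{10, 20, 35, 50} generations over 10 seeds, constant-Ne LD recovery
(Ne = 100, 200 generations) over 5 seeds, and pulse/no-pulse gene-flow
detection over 10 seeds, with the 2 × 100 cM × 5,000-marker genome
throughout. Brute-force oracles (exhaustive tree search, naive
maximal-run scanning) validate the fast implementations on smaller
random fixtures.
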