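# Methods

## Scope and model

`sewaves` analyzes an H3K27ac ChIP-seq time course over two arms — a
vehicle control ("EtOH") and an inducer ("ATRA") at days 2, 4 and 8, one
ChIP sample per time point — together with a replicate-level expression
matrix, a gene/TSS annotation with transcription-factor flags, a genome
FASTA, JASPAR-format PWMs and a GWAS SNP table.  Alignment, peak
calling and expression normalization are upstream: the pipeline
consumes peak calls (narrowPeak), coverage (bedGraph) and normalized
counts.

All coordinates in memory are 0-based half-open; SNP tables declared
1-based are converted exactly once at read time.

## Super-enhancer calling

Rank Ordering of Super-Enhancers, reimplemented:

1. *Promoter exclusion.*  Peaks whose midpoint is within ±2,000 b
   (closed bound) of any TSS are removed entirely before stitching.
2. *Stitching.*  Transitive merge of peaks with inter-peak gap
   ≤ 12,500 b per chromosome.
3. *Scoring.*  load = max(0, treat − input) coverage summed over the
   region.  Negative input-subtracted loads are floored at zero: a
   negative enhancer load has no ranking meaning and destroys the
   min–max scaling of the rank curve.
4. *Tangent cutoff.*  With loads sorted ascending, x = i/(n−1) and
   y = load/max(load), the cutoff index is argmax(x − y); for a convex
   hockey-stick curve this is where the slope-1 line is tangent.  Ties
   resolve to the largest index (fewest SEs), so an all-equal curve
   yields zero SEs.  The SE flag is strict: load > cutoff.
5. *Amplification masking.*  Regions overlapping user-declared
   amplified intervals are excluded from the cutoff fit (one amplified
   locus otherwise compresses the scaled curve and absorbs the whole SE
   budget) and then re-flagged against the fitted cutoff.  Masking is a
   declared substitute for the unspecified "account for amplification"
   adjustment; it never changes the flag of a region whose load is
   below the unmasked cutoff.
6. *Gene assignment.*  Every gene overlapping the SE or with TSS within
   50 kb (inclusive) of a boundary is paired with it; distance is 0 for
   overlap, else the distance to the nearer boundary.

RPM = count × 10⁶ / total mapped reads; RPMPR divides by reads falling
within peaks instead.

## Temporal partition and waves

Per-sample SE calls are concatenated and merged on any overlap into the
master set; membership of a sample SE in a master SE additionally
requires ≥ 50% of the smaller interval to overlap.  Profiles are RPM
over the master interval per sample.

Filters run in a fixed order on the treated time axis
(baseline = control day 2, then treated days 2/4/8):

* **stable** — sample-SD/mean (CV) < 0.30.  "SD < 30%" is only
  unit-free as a coefficient of variation, which is how it is read
  here.  A flat-zero profile counts as stable.
* **condition-invariant** — among non-stable SEs, max over days of
  |treated − control| < 200 RPM.  This reads the "max variance < 200"
  rule as a day-matched arm difference: an SE whose temporal change is
  reproduced in the control arm is time-driven, not treatment-driven,
  and is removed before clustering.  The source procedure's wording is
  ambiguous between a variance and a difference; the difference reading
  is declared here because it reconciles the "< threshold" direction
  with removing SEs that "change under both conditions".
* **dynamic** — everything else; z-scored per SE over the 4-point time
  axis (population SD; constant rows map to zero) and clustered with
  K-means (Lloyd, k-means++, n_init = 25, seeded; default k = 5).  A
  WCSS elbow table over k = 2..8 is emitted alongside.  Cluster labels
  come from the centroid argmax position (baseline → lost, day k →
  wave_k); clusters sharing an argmax merge under one label, which is
  how k = 5 reports four waves without discarding members.

The partition identity (stable + invariant + dynamic = total; wave
counts sum to dynamic) is asserted, not assumed.

## SE–gene linking

Candidate pairs come from the 50 kb assignment on dynamic master SEs.
Pearson r is computed between the SE RPM profile and gene expression at
**replicate resolution**: each expression replicate of a condition/day
is paired with that condition/day's single ChIP value (default 3
replicates × 6 condition-days = 18 matched points).  With only six
condition-day points the null distribution of r is so wide that a fixed
r ≥ 0.45 cutoff cannot separate real from permuted links
(P(r ≥ 0.45) ≈ 17% under a time permutation); replicate-resolution
pairing uses the information the replicated expression assay actually
carries and makes the cutoff discriminative.  The default rule is
signed r ≥ 0.45; a switch to r² ≥ 0.45 exists because both forms of
the threshold are in circulation.  Constant vectors yield r = NaN and
never pass.  No multiple-testing correction is applied — the procedure
is a fixed-threshold filter by design.

Group shifts are tested with a paired two-tailed t-test
(t = mean(d)/(SD(d)/√n), df = n−1).  All-zero differences return
(t = 0, p = 1); a nonzero constant difference vector has zero variance
and no finite t, and is rejected as degenerate.

## Core regulatory circuitry

PWMs are JASPAR count matrices normalized with a 0.01 per-cell
pseudocount; scanning scores log₂(p/background) summed over positions,
on both strands (N scores −∞), with the default threshold at 80% of
each PWM's maximum achievable score — chosen so that, for the sharp
synthetic PWMs, only exact consensus matches fire, making recovery
exactly testable; it is configurable in bits for diffuse real motifs.
Edge a → b exists when PWM_a hits inside any correlation-passing
("active") SE of TF b; self-edges are retained per CRC convention.
Nodes are ranked by mRNA expression (deterministic tie-break by name).
The LEAF document (JSON) and a DOT rendering are byte-deterministic.
Inward binding of a TF is its count of distinct in-neighbours; outward,
distinct out-neighbours.  SNP intersection is strict half-open
containment, carrying the SNP's GWAS statistics verbatim.

## Synthetic data generator

Each enhancer locus occupies its own small contig: SE loci (12 kb)
carry three 1 kb constituent peaks at 2/4/6 kb and one gene with TSS at
10 kb; typical-enhancer loci (4 kb) carry one weak peak and no gene.
This makes stitching, gene assignment and linking exactly separable, so
planted truth is recoverable without ambiguity — at the cost of not
exercising cross-locus interference, which the unit suites cover with
random configurations instead.

Class RPM templates over (EtOH 2/4/8D, ATRA 2/4/8D):

| class               | EtOH          | ATRA          |
|---------------------|---------------|---------------|
| stable              | 500, 500, 500 | 500, 500, 500 |
| condition-invariant | 300, 600, 900 | 320, 620, 880 |
| lost                | 560, 600, 640 | 350, 160, 60  |
| wave_2d             | 70, 80, 90    | 400, 230, 130 |
| wave_4d             | 90, 80, 70    | 160, 400, 230 |
| wave_8d             | 70, 80, 90    | 130, 230, 400 |

Typical enhancers draw a constant level from U(10, 40) RPM; each SE
gets one multiplicative level factor from U(0.8, 1.25).  Waves peak at
~5× their baseline with graded shoulders — closer to observed H3K27ac
gain magnitudes than an on/off spike — and the control arm drifts by a
few percent of the dynamic range rather than being frozen.  Default
class counts are 143/116/254/174/355/157 (stable/invariant/lost/
waves), with 600 typical enhancers; per-class TF quotas default to
10/10/31/17/49/15.  These levels were fixed once from the band
structure of the per-sample tangent cutoff (active SEs must always
clear it, typical enhancers never) and the discriminativeness of the
r ≥ 0.45 filter, and are not tuned per run.

*Noise model.*  Per-peak counts are negative binomial with mean
template × mapped-total/10⁶ (split over constituents by length) and
variance μ + (d·μ)², i.e. the `dispersion` parameter d is the
multiplicative CV of the signal at large mean — d = 0.05 means 5%
count noise, d = 0 is the exact noiseless limit (counts equal their
means).  This CV parameterization keeps the knob directly comparable to
the 30% stability threshold.  Gene expression per replicate is
intercept + slope × (linked SE RPM) + N(0, σ), clipped at 0; defaults
are noiseless so that the default bundle is the exact-recovery fixture.
One stable SE is optionally "amplified" (level × 10) and its interval
reported for cutoff masking, emulating a high-copy oncogene locus
without changing the master-set size.

Motif planting writes each source TF's consensus at fixed spaced
offsets inside the target TF's SE; the SE background is
rejection-sampled until a full scan with every PWM finds exactly the
planted instances, so CRC recovery has no false positives by
construction.  Consensus k-mers are pairwise (and against reverse
complements) at least 3 mismatches apart.  SNPs are placed inside
dynamic SEs; the first mimics a protective GWAS variant inside a lost
SE.  Identical config + seed gives byte-identical output trees.

What the generator does **not** emulate: read-level data (FASTQ/BAM),
fragment-length effects, replicate structure in the ChIP arm,
non-uniform peak shapes, copy-number variation beyond the single
amplified locus, and genes regulated by multiple SEs.  Passing tests
therefore demonstrate correctness of the algorithms under the stated
noise model, not robustness to every artifact of real ChIP-seq.

## Problem sizes and numerical choices

The default bundle (1,199 SEs, 600 typical enhancers, ~17 Mb genome)
runs end-to-end in a few seconds; oracle comparisons use 1,000 random
load vectors (lengths 3–10⁴), 500 random peak sets, 10 clustering
seeds at 10% noise and 1,000 links for the permutation experiment —
sizes at which the brute-force oracles are still exact and fast.
K-means is bit-reproducible given the seed; all scoring ties break
lexicographically by (chrom, start) or name.  Degenerate inputs are
defined, not special-cased: flat load curves flag no SEs, constant
profiles z-score to zero and correlate as NaN/non-passing, and a
zero-RPM mean classifies as stable.

## Known limitations

* The invariance filter interpretation (day-matched arm difference) is
  one of two defensible readings of its source description.
* Motif scanning covers full SE intervals; nucleosome-free sub-region
  masks can be supplied but are not inferred.
* The CRC uses motif presence only — no clique enumeration, footprint
  or binding evidence.
* Expression correlation assumes the condition/day grids of ChIP and
  expression match; there is no interpolation across missing days.
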