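# sewaves

Temporal super-enhancer (SE) dynamics for treatment time courses:
ROSE-style SE calling from H3K27ac ChIP-seq, master-SE-set construction
across samples, partition of SEs into stable / condition-invariant /
dynamic classes with K-means "wave" clustering, SE–gene linking by
proximity and expression correlation, motif-based core regulatory
circuitry (CRC) graphs with LEAF output, and GWAS SNP–SE intersection.

The package is aimed at regulatory-genomics analysts studying how an
inducer (e.g. a differentiation agent such as all-trans retinoic acid)
reorganizes the enhancer landscape of a cell line over days, and which
super-enhancer-driven transcription factors gain or lose activity in
sequential waves.  A first-class synthetic-data generator emits complete
input bundles with planted ground truth, so the whole pipeline runs and
is testable at desk scale.

## The method

**SE calling (per sample).** H3K27ac peaks whose midpoint lies within
±2 kb of an annotated TSS are excluded; the rest are stitched whenever
gaps are ≤ 12.5 kb.  Each stitched region is scored by its H3K27ac load
(coverage summed over the region, input subtracted, floored at 0).
Sorting loads ascending and min–max scaling both axes to the unit
square, the SE/TE threshold is the tangent point of the line *y = x*
with the rank curve — computed exactly as argmax(*x − y*) — and regions
with load strictly above the cutoff are super-enhancers.  Regions inside
user-declared amplified intervals (e.g. an *MYCN* amplicon) can be
masked out of the cutoff fit and re-flagged afterwards.

**Temporal partition.** Per-sample SE calls are merged (any overlap)
into a master set; each master SE is quantified as RPM
(reads per million mapped reads summed over the region) in every
sample.  SEs with a coefficient of variation < 30% over the treated time
course are *stable*; of the rest, SEs whose day-matched treated-vs-control
difference never reaches 200 RPM are *condition-invariant*; the
remainder are *dynamic*.  Dynamic SEs are z-scored over the ordered time
axis (baseline, day 2, 4, 8) and K-means clustered (default k = 5,
Lloyd + k-means++, 25 restarts, fixed seed); clusters are labelled by
their centroid's argmax — baseline → *lost*, day 2/4/8 →
*wave_2d/4d/8d* — with same-argmax clusters merged, so k = 5 still
reports four waves.

**Linking and CRC.** Candidate SE–gene pairs come from overlap or TSS
within 50 kb of the SE boundary (every qualifying gene, not
nearest-only).  A pair is kept when Pearson *r* between the SE's RPM
profile and the gene's expression over the matched condition/day grid is
≥ 0.45 (replicate-resolution pairing; an *r²* variant is available).
Restricting to transcription-factor genes, a directed CRC edge a → b is
drawn when TF a's binding motif (PWM log-odds scan, both strands,
threshold 80% of the maximum score) occurs in an active SE of TF b; the
LEAF (linked enhancer-activated factors) document ranks nodes by mRNA
expression.

## Worked example

```sh
sewaves simulate --seed 3 -o bundle/          # synthetic inputs + truth
python - <<'EOF'
from sewaves.pipeline import config_from_bundle, run_pipeline
report = run_pipeline(config_from_bundle("bundle", "out"))
print(report["partition"])
EOF
```

prints

```
{'n_total': 1199, 'n_stable': 143, 'n_invariant': 116, 'n_dynamic': 940,
 'n_lost': 254, 'n_wave_2d': 174, 'n_wave_4d': 355, 'n_wave_8d': 157}
```

i.e. of the 1199 master SEs, 143 are stable with treatment and 116
change identically in both arms; the 940 dynamic SEs split into a lost
cluster (254) and three sequential activation waves at days 2/4/8
(174/355/157) — exactly the classes the generator planted.  `out/`
contains every intermediate artifact: per-sample SE tables, the master
BED, RPM profiles, the classification with z-scores, SE–gene links with
correlations, the LEAF JSON/DOT graphs, inward/outward binding counts
and the SNP–SE overlap table (the planted rs2168101-like protective
variant lands in a *lost* SE, carrying its GWAS p-value and odds ratio
verbatim).

A single-sample SE call is also available from the shell:

```sh
sewaves call-se --peaks bundle/peaks/EtOH_2D.narrowPeak \
    --signal bundle/coverage/EtOH_2D.bedGraph \
    --genes bundle/genes.tsv --amplified bundle/amplified.bed -o se/
```

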