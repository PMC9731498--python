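# Methods

This document records the model assumptions, parameter defaults, and
numerical choices behind each stage of `hybridscar`.

## 1. F2 cross simulator (`hybridscar.cross`)

### Genome and recombination

A `GenomeModel` is a list of chromosomes with physical length (bp) and
genetic length (Morgans).  The default example genome is 3 chromosomes
of 100 Mb / 1 Morgan each — deliberately small so whole-litter
simulations finish in seconds; the genetic-to-physical ratio (1 cM/Mb)
is in the mammalian range.

An F1 gamete is simulated per chromosome as a crossover process with no
interference: the number of breakpoints is Poisson(genetic length in
Morgans), breakpoint positions are uniform on the chromosome, and the
starting strain is a fair coin.  An F2 embryo is two independent
gametes; its diplotype at any position is the pair of strain labels, so
catalog sites have 0, 1, or 2 copies of the alternate (strain-9) allele.

### Targeted loci and lethality

Genotypes at named knockout loci (`Fancd2`, `Smad3`) are drawn from the
Mendelian 1:2:1 per-locus distribution independently of the simulated
chromosomes (the loci are abstract labels, not positions).  `SimConfig.lethality`
maps genotype combinations to a death probability applied between
developmental stages; the default kills double knockouts with
probability 0.5 before E12.5, so weaned DKO frequencies are roughly half
of 1/16.

### Instability events

An `InstabilityEvent` has a kind (`CN_LOH`, `DELETION`, `DUPLICATION`,
`CHR_GAIN`, `CHR_LOSS`), an interval, a `haplotype` strain label, and a
`cell_fraction`.  The strain label names the *retained* haplotype for
losses/CN-LOH and the *gained* haplotype for gains.  Per-site copy
numbers inside the event follow from the germline diplotype, e.g. at a
heterozygous site CN-LOH(9) gives 2 alternate copies and 0 reference
copies; at a site homozygous for the other strain it changes nothing.
At sites homozygous for the acted-on strain, gains/losses act on one of
the two identical copies.

The expected VAF at a site is a linear mixture over the aberrant and
normal cell populations, weighted by total copy number, with a symmetric
base error rate `e` folded in:

```
vaf = (alt_weight · (1 − e) + ref_weight · e) / (alt_weight + ref_weight)
```

### Read sampling

Depth at a site is Poisson(mean_depth · copies/2), or negative binomial
with dispersion α (variance m + αm²) when `depth_dispersion > 0`.  Alt
counts are Binomial(depth, expected VAF).  Defaults: mean depth 80
(typical of high-coverage exomes), base error 0.001.

All randomness flows through named substreams:
`substream(seed, *names)` hashes the names with CRC-32 into a
`numpy.random.SeedSequence` child, so every component draws from an
independent, reproducible stream and every derived seed stays below
2³¹.

## 2. VCF I/O and catalog matching (`hybridscar.vcfio`)

VCFs are written as plain VCF 4.2 text with `FORMAT AD:DP` and read
with cyvcf2.  Multi-allelic and non-SNV records are dropped and counted;
missing `AD` becomes depth 0; a file without `FORMAT/AD` is an error.
Catalog matching is an exact set join on (chrom, pos, ref, alt) — allele
identity is required, not just position — over sorted inputs.

## 3. Variant triage (`hybridscar.triage`)

For each site, rank the per-sample VAFs: v1 = highest, v2 = runner-up.

- v1 ≤ `vaf_min` (default 0.05) → `EXCLUDED` (too weak to call anywhere);
- v2 > `second_to_max_ratio` · v1 (default 0.40) → `GERMLINE_OR_FALSE`
  (shared across embryos, so germline or a recurrent artifact);
- otherwise → `SOMATIC`, carried by the single top embryo.

Both comparisons are strict, matching the rule as stated.  Known catalog
sites can be pre-flagged `GERMLINE_OR_FALSE` and bypass the rule.  A
post-pass removes runs of ≥ `cluster_min_count` (default 3) somatic
calls from the same carrier within `cluster_window_bp` (default 1 Mb) —
the signature of a local alignment artifact rather than independent
mutations.  Ties for the top VAF leave the carrier undefined and the
site out of cluster removal.

## 4. Ancestry segmentation and instability scoring (`hybridscar.ancestry`)

A three-state per-chromosome Viterbi pass assigns each covered catalog
site `HOM_REF`, `HET`, or `HOM_ALT`.  Emissions are binomial with
success probabilities e, 0.5, 1 − e (e = `error_rate`, default 0.005 —
deliberately looser than the simulator's base error to absorb mapping
noise).  The probability of switching state between adjacent sites is
1 − (1 − t)^gap with per-bp switch rate t = 1e-7, split evenly between
the two other states; segment boundaries are placed at the midpoint
between flanking sites.  Chromosomes with fewer than two covered sites
fall back to a thresholded single-site call with a warning.  The
dynamic program is exact; tests check it against brute-force path
enumeration.

Instability metrics over sites assigned `HET` with depth ≥ `min_depth`
(default 10):

- `mad_score` — mean |VAF − 0.5|; for a balanced heterozygote at depth d
  this has a closed-form binomial expectation, which tests verify.
- `outlier_fraction` — fraction of het sites with |VAF − 0.5| > δ
  (default δ = 0.15).

**Workflow note.** Scoring a sample against its *own* segmentation hides
clonal CN-LOH: the affected region is confidently reassigned homozygous
and silently leaves the het track.  The supported paired design
segments a matched euploid sibling (or other germline reference) and
scores every sample against *that* heterozygous track.  The paired
acceptance test and `examples/03` both use this design.

## 5. Copy ratios (`hybridscar.cnv`)

Per-sample target depths are normalized to fractions (each sample sums
to 1), removing library-size differences.  The panel of normals is the
per-target median fraction across the designated normal samples; targets
with median ≤ 0 (or below `min_median`) are masked as unusable.  A
sample's copy ratio is its fraction divided by the panel median, then
divided by its own median so a euploid sample centers at 1 (this makes
the acceptance target — median ratio of a euploid sample = 1 — hold by
construction; the informative check is that *aberrant* regions deviate).

Segmentation minimizes Σ(residual²) + penalty·(number of segments) over
log2 ratios with an exact O(n²) dynamic program per chromosome.  The
penalty is 3·σ̂²·log n, with σ̂ estimated from the median absolute
difference of adjacent values (MAD/0.6745/√2).  The multiplier 3 was
chosen by measuring false-breakpoint rates on pure-noise tracks
(multiplier 1 badly over-segments, 2 gives ≈15% false positives, 3
gives ≈6% while still localizing a half-chromosome gain within 2
targets); it trades a little sensitivity for a clean null.

## 6. Statistics (`hybridscar.stats`)

- **Exact binomial test** — scipy's `binomtest` (minimum-likelihood
  two-sided rule); a continuity-corrected normal approximation is
  available as `method="normal"`.
- **Clopper–Pearson intervals** — beta-quantile form with the exact
  closed forms at x = 0 and x = n.
- **Bonferroni** — multiply by m, cap at 1; m may exceed the number of
  p-values supplied but not be smaller.
- **Breeding-frequency table** — per-breed exact test of the DKO count
  against p₀ = 1/16, Bonferroni-adjusted, with 95% Clopper–Pearson
  intervals.
- **Nine-class Mendelian goodness of fit** — chi-square against the
  1:2:1 ⊗ 1:2:1 two-locus class probabilities; when any expected count
  is < 5 the p-value comes from seeded Monte-Carlo resampling of the
  multinomial null instead of the asymptotic distribution.
- **Single-hit model** — the log-likelihood of
  P(negative | dose d) = exp(−f·d) is maximized over log f with a
  bounded scalar minimizer (xatol 1e-12); the Wald CI uses the observed
  information from a central difference.  All-negative and all-positive
  assays are flagged non-identifiable with boundary estimates (0, ∞).
  Group comparison is a likelihood-ratio test, 2(ℓ_a + ℓ_b − ℓ_shared)
  against χ²₁.

## What the simulator does and does not emulate

Emulated: recombinant ancestry mosaics, Mendelian segregation with
lethality, copy-number and CN-LOH events with subclonal cell fractions,
depth overdispersion, uniform sequencing error, shared capture
efficiency across samples.

Not emulated: interference in recombination, linkage between the
knockout loci and the simulated chromosomes, mapping bias and strand
artifacts, true de-novo point mutations, GC-dependent coverage waves,
contamination between samples.  Somatic *point* mutations are absent by
design: in a pure-germline simulation, every `SOMATIC` call is a
sampling artifact, which is what the triage specificity tests exploit.

## Problem sizes

The default sizes (3-chromosome 100 Mb genome, 3,000–20,000 catalog
sites, 1,200–2,000 targets, depth 80) are the package's own choices:
large enough that binomial noise is at realistic exome scale, small
enough that the full test suite runs in well under a minute and the
acceptance suite in seconds.
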