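# Methods

## Scope and data model

The package analyzes biallelic single-nucleotide variants from several
individuals, each called independently against one shared reference
assembly. The central object is the merged genotype matrix: sites sorted by
(chromosome, position) with per-sample states in {hom_ref, het, hom_alt,
missing}. Genotypes are unphased (`0/1` ≡ `1/0`). Internally all intervals
are 0-based half-open; VCF/GFF3 coordinates are converted at the I/O
boundary only, which keeps window binning and codon extraction free of
off-by-one arithmetic.

Because each input VCF lists only the sites its sample carries, merging must
decide what a missing record means. Without further information the package
treats non-carriage as hom_ref; when per-sample callable-region BEDs are
supplied, non-carriage outside a sample's callable track becomes `missing`
instead. Surveys built on a merged callable-site intersection can pass those
tracks explicitly; we do not guess them.

## Site filters

Filters run in a fixed order — missing genotype, triallelic/multi-allelic,
duplication mask, CpG context, proximity — each on the survivors of the
previous stage, with every removed site charged to its first failing filter.
Consequences worth knowing:

- the battery is idempotent (a second application removes nothing), and the
  attrition report reconciles by construction;
- the proximity filter (default 5 bp, symmetric: both neighbours go) is
  evaluated against the surviving variant set only. Indel calls are not an
  input, so proximity-to-indel screening is only possible by supplying
  indel positions in the mask; the filter is honest to the data it sees.
- CpG context is defined on the reference strand only (C followed by G, or
  G preceded by C; chromosome ends count as non-matching). This is
  deterministic without ancestral-state inference, at the price of not
  modelling lineage-specific CpG gain/loss.

All numeric knobs (proximity distance, flank sizes, window size, the
outlier multiplier) are configuration, not constants.

## Carrier sets, sharing, specificity

A sample carries a variant when its genotype is het or hom_alt. Sharing
counts use UpSet "distinct" semantics: each variant contributes to exactly
one subset, its exact carrier set, so subset counts always sum to the
matrix size. A variant is *specific* to a unit (one sample, or one
conspecific pair where both must carry) when its carrier set equals the
unit exactly and its site is not in the outgroup carrier set. The default
outgroup rule excludes any outgroup-carried site; a stricter mode excluding
only sites additionally carried by every ingroup sample is selectable, but
note it is vacuous for proper-subset units (such sites are never specific
anyway) — it exists to make the choice explicit rather than consequential.

Conspecific pairs can be collapsed to a shared pseudo-sample: only sites
both members carry, genotype hom_alt iff both are hom_alt, else het.

## Effect annotation

Each variant receives one region with precedence exonic > splicing > UTR >
intronic > ncRNA > upstream/downstream > intergenic; defaults flank = 1000
bp and splice = 2 bp follow common annotator conventions. UTR5/UTR3 are
collapsed into one UTR category, and all non-coding-transcript hits into one
ncRNA category. "Exonic" means inside a CDS of a coding transcript.

Exonic effects come from codon translation with the standard genetic code,
frame anchored at the annotated CDS start: stop-gain (alt codon is a stop,
ref is not), stop-loss (ref is a stop), otherwise synonymous iff the
residues match. Codons are built strand-aware from the reference; variants
in incomplete transcripts (CDS length ∤ 3) annotate as exonic with effect
`unknown` rather than guessing a frame. A variant hitting several
transcripts reports the most severe effect (stop-loss > stop-gain >
nonsynonymous > synonymous) and retains every transcript's
`TRANSCRIPT:exonN:c.RposA:p.XposY` notation.

The classifier is verified two independent ways: exhaustively against
direct translation of all 576 single-base codon changes, and against
variants planted by the simulator, whose truth labels come from mutating
and translating the whole CDS (a deliberately different code path).

## Window scans and the influence detector

Counts are binned on a fixed non-overlapping grid (default 50 kb; 10 kb and
100 kb are the other sizes worth trying). The partial terminal window is
reported in bin tables with its effective length, but excluded from
influence fitting — unequal exposure fakes influence.

The outlier detector asks, per chromosome and per sample j: regress sample
j's window counts on an intercept plus the leave-one-out mean of the other
samples' counts, and compute each window's Cook's distance via the
hat-matrix form D_i = e_i²/(p·s²) · h_ii/(1−h_ii)², p = 2. A window is an
outlier when D_i exceeds `multiplier` (default 30) times that fit's mean
distance; the per-fit mean gives one threshold per chromosome panel. This
design makes a window influential exactly when one sample departs from the
cross-sample consensus. The regression specification is a declared
interpretation — "Cook's distance over windows among the samples" admits
several designs — and is pluggable through the module's functions.

Two structural facts, established analytically and covered by tests:

- With s² = 0 (identical counts, perfect fit) all distances are defined as
  0 and nothing is flagged; a relative tolerance (s² ≤ 1e-12·mean(y²))
  guards against floating-point residuals masquerading as signal.
- Because mean(D) includes the outlier itself, D_i/mean(D) ≤ n for n
  windows: a threshold of 30× the mean is only exceedable with more than 30
  windows per chromosome. Toy genomes therefore need finer grids (or longer
  chromosomes); genome-scale data with thousands of 50-kb windows is
  unaffected. The detector's power — a single-window 5× single-sample count
  inflation flagged in ≥95 % of replicates — is measured at 60 windows ×
  8 samples with Poisson(50) base counts, a deliberately scaled-down stand-in
  for genome-wide nsSNV scans.

Broad multi-window elevations are the density scan's job (rate per
effective kb against a threshold), not the influence rule's; the
per-sample hotspot in the demo dataset illustrates the difference.

Outlier genes are those overlapping any flagged window that also hold at
least one nsSNV in at least one sample, each reported once with its
windows.

## Enrichment

Over-representation uses the hypergeometric upper tail P(X ≥ k) for k study
hits of a K-gene term, n study genes, N background genes; terms outside the
size range (default 5–500) are dropped before testing and overlaps below
min_k (default 3) after. Benjamini–Hochberg adjustment runs across the
surviving terms. Significance is reported on raw p < 0.05 — the convention
of the surveys this mirrors — with q emitted alongside so readers can apply
the stricter rule; the output makes both visible rather than taking a side.
Term maps and backgrounds are user inputs (two-column TSV or GMT); no
pathway database content is bundled.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

- **Tree-structured sharing.** Mutations are Poisson-placed on branches of
  a fixed rooted tree (intensity = expected count per branch); a branch
  mutation is carried by every leaf below it, so each observed carrier
  subset is a clade (infinite sites: every mutation gets a fresh position;
  a collision-permitting mode exists to exercise triallelic filtering).
- **Genotypes.** Carriers are hom_alt, downgraded to het independently with
  a per-sample probability — the simplest mechanism that dials in an
  arbitrary per-sample heterozygosity spread (the demo uses 0.17–0.63).
- **Substitution process.** The alternate allele is the transition partner
  with probability κ/(κ+1), else one of the two transversions uniformly;
  κ defaults to 2.2, the middle of the 2.17–2.25 range such surveys
  observe, and realized Ti/Tv is checked against binomial error at κ=2.17.
- **Outgroup.** Branches containing the outgroup leaf feed a carrier-site
  set used by the specificity exclusion, mirroring an outgroup mapped to
  the same reference.
- **Hotspots.** Extra sample-private mutations raise one sample's local
  rate by a fold factor inside a window range (the demo plants a 5× hotspot
  emulating a species-specific SNV-dense region).
- **Genes.** Non-overlapping 1–3-exon transcripts with optional UTRs; the
  coding strand is rewritten to ATG + non-stop codons + stop, so effect
  classes are all plantable and proteins are well-formed. Truth effect
  labels are computed at generation time by whole-CDS translation.

Identical config + seed gives byte-identical outputs.

**What the demo conditions do and do not show.** Demo branch intensities
(two 500-kb chromosomes, per-sample totals ≈ 3.4–6.2 k, i.e. 3.4–6.2
SNVs/kb) reproduce the qualitative pattern of a macaque-style survey:
reference-species sample smallest, most-diverged sample largest and most
specific, a low-diversity conspecific pair, per-sample het% spread. A
strict-clade tree cannot also reproduce non-nested sharing: real data show
the most-diverged sample sharing more than any clade structure allows
(incomplete lineage sorting), so demo specific fractions for that sample
run higher than real surveys report. Passing tests demonstrate correctness
of the set logic, not that real macaque sharing is clade-perfect. Likewise
the generator has no linked loci, no mapping error, and no genotype-quality
structure — the filters are exercised mechanically, not calibrated against
sequencing artefacts.

## Numerical and degenerate-input choices

- Percentages are reported to 2 decimals; ratios with zero denominators are
  NaN markers, never exceptions (a sample carrying nothing summarizes as
  zeros).
- Ranked spectra break count ties lexicographically for determinism.
- OLS uses pseudo-inverse normal equations so constant predictors (all
  samples identical) degrade gracefully; leverages are clipped below 1.
- Chromosomes with fewer than 4 complete windows or matrices with fewer
  than 2 samples are skipped by the outlier detector with a logged warning.
- Merging rejects mixed chromosome naming (`chr1` vs `1`) and positions
  beyond the reference length outright.

## Sizes used by the test and acceptance suites

Chosen as the package's own desk-scale study conditions: the demo dataset
is 8 samples × 1 Mb (~15 k merged sites); planted-variant recovery uses 400
variants over 80 genes; the Cook's oracle compares 1000 random fits of 5–25
points; detector power uses 100 replicates of 60 × 8 count matrices; Ti/Tv
calibration uses 100 k mutations on a 400-kb chromosome. Genome-scale
results (tens of millions of SNVs, hundreds of outlier bins) require the
original resequencing data and external pathway databases, which are not
inputs to this package; the published per-sample tables enter only as
printed counts whose derived percentages the summary arithmetic reproduces.
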