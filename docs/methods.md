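# Methods

This note documents the models, conventions and design choices behind
`topoclust`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinate and sequence conventions

All genomic intervals are 1-based and inclusive, matching GFF3; minus-strand
genes keep `start < end` (coordinates are never swapped). A transcription
unit's start position is the `start` of its first transcribed gene on the
plus strand and the `end` of that gene on the minus strand. Promoter windows
are 960 bp — 750 bp upstream of the translation start codon plus 210 bp
downstream — read 5'→3' on the coding strand, so the start codon always
begins at window position 751. Unknown bases (N) count as non-AT, keeping
every 100-bp window's denominator exactly 100.

## Upper-quartile normalization

Each sample is scaled by the 75th percentile of its *nonzero* gene counts,
then multiplied by a common reference (default: the median of the per-sample
upper quartiles, so values stay count-like). The quantile is the
sort-and-index empirical quantile: `sorted(x)[floor(0.75·n)]` (0-based),
i.e. the right-continuous inverse CDF, so `[10, 20, 30, 40] → 40`. This is
deterministic, interpolation-free, and makes normalization exactly invariant
to multiplying a sample's counts by a positive constant. Note it differs
from R's `type = 1` quantile precisely when `0.75·n` is an integer.

## Fold change, testing and SSG classification

log2FC = `log2(mean_treatment / mean_control)` on normalized values, so
induction under the perturbation is positive (the orientation used by the
result tables of studies in this area; some methods texts phrase the
division the other way). The pseudocount is 0 by default; a gene with a
zero mean in exactly one condition falls back to a pseudocount of 1 and is
flagged; a gene with both means zero gets a missing log2FC.

The aligner-integrated test statistics such experiments originally relied
on are tool-internal and unspecified; `topoclust` uses a two-sided Welch
t-test on `log2(normalized + 1)` across biological replicates — simple,
replicate-honest, and well-behaved when variances differ — and records the
method string in every output header. Zero-variance degenerate genes get
p = 1 (equal means) or p = 0 (unequal). Benjamini–Hochberg q-values are
computed over all tested genes and reported, but classification uses the
raw p < 0.05 together with |log2FC| > 1.5 (strictly), i.e. at least a
2.83-fold change; exempted genes (NAPs, topoisomerases) use p alone with
the direction from the sign of log2FC. Exact reproduction of any
particular study's gene lists is therefore not claimed.

## Window scan and cluster calls

Affected genes are mapped to transcription-unit start positions (point
assignment, not interval overlap); windows start at 1 and advance by the
step (default 250 kbp / 125 kbp at full chromosome scale), the final
windows clipped at the chromosome end — the chromosome arms carry genes
too. The per-window percentage uses transcription units in the window as
the denominator by default (`denominator="gene"` switches to genes, since
"percent of affected genes" is ambiguous between the two). Windows strictly
above the 5% threshold that overlap or abut are merged into one call,
because half-overlapping steps make neighbouring windows non-independent;
the peak percent and the member units are reported. Statistical calibration
of cluster calls (permutation p-values) is deliberately out of scope: the
rule is a density threshold.

The hypersensitive-region search maximizes the affected-gene count over all
width-bp intervals anchored at gene starts (default 30 kbp); ties break by
the higher affected/total ratio, then by the leftmost anchor. Both the scan
and the search are validated against brute-force re-enumeration in the test
suite.

## Promoter composition

AT% is computed in 100-bp windows with a 1-bp step and attributed to the
window's first base; profiles keep the full per-sequence matrix so any
position can be tested. Controls are (a) uniformly sampled promoters of
eligible genes (those with the full 750-bp upstream flank — clipping is
never used, so every window is exactly 960 bp) and (b) uniform random
960-bp genomic sequences from either strand. Position tests report
Shapiro–Wilk normality p per set (skipped below n = 3), a two-sample t-test
p (Welch by default; `equal_var=True` gives Student), and additionally a
Mann–Whitney p whenever a set fails normality at 0.05 — the t remains the
primary statistic. The tested positions are plain parameters (defaults 340
and 660); the package attaches no fixed biological label to them, since in
the motivating work one falls in the upstream GC-rich block and the other
in the AT-rich promoter-proximal region.

## ΔΔCt quantification

Technical replicates are averaged at the Ct level within a sample;
ΔCt(condition) = mean target Ct − mean reference Ct; ΔΔCt subtracts the
calibrator's ΔCt; relative level = `2^(−ΔΔCt)` with amplification
efficiency fixed at 2. Replicate dispersion is the ddof-1 standard
deviation of per-biological-replicate levels computed with
replicate-matched reference Cts and is labelled as a standard deviation
(not an s.e.m.). Per-sample constant Ct offsets cancel exactly.

## The synthetic-data generator

The generator emulates the *structure* of a supercoiling-perturbation
study on a GC-rich linear chromosome, not any particular dataset:

- **Genome**: i.i.d. bases at `gc_fraction` = 0.72 (G = C, A = T), giving
  28% AT in expectation; composition converges to the design value as
  length grows (checked at 10⁶ bp within 0.2 points).
- **Annotation**: 900 non-overlapping 600-bp genes tiled over 1 Mb with
  mixed inter-genic gaps; 35% of genes get a ≥960-bp upstream gap so
  promoter windows are extractable for a comfortable excess over the 66
  induced + 66 control promoters. Operons are runs of adjacent same-strand
  genes (40% of genes, mean size 3).
- **Counts**: `NB(mean = 200·2^effect, dispersion = 0.05)` with a common
  dispersion; dispersion 0 degenerates to Poisson for exact null checks.
  Conditions default to control (4 replicates), brief gyrase inhibition
  (3), long-term topoisomerase-I depletion (4) and mild induction (3) —
  within the 2–4 biological replicates typical of such designs.
- **Planted structure**: six up- and two down-regulated clusters
  (|log2 effect| = 3) under the depletion condition, each affecting a
  sampled 50% of its genes — real clusters mix affected and unaffected
  genes, and the >5% window rule must fire well below full penetrance. The
  66 induced genes carry a +3 log2 effect under gyrase inhibition and the
  promoter architecture: +3 AT points over window positions 610–809 (the
  2–3 point excess reported for relaxation-induced promoters) and +5 GC
  points over 290–489 (a clearly detectable but modest block; the
  magnitude of the natural one is not quantified). Both intervals fully
  contain the default tested 100-bp windows (660 and 340).
- **Ct tables**: `Ct_target = Ct_ref − log2(level) + N(0, σ)` with the
  reference Ct constant per sample, so zero-noise analysis recovers planted
  levels exactly.

Every generator is a pure function of (design, seed); per-stage substreams
are derived from one `SeedSequence`, and truth tables of all planted
effects are always written.

What the generator does **not** emulate: sequence-dependent expression,
gene-length or GC bias in counts, correlated dispersion, operon-level count
coupling, real promoter motifs, or genome-scale features (skew, rRNA
operons). Passing recovery tests therefore demonstrates that the analysis
logic is correct and well-calibrated under its stated noise model — not
that any particular biological dataset would yield the same lists.

## Problem sizes and numerical choices

Desk scale is a 1 Mb genome with 900 genes; the full 8.7 Mb / ~7,900-gene
scale is reached by overriding two design fields. On the 1 Mb demo the
window scan runs at 50 kbp / 25 kbp — the chromosome-scale 250/125 kbp
geometry scaled by the genome-length ratio — so the eight planted clusters
remain separable; the API default stays 250/125 kbp. Oracle-equivalence
tests use instances of ≤200 genes; power and calibration of the position
test use 200 and 500 simulations at n = 66 per set. Byte-identical re-runs
are guaranteed by seeding every random stage from the config seed and
keeping timestamps out of output metadata.

## Known limitations

- The Welch-on-log2 test is a stand-in for whatever statistic a given
  upstream pipeline produces; lists will differ near the thresholds.
- Cluster calls inherit the window geometry: clusters closer than one step
  merge, and sub-step-scale structure is invisible.
- The densest-region search is exhaustive over gene-start anchors
  (O(n·k)); adequate to ~10⁴ genes, not optimized beyond that.
- Upper-quartile normalization assumes most genes are unaffected; planting
  effects on a large fraction of the genome visibly shifts the quartile
  and biases fold changes (this is demonstrable with the generator).
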