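# Methods

## Model

`methsig` scores each differentially methylated CpG site (DMS) by the
enrichment of cis-regulatory and conformational elements in a fixed window
around it.  Writing *x₁…x_m* for the sites and *a₁…a_n* for the raw
attributes (G-quadruplex count, palindrome count, TFBS count, conserved-TFBS
overlap count, splicing observations, DNA-shape changes), a per-attribute
mapping *m_j* takes each raw value onto [0, 1], giving the signature matrix
*A′* = (a′_ij).  The genomic index is the linear mixture

    idx_i = Σ_j w_j · a′_ij ,  w_j ≥ 0,

and sites are ranked by descending idx.  With the default six attributes
and unit weights, idx ∈ [0, 6].  The index is real-valued: it is a weighted
sum of unit-interval quantities, and its useful resolution comes exactly
from the fractional count mappings.

The mapping functions are:

* counts (G4, Pals, TFBS, cTFBS): dataset min-max normalization,
  a′ = (a − min)/(max − min).  A constant column maps to 0 with a warning.
  The min/max actually used are stored in the signature's mapping metadata,
  and fixed global bounds can be supplied instead, because dataset-relative
  scaling makes indices comparable only within one run.  The closed
  interval [0, 1] is used (the extremes are attained by min-max by
  construction).
* splicing: logical OR of (any donor hit, any acceptor hit, any
  alternative-splicing-event overlap).
* shape: logical, positive when at least one of the four DNA-shape
  profiles changes significantly upon methylating the central CpG
  (Wilcoxon, p < 0.05).  Per-shape p-values are retained in the feature
  table for users who want the unjoined values.

Ties in the ranking are broken by |Δβ| descending, then (chrom, start)
ascending, so results are deterministic and independent of input order.

## Preprocessing

Coordinates are BED-style 0-based half-open throughout; a DMS is the single
base of the CpG cytosine (end = start + 1).  β values are methylation
fractions: from array intensities, β = M/(M + U + α) with α = 100; from
bisulfite counts, β = meth/total with sites below a read-depth threshold
masked (never a division error).  M values convert by β = 2^M/(2^M + 1) and
M = log2(β/(1−β)); the round trip is exact to better than 1e−9 for
|M| ≤ 20 (beyond that, β saturates in double precision).

Differential filtering computes per-site Δβ = mean(case) − mean(control)
(the case group is the first label in the annotation, or set explicitly),
a two-sided Welch t-test by default (Mann-Whitney as a configuration
switch — the choice is the caller's; no automatic normality gating, because
silent test switching harms reproducibility), and Benjamini–Hochberg FDR
across all tested sites.  Default thresholds: |Δβ| ≥ 0.3, p < 0.01,
FDR < 0.01.  Sites with fewer than two usable samples in either group are
excluded with a warning.  Score columns in BED input are either β-scale
(validated to [−1, 1]) or M-differences; a flag declares which — no unit
autodetection.  Large DMS lists can be subsampled uniformly (default cap
1,000 sites) under a seed.

## Feature detectors

**Windows.** The window is [start − offset, start + offset), default
offset 50 (100 nt).  Windows clipped at chromosome ends are analyzed at
their reduced length with the clipping recorded.  Soft-masked lowercase
genome bases are uppercased by default; a flag converts them to N instead,
since the masking policy materially changes motif counts.  Any placement of
a motif or k-mer covering an N is skipped, never scored.

**G-quadruplexes.** A canonical-motif detector: four runs of ≥ `min_run`
(default 3) guanines separated by three loops of length in
[`loop_min`, `loop_max`] (default [1, 7]).  Minus-strand structures are the
C-run pattern on the input strand.  Overlapping candidates are resolved
greedily left-to-right, longest match first at equal starts, which makes
counts stable and order-independent.  This is deliberately a deterministic,
exactly testable detector of quadruplex-capable sequence — not a
thermodynamic or imperfection-tolerant scorer; callers can substitute an
external detector behind the same counting interface.

**Palindromes.** Exact reverse-complement arms of length ≥ `min_arm`
(default 6) around a loop of ≤ `max_loop` (default 10).  Arms are expanded
outward to a mismatch, so only maximal arms are reported (one match per
(arm boundary, loop) pair).  Defaults are conservative, at the scale of
restriction/protein-binding sites; no arm mismatches are allowed.

**PWM scans.** JASPAR-style PFMs are converted to log2-odds with
background-proportional pseudocounts (default 0.8, uniform background) and
scanned on both strands; a placement is a hit when its relative score
(score − min)/(max − min) reaches `min_rel_score` (default 0.8).  These are
common motif-scanning defaults and all are exposed in configuration.

**Splice sites.** Donor (9 positions, −3..+6) and acceptor (15 positions)
per-position base-frequency tables are shipped as editable TSV data and
scored with the percentile scheme 100·(t − t_min)/(t_max − t_min), where t
sums the frequencies of the observed bases.  Hits require a score ≥ 80 by
default.  The bundled donor table follows the widely reproduced human
donor frequencies (invariant GT at +1/+2); the acceptor table is an
approximation of the published pyrimidine-tract/AG profile and is intended
to be replaced by users who need exact published matrices — the tables are
data, not code.

**Annotation tracks.** Conserved-TFBS and alternative-splicing annotations
are consumed as user-supplied BED tracks (no network retrieval) and counted
per overlapping interval, not per base.  Promoter and CpG-island tracks
restrict site sets by containment of the cytosine position.  A promoter
definition is deliberately not built in (there is no single distance-from-
TSS convention); the track is a required user input.

**DNA shape.** Shape profiles (MGW in Å, Roll and HelT in degrees, ProT in
degrees) are decoded from pentamer lookup tables over the alphabet
{A,C,G,T,M,W}, where M is 5-methylcytosine and W the guanine paired with a
methylated C on the opposite strand.  The central CpG dyad is modified
symmetrically (C→M, G→W) — CpG methylation is palindromic — and the
per-position difference between the methylated and native profiles is
tested with a two-sided Wilcoxon signed-rank test over the ≤ 6 positions
whose pentamers cover the dyad.  With fewer than 4 informative positions or
all-zero differences the test is degenerate and p is defined as 1.  The
package ships a *synthetic* pentamer table generator (seeded base values
plus a seeded methyl perturbation, sd 0.3 by default) with the same
interface as published methyl-aware tables, which are loadable from TSV;
the synthetic values are stand-ins for testing, not physical predictions.

## Statistics and reports

Group comparisons (feature enrichment between DMS+ and DMS−, between
methylation strata with mean β ≤ 0.1 vs ≥ 0.9, etc.) use two-sided Welch
t-tests by default with a Mann-Whitney switch; when both groups have zero
variance the comparison is defined as p = 1 with a warning.  The
expression association splits sites at the median |log2 fold change| (or an
explicit threshold), compares the genomic index between groups, and fits
ordinary least squares of |log2FC| on the index; a constant index yields an
undefined (NaN) slope.  Gene-to-site mapping is user-supplied.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of a config and seed (identical bytes
under identical seeds) and emulate the structure the framework assumes:

* genome: i.i.d. bases at a configurable G+C fraction (default 0.41,
  human-like), with a CG dinucleotide written at each site;
* β values: bimodal across sites — null sites draw both groups from one of
  two Beta modes (defaults Beta(0.5, 5) and Beta(5, 0.5), the array-like
  U-shape); differential sites use Beta distributions with target group
  means 0.2 apart by the configured effect (default Δβ = 0.4) at
  concentration κ = 100 (per-sample sd ≈ 0.04), keeping all values inside
  (0, 1);
* planted elements: fixed documented motif strings (a canonical G4 with
  TTA loops; a 20-nt arm-8/loop-4 palindrome; an 8-nt PFM consensus; the
  9-nt donor consensus) written at fixed offsets inside enriched-class
  windows with probability 0.9 versus 0.05 for desert-class windows, plus
  matching synthetic conserved-TFBS and alt-splicing interval tracks.
  Fixed strings make detector recall exactly testable (and it is 100% by
  construction);
* expression: |log2FC| = coupling × (number of planted elements) + Gaussian
  noise, signed opposite to Δβ (hypermethylation ↔ down-regulation).

Not emulated: probe-design structure (450k manifests, type I/II chemistry),
batch effects, cell-mixture composition, correlated methylation along the
genome, realistic motif degeneracy, and overlapping/nested regulatory
architecture.  Passing tests therefore demonstrate correctness of the
computations and recoverability of planted structure — not performance on
real tumour/normal data.

A note on the null-calibration check: the type-I-error property of the
differential test is verified on Beta(5, 5) null data (n = 10 + 10), where
the t-test is nominally calibrated; under the extreme U-shape mode
Beta(0.5, 5) the Welch test itself is conservative at this sample size
(achieved level ≈ 0.003 at nominal 0.01), and the Mann-Whitney test is too
discrete at n = 10 to attain nominal levels.  The calibration check exists
to catch implementation errors, so it is run where the test statistic's
nominal behaviour holds; robustness of the t-test to extreme skew is a
property of the test, not of this implementation.

## Problem sizes

Default study conditions: 400 sites (200 enriched / 200 desert), windows of
100 nt on an 80 kb genome, 10 samples per group; 20 seeded replicates for
end-to-end recovery, 100 replicates of 500 + 500 windows for the
methylation-stratum G4 contrast, 500 replicates for null calibration, and
500 seeded instances per detector for oracle equivalence.  These sizes give
stable Monte-Carlo estimates while keeping the full suite fast.

## Known limitations

* The G4 detector counts canonical motifs only (no bulged or two-quartet
  quadruplexes, no i-motifs, no folding energetics).
* Min-max normalization makes the genomic index run-relative; fixed bounds
  must be configured for cross-dataset comparisons.
* The bundled splice-site frequency tables are editable approximations;
  exact published matrices should be loaded for production use.
* The bundled pentamer shape table is synthetic; real methyl-aware tables
  are required for physically meaningful shape calls.
* Weights are user-set, not learned; the index is a prioritization score,
  not a calibrated probability.
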