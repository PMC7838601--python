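# Methods

`dpcnv` detects somatic copy-number variants (CNVs) from the binned
read-depth (RD) profile of a single tumor sample. The premise of all
RD-based callers is that the expected number of reads falling in a genomic
window scales with the local copy number; the difficulty is that tumor
purity dilutes the signal toward the diploid expectation, coverage is
limited, and GC content distorts counts. The pipeline has four stages:

1. **Profile construction.** Reads are counted into fixed-width bins
   (default 1000 bp) by leftmost mapped base; unmapped, secondary,
   supplementary and duplicate alignments are excluded. Because the bin
   width is constant the raw count is itself the depth proxy. GC content is
   taken from the reference sequence of each bin; bins that are mostly N, or
   that sit inside long runs (default ≥ 10) of zero-count bins, are masked
   and never re-enter the analysis. GC bias is removed by median-stratum
   scaling: `rd = count · m / m_gc`, where `m` is the global median count
   and `m_gc` the median within the bin's GC stratum (width 0.01). Strata
   with fewer than 20 bins borrow the global median (no correction), so
   sparse strata cannot amplify noise; zero-median strata are masked. The
   correction preserves the global median and is scale-equivariant.

2. **Segmentation.** Each contiguous unmasked stretch is smoothed with the
   1-D fused lasso

       min_β ½ Σ (y_i − β_i)² + λ Σ |β_{i+1} − β_i|,

   solved exactly by Condat's direct algorithm (no iterative approximation;
   the λ = 0 identity and λ → ∞ stretch-mean limits hold to machine
   precision). The default penalty is a universal-threshold rule
   λ = σ̂ √(2 ln n) with a robust noise scale estimated from first
   differences, σ̂ = median|Δy| / (0.6745 √2); it is user-overridable.
   Maximal constant runs of the fitted vector become segments; masked gaps
   always terminate segments. Segments shorter than `min_seg_bins`
   (default 20) are then absorbed into whichever genomic neighbor has the
   closer level, smallest first. Transient excursions of a few bins carry
   too little evidence to be reportable events at 4–6× depth, and their
   erratic fitted levels otherwise blur the contrast between the normal
   level cluster and genuine outlier segments. The segment level used by
   everything downstream is the fitted (absorption-weighted) value; the
   mean corrected depth is kept for reporting.

3. **Density-peak features.** Each segment is a point in the 1-D space of
   its RD level, with distance d(i,j) = |level_i − level_j|. With a radius
   γ — the 2 % quantile of all pairwise distances, falling back to the
   smallest positive distance under massive ties — two features are
   computed per segment:

   * local density ρ_i = #{ j ≠ i : d(i,j) < γ } (strict inequality);
   * minimum distance δ_i = min over strictly denser segments of d(i,j).
     Segments of globally maximal density have no denser neighbor; the
     first of them in genomic order is the density peak and takes
     δ = max_j d(i,j), later ones take their distance to the earlier
     maximal-density segments (a deterministic resolution of a non-unique
     peak). The strictly-denser rule matters under ties: every segment of a
     tied low-density group measures its isolation against genuinely denser
     segments, not against its own peers.

   Normal segments form one dense cluster (high ρ, tiny δ); CNV segments
   are sparse and isolated (ρ ≈ 0, large δ).

4. **Significance and typing.** A bivariate Gaussian N(μ, Σ) is fitted to
   the observed (ρ, δ) pairs and each segment is scored by the probability
   mass of the density region less probable than its own position, which
   for a bivariate Gaussian is exactly

       p_i = exp(−m_i²/2),  m_i² = (x_i − μ)ᵀ Σ⁻¹ (x_i − μ),

   the χ²(2 df) survival function of the squared Mahalanobis distance.
   Segments with p < α (default 0.005, no multiple-testing correction) in
   the outlier orientation are declared CNVs. Declared segments above the
   baseline r_b — the bin-count-weighted mean level of the γ-neighborhood
   of the densest segment — are amplifications, the rest deletions;
   adjacent same-status calls merge, keeping the minimum p.

## Robustness refinements around the null fit

The plain sample fit of N(μ, Σ) is kept as the estimator (`fit_null`), but
three measured failure modes of the raw procedure are handled explicitly:

* **Peak exclusion.** The density peak's δ is a convention (maximum
  distance), not a draw from the nearest-denser rule; a single huge value
  otherwise dominates var(δ) and masks every true outlier. The peak is
  excluded from the fitting set.
* **Gated refits.** Up to two refits drop segments that are already
  astronomically significant (p < 10⁻⁸) *and* in the outlier orientation
  (δ above the null mean, ρ below), so gross CNV segments stop inflating Σ.
  The orientation gate is what prevents the refit cascade that an
  unrestricted trimmed or re-weighted fit exhibits on CNV-free data.
* **Orientation-gated declaration.** CNV outliers are sparse, isolated
  objects — low ρ, high δ. A significant Mahalanobis deviation in any other
  direction (an unusually *dense* segment, say) is not a copy-number
  signature and is not declared.

### Shielded-outlier recovery

Recurrent events at the same copy number form a tight clump of levels whose
densest member absorbs the whole clump's isolation (its δ reaches the
distant normal cluster) while its peers measure δ only to each other and
look unremarkable. After the base declaration, a shielded segment is
re-tested at (ρ, δ′), where δ′ is its distance to the nearest denser
segment *outside* the declared set, provided (i) its own δ ≥ γ — chance
γ-tight pairs in a CNV-free tail are density-connected and must not
propagate; (ii) the denser segment that defined its δ is itself declared;
(iii) δ < 0.1 · δ′, i.e. the clump is an order of magnitude tighter than
its separation from everything denser; and (iv) the re-tested p clears
α/n — a multiplicity correction, since the recovery re-tests adaptively.
Rounds repeat until the declared set is stable. On CNV-free profiles this
recovery adds essentially nothing (the flagged fraction is unchanged to
three decimals); on profiles with several same-copy-number events it is
what keeps sensitivity monotone in purity.

## The simulator

The generator is a transparent purity-mixture count model, not a read-level
simulator. For a bin of tumor copy number CN at purity p,

    E[count] = base_depth · [(1 − p) + p · CN/2] · g(gc),

a mixture of diploid normal cells and tumor cells. Coverage presets assume
100 bp reads, so 4× ≈ 40 and 6× ≈ 60 expected reads per 1 kb diploid bin.
Counts are negative-binomial with overdispersion a (Var = μ + aμ², default
a = 0.02, a mild excess over Poisson typical of WGS count data; a = 0
selects Poisson). GC fractions follow a squashed AR(1) process confined to
[0.3, 0.7] (autocorrelation 0.98), and the optional GC response is
g = 1 + A·sin(2π·gc), mean-normalized, with A = 0.3 used for the
bias-removal checks. Planted events are disjoint intervals of 20–100 bins
with copy numbers {0, 1, 4, 6}, 20 per 50,000-bin profile in the reference
scenarios; the scenario grid crosses purity {0.2, 0.3, 0.4} with coverage
{4×, 6×}. Identical configuration and seed give bit-identical output.

What the simulator does **not** emulate: mappability structure, replication
timing waves, read-level artifacts, subclonal mixtures beyond a single
purity, chromosome-arm events, or the breakpoint microhomology of real
rearrangements. Passing the simulated checks therefore demonstrates the
statistical machinery under the stated count model, not performance on real
tumors, where masking tracks and orthogonal validation remain necessary.

## Evaluation conventions

A call is correct when it overlaps a truth interval of the same status
(amplification↔gain, deletion↔loss) by more than a configurable fraction of
the truth interval (default: any positive overlap). Precision is correct
calls over all calls; sensitivity is detected truth intervals — each
counted once — over all truth intervals; F1 is their harmonic mean, zero
when both are zero. The ODS concordance score for method A against k
others is ODS = m·m′ with m = overlap_total/k and m′ = overlap_total/own
calls, where overlap_total sums, over the other methods, A's calls that
overlap at least one of theirs (status-agnostic single-base overlap by
default; a reciprocal-fraction rule is available). A method with zero calls
reports ODS 0 with a warning rather than a division error.

## Numerical choices and degenerate inputs

* Fused-lasso merge tolerance 10⁻⁸ on adjacent fitted values; run means are
  used as the segment level.
* Near-singular Σ (min eigenvalue < 10⁻⁸·trace) receives a ridge of
  10⁻⁸·trace; a feature with no variance at all is an error, never NaN.
* Profiles yielding fewer than three segments, or with all pairwise level
  distances zero, produce an empty call set (success exit), since no
  density structure is definable.
* A segment exactly at r_b would be typed deletion (the "otherwise"
  branch); this cannot occur for a significant outlier in practice.
* Coordinates are 0-based half-open internally and in BED output.
* The pipeline contains no randomness: identical input and configuration
  give byte-identical output files.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the full pipeline on
50,000-bin profiles — 10 seeds per scenario for the purity × coverage grid
and 20 CNV-free replicates for calibration — and verify the two exact
routines against independent oracles (a box-constrained dual least-squares
solve for the fused lasso; literal double-loop feature computation for the
density-peak statistics) on 50–100 random instances each.

## Known limitations

* Features are length-blind: a 20-bin and a 200-bin segment at the same
  level are identical objects, so evidence does not accumulate with event
  size beyond segmentation itself. The minimum-segment absorption is the
  blunt instrument compensating for this.
* (ρ, δ) under the null is only approximately Gaussian; the empirical
  false-flag fraction at α = 0.005 is a few ×α (documented bound ≤ 0.05 of
  segments on CNV-free profiles).
* The fused lasso leaves shoulder segments at very large jumps, which can
  extend call boundaries by a few bins and occasionally produce a marginal
  flanking call.
* No absolute copy-number estimation and no purity estimation; calls are
  relative to the sample's own diploid baseline r_b.
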