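# Methods

## The model

A WGBS methylome, after strand merging and coverage filtering, is a
per-chromosome series of methylation levels `X_1 .. X_N` (one value per
CpG, `X_i = meth_i / total_i ∈ [0, 1]`). The genomic distance between
neighbouring CpGs is deliberately ignored: no objective model for the
irregular CpG spacing presents itself, and treating the data as a plain
successive series keeps the method to a single tuning parameter. The
series is assumed piecewise-constant in its mean; a methylated domain is a
maximal run of CpGs sharing one mean level.

Segment fit is measured by squared error about the segment mean,

    C(k:n) = Σ_{i=k..n} (X_i − μ_{k:n})²,

and a segmentation with changepoints `t_1 < … < t_m` is scored by

    Σ_j C(segment_j) + m·β.

`β` is a **fixed additive penalty per boundary**, default **1.0**, and is
*not* scaled with the series length: scaling (as BIC-style penalties do)
would make boundary sensitivity depend on chromosome size, which is
undesirable when every chromosome should be segmented with equal
sensitivity. In practice β = 1.0 balances sensitivity against
over-segmentation; lower values recover small faint domains (promoter
escapees) at the cost of many single-CpG fragments, higher values merge
away everything but the strongest boundaries. A boundary exists in the
two-segment case exactly when `C(1:N) > C(1:t) + C(t+1:N) + β`.

## Optimization

`pelt_segment` minimizes the objective exactly with PELT: the
optimal-partition recursion `F(t) = min_s F(s) + C(s+1:t) + β` with a
candidate set pruned by the condition `F(s) + C(s+1:t) > F(t)` (pruning
constant K = 0, valid because the cost is non-negative). Pruning provably
never discards a split that could become optimal — nor one that could tie
(the cost is super-additive over concatenation, making the exclusion
strict) — so PELT and the unpruned O(N²) recursion `dp_segment` return
identical changepoint sets, not merely equal objectives. `dp_segment` is
retained purely as the independent oracle; the test suite asserts exact
agreement on hundreds of random series.

Numerical choices:

- Segment costs come from prefix sums of `X` and `X²` held in extended
  precision (`np.longdouble`), so the cancellation in
  `ΣX² − (ΣX)²/n` is negligible at genome scale; a singleton segment is
  hard-wired to cost exactly 0.
- Ties between split points are broken toward the smallest index (the
  first argmin), identically in both optimizers, so outputs are
  deterministic.
- Each chromosome is segmented independently; results do not depend on
  chromosome processing order. No splitting is forced at intra-chromosomal
  coverage gaps, consistent with ignoring distance.
- Degenerate inputs: an empty series, a negative penalty, and non-finite
  values are rejected; `β = 0` legitimately yields a changepoint at every
  index of a strictly alternating series.

## Boundary reliability

Because detection sensitivity falls monotonically with β, the largest β at
which a boundary is still reported ranks boundaries by strength.
`max_penalty_scan` segments the series over a descending penalty grid
(default 25 geometric points from 50 down to 0.05 — a configurable
stand-in for an exact penalty-path computation, which is out of scope) and
records, per boundary, the largest grid penalty whose segmentation
contains it. The reported value is therefore grid-quantized from below.

## From changepoints to domains

Changepoints are mapped back to genomic coordinates: a domain runs from
the position of its first member CpG to the position of its last member
CpG + 2 (0-based half-open, covering the terminal CpG dinucleotide — the
original extent convention is not fixed anywhere, so the package picks the
smallest interval containing all member dinucleotides). Domain size is
`end − start`. Gaps before the first and after the last CpG of a
chromosome belong to no domain. Domains partition the retained CpGs
exactly; `Σ n_cpg` equals the retained site count by construction and is
asserted in tests.

Classification predicates (all configurable, defaults):

| label    | size              | mean level        |
|----------|-------------------|-------------------|
| PMD-like | > 10 kb           | < 0.70            |
| DMV-like | > 5 kb            | < 0.15            |
| FMR-like | ≥ 1 kb            | ≥ 0.70            |
| LMR-like | 100 bp – 1.5 kb   | 0.10 ≤ m < 0.50   |
| UMR-like | 1 – 3 kb          | < 0.10            |

PMD and DMV bounds are the published criteria for those region classes;
the FMR/LMR/UMR cluster boxes are descriptive ranges of where those
domains concentrate on the landscape, made concrete here with inclusive
lower bounds. Labels may co-occur (a large DMV is usually also PMD-like).

Overlap analysis against external region sets (e.g. HMM-defined
UMR/LMR/FMR intervals) uses exact base-pair arithmetic on merged
half-open intervals: per-domain covered fraction (selection threshold
strictly above 0.8 by default) and reciprocal coverage between two region
sets.

DMR calling between two segmented samples is deliberately minimal: the
union of both samples' boundaries cuts the genome into atoms, atoms where
both samples have a domain and the level difference reaches 0.3 (default)
are kept, and maximal abutting runs are reported with CpG-weighted means
per sample (a domain's CpG count is apportioned to an atom by its
base-pair share — the per-atom CpG counts themselves are not recoverable
from domain files). No significance testing is attempted.

## The MDL matrix and clustering

Each domain is a point at (log10 size, mean level); counting domains on a
20 × 20 grid gives the 400-pixel methylated-domain-landscape matrix. The
default axes span [100 bp, 10⁷ bp] × [0, 1]: wide enough for everything
from single-CpG fragments' neighbourhood up to multi-megabase methylated
blocks, and fixed across samples so pixel vectors are comparable. Bins are
half-open with the final bin closed; domains off the grid are counted in
`out_of_range` (and excluded from clustering vectors) rather than dropped.
The same grid serves display and clustering.

Similarity between methylomes is the Spearman rank correlation of their
row-major pixel vectors — computed as the Pearson correlation of
average-ranked values, the defining identity under the heavy zero-ties of
sparse count vectors. Samples are clustered by Ward's method on the
dissimilarity `d = 1 − ρ` (the "Ward on an arbitrary precomputed
dissimilarity" convention; pairing Ward with a rank correlation is only
meaningful this way). A constant pixel vector has no ranks and is
rejected with the sample named. Outputs: similarity TSV, a Newick tree
whose branch lengths are merge-height differences, and a heatmap ordered
by the dendrogram leaves.

## Downsampling

`thin_counts` emulates a smaller sequencing run at the count level:
per site, `total' ~ Binomial(total, f)` and
`meth' ~ Hypergeometric(meth, total − meth, total')` — distributionally
identical to retaining each read independently with probability `f`, and
unbiased for the methylation level. Sites thinned to zero coverage are
dropped.

## The synthetic generator

`simulate_methylome` draws from exactly the model the segmentation
assumes: per-domain constant `π`, geometric inter-CpG spacing (mean
100 bp; 10× denser inside designated island domains, reproducing the
CpG-density contrast that makes unmethylated islands detectable at high
penalties while CpG-poor low-methylated regions are not), per-site
coverage Poisson (default mean 30, a deep modern WGBS run), methylated
counts Binomial. `random_simspec` produces genomes of well-separated
domains (neighbour level steps ≥ 0.3, 50–200 expected CpGs each) for
recovery benchmarks; `methylome_simspec` produces methylome-shaped
genomes — methylated background, islands, LMRs, optionally large PMDs —
where detectability genuinely depends on coverage and penalty.

What the generator does **not** emulate: within-domain autocorrelation,
bisulfite conversion error, mapping artefacts, copy-number effects, or
biological replicate variance. Tests passing on these tracks show the
estimator works under its own model assumptions; they are not evidence
about noise structures real tissue adds.

Boundary recovery is scored in retained-CpG ordinals (the space the
optimizer actually works in) with a one-to-one maximum-cardinality
matching within ±2 CpGs; with no predicted boundaries precision is
reported as 1.0 by convention (no prediction is wrong).

## Problem sizes and designed conditions

The shipped benchmarks use: 100 random series up to N = 200 for the
PELT/DP equivalence; 20 genomes of 20 domains (depth 30, depth filter 5)
for boundary recovery; and, for the downsampling robustness experiment, a
single-chromosome genome of ~10⁵ CpGs (700 domains) at full-data mean
depth 10 with depth filter 3, thinned to f ∈ {0.1, 0.25, 0.5, 1.0} over
5 seeds. Depth 10 places the experiment in the retention-limited regime
of shallow WGBS, where the depth filter drives the retained-site gradient:
domain counts rise steeply from 10 % to 25 % of the data and plateau from
50 % to 100 %. At high full-data depth (λ = 30) thinning barely changes
retention and the trend can even invert mid-range — extra binomial noise
at moderate depth inflates the squared-error cost and over-segments — a
real property of a fixed-penalty SSE cost worth knowing when comparing
domain counts across datasets of very different depth.

## Known limitations

- The SSE cost models neither the binomial sampling variance of levels
  (low-coverage sites are as trusted as high-coverage ones beyond the
  depth filter) nor within-domain autocorrelation.
- The penalty grid quantizes boundary reliabilities; an exact
  solution-path algorithm would remove that but is out of scope.
- DMR calling is descriptive, with no statistical error control.
- MDL comparability requires a shared grid; the defaults are a choice,
  not a canon, and the package refuses to correlate mismatched grids.
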