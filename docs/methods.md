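# Methods

## Windowed GC%

An assembly is tiled per sequence with non-overlapping windows of fixed
size *w*; the last window of a sequence may be shorter. For a window,
GC% = 100·(G+C)/(A+C+G+T), counted case-insensitively: soft-masking
records repeat annotation, not composition, so lower-case bases keep their
identity. `N` and every other IUPAC ambiguity code carry no defined
composition and count only toward the window's `n_fraction`. Coordinates
are 0-based half-open, matching BED.

Two filtering decisions are ours, since standard practice varies and the
analyses this package supports are silent on them:

- a window enters downstream value sets only when `n_fraction ≤ 0.5`
  (configurable via `NPolicy`) — segmentation-style tools conventionally
  drop gap-dominated windows, and bridging assembly gaps would manufacture
  spurious long segments;
- trailing partial windows stay in the coordinate track but are excluded
  from value sets by default, because their higher binomial variance would
  inflate histogram tails at exactly the small-window scales the analysis
  cares about.

With those conventions, the length-weighted mean of window GC% over a
gap-free assembly equals the whole-assembly GC% identically (both reduce
to the same ratio of counts); the test suite asserts this to 1e-9 through
a FASTA round trip.

## Fisher–Jenks natural breaks and GVF

Given sorted values v₁ ≤ … ≤ vₙ, a k-class Jenks partition is a split into
k contiguous runs minimizing SDCM, the total within-class sum of squared
deviations from class means. We implement Fisher's exact dynamic program
on the *weighted* form: raw values are binned to 0.01 GC% resolution and
collapsed to (distinct value, multiplicity) pairs, and the DP cost of a
run is computed from prefix sums of w, w·v and w·v². The DP is exact on
the binned data; since the GC% of a w-bp window is a multiple of 100/w,
binning at 0.01 is lossless for windows up to 10 kb and sub-histogram-bin
for larger ones, while reducing millions of windows to at most ~10⁴
distinct values (the DP is quadratic in that number — the only hot spot
in the package). Ties between equally-optimal partitions are broken
deterministically by taking the first (smallest-index) argmin in each DP
cell, so repeated runs are byte-identical.

Goodness of variance fit is GVF = (SDAM − SDCM)/SDAM, where SDAM is the
deviation sum about the global mean: 0 for a single class, 1 when every
class is constant, and non-decreasing in k for optimal partitions (adding
a split never increases the optimal SDCM). On a constant array SDAM = 0
and GVF is defined as 0; class-count selection then reports k = 1 with
`threshold_reached=False` rather than dividing 0/0.

The natural class count is the **smallest k whose optimal partition
reaches GVF ≥ 0.9** (threshold and k_max = 10 configurable). Break
positions are reported as midpoints between the adjacent classes' extreme
values, so every value lies in exactly one class.

Correctness is anchored to an independent oracle: exhaustive enumeration
of all contiguous partitions for n ≤ 15 distinct values, which both the
unit tests and the acceptance script compare against exactly.

### A note on k under window-size averaging

One might expect the selected k to collapse when the window size exceeds
the domain length. Under the smallest-k-over-threshold rule the opposite
can happen: averaging turns a well-separated bimodal GC% distribution
(k = 2 at GVF ≈ 0.97) into a near-Gaussian one, and a Gaussian needs about
four contiguous classes before GVF crosses 0.9. What reliably collapses
with window size is the GC% range and dispersion, not necessarily the
class count — which is itself a finding about how sensitive "natural"
cluster counts are to the window-size choice.

## Isochore families and segments

Family intervals are lower-open, upper-closed and must tile (0, 100]; a
GC% exactly on a boundary belongs to the lower family. Defaults
L1 ≤ 37 < L2 ≤ 41 < H1 ≤ 46 < H2 ≤ 53 < H3 are the conventional
isochore-family limits of the segmentation literature and are fully
configurable (a one-line `name = upper_bound` config file is the ground
truth). Maximal runs of identically-labeled contiguous windows merge into
segments whose `mean_gc` is the window-length-weighted mean; an excluded
(gap-dominated) window terminates a run. The stacked per-family histogram
is constructed from the same admitted windows as the plain histogram, so
its family-marginal equals the plain histogram bin-for-bin by
construction — the tests assert the identity rather than trust it.

## Synthetic genomes

The generator emulates the two compositional organizations under study:
a single domain state gives a teleost-like homogeneous genome; two or more
states in alternation give a gar/mammal-like heterogeneous mosaic. Within
a domain, bases are iid at the domain's target GC% with G/C (and A/T)
equiprobable; domain lengths are geometric around the state's mean —
the simplest memoryless model producing a mixture of sub-window and
multi-window domains. The default heterogeneous condition is 20 Mb of
35% / 55% GC domains with 500 kb mean length: a ΔGC of 20 points spans the
observed range between AT-rich and GC-rich vertebrate material, and 500 kb
puts ~500 one-kb windows inside a typical domain while several domains fit
inside no 100 kb window cleanly.

Transposons are modeled as fixed-length elements with their own GC%,
overwritten (not inserted) at uniformly random non-overlapping positions —
overwriting keeps coordinates, truth BEDs and window grids aligned, which
is what the downstream comparisons need; an insertion model would add
bookkeeping without testing anything further. Placement redraws on
overlap up to 1000 attempts per copy and errors beyond that (random
sequential placement jams near 75% coverage, so feasible loads stay below
that). The homogenization experiment loads a heterogeneous genome with
elements at the genome-mean GC% (45 for the default two-state condition)
at 0–1200 copies/Mb of 500 bp elements (0–60% genome coverage), averaging
the window-GC standard deviation and selected k over five derived seeds
per load.

All randomness in a simulation flows from one `numpy` Generator seeded
from the spec, so a spec is a complete byte-reproducible description;
experiment-level seeds derive from a `SeedSequence` spawn of the base
seed.

What the generator does **not** emulate: real repeat families and their
phylogenies, indels and rearrangements, gap structure of real assemblies,
CpG effects, or any correlation structure within domains. Passing tests
therefore demonstrate that the pipeline recovers *known* compositional
structure under iid noise at realistic scales — not that any particular
real genome has that structure.

## Problem sizes and numerical choices

The validation suite runs at desk scale by design: the heterogeneous study
genome is 20 Mb (20 000 one-kb windows, 200 hundred-kb windows), the
homogenization experiment 10 Mb × 25 simulations, and oracle comparisons
use n ≤ 15 distinct values where exhaustive enumeration is exact. Key
tolerances: GC conservation identities at 1e-9 (pure floating-point
round-off), oracle SDCM equality at 1e-9 absolute, GVF monotonicity slack
1e-12; segment-cost expressions are clamped at 0 to absorb negative
round-off. Cluster counts for full-size real assemblies (hundreds of Mb)
run through the identical code path — only the DP's distinct-value count,
capped by the binning, matters for runtime — but require the assemblies
themselves as inputs.

## Known limitations

- Exact Jenks is quadratic in distinct binned values; at 0.001-resolution
  binning or raw continuous data it would need the divide-and-conquer DP
  speedup, which is not implemented.
- The smallest-k selection rule is one of several defensible readings of
  GVF-threshold selection (best-k-under-cap being another); it is the
  implemented default and configurable in spirit via `gvf_threshold` /
  fixed `n_classes`.
- Family classification rejects GC% outside (0, 100]; a window of zero
  unambiguous GC content (GC% = 0) is unclassifiable by the family
  definition and must be excluded upstream.
- The transposon model ignores element truncation, nesting and decay.
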