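# Methods

## The measurement problem

Filopodia are finger-like actin protrusions, typically 1–5 µm long and
below the diffraction limit in width, whose distal tip hosts a protein
complex (MYO10, VASP, integrins, RAPH1/lamellipodin).  Asking whether a
protein is *recruited to filopodia tips* means comparing its
fluorescence along the filopodium, from tip to base, across hundreds of
filopodia of different lengths — and doing the same kind of enrichment
reasoning on mass-spectrometry interactor screens and on live-cell
tip-spot dynamics.  This package implements that quantitative layer:
profile → 40-bin map → tip/shaft ratio, spectral-count filtering,
spot linking, and the permutation statistics tying it together.

## Intensity profiles and localization maps

**Normalization.**  Each channel of an image is affinely rescaled to
[0, 1] with the channel maximum (the brightest structure in the field)
as the upper bound and the channel minimum as the lower bound.  Only
the upper anchor is scientifically meaningful; the lower anchor is a
package choice, recorded so it can be audited, and an unnormalized path
is available (`--normalize none`).  Constant channels map to zeros.
The map is idempotent.

**Sampling.**  Profiles are sampled along tip-first polyline paths by
bilinear interpolation with no transverse averaging (a 1-pixel-wide
line profile).  Continuous pixel coordinates are 0-based with the
origin at the centre of pixel (0, 0).  For a path of arclength *L*
pixels, `round(L) + 1` samples are spaced uniformly over [0, *L*]: the
spacing is exactly one pixel whenever *L* is a whole number of pixels
and within half a pixel otherwise, and both endpoints are always
included, so the filopodium length `(n − 1) × spacing` is recovered
exactly.  (Unit spacing and endpoint inclusion cannot both hold for
fractional arclengths; uniform coverage of the full path was chosen
because length extraction is itself a reported measurement.)

**Binning.**  To homogenize filopodia of different lengths, each
profile is reduced to exactly 40 bins: sample *i* of *n* (0-based) goes
to bin `floor(40·i/n)`, which is the equal-width cut of normalized
position and yields contiguous, near-equal occupancy; the bin value is
the median of its samples, with the midpoint convention for even
counts.  Profiles shorter than 40 samples are an error by default
(silent empty bins would corrupt medians); an explicit `resample`
policy upsamples linearly first.  The binning rule is frozen and tested
bit-for-bit against an exhaustive grouping oracle for every length
40–200 so that independent re-implementations can match it exactly.

**Maps and enrichment.**  A condition's localization map is the
per-bin, per-channel arithmetic mean over its binned profiles (sd and
n recorded).  Maps may be rescaled per channel to [0, 1] for heatmap
display; statistics always use unrescaled values.  Preferential tip
recruitment of one filopodium is the enrichment ratio: mean of tip bins
1–6 divided by mean of shaft bins 7–40 (windows configurable, these
defaults fixed throughout).  A non-positive shaft mean flags the ratio
undefined rather than raising.

## Spectral-count enrichment filters

Interactor candidates are called from spectral counts with two rules:

| screen            | replicates | fold change        | count rule            |
|-------------------|-----------:|--------------------|-----------------------|
| FERM pulldown     | 2 + 2      | ≥ 2 × vs GFP *and* vs TLN1-FERM | > 10 total across repeats |
| MYO10-BioID       | 5 + 5      | ≥ 2 × vs GFP–MYO10 | > 5 total across repeats  |

Boundary semantics are deliberate and tested: the count threshold is
strict (a total of exactly 10 fails the pulldown rule) while the fold
change is inclusive.  "Across repeats" is read as the sum of bait
replicate counts (a `count_aggregation="min"` option exists).  Fold
change is the ratio of replicate-summed totals; a pseudocount of 1 is
added to both totals only when the control total is zero, so ordinary
ratios are unchanged.  Volcano p-values use Welch's t-test on
per-replicate counts — the original screens computed significance
inside a proprietary search platform whose statistic is unpublished, so
the p-value method is a labeled, configurable choice, and the filter
verdict never depends on it.  Cross-screen overlap intersects passing
sets on uppercased identifiers.

## Spot linking and track statistics

Tip spots are linked per cell between consecutive frames only (gap
closing disabled).  Each frame pair is solved as an optimal bipartite
assignment: candidate links farther than the maximum linking distance
(default 1 µm) are forbidden outright, and every spot has a "no link"
alternative priced at 1.05 × that distance in an augmented cost matrix
(solved with the Hungarian algorithm).  Because any allowed link is
cheaper than two no-links, the optimum links as many spots as possible
within range and, among such matchings, minimizes total distance —
the behavior expected of a simple linear-assignment tracker.  Ties are
resolved deterministically by the solver's row order.

Definitions are fixed: duration = (n_frames − 1) × frame interval
(default 5 s); total distance = sum of consecutive Euclidean steps;
mean speed = distance / duration, and 0 for single-frame tracks
(whether a tracker divides by elapsed time or by link count is
ambiguous in common tools; this package divides by elapsed time).
Per-cell summaries are arithmetic means over a cell's tracks and feed
the between-condition comparisons.  Spot *detection* from real images
is out of scope (real acquisitions use trained segmentation models); a
plain threshold/local-maximum detector is included only as a labeled
stand-in for synthetic images.

## Randomization statistics

The two-group randomization test uses the difference of means with
two-sided extremity.  When the number of distinct relabelings
C(n₁+n₂, n₁) is at most 20,000 the null is enumerated exhaustively and
the p-value is exact (the 3-vs-3 all-0 vs all-1 case gives p = 2/20 =
0.1); otherwise 1000 random relabelings are drawn by default under a
mandatory recorded seed, with add-one smoothing
p = (1 + hits)/(N + 1) so p is never zero and the observed labeling is
counted.  A relative tolerance of 1e-12 on |diff| comparisons guards
against float jitter in ties.  The reported effect size is the raw
difference of means, with Cohen's d alongside; the online tool the
field commonly uses for these tests does not publish its permutation
count or effect-size definition, so these defaults are documented
rather than claimed identical.  Welch's t-test (unequal variances,
Welch–Satterthwaite df) is delegated to scipy; a both-groups-constant
input is a degenerate-variance error.  Tukey boxplot summaries use
linear-interpolation quartiles (the spreadsheet/R default, not Tukey
hinges) with whiskers at the most extreme data inside 1.5 × IQR.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of their arguments including the
seed, and at zero noise they equal their analytic expectations exactly
— both properties are tested.

* **Profiles / images.**  A filopodium is a polyline (0.04 µm pixels,
  SIM scale, so a 2-µm filopodium spans 50 px) with a shaft amplitude
  per channel and a tip amplitude carried by the first 15% of arclength
  (6/40 bins, matching the tip window); images render the shaft as an
  anti-aliased line (Gaussian cross-section, sd 0.5 px) and the tip as
  a Gaussian punctum of sd 2 px, plus constant background and additive
  Gaussian noise.  Defaults: tip 3, shaft 1 (tip:shaft 4:1), noise sd
  0.2 × shaft, 120 samples/profile (3 per bin), 300 profiles per
  condition — the scale of filopodia counts the mapping procedure is
  designed for.  No intensity statistics were published for the
  original images, so amplitudes are free parameters, not calibrated.
  Not emulated: Poisson shot noise and PSF optics, curved/branching
  filopodia in images, retraction dynamics, autofluorescence.
* **Counts.**  Spectral counts are Poisson; `baseline_mean` is the
  expected *total* count of a background protein across a sample's
  replicates (counts are conventionally summed across repeats, which is
  what the filters consume), so each replicate draws
  Poisson(baseline/n_replicates).  Planted proteins multiply the bait
  total by the enrichment factor.  Defaults 50 proteins, 10 planted at
  20-fold over baseline 3 with 2+2 replicates.  Overdispersion
  (negative binomial) is not modeled — the filters use totals and
  ratios only, not a count likelihood.
* **Tracks.**  Gaussian random walks (step sd 0.1 µm/frame, 5-s
  frames) started on a grid with 5-µm pitch, far beyond the 1-µm
  linking radius, with optional isotropic detection jitter; no
  detection dropout, splitting or merging.  With noise 0 and that
  separation, identity recovery by the linker is exact and is asserted
  as such.

Consequently, passing tests demonstrate that the *computations* are
correct and that planted signals of realistic magnitude are recovered;
they do not demonstrate robustness to segmentation error, uneven
illumination, overdispersed counts, or dense/crossing trajectories.

## Validation sizes

The self-contained validation (`scripts/acceptance.py`) uses: the full
binning-oracle sweep over lengths 40–200; 300 profiles for ratio
recovery; 2000 null simulations × 1000 permutations (n = 30 + 30) for
the type-I error of the randomization test, checked against the
binomial 99% CI around 0.05; 1000 random 8-protein tables for
filter-oracle agreement; and 12 walkers × 15 frames for tracking
identity recovery.  These sizes give Monte-Carlo standard errors
comfortably below the decision margins while keeping a full run under
a minute.

## Known limitations

* The published spectral-count tables behind the original screens have
  no public accession; the package reproduces the *rules* and validates
  them on synthetic ground truth, and will run on the deposited tables
  if they are placed under `data/published/` (see
  `tests/test_acceptance.py::test_published_dataset_reproduction`).
* Path drawing, spot detection and image segmentation are inputs, not
  outputs: the pipeline quantifies, it does not detect.
* The enrichment-ratio denominator uses bins 7–40 as "shaft"; for very
  short or strongly curved filopodia the geometric meaning of the bins
  degrades with the quality of the traced path.
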