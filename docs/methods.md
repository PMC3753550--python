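# Methods

apicoquant quantifies apical plasma-membrane remodelling in fluorescence
time-lapse movies of epithelia — the motivating system is the
cellularizing *Drosophila* embryo, whose apical surface starts covered in
villous protrusions that retract over ~40 minutes while apical endosomes
proliferate and are trafficked basally.  Five measurement pipelines share
one calibrated container (`ImageStack`, T(Z)YX with μm/px and s/frame),
and a synthetic-scene generator supplies seeded ground truth for each.
All positions and distances are reported in μm; pixel indices are
0-based and internal.  In sagittal views the row index increases from
apical to basal.

## Protrusion coverage (apical flattening)

Protrusions appear in TIRF as thin bright ridges.  Per frame:

1. **Bleach correction.** Frame *t* is multiplied by
   mean(frame 0)/mean(frame *t*), fixing every frame's mean to the first
   frame's.  Exact by construction (tested at rel. 1e−9); a frame with
   zero mean is an error, not a silent skip.
2. **Oriented Mexican-hat bank.** The kernel in ridge coordinates
   (u along the ridge, v across) is G(u; σx)·R(v; σy) with the Ricker
   profile R(v) = (1 − v²/σy²)·exp(−v²/2σy²); defaults σx = 7 px,
   σy = 1 px.  Orientations θ_k = kπ/n for k = 0…n−1 (default n = 18,
   10° steps — π-periodicity suffices for undirected ridges; 10° is finer
   than the orientation spread of real protrusions).  The sampled kernel
   is shifted to exact zero mean, so uniform regions respond with exactly
   zero.  Support is (2h+1)² with h = ⌈4·max(σx, σy)⌉.  Correlation uses
   reflective padding (avoids edge-dark artifacts) and a shared FFT of
   the padded frame across all orientations.
3. **Orientation MIP and segmentation.** The per-pixel maximum over the
   angle-indexed response stack is thresholded by Otsu's method on the
   positive part of the response histogram (256 bins).  Otsu replaces the
   interactive, trained classifier a human operator would use: it is
   deterministic, training-free and reproducible.
4. **Skeleton coverage.** Coverage = skeleton pixels / frame pixels,
   using classic two-subiteration parallel thinning.  Skeleton density is
   insensitive to protrusion thickness (a thick and a thin protrusion of
   equal length contribute equally); the binary-mask area fraction is
   emitted alongside as a thickness-sensitive secondary column.  The
   thinning is implemented in the package (vectorized) so that tests can
   hold it to exact agreement with an independently coded reference of
   the same published algorithm; library variants of this operator differ
   pixel-for-pixel between implementations, which would make an exact
   oracle impossible.

Two robustness guards act only inside `coverage_timeseries` (the
primitive `segment_response` stays pure Otsu):

- **Structure gate.**  A frame is declared protrusion-free when its Otsu
  threshold does not exceed 2.5 robust SDs (1.4826·MAD) of the
  first-angle response.  On a field with no ridges, the orientation MIP
  is just the maximum of correlated noise responses and Otsu merely
  bisects that histogram at ~1.5 robust SDs; real ridge populations put
  the threshold at ≥3.5 robust SDs.  Without the gate, a structure-free
  movie reads out the skeleton of thresholded noise.
- **Component sieve.**  Segmented 4-connected components smaller than
  20 px are dropped.  Protrusions are extended ribbons (tens of px);
  suprathreshold noise excursions are specks whose abundance grows as
  bleach-corrected noise grows through the movie, and without the sieve
  they impose a spurious upward coverage trend.  4-connectivity is
  deliberate: diagonal chains of specks stay fragmented while solid
  ribbons are unaffected.

Conditions are compared with a two-sample Kolmogorov–Smirnov test.  For
n·m ≤ 100 the p-value is exact, by enumerating all C(n+m, n) assignments
of the pooled values (ties handled correctly; ECDFs computed from integer
cumulative counts so identical distributions give D exactly 0); larger
samples use the asymptotic KS distribution.  At n = m = 3 the smallest
achievable two-sided p is 0.1 — full separation of three movies per
condition lands exactly there, and that is the package's discrimination
floor at this sample size.

## Puncta counting and baseline normalization

Per frame, a **robust-background global threshold**: sort intensities,
discard the lowest and highest 5% (counts rounded down), threshold =
mean + 2 × population SD of the retained pixels (both constants
configurable).  8-connected components of the suprathreshold mask with
area in [2, 200] px are the detected puncta; integrated intensity is the
sum of member-pixel intensities, and an eccentricity column is kept so
elongated (tubular) and round (vesicular) structures can be split
downstream.  The area band spans diffraction-limited puncta to small
vacuoles at 0.1–0.2 μm/px.

Counts and integrated intensities are normalized as a ratio to the mean
of the first 20 frames, so different embryos can be pooled on a common
early-cellularization baseline.  The normalized series over the baseline
window has mean 1 by construction; normalization is scale-invariant.

This thresholding rule has a structural prerequisite worth stating
plainly: on *featureless* i.i.d. noise the trimmed SD is ~0.79 of the raw
SD (Gaussian case), so "mean + 2 trimmed SDs" sits at a ~5% upper tail
and the detector drowns in two-pixel speckle regardless of SNR.  The
rule works when the pixel histogram is dominated by *bounded*
illumination/background structure, in which case the threshold clears
the background maximum with margin.  Real TIRF/confocal fields have such
structure; the synthetic generators model it explicitly (below).

**Sub-apical structure counts.**  In volumetric stacks, objects are
counted independently in five z sections 0.2 μm apart (the 4–5 μm band
below the apical membrane), with no cross-z merging — the sections are
treated as independent samples, matching how such counts are done by
eye.  The threshold is global (computed on the full section); an object
belongs to a 25 × 25 μm² region when its centroid falls inside it.
Three such regions (625 μm² each) are placed per field, evenly spaced
and vertically centred unless origins are given.

## Endosome tracking and classification

Input is a detection table (t, y_um, x_um[, intensity]).  For each
consecutive frame pair, candidate links farther than the gate
(default 2.0 μm/frame) are forbidden, and the surviving bipartite
problem is solved as a globally optimal one-to-one assignment minimizing
total Euclidean displacement (augmented square cost matrix with
birth/death dummies priced at the gate, solved by the Hungarian method:
any feasible link costing ≤ gate beats leaving both endpoints unmatched
at 2×gate, so cardinality is maximized first and total displacement
broken second).  No gap closing: the minimum-duration criterion assumes
continuous detectability, and bridging gaps would change what "duration"
means.  Detections are canonically ordered within each frame, so the
result is invariant to input row order.

Track filters and classification, all in μm relative to the apical
reference: keep tracks with **duration ≥ 6 frames** and **origin within
5 μm** of the apical membrane (inclusive); classify as **descending**
when the maximal depth below the reference exceeds 5 μm, else
**persistent**.  Maximal depth (not net start-to-end displacement) is
the primary displacement readout — it is what "descends past 5 μm"
measures; net displacement is emitted as a secondary column.  The apical
reference is either given or estimated as the intensity-weighted mean
row of the brightest 1% of pixels in frame 0 (the apical membrane is the
dominant bright structure in sagittal views).

`displacement_profile` assigns each track to the stage window containing
its first frame and reports n, mean and population SD of maximal depth
per window and class, next to the window-mean furrow depth.  The furrow
front is an input series (config or generator truth), constrained
non-negative and non-decreasing; detecting it from images is out of
scope.

## Object-based colocalization

Both channels are segmented with the robust-background threshold and the
area band; a reference object is **positive** when ≥ 30% of its pixels
(configurable) lie on the partner channel's mask.  The headline number
is 100·n_positive/n_reference.  Per-object overlap fractions are always
emitted so any stricter criterion can be re-applied post hoc — the 30%
default makes explicit a judgement that is usually made by eye.
Manders' M1 is included as a pixel-weighted secondary summary.  Analysis
is single-plane; chromatic registration and z-association are out of
scope.

## Synthetic scenes and what they do (not) show

All generators are pure functions of (config, seed) — bit-identical
reruns — and every ground-truth table is computed on the noiseless
latent structure, never on rendered pixels.  Rendering uses the standard
camera approximation Poisson(gain·signal)/gain + Gaussian read noise,
clipped at zero.

- **Protrusion movies** (default T=60, 256², 0.1 μm/px): 1-px-wide
  anti-aliased line segments (lognormal lengths ~1.2 μm median, uniform
  orientations), resampled every frame over a textured membrane
  background, bleached at exp(−0.012·t).  Wild-type count decays
  exponentially to 10% by the last frame; the persistent profile
  (endocytosis-blocked phenotype) keeps it constant.  True coverage is
  the skeleton density of the latent binary mask.
- **Puncta movies** (default T=90, 320², birth 8/frame, lifetime 6):
  births are Poisson with stage multipliers over the first/middle/last
  thirds — (1, 3, 5) for the fivefold regime, (1, 2, 3) preset for the
  threefold one — starting one lifetime before frame 0 so the movie
  opens at steady state.  Spots are Gaussian (σ 1.2 px, peak 2000 ± 20%)
  with a 6 px minimum separation, over a bounded fringe-illumination
  background (level 2000 counts, amplitude 0.5, period 64 px) that gives
  robust-background thresholding its working regime; spot amplitudes are
  drawn independently of the fringe, a deliberate modeling simplification.
- **Track scenes** (default T=150, 100×40 μm field, birth 2/frame
  stopping at frame 120 so every descent completes): 70% of particles
  descend at 1 μm/frame to a per-particle N(15 μm, 2 μm) target depth,
  the rest random-walk within the 5 μm apical band; detections add
  0.1 μm Gaussian jitter; the furrow advances linearly 5→30 μm.  The
  descending fraction is an arbitrary, configurable choice — the real
  proportion is not known.
- **Colocalization pairs**: exactly n (default 100) discs on a jittered
  grid in the reference channel; ⌊f·n⌋ duplicated at identical positions
  in the partner channel plus 30 partner-only distractors, on the same
  fringe background.
- **Sub-apical stacks** (384², 0.2 μm/px): early/late pairs with 60
  structures per plane early and a configurable density ratio (default 5).

Problem sizes were chosen so that sampling error is small relative to
the documented recovery tolerances: e.g. the late/early count-ratio
estimator has ≈7% sampling SD at the default movie size (±20% recovery
band), and each stage window collects ≥20 descending tracks (±1.5 μm
depth band ≈ 4 standard errors).  What passing these tests shows is that
the pipelines recover known structure under realistic noise, bleaching
and bounded illumination inhomogeneity.  What they do not show: 
performance under unbounded background drift, detector hot pixels,
spot motion blur, protrusion curvature, furrow-coupled motion of
persistent endosomes, or any regime where the background histogram is
dominated by pure shot noise — in that last regime robust-background
thresholding is the wrong tool, as quantified above.

## Numerical choices and degenerate inputs

- Kernel zero-mean is enforced after discrete sampling (|Σ| < 1e−12).
- Otsu on an empty or constant positive part yields an empty mask; a
  two-level histogram thresholds between the levels exactly.
- Thresholds and filters use inclusive bounds where the criteria say
  "or more"/"within" (≥ 6 frames, ≤ 5 μm origin) and strict ones for
  "past" (> 5 μm descent); boundary behaviour is tested at one float ulp.
- Robust-background SD is the population SD (ddof 0); trimming counts
  round down.
- Linking cost ties are broken by the canonical within-frame ordering;
  in continuous coordinates exact ties have measure zero.
- Empty profile windows report n = 0 with missing means rather than 0.
- CSV floats are written via `repr` (exact round-trip); read back with
  `float_precision="round_trip"` for bit-equality.

## Known limitations

- The coverage pipeline's absolute scale differs from any interactively
  trained segmentation; only relative/temporal structure is claimed.
- The skeleton operator follows the classic parallel thinning scheme;
  other thinning variants yield slightly different (equally valid)
  skeletons, so coverage values are comparable only within one pipeline.
- The linker has no motion model and no gap closing; crossing particles
  closer than the gate can swap identities (~1–2% of links at default
  scene density).
- Exact KS enumeration is limited to n·m ≤ 100; beyond that the
  asymptotic distribution is used, which is approximate for moderate n.
- Sub-apical counts are per-section; a structure spanning several z
  sections is counted once per section by design, matching the manual
  protocol being emulated, and absolute counts are therefore not
  comparable to merged-3D counts.
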