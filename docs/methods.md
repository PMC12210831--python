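# Methods

This note records the models behind each pipeline stage, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
establish about performance on real images.

## Synthetic scenes

A scene is a 3-channel (DAPI, exon, intron) voxel array indexed
(z, y, x) at a default lateral pixel size of 144 nm — chosen so the standard
2.5-pixel colocalization window corresponds to 360 nm. Nuclei are
non-overlapping filled discs placed by rejection sampling (bounded retries;
failure names the offending parameters). Cytoplasm is not rendered, because
the assays this pipeline serves work on isolated nuclei.

Each punctum is an isotropic 2D Gaussian replicated over three z-planes with
fixed axial weights (0.5, 1.0, 0.5). The center-plane weight is exactly 1,
so in a noise-free image the voxel at a punctum's center reads
background + amplitude; this anchors closed-form checks of the fitting
stage. A full 3D PSF is deliberately not modelled: the downstream fit is
per-plane 2D, so axial realism beyond "the spot appears on adjacent planes
more dimly" would add parameters without exercising any additional code
path.

Per-nucleus counts are Poisson: transcription sites with mean 1.5 (the
typical per-cell average for a highly expressed housekeeping transcript in
HeLa-like cells) and single-RNA spots with mean 20 by default (nuclear
single RNAs are far fewer than the cytoplasmic complement). A transcription
site renders one exon and one intron punctum at the identical position;
single RNAs render in the exon channel only. Site foci default to 5× the
single-spot amplitude; the true ratio is not well characterized, so this is
an exposed modelling choice, not a measurement.

Noise is Poisson shot noise on the full signal plus additive Gaussian read
noise (sd 20 by default), the standard camera model; both components can be
disabled. All randomness in a generator call flows from one
`numpy.random.Generator`, so identical configs and seeds are bit-identical.

`min_spot_separation_px` (default 0, i.e. uniform placement) optionally
enforces a minimum distance between puncta within a nucleus. Real RNAs can
sit arbitrarily close; the option exists so that accuracy measurements can
separate detector performance from the physics of unresolvable pairs — two
true spots closer than the detector's minimum separation are one blob, and
no algorithm can count them twice. Band-pass filtering also has a negative
ring that measurably suppresses a dim spot within ~4–5 px of a 5×-brighter
focus; fixtures that assert exact recovery place spots ≥ 6 px apart.

What passing on these scenes does **not** show: robustness to uneven
illumination, autofluorescent debris, spectral bleed-through, overlapping
nuclei, or aspherical/elliptical PSFs. None of these are simulated.

## Spot detection and localization

Detection runs per z-plane on the negated, scale-normalized
Laplacian-of-Gaussian response (σ = 1.3 px by default, matching the rendered
PSF scale). A voxel is a candidate if its response strictly exceeds the
threshold and is ≥ its 8 in-plane neighbours; candidates within
`min_separation_px` (default 3) of a stronger candidate are suppressed, which
also selects, per spot, the z-plane of maximal response. The default
threshold is mean + 5·SD of the filtered channel — parameter-light and
robust across the simulated intensity range — with a fixed-value override.
The candidate definition is deliberately simple enough to be re-derived by
an exhaustive scan, which the test suite does on small stacks.

Localization fits `b + A·exp(−r²/2σ²)` by Levenberg–Marquardt on a
(2·4+1)² window around the candidate, on the candidate's own z-plane only;
z is metadata, never a fitted coordinate. The σ parameter enters the model
squared, so its sign is normalized after fitting. Acceptance filters:
positive amplitude (an essentially flat window converges to A ≈ 0 and is
rejected as "flat"), σ within [0.4, 5] px, fitted center inside the window,
and RMS residual / amplitude ≤ 1. Windows clipped by more than half their
area at an image border are rejected ("border") rather than fitted on too
few pixels. Near-duplicate fits within the minimum separation collapse to
the brighter spot. Measured on noiseless inputs the fit recovers centers to
≲10⁻⁶ px (on-pixel) and ≤0.05 px (subpixel); at an amplitude-to-read-noise
ratio of 5 the empirical localization error is ≈ 0.4 px per axis, which is
why detection-accuracy checks use a 1 px match tolerance.

Coordinates everywhere: 0-based, x = column, y = row, pixel centers at
integer coordinates; every CSV header block repeats this.

## Segmentation

Provided label masks are the primary path (mirroring manually drawn
boundaries); `segment_nuclei_auto` (Otsu threshold → fill holes → drop
objects < 50 px → connected components) is a deterministic convenience for
well-separated nuclei. Subpixel centers are mapped to mask pixels with
round-half-to-even — numpy's default, deterministic, and documented because
the .5 boundary case is otherwise a portability trap.

## Colocalization

Candidate exon–intron pairs are those within 2.5 px laterally and ±1
z-plane (fits are per-plane, so a purely lateral window plus a plane
tolerance replaces a 3D distance). Stage 1 matches greedily in ascending
distance order, ties broken by (exon id, intron id); each spot matches at
most once. Stage 2 (on by default) keeps a pair only when each member is
the other's nearest in-window neighbour — a standard disambiguation for
two-stage colocalization schemes. On instances whose within-channel spots
respect the detector's minimum separation, greedy matching empirically
coincides with the exhaustive minimum-total-distance maximum-cardinality
assignment (verified over 200 seeded instances); with adversarially placed
spot chains the two can differ, which is why the mutual-confirmation stage
exists.

A transcription site additionally requires both spots to carry the same
nucleus label ≥ 1. Per-cell tables include zero-count nuclei. Spot SNR is
reported as (background + amplitude) / background — peak including
background over local background — with amplitude/background available as an
alternative, since the field uses both conventions; medians of per-cell
counts get a seeded bootstrap SE when an error estimate is needed.

## Amplification kinetics

Each amplification round at binding efficiency e multiplies the expected
spot intensity by 2e. The estimator regresses log₂(per-round median
intensity) on (round − first round)/step, so the fitted fold is per
amplification round even when only alternate rounds were imaged; fold =
2^slope, efficiency = fold/2 (an identity asserted on every output;
efficiencies > 1 warn, never clamp). The median is the default response
because amplified foci have a heavy right intensity tail; a mean mode
exists. Nonpositive intensities are excluded with a recorded count, and a
round with no positive sample is a hard error naming the round. The
simulated series draws mean-preserving lognormal samples at a configurable
CV (default 0.1 at 200 spots/round), under which the fold is recovered
within ±0.05 in ≥95% of seeds.

## Sorting and correlation

Gates are half-open [lower, upper) intervals on log₁₀ fluorescence —
lower-inclusive so each boundary value belongs to exactly one gate — and
must be disjoint and increasing. Events with nonpositive or non-finite
fluorescence are flagged "invalid" and excluded; every event gets exactly
one label, so gating partitions the input. The flow simulator draws each
latent class's log-fluorescence from a normal distribution (defaults:
means 1, 2, 3; sd 0.2 — about a decade between low and high, with ≥95% of
events falling inside their class's midpoint-bounded gate) and couples
per-class qPCR abundance to the class mean fluorescence with small
multiplicative noise. Pearson r is computed on (gate mean fluorescence,
abundance) pairs; fewer than three matched groups is an error, and zero
variance yields an explicitly flagged undefined result rather than NaN
surprises downstream.

## Chromatin accessibility

For each (group, replicate), U_mean is the arithmetic mean FE of the three
control-gene amplicons (5′UTR, intron, 3′UTR) measured in that same group
and replicate; a missing amplicon is an error naming it. Then
RQ = 2^−(FE_target − U_mean) and logRQ = log₁₀(RQ + 10⁻¹⁰); the 10⁻¹⁰
offset keeps RQ = 0 finite at −10 while shifting RQ ≥ 10⁻⁶ by < 10⁻⁹
relative. Gate contrasts use a paired t-test on per-replicate mean logRQ,
pairing by replicate index: t = mean(d)/(SD(d)/√n), df = n−1, two-sided p
from the t CDF, implemented as the closed formula rather than delegated, so
the degenerate cases are explicit — all-zero differences give t = 0, p = 1;
nonzero constant differences have zero variance and are flagged rather than
reported as infinite t. Holm adjustment across the three gate pairs is
available but off by default, matching the single-comparison convention for
this assay. The FE simulator shifts the target gene's FE down by
`effect_size` per gate step (lower FE = more accessible) and leaves the
control gene's distribution gate-independent; at a 1-FE-unit step, noise sd
0.2 and 6 replicates the G1-vs-G3 test has empirical power ≈ 1, and at zero
effect its type-I error is ~5%, as the calibration tests verify by
simulation (2000 null and 1000 alternative datasets).

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to make
each check statistically meaningful at interactive runtimes: 500-spot
scenes for detection accuracy, 500 nuclei for count-distribution checks,
100 seeds for kinetics recovery, 20 seeds for site recall and gate
monotonicity, 2000/1000 replicates for test calibration. Every stochastic
step takes an explicit seed; CLI reruns with the same seed are byte-identical
in all CSV payloads (manifests record no timestamps).

## Known limitations

- The detector assumes roughly isotropic, roughly PSF-scale blobs; highly
  elliptical or diffraction-ringed spots will be rejected by the σ band.
- Per-plane 2D fitting under-uses axial information; spots exactly between
  two planes lose up to a third of their peak signal.
- Greedy matching is not globally optimal in adversarial geometries (see
  above); mutual confirmation trades recall for precision there.
- The gate/qPCR correlation is computed over as few as three group means;
  its value is reported with n and should not be over-interpreted.
- Auto-segmentation is a single-threshold method and will merge touching
  nuclei; provide masks for crowded fields.
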