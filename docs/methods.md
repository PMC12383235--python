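# Methods

This note documents the models, estimators and numerical conventions the
package implements, the defaults it ships with, and what its synthetic
data do and do not emulate.

## Units and coordinates

All analysis is done in physical units: nm for geometry, minutes/hours for
time, pA/mV/pS for electrophysiology. Arrays are 0-indexed; the centre of
pixel/voxel *i* is at (i + 0.5) × pixel_size. Calibration metadata (pixel
size, frame interval, sampling rate) is mandatory in every reader — there
is no silent pixel-unit fallback, because nm/pixel confusion is the
dominant error mode in this domain.

## Morphometry

**Tracing.** Foreground is segmented by a half-amplitude threshold between
the robust background (median) and robust peak (99.9th percentile); Otsu
degenerates on sparse noiseless fields where the background is a single
grey level. Each connected object is skeletonized; the particle's long
axis is the longest geodesic path between skeleton tips (8-connectivity,
√2 diagonal weights). The pixel path is Gaussian-smoothed (σ = 1 px),
extended at each tip along the local tangent to the subpixel crossing of
the segmentation level in the interpolated image, and then trimmed by half
the mean ribbon width (mask area / skeleton length) — the apparent
boundary of a tube lies one half-width beyond its centerline endpoint.
Objects touching the field border are flagged and excluded from length
statistics (their length is censored); skeletons with more than two tips
return the longest path with a branch flag.

**Cross-sections.** Profiles are sampled by bilinear interpolation along
the in-plane normal, with the tangent taken over a few nm of arc (long
enough to average tracing wiggle, short against realistic curvature). The
baseline is the median of the outer 25% of offsets on each side — robust
to a neighbouring particle in one wing. `average_length` averages parallel
profiles along the tangent, the analogue of summing tomographic slices or
class-averaging, and is how profile-level noise is suppressed without
widening the cross-section.

**Diameter at 15% above baseline.** The width is measured between the
outermost linear-interpolated crossings of
baseline + 0.15 × (peak − baseline). Above-level runs are clustered
around the run containing the peak, merging across below-level gaps
shorter than `max_gap` (default 1 nm), so an isolated noise spike in the
baseline cannot masquerade as an object edge while small on-object notches
are bridged. The measure is exactly invariant under affine intensity
rescaling. On a Gaussian profile of width σ the convention returns
2σ√(2 ln(1/0.15)) ≈ 3.896 σ (closed form, used as a test oracle).

Two biases are inherent to the convention and worth knowing: on a
projected cylinder (chord-length profile) the unblurred 15% width is
2R√(1 − 0.15²) ≈ 0.989 × 2R, and Gaussian blur widens it (≈ +0.28 nm at
σ = 0.3 nm for a 2.8 nm tube). At the rendering defaults (σ = 0.1 nm)
the two effects nearly cancel and the measured diameter is faithful to
≈ 0.01 nm.

**AFM heights.** Frames are first-order flattened (plane fit to non-object
pixels; an error is raised if the object covers more than 60% of the
frame). Height is peak minus baseline on a cross-profile. On coarse grids
(9–19 nm pixels) a raster sample rarely lands on the tip-dilated ridge
apex, so single cross-sections read 2.2–2.8 nm for a 2.8 nm tube — the
same registration effect that makes real AFM height readings scatter over
2.5–3.0 nm; `search_length` searches nearby stations for the apex.

**Ring geometry.** Two orthogonal line profiles through the ring centre
give the outer diameter (outermost crossings, either the 15% convention or
an "at baseline" variant — both are implemented because published values
mix the two conventions) and the inner channel diameter (the same
fractional convention applied to the inverted central dip, measured
strictly between the two wall peaks; a dip shallower than 15% of the ring
amplitude raises "no channel"). For 3D fields the channel length is the
axial extent of ring material at the mid-wall radius, measured at the
half-maximum crossing (unbiased for a step edge); on the channel axis
itself the density vanishes both inside and outside the ring, so the dip
has no measurable axial boundary there.

**Length statistics.** Median is exact; the modal length is the centre of
the highest Freedman–Diaconis histogram bin, with ties broken toward the
smaller length (conservative for growth claims). The bin rule is recorded
in the output. FD-histogram modes are noisy at small n and large
dispersion: by simulation, a lognormal population with 15% mode accuracy
in ≥90% of replicates needs n ≈ 100 at dispersion σ ≤ 0.25, or larger n
at wider dispersions.

## Assembly kinetics

**ThT normalization and lag end.** Baseline = mean of the first 5% of
points, plateau = mean of the top 5% of values; both tails are robust to
slow pre-transition drift. The lag end is the first upward crossing of 10%
of the normalized amplitude (midpoint: 50%), linearly interpolated on a
lightly smoothed series (11-point boxcar; the window is short against any
realistic transition, so the crossing is unbiased while threshold-level
sample noise is suppressed). Curves that start above threshold or cross it
more than once are rejected as non-sigmoidal. Note an estimator property:
on a very shallow sigmoid whose signal is already rising at t = 0, the
5%-tail baseline absorbs part of the early rise and the detected lag
shifts late by up to ~1 h; the estimators are unbiased when the record
starts well inside the baseline, which is how the assays are run.

**Growth tracking.** The frame-0 object's arc-length midpoint defines a
fixed anchor. Per frame the filament is re-traced — segmentation here uses
light smoothing plus hysteresis thresholding (low 0.15, high 0.6 of the
robust amplitude), because a tip-broadened filament only ~1.5 px wide dips
below any single threshold where pixel centres straddle it, while surface
roughness never reaches the high level to seed a false object. End
identity is propagated by nearest-endpoint matching (robust to
whole-filament drift); each end's excursion is the arc length along the
current path from the point nearest the anchor to that end, minus its
frame-0 value (arc length, not Euclidean displacement — curvilinear growth
would otherwise be undercounted). The anchor is projected onto a densely
resampled polyline; projecting onto raw vertices quantizes the split at
the pixel scale and was the dominant rate-error source in development.
Per-end rates are plain least-squares slopes of excursion vs time
("linear best fit"), and monomer addition rates divide by the 0.48 nm
strand rise. Both per-end excursions and cumulative length are reported.

## Electrophysiology

Conductance is g = I/V per sample with samples at |V| < 5 mV masked
(unobservable, not zero). The baseline current is taken from the 0 mV
steps of the protocol when present — channel current vanishes there
regardless of gating state — else from a stated all-closed window. Open
levels are modes of the baseline-subtracted conductance histogram
(smoothed peak finding; a level must clear 4× the baseline noise SD, else
"no channel detected", or an all-closed idealization on request). States
are assigned by half-amplitude thresholds between adjacent levels; events
shorter than two filter time constants (τ = 1/2πf_c) are merged into their
predecessor. Windowed analysis (default 2500 ms; 1000 ms available — both
window lengths appear in published protocols) histograms open-state
conductance in 10 pS bins *centred on multiples of the bin width*, so a
level sitting on a round number is not split across an edge; the modal
conductance is the highest bin's centre; windows with no open samples
report 0 and are flagged. Negative conductance excursions are clipped into
the zero bin rather than discarded so open probability stays unbiased.
Per-recording summaries report the median modal conductance and both
percentile (20th–80th) and min/max ranges, since published "typical
ranges" mix the two.

The Hille model and its closed-form inversion are as in the README; the
quadratic-root solution is verified against a numeric root-finder to
1e-9 and the diameter↔conductance round trip holds to 1e-9 across
(10–2000 pS) × (0–20 nm) × (10–200 Ω·cm).

## Stoichiometry

density conversion 825 Da/nm³ (the standard ~1.35 g/cm³ protein density;
sometimes misprinted as Da/Å³ — the printed worked results, e.g.
64,000 Å³ → 52.8 ≈ 53 kDa → dodecamer, identify the intended unit
unambiguously); strand rise 0.48 nm per monomer; monomer mass 4514.04 Da
computed from the canonical 42-residue sequence (average masses) and
frozen as a constant, cross-checked in tests against an independent
residue-mass table. A truncated mode uses the ordered-core mass (residues
15–42, 2833.35 Da) for densities that likely exclude the disordered
N-terminus; 52.8 kDa then corresponds to ≈19 core-equivalents — reported
as computed, without forcing agreement with any particular published
count. Monomer counts round to the nearest integer with the exact float
always reported; masses print at two significant figures in kDa.

## Synthetic data: what it emulates, and what it does not

**Centerlines** are persistent random walks (default persistence length
600 nm, step 0.5 nm) with rejection-based self-avoidance at one tube
diameter. No curvature statistics are published for curvilinear
protofibrils; the persistence length is a free parameter chosen to give
gently curved, occasionally tightly turning filaments.

**AFM series**: the assembly is a 2.8 nm tube lying on a flat support;
the imaged surface is the grayscale dilation of that surface by a
spherical tip cap (default radius 20 nm) — first-order tip convolution,
which broadens widths to ~20 nm while leaving heights untouched — plus
white Gaussian roughness (default 0.2 nm, typical for mica in liquid).
Growth extends each end by rate × frame interval along the continuing
walk; the generator returns exact per-frame excursions and arc lengths.
Defaults: 8 nm/min per end, 8-min frames, 6 frames, 9–19 nm pixel range
supported.

**Density fields**: tubes are constant-density solid cylinders — 3D
volumes store binary occupancy, 2D images store the line-of-sight
projection (chord length), which is what class averages and micrograph
slices show. Annuli with a stated channel length are cylindrical shells
of that axial extent; without one, circular-cross-section tori. Gaussian
blur (default σ = 0.1 nm) then additive Gaussian noise. Overlapping or
margin-violating layouts are rejected (ambiguous tracing ground truth).
There is no CTF, no projection physics, no stain or ice model.

**Channel traces**: continuous-time Markov gating with exponential dwells;
multi-level channels are independent open levels sharing one closed state.
Defaults: 320 pS, open/close 20 s⁻¹ (mean dwell 50 ms, consistent with
channels that stay open for long periods with flickering), ±80 mV step
protocol with a 0 mV step, 2 kHz sampling, 8-pole Bessel-designed
zero-phase low-pass at 0.2 kHz, 2 pA noise. Current is g·V plus optional
sinusoidal drift. No ion selectivity, liquid-junction or capacitance
artefacts.

**Kinetic curves** are logistics with steepness set so the 10% crossing
falls exactly at the requested lag time — a closed form used as the test
oracle. **Length populations** are lognormal with the requested
distribution mode (mode = exp(μ − σ²)), default dispersion σ = 0.4,
matching the breadth of published length violins.

Passing the round-trip tests therefore demonstrates that the estimators
recover known geometry and kinetics through realistic pixelation, tip
convolution, blur and noise — not that they are robust to stain
artefacts, CTF, drift between frames, or crowded fields, none of which
the generators produce.

## Problem sizes in the default test run

The suite regenerates all fixtures at run time: 60 cross-profiles from 12
rendered tubes for the diameter property; 20 seeds × 6 frames for
growth-rate recovery; 60 s of 2 kHz trace (24 windows) for the
electrophysiology recovery; 100 seeds for lag-time noise tolerance. These
sizes keep the full suite under ~10 s while leaving the statistical
margins wide (e.g. 60/60 recent growth-recovery seeds pass against the
18/20 requirement).

## Known limitations

* Tracing assumes one connected, non-overlapping object per particle;
  crossing filaments are returned as a single branched object with the
  longest path flagged, not disentangled.
* The 15% width convention reads high under blur ≥ 0.3 nm (see above);
  widths from heavily low-pass-filtered maps should be interpreted with
  the convention's bias in mind, or measured at a different
  `threshold_fraction`.
* Idealization is threshold-based; it does not fit dwell-time kinetics and
  will merge genuinely sub-millisecond flicker into its neighbours.
* The AFM tracker follows one assembly; fields with merging or colliding
  filaments truncate the track at the last clean frame rather than
  resolving the merge.
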