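# Methods

## Model of the analysis

The package analyses 2D particle tracks of organelles (signaling endosomes,
mitochondria) moving along a myelinated axon around one node of Ranvier.
Positions are projected onto a user-supplied centerline polyline; the signed
arclength from the node centre, `s` (μm, + = distal), is the spatial
coordinate of all node-centred statistics. Projection is exact nearest-point
projection onto the polyline (not a spline); ties between equidistant
segments resolve to the lower arclength so results are deterministic. Spots
farther than 10 μm (configurable) from the centerline are flagged and
excluded.

Step speeds use the 2D Euclidean displacement between consecutive spots over
the elapsed time, while the step *location* is the midpoint of the two
projected `s` values. The two conventions are deliberately decoupled: speed
reflects what the tracker saw in the image plane, location what the axon
geometry implies. A step is assigned entirely to one 2 μm bin; with bin
width ≫ per-frame displacement the assignment error is negligible. Bin
edges are aligned at `s = 0` (bins `[-2, 0)`, `[0, 2)`, ...). Subdomain
boundaries follow the 38 / 4 / 38 μm partition with the node closed on both
sides (`[-2, +2]`); steps at exactly ±2 μm belong to the node.

Pauses are steps at ≤ 0.1 μm/s — the threshold absorbs breathing/pulsing
artefacts of intravital imaging. Terminal pause runs of ≥ 10 steps are
trimmed iteratively from both track ends before qualification; interior
pause runs of any length are retained. A track qualifies when it contains
≥ 10 consecutive moving steps over contiguous frames; a gap-spanning step
(1 missing frame) restarts the run count, and gaps of more than 2 frame
intervals split the track. Low per-axon counts (20, or 10 for retrograde
mitochondria) produce warnings rather than exclusions, since enforcement
mechanics are a study-design choice, not an algorithmic one.

The regional *relative pause frequency* divides the pauses in a location by
the steps in that location — the regional analogue of the global
time-paused formula and the only definition that yields per-location
fractions comparable across locations. The alternative normalisation
(share of all pauses) is available via `pause_freq_mode="share_of_pauses"`.

Mitochondrial direction is the sign of the net axial displacement over
non-pause steps of a qualified track; tracks without a qualifying run, or
with |net| below 2 μm (one bin width), are stationary. Directional counts
are per organelle, not per movement event: one mitochondrion contributes at
most once per subdomain × direction cell. Pooled flux per direction is the
mean of the three subdomain fluxes. For length statistics a track's region
is the modal subdomain of its spots, with nodal-centre tracks grouped with
distal; stationary-labelled tracks observed for < 50 % of the video are
excluded from the stationary class, because a briefly-seen passer-by
truncated at the field of view is not a stationary organelle.

Fluorescence line profiles are normalised to whole-window mean 1 after
background subtraction. Two background estimators are provided: the 10th
percentile of the profile (parameter-light, appropriate when most of the
window is signal-free — note it removes any flat baseline), and the mean of
an off-axon background region, which preserves the axonal baseline and is
what the accumulation analysis requires; the profile pipeline selects the
region method automatically when background samples are present. Peak
metrics report the argmax over the distal side and its ratio to the
proximal-internode mean; a flat profile yields ratio 1 with an undefined
peak flag.

The constriction detector defines the node length as the full width of the
diameter dip at half depth (fraction configurable), with boundaries found
by linear interpolation after a light 0.5 μm moving-average smoothing; the
smoothing leaves half-depth crossings of linear or (anti)symmetric flanks
unchanged while suppressing spurious threshold crossings under sampling
noise. Profiles whose relative dip depth is below 10 % raise a
"no constriction" error; equal minima resolve to the sample nearest the
window midpoint.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth attached to every dataset. Motile organelles start uniformly
in ±45 μm, and at each frame either pause (region-dependent probability,
zero true displacement) or advance by `direction × speed × Δt`, with the
speed drawn from a truncated normal (floor 0.15 μm/s keeps moving steps
above the pause threshold) for the region of the step's *starting*
position. The default pause model is per-step i.i.d. Bernoulli, so the
programmed probability equals the expected pause-step fraction exactly and
recovery targets are analytic; a geometric run-length variant with the same
stationary fraction is available for realism. Tracking stops when an
organelle leaves the ±50 μm field of view, as in real acquisitions; the
centerline is a straight 100 μm polyline with the node at its centre.

Each organelle carries one lateral offset (SD 0.2 μm), clipped to the local
axon radius when funneling is enabled, so trajectories narrow through the
constriction; emitted positions add isotropic Gaussian localisation noise
(SD 0.01 μm — intentionally optimistic, chosen so that pause detection at
the 0.1 μm/s threshold is essentially unconfounded; the generator verifies
empirically that < 1 % of true-pause steps appear to move faster than the
threshold and refuses configurations that violate this). Stationary
organelles are placed from a Gaussian cluster centred +3.75 μm distal
(SD 2 μm) and never move. Frame intervals default to 0.5 s (endosomes,
120 frames) and 1.7 s (mitochondria, 240 frames), inside the acquisition
ranges of intravital imaging of these organelles; track counts default to
300 per dataset plus 30–40 stationary organelles, which keeps every
recovery run in the seconds range while giving regional estimates a few
percent of sampling error.

Presets encode the study conditions: `endosome_paper` (retrograde, speeds
2.40 / 1.25 / 2.10 μm/s for proximal / node / distal, SD 0.25; pause
probabilities 0.042 / 0.30 / 0.099), `endosome_soleus_paper` (2.41 / 1.30 /
2.00 μm/s; pause probabilities shared with the fast-muscle preset, since
only the velocity effects differ between the two muscle types),
`mito_paper` (anterograde 0.500 / 0.360 / 0.456, retrograde 0.500 / 0.380 /
0.494 μm/s, SD 0.05; anterograde fraction 0.76; anterograde pausing raised
to 0.20 at the node vs 0.12 elsewhere, retrograde uniform 0.12; stationary
length 1.8 μm vs motile 1.1 μm), `accumulation_paper` (baseline 1 +
Gaussian bump of amplitude 0.5 at +3.75 μm, SD 2 μm, multiplicative
lognormal noise SD 0.1, additive off-axon background 0.5), and
`morphometry_paper` (internode 3.0 μm, node 1.4 μm, raised-cosine dip with
full width at half depth 4.0 μm, 5 % noise). `null_uniform` is the negative
control with identical parameters in all regions. The profile generator
emits off-axon background samples alongside each profile, mirroring an
experimenter's background ROI; the raised-cosine diameter flank is used so
the half-depth width of the dip equals the programmed node length in
closed form.

What the generator does **not** emulate: image formation (PSF, photophysics,
detection failures), curved "S"-shaped or circular trajectories (only
bounded lateral offsets), drift, fission/fusion, organelle interactions, and
axon-to-axon parameter variability beyond sampling noise. Passing recovery
tests therefore demonstrates the correctness of the estimators under the
assumed generative structure, not robustness to every artefact of real
intravital data.

## Numerical choices and degenerate inputs

- Truncated-normal draws use inverse-CDF sampling (`scipy.special.ndtr` /
  `ndtri`); a zero SD degenerates gracefully to the mean.
- All randomness flows from one `numpy.random.default_rng(seed)` per
  dataset; identical configs reproduce datasets bit for bit.
- Locations with zero moving steps report NaN velocity (missing, never 0);
  empty step tables propagate as empty frames, and pipelines raise a clear
  error when no track qualifies.
- Pearson correlation requires ≥ 3 pairs and non-constant inputs; the
  p-value is the standard two-tailed t-test with n−2 degrees of freedom.
- Per-axon/per-animal aggregation is an unweighted mean of axon means,
  warning below 3 axons per animal.

## Problem sizes

Recovery runs use 300 tracks per dataset averaged over 5 seeds (tracks),
20 profiles (fluorescence) and 10 profiles (diameter) — sizes at which the
estimators' sampling error is well inside the recovery bands while the full
acceptance computation completes in a few seconds on one CPU.

## Known limitations

- Midpoint binning combined with region-of-start speed draws biases the
  measured nodal mean slightly upward (fast steps that start just distal of
  the node have their midpoints inside it). With endosome step lengths of
  ~1 μm against a 4 μm node the effect is a ~2–3 percentage-point
  attenuation of the nodal slowdown; it is inherent to assigning finite
  steps to point locations, affects real tracking data equally, and is left
  uncorrected.
- The percentile background estimator cannot preserve a flat axonal
  baseline; accumulation ratios need a background region (or known value).
- Direction classification near the 2 μm stationary threshold is
  necessarily noisy for short field-of-view transits; such tracks are
  excluded from stationary length statistics but still count as motile when
  they qualify.
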