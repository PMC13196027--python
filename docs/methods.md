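# Methods

This note documents the models, parameter choices and numerical
decisions behind `microswim`, and what validation on synthetic scenes
does and does not establish about real recordings.

## Conventions and units

All lengths are micrometres, times seconds, angles degrees; the only
unit conversions live in `microswim.optics`. Headings use a polar-plot
convention: 0° points to the top of the frame (where a stimulation
light source typically sits), angles grow clockwise, and since image
y grows downward a heading θ maps to the unit displacement
(sin θ, −cos θ). Straight-down sedimentation is therefore 180°.
Computed values keep full precision; rounding to display precision
happens only in presentation code.

## Optics formulas

`rayleigh_resolution` implements r = 0.61 λ/NA; with near-infrared
imaging light (λ = 0.85 µm) and an effective NA of 0.12 the limit is
≈4.3 µm, which is why the package works with centroids and areas and
makes no claim about subcellular structure. The rolling-shutter
estimates treat the worst case of a cell moving parallel to the sensor
scan axis: the relative velocity error E_rel = v/(L_FOV·f) and the
shape distortion ΔL = v·L_cell/(L_FOV·f) = L_cell·E_rel. For a 10 µm
cell at 250 µm/s in a 245 µm vertical FOV at 30 fps these give 3.4%
and 0.34 µm — below the optical resolution, so no rolling-shutter
correction is applied anywhere in the analysis. Calibration states are
plain (µm/px, fps, width, height) records; the FOV is defined as
µm/px × pixel count, which is treated as authoritative when quoted
FOVs disagree with it after rounding.

## Synthetic scenes

The generator produces the population structure the analyses assume:

* **swimmers** — each draws a base speed from N(mean, sd) (clipped at
  0) held for the whole recording; the heading starts isotropic, fixed,
  or von Mises-concentrated around a preferred direction, and diffuses
  by a per-frame Gaussian of sd `turn_sd_deg_per_frame`. This gives
  ballistic paths with realistic heading persistence.
* **sedimenters** — fixed heading 180°, no heading diffusion, uniform
  individual sinking speed.
* **adherent** — static.

A uniform drift vector (µm/frame) is added to every particle. An
optional per-frame speed multiplier imposes stimulus-coupled behaviour
(e.g. a photoshock pause) as a piecewise schedule; behaviour is imposed,
not modelled — there is no phototactic steering dynamics, no
hydrodynamics and no cell–cell interaction.

Positions wrap toroidally, keeping density constant the way cells
entering and leaving a real field of view do; wrap events are marked so
trajectory statistics can use the continuous (unwrapped) paths. Cells
render as anti-aliased bright disks (linear edge ramp over one pixel)
on a uniform background with Gaussian pixel noise, clipped and
quantised to 8 bits; fixtures are written as PNG frames for
portability, while the readers accept any 8/10/16-bit grayscale input.
Exposure is instantaneous: no motion blur and no rolling-shutter
simulation, consistent with the sub-resolution distortion estimated
above. Motion and pixel noise come from separate seeded streams, so a
scene is bit-reproducible from its echoed config and drift never
perturbs the random draws (adding drift d shifts every displacement by
exactly d).

Default study conditions used in validation: 40-cell populations,
swimmers at 100 µm/s (sd 5–10) with 4–5°/frame heading diffusion,
sedimenters at 25 µm/s (sd 2), cell radius 5 µm, 0.86 µm/px at 30 fps,
background 0.2, noise sd 0.02 — speeds and sizes in the range reported
for *C. reinhardtii*-like cells, on frames of 400×300 px (or smaller
for long stimulus recordings) so that full-length runs stay cheap.

## Top-down pipeline

Dense flow is a pyramidal iterative Lucas–Kanade estimator
(`skimage.registration.optical_flow_ilk`, window radius 7, 3 warps);
on a noisy multi-disk test scene it recovers a 3.9 px rigid shift to
better than 0.02 px. The magnitude threshold default of 0.5 px/frame
sits above the noise floor observed on identical-frame pairs (<0.05 px)
and well below typical swimmer displacements (~4 px/frame at the
default conditions). Cell regions come from Canny edges (σ = 1.5) on
the earlier frame of the pair, morphologically closed and filled;
components outside (0.25×, 4×) the expected cell area π r² are
discarded. A region's mean vector averages the member pixels that
survived thresholding — zeroed noise pixels would otherwise dilute a
cell's displacement — and its magnitude is the norm of the mean vector,
treating the cell as a rigid translating body so internal vector noise
cancels rather than inflating speed.

Consensus drift estimation grows, from each vector as a seed, the fixed
point of "member iff within 7.5° of the group's circular-mean direction
and within ±20% of the group median magnitude", and keeps the largest
group. The angular tolerance default is the midpoint of the sensible
5–10° range; the magnitude rule is this package's explicit completion
of a direction-only criterion. The group mean is the drift; correction
subtracts it from every region vector. Two refusal guards apply at the
pipeline level: no correction when the best group holds under
`min_support_frac` = 0.2 of vectors (no coherent bulk motion), and no
correction when it holds over `max_support_frac` = 0.8 — near-unanimous
motion is indistinguishable from collective phototactic swimming and
must not be cancelled. In that regime the drift should instead be
measured on a dark pre-exposure segment (`estimate_drift_dark`), where
no directed swimming is assumed, all region vectors are averaged
without any consensus restriction, and the stored estimate is applied
across the experiment. By default the drift-group regions (presumed
non-motile) are excluded from the speed average; a flag includes them.

Known bias: with small populations (under ~20 regions per pair) the
consensus step occasionally captures a handful of coincidentally
aligned swimmers, and correcting by their vector inflates the remaining
speeds by up to ~20%. At the 40-cell study conditions the support gate
makes this negligible (recovered 93.6 vs 100 µm/s). Crowding biases the
other way: merged regions mix swimmer and non-swimmer pixels and dilute
speed, which is why validation keeps densities in the dilute regime the
method is designed for.

## Bottom-up pipeline

Segmentation is a local-mean adaptive threshold (block 51 px, offset
−0.08 on the [0, 1] intensity scale): a pixel is foreground when it is
brighter than its neighbourhood by the offset, suiting bright cells on
a darker background; an `invert` flag handles the opposite polarity.
Contours are traced by Canny on the binary mask by default (closing
ragged outlines; union with the mask guarantees no cell is lost), with
a raw-frame mode available; components get intensity-weighted subpixel
centroids (<0.1 px error on rendered disks, 0.5 px asserted).

The area filter pools areas over the whole video (per-frame pooling is
available by flag but is unstable at low counts), computes the 10% and
90% empirical quantiles with linear interpolation between order
statistics, and keeps areas in (q_low, q_high] — a deterministic
boundary rule. Below 10 detections the quantiles are meaningless and
the filter disables itself with a warning.

The linker is implemented natively so its behaviour is fully specified:
per live track a constant-velocity prediction (coasting through missed
frames), per frame a globally minimal-cost one-to-one assignment of
predictions to detections (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`) with pairs beyond the gate
forbidden; unmatched detections seed tentative tracks reported once
they reach `init_hits` = 2 points; tracks end after `max_skip` = 3
consecutive misses. The gate default should be ~3× the expected
per-frame displacement (12 px at the study conditions). Tracks are
processed in id order and assignment is deterministic; on
well-separated instances with ≤5 particles the linker is verified to
equal exhaustive minimal-cost assignment with zero identity swaps over
100 random instances. Dense cultures remain out of scope: merged
silhouettes produce identity swaps and fragmentation, which is a
documented property of the approach, not a defect to be tuned away.

## Motility metrics

*Speed-based classification* labels a track motile when its mean step
speed exceeds 5 µm/s — well above apparent centroid-noise speed at all
supported calibrations at 30 fps (0.1 px jitter at 0.86 µm/px and
30 fps is ≈2.6 µm/s) — and is flagged comparative, since slow swimmers
and stuck cells are indistinguishable near a surface.

*Trajectory-angle classification* estimates the modal sedimentation
speed as the histogram mode (20 bins, fullest-bin centre) of mean
speeds of tracks heading within ±15° of straight down, then labels
non-motile exactly the tracks inside that cone whose mean speed is
within ±25% of the mode. Both tolerances are package defaults for a
criterion stated qualitatively; they separate a 25 µm/s sedimentation
mode cleanly from 100 µm/s swimmers. With no downward track the speed
anchor is undefined and classification falls back to angle-only with a
warning. The fraction is absolute. Under toroidal wrapping (or cells
leaving a real FOV) faster cells fragment into more tracks, biasing a
per-track fraction upward; validation therefore classifies idealised
one-track-per-particle trajectories built from ground truth, and the
bias is the main caveat when applying the per-track fraction to long
recordings.

*Orientation* histograms use 16 bins of 22.5° by default; the circular
mean is atan2 of the mean unit vector and R its length, computed from
raw headings, not bin centres. Callers pass motile entries only,
otherwise sedimentation imprints a spurious downward mode.

*Photoshock* detection is windowed and relative: baseline is the mean
speed over 5 s before onset; a response requires the speed to fall
below 0.5× baseline within 1 s of onset; the response lasts until the
speed first stays above 0.7× baseline for 5 consecutive samples. The
relative thresholds make the detector invariant to rescaling the speed
series; the windows suit pulses ≥10 s apart and ~5 s responses, and
overlapping analysis windows raise an error rather than silently
sharing samples. Missing samples (pairs with no detected regions) are
ignored.

`speed_summary` reports the mean and sample SD (ddof = 1) over
replicate means, one replicate per recording; a single replicate has no
defined SD and reports NaN.

## LED protocol

Commands are compact JSON objects with keys from {pulse, r, g, b, w,
ir}, intensities 0–1000 (PWM duty), pulse in ms; serialization orders
pulse first then r, g, b, w, ir with no whitespace, byte-exact with the
driver's documented examples. The parser is strict: unknown keys,
duplicate keys, non-integer values and out-of-range intensities are
rejected; standard JSON whitespace is tolerated. The simulated driver
restores the pre-pulse state when a pulse elapses; a constant command
during a pulse takes effect immediately and updates the restore state
(last-writer-wins per channel); a second pulse during an active one is
rejected, since the firmware behaviour is unspecified and refusing is
safe and testable. Mapping duty to photon flux (µE m⁻² s⁻¹) is a
caller-supplied linear calibration — it depends on the individual
device. Transports are byte sinks: tests use the in-memory mock; the
serial (115200 baud) and MQTT classes import their backends lazily and
are optional.

## Validation scope

Passing tests on synthetic scenes establish that the pipelines recover
known kinematics under the stated conditions: rendered disks, additive
Gaussian noise, ballistic motion, uniform drift, imposed pauses. They
do not establish robustness to real-world effects the generator omits:
defocus and intensity variation across the FOV, non-circular and
rolling cell silhouettes, flagellar beat wobble, hydrodynamic
interactions, illumination flicker, or dense-culture occlusion. The
tolerances asserted (10–15% on speed recovery, 0.3 px/frame on drift,
±5 points on motile fraction, ±0.5 s on photoshock duration) were
chosen as the accuracy the method needs to be useful at the study
conditions, and the problem sizes (300-frame scenes at 400×300 px,
24 s stimulus recordings at 208×160 px) keep a full validation run in
the minutes range on one CPU.
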