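# Methods

## Scope and data model

The package analyses per-nucleus time series from live-imaged embryos:
a protein trace (nuclear GFP via a LlamaTag-style reporter, arbitrary
units) and a nascent-transcription spot trace (MS2/PP7 dot intensity,
arbitrary units; 0 = no detectable spot), sampled on a uniform frame grid.
Time is expressed in minutes relative to the onset of gastrulation
(negative before). An `EmbryoDataset` couples the traces with a neighbor
graph, the frame interval, a manual gastrulation estimate and the
computed one. All downstream statistics operate on this container, whether
the traces came from the image-quantification module or from the synthetic
generator.

## Trace conditioning

* **Resampling** — linear interpolation to a 20 s interval, anchored at the
  first frame, never extrapolating; re-application is a no-op.
* **Smoothing** — protein traces (and any derivative) are averaged with a
  centered 4 min moving window (13 frames at 20 s), truncated at the trace
  edges. NaN frames (nucleus untracked) are excluded from the local mean.
* **Spot-gap filling** — grayscale closing with a 3-frame flat structuring
  element (dilation then erosion): dips of one or two frames inside a burst
  (a dot drifting out of focus) are filled; gaps of three or more frames
  survive and terminate a burst. The operation is extensive and idempotent.
* **Background subtraction** — a scalar background is subtracted without
  clipping at zero, keeping ensemble means unbiased. For constructs where
  the background cannot be measured directly, GFP copy number is resolved
  by the control-embryo rule: with T_lower = mean − SD of the 1×-control
  AB medians and T_upper = mean + SD of the 2×-control AB medians, an
  embryo's AB median below T_lower ⇒ 1×, above T_upper ⇒ 2×, otherwise the
  embryo is excluded (boundary equality excludes, conservatively). Medians
  use Tukey's rule (points beyond 1.5×IQR from the quartiles dropped).
  An alternative background mode takes the mean protein level of the
  anterior neighbors of AB nuclei at the last frame (used for constructs
  with channel bleed-through).
* **Motion correction** — protein divided by the nuclear-marker trace
  normalized to its first frame; cancels focus drift affecting both
  channels and partially compensates bleaching.
* **Gastrulation time** — per nucleus, the time of the last strict local
  extremum of the smoothed y-coordinate ("local movement time"; plateaus
  resolve at their last frame, detected as a sign change of the first
  difference with zeros carried forward). A Gaussian kernel density
  (Silverman bandwidth) over all local movement times is evaluated on a
  1 s grid and its global mode is the embryo's gastrulation time. Fewer
  than five usable nuclei, or no extremum at all, is an error.
* **Completeness** — analyses keep only nuclei tracked without gaps from
  the video start to the manual gastrulation time.

## Boundary classification

Protein levels at the manual gastrulation frame are split into `stripe` /
`non-stripe` with Otsu's criterion evaluated **exactly on the sorted
values** (the threshold is placed midway between the two data points whose
split maximizes the between-class variance). Histogram-based Otsu can
return a bin center that undercuts part of the low class when the clusters
are much narrower than a bin, which silently promotes AB nuclei; the exact
variant is scale-invariant and order-invariant.

PB nuclei are stripe nuclei with at least one non-stripe neighbor, all of
whose non-stripe neighbors lie anterior (smaller x). Requiring at least one
non-stripe neighbor is deliberate: without it, stripe-interior nuclei with
no non-stripe contact would satisfy the rule vacuously. AB nuclei are the
non-stripe anterior neighbors of PB nuclei; each AB nucleus is paired to a
single PB partner (lowest id) so it is never counted twice during
re-alignment. Stripe numbers are assigned anterior→posterior from
Otsu-thresholded projection regions (image mode) or from 1-D bands of the
stripe nuclei's x positions (trace mode; gaps split into intra/inter-band
groups by the exact Otsu criterion, accepted only when inter-band gaps are
at least 3× the widest intra-band gap). Nearest band wins, ties to the
lower number.

Two refinement rounds replace the original manual curation with an
injectable **acceptor** predicate (tests use ground truth; the CLI offers
accept-all / accept-none). Round 1 suggests (a) non-stripe-list nuclei —
including current AB members — whose protein rises after gastrulation by
more than 25% of the mean AB level (configurable; no published value
exists), and (b) AB nuclei strictly more than one SD brighter than the AB
mean at gastrulation. Accepted nuclei move to the stripe list and the
classification re-runs through stripe numbering. Round 2 repeats (b) and
flags obvious trace errors (missing-value runs, frame-to-frame jumps
beyond the tracking search radius), which are dropped from the boundary
rows. The final assignment is restricted to complete traces.

## Burst statistics and aligned ensembles

A burst is a maximal run of positive spot intensity in the gap-filled
trace; its duration is (end − start + 1) × frame interval and its mean
intensity the mean of in-run values. Derived per-nucleus traces: mRNA rate
(the spot trace itself), active fraction (binarized), activation
probability (1 at each burst's first frame), burst duration (each active
frame carries its burst's duration), dot intensity (active frames only),
and `cov_paper` — the variance over the mean of the spot trace in a
centered 100 s (5-frame) window. The name records that this source
statistic is variance/mean (a Fano factor), not the usual SD/mean; the
formula is implemented as stated.

For ensembles, each PB nucleus is shifted so its own local movement time
is t = 0; AB traces shift by their partner PB's offset. Per time point the
mean (and SD across contributing nuclei) is reported only where at least
25 nuclei participate (protein, mRNA rate, active fraction, activation
probability) or at least 3 active dots (dot intensity, burst duration,
cov); fraction-type quantities are computed over all included nuclei and
carry no SD. The stripe-level mean of protein and of activation
probability receives one extra 4 min smoothing pass. SDs pool nuclei
across embryos.

Dot-intensity mode analysis: burst-mean intensities per class are fitted
with Gaussian kernel densities whose common kernel width equals the
Freedman–Diaconis bin width (2·IQR·n^(−1/3)) of the smaller-count class;
the low/high threshold is the densities' crossing between their modes
(midpoint fallback, flagged, when they do not cross). A burst is `high`
when its mean intensity strictly exceeds the threshold.

Heat-shock embryos are grouped by shock start: early [−60, −30), mid
[−30, −15), late [−15, 0] min. The published phenotype call was manual;
the automated surrogate (labelled as such in every output) flags a late
embryo when more than half of the anterior neighbors of AB nuclei burst
after the shock, and an early/mid embryo when any normally silent nucleus
does. Pulse width is measured as the width at half-maximum of the
ensemble-mean protein trace; the baseline is fitted locally (linear
through the flank medians outside 1.5× a first-pass width estimate) so
slow developmental drift of the mean protein level does not bias the
crossing points.

## Timer-versus-threshold test

Events: per transcribing PB nucleus, the first burst's start time
(relative to the computed gastrulation) and the protein level at that
frame; non-transcribing PB nuclei are excluded, and for all constructs
except the engrailed one only pre-gastrulation events count (traces after
gastrulation are unreliable without motion correction).

Null constructions run per embryo and pool per stripe:

* **Available times** — per permutation round, the observed levels are
  permuted across nuclei; each nucleus registers a uniformly chosen frame
  where its trace matches the assigned level within a relative tolerance
  (|f(t) − L| ≤ 0.05·L; the tolerance is interpreted relative to the
  level, and is configurable since the convention is ambiguous), or
  nothing if no frame matches. Rounds: all n! permutations are enumerated
  when n! ≤ 10000, otherwise 10000 independent uniform permutations are
  sampled.
* **Available levels** — rounds permute the observed times and read each
  nucleus's trace at the assigned time (nearest frame; out-of-span times
  register nothing), until the pooled count is within 5% of the
  available-times count ("comparable") or the permutation budget is
  exhausted.

Each observed list is compared with its null by a one-sided two-sample
Kolmogorov–Smirnov test with alternative "available values are smaller"
(earlier times / lower levels): D⁻ = supₓ[F_avail(x) − F_obs(x)], p =
exp(−2 D⁻² mn/(m+n)), rejected at α = 0.05. An exact label-permutation
p-value is available for small samples; the closed-form one-sided formula
is mildly conservative there, and frame-grid ties deflate D⁻ slightly,
whereas the permutation p remains valid under ties. Verdict:
timer-consistent when the times test rejects and the levels test does not;
threshold-consistent for the mirror; inconclusive otherwise. Seeds for
every random element are recorded in the report.

## Synthetic embryo generator

The generator emulates the statistical structure the analysis assumes and
carries full ground truth, so recovery is checkable stage by stage. What
it does *not* emulate: nuclear divisions, bleaching kinetics, realistic
detector noise, z-motion artifacts, or embryo-to-embryo variation in
developmental speed — passing tests demonstrate the pipeline's
correctness on data with the stated structure, not performance on raw
microscopy.

* **Geometry** — a jittered hexagonal lattice (default 16 rows × 18
  columns, 20 px spacing; x anterior→posterior, y dorsal–ventral). Each of
  3 stripes occupies three columns; the anterior-most stripe column is the
  PB row and the column before it the AB row (48 PB and 48 AB nuclei per
  embryo). Neighbors come from a Delaunay triangulation with long edges
  removed. Nuclei drift in y at 3 px/min downward before their own
  gastrulation onset (drawn with 0.4 min jitter around t = 0) and upward
  after; the equal speeds keep the smoothed-trace extremum centered on the
  true onset, which the one-frame recovery property requires.
* **Protein** — class-specific monotone splines through calibration
  anchors: AB and PB share their history until −20 min (both declining
  from a −35 min peak), then PB rises to exactly `protein_ratio_pb_ab`
  (default 4) times the AB anchor (0.5 a.u.) at t = 0 and keeps rising
  after gastrulation (the diagnostics for misclassified dim boundary
  nuclei rely on that rise). Non-stripe nuclei follow 0.9× the AB shape,
  stripe-interior nuclei 1.05× the PB tail. Per-nucleus variability: a
  lognormal-like amplitude factor (SD 0.15) and a timing shift
  (SD 4 min); measurement noise is Gaussian (SD 0.05 a.u.) on top of a
  0.2 a.u. nuclear GFP background. With all noise fields zero the PB/AB
  ratio at t = 0 is exactly 4 and the whole pipeline is deterministic
  given the seed.
* **Transcription** — alternating on/off episodes. On-durations are
  truncated exponentials (low mode: mean 2 min, max 5 min, mean intensity
  0.4 ± 0.08 a.u.; high mode: mean 8 min, max 20 min, 1.1 ± 0.12 a.u.);
  off-intervals are exponential (means 3 and 2 min) with a 1 min floor so
  that the 3-frame closing can never merge two real bursts. Burst
  frequencies and inter-burst intervals are free parameters (no published
  values); the truncated-exponential choice is the simplest memoryless
  model matching the printed duration bounds. In-burst frames get Gaussian
  intensity noise and a 5% detection dropout, producing the short dips the
  gap-filling stage repairs. Intensities are floored at 0.05 a.u. (the
  detection floor).
* **Construct logic** — endogenous: AB and non-stripe nuclei burst in the
  low mode until a per-nucleus shutdown drawn as divergence time (−30 min)
  plus Exp(6 min) — so the AB activation probability declines after the
  divergence and the PB/AB mRNA-rate fold at t = 0 exceeds 50 as an
  emergent property; PB/interior nuclei burst low until their activation
  time, then high. zebra: low mode only, PB activity fading from −15 min.
  autoregulatory: high mode only, starting at the activation time (the
  first burst begins exactly at activation). engrailed / `second_gene`: a
  second high-mode unit starting `second_gene_offset` (10 min) after the
  first unit's activation.
* **Activation models** — timer: activation ~ Normal(−15, 3) min.
  threshold: the first frame at which the clean (noise- and
  background-free) protein signal reaches `threshold_level` (default
  1.2 a.u., which the mean PB trace crosses near −15 min, making the two
  models comparable). Under the timer, amplitude variability disperses the
  levels at activation while times stay tight; under the threshold, timing
  variability disperses the crossing times while levels pin to the
  threshold — the mirrored event-cloud structure the KS construction
  discriminates.
* **Heat shock** — a Gaussian pulse added to every protein trace, peaking
  15 min after the shock start, with width at half-maximum equal to
  `pulse_duration` (15 min). A late shock (start ≥ −15 min) makes each
  normally silent nucleus competent to burst ectopically with probability
  0.8; early shocks induce nothing.
* **Rendering** — any frame can be rendered as a 2-channel z-stack
  (Gaussian nuclear blobs; diffraction-limited spots spreading over
  adjacent planes; uniform cytoplasmic background) to exercise the image
  module round trip.

## Image quantification

Nuclei are segmented per frame on a maximum-intensity projection of a
z sub-stack around the middle plane: LoG filter sized to the nuclear
diameter, Otsu threshold, connected components, one-pixel thickening
without merging. Tracking is a constant-velocity predictive linker
(prediction = last position + last displacement; greedy nearest-match
within a 10 px initial / 20 px search radius; no gap closing) —
a self-contained equivalent of the Kalman tracker the original analysis
ran in external software, with the same radii. Labels are expanded to a
plane-covering tiling by nearest-seed assignment; tile adjacencies define
the neighbor graph. Protein is the mean of the protein channel within the
core mask over three slices centered on the brightest marker slice
(clipped at stack edges). Spots are detected per z-plane (LoG +
user-chosen threshold — a deliberate compromise between real and spurious
dots with no derivable default), quantified by a 7×7 px 2-D Gaussian fit
whose offset estimates the local background (fit failure falls back to
peak minus window median, flagged), clustered within 2 px in xy and
adjacent z with the brightest member representing the spot, assigned to
the expanded tile under them, and capped at one (the brightest) per
nucleus. Anomalous nuclei are dropped per frame when segmented or
expanded area deviates more than 2×MAD, or intensity more than 3×MAD,
from the median (raw MAD, no consistency factor; a zero MAD keeps exact
median values only, which preserves identical inputs and still rejects
gross outliers).

## Problem sizes and calibration experiments

The recovery experiments run the full pipeline at the study's default
configuration: 10 embryos (≈ 480 PB nuclei) for the ratio and
timer-verdict experiments, 5 embryos for the mode/duration and two-gene
experiments, 20 seeded replicates per activation model for verdict
recovery. Type-I calibration of the two KS tests draws the "observed"
events iid from the null construction itself (uniform trace/level pairs
with a uniformly chosen matching frame; uniform trace/time pairs read off
the trace) — a single extra permutation round would be a balanced,
stratified draw whose empirical distribution hugs the pool far too
closely to measure calibration — and uses the exact permutation p-value
against a 400-sample subsample of the pooled null, over 1500 replicates
split across three independent seed streams. Measured rejection rates sit
within the binomial band around the nominal 5%.

## Known limitations

* The acceptor predicate automates a manual curation step; on real data a
  human (or a trained classifier) must stand in for ground truth.
* The heat-shock phenotype call is a surrogate for visual scoring and is
  labelled as such in all outputs.
* Bleaching is only partially compensated (through motion correction), as
  in the source procedure.
* The closed-form one-sided KS p-value is mildly conservative for small
  event counts; the exact permutation option is preferred below ~100
  events.
* The image module assumes pre-rotated stacks (stripes vertical) and does
  not handle mitosis or 3-D segmentation.
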