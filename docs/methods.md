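# Methods

`memquant` quantifies how a cytosolic signaling protein is recruited to
the plasma membrane: equilibrium binding to lipid vesicles and
receptor-derived peptides, single-molecule colocalization kinetics with a
membrane receptor, and cell-image translocation metrics. This note
documents the models, the estimators, the synthetic data that the tests
run against, and the numerical choices that were genuinely open.

## Equilibrium binding

### Model

Both assays reduce to the one-site Langmuir isotherm. For SPR, the
steady-state response at protein concentration `P0` is normalised by the
saturating response `RUmax`, and the fractional occupancy obeys

    RU/RUmax = 1 / (1 + Kd / P0).

The approximation of `P0` by the *total* protein concentration is valid
because the protein is in vast excess over the lipid binding sites on the
sensor surface. For fluorescence anisotropy, the labelled peptide is held
at a few nM while the protein is titrated in μM; in this ligand-excess
regime the bound-peptide fraction follows the same hyperbola,
`A_norm = 1/(1 + Kd/P0)` after normalising the anisotropy to
`(A − A_min)/(A_max − A_min)`.

### Steady-state extraction

Association-phase sensorgrams are reduced to a plateau estimate as the
mean of the final 10% of time points; `RUmax` is the mean plateau of
replicate traces at a saturating concentration (e.g. 1 μM), with the
across-replicate SD reported. Dissociation phases are accepted by the
reader but never analysed (they are typically too slow to be useful).
The 10% tail is a package choice: it trades a small bias (if the trace
has not fully plateaued) against variance from single-sample plateaus.

### Fitting

Kd is optimised on a log scale — positivity by construction — by damped
(Levenberg-type) least squares, so the reported `Kd` is the global SSE
minimiser on noiseless data for any `Kd` between 1 nM and 1 mM (tested
property). The fit is invariant to the ordering of concentration points.
Standard errors come from the local curvature (Gauss–Newton Hessian) of
the residual surface via the delta method; a seeded case-resampling
bootstrap (n = 1000) is available instead, which matches the spirit of
the triplicate ± SD convention used when reporting table values.

The anisotropy fit carries one extra parameter: a free saturation
amplitude, profiled out in closed form at each candidate Kd. The reason
is structural: when `A_max` is taken as the *observed* maximum of a
titration that does not fully saturate (a 0–150 μM titration of a
~20 μM-Kd interaction reaches only ~88% occupancy), the normalised curve
cannot equal `1/(1+Kd/P0)` for any Kd, and forcing amplitude 1 biases Kd
downward by tens of percent. With the free amplitude the estimator is
exact on noiseless data regardless of how far the titration saturates,
and reduces to the amplitude-1 model when it does saturate. Lipid-surface
fits keep the amplitude fixed at 1 because `RU/RUmax` is normalised by an
independently measured `RUmax`.

A whole-isotherm response below 0.05 is rejected as "no binding
detected" rather than returning an unidentifiable Kd.

### Units and comparisons

Lipid-surface Kd values are carried in nM and peptide Kd values in μM,
explicitly, on every estimate; fold-change helpers refuse to compare
mismatched units. `affinity_fold_change` reports either the Kd ratio
(`kd_a/kd_b`) or the percent affinity increase `100·(kd_a/kd_b − 1)`
with affinity ∝ 1/Kd and `kd_a` the weaker binder. The packaged
reference Kd table (lipid surfaces and GS/L45 receptor peptides for the
wild type and binding-site mutants) feeds the selectivity report, which
emits fold changes versus the wild type and versus a reference surface
and flags loss of lipid selectivity below a configurable threshold
(default 2).

## Single-molecule colocalization kinetics

### Event model

Two registered, time-aligned channels: receptors (channel 1) and adaptor
molecules (channel 2). An adaptor is colocalized in a frame when its
Euclidean separation from a receptor is strictly below 400 nm; if several
receptors qualify, the nearest wins (ties to the lower receptor id — the
data give no better criterion, and a deterministic rule keeps runs
reproducible). An event is a maximal run of consecutive frames with the
same receptor; its duration is `n_frames × Δt` (the frame grid offers no
sub-frame information, so n frames map to n·Δt). Events with duration
≤ 0.2 s are discarded. Events touching a track's first/last frame or the
movie boundary are censored; the default policy excludes them from
fitting (reporting the count), with "include-as-uncensored" and a
Kaplan–Meier option ("km-censored") selectable.

### Survival fit and discretization

The empirical survival fraction `P(dwell ≥ t)` on the frame grid is fit
by nonlinear least squares to `P = P0·e^(−kt)` (k on a log scale,
uniform weights, bins with at least one surviving event), and the
dissociation half-life is `ln 2 / k`, exactly, by construction.

Dwell times generated by per-frame unbinding are geometric in frame
counts, with `p = 1 − e^(−k·Δt)`. Two consequences worth recording:

* The survival function of that law *is* exactly exponential at the grid
  times — `P(m ≥ j) = e^(+kΔt)·e^(−k·jΔt)` — so the survival-curve fit
  recovers the continuous-time `k` without discretization bias; the
  discretization is absorbed into the amplitude `P0` (which therefore
  legitimately exceeds 1 slightly).
* The closed-form moment estimator `k̂ = 1/(mean dwell − min_duration)`,
  reported as a cross-check on every fit, *is* biased:
  `mean − t0 = Δt/p ≈ 1/k + Δt/2`, i.e. a relative error growing like
  `k·Δt/2` (≈11% at k = 5 s⁻¹, Δt = 50 ms). Disagreement between the two
  at high `k·Δt` is expected, not a defect.

The per-molecule survival histogram (percentage of adaptors with at
least one event of duration ≥ t) is monotone non-increasing by
construction and matches the empirical survival function on simulated
dwells. Half-life time courses across stimulation timepoints attach an
SD from a seeded bootstrap that resamples cells when cell labels are
present (events otherwise), and flag the maximum — the transient peak of
receptor engagement a few minutes after stimulation is read off this
series.

Chance colocalization is *not* corrected for: a free adaptor that
lingers within 400 nm of a receptor for more than 0.2 s is an event by
definition. The generator conditions below quantify how rare this is in
a sparse field; in dense fields the fitted `k` will be biased downward.

## Spot detection, linking, registration

Detection: difference-of-Gaussians band-pass at σ and 2σ (σ = PSF sigma,
converted from nm to pixels), local maxima above `snr_threshold` times a
robust MAD-based noise estimate of the band-passed frame, minimum peak
separation at the 2σ resolution limit (closer maxima are shoulder
artefacts of one emitter), duplicate maxima within 1σ merged keeping the
brighter, and sub-pixel refinement by intensity-weighted centroid in a
4σ-radius window over the positive band-passed signal. Coordinates are
continuous nanometres with pixel centres at `(index + 0.5)·pixel_size`.
At SNR 10 this localises isolated spots to ~0.3 pixel RMSE; two emitters
closer than ~2.6 pixels merge — the density limit of the method.

Linking minimises the total squared displacement per frame pair over
pairs closer than `max_displacement` (optimal bipartite assignment via
the Hungarian algorithm on the gated cost matrix; deterministic, and
invariant to spot order within a frame). Unmatched spots seed new
tracks. Gaps up to `max_gap` frames are closed with the distance gate
scaled proportionally to the elapsed frames, and optionally filled by
linear interpolation so that a single missed detection does not split a
downstream colocalization run. Two asymmetries keep gap closing honest:

* resuming across a gap pays a surcharge of `(gap−1)·max_displacement²`,
  while skipping a frame costs a flat `max_displacement²` — so a track
  seen in the previous frame always outcompetes a stale one for the same
  spot. Without this, a spurious birth near a real molecule can survive
  indefinitely by "time-sharing" that molecule's detections with the
  genuine track (each track claiming every other frame, both kept alive
  by gap closing) — a failure mode we observed, which multiplies event
  counts several-fold;
* an optional dedupe pass drops tracks that shadow another track within
  a configurable radius for most of their overlap (off by default; use a
  radius well above the localization error and below typical
  inter-molecule distances).

Tracks shorter than `min_track_length` (default 4) are discarded. The
default gate `4·sqrt(4·D·Δt)` covers > 99.9% of Brownian per-frame
displacements at diffusion coefficient D.

Registration estimates the affine map taking channel-2 fiducial
positions onto channel 1 by linear least squares on ≥ 3 non-collinear
bead pairs (the classic chromatic-aberration correction), reports the
RMS residual, and is applied to spots or tracks before event calling.

## Synthetic data: what it emulates, and what it does not

All generators are seeded (`numpy.random.default_rng`, one stream per
call) and bit-reproducible.

* **Isotherms / titrations** — exact Langmuir curves plus additive
  i.i.d. Gaussian noise. Real sensorgrams have drift, bulk shifts and
  mass-transport effects that are *not* modelled; passing recovery tests
  bounds estimator error under the stated noise only.
* **Two-channel movies** — receptors and adaptors do 2-D Brownian steps
  (per-axis SD `sqrt(2DΔt)`) in a reflecting box; a free adaptor within
  the capture radius of a free receptor binds with `p_bind_per_frame`
  (nearest receptor first, strictly 1:1 — no stoichiometry information
  exists, and 1:1 is the simplest testable model); bound adaptors ride
  their receptor at zero true separation and unbind per frame with
  `1 − e^(−k_off·Δt)`, recovering the continuous rate as Δt → 0.
  Observed positions add isotropic Gaussian localization error, and the
  adaptor channel passes through an affine chromatic distortion. Not
  modelled: blinking and bleaching, 3-D excursions into the cytosol
  (unbinding leaves the adaptor diffusing in the plane), anomalous
  diffusion, membrane topology.
* **Frame rendering** — each localization becomes a 2-D Gaussian PSF of
  given integrated intensity on a constant background, with Poisson shot
  noise. SNR is defined as peak amplitude over `sqrt(background)`.
* **Cell images** — concentric compartments (nucleus, cytosol, a
  plasma-membrane ring straddling the cell edge) with additive Gaussian
  noise: enough to validate the ratio arithmetic and peak finding, not a
  model of real cell morphology.
* **Ratiometric pairs** — channel b is a constant reference and channel
  a is `calibration(mol%) + noise` times b, so the per-pixel ratio
  encodes the lipid map exactly; the calibration must be strictly
  monotone and is always injected (table or callable), never hard-coded.

### Study conditions for the movie-chain checks

The full-chain checks (render → detect → link → register → coloc → fit)
run at: 28 × 28 μm field, 100 nm pixels, PSF σ 130 nm, SNR 10 on
background 100; Δt = 50 ms, 2400 frames (2 min per movie; three movies
pooled for the rate fit in the test suite, eight in the reproduction
script); 16 receptors at D = 0.05 μm²/s and 10 adaptors at D = 3 μm²/s
free — values typical of slow, confined transmembrane receptor
complexes and peripherally attached lipid-binding domains, and sparse
enough that distinct molecules rarely come within the PSF merge radius
(chance pair encounters, which can swap or break track identities and
split events, scale with density squared and receptor mobility);
k_off = 1 s⁻¹; diffusion-limited binding (capture radius 150 nm,
binding probability 1), which keeps "capture statistics well
separated": an adaptor that approaches a receptor binds rather than
lingering, so proximity episodes and true bound intervals almost
coincide. Linking uses max_gap = 6 with interpolation, wide enough to
bridge the occasional multi-frame detection merge of two nearby
molecules. Event
precision/recall against ground truth is scored in exactly that regime
on registered true-identity tracks with 20 nm localization error,
pooled over five movies. Matching is coverage-based (the
temporal-event-detection convention): a called event is correct when at
least half of its frames lie inside true bound intervals of the
spatially same molecule pair, and a true interval is recovered when at
least half of its frames are covered by such events. Events may match
completed intervals of any duration — a binding just under the 0.2 s
cut whose approach frames push it over the cut is not a false positive
— while recall is scored only on above-cut intervals. One-to-one
interval matching would double-penalise a single proximity episode
spanning a quick unbind/rebind, which the <400 nm rule genuinely cannot
separate. Residual mismatches are rare >0.2 s grazes by unbound
adaptors and fragments from tracking splits.

## Image quantification

* **Membrane translocation** — on an optionally smoothed line profile
  across the cell, the plasma-membrane peaks are the highest local
  maxima in the outer thirds of the span (one per side; flat-topped
  peaks handled); `F_m` is the mean of the two peak intensities and
  `F_c` the mean strictly between them, excluding a half-smoothing-window
  buffer around each peak. The ratio is invariant to positive scaling
  and to reversing the line. Fewer than two usable peaks raises a
  shape error so the caller can redraw the line (e.g. avoiding a bright
  nucleus). With a wide membrane ring, ring-shoulder samples between
  the peaks inflate `F_c` by roughly `(F_m − F_c)·w_ring/L`; profiles
  should cross thin membrane sections, or the smoothing window be
  widened to match.
* **Nuclear translocation** — `I_nuc/I_cyto` from disjoint masks (≥ 50
  pixels each) or from ≥ 5 cross-sectional lines with explicit nuclear
  spans. Mean intensities are the default (area-independent); integrated
  ("total") intensities are available because both conventions appear in
  practice — with unequal compartment areas they differ by the area
  ratio, so the mode is recorded on the result.
* **TIRF time course** — masked mean intensity per timepoint minus the
  t = 0 mean; the series starts at exactly 0 by construction and is the
  raw series minus a constant. Per-cell series aggregate as mean ± SD.
* **Lipid maps** — per-pixel channel ratio a/b, with denominator pixels
  below 1% of the masked median of b excluded (division guard), mapped
  through the injected calibration (piecewise-linear for tables); ratios
  outside a table's domain are clamped, counted and warned about.
  The spatial average is the mean over valid pixels; display bounds
  default to 0–1.5 mol%, the physiological range of the target lipid.

## Problem sizes

Default test and reproduction runs use: 200 simulated isotherms and 200
titrations for recovery medians; 100 random small track instances for
oracle equivalence; 25 replicates × 4 rates × 1000 dwells for kinetics
recovery; three (tests) to eight (reproduction script) 2400-frame
movies for the full chain and five for event scoring. These sizes put
Monte-Carlo error comfortably below the
tolerances they are checked against while keeping a full run in minutes
on one core.

## Known limitations

* No correction for chance colocalization density; dense fields bias
  `k` downward.
* No two-component dwell mixtures or hidden-Markov bound/unbound
  inference; a single exponential is assumed.
* Detection merges emitters within ~2σ; the linker's dedupe pass can in
  principle delete a genuine molecule that shadows another for most of
  its lifetime.
* The membrane-profile rule depends on the line actually crossing two
  membrane sections; the package requires explicit line coordinates and
  does not attempt automated placement or cell segmentation.
* Kinetic (kon/koff) analysis of sensorgrams, mass-transport correction
  and competitive-binding models are out of scope; competition data are
  represented as separate Kd fits.
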