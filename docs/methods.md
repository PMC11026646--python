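# Methods

This note documents the models and procedures behind each pipeline stage,
the parameters that matter, what the synthetic scenes do and do not emulate,
and the numerical choices made where the design was genuinely open.

## Calibration model

All images are luminance arrays with physical calibration attached: an
isotropic lateral pixel size (µm/px), a frame interval (s) for time-lapse
series, and a z step (µm) for stacks. Every physical rule in the package —
the 5 µm² component-size rejection, the 15 µm overlap cut-off, top-hat
radii — is specified in micrometres and converted through the calibration,
so the same configuration applies across magnifications. Coordinates are
(row, col), 0-based, at pixel centres; bounding boxes are half-open.

## Synthetic scenes

The generator exists to make every stage testable by parameter recovery.
Its defaults encode the acquisition the pipelines assume:

| parameter | default | rationale |
|---|---|---|
| pixel size | 0.2 µm/px | confocal sampling at ~63–100× |
| frame interval × frames | 1 s × 60 | one image per second for a minute |
| tunnel segment | 145 µm | the analysed stretch of a microtunnel |
| tunnel ROI width | 12 px (2.4 µm) | the ROI hugs the axon bundle, not the full tunnel |
| PSF sigma | 1.2 px | diffraction-limited punctum at this sampling |
| puncta amplitude / noise σ | 500 / 100 counts | SNR 5, the hardest regime the pipelines are specified for |
| MEA | 10 kHz, 7 min, σ = 5 µV, −60 µV spikes, ~1 Hz, 2 ms refractory | typical in vitro multi-unit recording |

Mitochondria are isotropic Gaussian blobs on a flat-plus-linear-ramp
background (the nonuniform illumination the top-hat stage removes), either
stationary or advancing along the tunnel axis at a constant signed speed
(positive = anterograde = increasing column). Motility scenes place objects
with a minimum separation along the axis and use 31 stationary plus 2 or 5
motile per tunnel, giving realised motile ratios of 0.0606 and 0.1389 — the
two group means the recovery benchmarks target. Density scenes (counting)
use a 50-px-wide ROI and jittered-grid placement so 50–200 puncta stay
non-overlapping; sharp-edged discs of exactly known pixel area (e.g. 4 and
6 µm²) can be injected to calibrate the size-rejection rule. Neurite scenes
draw smooth monotone paths in disjoint horizontal bands with optional
monotone side branches; every free terminus carries a brighter bouton blob,
and the path graph fixes the true terminus count (two per path plus one per
branch — a geometry in which fewer than two termini per neurite cannot
occur). Synapse scenes stamp sharp discs: co-located in both channels for
true contacts, isolated per channel otherwise. MEA traces are white
Gaussian noise plus a fixed 1-ms biphasic dominant-negative template at
Poisson times; coupled pairs co-spike at a stated lag with a stated
probability, and truth records the rendered trough time of every spike.

One integer seed drives everything through named CRC-keyed sub-streams, so
identical parameters give bit-identical scenes.

What the scenes do **not** emulate: realistic 3-D optics (no axial PSF, no
depth blur), photobleaching, motion other than constant-velocity runs
(pausing, reversals, the short bidirectional flutter real mitochondria
show), neurite crossings between cells, intensity heterogeneity between
organelles, LFPs/oscillations, spike-waveform variability, electrode drift
or stimulus artifacts. Passing recovery tests therefore demonstrates that
the algorithms are correct and well-calibrated under their stated
assumptions — not that they are robust to every pathology of real data.

## Thresholding: when a histogram split is the wrong tool

Otsu's method and the Triangle method both pick a threshold from the
gray-level histogram, and both assume the foreground occupies an
appreciable histogram mass. In tunnel frames, filtered kymographs, z-stack
slices and sparse puncta channels the foreground is 1–10 % of pixels; at
SNR 5 the between-class criterion then lands inside the noise mode and the
mask floods (measured during development: ~70 false tracks per 8 true ones,
660 detections for 51 puncta). The detection stages therefore default to a
**noise-referenced robust threshold**: background level and noise scale are
estimated from the lower tail of the intensity distribution (the q10/q25
quantile pair, which bright objects cannot contaminate), and the threshold
is that level plus `threshold_nsigma` noise SDs. Histogram methods remain
available (`threshold_method="otsu"`) and are the right choice for
high-contrast, high-fill data; the bouton chain keeps Otsu but floors it at
the noise level, since adaptive equalisation stretches background-only
tiles as readily as signal. The `primitives.threshold` operator itself
implements plain Otsu/Triangle over 256 bins and is used directly wherever
fill fractions are healthy (coverage ratios, co-occurrence masks on dense
fields).

## Mitochondrial detection

Chain: Gaussian smooth at the PSF scale (a matched filter; the frame is
first padded with its median so reflect-style padding cannot double the
noise variance along the border) → white top-hat with a 2-µm disc →
robust threshold (4.25 σ footprint, with the additional requirement that a
component contain at least one ≥ 5 σ pixel — noise clusters hug the
footprint threshold, real puncta peak far above it) → 8-connected
components → rejection of components larger than 5 µm² or, for components
of at least 10 px (an ellipse fit on fewer pixels is meaningless), more
eccentric than 0.995. The count is the number of survivors.

Sizes default to the **sub-pixel half-maximum footprint** (marching-squares
contour at half the component's peak above background) minus the smoothing
kernel's own half-maximum area, 2π σ_k² ln 2 — an estimator that is unbiased
for Gaussian puncta and nearly exact for discs. The raw as-detected pixel
count (`size_mode="detected"`) is kept as an option; it depends on where
the global threshold happens to sit relative to each object's peak, which
makes it a poor calibration-stable size measure. Size recovery is verified
at SNR 10 (mean absolute error below one pixel-area); exact count recovery
is verified at SNR 5 for 50–200 objects per segment.

Z-stack height is (last signal slice − first + 1) × z step, a slice having
signal when its supra-threshold area exceeds `min_slice_area_um2` (1 µm²);
the per-slice criterion is config-exposed because no single rule is
canonical. The two-channel coverage ratio Otsu-binarises each channel and
divides foreground areas, flagging an empty denominator as undefined.

## Kymographs and motility

`build_kymograph` averages across the tunnel-ROI width per frame and stacks
rows in time order — it is linear in luminance by construction. The ROI is
drawn around the axon bundle (2.4 µm default width) rather than the full
10-µm tunnel: averaging the blank width at SNR 5 would bury the signal, in
the synthetic scenes as on a microscope.

Stationary suppression subtracts the per-column temporal median (robust to
a motile object transiting a column, unlike the mean) and counts stationary
mitochondria as peaks of the median profile exceeding `stripe_nsigma` (5)
noise SDs, the noise scale again taken from the profile's lower quartile so
the stripes themselves do not inflate it. Adjacent columns of one stripe
merge into one peak; objects closer than the PSF along the axis cannot be
resolved, which is a physical limit of the kymograph representation.

Track detection binarises the row-wise matched-filtered, stationary-
suppressed kymograph (3 σ), bridges the dashed streaks fast objects leave
with a wide, short closing footprint (5 × 13 px — an object at 2 µm/s
advances 10 px per row, and the closing must bridge along the distance axis
without merging structures vertically), skeletonises, and splits the
skeleton at junctions. Fragments are assembled into tracks by a seeded
iterative line fit (the longest fragment seeds; nearby fragments joining
the refitted line are absorbed), followed by a centroid-pair search over
the leftovers for heavily dashed lines no single fragment could seed, and a
final rejoin of groups whose fitted lines agree where they meet. Debris of
accepted tracks is removed from the pool so it cannot reassemble into ghost
lines. A candidate becomes a track if it spans ≥ 10 rows with ≥ 20 px of
support, fits a line with R² ≥ 0.8, and — the decisive physical check —
shows supra-threshold signal on ≥ 60 % of the rows along its fitted line
(chance alignments of debris from two crossing tracks fail this). Two
near-parallel same-speed streaks closer than the closing width can still
merge into one track; at study densities this costs at most one track in
tens and is the known failure mode.

Speed is |slope| × column size / row interval. Direction follows the sign
of the slope and the ROI's declared anterograde sign; tracks with net
displacement under 2 µm are *stationary* (vertical residuals) unless their
path length exceeds 6 µm, in which case they are *bidirectional* —
fluctuating in place. Bidirectional tracks are reported separately and
excluded from the motile ratio n_motile / (n_motile + n_stationary),
because kymographs do not capture that movement faithfully.

## Morphometry

Bouton counting follows the classic semi-automated chain: 4-µm top-hat,
tiled CLAHE (64-px kernel, clip 0.005 — at the default clip of 0.01 the
equalisation lifts noise tiles past the Otsu split on sparse fields), Otsu
floored at the noise level, 3×3 median, closing with a 2-px disc, hole
filling, removal of fragments under 50 px, thinning, and endpoint detection
(skeleton pixels with exactly one 8-neighbour). Spurs shorter than 10 px
that end in a junction are pruned first — thinning a thick band leaves such
twigs at width irregularities, while genuine termini sit at the end of long
branches. The automated count is preliminary by design: manual additions
from visual review enter through `with_manual_additions`, and an RGB
overlay (image, skeleton, endpoints) supports that review. Bouton density
is total boutons over Otsu-thresholded neurite area.

Synaptic co-occurrence is the AND of the presynaptic (Otsu) and
postsynaptic (Triangle) masks, both floored at their channels' noise
levels, followed by particle analysis. The 15-µm cut-off is interpreted as
an **equivalent diameter** (2√(area/π)); the area reading (15 µm²) is a
config switch, since the unit is genuinely ambiguous. Overlaps above the
cut-off are counted as excluded, not silently dropped.

## Electrophysiology

Filtering is a 2nd-order Butterworth band-pass, 300–3,000 Hz, applied
forward–backward (zero phase) so detection timestamps carry no filter
delay; the effective magnitude response is the square of the single-pass
response. Detection thresholds each channel at median − 5 SD of the whole
filtered trace (the plain SD; a MAD-based noise-only estimate is a config
option), timestamps each negative-going crossing at its trough within a
1-ms search window, and enforces a 1-ms dead time. Binning uses half-open
1-ms bins of spike counts; with the 1-ms dead time the bins are effectively
binary. The mean firing rate is spikes per second per electrode, averaged
over all electrodes by default (`mfr_scope="active"` restricts to
electrodes passing the 10-spike activity filter — which population the
network average should cover is genuinely open).

Connectivity: for each electrode pair, Pearson r between the binned trains
at every integer lag in ±100 ms (non-overlapping bins dropped; all 201
coefficients computed exactly in O(n log n) via prefix sums and an FFT
cross-term). The peak maximises signed r — co-firing is a positive-weight
connection — with ties broken toward the smaller |lag|, and becomes the
connection weight. Electrodes with fewer than 10 spikes are excluded
before pairing; pairs whose peak fails p ≤ 0.001 are excluded; the total
network correlation is the mean weight over survivors (nan-flagged when
none survive or fewer than two electrodes are active).

The p-value refers to the *selected peak* and must account for the scan
over 201 lags. For sparse 0/1 trains the textbook t-transform of r is
dramatically anti-conservative: with ~420 spikes in 420,000 bins the
co-occurrence count at a lag is Poisson with mean ~0.42, three chance
coincidences already give t-p < 10⁻⁴, and the maximum over 201 lags reaches
three coincidences in most independent pairs — the filter would pass ~80 %
of null pairs and defeat its own purpose (we measured exactly that). The
default (`p_method="peak_sidak"`) therefore computes an exact
hypergeometric tail on the binarised co-occurrence count at the peak lag,
Šidák-corrected across the scanned lags; under independence the fraction of
pairs passing p ≤ 0.001 is at most ~0.1 %, which matches a circular-shift
permutation null within Monte-Carlo error (tested). The uncorrected
t-transform is retained as `p_method="t_at_peak"` for comparison with
conventions that filter on the raw peak p.

## Orchestration and statistics

`run_stage` executes simulate / mito / kymo / morpho / ephys / report over
a YAML layout. Stages are deterministic given config + seed (per-unit seeds
derive from a hash of the unit key); result tables round floats to six
significant digits at write time so re-runs diff byte-identically, and each
stage writes a provenance log (package version, config digest, per-item
lines including exclusions). Group comparisons check normality per group
(Shapiro–Wilk at α = 0.05; groups with fewer than three values or zero
range are treated as non-normal) and route to t / paired-t versus
Mann–Whitney / Wilcoxon; degenerate groups are flagged rather than tested.
All statistics are thin calls to standard routines — they exist for report
parity, and all novel computation lives upstream.

## Benchmark problem sizes

The recovery benchmarks (`neuritescope.benchmarks`, shared by the test
suite and `scripts/acceptance.py`) use: 20 replicate 4-tunnel series per
speed group (≥ 150 tracks each); 20 tunnels per motile-ratio group; count
fields of 50, 136, 164 and 200 puncta with the 4/6-µm² disc pair; one
12-channel 7-minute recording (~5,000 spikes); a 3-electrode coupled
recording plus 100 independent 420,000-bin pairs for the null; six neurite
fields spanning 2–20 termini; and one stack per height group at a 0.25-µm
z step (35.5 and 10.75 µm spans — the closest grid representations of the
35.38 / 10.83 µm group means). These sizes keep the full benchmark run
around half a minute on one CPU while leaving each estimate's Monte-Carlo
error far below the tolerance it is checked against.

## Known limitations

* Kymograph analysis assumes constant-velocity runs; curved tracks are fit
  by a straight line and pausing objects may split into two tracks.
* Stationary counting resolves objects only beyond the PSF along the
  tunnel axis; axial (width-direction) stacking is invisible to it.
* The exact-count guarantee holds for non-overlapping puncta; touching
  organelles merge into single components, as in any connected-component
  scheme.
* The hypergeometric peak significance treats bins as exchangeable; strong
  rate nonstationarity (bursts) would require the permutation null, which
  the implementation of the test suite demonstrates but the default path
  does not run.
* Group statistics are classical two-sample routines; hierarchical
  structure (tunnels within networks) is not modelled.
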