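# Methods

`placecode` analyses place-cell population activity recorded (or simulated)
while a mouse shuttles on a 1.6 m linear track, sampled at 30 frames/s.
Its inputs are a per-frame position series and a neurons × frames matrix of
deconvolved calcium event counts; upstream imaging steps (motion
correction, CNMF-E source extraction, deconvolution) are consumed, not
reimplemented.  This note records the models, the parameter choices that
matter, and the limits of what the synthetic benchmarks show.

## Place-field mapping

The track is divided into 2 cm bins; one bin at each end (reward/dwell
zone) is discarded, leaving K = 78 bins.  Frames enter a map only while
the animal runs in the analysed direction at 8–25 cm/s.  Running speed is
a central finite difference of position times the frame rate, boxcar
smoothed over 5 frames (one-sided differences at the ends).  Event counts
and occupancy are accumulated per bin and each smoothed with a discrete
Gaussian kernel (σ = 1.5 bins, 5 taps); at the vector ends the kernel is
truncated and renormalised rather than padded, because occupancy next to
the discarded bins is structurally low.  The rate map is the ratio of the
smoothed vectors (events/s, since occupancy is in seconds); bins with zero
smoothed occupancy get rate 0 and are flagged unvisited.  The place
field's position is the map argmax, ties broken toward the lower index.

## Spatial information and the place-cell test

Spatial information content (bits/event) is

    I = Σ_i P_i (λ_i/λ̄) log2(λ_i/λ̄),   λ̄ = Σ_i P_i λ_i,

with P_i the occupancy fraction and λ_i the smoothed rate; zero-rate terms
contribute 0 and silent neurons are assigned I = 0.  Significance uses a
1000-sample shuffle null with the add-one permutation p-value
p = (1 + #{null ≥ observed})/(1 + N); a neuron is a place cell in a
direction iff p < 0.05 there.

Two nulls are implemented.  `permute_frames` (the default) permutes the
valid frames' bin assignments: for event trains that are conditionally
independent across frames this is the exact null, and it is calibrated
(untuned-cell positive rate ≈ the nominal 5%) with near-complete power on
tuned cells.  `circular` shifts the whole event train against the
trajectory by ≥15 s, the classical choice when event trains carry
autocorrelation that must be preserved.  On tightly stereotyped shuttle
behaviour, however, the trajectory is quasi-periodic and a circular shift
leaks position information into the null: measured on the generator's
sessions, the null's 95th percentile rises from ≈1.1 bits (true scatter)
to 1.3–1.7 bits, power on tuned cells drops to ≈50%, and the place-cell
count swings by a factor of two between statistically identical sessions.
That pathology, not convenience, is why frame permutation is the default;
the circular option remains for burst-structured data.

## Population-vector stability

Same-direction traversals are numbered in time and split by parity; each
half yields an independent map.  PVO(x, y) is the cosine similarity of the
population rate vectors at odd-half bin x and even-half bin y (all-zero
columns give 0 and are flagged); the neuron subset defaults to that
session's place cells.  The diagonal index DI = 1/Σ(PVO − I)² (identity
matrix I) grows as the PVO concentrates on its diagonal; a perfect
identity returns +inf.  Note a structural property that matters for
interpretation: Σ(PVO − I)² is far from its minimum both for a broadly
banded PVO (wide smooth fields) and for a noise-dominated one, so DI only
behaves as a stability index when the baseline PVO is diagonal-dominated —
which real place-cell ensembles, with their sharp irregular rate
landscapes, satisfy.

## Bayesian decoding

For a window of length τ (default 0.5 s — the window length is a free
choice and is always reported with results) centred on each valid frame,

    P(x|n) ∝ P(x) · Π_i f_i(x)^{n_i} · exp(−τ Σ_i f_i(x)),

computed in log space and normalised; boundary windows rescale τ to their
actual length.  Training uses the same session's place-cell maps (an
odd-train/even-test split is available).  Trained maps are clipped at a
floor of 0.01 events/s: maps estimated from a dozen traversals contain
sampling zeros, and an exact zero acts as a veto — one stray out-of-field
event from a neuron unsampled at the true bin sends the estimate across
the track (5–10% of frames decoded ~150 cm off without the floor; with
it, the synthetic baseline error is ≈1 cm/frame).  `posterior` itself
evaluates the formula exactly for whatever maps it is given.  The decoding
error is mean |x̂ − x| in cm per decoded frame.

## Autoencoder embedding

Rasters of the neurons detected in both conditions are cut into
non-overlapping 2.5 s epochs, binarised (count > 0), and flattened to
neurons × 75-frame vectors.  The autoencoder is symmetric: three dense
SELU layers down to a 100-unit code and three back up, sigmoid output,
binary cross-entropy loss, Adam.  Hidden widths interpolate geometrically
between the input size and the code.  A grid over learning rate, training
epochs and a hidden-width scale is selected on held-out (20%)
reconstruction loss with a fixed split; training is deterministic under
the seed.  The network is implemented directly on NumPy (LeCun-normal
initialisation, hand-written Adam) — at these input sizes that is fast and
keeps every arithmetic step reproducible.  Codes are visualised on their
top two principal components; because "the conditions separate" is not
testable as prose, the mean silhouette of the two condition labels in
code space quantifies it.

## Synthetic sessions

The generator defines the study conditions: 640 neurons, 12 traversals
per direction, 55% place cells with Gaussian tuning (SD 8 cm, in-field
peak 1 event/s), and the out-of-field rate solved so the population mean
event rate is 0.077 Hz.  Half of the place cells are direction-selective.
Events are Poisson per frame with mean rate/fps.

Two features beyond the plain Gaussian-bump model were needed to make the
synthetic data behave like recordings:

* **Behavioural variability.**  Traversal mean speed is jittered trial to
  trial (SD 4 cm/s around 15 cm/s, frame noise SD 2 cm/s) and end dwells
  are 2 ± 1.5 s.  Real mice vary at least this much, and the variability
  is what decorrelates the circular shuffle null at all.
* **Stable rate texture.**  Each tuned cell's curve is multiplied by a
  fixed lognormal spatial texture (mean 1, log-SD 1.0, 2 cm grain) that
  rides with the field.  Real place fields are irregular but reliable at
  the bin scale; without this, the cosine PVO is a broad smooth band,
  Σ(PVO − I)² sits above K, and any degradation *raises* DI — inverting
  the stability phenomenology.  With the texture the baseline PVO is
  diagonal-dominated and destabilisation lowers DI, as observed in
  recordings.

The drug effect scales rates (detected cells keep their identity; dropped
cells are marked undetected, not deleted), jitters each field's centre per
trial, remaps a fraction of fields, and adds a diffuse off-field rate.
The calibrated muscarinic-blockade preset is rate_scale 0.82,
detect_scale 0.847, jitter SD 24 cm, off-field 0.005 Hz, remap 0.3; the
jitter moves some field mass off the track, so the *measured* rate ratio
lands at ≈83% (the reported reduction), detected cells at ≈85%,
place-cell counts at ≈50%, DI at ≈72–77% and decoding error at ≈310–340%
of baseline.  The free destabilisation parameters were calibrated once
against those population-level changes and then frozen.

What the synthetic benchmark does *not* show: absolute decoding error and
absolute SIC depend on the (fixed) peak rate and field width, so they sit
near, not at, the recorded values (≈1 cm/frame vs 1.45; per-direction
classified place-cell fractions ≈40% vs 55% because direction-selective
cells are only classifiable in their tuned direction).  All headline
comparisons are therefore post/baseline ratios, which the generator
reproduces.

## CA1 network model

A 149-cell single-compartment network: 130 pyramidal cells (PYR), 8
basket (BC), 2 axo-axonic (AAC), 2 bistratified (BIS), 2 O-LM (OLM), 1
VIP+/CCK+ and 4 VIP+/calretinin+ cells.  Edges follow the standard CA1
cartoon exactly: CA3 → PYR/BC/AAC; PYR → every interneuron class; BC/AAC
and BIS/OLM → PYR; VIP-CR → OLM/BIS; VIP-CCK → BC; septum (SEP, 8 Hz
theta-modulated inhibitory conductance) → all interneurons.  The
entorhinal→CA1 pathway is disabled (retrieval mode).  CA3 afferents are
130 place-tuned Poisson inputs tiling the track, built by matching ~50
rectified-cosine grid inputs (periods 40/60/90 cm, random phases) to a
Gaussian template, rectifying, and windowing out distal interference
bumps — a rectifying spatial filter on grid-like input.

Cells are Wang–Buzsáki-type (instantaneous Na activation, h and n gates,
class-specific kinetic rate factors; leak 0.1 mS/cm²) plus the M-current
I_M = g_M·w·(V − E_K), E_K = −90 mV, with w∞ a sigmoid at −35 mV (slope
7 mV, so resting activation is small and the current acts as
depolarisation-driven adaptation) and τ_w = 100 ms.  Densities are in
mS/cm² (1 mS/cm² = 10 pS/µm² under the 1 µF/cm² convention, so the
2 pS/µm² interneuron density is 0.2 mS/cm²).  Baseline PYR g_M is
0.5 mS/cm²; the experiment scales it ×5/×10/×15/×20.  The interneuron
M-conductance multiplier is a fitted quantity (3.0), set so the mildest
(×5) condition reproduces the ≈17% population-rate reduction seen in the
recordings; it is applied in the treatment groups only.  BIS carries the
SST-class conductance.  Each PYR receives 4 topographic CA3 afferents
with a lognormal gain (CV 1.0), sparse strong non-spatial background
events (0.15 Hz, 0.25 mS/cm²) that set a condition-independent off-field
floor, and a slow Ornstein–Uhlenbeck excitability fluctuation (SD
0.35 µA/cm², τ 6 s) standing in for state drift.  6% of PYR receive
spatially diffuse afferent weight.

Integration is exponential-Euler at dt = 0.1 ms with voltage-indexed
lookup tables (numba-compiled); synapses are single-exponential
conductances (3 ms excitatory, 8 ms inhibitory) applied one step after
the presynaptic spike.  Halving dt changes a driven cell's rate by <2%.
The simulated animal makes 12 one-way traversals at 18 ± 2 cm/s
(instantaneous return): the afferents depend only on position, so the
analysed direction's statistics match a physical shuttle at half the
cost.  PYR spikes are binned at 30 Hz and fed to the identical
map/SIC/PVO pipeline.

Mechanistically, raising the pyramidal M-conductance adapts sustained
in-field firing, silences weakly driven cells, and leaves the background
floor relatively intact, so the place-cell fraction, the place-cell SIC
and the diagonal index all decrease monotonically with the scale.  At the
frozen calibration the baseline group sits at ≈82–85% place cells and
≈2.2 bits, the ×10 group near 1.8 bits, the ×20 group near 50–56% place
cells with DI at ≈80–85% of control.  The ×20 collapse of the place-cell
count to ~30% and of DI to ~65% reported for the original
multi-compartment implementation is *not* reproduced: with
single-compartment fluctuation-driven spiking, cells with sharp
CA3-defined fields stay statistically significant down to ~10 in-field
events, and sparser rasters shrink the PVO's off-diagonal energy, which
bounds how far DI can fall.  These are structural limits of the
simplification, documented rather than tuned around.

## Numerical and edge-case conventions

Argmax ties break to the lower bin; zero-occupancy bins are excluded from
information sums via P_i = 0; the permutation p-value can never be 0;
posterior normalisation is asserted to 1e−9; the PVO of an all-zero half
is 0 and flagged; DI of a perfect identity is +inf; generators and
simulations are bit-reproducible given a seed.

## Problem sizes used in the test suite

The shipped tests run reduced but statistically meaningful sizes: 250–500
neuron synthetic sessions (full 640 for paired-ratio checks), 500–1000
shuffles, 10 seeds for ratio calibrations, and 3 replicates per condition
for the 5-condition network experiment (the acceptance script uses 5
replicates for the 3 conditions it reports).
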