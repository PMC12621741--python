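# Methods

## Signal model and conventions

A recording is a channels × samples matrix in millivolts with sampling
rate `fs`; all ingestion paths scale to mV. Analysis channels are
depth-sorted per probe and shank, shallowest first, with larger probe
y-coordinates meaning shallower contacts; depth-sort ties break by contact
index so orderings are deterministic. Times are seconds, windows half-open
in samples, channel indices 0-based.

Recordings sampled at ≤2.5 kHz are analyzed as-is; faster recordings are
reduced to a target rate (default 1 kHz) by averaging bins of consecutive
samples, dropping the trailing partial bin so the output grid stays
uniform. Output timestamps are bin centers.

## Filter bank

Five Butterworth band-passes (order 4, applied forward-backward for zero
phase): theta 6–10 Hz, slow gamma 25–55 Hz, fast gamma 60–100 Hz, ripple
120–180 Hz, and the broad 5–100 Hz DS band. Zero-phase filtering is the
standard choice for LFP event timing because event indices must not be
biased by group delay. Band amplitude per channel is the standard
deviation of the filtered trace over the entire recording (events
included); normalized profiles divide by the per-band maximum over
non-noise channels. The first/last stretches of filtfilt output near the
recording edges are formally untrusted; detectors drop events whose
analysis windows cross the array bounds.

## DS detection

Positive peaks of the DS-band trace must exceed a height threshold and a
minimum prominence — both expressed per channel, in SDs of that channel's
filtered trace by default (height 4, prominence 2), convertible to
absolute mV — and be separated by ≥50 ms, matching the brevity of the
events; within any such window only the most prominent peak survives
(ties to the earlier), so multi-peaked events are not split. Events are
re-indexed to the raw-LFP maximum within a 20 ms window around the
filtered peak. Properties: amplitude (raw value at the re-indexed peak),
half-width at half prominence, asymmetry `(t_r - t_l)/(t_r + t_l)` from
the half-prominence crossing times to the peak (a documented choice; no
standard formula exists), and height above the surround, the peak minus
the mean raw LFP over the [-50,-25] ∪ [+25,+50] ms flanks (flank geometry
likewise a documented choice).

## SPW-R detection

The ripple envelope is the magnitude of the analytic signal; the
instantaneous frequency is the discrete derivative of the unwrapped
analytic phase, clipped to 120–180 Hz (the frequency criterion is
evaluated on the clipped trace, since clipping is part of the frequency
computation). Envelope peaks must exceed mean + 5 SD of the whole-recording
envelope, with event extent the contiguous region above mean + 2.5 SD;
duration between edge crossings is measured with linear interpolation and
must reach 20 ms; the mean instantaneous frequency over the extent must
reach 120 Hz; peaks are separated by ≥100 ms, and each kept event is
re-indexed to the largest positive ripple cycle within ±20 ms.

Thresholds are envelope **z-scores** (mean + k·SD), not bare multiples of
the SD: the envelope of band-limited noise is Rayleigh-distributed with
mean ≈ 1.9 SD, so a bare k·SD threshold sits inside the noise floor and
fires continuously on event-free channels. Defaults (peak 5, edge 2.5,
20 ms, 120 Hz, 100 ms interval) mirror common rodent SPW-R practice and
the 20–200 ms duration range of the events.

## Current source density

Standard CSD: `-sigma * (V_{i-1} - 2V_i + V_{i+1}) / h^2` with
conductivity sigma = 0.3 S/m and spacing h in mm; sinks are negative.
Vaknin's procedure (duplicating the boundary potentials) keeps the output
on all recorded channels; it necessarily leaves edge values that reflect
the boundary condition rather than local currents, so sink localization is
an interior statement. "Third-order Gaussian smoothing (σ=1)" is
implemented as a Gaussian kernel along the channel axis with σ = 1 channel
truncated at 3σ, applied after differencing. Since classification
normalizes per event, sigma affects units only.

Inverse CSD solves `F c = V` per time sample for planar source amplitudes
`c` under three forward models: δ (infinitely thin disks of radius
R = 500 µm at the electrode depths, on-axis kernel
`(sqrt(dz² + R²) − |dz|)/2σ`), step (uniform slabs between electrode
midpoints, kernel integrated numerically over each slab), and spline (CSD
parameterized by natural cubic splines through the electrode depths,
basis functions integrated against the kernel). Solved amplitudes are
already sinks-negative — a positive source produces a positive potential —
so no sign flip is applied. The forward matrix is rejected when its
condition number exceeds 1e12. Sources are assumed to lie within the
electrode span; potentials with a constant offset beyond the probe (far
sources) violate that assumption and show boundary artifacts, which is
inherent to the method, not a defect.

Peri-event stacks take a 100 ms window centered on each event over the
fissure-to-hilus channel range, computed on the DS-band filtered LFP for
classification (raw LFP for the interactive interval view); events whose
window crosses the recording edge are dropped with a logged count.

## Classification

Each event's CSD map is flattened and divided by its own maximum absolute
value (per-event max-abs rather than z-scoring — a documented choice; it
preserves the sink/source sign structure while removing amplitude), PCA
reduces to 2 components (deterministic full-SVD solver; coordinates are
defined up to axis sign), and K-means (k = 2, 10 restarts, seeded) or
DBSCAN partitions the embedding. DBSCAN's epsilon (default 0.5) is in
normalized PC units: coordinates are divided by their overall SD first,
making the default meaningful across recordings; noise points become
"undefined". Exactly two labeled clusters are required for auto-labeling:
each cluster's sink is the argmin of its mean CSD at the event-center
time bin (not the global map minimum, so co-occurring activity elsewhere
in the window cannot steal the sink), and the cluster whose sink is
nearer the fissure channel is DS1, the other DS2; sink ties fall back to
the second-deepest sink with a low-confidence flag. A swap operation
exchanges the labels everywhere and is an involution; swaps are counted
in the provenance record.

## Channel selection

Per-channel summaries carry event counts, mean amplitudes, mean height
above surround, and the ripple-to-theta band-amplitude ratio. The
recommended theta channel is the normalized-theta argmax (the fissure);
the SPW-R channel the ripple/theta-ratio argmax (CA1 pyramidal layer);
the DS channel the mean-DS-amplitude argmax among channels *deeper* than
the theta channel, encoding the anatomy (the hilus lies below the
fissure; apparent events above it are likely spurious). All argmax ties
break to the shallowest channel. Curation: delete marks events
restorable, erase removes them permanently (a restore of an erased id is
an error), add places a manual event on the nearest raw-LFP local maximum
within ±25 ms and validates the minimum-interval invariant.

## Synthetic generator

The generator states a 16-channel, 50 µm, 1 kHz, 10-minute world with
role channels CA1 = 2, fissure = 6, OML = 8, MML = 10, hilus = 13 and
DS1/DS2/SPW-R rates of 5 per minute each (reported DS rates span 2–3 per
minute to 2–3 per second; the default sits at the quiet-rest end so
events stay well separated). Events are placed uniformly with a global
250 ms minimum separation (rejection sampling), either at Poisson counts
from the rates or at exact requested counts.

DS events are depth-localized dipoles: a Gaussian sink (σ = 0.8 ch) at
the OML (DS1) or MML (DS2) channel balanced by an equal-area source three
channels deeper, converted to an LFP depth profile by discrete double
integration of the CSD profile — making the standard second-difference
CSD an exact inverse on interior channels, the keystone oracle of the
test suite — normalized to +1 at the hilus (hilar DS peaks are positive),
scaled by the DS amplitude (default 2 mV, matching the >1 mV phenomenon),
and multiplied by a temporal Gaussian (8 ms width parameter, FWHM ≈ 9.4 ms,
well under the 50 ms bound). Below the hilus the profile decays
exponentially (length 1.5 channels): the pure 1-D plane model would hold
the potential constant arbitrarily deep, which no real probe shows and
which would move the DS-amplitude argmax off the hilus.

SPW-Rs are 150 Hz tones under a Gaussian envelope (50 ms duration
parameter) with amplitude 0.35 mV at CA1 and Gaussian depth decay
(σ = 1 ch). Background: common 8 Hz theta with a depth-Gaussian amplitude
profile peaking at the fissure (0.25 mV, σ = 3 ch) over a 15%
volume-conducted floor (without the floor the ripple/theta ratio diverges
on deep channels where theta → 0), a small depth phase gradient, 40/80 Hz
gammas (0.03/0.02 mV, random phase per channel), a ripple-band background
confined to the CA1 pyramidal layer (0.05 mV — the elevated high-frequency
power of the cell layer, which also anchors the ripple/theta-ratio
landmark), white noise (0.03 mV), and 1/f noise from spectral shaping of
white noise (0.05 mV). Optional noise channels are replaced by pure white
noise and flagged in the recording's noise mask. Everything derives from
one seeded generator; equal seeds give bitwise-identical output.

What the generator does **not** emulate: behavioral-state modulation of
rates, movement artifacts, gamma bursts during locomotion, electrode
drift, non-stationary noise, and co-occurring DS/SPW-R events (the global
separation forbids overlap). A green detection test therefore establishes
correctness of the detectors' logic under stationary background, not
robustness to artifacts — which is exactly what the curation operations
exist for.

## Numerical choices

- Event-size statements in SD units ("SNR 5", "5 SD events") are
  interpreted as planted peak amplitude = k × RMS of the raw background
  LFP on the target channel, measured from an event-free run of the same
  configuration. Calibrating against the band-filtered SD instead would
  place events exactly at the detection threshold, where half are missed
  by construction.
- Sub-sample SPW-R durations use linear interpolation between envelope
  samples at the edge threshold.
- Greedy ground-truth matching pairs detections and planted events in
  order of increasing |Δt| within tolerance, one-to-one; it is invariant
  to row order.
- Event CSVs are written at full float precision and read back with
  round-trip float parsing, so write → read is the identity.
- K-means and PCA are seeded; rerunning any stage with the same seed
  reproduces outputs byte-for-byte.

## Known limitations

- Only generic array ingestion (.npy, delimited text) is built in; NWB
  and proprietary acquisition formats must be converted upstream.
- The standard CSD requires uniform spacing and errors otherwise,
  directing to the iCSD variants.
- Asymmetry and height-above-surround use documented but non-canonical
  definitions (no standard exists); compare across datasets only within
  this tool.
- DBSCAN can legitimately return one or three clusters on poorly
  separated data; auto-labeling then refuses and asks for different
  parameters rather than guessing.
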