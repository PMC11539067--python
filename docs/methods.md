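# Methods

This note documents the models, algorithms and numerical choices behind
`finwave`, in the order data flows through the pipeline.

## Bending-wave model

Body undulation is modelled on the local bending angle per segment
(radians, positive counter-clockwise), not on lateral displacement:
bending is what muscles control, reconstruction to an inextensible
midline is then exact, and stiffness acts naturally as a multiplicative
factor. The field is

θ(s, t) = A_st G(s; p, w) cos(2πft) + γ(s) A_tr s^q cos(2πft − 2πs/λ)

* `G` — Gaussian envelope, maximum 1 at the pectoral peak position `p`
  (default 0.25 BL), width `w` = 0.10 BL. A Gaussian is the minimal
  smooth unimodal envelope with an unambiguous peak position, which is
  the quantity later measured from video.
* Travelling amplitude grows caudally as `s^q` with `q` = 2,
  reflecting the caudally increasing bending of carangiform swimmers.
* `γ(s)` drops from 1 to `stiffness_gamma` at `stiffness_onset`
  (default 0.5 BL) through a half-cosine ramp of width 0.05 BL, so the
  reconstructed midline has no curvature discontinuity.
* Defaults: body length 30 mm, 50 segments (51 midline points),
  tail-beat 2.5 Hz, wavelength 1 BL, A_st = 0.03 and A_tr = 0.08 rad
  per segment. These give a tail-beat excursion of ≈0.17 BL, typical of
  steadily cruising adult zebrafish. `stiffness_gamma = 1` reproduces
  the fully flexible condition bit-for-bit.

Three presets define the conditions of interest: `flexible` (γ = 1),
`stiff` (γ = 0.3 caudal to 0.5 BL) and `compensated` (same stiffness,
standing amplitude ×1.8, peak shifted to 0.35 BL).

## Wave decomposition

An observed bending field is first reduced to a complex amplitude
profile Z(s) at the dominant frequency (argmax of the mean mid-body
power spectrum; then a per-segment least-squares cosine/sine fit — this
is exact for noiseless single-tone fields and degrades gracefully under
noise, with a low-power flag when the fit explains <5% of variance).
Z is split into counter-propagating components Z₊ + Z₋ by zeroing
negative/positive spatial frequencies of its FFT (DC and Nyquist shared
half-and-half). Standing amplitude is 2·min(|Z₊|,|Z₋|), travelling
amplitude ||Z₊|−|Z₋||, and the travelling index their ratio in [0, 1]
(0/0 defined as 0). Two caveats are inherent to this estimator: a
spatially growing amplitude envelope reads partly as standing content
(spectral leakage), and the index, being a ratio, is invariant to
uniformly scaling the travelling wave — so caudal to the stiffness
onset, where the standing wave is essentially absent, the index
responds to the stiffness *step*, saturating once γ ≲ 0.6.

The pectoral peak position is the argmax of |Z(s)| restricted to the
rostral half (ties broken rostrally, parabolic sub-segment refinement).
For tracked data the feature-level wrapper smooths θ along arc length
(Savitzky–Golay, window 9, order 2), trims 3 end segments (skeleton
endpoints are the noisiest) and searches s ∈ [0.08, 0.5].

## Propulsion model

Mean thrust uses elongated-body theory, which depends only on tail-tip
kinematics: T(U) = (m_a/2)(⟨ḣ²⟩ − U²⟨h′²⟩), with added mass per unit
length m_a = ρπ(b/2)² for tail span b = 4 mm. Drag is quadratic,
D(U) = ½ρC_d A_w U² with C_d = 0.1 and wetted area 150 mm². The steady
speed is the Brent root of T − D on (0, 20] BL/s, residual < 1e−8 of
the drag scale; zero undulation short-circuits to U = 0. With these
constants the flexible preset cruises at ≈1.2 BL/s, in the range of
real cruising fish.

**The mean swimming axis matters.** h is the tail tip's signed lateral
deviation from the least-squares line through the *anterior two-thirds*
of the midline, fitted per frame. Two alternatives fail instructive
sanity checks: a head-anchored frame credits rostral bending with the
full body-length lever arm (a freely swimming body instead recoils, so
rostral bending chiefly reorients the head), which would make rostral
standing waves always optimal and erase the caudal-shift prediction;
a fit through *all* points partially chases the tail and attenuates a
pure tail-plunge amplitude by ~11%, breaking the closed-form oracle
max|ḣ| = 2πfA. The anterior fit passes both: for a hinge at body
fraction `p` the tail deviation grows with `p` up to ≈2/3, so
compensation genuinely prefers a caudally placed standing wave, which
is the model's testable core.

`compare_conditions` adds multiplicative Gaussian jitter (CV 5%) to the
wave amplitudes and frequency across replicates to emulate
fish-to-fish variability; `compensation_grid_search` sweeps standing
amplitude ×1–3 and peak position 0.15–0.5 BL at fixed stiffness.

## Synthetic data

Generators produce every input the pipeline consumes, with ground
truth, so all downstream stages are testable without recordings.

* **Video**: the midline swept by a fusiform half-width profile
  (maximum ≈7% BL near 0.22 BL), filled as a dark polygon on a bright
  background at 6 px/mm with Gaussian pixel noise, 8-bit. Cruising
  clips default to 200 fps, escape clips to 936 fps.
* **Arena tracks**: reflected random walks in a 172×44 mm channel; the
  wildtype preset has an Ornstein–Uhlenbeck pull (2 s⁻¹) toward the
  longitudinal centre line, the mutant none and twice the step
  dispersion. Stream labels slow/medium/fast are categorical metadata
  (nominal pump flows 172/240/277 ml/s); no flow field is simulated.
* **Field potentials**: biphasic Gaussian-derivative templates with
  ~0.9 ms lobe separation — energy inside the 300–500 Hz band the real
  rig records — at given times and two amplitude classes, plus 50 Hz
  hum and white noise, sampled at 25 kHz (≥50× the passband top).
* **Axon images**: non-overlapping bright disks with known centres and
  diameters inside a triangular ROI, blurred and noised.
* **Escapes**: a uniform-curvature C-bend whose total turning angle
  follows a raised-cosine time course after a configurable
  post-stimulus latency, scaled to hit a requested peak tortuosity
  exactly (via the chord/arc relation).

What the generators do *not* emulate: fish-shaped intensity texture,
pigmentation, shadows, refraction, occlusions, multi-animal scenes,
electrode drift or movement artifacts. Passing tests therefore show the
algorithms are correct and well-calibrated on clean-but-noisy geometry,
not that they are robust to every artifact of real footage.

## Tracking

Per frame: Otsu (or fixed) threshold with configurable polarity →
largest connected component ≥ 50 px, holes filled → skeleton → longest
skeleton path by double-BFS over the 8-connected pixel graph → light
path smoothing → quadratic extrapolation of both ends to the mask
boundary (the skeleton erodes by roughly the local half-width; a
straight-tangent extension kinks when the end is bent) → resample to 51
equidistant points → **chord-midpoint refinement**: each point is moved
to the midpoint of the mask's cross-section along the local normal,
twice, at 0.25 px sampling. This last step is what makes the bending
field usable: the medial axis biases toward boundary corners in the
wide head region, phase-locked to the swim cycle, and the refinement
removes that systematic error (for a bilaterally symmetric body the
chord-midpoint locus *is* the midline). Resampling iterates the
arc-length interpolation until point spacing is uniform to 1e−7.

Head/tail orientation: the raw path order is arbitrary per frame, so
frames are first aligned to their predecessor (whichever order matches
point-for-point better); then a per-frame score — velocity alignment
(computed from the trajectory smoothed over the consistency window, so
tail-beat wobble cancels) plus a width vote (the head end is wider,
measured via the distance transform on interior bands 10–25% from each
end) — is averaged over a 31-frame window with hysteresis, so single
frames cannot flip the orientation. Unresolvable frames carry the
previous orientation and are flagged. Failed frames (no fish,
degenerate skeleton) are QC-flagged and filled from neighbours; more
than 20% failures aborts with a QC report.

## Features

* **Tortuosity** = (arc length − head-to-tail distance)/arc length,
  clipped to [0, 1]: 0 for a straight body, 1 when head touches tail.
  (The equivalent formula with the subtraction reversed and no
  normalisation guard would score straight bodies 0 but touching ones
  −1; the form here matches the stated endpoint semantics.)
* **Velocity**: centred differences; thrust velocity is the projection
  on the smoothed heading; summaries are medians.
* **Bending angle**: angle between the rostral-third and caudal-third
  chords (windows configurable); for a uniform arc of total turning Θ
  this equals 2Θ/3, which the tests use as a closed-form oracle.
* **Occupancy**: 2D histogram over the arena normalised to exactly
  100%; centre occupancy is the fraction of samples whose cross-stream
  coordinate lies within the central band (default ⅓ of channel
  width — a band, not a radial criterion, because the assay's "centre"
  is the centre line of the flow).
* **Escape series**: per-individual tortuosity/speed re-zeroed at the
  stimulus, resampled to a common grid when frame rates differ, with a
  percentile-bootstrap 95% band around the cross-individual median.

## Electrophysiology

Zero-phase 4th-order Butterworth band-pass 300–500 Hz (≥0.85 gain at
400 Hz, ≤0.1 at 50 Hz and 1 kHz) and a zero-phase 50 Hz notch
(Q = 30, ≥20 dB at 50 Hz, ≤1 dB at 400 Hz). Detection thresholds the
analytic (Hilbert) envelope at 5× the MAD-based noise scale — the
envelope peaks at the centre of a biphasic transient, where rectified
peak-picking would land on a lobe and bias times by ~0.6 ms — with a
2 ms refractory distance, light envelope smoothing (0.5 ms), a floor of
5% of the largest deflection (a noiseless trace has zero MAD), and
ring-lobe rejection: the band-pass filter rings with deterministic
envelope lobes of ≈13% of the peak near ±7 ms, so peaks below 20% of a
larger neighbour within ±8 ms are discarded. Consequence: a real spike
smaller than one-fifth of a neighbour within 8 ms would also be
discarded — acceptable for the two-class amplitude structure targeted
here. Classification is 1-D two-means on log-amplitudes with quantile
initialisation (deterministic); unimodal inputs collapse to one class
with a flag. Instantaneous spike frequency is 1/ISI at each spike;
PSTHs average per-train counts on a stimulus-aligned grid whose edge
nearest zero is snapped onto zero, so "the bin containing t = 0" is
[0, Δ) by construction.

## Morphometry and blinding

Axon profiles are pixels above threshold inside the ROI polygon,
connected components ≥ 9 px, equivalent diameter 2√(area/π) scaled by
µm/px. Blinding replaces sample ids with a seeded permutation of
opaque codes `S###`; the inverse map is returned separately and
consulted only after quantification. Group summaries (per-sample count
and median diameter) are compared by permutation test on per-sample
values and BH-corrected across measures; samples with no detections
are flagged and excluded.

## Sequence utilities

0-based end-exclusive coordinates, standard genetic code (translation
delegated to Biopython). `translate_to_stop` counts residues before
the first in-frame stop, including the initiator methionine — so "a
premature stop after amino acid N" corresponds to a return value of N
under the convention that the initiator is residue 1. A missing stop
returns the full length with a flag.

## Statistics

* **Permutation test**: two-sided, labels permuted without replacement
  (200,000 resamples by default; a with-replacement variant sits behind
  a flag), p = (1 + #{|stat*| ≥ |stat|})/(1 + R) so p ∈ [1/(R+1), 1].
  Default statistic is the difference of medians, matching the
  median-based group summaries used throughout; mean difference is
  available. Comparisons use a 1e−12 slack so ties at the observed
  statistic count as extreme.
* **BH-FDR**: statsmodels' step-up implementation behind a validated
  wrapper.
* **Rank-sum**: exact null for min(n) ≤ 10 without ties, otherwise the
  tie-corrected normal approximation; fully tied data returns p = 1
  with a warning.
* **Bootstrap median band**: individuals resampled with replacement,
  percentile interval per time point, clamped to contain the sample
  median; n = 1 collapses to the observed series. Empirical coverage
  for the median of 20 Gaussians is ≈94% at the nominal 95%, within
  the expected small-sample optimism of percentile intervals.

## Configuration and reproducibility

All numeric defaults live in the pydantic schema
(`finwave.config.PipelineConfig`), grouped by stage; empty YAML gives
defaults and any violation is reported by key. Every CLI run writes a
manifest (command, seed, config hash, package/numpy versions, input and
output hashes). All stochastic components take a seed or Generator.

## Problem sizes

The shipped analyses run at desk scale by choice: propulsion uses 2 s
of kinematics at 200 fps (≥4 full tail-beat cycles, enough for
period-averaged thrust to stabilise); end-to-end tracking validation
uses a 10 s clip at 200 fps and 6 px/mm; statistical calibration uses
2,000 null simulations at 2,000 resamples each (the add-one estimator's
granularity at R = 2,000 is 0.0005, ample to resolve a 0.04–0.06
acceptance band); the full 200,000-resample default is exercised where
a single test is computed. Scaling any of these up is a parameter
change, not a code change.

## Known limitations

* EBT ignores the wake and body-resolved forces; a resistive-force
  backend would integrate along the body and is the natural extension
  point (the contract of `mean_thrust`/`steady_speed` is backend
  agnostic).
* The tracker assumes a single fish, no occlusions, and bilateral
  symmetry of the silhouette; the chord-midpoint refinement relies on
  that symmetry.
* The travelling-index estimator attributes envelope growth partly to
  standing content (see above); comparisons should therefore be made
  within a fixed envelope family.
* Amplifier gain is treated as metadata; all ephys analysis is
  scale-invariant except the documented 5% threshold floor.
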