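# Methods

This note documents the models implemented in `sonoflex`, the parameter
choices that matter, and what the synthetic-data experiments do and do not
demonstrate.

## Interface acoustics and pillar geometry

Acoustic impedance is `Z = ρc` (reported in MRayl); interface transmission is
the *pressure-amplitude* coefficient `T = 2Z₂/(Z₁+Z₂)` — the convention that
reproduces both 0.58 (3.7 → 1.5 MRayl) and 0.082 (35 → 1.5 MRayl) quoted for
polymer and ceramic transducers on tissue. The hexagonal pillar "diameter"
is read as the across-flats width; similar hexagons on a hexagonal lattice
then give a fill factor `(d/(d+kerf))²` (0.64 for 40 µm pillars with a 10 µm
kerf) and a unit-cell area `√3/2·(d+kerf)²`. Pillar counts per element use
the continuum area/unit-cell approximation with no boundary correction; it
reproduces both reference element counts (2365 for a 1.6 × 3.2 mm element,
>52 000 for a 12-mm disc at 50 µm pitch), which is the accuracy this quantity
needs. All lengths are SI metres internally; µm, MHz and MRayl appear only
at I/O boundaries.

## Lossy KLM model

Each passive layer is an acoustic transmission line of impedance `ρcA`; the
piezo layer is the KLM network — the same line tapped at its midpoint, where
an ideal transformer couples to the electrical port through the clamped
capacitance `C0 = ε^S A/d` and the series reactance
`X1 = h²/(ω²Z0)·sin(kd)`, with turns ratio `φ = 2h/(ωZ0)·sin(kd/2)` and
`h = k_t√(ρc²/ε^S)`. This network is algebraically equivalent to the exact
1-D three-port (Mason) description; the test suite carries an independent
Mason solve as an oracle and the two agree to machine precision.

Losses follow standard practice for lossy polymer piezoelectrics:

* dielectric: `ε^S(f) = K(f)·ε₀·(1 − j tan δₑ(f))` with the fitted linear
  laws `K(f) = 6.5 − 0.0088 f_MHz` and `tan δₑ(f) = 0.075 + 0.04 f_MHz`
  (frequencies in MHz exactly as the laws are quoted; converted once at the
  material boundary);
* mechanical: complex stiffness, `c → c(1 + j tan δ_m/2)` with
  `tan δ_m = 0.125`, applied to the piezo layer.

`k_t = 0.185`. Semi-infinite backing (air) and load (water) terminate the
line; the 500 nm metal electrodes are neglected (thickness < λ/100).

### Homogenising the pillar layer

The piezo layer is not a monolithic plate: ~70 µm tall pillars with
air-filled kerfs stand between two ~10 µm continuous films. A laterally
free rod is softer along its axis than a laterally clamped plate: its bar
speed is `c_bar = c_plate·√((1+ν)(1−2ν)/(1−ν))`. With the handbook Poisson
ratio ν = 0.35 for PVDF copolymers, `c_bar ≈ 0.79·c_plate`. The model
therefore homogenises the composite into a single uniform layer that
preserves the acoustic travel time,

    d_eff = d_films + d_pillars · c_plate / c_bar
          = 20 µm + 70 µm × 1.267 ≈ 108.7 µm,

expressed at the measured plate speed (2100 m/s) and measured effective
impedance (3.7 MRayl), with the same `d_eff` used in `C0`. A plain 80 µm
plate at 2100 m/s would resonate near 11–13 MHz — far from the measured
8.6–8.8 MHz — whereas this single physically motivated correction
simultaneously reproduces the transmit resonance (8.61 MHz), the peak
transmit transfer (1.56 kPa/V), the −6 dB bandwidth (62%), the pulse-echo
insertion loss (−19.6 dB) and the measured receive peak (≈68 µV/Pa) of the
characterised devices. `effective_pillar_thickness()` exposes the pillar
height, film thickness and ν if a different device is modelled.

### Insertion loss definition

Insertion loss is reported as the round-trip transduction ratio
`20·log₁₀|S_tx(f_pk)·M_rx(f_pk)|` at the transmit peak frequency — surface
pressure per volt times open-circuit volts per Pascal against a perfect
reflector at the face with a lossless water path, an ideal voltage source
and an open-circuit receiver. Definitions with finite source/receiver
impedances differ by the corresponding voltage dividers (≈16 dB more loss
for 50 Ω on both sides with this high-impedance element) and are available
through the `source_ohm`/`receive_ohm` arguments.

### Defaults

Frequency grid 0.5–15 MHz with 2¹² points, linear; complex linear
interpolation when grids must be reconciled. Polyimide substrate: 14 µm,
1420 kg/m³, 2200 m/s (handbook values). Water 1000 kg/m³ × 1500 m/s;
coupling oil is acoustically equivalent (1.5 MRayl) but electrically
insulating, which is why air/oil tags exist on impedance spectra.

## Reciprocity and property fitting

A reciprocal electro-acoustic two-port obeys a closed relation between the
transmit transfer, the loaded electrical input impedance and the open-circuit
receive sensitivity:

    M_rx(f) = 2·A·Z_in(f)·S_tx(f) / (ρc)_load.

The factor 2 is the blocked-force pressure doubling at the face. The
implementation's contract is closure: applied to the model's own transmit and
impedance spectra it reproduces the direct KLM receive path to well under 1%
across the band (in fact to rounding error, since the network is reciprocal).

`fit_effective_properties` recovers `(k_t, a, b, c0, c1, tan δ_m)` from an
air-loaded impedance spectrum by bounded trust-region least squares. The
objective stacks the relative magnitude error and the phase error in radians
with equal weight — both observables are quoted with comparable relative
accuracy in practice. The laws are fitted in their linear-in-MHz form, not
as free per-frequency values. The start point is the nominal parameter set
plus a fixed number of seeded, jittered restarts, so the fit is deterministic
for identical inputs. A spectrum whose resonance dip (minimum of the
capacitor-flattened `|Z|·f`, lightly smoothed) touches the grid edge is
rejected as unidentifiable rather than silently extrapolated. Recovery on
self-generated spectra is exact to <1% noiseless and keeps the median `k_t`
error below 5% at 1% multiplicative noise.

## Angular-spectrum propagation

Fields sampled on a plane are decomposed into plane waves by 2-D FFT and
advanced by `exp(−j k_z dz)`, `k_z = √(k² − k_x² − k_y²)` (time convention
`e^{+jωt}`). Evanescent components decay on forward propagation and are
hard-zeroed on backward propagation — inverting an exponential decay
amplifies measurement noise without bound. The cost of that regularisation
is the circular ripple around a backpropagated finite aperture; it is
reproduced, not suppressed. Grids must satisfy `Δx < λ/2`; transforms are
zero-padded to twice the extent by default (wrap-around control), and
measured scans can be Tukey-windowed (α = 0.25) before backpropagation.
Synthetic-scan defaults (5 mm standoff, 8.93 MHz) are package choices for a
regime where a ±12% imposed source nonuniformity survives the scan →
backpropagation round trip to within ±2% over the aperture interior. The
active radius is the equivalent-circle radius of the single connected region
above a −6 dB threshold.

## Imaging chain

Preprocessing: per-channel DC removal; matched-filter chirp compression
normalised so a unit echo compresses to a unit peak *at the echo's start
time* (range-preserving delay convention); optional Tukey time gate and
zero-phase Butterworth band-pass.

Plane-wave compounding uses the transmit delay `(x sin θ + z cos θ)/c` (the
wavefront crosses the array origin at t = 0) plus the exact receive path,
sampling the analytic channel signals by linear interpolation, Hann
apodization inside a receive aperture gated at f-number 1.0, and coherent
summation over angles — nine angles uniformly spaced over ±8° by default
(the angle count is a study condition; the span is a package choice).

Stolt migration implements the plane-wave (normal-incidence) f–k mapping
`ω(k_x, k_z) = c(k_x² + k_z²)/(2k_z)` — transmit contributes a vertical `k`,
reception the usual `√(k² − k_x²)`, so on axis the relation reduces to the
round-trip factor 2 — with linear complex interpolation and the Jacobian
`dω/dk_z`. DAS and Stolt peak positions agree to better than λ/4 on point
targets. The f–k fan filter keeps apparent lateral speeds `|ω/k_x|` above a
cut-off with a cosine-tapered edge and is idempotent up to the taper.

B-mode images are envelope-detected (analytic-signal magnitude), normalised
to the image maximum and log-compressed with a clip at the dynamic range.
PSF metrics take lateral/axial profiles through the local peak and report
interpolated −6/−20 dB full widths. On a full-chain simulation of the
128-element array (11.5 mm aperture, 3–12 MHz chirp, wire at 20 mm) the
−6 dB lateral width lands in the 0.3–1.0 mm range expected of this aperture
and band; measured-phantom PSF values depend on the physical system and are
not reproduced numerically here.

## Vessel tracking and blood pressure

Walls are tracked by normalized cross-correlation of *adjacent* M-mode
frames within a depth gate around each wall (anterior/posterior), with
parabolic sub-sample peak refinement, gate re-centring on the running
estimate, and cumulative integration of the inter-frame delays. Adjacent-
frame correlation is robust to waveform shape; its integration drift is
negligible over the few cardiac cycles used here (an optional detrend is
deliberately left out of the default path). Frames whose peak correlation
drops below 0.7 are flagged and interpolated. Gates are user-supplied — in
practice the vessel is located manually in the M-mode display.

The pressure–area law is `p = p_d·exp(α(A/A_d − 1))` with a circular lumen
(`A ∝ D²`). Calibration is closed-form from a diastolic/systolic reference
pair: `α = ln(p_s/p_d)/(A_s/A_d − 1)`, with `A_d`/`A_s` from the
minimum/maximum tracked diameter. By construction the converted waveform
hits `p_d` and `p_s` exactly at the calibration frames, so the end-to-end
loop is scored on the *reconstructed waveform* as well as the peak: at
20 dB SNR, PRF 50 Hz and 62.5 MHz sampling, both the median peak-pressure
error and the median waveform error stay well below 5% over ten seeds.

## Synthetic data

All generators are pure functions of (spec, seed) and return ground truth
alongside the data; no pipeline stage reads the truth. The RF model is
single-scattering (Born): delayed copies of the transmit waveform with 1/r
receive spreading, hard-baffled strip-element directivity evaluated at the
pulse centre frequency, optional homogeneous attenuation (0.7 dB/(MHz·cm),
also applied at the centre frequency — a scalar approximation of the
phantom's frequency-dependent attenuation), and white Gaussian noise at a
specified SNR relative to the peak echo. Wire-phantom pulses are 3–12 MHz
Tukey-tapered linear chirps; vessel-wall echoes use a Gaussian-windowed tone
at 8.2 MHz standing in for the transducer's two-way impulse response (the
physical wall-echo spectrum is unknown; this choice is a documented model).
The vessel generator inverts the exponential wall law through a smooth
one-bump-per-cycle pressure waveform between `p_d` and `p_s` (80/120 mmHg,
1 Hz, α = 2.0, 5 mm diastolic lumen at 20 mm depth by default). At these
defaults the peak wall velocity corresponds to roughly 2–3 depth samples per
frame at PRF 50 Hz and 62.5 MHz sampling, comfortably inside the
cross-correlation search window.

What the synthetic experiments show: the *processing chain* is consistent —
delays, calibration identities, spectra and recovery errors behave as the
models predict. What they do not show: performance on real tissue (speckle,
reverberation, phase aberration, probe motion and electronic noise are not
emulated), so the quantitative agreement on synthetic data is a necessary,
not sufficient, condition for field performance.

## Numerical choices

* Band metrics interpolate the −6 dB (half-amplitude) crossings linearly and
  fail loudly (`TruncatedBandError`) when a crossing lies outside the grid.
* The KLM network is evaluated vectorised over frequency; degenerate inputs
  (zero-thickness layers, `k_t` outside (0,1), non-positive frequencies)
  raise before any numerics run.
* Beamforming grids default to λ/4 at the pulse centre frequency; sound
  speed defaults to 1540 m/s (soft-tissue convention).
* Image normalisation rejects all-zero images rather than emitting −inf.
* Random numbers come exclusively from `numpy.random.default_rng(seed)`.

## Known limitations

* The KLM model is 1-D: no lateral modes, no inter-pillar coupling, no
  curvature effects; the pillar correction is an effective-medium argument,
  not a 3-D computation.
* Stolt migration implements the normal-incidence mapping only; steered
  frames are refused rather than approximated.
* The fitting module fixes the loss laws to their linear forms; strongly
  non-linear dispersion would bias the recovered parameters.
* Attenuation in the RF generator is a centre-frequency scalar, so it does
  not reproduce depth-dependent spectral downshift.
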