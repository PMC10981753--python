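# sonoflex

Modelling and signal-processing toolkit for flexible polymer **pillar
ultrasound transducers** — thin P(VDF-TrFE) films hot-embossed into dense
hexagonal pillar arrays on a polyimide foil, used for wearable imaging and
non-invasive blood-pressure sensing.

The package covers the full computational chain of such a transducer study:

* **Stack geometry & interface acoustics** (`sonoflex.materials`) — layer
  stacks, acoustic impedance `Z = ρc`, pressure transmission
  `T = 2Z₂/(Z₁+Z₂)`, hexagonal pillar-lattice fill factor and pillar counts.
* **Lossy KLM model** (`sonoflex.klm`) — a transmission-line equivalent
  circuit of the layered thickness-mode stack with frequency-dependent
  dielectric loss, `ε(f) = ε₀K(f)(1 − j tan δₑ(f))`, and mechanical loss as a
  complex stiffness. Predicts electrical impedance, transmit transfer
  (Pa/V), open-circuit receive sensitivity (V/Pa), −6 dB band metrics, and
  pulse-echo insertion loss.
* **Characterization** (`sonoflex.characterization`) — receive sensitivity
  from reciprocity, `M(f) = 2A·Z(f)·S(f)/(ρc)`, and least-squares recovery of
  the piezo parameter laws `(k_t, K(f), tan δₑ(f), tan δ_m)` from measured
  electrical impedance spectra.
* **Wavefields** (`sonoflex.wavefield`) — angular-spectrum forward/backward
  propagation, surface-pressure maps from hydrophone scans, active-radius
  estimation.
* **Imaging** (`sonoflex.imaging`) — chirp compression, plane-wave-compounded
  delay-and-sum, Stolt f–k migration, f–k fan filtering, envelope detection
  and IEC-style PSF width metrics.
* **Hemodynamics** (`sonoflex.hemodynamics`) — vessel-wall tracking by
  cross-correlation of M-mode RF and conversion of lumen distension to blood
  pressure via the exponential wall law `p = p_d·exp(α(A/A_d − 1))`.
* **Synthetic data** (`sonoflex.synthetic`) — seeded generators for every
  input: noisy impedance spectra, hydrophone scan planes, wire-phantom plane-
  wave RF with 3–12 MHz chirps, and M-mode RF of a pulsating carotid-like
  vessel with known ground truth.

## Worked example

```python
import numpy as np
from sonoflex import klm

stack = klm.reference_design()           # air | polyimide | pillar composite | water
tx = klm.transmit_transfer(stack)        # Pa/V on a 0.5-15 MHz grid
bm = klm.band_metrics(tx)
rx = klm.receive_transfer_direct(stack)  # V/Pa, open circuit

print(f"peak transmit  {bm.peak_value/1e3:.2f} kPa/V at {bm.peak_frequency/1e6:.2f} MHz")
print(f"-6 dB bandwidth {bm.fractional_bandwidth:.1f} %")
print(f"peak receive   {np.abs(rx.values).max()*1e6:.1f} uV/Pa")
print(f"insertion loss {klm.pulse_echo_insertion_loss(stack):.1f} dB")
```

prints

```
peak transmit  1.56 kPa/V at 8.61 MHz
-6 dB bandwidth 61.8 %
peak receive   67.9 uV/Pa
insertion loss -19.6 dB
```

i.e. the 12-mm single-element design resonates near 8.6 MHz, produces about
1.5 kPa of surface pressure per volt, receives about 68 µV/Pa and loses about
20 dB on a pulse-echo round trip — the regime in which a backing- and
matching-layer-free polymer transducer works, thanks to its near-tissue
acoustic impedance (transmission coefficient 0.58 into tissue, against 0.082
for a conventional 35 MRayl ceramic).

The same workflow is available from the shell:

```bash
sonoflex geom                         # impedance table, fill factor, pillar counts
sonoflex model --load water --out out # transfer functions + impedance as CSV
sonoflex simulate vessel --seed 1 --noise 20 --out vessel.h5
sonoflex track-bp vessel.h5 --gates 16.5,18.5,21.5,23.5 --pd 80 --ps 120 --out bp.csv
```

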