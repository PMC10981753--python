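"""Lossy KLM transmission-line model of a layered thickness-mode transducer.

The electro-acoustic core is the KLM equivalent circuit: each passive layer
is an acoustic transmission line, the piezo layer is a line tapped at its
midpoint where an ideal transformer couples to the electrical port through
the clamped capacitance ``C0`` and the frequency-dependent reactance ``X1``.
Losses enter in the standard way for lossy polymer piezoelectrics:

* mechanical loss as a complex stiffness, ``c -> c (1 + j tan_dm / 2)``,
* dielectric loss as a complex permittivity, ``eps -> eps (1 - j tan_de(f))``,

with the permittivity and dielectric-loss laws linear in frequency (MHz), as
fitted from electrical impedance spectra.

Element values (``Z0 = rho c A`` is the area-scaled line impedance, ``k``
the complex wavenumber, ``d`` the piezo thickness, ``h`` the piezoelectric
pressure constant ``k_t sqrt(rho c^2 / eps^S)``)::

    C0  = eps^S A / d
    X1  = h^2 / (w^2 Z0) * sin(k d)
    phi = 2 h / (w Z0) * sin(k d / 2)        (transformer, V = phi * F)
    Zin = 1/(j w C0) + j X1 + phi^2 * (Z1 || Z2)

where ``Z1``/``Z2`` are the impedances of the two half-thickness piezo lines
terminated by the back/front layer chains and the semi-infinite media.  This
network is algebraically equivalent to the exact 1-D three-port (Mason)
description of the plate, which the test-suite uses as an independent oracle.

The *pillar* modification
-------------------------
The piezo layer of an embossed pillar transducer is not a monolithic plate:
~70 um tall hexagonal pillars with air-filled kerfs stand between two thin
continuous films (~10 um each).  A laterally free rod is softer in the
thickness direction than a laterally clamped plate, so the pillar portion
propagates at the *bar* speed rather than the plate speed measured on the
film.  The model homogenises the composite to a single uniform layer whose
acoustic travel time is preserved::

    d_eff = d_films + d_pillars * c_plate / c_bar,
    c_bar = c_plate * sqrt((1 + nu)(1 - 2 nu) / (1 - nu)),

with Poisson ratio ``nu = 0.35`` (handbook value for PVDF copolymers).  The
effective layer keeps the measured plate speed and measured impedance; the
same effective thickness is used in ``C0``.  See ``docs/methods.md``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import math

import numpy as np

from sonoflex.materials import (
    AIR,
    OIL,
    POLYIMIDE,
    WATER,
    CircularElement,
    InvalidMaterialError,
    Layer,
    Material,
    PiezoMaterial,
    TransducerStack,
    pvdf_trfe,
)


class TruncatedBandError(ValueError):
    """The -6 dB level is not crossed inside the frequency grid."""


@dataclass(frozen=True)
class TransferFunction:
    """Complex frequency response with a unit tag ('Pa/V', 'V/Pa' or 'Ohm')."""

    frequencies: np.ndarray  # Hz, strictly increasing
    values: np.ndarray  # complex
    unit: str

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=complex)
        if f.shape != v.shape:
            raise ValueError("frequencies and values must have the same length")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    def resample(self, frequencies: np.ndarray) -> "TransferFunction":
        """Linear interpolation in the complex values onto a new grid."""
        f = np.asarray(frequencies, dtype=float)
        re = np.interp(f, self.frequencies, self.values.real)
        im = np.interp(f, self.frequencies, self.values.imag)
        return TransferFunction(f, re + 1j * im, self.unit)


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex electrical impedance spectrum with a load-condition tag."""

    frequencies: np.ndarray  # Hz
    values: np.ndarray  # complex Ohm
    load: str = "air"  # air | oil | water

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        v = np.asarray(self.values, dtype=complex)
        if f.shape != v.shape:
            raise ValueError("frequencies and values must have the same length")
        if np.any(np.abs(v) <= 0):
            raise ValueError("impedance magnitude must be positive everywhere")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    def as_transfer(self) -> TransferFunction:
        return TransferFunction(self.frequencies, self.values, "Ohm")


@dataclass(frozen=True)
class BandMetrics:
    """Peak and -6 dB band descriptors of a transfer function."""

    peak_value: float
    peak_frequency: float  # Hz
    f_low: float  # Hz, lower -6 dB crossing
    f_high: float  # Hz, upper -6 dB crossing

    @property
    def center_frequency(self) -> float:
        return 0.5 * (self.f_low + self.f_high)

    @property
    def fractional_bandwidth(self) -> float:
        """-6 dB fractional bandwidth in percent of the centre frequency."""
        return 100.0 * (self.f_high - self.f_low) / self.center_frequency


# ---------------------------------------------------------------------------
# reference design


def effective_pillar_thickness(
    pillar_height: float = 70e-6,
    film_thickness: float = 20e-6,
    poisson: float = 0.35,
) -> float:
    """Travel-time-preserving effective thickness of the pillar composite.

    The laterally free pillars propagate at the bar speed
    ``c_bar = c_plate * sqrt((1+nu)(1-2nu)/(1-nu))``; expressing the layer at
    the measured plate speed stretches the pillar portion by the inverse of
    that factor.  ``film_thickness`` is the total thickness of the continuous
    (residual + capping) films, which do propagate at the plate speed.
    """
    if not 0.0 <= poisson < 0.5:
        raise ValueError("poisson must be in [0, 0.5)")
    bar_over_plate = math.sqrt(
        (1.0 + poisson) * (1.0 - 2.0 * poisson) / (1.0 - poisson)
    )
    return film_thickness + pillar_height / bar_over_plate


def reference_design(
    element_area: float | None = None,
    load: Material = WATER,
    piezo: PiezoMaterial | None = None,
    substrate_thickness: float = 14e-6,
) -> TransducerStack:
    """The default air-backed pillar-transducer stack.

    Backing -> load: air | polyimide foil (14 um) | homogenised P(VDF-TrFE)
    pillar composite | load medium (water by default).  The 500 nm metal
    electrodes are acoustically negligible (thickness << lambda/100) and are
    omitted.  The default element is the 12-mm-diameter single-element disc
    (113 mm^2).
    """
    if element_area is None:
        element_area = CircularElement(radius=6e-3).area
    if piezo is None:
        piezo = pvdf_trfe()
    layers = (
        Layer(POLYIMIDE, substrate_thickness),
        Layer(piezo, effective_pillar_thickness()),
    )
    return TransducerStack(
        layers=layers,
        element_area=element_area,
        backing_medium=AIR,
        load_medium=load,
    )


def default_grid(
    f_min: float = 0.5e6, f_max: float = 15e6, n: int = 4096
) -> np.ndarray:
    """Default linear frequency grid for all spectra (0.5-15 MHz, 2^12 pts)."""
    return np.linspace(f_min, f_max, n)


# ---------------------------------------------------------------------------
# network primitives (vectorised over frequency)


def _line_abcd(material: Material, thickness: float, f: np.ndarray, area: float):
    """ABCD matrix entries of an acoustic transmission-line layer.

    Maps (force, velocity) at the input port to the output port:
    ``[F1; u1] = [[A, B], [C, D]] [F2; u2]``, det = 1.
    """
    c = material.complex_wave_speed
    k = 2.0 * np.pi * f / c
    z0 = material.density * c * area
    kd = k * thickness
    return np.cos(kd), 1j * z0 * np.sin(kd), 1j * np.sin(kd) / z0, np.cos(kd)


def _chain_abcd(layers, f: np.ndarray, area: float):
    """Cascade ABCD of passive layers, ordered from the piezo outwards."""
    A = np.ones_like(f, dtype=complex)
    B = np.zeros_like(f, dtype=complex)
    C = np.zeros_like(f, dtype=complex)
    D = np.ones_like(f, dtype=complex)
    for lay in layers:
        a, b, c_, d = _line_abcd(lay.material, lay.thickness, f, area)
        A, B, C, D = A * a + B * c_, A * b + B * d, C * a + D * c_, C * b + D * d
    return A, B, C, D


def _radiation_impedance(medium: Material, f: np.ndarray, area: float):
    z = medium.density * medium.complex_wave_speed * area
    return np.broadcast_to(z, np.shape(f)).astype(complex)


def _terminated_chain_impedance(layers, medium: Material, f, area):
    """Input impedance looking from the piezo face through passive layers
    into a semi-infinite medium."""
    A, B, C, D = _chain_abcd(layers, f, area)
    z_rad = _radiation_impedance(medium, f, area)
    return (A * z_rad + B) / (C * z_rad + D)


class _KLMNetwork:
    """Per-stack KLM element values evaluated on a frequency grid."""

    def __init__(self, stack: TransducerStack, f: np.ndarray):
        f = np.asarray(f, dtype=float)
        if np.any(f <= 0):
            raise ValueError("frequencies must be positive")
        piezo_layer = stack.piezo_layer
        piezo: PiezoMaterial = piezo_layer.material  # type: ignore[assignment]
        if not 0.0 < piezo.k_t < 1.0:
            raise InvalidMaterialError("k_t must be in (0, 1)")
        area = stack.element_area
        d = piezo_layer.thickness

        w = 2.0 * np.pi * f
        c = piezo.complex_wave_speed
        rho = piezo.density
        eps = piezo.complex_permittivity(f)
        k = w / c
        z0 = rho * c * area

        self.f = f
        self.w = w
        self.area = area
        self.c0 = eps * area / d  # clamped capacitance, complex
        h = piezo.k_t * np.sqrt(rho * c**2 / eps)
        kd = k * d
        self.x1 = h**2 / (w**2 * z0) * np.sin(kd)
        self.phi = 2.0 * h / (w * z0) * np.sin(kd / 2.0)
        # half-thickness piezo lines
        self.half = _line_abcd(piezo, d / 2.0, f, area)
        # terminated back/front chains seen from the piezo faces
        self.zb_face = _terminated_chain_impedance(
            stack.back_layers, stack.backing_medium, f, area
        )
        self.zf_face = _terminated_chain_impedance(
            stack.front_layers, stack.load_medium, f, area
        )
        A, B, C, D = self.half
        self.z1 = (A * self.zb_face + B) / (C * self.zb_face + D)
        self.z2 = (A * self.zf_face + B) / (C * self.zf_face + D)
        self.za = self.z1 * self.z2 / (self.z1 + self.z2)
        self.zin = 1.0 / (1j * w * self.c0) + 1j * self.x1 + self.phi**2 * self.za
        # front chain from the centre tap to the outer surface
        a2, b2, c2, d2 = self.half
        af, bf, cf, df = _chain_abcd(stack.front_layers, f, area)
        self.front_chain = (
            a2 * af + b2 * cf,
            a2 * bf + b2 * df,
            c2 * af + d2 * cf,
            c2 * bf + d2 * df,
        )
        self.z_load = _radiation_impedance(stack.load_medium, f, area)

    def transmit_surface_pressure(self) -> np.ndarray:
        """Pressure at the outer (load-side) surface per volt, complex."""
        current = 1.0 / self.zin  # V = 1
        u_c = self.phi * current
        f_c = self.za * u_c
        u2 = f_c / self.z2  # velocity into the front half-line
        A, B, C, D = self.front_chain
        # [F_c; u2] = T [F_s; u_s]; det(T) = 1 for reciprocal lines
        f_surf = D * f_c - B * u2
        return f_surf / self.area

    def receive_open_circuit(self) -> np.ndarray:
        """Open-circuit voltage per Pa of incident plane-wave pressure."""
        # Thevenin source at the outer surface: blocked force 2*p*A behind
        # the load radiation impedance; chain reversed (surface -> centre).
        A, B, C, D = self.front_chain
        Ar, Br, Cr, Dr = D, B, C, A  # reversal of a reciprocal symmetric chain
        f_src = 2.0 * 1.0 * self.area  # p_inc = 1 Pa
        denom = (
            Ar + Br / self.z1 + self.z_load * (Cr + Dr / self.z1)
        )
        f_c = f_src / denom
        return self.phi * f_c


# ---------------------------------------------------------------------------
# public operations


def clamped_capacitance(
    stack: TransducerStack, f: np.ndarray | float
) -> np.ndarray | complex:
    """Complex clamped capacitance C0(f) = eps^S(f) A / d, farads.

    The imaginary part carries the dielectric loss ``(1 - j tan_de(f))``.
    """
    piezo_layer = stack.piezo_layer
    piezo: PiezoMaterial = piezo_layer.material  # type: ignore[assignment]
    return (
        piezo.complex_permittivity(f) * stack.element_area / piezo_layer.thickness
    )


def electrical_impedance(
    stack: TransducerStack,
    frequencies: np.ndarray | None = None,
    load: Material | None = None,
) -> ImpedanceSpectrum:
    """Complex input impedance at the electrical port of the KLM network."""
    if frequencies is None:
        frequencies = default_grid()
    if load is not None:
        stack = stack.with_load(load)
    net = _KLMNetwork(stack, frequencies)
    return ImpedanceSpectrum(net.f, net.zin, load=stack.load_medium.name)


def transmit_transfer(
    stack: TransducerStack, frequencies: np.ndarray | None = None
) -> TransferFunction:
    """Surface pressure per volt of drive (Pa/V) at the load-side surface."""
    if frequencies is None:
        frequencies = default_grid()
    net = _KLMNetwork(stack, frequencies)
    return TransferFunction(net.f, net.transmit_surface_pressure(), "Pa/V")


def receive_transfer_direct(
    stack: TransducerStack, frequencies: np.ndarray | None = None
) -> TransferFunction:
    """Open-circuit receive sensitivity (V/Pa) computed directly on the
    KLM network (acoustic drive, electrical port open)."""
    if frequencies is None:
        frequencies = default_grid()
    net = _KLMNetwork(stack, frequencies)
    return TransferFunction(net.f, net.receive_open_circuit(), "V/Pa")


def band_metrics(tf: TransferFunction) -> BandMetrics:
    """Peak and -6 dB band of a transfer-function magnitude.

    The -6 dB (half-amplitude) crossings are found by linear interpolation
    between grid samples on either side of the global peak; a
    :class:`TruncatedBandError` is raised if a crossing lies outside the grid.
    """
    mag = tf.magnitude
    f = tf.frequencies
    i = int(np.argmax(mag))
    level = mag[i] / 2.0

    below_lo = np.nonzero(mag[: i + 1] < level)[0]
    below_hi = np.nonzero(mag[i:] < level)[0]
    if len(below_lo) == 0 or len(below_hi) == 0:
        raise TruncatedBandError(
            "-6 dB level not crossed on both sides within the frequency grid"
        )
    j = below_lo[-1]
    f_low = f[j] + (level - mag[j]) * (f[j + 1] - f[j]) / (mag[j + 1] - mag[j])
    k = i + below_hi[0]
    f_high = f[k - 1] + (level - mag[k - 1]) * (f[k] - f[k - 1]) / (
        mag[k] - mag[k - 1]
    )
    return BandMetrics(
        peak_value=float(mag[i]),
        peak_frequency=float(f[i]),
        f_low=float(f_low),
        f_high=float(f_high),
    )


def pulse_echo_insertion_loss(
    stack: TransducerStack,
    frequencies: np.ndarray | None = None,
    source_ohm: float = 0.0,
    receive_ohm: float = math.inf,
) -> float:
    """Round-trip insertion loss in dB at the transmit peak frequency.

    A perfectly reflecting target at the transducer face returns the emitted
    surface pressure without propagation loss, so the round-trip voltage
    ratio is ``S_tx(f_pk) * M_rx(f_pk)`` (Pa/V times V/Pa).  By default the
    source is an ideal voltage source and the receiver is open-circuit; a
    finite ``source_ohm``/``receive_ohm`` inserts the corresponding voltage
    dividers against the transducer's electrical impedance.
    """
    if frequencies is None:
        frequencies = default_grid()
    net = _KLMNetwork(stack, frequencies)
    tx = net.transmit_surface_pressure()
    rx = net.receive_open_circuit()
    i = int(np.argmax(np.abs(tx)))
    ratio = tx[i] * rx[i]
    if source_ohm > 0:
        ratio *= net.zin[i] / (net.zin[i] + source_ohm)
    if math.isfinite(receive_ohm):
        ratio *= receive_ohm / (net.zin[i] + receive_ohm)
    return float(20.0 * np.log10(np.abs(ratio)))


@dataclass(frozen=True)
class MatchingNetwork:
    """Series tuning network between the source and the transducer."""

    series_inductance: float = 0.0  # H
    series_resistance: float = 0.0  # Ohm

    def impedance(self, f: np.ndarray) -> np.ndarray:
        return self.series_resistance + 1j * 2.0 * np.pi * f * self.series_inductance


def apply_matching_network(
    stack: TransducerStack,
    network: MatchingNetwork,
    frequencies: np.ndarray | None = None,
) -> TransferFunction:
    """Transmit transfer re-evaluated with a series tuning network.

    The network forms a voltage divider with the transducer impedance:
    ``S'(f) = S(f) * Zin / (Zin + Z_net)``.  The identity network leaves the
    transfer unchanged; an inductor resonating C0 near the peak boosts it.
    """
    if network.series_inductance < 0 or network.series_resistance < 0:
        raise ValueError("network element values must be >= 0")
    if frequencies is None:
        frequencies = default_grid()
    net = _KLMNetwork(stack, frequencies)
    tx = net.transmit_surface_pressure()
    divider = net.zin / (net.zin + network.impedance(net.f))
    return TransferFunction(net.f, tx * divider, "Pa/V")
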