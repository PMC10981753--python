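"""Synthetic-data generators for every pipeline input.

All generators are pure functions of their specification and a seed, and
always return the ground truth alongside the data so that recovery can be
scored without any stage reading the truth.

The RF generators use a single-scattering (Born) model: each target
contributes a delayed, range-attenuated copy of the transmit waveform; no
multiple reflections or speckle physics beyond an optional random scatterer
background.  Element directivity is the hard-baffled strip pattern
``sinc(w sin(theta) / lambda)`` evaluated at the pulse centre frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from sonoflex.hemodynamics import PressureModel, VesselTrack
from sonoflex.imaging import PlaneWaveEvent, RFFrame
from sonoflex.klm import ImpedanceSpectrum, electrical_impedance
from sonoflex.materials import Material, TransducerStack, WATER
from sonoflex.wavefield import FieldPlane, angular_spectrum_propagate


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class ChirpPulse:
    """Linear FM chirp with a Tukey amplitude taper."""

    f_start: float = 3e6  # Hz
    f_stop: float = 12e6  # Hz
    duration: float = 2.5e-6  # s
    taper: float = 0.25  # Tukey alpha

    @property
    def center_frequency(self) -> float:
        return 0.5 * (self.f_start + self.f_stop)

    @property
    def bandwidth(self) -> float:
        return abs(self.f_stop - self.f_start)

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Waveform at arbitrary (possibly sub-sample) times; zero outside
        [0, duration]."""
        t = np.asarray(t, float)
        T = self.duration
        rate = (self.f_stop - self.f_start) / T
        phase = 2.0 * np.pi * (self.f_start * t + 0.5 * rate * t**2)
        u = t / T
        a = self.taper
        env = np.zeros_like(t)
        inside = (u >= 0) & (u <= 1)
        env[inside] = 1.0
        if a > 0:
            rising = inside & (u < a / 2)
            falling = inside & (u > 1 - a / 2)
            env[rising] = 0.5 * (1 + np.cos(np.pi * (2 * u[rising] / a - 1)))
            env[falling] = 0.5 * (1 + np.cos(np.pi * (2 * (u[falling] - 1) / a + 1)))
        return env * np.cos(phase)

    def waveform(self, sample_rate: float) -> np.ndarray:
        """Replica sampled at `sample_rate` (for matched filtering)."""
        n = int(round(self.duration * sample_rate)) + 1
        return self.sample(np.arange(n) / sample_rate)


@dataclass(frozen=True)
class GaborPulse:
    """Gaussian-windowed tone: a generic two-way impulse response."""

    center_frequency: float = 8.2e6  # Hz
    fractional_bandwidth: float = 0.6  # -6 dB, fraction of f_c

    def sample(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        # -6 dB envelope bandwidth B = fbw * fc; gaussian envelope
        sigma_f = self.fractional_bandwidth * self.center_frequency / (
            2.0 * math.sqrt(2.0 * math.log(2.0))
        )
        sigma_t = 1.0 / (2.0 * np.pi * sigma_f)
        return np.exp(-0.5 * (t / sigma_t) ** 2) * np.cos(
            2.0 * np.pi * self.center_frequency * t
        )


@dataclass(frozen=True)
class ArrayGeometry:
    """Uniform linear array on z = 0."""

    n_elements: int = 64
    pitch: float = 180e-6  # m
    element_width: float = 175e-6  # m
    sound_speed: float = 1540.0  # m/s

    @property
    def element_x(self) -> np.ndarray:
        return (np.arange(self.n_elements) - (self.n_elements - 1) / 2.0) * self.pitch


@dataclass(frozen=True)
class ScattererSet:
    """Point targets in the imaging plane."""

    x: np.ndarray  # m
    z: np.ndarray  # m, > 0
    reflectivity: np.ndarray | None = None

    def __post_init__(self) -> None:
        x = np.atleast_1d(np.asarray(self.x, float))
        z = np.atleast_1d(np.asarray(self.z, float))
        if len(x) != len(z):
            raise ValueError("x and z must have equal length")
        if np.any(z <= 0):
            raise ValueError("all scatterers must lie at positive depth")
        r = (np.ones_like(x) if self.reflectivity is None
             else np.atleast_1d(np.asarray(self.reflectivity, float)))
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "reflectivity", r)


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Pulsating carotid-like vessel phantom."""

    lumen_diameter: float = 5e-3  # m, diastolic
    outer_diameter: float = 10e-3  # m
    center_depth: float = 20e-3  # m
    wall_reflectivity: float = 1.0
    p_d: float = 80.0  # mmHg
    p_s: float = 120.0  # mmHg
    heart_rate: float = 1.0  # Hz
    alpha_true: float = 2.0

    def __post_init__(self) -> None:
        if self.outer_diameter <= self.lumen_diameter:
            raise ValueError("outer diameter must exceed the lumen diameter")
        if not self.p_s > self.p_d > 0:
            raise ValueError("need p_s > p_d > 0")

    def model(self) -> PressureModel:
        return PressureModel(
            p_d=self.p_d,
            alpha=self.alpha_true,
            A_d=math.pi * self.lumen_diameter**2 / 4.0,
        )

    def pressure(self, t: np.ndarray) -> np.ndarray:
        """Smooth periodic pressure with min p_d and max p_s.

        One systolic upstroke per cycle: a sin^2 bump with an exponential
        relaxation, normalised so the extrema hit the calibration pressures
        exactly.
        """
        phase = np.mod(np.asarray(t, float) * self.heart_rate, 1.0)
        shape = np.sin(np.pi * phase) ** 2 * np.exp(-1.5 * phase)
        ref = np.sin(np.pi * np.linspace(0, 1, 2001)) ** 2 * np.exp(
            -1.5 * np.linspace(0, 1, 2001)
        )
        return self.p_d + (self.p_s - self.p_d) * shape / ref.max()


# ---------------------------------------------------------------------------
# generators


def gen_impedance(
    stack: TransducerStack,
    frequencies: np.ndarray,
    noise_rel: float = 0.0,
    seed: int = 0,
    load: Material | None = None,
) -> ImpedanceSpectrum:
    """KLM impedance spectrum with multiplicative Gaussian noise.

    Independent relative noise on the real and imaginary parts,
    reproducible per seed; ``noise_rel = 0`` returns the model output
    bit-identically.
    """
    if noise_rel < 0:
        raise ValueError("noise_rel must be >= 0")
    z = electrical_impedance(stack, frequencies, load=load)
    if noise_rel == 0.0:
        return z
    rng = np.random.default_rng(seed)
    re = z.values.real * (1.0 + noise_rel * rng.standard_normal(len(z.values)))
    im = z.values.imag * (1.0 + noise_rel * rng.standard_normal(len(z.values)))
    return ImpedanceSpectrum(z.frequencies, re + 1j * im, load=z.load)


def _directivity(geom: ArrayGeometry, sin_theta: np.ndarray, f_c: float) -> np.ndarray:
    lam = geom.sound_speed / f_c
    return np.sinc(geom.element_width * sin_theta / lam)


def gen_wire_phantom_rf(
    scatterers: ScattererSet,
    geometry: ArrayGeometry = ArrayGeometry(),
    pulse: ChirpPulse = ChirpPulse(),
    angles: np.ndarray | None = None,
    sample_rate: float = 62.5e6,
    max_depth: float = 40e-3,
    attenuation_db_mhz_cm: float | None = None,
    snr_db: float | None = None,
    seed: int = 0,
) -> list[RFFrame]:
    """Plane-wave RF frames of a wire-target phantom, one frame per angle.

    Each scatterer contributes the transmit chirp delayed by the exact
    round-trip time (transmit plane-wave arrival plus the element-to-target
    path), with 1/r spreading on the receive leg, strip-element directivity,
    and optionally a homogeneous attenuation of ``attenuation_db_mhz_cm``
    evaluated at the chirp centre frequency over the round-trip path.
    ``snr_db`` adds white Gaussian noise relative to the peak echo amplitude.
    """
    if angles is None:
        angles = np.deg2rad(np.linspace(-8.0, 8.0, 9))
    c = geometry.sound_speed
    ex = geometry.element_x
    n_samples = int(round((2.0 * max_depth / c + pulse.duration) * sample_rate))
    t = np.arange(n_samples) / sample_rate
    rng = np.random.default_rng(seed)
    if np.any(scatterers.z <= 0):
        raise ValueError("scatterer behind the array plane")

    frames = []
    for angle in np.atleast_1d(angles):
        data = np.zeros((geometry.n_elements, n_samples))
        tau_tx = (scatterers.x * np.sin(angle) + scatterers.z * np.cos(angle)) / c
        for s in range(len(scatterers.x)):
            dx = scatterers.x[s] - ex
            r = np.hypot(dx, scatterers.z[s])
            tau = tau_tx[s] + r / c
            amp = scatterers.reflectivity[s] / np.maximum(r, 1e-6)
            amp = amp * _directivity(geometry, dx / r, pulse.center_frequency)
            if attenuation_db_mhz_cm is not None:
                path_cm = (scatterers.z[s] * np.cos(angle) + r) * 100.0
                f_mhz = pulse.center_frequency / 1e6
                amp = amp * 10.0 ** (
                    -attenuation_db_mhz_cm * f_mhz * path_cm / 20.0
                )
            data += amp[:, None] * pulse.sample(t[None, :] - tau[:, None])
        if snr_db is not None:
            peak = np.abs(data).max()
            if peak > 0:
                sigma = peak * 10.0 ** (-snr_db / 20.0)
                data = data + sigma * rng.standard_normal(data.shape)
        frames.append(
            RFFrame(
                data=data,
                sample_rate=sample_rate,
                element_x=ex,
                transmit=PlaneWaveEvent(angle=float(angle)),
                t0=0.0,
                sound_speed=c,
            )
        )
    return frames


def gen_pulsating_vessel_rf(
    spec: VesselPhantomSpec = VesselPhantomSpec(),
    prf: float = 50.0,
    sample_rate: float = 62.5e6,
    duration: float = 3.0,
    snr_db: float | None = 20.0,
    seed: int = 0,
    pulse: GaborPulse = GaborPulse(),
    sound_speed: float = 1540.0,
) -> tuple[list[RFFrame], VesselTrack, np.ndarray]:
    """M-mode RF of a pulsating vessel, plus the ground truth.

    The pressure waveform of the spec is pushed through the exponential wall
    model (``alpha_true``) to obtain the lumen diameter per frame; each frame
    carries one anterior and one posterior wall echo (two-way impulse
    response ``pulse``) at the exact wall depths, plus white noise at
    ``snr_db`` relative to the echo amplitude.

    Returns ``(frames, truth_track, truth_pressure)`` where ``truth_pressure``
    is the pressure sample per frame in the spec's units.
    """
    if prf < 20.0 * spec.heart_rate:
        raise ValueError("PRF must be at least 20x the heart rate for tracking")
    rng = np.random.default_rng(seed)
    n_frames = int(round(duration * prf))
    times = np.arange(n_frames) / prf
    pressure = spec.pressure(times)
    model = spec.model()
    area = np.asarray(model.area(pressure))
    diameter = np.sqrt(4.0 * area / math.pi)
    if np.any(diameter <= 0):
        raise ValueError("wall collision: model produced non-positive diameter")
    anterior = spec.center_depth - diameter / 2.0
    posterior = spec.center_depth + diameter / 2.0

    max_z = spec.center_depth + spec.outer_diameter  # headroom below the vessel
    n_samples = int(round(2.0 * max_z / sound_speed * sample_rate))
    t = np.arange(n_samples) / sample_rate

    frames = []
    for i in range(n_frames):
        trace = spec.wall_reflectivity * (
            pulse.sample(t - 2.0 * anterior[i] / sound_speed)
            + pulse.sample(t - 2.0 * posterior[i] / sound_speed)
        )
        if snr_db is not None:
            sigma = spec.wall_reflectivity * 10.0 ** (-snr_db / 20.0)
            trace = trace + sigma * rng.standard_normal(n_samples)
        frames.append(
            RFFrame(
                data=trace[None, :],
                sample_rate=sample_rate,
                element_x=np.array([0.0]),
                transmit=PlaneWaveEvent(0.0),
                t0=0.0,
                sound_speed=sound_speed,
            )
        )
    truth = VesselTrack(times=times, anterior=anterior, posterior=posterior)
    return frames, truth, pressure


def gen_hydrophone_scan(
    source_radius: float = 6e-3,
    scan_height: float = 5e-3,
    frequency: float = 8.6e6,
    extent: float = 24e-3,
    n_points: int = 256,
    nonuniformity: np.ndarray | float | None = None,
    noise_rel: float = 0.0,
    seed: int = 0,
    medium: Material = WATER,
) -> tuple[FieldPlane, FieldPlane]:
    """Synthetic hydrophone scan of a uniform disc source.

    The source plane is a disc of the given radius with complex amplitude
    ``1 + nonuniformity`` (a map on the full grid, or a scalar peak value of
    a smooth random map drawn from the seed), forward-propagated to the scan
    height; complex Gaussian noise of relative level ``noise_rel`` is added.

    Returns ``(scan_plane, truth_source_plane)``.
    """
    half = extent / 2.0
    x = np.linspace(-half, half, n_points)
    y = np.linspace(-half, half, n_points)
    xx, yy = np.meshgrid(x, y)
    disc = (xx**2 + yy**2 <= source_radius**2).astype(complex)

    rng = np.random.default_rng(seed)
    if nonuniformity is None:
        amp = disc
    elif np.isscalar(nonuniformity):
        # smooth random map with the requested peak relative deviation
        rough = rng.standard_normal((n_points, n_points))
        spec = np.fft.fft2(rough)
        fx = np.fft.fftfreq(n_points, x[1] - x[0])
        lowpass = np.exp(-((fx[None, :] ** 2 + fx[:, None] ** 2)) / (2 * (200.0) ** 2))
        smooth = np.real(np.fft.ifft2(spec * lowpass))
        smooth *= float(nonuniformity) / np.abs(smooth).max()
        amp = disc * (1.0 + smooth)
    else:
        amp = disc * (1.0 + np.asarray(nonuniformity, complex))

    source = FieldPlane(x=x, y=y, z=0.0, frequencies=np.array([frequency]),
                        values=amp[None, :, :])
    scan = angular_spectrum_propagate(source, scan_height, medium)
    if noise_rel > 0:
        scale = np.abs(scan.values).max() * noise_rel
        noise = scale * (
            rng.standard_normal(scan.values.shape)
            + 1j * rng.standard_normal(scan.values.shape)
        ) / math.sqrt(2.0)
        scan = FieldPlane(scan.x, scan.y, scan.z, scan.frequencies,
                          scan.values + noise)
    return scan, source
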