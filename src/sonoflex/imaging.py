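"""RF post-processing and image formation for plane-wave acquisitions.

The chain mirrors standard coded-excitation plane-wave imaging practice:

1. mean (DC) subtraction per channel,
2. chirp (matched-filter) compression against the transmit replica,
3. optional time windowing and band-pass filtering,
4. image formation — plane-wave-compounded delay-and-sum (DAS) or Stolt
   f-k migration,
5. optional wavenumber-frequency (f-k) filtering of the channel data,
6. envelope detection and log compression,
7. PSF width metrics on wire targets.

Conventions: elements lie on the z = 0 line at positions ``element_x``;
``t0`` is the time at which the transmitted plane wavefront crosses the
array origin (x = 0, z = 0); sample ``n`` of a trace is at time
``t0 + n / sample_rate``.  A plane wave steered by ``angle`` reaches the
point (x, z) at ``(x sin(angle) + z cos(angle)) / c``; the echo returns to an
element at ``sqrt((x - xe)^2 + z^2) / c``.  Matched filtering preserves this
timing: a unit echo starting at delay tau compresses to a peak at tau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, fftconvolve, hilbert, sosfiltfilt
from scipy.signal.windows import tukey


@dataclass(frozen=True)
class PlaneWaveEvent:
    """Plane-wave transmit: steering angle in radians (0 = normal)."""

    angle: float = 0.0


@dataclass(frozen=True)
class FocusedEvent:
    """Focused transmit (kept for container completeness)."""

    focus_x: float
    focus_z: float


@dataclass(frozen=True)
class RFFrame:
    """Multi-channel RF data for one transmit event.

    ``data`` is (channels, samples); ``element_x`` gives the lateral element
    positions (m) on the z = 0 line.
    """

    data: np.ndarray
    sample_rate: float  # Hz
    element_x: np.ndarray  # m
    transmit: PlaneWaveEvent | FocusedEvent = field(default_factory=PlaneWaveEvent)
    t0: float = 0.0  # s
    sound_speed: float = 1540.0  # m/s

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        ex = np.asarray(self.element_x, dtype=float)
        if data.ndim != 2 or data.shape[0] != len(ex):
            raise ValueError(
                "data must be (channels, samples) with one element position "
                "per channel"
            )
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "element_x", ex)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.sample_rate

    @property
    def pitch(self) -> float:
        d = np.diff(self.element_x)
        if not np.allclose(d, d[0]):
            raise ValueError("element pitch is not uniform")
        return float(d[0])


@dataclass(frozen=True)
class ComplexImage:
    """Beamformed complex image on an (z, x) grid."""

    x: np.ndarray
    z: np.ndarray
    values: np.ndarray  # (nz, nx) complex


@dataclass(frozen=True)
class BModeImage:
    """Envelope-detected, log-compressed image in dB relative to its max."""

    x: np.ndarray
    z: np.ndarray
    values_db: np.ndarray  # (nz, nx), max = 0 dB
    dynamic_range: float  # dB


@dataclass(frozen=True)
class PSFMetrics:
    """IEC-style point-spread-function widths (full widths, metres)."""

    lateral_width_6db: float
    lateral_width_20db: float
    axial_length_6db: float
    axial_length_20db: float
    peak_x: float
    peak_z: float


# ---------------------------------------------------------------------------
# preprocessing


def matched_filter(data: np.ndarray, replica: np.ndarray) -> np.ndarray:
    """Cross-correlate each row with the replica (pulse compression).

    ``out[n] = sum_m data[n + m] * conj(replica[m]) / sum_m |replica[m]|^2``
    so a unit-amplitude echo whose replica starts at sample ``n0`` compresses
    to a peak of roughly unit height at ``n0`` — the delay convention
    preserves target range.
    """
    replica = np.asarray(replica)
    if replica.size > data.shape[-1]:
        raise ValueError("replica longer than the trace")
    kernel = np.conj(replica[::-1])[None, :]
    full = fftconvolve(data, kernel, mode="full", axes=-1)
    start = replica.size - 1
    out = full[:, start:start + data.shape[-1]]
    return np.real(out) / np.sum(np.abs(replica) ** 2)


def preprocess(
    rf: RFFrame,
    replica: np.ndarray | None = None,
    time_gate: tuple[float, float] | None = None,
    gate_taper: float = 0.1,
    band: tuple[float, float] | None = None,
) -> RFFrame:
    """Standard RF conditioning: DC removal, chirp compression, optional
    raised-cosine time gate and band-pass filter.

    Parameters
    ----------
    replica : array, optional
        Transmit waveform samples (at ``rf.sample_rate``) for matched-filter
        compression.
    time_gate : (t_start, t_end), optional
        Keep only this absolute-time interval (Tukey-tapered edges).
    band : (f_low, f_high), optional
        Zero-phase Butterworth band-pass, e.g. the chirp band.
    """
    data = rf.data - rf.data.mean(axis=1, keepdims=True)
    if replica is not None:
        data = matched_filter(data, replica)
    if time_gate is not None:
        t = rf.times
        inside = (t >= time_gate[0]) & (t <= time_gate[1])
        gate = np.zeros(rf.n_samples)
        n_in = int(inside.sum())
        if n_in:
            gate[inside] = tukey(n_in, gate_taper)
        data = data * gate[None, :]
    if band is not None:
        nyq = rf.sample_rate / 2.0
        sos = butter(4, [band[0] / nyq, band[1] / nyq], btype="band", output="sos")
        data = sosfiltfilt(sos, data, axis=-1)
    return replace(rf, data=data)


# ---------------------------------------------------------------------------
# image formation


def das_pwc(
    frames: list[RFFrame],
    x_grid: np.ndarray,
    z_grid: np.ndarray,
    sound_speed: float | None = None,
    f_number: float = 1.0,
    apodization: str = "hann",
) -> ComplexImage:
    """Plane-wave-compounded delay-and-sum beamforming.

    For each pixel, each frame (steering angle) and each receiving element,
    the analytic channel signal is sampled at the round-trip delay
    ``tau = (x sin(a) + z cos(a)) / c + |r_pixel - r_element| / c`` and summed
    with Hann apodization inside a receive aperture gated at the given
    f-number; the per-angle images are summed coherently.  The result is
    linear in the input RF amplitude.
    """
    if not frames:
        raise ValueError("need at least one frame")
    x_grid = np.asarray(x_grid, float)
    z_grid = np.asarray(z_grid, float)
    c = sound_speed if sound_speed is not None else frames[0].sound_speed

    xx = x_grid[None, :]
    zz = z_grid[:, None]
    image = np.zeros((len(z_grid), len(x_grid)), dtype=complex)

    for frame in frames:
        if not isinstance(frame.transmit, PlaneWaveEvent):
            raise ValueError("das_pwc expects plane-wave frames")
        angle = frame.transmit.angle
        analytic = hilbert(frame.data, axis=-1)
        t = frame.times
        tau_tx = (xx * np.sin(angle) + zz * np.cos(angle)) / c
        for ch in range(frame.n_channels):
            xe = frame.element_x[ch]
            half_aperture = zz / (2.0 * f_number)
            dxpix = xx - xe
            inside = np.abs(dxpix) <= half_aperture
            if not inside.any():
                continue
            if apodization == "hann":
                w = np.where(
                    inside,
                    0.5 + 0.5 * np.cos(np.pi * dxpix / np.maximum(half_aperture, 1e-12)),
                    0.0,
                )
            else:
                w = inside.astype(float)
            tau = tau_tx + np.sqrt(dxpix**2 + zz**2) / c
            re = np.interp(tau.ravel(), t, analytic[ch].real, left=0.0, right=0.0)
            im = np.interp(tau.ravel(), t, analytic[ch].imag, left=0.0, right=0.0)
            image += w * (re + 1j * im).reshape(tau.shape)

    return ComplexImage(x=x_grid, z=z_grid, values=image)


def stolt_migrate(
    frame: RFFrame,
    sound_speed: float | None = None,
    pad_factor: int = 2,
) -> ComplexImage:
    """Stolt f-k migration of a single normal-incidence plane-wave frame.

    The (channel, time) data are mapped to the (kx, w) domain; for
    plane-wave pulse-echo the vertical wavenumber of a scatterer is the sum
    of the transmit (vertical) and receive components, giving the dispersion
    relation ``w(kx, kz) = c (kx^2 + kz^2) / (2 kz)`` — the round-trip
    (factor-2) relation on axis.  The spectrum is linearly interpolated onto
    the (kx, kz) grid, scaled by the Jacobian ``dw/dkz``, and inverse
    transformed to (x, z).
    """
    if isinstance(frame.transmit, PlaneWaveEvent) and abs(frame.transmit.angle) > 1e-9:
        raise ValueError("stolt_migrate implements the normal-incidence mapping")
    c = sound_speed if sound_speed is not None else frame.sound_speed
    pitch = frame.pitch  # raises on non-uniform spacing

    data = hilbert(frame.data, axis=-1)  # analytic: positive-frequency half
    nx, nt = data.shape
    nt_p, nx_p = pad_factor * nt, pad_factor * nx
    spec = np.fft.fft2(np.pad(data, ((0, nx_p - nx), (0, nt_p - nt))))
    # spec indices: [kx, w]
    w_axis = 2.0 * np.pi * np.fft.fftfreq(nt_p, 1.0 / frame.sample_rate)
    kx_axis = 2.0 * np.pi * np.fft.fftfreq(nx_p, pitch)
    if frame.t0:
        spec *= np.exp(-1j * w_axis * frame.t0)[None, :]

    # positive-w half on a monotone axis for interpolation
    pos = w_axis >= 0
    w_pos = w_axis[pos]
    spec_pos = spec[:, pos]

    # target kz grid matched to the on-axis factor-2 mapping kz = 2 w / c
    kz = 2.0 * w_pos / c
    migrated = np.zeros((nx_p, len(kz)), dtype=complex)
    kz_col = kz[None, :]
    kx_col = np.abs(kx_axis)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        w_req = c * (kx_col**2 + kz_col**2) / (2.0 * kz_col)
        jac = c * (kz_col**2 - kx_col**2) / (2.0 * kz_col**2)
    valid = (kz_col > kx_col) & np.isfinite(w_req) & (w_req <= w_pos[-1])
    w_req = np.where(valid, w_req, 0.0)
    jac = np.where(valid, jac, 0.0)
    for i in range(nx_p):
        re = np.interp(w_req[i], w_pos, spec_pos[i].real, left=0.0, right=0.0)
        im = np.interp(w_req[i], w_pos, spec_pos[i].imag, left=0.0, right=0.0)
        migrated[i] = (re + 1j * im) * jac[i] * valid[i]

    img = np.fft.ifft(migrated, axis=1)  # kz -> z (kz grid is uniform)
    img = np.fft.ifft(img, axis=0)  # kx -> x
    dz = c / (2.0 * frame.sample_rate) * (nt_p / img.shape[1]) if img.shape[1] else 0.0
    # kz spacing = 2 dw / c -> z extent = 2 pi / dkz = c nt_p / (2 fs)
    nz = img.shape[1]
    z = np.arange(nz) * (c * nt_p / (2.0 * frame.sample_rate)) / nz
    x = frame.element_x[0] + np.arange(nx_p) * pitch
    return ComplexImage(x=x[:nx], z=z, values=img[:nx].T)


def fk_filter(
    frame: RFFrame,
    cutoff_speed: float,
    taper: float = 0.2,
) -> RFFrame:
    """Wavenumber-frequency fan filter on the channel data.

    Keeps components with apparent lateral speed ``|w / kx| >= cutoff_speed``
    (i.e. near-vertical propagation); slower, laterally travelling artifacts
    are rejected.  The mask edge is cosine-tapered over a fractional width
    ``taper`` so the filter is idempotent to within the taper band.
    """
    pitch = frame.pitch
    data = frame.data
    nx, nt = data.shape
    spec = np.fft.fft2(data)
    w = 2.0 * np.pi * np.fft.fftfreq(nt, 1.0 / frame.sample_rate)
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, pitch)
    kx_lim = np.abs(w)[None, :] / cutoff_speed  # keep |kx| <= |w|/c_cut
    akx = np.abs(kx)[:, None]
    lo = kx_lim * (1.0 - taper)
    mask = np.ones_like(spec, dtype=float)
    in_taper = (akx > lo) & (akx <= kx_lim)
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp = (akx - lo) / np.maximum(kx_lim - lo, 1e-300)
    mask[akx > kx_lim] = 0.0
    mask[in_taper] = 0.5 * (1.0 + np.cos(np.pi * ramp[in_taper]))
    filtered = np.real(np.fft.ifft2(spec * mask))
    energy_in = float(np.sum(data**2))
    energy_out = float(np.sum(filtered**2))
    if energy_in > 0 and energy_out < 1e-12 * energy_in:
        warnings.warn("f-k mask removed essentially all energy", stacklevel=2)
    return replace(frame, data=filtered)


# ---------------------------------------------------------------------------
# envelope / metrics


def envelope_logcompress(
    image: ComplexImage | np.ndarray,
    dynamic_range: float = 50.0,
    x: np.ndarray | None = None,
    z: np.ndarray | None = None,
) -> BModeImage:
    """Envelope detection, normalisation to the image maximum and log
    compression clipped at ``-dynamic_range`` dB.

    A complex (beamformed) image uses the magnitude directly; a real array
    is converted to its analytic signal along the depth axis first.
    """
    if isinstance(image, ComplexImage):
        vals, x, z = image.values, image.x, image.z
    else:
        vals = np.asarray(image)
        if x is None or z is None:
            x = np.arange(vals.shape[1], dtype=float)
            z = np.arange(vals.shape[0], dtype=float)
    if np.iscomplexobj(vals):
        env = np.abs(vals)
    else:
        env = np.abs(hilbert(vals, axis=0))
    peak = env.max()
    if peak == 0:
        raise ValueError("all-zero image: normalisation undefined")
    db = 20.0 * np.log10(np.maximum(env / peak, 10.0 ** (-dynamic_range / 20.0 - 2)))
    db = np.clip(db, -dynamic_range, 0.0)
    return BModeImage(x=np.asarray(x), z=np.asarray(z), values_db=db,
                      dynamic_range=dynamic_range)


def peak_location(image: ComplexImage) -> tuple[float, float]:
    """Sub-pixel (x, z) location of the image envelope maximum.

    Parabolic refinement of the peak in each axis; the grid step limits the
    raw argmax to half a pixel, which matters when comparing beamformers on
    different grids.
    """
    env = np.abs(image.values)
    iz, ix = np.unravel_index(int(np.argmax(env)), env.shape)

    def refine(axis: np.ndarray, prof: np.ndarray, i: int) -> float:
        if i <= 0 or i >= len(prof) - 1:
            return float(axis[i])
        y0, y1, y2 = prof[i - 1], prof[i], prof[i + 1]
        den = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / den if den != 0 else 0.0
        return float(axis[i] + delta * (axis[1] - axis[0]))

    return refine(image.x, env[iz, :], ix), refine(image.z, env[:, ix], iz)


def _width_at_level(axis: np.ndarray, profile_db: np.ndarray, level: float) -> float:
    """Interpolated full width of a dB profile at `level` below its peak."""
    i = int(np.argmax(profile_db))
    target = profile_db[i] + level  # level is negative
    left = None
    for j in range(i, 0, -1):
        if profile_db[j - 1] < target:
            left = np.interp(target, [profile_db[j - 1], profile_db[j]],
                             [axis[j - 1], axis[j]])
            break
    right = None
    for j in range(i, len(axis) - 1):
        if profile_db[j + 1] < target:
            right = np.interp(target, [profile_db[j + 1], profile_db[j]],
                              [axis[j + 1], axis[j]])
            break
    if left is None or right is None:
        raise ValueError(
            f"{-level:.0f} dB level not reached within the search window"
        )
    return float(right - left)


def psf_metrics(
    image: BModeImage,
    approx_location: tuple[float, float],
    search_radius: float = 3e-3,
) -> PSFMetrics:
    """Lateral/axial full widths of an isolated point target at the -6 and
    -20 dB levels, by linear interpolation of the profiles through the local
    peak (IEC 61391-style wire-target quantification)."""
    x0, z0 = approx_location
    ix = (image.x >= x0 - search_radius) & (image.x <= x0 + search_radius)
    iz = (image.z >= z0 - search_radius) & (image.z <= z0 + search_radius)
    if not ix.any() or not iz.any():
        raise ValueError("search window is outside the image")
    sub = image.values_db[np.ix_(iz, ix)]
    pk = np.unravel_index(np.argmax(sub), sub.shape)
    zi = np.nonzero(iz)[0][pk[0]]
    xi = np.nonzero(ix)[0][pk[1]]

    lateral = image.values_db[zi, :]
    axial = image.values_db[:, xi]
    lw6 = _width_at_level(image.x, lateral, -6.0)
    lw20 = _width_at_level(image.x, lateral, -20.0)
    al6 = _width_at_level(image.z, axial, -6.0)
    al20 = _width_at_level(image.z, axial, -20.0)
    return PSFMetrics(
        lateral_width_6db=lw6,
        lateral_width_20db=lw20,
        axial_length_6db=al6,
        axial_length_20db=al20,
        peak_x=float(image.x[xi]),
        peak_z=float(image.z[zi]),
    )
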