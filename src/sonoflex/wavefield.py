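"""Angular-spectrum propagation of monochromatic pressure fields.

A field sampled on a plane is decomposed into plane waves by a 2-D spatial
FFT; each component (kx, ky) is advanced over a distance ``dz`` by the
spectral phase factor ``exp(-j kz dz)`` with ``kz = sqrt(k^2 - kx^2 - ky^2)``
(time convention ``exp(+j w t)``, waves travel towards +z).  Components with
``kx^2 + ky^2 > k^2`` are evanescent: they decay exponentially on forward
propagation and are hard-zeroed on backward propagation, because inverting
their decay amplifies measurement noise without bound.  The price of the
regularisation is the familiar circular ripple artifact around a
backpropagated finite aperture; it is reproduced, not suppressed.

Grids are zero-padded to twice their extent before the transforms to limit
wrap-around, and measured scans can be windowed (Tukey) before
backpropagation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import label
from scipy.signal.windows import tukey

from sonoflex.materials import Material, WATER


class SamplingError(ValueError):
    """Grid too coarse for the highest requested frequency."""


@dataclass(frozen=True)
class FieldPlane:
    """Complex pressure sampled on a uniform x-y grid at height z.

    ``values`` has shape (n_freq, ny, nx); x is the lateral axis, y the
    elevation axis, z depth into the medium.
    """

    x: np.ndarray  # m, uniform
    y: np.ndarray  # m, uniform
    z: float  # m
    frequencies: np.ndarray  # Hz
    values: np.ndarray  # complex, (nf, ny, nx)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, float)
        y = np.asarray(self.y, float)
        f = np.atleast_1d(np.asarray(self.frequencies, float))
        v = np.asarray(self.values, complex)
        if v.ndim == 2:
            v = v[None, :, :]
        if v.shape != (len(f), len(y), len(x)):
            raise ValueError(
                f"values shape {v.shape} != (n_freq, ny, nx) = "
                f"({len(f)}, {len(y)}, {len(x)})"
            )
        for axis in (x, y):
            d = np.diff(axis)
            if len(d) and not np.allclose(d, d[0]):
                raise ValueError("sampling must be uniform")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "values", v)

    @property
    def dx(self) -> float:
        return float(self.x[1] - self.x[0])

    @property
    def dy(self) -> float:
        return float(self.y[1] - self.y[0])


def _check_sampling(plane: FieldPlane, medium: Material) -> None:
    lam_min = medium.wave_speed / float(np.max(plane.frequencies))
    if plane.dx > lam_min / 2 or plane.dy > lam_min / 2:
        raise SamplingError(
            f"grid spacing ({plane.dx:.2e}, {plane.dy:.2e}) m exceeds "
            f"lambda/2 = {lam_min / 2:.2e} m at the highest frequency"
        )


def angular_spectrum_propagate(
    plane: FieldPlane,
    dz: float,
    medium: Material = WATER,
    pad_factor: int = 2,
) -> FieldPlane:
    """Propagate a field plane over a signed distance ``dz``.

    ``dz > 0`` propagates away from the source (evanescent components decay);
    ``dz < 0`` backpropagates (evanescent components are zeroed).  Energy in
    the propagating band is conserved for a lossless medium.
    """
    _check_sampling(plane, medium)
    nf, ny, nx = plane.values.shape
    px, py = nx * (pad_factor - 1), ny * (pad_factor - 1)
    out = np.empty_like(plane.values)
    c = medium.wave_speed

    for i, f in enumerate(plane.frequencies):
        k = 2.0 * np.pi * f / c
        field = np.pad(plane.values[i], ((0, py), (0, px)))
        kx = 2.0 * np.pi * np.fft.fftfreq(field.shape[1], plane.dx)
        ky = 2.0 * np.pi * np.fft.fftfreq(field.shape[0], plane.dy)
        kx2 = kx[None, :] ** 2 + ky[:, None] ** 2
        spec = np.fft.fft2(field)
        kz = np.sqrt((k**2 - kx2).astype(complex))
        # branch: decay (not growth) for evanescent components, dz > 0
        kz = np.where(kz.imag > 0, -kz, kz)
        prop = kx2 <= k**2
        if dz >= 0:
            spec *= np.exp(-1j * kz * dz)
        else:
            spec = np.where(prop, spec * np.exp(-1j * kz.real * dz), 0.0)
        field = np.fft.ifft2(spec)
        out[i] = field[:ny, :nx]

    return replace(plane, z=plane.z + dz, values=out)


def surface_pressure_map(
    scan: FieldPlane,
    z_surface: float = 0.0,
    medium: Material = WATER,
    window_alpha: float | None = 0.25,
) -> FieldPlane:
    """Backpropagate a hydrophone scan plane to the transducer surface.

    An optional separable Tukey window (default alpha = 0.25) tapers the
    scan edges before the transform; pass ``window_alpha=None`` for synthetic
    data that is already compactly supported.  The magnitude of the returned
    plane is the per-position transmit efficiency map; the circular ripple
    around the aperture edge is an artifact of zeroing the evanescent
    spectrum on backpropagation.
    """
    if z_surface >= scan.z:
        raise ValueError("surface must lie below the scan plane (z_surface < scan.z)")
    values = scan.values
    if window_alpha is not None:
        wx = tukey(len(scan.x), window_alpha)
        wy = tukey(len(scan.y), window_alpha)
        values = values * wy[None, :, None] * wx[None, None, :]
        scan = replace(scan, values=values)
    return angular_spectrum_propagate(scan, z_surface - scan.z, medium)


def active_radius(
    surface: FieldPlane,
    threshold_db: float = -6.0,
    freq_index: int = 0,
) -> float:
    """Equivalent-circle radius of the active area of a surface map.

    The active area is the set of pixels whose magnitude exceeds the map
    peak by more than ``threshold_db`` (dB, negative).  It must be a single
    connected region; the radius of the circle with the same area is
    returned.
    """
    mag = np.abs(surface.values[freq_index])
    peak = mag.max()
    if peak == 0:
        raise ValueError("empty field: no active area")
    mask = mag >= peak * 10.0 ** (threshold_db / 20.0)
    if not mask.any():
        raise ValueError("no pixels above threshold")
    labelled, n = label(mask)
    if n != 1:
        raise ValueError(
            f"active region is not connected ({n} components above threshold)"
        )
    area = mask.sum() * surface.dx * surface.dy
    return float(np.sqrt(area / np.pi))
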