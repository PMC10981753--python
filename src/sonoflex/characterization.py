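"""Measurement-side computations.

Receive sensitivity from reciprocity
------------------------------------
A thickness-mode transducer is a reciprocal electro-acoustic two-port
between the electrical terminals and its radiating surface.  Writing the
two-port in impedance form and eliminating the internal parameters yields a
closed relation between three measurable quantities — the transmit transfer
``S_tx`` (surface pressure per volt under voltage drive), the electrical
input impedance ``Z_in`` (measured in the same load condition) and the
open-circuit receive sensitivity ``M_rx`` (volts per Pascal of incident
plane-wave pressure)::

    M_rx(f) = 2 * A * Z_in(f) * S_tx(f) / (rho * c)_load

with ``A`` the element area and ``(rho c)_load`` the specific acoustic
impedance of the loading medium.  The factor 2 is the pressure doubling of
the blocked force on the face.  No model parameters enter: this is how a
receive calibration is obtained from a hydrophone transmit scan plus an
impedance measurement.

Effective-property fitting
--------------------------
``fit_effective_properties`` recovers the piezo parameter set
``(k_t, a, b, c0, c1, tan_dm)`` from a measured air-loaded electrical
impedance spectrum by bounded least squares against the KLM model, with the
permittivity and dielectric-loss laws constrained to their linear-in-MHz
forms.  The objective combines the relative magnitude error and the phase
error in radians with equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from sonoflex.klm import (
    ImpedanceSpectrum,
    TransferFunction,
    electrical_impedance,
)
from sonoflex.materials import Material, PiezoMaterial, TransducerStack, pvdf_trfe


@dataclass(frozen=True)
class FittedProperties:
    """Piezo parameters recovered from an impedance spectrum."""

    k_t: float
    permittivity_law: tuple[float, float]
    dielectric_loss_law: tuple[float, float]
    mech_loss_tangent: float
    residual: float  # root-mean-square of the combined objective

    def as_piezo(self, template: PiezoMaterial) -> PiezoMaterial:
        """Materialise the fit onto a template (keeps density/speed/name)."""
        return PiezoMaterial(
            name=template.name,
            density=template.density,
            wave_speed=template.wave_speed,
            mech_loss_tangent=self.mech_loss_tangent,
            k_t=self.k_t,
            permittivity_law=self.permittivity_law,
            dielectric_loss_law=self.dielectric_loss_law,
            d33=template.d33,
        )


class FitFailureError(RuntimeError):
    """The impedance fit did not converge to a usable parameter set."""


def receive_from_reciprocity(
    tx: TransferFunction,
    z: ImpedanceSpectrum,
    element_area: float,
    load: Material,
) -> TransferFunction:
    """Open-circuit receive sensitivity from transmit transfer + impedance.

    ``tx`` must be in Pa/V and ``z`` measured in the same (load) condition;
    ``z`` is resampled onto the transmit grid when the grids differ.
    """
    if tx.unit != "Pa/V":
        raise ValueError(f"transmit transfer must be in Pa/V, got {tx.unit}")
    if element_area <= 0:
        raise ValueError("element_area must be positive")
    f = tx.frequencies
    zf = z.values
    if len(z.frequencies) != len(f) or not np.allclose(z.frequencies, f):
        if f[0] < z.frequencies[0] or f[-1] > z.frequencies[-1]:
            raise ValueError(
                "impedance spectrum does not cover the transmit grid"
            )
        zf = z.as_transfer().resample(f).values
    rc = load.density * load.wave_speed
    values = 2.0 * element_area * zf * tx.values / rc
    return TransferFunction(f, values, "V/Pa")


def pulse_echo_efficiency(tx_peak: float, rx_peak: float) -> float:
    """Dimensionless round-trip efficiency: peak Pa/V times peak V/Pa.

    Both arguments in SI units (Pa/V and V/Pa).  The paper-style headline
    figure is this value quoted to one significant digit.
    """
    if tx_peak <= 0 or rx_peak <= 0:
        raise ValueError("peaks must be positive")
    return tx_peak * rx_peak


_PARAM_NAMES = ("k_t", "perm_a", "perm_b", "loss_c0", "loss_c1", "tan_dm")
# physically sensible bounds for the polymer composite
_LOWER = np.array([0.01, 1.0, 0.0, 0.0, 0.0, 0.0])
_UPPER = np.array([0.6, 20.0, 0.1, 0.5, 0.2, 0.5])


def _spectrum_from_params(
    params: np.ndarray,
    geometry: TransducerStack,
    f: np.ndarray,
) -> np.ndarray:
    kt, a, b, c0, c1, tdm = params
    template: PiezoMaterial = geometry.piezo_layer.material  # type: ignore[assignment]
    piezo = PiezoMaterial(
        name=template.name,
        density=template.density,
        wave_speed=template.wave_speed,
        mech_loss_tangent=tdm,
        k_t=kt,
        permittivity_law=(a, b),
        dielectric_loss_law=(c0, c1),
    )
    layers = tuple(
        lay if i != geometry.piezo_index else type(lay)(piezo, lay.thickness)
        for i, lay in enumerate(geometry.layers)
    )
    stack = TransducerStack(
        layers, geometry.element_area, geometry.backing_medium,
        geometry.load_medium,
    )
    return electrical_impedance(stack, f).values


def _objective(params, geometry, f, z_meas):
    z_mod = _spectrum_from_params(params, geometry, f)
    rel_mag = (np.abs(z_mod) - np.abs(z_meas)) / np.abs(z_meas)
    dphase = np.angle(z_mod) - np.angle(z_meas)
    return np.concatenate([rel_mag, dphase])


def fit_effective_properties(
    z_air: ImpedanceSpectrum,
    geometry: TransducerStack,
    x0: FittedProperties | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    max_residual: float = 1.0,
) -> FittedProperties:
    """Least-squares recovery of the piezo parameter laws from an air-loaded
    impedance spectrum.

    ``geometry`` supplies everything except the piezo unknowns (thickness,
    area, wave speed, density, passive layers); its piezo layer material is
    used as the template whose mechanical constants are kept.  The optimiser
    is deterministic: a bounded trust-region start from ``x0`` (defaults to
    the nominal P(VDF-TrFE) values) followed by ``n_restarts`` jittered
    restarts drawn from a seeded generator; the best solution wins.

    Raises
    ------
    FitFailureError
        If no start converges, or the best residual exceeds
        ``max_residual`` (e.g. the spectrum does not cover the resonance and
        the parameters are unidentifiable).
    """
    if z_air.load != "air":
        raise ValueError("fitting is defined for air-loaded spectra")
    f = np.asarray(z_air.frequencies, dtype=float)
    z_meas = z_air.values

    # identifiability: the resonance dip must be inside the band.  |Z|*f is
    # flat for a pure capacitor, so its minimum marks the series resonance;
    # a minimum at the grid edge means the spectrum is truncated.
    flattened = np.abs(z_meas) * f
    if len(flattened) >= 9:  # smooth so noise cannot fake an edge minimum
        kernel = np.ones(9)
        counts = np.convolve(np.ones_like(flattened), kernel, mode="same")
        flattened = np.convolve(flattened, kernel, mode="same") / counts
    dip = int(np.argmin(flattened))
    if dip <= 1 or dip >= len(f) - 2:
        raise FitFailureError(
            "impedance spectrum does not cover the resonance; the piezo "
            "parameters are not identifiable"
        )

    if x0 is None:
        nominal = pvdf_trfe()
        start = np.array([
            nominal.k_t, *nominal.permittivity_law,
            *nominal.dielectric_loss_law, nominal.mech_loss_tangent,
        ])
    else:
        start = np.array([
            x0.k_t, *x0.permittivity_law, *x0.dielectric_loss_law,
            x0.mech_loss_tangent,
        ])

    rng = np.random.default_rng(seed)
    starts = [start]
    for _ in range(n_restarts):
        jitter = start * (1.0 + 0.2 * rng.standard_normal(start.size))
        starts.append(np.clip(jitter, _LOWER * 1.01, _UPPER * 0.99))

    best = None
    for s in starts:
        try:
            res = least_squares(
                _objective, s, bounds=(_LOWER, _UPPER),
                args=(geometry, f, z_meas), method="trf",
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res

    if best is None:
        raise FitFailureError("no optimiser start converged")
    rms = float(np.sqrt(2.0 * best.cost / len(best.fun)))
    if rms > max_residual:
        raise FitFailureError(
            f"fit residual {rms:.3g} exceeds {max_residual}: spectrum likely "
            "does not constrain the parameters (e.g. resonance not covered)"
        )
    kt, a, b, c0, c1, tdm = best.x
    return FittedProperties(
        k_t=float(kt),
        permittivity_law=(float(a), float(b)),
        dielectric_loss_law=(float(c0), float(c1)),
        mech_loss_tangent=float(tdm),
        residual=rms,
    )
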