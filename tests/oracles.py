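"""Independent reference implementations used only as test oracles.

The piezo plate is evaluated through its exact 1-D three-port impedance
matrix (the Mason description): with face velocities u1, u2 flowing into the
plate and current I into the electrical port,

    F1 = Z0/(j tan kd) u1 + Z0/(j sin kd) u2 + h/(jw) I
    F2 = Z0/(j sin kd) u1 + Z0/(j tan kd) u2 + h/(jw) I
    V  = h/(jw) (u1 + u2) + I/(jw C0)

terminated by the back/front layer chains.  This is solved per frequency as
a dense linear system — a deliberately different route from the package's
KLM network algebra.
"""

import numpy as np

EPS0 = 8.8541878128e-12


def _chain_to_medium(layers, medium, f, area):
    """Input impedance through passive layers into a semi-infinite medium."""
    z = medium.density * medium.complex_wave_speed * area
    for lay in layers:
        c = lay.material.complex_wave_speed
        z0 = lay.material.density * c * area
        kd = 2 * np.pi * f / c * lay.thickness
        z = z0 * (z + 1j * z0 * np.tan(kd)) / (z0 + 1j * z * np.tan(kd))
    return z


def mason_solve(stack, frequencies):
    """Impedance, transmit and receive spectra of a stack via the Mason
    three-port, solved frequency by frequency.

    Only supports stacks without passive layers on the *front* side (all the
    stacks used in the oracle comparisons), so the front face pressure is the
    surface pressure.
    """
    assert len(stack.front_layers) == 0
    area = stack.element_area
    piezo_layer = stack.piezo_layer
    piezo = piezo_layer.material
    d = piezo_layer.thickness

    zin = np.empty(len(frequencies), complex)
    tx = np.empty(len(frequencies), complex)
    rx = np.empty(len(frequencies), complex)
    for n, f in enumerate(np.asarray(frequencies, float)):
        w = 2 * np.pi * f
        c = piezo.complex_wave_speed
        rho = piezo.density
        eps = piezo.complex_permittivity(f)
        k = w / c
        z0 = rho * c * area
        c0 = eps * area / d
        h = piezo.k_t * np.sqrt(rho * c**2 / eps)
        kd = k * d
        z11 = z0 / (1j * np.tan(kd))
        z12 = z0 / (1j * np.sin(kd))
        zb = _chain_to_medium(stack.back_layers, stack.backing_medium, f, area)
        zf = stack.load_medium.density * stack.load_medium.complex_wave_speed * area
        hw = h / (1j * w)
        m = np.array(
            [
                [z11 + zb, z12, hw],
                [z12, z11 + zf, hw],
                [hw, hw, 1.0 / (1j * w * c0)],
            ]
        )
        # transmit: V = 1 across the electrical port
        u1, u2, cur = np.linalg.solve(m, [0.0, 0.0, 1.0])
        zin[n] = 1.0 / cur
        tx[n] = -zf * u2 / area
        # receive: open circuit, blocked-force source 2*p*A behind Z_F
        m2 = np.array([[z11 + zb, z12], [z12, z11 + zf]])
        v1, v2 = np.linalg.solve(m2, [0.0, 2.0 * 1.0 * area])
        rx[n] = hw * (v1 + v2)
    return zin, tx, rx


def piston_on_axis(radius, z, frequency, medium):
    """Exact on-axis pressure magnitude of a disc with uniform unit
    *pressure* on the source plane (Dirichlet data, Rayleigh integral of the
    second kind): |exp(-jkz) - (z/R_a) exp(-jkR_a)| with R_a = sqrt(z^2+a^2).
    """
    k = 2 * np.pi * frequency / medium.wave_speed
    ra = np.sqrt(z**2 + radius**2)
    return np.abs(np.exp(-1j * k * z) - (z / ra) * np.exp(-1j * k * ra))
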