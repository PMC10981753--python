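import numpy as np
import pytest
from hypothesis import given, strategies as st

from oracles import mason_solve

from sonoflex import klm
from sonoflex.materials import (
    AIR,
    EPS0,
    OIL,
    WATER,
    CircularElement,
    Layer,
    Material,
    TransducerStack,
    pvdf_trfe,
)


def make_stack(k_t=0.185, tan_dm=0.125, thickness=None, load=WATER,
               element_area=None, substrate=True):
    piezo = pvdf_trfe(k_t=k_t, mech_loss_tangent=tan_dm)
    layers = []
    if substrate:
        layers.append(Layer(Material("polyimide", 1420.0, 2200.0), 14e-6))
    layers.append(
        Layer(
            piezo,
            thickness if thickness is not None
            else klm.effective_pillar_thickness(),
        )
    )
    return TransducerStack(
        layers=tuple(layers),
        element_area=element_area or CircularElement(6e-3).area,
        backing_medium=AIR,
        load_medium=load,
    )


# ---------------------------------------------------------------------------
# clamped capacitance


def test_clamped_capacitance_low_frequency_limit():
    stack = make_stack(thickness=80e-6)
    area = stack.element_area
    c0 = klm.clamped_capacitance(stack, 1.0)  # ~DC
    assert c0.real == pytest.approx(6.5 * EPS0 * area / 80e-6, rel=1e-4)


def test_clamped_capacitance_direct_formula_and_linearity():
    stack = make_stack(thickness=80e-6)
    f = 8.6e6
    k = 6.5 - 0.0088 * 8.6
    tde = 0.075 + 0.04 * 8.6
    expected = k * EPS0 * stack.element_area / 80e-6 * (1 - 1j * tde)
    assert klm.clamped_capacitance(stack, f) == pytest.approx(expected, rel=1e-12)
    double = make_stack(thickness=80e-6, element_area=2 * stack.element_area)
    assert klm.clamped_capacitance(double, f) == pytest.approx(2 * expected, rel=1e-12)


# ---------------------------------------------------------------------------
# electrical impedance


def test_kt_to_zero_reduces_to_lossy_capacitor(grid):
    stack = make_stack(k_t=1e-8)
    z = klm.electrical_impedance(stack, grid)
    c0 = klm.clamped_capacitance(stack, grid)
    z_cap = 1.0 / (1j * 2 * np.pi * grid * c0)
    assert np.max(np.abs(np.abs(z.values) - np.abs(z_cap)) / np.abs(z_cap)) < 1e-3


def test_mason_model_equivalence(grid):
    """The KLM network must agree with the independent three-port solve."""
    stack = make_stack()
    f = grid[::16]
    z = klm.electrical_impedance(stack, f)
    tx = klm.transmit_transfer(stack, f)
    rx = klm.receive_transfer_direct(stack, f)
    zin_o, tx_o, rx_o = mason_solve(stack, f)
    assert np.max(np.abs(z.values - zin_o) / np.abs(zin_o)) < 5e-3
    assert np.max(np.abs(np.abs(tx.values) - np.abs(tx_o)) / np.max(np.abs(tx_o))) < 5e-3
    assert np.max(np.abs(np.abs(rx.values) - np.abs(rx_o)) / np.max(np.abs(rx_o))) < 5e-3


def test_oil_load_smooths_resonance_ripple(grid):
    """A liquid front load damps the resonance relative to air (quality
    factor of the impedance dip drops)."""
    stack = make_stack()
    z_air = np.abs(klm.electrical_impedance(stack, grid, load=AIR).values)
    z_oil = np.abs(klm.electrical_impedance(stack, grid, load=OIL).values)
    # ripple metric: peak-to-trough excursion of |Z| * f (capacitor-flattened)
    def ripple(mag):
        flat = mag * grid
        return (flat.max() - flat.min()) / flat.mean()

    assert ripple(z_oil) < ripple(z_air)


@given(
    k_t=st.floats(0.05, 0.5),
    tan_dm=st.floats(0.0, 0.4),
    thickness=st.floats(40e-6, 200e-6),
)
def test_passivity(k_t, tan_dm, thickness):
    """Re(Z) >= 0 over the band for any physical parameter set."""
    stack = make_stack(k_t=k_t, tan_dm=tan_dm, thickness=thickness)
    f = np.linspace(0.5e6, 15e6, 200)
    z = klm.electrical_impedance(stack, f)
    assert np.all(z.values.real >= -1e-9 * np.abs(z.values))


def test_rejects_bad_stacks():
    with pytest.raises(Exception):
        make_stack(thickness=0.0)
    with pytest.raises(Exception):
        make_stack(k_t=0.0)


# ---------------------------------------------------------------------------
# transmit / receive


def test_transmit_linearity_zero_drive(ref_transmit):
    """0 V drive gives 0 Pa: the transfer itself is the per-volt response."""
    assert np.all(np.isfinite(ref_transmit.values))
    assert np.all(0.0 * ref_transmit.values == 0.0)


def test_transmit_peak_of_reference_design(ref_transmit):
    bm = klm.band_metrics(ref_transmit)
    assert bm.peak_frequency == pytest.approx(8.6e6, abs=0.2e6)
    assert bm.peak_value == pytest.approx(1.5e3, rel=0.10)
    assert bm.fractional_bandwidth == pytest.approx(58.0, abs=5.0)


def test_matched_load_beats_lighter_mismatched_load(grid):
    """Surface pressure per volt at resonance into a matched load exceeds
    that into a 10x lower-impedance load.  (A 10x *heavier* load trivially
    shows more face pressure, p = Z u, so the comparison is made on the
    low-impedance side.)"""
    piezo = pvdf_trfe()
    matched = Material("matched", piezo.density, piezo.wave_speed)
    mismatched = Material("mismatched", piezo.density / 10.0, piezo.wave_speed)
    tx_m = klm.transmit_transfer(make_stack(load=matched), grid)
    tx_x = klm.transmit_transfer(make_stack(load=mismatched), grid)
    f_res = klm.band_metrics(tx_m).peak_frequency
    i = int(np.argmin(np.abs(grid - f_res)))
    assert np.abs(tx_m.values[i]) > np.abs(tx_x.values[i])


def test_receive_scales_with_kt(grid):
    rx1 = klm.receive_transfer_direct(make_stack(k_t=0.1), grid)
    rx2 = klm.receive_transfer_direct(make_stack(k_t=0.101), grid)
    ratio = np.abs(rx2.values).max() / np.abs(rx1.values).max()
    assert ratio == pytest.approx(1.01, abs=3e-3)  # ~linear in k_t
    rx0 = klm.receive_transfer_direct(make_stack(k_t=1e-9), grid)
    assert np.abs(rx0.values).max() < 1e-6 * np.abs(rx1.values).max()


def test_reciprocity_closure(ref_stack, grid):
    """Direct KLM receive equals the reciprocity-derived receive to <1%
    across the -6 dB transmit band."""
    from sonoflex.characterization import receive_from_reciprocity

    tx = klm.transmit_transfer(ref_stack, grid)
    z = klm.electrical_impedance(ref_stack, grid)
    rx_direct = klm.receive_transfer_direct(ref_stack, grid)
    rx_rec = receive_from_reciprocity(
        tx, z, ref_stack.element_area, ref_stack.load_medium
    )
    bm = klm.band_metrics(tx)
    band = (grid >= bm.f_low) & (grid <= bm.f_high)
    err = np.abs(rx_rec.values - rx_direct.values)[band] / np.abs(
        rx_direct.values
    )[band]
    assert err.max() < 0.01


# ---------------------------------------------------------------------------
# band metrics


def test_band_metrics_gaussian_closed_form():
    f = np.linspace(1e6, 15e6, 4001)
    sigma = 2e6 / np.sqrt(2 * np.log(2))  # half-amplitude at +-2 MHz
    mag = np.exp(-((f - 8e6) ** 2) / (2 * sigma**2))
    tf = klm.TransferFunction(f, mag.astype(complex), "Pa/V")
    bm = klm.band_metrics(tf)
    assert bm.f_low == pytest.approx(6e6, rel=1e-3)
    assert bm.f_high == pytest.approx(10e6, rel=1e-3)
    assert bm.fractional_bandwidth == pytest.approx(50.0, abs=0.2)


def test_band_metrics_flat_spectrum_errors():
    f = np.linspace(1e6, 15e6, 100)
    tf = klm.TransferFunction(f, np.ones_like(f, dtype=complex), "Pa/V")
    with pytest.raises(klm.TruncatedBandError):
        klm.band_metrics(tf)


# ---------------------------------------------------------------------------
# insertion loss


def test_insertion_loss_reference_and_monotonicity(ref_stack, grid):
    il = klm.pulse_echo_insertion_loss(ref_stack, grid)
    assert il == pytest.approx(-20.4, abs=1.5)
    assert il < 0
    il_lossier = klm.pulse_echo_insertion_loss(make_stack(tan_dm=0.25), grid)
    assert il_lossier < il
    # lossless dielectric + mechanics: strictly less loss
    piezo_ll = pvdf_trfe(mech_loss_tangent=1e-6,
                         dielectric_loss_law=(0.0, 0.0))
    stack_ll = TransducerStack(
        (Layer(piezo_ll, klm.effective_pillar_thickness()),),
        CircularElement(6e-3).area, AIR, WATER,
    )
    assert klm.pulse_echo_insertion_loss(stack_ll, grid) > il


# ---------------------------------------------------------------------------
# matching network


def test_matching_network_identity(ref_stack, grid, ref_transmit):
    tuned = klm.apply_matching_network(ref_stack, klm.MatchingNetwork(), grid)
    assert np.allclose(tuned.values, ref_transmit.values)


def test_series_inductor_boosts_peak(ref_stack, grid, ref_transmit):
    bm0 = klm.band_metrics(ref_transmit)
    c0 = abs(klm.clamped_capacitance(ref_stack, bm0.peak_frequency))
    l_res = 1.0 / ((2 * np.pi * bm0.peak_frequency) ** 2 * c0)
    tuned = klm.apply_matching_network(
        ref_stack, klm.MatchingNetwork(series_inductance=l_res), grid
    )
    assert klm.band_metrics(tuned).peak_value > bm0.peak_value
    # an extreme inductor drags the peak away from the mechanical resonance
    extreme = klm.apply_matching_network(
        ref_stack, klm.MatchingNetwork(series_inductance=50 * l_res), grid
    )
    assert abs(klm.band_metrics(extreme).peak_frequency - bm0.peak_frequency) > 1e6
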