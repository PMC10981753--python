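import numpy as np
import pytest

from sonoflex.imaging import (
    BModeImage,
    ComplexImage,
    PlaneWaveEvent,
    RFFrame,
    das_pwc,
    envelope_logcompress,
    fk_filter,
    matched_filter,
    peak_location,
    preprocess,
    psf_metrics,
    stolt_migrate,
)
from sonoflex.synthetic import ArrayGeometry, ChirpPulse, ScattererSet, gen_wire_phantom_rf

FS = 62.5e6
PULSE = ChirpPulse()  # 3-12 MHz
GEOM = ArrayGeometry()  # 64 elements, 180 um pitch
LAMBDA_C = GEOM.sound_speed / PULSE.center_frequency


def single_scatterer_frames(angles=None, x=0.0, z=20e-3, snr_db=None, seed=0):
    sc = ScattererSet(x=[x], z=[z])
    frames = gen_wire_phantom_rf(sc, GEOM, PULSE, angles=angles,
                                 sample_rate=FS, max_depth=32e-3,
                                 snr_db=snr_db, seed=seed)
    replica = PULSE.waveform(FS)
    return [preprocess(f, replica=replica) for f in frames]


# ---------------------------------------------------------------------------
# preprocessing


def test_matched_filter_peaks_at_true_delay():
    replica = PULSE.waveform(FS)
    n = 4000
    delay_samples = 1507
    t = (np.arange(n) - delay_samples) / FS
    rng = np.random.default_rng(0)
    trace = PULSE.sample(t) + 0.05 * rng.standard_normal(n)
    out = matched_filter(trace[None, :], replica)[0]
    assert abs(int(np.argmax(np.abs(out))) - delay_samples) <= 1
    # unit echo compresses to ~unit peak (normalised correlation)
    assert np.abs(out).max() == pytest.approx(1.0, rel=0.1)


def test_matched_filter_resolves_echoes_two_over_bandwidth_apart():
    replica = PULSE.waveform(FS)
    sep = int(round(2.0 / PULSE.bandwidth * FS))  # 2/B
    n = 4000
    t = np.arange(n) / FS
    trace = PULSE.sample(t - 1000 / FS) + PULSE.sample(t - (1000 + sep) / FS)
    out = np.abs(matched_filter(trace[None, :], replica)[0])
    p1 = 1000 + np.argmax(out[1000 - sep // 2: 1000 + sep // 2]) - sep // 2
    p2 = 1000 + sep + np.argmax(out[1000 + sep // 2: 1000 + 3 * sep // 2]) - sep // 2
    assert abs(p1 - 1000) <= 2 and abs(p2 - (1000 + sep)) <= 2
    trough = out[(p1 + p2) // 2]
    assert trough < 0.7 * min(out[p1], out[p2])


def test_preprocess_removes_dc():
    data = 3.7 * np.ones((4, 256))
    frame = RFFrame(data=data, sample_rate=FS, element_x=np.arange(4) * 180e-6)
    out = preprocess(frame)
    assert np.allclose(out.data, 0.0)


def test_matched_filter_rejects_long_replica():
    with pytest.raises(ValueError):
        matched_filter(np.zeros((1, 10)), np.zeros(11))


# ---------------------------------------------------------------------------
# DAS


def test_das_focuses_single_scatterer():
    frames = single_scatterer_frames()
    x = np.linspace(-3e-3, 3e-3, 61)
    z = np.linspace(17e-3, 23e-3, 121)
    img = das_pwc(frames, x, z)
    px, pz = peak_location(img)
    assert abs(px - 0.0) < 0.1e-3
    assert abs(pz - 20e-3) < 0.1e-3


def test_das_zero_rf_gives_zero_image():
    frames = single_scatterer_frames(angles=np.array([0.0]))
    zero = [RFFrame(0.0 * f.data, f.sample_rate, f.element_x, f.transmit,
                    f.t0, f.sound_speed) for f in frames]
    img = das_pwc(zero, np.linspace(-2e-3, 2e-3, 21), np.linspace(18e-3, 22e-3, 41))
    assert np.allclose(img.values, 0.0)


def test_das_linearity():
    frames = single_scatterer_frames(angles=np.array([0.0]))
    x = np.linspace(-2e-3, 2e-3, 41)
    z = np.linspace(18e-3, 22e-3, 81)
    img1 = das_pwc(frames, x, z)
    scaled = [RFFrame(2.5 * f.data, f.sample_rate, f.element_x, f.transmit,
                      f.t0, f.sound_speed) for f in frames]
    img2 = das_pwc(scaled, x, z)
    assert np.allclose(img2.values, 2.5 * img1.values, rtol=1e-10)


def test_compounding_reduces_sidelobes():
    """Coherent compounding over nine angles lowers the side-lobe level of a
    point target relative to a single transmission."""
    frames9 = single_scatterer_frames()
    x = np.linspace(-5e-3, 5e-3, 101)
    z = np.linspace(18e-3, 22e-3, 81)

    def sidelobe_db(img):
        env = np.abs(img.values)
        peak = env.max()
        mainlobe = (np.abs(img.x[None, :]) < 1.2e-3)
        side = np.where(np.broadcast_to(mainlobe, env.shape), 0.0, env)
        return 20 * np.log10(side.max() / peak)

    img9 = das_pwc(frames9, x, z)
    img1 = das_pwc(frames9[4:5], x, z)  # normal incidence only
    assert sidelobe_db(img9) < sidelobe_db(img1)


def test_das_resolution_scales_with_depth_over_aperture():
    """With the receive aperture clipped by the array extent, the -6 dB
    lateral width grows proportionally to depth (within 15% over 2x).

    Single normal-incidence transmit and boxcar apodization: compounded
    steering adds a depth-independent transmit-aperture term and the Hann
    taper reshapes the clipped aperture with depth, both of which break the
    proportionality on purpose."""
    widths = []
    for depth in (15e-3, 30e-3):
        sc = ScattererSet(x=[0.0], z=[depth])
        frames = gen_wire_phantom_rf(sc, GEOM, PULSE, angles=np.array([0.0]),
                                     sample_rate=FS, max_depth=depth + 8e-3)
        frames = [preprocess(f, replica=PULSE.waveform(FS)) for f in frames]
        x = np.linspace(-4e-3, 4e-3, 161)
        z = np.linspace(depth - 3e-3, depth + 3e-3, 121)
        img = das_pwc(frames, x, z, apodization="none")
        bm = envelope_logcompress(img, 60.0)
        widths.append(psf_metrics(bm, (0.0, depth)).lateral_width_6db)
    ratio = widths[1] / widths[0]
    assert ratio == pytest.approx(2.0, rel=0.15)


# ---------------------------------------------------------------------------
# Stolt


def test_stolt_agrees_with_das_on_point_target():
    frames = single_scatterer_frames(angles=np.array([0.0]), x=0.5e-3)
    x = np.linspace(-2e-3, 3e-3, 101)
    z = np.linspace(18e-3, 22e-3, 161)
    img_das = das_pwc(frames, x, z)
    img_stolt = stolt_migrate(frames[0])
    p_das = peak_location(img_das)
    p_stolt = peak_location(img_stolt)
    assert abs(p_das[0] - p_stolt[0]) < LAMBDA_C / 4
    assert abs(p_das[1] - p_stolt[1]) < LAMBDA_C / 4


def test_stolt_zero_input():
    frames = single_scatterer_frames(angles=np.array([0.0]))
    zero = RFFrame(0.0 * frames[0].data, FS, frames[0].element_x,
                   PlaneWaveEvent(0.0))
    img = stolt_migrate(zero)
    assert np.allclose(img.values, 0.0)


def test_stolt_recovers_two_depths():
    sc = ScattererSet(x=[-2e-3, 2e-3], z=[15e-3, 25e-3])
    frames = gen_wire_phantom_rf(sc, GEOM, PULSE, angles=np.array([0.0]),
                                 sample_rate=FS, max_depth=32e-3)
    frame = preprocess(frames[0], replica=PULSE.waveform(FS))
    img = stolt_migrate(frame)
    env = np.abs(img.values)
    for xs, zs in [(-2e-3, 15e-3), (2e-3, 25e-3)]:
        win = ((np.abs(img.z[:, None] - zs) < 2e-3)
               & (np.abs(img.x[None, :] - xs) < 2e-3))
        local = np.where(win, env, 0.0)
        iz, ix = np.unravel_index(np.argmax(local), local.shape)
        assert abs(img.z[iz] - zs) < LAMBDA_C / 2


def test_stolt_rejects_steered_frames():
    frames = single_scatterer_frames(angles=np.array([np.deg2rad(8.0)]))
    with pytest.raises(ValueError):
        stolt_migrate(frames[0])


# ---------------------------------------------------------------------------
# f-k filter


def _plane_component(speed_lateral, f0=2e6, n=(64, 1024)):
    """Channel data of a component sweeping laterally at a given speed.

    The frequency is kept low enough that kx = 2 pi f / v stays below the
    lateral Nyquist of the 180 um pitch.
    """
    nx, nt = n
    t = np.arange(nt) / FS
    x = np.arange(nx) * GEOM.pitch
    return np.cos(2 * np.pi * f0 * (t[None, :] - x[:, None] / speed_lateral))


def test_fk_filter_passes_normal_incidence():
    sc = ScattererSet(x=[0.0], z=[20e-3])
    frames = gen_wire_phantom_rf(sc, GEOM, PULSE, angles=np.array([0.0]),
                                 sample_rate=FS, max_depth=30e-3)
    frame = frames[0]
    out = fk_filter(frame, cutoff_speed=2000.0)
    num = np.linalg.norm(out.data - frame.data)
    den = np.linalg.norm(frame.data)
    assert num / den < 0.01


def test_fk_filter_rejects_slow_lateral_artifact():
    slow = _plane_component(800.0)  # well inside the stop band
    frame = RFFrame(slow, FS, GEOM.element_x, PlaneWaveEvent(0.0))
    out = fk_filter(frame, cutoff_speed=3000.0)
    rejection_db = 20 * np.log10(
        np.linalg.norm(out.data) / np.linalg.norm(frame.data)
    )
    assert rejection_db < -20.0


def test_fk_filter_idempotent():
    rng = np.random.default_rng(1)
    frame = RFFrame(rng.standard_normal((64, 512)), FS, GEOM.element_x)
    once = fk_filter(frame, cutoff_speed=1540.0)
    twice = fk_filter(once, cutoff_speed=1540.0)
    num = np.linalg.norm(twice.data - once.data)
    den = np.linalg.norm(once.data)
    assert num / den < 0.05


def test_fk_filter_warns_when_all_energy_removed():
    # pure lateral-Nyquist component: no kx = 0 content survives the mask
    t = np.arange(512) / FS
    alt = np.outer((-1.0) ** np.arange(64), np.cos(2 * np.pi * 7.8125e6 * t))
    frame = RFFrame(alt, FS, GEOM.element_x)
    with pytest.warns(UserWarning):
        fk_filter(frame, cutoff_speed=50000.0, taper=0.01)


# ---------------------------------------------------------------------------
# envelope & PSF


# a carrier with an integer number of cycles keeps the FFT-based analytic
# signal exact (no leakage at the trace ends)
F_PERIODIC = FS * 64 / 512


def test_envelope_of_tone_is_flat():
    z = np.arange(512) / FS
    tone = np.cos(2 * np.pi * F_PERIODIC * z)
    img = np.tile(tone[:, None], (1, 4))
    bm = envelope_logcompress(img, 40.0)
    assert np.max(np.abs(bm.values_db)) < 0.01  # flat 0 dB everywhere


def test_envelope_half_amplitude_is_minus_6db():
    z = np.arange(512) / FS
    tone = np.cos(2 * np.pi * F_PERIODIC * z)
    img = np.stack([tone, 0.5 * tone], axis=1)
    bm = envelope_logcompress(img, 40.0)
    assert np.median(bm.values_db[:, 1]) == pytest.approx(-6.02, abs=0.05)


def test_envelope_tracks_am_ramp():
    z = np.arange(2048) / FS
    ramp = np.linspace(0.2, 1.0, len(z))
    sig = ramp * np.cos(2 * np.pi * FS * 256 / 2048 * z)
    bm = envelope_logcompress(sig[:, None], 40.0)
    expected = 20 * np.log10(ramp / ramp.max())
    # the edge transient sets the normalisation, so compare up to a constant
    diff = bm.values_db[200:-200, 0] - expected[200:-200]
    assert abs(diff.mean()) < 1.0
    assert np.max(np.abs(diff - diff.mean())) < 0.15


def test_envelope_rejects_all_zero():
    with pytest.raises(ValueError):
        envelope_logcompress(np.zeros((16, 16)), 40.0)


def test_psf_metrics_gaussian_closed_form():
    x = np.linspace(-5e-3, 5e-3, 401)
    z = np.linspace(15e-3, 25e-3, 401)
    sx, sz = 0.27e-3, 0.1e-3
    env = np.exp(-((x[None, :]) ** 2) / (2 * sx**2)
                 - ((z[:, None] - 20e-3) ** 2) / (2 * sz**2))
    img = ComplexImage(x=x, z=z, values=env.astype(complex))
    bm = envelope_logcompress(img, 60.0)
    m = psf_metrics(bm, (0.0, 20e-3))
    w6 = 2 * sx * np.sqrt(2 * np.log(10 ** (6 / 20)))
    w20 = 2 * sx * np.sqrt(2 * np.log(10 ** (20 / 20)))
    assert m.lateral_width_6db == pytest.approx(w6, rel=0.02)
    assert m.lateral_width_20db == pytest.approx(w20, rel=0.02)
    assert m.lateral_width_20db >= m.lateral_width_6db
    assert m.axial_length_20db >= m.axial_length_6db


def test_full_chain_psf_plausibility():
    """Full simulation (11.5 mm aperture, 3-12 MHz chirp, wire at 20 mm):
    the -6 dB lateral width should land in the 0.3-1.0 mm range expected of
    this aperture and band."""
    frames = single_scatterer_frames(snr_db=40.0, seed=7)
    x = np.linspace(-3e-3, 3e-3, 121)
    z = np.linspace(18e-3, 22e-3, 161)
    img = das_pwc(frames, x, z)
    bm = envelope_logcompress(img, 60.0)
    m = psf_metrics(bm, (0.0, 20e-3))
    assert 0.3e-3 < m.lateral_width_6db < 1.0e-3
    assert m.axial_length_6db < 0.5e-3


def test_chain_linearity_up_to_log_compression():
    """Scaling the RF shifts the log-compressed image uniformly (here: the
    normalised B-mode is invariant, envelope scales linearly)."""
    frames = single_scatterer_frames(angles=np.array([0.0]))
    x = np.linspace(-2e-3, 2e-3, 41)
    z = np.linspace(18e-3, 22e-3, 81)
    img = das_pwc(frames, x, z)
    scaled = [RFFrame(0.1 * f.data, f.sample_rate, f.element_x, f.transmit,
                      f.t0, f.sound_speed) for f in frames]
    img_s = das_pwc(scaled, x, z)
    b1 = envelope_logcompress(img, 60.0)
    b2 = envelope_logcompress(img_s, 60.0)
    assert np.allclose(b1.values_db, b2.values_db, atol=1e-9)
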