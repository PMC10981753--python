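"""Vessel-wall tracking and distension-to-pressure conversion.

Wall tracking
-------------
Repeated single-line (M-mode) RF acquisitions show two dominant echoes: the
anterior and posterior walls of the vessel.  Within a depth gate around each
wall, consecutive frames are cross-correlated; the correlation peak plus
parabolic sub-sample refinement gives the inter-frame delay, which is
integrated to a cumulative wall displacement.  Each gate is re-centred on the
running estimate so the echo never leaves the window.  Frames whose peak
correlation coefficient falls below a threshold are flagged and their
inter-frame displacement linearly interpolated from their neighbours.
Adjacent-frame (rather than fixed-reference) correlation is used: it is
robust to slow waveform shape changes at the cost of a random-walk error
floor, negligible over a few cardiac cycles.

Pressure model
--------------
The arterial wall is described by the exponential single-parameter law

    p(t) = p_d * exp( alpha * (A(t) / A_d - 1) ),

with ``p_d`` the diastolic pressure, ``A_d`` the diastolic lumen area and
``alpha`` the dimensionless wall-stiffness coefficient.  The lumen is assumed
circular, so ``A ∝ D^2`` with ``D`` the tracked diameter.  ``alpha`` is
calibrated in closed form from a reference diastolic/systolic pressure pair:

    alpha = ln(p_s / p_d) / (A_s / A_d - 1).

By construction, the converted waveform returns ``p_d`` at the diastolic
(minimum) diameter and ``p_s`` at the systolic (maximum) diameter exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from sonoflex.imaging import RFFrame


@dataclass(frozen=True)
class VesselTrack:
    """Per-frame wall depths (m) on a PRF-spaced time axis (s)."""

    times: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    flagged: np.ndarray | None = None  # bool per frame, low-correlation

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        a = np.asarray(self.anterior, float)
        p = np.asarray(self.posterior, float)
        if not (len(t) == len(a) == len(p)):
            raise ValueError("times, anterior and posterior must share length")
        if np.any(p - a <= 0):
            raise ValueError("posterior wall must stay below the anterior wall")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "anterior", a)
        object.__setattr__(self, "posterior", p)

    @property
    def diameter(self) -> np.ndarray:
        return self.posterior - self.anterior


@dataclass(frozen=True)
class PressureModel:
    """Exponential pressure-area law p = p_d exp(alpha (A/A_d - 1))."""

    p_d: float  # diastolic pressure (any consistent unit, e.g. mmHg)
    alpha: float  # dimensionless stiffness
    A_d: float  # diastolic lumen area, m^2

    def __post_init__(self) -> None:
        if self.p_d <= 0 or self.alpha <= 0 or self.A_d <= 0:
            raise ValueError("p_d, alpha and A_d must be positive")

    def pressure(self, area: np.ndarray | float) -> np.ndarray | float:
        return self.p_d * np.exp(self.alpha * (np.asarray(area) / self.A_d - 1.0))

    def area(self, pressure: np.ndarray | float) -> np.ndarray | float:
        """Inverse law: lumen area at a given pressure."""
        return self.A_d * (1.0 + np.log(np.asarray(pressure) / self.p_d) / self.alpha)


def _subsample_peak(corr: np.ndarray, i: int) -> float:
    """Parabolic interpolation of a correlation peak position."""
    if i <= 0 or i >= len(corr) - 1:
        return float(i)
    y0, y1, y2 = corr[i - 1], corr[i], corr[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * (y0 - y2) / denom


def _normalized_xcorr(a: np.ndarray, b: np.ndarray, max_lag: int):
    """Normalized cross-correlation of b against a for lags in
    [-max_lag, max_lag]; returns (lags, coefficients)."""
    a = a - a.mean()
    lags = np.arange(-max_lag, max_lag + 1)
    coeffs = np.empty(len(lags))
    n = len(a)
    for k, lag in enumerate(lags):
        seg = b[max_lag + lag: max_lag + lag + n]
        seg = seg - seg.mean()
        denom = math.sqrt(float(np.dot(a, a)) * float(np.dot(seg, seg)))
        coeffs[k] = float(np.dot(a, seg)) / denom if denom > 0 else 0.0
    return lags, coeffs


def _locate_echo(trace: np.ndarray, lo: int, hi: int) -> int:
    """Envelope-peak sample index of the dominant echo inside a gate."""
    env = np.abs(hilbert(trace))
    return lo + int(np.argmax(env[lo:hi]))


def track_walls(
    frames: list[RFFrame],
    gates: tuple[tuple[float, float], tuple[float, float]],
    prf: float,
    gate_halfwidth: float = 0.4e-3,
    max_shift_samples: int = 16,
    corr_threshold: float = 0.7,
) -> VesselTrack:
    """Track the anterior and posterior wall echoes across M-mode frames.

    Parameters
    ----------
    frames : list of single-channel RFFrame, one per pulse
    gates : two (z_min, z_max) depth windows (m) that each contain one
        dominant wall echo in the first frame; the walls are located at the
        envelope peak inside each gate and tracked from there.
    prf : pulse repetition frequency, Hz.
    gate_halfwidth : half-width (m) of the correlation kernel around the
        running wall position.
    max_shift_samples : correlation search range per frame pair.
    corr_threshold : frames whose peak normalized correlation falls below
        this are flagged and their displacement interpolated.
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames to track")
    fs = frames[0].sample_rate
    c = frames[0].sound_speed
    t0 = frames[0].t0
    n = frames[0].n_samples
    traces = np.stack([f.data[0] for f in frames])
    n_frames = len(frames)

    def depth_to_sample(z: float) -> int:
        return int(round((2.0 * z / c - t0) * fs))

    half = max(4, int(round(2.0 * gate_halfwidth / c * fs)))
    walls = []
    flags = np.zeros(n_frames, dtype=bool)

    for z_lo, z_hi in gates:
        i0 = _locate_echo(traces[0], depth_to_sample(z_lo), depth_to_sample(z_hi))
        z_echo0 = (i0 / fs + t0) * c / 2.0
        disp = np.zeros(n_frames)  # cumulative displacement in samples
        step = np.zeros(n_frames)
        centre = i0
        for j in range(1, n_frames):
            lo = max(centre - half, 0)
            hi = min(centre + half, n)
            ref = traces[j - 1][lo:hi]
            pad = max_shift_samples
            blo, bhi = lo - pad, hi + pad
            if blo < 0 or bhi > n:
                raise ValueError("gate drifted outside the trace")
            search = traces[j][blo:bhi]
            lags, coeffs = _normalized_xcorr(ref, search, pad)
            ipk = int(np.argmax(coeffs))
            if coeffs[ipk] < corr_threshold:
                flags[j] = True
                step[j] = np.nan
            else:
                step[j] = lags[0] + _subsample_peak(coeffs, ipk)
            if not np.isnan(step[j]):
                disp[j] = disp[j - 1] + step[j]
            else:
                disp[j] = disp[j - 1]
            centre = i0 + int(round(disp[j]))
        if np.isnan(step).any():
            good = ~np.isnan(step)
            idx = np.arange(n_frames)
            step[~good] = np.interp(idx[~good], idx[good], step[good])
            disp = np.concatenate([[0.0], np.cumsum(step[1:])])
        walls.append(z_echo0 + disp * c / (2.0 * fs))

    times = np.arange(n_frames) / prf
    anterior, posterior = walls
    return VesselTrack(times=times, anterior=anterior, posterior=posterior,
                       flagged=flags)


def calibrate_alpha(track: VesselTrack, p_d: float, p_s: float) -> float:
    """Closed-form stiffness: alpha = ln(p_s/p_d) / (A_s/A_d - 1).

    The diastolic/systolic areas come from the minimum/maximum tracked
    diameters (circular lumen, A ∝ D^2).
    """
    if not p_s > p_d > 0:
        raise ValueError("need p_s > p_d > 0")
    d = track.diameter
    area_ratio = (d.max() / d.min()) ** 2
    if np.isclose(area_ratio, 1.0):
        raise ValueError("flat track: systolic and diastolic areas coincide")
    return float(math.log(p_s / p_d) / (area_ratio - 1.0))


def calibrate_model(track: VesselTrack, p_d: float, p_s: float) -> PressureModel:
    """Calibrated :class:`PressureModel` with A_d from the minimum diameter."""
    alpha = calibrate_alpha(track, p_d, p_s)
    d_min = float(track.diameter.min())
    return PressureModel(p_d=p_d, alpha=alpha, A_d=math.pi * d_min**2 / 4.0)


def pressure_waveform(track: VesselTrack, model: PressureModel) -> np.ndarray:
    """Convert a diameter track to a pressure time series via the model."""
    area = math.pi * track.diameter**2 / 4.0
    return np.asarray(model.pressure(area))
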