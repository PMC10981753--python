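"""File formats: transfer/impedance CSV, RF HDF5 and stack YAML configs.

CSV columns follow the conventions of the rest of the package:
``frequency_Hz, real, imag, unit`` for transfer functions and
``frequency_Hz, re_ohm, im_ohm, load_tag`` for impedance spectra.  RF frames
are stored one HDF5 group per transmit event with the geometry and timing as
attributes.  Stack description files are YAML with one entry per layer,
ordered backing → load, units declared in the key names.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from sonoflex.imaging import PlaneWaveEvent, RFFrame
from sonoflex.klm import ImpedanceSpectrum, TransferFunction
from sonoflex.materials import Layer, Material, PiezoMaterial, TransducerStack


def save_transfer_csv(tf: TransferFunction, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_Hz": tf.frequencies,
            "real": tf.values.real,
            "imag": tf.values.imag,
            "unit": tf.unit,
        }
    ).to_csv(path, index=False)


def load_transfer_csv(path: str | Path) -> TransferFunction:
    df = pd.read_csv(path)
    return TransferFunction(
        df["frequency_Hz"].to_numpy(),
        df["real"].to_numpy() + 1j * df["imag"].to_numpy(),
        str(df["unit"].iloc[0]),
    )


def save_impedance_csv(z: ImpedanceSpectrum, path: str | Path) -> None:
    pd.DataFrame(
        {
            "frequency_Hz": z.frequencies,
            "re_ohm": z.values.real,
            "im_ohm": z.values.imag,
            "load_tag": z.load,
        }
    ).to_csv(path, index=False)


def load_impedance_csv(path: str | Path) -> ImpedanceSpectrum:
    df = pd.read_csv(path)
    return ImpedanceSpectrum(
        df["frequency_Hz"].to_numpy(),
        df["re_ohm"].to_numpy() + 1j * df["im_ohm"].to_numpy(),
        load=str(df["load_tag"].iloc[0]),
    )


def save_rf_h5(frames: list[RFFrame], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        for i, frame in enumerate(frames):
            g = fh.create_group(f"frame{i:04d}")
            g.create_dataset("rf", data=frame.data)
            g.attrs["sample_rate"] = frame.sample_rate
            g.attrs["t0"] = frame.t0
            g.attrs["sound_speed"] = frame.sound_speed
            g.create_dataset("element_x", data=frame.element_x)
            if isinstance(frame.transmit, PlaneWaveEvent):
                g.attrs["angle"] = frame.transmit.angle


def load_rf_h5(path: str | Path) -> list[RFFrame]:
    frames = []
    with h5py.File(path, "r") as fh:
        for name in sorted(fh):
            g = fh[name]
            frames.append(
                RFFrame(
                    data=g["rf"][()],
                    sample_rate=float(g.attrs["sample_rate"]),
                    element_x=g["element_x"][()],
                    transmit=PlaneWaveEvent(float(g.attrs.get("angle", 0.0))),
                    t0=float(g.attrs["t0"]),
                    sound_speed=float(g.attrs["sound_speed"]),
                )
            )
    return frames


def _material_from_dict(d: dict) -> Material:
    common = dict(
        name=d.get("name", "material"),
        density=float(d["density_kg_m3"]),
        wave_speed=float(d["wave_speed_m_s"]),
        mech_loss_tangent=float(d.get("mech_loss_tangent", 0.0)),
    )
    if d.get("piezo", False):
        return PiezoMaterial(
            **common,
            k_t=float(d["k_t"]),
            permittivity_law=tuple(float(v) for v in d["permittivity_law"]),
            dielectric_loss_law=tuple(float(v) for v in d["dielectric_loss_law"]),
            d33=float(d["d33_pC_N"]) if "d33_pC_N" in d else None,
        )
    return Material(**common)


def _material_to_dict(m: Material) -> dict:
    d = {
        "name": m.name,
        "density_kg_m3": float(m.density),
        "wave_speed_m_s": float(m.wave_speed),
        "mech_loss_tangent": float(m.mech_loss_tangent),
    }
    if isinstance(m, PiezoMaterial):
        d.update(
            piezo=True,
            k_t=float(m.k_t),
            permittivity_law=[float(v) for v in m.permittivity_law],
            dielectric_loss_law=[float(v) for v in m.dielectric_loss_law],
        )
        if m.d33 is not None:
            d["d33_pC_N"] = float(m.d33)
    return d


def load_stack_yaml(path: str | Path) -> TransducerStack:
    """Read a stack description: layers ordered backing → load."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    layers = tuple(
        Layer(_material_from_dict(lay), float(lay["thickness_um"]) * 1e-6)
        for lay in cfg["layers"]
    )
    return TransducerStack(
        layers=layers,
        element_area=float(cfg["element_area_mm2"]) * 1e-6,
        backing_medium=_material_from_dict(cfg["backing_medium"]),
        load_medium=_material_from_dict(cfg["load_medium"]),
    )


def save_stack_yaml(stack: TransducerStack, path: str | Path) -> None:
    cfg = {
        "element_area_mm2": float(stack.element_area * 1e6),
        "backing_medium": _material_to_dict(stack.backing_medium),
        "load_medium": _material_to_dict(stack.load_medium),
        "layers": [
            {**_material_to_dict(lay.material),
             "thickness_um": float(lay.thickness * 1e6)}
            for lay in stack.layers
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
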