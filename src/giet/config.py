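"""TOML configuration for the analysis pipeline.

A config file carries sections ``[stack]``, ``[emitter]``, ``[irf]``,
``[fit]``, ``[inversion]`` and ``[simulation]``; every key is optional and
falls back to the packaged study defaults.  Example::

    [stack]
    n_sio2 = 1.46
    sio2_thickness_nm = 10.0
    graphene_dispersion = "my_graphene.csv"   # wavelength_nm,n,k table

    [emitter]
    tau0_ns = 2.6
    phi = 0.36
    orientation = "horizontal"
    spectrum = "my_dye.csv"                   # wavelength_nm,weight table

    [irf]
    sigma_ns = 0.1
    shift_ns = 2.0

    [inversion]
    d_max_nm = 10.0
    d_step_nm = 0.25
    tol_nm = 0.01
    max_iter = 20

    [simulation]
    photons_per_bunch = 1000000
    n_bunches = 20
    leaflet_fraction = 0.5
    background_fraction = 0.02
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from . import materials
from .calibration import StackSpec, ThicknessInverter
from .optics import DispersionTable, EmissionSpectrum, Emitter
from .tcspc import IRFModel

__all__ = ["AnalysisConfig", "load_config"]


@dataclass
class AnalysisConfig:
    """Resolved configuration: concrete objects for every pipeline stage."""

    stack: StackSpec = field(default_factory=StackSpec)
    emitter: Emitter = field(default_factory=materials.atto655)
    irf: IRFModel = field(default_factory=IRFModel)
    inversion: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    fit: dict = field(default_factory=dict)

    def make_inverter(self) -> ThicknessInverter:
        return ThicknessInverter(self.emitter, self.stack, **self.inversion)


def _build_stack(section: dict, base: Path) -> StackSpec:
    kwargs = {k: section[k] for k in
              ("n_glass", "n_sio2", "n_water", "n_slb",
               "sio2_thickness_nm", "graphene_thickness_nm") if k in section}
    if "graphene_dispersion" in section:
        kwargs["graphene"] = DispersionTable.from_csv(base / section["graphene_dispersion"])
    return StackSpec(**kwargs)


def _build_emitter(section: dict, base: Path) -> Emitter:
    spectrum = (EmissionSpectrum.from_csv(base / section["spectrum"])
                if "spectrum" in section else materials.atto655_spectrum())
    return Emitter(tau0_ns=section.get("tau0_ns", 2.6),
                   phi=section.get("phi", 0.36),
                   orientation=section.get("orientation", "horizontal"),
                   spectrum=spectrum)


def load_config(path=None) -> AnalysisConfig:
    """Load a TOML config; a missing path yields the packaged defaults."""
    if path is None:
        return AnalysisConfig()
    path = Path(path)
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    base = path.parent
    return AnalysisConfig(
        stack=_build_stack(raw.get("stack", {}), base),
        emitter=_build_emitter(raw.get("emitter", {}), base),
        irf=IRFModel(**raw.get("irf", {})),
        inversion=raw.get("inversion", {}),
        simulation=raw.get("simulation", {}),
        fit=raw.get("fit", {}),
    )
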