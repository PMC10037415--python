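"""Default materials for the GIET substrate and the Atto655 emitter.

The substrate is a glass coverslip carrying a single graphene sheet under a
10 nm SiO2 spacer, with an aqueous medium on top.  All indices and
thicknesses here are package defaults and can be overridden through the
configuration layer.
"""

from __future__ import annotations

import numpy as np

from .optics import DispersionTable, EmissionSpectrum, Emitter, Layer, LayerStack

__all__ = [
    "N_GLASS",
    "N_SIO2",
    "N_WATER",
    "N_SLB",
    "GRAPHENE_THICKNESS_NM",
    "SIO2_THICKNESS_NM",
    "graphene_dispersion",
    "atto655_spectrum",
    "atto655",
    "giet_stack",
]

N_GLASS = 1.52
N_SIO2 = 1.46
N_WATER = 1.333
N_SLB = 1.46  # supported lipid bilayer slab

GRAPHENE_THICKNESS_NM = 0.34  # single-sheet effective optical thickness
SIO2_THICKNESS_NM = 10.0

# Bruna & Borini (APL 2009) visible-range parametrization of monolayer
# graphene: n = 3.0, k = (C1/3) * lambda[um] with C1 = 5.446 um^-1.
_BRUNA_BORINI_C1 = 5.446  # 1/um


def graphene_dispersion(wl_min_nm: float = 400.0, wl_max_nm: float = 900.0,
                        step_nm: float = 2.0) -> DispersionTable:
    """Default complex refractive index of monolayer graphene.

    Generated from the Bruna–Borini constant-n parametrization of graphene
    ellipsometry (n = 3.0, k growing linearly with wavelength); a measured
    table can be substituted via :meth:`DispersionTable.from_csv`.
    """
    wl = np.arange(wl_min_nm, wl_max_nm + 0.5 * step_nm, step_nm)
    n = np.full_like(wl, 3.0)
    k = (_BRUNA_BORINI_C1 / 3.0) * (wl * 1e-3)
    return DispersionTable(wl, n, k, name="graphene (Bruna-Borini model)")


def atto655_spectrum(step_nm: float = 1.0) -> EmissionSpectrum:
    """Synthetic stand-in for the Atto655 emission spectrum.

    An asymmetric Gaussian peaked at 684 nm (sigma 14 nm on the blue side,
    26 nm on the red side) emulating the dye's red-shouldered emission band
    over 650–750 nm.  Replace with a measured `wavelength_nm,weight` table
    for quantitative work with other dyes.
    """
    wl = np.arange(650.0, 750.0 + 0.5 * step_nm, step_nm)
    sigma = np.where(wl < 684.0, 14.0, 26.0)
    w = np.exp(-0.5 * ((wl - 684.0) / sigma) ** 2)
    return EmissionSpectrum(wl, w, name="Atto655 emission (synthetic)")


def atto655() -> Emitter:
    """Atto655 head-group label: tau0 = 2.6 ns, phi = 0.36, horizontal dipole."""
    return Emitter(tau0_ns=2.6, phi=0.36, orientation="horizontal",
                   spectrum=atto655_spectrum())


def giet_stack(*, n_glass: float = N_GLASS, n_sio2: float = N_SIO2,
               n_water: float = N_WATER,
               sio2_thickness_nm: float = SIO2_THICKNESS_NM,
               graphene_thickness_nm: float = GRAPHENE_THICKNESS_NM,
               graphene: DispersionTable | complex | None = None,
               layers_above: tuple[Layer, ...] = ()) -> LayerStack:
    """Glass / graphene / SiO2 spacer stack with water on top.

    Heights are measured from the SiO2 top surface; ``layers_above`` may
    carry an SLB slab sitting immediately above the emitter plane.
    """
    if graphene is None:
        graphene = graphene_dispersion()
    return LayerStack(
        substrate_medium=n_glass,
        layers=(Layer(graphene_thickness_nm, graphene), Layer(sio2_thickness_nm, n_sio2)),
        top_medium=n_water,
        layers_above=tuple(layers_above),
    )
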