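"""Helpers for testing and verification (single-line test nuclides)."""

from __future__ import annotations

from .nuclide import NuclideData

_WATER_TABLE = (
    (20.0, 3.7391e-01, 2.0658e-01),
    (100.0, 2.7600e-03, 1.6472e-01),
    (600.0, 1.1683e-05, 8.9419e-02),
)
_RANGE_TABLE = ((10.0, 0.0025), (100.0, 0.1431), (600.0, 2.25))


def mono_beta_nuclide(e_kev: float = 100.0) -> NuclideData:
    """Pure beta emitter with a single-line spectrum.

    Removes spectrum-sampling variance so closed-form dose checks
    (N * E / m) become exact.
    """
    return NuclideData(
        name="mono-beta", physical_half_life_h=100.0,
        beta_spectrum=((e_kev, 1.0),), photon_lines=(),
        mass_attenuation_water=_WATER_TABLE, csda_range_water=_RANGE_TABLE)


def mono_photon_nuclide(e_kev: float = 208.0, yield_per_decay: float = 1.0,
                        beta_kev: float = 1.0) -> NuclideData:
    """Photon-dominated emitter (a token beta keeps the spectrum valid)."""
    return NuclideData(
        name="mono-photon", physical_half_life_h=100.0,
        beta_spectrum=((beta_kev, 1.0),),
        photon_lines=((e_kev, yield_per_decay),),
        mass_attenuation_water=_WATER_TABLE, csda_range_water=_RANGE_TABLE)
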