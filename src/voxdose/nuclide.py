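"""Radionuclide decay/interaction data loaded from an editable YAML config.

The packaged default describes Lu-177 (the therapy nuclide): a soft beta
emitter (mean ~134 keV, endpoint 498 keV, range below one SPECT voxel)
with two principal gamma lines at 113 and 208 keV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

KEV_TO_J = 1.602176634e-16


@dataclass(frozen=True)
class NuclideData:
    """Decay data plus water interaction tables.

    ``beta_spectrum`` rows are (mean energy keV, branch probability) and
    probabilities must sum to 1.  ``photon_lines`` rows are
    (energy keV, yield per decay).  Attenuation and CSDA tables are
    log-log interpolated.
    """

    name: str
    physical_half_life_h: float
    beta_spectrum: tuple[tuple[float, float], ...]
    photon_lines: tuple[tuple[float, float], ...]
    mass_attenuation_water: tuple[tuple[float, float, float], ...]
    csda_range_water: tuple[tuple[float, float], ...]
    beta_endpoint_kev: float = 498.0
    beta_range_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.physical_half_life_h <= 0:
            raise ValueError("half-life must be positive")
        psum = sum(p for _, p in self.beta_spectrum)
        if abs(psum - 1.0) > 1e-9:
            raise ValueError(f"beta spectrum probabilities sum to {psum}, not 1")
        if any(y < 0 for _, y in self.photon_lines):
            raise ValueError("photon yields must be >= 0")

    @property
    def mean_beta_energy_kev(self) -> float:
        return float(sum(e * p for e, p in self.beta_spectrum))

    @property
    def photon_energy_per_decay_kev(self) -> float:
        return float(sum(e * y for e, y in self.photon_lines))

    @property
    def total_energy_per_decay_kev(self) -> float:
        return self.mean_beta_energy_kev + self.photon_energy_per_decay_kev

    # -- water interaction tables ------------------------------------------

    def _interp_loglog(self, table: np.ndarray, col: int, energy_kev) -> np.ndarray:
        e = np.asarray(energy_kev, dtype=np.float64)
        x = np.log(table[:, 0])
        y = np.log(np.maximum(table[:, col], 1e-300))
        return np.exp(np.interp(np.log(np.clip(e, table[0, 0], table[-1, 0])), x, y))

    def mu_photoelectric(self, energy_kev) -> np.ndarray:
        """Photoelectric mass attenuation in water, cm^2/g."""
        return self._interp_loglog(np.asarray(self.mass_attenuation_water), 1, energy_kev)

    def mu_incoherent(self, energy_kev) -> np.ndarray:
        """Incoherent (Compton) mass attenuation in water, cm^2/g."""
        return self._interp_loglog(np.asarray(self.mass_attenuation_water), 2, energy_kev)

    def mu_total(self, energy_kev) -> np.ndarray:
        return self.mu_photoelectric(energy_kev) + self.mu_incoherent(energy_kev)

    def csda_range_mm(self, energy_kev) -> np.ndarray:
        """Electron CSDA range in water (mm at unit density)."""
        return self._interp_loglog(np.asarray(self.csda_range_water), 1, energy_kev)


def load_nuclide(path: str | Path | None = None) -> NuclideData:
    """Load nuclide data from YAML; defaults to the packaged Lu-177 file."""
    if path is None:
        with resources.files("voxdose.data").joinpath("lu177.yaml").open() as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = yaml.safe_load(Path(path).read_text())
    return NuclideData(
        name=raw["name"],
        physical_half_life_h=float(raw["physical_half_life_h"]),
        beta_spectrum=tuple((float(e), float(p)) for e, p in raw["beta_spectrum"]),
        photon_lines=tuple((float(e), float(y)) for e, y in raw["photon_lines"]),
        mass_attenuation_water=tuple(
            (float(e), float(pe), float(inc)) for e, pe, inc in raw["mass_attenuation_water"]
        ),
        csda_range_water=tuple((float(e), float(r)) for e, r in raw["csda_range_water"]),
        beta_endpoint_kev=float(raw.get("beta_endpoint_kev", 498.0)),
        beta_range_mm=float(raw.get("beta_range_mm", 2.0)),
    )
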