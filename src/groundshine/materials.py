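"""Materials and photon interaction data for the air-over-ground geometry.

The transport model follows the classic environmental gamma-ray treatment:
photoelectric absorption, incoherent (Compton) scattering and pair production
are the interaction processes; coherent scattering is not taken into account.
Air and soil have constant densities of 1.2e-3 and 1.0 g/cm^3 and the soil is
a SiO2 / Al2O3 / Fe2O3 / H2O mixture with weight fractions 58.3 / 16.7 / 8.3
/ 16.7 %.

Mass coefficients are interpolated log-log between the nodes of the bundled
tables (0.01-3 MeV); compound coefficients obey mass-fraction additivity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import xsection as xs

ENERGY_MIN_MEV = 0.01
ENERGY_MAX_MEV = 3.0

PROCESS_NAMES = ("photoelectric", "compton", "pair")


@dataclass(frozen=True)
class Material:
    """A named medium with compound weight fractions and a density in g/cm^3."""

    name: str
    components: tuple[tuple[str, float], ...]
    density: float

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"weight fractions of {self.name!r} sum to {total}, not 1")
        if self.density <= 0:
            raise ValueError("density must be positive")
        for formula, w in self.components:
            if w <= 0:
                raise ValueError(f"non-positive weight fraction for {formula}")
            xs.parse_formula(formula)

    def element_fractions(self) -> dict[str, float]:
        """Element mass fractions of the mixture (mass-additivity rule)."""
        frac: dict[str, float] = {}
        for formula, w in self.components:
            for sym, f in xs.element_mass_fractions(formula).items():
                frac[sym] = frac.get(sym, 0.0) + w * f
        return frac


@dataclass
class AttenuationTable:
    """Tabulated mass attenuation data for one material.

    ``mu_rho`` is the total mass attenuation coefficient excluding coherent
    scattering, ``mu_en_rho`` the mass energy-transfer coefficient used for
    kerma scoring, and ``process_fractions`` the per-energy shares of the
    three modelled processes (photoelectric, incoherent, pair).
    """

    energy_grid: np.ndarray
    mu_rho: np.ndarray
    mu_en_rho: np.ndarray
    process_fractions: np.ndarray  # shape (n, 3)
    material_name: str = "unknown"
    _log_e: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.energy_grid = np.asarray(self.energy_grid, dtype=float)
        self.mu_rho = np.asarray(self.mu_rho, dtype=float)
        self.mu_en_rho = np.asarray(self.mu_en_rho, dtype=float)
        self.process_fractions = np.asarray(self.process_fractions, dtype=float)
        if np.any(np.diff(self.energy_grid) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.mu_rho <= 0) or np.any(self.mu_en_rho <= 0):
            raise ValueError("attenuation coefficients must be positive")
        if np.any(self.mu_en_rho > self.mu_rho * (1 + 1e-9)):
            raise ValueError("mu_en/rho exceeds mu/rho")
        sums = self.process_fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("process fractions do not sum to 1")
        # renormalise exactly so sampled frequencies are well defined
        self.process_fractions = self.process_fractions / sums[:, None]
        self._log_e = np.log(self.energy_grid)

    def _check_range(self, energy) -> np.ndarray:
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_grid[0], self.energy_grid[-1]
        if np.any(e < lo * (1 - 1e-9)) or np.any(e > hi * (1 + 1e-9)):
            raise ValueError(
                f"energy outside table range [{lo}, {hi}] MeV for {self.material_name}")
        return np.clip(e, lo, hi)

    def mu(self, energy):
        """Log-log interpolated total mass attenuation coefficient, cm^2/g."""
        e = self._check_range(energy)
        out = np.exp(np.interp(np.log(e), self._log_e, np.log(self.mu_rho)))
        return out if out.shape else float(out)

    def mu_en(self, energy):
        """Log-log interpolated mass energy-transfer coefficient, cm^2/g."""
        e = self._check_range(energy)
        out = np.exp(np.interp(np.log(e), self._log_e, np.log(self.mu_en_rho)))
        return out if out.shape else float(out)

    def fractions(self, energy) -> np.ndarray:
        """Process fractions at the given energies, renormalised; pair is
        forced to zero below the 1.022 MeV threshold."""
        e = np.atleast_1d(self._check_range(energy))
        cols = [np.interp(np.log(e), self._log_e, self.process_fractions[:, j])
                for j in range(3)]
        f = np.stack(cols, axis=-1)
        f[:, 2] = np.where(e < 2.0 * xs.ELECTRON_REST_MEV, 0.0, f[:, 2])
        f /= f.sum(axis=-1, keepdims=True)
        return f if np.ndim(energy) else f[0]


def _data_dir() -> Path:
    return Path(resources.files("groundshine") / "data")


def load_attenuation_table(material: str | Material | Path) -> AttenuationTable:
    """Load a bundled (or external CSV) attenuation table.

    Accepts a material name ("air", "soil"), a :class:`Material` whose name is
    bundled, or a path to a CSV with columns
    energy_MeV, mu_rho, mu_en_rho, f_photo, f_compton, f_pair.
    """
    if isinstance(material, Material):
        name = material.name
    else:
        name = str(material)
    path = Path(name)
    if not path.suffix:
        path = _data_dir() / "attenuation" / f"{name}.csv"
    df = pd.read_csv(path, comment="#")
    return AttenuationTable(
        energy_grid=df["energy_MeV"].to_numpy(),
        mu_rho=df["mu_rho"].to_numpy(),
        mu_en_rho=df["mu_en_rho"].to_numpy(),
        process_fractions=df[["f_photo", "f_compton", "f_pair"]].to_numpy(),
        material_name=Path(path).stem,
    )


def compose_attenuation_table(material: Material) -> AttenuationTable:
    """Build a material table at run time from the bundled per-element
    component files via the mass-fraction mixture rule.

    Serves arbitrary mixtures of the bundled elements and doubles as an
    independent route to the shipped per-material tables.
    """
    frac = material.element_fractions()
    tau = incoh = kappa = None
    grid = None
    for sym, w in frac.items():
        df = pd.read_csv(_data_dir() / "attenuation" / "elements" / f"{sym}.csv",
                         comment="#")
        if grid is None:
            grid = df["energy_MeV"].to_numpy()
            tau = np.zeros_like(grid)
            incoh = np.zeros_like(grid)
            kappa = np.zeros_like(grid)
        tau += w * df["tau_rho"].to_numpy()
        incoh += w * df["sigma_incoh_rho"].to_numpy()
        kappa += w * df["kappa_rho"].to_numpy()
    mu = tau + incoh + kappa
    f_tr = xs.kn_mean_transfer_fraction(grid)
    k = grid / xs.ELECTRON_REST_MEV
    pair_frac = np.clip((k - 2.0) / k, 0.0, None)
    mu_tr = tau + incoh * f_tr + kappa * pair_frac
    fractions = np.stack([tau / mu, incoh / mu, kappa / mu], axis=1)
    return AttenuationTable(grid, mu, mu_tr, fractions, material.name)


AIR = Material("air", (("N2", 0.7552), ("O2", 0.2320), ("Ar", 0.0128)), 1.2e-3)
SOIL = Material(
    "soil",
    (("SiO2", 0.583), ("Al2O3", 0.167), ("Fe2O3", 0.083), ("H2O", 0.167)),
    1.0,
)


def make_standard_materials() -> tuple[Material, Material]:
    """The standard air (1.2e-3 g/cm^3) and soil (1.0 g/cm^3) media."""
    return AIR, SOIL


_TABLE_CACHE: dict[str, AttenuationTable] = {}


def get_table(material: Material | str) -> AttenuationTable:
    name = material.name if isinstance(material, Material) else material
    if name not in _TABLE_CACHE:
        _TABLE_CACHE[name] = load_attenuation_table(name)
    return _TABLE_CACHE[name]


def mass_attenuation(material: Material | str, energy):
    """Total mass attenuation coefficient (cm^2/g), coherent excluded."""
    return get_table(material).mu(energy)


def mass_energy_transfer(material: Material | str, energy):
    """Mass energy-transfer coefficient (cm^2/g) used for kerma scoring."""
    return get_table(material).mu_en(energy)


def sample_interaction(energy, material: Material | str, rng) -> np.ndarray:
    """Draw the interaction process at each energy.

    Returns an integer array (0 photoelectric, 1 incoherent, 2 pair) drawn
    proportionally to the tabulated process fractions.
    """
    table = get_table(material)
    e = np.atleast_1d(np.asarray(energy, dtype=float))
    f = table.fractions(e)
    u = rng.random(e.shape)
    proc = np.full(e.shape, 1, dtype=np.int8)
    cum0 = f[..., 0]
    cum1 = cum0 + f[..., 1]
    proc = np.where(u < cum0, 0, np.where(u < cum1, 1, 2)).astype(np.int8)
    return proc if np.ndim(energy) else proc[0]
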