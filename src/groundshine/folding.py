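"""Folding kerma coefficients and dose curves into nuclide dose-rate coefficients.

For a mono-energetic exponential ground source the effective-dose conversion
coefficient factorises as

    E(e, alpha) = E(e) * K(e, alpha)        [Sv per photon/m^2]

where E(e) (Sv/Gy) converts air kerma to effective dose for a plane source at
a mass depth of 0.5 g/cm^2 — a curve that represents exponential sources over
a wide range of relaxation depths within a few percent (at most ~15 % for
volume-like sources), which is the central modelling assumption of the
pipeline — and K(e, alpha) (Gy per photon/m^2) is the transport engine's air
kerma coefficient.  For a radionuclide N with photon lines (e_i, y_i),

    E(N, alpha) = c * sum_i y_i * E(e_i) * K(e_i, alpha)   [Sv/h per Bq/m^2]

with c = 3600 s/h adjusting the time dimension (Bq = 1/s, coefficient per hour).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import NuclideSpectrum, filter_lines
from .transport import KermaGrid

#: seconds per hour — the time-dimension constant c
SECONDS_PER_HOUR = 3600.0

DEFAULT_LINE_FLOOR_MEV = 0.01


@dataclass
class DoseCurve:
    """Air-kerma-to-effective-dose curve E(e), Sv/Gy, for one phantom/scheme.

    Represents a plane source at a mass depth of 0.5 g/cm^2; tagged with the
    phantom ("adult" or "baby") and weighting scheme ("icrp103" or "icrp60").
    """

    phantom: str
    scheme: str
    energies: np.ndarray
    values: np.ndarray
    source_tag: str = "plane source at 0.5 g/cm^2"
    _log_e: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("dose-curve energy grid must be strictly increasing")
        if np.any(self.values <= 0):
            raise ValueError("dose-curve values must be positive")
        self._log_e = np.log(self.energies)

    def __call__(self, energy):
        """Log-log interpolated E(e); hard error outside the grid range."""
        e = np.asarray(energy, dtype=float)
        if np.any(e < self.energies[0] * (1 - 1e-9)) or np.any(
                e > self.energies[-1] * (1 + 1e-9)):
            raise ValueError("energy outside the dose-curve range (no extrapolation)")
        out = np.exp(np.interp(np.log(e), self._log_e, np.log(self.values)))
        return out if out.shape else float(out)

    def to_csv(self, path) -> None:
        pd.DataFrame({"energy_MeV": self.energies, "E_Sv_per_Gy": self.values}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path, phantom: str = "adult", scheme: str = "icrp103"):
        df = pd.read_csv(path, comment="#")
        return cls(phantom, scheme, df["energy_MeV"].to_numpy(),
                   df["E_Sv_per_Gy"].to_numpy())


@dataclass
class CoefficientTable:
    """E(N, alpha) in Sv/h per Bq/m^2 for a set of nuclides and depths."""

    phantom: str
    scheme: str
    entries: pd.DataFrame  # columns nuclide, alpha_gcm2, coefficient
    time_constant: float = SECONDS_PER_HOUR
    provenance: str = ""

    @property
    def nuclides(self) -> list[str]:
        return list(dict.fromkeys(self.entries["nuclide"]))

    @property
    def alphas(self) -> np.ndarray:
        return np.unique(self.entries["alpha_gcm2"])

    def value(self, nuclide: str, alpha: float) -> float:
        sel = self.entries[
            (self.entries["nuclide"] == nuclide)
            & np.isclose(self.entries["alpha_gcm2"], alpha)]
        if sel.empty:
            raise KeyError(f"no entry for {nuclide} at alpha={alpha}")
        return float(sel["coefficient"].iloc[0])

    def to_csv(self, path) -> None:
        df = self.entries.copy()
        df["phantom"] = self.phantom
        df["scheme"] = self.scheme
        df.rename(columns={"coefficient": "coefficient_Sv_per_h_per_Bq_m2"}).to_csv(
            path, index=False)


def fold_mono(e_curve: DoseCurve, k_grid: KermaGrid, energy: float,
              alpha: float, height: float = None) -> float:
    """E(e, alpha): product of interpolated E(e) and K(e, alpha), Sv per photon/m^2."""
    return float(e_curve(energy)) * float(k_grid.interpolate(energy, alpha, height))


def fold_nuclide(spectrum: NuclideSpectrum, e_curve: DoseCurve,
                 k_grid: KermaGrid, alpha: float,
                 c: float = SECONDS_PER_HOUR,
                 line_floor: float = DEFAULT_LINE_FLOOR_MEV,
                 height: float = None) -> float:
    """E(N, alpha) = c * sum_i y_i E(e_i) K(e_i, alpha), Sv/h per Bq/m^2.

    Lines below ``line_floor`` (default the transport cutoff, 0.01 MeV) are
    dropped first; a spectrum with no retained lines yields 0 with a warning
    (pure beta emitter as far as the photon field is concerned).
    """
    kept = filter_lines(spectrum, line_floor)
    if not kept.lines:
        warnings.warn(f"{spectrum.nuclide_id}: no photon lines at or above "
                      f"{line_floor} MeV; coefficient is 0", stacklevel=2)
        return 0.0
    total = 0.0
    for line in kept.lines:
        total += line.yield_per_decay * fold_mono(
            e_curve, k_grid, line.energy, alpha, height)
    return c * total


def build_table(spectra, alphas, e_curve: DoseCurve, k_grid: KermaGrid,
                c: float = SECONDS_PER_HOUR,
                line_floor: float = DEFAULT_LINE_FLOOR_MEV) -> CoefficientTable:
    """Fold every nuclide at every relaxation depth into a CoefficientTable.

    ``spectra`` is a mapping nuclide -> NuclideSpectrum (or an iterable of
    spectra); per-nuclide warnings propagate.
    """
    if isinstance(spectra, dict):
        spectra = list(spectra.values())
    rows = []
    for spec in spectra:
        for a in np.atleast_1d(np.asarray(alphas, dtype=float)):
            rows.append((spec.nuclide_id, float(a),
                         fold_nuclide(spec, e_curve, k_grid, float(a), c, line_floor)))
    entries = pd.DataFrame(rows, columns=["nuclide", "alpha_gcm2", "coefficient"])
    return CoefficientTable(
        phantom=e_curve.phantom, scheme=e_curve.scheme, entries=entries,
        time_constant=c,
        provenance=f"curve={e_curve.phantom}/{e_curve.scheme}; c={c} s/h")
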