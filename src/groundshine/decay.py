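"""Per-nuclide photon emission spectra (line energies and yields per decay).

The library format is a simple CSV dialect: columns
``nuclide,energy_MeV,yield_per_decay``, one photon line per row, ``#``
comment lines carrying provenance.  Nuclide identifiers follow the
element-massnumber grammar with an optional metastable suffix, e.g.
``Co-60``, ``Ba-137m``.

A small library is bundled for the nuclides discussed in the accompanying
analyses (Co-60, Ba-137m, Cs-134, Am-241, Sm-151, Bi-214, Ce-141, ...); it
is an approximate transcription of an ICRP-107-style decay compilation with
X-ray multiplets binned into single lines.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

NUCLIDE_RE = re.compile(r"^[A-Z][a-z]?-\d{1,3}m?\d?$")


@dataclass(frozen=True, order=True)
class PhotonLine:
    """One photon emission: energy in MeV, yield in photons per decay."""

    energy: float
    yield_per_decay: float

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("line energy must be positive")
        if not (0.0 < self.yield_per_decay <= 2.0):
            raise ValueError(
                f"yield {self.yield_per_decay} outside (0, 2] "
                "(2 allows summed multiplets)")


@dataclass(frozen=True)
class NuclideSpectrum:
    """A nuclide identifier with its photon lines, sorted by energy."""

    nuclide_id: str
    lines: tuple[PhotonLine, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not NUCLIDE_RE.match(self.nuclide_id):
            raise ValueError(f"bad nuclide identifier {self.nuclide_id!r}")
        object.__setattr__(self, "lines",
                           tuple(sorted(self.lines, key=lambda l: l.energy)))

    @property
    def total_yield(self) -> float:
        return sum(l.yield_per_decay for l in self.lines)


def read_library(path) -> dict[str, NuclideSpectrum]:
    """Read a photon-line library CSV into a nuclide -> spectrum map.

    Malformed rows raise with the offending line number; duplicate rows for a
    nuclide are merged (with a warning when a whole nuclide block repeats).
    """
    lines_by_nuclide: dict[str, list[PhotonLine]] = {}
    provenance: list[str] = []
    with open(path) as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text:
                continue
            if text.startswith("#"):
                provenance.append(text.lstrip("# "))
                continue
            parts = [p.strip() for p in text.split(",")]
            if not header_seen:
                if parts[:3] != ["nuclide", "energy_MeV", "yield_per_decay"]:
                    raise ValueError(
                        f"{path}:{lineno}: expected header "
                        "'nuclide,energy_MeV,yield_per_decay'")
                header_seen = True
                continue
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 fields, got {len(parts)}")
            nuclide = parts[0]
            if not NUCLIDE_RE.match(nuclide):
                raise ValueError(f"{path}:{lineno}: bad nuclide id {nuclide!r}")
            try:
                energy = float(parts[1])
                y = float(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric field") from exc
            if not (0.0 < y <= 2.0):
                raise ValueError(
                    f"{path}:{lineno}: yield {y} outside (0, 2]")
            if nuclide in lines_by_nuclide and any(
                    abs(l.energy - energy) < 1e-12 for l in lines_by_nuclide[nuclide]):
                warnings.warn(f"duplicate line for {nuclide} at {energy} MeV; merging",
                              stacklevel=2)
                merged = []
                for l in lines_by_nuclide[nuclide]:
                    if abs(l.energy - energy) < 1e-12:
                        merged.append(PhotonLine(energy, l.yield_per_decay + y))
                    else:
                        merged.append(l)
                lines_by_nuclide[nuclide] = merged
                continue
            lines_by_nuclide.setdefault(nuclide, []).append(PhotonLine(energy, y))
    prov = " ".join(provenance)
    return {n: NuclideSpectrum(n, tuple(ls), prov)
            for n, ls in lines_by_nuclide.items()}


def write_library(spectra, path) -> None:
    """Write spectra back to the CSV dialect (round-trips exactly)."""
    with open(path, "w") as fh:
        fh.write("# photon-line library written by groundshine\n")
        fh.write("nuclide,energy_MeV,yield_per_decay\n")
        for spec in spectra.values() if isinstance(spectra, dict) else spectra:
            for line in spec.lines:
                fh.write(f"{spec.nuclide_id},{line.energy!r},{line.yield_per_decay!r}\n")


def load_bundled_library() -> dict[str, NuclideSpectrum]:
    """The photon-line library shipped with the package."""
    path = Path(resources.files("groundshine") / "data" / "decay" / "photon_lines.csv")
    return read_library(path)


def filter_lines(spectrum: NuclideSpectrum, energy_floor: float) -> NuclideSpectrum:
    """Remove lines below the floor (MeV); idempotent and monotone in it.

    The removed yield fraction is reported through a warning when it exceeds
    5 % of the total, since dropped soft lines mean the folded coefficient
    misses part of the emission.
    """
    if energy_floor < 0:
        raise ValueError("energy floor must be >= 0")
    kept = tuple(l for l in spectrum.lines if l.energy >= energy_floor)
    dropped = spectrum.total_yield - sum(l.yield_per_decay for l in kept)
    if spectrum.total_yield > 0 and dropped / spectrum.total_yield >= 0.05:
        warnings.warn(
            f"{spectrum.nuclide_id}: {100 * dropped / spectrum.total_yield:.1f} % "
            f"of photon yield below {energy_floor} MeV was dropped", stacklevel=2)
    return NuclideSpectrum(spectrum.nuclide_id, kept, spectrum.provenance)
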