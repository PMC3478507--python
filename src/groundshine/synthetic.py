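"""Synthetic inputs with the statistical structure the pipeline assumes.

Real air-kerma-to-effective-dose curves and organ-dose sets come from
voxel-phantom transport published elsewhere and are user-supplied; the
generators here stand in for them in tests and examples.  They emulate the
qualitative features the pipeline relies on — smooth positive E(e) curves of
order 0.1-2 Sv/Gy, kerma grids strictly decreasing with relaxation depth
(soil shielding) and less steeply so at higher energy, line spectra with
yields in (0, 1], and organ-dose sets with bounded anisotropy — without any
claim to phantom-level realism.

Every generator is a pure function of an explicit :class:`SyntheticSpec`
(no hidden RNG state): the same spec always produces identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import NuclideSpectrum, PhotonLine
from .folding import DoseCurve
from .transport import KermaGrid
from .weighting import OrganDoseSet, load_scheme


@dataclass(frozen=True)
class SyntheticSpec:
    """Reproducible recipe for synthetic pipeline inputs."""

    seed: int = 0
    energy_range: tuple[float, float] = (0.01, 3.0)  # MeV, the transport range
    n_energies: int = 25
    n_lines: tuple[int, int] = (1, 8)
    anisotropy: float = 2.0  # max/min organ-dose ratio bound
    noise: float = 0.0
    alphas: tuple[float, ...] = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0, 10.0, 100.0)
    height: float = 1.0  # m

    def __post_init__(self) -> None:
        if self.energy_range[0] <= 0 or self.energy_range[1] <= self.energy_range[0]:
            raise ValueError("bad energy range")
        if self.anisotropy < 1.0:
            raise ValueError("anisotropy bound must be >= 1")
        if self.n_lines[0] < 1 or self.n_lines[1] < self.n_lines[0]:
            raise ValueError("bad n_lines range")


def _stream_key(stream: str) -> int:
    import zlib

    return zlib.crc32(stream.encode()) % 2**31


def _rng(spec: SyntheticSpec, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, _stream_key(stream)]))


def gen_dose_curve(spec: SyntheticSpec, phantom: str = "adult",
                   scheme: str = "icrp103") -> DoseCurve:
    """A smooth, positive Sv/Gy curve: log-log piecewise linear with bounded
    slope, values of realistic magnitude (roughly 0.1-2 Sv/Gy)."""
    rng = np.random.default_rng(
        np.random.SeedSequence([spec.seed, 1, _stream_key(phantom),
                                _stream_key(scheme)]))
    e = np.geomspace(*spec.energy_range, spec.n_energies)
    # bounded-slope random walk in log-log space
    slopes = rng.uniform(-0.4, 0.6, spec.n_energies - 1)
    log_v = np.concatenate([[0.0], np.cumsum(slopes * np.diff(np.log(e)))])
    v = np.exp(log_v)
    v = 0.15 + (1.8 - 0.15) * (v - v.min()) / (v.max() - v.min() + 1e-300)
    return DoseCurve(phantom, scheme, e, v)


def gen_kerma_grid(spec: SyntheticSpec) -> KermaGrid:
    """K(e, alpha) = K0(e) exp(-alpha / lambda(e)) with lambda increasing in
    energy — strictly decreasing in depth, and less steeply at higher energy,
    the qualitative behaviour of the transport results."""
    rng = _rng(spec, "kerma")
    e = np.geomspace(*spec.energy_range, spec.n_energies)
    alphas = np.asarray(spec.alphas, dtype=float)
    # magnitudes bracketing the published coefficient range
    k0 = 2.5e-18 * e ** rng.uniform(0.8, 1.2)
    lam = 3.0 * (e / e[-1]) ** rng.uniform(0.3, 0.6) * 10.0
    K = k0[:, None] * np.exp(-alphas[None, :] / lam[:, None])
    if spec.noise > 0:
        K = K * np.exp(spec.noise * rng.standard_normal(K.shape))
    stderr = np.zeros_like(K)
    return KermaGrid(e, alphas, np.array([spec.height]), K[:, :, None],
                     stderr[:, :, None], n_histories=0)


def gen_spectrum(spec: SyntheticSpec, nuclide_id: str = "Sy-99") -> NuclideSpectrum:
    """A synthetic line spectrum: energies log-uniform in range, yields in (0, 1]."""
    rng = _rng(spec, "spectrum")
    n = int(rng.integers(spec.n_lines[0], spec.n_lines[1] + 1))
    lo, hi = spec.energy_range
    energies = np.exp(rng.uniform(np.log(lo), np.log(hi), n))
    yields = 1.0 - rng.random(n)  # in (0, 1]
    lines = tuple(PhotonLine(float(e), float(y)) for e, y in zip(energies, yields))
    return NuclideSpectrum(nuclide_id, lines, provenance="synthetic")


def gen_organ_doses(spec: SyntheticSpec) -> tuple[OrganDoseSet, OrganDoseSet]:
    """Organ-dose sets for both sexes covering both schemes' vocabularies.

    Doses are log-uniform within the anisotropy bound (max/min <= bound by
    construction); bound 1 gives exactly uniform doses.
    """
    rng = _rng(spec, "organs")
    vocab = {}
    for sex in ("male", "female"):
        tissues = set()
        for scheme_id in ("icrp103", "icrp60"):
            tissues |= load_scheme(scheme_id).vocabulary(sex)
        vocab[sex] = sorted(tissues)
    out = []
    for sex in ("male", "female"):
        u = rng.random(len(vocab[sex]))
        doses = np.exp(u * np.log(spec.anisotropy))  # in [1, anisotropy]
        out.append(OrganDoseSet(sex, dict(zip(vocab[sex], doses))))
    return out[0], out[1]
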