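"""Analytic photon cross-section models.

The transport model treats three interaction processes — photoelectric
absorption, incoherent (Compton) scattering and pair production — and
deliberately excludes coherent (Rayleigh) scattering from the total cross
section.  Incoherent scattering is modelled on free electrons with the exact
Klein-Nishina formulae; a Thomas-Fermi screened Rayleigh estimate is provided
only so that photoelectric components can be extracted from published total
attenuation anchors when the bundled tables are (re)generated.

All energies are in MeV, microscopic cross sections in cm^2 (per electron or
per atom), mass coefficients in cm^2/g.
"""

from __future__ import annotations

import re

import numpy as np

# Physical constants (CODATA-rounded)
ELECTRON_REST_MEV = 0.510998950
CLASSICAL_ELECTRON_RADIUS_CM = 2.8179403262e-13
AVOGADRO = 6.02214076e23
HBARC_MEV_CM = 1.973269804e-11
BOHR_RADIUS_CM = 5.29177210903e-9
#: Thomson cross section per electron, cm^2
THOMSON_CM2 = 8.0 * np.pi / 3.0 * CLASSICAL_ELECTRON_RADIUS_CM**2

#: (Z, atomic mass g/mol) for the elements appearing in air and soil.
ELEMENTS: dict[str, tuple[int, float]] = {
    "H": (1, 1.008),
    "C": (6, 12.011),
    "N": (7, 14.007),
    "O": (8, 15.999),
    "Al": (13, 26.982),
    "Si": (14, 28.085),
    "Ar": (18, 39.948),
    "Fe": (26, 55.845),
}

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a simple chemical formula like ``SiO2`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in ELEMENTS:
            raise ValueError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def formula_mass(formula: str) -> float:
    """Molar mass (g/mol) of a simple formula."""
    return sum(n * ELEMENTS[s][1] for s, n in parse_formula(formula).items())


def element_mass_fractions(formula: str) -> dict[str, float]:
    """Element mass fractions of a compound formula."""
    counts = parse_formula(formula)
    m = formula_mass(formula)
    return {s: n * ELEMENTS[s][1] / m for s, n in counts.items()}


# ---------------------------------------------------------------------------
# Klein-Nishina (free-electron incoherent scattering)
# ---------------------------------------------------------------------------

def kn_total_cross_section(energy_mev):
    """Exact Klein-Nishina total cross section per electron (cm^2).

    Approaches the Thomson value 0.6652 b as the photon energy goes to zero.
    """
    e = np.asarray(energy_mev, dtype=float)
    a = e / ELECTRON_REST_MEV
    small = a < 1e-4
    a_safe = np.where(small, 1.0, a)
    t = 1.0 + 2.0 * a_safe
    term = (
        (1.0 + a_safe) / a_safe**2
        * (2.0 * (1.0 + a_safe) / t - np.log(t) / a_safe)
        + np.log(t) / (2.0 * a_safe)
        - (1.0 + 3.0 * a_safe) / t**2
    )
    sigma = 2.0 * np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * term
    # Low-energy Taylor expansion: sigma_T * (1 - 2a + 26/5 a^2 ...)
    sigma = np.where(small, THOMSON_CM2 * (1.0 - 2.0 * a), sigma)
    return sigma if sigma.shape else float(sigma)


def kn_differential(energy_mev: float, mu):
    """Klein-Nishina dsigma/dmu per electron (cm^2), mu the scattering cosine."""
    a = energy_mev / ELECTRON_REST_MEV
    mu = np.asarray(mu, dtype=float)
    t = 1.0 / (1.0 + a * (1.0 - mu))
    return np.pi * CLASSICAL_ELECTRON_RADIUS_CM**2 * t**2 * (t + 1.0 / t - 1.0 + mu**2)


def compton_scattered_energy(energy_mev, mu):
    """Compton kinematics: scattered photon energy for scattering cosine mu."""
    e = np.asarray(energy_mev, dtype=float)
    return e / (1.0 + (e / ELECTRON_REST_MEV) * (1.0 - np.asarray(mu, dtype=float)))


def kn_mean_transfer_fraction(energy_mev):
    """Mean fraction of photon energy given to the electron per KN scatter.

    Evaluated by Gauss-Legendre quadrature of the differential cross section.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    nodes, weights = np.polynomial.legendre.leggauss(128)
    out = np.empty_like(e)
    for i, ei in enumerate(e):
        d = kn_differential(ei, nodes)
        eprime = compton_scattered_energy(ei, nodes)
        sigma = np.sum(weights * d)
        mean_scattered = np.sum(weights * d * eprime) / sigma
        out[i] = 1.0 - mean_scattered / ei
    return out if np.ndim(energy_mev) else float(out[0])


def sample_compton(energy_mev, rng, size=None):
    """Sample (scattered energy, scattering cosine) from the Klein-Nishina law.

    Kahn's composition-rejection technique, vectorised; valid at all energies
    (reduces to the symmetric Thomson distribution at low energy).  The
    returned pair satisfies the Compton relation exactly.
    """
    scalar = np.ndim(energy_mev) == 0 and size is None
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    if size is not None:
        e = np.broadcast_to(e, (size,)).copy() if e.size == 1 else e
    if np.any(e <= 0):
        raise ValueError("photon energy must be positive")
    a = e / ELECTRON_REST_MEV
    n = e.size
    x = np.empty(n)  # x = E/E' in [1, 1+2a]
    todo = np.ones(n, dtype=bool)
    while todo.any():
        idx = np.nonzero(todo)[0]
        ai = a[idx]
        r1, r2, r3 = rng.random((3, idx.size))
        branch1 = r1 <= (2.0 * ai + 1.0) / (2.0 * ai + 9.0)
        xi = np.where(branch1, 1.0 + 2.0 * ai * r2,
                      (2.0 * ai + 1.0) / (2.0 * ai * r2 + 1.0))
        mu_i = 1.0 - (xi - 1.0) / np.where(ai > 0, ai, 1.0)
        acc1 = r3 <= 4.0 * (1.0 / xi - 1.0 / xi**2)
        acc2 = r3 <= 0.5 * (mu_i**2 + 1.0 / xi)
        accept = np.where(branch1, acc1, acc2)
        x[idx[accept]] = xi[accept]
        todo[idx[accept]] = False
    mu = 1.0 - (x - 1.0) / a
    eprime = e / x
    if scalar:
        return float(eprime[0]), float(mu[0])
    return eprime, mu


# ---------------------------------------------------------------------------
# Rayleigh estimate (decomposition only — never part of the transport total)
# ---------------------------------------------------------------------------

#: screening-length multiplier, tuned once so that the composed coherent
#: estimate for air matches the published air coherent component over
#: 30-100 keV; only used when extracting photoelectric components from
#: published total-attenuation anchors.
_RAYLEIGH_SCREEN = 1.2


def rayleigh_cross_section_estimate(z: int, energy_mev: float) -> float:
    """Approximate integrated Rayleigh cross section per atom (cm^2).

    Thomson angular factor times the square of a hydrogen-like dipole form
    factor with Thomas-Fermi Z^(-1/3) screening length.  Good to tens of
    percent — sufficient for its sole role of separating the photoelectric
    part from total-attenuation anchor values.
    """
    b = _RAYLEIGH_SCREEN * 0.8853 * BOHR_RADIUS_CM * z ** (-1.0 / 3.0)
    mu, w = np.polynomial.legendre.leggauss(256)
    q = (energy_mev / HBARC_MEV_CM) * np.sqrt(np.clip(2.0 * (1.0 - mu), 0.0, None))
    ff = z / (1.0 + (q * b / 2.0) ** 2) ** 2
    # dsigma/dOmega integrated with dOmega = 2*pi dmu
    dsig_domega = 0.5 * CLASSICAL_ELECTRON_RADIUS_CM**2 * (1.0 + mu**2) * ff**2
    return float(2.0 * np.pi * np.sum(w * dsig_domega))


# ---------------------------------------------------------------------------
# Pair production (near-threshold parameterisation)
# ---------------------------------------------------------------------------

#: mass-coefficient scale, cm^2/g per unit Z(Z+1)/A, calibrated on the pair
#: component of air at 2 and 3 MeV from a standard compilation.
_PAIR_SCALE = 1.047e-3
_PAIR_EXPONENT = 3.4


def pair_mass_coefficient(z: int, a_mass: float, energy_mev) -> np.ndarray:
    """Nuclear+electron pair-production mass coefficient (cm^2/g).

    Zero below the 2 m_e c^2 threshold; a single-parameter near-threshold
    power law above it, adequate below 3 MeV where pair production is a
    few-percent correction in low-Z media.
    """
    e = np.asarray(energy_mev, dtype=float)
    k = e / ELECTRON_REST_MEV
    f = np.clip((k - 2.0) / k, 0.0, None) ** _PAIR_EXPONENT
    return _PAIR_SCALE * z * (z + 1.0) / a_mass * f


def incoherent_mass_coefficient(z: int, a_mass: float, energy_mev):
    """Free-electron (Klein-Nishina) incoherent mass coefficient (cm^2/g)."""
    return kn_total_cross_section(energy_mev) * z / a_mass * AVOGADRO
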