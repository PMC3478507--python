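"""Plane-parallel Monte Carlo photon transport for the air-over-ground geometry.

The source is uniform and infinite in the horizontal plane, so the transport
state reduces exactly to (height/depth z, polar direction cosine u, energy,
weight); horizontal coordinates never enter any score.  This realises a
laterally infinite source with no horizontal cutoff bias: photons emitted per
unit area and detectors of unit area are equivalent by symmetry.

The engine produces K(e, alpha) — air kerma (Gy) at a detector height per
unit photon emission per unit area (photon/m^2) — for mono-energetic sources
distributed exponentially in depth with relaxation (mass) depth alpha in
g/cm^2, or concentrated on a plane at fixed mass depth.  Because depth is
handled in mass-thickness units, results are invariant under changes of the
geometric soil density.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import exp1

from .materials import AIR, SOIL, Material, get_table
from .xsection import ELECTRON_REST_MEV, sample_compton

MEV_TO_J = 1.602176634e-13
#: cm^2/g -> m^2/kg
CM2G_TO_M2KG = 0.1

#: photons are abandoned below this mass depth in soil (g/cm^2); at 3 MeV
#: this is >8 mean free paths, so the neglected return flux is far below
#: Monte Carlo resolution.
KILL_DEPTH_GCM2 = 300.0


@dataclass(frozen=True)
class ExponentialSourceSpec:
    """Mono-energetic source exponentially distributed in the ground.

    ``relaxation_depth`` (alpha, g/cm^2) is the mass depth at which the
    activity concentration falls to 1/e of its surface value; alpha = 0
    degenerates to a plane source on the interface.  ``plane_depth`` selects
    plane-source mode at a fixed mass depth instead (mutually exclusive with
    alpha > 0).
    """

    energy: float  # MeV
    relaxation_depth: float = 0.0  # g/cm^2
    plane_depth: float | None = None  # g/cm^2

    def __post_init__(self) -> None:
        if self.energy <= 0:
            raise ValueError("energy must be positive")
        if self.relaxation_depth < 0:
            raise ValueError("relaxation depth must be >= 0")
        if self.plane_depth is not None:
            if self.plane_depth < 0:
                raise ValueError("plane depth must be >= 0")
            if self.relaxation_depth > 0:
                raise ValueError("plane_depth and relaxation_depth > 0 are exclusive")


@dataclass(frozen=True)
class TransportConfig:
    """Run parameters for the transport engine."""

    n_histories: int = 100_000
    detector_heights: tuple[float, ...] = (1.0,)  # m above the interface
    energy_cutoff: float = 0.01  # MeV; terminated with local deposition
    depth_truncation: float = 20.0  # multiples of alpha
    seed: int = 0
    estimator: str = "plane-crossing"  # or "collision-density"
    n_batches: int = 20
    max_height_m: float = 1000.0  # photons escaping above are abandoned
    u_floor: float = 0.01  # cap of the 1/|u| crossing estimator
    slab_thickness_m: float = 2.0  # collision-density estimator slab
    soil_density: float = SOIL.density  # g/cm^3, geometric only
    uncollided_only: bool = False  # score only never-collided photons
    convergence_threshold: float = 0.10  # stderr/K above this flags a cell

    def __post_init__(self) -> None:
        if self.n_histories <= 0:
            raise ValueError("n_histories must be positive")
        if any(h <= 0 for h in self.detector_heights):
            raise ValueError("detector heights must be positive")
        if self.estimator not in ("plane-crossing", "collision-density"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.n_batches < 2 or self.n_histories < self.n_batches:
            raise ValueError("need at least 2 batches and 1 history per batch")


@dataclass
class KermaGrid:
    """K(e, alpha) on an energy x relaxation-depth x height grid.

    ``K`` and ``stderr`` are in Gy per (photon/m^2), indexed
    [energy, alpha, height]; ``converged`` flags cells whose relative error
    is below the configured threshold.
    """

    energies: np.ndarray
    alphas: np.ndarray
    heights: np.ndarray
    K: np.ndarray
    stderr: np.ndarray
    n_histories: int
    converged: np.ndarray | None = None
    n_capped: int = 0

    def __post_init__(self) -> None:
        self.energies = np.atleast_1d(np.asarray(self.energies, dtype=float))
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        self.K = np.asarray(self.K, dtype=float)
        self.stderr = np.asarray(self.stderr, dtype=float)
        if self.K.shape != (self.energies.size, self.alphas.size, self.heights.size):
            raise ValueError("K shape does not match the grids")
        if self.converged is None:
            self.converged = np.ones_like(self.K, dtype=bool)

    def value(self, energy: float, alpha: float, height: float = None) -> float:
        """Exact-cell lookup (no interpolation)."""
        i = _index_of(self.energies, energy, "energy")
        j = _index_of(self.alphas, alpha, "alpha")
        if height is None:
            height = self.heights[0]
        k = _index_of(self.heights, height, "height")
        return float(self.K[i, j, k])

    def interpolate(self, energy, alpha: float, height: float = None) -> np.ndarray:
        """Log-log interpolation in energy, linear in alpha, at one height.

        Raises for queries outside the tabulated ranges (no extrapolation).
        """
        if height is None:
            height = self.heights[0]
        k = _index_of(self.heights, height, "height")
        e = np.atleast_1d(np.asarray(energy, dtype=float))
        if np.any(e < self.energies[0] * (1 - 1e-9)) or np.any(
                e > self.energies[-1] * (1 + 1e-9)):
            raise ValueError("energy outside the kerma grid range")
        if alpha < self.alphas[0] - 1e-12 or alpha > self.alphas[-1] + 1e-12:
            raise ValueError("alpha outside the kerma grid range")
        # linear in alpha first
        ka = np.empty((self.energies.size,))
        for i in range(self.energies.size):
            ka[i] = np.interp(alpha, self.alphas, self.K[i, :, k])
        out = np.exp(np.interp(np.log(np.clip(e, self.energies[0], None)),
                               np.log(self.energies), np.log(ka)))
        return out if np.ndim(energy) else float(out[0])

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, e in enumerate(self.energies):
            for j, a in enumerate(self.alphas):
                for k, h in enumerate(self.heights):
                    rows.append((e, a, h, self.K[i, j, k], self.stderr[i, j, k],
                                 self.n_histories, bool(self.converged[i, j, k])))
        return pd.DataFrame(rows, columns=[
            "energy_MeV", "alpha_gcm2", "height_m", "K_Gy_per_photon_m2",
            "stderr", "n_histories", "converged"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "KermaGrid":
        import pandas as pd

        df = pd.read_csv(path, comment="#")
        energies = np.unique(df["energy_MeV"])
        alphas = np.unique(df["alpha_gcm2"])
        heights = np.unique(df["height_m"])
        shape = (energies.size, alphas.size, heights.size)
        K = np.full(shape, np.nan)
        err = np.zeros(shape)
        for _, r in df.iterrows():
            i = _index_of(energies, r["energy_MeV"], "energy")
            j = _index_of(alphas, r["alpha_gcm2"], "alpha")
            k = _index_of(heights, r["height_m"], "height")
            K[i, j, k] = r["K_Gy_per_photon_m2"]
            err[i, j, k] = r.get("stderr", 0.0)
        if np.any(np.isnan(K)):
            raise ValueError("kerma grid CSV does not cover the full grid")
        n = int(df["n_histories"].iloc[0]) if "n_histories" in df else 0
        return cls(energies, alphas, heights, K, err, n)


def _index_of(grid: np.ndarray, value: float, what: str) -> int:
    idx = np.nonzero(np.isclose(grid, value, rtol=1e-9, atol=1e-12))[0]
    if idx.size == 0:
        raise KeyError(f"{what} {value} not on the grid {grid}")
    return int(idx[0])


# ---------------------------------------------------------------------------
# source sampling
# ---------------------------------------------------------------------------

def truncation_depth(alpha: float, truncation: float = 20.0) -> float:
    """Mass depth (g/cm^2) beyond which the exponential source is truncated."""
    return min(truncation * alpha, 100.0)


def sample_source_depth(alpha: float, truncation: float, rng, size=None):
    """Sample source mass depths (g/cm^2) from the truncated exponential.

    For alpha = 0 returns exactly zero (plane source on the interface).
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if alpha == 0:
        return np.zeros(size) if size is not None else 0.0
    t = truncation_depth(alpha, truncation)
    u = rng.random(size)
    d = -alpha * np.log1p(-u * (1.0 - np.exp(-t / alpha)))
    return d


def score_plane_crossing(weight, energy, u, height=None, *, u_floor=0.01):
    """Kerma contribution (Gy per photon/m^2) of one crossing of z = height.

    weight * E[J] * (mu_en/rho)_air[m^2/kg] / max(|u|, u_floor); the height
    argument is accepted for interface symmetry but the planar estimator is
    height-independent once the crossing is established.
    """
    mu_en = get_table(AIR).mu_en(energy) * CM2G_TO_M2KG
    e_j = np.asarray(energy, dtype=float) * MEV_TO_J
    denom = np.maximum(np.abs(np.asarray(u, dtype=float)), u_floor)
    out = np.asarray(weight, dtype=float) * e_j * mu_en / denom
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# the transport kernel
# ---------------------------------------------------------------------------

def _transport_batch(source: ExponentialSourceSpec, config: TransportConfig,
                     n: int, rng) -> tuple[np.ndarray, int]:
    """Transport one batch; returns (kerma per height, n_capped)."""
    air_t = get_table(AIR)
    soil_t = get_table(SOIL)
    rho_a = AIR.density  # g/cm^3
    rho_s = config.soil_density
    heights_cm = np.asarray(config.detector_heights, dtype=float) * 100.0
    hmax_cm = config.max_height_m * 100.0
    zkill_cm = -KILL_DEPTH_GCM2 / rho_s
    mu_en_air_m2kg = lambda e: air_t.mu_en(e) * CM2G_TO_M2KG  # noqa: E731

    # source
    if source.plane_depth is not None:
        depth = np.full(n, source.plane_depth)
    else:
        depth = np.asarray(sample_source_depth(
            source.relaxation_depth, config.depth_truncation, rng, size=n))
    z = -depth / rho_s - 1e-9  # cm; tiny nudge keeps depth-0 photons in soil
    u = rng.uniform(-1.0, 1.0, n)
    e = np.full(n, float(source.energy))
    w = np.ones(n)
    collided = np.zeros(n, dtype=bool)

    score = np.zeros(heights_cm.size)
    n_capped = 0
    use_crossing = config.estimator == "plane-crossing"
    slab_half_cm = config.slab_thickness_m * 50.0

    max_steps = 10_000
    for _ in range(max_steps):
        if e.size == 0:
            break
        # one free flight per photon, stepping across the interface as needed
        tau = -np.log(rng.random(e.size))
        alive = np.ones(e.size, dtype=bool)
        in_flight = np.ones(e.size, dtype=bool)
        while in_flight.any():
            idx = np.nonzero(in_flight)[0]
            zi, ui, ei = z[idx], u[idx], e[idx]
            in_air = zi >= 0.0
            mu_lin = np.where(
                in_air,
                air_t.mu(ei) * rho_a,
                soil_t.mu(ei) * rho_s,
            )  # 1/cm
            s_int = tau[idx] / mu_lin
            # distance to the relevant boundary of the current medium
            d_b = np.full(idx.size, np.inf)
            going_up = ui > 0
            going_dn = ui < 0
            # soil -> interface
            m = ~in_air & going_up
            d_b[m] = -zi[m] / ui[m]
            # air -> interface
            m = in_air & going_dn
            d_b[m] = zi[m] / (-ui[m])
            # air -> escape plane
            m = in_air & going_up
            d_b[m] = (hmax_cm - zi[m]) / ui[m]
            step = np.minimum(s_int, d_b)
            z_new = zi + ui * step
            if use_crossing:
                for k, h in enumerate(heights_cm):
                    crossed = ((zi - h) * (z_new - h) < 0.0)
                    if crossed.any():
                        ii = idx[crossed]
                        absu = np.abs(u[ii])
                        n_capped += int(np.sum(absu < config.u_floor))
                        score[k] += np.sum(
                            w[ii] * e[ii] * MEV_TO_J * mu_en_air_m2kg(e[ii])
                            / np.maximum(absu, config.u_floor))
            hit_boundary = d_b < s_int
            tau[idx] -= mu_lin * step
            # nudge across the interface / stop at escape or kill planes
            eps = 1e-9
            z[idx] = np.where(hit_boundary, z_new + np.sign(ui) * eps, z_new)
            in_flight[idx] = hit_boundary
            # photons reaching the escape plane or the soil kill depth die
            dead = (z[idx] >= hmax_cm) | (z[idx] <= zkill_cm)
            alive[idx[dead]] = False
            in_flight[idx[dead]] = False

        # collisions for photons that did not escape
        cidx = np.nonzero(alive)[0]
        if cidx.size == 0:
            break
        zi, ei = z[cidx], e[cidx]
        in_air = zi >= 0.0
        if (not use_crossing) and in_air.any():
            # collision-density estimator: collisions in a slab around each h
            ai = cidx[in_air]
            mu_lin_air = air_t.mu(e[ai]) * rho_a  # 1/cm
            for k, h in enumerate(heights_cm):
                # clip the scoring slab to the air half-space
                lo = max(0.0, h - slab_half_cm)
                hi = h + slab_half_cm
                in_slab = (z[ai] >= lo) & (z[ai] <= hi)
                if in_slab.any():
                    ii = ai[in_slab]
                    score[k] += np.sum(
                        w[ii] * e[ii] * MEV_TO_J * mu_en_air_m2kg(e[ii])
                        / (mu_lin_air[in_slab] * 100.0  # 1/cm -> 1/m
                           * (hi - lo) / 100.0))
        if config.uncollided_only:
            break
        collided[cidx] = True
        table_frac = np.empty((cidx.size, 3))
        table_frac[in_air] = air_t.fractions(ei[in_air])
        table_frac[~in_air] = soil_t.fractions(ei[~in_air])
        r = rng.random(cidx.size)
        proc = np.where(r < table_frac[:, 0], 0,
                        np.where(r < table_frac[:, 0] + table_frac[:, 1], 1, 2))

        # photoelectric: terminate
        survive = proc != 0

        # Compton
        cm = proc == 1
        if cm.any():
            enew, mu_s = sample_compton(ei[cm], rng)
            phi = rng.uniform(0.0, 2.0 * np.pi, int(cm.sum()))
            ui = u[cidx[cm]]
            sin_t = np.sqrt(np.clip(1.0 - mu_s**2, 0.0, None))
            sin_u = np.sqrt(np.clip(1.0 - ui**2, 0.0, None))
            u[cidx[cm]] = np.clip(ui * mu_s + sin_u * sin_t * np.cos(phi), -1.0, 1.0)
            e[cidx[cm]] = enew

        # pair production: the photon is replaced by the two annihilation
        # quanta, emitted isotropically back-to-back (kerma approximation)
        pm = proc == 2
        partners = None
        if pm.any():
            upair = rng.uniform(-1.0, 1.0, int(pm.sum()))
            u[cidx[pm]] = upair
            e[cidx[pm]] = ELECTRON_REST_MEV
            partners = (z[cidx[pm]].copy(), -upair, w[cidx[pm]].copy())

        survive &= e[cidx] >= config.energy_cutoff
        survive &= z[cidx] > zkill_cm  # nothing returns from far below
        keep = np.zeros(e.size, dtype=bool)
        keep[cidx[survive]] = True
        z, u, e, w, collided = z[keep], u[keep], e[keep], w[keep], collided[keep]
        if partners is not None:
            pz, pu, pw = partners
            z = np.concatenate([z, pz])
            u = np.concatenate([u, pu])
            e = np.concatenate([e, np.full(pz.size, ELECTRON_REST_MEV)])
            w = np.concatenate([w, pw])
            collided = np.concatenate([collided, np.ones(pz.size, dtype=bool)])
    else:
        raise RuntimeError("transport did not terminate within the step limit")

    return score / n, n_capped


def simulate_kerma(source: ExponentialSourceSpec,
                   config: TransportConfig) -> KermaGrid:
    """Estimate K(e, alpha) at each detector height for one source.

    Returns a single-energy, single-alpha :class:`KermaGrid`; the standard
    error is estimated from independent batches, and reproducibility is
    guaranteed by the configured seed.
    """
    ss = np.random.SeedSequence(config.seed)
    batch_sizes = np.full(config.n_batches, config.n_histories // config.n_batches)
    batch_sizes[: config.n_histories % config.n_batches] += 1
    scores = np.zeros((config.n_batches, len(config.detector_heights)))
    n_capped = 0
    for b, child in enumerate(ss.spawn(config.n_batches)):
        rng = np.random.default_rng(child)
        scores[b], capped = _transport_batch(source, config, int(batch_sizes[b]), rng)
        n_capped += capped
    K = scores.mean(axis=0)
    err = scores.std(axis=0, ddof=1) / np.sqrt(config.n_batches)
    alpha = source.relaxation_depth if source.plane_depth is None else 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(K > 0, err / np.where(K > 0, K, 1.0), np.inf)
    return KermaGrid(
        energies=[source.energy], alphas=[alpha],
        heights=np.asarray(config.detector_heights, dtype=float),
        K=K[None, None, :], stderr=err[None, None, :],
        n_histories=config.n_histories,
        converged=(rel < config.convergence_threshold)[None, None, :],
        n_capped=n_capped,
    )


def run_grid(energies, alphas, config: TransportConfig) -> KermaGrid:
    """Run the transport over an energy x alpha grid.

    Per-cell seeds derive deterministically from the master seed, so cells
    are independent and the whole grid is reproducible.
    """
    energies = np.atleast_1d(np.asarray(energies, dtype=float))
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    if energies.size == 0 or alphas.size == 0:
        raise ValueError("energy and alpha grids must be non-empty")
    nH = len(config.detector_heights)
    K = np.zeros((energies.size, alphas.size, nH))
    err = np.zeros_like(K)
    conv = np.zeros(K.shape, dtype=bool)
    n_capped = 0
    master = np.random.SeedSequence(config.seed)
    children = master.spawn(energies.size * alphas.size)
    for i, e in enumerate(energies):
        for j, a in enumerate(alphas):
            child = children[i * alphas.size + j]
            cell_cfg = replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
            cell = simulate_kerma(ExponentialSourceSpec(e, a), cell_cfg)
            K[i, j], err[i, j] = cell.K[0, 0], cell.stderr[0, 0]
            conv[i, j] = cell.converged[0, 0]
            n_capped += cell.n_capped
    return KermaGrid(energies, alphas, np.asarray(config.detector_heights, float),
                     K, err, config.n_histories, conv, n_capped)


# ---------------------------------------------------------------------------
# closed-form oracle for the uncollided component
# ---------------------------------------------------------------------------

def uncollided_plane_kerma(energy: float, plane_depth: float,
                           height_m: float) -> float:
    """Uncollided air kerma from an isotropic plane source at a mass depth.

    K = E[J]/2 * (mu_en/rho)_air[m^2/kg] * E1(tau) with tau the total optical
    thickness (mass units) of the soil above the source plus the air below
    the detector.  Serves as the independent closed-form check of the Monte
    Carlo in uncollided-only mode.
    """
    tau = (plane_depth * get_table(SOIL).mu(energy)
           + height_m * 100.0 * AIR.density * get_table(AIR).mu(energy))
    mu_en = get_table(AIR).mu_en(energy) * CM2G_TO_M2KG
    return 0.5 * energy * MEV_TO_J * mu_en * float(exp1(tau))
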