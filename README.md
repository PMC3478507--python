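# groundshine

Effective-dose-rate conversion coefficients for radionuclides deposited in
the ground, for environmental radiation dosimetry and accident consequence
assessment.

After atmospheric releases (Chernobyl, Fukushima), deposited radionuclides
migrate into soil and their activity concentration is well approximated by
an exponential profile in mass depth.  Evaluating public exposure then needs
coefficients that link the deposit (Bq/m²) to an effective dose rate (Sv/h)
as a function of the relaxation depth α (g/cm²) — the mass depth at which
the concentration has fallen to 1/e of its surface value.

`groundshine` implements the standard factorised pipeline for these
coefficients:

- a **plane-parallel Monte Carlo photon transport engine** for the
  air-over-ground geometry (air 1.2×10⁻³ g/cm³ over soil 1 g/cm³, an
  SiO₂/Al₂O₃/Fe₂O₃/H₂O mixture), producing air-kerma coefficients
  *K*(*e*, α) in Gy per (photon/m²) at configurable detector heights, with
  photoelectric absorption, Klein–Nishina Compton scattering and pair
  production (coherent scattering excluded);
- a **folding engine** implementing

  *E*(*e*, α) = *E*(*e*) · *K*(*e*, α)  and
  *E*(N, α) = *c* Σᵢ *y*ᵢ · *E*(*e*ᵢ) · *K*(*e*ᵢ, α),

  where *E*(*e*) (Sv/Gy) is an air-kerma-to-effective-dose curve for a plane
  source at 0.5 g/cm² mass depth, (*e*ᵢ, *y*ᵢ) are a nuclide's photon line
  energies and yields per decay, and *c* = 3600 s/h;
- **ICRP 103 and ICRP 60 tissue weighting** of organ equivalent doses
  (sex-averaged, remainder rules simplified as documented);
- a **decay-photon library** reader with a small bundled
  (ICRP-107-style, approximate) line library;
- **analysis routines over the published coefficient tables** for reference
  adults and an 8-week-old Baby phantom (72 nuclides × 14 relaxation
  depths, packaged as checksummed fixtures): body-size ratios, depth
  attenuation factors and ratio-distribution statistics;
- **synthetic generators** for dose curves, kerma grids, spectra and
  organ-dose sets so the full pipeline is testable without external data.

Real *E*(*e*) curves come from voxel-phantom transport published in the
companion literature and are user-supplied; the package does not re-derive
organ doses (see `docs/methods.md` for scope and assumptions).

## Worked example

Air-kerma depth ratios for mono-energetic sources at 1 m height
(200 000 histories per cell):

```python
from groundshine.transport import TransportConfig, run_grid

cfg = TransportConfig(n_histories=200_000, seed=1)
grid = run_grid([0.05, 2.0], [0.0, 5.0], cfg)
for i, e in enumerate(grid.energies):
    r = grid.K[i, 1, 0] / grid.K[i, 0, 0]
    print(f"{e:4.2f} MeV: K(0) = {grid.K[i,0,0]:.3e} Gy per photon/m^2, "
          f"K(5)/K(0) at 1 m = {r:.3f}")
```

prints

```
0.05 MeV: K(0) = 7.986e-17 Gy per photon/m^2, K(5)/K(0) at 1 m = 0.171
2.00 MeV: K(0) = 1.958e-15 Gy per photon/m^2, K(5)/K(0) at 1 m = 0.431
```

Burying a 2 MeV emitter exponentially with α = 5 g/cm² leaves about 40 % of
the surface-deposit kerma; for a 50 keV emitter soil shielding is much
stronger and leaves under 20 %.

The same statistics are available from the command line; over the packaged
printed tables:

```console
$ groundshine analyze-tables --stat distribution --alpha 0 --out hist.csv
subset distribution at alpha=0.0: 80.6 % of nuclides below ratio 1.5

$ groundshine decay-info Ba-137m
Ba-137m: 3 photon lines, total yield 0.9680 per decay
      32.20 keV   0.0568
      36.40 keV   0.0132
     661.66 keV   0.8980
```

i.e. for four out of five tabulated nuclides the Baby/adult effective-dose
ratio stays below 1.5; the exceptions are soft-photon emitters (the ratio
reaches ≈ 3.2 for Sm-151).

Other entry points: `groundshine simulate-kerma` (transport grids to CSV),
`groundshine fold` (coefficient tables from a decay library, a dose curve
and a kerma grid), `groundshine effective-dose` (tissue weighting of an
organ-dose CSV) and `groundshine gen-fixtures` (synthetic inputs).

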