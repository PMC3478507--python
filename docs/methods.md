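# Methods

This note records the physical model, the numerical choices and the known
limitations of `groundshine`, in the spirit of the model documentation of
packages such as msprime or statsmodels: enough detail that a user can judge
what a result means and what it does not.

## Geometry and transport model

The environment is two homogeneous half-spaces separated by an infinite
plane: air (density 1.2×10⁻³ g/cm³, N₂/O₂/Ar by mass 75.52/23.20/1.28 %)
above soil (density 1.0 g/cm³; SiO₂/Al₂O₃/Fe₂O₃/H₂O with weight fractions
58.3/16.7/8.3/16.7 %).  The source is mono-energetic, isotropic, uniform
and infinite in the horizontal plane, distributed in depth either
exponentially with relaxation mass depth α (g/cm²) or on a plane at fixed
mass depth.

Because source and geometry are laterally invariant, the transport state
reduces exactly to (z, u, E, w): height/depth, polar direction cosine,
energy, weight.  Horizontal coordinates never enter any score, so the
laterally infinite source is simulated with no truncation bias.  Depth is
handled in mass-thickness units; the geometric soil density is a free
parameter that provably (and, in the test suite, verifiably) does not
affect the photon field in air when source depths are fixed in g/cm².

Interaction processes are photoelectric absorption, incoherent (Compton)
scattering and pair production; coherent scattering is excluded from the
total cross section.  Choices per process:

- **Compton**: free-electron Klein–Nishina.  Scattering angles/energies are
  sampled with Kahn's composition–rejection method, which is exact for the
  KN density at all energies; the sampled pair always satisfies the Compton
  kinematic relation to machine precision.  Electron binding (Doppler
  broadening, incoherent scattering functions) is neglected — in the soil
  constituents this overestimates the incoherent cross section below
  ~50 keV, where photoelectric absorption dominates anyway.
- **Photoelectric**: history terminated; fluorescence is neglected (low-Z
  media, sub-keV K X-rays except iron's at 6.4 keV, below the transport
  cutoff).
- **Pair production**: the photon is replaced by the two 0.511 MeV
  annihilation quanta, emitted isotropically back-to-back from the
  interaction point (kerma approximation; positron range and in-flight
  annihilation neglected — standard below 3 MeV).

Photons are terminated below **10 keV** (absorbed within millimetres of
soil; their air kerma at 1 m is negligible), beyond **1000 m height**
(≈ 5 mean free paths of air at 2 MeV; the neglected return scatter is far
below Monte Carlo resolution), and **300 g/cm² below ground**.  The
exponential source is truncated at 20α, capped at 100 g/cm²; the neglected
tail carries e⁻²⁰ of the activity.

## Scoring

Air kerma is scored with a **surface-crossing planar-flux estimator**: each
crossing of a detector plane at height h contributes
w · E[J] · (μ_tr/ρ)_air(E) / |u|, with the 1/|u| divergence capped at
|u| = 0.01 (capped events are counted and reported).  A
**collision-density estimator** (collisions in a slab around the detector
plane, clipped to the air half-space, default 2 m thick) is provided as an
independent cross-check; it carries much higher variance since air
collisions near the ground are rare, and the slab average biases it
slightly where the field has curvature in height.

Kerma uses the mass energy-*transfer* coefficient composed from the same
three processes that drive the transport (photoelectric: full energy;
Compton: Klein–Nishina mean electron fraction; pair: (E − 1.022 MeV)/E).
Radiative losses distinguish μ_tr from μ_en by < 1 % below 3 MeV in air and
are neglected, so transport and scoring share one self-consistent physics
model.

Standard errors come from independent batches (default 20) seeded by
spawned `SeedSequence` children; grid cells likewise get independently
derived per-cell seeds, so results are reproducible bit-for-bit for a given
master seed and any cell subset is statistically independent.

An analytic oracle anchors the engine: in uncollided-only mode the kerma
from a plane source at mass depth d equals (E/2)·(μ_tr/ρ)_air·E₁(τ) with τ
the total optical thickness in mass units; the exponential-source case
follows by quadrature over depth.  The test suite holds the engine to 3σ
agreement with these closed forms.

## Photon interaction data

No runtime download is performed; the tables under
`src/groundshine/data/attenuation/` are bundled and regenerable with
`tools/build_attenuation_tables.py`.  They are built as follows:

- anchor values of the *total* mass attenuation coefficient (including
  coherent scattering) for H, C, N, O, Al, Si, Ar and Fe at 12 energies
  between 10 and 300 keV, transcribed from the standard published
  compilation for elements;
- the photoelectric component is extracted by subtracting the analytic
  Klein–Nishina incoherent term and a screened-Rayleigh estimate
  (Thomson angular factor × hydrogen-like dipole form factor with a
  Thomas–Fermi Z^(-1/3) screening length, its single multiplier calibrated
  once against the published coherent component of air at 30–100 keV);
  beyond the last energy where photoelectric exceeds 3 % of the total, a
  log-log power-law continuation is used (photoelectric is < 1 % of the
  total there);
- pair production uses a near-threshold power law in (k−2)/k (k = E/mc²),
  scaled by Z(Z+1)/A and calibrated on the published pair component of air
  at 2–3 MeV;
- compounds and materials follow mass-fraction additivity, on a 60-point
  log grid over 0.01–3 MeV, interpolated log-log.

Accuracy: composed air μ_tr agrees with the classic published air μ_en
within ~4 % at 50 keV and < 1 % above 100 keV (a characterisation test pins
this); totals for air and soil track the compilation-minus-coherent within
a few percent.  Residual uncertainty is largest (~10–20 %) for the
photoelectric component of iron above 100 keV, where it is a small share of
the soil total.  All headline outputs of the engine are kerma *ratios*,
which are insensitive at this level.

## Folding

`fold_mono` and `fold_nuclide` implement the factorisation
E(e, α) = E(e)·K(e, α) and E(N, α) = c Σ yᵢ E(eᵢ) K(eᵢ, α), c = 3600 s/h
(exposed for unit audits).  The central modelling assumption, inherited
from the established methodology for environmental sources, is that one
air-kerma-to-effective-dose curve — computed for a plane source at
0.5 g/cm² mass depth — represents exponential sources of any relaxation
depth.  For α ≤ 3 g/cm² this holds within a few percent, and within ~15 %
even in the volume-source limit; this error bound is inherent to every
folded coefficient and is *not* testable inside this package (it would
require phantom organ-dose transport).

Numerical choices: log-log interpolation in energy for both E(e) and K
(photon data are near power laws between nodes), linear interpolation in α
(K varies smoothly on the printed 0–100 g/cm² grid); **no extrapolation**
beyond either table's range — out-of-range queries are hard errors, since
silent extrapolation is the classic dosimetry bug.  Photon lines below the
transport cutoff (default 10 keV, or the coverage limit of the supplied
curve/grid when folding from the command line) are dropped; a dropped yield
fraction ≥ 5 % triggers a warning, and a spectrum with no retained lines
folds to 0 with a warning rather than an error (pure beta emitters are
legitimate inputs).

## Tissue weighting

Effective dose is the sex-averaged, tissue-weighted sum
Σ_T w_T (H_T^M + H_T^F)/2 with the published w_T sets of ICRP 103 and
ICRP 60 embedded as data files.  Remainder handling is simplified to the
unweighted arithmetic mean of each sex's designated remainder tissues
(13 for ICRP 103 with prostate/uterus sex-specific; 10 for ICRP 60 with
uterus female-only).  ICRP 60's mass-weighted remainder rule and its
splitting rule are *not* applied — organ masses are phantom-specific and
out of scope — and the same sex-averaging is applied under both schemes,
matching the practice of applying ICRP 60 factors to the same
reference-phantom organ-dose sets.  Radiation weighting is trivial for
photons (w_R = 1).

## Printed coefficient tables

The packaged fixtures transcribe the published effective-dose conversion
coefficients for 72 radionuclides × 14 relaxation depths × 2 phantoms
(reference adults; 8-week-old Baby), with the printed scientific-notation
strings preserved verbatim and SHA-256 digests checked at load.  One
printed symbol ("Ma" for mass number 54) is an evident typographical
artefact and is transcribed as Mn-54.  Every row is non-increasing across
the 14 depths; this is asserted on load as a transcription guard.

The published distribution statistics cover 185 nuclides; only the printed
72-nuclide subset is available here, so all summary outputs are labelled
"subset".  The subset reproduces the published qualitative statements: the
Baby/adult ratio reaches ≈ 3.2 (Sm-151, photons below 20 keV), exceeds 1.7
at all depths for Am-241 (60 keV), is ≈ 1.3 for Ba-137m/Co-60/Bi-214, stays
below 1.5 for > 80 % of nuclides, and the 0→5 g/cm² depth factor lies in
[2, 5] for the higher-energy emitters.  The depth underlying the published
distribution statistics is not stated; α = 0 is used by default.  "Within
50 % body-size difference" is interpreted as ratio < 1.5 (the Baby
coefficients exceed the adult ones throughout the printed tables).

## Synthetic data

The generators emulate only the *structural* properties the pipeline
assumes: smooth positive E(e) curves of order 0.1–2 Sv/Gy (bounded-slope
log-log random walks), kerma grids K₀(e)·exp(−α/λ(e)) with λ increasing in
energy (soil shielding bites harder at low energy), line spectra with
yields in (0, 1], and organ-dose sets with bounded max/min anisotropy.
Magnitudes bracket the printed coefficient range (10⁻¹⁸–10⁻¹¹ Sv/h per
Bq/m²) so extreme-exponent formatting is exercised.  They do **not**
emulate phantom anatomy, realistic organ-dose physics or real nuclide
spectra: pipeline tests passing on synthetic inputs demonstrate the
correctness of the plumbing and the stated invariants, not agreement with
any published absolute coefficient.  All generators are pure functions of
an explicit seed-carrying spec; there is no hidden RNG state.

The bundled decay-photon library is an approximate transcription
(yields rounded, X-ray multiplets binned into representative lines) that is
adequate for exercising the folding pipeline and for the qualitative
spectral statements in the analyses; it is not a dosimetric-grade library.

## Problem sizes

The ratio checks in the acceptance suite use 10⁶ histories per (energy, α)
cell — relative standard errors of a few per mil at 1 m — and the
property-level Monte Carlo checks use 0.8–1.5×10⁵ histories, sized so that
3σ criteria are meaningful while the whole suite stays interactive.
`scripts/acceptance.py` uses 10⁶ histories per cell.

## Known limitations

- Absolute reproduction of the printed coefficient tables is out of scope:
  it requires the externally published E(e) curves and the original K
  datasets.  The packaged fixtures are the reference for table analyses;
  the transport engine is validated against closed forms, internal
  cross-checks and the published *ratio* statements.
- The cross-section model is a compiled approximation (see above), not a
  licensed evaluated library; users needing evaluated-library fidelity can
  drop in replacement CSVs with the same schema.
- No electron transport, bremsstrahlung, ground roughness, atmospheric
  density gradients, or decay-chain ingrowth (daughter spectra such as
  Ba-137m must be selected explicitly).
- Skyshine-only and submersion geometries, and non-exponential depth
  profiles other than the plane special case, are not modelled.
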