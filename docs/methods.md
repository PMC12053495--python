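# Methods

## The model

`phaseseed` treats crystallographic phasing as a fitting problem: given
observed amplitudes |F_obs(h)| over the symmetry-independent reflections
of a non-centrosymmetric crystal, estimate the phases φ(h). The
"parameters" are the phases themselves; the data constraint is the
amplitude set; the regularizer is the atomistic hypothesis imposed in
real space. The package studies how much *initial* phase information — a
seed of reflections carrying true but coarsely discretized phases — the
dual-space refinement needs in order to converge.

### Conventions

* Structure factors use F(h) = Σ_j f_j exp(+2πi h·x_j) with fractional
  coordinates; phases are degrees in [0, 360).
* Symmetry operators act as x' = Rx + t; Miller indices transform as
  h' = hR with φ(hR) = φ(h) − 360°·(h·t).
* A reflection is centric when some rotation maps h to −h; its phase is
  then restricted to {φ₀, φ₀ + 180°} with φ₀ = 180°·(h·t) mod 180°.
  ε(h) counts rotations fixing h; systematically absent reflections
  (some op fixes h with non-integral h·t) are excluded throughout, as is
  F(000). Friedel mates are merged; the orbit representative is the
  lexicographically largest index triple.
* Atomic scattering factors are the International Tables 4-Gaussian
  fits (via gemmi), with isotropic Debye–Waller damping exp(−B s²),
  s = sinθ/λ. Anomalous scattering, anisotropic displacement and
  twinning are not modelled.
* Supported space groups: P1, P2₁, C2, P2₁2₁2₁, P3₁, R3 (hexagonal
  setting), shipped as an xyz-triplet table. They cover identity-only
  symmetry, screw axes, centring, and trigonal groups without restricted
  reflections; other non-centrosymmetric groups can be added as operator
  lists. Centrosymmetric groups are rejected: with a binary phase the
  discretization question this package studies is void.

### Pre-processing (discretization + seeding)

The sampling grid holds k ∈ {2, 3, 4, 6} equispaced values 360°·j/k. The
4-point grid is {0°, 90°, 180°, 270°}; discretization maps a phase to
the nearest grid value on the circle, exact ties breaking toward the
smaller angle so that runs are deterministic. Non-seed general
reflections get uniform-random phases, then discretized; non-seed
centric reflections get a random choice of their two allowed values.
Seed general reflections get the discretized true phase; seed centric
reflections the exact true phase (their allowed pair is already a
2-point grid). Seed size is |seed| = round(Perc_seed·N_refl/100) for all
strategies except `hkl_sorted`, where the box bound h_max fixes the
membership instead.

Under these rules the expected pre-EDM MPE is analytic: a non-seed
reflection contributes 90° on average, a seed general reflection the
mean discretization error 90°/k, a seed centric reflection 0°, so
MPE(p) ≈ (1−p)·90° + p(1−c)·90°/k for centric fraction c — linear in the
seed fraction p. The measured curves reproduce this (R² > 0.99), which
is why the MPE at a given (k, Perc_seed) barely depends on the
structure.

MPE is the unweighted mean circular difference over symmetry-independent
measured reflections, computed without origin or enantiomorph search:
the seed pins the origin, so an origin-shifted "solution" is counted as
wrong. This convention makes the unseeded (Perc_seed = 0) baseline
essentially unsolvable in polar groups, where the origin is continuous —
a known difference from phasing programs that align the solution to the
model before scoring.

### Phasing (EDM engine)

Each cycle: (1) Fourier synthesis of ρ on an FFT grid with spacing
≤ d_min/3 (smallest 5-smooth sizes; oversampling configurable) from the
full-sphere expansion of the unique reflections; (2) density
modification: keep the largest `keep_fraction` of grid points, zero the
rest and all negative density; (3) inversion; measured reflections keep
|F_obs| and adopt the new phase, centric phases snapped to the nearest
allowed value. With `free_lunch` enabled, unmeasured reflections with
d ∈ [extension_factor·d_min, d_min) ride along carrying fully calculated
amplitude and phase from the modified map (unscaled); they stabilize the
recycling and are never counted in MPE or Rf. Phase updates are hard
replacement — no σA-style weighting and no extra weight on seed
reflections; pre-processing and phasing are deliberately independent
stages.

Stopping: at most `n_cycles` (default 200); early stop when Rf changes
by less than 1e-5 for 15 consecutive cycles (converged) or rises by more
than 0.1% relative for 10 consecutive cycles (diverged → unsolved). The
0.1% materiality guard exists because at a converged plateau Rf drifts
upward by ~1e-6 per cycle, which is not divergence.

A run is *solved* when the final MPE ≤ 45° (configurable): midway
between random phases (90°) and an essentially correct map (< 20°), and
comfortably below the pre-EDM errors (65–85°) from which solvable seeds
start. No numerical solved-criterion exists in the literature this
emulates; this threshold is this package's convention.

### Parameter defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| `keep_fraction` | 0.05 | on 10–15-atom fixtures at ≤1 Å, 5% truncation retains ~25 grid points per atom and solves 9–10/10 seeded runs; 3% over-truncates small cells and drops the rate below 50%. For protein-scale maps a gentler 0.15 is suggested. |
| `n_cycles` | 200 | runs converge or stall well before this on the fixture sizes studied. |
| `free_lunch`, `extension_factor` | on, 0.8 | extrapolating one resolution shell beyond the data measurably lowers the fixed-point MPE (≈8° vs ≈21° from true phases on the standard fixture). |
| `solved_mpe_threshold` | 45° | see above. |
| grid spacing | d_min/3 | standard anti-aliasing margin for point-nonlinear real-space operators. |
| E-normalization | 10 equal-population shells in 1/d², ε-weighted | enforces ⟨E²⟩ = 1 per shell, reconciling the global definition with resolution independence. |
| Rf | least-squares scale on by default | the comparisons of interest (extracted vs true amplitudes) are on different scales. |

The true-phase fixed point of the engine sits ~8° from the truth, not at
0°: hard truncation scatters the phases of weak reflections, and the
unweighted MPE counts them fully. This is a property of truncation EDM,
not a convergence failure; amplitude-weighted error measures would hide
it.

## Synthetic data

The generator emulates the test regime of phase-seeding studies: random
non-centrosymmetric structures with n_asym non-H atoms (size presets:
small 20 at 0.85 Å, medium 150 at 1.0 Å, large 350 at 1.8 Å), C/N/O
composition with ~70 atoms per 1000 Å³ (organic packing density),
rejection-sampled so all symmetry- and lattice-expanded pairs are
≥ 1.2 Å apart, B factors uniform in a size-appropriate range, optional
single heavy atom (Ba/Mo) per asymmetric unit. Cell shapes follow the
crystal system (monoclinic β = 100°, hexagonal a = b, γ = 120°) with
unequal axis ratios to avoid accidental metric symmetry.

Observations are f_obs = f_true(1 + ε), ε ~ N(0, σ), clipped at zero;
phases noise-free. The powder mode sorts reflections by
2θ = 2 asin(λ/2d) (Cu Kα), clusters runs with gaps below a peak width,
and redistributes each cluster's multiplicity-weighted intensity equally
among members — deterministic equipartition, the worst-case model of
naive intensity extraction. The default width 0.6° 2θ puts the
amplitude degradation at Rf ≈ 42% against the true amplitudes,
matching the error level typical of overlap-limited extraction; it is
wider than a real diffractometer's FWHM because the synthetic cells are
small and their reflection lists sparse in 2θ.

What the generator does **not** emulate: solvent and disorder,
anisotropic displacement, realistic completeness/σ(F) profiles,
resolution-dependent noise, Le Bail/Pawley correlations within overlap
groups, or preferred orientation. Passing tests therefore demonstrate
the behaviour of the *method* under controlled error models, not
end-to-end performance on real data.

## Study protocol

`find_perc_lim` walks the Perc_seed grid (default 10…100, step 10) and
reports the first value at which the majority of `n_repeats` (default 5)
independent seedings solve; `MPE_lim` is the mean pre-EDM MPE there.
Repeats-plus-majority replaces the single deterministic run of phasing
suites built on one program trial, making the estimate stable under RNG
choice. Unsolvable structures carry explicit `None` and are counted,
never dropped, by `aggregate`.

Problem sizes throughout the tests and the acceptance script — 10–40
atom structures, 0.8–1.0 Å data, cohorts of 10, 5 repeats — were chosen
so a full sweep runs in ~1 minute; the measured quantities (seeding
MPEs, linearity, strategy ordering) are size-stable, which the
medium/large presets let a user verify at leisure.

## Known limitations

* Absolute Perc_lim values depend on the EDM parameterization; published
  values obtained with proprietary, differently-tuned engines (tangent
  stages, RELAX origin correction, solvent envelopes) will differ
  especially for the plain `random` strategy, which our
  deliberately-simple truncation engine handles less efficiently. The
  *ordering* of strategies and the pre-EDM MPE levels are robust.
* No origin/enantiomorph alignment in MPE: unseeded baselines read as
  unsolved even when the map is a translated copy of the truth.
* One RNG stream per run: seed selection draws first, phase assignment
  second; changing either draw count changes downstream numbers for the
  same seed.
* Powder support is the amplitude-degradation operator only — no
  profile synthesis or real extraction.
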