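# Methods

## Model and procedure

The package estimates thermodynamic-limit fluctuation properties from
finite open subvolumes of a closed NVT simulation box (the small-system
method). The observation volumes are cylinders and cylindrical shells
around a fixed z-aligned axis:

1. **Counting.** For a subvolume with radial interval `[r_in, r_out)` and
   axial window `[z0, z0+L)`, solvent-oxygen centres are counted using
   the x,y minimum image for the radial distance and periodic wrap in z.
   Half-open intervals make concentric shells and stacked windows
   partition space exactly; particles are points (no excluded-volume or
   molecule-splitting corrections).
2. **Fluctuation profile.** For each height `L` the window is translated
   along the axis in steps of `z_step` (default 0.1 nm) and counts are
   pooled over all placements and frames, giving
   `1/Γ(L) = (⟨N²⟩ − ⟨N⟩²)/⟨N⟩`.
3. **Extrapolation.** `1/Γ(L)` is fitted by ordinary least squares
   against `1/L` inside a window of intermediate heights; the intercept
   is the `L → ∞` limit. For bulk solvent the per-radius intercepts are
   fitted once more against `1/rc`; the resulting intercept (`1/L` and
   `1/rc` both → 0) converts to the isothermal compressibility via
   `1/Γ∞ = ρ k_B T χ_T` with `k_B = 0.1380649 bar·nm³/K` (so that
   ρ in nm⁻³ and T in K give χ in bar⁻¹).
4. **Uncertainty.** The trajectory is split into `n_blocks = 4`
   contiguous blocks; every quantity — including the fit intercepts,
   which are refitted per block — is recomputed per block, and the
   standard error is the between-block scatter divided by √n_blocks.
   Overlapping z-translations are deliberately pooled as if independent;
   their correlation is absorbed entirely by the block SE.

Hydration shells are delimited from the proximal radial distribution
function `g_p(r)` (cylindrical annuli of width `dr` over the full box
height, normalised by the bulk density and annulus volume). The inner
boundary `r1` of the first shell is the smallest radius at which the
cumulative mean solvent count in the solid cylinder of height `lz`
exceeds one molecule (midpoint quadrature; `r1` is reported as the upper
edge of the crossing bin). Outer boundaries are successive local minima
of the smoothed `g_p` beyond its first maximum.

Excess shell properties subtract, from each polymer-shell quantity, the
same quantity computed in shells of *identical radii* in a pure-solvent
system (axis through the box centre). Both legs must share radii, fit
windows, density convention and temperature — a mismatch is a hard
error. Standard errors combine in quadrature. Finite-height differences
`Δ1/Γs(L)` are taken pointwise on the shared `L` grid (matching
tolerance: half a grid spacing, no interpolation).

## Key parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| `z_step` | 0.1 | nm | translation step of the observation window; matches the L-grid spacing |
| L grid | 0.1, 0.2, … | nm | heights of the observation window, up to `lz` |
| bulk L fit window | [1.0, 2.0] | nm | intermediate regime between particle granularity and box-size depletion |
| shell L fit window | [1.2, 2.5] | nm | as above, for shell profiles |
| `rc` fit window | rc < 1.5 | nm | linear regime of `1/Γ(rc)` vs `1/rc` |
| `n_blocks` | 4 | — | contiguous trajectory windows for block averaging |
| pRDF `dr` | 0.005 | nm | fine enough that boundary positions are bin-limited |
| smoothing window | 5 | bins | centred moving average before minima detection |
| H-bond criterion | 0.35 nm, 30° | — | standard geometric O–O distance / H–O···O angle cutoffs |
| water models | TIP4P/2005 (σ=0.31589 nm, ε=0.7749 kJ/mol), SPC/E (0.3166, 0.650) | — | oxygen LJ self-parameters entering the mixing rule |
| α grid | 1, 2, 4, 6, 8, 10, 12, 15, 20 | — | repulsion scalings of the bead–water potential |

All fit windows are configuration: the "linear regime" is a judgement
call, so the defaults above are starting points, and every output embeds
the resolved settings.

The density entering the shell compressibility conversion is switchable:
`"shell"` (default) uses the shell-local density
`⟨N_shell⟩/(shell volume at L = lz)`, `"bulk"` the box-average solvent
density. The shell-local choice makes `χ_s` an intensive property of the
shell's own material, which is the natural reading for a shell-resolved
compressibility; because the excess subtraction uses the same convention
on both legs, the sign structure of `Δχ_s` is insensitive to the choice.

## What the synthetic generators emulate

* `generate_ideal_gas` — a fixed number `N_b = round(ρV_b)` of
  independent uniform points per frame. Counts in any subvolume are
  exactly Binomial(`N_b`, `v/V_b`), so `1/Γ = 1 − v/V_b` is known in
  closed form. This isolates sampler and extrapolation correctness from
  all solvent physics.
* `generate_radial_profile` — an inhomogeneous Poisson process with
  intensity `ρ·g*(r)` around the axis (thinning), the oracle for the
  pRDF estimator and boundary detector.
* `generate_neighbor_geometry` — perfect-tetrahedral, collinear and
  uniform-random neighbour sets with `q_tet` = 1, −3 and mean 0.
* `generate_bead_string_system` — a rigid z-periodic bead chain with a
  cylindrical solvent exclusion zone; the solvent count is fixed at
  `round(ρ·V_free)` so the density outside the exclusion radius equals ρ.
* `rigid_water_frame` — ideal three-site waters (O–H 0.09572 nm, H–O–H
  104.52°) at controlled orientations for hydrogen-bond tests.

These fixtures have **no** inter-particle correlations, hydrogen-bond
network, or realistic pair structure. Passing tests therefore certify
the estimators, geometry, fits and error propagation — not that real
water reproduces any particular χ_T, q_tet, or crossover value. Those
physical numbers require real-water MD trajectories supplied by the
user.

## Numerical choices and degenerate inputs

* Counting uses `searchsorted` on per-frame sorted z-coordinates with a
  periodically extended cumulative count — exact integer counts,
  verified against an O(N) brute-force recount.
* An empty subvolume at some `L` yields an undefined `1/Γ` recorded as
  NaN with a warning; fits require ≥ 3 defined points in the window.
* OLS is unweighted by default; a `1/SE²`-weighted variant is available.
  Fit quality is reported as R² with per-point residuals.
* Boundary detection breaks plateau ties towards smaller r and requires
  an intervening maximum between successive minima; requesting more
  shells than exist is an error that names the number found.
* Within the closed box, `1/Γ` of an uncorrelated system is depleted by
  exactly `v/V_b`. Validation pipelines therefore use radii with
  `v ≪ V_b`; with the 6-nm validation box, radii ≤ 0.75 nm keep the
  residual depletion of the two-stage extrapolation below 3%, within the
  5% recovery target of the acceptance suite.
* The pooled variance estimator carries an `O(1/F_block)` downward bias
  (the block grand mean absorbs the frame-level count variance). The
  test-suite oracle includes its leading term
  `(L/lz)² var(n_in)/F_block`; at ≥ 500 frames per block it is well
  below the statistical error.
* Problem sizes in the validation suite (2000 frames for the binomial
  oracle, 300–400 frames for null and recovery tests, 10⁵ samples for
  the q_tet Monte-Carlo) were chosen so each closed-form check resolves
  its target at 3σ.

## Known limitations

* Orthorhombic boxes only; the axis is fixed along z (a rigid, stretched
  solute). Flexible polymers would need dynamical observation volumes.
* NVT analysis: box fluctuations (NPT) are not supported.
* No grand-canonical reweighting, no Kirkwood–Buff integrals, no
  spherical/cubic subvolumes (straightforward extensions; fluctuation
  scaling is shape-independent at matched surface-to-volume ratio).
* Hydrogen-bond analysis assumes GROMACS-style site ordering (each
  oxygen followed by its hydrogen/virtual sites) and needs explicit
  hydrogens; oxygen-only trajectories support fluctuation and q_tet
  analyses only.
* The binary formats XTC/TRR/DCD are out of scope; convert to GRO/XYZ
  first.
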