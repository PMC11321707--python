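# Methods

`silafract` analyses the solution-state templates of biomimetic silica
formation: short silica-precipitating peptides (the diatom-derived 19-mer
R5, SSKKSGSYSGSKGSKRRIL, and its phosphorylated analogues) that counterions
(inorganic phosphate or long-chain polyamines, LCPA) bridge into trimeric
building blocks, which in turn aggregate into larger supramolecular
assemblies on whose surface silica nucleates. The package computes the
structural and NMR observables used to characterize those templates and
ships a synthetic-data generator with known ground truth, so every stage of
the analysis can be validated without experimental data.

## Fractal-cluster metrics

For a cluster of peptide chains the package computes, per frame or averaged
over a trajectory window:

- radius of gyration `Rg` (mass-weighted RMS distance from the centre of
  mass, Å; chains straddling a periodic boundary are unwrapped first);
- molecular volume `V_mol = κ·Mw` with κ = 1.21 Å³/Da, the standard protein
  specific-volume prefactor, and `Mw` the cluster's total peptide mass;
- compactness `φ = V_mol / ((4/3)π Rg³)`;
- contact valency: chains are in contact when any bead pair comes within
  4.5 Å surface-to-surface distance (distance minus the bead radii; the
  criterion is configurable). Valency is the mean number of distinct
  contact partners per monomer; a bead-pair-count mode is also available.
  Counterion beads never count toward peptide–peptide contacts; chain pairs
  sharing a nearby counterion are reported separately as bridges.
- fractal dimension `d_f = 3(1 − log φ / log valency)`, evaluated on the
  largest connected cluster. The formula is log-base invariant and has the
  exact limits d_f = 3 at φ = 1 and d_f = 0 at φ = valency; it is reported
  with an `undefined` flag when valency ≤ 1 or φ ≤ 0 and an `out-of-range`
  flag (never clipped) when the value leaves [0, 3].

### Where the analytic d_f is meaningful

The compactness-valency formula assumes a hierarchically packed cluster
whose compactness sits between 1 and the valency, which is the regime of
dense, droplet-like assemblies. Applied across *extreme* morphologies at
equal mass, it inverts the physical ordering: a rod has a much larger `Rg`,
hence a much smaller cluster-level φ, hence (log φ < 0) a *larger* analytic
d_f than a compact cluster. Because d_f is strictly decreasing in φ at
fixed valency, and valency is intentionally morphology-independent here, no
parameter choice restores the ordering. A hierarchical reading that
evaluates φ at the *monomer* level (constant per peptide) and lets the
valency carry the morphology signal would restore the physical ordering;
the package computes the cluster-level form throughout, and relies on the
independent mass-radius estimator whenever morphologies must be ranked.

### Independent mass-radius estimator

`mass_radius_dimension` fits the slope of log N(<r) against log r, where
N(<r) counts beads within r of the cluster's centre of mass, over
r ∈ [2·bead radius, Rg] (24 log-spaced radii). Radii enclosing fewer than
five beads are dropped (the centre of mass can sit in a packing void and
such counts carry no scaling signal), and residuals are weighted by √N
(Poisson counts: var log N ≈ 1/N). This estimator never sees φ or the
valency and serves as the oracle for generated morphologies; on 50-block
assemblies it recovers ≈1.0 / 1.8 / 2.7 for linear / planar / compact
growth.

## Synthetic-data generator

**Building blocks.** One bead per residue (radius 3.0 Å, average residue
masses from the standard table plus one water per chain), chains grown as
confined self-avoiding random walks (bond 3.8 Å, confinement radius 6 Å,
relaxed 5% per restart so crowded seeds still terminate); three chains per
block, bridged by counterion beads (radius 2.0 Å; phosphate 94.97 Da or a
single-bead LCPA at 285 Da) between the arginine-rich linker sites of
cyclically adjacent chains. No two non-bonded beads sit closer than 0.8×
the sum of their radii. The resulting trimer has Rg ≈ 1.0 nm, i.e. the
nanometre scale of the trimeric species seen in solution.

**Assemblies.** Rigid copies of a block are aggregated under a chosen
morphology: `linear` (blocks attached along one axis), `planar` (square
spiral in a plane), `compact` (centre-seeking ballistic aggregation: each
block approaches the cluster along a straight line, lands at first contact,
and then settles toward the centre of mass until its surface gap closes to
2 Å), and `dla` (random attachment directions off random blocks). In the
lattice modes each new block is pulled into contact (3 Å surface gap) with
exactly one parent; because every mode attaches blocks essentially one
parent at a time, the mean per-monomer valency is nearly
morphology-independent (≈2.9–3.5, spread ≈20%), mirroring the observation
that the number of peptide–peptide contacts stays constant while assembly
morphology varies. The `target_valency` field is best-effort: a warning
reports the achieved valency when it falls outside ±25% of the target.

**Peak tables.** A reference amide-correlation table (¹H ≈ 8.25 ± 0.45 ppm,
¹⁵N ≈ 118 ± 6 ppm, unit intensities) is perturbed by a per-residue shift
profile plus Gaussian noise, and intensities are attenuated to
`1 − bound_fraction` — only the dissolved fraction stays NMR-visible. The
presets 0.17 (R5 with 25 mM silicic acid), 0.20/0.09 (low/high LCPA) and
0.007/0.0001 (phosphate-driven assembly) reflect the residual dissolved
fractions of the studied conditions.

**DOSY.** Stejskal-Tanner decays
`I(g) = I₀ exp(−D γ² g² δ² (Δ − δ/3))` on the study's acquisition grid:
128 points, g = 0→0.1 T/m, Δ = 60 ms. The gradient pulse length δ is not
printed in the source material; the default δ = 10 ms gives an endpoint
attenuation of ≈0.3 for a 0.8-nm peptide, the level a spectroscopist dials
in for a reliable diffusion fit. At 1% intensity noise the fitted
Stokes-Einstein radius recovers the generating radius to ≤1.5%.

**Silicification kinetics.** Each residue decays as
`I(t) = (1 − B) exp(−k t) + B` on a 7-hour grid sampled every 140 s (the
real-time acquisition cadence). Surface-flagged residues (the C-terminal
RRIL motif for R5, where phosphate binds and silica nucleates) use
`surface_rate`, all others `core_rate`; defaults 2×10⁻³ / 1×10⁻³ s⁻¹ with
plateau 0.17. The single-exponential-plus-plateau form is this package's
generative choice — the experiments were fitted with exponentials but no
generating model is established.

**Crowded box.** `build_crowded_box` evaluates the density-matching rule
d = 9·m·u/(4π·Rh³) (u the atomic mass unit in grams) and the cubic edge
that conserves total peptide mass. For R5 (m = 2013.3 Da, Rh = 1.3 nm) the
formula gives 1.09 g/mL; the printed reference densities (0.6194 and
0.8899 g/mL) are not reproducible from this formula with the stated masses
and radii, and the package reports the formula's value without forcing
agreement.

All generator outputs are bit-identical under a fixed seed; per-stream
seeds are derived from one master seed and recorded in a JSON manifest
sufficient to regenerate a dataset exactly.

## NMR observables

- **CSP**: `sqrt((w_a Δδ_a)² + (w_b Δδ_b)²)` with w = (1, 0.14) for ¹H-¹⁵N
  and (0.30, 0.14) for ¹³C-¹⁵N correlations (the community-standard
  weights; configurable). ¹H-³¹P tables reuse the ¹H-¹⁵N path with a
  configurable weight. Residues missing in either table are flagged
  absent, never zero-filled.
- **Intensity ratios / residual fraction**: per-residue I/I₀ with an
  optional detection floor (below-floor residues reported missing); the
  dissolved fraction is the arithmetic mean of detected ratios, exactly c
  for a uniformly scaled table.
- **Decay-rate fitting**: nonlinear least squares of `A exp(−kt) + B`
  (B fixed 0 for relaxation rates), seeded by a log-linear estimate plus a
  fixed multistart grid over the rate — deterministic, no random
  initialization. Exactly constant traces short-circuit to k = 0.
  Non-convergence is flagged on the result, not raised.
- **Surface/core classification**: with med the median rate over converged
  fits, the band is max(1.4826×MAD, 3× the median fit standard error);
  rates above med + band are *surface*, within ±band *core*, otherwise
  *undetermined*. The standard-error guard keeps the band meaningful when
  most rates coincide and the raw MAD collapses to fit noise. At the
  default two-rate conditions the pooled label accuracy is ≈99%.
- **DOSY → Rh**: Stejskal-Tanner least squares (linearized ln I vs b seed,
  multistart refinement); `Rh = k_B T/(6πηD)` under the hard-wired sphere
  assumption, water viscosity 0.8937 mPa·s at 298.15 K by default (no D₂O
  co-solvent correction). Gyration radii convert to hydrodynamic radii via
  Rg/Rh = 1.1.

## Scattering

`debye_curve` evaluates I(q) = Σᵢⱼ fᵢfⱼ sin(q rᵢⱼ)/(q rᵢⱼ) with unit form
factors by default (the bead model carries no element contrast); q in nm⁻¹,
λ defaulting to 0.1542 nm. Point-bead curves flatten to the self-term
(I → N) at high q; `restrict_above_background` keeps the coherent window
(≥5× that level), the analogue of experimental background subtraction.

`guinier_fit` iterates the window until q·Rg ≤ 1.3 (the globular default;
strongly elongated particles should use the classical 1.0 limit, exposed as
a parameter) and flags curves with no resolvable Guinier knee.
`beaucage_fit` fits the one-level unified function
`I(q) = G exp(−q²Rg²/3) + B [erf(qRg/√6)]³ᴾ/qᴾ` in log intensity with the
exponent bounded to P ∈ [1, 4.5] — below 1 the power term degenerates into a
flat pedestal under the Guinier knee and corrupts Rg.

Known limitation: the one-level unified fit is reliable for small
monodisperse, single-structural-level species (ensemble-averaged trimer
curves recover Rg to ≈2–3%, flat assemblies to ≈7%), but for dense
multi-level clusters (20–50 blocks, where block-level substructure enters
the tail) it systematically overestimates Rg by 10–20%. That overestimate
is a documented property of the unified form on non-fractal dense shapes,
not a fitting defect; rank information (the exponent P of extended vs
compact assemblies) remains correct.

## What the generator does and does not emulate

The synthetic streams reproduce the *structure* of the real data — trimeric
blocks, morphology-controlled aggregates, attenuation-scaled peak tables,
Stejskal-Tanner decays, two-rate silicification traces — with exactly known
ground truth. They do not emulate chemical-shift physics (shift profiles
are arbitrary offsets), exchange dynamics, spectral overlap, silica
condensation chemistry, or the µs-scale conformational dynamics of real
assemblies; passing tests therefore demonstrate that the analysis recovers
known inputs under realistic noise, not that the experimental values
themselves are reproduced.

## Problem sizes

Default validation sizes, chosen to characterize the estimators well while
keeping runs lightweight: 50-block assemblies (≈3000 beads) with 20 seeds
per morphology in tests and 5 in the acceptance script; 128-point DOSY
series at 50 (tests) or 20 (script) noise seeds; 19-residue kinetic traces
with 181 time points at 50/20 seeds; 10-conformer trimer ensembles for
scattering.
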