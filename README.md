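# silafract

Fractal-cluster metrics and NMR observables for peptide/counterion
self-assembly templates of biomimetic silica formation — with a
ground-truth-known synthetic data generator, so the whole analysis chain is
testable end to end.

## The problem

Silica-precipitating peptides such as the diatom-derived 19-mer **R5**
(SSKKSGSYSGSKGSKRRIL) assemble, with phosphate or long-chain polyamine
counterions, into trimeric building blocks that aggregate further into
supramolecular templates; silica then nucleates on the template surface.
Characterizing those solution-state templates combines several observables:

- **Fractal-cluster metrics** of coarse-grained assemblies: radius of
  gyration *R*g, molecular volume *V*mol = κ·*M*w (κ = 1.21 Å³/Da),
  compactness φ = *V*mol / ((4/3)π *R*g³), mean contact valency per
  monomer, and the fractal dimension

  *d*f = 3 (1 − log φ / log valency),

  plus an independent mass-radius scaling estimate (slope of
  log *N*(<r) vs log r) used as an oracle;
- **Chemical shift perturbations** CSP = √((*w*ₐΔδₐ)² + (*w*ᵦΔδᵦ)²),
  intensity ratios *I*/*I*₀ and residual dissolved fractions from peak
  tables;
- **Real-time silicification kinetics**: per-residue exponential decay
  rates *I*(t) = *A* e^(−kt) + *B* with surface/core classification
  (surface residues lose signal fastest);
- **DOSY diffusion**: Stejskal-Tanner fits
  *I*(g) = *I*₀ exp(−D γ²g²δ²(Δ−δ/3)) and Stokes-Einstein radii
  *R*h = *k*B*T*/(6πη*D*), with *R*g/*R*h = 1.1 to compare simulation and
  experiment;
- **Small-angle scattering**: Debye curves from bead models, Guinier
  analysis, and one-level Beaucage unified fits for *R*g.

Because no public dataset accompanies this kind of study, the `synthgen`
module generates every input stream with known ground truth: trimer
building blocks, assemblies of controlled morphology (linear / planar /
compact / diffusion-limited), HSQC-like peak tables, DOSY decays, two-rate
kinetic traces, and density-matched crowded-box parameters
(d = 9·m/(4π·*R*h³)).

See `docs/methods.md` for the model details, parameter choices, and known
limitations.

## Worked example

```bash
silafract demo --seed 1 --out demo_out --n-blocks 12
```

generates one 12-block assembly per morphology, analyses each, and runs the
peak-table, DOSY and kinetics round trips. Output (abridged):

```json
{
  "assembly_linear":  {"rg_A": 106.7, "valency": 2.78, "d_f_mass_radius": 1.21},
  "assembly_planar":  {"rg_A": 50.9,  "valency": 2.72, "d_f_mass_radius": 1.69},
  "assembly_compact": {"rg_A": 33.1,  "valency": 3.78, "d_f_mass_radius": 2.78},
  "residual_fraction": 0.17,
  "dosy": {"D_true": 3.054e-10, "D_fit": 3.032e-10, "rh_nm": 0.806},
  "kinetics": {"n_surface": 4, "n_core": 15}
}
```

Reading it: the mass-radius dimension tracks the generated dimensionality
(rod ≈ 1.2, sheet ≈ 1.7, globule ≈ 2.8) while the mean contact valency
stays nearly constant across morphologies — the structural signature of
assemblies built from conserved trimer contacts. A peak table attenuated
to 17% recovers a residual dissolved fraction of exactly 0.17; a DOSY
series generated for *D* = 3.054×10⁻¹⁰ m²/s at 1% noise fits back to a
hydrodynamic radius of 0.81 nm (truth: 0.80 nm); and the classifier labels
exactly the four C-terminal RRIL residues as fast-decaying surface sites.

The same steps are available as a library:

```python
import silafract as sf

block = sf.generate_building_block(sf.BuildingBlock(), seed=1)
frame = sf.aggregate_assembly(block, sf.MorphologySpec(mode="compact", n_blocks=25))
metrics = sf.analyze_frame(frame)          # Rg, phi, valency, d_f
oracle = sf.mass_radius_dimension(frame)   # independent dimension estimate
```

Other CLI entry points: `silafract generate`, `analyze-assembly`,
`analyze-nmr`, `analyze-kinetics`, `analyze-dosy`, `saxs`. Every run
serializes its configuration and a log next to its results, and fixed seeds
reproduce outputs bit-identically.

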