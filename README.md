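# popswitch

Quantitative analysis of a metal-responsive enzyme switch built from prolyl
oligopeptidase (POP) carrying two genetically encoded bipyridylalanine (Bpy)
residues. Adding Ni(II) cross-links the two Bpy side chains into a Bpy₂Ni
site, pulling the enzyme from an open into a closed conformation; removing
the metal reverses it. This package implements the analysis chain that
connects the simulated conformational free-energy landscape of that switch
to its measured metal-binding and spectroscopic behaviour:

- **WHAM** — reconstruct the potential of mean force W(x) along the Bpy–Bpy
  N–N distance from harmonically biased umbrella-sampling windows, with
  overlap diagnostics.
- **Thermodynamic linkage** — split the PMF into closed (x < d) and open
  (x > d) basins by Boltzmann integration,
  ΔG_s = −kT ln[∫₀^d e^(−W_s/kT) dx / ∫_d^∞ e^(−W_s/kT) dx],
  and convert the metal-state stabilization into an apparent dissociation
  constant, K_app(d) = e^(ΔG_M/kT) · K_open(d), or invert it to infer ΔG_M
  from a measured K_app.
- **Binding** — exact mass-action speciation for Ni(II)/chelator/protein
  competition, global fitting of competition titrations (magfura-2-style
  quench assays) with seeded bootstrap confidence intervals, and
  ligand-depletion isotherm fits for weak (¹⁹F-NMR-style) binding.
- **FRET** — Förster-law predictions E = 1/(1+(r/R₀)⁶), the donor-quenching
  estimator E = 1 − F_DA/F_D for dark-quencher acceptors, label-site
  screening by regression against the switching coordinate, and two-state
  (near/distant) catalytic-triad conformer classification.
- **Synthetic data** — a generator for every input the pipeline consumes
  (two-basin model landscapes, biased window samples, noisy titrations,
  bimodal distance trajectories) with known ground truth, so each estimator
  is validated by closed-loop recovery.

## Worked example

```python
import popswitch as ps

# model landscape with the landmark features: broad open minimum near 25 A,
# closed state ~15 kcal/mol up without metal, deep narrow well at 2.5 A with
params = ps.ModelPMFParams()
pmf_metal = ps.make_pmf(params, metal_bound=True)
pmf_apo = ps.make_pmf(params, metal_bound=False)

dg_m = ps.basin_free_energy(pmf_metal, cutoff_d=4.0)   # -> -6.77 kcal/mol
dg_0 = ps.basin_free_energy(pmf_apo, cutoff_d=4.0)     # -> +17.20 kcal/mol
ps.apparent_kd(dg_m, k_open=933.0)                     # -> 0.0102 nM
ps.apparent_kd(-7.6, k_open=933.0, temperature=299.0)  # -> 0.0026 nM
ps.infer_dG(41.0, 933.0)                               # -> -1.85 kcal/mol
ps.forster_efficiency(35.3, 33.0), ps.forster_efficiency(23.1, 33.0)
# -> (0.400, 0.895)
```

The first two numbers are the closed-state free energies of the synthetic
landscape with and without metal; pushing the metal-state value through the
linkage relation predicts a sub-picomolar apparent Kd, while inverting the
relation on a measured 41 nM apparent Kd yields the ≈ −2 kcal/mol
stabilization consistent with experiment. The Förster pair shows the
expected low-FRET open (~0.4) and high-FRET closed (~0.9) efficiencies for a
33 Å Förster radius.

The same pipeline is scriptable from the shell:

```bash
popswitch full-demo --seed 1 --out report.json   # end-to-end recovery demo
popswitch fret --r 35.3 --r0 33                  # {"efficiency": 0.4003, ...}
```

`full-demo` generates both landscapes, samples umbrella windows, solves
WHAM, integrates the basins, predicts K_app, and in parallel simulates a
three-replicate competition titration and refits it — reporting
ground-truth-vs-recovered deltas for every stage.

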