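# tightbind

Analysis toolkit for **slow, tight-binding enzyme inhibition** — the
two-step mechanism

```
E + I  <--k3/k4-->  E:I  <--k5/k6-->  E:I*
```

in which a fast encounter complex (K_I = k4/k3) slowly tightens into a
long-lived complex E:I* with overall dissociation constant
K_I* = k4/(k3(1 + k5/k6)). The motivating system is the inhibition of
peptide deformylase (a metal-dependent enzyme that removes the N-terminal
formyl group from nascent proteins) by actinonin, a natural hydroxamate
pseudo-peptide that mimics the reaction's transition state; the machinery
applies to any slow-onset inhibitor analyzed the same way.

For whom: enzymologists and medicinal chemists fitting progress curves and
k_obs series; structural biologists quantifying ligand-induced domain
closure; anyone teaching or testing induced-fit vs conformational-selection
discrimination.

What it does:

* **Closed-form kinetics** (`tightbind.kinetics`) — k_obs for both limiting
  mechanisms, K_I*, k6 from the tightening ratio, complex half-life
  `0.693(k4+k5+k6)/(k4 k6)`, ddG = RT ln(K_I/K_I*), Michaelis-Menten
  velocities.
* **Staged inference** (`tightbind.inference`) — progress-curve fits with
  the integrated form `P(t) = vs t + (v0-vs)(1-e^{-k_obs t})/k_obs`;
  weighted induced-fit hyperbola fits of k_obs series; double-reciprocal
  plots; a mechanism classifier (rising saturable k_obs = induced fit,
  falling = conformational selection); Henderson tight-binding regression
  returning K_I* and the active-enzyme concentration; Michaelis-Menten fits.
* **Synthetic assays** (`tightbind.simulate`) — stiff-ODE simulation of the
  full scheme coupled to substrate turnover, with inhibitor depletion
  tracked exactly, seeded noise, preincubation, and Henderson tables from
  the Morrison quadratic; toy C-alpha conformers with prescribed geometry.
* **Conformer geometry** (`tightbind.geometry`) — PDB reading (gemmi),
  Kabsch superposition RMSD, the aperture angle at a conserved active-site
  residue, per-residue displacements, atom distances, and classification
  into open/intermediate/closed/super-closed states in the
  (aperture angle, RMSD) plane.
* A thin CLI (`tightbind simulate | kinetics | geometry`) writing manifests
  for exact reproducibility, and narrative scripts under `examples/`.

## Worked example

```python
from tightbind import (ATPDF_ACTINONIN, MichaelisParams, estimate_scheme,
                       kobs_assay_design, simulate_assay)

mm = MichaelisParams(kcat=37.0, Km=1e-3)
design = kobs_assay_design(seed=42)          # 1% + 2 nM noise, 3 replicates
curves, _ = simulate_assay(ATPDF_ACTINONIN, mm, design)
est = estimate_scheme(curves)
print(est.report)
```

prints (formatted):

```
recovered k5 =  62.5 e-3 1/s   (true 63)
recovered k6 =   4.3 e-4 1/s   (true 4)
recovered KI =   140 nM        (true 140)
mechanism verdict: induced_fit (rising saturable k_obs)
```

i.e. eighteen noisy simulated progress curves are fitted individually, the
resulting k_obs series is fitted with the hyperbola
`k_obs = k6 + k5[I]/(K_I+[I])`, and the generating constants come back
within a few percent; the rising saturable trend identifies induced fit.
From the same constants the derived report gives K_I* ≈ 0.97 nM, a
tightening ratio ≈ 145, a complex half-life ≈ 27 min and a tightening free
energy ≈ 3.1 kcal/mol. Run `python examples/progress_curve_inference.py`
to reproduce it; the other scripts in `examples/` demonstrate the derived
constants, the mechanism call, Henderson titrations and conformer-state
classification.

## Layout

```
src/tightbind/    kinetics, inference, simulate, geometry, cli
examples/         one narrative script per capability
tests/            pytest suite (unit, property, end-to-end)
docs/methods.md   model, assumptions, numerics, design choices, limitations
```
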