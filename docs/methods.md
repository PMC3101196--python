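# Methods

## The kinetic model

`tightbind` analyzes slow, tight-binding enzyme inhibition through the
two-step scheme

```
E + I  <--k3/k4-->  E:I  <--k5/k6-->  E:I*
```

A fast, reversible encounter complex E:I (dissociation constant
K_I = k4/k3) slowly isomerizes into a tightened complex E:I* (forward k5,
reverse k6). The overall dissociation constant of the final complex is

```
K_I* = k4 / (k3 (1 + k5/k6)) = K_I k6 / (k5 + k6)
```

Under a rapid-equilibrium treatment of the first step and pseudo-first-order
conditions ([I] >> [E]), the approach of the catalytic rate to its inhibited
steady state is a single exponential with observed rate

```
k_obs = k6 + k5 [I] / (K_I + [I])        (induced fit: rising, saturating)
k_obs = k6 + k5 / (1 + [I]/K_I)          (conformational selection: falling)
```

The sign of dk_obs/d[I] is the classical discriminator between the two
limiting binding mechanisms, and the mechanism classifier fits both
hyperbolas, compares their AIC, and tests the monotone trend with Kendall's
tau; the verdict is "ambiguous" whenever the trend is not significant or the
two criteria disagree. A rank trend statistic was chosen over a parametric
slope test because the series are short (typically six levels) and strongly
curved; on such designs the two tests agree whenever either is meaningful.

Derived quantities:

* complex half-life `t1/2 = 0.693 (k4+k5+k6)/(k4 k6)`, which collapses onto
  the residence-time reading `0.693/k6` when k6 << k5 << k4. The literal
  0.693 is used by default to reproduce literature tables digit-for-digit; a
  flag switches to ln 2 at full precision.
* tightening free energy `ddG = RT ln(K_I/K_I*)`, with R fixed at
  1.987e-3 kcal/(mol K) so that RT(310.15 K) = 0.616 kcal/mol.
* k4 = k3 K_I under the diffusion-limit convention k3 = 1e9 1/(M s),
  overridable everywhere it is used.

Internally everything is SI (molar, seconds, kelvin); reporting helpers
convert to the nM / min / kcal per mol conventions of the inhibition
literature.

A note on the reference constants: the bundled plant-deformylase scheme uses
k5 = 63e-3 1/s and k6 = 4e-4 1/s. Some narrative passages in the source
literature quote k5 = 0.044 and k6 = 0.0006 for the same system while citing
the same table; the tabulated values are used here because every derived
quantity (K_I*, ratio, half-life) is mutually consistent only with them. The
tabulated half-life of the third enzyme (thermophilic bacterial isoform 2,
printed 1.1 min) is arithmetically inconsistent with its own rate constants
(the formula gives ~10.5 min) and is deliberately not used as a check.

## Staged inference

1. **Progress curves.** Each product-vs-time course at fixed ([I], [S]) is
   fitted with the integrated Morrison-Walsh form
   `P(t) = vs t + (v0 - vs)(1 - exp(-k_obs t))/k_obs` by nonlinear least
   squares (lmfit/MINPACK). The signal is normalized to O(1) before fitting;
   without this, MINPACK's relative step heuristics stall on nM-scale
   parameters. Initial guesses: v0 from the slope of the first 10% of
   points, vs from the last 10%, k_obs from the burst amplitude. When the
   two segment slopes agree within 5% (configurable) the curve has no usable
   curvature: a straight line is fitted and the result flagged degenerate
   with k_obs undefined — the expected outcome for uninhibited controls.
2. **k_obs series.** The induced-fit hyperbola is fitted with
   inverse-variance weights when per-point standard errors exist, unweighted
   otherwise. Replicates can be aggregated to per-level means with sample
   standard errors first (`KobsSeries.aggregate_replicates`). Points whose
   curve fit was non-convergent or whose k_obs standard error exceeds the
   estimate are excluded by the pipeline: they carry noise, not signal.
   A falling series is still fitted but flagged inconsistent-with-model.
3. **Double-reciprocal line.** `1/k_obs` on `1/[I]`, restricted to points
   with k_obs > 10 k6 (cutoff configurable; the literature states the
   condition k_obs >> k6 without a threshold). Note the linearization
   neglects k6, so even noiseless data from the full scheme bow slightly:
   r^2 = 0.9996 for the reference constants, which prints as a correlation
   of 1.00. The slope is K_I/k5 and the intercept 1/k5.
4. **Henderson analysis.** For tight-binding titrations ([I] comparable to
   [E]t), `[I]/(1 - vi/v0)` regressed on `v0/vi` gives slope K_I*app and
   intercept E_t — an exact rearrangement of the Morrison quadratic, so the
   noiseless round trip is exact. The competitive correction
   `K_I* = K_I*app/(1 + [S]/Km)` is applied per substrate level and the
   corrected values pooled by unweighted mean.
5. **Michaelis-Menten.** Standard nonlinear fit; kcat = Vmax/[E].

An identifiability caveat worth stating plainly: with direct noise of a few
percent on k_obs, the intercept k6 (two orders of magnitude below the
asymptote) is weakly identified — Monte-Carlo runs at 5% noise put the
median k6 error near 50% however the fit is weighted. This is why
practitioners derive k6 from the K_I/K_I* ratio (`k6 = k5/(K_I/K_I* - 1)`)
rather than from the intercept. The full pipeline does better (median ~19%
at the default noise) because the per-curve fits return honest, much smaller
standard errors that weight the hyperbola fit.

## The simulator

`simulate_assay` integrates the mass-action system

```
dE/dt    = -k3 E I_free + k4 EI
dEI/dt   =  k3 E I_free - (k4+k5) EI + k6 EIstar
dEIstar/dt = k5 EI - k6 EIstar
dP/dt    =  kcat E S/(Km+S) = -dS/dt
I_free   =  I_total - EI - EIstar
```

with LSODA (rtol 1e-8, atol 1e-12 M — the rate constants span six decades,
so a stiff-capable method is required). Substrate turnover is
rapid-equilibrium Michaelis-Menten on free enzyme with no explicit E:S
species: the single mechanistic simplification, consistent with the
competitive analysis applied downstream. Mass conservation
(E + EI + EIstar and S + P) is asserted on every trajectory. Preincubation
integrates the binding subsystem with substrate absent, then introduces
substrate at t = 0.

The coupled detection enzyme is treated as instantaneous and stoichiometric
(signal = [P]); in the emulated assay the coupling step is not rate-limiting.

Defaults emulate the published assay conditions: 100 nM enzyme, 2 mM
formylated tripeptide substrate, kcat = 37 1/s, 37 deg C. The substrate Km
is not printed in the source material; 1 mM is used as a realistic value for
formylated tripeptide substrates of this enzyme family and is configurable
everywhere. The noise model is 1% multiplicative plus 2 nM additive
Gaussian (no noise model is published; these are typical plate-reader
figures). One master seed is spawned into per-curve substreams, so
noiseless output is seed-independent and noisy output is reproducible.

**k_obs assay design.** The closed-form k_obs assumes no inhibitor
depletion. The exact ODE shows the cost of ignoring this: at 10-fold
inhibitor excess the fitted k_obs is ~3.5% below the hyperbola at the low
end of the grid (and the bias propagates ~2-fold into the fitted intercept
k6); at 100-fold excess all grid points agree within ~0.5%. The
k_obs-series design factory therefore scales enzyme per curve to maintain a
100-fold inhibitor excess (0.1 nM enzyme at the 10 nM grid point, 30 nM at
3 uM) — exactly what a careful experimentalist does to keep both
pseudo-first-order validity and measurable signal. The degradation at 10x
and 2x excess is itself tested, not hidden.

Problem sizes used by the test suite: 120 samples per curve over 5/k_obs,
six concentrations spanning 10 nM - 3 uM, three replicates, 100 Monte-Carlo
replicates for the recovery suite. These run in seconds to a couple of
minutes on one core.

`generate_henderson_table` bypasses the ODE and evaluates the Morrison
quadratic with K_eff = K_I*(1 + [S]/Km) directly — the exact equilibrium
result for a preincubated (fully equilibrated) titration.

## Conformational-state geometry

Two scalar coordinates quantify ligand-induced closure:

* **RMSD** after optimal rigid superposition of author-number-matched
  C-alpha atoms (Kabsch/SVD, proper rotation enforced). Secondary-structure
  matching was deliberately not reimplemented: for single-domain enzymes of
  this size, residue-number matching is deterministic and equivalent.
* **Aperture angle delta_ap**: the angle at the C-alpha of a conserved
  active-site residue between the C-alpha atoms of two conserved residues
  anchoring the flanking domains. The source figure lists three marker
  residues without naming the vertex; the default is the *second* in the
  conventional cysteine-histidine-isoleucine listing order (the histidine,
  geometrically between the two domain anchors). This is an interpretation,
  configurable via `MarkerTriple.vertex`, and there is no published check
  value to validate it against.

States (open / intermediate / closed / super-closed) are assigned by
point-in-rectangle lookup in the (delta_ap, rmsd) plane. Zone boundaries
are *not* published numerically; the shipped defaults are an explicitly
approximate, non-authoritative reading anchored only by the fact that
independent open structures superpose below 0.25 A r.m.s.d. Boundary points
belong to the first zone in config order; interior overlap is a
configuration error at load time. Calibrate zones on your own ensemble
before trusting labels.

The toy conformer generator positions three marker residues on a generic
helical scaffold so the aperture angle is exact by construction, applies
optional Gaussian coordinate noise and a rigid pose last. The synthetic
open/closed pair used in tests shares every C-alpha except one residue
displaced by exactly 4.0 A, plus an N/O atom pair contracting from 5.0 to
2.8 A — the magnitudes characteristic of the domain-closure event the
package is designed to quantify. These fixtures exercise the full geometry
stack but are *not* protein-like: they carry no secondary structure, no
side chains and no packing, so passing tests demonstrate correctness of the
geometric operators, not of any biological conclusion.

## Known limitations

* k_obs inference assumes the rapid-equilibrium, pseudo-first-order regime;
  the simulator is exact and quantifies the error outside it, but the
  fitting layer does not correct for depletion (a global ODE fit is a
  documented extension point, not implemented).
* Asymptotic standard errors only; no bootstrap.
* The conformational-state zones are configuration, not science; defaults
  are placeholders.
* Calorimetric, crystallographic and electron-density analyses are out of
  scope; the geometry layer consumes coordinates, never density.
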