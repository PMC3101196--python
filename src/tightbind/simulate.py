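"""Synthetic assay and structure generation for the slow-binding pipeline.

Three generators replace the wet-lab inputs:

* :func:`simulate_assay` integrates the two-step inhibition scheme coupled to
  Michaelis-Menten turnover as a stiff ODE system and emits progress curves
  in the same CSV dialect the inference layer reads.  Substrate binding is
  treated as rapid-equilibrium turnover on free enzyme (no explicit E:S
  species) -- the one mechanistic simplification, matching the competitive
  analysis applied downstream.  Free-inhibitor depletion is tracked exactly,
  so the pseudo-first-order closed form and the simulator disagree measurably
  when [I] approaches [E]; that disagreement is a feature, not a bug.
* :func:`generate_henderson_table` produces preincubated fractional
  velocities from the Morrison tight-binding quadratic with the competitive
  apparent constant K_eff = K_I*(1 + [S]/Km).
* :func:`generate_conformer` builds toy C-alpha backbones whose three marker
  residues realize a prescribed aperture angle, for exercising the geometry
  stack without crystal structures.

Noise model: multiplicative Gaussian (default CV 1%) plus additive Gaussian
(default sigma 2 nM) on the product signal.  One master seed; per-curve
substreams are spawned deterministically, so noiseless output is
seed-independent and noisy output depends only on (seed, design).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.integrate import solve_ivp

from .geometry import MarkerTriple, StructureModel
from .inference import HendersonTable, ProgressCurve
from .kinetics import KineticScheme, MichaelisParams, kobs_induced_fit, ki_star

__all__ = [
    "AssayDesign",
    "SimTrace",
    "simulate_assay",
    "generate_henderson_table",
    "generate_conformer",
    "generate_closure_pair",
    "morrison_fractional_velocity",
    "kobs_assay_design",
    "write_structure_pdb",
    "structure_to_pdb_string",
]

#: Default inhibitor grid for k_obs-series experiments (M); spans 300-fold.
DEFAULT_KOBS_GRID = (10e-9, 30e-9, 100e-9, 300e-9, 1000e-9, 3000e-9)


@dataclass(frozen=True)
class AssayDesign:
    """The simulated experiment.

    Defaults follow the published assay conditions: 100 nM enzyme, 2 mM
    formylated tripeptide substrate, 37 deg C coupled assay.  ``duration_s``
    of ``None`` sets each curve's span adaptively to ``5/k_obs`` predicted
    from the scheme (plus a floor), the usual practice for slow-onset fits.
    """

    enzyme_total: float = 100e-9
    substrate0: float = 2e-3
    inhibitor_grid: tuple[float, ...] = DEFAULT_KOBS_GRID
    #: when set, each inhibited curve uses enzyme_total = [I]/inhibitor_excess,
    #: keeping the pseudo-first-order excess constant across the grid while the
    #: signal stays measurable at high [I] (the usual bench practice)
    inhibitor_excess: float | None = None
    preincubation_s: float = 0.0
    duration_s: float | None = None
    n_points: int = 120
    replicates: int = 1
    noise_cv: float = 0.01
    noise_sigma: float = 2e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.enzyme_total < 0 or self.substrate0 < 0:
            raise ValueError("concentrations must be >= 0")
        if any(i < 0 for i in self.inhibitor_grid):
            raise ValueError("inhibitor concentrations must be >= 0")
        if self.n_points < 8:
            raise ValueError("need >= 8 sampled points per curve")


def kobs_assay_design(**overrides) -> AssayDesign:
    """Design for k_obs-series runs: 0.1 nM enzyme so even the lowest default
    grid point (10 nM inhibitor) keeps a 100-fold inhibitor excess and the
    pseudo-first-order closed form applies without depletion bias; three
    replicates per level."""
    kw = dict(enzyme_total=0.1e-9, inhibitor_excess=100.0, replicates=3)
    kw.update(overrides)
    return AssayDesign(**kw)


@dataclass
class SimTrace:
    """Noiseless species trajectories for one inhibitor concentration."""

    times: np.ndarray
    E: np.ndarray
    EI: np.ndarray
    EIstar: np.ndarray
    S: np.ndarray
    P: np.ndarray
    inhibitor_total: float

    def check_mass_conservation(self, enzyme_total: float, substrate0: float,
                                rtol: float = 1e-6) -> None:
        e_tot = self.E + self.EI + self.EIstar
        s_tot = self.S + self.P
        if not np.allclose(e_tot, enzyme_total, rtol=rtol, atol=1e-15):
            raise AssertionError("enzyme mass not conserved in simulation")
        if not np.allclose(s_tot, substrate0, rtol=rtol, atol=1e-15):
            raise AssertionError("substrate+product mass not conserved")


def _rhs(scheme: KineticScheme, mm: MichaelisParams, I_total: float, with_substrate: bool):
    k3, k4, k5, k6 = scheme.k3, scheme.k4, scheme.k5, scheme.k6
    kcat, Km = mm.kcat, mm.Km

    def f(t, y):
        E, EI, EIs, S, P = y
        I_free = max(I_total - EI - EIs, 0.0)
        dE = -k3 * E * I_free + k4 * EI
        dEI = k3 * E * I_free - (k4 + k5) * EI + k6 * EIs
        dEIs = k5 * EI - k6 * EIs
        dP = kcat * E * S / (Km + S) if with_substrate else 0.0
        return [dE, dEI, dEIs, -dP, dP]

    return f


def _integrate(scheme, mm, y0, I_total, t_eval, with_substrate=True):
    sol = solve_ivp(
        _rhs(scheme, mm, I_total, with_substrate),
        (t_eval[0], t_eval[-1]), y0, t_eval=t_eval,
        method="LSODA", rtol=1e-8, atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"ODE solver failed: {sol.message}")
    return sol


def _curve_duration(scheme: KineticScheme, I: float, design: AssayDesign) -> float:
    if design.duration_s is not None:
        return design.duration_s
    if I <= 0:
        return 300.0
    return max(5.0 / kobs_induced_fit(scheme, I), 60.0)


def simulate_assay(
    scheme: KineticScheme,
    mm: MichaelisParams,
    design: AssayDesign,
) -> tuple[list[ProgressCurve], list[SimTrace]]:
    """Simulate one progress curve per (inhibitor level, replicate).

    Without preincubation the reaction starts from free enzyme, free
    inhibitor and substrate together (enzyme-initiated assay).  With
    preincubation the binding system is first integrated for
    ``preincubation_s`` with substrate absent, then substrate is introduced
    and t = 0 is the moment of substrate addition.  Noise is applied per
    replicate from deterministically spawned substreams of ``design.seed``.
    """
    master = np.random.SeedSequence(design.seed)
    streams = master.spawn(len(design.inhibitor_grid) * design.replicates)
    curves: list[ProgressCurve] = []
    traces: list[SimTrace] = []
    k = 0
    for I_total in design.inhibitor_grid:
        E_total = design.enzyme_total
        if design.inhibitor_excess is not None and I_total > 0:
            E_total = I_total / design.inhibitor_excess
        t_end = _curve_duration(scheme, I_total, design)
        t_eval = np.linspace(0.0, t_end, design.n_points)
        y0 = [E_total, 0.0, 0.0, design.substrate0, 0.0]
        if design.preincubation_s > 0:
            pre = _integrate(
                scheme, mm,
                [E_total, 0.0, 0.0, 0.0, 0.0],
                I_total, np.array([0.0, design.preincubation_s]),
                with_substrate=False,
            )
            E, EI, EIs = pre.y[0, -1], pre.y[1, -1], pre.y[2, -1]
            y0 = [E, EI, EIs, design.substrate0, 0.0]
        sol = _integrate(scheme, mm, y0, I_total, t_eval)
        trace = SimTrace(
            times=t_eval, E=sol.y[0], EI=sol.y[1], EIstar=sol.y[2],
            S=sol.y[3], P=sol.y[4], inhibitor_total=I_total,
        )
        trace.check_mass_conservation(E_total, design.substrate0)
        traces.append(trace)
        for rep in range(design.replicates):
            rng = np.random.default_rng(streams[k])
            k += 1
            sig = trace.P.copy()
            if design.noise_cv > 0:
                sig = sig * (1.0 + design.noise_cv * rng.standard_normal(sig.shape))
            if design.noise_sigma > 0:
                sig = sig + design.noise_sigma * rng.standard_normal(sig.shape)
            curves.append(ProgressCurve(
                times=t_eval, signal=sig, inhibitor_conc=I_total,
                substrate_conc=design.substrate0,
                preincubated=design.preincubation_s > 0, replicate=rep,
            ))
    return curves, traces


def morrison_fractional_velocity(I_total, E_total: float, Ki_app: float) -> np.ndarray:
    """vi/v0 for a tight-binding inhibitor from the Morrison quadratic.

    ``Ki_app`` is the apparent dissociation constant at the working substrate
    concentration (K_I*(1+[S]/Km) for competitive inhibition).  Exact in
    enzyme depletion, hence valid for [I] comparable to [E].
    """
    It = np.asarray(I_total, dtype=float)
    b = E_total + It + Ki_app
    frac_inhibited = (b - np.sqrt(b * b - 4.0 * E_total * It)) / (2.0 * E_total)
    return 1.0 - frac_inhibited


def generate_henderson_table(
    scheme: KineticScheme,
    mm: MichaelisParams,
    design: AssayDesign,
    substrate_levels: tuple[float, ...] | None = None,
    noise_cv: float = 0.0,
) -> HendersonTable:
    """Fractional initial velocities for a preincubated (equilibrated E:I*)
    titration, at each combination of inhibitor level and substrate level.

    vi/v0 comes from the Morrison quadratic with K_eff = K_I*(1 + [S]/Km).
    Optional multiplicative noise with CV ``noise_cv`` (seeded from the
    design).
    """
    KIstar = ki_star(scheme)
    S_levels = substrate_levels if substrate_levels is not None else (design.substrate0,)
    rng = np.random.default_rng(design.seed)
    I_col, S_col, f_col = [], [], []
    for S in S_levels:
        Ki_app = KIstar * (1.0 + S / mm.Km)
        f = morrison_fractional_velocity(
            np.asarray(design.inhibitor_grid), design.enzyme_total, Ki_app
        )
        if noise_cv > 0:
            f = np.clip(f * (1.0 + noise_cv * rng.standard_normal(f.shape)), 1e-9, None)
        I_col.extend(design.inhibitor_grid)
        S_col.extend([S] * len(design.inhibitor_grid))
        f_col.extend(f)
    return HendersonTable(
        inhibitor_conc=np.array(I_col),
        substrate_conc=np.array(S_col),
        fractional_velocity=np.array(f_col),
    )


def _default_markers_for(size: int) -> MarkerTriple:
    return MarkerTriple(residues=(size // 4, size // 2, 3 * size // 4), vertex=2)


def generate_conformer(
    scaffold_size: int = 100,
    target_delta_ap: float = 95.0,
    rigid_pose: tuple[np.ndarray, np.ndarray] | None = None,
    coord_noise: float = 0.0,
    seed: int = 0,
    markers: MarkerTriple | None = None,
    arm_length: float = 15.0,
) -> tuple[StructureModel, MarkerTriple]:
    """Deterministic toy C-alpha backbone realizing a prescribed aperture angle.

    The scaffold is a gentle helix of ``scaffold_size`` residues (3.8 A
    spacing); the three marker residues are then repositioned so that the
    angle at the vertex marker equals ``target_delta_ap`` exactly (before
    noise).  Gaussian coordinate noise (sigma ``coord_noise`` A) is applied to
    every atom, then the optional rigid pose ``(R, t)`` last.  Same seed,
    same coordinates.
    """
    if not (0.0 < target_delta_ap < 180.0):
        raise ValueError("target aperture angle must be in (0, 180) degrees")
    if markers is None:
        markers = _default_markers_for(scaffold_size)
    rng = np.random.default_rng(seed)
    idx = np.arange(1, scaffold_size + 1)
    coords = np.column_stack([
        1.5 * idx,
        6.0 * np.sin(0.5 * idx),
        6.0 * np.cos(0.5 * idx),
    ])
    ca = {int(n): coords[i].copy() for i, n in enumerate(idx)}

    m1, m2, m3 = markers.residues
    order = [m1, m2, m3]
    vertex_res = order[markers.vertex - 1]
    arms = [r for r in order if r != vertex_res]
    apex = ca[vertex_res]
    theta = math.radians(target_delta_ap)
    ca[arms[0]] = apex + arm_length * np.array([1.0, 0.0, 0.0])
    ca[arms[1]] = apex + arm_length * np.array([math.cos(theta), math.sin(theta), 0.0])

    if coord_noise > 0:
        for n in ca:
            ca[n] = ca[n] + rng.normal(0.0, coord_noise, 3)

    resnames = {int(n): "ALA" for n in idx}
    resnames[m1], resnames[m2], resnames[m3] = "CYS", "HIS", "ILE"
    atoms = {(int(n), "CA"): c for n, c in ca.items()}
    model = StructureModel(chain="A", ca=ca, resnames=resnames, atoms=atoms)
    if rigid_pose is not None:
        R, t = rigid_pose
        model = model.transformed(np.asarray(R), np.asarray(t))
    return model, markers


def generate_closure_pair(
    scaffold_size: int = 100,
    displaced_residue: int = 60,
    displacement: float = 4.0,
    hbond_residue: int = 42,
    no_dist_open: float = 5.0,
    no_dist_closed: float = 2.8,
    seed: int = 0,
) -> tuple[StructureModel, StructureModel]:
    """Synthetic open/closed pair mirroring a domain-closure event.

    Both structures share every C-alpha except ``displaced_residue``, whose
    closed-state C-alpha is translated by exactly ``displacement`` A, so a
    superposition on the remaining residues is the identity and the reported
    maximum displacement is exact.  A backbone N at ``hbond_residue`` and a
    pseudo-ligand carbonyl O are placed ``no_dist_open`` A apart in the open
    form and ``no_dist_closed`` A apart in the closed form (the
    hydrogen-bond-formation distance change).  Entirely synthetic fixtures:
    no relation to any deposited coordinates.
    """
    open_model, _ = generate_conformer(scaffold_size=scaffold_size, seed=seed)
    n_pos = open_model.ca[hbond_residue] + np.array([0.0, 1.3, 0.0])
    u = np.array([0.0, 1.0, 0.0])
    open_model.atoms[(hbond_residue, "N")] = n_pos
    lig_num = scaffold_size + 400
    open_model.atoms[(lig_num, "O")] = n_pos + no_dist_open * u
    open_model.resnames[lig_num] = "LIG"

    closed = StructureModel(
        chain=open_model.chain,
        ca={n: c.copy() for n, c in open_model.ca.items()},
        resnames=dict(open_model.resnames),
        atoms={k: c.copy() for k, c in open_model.atoms.items()},
    )
    shift = displacement * np.array([0.0, 0.0, 1.0])
    closed.ca[displaced_residue] = closed.ca[displaced_residue] + shift
    closed.atoms[(displaced_residue, "CA")] = closed.ca[displaced_residue]
    closed.atoms[(lig_num, "O")] = n_pos + no_dist_closed * u
    return open_model, closed


def structure_to_pdb_string(model: StructureModel) -> str:
    """Serialize a StructureModel to PDB-format text (ATOM records)."""
    st = gemmi.Structure()
    st.name = "synthetic"
    gm = gemmi.Model("1")
    ch = gemmi.Chain(model.chain)
    for num in sorted({k[0] for k in model.atoms}):
        res = gemmi.Residue()
        res.name = model.resnames.get(num, "ALA")
        res.seqid = gemmi.SeqId(num, " ")
        for (rn, aname), pos in sorted(model.atoms.items()):
            if rn != num:
                continue
            at = gemmi.Atom()
            at.name = aname
            at.element = gemmi.Element(aname[0])
            at.pos = gemmi.Position(*pos)
            at.occ = 1.0
            res.add_atom(at)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    return st.make_pdb_string()


def write_structure_pdb(model: StructureModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(structure_to_pdb_string(model))
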