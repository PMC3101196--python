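"""Conformational-state geometry: Kabsch superposition, aperture angle, state map.

Ligand-induced closure of a single-domain metalloenzyme is quantified here by
two scalar coordinates:

* the C-alpha r.m.s.d. of a structure against an open reference after optimal
  rigid (Kabsch) superposition, and
* the aperture angle ``delta_ap`` subtended at the C-alpha of a conserved
  active-site residue by the C-alpha atoms of two other conserved residues,
  one anchoring each domain flanking the active-site crevice.

Points in the (delta_ap, rmsd) plane are classified into open (O),
intermediate (I), closed (C) and super-closed (S) conformational states by a
user-configurable zone map.  The default zones shipped here are an explicitly
approximate reading of the published state map and are NOT authoritative: the
only hard number behind them is that independent open structures superpose to
r.m.s.d. < 0.25 A.  Calibrate zones on your own ensemble before trusting
labels.

The vertex of the aperture angle defaults to the *second* marker residue
(the conserved histidine when markers are listed in the conventional
cysteine-histidine-isoleucine order); this is a documented interpretation,
configurable via ``MarkerTriple.vertex``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
import yaml

__all__ = [
    "StructureModel",
    "MarkerTriple",
    "ApertureResult",
    "StateZone",
    "StateZoneConfig",
    "read_structure",
    "kabsch_superpose",
    "aperture_angle",
    "residue_displacement",
    "atom_distance",
    "classify_state",
    "DEFAULT_MARKERS",
    "DEFAULT_ZONES",
]


@dataclass
class StructureModel:
    """Residue-indexed C-alpha coordinates for one chain (author numbering).

    ``ca`` maps residue number -> C-alpha coordinate (A); ``atoms`` maps
    (residue number, atom name) -> coordinate for arbitrary-atom distance
    queries; ``resnames`` maps residue number -> residue name.
    """

    chain: str
    ca: dict[int, np.ndarray]
    resnames: dict[int, str] = field(default_factory=dict)
    atoms: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ca)

    @property
    def residue_numbers(self) -> list[int]:
        return sorted(self.ca)

    def ca_array(self, selection=None) -> tuple[np.ndarray, list[int]]:
        """(n, 3) array of C-alpha coordinates and the residue numbers used."""
        nums = self.residue_numbers if selection is None else sorted(selection)
        missing = [n for n in nums if n not in self.ca]
        if missing:
            raise KeyError(f"chain {self.chain}: no C-alpha for residues {missing}")
        return np.array([self.ca[n] for n in nums]), nums

    def get_atom(self, resnum: int, atom_name: str) -> np.ndarray:
        try:
            return self.atoms[(resnum, atom_name)]
        except KeyError:
            raise KeyError(
                f"chain {self.chain}: atom {atom_name} of residue {resnum} not present"
            ) from None

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureModel":
        """Copy with x -> R x + t applied to every coordinate."""
        R, t = np.asarray(rotation), np.asarray(translation)
        return StructureModel(
            chain=self.chain,
            ca={n: R @ c + t for n, c in self.ca.items()},
            resnames=dict(self.resnames),
            atoms={k: R @ c + t for k, c in self.atoms.items()},
        )


@dataclass(frozen=True)
class MarkerTriple:
    """Three marker residues defining the aperture angle.

    ``residues`` are residue numbers in a fixed order; ``vertex`` selects
    which of the three (1-based) is the apex of the angle.  Default vertex is
    2, the middle of the conventional listing order.
    """

    residues: tuple[int, int, int]
    chain: str | None = None
    vertex: int = 2

    def __post_init__(self) -> None:
        if len(set(self.residues)) != 3:
            raise ValueError(f"markers must be three distinct residues, got {self.residues}")
        if self.vertex not in (1, 2, 3):
            raise ValueError(f"vertex must be 1, 2 or 3, got {self.vertex}")


#: Conserved-motif markers for the plant deformylase numbering
#: (Cys91 in motif 2, His137 in motif 3, Ile42 in motif 1); vertex = His.
DEFAULT_MARKERS = MarkerTriple(residues=(91, 137, 42), vertex=2)


@dataclass(frozen=True)
class ApertureResult:
    """One structure's position in the (delta_ap, rmsd) plane plus its label."""

    delta_ap: float
    rmsd_vs_reference: float
    state: str  # "O", "I", "C", "S" or "unassigned"


@dataclass(frozen=True)
class StateZone:
    """A closed rectangle [delta_min, delta_max] x [rmsd_min, rmsd_max]."""

    label: str
    delta_min: float
    delta_max: float
    rmsd_min: float
    rmsd_max: float

    def contains(self, delta: float, rmsd: float) -> bool:
        return (self.delta_min <= delta <= self.delta_max
                and self.rmsd_min <= rmsd <= self.rmsd_max)

    def _interior_overlaps(self, other: "StateZone") -> bool:
        return (self.delta_min < other.delta_max and other.delta_min < self.delta_max
                and self.rmsd_min < other.rmsd_max and other.rmsd_min < self.rmsd_max)


class StateZoneConfig:
    """Ordered, interior-disjoint zones in the (delta_ap, rmsd) plane.

    Boundary points belong to the first zone (in config order) whose closed
    rectangle contains them; interior overlap is a configuration error.
    """

    def __init__(self, zones: list[StateZone]):
        for i, a in enumerate(zones):
            for b in zones[i + 1:]:
                if a._interior_overlaps(b):
                    raise ValueError(f"zones {a.label!r} and {b.label!r} overlap")
        self.zones = list(zones)

    @classmethod
    def from_yaml(cls, text: str) -> "StateZoneConfig":
        raw = yaml.safe_load(text)
        return cls([StateZone(**z) for z in raw["zones"]])

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"zones": [vars(z) for z in self.zones]}, sort_keys=False
        )


# Approximate default state map; delta_ap bands are disjoint so the rectangles
# cannot overlap.  Only the O-zone rmsd edge (0.25 A) is anchored to a
# published number; everything else must be calibrated per ensemble.
DEFAULT_ZONES = StateZoneConfig([
    StateZone("O", 88.0, 180.0, 0.0, 0.25),
    StateZone("I", 82.0, 88.0, 0.25, 0.70),
    StateZone("C", 74.0, 82.0, 0.60, 1.20),
    StateZone("S", 0.0, 74.0, 0.80, 3.00),
])


def read_structure(pdb_text: str, chain: str | None = None) -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel`.

    Only the requested chain (default: first chain of the first model) is
    read.  Alternate locations are resolved to the highest-occupancy conformer,
    ties broken alphabetically by altloc id.  A residue without a C-alpha does
    not fail here; lookups fail later, explicitly.
    """
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError("no models/chains in PDB text")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"chain {chain!r} not found")

    ca: dict[int, np.ndarray] = {}
    resnames: dict[int, str] = {}
    atoms: dict[tuple[int, str], np.ndarray] = {}
    best_alt: dict[tuple[int, str], tuple[float, str]] = {}
    for res in ch:
        num = res.seqid.num
        resnames[num] = res.name
        for atom in res:
            key = (num, atom.name)
            rank = (-atom.occ, atom.altloc or "")
            if key in best_alt and rank >= best_alt[key]:
                continue
            best_alt[key] = rank
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            atoms[key] = pos
            if atom.name == "CA":
                ca[num] = pos
    return StructureModel(chain=ch.name, ca=ca, resnames=resnames, atoms=atoms)


def kabsch_superpose(
    mobile: StructureModel,
    reference: StructureModel,
    residue_selection=None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of matched C-alpha atoms (Kabsch, SVD).

    Returns ``(rotation, translation, rmsd)`` such that ``R @ x + t`` maps
    mobile coordinates onto the reference with minimal C-alpha RMSD.  The
    rotation is always proper (det = +1).  Residues are matched by author
    number; ``residue_selection`` restricts the match.
    """
    common = set(mobile.ca) & set(reference.ca)
    if residue_selection is not None:
        common &= set(residue_selection)
    if len(common) < 3:
        raise ValueError(f"need >= 3 matched residues, got {len(common)}")
    X, _ = mobile.ca_array(common)
    Y, _ = reference.ca_array(common)
    xc, yc = X.mean(axis=0), Y.mean(axis=0)
    H = (X - xc).T @ (Y - yc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = yc - R @ xc
    diff = (X @ R.T + t) - Y
    rmsd = float(np.sqrt((diff ** 2).sum() / len(common)))
    return R, t, rmsd


def aperture_angle(model: StructureModel, markers: MarkerTriple = DEFAULT_MARKERS) -> float:
    """Aperture angle delta_ap in degrees at the vertex marker's C-alpha.

    Invariant under rigid motion; raises if any marker C-alpha is missing or
    the points are coincident.
    """
    coords = []
    for num in markers.residues:
        if num not in model.ca:
            raise KeyError(f"marker residue {num} has no C-alpha in chain {model.chain}")
        coords.append(model.ca[num])
    v_idx = markers.vertex - 1
    apex = coords[v_idx]
    arms = [c for i, c in enumerate(coords) if i != v_idx]
    u, w = arms[0] - apex, arms[1] - apex
    nu, nw = np.linalg.norm(u), np.linalg.norm(w)
    if nu == 0 or nw == 0:
        raise ValueError("coincident marker points: aperture angle undefined")
    cosang = np.clip(u @ w / (nu * nw), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def residue_displacement(
    mobile: StructureModel,
    reference: StructureModel,
    rotation: np.ndarray,
    translation: np.ndarray,
) -> tuple[dict[int, float], int]:
    """Per-residue C-alpha displacement (A) after applying the transform.

    Returns ``(displacements, argmax_residue)`` over residues common to both
    structures.
    """
    common = sorted(set(mobile.ca) & set(reference.ca))
    disp = {
        n: float(np.linalg.norm(rotation @ mobile.ca[n] + translation - reference.ca[n]))
        for n in common
    }
    argmax = max(disp, key=disp.get)
    return disp, argmax


def atom_distance(
    model: StructureModel,
    atom_ref_a: tuple[int, str],
    atom_ref_b: tuple[int, str],
) -> float:
    """Euclidean distance (A) between two atoms given as (resnum, atom name)."""
    a = model.get_atom(*atom_ref_a)
    b = model.get_atom(*atom_ref_b)
    return float(np.linalg.norm(a - b))


def classify_state(
    delta_ap: float,
    rmsd: float,
    zones: StateZoneConfig = DEFAULT_ZONES,
) -> str:
    """Label a (delta_ap, rmsd) point; 'unassigned' outside every zone."""
    for zone in zones.zones:
        if zone.contains(delta_ap, rmsd):
            return zone.label
    return "unassigned"
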