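"""Structure I/O and reference feature assignment for design scaffolds.

Reads and writes PDB-format coordinate files, detects C-alpha-only input,
rebuilds backbone heavy atoms from the CA trace when needed, and assigns the
reference structural features used by the design force field: 3-state
secondary structure (hydrogen-bond based, Kabsch–Sander style), backbone
phi/psi torsions, and relative solvent accessibility (Shrake–Rupley sphere
sampling against per-residue-type maximum areas).
"""
from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial import cKDTree

from ._data import (
    AA_INDEX,
    MAX_ASA,
    MAX_ASA_DEFAULT,
    ONE_TO_THREE,
    THREE_TO_ONE,
    VDW_DEFAULT,
    VDW_RADII,
)
from ._geom import dihedral, fibonacci_sphere, molecular_frame, unit

#: Minimum scaffold length for a meaningful fold.
MIN_SCAFFOLD_LENGTH = 30

# Ideal backbone internal coordinates (A) used in reconstruction.
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
CA_CA = 3.80

# In-plane offsets of C(i) and N(i+1) from CA(i) in the (axis, normal)
# frame of a trans peptide unit with CA-CA = 3.8 A; solved from the three
# bond-length constraints with symmetric out-of-axis displacement.
_PEP_C = (1.449364, 0.457978)
_PEP_N = (2.413690, -0.457978)

# Kabsch-Sander electrostatic hydrogen-bond model.
_HB_COUPLING = 0.084 * 332.0  # kcal/mol * A
HB_ENERGY_CUTOFF = -0.5  # kcal/mol


class StructureError(ValueError):
    """Malformed or unusable structure input."""


class ScaffoldTooShortError(StructureError):
    pass


class FeatureAssignmentError(StructureError):
    pass


@dataclasses.dataclass
class Residue:
    number: int
    icode: str
    aa: str  # one-letter code, "X" if unknown
    atoms: Dict[str, np.ndarray]

    @property
    def identity(self) -> str:
        return f"{self.number}{self.icode}".strip()

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclasses.dataclass
class HeteroAtom:
    name: str
    resname: str
    coord: np.ndarray


@dataclasses.dataclass
class Structure:
    """Ordered per-residue coordinates plus non-water hetero atoms."""

    residues: List[Residue]
    hetero_atoms: List[HeteroAtom] = dataclasses.field(default_factory=list)
    chain_id: str = "A"
    name: str = ""

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.residues])

    def copy(self) -> "Structure":
        return Structure(
            residues=[
                Residue(r.number, r.icode, r.aa,
                        {k: v.copy() for k, v in r.atoms.items()})
                for r in self.residues
            ],
            hetero_atoms=[HeteroAtom(h.name, h.resname, h.coord.copy())
                          for h in self.hetero_atoms],
            chain_id=self.chain_id,
            name=self.name,
        )

    def transformed(self, rot: np.ndarray, trans: np.ndarray) -> "Structure":
        """Rigid-body transformed copy (x -> rot @ x + trans)."""
        out = self.copy()
        for r in out.residues:
            for k in r.atoms:
                r.atoms[k] = rot @ r.atoms[k] + trans
        for h in out.hetero_atoms:
            h.coord = rot @ h.coord + trans
        return out


@dataclasses.dataclass
class ScaffoldFeatures:
    """Reference features of the scaffold: SS, torsions and relative SA.

    ``ss`` uses the 3-letter alphabet H/E/C; ``phi``/``psi`` are degrees in
    (-180, 180] with NaN at chain termini where the dihedral is undefined;
    ``rsa`` is exposed area over the per-residue-type maximum, in [0, 1].
    """

    ss: str
    phi: np.ndarray
    psi: np.ndarray
    rsa: np.ndarray

    def __len__(self) -> int:
        return len(self.ss)


def read_pdb(path, chain: Optional[str] = None,
             min_length: int = MIN_SCAFFOLD_LENGTH) -> Structure:
    """Read one chain of a PDB file into a :class:`Structure`.

    Takes model 1 and, by default, the first chain containing CA atoms.
    Non-water HETATM records from the whole model are collected as hetero
    atoms. Raises :class:`ScaffoldTooShortError` below ``min_length``
    residues (pass a smaller ``min_length`` for homolog-library members).
    """
    path = Path(path)
    parser = PDBParser(QUIET=True)
    model = parser.get_structure(path.stem, str(path))[0]

    target_chain = None
    for ch in model:
        has_ca = any("CA" in res for res in ch if res.id[0] == " ")
        if chain is None and has_ca:
            target_chain = ch
            break
        if chain is not None and ch.id == chain:
            target_chain = ch
            break
    if target_chain is None:
        raise StructureError(f"{path}: no chain with CA atoms"
                             + (f" (requested chain {chain!r})" if chain else ""))

    residues: List[Residue] = []
    for res in target_chain:
        if res.id[0] != " ":
            continue
        atoms = {a.get_name(): a.get_coord().astype(float) for a in res}
        if "CA" not in atoms:
            continue
        aa = THREE_TO_ONE.get(res.get_resname().strip(), "X")
        residues.append(Residue(res.id[1], res.id[2].strip(), aa, atoms))
    if not residues:
        raise StructureError(f"{path}: no ATOM records with CA atoms")
    if len(residues) < min_length:
        raise ScaffoldTooShortError(
            f"{path}: scaffold has {len(residues)} residues; "
            f"at least {min_length} are required for a meaningful fold"
        )

    hetero: List[HeteroAtom] = []
    for ch in model:
        for res in ch:
            hetfield = res.id[0]
            if hetfield == " " or hetfield == "W":
                continue
            resname = res.get_resname().strip()
            if resname == "HOH":
                continue
            for atom in res:
                hetero.append(HeteroAtom(atom.get_name(), resname,
                                         atom.get_coord().astype(float)))

    if not np.all(np.isfinite(np.concatenate(
            [a for r in residues for a in r.atoms.values()]))):
        raise StructureError(f"{path}: non-finite coordinates")
    return Structure(residues, hetero, target_chain.id, path.stem)


_BB_ORDER = ("N", "CA", "C", "O", "CB")


def write_pdb(structure: Structure, path) -> None:
    """Write a structure back out as fixed-column ATOM/HETATM records."""
    lines = []
    serial = 1
    for res in structure.residues:
        resname = ONE_TO_THREE.get(res.aa, "UNK")
        names = [n for n in _BB_ORDER if n in res.atoms]
        names += [n for n in res.atoms if n not in _BB_ORDER]
        for name in names:
            x, y, z = res.atoms[name]
            pad = name if len(name) >= 4 else f" {name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {pad}{'':1s}{resname:>3s} "
                f"{structure.chain_id:1s}{res.number:4d}{res.icode or ' ':1s}"
                f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {name[0]:>2s}"
            )
            serial += 1
    lines.append(f"TER   {serial:5d}      "
                 f"{ONE_TO_THREE.get(structure.residues[-1].aa, 'UNK'):>3s} "
                 f"{structure.chain_id}{structure.residues[-1].number:4d}")
    serial += 1
    for i, het in enumerate(structure.hetero_atoms):
        x, y, z = het.coord
        name = het.name
        pad = name if len(name) >= 4 else f" {name:<3s}"
        lines.append(
            f"HETATM{serial:5d} {pad}{'':1s}{het.resname[:3]:>3s} "
            f"{structure.chain_id:1s}{9000 + i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def is_ca_only(structure: Structure) -> bool:
    """True when the backbone is incomplete, i.e. not every residue carries
    all of N, CA and C — such structures need reconstruction before feature
    assignment."""
    return not all(r.has_backbone() for r in structure.residues)


def reconstruct_backbone(structure: Structure) -> Structure:
    """Rebuild backbone heavy atoms (N, C, O) on a CA-trace structure.

    Each trans peptide unit CA(i)->CA(i+1) receives C(i) and N(i+1) at
    ideal in-plane offsets; carbonyl O is placed by the bisector rule. CA
    positions are untouched; residues that already have a complete backbone
    keep their atoms, so the operation is the identity on full-backbone
    input and idempotent on its own output. Side chains are not built.
    """
    if not is_ca_only(structure):
        return structure
    if len(structure) < 3:
        raise StructureError(
            "backbone reconstruction needs at least 3 residues to define "
            "local CA-trace geometry"
        )
    out = structure.copy()
    ca = out.ca_coords()
    n_res = len(out)

    # peptide-plane normal for unit i: span of e1 and the next CA direction
    def plane_normal(i: int, e1: np.ndarray) -> np.ndarray:
        if i + 2 < n_res:
            ref = ca[i + 2] - ca[i]
        else:
            ref = ca[i] - ca[i - 1]
        nrm = np.cross(e1, ref)
        if np.linalg.norm(nrm) < 1e-8:  # collinear trace: pick any perp
            ref = np.array([1.0, 0.0, 0.0])
            if abs(np.dot(unit(e1), ref)) > 0.9:
                ref = np.array([0.0, 1.0, 0.0])
            nrm = np.cross(e1, ref)
        return unit(nrm)

    for i in range(n_res - 1):
        e1 = ca[i + 1] - ca[i]
        d = np.linalg.norm(e1)
        e1u = e1 / d
        scale = d / CA_CA  # tolerate slightly non-ideal CA spacing
        m = np.cross(plane_normal(i, e1), e1u)
        c_pos = ca[i] + _PEP_C[0] * scale * e1u + _PEP_C[1] * m
        n_pos = ca[i] + _PEP_N[0] * scale * e1u + _PEP_N[1] * m
        out.residues[i].atoms.setdefault("C", c_pos)
        out.residues[i + 1].atoms.setdefault("N", n_pos)

    # terminal extrapolations so every residue has N and C
    out.residues[0].atoms.setdefault(
        "N", ca[0] + BOND_N_CA * unit(ca[0] - ca[1]))
    out.residues[-1].atoms.setdefault(
        "C", ca[-1] + BOND_CA_C * unit(ca[-1] - ca[-2]))

    for i in range(n_res):
        res = out.residues[i]
        if "O" in res.atoms:
            continue
        c_pos = res.atoms["C"]
        if i + 1 < n_res:
            n_next = out.residues[i + 1].atoms["N"]
            o_dir = -(unit(n_next - c_pos) + unit(res.atoms["CA"] - c_pos))
        else:
            o_dir = np.cross(unit(c_pos - res.atoms["CA"]),
                             plane_normal(i - 1, ca[i] - ca[i - 1]))
            if np.linalg.norm(o_dir) < 1e-8:
                o_dir = np.array([0.0, 0.0, 1.0])
        res.atoms["O"] = c_pos + BOND_C_O * unit(o_dir)
    return out


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander style hydrogen bonds)
# ---------------------------------------------------------------------------

def _amide_hydrogens(structure: Structure) -> List[Optional[np.ndarray]]:
    """Backbone amide H positions: 1 A from N, anti-parallel to the
    preceding carbonyl C->O vector (the classic DSSP construction). The
    first residue (and any Pro-like gap) gets no donor."""
    hs: List[Optional[np.ndarray]] = [None]
    for i in range(1, len(structure)):
        prev = structure.residues[i - 1]
        res = structure.residues[i]
        if "C" not in prev.atoms or "O" not in prev.atoms or "N" not in res.atoms:
            hs.append(None)
            continue
        if res.aa == "P":  # proline has no amide hydrogen
            hs.append(None)
            continue
        direction = prev.atoms["C"] - prev.atoms["O"]
        hs.append(res.atoms["N"] + unit(direction))
    return hs


def hydrogen_bond_energy(n, h, c, o) -> float:
    """Electrostatic H-bond energy (kcal/mol) of donor N-H vs acceptor C=O."""
    r_on = np.linalg.norm(o - n)
    r_ch = np.linalg.norm(c - h)
    r_oh = np.linalg.norm(o - h)
    r_cn = np.linalg.norm(c - n)
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:
        return -9.9
    return _HB_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _hbond_matrix(structure: Structure) -> np.ndarray:
    """hb[d, a] True when the N-H of residue d donates to the C=O of a."""
    n_res = len(structure)
    hs = _amide_hydrogens(structure)
    hb = np.zeros((n_res, n_res), dtype=bool)
    co = []
    for res in structure.residues:
        if "C" in res.atoms and "O" in res.atoms:
            co.append((res.atoms["C"], res.atoms["O"]))
        else:
            co.append(None)
    ca = structure.ca_coords()
    tree = cKDTree(ca)
    neighbor = tree.query_ball_tree(tree, r=9.0)
    for d in range(n_res):
        if hs[d] is None:
            continue
        n_pos = structure.residues[d].atoms.get("N")
        if n_pos is None:
            continue
        for a in neighbor[d]:
            if abs(d - a) < 2 or co[a] is None:
                continue
            e = hydrogen_bond_energy(n_pos, hs[d], co[a][0], co[a][1])
            if e < HB_ENERGY_CUTOFF:
                hb[d, a] = True
    return hb


def _assign_ss(structure: Structure) -> str:
    """3-state SS from backbone hydrogen bonds.

    n-turns (n = 3, 4, 5) and bridge patterns follow the Kabsch–Sander
    definitions; 4-helices, then strand bridges, then 3/5-helices are
    marked, and the 8-state repertoire is collapsed as H,G,I -> H and
    E,B -> E with everything else coil.
    """
    n_res = len(structure)
    hb = _hbond_matrix(structure)

    def turn(n: int) -> np.ndarray:
        t = np.zeros(n_res, dtype=bool)
        for i in range(n_res - n):
            if hb[i + n, i]:
                t[i] = True
        return t

    t3, t4, t5 = turn(3), turn(4), turn(5)
    ss = ["C"] * n_res

    def mark_helix(t: np.ndarray, n: int) -> np.ndarray:
        marked = np.zeros(n_res, dtype=bool)
        for i in range(1, n_res - n):
            if t[i - 1] and t[i]:
                marked[i:i + n] = True
        return marked

    helix4 = mark_helix(t4, 4)
    helix3 = mark_helix(t3, 3)
    helix5 = mark_helix(t5, 5)

    bridge = np.zeros(n_res, dtype=bool)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            para = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            anti = (hb[i, j] and hb[j, i]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1])
            if para or anti:
                bridge[i] = bridge[j] = True

    for i in range(n_res):
        if helix4[i]:
            ss[i] = "H"
        elif bridge[i]:
            ss[i] = "E"
        elif helix3[i] or helix5[i]:
            ss[i] = "H"
    return "".join(ss)


# ---------------------------------------------------------------------------
# Solvent accessibility (Shrake-Rupley)
# ---------------------------------------------------------------------------

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960


def _atom_radius(name: str) -> float:
    element = name.strip()[0]
    return VDW_RADII.get(element, VDW_DEFAULT)


def shrake_rupley_areas(coords: np.ndarray, radii: np.ndarray,
                        n_points: int = N_SPHERE_POINTS,
                        probe: float = PROBE_RADIUS) -> np.ndarray:
    """Per-atom solvent-accessible surface area by sphere-point sampling.

    Sample points are oriented in the molecule's own principal-axis frame,
    which makes the result exactly invariant under rigid rotation and
    translation of the input.
    """
    coords = np.asarray(coords, dtype=float)
    n_atoms = len(coords)
    sphere = fibonacci_sphere(n_points)
    if n_atoms >= 3:
        sphere = sphere @ molecular_frame(coords)
    ext = radii + probe
    tree = cKDTree(coords)
    areas = np.empty(n_atoms)
    max_ext = ext.max()
    for i in range(n_atoms):
        pts = coords[i] + ext[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], ext[i] + max_ext)
                     if j != i]
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = np.einsum("ij,ij->i", pts - coords[j], pts - coords[j])
            exposed &= d2 > ext[j] ** 2
        areas[i] = 4.0 * math.pi * ext[i] ** 2 * exposed.sum() / n_points
    return areas


def relative_accessibility(structure: Structure) -> np.ndarray:
    coords, radii, owner = [], [], []
    for ri, res in enumerate(structure.residues):
        for name, xyz in res.atoms.items():
            coords.append(xyz)
            radii.append(_atom_radius(name))
            owner.append(ri)
    areas = shrake_rupley_areas(np.array(coords), np.array(radii))
    rsa = np.zeros(len(structure))
    np.add.at(rsa, np.array(owner), areas)
    for ri, res in enumerate(structure.residues):
        max_area = (MAX_ASA[AA_INDEX[res.aa]]
                    if res.aa in AA_INDEX else MAX_ASA_DEFAULT)
        rsa[ri] /= max_area
    return np.clip(rsa, 0.0, 1.0)


def assign_features(structure: Structure) -> ScaffoldFeatures:
    """Reference SS / phi / psi / relative-SA tracks for a full-backbone
    scaffold. Raises :class:`FeatureAssignmentError` naming the first
    residue whose backbone is incomplete."""
    for res in structure.residues:
        if not res.has_backbone() or "O" not in res.atoms:
            raise FeatureAssignmentError(
                f"residue {res.identity} ({res.aa}) lacks backbone atoms; "
                "run reconstruct_backbone first"
            )
    n_res = len(structure)
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    for i in range(n_res):
        res = structure.residues[i].atoms
        if i > 0:
            prev = structure.residues[i - 1].atoms
            phi[i] = dihedral(prev["C"], res["N"], res["CA"], res["C"])
        if i + 1 < n_res:
            nxt = structure.residues[i + 1].atoms
            psi[i] = dihedral(res["N"], res["CA"], res["C"], nxt["N"])
    return ScaffoldFeatures(
        ss=_assign_ss(structure),
        phi=phi,
        psi=psi,
        rsa=relative_accessibility(structure),
    )


def binding_site_residues(structure: Structure, radius: float = 8.0) -> Set[int]:
    """Residue numbers with any atom within ``radius`` A of a hetero atom."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not structure.hetero_atoms:
        return set()
    het = np.array([h.coord for h in structure.hetero_atoms])
    out: Set[int] = set()
    for res in structure.residues:
        pts = np.array(list(res.atoms.values()))
        d2 = ((pts[:, None, :] - het[None, :, :]) ** 2).sum(axis=2)
        if (d2 <= radius ** 2).any():
            out.add(res.number)
    return out
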