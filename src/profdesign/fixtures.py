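"""Deterministic synthetic structures and structure families.

Everything downstream (profile construction, predictor training, design
runs) is exercised on structures generated here: chains built from ideal
backbone internal coordinates for a requested topology, plus "families" of
structural neighbours obtained by jittering coordinates and mutating
sequences at known rates, so profile-recovery tests have ground truth.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._data import AA_ALPHABET, AA_INDEX, N_AA
from ._geom import kabsch, place_atom, unit
from .structio import (
    BOND_C_N,
    BOND_C_O,
    BOND_CA_C,
    BOND_N_CA,
    MIN_SCAFFOLD_LENGTH,
    HeteroAtom,
    Residue,
    Structure,
)

# Ideal backbone bond angles (degrees).
_ANG_N_CA_C = 111.0
_ANG_CA_C_N = 116.2
_ANG_C_N_CA = 121.7
_OMEGA = 180.0

# Canonical (phi, psi) per topology element.
HELIX_PHI_PSI = (-62.0, -41.0)
STRAND_PHI_PSI = (-140.0, 135.0)
# A short connecting loop that turns the chain back on itself.
_LOOP_TORSIONS = [(-90.0, 0.0), (75.0, 60.0), (-100.0, 20.0), (-70.0, 140.0)]

TOPOLOGIES = ("helix_bundle", "beta_hairpin", "mixed")

# Residue pools biased toward each SS class, used to give synthetic chains
# sequences whose composition correlates with their local structure.
_SS_POOLS = {
    "H": "AELMKQRAELMK",
    "E": "VIFYTWVIFYCT",
    "C": "GPSNDGTSHQKD",
}


@dataclasses.dataclass
class FamilySpec:
    """Generator settings for a synthetic structure family."""

    n_members: int = 15
    coordinate_noise: float = 0.5  # A, per-coordinate Gaussian std
    mutation_rate: float = 0.1  # per-position substitution probability
    topology: str = "helix_bundle"
    length: int = 40
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.coordinate_noise < 0:
            raise ValueError("coordinate_noise must be non-negative")
        if self.length < MIN_SCAFFOLD_LENGTH:
            raise ValueError(
                f"length must be >= {MIN_SCAFFOLD_LENGTH}, got {self.length}")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")


def _topology_torsions(topology: str, length: int) -> Tuple[List[Tuple[float, float]], str]:
    """(phi, psi) per residue plus the intended SS label string."""
    torsions: List[Tuple[float, float]] = []
    labels: List[str] = []

    def add(kind: str, n: int) -> None:
        for k in range(n):
            if kind == "H":
                torsions.append(HELIX_PHI_PSI)
            elif kind == "E":
                torsions.append(STRAND_PHI_PSI)
            else:
                torsions.append(_LOOP_TORSIONS[k % len(_LOOP_TORSIONS)])
            labels.append(kind)

    if topology == "helix_bundle":
        pattern = [("H", 12), ("C", 4)]
    elif topology == "beta_hairpin":
        pattern = [("E", 8), ("C", 4)]
    else:  # mixed
        pattern = [("H", 10), ("C", 3), ("E", 7), ("C", 3)]

    i = 0
    while len(torsions) < length:
        kind, n = pattern[i % len(pattern)]
        add(kind, min(n, length - len(torsions)))
        i += 1
    return torsions[:length], "".join(labels[:length])


def _build_backbone(torsions: List[Tuple[float, float]]) -> List[Dict[str, np.ndarray]]:
    """Backbone atoms (N, CA, C, O) from a phi/psi list, ideal geometry."""
    length = len(torsions)
    atoms: List[Dict[str, np.ndarray]] = [dict() for _ in range(length)]
    atoms[0]["N"] = np.zeros(3)
    atoms[0]["CA"] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _ANG_N_CA_C)
    atoms[0]["C"] = atoms[0]["CA"] + BOND_CA_C * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, length):
        prev = atoms[i - 1]
        psi_prev = torsions[i - 1][1]
        atoms[i]["N"] = place_atom(prev["N"], prev["CA"], prev["C"],
                                   BOND_C_N, _ANG_CA_C_N, psi_prev)
        atoms[i]["CA"] = place_atom(prev["CA"], prev["C"], atoms[i]["N"],
                                    BOND_N_CA, _ANG_C_N_CA, _OMEGA)
        atoms[i]["C"] = place_atom(prev["C"], atoms[i]["N"], atoms[i]["CA"],
                                   BOND_CA_C, _ANG_N_CA_C, torsions[i][0])
    for i in range(length):
        c = atoms[i]["C"]
        if i + 1 < length:
            o_dir = -(unit(atoms[i + 1]["N"] - c) + unit(atoms[i]["CA"] - c))
        else:
            o_dir = unit(np.cross(c - atoms[i]["CA"],
                                  atoms[i]["CA"] - atoms[i]["N"]))
        atoms[i]["O"] = c + BOND_C_O * unit(o_dir)
    return atoms


def _sample_sequence(labels: str, rng: np.random.Generator) -> str:
    return "".join(_SS_POOLS[c][rng.integers(len(_SS_POOLS[c]))] for c in labels)


def make_ideal_structure(topology: str, length: int, seed: int = 0,
                         with_ligand: bool = False) -> Structure:
    """Full-backbone structure with ideal torsions for ``topology``.

    The sequence is sampled with SS-class-biased residue pools so that
    sequence composition carries a learnable structural signal; generation
    is deterministic per seed. ``with_ligand`` drops a 3-atom pseudo-ligand
    near the chain midpoint for binding-site tests.
    """
    if topology not in TOPOLOGIES:
        raise ValueError(f"unknown topology {topology!r}; one of {TOPOLOGIES}")
    if length < MIN_SCAFFOLD_LENGTH:
        raise ValueError(
            f"length must be >= {MIN_SCAFFOLD_LENGTH}, got {length}")
    rng = np.random.default_rng(seed)
    torsions, labels = _topology_torsions(topology, length)
    backbone = _build_backbone(torsions)
    sequence = _sample_sequence(labels, rng)
    residues = [
        Residue(number=i + 1, icode="", aa=sequence[i], atoms=backbone[i])
        for i in range(length)
    ]
    hetero: List[HeteroAtom] = []
    if with_ligand:
        mid = backbone[length // 2]["CA"]
        offsets = np.array([[4.0, 0.5, 0.0], [4.8, 1.6, 0.4], [5.4, 0.2, -0.8]])
        for k, off in enumerate(offsets):
            hetero.append(HeteroAtom(f"C{k + 1}", "LIG", mid + off))
    return Structure(residues, hetero, "A", f"{topology}_{length}_{seed}")


def make_antiparallel_sheet(n_per_strand: int = 8, seed: int = 0) -> Structure:
    """Two extended strands paired antiparallel with sheet hydrogen bonds.

    The partner strand is the 180-degree-rotated copy of an ideal extended
    strand, offset so backbone N-H / C=O groups register across the pair.
    A slightly flattened strand twist is used (a rigidly paired copy of a
    fully twisted strand registers hydrogen bonds only at alternating
    positions); the torsions and registration offsets were tuned once
    against the hydrogen-bond assignment and frozen.
    """
    torsions = [_SHEET_STRAND_PHI_PSI] * n_per_strand
    backbone = _build_backbone(torsions)
    coords = np.array([a for res in backbone for a in
                       (res["N"], res["CA"], res["C"], res["O"])])
    axis = unit(backbone[-1]["CA"] - backbone[0]["CA"])
    # rotate 180 deg about the axis perpendicular to both the strand axis
    # and the pairing direction, then translate across the pairing direction
    ref = np.array([0.0, 0.0, 1.0])
    pair_dir = unit(np.cross(axis, ref))
    rot_axis = unit(np.cross(axis, pair_dir))
    rot = _rotation_about(rot_axis, np.pi)
    center = coords.mean(axis=0)
    shift = _SHEET_PAIR_OFFSET[0] * axis + _SHEET_PAIR_OFFSET[1] * pair_dir \
        + _SHEET_PAIR_OFFSET[2] * rot_axis
    rng = np.random.default_rng(seed)
    seq1 = _sample_sequence("E" * n_per_strand, rng)
    seq2 = _sample_sequence("E" * n_per_strand, rng)
    residues = []
    for i in range(n_per_strand):
        residues.append(Residue(i + 1, "", seq1[i], dict(backbone[i])))
    for i in range(n_per_strand):
        atoms = {k: rot @ (v - center) + center + shift
                 for k, v in backbone[n_per_strand - 1 - i].items()}
        residues.append(Residue(n_per_strand + i + 1, "", seq2[i], atoms))
    return Structure(residues, [], "A", f"sheet_pair_{n_per_strand}")


# Frozen sheet-pair registration: strand torsions and (along-axis,
# pairing, out-of-plane) translation of the partner strand in A.
_SHEET_STRAND_PHI_PSI = (-119.0, 113.0)
_SHEET_PAIR_OFFSET = (2.0, 4.0, 0.0)


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = unit(axis)
    k = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * k @ k


def mutate_sequence(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for aa in seq:
        if rng.random() < rate:
            choices = [a for a in AA_ALPHABET if a != aa]
            out.append(choices[rng.integers(19)])
        else:
            out.append(aa)
    return "".join(out)


def make_family(spec: FamilySpec) -> Tuple[Structure, List[Structure], np.ndarray]:
    """A scaffold plus a library of jittered, mutated structural neighbours.

    Returns ``(scaffold, members, true_profile)`` where ``true_profile`` is
    the L x 20 per-position residue distribution the member sequences were
    drawn from: scaffold residue with probability 1 - mutation_rate, the
    other 19 residues uniformly sharing the rest.
    """
    spec.validate()
    scaffold = make_ideal_structure(spec.topology, spec.length, spec.seed)
    rng = np.random.default_rng(spec.seed + 1)
    members: List[Structure] = []
    for m in range(spec.n_members):
        member = scaffold.copy()
        member.name = f"member_{m:03d}"
        new_seq = mutate_sequence(scaffold.sequence, spec.mutation_rate, rng)
        for i, res in enumerate(member.residues):
            res.aa = new_seq[i]
            for k in res.atoms:
                res.atoms[k] = res.atoms[k] + rng.normal(
                    0.0, spec.coordinate_noise, 3)
        members.append(member)

    true_profile = np.full((spec.length, N_AA),
                           spec.mutation_rate / 19.0 if spec.mutation_rate else 0.0)
    for i, aa in enumerate(scaffold.sequence):
        true_profile[i, AA_INDEX[aa]] = 1.0 - spec.mutation_rate
    if spec.mutation_rate == 0.0:
        for i, aa in enumerate(scaffold.sequence):
            true_profile[i] = 0.0
            true_profile[i, AA_INDEX[aa]] = 1.0
    return scaffold, members, true_profile


def make_training_chains(n_chains: int, length: int = 40, seed: int = 0):
    """(sequence, ScaffoldFeatures) pairs for predictor training, covering
    all three topologies."""
    from .structio import assign_features

    rng = np.random.default_rng(seed)
    out = []
    for k in range(n_chains):
        topo = TOPOLOGIES[k % len(TOPOLOGIES)]
        s = make_ideal_structure(topo, length, seed=int(rng.integers(2 ** 31)))
        out.append((s.sequence, assign_features(s)))
    return out


def write_fixture_library(outdir, spec: FamilySpec) -> Path:
    """Write a family to disk as a scaffold PDB, a library directory of
    member PDBs, and a truth JSON with the generating distribution."""
    from .structio import write_pdb

    outdir = Path(outdir)
    (outdir / "library").mkdir(parents=True, exist_ok=True)
    scaffold, members, true_profile = make_family(spec)
    write_pdb(scaffold, outdir / "scaffold.pdb")
    for m in members:
        write_pdb(m, outdir / "library" / f"{m.name}.pdb")
    truth = {
        "spec": dataclasses.asdict(spec),
        "scaffold_sequence": scaffold.sequence,
        "true_profile": true_profile.tolist(),
        "alphabet": AA_ALPHABET,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
    return outdir
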