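"""Backbone geometry: dihedrals to Cartesian coordinates and back.

A protein backbone is represented by per-residue (phi, psi) dihedral angles;
Cartesian coordinates for N, CA, C, O and a single side-chain pseudo-atom
(emitted as CB) are built deterministically by sequential internal-coordinate
chain extension with fixed ideal bond lengths and angles (Engh--Huber-like
values, omega fixed at 180 degrees). Glycine carries no side-chain atom; for
alanine the pseudo-atom is the true CB; for all other residues it is a CB-like
placeholder at the ideal CB position.

Angles are in degrees throughout, in the half-open range (-180, 180]; the
undefined terminal angles phi(1) and psi(L) are stored as NaN sentinels and
never enter the construction. Residue indices are 1-based at all interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

#: Sentinel for the undefined terminal angles phi(1) and psi(L).
UNDEFINED_ANGLE = math.nan

BACKBONE_ROLES = ("N", "CA", "C", "O", "SC")


def wrap_angle(x):
    """Wrap angles (degrees) into (-180, 180]."""
    y = np.mod(np.asarray(x, dtype=float) + 180.0, 360.0) - 180.0
    y = np.where(y == -180.0, 180.0, y)
    if np.ndim(x) == 0:
        return float(y)
    return y


@dataclass(frozen=True)
class Sequence:
    """An amino-acid sequence in one-letter code (length >= 2)."""

    letters: str

    def __post_init__(self):
        if len(self.letters) < 2:
            raise ValueError("sequence must contain at least 2 residues")
        bad = set(self.letters) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"invalid amino-acid codes: {sorted(bad)}")

    def __len__(self):
        return len(self.letters)

    def __iter__(self):
        return iter(self.letters)

    def __getitem__(self, i):
        return self.letters[i]


@dataclass
class DihedralPath:
    """Fine-grained chain state: per-residue (phi, psi) angles plus the hidden
    basin state that emitted them.

    phi[0] and psi[-1] are NaN sentinels (undefined at the termini).
    """

    phi: np.ndarray
    psi: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int64)
        L = self.phi.shape[0]
        if self.psi.shape[0] != L or self.states.shape[0] != L:
            raise ValueError("phi, psi and states must have equal length")
        for name, arr in (("phi", self.phi), ("psi", self.psi)):
            finite = arr[np.isfinite(arr)]
            if finite.size and (np.any(finite <= -180.0) or np.any(finite > 180.0)):
                raise ValueError(f"{name} angles must lie in (-180, 180]")

    def __len__(self):
        return self.phi.shape[0]

    def copy(self) -> "DihedralPath":
        return DihedralPath(self.phi.copy(), self.psi.copy(), self.states.copy())


@dataclass(frozen=True)
class GeometryParams:
    """Ideal backbone geometry (Engh--Huber-like defaults).

    Bond lengths in Angstrom, angles in degrees. ``torsion_cb`` is the improper
    dihedral C-N-CA-CB fixing the side-chain pseudo-atom in the local frame;
    the default gives L-amino-acid chirality.
    """

    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_ca_cb: float = 1.521
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.8
    angle_n_ca_cb: float = 110.4
    torsion_cb: float = 122.9
    omega: float = 180.0

    def as_array(self) -> np.ndarray:
        g = np.empty(K.G_NPARAMS)
        g[K.G_B_N_CA] = self.bond_n_ca
        g[K.G_B_CA_C] = self.bond_ca_c
        g[K.G_B_C_N] = self.bond_c_n
        g[K.G_B_C_O] = self.bond_c_o
        g[K.G_B_CA_CB] = self.bond_ca_cb
        g[K.G_A_N_CA_C] = self.angle_n_ca_c
        g[K.G_A_CA_C_N] = self.angle_ca_c_n
        g[K.G_A_C_N_CA] = self.angle_c_n_ca
        g[K.G_A_CA_C_O] = self.angle_ca_c_o
        g[K.G_A_N_CA_CB] = self.angle_n_ca_cb
        g[K.G_T_CB] = self.torsion_cb
        g[K.G_OMEGA] = self.omega
        return g

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryParams":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown geometry parameters: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Conformation:
    """Cartesian backbone coordinates, one row per residue and role.

    ``sc`` rows are NaN where ``sc_mask`` is False (glycine).
    """

    n: np.ndarray
    ca: np.ndarray
    c: np.ndarray
    o: np.ndarray
    sc: np.ndarray
    sc_mask: np.ndarray

    def __len__(self):
        return self.n.shape[0]

    @property
    def n_atoms(self) -> int:
        return 4 * len(self) + int(np.sum(self.sc_mask))

    def atom_records(self):
        """Yield (residue index 1-based, role, position) in canonical order."""
        for i in range(len(self)):
            yield i + 1, "N", self.n[i]
            yield i + 1, "CA", self.ca[i]
            yield i + 1, "C", self.c[i]
            yield i + 1, "O", self.o[i]
            if self.sc_mask[i]:
                yield i + 1, "SC", self.sc[i]

    def coords(self, roles=None) -> np.ndarray:
        """Stacked coordinates for the selected roles (default: all atoms)."""
        roles = BACKBONE_ROLES if roles is None else tuple(roles)
        unknown = set(roles) - set(BACKBONE_ROLES)
        if unknown:
            raise ValueError(f"unknown atom roles: {sorted(unknown)}")
        parts = []
        by_role = {"N": self.n, "CA": self.ca, "C": self.c, "O": self.o}
        for role in roles:
            if role == "SC":
                parts.append(self.sc[self.sc_mask])
            else:
                parts.append(by_role[role])
        return np.concatenate(parts, axis=0)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Conformation":
        """Apply a rigid motion x -> R x + t."""
        rot = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return Conformation(
            self.n @ rot.T + t, self.ca @ rot.T + t, self.c @ rot.T + t,
            self.o @ rot.T + t, self.sc @ rot.T + t, self.sc_mask.copy(),
        )


def build_backbone(dihedrals: DihedralPath, sequence: Sequence,
                   geometry: GeometryParams | None = None) -> Conformation:
    """Build Cartesian coordinates from dihedral angles by chain extension.

    The interior angles phi(2..L) and psi(1..L-1) must be defined (finite);
    the terminal sentinels are ignored.
    """
    geometry = geometry or GeometryParams()
    L = len(dihedrals)
    if L != len(sequence):
        raise ValueError(
            f"dihedral path length {L} does not match sequence length {len(sequence)}")
    phi = dihedrals.phi
    psi = dihedrals.psi
    if not np.all(np.isfinite(phi[1:])) or not np.all(np.isfinite(psi[:-1])):
        raise ValueError("interior phi/psi angles must be finite")
    sc_mask = np.array([aa != "G" for aa in sequence], dtype=np.bool_)
    n, ca, c, o, sc = K.build_chain(phi, psi, sc_mask, geometry.as_array())
    return Conformation(n, ca, c, o, sc, sc_mask)


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Dihedral angle in degrees, IUPAC sign convention, range (-180, 180].

    Right-hand rule about the p2->p3 axis: looking from p2 towards p3, a
    positive angle rotates p1's projection clockwise onto p4's.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if np.linalg.norm(b1) < 1e-10 or nb2 < 1e-10 or np.linalg.norm(b3) < 1e-10:
        raise ValueError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        raise ValueError("three consecutive points are collinear")
    m = np.cross(n1, b2 / nb2)
    ang = -math.degrees(math.atan2(np.dot(m, n2), np.dot(n1, n2)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def measure_backbone_dihedrals(conformation: Conformation) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) arrays measured from coordinates, NaN at the terminal slots.

    phi(i) is the dihedral C(i-1)-N(i)-CA(i)-C(i); psi(i) is
    N(i)-CA(i)-C(i)-N(i+1).
    """
    L = len(conformation)
    phi = np.full(L, UNDEFINED_ANGLE)
    psi = np.full(L, UNDEFINED_ANGLE)
    n, ca, c = conformation.n, conformation.ca, conformation.c
    for i in range(1, L):
        phi[i] = measure_dihedral(c[i - 1], n[i], ca[i], c[i])
    for i in range(L - 1):
        psi[i] = measure_dihedral(n[i], ca[i], c[i], n[i + 1])
    return phi, psi


def radius_of_gyration(conformation: Conformation, roles=None) -> float:
    """Root-mean-square distance (A) of the selected atoms to their unweighted
    centroid. Default selection: all emitted atoms."""
    coords = conformation.coords(roles)
    if coords.shape[0] == 0:
        raise ValueError("empty atom selection")
    centroid = coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((coords - centroid) ** 2, axis=1))))


def write_pdb(conformation: Conformation, sequence: Sequence, path) -> None:
    """Write ATOM records (chain A, 1-based residue numbering) via Bio.PDB.

    The side-chain pseudo-atom is emitted under the atom name CB.
    """
    from Bio.PDB.StructureBuilder import StructureBuilder
    from Bio.PDB.PDBIO import PDBIO

    if len(conformation) != len(sequence):
        raise ValueError("conformation and sequence lengths differ")
    sb = StructureBuilder()
    sb.init_structure("s")
    sb.init_model(0)
    sb.init_chain("A")
    sb.init_seg("    ")
    serial = 1
    names = {"N": ("N", "N"), "CA": ("CA", "C"), "C": ("C", "C"),
             "O": ("O", "O"), "SC": ("CB", "C")}
    current = None
    for resi, role, pos in conformation.atom_records():
        if resi != current:
            sb.init_residue(THREE_LETTER[sequence[resi - 1]], " ", resi, " ")
            current = resi
        name, element = names[role]
        sb.init_atom(name, np.asarray(pos, dtype=float), 0.0, 1.0, " ",
                     name.center(4) if len(name) < 4 else name,
                     serial, element=element)
        serial += 1
    io = PDBIO()
    io.set_structure(sb.get_structure())
    io.save(str(path))


def read_pdb_coords(path) -> np.ndarray:
    """Coordinates of all ATOM records, in file order (round-trip helper)."""
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    return np.array([atom.coord for atom in structure.get_atoms()], dtype=float)
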