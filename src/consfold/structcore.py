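"""Coordinate/sequence data model, PDB I/O and core geometry.

Conventions used throughout the package:

* coordinates in Angstrom, residue numbering 1-based, closed intervals;
* single chain, ``ATOM`` records only (HETATM, insertion codes and
  multi-chain files are rejected);
* helix assignment is torsion-window based (phi within 30 deg of -57,
  psi within 30 deg of -47, minimum run of three residues), not
  hydrogen-bond based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import gemmi
import numpy as np

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA3_TO_1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

#: element guessed from the first letter of a backbone/CB atom name
_ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


class StructureError(ValueError):
    """Raised for malformed structures or unsupported PDB dialects."""


@dataclass(frozen=True)
class Sequence:
    """One-letter amino-acid sequence with 1-based residue numbering."""

    residues: str
    identifier: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = set(self.residues) - set(AA1)
        if bad:
            raise ValueError(f"non-canonical residue codes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, idx):
        return self.residues[idx]


@dataclass
class AtomRecord:
    atom_name: str
    element: str
    residue_index: int  # 1-based
    residue_type: str   # one-letter code
    position: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position components must be finite")
        if self.residue_index < 1:
            raise ValueError("residue_index must be >= 1")


@dataclass
class Model:
    """All-atom coordinate set for one sequence.

    ``coarse_grained`` marks CA-only traces (accepted on input but unusable
    for torsion- or sidechain-level operations).
    """

    sequence: Sequence
    atoms: list[AtomRecord]
    label: str = ""
    coarse_grained: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- access helpers -------------------------------------------------

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def atom_index(self) -> dict[tuple[int, str], int]:
        """(residue_index, atom_name) -> position in ``atoms``."""
        return {(a.residue_index, a.atom_name): i for i, a in enumerate(self.atoms)}

    def ca_coords(self) -> np.ndarray:
        ca = {a.residue_index: a.position for a in self.atoms if a.atom_name == "CA"}
        return np.array([ca[i] for i in range(1, len(self.sequence) + 1)])

    def get_atom(self, residue_index: int, atom_name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.residue_index == residue_index and a.atom_name == atom_name:
                return a
        return None

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Model":
        """Copy of this model with every atom position replaced."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            AtomRecord(a.atom_name, a.element, a.residue_index, a.residue_type, c)
            for a, c in zip(self.atoms, coords)
        ]
        return Model(self.sequence, atoms, label if label is not None else self.label,
                     self.coarse_grained)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        n_res = len(self.sequence)
        seen: dict[int, set[str]] = {}
        for a in self.atoms:
            if a.residue_index > n_res:
                raise StructureError(
                    f"atom {a.atom_name} references residue {a.residue_index} "
                    f"beyond sequence length {n_res}")
            seen.setdefault(a.residue_index, set()).add(a.atom_name)
        for i in range(1, n_res + 1):
            names = seen.get(i, set())
            if not names:
                raise StructureError(f"residue {i} has no atoms")
            if "CA" not in names:
                raise StructureError(f"residue {i} ({self.sequence[i - 1]}) lacks a CA atom")


@dataclass
class Ensemble:
    """Ordered collection of models sharing sequence and atom naming."""

    models: list[Model]
    sequence: Sequence

    def __post_init__(self) -> None:
        if len(self.models) < 1:
            raise ValueError("ensemble must contain at least one model")
        names0 = [(a.residue_index, a.atom_name) for a in self.models[0].atoms]
        for m in self.models:
            if m.sequence.residues != self.sequence.residues:
                raise StructureError("ensemble members must share one sequence")
            names = [(a.residue_index, a.atom_name) for a in m.atoms]
            if names != names0:
                raise StructureError("ensemble members must share atom naming/order")

    def __len__(self) -> int:
        return len(self.models)

    def __iter__(self):
        return iter(self.models)

    def __getitem__(self, i) -> Model:
        return self.models[i]


@dataclass
class TorsionAngles:
    """Backbone phi/psi per residue in degrees; NaN where undefined."""

    phi: np.ndarray
    psi: np.ndarray

    def defined(self) -> np.ndarray:
        return ~(np.isnan(self.phi) | np.isnan(self.psi))


# ----------------------------------------------------------------------
# PDB I/O
# ----------------------------------------------------------------------

def _gemmi_model_to_model(gmodel: gemmi.Model, label: str) -> Model:
    if len(gmodel) != 1:
        raise StructureError(f"expected a single chain, found {len(gmodel)}")
    chain = gmodel[0]
    atoms: list[AtomRecord] = []
    residues: list[tuple[int, str]] = []
    for res in chain:
        if res.het_flag == "H":
            raise StructureError(f"HETATM records are not supported (residue {res.name})")
        if res.seqid.icode not in (" ", "", "\x00"):
            raise StructureError(f"insertion codes are not supported (residue {res.seqid})")
        if res.name not in AA3_TO_1:
            raise StructureError(f"unknown residue type {res.name!r} at {res.seqid.num}")
        one = AA3_TO_1[res.name]
        idx = res.seqid.num
        residues.append((idx, one))
        # altloc policy: highest occupancy, tie -> first listed
        res_atoms = list(res)
        best: dict[str, int] = {}
        for k, atom in enumerate(res_atoms):
            b = best.get(atom.name)
            if b is None or atom.occ > res_atoms[b].occ:
                best[atom.name] = k
        for k, atom in enumerate(res_atoms):  # preserve file order
            if best[atom.name] != k:
                continue
            pos = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
            element = atom.element.name
            if element in ("X", ""):
                element = _ELEMENT_OF.get(atom.name, atom.name[0])
            atoms.append(AtomRecord(atom.name, element, idx, one, pos))
    if not atoms:
        raise StructureError("no ATOM records found")
    indices = [i for i, _ in residues]
    if indices != list(range(indices[0], indices[0] + len(indices))):
        raise StructureError("residue numbering must be consecutive")
    if indices[0] != 1:
        # renumbering is not silently applied; the pipeline is 1-based
        raise StructureError("residue numbering must start at 1")
    seq = Sequence("".join(one for _, one in residues))
    coarse = all(a.atom_name == "CA" for a in atoms)
    return Model(seq, atoms, label=label, coarse_grained=coarse)


def read_pdb(path: str | Path) -> Model:
    """Read a single-chain, ATOM-only PDB file.

    Altloc duplicates keep the highest-occupancy copy (tie: first listed).
    A CA-only trace is accepted and flagged ``coarse_grained``.
    """
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) != 1:
        raise StructureError("multi-model file: use read_ensemble")
    return _gemmi_model_to_model(st[0], label=path.stem)


def read_ensemble(path: str | Path) -> Ensemble:
    """Read a multi-model (MODEL/ENDMDL) PDB file as an Ensemble."""
    path = Path(path)
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    models = [_gemmi_model_to_model(g, label=f"{path.stem}_{k + 1}")
              for k, g in enumerate(st)]
    return Ensemble(models, models[0].sequence)


def _format_atom_line(serial: int, a: AtomRecord) -> str:
    if serial > 99999:
        raise OverflowError("atom serial number exceeds 99999")
    if a.residue_index > 9999:
        raise OverflowError("residue number exceeds 9999")
    name = a.atom_name
    # columns 13-16: names shorter than 4 characters start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    res3 = AA1_TO_3[a.residue_type]
    x, y, z = a.position
    return (f"ATOM  {serial:5d} {name_field} {res3:>3s} A{a.residue_index:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")


def write_pdb(model: Model, path: str | Path) -> None:
    """Write fixed-column ATOM records (occupancy 1.00, B-factor 0.00)."""
    lines = [_format_atom_line(i + 1, a) for i, a in enumerate(model.atoms)]
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble as a MODEL/ENDMDL multi-model PDB file."""
    lines: list[str] = []
    for k, model in enumerate(ensemble):
        lines.append(f"MODEL     {k + 1:4d}")
        lines.extend(_format_atom_line(i + 1, a) for i, a in enumerate(model.atoms))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Superposition
# ----------------------------------------------------------------------

def kabsch_superimpose(coords_a: np.ndarray, coords_b: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` with
    ``coords_a ~ coords_b @ rotation.T + translation``.  The rotation is
    proper (determinant +1; SVD sign correction guards against
    reflections).  Collinear point sets are rejected.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must both be (n, 3) with equal n")
    n = A.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    A0, B0 = A - ca, B - cb
    for X in (A0, B0):
        sv = np.linalg.svd(X, compute_uv=False)
        if sv[1] <= 1e-8 * max(sv[0], 1.0):
            raise ValueError("collinear (degenerate) point set")
    H = B0.T @ A0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - cb @ R.T
    diff = A - (B @ R.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return R, t, rmsd


def ca_rmsd(model_a: Model, model_b: Model) -> float:
    """CA-only Kabsch RMSD between two models of the same sequence."""
    return kabsch_superimpose(model_a.ca_coords(), model_b.ca_coords())[2]


def superimpose_repeats(model: Model, range_a: tuple[int, int],
                        range_b: tuple[int, int]) -> tuple[float, int]:
    """Superimpose two equal-length residue intervals of one model (CA only).

    Intervals are 1-based and closed, e.g. ``(10, 94)``.  Returns the
    Kabsch RMSD and the number of equivalenced CA atoms.  No alignment is
    attempted: the residue correspondence is positional within the
    intervals.
    """
    (a1, a2), (b1, b2) = range_a, range_b
    if a2 - a1 != b2 - b1:
        raise ValueError("residue intervals must have equal length")
    ca = model.ca_coords()
    A = ca[a1 - 1:a2]
    B = ca[b1 - 1:b2]
    _, _, rmsd = kabsch_superimpose(A, B)
    return rmsd, A.shape[0]


# ----------------------------------------------------------------------
# Torsions and helix assignment
# ----------------------------------------------------------------------

def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = math.degrees(math.atan2(-y, x))
    return 180.0 if ang <= -180.0 else ang


def backbone_torsions(model: Model) -> TorsionAngles:
    """Backbone phi/psi per residue; chain termini and residues with
    missing backbone atoms are flagged undefined (NaN), never fabricated."""
    n = len(model.sequence)
    idx = model.atom_index()

    def pos(i: int, name: str):
        j = idx.get((i, name))
        return None if j is None else model.atoms[j].position

    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    for i in range(1, n + 1):
        N, CA, C = pos(i, "N"), pos(i, "CA"), pos(i, "C")
        if i > 1:
            Cprev = pos(i - 1, "C")
            if all(p is not None for p in (Cprev, N, CA, C)):
                phi[i - 1] = dihedral(Cprev, N, CA, C)
        if i < n:
            Nnext = pos(i + 1, "N")
            if all(p is not None for p in (N, CA, C, Nnext)):
                psi[i - 1] = dihedral(N, CA, C, Nnext)
    return TorsionAngles(phi, psi)


HELIX_PHI, HELIX_PSI, HELIX_TOL = -57.0, -47.0, 30.0


def helix_fraction(model: Model, min_run: int = 3) -> float:
    """Fraction of residues in alpha-helical conformation.

    A residue qualifies iff phi is within 30 deg of -57 and psi within
    30 deg of -47, and it belongs to a run of at least ``min_run``
    consecutive qualifying residues.  Residues with undefined torsions
    (including the chain termini) count in the denominator.
    """
    tors = backbone_torsions(model)
    ok = ((np.abs(tors.phi - HELIX_PHI) <= HELIX_TOL)
          & (np.abs(tors.psi - HELIX_PSI) <= HELIX_TOL))
    ok = np.where(np.isnan(tors.phi) | np.isnan(tors.psi), False, ok)
    helical = np.zeros_like(ok)
    n = len(ok)
    i = 0
    while i < n:
        if ok[i]:
            j = i
            while j < n and ok[j]:
                j += 1
            if j - i >= min_run:
                helical[i:j] = True
            i = j
        else:
            i += 1
    return float(helical.sum()) / n
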