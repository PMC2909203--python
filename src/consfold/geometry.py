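"""Internal-coordinate chain building and torsion-space moves.

Backbones are built with ideal covalent geometry (N-CA 1.458, CA-C 1.525,
C-N 1.329 A; standard angles; omega fixed at 180 deg) by natural extension
of reference frames (NeRF).  Torsion changes are applied to existing
coordinates as rigid rotations about the N-CA (phi) or CA-C (psi) bond, so
covalent geometry is preserved exactly — the machinery behind both the
synthetic ensemble perturbation and the annealing moves in model building.
"""

from __future__ import annotations

import math

import numpy as np

from consfold.structcore import AtomRecord, Model, Sequence, dihedral

# ideal backbone geometry
B_N_CA, B_CA_C, B_C_N = 1.458, 1.525, 1.329
B_C_O, B_CA_CB = 1.231, 1.521
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.2, 116.2, 121.7
A_CA_C_O, A_N_CA_CB = 120.8, 110.4
OMEGA = 180.0
# improper C(i-1)...; torsion C-N-CA-CB giving the L configuration
T_CB = -122.6


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position of atom D given A, B, C with |CD|, angle(BCD), torsion(ABCD)."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(sequence: Sequence | str, phi: np.ndarray, psi: np.ndarray,
                   label: str = "") -> Model:
    """Build an all-backbone (+CB except Gly) model from phi/psi angles.

    ``phi[0]`` and ``psi[-1]`` have no structural effect beyond placing the
    first C and last O and may be any finite value.
    """
    seq = sequence if isinstance(sequence, Sequence) else Sequence(sequence)
    n = len(seq)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (n,) or psi.shape != (n,):
        raise ValueError("phi/psi must have one value per residue")

    N = np.zeros((n, 3))
    CA = np.zeros((n, 3))
    C = np.zeros((n, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [B_N_CA, 0.0, 0.0]
    ang = math.radians(A_N_CA_C)
    C[0] = CA[0] + [B_CA_C * -math.cos(ang), B_CA_C * math.sin(ang), 0.0]
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], B_C_N, A_CA_C_N, psi[i])
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], B_N_CA, A_C_N_CA, OMEGA)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], B_CA_C, A_N_CA_C, phi[i + 1])

    atoms: list[AtomRecord] = []
    for i in range(n):
        res = seq[i]
        ridx = i + 1
        atoms.append(AtomRecord("N", "N", ridx, res, N[i]))
        atoms.append(AtomRecord("CA", "C", ridx, res, CA[i]))
        atoms.append(AtomRecord("C", "C", ridx, res, C[i]))
        # O anti to the next N: dihedral N-CA-C-O = psi + 180
        O = place_atom(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi[i] + 180.0)
        atoms.append(AtomRecord("O", "O", ridx, res, O))
        if res != "G":
            CB = place_atom(C[i], N[i], CA[i], B_CA_CB, A_N_CA_CB, T_CB)
            atoms.append(AtomRecord("CB", "C", ridx, res, CB))
    return Model(seq, atoms, label=label)


# ----------------------------------------------------------------------
# Torsion moves on flat coordinate arrays
# ----------------------------------------------------------------------

def _dihedral_fast(p0, p1, p2, p3) -> float:
    """Scalar-math dihedral (same convention as structcore.dihedral);
    avoids numpy overhead in the annealing inner loop."""
    b0x, b0y, b0z = p1[0] - p0[0], p1[1] - p0[1], p1[2] - p0[2]
    b1x, b1y, b1z = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    b2x, b2y, b2z = p3[0] - p2[0], p3[1] - p2[1], p3[2] - p2[2]
    n1x, n1y, n1z = (b0y * b1z - b0z * b1y, b0z * b1x - b0x * b1z,
                     b0x * b1y - b0y * b1x)
    n2x, n2y, n2z = (b1y * b2z - b1z * b2y, b1z * b2x - b1x * b2z,
                     b1x * b2y - b1y * b2x)
    nb = math.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
    m1x, m1y, m1z = ((n1y * b1z - n1z * b1y) / nb, (n1z * b1x - n1x * b1z) / nb,
                     (n1x * b1y - n1y * b1x) / nb)
    x = n1x * n2x + n1y * n2y + n1z * n2z
    y = m1x * n2x + m1y * n2y + m1z * n2z
    ang = math.degrees(math.atan2(-y, x))
    return 180.0 if ang <= -180.0 else ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit ``axis``."""
    axis = axis / np.linalg.norm(axis)
    th = math.radians(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(th) * K + (1 - math.cos(th)) * (K @ K)


class TorsionEngine:
    """Applies phi/psi rotations in place on a model's coordinate array.

    Keeps index tables for the standard atom layout (N, CA, C, O[, CB] per
    residue) so a single move is one vectorized rigid rotation of the
    downstream atoms.
    """

    def __init__(self, model: Model):
        self.model = model
        self.n_res = len(model.sequence)
        self.res_idx = np.array([a.residue_index for a in model.atoms])
        names = [a.atom_name for a in model.atoms]
        idx = model.atom_index()
        self.i_n = np.array([idx[(r, "N")] for r in range(1, self.n_res + 1)])
        self.i_ca = np.array([idx[(r, "CA")] for r in range(1, self.n_res + 1)])
        self.i_c = np.array([idx[(r, "C")] for r in range(1, self.n_res + 1)])
        is_n = np.array([nm == "N" for nm in names])
        is_ca = np.array([nm == "CA" for nm in names])
        is_o = np.array([nm == "O" for nm in names])
        # phi(i): rotate about N(i)->CA(i); moves residue i atoms other
        # than N/CA (C, O, CB rotate together, preserving chirality) plus
        # every later residue.
        self._phi_mask = [
            (self.res_idx > r + 1) | ((self.res_idx == r + 1) & ~is_n & ~is_ca)
            for r in range(self.n_res)
        ]
        # psi(i): rotate about CA(i)->C(i); moves O(i) and later residues.
        self._psi_mask = [
            (self.res_idx > r + 1) | ((self.res_idx == r + 1) & is_o)
            for r in range(self.n_res)
        ]

    def apply_phi(self, coords: np.ndarray, residue: int, delta_deg: float) -> None:
        """Rotate phi of 1-based ``residue`` by ``delta_deg`` in place."""
        r = residue - 1
        p0 = coords[self.i_n[r]]
        axis = coords[self.i_ca[r]] - p0
        R = rotation_about_axis(axis, delta_deg)
        m = self._phi_mask[r]
        coords[m] = (coords[m] - p0) @ R.T + p0

    def apply_psi(self, coords: np.ndarray, residue: int, delta_deg: float) -> None:
        r = residue - 1
        p0 = coords[self.i_ca[r]]
        axis = coords[self.i_c[r]] - p0
        R = rotation_about_axis(axis, delta_deg)
        m = self._psi_mask[r]
        coords[m] = (coords[m] - p0) @ R.T + p0

    def phi(self, coords: np.ndarray, residue: int) -> float:
        r = residue - 1
        if r == 0:
            return math.nan
        return _dihedral_fast(coords[self.i_c[r - 1]], coords[self.i_n[r]],
                              coords[self.i_ca[r]], coords[self.i_c[r]])

    def psi(self, coords: np.ndarray, residue: int) -> float:
        r = residue - 1
        if r == self.n_res - 1:
            return math.nan
        return _dihedral_fast(coords[self.i_n[r]], coords[self.i_ca[r]],
                              coords[self.i_c[r]], coords[self.i_n[r + 1]])

    def set_torsions(self, coords: np.ndarray, residue: int,
                     phi_deg: float | None, psi_deg: float | None) -> None:
        """Set phi/psi of ``residue`` to target values (in place)."""
        if phi_deg is not None and residue > 1:
            cur = self.phi(coords, residue)
            self.apply_phi(coords, residue, phi_deg - cur)
        if psi_deg is not None and residue < self.n_res:
            cur = self.psi(coords, residue)
            self.apply_psi(coords, residue, psi_deg - cur)
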