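"""Synthetic inputs for every pipeline stage.

The generators emulate the study conditions of the refinement protocol:
helical-bundle "native" folds, ensembles of perturbed copies standing in
for structure-prediction server models, a miniature training corpus for
the knowledge-based potential, and sequences carrying a planted
amphipathic helix with a cluster of basic residues (the lysine spacing
mirrors the K169/K172/K179/K183/K186 pattern of PDCD10's alpha-5 helix).

All generators are pure functions of (spec, seed).  Fixtures are
backbone + CB resolution: every downstream scoring term is defined at
that resolution, so full sidechains would add nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from consfold.geometry import TorsionEngine, build_backbone, rotation_about_axis
from consfold.structcore import (
    Ensemble,
    Model,
    Sequence,
    kabsch_superimpose,
)

_HYDRO_POOL = "LIVF"
_POLAR_POOL = "EKSQDTN"
_LOOP_POOL = "GSND"


@dataclass(frozen=True)
class BundleSpec:
    """Geometry of an idealized helical bundle fixture."""

    n_helices: int = 3
    residues_per_helix: int = 12
    loop_length: int = 4
    packing_radius: float = 8.0
    antiparallel: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_helices < 1:
            raise ValueError("n_helices must be >= 1")
        if self.residues_per_helix < 6:
            raise ValueError("residues_per_helix must be >= 6")
        if self.loop_length < 0:
            raise ValueError("loop_length must be >= 0")

    @property
    def n_residues(self) -> int:
        return (self.n_helices * self.residues_per_helix
                + (self.n_helices - 1) * self.loop_length)


@dataclass(frozen=True)
class PerturbSpec:
    """Torsion-noise perturbation emulating server-model diversity."""

    target_rmsd: float = 2.0
    n_models: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_rmsd < 0:
            raise ValueError("target_rmsd must be >= 0")
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")


def bundle_helix_intervals(spec: BundleSpec) -> list[tuple[int, int]]:
    """1-based closed residue intervals occupied by each helix."""
    intervals = []
    start = 1
    for _ in range(spec.n_helices):
        intervals.append((start, start + spec.residues_per_helix - 1))
        start += spec.residues_per_helix + spec.loop_length
    return intervals


def _bundle_sequence(spec: BundleSpec, rng: np.random.Generator) -> str:
    """Heptad-patterned helices (hydrophobic a/d) joined by polar loops."""
    seq: list[str] = []
    for h in range(spec.n_helices):
        for i in range(spec.residues_per_helix):
            if i % 7 in (0, 3):  # heptad a/d positions face the core
                seq.append(_HYDRO_POOL[rng.integers(len(_HYDRO_POOL))])
            else:
                seq.append(_POLAR_POOL[rng.integers(len(_POLAR_POOL))])
        if h < spec.n_helices - 1:
            for _ in range(spec.loop_length):
                seq.append(_LOOP_POOL[rng.integers(len(_LOOP_POOL))])
    return "".join(seq)


def _ideal_helix_model(sequence: str) -> Model:
    n = len(sequence)
    return build_backbone(sequence, np.full(n, -57.0), np.full(n, -47.0))


def _helix_axis(ca: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(centroid, unit axis from N- to C-terminus) of a helical CA trace."""
    centroid = ca.mean(axis=0)
    X = ca - centroid
    _, _, Vt = np.linalg.svd(X)
    axis = Vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    return centroid, axis


def _align_axis(coords: np.ndarray, centroid: np.ndarray, axis: np.ndarray,
                target_axis: np.ndarray, target_center: np.ndarray) -> np.ndarray:
    v = np.cross(axis, target_axis)
    c = float(np.dot(axis, target_axis))
    if np.linalg.norm(v) < 1e-12:
        R = np.eye(3) if c > 0 else rotation_about_axis(
            np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0]),
            180.0)
    else:
        angle = np.degrees(np.arctan2(np.linalg.norm(v), c))
        R = rotation_about_axis(v, angle)
    return (coords - centroid) @ R.T + target_center


def make_bundle(spec: BundleSpec) -> Model:
    """Idealized helical bundle: helices at (phi, psi) = (-57, -47) with
    axes on a circle of ``packing_radius``, joined by extended loops.

    Helix axes run parallel to z, alternating direction when
    ``antiparallel``.  Loop backbones are extended segments laid along the
    straight line joining consecutive helix termini (their junction
    geometry is approximate; helix interiors are ideal).  Deterministic
    per seed.  Raises if the packing radius forces steric overlap.
    """
    rng = np.random.default_rng(spec.seed)
    sequence = _bundle_sequence(spec, rng)
    intervals = bundle_helix_intervals(spec)

    n_total = spec.n_residues
    placed = np.full((0, 3), 0.0)
    per_res_coords: dict[int, dict[str, np.ndarray]] = {}

    helix_ends: list[tuple[np.ndarray, np.ndarray]] = []  # (start N, end C)
    helix_placed = []
    for h, (r1, r2) in enumerate(intervals):
        sub = sequence[r1 - 1:r2]
        hm = _ideal_helix_model(sub)
        ca = hm.ca_coords()
        centroid, axis = _helix_axis(ca)
        theta = 2.0 * np.pi * h / max(spec.n_helices, 2) if spec.n_helices > 1 else 0.0
        target_center = np.array([spec.packing_radius * np.cos(theta),
                                  spec.packing_radius * np.sin(theta), 0.0])
        direction = np.array([0.0, 0.0, 1.0])
        if spec.antiparallel and h % 2 == 1:
            direction = -direction
        coords = _align_axis(hm.coords(), centroid, axis, direction, target_center)
        helix_placed.append((hm, coords, r1))

    # steric feasibility: CA atoms of distinct helices must stay separated
    for a in range(len(helix_placed)):
        for b in range(a + 1, len(helix_placed)):
            ca_a = helix_placed[a][1][[i for i, at in enumerate(helix_placed[a][0].atoms)
                                       if at.atom_name == "CA"]]
            ca_b = helix_placed[b][1][[i for i, at in enumerate(helix_placed[b][0].atoms)
                                       if at.atom_name == "CA"]]
            d = np.sqrt(((ca_a[:, None, :] - ca_b[None, :, :]) ** 2).sum(-1))
            if d.min() < 3.2:
                raise ValueError(
                    f"packing_radius {spec.packing_radius} A too small: helices "
                    f"{a + 1} and {b + 1} clash (min CA-CA {d.min():.2f} A)")

    # assemble atom records helix by helix, loops in between
    from consfold.structcore import AtomRecord
    atoms: list[AtomRecord] = []
    for h, (hm, coords, r1) in enumerate(helix_placed):
        for at, pos in zip(hm.atoms, coords):
            atoms.append(AtomRecord(at.atom_name, at.element,
                                    at.residue_index + r1 - 1, at.residue_type, pos))
        if h < len(helix_placed) - 1 and spec.loop_length > 0:
            # extended loop along the gap between this helix's last C and
            # the next helix's first N
            end_c = coords[[i for i, at in enumerate(hm.atoms)
                            if at.atom_name == "C"][-1]]
            nxt_hm, nxt_coords, nxt_r1 = helix_placed[h + 1]
            start_n = nxt_coords[[i for i, at in enumerate(nxt_hm.atoms)
                                  if at.atom_name == "N"][0]]
            loop_start = intervals[h][1] + 1
            loop_seq = sequence[loop_start - 1:loop_start - 1 + spec.loop_length]
            lm = build_backbone(loop_seq, np.full(spec.loop_length, 180.0),
                                np.full(spec.loop_length, 180.0))
            lca = lm.ca_coords()
            l_centroid, l_axis = _helix_axis(lca) if spec.loop_length >= 2 else (
                lca.mean(axis=0), np.array([1.0, 0.0, 0.0]))
            gap = start_n - end_c
            gap_dir = gap / max(np.linalg.norm(gap), 1e-9)
            mid = (end_c + start_n) / 2.0
            lcoords = _align_axis(lm.coords(), l_centroid, l_axis, gap_dir, mid)
            for at, pos in zip(lm.atoms, lcoords):
                atoms.append(AtomRecord(at.atom_name, at.element,
                                        at.residue_index + loop_start - 1,
                                        at.residue_type, pos))

    model = Model(Sequence(sequence, identifier=f"bundle_seed{spec.seed}"), atoms,
                  label=f"bundle_{spec.n_helices}x{spec.residues_per_helix}_s{spec.seed}")
    assert len(model.sequence) == n_total
    return model


def perturb_ensemble(model: Model, spec: PerturbSpec) -> Ensemble:
    """Ensemble of torsion-noise perturbed copies of ``model``.

    Per member, independent Gaussian noise is added to every phi/psi; the
    common noise scale is calibrated (bisection on a fixed noise draw, so
    the operation stays deterministic per seed) so the mean CA RMSD of the
    members to the source lands within a few percent of ``target_rmsd``.
    """
    rng = np.random.default_rng(spec.seed)
    engine = TorsionEngine(model)
    n_res = len(model.sequence)
    base = model.coords()
    base_ca_idx = engine.i_ca
    z = rng.standard_normal((spec.n_models, 2, n_res))  # fixed draw

    def realize(scale_deg: float) -> list[np.ndarray]:
        out = []
        for m in range(spec.n_models):
            c = base.copy()
            for r in range(2, n_res + 1):
                engine.apply_phi(c, r, scale_deg * z[m, 0, r - 1])
            for r in range(1, n_res):
                engine.apply_psi(c, r, scale_deg * z[m, 1, r - 1])
            out.append(c)
        return out

    def mean_rmsd(coord_sets: list[np.ndarray]) -> float:
        vals = [kabsch_superimpose(base[base_ca_idx], c[base_ca_idx])[2]
                for c in coord_sets]
        return float(np.mean(vals))

    if spec.target_rmsd == 0.0:
        sets = [base.copy() for _ in range(spec.n_models)]
    else:
        lo, hi = 0.0, 2.0
        achieved = mean_rmsd(realize(hi))
        tries = 0
        while achieved < spec.target_rmsd:
            hi *= 2.0
            tries += 1
            if hi > 360.0 or tries > 12:
                raise ValueError(
                    f"target_rmsd {spec.target_rmsd} A unreachable for a "
                    f"{n_res}-residue chain")
            achieved = mean_rmsd(realize(hi))
        for _ in range(24):
            mid = 0.5 * (lo + hi)
            a = mean_rmsd(realize(mid))
            if abs(a - spec.target_rmsd) <= 0.02 * spec.target_rmsd:
                hi = mid
                break
            if a < spec.target_rmsd:
                lo = mid
            else:
                hi = mid
        sets = realize(hi)

    models = [model.with_coords(c, label=f"{model.label}_pert{m + 1}")
              for m, c in enumerate(sets)]
    return Ensemble(models, model.sequence)


def make_rapdf_training(n_structures: int, seed: int = 0) -> list[Model]:
    """Miniature training corpus: a mixture of helical-bundle topologies
    and compact-coil decoys with varied compositions, deterministic per
    seed."""
    if n_structures < 5:
        raise ValueError("need at least 5 training structures")
    rng = np.random.default_rng(seed)
    models: list[Model] = []
    for k in range(n_structures):
        cls = k % 4
        sub_seed = int(rng.integers(2 ** 31))
        if cls == 3:  # coil decoy: random torsions from broad basins
            srng = np.random.default_rng(sub_seed)
            n = int(srng.integers(24, 48))
            seq = "".join((_HYDRO_POOL + _POLAR_POOL)[srng.integers(11)]
                          for _ in range(n))
            basins = np.array([[-60.0, -45.0], [-120.0, 130.0], [-75.0, 150.0]])
            pick = srng.integers(3, size=n)
            phi = basins[pick, 0] + srng.normal(0, 15, n)
            psi = basins[pick, 1] + srng.normal(0, 15, n)
            models.append(build_backbone(seq, phi, psi, label=f"coil_{k}"))
        else:
            n_hel = cls + 2  # 2-, 3-, 4-helix bundles
            spec = BundleSpec(
                n_helices=n_hel,
                residues_per_helix=int(rng.integers(8, 14)),
                loop_length=int(rng.integers(3, 5)),
                packing_radius=float(rng.uniform(7.0, 9.5)),
                antiparallel=True,
                seed=sub_seed,
            )
            models.append(make_bundle(spec))
    return models


def make_amphipathic_sequence(length: int, helix_start: int, helix_len: int,
                              basic_positions: list[int], seed: int = 0) -> Sequence:
    """Sequence with a planted amphipathic helix carrying basic residues.

    Within ``[helix_start, helix_start + helix_len)`` the helical-wheel
    angle (100 deg/residue) decides the face: hydrophobic face gets L/I/F,
    the opposite face S/E/Q; lysine is forced at ``basic_positions``
    (1-based absolute indices inside the window).  Everything outside the
    window is random polar.  Deterministic per seed.
    """
    if helix_start < 1 or helix_start + helix_len - 1 > length:
        raise ValueError("helix window outside sequence")
    bp = list(basic_positions)
    if len(bp) != len(set(bp)):
        raise ValueError("duplicate basic positions")
    for p in bp:
        if not (helix_start <= p < helix_start + helix_len):
            raise ValueError(f"basic position {p} outside the helix window")
    rng = np.random.default_rng(seed)
    polar_out = "STNQEDG"
    seq = [polar_out[rng.integers(len(polar_out))] for _ in range(length)]
    hydro = "LIF"
    polar_in = "SEQ"
    for i in range(helix_start, helix_start + helix_len):
        angle = np.radians(100.0 * (i - helix_start))
        if np.cos(angle) > 0.0:
            seq[i - 1] = hydro[rng.integers(3)]
        else:
            seq[i - 1] = polar_in[rng.integers(3)]
    for p in bp:
        seq[p - 1] = "K"
    return Sequence("".join(seq), identifier=f"amphipathic_s{seed}")
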