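"""Constraint-restrained conformation generation and decoy filtering.

Conformations are generated from an extended chain by basin-hopping
Metropolis annealing in (phi, psi) space: each proposal replaces one
residue's torsions (drawn from a Ramachandran-like prior trained on a
structure corpus, or a small local tweak), the proposal is relaxed by a
short torsion-space FIRE quench driven by an analytic restraint gradient,
and acceptance compares the quenched energies

    U = sum_constraints weight * (d_ij - target)^2  +  vdw_term.

A variable-target schedule activates restraints from short to full
sequence separation over the trajectory, the way torsion-space distance
geometry traditionally ramps its target function.  The whole scheme is a
deliberately simplified, self-contained stand-in for restrained
torsion-angle molecular dynamics: the search space (torsions over ideal
covalent geometry) and the restraint semantics are the same, the dynamics
are not.  The returned conformation of each trajectory is the
lowest-energy state visited, so the final energy never exceeds the
initial one.

Decoy filtering removes half of an ensemble by sequentially applying
RAPDF, the van der Waals term, hydrophobic compactness and
electrostatics, each stage removing an equal share of the worst-scoring
models (remainder at the last stage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from consfold.geometry import build_backbone
from consfold.rapdf import RAPDFTable, score_model
from consfold.structcore import Ensemble, Model, Sequence, backbone_torsions
from consfold.tables import VDW_RADIUS

PRIOR_BIN_DEG = 10.0
PRIOR_NBINS = 36
PRIOR_CLASSES = ("G", "P", "prePro", "generic")


@dataclass
class TorsionPrior:
    """Per-residue-class (phi, psi) bin probabilities over 10-degree bins."""

    probs: dict[str, np.ndarray]  # class -> (36, 36), sums to 1

    def __post_init__(self) -> None:
        for cls, p in self.probs.items():
            if abs(float(p.sum()) - 1.0) > 1e-9:
                raise ValueError(f"probabilities for class {cls} do not sum to 1")

    @staticmethod
    def residue_class(sequence: Sequence | str, residue: int) -> str:
        """Class of 1-based ``residue``: Gly, Pro, pre-Pro or generic."""
        res = sequence[residue - 1]
        if res == "G":
            return "G"
        if res == "P":
            return "P"
        if residue < len(sequence) and sequence[residue] == "P":
            return "prePro"
        return "generic"

    def sample(self, cls: str, rng: np.random.Generator) -> tuple[float, float]:
        """Draw (phi, psi) in degrees: bin by probability, uniform within."""
        cum = self._cumulative(cls)
        flat = int(np.searchsorted(cum, rng.random(), side="right"))
        flat = min(flat, cum.size - 1)
        bi, bj = divmod(flat, PRIOR_NBINS)
        phi = -180.0 + PRIOR_BIN_DEG * (bi + rng.random())
        psi = -180.0 + PRIOR_BIN_DEG * (bj + rng.random())
        return phi, psi

    def _cumulative(self, cls: str) -> np.ndarray:
        cache = getattr(self, "_cum_cache", None)
        if cache is None:
            cache = {}
            object.__setattr__(self, "_cum_cache", cache)
        if cls not in cache:
            cache[cls] = np.cumsum(self.probs[cls].ravel())
        return cache[cls]


def _torsion_bin(angle: float) -> int:
    b = int(math.floor((angle + 180.0) / PRIOR_BIN_DEG))
    return min(max(b, 0), PRIOR_NBINS - 1)


def train_torsion_prior(structures: list[Model]) -> TorsionPrior:
    """Binned (phi, psi) frequencies with add-one smoothing, per residue
    class {Gly, Pro, pre-Pro, generic}."""
    if not structures:
        raise ValueError("empty training set")
    counts = {cls: np.ones((PRIOR_NBINS, PRIOR_NBINS)) for cls in PRIOR_CLASSES}
    for m in structures:
        tors = backbone_torsions(m)
        for i in range(1, len(m.sequence) + 1):
            phi, psi = tors.phi[i - 1], tors.psi[i - 1]
            if np.isnan(phi) or np.isnan(psi):
                continue
            cls = TorsionPrior.residue_class(m.sequence, i)
            counts[cls][_torsion_bin(phi), _torsion_bin(psi)] += 1.0
    probs = {cls: c / c.sum() for cls, c in counts.items()}
    return TorsionPrior(probs)


@dataclass
class BuildConfig:
    """Annealing configuration; defaults follow the published protocol
    counts (fifty rounds of twenty models per constraint set)."""

    rounds: int = 50
    models_per_round: int = 20
    t_start: float = 4.0
    t_end: float = 0.05
    steps: int | None = None       # annealing moves; default: 3 per residue
    local_move_prob: float = 0.5   # share of small-tweak proposals
    local_move_sigma: float = 12.0  # degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1 or self.models_per_round < 1:
            raise ValueError("rounds and models_per_round must be >= 1")
        if not (self.t_start > self.t_end > 0):
            raise ValueError("need t_start > t_end > 0")


class _Energy:
    """Vectorized energy: harmonic consensus restraints + soft-sphere vdW.

    Restraints are sorted by sequence separation so the annealer can apply
    a variable-target schedule (short-range restraints first, the full set
    later) by activating a growing prefix.
    """

    def __init__(self, model: Model, constraint_set) -> None:
        idx = model.atom_index()
        rows = []
        for c in constraint_set.constraints:
            if c.atom_i not in idx or c.atom_j not in idx:
                raise ValueError(
                    f"constraint references missing atom {c.atom_i} or {c.atom_j}")
            rows.append((abs(c.atom_j[0] - c.atom_i[0]), idx[c.atom_i],
                         idx[c.atom_j], c.distance, c.weight))
        rows.sort(key=lambda r: r[0])
        self.seqsep = np.array([r[0] for r in rows], dtype=int)
        self.ci = np.array([r[1] for r in rows], dtype=int)
        self.cj = np.array([r[2] for r in rows], dtype=int)
        self.targets = np.array([r[3] for r in rows])
        self.weights = np.array([r[4] for r in rows])

        resi = np.array([a.residue_index for a in model.atoms])
        radii = np.array([VDW_RADIUS.get(a.element, 1.7) for a in model.atoms])
        iu, ju = np.triu_indices(len(model.atoms), k=1)
        ok = np.abs(resi[iu] - resi[ju]) >= 2
        self.vi, self.vj = iu[ok], ju[ok]
        self.rsum = 0.9 * (radii[self.vi] + radii[self.vj])
        self.rsum2 = self.rsum ** 2

    def n_active(self, max_seqsep: int | None) -> int:
        if max_seqsep is None:
            return len(self.ci)
        return int(np.searchsorted(self.seqsep, max_seqsep, side="right"))

    def __call__(self, coords: np.ndarray, k: int | None = None) -> float:
        u = 0.0
        k = len(self.ci) if k is None else k
        if k:
            ci, cj = self.ci[:k], self.cj[:k]
            diff = coords[ci] - coords[cj]
            d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
            u += float((self.weights[:k] * (d - self.targets[:k]) ** 2).sum())
        diff = coords[self.vi] - coords[self.vj]
        d2 = np.einsum("ij,ij->i", diff, diff)
        clash = d2 < self.rsum2
        if clash.any():  # sqrt only where an overlap is possible
            overlap = self.rsum[clash] - np.sqrt(d2[clash])
            u += float((overlap ** 2).sum())
        return u


def build_conformations(sequence: Sequence | str, constraint_set,
                        prior: TorsionPrior, config: BuildConfig) -> Ensemble:
    """Generate ``rounds * models_per_round`` conformations under one
    constraint set.

    Each trajectory starts from the fully extended chain and anneals with
    per-residue torsion proposals (prior draws mixed with small local
    tweaks); the geometric temperature ladder runs t_start -> t_end.
    Deterministic per (seed, round, model).  Each returned model carries a
    ``build_energy`` attribute with the initial and final energy.
    """
    from consfold._kernels import anneal_trajectory

    seq = sequence if isinstance(sequence, Sequence) else Sequence(sequence)
    n = len(seq)
    template = build_backbone(seq, np.full(n, 180.0), np.full(n, 180.0))
    energy = _Energy(template, constraint_set)  # validates constraint atoms
    steps = config.steps if config.steps is not None else 3 * n
    temps = config.t_start * (config.t_end / config.t_start) ** (
        np.arange(steps) / max(steps - 1, 1))

    # kinematic atom order (per residue N, CA, C, CB, O) makes every
    # torsion's moving set a contiguous suffix
    rank = {"N": 0, "CA": 1, "C": 2, "CB": 3, "O": 4}
    order = sorted(range(len(template.atoms)),
                   key=lambda i: (template.atoms[i].residue_index,
                                  rank[template.atoms[i].atom_name]))
    inv = np.empty(len(order), dtype=int)
    inv[np.array(order)] = np.arange(len(order))
    kin_coords = template.coords()[order]
    kin_index = {}
    for kpos, i in enumerate(order):
        a = template.atoms[i]
        kin_index[(a.residue_index, a.atom_name)] = kpos
    i_n = np.array([kin_index[(r, "N")] for r in range(1, n + 1)], dtype=np.int64)
    i_ca = np.array([kin_index[(r, "CA")] for r in range(1, n + 1)], dtype=np.int64)
    i_c = np.array([kin_index[(r, "C")] for r in range(1, n + 1)], dtype=np.int64)
    i_o = np.array([kin_index[(r, "O")] for r in range(1, n + 1)], dtype=np.int64)

    kin_of = inv[np.arange(len(order))]  # original index -> kinematic pos
    ci = kin_of[energy.ci]
    cj = kin_of[energy.cj]
    vi = kin_of[energy.vi]
    vj = kin_of[energy.vj]

    # variable-target schedule: restraints activate from short to full
    # sequence separation over the first 60% of the trajectory, the way
    # torsion-space distance geometry traditionally ramps its target
    max_sep = int(energy.seqsep.max()) if len(energy.seqsep) else 0
    ramp_end = int(0.6 * steps)
    levels = np.empty(steps, dtype=int)
    if max_sep > 0 and ramp_end > 0:
        levels[:ramp_end] = np.linspace(4, max_sep, ramp_end).astype(int)
        levels[ramp_end:] = max_sep
    else:
        levels[:] = max_sep
    active = np.array([energy.n_active(int(l)) for l in levels], dtype=np.int64)

    res_class = np.array([PRIOR_CLASSES.index(TorsionPrior.residue_class(seq, i))
                          for i in range(1, n + 1)], dtype=np.int64)
    prior_cum = np.stack([prior._cumulative(cls) for cls in PRIOR_CLASSES])

    models: list[Model] = []
    for rnd in range(config.rounds):
        for k in range(config.models_per_round):
            traj_seed = int(np.random.SeedSequence(
                [config.seed, rnd, k]).generate_state(1)[0] % 2 ** 31)
            best, u0, u_final = anneal_trajectory(
                kin_coords, ci, cj, energy.targets, energy.weights,
                vi, vj, energy.rsum, energy.rsum2,
                i_n, i_ca, i_c, i_o, temps, active, res_class, prior_cum,
                config.local_move_prob,
                math.radians(config.local_move_sigma),
                200, traj_seed)
            coords = np.empty_like(best)
            coords[np.array(order)] = best  # back to standard atom order
            m = template.with_coords(coords, label=f"build_r{rnd + 1}m{k + 1}")
            m.build_energy = {"initial": float(u0), "final": float(u_final)}
            models.append(m)
    return Ensemble(models, seq)


# ----------------------------------------------------------------------
# Cartesian relaxation
# ----------------------------------------------------------------------

_BONDS = (("N", "CA", 0), ("CA", "C", 0), ("C", "O", 0), ("CA", "CB", 0),
          ("C", "N", 1))


def relax(model: Model, steps: int = 50, bond_k: float = 10.0,
          step_size: float = 0.02) -> Model:
    """Steepest descent on the soft-sphere clash term with harmonic
    bond-length restraints (targets = input lengths).  Guarded line
    search: a step is only taken if the clash term does not increase, so
    the van der Waals energy is non-increasing by construction."""
    coords = model.coords().copy()
    idx = model.atom_index()
    n_res = len(model.sequence)

    bi, bj = [], []
    for a_name, b_name, off in _BONDS:
        for r in range(1, n_res + 1):
            ka, kb = (r, a_name), (r + off, b_name)
            if ka in idx and kb in idx:
                bi.append(idx[ka])
                bj.append(idx[kb])
    bi = np.array(bi, dtype=int)
    bj = np.array(bj, dtype=int)
    b0 = np.linalg.norm(coords[bi] - coords[bj], axis=1)

    resi = np.array([a.residue_index for a in model.atoms])
    radii = np.array([VDW_RADIUS.get(a.element, 1.7) for a in model.atoms])
    iu, ju = np.triu_indices(len(model.atoms), k=1)
    ok = np.abs(resi[iu] - resi[ju]) >= 2
    vi, vj = iu[ok], ju[ok]
    rsum = 0.9 * (radii[vi] + radii[vj])

    def vdw(c: np.ndarray) -> float:
        d = np.linalg.norm(c[vi] - c[vj], axis=1)
        return float((np.maximum(rsum - d, 0.0) ** 2).sum())

    def grad(c: np.ndarray) -> np.ndarray:
        g = np.zeros_like(c)
        dvec = c[vi] - c[vj]
        d = np.linalg.norm(dvec, axis=1)
        overlap = np.maximum(rsum - d, 0.0)
        act = overlap > 0
        if act.any():
            coef = (-2.0 * overlap[act] / np.maximum(d[act], 1e-9))[:, None]
            f = coef * dvec[act]
            np.add.at(g, vi[act], f)
            np.add.at(g, vj[act], -f)
        bvec = c[bi] - c[bj]
        bd = np.linalg.norm(bvec, axis=1)
        coef = (2.0 * bond_k * (bd - b0) / np.maximum(bd, 1e-9))[:, None]
        fb = coef * bvec
        np.add.at(g, bi, fb)
        np.add.at(g, bj, -fb)
        return g

    v = vdw(coords)
    for _ in range(steps):
        if v <= 1e-12:
            break
        g = grad(coords)
        gn = float(np.abs(g).max())
        if gn < 1e-9:
            break
        lr = step_size / gn
        for _ in range(8):  # backtracking on the clash term
            trial = coords - lr * g
            v_new = vdw(trial)
            if v_new <= v:
                coords, v = trial, v_new
                break
            lr *= 0.5
        else:
            break
    return model.with_coords(coords, label=model.label)


# ----------------------------------------------------------------------
# Sequential four-term filter
# ----------------------------------------------------------------------

FILTER_STAGES = ("rapdf", "vdw", "compactness", "electrostatics")


def stage_removals(n_models: int, keep_fraction: float = 0.5
                   ) -> tuple[int, int, int, int]:
    """Per-stage removal counts: total N - ceil(N*keep) split equally over
    the four stages, remainder removed at the last stage."""
    keep = math.ceil(n_models * keep_fraction)
    total = n_models - keep
    base = total // 4
    return (base, base, base, total - 3 * base)


def sequential_filter(ensemble: Ensemble, table: RAPDFTable,
                      keep_fraction: float = 0.5) -> Ensemble:
    """Keep ceil(N * keep_fraction) models by sequentially removing the
    worst scorers under RAPDF, vdW, compactness and electrostatics.

    Ties (and undefined scores, which sort worst) break by stable input
    order; the output preserves input order.
    """
    models = list(ensemble)
    breakdowns = [score_model(m, table) for m in models]
    removals = stage_removals(len(models), keep_fraction)

    def key(b, stage: str) -> float:
        val = {"rapdf": b.rapdf_normalized, "vdw": b.vdw_energy,
               "compactness": b.compactness,
               "electrostatics": b.electrostatics}[stage]
        return math.inf if val is None else val

    alive = list(range(len(models)))
    for stage, n_remove in zip(FILTER_STAGES, removals):
        if n_remove <= 0:
            continue
        # worst = highest score; stable order keeps the earlier model on ties
        ranked = sorted(alive, key=lambda i: (-key(breakdowns[i], stage), -i))
        drop = set(ranked[:n_remove])
        alive = [i for i in alive if i not in drop]
    survivors = [models[i] for i in alive]
    return Ensemble(survivors, ensemble.sequence)
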