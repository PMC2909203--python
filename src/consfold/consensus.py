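"""Consensus interatomic distances and cutoff-limited constraint sets.

From an ensemble of candidate models sharing one sequence, every
qualifying atom pair (residue separation >= 3) is examined for a sliding
window of width 0.5 A containing the pair's distance in at least four of
the five models (both parameters configurable).  Surviving pairs become
distance constraints, weighted by their RAPDF score rank and by whether
the distance was seen in the whole ensemble or only the quorum, and are
compiled into one-best-per-residue-pair constraint sets at maximal
distance cutoffs of 12, 16 and 20 A.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from consfold.rapdf import RAPDFTable, atom_type
from consfold.structcore import Ensemble

DEFAULT_WINDOW = 0.5
DEFAULT_MIN_SUPPORT = 4
DEFAULT_CUTOFFS = (12.0, 16.0, 20.0)
MIN_SEQSEP = 3

AtomKey = tuple[int, str]  # (1-based residue index, atom name)


@dataclass(frozen=True)
class ConsensusConstraint:
    """One consensus atom-pair distance with provenance and weight."""

    atom_i: AtomKey
    atom_j: AtomKey
    distance: float
    support: int
    rapdf_score: float = 0.0
    weight: float = 1.0

    def residue_pair(self) -> tuple[int, int]:
        return (self.atom_i[0], self.atom_j[0])


@dataclass
class ConstraintSet:
    cutoff: float
    constraints: list[ConsensusConstraint]
    source_ensemble: str = ""

    def __len__(self) -> int:
        return len(self.constraints)

    def write(self, path: str | Path) -> None:
        lines = [f"# cutoff\t{self.cutoff!r}",
                 f"# source\t{self.source_ensemble}",
                 "res_i\tatom_i\tres_j\tatom_j\tdistance\tsupport\trapdf\tweight"]
        for c in self.constraints:
            lines.append(
                f"{c.atom_i[0]}\t{c.atom_i[1]}\t{c.atom_j[0]}\t{c.atom_j[1]}"
                f"\t{float(c.distance)!r}\t{c.support}"
                f"\t{float(c.rapdf_score)!r}\t{float(c.weight)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "ConstraintSet":
        cutoff, source = 0.0, ""
        constraints = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# cutoff"):
                cutoff = float(line.split("\t")[1])
            elif line.startswith("# source"):
                parts = line.split("\t")
                source = parts[1] if len(parts) > 1 else ""
            elif line and not line.startswith("res_i"):
                ri, ai, rj, aj, d, s, r, w = line.split("\t")
                constraints.append(ConsensusConstraint(
                    (int(ri), ai), (int(rj), aj), float(d), int(s),
                    float(r), float(w)))
        return cls(cutoff, constraints, source)

    def write_cyana_limits(self, path_upper: str | Path, path_lower: str | Path,
                           window: float = DEFAULT_WINDOW) -> None:
        """Distance +/- window/2 as upper/lower limit lists (CYANA-style
        ``resno atom resno atom limit`` text rows)."""
        up, lo = [], []
        for c in self.constraints:
            up.append(f"{c.atom_i[0]:4d} {c.atom_i[1]:<4s} {c.atom_j[0]:4d} "
                      f"{c.atom_j[1]:<4s} {c.distance + window / 2:8.3f}")
            lo.append(f"{c.atom_i[0]:4d} {c.atom_i[1]:<4s} {c.atom_j[0]:4d} "
                      f"{c.atom_j[1]:<4s} {max(c.distance - window / 2, 0.0):8.3f}")
        Path(path_upper).write_text("\n".join(up) + "\n")
        Path(path_lower).write_text("\n".join(lo) + "\n")


def best_window_support(values: np.ndarray, window: float) -> tuple[int, float]:
    """Maximal number of values coverable by a width-``window`` interval and
    the mean of the covered values at the best (leftmost) placement.

    Candidate placements with the interval's left edge at each observed
    value are exhaustive for maximizing occupancy.
    """
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    best_count, best_mean = 0, 0.0
    for i in range(n):
        j = int(np.searchsorted(v, v[i] + window, side="right"))
        count = j - i
        if count > best_count:
            best_count = count
            best_mean = float(v[i:j].mean())
    return best_count, best_mean


def extract_consensus(ensemble: Ensemble, window: float = DEFAULT_WINDOW,
                      min_support: int = DEFAULT_MIN_SUPPORT,
                      representative: str = "mean"
                      ) -> list[ConsensusConstraint]:
    """Unweighted consensus constraints from an ensemble.

    For each atom pair with residue separation >= 3, the best placement of
    a sliding interval of width ``window`` is found over the pair's
    per-model distances; if it covers at least ``min_support`` models, one
    constraint is emitted whose distance is the mean (or, with
    ``representative="median"``, the median) of the covered values and
    whose support is the maximal coverage.
    """
    if representative not in ("mean", "median"):
        raise ValueError("representative must be 'mean' or 'median'")
    if len(ensemble) < min_support:
        raise ValueError(
            f"ensemble of {len(ensemble)} models is smaller than "
            f"min_support={min_support}")
    ref = ensemble[0]
    keys: list[AtomKey] = []
    for a in ref.atoms:
        if atom_type(a.atom_name, a.residue_type) is None:
            continue
        keys.append((a.residue_index, a.atom_name))
    index_of = {(a.residue_index, a.atom_name): k for k, a in enumerate(ref.atoms)}
    sel = np.array([index_of[k] for k in keys], dtype=int)
    resi = np.array([k[0] for k in keys])

    stacks = np.stack([cdist(m.coords()[sel], m.coords()[sel]) for m in ensemble])
    iu, ju = np.triu_indices(len(keys), k=1)
    ok = np.abs(resi[iu] - resi[ju]) >= MIN_SEQSEP
    iu, ju = iu[ok], ju[ok]
    dists = stacks[:, iu, ju]  # (n_models, n_pairs)

    # vectorized best-window occupancy over the (small) model axis
    v = np.sort(dists, axis=0).T                       # (n_pairs, n_models)
    inwin = (v[:, None, :] >= v[:, :, None]) & (v[:, None, :] <= v[:, :, None] + window)
    # entry [p, i, j]: value j inside the window anchored at value i
    counts = inwin.sum(axis=2)                         # (n_pairs, n_anchors)
    support = counts.max(axis=1)
    anchor = counts.argmax(axis=1)                     # leftmost best anchor

    out: list[ConsensusConstraint] = []
    for p in np.nonzero(support >= min_support)[0]:
        i0 = int(anchor[p])
        vals = v[p, inwin[p, i0]]
        rep = float(vals.mean()) if representative == "mean" else float(
            np.median(vals))
        ki, kj = keys[iu[p]], keys[ju[p]]
        if (kj[0], kj[1]) < (ki[0], ki[1]):
            ki, kj = kj, ki
        out.append(ConsensusConstraint(ki, kj, rep, int(support[p])))
    return out


def attach_rapdf_weights(constraints: list[ConsensusConstraint], table: RAPDFTable,
                         ensemble_size: int = 5,
                         min_support: int = DEFAULT_MIN_SUPPORT,
                         sequence=None) -> list[ConsensusConstraint]:
    """Score each constraint with the RAPDF table and assign weights.

    weight = support_factor * rank_factor.  support_factor is 1.0 at full
    ensemble support and 0.8 at the quorum minimum (linear in between for
    larger ensembles); rank_factor maps the RAPDF-score rank linearly onto
    (0, 1] with the most favorable (lowest) score at 1.  Ties share the
    better rank.  Passing the ``sequence`` types CB atoms by residue
    class; otherwise CB defaults to the hydrophobic class.
    """
    if not constraints:
        return []
    scored = []
    for c in constraints:
        ta = _constraint_atom_type(c.atom_i, sequence)
        tb = _constraint_atom_type(c.atom_j, sequence)
        s = table.lookup(ta, tb, c.distance)
        scored.append(replace(c, rapdf_score=s))

    vals = np.array([c.rapdf_score for c in scored])
    order = np.argsort(vals, kind="stable")
    m = len(scored)
    rank = np.empty(m, dtype=int)
    # competition ranking: ties share the lowest (best) rank
    sorted_vals = vals[order]
    ranks_sorted = np.empty(m, dtype=int)
    for i in range(m):
        if i > 0 and sorted_vals[i] == sorted_vals[i - 1]:
            ranks_sorted[i] = ranks_sorted[i - 1]
        else:
            ranks_sorted[i] = i + 1
    rank[order] = ranks_sorted

    out = []
    for c, r in zip(scored, rank):
        if ensemble_size == min_support:
            support_factor = 1.0 if c.support >= ensemble_size else 0.8
        else:
            frac = (c.support - min_support) / (ensemble_size - min_support)
            support_factor = 0.8 + 0.2 * min(max(frac, 0.0), 1.0)
        rank_factor = (m - int(r) + 1) / m
        out.append(replace(c, weight=float(support_factor * rank_factor)))
    return out


def _constraint_atom_type(key: AtomKey, sequence=None) -> str:
    name = key[1]
    if name in ("N", "CA", "C", "O"):
        return name
    if sequence is not None:
        from consfold.rapdf import _CLASS_SUFFIX
        from consfold.tables import residue_class
        return "CB_" + _CLASS_SUFFIX[residue_class(sequence.residues[key[0] - 1])]
    return "CB_h"


def compile_constraint_sets(weighted: list[ConsensusConstraint],
                            cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
                            source: str = "",
                            prefer: str = "favorable") -> list[ConstraintSet]:
    """One best constraint per residue pair, per maximal-distance cutoff.

    Within a residue pair the most favorable (lowest) RAPDF score wins
    (``prefer="numeric"`` keeps the numerically largest score instead);
    ties break by larger support, then shorter distance, then
    lexicographic atom names.
    """
    if prefer not in ("favorable", "numeric"):
        raise ValueError("prefer must be 'favorable' or 'numeric'")
    sign = 1.0 if prefer == "favorable" else -1.0
    sets = []
    for cutoff in cutoffs:
        eligible = [c for c in weighted if c.distance <= cutoff]
        best: dict[tuple[int, int], ConsensusConstraint] = {}
        for c in eligible:
            key = c.residue_pair()
            cur = best.get(key)
            if cur is None or _better(c, cur, sign):
                best[key] = c
        constraints = sorted(best.values(),
                             key=lambda c: (c.atom_i[0], c.atom_j[0], c.atom_i[1],
                                            c.atom_j[1]))
        sets.append(ConstraintSet(cutoff, constraints, source))
    return sets


def _better(a: ConsensusConstraint, b: ConsensusConstraint,
            sign: float = 1.0) -> bool:
    ka = (sign * a.rapdf_score, -a.support, a.distance, a.atom_i[1], a.atom_j[1])
    kb = (sign * b.rapdf_score, -b.support, b.distance, b.atom_i[1], b.atom_j[1])
    return ka < kb
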