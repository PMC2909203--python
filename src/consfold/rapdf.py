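"""Knowledge-based scoring: the residue-specific all-atom probability
discriminatory function (RAPDF) and the three auxiliary decoy-filter terms.

The RAPDF is a binned log-odds table over reduced atom-type pairs: for
every pair type the observed distance distribution in a training corpus is
compared against the corpus-wide background,

    score(pair, bin) = -ln[ P(bin | pair) / P(bin) ],

so favorable (native-like) distances score negative.  Atom typing is
reduced to five backbone/CB categories with the CB typed by residue
character class (hydrophobic / polar / positive / negative); the full
167-type scheme of the original RAPDF literature is not trainable from a
desk-scale corpus.

The auxiliary terms are declared stand-ins with standard ranking
semantics: a soft-sphere van der Waals clash penalty, a hydrophobic
compactness ratio, and a screened-charge electrostatic term on CB
pseudo-charges.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from consfold.structcore import Model
from consfold.tables import (
    HYDROPHOBIC,
    NEGATIVE,
    POSITIVE,
    VDW_RADIUS,
    residue_class,
)

ATOM_TYPES = ("N", "CA", "C", "O", "CB_h", "CB_p", "CB_pos", "CB_neg")
_CLASS_SUFFIX = {"hydrophobic": "h", "polar": "p", "positive": "pos", "negative": "neg"}

#: normalization constant placing scores on the scale of the -55
#: correct-topology threshold
NORMALIZATION = 100.0

#: strict threshold below which a normalized score indicates correct topology
CORRECT_TOPOLOGY_THRESHOLD = -55.0

RAPDF_MIN_SEQSEP = 3
VDW_MIN_SEQSEP = 2


def atom_type(atom_name: str, residue_type: str) -> str | None:
    """Reduced type of an atom, or None if the atom is untyped."""
    if atom_name in ("N", "CA", "C", "O"):
        return atom_name
    if atom_name == "CB":
        return "CB_" + _CLASS_SUFFIX[residue_class(residue_type)]
    return None


PAIR_KEYS: list[tuple[str, str]] = [
    tuple(sorted(p)) for p in itertools.combinations_with_replacement(ATOM_TYPES, 2)
]
PAIR_INDEX = {p: k for k, p in enumerate(PAIR_KEYS)}

_TYPE_INDEX = {t: i for i, t in enumerate(ATOM_TYPES)}
_PAIR_LOOKUP = np.zeros((len(ATOM_TYPES), len(ATOM_TYPES)), dtype=int)
for (a, b), k in PAIR_INDEX.items():
    _PAIR_LOOKUP[_TYPE_INDEX[a], _TYPE_INDEX[b]] = k
    _PAIR_LOOKUP[_TYPE_INDEX[b], _TYPE_INDEX[a]] = k


@dataclass
class RAPDFTable:
    """Binned atom-type-pair distance log-odds table."""

    bin_width: float
    r_min: float
    r_max: float
    pseudocount: float
    counts: np.ndarray      # (n_pairs, n_bins)
    log_odds: np.ndarray    # (n_pairs, n_bins)
    training_ids: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def bin_edges(self) -> np.ndarray:
        return self.r_min + self.bin_width * np.arange(self.n_bins + 1)

    def bin_of(self, distance: float | np.ndarray) -> np.ndarray:
        """Half-open bin index [lo, hi); -1 outside [r_min, r_max)."""
        d = np.atleast_1d(np.asarray(distance, dtype=float))
        idx = np.floor((d - self.r_min) / self.bin_width).astype(int)
        idx[(d < self.r_min) | (d >= self.r_max)] = -1
        return idx

    def probabilities(self) -> tuple[np.ndarray, np.ndarray]:
        """(P(bin|pair), P(bin)) with add-pseudocount smoothing."""
        pc = self.pseudocount
        with np.errstate(divide="ignore", invalid="ignore"):
            per_pair = (self.counts + pc) / (
                self.counts.sum(axis=1, keepdims=True) + pc * self.n_bins)
        tot = self.counts.sum(axis=0)
        marginal = (tot + pc) / (tot.sum() + pc * self.n_bins)
        return per_pair, marginal

    def lookup(self, type_a: str, type_b: str, distance: float) -> float:
        k = PAIR_INDEX[tuple(sorted((type_a, type_b)))]
        b = int(self.bin_of(np.array([distance]))[0])
        if b < 0:
            return 0.0
        return float(self.log_odds[k, b])

    # -- persistence (tab-delimited, bit-exact float round-trip) --------

    def write(self, path: str | Path) -> None:
        lines = [
            f"# bin_width\t{self.bin_width!r}",
            f"# r_min\t{self.r_min!r}",
            f"# r_max\t{self.r_max!r}",
            f"# pseudocount\t{self.pseudocount!r}",
            f"# training_ids\t{','.join(self.training_ids)}",
            "pair_a\tpair_b\tbin_lo\tbin_hi\tcount\tlog_odds",
        ]
        edges = self.bin_edges()
        for (a, b), k in PAIR_INDEX.items():
            for j in range(self.n_bins):
                lines.append(
                    f"{a}\t{b}\t{float(edges[j])!r}\t{float(edges[j + 1])!r}\t"
                    f"{float(self.counts[k, j])!r}\t"
                    f"{float(self.log_odds[k, j])!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RAPDFTable":
        meta: dict[str, str] = {}
        rows = []
        for line in Path(path).read_text().splitlines():
            if line.startswith("# "):
                key, _, val = line[2:].partition("\t")
                meta[key] = val
            elif line and not line.startswith("pair_a"):
                rows.append(line.split("\t"))
        bin_width = float(meta["bin_width"])
        r_min = float(meta["r_min"])
        r_max = float(meta["r_max"])
        n_bins = int(round((r_max - r_min) / bin_width))
        counts = np.zeros((len(PAIR_KEYS), n_bins))
        log_odds = np.zeros((len(PAIR_KEYS), n_bins))
        for a, b, lo, hi, cnt, lod in rows:
            k = PAIR_INDEX[tuple(sorted((a, b)))]
            j = int(round((float(lo) - r_min) / bin_width))
            counts[k, j] = float(cnt)
            log_odds[k, j] = float(lod)
        ids = [s for s in meta.get("training_ids", "").split(",") if s]
        return cls(bin_width, r_min, r_max, float(meta["pseudocount"]),
                   counts, log_odds, ids)


@dataclass
class ScoreBreakdown:
    """All scoring terms for one model (dimensionless)."""

    rapdf_raw: float
    rapdf_normalized: float | None  # None when the model has no contacts
    n_contacts: int
    vdw_energy: float
    compactness: float | None       # None when no hydrophobic residue present
    electrostatics: float


def _typed_atoms(model: Model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(coords, type_index, residue_index) for typed atoms of a model."""
    coords, types, resi = [], [], []
    for a in model.atoms:
        t = atom_type(a.atom_name, a.residue_type)
        if t is not None:
            coords.append(a.position)
            types.append(_TYPE_INDEX[t])
            resi.append(a.residue_index)
    return np.array(coords), np.array(types, dtype=int), np.array(resi, dtype=int)


def _count_pairs(model: Model, table: RAPDFTable) -> tuple[np.ndarray, int]:
    """Accumulate (pair, bin) counts of one model into a fresh array."""
    coords, types, resi = _typed_atoms(model)
    counts = np.zeros((len(PAIR_KEYS), table.n_bins))
    d = cdist(coords, coords)
    iu, ju = np.triu_indices(len(coords), k=1)
    sep_ok = np.abs(resi[iu] - resi[ju]) >= RAPDF_MIN_SEQSEP
    dv = d[iu, ju]
    bins = table.bin_of(dv)
    ok = sep_ok & (bins >= 0)
    pk = _PAIR_LOOKUP[types[iu[ok]], types[ju[ok]]]
    np.add.at(counts, (pk, bins[ok]), 1.0)
    return counts, int(ok.sum())


def train_rapdf(structures: list[Model], bin_width: float = 1.0,
                r_min: float = 3.0, r_max: float = 20.0,
                pseudocount: float = 1.0) -> RAPDFTable:
    """Train the log-odds table from a corpus of validated structures.

    Counts accumulate over atom pairs with residue separation >= 3 and
    distance in [r_min, r_max); both conditional and background
    distributions receive add-pseudocount smoothing.
    """
    if not structures:
        raise ValueError("empty training set")
    n_bins = int(round((r_max - r_min) / bin_width))
    table = RAPDFTable(bin_width, r_min, r_max, pseudocount,
                       counts=np.zeros((len(PAIR_KEYS), n_bins)),
                       log_odds=np.zeros((len(PAIR_KEYS), n_bins)),
                       training_ids=[m.label for m in structures])
    for m in structures:
        c, _ = _count_pairs(m, table)
        table.counts += c
    per_pair, marginal = table.probabilities()
    with np.errstate(divide="ignore", invalid="ignore"):
        table.log_odds = -np.log(per_pair / marginal[None, :])
    # pair types never observed (possible only without smoothing) score 0
    table.log_odds[~np.isfinite(table.log_odds)] = 0.0
    return table


def score_model(model: Model, table: RAPDFTable) -> ScoreBreakdown:
    """Full score breakdown: RAPDF raw/normalized plus the three filters.

    ``rapdf_raw`` sums log-odds over qualifying pairs at their binned
    distances; ``rapdf_normalized = 100 * raw / n_contacts`` (flagged None
    for a contact-free model).
    """
    coords, types, resi = _typed_atoms(model)
    d = cdist(coords, coords)
    iu, ju = np.triu_indices(len(coords), k=1)
    sep_ok = np.abs(resi[iu] - resi[ju]) >= RAPDF_MIN_SEQSEP
    bins = table.bin_of(d[iu, ju])
    ok = sep_ok & (bins >= 0)
    pk = _PAIR_LOOKUP[types[iu[ok]], types[ju[ok]]]
    raw = float(table.log_odds[pk, bins[ok]].sum())
    n_contacts = int(ok.sum())
    normalized = NORMALIZATION * raw / n_contacts if n_contacts else None
    return ScoreBreakdown(
        rapdf_raw=raw,
        rapdf_normalized=normalized,
        n_contacts=n_contacts,
        vdw_energy=vdw_term(model),
        compactness=compactness_term(model),
        electrostatics=electrostatics_term(model),
    )


def flag_correct_topology(rapdf_normalized: float) -> bool:
    """True iff the normalized score is strictly better than -55."""
    return rapdf_normalized < CORRECT_TOPOLOGY_THRESHOLD


def vdw_term(model: Model) -> float:
    """Soft-sphere clash penalty over pairs with residue separation >= 2:
    sum of max(0, 0.9*(r_i + r_j) - d)^2, radii per element."""
    coords = model.coords()
    resi = np.array([a.residue_index for a in model.atoms])
    radii = np.array([VDW_RADIUS.get(a.element, 1.7) for a in model.atoms])
    d = cdist(coords, coords)
    iu, ju = np.triu_indices(len(coords), k=1)
    ok = np.abs(resi[iu] - resi[ju]) >= VDW_MIN_SEQSEP
    overlap = 0.9 * (radii[iu[ok]] + radii[ju[ok]]) - d[iu, ju][ok]
    return float((np.maximum(0.0, overlap) ** 2).sum())


def compactness_term(model: Model) -> float | None:
    """Hydrophobic compactness: Rg(hydrophobic CB) / Rg(all CA).

    Lower means a better-buried hydrophobic core.  None when the model
    has no hydrophobic residue with a CB atom.
    """
    cb = np.array([a.position for a in model.atoms
                   if a.atom_name == "CB" and a.residue_type in HYDROPHOBIC])
    if len(cb) == 0:
        return None
    ca = model.ca_coords()

    def rg(x: np.ndarray) -> float:
        c = x - x.mean(axis=0)
        return float(np.sqrt((c ** 2).sum(axis=1).mean()))

    rg_ca = rg(ca)
    if rg_ca == 0.0:
        return None
    return rg(cb) / rg_ca


def electrostatics_term(model: Model) -> float:
    """Screened Coulomb term with unit charges on CB (+1 K/R, -1 D/E) and
    a distance-dependent dielectric (eps = 4d): sum of q_i q_j / (4 d^2)."""
    pos: list[np.ndarray] = []
    q: list[float] = []
    for a in model.atoms:
        if a.atom_name != "CB":
            continue
        if a.residue_type in POSITIVE:
            pos.append(a.position)
            q.append(1.0)
        elif a.residue_type in NEGATIVE:
            pos.append(a.position)
            q.append(-1.0)
    if len(q) < 2:
        return 0.0
    P = np.array(pos)
    Q = np.array(q)
    d = cdist(P, P)
    iu, ju = np.triu_indices(len(Q), k=1)
    return float((Q[iu] * Q[ju] / (4.0 * d[iu, ju] ** 2)).sum())
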