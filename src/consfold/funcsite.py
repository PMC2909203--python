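"""Functional-site analyses on sequences and final models.

Sequence level: hydrophobic moments and amphipathic-helix detection
(Eisenberg consensus scale, 100 deg/residue helical wheel), basic-residue
(Lys/Arg) cluster detection anchored to amphipathic helices, heptad
register assignment, residue composition and sequence-based mass
estimates.  Surface level: Shrake-Rupley accessible surface areas and
desolvation surface patches ranked by atomic solvation parameters
(an octanol/water-transfer style re-parameterization with optimal-
docking-area ranking semantics).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from consfold.structcore import Model, Sequence
from consfold.tables import (
    ASP,
    EISENBERG,
    RESIDUE_MASS,
    VDW_RADIUS,
    WATER_MASS,
    atom_asp_class,
)

WHEEL_ANGLE = 100.0  # degrees per residue of an ideal alpha-helix


@dataclass
class HelixAnnotation:
    """Predicted amphipathic helix: interval, moment, face assignment."""

    start: int  # 1-based, closed
    end: int
    mean_moment: float
    face_hydrophobic: list[bool]  # per residue in [start, end]

    def __post_init__(self) -> None:
        if self.end < self.start + 5:
            raise ValueError("annotation must span at least 6 residues")


@dataclass
class BasicPatch:
    """Cluster of basic residues anchored to an amphipathic helix."""

    helix: HelixAnnotation
    basic_residues: list[tuple[int, str]]
    span: int  # residues between first and last member, inclusive


@dataclass
class SurfacePatch:
    """Desolvation surface patch centered on one surface atom."""

    center_atom: int            # atom index in the model
    member_atoms: list[int]
    oda_score: float
    rank: int


# ----------------------------------------------------------------------
# Sequence analyses
# ----------------------------------------------------------------------

def _window_moment_vector(window: str, angle: float) -> complex:
    total = 0j
    for n, res in enumerate(window):
        try:
            h = EISENBERG[res]
        except KeyError:
            raise ValueError(f"non-canonical residue {res!r}") from None
        total += h * np.exp(1j * math.radians(angle) * n)
    return total


def hydrophobic_moment(sequence_window: str, angle: float = WHEEL_ANGLE) -> float:
    """Eisenberg hydrophobic moment of a window:
    |sum h_n exp(i n angle)| / N."""
    if len(sequence_window) < 6:
        raise ValueError("window must span at least 6 residues")
    return float(abs(_window_moment_vector(sequence_window, angle))) / len(sequence_window)


def find_amphipathic_helices(sequence: Sequence | str, window: int = 18,
                             min_moment: float = 0.25) -> list[HelixAnnotation]:
    """Sliding-window scan for amphipathic segments.

    Maximal runs of windows with moment >= min_moment are merged into one
    annotation; the face assignment marks residues whose helical-wheel
    angle lies within 90 degrees of the mean moment direction.
    """
    seq = sequence.residues if isinstance(sequence, Sequence) else sequence
    n = len(seq)
    if n < window:
        raise ValueError("sequence shorter than the scan window")
    moments = np.array([hydrophobic_moment(seq[i:i + window])
                        for i in range(n - window + 1)])
    hits = moments >= min_moment
    annotations: list[HelixAnnotation] = []
    i = 0
    while i < len(hits):
        if not hits[i]:
            i += 1
            continue
        j = i
        while j < len(hits) and hits[j]:
            j += 1
        start, end = i + 1, j - 1 + window  # merged run, 1-based closed
        vec = _window_moment_vector(seq[start - 1:end], WHEEL_ANGLE)
        phase = math.degrees(np.angle(vec))
        face = []
        for k in range(start, end + 1):
            ang = (WHEEL_ANGLE * (k - start)) % 360.0
            diff = abs((ang - phase + 180.0) % 360.0 - 180.0)
            face.append(diff <= 90.0)
        annotations.append(HelixAnnotation(start, end,
                                           float(moments[i:j].mean()), face))
        i = j
    return annotations


def find_basic_clusters(sequence: Sequence | str, helices: list[HelixAnnotation],
                        min_basic: int = 4, max_span: int = 20,
                        loop_extension: int = 5) -> list[BasicPatch]:
    """Maximal groups of K/R within ``max_span`` residues, anchored to an
    annotated helix (the search region extends ``loop_extension`` residues
    past the helix end, covering a trailing flexible loop)."""
    seq = sequence.residues if isinstance(sequence, Sequence) else sequence
    patches: list[BasicPatch] = []
    for helix in helices:
        lo = helix.start
        hi = min(helix.end + loop_extension, len(seq))
        basics = [(i, seq[i - 1]) for i in range(lo, hi + 1)
                  if seq[i - 1] in ("K", "R")]
        best: list[tuple[int, str]] | None = None
        for a in range(len(basics)):
            group = [basics[a]]
            for b in range(a + 1, len(basics)):
                if basics[b][0] - basics[a][0] + 1 <= max_span:
                    group.append(basics[b])
            if len(group) >= min_basic and (best is None or len(group) > len(best)):
                best = group
        if best is not None:
            span = best[-1][0] - best[0][0] + 1
            patches.append(BasicPatch(helix, best, span))
    return patches


def residue_composition(sequence: Sequence | str) -> dict[str, int]:
    """Exact per-residue-type counts; values sum to the sequence length."""
    seq = sequence.residues if isinstance(sequence, Sequence) else sequence
    return dict(Counter(seq))


def estimate_mw(sequence: Sequence | str, n_copies: int = 1) -> float:
    """Average-isotope molecular weight in Da: residue masses plus one
    water per chain, times ``n_copies`` (no inter-chain bonds)."""
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    seq = sequence.residues if isinstance(sequence, Sequence) else sequence
    chain = sum(RESIDUE_MASS[r] for r in seq) + WATER_MASS
    return n_copies * chain


def detect_heptad_repeats(sequence: Sequence | str,
                          helices: list[HelixAnnotation]
                          ) -> list[dict | None]:
    """Best heptad (a-g) register per helix.

    For each of the 7 frames, the mean Eisenberg hydrophobicity at the
    a/d positions is compared with the helix-wide mean; the frame with
    the largest margin wins.  Helices shorter than 14 residues yield
    None (register undefined)."""
    seq = sequence.residues if isinstance(sequence, Sequence) else sequence
    out: list[dict | None] = []
    for helix in helices:
        length = helix.end - helix.start + 1
        if length < 14:
            out.append(None)
            continue
        h = np.array([EISENBERG[seq[i - 1]]
                      for i in range(helix.start, helix.end + 1)])
        overall = float(h.mean())
        best_frame, best_margin = 0, -math.inf
        for frame in range(7):
            ad = [(i + frame) % 7 in (0, 3) for i in range(length)]
            margin = float(h[np.array(ad)].mean()) - overall
            if margin > best_margin:
                best_frame, best_margin = frame, margin
        out.append({"frame": best_frame, "margin": best_margin,
                    "register": "".join("abcdefg"[(i + best_frame) % 7]
                                        for i in range(length))})
    return out


# ----------------------------------------------------------------------
# Surface analyses
# ----------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere.

    Golden-spiral construction, made antipodally symmetric (each point is
    paired with its inversion) so mirror-symmetric atom arrangements get
    exactly equal areas."""
    half = max(n // 2, 1)
    k = np.arange(half) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / (2 * half))
    theta = math.pi * (1.0 + math.sqrt(5.0)) * k
    pts = np.stack([np.sin(phi) * np.cos(theta),
                    np.sin(phi) * np.sin(theta),
                    np.cos(phi)], axis=1)
    return np.concatenate([pts, -pts], axis=0)


def sasa(model: Model, probe: float = 1.4, n_points: int = 240) -> np.ndarray:
    """Shrake-Rupley accessible surface area per atom (A^2)."""
    coords = model.coords()
    radii = np.array([VDW_RADIUS.get(a.element, 1.7) for a in model.atoms]) + probe
    pts = _sphere_points(n_points)
    tree = cKDTree(coords)
    areas = np.zeros(len(coords))
    rmax = radii.max()
    for i, (c, r) in enumerate(zip(coords, radii)):
        neighbors = [j for j in tree.query_ball_point(c, r + rmax) if j != i]
        test = c + r * pts
        free = np.ones(n_points, dtype=bool)
        for j in neighbors:
            free &= ((test - coords[j]) ** 2).sum(axis=1) > radii[j] ** 2
        areas[i] = 4.0 * math.pi * r * r * free.sum() / n_points
    return areas


SURFACE_SASA_MIN = 1.0  # A^2; atoms below this never seed or join patches


def oda_patches(model: Model, patch_radius: float = 10.0,
                areas: np.ndarray | None = None) -> list[SurfacePatch]:
    """Desolvation surface patches ranked most-favorable first.

    Every surface atom seeds a candidate patch of surface atoms within
    ``patch_radius``; the patch score sums ASP(atom class) * SASA(atom)
    over members (negative = favorable to desolvate = candidate
    interface).  Overlapping candidates are pruned greedily: the best
    patch is kept and any later candidate centered inside a kept patch is
    dropped.
    """
    if areas is None:
        areas = sasa(model)
    coords = model.coords()
    surface = np.nonzero(areas > SURFACE_SASA_MIN)[0]
    if len(surface) == 0:
        return []
    asp = np.array([ASP[atom_asp_class(a.atom_name, a.element, a.residue_type)]
                    for a in model.atoms])
    contrib = asp * areas
    tree = cKDTree(coords[surface])
    candidates = []
    for s_idx, atom_idx in enumerate(surface):
        members = surface[tree.query_ball_point(coords[atom_idx], patch_radius)]
        score = float(contrib[members].sum())
        candidates.append((score, int(atom_idx), [int(m) for m in members]))
    candidates.sort(key=lambda t: (t[0], t[1]))
    kept: list[SurfacePatch] = []
    covered: set[int] = set()
    for score, center, members in candidates:
        if center in covered:
            continue
        kept.append(SurfacePatch(center, members, score, rank=len(kept)))
        covered.update(members)
    return kept


def write_patches(patches: list[SurfacePatch], path: str | Path) -> None:
    lines = ["rank\tcenter_atom\toda_score\tn_members\tmember_atoms"]
    for p in patches:
        lines.append(f"{p.rank}\t{p.center_atom}\t{p.oda_score!r}\t"
                     f"{len(p.member_atoms)}\t{','.join(map(str, p.member_atoms))}")
    Path(path).write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Packaged reference sequence
# ----------------------------------------------------------------------

def read_fasta(path: str | Path) -> Sequence:
    """Read the first record of a plain-text FASTA file."""
    header = ""
    chunks: list[str] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            if chunks:
                break
            header = line[1:].strip()
        elif line.strip():
            chunks.append(line.strip())
    if not chunks:
        raise ValueError(f"no sequence found in {path}")
    return Sequence("".join(chunks), identifier=header)


def write_fasta(sequence: Sequence, path: str | Path, width: int = 60) -> None:
    lines = [f">{sequence.identifier or 'sequence'}"]
    for i in range(0, len(sequence), width):
        lines.append(sequence.residues[i:i + width])
    Path(path).write_text("\n".join(lines) + "\n")


def pdcd10_sequence() -> Sequence:
    """The 212-residue PDCD10 (CCM3) reference sequence packaged with the
    library (21 Lys, 21 Glu; the five alpha-5 lysines sit at
    K169/K172/K179/K183/K186)."""
    ref = resources.files("consfold").joinpath("data/pdcd10.fasta")
    with resources.as_file(ref) as path:
        return read_fasta(path)
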